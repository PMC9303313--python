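"""Independent oracles for the alignment scan, kept structurally separate
from the implementation they check.

``naive_semi_global`` fills the full DP matrix row-by-row with numpy
(vectorized along the text using the unit-cost prefix-min trick) -- a
different axis order and data layout from the package's column-wise scan.
``brute_force_min_substring_distance`` enumerates every substring and runs
a plain global edit distance; exponential-free but O(n^2 m), so only for
tiny texts.  ``edlib_infix`` wraps the edlib C library in infix (HW) mode.
"""

import edlib
import numpy as np


def naive_semi_global(pattern: str, text: str) -> int:
    m, n = len(pattern), len(text)
    p = np.frombuffer(pattern.encode(), dtype=np.uint8)
    t = np.frombuffer(text.encode(), dtype=np.uint8)
    steps = np.arange(n + 1)
    row = np.zeros(n + 1, dtype=np.int64)  # free start in text
    for i in range(m):
        sub = np.empty(n + 1, dtype=np.int64)
        sub[0] = i + 1  # column 0: pattern prefix deleted
        sub[1:] = row[:-1] + (t != p[i])
        cand = np.minimum(sub, np.r_[i + 1, row[1:] + 1])
        # resolve left-to-right (insertion) dependency: unit-cost prefix min
        row = np.minimum.accumulate(cand - steps) + steps
    return int(row.min())


def global_edit_distance(a: str, b: str) -> int:
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j - 1] + (ca != cb), prev[j] + 1, cur[-1] + 1))
        prev = cur
    return prev[-1]


def brute_force_min_substring_distance(pattern: str, text: str) -> int:
    best = len(pattern)  # empty substring: delete everything
    for i in range(len(text)):
        for j in range(i + 1, len(text) + 1):
            best = min(best, global_edit_distance(pattern, text[i:j]))
    return best


def edlib_infix(pattern: str, text: str) -> int:
    res = edlib.align(pattern, text, mode="HW", task="distance")
    d = res["editDistance"]
    return len(pattern) if d == -1 else min(d, len(pattern))


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))
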