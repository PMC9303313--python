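"""Approximate complementarity search of ASOs against a transcriptome.

The complementarity measure is the distance *d*: the total number of
mismatches, insertions and deletions (unit-cost Levenshtein) in the best
semi-global alignment of the reverse complement of the ASO against a
transcript sense strand -- the pattern aligns end-to-end, the text ends are
free.  Genes are grouped by their minimal d over all transcripts into the
classes d0, d1, d2 and d3plus (d >= 3 pooled).

Candidate ASOs intended to be transcriptome-naive are screened by
excluding every sequence with a complementary region at d <= 1 ("perfect
match or 1-mismatch").  Because public search engines offer both a full
edit distance and a substitution-only distance, the screen supports an
``edit`` (Levenshtein) and a ``mismatch_only`` (Hamming) mode.

Patterns here are short (~14 nt) and searches desk-scale, so the scan is a
plain dynamic program; no index structure is built.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from gapmertox.gapmer import GapmerASO, normalize_sequence, reverse_complement

__all__ = [
    "OffTargetHit",
    "GeneDistanceMap",
    "d_class",
    "semi_global_distance",
    "scan_transcript",
    "classify_offtargets",
    "exclusion_screen",
    "hamming_min",
]

Transcripts = Union[Mapping[str, str], Iterable[tuple[str, str]]]

D_CLASSES = ("d0", "d1", "d2", "d3plus")


def d_class(d: int) -> str:
    """Pooled distance-class label: d0, d1, d2, or d3plus for d >= 3."""
    if d < 0:
        raise ValueError("distance must be non-negative")
    return f"d{d}" if d < 3 else "d3plus"


@dataclass(frozen=True)
class OffTargetHit:
    """One approximate complementary match of an ASO in a transcript.

    ``start``/``end`` are 0-based half-open offsets on the transcript sense
    strand; ``d == n_mismatch + n_ins + n_del`` where insertions/deletions
    are counted relative to the query (an insertion is an unmatched
    transcript base, a deletion an unmatched query base).
    """

    aso_id: str
    transcript_id: str
    start: int
    end: int
    d: int
    n_mismatch: int
    n_ins: int
    n_del: int
    aligned_query: str
    aligned_target: str


def _last_row(pattern: str, text: str) -> list[int]:
    """Semi-global DP: minimal edit distance of ``pattern`` against the
    substring of ``text`` ending at each position j (j = 0..len(text))."""
    m = len(pattern)
    col = list(range(m + 1))
    out = [m]
    for ch in text:
        prev = col
        col = [0] * (m + 1)
        for i in range(1, m + 1):
            a = prev[i - 1] + (pattern[i - 1] != ch)
            b = prev[i] + 1
            c = col[i - 1] + 1
            col[i] = a if a <= b and a <= c else (b if b <= c else c)
        out.append(col[m])
    return out


def semi_global_distance(pattern: str, text: str) -> int:
    """Minimum edit distance between ``pattern`` and any substring of ``text``.

    Unit costs for mismatch, insertion and deletion; the pattern aligns
    end-to-end, text ends are free.  An empty text yields ``len(pattern)``
    (the pattern must be fully deleted); an empty pattern is an error.
    """
    pattern = normalize_sequence(pattern)
    text = normalize_sequence(text)
    if not pattern:
        raise ValueError("empty pattern")
    return min(_last_row(pattern, text))


def _traceback(pattern: str, window: str) -> tuple[int, int, int, int, str, str]:
    """Full DP + traceback of ``pattern`` vs ``window`` with free window
    start and the alignment forced to end at the window end.

    Returns (start_in_window, n_mismatch, n_ins, n_del, aligned_query,
    aligned_target).  Ties prefer match/mismatch over gaps (fewest indels).
    """
    m, n = len(pattern), len(window)
    D = [[0] * (n + 1) for _ in range(m + 1)]
    for i in range(1, m + 1):
        D[i][0] = i
    for i in range(1, m + 1):
        row, above = D[i], D[i - 1]
        pc = pattern[i - 1]
        for j in range(1, n + 1):
            a = above[j - 1] + (pc != window[j - 1])
            b = above[j] + 1
            c = row[j - 1] + 1
            row[j] = a if a <= b and a <= c else (b if b <= c else c)
    i, j = m, n
    q_parts: list[str] = []
    t_parts: list[str] = []
    n_mm = n_ins = n_del = 0
    while i > 0:
        here = D[i][j]
        sub = pattern[i - 1] != window[j - 1] if j > 0 else None
        if j > 0 and D[i - 1][j - 1] + (1 if sub else 0) == here:
            q_parts.append(pattern[i - 1])
            t_parts.append(window[j - 1])
            n_mm += 1 if sub else 0
            i -= 1
            j -= 1
        elif D[i - 1][j] + 1 == here:
            q_parts.append(pattern[i - 1])
            t_parts.append("-")
            n_del += 1
            i -= 1
        else:
            q_parts.append("-")
            t_parts.append(window[j - 1])
            n_ins += 1
            j -= 1
    return j, n_mm, n_ins, n_del, "".join(reversed(q_parts)), "".join(reversed(t_parts))


def scan_transcript(
    aso: GapmerASO,
    transcript: tuple[str, str],
    d_max: int,
) -> list[OffTargetHit]:
    """All non-redundant complementary matches of ``aso`` at distance <= d_max.

    The reverse complement of the ASO sequence is scanned along the
    transcript sense strand.  Overlapping candidate alignments of the same
    local site are merged keeping the lowest d (ties: leftmost start, then
    fewest indels).
    """
    if d_max < 0:
        raise ValueError("d_max must be >= 0")
    transcript_id, seq = transcript
    text = normalize_sequence(seq)
    if not text:
        return []
    pattern = reverse_complement(aso.sequence)
    m = len(pattern)
    last = _last_row(pattern, text)
    raw: list[OffTargetHit] = []
    for j in range(1, len(text) + 1):
        if last[j] > d_max:
            continue
        w_start = max(0, j - m - d_max)
        k, n_mm, n_ins, n_del, aq, at = _traceback(pattern, text[w_start:j])
        raw.append(
            OffTargetHit(
                aso_id=aso.id,
                transcript_id=transcript_id,
                start=w_start + k,
                end=j,
                d=last[j],
                n_mismatch=n_mm,
                n_ins=n_ins,
                n_del=n_del,
                aligned_query=aq,
                aligned_target=at,
            )
        )
    return _merge_overlapping(raw)


def _merge_overlapping(hits: list[OffTargetHit]) -> list[OffTargetHit]:
    """Keep one hit per overlapping local region: lowest d, then leftmost
    start, then fewest indels."""
    if not hits:
        return []
    hits = sorted(hits, key=lambda h: (h.start, h.end))
    groups: list[list[OffTargetHit]] = [[hits[0]]]
    reach = hits[0].end
    for h in hits[1:]:
        if h.start < reach:
            groups[-1].append(h)
        else:
            groups.append([h])
        reach = max(reach, h.end)
    return [
        min(g, key=lambda h: (h.d, h.start, h.n_ins + h.n_del))
        for g in groups
    ]


@dataclass
class GeneDistanceMap:
    """Per-gene minimal distance of one ASO against a transcriptome.

    Genes with no hit at the scan's d_max are absent and treated as
    d >= 3 ('d3plus') downstream.
    """

    aso_id: str
    min_d: dict[str, int]

    def class_of(self, gene_id: str) -> str:
        d = self.min_d.get(gene_id)
        return "d3plus" if d is None else d_class(d)

    def genes_at_most(self, d_cutoff: int) -> list[str]:
        return [g for g, d in self.min_d.items() if d <= d_cutoff]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"aso_id": self.aso_id, "gene_id": g, "min_d": d, "class": d_class(d)}
            for g, d in sorted(self.min_d.items())
        ]
        return pd.DataFrame(rows, columns=["aso_id", "gene_id", "min_d", "class"])

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, aso_id: Optional[str] = None) -> "GeneDistanceMap":
        if aso_id is None:
            ids = frame["aso_id"].unique()
            if len(ids) != 1:
                raise ValueError(f"expected a single aso_id, got {list(ids)}")
            aso_id = ids[0]
        sub = frame[frame["aso_id"] == aso_id]
        return cls(aso_id=aso_id, min_d=dict(zip(sub["gene_id"], sub["min_d"].astype(int))))


def _as_items(transcripts: Transcripts) -> list[tuple[str, str]]:
    if isinstance(transcripts, Mapping):
        return list(transcripts.items())
    return list(transcripts)


def classify_offtargets(
    aso: GapmerASO,
    transcripts: Transcripts,
    tx2gene: Optional[Mapping[str, str]] = None,
    d_max: int = 3,
) -> GeneDistanceMap:
    """Group genes by minimal complementarity distance to ``aso``.

    ``tx2gene`` maps transcript ids to gene ids (identity if omitted);
    transcripts without a mapping raise a ``KeyError`` listing offenders.
    The minimum d is taken over all transcripts (isoforms) of a gene.
    """
    items = _as_items(transcripts)
    if tx2gene is not None:
        missing = [tid for tid, _ in items if tid not in tx2gene]
        if missing:
            raise KeyError(f"transcripts without gene mapping: {missing}")
    min_d: dict[str, int] = {}
    for tid, seq in items:
        hits = scan_transcript(aso, (tid, seq), d_max)
        if not hits:
            continue
        gene = tx2gene[tid] if tx2gene is not None else tid
        best = min(h.d for h in hits)
        if gene not in min_d or best < min_d[gene]:
            min_d[gene] = best
    return GeneDistanceMap(aso_id=aso.id, min_d=min_d)


def hamming_min(pattern: str, text: str) -> float:
    """Minimum Hamming distance of ``pattern`` over all equal-length windows
    of ``text``; ``inf`` if the text is shorter than the pattern."""
    pattern = normalize_sequence(pattern)
    text = normalize_sequence(text)
    m = len(pattern)
    if m == 0:
        raise ValueError("empty pattern")
    if len(text) < m:
        return math.inf
    t = np.frombuffer(text.encode("ascii"), dtype=np.uint8)
    p = np.frombuffer(pattern.encode("ascii"), dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(t, m)
    return int((windows != p).sum(axis=1).min())


def exclusion_screen(
    candidates: Sequence[str],
    transcripts: Transcripts,
    mode: str = "edit",
    d_exclude: int = 1,
) -> pd.DataFrame:
    """Transcriptome-exclusion screen for candidate ASO sequences.

    A candidate *passes* iff no complementary region at distance
    <= ``d_exclude`` (default 1: perfect match or single mismatch/edit)
    exists in any transcript.  ``mode='edit'`` uses the full Levenshtein
    distance; ``mode='mismatch_only'`` the substitution-only (Hamming)
    distance.  Returns a frame with columns sequence, best_d, passed;
    best_d is ``inf`` when the transcriptome is empty (audit column).
    """
    if mode not in ("edit", "mismatch_only"):
        raise ValueError(f"unknown screen mode {mode!r}")
    items = _as_items(transcripts)
    rows = []
    for cand in candidates:
        seq = normalize_sequence(cand)
        pattern = reverse_complement(seq)
        best: float = math.inf
        for _, tx in items:
            if mode == "edit":
                d: float = semi_global_distance(pattern, tx)
            else:
                d = hamming_min(pattern, tx)
            if d < best:
                best = d
            if best == 0:
                break
        rows.append({"sequence": seq, "best_d": best, "passed": best > d_exclude})
    return pd.DataFrame(rows, columns=["sequence", "best_d", "passed"])
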