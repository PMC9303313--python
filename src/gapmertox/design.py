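"""Random candidate generation and the design-selection funnel.

Candidate gapmer sequences (14-mers by default) are drawn uniformly at
random, screened against a transcriptome to exclude anything with a
complementary region at d <= 1, and optionally filtered to sequences
carrying at least one motif of interest (TGC/TCC by default).  The manual
curation used in practice to pick a final panel is replaced by explicit,
configurable filters with a full audit trail: every stage count in the
report is reproducible from the stored intermediate lists.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from gapmertox.gapmer import count_motifs
from gapmertox.offtarget import Transcripts, exclusion_screen

__all__ = ["DesignConfig", "FunnelReport", "generate_candidates", "design_funnel"]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class DesignConfig:
    """Parameters of one design run.

    gc_bounds is an optional (lo, hi) band on GC fraction and
    max_homopolymer an optional cap on the longest single-base run;
    both default to no constraint.
    """

    k: int = 14
    n_raw: int = 100
    seed: int = 0
    motif_list: tuple[str, ...] = ("TGC", "TCC")
    require_motif: bool = False
    screen_mode: str = "edit"
    gc_bounds: Optional[tuple[float, float]] = None
    max_homopolymer: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_raw < 1:
            raise ValueError("n_raw must be >= 1")
        if self.motif_list and self.k < max(len(m) for m in self.motif_list):
            raise ValueError("k must be >= the longest motif")


def _gc_fraction(seq: str) -> float:
    return (seq.count("G") + seq.count("C")) / len(seq)


def _max_run(seq: str) -> int:
    best = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


def _satisfies(seq: str, cfg: DesignConfig) -> bool:
    if cfg.gc_bounds is not None:
        lo, hi = cfg.gc_bounds
        if not (lo <= _gc_fraction(seq) <= hi):
            return False
    if cfg.max_homopolymer is not None and _max_run(seq) > cfg.max_homopolymer:
        return False
    return True


def generate_candidates(cfg: DesignConfig, max_draw_factor: int = 1000) -> list[str]:
    """Draw ``cfg.n_raw`` unique random k-mers over ACGT, deterministically
    per seed.

    Uniform per-position base draws, then uniqueness and (optional)
    GC/homopolymer constraints.  Raises if ``n_raw`` exceeds the number of
    distinct k-mers or the retry budget (``max_draw_factor * n_raw`` draws)
    is exhausted -- the latter signals infeasible constraints.
    """
    if 4 ** min(cfg.k, 32) < cfg.n_raw:
        raise ValueError(f"cannot draw {cfg.n_raw} unique {cfg.k}-mers: only {4 ** cfg.k} exist")
    rng = np.random.default_rng(cfg.seed)
    out: list[str] = []
    seen: set[str] = set()
    budget = max_draw_factor * cfg.n_raw
    while len(out) < cfg.n_raw:
        if budget <= 0:
            raise RuntimeError(
                f"candidate generation exhausted its retry budget with "
                f"{len(out)}/{cfg.n_raw} sequences; constraints look infeasible"
            )
        batch = min(budget, max(cfg.n_raw - len(out), 64))
        budget -= batch
        draws = rng.integers(0, 4, size=(batch, cfg.k))
        for row in draws:
            seq = "".join(_BASES[row])
            if seq in seen or not _satisfies(seq, cfg):
                continue
            seen.add(seq)
            out.append(seq)
            if len(out) == cfg.n_raw:
                break
    return out


@dataclass
class FunnelReport:
    """Audit trail of one design funnel run.

    Stage counts are monotone non-increasing: raw candidates -> sequences
    passing the exclusion screen -> sequences satisfying the motif filter.
    ``survivors`` is the final list and ``motif_counts`` its per-sequence
    motif occurrence table.
    """

    config: DesignConfig
    raw: list[str]
    screen_passing: list[str]
    survivors: list[str]
    motif_counts: dict[str, dict[str, int]] = field(default_factory=dict)

    @property
    def n_raw(self) -> int:
        return len(self.raw)

    @property
    def n_screen_pass(self) -> int:
        return len(self.screen_passing)

    @property
    def n_survivors(self) -> int:
        return len(self.survivors)

    def to_json(self) -> str:
        payload = {
            "parameters": {
                "k": self.config.k,
                "n_raw": self.config.n_raw,
                "seed": self.config.seed,
                "motif_list": list(self.config.motif_list),
                "require_motif": self.config.require_motif,
                "screen_mode": self.config.screen_mode,
                "gc_bounds": self.config.gc_bounds,
                "max_homopolymer": self.config.max_homopolymer,
            },
            "stage_counts": {
                "raw": self.n_raw,
                "screen_pass": self.n_screen_pass,
                "survivors": self.n_survivors,
            },
            "survivors": self.survivors,
            "motif_counts": self.motif_counts,
        }
        return json.dumps(payload, indent=2)


def design_funnel(cfg: DesignConfig, transcripts: Transcripts) -> FunnelReport:
    """Run the full selection funnel: generate, screen, motif-filter.

    The exclusion screen removes every candidate with a complementary
    region at d <= 1 in the transcriptome (mode per ``cfg.screen_mode``);
    with ``require_motif`` the survivors are additionally restricted to
    sequences carrying >= 1 occurrence of some motif in ``cfg.motif_list``.
    """
    raw = generate_candidates(cfg)
    screened = exclusion_screen(raw, transcripts, mode=cfg.screen_mode)
    passing = [s for s, ok in zip(screened["sequence"], screened["passed"]) if ok]
    counts = {s: count_motifs(s, cfg.motif_list) for s in passing}
    if cfg.require_motif:
        survivors = [s for s in passing if any(c > 0 for c in counts[s].values())]
    else:
        survivors = list(passing)
    return FunnelReport(
        config=cfg,
        raw=raw,
        screen_passing=passing,
        survivors=survivors,
        motif_counts={s: counts[s] for s in survivors},
    )
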