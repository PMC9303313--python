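"""Hepatotoxicity calls, delta-Tm bookkeeping, and correlation analyses.

Serum aminotransferases AST and ALT (U/l) mark hepatocellular injury; an
ASO is called hepatotoxic when both exceed a threshold (100 U/l by
default, strict inequality).  The conjunctive reading is the default
because screening tables report both enzymes elevated together; a
disjunctive mode ('either') is provided.

Tm records track duplex melting temperatures of ASO:RNA hybrids; delta-Tm
against the parent ASO flags destabilizing nucleobase chemistries
(drop > 5 degC) versus Tm-equivalent ones (|delta| <= 2 degC).

Correlation (Pearson/Spearman) is delegated to scipy; AST/ALT are best
compared on a log scale since toxic and non-toxic values span two orders
of magnitude.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ToxRecord",
    "TmRecord",
    "classify_hepatotoxic",
    "delta_tm",
    "flag_tm_drops",
    "correlate",
]


@dataclass(frozen=True)
class ToxRecord:
    """Serum chemistry for one ASO treatment group."""

    aso_id: str
    ast: float
    alt: float
    dose: float = 20.0
    n_animals: Optional[int] = None
    flags: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.ast < 0 or self.alt < 0:
            raise ValueError(f"{self.aso_id}: AST/ALT must be non-negative")


@dataclass(frozen=True)
class TmRecord:
    """Melting temperature of the ASO:complementary-RNA duplex."""

    aso_id: str
    tm: float
    source: str = "measured"
    parent_id: Optional[str] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.tm <= 120.0):
            warnings.warn(
                f"{self.aso_id}: Tm {self.tm} degC outside the plausible 0-120 range",
                stacklevel=2,
            )


def classify_hepatotoxic(rec: ToxRecord, threshold: float = 100.0, mode: str = "both") -> bool:
    """Hepatotoxicity call from serum chemistry.

    True iff AST > threshold AND ALT > threshold (strict) with the default
    conjunctive mode; ``mode='either'`` requires only one enzyme elevated.
    """
    if mode == "both":
        return rec.ast > threshold and rec.alt > threshold
    if mode == "either":
        return rec.ast > threshold or rec.alt > threshold
    raise ValueError(f"mode must be 'both' or 'either', got {mode!r}")


def delta_tm(modified: TmRecord, parent: Optional[TmRecord]) -> float:
    """Tm shift of a modified ASO against its parent (negative = destabilized)."""
    if parent is None:
        raise ValueError(f"{modified.aso_id}: no parent Tm record")
    return modified.tm - parent.tm


def flag_tm_drops(
    records: Iterable[TmRecord],
    drop_cutoff: float = 5.0,
    equiv_band: float = 2.0,
) -> pd.DataFrame:
    """Label every modified ASO by its Tm shift against its parent.

    Labels: ``large_drop`` (delta < -drop_cutoff), ``equivalent``
    (|delta| <= equiv_band), ``intermediate`` otherwise.  Records whose
    ``parent_id`` does not resolve raise a ``KeyError`` listing offenders;
    records without a parent_id (the parents themselves) are ignored.
    """
    recs = list(records)
    by_id = {r.aso_id: r for r in recs}
    modified = [r for r in recs if r.parent_id is not None]
    orphans = [f"{r.aso_id} -> {r.parent_id}" for r in modified if r.parent_id not in by_id]
    if orphans:
        raise KeyError(f"Tm records with unresolvable parent: {orphans}")
    rows = []
    for r in modified:
        shift = delta_tm(r, by_id[r.parent_id])
        if shift < -drop_cutoff:
            label = "large_drop"
        elif abs(shift) <= equiv_band:
            label = "equivalent"
        else:
            label = "intermediate"
        rows.append({"aso_id": r.aso_id, "parent_id": r.parent_id, "delta_tm": shift, "label": label})
    frame = pd.DataFrame(rows, columns=["aso_id", "parent_id", "delta_tm", "label"])
    frame.attrs["counts"] = (
        frame["label"].value_counts().reindex(["large_drop", "equivalent", "intermediate"], fill_value=0).to_dict()
        if len(frame)
        else {"large_drop": 0, "equivalent": 0, "intermediate": 0}
    )
    return frame


def correlate(
    x: Sequence[float],
    y: Sequence[float],
    method: str = "pearson",
    log_y: bool = False,
) -> tuple[float, float, int]:
    """Correlation between paired per-ASO values.

    Returns (r, two-sided p, n).  ``log_y=True`` log-transforms y first
    (recommended for AST/ALT).  Constant input raises, since the
    correlation is undefined.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D sequences")
    n = len(xa)
    if n < 3:
        raise ValueError("need at least 3 pairs")
    if log_y:
        if (ya <= 0).any():
            raise ValueError("log transform requires positive y values")
        ya = np.log(ya)
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise ValueError("correlation undefined for a constant vector")
    if method == "pearson":
        r, p = stats.pearsonr(xa, ya)
    elif method == "spearman":
        r, p = stats.spearmanr(xa, ya)
    else:
        raise ValueError(f"method must be 'pearson' or 'spearman', got {method!r}")
    return float(r), float(p), n
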