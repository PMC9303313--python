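"""Off-target down-regulation index from expression ratios + distance classes.

The index quantifies how broadly an ASO knocks down near-complementary
genes: over genes whose minimal complementarity distance d is at most a
cutoff (default 2) and that are down-regulated (ratio < 1), it sums the
absolute log expression ratio (treated/control):

    index = sum_{g : d(g) <= d_cutoff, r_g < 1} | log2 r_g |

Log base 2 by default; the base is configurable and the parent-vs-modified
*ratio* of two indices is base-invariant (a change of base rescales both
numerator and denominator by the same constant), which is why percentage
comparisons between ASOs are well-defined whatever base is used.

Genes absent from the distance map are treated as d >= 3 and so excluded
at the default cutoff.  A ratio of exactly 1 contributes zero either way.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from gapmertox.offtarget import D_CLASSES, GeneDistanceMap

__all__ = [
    "ExpressionTable",
    "OffTargetIndex",
    "compute_offtarget_index",
    "index_ratio",
    "dclass_scatter_summary",
]


@dataclass
class ExpressionTable:
    """Per-gene expression ratios (treated/control) for one ASO treatment.

    ``data`` holds columns gene_id, ratio (> 0) and optionally
    control_intensity (for intensity-vs-ratio scatter plots).
    """

    aso_id: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"gene_id", "ratio"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"expression table missing columns: {sorted(missing)}")
        if (self.data["ratio"] <= 0).any():
            bad = self.data.loc[self.data["ratio"] <= 0, "gene_id"].tolist()
            raise ValueError(f"non-positive expression ratios for genes: {bad[:5]}")
        if self.data["gene_id"].duplicated().any():
            dup = self.data.loc[self.data["gene_id"].duplicated(), "gene_id"].tolist()
            raise ValueError(f"duplicate gene ids: {dup[:5]}")

    @classmethod
    def from_records(cls, aso_id: str, records: Iterable[tuple[str, float]]) -> "ExpressionTable":
        frame = pd.DataFrame(records, columns=["gene_id", "ratio"])
        return cls(aso_id=aso_id, data=frame)


@dataclass(frozen=True)
class OffTargetIndex:
    """The summed |log ratio| over qualifying genes for one ASO."""

    aso_id: str
    d_cutoff: int
    value: float
    n_genes_used: int
    direction: str = "down"
    log_base: float = 2.0


def compute_offtarget_index(
    expr: ExpressionTable,
    dist: GeneDistanceMap,
    d_cutoff: int = 2,
    direction: str = "down",
    log_base: float = 2.0,
    missing: str = "skip",
) -> OffTargetIndex:
    """Compute the off-target down-regulation index.

    Parameters
    ----------
    d_cutoff : genes with min_d <= d_cutoff qualify (default 2).
    direction : 'down' restricts to ratio < 1 (strict); 'both' sums all
        qualifying genes.
    missing : a gene in the distance map but absent from the expression
        table is skipped with a warning ('skip', default) or raises
        ('strict').
    """
    if direction not in ("down", "both"):
        raise ValueError(f"direction must be 'down' or 'both', got {direction!r}")
    if expr.aso_id != dist.aso_id:
        raise ValueError(f"table is for {expr.aso_id!r}, distance map for {dist.aso_id!r}")
    ratios = dict(zip(expr.data["gene_id"], expr.data["ratio"].astype(float)))
    log_scale = math.log(log_base)
    total = 0.0
    n_used = 0
    absent = []
    for gene in dist.genes_at_most(d_cutoff):
        r = ratios.get(gene)
        if r is None:
            absent.append(gene)
            continue
        if direction == "down" and not r < 1.0:
            continue
        total += abs(math.log(r) / log_scale)
        n_used += 1
    if absent:
        if missing == "strict":
            raise KeyError(f"genes in distance map missing from expression table: {absent[:5]}")
        warnings.warn(
            f"{len(absent)} gene(s) in distance map absent from expression table; skipped",
            stacklevel=2,
        )
    return OffTargetIndex(
        aso_id=expr.aso_id,
        d_cutoff=d_cutoff,
        value=total,
        n_genes_used=n_used,
        direction=direction,
        log_base=log_base,
    )


def index_ratio(modified: OffTargetIndex, parent: OffTargetIndex) -> float:
    """Modified-vs-parent index ratio in percent: 100 * modified / parent.

    Requires matching d_cutoff and direction; the parent index must be
    positive.  Base-invariant because both indices share the log base.
    """
    if modified.d_cutoff != parent.d_cutoff or modified.direction != parent.direction:
        raise ValueError("index ratio requires matching d_cutoff and direction")
    if parent.value == 0:
        raise ZeroDivisionError(f"parent index for {parent.aso_id!r} is zero; ratio undefined")
    return 100.0 * modified.value / parent.value


def dclass_scatter_summary(
    expr: ExpressionTable,
    dist: GeneDistanceMap,
    log_base: float = 2.0,
) -> pd.DataFrame:
    """Per-distance-class summary backing an intensity/ratio scatter plot.

    For each class d0/d1/d2/d3plus (genes absent from the distance map are
    d3plus): number of genes, mean and median log ratio, and the fraction
    down-regulated (ratio < 1).  Empty classes report n=0 and NaN moments.
    """
    frame = expr.data.copy()
    frame["dclass"] = [dist.class_of(g) for g in frame["gene_id"]]
    frame["log_ratio"] = np.log(frame["ratio"].astype(float)) / math.log(log_base)
    rows = []
    for cls in D_CLASSES:
        sub = frame[frame["dclass"] == cls]
        rows.append(
            {
                "class": cls,
                "n": len(sub),
                "mean_log_ratio": sub["log_ratio"].mean() if len(sub) else math.nan,
                "median_log_ratio": sub["log_ratio"].median() if len(sub) else math.nan,
                "frac_down": (sub["ratio"] < 1).mean() if len(sub) else math.nan,
            }
        )
    return pd.DataFrame(rows, columns=["class", "n", "mean_log_ratio", "median_log_ratio", "frac_down"])
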