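"""Expression fold changes of genes flanking BA-SV break-ends.

For each boundary-affecting SV, the nearest non-overlapping genes upstream of
the 5' break-end and downstream of the 3' break-end are identified; the fold
change is the gene's expression in the carrier sample divided by its mean
over the remaining samples of the same cohort.  Records are filtered for low
cohort-level expression (< 0.1 FPKM), amplified copy number (> 4) and
distance (> 1 Mb).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .sv import SVEvent

__all__ = [
    "GeneRecord", "FoldChangeRecord",
    "nearest_flank_genes", "fold_change", "flank_fold_changes",
    "apply_filters", "group_test", "twofold_fraction",
]

log = logging.getLogger(__name__)

FLANK_RELATIONS = ("to-more-active", "to-less-active", "same-class")


@dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"gene end must exceed start: {self.gene_id}")


@dataclass
class FoldChangeRecord:
    """One flank gene of one BA-SV with its cohort-relative fold change."""

    sv: SVEvent
    gene_id: str
    side: str                    # upstream | downstream
    distance_bp: int
    fc: float
    flank_relation: str | None = None
    filtered_reason: str = ""

    @property
    def log2fc(self) -> float:
        return float(np.log2(self.fc)) if self.fc > 0 else np.nan

    @property
    def retained(self) -> bool:
        return self.filtered_reason == ""


def nearest_flank_genes(sv: SVEvent, genes: Sequence[GeneRecord],
                        ) -> tuple[GeneRecord | None, GeneRecord | None]:
    """Nearest genes wholly left of sv.start and wholly right of sv.end.

    Genes overlapping either break-end are excluded from candidacy; an
    equidistant tie is broken toward the smaller coordinate.
    """
    up = down = None
    up_d = down_d = None
    for g in sorted(genes, key=lambda g: (g.start, g.end)):
        if g.chrom != sv.chrom:
            continue
        if g.end <= sv.start:                      # wholly left
            d = sv.start - g.end
            if up_d is None or d <= up_d:          # later gene with same d
                if up_d is None or d < up_d or g.start < up.start:
                    up, up_d = g, d
        elif g.start >= sv.end:                    # wholly right
            d = g.start - sv.end
            if down_d is None or d < down_d:       # first wins ties (smaller coord)
                down, down_d = g, d
    return up, down


def fold_change(gene_id: str, sample_id: str,
                cohort_expression: pd.DataFrame) -> float:
    """Expression in the carrier sample over the mean of the other samples."""
    if cohort_expression.shape[1] < 2:
        raise ValueError("fold change requires at least 2 cohort samples")
    row = cohort_expression.loc[gene_id]
    others = row.drop(labels=sample_id)
    denom = float(others.mean())
    if denom <= 0:
        return np.nan
    return float(row[sample_id]) / denom


def flank_fold_changes(svs: Sequence[SVEvent], genes: Sequence[GeneRecord],
                       expression: pd.DataFrame) -> list[FoldChangeRecord]:
    """Fold-change records for both flank genes of every SV."""
    out: list[FoldChangeRecord] = []
    for sv in svs:
        up, down = nearest_flank_genes(sv, genes)
        for side, g in (("upstream", up), ("downstream", down)):
            if g is None or g.gene_id not in expression.index:
                continue
            if sv.sample_id not in expression.columns:
                continue
            fc = fold_change(g.gene_id, sv.sample_id, expression)
            dist = (sv.start - g.end) if side == "upstream" else (g.start - sv.end)
            rec = FoldChangeRecord(sv, g.gene_id, side, int(dist),
                                   fc if np.isfinite(fc) else np.nan)
            if not np.isfinite(fc):
                rec.filtered_reason = "zero-denominator"
            out.append(rec)
    return out


def apply_filters(records: Sequence[FoldChangeRecord],
                  expression: pd.DataFrame,
                  cn_table: pd.DataFrame | None = None,
                  fpkm_min: float = 0.1, cn_max: float = 4.0,
                  max_distance: int = 1_000_000) -> list[FoldChangeRecord]:
    """Mark records failing the expression, copy-number and distance filters.

    A record is dropped when the gene's cohort-mean expression is strictly
    below ``fpkm_min``, when the carrier sample's copy number at the gene is
    strictly above ``cn_max`` (missing entries count as CN = 2), or when the
    gene lies strictly more than ``max_distance`` bp from the break-end.
    Returns the retained records; every record's ``filtered_reason`` is set.
    """
    warned_cn = False
    retained = []
    for rec in records:
        if rec.filtered_reason:
            continue
        if float(expression.loc[rec.gene_id].mean()) < fpkm_min:
            rec.filtered_reason = "low-expression"
            continue
        cn = 2.0
        if cn_table is not None:
            try:
                cn = float(cn_table.loc[rec.gene_id, rec.sv.sample_id])
            except KeyError:
                if not warned_cn:
                    log.warning("missing copy-number entries treated as CN=2")
                    warned_cn = True
        if cn > cn_max:
            rec.filtered_reason = "high-copy-number"
            continue
        if rec.distance_bp > max_distance:
            rec.filtered_reason = "distal"
            continue
        retained.append(rec)
    return retained


def group_test(records: Sequence[FoldChangeRecord], group_a: str,
               group_b: str) -> tuple[float, dict]:
    """One-tailed Mann–Whitney U: log2 fold changes of group A exceed group B.

    Groups are selected by ``flank_relation``.  The exact null distribution
    is used for group sizes up to 20 with no ties; otherwise the normal
    approximation with tie correction.
    """
    a = [r.log2fc for r in records
         if r.retained and r.flank_relation == group_a and np.isfinite(r.log2fc)]
    b = [r.log2fc for r in records
         if r.retained and r.flank_relation == group_b and np.isfinite(r.log2fc)]
    for name, vals in ((group_a, a), (group_b, b)):
        if len(vals) < 3:
            raise ValueError(f"group {name!r} has fewer than 3 records")
    no_ties = len(set(a) | set(b)) == len(a) + len(b)
    method = "exact" if (max(len(a), len(b)) <= 20 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="greater", method=method)
    summary = {"n_a": len(a), "n_b": len(b),
               "median_log2fc_a": float(np.median(a)),
               "median_log2fc_b": float(np.median(b)),
               "method": method}
    return float(res.pvalue), summary


def twofold_fraction(records: Sequence[FoldChangeRecord]) -> float:
    """Fraction of retained records with fold change above 2 or below 0.5.

    Both inequalities are strict; a fold change of exactly 2 (or 0.5) does
    not count.
    """
    fcs = [r.fc for r in records if r.retained and np.isfinite(r.fc)]
    if not fcs:
        raise ValueError("no retained fold-change records")
    hit = sum(1 for f in fcs if f > 2.0 or f < 0.5)
    return hit / len(fcs)
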