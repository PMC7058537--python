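"""Structural-variant model and boundary-affecting (BA) SV statistics.

An SV is *boundary affecting* when its footprint fully contains a TAD
boundary interval (containment inclusive at both ends).  Enrichment of BA
events over chance is assessed against shuffled boundary sets that keep the
per-chromosome boundary count constant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .boundaries import ShuffleNullResult, shuffle_starts_batch, summarize_null
from .hic import Boundary, BoundarySet

__all__ = [
    "SVEvent", "BAAnnotation", "InsulatedNeighborhood",
    "classify_range", "dedupe_svs", "annotate_ba", "ba_enrichment",
    "germline_somatic_rates", "recurrence", "loop_disruption",
    "boundaries_per_sv_histogram",
]

log = logging.getLogger(__name__)

SV_TYPES = ("DEL", "DUP", "INV", "COMPLEX")


@dataclass(frozen=True)
class SVEvent:
    """One intra-chromosomal SV: a typed break-end pair in one sample."""

    sample_id: str
    cohort: str
    chrom: str
    start: int
    end: int
    sv_type: str
    origin: str = "somatic"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"SV start must precede end: {self}")
        if self.sv_type not in SV_TYPES:
            raise ValueError(f"unknown sv_type {self.sv_type!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class BAAnnotation:
    """An SV with the boundaries its footprint fully contains."""

    sv: SVEvent
    boundaries_spanned: list[Boundary] = field(default_factory=list)

    @property
    def is_ba(self) -> bool:
        return len(self.boundaries_spanned) > 0


@dataclass(frozen=True)
class InsulatedNeighborhood:
    """A CTCF–CTCF loop: two anchor intervals on one chromosome."""

    chrom: str
    anchor1: tuple[int, int]
    anchor2: tuple[int, int]

    def __post_init__(self) -> None:
        if self.anchor1[0] >= self.anchor2[0]:
            raise ValueError("anchor1 must precede anchor2")


def classify_range(sv: SVEvent, cutoff: int = 2_000_000) -> str:
    """'short' for events shorter than ``cutoff`` bp, else 'long'."""
    if sv.length <= 0:
        raise ValueError("SV length must be positive")
    return "short" if sv.length < cutoff else "long"


def dedupe_svs(svs: Iterable[SVEvent]) -> list[SVEvent]:
    """Drop duplicate (sample, chrom, start, end, type) records."""
    seen: set[tuple] = set()
    out = []
    for sv in svs:
        key = (sv.sample_id, sv.chrom, sv.start, sv.end, sv.sv_type)
        if key not in seen:
            seen.add(key)
            out.append(sv)
    return out


# ---------------------------------------------------------------------------
# BA annotation
# ---------------------------------------------------------------------------

def annotate_ba(svs: Sequence[SVEvent],
                boundaries: BoundarySet) -> list[BAAnnotation]:
    """Annotate each SV with every boundary it fully contains.

    Boundary b is spanned by sv iff ``sv.start <= b.start`` and
    ``sv.end >= b.end`` (inclusive containment).
    """
    by_chrom: dict[str, list[Boundary]] = {}
    for b in boundaries:
        by_chrom.setdefault(b.chrom, []).append(b)
    starts = {c: np.array([b.start for b in bs])
              for c, bs in by_chrom.items()}  # sorted by BoundarySet order
    out = []
    for sv in svs:
        spanned: list[Boundary] = []
        bs = by_chrom.get(sv.chrom)
        if bs:
            st = starts[sv.chrom]
            lo = int(np.searchsorted(st, sv.start, side="left"))
            for b in bs[lo:]:
                if b.start > sv.end:
                    break
                if b.end <= sv.end:
                    spanned.append(b)
        out.append(BAAnnotation(sv, spanned))
    return out


def _containment_bounds(svs: Sequence[SVEvent], width_bins: int,
                        bin_size: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-SV [lo, hi] range of boundary start *bins* it would contain."""
    s = np.array([sv.start for sv in svs])
    e = np.array([sv.end for sv in svs])
    lo = -(-s // bin_size)                       # ceil
    hi = (e - width_bins * bin_size) // bin_size  # floor
    return lo, hi


def ba_enrichment(svs: Sequence[SVEvent], boundaries: BoundarySet,
                  chrom_sizes: Mapping[str, int], n_shuffles: int = 10_000,
                  seed: int = 0, bin_size: int = 25_000,
                  short_cutoff: int = 2_000_000,
                  ) -> dict[str, tuple[float, ShuffleNullResult]]:
    """BA fraction per SV type against the shuffled-boundary null.

    Only short-range events enter the test.  For each type, the observed BA
    count is compared with counts under ``n_shuffles`` shuffled boundary sets
    (per-chromosome counts preserved); ``fold = observed / null_mean``.
    Types with no events are omitted.
    """
    svs = [sv for sv in dedupe_svs(svs) if classify_range(sv, short_cutoff) == "short"]
    widths = {(b.end - b.start) for b in boundaries}
    if len(widths) > 1:
        raise ValueError("ba_enrichment requires uniform boundary width")
    width_bins = widths.pop() // bin_size if widths else 3

    rng = np.random.default_rng(seed)
    by_type: dict[str, list[SVEvent]] = {}
    for sv in svs:
        by_type.setdefault(sv.sv_type, []).append(sv)

    # observed BA flags
    ann = annotate_ba(svs, boundaries)
    obs_flag = {id(a.sv): a.is_ba for a in ann}

    # null: per chromosome, shuffled boundary start bins; an SV is BA in a
    # shuffle iff any start bin falls in its containment range
    chroms = sorted({sv.chrom for sv in svs})
    ba_null = {t: np.zeros(n_shuffles) for t in by_type}
    for chrom in chroms:
        nb = len(boundaries.on_chrom(chrom))
        if nb == 0:
            continue
        n_bins = chrom_sizes[chrom] // bin_size
        starts = shuffle_starts_batch(nb, n_bins, width_bins, n_shuffles, rng)
        for t, tsvs in by_type.items():
            csvs = [sv for sv in tsvs if sv.chrom == chrom]
            if not csvs:
                continue
            lo, hi = _containment_bounds(csvs, width_bins, bin_size)
            chunk = max(1, 10_000_000 // (nb * max(len(csvs), 1)))
            for k0 in range(0, n_shuffles, chunk):
                S = starts[k0:k0 + chunk]                      # (c, nb)
                hit = ((S[:, :, None] >= lo) &
                       (S[:, :, None] <= hi)).any(axis=1)      # (c, nsv)
                ba_null[t][k0:k0 + chunk] += hit.sum(axis=1)

    out: dict[str, tuple[float, ShuffleNullResult]] = {}
    for t, tsvs in sorted(by_type.items()):
        n_ba = sum(obs_flag[id(sv)] for sv in tsvs)
        frac = n_ba / len(tsvs)
        out[t] = (frac, summarize_null(n_ba, ba_null[t], seed))
    return out


# ---------------------------------------------------------------------------
# germline comparison, recurrence, loops
# ---------------------------------------------------------------------------

def germline_somatic_rates(somatic_dels: Sequence[SVEvent],
                           germline_dels: Sequence[SVEvent],
                           boundaries: BoundarySet,
                           len_range: tuple[int, int] = (75_000, 250_000),
                           ) -> dict:
    """BA rates of length-matched somatic vs germline deletions.

    Both sets are filtered to lengths within ``len_range`` (closed interval);
    the rate is BA events / filtered events.  Also reports the fraction of
    all boundaries hit by each set.
    """
    lo, hi = len_range
    res: dict = {}
    n_bound = max(len(boundaries), 1)
    for name, dels in (("somatic", somatic_dels), ("germline", germline_dels)):
        if any(sv.sv_type != "DEL" for sv in dels):
            raise ValueError("germline_somatic_rates expects deletions only")
        kept = [sv for sv in dels if lo <= sv.length <= hi]
        ann = annotate_ba(kept, boundaries)
        n_ba = sum(a.is_ba for a in ann)
        hit = {(b.chrom, b.start) for a in ann for b in a.boundaries_spanned}
        res[f"rate_{name}"] = n_ba / len(kept) if kept else np.nan
        res[f"n_{name}"] = len(kept)
        res[f"n_ba_{name}"] = n_ba
        res[f"boundaries_hit_frac_{name}"] = len(hit) / n_bound
        if not kept:
            log.warning("no %s deletions within %s", name, len_range)
    return res


def _boundary_id(b: Boundary) -> str:
    return f"{b.chrom}:{b.start}-{b.end}"


def recurrence(cohort_svs: Sequence[SVEvent], boundaries: BoundarySet,
               frac: float = 0.10) -> tuple[pd.DataFrame, list[str]]:
    """Sample x boundary binary BA matrix and recurrently affected boundaries.

    A boundary is recurrent when affected in strictly more than ``frac`` of
    the cohort's samples.
    """
    samples = sorted({sv.sample_id for sv in cohort_svs})
    if not samples:
        raise ValueError("empty cohort")
    cols = [_boundary_id(b) for b in boundaries]
    mat = pd.DataFrame(0, index=samples, columns=cols, dtype=int)
    for a in annotate_ba(dedupe_svs(cohort_svs), boundaries):
        for b in a.boundaries_spanned:
            mat.loc[a.sv.sample_id, _boundary_id(b)] = 1
    frac_affected = mat.mean(axis=0)
    recurrent = list(frac_affected.index[frac_affected > frac])
    return mat, recurrent


def _overlaps(a0: int, a1: int, b0: int, b1: int) -> bool:
    return a0 < b1 and b0 < a1  # half-open intervals


def loop_disruption(svs: Sequence[SVEvent],
                    neighborhoods: Sequence[InsulatedNeighborhood],
                    ) -> list[tuple[SVEvent, InsulatedNeighborhood]]:
    """SVs overlapping exactly one anchor of an insulated neighborhood."""
    out = []
    for sv in svs:
        for nb in neighborhoods:
            if nb.chrom != sv.chrom:
                continue
            h1 = _overlaps(sv.start, sv.end, *nb.anchor1)
            h2 = _overlaps(sv.start, sv.end, *nb.anchor2)
            if h1 != h2:
                out.append((sv, nb))
    return out


def boundaries_per_sv_histogram(ba_annotations: Sequence[BAAnnotation],
                                length_thresholds: Sequence[int] = (
                                    500_000, 1_000_000, 2_000_000),
                                ) -> pd.DataFrame:
    """Distribution of spanned-boundary counts per BA-SV.

    For each SV type and each maximum-length threshold, tabulates how many
    BA-SVs (events shorter than the threshold) span k = 1, 2, ... boundaries;
    fractions sum to 1 within each (type, threshold) stratum.
    """
    rows = []
    for thr in length_thresholds:
        strata: dict[tuple[str, int], int] = {}
        totals: dict[str, int] = {}
        for a in ba_annotations:
            if not a.is_ba or a.sv.length >= thr:
                continue
            k = len(a.boundaries_spanned)
            strata[(a.sv.sv_type, k)] = strata.get((a.sv.sv_type, k), 0) + 1
            totals[a.sv.sv_type] = totals.get(a.sv.sv_type, 0) + 1
        for (t, k), c in sorted(strata.items()):
            rows.append({"sv_type": t, "max_length": thr, "n_boundaries": k,
                         "count": c, "fraction": c / totals[t]})
    return pd.DataFrame(rows, columns=["sv_type", "max_length",
                                       "n_boundaries", "count", "fraction"])
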