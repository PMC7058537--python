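"""TAD-fusion statistics on rearranged contact maps.

The expected contact at a given genomic distance is the empirical mean over
all unmasked bin pairs at that separation (the distance-decay curve).  Around
each SV, observed contacts are compared with this expectation: a per-SV
scaling factor corrects for ploidy (SVs scaling below 0.1 are treated as
unsupported calls and excluded), cross-SV bin pairs are split into
intra-TAD/SV and inter-TAD/SV by the nearest boundary beyond each break-end,
and their observed/expected decay curves are contrasted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .hic import BoundarySet, ContactMatrix
from .sv import SVEvent

__all__ = [
    "DecayCurve", "FusionResult",
    "expected_by_distance", "genome_wide_decay", "expected_matrix",
    "sv_scaling_factor", "classify_fusion_bins", "fusion_decay_compare",
    "breakend_aggregate",
]

log = logging.getLogger(__name__)


@dataclass
class DecayCurve:
    """Mean contact frequency per genomic distance (in bins)."""

    distances: np.ndarray        # 1..n_bins-1
    mean: np.ndarray             # NaN where no unmasked pairs
    count: np.ndarray
    chrom: str = "genome"

    def value_at(self, d: np.ndarray | int) -> np.ndarray:
        d = np.atleast_1d(np.asarray(d, dtype=int))
        out = np.full(d.shape, np.nan)
        ok = (d >= 1) & (d <= self.distances[-1])
        out[ok] = self.mean[d[ok] - 1]
        return out


@dataclass
class FusionResult:
    """Per-SV fusion statistics."""

    sv: SVEvent
    scaling_factor: float
    excluded: bool
    reason: str = ""
    window_used: tuple[int, int] | None = None
    intra_mean: float = np.nan
    inter_mean: float = np.nan
    curves: pd.DataFrame | None = None

    @property
    def ratio(self) -> float:
        return self.intra_mean / self.inter_mean \
            if np.isfinite(self.intra_mean) and self.inter_mean > 0 else np.nan


def expected_by_distance(mat: ContactMatrix,
                         min_pairs: int = 10) -> DecayCurve:
    """Empirical distance-decay curve of one chromosome.

    The mean at each separation is taken over unmasked pairs only; distances
    supported by fewer than ``min_pairs`` pairs are pooled with neighboring
    distances (running right-to-left) so every reported mean rests on at
    least ``min_pairs`` pairs where possible.
    """
    n = mat.n_bins
    sums = np.zeros(n - 1)
    counts = np.zeros(n - 1)
    for d in range(1, n):
        diag = np.diagonal(mat.values, offset=d)
        ok = np.isfinite(diag)
        sums[d - 1] = diag[ok].sum()
        counts[d - 1] = ok.sum()
    if counts.sum() == 0:
        log.warning("%s: fully masked; empty decay curve", mat.chrom)
    mean = np.full(n - 1, np.nan)

    # pool sparse distances with neighbors (toward the diagonal)
    d = n - 2
    while d >= 0:
        if counts[d] == 0:
            d -= 1
            continue
        lo = d
        s, c = sums[d], counts[d]
        while c < min_pairs and lo > 0:
            lo -= 1
            s += sums[lo]
            c += counts[lo]
        if c > 0:
            mean[lo:d + 1] = s / c
        d = lo - 1
    return DecayCurve(np.arange(1, n), mean, counts, mat.chrom)


def genome_wide_decay(curves: Sequence[DecayCurve]) -> DecayCurve:
    """Pair-count-weighted combination of per-chromosome decay curves."""
    n = max(c.distances[-1] for c in curves)
    sums = np.zeros(n)
    counts = np.zeros(n)
    for c in curves:
        m = c.distances.size
        ok = np.isfinite(c.mean)
        sums[:m][ok] += (c.mean * c.count)[ok]
        counts[:m][ok] += c.count[ok]
    mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return DecayCurve(np.arange(1, n + 1), mean, counts, "genome")


def expected_matrix(mat: ContactMatrix, decay: DecayCurve) -> np.ndarray:
    """Dense expected map E[i, j] = decay(|i - j|); diagonal NaN."""
    n = mat.n_bins
    d = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    e = np.full((n, n), np.nan)
    off = d > 0
    e[off] = decay.value_at(d[off])
    e[mat.mask, :] = np.nan
    e[:, mat.mask] = np.nan
    return e


# ---------------------------------------------------------------------------
# per-SV window and scaling
# ---------------------------------------------------------------------------

def _sv_window(sv: SVEvent, chrom_size: int, window: int,
               other_svs: Sequence[SVEvent] = ()) -> tuple[int, int]:
    """SV footprint symmetrically extended to ``window`` total span.

    Each side's extension is truncated at the nearest break-end of another SV
    and clamped to the chromosome.
    """
    pad = max(0, (window - sv.length) // 2)
    lo, hi = sv.start - pad, sv.end + pad
    for o in other_svs:
        if o is sv or o.chrom != sv.chrom:
            continue
        for be in (o.start, o.end):
            if sv.start >= be > lo:
                lo = be
            if sv.end <= be < hi:
                hi = be
    return max(0, lo), min(chrom_size, hi)


def sv_scaling_factor(mat: ContactMatrix, sv: SVEvent, decay: DecayCurve,
                      window: int = 2_000_000,
                      other_svs: Sequence[SVEvent] = (),
                      scaling_min: float = 0.1) -> FusionResult:
    """Mean observed over mean expected contact in the SV's 2-Mb window.

    The result is flagged excluded when the window collapses below 4 bins or
    the factor falls below ``scaling_min`` (unsupported SV call).
    """
    lo, hi = _sv_window(sv, mat.chrom_size, window, other_svs)
    b0, b1 = lo // mat.bin_size, -(-hi // mat.bin_size)
    if b1 - b0 < 4:
        return FusionResult(sv, np.nan, True, "window-collapsed", (lo, hi))
    sub = mat.values[b0:b1, b0:b1]
    iu = np.triu_indices(b1 - b0, k=1)
    obs = sub[iu]
    exp = decay.value_at(iu[1] - iu[0])
    ok = np.isfinite(obs) & np.isfinite(exp)
    if ok.sum() == 0 or exp[ok].mean() <= 0:
        return FusionResult(sv, np.nan, True, "no-valid-pairs", (lo, hi))
    scaling = float(obs[ok].mean() / exp[ok].mean())
    excluded = scaling < scaling_min
    return FusionResult(sv, scaling, excluded,
                        "low-scaling" if excluded else "", (lo, hi))


def classify_fusion_bins(sv: SVEvent, boundaries: BoundarySet,
                         window_used: tuple[int, int], bin_size: int = 25_000,
                         ) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Label cross-SV bin pairs as intra-TAD/SV or inter-TAD/SV.

    For each break-end the nearest boundary beyond it (away from the SV) is
    located.  Pairs with one bin on each side of the SV whose bins both lie
    between a break-end and its nearest boundary are intra-TAD/SV; cross-SV
    pairs reaching past either boundary are inter-TAD/SV.  All remaining
    in-window pairs are 'other'.  Bin indices are absolute; each label maps
    to (row_bins, col_bins) with row < col.
    """
    lo, hi = window_used
    w0, w1 = lo // bin_size, -(-hi // bin_size)
    bl, br = sv.start // bin_size, (sv.end - 1) // bin_size

    left_lim, right_lim = w0, w1  # fallback: window edge
    have_left = have_right = False
    for b in boundaries.on_chrom(sv.chrom):
        if b.end <= sv.start and b.end // bin_size >= w0:
            left_lim = max(left_lim, b.end // bin_size)
            have_left = True
        if b.start >= sv.end and b.start // bin_size <= w1:
            if not have_right:
                right_lim, have_right = b.start // bin_size, True
            else:
                right_lim = min(right_lim, b.start // bin_size)
    if not (have_left and have_right):
        log.info("SV %s:%d-%d lacks a flanking boundary in window",
                 sv.chrom, sv.start, sv.end)

    rows, cols = np.meshgrid(np.arange(w0, w1), np.arange(w0, w1),
                             indexing="ij")
    upper = rows < cols
    cross = upper & (rows < bl) & (cols > br)
    left_in = (rows >= left_lim) if have_left else np.zeros_like(upper)
    right_in = (cols < right_lim) if have_right else np.zeros_like(upper)
    intra = cross & left_in & right_in
    inter = cross & ~intra
    other = upper & ~cross
    return {
        "intra": (rows[intra], cols[intra]),
        "inter": (rows[inter], cols[inter]),
        "other": (rows[other], cols[other]),
    }


def fusion_decay_compare(mat: ContactMatrix,
                         labels: Mapping[str, tuple[np.ndarray, np.ndarray]],
                         decay: DecayCurve) -> dict:
    """Observed/expected decay statistics of intra- vs inter-TAD/SV pairs.

    Distances are measured in reference coordinates.  For each class the
    per-distance mean observed/expected ratio and the overall pair-mean ratio
    are reported; the headline statistic is ``intra_mean / inter_mean``.
    """
    out: dict = {"curves": {}}
    for cls in ("intra", "inter"):
        ii, jj = labels[cls]
        if ii.size == 0:
            out[f"{cls}_mean"] = np.nan
            log.info("no %s-TAD/SV pairs; statistic undefined", cls)
            continue
        obs = mat.values[ii, jj]
        exp = decay.value_at(jj - ii)
        ok = np.isfinite(obs) & np.isfinite(exp) & (exp > 0)
        if ok.sum() == 0:
            out[f"{cls}_mean"] = np.nan
            continue
        ratio = obs[ok] / exp[ok]
        d = (jj - ii)[ok]
        out[f"{cls}_mean"] = float(ratio.mean())
        out["curves"][cls] = (pd.DataFrame({"distance": d, "ratio": ratio})
                              .groupby("distance")["ratio"].mean())
    im, xm = out.get("intra_mean", np.nan), out.get("inter_mean", np.nan)
    out["ratio"] = im / xm if np.isfinite(im) and np.isfinite(xm) and xm > 0 \
        else np.nan
    return out


def breakend_aggregate(matrices: Mapping[str, Mapping[str, ContactMatrix]],
                       svs: Sequence[SVEvent],
                       half_width_bins: int = 5) -> dict:
    """Aggregate observed/expected contact around SV break-end pixels.

    For each SV the (2h+1)^2 submatrix of observed/expected folds centered on
    the (start-bin, end-bin) pixel of its sample's map is collected; SVs whose
    center pixel is masked are skipped and counted.  Returns the aggregate
    mean fold matrix, per-SV center folds, and their mean.
    """
    h = half_width_bins
    decays: dict[int, DecayCurve] = {}
    mats_folds: list[np.ndarray] = []
    center_folds: list[float] = []
    n_skipped = 0
    for sv in svs:
        m = matrices.get(sv.sample_id, {}).get(sv.chrom)
        if m is None:
            n_skipped += 1
            continue
        if id(m) not in decays:
            decays[id(m)] = expected_by_distance(m)
        decay = decays[id(m)]
        bi, bj = sv.start // m.bin_size, (sv.end - 1) // m.bin_size
        if not (h <= bi < m.n_bins - h and h <= bj < m.n_bins - h) \
                or m.mask[bi] or m.mask[bj]:
            n_skipped += 1
            continue
        obs = m.values[bi - h:bi + h + 1, bj - h:bj + h + 1]
        rows = np.arange(bi - h, bi + h + 1)
        cols = np.arange(bj - h, bj + h + 1)
        dist = np.abs(np.subtract.outer(rows, cols))
        exp = np.where(dist > 0, decay.value_at(dist.ravel()).reshape(dist.shape),
                       np.nan)
        with np.errstate(invalid="ignore", divide="ignore"):
            fold = obs / exp
        mats_folds.append(fold)
        center_folds.append(float(fold[h, h]))
    if not mats_folds:
        return {"aggregate": None, "center_folds": [],
                "center_fold_mean": np.nan, "n_skipped": n_skipped}
    agg = np.nanmean(np.stack(mats_folds), axis=0)
    return {"aggregate": agg,
            "center_folds": center_folds,
            "center_fold_mean": float(np.nanmean(center_folds)),
            "n_used": len(center_folds), "n_skipped": n_skipped}
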