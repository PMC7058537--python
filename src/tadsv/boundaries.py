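"""Cross-cell-type consensus boundaries and shuffle-null statistics.

The permutation scheme used throughout the pipeline is defined here: shuffled
boundary sets keep the per-chromosome boundary count and widths but re-place
each boundary uniformly on the bin grid without overlap.  Observed statistics
are compared against the bootstrap distribution via a z-score, a
normal-approximation two-sided p, and a one-sided (upper tail, add-one
corrected) empirical p.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .hic import Boundary, BoundarySet

__all__ = [
    "ShuffleNullResult", "FeatureTrack",
    "shuffle_boundaries", "shuffle_starts_batch", "consensus_boundaries",
    "boundary_overlap_test", "profile_around_boundaries", "summarize_null",
]


@dataclass
class ShuffleNullResult:
    """Observed statistic against its bootstrap shuffle null.

    ``p_normal`` is the two-sided normal-approximation p from ``z``;
    ``p_empirical`` is the one-sided upper-tail (enrichment) empirical p with
    add-one correction, so it is never below ``1 / (n_shuffles + 1)``.
    """

    observed: float
    null_mean: float
    null_sd: float
    z: float
    p_normal: float
    p_empirical: float
    n_shuffles: int
    seed: int

    @property
    def fold(self) -> float:
        return self.observed / self.null_mean if self.null_mean > 0 else np.nan


def summarize_null(observed: float, null: np.ndarray,
                   seed: int) -> ShuffleNullResult:
    """Build a :class:`ShuffleNullResult` from an observed value and null draws."""
    null = np.asarray(null, dtype=float)
    k = null.size
    mean, sd = float(null.mean()), float(null.std(ddof=1)) if k > 1 else 0.0
    if sd > 0:
        z = (observed - mean) / sd
        p_norm = float(2 * stats.norm.sf(abs(z)))
    else:
        z = 0.0 if observed == mean else np.inf * np.sign(observed - mean)
        p_norm = 1.0 if observed == mean else 0.0
    p_emp = float((np.sum(null >= observed) + 1) / (k + 1))
    return ShuffleNullResult(float(observed), mean, sd, float(z), p_norm,
                             p_emp, k, seed)


# ---------------------------------------------------------------------------
# shuffled boundary placement
# ---------------------------------------------------------------------------

def shuffle_starts_batch(n_boundaries: int, n_bins: int, width_bins: int,
                         size: int, rng: np.random.Generator) -> np.ndarray:
    """Sample ``size`` non-overlapping placements of equal-width boundaries.

    Returns a ``(size, n_boundaries)`` array of sorted start bins, uniform
    over all configurations with no two boundaries overlapping.  Uses the
    standard bijection: sorted distinct draws t_1 < ... < t_n from
    {0..B-w-(n-1)(w-1)} map to starts s_i = t_i + (i-1)(w-1), which enforces
    s_{i+1} >= s_i + w.
    """
    n, w = n_boundaries, width_bins
    if n * w > n_bins:
        raise ValueError(
            f"cannot place {n} boundaries of {w} bins on {n_bins} bins "
            "without overlap")
    if n == 0:
        return np.zeros((size, 0), dtype=int)
    m = n_bins - w - (n - 1) * (w - 1)  # max value of t_n
    out = np.empty((size, n), dtype=int)
    offsets = np.arange(n) * (w - 1)
    for k in range(size):
        t = np.sort(rng.choice(m + 1, size=n, replace=False))
        out[k] = t + offsets
    return out


def shuffle_boundaries(bset: BoundarySet, chrom_sizes: Mapping[str, int],
                       seed: int, bin_size: int = 25_000) -> BoundarySet:
    """Re-place every boundary uniformly on its own chromosome.

    Per-chromosome boundary counts and widths are preserved; placements are
    uniform on the bin grid and mutually non-overlapping.  Deterministic in
    ``seed``.
    """
    rng = np.random.default_rng(seed)
    out: list[Boundary] = []
    for chrom in bset.chroms():
        if chrom not in chrom_sizes:
            raise KeyError(f"no size for chromosome {chrom}")
        members = list(bset.on_chrom(chrom))
        widths = np.array([(b.end - b.start) // bin_size for b in members])
        n_bins = chrom_sizes[chrom] // bin_size
        if widths.sum() > n_bins:
            raise ValueError(f"{chrom}: too short for its boundary count")
        if len(set(widths)) == 1:
            starts = shuffle_starts_batch(len(members), n_bins,
                                          int(widths[0]), 1, rng)[0]
            order = rng.permutation(len(members))
            for s, bi in zip(starts, order):
                b = members[bi]
                out.append(Boundary(chrom, int(s) * bin_size,
                                    (int(s) + int(widths[bi])) * bin_size,
                                    b.strength, b.source))
        else:  # mixed widths: per-configuration rejection sampling
            for _ in range(1000):
                perm = rng.permutation(len(members))
                starts = rng.integers(0, n_bins - widths[perm] + 1)
                o = np.argsort(starts)
                if (starts[o][1:] >= starts[o][:-1] + widths[perm][o][:-1]).all():
                    for s, bi in zip(starts, perm):
                        b = members[bi]
                        out.append(Boundary(chrom, int(s) * bin_size,
                                            (int(s) + int(widths[bi])) * bin_size,
                                            b.strength, b.source))
                    break
            else:
                raise RuntimeError(f"{chrom}: could not place mixed-width "
                                   "boundaries without overlap")
    return BoundarySet(out)


# ---------------------------------------------------------------------------
# consensus
# ---------------------------------------------------------------------------

def consensus_boundaries(sets: Sequence[BoundarySet], tol: int = 50_000,
                         bin_size: int = 25_000) -> BoundarySet:
    """Boundaries shared by every input set.

    Boundary centers from all sets are pooled per chromosome and grouped
    greedily left-to-right: a boundary joins the open group while its center
    is within ``tol`` of the previous member's center (chained adjacency).  A
    group containing at least one member from every input set yields one
    consensus boundary at the bin holding the median member center, emitted as
    a 3-bin interval with source ``"consensus"`` and strength the mean member
    strength.
    """
    if len(sets) < 2:
        raise ValueError("consensus requires at least 2 boundary sets")
    chroms = sorted({c for s in sets for c in s.chroms()})
    out: list[Boundary] = []
    for chrom in chroms:
        items = sorted(
            (b.center, si, b)
            for si, s in enumerate(sets) for b in s.on_chrom(chrom)
        )
        group: list[tuple[int, int, Boundary]] = []

        def flush() -> None:
            if {si for _, si, _ in group} == set(range(len(sets))):
                centers = np.array([c for c, _, _ in group])
                cb = int(np.median(centers)) // bin_size
                strength = float(np.mean([b.strength for _, _, b in group]))
                start = max(0, cb - 1) * bin_size
                out.append(Boundary(chrom, start, (cb + 2) * bin_size,
                                    strength, "consensus"))

        for item in items:
            if group and item[0] - group[-1][0] > tol:
                flush()
                group = []
            group.append(item)
        if group:
            flush()
    return BoundarySet(out)


# ---------------------------------------------------------------------------
# overlap significance
# ---------------------------------------------------------------------------

def _boundary_bins(bset: BoundarySet, chrom: str, n_bins: int,
                   bin_size: int) -> np.ndarray:
    cover = np.zeros(n_bins, dtype=bool)
    for b in bset.on_chrom(chrom):
        cover[b.start // bin_size: min(n_bins, -(-b.end // bin_size))] = True
    return cover


def boundary_overlap_test(a: BoundarySet, b: BoundarySet,
                          chrom_sizes: Mapping[str, int], n_shuffles: int = 10_000,
                          seed: int = 0, bin_size: int = 25_000) -> ShuffleNullResult:
    """Significance of the bin-level overlap between two boundary sets.

    The genome is discretized to ``bin_size`` bins and each set converted to a
    binary track; the observed statistic is the count of bins covered by both
    (logical AND).  The null re-places set ``b`` with
    :func:`shuffle_boundaries` ``n_shuffles`` times.
    """
    rng = np.random.default_rng(seed)
    chroms = sorted(set(chrom_sizes) & (set(a.chroms()) | set(b.chroms())))
    observed = 0
    null = np.zeros(n_shuffles)
    for chrom in chroms:
        n_bins = chrom_sizes[chrom] // bin_size
        a_cov = _boundary_bins(a, chrom, n_bins, bin_size)
        b_members = list(b.on_chrom(chrom))
        if not b_members:
            continue
        b_cov = _boundary_bins(b, chrom, n_bins, bin_size)
        observed += int((a_cov & b_cov).sum())
        w = (b_members[0].end - b_members[0].start) // bin_size
        if all((m.end - m.start) // bin_size == w for m in b_members):
            starts = shuffle_starts_batch(len(b_members), n_bins, w,
                                          n_shuffles, rng)
            bins = starts[:, :, None] + np.arange(w)        # (k, n, w)
            null += a_cov[bins.reshape(n_shuffles, -1)].sum(axis=1)
        else:
            for k in range(n_shuffles):
                sh = shuffle_boundaries(b.on_chrom(chrom),
                                        {chrom: chrom_sizes[chrom]},
                                        int(rng.integers(2**31)), bin_size)
                null[k] += (a_cov & _boundary_bins(sh, chrom, n_bins,
                                                   bin_size)).sum()
    if len(a) == 0 or len(b) == 0:
        return ShuffleNullResult(0.0, 0.0, 0.0, 0.0, 1.0, 1.0, n_shuffles, seed)
    return summarize_null(observed, null, seed)


# ---------------------------------------------------------------------------
# feature profiles around boundaries
# ---------------------------------------------------------------------------

class FeatureTrack:
    """Per-bin counts of a genomic feature (CTCF sites, DNase sites, ...)."""

    def __init__(self, counts: Mapping[str, np.ndarray], bin_size: int):
        self.counts = {c: np.asarray(v, dtype=float) for c, v in counts.items()}
        self.bin_size = bin_size
        for c, v in self.counts.items():
            if (v < 0).any():
                raise ValueError(f"negative feature counts on {c}")

    @classmethod
    def from_intervals(cls, intervals: Sequence[tuple[str, int, int]],
                       chrom_sizes: Mapping[str, int],
                       bin_size: int) -> "FeatureTrack":
        """Count interval midpoints per bin."""
        counts = {c: np.zeros(sz // bin_size) for c, sz in chrom_sizes.items()}
        for chrom, start, end in intervals:
            if chrom in counts:
                mid = (start + end) // 2 // bin_size
                if 0 <= mid < counts[chrom].size:
                    counts[chrom][mid] += 1
        return cls(counts, bin_size)


def profile_around_boundaries(bset: BoundarySet, feat: FeatureTrack,
                              flank_bp: int, shuffles: int,
                              chrom_sizes: Mapping[str, int],
                              seed: int = 0) -> dict[str, np.ndarray]:
    """Aligned average feature level around boundary centers.

    Returns offsets (bins), the observed mean profile, and the mean profile
    over ``shuffles`` shuffled boundary sets (the dashed-baseline analogue).
    Boundaries near chromosome ends contribute only where defined.
    """
    if flank_bp % feat.bin_size:
        raise ValueError("flank_bp must be a multiple of the track bin size")
    f = flank_bp // feat.bin_size
    offsets = np.arange(-f, f + 1)

    def one_profile(bs: BoundarySet) -> np.ndarray:
        acc = np.zeros(2 * f + 1)
        cnt = np.zeros(2 * f + 1)
        for b in bs:
            track = feat.counts.get(b.chrom)
            if track is None:
                continue
            c = b.center // feat.bin_size
            for k, off in enumerate(offsets):
                j = c + off
                if 0 <= j < track.size:
                    acc[k] += track[j]
                    cnt[k] += 1
        with np.errstate(invalid="ignore"):
            return np.where(cnt > 0, acc / np.maximum(cnt, 1), np.nan)

    observed = one_profile(bset)
    rng = np.random.default_rng(seed)
    sh_acc = np.zeros(2 * f + 1)
    for _ in range(shuffles):
        sh = shuffle_boundaries(bset, chrom_sizes, int(rng.integers(2**31)),
                                feat.bin_size)
        sh_acc += np.nan_to_num(one_profile(sh))
    shuffled = sh_acc / max(shuffles, 1)
    return {"offsets": offsets, "observed": observed, "shuffled": shuffled}
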