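"""Contact-matrix model, normalization, and insulation-based boundary calling.

The central objects are :class:`ContactMatrix` (one chromosome of a binned,
symmetric Hi-C map with a per-bin validity mask) and :class:`BoundarySet`
(bin-aligned TAD boundary intervals).  Boundaries are called from an
insulation profile: the mean contact frequency in a square window sliding
along the matrix diagonal, log2-normalized to the chromosome mean; local
minima of this profile — detected as upward zero crossings of a delta track —
mark TAD boundaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np

from .config import PipelineConfig

__all__ = [
    "ContactMatrix", "NormalizationVector", "InsulationProfile",
    "Boundary", "BoundarySet",
    "apply_kr", "ice_normalize", "tad_signal", "insulation_profile",
    "call_boundaries",
]


# ---------------------------------------------------------------------------
# data model
# ---------------------------------------------------------------------------

@dataclass
class ContactMatrix:
    """Symmetric intra-chromosomal contact map at fixed bin size.

    ``values`` is an ``(n_bins, n_bins)`` float array; rows/columns of masked
    bins are NaN, never silently zero.  ``mask[i]`` is True when bin ``i`` is
    unmappable or low-coverage and must be excluded from all statistics.
    """

    chrom: str
    bin_size: int
    values: np.ndarray
    mask: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("contact matrix must be square")
        if self.mask is None:
            self.mask = np.zeros(self.n_bins, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != (self.n_bins,):
            raise ValueError("mask length must equal n_bins")
        self._apply_mask()

    def _apply_mask(self) -> None:
        if self.mask.any():
            self.values[self.mask, :] = np.nan
            self.values[:, self.mask] = np.nan

    @property
    def n_bins(self) -> int:
        return self.values.shape[0]

    @property
    def chrom_size(self) -> int:
        return self.n_bins * self.bin_size

    def check_symmetric(self, tol: float = 1e-8) -> bool:
        v = np.nan_to_num(self.values)
        return bool(np.allclose(v, v.T, atol=tol))

    def copy(self) -> "ContactMatrix":
        return ContactMatrix(self.chrom, self.bin_size,
                             self.values.copy(), self.mask.copy())

    def with_auto_mask(self) -> "ContactMatrix":
        """Mask bins whose (off-diagonal inclusive) row sum is zero."""
        v = np.nan_to_num(self.values)
        dead = v.sum(axis=0) <= 0
        return ContactMatrix(self.chrom, self.bin_size, self.values.copy(),
                             self.mask | dead)


@dataclass
class NormalizationVector:
    """Per-bin multiplicative bias (KR or ICE); NaN where the bin is masked."""

    chrom: str
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)

    @property
    def missing(self) -> np.ndarray:
        return ~np.isfinite(self.scores) | (self.scores <= 0)


@dataclass
class InsulationProfile:
    """Per-bin insulation score track for one chromosome.

    ``score`` is the log2-normalized insulation; ``delta`` the directional
    difference track used for minimum detection; ``strength`` the boundary
    strength, NaN away from called candidate bins.
    """

    chrom: str
    bin_size: int
    score: np.ndarray
    delta: np.ndarray
    strength: np.ndarray

    @property
    def n_bins(self) -> int:
        return self.score.shape[0]


@dataclass(frozen=True)
class Boundary:
    """A TAD boundary: a bin-aligned, 0-based half-open interval."""

    chrom: str
    start: int
    end: int
    strength: float = 0.0
    source: str = ""

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("boundary end must exceed start")

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2

    def center_bin(self, bin_size: int) -> int:
        return self.center // bin_size


class BoundarySet:
    """An ordered collection of boundaries, sorted by (chrom, start)."""

    def __init__(self, boundaries: Iterable[Boundary] = ()):  # noqa: D107
        self._b = sorted(boundaries, key=lambda b: (b.chrom, b.start, b.end))

    def __len__(self) -> int:
        return len(self._b)

    def __iter__(self) -> Iterator[Boundary]:
        return iter(self._b)

    def __getitem__(self, i):
        return self._b[i]

    def __eq__(self, other) -> bool:
        return isinstance(other, BoundarySet) and self._b == other._b

    def chroms(self) -> list[str]:
        return sorted({b.chrom for b in self._b})

    def on_chrom(self, chrom: str) -> "BoundarySet":
        return BoundarySet(b for b in self._b if b.chrom == chrom)

    def starts(self, chrom: str | None = None) -> np.ndarray:
        bs = self._b if chrom is None else [b for b in self._b if b.chrom == chrom]
        return np.array([b.start for b in bs], dtype=int)

    def centers(self, chrom: str) -> np.ndarray:
        return np.array([b.center for b in self._b if b.chrom == chrom], dtype=int)

    def to_records(self) -> list[tuple]:
        return [(b.chrom, b.start, b.end, b.source, b.strength) for b in self._b]


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def apply_kr(raw: ContactMatrix, kr: NormalizationVector) -> ContactMatrix:
    """Normalize a raw map by Knight–Ruiz scores.

    ``out[i, j] = raw[i, j] / (kr[i] * kr[j])``.  Bins whose score is missing
    or non-positive are masked in the output.
    """
    if raw.chrom != kr.chrom:
        raise ValueError(f"chromosome mismatch: {raw.chrom} vs {kr.chrom}")
    if kr.scores.shape != (raw.n_bins,):
        raise ValueError("normalization vector length must equal n_bins")
    bad = kr.missing
    if (bad & ~raw.mask & np.isfinite(kr.scores)).any():
        warnings.warn("non-positive KR scores: affected bins masked")
    scores = np.where(bad, np.nan, kr.scores)
    out = raw.values / np.outer(scores, scores)
    return ContactMatrix(raw.chrom, raw.bin_size, out, raw.mask | bad)


def ice_normalize(raw: ContactMatrix, max_iter: int = 200,
                  tol: float = 1e-5) -> tuple[ContactMatrix, NormalizationVector]:
    """Iterative correction (ICE): alternately equalize row/column sums.

    Returns the balanced matrix and the bias vector ``b`` with
    ``out[i, j] = raw[i, j] / (b[i] * b[j])``.  Bins with zero marginals are
    auto-masked.  Biases are rescaled to mean 1 over unmasked bins so the
    overall count scale is preserved.
    """
    m = raw.with_auto_mask()
    live = ~m.mask
    if live.sum() < 2:
        raise ValueError("ICE requires at least 2 unmasked bins")
    v = np.nan_to_num(m.values[np.ix_(live, live)])
    if not v.sum() > 0:
        raise ValueError("cannot balance an all-zero matrix")

    bias = np.ones(v.shape[0])
    converged = False
    for _ in range(max_iter):
        s = v.sum(axis=1)
        target = s[s > 0].mean()
        adj = np.where(s > 0, s / target, 1.0)
        v /= np.outer(adj, adj)
        bias *= adj
        cv = s.std() / s.mean() if s.mean() > 0 else np.inf
        if cv <= tol:
            converged = True
            break
    if not converged:
        warnings.warn(f"ICE did not converge within {max_iter} iterations")

    scale = bias.mean()
    bias /= scale
    v *= scale * scale

    full_bias = np.full(m.n_bins, np.nan)
    full_bias[live] = bias
    out = np.full_like(m.values, np.nan)
    out[np.ix_(live, live)] = v
    return (ContactMatrix(m.chrom, m.bin_size, out, m.mask),
            NormalizationVector(m.chrom, full_bias))


# ---------------------------------------------------------------------------
# TAD signal and insulation
# ---------------------------------------------------------------------------

def tad_signal(mat: ContactMatrix, window: int = 2_000_000) -> np.ndarray:
    """Banded row-sum TAD signal.

    For each bin i, S(i) sums contacts to unmasked bins within ``window`` bp
    (diagonal excluded, truncated at chromosome ends); the signal is
    log2(S(i) / mean of S over bins within the window of i).  Masked bins and
    bins whose local mean is zero are NaN.
    """
    if window % mat.bin_size:
        raise ValueError("window must be a multiple of bin_size")
    w = window // mat.bin_size
    n = mat.n_bins
    v = np.nan_to_num(mat.values)
    s = np.full(n, np.nan)
    for i in range(n):
        lo, hi = max(0, i - w), min(n, i + w + 1)
        sel = np.arange(lo, hi)
        sel = sel[(sel != i) & ~mat.mask[sel]]
        s[i] = v[i, sel].sum() if sel.size else np.nan
    s[mat.mask] = np.nan

    sig = np.full(n, np.nan)
    for i in range(n):
        if mat.mask[i] or not np.isfinite(s[i]):
            continue
        lo, hi = max(0, i - w), min(n, i + w + 1)
        local = s[lo:hi]
        local = local[np.isfinite(local)]
        if local.size == 0 or local.mean() <= 0 or s[i] <= 0:
            continue
        sig[i] = np.log2(s[i] / local.mean())
    return sig


def insulation_profile(mat: ContactMatrix,
                       cfg: PipelineConfig | None = None) -> InsulationProfile:
    """Insulation score along the diagonal plus its delta track.

    The raw insulation I(i) is the mean contact over the square
    ``(i-s..i-1) x (i+1..i+s)`` (s bins per side) using unmasked entries only;
    a square with fewer than ``min_window_unmasked_frac`` valid entries is
    missing.  Scores are log2-normalized to the chromosome mean of I.
    ``delta(i)`` = mean score over ``(i+1..i+d)`` minus mean over
    ``(i-d..i-1)``; it crosses zero upward at insulation minima.
    """
    cfg = cfg or PipelineConfig()
    if cfg.insulation_square % mat.bin_size or cfg.delta_span % mat.bin_size:
        raise ValueError("insulation_square and delta_span must be multiples of bin_size")
    s = cfg.insulation_square // mat.bin_size
    d = cfg.delta_span // mat.bin_size
    n = mat.n_bins
    nan = np.full(n, np.nan)
    if n < 2 * s:
        warnings.warn(f"{mat.chrom}: shorter than twice the insulation square; "
                      "empty profile")
        return InsulationProfile(mat.chrom, mat.bin_size, nan.copy(),
                                 nan.copy(), nan.copy())

    raw = np.full(n, np.nan)
    for i in range(s, n - s):
        if mat.mask[i]:
            continue
        sq = mat.values[i - s:i, i + 1:i + s + 1]
        ok = np.isfinite(sq)
        if ok.sum() < cfg.min_window_unmasked_frac * sq.size:
            continue
        raw[i] = sq[ok].mean()

    finite = np.isfinite(raw)
    mean_i = raw[finite].mean() if finite.any() else np.nan
    score = np.full(n, np.nan)
    if np.isfinite(mean_i) and mean_i > 0:
        pos = finite & (raw > 0)
        score[pos] = np.log2(raw[pos] / mean_i)

    delta = np.full(n, np.nan)
    for i in range(n):
        right = score[i + 1:i + d + 1]
        left = score[max(0, i - d):i]
        right = right[np.isfinite(right)]
        left = left[np.isfinite(left)]
        if right.size and left.size:
            delta[i] = right.mean() - left.mean()
    return InsulationProfile(mat.chrom, mat.bin_size, score, delta, nan.copy())


# ---------------------------------------------------------------------------
# boundary calling
# ---------------------------------------------------------------------------

def _local_extrema(delta: np.ndarray, idx: int, kind: str,
                   direction: int) -> float:
    """Value of the nearest local extremum of ``delta`` walking from idx."""
    n = delta.shape[0]
    i = idx
    best = delta[idx] if np.isfinite(delta[idx]) else 0.0
    while 0 <= i + direction < n and np.isfinite(delta[i + direction]):
        nxt = delta[i + direction]
        if kind == "max" and nxt < best:
            break
        if kind == "min" and nxt > best:
            break
        best = nxt
        i += direction
    return best


def call_boundaries(prof: InsulationProfile, cfg: PipelineConfig | None = None,
                    source: str = "") -> BoundarySet:
    """Call TAD boundaries from an insulation profile.

    Candidates sit at upward zero crossings of the delta track (insulation
    minima).  Strength is the delta swing across the crossing — the nearest
    following local maximum minus the nearest preceding local minimum of
    delta.  Candidates below ``noise_threshold`` are dropped; candidates
    within ``boundary_margin`` bins are merged keeping the stronger (ties:
    smaller coordinate).  Each boundary is emitted as a 3-bin interval
    centered on the minimum bin.
    """
    cfg = cfg or PipelineConfig()
    delta, score = prof.delta, prof.score
    n = prof.n_bins
    half = cfg.boundary_bins // 2  # 1 bin each side for the default 75 kb

    cands: list[tuple[int, float]] = []
    for i in range(1, n):
        if not (np.isfinite(delta[i - 1]) and np.isfinite(delta[i])):
            continue
        if delta[i - 1] < 0 <= delta[i]:
            # place the candidate on the lower-insulation side of the crossing
            j = i - 1 if (np.isfinite(score[i - 1]) and np.isfinite(score[i])
                          and score[i - 1] < score[i]) else i
            lo = _local_extrema(delta, i - 1, "min", -1)
            hi = _local_extrema(delta, i, "max", +1)
            strength = hi - lo
            if strength >= cfg.noise_threshold:
                cands.append((j, strength))

    # merge candidates within boundary_margin bins, stronger wins
    merged: list[tuple[int, float]] = []
    for j, st in sorted(cands):
        if merged and j - merged[-1][0] <= cfg.boundary_margin:
            if st > merged[-1][1]:
                merged[-1] = (j, st)
        else:
            merged.append((j, st))

    out = []
    for j, st in merged:
        start = max(0, j - half) * prof.bin_size
        end = min(n, j + half + 1) * prof.bin_size
        out.append(Boundary(prof.chrom, start, end, strength=float(st),
                            source=source))
    return BoundarySet(out)
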