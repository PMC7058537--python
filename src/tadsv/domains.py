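"""TAD annotation by chromatin state and domain-level statistics.

Domains are the genomic regions between adjacent consensus boundaries.  Each
domain carries a 15-vector of chromatin-state coverage fractions and is
assigned to one of five classes (heterochromatin, low, repressed, low-active,
active) by k-means clustering of the coverage matrix; clusters are named by
the active-minus-quiescent mass of their centroid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from .boundaries import ShuffleNullResult, shuffle_boundaries, summarize_null
from .config import DEFAULT_STATE_DICTIONARY, DOMAIN_CLASS_ORDER
from .hic import Boundary, BoundarySet
from .sv import BAAnnotation, SVEvent

__all__ = [
    "DomainAnnotation", "LADTrack",
    "domains_from_boundaries", "state_coverage", "classify_domains",
    "flanking_pair_counts", "lad_overlap_test", "domain_expression_summary",
]

log = logging.getLogger(__name__)

N_STATES = 15


@dataclass
class DomainAnnotation:
    """One inter-boundary domain with optional state coverage and class."""

    chrom: str
    start: int
    end: int
    coverage: np.ndarray | None = None       # 15-vector of state fractions
    domain_class: str | None = None
    activity_rank: int | None = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("domain end must exceed start")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> float:
        return (self.start + self.end) / 2


@dataclass
class LADTrack:
    """Constitutive LAD / inter-LAD intervals per chromosome."""

    lads: Mapping[str, Sequence[tuple[int, int]]]
    inter_lads: Mapping[str, Sequence[tuple[int, int]]]

    def __post_init__(self) -> None:
        self.lads = {c: sorted(v) for c, v in self.lads.items()}
        self.inter_lads = {c: sorted(v) for c, v in self.inter_lads.items()}
        for track in (self.lads, self.inter_lads):
            for c, ivs in track.items():
                for (s0, e0), (s1, e1) in zip(ivs, ivs[1:]):
                    if s1 < e0:
                        raise ValueError(f"overlapping intervals on {c}")

    def label_at(self, chrom: str, pos: int) -> str | None:
        for name, track in (("LAD", self.lads), ("interLAD", self.inter_lads)):
            for s, e in track.get(chrom, ()):
                if s <= pos < e:
                    return name
        return None


def domains_from_boundaries(bset: BoundarySet,
                            chrom_sizes: Mapping[str, int],
                            ) -> list[DomainAnnotation]:
    """One domain per gap between adjacent boundaries on each chromosome.

    Domains exclude the boundary intervals themselves; chromosome-terminal
    segments (before the first / after the last boundary) are excluded.
    Chromosomes with fewer than two boundaries yield no domains.
    """
    out: list[DomainAnnotation] = []
    for chrom in bset.chroms():
        members = list(bset.on_chrom(chrom))
        if len(members) < 2:
            log.info("%s: fewer than 2 boundaries, no domains", chrom)
            continue
        for a, b in zip(members, members[1:]):
            if b.start > a.end:
                out.append(DomainAnnotation(chrom, a.end, b.start))
    return out


def state_coverage(domain: DomainAnnotation,
                   state_track: Sequence[tuple[str, int, int, int]],
                   ) -> np.ndarray:
    """Fraction of the domain covered by each of the 15 chromatin states.

    ``state_track`` rows are (chrom, start, end, state) with state in 1..15.
    Intervals of different states may not overlap each other.
    """
    cov = np.zeros(N_STATES)
    rows = sorted(r for r in state_track if r[0] == domain.chrom)
    prev_end_by_state: list[tuple[int, int, int]] = []
    for (_, s0, e0, st0), (_, s1, e1, st1) in zip(rows, rows[1:]):
        if s1 < e0 and st0 != st1:
            raise ValueError("overlapping state intervals of different states")
    for _, s, e, state in rows:
        if not 1 <= state <= N_STATES:
            raise ValueError(f"state {state} outside 1..{N_STATES}")
        ov = min(e, domain.end) - max(s, domain.start)
        if ov > 0:
            cov[state - 1] += ov
    return cov / domain.length


def _name_clusters(centroids: np.ndarray,
                   state_dictionary: Mapping[int, str]) -> list[str]:
    """Order cluster centroids by activity and assign the five class names."""
    active = np.array([state_dictionary.get(s + 1) == "active"
                       for s in range(N_STATES)])
    quiet = np.array([state_dictionary.get(s + 1) == "quiescent"
                      for s in range(N_STATES)])
    score = centroids[:, active].sum(axis=1) - centroids[:, quiet].sum(axis=1)
    order = np.argsort(score, kind="stable")  # least active first
    names = [""] * centroids.shape[0]
    for rank, ci in enumerate(order):
        names[ci] = DOMAIN_CLASS_ORDER[rank]
    return names


def classify_domains(coverage_matrix: np.ndarray, k: int = 5, seed: int = 0,
                     n_restarts: int = 50,
                     state_dictionary: Mapping[int, str] | None = None,
                     ) -> tuple[list[str], list[int], np.ndarray]:
    """k-means classification of domains by state coverage.

    Returns (class name per domain, activity rank per domain, centroids).
    Clusters are named by ranking centroids on active-state mass minus
    quiescent/heterochromatin mass, mapped onto the five canonical classes in
    increasing activity order.
    """
    state_dictionary = state_dictionary or DEFAULT_STATE_DICTIONARY
    X = np.asarray(coverage_matrix, dtype=float)
    if X.ndim != 2 or X.shape[1] != N_STATES:
        raise ValueError(f"coverage matrix must be (n, {N_STATES})")
    if np.unique(X, axis=0).shape[0] < k:
        raise ValueError(f"need at least {k} distinct coverage rows")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    labels = km.fit_predict(X)
    if k != len(DOMAIN_CLASS_ORDER):
        names = [f"cluster{i}" for i in range(k)]
        order = {i: i for i in range(k)}
        return ([names[l] for l in labels], [order[l] for l in labels],
                km.cluster_centers_)
    names = _name_clusters(km.cluster_centers_, state_dictionary)
    rank = {n: i for i, n in enumerate(DOMAIN_CLASS_ORDER)}
    return ([names[l] for l in labels],
            [rank[names[l]] for l in labels],
            km.cluster_centers_)


def annotate_domain_classes(domains: Sequence[DomainAnnotation],
                            state_track, k: int = 5, seed: int = 0,
                            n_restarts: int = 50,
                            state_dictionary=None) -> np.ndarray:
    """Compute coverage for every domain and classify in place."""
    X = np.vstack([state_coverage(d, state_track) for d in domains])
    names, ranks, centroids = classify_domains(
        X, k=k, seed=seed, n_restarts=n_restarts,
        state_dictionary=state_dictionary)
    for d, cov, nm, rk in zip(domains, X, names, ranks):
        d.coverage, d.domain_class, d.activity_rank = cov, nm, rk
    return centroids


# ---------------------------------------------------------------------------
# flanking-domain pairs
# ---------------------------------------------------------------------------

def _nearest_domain(domains: Sequence[DomainAnnotation],
                    chrom: str, pos: int) -> DomainAnnotation | None:
    """Domain containing pos, else nearest by center (ties to the left)."""
    best, best_d = None, None
    for d in domains:
        if d.chrom != chrom:
            continue
        if d.start <= pos < d.end:
            return d
        dist = abs(d.center - pos)
        if best_d is None or dist < best_d or (dist == best_d
                                               and d.start < best.start):
            best, best_d = d, dist
    return best


def flanking_pair_counts(ba_annotations: Sequence[BAAnnotation],
                         domains: Sequence[DomainAnnotation],
                         chrom_sizes: Mapping[str, int],
                         boundaries: BoundarySet | None = None,
                         n_shuffles: int = 200, seed: int = 0,
                         bin_size: int = 25_000,
                         ) -> tuple[pd.DataFrame, ShuffleNullResult]:
    """Class pair counts of the domains flanking each BA-SV's break-ends.

    For each BA-SV the class of the nearest domain at each break-end is
    looked up and the unordered pair counted into a half-matrix.  The
    same-class (diagonal) count is tested against a null in which boundaries
    are shuffled, the domain partition re-derived, and each null domain
    assigned the class of the original domain nearest to its center.
    """
    if any(d.domain_class is None for d in domains):
        raise ValueError("domains must be classified first")
    classes = list(DOMAIN_CLASS_ORDER)
    counts = pd.DataFrame(0, index=classes, columns=classes, dtype=int)

    def pair_counts(doms: Sequence[DomainAnnotation]) -> tuple[pd.DataFrame, int]:
        c = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
        same = 0
        for a in ba_annotations:
            if not a.is_ba:
                continue
            dl = _nearest_domain(doms, a.sv.chrom, a.sv.start)
            dr = _nearest_domain(doms, a.sv.chrom, a.sv.end)
            if dl is None or dr is None:
                log.info("SV %s has an undefined flank; skipped", a.sv)
                continue
            lo, hi = sorted([dl.domain_class, dr.domain_class],
                            key=classes.index)
            c.loc[lo, hi] += 1
            same += dl.domain_class == dr.domain_class
        return c, same

    counts, same_obs = pair_counts(domains)

    rng = np.random.default_rng(seed)
    null = np.zeros(n_shuffles)
    if boundaries is not None and n_shuffles > 0:
        for i in range(n_shuffles):
            sh = shuffle_boundaries(boundaries, chrom_sizes,
                                    int(rng.integers(2**31)), bin_size)
            sh_doms = domains_from_boundaries(sh, chrom_sizes)
            for d in sh_doms:
                src = _nearest_domain(domains, d.chrom, int(d.center))
                d.domain_class = src.domain_class if src else classes[0]
            _, null[i] = pair_counts(sh_doms)
        res = summarize_null(same_obs, null, seed)
    else:
        res = ShuffleNullResult(float(same_obs), np.nan, np.nan, np.nan,
                                np.nan, np.nan, 0, seed)
    return counts, res


# ---------------------------------------------------------------------------
# LAD overlap
# ---------------------------------------------------------------------------

LAD_CATEGORIES = ("within-LAD", "within-interLAD", "crossing")


def _categorize(track: LADTrack, chrom: str, start: int,
                end: int) -> str | None:
    l1 = track.label_at(chrom, start)
    l2 = track.label_at(chrom, end - 1)
    if l1 is None or l2 is None:
        return None
    if l1 == l2 == "LAD":
        return "within-LAD"
    if l1 == l2 == "interLAD":
        return "within-interLAD"
    return "crossing"


def lad_overlap_test(svs: Sequence[SVEvent], lads: LADTrack,
                     chrom_sizes: Mapping[str, int], n_shuffles: int = 10_000,
                     seed: int = 0) -> dict[tuple[str, str], ShuffleNullResult]:
    """SV placement relative to constitutive LADs, per type and category.

    Each SV is categorized by the LAD membership of its two break-ends.  The
    null re-places each event uniformly on its own chromosome preserving its
    length, ``n_shuffles`` times; a z and p are reported per (sv_type,
    category).
    """
    rng = np.random.default_rng(seed)
    by_type: dict[str, list[SVEvent]] = {}
    for sv in svs:
        if sv.chrom not in chrom_sizes:
            log.info("SV on %s absent from track; skipped", sv.chrom)
            continue
        by_type.setdefault(sv.sv_type, []).append(sv)

    out: dict[tuple[str, str], ShuffleNullResult] = {}
    for t, tsvs in sorted(by_type.items()):
        obs = {c: 0 for c in LAD_CATEGORIES}
        for sv in tsvs:
            c = _categorize(lads, sv.chrom, sv.start, sv.end)
            if c:
                obs[c] += 1
        null = {c: np.zeros(n_shuffles) for c in LAD_CATEGORIES}
        for sv in tsvs:
            span = chrom_sizes[sv.chrom] - sv.length
            if span <= 0:
                continue
            starts = rng.integers(0, span + 1, size=n_shuffles)
            for k, s in enumerate(starts):
                c = _categorize(lads, sv.chrom, int(s), int(s) + sv.length)
                if c:
                    null[c][k] += 1
        for c in LAD_CATEGORIES:
            out[(t, c)] = summarize_null(obs[c], null[c], seed)
    return out


# ---------------------------------------------------------------------------
# domain-level expression
# ---------------------------------------------------------------------------

def domain_expression_summary(domains: Sequence[DomainAnnotation],
                              genes: Sequence,
                              expression: pd.DataFrame,
                              ) -> tuple[pd.Series, dict[str, float]]:
    """Median log2 expression per domain class and rank tests vs active.

    Genes are assigned to the unique domain containing their start; each
    gene's expression is its mean over samples, log2-transformed.  For every
    non-active class a one-tailed Mann–Whitney U tests whether its genes are
    expressed below the active class; classes with fewer than 3 genes are
    skipped.
    """
    if any(d.domain_class is None for d in domains):
        raise ValueError("domains must be classified first")
    per_class: dict[str, list[float]] = {c: [] for c in DOMAIN_CLASS_ORDER}
    for g in genes:
        if g.gene_id not in expression.index:
            continue
        d = next((d for d in domains
                  if d.chrom == g.chrom and d.start <= g.start < d.end), None)
        if d is None:
            continue
        val = float(expression.loc[g.gene_id].mean())
        if val > 0:
            per_class[d.domain_class].append(np.log2(val))

    medians = pd.Series({c: (np.median(v) if v else np.nan)
                         for c, v in per_class.items()})
    pvals: dict[str, float] = {}
    active = per_class["active"]
    for c in DOMAIN_CLASS_ORDER[:-1]:
        if len(per_class[c]) >= 3 and len(active) >= 3:
            pvals[c] = float(stats.mannwhitneyu(
                per_class[c], active, alternative="less").pvalue)
    return medians, pvals
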