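"""Synthetic input generators with known ground truth.

Every pipeline input — distance-decay contact maps with block TADs, cohort SV
catalogs, chromatin-state tracks, LADs, gene models, expression and
copy-number tables — can be generated here as a pure function of a spec and a
seed, enabling parameter-recovery and calibration tests without any external
data.  Contact maps follow expected(i, j) = depth * d^(-alpha) * (1 +
tau*[same TAD]) with Poisson counts; rearranged maps are simulated on the
derived (post-SV) genome and projected back to reference coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .domains import DomainAnnotation, LADTrack
from .expression import GeneRecord
from .hic import Boundary, BoundarySet, ContactMatrix

__all__ = [
    "GenomeSpec", "CohortSpec", "EffectSpec", "TruthBundle",
    "plant_boundaries", "simulate_hic", "simulate_rearranged_hic",
    "simulate_sv_catalog", "simulate_states_lads_genes_expression",
    "simulate_bundle", "CLASS_ARCHETYPES", "CLASS_EXPRESSION_MEAN",
]


@dataclass(frozen=True)
class GenomeSpec:
    """Chromosome names/sizes and bin size of the synthetic genome."""

    chrom_sizes: Mapping[str, int] = field(
        default_factory=lambda: {"chr1": 20_000_000, "chr2": 20_000_000})
    bin_size: int = 25_000

    def __post_init__(self) -> None:
        for c, s in self.chrom_sizes.items():
            if s % self.bin_size:
                raise ValueError(f"{c}: size must be a multiple of bin_size")

    def n_bins(self, chrom: str) -> int:
        return self.chrom_sizes[chrom] // self.bin_size


@dataclass
class CohortSpec:
    """Shape of a simulated SV cohort."""

    cohort: str = "SIM"
    n_samples: int = 30
    svs_per_sample: float = 8.0          # Poisson mean
    type_mix: Mapping[str, float] = field(default_factory=lambda: {
        "DEL": 0.40, "DUP": 0.30, "INV": 0.20, "COMPLEX": 0.10})
    len_range: tuple[int, int] = (50_000, 2_000_000)  # log-uniform
    origin: str = "somatic"


@dataclass
class EffectSpec:
    """Planted expression effect for BA carrier samples."""

    effect: float = 8.0
    n_affected_samples: int = 5
    n_target_genes: int = 20
    noise_cv: float = 0.3


@dataclass
class TruthBundle:
    """Ground truth of one simulated study."""

    seed: int
    boundaries: dict[str, BoundarySet] = field(default_factory=dict)
    consensus: BoundarySet | None = None
    domain_classes: list[str] = field(default_factory=list)
    svs: list = field(default_factory=list)
    ba_flags: list[bool] = field(default_factory=list)
    affected_samples: list[str] = field(default_factory=list)
    target_genes: list[str] = field(default_factory=list)
    effect: float = 1.0


# ---------------------------------------------------------------------------
# boundaries and contact maps
# ---------------------------------------------------------------------------

def plant_boundaries(spec: GenomeSpec, spacing: int = 2_000_000,
                     margin: int = 2_000_000, jitter_bins: int = 0,
                     seed: int = 0, source: str = "planted") -> BoundarySet:
    """Evenly spaced 3-bin boundaries, optionally jittered by whole bins."""
    rng = np.random.default_rng(seed)
    b = spec.bin_size
    out = []
    for chrom, size in spec.chrom_sizes.items():
        for center in range(margin, size - margin + 1, spacing):
            cb = center // b
            if jitter_bins:
                cb += int(rng.integers(-jitter_bins, jitter_bins + 1))
            out.append(Boundary(chrom, (cb - 1) * b, (cb + 2) * b,
                                strength=1.0, source=source))
    return BoundarySet(out)


def _tad_ids(junction_bins: np.ndarray, n_bins: int) -> np.ndarray:
    """TAD index per bin given junction (boundary-center) bins."""
    return np.searchsorted(np.sort(junction_bins), np.arange(n_bins),
                           side="right")


def _sample_contacts(expected: np.ndarray,
                     rng: np.random.Generator) -> np.ndarray:
    """Poisson counts on the upper triangle, mirrored to a symmetric matrix."""
    n = expected.shape[0]
    iu = np.triu_indices(n)
    counts = rng.poisson(expected[iu]).astype(float)
    m = np.zeros((n, n))
    m[iu] = counts
    m.T[iu] = counts
    return m


def simulate_hic(spec: GenomeSpec, boundaries: BoundarySet, alpha: float = 1.0,
                 tau: float = 1.0, depth: float = 60.0,
                 seed: int = 0) -> dict[str, ContactMatrix]:
    """Block-TAD contact maps with power-law distance decay.

    ``expected(i, j) = depth * max(|i-j|, 1)^(-alpha) * (1 + tau*[same TAD])``
    with independent Poisson counts per bin pair.  Deterministic in ``seed``.
    """
    if alpha <= 0 or tau < 0:
        raise ValueError("alpha must be > 0 and tau >= 0")
    out = {}
    for ci, (chrom, size) in enumerate(spec.chrom_sizes.items()):
        rng = np.random.default_rng([seed, ci])
        n = spec.n_bins(chrom)
        centers = np.array([b.center_bin(spec.bin_size)
                            for b in boundaries.on_chrom(chrom)], dtype=int)
        tid = _tad_ids(centers, n)
        d = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
        expected = depth * np.maximum(d, 1) ** (-alpha) \
            * (1 + tau * (tid[:, None] == tid[None, :]))
        out[chrom] = ContactMatrix(chrom, spec.bin_size,
                                   _sample_contacts(expected, rng))
    return out


def _derived_bins(n_bins: int, svs: Sequence, bin_size: int) -> np.ndarray:
    """Reference-bin sequence of the derived (rearranged) chromosome."""
    events = sorted(svs, key=lambda s: s.start)
    for a, b in zip(events, events[1:]):
        if b.start < a.end:
            raise ValueError("nested/overlapping SVs are not supported")
    seq: list[np.ndarray] = []
    cur = 0
    for sv in events:
        s, e = sv.start // bin_size, -(-sv.end // bin_size)
        seq.append(np.arange(cur, s))
        seg = np.arange(s, e)
        if sv.sv_type == "DEL":
            pass
        elif sv.sv_type == "DUP":
            seq.extend([seg, seg])
        elif sv.sv_type == "INV":
            seq.append(seg[::-1])
        else:
            raise ValueError(f"unsupported sv_type {sv.sv_type} in rearrangement")
        cur = e
    seq.append(np.arange(cur, n_bins))
    return np.concatenate(seq)


def simulate_rearranged_hic(spec: GenomeSpec, boundaries: BoundarySet,
                            sv_list: Sequence, alpha: float = 1.0,
                            tau: float = 1.0, depth: float = 60.0,
                            seed: int = 0) -> dict[str, ContactMatrix]:
    """Contact maps of a rearranged genome, projected to reference bins.

    Deletions remove bins, tandem duplications repeat the segment, inversions
    reverse it.  TADs are re-derived from the boundaries surviving on the
    derived chromosome; contacts are simulated there (distance measured in
    derived coordinates) and each derived pair's counts are added to the
    reference bin pair, summing over duplicated copies.  Bins deleted on
    every haplotype copy are masked.
    """
    out = {}
    for ci, (chrom, size) in enumerate(spec.chrom_sizes.items()):
        rng = np.random.default_rng([seed + 1_000_003, ci])
        n = spec.n_bins(chrom)
        chrom_svs = [sv for sv in sv_list if sv.chrom == chrom]
        derived = _derived_bins(n, chrom_svs, spec.bin_size)
        m = derived.size
        centers = np.array([b.center_bin(spec.bin_size)
                            for b in boundaries.on_chrom(chrom)], dtype=int)
        # surviving boundary junctions, at every derived occurrence
        junc = np.nonzero(np.isin(derived, centers))[0]
        tid = _tad_ids(junc, m)
        d = np.abs(np.subtract.outer(np.arange(m), np.arange(m)))
        expected = depth * np.maximum(d, 1) ** (-alpha) \
            * (1 + tau * (tid[:, None] == tid[None, :]))
        dm = _sample_contacts(expected, rng)
        ref = np.zeros((n, n))
        np.add.at(ref, (derived[:, None] * np.ones(m, int),
                        np.ones(m, int)[:, None] * derived), dm)
        present = np.zeros(n, dtype=bool)
        present[derived] = True
        out[chrom] = ContactMatrix(chrom, spec.bin_size, ref, ~present)
    return out


# ---------------------------------------------------------------------------
# SV catalogs
# ---------------------------------------------------------------------------

def simulate_sv_catalog(spec: GenomeSpec, cohort: CohortSpec,
                        boundaries: BoundarySet,
                        enrichment_knob: float | Mapping[str, float] = 0.0,
                        seed: int = 0) -> tuple[list, list[bool]]:
    """Cohort SV catalog with recorded boundary-spanning truth flags.

    Lengths are log-uniform within ``cohort.len_range``; placement is uniform
    except for a per-type fraction of events (``enrichment_knob``, positive)
    forced to span a boundary, or (negative) forced to avoid all boundaries.
    Returns (events, truth BA flags), deterministic in ``seed``.
    """
    from .sv import SVEvent  # local import to avoid cycle at module load

    rng = np.random.default_rng(seed)
    knobs = (dict.fromkeys(cohort.type_mix, float(enrichment_knob))
             if np.isscalar(enrichment_knob) else dict(enrichment_knob))
    chroms = list(spec.chrom_sizes)
    weights = np.array([spec.chrom_sizes[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    types = list(cohort.type_mix)
    probs = np.array([cohort.type_mix[t] for t in types], dtype=float)
    probs /= probs.sum()
    lo, hi = cohort.len_range

    b_by_chrom = {c: list(boundaries.on_chrom(c)) for c in chroms}

    def spans_any(chrom: str, s: int, e: int) -> bool:
        return any(s <= b.start and e >= b.end for b in b_by_chrom[chrom])

    events, flags = [], []
    for si in range(cohort.n_samples):
        sample = f"{cohort.cohort}_S{si:03d}"
        n_sv = rng.poisson(cohort.svs_per_sample)
        for _ in range(n_sv):
            t = types[rng.choice(len(types), p=probs)]
            length = int(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            length = max(length, spec.bin_size)
            chrom = chroms[rng.choice(len(chroms), p=weights)]
            size = spec.chrom_sizes[chrom]
            knob = knobs.get(t, 0.0)
            forced_span = knob > 0 and rng.random() < knob
            forced_avoid = knob < 0 and rng.random() < -knob
            placed = False
            for _ in range(1000):
                if forced_span and b_by_chrom[chrom]:
                    b = b_by_chrom[chrom][rng.integers(len(b_by_chrom[chrom]))]
                    width = b.end - b.start
                    if length <= width:  # too short to contain the boundary
                        length = int(np.exp(rng.uniform(
                            np.log(width + spec.bin_size), np.log(hi))))
                    s_lo = max(0, b.end - length)
                    s_hi = min(b.start, size - length)
                    if s_hi < s_lo:
                        continue
                    start = int(rng.integers(s_lo, s_hi + 1))
                else:
                    start = int(rng.integers(0, size - length + 1))
                end = start + length
                if forced_avoid and spans_any(chrom, start, end):
                    continue
                events.append(SVEvent(sample, cohort.cohort, chrom, start,
                                      end, t, cohort.origin))
                flags.append(spans_any(chrom, start, end))
                placed = True
                break
            if not placed:
                raise RuntimeError("could not place SV after 1000 retries")
    return events, flags


# ---------------------------------------------------------------------------
# states, LADs, genes, expression
# ---------------------------------------------------------------------------

#: Per-class 15-state composition archetypes (rows sum to 1).  State indices
#: follow the Roadmap-style core model; activity increases down the list.
CLASS_ARCHETYPES: dict[str, np.ndarray] = {
    "heterochromatin": np.array(
        [.01, .01, 0, .01, .01, 0, .01, .02, .80, 0, 0, 0, .02, .03, .08]),
    "low": np.array(
        [.01, .01, 0, .01, .02, 0, .01, .01, .05, 0, 0, 0, .02, .06, .80]),
    "repressed": np.array(
        [.01, .01, 0, .01, .02, 0, .02, .01, .05, .02, .02, .02, .50, .21, .10]),
    "low-active": np.array(
        [.04, .03, .01, .10, .15, .02, .05, .02, .05, .02, .02, .02, .07, .10, .30]),
    "active": np.array(
        [.15, .10, .04, .25, .12, .04, .10, .02, .02, .02, .02, .02, .03, .03, .04]),
}

#: Planted per-class mean expression (RPKM-like), ordered by activity.
CLASS_EXPRESSION_MEAN: dict[str, float] = {
    "heterochromatin": 0.5, "low": 1.0, "repressed": 2.0,
    "low-active": 8.0, "active": 32.0,
}


def simulate_states_lads_genes_expression(
        spec: GenomeSpec, domains: Sequence[DomainAnnotation],
        domain_classes: Sequence[str], effect: EffectSpec | None = None,
        genes_per_mb: float = 8.0, dirichlet_conc: float = 60.0,
        cn_aberrant_frac: float = 0.05, seed: int = 0) -> dict:
    """State track, LADs, genes, expression and CN tables from planted classes.

    Each domain draws its state composition from a Dirichlet around its
    class archetype and is written as contiguous state intervals.
    Heterochromatin/low domains become constitutive LADs, the rest inter-LADs.
    Genes are placed uniformly within domains (density per Mb); expression is
    log-normal around the class mean with the requested CV; a planted effect
    multiplies the target genes' expression in the affected samples.  Copy
    number is 2 apart from a small aberrant fraction.
    """
    if len(domains) != len(domain_classes):
        raise ValueError("one class per domain required")
    effect = effect or EffectSpec(effect=1.0, n_affected_samples=0,
                                  n_target_genes=0)
    rng = np.random.default_rng(seed)

    state_track: list[tuple[str, int, int, int]] = []
    lads: dict[str, list[tuple[int, int]]] = {c: [] for c in spec.chrom_sizes}
    inter: dict[str, list[tuple[int, int]]] = {c: [] for c in spec.chrom_sizes}
    genes: list[GeneRecord] = []
    gene_class: list[str] = []

    gid = 0
    for d, cls in zip(domains, domain_classes):
        comp = rng.dirichlet(CLASS_ARCHETYPES[cls] * dirichlet_conc + 1e-3)
        prev = 0
        order = rng.permutation(15)
        for st in order:
            seg = int(comp[st] * d.length)
            if seg > 0:
                state_track.append((d.chrom, d.start + prev,
                                    min(d.start + prev + seg, d.end), st + 1))
                prev += seg
        if prev < d.length:  # rounding remainder -> quiescent
            state_track.append((d.chrom, d.start + prev, d.end, 15))
        (lads if cls in ("heterochromatin", "low") else inter)[d.chrom].append(
            (d.start, d.end))

        n_genes = rng.poisson(genes_per_mb * d.length / 1e6)
        for _ in range(n_genes):
            gs = int(rng.integers(d.start, max(d.start + 1, d.end - 10_000)))
            genes.append(GeneRecord(f"g{gid:05d}", d.chrom, gs, gs + 10_000))
            gene_class.append(cls)
            gid += 1

    samples = [f"SIM_S{si:03d}" for si in range(max(effect.n_affected_samples,
                                                    0) + 25)]
    sigma = np.sqrt(np.log(1 + effect.noise_cv ** 2))
    base = np.array([CLASS_EXPRESSION_MEAN[c] for c in gene_class])
    base = base * rng.lognormal(0.0, 0.4, size=base.size)  # gene-level spread
    noise = rng.lognormal(-sigma ** 2 / 2, sigma,
                          size=(base.size, len(samples)))
    expr = pd.DataFrame(base[:, None] * noise,
                        index=[g.gene_id for g in genes], columns=samples)

    affected = samples[:effect.n_affected_samples]
    candidates = [g.gene_id for g in genes]
    targets = list(rng.choice(candidates,
                              size=min(effect.n_target_genes, len(candidates)),
                              replace=False)) if effect.n_target_genes else []
    for g in targets:
        expr.loc[g, affected] *= effect.effect

    cn = pd.DataFrame(2.0, index=expr.index, columns=samples)
    ab = rng.random(size=cn.shape) < cn_aberrant_frac
    cn.values[ab] = rng.choice([0, 1, 3, 5, 6], size=int(ab.sum()))

    return {
        "state_track": sorted(state_track),
        "lad_track": LADTrack(lads, inter),
        "genes": genes,
        "gene_classes": gene_class,
        "expression": expr,
        "cn": cn,
        "affected_samples": affected,
        "target_genes": targets,
    }


# ---------------------------------------------------------------------------
# full bundle
# ---------------------------------------------------------------------------

def simulate_bundle(spec: GenomeSpec | None = None, seed: int = 0,
                    n_cell_types: int = 3, private_per_chrom: int = 2,
                    cohort: CohortSpec | None = None,
                    enrichment_knob: float | Mapping[str, float] = 0.0,
                    effect: EffectSpec | None = None,
                    alpha: float = 1.0, tau: float = 1.0,
                    depth: float = 60.0) -> dict:
    """One complete simulated study: maps, boundary truth, SVs, annotations.

    Cell-type boundary sets share the planted consensus boundaries; each cell
    type additionally carries a few private boundaries so consensus building
    is non-trivial.
    """
    spec = spec or GenomeSpec()
    cohort = cohort or CohortSpec()
    rng = np.random.default_rng(seed)
    shared = plant_boundaries(spec, source="shared")
    truth = TruthBundle(seed=seed, consensus=shared)

    cell_sets: dict[str, BoundarySet] = {}
    matrices: dict[str, dict[str, ContactMatrix]] = {}
    for k in range(n_cell_types):
        name = f"CT{k}"
        extra = []
        for chrom, size in spec.chrom_sizes.items():
            shared_bins = {b.center_bin(spec.bin_size)
                           for b in shared.on_chrom(chrom)}
            n_bins = size // spec.bin_size
            for _ in range(private_per_chrom):
                # keep private boundaries at least 600 kb (24 bins) from any
                # other boundary so adjacent insulation minima stay resolvable
                while True:
                    cb = int(rng.integers(60, n_bins - 60))
                    if all(abs(cb - sb) >= 24 for sb in shared_bins):
                        shared_bins.add(cb)
                        break
                extra.append(Boundary(chrom, (cb - 1) * spec.bin_size,
                                      (cb + 2) * spec.bin_size, 1.0, name))
        bset = BoundarySet(list(shared) + extra)
        cell_sets[name] = bset
        truth.boundaries[name] = bset
        matrices[name] = simulate_hic(spec, bset, alpha, tau, depth,
                                      seed=int(rng.integers(2**31)))

    svs, flags = simulate_sv_catalog(spec, cohort, shared, enrichment_knob,
                                     seed=int(rng.integers(2**31)))
    truth.svs, truth.ba_flags = svs, flags

    from .domains import domains_from_boundaries
    domains = domains_from_boundaries(shared, spec.chrom_sizes)
    class_names = list(CLASS_ARCHETYPES)
    classes = [class_names[int(i)] for i in rng.integers(0, 5, len(domains))]
    truth.domain_classes = classes
    anno = simulate_states_lads_genes_expression(
        spec, domains, classes, effect, seed=int(rng.integers(2**31)))
    truth.affected_samples = anno["affected_samples"]
    truth.target_genes = anno["target_genes"]
    truth.effect = effect.effect if effect else 1.0

    return {
        "spec": spec,
        "truth": truth,
        "cell_sets": cell_sets,
        "matrices": matrices,
        "svs": svs,
        "domains": domains,
        **anno,
    }
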