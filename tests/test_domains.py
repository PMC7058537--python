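"""Domain construction, state classification, flanking pairs, LAD tests."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from tadsv.config import DOMAIN_CLASS_ORDER
from tadsv.domains import (DomainAnnotation, LADTrack, classify_domains,
                           domain_expression_summary, domains_from_boundaries,
                           flanking_pair_counts, lad_overlap_test,
                           state_coverage)
from tadsv.expression import GeneRecord
from tadsv.hic import Boundary, BoundarySet
from tadsv.sv import BAAnnotation, SVEvent, annotate_ba
from tadsv.synthetic import CLASS_ARCHETYPES

from conftest import boundary_at

SIZES = {"chr1": 20_000_000}


class TestDomainConstruction:
    def test_gap_between_boundaries(self):
        bset = BoundarySet([Boundary("chr1", 1_000_000, 1_075_000, 1, "c"),
                            Boundary("chr1", 2_000_000, 2_075_000, 1, "c")])
        doms = domains_from_boundaries(bset, SIZES)
        assert len(doms) == 1
        assert (doms[0].start, doms[0].end) == (1_075_000, 2_000_000)

    def test_touching_boundaries_drop_zero_length_domain(self):
        bset = BoundarySet([Boundary("chr1", 1_000_000, 1_075_000, 1, "c"),
                            Boundary("chr1", 1_075_000, 1_150_000, 1, "c")])
        assert domains_from_boundaries(bset, SIZES) == []

    def test_three_boundaries_two_domains_and_tiling(self):
        bset = BoundarySet([boundary_at(c) for c in (100, 300, 500)])
        doms = domains_from_boundaries(bset, SIZES)
        assert len(doms) == 2
        # domains + boundaries tile the interior without overlap
        pieces = sorted([(b.start, b.end) for b in bset]
                        + [(d.start, d.end) for d in doms])
        for (s0, e0), (s1, e1) in zip(pieces, pieces[1:]):
            assert e0 == s1

    def test_single_boundary_chromosome_yields_nothing(self):
        assert domains_from_boundaries(BoundarySet([boundary_at(100)]),
                                       SIZES) == []


class TestStateCoverage:
    def test_single_state_unit_vector(self):
        d = DomainAnnotation("chr1", 0, 100_000)
        cov = state_coverage(d, [("chr1", 0, 100_000, 7)])
        assert cov[6] == 1.0 and cov.sum() == 1.0

    def test_half_and_half(self):
        d = DomainAnnotation("chr1", 0, 100_000)
        cov = state_coverage(d, [("chr1", 0, 50_000, 1),
                                 ("chr1", 50_000, 100_000, 15)])
        assert cov[0] == 0.5 and cov[14] == 0.5

    def test_toy_track_matches_bruteforce_bp_oracle(self):
        d = DomainAnnotation("chr1", 30_000, 170_000)
        track = [("chr1", 0, 40_000, 1), ("chr1", 40_000, 55_000, 4),
                 ("chr1", 55_000, 90_000, 9), ("chr1", 90_000, 120_000, 15),
                 ("chr1", 120_000, 150_000, 13), ("chr1", 150_000, 200_000, 1),
                 ("chr2", 0, 1_000_000, 2)]
        cov = state_coverage(d, track)
        oracle = np.zeros(15)
        for pos in range(30_000, 170_000, 1000):  # 1-kb brute-force scan
            for chrom, s, e, st in track:
                if chrom == "chr1" and s <= pos < e:
                    oracle[st - 1] += 1000
        assert np.allclose(cov, oracle / 140_000)

    def test_overlapping_states_rejected(self):
        d = DomainAnnotation("chr1", 0, 100_000)
        with pytest.raises(ValueError):
            state_coverage(d, [("chr1", 0, 60_000, 1),
                               ("chr1", 50_000, 100_000, 2)])


class TestClassification:
    def test_planted_archetypes_recovered_and_named(self):
        rng = np.random.default_rng(43)
        truth, rows = [], []
        names = list(CLASS_ARCHETYPES)
        for i in range(300):
            cls = names[i % 5]
            truth.append(cls)
            rows.append(rng.dirichlet(CLASS_ARCHETYPES[cls] * 60 + 1e-3))
        labels, ranks, centroids = classify_domains(np.vstack(rows), seed=0)
        assert adjusted_rand_score(truth, labels) >= 0.9
        # majority label of each truth class is the truth class itself
        for cls in names:
            got = pd.Series([l for l, t in zip(labels, truth) if t == cls])
            assert got.mode()[0] == cls

    def test_deterministic_under_fixed_seed(self):
        rng = np.random.default_rng(47)
        X = rng.dirichlet(np.ones(15), size=40)
        a = classify_domains(X, seed=3)[0]
        b = classify_domains(X, seed=3)[0]
        assert a == b

    def test_identical_rows_rejected(self):
        X = np.tile(np.full(15, 1 / 15), (10, 1))
        with pytest.raises(ValueError):
            classify_domains(X)


def _classified_domains():
    """Six classified domains over chr1 (alternating repressed/active)."""
    doms = []
    classes = ["repressed", "active"] * 3
    rank = {n: i for i, n in enumerate(DOMAIN_CLASS_ORDER)}
    for i, cls in enumerate(classes):
        d = DomainAnnotation("chr1", 1_000_000 + i * 3_000_000,
                             3_500_000 + i * 3_000_000)
        d.domain_class, d.activity_rank = cls, rank[cls]
        doms.append(d)
    return doms


class TestFlankingPairs:
    def test_manual_pair_assignment(self):
        doms = _classified_domains()
        svs = [
            SVEvent("S1", "C", "chr1", 2_000_000, 3_000_000, "DEL"),   # rep-rep
            SVEvent("S1", "C", "chr1", 2_000_000, 5_000_000, "DEL"),   # rep-act
            SVEvent("S1", "C", "chr1", 5_000_000, 8_000_000, "DUP"),   # act-rep
            SVEvent("S1", "C", "chr1", 4_500_000, 6_000_000, "INV"),   # act-act
        ]
        ann = [BAAnnotation(s, [Boundary("chr1", 0, 75_000, 1, "c")])
               for s in svs]
        counts, _ = flanking_pair_counts(ann, doms, SIZES, n_shuffles=0)
        assert counts.loc["repressed", "repressed"] == 1
        assert counts.loc["repressed", "active"] == 2  # unordered pair
        assert counts.loc["active", "active"] == 1
        assert counts.to_numpy().sum() == 4

    def test_all_svs_in_one_class_only_diagonal(self):
        doms = _classified_domains()
        svs = [SVEvent("S1", "C", "chr1", 1_200_000 + k * 10_000,
                       1_400_000 + k * 10_000, "DEL") for k in range(3)]
        ann = [BAAnnotation(s, [Boundary("chr1", 0, 75_000, 1, "c")])
               for s in svs]
        counts, _ = flanking_pair_counts(ann, doms, SIZES, n_shuffles=0)
        assert counts.loc["repressed", "repressed"] == 3
        assert counts.to_numpy().sum() == 3

    def test_total_equals_svs_with_both_flanks(self):
        doms = _classified_domains()
        rng = np.random.default_rng(53)
        svs = [SVEvent("S1", "C", "chr1", int(s), int(s) + 400_000, "DEL")
               for s in rng.integers(1_000_000, 18_000_000, 25)]
        ann = [BAAnnotation(s, [Boundary("chr1", 0, 75_000, 1, "c")])
               for s in svs]
        counts, _ = flanking_pair_counts(ann, doms, SIZES, n_shuffles=0)
        assert counts.to_numpy().sum() == len(svs)


class TestLADOverlap:
    def test_full_lad_genome_all_within(self):
        track = LADTrack({"chr1": [(0, 20_000_000)]}, {})
        svs = [SVEvent("S1", "C", "chr1", s, s + 300_000, "DEL")
               for s in range(1_000_000, 10_000_000, 1_000_000)]
        res = lad_overlap_test(svs, track, SIZES, n_shuffles=50, seed=1)
        assert res[("DEL", "within-LAD")].observed == len(svs)
        assert res[("DEL", "crossing")].observed == 0

    def test_planted_border_crossing_enriched(self):
        # LADs on even megabases; SVs planted across borders
        lads = {"chr1": [(i * 2_000_000, i * 2_000_000 + 1_000_000)
                         for i in range(10)]}
        inter = {"chr1": [(i * 2_000_000 + 1_000_000, (i + 1) * 2_000_000)
                          for i in range(10)]}
        track = LADTrack(lads, inter)
        svs = [SVEvent("S1", "C", "chr1", i * 2_000_000 + 900_000,
                       i * 2_000_000 + 1_100_000, "DEL") for i in range(9)]
        res = lad_overlap_test(svs, track, SIZES, n_shuffles=400, seed=2)
        assert res[("DEL", "crossing")].z > 3


class TestDomainExpression:
    def test_planted_ordering_recovered(self):
        rng = np.random.default_rng(59)
        doms, genes, vals = [], [], {}
        rank = {n: i for i, n in enumerate(DOMAIN_CLASS_ORDER)}
        means = {"heterochromatin": 0.5, "low": 1, "repressed": 2,
                 "low-active": 8, "active": 32}
        gid = 0
        for i, cls in enumerate(list(means) * 4):
            d = DomainAnnotation("chr1", i * 1_000_000, (i + 1) * 1_000_000)
            d.domain_class, d.activity_rank = cls, rank[cls]
            doms.append(d)
            for _ in range(5):
                g = GeneRecord(f"g{gid}", "chr1",
                               i * 1_000_000 + int(rng.integers(0, 900_000)),
                               i * 1_000_000 + 990_000)
                genes.append(g)
                vals[g.gene_id] = means[cls] * rng.lognormal(0, 0.3, 4)
                gid += 1
        expr = pd.DataFrame(vals).T
        med, pvals = domain_expression_summary(doms, genes, expr)
        ordered = med[list(DOMAIN_CLASS_ORDER)]
        assert ordered.is_monotonic_increasing
        assert all(p < 0.01 for p in pvals.values())

    def test_gene_outside_all_domains_excluded(self):
        d = DomainAnnotation("chr1", 1_000_000, 2_000_000)
        d.domain_class, d.activity_rank = "active", 4
        genes = [GeneRecord("in", "chr1", 1_500_000, 1_510_000),
                 GeneRecord("out", "chr1", 5_000_000, 5_010_000)]
        expr = pd.DataFrame({"s1": [4.0, 9.0], "s2": [4.0, 9.0]},
                            index=["in", "out"])
        med, _ = domain_expression_summary([d], genes, expr)
        assert med["active"] == pytest.approx(2.0)  # log2(4)
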