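"""Contact-matrix normalization, insulation scoring and boundary calling."""

import numpy as np
import pytest

from tadsv.config import PipelineConfig
from tadsv.hic import (ContactMatrix, InsulationProfile, NormalizationVector,
                       apply_kr, call_boundaries, ice_normalize,
                       insulation_profile, tad_signal)

from conftest import constant_matrix


class TestApplyKR:
    def test_identity_scores_leave_matrix_unchanged(self):
        m = constant_matrix(10, 3.0)
        out = apply_kr(m, NormalizationVector("chrT", np.ones(10)))
        assert np.allclose(out.values, m.values)

    def test_score_product_division(self):
        v = np.full((4, 4), 8.0)
        m = ContactMatrix("chrT", 25_000, v)
        kr = NormalizationVector("chrT", np.array([2.0, 2.0, 1.0, 1.0]))
        out = apply_kr(m, kr)
        assert out.values[0, 1] == pytest.approx(8 / 4)
        assert out.values[0, 2] == pytest.approx(8 / 2)
        assert out.values[2, 3] == pytest.approx(8.0)

    def test_missing_score_masks_row_and_column(self):
        m = constant_matrix(5)
        scores = np.ones(5)
        scores[2] = np.nan
        out = apply_kr(m, NormalizationVector("chrT", scores))
        assert out.mask[2]
        assert np.isnan(out.values[2, :]).all()
        assert np.isnan(out.values[:, 2]).all()
        assert not out.mask[[0, 1, 3, 4]].any()

    def test_nonpositive_score_masks_with_warning(self):
        m = constant_matrix(4)
        scores = np.array([1.0, -1.0, 1.0, 1.0])
        with pytest.warns(UserWarning):
            out = apply_kr(m, NormalizationVector("chrT", scores))
        assert out.mask[1]

    def test_dimension_mismatch_is_fatal(self):
        with pytest.raises(ValueError):
            apply_kr(constant_matrix(4), NormalizationVector("chrT", np.ones(5)))


def ice_oracle(v: np.ndarray, n_iter: int = 500) -> np.ndarray:
    """Independent plain alternating row/column balancing."""
    v = v.copy().astype(float)
    for _ in range(n_iter):
        s = v.sum(axis=1)
        adj = s / s.mean()
        v = v / np.outer(adj, adj)
    return v


class TestICE:
    def test_constant_matrix_unchanged_up_to_scale(self):
        m = constant_matrix(6, 4.0)
        out, bias = ice_normalize(m)
        ratio = out.values[0, 0] / m.values[0, 0]
        assert np.allclose(out.values, m.values * ratio)
        assert np.allclose(bias.scores, bias.scores[0])

    def test_scaled_row_matches_hand_iterated_oracle(self):
        rng = np.random.default_rng(0)
        v = rng.uniform(1, 5, (3, 3))
        v = (v + v.T) / 2
        v[0, :] *= 2
        v[:, 0] *= 2  # keep symmetric: bin 0 has doubled coverage
        out, bias = ice_normalize(ContactMatrix("chrT", 25_000, v), tol=1e-10)
        oracle = ice_oracle(v)
        # same solution up to global scale
        ratio = out.values[0, 1] / oracle[0, 1]
        assert np.allclose(out.values, oracle * ratio, rtol=1e-6)
        s = np.nansum(out.values, axis=1)
        assert s.std() / s.mean() < 1e-8
        # reconstruction identity out = raw / (b_i b_j)
        rec = v / np.outer(bias.scores, bias.scores)
        assert np.allclose(rec, out.values, rtol=1e-6)

    def test_zero_row_is_auto_masked_and_rest_balanced(self):
        v = np.ones((4, 4))
        v[1, :] = 0
        v[:, 1] = 0
        out, bias = ice_normalize(ContactMatrix("chrT", 25_000, v))
        assert out.mask[1]
        assert np.isnan(bias.scores[1])
        live = np.nansum(out.values[[0, 2, 3]][:, [0, 2, 3]], axis=1)
        assert live.std() / live.mean() < 1e-4

    def test_all_zero_matrix_is_an_error(self):
        with pytest.raises(ValueError):
            ice_normalize(ContactMatrix("chrT", 25_000, np.zeros((4, 4))))


class TestTadSignal:
    def test_constant_matrix_gives_zero_signal(self):
        m = constant_matrix(60, 2.0)
        sig = tad_signal(m, window=10 * 25_000)
        inner = sig[20:40]  # bins whose whole local window is edge-free
        assert np.allclose(inner, 0.0, atol=1e-12)

    def test_doubled_bin_matches_bruteforce_sum_oracle(self):
        n, w = 40, 5
        v = np.ones((n, n))
        v[20, :] *= 2
        v[:, 20] *= 2
        m = ContactMatrix("chrT", 1, v.copy(), np.zeros(n, bool))
        sig = tad_signal(m, window=w)

        def oracle(i):
            s = {}
            for k in range(n):
                tot = sum(v[k, j] for j in range(max(0, k - w), min(n, k + w + 1))
                          if j != k)
                s[k] = tot
            local = [s[k] for k in range(max(0, i - w), min(n, i + w + 1))]
            return np.log2(s[i] / np.mean(local))

        for i in (20, 18, 25, 0):
            assert sig[i] == pytest.approx(oracle(i), rel=1e-12)
        assert sig[20] > 0

    def test_first_bin_uses_right_truncated_window(self):
        m = constant_matrix(30, 1.0)
        sig = tad_signal(m, window=4 * 25_000)
        assert np.isfinite(sig[0])

    def test_scale_invariance(self, tad_map):
        s1 = tad_signal(tad_map, 2_000_000)
        scaled = ContactMatrix(tad_map.chrom, tad_map.bin_size,
                               np.nan_to_num(tad_map.values) * 7.5)
        s2 = tad_signal(scaled, 2_000_000)
        ok = np.isfinite(s1) & np.isfinite(s2)
        assert np.allclose(s1[ok], s2[ok], atol=1e-10)


class TestInsulation:
    def test_constant_matrix_flat_profile(self):
        cfg = PipelineConfig(bin_size=1, insulation_square=8, delta_span=3,
                             tad_signal_window=16, boundary_width=3,
                             short_range_cutoff=16, fusion_window=16)
        m = ContactMatrix("chrT", 1, np.full((40, 40), 3.0))
        prof = insulation_profile(m, cfg)
        inner = prof.score[8:32]
        assert np.allclose(inner, 0.0, atol=1e-12)
        d = prof.delta[np.isfinite(prof.delta)]
        assert np.allclose(d, 0.0, atol=1e-12)

    def test_two_block_matrix_minimum_at_junction(self):
        # exhaustive evaluation on a 60-bin toy: blocks [0,30) and [30,60)
        n, j = 60, 30
        v = np.full((n, n), 1.0)
        v[:j, :j] = 5.0
        v[j:, j:] = 5.0
        cfg = PipelineConfig(bin_size=1, insulation_square=10, delta_span=4,
                             tad_signal_window=20, boundary_width=3,
                             short_range_cutoff=20, fusion_window=20)
        prof = insulation_profile(ContactMatrix("chrT", 1, v), cfg)
        valid = np.where(np.isfinite(prof.score))[0]
        assert valid.min() == 10 and valid.max() == n - 11
        # squares at 29 and 30 are purely cross-block; either is the minimum
        assert np.nanargmin(prof.score) in (j - 1, j)

    def test_square_size_is_40_bins_at_25kb(self, cfg):
        assert cfg.square_bins == 40
        assert cfg.delta_bins == 8

    def test_short_chromosome_yields_empty_profile(self, cfg):
        with pytest.warns(UserWarning):
            prof = insulation_profile(constant_matrix(50), cfg)
        assert np.isnan(prof.score).all()

    def test_scale_invariance_of_normalized_score(self, tad_map, cfg):
        p1 = insulation_profile(tad_map, cfg)
        scaled = ContactMatrix(tad_map.chrom, tad_map.bin_size,
                               np.nan_to_num(tad_map.values) * 3.0)
        p2 = insulation_profile(scaled, cfg)
        ok = np.isfinite(p1.score)
        assert np.allclose(p1.score[ok], p2.score[ok], atol=1e-10)


def make_profile(delta, score=None):
    n = len(delta)
    score = np.zeros(n) if score is None else np.asarray(score, float)
    return InsulationProfile("chr1", 25_000, score, np.asarray(delta, float),
                             np.full(n, np.nan))


class TestCallBoundaries:
    def test_flat_profile_yields_no_boundaries(self, cfg):
        prof = make_profile(np.zeros(100))
        assert len(call_boundaries(prof, cfg)) == 0

    def test_planted_four_tads_give_three_boundaries(self, spec_1chrom, cfg):
        from tadsv.synthetic import plant_boundaries, simulate_hic
        spec = spec_1chrom
        truth = plant_boundaries(spec, spacing=5_000_000, margin=5_000_000)
        assert len(truth) == 3
        m = simulate_hic(spec, truth, tau=1.0, depth=60, seed=21)["chr1"]
        called = call_boundaries(insulation_profile(m, cfg), cfg)
        assert len(called) == 3
        truth_bins = sorted(b.center_bin(25_000) for b in truth)
        called_bins = sorted(b.center_bin(25_000) for b in called)
        assert all(abs(c - t) <= 1 for c, t in zip(called_bins, truth_bins))

    def test_adjacent_candidates_merge_keeping_stronger(self, cfg):
        # two upward crossings placing candidates one bin apart; the second
        # swing (0.9 - (-0.3) = 1.2) beats the first (0.2 - (-0.5) = 0.7)
        delta = np.array([-0.5, 0.2, -0.3, 0.9, 0.1, -0.1, -0.1, -0.1])
        score = np.array([0.2, 0.0, 0.0, 0.1, 0.2, 0.2, 0.2, 0.2])
        called = call_boundaries(make_profile(delta, score), cfg)
        assert len(called) == 1
        assert called[0].center_bin(25_000) == 2  # the stronger candidate

    def test_symmetry_under_transpose(self, tad_map, cfg):
        t = ContactMatrix(tad_map.chrom, tad_map.bin_size,
                          np.nan_to_num(tad_map.values).T.copy())
        b1 = call_boundaries(insulation_profile(tad_map, cfg), cfg)
        b2 = call_boundaries(insulation_profile(t, cfg), cfg)
        assert [b.start for b in b1] == [b.start for b in b2]

    def test_boundary_interval_is_three_bins(self, tad_map, cfg):
        for b in call_boundaries(insulation_profile(tad_map, cfg), cfg):
            assert b.end - b.start == cfg.boundary_width
            assert b.start % cfg.bin_size == 0
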