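import numpy as np
import pytest

from countdiff import (
    DegenerateLaneError,
    InsufficientGenesError,
    normalize_quantile,
    normalize_tmm,
    normalize_tpm,
    round_counts,
    tmm_scale_factor,
)

from conftest import make_matrix

RNG = np.random.default_rng(7)
# a fixed positive lane profile used as TMM reference material
REF_LANE = RNG.integers(1, 500, size=60).astype(float)


class TestTPM:
    def test_lane_scaled_to_million(self):
        cm = make_matrix([[2, 2], [3, 3]])
        out = normalize_tpm(cm).normalized.counts.to_numpy()
        np.testing.assert_allclose(out[:, 0], [400000.0, 600000.0])
        np.testing.assert_allclose(out.sum(axis=0), [1e6, 1e6], rtol=1e-6)

    def test_million_total_lane_unchanged(self):
        cm = make_matrix([[400000, 1], [600000, 1]])
        out = normalize_tpm(cm).normalized.counts.to_numpy()
        np.testing.assert_allclose(out[:, 0], [400000.0, 600000.0])

    def test_zero_lane_rejected(self):
        cm = make_matrix([[1, 0], [2, 0]])
        with pytest.raises(DegenerateLaneError):
            normalize_tpm(cm)

    def test_every_lane_sums_to_million(self):
        cm = make_matrix(RNG.integers(0, 1000, size=(50, 4)))
        out = normalize_tpm(cm).normalized.counts.to_numpy()
        np.testing.assert_allclose(out.sum(axis=0), 1e6, rtol=1e-6)


class TestTMMFactor:
    def test_identical_lanes_give_unit_factor(self):
        assert tmm_scale_factor(REF_LANE, REF_LANE) == 1.0

    def test_doubled_lane_gives_factor_two(self):
        # every per-gene log2 ratio is exactly 1, so any trimmed mean is 1
        assert tmm_scale_factor(2 * REF_LANE, REF_LANE) == pytest.approx(2.0)

    def test_gene_order_irrelevant(self):
        test = REF_LANE * np.linspace(0.5, 2.0, REF_LANE.size)
        f1 = tmm_scale_factor(test, REF_LANE)
        perm = RNG.permutation(REF_LANE.size)
        f2 = tmm_scale_factor(test[perm], REF_LANE[perm])
        assert f1 == pytest.approx(f2)

    def test_zero_genes_excluded_not_fatal(self):
        test = REF_LANE.copy()
        test[:5] = 0.0
        assert tmm_scale_factor(test, REF_LANE) > 0

    def test_too_few_surviving_genes_rejected(self):
        with pytest.raises(InsufficientGenesError):
            tmm_scale_factor(np.array([0.0, 5.0]), np.array([3.0, 0.0]))


class TestNormalizeTMM:
    def test_identical_lanes_equal_tpm(self):
        values = np.column_stack([REF_LANE, REF_LANE, REF_LANE, REF_LANE])
        cm = make_matrix(values)
        tmm_out = normalize_tmm(cm)
        tpm_out = normalize_tpm(cm).normalized.counts.to_numpy()
        assert all(f == pytest.approx(1.0) for f in tmm_out.scale_factor_of_lane.values())
        np.testing.assert_allclose(tmm_out.normalized.counts.to_numpy(), tpm_out)

    def test_pure_depth_difference_removed(self):
        cm = make_matrix(np.column_stack([REF_LANE, 3 * REF_LANE]))
        out = normalize_tmm(cm).normalized.counts.to_numpy()
        np.testing.assert_allclose(out[:, 0], out[:, 1], rtol=1e-12)

    def test_factors_geometric_mean_one(self):
        values = RNG.integers(1, 2000, size=(80, 5)).astype(float)
        factors = np.array(list(normalize_tmm(make_matrix(values)).scale_factor_of_lane.values()))
        assert np.exp(np.mean(np.log(factors))) == pytest.approx(1.0, rel=1e-12)

    def test_invariant_to_scaling_a_lane(self):
        # the factor absorbs a constant multiple of a lane; invariance is
        # approximate because the precision weights depend on lane depth
        lam = np.exp(RNG.uniform(np.log(50), np.log(5000), 400))
        values = RNG.poisson(lam[:, None], size=(400, 4)).astype(float)
        base = normalize_tmm(make_matrix(values)).normalized.counts.to_numpy()
        scaled = values.copy()
        scaled[:, 3] *= 2.0
        out = normalize_tmm(make_matrix(scaled)).normalized.counts.to_numpy()
        np.testing.assert_allclose(out, base, rtol=0.02)


class TestQuantile:
    def test_identical_lanes_unchanged(self):
        cm = make_matrix(np.column_stack([REF_LANE, REF_LANE]))
        out = normalize_quantile(cm).normalized.counts.to_numpy()
        np.testing.assert_allclose(out[:, 0], REF_LANE)
        np.testing.assert_allclose(out[:, 1], REF_LANE)

    def test_two_lane_hand_example(self):
        cm = make_matrix([[1, 10], [2, 20], [3, 30]])
        out = normalize_quantile(cm).normalized.counts.to_numpy()
        np.testing.assert_allclose(out[:, 0], [5.5, 11.0, 16.5])
        np.testing.assert_allclose(out[:, 1], [5.5, 11.0, 16.5])

    def test_ties_get_mean_of_tied_rank_references(self):
        # sorted references: rank-wise medians of [1,3],[1,6],[2,9] = 2, 3.5, 5.5;
        # the two tied 1s in lane 1 share mean(2, 3.5) = 2.75
        cm = make_matrix([[1, 3], [1, 6], [2, 9]])
        out = normalize_quantile(cm).normalized.counts.to_numpy()
        np.testing.assert_allclose(out[:, 0], [2.75, 2.75, 5.5])
        np.testing.assert_allclose(out[:, 1], [2.0, 3.5, 5.5])

    def test_lanes_share_multiset_and_monotone(self):
        # tie-free lanes (distinct values): every lane ends up with the
        # identical reference multiset and the within-lane order is kept
        values = np.column_stack(
            [RNG.choice(100000, size=40, replace=False) for _ in range(3)]
        ).astype(float)
        cm = make_matrix(values)
        out = normalize_quantile(cm).normalized.counts.to_numpy()
        ref = np.sort(out[:, 0])
        for j in range(out.shape[1]):
            np.testing.assert_allclose(np.sort(out[:, j]), ref)
            order = np.argsort(values[:, j], kind="stable")
            assert np.all(np.diff(out[order, j]) >= -1e-12)


class TestRoundCounts:
    def test_half_away_from_zero(self):
        cm = make_matrix([[5.5, 5.4], [0.0, 2.5]])
        out = round_counts(cm).counts.to_numpy()
        np.testing.assert_array_equal(out, [[6.0, 5.0], [0.0, 3.0]])

    def test_integer_matrix_unchanged_and_flagged(self):
        cm = make_matrix([[1, 2], [3, 4]])
        out = round_counts(cm)
        np.testing.assert_array_equal(out.counts.to_numpy(), cm.counts.to_numpy())
        assert out.is_integer

    def test_rounding_bound(self):
        values = RNG.uniform(0, 100, size=(30, 3))
        out = round_counts(make_matrix(values)).counts.to_numpy()
        diff = out - values
        assert np.all((diff > -0.5) & (diff <= 0.5))

    def test_accepts_normalization_result(self):
        norm = normalize_tpm(make_matrix([[2, 3], [3, 2]]))
        out = round_counts(norm)
        assert out.is_integer
        np.testing.assert_array_equal(
            out.counts.to_numpy(), [[400000.0, 600000.0], [600000.0, 400000.0]]
        )
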