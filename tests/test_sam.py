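"""SAM relative-difference statistic, permutation null and Delta calls."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pkaglucose as pk
from pkaglucose.sam import (
    DegenerateScatterError,
    InsufficientReplicatesError,
    S0Method,
    SamConfig,
)

from conftest import make_matrix
from sam_oracle import (
    oracle_calls,
    oracle_d,
    oracle_null,
    oracle_s0_cv_search,
    oracle_scatter,
)


class TestPooledScatter:
    def test_hand_computed_tusher_form(self):
        assert pk.pooled_scatter([1, 3], [5, 7]) == pytest.approx(math.sqrt(2))

    def test_constant_groups_give_zero(self):
        assert pk.pooled_scatter([4, 4], [9, 9]) == 0.0

    @given(
        a=st.floats(-100, 100), b=st.floats(-100, 100), c=st.floats(0.1, 50)
    )
    @settings(max_examples=50, deadline=None)
    def test_shift_invariance(self, a, b, c):
        s1 = pk.pooled_scatter([a, a + c], [b, b + c])
        s2 = pk.pooled_scatter([0, c], [10, 10 + c])
        assert s1 == pytest.approx(s2, rel=1e-9)

    def test_single_replicate_rejected(self):
        with pytest.raises(InsufficientReplicatesError):
            pk.pooled_scatter([1], [2, 3])


class TestRelativeDifference:
    def test_equal_means_give_zero(self):
        assert pk.relative_difference([2, 4], [1, 5], s0=0.5) == 0.0

    def test_hand_computed_value(self):
        assert pk.relative_difference([1, 3], [5, 7], s0=0) == pytest.approx(
            4 / math.sqrt(2)
        )

    def test_huge_s0_shrinks_d_to_zero(self):
        assert abs(pk.relative_difference([1, 3], [50, 70], s0=1e9)) < 1e-6

    def test_degenerate_scatter_with_unequal_means(self):
        with pytest.raises(DegenerateScatterError):
            pk.relative_difference([4, 4], [9, 9], s0=0)

    def test_zero_scatter_equal_means_is_zero(self):
        assert pk.relative_difference([4, 4], [4, 4], s0=0) == 0.0


class TestEstimateS0:
    def test_degenerate_distribution_any_method(self):
        for method in S0Method:
            config = SamConfig(s0_method=method)
            assert pk.estimate_s0([2.0] * 10, [1.0] * 10, config) == 2.0

    def test_median_method(self):
        config = SamConfig(s0_method=S0Method.MEDIAN)
        assert pk.estimate_s0([1.0, 2.0, 9.0], config=config) == 2.0

    def test_cv_search_matches_brute_force_on_fixture(self):
        rng = np.random.default_rng(42)
        scatters = rng.lognormal(0, 1, size=50)
        diffs = rng.normal(0, 2, size=50) * (scatters + 0.3)
        config = SamConfig()
        got = pk.estimate_s0(scatters, diffs, config)
        want = oracle_s0_cv_search(scatters, diffs, config.s0_percentile_grid)
        assert got == pytest.approx(want, rel=1e-12)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            pk.estimate_s0([], [], SamConfig())


class TestPermutationNull:
    def test_two_vs_two_enumerates_six_relabelings(self):
        rng = np.random.default_rng(0)
        block = rng.normal(10, 2, size=(5, 4))
        expected, null_d = pk.permutation_null(block[:, :2], block[:, 2:], s0=1.0)
        assert null_d.shape == (6, 5)  # C(4,2) = 6, identity included

    def test_constant_genes_have_null_d_zero(self):
        block = np.full((4, 4), 7.0)
        expected, null_d = pk.permutation_null(block[:, :2], block[:, 2:], s0=1.0)
        np.testing.assert_array_equal(null_d, 0.0)
        np.testing.assert_array_equal(expected, 0.0)

    def test_sampled_mode_is_seed_deterministic(self):
        rng = np.random.default_rng(1)
        block = rng.normal(10, 2, size=(8, 10))
        config = SamConfig(max_enumerated_permutations=40, seed=11)
        out1 = pk.permutation_null(block[:, :5], block[:, 5:], 0.5, config)
        out2 = pk.permutation_null(block[:, :5], block[:, 5:], 0.5, config)
        np.testing.assert_array_equal(out1[1], out2[1])
        assert out1[1].shape == (40, 8)


class TestCallSignificant:
    def _small_case(self):
        rng = np.random.default_rng(5)
        data = rng.normal(100, 5, size=(20, 4))
        data[:3, 2:] += 60  # three planted large effects
        s0 = 1.0
        d = np.array([oracle_d(list(r[:2]), list(r[2:]), s0) for r in data])
        expected, null_d = pk.permutation_null(data[:, :2], data[:, 2:], s0)
        return d, expected, null_d, data, s0

    def test_oversized_delta_calls_nothing(self):
        d, expected, null_d, *_ = self._small_case()
        huge = np.max(np.abs(np.sort(d) - expected)) + 1
        called, fdr, *_ = pk.call_significant(d, expected, null_d, huge)
        assert called.sum() == 0
        assert fdr == 0.0

    def test_delta_zero_on_self_null_calls_everything_fdr_one(self):
        d = np.array([-2.0, -0.5, 0.0, 0.7, 3.0])
        expected = np.sort(d)
        null_d = d.reshape(1, -1)
        called, fdr, *_ = pk.call_significant(d, expected, null_d, 0.0)
        assert called.sum() == np.count_nonzero(d)
        assert fdr == pytest.approx(1.0)

    def test_planted_effects_match_brute_force(self):
        d, expected, null_d, data, s0 = self._small_case()
        for delta in (0.5, 1.0, 2.0, 4.0):
            called, fdr, cl, cu = pk.call_significant(d, expected, null_d, delta)
            rows = [list(r) for r in data]
            o_exp, o_null = oracle_null(rows, 2, s0)
            o_called, o_fdr, o_cl, o_cu = oracle_calls(list(d), o_exp, o_null, delta)
            assert list(called) == o_called
            assert fdr == pytest.approx(o_fdr)
            assert (cl, cu) == pytest.approx((o_cl, o_cu))

    def test_called_set_non_increasing_in_delta(self):
        d, expected, null_d, *_ = self._small_case()
        sizes = [
            pk.call_significant(d, expected, null_d, delta)[0].sum()
            for delta in np.linspace(0, 5, 30)
        ]
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))


class TestEndToEnd:
    def test_full_pipeline_matches_oracle_on_small_matrices(self):
        """d, s, the 6-permutation null and Delta calls agree exactly with
        exhaustive enumeration on <= 8-sample fixtures."""
        rng = np.random.default_rng(7)
        for n1, n2 in ((2, 2), (2, 3), (3, 3), (4, 4)):
            data = rng.lognormal(4, 0.6, size=(15, n1 + n2))
            matrix = make_matrix(data, scaled=True)
            config = SamConfig(delta=1.0, s0_method=S0Method.MEDIAN)
            result = pk.sam_two_group(
                matrix, matrix.sample_ids[:n1], matrix.sample_ids[n1:], config
            )
            rows = [list(r) for r in data]
            s0 = float(np.median([oracle_scatter(r[:n1], r[n1:]) for r in rows]))
            assert result.s0 == pytest.approx(s0, rel=1e-12)
            for gene_i, row in enumerate(rows):
                assert result.s.iloc[gene_i] == pytest.approx(
                    oracle_scatter(row[:n1], row[n1:]), rel=1e-12
                )
                assert result.d.iloc[gene_i] == pytest.approx(
                    oracle_d(row[:n1], row[n1:], s0), rel=1e-12
                )
            o_exp, o_null = oracle_null(rows, n1, s0)
            np.testing.assert_allclose(result.null_expected, o_exp, rtol=1e-12, atol=1e-12)
            o_called, o_fdr, *_ = oracle_calls(list(result.d), o_exp, o_null, 1.0)
            assert list(result.called) == o_called
            assert result.estimated_fdr == pytest.approx(o_fdr)

    def test_abs_d_non_increasing_in_s0(self):
        rng = np.random.default_rng(3)
        data = rng.normal(50, 5, size=(10, 4))
        matrix = make_matrix(data, scaled=True)
        previous = None
        for s0 in (0.0, 0.5, 2.0, 10.0):
            config = SamConfig(s0_method=S0Method.MEDIAN, delta=1.0)
            block1 = data[:, :2]
            block2 = data[:, 2:]
            d = np.array(
                [pk.relative_difference(b1, b2, s0) for b1, b2 in zip(block1, block2)]
            )
            if previous is not None:
                assert np.all(np.abs(d) <= np.abs(previous) + 1e-12)
            previous = d

    def test_insufficient_replicates_rejected(self):
        matrix = make_matrix([[1.0, 2.0, 3.0]], scaled=True)
        with pytest.raises(InsufficientReplicatesError):
            pk.sam_two_group(matrix, ["s1"], ["s2", "s3"])
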