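"""The bootstrapped log-LR pipeline: rescaling, regularization, monotonization,
and median-with-confidence-bounds summaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from acmgcalib.calibration_core import (
    CalibrationConfig,
    LogLRMatrix,
    TruthsetScores,
    adaptive_lambda,
    clamp_and_rescale,
    compute_loglr_matrix,
    direction_of_monotonicity,
    mad_profile,
    map_to_scores,
    monotonize,
    shrink_loglr,
    sign_test_ci_ranks,
    summarize_curve,
)
from helpers import brute_force_monotone_fit, scan_sign_test_ranks


def make_matrix(values):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    return LogLRMatrix(values=values, common_grid=np.linspace(0, 1, values.shape[1]))


class TestClampAndRescale:
    @pytest.mark.parametrize("score, expected", [(12.0, 1.0), (6.0, 0.5), (2.0, 0.0), (-3.0, 0.0)])
    def test_clamp_then_affine(self, score, expected):
        assert clamp_and_rescale([score], 2.0, 10.0)[0] == pytest.approx(expected)

    def test_nan_passes_through(self):
        out = clamp_and_rescale([np.nan, 6.0], 2.0, 10.0)
        assert np.isnan(out[0]) and out[1] == 0.5

    def test_degenerate_range_rejected(self):
        with pytest.raises(ValueError):
            clamp_and_rescale([1.0], 5.0, 5.0)


class TestMadProfile:
    def test_constant_column_is_zero(self):
        m = make_matrix([[1.0, 0.0], [1.0, 2.0], [1.0, 4.0]])
        assert mad_profile(m)[0] == 0.0

    def test_unit_scale_example(self):
        m = make_matrix([[1.0, 1.0], [2.0, 2.0], [3.0, 3.0]])
        assert mad_profile(m, scale=1.0)[0] == pytest.approx(1.0)

    def test_single_row_all_zero(self):
        assert np.array_equal(mad_profile(make_matrix([[3.0, -1.0, 2.0]])), [0, 0, 0])


class TestAdaptiveLambda:
    def test_flat_profile_gives_zero(self):
        assert np.array_equal(adaptive_lambda([2.0, 2.0, 2.0]), [0, 0, 0])

    def test_hand_computed_example(self):
        lam = adaptive_lambda([1.0, 2.0, 1.0])
        assert lam == pytest.approx([0.176777, 0.353553, 0.176777], abs=1e-6)

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(
        c=st.floats(1e-6, 1e6),
        mads=st.lists(st.floats(0.0, 10.0), min_size=2, max_size=20).filter(
            lambda v: max(v) > 0
        ),
    )
    def test_invariant_to_uniform_rescaling(self, c, mads):
        mads = np.asarray(mads)
        assert np.allclose(adaptive_lambda(c * mads), adaptive_lambda(mads), rtol=1e-9, atol=1e-12)

    def test_all_zero_profile(self):
        assert np.array_equal(adaptive_lambda([0.0, 0.0]), [0.0, 0.0])


class TestShrink:
    def test_zero_lambda_is_identity(self):
        m = make_matrix([[1.0, -2.0, 3.0]])
        out = shrink_loglr(m, np.zeros(3))
        assert np.array_equal(out.values, m.values)

    def test_unit_lambda_halves(self):
        out = shrink_loglr(make_matrix([[2.0]]), np.array([1.0]))
        assert out.values[0, 0] == pytest.approx(1.0)

    def test_contraction_toward_zero(self, rng):
        m = make_matrix(rng.normal(size=(5, 8)))
        lam = rng.uniform(0, 2, size=8)
        out = shrink_loglr(m, lam)
        assert np.all(np.abs(out.values) <= np.abs(m.values) + 1e-15)
        assert np.all(np.sign(out.values) == np.sign(m.values))

    def test_negative_lambda_rejected(self):
        with pytest.raises(ValueError):
            shrink_loglr(make_matrix([[1.0, 2.0]]), np.array([0.5, -0.1]))


class TestDirection:
    def test_increasing_means(self):
        assert direction_of_monotonicity(make_matrix([[-1.0, 0.0, 1.0]])) == 1

    def test_decreasing_means(self):
        assert direction_of_monotonicity(make_matrix([[1.0, 0.0, -1.0]])) == -1

    def test_constant_means_rejected(self):
        with pytest.raises(ValueError, match="inspect the input data"):
            direction_of_monotonicity(make_matrix([[1.0, 1.0, 1.0], [1.0, 1.0, 1.0]]))


class TestMonotonize:
    def test_pools_adjacent_violators(self):
        out = monotonize(make_matrix([[0.0, 1.0, 0.5]]), 1)
        assert out.values[0] == pytest.approx([0.0, 0.75, 0.75])

    def test_monotone_row_unchanged(self):
        m = make_matrix([[0.0, 0.5, 2.0]])
        assert np.allclose(monotonize(m, 1).values, m.values)

    @pytest.mark.parametrize("direction", [1, -1])
    def test_matches_brute_force_on_short_rows(self, direction, rng):
        for _ in range(25):
            row = rng.normal(size=rng.integers(2, 7))
            got = monotonize(make_matrix([row]), direction).values[0]
            expected = brute_force_monotone_fit(row, direction)
            assert np.allclose(got, expected, atol=1e-9)

    def test_invalid_direction_rejected(self):
        with pytest.raises(ValueError):
            monotonize(make_matrix([[0.0, 1.0]]), 0)


class TestSignTestRanks:
    def test_ten_samples_95(self):
        assert sign_test_ci_ranks(10, 0.95) == (2, 9)

    @pytest.mark.parametrize("n", [6, 17, 120, 1000])
    def test_matches_exhaustive_scan(self, n):
        assert sign_test_ci_ranks(n, 0.95) == scan_sign_test_ranks(n, 0.95)

    @pytest.mark.parametrize("n", [10, 101, 1000])
    def test_guaranteed_coverage(self, n):
        from scipy.stats import binom

        lo, hi = sign_test_ci_ranks(n, 0.95)
        coverage = 1.0 - 2.0 * binom.cdf(lo - 1, n, 0.5)
        assert coverage >= 0.95
        assert hi == n + 1 - lo

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            sign_test_ci_ranks(5, 0.95)


class TestSummarize:
    def test_identical_monotone_rows(self):
        row = np.array([-1.0, 0.0, 2.0])
        m = make_matrix(np.tile(row, (50, 1)))
        curve = summarize_curve(m, CalibrationConfig(n_resamples=50, grid_size=3), 1)
        for v in (curve.median_loglr, curve.lower_loglr, curve.upper_loglr):
            assert np.allclose(v, row)

    def test_order_statistic_bounds(self):
        # column r holds value r+1 scaled by column index: rows 1..1000
        base = np.arange(1.0, 1001.0)[:, None]
        m = make_matrix(base * np.array([1.0, 2.0]))
        cfg = CalibrationConfig(n_resamples=1000, grid_size=2)
        curve = summarize_curve(m, cfg, 1)
        lo, hi = sign_test_ci_ranks(1000, 0.95)
        assert curve.median_loglr[0] == pytest.approx(500.5)
        assert curve.lower_loglr[0] == float(lo)
        assert curve.upper_loglr[0] == float(hi)

    def test_bounds_bracket_median(self, rng):
        rows = np.sort(rng.normal(size=(40, 6)), axis=1)
        curve = summarize_curve(
            make_matrix(rows), CalibrationConfig(n_resamples=40, grid_size=6), 1
        )
        assert np.all(curve.lower_loglr <= curve.median_loglr)
        assert np.all(curve.median_loglr <= curve.upper_loglr)

    def test_non_monotone_rows_rejected(self):
        m = make_matrix(np.tile([1.0, 0.0, 2.0], (30, 1)))
        with pytest.raises(AssertionError):
            summarize_curve(m, CalibrationConfig(n_resamples=30, grid_size=3), 1)


class TestMapToScores:
    def _curve(self):
        m = make_matrix(np.tile(np.linspace(-2, 2, 5), (20, 1)))
        return summarize_curve(m, CalibrationConfig(n_resamples=20, grid_size=5), 1)

    def test_exact_node(self):
        curve = self._curve()
        triple = map_to_scores(curve, [0.25])[0]
        assert triple[1] == pytest.approx(np.exp(curve.median_loglr[1]))

    def test_equal_scores_identical_triples(self):
        out = map_to_scores(self._curve(), [0.4, 0.4])
        assert np.array_equal(out[0], out[1])

    def test_monotone_in_score(self):
        out = map_to_scores(self._curve(), np.linspace(0, 1, 11))
        assert np.all(np.diff(out[:, 1]) >= 0)

    def test_tie_resolves_to_lower_index(self):
        curve = self._curve()  # 5 grid nodes; 0.125 is exactly between nodes 0 and 1
        triple = map_to_scores(curve, [0.125])[0]
        assert triple[1] == pytest.approx(np.exp(curve.median_loglr[0]))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            map_to_scores(self._curve(), [1.2])

    def test_nan_gives_nan_triple(self):
        out = map_to_scores(self._curve(), [np.nan])
        assert np.all(np.isnan(out))


@pytest.fixture(scope="module")
def small_truthset():
    rng = np.random.default_rng(7)
    scores = np.concatenate([rng.normal(0.7, 0.1, 12), rng.normal(0.3, 0.1, 12)])
    labels = ["P"] * 12 + ["B"] * 12
    return TruthsetScores(scores=scores, labels=np.array(labels, dtype=object))


@pytest.fixture(scope="module")
def small_config():
    return CalibrationConfig(n_resamples=100, grid_size=256, seed=5)


class TestLogLRMatrix:
    def test_shape_and_finiteness(self, small_truthset, small_config):
        m = compute_loglr_matrix(small_truthset, small_config)
        assert m.values.shape == (100, 256)
        assert np.all(np.isfinite(m.values))

    def test_fixed_seed_bit_identical(self, small_truthset, small_config):
        m1 = compute_loglr_matrix(small_truthset, small_config)
        m2 = compute_loglr_matrix(small_truthset, small_config)
        assert np.array_equal(m1.values, m2.values)

    def test_identical_classes_cancel(self):
        rng = np.random.default_rng(3)
        base = rng.normal(0.5, 0.12, 30)
        ts = TruthsetScores(
            scores=np.concatenate([base, base]),
            labels=np.array(["P"] * 30 + ["B"] * 30, dtype=object),
        )
        m = compute_loglr_matrix(ts, CalibrationConfig(n_resamples=150, grid_size=256, seed=9))
        median = np.median(m.values, axis=0)
        interior = slice(64, 192)  # central half of the grid
        assert np.all(np.abs(median[interior]) <= 0.1)

    def test_undersized_truthset_rejected(self):
        ts = TruthsetScores(
            scores=np.arange(15.0), labels=np.array(["P"] * 9 + ["B"] * 6, dtype=object)
        )
        with pytest.raises(ValueError, match="pathogenic labels: 9 < 10"):
            compute_loglr_matrix(ts, CalibrationConfig(n_resamples=10, grid_size=64))
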