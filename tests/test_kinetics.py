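"""Interval summaries, cubic fitting, landmark extraction, block duration."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, strategies as st
from numpy.polynomial import Polynomial

from nerveblock.assay import MPEValue
from nerveblock.design import DesignSpec
from nerveblock.kinetics import (
    CubicFit,
    IntervalSummary,
    NoBlockError,
    block_duration,
    extract_landmarks,
    fit_cubic,
    summarize_intervals,
)

SPEC = DesignSpec(n_mice_per_group=6)


def _mpe(points):
    return [MPEValue(f"m{i}", t, v) for i, (t, v) in enumerate(points)]


def _summaries(mids, means, n=6):
    return [
        IntervalSummary(i, float(t), float(m), 0.0, n)
        for i, (t, m) in enumerate(zip(mids, means))
    ]


def cubic_ols_oracle(ts, ys):
    """Exact-rational normal-equation solve of the cubic least-squares problem."""
    ts = [Fraction(float(t)) for t in ts]
    ys = [Fraction(float(y)) for y in ys]
    X = [[t**k for k in range(4)] for t in ts]
    A = [[sum(row[i] * row[j] for row in X) for j in range(4)] for i in range(4)]
    b = [sum(row[i] * y for row, y in zip(X, ys)) for i in range(4)]
    M = [ai[:] + [bi] for ai, bi in zip(A, b)]
    for i in range(4):
        piv = next(r for r in range(i, 4) if M[r][i] != 0)
        M[i], M[piv] = M[piv], M[i]
        M[i] = [x / M[i][i] for x in M[i]]
        for r in range(4):
            if r != i and M[r][i] != 0:
                f = M[r][i]
                M[r] = [x - f * y for x, y in zip(M[r], M[i])]
    return np.array([float(M[i][4]) for i in range(4)])


class TestSummarizeIntervals:
    def test_constant_window(self):
        s = summarize_intervals(_mpe([(1.5, 50.0), (3.0, 50.0), (6.0, 50.0)]), SPEC)
        assert s[0].mean_mpe_pct == 50.0 and s[0].sd_mpe_pct == 0.0 and s[0].n == 3

    def test_sample_sd(self):
        s = summarize_intervals(_mpe([(0.0, 0.0), (4.5, 50.0), (9.0, 100.0)]), SPEC)
        assert s[0].mean_mpe_pct == pytest.approx(50.0)
        assert s[0].sd_mpe_pct == pytest.approx(50.0)  # sample SD of {0, 50, 100}

    def test_half_open_window_assignment(self):
        s = summarize_intervals(_mpe([(13.5, 80.0)]), SPEC)
        assert s[0].n == 0 and math.isnan(s[0].mean_mpe_pct)
        assert s[1].n == 1 and s[1].mean_mpe_pct == 80.0

    def test_midpoints_and_window_count(self):
        s = summarize_intervals(_mpe([(0.0, 10.0)]), SPEC)
        assert len(s) == 20
        assert [w.midpoint_min for w in s][:3] == [6.75, 20.25, 33.75]

    def test_out_of_horizon_rejected(self):
        with pytest.raises(ValueError, match="horizon"):
            summarize_intervals(_mpe([(270.0, 10.0)]), SPEC)


class TestFitCubic:
    def test_exact_cubic_recovered(self):
        poly = Polynomial([2.0, 1.0, -0.5, 0.01])
        mids = np.arange(20) * 13.5 + 6.75
        fit = fit_cubic(_summaries(mids, poly(mids)))
        assert fit.coefficients == pytest.approx(tuple(poly.coef), rel=1e-8)
        assert fit.r_squared == pytest.approx(1.0)

    def test_constant_response(self):
        mids = np.arange(20) * 13.5 + 6.75
        with pytest.warns(UserWarning, match="zero-variance"):
            fit = fit_cubic(_summaries(mids, np.full(20, 40.0)))
        assert fit.coefficients == pytest.approx((40.0, 0.0, 0.0, 0.0), abs=1e-9)
        assert fit.r_squared == 0.0

    def test_underdetermined(self):
        mids = [6.75, 20.25, 33.75]
        with pytest.raises(ValueError, match="underdetermined cubic"):
            fit_cubic(_summaries(mids, [1, 2, 3]))

    @given(
        n=st.integers(min_value=4, max_value=20),
        seed=st.integers(0, 2**16),
    )
    def test_matches_exact_normal_equation_oracle(self, n, seed):
        rng = np.random.default_rng(seed)
        mids = np.arange(n) * 13.5 + 6.75
        ys = rng.uniform(0, 100, n)
        fit = fit_cubic(_summaries(mids, ys))
        oracle = cubic_ols_oracle(mids, ys)
        scale = max(1.0, float(np.max(np.abs(oracle))))
        assert np.max(np.abs(np.array(fit.coefficients) - oracle)) / scale < 1e-8

    def test_r_squared_invariant_to_affine_time(self):
        rng = np.random.default_rng(5)
        mids = np.arange(12) * 13.5 + 6.75
        ys = rng.uniform(0, 100, 12)
        r2a = fit_cubic(_summaries(mids, ys)).r_squared
        r2b = fit_cubic(_summaries(3.0 * mids + 40.0, ys)).r_squared
        assert r2a == pytest.approx(r2b, rel=1e-9)

    def test_domain_restriction(self):
        poly = Polynomial([1.0, 0.5, 0.0, 0.0])
        mids = np.arange(20) * 13.5 + 6.75
        ys = poly(mids)
        ys[10:] = 0.0  # corrupt outside the segment
        fit = fit_cubic(_summaries(mids, ys), domain=(0.0, 130.0))
        assert fit(50.0) == pytest.approx(poly(50.0), abs=1e-8)


class TestExtractLandmarks:
    def test_interior_max_and_min(self):
        # f(t) = t^3 - 6 t^2 + 9 t, f' = 3 (t-1)(t-3)
        fit = CubicFit((0.0, 9.0, -6.0, 1.0), (0.0, 3.5), 1.0)
        marks = {m.kind: m for m in extract_landmarks(fit)}
        onset = marks["onset_peak"]
        assert (onset.t_min, onset.mpe_pct) == (pytest.approx(1.0), pytest.approx(4.0))
        release = marks["release_local_min"]
        assert (release.t_min, release.mpe_pct) == (pytest.approx(3.0), pytest.approx(0.0))

    def test_strictly_increasing_cubic_peaks_at_boundary(self):
        fit = CubicFit((0.0, 1.0, 0.0, 0.001), (0.0, 10.0), 1.0)
        marks = extract_landmarks(fit)
        assert len(marks) == 1
        assert marks[0].kind == "onset_peak"
        assert marks[0].t_min == 10.0 and marks[0].at_boundary

    def test_degenerate_linear_fit(self):
        fit = CubicFit((5.0, -1.0, 0.0, 0.0), (0.0, 4.0), 1.0)
        marks = extract_landmarks(fit)
        assert [m.kind for m in marks] == ["onset_peak"]
        assert marks[0].t_min == 0.0 and marks[0].at_boundary

    @given(
        coeffs=st.tuples(
            st.floats(-50, 50),
            st.floats(-5, 5),
            st.floats(-0.5, 0.5),
            st.floats(-0.01, 0.01),
        ),
        width=st.floats(min_value=5.0, max_value=270.0),
    )
    def test_agrees_with_dense_grid_scan(self, coeffs, width):
        fit = CubicFit(coeffs, (0.0, width), 1.0)
        grid = np.arange(0.0, width + 1e-9, 1e-3)
        values = Polynomial(coeffs)(grid)
        scale = max(1.0, float(np.max(np.abs(values))))
        onset = extract_landmarks(fit)[0]
        assert onset.mpe_pct >= float(values.max()) - 1e-6 * scale
        if float(values.max() - values.min()) > 1e-6 * scale:
            assert abs(onset.t_min - grid[int(np.argmax(values))]) <= 1e-3 + 1e-9


class TestBlockDurationFromFit:
    def test_downward_crossing_located_analytically(self):
        # decaying quadratic-free cubic: single crossing of 15 inside the domain
        poly = Polynomial([80.0, -0.65, 0.0, 0.0])
        t_cross = (80.0 - 15.0) / 0.65
        fit = CubicFit(tuple(np.r_[poly.coef, [0.0, 0.0]][:4]), (0.0, 270.0), 1.0)
        d = block_duration(fit)
        assert not d.censored_above_total
        assert d.duration_min == pytest.approx(t_cross, abs=1e-9)

    def test_curve_above_threshold_at_domain_end_is_censored(self):
        fit = CubicFit((60.0, 0.0, 0.0, 0.0), (0.0, 270.0), 1.0)
        d = block_duration(fit)
        assert d.censored_above_total and d.duration_min is None

    def test_no_block_when_peak_below_threshold(self):
        fit = CubicFit((5.0, 0.0, 0.0, 0.0), (0.0, 270.0), 1.0)
        with pytest.raises(NoBlockError):
            block_duration(fit)

    def test_reblock_pushes_duration_to_final_crossing(self):
        # f - 15 = -(t-2)(t-5)(t-8): dips below 15 at t=2, re-blocks at t=5,
        # final release at t=8
        fit = CubicFit((95.0, -66.0, 15.0, -1.0), (0.0, 10.0), 1.0)
        d = block_duration(fit)
        assert d.duration_min == pytest.approx(8.0, abs=1e-9)


class TestBlockDurationFromMeans:
    def test_interpolated_crossing(self):
        mids = np.arange(20) * 13.5 + 6.75
        means = np.maximum(0.0, 80.0 - 0.65 * mids)  # linear decay through 15%
        d = block_duration(_summaries(mids, means))
        assert d.method == "interval_means"
        # crossing recovered to within half a window (the estimator's contract)
        assert d.duration_min == pytest.approx(100.0, abs=6.75)

    def test_censored_when_final_windows_stay_above(self):
        mids = np.arange(20) * 13.5 + 6.75
        d = block_duration(_summaries(mids, np.full(20, 55.0)))
        assert d.censored_above_total

    def test_all_means_below_threshold(self):
        mids = np.arange(20) * 13.5 + 6.75
        with pytest.raises(NoBlockError, match="no block established"):
            block_duration(_summaries(mids, np.full(20, 5.0)))

    def test_isolated_noisy_window_does_not_reblock(self):
        mids = np.arange(20) * 13.5 + 6.75
        means = np.maximum(0.0, 80.0 - 0.65 * mids)
        means[14] = 17.0  # single spurious re-exceedance late in the horizon
        d = block_duration(_summaries(mids, means))
        assert not d.censored_above_total
        assert d.duration_min == pytest.approx(100.0, abs=4.0)

    def test_sustained_reblock_moves_the_crossing(self):
        mids = np.arange(20) * 13.5 + 6.75
        means = np.maximum(0.0, 80.0 - 0.9 * mids)
        means[10:14] = 40.0  # genuine re-block over four windows
        means[14:] = 5.0
        d = block_duration(_summaries(mids, means))
        assert d.duration_min > mids[13]
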