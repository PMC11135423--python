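"""MSD estimator vs brute-force oracle; anomalous fit; exponent classes."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trackmotion import (
    AnomalousFit,
    MSDCurve,
    Thresholds,
    classify_alpha,
    compute_msd,
    fit_anomalous,
)

from conftest import make_track


def brute_force_msd(traj, max_lag_fraction):
    """Independent O(N^2) oracle: enumerate every (i, i+k) pair explicitly."""
    n = traj.n_frames
    k_max = max(1, int(np.floor(max_lag_fraction * (n - 1))))
    lags, msd, n_pairs = [], [], []
    for k in range(1, k_max + 1):
        acc = 0.0
        count = 0
        for i in range(n - k):
            acc += (traj.x[i + k] - traj.x[i]) ** 2 + (traj.y[i + k] - traj.y[i]) ** 2
            count += 1
        lags.append(k * traj.dt)
        msd.append(acc / count)
        n_pairs.append(count)
    return np.array(lags), np.array(msd), np.array(n_pairs)


class TestComputeMSD:
    def test_three_point_hand_enumeration(self):
        # x = (0, 1, 2): lag 1 pairs (0,1),(1,2) -> mean 1; lag 2 pair (0,2) -> 4
        curve = compute_msd(make_track([0, 1, 2]), max_lag_fraction=1.0)
        np.testing.assert_allclose(curve.lags, [0.6, 1.2])
        np.testing.assert_allclose(curve.msd, [1.0, 4.0])
        np.testing.assert_array_equal(curve.n_pairs, [2, 1])

    def test_zigzag_hand_enumeration(self):
        # x = (0, 1, 0, 1): lag-1 pairs all 1; lag-2 pairs (0,0),(1,1) both 0;
        # lag-3 pair (0,1) gives 1 (values frozen from the pair-enumeration oracle)
        curve = compute_msd(make_track([0, 1, 0, 1]), max_lag_fraction=1.0)
        np.testing.assert_allclose(curve.msd, [1.0, 0.0, 1.0])

    def test_stationary_track_is_zero_everywhere(self):
        curve = compute_msd(make_track(np.zeros(30)), max_lag_fraction=0.5)
        np.testing.assert_array_equal(curve.msd, 0.0)

    def test_lag_cap_and_minimum_one_lag(self):
        assert len(compute_msd(make_track(np.arange(101.0))).lags) == 25  # floor(.25*100)
        assert len(compute_msd(make_track([0.0, 1.0, 2.0])).lags) == 1  # fraction rounds to 0

    def test_matches_brute_force_oracle_on_random_tracks(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = rng.integers(2, 51)
            traj = make_track(rng.normal(size=n), y=rng.normal(size=n))
            frac = rng.uniform(0.1, 1.0)
            lags, msd, n_pairs = brute_force_msd(traj, frac)
            curve = compute_msd(traj, frac)
            np.testing.assert_allclose(curve.msd, msd, rtol=1e-12)
            np.testing.assert_allclose(curve.lags, lags, rtol=1e-12)
            np.testing.assert_array_equal(curve.n_pairs, n_pairs)

    def test_too_few_frames_rejected(self):
        with pytest.raises(ValueError):
            compute_msd(make_track([0.0, 1.0]), max_lag_fraction=0.0)

    @given(
        scale=st.floats(min_value=0.01, max_value=100.0),
        seed=st.integers(min_value=0, max_value=2**16),
    )
    @settings(max_examples=30)
    def test_scale_covariance(self, scale, seed):
        # positions scaled by c => every msd value scaled by c^2
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=40), rng.normal(size=40)
        base = compute_msd(make_track(x, y=y))
        scaled = compute_msd(make_track(scale * x, y=scale * y))
        np.testing.assert_allclose(scaled.msd, scale**2 * base.msd, rtol=1e-9)


def _curve_from(fn, taus):
    taus = np.asarray(taus, dtype=float)
    return MSDCurve(lags=taus, msd=fn(taus), n_pairs=np.full(len(taus), 10))


class TestFitAnomalous:
    taus = np.arange(1, 16) * 0.6

    def test_recovers_quadratic_law(self):
        fit = fit_anomalous(_curve_from(lambda t: t**2, self.taus))
        assert fit.converged
        assert fit.alpha == pytest.approx(2.0, abs=1e-3)
        assert fit.A == pytest.approx(1.0, abs=1e-3)
        assert fit.B == pytest.approx(0.0, abs=1e-3)

    def test_recovers_linear_law(self):
        fit = fit_anomalous(_curve_from(lambda t: 0.6 * t, self.taus))
        assert fit.converged
        assert fit.alpha == pytest.approx(1.0, abs=1e-3)

    def test_recovers_offset(self):
        fit = fit_anomalous(_curve_from(lambda t: 0.3 * t**0.8 + 0.05, self.taus))
        assert fit.converged
        assert fit.alpha == pytest.approx(0.8, abs=1e-2)
        assert fit.B == pytest.approx(0.05, abs=1e-2)

    def test_flat_curve_is_non_identifiable(self):
        fit = fit_anomalous(_curve_from(lambda t: np.full_like(t, 0.7), self.taus))
        assert not fit.converged
        fit0 = fit_anomalous(_curve_from(lambda t: np.zeros_like(t), self.taus))
        assert not fit0.converged

    def test_fewer_than_three_lags_not_fittable(self):
        fit = fit_anomalous(_curve_from(lambda t: t, self.taus[:2]))
        assert not fit.converged and fit.n_lags_used == 2

    def test_nonfinite_curve_rejected(self):
        with pytest.raises(ValueError):
            fit_anomalous(_curve_from(lambda t: np.where(t > 3, np.nan, t), self.taus))

    def test_alpha_invariant_under_position_rescaling(self):
        base = fit_anomalous(_curve_from(lambda t: 0.2 * t**1.4, self.taus))
        scaled = fit_anomalous(_curve_from(lambda t: 9.0 * 0.2 * t**1.4, self.taus))
        assert scaled.alpha == pytest.approx(base.alpha, abs=1e-6)


def _fit(alpha, converged=True):
    return AnomalousFit(A=0.1, alpha=alpha, B=0.0, residual_norm=0.0,
                        converged=converged, n_lags_used=10)


class TestClassifyAlpha:
    @pytest.mark.parametrize(
        "alpha,expected",
        [
            (1.8, "active"),
            (2.5, "active"),
            (1.0, "diffusive"),
            (0.95, "diffusive"),
            (0.3, "confined"),
            (0.0, "confined"),
            (0.7, "ambiguous"),  # gap between confined and diffusive
            (1.3, "ambiguous"),  # gap between diffusive and active
            (0.5, "ambiguous"),  # boundaries are strict
            (0.9, "ambiguous"),
            (1.1, "ambiguous"),
            (1.5, "ambiguous"),
        ],
    )
    def test_printed_windows_with_strict_boundaries(self, alpha, expected):
        assert classify_alpha(_fit(alpha)) == expected

    def test_failed_fit_is_ambiguous(self):
        assert classify_alpha(_fit(np.nan, converged=False)) == "ambiguous"

    @given(st.floats(min_value=0.0, max_value=3.0, allow_nan=False))
    def test_every_alpha_gets_exactly_one_label(self, alpha):
        labels = [classify_alpha(_fit(alpha), Thresholds())]
        assert len(labels) == 1
        assert labels[0] in ("active", "diffusive", "confined", "ambiguous")
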