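"""Exact-inference checks against brute-force joint-Gaussian oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import signal, stats

from oscdecomp.ssm_core import (
    OscillatorParams,
    OscModel,
    TimeSeriesData,
    build_model,
    component_spectrum,
    kalman_filter,
    kalman_smoother,
    log_likelihood,
    loglik_per_time,
    simulate_ssm,
    simulate_states,
    stationary_state_cov,
)

from _oracles import brute_loglik, brute_smoother, random_model


# ---------------------------------------------------------------------------
# containers and model assembly
# ---------------------------------------------------------------------------


class TestContainers:
    def test_rejects_missing_values(self):
        vals = np.ones((10, 2))
        vals[3, 1] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            TimeSeriesData(values=vals, dt=0.1)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"values": np.ones((1, 2)), "dt": 0.1},
            {"values": np.ones((10, 2)), "dt": 0.0},
        ],
    )
    def test_rejects_invalid_shape_or_dt(self, kwargs):
        with pytest.raises(ValueError):
            TimeSeriesData(**kwargs)

    @pytest.mark.parametrize("a", [0.0, 1.0, 1.3, -0.2])
    def test_regularity_bounds(self, a):
        with pytest.raises(ValueError, match="regularity"):
            OscillatorParams(a=a, f=1.0, sigma2=0.1)

    def test_frequency_above_nyquist_rejected(self):
        osc = OscillatorParams(a=0.9, f=6.0, sigma2=0.1)
        with pytest.raises(ValueError, match="Nyquist"):
            OscModel(oscillators=(osc,), projections=[[[1.0, 0.0]]], tau2=0.1, dt=0.1)

    def test_reference_projection_fixed(self):
        osc = OscillatorParams(a=0.9, f=1.0, sigma2=0.1)
        with pytest.raises(ValueError, match="reference"):
            OscModel(oscillators=(osc,), projections=[[[0.9, 0.0]]], tau2=0.1, dt=0.1)


class TestBuildModel:
    def test_rotation_block_at_2hz(self):
        """f=2 Hz at dt=0.1 s gives theta = 0.4*pi; block = a * R(0.4*pi)."""
        osc = OscillatorParams(a=0.99, f=2.0, sigma2=0.01)
        m = OscModel(oscillators=(osc,), projections=[[[1.0, 0.0]]], tau2=1e-6, dt=0.1)
        F, Q, H, R = build_model(m)
        th = 0.4 * np.pi
        expected = 0.99 * np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        np.testing.assert_allclose(F, expected, atol=1e-15)
        np.testing.assert_allclose(Q, 0.01 * np.eye(2))
        np.testing.assert_allclose(H, [[1.0, 0.0]])
        np.testing.assert_allclose(R, [[1e-6]])

    def test_zero_frequency_is_scaled_identity(self):
        osc = OscillatorParams(a=0.7, f=0.0, sigma2=0.1)
        m = OscModel(oscillators=(osc,), projections=[[[1.0, 0.0]]], tau2=0.1, dt=0.1)
        F, _, _, _ = build_model(m)
        np.testing.assert_allclose(F, 0.7 * np.eye(2), atol=1e-15)

    def test_determinant_and_rotation_property(self, rng):
        """det(F) = prod a_k^2 and F_k^T F_k = a_k^2 I for every block."""
        m = random_model(rng, K=3, J=2)
        F, _, _, _ = build_model(m)
        np.testing.assert_allclose(np.linalg.det(F), np.prod(m.a**2), rtol=1e-10)
        for k in range(3):
            blk = F[2 * k : 2 * k + 2, 2 * k : 2 * k + 2]
            np.testing.assert_allclose(blk.T @ blk, m.a[k] ** 2 * np.eye(2), atol=1e-14)


# ---------------------------------------------------------------------------
# filter and smoother vs brute force
# ---------------------------------------------------------------------------


@settings(max_examples=20, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000), K=st.integers(1, 3), J=st.integers(1, 2), n=st.integers(5, 30))
def test_filter_matches_joint_gaussian_density(seed, K, J, n):
    """Prediction-error log likelihood equals the explicit joint Gaussian density."""
    rng = np.random.default_rng(seed)
    m = random_model(rng, K=K, J=J)
    data, _ = simulate_ssm(m, n, rng)
    assert log_likelihood(m, data) == pytest.approx(brute_loglik(m, data), rel=1e-8)


@settings(max_examples=10, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000), K=st.integers(1, 2))
def test_smoother_matches_conditional_gaussian(seed, K):
    """Smoothed moments equal the conditional Gaussian given all observations."""
    rng = np.random.default_rng(seed)
    m = random_model(rng, K=K, J=2)
    data, _ = simulate_ssm(m, 20, rng)
    traj = kalman_smoother(m, data)
    mean, covs = brute_smoother(m, data)
    np.testing.assert_allclose(traj.means, mean, atol=1e-8)
    np.testing.assert_allclose(traj.covariances, covs, atol=1e-8)


def test_filter_per_time_sums_to_total(rng):
    m = random_model(rng, K=2, J=2)
    data, _ = simulate_ssm(m, 50, rng)
    ll = loglik_per_time(m, data)
    assert np.sum(ll) == pytest.approx(log_likelihood(m, data), rel=1e-12)
    fr = kalman_filter(m, data)
    np.testing.assert_allclose(fr.loglik_per_time, ll, atol=1e-9)


def test_degenerate_latent_process_reduces_to_iid_noise(rng):
    """sigma2 = 0 with stationary init pins the state at 0: y is pure noise."""
    osc = OscillatorParams(a=0.9, f=1.0, sigma2=0.0)
    tau2 = 0.3
    m = OscModel(oscillators=(osc,), projections=[[[1.0, 0.0]]], tau2=tau2, dt=0.1)
    y = rng.normal(size=(40, 1))
    data = TimeSeriesData(values=y, dt=0.1)
    expected = stats.norm.logpdf(y, scale=np.sqrt(tau2)).sum()
    assert log_likelihood(m, data) == pytest.approx(expected, rel=1e-10)


def test_noiseless_observation_limit(rng):
    """tau2 -> 0 with J=1, K=1, c=(1,0): the smoothed first coordinate tracks y."""
    osc = OscillatorParams(a=0.95, f=0.8, sigma2=0.2)
    m = OscModel(oscillators=(osc,), projections=[[[1.0, 0.0]]], tau2=1e-12, dt=0.1)
    data, _ = simulate_ssm(m, 60, rng)
    traj = kalman_smoother(m, data)
    np.testing.assert_allclose(traj.means[:, 0], data.values[:, 0], atol=1e-4)


def test_smoothing_never_inflates_variance(rng):
    """Smoothed posterior variances are bounded by filtered variances."""
    m = random_model(rng, K=2, J=2)
    data, _ = simulate_ssm(m, 40, rng)
    fr = kalman_filter(m, data)
    traj = kalman_smoother(m, data)
    f_diag = np.diagonal(fr.filtered_covs, axis1=1, axis2=2)
    s_diag = np.diagonal(traj.covariances, axis1=1, axis2=2)
    assert np.all(s_diag <= f_diag + 1e-10)


def test_filter_rejects_mismatched_series_count(rng):
    m = random_model(rng, K=1, J=2)
    data = TimeSeriesData(values=rng.normal(size=(20, 1)), dt=0.1)
    with pytest.raises(ValueError, match="series"):
        log_likelihood(m, data)


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------


class TestSimulation:
    def test_seed_reproducibility(self, rng):
        m = random_model(rng, K=2, J=2)
        d1, x1 = simulate_ssm(m, 100, 7)
        d2, x2 = simulate_ssm(m, 100, 7)
        np.testing.assert_array_equal(d1.values, d2.values)
        np.testing.assert_array_equal(x1, x2)

    def test_latent_variance_matches_stationary_formula(self):
        """Long-run sample variance of each coordinate approaches sigma2/(1-a^2)."""
        osc = OscillatorParams(a=0.9, f=0.7, sigma2=0.19)
        m = OscModel(oscillators=(osc,), projections=[[[1.0, 0.0]]], tau2=1e-6, dt=0.1)
        x = simulate_states(m, 100_000, 3)
        assert np.var(x[:, 0]) == pytest.approx(osc.power, rel=0.05)
        assert np.var(x[:, 1]) == pytest.approx(osc.power, rel=0.05)

    def test_zero_innovations_give_pure_observation_noise(self):
        osc = OscillatorParams(a=0.9, f=0.7, sigma2=0.0)
        tau2 = 0.04
        m = OscModel(oscillators=(osc,), projections=[[[1.0, 0.0]]], tau2=tau2, dt=0.1)
        data, x = simulate_ssm(m, 20_000, 5)
        assert np.all(x == 0.0)
        assert np.var(data.values) == pytest.approx(tau2, rel=0.05)


# ---------------------------------------------------------------------------
# spectra
# ---------------------------------------------------------------------------


class TestComponentSpectrum:
    def _model(self, a=0.95, f=1.5, sigma2=0.1, tau2=0.01):
        osc = OscillatorParams(a=a, f=f, sigma2=sigma2)
        proj = [[[1.0, 0.0]], [[0.5, 0.5]]]
        return OscModel(oscillators=(osc,), projections=proj, tau2=tau2, dt=0.1)

    def test_peak_location_and_narrowing(self):
        grid = np.linspace(0.01, 4.99, 2000)
        m1 = self._model(a=0.9)
        m2 = self._model(a=0.99)
        s1 = component_spectrum(m1, grid)["per_oscillator"][0, 0]
        s2 = component_spectrum(m2, grid)["per_oscillator"][0, 0]
        assert abs(grid[np.argmax(s1)] - 1.5) < 0.05
        assert abs(grid[np.argmax(s2)] - 1.5) < 0.05
        width1 = np.sum(s1 > s1.max() / 2)
        width2 = np.sum(s2 > s2.max() / 2)
        assert width2 < width1

    def test_zero_innovation_component_vanishes(self):
        m = self._model(sigma2=0.0)
        s = component_spectrum(m, np.linspace(0, 5, 50))["per_oscillator"]
        np.testing.assert_allclose(s, 0.0, atol=1e-300)

    def test_nonnegative_and_symmetric(self):
        m = self._model()
        grid = np.linspace(-5, 5, 501)
        out = component_spectrum(m, grid)
        assert np.all(out["total"] >= 0)
        np.testing.assert_allclose(out["total"][:, ::-1], out["total"], rtol=1e-10)

    def test_integral_equals_component_variance(self):
        """Density normalization: integral over [-Nyq, Nyq] = stationary variance."""
        m = self._model()
        grid = np.linspace(-5, 5, 20_001)
        out = component_spectrum(m, grid)
        for j, c in ((0, (1.0, 0.0)), (1, (0.5, 0.5))):
            var = (c[0] ** 2 + c[1] ** 2) * m.oscillators[0].power
            integral = np.trapezoid(out["per_oscillator"][j, 0], grid)
            assert integral == pytest.approx(var, rel=1e-3)

    def test_total_density_matches_welch_periodogram(self):
        """Average periodogram of a long simulation tracks the theoretical total."""
        m = self._model()
        data, _ = simulate_ssm(m, 2**15, 11)
        freqs, pxx = signal.welch(
            data.values[:, 0], fs=10.0, nperseg=2048, noverlap=1024, detrend=False
        )
        theory = component_spectrum(m, freqs)["total"][0]
        # one-sided Welch density carries twice the two-sided mass off DC/Nyquist
        band = (freqs > 0.3) & (freqs < 4.7)
        ratio = pxx[band] / (2.0 * theory[band])
        assert np.median(ratio) == pytest.approx(1.0, abs=0.1)

    def test_grid_outside_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            component_spectrum(self._model(), np.array([5.5]))
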