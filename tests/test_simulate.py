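"""fGn generator, duration law, hFBM ensembles, superstatistical samples."""
import numpy as np
import pytest
from scipy.linalg import toeplitz
from scipy.stats import kstest

from endotrack import simulate as sim_mod
from endotrack.simulate import (
    Coupling,
    DurationLaw,
    HurstProcess,
    SimConfig,
    fgn_autocovariance,
    fit_truncated_pareto_mle,
    sample_durations,
    sample_superstat_displacements,
    sample_truncated_pareto,
    simulate_fgn,
    simulate_hfbm_ensemble,
    superstat_tail_window,
    truncated_pareto_cdf,
)


class TestFgn:
    def test_h_half_is_uncorrelated_white_noise(self):
        x = simulate_fgn(0.5, 100_000, seed=2)
        r1 = np.corrcoef(x[1:], x[:-1])[0, 1]
        assert abs(r1) < 0.02

    def test_antipersistent_lag1_autocorrelation(self):
        # closed form: rho(1) = 2^{2H-1} - 1
        x = simulate_fgn(0.25, 100_000, seed=1)
        r1 = np.corrcoef(x[1:], x[:-1])[0, 1]
        assert r1 == pytest.approx(2 ** (2 * 0.25 - 1) - 1, abs=0.01)

    def test_sample_autocovariance_matches_analytic(self):
        n = 100_000
        H = 0.3
        x = simulate_fgn(H, n, seed=5)
        for k in range(6):
            emp = np.mean(x[k:] * x[: n - k] if k else x * x)
            se = 3.0 / np.sqrt(n)  # ~3 standard errors for unit-variance products
            assert emp == pytest.approx(fgn_autocovariance(H, k), abs=se)

    def test_fbm_variance_law(self):
        rng = np.random.default_rng(5)
        paths = np.array([np.cumsum(simulate_fgn(0.75, 256, 1.0, rng))
                          for _ in range(1500)])
        ratios = [paths[:, t - 1].var() / t**1.5 for t in (16, 64, 256)]
        assert np.allclose(ratios, 1.0, atol=0.12)

    def test_dt_scaling(self):
        # gamma(0) = dt^{2H}: per-step variance scales with spacing
        x = simulate_fgn(0.25, 50_000, dt=0.05, seed=8)
        assert np.var(x) == pytest.approx(0.05**0.5, rel=0.05)

    def test_durbin_levinson_equals_cholesky_oracle(self):
        for H in (0.2, 0.5, 0.8):
            n = 64
            g = fgn_autocovariance(H, np.arange(n))
            L = np.linalg.cholesky(toeplitz(g))
            z = np.random.default_rng(7).standard_normal(n)
            dl = sim_mod._fgn_durbin_levinson(H, n, np.random.default_rng(7))
            np.testing.assert_allclose(dl, L @ z, atol=1e-10)

    def test_invalid_hurst_rejected(self):
        for H in (0.0, 1.0, -0.3):
            with pytest.raises(ValueError):
                simulate_fgn(H, 10)

    def test_reproducible_under_seed(self):
        np.testing.assert_array_equal(simulate_fgn(0.25, 1000, seed=3),
                                      simulate_fgn(0.25, 1000, seed=3))


class TestDurations:
    def test_degenerate_support(self):
        d = sample_durations(1.85, 1.0, 1.0 + 1e-9, 100, seed=0)
        assert np.allclose(d, 1.0, atol=1e-6)

    def test_mle_recovers_generating_exponent(self):
        d = sample_durations(1.85, 0.5, 200.0, 100_000, seed=11)
        assert fit_truncated_pareto_mle(d, 0.5, 200.0) == pytest.approx(1.85, abs=0.02)

    def test_empirical_cdf_matches_analytic(self):
        d = sample_durations(1.85, 0.5, 200.0, 100_000, seed=4)
        stat = kstest(d, lambda x: truncated_pareto_cdf(x, 1.85, 0.5, 200.0)).statistic
        assert stat < 0.01

    def test_invalid_bounds(self):
        with pytest.raises(ValueError):
            sample_durations(1.85, 5.0, 1.0, 10)
        with pytest.raises(ValueError):
            sample_durations(0.9, 0.5, 200.0, 10)


class TestHfbmEnsemble:
    def test_zero_diffusivity_stays_at_origin(self):
        config = SimConfig(n_traj=1, coupling=Coupling(c=1e-30), seed=0)
        ens = simulate_hfbm_ensemble(config)
        assert np.allclose(ens[0].xs, 0.0, atol=1e-12)

    def test_coupling_slope_exact(self):
        ens = simulate_hfbm_ensemble(SimConfig(n_traj=300, seed=1))
        slope = np.polyfit(np.log10(ens.durations),
                           np.log10(ens.meta["diffusivities"]), 1)[0]
        assert slope == pytest.approx(-0.6, abs=1e-9)

    def test_fixed_seed_bit_identical(self):
        a = simulate_hfbm_ensemble(SimConfig(n_traj=20, seed=5))
        b = simulate_hfbm_ensemble(SimConfig(n_traj=20, seed=5))
        for ta, tb in zip(a, b):
            np.testing.assert_array_equal(ta.xs, tb.xs)
            np.testing.assert_array_equal(ta.ys, tb.ys)

    def test_tmin_below_two_frames_is_config_error(self):
        with pytest.raises(ValueError):
            SimConfig(duration_law=DurationLaw(t_min=0.05), dt=0.05)

    def test_noise_shifts_emsd_by_static_offset(self):
        from endotrack import emsd
        from endotrack.validation import fbm_constant_ensemble

        sigma = 0.1
        rng_seed = 21
        clean = fbm_constant_ensemble(0.25, 400, 64, 0.05, 0.01, rng_seed)
        noisy = []
        rng = np.random.default_rng(99)
        for t in clean:
            noisy.append(type(t)(t.id, t.dt,
                                 t.xs + rng.normal(0, sigma, t.n_points),
                                 t.ys + rng.normal(0, sigma, t.n_points)))
        from endotrack import Ensemble
        shift = (emsd(Ensemble(noisy)).values[0] - emsd(clean).values[0])
        # static localization error adds ~4 sigma^2 at vanishing lag
        assert shift == pytest.approx(4 * sigma**2, rel=0.25)

    def test_two_state_mode_runs_and_mixes(self):
        hp = HurstProcess(mode="two_state", H_persistent=0.75,
                          H_antipersistent=0.25, mean_sojourn=0.5)
        ens = simulate_hfbm_ensemble(SimConfig(n_traj=10, hurst=hp, seed=3))
        assert len(ens) == 10
        assert all(t.n_points >= 2 for t in ens)


class TestSuperstat:
    def test_single_diffusivity_limit_is_gaussian(self):
        from scipy.stats import kurtosis

        x = sample_superstat_displacements(0.5, 1.0, 1.0, 1.0, 1.0, 200_000, seed=0)
        assert abs(kurtosis(x)) < 0.05

    @pytest.mark.parametrize("gamma,tol", [(1.7, 0.2), (0.5, 0.15)])
    def test_tail_matches_mixture_integral_oracle(self, gamma, tol):
        """Histogram tail slope vs direct numerical integration of the
        Gaussian mixture over p(D)."""
        from scipy.integrate import quad

        d_min, d_max, n = 1e-2, 1e2, 400_000
        x = sample_superstat_displacements(gamma, d_min, d_max, 1.0, 1.0, n, seed=6)
        sigma = np.std(x)
        lo, hi = superstat_tail_window(gamma, d_min, d_max, 1.0, 1.0)
        grid = np.linspace(max(2.0, 3 * lo), hi / 2.0, 12)

        z = quad(lambda D: D ** (-1 - gamma), d_min, d_max)[0]

        def mix_pdf(xi):
            return quad(
                lambda D: D ** (-1 - gamma) / z
                * np.exp(-((xi * sigma) ** 2) / (4 * D)) / np.sqrt(4 * np.pi * D) * sigma,
                d_min, d_max)[0]

        oracle_slope = np.polyfit(np.log10(grid),
                                  np.log10([mix_pdf(g) for g in grid]), 1)[0]
        # oracle window really is the power-law regime
        assert oracle_slope == pytest.approx(-(1 + 2 * gamma), abs=2 * tol)
        # empirical histogram slope agrees with the oracle
        a = np.abs(x / sigma)
        edges = np.logspace(np.log10(grid[0]), np.log10(grid[-1]), 12)
        counts, _ = np.histogram(a, bins=edges)
        dens = counts / (a.size * np.diff(edges))
        centers = np.sqrt(edges[:-1] * edges[1:])
        nz = counts > 0
        emp_slope = np.polyfit(np.log10(centers[nz]), np.log10(dens[nz]), 1)[0]
        assert emp_slope == pytest.approx(oracle_slope, abs=2 * tol)

    def test_invalid_bounds(self):
        with pytest.raises(ValueError):
            sample_superstat_displacements(0.5, 1.0, 0.5, 1.0, 1.0, 10)
        with pytest.raises(ValueError):
            sample_superstat_displacements(-1.0, 0.1, 1.0, 1.0, 1.0, 10)
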