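"""Scaled-displacement propagators, tail fits and reference propagators."""
import numpy as np
import pytest
from scipy.stats import norm

from endotrack import (
    Ensemble,
    PropagatorPDF,
    Trajectory,
    consistency_check,
    fit_tail_exponent,
    obstructed_propagator,
    propagator_pdf,
    scaled_displacement_pdf,
)
from endotrack import simulate as sim_mod
from endotrack.local import DistributionFit


class TestPdfConstruction:
    def test_gaussian_sample_matches_standard_normal(self):
        rng = np.random.default_rng(0)
        pdf = scaled_displacement_pdf(rng.normal(0, 3.0, 1_000_000), lag=1.0,
                                      n_bins=101, xi_max=5.0)
        assert np.max(np.abs(pdf.density - norm.pdf(pdf.xi_centers))) < 0.02

    def test_density_integrates_to_one(self):
        rng = np.random.default_rng(1)
        pdf = scaled_displacement_pdf(rng.laplace(size=200_000), lag=1.0, n_bins=401)
        dx = pdf.xi_centers[1] - pdf.xi_centers[0]
        assert np.sum(pdf.density) * dx == pytest.approx(1.0, abs=0.01)

    def test_degenerate_equal_displacements_is_error(self):
        with pytest.raises(ValueError, match="zero displacement"):
            scaled_displacement_pdf(np.full(1000, 2.5), lag=1.0)

    def test_ensemble_pooling_matches_manual_displacements(self, rng):
        trajs = [Trajectory(f"t{i}", 0.5, rng.normal(size=40), rng.normal(size=40))
                 for i in range(20)]
        ens = Ensemble(trajs)
        pdf = propagator_pdf(ens, lag=1.0, n_bins=51)
        k = 2
        manual = np.concatenate([t.xs[k:] - t.xs[:-k] for t in trajs])
        assert pdf.n_samples == manual.size
        assert pdf.sigma_x == pytest.approx(np.std(manual))

    def test_superstat_sample_matches_mixture_integral(self):
        from scipy.integrate import quad

        gamma, d_min, d_max = 0.5, 1e-1, 1e1
        x = sim_mod.sample_superstat_displacements(gamma, d_min, d_max, 1.0, 1.0,
                                                   500_000, seed=5)
        pdf = scaled_displacement_pdf(x, lag=1.0, n_bins=81, xi_max=4.0)
        z = quad(lambda D: D ** (-1 - gamma), d_min, d_max)[0]

        def mix(xi):
            return quad(lambda D: D ** (-1 - gamma) / z * pdf.sigma_x
                        * np.exp(-((xi * pdf.sigma_x) ** 2) / (4 * D))
                        / np.sqrt(4 * np.pi * D), d_min, d_max)[0]

        grid = pdf.xi_centers[::8]
        oracle = np.array([mix(g) for g in grid])
        emp = pdf.density[::8]
        assert np.max(np.abs(emp - oracle)) < 0.02


class TestTailFit:
    def test_exact_power_law_density_algebra(self):
        # density ∝ |xi|^-2 should give gamma = 0.5 through gamma = (-s-1)/2
        centers = np.concatenate([-np.logspace(1.3, 0.3, 20), np.logspace(0.3, 1.3, 20)])
        order = np.argsort(centers)
        pdf = PropagatorPDF(lag=1.0, xi_centers=centers[order],
                            density=np.abs(centers[order]) ** -2.0,
                            sigma_x=1.0, n_samples=10_000)
        fit = fit_tail_exponent(pdf, (2.0, 20.0))
        assert fit.gamma == pytest.approx(0.5, abs=1e-9)

    @pytest.mark.parametrize("gamma,tol", [(1.7, 0.15), (0.5, 0.1), (1.0, 0.1)])
    def test_recovers_generating_gamma(self, gamma, tol):
        x = sim_mod.sample_superstat_displacements(gamma, 1e-2, 1e2, 1.0, 1.0,
                                                   1_000_000, seed=9)
        pdf = scaled_displacement_pdf(x, lag=1.0, n_bins=201, xi_max=30.0)
        lo, hi = sim_mod.superstat_tail_window(gamma, 1e-2, 1e2, 1.0, 1.0)
        fit = fit_tail_exponent(pdf, (max(2.0, 3 * lo), hi / 2))
        assert fit.gamma == pytest.approx(gamma, abs=tol)

    def test_invariant_under_displacement_rescaling(self):
        x = sim_mod.sample_superstat_displacements(1.0, 1e-2, 1e2, 1.0, 1.0,
                                                   200_000, seed=3)
        f1 = fit_tail_exponent(scaled_displacement_pdf(x, 1.0, xi_max=30.0), (2, 10))
        f2 = fit_tail_exponent(scaled_displacement_pdf(137.0 * x, 1.0, xi_max=30.0), (2, 10))
        assert f1.gamma == pytest.approx(f2.gamma, abs=1e-9)

    def test_insufficient_bins_is_error(self):
        pdf = PropagatorPDF(lag=1.0, xi_centers=np.array([-0.5, 0.0, 0.5]),
                            density=np.array([0.2, 0.6, 0.2]), sigma_x=1.0,
                            n_samples=1000)
        with pytest.raises(ValueError):
            fit_tail_exponent(pdf, (2.0, 20.0))


class TestObstructedPropagator:
    def grid(self):
        half = np.linspace(0.05, 6.0, 400)
        return np.concatenate([-half[::-1], half])

    def test_even_symmetry(self):
        dens = obstructed_propagator(self.grid())
        np.testing.assert_allclose(dens, dens[::-1])

    def test_unnormalized_ratio_direct_evaluation(self):
        dens = obstructed_propagator(self.grid())
        g = self.grid()
        i1 = np.argmin(np.abs(g - 1.0))
        i2 = np.argmin(np.abs(g - 2.0))
        expected = (g[i1] / g[i2]) ** -0.108 * np.exp(-g[i1] ** 1.65 + g[i2] ** 1.65)
        assert dens[i1] / dens[i2] == pytest.approx(expected, rel=1e-9)

    def test_trapezoid_normalization(self):
        g = self.grid()
        assert np.trapezoid(obstructed_propagator(g), g) == pytest.approx(1.0, abs=1e-6)

    def test_grid_containing_zero_rejected(self):
        with pytest.raises(ValueError):
            obstructed_propagator(np.linspace(-1, 1, 21))


class TestConsistencyCheck:
    @pytest.mark.parametrize("d_exp,gamma,expected", [
        (2.7, 1.7, True),   # slow movers: p(D) ~ D^-2.7 vs tail gamma 1.7
        (1.5, 0.5, True),   # fast movers
        (2.0, 0.2, False),  # 2.0 != 1.2
    ])
    def test_superstatistics_arithmetic(self, d_exp, gamma, expected):
        report = consistency_check(d_exp, gamma)
        assert report["consistent"] is expected
        assert report["expected_d_exponent"] == pytest.approx(1 + gamma)

    def test_accepts_fit_objects(self):
        d_fit = DistributionFit("power_law", 2.7, (0.01, 10.0), "loglog_ls", 5000)
        report = consistency_check(d_fit, 1.7)
        assert report["consistent"]
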