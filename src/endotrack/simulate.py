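"""Synthetic ensembles of (heterogeneous) fractional Brownian motion.

Fractional Brownian motion (FBM) with Hurst exponent H has stationary
Gaussian increments (fractional Gaussian noise, fGn) with autocovariance

    γ(k) = ½ (|k+1|^{2H} − 2|k|^{2H} + |k−1|^{2H}) · dt^{2H},

and Var[B_H(t)] = t^{2H}. Heterogeneous FBM (hFBM) draws per-trajectory
durations from a truncated power law φ(T) ∝ T^−μ_T and couples the
generalized diffusion coefficient to duration, D = c·T^−μ_D, emulating the
survival bias of live-cell tracking: slow particles stay in the field of
view longer, so long tracks are systematically less diffusive.

fGn is generated by circulant embedding (Davies–Harte), which is exact in
distribution and O(n log n); if the embedding spectrum has a negative
eigenvalue the generator falls back to the exact O(n²) Durbin–Levinson
recursion.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.optimize import minimize_scalar

from .trajectory import DEFAULT_DT, Ensemble, Trajectory

logger = logging.getLogger("endotrack")


# --------------------------------------------------------------------------
# configuration types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class HurstProcess:
    """Constant or two-state switching Hurst exponent.

    In ``two_state`` mode H alternates between a persistent (>0.5) and an
    anti-persistent (<0.5) value with exponentially distributed sojourn
    times of mean ``mean_sojourn`` seconds; increments are generated
    segment-wise, which neglects cross-segment increment correlations.
    """

    mode: str = "constant"
    H: float = 0.25
    H_persistent: float = 0.75
    H_antipersistent: float = 0.25
    mean_sojourn: float = 1.0

    def __post_init__(self) -> None:
        if self.mode not in ("constant", "two_state"):
            raise ValueError("mode must be 'constant' or 'two_state'")
        for h in (self.H, self.H_persistent, self.H_antipersistent):
            if not 0.0 < h < 1.0:
                raise ValueError("every Hurst exponent must lie in (0, 1)")
        if self.mode == "two_state":
            if not self.H_persistent > 0.5 > self.H_antipersistent:
                raise ValueError("two_state needs H_persistent>0.5>H_antipersistent")
            if self.mean_sojourn <= 0:
                raise ValueError("mean_sojourn must be positive")


@dataclass(frozen=True)
class DurationLaw:
    """Truncated power-law trajectory-duration distribution φ(T) ∝ T^−mu_T."""

    mu_T: float = 1.85
    t_min: float = 0.5
    t_max: float = 200.0

    def __post_init__(self) -> None:
        if self.mu_T <= 1:
            raise ValueError("mu_T must exceed 1")
        if not 0 < self.t_min < self.t_max:
            raise ValueError("need 0 < t_min < t_max")


@dataclass(frozen=True)
class Coupling:
    """Duration–diffusivity coupling D = c·T^−mu_D."""

    c: float = 0.1
    mu_D: float = 0.6

    def __post_init__(self) -> None:
        if self.c <= 0:
            raise ValueError("prefactor c must be positive")


@dataclass(frozen=True)
class SimConfig:
    """Full recipe for a heterogeneous-FBM ensemble."""

    n_traj: int = 1000
    dt: float = DEFAULT_DT
    duration_law: DurationLaw = field(default_factory=DurationLaw)
    coupling: Coupling = field(default_factory=Coupling)
    hurst: HurstProcess = field(default_factory=HurstProcess)
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_traj < 1:
            raise ValueError("n_traj must be >= 1")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.duration_law.t_min < 2 * self.dt:
            raise ValueError("T_min must be at least 2·dt so trajectories have >= 2 points")


# --------------------------------------------------------------------------
# fractional Gaussian noise
# --------------------------------------------------------------------------

def fgn_autocovariance(H: float, lags, dt: float = 1.0) -> np.ndarray:
    """Analytic fGn autocovariance γ(k) at integer lags for spacing dt."""
    k = np.abs(np.asarray(lags, dtype=float))
    h2 = 2.0 * H
    return 0.5 * ((k + 1) ** h2 - 2 * k**h2 + np.abs(k - 1) ** h2) * dt**h2


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _fgn_davies_harte(H: float, n: int, rng: np.random.Generator):
    """Circulant-embedding fGn sample of unit spacing, or None if the
    embedding spectrum is not non-negative."""
    g = fgn_autocovariance(H, np.arange(n + 1))
    if n == 1:
        return rng.standard_normal(1) * np.sqrt(g[0])
    c = np.concatenate([g, g[-2:0:-1]])  # circulant first row, length 2n
    lam = np.fft.fft(c).real
    if lam.min() < -1e-10 * lam.max():
        return None
    lam = np.clip(lam, 0.0, None)
    m = 2 * n
    z = rng.standard_normal(m)
    w = np.empty(m, dtype=complex)
    w[0] = np.sqrt(lam[0] / m) * z[0]
    w[n] = np.sqrt(lam[n] / m) * z[1]
    re = z[2 : n + 1]
    im = z[n + 1 : m]
    w[1:n] = np.sqrt(lam[1:n] / (2 * m)) * (re + 1j * im)
    w[n + 1 :] = np.conj(w[1:n][::-1])
    return np.fft.fft(w).real[:n]


def _fgn_durbin_levinson(H: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """Exact O(n²) fGn sample of unit spacing via the Durbin–Levinson
    (Hosking) recursion. Consumes one standard normal per step, in order,
    so it equals L·z with L the lower Cholesky factor of the covariance."""
    g = fgn_autocovariance(H, np.arange(n))
    z = rng.standard_normal(n)
    out = np.empty(n)
    phi = np.zeros(n)
    v = g[0]
    out[0] = np.sqrt(v) * z[0]
    for t in range(1, n):
        if t == 1:
            kappa = g[1] / v
        else:
            kappa = (g[t] - phi[: t - 1] @ g[t - 1 : 0 : -1]) / v
            phi[: t - 1] = phi[: t - 1] - kappa * phi[t - 2 :: -1]
        phi[t - 1] = kappa
        v *= 1.0 - kappa * kappa
        out[t] = phi[:t] @ out[t - 1 :: -1] + np.sqrt(v) * z[t]
    return out


def simulate_fgn(H: float, n: int, dt: float = 1.0, seed=None) -> np.ndarray:
    """Sample ``n`` fGn increments with Hurst exponent H and spacing dt.

    Circulant embedding is tried first; on a non-positive embedding
    spectrum the exact Durbin–Levinson recursion is used instead. The
    cumulative sum is an FBM path with Var[B_H(k·dt)] = (k·dt)^{2H}.
    """
    if not 0.0 < H < 1.0:
        raise ValueError("H must lie in (0, 1)")
    if n < 1:
        raise ValueError("n must be >= 1")
    if dt <= 0:
        raise ValueError("dt must be positive")
    rng = _rng(seed)
    inc = _fgn_davies_harte(H, int(n), rng)
    if inc is None:  # pragma: no cover - fGn embedding is non-negative for H in (0,1)
        logger.info("circulant embedding failed for H=%g, n=%d; using Durbin-Levinson", H, n)
        inc = _fgn_durbin_levinson(H, int(n), rng)
    return inc * dt**H


# --------------------------------------------------------------------------
# duration law and its MLE
# --------------------------------------------------------------------------

def sample_truncated_pareto(exponent: float, x_min: float, x_max: float,
                            n: int, seed=None) -> np.ndarray:
    """i.i.d. draws from density ∝ x^−exponent on [x_min, x_max] (inverse CDF)."""
    if not 0 < x_min < x_max:
        raise ValueError("need 0 < x_min < x_max")
    rng = _rng(seed)
    u = rng.random(int(n))
    a = 1.0 - exponent
    if abs(a) < 1e-12:
        return x_min * (x_max / x_min) ** u
    return (x_min**a + u * (x_max**a - x_min**a)) ** (1.0 / a)


def truncated_pareto_cdf(x, exponent: float, x_min: float, x_max: float) -> np.ndarray:
    """Analytic CDF of the truncated Pareto density ∝ x^−exponent."""
    x = np.clip(np.asarray(x, dtype=float), x_min, x_max)
    a = 1.0 - exponent
    if abs(a) < 1e-12:
        return np.log(x / x_min) / np.log(x_max / x_min)
    return (x**a - x_min**a) / (x_max**a - x_min**a)


def sample_durations(mu_T: float, t_min: float, t_max: float, n: int,
                     seed=None) -> np.ndarray:
    """Trajectory durations from the truncated power law φ(T) ∝ T^−mu_T."""
    if mu_T <= 1:
        raise ValueError("mu_T must exceed 1")
    return sample_truncated_pareto(mu_T, t_min, t_max, n, seed)


def fit_truncated_pareto_mle(samples, x_min: float, x_max: float) -> float:
    """Maximum-likelihood exponent of a truncated Pareto density ∝ x^−μ.

    Maximizes ℓ(μ) = −μ Σ ln x − n ln Z(μ) with
    Z(μ) = (x_max^{1−μ} − x_min^{1−μ})/(1−μ) by bounded scalar search.
    """
    x = np.asarray(samples, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    if np.any(x < x_min * (1 - 1e-9)) or np.any(x > x_max * (1 + 1e-9)):
        raise ValueError("samples outside [x_min, x_max]")
    s = float(np.mean(np.log(x)))

    def negll(mu: float) -> float:
        a = 1.0 - mu
        if abs(a) < 1e-9:
            logz = np.log(np.log(x_max / x_min))
        else:
            logz = np.log(abs((x_max**a - x_min**a) / a))
        return mu * s + logz

    res = minimize_scalar(negll, bounds=(1e-3, 10.0), method="bounded",
                          options={"xatol": 1e-8})
    return float(res.x)


# --------------------------------------------------------------------------
# hFBM ensembles
# --------------------------------------------------------------------------

def _hurst_increments(hurst: HurstProcess, n: int, dt: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Unit-diffusivity fGn increments for a constant or switching H."""
    if hurst.mode == "constant":
        return simulate_fgn(hurst.H, n, dt, rng)
    # two-state: exponential sojourns, segment-wise generation
    segments = []
    state_persistent = rng.random() < 0.5
    remaining = n
    while remaining > 0:
        length = max(1, int(round(rng.exponential(hurst.mean_sojourn) / dt)))
        length = min(length, remaining)
        h = hurst.H_persistent if state_persistent else hurst.H_antipersistent
        segments.append(simulate_fgn(h, length, dt, rng))
        state_persistent = not state_persistent
        remaining -= length
    return np.concatenate(segments)


def simulate_hfbm_ensemble(config: SimConfig) -> Ensemble:
    """Simulate a heterogeneous-FBM ensemble.

    Per trajectory: duration T ~ φ(T) ∝ T^−μ_T (rounded down to whole
    frames), diffusivity D = c·T^−μ_D on the realized duration, and per
    coordinate x(t) = √(2D)·B_H(t) + ξ with i.i.d. Gaussian localization
    noise ξ of std ``noise_sigma`` per frame, so the noiseless 2D MSD is
    4·D·t^{2H}. Bit-identical for a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    law = config.duration_law
    raw_T = sample_durations(law.mu_T, law.t_min, law.t_max, config.n_traj, rng)
    trajectories = []
    diffusivities = []
    for i, T in enumerate(raw_T):
        n_steps = int(np.floor(T / config.dt))
        n_steps = max(n_steps, 1)
        T_real = n_steps * config.dt
        D = config.coupling.c * T_real ** (-config.coupling.mu_D)
        amp = np.sqrt(2.0 * D)
        xs = np.concatenate(
            [[0.0], np.cumsum(amp * _hurst_increments(config.hurst, n_steps, config.dt, rng))]
        )
        ys = np.concatenate(
            [[0.0], np.cumsum(amp * _hurst_increments(config.hurst, n_steps, config.dt, rng))]
        )
        if config.noise_sigma > 0:
            xs = xs + rng.normal(0.0, config.noise_sigma, n_steps + 1)
            ys = ys + rng.normal(0.0, config.noise_sigma, n_steps + 1)
        trajectories.append(
            Trajectory(id=f"sim{i:06d}", dt=config.dt, xs=xs, ys=ys)
        )
        diffusivities.append(D)
    meta = {
        "source": "simulation",
        "config": asdict(config),
        "diffusivities": diffusivities,
    }
    return Ensemble(trajectories, meta=meta)


# --------------------------------------------------------------------------
# superstatistical displacement samples
# --------------------------------------------------------------------------

def sample_superstat_displacements(gamma: float, d_min: float, d_max: float,
                                   lag: float, alpha: float, n: int,
                                   seed=None) -> np.ndarray:
    """Displacements from a Gaussian mixture over power-law diffusivities.

    Each draw takes D ~ density ∝ D^{−1−γ} on [d_min, d_max], then a
    displacement ~ Gaussian(0, 2·D·lag^α). The scaled displacement
    ξ = x/σ_x has an intermediate power-law tail ∝ |ξ|^{−1−2γ} over the
    window set by the diffusivity support (see
    :func:`superstat_tail_window`).
    """
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    if lag <= 0:
        raise ValueError("lag must be positive")
    if not 0 < d_min <= d_max:
        raise ValueError("need 0 < d_min <= d_max")
    rng = _rng(seed)
    if d_min == d_max:
        D = np.full(int(n), float(d_min))
    else:
        D = sample_truncated_pareto(1.0 + gamma, d_min, d_max, n, rng)
    return rng.standard_normal(int(n)) * np.sqrt(2.0 * D * lag**alpha)


def truncated_pareto_mean(exponent: float, x_min: float, x_max: float) -> float:
    """E[X] for density ∝ x^−exponent on [x_min, x_max]."""
    a = 1.0 - exponent
    b = 2.0 - exponent

    def integ(p, lo, hi):
        if abs(p) < 1e-12:
            return np.log(hi / lo)
        return (hi**p - lo**p) / p

    return integ(b, x_min, x_max) / integ(a, x_min, x_max)


def superstat_tail_window(gamma: float, d_min: float, d_max: float,
                          lag: float, alpha: float) -> tuple[float, float]:
    """Analytic |ξ| window where the mixture tail follows |ξ|^{−1−2γ}.

    σ_x² = 2·E[D]·lag^α for the truncated-Pareto diffusivity density, and
    the power law holds where the saddle diffusivity σ_x²ξ²/2 lies inside
    [d_min, d_max], i.e. for sqrt(d_min/E[D]) ≪ |ξ| ≪ sqrt(d_max/E[D]).
    """
    mean_d = truncated_pareto_mean(1.0 + gamma, d_min, d_max)
    return float(np.sqrt(d_min / mean_d)), float(np.sqrt(d_max / mean_d))
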