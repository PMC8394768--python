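"""Velocity autocorrelation functions of finite-difference velocities.

Velocities are defined over an interval τ (an integer multiple of the
frame interval): v(t) = (r(t+τ) − r(t))/τ. The time-averaged VACF of one
trajectory is the time average of the 2D dot product v(t′+t)·v(t′); the
ensemble-time-averaged VACF (E-TVACF) is its per-lag ensemble mean. For
FBM the normalized VACF has the closed form

    C(t)/C(0) = (|t+τ|^{2H} + |t−τ|^{2H} − 2|t|^{2H}) / (2 τ^{2H}),

negative at t = τ for anti-persistent H < 0.5 (value 2^{2H−1} − 1) and
positive for persistent H > 0.5 — the diagnostic signature separating
FBM-like motion from uncorrelated-increment models.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .msd import LagCurve
from .trajectory import Ensemble, Trajectory


@dataclass(frozen=True)
class VacfConfig:
    """Velocity-differencing interval τ (s), maximum lag and normalization."""

    tau: float
    max_lag: float
    normalize: bool = True

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.max_lag < self.tau:
            raise ValueError("max_lag must be at least tau")


def _tau_frames(config: VacfConfig, dt: float) -> int:
    m = config.tau / dt
    if abs(m - round(m)) > 1e-6:
        raise ValueError(f"tau={config.tau} s is not an integer multiple of dt={dt} s")
    return int(round(m))


def _tvacf_values(traj: Trajectory, m: int, kmax: int) -> tuple[np.ndarray, np.ndarray]:
    """Raw VACF values and pair counts at lags 0..kmax frames."""
    dt = traj.dt
    vx = (traj.xs[m:] - traj.xs[:-m]) / (m * dt)
    vy = (traj.ys[m:] - traj.ys[:-m]) / (m * dt)
    vals = np.empty(kmax + 1)
    counts = np.empty(kmax + 1, dtype=int)
    for k in range(kmax + 1):
        if k == 0:
            dots = vx * vx + vy * vy
        else:
            dots = vx[k:] * vx[:-k] + vy[k:] * vy[:-k]
        vals[k] = np.mean(dots)
        counts[k] = dots.size
    return vals, counts


def tvacf(traj: Trajectory, config: VacfConfig) -> LagCurve:
    """Time-averaged VACF of one trajectory at lags 0, dt, …, max_lag.

    Velocities exist only where t+τ is inside the trajectory (no
    extrapolation). If ``normalize``, the curve is divided by its lag-0
    value, the time-averaged squared speed.
    """
    dt = traj.dt
    m = _tau_frames(config, dt)
    kmax = int(np.floor(config.max_lag / dt + 1e-9))
    n_vel = traj.n_points - m
    if n_vel - kmax < 1:
        raise ValueError(
            f"trajectory {traj.id!r} needs at least {m + kmax + 1} points "
            f"for tau={config.tau} s and max_lag={config.max_lag} s; has {traj.n_points}"
        )
    vals, counts = _tvacf_values(traj, m, kmax)
    if config.normalize:
        if vals[0] == 0:
            raise ValueError("cannot normalize: zero time-averaged squared speed")
        vals = vals / vals[0]
    return LagCurve(dt * np.arange(kmax + 1), vals, counts, "TVACF")


def etvacf(ensemble: Ensemble, config: VacfConfig) -> LagCurve:
    """Per-lag ensemble mean of individual TVACFs.

    Each trajectory contributes up to the largest lag it supports;
    trajectories too short to define any velocity pair are skipped and
    counted. Normalization (if requested) is per trajectory, before
    averaging.
    """
    if len(ensemble) == 0:
        raise ValueError("empty ensemble")
    dt = ensemble.dt
    m = _tau_frames(config, dt)
    kmax = int(np.floor(config.max_lag / dt + 1e-9))
    sums = np.zeros(kmax + 1)
    counts = np.zeros(kmax + 1, dtype=int)
    n_skipped = 0
    for traj in ensemble:
        k_traj = min(kmax, traj.n_points - m - 1)
        if k_traj < 0:
            n_skipped += 1
            continue
        vals, _ = _tvacf_values(traj, m, k_traj)
        if config.normalize:
            if vals[0] == 0:
                n_skipped += 1
                continue
            vals = vals / vals[0]
        sums[: k_traj + 1] += vals
        counts[: k_traj + 1] += 1
    if counts[0] == 0:
        raise ValueError(f"no admissible trajectories (skipped {n_skipped})")
    keep = counts > 0
    lags = dt * np.arange(kmax + 1)
    return LagCurve(lags[keep], sums[keep] / counts[keep], counts[keep], "E-TVACF")


def fbm_vacf_reference(H: float, tau: float, lags) -> np.ndarray:
    """Normalized analytic FBM VACF at the requested lag times.

    C(t)/C(0) = (|t+τ|^{2H} + |t−τ|^{2H} − 2|t|^{2H}) / (2 τ^{2H});
    equals 1 at t = 0 and 2^{2H−1} − 1 at t = τ.
    """
    if not 0.0 < H < 1.0:
        raise ValueError("H must lie in (0, 1)")
    t = np.asarray(lags, dtype=float)
    h2 = 2.0 * H
    return (np.abs(t + tau) ** h2 + np.abs(t - tau) ** h2 - 2 * np.abs(t) ** h2) / (
        2.0 * tau**h2
    )
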