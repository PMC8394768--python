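"""Ensemble-, time- and ensemble-time-averaged mean squared displacements.

For 2D paths r(t) = {x(t), y(t)} the estimators are

    EMSD(t)   = ⟨(x(t)−x(0))² + (y(t)−y(0))²⟩ / l²           (ensemble average)
    TMSD(t)   = (1/(n−k)) Σ_i |r_{i+k} − r_i|² / l²          (t = k·dt, overlapping windows)
    E-TMSD(t) = ⟨TMSD_i(t)⟩                                   (ensemble mean of TMSDs)

The EMSD averages only trajectories still alive at lag t (survivor
average); on duration–diffusivity coupled ensembles this is exactly what
produces the spurious long-lag behavior the analysis is after.

Power-law fits use ordinary least squares of log10(value) on
log10(lag/τ); the amplitude follows the 2D convention MSD = 4·D_α·(t/τ)^α
with l = 1 μm and τ = 1 s by default, making D_α dimensionless.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .trajectory import Ensemble, Trajectory, Units

logger = logging.getLogger("endotrack")

#: default intermediate-lag fit window, s
DEFAULT_FIT_RANGE = (0.2, 2.0)


@dataclass
class LagCurve:
    """A function of lag time with per-lag contributing counts.

    ``kind`` is one of EMSD, TMSD, E-TMSD, TVACF, E-TVACF. Values are
    dimensionless (lengths divided by l², velocities by (l/τ)²).
    """

    lags: np.ndarray
    values: np.ndarray
    n_contributing: np.ndarray
    kind: str

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.n_contributing = np.asarray(self.n_contributing, dtype=int)
        if not (len(self.lags) == len(self.values) == len(self.n_contributing)):
            raise ValueError("lags, values, n_contributing must have equal length")
        if len(self.lags) and np.any(np.diff(self.lags) <= 0):
            raise ValueError("lags must be strictly increasing")


@dataclass
class PowerLawFit:
    """Result of a log-log power-law fit MSD = 4·D_α·(t/τ)^α."""

    exponent: float
    coefficient: float
    fit_range: tuple[float, float]
    r_squared: float
    n_lags: int


def _check_loglog(x: np.ndarray, y: np.ndarray):
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 - np.sum(resid**2) / ss_tot if ss_tot > 0 else 1.0
    return float(slope), float(intercept), float(r2)


def emsd(ensemble: Ensemble, max_lag: float | None = None,
         units: Units = Units()) -> LagCurve:
    """Ensemble-averaged MSD from the trajectory origins (survivor average).

    At each lag t = k·dt the mean of |r_i(t) − r_i(0)|² runs over the
    trajectories whose duration is at least t; the contributing count is
    recorded per lag. A ``max_lag`` beyond the longest duration truncates
    the curve with a warning.
    """
    if len(ensemble) == 0:
        raise ValueError("empty ensemble")
    dt = ensemble.dt
    longest = int(max(t.n_points for t in ensemble)) - 1
    if max_lag is None:
        kmax = longest
    else:
        kmax = int(np.floor(max_lag / dt + 1e-9))
        if kmax > longest:
            logger.warning("max_lag %.3g s exceeds longest duration %.3g s; truncating",
                           max_lag, longest * dt)
            kmax = longest
    kmax = max(kmax, 1)
    sums = np.zeros(kmax)
    counts = np.zeros(kmax, dtype=int)
    for traj in ensemble:
        k = min(traj.n_points - 1, kmax)
        dx = traj.xs[1 : k + 1] - traj.xs[0]
        dy = traj.ys[1 : k + 1] - traj.ys[0]
        sums[:k] += dx * dx + dy * dy
        counts[:k] += 1
    keep = counts > 0
    lags = dt * np.arange(1, kmax + 1)
    return LagCurve(lags[keep], sums[keep] / counts[keep] / units.l**2,
                    counts[keep], "EMSD")


def tmsd(traj: Trajectory, max_lag: float | None = None,
         units: Units = Units()) -> LagCurve:
    """Time-averaged MSD of one trajectory over overlapping windows."""
    n = traj.n_points
    dt = traj.dt
    if max_lag is None:
        kmax = n - 1
    else:
        kmax = min(int(np.floor(max_lag / dt + 1e-9)), n - 1)
    kmax = max(kmax, 1)
    vals = np.empty(kmax)
    counts = np.empty(kmax, dtype=int)
    for k in range(1, kmax + 1):
        dx = traj.xs[k:] - traj.xs[:-k]
        dy = traj.ys[k:] - traj.ys[:-k]
        vals[k - 1] = np.mean(dx * dx + dy * dy)
        counts[k - 1] = n - k
    return LagCurve(dt * np.arange(1, kmax + 1), vals / units.l**2, counts, "TMSD")


def etmsd(ensemble: Ensemble, max_lag: float | None = None,
          units: Units = Units()) -> LagCurve:
    """Ensemble mean of individual TMSDs (unweighted per lag).

    Trajectories contribute to a lag only while their duration covers it.
    """
    if len(ensemble) == 0:
        raise ValueError("empty ensemble")
    dt = ensemble.dt
    longest = int(max(t.n_points for t in ensemble)) - 1
    kmax = longest if max_lag is None else min(
        int(np.floor(max_lag / dt + 1e-9)), longest)
    kmax = max(kmax, 1)
    sums = np.zeros(kmax)
    counts = np.zeros(kmax, dtype=int)
    for traj in ensemble:
        curve = tmsd(traj, kmax * dt, units)
        k = len(curve.values)
        sums[:k] += curve.values
        counts[:k] += 1
    keep = counts > 0
    lags = dt * np.arange(1, kmax + 1)
    return LagCurve(lags[keep], sums[keep] / counts[keep], counts[keep], "E-TMSD")


def fit_power_law(curve: LagCurve, fit_range: tuple[float, float] = DEFAULT_FIT_RANGE,
                  units: Units = Units()) -> PowerLawFit:
    """Fit MSD(t) = 4·D_α·(t/τ)^α on the given lag window by log-log OLS.

    Non-positive values inside the window are excluded; at least 3 usable
    lags are required. ``coefficient`` is D_α = 10^intercept / 4.
    """
    lo, hi = fit_range
    mask = (curve.lags >= lo) & (curve.lags <= hi) & (curve.values > 0)
    if int(mask.sum()) < 3:
        raise ValueError(
            f"fewer than 3 positive lags in fit range {fit_range}; have {int(mask.sum())}"
        )
    x = np.log10(curve.lags[mask] / units.tau)
    y = np.log10(curve.values[mask])
    slope, intercept, r2 = _check_loglog(x, y)
    return PowerLawFit(exponent=slope, coefficient=10.0**intercept / 4.0,
                       fit_range=(float(lo), float(hi)), r_squared=r2,
                       n_lags=int(mask.sum()))
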