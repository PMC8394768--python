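"""Sliding-window local MSD analysis: αL(t) and DL(t) along a trajectory.

A window of N frames (N > 10) slides along the path one frame at a time.
Within each window the time-averaged MSD is computed and its first 10 lag
points fitted with 4·DL·(t'/τ)^{αL} by log-log least squares, yielding a
time series of local anomalous exponents αL(t) and local generalized
diffusion coefficients DL(t). Pooled over an ensemble, their
distributions are the heterogeneity fingerprint: exponential for αL,
power-law for DL.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .trajectory import Trajectory, Units

logger = logging.getLogger("endotrack")

#: number of L-TMSD lag points entering every local fit
N_FIT_LAGS = 10

#: default sliding-window length, frames (must exceed 10)
DEFAULT_WINDOW_POINTS = 20


@dataclass
class LocalSeries:
    """Time-indexed αL(t) and DL(t) for one trajectory at one window size."""

    traj_id: str
    times: np.ndarray
    alpha_local: np.ndarray
    d_local: np.ndarray
    window_points: int

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.alpha_local = np.asarray(self.alpha_local, dtype=float)
        self.d_local = np.asarray(self.d_local, dtype=float)
        if not (len(self.times) == len(self.alpha_local) == len(self.d_local)):
            raise ValueError("times, alpha_local, d_local must have equal length")
        if self.window_points <= 10:
            raise ValueError("window_points must exceed 10")

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class DistributionFit:
    """Fitted exponential rate or power-law exponent magnitude."""

    family: str  # 'exponential' | 'power_law'
    parameter: float
    fit_range: tuple[float, float]
    method: str  # 'mle' | 'loglog_ls'
    n: int


def local_series(traj: Trajectory, window_points: int = DEFAULT_WINDOW_POINTS,
                 units: Units = Units()) -> LocalSeries:
    """Compute αL(t) and DL(t) with a sliding window of ``window_points`` frames.

    Every placement where the full window fits inside the trajectory is
    used, advancing one frame at a time; the series is indexed by the
    window-center time. Windows whose L-TMSD has fewer than 3 positive
    points among the first 10 lags are skipped. A too-short trajectory
    yields an empty series (logged).
    """
    if window_points <= 10:
        raise ValueError("window_points must exceed 10 frames")
    n = traj.n_points
    N = int(window_points)
    if n < N + 1:
        logger.info("trajectory %r too short for window of %d frames", traj.id, N)
        return LocalSeries(traj.id, [], [], [], N)

    dt = traj.dt
    n_windows = n - N + 1
    # prefix sums of per-lag squared displacements -> windowed TMSD in O(n)
    M = np.empty((n_windows, N_FIT_LAGS))
    for k in range(1, N_FIT_LAGS + 1):
        dx = traj.xs[k:] - traj.xs[:-k]
        dy = traj.ys[k:] - traj.ys[:-k]
        sq = (dx * dx + dy * dy) / units.l**2
        prefix = np.concatenate([[0.0], np.cumsum(sq)])
        # window starting at s averages sq[s : s + N - k]
        M[:, k - 1] = (prefix[N - k : N - k + n_windows] - prefix[:n_windows]) / (N - k)

    x = np.log10(np.arange(1, N_FIT_LAGS + 1) * dt / units.tau)
    with np.errstate(divide="ignore", invalid="ignore"):
        Y = np.where(M > 0, np.log10(np.where(M > 0, M, 1.0)), np.nan)
    valid = np.isfinite(Y)
    n_valid = valid.sum(axis=1)
    keep = n_valid >= 3

    xb = np.where(valid, x[None, :], np.nan)
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-nan rows are dropped below
        xm = np.nanmean(xb, axis=1)
        ym = np.nanmean(Y, axis=1)
        sxx = np.nansum((xb - xm[:, None]) ** 2, axis=1)
        sxy = np.nansum((xb - xm[:, None]) * (Y - ym[:, None]), axis=1)
    keep &= sxx > 0
    slope = np.where(keep, sxy / np.where(sxx > 0, sxx, 1.0), np.nan)
    intercept = ym - slope * xm

    centers = traj.t0 + (np.arange(n_windows) + (N - 1) / 2.0) * dt
    return LocalSeries(
        traj_id=traj.id,
        times=centers[keep],
        alpha_local=slope[keep],
        d_local=10.0 ** intercept[keep] / 4.0,
        window_points=N,
    )


def pool_local_values(series: Iterable[LocalSeries]) -> tuple[np.ndarray, np.ndarray]:
    """Concatenate αL and DL samples across trajectories and times."""
    series = list(series)
    if not series:
        raise ValueError("no local series to pool")
    alpha = np.concatenate([s.alpha_local for s in series]) if series else np.array([])
    d = np.concatenate([s.d_local for s in series])
    logger.info("pooled %d local values from %d series", len(alpha), len(series))
    return alpha, d


def fit_exponential(samples: Sequence[float], min_samples: int = 100) -> DistributionFit:
    """MLE of an exponential rate: λ = 1 / sample mean (samples must be ≥ 0)."""
    x = np.asarray(samples, dtype=float)
    if x.size < min_samples:
        raise ValueError(f"need at least {min_samples} samples, got {x.size}")
    if np.any(x < 0):
        raise ValueError("exponential fit requires non-negative samples")
    mean = float(np.mean(x))
    if mean <= 0:
        raise ValueError("degenerate all-zero sample")
    return DistributionFit(family="exponential", parameter=1.0 / mean,
                           fit_range=(0.0, float(np.max(x))), method="mle",
                           n=int(x.size))


def fit_power_law_pdf(samples: Sequence[float], x_min: float, x_max: float,
                      bins_per_decade: int = 20,
                      min_samples: int = 100) -> DistributionFit:
    """Power-law exponent magnitude from a log-binned density, by log-log LS.

    Histograms the samples on logarithmically spaced bins (20 per decade
    by default) within [x_min, x_max], normalizes counts by bin width,
    drops empty bins and fits log10 density against log10 bin center,
    weighting each bin by √count (Poisson weighting; unweighted LS is
    biased shallow by sparse far-tail bins).
    """
    x = np.asarray(samples, dtype=float)
    if not 0 < x_min < x_max:
        raise ValueError("need 0 < x_min < x_max")
    inside = x[(x >= x_min) & (x <= x_max)]
    if inside.size < min_samples:
        raise ValueError(f"need at least {min_samples} samples in range, got {inside.size}")
    n_bins = max(int(np.ceil(np.log10(x_max / x_min) * bins_per_decade)), 3)
    edges = np.logspace(np.log10(x_min), np.log10(x_max), n_bins + 1)
    counts, _ = np.histogram(inside, bins=edges)
    widths = np.diff(edges)
    centers = np.sqrt(edges[:-1] * edges[1:])
    dens = counts / (inside.size * widths)
    nz = counts > 0
    if int(nz.sum()) < 3:
        raise ValueError("fewer than 3 non-empty bins; cannot fit")
    slope, _ = np.polyfit(np.log10(centers[nz]), np.log10(dens[nz]), 1,
                          w=np.sqrt(counts[nz]))
    return DistributionFit(family="power_law", parameter=float(-slope),
                           fit_range=(float(x_min), float(x_max)),
                           method="loglog_ls", n=int(inside.size))


def fit_power_law_mle(samples: Sequence[float], x_min: float, x_max: float) -> float:
    """Truncated-Pareto MLE of the density exponent (cross-check estimator)."""
    from .simulate import fit_truncated_pareto_mle

    x = np.asarray(samples, dtype=float)
    inside = x[(x >= x_min) & (x <= x_max)]
    return fit_truncated_pareto_mle(inside, x_min, x_max)


def local_correlation(series: Iterable[LocalSeries]) -> float:
    """Spearman rank correlation between pooled αL and log10 DL values."""
    alpha, d = pool_local_values(series)
    if alpha.size < 10:
        raise ValueError("need at least 10 pooled pairs")
    if np.all(alpha == alpha[0]) or np.all(d == d[0]):
        raise ValueError("correlation undefined for constant input")
    rho, _ = stats.spearmanr(alpha, np.log10(d))
    return float(rho)
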