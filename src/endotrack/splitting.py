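"""Slow/fast classification of trajectories.

Two classifiers:

* maximum excursion — a trajectory is *fast* iff the maximum distance from
  its origin, max R(t) with R(t) = √((x(t)−x(0))² + (y(t)−y(0))²), strictly
  exceeds a threshold ε (default 0.25 μm);
* local-exponent runs — a trajectory is *fast* iff its local anomalous
  exponent series αL(t) is superdiffusive (>1) for at least ``run_length``
  consecutive points (default 5, i.e. "more than 4"). Series shorter than
  the run length are not classifiable and end up discarded.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .local import DEFAULT_WINDOW_POINTS, LocalSeries, local_series
from .trajectory import Ensemble, Trajectory

logger = logging.getLogger("endotrack")


@dataclass(frozen=True)
class SplitConfig:
    """Thresholds for the two classifiers.

    ``epsilon``: excursion threshold, μm. ``run_length``: consecutive
    superdiffusive local-exponent points required for *fast*.
    ``alpha_threshold``: the superdiffusion boundary (1 = linear MSD).
    """

    epsilon: float = 0.25
    run_length: int = 5
    alpha_threshold: float = 1.0

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.run_length < 1:
            raise ValueError("run_length must be >= 1")


def distance_from_origin(traj: Trajectory) -> np.ndarray:
    """R(t_k) = √((x_k − x_0)² + (y_k − y_0)²), μm; R(t_0) = 0."""
    dx = traj.xs - traj.xs[0]
    dy = traj.ys - traj.ys[0]
    return np.sqrt(dx * dx + dy * dy)


def classify_by_max_distance(traj: Trajectory, config: SplitConfig = SplitConfig()) -> str:
    """Label *fast* iff max R(t) strictly exceeds ε, else *slow*.

    The label is also stored on the trajectory.
    """
    label = "fast" if float(np.max(distance_from_origin(traj))) > config.epsilon else "slow"
    traj.label = label
    return label


def classify_by_local_exponent(local: LocalSeries,
                               config: SplitConfig = SplitConfig()) -> str | None:
    """Label from runs of superdiffusive local exponents.

    Returns ``"fast"`` if some run of ≥ ``run_length`` consecutive αL
    values exceeds ``alpha_threshold``, ``"slow"`` otherwise, and ``None``
    when the series is shorter than the run length (not classifiable —
    short trajectories are discarded by :func:`split_ensemble`).
    """
    if len(local) < config.run_length:
        return None
    above = local.alpha_local > config.alpha_threshold
    run = 0
    for flag in above:
        run = run + 1 if flag else 0
        if run >= config.run_length:
            return "fast"
    return "slow"


def split_ensemble(ensemble: Ensemble, method: str = "max_distance",
                   config: SplitConfig = SplitConfig(),
                   window_points: int = DEFAULT_WINDOW_POINTS,
                   ) -> tuple[Ensemble, Ensemble, Ensemble]:
    """Partition an ensemble into (slow, fast, discarded) sub-ensembles.

    ``method`` is ``"max_distance"`` (discarded always empty) or
    ``"local_exponent"`` (trajectories whose local series is too short for
    the run rule are discarded). Sub-ensemble metadata records the method
    and configuration.
    """
    if len(ensemble) == 0:
        raise ValueError("empty ensemble")
    if method not in ("max_distance", "local_exponent"):
        raise ValueError(f"unknown split method {method!r}")
    slow, fast, discarded = [], [], []
    for traj in ensemble:
        if method == "max_distance":
            label = classify_by_max_distance(traj, config)
        else:
            label = classify_by_local_exponent(local_series(traj, window_points), config)
        if label == "fast":
            traj.label = "fast"
            fast.append(traj)
        elif label == "slow":
            traj.label = "slow"
            slow.append(traj)
        else:
            traj.label = None
            discarded.append(traj)
    logger.info("split: %d slow, %d fast, %d discarded (method=%s)",
                len(slow), len(fast), len(discarded), method)

    def sub(trajs, name):
        meta = dict(ensemble.meta)
        meta.update(split_method=method, split_class=name,
                    epsilon_um=config.epsilon, run_length=config.run_length,
                    alpha_threshold=config.alpha_threshold)
        return Ensemble(trajs, meta=meta)

    return sub(slow, "slow"), sub(fast, "fast"), sub(discarded, "discarded")
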