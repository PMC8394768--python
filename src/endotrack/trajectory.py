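"""Domain types and CSV I/O for 2D single-particle tracking trajectories.

A :class:`Trajectory` is one tracked particle's uniformly sampled 2D path
(positions in μm, times in s); an :class:`Ensemble` is a collection of
trajectories sharing a common frame interval, plus provenance metadata.

The on-disk format is a plain CSV with columns
``track_id,frame,t_s,x_um,y_um`` (0-based frames, '.' decimal, UTF-8).
A *dialect* mapping lets users rename columns when reading foreign files.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("endotrack")

#: canonical CSV column names
CSV_COLUMNS = ("track_id", "frame", "t_s", "x_um", "y_um")

#: relative tolerance on frame-interval uniformity
DT_RTOL = 1e-3

#: default frame interval for simulation, s (configurable everywhere)
DEFAULT_DT = 0.05


class FormatError(ValueError):
    """Raised when an input file does not match the trajectory CSV contract."""


@dataclass(frozen=True)
class Units:
    """Nondimensionalization scales: length ``l`` (μm) and time ``tau`` (s).

    MSDs are reported divided by ``l**2`` and lag times by ``tau``, making
    fitted generalized diffusion coefficients dimensionless.
    """

    l: float = 1.0
    tau: float = 1.0

    def __post_init__(self) -> None:
        if not (self.l > 0 and self.tau > 0):
            raise ValueError("unit scales must be positive")


@dataclass
class Trajectory:
    """One particle's 2D path sampled at a uniform frame interval ``dt``.

    Attributes
    ----------
    id : str
        Track identifier, unique within an ensemble.
    dt : float
        Frame interval, s.
    xs, ys : ndarray
        Positions, μm; equal length ``n_points >= 2``.
    t0 : float
        Time of the first frame, s.
    label : str or None
        Optional classification: ``"slow"``, ``"fast"`` or None (unclassified).
    """

    id: str
    dt: float
    xs: np.ndarray
    ys: np.ndarray
    t0: float = 0.0
    label: str | None = None

    def __post_init__(self) -> None:
        self.xs = np.asarray(self.xs, dtype=float)
        self.ys = np.asarray(self.ys, dtype=float)
        if self.xs.ndim != 1 or self.ys.ndim != 1 or len(self.xs) != len(self.ys):
            raise ValueError("xs and ys must be 1-D sequences of equal length")
        if len(self.xs) < 2:
            raise ValueError("a trajectory needs at least 2 points")
        if not (np.all(np.isfinite(self.xs)) and np.all(np.isfinite(self.ys))):
            raise ValueError("positions must be finite")
        if not (self.dt > 0 and np.isfinite(self.dt)):
            raise ValueError("dt must be a positive finite number")

    @property
    def n_points(self) -> int:
        return len(self.xs)

    @property
    def duration(self) -> float:
        """Duration T = (n_points - 1)·dt, s (endpoints inclusive)."""
        return (self.n_points - 1) * self.dt

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.n_points)


@dataclass
class Ensemble:
    """A collection of trajectories sharing one frame interval.

    ``meta`` carries provenance: source file or simulation parameters, the
    seed used, and any filters applied.
    """

    trajectories: list[Trajectory]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [t.id for t in self.trajectories]
        if len(set(ids)) != len(ids):
            raise ValueError("trajectory ids must be unique within an ensemble")
        if self.trajectories:
            dt0 = self.trajectories[0].dt
            for t in self.trajectories:
                if abs(t.dt - dt0) > DT_RTOL * dt0:
                    raise ValueError(
                        f"mixed frame intervals in ensemble: {t.dt} vs {dt0}"
                    )

    def __len__(self) -> int:
        return len(self.trajectories)

    def __iter__(self) -> Iterator[Trajectory]:
        return iter(self.trajectories)

    def __getitem__(self, i: int) -> Trajectory:
        return self.trajectories[i]

    @property
    def dt(self) -> float:
        if not self.trajectories:
            raise ValueError("empty ensemble has no frame interval")
        return self.trajectories[0].dt

    @property
    def durations(self) -> np.ndarray:
        return np.array([t.duration for t in self.trajectories])


def _resolve_columns(df: pd.DataFrame, dialect: Mapping[str, str] | None) -> dict:
    """Map logical names (id, time, frame, x, y) to dataframe columns."""
    defaults = {"id": "track_id", "time": "t_s", "frame": "frame",
                "x": "x_um", "y": "y_um"}
    if dialect:
        defaults.update(dialect)
    found = {k: v for k, v in defaults.items() if v in df.columns}
    missing = [k for k in ("id", "x", "y") if k not in found]
    if missing:
        raise FormatError(
            f"missing required columns for {missing}; available: {list(df.columns)}"
        )
    if "time" not in found and "frame" not in found:
        raise FormatError("need a time column or a frame column")
    return found


def read_trajectories(
    path,
    dialect: Mapping[str, str] | None = None,
    dt: float | None = None,
) -> Ensemble:
    """Read an ensemble from a trajectory CSV.

    One :class:`Trajectory` is built per distinct id, rows sorted by time.
    The frame interval is inferred as the modal consecutive time difference;
    trajectories with non-uniform spacing (beyond ``DT_RTOL``) or fewer than
    2 points are dropped with a logged warning. Mixed frame intervals across
    trajectories are a load error.

    Parameters
    ----------
    dialect : mapping, optional
        Renames logical columns, e.g. ``{"id": "particle", "x": "x [um]"}``.
        Logical keys: ``id``, ``time``, ``frame``, ``x``, ``y``.
    dt : float, optional
        Frame interval, s; required only for frame-indexed files without a
        time column.
    """
    df = pd.read_csv(path)
    cols = _resolve_columns(df, dialect)
    if "time" in cols:
        tvals = df[cols["time"]].to_numpy(dtype=float)
    else:
        if dt is None:
            raise FormatError("frame-indexed file needs an explicit dt")
        tvals = df[cols["frame"]].to_numpy(dtype=float) * dt
    df = df.assign(_t=tvals)

    trajectories: list[Trajectory] = []
    for tid, group in df.groupby(cols["id"], sort=True):
        group = group.sort_values("_t")
        if len(group) < 2:
            logger.warning("trajectory %r has < 2 points; dropped", tid)
            continue
        t = group["_t"].to_numpy()
        diffs = np.diff(t)
        # modal spacing, robust to occasional duplicated rows
        vals, counts = np.unique(np.round(diffs, 9), return_counts=True)
        dt_i = float(vals[np.argmax(counts)])
        if dt_i <= 0:
            logger.warning("trajectory %r has non-increasing times; dropped", tid)
            continue
        if np.any(np.abs(diffs - dt_i) > DT_RTOL * dt_i):
            logger.warning("trajectory %r has non-uniform spacing; dropped", tid)
            continue
        trajectories.append(
            Trajectory(
                id=str(tid),
                dt=dt_i,
                xs=group[cols["x"]].to_numpy(dtype=float),
                ys=group[cols["y"]].to_numpy(dtype=float),
                t0=float(t[0]),
            )
        )
    if trajectories:
        dts = np.array([t.dt for t in trajectories])
        dt0 = dts[0]
        if np.any(np.abs(dts - dt0) > DT_RTOL * dt0):
            raise FormatError("trajectories have mixed frame intervals")
    return Ensemble(trajectories, meta={"source": str(path)})


def write_trajectories(ensemble: Ensemble, path) -> None:
    """Write an ensemble to the canonical trajectory CSV.

    Rows are ordered by id then frame; frames are 0-based. Writing an empty
    ensemble is an error.
    """
    if len(ensemble) == 0:
        raise ValueError("refusing to write an empty ensemble")
    frames = []
    for traj in sorted(ensemble, key=lambda t: t.id):
        k = np.arange(traj.n_points)
        frames.append(
            pd.DataFrame(
                {
                    "track_id": traj.id,
                    "frame": k,
                    "t_s": traj.t0 + traj.dt * k,
                    "x_um": traj.xs,
                    "y_um": traj.ys,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def filter_by_duration(ensemble: Ensemble, t_min: float) -> Ensemble:
    """Keep trajectories with duration strictly greater than ``t_min`` (s)."""
    if t_min < 0:
        raise ValueError("t_min must be >= 0")
    kept = [t for t in ensemble if t.duration > t_min]
    meta = dict(ensemble.meta)
    meta["min_duration_s"] = max(float(t_min), float(meta.get("min_duration_s", 0.0)))
    return Ensemble(kept, meta=meta)
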