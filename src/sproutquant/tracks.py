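"""Trajectory statistics for tracked cells and sprout tips.

Positions are in micrometres on a uniform time grid (hours). The two core
estimators are the mean displacement over a lag, d(tau) = <|x_i(t+tau) - x_i(t)|>
averaged over all cells i and times t, and the time-dependent mean speed
v(t) = <|x_i(t+tau0) - x_i(t)|/tau0> averaged over the cells present at both
endpoints (tau0 = 1 h by convention). Error stripes are SEM over the pair/cell
population. Gaps in a track simply exclude the affected pairs; nothing is
imputed or smoothed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TrackSet",
    "LagCurve",
    "SpeedCurve",
    "mean_displacement",
    "mean_speed_timeseries",
    "pool_curves",
    "tip_speed_curve",
]

_GRID_TOL = 1e-9


@dataclass
class TrackSet:
    """Per-track position time series on a shared uniform time grid.

    Parameters
    ----------
    times : (T,) array
        Sampling instants in hours, strictly increasing and uniformly spaced.
    positions : (N, T, 2) array
        x/y coordinates in micrometres; NaN rows mark absent observations
        (cell lost, or entered the field late).
    track_ids : sequence, optional
        One identifier per track; defaults to 0..N-1.
    """

    times: np.ndarray
    positions: np.ndarray
    track_ids: list = field(default_factory=list)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[2] != 2:
            raise ValueError("positions must have shape (n_tracks, n_times, 2)")
        if self.positions.shape[1] != self.times.size:
            raise ValueError("positions and times disagree on the number of frames")
        if self.times.size < 2:
            raise ValueError("need at least two time points")
        steps = np.diff(self.times)
        if np.any(steps <= 0):
            raise ValueError("times must be strictly increasing")
        if np.ptp(steps) > _GRID_TOL * max(1.0, abs(self.times[-1])):
            raise ValueError("times must be uniformly spaced")
        finite_xy = np.isfinite(self.positions)
        if np.any(finite_xy[..., 0] != finite_xy[..., 1]):
            raise ValueError("a position must be either fully present or fully absent")
        if not self.track_ids:
            self.track_ids = list(range(self.positions.shape[0]))

    @property
    def n_tracks(self) -> int:
        return self.positions.shape[0]

    @property
    def dt(self) -> float:
        """Sampling interval in hours."""
        return float(np.mean(np.diff(self.times)))

    @property
    def present(self) -> np.ndarray:
        """(N, T) boolean mask of observed positions."""
        return np.isfinite(self.positions[..., 0])

    def to_frame(self) -> pd.DataFrame:
        """Long-format table, one row per observation."""
        rows = []
        for i, tid in enumerate(self.track_ids):
            ok = self.present[i]
            rows.append(
                pd.DataFrame(
                    {
                        "track_id": tid,
                        "frame": np.nonzero(ok)[0],
                        "t_hours": self.times[ok],
                        "x_um": self.positions[i, ok, 0],
                        "y_um": self.positions[i, ok, 1],
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TrackSet":
        """Build from a long-format table with columns track_id, t_hours, x_um, y_um."""
        required = {"track_id", "t_hours", "x_um", "y_um"}
        missing = sorted(required - set(df.columns))
        if missing:
            raise ValueError(f"track table is missing columns: {', '.join(missing)}")
        times = np.unique(df["t_hours"].to_numpy(dtype=float))
        if times.size < 2:
            raise ValueError("need at least two time points")
        steps = np.diff(times)
        if np.ptp(steps) > _GRID_TOL * max(1.0, abs(times[-1])):
            raise ValueError("frame intervals are not uniform")
        idx = {t: k for k, t in enumerate(times)}
        ids = list(pd.unique(df["track_id"]))
        pos = np.full((len(ids), times.size, 2), np.nan)
        for i, tid in enumerate(ids):
            sub = df[df["track_id"] == tid]
            for t, x, y in zip(sub["t_hours"], sub["x_um"], sub["y_um"]):
                pos[i, idx[float(t)]] = (x, y)
        return cls(times=times, positions=pos, track_ids=ids)


@dataclass
class LagCurve:
    """Mean displacement (µm) vs. lag (h), with SEM and pair counts."""

    lags: np.ndarray
    mean: np.ndarray
    sem: np.ndarray
    n: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"lag_hours": self.lags, "mean": self.mean, "sem": self.sem, "n": self.n}
        )

    @property
    def grid(self) -> np.ndarray:
        return self.lags


@dataclass
class SpeedCurve:
    """Mean speed (µm/h) vs. culture time (h), with SEM and cell counts."""

    times: np.ndarray
    mean: np.ndarray
    sem: np.ndarray
    n: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"t_hours": self.times, "mean": self.mean, "sem": self.sem, "n": self.n}
        )

    @property
    def grid(self) -> np.ndarray:
        return self.times


def _sem(values: np.ndarray) -> float:
    n = values.size
    if n < 2:
        return 0.0
    return float(np.std(values, ddof=1) / np.sqrt(n))


def _lag_steps(lag: float, dt: float) -> int:
    k = lag / dt
    k_round = int(round(k))
    if k_round < 1 or abs(k - k_round) > 1e-6:
        raise ValueError(f"lag {lag} h is not a positive multiple of dt = {dt} h")
    return k_round


def mean_displacement(tracks: TrackSet, lags, rms: bool = False) -> LagCurve:
    """Average displacement over each requested lag.

    For lag tau, averages |x_i(t+tau) - x_i(t)| over every (track, time) pair
    with both endpoints observed.  With ``rms=True`` the root-mean-square
    displacement sqrt(<|dx|^2>) is returned instead of the plain mean.
    Lags with no valid pair are dropped from the curve with a warning.
    """
    if tracks.n_tracks == 0:
        raise ValueError("no tracks")
    lags = np.atleast_1d(np.asarray(lags, dtype=float))
    dt = tracks.dt
    out_lag, out_mean, out_sem, out_n = [], [], [], []
    for lag in lags:
        k = _lag_steps(lag, dt)
        if k >= tracks.times.size:
            warnings.warn(f"lag {lag} h exceeds the recording span; skipped")
            continue
        delta = tracks.positions[:, k:, :] - tracks.positions[:, :-k, :]
        mag = np.hypot(delta[..., 0], delta[..., 1])
        valid = mag[np.isfinite(mag)]
        if valid.size == 0:
            warnings.warn(f"lag {lag} h has no valid displacement pairs; skipped")
            continue
        if rms:
            m = float(np.sqrt(np.mean(valid**2)))
            s = _sem(valid**2)
            s = float(s / (2 * m)) if m > 0 else 0.0  # delta-method SEM of the RMS
        else:
            m = float(np.mean(valid))
            s = _sem(valid)
        out_lag.append(lag)
        out_mean.append(m)
        out_sem.append(s)
        out_n.append(valid.size)
    return LagCurve(
        lags=np.array(out_lag),
        mean=np.array(out_mean),
        sem=np.array(out_sem),
        n=np.array(out_n, dtype=int),
    )


def mean_speed_timeseries(tracks: TrackSet, tau0: float = 1.0) -> SpeedCurve:
    """Time-dependent mean speed with a fixed time lag.

    For each time t, averages |x_i(t+tau0) - x_i(t)| / tau0 over the cells
    observed at both t and t + tau0.  Times with no eligible cell are absent
    from the curve.
    """
    if tracks.n_tracks == 0:
        raise ValueError("no tracks")
    dt = tracks.dt
    k = _lag_steps(tau0, dt)
    if k >= tracks.times.size:
        raise ValueError(
            f"tau0 = {tau0} h exceeds the recording span of "
            f"{tracks.times[-1] - tracks.times[0]} h"
        )
    delta = tracks.positions[:, k:, :] - tracks.positions[:, :-k, :]
    speeds = np.hypot(delta[..., 0], delta[..., 1]) / tau0  # (N, T-k)
    out_t, out_mean, out_sem, out_n = [], [], [], []
    for j in range(speeds.shape[1]):
        col = speeds[:, j]
        col = col[np.isfinite(col)]
        if col.size == 0:
            continue
        out_t.append(tracks.times[j])
        out_mean.append(float(np.mean(col)))
        out_sem.append(_sem(col))
        out_n.append(col.size)
    return SpeedCurve(
        times=np.array(out_t),
        mean=np.array(out_mean),
        sem=np.array(out_sem),
        n=np.array(out_n, dtype=int),
    )


def pool_curves(curves):
    """Pool curves from independent experiments on an identical grid.

    The underlying pair/cell populations are merged before averaging: the
    result is the pooled mean and pooled SEM one would obtain from a single
    pass over the concatenated data, not a mean of per-experiment means.
    """
    if not curves:
        raise ValueError("no curves to pool")
    first = curves[0]
    grid = first.grid
    for c in curves[1:]:
        if c.grid.size != grid.size or not np.allclose(c.grid, grid, atol=_GRID_TOL):
            bad = (
                np.setxor1d(np.round(c.grid, 9), np.round(grid, 9))
                if c.grid.size != grid.size
                else grid[~np.isclose(c.grid, grid, atol=_GRID_TOL)]
            )
            raise ValueError(f"curve grids do not match at: {bad}")
    n = np.sum([c.n for c in curves], axis=0)
    mean = np.sum([c.n * c.mean for c in curves], axis=0) / n
    # reconstruct each curve's sum of squares from (mean, sem, n):
    # s^2 = sem^2 * n (sample variance, ddof=1), SS = (n-1) s^2 + n m^2
    ss = np.sum(
        [(c.n - 1) * (c.sem**2 * c.n) + c.n * c.mean**2 for c in curves], axis=0
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        var = np.where(n > 1, (ss - n * mean**2) / np.maximum(n - 1, 1), 0.0)
        sem = np.sqrt(np.maximum(var, 0.0) / n)
    kwargs = dict(mean=mean, sem=sem, n=n.astype(int))
    if isinstance(first, LagCurve):
        return LagCurve(lags=grid.copy(), **kwargs)
    return SpeedCurve(times=grid.copy(), **kwargs)


def tip_speed_curve(tip_tracks: TrackSet, tau0: float = 1.0) -> SpeedCurve:
    """Mean sprout-tip speed vs. culture time (hourly frames, 1 h lag)."""
    return mean_speed_timeseries(tip_tracks, tau0=tau0)
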