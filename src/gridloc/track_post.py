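"""Track post-processing: coordinate smoothing and outlier-speed filtering.

The third smoothing axis of the workflow applies the signal smoothers to
the estimated coordinate series — x(t) and y(t) independently, timestamps
untouched.  Speed filtering removes fixes that terminate a step faster
than a threshold (the 95% quantile of the track set's step speeds, or a
hard biological cap such as 25 m/s for hummingbirds), iterating until no
step exceeds it.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .smoothing import smooth_series

__all__ = ["smooth_track", "step_speeds", "speed_threshold", "filter_speeds"]

DEFAULT_SPEED_QUANTILE = 0.95
HUMMINGBIRD_SPEED_CAP = 25.0  # m/s


def smooth_track(track: pd.DataFrame, method: str, step: float | None = None) -> pd.DataFrame:
    """Smooth x(t), y(t) of a track ('none' | 'spline' | 'kalman').

    ``track`` needs columns ``t, x, y``; short series fall through
    unchanged per the smoothing module's thresholds.  The kalman grid step
    defaults to the median fix interval.
    """
    out = track.copy()
    if method == "none" or len(track) == 0:
        return out
    t = track["t"].to_numpy(dtype=float)
    if step is None and method == "kalman":
        step = float(np.median(np.diff(t))) if len(t) > 1 else 1.0
    for col in ("x", "y"):
        vals, _ = smooth_series(t, track[col].to_numpy(dtype=float), method, step=step, collision="first")
        out[col] = vals
    return out


def step_speeds(track: pd.DataFrame) -> np.ndarray:
    """Planar speed (m/s) of each consecutive-fix step; length len(track)-1."""
    dt = np.diff(track["t"].to_numpy(dtype=float))
    dx = np.diff(track["x"].to_numpy(dtype=float))
    dy = np.diff(track["y"].to_numpy(dtype=float))
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(dt > 0, np.hypot(dx, dy) / dt, np.inf)


def speed_threshold(tracks, quantile: float = DEFAULT_SPEED_QUANTILE) -> float:
    """Quantile of the pooled step-speed distribution over a track set."""
    speeds = np.concatenate([step_speeds(t) for t in tracks if len(t) >= 2])
    speeds = speeds[np.isfinite(speeds)]
    if speeds.size == 0:
        return np.inf
    return float(np.quantile(speeds, quantile))


def filter_speeds(
    track: pd.DataFrame,
    quantile: float = DEFAULT_SPEED_QUANTILE,
    hard_cap: float | None = None,
    track_set=None,
):
    """Iteratively drop fixes terminating over-threshold steps.

    The threshold is ``hard_cap`` when given, otherwise the ``quantile`` of
    the step speeds of ``track_set`` (defaulting to this track alone).
    Each pass removes the later fix of every offending step, then speeds
    are recomputed; returns ``(filtered_track, n_removed)``.
    """
    if len(track) < 3:
        raise ValueError("speed filtering needs >= 3 fixes")
    thr = hard_cap if hard_cap is not None else speed_threshold(track_set or [track], quantile)
    out = track.reset_index(drop=True)
    n_removed = 0
    while len(out) >= 2:
        speeds = step_speeds(out)
        bad = np.flatnonzero(speeds > thr)
        if bad.size == 0:
            break
        # one teleported fix inflates both adjacent steps: drop only the
        # first offending step's end fix, then re-measure
        out = out.drop(index=int(bad[0]) + 1).reset_index(drop=True)
        n_removed += 1
    if len(out) == 0:
        raise ValueError("speed filter removed every fix")
    return out, n_removed
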