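"""Error evaluation: ground-truth comparison, random-track nulls, covariates.

Error is the planar Euclidean distance in metres between an estimated and a
known location.  Beyond the per-workflow repeated-measures table (built by
:mod:`gridloc.workflow`), this module provides

* a random-track null: step-resampling surrogate tracks that preserve each
  trial's duration, fix count and step-speed distribution, compared to the
  observed errors with a paired Wilcoxon signed-rank test over trials;
* spatial covariates of error (terrain ruggedness, flight height, dominant
  vegetation class, grid membership and signed distance to the grid edge)
  for downstream mixed-model analysis, which is deliberately left to
  external tools.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import wilcoxon
from shapely.geometry import Point

from .io import NodeGrid, WorkflowConfig
from .rasters import Raster, VegClassRaster

__all__ = [
    "compute_error",
    "enumerate_workflows",
    "surrogate_track",
    "random_track_null",
    "NullComparison",
    "spatial_covariates",
    "covariate_table",
]

MIN_NULL_FIXES = 10
DEFAULT_N_SIMS = 99


def compute_error(estimates: pd.DataFrame, track: pd.DataFrame) -> pd.DataFrame:
    """Attach ``error_m`` to a location-estimate table for one trial."""
    idx = estimates["reloc_idx"].to_numpy()
    tx = track["x"].to_numpy()[idx]
    ty = track["y"].to_numpy()[idx]
    out = estimates.copy()
    out["error_m"] = np.hypot(out["x_hat"].to_numpy() - tx, out["y_hat"].to_numpy() - ty)
    return out


def enumerate_workflows() -> list[WorkflowConfig]:
    """All 216 members of the workflow factorial."""
    return WorkflowConfig.factorial()


def surrogate_track(
    track: pd.DataFrame,
    rng: np.random.Generator,
    bounds: tuple[float, float, float, float],
    pad: float = 500.0,
) -> np.ndarray:
    """One step-resampling surrogate of a trial track.

    Step lengths and turning angles are resampled with replacement
    (independently), the walk starts at the trial's centroid with a random
    heading, and positions are clipped to the padded grid bounding box.
    Returns an (n_fix, 2) array time-matched to the input fixes.
    """
    x = track["x"].to_numpy(dtype=float)
    y = track["y"].to_numpy(dtype=float)
    dx, dy = np.diff(x), np.diff(y)
    lengths = np.hypot(dx, dy)
    headings = np.arctan2(dy, dx)
    turns = np.diff(headings)
    turns = np.arctan2(np.sin(turns), np.cos(turns))  # wrap to (-pi, pi]
    n_steps = len(lengths)
    L = rng.choice(lengths, size=n_steps, replace=True)
    if len(turns):
        T = rng.choice(turns, size=n_steps, replace=True)
    else:
        T = np.zeros(n_steps)
    T[0] = rng.uniform(-np.pi, np.pi)
    head = np.cumsum(T)
    start = np.array([x.mean(), y.mean()])
    pos = start + np.concatenate(
        [[[0.0, 0.0]], np.cumsum(np.column_stack([L * np.cos(head), L * np.sin(head)]), axis=0)]
    )
    xmin, ymin, xmax, ymax = bounds
    pos[:, 0] = np.clip(pos[:, 0], xmin - pad, xmax + pad)
    pos[:, 1] = np.clip(pos[:, 1], ymin - pad, ymax + pad)
    return pos


@dataclass
class NullComparison:
    """Observed-vs-random error comparison across trials."""

    per_trial: pd.DataFrame  # trial_id, n_fixes, observed_median, surrogate_median
    statistic: float
    pvalue: float
    n_sims: int
    degenerate: bool = False
    excluded_trials: list[str] | None = None


def random_track_null(
    tracks: dict[str, pd.DataFrame],
    observed_errors: pd.DataFrame,
    nodes: NodeGrid,
    n_sims: int = DEFAULT_N_SIMS,
    seed: int = 0,
) -> NullComparison:
    """Compare observed localisation error to a random-movement null.

    For each trial with >= 10 fixes, ``n_sims`` surrogate tracks are drawn
    and the 'random error' of relocation i is its distance to the
    time-matched surrogate point.  The paired signed-rank test contrasts
    each trial's observed median error with the mean of its surrogate
    medians.
    """
    rng = np.random.default_rng(seed)
    bounds = nodes.hull.bounds
    obs_median = observed_errors.groupby("trial_id")["error_m"].median()
    rows, excluded = [], []
    for trial_id, track in sorted(tracks.items()):
        if len(track) < MIN_NULL_FIXES:
            excluded.append(trial_id)
            continue
        if trial_id not in obs_median.index:
            excluded.append(trial_id)
            continue
        x = track["x"].to_numpy()
        y = track["y"].to_numpy()
        med = np.empty(n_sims)
        for s in range(n_sims):
            pos = surrogate_track(track, rng, bounds)
            med[s] = np.median(np.hypot(pos[:, 0] - x, pos[:, 1] - y))
        rows.append((trial_id, len(track), float(obs_median[trial_id]), float(med.mean())))
    per_trial = pd.DataFrame(
        rows, columns=["trial_id", "n_fixes", "observed_median", "surrogate_median"]
    )
    diffs = per_trial["observed_median"] - per_trial["surrogate_median"]
    if len(per_trial) < 2 or np.allclose(diffs, 0.0):
        return NullComparison(per_trial, float("nan"), float("nan"), n_sims, True, excluded)
    stat, p = wilcoxon(per_trial["observed_median"], per_trial["surrogate_median"])
    return NullComparison(per_trial, float(stat), float(p), n_sims, False, excluded)


def spatial_covariates(
    x: float,
    y: float,
    elevation_gps: float,
    dem: Raster,
    veg: VegClassRaster | None,
    nodes: NodeGrid,
    radius: float = 100.0,
) -> dict:
    """Landscape covariates of one relocation.

    ruggedness = sd of DEM cell centres within the buffer; flight height =
    GPS elevation minus bilinear ground elevation; dominant vegetation by
    occupied area in the buffer; grid membership against the convex hull of
    node positions, with the signed distance to its boundary (negative
    outside).
    """
    ground = dem.value_bilinear(x, y)
    hull = nodes.hull
    point = Point(x, y)
    inside = bool(hull.contains(point) or hull.touches(point))
    edge_dist = float(point.distance(hull.exterior))
    return {
        "ruggedness": dem.ruggedness(x, y, radius),
        "flight_height": float(elevation_gps) - ground if np.isfinite(ground) else float("nan"),
        "veg_class": veg.dominant_class(x, y, radius) if veg is not None else None,
        "inside_grid": inside,
        "dist_to_edge": edge_dist if inside else -edge_dist,
    }


def covariate_table(
    tracks: dict[str, pd.DataFrame],
    dem: Raster,
    veg: VegClassRaster | None,
    nodes: NodeGrid,
    radius: float = 100.0,
) -> pd.DataFrame:
    """Covariates for every relocation of every trial."""
    rows = []
    for trial_id, track in sorted(tracks.items()):
        for i, r in track.reset_index(drop=True).iterrows():
            cov = spatial_covariates(r["x"], r["y"], r["elevation_gps"], dem, veg, nodes, radius)
            rows.append({"trial_id": trial_id, "reloc_idx": i, **cov})
    return pd.DataFrame(rows)
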