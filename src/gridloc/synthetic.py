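"""Synthetic ARTS scenes with a known ground-truth decay law.

Generates everything the pipeline ingests — a receiver lattice, a DEM, a
vegetation map, calibration-trial tracks and raw RSS detections — so every
stage is testable without field data.  Defaults emulate the study system
the package targets: a 46-node grid at 150 m spacing (a 7×7 lattice with
three receivers dropped), solar tags emitting every 2 s (battery tags every
60 s), drone trials at ~3.57 m/s roughly 39 m above ground, and walking
trials at 0.44 / 0.31 m/s at 1 m / ground level.

RSS at distance d is a·exp(−S·d) + K plus a fixed per-node offset, a
vegetation penalty for the class at the emitter, and AR(1) noise per node;
reads below the detection floor are censored (never emitted).  All
randomness flows from one scene seed through named substreams.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import box

from .io import NodeGrid, TagSpec, write_detections, write_track_gpx
from .projection import UTMProjection
from .rasters import Raster, VegClassRaster, rasterize_vegetation, write_veg_geojson

__all__ = ["SceneConfig", "TrialSpec", "Scene", "make_grid", "make_dem", "make_vegetation", "simulate_track", "emit_rss", "make_scene", "write_scene", "default_trials"]

#: trial-mode kinematics: (duration s, mean speed m/s, speed sd m/s, height agl m)
MODE_DEFAULTS = {
    "high_flight": (389.0, 3.57, 1.78, 39.0),
    "low_flight": (261.0, 0.44, 0.12, 1.0),
    "ground": (371.0, 0.31, 0.06, 0.0),
}

EPOCH = pd.Timestamp("2023-01-15T12:00:00Z")


@dataclass(frozen=True)
class SceneConfig:
    """Ground-truth parameters of a synthetic scene."""

    n_rows: int = 7
    n_cols: int = 7
    spacing: float = 150.0
    drop_nodes: tuple[str, ...] = ("n0_0", "n3_4", "n6_6")  # 49 -> 46 receivers
    a: float = 68.0
    S: float = 0.01
    K: float = -105.0
    node_offset_sd: float = 3.0
    noise_sd: float = 2.0
    noise_ar1: float = 0.6
    veg_attenuation: tuple[tuple[str, float], ...] = (
        ("grassland", 0.0),
        ("paramo", 2.0),
        ("dense", 10.0),
        ("builtup", 5.0),
    )
    detection_floor: float = -115.0
    ref_lon: float = -73.7733
    ref_lat: float = 4.5251
    base_elevation: float = 3250.0
    seed: int = 0

    def __post_init__(self):
        if self.spacing <= 0 or self.noise_sd < 0:
            raise ValueError("spacing must be > 0 and noise_sd >= 0")
        if not 0.0 <= self.noise_ar1 < 1.0:
            raise ValueError("noise_ar1 must be in [0, 1)")
        # a floor at or above K + a censors everything; allowed (total censoring)

    @property
    def veg_penalty(self) -> dict[str, float]:
        return dict(self.veg_attenuation)


@dataclass(frozen=True)
class TrialSpec:
    """One calibration trial: movement mode, duration, tag schedule."""

    trial_id: str
    mode: str = "ground"
    duration: float | None = None
    speed_mean: float | None = None
    speed_sd: float | None = None
    fix_interval: float = 2.0
    tag: TagSpec = field(default_factory=lambda: TagSpec("tag01", "life"))
    t_offset: float = 0.0  # trial start relative to the scene epoch, s

    def __post_init__(self):
        if self.mode not in MODE_DEFAULTS:
            raise ValueError(f"unknown trial mode {self.mode!r}")
        dur, sp, sd, _ = MODE_DEFAULTS[self.mode]
        if self.duration is None:
            object.__setattr__(self, "duration", dur)
        if self.speed_mean is None:
            object.__setattr__(self, "speed_mean", sp)
        if self.speed_sd is None:
            object.__setattr__(self, "speed_sd", sd)
        if self.duration <= 0 or self.speed_mean <= 0:
            raise ValueError("duration and speed_mean must be > 0")


def default_trials(n_high: int = 2, n_low: int = 3, n_ground: int = 3) -> list[TrialSpec]:
    """A desk-scale trial roster mixing the three movement modes.

    Tags cycle over three ids so per-tag calibration has groups to fit.
    """
    tags = [TagSpec("tag01", "life"), TagSpec("tag02", "life"), TagSpec("tag03", "life")]
    specs = []
    i = 0
    for mode, n in (("high_flight", n_high), ("low_flight", n_low), ("ground", n_ground)):
        for j in range(n):
            specs.append(
                TrialSpec(
                    trial_id=f"{mode[:2]}{j:02d}",
                    mode=mode,
                    tag=tags[i % len(tags)],
                    t_offset=3600.0 * i,
                )
            )
            i += 1
    return specs


def make_grid(config: SceneConfig, proj: UTMProjection | None = None) -> NodeGrid:
    """Rectangular receiver lattice centred on the reference point."""
    if config.n_rows * config.n_cols < 4:
        raise ValueError("grid needs at least 4 nodes")
    proj = proj or UTMProjection.for_point(config.ref_lon, config.ref_lat)
    cx, cy = proj.forward(config.ref_lon, config.ref_lat)
    ids, xs, ys = [], [], []
    for r in range(config.n_rows):
        for c in range(config.n_cols):
            ids.append(f"n{r}_{c}")
            xs.append(cx + (c - (config.n_cols - 1) / 2.0) * config.spacing)
            ys.append(cy + (r - (config.n_rows - 1) / 2.0) * config.spacing)
    grid = NodeGrid.from_xy(ids, xs, ys, proj)
    if config.drop_nodes:
        present = [n for n in config.drop_nodes if n in ids]
        grid = grid.drop(present)
    return grid


def make_dem(config: SceneConfig, nodes: NodeGrid, rng: np.random.Generator, res: float = 30.0, margin: float = 600.0) -> Raster:
    """Smooth valley-like DEM over the grid plus a margin.

    A low-order random cosine surface (~60 m relief) over a constant base —
    enough structure for ruggedness and flight-height covariates.
    """
    xmin, ymin, xmax, ymax = nodes.hull.bounds
    x0, y1 = xmin - margin, ymax + margin
    nx = int(np.ceil((xmax + margin - x0) / res))
    ny = int(np.ceil((y1 - (ymin - margin)) / res))
    xs = x0 + res * (np.arange(nx) + 0.5)
    ys = y1 - res * (np.arange(ny) + 0.5)
    gx, gy = np.meshgrid(xs, ys)
    lx, ly = (xmax - xmin) + 2 * margin, (ymax - ymin) + 2 * margin
    z = np.full(gx.shape, config.base_elevation)
    for kx in range(1, 4):
        for ky in range(1, 4):
            amp = rng.normal(0.0, 20.0 / (kx + ky))
            phx, phy = rng.uniform(0, 2 * np.pi, size=2)
            z += amp * np.cos(2 * np.pi * kx * (gx - x0) / lx + phx) * np.cos(
                2 * np.pi * ky * (gy - ys[-1]) / ly + phy
            )
    return Raster(z, x0, y1, res)


def make_vegetation(config: SceneConfig, nodes: NodeGrid, res: float = 1.0) -> tuple[list, VegClassRaster]:
    """Block-pattern vegetation map: grassland matrix with paramo, dense
    forest/bamboo and a small built-up patch."""
    xmin, ymin, xmax, ymax = nodes.hull.bounds
    pad = 300.0
    w, h = xmax - xmin, ymax - ymin
    polys_xy = [
        ("paramo", box(xmin - pad, ymin - pad, xmin + 0.45 * w, ymax + pad)),
        ("dense", box(xmin + 0.55 * w, ymin + 0.5 * h, xmax + pad, ymax + pad)),
        ("builtup", box(xmin + 0.40 * w, ymin - pad, xmin + 0.55 * w, ymin + 0.15 * h)),
    ]
    proj = nodes.proj
    polys = []
    for cls, geom in polys_xy:
        lonlat = []
        for x, y in geom.exterior.coords:
            lon, lat = proj.inverse(x, y)
            lonlat.append((float(lon), float(lat)))
        from shapely.geometry import Polygon

        polys.append((cls, Polygon(lonlat)))
    bounds = (xmin - pad, ymin - pad, xmax + pad, ymax + pad)
    veg = rasterize_vegetation(polys, proj, bounds, res=res)
    return polys, veg


def simulate_track(spec: TrialSpec, nodes: NodeGrid, dem: Raster, rng: np.random.Generator) -> pd.DataFrame:
    """Correlated random walk inside the grid bounding box.

    Lognormal step speeds matched to the trial's mean/sd, wrapped-normal
    turning angles, reflective boundaries; elevation is the DEM plus the
    mode's height above ground (drone altitude drawn once per trial,
    N(39, 16) m clipped to [10, 80]).
    """
    if spec.duration < 10 * spec.fix_interval:
        raise ValueError("trial too short: need >= 10 fix intervals")
    xmin, ymin, xmax, ymax = nodes.hull.bounds
    n_fix = int(np.floor(spec.duration / spec.fix_interval)) + 1
    m, s = spec.speed_mean, max(spec.speed_sd, 1e-6)
    sigma2 = np.log(1.0 + (s / m) ** 2)
    mu = np.log(m) - sigma2 / 2.0
    x = rng.uniform(xmin + 0.25 * (xmax - xmin), xmax - 0.25 * (xmax - xmin))
    y = rng.uniform(ymin + 0.25 * (ymax - ymin), ymax - 0.25 * (ymax - ymin))
    heading = rng.uniform(0, 2 * np.pi)
    xs, ys = [x], [y]
    for _ in range(n_fix - 1):
        heading += rng.normal(0.0, 0.6)
        step = rng.lognormal(mu, np.sqrt(sigma2)) * spec.fix_interval
        x += step * np.cos(heading)
        y += step * np.sin(heading)
        # reflective boundary
        if x < xmin:
            x = 2 * xmin - x
            heading = np.pi - heading
        elif x > xmax:
            x = 2 * xmax - x
            heading = np.pi - heading
        if y < ymin:
            y = 2 * ymin - y
            heading = -heading
        elif y > ymax:
            y = 2 * ymax - y
            heading = -heading
        xs.append(x)
        ys.append(y)
    height = MODE_DEFAULTS[spec.mode][3]
    if spec.mode == "high_flight":
        height = float(np.clip(rng.normal(39.0, 16.0), 10.0, 80.0))
    t = spec.t_offset + spec.fix_interval * np.arange(n_fix)
    xs, ys = np.array(xs), np.array(ys)
    elev = np.array([dem.value_bilinear(px, py) for px, py in zip(xs, ys)]) + height
    return pd.DataFrame(
        {
            "trial_id": spec.trial_id,
            "timestamp_utc": EPOCH + pd.to_timedelta(t, unit="s"),
            "t": EPOCH.timestamp() + t,
            "x": xs,
            "y": ys,
            "elevation_gps": elev,
            "mode": spec.mode,
        }
    )


def emit_rss(
    track: pd.DataFrame,
    spec: TrialSpec,
    nodes: NodeGrid,
    config: SceneConfig,
    veg: VegClassRaster | None,
    node_offsets: dict[str, float],
    rng: np.random.Generator,
    jitter: float = 1.0,
) -> pd.DataFrame:
    """Raw detections for one trial under the ground-truth decay law.

    Tag emissions follow the nominal interval; the tag position is
    interpolated along the track.  Reads below the detection floor are
    censored.  Detection timestamps are jittered by up to ``jitter``
    seconds to exercise the 10 s matching step.
    """
    t = track["t"].to_numpy()
    te = np.arange(t[0], t[-1] + 1e-9, spec.tag.nominal_interval)
    px = np.interp(te, t, track["x"].to_numpy())
    py = np.interp(te, t, track["y"].to_numpy())
    # vegetation attenuates tags in or under the canopy, not drones above it
    mode_factor = {"high_flight": 0.0, "low_flight": 0.5, "ground": 1.0}[spec.mode]
    penalty = np.zeros(len(te))
    if veg is not None and mode_factor > 0.0:
        pen = config.veg_penalty
        penalty = mode_factor * np.array(
            [pen[veg.class_at(x, y)] for x, y in zip(px, py)]
        )
    rows = []
    rho, sd = config.noise_ar1, config.noise_sd
    for node_id, nx, ny in nodes.df[["node_id", "x", "y"]].itertuples(index=False):
        d = np.hypot(px - nx, py - ny)
        clean = config.a * np.exp(-config.S * d) + config.K
        eps = np.zeros(len(te))
        if sd > 0:
            z = rng.normal(0.0, sd, size=len(te))
            eps[0] = z[0]
            for i in range(1, len(te)):
                eps[i] = rho * eps[i - 1] + np.sqrt(1.0 - rho**2) * z[i]
        rss = clean + node_offsets[node_id] - penalty + eps
        keep = rss >= config.detection_floor
        if not keep.any():
            continue
        tt = te[keep] + rng.uniform(0.0, jitter, size=int(keep.sum()))
        rows.append(
            pd.DataFrame(
                {
                    "tag_id": spec.tag.tag_id,
                    "node_id": node_id,
                    "timestamp_utc": pd.to_datetime(tt, unit="s", utc=True),
                    "rss_db": rss[keep],
                }
            )
        )
    if not rows:
        return pd.DataFrame(columns=["tag_id", "node_id", "timestamp_utc", "rss_db"])
    out = pd.concat(rows, ignore_index=True)
    return out.sort_values("timestamp_utc", kind="stable").reset_index(drop=True)


@dataclass
class Scene:
    """A complete synthetic study: inputs for every pipeline stage."""

    config: SceneConfig
    nodes: NodeGrid
    dem: Raster
    veg: VegClassRaster
    veg_polys: list
    trials: list[TrialSpec]
    tracks: dict[str, pd.DataFrame]
    detections: pd.DataFrame
    node_offsets: dict[str, float]

    @property
    def truth_decay(self):
        return self.config.a, self.config.S, self.config.K


def make_scene(
    config: SceneConfig | None = None,
    trials: list[TrialSpec] | None = None,
    with_landscape: bool = True,
) -> Scene:
    """Build a full scene from one seed via named random substreams."""
    config = config or SceneConfig()
    trials = trials if trials is not None else default_trials()
    root = np.random.SeedSequence(config.seed)
    ss = dict(zip(("dem", "offsets", "tracks", "noise"), root.spawn(4)))
    nodes = make_grid(config)
    rng_dem = np.random.default_rng(ss["dem"])
    dem = make_dem(config, nodes, rng_dem)
    if with_landscape:
        veg_polys, veg = make_vegetation(config, nodes)
    else:
        veg_polys, veg = [], None
    rng_off = np.random.default_rng(ss["offsets"])
    node_offsets = {
        n: (float(rng_off.normal(0.0, config.node_offset_sd)) if config.node_offset_sd > 0 else 0.0)
        for n in nodes.node_ids
    }
    rng_tracks = np.random.default_rng(ss["tracks"])
    rng_noise = np.random.default_rng(ss["noise"])
    tracks, det_parts = {}, []
    for spec in trials:
        track = simulate_track(spec, nodes, dem, rng_tracks)
        tracks[spec.trial_id] = track
        det_parts.append(
            emit_rss(track, spec, nodes, config, veg, node_offsets, rng_noise)
        )
    detections = (
        pd.concat(det_parts, ignore_index=True)
        if det_parts
        else pd.DataFrame(columns=["tag_id", "node_id", "timestamp_utc", "rss_db"])
    )
    if veg is None:
        _, veg = make_vegetation(config, nodes, res=30.0)  # coarse placeholder raster
    return Scene(config, nodes, dem, veg, veg_polys, trials, tracks, detections, node_offsets)


def write_scene(scene: Scene, outdir) -> None:
    """Write a scene in the pipeline's own input formats (dogfooding)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_detections(scene.detections, outdir / "detections.csv")
    scene.nodes.to_csv(outdir / "nodes.csv")
    for trial_id, track in scene.tracks.items():
        write_track_gpx(track, scene.nodes.proj, outdir / f"track_{trial_id}.gpx")
    scene.dem.to_geotiff(outdir / "dem.tif")
    write_veg_geojson(scene.veg_polys, outdir / "vegetation.geojson")
    cfg = asdict(scene.config)
    (outdir / "scene_config.json").write_text(json.dumps(cfg, indent=2), encoding="utf-8")
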