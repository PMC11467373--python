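"""Canonical schemas and readers/writers shared by every pipeline stage.

Tabular data lives in pandas DataFrames with fixed column contracts:

* detections — ``tag_id, node_id, timestamp_utc, rss_db``; one row per raw
  radio signal read at a receiving node.
* relocations — ``trial_id, timestamp_utc, t, x, y, elevation_gps, mode``;
  one row per ground-truth fix of a calibration trial, projected to the
  working CRS (``t`` is float seconds since the Unix epoch).
* nodes — held in :class:`NodeGrid`, with both geographic and projected
  coordinates.

Vendor exports (CTT SensorStation) are handled by a declarative column map,
not a separate parser.
"""

from __future__ import annotations

import logging
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import MultiPoint, Polygon

from .projection import UTMProjection

logger = logging.getLogger("gridloc")

__all__ = [
    "SchemaError",
    "TooShortTrackError",
    "TagSpec",
    "WorkflowConfig",
    "NodeGrid",
    "read_detections",
    "write_detections",
    "read_truth_track",
    "write_track_gpx",
    "DETECTION_COLUMNS",
    "SENSORSTATION_COLUMN_MAP",
    "RSS_WINDOW",
]

DETECTION_COLUMNS = ["tag_id", "node_id", "timestamp_utc", "rss_db"]
#: header remapping for CTT SensorStation raw exports
SENSORSTATION_COLUMN_MAP = {
    "TagId": "tag_id",
    "NodeId": "node_id",
    "Time": "timestamp_utc",
    "TagRSSI": "rss_db",
}
#: default RSS plausibility window in dB, a superset of field-observed ranges
RSS_WINDOW = (-120.0, 0.0)


class SchemaError(ValueError):
    """A mandatory column is missing or a field cannot be parsed."""


class TooShortTrackError(ValueError):
    """A ground-truth track has fewer than two usable fixes."""


@dataclass(frozen=True)
class TagSpec:
    """A radio tag and its nominal emission schedule.

    Solar-powered "life" tags emit every 2 s; battery "power" tags every
    60 s.
    """

    tag_id: str
    kind: str = "life"
    nominal_interval: float | None = None

    def __post_init__(self):
        if self.kind not in ("life", "power"):
            raise ValueError(f"tag kind {self.kind!r} not in {{'life', 'power'}}")
        if self.nominal_interval is None:
            object.__setattr__(
                self, "nominal_interval", 2.0 if self.kind == "life" else 60.0
            )
        if self.nominal_interval <= 0:
            raise ValueError("nominal_interval must be > 0")


RSS_TYPES = ("max", "avg")
SIGNAL_SMOOTHERS = ("none", "spline", "kalman")
MODEL_SCOPES = ("general", "node", "tag")
LOC_METHODS = ("all_nodes", "strongest3", "nearest3", "grouped_kmeans")
TRACK_SMOOTHERS = ("none", "spline", "kalman")


@dataclass(frozen=True)
class WorkflowConfig:
    """One cell of the localisation decision factorial.

    Five axes — RSS summary, signal smoothing, decay-model scope,
    localisation method, track smoothing — give 2·3·3·4·3 = 216 workflows.
    """

    rss_type: str = "max"
    signal_smoother: str = "none"
    model_scope: str = "general"
    loc_method: str = "all_nodes"
    track_smoother: str = "none"

    def __post_init__(self):
        for value, allowed, name in (
            (self.rss_type, RSS_TYPES, "rss_type"),
            (self.signal_smoother, SIGNAL_SMOOTHERS, "signal_smoother"),
            (self.model_scope, MODEL_SCOPES, "model_scope"),
            (self.loc_method, LOC_METHODS, "loc_method"),
            (self.track_smoother, TRACK_SMOOTHERS, "track_smoother"),
        ):
            if value not in allowed:
                raise ValueError(f"{name}={value!r} not in {allowed}")

    @classmethod
    def factorial(cls) -> list["WorkflowConfig"]:
        """Every workflow in the five-axis factorial, in a fixed order."""
        return [
            cls(r, s, m, l, t)
            for r, s, m, l, t in product(
                RSS_TYPES, SIGNAL_SMOOTHERS, MODEL_SCOPES, LOC_METHODS, TRACK_SMOOTHERS
            )
        ]

    def label(self) -> str:
        return "/".join(
            (
                self.rss_type,
                self.signal_smoother,
                self.model_scope,
                self.loc_method,
                self.track_smoother,
            )
        )


@dataclass
class NodeGrid:
    """The fixed receiver grid: ids, geographic and projected positions.

    ``df`` columns: node_id, lon, lat, x, y, height_agl.  The working CRS is
    the UTM zone of the registry centroid unless an explicit CRS id was
    given.
    """

    df: pd.DataFrame
    proj: UTMProjection

    def __post_init__(self):
        if self.df["node_id"].duplicated().any():
            dupes = self.df.loc[self.df["node_id"].duplicated(), "node_id"].tolist()
            raise SchemaError(f"duplicate node_id values: {dupes}")
        self.df = self.df.reset_index(drop=True)

    @classmethod
    def from_csv(cls, path, crs: str | None = None, height_agl: float = 2.5) -> "NodeGrid":
        df = pd.read_csv(path, dtype={"node_id": str})
        for col in ("node_id", "lon", "lat"):
            if col not in df.columns:
                raise SchemaError(f"node registry is missing column {col!r}")
        if "height_agl" not in df.columns:
            df["height_agl"] = height_agl
        proj = (
            UTMProjection.from_crs_id(crs)
            if crs
            else UTMProjection.for_point(df["lon"].mean(), df["lat"].mean())
        )
        df["x"], df["y"] = proj.forward(df["lon"].to_numpy(), df["lat"].to_numpy())
        return cls(df[["node_id", "lon", "lat", "x", "y", "height_agl"]], proj)

    @classmethod
    def from_xy(
        cls,
        node_ids,
        x,
        y,
        proj: UTMProjection,
        height_agl: float = 2.5,
    ) -> "NodeGrid":
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        lon, lat = proj.inverse(x, y)
        df = pd.DataFrame(
            {
                "node_id": [str(n) for n in node_ids],
                "lon": lon,
                "lat": lat,
                "x": x,
                "y": y,
                "height_agl": height_agl,
            }
        )
        return cls(df, proj)

    def to_csv(self, path) -> None:
        self.df[["node_id", "lon", "lat", "height_agl"]].to_csv(path, index=False)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def node_ids(self) -> list[str]:
        return self.df["node_id"].tolist()

    @property
    def positions(self) -> np.ndarray:
        """(n, 2) array of projected node positions, row order = df order."""
        return self.df[["x", "y"]].to_numpy()

    def position_of(self, node_id: str) -> np.ndarray:
        row = self.df.loc[self.df["node_id"] == node_id]
        if row.empty:
            raise KeyError(node_id)
        return row[["x", "y"]].to_numpy()[0]

    @property
    def hull(self) -> Polygon:
        """Convex hull of node positions — the operational 'grid' polygon."""
        return MultiPoint(self.positions).convex_hull

    def drop(self, node_ids) -> "NodeGrid":
        """Grid without the listed nodes (e.g. a receiver that failed)."""
        keep = ~self.df["node_id"].isin(list(node_ids))
        return NodeGrid(self.df.loc[keep].reset_index(drop=True), self.proj)


def _parse_timestamps(raw: pd.Series, path) -> pd.Series:
    ts = pd.to_datetime(raw, utc=True, format="ISO8601", errors="coerce")
    bad = ts.isna() & raw.notna()
    if bad.any():
        # +2: header line and 1-based numbering
        line = int(bad.idxmax()) + 2
        raise SchemaError(
            f"{path}: unparseable timestamp {raw[bad.idxmax()]!r} on line {line}"
        )
    return ts


def read_detections(
    path,
    dialect: str = "canonical",
    column_map: dict[str, str] | None = None,
    rss_window: tuple[float, float] = RSS_WINDOW,
) -> pd.DataFrame:
    """Read a detection table, normalising vendor headers and units.

    Rows with RSS outside ``rss_window`` (default [-120, 0) dB) are dropped
    with a logged count, recorded in ``df.attrs['n_rss_dropped']``.
    """
    if column_map is None:
        if dialect == "canonical":
            column_map = {}
        elif dialect == "sensorstation":
            column_map = SENSORSTATION_COLUMN_MAP
        else:
            raise ValueError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(path, dtype={"tag_id": str, "node_id": str}, float_precision="round_trip")
    df = df.rename(columns=column_map)
    for col in DETECTION_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing mandatory column {col!r}")
    df = df[DETECTION_COLUMNS].copy()
    df["tag_id"] = df["tag_id"].astype(str)
    df["node_id"] = df["node_id"].astype(str)
    df["timestamp_utc"] = _parse_timestamps(df["timestamp_utc"], path)
    df["rss_db"] = pd.to_numeric(df["rss_db"])
    lo, hi = rss_window
    ok = (df["rss_db"] >= lo) & (df["rss_db"] < hi)
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.warning(
            "%s: dropped %d detections with RSS outside [%g, %g) dB",
            path,
            n_dropped,
            lo,
            hi,
        )
    df = df.loc[ok].reset_index(drop=True)
    df.attrs["n_rss_dropped"] = n_dropped
    return df


def write_detections(df: pd.DataFrame, path) -> None:
    """Write detections in the canonical CSV dialect (round-trip stable)."""
    out = df[DETECTION_COLUMNS].copy()
    out["timestamp_utc"] = out["timestamp_utc"].dt.strftime("%Y-%m-%dT%H:%M:%S.%fZ")
    # %.17g round-trips IEEE doubles exactly
    out.to_csv(path, index=False, float_format="%.17g")


def _strip_ns(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _read_gpx_fixes(path) -> pd.DataFrame:
    rows = []
    for _, elem in ET.iterparse(str(path)):
        if _strip_ns(elem.tag) != "trkpt":
            continue
        rec = {"lat": float(elem.get("lat")), "lon": float(elem.get("lon"))}
        for child in elem:
            name = _strip_ns(child.tag)
            if name == "ele":
                rec["elevation_m"] = float(child.text)
            elif name == "time":
                rec["timestamp_utc"] = child.text
        rows.append(rec)
    return pd.DataFrame(rows)


def read_truth_track(
    path,
    fmt: str | None = None,
    crs: str | UTMProjection | None = None,
    trial_id: str | None = None,
    mode: str = "ground",
) -> pd.DataFrame:
    """Read a ground-truth calibration track (GPX 1.1 or CSV) as relocations.

    Fixes are projected to the working CRS, sorted by time, and duplicate
    timestamps collapsed to the first occurrence (with a warning).  ``crs``
    defaults to the UTM zone of the first fix.
    """
    path = Path(path)
    if fmt is None:
        fmt = "gpx" if path.suffix.lower() == ".gpx" else "csv"
    if fmt == "gpx":
        df = _read_gpx_fixes(path)
    elif fmt == "csv":
        df = pd.read_csv(path, float_precision="round_trip")
    else:
        raise ValueError(f"unknown track format {fmt!r}")
    for col in ("timestamp_utc", "lon", "lat"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing mandatory column {col!r}")
    if len(df) < 2:
        raise TooShortTrackError(f"{path}: track has {len(df)} fixes; need >= 2")
    df["timestamp_utc"] = _parse_timestamps(df["timestamp_utc"], path)
    df = df.sort_values("timestamp_utc", kind="stable")
    n_dup = int(df["timestamp_utc"].duplicated().sum())
    if n_dup:
        logger.warning("%s: collapsed %d duplicate-timestamp fixes", path, n_dup)
        df = df.loc[~df["timestamp_utc"].duplicated()]
    if len(df) < 2:
        raise TooShortTrackError(f"{path}: <2 fixes after de-duplication")
    proj = (
        crs
        if isinstance(crs, UTMProjection)
        else UTMProjection.from_crs_id(crs)
        if crs
        else UTMProjection.for_point(float(df["lon"].iloc[0]), float(df["lat"].iloc[0]))
    )
    x, y = proj.forward(df["lon"].to_numpy(), df["lat"].to_numpy())
    out = pd.DataFrame(
        {
            "trial_id": trial_id if trial_id is not None else path.stem,
            "timestamp_utc": df["timestamp_utc"].to_numpy(),
            "t": df["timestamp_utc"].astype("int64").to_numpy() / 1e9,
            "x": x,
            "y": y,
            "elevation_gps": df.get(
                "elevation_m", pd.Series(np.nan, index=df.index)
            ).to_numpy(),
            "mode": mode,
        }
    ).reset_index(drop=True)
    return out


def write_track_gpx(track: pd.DataFrame, proj: UTMProjection, path) -> None:
    """Write relocations as a minimal GPX 1.1 track."""
    lon, lat = proj.inverse(track["x"].to_numpy(), track["y"].to_numpy())
    times = pd.to_datetime(track["timestamp_utc"]).dt.strftime("%Y-%m-%dT%H:%M:%S.%fZ")
    parts = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        '<gpx version="1.1" creator="gridloc" xmlns="http://www.topografix.com/GPX/1/1">',
        "<trk><trkseg>",
    ]
    elev = track.get("elevation_gps")
    for i in range(len(track)):
        parts.append(f'<trkpt lat="{lat[i]:.8f}" lon="{lon[i]:.8f}">')
        if elev is not None and np.isfinite(elev.iloc[i]):
            parts.append(f"<ele>{elev.iloc[i]:.2f}</ele>")
        parts.append(f"<time>{times.iloc[i]}</time></trkpt>")
    parts.append("</trkseg></trk></gpx>")
    Path(path).write_text("\n".join(parts), encoding="utf-8")
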