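"""Minimal raster support: DEM grids (GeoTIFF) and vegetation class grids.

Rasters are regular north-up grids in the working projected CRS, carried as
a 2-D array plus an origin/cell-size georeference.  GeoTIFF I/O goes
through tifffile with the standard ModelPixelScale / ModelTiepoint geo-tags
(pixel-is-area convention: the tiepoint is the outer corner of the top-left
cell).  Vegetation polygons travel as GeoJSON in lon/lat and are rasterised
onto a 1 m grid in the working CRS.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import shapely
import tifffile
from shapely.geometry import mapping, shape
from shapely.ops import transform as shp_transform

from .projection import UTMProjection

__all__ = ["Raster", "VEG_CLASSES", "VegClassRaster", "read_veg_geojson", "write_veg_geojson", "rasterize_vegetation"]

_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922

#: vegetation classes in declared tie-break preference order
VEG_CLASSES = ("grassland", "paramo", "dense", "builtup")


@dataclass
class Raster:
    """North-up grid: ``data[row, col]`` with cell size ``res`` metres.

    ``x0, y0`` is the outer corner of cell (0, 0), i.e. the minimum-x /
    maximum-y corner of the grid.
    """

    data: np.ndarray
    x0: float
    y0: float
    res: float

    @property
    def bounds(self):
        ny, nx = self.data.shape
        return (self.x0, self.y0 - ny * self.res, self.x0 + nx * self.res, self.y0)

    def cell_centers(self):
        ny, nx = self.data.shape
        xs = self.x0 + self.res * (np.arange(nx) + 0.5)
        ys = self.y0 - self.res * (np.arange(ny) + 0.5)
        return xs, ys

    def contains(self, x: float, y: float) -> bool:
        xmin, ymin, xmax, ymax = self.bounds
        return xmin <= x <= xmax and ymin <= y <= ymax

    def value_bilinear(self, x: float, y: float) -> float:
        """Bilinear interpolation on cell centres; NaN outside the raster."""
        if not self.contains(x, y):
            return float("nan")
        ny, nx = self.data.shape
        fc = np.clip((x - self.x0) / self.res - 0.5, 0.0, nx - 1.0)
        fr = np.clip((self.y0 - y) / self.res - 0.5, 0.0, ny - 1.0)
        c0, r0 = int(np.floor(fc)), int(np.floor(fr))
        c1, r1 = min(c0 + 1, nx - 1), min(r0 + 1, ny - 1)
        wc, wr = fc - c0, fr - r0
        z = self.data
        return float(
            z[r0, c0] * (1 - wr) * (1 - wc)
            + z[r0, c1] * (1 - wr) * wc
            + z[r1, c0] * wr * (1 - wc)
            + z[r1, c1] * wr * wc
        )

    def values_in_radius(self, x: float, y: float, radius: float) -> np.ndarray:
        """Values of cells whose centres fall within ``radius`` of (x, y)."""
        xs, ys = self.cell_centers()
        cmask = np.abs(xs - x) <= radius
        rmask = np.abs(ys - y) <= radius
        if not cmask.any() or not rmask.any():
            return np.empty(0)
        sub = self.data[np.ix_(rmask, cmask)]
        gx, gy = np.meshgrid(xs[cmask], ys[rmask])
        inside = (gx - x) ** 2 + (gy - y) ** 2 <= radius**2
        return sub[inside]

    def ruggedness(self, x: float, y: float, radius: float = 100.0) -> float:
        """Terrain ruggedness: sd of elevations within the radius buffer."""
        vals = self.values_in_radius(x, y, radius)
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            return float("nan")
        return float(np.std(vals))

    def to_geotiff(self, path) -> None:
        tifffile.imwrite(
            str(path),
            self.data.astype(np.float32),
            extratags=[
                (_TAG_PIXEL_SCALE, "d", 3, (self.res, self.res, 0.0)),
                (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, self.x0, self.y0, 0.0)),
            ],
        )

    @classmethod
    def from_geotiff(cls, path) -> "Raster":
        with tifffile.TiffFile(str(path)) as tif:
            page = tif.pages[0]
            data = page.asarray().astype(float)
            try:
                sx, sy, _ = page.tags[_TAG_PIXEL_SCALE].value
                ti = page.tags[_TAG_TIEPOINT].value
            except KeyError as exc:
                raise ValueError(f"{path}: missing GeoTIFF georeference tags") from exc
            if abs(sx - sy) > 1e-9:
                raise ValueError(f"{path}: anisotropic cells not supported")
            # tiepoint maps raster (i, j) -> model (x, y); standard case i=j=0
            x0 = ti[3] - ti[0] * sx
            y0 = ti[4] + ti[1] * sy
        return cls(data, float(x0), float(y0), float(sx))


@dataclass
class VegClassRaster:
    """1 m vegetation-class grid; values index into :data:`VEG_CLASSES`."""

    raster: Raster  # integer codes stored as the data array

    def class_at(self, x: float, y: float) -> str:
        r = self.raster
        col = int((x - r.x0) / r.res)
        row = int((r.y0 - y) / r.res)
        ny, nx = r.data.shape
        if not (0 <= row < ny and 0 <= col < nx):
            return VEG_CLASSES[0]
        return VEG_CLASSES[int(r.data[row, col])]

    def dominant_class(self, x: float, y: float, radius: float = 100.0) -> str:
        """Class with the largest occupied area in the radius buffer.

        Area ties resolve by the declared preference order
        grassland > paramo > dense > builtup (the classes' index order).
        """
        codes = self.raster.values_in_radius(x, y, radius).astype(int)
        if codes.size == 0:
            return self.class_at(x, y)
        counts = np.bincount(codes, minlength=len(VEG_CLASSES))
        return VEG_CLASSES[int(np.argmax(counts))]


def read_veg_geojson(path):
    """GeoJSON polygons (lon/lat) with a ``class`` property."""
    gj = json.loads(Path(path).read_text(encoding="utf-8"))
    polys = []
    for feat in gj.get("features", []):
        cls = feat.get("properties", {}).get("class")
        if cls not in VEG_CLASSES:
            raise ValueError(f"{path}: unknown vegetation class {cls!r}")
        polys.append((cls, shape(feat["geometry"])))
    return polys


def write_veg_geojson(polys, path) -> None:
    feats = [
        {"type": "Feature", "properties": {"class": cls}, "geometry": mapping(geom)}
        for cls, geom in polys
    ]
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": feats}), encoding="utf-8"
    )


def rasterize_vegetation(
    polys,
    proj: UTMProjection,
    bounds: tuple[float, float, float, float],
    res: float = 1.0,
    background: str = "grassland",
    geographic: bool = True,
) -> VegClassRaster:
    """Burn class polygons onto a grid over ``bounds`` (working-CRS metres).

    Polygons later in the list overwrite earlier ones where they overlap.
    ``geographic=True`` treats polygon coordinates as lon/lat and projects
    them first.
    """
    xmin, ymin, xmax, ymax = bounds
    nx = int(np.ceil((xmax - xmin) / res))
    ny = int(np.ceil((ymax - ymin) / res))
    y0 = ymin + ny * res
    codes = np.full((ny, nx), VEG_CLASSES.index(background), dtype=np.uint8)
    xs = xmin + res * (np.arange(nx) + 0.5)
    ys = y0 - res * (np.arange(ny) + 0.5)
    gx, gy = np.meshgrid(xs, ys)
    for cls, geom in polys:
        if geographic:
            geom = shp_transform(lambda lon, lat: proj.forward(lon, lat), geom)
        inside = shapely.contains_xy(geom, gx.ravel(), gy.ravel()).reshape(ny, nx)
        codes[inside] = VEG_CLASSES.index(cls)
    return VegClassRaster(Raster(codes, xmin, y0, res))
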