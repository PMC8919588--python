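"""Land/sea mask for the Indian Ocean study window.

The refinement model assigns probability zero to positions on land, so the
mask only needs to resolve coastlines at the scale of geolocator error
(~100–200 km). A coarse built-in set of continental polygons (Africa/Arabia,
India, Indochina–Sunda, Australia, Madagascar) covers the study window;
user-supplied GeoJSON polygons override it.

The breeding island itself (a few km across) is far below geolocator
resolution and is deliberately not part of the mask — ashore positions are
handled as the colony point, not via the spatial mask.
"""

from __future__ import annotations

import json
import pathlib

import numpy as np
import shapely
from shapely.geometry import MultiPolygon, Polygon, shape, mapping

_BUILTIN_POLYGONS = [
    # Africa (eastern half, coarse)
    [(5, -36), (5, 38), (32, 33), (43, 12), (40, -4), (40, -16), (35, -20), (33, -29), (20, -36)],
    # Arabian peninsula + Iran/Pakistan coast
    [(34, 31), (43, 12), (52, 12), (57, 17), (60, 22), (66, 25), (66, 31)],
    # Indian subcontinent
    [(66, 31), (66, 25), (71, 20), (77, 8), (80, 13), (89, 21), (92, 27), (80, 31)],
    # Indochina + Malay peninsula + Sumatra/Java arc (coarse)
    [(92, 27), (89, 21), (95, 15), (97, 5), (105, -9), (116, -9), (106, -5), (104, 2),
     (104, 12), (109, 12), (109, 22), (100, 28)],
    # Borneo (coarse)
    [(109, 1), (114, 4), (119, 0), (116, -4), (110, -3)],
    # Australia
    [(113, -22), (115, -35), (130, -32), (140, -38), (148, -39), (153, -28), (142, -11),
     (135, -12), (130, -11), (122, -17)],
    # Madagascar
    [(43.5, -16), (49.5, -12.5), (50.5, -16), (47.2, -25.2), (44, -25)],
    # continental Eurasia north of the subtropical coasts (coarse band; the
    # study window is the Indian Ocean, so far-eastern ocean cells caught by
    # this band are irrelevant)
    [(5, 33), (60, 29), (66, 27), (80, 29), (92, 25), (102, 23), (160, 21),
     (160, 60), (5, 60)],
]


class LandMask:
    """Point-in-polygon land test over a set of (multi)polygons."""

    def __init__(self, polygons: list[Polygon] | MultiPolygon | None = None):
        if polygons is None:
            polygons = [Polygon(p) for p in _BUILTIN_POLYGONS]
        if isinstance(polygons, MultiPolygon):
            polygons = list(polygons.geoms)
        merged = shapely.unary_union(
            [Polygon(p) if not isinstance(p, Polygon) else p for p in polygons]
        )
        if isinstance(merged, Polygon):
            merged = MultiPolygon([merged])
        self.geometry = merged
        shapely.prepare(self.geometry)

    def on_land(self, lon, lat) -> np.ndarray:
        """Boolean array: True where (lon, lat) falls inside a land polygon."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        return shapely.contains_xy(self.geometry, lon, lat)

    def raster(
        self,
        lon_min: float = -20.0,
        lon_max: float = 160.0,
        lat_min: float = -65.0,
        lat_max: float = 45.0,
        res_deg: float = 0.2,
    ) -> tuple[np.ndarray, float, float, float]:
        """Rasterised land grid (True = land) with its origin and resolution.

        Cell centres are tested; used by samplers needing many cheap lookups.
        The default raster is cached on the instance.
        """
        key = (lon_min, lon_max, lat_min, lat_max, res_deg)
        cache = getattr(self, "_raster_cache", None)
        if cache is not None and cache[0] == key:
            return cache[1]
        lons = np.arange(lon_min + res_deg / 2, lon_max, res_deg)
        lats = np.arange(lat_min + res_deg / 2, lat_max, res_deg)
        gx, gy = np.meshgrid(lons, lats)
        grid = self.on_land(gx.ravel(), gy.ravel()).reshape(len(lats), len(lons))
        out = (grid, lon_min, lat_min, res_deg)
        self._raster_cache = (key, out)
        return out

    def on_land_raster(self, lon, lat) -> np.ndarray:
        """Land test against the default raster (the samplers' mask definition).

        Points outside the rasterised window count as land, matching the
        refinement model's behaviour.
        """
        grid, lon0, lat0, res = self.raster()
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        ix = np.floor((lon - lon0) / res).astype(int)
        iy = np.floor((lat - lat0) / res).astype(int)
        inside = (ix >= 0) & (ix < grid.shape[1]) & (iy >= 0) & (iy < grid.shape[0])
        out = np.ones(lon.shape, dtype=bool)
        out[inside] = grid[iy[inside], ix[inside]]
        return out

    @classmethod
    def from_geojson(cls, path) -> "LandMask":
        with open(path) as fh:
            gj = json.load(fh)
        feats = gj["features"] if gj.get("type") == "FeatureCollection" else [gj]
        polys: list[Polygon] = []
        for f in feats:
            geom = shape(f["geometry"] if "geometry" in f else f)
            if isinstance(geom, MultiPolygon):
                polys.extend(geom.geoms)
            elif isinstance(geom, Polygon):
                polys.append(geom)
        if not polys:
            raise ValueError(f"{path}: no polygon geometries found")
        return cls(polys)

    def to_geojson(self, path) -> None:
        gj = {
            "type": "FeatureCollection",
            "features": [
                {"type": "Feature", "properties": {}, "geometry": mapping(p)}
                for p in self.geometry.geoms
            ],
        }
        pathlib.Path(path).write_text(json.dumps(gj))


def default_mask() -> LandMask:
    return LandMask()
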