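"""Raster data model and I/O.

All grids in a run share one projected coordinate system and one cell size
(30 m by default, i.e. 0.09 ha per cell). Indexing is 0-based, row-major,
with the origin at the top-left corner; adjacency throughout the package is
the 8-neighborhood.

Two raster dialects are supported: ESRI-style ASCII grid (the plain-text
fixture format, 6-line header) and single-band GeoTIFF via tifffile, with
the georeference carried in the ImageDescription tag.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd


class LandCover(enum.IntEnum):
    """Land-cover classes. WATER, NONFOREST and URBAN are immutable in simulation."""

    FOREST = 1
    DEFORESTED = 2
    SECONDARY = 3
    WATER = 4
    NONFOREST = 5
    URBAN = 6


class Region(enum.IntEnum):
    """Model regions. Rates, weights and road dynamics are estimated per region.

    APP is the legally protected riparian strip; APP2008 the portion of it
    already cleared by 2008 (used only under the 2012 Forest Code scenario).
    """

    NONE = 0
    CU = 1        # conservation unit
    IL = 2        # indigenous land
    RB = 3        # 1-km buffer along rivers >= 30 m wide
    IR = 4        # area under road influence
    IA = 5        # isolated area, no land access
    APP = 6
    APP2008 = 7


LANDCOVER_CODES = frozenset(int(c) for c in LandCover)
REGION_CODES = frozenset(int(c) for c in Region)

#: codes that never change state during simulation
IMMUTABLE_CLASSES = (LandCover.WATER, LandCover.NONFOREST, LandCover.URBAN)

_ROLE_CODES = {
    "landcover": LANDCOVER_CODES,
    "region": REGION_CODES,
    "binary": frozenset({0, 1}),
}


class GridValidationError(ValueError):
    """A grid's values violate the invariants of its declared role."""


@dataclass
class GridMap:
    """A single-band raster on the shared model grid.

    Parameters
    ----------
    values
        2-D array, row-major, row 0 at the top.
    cell_size
        Cell edge in meters (default 30).
    origin
        (x, y) projected coordinates of the top-left corner.
    nodata
        Sentinel for cells outside the study area.
    role
        One of ``landcover``, ``region``, ``binary``, ``float``, ``int``.
    """

    values: np.ndarray
    cell_size: float = 30.0
    origin: tuple[float, float] = (0.0, 0.0)
    nodata: float = -9999
    role: str = "float"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise GridValidationError("grid values must be 2-D")
        self.validate()

    # -- geometry ----------------------------------------------------------
    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def cell_area_ha(self) -> float:
        return (self.cell_size / 100.0) ** 2

    @property
    def cell_area_km2(self) -> float:
        return (self.cell_size / 1000.0) ** 2

    @property
    def mask(self) -> np.ndarray:
        """Boolean mask of in-study-area (non-nodata) cells."""
        return self.values != self.nodata

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        x0, y0 = self.origin
        return (x0 + (col + 0.5) * self.cell_size, y0 - (row + 0.5) * self.cell_size)

    def like(self, values: np.ndarray, role: str | None = None) -> "GridMap":
        """A new grid sharing this one's georeference."""
        return replace(self, values=np.asarray(values), role=role or self.role)

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        allowed = _ROLE_CODES.get(self.role)
        if allowed is None:
            return
        vals = self.values[self.mask]
        bad = ~np.isin(vals, list(allowed))
        if bad.any():
            rows, cols = np.nonzero(self.mask)
            idx = int(np.nonzero(bad)[0][0])
            code = vals[bad][0]
            raise GridValidationError(
                f"illegal code {code!r} for role {self.role!r} at cell "
                f"({rows[idx]}, {cols[idx]})"
            )

    def __eq__(self, other: object) -> bool:  # value+georeference equality
        if not isinstance(other, GridMap):
            return NotImplemented
        return (
            np.array_equal(self.values, other.values)
            and self.cell_size == other.cell_size
            and self.origin == other.origin
            and self.nodata == other.nodata
        )


@dataclass
class RiverNetwork:
    """River reaches with per-reach channel widths and an optional floodplain.

    Each reach is a (shapely LineString, regular_width_m, maxlevel_width_m)
    triple; the maximum-water-level width is never narrower than the regular
    (minimum) channel. The floodplain mask, when present, covers every
    reach's channel cells.
    """

    reaches: list[tuple]  # (LineString, regular_width_m, maxlevel_width_m)
    floodplain_mask: GridMap | None = None

    def __post_init__(self) -> None:
        for _, reg, mx in self.reaches:
            if not (reg > 0):
                raise GridValidationError(f"regular width must be positive, got {reg}")
            if mx < reg:
                raise GridValidationError(
                    f"max-level width {mx} narrower than regular channel {reg}"
                )


# ---------------------------------------------------------------------------
# raster I/O
# ---------------------------------------------------------------------------

def read_grid(path: str | Path, role: str = "float") -> GridMap:
    """Read a raster (ASCII grid or GeoTIFF, chosen by extension) and
    validate it against *role*'s code set."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        return _read_geotiff(path, role)
    return _read_ascii(path, role)


def write_grid(grid: GridMap, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix.lower() in {".tif", ".tiff"}:
        _write_geotiff(grid, path)
    else:
        _write_ascii(grid, path)


def _read_ascii(path: Path, role: str) -> GridMap:
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        data = np.loadtxt(fh)
    ncols = int(header["ncols"])
    nrows = int(header["nrows"])
    data = np.atleast_2d(data).reshape(nrows, ncols)
    cell = header["cellsize"]
    nodata = header.get("nodata_value", -9999)
    # ASCII header gives the lower-left corner; convert to top-left origin
    origin = (header["xllcorner"], header["yllcorner"] + nrows * cell)
    if role in _ROLE_CODES or role == "int":
        data = data.astype(np.int64)
        nodata = int(nodata)
    return GridMap(data, cell_size=cell, origin=origin, nodata=nodata, role=role)


def _write_ascii(grid: GridMap, path: Path) -> None:
    x0, ytop = grid.origin
    yll = ytop - grid.n_rows * grid.cell_size
    fmt = "%d" if np.issubdtype(grid.values.dtype, np.integer) else "%.8g"
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.n_cols}\n")
        fh.write(f"nrows {grid.n_rows}\n")
        fh.write(f"xllcorner {x0:.6f}\n")
        fh.write(f"yllcorner {yll:.6f}\n")
        fh.write(f"cellsize {grid.cell_size:.6f}\n")
        fh.write(f"nodata_value {grid.nodata}\n")
        np.savetxt(fh, grid.values, fmt=fmt)


def _read_geotiff(path: Path, role: str) -> GridMap:
    import tifffile

    with tifffile.TiffFile(str(path)) as tf:
        data = tf.asarray()
        desc = tf.pages[0].description or "{}"
    try:
        meta = json.loads(desc)
    except json.JSONDecodeError:
        meta = {}
    return GridMap(
        data,
        cell_size=float(meta.get("cell_size", 30.0)),
        origin=tuple(meta.get("origin", (0.0, 0.0))),
        nodata=meta.get("nodata", -9999),
        role=role,
    )


def _write_geotiff(grid: GridMap, path: Path) -> None:
    import tifffile

    meta = {
        "cell_size": grid.cell_size,
        "origin": list(grid.origin),
        "nodata": grid.nodata,
    }
    tifffile.imwrite(str(path), grid.values, description=json.dumps(meta))


# ---------------------------------------------------------------------------
# vector I/O (GeoJSON)
# ---------------------------------------------------------------------------

def read_rivers(path: str | Path) -> RiverNetwork:
    """Read a river network from GeoJSON LineString features carrying
    ``regular_width_m`` and ``maxlevel_width_m`` properties."""
    from shapely.geometry import shape

    with open(path) as fh:
        gj = json.load(fh)
    reaches = []
    for feat in gj["features"]:
        geom = shape(feat["geometry"])
        props = feat.get("properties", {})
        reaches.append(
            (geom, float(props["regular_width_m"]), float(props["maxlevel_width_m"]))
        )
    return RiverNetwork(reaches=reaches)


def write_rivers(net: RiverNetwork, path: str | Path) -> None:
    from shapely.geometry import mapping

    feats = [
        {
            "type": "Feature",
            "geometry": mapping(line),
            "properties": {"regular_width_m": reg, "maxlevel_width_m": mx},
        }
        for line, reg, mx in net.reaches
    ]
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)


def read_lines(path: str | Path) -> list:
    from shapely.geometry import shape

    with open(path) as fh:
        gj = json.load(fh)
    return [shape(f["geometry"]) for f in gj["features"]]


def write_lines(lines: list, path: str | Path) -> None:
    from shapely.geometry import mapping

    feats = [{"type": "Feature", "geometry": mapping(g), "properties": {}} for g in lines]
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def class_areas(lc: GridMap) -> pd.Series:
    """Per-class area in km² for a land-cover grid.

    Nodata cells are excluded; the sum over classes equals the total
    non-nodata area.
    """
    vals = lc.values[lc.mask]
    areas = {
        cls.name: float(np.count_nonzero(vals == cls) * lc.cell_area_km2)
        for cls in LandCover
    }
    return pd.Series(areas, name="area_km2")
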