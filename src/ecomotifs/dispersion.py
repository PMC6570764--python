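"""Range grids, cell filtering, and assemblage dispersion fields.

The geographic stage works on a stack of per-species binary range
grids sharing one lon/lat extent and resolution. Two products feed the
grade-of-membership models:

* a global presence-absence matrix, keeping only grid cells with
  sufficient land cover and overlapped by enough breeding ranges; and
* per-site assemblage dispersion fields — for each surveyed community,
  the grid counting how many of its species' ranges cover each cell —
  vectorized and stacked into a sites x cells count matrix.

Grid convention (fixed so column ids are reproducible): arrays are
stored with row 0 at the NORTHERN edge, vectorization is row-major from
the north-west corner, cells are centre-registered, longitudes are
east-positive degrees. Grids are read and written as ESRI ASCII rasters,
whose row order (north first) matches the in-memory layout.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .matrices import CountMatrix, PresenceMatrix

__all__ = [
    "GridGeometry",
    "RangeGridSet",
    "SiteTable",
    "DispersionField",
    "build_presence_matrix",
    "dispersion_field",
    "stack_dispersion_fields",
    "unstack_row_to_grid",
    "normalize_species_name",
    "read_ascii_grid",
    "write_ascii_grid",
    "read_range_grids",
    "himalayan_geometry",
]


@dataclass(frozen=True)
class GridGeometry:
    """Lon/lat extent (degrees) and square cell size of a raster."""

    lon_min: float
    lon_max: float
    lat_min: float
    lat_max: float
    resolution: float

    def __post_init__(self) -> None:
        if self.lon_max <= self.lon_min or self.lat_max <= self.lat_min:
            raise ValueError("extent must have positive span")
        for name, n in (("columns", self._span_cells(self.lon_min, self.lon_max)),
                        ("rows", self._span_cells(self.lat_min, self.lat_max))):
            if abs(n - round(n)) > 1e-6:
                raise ValueError(f"extent is not a whole number of {name} at this resolution")

    def _span_cells(self, lo: float, hi: float) -> float:
        return (hi - lo) / self.resolution

    @property
    def n_rows(self) -> int:
        return round(self._span_cells(self.lat_min, self.lat_max))

    @property
    def n_cols(self) -> int:
        return round(self._span_cells(self.lon_min, self.lon_max))

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        """(lon, lat) of the centre of grid cell (row, col); row 0 is north."""
        lon = self.lon_min + (col + 0.5) * self.resolution
        lat = self.lat_max - (row + 0.5) * self.resolution
        return lon, lat

    def cell_id(self, row: int, col: int) -> str:
        return f"cell_{row:04d}_{col:04d}"

    def all_cell_ids(self) -> list[str]:
        """Row-major cell ids starting from the north-west corner."""
        return [self.cell_id(r, c) for r in range(self.n_rows) for c in range(self.n_cols)]

    def parse_cell_id(self, cell_id: str) -> tuple[int, int]:
        m = re.fullmatch(r"cell_(\d+)_(\d+)", cell_id)
        if not m:
            raise ValueError(f"not a cell id: {cell_id!r}")
        return int(m.group(1)), int(m.group(2))

    def cell_of(self, lon: float, lat: float) -> tuple[int, int]:
        if not (self.lon_min <= lon <= self.lon_max and self.lat_min <= lat <= self.lat_max):
            raise ValueError(f"({lon}, {lat}) outside grid extent")
        col = min(int((lon - self.lon_min) / self.resolution), self.n_cols - 1)
        row = min(int((self.lat_max - lat) / self.resolution), self.n_rows - 1)
        return row, col


def himalayan_geometry(resolution: float = 0.125) -> GridGeometry:
    """The Himalaya/South-Asia window, 50-120E x 5-50N; 1/8 deg gives 360x560."""
    return GridGeometry(50.0, 120.0, 5.0, 50.0, resolution)


def normalize_species_name(name: str) -> str:
    """Case-fold and collapse underscores/whitespace; matching stays exact."""
    return re.sub(r"[\s_]+", " ", str(name).strip()).lower()


@dataclass
class RangeGridSet:
    """Binary range grids for a set of species on a shared geometry."""

    geometry: GridGeometry
    species_ids: list[str]
    grids: np.ndarray  # S x rows x cols, binary

    def __post_init__(self) -> None:
        g = np.asarray(self.grids)
        if g.ndim != 3 or g.shape[0] != len(self.species_ids):
            raise ValueError("grids must be S x rows x cols matching species_ids")
        if g.shape[1:] != self.geometry.shape:
            raise ValueError(
                f"grid dims {g.shape[1:]} do not match geometry {self.geometry.shape}"
            )
        if not np.isin(g, (0, 1)).all():
            raise ValueError("range grids must be binary")
        self.grids = g.astype(np.uint8)
        if len(set(self.species_ids)) != len(self.species_ids):
            raise ValueError("duplicate species ids")
        self._index = {normalize_species_name(s): i for i, s in enumerate(self.species_ids)}

    @property
    def n_species(self) -> int:
        return len(self.species_ids)

    def lookup(self, names: Iterable[str]) -> np.ndarray:
        """Indices for species names; raises listing every unmatched name."""
        idx, missing = [], []
        for name in names:
            key = normalize_species_name(name)
            if key in self._index:
                idx.append(self._index[key])
            else:
                missing.append(name)
        if missing:
            raise KeyError(f"species not in range set: {missing}")
        return np.asarray(idx, dtype=int)

    def richness(self) -> np.ndarray:
        """Per-cell count of overlapping ranges, over all species."""
        return self.grids.sum(axis=0).astype(np.int64)

    def to_directory(self, directory: str | Path) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        for sp, grid in zip(self.species_ids, self.grids):
            fname = re.sub(r"[\s/]+", "_", sp) + ".asc"
            write_ascii_grid(d / fname, grid, self.geometry)


@dataclass
class SiteTable:
    """Survey-site metadata: id, lon/lat, elevation (m), region label."""

    table: pd.DataFrame

    REQUIRED = ("site_id", "lon", "lat", "elevation_m", "region")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"site table missing columns: {missing}")
        ids = self.table["site_id"].astype(str)
        if ids.duplicated().any():
            raise ValueError("duplicate site ids")
        self.table = self.table.assign(site_id=ids).reset_index(drop=True)

    @property
    def site_ids(self) -> list[str]:
        return self.table["site_id"].tolist()

    def row(self, site_id: str) -> pd.Series:
        hit = self.table[self.table["site_id"] == site_id]
        if hit.empty:
            raise KeyError(f"unknown site {site_id!r}")
        return hit.iloc[0]

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "SiteTable":
        return cls(pd.read_csv(path))


@dataclass
class DispersionField:
    """Per-site grid counting overlapping ranges of the site's species."""

    site_id: str
    grid: np.ndarray
    species_count: int
    geometry: GridGeometry

    def __post_init__(self) -> None:
        g = np.asarray(self.grid)
        if g.shape != self.geometry.shape:
            raise ValueError("field grid does not match geometry")
        if (g < 0).any() or (g > self.species_count).any():
            raise ValueError("field values must lie in [0, species_count]")
        self.grid = g.astype(np.int64)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def build_presence_matrix(
    ranges: RangeGridSet,
    land_fraction: np.ndarray,
    min_land: float = 0.10,
    min_species: int = 3,
) -> PresenceMatrix:
    """Cells x species presence matrix under the land / richness filters.

    A cell becomes a row when its land fraction is >= ``min_land`` AND at
    least ``min_species`` breeding ranges overlap it. Rows are ordered
    row-major from the north-west corner; columns keep every species.
    """
    land = np.asarray(land_fraction, dtype=float)
    if land.shape != ranges.geometry.shape:
        raise ValueError(
            f"land grid {land.shape} does not match range geometry {ranges.geometry.shape}"
        )
    richness = ranges.richness()
    keep = (land >= min_land) & (richness >= min_species)
    rows, cols = np.nonzero(keep)
    if rows.size == 0:
        raise ValueError("no cells pass the land/richness filters")
    values = ranges.grids[:, rows, cols].T  # cells x species
    ids = [ranges.geometry.cell_id(r, c) for r, c in zip(rows, cols)]
    return PresenceMatrix(values, ids, list(ranges.species_ids))


def dispersion_field(
    site_species: Sequence[str],
    ranges: RangeGridSet,
    site_id: str = "site",
) -> DispersionField:
    """Assemblage dispersion field: per cell, how many of the listed
    species' ranges cover it."""
    if len(site_species) == 0:
        grid = np.zeros(ranges.geometry.shape, dtype=np.int64)
        return DispersionField(site_id, grid, 0, ranges.geometry)
    idx = ranges.lookup(site_species)
    grid = ranges.grids[idx].sum(axis=0).astype(np.int64)
    return DispersionField(site_id, grid, len(idx), ranges.geometry)


def stack_dispersion_fields(fields: Sequence[DispersionField]) -> CountMatrix:
    """Vectorize fields row-major from the NW corner and stack into a
    sites x cells count matrix; exactly invertible back to grids."""
    if not fields:
        raise ValueError("no fields to stack")
    geom = fields[0].geometry
    for f in fields[1:]:
        if f.geometry != geom:
            raise ValueError("all fields must share one geometry")
    values = np.stack([f.grid.reshape(-1) for f in fields])
    return CountMatrix(values, [f.site_id for f in fields], geom.all_cell_ids())


def unstack_row_to_grid(row_values: np.ndarray, geometry: GridGeometry) -> np.ndarray:
    """Inverse of the stacking vectorization for one matrix row."""
    v = np.asarray(row_values)
    if v.size != geometry.n_cells:
        raise ValueError(f"expected {geometry.n_cells} values, got {v.size}")
    return v.reshape(geometry.shape)


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O
# ---------------------------------------------------------------------------


def write_ascii_grid(path: str | Path, grid: np.ndarray, geometry: GridGeometry) -> None:
    grid = np.asarray(grid)
    if grid.shape != geometry.shape:
        raise ValueError("grid does not match geometry")
    header = (
        f"ncols {geometry.n_cols}\n"
        f"nrows {geometry.n_rows}\n"
        f"xllcorner {geometry.lon_min!r}\n"
        f"yllcorner {geometry.lat_min!r}\n"
        f"cellsize {geometry.resolution!r}\n"
        f"NODATA_value -9999\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, grid, fmt="%d" if np.issubdtype(grid.dtype, np.integer) else "%.10g")


def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, GridGeometry]:
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        grid = np.loadtxt(fh)
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    res = header["cellsize"]
    geom = GridGeometry(
        lon_min=header["xllcorner"],
        lon_max=header["xllcorner"] + ncols * res,
        lat_min=header["yllcorner"],
        lat_max=header["yllcorner"] + nrows * res,
        resolution=res,
    )
    grid = np.atleast_2d(grid)
    if grid.shape != (nrows, ncols):
        raise ValueError(f"grid body {grid.shape} disagrees with header ({nrows}, {ncols})")
    return grid, geom


def read_range_grids(directory: str | Path, pattern: str = "*.asc") -> RangeGridSet:
    """Load one-grid-per-species ASCII rasters from a directory."""
    d = Path(directory)
    files = sorted(d.glob(pattern))
    if not files:
        raise FileNotFoundError(f"no {pattern} grids under {d}")
    grids, names, geom = [], [], None
    for f in files:
        grid, g = read_ascii_grid(f)
        if geom is None:
            geom = g
        elif g != geom:
            raise ValueError(f"{f.name} has mismatched geometry")
        grids.append(grid)
        names.append(f.stem)
    return RangeGridSet(geom, names, np.stack(grids))
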