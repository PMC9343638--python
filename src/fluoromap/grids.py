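"""Planar raster grids and multi-band covariate stacks.

All grids are planar and axis-aligned: a grid is defined by its top-left
corner ``(x0, y0)``, a square cell size, and a shape ``(nrows, ncols)``.
Row 0 is the northernmost row (y decreases with row index), matching the
usual raster convention. Cells are half-open intervals ``[edge, edge + size)``
in both axes; points landing exactly on the maximum boundary are assigned
to the last cell so that the grid's bounding box is fully covered.

Rasters are written and read as ESRI ASCII grids (plain text), the common
interchange format for single-band grids.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

NODATA = -9999.0


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a planar raster grid."""

    nrows: int
    ncols: int
    x0: float = 0.0
    y0: float = 0.0
    cell_size: float = 1.0
    nodata: float = NODATA

    def __post_init__(self) -> None:
        if self.nrows <= 0 or self.ncols <= 0:
            raise ValueError(f"grid shape must be positive, got {(self.nrows, self.ncols)}")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nrows, self.ncols)

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax)."""
        return (
            self.x0,
            self.y0 - self.nrows * self.cell_size,
            self.x0 + self.ncols * self.cell_size,
            self.y0,
        )

    def cell_of(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Map point coordinates to (row, col, inside) arrays.

        Points on the max x / min y boundary are clamped into the last
        cell; anything strictly outside the bounds is flagged.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        xmin, ymin, xmax, ymax = self.bounds
        inside = (x >= xmin) & (x <= xmax) & (y >= ymin) & (y <= ymax)
        col = np.floor((x - self.x0) / self.cell_size).astype(int)
        row = np.floor((self.y0 - y) / self.cell_size).astype(int)
        col = np.clip(col, 0, self.ncols - 1)
        row = np.clip(row, 0, self.nrows - 1)
        return row, col, inside

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinate arrays of every cell center, shape (nrows, ncols)."""
        xs = self.x0 + (np.arange(self.ncols) + 0.5) * self.cell_size
        ys = self.y0 - (np.arange(self.nrows) + 0.5) * self.cell_size
        return np.meshgrid(xs, ys)


@dataclass
class Raster:
    """A single-band grid: a 2-D float array plus its geometry."""

    data: np.ndarray
    grid: GridSpec

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.shape != self.grid.shape:
            raise ValueError(
                f"data shape {self.data.shape} does not match grid {self.grid.shape}"
            )

    @property
    def mask(self) -> np.ndarray:
        """Boolean array, True where the cell holds valid data."""
        return ~np.isclose(self.data, self.grid.nodata) & ~np.isnan(self.data)

    def aligned_with(self, other: "Raster") -> bool:
        g, h = self.grid, other.grid
        return (
            g.shape == h.shape
            and np.isclose(g.x0, h.x0)
            and np.isclose(g.y0, h.y0)
            and np.isclose(g.cell_size, h.cell_size)
        )

    def sample(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Values at the cells containing the given points; returns (values, inside)."""
        row, col, inside = self.grid.cell_of(x, y)
        values = np.full(np.shape(row), np.nan, dtype=float)
        values[inside] = self.data[row[inside], col[inside]]
        return values, inside


@dataclass
class Band:
    """A named covariate layer with its semantic kind and native resolution."""

    name: str
    raster: Raster
    kind: str = "continuous"  # continuous | categorical
    categories: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "categorical"):
            raise ValueError(f"unknown band kind {self.kind!r}")
        if self.kind == "categorical" and self.categories is None:
            valid = self.raster.data[self.raster.mask]
            self.categories = tuple(sorted(int(v) for v in np.unique(valid)))

    @property
    def native_resolution(self) -> float:
        return self.raster.grid.cell_size


@dataclass
class CovariateStack:
    """An ordered collection of covariate bands over one spatial extent.

    Bands may live at different (integer-multiple) resolutions before
    harmonization; the *fine grid* is the grid of the finest band.
    """

    bands: dict[str, Band] = field(default_factory=dict)

    def add(self, band: Band) -> None:
        if band.name in self.bands:
            raise ValueError(f"duplicate band {band.name!r}")
        self.bands[band.name] = band

    @property
    def names(self) -> list[str]:
        return list(self.bands)

    @property
    def fine_grid(self) -> GridSpec:
        return min(
            (b.raster.grid for b in self.bands.values()), key=lambda g: g.cell_size
        )

    def is_harmonized(self) -> bool:
        grids = [b.raster.grid for b in self.bands.values()]
        return all(g == grids[0] for g in grids)

    def subset(self, names: list[str]) -> "CovariateStack":
        missing = [n for n in names if n not in self.bands]
        if missing:
            raise KeyError(f"bands not in stack: {missing}")
        out = CovariateStack()
        for n in names:
            out.add(self.bands[n])
        return out


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O


def write_ascii(raster: Raster, path: str | Path) -> None:
    g = raster.grid
    header = (
        f"ncols {g.ncols}\n"
        f"nrows {g.nrows}\n"
        f"xllcorner {g.x0!r}\n"
        f"yllcorner {g.y0 - g.nrows * g.cell_size!r}\n"
        f"cellsize {g.cell_size!r}\n"
        f"NODATA_value {g.nodata!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, raster.data, fmt="%.8g")


def read_ascii(path: str | Path) -> Raster:
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, value = fh.readline().split()
            header[key.lower()] = float(value)
        data = np.loadtxt(fh)
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    data = data.reshape(nrows, ncols)
    cell = header["cellsize"]
    grid = GridSpec(
        nrows=nrows,
        ncols=ncols,
        x0=header["xllcorner"],
        y0=header["yllcorner"] + nrows * cell,
        cell_size=cell,
        nodata=header.get("nodata_value", NODATA),
    )
    return Raster(data, grid)


def coarse_grid(fine: GridSpec, factor: int) -> GridSpec:
    """The grid covering the same extent at `factor`-times coarser cells."""
    if fine.nrows % factor or fine.ncols % factor:
        raise ValueError("fine grid shape must be divisible by the coarsening factor")
    return replace(
        fine,
        nrows=fine.nrows // factor,
        ncols=fine.ncols // factor,
        cell_size=fine.cell_size * factor,
    )
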