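"""Raster data model, canopy-height differencing and masking.

A canopy height model (CHM) is the cell-wise difference between a digital
surface model (DSM, altitude at the top of vegetation canopies) and a
digital terrain model (DTM, bare-ground altitude).  Before boundary
attribution the CHM is screened: cells falling in land-cover classes where
hedges cannot occur or be detected (built-up, woodland, littoral,
sub-littoral) or above an altitude cutoff are set to zero height.

Georeferencing convention: the origin is the grid's top-left corner, rows
increase southwards, and cell ``(r, c)`` covers the half-open square
``[x0 + c*s, x0 + (c+1)*s) x (y0 - (r+1)*s, y0 - r*s]``.  A point on a
shared cell edge therefore belongs to the cell to its east/south.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .errors import AlignmentError, ConfigurationError, CoverageError, ParameterError

DEFAULT_NODATA = -9999.0

#: land-cover class names that must be present in any legend
REQUIRED_CLASSES = frozenset({"built_up", "woodland", "littoral", "sublittoral", "other"})


@dataclass
class HeightGrid:
    """Georeferenced single-band raster of heights/altitudes in metres.

    Parameters
    ----------
    origin_x, origin_y
        Planar coordinates (m) of the top-left corner.
    cell_size
        Edge length of a square cell (m).
    values
        2-D array, rows north to south.
    nodata
        Sentinel excluded from every statistic.
    """

    origin_x: float
    origin_y: float
    cell_size: float
    values: np.ndarray
    nodata: float = DEFAULT_NODATA

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.cell_size <= 0:
            raise ParameterError(f"cell_size must be > 0, got {self.cell_size}")
        if self.values.ndim != 2 or self.values.size == 0:
            raise ParameterError("values must be a non-empty 2-D array")
        data = self.values[self.values != self.nodata]
        if data.size and not np.all(np.isfinite(data)):
            raise ParameterError("non-nodata values must be finite")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(min_x, min_y, max_x, max_y) of the grid extent."""
        return (
            self.origin_x,
            self.origin_y - self.n_rows * self.cell_size,
            self.origin_x + self.n_cols * self.cell_size,
            self.origin_y,
        )

    def data_mask(self) -> np.ndarray:
        """Boolean array, True where a cell holds real data."""
        return self.values != self.nodata

    def aligned_with(self, other: "HeightGrid | LandCoverGrid") -> bool:
        try:
            self.check_aligned(other)
        except AlignmentError:
            return False
        return True

    def check_aligned(self, other: "HeightGrid | LandCoverGrid") -> None:
        """Raise :class:`AlignmentError` naming the first mismatching field."""
        for name in ("origin_x", "origin_y", "cell_size"):
            a, b = getattr(self, name), getattr(other, name)
            if a != b:
                raise AlignmentError(f"grids are misaligned on {name}: {a} != {b}")
        if self.values.shape != other.values.shape:
            raise AlignmentError(
                f"grids are misaligned on shape: {self.values.shape} != {other.values.shape}"
            )

    def cell_index(self, x: float, y: float) -> tuple[int, int]:
        """Map a point to (row, col) by floor division.

        Interior cell edges are half-open (a point on a shared edge belongs
        to the cell to its east/south); the far south/east edges of the grid
        extent are closed, so points exactly on the extent boundary sample
        the last row/column rather than falling outside.
        """
        col = int(np.floor((x - self.origin_x) / self.cell_size))
        row = int(np.floor((self.origin_y - y) / self.cell_size))
        if col == self.n_cols and x == self.origin_x + self.n_cols * self.cell_size:
            col -= 1
        if row == self.n_rows and y == self.origin_y - self.n_rows * self.cell_size:
            row -= 1
        return row, col

    def contains_point(self, x: float, y: float) -> bool:
        r, c = self.cell_index(x, y)
        return 0 <= r < self.n_rows and 0 <= c < self.n_cols

    def value_at(self, x: float, y: float) -> float:
        """Value of the cell containing (x, y); CoverageError outside."""
        r, c = self.cell_index(x, y)
        if not (0 <= r < self.n_rows and 0 <= c < self.n_cols):
            raise CoverageError(
                f"point ({x}, {y}) falls outside the grid extent {self.bounds}"
            )
        return float(self.values[r, c])

    def sample(self, xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
        """Vectorised point lookup; any point outside raises CoverageError."""
        xs = np.asarray(xs, dtype=float)
        ys = np.asarray(ys, dtype=float)
        cols = np.floor((xs - self.origin_x) / self.cell_size).astype(int)
        rows = np.floor((self.origin_y - ys) / self.cell_size).astype(int)
        # far south/east extent edges are closed (see cell_index)
        x_max = self.origin_x + self.n_cols * self.cell_size
        y_min = self.origin_y - self.n_rows * self.cell_size
        cols = np.where((cols == self.n_cols) & (xs == x_max), cols - 1, cols)
        rows = np.where((rows == self.n_rows) & (ys == y_min), rows - 1, rows)
        bad = (rows < 0) | (rows >= self.n_rows) | (cols < 0) | (cols >= self.n_cols)
        if np.any(bad):
            i = int(np.argmax(bad))
            raise CoverageError(
                f"point ({xs.flat[i]}, {ys.flat[i]}) falls outside the grid extent {self.bounds}"
            )
        return self.values[rows, cols]

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(X, Y) arrays of cell-centre coordinates, same shape as values."""
        s = self.cell_size
        xs = self.origin_x + (np.arange(self.n_cols) + 0.5) * s
        ys = self.origin_y - (np.arange(self.n_rows) + 0.5) * s
        return np.meshgrid(xs, ys)

    def copy(self) -> "HeightGrid":
        return HeightGrid(self.origin_x, self.origin_y, self.cell_size,
                          self.values.copy(), self.nodata)


@dataclass
class LandCoverGrid:
    """Categorical raster with an integer-code legend.

    The legend must provide the class names used by masking (built_up,
    woodland, littoral, sublittoral, other); every cell code must appear
    in the legend.
    """

    origin_x: float
    origin_y: float
    cell_size: float
    values: np.ndarray
    legend: Mapping[int, str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.cell_size <= 0:
            raise ParameterError(f"cell_size must be > 0, got {self.cell_size}")
        if not np.issubdtype(self.values.dtype, np.integer):
            self.values = self.values.astype(int)
        codes = set(np.unique(self.values).tolist())
        missing = codes - set(self.legend)
        if missing:
            raise ConfigurationError(f"cell codes {sorted(missing)} missing from legend")

    # georeferencing helpers shared with HeightGrid
    n_rows = HeightGrid.n_rows
    n_cols = HeightGrid.n_cols
    bounds = HeightGrid.bounds
    check_aligned = HeightGrid.check_aligned
    aligned_with = HeightGrid.aligned_with
    cell_index = HeightGrid.cell_index

    def class_codes(self, names: set[str]) -> set[int]:
        """Legend codes whose class name is in ``names``."""
        return {code for code, name in self.legend.items() if name in names}


@dataclass
class MaskConfig:
    """Which areas are screened out of the canopy height model."""

    excluded_classes: frozenset = field(
        default_factory=lambda: frozenset({"built_up", "woodland", "littoral", "sublittoral"})
    )
    altitude_cutoff: float = 300.0

    def __post_init__(self) -> None:
        self.excluded_classes = frozenset(self.excluded_classes)
        if self.altitude_cutoff <= 0:
            raise ParameterError(f"altitude_cutoff must be > 0, got {self.altitude_cutoff}")


def canopy_height(dsm: HeightGrid, dtm: HeightGrid) -> HeightGrid:
    """Canopy height model: DSM minus DTM, nodata wherever either is nodata."""
    dsm.check_aligned(dtm)
    out = np.full_like(dsm.values, dsm.nodata)
    ok = dsm.data_mask() & dtm.data_mask()
    out[ok] = dsm.values[ok] - dtm.values[ok]
    return HeightGrid(dsm.origin_x, dsm.origin_y, dsm.cell_size, out, dsm.nodata)


def apply_mask(
    chm: HeightGrid,
    landcover: LandCoverGrid,
    terrain: HeightGrid,
    cfg: MaskConfig | None = None,
) -> HeightGrid:
    """Zero canopy heights in excluded land-cover classes or above the
    altitude cutoff.

    ``landcover`` must be aligned with ``chm``.  ``terrain`` may be a
    coarser grid (e.g. a 50-m screening DTM against a 5-m CHM); it is
    resampled to the CHM grid by nearest neighbour (each CHM cell centre
    looks up the terrain cell containing it) and must cover the CHM extent.
    Masked cells become 0; nodata cells stay nodata (missing, not masked).
    """
    cfg = cfg or MaskConfig()
    chm.check_aligned(landcover)
    legend_names = set(landcover.legend.values())
    missing = cfg.excluded_classes - legend_names
    if missing:
        raise ConfigurationError(
            f"legend is missing required class name(s): {sorted(missing)}"
        )

    if chm.aligned_with(terrain):
        altitude = terrain.values
    else:
        X, Y = chm.cell_centers()
        altitude = terrain.sample(X, Y)

    excluded_codes = landcover.class_codes(cfg.excluded_classes)
    excl = np.isin(landcover.values, list(excluded_codes)) if excluded_codes else np.zeros(
        chm.values.shape, dtype=bool
    )
    excl |= altitude > cfg.altitude_cutoff

    out = chm.values.copy()
    out[excl & chm.data_mask()] = 0.0
    return HeightGrid(chm.origin_x, chm.origin_y, chm.cell_size, out, chm.nodata)
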