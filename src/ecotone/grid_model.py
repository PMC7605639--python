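"""Georeferenced raster data model.

Grids are stored north-up: row 0 is the northernmost row, indices are
0-based, and the map coordinate of a pixel is its centre.  All geometry
comparisons use an absolute tolerance of 1e-9.  No reprojection is done
anywhere: layers must already share a CRS tag, and a mismatch is an error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import shapely

GEOM_ATOL = 1e-9

#: vegetation-occurrence label codes
ABSENT = -1
SUBTROPICAL = 0
TEMPERATE = 1


class AlignmentError(ValueError):
    """Raised when covariate layers do not share a grid geometry."""


class UnusablePairError(ValueError):
    """Raised when a vegetation pair lacks pixels of one (or both) classes."""


@dataclass(frozen=True)
class GridGeometry:
    """Shared placement of a raster: NW-corner origin, square cells, shape."""

    origin_x: float
    origin_y: float
    cell_size: float
    n_rows: int
    n_cols: int
    crs_tag: str = ""

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError(f"cell_size must be positive, got {self.cell_size}")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and one column")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def pixel_center(self, row, col):
        """Map coordinates of pixel centres (vectorised)."""
        x = self.origin_x + (np.asarray(col) + 0.5) * self.cell_size
        y = self.origin_y - (np.asarray(row) + 0.5) * self.cell_size
        return x, y

    def point_to_pixel(self, x, y):
        """Row/col of the pixel containing a map point (floor rule)."""
        col = np.floor((np.asarray(x) - self.origin_x) / self.cell_size).astype(int)
        row = np.floor((self.origin_y - np.asarray(y)) / self.cell_size).astype(int)
        return row, col

    def matches(self, other: "GridGeometry") -> bool:
        return (
            self.shape == other.shape
            and math.isclose(self.origin_x, other.origin_x, abs_tol=GEOM_ATOL)
            and math.isclose(self.origin_y, other.origin_y, abs_tol=GEOM_ATOL)
            and math.isclose(self.cell_size, other.cell_size, abs_tol=GEOM_ATOL)
            and self.crs_tag == other.crs_tag
        )


@dataclass
class Grid:
    """A single raster layer: values plus a nodata mask.

    Masked cells never enter any statistic; every operation that consumes a
    Grid must honour ``nodata_mask``.
    """

    values: np.ndarray
    geometry: GridGeometry
    nodata_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("Grid values must be 2-D")
        if self.nodata_mask is None:
            self.nodata_mask = np.zeros(self.values.shape, dtype=bool)
        self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        if self.nodata_mask.shape != self.values.shape:
            raise ValueError("values and nodata_mask must have identical shape")
        if self.values.shape != self.geometry.shape:
            raise ValueError(
                f"values shape {self.values.shape} != geometry shape {self.geometry.shape}"
            )

    @classmethod
    def from_array(
        cls,
        values,
        origin_x: float = 0.0,
        origin_y: float | None = None,
        cell_size: float = 1.0,
        crs_tag: str = "",
        nodata_mask=None,
    ) -> "Grid":
        values = np.asarray(values, dtype=float)
        if origin_y is None:
            origin_y = values.shape[0] * cell_size
        geom = GridGeometry(origin_x, origin_y, cell_size, *values.shape, crs_tag)
        return cls(values, geom, nodata_mask)


@dataclass
class CovariateStack:
    """Ordered, named raster layers sharing one geometry (co-registered)."""

    layers: dict[str, Grid]

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("CovariateStack needs at least one layer")
        assert_aligned(self)

    @property
    def geometry(self) -> GridGeometry:
        return next(iter(self.layers.values())).geometry

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    def __getitem__(self, name: str) -> Grid:
        return self.layers[name]

    def combined_mask(self, variables: Sequence[str] | None = None) -> np.ndarray:
        """True where ANY of the requested layers is masked."""
        names = self.names if variables is None else list(variables)
        mask = np.zeros(self.geometry.shape, dtype=bool)
        for name in names:
            mask |= self.layers[name].nodata_mask
        return mask


@dataclass(frozen=True)
class PairSpec:
    """One subtropical/temperate vegetation pairing (e.g. the two pines)."""

    group_id: str
    subtropical_name: str
    temperate_name: str

    def __post_init__(self) -> None:
        if self.subtropical_name == self.temperate_name:
            raise ValueError("pair names must be distinct")


@dataclass
class VegetationOccurrence:
    """Per-pixel labels for one pair: -1 absent, 0 subtropical, 1 temperate."""

    labels: np.ndarray
    pair: PairSpec
    geometry: GridGeometry

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.shape != self.geometry.shape:
            raise ValueError("labels shape must match geometry")
        bad = ~np.isin(self.labels, (ABSENT, SUBTROPICAL, TEMPERATE))
        if bad.any():
            raise ValueError("labels must be in {-1, 0, 1}")

    def require_usable(self) -> "VegetationOccurrence":
        if not (self.labels == SUBTROPICAL).any() or not (self.labels == TEMPERATE).any():
            raise UnusablePairError(
                f"pair {self.pair.group_id}: need at least one pixel of each class"
            )
        return self


def assert_aligned(stack: CovariateStack) -> CovariateStack:
    """Verify every layer shares the stack geometry; identity on success."""
    ref_name = next(iter(stack.layers))
    ref = stack.layers[ref_name].geometry
    for name, grid in stack.layers.items():
        if not grid.geometry.matches(ref):
            raise AlignmentError(
                f"layer {name!r} is not aligned with layer {ref_name!r}: "
                f"{grid.geometry} vs {ref}"
            )
    return stack


def aggregate_mean(grid: Grid, factor: int) -> Grid:
    """Block-mean resampling (e.g. 90 m elevation -> 1 km by averaging).

    Each output cell is the mean of the non-masked input cells in its
    factor x factor block; a fully masked block yields a masked cell.
    Partial blocks at the south/east edges average whatever cells exist.
    """
    if not isinstance(factor, (int, np.integer)) or factor <= 0:
        raise ValueError(f"factor must be a positive integer, got {factor!r}")
    factor = int(factor)
    if factor == 1:
        return Grid(grid.values.copy(), grid.geometry, grid.nodata_mask.copy())

    nr, nc = grid.values.shape
    out_r = -(-nr // factor)
    out_c = -(-nc // factor)
    # pad to full blocks with masked NaNs, then reduce with nanmean
    padded = np.full((out_r * factor, out_c * factor), np.nan)
    padded[:nr, :nc] = np.where(grid.nodata_mask, np.nan, grid.values)
    blocks = padded.reshape(out_r, factor, out_c, factor).swapaxes(1, 2)
    with np.errstate(invalid="ignore"):
        counts = np.sum(~np.isnan(blocks), axis=(2, 3))
        sums = np.nansum(blocks, axis=(2, 3))
    out_mask = counts == 0
    out_values = np.where(out_mask, 0.0, sums / np.maximum(counts, 1))
    g = grid.geometry
    geom = GridGeometry(
        g.origin_x, g.origin_y, g.cell_size * factor, out_r, out_c, g.crs_tag
    )
    return Grid(out_values, geom, out_mask)


def rasterize_occurrences(
    features: Iterable[tuple[shapely.Geometry, str]],
    geometry: GridGeometry,
    pair: PairSpec,
) -> VegetationOccurrence:
    """Burn vegetation features onto the grid as pair labels.

    A pixel whose centre falls inside a subtropical (resp. temperate)
    polygon gets 0 (resp. 1); point features label their containing pixel.
    A pixel claimed by both classes is set to -1 (excluded) to avoid label
    noise.  Features of other vegetation types are ignored.
    """
    features = list(features)
    class_of = {pair.subtropical_name: SUBTROPICAL, pair.temperate_name: TEMPERATE}
    hits: dict[int, np.ndarray] = {
        SUBTROPICAL: np.zeros(geometry.shape, dtype=bool),
        TEMPERATE: np.zeros(geometry.shape, dtype=bool),
    }
    rows, cols = np.meshgrid(
        np.arange(geometry.n_rows), np.arange(geometry.n_cols), indexing="ij"
    )
    cx, cy = geometry.pixel_center(rows.ravel(), cols.ravel())

    for geom, veg_type in features:
        label = class_of.get(veg_type)
        if label is None:
            continue
        gtype = shapely.get_type_id(geom)
        if gtype in (0, 4):  # Point / MultiPoint: label the containing pixel
            pts = shapely.get_coordinates(geom)
            r, c = geometry.point_to_pixel(pts[:, 0], pts[:, 1])
            ok = (r >= 0) & (r < geometry.n_rows) & (c >= 0) & (c < geometry.n_cols)
            hits[label][r[ok], c[ok]] = True
        else:
            inside = shapely.contains_xy(geom, cx, cy).reshape(geometry.shape)
            hits[label] |= inside

    labels = np.full(geometry.shape, ABSENT, dtype=int)
    labels[hits[SUBTROPICAL]] = SUBTROPICAL
    labels[hits[TEMPERATE]] = TEMPERATE
    labels[hits[SUBTROPICAL] & hits[TEMPERATE]] = ABSENT
    occ = VegetationOccurrence(labels, pair, geometry)
    return occ.require_usable()


def extract_labeled_pixels(
    stack: CovariateStack,
    occ: VegetationOccurrence,
    variables: Sequence[str],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Training matrix for a pair: one row per labelled, fully observed pixel.

    Returns ``(features, labels, flat_indices)`` in row-major pixel order;
    a pixel masked in ANY requested variable is excluded.
    """
    missing = [v for v in variables if v not in stack.layers]
    if missing:
        raise KeyError(f"variables not in stack: {missing}")
    if not stack.geometry.matches(occ.geometry):
        raise AlignmentError("occurrence geometry does not match stack geometry")
    labeled = occ.labels >= 0
    keep = labeled & ~stack.combined_mask(variables)
    idx = np.flatnonzero(keep.ravel())
    if idx.size == 0:
        raise UnusablePairError(
            f"pair {occ.pair.group_id}: no training pixels after masking"
        )
    features = np.column_stack(
        [stack.layers[v].values.ravel()[idx] for v in variables]
    )
    labels = occ.labels.ravel()[idx]
    return features, labels, idx
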