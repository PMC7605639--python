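"""Inter-zone boundary polylines and the composed transition band.

The boundary of a two-zone map is the set of pixel edges shared by a
subtropical (0) pixel and a temperate (1) pixel, using 4-connectivity;
unit edge segments are chained into maximal polylines in map coordinates.

Several vegetation pairs give several boundaries.  The transition zone is
the band they jointly sweep: per raster column (west to east) the
northernmost and southernmost boundary crossings over all pairs bound the
band (inclusive); pixels north of the band are temperate, pixels south of
it subtropical.  Columns crossed by no boundary inherit the envelopes of
the nearest crossed column and are excluded from the mean width.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import LineString, MultiLineString, box
from shapely.ops import linemerge, unary_union

from .grid_model import GridGeometry, PairSpec
from .zonation import ZoneMap

ZONE_SUBTROPICAL = 0
ZONE_TRANSITION = 1
ZONE_TEMPERATE = 2
ZONE_MASKED = -1

THREE_ZONE_NAMES = {
    ZONE_SUBTROPICAL: "subtropical",
    ZONE_TRANSITION: "transition",
    ZONE_TEMPERATE: "temperate",
}


@dataclass
class BoundarySet:
    """Maximal polylines separating the two zones of one pair's map."""

    lines: list[LineString]
    pair: PairSpec | None
    geometry: GridGeometry

    @property
    def total_length(self) -> float:
        return float(sum(line.length for line in self.lines))

    @property
    def n_unit_edges(self) -> int:
        return round(self.total_length / self.geometry.cell_size)

    def is_empty(self) -> bool:
        return not self.lines


@dataclass
class TransitionZone:
    polygon: shapely.Geometry
    north_boundary: LineString
    south_boundary: LineString
    north_rows: np.ndarray      # per-column northern envelope (edge-row index)
    south_rows: np.ndarray      # per-column southern envelope (edge-row index)
    interpolated: np.ndarray    # columns filled by nearest-column interpolation
    width_profile: np.ndarray   # per-column north-south extent, km
    mean_width: float           # km, over interpolation-free columns
    km_per_cell: float


@dataclass
class ThreeZonePartition:
    """Raster labelling each pixel subtropical, transition or temperate."""

    zones: np.ndarray
    geometry: GridGeometry

    def __post_init__(self) -> None:
        self.zones = np.asarray(self.zones, dtype=int)
        if self.zones.shape != self.geometry.shape:
            raise ValueError("zones shape must match geometry")
        if not np.isin(
            self.zones,
            (ZONE_MASKED, ZONE_SUBTROPICAL, ZONE_TRANSITION, ZONE_TEMPERATE),
        ).all():
            raise ValueError("zone codes must be in {-1, 0, 1, 2}")

    def counts(self) -> dict[int, int]:
        codes, n = np.unique(self.zones, return_counts=True)
        return dict(zip(codes.tolist(), n.tolist()))

    def zone_indices(self, code: int) -> np.ndarray:
        return np.flatnonzero(self.zones.ravel() == code)


def extract_boundary(zonemap: ZoneMap) -> BoundarySet:
    """Chain the 0/1-adjacent pixel edges into maximal polylines.

    Edges touching a masked pixel contribute nothing.  A single-class map
    yields an empty set with a warning.
    """
    z = zonemap.zones
    g = zonemap.geometry
    ox, oy, cs = g.origin_x, g.origin_y, g.cell_size

    segments: list[tuple[tuple[float, float], tuple[float, float]]] = []
    # vertical edges between horizontally adjacent pixels
    left, right = z[:, :-1], z[:, 1:]
    vr, vc = np.nonzero((left >= 0) & (right >= 0) & (left != right))
    for r, c in zip(vr.tolist(), vc.tolist()):
        x = ox + (c + 1) * cs
        segments.append(((x, oy - r * cs), (x, oy - (r + 1) * cs)))
    # horizontal edges between vertically adjacent pixels
    top, bottom = z[:-1, :], z[1:, :]
    hr, hc = np.nonzero((top >= 0) & (bottom >= 0) & (top != bottom))
    for r, c in zip(hr.tolist(), hc.tolist()):
        y = oy - (r + 1) * cs
        segments.append(((ox + c * cs, y), (ox + (c + 1) * cs, y)))

    if not segments:
        warnings.warn("zone map has a single class: empty boundary set",
                      stacklevel=2)
        return BoundarySet([], zonemap.pair, g)
    merged = linemerge(MultiLineString(segments))
    if isinstance(merged, LineString):
        lines = [merged]
    else:
        lines = list(merged.geoms)
    return BoundarySet(lines, zonemap.pair, g)


def boundary_crossing_rows(
    boundary: BoundarySet, geometry: GridGeometry
) -> list[np.ndarray]:
    """Edge-row indices where the boundary crosses each column's centre line.

    Edge row r is the horizontal pixel edge between rows r-1 and r; a
    boundary crossing at edge row r means the pixel rows r and above/below
    lie in different zones.  Columns the boundary does not cross get an
    empty array.
    """
    ox, oy, cs = geometry.origin_x, geometry.origin_y, geometry.cell_size
    out: list[np.ndarray] = []
    union = unary_union(boundary.lines) if boundary.lines else None
    y0, y1 = oy - geometry.n_rows * cs, oy
    for c in range(geometry.n_cols):
        if union is None:
            out.append(np.empty(0, dtype=int))
            continue
        x = ox + (c + 0.5) * cs
        cross = union.intersection(LineString([(x, y0 - cs), (x, y1 + cs)]))
        ys = shapely.get_coordinates(cross)[:, 1] if not cross.is_empty else []
        rows = np.unique(np.rint((oy - np.asarray(ys)) / cs).astype(int))
        out.append(rows)
    return out


def boundary_median_rows(
    boundary: BoundarySet, geometry: GridGeometry
) -> np.ndarray:
    """Per-column boundary position: median crossing row (NaN if uncrossed).

    The median is robust to isolated misclassified pixels away from the
    main boundary, so it is the summary used to score boundary recovery
    against a known truth.
    """
    out = np.full(geometry.n_cols, np.nan)
    for c, rows in enumerate(boundary_crossing_rows(boundary, geometry)):
        if rows.size:
            out[c] = float(np.median(rows))
    return out


def _interp_nearest(values: np.ndarray, known: np.ndarray) -> np.ndarray:
    """Fill unknown columns with the value of the nearest known column
    (ties go west)."""
    idx = np.flatnonzero(known)
    if idx.size == 0:
        raise ValueError("no known columns to interpolate from")
    cols = np.arange(values.size)
    dist = np.abs(cols[:, None] - idx[None, :])
    nearest = idx[np.argmin(dist, axis=1)]
    filled = values.copy()
    filled[~known] = values[nearest[~known]]
    return filled


def _step_polyline(geometry: GridGeometry, edge_rows: np.ndarray) -> LineString:
    """Per-column horizontal edge rows -> a west-to-east step polyline."""
    ox, oy, cs = geometry.origin_x, geometry.origin_y, geometry.cell_size
    pts: list[tuple[float, float]] = []
    for c, r in enumerate(edge_rows.tolist()):
        y = oy - r * cs
        p0, p1 = (ox + c * cs, y), (ox + (c + 1) * cs, y)
        if not pts or pts[-1] != p0:
            pts.append(p0)
        pts.append(p1)
    return LineString(pts)


def compose_transition(
    boundaries: list[BoundarySet],
    geometry: GridGeometry,
    nodata_mask: np.ndarray | None = None,
    km_per_cell: float | None = None,
) -> tuple[TransitionZone, ThreeZonePartition]:
    """Compose several pairs' boundaries into the transition band.

    ``km_per_cell`` defaults to cell_size/1000 (metre CRS, as with 1-km
    cells); pass 1.0 for cell-unit widths or the true scale for degree
    grids.  Coincident boundaries yield a one-pixel-high band so the
    three-zone partition always exists.
    """
    nonempty = [b for b in boundaries if not b.is_empty()]
    if not nonempty:
        raise ValueError("all boundary sets are empty; nothing to compose")
    if len(nonempty) < 2:
        warnings.warn("composing a single boundary set: band degenerates to "
                      "that boundary", stacklevel=2)
    if km_per_cell is None:
        km_per_cell = geometry.cell_size / 1000.0

    n_cols = geometry.n_cols
    north = np.full(n_cols, np.iinfo(int).max)
    south = np.full(n_cols, np.iinfo(int).min)
    crossed = np.zeros(n_cols, dtype=bool)
    for b in nonempty:
        for c, rows in enumerate(boundary_crossing_rows(b, geometry)):
            if rows.size:
                crossed[c] = True
                north[c] = min(north[c], int(rows.min()))
                south[c] = max(south[c], int(rows.max()))
    if not crossed.any():
        raise ValueError("no boundary crosses any column centre line")
    north = _interp_nearest(np.where(crossed, north, 0), crossed)
    south = _interp_nearest(np.where(crossed, south, 0), crossed)
    # band rows are inclusive: [north, south]; clamp inside the raster
    north = np.clip(north, 0, geometry.n_rows - 1)
    south = np.clip(south, 0, geometry.n_rows - 1)

    rows = np.arange(geometry.n_rows)[:, None]
    zones = np.where(
        rows < north[None, :],
        ZONE_TEMPERATE,
        np.where(rows > south[None, :], ZONE_SUBTROPICAL, ZONE_TRANSITION),
    )
    if nodata_mask is not None:
        zones = np.where(nodata_mask, ZONE_MASKED, zones)
    partition = ThreeZonePartition(zones, geometry)

    width = (south - north + 1).astype(float) * km_per_cell
    mean_width = float(width[crossed].mean())
    ox, oy, cs = geometry.origin_x, geometry.origin_y, geometry.cell_size
    col_boxes = [
        box(ox + c * cs, oy - (south[c] + 1) * cs, ox + (c + 1) * cs, oy - north[c] * cs)
        for c in range(n_cols)
    ]
    zone = TransitionZone(
        polygon=unary_union(col_boxes),
        north_boundary=_step_polyline(geometry, north),
        south_boundary=_step_polyline(geometry, south + 1),
        north_rows=north,
        south_rows=south,
        interpolated=~crossed,
        width_profile=width,
        mean_width=mean_width,
        km_per_cell=km_per_cell,
    )
    return zone, partition
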