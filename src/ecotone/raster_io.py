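"""Plain-text raster and vector I/O.

Rasters travel as ESRI ASCII grid (.asc) with an optional sidecar ``.prj``
file holding the CRS tag; vectors as GeoJSON FeatureCollections whose
features carry a ``veg_type`` string property.  ASCII grid only supports
square cells, which matches the data model.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import numpy as np
import shapely
from shapely.geometry import mapping, shape

from .grid_model import Grid, GridGeometry

_NODATA = -9999.0


def write_ascii_grid(grid: Grid, path: str | Path, fmt: str = "%.10g") -> None:
    path = Path(path)
    g = grid.geometry
    values = np.where(grid.nodata_mask, _NODATA, grid.values)
    header = (
        f"ncols {g.n_cols}\n"
        f"nrows {g.n_rows}\n"
        f"xllcorner {g.origin_x!r}\n"
        f"yllcorner {g.origin_y - g.n_rows * g.cell_size!r}\n"
        f"cellsize {g.cell_size!r}\n"
        f"NODATA_value {_NODATA:g}\n"
    )
    with path.open("w") as fh:
        fh.write(header)
        np.savetxt(fh, values, fmt=fmt)
    if g.crs_tag:
        path.with_suffix(".prj").write_text(g.crs_tag + "\n")


def read_ascii_grid(path: str | Path) -> Grid:
    path = Path(path)
    header: dict[str, float] = {}
    with path.open() as fh:
        for _ in range(6):
            pos = fh.tell()
            parts = fh.readline().split()
            key = parts[0].lower()
            if key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
                       "nodata_value"):
                header[key] = float(parts[1])
            else:  # nodata line is optional in the format
                fh.seek(pos)
                break
        values = np.loadtxt(fh, ndmin=2)
    n_rows, n_cols = int(header["nrows"]), int(header["ncols"])
    if values.shape != (n_rows, n_cols):
        raise ValueError(f"{path}: data shape {values.shape} != header "
                         f"({n_rows}, {n_cols})")
    cell = header["cellsize"]
    nodata = header.get("nodata_value", _NODATA)
    prj = path.with_suffix(".prj")
    crs_tag = prj.read_text().strip() if prj.exists() else ""
    geom = GridGeometry(
        origin_x=header["xllcorner"],
        origin_y=header["yllcorner"] + n_rows * cell,
        cell_size=cell,
        n_rows=n_rows,
        n_cols=n_cols,
        crs_tag=crs_tag,
    )
    mask = values == nodata
    return Grid(np.where(mask, 0.0, values), geom, mask)


def write_geojson(
    features: Iterable[tuple[shapely.Geometry, dict]],
    path: str | Path,
) -> None:
    """Write (geometry, properties) pairs as a GeoJSON FeatureCollection."""
    fc = {
        "type": "FeatureCollection",
        "features": [
            {"type": "Feature", "geometry": mapping(geom), "properties": props}
            for geom, props in features
        ],
    }
    Path(path).write_text(json.dumps(fc, indent=1, sort_keys=True) + "\n")


def read_geojson(path: str | Path) -> list[tuple[shapely.Geometry, dict]]:
    fc = json.loads(Path(path).read_text())
    if fc.get("type") != "FeatureCollection":
        raise ValueError(f"{path}: expected a GeoJSON FeatureCollection")
    return [
        (shape(f["geometry"]), f.get("properties") or {})
        for f in fc["features"]
    ]


def read_vegetation_features(path: str | Path) -> list[tuple[shapely.Geometry, str]]:
    """Read occurrence features; each must carry a 'veg_type' property."""
    out = []
    for geom, props in read_geojson(path):
        if "veg_type" not in props:
            raise ValueError(f"{path}: feature missing 'veg_type' property")
        out.append((geom, str(props["veg_type"])))
    return out
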