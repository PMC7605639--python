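"""Synthetic mountain-transect landscapes with known ground truth.

The generator emulates the structure of a mid-latitude mountain study
area: climate covariates follow a smooth monotone north-south profile —
plateaus on either side of the climatic divide joined by a logistic ramp,
the way temperature, precipitation and accumulated temperature all jump
across a mountain barrier — measured with additive Gaussian noise; soil-like
nuisance covariates are spatially autocorrelated fields independent of
vegetation, and each vegetation pair occupies its climatic side of a known
boundary curve, observed only at a sparse fraction of pixels (vegetation
polygons never tile a whole climate zone).  Because the generating
boundary rows, response structure and seeds are recorded, every pipeline
stage can be scored against truth without external data.

Defaults are the package's reference study conditions: a 200 x 200 grid of
1-km cells, three vegetation pairs with flat true boundaries at rows
85/100/115 (a 31-row true transition band), gradient range 10 covariate
units, measurement noise sd 0.3 units, and 15% occupancy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy import ndimage
from scipy.special import expit

from .characterize_validate import QuadratRecord
from .grid_model import (
    ABSENT,
    SUBTROPICAL,
    TEMPERATE,
    CovariateStack,
    Grid,
    GridGeometry,
    PairSpec,
    VegetationOccurrence,
)

DEFAULT_PAIRS = (
    PairSpec("I", "Quercus fabri forest", "Quercus wutaishanica forest"),
    PairSpec("II", "Pinus massoniana forest", "Pinus tabuliformis forest"),
    PairSpec("III", "Cyclobalanopsis glauca forest", "Populus davidiana forest"),
)

DEFAULT_DRIVERS = ("meantem01", "pa", "tadem", "aat0")
DEFAULT_NUISANCE = ("soil_organic", "soil_nitrogen", "sand_content", "clay_content")


@dataclass
class SyntheticTruth:
    """Generating parameters of a simulated landscape."""

    boundary_rows: dict[str, float] = field(
        default_factory=lambda: {"I": 115.0, "II": 100.0, "III": 85.0}
    )
    boundary_amplitude: float = 0.0   # cells; sinusoidal bend of the boundary
    driver_variables: tuple[str, ...] = DEFAULT_DRIVERS
    nuisance_variables: tuple[str, ...] = DEFAULT_NUISANCE
    gradient_range: float = 10.0      # covariate units across the grid
    gradient_midpoint_row: float | None = None   # None: mean boundary row
    gradient_steepness_frac: float = 0.05        # ramp e-folding, fraction of rows
    ridge_amplitude: float = 0.0      # adds an east-west ridge to the last driver
    noise_sd: float = 0.3             # covariate units
    nuisance_corr_length: float = 5.0  # cells
    response_slope: float = 4.0       # quadrat count decay, per cell past boundary
    occupancy_rate: float = 0.15
    cell_size: float = 1000.0         # metres (1-km cells)
    crs_tag: str = "synthetic-metre-grid"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.occupancy_rate <= 1):
            raise ValueError("occupancy_rate must be in (0, 1]")
        if self.noise_sd < 0 or self.gradient_range <= 0:
            raise ValueError("noise_sd must be >= 0 and gradient_range > 0")
        if not self.boundary_rows:
            raise ValueError("at least one pair boundary is required")

    @classmethod
    def scaled_to_shape(cls, shape: tuple[int, int], **kwargs) -> "SyntheticTruth":
        """Default truth with the three pair boundaries (42.5/50/57.5% of the
        rows, i.e. 85/100/115 on the reference 200-row grid) scaled to fit."""
        n_rows = shape[0]
        kwargs.setdefault(
            "boundary_rows",
            {gid: round(frac * n_rows)
             for gid, frac in (("I", 0.575), ("II", 0.5), ("III", 0.425))},
        )
        return cls(**kwargs)

    def boundary_row_fn(self, group_id: str, cols: np.ndarray, n_cols: int) -> np.ndarray:
        """True boundary row per column (flat unless boundary_amplitude > 0)."""
        base = self.boundary_rows[group_id]
        if self.boundary_amplitude == 0:
            return np.full(np.asarray(cols).shape, float(base))
        bend = self.boundary_amplitude * np.sin(2 * np.pi * np.asarray(cols) / n_cols)
        return base + bend

    def pairs(self) -> list[PairSpec]:
        by_id = {p.group_id: p for p in DEFAULT_PAIRS}
        return [
            by_id.get(gid, PairSpec(gid, f"subtropical_{gid}", f"temperate_{gid}"))
            for gid in self.boundary_rows
        ]


def _correlated_field(rng: np.random.Generator, shape, corr_length: float) -> np.ndarray:
    """Zero-mean, unit-sd spatially autocorrelated Gaussian field."""
    white = rng.standard_normal(shape)
    smooth = ndimage.gaussian_filter(white, sigma=corr_length, mode="reflect")
    return (smooth - smooth.mean()) / smooth.std()


def generate_landscape(
    truth: SyntheticTruth,
    shape: tuple[int, int] = (200, 200),
) -> tuple[CovariateStack, dict[str, VegetationOccurrence], SyntheticTruth]:
    """Simulate the covariate stack and per-pair vegetation occurrences.

    Driver covariates carry the north-south climate gradient (values
    increase southward) plus i.i.d. Gaussian measurement noise; nuisance
    covariates are autocorrelated fields carrying no class signal.  A
    pixel is temperate when it lies north of its pair's boundary curve,
    subtropical otherwise, and is actually labelled with probability
    ``occupancy_rate``.
    """
    n_rows, n_cols = shape
    if n_rows < 2 or n_cols < 2:
        raise ValueError(f"degenerate shape {shape}")
    rng = np.random.default_rng(truth.seed)
    geom = GridGeometry(
        origin_x=0.0,
        origin_y=n_rows * truth.cell_size,
        cell_size=truth.cell_size,
        n_rows=n_rows,
        n_cols=n_cols,
        crs_tag=truth.crs_tag,
    )
    # climate fields across a mountain divide: plateaus on each side with a
    # smooth logistic ramp centred on the divide (the mean boundary row)
    mid = (
        float(np.mean(list(truth.boundary_rows.values())))
        if truth.gradient_midpoint_row is None
        else truth.gradient_midpoint_row
    )
    s = truth.gradient_steepness_frac * n_rows
    rows_f = np.arange(n_rows, dtype=float)[:, None]
    row_frac = rows_f / (n_rows - 1)
    gradient = truth.gradient_range * expit((rows_f - mid) / s) * np.ones((1, n_cols))

    layers: dict[str, Grid] = {}
    for i, name in enumerate(truth.driver_variables):
        values = gradient + rng.normal(0.0, truth.noise_sd, shape)
        last = i == len(truth.driver_variables) - 1
        if truth.ridge_amplitude and last:
            # east-west ridge bump, emulating an elevation covariate
            ridge = truth.ridge_amplitude * np.exp(
                -0.5 * ((row_frac - 0.5) / 0.15) ** 2
            ) * np.ones((1, n_cols))
            values = values + ridge
        layers[name] = Grid(values, geom)
    for name in truth.nuisance_variables:
        layers[name] = Grid(
            truth.gradient_range / 4.0
            * _correlated_field(rng, shape, truth.nuisance_corr_length),
            geom,
        )
    stack = CovariateStack(layers)

    rows = np.arange(n_rows)[:, None]
    cols = np.arange(n_cols)[None, :]
    occurrences: dict[str, VegetationOccurrence] = {}
    for pair in truth.pairs():
        b = truth.boundary_row_fn(pair.group_id, cols, n_cols)
        classes = np.where(rows < b, TEMPERATE, SUBTROPICAL)
        observed = rng.random(shape) < truth.occupancy_rate
        labels = np.where(observed, classes, ABSENT)
        occurrences[pair.group_id] = VegetationOccurrence(labels, pair, geom)
    return stack, occurrences, truth


#: validation indicator species and the side of the boundary they occupy
QUADRAT_SPECIES = {
    "Platycarya strobilacea": ("subtropical", "III"),
    "Pinus massoniana": ("subtropical", "II"),
    "Pinus tabuliformis": ("temperate", "II"),
}


def write_fixtures(
    truth: SyntheticTruth,
    out_dir,
    shape: tuple[int, int] = (200, 200),
    n_quadrats: int = 121,
) -> dict:
    """Write a simulated study area to disk as pipeline-ready files.

    Covariates become ASCII grids, each pair's labelled pixels become
    GeoJSON point features (pixel centres) with a ``veg_type`` property,
    quadrats a CSV, and the generating truth a YAML; returns a run-config
    dict pointing at the files, also written as ``run.yaml``.
    """
    from pathlib import Path

    import pandas as pd
    import yaml

    from . import raster_io

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stack, occurrences, _ = generate_landscape(truth, shape)
    geom = stack.geometry
    for name, grid in stack.layers.items():
        raster_io.write_ascii_grid(grid, out / f"{name}.asc")
    cfg: dict = {"covariates": {n: f"{n}.asc" for n in stack.names}, "pairs": []}
    for pair in truth.pairs():
        occ = occurrences[pair.group_id]
        feats = []
        for label, veg in ((SUBTROPICAL, pair.subtropical_name),
                           (TEMPERATE, pair.temperate_name)):
            rr, cc = np.nonzero(occ.labels == label)
            xs, ys = geom.pixel_center(rr, cc)
            feats += [
                (shapely.Point(x, y), {"veg_type": veg})
                for x, y in zip(xs.tolist(), ys.tolist())
            ]
        fname = f"occ_{pair.group_id}.geojson"
        raster_io.write_geojson(feats, out / fname)
        cfg["pairs"].append(
            {
                "group_id": pair.group_id,
                "subtropical": pair.subtropical_name,
                "temperate": pair.temperate_name,
                "occurrences": fname,
            }
        )
    records = generate_quadrats(truth, n_quadrats, shape)
    pd.DataFrame(
        [(r.x, r.y, r.species, r.count) for r in records],
        columns=["x", "y", "species", "count"],
    ).to_csv(out / "quadrats.csv", index=False, float_format="%.12g")
    cfg.update(
        {
            "quadrats": "quadrats.csv",
            "out_dir": "out",
            "threshold": 0.3,
            "k": 4,
        }
    )
    truth_dict = {
        "boundary_rows": {k: float(v) for k, v in truth.boundary_rows.items()},
        "gradient_range": truth.gradient_range,
        "noise_sd": truth.noise_sd,
        "occupancy_rate": truth.occupancy_rate,
        "seed": truth.seed,
        "shape": list(shape),
    }
    (out / "truth.yaml").write_text(yaml.safe_dump(truth_dict, sort_keys=True))
    (out / "run.yaml").write_text(yaml.safe_dump(cfg, sort_keys=True))
    return cfg


def generate_quadrats(
    truth: SyntheticTruth,
    n_quadrats: int = 121,
    shape: tuple[int, int] = (200, 200),
    seed: int | None = None,
    mean_count: float = 30.0,
) -> list[QuadratRecord]:
    """Simulate field-survey quadrats with boundary-dependent stem counts.

    Quadrat locations are uniform over the grid; each record's species is
    drawn from the indicator set and its count is Poisson with a mean that
    is ``mean_count`` on the species' own side of its pair's true boundary
    and decays exponentially (``response_slope`` cells e-folding) past it.
    """
    if n_quadrats < 1:
        raise ValueError("n_quadrats must be >= 1")
    n_rows, n_cols = shape
    rng = np.random.default_rng(truth.seed + 1 if seed is None else seed)
    species_names = list(QUADRAT_SPECIES)
    records: list[QuadratRecord] = []
    for _ in range(n_quadrats):
        row = rng.uniform(0, n_rows)
        col = rng.uniform(0, n_cols)
        species = species_names[rng.integers(len(species_names))]
        side, group = QUADRAT_SPECIES[species]
        if group not in truth.boundary_rows:
            group = next(iter(truth.boundary_rows))
        b = float(truth.boundary_row_fn(group, np.array([col]), n_cols)[0])
        # signed cells past the species' own boundary (positive = wrong side)
        excess = (b - row) if side == "subtropical" else (row - b)
        mean = mean_count * np.exp(-max(excess, 0.0) / truth.response_slope)
        count = int(rng.poisson(mean))
        x = col * truth.cell_size
        y = (n_rows - row) * truth.cell_size
        records.append(QuadratRecord(x, y, species, count))
    return records
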