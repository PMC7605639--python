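"""Binary max-margin zonation: SVM on index-system covariates.

Labelled pixels (0 subtropical, 1 temperate) train a support-vector
classifier on the pair's selected covariates; the fitted model is then
applied wall-to-wall to classify every non-masked pixel, yielding a
two-zone map.  Features are z-score standardised by default and classes
are inverse-frequency weighted, since the two vegetation types rarely
cover equal areas.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .grid_model import CovariateStack, GridGeometry, PairSpec
from .index_selection import IndexSystem

MASKED_ZONE = -1


@dataclass
class ZonerConfig:
    kernel: str = "rbf"          # "rbf" or "linear"
    C: float = 1.0
    kernel_scale: float | str = "auto"  # gamma; "auto" = 1/(n_feat * var)
    standardize: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError(f"C must be positive, got {self.C}")
        if self.kernel not in ("rbf", "linear"):
            raise ValueError(f"kernel must be 'rbf' or 'linear', got {self.kernel!r}")


@dataclass
class Zoner:
    """A fitted binary zone predictor plus the variables it expects."""

    model: Pipeline
    variables: list[str]
    cfg: ZonerConfig

    def predict(self, features: np.ndarray) -> np.ndarray:
        return self.model.predict(features).astype(int)

    def training_accuracy(self, features: np.ndarray, labels: np.ndarray) -> float:
        return float(np.mean(self.predict(features) == labels))


@dataclass
class ZoneMap:
    """Wall-to-wall two-zone raster: 0 subtropical, 1 temperate, -1 masked."""

    zones: np.ndarray
    pair: PairSpec | None
    index_system: IndexSystem | None
    geometry: GridGeometry

    def __post_init__(self) -> None:
        self.zones = np.asarray(self.zones, dtype=int)
        if not np.isin(self.zones, (-1, 0, 1)).all():
            raise ValueError("zone values must be in {-1, 0, 1}")


def fit_zoner(
    features: np.ndarray,
    labels: np.ndarray,
    cfg: ZonerConfig | None = None,
    variables: list[str] | None = None,
) -> Zoner:
    """Train the max-margin classifier on labelled pixel rows."""
    cfg = cfg or ZonerConfig()
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if features.ndim != 2 or features.shape[0] != labels.size:
        raise ValueError("features must be 2-D with one row per label")
    if not np.isfinite(features).all():
        raise ValueError("features contain non-finite values")
    present = np.unique(labels)
    if not np.array_equal(present, [0, 1]):
        raise ValueError(f"both classes required for training, got labels {present}")
    gamma = "scale" if cfg.kernel_scale == "auto" else cfg.kernel_scale
    svc = SVC(
        kernel=cfg.kernel,
        C=cfg.C,
        gamma=gamma,
        class_weight="balanced",
        random_state=cfg.seed,
    )
    steps = []
    if cfg.standardize:
        steps.append(("scale", StandardScaler()))
    steps.append(("svc", svc))
    model = Pipeline(steps)
    model.fit(features, labels)
    if variables is None:
        variables = [f"x{i}" for i in range(features.shape[1])]
    return Zoner(model, list(variables), cfg)


def predict_zonemap(
    zoner: Zoner,
    stack: CovariateStack,
    index_system: IndexSystem,
    block_rows: int = 256,
) -> ZoneMap:
    """Classify every non-masked pixel; masked pixels propagate as -1.

    Prediction streams in row blocks to bound memory on large rasters; the
    block size has no effect on the output.
    """
    missing = [v for v in index_system.variables if v not in stack.layers]
    if missing:
        raise KeyError(f"stack is missing index-system variables: {missing}")
    geom = stack.geometry
    mask = stack.combined_mask(index_system.variables)
    zones = np.full(geom.shape, MASKED_ZONE, dtype=int)
    for r0 in range(0, geom.n_rows, block_rows):
        r1 = min(r0 + block_rows, geom.n_rows)
        valid = ~mask[r0:r1]
        if not valid.any():
            continue
        rows = np.column_stack(
            [stack.layers[v].values[r0:r1][valid] for v in index_system.variables]
        )
        zones[r0:r1][valid] = zoner.predict(rows)
    return ZoneMap(zones, index_system.pair, index_system, geom)
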