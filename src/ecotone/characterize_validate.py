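"""Characterise the three zones and validate them against quadrat surveys.

Characterisation draws a fixed number of random pixels per zone (without
replacement), reports each index's per-zone mean, and quantifies the
stratified heterogeneity of the three-zone partition with a three-stratum
q-statistic on the pooled sample.

Validation grades field-quadrat stem counts into low/moderate/high bins
per indicator species and tabulates where each graded quadrat falls in the
partition; subtropical indicators are expected in the subtropical or
transition zones, temperate indicators in the temperate or transition
zones, and the per-species fraction meeting that expectation is the
consistency score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .boundary_transition import (
    THREE_ZONE_NAMES,
    ZONE_SUBTROPICAL,
    ZONE_TEMPERATE,
    ZONE_TRANSITION,
    ThreeZonePartition,
)
from .geodetector import StratifiedSample, factor_q
from .grid_model import CovariateStack

GRADES = ("low", "moderate", "high")
UNGRADED = "ungraded"


@dataclass(frozen=True)
class QuadratRecord:
    x: float
    y: float
    species: str
    count: int
    grade: str = UNGRADED

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValueError("count must be non-negative")


@dataclass
class GradeBins:
    """Per-species inclusive count intervals for low/moderate/high.

    The published field-survey grading: Platycarya strobilacea and Pinus
    massoniana (subtropical indicators) use 2-3 / 4-10 / 11-98; Pinus
    tabuliformis (temperate indicator) uses 2-10 / 11-20 / 21-60.  Counts
    outside every bin are left ungraded.
    """

    bins: dict[str, tuple[tuple[int, int], tuple[int, int], tuple[int, int]]]

    def __post_init__(self) -> None:
        for species, ivals in self.bins.items():
            flat = [v for lo_hi in ivals for v in lo_hi]
            if any(lo > hi for lo, hi in ivals):
                raise ValueError(f"{species}: interval lo > hi")
            if flat != sorted(flat):
                raise ValueError(f"{species}: intervals must be ordered and disjoint")

    @classmethod
    def survey_defaults(cls) -> "GradeBins":
        sub = ((2, 3), (4, 10), (11, 98))
        temp = ((2, 10), (11, 20), (21, 60))
        return cls({
            "Platycarya strobilacea": sub,
            "Pinus massoniana": sub,
            "Pinus tabuliformis": temp,
        })

    def grade(self, species: str, count: int) -> str:
        if species not in self.bins:
            warnings.warn(f"no grade bins for species {species!r}: ungraded",
                          stacklevel=2)
            return UNGRADED
        for name, (lo, hi) in zip(GRADES, self.bins[species]):
            if lo <= count <= hi:
                return name
        return UNGRADED


def sample_zones(
    partition: ThreeZonePartition,
    n_per_zone: int,
    seed: int = 0,
) -> dict[int, np.ndarray]:
    """Uniform without-replacement pixel sample (flat indices) per zone.

    A zone smaller than ``n_per_zone`` is taken in full with a warning.
    """
    if n_per_zone < 1:
        raise ValueError("n_per_zone must be >= 1")
    rng = np.random.default_rng(seed)
    out: dict[int, np.ndarray] = {}
    for code in (ZONE_SUBTROPICAL, ZONE_TRANSITION, ZONE_TEMPERATE):
        idx = partition.zone_indices(code)
        if idx.size == 0:
            raise ValueError(f"zone {THREE_ZONE_NAMES[code]} is empty")
        if idx.size < n_per_zone:
            warnings.warn(
                f"zone {THREE_ZONE_NAMES[code]} has only {idx.size} pixels "
                f"(< {n_per_zone}); taking all", stacklevel=2,
            )
            out[code] = np.sort(idx)
        else:
            out[code] = np.sort(rng.choice(idx, size=n_per_zone, replace=False))
    return out


def characterize(
    partition: ThreeZonePartition,
    stack: CovariateStack,
    indexes: list[str],
    n_per_zone: int = 500,
    seed: int = 0,
) -> pd.DataFrame:
    """Zone table: per-index three-stratum q and per-zone sample means.

    Rows are indexed by covariate name; columns are ``q`` plus
    ``mean_<zone>`` in raw covariate units.  Sampled pixels that are
    masked in an index are dropped for that index.
    """
    missing = [v for v in indexes if v not in stack.layers]
    if missing:
        raise KeyError(f"indexes not in stack: {missing}")
    samples = sample_zones(partition, n_per_zone, seed)
    rows = {}
    for name in indexes:
        vals = stack.layers[name].values.ravel()
        msk = stack.layers[name].nodata_mask.ravel()
        ys, hs = [], []
        row: dict[str, float] = {}
        for code, idx in samples.items():
            keep = idx[~msk[idx]]
            y = vals[keep]
            row[f"mean_{THREE_ZONE_NAMES[code]}"] = float(y.mean()) if y.size else float("nan")
            ys.append(y)
            hs.append(np.full(y.size, code))
        sample = StratifiedSample(np.concatenate(ys), np.concatenate(hs))
        row["q"] = factor_q(sample)
        rows[name] = row
    cols = ["q"] + [f"mean_{THREE_ZONE_NAMES[c]}" for c in
                    (ZONE_TEMPERATE, ZONE_TRANSITION, ZONE_SUBTROPICAL)]
    table = pd.DataFrame.from_dict(rows, orient="index")[cols].loc[indexes]
    table.index.name = "index"
    return table


def grade_quadrats(
    records: list[QuadratRecord], bins: GradeBins
) -> list[QuadratRecord]:
    """Assign each record its count grade (total: exactly one of four)."""
    return [
        QuadratRecord(r.x, r.y, r.species, r.count, bins.grade(r.species, r.count))
        for r in records
    ]


def overlay_consistency(
    records: list[QuadratRecord],
    partition: ThreeZonePartition,
    subtropical_indicators: set[str] | None = None,
    temperate_indicators: set[str] | None = None,
) -> dict:
    """Tabulate graded quadrats per zone and score indicator consistency.

    A subtropical indicator is consistent when its quadrat falls in the
    subtropical or transition zone; a temperate indicator when it falls in
    the temperate or transition zone.  Records outside the raster extent
    or without a grade are skipped.
    """
    if subtropical_indicators is None:
        subtropical_indicators = {"Platycarya strobilacea", "Pinus massoniana"}
    if temperate_indicators is None:
        temperate_indicators = {"Pinus tabuliformis"}
    geom = partition.geometry
    counts: dict[tuple[str, str, str], int] = {}
    consistent: dict[str, list[int]] = {}
    skipped = 0
    for rec in records:
        if rec.grade == UNGRADED:
            continue
        r, c = geom.point_to_pixel(rec.x, rec.y)
        if not (0 <= r < geom.n_rows and 0 <= c < geom.n_cols):
            skipped += 1
            continue
        code = int(partition.zones[r, c])
        if code == -1:
            skipped += 1
            continue
        zone = THREE_ZONE_NAMES[code]
        key = (rec.species, rec.grade, zone)
        counts[key] = counts.get(key, 0) + 1
        if rec.species in subtropical_indicators:
            ok = code in (ZONE_SUBTROPICAL, ZONE_TRANSITION)
        elif rec.species in temperate_indicators:
            ok = code in (ZONE_TEMPERATE, ZONE_TRANSITION)
        else:
            continue
        consistent.setdefault(rec.species, []).append(int(ok))
    if skipped:
        warnings.warn(f"{skipped} quadrats outside extent or masked: skipped",
                      stacklevel=2)
    table = pd.DataFrame(
        [(s, g, z, n) for (s, g, z), n in sorted(counts.items())],
        columns=["species", "grade", "zone", "n"],
    )
    fractions = {
        s: float(np.mean(v)) for s, v in sorted(consistent.items())
    }
    return {"zone_counts": table, "consistency": fractions, "skipped": skipped}
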