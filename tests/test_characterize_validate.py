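import numpy as np
import pytest

from ecotone import (
    CovariateStack,
    GradeBins,
    Grid,
    GridGeometry,
    QuadratRecord,
    ThreeZonePartition,
    characterize,
    grade_quadrats,
    overlay_consistency,
    sample_zones,
)
from .conftest import brute_force_q


@pytest.fixture
def banded_partition():
    """40x20 raster: temperate rows 0-11, transition 12-27, subtropical 28+."""
    rows = np.arange(40)[:, None] * np.ones((1, 20), int)
    zones = np.where(rows < 12, 2, np.where(rows < 28, 1, 0))
    geom = GridGeometry(0.0, 40.0, 1.0, 40, 20, "test")
    return ThreeZonePartition(zones, geom)


@pytest.fixture
def banded_stack(banded_partition):
    geom = banded_partition.geometry
    rows = np.arange(40, dtype=float)[:, None] * np.ones((1, 20))
    return CovariateStack({
        "grad": Grid(rows, geom),                      # north-south gradient
        "zoneid": Grid(banded_partition.zones.astype(float), geom),
        "const": Grid(np.full((40, 20), 3.3), geom),
    })


class TestSampleZones:
    def test_without_replacement_within_zone(self, banded_partition):
        samples = sample_zones(banded_partition, 100, seed=7)
        for code, idx in samples.items():
            assert len(np.unique(idx)) == 100
            assert (banded_partition.zones.ravel()[idx] == code).all()

    def test_small_zone_taken_in_full_with_warning(self, banded_partition):
        with pytest.warns(UserWarning):
            samples = sample_zones(banded_partition, 10_000, seed=0)
        counts = banded_partition.counts()
        for code, idx in samples.items():
            assert idx.size == counts[code]

    def test_different_seeds_same_summary_on_homogeneous_zone(self, banded_partition,
                                                              banded_stack):
        vals = banded_stack["const"].values.ravel()
        a = sample_zones(banded_partition, 150, seed=1)
        b = sample_zones(banded_partition, 150, seed=2)
        assert not all(np.array_equal(a[c], b[c]) for c in a)
        for code in a:
            assert vals[a[code]].mean() == pytest.approx(vals[b[code]].mean())

    def test_empty_zone_is_an_error(self):
        geom = GridGeometry(0.0, 4.0, 1.0, 4, 4, "test")
        part = ThreeZonePartition(np.zeros((4, 4), int), geom)
        with pytest.raises(ValueError):
            sample_zones(part, 5)


class TestCharacterize:
    def test_constant_covariate_has_equal_means_and_zero_q(self, banded_partition,
                                                           banded_stack):
        table = characterize(banded_partition, banded_stack, ["const"],
                             n_per_zone=100, seed=3)
        row = table.loc["const"]
        assert row["q"] == 0.0
        assert row["mean_temperate"] == row["mean_transition"] == \
            row["mean_subtropical"] == pytest.approx(3.3)

    def test_zone_id_covariate_has_unit_q_and_exact_means(self, banded_partition,
                                                          banded_stack):
        table = characterize(banded_partition, banded_stack, ["zoneid"],
                             n_per_zone=100, seed=3)
        row = table.loc["zoneid"]
        assert row["q"] == 1.0
        assert row["mean_temperate"] == 2.0
        assert row["mean_transition"] == 1.0
        assert row["mean_subtropical"] == 0.0

    def test_transition_mean_between_other_zones_for_gradient(self, banded_partition,
                                                              banded_stack):
        table = characterize(banded_partition, banded_stack, ["grad"],
                             n_per_zone=150, seed=5)
        row = table.loc["grad"]
        assert row["mean_temperate"] < row["mean_transition"] < \
            row["mean_subtropical"]

    def test_full_census_is_seed_independent(self, banded_partition, banded_stack):
        n_all = max(banded_partition.counts().values())
        with pytest.warns(UserWarning):
            t1 = characterize(banded_partition, banded_stack, ["grad"],
                              n_per_zone=n_all, seed=1)
        with pytest.warns(UserWarning):
            t2 = characterize(banded_partition, banded_stack, ["grad"],
                              n_per_zone=n_all, seed=999)
        assert t1.equals(t2)

    def test_three_strata_q_matches_brute_force(self, banded_partition,
                                                banded_stack):
        table = characterize(banded_partition, banded_stack, ["grad"],
                             n_per_zone=120, seed=11)
        samples = sample_zones(banded_partition, 120, seed=11)
        vals = banded_stack["grad"].values.ravel()
        y = np.concatenate([vals[samples[c]] for c in samples])
        h = np.concatenate([np.full(samples[c].size, c) for c in samples])
        assert table.loc["grad", "q"] == pytest.approx(brute_force_q(y, h),
                                                       abs=1e-12)


class TestGradeQuadrats:
    def test_survey_bin_membership(self):
        bins = GradeBins.survey_defaults()
        recs = [
            QuadratRecord(0, 0, "Platycarya strobilacea", 5),
            QuadratRecord(0, 0, "Pinus tabuliformis", 21),
            QuadratRecord(0, 0, "Pinus massoniana", 1),
            QuadratRecord(0, 0, "Pinus massoniana", 98),
        ]
        graded = grade_quadrats(recs, bins)
        assert [r.grade for r in graded] == ["moderate", "high", "ungraded", "high"]

    def test_unknown_species_ungraded_with_warning(self):
        with pytest.warns(UserWarning):
            graded = grade_quadrats(
                [QuadratRecord(0, 0, "Quercus fabri", 5)],
                GradeBins.survey_defaults(),
            )
        assert graded[0].grade == "ungraded"

    def test_grading_is_total(self):
        bins = GradeBins.survey_defaults()
        recs = [QuadratRecord(0, 0, "Pinus tabuliformis", c) for c in range(0, 70)]
        for r in grade_quadrats(recs, bins):
            assert r.grade in ("low", "moderate", "high", "ungraded")

    def test_disordered_bins_rejected(self):
        with pytest.raises(ValueError):
            GradeBins({"x": ((5, 10), (2, 4), (11, 20))})


class TestOverlayConsistency:
    def test_all_indicators_in_expected_zone_score_one(self, banded_partition):
        recs = grade_quadrats(
            [QuadratRecord(5.5, 3.5, "Pinus massoniana", 20),   # deep south
             QuadratRecord(6.5, 38.5, "Pinus tabuliformis", 15)],  # far north
            GradeBins.survey_defaults(),
        )
        out = overlay_consistency(recs, banded_partition)
        assert out["consistency"] == {"Pinus massoniana": 1.0,
                                      "Pinus tabuliformis": 1.0}

    def test_zero_records_give_empty_summary(self, banded_partition):
        out = overlay_consistency([], banded_partition)
        assert out["zone_counts"].empty
        assert out["consistency"] == {}

    def test_record_outside_extent_skipped_with_warning(self, banded_partition):
        recs = grade_quadrats(
            [QuadratRecord(-5.0, 2.0, "Pinus massoniana", 20),
             QuadratRecord(5.5, 3.5, "Pinus massoniana", 20)],
            GradeBins.survey_defaults(),
        )
        with pytest.warns(UserWarning):
            out = overlay_consistency(recs, banded_partition)
        assert out["skipped"] == 1
        assert out["zone_counts"]["n"].sum() == 1

    def test_misplaced_indicator_lowers_fraction(self, banded_partition):
        recs = grade_quadrats(
            [QuadratRecord(5.5, 3.5, "Pinus tabuliformis", 15),   # south: wrong
             QuadratRecord(6.5, 38.5, "Pinus tabuliformis", 15)],  # north: right
            GradeBins.survey_defaults(),
        )
        out = overlay_consistency(recs, banded_partition)
        assert out["consistency"]["Pinus tabuliformis"] == pytest.approx(0.5)
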