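"""Sea-ice covariates: radius average, patch filtering, signed edge distance."""

import numpy as np
import pytest

from bowpam.ice_metrics import (IceField, classify_and_filter, edge_distance,
                                ice_covariates, mean_concentration,
                                patch_area_km2)
from bowpam.scene_synth import IceGeometrySpec, synth_icefield
from conftest import brute_edge_distance, brute_mean_concentration


def random_field(rng, shape=(64, 64)):
    from scipy.ndimage import gaussian_filter
    raw = gaussian_filter(rng.standard_normal(shape), sigma=2.0)
    conc = np.clip((raw - raw.min()) / (raw.max() - raw.min()) * 130 - 15,
                   0, 100)
    r = tuple(int(v) for v in rng.integers(0, shape[0], 2))
    return IceField(concentration=conc, recorder_row=r[0], recorder_col=r[1])


class TestPatchArea:
    def test_fifty_cell_patch_area(self):
        assert patch_area_km2(50) == pytest.approx(488.28125)


class TestMeanConcentration:
    def test_constant_field(self):
        field = IceField(np.full((30, 30), 80.0), recorder_row=15,
                         recorder_col=15)
        assert mean_concentration(field) == pytest.approx(80.0)

    def test_half_plane_symmetry(self):
        field = synth_icefield(IceGeometrySpec(
            (41, 41), "half_plane", {"edge_col": 19, "conc_ice": 100.0},
            recorder=(20, 20)))
        # recorder sits on the first water column next to the boundary
        assert mean_concentration(field) == pytest.approx(50.0, abs=5.0)

    def test_no_cells_in_radius_is_undefined(self):
        field = IceField(np.full((5, 5), np.nan), recorder_row=2,
                         recorder_col=2)
        assert np.isnan(mean_concentration(field))

    def test_bounded_by_in_radius_extremes(self, rng):
        field = random_field(rng)
        m = mean_concentration(field)
        dist = field.cell_distances_km()
        sel = dist <= 35.0
        assert field.concentration[sel].min() <= m <= field.concentration[sel].max()


class TestClassifyAndFilter:
    def patch_field(self, n_cells):
        # a rectangular ice patch of n_cells in open water, plus a large
        # ice slab far away so an edge target always survives
        conc = np.zeros((60, 60))
        conc[:, 55:] = 90.0                     # big slab, 300 cells
        rows, cols = 5, n_cells // 5
        conc[10:10 + rows, 10:10 + cols] = 90.0
        extra = n_cells - rows * cols
        if extra:
            conc[10 + rows, 10:10 + extra] = 90.0
        return IceField(conc, recorder_row=12, recorder_col=2)

    def test_boundary_at_fifty_cells(self):
        filt50 = classify_and_filter(self.patch_field(50))
        assert not filt50.ice_candidates[10:15, 10:20].any()
        filt51 = classify_and_filter(self.patch_field(51))
        assert filt51.ice_candidates[10:15, 10:20].any()

    def test_threshold_boundary_is_ice(self):
        conc = np.zeros((80, 3))
        conc[0, 0] = 15.0
        filt = classify_and_filter(IceField(conc))
        assert filt.ice_mask[0, 0]

    def test_small_water_patches_also_excluded(self):
        conc = np.full((60, 60), 90.0)
        conc[20:23, 20:23] = 0.0  # 9-cell pond
        filt = classify_and_filter(IceField(conc, recorder_row=0,
                                            recorder_col=0))
        assert not filt.water_candidates[20:23, 20:23].any()


class TestEdgeDistance:
    def test_half_plane_water_side(self):
        field = synth_icefield(IceGeometrySpec(
            (64, 64), "half_plane", {"edge_col": 10}, recorder=(30, 22)))
        ed = edge_distance(field)
        assert ed.defined and ed.value_km == pytest.approx(37.5)

    def test_half_plane_ice_side(self):
        field = synth_icefield(IceGeometrySpec(
            (64, 64), "half_plane", {"edge_col": 12}, recorder=(30, 5)))
        ed = edge_distance(field)
        assert ed.defined and ed.value_km == pytest.approx(-25.0)

    def test_uniform_field_undefined(self):
        field = synth_icefield(IceGeometrySpec((20, 20), "uniform",
                                               {"value": 0.0}))
        assert not edge_distance(field).defined

    def test_patch_exclusion_changes_distance(self):
        field = TestClassifyAndFilter().patch_field(50)
        near = TestClassifyAndFilter().patch_field(51)
        d_excluded = edge_distance(field).value_km
        d_near = edge_distance(near).value_km
        assert d_excluded > d_near  # small patch skipped, slab used instead

    def test_filtering_monotonicity(self, rng):
        for _ in range(10):
            field = random_field(rng)
            d_filtered = edge_distance(field)
            d_raw = edge_distance(field, max_patch=0)
            if d_filtered.defined and d_raw.defined:
                assert abs(d_filtered.value_km) >= abs(d_raw.value_km)

    def test_sign_convention(self, rng):
        for _ in range(10):
            field = random_field(rng)
            ed = edge_distance(field)
            if ed.defined:
                in_ice = field.concentration[field.recorder_row,
                                             field.recorder_col] >= 15
                assert (ed.value_km < 0) == bool(in_ice)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(10):
            field = random_field(rng, shape=(32, 32))
            ed = edge_distance(field)
            expected = brute_edge_distance(field)
            if expected is None:
                assert not ed.defined
            else:
                assert ed.value_km == pytest.approx(expected)
            m = mean_concentration(field)
            assert m == pytest.approx(brute_mean_concentration(field, 35.0))


class TestGeolocatedGrids:
    def test_great_circle_distances(self):
        lat, lon = np.meshgrid(np.arange(78.0, 78.5, 0.1),
                               np.arange(5.0, 5.5, 0.1), indexing="ij")
        conc = np.zeros(lat.shape)
        conc[0, :] = 90.0
        field = IceField(conc, recorder_row=2, recorder_col=2,
                         lat=lat, lon=lon)
        ed = edge_distance(field, max_patch=0)  # grid too small for patches
        # 0.2 degrees of latitude is ~22.2 km on a 6371-km sphere
        assert ed.defined and ed.value_km == pytest.approx(22.24, abs=0.1)


class TestCovariateTable:
    def test_per_day_rows(self):
        fields = {f"2023-01-0{d}": synth_icefield(IceGeometrySpec(
            (40, 40), "half_plane", {"edge_col": 5 + d}, recorder=(20, 30)))
            for d in range(1, 4)}
        table = ice_covariates(fields)
        assert list(table.columns) == ["date", "mean_concentration_pct",
                                       "edge_distance_km", "defined"]
        assert len(table) == 3
        assert table["defined"].all()
        assert (table["edge_distance_km"].to_numpy()
                == np.array([24 * 3.125, 23 * 3.125, 22 * 3.125])).all()
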