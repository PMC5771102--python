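"""Observable extraction: volumes, fluxes, crossings, interpolation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cryovessel as cv
from cryovessel.bioheat import TemperatureField
from cryovessel.geometry import Label, LabeledGrid
from cryovessel.metrics import (EXCEEDS_HORIZON, MetricSeries,
                                frozen_component_count, treatment_time)


def _tissue_grid(n=32, h=1.0):
    labels = np.full((n, n, n), Label.TISSUE, dtype=np.uint8)
    return LabeledGrid(labels=labels, h=h,
                       origin=np.array([0.0, 0.0, -n * h]))


def _field(grid, data):
    return TemperatureField(data=data.astype(float), time=0.0, grid=grid)


def _radial_field(grid, T0=-10.0):
    X, Y, Z = grid.cell_centers()
    n = grid.shape[0]
    c = grid.origin + n * grid.h / 2.0
    r = np.sqrt((X - c[0]) ** 2 + (Y - c[1]) ** 2 + (Z - c[2]) ** 2)
    return T0 + r  # degC; T <= 0 inside radius |T0| mm


class TestThresholdVolume:
    def test_uniform_cold_field_gives_total_volume(self):
        grid = _tissue_grid(10)
        vol = cv.threshold_volume(_field(grid, np.full(grid.shape, -10.0)),
                                  grid, 0.0)
        assert vol == pytest.approx(1.0)  # 10^3 mm^3 = 1 cm^3

    def test_uniform_warm_field_gives_zero(self):
        grid = _tissue_grid(10)
        assert cv.threshold_volume(_field(grid, np.full(grid.shape, 37.0)),
                                   grid, 0.0) == 0.0

    def test_sphere_oracle(self):
        # T(r) = -10 + r: iso-surface T=0 is a sphere of radius 10 mm,
        # volume 4/3 pi 10^3 = 4.19 cm^3
        grid = _tissue_grid(32, 1.0)
        field = _field(grid, _radial_field(grid))
        vol = cv.threshold_volume(field, grid, 0.0)
        assert vol == pytest.approx(4.18879, rel=0.03)

    def test_subcell_beats_counting(self):
        exact = 4.0 / 3.0 * np.pi
        errs = {}
        for h, n in ((2.0, 16), (1.0, 32)):
            grid = _tissue_grid(n, h)
            field = _field(grid, _radial_field(grid))
            errs[h] = {
                "sub": abs(cv.threshold_volume(field, grid, 0.0) - exact),
                "cnt": abs(cv.threshold_volume(field, grid, 0.0,
                                               subcell=False) - exact),
            }
        # sub-cell correction converges about one order faster than plain
        # counting and is already within a percent or two at h = 1 mm
        assert errs[1.0]["sub"] < 0.4 * errs[2.0]["sub"]
        assert errs[1.0]["sub"] / (4.0 / 3.0 * np.pi) < 0.02

    @settings(max_examples=30, deadline=None)
    @given(st.floats(min_value=-60.0, max_value=5.0),
           st.floats(min_value=-60.0, max_value=5.0))
    def test_monotone_in_threshold(self, t1, t2):
        grid = _tissue_grid(16, 2.0)
        field = _field(grid, _radial_field(grid, T0=-30.0))
        lo, hi = sorted((t1, t2))
        assert cv.threshold_volume(field, grid, lo) <= \
            cv.threshold_volume(field, grid, hi) + 1e-12

    def test_excludes_lumen(self):
        grid = _tissue_grid(10)
        grid.labels[4:6] = Label.LUMEN
        vol = cv.threshold_volume(_field(grid, np.full(grid.shape, -10.0)),
                                  grid, 0.0)
        assert vol == pytest.approx(0.8)


class TestArterySurfaceFlux:
    def _two_cell(self):
        labels = np.array([[[Label.LUMEN]], [[Label.TISSUE]]], dtype=np.uint8)
        grid = LabeledGrid(labels=labels, h=1.0,
                           origin=np.array([0.0, 0.0, -1.0]))
        return grid, cv.interface_faces(grid)

    def test_hand_computed_face_flux(self, props):
        grid, faces = self._two_cell()
        data = np.array([[[37.0]], [[0.0]]])
        q = cv.artery_surface_flux(_field(grid, data), grid, faces, props)
        # harmonic mean of 0.5 and 0.5 is 0.5: q = 0.5*37/1e-3 * 1e-6 W
        assert q == pytest.approx(0.0185)

    def test_isothermal_gives_zero(self, props):
        grid, faces = self._two_cell()
        q = cv.artery_surface_flux(_field(grid, np.full(grid.shape, 37.0)),
                                   grid, faces, props)
        assert q == 0.0

    def test_sign_convention(self, props):
        grid, faces = self._two_cell()
        data = np.array([[[0.0]], [[37.0]]])  # tissue warmer than blood
        q = cv.artery_surface_flux(_field(grid, data), grid, faces, props)
        assert q < 0


class TestTreatmentTime:
    def test_exact_hit(self):
        assert treatment_time([0.0, 10.0], [37.0, 0.0], 1200.0) == 10.0

    def test_linear_interpolation(self):
        assert treatment_time([0, 8, 12], [37, 5, -5], 1200.0) == \
            pytest.approx(10.0)

    def test_never_crossing_exceeds_horizon(self):
        t = np.arange(0, 1201, 10.0)
        w = np.full_like(t, 5.0)
        assert treatment_time(t, w, 1200.0) == EXCEEDS_HORIZON

    def test_zero_horizon_all_sentinel(self):
        assert treatment_time([10.0], [-5.0], 0.0) == EXCEEDS_HORIZON

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            treatment_time([], [], 1200.0)


class TestSamplePointTemperature:
    def test_cell_center_and_uniform(self):
        grid = _tissue_grid(8, 2.0)
        field = _field(grid, np.full(grid.shape, 21.5))
        p = grid.origin + (np.array([3, 4, 5]) + 0.5) * grid.h
        assert cv.sample_point_temperature(field, p) == pytest.approx(21.5)

    def test_exact_on_linear_fields(self, rng):
        grid = _tissue_grid(10, 1.5)
        X, Y, Z = grid.cell_centers()
        for _ in range(5):
            a = rng.normal(size=3)
            b = rng.normal()
            field = _field(grid, a[0] * X + a[1] * Y + a[2] * Z + b)
            p = grid.origin + rng.uniform(2.0, 13.0, size=3)
            expected = a @ p + b
            assert cv.sample_point_temperature(field, p) == \
                pytest.approx(expected, rel=1e-9, abs=1e-9)

    def test_outside_domain_rejected(self):
        grid = _tissue_grid(8)
        field = _field(grid, np.zeros(grid.shape))
        with pytest.raises(ValueError):
            cv.sample_point_temperature(field, grid.origin - 5.0)


class TestMinWallTemperature:
    def test_face_value_between_cell_values(self, props):
        labels = np.array([[[Label.LUMEN]], [[Label.TISSUE]]], dtype=np.uint8)
        grid = LabeledGrid(labels=labels, h=1.0,
                           origin=np.array([0.0, 0.0, -1.0]))
        faces = cv.interface_faces(grid)
        data = np.array([[[30.0]], [[10.0]]])
        w = cv.min_wall_temperature(_field(grid, data), faces, props)
        assert 10.0 < w < 30.0


class TestFrozenComponents:
    def test_two_blobs_then_merged(self):
        grid = _tissue_grid(24, 1.0)
        X, Y, Z = grid.cell_centers()
        c1 = grid.origin + np.array([6, 12, 12])
        c2 = grid.origin + np.array([18, 12, 12])
        r1 = np.sqrt((X - c1[0]) ** 2 + (Y - c1[1]) ** 2 + (Z - c1[2]) ** 2)
        r2 = np.sqrt((X - c2[0]) ** 2 + (Y - c2[1]) ** 2 + (Z - c2[2]) ** 2)
        small = _field(grid, np.minimum(r1, r2) - 4.0)
        big = _field(grid, np.minimum(r1, r2) - 8.0)
        assert frozen_component_count(small, grid) == 2
        assert frozen_component_count(big, grid) == 1


class TestMetricSeries:
    def test_strictly_increasing_times_enforced(self):
        s = MetricSeries()
        s.append(0.0, 0.0, 0.0, 0.0, 37.0)
        with pytest.raises(ValueError):
            s.append(0.0, 0.0, 0.0, 0.0, 37.0)

    def test_frame_roundtrip(self, tmp_path):
        s = MetricSeries(sample_names=["p1"])
        s.append(0.0, 0.0, 0.0, 0.0, 37.0, [37.0])
        s.append(1.0, 0.5, 0.1, 2.0, 30.0, [35.0])
        path = tmp_path / "m.csv"
        s.to_csv(path)
        import pandas as pd
        df = pd.read_csv(path)
        assert list(df["time_s"]) == [0.0, 1.0]
        assert "T_p1_C" in df.columns
        assert s.summary()["final_iceball_volume_cm3"] == 0.5
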