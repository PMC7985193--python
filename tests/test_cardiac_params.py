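"""LV endpoint computation: disk geometry, volumes, areas, dimensions,
Teichholz and cube-formula mass, against closed-form oracles."""

import numpy as np
import pytest

from conftest import half_ellipse_contour
from murineecho.cardiac_params import (
    DiskStack,
    MModeDimensions,
    bmode_measures,
    contour_area,
    contour_axis_and_disks,
    contour_dimension,
    contour_from_mask,
    disk_volume,
    lv_mass,
    mmode_measures,
    teichholz_volume,
)
from murineecho.errors import EchoWarning, ValidationError
from murineecho.phantom import ground_truth_mask
from murineecho.types import LvContour, Phase

L, D = 8.0, 4.0
ANALYTIC_VOLUME = np.pi * L * D**2 / 6  # half-ellipsoid of revolution


class TestDiskGeometry:
    def test_chords_match_analytic_ellipse(self):
        stack = contour_axis_and_disks(half_ellipse_contour(L, D), n_disks=20)
        assert stack.L == pytest.approx(L, rel=1e-4)
        centers = (np.arange(20) + 0.5) * L / 20
        analytic = D * np.sqrt(1 - (centers / L) ** 2)
        np.testing.assert_allclose(stack.diameters, analytic, rtol=0.01)

    def test_single_disk_is_mid_axis_chord(self):
        stack = contour_axis_and_disks(half_ellipse_contour(L, D), n_disks=1)
        assert stack.diameters[0] == pytest.approx(
            D * np.sqrt(1 - 0.25), rel=0.01
        )

    def test_circle_with_diameter_base_warns(self):
        phi = np.linspace(0, 2 * np.pi, 64, endpoint=False)
        verts = np.column_stack([np.cos(phi) * 2 + 3, np.sin(phi) * 2 + 3])
        contour = LvContour(vertices=verts, basal_indices=(0, 32), phase=Phase.ED)
        with pytest.warns(EchoWarning, match="basal chord"):
            stack = contour_axis_and_disks(contour)
        # the recovered axis is only a radius of the circle
        assert stack.L == pytest.approx(2.0, rel=0.01)

    def test_dimension_is_base_adjacent_maximum(self):
        stack = contour_axis_and_disks(half_ellipse_contour(L, D), n_disks=20)
        assert int(np.argmax(stack.diameters)) == 0
        assert contour_dimension(half_ellipse_contour(L, D), stack) == pytest.approx(
            D, rel=0.01
        )


class TestDiskVolume:
    def test_twenty_disks_within_half_percent_of_analytic(self):
        stack = contour_axis_and_disks(half_ellipse_contour(L, D), n_disks=20)
        assert disk_volume(stack) == pytest.approx(ANALYTIC_VOLUME, rel=0.005)
        assert ANALYTIC_VOLUME == pytest.approx(67.02, abs=0.01)

    def test_convergence_monotone_in_n_disks(self):
        contour = half_ellipse_contour(L, D)
        errors = [
            abs(disk_volume(contour_axis_and_disks(contour, n)) - ANALYTIC_VOLUME)
            for n in (5, 10, 20, 40, 80)
        ]
        assert all(a > b for a, b in zip(errors, errors[1:]))

    def test_zero_diameters_zero_volume(self):
        stack = DiskStack(L=8.0, diameters=np.zeros(20), n_disks=20, A_m=0, A_p=0)
        assert disk_volume(stack) == 0.0

    def test_quadratic_scaling_law(self):
        stack = contour_axis_and_disks(half_ellipse_contour(L, D), n_disks=20)
        doubled = DiskStack(
            L=stack.L,
            diameters=2 * stack.diameters,
            n_disks=20,
            A_m=stack.A_m,
            A_p=stack.A_p,
        )
        assert disk_volume(doubled) == pytest.approx(4 * disk_volume(stack))


class TestAreas:
    def test_unit_square_area(self):
        # 8-vertex unit square (edge midpoints added)
        verts = np.array(
            [[0, 0], [0.5, 0], [1, 0], [1, 0.5], [1, 1], [0.5, 1], [0, 1], [0, 0.5]]
        )
        contour = LvContour(vertices=verts, basal_indices=(0, 2), phase=Phase.ED)
        assert contour_area(contour) == pytest.approx(1.0)

    def test_half_ellipse_area(self):
        assert contour_area(half_ellipse_contour(L, D)) == pytest.approx(
            np.pi * L * D / 4, rel=0.01
        )


class TestBmodeMeasures:
    def test_no_contraction_zeroes_functional_indices(self):
        ed = half_ellipse_contour(L, D)
        es = half_ellipse_contour(L, D)
        es.phase = Phase.ES
        ms = bmode_measures(ed, es, heart_rate=450.0)
        for name in ("EF", "FS", "FAC", "SV", "CO"):
            assert ms.values[name] == pytest.approx(0.0, abs=1e-9)

    def test_ef_matches_independent_disk_sum(self):
        """EF equals a spreadsheet-style oracle built from analytic chords."""
        ed = half_ellipse_contour(8.0, 4.0)
        es = half_ellipse_contour(7.4, 2.9)
        es.phase = Phase.ES
        ms = bmode_measures(ed, es)

        def oracle_volume(length, diam, n=20):
            centers = (np.arange(n) + 0.5) * length / n
            chords = diam * np.sqrt(1 - (centers / length) ** 2)
            return np.sum(np.pi / 4 * chords**2) * length / n

        edv, esv = oracle_volume(8.0, 4.0), oracle_volume(7.4, 2.9)
        ef_oracle = 100 * (edv - esv) / edv
        # both routes use 20 disks; the contour route sees the polygonized
        # boundary, hence the small geometric tolerance
        assert ms.values["EF"] == pytest.approx(ef_oracle, abs=0.05)

    def test_heart_rate_gates_cardiac_output(self):
        ed = half_ellipse_contour(8.0, 4.0)
        es = half_ellipse_contour(7.4, 2.9)
        es.phase = Phase.ES
        assert "CO" not in bmode_measures(ed, es).values
        with_hr = bmode_measures(ed, es, heart_rate=450.0)
        assert with_hr.values["CO"] == pytest.approx(
            with_hr.values["SV"] * 450 / 1000
        )

    def test_functional_indices_bounded(self):
        ed = half_ellipse_contour(8.0, 4.0)
        es = half_ellipse_contour(6.0, 2.0)
        es.phase = Phase.ES
        ms = bmode_measures(ed, es)
        for name in ("EF", "FS", "FAC"):
            assert 0 <= ms.values[name] <= 100
        assert ms.values["SV"] + ms.values["ESV"] == pytest.approx(ms.values["EDV"])


class TestTeichholz:
    def test_printed_values(self):
        assert teichholz_volume(4.0) == pytest.approx(70.0)
        assert teichholz_volume(2.8) == pytest.approx(7 / 5.2 * 2.8**3, abs=1e-9)
        assert teichholz_volume(2.8) == pytest.approx(29.55, abs=0.01)

    def test_monotone_increasing(self):
        d = np.linspace(0.5, 8.0, 200)
        v = np.array([teichholz_volume(x) for x in d])
        assert np.all(np.diff(v) > 0)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValidationError):
            teichholz_volume(0.0)


class TestMmodeMeasures:
    def _dims(self, lvid_d=4.0, lvid_s=2.8, wall=0.8):
        return MModeDimensions(
            lvid_d=lvid_d, lvid_s=lvid_s,
            lvaw_d=wall, lvaw_s=wall + 0.3, lvpw_d=wall, lvpw_s=wall + 0.3,
        )

    def test_fractional_shortening(self):
        ms = mmode_measures(self._dims())
        assert ms.values["FS"] == pytest.approx(30.0)

    def test_cube_formula_mass_and_correction(self):
        ms = mmode_measures(self._dims())
        assert ms.values["LV mass"] == pytest.approx(117.53, abs=0.01)
        assert ms.values["LV mass corr"] == pytest.approx(94.02, abs=0.01)
        assert lv_mass(4.0, 0.8, 0.8) == pytest.approx(1.053 * (5.6**3 - 4.0**3))

    def test_mass_correction_is_constant_ratio(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            dims = self._dims(
                lvid_d=rng.uniform(3.5, 4.5),
                lvid_s=rng.uniform(2.2, 3.2),
                wall=rng.uniform(0.6, 1.0),
            )
            ms = mmode_measures(dims)
            assert ms.values["LV mass corr"] / ms.values["LV mass"] == pytest.approx(
                0.8
            )

    def test_non_contracting_ventricle_warns_not_fails(self):
        with pytest.warns(EchoWarning, match="contract"):
            MModeDimensions(
                lvid_d=3.0, lvid_s=3.2, lvaw_d=0.8, lvaw_s=0.9,
                lvpw_d=0.8, lvpw_s=0.9,
            ).validate()


class TestContourFromMask:
    def test_phantom_mask_roundtrip(self, bmode_spec, bmode_phantom):
        mask = ground_truth_mask(bmode_spec, bmode_phantom.ed_frame)
        contour = contour_from_mask(mask, bmode_spec.pixel_spacing_mm, Phase.ED)
        mask_area = mask.sum() * bmode_spec.pixel_spacing_mm**2
        assert contour.area_mm2() == pytest.approx(mask_area, rel=0.03)
        # basal chord length approximates the ED diameter
        i, j = contour.basal_indices
        chord = np.linalg.norm(contour.vertices[i] - contour.vertices[j])
        assert chord == pytest.approx(bmode_spec.lv_diameter_ed_mm, rel=0.1)

    def test_derived_volume_close_to_analytic(self, bmode_spec, bmode_phantom):
        mask = ground_truth_mask(bmode_spec, bmode_phantom.ed_frame)
        contour = contour_from_mask(mask, bmode_spec.pixel_spacing_mm, Phase.ED)
        stack = contour_axis_and_disks(contour)
        analytic = (
            np.pi
            * bmode_spec.lv_length_mm
            * bmode_spec.lv_diameter_ed_mm**2
            / 6
        )
        assert disk_volume(stack) == pytest.approx(analytic, rel=0.05)
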