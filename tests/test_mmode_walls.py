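"""M-mode wall tracing: search regions, cost images, dynamic programming
(against brute-force oracles), spectral filtering, phase detection and
measurement."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from murineecho.cardiac_params import teichholz_volume
from murineecho.errors import (
    SegmentationError,
    UniformCostWarning,
    ValidationError,
)
from murineecho.mmode_walls import (
    CostImage,
    PhaseMarks,
    Polarity,
    WallSet,
    WallTrace,
    cost_pixels,
    detect_phases,
    dp_path,
    edit_trace,
    make_region,
    measure_walls,
    optimal_path,
    segment_mmode,
    spectral_filter,
)
from murineecho.phantom import MmodePhantomSpec, make_mmode_phantom, phantom_seeds
from murineecho.types import SeedPointPair, WallId, WALL_ORDER


class TestMakeRegion:
    def test_band_spans_seed_depths(self, mmode_phantom):
        image, _ = mmode_phantom
        seeds = SeedPointPair(
            wall_id=WallId.ANT_ENDO, upper=(0.0, 2.0), lower=(100.0, 3.0)
        )
        region = make_region(seeds, image, margin_px=0)
        sp = image.meta.pixel_spacing_axial
        assert region.row_range == (int(2.0 / sp), int(np.ceil(3.0 / sp)))
        assert region.polarity == Polarity.BRIGHT_TO_DARK

    def test_seed_order_irrelevant(self, mmode_phantom):
        image, _ = mmode_phantom
        a = make_region(
            SeedPointPair(WallId.POST_EPI, (0.0, 5.8), (100.0, 6.6)), image
        )
        b = make_region(
            SeedPointPair(WallId.POST_EPI, (0.0, 6.6), (100.0, 5.8)), image
        )
        assert a.row_range == b.row_range

    def test_seed_outside_image_rejected(self, mmode_phantom):
        image, _ = mmode_phantom
        with pytest.raises(ValidationError, match="outside"):
            make_region(
                SeedPointPair(WallId.ANT_EPI, (0.0, -1.0), (0.0, 2.0)), image
            )


class TestCostImage:
    def _step(self, r=10, rows=21, cols=12, lo=10.0, hi=200.0):
        img = np.full((rows, cols), lo)
        img[r:] = hi
        return img

    def test_matching_polarity_minimum_at_edge(self):
        cost, uniform = cost_pixels(self._step(), Polarity.DARK_TO_BRIGHT)
        assert not uniform
        argmins = cost.argmin(axis=0)
        assert np.all(np.abs(argmins - 10) <= 1)

    def test_opposite_polarity_rectified_away(self):
        cost, _ = cost_pixels(self._step(), Polarity.BRIGHT_TO_DARK)
        assert cost[10].min() > 0.95  # the edge is invisible to this polarity

    def test_uniform_region_warns_cost_one(self):
        with pytest.warns(UniformCostWarning):
            cost, uniform = cost_pixels(np.full((6, 8), 5.0), Polarity.DARK_TO_BRIGHT)
        assert uniform and np.all(cost == 1.0)

    def test_too_short_band_rejected(self):
        with pytest.raises(ValidationError):
            cost_pixels(np.zeros((2, 5)), Polarity.DARK_TO_BRIGHT)


def brute_force_min_cost(grid, max_step):
    """Exhaustive enumeration over all feasible paths (oracle)."""
    n_rows, n_cols = grid.shape
    best = np.inf
    for path in itertools.product(range(n_rows), repeat=n_cols):
        if all(abs(a - b) <= max_step for a, b in zip(path, path[1:])):
            best = min(best, sum(grid[r, t] for t, r in enumerate(path)))
    return best


class TestDpPath:
    def test_zero_cost_row_followed(self):
        grid = np.ones((6, 10))
        grid[3] = 0.0
        np.testing.assert_array_equal(dp_path(grid), 3)

    def test_matches_brute_force_on_random_grids(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            grid = rng.random((5, 6))
            path = dp_path(grid, max_step=2)
            got = grid[path, np.arange(grid.shape[1])].sum()
            assert got == pytest.approx(brute_force_min_cost(grid, 2), abs=1e-12)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(
        st.integers(2, 5),
        st.integers(2, 5),
        st.integers(1, 2),
        st.integers(0, 2**31 - 1),
    )
    def test_exhaustive_equivalence_property(self, rows, cols, max_step, seed):
        grid = np.random.default_rng(seed).random((rows, cols))
        path = dp_path(grid, max_step)
        assert np.all(np.abs(np.diff(path)) <= max_step)
        got = grid[path, np.arange(cols)].sum()
        assert got == pytest.approx(brute_force_min_cost(grid, max_step), abs=1e-12)

    def test_step_constraint_respected_on_infeasible_seam(self):
        # zero-cost seam alternating rows 0 and 3 (|step| = 3 > max_step 2)
        grid = np.ones((4, 8))
        for t in range(8):
            grid[0 if t % 2 == 0 else 3, t] = 0.0
        path = dp_path(grid, max_step=2)
        assert np.all(np.abs(np.diff(path)) <= 2)
        assert grid[path, np.arange(8)].sum() > 0

    def test_tie_breaks_toward_smaller_row(self):
        path = dp_path(np.zeros((5, 6)), max_step=2)
        np.testing.assert_array_equal(path, 0)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValidationError):
            dp_path(np.zeros((3, 0)))


def _trace(depths, dt_ms=1.0):
    depths = np.asarray(depths, dtype=float)
    return WallTrace(
        wall_id=WallId.ANT_ENDO,
        depth_mm=depths,
        col_times_ms=np.arange(depths.size) * dt_ms,
    )


class TestSpectralFilter:
    def test_pure_sinusoid_unchanged(self):
        t = np.arange(256)
        x = 3.0 + 0.5 * np.sin(2 * np.pi * 8 * t / 256)  # integer bin
        out = spectral_filter(_trace(x))
        np.testing.assert_allclose(out.depth_mm, x, atol=1e-6 * 0.5)

    def test_two_tone_keeps_dominant_amplitude(self):
        t = np.arange(2000) / 1000.0  # 2 s at 1 kHz: 7.5 Hz falls on a bin
        x = 2.0 + 1.0 * np.sin(2 * np.pi * 7.5 * t) + 0.2 * np.sin(2 * np.pi * 30 * t)
        out = spectral_filter(_trace(x), frame_rate=1000.0)
        amp = (out.depth_mm.max() - out.depth_mm.min()) / 2
        assert amp == pytest.approx(1.0, rel=0.05)

    def test_constant_trace_unchanged(self):
        x = np.full(32, 4.2)
        out = spectral_filter(_trace(x))
        np.testing.assert_array_equal(out.depth_mm, x)

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        x = 3 + rng.standard_normal(200) * 0.2
        once = spectral_filter(_trace(x))
        twice = spectral_filter(once)
        np.testing.assert_allclose(twice.depth_mm, once.depth_mm, atol=1e-9)

    def test_short_trace_rejected(self):
        with pytest.raises(ValidationError):
            spectral_filter(_trace(np.arange(5.0)))


def _wallset_from_lvid(lvid, centre=3.5, wall=0.8):
    n = lvid.size
    t = np.arange(n, dtype=float)

    def tr(w, d):
        return WallTrace(wall_id=w, depth_mm=d, col_times_ms=t)

    ant_endo = centre - lvid / 2
    post_endo = centre + lvid / 2
    return WallSet(
        {
            WallId.ANT_EPI: tr(WallId.ANT_EPI, ant_endo - wall),
            WallId.ANT_ENDO: tr(WallId.ANT_ENDO, ant_endo),
            WallId.POST_ENDO: tr(WallId.POST_ENDO, post_endo),
            WallId.POST_EPI: tr(WallId.POST_EPI, post_endo + wall),
        }
    )


class TestDetectPhases:
    def test_sinusoid_extrema_located(self):
        n, period = 1000, 133.0
        t = np.arange(n)
        lvid = 3.4 + 0.6 * np.cos(2 * np.pi * t / period)
        marks = detect_phases(_wallset_from_lvid(lvid))
        for c in marks.ed_cols:
            k = np.round(c / period)
            assert abs(c - k * period) <= 1
        for c in marks.es_cols:
            k = np.floor(c / period)
            assert abs(c - (k + 0.5) * period) <= 1

    def test_constant_lvid_rejected(self):
        with pytest.raises(SegmentationError, match="insufficient beats"):
            detect_phases(_wallset_from_lvid(np.full(100, 3.0)))

    def test_phantom_cycle_count(self, mmode_phantom, mmode_spec):
        image, truth = mmode_phantom
        marks = detect_phases(truth)
        expected = int(mmode_spec.heart_rate_bpm / 60 * 5)
        assert abs(len(marks.ed_cols) - expected) <= 1


class TestMeasureWalls:
    def test_noiseless_phantom_recovered_within_2pct(self):
        spec = MmodePhantomSpec(speckle_scale=0.0, rng_seed=0)
        image, truth = make_mmode_phantom(spec)
        dims = measure_walls(truth, detect_phases(truth))
        for name, want in [
            ("lvid_d", spec.lvid_d_mm),
            ("lvid_s", spec.lvid_s_mm),
            ("lvaw_d", spec.lvaw_d_mm),
            ("lvaw_s", spec.lvaw_s_mm),
            ("lvpw_d", spec.lvpw_d_mm),
            ("lvpw_s", spec.lvpw_s_mm),
        ]:
            assert getattr(dims, name) == pytest.approx(want, rel=0.02)

    def test_ordering_violation_rejected(self):
        ws = _wallset_from_lvid(3.4 + 0.6 * np.cos(np.arange(300) / 20))
        ws.traces[WallId.ANT_ENDO].depth_mm += 5.0  # push below POST_ENDO
        with pytest.raises(ValidationError, match="ordering"):
            measure_walls(ws, PhaseMarks(np.array([10]), np.array([40])))

    def test_single_beat_mean_of_one(self):
        lvid = 3.4 + 0.6 * np.cos(2 * np.pi * np.arange(150) / 133)
        ws = _wallset_from_lvid(lvid)
        marks = PhaseMarks(ed_cols=np.array([0]), es_cols=np.array([66]))
        dims = measure_walls(ws, marks)
        assert dims.lvid_d == pytest.approx(lvid[0])
        assert len(dims.per_beat["lvid_d"]) == 1


class TestSegmentMmode:
    def test_speckled_phantom_recovery(self, mmode_phantom, mmode_spec, mmode_seeds):
        image, _ = mmode_phantom
        _, marks, dims = segment_mmode(image, mmode_seeds)
        assert dims.lvid_d == pytest.approx(mmode_spec.lvid_d_mm, rel=0.05)
        assert dims.lvid_s == pytest.approx(mmode_spec.lvid_s_mm, rel=0.05)

    def test_triplicate_runs_identical(self, mmode_phantom, mmode_seeds):
        image, _ = mmode_phantom
        runs = [segment_mmode(image, mmode_seeds) for _ in range(3)]
        for w in WALL_ORDER:
            np.testing.assert_array_equal(
                runs[0][0][w].depth_mm, runs[1][0][w].depth_mm
            )
            np.testing.assert_array_equal(
                runs[1][0][w].depth_mm, runs[2][0][w].depth_mm
            )
        assert runs[0][2] == runs[1][2] == runs[2][2]

    def test_cavity_only_band_flagged_low_confidence(self, mmode_phantom):
        image, truth = mmode_phantom
        # band strictly inside the cavity: no wall edge of either polarity
        seeds = SeedPointPair(WallId.ANT_ENDO, (0.0, 3.3), (100.0, 3.6))
        from murineecho.mmode_walls import cost_image as make_cost

        region = make_region(seeds, image, margin_px=0)
        with pytest.warns(UniformCostWarning):
            spec0 = MmodePhantomSpec(speckle_scale=0.0, rng_seed=0)
            img0, _ = make_mmode_phantom(spec0)
            cimg = make_cost(img0, region)
        trace = optimal_path(cimg)
        assert trace.low_confidence


class TestEditTrace:
    def _ws(self):
        lvid = 3.4 + 0.6 * np.cos(2 * np.pi * np.arange(400) / 133)
        return _wallset_from_lvid(lvid)

    def test_identity_edit_unchanged(self):
        ws = self._ws()
        old = ws[WallId.ANT_ENDO].depth_mm.copy()
        out = edit_trace(ws, WallId.ANT_ENDO, (10, 20), old[10:20])
        np.testing.assert_array_equal(out[WallId.ANT_ENDO].depth_mm, old)

    def test_order_breaking_edit_rejected(self):
        ws = self._ws()
        with pytest.raises(ValidationError, match="ordering"):
            edit_trace(ws, WallId.ANT_ENDO, (0, 5), np.full(5, 6.0))

    def test_edit_locality_in_measures(self):
        ws = self._ws()
        marks = detect_phases(ws)
        before = measure_walls(ws, marks)
        # corrupt then fix one column far from any other beat's mark
        target_col = int(marks.ed_cols[1])
        edited = edit_trace(
            ws,
            WallId.POST_ENDO,
            (target_col, target_col + 1),
            [ws[WallId.POST_ENDO].depth_mm[target_col] + 0.2],
        )
        after = measure_walls(edited, marks)
        n = len(marks.ed_cols)
        assert after.lvid_d == pytest.approx(before.lvid_d + 0.2 / n)
        assert after.lvid_s == before.lvid_s  # systolic beats untouched


def test_teichholz_links_dims_to_ef(mmode_phantom, mmode_seeds, mmode_spec):
    """EF derived from traced dimensions lands near the phantom truth."""
    image, _ = mmode_phantom
    _, _, dims = segment_mmode(image, mmode_seeds)
    edv, esv = teichholz_volume(dims.lvid_d), teichholz_volume(dims.lvid_s)
    ef = 100 * (edv - esv) / edv
    edv_t = teichholz_volume(mmode_spec.lvid_d_mm)
    esv_t = teichholz_volume(mmode_spec.lvid_s_mm)
    ef_t = 100 * (edv_t - esv_t) / edv_t
    assert abs(ef - ef_t) <= 3.0
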