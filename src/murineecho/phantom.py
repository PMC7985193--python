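"""Synthetic echocardiogram phantoms with exact ground truth.

The B-mode phantom models the long-axis LV cavity as a half-ellipsoid
cross-section (an ellipse truncated at the mitral base) whose minor
diameter oscillates sinusoidally at the heart rate between the ED and ES
values; the myocardium is a bright band of fixed thickness around it.
The M-mode phantom renders four sinusoidal wall-interface depth signals
phased so the internal diameter swings between LVID;d and LVID;s, with
bright wall bands and a dark cavity.

Speckle is modelled as unit-mean multiplicative gamma noise followed by a
one-pixel Gaussian point-spread blur — the minimal model reproducing the
low signal-to-noise of high-frequency ultrasound without simulating wave
physics.  Every generator is a pure function of (spec, seed): ground
truth is exact by construction, so any error measured downstream is the
algorithm's.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Dict, NamedTuple, Optional, Tuple

import numpy as np
from scipy import ndimage

from .bmode_atlas import AtlasEntry, ReferenceLibrary
from .errors import ValidationError
from .mmode_walls import WallSet, WallTrace
from .types import (
    CineLoop,
    ImageMeta,
    LvContour,
    MModeImage,
    Phase,
    SeedPointPair,
    WallId,
    WALL_ORDER,
)

# rendered tissue intensities (arbitrary units, background < wall)
_I_CAVITY = 8.0
_I_BACKGROUND = 40.0
_I_WALL = 200.0


@dataclass(frozen=True)
class BmodePhantomSpec:
    """Parameters of a synthetic long-axis B-mode cine loop.

    Defaults follow the acquisition protocol the package targets: a
    300-frame loop at 6.67 ms/frame with heart rate 450 bpm (mid-range of
    the 400-500 bpm physiological window for anesthetized mice).
    """

    lv_length_mm: float = 8.0  # base-to-apex L
    lv_diameter_ed_mm: float = 4.0
    lv_diameter_es_mm: float = 2.8
    wall_thickness_mm: float = 0.8
    heart_rate_bpm: float = 450.0
    n_frames: int = 300
    frame_interval_ms: float = 6.67
    speckle_scale: float = 0.3
    rng_seed: int = 0
    # rendering geometry
    pixel_spacing_mm: float = 0.05
    image_shape: Tuple[int, int] = (160, 256)  # (depth rows, lateral cols)
    base_x_mm: float = 2.0  # lateral position of the mitral base
    center_depth_mm: float = 4.0  # depth of the long axis
    tilt_deg: float = 0.0  # axis rotation about the base

    def validate(self) -> "BmodePhantomSpec":
        if not self.lv_diameter_es_mm < self.lv_diameter_ed_mm:
            raise ValidationError("ES diameter must be smaller than ED diameter")
        if not 200 <= self.heart_rate_bpm <= 800:
            raise ValidationError("heart rate outside plausible murine range")
        if self.n_frames < 2:
            raise ValidationError("need >= 2 frames")
        for name in (
            "lv_length_mm",
            "wall_thickness_mm",
            "frame_interval_ms",
            "pixel_spacing_mm",
        ):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be > 0")
        if self.speckle_scale < 0:
            raise ValidationError("speckle_scale must be >= 0")
        return self


@dataclass(frozen=True)
class MmodePhantomSpec:
    """Parameters of a synthetic short-axis M-mode sweep.

    Defaults: a 5-second sweep sampled at 1 kHz (1 ms/column, the sweep
    rate needed for wall excursions to stay within the tracer's step
    constraint at 0.01 mm axial pixels), heart rate 450 bpm, diastolic
    chamber 4.0 mm contracting to 2.8 mm, walls thickening from 0.8 mm
    (diastole) to 1.1 mm (systole).
    """

    lvid_d_mm: float = 4.0
    lvid_s_mm: float = 2.8
    lvaw_d_mm: float = 0.8
    lvaw_s_mm: float = 1.1
    lvpw_d_mm: float = 0.8
    lvpw_s_mm: float = 1.1
    heart_rate_bpm: float = 450.0
    duration_ms: float = 5000.0
    columns: int = 5000
    depth_px: int = 700
    pixel_spacing_mm: float = 0.01
    speckle_scale: float = 0.3
    rng_seed: int = 0

    def validate(self) -> "MmodePhantomSpec":
        if not self.lvid_s_mm < self.lvid_d_mm:
            raise ValidationError("LVID;s must be smaller than LVID;d")
        for name in ("lvaw_d_mm", "lvaw_s_mm", "lvpw_d_mm", "lvpw_s_mm"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be > 0")
        beats = self.heart_rate_bpm / 60.0 * self.duration_ms / 1000.0
        if beats <= 2:
            raise ValidationError("duration must cover more than 2 beats")
        return self


class BmodePhantom(NamedTuple):
    loop: CineLoop
    ed_contour: LvContour
    es_contour: LvContour
    ed_frame: int
    es_frame: int


# ---------------------------------------------------------------------------
# B-mode


def _speckle(img: np.ndarray, scale: float, rng: np.random.Generator) -> np.ndarray:
    if scale > 0:
        shape = 1.0 / scale**2
        img = img * rng.gamma(shape, 1.0 / shape, size=img.shape)
    return ndimage.gaussian_filter(img, sigma=1.0, mode="nearest")


def _axis_frame(spec: BmodePhantomSpec) -> tuple:
    theta = np.deg2rad(spec.tilt_deg)
    u = np.array([np.cos(theta), np.sin(theta)])  # along axis, base -> apex
    v = np.array([-np.sin(theta), np.cos(theta)])  # perpendicular
    base = np.array([spec.base_x_mm, spec.center_depth_mm])
    return base, u, v


def _diameter_at(spec: BmodePhantomSpec, t_ms: np.ndarray) -> np.ndarray:
    mean = 0.5 * (spec.lv_diameter_ed_mm + spec.lv_diameter_es_mm)
    amp = 0.5 * (spec.lv_diameter_ed_mm - spec.lv_diameter_es_mm)
    omega = 2 * np.pi * spec.heart_rate_bpm / 60.0 / 1000.0  # rad/ms
    return mean + amp * np.cos(omega * np.asarray(t_ms))


def _cavity_mask(spec: BmodePhantomSpec, diameter_mm: float) -> np.ndarray:
    """Exact rasterization of the half-ellipse cavity at one diameter."""
    rows, cols = spec.image_shape
    sp = spec.pixel_spacing_mm
    yy, xx = np.mgrid[0:rows, 0:cols]
    pts = np.stack([xx * sp, yy * sp], axis=-1)
    base, u, v = _axis_frame(spec)
    rel = pts - base
    a = rel @ u
    b = rel @ v
    L, r = spec.lv_length_mm, diameter_mm / 2.0
    return (a >= 0) & ((a / L) ** 2 + (b / r) ** 2 <= 1.0)


def _render_frame(spec: BmodePhantomSpec, diameter_mm: float) -> np.ndarray:
    cavity = _cavity_mask(spec, diameter_mm)
    w = spec.wall_thickness_mm
    outer_spec = replace(
        spec,
        lv_length_mm=spec.lv_length_mm + w,
        base_x_mm=spec.base_x_mm
        - w * np.cos(np.deg2rad(spec.tilt_deg)),
        center_depth_mm=spec.center_depth_mm
        - w * np.sin(np.deg2rad(spec.tilt_deg)),
    )
    outer = _cavity_mask(outer_spec, diameter_mm + 2 * w)
    img = np.full(spec.image_shape, _I_BACKGROUND)
    img[outer] = _I_WALL
    img[cavity] = _I_CAVITY
    return img


def _contour(spec: BmodePhantomSpec, diameter_mm: float, phase: Phase) -> LvContour:
    """Exact endocardial boundary of the rendered cavity (64-point arc)."""
    base, u, v = _axis_frame(spec)
    L, r = spec.lv_length_mm, diameter_mm / 2.0
    phi = np.linspace(np.pi / 2, -np.pi / 2, 64)
    verts = base + np.outer(L * np.cos(phi), u) + np.outer(r * np.sin(phi), v)
    return LvContour(
        vertices=verts, basal_indices=(0, len(phi) - 1), phase=phase
    ).validate()


def _mid_cycle_extrema(spec: BmodePhantomSpec) -> tuple:
    """ED/ES frame indices: argmax/argmin of cavity size over one mid-loop cycle."""
    t = np.arange(spec.n_frames) * spec.frame_interval_ms
    d = _diameter_at(spec, t)
    period = 60000.0 / spec.heart_rate_bpm / spec.frame_interval_ms
    start = max(0, min(spec.n_frames // 2, spec.n_frames - int(np.ceil(period)) - 1))
    stop = min(spec.n_frames, start + int(np.ceil(period)) + 1)
    window = d[start:stop]
    return start + int(np.argmax(window)), start + int(np.argmin(window))


def make_bmode_phantom(spec: BmodePhantomSpec = BmodePhantomSpec()) -> BmodePhantom:
    """Render a beating-LV cine loop with exact ED/ES ground truth.

    Returns the loop, the exact endocardial contours at the selected ED
    and ES frames, and those frame indices (argmax/argmin of cavity size
    over one mid-loop cycle, mirroring the manual frame-selection step).
    Deterministic under ``spec.rng_seed``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.rng_seed)
    t = np.arange(spec.n_frames) * spec.frame_interval_ms
    diameters = _diameter_at(spec, t)
    frames = np.stack(
        [
            _speckle(_render_frame(spec, d), spec.speckle_scale, rng)
            for d in diameters
        ]
    )
    meta = ImageMeta(
        pixel_spacing_axial=spec.pixel_spacing_mm,
        pixel_spacing_lateral=spec.pixel_spacing_mm,
        frame_interval_ms=spec.frame_interval_ms,
        heart_rate_bpm=spec.heart_rate_bpm,
        mode_tag="B-mode",
        subject_id=f"phantom-{spec.rng_seed}",
    )
    loop = CineLoop(frames=frames, meta=meta).validate()
    ed_idx, es_idx = _mid_cycle_extrema(spec)
    return BmodePhantom(
        loop=loop,
        ed_contour=_contour(spec, diameters[ed_idx], Phase.ED),
        es_contour=_contour(spec, diameters[es_idx], Phase.ES),
        ed_frame=ed_idx,
        es_frame=es_idx,
    )


def ground_truth_mask(spec: BmodePhantomSpec, frame_index: int) -> np.ndarray:
    """Exact binary cavity mask for one frame of a B-mode phantom."""
    spec.validate()
    t = frame_index * spec.frame_interval_ms
    return _cavity_mask(spec, float(_diameter_at(spec, np.array([t]))[0]))


#: spec_ranges defaults for library generation: morphological variability of
#: a healthy adult mouse cohort (length, diameters, walls), moderate probe
#: tilt and translation, acquisition heart-rate window 400-500 bpm.
DEFAULT_SPEC_RANGES: Dict[str, tuple] = {
    "lv_length_mm": (7.0, 9.0),
    "lv_diameter_ed_mm": (3.6, 4.4),
    "lv_diameter_es_mm": (2.5, 3.1),
    "wall_thickness_mm": (0.7, 0.9),
    "heart_rate_bpm": (400.0, 500.0),
    "tilt_deg": (-8.0, 8.0),
    "base_x_mm": (1.6, 2.4),
    "center_depth_mm": (3.6, 4.4),
}

#: library entries use a short loop spanning ~2 cardiac cycles; only the
#: selected ED and ES frames enter the library.
_LIBRARY_N_FRAMES = 42


def make_library(
    n: int,
    spec_ranges: Optional[Dict[str, tuple]] = None,
    rng_seed: int = 0,
    speckle_scale: float = 0.3,
) -> ReferenceLibrary:
    """Generate a synthetic reference library of n traced phantoms.

    Each phantom contributes one ED and one ES (frame, exact binary mask)
    entry, parameters drawn uniformly from ``spec_ranges`` (defaults:
    :data:`DEFAULT_SPEC_RANGES`).  Entries share a subject id per phantom.
    """
    if n < 2:
        raise ValidationError("library requires n >= 2 phantoms")
    ranges = dict(DEFAULT_SPEC_RANGES)
    if spec_ranges:
        ranges.update(spec_ranges)
    valid_fields = {f.name for f in fields(BmodePhantomSpec)}
    for name, (lo, hi) in ranges.items():
        if name not in valid_fields:
            raise ValidationError(f"unknown spec field in spec_ranges: {name}")
        if lo > hi:
            raise ValidationError(f"degenerate range for {name}: {lo} > {hi}")
    rng = np.random.default_rng(rng_seed)
    entries = []
    for idx in range(n):
        draw = {k: float(rng.uniform(lo, hi)) for k, (lo, hi) in ranges.items()}
        seed = int(rng.integers(0, 2**31 - 1))
        spec = BmodePhantomSpec(
            n_frames=_LIBRARY_N_FRAMES,
            speckle_scale=speckle_scale,
            rng_seed=seed,
            **draw,
        )
        phantom = make_bmode_phantom(spec)
        subject = f"lib{idx:03d}"
        for phase, frame_idx in (
            (Phase.ED, phantom.ed_frame),
            (Phase.ES, phantom.es_frame),
        ):
            entries.append(
                AtlasEntry(
                    frame=phantom.loop.frames[frame_idx],
                    mask=ground_truth_mask(spec, frame_idx),
                    phase=phase,
                    id=f"{subject}-{phase.value}",
                    subject=subject,
                    pixel_spacing_mm=spec.pixel_spacing_mm,
                )
            )
    return ReferenceLibrary(entries).validate()


# ---------------------------------------------------------------------------
# M-mode


def _interface_signals(spec: MmodePhantomSpec, t_ms: np.ndarray) -> Dict[WallId, np.ndarray]:
    omega = 2 * np.pi * spec.heart_rate_bpm / 60.0 / 1000.0
    c = np.cos(omega * t_ms)

    def osc(d_val, s_val):
        return 0.5 * (d_val + s_val) + 0.5 * (d_val - s_val) * c

    lvid = osc(spec.lvid_d_mm, spec.lvid_s_mm)
    lvaw = osc(spec.lvaw_d_mm, spec.lvaw_s_mm)
    lvpw = osc(spec.lvpw_d_mm, spec.lvpw_s_mm)
    centre = spec.depth_px * spec.pixel_spacing_mm / 2.0
    ant_endo = centre - lvid / 2.0
    post_endo = centre + lvid / 2.0
    return {
        WallId.ANT_EPI: ant_endo - lvaw,
        WallId.ANT_ENDO: ant_endo,
        WallId.POST_ENDO: post_endo,
        WallId.POST_EPI: post_endo + lvpw,
    }


def make_mmode_phantom(spec: MmodePhantomSpec = MmodePhantomSpec()) -> tuple:
    """Render an M-mode sweep and its exact ground-truth wall set.

    The four interface depths are sinusoids at the heart rate, phased so
    LVID(t) attains LVID;d at t = 0; walls are bright bands between the
    epicardial and endocardial interfaces, the cavity dark.  The returned
    WallSet holds the exact interface depths at full column resolution.
    """
    spec.validate()
    t = np.arange(spec.columns) * spec.duration_ms / spec.columns
    ifs = _interface_signals(spec, t)
    depths = np.array([ifs[w] for w in WALL_ORDER])
    if np.any(np.diff(depths, axis=0) <= 0):
        raise ValidationError("wall interfaces cross (cavity closes)")
    if depths.min() < 0 or depths.max() > spec.depth_px * spec.pixel_spacing_mm:
        raise ValidationError("interfaces leave the imaged depth range")

    depth_axis = (np.arange(spec.depth_px) * spec.pixel_spacing_mm)[:, None]
    in_ant = (depth_axis >= ifs[WallId.ANT_EPI]) & (
        depth_axis < ifs[WallId.ANT_ENDO]
    )
    in_post = (depth_axis >= ifs[WallId.POST_ENDO]) & (
        depth_axis < ifs[WallId.POST_EPI]
    )
    in_cavity = (depth_axis >= ifs[WallId.ANT_ENDO]) & (
        depth_axis < ifs[WallId.POST_ENDO]
    )
    img = np.full((spec.depth_px, spec.columns), _I_BACKGROUND)
    img[in_ant | in_post] = _I_WALL
    img[in_cavity] = _I_CAVITY
    rng = np.random.default_rng(spec.rng_seed)
    img = _speckle(img, spec.speckle_scale, rng)

    meta = ImageMeta(
        pixel_spacing_axial=spec.pixel_spacing_mm,
        time_per_column=spec.duration_ms / spec.columns,
        heart_rate_bpm=spec.heart_rate_bpm,
        mode_tag="M-mode",
        subject_id=f"phantom-{spec.rng_seed}",
    )
    image = MModeImage(grid=img, meta=meta).validate()
    truth = WallSet(
        {
            w: WallTrace(wall_id=w, depth_mm=ifs[w], col_times_ms=t)
            for w in WALL_ORDER
        }
    ).validate()
    return image, truth


def phantom_seeds(
    spec: MmodePhantomSpec, pad_mm: float = 0.25
) -> list:
    """Seed-point pairs bracketing each true interface of an M-mode phantom.

    Emulates the user's two-point placement: upper/lower bounds ``pad_mm``
    beyond the extreme excursion of each interface, at the sweep start and
    end times.
    """
    spec.validate()
    t = np.arange(spec.columns) * spec.duration_ms / spec.columns
    ifs = _interface_signals(spec, t)
    t_end = float(t[-1])
    seeds = []
    for w in WALL_ORDER:
        lo = float(ifs[w].min()) - pad_mm
        hi = float(ifs[w].max()) + pad_mm
        seeds.append(
            SeedPointPair(wall_id=w, upper=(0.0, lo), lower=(t_end, hi)).validate()
        )
    return seeds
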