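"""Semi-automated M-mode wall tracing.

For each of the four LV wall interfaces the user places two seed points
bracketing the wall; the band between them (plus a margin) becomes a
search region.  The region is smoothed, a polarity-rectified axial
gradient is turned into a cost image, and a dynamic-programming routine
finds the globally optimal depth-vs-time path under a per-column step
constraint.  Each trace is then filtered in the spectral domain down to
its dominant periodic component; the peaks of the filtered LV internal
diameter mark end-diastole and end-systole, at which the wall thicknesses
and chamber diameters are measured and averaged over beats.

Polarity is expressed in the increasing-depth (downward) direction with
the anterior wall above the cavity: ANT_EPI and POST_ENDO are
dark-to-bright transitions, ANT_ENDO and POST_EPI bright-to-dark.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Dict, List, Optional, Sequence

import numpy as np
from scipy import ndimage

from .cardiac_params import MModeDimensions
from .errors import SegmentationError, UniformCostWarning, ValidationError
from .types import MModeImage, SeedPointPair, WallId, WALL_ORDER


class Polarity(str, Enum):
    DARK_TO_BRIGHT = "dark-to-bright"
    BRIGHT_TO_DARK = "bright-to-dark"


#: Expected axial (downward) intensity transition at each interface.
WALL_POLARITY: Dict[WallId, Polarity] = {
    WallId.ANT_EPI: Polarity.DARK_TO_BRIGHT,
    WallId.ANT_ENDO: Polarity.BRIGHT_TO_DARK,
    WallId.POST_ENDO: Polarity.DARK_TO_BRIGHT,
    WallId.POST_EPI: Polarity.BRIGHT_TO_DARK,
}


# ---------------------------------------------------------------------------
# containers


@dataclass
class SearchRegion:
    """Depth band (over the full time extent) to search for one wall."""

    wall_id: WallId
    row_range: tuple  # (r_min, r_max) inclusive
    polarity: Polarity

    def validate(self) -> "SearchRegion":
        r_min, r_max = self.row_range
        if r_min >= r_max or (r_max - r_min + 1) < 3:
            raise ValidationError("search band must span at least 3 rows")
        return self


@dataclass
class CostImage:
    """Per-pixel boundary cost for one wall's search region."""

    grid: np.ndarray  # (band_rows, columns), values in [0, 1]
    wall_id: WallId
    row_offset: int
    axial_spacing_mm: float
    col_times_ms: np.ndarray
    uniform: bool = False

    def validate(self) -> "CostImage":
        if self.grid.ndim != 2:
            raise ValidationError("cost grid must be 2-D")
        if not np.all(np.isfinite(self.grid)) or self.grid.min() < 0:
            raise ValidationError("cost values must be finite and >= 0")
        return self


@dataclass
class WallTrace:
    """Boundary depth (mm) at every time column for one interface."""

    wall_id: WallId
    depth_mm: np.ndarray
    col_times_ms: np.ndarray
    low_confidence: bool = False

    def validate(self) -> "WallTrace":
        self.depth_mm = np.asarray(self.depth_mm, dtype=float)
        self.col_times_ms = np.asarray(self.col_times_ms, dtype=float)
        if self.depth_mm.shape != self.col_times_ms.shape:
            raise ValidationError("trace and time axes differ in length")
        return self

    def __len__(self) -> int:
        return len(self.depth_mm)


@dataclass
class WallSet:
    """The four wall traces, depth-ordered at every column."""

    traces: Dict[WallId, WallTrace]

    def validate(self) -> "WallSet":
        missing = [w for w in WALL_ORDER if w not in self.traces]
        if missing:
            raise ValidationError(f"wall set missing traces: {missing}")
        arrs = [self.traces[w].validate().depth_mm for w in WALL_ORDER]
        for upper, lower, wu, wl in zip(arrs, arrs[1:], WALL_ORDER, WALL_ORDER[1:]):
            if np.any(upper > lower + 1e-9):
                raise ValidationError(
                    f"depth ordering violated: {wu.value} below {wl.value}"
                )
        return self

    def __getitem__(self, wall: WallId) -> WallTrace:
        return self.traces[WallId(wall)]

    def lvid_mm(self) -> np.ndarray:
        """LV internal diameter signal POST_ENDO(t) - ANT_ENDO(t)."""
        return (
            self.traces[WallId.POST_ENDO].depth_mm
            - self.traces[WallId.ANT_ENDO].depth_mm
        )


@dataclass
class PhaseMarks:
    """Column indices of end-diastole (LVID maxima) and end-systole."""

    ed_cols: np.ndarray
    es_cols: np.ndarray

    def validate(self) -> "PhaseMarks":
        self.ed_cols = np.asarray(self.ed_cols, dtype=int)
        self.es_cols = np.asarray(self.es_cols, dtype=int)
        if self.ed_cols.size == 0 or self.es_cols.size == 0:
            raise ValidationError("phase marks require at least one full cycle")
        merged = sorted(
            [(c, "ed") for c in self.ed_cols] + [(c, "es") for c in self.es_cols]
        )
        kinds = [k for _, k in merged]
        if any(a == b for a, b in zip(kinds, kinds[1:])):
            raise ValidationError("ED/ES marks must alternate in time")
        return self


@dataclass(frozen=True)
class MModeOptions:
    """Tunable parameters of the M-mode tracing pipeline."""

    max_step: int = 2  # DP smoothness: max row change per column
    margin_frac: float = 0.10  # search-band margin as fraction of seed span
    smooth_sigma: float = 1.0  # px, pre-gradient Gaussian
    bins_unused: int = 0  # reserved


# ---------------------------------------------------------------------------
# stages


def make_region(
    seeds: SeedPointPair,
    image: MModeImage,
    margin_px: Optional[int] = None,
) -> SearchRegion:
    """Turn a seed-point pair into a depth search band.

    The band spans the two seed depths, grown by ``margin_px`` (default:
    10% of the seed span) and clipped to the image.  Polarity comes from
    the wall identity.  Seed order is normalized, so swapping the two
    points yields the same region.
    """
    seeds = seeds.validate(image)
    sp = image.meta.pixel_spacing_axial
    d_lo, d_hi = seeds.upper[1], seeds.lower[1]
    if margin_px is None:
        margin_px = int(round(MModeOptions().margin_frac * (d_hi - d_lo) / sp))
    r_min = int(np.floor(d_lo / sp)) - margin_px
    r_max = int(np.ceil(d_hi / sp)) + margin_px
    r_min = max(0, r_min)
    r_max = min(image.grid.shape[0] - 1, r_max)
    return SearchRegion(
        wall_id=seeds.wall_id,
        row_range=(r_min, r_max),
        polarity=WALL_POLARITY[seeds.wall_id],
    ).validate()


def cost_pixels(
    pixels: np.ndarray, polarity: Polarity, smooth_sigma: float = 1.0
) -> tuple:
    """Gradient cost for a region: returns ``(cost, uniform_flag)``.

    Gaussian smoothing, signed depth-direction derivative, polarity
    rectification (the expected transition direction keeps its sign, the
    opposite one is clamped to zero) and min-max normalization; cost is
    ``1 - normalized gradient`` so boundary pixels are cheap.  A constant
    region yields uniform cost 1 with a :class:`UniformCostWarning`.
    """
    pixels = np.asarray(pixels, dtype=float)
    if pixels.shape[0] < 3:
        raise ValidationError("cost region requires at least 3 rows")
    smoothed = ndimage.gaussian_filter(pixels, sigma=smooth_sigma, mode="nearest")
    g = np.gradient(smoothed, axis=0)
    if Polarity(polarity) == Polarity.BRIGHT_TO_DARK:
        g = -g
    rect = np.maximum(g, 0.0)
    lo, hi = rect.min(), rect.max()
    if hi - lo < 1e-12:
        warnings.warn(
            "search region has no gradient of the expected polarity",
            UniformCostWarning,
            stacklevel=2,
        )
        return np.ones_like(pixels), True
    return 1.0 - (rect - lo) / (hi - lo), False


def cost_image(
    image: MModeImage, region: SearchRegion, opts: MModeOptions = MModeOptions()
) -> CostImage:
    """Cost image for one wall's search region of an M-mode sweep."""
    region.validate()
    r_min, r_max = region.row_range
    grid, uniform = cost_pixels(
        image.grid[r_min : r_max + 1], region.polarity, opts.smooth_sigma
    )
    return CostImage(
        grid=grid,
        wall_id=region.wall_id,
        row_offset=r_min,
        axial_spacing_mm=image.meta.pixel_spacing_axial,
        col_times_ms=image.col_times_ms(),
        uniform=uniform,
    ).validate()


def dp_path(cost: np.ndarray, max_step: int = 2) -> np.ndarray:
    """Minimum-cost row path through a cost grid, one row per column.

    Exact global optimum of ``sum_t cost[r(t), t]`` subject to
    ``|r(t+1) - r(t)| <= max_step``; ties broken toward the smaller row at
    every backtrack step.
    """
    cost = np.asarray(cost, dtype=float)
    if cost.ndim != 2 or cost.shape[1] == 0:
        raise ValidationError("dp_path requires a non-empty 2-D cost grid")
    if max_step < 1:
        raise ValidationError("max_step must be >= 1")
    n_rows, n_cols = cost.shape
    acc = np.empty_like(cost)
    acc[:, 0] = cost[:, 0]
    win = 2 * max_step + 1
    for t in range(1, n_cols):
        best_prev = ndimage.minimum_filter1d(
            acc[:, t - 1], size=win, mode="constant", cval=np.inf
        )
        acc[:, t] = cost[:, t] + best_prev
    path = np.empty(n_cols, dtype=int)
    path[-1] = int(np.argmin(acc[:, -1]))  # first occurrence = smallest row
    for t in range(n_cols - 1, 0, -1):
        r = path[t]
        lo = max(0, r - max_step)
        hi = min(n_rows, r + max_step + 1)
        path[t - 1] = lo + int(np.argmin(acc[lo:hi, t - 1]))
    return path


def optimal_path(cost: CostImage, max_step: int = 2) -> WallTrace:
    """Dynamic-programming wall boundary trace for one cost image."""
    rows = dp_path(cost.validate().grid, max_step)
    return WallTrace(
        wall_id=cost.wall_id,
        depth_mm=(rows + cost.row_offset) * cost.axial_spacing_mm,
        col_times_ms=cost.col_times_ms,
        low_confidence=cost.uniform,
    ).validate()


def spectral_filter(trace: WallTrace, frame_rate: Optional[float] = None) -> WallTrace:
    """Keep only the dominant periodic component of a trace.

    Mean is removed, the discrete Fourier transform is taken, every bin
    except the single largest-magnitude positive frequency (and its
    conjugate) is zeroed, and the mean is restored: the trace collapses to
    its dominant sinusoid plus baseline.  Idempotent; an all-constant
    trace is returned unchanged.  ``frame_rate`` (columns/s) is accepted
    for callers that want the retained frequency in Hz but does not affect
    the filtering.
    """
    trace = trace.validate()
    x = trace.depth_mm
    if x.size < 8:
        raise ValidationError("spectral_filter requires >= 8 columns")
    mean = x.mean()
    spectrum = np.fft.rfft(x - mean)
    mags = np.abs(spectrum)
    if x.size < 2 or mags[1:].max() < 1e-12 * max(1.0, abs(mean)):
        return replace(trace, depth_mm=x.copy())
    k = 1 + int(np.argmax(mags[1:]))
    kept = np.zeros_like(spectrum)
    kept[k] = spectrum[k]
    filtered = np.fft.irfft(kept, n=x.size) + mean
    return replace(trace, depth_mm=filtered)


def _next_nonzero_sign(d: np.ndarray) -> np.ndarray:
    """Backward-fill of sign(d): value at i is the next nonzero sign at >= i."""
    s = np.sign(d)
    out = s.copy()
    for i in range(len(s) - 2, -1, -1):
        if out[i] == 0:
            out[i] = out[i + 1]
    return out


def _plateau_extrema(s: np.ndarray) -> tuple:
    d = np.diff(s)
    right = _next_nonzero_sign(d)
    maxima, minima = [], []
    for i in range(1, len(s) - 1):
        if d[i - 1] > 0 and right[i] < 0:
            maxima.append(i)  # first index of a maximum plateau
        elif d[i - 1] < 0 and right[i] > 0:
            minima.append(i)
    return np.array(maxima, dtype=int), np.array(minima, dtype=int)


def detect_phases(wallset: WallSet) -> PhaseMarks:
    """Locate ED/ES columns from the filtered LV internal diameter.

    ED columns are local maxima of ``LVID(t)``, ES columns local minima,
    with plateau-safe comparisons (first index of a plateau).  Raises if
    fewer than one full cycle (one maximum and one minimum) is present.
    """
    lvid = wallset.validate().lvid_mm()
    if np.ptp(lvid) < 1e-12:
        raise SegmentationError("insufficient beats: LVID signal is constant")
    ed, es = _plateau_extrema(lvid)
    if ed.size == 0 or es.size == 0:
        raise SegmentationError("insufficient beats: no full cardiac cycle found")
    return PhaseMarks(ed_cols=ed, es_cols=es).validate()


def refine_marks(wallset: WallSet, marks: PhaseMarks) -> PhaseMarks:
    """Snap filtered-signal phase marks to the raw LVID extrema.

    The single-bin spectral filter quantizes the cardiac frequency to the
    DFT grid, so for a non-integer number of cycles its peak columns
    drift slowly against the true beats.  The filtered peaks therefore
    only *locate* each systolic/diastolic section; within a window of
    0.4x the smallest inter-mark gap each ED mark is moved to the raw
    LVID maximum and each ES mark to the raw minimum.
    """
    lvid = wallset.validate().lvid_mm()
    marks.validate()
    merged = np.sort(np.concatenate([marks.ed_cols, marks.es_cols]))
    gap = int(np.diff(merged).min()) if merged.size > 1 else len(lvid)
    w = max(1, int(0.4 * gap))

    def snap(cols, extremum):
        out = []
        for c in cols:
            lo, hi = max(0, c - w), min(len(lvid), c + w + 1)
            out.append(lo + int(extremum(lvid[lo:hi])))
        return np.array(sorted(set(out)), dtype=int)

    return PhaseMarks(
        ed_cols=snap(marks.ed_cols, np.argmax),
        es_cols=snap(marks.es_cols, np.argmin),
    ).validate()


def measure_walls(wallset: WallSet, marks: PhaseMarks) -> MModeDimensions:
    """Chamber and wall dimensions at the marked beats, averaged.

    At each end-diastolic column: LVID;d = POST_ENDO - ANT_ENDO,
    LVAW;d = ANT_ENDO - ANT_EPI, LVPW;d = POST_EPI - POST_ENDO; the
    systolic triplet analogously at the ES columns.  The reported value of
    each dimension is the mean over all detected beats; per-beat values
    are retained for audit.
    """
    wallset.validate()
    marks.validate()
    t = {w: wallset[w].depth_mm for w in WALL_ORDER}
    ed, es = marks.ed_cols, marks.es_cols
    per_beat = {
        "lvid_d": t[WallId.POST_ENDO][ed] - t[WallId.ANT_ENDO][ed],
        "lvaw_d": t[WallId.ANT_ENDO][ed] - t[WallId.ANT_EPI][ed],
        "lvpw_d": t[WallId.POST_EPI][ed] - t[WallId.POST_ENDO][ed],
        "lvid_s": t[WallId.POST_ENDO][es] - t[WallId.ANT_ENDO][es],
        "lvaw_s": t[WallId.ANT_ENDO][es] - t[WallId.ANT_EPI][es],
        "lvpw_s": t[WallId.POST_EPI][es] - t[WallId.POST_ENDO][es],
    }
    return MModeDimensions(
        lvid_d=float(per_beat["lvid_d"].mean()),
        lvid_s=float(per_beat["lvid_s"].mean()),
        lvaw_d=float(per_beat["lvaw_d"].mean()),
        lvaw_s=float(per_beat["lvaw_s"].mean()),
        lvpw_d=float(per_beat["lvpw_d"].mean()),
        lvpw_s=float(per_beat["lvpw_s"].mean()),
        per_beat={k: v.tolist() for k, v in per_beat.items()},
    ).validate()


def segment_mmode(
    image: MModeImage,
    seeds: Sequence[SeedPointPair],
    opts: MModeOptions = MModeOptions(),
) -> tuple:
    """Full M-mode pipeline: regions -> costs -> DP -> filter -> measure.

    ``seeds`` must contain one pair per wall interface.  Phase marks come
    from the spectrally filtered traces; dimensions are measured on the
    raw dynamic-programming traces at those columns (the filtered signal
    provides peak *locations*, avoiding amplitude bias from spectral
    leakage).  Deterministic for fixed inputs.  Returns
    ``(raw WallSet, PhaseMarks, MModeDimensions)``.
    """
    image.validate()
    by_wall = {SeedPointPair(s.wall_id, s.upper, s.lower).wall_id: s for s in seeds}
    missing = [w for w in WALL_ORDER if w not in by_wall]
    if missing:
        raise ValidationError(f"need one seed pair per wall; missing {missing}")
    traces = {}
    for wall in WALL_ORDER:
        region = make_region(by_wall[wall], image)
        cimg = cost_image(image, region, opts)
        traces[wall] = optimal_path(cimg, opts.max_step)
    raw = WallSet(traces).validate()
    frame_rate = 1000.0 / float(image.meta.time_per_column)
    filtered = WallSet(
        {w: spectral_filter(tr, frame_rate) for w, tr in raw.traces.items()}
    )
    marks = refine_marks(raw, detect_phases(filtered))
    dims = measure_walls(raw, marks)
    return raw, marks, dims


def edit_trace(
    wallset: WallSet,
    wall_id: WallId,
    column_range: tuple,
    new_depths: Sequence[float],
) -> WallSet:
    """Splice manually corrected depths into one trace.

    ``column_range`` is a half-open ``(start, stop)`` column interval.
    The edited wall set is revalidated; an edit that breaks the depth
    ordering of the four interfaces is rejected with a diagnostic.
    """
    wall_id = WallId(wall_id)
    start, stop = column_range
    new_depths = np.asarray(new_depths, dtype=float)
    old = wallset[wall_id]
    if not (0 <= start < stop <= len(old)):
        raise ValidationError("column_range outside the trace")
    if new_depths.size != stop - start:
        raise ValidationError("new_depths length must match column_range")
    depths = old.depth_mm.copy()
    depths[start:stop] = new_depths
    traces = dict(wallset.traces)
    traces[wall_id] = replace(old, depth_mm=depths)
    return WallSet(traces).validate()
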