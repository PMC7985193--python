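"""Core calibrated-image and geometry containers.

Conventions used throughout the package:

* pixel indices are 0-based; row 0 is the shallowest depth (transducer side)
  and depth increases downward, matching the on-screen ultrasound display;
* physical coordinates are millimetres with the origin at the image top-left,
  ``x`` along the lateral (column) direction and ``y`` along depth (rows);
* times are milliseconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import numpy as np
from shapely.geometry import Polygon

from .errors import ValidationError


class Phase(str, Enum):
    """Cardiac phase of a traced frame."""

    ED = "ED"  # end-diastole: maximal filling
    ES = "ES"  # end-systole: maximal contraction


class WallId(str, Enum):
    """The four short-axis M-mode wall interfaces, ordered by depth."""

    ANT_EPI = "ANT_EPI"
    ANT_ENDO = "ANT_ENDO"
    POST_ENDO = "POST_ENDO"
    POST_EPI = "POST_EPI"


#: Depth ordering of the four interfaces (shallow to deep).
WALL_ORDER = (WallId.ANT_EPI, WallId.ANT_ENDO, WallId.POST_ENDO, WallId.POST_EPI)


@dataclass
class ImageMeta:
    """Calibration and provenance metadata for one acquisition.

    ``pixel_spacing_lateral`` applies to B-mode frames; ``time_per_column``
    applies to M-mode sweeps (exactly one of the two is meaningful for a
    given mode).  ``heart_rate_bpm`` may be absent: heart-rate-dependent
    endpoints are then withheld rather than the run aborting.
    """

    pixel_spacing_axial: float  # mm / px, depth direction
    pixel_spacing_lateral: Optional[float] = None  # mm / px (B-mode)
    time_per_column: Optional[float] = None  # ms / px (M-mode)
    frame_interval_ms: Optional[float] = None  # cine loops
    heart_rate_bpm: Optional[float] = None
    mode_tag: str = ""
    subject_id: str = ""
    acquisition_time: Optional[str] = None

    def validate(self) -> "ImageMeta":
        if not self.mode_tag:
            raise ValidationError("mode_tag must be non-empty")
        if not self.pixel_spacing_axial > 0:
            raise ValidationError("pixel_spacing_axial must be > 0")
        for name in ("pixel_spacing_lateral", "time_per_column", "frame_interval_ms"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise ValidationError(f"{name} must be > 0 when present")
        return self


@dataclass
class CineLoop:
    """A B-mode cine loop: ordered stack of 2-D frames plus calibration."""

    frames: np.ndarray  # (n_frames, rows, cols)
    meta: ImageMeta

    def validate(self) -> "CineLoop":
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3 or self.frames.shape[0] < 2:
            raise ValidationError("cine loop requires >=2 frames of equal shape")
        if not np.all(np.isfinite(self.frames)) or self.frames.min() < 0:
            raise ValidationError("frame intensities must be finite and >= 0")
        self.meta.validate()
        if self.meta.frame_interval_ms is None:
            raise ValidationError("cine loop requires frame_interval_ms")
        return self

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def frame_shape(self) -> tuple:
        return tuple(self.frames.shape[1:])


@dataclass
class MModeImage:
    """An M-mode sweep: rows are depth, columns are time (left to right)."""

    grid: np.ndarray  # (depth_px, columns)
    meta: ImageMeta

    def validate(self) -> "MModeImage":
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 2 or self.grid.shape[1] < 2:
            raise ValidationError("M-mode image requires a 2-D grid with >=2 columns")
        if not np.all(np.isfinite(self.grid)) or self.grid.min() < 0:
            raise ValidationError("intensities must be finite and >= 0")
        self.meta.validate()
        if self.meta.time_per_column is None:
            raise ValidationError("M-mode image requires time_per_column")
        return self

    @property
    def n_columns(self) -> int:
        return int(self.grid.shape[1])

    @property
    def depth_extent_mm(self) -> float:
        return self.grid.shape[0] * self.meta.pixel_spacing_axial

    def col_times_ms(self) -> np.ndarray:
        return np.arange(self.n_columns) * float(self.meta.time_per_column)


@dataclass
class LvContour:
    """Closed endocardial polygon for one cardiac phase.

    ``basal_indices`` flag the two vertices whose connecting chord is the
    LV base (mitral plane); the long axis runs from the chord midpoint to
    the farthest vertex (apex).
    """

    vertices: np.ndarray  # (n, 2) of (x_mm, y_mm)
    basal_indices: tuple
    phase: Phase

    def validate(self) -> "LvContour":
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise ValidationError("vertices must be an (n, 2) array")
        if self.vertices.shape[0] < 8:
            raise ValidationError("contour requires >= 8 vertices")
        i, j = self.basal_indices
        n = self.vertices.shape[0]
        if i == j or not (0 <= i < n and 0 <= j < n):
            raise ValidationError("basal_indices must be two distinct valid indices")
        if not self.polygon().is_simple:
            raise ValidationError("contour polygon is self-intersecting")
        self.phase = Phase(self.phase)
        return self

    def polygon(self) -> Polygon:
        return Polygon(self.vertices)

    def area_mm2(self) -> float:
        """Enclosed area by the shoelace formula (shapely)."""
        return float(self.polygon().area)


@dataclass
class SeedPointPair:
    """User-placed upper/lower bounds around one M-mode wall interface."""

    wall_id: WallId
    upper: tuple  # (t_ms, depth_mm)
    lower: tuple  # (t_ms, depth_mm)

    def validate(self, image: Optional[MModeImage] = None) -> "SeedPointPair":
        self.wall_id = WallId(self.wall_id)
        u_t, u_d = self.upper
        l_t, l_d = self.lower
        if u_d >= l_d:
            # normalize: seed order should not matter to the caller
            self.upper, self.lower = (l_t, l_d), (u_t, u_d)
            u_d, l_d = l_d, u_d
        if self.upper[1] == self.lower[1]:
            raise ValidationError("seed points must differ in depth")
        if image is not None:
            depth = image.depth_extent_mm
            t_max = image.n_columns * float(image.meta.time_per_column)
            for t, d in (self.upper, self.lower):
                if not (0 <= d <= depth) or not (0 <= t <= t_max):
                    raise ValidationError(
                        f"seed point ({t} ms, {d} mm) outside image extent"
                    )
        return self


#: Report column registry: endpoint name -> unit string, in the fixed order
#: used by io_formats.write_report.
MEASURE_UNITS = {
    "ESA": "mm^2",
    "EDA": "mm^2",
    "ESV": "uL",
    "EDV": "uL",
    "ESD": "mm",
    "EDD": "mm",
    "EF": "%",
    "FS": "%",
    "FAC": "%",
    "SV": "uL",
    "CO": "mL/min",
    "LVID;s": "mm",
    "LVID;d": "mm",
    "LVAW;s": "mm",
    "LVAW;d": "mm",
    "LVPW;s": "mm",
    "LVPW;d": "mm",
    "LV mass": "mg",
    "LV mass corr": "mg",
}


@dataclass
class MeasureSet:
    """Named LV endpoints for one subject/timepoint in one imaging mode.

    ``values`` maps endpoint names from :data:`MEASURE_UNITS` to numbers;
    heart-rate-dependent endpoints (CO) are simply absent when the header
    carried no heart rate.
    """

    subject_id: str
    mode: str  # "B-mode" | "M-mode"
    values: dict = field(default_factory=dict)
    label: str = ""  # timepoint / condition, e.g. "baseline"
    heart_rate_bpm: Optional[float] = None

    def validate(self) -> "MeasureSet":
        unknown = set(self.values) - set(MEASURE_UNITS)
        if unknown:
            raise ValidationError(f"unknown endpoint names: {sorted(unknown)}")
        return self

    @property
    def key(self) -> tuple:
        return (self.subject_id, self.label, self.mode)
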