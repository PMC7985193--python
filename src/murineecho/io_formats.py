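"""Readers and writers for images, ROIs, seed points and result reports.

Image formats
-------------
Two interchangeable on-disk forms are supported for both cine loops and
M-mode sweeps:

* multi-page TIFF (or single-page for M-mode) with a JSON *sidecar* file at
  ``<image>.json`` carrying calibration (spacings, frame interval, sweep
  speed, optional heart rate, mode tag, subject id);
* multi-frame DICOM, where the standard tags are authoritative
  (PixelSpacing, FrameTime, HeartRate, SeriesDescription, PatientID).

All round trips are lossless: intensities exactly, coordinates to 1e-6 mm.
The DICOM path stores integer-valued grids only (bit-exact PixelData);
floating-point data round-trips through the TIFF+sidecar path.

ROI and seed-point schemas (JSON)
---------------------------------
ROI:   ``{"phase": "ED"|"ES", "vertices": [[x_mm, y_mm], ...],
          "basal_indices": [i, j]}``
Seeds: ``[{"wall": "ANT_EPI", "upper": [t_ms, depth_mm],
           "lower": [t_ms, depth_mm]}, ...]`` (four entries).

The study report is a CSV with a fixed, unit-annotated column order plus an
optional PNG overlay snapshot per subject; re-writing with updated measures
replaces the row with the same (subject, label, mode) key.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import pydicom
import tifffile
from pydicom.dataset import FileDataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from .errors import FormatError, MetadataError, ModeMismatchWarning, ValidationError
from .types import (
    MEASURE_UNITS,
    CineLoop,
    ImageMeta,
    LvContour,
    MeasureSet,
    MModeImage,
    Phase,
    SeedPointPair,
    WallId,
)

_SC_MULTIFRAME_UID = "1.2.840.10008.5.1.4.1.1.7.2"  # multi-frame secondary capture


# ---------------------------------------------------------------------------
# sidecar metadata


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def _meta_to_dict(meta: ImageMeta) -> dict:
    return {k: v for k, v in vars(meta).items() if v is not None}


def _meta_from_sidecar(path: Path, mode_expected: str) -> ImageMeta:
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise MetadataError(f"missing sidecar metadata file {sidecar}")
    try:
        raw = json.loads(sidecar.read_text())
    except json.JSONDecodeError as exc:
        raise MetadataError(f"unparsable sidecar {sidecar}: {exc}") from exc
    known = set(ImageMeta.__dataclass_fields__)
    meta = ImageMeta(**{k: v for k, v in raw.items() if k in known})
    _check_mode(meta, mode_expected)
    return meta


def _check_mode(meta: ImageMeta, expected: str) -> None:
    if meta.mode_tag and meta.mode_tag != expected:
        warnings.warn(
            f"image tagged {meta.mode_tag!r} read as {expected}",
            ModeMismatchWarning,
            stacklevel=3,
        )


# ---------------------------------------------------------------------------
# cine loops (B-mode)


def read_cine(path) -> CineLoop:
    """Read a B-mode cine loop from multi-page TIFF+sidecar or DICOM.

    The mode tag is taken from the header; a non-"B-mode" tag raises a
    :class:`ModeMismatchWarning` but still returns the data.  A missing
    heart rate is valid; missing spacing raises :class:`MetadataError`.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if path.suffix.lower() in (".dcm", ".dicom"):
        frames, meta = _read_dicom(path, expect_frames=True)
        _check_mode(meta, "B-mode")
    else:
        try:
            frames = tifffile.imread(path)
        except Exception as exc:  # unreadable / not a TIFF
            raise FormatError(f"cannot read {path} as TIFF: {exc}") from exc
        meta = _meta_from_sidecar(path, "B-mode")
    frames = np.asarray(frames)
    if frames.ndim == 2:
        raise ValidationError(">=2 frames required for a cine loop")
    if meta.pixel_spacing_lateral is None:
        raise MetadataError("cine loop metadata lacks lateral pixel spacing")
    return CineLoop(frames=frames, meta=meta).validate()


def write_cine(loop: CineLoop, path) -> Path:
    """Write a cine loop to multi-page TIFF+sidecar or multi-frame DICOM."""
    loop.validate()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix.lower() in (".dcm", ".dicom"):
        _write_dicom(loop.frames, loop.meta, path)
    else:
        tifffile.imwrite(path, loop.frames, photometric="minisblack")
        _sidecar_path(path).write_text(json.dumps(_meta_to_dict(loop.meta), indent=1))
    return path


# ---------------------------------------------------------------------------
# M-mode sweeps


def read_mmode(path) -> MModeImage:
    """Read an M-mode sweep (single-page TIFF/PNG + sidecar, or DICOM)."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if path.suffix.lower() in (".dcm", ".dicom"):
        grid, meta = _read_dicom(path, expect_frames=False)
        _check_mode(meta, "M-mode")
    else:
        try:
            grid = tifffile.imread(path)
        except Exception as exc:
            raise FormatError(f"cannot read {path} as TIFF: {exc}") from exc
        meta = _meta_from_sidecar(path, "M-mode")
    if meta.time_per_column is None:
        raise MetadataError("M-mode metadata lacks time_per_column")
    return MModeImage(grid=np.asarray(grid), meta=meta).validate()


def write_mmode(image: MModeImage, path) -> Path:
    image.validate()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix.lower() in (".dcm", ".dicom"):
        _write_dicom(image.grid[np.newaxis], image.meta, path)
    else:
        tifffile.imwrite(path, image.grid)
        _sidecar_path(path).write_text(json.dumps(_meta_to_dict(image.meta), indent=1))
    return path


# ---------------------------------------------------------------------------
# DICOM backend


def _write_dicom(frames: np.ndarray, meta: ImageMeta, path: Path) -> None:
    frames = np.asarray(frames)
    if not np.issubdtype(frames.dtype, np.integer):
        if np.allclose(frames, np.round(frames)):
            frames = np.round(frames).astype(np.uint16)
        else:
            raise FormatError(
                "DICOM writer stores integer intensities only; "
                "use the TIFF+sidecar format for floating-point data"
            )
    if frames.min() < 0 or frames.max() > 0xFFFF:
        raise FormatError("DICOM writer supports unsigned 16-bit intensities")
    frames = frames.astype(np.uint16)

    fm = FileMetaDataset()
    fm.MediaStorageSOPClassUID = _SC_MULTIFRAME_UID
    fm.MediaStorageSOPInstanceUID = generate_uid()
    fm.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(str(path), {}, file_meta=fm, preamble=b"\0" * 128)
    ds.SOPClassUID = _SC_MULTIFRAME_UID
    ds.SOPInstanceUID = fm.MediaStorageSOPInstanceUID
    ds.Modality = "US"
    ds.SeriesDescription = meta.mode_tag
    ds.PatientID = meta.subject_id or "unknown"
    if meta.acquisition_time:
        ds.ContentDate = meta.acquisition_time.replace("-", "")[:8]
    ds.NumberOfFrames = frames.shape[0]
    ds.Rows, ds.Columns = frames.shape[1], frames.shape[2]
    lateral = meta.pixel_spacing_lateral
    if lateral is None and meta.time_per_column is not None:
        lateral = meta.time_per_column  # ms/px carried in the col-spacing slot
    ds.PixelSpacing = [str(meta.pixel_spacing_axial), str(lateral)]
    if meta.frame_interval_ms is not None:
        ds.FrameTime = str(meta.frame_interval_ms)
    if meta.heart_rate_bpm is not None:
        ds.HeartRate = int(round(meta.heart_rate_bpm))
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    ds.PixelData = frames.tobytes()
    ds.save_as(path, enforce_file_format=True)


def _read_dicom(path: Path, expect_frames: bool):
    try:
        ds = pydicom.dcmread(path)
    except Exception as exc:
        raise FormatError(f"cannot read {path} as DICOM: {exc}") from exc
    if "PixelSpacing" not in ds:
        raise MetadataError(f"{path} has no PixelSpacing tag")
    arr = ds.pixel_array
    n = int(getattr(ds, "NumberOfFrames", 1))
    if n > 1:
        arr = arr.reshape(n, ds.Rows, ds.Columns)
    axial, col_spacing = (float(v) for v in ds.PixelSpacing)
    mode_tag = str(getattr(ds, "SeriesDescription", ""))
    hr = getattr(ds, "HeartRate", None)
    meta = ImageMeta(
        pixel_spacing_axial=axial,
        pixel_spacing_lateral=col_spacing if expect_frames else None,
        time_per_column=None if expect_frames else col_spacing,
        frame_interval_ms=float(ds.FrameTime) if "FrameTime" in ds else None,
        heart_rate_bpm=float(hr) if hr is not None else None,
        mode_tag=mode_tag,
        subject_id=str(getattr(ds, "PatientID", "")),
    )
    if expect_frames:
        return arr, meta
    return (arr[0] if arr.ndim == 3 else arr), meta


# ---------------------------------------------------------------------------
# ROI contours and seed points


def read_roi(path) -> LvContour:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        raw = json.loads(path.read_text())
        contour = LvContour(
            vertices=np.asarray(raw["vertices"], dtype=float),
            basal_indices=tuple(raw["basal_indices"]),
            phase=Phase(raw["phase"]),
        )
    except (KeyError, TypeError, json.JSONDecodeError) as exc:
        raise FormatError(f"bad ROI file {path}: {exc}") from exc
    return contour.validate()


def write_roi(contour: LvContour, path) -> Path:
    contour.validate()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {
        "phase": contour.phase.value,
        "vertices": np.round(contour.vertices, 6).tolist(),
        "basal_indices": [int(i) for i in contour.basal_indices],
    }
    path.write_text(json.dumps(payload, indent=1))
    return path


def read_seeds(path) -> list:
    """Read the four M-mode seed-point pairs (8 points) from JSON."""
    path = Path(path)
    try:
        raw = json.loads(path.read_text())
        seeds = [
            SeedPointPair(
                wall_id=WallId(e["wall"]),
                upper=tuple(e["upper"]),
                lower=tuple(e["lower"]),
            ).validate()
            for e in raw
        ]
    except (KeyError, TypeError, json.JSONDecodeError) as exc:
        raise FormatError(f"bad seeds file {path}: {exc}") from exc
    return seeds


def write_seeds(seeds: Sequence[SeedPointPair], path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = [
        {
            "wall": s.wall_id.value,
            "upper": [round(float(v), 6) for v in s.upper],
            "lower": [round(float(v), 6) for v in s.lower],
        }
        for s in seeds
    ]
    path.write_text(json.dumps(payload, indent=1))
    return path


# ---------------------------------------------------------------------------
# study report


REPORT_KEY_COLUMNS = ["subject_id", "label", "mode", "heart_rate_bpm"]
REPORT_COLUMNS = REPORT_KEY_COLUMNS + [
    f"{name} ({unit})" for name, unit in MEASURE_UNITS.items()
]


def write_report(
    measures: Sequence[MeasureSet],
    path,
    overlays: Optional[dict] = None,
) -> Path:
    """Write (or update) the aggregated study CSV report.

    One row per (subject, label, mode) key, fixed column order with units in
    the header.  If ``path`` already exists, rows with matching keys are
    replaced and all other rows are preserved, so re-running an analysis
    updates the report in place.  Endpoints absent from a MeasureSet (e.g.
    CO when the header carried no heart rate) leave their cell empty.

    ``overlays`` optionally maps subject_id to an already-rendered
    matplotlib Figure; each is saved as ``<report stem>_<subject>.png``.
    """
    if not measures:
        raise ValidationError("write_report requires a non-empty measure list")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    rows = {}
    if path.exists():
        old = pd.read_csv(path, dtype={"subject_id": str, "label": str, "mode": str})
        old = old.fillna({"label": ""})
        for _, r in old.iterrows():
            rows[(r["subject_id"], r["label"], r["mode"])] = r.to_dict()
    for m in measures:
        m.validate()
        row = {c: "" for c in REPORT_COLUMNS}
        row["subject_id"] = m.subject_id
        row["label"] = m.label
        row["mode"] = m.mode
        row["heart_rate_bpm"] = (
            "" if m.heart_rate_bpm is None else float(m.heart_rate_bpm)
        )
        for name, value in m.values.items():
            # reporting precision 1e-4: stable under the 1e-6 mm coordinate
            # round trip of stored ROI files
            row[f"{name} ({MEASURE_UNITS[name]})"] = round(float(value), 4)
        rows[m.key] = row
    frame = pd.DataFrame(
        [rows[k] for k in sorted(rows)], columns=REPORT_COLUMNS
    )
    frame.to_csv(path, index=False)

    if overlays:
        for subject_id, fig in overlays.items():
            fig.savefig(path.with_name(f"{path.stem}_{subject_id}.png"), dpi=100)
    return path


def read_report(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such report: {path}")
    return pd.read_csv(path)
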