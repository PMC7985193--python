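"""Batch study processing: manifest-driven runs and report regeneration.

A study manifest (JSON) lists the subjects to process, each with its cine
loop, M-mode sweep, user-selected ED/ES frame indices and seed-point file,
plus the reference library directory and an optional analysis config.
``run_study`` processes every subject — B-mode multi-atlas segmentation of
the two selected frames and M-mode wall tracing — computes the endpoint
sets, writes per-subject artifacts (masks, ROI contours, traces, phase
marks, overlay snapshots) and an aggregated CSV report, and logs every
automated decision (NMI scores, fusion choices) for audit.  Per-subject
failures are isolated: the run continues and reports them.

``regenerate_reports`` recomputes all measures from the stored (possibly
hand-edited) segmentations, so the report always reflects the latest
edits only.
"""

from __future__ import annotations

import json
import traceback
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import tifffile

from . import io_formats
from .bmode_atlas import ReferenceLibrary, SegmentOptions, load_library, segment_frame
from .cardiac_params import (
    DEFAULT_N_DISKS,
    bmode_measures,
    contour_from_mask,
    mmode_measures,
)
from .errors import EchoError, ValidationError
from .mmode_walls import (
    MModeOptions,
    PhaseMarks,
    WallSet,
    WallTrace,
    detect_phases,
    measure_walls,
    refine_marks,
    spectral_filter,
)
from .types import Phase, WallId, WALL_ORDER


@dataclass
class SubjectSpec:
    """One study subject: inputs plus the user's frame/seed selections."""

    id: str
    bmode_path: Optional[str] = None
    mmode_path: Optional[str] = None
    ed_frame: Optional[int] = None
    es_frame: Optional[int] = None
    seeds_path: Optional[str] = None
    heart_rate: Optional[float] = None
    label: str = ""


@dataclass
class StudyManifest:
    subjects: List[SubjectSpec]
    library_dir: Optional[str] = None
    config_path: Optional[str] = None

    def validate(self) -> "StudyManifest":
        ids = [s.id for s in self.subjects]
        if len(set(ids)) != len(ids):
            raise ValidationError("subject ids must be unique")
        return self


@dataclass
class StudyConfig:
    """Analysis configuration shared by every subject of a run."""

    segment: SegmentOptions = field(default_factory=SegmentOptions)
    mmode: MModeOptions = field(default_factory=MModeOptions)
    n_disks: int = DEFAULT_N_DISKS

    @classmethod
    def from_json(cls, path) -> "StudyConfig":
        raw = json.loads(Path(path).read_text())
        seg = {k: v for k, v in raw.get("segment", {}).items()}
        if "max_evals" in seg:
            seg["max_evals"] = tuple(seg["max_evals"])
        return cls(
            segment=SegmentOptions(**seg),
            mmode=MModeOptions(**raw.get("mmode", {})),
            n_disks=int(raw.get("n_disks", DEFAULT_N_DISKS)),
        )


@dataclass
class StudyResult:
    report_path: Path
    processed: List[str]
    failures: dict  # subject id -> error text
    log_path: Path


def load_manifest(path) -> StudyManifest:
    raw = json.loads(Path(path).read_text())
    subjects = [SubjectSpec(**s) for s in raw["subjects"]]
    return StudyManifest(
        subjects=subjects,
        library_dir=raw.get("library_dir"),
        config_path=raw.get("config_path"),
    ).validate()


def _save_traces(wallset: WallSet, marks: PhaseMarks, subject_dir: Path) -> None:
    frame = pd.DataFrame(
        {
            "col_time_ms": wallset[WALL_ORDER[0]].col_times_ms,
            **{w.value: wallset[w].depth_mm for w in WALL_ORDER},
        }
    )
    frame.to_csv(subject_dir / "walls.csv", index=False)
    (subject_dir / "marks.json").write_text(
        json.dumps(
            {"ed_cols": marks.ed_cols.tolist(), "es_cols": marks.es_cols.tolist()}
        )
    )


def _load_traces(subject_dir: Path) -> WallSet:
    frame = pd.read_csv(subject_dir / "walls.csv")
    t = frame["col_time_ms"].to_numpy()
    return WallSet(
        {
            w: WallTrace(wall_id=w, depth_mm=frame[w.value].to_numpy(), col_times_ms=t)
            for w in WALL_ORDER
        }
    ).validate()


def _overlay_figure(frames_masks, mmode_pair):
    n = len(frames_masks) + (1 if mmode_pair else 0)
    fig, axes = plt.subplots(1, max(n, 1), figsize=(4 * max(n, 1), 3.2))
    axes = np.atleast_1d(axes)
    for ax, (title, frame, mask) in zip(axes, frames_masks):
        ax.imshow(frame, cmap="gray")
        ax.contour(mask.astype(float), levels=[0.5], colors="r", linewidths=0.8)
        ax.set_title(title, fontsize=8)
        ax.axis("off")
    if mmode_pair:
        ax = axes[len(frames_masks)]
        image, wallset = mmode_pair
        sp = image.meta.pixel_spacing_axial
        ax.imshow(image.grid, cmap="gray", aspect="auto")
        for w in WALL_ORDER:
            ax.plot(wallset[w].depth_mm / sp, lw=0.6)
        ax.set_title("M-mode walls", fontsize=8)
        ax.axis("off")
    fig.tight_layout()
    return fig


def _process_subject(
    subject: SubjectSpec,
    library: Optional[ReferenceLibrary],
    config: StudyConfig,
    subject_dir: Path,
    log: dict,
):
    subject_dir.mkdir(parents=True, exist_ok=True)
    measures = []
    overlay_panels = []
    mmode_pair = None
    meta_record = {"label": subject.label}

    if subject.bmode_path:
        if library is None:
            raise ValidationError("B-mode processing requires a reference library")
        loop = io_formats.read_cine(subject.bmode_path)
        if subject.ed_frame is None or subject.es_frame is None:
            raise ValidationError("manifest must give ed_frame and es_frame")
        hr = subject.heart_rate or loop.meta.heart_rate_bpm
        spacing = loop.meta.pixel_spacing_axial
        contours = {}
        for phase, idx in ((Phase.ED, subject.ed_frame), (Phase.ES, subject.es_frame)):
            frame = loop.frames[idx]
            mask, _, results = segment_frame(
                frame, library, config.segment, phase=phase, spacing_mm=spacing
            )
            tifffile.imwrite(
                subject_dir / f"{phase.value.lower()}_mask.tif", mask.astype(np.uint8)
            )
            contour = contour_from_mask(mask, spacing, phase)
            io_formats.write_roi(
                contour, subject_dir / f"{phase.value.lower()}_roi.json"
            )
            contours[phase] = contour
            overlay_panels.append((f"{subject.id} {phase.value}", frame, mask))
            log.setdefault("registrations", {})[f"{subject.id}/{phase.value}"] = [
                {"entry": r.entry_id, "nmi": round(r.nmi_score, 6)} for r in results
            ]
        measures.append(
            bmode_measures(
                contours[Phase.ED],
                contours[Phase.ES],
                heart_rate=hr,
                n_disks=config.n_disks,
                subject_id=subject.id,
                label=subject.label,
            )
        )
        meta_record["bmode"] = {"heart_rate": hr, "pixel_spacing_mm": spacing}

    if subject.mmode_path:
        image = io_formats.read_mmode(subject.mmode_path)
        if not subject.seeds_path:
            raise ValidationError("manifest must give seeds_path for M-mode")
        seeds = io_formats.read_seeds(subject.seeds_path)
        from .mmode_walls import segment_mmode  # local to keep import graph flat

        wallset, marks, dims = segment_mmode(image, seeds, config.mmode)
        _save_traces(wallset, marks, subject_dir)
        hr = subject.heart_rate or image.meta.heart_rate_bpm
        measures.append(
            mmode_measures(dims, heart_rate=hr, subject_id=subject.id,
                           label=subject.label)
        )
        mmode_pair = (image, wallset)
        meta_record["mmode"] = {
            "heart_rate": hr,
            "pixel_spacing_mm": image.meta.pixel_spacing_axial,
            "time_per_column": image.meta.time_per_column,
        }

    (subject_dir / "meta.json").write_text(json.dumps(meta_record, indent=1))
    fig = _overlay_figure(overlay_panels, mmode_pair)
    fig.savefig(subject_dir / "overlay.png", dpi=100)
    plt.close(fig)
    return measures


def run_study(
    manifest: StudyManifest,
    out_dir,
    config: Optional[StudyConfig] = None,
) -> StudyResult:
    """Process every subject in the manifest; isolate per-subject failures.

    Deterministic: identical manifest, config and inputs yield a
    byte-identical report.
    """
    manifest.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if config is None:
        config = (
            StudyConfig.from_json(manifest.config_path)
            if manifest.config_path
            else StudyConfig()
        )
    library = load_library(manifest.library_dir) if manifest.library_dir else None

    all_measures, processed, failures = [], [], {}
    log: dict = {"subjects": {}}
    for subject in manifest.subjects:
        try:
            measures = _process_subject(
                subject, library, config, out_dir / subject.id, log
            )
            all_measures.extend(measures)
            processed.append(subject.id)
            log["subjects"][subject.id] = "ok"
        except (EchoError, OSError, IndexError, KeyError) as exc:
            failures[subject.id] = f"{type(exc).__name__}: {exc}"
            log["subjects"][subject.id] = failures[subject.id]
    if not all_measures:
        raise EchoError(f"no subject processed successfully: {failures}")
    report_path = io_formats.write_report(all_measures, out_dir / "report.csv")
    log_path = out_dir / "log.json"
    log_path.write_text(json.dumps(log, indent=1, sort_keys=True))
    return StudyResult(
        report_path=report_path,
        processed=processed,
        failures=failures,
        log_path=log_path,
    )


def regenerate_reports(results_dir) -> StudyResult:
    """Recompute all measures from stored (possibly edited) segmentations.

    Reads each subject's ROI contours and wall traces back from the
    results directory, re-derives phase marks and endpoint sets, and
    rewrites the aggregated report so it reflects the latest edits only.
    Missing segmentation files are listed; other subjects regenerate.
    """
    results_dir = Path(results_dir)
    measures, processed, failures = [], [], {}
    for subject_dir in sorted(p for p in results_dir.iterdir() if p.is_dir()):
        sid = subject_dir.name
        meta_path = subject_dir / "meta.json"
        if not meta_path.exists():
            continue
        meta = json.loads(meta_path.read_text())
        label = meta.get("label", "")
        try:
            if "bmode" in meta:
                ed = io_formats.read_roi(subject_dir / "ed_roi.json")
                es = io_formats.read_roi(subject_dir / "es_roi.json")
                measures.append(
                    bmode_measures(
                        ed,
                        es,
                        heart_rate=meta["bmode"].get("heart_rate"),
                        subject_id=sid,
                        label=label,
                    )
                )
            if "mmode" in meta:
                wallset = _load_traces(subject_dir)
                frame_rate = 1000.0 / meta["mmode"]["time_per_column"]
                filtered = WallSet(
                    {
                        w: spectral_filter(tr, frame_rate)
                        for w, tr in wallset.traces.items()
                    }
                )
                marks = refine_marks(wallset, detect_phases(filtered))
                dims = measure_walls(wallset, marks)
                measures.append(
                    mmode_measures(
                        dims,
                        heart_rate=meta["mmode"].get("heart_rate"),
                        subject_id=sid,
                        label=label,
                    )
                )
            processed.append(sid)
        except (EchoError, OSError, KeyError) as exc:
            failures[sid] = f"{type(exc).__name__}: {exc}"
    if not measures:
        raise EchoError("nothing to regenerate")
    report_file = results_dir / "report.csv"
    if report_file.exists():  # regenerated report reflects latest edits only
        report_file.unlink()
    report_path = io_formats.write_report(measures, report_file)
    return StudyResult(
        report_path=report_path,
        processed=processed,
        failures=failures,
        log_path=results_dir / "log.json",
    )
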