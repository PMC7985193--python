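"""Multi-atlas segmentation of long-axis B-mode frames.

A target frame is denoised and down-sampled, every entry of a manually
traced reference library is affinely registered to it with normalized
mutual information (NMI) as the objective, the warped labels of the five
best-scoring registrations are averaged into a probability map, and a
threshold (with largest-component selection and hole filling) produces the
final LV mask.

NMI is fixed as ``(H(a) + H(b)) / H(a, b)`` computed from a joint histogram
with equal-width bins per image (32 by default); its range is [1, 2].  The
affine optimizer is a three-level multi-resolution Powell ascent on NMI —
fully deterministic, so repeat analyses of the same frame are bit-identical.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
import tifffile
from scipy import ndimage, optimize

from .errors import (
    LibrarySizeWarning,
    SegmentationError,
    ValidationError,
)
from .types import Phase

# ---------------------------------------------------------------------------
# reference library


@dataclass
class AtlasEntry:
    """One manually traced reference image: a frame and its binary LV mask."""

    frame: np.ndarray
    mask: np.ndarray
    phase: Phase
    id: str
    subject: str = ""
    pixel_spacing_mm: float = 1.0

    def validate(self) -> "AtlasEntry":
        self.frame = np.asarray(self.frame, dtype=float)
        self.mask = np.asarray(self.mask).astype(bool)
        if self.frame.shape != self.mask.shape:
            raise ValidationError(f"entry {self.id}: frame/mask shape mismatch")
        if not self.mask.any():
            raise ValidationError(f"entry {self.id}: empty mask")
        self.phase = Phase(self.phase)
        return self


@dataclass
class ReferenceLibrary:
    """Atlas of (frame, LV mask, phase) entries driving B-mode segmentation.

    Each traced subject contributes one ED and one ES entry; entries are
    stored flat and selected by phase at segmentation time so that ED
    targets are matched against ED atlases and ES against ES.
    """

    entries: List[AtlasEntry] = field(default_factory=list)

    def validate(self) -> "ReferenceLibrary":
        for e in self.entries:
            e.validate()
        return self

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def subjects(self) -> list:
        seen: dict = {}
        for e in self.entries:
            seen.setdefault(e.subject or e.id, None)
        return list(seen)

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def phase_subset(self, phase: Phase) -> "ReferenceLibrary":
        phase = Phase(phase)
        return ReferenceLibrary([e for e in self.entries if e.phase == phase])

    def subject_subset(self, subjects: Sequence[str]) -> "ReferenceLibrary":
        wanted = set(subjects)
        return ReferenceLibrary(
            [e for e in self.entries if (e.subject or e.id) in wanted]
        )


def save_library(library: ReferenceLibrary, directory) -> Path:
    """Persist a library as per-entry TIFF pairs plus a JSON index."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    index = []
    for e in library.validate().entries:
        tifffile.imwrite(directory / f"{e.id}_frame.tif", e.frame.astype(np.float32))
        tifffile.imwrite(directory / f"{e.id}_mask.tif", e.mask.astype(np.uint8))
        index.append(
            {
                "id": e.id,
                "subject": e.subject,
                "phase": e.phase.value,
                "pixel_spacing_mm": e.pixel_spacing_mm,
            }
        )
    (directory / "library.json").write_text(json.dumps(index, indent=1))
    return directory


def load_library(directory) -> ReferenceLibrary:
    directory = Path(directory)
    index = json.loads((directory / "library.json").read_text())
    entries = [
        AtlasEntry(
            frame=tifffile.imread(directory / f"{rec['id']}_frame.tif"),
            mask=tifffile.imread(directory / f"{rec['id']}_mask.tif"),
            phase=Phase(rec["phase"]),
            id=rec["id"],
            subject=rec.get("subject", ""),
            pixel_spacing_mm=rec.get("pixel_spacing_mm", 1.0),
        )
        for rec in index
    ]
    return ReferenceLibrary(entries).validate()


# ---------------------------------------------------------------------------
# options and result containers


@dataclass(frozen=True)
class SegmentOptions:
    """Fixed parameters of the multi-atlas pipeline.

    bins:       joint-histogram bins per axis for NMI.
    k:          number of highest-NMI registrations fused.
    threshold:  probability-map cut for the final mask.
    levels:     multi-resolution pyramid depth (coarsest = 2**(levels-1)).
    max_evals:  NMI-evaluation cap per pyramid level, coarse to fine.
    """

    bins: int = 32
    k: int = 5
    threshold: float = 0.5
    levels: int = 3
    max_evals: Tuple[int, ...] = (400, 300, 200)


@dataclass
class RegistrationResult:
    """Affine registration of one atlas entry onto the target frame.

    ``matrix``/``translation_mm`` map target (row, col) physical
    coordinates (mm, origin top-left) into atlas coordinates — the pull
    transform used for resampling.  ``nmi_score`` lies in [1, 2].
    """

    matrix: np.ndarray  # (2, 2)
    translation_mm: np.ndarray  # (2,)
    nmi_score: float
    warped_mask: np.ndarray
    entry_id: str = ""
    converged: bool = True

    def validate(self) -> "RegistrationResult":
        if abs(np.linalg.det(self.matrix)) < 1e-12:
            raise ValidationError("registration transform is singular")
        return self


@dataclass
class ProbabilityMap:
    """Per-pixel LV probability from fused warped atlas labels."""

    grid: np.ndarray

    def validate(self) -> "ProbabilityMap":
        g = np.asarray(self.grid, dtype=float)
        if g.min() < -1e-12 or g.max() > 1 + 1e-12:
            raise ValidationError("probability values must lie in [0, 1]")
        self.grid = np.clip(g, 0.0, 1.0)
        return self


# ---------------------------------------------------------------------------
# pipeline stages


def preprocess(frame: np.ndarray) -> np.ndarray:
    """Denoise and down-sample a frame by a factor of 2.

    3x3 median filter (speckle suppression) followed by 2x2 block-mean
    down-sampling; an odd trailing row/column is cropped first.  The caller
    is responsible for doubling the pixel spacing of the result.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2 or min(frame.shape) < 4:
        raise ValidationError("preprocess requires a 2-D frame of at least 4x4")
    out = ndimage.median_filter(frame, size=3, mode="nearest")
    r, c = (out.shape[0] // 2) * 2, (out.shape[1] // 2) * 2
    out = out[:r, :c]
    return out.reshape(r // 2, 2, c // 2, 2).mean(axis=(1, 3))


def _entropy(p: np.ndarray) -> float:
    # sorted summation: exact argument-order symmetry of nmi(a, b)
    p = np.sort(p[p > 0])
    return float(-np.sum(p * np.log(p)))


def _hist_range(x: np.ndarray) -> tuple:
    lo, hi = float(x.min()), float(x.max())
    if lo == hi:  # constant image: single occupied bin
        hi = lo + 1.0
    return lo, hi


def nmi(a: np.ndarray, b: np.ndarray, bins: int = 32) -> float:
    """Normalized mutual information (H(a)+H(b))/H(a,b).

    Bin edges are equal-width and recomputed per image over its own range,
    making the measure invariant to positive linear intensity rescaling.
    Equals 2 when ``a`` and ``b`` are deterministically related pixel-wise,
    and tends to 1 for independent images.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValidationError("nmi requires equal-shape images")
    if bins < 2:
        raise ValidationError("nmi requires bins >= 2")
    range_a, range_b = _hist_range(a), _hist_range(b)
    joint, _, _ = np.histogram2d(
        a.ravel(), b.ravel(), bins=bins, range=[range_a, range_b]
    )
    n = joint.sum()
    joint /= n
    # marginals from 1-D histograms (identical counts, symmetric evaluation)
    h_a = _entropy(np.histogram(a.ravel(), bins=bins, range=range_a)[0] / n)
    h_b = _entropy(np.histogram(b.ravel(), bins=bins, range=range_b)[0] / n)
    h_ab = _entropy(joint.ravel())
    if h_ab == 0.0:  # both images constant
        return 2.0
    return (h_a + h_b) / h_ab


def _block_mean(img: np.ndarray, f: int) -> np.ndarray:
    if f == 1:
        return img
    r, c = (img.shape[0] // f) * f, (img.shape[1] // f) * f
    return img[:r, :c].reshape(r // f, f, c // f, f).mean(axis=(1, 3))


def _warp(
    entry: np.ndarray,
    matrix: np.ndarray,
    translation_mm: np.ndarray,
    spacing_mm: float,
    out_shape: tuple,
    order: int,
) -> np.ndarray:
    # target px -> target mm -> atlas mm -> atlas px; equal spacing on both
    # sides folds into an offset in pixel units.
    offset = np.asarray(translation_mm, dtype=float) / spacing_mm
    return ndimage.affine_transform(
        entry,
        matrix,
        offset=offset,
        output_shape=out_shape,
        order=order,
        mode="nearest" if order > 0 else "constant",
        cval=0.0,
    )


def _params_to_transform(p: np.ndarray) -> tuple:
    matrix = np.array([[p[0], p[1]], [p[2], p[3]]], dtype=float)
    return matrix, np.array([p[4], p[5]], dtype=float)


_IDENTITY = np.array([1.0, 0.0, 0.0, 1.0, 0.0, 0.0])


def register_affine(
    entry_frame: np.ndarray,
    entry_mask: np.ndarray,
    target: np.ndarray,
    opts: SegmentOptions = SegmentOptions(),
    spacing_mm: float = 1.0,
    entry_id: str = "",
) -> RegistrationResult:
    """Affinely register one atlas entry to the target, maximizing NMI.

    Multi-resolution (coarse-to-fine block-mean pyramid) Powell ascent with
    a per-level evaluation cap; entirely deterministic.  The returned score
    is never below the identity-transform score: if the optimizer ends in a
    worse basin the identity is returned with ``converged=False``.
    ``warped_mask`` is the entry label resampled by the recovered transform
    with nearest-neighbour interpolation.
    """
    entry_frame = np.asarray(entry_frame, dtype=float)
    target = np.asarray(target, dtype=float)
    entry_mask = np.asarray(entry_mask).astype(float)

    params = _IDENTITY.copy()
    factors = [2 ** (opts.levels - 1 - i) for i in range(opts.levels)]

    # deterministic coarse translation sweep to seed the ascent: NMI peaks
    # are narrow, so a pure local optimizer started at identity can stall
    # on the surrounding plateau.
    coarse = _block_mean(target, factors[0])
    src0 = _block_mean(entry_frame, factors[0])
    sp0 = spacing_mm * factors[0]
    best = (-np.inf, (0.0, 0.0))
    for dr in range(-4, 5):
        for dc in range(-4, 5):
            t = np.array([dr * sp0, dc * sp0])
            score0 = nmi(
                _warp(src0, np.eye(2), t, sp0, coarse.shape, 1), coarse, opts.bins
            )
            if score0 > best[0]:
                best = (score0, (t[0], t[1]))
    params[4], params[5] = best[1]

    for level, factor in enumerate(factors):
        tgt = _block_mean(target, factor)
        src = _block_mean(entry_frame, factor)
        sp = spacing_mm * factor

        def neg_nmi(p, tgt=tgt, src=src, sp=sp):
            m, t = _params_to_transform(p)
            if abs(np.linalg.det(m)) < 1e-6:
                return 0.0  # worst possible (-nmi >= -2)
            warped = _warp(src, m, t, sp, tgt.shape, order=1)
            return -nmi(warped, tgt, opts.bins)

        # initial step sizes: ~5% on matrix terms, ~4 coarse px translation
        step_t = 4.0 * sp if level == 0 else 1.5 * sp
        direc = np.diag([0.05, 0.05, 0.05, 0.05, step_t, step_t])
        res = optimize.minimize(
            neg_nmi,
            params,
            method="Powell",
            options={
                "direc": direc,
                "maxfev": opts.max_evals[min(level, len(opts.max_evals) - 1)],
                "xtol": 1e-3,
                "ftol": 1e-5,
            },
        )
        params = np.asarray(res.x, dtype=float)

    matrix, translation = _params_to_transform(params)
    final_tgt = target
    score = nmi(
        _warp(entry_frame, matrix, translation, spacing_mm, target.shape, 1),
        final_tgt,
        opts.bins,
    )
    id_matrix, id_translation = _params_to_transform(_IDENTITY)
    id_score = nmi(
        _warp(entry_frame, id_matrix, id_translation, spacing_mm, target.shape, 1),
        final_tgt,
        opts.bins,
    )
    converged = bool(res.success)
    if id_score > score:  # optimizer contract: never worse than identity
        matrix, translation, score = id_matrix, id_translation, id_score
        converged = False

    warped_mask = (
        _warp(entry_mask, matrix, translation, spacing_mm, target.shape, 0) > 0.5
    )
    return RegistrationResult(
        matrix=matrix,
        translation_mm=translation,
        nmi_score=float(score),
        warped_mask=warped_mask,
        entry_id=entry_id,
        converged=converged,
    ).validate()


def fuse_top_k(results: Sequence[RegistrationResult], k: int = 5) -> ProbabilityMap:
    """Average the warped labels of the k highest-NMI registrations.

    Ties on the score are broken by ascending entry id so fusion is
    deterministic and independent of the input ordering.  With fewer than
    k results all are used and a :class:`LibrarySizeWarning` is emitted.
    """
    if not results:
        raise ValidationError("fuse_top_k requires at least one registration")
    if len(results) < k:
        warnings.warn(
            f"only {len(results)} registrations available for top-{k} fusion",
            LibrarySizeWarning,
            stacklevel=2,
        )
        k = len(results)
    ranked = sorted(results, key=lambda r: (-r.nmi_score, r.entry_id))[:k]
    stack = np.stack([r.warped_mask.astype(float) for r in ranked])
    return ProbabilityMap(stack.mean(axis=0)).validate()


def threshold_map(pmap: ProbabilityMap, t: float = 0.5) -> np.ndarray:
    """Threshold the probability map into the final LV mask.

    Keeps the largest 4-connected component at or above ``t`` and fills
    interior holes.  An empty result raises :class:`SegmentationError`.
    """
    if not 0.0 < t < 1.0:
        raise ValidationError("threshold must lie in (0, 1)")
    mask = pmap.validate().grid >= t
    if not mask.any():
        raise SegmentationError("no consensus segmentation above threshold")
    labels, n = ndimage.label(mask)  # default structure = 4-connectivity
    if n > 1:
        sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
        mask = labels == (1 + int(np.argmax(sizes)))
    return ndimage.binary_fill_holes(mask)


def segment_frame(
    frame: np.ndarray,
    library: ReferenceLibrary,
    opts: SegmentOptions = SegmentOptions(),
    phase: Optional[Phase] = None,
    spacing_mm: float = 1.0,
) -> tuple:
    """Full multi-atlas segmentation of one selected frame.

    preprocess -> register every (phase-matched) library entry -> fuse the
    top-k labels -> threshold.  Returns ``(mask, probability_map, results)``
    with the mask up-sampled back to the input frame grid.  The whole chain
    is a pure function of its inputs: repeat runs are bit-identical.
    """
    lib = library.phase_subset(phase) if phase is not None else library
    if not lib.entries:
        raise ValidationError("reference library has no matching entries")
    target = preprocess(frame)
    proc_spacing = spacing_mm * 2.0
    results = []
    for e in lib.validate().entries:
        src = preprocess(e.frame)
        # labels live on the entry's preprocessed grid
        msk = _block_mean(e.mask.astype(float), 2) >= 0.5
        results.append(
            register_affine(
                src, msk, target, opts, spacing_mm=proc_spacing, entry_id=e.id
            )
        )
    pmap = fuse_top_k(results, opts.k)
    mask_small = threshold_map(pmap, opts.threshold)
    mask = np.zeros(np.asarray(frame).shape, dtype=bool)
    up = np.repeat(np.repeat(mask_small, 2, axis=0), 2, axis=1)
    mask[: up.shape[0], : up.shape[1]] = up
    return mask, pmap, results


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|a&b| / (|a| + |b|); 1.0 when both masks are empty."""
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    if a.shape != b.shape:
        raise ValidationError("dice requires equal-shape masks")
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(a, b).sum() / denom)
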