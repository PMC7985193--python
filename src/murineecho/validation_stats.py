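"""Validation machinery: regression r-squared, triplicate coefficients of
variation, within-subjects t-tests and leave-n-out Dice experiments.

These are the statistics used to qualify the segmentation tool: Pearson
r-squared between endpoint series from two analysis routes, the percent
coefficient of variation of triplicate re-analyses, a paired t-test on CVs
between methods, and a seeded leave-n-out multi-atlas Dice experiment on a
reference library.

CV is implemented as ``100 * sample SD / mean`` (the conventional
definition; all reliability thresholds in the field are quoted on this
scale).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
from scipy import stats

from .bmode_atlas import ReferenceLibrary, SegmentOptions, dice, segment_frame
from .errors import ValidationError
from .types import Phase

ALPHA = 0.05  # significance level for r/r^2 and t-tests


@dataclass
class RegressionReport:
    """Pearson regression between two endpoint series."""

    r: float
    r_squared: float  # percent
    p_value: float
    n: int

    def validate(self) -> "RegressionReport":
        if not -1.0 - 1e-12 <= self.r <= 1.0 + 1e-12:
            raise ValidationError("r outside [-1, 1]")
        if self.n < 3:
            raise ValidationError("regression requires n >= 3")
        return self

    @property
    def significant(self) -> bool:
        return self.p_value <= ALPHA


@dataclass
class CvReport:
    """Percent coefficient of variation of replicate measurements."""

    endpoint: str
    cv_percent: float
    replicates: List[float] = field(default_factory=list)


@dataclass
class PairedTReport:
    """Within-subjects t-test; ``all_tied`` flags a degenerate exact tie."""

    t: float
    p: float
    n: int
    all_tied: bool = False


@dataclass
class DiceSummary:
    """Per-case and aggregate Dice of a leave-n-out experiment."""

    cases: List[tuple]  # (subject, phase, dice)
    mean: float
    sd: float
    min: float
    max: float
    test_subjects: List[str] = field(default_factory=list)


def pearson_r2(x: Sequence[float], y: Sequence[float]) -> RegressionReport:
    """Pearson r and r-squared (as percent) with a two-sided p-value.

    The p-value comes from the t transform with n-2 degrees of freedom.
    Requires n >= 3 and nonzero variance in both series.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("pearson_r2 requires two equal-length 1-D series")
    if x.size < 3:
        raise ValidationError("pearson_r2 requires n >= 3")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValidationError("pearson_r2 requires nonzero variance in both series")
    res = stats.pearsonr(x, y)
    r = float(res.statistic)
    return RegressionReport(
        r=r, r_squared=100.0 * r * r, p_value=float(res.pvalue), n=x.size
    ).validate()


def cv_percent(values: Sequence[float]) -> float:
    """Percent coefficient of variation: 100 * sample SD / mean."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValidationError("cv_percent requires >= 2 replicates")
    if np.all(values == values[0]):
        # exact zero for identical replicates (float mean of n equal values
        # need not equal them, which would otherwise leak ~1e-14 CVs)
        if values[0] == 0:
            raise ValidationError("cv_percent undefined for zero mean")
        return 0.0
    mean = values.mean()
    if mean == 0:
        raise ValidationError("cv_percent undefined for zero mean")
    return float(100.0 * values.std(ddof=1) / mean)


def cv_report(endpoint: str, values: Sequence[float]) -> CvReport:
    return CvReport(
        endpoint=endpoint,
        cv_percent=cv_percent(values),
        replicates=[float(v) for v in values],
    )


def paired_t(cv_a: Sequence[float], cv_b: Sequence[float]) -> PairedTReport:
    """Within-subjects t-test on paired CV lists (df = n - 1).

    Identical lists (every difference zero) return an exact-tie report
    (t = 0, p = 1, ``all_tied=True``); a constant nonzero difference has
    no variance to test against and raises.
    """
    a = np.asarray(cv_a, dtype=float)
    b = np.asarray(cv_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValidationError("paired_t requires two equal-length lists, n >= 2")
    d = a - b
    if np.all(d == 0):
        return PairedTReport(t=0.0, p=1.0, n=a.size, all_tied=True)
    if np.var(d) == 0:
        raise ValidationError("paired differences have zero variance")
    res = stats.ttest_rel(a, b)
    return PairedTReport(t=float(res.statistic), p=float(res.pvalue), n=a.size)


def leave_n_out_dice(
    library: ReferenceLibrary,
    n_test: int,
    opts: SegmentOptions = SegmentOptions(),
    rng_seed: int = 0,
) -> DiceSummary:
    """Seeded leave-n-out multi-atlas Dice experiment.

    ``n_test`` subjects are held out at random (seeded, reproducible);
    each held-out ED and ES frame is segmented against the remaining
    subjects' entries of the matching phase and scored against its own
    ground-truth mask.  Returns every per-case Dice plus the summary.
    """
    if n_test < 1:
        raise ValidationError("n_test must be >= 1")
    subjects = library.validate().subjects
    if len(subjects) <= n_test:
        raise ValidationError("library must be larger than the test split")
    rng = np.random.default_rng(rng_seed)
    test_subjects = sorted(
        rng.choice(np.asarray(subjects, dtype=object), size=n_test, replace=False)
    )
    atlas = library.subject_subset([s for s in subjects if s not in test_subjects])
    cases = []
    for subject in test_subjects:
        for entry in library.subject_subset([subject]).entries:
            mask, _, _ = segment_frame(
                entry.frame,
                atlas,
                opts,
                phase=entry.phase,
                spacing_mm=entry.pixel_spacing_mm,
            )
            cases.append((subject, entry.phase.value, dice(mask, entry.mask)))
    scores = np.array([c[2] for c in cases])
    return DiceSummary(
        cases=cases,
        mean=float(scores.mean()),
        sd=float(scores.std(ddof=1)) if scores.size > 1 else 0.0,
        min=float(scores.min()),
        max=float(scores.max()),
        test_subjects=[str(s) for s in test_subjects],
    )
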