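"""Repeat-analysis reproducibility of the M-mode tracer.

Runs the tracing pipeline in triplicate on the same sweep (the tool's
repeatability protocol), computes the percent coefficient of variation
of every endpoint, and contrasts it with the CV of a simulated manual
analyst whose replicates scatter by a few percent.
"""

import numpy as np

from murineecho.cardiac_params import mmode_measures
from murineecho.mmode_walls import segment_mmode
from murineecho.phantom import MmodePhantomSpec, make_mmode_phantom, phantom_seeds
from murineecho.validation_stats import cv_percent, paired_t

spec = MmodePhantomSpec(rng_seed=5)
image, _ = make_mmode_phantom(spec)
seeds = phantom_seeds(spec)

runs = [
    mmode_measures(segment_mmode(image, seeds)[2], heart_rate=450.0).values
    for _ in range(3)
]

rng = np.random.default_rng(0)
endpoints = ("LVID;d", "LVID;s", "EF", "FS", "SV")
print(f"{'endpoint':8s} {'algorithm CV %':>15s} {'manual CV %':>12s}")
algo_cvs, manual_cvs = [], []
for name in endpoints:
    replicates = [run[name] for run in runs]
    algo_cv = cv_percent(replicates)
    # a manual analyst re-tracing the same image scatters by ~4%
    manual = replicates[0] * (1 + rng.normal(0, 0.04, size=3))
    manual_cv = cv_percent(manual)
    algo_cvs.append(algo_cv)
    manual_cvs.append(manual_cv)
    print(f"{name:8s} {algo_cv:15.2f} {manual_cv:12.2f}")

report = paired_t(algo_cvs, manual_cvs)
print(f"\npaired t on CVs (algorithm vs manual): t={report.t:.2f}, p={report.p:.3f}")
print(
    "\nThe tracer is deterministic, so its triplicate CV is exactly zero "
    "for every endpoint - repeat analysis of the same frames cannot "
    "disagree with itself."
)
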