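"""Multi-atlas segmentation of a long-axis B-mode frame.

Builds a small synthetic reference library, renders a new phantom that is
NOT in the library, segments its end-diastolic frame by NMI-affine
registration and top-5 label fusion, and scores the mask against the
exact ground truth.
"""

import numpy as np

from murineecho.bmode_atlas import dice, segment_frame
from murineecho.phantom import (
    BmodePhantomSpec,
    ground_truth_mask,
    make_bmode_phantom,
    make_library,
)

library = make_library(10, rng_seed=0)
print(f"reference library: {library.n_subjects} subjects, {len(library)} entries")

spec = BmodePhantomSpec(rng_seed=777, n_frames=42, tilt_deg=4.0, lv_length_mm=8.3)
phantom = make_bmode_phantom(spec)
frame = phantom.loop.frames[phantom.ed_frame]
truth = ground_truth_mask(spec, phantom.ed_frame)

mask, pmap, results = segment_frame(
    frame, library, phase="ED", spacing_mm=spec.pixel_spacing_mm
)

ranked = sorted(results, key=lambda r: -r.nmi_score)
print("top-5 fused registrations (highest NMI wins):")
for r in ranked[:5]:
    print(f"  {r.entry_id:12s} NMI {r.nmi_score:.4f}")
print(f"probability map range: {pmap.grid.min():.2f} - {pmap.grid.max():.2f}")
print(f"Dice vs ground truth: {dice(mask, truth):.4f}")
print(
    "\nDice of 1.0 would be pixel-perfect agreement; values above ~0.9 "
    "mean the fused atlas labels recovered the cavity almost exactly."
)
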