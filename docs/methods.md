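# Methods

`murineecho` re-implements a semi-automated analysis chain for murine
left-ventricle (LV) echocardiograms: multi-atlas segmentation of long-axis
(PLAX) B-mode frames, seed-guided dynamic-programming tracing of short-axis
(SAX) M-mode wall interfaces, derivation of the standard LV structural and
functional endpoints from both, and the statistics used to qualify such a
tool (Dice overlap, Pearson r², coefficients of variation, within-subjects
t-tests). This note records the models, the tunable parameters, the
numerical choices, and what the synthetic phantoms do and do not establish.

## B-mode multi-atlas segmentation

A target frame (the user-selected end-diastolic or end-systolic frame of a
cine loop) is segmented by registering every entry of a traced reference
library onto it and fusing the warped labels:

1. **Preprocess** — 3×3 median filter, then 2×2 block-mean down-sampling
   (spacing doubles). An odd trailing row/column is cropped first.
2. **Register** — each library frame is affinely registered (6 parameters:
   2×2 matrix plus translation in mm) to the target, maximizing normalized
   mutual information. NMI is fixed as `(H(a)+H(b))/H(a,b)` on a joint
   histogram with 32 equal-width bins per image, computed over each image's
   own intensity range; its range is [1, 2], it equals 2 for
   deterministically related images and tends to 1 under independence, and
   it is invariant to positive linear intensity rescaling.
3. **Fuse** — the warped labels of the 5 highest-NMI registrations are
   averaged into a probability map (values on the lattice {0, 1/5, …, 1});
   score ties break by ascending entry id, so fusion is order-independent.
4. **Threshold** — the map is cut at 0.5 (majority of 5), the largest
   4-connected component is kept, and interior holes are filled.

The optimizer is a three-level coarse-to-fine pyramid (block-mean factors
4/2/1) of Powell ascent with per-level evaluation caps (400/300/200),
preceded by a deterministic ±4-pixel translation sweep at the coarsest
level — NMI peaks are narrow and a purely local ascent started at identity
can stall on the surrounding plateau. Frames are resampled with linear
interpolation, labels with nearest-neighbour (label integrity). Every step
is deterministic: repeat analyses of the same frame are bit-identical, so
triplicate coefficients of variation are exactly zero by construction. If
the optimizer ends below the identity-transform score, the identity is
returned and the result flagged unconverged; the reported score is never
worse than identity.

Assumptions: the atlas and target show the same view with the LV cavity
darker than the myocardium, and an affine map captures the inter-subject
shape difference. No deformable registration, no learned segmentation, and
no automatic ED/ES frame detection — frame choice is a caller input.

## M-mode wall tracing

The four interfaces (anterior epicardium/endocardium, posterior
endocardium/epicardium, ordered by depth) are traced one at a time:

1. **Search region** — the user's two seed points bracket the wall; the
   depth band between them is grown by a margin (default 10 % of the seed
   span) and clipped to the image. Each interface carries an expected
   axial intensity transition, expressed in the increasing-depth
   direction: dark→bright for ANT_EPI and POST_ENDO, bright→dark for
   ANT_ENDO and POST_EPI (anterior wall above the cavity, transducer at
   row 0). Seed order is normalized, so swapping the points is harmless.
2. **Cost image** — Gaussian smoothing (σ = 1 px), signed depth-direction
   derivative, polarity rectification (the wrong-signed transition is
   clamped to zero), min–max normalization, and `cost = 1 − normalized
   gradient`. A gradient-free region yields uniform cost 1, a warning,
   and a low-confidence flag on the resulting trace.
3. **Optimal path** — dynamic programming finds the exact global minimum
   of the summed cost under a smoothness constraint of at most 2 rows per
   column (`max_step`), with ties broken toward the shallower row at
   every backtrack step. The constraint exists because an unconstrained
   minimum could jump arbitrarily between columns; 2 rows/column at the
   default calibration (0.01 mm axial pixels, 1 ms columns) admits wall
   velocities up to 20 mm/s, comfortably above the excursion rates of a
   mouse heart at 400–500 bpm.
4. **Spectral filter** — each trace is reduced to its dominant periodic
   component: mean removed, DFT, all bins zeroed except the single
   largest-magnitude positive frequency (and conjugate), inverse DFT,
   mean restored. The operation is idempotent and leaves a pure
   bin-aligned sinusoid unchanged. "Dominant" rather than literally
   "highest" frequency is an interpretive choice: the highest retained
   frequency would keep noise and discard cardiac motion.
5. **Phase detection and measurement** — end-diastole/end-systole columns
   are the local maxima/minima of the filtered LV internal diameter
   `LVID(t) = POST_ENDO(t) − ANT_ENDO(t)` (plateau-safe, first index of a
   plateau, alternation enforced). Because the single-bin filter
   quantizes the cardiac frequency to the DFT grid, its peaks drift
   slowly against the true beats when the record holds a non-integer
   number of cycles; each mark is therefore snapped to the raw-trace
   extremum within 0.4× the smallest inter-mark gap before measuring.
   The six dimensions (LVID, LVAW, LVPW at diastole and systole) are read
   off the *raw* dynamic-programming traces at the marked columns —
   measuring the filtered traces would inherit the filter's spectral-
   leakage amplitude bias — and averaged over all detected beats, with
   per-beat values retained for audit. Manual trace edits are spliced in
   through `edit_trace`, which re-validates the depth ordering of the
   four interfaces and rejects edits that break it.

## LV endpoints

**B-mode (monoplane method of disks).** The basal chord midpoint and the
farthest contour vertex define the long axis (length L); the axis is cut
into `n_disks` equal slabs (default 20, configurable — the ASE-recommended
count) and each disk diameter `d_i` is the contour chord perpendicular to
the axis at the slab centre (longest segment if the chord crosses the
boundary more than twice). Volume is the disk sum

    V = Σᵢ (π/4) d_i² (L / n)   [mm³ ≡ µL],

which for a half-ellipsoid converges to the analytic πLD²/6 with the
composite-midpoint O(n⁻²) error (≈0.03 % at n = 20). Disk cross-sections
are assumed circular (a single imaging plane is available). Areas use the
shoelace formula; the chamber dimension is the largest disk diameter. Then
EF = 100·(EDV−ESV)/EDV, SV = EDV−ESV, FS = 100·(EDD−ESD)/EDD,
FAC = 100·(EDA−ESA)/EDA, CO = SV·HR/1000 mL/min. A missing heart rate
never aborts a run; only CO is withheld. A contour whose width exceeds
1.5× its axis length (e.g. a circle whose "basal chord" spans a full
diameter) triggers a degenerate-geometry warning.

**M-mode.** Diameters convert to volumes by the Teichholz formula
`V = 7.0/(2.4 + D)·D³` (µL from mm) and to mass by the cube formula
`1.053·[(LVID;d + LVPW;d + LVAW;d)³ − LVID;d³]` mg with the conventional
0.8 multiplicative correction; both coefficient sets are overridable. The
corrected mass is by construction a constant multiple of the uncorrected
one, so any correlation statistic computed on the two is identical.

**Workflow reports** are CSV (one row per subject × timepoint × mode,
fixed unit-annotated column order, values at 1e-4 reporting precision so
regeneration from stored ROIs is byte-stable) plus PNG overlays; rows are
keyed and replaced on re-runs, and `regenerate_reports` recomputes every
endpoint from the stored — possibly hand-edited — segmentations.

## Validation statistics

Pearson r² is reported as a percent with the two-sided p from the
t-transform (n−2 df). The coefficient of variation is `100·SD/mean` with
the sample (n−1) SD; identical replicates return exactly 0 (a float mean
of equal values need not equal them, which would otherwise leak ~1e-14
CVs). The paired t-test uses n−1 df; an all-zero difference vector returns
an exact-tie report instead of dividing by zero. The leave-n-out Dice
experiment splits a library by subject with a seeded generator, segments
every held-out ED and ES frame against the remaining subjects' entries of
the matching phase, and reports per-case scores with mean/SD/range. No
multiple-comparison correction is applied to r² p-values; α = 0.05.

## Synthetic phantoms

The generators are pure functions of (spec, seed) and carry exact ground
truth, so downstream error is attributable to the algorithms alone.

* **B-mode**: the cavity is a half-ellipsoid cross-section (ellipse
  truncated at the mitral base; base-to-apex length L is the semi-axis)
  whose minor diameter oscillates sinusoidally at the heart rate between
  the ED and ES values; the myocardium is a bright band of fixed
  thickness. Defaults follow the targeted acquisition protocol: 300
  frames at 6.67 ms/frame, heart rate 450 bpm (mid 400–500 bpm window),
  LV 8.0 mm × 4.0→2.8 mm, wall 0.8 mm, 0.05 mm pixels on a 160×256 grid.
  ED/ES frame indices are the argmax/argmin of cavity size over one
  mid-loop cycle, mirroring the manual frame-selection step.
* **M-mode**: four sinusoidal interface depth signals phased so LVID
  attains LVID;d at t = 0; bright wall bands, dark cavity. Defaults: 5 s
  sweep at 1 kHz (1 ms/column), 0.01 mm axial pixels, LVID 4.0→2.8 mm,
  walls 0.8→1.1 mm. The 1 kHz rate is the sampling needed for wall
  excursions to stay within the tracer's step constraint at this pixel
  size, and is typical of high-frequency M-mode acquisition.
* **Speckle**: unit-mean multiplicative gamma noise (variance =
  `speckle_scale²`, default 0.3) followed by a 1-pixel Gaussian
  point-spread blur — the minimal model reproducing the low
  signal-to-noise granularity of ultrasound without simulating wave
  physics. There is no attenuation, refraction, shadowing, off-axis
  anatomy, valve apparatus or papillary muscle.
* **Libraries**: n phantoms drawn uniformly from per-parameter ranges
  (defaults: L 7–9 mm, D_ED 3.6–4.4 mm, D_ES 2.5–3.1 mm, wall
  0.7–0.9 mm, tilt ±8°, base position and axis depth ±0.4 mm, HR
  400–500 bpm), each contributing one ED and one ES (frame, exact mask)
  entry. How much morphological variability a faithful surrogate of a
  real multi-model library needs is not knowable from desk work; the
  ranges are exposed as user input.

Because the phantoms share a two-parameter shape family, passing the
leave-five-out Dice experiment shows that the registration/fusion chain
recovers affine shape variation under speckle — it does not establish
performance on real images with unclear landmarks, dropout, or diseased
morphology outside the sampled ranges.

## Problem sizes and budgets

The shipped experiments run on one CPU: the leave-five-out experiment
uses a 30-subject library (60 entries, 250 registrations at 80×128
after preprocessing, a few minutes), M-mode recovery uses 20 phantoms
(700×5000 sweeps, seconds each), and the dynamic-programming oracle
checks 100 grids up to 6×12 against exhaustive recursion. These sizes
were chosen as the smallest that exercise every code path with stable
statistics.

## Known limitations

* Affine-only registration: strongly non-affine shape change (aneurysm,
  regional dyskinesis) is outside the model.
* The basal-chord heuristic in `contour_from_mask` (longest straight edge
  of the simplified boundary) presumes a base-truncated LV shape; it is
  not a general mitral-plane detector.
* Teichholz and cube-formula coefficients are conventions; they are
  exposed as parameters rather than asserted as ground truth.
* The M-mode tracer requires seed points; there is no automatic seed
  placement, and a band that misses the wall entirely produces a flagged
  low-confidence trace rather than a recovery attempt.
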