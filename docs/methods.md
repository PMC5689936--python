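# Methods

This note documents the models, numerical choices, and open design
decisions behind `cbctgamma`, and what the synthetic phantom does and does
not establish about clinical data.

## Anatomical gamma index

The gamma index, standard in dose-distribution QA, is applied here to
CT-number volumes: for a masked reference voxel at position **r**,

γ(r) = min over evaluated voxel centers **r′** of
√( (‖r − r′‖ / DTA)² + ((HU_eval(**r′**) − HU_ref(**r**)) / ΔHU)² ).

Key numerical choices:

* **Voxel-center search, no sub-voxel interpolation.** Candidates are the
  evaluated volume's voxel centers. CBCT in-plane spacing (~1 mm clinically,
  2 mm for the default phantom) is well below the 3 mm DTA, so the lattice
  resolves the distance term adequately. Whether the original clinical
  implementations interpolated is generally unstated; voxel-center search is
  this package's documented convention, and it interacts with image
  smoothness (see *Tissue-interface smoothing* below).
* **Full-volume search.** The DTA search ranges over the whole evaluated
  volume, not just the masked region; only the *reference* voxels being
  scored are masked.
* **Cap = 5 and exactness.** γ is clipped at `cap` (default 5). Outside a
  sphere of radius `cap × DTA` the distance term alone exceeds the cap, so
  restricting the search to that sphere is exact for every value below the
  cap. Candidates are visited in order of increasing physical distance, and
  a voxel retires as soon as its current best value is ≤ distance/DTA —
  this pruning provably cannot change the minimum, and the test suite
  checks bit-level agreement with an unpruned brute-force implementation.
  The cap leaves headroom for failed-histogram percentiles; the failure-set
  extractor warns when more than 10% of failed values saturate at the cap.
* **Anisotropic spacing.** All distances are physical (slice thickness
  differs from in-plane spacing).
* **Asymmetry.** γ(ref, eval) ≠ γ(eval, ref); the reference is always the
  plan segment's first CBCT.
* **Performance.** The active-set pruning makes cost scale with the failing
  region, not the search sphere: a 96×96×48 comparison takes ~0.1–1 s on one
  CPU at (3 mm, 30 HU) depending on how much anatomy mismatch is present.

## Analysis mask

Failed pixels far outside the patient (ring/streak artifacts in air) would
pollute the statistics, so comparisons are restricted to the external
contour dilated by 10 mm (Euclidean distance transform with physical
sampling, so anisotropic grids dilate correctly), limited in z to the slice
range spanned by the highest-dose CTV — the region of clinical concern.
Masks live on the reference grid; an evaluated volume on a different grid is
trilinearly resampled to it first (out-of-extent voxels fill with −1000 HU,
air). RT Structure Set contours rasterize per slice with even-odd fill,
points assigned to the nearest slice by z, with no inter-slice
interpolation — the simplest defensible dialect. How the planning-CT
external contour maps onto the CBCT frame beyond the clinical couch-shift
registration is assumed to be identity.

## Match quality parameter

Each comparison is reduced to γ_x, the x-th percentile (linear interpolation
between closest ranks, the common convention; rank 1 + (n−1)·x/100) of the
gamma values *strictly* greater than 1. An empty failure set yields
γ_x := 1.0, the pass/fail boundary, so two failure-free comparisons give
MQP = 0. MQP_x,i = γ_x,ref − γ_x,i, where the reference comparison is the
segment's first-vs-second CBCT; the reference record therefore has MQP = 0
identically, and a replan starts a new segment with a fresh reference. The
series is indexed by treatment-fraction number (not CBCT ordinal) because
the decision window is expressed in fractions.

Note that γ_x of the *failed* subset is not guaranteed monotone under
worsening anatomy at coarse voxel sizes: newly failing voxels enter the
histogram just above 1 and can transiently dilute the percentile. At the
default phantom resolution the erosion signal dominates and noise-free
eroding courses produce strictly non-increasing MQP.

## Decision rule and ROC training

A re-CT is recommended at the first record completing `run_length` = 3
consecutive comparisons with MQP ≤ threshold. "Consecutive" means
consecutive *acquired* comparisons — calendar gaps never break a run, an
above-threshold value does. The zero-valued reference record participates in
the scan but can never satisfy a negative threshold. Thresholds are negative
by definition (a positive threshold would recommend re-CT while the match
has not deteriorated); the training sweep uses the fixed 500-value grid
−0.001·k, k = 1…500.

Against a recorded order at fraction f_o, a trigger at f_t scores TP when
|f_t − f_o| ≤ 3 fractions, FP when earlier, FN when later or absent; with no
order, any trigger is FP, none is TN. Segments with fewer than
`run_length` comparisons beyond the reference are non-evaluable and stay out
of all denominators. The sweep computes gamma maps once per (DTA, ΔHU) and
reuses the cached failed-pixel sets across percentiles and thresholds. The
optimum maximizes the Youden index J = TPF − FPF with a deterministic
tie-break (higher TPF, then more negative threshold, then smaller DTA, ΔHU,
percentile); "best trade-off" is not uniquely defined, so the rule is
explicit and configurable.

One structural property worth knowing: TPF/FPF are monotone along the
threshold grid only when no trigger can fire before f_o − window. A looser
threshold can trigger *early* (scored FP), and tightening it converts that
FP to a TP — so the windowed rates are not monotone for cohorts whose
anatomy changes long after monitoring starts. The monotonicity tests use
cohorts with change onset at the second fraction, where the precondition
holds by construction.

## Synthetic phantom

The generator emulates a head-and-neck CBCT course: an elliptical
soft-tissue cylinder (40 HU, default semi-axes 65×80 mm) containing a bony
spine (800 HU, 12 mm radius) with a spinal-canal core (0 HU), an airway
(−1000 HU), and a mid-neck CTV cylinder defining the axial analysis range;
grid 96×96×48 at 2×2×3 mm (a clinical-scale 384×384×70 grid is reachable by
passing a larger `PhantomSpec`, at proportional cost).

* **Weight loss** is bilateral lateral erosion: at cumulative depth d each
  lateral side recedes by d/2, so the external contour's total width shrinks
  by d mm; d grows linearly (default 2 mm/fraction) from the onset fraction.
  Erosion that would reach the spine or airway raises an error. The
  simulated re-CT order is the first CBCT fraction with d ≥ 10 mm,
  mirroring the clinical "≥ 1 cm external contour difference" review
  trigger, which ties ground truth to practice rather than to an arbitrary
  label.
* **Tissue-interface smoothing** (`edge_blur_mm`, default 8 mm): tissue
  boundaries are smoothed in-plane with a Gaussian. Real necks ramp from
  air through skin and subcutaneous fat over ~1 cm, and the scanner PSF
  blurs further; a binary HU step, by contrast, makes every sub-voxel setup
  shift produce partial-volume boundary values that exist nowhere on the
  evaluated lattice, which the voxel-center DTA search scores as spurious
  high-γ failures. With the default smoothing the stable-course MQP noise
  floor is ±0.05 while multi-mm erosion remains fully detectable (the
  erosion signal is carried by the DTA term, not the edge gradient).
* **Degradation** per CBCT: a random rigid setup shift (per-axis σ = 0.5 mm,
  trilinear resample), then artifacts, then i.i.d. Gaussian HU noise
  (σ = 20 HU). Each stage draws from an independent seeded substream, so
  toggling one stage leaves the others' realizations bit-identical — which
  is what makes artifact-perturbation measurements clean.
* **Ring artifacts** are scanner-frame radial waves (amplitude ≤ 100 HU, the
  reported magnitude of CBCT-number artifacts; period 30 mm) that are
  *static across fractions* up to a small per-fraction gain drift (5%),
  because detector-gain rings recur at the same image position. Static
  patterns largely cancel between reference and evaluated scans; the
  residual MQP perturbation comes from the patient shifting under the fixed
  pattern and is measured by the suite (max ≈ 0.08 at the 100 HU amplitude
  bound — above the ±0.05 noise floor for some seeds, but far too small and
  too uncorrelated to complete a 3-fraction trigger run at −0.11, which is
  the clinically relevant statement). Streaks are radial spokes with
  per-fraction random orientation, off by default. No projection or
  reconstruction physics is simulated.
* **Default schedule: daily CBCT.** With twice-weekly imaging (3–4 fractions
  between scans) a run of three consecutive sub-threshold values completes
  ≥ ~7 fractions after first detection, which cannot land inside a
  ±3-fraction window of the order — the run-of-three rule is only
  compatible with that window on the daily-CBCT arm of the imaging
  guideline. Sparser schedules remain available via `cbct_fractions`.
* **Cohorts** draw per-patient onsets uniformly from [10, 20] (changers) on
  30-fraction courses; stable patients share the noise model. Everything is
  a pure function of the master seed.

### What passing tests do and do not show

The phantom establishes the pipeline's *mechanics*: exactness of the gamma
computation, the MQP identity and reference resets, run bookkeeping,
scoring, and that the trained rule recovers programmed changes at the
programmed time under realistic noise. It does not model deformable
anatomy, CBCT scatter/cupping HU drift between fractions, couch-registration
residuals beyond rigid jitter, day-1 anatomy that already differs from the
planning CT, or inter-patient variability in baseline image quality — so
synthetic sensitivity/specificity figures characterize the generator's
conditions, not expected clinical performance. Realistic inter-fraction HU
drift in particular is not characterized here; the noise and artifact
defaults are stand-ins exposed as parameters.

## Problem sizes used by the test and acceptance runs

Unit tests run on downscaled phantoms (48×48×24 and 32×32×16). The
end-to-end checks use the default 96×96×48 phantom: a 2+2-patient cohort
over the {3,6} mm × {30,60} HU criteria grid for ROC structure, a
10-changer + 10-stable cohort (30-fraction daily courses) for parameter
recovery at (3 mm, 30 HU, x = 80), and 5 seeded course pairs for the
ring-artifact bound. `scripts/acceptance.py` trains on a 6+6 cohort of
24-fraction courses. These sizes were chosen to exercise the full pipeline
at the default resolution while keeping a complete run in the
minutes range on a single CPU.

## Known limitations

* Rigid setup error only; no deformable registration or rotations.
* The gamma search does not interpolate between voxels, so sub-voxel
  anatomy shifts at *sharp* intensity edges register as HU failures rather
  than small distances; real CBCT's PSF (and the phantom's interface
  smoothing) keeps this benign, but razor-sharp synthetic edges would not be
  scored meaningfully.
* γ_x is computed over failed voxels only; comparisons with empty failure
  sets all map to γ_x = 1.0 and are indistinguishable.
* The DICOM readers assume axial, identity-orientation series; NIfTI
  volumes assume a diagonal affine.
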