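# Methods

## The model chain

### Stimulus apertures

The mapping stimuli are modelled as binary visual-field occupancy
movies: one mask per acquired volume (frame period = TR = 2 s), on a
square raster of pixel centres at integer multiples of the pixel step
(default ±45° at 0.5°/pixel, 181×181).  Only spatial occupancy enters
the forward model; the checkerboard texture and its 2 Hz contrast
reversal are far faster than a volume and are not rendered.

*Wedge*: a 45°-wide sector whose leading edge starts on the positive
horizontal meridian (the start angle is not constrained by the
experiment and is recorded in metadata) and advances counterclockwise
by 360°·TR/64 s per frame, one revolution per 64 s cycle.  The wedge
width is treated as constant.

*Ring*: annulus edges are placed uniformly in u = log(e + e₂) with
e₂ = 0.75°, which makes each annulus width proportional to (e + e₂) —
the inverse-linear cortical-magnification scaling — while guaranteeing
that frame 0 is a central disc, the union of one cycle tiles the full
disc, the sweep reaches the maximum eccentricity in exactly one cycle,
and e₂ → ∞ degenerates to constant width.  Because foveal annuli are
thinner than a raster pixel, a pixel is marked active when its
footprint intersects the annulus (radial dilation by half a pixel);
otherwise early frames would be blank.

### pRF forward model and fit

Per-frame neural drive is Σ_pixels aperture · exp(−((x−x₀)²+(y−y₀)²)/2σ²),
convolved causally with a canonical double-gamma HRF (peak 6 s,
undershoot 16 s, dispersions 1 s, undershoot ratio 1/6, 32 s kernel,
unit sum — the experiment does not constrain the HRF) and scaled to
unit peak.  Amplitude β (constrained non-negative: negative visual
responses are outside the model and destabilise coverage maps) and
baseline are solved in closed form per candidate; (x₀, y₀, σ) come from
a coarse grid (polar lattice of 10 log-spaced eccentricities × 16
angles plus fixation; 8 σ values log-spaced 0.5–15°) followed by
bounded Nelder–Mead refinement over (x₀, y₀, log σ) with tolerance
1e−3 (switchable off for exact-grid reproducibility).  Exact RSS ties
resolve to the smallest σ, then smallest eccentricity, then
lexicographic position.  Variance explained is 1 − RSS/TSS; a flat
series returns a degenerate estimate with VE = 0.  Voxels are retained
at VE ≥ 0.20 (inclusive).  Wedge and ring runs are fitted jointly by
temporal concatenation; separate fits remain possible by passing a
single aperture.

### Coverage, downsampling, classification

Coverage is the per-pixel maximum of unit-peak Gaussian profiles over
retained voxels — deliberately not β-weighted, so coverage reads as
"does any population respond here", matching a detection (not
sensitivity) interpretation.  Downsampling takes the maximum raster
value inside each half-open 6°×6° cell [x−3, x+3)×[y−3, y+3) centred on
a 30-2 location (mean aggregation available for sensitivity analysis),
then divides all 76 location values by their global maximum; the two
normalisations (per-voxel unit peak, then map-level max) are idempotent
whenever some location reaches 1.  Binarisation is strictly greater
than the threshold (default 0.5; 0.25/0.75 for robustness checks).

The 30-2 grid places test locations at x, y ∈ {±3, ±9, ±15, ±21, ±27}
minus 6 corner points per quadrant; the trimming rule (drop if
eccentricity > 30° or both |x|, |y| ≥ 21) is chosen to reproduce the
canonical 76 locations, 38 per hemifield.  The single blind-spot
candidate is (15, −3) mirrored into the temporal field of the tested
eye.  Classification: Hum+ iff dB > 0 strictly (a location "seen" only
at maximum intensity counts as blind), Ret+ iff binarised coverage;
the blind spot is excluded before anything else, and the infrequent
Hum+/Ret− class can be dropped (reversibly) from downstream statistics.

### Statistics

Category training effects are mean dB change (post − pre) per category
with two pooling units — per-patient means averaged across patients
(default; SE is the between-patient SD over √n) or all locations
pooled — and two variants: all included locations, or changed-only
(gain ≥ 1 dB, the perimeter's resolution; a strict ≠ 0 rule is behind a
flag).  The permutation test shuffles category labels *within each
patient*, preserving per-patient category composition and
between-patient heterogeneity, recomputes pooled means, and reports
one-sided p = (1 + #{null ≥ observed}) / (1 + N) (the +1 smoothing is
the standard Monte-Carlo correction; two-sided available).  Both
pairwise reserve comparisons are reported without multiplicity
correction.  The trained-vs-untrained contrast is a two-sample
permutation test on per-patient mean changes.  The GAS association is
an ordinary least-squares fit with Pearson r and two-sided p; the
predictor is the per-patient count of reserve locations improved by
≥ 1 dB and the outcome the mean of the (three) goal scores.

## Synthetic cohorts

The generator emulates the three study inputs with explicit ground
truth.  A lesion is a behavioral scotoma region (half-planes, discs,
sectors, and their compositions) with two reserve-creating mechanisms,
mirroring the two candidate physiologies: *spared islands* (discs
inside the scotoma where voxels survive) and a *reserve margin* (the
neural scotoma is the behavioral one eroded by a fixed number of
degrees — latent tissue at the defect border).  Voxel centres tile the
field with density uniform in log(e + e₂)×angle (inverse-linear
cortical magnification, e₂ = 0.75°) and σ = 0.75° + 0.1·e.  BOLD series
are β·prediction + baseline + white noise of SD β/SNR per run, with
three runs averaged by default — the standard retinotopy session; the
default per-run SNR is 3.

Perimetry is a hill of vision, peak 33 dB falling 0.3 dB/°, floored at
0, with 0 dB inside the behavioral scotoma and at the blind spot, and
per-location Gaussian test-retest noise (SD 1.5 dB, a clinical-range
value) applied where there is something to measure (pre > 0; deep
scotoma locations retest at a hard 0 dB).  Training effects are drawn
per location by ground-truth category.  The default *mixture* mode is
zero-inflated: a location changes with probability mean/changed-mean,
in which case its gain is drawn ≥ 1 dB around the category's
changed-location mean (defaults 1.34/0.76/0.22 dB category means with
9.12/3.09/3.25 dB changed-location means for reserve/seen/blind); this
reproduces both the small category means and the large gains
concentrated on a minority of locations.  A plain Gaussian mode exists;
the untrained (test-retest) cohort uses it with a uniform 0.11 dB
drift at measurable locations.  Post maps are clipped to [0, 50] dB —
note that a *null* cohort (category-independent effects) must therefore
use a nonnegative effect distribution (e.g. the mixture with identical
parameters for all categories) so the clip never acts and category
labels remain exchangeable; the calibration tests do exactly this.
GAS goal scores are linear in the improved-reserve count (slope 0.06,
intercept −1, goal noise SD 0.6), clipped to the 6-point scale [−3, +2]
and kept continuous by default so that zero-noise simulations are
exactly collinear; integer rounding is behind a flag (real GAS is
integer-valued).

**Ground truth.**  The ground-truth category of a location is defined
operationally: the classification rule applied to the *noiseless*
generator outputs (noiseless perimetry and coverage of the true pRFs).
With noise disabled the pipeline therefore reproduces the truth
exactly — a determinism check — and with noise or fitted pRFs the truth
is an exact confusion-matrix reference.  Lesion-geometry defaults
(margin 9°, 3–5 islands of radius 3.5–5.5°) make neural reserve about a
quarter of tested locations, near the share reported in real
hemianopic cohorts.

**What the generator does not emulate** — and hence what passing tests
do not show about real data: hemodynamic nonlinearity and structured
physiological noise; SNR differences between cortical areas; the SITA
thresholding staircase and its floor effects; fixation instability;
anatomical realism of lesions; integer-valued GAS ratings.  Recovery of
the category means by the pipeline shows internal consistency of the
chain under the stated noise model, not clinical validity.

## Numerical choices and problem sizes

Degenerate inputs: flat time series → degenerate estimate (VE 0);
empty voxel sets → zero coverage with a warning; empty categories are
reported with n = 0; a constant GAS predictor flags the association
undefined rather than raising.  Predictions whose peak drive falls
below 1e−12 are treated as flat rather than renormalised from rounding
noise.  All stochastic stages take explicit seeds; cohorts use
hierarchical per-patient sub-seeds recorded in the manifest, making
every stage bit-reproducible.

Tests and the acceptance script run the pipeline at reduced but
representative sizes chosen by this package: a 1°/pixel raster for
fitting and cohorts (0.5° remains the library default), four 64-s
cycles per stimulus, 100-voxel recovery samples, 10–20-patient cohorts,
1,000 permutation iterations inside replicated calibration loops and
the full 10,000 for single analyses.  The permutation-calibration check
uses 200 replicate null cohorts; the effect-recovery check uses 10
replicate trained cohorts.

## Known limitations

σ recovery degrades toward the edge of the stimulated field, where
pRFs are clipped by the aperture and parameters become weakly
identified; coverage maps inherit the single detection threshold
across eccentricities (sensible because behavioral sensitivity also
falls with eccentricity, but it ignores SNR and magnification
gradients across areas).  Sector regions do not support erosion;
unions erode component-wise (conservative).  The Hum+ rule treats
device "< 0 dB" output as 0 dB (blind).
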