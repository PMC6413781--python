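# Methods

## Iris transillumination image scoring

A TI photograph is modeled by a hand-annotated circle (center `(cx, cy)`,
iris radius `R`, pupil radius `r_p`, all in pixels; 0-based coordinates,
sub-pixel centers allowed; a pixel belongs to a disk if its center does).

**Sampling layout.** The iris circle's bounding square is split through
the center into 4 quadrant squares of side `R`, each split again into 4
equal sub-squares; the 16 sampling sites are the sub-square centers, at
offsets `(±R/4 or ±3R/4, ±R/4 or ±3R/4)` from the center. Each site
carries a sampling disk of radius 75 px at a reference iris radius
(default `scale_reference = 1000` px, matching a 150 px diameter marker on
native-resolution slit-lamp photographs), scaled proportionally to the
annotated `R`. A site is excluded — and recorded with a reason — when its
disk cannot intersect the iris annulus `r_p < r ≤ R` at all: wholly
inside the pupil (`d + r_disk ≤ r_p`) or wholly outside the iris
(`d − r_disk ≥ R`), `d` the site's distance from the center. Excluding
pupil-only sites keeps the bright retinal red reflex out of the melanin
signal.

**Measurement.** The red channel is smoothed with a Gaussian
(default σ = 25 px at the reference scale, scaled with `R`) restricted to
the annulus by normalized convolution: `blur(red·mask)/blur(mask)`.
Restricting the blur to the annulus is a deliberate choice — an
unrestricted blur would bleed the saturated pupil and the dark background
into annulus pixels, making the score depend on the blur radius even for
a uniformly pigmented iris. With the masked blur, a constant annulus
scores identically to its plain mean for any σ and disk radius (a tested
oracle property), and the score is insensitive to the σ convention, which
image-editor "blur radius" settings leave underdetermined. The smoothed
red values are averaged over each retained disk ∩ annulus, and the score
is the linear map `8 × mean(site means)/255` — the simplest monotone
0–8 calibration, with 0 = no transmitted light and 8 = saturated red
reflex. The map is a declared convention, not a claim about any
photograph-specific calibration; it is exposed as parameters for
recalibration. Per eye-visit, scores of the available images (nominally
2) are averaged.

## Grader panel and reliability

Grades live on a 0–8 scale with at most one decimal. Aggregation is
two-stage (per-grader image means, then across graders), so an unbalanced
grader still contributes one vote. The ICC uses the two-way
random-effects, absolute-agreement model: participants and graders both
random, from the complete participants × graders matrix of per-grader
image means. From ANOVA mean squares (rows MSR, columns MSC, error MSE;
n participants, k graders):

    ICC(A,1) = (MSR − MSE) / (MSR + (k−1)·MSE + (k/n)(MSC − MSE))
    ICC(A,k) = (MSR − MSE) / (MSR + (MSC − MSE)/n)

The single-measure form is primary (conservative); the average-measure
variant is reported alongside. The 95% CI follows the McGraw–Wong
F-distribution construction with Satterthwaite degrees of freedom for the
grader term; the average-measure CI is the Spearman–Brown transform of
the single-measure bounds. Constant matrices make the ICC undefined and
raise. Incomplete panels raise by default; an explicit complete-case mode
drops participants not graded by every grader. Panel-vs-automated-score
agreement is Spearman's rank correlation with midranks for ties, pooling
all eye-visit pairs across eyes and visits (the two scores are plotted
and compared pooled, not per stratum).

## Melanin index

`M = 100·log10(1/band)` with
`band = ((PR650 + PR660 + 0.5·PR640 + 0.5·PR670)/3)/100` on the
400–700 nm / 10 nm grid. The 640–670 nm band isolates melanin absorption
from haemoglobin; M is invariant to reflectance outside the band, strictly
decreasing in band reflectance, and log-linear (×10 reflectance ⇒ −100 in
M). Replicates (nominally 5 per site) are aggregated by averaging
per-replicate M values — M is the analyzed quantity — with spectrum-first
averaging available as an alternative. Hair spectra are processed
identically to skin under the site label `hair`. Calibration scans are
checked against 100% (white standard) and 0% (light trap) within ±2
percentage points by default. No erythema or other chromophore index is
computed; alternative indices can be applied to the same spectra by the
caller.

## Hair markers

PTCA and 4-AHP concentrations (ng/mg) are summarized as change from each
participant's earliest recorded visit: n, mean, and sample (n−1) SD per
marker, the usual trial-reporting convention; a single participant yields
an undefined SD, reported as missing. A PTCA/4-AHP ratio per record is an
added convenience output.

## Longitudinal statistics

Change from baseline uses the earliest visit with data per unit
(participant, or participant × eye). Both the directional mean (signed)
and the absolute mean (magnitude regardless of direction) are reported —
the absolute form suits a primary endpoint asking *whether pigmentation
changed at all*. Eye-level outcomes are summarized per eye (OD, OS) and
pooled over all eye-level changes (OU).

The mixed model has categorical visit fixed effects with baseline as
reference (the month-12 coefficient *is* the modeled mean change at month
12), a participant random intercept and optionally a random slope in
months, and compound-symmetry within-unit correlation — realized as the
exchangeable correlation the random intercepts induce, the classical CS
equivalence; `statsmodels` MixedLM has no separate R-side CS structure,
and with a random intercept the two parameterizations coincide. With both
eyes present, eyes are nested within participants via an eye-level
variance component inside each participant group; no eye fixed effect is
included (eyes enter only through nesting). Estimation is REML (L-BFGS
first, Powell retry for ill-scaled or boundary cases); fixed-effect CIs
and p-values use the normal approximation, as variance-component
uncertainty is not propagated — adequate at the simulated sizes, and the
small-sample behavior is characterized by the coverage simulation below.

**Fallback.** The intercept+slope model falls back automatically to
intercept-only — flagged and logged — when the optimizer fails, a
fixed-effect SE is not finite, the random-effects covariance is
near-singular, or the slope variance falls below the resolution at which
a slope variance is estimable at all: `σ²_resid / mean_i Σ_t (t − t̄)²`,
the sampling variance of one participant's individually fitted slope.
Estimates below that floor are statistically indistinguishable from a
boundary solution. If the intercept-only refit also fails, a fit error
with diagnostics is raised.

Labels: p < 0.05 "significant", 0.05 ≤ p < 0.10 "moderately significant";
no multiplicity adjustment (all analyses exploratory by design).

## Synthetic cohort

The generator emulates a 5-participant, both-eyes, 7-visit (months
0,3,6,9,12,15,18) open-label design with an 18-grader panel and 2 images
per eye-visit. Latent eye-visit scores follow

    L(i,e,t) = μ₀ + b_i + s_i·t + δ_t,   clamped to [0,8]

with defaults μ₀ = 3.0, b_i ~ N(0, 1.0²), s_i ~ N(0, 0.04²) per month,
and per-visit mean changes δ ramping 0 → 1.0 at month 12 (held
thereafter). Both eyes share the participant trajectory. Grades are
`round₁(clip(L + γ_g + ε, 0, 8))` with grader bias γ_g ~ N(0, 0.3²) fixed
per grader and noise ε ~ N(0, 0.5²) per grade. These variance components
are not published quantities; they were chosen once to place panel
reliability in the high-ICC regime (≈0.85–0.95 at n = 5) reported for
trained research-assistant graders, and are all overridable. Images
encode L in the annulus red mean (`L/8·255`, + N(0, 2²) pixel noise by
default) with a saturated-red pupil and dark background — no attempt at
photorealistic slit-lamp optics, iris texture or flash artifacts; the
bright pupil exists to exercise the scorer's pupil-masking logic.
Rendered images are 160×160 (iris radius 64 px), which keeps the full
cohort render under a second; the scorer's scale-proportional disk and
blur parameters make the score resolution-independent.

Reflectance spectra are synthesized by inverting the M-index formula
(band reflectance `100·10^(−m/100)`), with per-participant site offsets
(SD 3 M units), replicate noise in M space (SD 0.5), and site effects
ramping to their month-12 truth values (inner bicep +1.72, outer forearm
+3.4, hair +17.3 M units — the effect sizes observed in the reference
trial, used as generating values). Hair PTCA/4-AHP baselines are
lognormal, moment-matched to baseline means (SD) of 26.22 (20.59) and
13.28 (19.66) ng/mg, with additive shifts ramping to +7.62 / −5.92 at
month 12 and relaxing toward +0.52 / −5.24 at the final visit, plus
per-visit change noise (SD 6.43 / 11.68). Acuity letters use a per-eye
random structure with a +4.6-letter month-12 effect. The protocol's two
baseline visits are collapsed to month 0 by default; a `second_baseline`
flag adds a month −1 visit to exercise the earliest-baseline rule. All
randomness flows from one seed through independent substreams per data
type, so bundles are bit-reproducible.

**What passing tests show — and don't.** Recovery of the generating
effects demonstrates the estimators and conventions are implemented
correctly under the stated model. Real TI photographs have operator
variability in the circle annotation, uneven illumination, iris texture
and acquisition artifacts that the renderer deliberately omits, so
synthetic round-trip accuracy (±0.05 score units) should not be read as a
claim about photographic accuracy.

## Numerical choices and degenerate inputs

- 8-bit quantization bounds the render/score round-trip error at
  8·0.5/255 ≈ 0.016 score units.
- Sites whose disk ∩ annulus contains no pixel centers are dropped at
  scoring time (in addition to the analytic zero-overlap exclusion); an
  image with no usable site raises a scoring error.
- Grade validation enforces the one-decimal convention to 1e-9.
- A z-based p-value that underflows to 0 is floored at the smallest
  positive normal float so downstream labeling stays defined.
- Mixed-model simulations (200 replicates × 100 participants × 7 visits)
  show month-12 effect bias < 0.01 with 95% CI coverage ≈ 0.95; these
  sizes were chosen as the smallest at which bias and coverage stabilize.

## Known limitations

- No automatic iris/pupil segmentation: the circle model is operator
  input, and annotation error propagates into the score.
- The ICC CI construction is one defensible convention among several
  (F-based, Satterthwaite df); bootstrap or exact methods may differ in
  small panels.
- Degrees-of-freedom corrections (Kenward–Roger/Satterthwaite) for the
  fixed effects are not implemented; normal-approximation CIs can be
  slightly anticonservative for very few participants.
- The pluggable reflectance-index surface computes only the M index;
  other published indices over the same spectra must be supplied by the
  caller.
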