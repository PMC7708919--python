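# Methods

This note documents the models implemented in `pawtherm`, the default
parameter values and why they were chosen, the simulator's statistical
structure, and the numerical conventions that the code relies on.

## Radiometric model

A microbolometer reports an apparent temperature mixing target emission
with reflected ambient radiance. `pawtherm` uses the band-integrated
grey-body (Stefan-Boltzmann) model in Kelvin,

    W(T_app) = ε · T_obj⁴ + (1 − ε) · T_refl⁴,     T in K,

inverted in closed form for correction. Atmospheric transmittance is
fixed at 1: at the standardized 20 cm working distance, air absorption
is negligible. Commercial camera software applies a proprietary variant
of this correction; the band-integrated T⁴ model is the standard open
formulation and is documented here as this package's choice. No
single-wavelength Planck model and no humidity model are attempted.
Emissivities: skin 0.98 (bare paws), fur 0.94 (back), blackbody
reference 0.95.

Calibration QC fits ordinary least squares of the *mean replicate
reading* per blackbody reference against the reference temperature and
reports slope, intercept, R², and the maximum absolute deviation of a
mean reading from its reference. The accuracy gate passes when that
maximum deviation is within a tolerance, 0.2 °C by default — the
accuracy a camera must demonstrate in the 35–40 °C body-temperature
range before animal imaging. The fit refuses degenerate designs (fewer
than two distinct references).

## ROI geometry and discretization

Seven ellipses at fixed frame coordinates: four paw ROIs (wrist joints
of the front paws, ankle joints of the hind paws) and three back
references along the body midline. The legacy numbering El1–El7 maps to
FL, FR, HL, HR, back1–back3 in that order (a convention of this
package; the anatomical assignment order is otherwise arbitrary).
Geometry is defined at the native 80×60 px resolution and scaled
linearly to larger frames; frames below 80×60 are rejected.

Discretization conventions (the procedure itself does not fix them, so
they are pinned here and tested):

* pixels are 0-based, x = column, y = row, y increasing downward;
* a pixel belongs to an ROI iff its **center** satisfies the rotated
  ellipse inequality ≤ 1; off-frame parts are silently clipped, a fully
  off-frame ROI is an error;
* ROI standard deviations are population SDs (divide by N);
* emissivity correction is applied **per ROI** with the ROI's tissue
  role (skin vs. fur) before statistics, so one raw frame can carry
  both tissue types.

## Temperature index

TI of a paw is the ratio of its ROI mean to the average of the three
back ROI means, computed **on the Celsius scale**. The published value
range (TI 0.80–1.0 at paw temperatures 28–34 °C and back ≈ 34 °C) is
only consistent with a Celsius ratio — the same temperatures in Kelvin
give TI ≈ 0.98–1.0 — so Celsius is the default and a Kelvin switch is
provided for sensitivity analyses (`temperature_index(..., scale="kelvin")`).
TI is not clamped; values above 1 classify as severe with a warning,
values below the nominal absent bin (0.80) classify as absent with a
warning.

Severity bins are left-closed/right-open with an open-ended severe top
bin: TI [0.85, 0.90) mild, [0.90, 0.95) moderate, ≥ 0.95 severe;
thickness 2/2.5/3 mm edges; clinical score {0}, {1}, {2,3}, {4}. The
therapeutic-study inclusion rule requires **all four** joints at
TI ≥ 0.9 (boundary inclusive); the and/or ambiguity in the original
exclusion phrasing is resolved to "exclude if *any* joint < 0.9", which
matches the stated 0.9 ≤ TI ≤ 1 condition for enrolled animals.

## Synthetic cohort model

The generator's defaults are the study conditions the pipeline is
validated against: 14 immunized (CIA) mice of which 2 are
non-responders, 4 healthy controls, measurements on days 0, 7, 14, 21,
28 with an LPS-synchronized flare at day 28.

Marginal distributions (Celsius / mm, all tunable):

| quantity | baseline | day-28 responder |
|---|---|---|
| back temperature | N(34.0, 0.2) | same |
| paw temperature, CIA | N(28.65, 0.35) | N(31.9, 0.5) |
| paw temperature, control | N(28.14, 0.35) | same as baseline |
| per-paw thickness | N(1.79, 0.13) | N(2.65, 0.20) |

These imply per-paw TI ≈ 0.843 (CIA baseline), 0.828 (control), 0.938
(flare), i.e. cohort TI_total means ≈ 3.37 / 3.31 / 3.71 and total
thickness ≈ 7.17 / 10.15 mm — the group summaries the regression tests
check. Non-responders stay at the baseline distributions at every day.
Between baseline and flare, responder means and SDs interpolate
linearly along a flare profile (fractions 0, 0, 0.05, 0.2, 1 on days
0–28): subclinical through week 3, full flare 48 h after LPS.

**Noise structure.** Each measurement deviates from its group mean by

    sd · (m + κ·u + λ·w) / sqrt(1 + κ² + λ²)

with `m` a persistent per-mouse latent-severity factor shared across
modalities and days, `u` a modality-specific per-mouse-day factor
(κ = `cross_modality_noise`, default 4.0), and `w` per-paw noise
(λ = paw scatter, default 0.15 for temperature and thickness, 3.0 for
the clinical score). The normalization keeps every marginal SD exactly
at its table value whatever the knobs, so coupling can be varied
without moving the group summaries. Temperature and thickness use small
paw scatter because an arthritic flare is a systemic per-animal event
(all four joints flare together); the ordinal clinical score uses large
paw scatter because per-paw grading varies strongly — with coherent
paws, per-mouse score totals collapse onto multiples of 4 and the
cohort median cannot sit at intermediate values.

**Clinical scores** threshold a latent severity (flare fraction +
0.25 · deviate) at (0.35, 0.65, 0.95, 1.25), calibrated by replicate
simulation so that the day-28 responder cohort has a modal median total
score of 10 with totals ranging roughly 8–14, and baseline animals
score 0. Expected score is strictly increasing in latent severity, as
are expected temperature and thickness (the monotone measurement-model
property the tests check).

**Default κ and the cross-modality correlation.** The day-28 Pearson
correlation between TI_total and total thickness across the 14 CIA mice
is dominated by the responder/non-responder mixture: the two clusters
are separated by several within-cluster SDs in both endpoints, which by
itself forces an expected sample correlation around 0.79 even with *no*
shared factor at all (κ → ∞), and coupling can only raise it. The
in-vivo value reported for this design (r ≈ 0.615) is therefore not
reachable by any κ under the two-point severity mixture above — real
cohorts have a severity continuum that the binary responder model does
not emulate. κ = 4 (weak coupling, paw-level cross-modality correlation
≈ 0.06) was chosen to keep the simulated modality disagreement
realistic (moderate-severe counts by TI / thickness / score of roughly
12 / 9 / 9 out of 14, mirroring the disagreement seen in practice); the
resulting mean day-28 correlation is ≈ 0.80 and is reported as such.
This is a known, documented limitation of the generator, not of the
scoring pipeline.

**Selection probability.** Under the defaults the probability that
exactly 12 of 14 mice pass the all-joints TI ≥ 0.9 rule is 0.908
(computed by Gauss-Hermite quadrature on the measurement model:
per-responder pass probability 0.9920, non-responder pass probability
≈ 3·10⁻⁷). Because the margin over 0.90 is smaller than the Monte-Carlo
error of a few hundred replicates, the test suite estimates this rate
on 10⁴ replicates through a vectorized path that a unit test pins to
the ordinary scoring route.

**Reproducibility.** All draws flow from one
`numpy.random.default_rng(seed)` in fixed order; a fixed seed
reproduces cohort tables byte-for-byte, and every pipeline artifact is
stamped with the seed and a configuration hash.

## Phantom frames

An 80×60 frame is painted piecewise-constant: plate background
(34 °C), a body ellipse at the back temperature, four paw ellipses at
their own temperatures — at exactly the ROI-layout geometry — plus
i.i.d. Gaussian sensor noise (NETD 0.1 °C). Zero-noise phantoms
therefore reproduce region temperatures exactly under ROI averaging (to
float summation error, ≤ 1e-12), and noisy phantoms obey the
σ/√(n_px·n_frames) convergence the Monte-Carlo tests check. The phantom
does not attempt fur texture, anesthesia physiology, limb pose
variation, or visible-light fusion; passing tests demonstrate the
correctness of the extraction/scoring chain, not robustness to real
segmentation or pose errors.

## Statistics

* Trapezoid AUC per mouse over the observed day grid, no baseline
  subtraction ("cumulative burden over the whole period"); unequal
  spacing is handled by the composite rule.
* Two-group comparisons: ordinal endpoints → two-sided Mann-Whitney;
  continuous endpoints → Shapiro-Wilk per group at α = 0.05, Student's
  t only if both groups pass, otherwise Mann-Whitney (the ambiguous
  one-normal-one-not case and groups too small to gate also route
  nonparametric). Identical samples short-circuit to p = 1. Two-sided
  throughout.
* Correlations: Pearson for continuous-continuous, tie-corrected
  Kendall τ-b for continuous-ordinal.
* No multiple-testing correction by default, matching the
  cross-sectional analysis style this mirrors; Holm adjustment is
  available as a flag on the AUC comparisons.
* Efficacy analysis computes per-mouse AUCs (not group-mean curves) so
  that group dispersion and tests on AUCs are well defined; pairs where
  a group has fewer than two mice are skipped.

## Problem sizes used in validation

Replicate counts were chosen so that Monte-Carlo error is small against
each check's tolerance: 200 seeded cohorts for group-summary and
correlation regressions (SE of the mean TI_total ≈ 0.003), 500 series
for calibration linearity, 10⁴ replicates for the near-boundary
selection rate, 100 random instances per brute-force oracle
equivalence, and 1000 null replicates for the type-I-error calibration
of the gated test procedure.

## Known limitations

* The binary responder/non-responder severity model cannot reproduce
  continuum-valued cross-modality correlations (see above).
* The radiometric correction is the open T⁴ grey-body model, not any
  vendor's proprietary chain; whether distance/humidity terms matter at
  20 cm is untested (assumed unity).
* The ROI layout is fixed; no automatic paw detection. Real-world pose
  variation is out of scope.
* TI values outside [0.80, 1.0] are accepted with warnings rather than
  rejected; the published bins do not define behavior there.
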