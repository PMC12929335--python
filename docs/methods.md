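# Methods

## Model

Post-contrast mean liver attenuation L′ (HU) is mapped to a
non-contrast-equivalent value with a phase-specific increasing
exponential-decay curve

    corrected L = α + β · (1 − e^(−L′·κ)),   β > 0, κ > 0.

The curve is strictly increasing in L′ and saturates at α + β, reflecting
that heavily enhancing livers carry diminishing information about the
unenhanced baseline. Its exact inverse,
L′ = −ln(1 − (L − α)/β)/κ, is defined only on the open interval
(α, α + β) and is what the cohort simulator uses to generate paired data.
The registry ships one immutable coefficient triple per post-contrast
phase: arterial (−31.478, 114.8, 0.022), venous (−33.488, 109.094, 0.015),
delayed (−25.431, 96.961, 0.02), with residual RMSEs of 4.7, 7.4 and
4.9 HU respectively on their derivation data.

Fat fraction is the established linear non-contrast conversion
FF (%) = −0.58·L + 38.2, applied to the corrected value. Because FF is
strictly decreasing in L, classification by FF > 15 % is algebraically
identical to corrected L < 40 HU; both thresholds are applied as strict
inequalities. Implausible values (FF < 0, non-positive post-contrast
input) are flagged, never clamped: transparency beats silent repair for
downstream QC.

## Fitting

Coefficients are estimated by unweighted nonlinear least squares on paired
(L′, L) observations, minimising Σ(L − f(L′))². The optimiser is a
hand-rolled Levenberg–Marquardt with the analytic Jacobian
(∂f/∂α = 1, ∂f/∂β = 1 − e^(−L′κ), ∂f/∂κ = β·L′·e^(−L′κ)), a relative-SSE
convergence tolerance of 1e−10, at most 200 iterations, and steps rejected
if they would leave the admissible region β > 0, κ > 0. Exponential fits
are sensitive to the rate-constant start, so the fit is repeated from
κ₀ ∈ {0.005, 0.01, 0.02, 0.04} with α₀ = min(L) − 5 and
β₀ = range(L) + 10; the start with the lowest SSE wins, keeping results
deterministic. Reported RMSE uses divisor n (not n − 3); the divisor is
documented here precisely because cohort-to-cohort RMSE comparisons depend
only on using it consistently. Tests cross-check the optimum against both
a dense coarse grid over (α, β, κ) and an independent optimiser
(`scipy.optimize.curve_fit`); noiseless recovery is exact to 1e−6 and
noisy recovery is unbiased within Monte-Carlo error over 50 seeds.

## Attenuation extraction

Volumetric means are arithmetic means over all voxels carrying the organ
label; the voxel count is always reported alongside, since partial-organ
fields of view simply reduce the count. ROI means pool all pixels across
all ROIs — a pixel-count-weighted mean, not a mean of per-ROI means — with
membership defined as pixel center within the mm radius on the ROI's axial
slice (radius converted per-axis via in-plane spacing). Pixels inside two
overlapping discs are counted once per disc; overlap handling had to be
fixed for bit-exact tests and the pooled-with-multiplicity rule is the
simplest contract consistent with pooling "all pixels across all ROIs".
The L/S ratio is reported as undefined when |S| ≤ 1 HU: spleen means near
zero are physically implausible and the guard avoids division blow-up on
synthetic edge cases. No HU rescaling is performed; volumes are assumed
already in HU.

## Phase voting

The scan-level phase is the label maximising the summed confidence over
slice predictions. Exact weight ties are broken by the fixed order
non-contrast > delayed > venous > arterial and flagged `tied=True`; the
order is arbitrary but deterministic, which is what reproducibility
requires. If every confidence is zero the vote falls back to an unweighted
slice count (with a logged warning). Weights are raw confidences — no
exponentiation or thresholding — the plainest reading of
confidence-weighted voting.

## Evaluation

Sensitivity, specificity, PPV and NPV come from the confusion counts;
balanced accuracy is the mean of sensitivity and specificity, computed at
full precision and only rounded (half-up, one decimal) for reporting. A
metric with a zero denominator is reported as undefined, never as zero.
Threshold sweeps default to 5-HU grids for attenuation statistics and
5-percentage-point grids for FF; the optimum maximises balanced accuracy
with exact ties broken toward the more specific threshold. The positive
class is steatosis throughout; attenuation-like scores, where lower means
positive, are negated before ROC analysis so an informative marker yields
AUROC > 0.5.

AUROC is the trapezoidal area under the ROC curve built over all distinct
score cutoffs; with tied scores this equals the pairwise concordance
probability with tie credit 1/2, and the test suite enforces that equality
to 1e−12 against a brute-force pair count. Paired ROC curves are compared
with DeLong's method in the midrank placement-value formulation;
z = (AUC_a − AUC_b)/√var(diff) is referred to the standard normal,
two-sided, with no multiple-testing correction. When the variance of the
difference degenerates to zero with equal AUCs (e.g. identical score
vectors) the comparison returns z = 0, p = 1; with unequal AUCs the
p-value is left undefined with an explanation. Spearman correlation uses
midranks and the t-approximation with n − 2 degrees of freedom (delegated
to `scipy.stats.spearmanr`, which implements exactly that contract).

## Synthetic data

The cohort simulator emulates a derivation-like population: a
two-component Gaussian mixture of latent true non-contrast liver
attenuation with steatotic mean 28.8 HU, non-steatotic mean 57.9 HU and
moderate-to-severe prevalence 7.6 %; ground truth is latent L < 40 HU. For
each post-contrast phase the post-contrast value is the exact model
inverse of the latent value, and Gaussian residual noise with the phase's
RMSE (4.7 / 7.4 / 4.9 HU) lands on the non-contrast side of the pair —
the response variable of the correction regression. The long-format
output therefore carries, on post-contrast rows, both the post-contrast
measurement (`liver_hu`) and that phase's observed non-contrast pairing
(`nc_observed_hu`); non-contrast rows hold the latent value itself.

Component SDs are not published; 6 HU per component was chosen as the
default because it keeps the latent-threshold event L < 40 HU coherent
with the configured prevalence (with SDs near 10 HU the class overlap
inflates the sub-40 rate well beyond the nominal prevalence) while leaving
the classes realistically non-separable under phase noise. Spleen means
per phase default to a worked multi-phase example (non-contrast 38.2,
arterial 86.0, venous 99.3, delayed 73.1 HU; SD 6 HU), as no population
spleen distributions are available — these are stand-ins, not estimates.

Latent draws are truncated to (5, α+β−5) HU for every requested
post-contrast phase so the model inverse stays defined (out-of-range draws
are resampled, at most 1000 rounds). The delayed model saturates at
71.5 HU, so including it visibly truncates the upper tail of the
non-steatotic component; the tests check the empirical mean against the
analytic truncated-normal expectation in that configuration, and against
the raw configured means when only higher-saturation phases are requested.

The phantom generator voxelises two axis-aligned ellipsoids (liver,
spleen) over an air background (−1000 HU) with optional Gaussian texture
and optional axial cropping from the top of the stack, emulating
partial-organ fields of view — the simplest geometry that exercises
masked-mean extraction. The slice-prediction simulator assigns the true
phase with a configurable per-slice accuracy, errors spread uniformly over
the other phases, and Beta-distributed confidences (mean 0.8 for correct,
0.5 for incorrect labels).

None of the simulators model real anatomy, contrast kinetics over time,
scanner or kernel effects, or heterogeneous fat distribution; passing
tests demonstrate that the pipeline's math and plumbing are correct under
the stated statistical assumptions, not that the correction equations
generalise to new scanner populations.

## Pipeline and reproducibility

The `run` orchestrator executes the stages simulate-cohort,
simulate-phantom, extract, phase-vote, correct, ff, evaluate in order,
writing CSV/JSON artifacts and a manifest with SHA-256 checksums. One
global seed fans out to per-stage child seeds through
`numpy.random.SeedSequence([seed, stage_index])`, so stages are
individually reproducible without ever reusing a stream. Identical
config+seed runs are byte-identical; changing the seed changes stochastic
outputs but not schemas.

## Problem sizes

Default study sizes were chosen so each check is statistically meaningful
at interactive cost: simulate-and-refit studies use 1000 pairs × 50 seeds
(coefficient Monte-Carlo SEs ≈ 0.1–0.5 HU), the RMSE study 2000 pairs,
cohort-level discrimination and threshold-stability checks 10 000
subjects, and bootstrap/grid oracles 2000 resamples / 60³ candidates.

## Known limitations

- The correction registry applies to mean liver attenuation from
  GE-kernel-like acquisitions; transfer to other protocols is a validation
  question the synthetic tests cannot answer.
- The FF line's validity range is not characterised here; extreme inputs
  are flagged but not rejected.
- DICOM ingestion and organ segmentation are out of scope: masks and
  attenuation values are inputs.
- The DeLong implementation requires at least two subjects per class for
  a finite variance estimate.
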