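# Methods and design notes

## Signal model

The closed-form synthesis evaluates the MPRAGE steady state under the
standard assumptions: perfect (180°) inversion, perfect spoiling between
excitations, linear k-space ordering with the main (contrast-defining) echo
at the centre of the readout train, and no transmit/receive field bias. The
repeated excitation is folded into an apparent relaxation time
`T1* = (R1 − ln cos α / ES)⁻¹` with driven equilibrium `R1·T1*`: one
echo-spacing interval plus one pulse acts on longitudinal magnetization as
`Mz → R1·T1* + (Mz − R1·T1*)·exp(−ES/T1*)`, which is exact in the sense that
`exp(−ES·R1)·cos α = exp(−ES/T1*)`. The factor `Q` is the fixed point of the
cycle map (inversion → relax `TI − τ/2` → n such intervals → relax `TD`)
read at the central excitation.

**Units.** All times are stored in seconds and rates in s⁻¹ throughout the
library; constructors and the CLI accept milliseconds (`from_ms`, `--ti-ms`,
…) and convert at the boundary. This removes the ms/s mix-up risk between
the echo-spacing term of `T1*` and the second-scale TI/TR terms.

**Infeasible timings.** `TD = TR − (TI − τ/2) − τ` may be negative: the
readout would not fit in the cycle, so no scanner could acquire the setting.
Reconstruction has no such constraint, so synthesis proceeds (then
`E2 = exp(−TD·R1) > 1`) with a warning; the feasibility flag also covers
`TI < τ/2` (train would start before the inversion). No clamping is applied
to `E2`. The calibration-optimal setting used throughout the examples
(α=14°, TI=900 ms, TR=1400 ms, TE=0, ES=14 ms, n=176) is exactly such a
case: τ=2464 ms, TD=−732 ms.

**Flip angle.** α is restricted to [0°, 90°): the upper bound keeps
`ln cos α` defined; α=0 is the degenerate no-excitation case and yields zero
signal exactly. The partition count `n` defaults to the full 176 (the
partial-Fourier-reduced effective count is a configurable alternative; the
choice only rescales τ).

**Invalid voxels.** Quantitative maps routinely contain NaN or negative
background garbage; such voxels are masked and synthesized as zero.

## Verification oracle

`bloch.mprage_steady_state` recomputes the steady state by brute force:
it simulates the preparation cycle pulse-by-pulse and iterates cycles until
the start-of-cycle magnetization converges, then reads `sin α · Mz` at the
central excitation (1-based index ⌈n/2⌉, i.e. after ⌈n/2⌉ train intervals —
for even n exactly time τ/2 into the train; test grids use even n so the
convention is exact). Within the train it propagates the same per-interval
effective-relaxation operator the closed form assumes, so what the oracle
verifies independently is the *steady-state algebra* — the composition of
E1..E4 and the fixed-point solution — not the intra-train approximation
itself. A literal discrete train relaxing toward thermal equilibrium between
pulses has a slightly different within-train asymptote
(`(1−e^{−ES·R1})/(1−e^{−ES·R1} cos α)` vs `R1·T1*`), which differs at the
0.5–2.5% level for typical settings; the closed form deliberately adopts the
effective-relaxation description, and the oracle checks the algebra built on
top of it (agreement is ~1e−12, asserted at 1e−3). The oracle refuses
TD < 0: it verifies physically realizable cycles only.

## Phantoms and ground truth

Phantoms are tilted circular cylinders (cord) inside a CSF annulus inside a
background compartment, voxelized with k³ regular subvoxel samples per voxel
(default k=5) so the partial-volume fraction error per slice is bounded by
(1/k)². Ground truth is analytic: the perpendicular cross-section is πr² and
an in-plane cut of a cylinder tilted by θ is πr²/cos θ. Gaussian noise is
added per map, and all generators are pure functions of (spec, seed).

**Tissue parameters.** The default tissue values (cord PD 0.70, R1 1.0 s⁻¹,
R2\* 30 s⁻¹; CSF PD 1.0, R1 0.25 s⁻¹, R2\* 1.5 s⁻¹; background PD 0.40,
R1 0.60 s⁻¹, R2\* 40 s⁻¹ — a lumped low-signal extra-spinal compartment) are
plausible 3 T values chosen for this package; they are configurable and not
tied to any cohort. They produce the expected T1-weighted ordering (cord
brightest, CSF darkest) at every parameter setting exercised in the tests.

**Partial-volume bias and the PD-contrast phantom.** With R1-driven
contrast, the synthesized intensity is a *concave* function of the cord
fraction in a mixed voxel, so the half-intensity level sits at roughly 30%
cord fraction and a half-intensity boundary lies outside the geometric
edge — inflating measured CSA by a few percent for a straight cord and by
~10% when a 30° tilt widens the boundary zone. This is a genuine
partial-volume property of T1-weighted contrast, not a defect of the area
measurement. Geometry validation therefore uses `PD_CONTRAST_TISSUES`:
equal R1 and R2\* across classes with contrast carried by PD alone, making
intensity exactly linear in the cord fraction so that the half-intensity
boundary is the geometric boundary. With it the pipeline recovers πr² to
+3.4% (straight and 30°-tilted alike), which is the pure digitization floor
at 1 mm isotropic resolution. The R1-contrast bias is left observable with
the default tissues and should be kept in mind when interpreting absolute
(rather than differential) CSA from threshold segmentations.

## Segmentation and CSA measurement

Segmentation is deliberately simple and fully documented (the clinical
workflow this emulates delegates to a learned segmenter): a global threshold
— midpoint of the 0.5th/99.5th intensity percentiles by default (the cord is
a small bright structure, so the upper percentile sits inside the cord
class), Otsu and fixed-value alternatives — followed by largest connected
component per axial slice. It is scale-invariant for the relative methods.

Raw per-slice area is voxel count × in-plane voxel area. The centerline is
the path of slice centroids smoothed with a Gaussian of σ=2 slices
(configurable); its tangent comes from central differences, and each slice's
area is multiplied by cos θ, the angle between tangent and slice normal —
the per-slice cosine convention (an alternative, path-length rescaling, is
not implemented; for smooth cords they agree to first order). Slices are the
third array axis; vertebral levels are user-supplied slice ranges, and
per-level means average corrected areas. A boundary partial-volume
refinement exists conceptually but is off by default to keep the default
pipeline exactly reproducible from the threshold alone.

## Parameter calibration

The grid search is exhaustive over the Cartesian product of per-parameter
values (defaults: α 6–14° step 1°, TI 400–1000 ms step 50 ms, TR
1000–2500 ms step 100 ms, TE 0–10 ms step 1 ms, ES 5–16 ms step 1 ms — the
steps are round values spanning the stated calibration ranges, as none are
prescribed). Per subject the objective takes the *median* CSA across levels;
across subjects it minimizes the *absolute value of the mean* signed
difference by default. The mean-of-absolute-differences aggregation is
available (`aggregation="mean_abs"`); the |mean| default targets the
cohort-level bias, which is the quantity the agreement analysis reports, and
has the documented property that opposite-signed subject differences cancel.
Ties (relative tolerance 1e−9) are all recorded and broken lexicographically
in (α, TI, TR, TE, ES) ascending order. On noise-free phantoms the
segmentation boundary — hence CSA — is unchanged by most contrast changes,
so the zero-objective optimum is a large tie class containing the generating
parameters; recovery tests assert membership in that class. Validation runs
use a default-step sub-grid (e.g. α × TI × ES with TR, TE fixed) sized to
finish in seconds; the full 5-D product (~250k cells) is supported but is a
long batch job.

## Agreement statistics

Bland-Altman: differences B − A, bias = mean, limits of agreement = bias ±
1.96·SD (sample SD, n−1); the multiplier is the conventional 95% normal
value. Percentages are relative to the grand mean of the two method means.
One agreement point per (subject, timepoint), averaged across levels —
matching how CSA is reported — and the group-bias comparison feeds
*per-subject mean* differences to the Bayes factor so its independence
assumption holds.

The JZS two-sample Bayes factor places a Cauchy prior (default scale √2/2)
on the standardized effect and integrates the Zellner-Siow g-mixture
numerically (adaptive quadrature; relative tolerance 1e−10). BF10 > 3 is
read as substantial evidence for a group difference, BF10 < 1/3 for
equivalence, in between inconclusive. Two zero-variance samples with equal
means are degenerate and return BF10 = 0 with a warning. Tests cross-check
against a dense fixed-grid Simpson quadrature of the same integrand and
against an independent published implementation.

Precision is the per-subject sample SD of CSA across timepoints (per level,
then averaged across levels by default), summarized as cohort mean ± SD;
subjects with fewer than two timepoints are excluded.

## Cohort simulator

The generative model mirrors the analysis model: CSA = group intercept +
level offset + (group rate + subject slope + age-coefficient × centered
age)·t + (group quadratic + subject quadratic)·t² + subject intercept +
subject level offset + occasion noise, with each modality adding its own
bias and independent measurement noise on top of the shared latent value.
Defaults are fixed to the study conditions this package models: 21 controls
and 23 patients at 0/2/6/12/24 months over levels C1–C3; intercepts
66.08/64.27 mm²; linear rates +0.063/−0.527 mm²/month; quadratic terms
−0.0017/+0.0059 mm²/month² (chosen so the group trajectories pass through
the default baseline and 2-year levels); synthetic-modality bias
−0.31 mm²; random-effect SDs 7 mm² (intercept), 0.1 mm²/month (slope),
1 mm² (level); occasion and modality noise 1 mm² each, giving a control
repeatability SD near 1.4 mm². Ages are uniform on group-specific ranges
reproducing the cohorts' means; the scanner identifier switches at 10 months
to emulate a mid-study upgrade. Non-positive draws are resampled and
counted.

What the simulator does **not** emulate: artifact-driven exclusions,
level-specific artifact rates, scanner-specific bias, or any coupling
between pathology and measurement error. Consequently, passing recovery
tests demonstrates correctness of the estimators under the assumed
generative structure, not robustness to real-world artifact processes. A
single additive-noise model also cannot simultaneously match an arbitrary
per-point scatter (limits of agreement) and a given repeatability SD; the
defaults prioritize the bias and the repeatability scale.

## Trajectory model

Fixed effects: level (categorical), time and time² and their interactions
with group, age×time (age mean-centered), and scanner where it varies. Time
is months since enrollment, uncentered. Random effects per subject:
intercept, time slope, time², and level offsets, estimated by REML by
default. If the full structure is singular or fails to converge the model is
refitted dropping time², then level, then the slope, in that order, with the
structure actually used recorded on the fit; fully degenerate (zero-noise)
data falls back to fixed-effects OLS, which identifies the coefficients
exactly. Inference uses the normal approximation on fixed-effect contrasts;
confidence intervals and p-values are therefore mildly anticonservative for
small cohorts (a Satterthwaite-style correction is a known omission).
Family-wise adjustment over the contrasts requested in one call uses the
joint normal distribution of the contrast statistics (max-|z|), which for a
single contrast reduces to the raw p-value. Marginal CSA per group averages
over levels with age at the cohort mean and the reference scanner;
extrapolation beyond the observed time range warns. Every reported contrast
equals the difference of its per-group estimates by construction.

## Trial power

The ANCOVA sample size per group is
`ceil(2·(z₁₋α/₂ + z₁₋β)²·σ²·(1 − ρ²)/Δ²)` with a floor of 2: adjusting for a
baseline correlated ρ with the follow-up multiplies the residual variance by
(1 − ρ²), and ρ=0 recovers the standard two-sample formula. Δ is an effect
fraction times a reference difference (the patients-minus-controls CSA gap
at two years), so a 100% effect abolishes the atrophy-related difference.
The σ of follow-up CSA is a required user input — it cannot be derived from
published summaries — and the cohort simulator provides realistic values for
testing. A t-quantile fixed-point iteration (`use_t=True`) gives the small-n
correction; the normal form is the default and its Monte-Carlo check is run
at moderate n (tens per group), where the z/t discrepancy is within the
simulation tolerance. The Monte-Carlo power simulator draws bivariate-normal
(baseline, follow-up) pairs and tests the arm effect in the OLS fit
`follow-up ~ baseline + arm`.

## Problem sizes

Validation and acceptance runs use sizes chosen to exercise every code path
at desk scale: phantoms of 32–64 voxels per side at 1 mm isotropic, a
default-step calibration sub-grid of ~1400 cells over three phantoms, 200
simulated cohorts at the 21+23 study size for rate-difference recovery
(simple random structure matching that experiment's generative model), 10
study-condition cohorts with the full model for the trajectory summaries,
and 2000-trial Monte-Carlo power runs. All randomness flows from explicit
seeds; reruns are bit-identical for the deterministic stages.
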