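# Methods

This note documents the models, numerical conventions and design choices
behind `tractfa`, and what the synthetic-data validation does and does not
establish about real data.

## Diffusion model and simulation

Each voxel carries a symmetric positive-definite 3×3 diffusion tensor D
(mm²/s), stored as its 6 unique components (Dxx, Dyy, Dzz, Dxy, Dxz, Dyz).
The diffusion-weighted signal follows the mono-exponential model
S = S₀·exp(−b·gᵀDg) for b-value b (s/mm²) and unit direction g.

**Gradient scheme.** Default 30 weighted directions at b = 1000 s/mm² plus
one b = 0 volume.  The directions are not prescribed by any table; they are
spread over the sphere by minimising an electrostatic (Coulomb) potential in
which every direction repels both the other directions and their antipodes
(diffusion encoding is sign-invariant).  The optimisation is a fixed
600-iteration projected gradient descent from a seeded random start, so a
given seed always yields the same scheme.  For 30 directions the minimum
pairwise angular separation is ≈ 26°, versus ≈ 11° for the best of 1000
random placements.

**Phantoms.** Fiber bundles are tubes of radius r (mm) around an analytic
centerline — a straight segment or a circular arc — inside a regular grid of
2.5 mm isotropic voxels.  A voxel belongs to a bundle when its center lies
within r of the centerline; it then receives the bundle eigenvalues (default
λ = (1.7, 0.3, 0.2)×10⁻³ mm²/s, FA ≈ 0.836) with the principal axis along
the local centerline tangent.  All other voxels are isotropic (default
0.7×10⁻³ mm²/s, FA = 0).  Bundles claiming the same voxel are rejected —
which also means two tubes cannot literally abut; junction behaviour is
exercised on directly constructed tensor fields instead.  The label volume
doubles as the seeding atlas (integer parcel ids ≤ 54).

**Noise.** Rician: the simulated magnitude is √((S+ε₁)² + ε₂²) with
independent ε ~ N(0, σ²), the magnitude of a complex Gaussian perturbation.
Default σ = S₀/30 (SNR 30, typical for clinical 3T DTI).  σ = 0 reproduces
the noiseless forward model exactly; at S = 0 the expected magnitude is the
Rayleigh mean σ·√(π/2), which the tests verify.

## Tensor estimation

Taking logs linearises the model in (ln S₀, D): one OLS solve per voxel
against the 7-column design built from the gradient scheme.  Signals ≤ 0 are
clamped to a 10⁻¹⁰ floor before the log; voxels with no positive signal get
zero tensors and are excluded via the fit mask.  OLS (rather than WLS) is
the default because it is the simplest reproducible baseline; the noiseless
round trip is then exact to machine precision (~10⁻¹⁵ relative), and at SNR
30 the median FA error of a repeated-voxel fit is below 0.03.

Eigenvalues are sorted descending; eigenvector sign is fixed by making each
vector's largest-magnitude component positive, so downstream tracking is
deterministic.  Negative eigenvalues (possible under noise) are clamped to 0
before FA; all-zero voxels get FA = 0 by convention, keeping FA ∈ [0, 1]
everywhere without discarding voxels.

**Geometry.** Voxel indices are 0-based; world position of voxel (i, j, k)
is affine·(i, j, k, 1), with the default affine a pure scaling by the voxel
size (voxel centers at i·2.5 mm).  Interpolation of tensors (component-wise)
and scalars is trilinear over the 8 nearest voxel centers; the valid domain
is the convex hull of voxel centers (continuous voxel coordinates in
[0, n−1]), and stepping outside it is a tracking termination event, not an
error.

## Tractography

The propagation rule is pure tensor deflection: v_out = normalize(D·v_in),
sign-aligned to make an acute angle with v_in.  An optional blend weight
w ∈ (0, 1] mixes deflection with straight continuation
(v_out ∝ w·D̂v + (1−w)·v); the default w = 1 is pure TEND, the simplest
reading of the method, with the blend exposed for experimentation only.

Tracking is bidirectional from every seed along ±e₁ of the interpolated seed
tensor, Euler-integrated at a fixed 0.5 mm arc step, the two half-tracks
concatenated with the seed appearing once.  Per candidate step the tensor is
interpolated at the current point, deflected, and the new point accepted only
if (a) it stays inside the hull, (b) its interpolated FA ≥ 0.25, and (c) the
turning angle between successive step directions ≤ 45°; otherwise the end
terminates with the corresponding tagged reason (out-of-bounds / low-FA /
sharp-turn, plus a 2000-step safety cap).  The FA criterion is evaluated on
the interpolated FA map at the candidate point, consistent with per-step FA
sampling; the angle criterion is the per-step turning angle (not an
accumulated per-voxel angle — the most common reading).

Seeds are placed at the centers of all voxels carrying the parcel label, in
lexicographic index order.  `seeds_per_voxel > 1` replicates the center seed:
with a deterministic propagation rule the replicates retrace the same path,
so bundle summaries are exactly invariant to seeding density.  Sub-voxel
jitter was deliberately rejected: on a hard-edged tube phantom, off-center
seeds systematically track through partial-volume FA at the tube boundary
and shift the pooled tract FA by ~0.1 rather than densifying the bundle.

A practical property of TEND worth knowing: with trilinear interpolation the
tensor field changes over a full voxel, so even an 85° orientation change
between abutting regions produces per-step turns below 45° at 2.5 mm voxels
and 0.5 mm steps — the deflection rule rounds corners rather than stopping
at them.  The sharp-turn criterion therefore fires on orientation changes
that are abrupt at the *step* scale (verified on a fine-voxel junction
field, where a 60° junction turns ~54° in one step) and on noisy data, not
at smooth macroscopic crossings.

**Tract FA.** The tract summary is the mean FA over all stepping points of
all fibers pooled ("pooled points"), weighting each 0.5 mm sample equally —
consistent with per-point FA sampling along fibers; mean-of-fiber-means is
available as an option.  Empty bundles yield a missing value (logged), not
an error, and missing cells are handled by listwise deletion within each
tract's model downstream.

## Cohort generator

Three groups (HC, MDD, BD) of n = 30 by default.  Per-tract FA per subject
is Normal(baseline + group offset, SD), baseline 0.45 and SD 0.03, with the
default effect a −0.05 FA offset in the bilateral body of the corpus
callosum in BD.  Covariate distributions follow the study's printed
three-group table: age ≈ 52 ± 14 per group, gender ≈ 40–50% male, illness
duration 8.6 ± 9.8 (MDD) / 19.7 ± 14.3 (BD) years, depressive episodes
3.2 ± 4.2 / 8.9 ± 7.8, both clipped at 0 and identically 0 for HC (the
zero-fill convention for variables undefined in healthy controls).
Cognition scores are Normal per group (e.g. RVP A′ 0.92/0.88/0.93 ± ~0.05).

**Correlation injection.** For one designated (group, tract, score) triple
(default: BD, left body of corpus callosum, RVP A′, r = 0.387) the score is
generated as μ_s + r·(σ_s/σ_FA)·(FA − μ_FA) + ε with
ε ~ N(0, σ_s²(1−r²)), which fixes the population correlation at exactly r
while preserving the score's mean and SD.  |r| ≥ 1 is rejected.  At
n = 10,000 the sample correlation lands within ±0.01 of the target.

**What the generator does not emulate.** Spatial covariance between tracts
(tract FA values are independent given group), non-Gaussian FA
distributions, scanner/site effects, motion or eddy-current artifacts,
registration error, and any real correlation structure among covariates
(duration and episodes are drawn independently).  Passing tests therefore
validate the estimators and the pipeline plumbing under the stated
conditions, not robustness to those real-data complications.

## Group statistics

Per tract: a linear model outcome ~ 1 + I(MDD) + I(BD) + age + gender +
duration + episodes (HC the reference level, gender a single 0/1 dummy),
fitted by least squares; the group effect is the partial F comparing the
full model to the covariates-only reduction, with the exact F(2, n−7)
reference.  When no tract has missing cells the family shares one design
matrix and all outcomes are solved in a single batched lstsq — numerically
identical to per-tract fits (asserted in tests, and cross-checked against
statsmodels).  Sums of squares below 10⁻¹² of the outcome's scale are
treated as zero so a constant outcome gives F = 0 rather than 0/0.

The 54-test family threshold defaults to the literal p < .001 ("paper
mode", the rounded 0.05/54); exact mode uses α/n.  Post hoc pairwise
contrasts (MDD−HC, BD−HC, MDD−BD) come from the same full model's
coefficient covariance, each two-sided p multiplied by 3 and capped at 1
(Bonferroni).  Pearson correlations use the t-transform p with n−2 df.
Summary-statistic tests (one-way ANOVA from group means/SDs/ns, pooled or
Welch two-sample t, Pearson χ² without continuity correction) allow the
demographic table to be checked from printed values alone; with equal group
sizes pooled and Welch t coincide, so pooled is the default.

## Calibration results and a known power limitation

Under the generator's null (no group effects) the family analysis flags
~0.08% of 54 tracts × 500 replicate cohorts at the .001 threshold,
consistent with the nominal rate.  With the planted −0.05 FA deficit
(SD 0.03, n = 30/group) the affected tract is flagged in ~85–92% of 200
replicates depending on the Monte-Carlo seed (true rate ≈ 0.885 over 1000
replicates), and among flagged replicates the post hoc contrasts isolate the
affected group ~95% of the time.

The power sits below what the raw effect size (d ≈ 1.67) would suggest —
an unadjusted one-way ANOVA detects the same deficit in 99.9% of
replicates — because the covariates are strongly group-dependent by design:
illness duration and episode counts are zero for every control and differ
between the patient groups, so adjusting for them absorbs part of the group
effect.  This is a genuine property of the zero-fill ANCOVA design, not a
defect of the estimator, and it is reported as measured.

## Problem sizes

The shipped validation uses a 20³-voxel round-trip phantom, tracking
phantoms of ~40×40×8 voxels (hundreds of streamlines, ~10⁵ stepping
points), 500 null and 200 power replicate cohorts of 90 subjects × 54
tracts, and n = 10,000 per group for the correlation check — sizes at which
every Monte-Carlo bound above is stable to a few percent while the whole
suite runs in minutes on one CPU.
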