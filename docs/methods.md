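# Methods

This note documents the models, numerical choices, and synthetic-data
design behind `ficmap`, and what the test suite does and does not
establish about behavior on real data.

## Diffusion models

**NODDI.** Three compartments on the normalized signal
S/S₀ = (1−v_iso)(v_ic·A_ic + (1−v_ic)·A_ec) + v_iso·e^(−b·d_iso):

- *Intra-neurite*: sticks (zero perpendicular diffusivity) dispersed by
  a Watson distribution with concentration κ about a mean orientation μ.
- *Extra-neurite*: a zeppelin with the same Watson dispersion and a
  tortuosity coupling d⊥ = d∥(1−v_ic). The coupling follows the
  standard NODDI formulation; it is an assumption, not a fit.
- *Free water*: isotropic with d_iso fixed at 3.0×10⁻³ mm²/s (CSF at
  body temperature). d∥ is fixed at 1.1×10⁻³ mm²/s, an optimized
  gray-matter value; both are exposed as CLI overrides (`--dpar`,
  `--diso`).

Watson-compartment signals are evaluated by numerical quadrature over
the sphere in the frame where μ is the pole: 48-node Gauss–Legendre in
cos θ on [0, 1] × 48 midpoint nodes in φ on [0, π], exploiting the even
symmetry of both the Watson weight and the squared gradient projection.
The Watson exponent is max-subtracted for numerical stability, and for
κ > 10³ (beyond quadrature resolution, ODI < 0.0006) the undispersed
stick/zeppelin limit is used. The quadrature agrees with closed-form
limits (pure free water, undispersed stick, κ-independence of the
spherical mean) to better than 10⁻³.

**Fitting (SMT-accelerated).** Stage 1 fits (v_ic, v_iso) to the
per-shell spherical means, which are analytic (error-function
expressions) and independent of κ and μ. Stage 2 refits
(v_ic, v_iso, ODI, μ) on the full signal by bounded trust-region least
squares (max 200 iterations, tolerance 10⁻⁸), initialized from stage 1
and a log-linear DTI principal direction. Dispersion is parameterized
as ODI ∈ [0.01, 0.99] rather than κ for better conditioning. Which
parameters the original SMT acceleration holds fixed in its second
stage is not fully specified in the literature we follow; refitting all
of them from the SMT initialization is this package's choice and is
validated by round-trip recovery (noiseless error < 0.001 per parameter
across a 5×5×3 grid; the 0.02 acceptance margin is generous).
Voxels whose shell means show almost no attenuation (minimum > 0.95)
are flagged (code 2): dispersion is unidentifiable without attenuation.
Non-finite or zero-b0 voxels are flagged (code 1) and skipped.

**Free-water DTI.** Weighted linear least squares on the log signal
initializes the tensor; bounded nonlinear least squares then fits the
six tensor elements plus f ∈ [0, 1]. Tissue diagonal elements are
bounded at 2.5×10⁻³ mm²/s — below d_iso — because an isotropic tissue
tensor at d_iso is exactly degenerate with the free-water compartment;
brain tissue diffusivities sit well under this bound. f is initialized
at 0.8 when the WLLS mean diffusivity exceeds 2.0×10⁻³ mm²/s (the voxel
is probably mostly CSF), else 0.05. Voxels fitted with f ≥ 0.95 carry
an "unreliable tensor" flag. Negative eigenvalues are clamped to zero
before FA/MD for noise robustness; FA of an all-zero tensor is defined
as 0.

## Cortical sampling

Depth sampling is linear in Euclidean space along each vertex's
white→pial segment (no streamline or equivolumetric trajectories),
with n = 15 points including both endpoints, so a sample sits exactly
at the mid-thickness. Weights are Gaussian in normalized depth with σ
solved from w(0.5) = 1 and w(0) = w(1) = 0.05; endpoints are included
because the boundary weight makes their influence ≤ 1% either way, and
including them keeps the two calibration points exact. Outliers are
detected once (no iteration) using the *unweighted* mean/SD of the
finite samples (|z| > 3 removed), then the mean/SD are recomputed with
the depth weights over the survivors; detection on the unweighted
statistics is simpler and stable, and the weights enter only as ratios
(the result is invariant to rescaling all weights).

"Tricubic" interpolation is the order-3 B-spline kernel of
`scipy.ndimage.map_coordinates`; it reproduces linear fields exactly
away from boundaries. The spline prefilter runs with mirror boundary
conditions — the constant-padded prefilter smears edge values several
voxels inward — while evaluation uses NaN constant padding so
out-of-field samples return the missing sentinel. Volumes containing
NaN voxels (e.g. outside a fit mask) are zero-filled before filtering
and any sample whose trilinear support touches a missing voxel is
re-flagged NaN, because the IIR prefilter would otherwise propagate
NaN globally. Vertices with no finite samples are flagged missing, not
zero. Atlas resampling is barycentric over per-atlas-vertex triplets;
weights from missing corners are renormalized over the finite ones, and
a vertex goes missing only when all three corners are missing.

## Morphometry

Vertex area is the equal-thirds split of mid-thickness triangle areas
(mid-thickness rather than white or pial because it matches the
sampling scheme's center of mass), so vertex areas sum *exactly* to
total mid-surface area. Thickness is the corresponding-vertex
distance. Ribbon volume decomposes each white/pial triangle prism into
three tetrahedra along a fixed diagonal rule (w₀w₁w₂p₂, w₀w₁p₂p₁,
w₀p₁p₂p₀), signed volumes summed; a global sign flip normalizes mesh
orientation and residual negative prisms (self-intersection) are
clamped to zero and counted. On a level-4 icosphere pair the totals
agree with 4πr² and (4/3)π(R³−r³) to 0.12% and 0.22% respectively —
the residual is the geometric deficit of the polyhedral approximation,
not numerical error.

## Parcellation

Laplacian smoothing is v ← v + λ(neighbor mean − v), λ = 0.3, 2
iterations, edge-neighbor averages excluding missing vertices (a
contraction: the output range is inside the input range). Thresholding
is strict (<) for ODI, strict (>) for FA, intersected with the
restriction mask. The mode filter is one synchronous pass over closed
neighborhoods (vertex + edge neighbors) with ties keeping the current
label; the number of iterations and neighborhood definition were open
choices, fixed here for determinism. Because a majority vote at the
mask border can annex vertices outside the restriction, the chain
re-intersects with the restriction afterwards, preserving the
mask ⊆ restriction invariant. Largest-component ties break by summed
vertex area, then by lowest minimum vertex index — ties genuinely occur
on symmetric synthetic meshes. Mean parcel thickness is area-weighted;
percent metrics divide by whole-cortex totals. The packaged
anterior-insula restriction (`data/insula_restriction_ico4_synthetic.csv`)
is a synthetic stand-in — a 0.55-radian cap on the level-4 icosphere
atlas topology — since the reference mask is manually drawn on a
population-average surface; real studies should supply their own
vertex-index list.

## Threshold optimization

The sweep evaluates 41 thresholds (0 to 1, step 0.025), runs the full
parcellation chain per subject per threshold, and minimizes the
absolute adjusted Fisher–Pearson skewness of the cohort FI-volume
distribution (sample-size–corrected; ties resolve to the lower
threshold; thresholds where volumes are constant — all parcels empty or
all saturated — have undefined skewness and are excluded).

## Synthetic data design

The phantom is a pair of concentric icospheres (white 30 mm, pial
33 mm, level 4 → 2562 vertices) with a planted angular cap of low ODI
(0.28 vs 0.52 background) and high FA (0.25 vs 0.12) in the ribbon;
those levels straddle the working thresholds (ODI 0.375, FA 0.180) the
way FI straddles them in cortex. Noise is additive Gaussian
(high-SNR regime, keeps every oracle analytic; a Rician option exists
for the DWI generator). Ground-truth patch membership is defined on
vertices by the angular distance of the mid-thickness point, matching
how parcellation is scored.

The threshold-sweep cohort plants a *known* skewness optimum: each
subject's patch takes the uniform value 0.4 + δᵢ (δ ~ N(0, 0.05)) plus
per-vertex noise (SD 0.03), background 0.6, with the restriction mask
eroded to 0.65 rad inside the 0.9 rad patch so smoothing cannot bleed
background values into it. At threshold t each subject's parcel is
then nearly all-or-nothing in δᵢ, so the cohort volume distribution is
a two-point mixture whose skewness decreases monotonically through
zero exactly where half the offsets are crossed, i.e. at t = 0.4;
fully saturated thresholds give exactly constant volumes and drop out
as undefined. Two rejected designs are worth recording: a logistic
volume-vs-threshold profile left a quantized near-saturation band
where the volume distribution could be accidentally symmetric, and a
non-saturating cubic profile produced skewness amplitudes below the
sample-skewness noise floor at n = 40. The mixture design has no such
competing minima; 40/40 generator seeds recover the optimum within one
grid increment.

The ACE cohort draws A + C + E with variance fractions summing to 1:
MZ pairs share A and C, DZ pairs share half of A and all of C, and
non-twin siblings share genetics like DZ but are labelled `NT`
(cohort analyses treat them as a separate empirical group). Observed
values add measurement noise; the retest table is an independent noisy
draw of the same latent trait. The behavioral column has a planted
standardized slope against the latent trait.

## Cohort statistics

The ICC formula's σ_between and σ_within are interpreted as the
between- and within-subject *mean squares* of a one-way decomposition:
with k = 2 sessions, (MS_b − MS_w)/(MS_b + MS_w) is then algebraically
identical to the classical one-way ICC(1) = (MS_b − MS_w)/(MS_b +
(k−1)MS_w), which the tests verify to 10⁻¹⁰ against an independent
implementation. The variance-components reading of the same symbols
would not have this property. CoV is the within-subject SD over the
mean. Sibling correlations are double-entry intraclass correlations
(each pair entered in both orders), so they are invariant to within-pair
ordering; sibships larger than two contribute all unordered pairs,
matched on both parent IDs. Falconer's H²_b = 2(r_MZ − r_DZ) cancels
shared-environment variance under ACE assumptions.

Regression standardizes continuous variables to zero mean and unit
variance (the predictor's coefficient is then a standardized β; with a
single predictor it equals the Pearson correlation, verified to 10⁻¹⁰),
codes two-level categoricals 0/1, and excludes outliers by Tukey fences
(1.5 IQR beyond the quartiles, linear-interpolation quantiles,
computed on the full cohort per variable before fitting). A stepwise
covariate search was replaced by a fixed covariate set for determinism.
ΔBIC = BIC(without predictor) − BIC(with), BIC = n·ln(RSS/n) + k·ln(n);
positive values favor keeping the predictor. Designs with condition
number above 10¹⁰ are rejected. FDR correction is Benjamini–Hochberg
step-up (verified to equal the brute-force max-k definition on random
instances). Left–right contrasts use a paired t-test, group contrasts
Welch's t by default; a covariate-adjusted regression route is also
available since the original analysis is ambiguous between the two.

## Problem sizes and determinism

Default test and acceptance runs use level-4 icosphere phantoms
(2562 vertices, 72³ voxel grids), a 3-shell × 24-direction protocol
with 6 b0 volumes, 75-voxel NODDI and 9-voxel FW-DTI round-trip grids,
40-subject sweep cohorts, and 2000+2000-pair twin cohorts — sizes at
which every recovery criterion has comfortable Monte-Carlo margin while
a full suite run stays under a minute. All randomness flows through
explicit integer seeds (`numpy.random.default_rng`); identical
seeds give bitwise-identical phantoms, cohorts, and pipeline outputs.

## What passing tests do and do not show

The synthetic phantoms have spherical geometry, piecewise-constant
parameters, Gaussian noise, and perfect surface placement. Passing
recovery tests therefore demonstrates correctness of the estimators,
the sampling geometry, and the statistical machinery — not robustness
to gyrified anatomy, surface misplacement, susceptibility distortion,
Rician bias at low SNR, or partial-volume profiles other than the
boundary effects the depth weighting is designed for. Cohort-level
reliability and heritability of *real* FI metrics depend on scanner and
population factors the ACE generator does not model. The package also
does not perform surface reconstruction, spherical registration, or
transform estimation; correspondence and alignment are inputs.
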