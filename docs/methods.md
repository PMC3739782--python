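# Methods

This note documents the models, numerical choices and limitations behind
`taphomorph`, in the spirit of a statistics package's methods appendix.

## Superimposition

GPA removes position, scale and orientation.  Each configuration is
centered, scaled to unit centroid size (`CS = sqrt(Σ ||x_i − x̄||²)`), and
iteratively rotated onto the running consensus; the consensus is the
arithmetic mean of aligned shapes, renormalized to unit size each
iteration.  Convergence: consensus movement < 1e−10 (root summed square)
or 200 iterations (then the partial result is returned flagged
`converged=False`).  The rotation subproblem is solved by SVD of the 3×3
cross-covariance with a determinant correction so that only proper
rotations (det +1) are used.  This is deliberate: mirror reflection would
superimpose a left-crushed skull onto a right-crushed one and destroy
exactly the asymmetry signal the analysis is about.  Full Procrustes
scaling refinements (rescaling each specimen by the cosine of its
Procrustes distance) are not applied; unit-size ("partial Procrustes")
scaling keeps centroid sizes interpretable for the allometry tests.

The iteration is initialized from the first specimen, which fixes the
solution only up to a global rotation; the final frame is therefore
canonicalized to the principal axes of the consensus with deterministic
signs (largest-magnitude coordinate along each axis positive, third axis
the cross product).  This makes GPA output a function of the shapes alone,
invariant (< 1e−8) to how the input coordinates happened to be oriented,
scaled or translated.

Aligned shapes lie on a unit sphere in 3K dimensions; PCA assumes a flat
space.  By default each shape is orthogonally projected onto the tangent
hyperplane at the consensus (`x ← x − (x·ĉ − |c|) ĉ`).  The projection is
idempotent and moves a shape at Procrustes distance ρ from the consensus
by O(ρ²) — for the shape variation typical of a single-species cohort
(ρ ≤ 0.2) the effect is small, but the switch is exposed
(`tangent=False`) and recorded in the run log.

## Ordination and intervals

PCA is computed by SVD of the centered n×3K data matrix; eigenvalues are
the sample (n−1) variances of the score columns.  Superimposition removes
7 degrees of freedom in 3D (3 translation, 3 rotation, 1 scale), so at
most `min(n−1, 3K−7)` eigenvalues are non-null; eigenvalues below 1e−12
of the largest (or below 1e−24 absolutely, squared machine precision for
unit-size shapes) are treated as exactly zero.  Loading signs are fixed by
making each loading's largest-magnitude element positive; all reported
statistics are sign-invariant.

Component selection offers the broken-stick rule — retain PCs 1..k while
each *strictly* exceeds its threshold `b_k = (1/p) Σ_{i=k..p} 1/i`,
stopping at the first failure — and a `fixed_k` override for analyses
that retain axes by interpretability (deformation axes can be
interpretable well past the broken-stick cutoff, since single recurrent
crushing styles may carry modest variance).

Confidence bands are per-axis intervals `x̄ ± 1.96σ` with the sample
(n−1) SD.  Because score columns are centered with variance equal to the
eigenvalue, the half-width is identically `1.96·sqrt(λ_k)`; this identity
is used when only a printed variance table is available and is verified
in the test suite.  Per-axis bands (whose 2D products are rectangles, or
circles when drawn with equal radii) are the default; a Mahalanobis
covariance ellipse for any score plane is provided as an alternative.
Outlier flagging is strict (`score < lower` or `score > upper`), per PC
independently; with Gaussian scores about 5% of specimens are flagged per
axis by construction, which calibrates the interpretation of flags in
small samples.

## Error protocol and allometry

The replicate-digitization protocol projects R repeat digitizations of one
specimen into the morphospace fitted to the main sample (centered on the
main-sample mean, rotated by its loadings) rather than including them in
the PCA, so the main model is unchanged by the error assessment; a joint
38-observation PCA variant is available by simply concatenating the
configurations before fitting.  Distances are Euclidean norms over the
first P PCs (default 4) to the replicate mean; `overlap` is true when the
farthest replicate reaches at least as far as the nearest other specimen.

Spearman's r_s uses midranks for ties.  Two-sided p-values are exact
(full enumeration of the n! rank permutations, chunked to bound memory)
for n ≤ 10 and use the t approximation with n−2 degrees of freedom above
that; under an independence null at n = 28 the test rejects at
5.0–5.4% for α = 0.05 over 10,000 simulations (the t approximation is
mildly anti-conservative at this n, which is acceptable for the
screening use here).  Sensitivity analyses re-run the full chain
(re-superimposition, re-PCA, re-testing) on the reduced specimen list;
dropping a specimen changes the consensus and hence every aligned shape,
so projecting old scores would be wrong.

## The simulator

The synthetic cohort generator emulates a single-species skull sample
deformed post-burial.  A bilaterally symmetric template places the 56
scheme landmarks (naris/orbit/temporal-fenestra rings, jugal horns at
maximal width, midline points at y = 0) parametrically; paired landmarks
mirror exactly through the sagittal plane.

Template default proportions are 220 (length) × 100 (width) × 150
(height).  These are deliberately anisotropic: the shape-space directions
of dorsoventral and mediolateral compression overlap with cosine
`−sqrt(ab/((1−a)(1−b)))` where a and b are the template's z- and
y-variance fractions, so a near-isotropic template makes the two
compression styles nearly collinear in shape space and *no* ordination
method could attribute variance to one or the other.  Distinct axis
spreads (x > z > y) keep the canonical deformation modes mutually
identifiable, which is the property the simulator exists to validate;
consequences for real, more isotropic skulls are discussed under
Limitations.

Deformation operators (composable, left-to-right):

* `dorsoventral_compression` — z scaled toward the mid-height plane by
  c ∈ (0,1], uniformly or grading in caudally from a hinge (smoothstep
  over a `falloff` fraction of skull length);
* `mediolateral_compression` — y scaled by c toward the sagittal plane;
* `unilateral_crush` — y scaled by c on one side only, graded by a
  smoothstep in |y| so the midline stays fixed and the field is
  continuous;
* `caudal_rotation` — landmarks caudal to the hinge rigidly rotated by θ
  about the mediolateral axis through the hinge at mid-height; rostral
  landmarks are returned bit-identical;
* `allometric_juvenile` — isotropic scale s < 1 about the centroid plus a
  shape offset (orbit rings expanded radially, rostral quarter shifted
  caudally) of default magnitude 0.06·(1−s)·length, i.e. juveniles occupy
  a displaced but nearby region of shape space rather than a separate
  cluster.

Identity magnitudes (c = 1, θ = 0, s = 1) short-circuit to bit-identical
output.

Cohorts draw deformations per specimen.  Default composition is
`independent`: each mode is applied with its configured probability
(dorsoventral 0.60 — compaction under vertical lithostatic load affects
most flat-buried skulls; mediolateral 0.25; one-sided crushing 0.10 per
side; caudal rotation 0.20), so specimens can combine modes or escape
deformation entirely, as real material does.  An `exclusive` mode (one
draw per specimen from normalized weights) emulates a cohort of cleanly
distinct burial styles; note that under exclusive composition PCA axes
are between-style contrasts, not individual mode directions.  Magnitudes
are uniform on per-mode ranges (compression 0.6–1.0 / 0.7–1.0 / 0.6–0.95;
rotation 0–0.35 rad).  Noise is isotropic Gaussian per landmark:
individual variation (default SD 1.5 length units ≈ 0.7% of skull length)
then digitizing noise (default SD 0.5 units, stylus-scale); heteroscedastic
digitizing error is not modeled.  All randomness flows from one integer
seed; truth (modes, magnitudes, age class, seed) is recorded in specimen
metadata and a JSON sidecar.

Recovery is scored by building each mode's shape-space direction — the
Procrustes-aligned, tangent-consistent difference between the template
deformed at a reference magnitude and the undeformed template, normalized
— and reporting |cosine| against each retained PC loading.  The direction
is insensitive to the reference magnitude (the operators are nearly
linear in shape space over their ranges).  Under the two-compression
validation design (n = 28, magnitude ranges above, digitizing noise with
total perturbation norm 0.5% of centroid size) PC1/PC2 recover the two
generating directions at |cosine| > 0.9 in ≥ 18 of 20 seeds.

## Problem sizes

The test suite and the acceptance script run the full chain on simulated
cohorts of 28–30 specimens × 56 landmarks (the study-scale design),
10,000-replicate calibrations of the outlier and Spearman nulls, and
20-seed recovery batteries; the complete suite executes in well under a
minute on one core.

## What the synthetic validation does and does not show

Passing tests show the pipeline's algebra is correct (against independent
grid-search and Jacobi oracles), its statistics are calibrated, and that
when deformation styles are geometrically identifiable the morphospace
axes recover them.  They do not show that real psittacosaur skulls meet
the identifiability conditions: real skulls are closer to isotropic than
the validation template, so real PC axes are expected to *mix*
compression styles (a dorsoventrally-flattened-plus-left-crushed axis,
say) — consistent with empirical axes that blend flattening with
asymmetric crushing.  The simulator also idealizes deformation as smooth
coordinate scalings and rigid rotations; plastic flow, shear and breakage
are not modeled (broken landmarks are represented only as missing data).

## Other limitations

* No missing-landmark estimation: specimens missing retained landmarks
  are dropped (trading landmarks for specimens is governed by the scheme's
  exclusion flags, decided by the analyst, not imputed around).
* The exact permutation Spearman p is enumerated only to n = 10 (10! ≈
  3.6M correlations); beyond that the t approximation is used.
* Confidence bands treat PCs independently; simultaneous coverage over
  four axes is below 95% (≈ 0.95⁴ ≈ 81%), matching standard per-axis
  practice in morphometrics rather than a familywise guarantee.
* Retrodeformation is out of scope by design.
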