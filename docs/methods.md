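# Methods

This note records the models the package implements, the conventions
chosen where the underlying methods leave room, the defaults and why,
what the synthetic data does and does not emulate, and known
limitations. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Optical density (`ihcnorm.od`)

Beer–Lambert: `OD_c = -log(I_c / I0_c)` per channel, `I0 = 255` for
8-bit images. Zero-intensity pixels are floored at 1 before the log,
bounding OD at `log 255 ≈ 5.54` — the 8-bit dynamic range; the inverse
transform `I = I0 · exp(-OD)` is clipped to `[0, 255]`. All arithmetic is
double precision; images may enter as `uint8` but OD is always float.
No illuminant estimation is attempted: `I0` is a constant, configurable
per channel.

## STRESS contrast stretching (`ihcnorm.stress`)

For each pixel p0, a spray of M samples is drawn uniformly over the
*area* of a disk of radius R (radius `R·sqrt(u)`, angle uniform;
equivalently rejection from the bounding square, which is what the
compiled kernel does). Samples falling outside the image, or on the
center itself, are redrawn a bounded number of times and then clamped to
the border. Over N sprays the sample range `r_i = s_max − s_min` and the
relative value `v_i = (p0 − s_min)/r_i` are averaged; the envelopes are
`E_min = p0 − v̄·r̄`, `E_max = E_min + r̄`, and the stretched value
`(p0 − E_min)/(E_max − E_min)` algebraically reduces to `v̄`.

Conventions:

- `v_i = 1/2` when a spray has zero range, and the output is 0.5 when
  `r̄ = 0` (the constant-neighborhood limit of the same rule);
- `v_i` is clipped to `[0, 1]`, which guarantees `E_min ≤ p0 ≤ E_max`
  even though the center is excluded from its own spray;
- each color channel is processed independently with its own RNG stream
  derived from the master seed, so runs are bitwise reproducible.

Defaults: `R = max(H, W)` (sprays can reach the whole image — a global
illumination reading), `M = 30`, `N = 100`. M and N trade noise in the
envelope estimates for time; a larger R needs a larger M for adequate
sampling density. Two consequences worth knowing, both visible in the
test suite's measurement conditions: on images whose background is a
large constant region, sprays that see only background hit the
zero-range rule and pull the background toward mid-gray, so M should be
large enough that most sprays reach stained content; and any local
contrast stretch amplifies low-amplitude background noise. The inner
loop is compiled with numba; the pure-numpy `sample_spray` is the
reference implementation of the sampling law and is statistically tested
against it.

## Stain separation (`ihcnorm.stains`)

**SVD/angle estimator.** Pixels with max-channel OD below β
(default 0.15; `beta=None` disables the filter) are dropped; the rank-2
singular subspace of the remaining OD tuples is computed, with each
direction's sign flipped so the mean projection is non-negative (makes
results backend-independent); pixels are projected onto the plane and
their in-plane angles taken; the stain vectors are the OD-space unit
directions at the 1st and 99th angle percentiles (α = 1 by default),
clipped to non-negative and renormalized. Fewer than 3 surviving pixels
or an effectively rank-1 cloud (second singular value < 1e-6 of the
first) raises an estimation error. The filter matters: unstained pixels
have near-zero OD and therefore *noise-valued* angles; with a clean
white background they dominate the angle distribution and destroy the
percentile extremes if not removed.

**Sparse coding.** Per pixel, `min_{s≥0} ½‖od − Vs‖² + λ‖s‖₁` by cyclic
coordinate descent, vectorized across pixels (each coordinate update is
a closed-form soft-threshold; the problem is convex with strictly convex
coordinates for unit-norm columns). Certified in tests against a brute
force grid search and an independent positive-LASSO solver.

**NMF / sparse NMF.** Alternating minimization: exact sparse coding for
S, then block coordinate descent over dictionary columns with projection
onto the non-negative unit ball, followed by rescaling to exactly unit
column norm with the compensating inverse scaling of the S rows (leaves
`VS` unchanged, can only shrink the ℓ1 term) — so the penalized
objective is non-increasing across outer iterations. `λ = 0` reduces
sparse NMF to plain NMF exactly (same code path). The dictionary is
warm-started from the SVD/angle estimate when it is available (random
data pixels otherwise): the objective is non-convex and the warm start
selects the physically right basin. Defaults: `λ = 0.1`,
`max_iters = 200`, `tol = 1e-6` relative objective change. An optional
helper performs a grid search for λ by reconstruction error; it is off
by default.

**Stain ordering.** Estimated columns carry no labels, so a fixed
convention orders them: each column is assigned to whichever canonical
OD direction (standard brightfield hematoxylin `(0.650, 0.704, 0.286)`
or DAB `(0.269, 0.568, 0.778)`, normalized) it subtends the smaller
angle with; ties fall back to blue-channel OD weight (hematoxylin
absorbs little blue light, DAB much), with a warning.

## Structure-preserving normalization (`ihcnorm.spcn`)

Both images are factorized with sparse NMF and their stains put in
canonical order; each source density row is rescaled by
`RM(S_t)_j / RM(S_s)_j`, where `RM` is the per-row 99% quantile (linear
interpolation between order statistics — quantile dialects differ, so
the convention is fixed here); the output is `OD = V_t S_s_norm`
inverted to RGB. Row scaling cannot change the support or the spatial
rank order of any stain's density — that is the structure-preservation
guarantee, asserted in tests.

One design choice deserves emphasis: the ℓ1 penalty is a *fitting
device* for the basis. Carrying its shrinkage into the reconstruction
biases every stained pixel brighter (the coded densities
underestimate the true ones by roughly `λ/(1+cos θ)` per stain), so the
densities used for quantile matching and reconstruction are re-coded
against the fitted bases by non-negative least squares
(`reconstruction_lambda = 0`, configurable). With that choice,
self-normalization (target = source) reproduces the source up to the
rank-2 model residual. A degenerate source stain row (zero
pseudo-maximum with nonzero mass) raises; an entirely empty row passes
through unscaled with a warning.

## Self-sparse fuzzy clustering (`ihcnorm.rssfca`)

The dissimilarity is the Gaussian negative log-likelihood
`Φ(x|v,Σ) = ½(x−v)ᵀΣ⁻¹(x−v) + (D/2)ln 2π + ½ln|Σ|` (evaluated by
Cholesky). When covariances shrink, `Φ` can go negative; the whole
matrix is then shifted up by its global minimum (a uniform shift leaves
every membership subproblem's minimizer unchanged because memberships
sum to one per pixel). The membership update — not given in closed form
by the original formulation — follows from the KKT conditions of
`min Σ_i (u_i Φ′_i + γ u_i²)` on the simplex: it is the Euclidean
projection of `−Φ′/(2γ)` onto the probability simplex, computed by the
standard O(c log c) sort-and-threshold rule and certified against a
numerical constrained-QP solver. Memberships attain exact zeros
(self-sparsity) whenever a cluster's dissimilarity exceeds the
column's support threshold. Centers are membership-weighted means;
covariances membership-weighted scatter plus a diagonal ridge
(`cov_ridge = 1e-6` — a full identity would swamp covariances of
[0, 1]-scaled RGB features). Initialization is 20 iterations of
standard fuzzy c-means (fuzzifier 2, seeded centers from data points).
Iteration stops when the objective changes by at most η (1e-5) or after
T (100) iterations. Empty clusters are reseeded from random data points
and flagged.

Segmentation runs the fit on [0, 1]-scaled RGB features with c = 2; the
cluster whose center has the highest luminance is background, the rest
nuclei; connected nuclei components smaller than `min_area_fraction`
(1e-4) of the image are returned to background — a deliberately simple
area filter for over-segmentation control. γ defaults to 3.0 on this
feature scale. c is configurable (c = 3 separates blue and brown nuclei
if wanted).

Note on monotonicity: each update (memberships, centers, covariances)
minimizes the objective with the others held fixed, so the objective
sequence is non-increasing *as long as the Φ shift is inactive* (true
whenever `½ln|Σ| + (D/2)ln 2π > 0`, e.g. unit-scale data). When
covariances are tiny the shift re-bases the objective between
iterations and strict monotonicity of the reported sequence is not
guaranteed.

## Quaternion SSIM (`ihcnorm.qssim`)

Each pixel is the pure quaternion `r·i + g·j + b·k` on the [0, 1] scale.
Over every 8 × 8 sliding window (stride 1, uniform weights; a global
mode pools once over the whole image), the score is the modulus of the
product of a luminance term `2 μ_r conj(μ_d) / (|μ_r|² + |μ_d|²)` and a
structural term `2 σ_rd / (σ_r² + σ_d²)`, where `σ_rd` is the
window mean of `(q_r − μ_r)·conj(q_d − μ_d)` (Hamilton product: scalar
part the channel-covariance sum, vector part the negative mean cross
product) and σ² the mean squared modulus of the centered quaternions.
Because the quaternion modulus is multiplicative, the luminance factor
reduces to `2|μ_r||μ_d|/(|μ_r|²+|μ_d|²)`. A stabilizer ε = 1e-12 is
added to numerators *and* denominators — SSIM-style — so two identical
constant windows (including black, where μ = 0) score 1 rather than
0/0. Cauchy–Schwarz bounds the structural factor by 1, so the score
lies in [0, 1] with 1 iff the images agree.

Limitation, measured in development and worth knowing before using the
metric for chroma fidelity: since the luminance factor sees only |μ|
and the cross-covariance stays large whenever the color channels are
mutually correlated (as they strongly are in two-stain histology), the
windowed score is weakly sensitive — in the extreme, blind — to global
channel permutations of channel-correlated imagery. It remains sharply
sensitive to structural degradation (noise, scrambling, blur).

## Nuclei classification (`ihcnorm.cnacd`)

The stain basis is estimated automatically (SVD/angle method with the
default β = 0.15 filter — see the filtering remark above; the
no-filtering sentinel is available but degenerates on clean-background
images), the whole image is sparse-coded against it with λ₁ = 0.1, each
stain's rank-1 OD contribution `V(:,j) S(j,:)` is inverted to RGB and
reduced to grayscale with fixed luma weights (0.299, 0.587, 0.114), and
an annotated pixel is labeled immunonegative when the positive-stain
plane is strictly lighter there than the negative-stain plane, else
immunopositive (ties → positive). Classification is single-pixel by
design; nuclei whose center pixel is atypical of the nucleus (e.g.
brown nuclei with blue patches) need neighborhood evidence and are out
of scope. Accuracy is `(TP+TN)/(TP+FN+TN+FP)` with `+` the positive
class.

## Pipeline (`ihcnorm.pipeline`)

STRESS both images → SPCN on the stretched pair → RSSFCA segmentation
of the *stretched source* → merge (nuclei from SPCN, background from
STRESS). The merge rule is isolated in one three-line operation so it
can be swapped. Stage seeds derive from the master seed by fixed
offsets, making each stage individually reproducible. Stage failures
are re-raised with the stage name attached. Only the source is
segmented; the target's segmentation plays no role.

## Synthetic scenes (`ihcnorm.synth`)

Scenes are rendered through the same forward model the analysis
inverts: non-overlapping disk nuclei (rejection-sampled), each purely
hematoxylin or purely DAB by default, with a cosine radial density
profile falling from a peak drawn from `density_range = (0.8, 1.2)` to
`rim_fraction = 0.3` of the peak at the rim — nuclei have a visible
boundary; a profile fading to zero would make rim pixels
indistinguishable from background at 8-bit quantization and no
segmenter could match the geometric mask. The background is unstained
(pure white); optional uniform haze and cross-stain density are
available but default to zero. Gaussian OD noise (σ = 0.01 by default;
0.02 in the harder classification checks) is added before rendering
through the inverse Beer–Lambert transform and `uint8` quantization.
Default geometry: 256 × 256 with 12 nuclei of radius 8–16, half
immunopositive.

What passing on these scenes does **not** show about clinical images:
no chromatin texture, no overlapping or touching nuclei, no stroma or
cytoplasmic staining, no JPEG artifacts, no illumination gradients, and
stain vectors that match the canonical directions exactly. The scenes
exercise the algebra and the estimators under controlled, favorable
conditions; clinical performance claims need clinical data.

## Problem sizes and numerical choices

The heavier checks run at deliberately modest sizes chosen to exercise
the full code path: 256 × 256 scenes for stain recovery and
classification, 128 × 128 pairs for the end-to-end pipeline, n = 2000
for the clustering oracle. Tolerances appearing in tests: 1e-6 against
the membership QP oracle, 1e-8 for objective monotonicity, 1° / 5°
for noiseless / noisy stain recovery, two intensity levels for
self-normalization, 1e-9 for QSSIM self-similarity. Degenerate inputs
(constant images, single pixels, empty stain rows, rank-1 OD clouds)
are handled explicitly and tested.
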