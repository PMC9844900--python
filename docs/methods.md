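# Methods

## Model

The classifier turns an `n`-class problem over a semimetrizable feature
space into a regression problem onto a geometrically structured latent
space.  `Z = R^(n-1)` is partitioned into cone segments `C_1 … C_n` defined
by the vertices `p_1 … p_n` of a regular `(n-1)`-simplex with barycenter 0
and unit circumradius: `C_k` is the set of nonnegative combinations of the
mirrored vertices `{−p_i : i ≠ k}`.  The segments cover `Z` and overlap only
on their boundaries, and membership reduces to a distance rule: `z ∈ C_k`
iff `‖z − p_k‖ ≤ ‖z − p_l‖` for all `l`.  Because all vertices are unit
vectors this is equivalent to `z·p_k ≥ z·p_l`, which is how the package
evaluates it — the inner-product form makes the smallest-index tie-break
exact in floating point (at `z = 0` every dot product is exactly zero).

Vertices are built deterministically from the Helmert orthonormal basis of
the sum-zero hyperplane of `R^n`, scaled to unit norm, with a global sign
chosen so that for `n = 2` the first (sorted) class owns the negative
half-line.  Any orthogonal image of the vertex set defines the same
classifier, since every decision depends only on distances; the constructed
set satisfies `Σ p_i = 0`, `‖p_i‖ = 1` and `p_i·p_j = −1/(n−1)` to 1e−10.

**Training transform.**  Each training point is mapped into its class's
open cone by

    f(x) = α A(x) p_{y(x)} + Σ_{y≠y(x)} β R(x,y) (−p_y),

with attraction `A(x)` the reciprocal mean distance to the `k_α` nearest
own-class neighbors and repulsion `R(x,y)` the mean distance to the `k_β`
nearest class-`y` neighbors.  Validity requires `α + β > 0`, `k_α ≤ c − 1`,
`k_β ≤ c` with `c` the smallest class size; under these bounds and distinct
intra-class points all coefficients are positive and finite and every
target is strictly interior to its cone.  Neighbor ties are resolved by
(distance, index) order, which cannot change the mean.  Intra-class
duplicate points make the attraction infinite and raise an error when
`α > 0`; duplicates across classes only produce a boundary target and are
surfaced as a warning.  A convenience parameterization `γ = β = 1 − α`
reduces the two weights to one dial: `γ = 1` is pure repulsion, `γ = 0`
pure attraction.

**Regression backend.**  A single Gaussian-process regressor with a shared
kernel across the `n−1` outputs is fitted to `(x_i, f(x_i))`.  The
predictive distribution is modeled as an isotropic normal
`N(f̂(x), σ(x)² I)`; nothing in the construction introduces
inter-dimension covariance, and the shared kernel makes the per-dimension
standard deviations identical.  Any object with `fit` / `predict_mean` /
`predict_gaussian` is accepted as a backend, so density regressors such as
mean-variance neural networks can be plugged in without changes.

**Prediction.**  Labels come from the distance rule applied to `f̂(x)`.
Class probabilities are the cone masses of `q̂(·|x)`:

* `n = 2`: closed form.  The segments are the half-lines around 0, so the
  positive-side class has probability `Φ(μ/σ)`.
* `n > 2`: Monte-Carlo integration with `mc_samples` draws (default 10⁴)
  from `q̂`, classified by the same distance rule (boundary draws follow the
  min-index rule); the returned vector of empirical frequencies sums to one
  by construction and is deterministic given `mc_seed`.  One standard-normal
  block is shared across query points, so per-point scores are
  `μ·p_k + σ (e·p_k)`; with 10⁴ draws the per-point standard error is at
  most 0.005.

**Compression map.**  For visualisation, `C(z) = z / (1 + m(z))` with
`m(z) = (n−1) max_k (−z·p_k)` maps `Z` bijectively onto the open simplex
interior (`m(w) < 1` is exactly the facet description of the interior), with
inverse `w ↦ w / (1 − m(w))`.  Because it rescales by a positive scalar it
preserves segment membership exactly.  The map is continuous but only
piecewise-smooth across cone boundaries; the classifier itself never uses
it.

## Default parameters

| parameter | default | meaning |
|---|---|---|
| `α`, `β` | 0, 1 | attraction/repulsion weights (unitless); `γ = β = 1−α` |
| `k_α`, `k_β` | 1, 1 | neighbor counts of the mean-distance coefficients |
| semimetric | euclidean | also built in: taxicab; arbitrary callables accepted |
| kernel | `C(1, [1e−3,1e3]) · Matérn(ν=2.5, ℓ=1, [1e−2,1e2]) + White(1e−3, [1e−6,1e1])` | backend covariance |
| `n_restarts` | 2 | marginal-likelihood optimizer restarts |
| `mc_samples` | 10⁴ | Monte-Carlo draws per query for `n > 2` |

The signal-variance prefactor on the Matérn term matters: with a fixed unit
amplitude the marginal-likelihood optimization degenerates on
attraction-weighted transforms (whose targets vary over an order of
magnitude), collapsing the length scale and absorbing everything into
noise, which dilutes the predicted probabilities toward uniform.  The
optimizer restarts guard against the same local optimum on individual
tasks.  Features are standardized to training mean and standard deviation
before both the transform and the regression; zero-variance features are
centered only.

## Synthetic data

`make_quadrant_task` emulates the study conditions of the synthetic
benchmark: a 4-class problem on `[−1, 1]²` whose noise-free label is the
quadrant of the point (boundaries assigned by the `≥ 0` convention), with
`D = 40` uniform training and `T = 10000` uniform test points per task.
`make_ternary_toy` gives a 9-point, 3-class banded problem for transform and
visualisation tests.  These generators produce noise-free labels, uniform
sampling and low feature dimension; passing tests on them demonstrates the
geometry, the probability machinery and the benchmark pipeline, not
robustness to label noise, class imbalance or high-dimensional features.

## Benchmark harness

`run_synthetic_benchmark` runs 10 independent tasks.  Per task the
transform hyperparameters are tuned by stratified 5-fold cross-validation
over the grid `γ ∈ {0, 0.25, 0.5, 0.75, 1}`, `k_α ∈ {1,2,3}`,
`k_β ∈ {1,2,3,5}` (entries intersected with the per-fold neighbor bounds;
entries whose weight is zero for a neighbor count are collapsed, ties keep
the smaller entry).  The selection criterion is the cross-validated
*proba-loss* `δp = 1 − mean p̂(true class)` — the calibration quantity the
method is designed to minimize.  Selecting on cross-validated log-loss is
available (`cv_scoring="log_loss"`) but systematically prefers smoother,
under-confident transforms: log-loss punishes a handful of confidently
wrong points (clipped at the 1e−15 floor) so harshly that it vetoes sharp
transforms whose mean predicted probability error is 3–4× better.  The
comparator is scikit-learn's one-vs-rest Gaussian-process classifier with
the same kernel family and standardization, its hyperparameters tuned by
its internal marginal-likelihood optimization.

Scores: accuracy, log-loss (probability floor 1e−15), and proba-loss.  For
binary problems the calibration curve uses ten equal-width bins on [0, 1]
(last bin right-closed); empty bins carry no curve point, and the
area-deviation is the trapezoidal integral of |curve − diagonal| over the
occupied-bin mean-predicted abscissa — with a single occupied bin the area
is zero by convention.

Problem sizes used by the test suite and the acceptance script: the full
10-task benchmark at `D = 40`, `T = 10000` with the default grid (about
20 s per task), plus seconds-scale geometry and probability checks.

## Known limitations

* Training cost is quadratic in `D` (pairwise distances; dense matrix up to
  4000 points, row-wise beyond) — the intended regime is small training
  sets.
* The compression map is not differentiable across cone boundaries.
* Monte-Carlo probabilities cannot resolve masses below `1/mc_samples`;
  log-loss on confidently wrong points therefore saturates at the clipping
  floor.
* The Gaussian-process backend requires numeric features; non-numeric
  feature spaces need a custom backend plus a custom semimetric.
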