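# Methods

## Model and procedure

For each target `y` (one column of the d×t matrix `Y`) we consider the
linear model `y = Xβ + ε` with design `X` (d×p). The ordinary
least-squares estimate minimizes squared error; where `X` is rank
deficient the Moore-Penrose pseudoinverse solution is used in its place.
Ridge regression adds a penalty `α` on the squared L2-norm of `β`,

    β̂ᴿᴿ = (XᵀX + αI)⁻¹ Xᵀy.

Writing the SVD `X = U S Vᵀ` with singular values λ₁ ≥ … ≥ λ_r > 0 and
rotating (ỹ = Uᵀy, β̃ = Vᵀβ), ridge becomes per-component scalar
shrinkage of the rotated OLS solution:

    β̃ᴼᴸˢᵢ = ỹᵢ/λᵢ,   β̃ᴿᴿᵢ = λᵢ²/(λᵢ² + α) · β̃ᴼᴸˢᵢ.

Components carried by larger singular values are shrunk less. Because `V`
is orthonormal, L2-norms agree between rotated and original spaces, so the
fraction

    γ(α) = ‖β̃ᴿᴿ‖₂ / ‖β̃ᴼᴸˢ‖₂

computed in the rotated space is exactly the fraction of the returned
coefficients. The solver:

1. decomposes `X` once (singular values below `tol·λ₁` are treated as
   zero, `tol = max(d,p)·ε` by default — the standard pseudoinverse
   convention);
2. rotates all targets with one matrix product and solves OLS with one
   broadcast division;
3. builds a log-spaced candidate α grid on `[10⁻³λ_r², 10³λ₁²]`
   (0.2 log₁₀ spacing), whose endpoints are snapped *outward* onto the
   spacing lattice so the grid depends only on the singular-value range;
4. tabulates the shrinkage factors λᵢ²/(λᵢ²+αⱼ) once as an outer
   operation;
5. per target, evaluates γ at every grid α, interpolates to find the α
   achieving each requested γ, and scales the rotated OLS solution;
6. back-rotates all solutions with a single multiplication by `V`.

When d > p the singular values may be taken as square roots of the
eigenvalues of the p×p matrix `XᵀX` (the default for d > p; also available
explicitly via `method="gram"`). Working on the squared scale halves the
attainable precision: eigenvalues below `max(d,p)·ε` times the largest are
indistinguishable from zero and are truncated on that scale, so the Gram
route cannot resolve condition numbers beyond ~√(1/ε). The direct SVD
route remains available where that matters.

## Interpolation

The grid gives pairs (αⱼ, γⱼ) with γ strictly decreasing in α. We
interpolate **log₁₀(α) piecewise-linearly as a function of γ** and
exponentiate. γ varies smoothly and near-linearly in log α across the
shrinkage transition, which is what makes the coarse 0.2-log₁₀ grid
sufficient: across the simulated scenarios the achieved fractions deviate
from the requested ones by well under 1% (the acceptance script measures
≈0.25–0.27%). The alternatives (interpolating α directly against γ, or
numerically inverting γ(log α)) are either less accurate at this grid
spacing or more expensive; this choice is validated by the fraction-accuracy
tests rather than assumed.

Degenerate and boundary cases:

- requested γ=1 bypasses interpolation (α ≔ 0, exact OLS/pseudoinverse);
- requested γ=0 bypasses interpolation (β ≔ 0, α recorded as +∞ and
  serialized as the string `inf`);
- a requested γ above the largest grid-achieved γ (possible because the
  grid's minimum α is positive) is linearly extrapolated in the
  γ–log₁₀(α) plane; exponentiation keeps α non-negative;
- a target whose OLS solution is exactly zero has γ undefined (0/0); it
  receives zero coefficients at every fraction with NaN recorded for α and
  the achieved fraction;
- exact floating-point ties in the γ curve (it can saturate to 1.0 at the
  small-α end of the grid on ill-conditioned designs) are collapsed before
  interpolation, keeping the smallest α; a genuine *increase* along the
  grid raises an internal-consistency error.

Requested fraction lists are deduplicated and sorted internally; outputs
follow the caller's original order.

## Closed-form identities (`theory`)

For a flat spectrum (all λᵢ = λ), γ = λ²/(λ² + α), inverted by
α = λ²(1/γ − 1). These are used only as independent oracles for the
interpolation machinery, never as a fast path. The effective degrees of
freedom Σᵢ λᵢ²/(λᵢ² + α) decrease strictly from the rank r (α=0) toward 0;
under the equal-magnitude-coefficient assumption the rotated-space L1-norm
shrinkage equals this sum divided by p. The L1 identity holds in the
rotated space only; no original-space L1 claim is made.

## Estimator layer (`model`)

`FractionalRidge` standardizes predictors optionally ("center" removes
per-predictor means, "zscore" also scales to unit SD; a zero-variance
predictor with scaling on is an error naming the column). When centering
is on, targets are centered too and the training target mean is re-added
at prediction time — this plays the role of an intercept while keeping γ
defined purely on the predictor coefficients; no explicit intercept column
is added. Cross-validated selection (`cv_select`) uses a single
train/test split (test fraction configurable, default 50/50) with the
permutation drawn from a caller-supplied seed and recorded in the result;
per target the fraction maximizing held-out R² is selected, exact ties
breaking toward the smallest (most regularized) fraction. Aggregation
over multiple splits is deliberately left to the caller — reasonable
practices differ (adopt the split's fraction, refit on all data, or
average over n folds) and the package does not pick one.

R² is computed as 1 − SS_res/SS_tot (it may be negative; zero-variance
observations raise an error) and is cross-checked against
scikit-learn's implementation in the test suite.

## Synthetic scenarios (`simulation`)

The generator emulates many-target encoding-model regression:

- **Design**: d×p iid standard-normal entries; then `2p` times (default),
  two distinct predictors are drawn at random and the first is replaced by
  their sum plus fresh standard-normal noise, inducing realistic
  collinearity; finally each column is z-scored. z-scoring uses the
  population SD (divide by n) so the unit-SD invariant is exact and
  deterministic; the constant factor relative to sample SD is absorbed by
  the regularization scale.
- **Targets**: β ~ Normal(0, 1) per entry (`beta_sd` configurable),
  `Y = Xβ + ε` with iid Gaussian noise. The default noise level is
  `"match-signal"`: each target's noise SD equals the population SD of its
  noiseless signal, i.e., a signal-to-noise ratio of 1 — a deliberately
  hard, realistic regime in which regularization genuinely helps.
- All randomness flows from the scenario's single seed through named
  splittable streams (design and targets draw from independent child
  generators), so every artifact is reproducible bit for bit.

The reference scenarios are d=100 with p=5 (tall) and p=100 (square). Two
standard-ridge baselines solve the same problems on the heuristic α grid
{0} ∪ {10⁻⁴ … 10⁵·⁵, 0.5 log₁₀ steps} (21 levels): a naive per-α
pseudo-inversion, and a rotation-based solver reusing one SVD. They are
mutual cross-checks; `compare_frr_srr` fits FRR and SRR on the same
half-split problem and tabulates train/test R², fractional norm, and
effective DOF per level. What these simulations do **not** emulate:
structured (e.g., temporally autocorrelated) noise, heavy-tailed
responses, or feature matrices derived from real stimuli — passing tests
show the solver achieves its contract on Gaussian problems with induced
collinearity, not that regularized encoding models are well specified for
any particular dataset.

## Numerical choices

- Truncation: `tol = max(d,p)·ε` relative to λ₁ (Gram route: the same
  relative cutoff applied to eigenvalues, see above).
- Grid endpoints snapped outward to the 0.2 log₁₀ lattice →
  deterministic grids; at the grid minimum every shrinkage factor is ≥
  1/(1+10⁻³), at the maximum ≤ 10⁻³.
- `α=0` in the direct-inversion oracle on a rank-deficient design falls
  back to the pseudoinverse (with a logged warning).
- File output uses 17 significant digits, so write→read round-trips
  float64 exactly and repeated runs with one seed are byte-identical.

## Problem sizes

Tests and the acceptance script use the reference scenario sizes (d=100,
p ∈ {5, 100}, 10 targets, 10 seeds) and small random problems
(d ∈ {10, 50}, p ∈ {3, 10, 60}); the whole suite runs in a few seconds on
one CPU. Larger problems are limited only by the SVD (O(dp·min(d,p))) and
memory for the p×f×t coefficient array.

## Known limitations

- The α grid is itself a heuristic; only the interpolated fractions are
  validated (~1% accuracy). Requested fractions extremely close to (but
  not exactly) 1 rely on extrapolation beyond the grid.
- The method is specific to the L2 penalty; L1 (lasso) and elastic-net
  penalties change the computational structure entirely and are out of
  scope, as are generalized cross-validation and non-negativity
  constraints.
- If there is a reason to hold one α fixed across targets or models, the
  per-target α selection that FRR performs is not appropriate.
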