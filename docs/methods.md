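# Methods

## Model and estimator

`sgpath` fits the penalized linear model

    min_{b,u} (1/2n)||y − Xb − Zu||₂² + αλ Σ_j ω_j^F |u_j|
              + (1−α)λ Σ_l ω_l^G ||u^(l)||₂

over a decreasing penalty grid. `b` (the unpenalized block) absorbs
effects that must stay in the model — an intercept is simply a
ones-column in `X`; when `X` is absent the term `Xb` is identically zero.
The p penalized features are partitioned into L non-overlapping groups.
The convex mix `α` interpolates between the lasso (`α = 1`, sparsity per
feature) and the group lasso (`α = 0`, sparsity per group); intermediate
values yield solutions sparse both across and within groups.

Group weights are derived from the feature weights as
`ω_l^G = sqrt(p_l · mean_{j in l} ω_j^F)`, so with unit feature weights
the group penalty carries the familiar `sqrt(p_l)` size adjustment.
Feature weights let one express several published lasso variants without
new code: constant per-modality weights with `α = 1` give the IPF-lasso
(the per-modality penalty is proportional to `λ · factor_m`; formulations
that scale the least-squares term by 2n absorb that factor into their λ —
here the scale stays on the grid and only the ratios matter), and
`2·sqrt(MAF(1−MAF))` weights give the allele-frequency-adaptive lasso
used in genome-wide association settings.

No implicit standardization: `X`, `Z` and `y` are used as given, and
estimates are on the input scale. Users who want correlation-scale
penalties should standardize before calling the solver.

## Optimization

Each grid point is solved by plain (non-accelerated) proximal gradient
descent. The smooth part `f(b,u) = (1/2n)||y − Xb − Zu||²` has gradient
`(−X'r/n, −Z'r/n)` with `r` the residual. One iteration maps
`(b, u) → (b − t∇_b f, prox_{tP}(u − t∇_u f))` where `P` is the penalty
on `u`; `b` is unpenalized so its prox is the identity.

**Proximal map.** For the sum of a weighted ℓ1 and a weighted group-ℓ2
penalty on the same block, the proximal operator is exactly the
composition: soft-threshold every coordinate at `t·αλ·ω_j^F`, then apply
block shrinkage `v → max(0, 1 − τ/||v||)·v` at `τ = t·(1−α)λ·ω_l^G` per
group. Both stages produce exact zeros, so reported non-zero counts need
no thresholding epsilon. The test suite pins this map against a
brute-force minimizer of the prox objective (exhaustive support
enumeration, valid for the small p used in tests).

**Line search.** The step `t` is accepted when the quadratic majorization
`f(x⁺) ≤ f(x) + ∇f(x)'(x⁺−x) + ||x⁺−x||²/(2t)` holds (with a ~1e−15
absolute slack so exact fixed points do not shrink the step through
rounding); otherwise `t ← shrink·t`. Defaults `step0 = 1`, `shrink = 0.5`.
A step below 1e−30 raises a line-search error — in practice unreachable
for finite inputs. The accepted step carries over to the next λ of the
path, since the Lipschitz constant of `∇f` does not change along the
grid; the step policy affects iteration counts only, never the converged
solutions beyond tolerance.

**Stopping.** After each iteration the solver checks
`||(b,u)^[k] − (b,u)^[k−1]||_∞ / ||(b,u)^[k]||₂ ≤ eps_rel` on the
concatenated coefficient vector. At least one iteration is always
performed; if the current iterate is exactly zero the criterion counts as
met only when the update was exactly zero too. Hitting `max_iter` flags
`converged = False` in the diagnostics instead of raising. The
diagnostics also carry an independent optimality certificate: the maximal
violation of the stationarity conditions (exact gradient on `b`; for `u`,
subgradient conditions — for a zero group, the distance of the group
gradient from the Minkowski sum of the weighted ℓ∞ ball and the group ℓ2
ball, which is `max(0, ||ST(c, αλω^F)|| − (1−α)λω^G)`).

## Penalty grid

`λ_max` is the smallest penalty at which `u = 0` (together with the
least-squares `b` on `X` alone — minimum-norm if `X` is rank-deficient)
is optimal. With `g^(l) = Z^(l)'r₀/n`: the closed forms
`max_j |g_j|/ω_j^F` (α = 1) and `max_l ||g^(l)||/ω_l^G` (α = 0) follow
directly from the subgradient conditions; for mixed α the per-group
critical value solves `||ST(g^(l), αλω^F)||₂ = (1−α)λω_l^G`, whose left
side minus right side is strictly decreasing in λ, by bisection
(bracket [0, max_j |g_j|/(αω_j^F)], relative tolerance 1e−10). If
`Z'r₀ = 0` no finite `λ_max` exists and a degenerate-problem error is
raised. The grid is `λ_k = λ_max · ξ^{k/(K−1)}`, i.e. log-equispaced down
to `ξλ_max`; `K = 1` returns only `λ_max`. Solves proceed in decreasing
order with warm starts. Defaults `α = 0.95`, `K = 50`, `ξ = 0.001`,
`eps_rel = 1e−4`, `max_iter = 1000` mirror common practice for this
solver family; tighter `eps_rel` (1e−6…1e−8) trades time for accuracy.

## Synthetic data generator

`generate_problem` emulates the solver's target regime: grouped,
correlated predictors with group-sparse truth. Rows of `Z` are zero-mean
Gaussian with correlation `ρ` within groups (one shared factor per group)
and zero across groups; `u_true` holds ±`effect_size` on a few active
groups; `y = Xb_true + Zu_true + N(0, noise_sd²)`. Defaults — n = 100,
10 groups of 6 (p = 60), 2 active groups, effect 1, ρ = 0.3, noise 1,
intercept — give a clearly detectable but noisy signal and are the
conditions of the reference study in `scripts/acceptance.py` and the
recovery tests. Passing an existing truth re-draws only design and noise,
which is how holdout sets are made.

What the generator does **not** emulate: marginal distributions of real
molecular data (e.g. bounded methylation beta values), heavy tails,
long-range correlation, missingness, or n in the hundreds of thousands of
features. Passing tests therefore certify the optimization and selection
machinery, not field performance on any particular assay.

Holdout evaluation (`evaluate_path`) follows the standard protocol:
prediction MSE per grid point on an independent sample, minimizer (first
index on ties), squared Pearson correlation and exact non-zero count at
that point.

## Numerical choices and limitations

- Tie-breaks: group shrinkage returns exactly zero when
  `||v|| ≤ τ` (boundary inclusive), which makes `λ_max` an exact
  zero-solution boundary; `-0.0` outputs are normalized to `+0.0`.
- The solver is plain PGD by design; momentum/FISTA acceleration,
  generalized linear models (logistic, Cox), overlapping groups,
  cross-validation and sparse-matrix designs are out of scope.
- Warm starts change iteration counts, not solutions: warm and cold paths
  agree to 1e−5 relative objective in the acceptance suite.
- Problem sizes in tests (n ≤ 100, p ≤ 60) keep the full suite under a
  minute while exercising every code path; the solver itself is dense
  numpy and scales to the 1e4–1e6 feature range memory permitting.
- Validation is strict: dimension mismatches, non-finite entries and
  non-positive weights raise distinct named errors; group labels may be
  arbitrary and are relabelled to contiguous codes in first-appearance
  order, with original labels preserved in all outputs.
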