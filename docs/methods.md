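# Methods

## Model

For patient n = 1..N observed on days t = 1..T_n with R variables,

    y_nt = Σ_{i=1..p} A_ni y_{n,t−i} + ε_nt,    ε_nt ~ MVN(0, Λ⁻¹),

with a single innovation precision Λ shared across patients. Writing
w_n = vec([A_n1 … A_np]) (column-major within each lag block, blocks in lag
order; all code shares this convention through `var_core.coef_to_matrices`),
the coefficients decompose into a population part and a patient deviation,
w_n = w + v_n.

**Population prior (doubly adaptive elastic net).** w ~ MVN(0, D⁻¹) with
D = diag(λ2_k + 1/(2τ²_k)). Each latent scale 2τ²_k is exponential with rate
λ1²_k / (2ξ²_k), where ξ²_k is the conditional variance of coordinate k
given its trailing coordinates under the covariance I_{Rp} ⊗ Λ⁻¹. Because
that covariance is block diagonal, ξ²_k depends only on the position
j = ((k−1) mod R) + 1 inside its block and equals the (j, j) entry of the
inverse of the leading j×j block of Λ (`hier_gibbs.compute_xi2`).
Marginally each w_k mixes a Gaussian (ridge) and a Laplace (lasso) factor
with coefficient-specific weights λ1_k, λ2_k, so posterior modes are sparse
and the shrinkage is adaptive per coefficient. Conditioning the latent-scale
rate on Λ keeps each w_k's conditional posterior unimodal.

**Hierarchy and hyperpriors.** v_n ~ MVN(0, Θ_v⁻¹) with Θ_v =
diag(θ_v1..θ_vk). Gamma hyperpriors are parameterized by (mean m, degrees of
freedom d), i.e. shape d/2 and rate d/(2m); pass `gamma_mean_dof=False` for
direct shape/rate. Defaults (weakly informative, nearly flat):

| parameter | prior | default (m, d) |
|---|---|---|
| λ1²_k | Gamma | (1, 0.001) |
| λ2_k  | Gamma | (1, 0.01) |
| θ_vk  | Gamma | (1, 0.01) |
| Λ     | Wishart(K, ν), prior mean νK | K = (R−1)I_R, ν = 1 |
| α_k   | Normal(0, c) | c = 100 |

The Gamma prior sits on λ1² (not λ1); `l1_prior_on_square=False` switches to
a prior on λ1 itself, at the cost of a non-conjugate (slice-sampled) update.
The ν = 1 Wishart prior is singular for R > 1; it is never sampled from —
only the conjugate-form posterior, whose degrees of freedom exceed R, is.

## Gibbs sampler with parameter expansion

Deviations and their precisions are strongly coupled a posteriori (small
θ draws force small v draws and vice versa), so the sampler augments the
model with a multiplicative expansion vector α ~ MVN(0, c·I): the likelihood
uses w + α∘v_n, and the identified deviation is v*_n = α∘v_n. α, v and θ_v
are individually non-identified; all reported quantities use v*, w_n =
w + v*_n, and the identified deviation precision θ_vk/α_k² (stored as
`theta_v`; the raw draw is kept as `theta_raw`).

One sweep updates, in fixed order:

1. **w** — conjugate MVN: precision Σ_n (H_n H_nᵀ) ⊗ Λ + D.
2. **v_n** (each) — conjugate MVN with α absorbed into the regressors.
3. **α** — conjugate MVN with v_n absorbed into the regressors.
4. **Λ** — the latent-scale priors depend on Λ through ξ²_k, so the exact
   conditional is Wishart × Π_k (1/ξ²_k) exp(−λ1²_k τ²_k / ξ²_k). The
   determinant part telescopes exactly to det(Λ)^{Rp} and the j = 1 terms
   are linear in Λ₁₁; both fold into a Wishart proposal (dof ν + Σ(T_n−p) +
   2Rp, inverse scale K⁻¹ + residual scatter + 2q₁ e₁e₁ᵀ). The remaining
   j ≥ 2 terms enter an independence-Metropolis accept ratio. For R = 1 the
   ratio is identically 1 (exact Gibbs); for the diary-sized fits the
   proposal is dominated by the likelihood and acceptance is high.
5. **2τ²_k** — exact density ∝ u^{−1/2}(1+λ2_k u)^{1/2}
   exp(−w_k²/(2u) − λ1²_k u/(2ξ²_k)); the √(1+λ2u) factor (absent from the
   pure-lasso case, where 1/u would be inverse-Gaussian) makes it non-named,
   so it is slice-sampled in log space.
6. **λ1²_k** — conjugate Gamma(a₁+1, b₁ + τ²_k/ξ²_k).
7. **λ2_k** — non-conjugate (a √(λ2 + 1/u) factor from the w_k prior
   normalizer); slice-sampled in log space.
8. **θ_vk** — conjugate Gamma(a₃ + N/2, b₃ + ½Σ_n v²_nk).

Every conditional is validated against an oracle before use in the sweep
(tests/test_gibbs_conditionals.py): conjugate updates against their closed
forms, slice updates against normalized 1-D numeric integration of
prior × likelihood, via KS tests at the 0.1% level on 10⁴ draws; and the
whole sampler against a brute-force (w × Λ) grid posterior on the scalar
model, with the deviation and expansion factor collapsed by quadrature
(tests/test_gibbs.py), agreeing within 5% in mean and SD (measured ~1%).
A prior-only sweep (no data) leaves the joint prior invariant; in particular
the Λ marginal stays Wishart, which pins down the (scale, dof) convention
empirically rather than by assumption.

**Numerics.** Conditional precision matrices are symmetrized and, on
Cholesky failure, jittered by an escalating multiple of 1e−10·mean(diag)
(counted in `ModelState.jitter_events`). Slice-sampled positive scalars are
confined to [1e−300, 1e300]: under the nearly flat default hyperpriors their
conditionals can spread over hundreds of log-decades, and the bound only
trims float-overflow territory. Initialization: coefficients at 0, α at 1,
Λ at the diagonally loaded pooled sample precision, positive scalars drawn
from their priors (clipped to [1e−6, 1e6]); deterministic given the seed.
Chains get independent streams spawned from the master seed.

**Sampler configuration.** Stored draws per chain = (iterations − warmup) /
thin. The study configuration is 4 chains × 10,000 iterations, first half
warmup; with thin = 20 that stores 250 draws/chain (the published 500/chain
corresponds to thin = 10 over the retained half — both readings are
reachable through the config). Tests and the acceptance script use
scaled-down runs (e.g. 4 × 2,000, thin 4); on study-shaped panels the
maximum Gelman–Rubin over identified parameters is ≈ 1.02 already at that
size. R-hat is the classic between/within-chain formulation without chain
splitting; α and the raw (v, θ) are excluded from convergence summaries
because they are non-identified by design.

## Preprocessing

Per patient and variable, in order: fill day-index gaps as missing rows;
impute (``flank_mean``: a missing run gets the mean of its two flanking
observations, boundary runs copy the single nearest one; or
``moving_average``: centered window mean, window widened at boundaries,
default window 4); log(x + offset) (offset 0 for positive scales, +1 for
counts including 0, e.g. cigarettes); standardize to sample mean 0 and
variance 1 (denominator T−1); detrend by OLS on (1, day), keeping residuals.
The order standardize-then-detrend follows the order the steps are listed in
the study; the applied steps are recorded in `panel.provenance`. Constant
series cannot be standardized and raise (mirroring the exclusion of
no-variance diaries). Multiple same-day records are collapsed to their mean
over non-missing entries first when requested.

## Forecasting and evaluation

For each stored draw: build A_n from w + v*_n, draw one MVN(0, Λ̂⁻¹)
innovation per step, iterate the recursion for h = 1..H feeding forecasts
back as lags. Points are predictive means (the MSE-optimal summary — modes
are used for parameter reports, means for forecasts); intervals are the
2.5/97.5 predictive percentiles. Evaluation on a positional holdout (last
1 day, or last 10 days for longer diaries): MSE per variable and overall,
95% coverage over (patient, horizon, variable) cells, and the fraction of
intervals narrower than a comparator's. The split is applied after
preprocessing, matching the original protocol; the standardization and
detrending constants therefore see the held-out day — a small leakage the
comparison inherits deliberately, since all three models share it.

Baselines: per-patient MLE VAR (equation-wise least squares, no intercept on
the centered/detrended scale; residual covariance with divisor T−p; Gaussian
plug-in intervals from the h-step error covariance Σ_{j<h} Φ_j Σ̂ Φ_jᵀ,
ignoring parameter uncertainty — the original interval construction was not
reported, so the plug-in choice is labelled) and per-patient elastic net
(mixing weight 0.5, i.e. penalty λ(0.5‖β‖₁ + 0.25‖β‖₂²) in the
scikit-learn convention, intercept unpenalized; 50-point geometric penalty
path; seeded 3-fold CV with the one-standard-error rule — the strongest
penalty within one SE of the minimum CV MSE; residual-bootstrap percentile
intervals, B = 500 by default).

## Synthetic data

`sample_truth` draws a sparse population vector (nonzeros uniform on
±[0.1, 0.6]), Gaussian deviations with per-coefficient SDs, and redraws any
configuration whose companion spectral radius reaches 1 (up to 100
attempts). `simulate_panel` iterates the VAR from zero lags, discards a
200-step burn-in (cheaper than sampling the stationary law directly and
indistinguishable after burn-in), then adds optional linear day trends and
completely-at-random missingness. `application1_like_panel` bundles the
study-shaped defaults: N = 25, R = 3, p = 1, lengths 10–33 days averaging
≈ 26, ~2% missing cells, Λ = I, and gender/age labels yielding the 8/8/9
young-female / young-male / old-male split.

What the generator emulates: the hierarchical VAR's dependence structure,
short unbalanced series, modest missingness, demographic grouping. What it
does not: raw bounded ordinal scales (data are generated on the
post-transformation scale, so synthetic pipelines skip the log step),
informative missingness, measurement error, non-Gaussian innovations.
Passing the synthetic suites therefore demonstrates correct inference under
the model's own assumptions — identifiability, calibration, the pooling
advantage on short series — not robustness to misspecification.

## Problem sizes used in tests and the acceptance script

Scaled to single-core runtimes: conditional oracles use the scalar model
with 10⁴ draws; the grid oracle a 201×201 (w, Λ) grid and 4 × 4,000
iterations; recovery suites 10 panels at N = 25, T = 25 (plus 3 at T = 100)
with 2 × 1,600 iterations; the pooling property 50 panels at N = 12, T = 12
with 2 × 800; the acceptance script one study-shaped panel with 4 × 2,000
(and 2 × 1,500 at p = 2 for order selection).

## Known limitations

- A single Λ for all patients (per the model); patient-specific innovation
  precisions are out of scope.
- Missing data are imputed before fitting, not within the sampler.
- The empirical-density mode estimator (KDE argmax restricted to the draws,
  Silverman bandwidth, ties toward the smaller magnitude) is deliberately
  crude; its argmax has Monte-Carlo spread ≈ 0.2·SD at 10⁴ draws of a flat-
  topped posterior.
- The elastic-net CV baseline inherits fold randomness; results are
  seed-reproducible but fold-sensitive on very short series.
- h-step forecasting is recursive only; no direct multi-horizon fits, and no
  proper scoring rules (CRPS, log score).
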