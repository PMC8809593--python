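# Methods

## Problem and model

`croptail` estimates the probability that an annual crop-yield loss is
extreme given that a weather variable is extreme — a conditional tail
probability, not a mean effect. The analysis is strictly bivariate: a
response X₁ (reflected yield, so large values are large losses) and one
conditioning weather variable X₂ (growing-season precipitation, possibly
reflected to target droughts, or mean daily minimum/maximum temperature).

### Data rules

Raw panels are annual country-level records (nominally 1961–2002, so at most
42 observations per country). A (country, year) row is dropped if any of the
four variables is missing. Because 42 observations are far too few for tail
estimation, countries are pooled into six larger geographical regions (the
packaged `data/regions.csv` maps countries to regions; it is user-editable).
Before pooling, each variable is standardized within country — subtract the
country mean, divide by the country standard deviation (ddof = 1), both
computed over that country's complete-case years — so that one country's
scale does not swamp another's extremes. Standardization after omission is
deliberate: omission changes the per-country moments. A `min_years` filter
(default 0, i.e. off) can exclude countries with very short post-omission
series.

### Semi-parametric marginals

Each margin is modelled empirically below a high threshold u and by a
generalized Pareto distribution (GPD) above it:

    F(x) = F̃(x),                                           x ≤ u
    F(x) = 1 − (1 − F̃(u)) · (1 + ξ (x−u)/β)₊^(−1/ξ),       x > u

The empirical part F̃ uses plotting positions i/(n+1) with linear
interpolation between order statistics, which keeps F strictly inside (0,1)
on the observed range, continuous at the splice, and invertible. The
threshold defaults to the 80th percentile of each variable; mean-residual-life
curves and PP/QQ-style diagnostics are emitted as tables so the choice can be
audited, but no automatic selector is applied. GPD parameters are estimated
by maximum likelihood (Nelder–Mead on (log β, ξ), moment-based start plus
random perturbations, best of the starts kept), with observed-information
standard errors; |ξ| < 1e−4 switches to the exponential-limit formulas to
avoid cancellation.

Margins are then mapped to the standard Laplace scale,

    Y = log(2 F(X))       if F(X) < 1/2,
    Y = −log(2 (1−F(X)))  if F(X) ≥ 1/2,

giving unit-exponential tails on both sides. CDF values within 1/(2n) of 0
or 1 are clamped (with a warning) so the transform stays finite.

### Conditional dependence model

On Laplace margins, for conditioning values y above a high threshold,

    Y_resp | Y_cond = y  =  a·y + y^b · Z,    a ∈ [−1, 1], b < 1,

with Z independent of Y_cond in the limit. a > 0 / a < 0 encode positive /
negative extremal dependence; (a, b) = (1, 0) is perfect dependence, (0, 0)
independence; a Gaussian copula with correlation ρ has limit
(a, b) = (sign(ρ)·ρ², ½). Estimation maximizes the standard working
pseudo-likelihood that treats Z as i.i.d. Gaussian with free location μ and
scale σ; for fixed (a, b) the nuisance pair profiles out in closed form, so
the search is two-dimensional (unconstrained coordinates atanh a and
log(1−b), multi-start Nelder–Mead). The dependence threshold is the
theoretical Laplace quantile of q_dep (default 0.90); threshold-stability
traces with bootstrap bands over candidate quantiles 0.50–0.90 support the
choice, and a rank-correlation diagnostic checks the assumed independence of
Z from the conditioning variable.

Joint constraints keep the fit consistent with the margins: with z⁻, z⁺ the
2.5%/97.5% empirical residual quantiles and v_max the largest conditioning
exceedance, we require for all v ≥ v_max

    a·v + v^b z⁺ ≤ v     and     a·v + v^b z⁻ ≥ −v,

i.e. the fitted conditional quantile band never escapes the envelope implied
by perfect positive (negative) dependence at or beyond the data range.
Because b < 1 both conditions are monotone in v, so they reduce to a
closed-form check at v_max (with the |a| = 1 edges requiring the residual
quantile on that side to have the compatible sign). The predicate is exposed
separately (`constraints_feasible`) and can be disabled for comparison.
Candidates violating it are rejected by penalty during optimization. When
the residual spread is below 1e−6 (perfect dependence) b is unidentified and
flagged as such rather than reported as a bare number.

### Extrapolation and uncertainty

The risk measure is p(q_c) = P(response > its q_r quantile | conditioning >
its q_c quantile), with q_r = 0.90 and q_c running over a grid from 0.91 to
0.9999. Conditioning on the *exceedance event* (not equality) is sampled
directly: on the Laplace scale the excess over the level v(q_c) is unit
exponential, so each pseudo-draw is y_cond = v + Exp(1), z resampled with
replacement from the stored empirical residuals (kernel smoothing is off by
default), and y_resp = â·y_cond + y_cond^b̂·z. The default 1000 pseudo-draws
per grid level give a Monte-Carlo standard error of at most ~0.016.
Exceedance fractions are identical on the Laplace and original scales
because the marginal transform is monotone.

Confidence intervals are percentile bootstrap: observation rows are
resampled in pairs and the *entire* pipeline — both marginals, the
transform, the dependence fit, the simulation — is refit per replicate
(100 replicates, 95% level by default; a flag reuses the point fit's
marginals and refits only the dependence stage). Percentile bounds use the
symmetric order-statistic convention k-th smallest / k-th largest with
k = ⌈α/2·n_boot⌉ — the 3rd and 98th of 100. Replicates that fail to fit are
counted and excluded; more than 50% failures aborts. Seed discipline: one
master seed, with per-fit and per-replicate streams derived through
`numpy.random.SeedSequence`, so any replicate is reproducible in isolation
and whole runs are byte-identical under a fixed seed.

### Summaries

The fragility table reports, per (region, crop, hazard, orientation), the
conditional loss probability at q_c = 0.98 (for low-precipitation hazards
the reflection makes this the 2nd percentile of precipitation); cells whose
95% interval reaches zero are flagged not-shown. The worst-case index
reports, per region, the maximum CI upper bound over all crop × hazard
combinations at q_c = 0.98, with argmax labels; ties break lexicographically
by (crop, variable, orientation).

## Synthetic data and oracles

The generator replaces the study's proprietary yield/weather panel with
draws whose tail dependence is known exactly:

- **gaussian** copula (ρ): asymptotically independent; limit (sign(ρ)ρ², ½).
- **logistic** max-stable copula (α ∈ (0,1]): asymptotically dependent for
  α < 1, limit (1, 0); tail-dependence coefficient χ = 2 − 2^α. Simulated by
  the positive-stable mixture construction.
- **independent**, **perfect**: limits (0,0) and (1,0).
- **ht-exact**: draws from the conditional model itself with chosen (a, b)
  and Gaussian residuals on the positive conditioning half; the response
  margin is only approximately Laplace, which is adequate for
  dependence-stage checks that see high exceedances only.

Copula uniforms are mapped through Student-t (df = 5) margins by default —
heavy enough tails that the GPD stage has signal at a few hundred
observations. Panel fixtures add country-specific offsets/scales (so
standardization is non-trivial), a tmax ≥ tmin gap by construction,
independent filler weather variables, and cell-level missingness. What the
generator does *not* emulate: temporal autocorrelation, trends
(technological progress in yields), spatial correlation between countries,
and crop-calendar aggregation artifacts — so passing tests demonstrate
correctness of the statistical machinery, not robustness to those features
of real panels.

A brute-force oracle computes P(response > q_r | conditioning > q_c) by
direct Monte Carlo from the generative copula (default 10⁷ draws, binomial
standard error reported); for the Gaussian family the tests additionally
cross-check the oracle against the closed-form bivariate-normal rectangle
probability.

## Numerical choices and problem sizes

- Empirical quantiles use numpy's default linear interpolation everywhere.
- GPD and dependence optimizations use Nelder–Mead (xatol 1e−6/1e−7) with
  multi-start; the dependence working likelihood floors σ² at 1e−20 so
  perfect dependence degenerates gracefully.
- Self-checks and test problem sizes are chosen for desk-scale runs: GPD
  recovery at 5000 exceedances, dependence recovery at 50000 pairs, oracle
  comparisons at 10⁷ draws, and interval-coverage studies over 200 worlds of
  1200 pairs with 50 bootstrap replicates each.

## Known limitations

- **b under sub-asymptotic dependence.** For Gaussian-copula data the
  conditional location on Laplace margins contains an O(log y) drift beside
  the leading ρ²y term. The working model absorbs it into μ·y^b, which
  pulls b̂ below its limit ½ at practical thresholds: at the 0.90 conditioning
  quantile the pseudo-true value is ≈ 0.36 regardless of sample size, and
  n = 50000 fits centre near 0.30. Estimates of a and of extrapolated
  probabilities are much less affected (the oracle-agreement checks pass),
  but b̂ should be read as threshold-dependent, not as an estimate of the
  limit exponent.
- **Small-panel shrinkage.** At realistic pooled-panel sizes (~600 rows,
  ~60 dependence exceedances) the joint constraints bind often and shrink â
  toward zero; point estimates of extrapolated probabilities are then biased
  slightly low and percentile intervals can undercover on the low side
  (measured ≈ 0.80 at n ≈ 630 versus 0.90 at n = 1200 for nominal 0.95).
  The interval-coverage self-check is therefore run at n = 1200, where the
  estimator is near-unbiased and the interval procedure itself is what is
  being tested; treat real-panel intervals as approximate.
- The logistic (asymptotically dependent) family is used for χ-level checks;
  at finite thresholds the constrained fit caps â below 1 there, as expected
  from the envelope constraints with finite v_max.
- Bootstrap refits inherit the point fit's threshold choices; threshold
  uncertainty is not propagated.
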