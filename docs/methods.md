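# Methods

## Problem and model

Screening questionnaires for common mental disorders (alcohol use,
depression, anxiety) produce ordinal item responses whose raw sum or mean
scores are hard to compare across instruments and heavily skewed in
general-population samples.  normforge implements the standard norming
workflow for such screeners:

1. fit a unidimensional **graded response model** (GRM) per scale,
2. score every achievable raw score with the **EAP-per-sum-score**
   estimator,
3. convert raw scores to **normalized T-scores** and closed-form
   conversion equations,
4. bin raw scores into **seven percentile norm levels**, and
5. audit the scale with Mokken scalability, monotonicity, Yen's Q3,
   S-χ² item fit and ordinal-logistic-regression DIF.

### Graded response model

For item *i* with K ordered categories, discrimination `a_i > 0` and
strictly increasing thresholds `b_i1 < … < b_i,K-1`:

    P(X_i >= k | θ) = logistic(a_i (θ − b_ik)),     k = 1 … K−1

and category probabilities are adjacent differences of these curves.  No
1.7 scaling constant is applied; parameters are on the logistic metric.
Calibration is marginal maximum likelihood via EM: the E-step computes each
person's posterior weights on a fixed quadrature grid (default 61 equally
spaced nodes on [−6, 6] with renormalized standard-normal density weights —
the prior identifies the latent scale); the M-step maximizes each item's
expected complete-data log-likelihood by quasi-Newton steps on
`(log a, b_1, log threshold gaps)`, which enforces positivity and threshold
order by construction.  Convergence: largest absolute parameter change
< 1e−4, cap 500 cycles (both configurable); the marginal log-likelihood is
monotone over cycles and asserted so in tests.  Persons with any missing
item are excluded from calibration and scoring of that scale (complete
case); a prorated-score option exists for presentation but never feeds the
IRT machinery.

### Summed-score scoring and crosswalks

`P(sum = s | θ)` is built by the Lord–Wingersky recursion (one item at a
time; each grid column sums to 1 at machine precision).  The EAP trait for
a raw score s is the posterior mean over the grid; it is strictly
increasing in s.

The T-score is *normalized* (rank-based), not linear in theta:

    percentile(s) = (count below s + count at s / 2) / n
    T(s) = 50 + 10 Φ⁻¹(percentile(s))

A linear alternative `T = 50 + 10·standardized θ̂` is available via
`build_crosswalk(..., t_metric="linear")`; the normalized form is the
default because it reproduces the characteristic crosswalk shape of
zero-inflated screeners (e.g. 34% of the sample at the minimum score gives
T(min) = 50 + 10 Φ⁻¹(0.17) ≈ 40.5).  Raw scores unobserved in the norming
sample get T by monotone interpolation on the theta scale between flanking
observed scores (linear extrapolation in theta beyond the extremes), so the
T column is strictly increasing over the whole table.  Subgroup crosswalks
(gender, age bands) reuse the pooled item parameters and recompute only the
score frequencies; re-calibrating per subgroup would conflate DIF with
norming differences.

Conversion equations: twelve families (linear, quadratic, cubic,
exponential, logarithmic, power, rational, sigmoid, hyperbolic, and
exponential/logarithmic/power with an added linear term) are fitted to the
observed (raw, T) pairs by least squares with five deterministic starts per
family (Levenberg–Marquardt).  Fixed parameterizations, with x shifted so
min(x) = 1 for families needing a positive argument:

    rational   (c0 + c1 x) / (1 + |c2| x)
    sigmoid    c0 + c1 / (1 + exp(−(x − c2)/|c3|))
    hyperbolic c0 + c1 / x

Model choice is by BIC in the Gaussian profile form
`n ln(RSS/n) + (p+1) ln n` with the error variance counted as a parameter;
ties break toward fewer coefficients; families that fail to converge are
recorded and skipped.  Validation computes person-level agreement between
table T and equation T: ICC(A,1) (two-way, absolute agreement, single
measures) and Bland–Altman bias ± 1.96 SD.

### Norm levels

Seven levels at cumulative boundaries 5/20/40/60/80/95%.  The cut opening
a level is the smallest observed score lying strictly above the boundary
percentile; a score whose tied mass contains one or more boundaries stays
in the lower level, so with heavy zero inflation intermediate levels
collapse and are rendered absent (a bulk minimum score never reaches "very
high").  On an untied sample of n = 100,000 the realized level shares match
(5, 15, 20, 20, 20, 15, 5)% within 0.5 points.

### Quality diagnostics

* **Mokken's H** (polytomous): H_ij = cov(X_i, X_j) divided by the maximum
  covariance attainable given the two marginals (the sorted/comonotonic
  coupling); item and scale H are ratios of summed covariances.  H = 1 on
  perfect Guttman data.  Bands: < 0.3 unscalable, 0.3–0.4 low, 0.4–0.5
  moderate, ≥ 0.5 high quality.
* **Monotonicity**: item mean score across ordered rest-score groups,
  adjacent groups merged to a minimum size.  The API default minimum is 50,
  but group means at n = 50 carry SE ≈ 0.1, so violation counts at small
  group sizes mostly measure noise; the test suite and pipeline guidance
  use n/10 (the convention of the standard Mokken software), at which
  model-generated data show zero violations beyond a 0.03 tolerance.
* **Yen's Q3**: correlation across persons of residuals
  `observed − E[X | θ̂]` at the full-pattern EAP theta (not the sum-score
  theta; the difference is negligible for complete data).  Bands:
  |Q3| ∈ [0.24, 0.37) moderate, ≥ 0.37 large local dependence.
* **S-χ²** item fit: observed vs model-expected item-category frequencies
  conditional on the total score, the expectation integrating the item
  curve against the rest-score Lord–Wingersky likelihood.  Adjacent cells
  with expected count < 1 are merged; rows left with < 2 cells dropped;
  df = Σ(cells − 1) − (item parameter count), floored at 1; items with
  p < 0.001 are flagged.  Under the generating model, flagged items are
  rare (0/10 in the null test); a 1.0 threshold shift is flagged at
  p < 1e−100.

### DIF

Per item, three nested proportional-odds models on the matching trait θ̂
(pooled-calibration EAP) and the binary group: trait only; + group;
+ trait×group.  Likelihood-ratio tests give uniform (df 1), nonuniform
(df 1) and total (df 2) DIF; the flag is ΔMcFadden-R² (full vs trait-only)
≥ 0.02.  The fitter is an analytic-gradient BFGS on
`(α_1, log gaps, β)`; it matches statsmodels' `OrderedModel` to 1e−5 and is
fast enough for simulation studies (≈ 10 ms per fit at n = 2000).

Power properties worth knowing:

* The 0.02 ΔR² gate is deliberately conservative (it flags ≈ 0% of items
  under the null in our simulations, versus ≈ 5% for the α = 0.05 LR
  test).  Its power scales with item discrimination: a 0.5-logit uniform
  threshold shift at n = 1000/group is flagged in ≥ 90% of runs for items
  with a ≈ 2.4–3.3 (typical of short clinical screeners) but in almost
  none for a ≈ 1.6–2.2, where only the LR test retains power.  The DIF
  study fixture therefore uses strongly discriminating items.
* A pure discrimination change (nonuniform DIF) rescales *all* category
  intercepts of the focal group; the shared-intercept interaction model
  can absorb much of that, and for items with thresholds symmetric about
  the trait mean the interaction MLE can be near zero even under perfect
  matching.  Detection is reliable for asymmetric (hard) items on longer
  scales at larger n; the test fixture uses a 10-item scale at
  n = 3000/group.
* Matching is single-pass (no purification).  Because `olr_dif` accepts
  any matching vector, callers can iterate purification externally;
  with the small flagged-item counts the workflow expects, the single-pass
  and purified results rarely differ.

## Synthetic data generator

The generator emulates the survey the analysis assumes, not any particular
dataset:

* **Covariates** are independent draws from fixed strata: gender 57.9%
  female, six age decades (8.2/20.6/19.8/21.3/20.2/9.9%), region 64.2%
  urban, education 42.0/41.3/16.7% primary/secondary/higher.
* **Traits** are standard-normal noise plus configured subgroup shifts in
  SD units (defaults per instrument, e.g. men +0.84 SD on the alcohol
  trait, women +0.35 to +0.50 SD on depression/anxiety traits, younger
  respondents +0.09 to +0.15 SD), then re-standardized to overall mean 0,
  SD 1.  Because within-group variance stays at 1, the realized pooled-SD
  Cohen's d matches the configured shift.  Effects act on the trait only;
  item-level group differences enter exclusively through `inject_dif`,
  keeping impact and DIF separable.
* **Responses** are drawn from the GRM at each person's trait with one
  uniform per response, so the whole path is bit-reproducible under a
  fixed seed.  Missingness is MCAR at a configurable rate (default 0).
* **Item banks** are frozen constants.  The AUDIT-like bank's threshold
  shift and gap scale were solved (scripts/calibrate_banks.py, exact on a
  201-node grid) so the model-implied total-score distribution has 34%
  zeros and 90% of totals ≤ 6 — the zero-inflated right-skewed shape these
  screeners show in population samples; the other banks reproduce their
  instruments' qualitative marginals (floor-heavy mean scores on the
  agoraphobic-cognitions scales, right-skewed totals elsewhere).

What the generator does *not* emulate: multidimensionality and local
dependence (each scale is generated unidimensionally), item-level
idiosyncrasies of the real instruments, correlations between instruments,
informative nonresponse, and survey design effects.  Passing tests
therefore demonstrate that the *machinery* is correct and well calibrated
under the stated generating conditions, not that any particular published
norm table is recovered.

## Problem sizes and numerical choices

Default study-scale runs use n = 2863 per instrument; calibration-quality
checks use n = 2000–10,000, the norm-share check n = 100,000, DIF
simulations n = 1000/group × 20 replications (power) and 80 × 5 items
(type-I).  Quadrature: 61 nodes on [−6, 6] (EAP values agree with a
601-node grid to < 1e−4).  Probabilities are floored at 1e−300 inside logs;
the Lord–Wingersky partition-of-unity holds to machine precision.
Degenerate inputs (constant items, zero-variance residuals, empty
frequency tables, undersized groups) raise errors rather than being
repaired.

## Known limitations

* Missing-data handling is complete-case (with an optional prorated score
  for presentation); the workflow has no pattern-level IRT scoring for
  partial responses.
* No multidimensional or alternative IRT models; no limited-information
  fit statistics (M2/RMSEA/SRMR/TLI/CFI).
* The ΔR² DIF gate's low power for weakly discriminating items and for
  pure discrimination ratios is inherent to the method (see above).
* Norm tables and crosswalks are sample statistics: with n ≈ 2800 the T
  values in sparse score regions carry multi-point sampling error.
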