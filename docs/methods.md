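# Methods

## The model

The package analyses geographic variation in two binary birth outcomes —
low birth weight (LBW, weighed < 2,500 g at birth) and small birth size
(SBS, mother's report of "very small" or "smaller than average") — across a
strictly nested geography: children (level 1) in small areas (survey
clusters, level 2) in districts (level 3) in states (level 4).

The national model is an intercept-only 4-level random-effects logistic
regression.  With child *i* in small area *j*, district *k*, state *l*:

    logit P(Y_ijkl = 1) = β0 + c_jkl + d_kl + s_l
    c_jkl ~ N(0, σ²_c),  d_kl ~ N(0, σ²_d),  s_l ~ N(0, σ²_s)

State-specific models drop the state level (3 levels); a state with a single
district additionally drops the district level (2 levels) and is flagged, so
its geographic variance is attributed entirely to small areas.

Under the latent-variable (threshold) view of the logistic model the child
level has a fixed residual variance of π²/3 ≈ 3.29.  The *geographic*
variance is σ²_c + σ²_d + σ²_s, and the share of level *z* is

    VPC_z = 100 · σ²_z / (σ²_c + σ²_d + σ²_s)       (percent)

The child-level constant is reported but excluded from the denominator.
Within one state the small-area share is 100·σ²_c/(σ²_c + σ²_d), defined as
exactly 100 for flagged single-district states.

## Estimation

Fitting is Bayesian via Gibbs sampling with Pólya-Gamma (PG) data
augmentation.  Each Bernoulli observation receives a latent ω ~ PG(1, ψ)
with ψ its linear predictor; conditional on ω the likelihood is Gaussian in
(β0, c, d, s), so every sweep updates, in turn, the small-area residuals,
district residuals, state residuals, the intercept and the three variance
components from exact conditional distributions — no tuning, no rejections
at the sweep level.  Because all children of a small area share one ψ, their
ω's enter only through per-area sums, drawn directly as PG(n_area, ψ)
variates (the sum of n_area independent PG(1, ψ) draws).

The PG(1, z) generator is the exact alternating-series rejection sampler
(truncation point 0.64, truncated inverse-Gaussian and exponential proposal
branches), compiled with numba and validated against the closed-form moments
E[PG(b,z)] = b·tanh(z/2)/(2z) and Var[PG(b,z)] = b(sinh z − z)/(4z³cosh²(z/2)).

* **Priors.** Improper flat prior on β0; inverse-gamma(0.001, 0.001) on each
  variance component — a conventional diffuse choice, configurable through
  `ModelSpec(prior_shape=, prior_rate=)`.
* **Chain protocol.** 5,000 monitored iterations after a burn-in of 500, no
  thinning (all defaults configurable).  Posterior summaries are means and
  equal-tailed 95% credible intervals (2.5th/97.5th percentiles, linear
  interpolation); effective sample size per scalar via `arviz.ess`.
* **Starting values.** β0 starts at the empirical logit of the overall
  prevalence (0.5 continuity correction).  Variance starts use a top-down
  method of moments on empirical logits: each level's between-unit logit
  variance, net of mean binomial noise and of the starts of the levels above
  it, floored at 0.01.  These replace software-specific frequentist
  pre-estimates; with 5,500 total iterations the start affects only burn-in
  adequacy, which the ESS column diagnoses.
* **Reproducibility.** One `numpy.random.Generator` per fit, seeded from
  `ModelSpec.seed`; all per-unit draws occur in sorted unit-ID order, so
  permuting input rows changes nothing.  State-specific fits split per-state
  seeds from the master seed in sorted state order.
* **Validation.** On a 5-cluster two-level toy the sampler's posterior means
  of β0 and σ²_c agree with an independent dense-grid posterior
  (Gauss–Hermite marginalisation of the cluster effects over a (β0, log σ²)
  grid) within 3 Monte-Carlo standard errors; at the survey-like scale the
  generating variances fall inside their 95% credible intervals at the
  nominal rate across seeded replicates.

Known mixing behaviour: β0 trades off against the level means of the
residuals, so its ESS is low (tens out of 5,000) in deep hierarchies — an
expected property of the non-centred parameterisation.  The variance
components, which carry the scientific conclusions, mix well (ESS in the
hundreds to thousands).  Sums and differences like β0 + s_l mix fast, so the
precision-weighted prevalences are unaffected.

## Precision-weighted prevalence and dispersion

Small-area prevalence plugs posterior-mean residuals into one inverse logit:
100·expit(β0 + ĉ_jkl + d̂_kl + ŝ_l); districts drop the ĉ term.  This is the
plug-in convention (the posterior mean of per-draw inverse logits, which is
slightly larger in expectation, is not the default).  Since posterior means
of random effects are shrunken toward zero, small-area estimates are pulled
toward their district/state mean — the estimates are conservative and
strictly inside (0, 100).

Within-district small-area inequality is the n−1 sample SD of the district's
small-area prevalences; districts with one small area get a missing SD.  The
prevalence–SD association is the Pearson correlation over districts
(nationally and per state; groups need ≥ 3 districts with defined SD).  On
the probability scale a constant latent σ²_c fans out: a district at 15%
prevalence spreads more in percentage points than one at 8%, so the
correlation is positive even with no structural coupling — the pipeline
reproduces this direction on synthetic data.

Individual-level agreement between the weighed and the reported outcome is
summarised by sensitivity = P(SBS=1 | LBW=1), specificity = P(SBS=0 | LBW=0)
and the single-binary-predictor ROC area (sensitivity + specificity)/2.

## Policy classification

Districts are ranked on prevalence and on SD and cut into balanced rank
groups: tertiles (low/medium/high) and deciles (1–10).  Balanced-rank
cutting (sizes differing by at most one, remainder to the highest groups,
ties broken by stable district-ID order) is used instead of
quantile-threshold cutting, which can unbalance badly under ties; 640
districts give tertiles of 213/213/214 and deciles of 64.  The 3×3
prevalence-by-SD cross-tabulation (counts and percentages) highlights
high-prevalence/high-SD districts.  The aspirational-district flag is a
user-supplied column; groups are compared descriptively (n, means, SDs, and
a Mann-Whitney rank statistic with its attained level — no significance
threshold is enforced).

## Synthetic data

The generator emulates the survey's architecture, not its content:

* **Design.** The `nfhs-small` profile draws 30 states, 5–15 districts per
  state, 4–8 small areas per district, and the survey's fixed take of 22
  children per small area (≈ 40,000 children, ≈ 1,750 small areas) — a
  scaled-down version of the real frame (36 states/UTs, 640 districts,
  ≈ 28,000 small areas) chosen so a full 5,500-iteration fit runs in well
  under a minute while every level keeps enough units to be identifiable.
  One RNG stream per level is split from the master seed, so changing the
  children-per-cluster setting does not perturb the hierarchy draw.
* **Outcomes.** Default truth: β0 = logit(0.176) with (σ²_s, σ²_d, σ²_c) =
  (0.18, 0.07, 0.28) — the reported national LBW prevalence and posterior
  variance components, so simulated data live in the regime the analysis
  targets.  Birth weight and the 5-category size label are filled in
  consistently with the binary outcome (weight uniform 1,200–2,499 g when
  positive, 2,500–4,200 g otherwise; positive children labelled very_small
  with probability 0.25, else smaller_than_average; magnitudes are only ever
  thresholded downstream).
* **Missingness.** Weight is blanked at a requested marginal rate (default
  0.254) with per-cluster log-odds tilted by a deprivation gradient (one
  uniform(0,1) deprivation score per cluster; the tilt intercept is solved
  numerically so the marginal rate is preserved); a configurable share of
  clusters is forced to 100% missing, mirroring the fully-excluded clusters
  of the real extraction.  Size is blanked at a small rate (< 2%), half
  recorded as "don't know".
* **Not emulated.** Two-stage PPS household sampling and survey weights
  (the analysis model is unweighted), child-level missingness covariates,
  reporting heaping/digit preference, and the single shared latent outcome
  means synthetic LBW and SBS coincide (real agreement is far weaker — the
  agreement statistics are exercised on independently simulated vectors in
  tests).  Passing tests therefore demonstrate correctness of the machinery
  and calibration under the stated model, not robustness to the real data's
  reporting artefacts.

## Numerical choices and degenerate inputs

* Integer display shares round half-away-from-zero (the convention matching
  reported integer percentages); exact shares are always carried alongside.
* VPC with all components zero, samples whose outcome is constant, hierarchies
  that are not strictly nested, non-positive observed weights, unrecognised
  size labels and out-of-range missingness rates are rejected with messages
  rather than coerced.
* Tertiles need ≥ 3 values, deciles ≥ 10, correlations ≥ 3 districts with
  defined SD and non-degenerate coordinates; failing groups are skipped with
  a logged warning, not invented.
* The full `report` pipeline writes floats with a fixed `%.10g` format and
  derives every stage's seed from one master seed, so reruns are
  byte-identical.

## Limitations

Intercept-only models (no covariates); nested structures only (no
cross-classification); no spatial smoothing across neighbouring districts;
no survey weights; convergence diagnostics limited to ESS.  The pipeline's
aspirational flag on synthetic data is assigned at random (rate 0.175) purely
to exercise the comparison code path; it carries no policy meaning.
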