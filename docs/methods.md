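# Methods

## Scope and model

`mpyeval` evaluates two fixed, published predictors of milk protein yield
(MPY, g true protein/d) for lactating Holstein cows against observed
yields; it does not refit or recalibrate them. Nutrient supplies (MP,
individual EAA, DE, digestible NDF) and protein expenditures are taken as
*inputs* — the upstream feed-evaluation chain that derives them from diet
composition (intake equations, microbial protein, rumen-undegradable
protein, AA digestibility) is deliberately out of scope. A supply profile
is attached to a cow per dry-matter-intake scenario: `DMI_Ao`
(animal-traits-only intake prediction) or `DMI_AR` (animal + ration
fibre), and each predictor is evaluated under each scenario.

### The multivariate predictor

An affine function of the five most-limiting essential amino acid flows
(His, Ile, Leu, Lys, Met, g/d), the grouped remaining amino acids (OAA),
the sum of squared EAA flows, non-protein digestible energy intake
(Mcal/d), digestible NDF concentration (% of DM, centred at 17.06) and
body weight (kg, centred at 612). Coefficients are hard-coded constants;
fidelity is asserted by finite-difference tests rather than trusted to
transcription.

The source model adjusts these coefficients by the herd's rolling herd
average (RHA, kg milk true protein/305 d) but publishes no formula. The
default here is **no adjustment**. An optional, clearly-labelled hook
(`rha_adjustment="scalar"`) multiplies the supply-response terms (the
five EAA, OAA and DEInp terms — not the intercept, EAA², dNDF or BW
terms) by RHA/280, 280 being the standard substitute for a missing RHA
record. This is an assumption of this package, exercised by the
sensitivity analysis, not a reconstruction of the original scheme.

### The variable-efficiency predictor

Efficiency of MP utilization (in %) is a convex quadratic in
Ratio = (MP supply − urinary endogenous loss)/DE intake (g/MJ), declining
linearly with days in milk; its vertex sits at Ratio ≈ 12.18 g/MJ, well
above the realistic range (≈ 5–8), so efficiency decreases with Ratio in
practice. Energy arrives in Mcal/d and is converted at exactly
4.184 MJ/Mcal. Yield is then

    MPY_eff = (MPsup − TPuri) · Eff/100 − (TPfecal + TPscurf + TPgrowth),

with the three export expenditures converted from their MP basis to true
protein by the 69 % target efficiency. The source typesets this equation
ambiguously; the algebraic reading above — efficiency applied to the
supply net of urinary endogenous loss, export expenditures subtracted on
a true-protein basis — is adopted because it is the consistent form in
the variable-efficiency framework. Urinary endogenous loss is treated as
identical on MP and true-protein bases and never converted.

Predictions from both equations are returned **unclamped**: a negative
value is physiologically meaningless but statistically informative, and
clamping would bias the agreement metrics. Reports count negative
predictions instead. A supply below the urinary endogenous loss
(possible in stress tests) yields a negative Ratio with a warning rather
than an error.

## Agreement metrics

All metrics use population (divide-by-*n*) moments by default, which
matches Lin's (1989) CCC definition and makes the MSE decomposition

    CTB = (mean_pred − mean_obs)²,  RB = (s_p − r·s_o)²,  DB = (1 − r²)·s_o²

an exact identity (CTB + RB + DB = MSE). Sample moments are available via
`moments="sample"`; at n ≈ 500 the difference is in the third decimal.
Residuals are `obs − pred` everywhere, so a predictor that overestimates
late-lactation cows produces a *negative* residual–DIM correlation.
Residual-covariate correlations carry two-sided p-values from the t
distribution on n − 2 df; p-values are reported, never used for gating,
and not multiplicity-corrected. RB and DB are direction-dependent
(swapping obs and pred preserves MSE, CCC and CTB but redistributes
RB/DB); the tests document this asymmetry. The report carries both
regression directions: `slope`/`intercept` for pred-on-obs and
`slope_obs_on_pred`/`intercept_obs_on_pred` for the line drawn through
observed-vs-predicted scatter plots.

## Synthetic herd generator

The generator emulates a ~23-herd, ~541-cow commercial dataset:

* **Herd structure.** Herd sizes from a rounded normal (mean 44.8,
  SD 16.9), floored at 2 and nudged round-robin to hit the configured
  total cow count.
* **Cow traits.** Truncated-normal marginals with the published means,
  SDs and ranges: BW 672 ± 57.7 kg [535, 841], DIM 202 ± 116 d [22, 684],
  parity 2.4 ± 1.5 [1, 8] (rounded to integers), RHA 304 ± 57 kg/305 d
  [151, 479], marginal MPY 894 ± 248 g/d [211, 1601]. For one-sidedly
  truncated traits the underlying location is solved numerically so the
  *truncated* mean equals the target; naive truncation would inflate the
  DIM mean by ~7 % (its lower bound is only 1.55 SD below the mean). The
  cost is a mildly compressed DIM SD (~14 % below nominal), accepted
  because the means drive the worked examples. DIM is drawn symmetric
  despite the right skew of real lactation-stage distributions.
* **Herd effects.** A single mean-one multiplicative lognormal intercept
  per herd scales the production traits (RHA, observed MPY; CV 0.10,
  chosen from the published herd-level dispersion) and, dampened
  (CV 0.03), body weight. No herd × scenario interaction.
* **Supplies.** A single per-cow standard-normal intake propensity drives
  DMI in both scenarios (DMI_Ao 23.4 ± 2.5, DMI_AR 20.9 ± 2.8 kg/d),
  which correlates them and induces the dominant supply covariance. MP,
  DE and digestible NDF are per-kg-DMI ratios times DMI times mean-one
  lognormal noise; the ratios are the quotients of the published scenario
  means (e.g. 2059/23.4 ≈ 88 g MP/kg DMI), and the noise CVs are set so
  the product reproduces the published supply SDs. Each EAA is its
  fraction of MP (His 2.22 %, Ile 5.97 %, Leu 8.89 %, Lys 7.48 %,
  Met 2.19 %) with independent lognormal noise; OAA is 88.2 % of MP.
  ΣEAA² is always computed exactly from the five drawn flows — the
  published dataset-level ΣEAA² mean is not targeted, because it reflects
  within-herd variance and is not reproducible from the AA means alone
  (sum of squared means ≈ 76,475 vs the printed 133,934 g²/d²).
  Non-protein DE is a truncated-normal fraction (~0.789) of DE, which
  guarantees DEInp ≤ DE.
* **Expenditures.** Urinary endogenous 223 g/d at 672 kg BW, scaling with
  BW; metabolic fecal 18.0 g/kg DMI (calibrated on the DMI_Ao column;
  applied to the DMI_AR mean it gives ≈ 376 vs the published 365 g/d, a
  3 % discrepancy accepted rather than introducing a scenario-dependent
  coefficient); scurf 12 g/d scaling with BW; growth 26 ± 1 g/d for
  first-parity cows and zero otherwise; target efficiency 0.69.
* **Observed MPY.** Either the marginal draw (`external_table`) or a
  truth model: one predictor's output on the truth scenario times mean-one
  lognormal noise (default σ = 0.10) times the herd factor, truncated to
  [211, 1601] g/d. The latent noiseless yield and efficiency are stored,
  enabling exact-recovery tests (σ = 0 ⇒ RMSE 0, CCC 1 for the matching
  predictor) and calibrated-noise tests (obs-on-pred slope → 1, C_b → 1
  as σ → 0, since the noise is mean-one and independent of the
  prediction).

What passing these tests shows — and does not. The generator reproduces
marginal summaries, the intake-driven supply covariance and a
herd-intercept structure; it does not reproduce the real joint
distribution of DIM with supplies, RHA with production, lactation-stage
skew, or genuine model misspecification. Recovery results therefore
validate the *machinery* (predictors, metrics, pipeline), not the
field performance of either predictor.

## Numerical choices

* Truncated-normal draws via `scipy.stats.truncnorm` with the location
  solved by Brent's method (tolerance 1e-10); degenerate SD = 0 returns
  the constant target.
* All randomness flows through one `numpy.random.Generator`; identical
  config + seed gives bit-identical datasets.
* Table I/O parses numbers with Python's correctly-rounded `float()`, so
  write → read → write round-trips byte-identically.
* MSE decomposition percentages are defined as shares of CTB + RB + DB
  (identically MSE under population moments); a zero total reports 0/0/0.
* Zero-variance residuals (a perfect fit) make residual correlations
  undefined; the pipeline records NaN instead of failing.
* Cows present in the cow table but absent from the supply table are
  excluded with a logged count; a missing RHA is imputed as 280 kg/305 d
  with a logged count. Record conservation (evaluated + excluded = input)
  is asserted in tests.

## Problem sizes

The test suite and the acceptance script use the full 541-cow default for
recovery checks, 5,000 cows for generator-fidelity checks, and 1,000
short random vectors for the metric oracle; these sizes give sampling
errors comfortably below the asserted tolerances while keeping a full run
under a minute.

## Known limitations

* The RHA coefficient-adjustment scheme is a documented assumption; in
  scalar mode a ±15 % RHA shift moves NRMSE by several percentage points
  on synthetic data because it rescales the whole supply response — no
  claim is made that the original model behaves this way.
* Herd structure is a single multiplicative intercept; no within-herd
  diet covariance, no herd-level supply effects.
* No confidence intervals for CCC and no mixed-model (per-herd)
  evaluation; cows are pooled, matching the evaluation design the
  package reproduces.
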