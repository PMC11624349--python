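# mpyeval

Evaluation of milk protein yield (MPY) predictors for lactating dairy cows
on multi-herd, commercial-farm-style data.

Feed evaluation models such as NASEM (2021) predict per-cow nutrient
supplies — metabolizable protein (MP), individual essential amino acids
(EAA), digestible energy (DE) — and from those, milk protein yield. Two
predictors are commonly compared:

* **MPY_multi**, a multivariate regression on digested nutrient flows and
  body weight:

  MPY_multi = −97.0 + 1.68·His + 0.885·Ile + 0.466·Leu + 1.15·Lys + 1.84·Met
  \+ 0.077·OAA − 0.00215·ΣEAA² + 10.8·DEInp − 4.6·(dNDF − 17.06) − 0.42·(BW − 612)

  with AA supplies in g/d, OAA the grouped remaining amino acids, ΣEAA²
  the sum of the five squared EAA supplies (g²/d²), DEInp non-protein DE
  intake (Mcal/d), dNDF digestible NDF (% of DM) and BW body weight (kg).

* **MPY_eff**, built from a *variable efficiency* of MP utilization,

  Eff (%) = 176 − 21.2·Ratio + 0.87·Ratio² − 0.041·DIM,
  Ratio = (MP supply − urinary endogenous MP loss) / DE intake (g/MJ),

  applied to the supply net of maintenance expenditures:

  MPY_eff = (MPsup − TPuri)·Eff/100 − (TPfecal + TPscurf + TPgrowth),

  with the export expenditures converted from their MP basis to true
  protein via the 69 % target efficiency.

Each predictor can be driven by either of two dry-matter-intake
predictions: animal-traits-only (**DMI_Ao**) or animal + ration fibre
(**DMI_A&R**), giving up to four prediction sets. Agreement with observed
yields is judged with RMSE, NRMSE, Pearson *r*, Lin's concordance
correlation coefficient (CCC) and its bias-correction factor C_b, and the
decomposition of mean square error into central-tendency (CTB),
regression (RB) and disturbance (DB) bias, plus residual correlations
with days in milk (DIM) and the rolling herd average (RHA).

Because per-cow farm datasets of this kind are typically proprietary, the
package also ships a **synthetic multi-herd generator** reproducing the
published descriptive statistics (herd structure, trait means/SDs and
ranges, supply scaling with intake) with a configurable truth model, so
the entire pipeline is testable end to end.

## Worked example

```python
from mpyeval import MPYEvaluation

results = MPYEvaluation.from_synthetic(seed=42).fit()
print(results.summary())
```

prints

```
Milk protein yield prediction — evaluation summary
==============================================================================
set                 n     obs    pred    RMSE  NRMSE%      r     Cb    CCC   CTB%    RB%    DB%
------------------------------------------------------------------------------
DMI_AR/multi      541     991     854   209.8    21.2   0.49   0.66   0.32   42.7    2.5   54.8
DMI_AR/eff        541     991     863   191.1    19.3   0.63   0.75   0.47   45.1    2.8   52.1
DMI_Ao/multi      541     991     959   153.5    15.5   0.54   0.87   0.47    4.5    0.5   95.0
DMI_Ao/eff        541     991     985   114.2    11.5   0.77   0.97   0.74    0.3    0.0   99.7
------------------------------------------------------------------------------
Residual correlations (obs − pred vs covariate):
  DMI_AR/multi vs DIM  r = -0.48 (p = 4.84e-33)
  ...
```

Each row is one scenario × predictor pair evaluated on the same 541
synthetic cows: `RMSE` in g/d, `NRMSE%` as a share of the observed mean,
and the CTB/RB/DB columns as percent of MSE. In this run the observed
yields were generated from the variable-efficiency predictor under the
animal-only DMI (`DMI_Ao/eff`), so that set shows the best agreement
(CCC 0.74, C_b 0.97) while the multivariate predictor picks up a strong
negative residual correlation with DIM — the efficiency decline over
lactation it does not model.

The same analysis is available from the shell:

```bash
mpyeval simulate --seed 42 --outdir out      # write cows.csv / supplies.csv
mpyeval run --cows out/cows.csv --supplies out/supplies.csv --outdir out
mpyeval sensitivity --seed 42 --delta 0.15 --outdir out
```

`run` writes `metrics.csv` (one row per prediction set),
`predictions.csv` (per-cow yields and residuals), `rha_sensitivity.csv`,
`summary.txt` and `run_log.txt` (imputation/exclusion/negative-prediction
counts).

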