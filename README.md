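# lcmsr

Latent curve models with structured residuals (LCM-SR) for
measurement-burst panel data, with deficit-accumulation frailty and
UCLA-3 loneliness scoring.

## The problem

Frailty and loneliness in older adults are correlated, but a correlation
across people says little about what happens *within* a person over weeks:
does a dip in health predict feeling lonelier two weeks later, or the
reverse? Measurement-burst studies — clusters of biweekly assessments
repeated a year apart — make that question answerable, but only with a
model that separates stable between-person differences from short-term
within-person dynamics.

The LCM-SR does exactly that. Each observed score is decomposed as

```
y_ct = RI_c,b(t) + c_t * S_c,b(t) + r_ct
```

where `RI` is a per-burst random intercept (and `S` an optional per-burst
slope with loadings 0, 1, 2, ... within the burst), and the structured
residual `r_ct` carries the within-person dynamics:

```
r_FI,t+1 = alpha_t r_FI,t + delta_t r_LS,t + e_FI,t+1
r_LS,t+1 = beta_t  r_LS,t + gamma_t r_FI,t + e_LS,t+1,   cov(e_FI,t, e_LS,t) = lambda_t
```

`alpha, beta` are autoregressions, `gamma, delta` cross-lagged effects,
`lambda_t` the within-wave residual covariance, and the `zeta` covariances
link the four random intercepts (two constructs x two bursts). For two
constructs over 14 waves in two bursts of 7, the canonical model (frailty
with random intercepts, loneliness with random intercepts plus fixed
slopes) has 110 free parameters and 324 degrees of freedom against the
saturated mean-and-covariance structure.

Everything is estimated by full-information maximum likelihood (FIML):
each person contributes the normal log-density of exactly the waves they
completed, which handles monotone attrition under MAR. Standard errors
are Huber-White sandwich estimates `H^-1 B H^-1`. Model building follows
a four-step univariate ladder (autoregressive only → + random intercepts
→ + fixed slopes → + random slopes) compared by likelihood-ratio tests,
and global fit is judged by the chi-square, CFI, TLI, RMSEA (90% CI) and
SRMR with the usual adequacy thresholds (CFI/TLI ≥ 0.95, RMSEA/SRMR ≤ 0.05).

The package also ships the two scale builders (a 37-item
deficit-accumulation frailty index in [0, 1] with an 80%-validity rule,
and the 3-item UCLA loneliness sum in 3–9), multiple-group analysis,
exogenous time-varying covariates, and a synthetic two-burst generator so
the entire pipeline is testable without access-restricted cohort data.

## Worked example

```python
import numpy as np
from lcmsr import LCMSR, PanelData, fit_indices
from lcmsr.synthetic import GeneratorConfig, simulate_panel

panel = simulate_panel(GeneratorConfig(n_persons=426, seed=1)).drop(columns="person_id")
model = LCMSR().fit(panel)            # canonical bivariate LCM-SR, FIML + sandwich SEs
idx = fit_indices(model.result_, data=PanelData(panel))
```

With the default generator (426 persons, two bursts of 7 biweekly waves,
monotone attrition from 426 down to 202 at the last wave) this prints:

```
converged: True
loglik: 3598.83  df: 324  free: 110
chisq(324) = 333.46, CFI = 0.999, TLI = 0.999, RMSEA = 0.008 [0.000, 0.020], SRMR = 0.026
imean_FI_1       est  0.183  std  0.183 [ 0.171,  0.195]
imean_FI_2       est  0.200  std  0.200 [ 0.188,  0.212]
imean_LS_1       est  3.355  std  3.355 [ 3.286,  3.424]
imean_LS_2       est  3.457  std  3.457 [ 3.386,  3.528]
icov_FI1_FI2     est  0.015  std  0.949 [ 0.934,  0.963]
icov_FI1_LS1     est  0.042  std  0.513 [ 0.438,  0.588]
wcov_FI_LS_1     est  0.003  std  0.174 [ 0.055,  0.293]
ar_FI_1          est  0.183  std  0.176 [ 0.054,  0.297]
```

Reading the output: the burst-level frailty intercepts recover the
generating means (0.18, 0.20 on the 0–1 frailty index; 3.39/3.51 for
loneliness, here estimated 3.36/3.46); the frailty intercepts correlate
0.95 across bursts (people keep their rank over a year); intercepts of the
two constructs correlate ≈ 0.51 (frailer people are lonelier); and the
within-wave standardized residual covariance ≈ 0.17 means that in a wave
where someone is frailer than their own norm they also tend to report more
loneliness. Covariances are reported as correlations in the standardized
column; growth-factor means are left on the raw scale.

The same workflow is scriptable from the shell:

```bash
lcmsr simulate --n-persons 426 --seed 1 --out panel.csv
lcmsr ladder   --data panel.csv --construct FI --out ladder_fi/
lcmsr fit      --data panel.csv --model model.yaml --out fit/
lcmsr groups   --data panel.csv --model model.yaml --group-col sex --out groups/
```

## Layout

- `lcmsr.scales` — frailty-index and loneliness scoring, item-map configs
- `lcmsr.model_spec` — symbolic model builders and RAM compilation
- `lcmsr.estimation` — FIML, sandwich SEs, standardization, multi-group
- `lcmsr.inference` — likelihood-ratio tests, fit indices, model ladder
- `lcmsr.synthetic` — two-burst panel generator and deficit-item simulator
- `lcmsr.estimator` — scikit-learn style `LCMSR` facade
- `lcmsr.cli` — `lcmsr score|simulate|fit|ladder|groups`

See `docs/methods.md` for the model, estimation details and limitations.
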