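# mnarps — propensity score analysis with MNAR confounders

Observational studies estimate causal treatment effects with propensity score
analysis (PSA), but baseline confounders are frequently missing — and often
*missing not at random* (MNAR): the probability that a value is withheld
depends on the value itself or on unobserved influences. Standard multiple
imputation assumes MAR and can leave residual confounding. `mnarps`
implements, in one tested library, the family of *missingness-pattern
approaches* that use the missingness itself as information:

* **DFPI** — dual-forest proximity imputation. Two supervised random forests
  are fitted on the current completed confounders augmented with the missing
  indicators S: a classification forest for the treatment Z and a regression
  forest for the outcome Y. Each forest yields a co-leaf proximity matrix

      M(i, i′) = (1/B) Σ_b 1{ℓ_b(i) = ℓ_b(i′)},

  and their element-wise average (diagonal zeroed) defines donor weights
  ω_ii′ = M(i, i′) / Σ_k M(i, k). Every originally missing continuous cell is
  replaced by the proximity-weighted donor mean Σ ω_ii′ X_i′j; binary cells by
  the category maximising observed-proportion × weighted donor support. The
  update iterates until the relative change falls below 1e−5 or a maximum
  iteration count.
* **PI-I / PI-U** — the same proximity-weighted iteration driven by a single
  supervised forest (Y on [X | S | Z]) or an unsupervised synthetic-class
  forest on [X | S].
* **MP-LR / MP-RF** — no imputation: a separate propensity model (logistic or
  forest) per pooled missingness-pattern group, with the minimum-100 pooling
  rule (small patterns agglomerate among themselves until each pooled group
  reaches 100 rows; large patterns stand alone).
* **MIMP-LR / MIMP-RF** — MICE with predictive mean matching (m = 10 copies,
  outcome and treatment in every univariate model), propensity models with
  missing indicators, Rubin's-rule pooling.

Downstream, all chains share inverse-probability-of-treatment weighting
(ATE: w = Z/e + (1−Z)/(1−e); ATT: w = Z + (1−Z)e/(1−e)), Hájek weighted-mean
effect estimates with Taylor-linearised standard errors, covariate-balance
and common-support diagnostics, and a weighted Poisson model for non-negative
ATT outcomes.

The package also contains the Monte Carlo machinery used to evaluate these
methods: a calibrated data-generating process (multivariate-normal
confounders, half dichotomised; logistic treatment model calibrated to a
0.2 treated fraction and 0.2 McKelvey–Zavoina pseudo-R²; linear outcome model
with treatment effect δ = 0.5 and R² = 0.2) with MAR and five MNAR missingness
mechanisms imposed at calibrated marginal rates, plus the study metrics
RB(d), RB(SE(d)), MSE and factorial effect sizes (η²G, PEV).

## Worked example

```python
from mnarps import (ChainConfig, MissingConfounderPSA, SimulationConfig,
                    simulate_dataset)

cfg = SimulationConfig(n=1000, p=10, missing_rate=0.3,
                       mechanism="FD_MNAR", seed=42)
ds, params = simulate_dataset(cfg)           # 30% of cells in x2..x10 withheld
chain = ChainConfig.default(seed=42, n_trees=200)
res = MissingConfounderPSA.from_generated(ds, method="DFPI", config=chain).fit()
print(res.summary())
```

```
Propensity score analysis with missing confounders
====================================================
Method:        DFPI
Estimand:      ATE
N:             1000 (treated 172, control 828)
Estimate:       0.5166
Std. error:     0.0931
95% CI:        [ 0.3342,  0.6991]
Balance:       max |SMD| 0.135, mean 0.064, 6 covariate(s) > 0.05
```

The dataset was generated with a true treatment effect of 0.5; under
focused-direct MNAR at 30% missingness the DFPI chain recovers 0.517 with a
linearised SE of 0.093, and the post-weighting standardized mean differences
summarise residual imbalance. `res.balance()`, `res.common_support()` and
`res.imputed` expose the diagnostics and the completed confounder table;
multiple-imputation chains additionally carry the Rubin decomposition in
`res.pooled`.

The same chains are available from the shell:

```bash
mnarps --seed 7 simulate --n 500 --p 10 --missing-rate 0.3 --out sim/
mnarps --seed 7 impute --method dfpi --in sim/rep1.csv --out imputed.csv
mnarps --seed 7 estimate --method plain --in imputed.csv --out effect.json
mnarps --seed 7 study --reps 100 --n 500 --p 10 --mechanism MAR --out results/
```

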