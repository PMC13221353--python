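# Methods

This note records the statistical models implemented in `mnarps`, the
choices made where the design was genuinely open, and what the synthetic
data generator does and does not emulate.

## Problem setting

A binary treatment Z, a continuous outcome Y and p baseline confounders X
are observed for n units; cells of X (never Z or Y) may be missing, with the
missingness possibly depending on the withheld values themselves (MNAR).
S is the n×p missing-indicator table with S = 1 ⇔ the cell is withheld.
All methods produce propensity scores e(·), inverse-probability weights, and
a Hájek weighted-mean treatment-effect estimate with a linearised standard
error; they differ in how they use X, S and the pattern structure of S.

## Data-generating process

Confounders are multivariate standard normal with an exchangeable
correlation (ρ = 0.2 by default; identity and user matrices supported); the
upper half of the columns is dichotomised at 0, so binary columns have
marginal probability 0.5 and attenuated correlations. Treatment follows a
logistic model Z ~ Bernoulli(expit(β₀ + Xβ)); the outcome is
Y = Xπ + δZ + e with e ~ N(0,1) and δ = 0.5 by default. A flag reproduces a
literal deterministic threshold-at-zero treatment rule instead of the
Bernoulli draw; it is off by default because a deterministic threshold
destroys overlap between arms.

Calibration: β is drawn from U(−0.4, 0.4) and rescaled by one constant so
the McKelvey–Zavoina pseudo-R², var(Xβ)/(var(Xβ)+π²/3), hits its target
(0.2 default); β₀ is root-found so the marginal treated fraction hits its
target (0.2). π is drawn from U(0.1, 0.8) and rescaled so the population R²
of the outcome model, var(Xπ+δZ)/(var(Xπ+δZ)+1), hits its target (0.2) —
note the variance of the systematic part includes the X–Z covariance
induced by confounding. All calibration uses a 100 000-row Monte Carlo
sample with a seed derived from the master seed; achieved values are stored
with the parameters. On the calibration sample all targets are met to
±0.01.

Missingness is imposed on columns 2..p (column 1 is always fully observed)
through a latent score γ₀ + linear predictor + ε with ε ~ logistic(0, 1),
thresholded at zero — drawn equivalently as Bernoulli(expit(·)). The six
mechanisms differ only in the linear predictor:

| mechanism | predictor |
|---|---|
| MAR | γ₁X₁ |
| FD-MNAR (focused-direct) | γ₁X_k (the withheld value itself) |
| FI-MNAR (focused-indirect) | γ₁X*, X* ~ N(0,1) unobserved |
| DF-MNAR (diffuse) | Σ_j γ_j X_j over all p columns including the target |
| DF-MNAR-INT1 | γ₁X₁ + γ₂X_k + γ₃(X₁·X_k) |
| DF-MNAR-INT2 | γ₁X₁ + γ₂X* + γ₃(X₁·X*) |

Slopes are drawn from U(0.1, 0.5) per target column; γ₀ is root-found per
column so each column's marginal missing rate hits the target (10/30/50%
in the study designs). The auxiliary X* is drawn internally and never
exposed to any downstream method. By default each Monte Carlo replication
redraws β, π and γ (a `fix_coefficients` option reuses one draw and varies
only the data seed); the redraw choice treats the coefficient draws as part
of the sampled universe rather than fixed population values.

What the generator does *not* emulate: the empirical correlation structure
of a real survey panel (the exchangeable ρ = 0.2 stand-in is a deliberate,
documented simplification), item-level survey semantics, sampling weights,
skewed or log-scale covariates, and missingness in treatment or outcome.
Passing tests therefore demonstrate behaviour under a clean, calibrated
MNAR laboratory, not performance on any particular applied dataset.

## Proximity imputation

All forests are scikit-learn random forests with B = 500 trees by default,
mtry = ⌊√q⌋ features per split, Gini impurity (classification) or variance
reduction (regression), and the library's default node sizes. The proximity
of two rows is the fraction of trees in which they share a terminal node,
computed per tree by grouping equal leaf ids (a sparse indicator product);
this equals the naive pairwise count exactly and is what the tests assert.
Proximities are computed over all training rows (in-bag pairs included); an
OOB-pairs-only variant exists but is off by default.

DFPI iterates: strawman initialisation (column median for continuous,
observed mode for binary cells); fit the treatment forest (Z on [X|S]) and
the outcome forest (Y on [X|S]; a flag adds Z to the outcome forest,
default off); average the two proximity matrices element-wise and zero the
diagonal; replace every originally missing cell by the proximity-weighted
donor value. Donors contribute their *current* values, so previously
imputed donors participate — this is why initialisation and iteration are
required. Binary cells are imputed by weighted vote with the weighted
support of each category additionally multiplied by its observed marginal
proportion; ties resolve to the lowest category. Rows whose proximities sum
to zero fall back to uniform weights over donors observed in the column
(logged).

Convergence is declared when the L1 relative change over originally missing
continuous cells falls below 1e−5 *and* no categorical cell changed; the
iteration cap is 10. Because the forests are refitted with fresh seeds each
iteration, the trace typically flattens near the forest Monte Carlo noise
floor rather than reaching the tolerance; the last iterate is returned with
`converged=False` in that case. The trace is recorded but monotonicity is
not asserted — it is not guaranteed by the procedure.

PI-I uses one supervised regression forest of Y on [X|S|Z] (treatment
included: imputation should reflect similarity "given treatment status");
PI-U uses Breiman's synthetic-class unsupervised forest on [X|S] — a shadow
dataset permutes each column independently and a classifier separates real
from shadow, so the partition reflects the joint covariate-and-indicator
structure without response information. Exact reference algorithms for
these two variants are not published in full; the implementations follow
the available prose descriptions and are labelled accordingly.

A known behaviour worth stating: rows that are missing the *same* column
co-cluster through their shared indicator and identical initial fill, so at
high missing rates the first iterations can echo the strawman values among
missing-together donors. The effect fades with iteration and with lower
missing rates; it is inherent to the donors-contribute-current-values rule.

## MICE-PMM

`statsmodels` MICEData provides the chained-equations engine: every
incomplete column is imputed by predictive mean matching with 5 candidate
donors, each univariate model conditioning on all other confounders, Z and
Y. m = 10 independent chains are run (each seeded separately and burned in
for 5 full sweeps) rather than taking consecutive states of one chain.
Imputed values are always observed donor values, so binary columns remain
binary by construction. Imputation is not run separately by treatment arm;
Z as a predictor in every univariate model plays that role.

## Pattern pooling

The missingness pattern of a row is its indicator vector. Patterns with at
least `min_size` = 100 members stand alone as groups. Smaller patterns are
agglomerated among themselves: repeatedly, the smallest cluster merges with
the closest other small cluster — Euclidean distance between representative
(largest-member) pattern vectors, ties to the larger cluster and then the
lexicographically smaller pattern — until every pooled cluster reaches
`min_size`. An undersized leftover is absorbed into the nearest settled
group; if the data cannot reach `min_size` at all, all rows form one group.
Keeping large patterns out of the small-pattern agglomeration is what makes
MP methods genuinely stratified at realistic missing rates; merging small
patterns straight into the large ones collapses nearly every design to a
single stratum (it is almost always at distance 1 from the fully observed
pattern), reducing MP to plain PSA.

## Propensity scores, weights, estimation

Logistic scores are maximum-likelihood fits (statsmodels); when the
likelihood fails (separation), a ridge-penalised refit is used and logged.
Forest scores are out-of-bag treated-class proportions, clipped to
[0.005, 0.995] by default because forest votes frequently reach 0/1;
logistic scores are unclipped by default. The MP estimator mean-fills
missing cells from overall observed column means before the per-group fits
(a variant restricts each group to its fully observed columns); within a
group, columns that no longer vary are dropped. Groups with a single
treatment class are failures: their rows receive NaN scores and downstream
estimation drops them, with the failure surfaced and, in the Monte Carlo
driver, counted per method.

ATE weights are Z/e + (1−Z)/(1−e); ATT weights Z + (1−Z)e/(1−e). The effect
is the Hájek (weight-normalised) difference of weighted outcome means —
invariant to rescaling all weights — with a standard error from Taylor
linearisation of the two ratio means under a with-replacement design, no
finite-population correction, and no propagation of propensity-model
uncertainty (the survey-analysis convention). Rubin's rules pool
multiple-imputation chains: T = W + (1 + 1/m)B. Balance is the absolute
weighted mean difference over the unweighted pooled SD √((s₁²+s₀²)/2), with
means and SDs averaged across imputed copies first; the 0.05 threshold
flags imbalance. The weighted Poisson ATT model log E[Y] = γ₀ + γ₁Z uses a
sandwich standard error; unweighted, γ₁ is exactly log(Ȳ₁/Ȳ₀).

## Monte Carlo study and metrics

For R replications of a condition, each method chain runs end to end per
the method definitions above; pre-imputation chains (PI-I, PI-U, DFPI) use
a logistic propensity model that includes the missing indicators by default
(`ps_indicators=False` drops them). Metrics: RB(d) = mean((d_r − δ)/δ);
RB(SE) = (mean SE_r − SD(d))/SD(d) with SD(d) the empirical SD across
replications; MSE = mean((d_r − δ)²), which satisfies MSE = bias² +
population variance exactly. Cells are flagged acceptable at |RB| < 0.05
and |RB(SE)| ≤ 0.1. Factorial effect sizes on cell-level summaries use
type-II sums of squares over the declared main effects and interactions;
PEV is each effect's share of the modeled effect SS, and η²G divides by
modeled-plus-residual SS — an approximation, since the residual of a
cell-means fit is not a replication-level mixed-model error term, and it is
labelled as such.

## Problem sizes

The default test suite runs reduced designs (tens of replications, forests
of 25–150 trees, n ≤ 2000). The reproduction script uses 50 replications
per sub-condition, 100-tree forests, and caps DFPI at 2 proximity
iterations — forest refits dominate its cost and the imputation stabilises
within the first passes — while library defaults remain B = 500 and 10
iterations. Scaled-down relative-bias estimates carry Monte Carlo standard
errors of roughly 0.03–0.06, which should be kept in mind when comparing
cells.

## Known limitations

* The exchangeable(0.2) correlation stand-in shifts cell-level magnitudes
  relative to designs built on an empirical covariance; qualitative method
  orderings are robust in our runs, exact cell values are not.
* DFPI is a single-imputation method; its linearised SE does not reflect
  imputation uncertainty (only the MIMP chains do, via Rubin's rules).
* The linearised SE treats weights as fixed; with an estimated propensity
  model it is mildly conservative on complete data (ratio ≈ 0.96–1.05 to
  the empirical SD in our calibrated conditions) and can be anti-
  conservative for pattern-stratified fits with many covariates.
* η²G is approximate (see above); a faithful mixed-design decomposition
  would need replication-level outcomes.
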