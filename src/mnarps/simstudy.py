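"""Monte Carlo orchestration over conditions × methods and outcome metrics.

For each replication of a condition the module generates a dataset, imposes
missingness, runs every requested method chain, and summarises the estimates
into the study's outcome metrics: relative bias of the effect RB(d), relative
bias of the estimated standard error against the empirical SD RB(SE), and
mean squared error. Cell-level summaries can be decomposed into factorial
effect sizes (generalized eta-squared and proportion of effect variance).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .imputers import ImputationConfig
from .model import ChainConfig, MissingConfounderPSA
from .simgen import ModelParams, SimulationConfig, calibrate_coefficients, simulate_dataset

logger = logging.getLogger(__name__)

# the acceptability thresholds used when flagging cells
RB_ACCEPTABLE = 0.05
RB_SE_ACCEPTABLE = 0.1


@dataclass
class MethodSummary:
    method: str
    rb: float
    rb_se: float
    mse: float
    mean_estimate: float
    empirical_sd: float
    mean_se: float
    n_success: int
    n_failed: int
    estimates: np.ndarray = field(repr=False, default=None)
    ses: np.ndarray = field(repr=False, default=None)


@dataclass
class ConditionSummary:
    config: SimulationConfig
    R: int
    methods: dict[str, MethodSummary]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, s in self.methods.items():
            rows.append(
                {
                    "n": self.config.n, "p": self.config.p,
                    "missing_rate": self.config.missing_rate,
                    "mechanism": self.config.mechanism,
                    "method": name, "RB": s.rb, "RB_SE": s.rb_se, "MSE": s.mse,
                    "mean_estimate": s.mean_estimate,
                    "empirical_sd": s.empirical_sd, "mean_se": s.mean_se,
                    "R": self.R, "failures": s.n_failed,
                    "rb_acceptable": abs(s.rb) < RB_ACCEPTABLE if np.isfinite(s.rb) else False,
                    "rb_se_acceptable": abs(s.rb_se) <= RB_SE_ACCEPTABLE if np.isfinite(s.rb_se) else False,
                }
            )
        return pd.DataFrame(rows)


def summarize_metrics(
    estimates: np.ndarray, ses: np.ndarray, delta: float
) -> tuple[float, float, float]:
    """RB(d) = mean((d_r − δ)/δ); RB(SE) = (mean SE_r − SD(d))/SD(d);
    MSE = mean((d_r − δ)²)."""
    if delta == 0:
        raise ValueError("relative bias undefined for delta = 0")
    d = np.asarray(estimates, dtype=float)
    s = np.asarray(ses, dtype=float)
    rb = float(((d - delta) / delta).mean())
    mse = float(((d - delta) ** 2).mean())
    if d.size >= 2:
        sd = float(d.std(ddof=1))
        rb_se = float((s.mean() - sd) / sd) if sd > 0 else np.nan
    else:
        rb_se = np.nan
    return rb, rb_se, mse


def run_method_chain(
    dataset, method: str, chain: ChainConfig
):
    """Fit one method on one dataset; returns (estimate, se) or raises."""
    res = MissingConfounderPSA.from_generated(dataset, method=method, config=chain).fit()
    if not np.isfinite(res.estimate) or not np.isfinite(res.se):
        raise RuntimeError(f"{method}: non-finite estimate")
    return res.estimate, res.se


def run_condition(
    config: SimulationConfig,
    methods: Sequence[str],
    R: int,
    seed: Optional[int] = None,
    chain: Optional[ChainConfig] = None,
    fix_coefficients: bool = False,
) -> ConditionSummary:
    """R replications of one condition for a set of method chains.

    Per replication the population coefficients are redrawn by default
    (``fix_coefficients`` reuses one calibrated draw and varies only the data
    seed). Replications where a method fails (for example a pooled pattern
    group with a single treatment class leaving an arm empty) are excluded
    from that method's summary and counted.
    """
    if R < 1:
        raise ValueError("R must be >= 1")
    master = config.seed if seed is None else seed
    rep_seeds = np.random.SeedSequence([int(master), 99]).generate_state(R) % (2**31)
    base_chain = chain or ChainConfig.default(seed=int(master))
    shared_params: Optional[ModelParams] = None
    if fix_coefficients:
        shared_params = calibrate_coefficients(replace(config, seed=int(master)))

    collected: dict[str, list[tuple[float, float]]] = {m: [] for m in methods}
    failures: dict[str, int] = {m: 0 for m in methods}
    for r in range(R):
        rs = int(rep_seeds[r])
        if fix_coefficients:
            ds, _ = simulate_dataset(
                replace(config, seed=int(master)), params=shared_params, data_seed=rs
            )
        else:
            ds, _ = simulate_dataset(replace(config, seed=rs))
        rep_chain = replace(
            base_chain, imputation=replace(base_chain.imputation, seed=rs)
        )
        for m in methods:
            try:
                collected[m].append(run_method_chain(ds, m, rep_chain))
            except Exception as err:
                failures[m] += 1
                logger.warning("replication %d method %s failed: %s", r, m, err)

    summaries: dict[str, MethodSummary] = {}
    for m in methods:
        pairs = collected[m]
        if not pairs:
            summaries[m] = MethodSummary(
                method=m, rb=np.nan, rb_se=np.nan, mse=np.nan,
                mean_estimate=np.nan, empirical_sd=np.nan, mean_se=np.nan,
                n_success=0, n_failed=failures[m],
                estimates=np.array([]), ses=np.array([]),
            )
            continue
        d = np.array([p[0] for p in pairs])
        s = np.array([p[1] for p in pairs])
        rb, rb_se, mse = summarize_metrics(d, s, config.delta)
        summaries[m] = MethodSummary(
            method=m, rb=rb, rb_se=rb_se, mse=mse,
            mean_estimate=float(d.mean()),
            empirical_sd=float(d.std(ddof=1)) if d.size > 1 else np.nan,
            mean_se=float(s.mean()),
            n_success=len(pairs), n_failed=failures[m],
            estimates=d, ses=s,
        )
    return ConditionSummary(config=config, R=R, methods=summaries)


def run_study(
    base: SimulationConfig,
    methods: Sequence[str],
    R: int,
    ns: Sequence[int],
    ps: Sequence[int],
    rates: Sequence[float],
    mechanisms: Sequence[str],
    seed: int = 0,
    chain: Optional[ChainConfig] = None,
) -> pd.DataFrame:
    """Fully crossed study; returns the long-format condition × method table."""
    frames = []
    ss = np.random.SeedSequence([int(seed), 7])
    cells = [
        (n, p, rate, mech)
        for n in ns for p in ps for rate in rates for mech in mechanisms
    ]
    cell_seeds = ss.generate_state(len(cells)) % (2**31)
    for (n, p, rate, mech), cs in zip(cells, cell_seeds):
        cfg = replace(base, n=n, p=p, missing_rate=rate, mechanism=mech, seed=int(cs))
        frames.append(run_condition(cfg, methods, R, chain=chain).to_frame())
    return pd.concat(frames, ignore_index=True)


@dataclass
class EffectSizeTable:
    table: pd.DataFrame  # effect, sum_sq, eta2_g, pev

    def __getitem__(self, effect: str) -> pd.Series:
        return self.table.set_index("effect").loc[effect]


def anova_effect_sizes(
    cell_data: pd.DataFrame,
    outcome: str,
    factors: Sequence[str],
    interactions: Optional[Sequence[tuple[str, ...]]] = None,
) -> EffectSizeTable:
    """Fixed-effects factorial decomposition of cell-level outcomes.

    Computes type-II sums of squares for the main effects and the declared
    interactions; η²G (approximate: the SS_error term is the residual of this
    cell-means fit, not a replication-level mixed-model error) and PEV =
    SS_effect / Σ SS_effects over the modeled effects.
    """
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    df = cell_data.copy()
    # require a complete crossed design
    sizes = df.groupby(list(factors), observed=True).size()
    expected = int(np.prod([df[f].nunique() for f in factors]))
    if sizes.size != expected:
        missing = expected - sizes.size
        raise ValueError(f"incomplete factorial design: {missing} empty cell(s)")
    if np.allclose(df[outcome].var(ddof=0), 0.0):
        raise ValueError("outcome is constant across cells; effect sizes undefined")

    terms = [f"C({f})" for f in factors]
    for inter in interactions or []:
        terms.append(":".join(f"C({f})" for f in inter))
    formula = f"{outcome} ~ " + " + ".join(terms)
    fit = smf.ols(formula, data=df).fit()
    tab = anova_lm(fit, typ=2)
    ss_error = float(tab.loc["Residual", "sum_sq"])
    effects = tab.drop(index="Residual")
    ss = effects["sum_sq"].astype(float)
    total_effect_ss = float(ss.sum())
    denom = total_effect_ss + ss_error
    out = pd.DataFrame(
        {
            "effect": [e.replace("C(", "").replace(")", "") for e in effects.index],
            "sum_sq": ss.values,
            "eta2_g": ss.values / denom if denom > 0 else np.nan,
            "pev": ss.values / total_effect_ss if total_effect_ss > 0 else np.nan,
        }
    )
    return EffectSizeTable(table=out)
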