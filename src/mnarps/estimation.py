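"""Weighted effect estimation, linearised variance, Rubin pooling, balance.

The effect estimator is the Hájek (weight-normalised) difference of weighted
outcome means between arms. Its standard error comes from Taylor-series
linearisation of the two ratio means under a with-replacement design (no
finite-population correction), treating the weights as fixed — the convention
of survey-package analyses, which deliberately ignores the uncertainty of the
propensity model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .propensity import IpwWeights


@dataclass
class EffectEstimate:
    estimate: float
    se: float
    estimand: str = "ATE"
    n_treated: float = 0.0
    n_control: float = 0.0


@dataclass
class PooledEstimate:
    estimate: float
    se: float
    within: float
    between: float
    total: float
    m: int


@dataclass
class BalanceTable:
    std_diffs: np.ndarray  # absolute standardized differences per covariate
    threshold: float = 0.05
    zero_variance: Optional[np.ndarray] = None

    @property
    def max(self) -> float:
        return float(self.std_diffs.max())

    @property
    def mean(self) -> float:
        return float(self.std_diffs.mean())

    @property
    def n_exceeding(self) -> int:
        return int((self.std_diffs > self.threshold).sum())


def weighted_effect(
    Y: np.ndarray, Z: np.ndarray, weights: IpwWeights
) -> EffectEstimate:
    """Hájek weighted mean difference with linearised (influence-function) SE.

    The influence contribution of row i is
    u_i = Z_i w_i (Y_i − μ̂₁)/Ŵ₁ − (1−Z_i) w_i (Y_i − μ̂₀)/Ŵ₀
    and Var ≈ n/(n−1) Σ (u_i − ū)². Rows with NaN weights (failed PS) are
    dropped. Invariant to rescaling all weights by a positive constant.
    """
    Y = np.asarray(Y, dtype=float)
    Z = np.asarray(Z, dtype=float)
    w = np.asarray(weights.w, dtype=float)
    keep = np.isfinite(w)
    Y, Z, w = Y[keep], Z[keep], w[keep]
    n = Y.size
    w1 = (w * Z).sum()
    w0 = (w * (1 - Z)).sum()
    if w1 <= 0 or w0 <= 0:
        raise ValueError("both arms must carry positive total weight")
    mu1 = (w * Z * Y).sum() / w1
    mu0 = (w * (1 - Z) * Y).sum() / w0
    u = Z * w * (Y - mu1) / w1 - (1 - Z) * w * (Y - mu0) / w0
    var = n / (n - 1) * ((u - u.mean()) ** 2).sum()
    return EffectEstimate(
        estimate=float(mu1 - mu0),
        se=float(np.sqrt(var)),
        estimand=weights.estimand,
        n_treated=float(Z.sum()),
        n_control=float((1 - Z).sum()),
    )


def rubin_pool(estimates: Sequence[float], ses: Sequence[float]) -> PooledEstimate:
    """Rubin's rules: pooled mean, within W = mean(se²), between B = sample
    variance of the estimates, total T = W + (1 + 1/m)B."""
    estimates = np.asarray(estimates, dtype=float)
    ses = np.asarray(ses, dtype=float)
    m = estimates.size
    if m < 2:
        raise ValueError("Rubin pooling needs m >= 2 estimates")
    W = float((ses**2).mean())
    B = float(estimates.var(ddof=1))
    T = W + (1.0 + 1.0 / m) * B
    return PooledEstimate(
        estimate=float(estimates.mean()), se=float(np.sqrt(T)),
        within=W, between=B, total=T, m=m,
    )


def _weighted_mean(x, z, w):
    return (w * z * x).sum() / (w * z).sum()


def balance_table(
    X: np.ndarray,
    Z: np.ndarray,
    weights: IpwWeights,
    threshold: float = 0.05,
    imputation_sets: Optional[Sequence[np.ndarray]] = None,
) -> BalanceTable:
    """Absolute weighted standardized mean differences per covariate.

    The numerator is the weighted arm-mean difference; the denominator is the
    unweighted pooled SD sqrt((s₁² + s₀²)/2). With ``imputation_sets`` the
    means and SDs are averaged across the completed copies before the ratio.
    Zero-variance covariates report 0 with a flag.
    """
    Z = np.asarray(Z, dtype=float)
    w = np.asarray(weights.w, dtype=float)
    keep = np.isfinite(w)
    sets = [np.asarray(X, dtype=float)] if imputation_sets is None else [
        np.asarray(x, dtype=float) for x in imputation_sets
    ]
    diffs, sds = [], []
    for Xi in sets:
        Xi, Zi, wi = Xi[keep], Z[keep], w[keep]
        d = np.array([
            _weighted_mean(Xi[:, j], Zi, wi) - _weighted_mean(Xi[:, j], 1 - Zi, wi)
            for j in range(Xi.shape[1])
        ])
        s1 = Xi[Zi == 1].std(axis=0, ddof=1)
        s0 = Xi[Zi == 0].std(axis=0, ddof=1)
        diffs.append(d)
        sds.append(np.sqrt((s1**2 + s0**2) / 2.0))
    mean_diff = np.mean(diffs, axis=0)
    mean_sd = np.mean(sds, axis=0)
    zero_var = mean_sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        std = np.where(zero_var, 0.0, np.abs(mean_diff) / mean_sd)
    return BalanceTable(std_diffs=std, threshold=threshold, zero_variance=zero_var)


def common_support_summary(scores: np.ndarray, Z: np.ndarray) -> dict:
    """Numeric overlap diagnostics: per-arm PS min/max/quartiles."""
    e = np.asarray(scores, dtype=float)
    Z = np.asarray(Z, dtype=float)
    qs = [0.0, 0.25, 0.5, 0.75, 1.0]
    out = {}
    for arm, mask in (("treated", Z == 1), ("control", Z == 0)):
        vals = e[mask & np.isfinite(e)]
        out[arm] = {f"q{int(q * 100)}": float(np.quantile(vals, q)) for q in qs}
    return out


def poisson_att(
    Y: np.ndarray, Z: np.ndarray, weights: IpwWeights
) -> EffectEstimate:
    """Weighted Poisson regression log E[Y] = γ₀ + γ₁Z; returns γ₁ with a
    sandwich (linearised) SE. Unweighted, γ₁ is exactly log(Ȳ₁/Ȳ₀)."""
    import statsmodels.api as sm

    Y = np.asarray(Y, dtype=float)
    Z = np.asarray(Z, dtype=float)
    w = np.asarray(weights.w, dtype=float)
    keep = np.isfinite(w)
    Y, Z, w = Y[keep], Z[keep], w[keep]
    if (Y < 0).any():
        raise ValueError("Poisson outcome must be non-negative")
    if not (Y > 0).any():
        raise ValueError("outcome is all zero")
    design = sm.add_constant(Z)
    model = sm.GLM(Y, design, family=sm.families.Poisson(), freq_weights=w)
    res = model.fit(cov_type="HC0")
    return EffectEstimate(
        estimate=float(res.params[1]),
        se=float(res.bse[1]),
        estimand="ATT",
        n_treated=float(Z.sum()),
        n_control=float((1 - Z).sum()),
    )
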