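"""Model/results interface for propensity-score analysis with missing
confounders.

``MissingConfounderPSA`` is constructed from one observational dataset
(confounders with missing cells, binary treatment, continuous outcome) and a
method name; ``fit()`` runs the method's impute → propensity → weight →
estimate chain and returns a ``PSAResults`` carrying the effect estimate, its
linearised (or Rubin-pooled) standard error, the propensity scores, weights
and diagnostics.

Methods
-------
``MP-LR`` / ``MP-RF``
    No imputation; separate logistic / forest PS model per pooled missingness
    pattern group (minimum group size 100 by default).
``MIMP-LR`` / ``MIMP-RF``
    MICE-PMM multiple imputation; PS on each completed copy with missing
    indicators; Rubin's-rule pooling of the m effect estimates.
``PI-I`` / ``PI-U`` / ``DFPI``
    Proximity-based single pre-imputation (supervised / unsupervised /
    dual-forest), then a logistic PS model; indicators are included in the PS
    model by default (``ps_indicators=False`` drops them).
``plain``
    No missingness handling; PS directly on the covariates (requires a
    complete table). The no-missing-data reference all methods collapse to.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import estimation, imputers, patterns, propensity
from .imputers import CompletedDataset, ImputationConfig, MultipleImputationSet
from .simgen import GeneratedDataset

METHODS = ("MP-LR", "MIMP-LR", "MP-RF", "MIMP-RF", "PI-I", "PI-U", "DFPI", "plain")


@dataclass
class ChainConfig:
    """Knobs shared by the method chains."""

    imputation: ImputationConfig
    min_pattern_size: int = 100
    ps_trees: int = 500
    ps_indicators: bool = True
    estimand: str = "ATE"
    restrict_mp_columns: bool = False

    @classmethod
    def default(cls, seed: int = 0, n_trees: int = 500, **kw) -> "ChainConfig":
        return cls(imputation=ImputationConfig(seed=seed, n_trees=n_trees), **kw)


class PSAResults:
    """Results of one fitted chain (statsmodels-flavoured)."""

    def __init__(
        self,
        model: "MissingConfounderPSA",
        estimate: float,
        se: float,
        scores,
        weights,
        imputed: Union[CompletedDataset, MultipleImputationSet, None],
        pooled: Optional[estimation.PooledEstimate] = None,
        failed_groups: Optional[list[int]] = None,
    ) -> None:
        self.model = model
        self.estimate = estimate
        self.se = se
        self.bse = se  # statsmodels-style alias
        self.method = model.method
        self.estimand = model.config.estimand
        self.scores = scores
        self.weights = weights
        self.imputed = imputed
        self.pooled = pooled
        self.failed_groups = failed_groups or []

    def conf_int(self, alpha: float = 0.05) -> tuple[float, float]:
        from scipy.stats import norm

        z = norm.ppf(1 - alpha / 2)
        return self.estimate - z * self.se, self.estimate + z * self.se

    def _completed_sets(self) -> list[np.ndarray]:
        if isinstance(self.imputed, MultipleImputationSet):
            return [d.X_imputed for d in self.imputed.datasets]
        if isinstance(self.imputed, CompletedDataset):
            return [self.imputed.X_imputed]
        return [self.model.X_observed]

    def balance(self, threshold: float = 0.05) -> estimation.BalanceTable:
        """Post-weighting covariate balance (averaged over imputed copies)."""
        sets = self._completed_sets()
        w = self.weights[0] if isinstance(self.weights, list) else self.weights
        return estimation.balance_table(
            sets[0], self.model.Z, w, threshold=threshold,
            imputation_sets=sets if len(sets) > 1 else None,
        )

    def common_support(self) -> dict:
        e = self.scores[0].e if isinstance(self.scores, list) else self.scores.e
        return estimation.common_support_summary(e, self.model.Z)

    def summary(self) -> str:
        lo, hi = self.conf_int()
        lines = [
            "Propensity score analysis with missing confounders",
            "=" * 52,
            f"Method:        {self.method}",
            f"Estimand:      {self.estimand}",
            f"N:             {self.model.n} "
            f"(treated {int(self.model.Z.sum())}, "
            f"control {int((1 - self.model.Z).sum())})",
            f"Estimate:      {self.estimate: .4f}",
            f"Std. error:    {self.se: .4f}",
            f"95% CI:        [{lo: .4f}, {hi: .4f}]",
        ]
        if self.pooled is not None:
            lines += [
                f"MI pooling:    m={self.pooled.m}, within={self.pooled.within:.5f}, "
                f"between={self.pooled.between:.5f}",
            ]
        if self.failed_groups:
            lines.append(f"Failed groups: {self.failed_groups}")
        bal = self.balance()
        lines += [
            f"Balance:       max |SMD| {bal.max:.3f}, mean {bal.mean:.3f}, "
            f"{bal.n_exceeding} covariate(s) > {bal.threshold}",
        ]
        return "\n".join(lines)


class MissingConfounderPSA:
    """Propensity-score analysis of one dataset with MNAR-prone confounders.

    Parameters
    ----------
    X_observed : (n, p) confounder table with NaN for missing cells.
    Z : binary treatment vector; must be fully observed.
    Y : continuous outcome vector; must be fully observed.
    column_types : "continuous"/"binary" per column; inferred from the
        observed values when omitted.
    method : one of ``METHODS``.
    config : chain configuration; ``ChainConfig.default(seed)`` when omitted.
    """

    def __init__(
        self,
        X_observed: np.ndarray,
        Z: np.ndarray,
        Y: np.ndarray,
        column_types: Optional[Sequence[str]] = None,
        method: str = "DFPI",
        config: Optional[ChainConfig] = None,
    ) -> None:
        if method not in METHODS:
            raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
        self.X_observed = np.asarray(X_observed, dtype=float)
        self.Z = np.asarray(Z, dtype=float)
        self.Y = np.asarray(Y, dtype=float)
        if np.isnan(self.Z).any() or np.isnan(self.Y).any():
            raise ValueError("treatment and outcome must be fully observed")
        if set(np.unique(self.Z)) - {0.0, 1.0}:
            raise ValueError("treatment must be binary 0/1")
        self.S = np.isnan(self.X_observed)
        self.column_types = (
            list(column_types) if column_types is not None
            else infer_column_types(self.X_observed)
        )
        self.method = method
        self.config = config or ChainConfig.default()

    @property
    def n(self) -> int:
        return self.X_observed.shape[0]

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        covariates: Sequence[str],
        treatment: str = "z",
        outcome: str = "y",
        **kwargs,
    ) -> "MissingConfounderPSA":
        return cls(
            df[list(covariates)].to_numpy(dtype=float),
            df[treatment].to_numpy(dtype=float),
            df[outcome].to_numpy(dtype=float),
            **kwargs,
        )

    @classmethod
    def from_generated(
        cls, ds: GeneratedDataset, method: str = "DFPI",
        config: Optional[ChainConfig] = None,
    ) -> "MissingConfounderPSA":
        return cls(
            ds.X_observed, ds.Z, ds.Y, column_types=ds.column_types,
            method=method, config=config,
        )

    # ------------------------------------------------------------------ fit
    def fit(self) -> PSAResults:
        method = self.method
        cfg = self.config
        seed = cfg.imputation.seed
        if method == "plain":
            if self.S.any():
                raise ValueError("'plain' requires a complete covariate table")
            scores = propensity.estimate_propensity(
                self.X_observed, self.Z, model="lr",
            )
            return self._single(scores, imputed=None)
        if method in ("MP-LR", "MP-RF"):
            table = patterns.extract_patterns(self.S)
            pooling = patterns.pool_patterns(table, min_size=cfg.min_pattern_size)
            scores = propensity.mp_propensity(
                self.X_observed, self.S, self.Z, table, pooling,
                model="lr" if method == "MP-LR" else "rf",
                n_trees=cfg.ps_trees, seed=seed,
                restrict_columns=cfg.restrict_mp_columns,
            )
            return self._single(scores, imputed=None,
                                failed_groups=scores.failed_groups)
        if method in ("MIMP-LR", "MIMP-RF"):
            mi = imputers.mice_pmm_impute(
                self.X_observed, self.S, self.Z, self.Y, self.column_types,
                cfg.imputation,
            )
            ests, ses, score_list, weight_list = [], [], [], []
            for k, comp in enumerate(mi.datasets):
                scores = propensity.estimate_propensity(
                    comp.X_imputed, self.Z,
                    model="lr" if method == "MIMP-LR" else "rf",
                    indicators=self.S.astype(float),
                    n_trees=cfg.ps_trees, seed=None if seed is None else seed + k,
                )
                w = propensity.ipw_weights(scores, self.Z, cfg.estimand)
                eff = estimation.weighted_effect(self.Y, self.Z, w)
                ests.append(eff.estimate)
                ses.append(eff.se)
                score_list.append(scores)
                weight_list.append(w)
            pooled = estimation.rubin_pool(ests, ses)
            return PSAResults(
                self, pooled.estimate, pooled.se, score_list, weight_list,
                imputed=mi, pooled=pooled,
            )
        # pre-imputation chains
        if method == "DFPI":
            comp = imputers.dfpi_impute(
                self.X_observed, self.S, self.Z, self.Y, self.column_types,
                cfg.imputation,
            )
        elif method == "PI-I":
            comp = imputers.pi_i_impute(
                self.X_observed, self.S, self.Z, self.Y, self.column_types,
                cfg.imputation,
            )
        else:  # PI-U
            comp = imputers.pi_u_impute(
                self.X_observed, self.S, self.column_types, cfg.imputation,
            )
        indicators = self.S.astype(float) if cfg.ps_indicators else None
        scores = propensity.estimate_propensity(
            comp.X_imputed, self.Z, model="lr", indicators=indicators,
        )
        return self._single(scores, imputed=comp)

    def _single(self, scores, imputed, failed_groups=None) -> PSAResults:
        w = propensity.ipw_weights(scores, self.Z, self.config.estimand)
        eff = estimation.weighted_effect(self.Y, self.Z, w)
        return PSAResults(
            self, eff.estimate, eff.se, scores, w, imputed=imputed,
            failed_groups=failed_groups,
        )


def infer_column_types(X: np.ndarray) -> list[str]:
    """A column whose observed values are a subset of {0, 1} is binary."""
    types = []
    for j in range(X.shape[1]):
        obs = X[~np.isnan(X[:, j]), j]
        types.append("binary" if np.isin(obs, (0.0, 1.0)).all() else "continuous")
    return types
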