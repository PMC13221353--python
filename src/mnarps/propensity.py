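"""Propensity-score estimation and inverse-probability weights.

Logistic-regression scores are maximum-likelihood fits (with a ridge-penalised
fallback when the likelihood does not converge, e.g. under separation).
Random-forest scores are out-of-bag treated-class proportions, clipped away
from 0/1 by default because forest votes are frequently extreme. The
missingness-pattern (MP) estimator fits a separate model per pooled pattern
group after mean-filling missing cells from overall observed column means
(optionally restricting each group to its fully observed columns instead).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import statsmodels.api as sm

from .forests import fit_supervised_forest
from .patterns import PatternPooling, PatternTable

logger = logging.getLogger(__name__)

RF_CLIP = (0.005, 0.995)


@dataclass
class PropensityScores:
    e: np.ndarray
    model: str = "lr"
    clipped: bool = False
    failed_groups: list[int] = field(default_factory=list)

    @property
    def n_failed_rows(self) -> int:
        return int(np.isnan(self.e).sum())


@dataclass
class IpwWeights:
    w: np.ndarray
    estimand: str = "ATE"


def _drop_constant_columns(F: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    keep = F.std(axis=0) > 0
    return F[:, keep], keep


def _logit_fit(F: np.ndarray, Z: np.ndarray) -> np.ndarray:
    """MLE logistic scores with a penalised fallback on failure."""
    design = sm.add_constant(F, has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(Z, design).fit(disp=0, maxiter=200)
            if np.isfinite(res.params).all():
                return np.asarray(res.predict(design))
        except Exception:
            pass
    logger.warning("logistic MLE failed (separation?); ridge-penalised refit")
    from sklearn.linear_model import LogisticRegression

    clf = LogisticRegression(C=100.0, max_iter=2000)
    clf.fit(F, Z)
    return clf.predict_proba(F)[:, 1]


def estimate_propensity(
    X_complete: np.ndarray,
    Z: np.ndarray,
    model: str = "lr",
    indicators: Optional[np.ndarray] = None,
    n_trees: int = 500,
    seed: Optional[int] = None,
    clip: Optional[tuple[float, float]] = None,
) -> PropensityScores:
    """PS on a completed covariate table, optionally augmented with missing
    indicators. ``clip`` defaults to no clipping for LR and to ``RF_CLIP``
    for forests."""
    X = np.asarray(X_complete, dtype=float)
    if np.isnan(X).any():
        raise ValueError("X_complete has missing cells; impute first")
    Z = np.asarray(Z, dtype=float)
    if np.unique(Z).size < 2:
        raise ValueError("treatment is constant")
    F = X
    if indicators is not None:
        F = np.hstack([X, np.asarray(indicators, dtype=float)])
    F, _ = _drop_constant_columns(F)
    clipped = False
    if model == "lr":
        e = _logit_fit(F, Z)
        if clip is not None:
            e = np.clip(e, *clip)
            clipped = True
    elif model == "rf":
        forest = fit_supervised_forest(
            F, Z.astype(int), task="classification", n_trees=n_trees,
            seed=seed, oob=True,
        )
        proba = forest.oob_probabilities()
        classes = forest.estimator.classes_
        e = proba[:, int(np.flatnonzero(classes == 1)[0])]
        # rows never OOB yield NaN rows in sklearn; fall back to in-bag votes
        bad = ~np.isfinite(e)
        if bad.any():
            e[bad] = forest.estimator.predict_proba(F[bad])[:, 1]
        lo, hi = clip if clip is not None else RF_CLIP
        e = np.clip(e, lo, hi)
        clipped = True
    else:
        raise ValueError("model must be 'lr' or 'rf'")
    return PropensityScores(e=e, model=model, clipped=clipped)


def mp_propensity(
    X_observed: np.ndarray,
    S: np.ndarray,
    Z: np.ndarray,
    table: PatternTable,
    pooling: PatternPooling,
    model: str = "lr",
    n_trees: int = 500,
    seed: Optional[int] = None,
    restrict_columns: bool = False,
    clip: Optional[tuple[float, float]] = None,
) -> PropensityScores:
    """Missingness-pattern PS: one model per pooled pattern group.

    Missing cells are first filled with the overall observed column means;
    within each group the model uses all covariates whose filled values still
    vary there (with ``restrict_columns`` the group is instead limited to
    columns fully observed in every one of its rows). Groups where treatment
    is single-class are recorded as failures and their rows get NaN scores.
    """
    X = np.asarray(X_observed, dtype=float)
    S_arr = np.asarray(S, dtype=bool)
    Z = np.asarray(Z, dtype=float)
    n = X.shape[0]
    col_means = np.nanmean(np.where(S_arr, np.nan, X), axis=0)
    filled = np.where(S_arr, col_means[None, :], X)

    groups = pooling.row_groups(table)
    e = np.full(n, np.nan)
    failed: list[int] = []
    for g in range(pooling.n_groups):
        rows = groups == g
        Zg = Z[rows]
        if np.unique(Zg).size < 2:
            failed.append(g)
            logger.warning("pattern group %d has a single treatment class", g)
            continue
        if restrict_columns:
            cols = ~S_arr[rows].any(axis=0)
            Fg = X[np.ix_(rows, np.flatnonzero(cols))]
        else:
            Fg = filled[rows]
        Fg, _ = _drop_constant_columns(Fg)
        if Fg.shape[1] == 0:
            Fg = np.zeros((rows.sum(), 0))
        sub = estimate_propensity(
            Fg if Fg.shape[1] else np.zeros((int(rows.sum()), 1)),
            Zg, model=model, n_trees=n_trees, seed=seed, clip=clip,
        )
        e[rows] = sub.e
    return PropensityScores(e=e, model=f"mp-{model}", clipped=model == "rf",
                            failed_groups=failed)


def ipw_weights(scores: PropensityScores, Z: np.ndarray, estimand: str = "ATE") -> IpwWeights:
    """Inverse-probability weights: ATE w = Z/e + (1−Z)/(1−e); ATT w = Z +
    (1−Z)e/(1−e)."""
    Z = np.asarray(Z, dtype=float)
    e = np.asarray(scores.e, dtype=float)
    valid = np.isfinite(e)
    if ((e[valid] <= 0) | (e[valid] >= 1)).any():
        raise ValueError("propensity scores at 0 or 1; clip before weighting")
    estimand = estimand.upper()
    if estimand == "ATE":
        w = Z / e + (1.0 - Z) / (1.0 - e)
    elif estimand == "ATT":
        w = Z + (1.0 - Z) * e / (1.0 - e)
    else:
        raise ValueError("estimand must be 'ATE' or 'ATT'")
    return IpwWeights(w=w, estimand=estimand)
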