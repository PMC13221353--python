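"""Pre-imputation engines for confounders with missing cells.

Four proximity/forest-based single imputers plus MICE with predictive mean
matching:

* ``strawman_initialize`` — column median (continuous) / mode (binary) fill,
  the starting point all iterative imputers share.
* ``dfpi_impute`` — dual-forest proximity imputation: at each iteration two
  supervised forests (treatment classification, outcome regression) are fit on
  the current completed confounders augmented with the missing indicators;
  their co-leaf proximity matrices are averaged into a confounder-signified
  proximity with zero diagonal, and every originally-missing cell is replaced
  by a proximity-weighted donor mean (continuous) or weighted category vote
  (binary). Iterates until the relative change over imputed cells is below
  ``tol`` or ``max_iter`` is reached.
* ``pi_i_impute`` — the same iteration driven by a single supervised
  regression forest predicting the outcome from confounders, indicators and
  treatment (exact supplementary algorithm unavailable; this follows the
  main-text description).
* ``pi_u_impute`` — the same iteration driven by an unsupervised
  (synthetic-class) forest on confounders and indicators only; uses no
  treatment or outcome information.
* ``mice_pmm_impute`` — m independent chained-equation imputations, each
  univariate model conditioning on all other confounders, treatment and
  outcome, with predictive-mean-matching donors.

Observed cells are never altered by any imputer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .forests import (
    ProximityMatrix,
    combine_proximities,
    fit_supervised_forest,
    fit_unsupervised_forest,
    proximity_from_leaves,
)

logger = logging.getLogger(__name__)


@dataclass
class ImputationConfig:
    """Shared knobs of the imputation engines.

    ``n_trees`` is used per forest (500 matches the forests used throughout;
    smaller values trade proximity stability for speed). ``tol`` is the
    relative-change stopping threshold of the iterative imputers; ``m`` and
    ``pmm_donors`` only matter for MICE.
    """

    n_trees: int = 500
    max_iter: int = 10
    tol: float = 1e-5
    m: int = 10
    pmm_donors: int = 5
    seed: int = 0
    include_treatment_in_outcome_forest: bool = False
    mice_burn_in: int = 5

    def __post_init__(self) -> None:
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


@dataclass
class CompletedDataset:
    """A single completed confounder table plus its iteration trace."""

    X_imputed: np.ndarray
    S: np.ndarray
    trace: list[float] = field(default_factory=list)
    iterations_used: int = 0
    converged: bool = True
    fallback_rows: int = 0


@dataclass
class MultipleImputationSet:
    """m completed copies that agree on every observed cell."""

    datasets: list[CompletedDataset]
    method: str = "mice-pmm"

    @property
    def m(self) -> int:
        return len(self.datasets)


def _validate_inputs(X_observed: np.ndarray, S: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X_observed, dtype=float)
    S = np.asarray(S, dtype=bool)
    if X.shape != S.shape:
        raise ValueError("X_observed and S must have the same shape")
    if np.isnan(X[~S]).any():
        raise ValueError("NaN found in cells marked observed")
    return X, S


def strawman_initialize(
    X_observed: np.ndarray, S: np.ndarray, column_types: Sequence[str]
) -> CompletedDataset:
    """Median fill for continuous columns, observed mode for binary columns."""
    X, S = _validate_inputs(X_observed, S)
    out = X.copy()
    for j, kind in enumerate(column_types):
        miss = S[:, j]
        if not miss.any():
            continue
        obs = X[~miss, j]
        if obs.size == 0:
            raise ValueError(f"column {j} has no observed values to initialize from")
        if kind == "binary":
            vals, counts = np.unique(obs, return_counts=True)
            fill = vals[np.argmax(counts)]
        else:
            fill = np.median(obs)
        out[miss, j] = fill
    return CompletedDataset(X_imputed=out, S=S, iterations_used=0)


def _observed_category_props(
    X_observed_col: np.ndarray, miss: np.ndarray, categories: np.ndarray
) -> np.ndarray:
    obs = X_observed_col[~miss]
    return np.array([(obs == c).mean() for c in categories])


def proximity_weighted_update(
    X_current: np.ndarray,
    S: np.ndarray,
    M: ProximityMatrix,
    column_types: Sequence[str],
) -> CompletedDataset:
    """One proximity-weighted imputation pass over all originally-missing cells.

    Weights are the row-normalised proximities over all donors (donors'
    *current* values are used, so previously imputed donors contribute).
    Continuous cells get the weighted donor mean; binary cells get the
    category maximising observed-proportion × weighted donor support, ties
    resolved toward the lowest category. Rows whose proximities are all zero
    fall back to uniform weights over donors observed in that column.
    """
    X = np.asarray(X_current, dtype=float)
    S = np.asarray(S, dtype=bool)
    P = M.values
    if P.shape != (X.shape[0],) * 2:
        raise ValueError("proximity matrix does not match the data")
    if np.diagonal(P).any():
        raise ValueError("proximity diagonal must be zeroed before imputation")

    row_sums = P.sum(axis=1)
    zero_rows = row_sums == 0.0
    n_fallback = int((zero_rows & S.any(axis=1)).sum())
    if n_fallback:
        logger.warning(
            "%d row(s) with all-zero proximities; falling back to uniform "
            "weights over observed donors", n_fallback,
        )
    safe = np.where(zero_rows, 1.0, row_sums)
    W = P / safe[:, None]

    out = X.copy()
    for j, kind in enumerate(column_types):
        miss = S[:, j]
        if not miss.any():
            continue
        obs_mask = ~miss
        if kind == "binary":
            categories = np.unique(X[obs_mask, j])
            props = _observed_category_props(X[:, j], miss, categories)
            scores = np.empty((miss.sum(), categories.size))
            for ci, c in enumerate(categories):
                ind = (X[:, j] == c).astype(float)
                support = W[miss] @ ind
                # fallback rows: uniform weights over observed donors
                if n_fallback:
                    zr = zero_rows[miss]
                    if zr.any():
                        support[zr] = (ind * obs_mask).sum() / max(obs_mask.sum(), 1)
                scores[:, ci] = props[ci] * support
            # argmax with ties to the lowest category
            out[miss, j] = categories[np.argmax(scores, axis=1)]
        else:
            vals = W[miss] @ X[:, j]
            if n_fallback:
                zr = zero_rows[miss]
                if zr.any():
                    vals[zr] = X[obs_mask, j].mean()
            out[miss, j] = vals
    return CompletedDataset(X_imputed=out, S=S, fallback_rows=n_fallback)


def _relative_change(
    X_new: np.ndarray, X_old: np.ndarray, S: np.ndarray, column_types: Sequence[str]
) -> tuple[float, int]:
    """(relative L1 change over missing continuous cells, count of changed
    missing categorical cells)."""
    cont = np.array([k != "binary" for k in column_types])
    cat = ~cont
    cont_cells = S & cont[None, :]
    cat_cells = S & cat[None, :]
    rel = 0.0
    if cont_cells.any():
        num = np.abs(X_new[cont_cells] - X_old[cont_cells]).sum()
        den = np.abs(X_new[cont_cells]).sum()
        rel = num / den if den > 0 else float(num > 0)
    changed = int((X_new[cat_cells] != X_old[cat_cells]).sum()) if cat_cells.any() else 0
    return rel, changed


def _iterative_proximity_impute(
    X_observed: np.ndarray,
    S: np.ndarray,
    column_types: Sequence[str],
    config: ImputationConfig,
    proximity_fn,
) -> CompletedDataset:
    """Common iteration loop of DFPI / PI-I / PI-U.

    ``proximity_fn(X_aug, iteration)`` must return a ProximityMatrix with a
    zeroed diagonal for the current augmented predictor matrix [X | S].
    """
    X, S = _validate_inputs(X_observed, S)
    if not S.any():
        return CompletedDataset(X_imputed=X.copy(), S=S, iterations_used=0)
    current = strawman_initialize(X, S, column_types).X_imputed
    S_float = S.astype(float)
    trace: list[float] = []
    converged = False
    fallback_rows = 0
    for it in range(config.max_iter):
        X_aug = np.hstack([current, S_float])
        M = proximity_fn(X_aug, it)
        step = proximity_weighted_update(current, S, M, column_types)
        fallback_rows = max(fallback_rows, step.fallback_rows)
        rel, changed = _relative_change(step.X_imputed, current, S, column_types)
        trace.append(rel)
        current = step.X_imputed
        if rel < config.tol and changed == 0:
            converged = True
            break
    if not converged:
        logger.info(
            "proximity imputation stopped at max_iter=%d (last relative change %.3g)",
            config.max_iter, trace[-1] if trace else 0.0,
        )
    return CompletedDataset(
        X_imputed=current, S=S, trace=trace,
        iterations_used=len(trace), converged=converged,
        fallback_rows=fallback_rows,
    )


def dfpi_impute(
    X_observed: np.ndarray,
    S: np.ndarray,
    Z: np.ndarray,
    Y: np.ndarray,
    column_types: Sequence[str],
    config: Optional[ImputationConfig] = None,
) -> CompletedDataset:
    """Dual-forest proximity imputation.

    Treatment forest: classification of Z on [X | S]; outcome forest:
    regression of Y on the same predictors (Z is not among them unless
    ``include_treatment_in_outcome_forest`` is set). Their proximities are
    averaged element-wise with the diagonal zeroed before each
    proximity-weighted pass.
    """
    config = config or ImputationConfig()
    Z = np.asarray(Z)
    Y = np.asarray(Y, dtype=float)
    if set(np.unique(Z)) - {0, 1, 0.0, 1.0}:
        raise ValueError("Z must be binary")
    if np.isnan(Y).any():
        raise ValueError("Y must be fully observed")
    ss = np.random.SeedSequence(config.seed)

    def proximity(X_aug: np.ndarray, it: int) -> ProximityMatrix:
        s_t, s_y = ss.spawn(1)[0].generate_state(2, dtype=np.uint32)
        f_t = fit_supervised_forest(
            X_aug, Z, task="classification", n_trees=config.n_trees,
            seed=int(s_t),
        )
        Y_feats = X_aug
        if config.include_treatment_in_outcome_forest:
            Y_feats = np.hstack([X_aug, np.asarray(Z, float)[:, None]])
        f_y = fit_supervised_forest(
            Y_feats, Y, task="regression", n_trees=config.n_trees, seed=int(s_y),
        )
        m_t = proximity_from_leaves(f_t, X_aug, source="treatment")
        m_y = proximity_from_leaves(f_y, Y_feats, source="outcome")
        return combine_proximities(m_t, m_y)

    return _iterative_proximity_impute(X_observed, S, column_types, config, proximity)


def pi_i_impute(
    X_observed: np.ndarray,
    S: np.ndarray,
    Z: np.ndarray,
    Y: np.ndarray,
    column_types: Sequence[str],
    config: Optional[ImputationConfig] = None,
) -> CompletedDataset:
    """Proximity imputation with indicators via one supervised forest
    (regression of Y on [X | S | Z])."""
    config = config or ImputationConfig()
    Z = np.asarray(Z, dtype=float)
    Y = np.asarray(Y, dtype=float)
    ss = np.random.SeedSequence(config.seed)

    def proximity(X_aug: np.ndarray, it: int) -> ProximityMatrix:
        (s,) = ss.spawn(1)[0].generate_state(1, dtype=np.uint32)
        feats = np.hstack([X_aug, Z[:, None]])
        f = fit_supervised_forest(
            feats, Y, task="regression", n_trees=config.n_trees, seed=int(s)
        )
        return proximity_from_leaves(f, feats, source="outcome").zero_diagonal()

    return _iterative_proximity_impute(X_observed, S, column_types, config, proximity)


def pi_u_impute(
    X_observed: np.ndarray,
    S: np.ndarray,
    column_types: Sequence[str],
    config: Optional[ImputationConfig] = None,
) -> CompletedDataset:
    """Proximity imputation via an unsupervised (synthetic-class) forest on
    [X | S]; treatment and outcome play no role by construction."""
    config = config or ImputationConfig()
    ss = np.random.SeedSequence(config.seed)

    def proximity(X_aug: np.ndarray, it: int) -> ProximityMatrix:
        (s,) = ss.spawn(1)[0].generate_state(1, dtype=np.uint32)
        f = fit_unsupervised_forest(X_aug, n_trees=config.n_trees, seed=int(s))
        return proximity_from_leaves(f, X_aug).zero_diagonal()

    return _iterative_proximity_impute(X_observed, S, column_types, config, proximity)


def mice_pmm_impute(
    X_observed: np.ndarray,
    S: np.ndarray,
    Z: np.ndarray,
    Y: np.ndarray,
    column_types: Sequence[str],
    config: Optional[ImputationConfig] = None,
) -> MultipleImputationSet:
    """m independent MICE chains with predictive mean matching.

    Every univariate imputation model conditions on all other confounders,
    the treatment and the outcome. Each chain runs ``mice_burn_in`` full
    update sweeps before its completed table is taken, so chains are
    independent draws rather than consecutive states of one chain. Imputed
    values are donor values, so binary columns stay in their categories.
    """
    from statsmodels.imputation.mice import MICEData

    config = config or ImputationConfig()
    if config.m < 2:
        raise ValueError("m must be >= 2 for multiple imputation")
    X, S = _validate_inputs(X_observed, S)
    n, p = X.shape
    cols = [f"x{j + 1}" for j in range(p)]
    df = pd.DataFrame(X, columns=cols)
    df["z"] = np.asarray(Z, dtype=float)
    df["y"] = np.asarray(Y, dtype=float)

    datasets: list[CompletedDataset] = []
    if not S.any():
        for _ in range(config.m):
            datasets.append(CompletedDataset(X_imputed=X.copy(), S=S))
        return MultipleImputationSet(datasets=datasets)

    ss = np.random.SeedSequence([int(config.seed), 17])
    chain_seeds = ss.generate_state(config.m, dtype=np.uint32)
    for chain_seed in chain_seeds:
        # MICEData draws from the global numpy RandomState
        state = np.random.get_state()
        try:
            np.random.seed(int(chain_seed))
            md = MICEData(df, k_pmm=config.pmm_donors)
            md.update_all(config.mice_burn_in)
            completed = md.data[cols].to_numpy(dtype=float)
        finally:
            np.random.set_state(state)
        completed[~S] = X[~S]  # guard: observed cells are authoritative
        datasets.append(CompletedDataset(X_imputed=completed, S=S))
    return MultipleImputationSet(datasets=datasets)
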