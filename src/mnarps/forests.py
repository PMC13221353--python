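"""Random-forest adapter and co-leaf proximity engine.

Forests are fitted with scikit-learn; this module adds what the proximity
imputers need on top: stable terminal-node (leaf) retrieval, Breiman's
synthetic-class construction for unsupervised forests, and the n×n proximity
matrix — the proportion of trees in which a pair of observations shares a
terminal node. Proximities are computed per tree by grouping equal leaf ids
(sparse indicator product), which equals the naive per-pair count exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import scipy.sparse as sp
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor


def default_mtry(q: int) -> int:
    """Features considered per split: floor(sqrt(q)), at least 1."""
    return max(1, int(math.isqrt(q)))


@dataclass
class ForestModel:
    """A fitted forest with retrievable terminal-node assignments."""

    task: str  # "classification" | "regression"
    estimator: object
    n_trees: int
    n_features: int
    unsupervised: bool = False

    def leaves(self, features: np.ndarray) -> np.ndarray:
        """Terminal-node id of each row in each tree (n × n_trees)."""
        features = np.asarray(features, dtype=float)
        if features.ndim != 2 or features.shape[1] != self.n_features:
            raise ValueError(
                f"feature schema mismatch: expected {self.n_features} columns, "
                f"got {features.shape}"
            )
        return self.estimator.apply(features)

    def oob_probabilities(self) -> np.ndarray:
        """OOB class probabilities (classification forests fitted with
        ``oob=True``)."""
        if not hasattr(self.estimator, "oob_decision_function_"):
            raise AttributeError("forest was not fitted with oob=True")
        return self.estimator.oob_decision_function_


@dataclass
class ProximityMatrix:
    """Symmetric n×n co-leaf proportions in [0, 1]."""

    values: np.ndarray
    source: str = "unspecified"

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def zero_diagonal(self) -> "ProximityMatrix":
        out = self.values.copy()
        np.fill_diagonal(out, 0.0)
        return ProximityMatrix(values=out, source=self.source)


def _check_complete(features: np.ndarray) -> np.ndarray:
    features = np.asarray(features, dtype=float)
    if features.ndim != 2:
        raise ValueError("features must be a 2-D array")
    if np.isnan(features).any():
        raise ValueError("features contain missing cells; pre-complete them first")
    return features


def fit_supervised_forest(
    features: np.ndarray,
    response: np.ndarray,
    task: str,
    n_trees: int = 500,
    mtry: Optional[int] = None,
    seed: Optional[int] = None,
    oob: bool = False,
    min_samples_leaf: int = 1,
) -> ForestModel:
    """Fit a classification (Gini) or regression (variance-reduction) forest.

    Raises on missing feature cells and on a constant response.
    """
    features = _check_complete(features)
    response = np.asarray(response)
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    if np.unique(response).size < 2:
        raise ValueError("response is constant; nothing to learn")
    if mtry is None:
        mtry = default_mtry(features.shape[1])
    common = dict(
        n_estimators=n_trees,
        max_features=mtry,
        random_state=None if seed is None else int(seed) % (2**32),
        n_jobs=1,
        min_samples_leaf=min_samples_leaf,
        oob_score=oob,
        bootstrap=True,
    )
    if task == "classification":
        est = RandomForestClassifier(criterion="gini", **common)
    elif task == "regression":
        est = RandomForestRegressor(criterion="squared_error", **common)
    else:
        raise ValueError("task must be 'classification' or 'regression'")
    est.fit(features, response)
    return ForestModel(
        task=task, estimator=est, n_trees=n_trees, n_features=features.shape[1]
    )


def fit_unsupervised_forest(
    features: np.ndarray,
    n_trees: int = 500,
    mtry: Optional[int] = None,
    seed: Optional[int] = None,
    min_samples_leaf: int = 1,
) -> ForestModel:
    """Breiman's synthetic-class trick: a shadow copy of the data is formed by
    independently permuting each column, and a classification forest is fit to
    real-vs-shadow. Leaf assignments are then queried for the real rows only,
    so the forest's partition reflects the joint covariate structure without
    any response."""
    features = _check_complete(features)
    n, q = features.shape
    if q == 0:
        raise ValueError("features must have at least one column")
    rng = np.random.default_rng(seed)
    shadow = np.column_stack([rng.permutation(features[:, j]) for j in range(q)])
    stacked = np.vstack([features, shadow])
    labels = np.concatenate([np.ones(n, dtype=int), np.zeros(n, dtype=int)])
    model = fit_supervised_forest(
        stacked, labels, task="classification", n_trees=n_trees, mtry=mtry,
        seed=None if seed is None else int(seed) + 1,
        min_samples_leaf=min_samples_leaf,
    )
    model.unsupervised = True
    return model


def proximity_from_leaf_matrix(leaves: np.ndarray, source: str = "unspecified") -> ProximityMatrix:
    """Proximity from an explicit n × B leaf-id matrix.

    values(i, i') = (1/B) Σ_b 1{leaf_b(i) = leaf_b(i')}, computed per tree by
    one-hot grouping; exactly equal to the brute-force pairwise count.
    """
    leaves = np.asarray(leaves)
    n, B = leaves.shape
    codes = np.empty_like(leaves, dtype=np.int64)
    offsets = 0
    for b in range(B):
        _, inv = np.unique(leaves[:, b], return_inverse=True)
        codes[:, b] = inv + offsets
        offsets += inv.max() + 1
    rows = np.repeat(np.arange(n), B)
    A = sp.csr_matrix(
        (np.ones(n * B), (rows, codes.ravel())), shape=(n, offsets)
    )
    P = np.asarray((A @ A.T).todense()) / B
    return ProximityMatrix(values=P, source=source)


def proximity_from_leaves(
    model: ForestModel, features: np.ndarray, source: Optional[str] = None
) -> ProximityMatrix:
    """Proximity matrix of ``features`` under a fitted forest (all rows; the
    in-bag/OOB distinction is ignored, matching the unconditional count)."""
    leaves = model.leaves(_check_complete(features))
    if source is None:
        source = "unsupervised" if model.unsupervised else model.task
    return proximity_from_leaf_matrix(leaves, source=source)


def proximity_oob_only(
    model: ForestModel, features: np.ndarray, source: Optional[str] = None
) -> ProximityMatrix:
    """Variant counting only trees for which *both* rows of a pair are
    out-of-bag, normalised by the number of such trees (off by default in the
    imputers; relies on reproducing each tree's bootstrap from its seed)."""
    from sklearn.ensemble._forest import (  # type: ignore[attr-defined]
        _generate_unsampled_indices,
        _get_n_samples_bootstrap,
    )

    features = _check_complete(features)
    n = features.shape[0]
    leaves = model.leaves(features)
    est = model.estimator
    n_boot = _get_n_samples_bootstrap(n, est.max_samples)
    agree = np.zeros((n, n))
    counted = np.zeros((n, n))
    for b, tree in enumerate(est.estimators_):
        oob_idx = _generate_unsampled_indices(tree.random_state, n, n_boot)
        mask = np.zeros(n, dtype=bool)
        mask[oob_idx] = True
        both = np.outer(mask, mask)
        counted += both
        same = np.equal.outer(leaves[:, b], leaves[:, b])
        agree += both & same
    with np.errstate(invalid="ignore", divide="ignore"):
        P = np.where(counted > 0, agree / counted, 0.0)
    np.fill_diagonal(P, 1.0)
    if source is None:
        source = "unsupervised" if model.unsupervised else model.task
    return ProximityMatrix(values=P, source=source)


def combine_proximities(
    m_treat: ProximityMatrix, m_outcome: ProximityMatrix
) -> ProximityMatrix:
    """Element-wise average of the treatment- and outcome-forest proximities
    with the diagonal zeroed, so rows are imputed from other observations."""
    if m_treat.values.shape != m_outcome.values.shape:
        raise ValueError("proximity matrices must have the same shape")
    combined = 0.5 * (m_treat.values + m_outcome.values)
    np.fill_diagonal(combined, 0.0)
    return ProximityMatrix(values=combined, source="combined")
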