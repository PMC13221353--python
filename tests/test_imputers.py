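"""Imputation engines: weighted-update arithmetic against brute force,
observed-cell preservation, convergence behaviour, recovery quality."""

import numpy as np
import pytest

from mnarps.forests import ProximityMatrix
from mnarps.imputers import (
    ImputationConfig,
    dfpi_impute,
    mice_pmm_impute,
    pi_i_impute,
    pi_u_impute,
    proximity_weighted_update,
    strawman_initialize,
)


def brute_force_update(X, S, P, column_types):
    """Direct per-cell implementation of the proximity-weighted rules."""
    n, p = X.shape
    out = X.copy()
    for i in range(n):
        denom = sum(P[i, k] for k in range(n) if k != i)
        for j in range(p):
            if not S[i, j]:
                continue
            if denom == 0:
                obs = X[~S[:, j], j]
                if column_types[j] == "binary":
                    cats = np.unique(obs)
                    props = [(obs == c).mean() for c in cats]
                    scores = [props[ci] * props[ci] for ci in range(len(cats))]
                    out[i, j] = cats[int(np.argmax(scores))]
                else:
                    out[i, j] = obs.mean()
                continue
            w = np.array([P[i, k] / denom if k != i else 0.0 for k in range(n)])
            if column_types[j] == "binary":
                cats = np.unique(X[~S[:, j], j])
                obs = X[~S[:, j], j]
                best, best_score = None, -np.inf
                for c in cats:  # ties go to the lowest category
                    score = (obs == c).mean() * (w * (X[:, j] == c)).sum()
                    if score > best_score:
                        best, best_score = c, score
                out[i, j] = best
            else:
                out[i, j] = (w * X[:, j]).sum()
    return out


class TestStrawman:
    def test_median_example(self):
        X = np.array([[1.0], [2.0], [100.0], [np.nan]])
        S = np.isnan(X)
        res = strawman_initialize(X, S, ["continuous"])
        assert res.X_imputed[3, 0] == 2.0

    def test_mode_for_binary(self):
        X = np.array([[0.0], [0.0], [1.0], [np.nan]])
        res = strawman_initialize(X, np.isnan(X), ["binary"])
        assert res.X_imputed[3, 0] == 0.0

    def test_identity_without_missing(self, rng):
        X = rng.standard_normal((10, 3))
        res = strawman_initialize(X, np.zeros_like(X, dtype=bool),
                                  ["continuous"] * 3)
        assert np.array_equal(res.X_imputed, X)

    def test_fully_missing_column_raises(self):
        X = np.array([[np.nan], [np.nan]])
        with pytest.raises(ValueError, match="column 0"):
            strawman_initialize(X, np.isnan(X), ["continuous"])


class TestProximityWeightedUpdate:
    def test_weighted_mean_hand_example(self):
        # donors rows 0 and 2 with proximities 0.2 and 0.6 -> weights 1/4, 3/4
        X = np.array([[1.0], [0.0], [3.0]])
        S = np.array([[False], [True], [False]])
        P = np.array([[0.0, 0.2, 0.1], [0.2, 0.0, 0.6], [0.1, 0.6, 0.0]])
        res = proximity_weighted_update(X, S, ProximityMatrix(P), ["continuous"])
        assert res.X_imputed[1, 0] == pytest.approx(0.25 * 1.0 + 0.75 * 3.0)

    def test_binary_vote_weighted_by_observed_proportion(self):
        # equal proximity support for both categories; observed proportions
        # 0.8 vs 0.2 break the tie toward category 0
        X = np.array([[0.0], [0.0], [0.0], [0.0], [1.0], [np.nan]])
        S = np.isnan(X)
        X_start = np.where(S, 0.0, X)
        P = np.zeros((6, 6))
        P[5, [3, 4]] = [0.5, 0.5]
        P[[3, 4], 5] = 0.5
        res = proximity_weighted_update(X_start, S, ProximityMatrix(P), ["binary"])
        assert res.X_imputed[5, 0] == 0.0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_equals_brute_force_on_random_fixture(self, seed):
        rng = np.random.default_rng(seed)
        n, p = 20, 4
        types = ["continuous", "continuous", "binary", "binary"]
        X = rng.standard_normal((n, p))
        X[:, 2:] = (X[:, 2:] > 0).astype(float)
        S = rng.random((n, p)) < 0.25
        S[:, 0] = False
        X_start = np.where(S, 0.0, X)
        P = rng.random((n, n))
        P = 0.5 * (P + P.T)
        np.fill_diagonal(P, 0.0)
        res = proximity_weighted_update(X_start, S, ProximityMatrix(P), types)
        expected = brute_force_update(X_start, S, P, types)
        assert np.allclose(res.X_imputed, expected)

    def test_zero_proximity_row_fallback(self):
        X = np.array([[1.0], [2.0], [np.nan]])
        S = np.isnan(X)
        X_start = np.where(S, 0.0, X)
        P = np.zeros((3, 3))
        res = proximity_weighted_update(X_start, S, ProximityMatrix(P), ["continuous"])
        assert res.X_imputed[2, 0] == pytest.approx(1.5)
        assert res.fallback_rows == 1

    def test_requires_zero_diagonal(self):
        X = np.zeros((2, 1))
        with pytest.raises(ValueError, match="diagonal"):
            proximity_weighted_update(
                X, np.zeros((2, 1), bool), ProximityMatrix(np.eye(2)), ["continuous"]
            )


class TestIterativeImputers:
    def test_no_missing_is_identity_with_zero_iterations(self, rng):
        X = rng.standard_normal((30, 4))
        S = np.zeros_like(X, dtype=bool)
        Z = (rng.random(30) < 0.4).astype(float)
        Y = X[:, 0] + rng.standard_normal(30)
        types = ["continuous"] * 4
        cfg = ImputationConfig(n_trees=10, seed=0)
        for res in (
            dfpi_impute(X, S, Z, Y, types, cfg),
            pi_i_impute(X, S, Z, Y, types, cfg),
            pi_u_impute(X, S, types, cfg),
        ):
            assert np.array_equal(res.X_imputed, X)
            assert res.iterations_used == 0

    def test_observed_cells_preserved_everywhere(self, small_masked_dataset):
        _, _, ds = small_masked_dataset
        cfg = ImputationConfig(n_trees=25, max_iter=2, m=2, seed=4)
        results = [
            dfpi_impute(ds.X_observed, ds.S, ds.Z, ds.Y, ds.column_types, cfg),
            pi_i_impute(ds.X_observed, ds.S, ds.Z, ds.Y, ds.column_types, cfg),
            pi_u_impute(ds.X_observed, ds.S, ds.column_types, cfg),
        ]
        mi = mice_pmm_impute(ds.X_observed, ds.S, ds.Z, ds.Y, ds.column_types, cfg)
        results.extend(mi.datasets)
        for res in results:
            assert np.array_equal(res.X_imputed[~ds.S], ds.X_complete[~ds.S])
            assert not np.isnan(res.X_imputed).any()

    def test_binary_cells_get_valid_categories(self, small_masked_dataset):
        _, _, ds = small_masked_dataset
        cfg = ImputationConfig(n_trees=25, max_iter=2, seed=4)
        res = dfpi_impute(ds.X_observed, ds.S, ds.Z, ds.Y, ds.column_types, cfg)
        for j, kind in enumerate(ds.column_types):
            if kind == "binary":
                assert np.isin(res.X_imputed[:, j], (0.0, 1.0)).all()

    def test_trace_recorded_and_stops_at_max_iter(self, small_masked_dataset):
        _, _, ds = small_masked_dataset
        cfg = ImputationConfig(n_trees=15, max_iter=3, seed=4)
        res = dfpi_impute(ds.X_observed, ds.S, ds.Z, ds.Y, ds.column_types, cfg)
        assert res.iterations_used == len(res.trace) <= 3
        assert all(t >= 0 for t in res.trace)

    def test_constant_treatment_rejected(self, small_masked_dataset):
        _, _, ds = small_masked_dataset
        with pytest.raises(ValueError):
            dfpi_impute(ds.X_observed, ds.S, np.ones(ds.n), ds.Y,
                        ds.column_types, ImputationConfig(n_trees=5))

    def test_dfpi_beats_strawman_rmse_under_mcar(self, rng):
        """Smooth fixture, Y strongly tied to X, 10% MCAR masking: DFPI's
        imputation error should not exceed median fill's."""
        n, p = 150, 4
        X = rng.standard_normal((n, p))
        X[:, 1] = X[:, 0] + 0.3 * rng.standard_normal(n)
        X[:, 2] = -X[:, 0] + 0.3 * rng.standard_normal(n)
        Y = X @ np.array([1.0, 1.0, -1.0, 0.5]) + 0.2 * rng.standard_normal(n)
        Z = (rng.random(n) < 0.5).astype(float)
        S = rng.random((n, p)) < 0.1
        S[:, 0] = False
        X_obs = np.where(S, np.nan, X)
        types = ["continuous"] * p
        dfpi = dfpi_impute(X_obs, S, Z, Y, types,
                           ImputationConfig(n_trees=100, max_iter=3, seed=0))
        straw = strawman_initialize(X_obs, S, types)
        rmse = lambda M: np.sqrt(np.mean((M[S] - X[S]) ** 2))
        assert rmse(dfpi.X_imputed) <= rmse(straw.X_imputed)

    def test_pi_u_ignores_outcome_and_respects_clusters(self, rng):
        n = 200
        X = np.vstack([
            rng.standard_normal((n // 2, 4)) - 5.0,
            rng.standard_normal((n // 2, 4)) + 5.0,
        ])
        S = rng.random((n, 4)) < 0.1
        S[:, 0] = False
        X_obs = np.where(S, np.nan, X)
        res = pi_u_impute(X_obs, S, ["continuous"] * 4,
                          ImputationConfig(n_trees=150, max_iter=5, seed=1))
        cluster = np.repeat([0, 1], n // 2)
        correct = 0
        for i, j in zip(*np.nonzero(S)):
            lo, hi = (-9, -1) if cluster[i] == 0 else (1, 9)
            correct += lo < res.X_imputed[i, j] < hi
        assert correct / S.sum() >= 0.9


class TestMicePmm:
    def test_returns_m_copies_with_pmm_property(self, small_masked_dataset):
        _, _, ds = small_masked_dataset
        cfg = ImputationConfig(m=3, seed=6)
        mi = mice_pmm_impute(ds.X_observed, ds.S, ds.Z, ds.Y, ds.column_types, cfg)
        assert mi.m == 3
        for comp in mi.datasets:
            for j in range(ds.p):
                observed_vals = ds.X_observed[~ds.S[:, j], j]
                imputed_vals = comp.X_imputed[ds.S[:, j], j]
                assert np.isin(imputed_vals, observed_vals).all()

    def test_chains_differ_but_agree_on_observed(self, small_masked_dataset):
        _, _, ds = small_masked_dataset
        cfg = ImputationConfig(m=2, seed=6)
        mi = mice_pmm_impute(ds.X_observed, ds.S, ds.Z, ds.Y, ds.column_types, cfg)
        a, b = mi.datasets
        assert np.array_equal(a.X_imputed[~ds.S], b.X_imputed[~ds.S])
        assert not np.array_equal(a.X_imputed, b.X_imputed)

    def test_no_missing_yields_identical_copies(self, rng):
        X = rng.standard_normal((40, 3))
        S = np.zeros_like(X, dtype=bool)
        mi = mice_pmm_impute(X, S, (rng.random(40) < 0.3).astype(float),
                             rng.standard_normal(40), ["continuous"] * 3,
                             ImputationConfig(m=2, seed=0))
        assert all(np.array_equal(d.X_imputed, X) for d in mi.datasets)

    def test_m_below_two_rejected(self, small_masked_dataset):
        _, _, ds = small_masked_dataset
        with pytest.raises(ValueError):
            mice_pmm_impute(ds.X_observed, ds.S, ds.Z, ds.Y, ds.column_types,
                            ImputationConfig(m=1))

    def test_reproducible_given_seed(self, small_masked_dataset):
        _, _, ds = small_masked_dataset
        cfg = ImputationConfig(m=2, seed=8)
        a = mice_pmm_impute(ds.X_observed, ds.S, ds.Z, ds.Y, ds.column_types, cfg)
        b = mice_pmm_impute(ds.X_observed, ds.S, ds.Z, ds.Y, ds.column_types, cfg)
        assert np.array_equal(a.datasets[0].X_imputed, b.datasets[0].X_imputed)
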