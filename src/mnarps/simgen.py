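"""Simulated observational data with MAR / MNAR missingness in confounders.

The data-generating process mirrors a standard propensity-score simulation
design: ``p`` confounders drawn from a multivariate standard normal (half of
them dichotomised at 0 into binaries), a logistic treatment-assignment model,
and a linear outcome model with a constant treatment effect ``delta``.
Coefficients are drawn from uniform distributions and rescaled by a single
multiplicative constant so the treatment model reaches a target
McKelvey–Zavoina pseudo-R² and the outcome model a target R²; intercepts are
root-found so the marginal treated proportion and per-column missing rates hit
their targets on a large calibration sample.

Missingness is imposed on columns 2..p (the first confounder is always fully
observed) by one of six mechanisms: MAR (driven by the fully observed X1),
focused-direct MNAR (driven by the value being withheld itself),
focused-indirect MNAR (driven by an unobserved auxiliary), diffuse MNAR
(driven by all confounders), and two diffuse-interaction variants. The missing
indicator convention throughout is ``S = 1`` ⇔ the cell is withheld.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit, logit

MECHANISMS = (
    "MAR",
    "FD_MNAR",
    "FI_MNAR",
    "DF_MNAR",
    "DF_MNAR_INT1",
    "DF_MNAR_INT2",
)

# sub-stream tags for the master seed
_TAG_COEFF = 1
_TAG_CALIB = 2
_TAG_DATA = 3
_TAG_MISS = 4

_LOGISTIC_VAR = math.pi**2 / 3.0


def binary_columns(p: int) -> np.ndarray:
    """0-based indices of the dichotomised confounders (the upper half)."""
    return np.arange(math.ceil(p / 2), p)


@dataclass
class SimulationConfig:
    """Design of one simulated condition.

    Parameters
    ----------
    n : sample size (>= 50 recommended; >= 2 enforced at generation).
    p : number of confounders (>= 2); the upper half are dichotomised at 0.
    delta : population treatment effect in the outcome model.
    target_prop_treated : marginal P(Z=1) the intercept is calibrated to.
    target_pseudo_r2 : McKelvey–Zavoina pseudo-R² of the treatment model.
    target_r2 : population R² of the outcome model (unit residual variance).
    missing_rate : target marginal missing proportion per incomplete column;
        0 disables missingness.
    mechanism : one of ``MECHANISMS``.
    corr : "exchangeable", "identity", or an explicit correlation matrix.
    corr_rho : off-diagonal correlation for the exchangeable structure.
    deterministic_threshold : reproduce the literal threshold-at-zero
        treatment assignment (no latent logistic error). Off by default; the
        deterministic rule destroys overlap between arms.
    calib_n : calibration sample size used for coefficient scaling and
        intercept root-finding.
    seed : master seed; all randomness derives from it.
    """

    n: int
    p: int = 10
    delta: float = 0.5
    target_prop_treated: float = 0.2
    target_pseudo_r2: float = 0.2
    target_r2: float = 0.2
    missing_rate: float = 0.3
    mechanism: str = "MAR"
    corr: Union[str, np.ndarray] = "exchangeable"
    corr_rho: float = 0.2
    deterministic_threshold: bool = False
    calib_n: int = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.p < 2:
            raise ValueError("p must be >= 2")
        if not 0.0 < self.target_prop_treated < 1.0:
            raise ValueError("target_prop_treated must be in (0, 1)")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        if not 0.0 <= self.target_pseudo_r2 < 1.0:
            raise ValueError("target_pseudo_r2 must be in [0, 1)")
        if not 0.0 <= self.target_r2 < 1.0:
            raise ValueError("target_r2 must be in [0, 1)")
        if self.mechanism not in MECHANISMS:
            raise ValueError(
                f"unknown mechanism {self.mechanism!r}; expected one of {MECHANISMS}"
            )
        # validate the correlation structure eagerly
        self.correlation_matrix()

    def correlation_matrix(self) -> np.ndarray:
        if isinstance(self.corr, str):
            if self.corr == "identity":
                return np.eye(self.p)
            if self.corr == "exchangeable":
                R = np.full((self.p, self.p), self.corr_rho)
                np.fill_diagonal(R, 1.0)
            else:
                raise ValueError(f"unknown corr spec {self.corr!r}")
        else:
            R = np.asarray(self.corr, dtype=float)
        if R.shape != (self.p, self.p):
            raise ValueError("correlation matrix shape must be (p, p)")
        if not np.allclose(R, R.T) or not np.allclose(np.diag(R), 1.0):
            raise ValueError("correlation matrix must be symmetric with unit diagonal")
        if np.linalg.eigvalsh(R).min() <= 1e-10:
            raise ValueError("correlation matrix must be positive definite")
        return R


@dataclass
class ModelParams:
    """Calibrated population coefficients for one condition.

    ``gamma`` maps each incomplete column (0-based index) to its
    mechanism-specific slope vector; ``gamma0`` holds the calibrated
    missingness intercepts (NaN for the always-observed first column).
    ``achieved`` records the calibration-sample values of the targets.
    """

    beta0: float
    beta: np.ndarray
    pi0: float
    pi: np.ndarray
    gamma0: np.ndarray
    gamma: dict[int, np.ndarray]
    achieved: dict[str, float] = field(default_factory=dict)


@dataclass
class GeneratedDataset:
    """One simulated dataset: complete truth plus the observed (masked) view."""

    X_complete: np.ndarray
    Z: np.ndarray
    Y: np.ndarray
    X_observed: np.ndarray
    S: np.ndarray
    column_types: list[str]

    @property
    def n(self) -> int:
        return self.X_complete.shape[0]

    @property
    def p(self) -> int:
        return self.X_complete.shape[1]


def _rng(config: SimulationConfig, tag: int, extra: Optional[int] = None):
    key = [int(config.seed), tag]
    if extra is not None:
        key.append(int(extra))
    return np.random.default_rng(key)


def draw_covariates(config: SimulationConfig, n: int, rng) -> np.ndarray:
    """Multivariate standard normal confounders with the upper half
    dichotomised at 0 into {0, 1}."""
    L = np.linalg.cholesky(config.correlation_matrix())
    X = rng.standard_normal((n, config.p)) @ L.T
    b = binary_columns(config.p)
    X[:, b] = (X[:, b] > 0.0).astype(float)
    return X


def column_types(p: int) -> list[str]:
    b = set(binary_columns(p).tolist())
    return ["binary" if j in b else "continuous" for j in range(p)]


def _treat_prob(config: SimulationConfig, eta: np.ndarray) -> np.ndarray:
    if config.deterministic_threshold:
        return (eta > 0.0).astype(float)
    return expit(eta)


def _gamma_arity(mechanism: str, p: int) -> int:
    return {
        "MAR": 1,
        "FD_MNAR": 1,
        "FI_MNAR": 1,
        "DF_MNAR": p,
        "DF_MNAR_INT1": 3,
        "DF_MNAR_INT2": 3,
    }[mechanism]


def _missing_linear_predictor(
    mechanism: str, X: np.ndarray, k: int, slopes: np.ndarray, aux: Optional[np.ndarray]
) -> np.ndarray:
    """Mechanism-specific slope part of logit P(S_k = 1), without intercept."""
    x1 = X[:, 0]
    xk = X[:, k]
    if mechanism == "MAR":
        return slopes[0] * x1
    if mechanism == "FD_MNAR":
        return slopes[0] * xk
    if mechanism == "FI_MNAR":
        return slopes[0] * aux
    if mechanism == "DF_MNAR":
        return X @ slopes
    if mechanism == "DF_MNAR_INT1":
        return slopes[0] * x1 + slopes[1] * xk + slopes[2] * (x1 * xk)
    if mechanism == "DF_MNAR_INT2":
        return slopes[0] * x1 + slopes[1] * aux + slopes[2] * (x1 * aux)
    raise ValueError(f"unknown mechanism {mechanism!r}")


def _solve_intercept(target: float, prob_fn, lo: float = -40.0, hi: float = 40.0) -> float:
    f = lambda b: prob_fn(b) - target
    try:
        return brentq(f, lo, hi, xtol=1e-10)
    except ValueError as err:  # pragma: no cover - defensive
        raise RuntimeError(f"intercept calibration failed to bracket a root: {err}")


def calibrate_coefficients(config: SimulationConfig) -> ModelParams:
    """Draw and rescale the population coefficients for one condition.

    Treatment slopes are drawn from U(−0.4, 0.4) and scaled by one constant so
    var(Xβ)/(var(Xβ)+π²/3) equals the target pseudo-R²; the intercept is
    root-found so the marginal treated proportion hits its target. Outcome
    slopes are drawn from U(0.1, 0.8) and scaled so the population R² of the
    outcome model (with unit residual variance) hits its target. Missingness
    slopes are drawn from U(0.1, 0.5) per incomplete column and the per-column
    intercepts root-found so each column's marginal missing rate hits the
    target. All calibration uses a ``calib_n``-row Monte Carlo sample with a
    seed derived from the master seed.
    """
    p = config.p
    rng_coeff = _rng(config, _TAG_COEFF)
    rng_calib = _rng(config, _TAG_CALIB)
    Xc = draw_covariates(config, config.calib_n, rng_calib)

    # treatment model
    beta_raw = rng_coeff.uniform(-0.4, 0.4, size=p)
    eta0 = Xc @ beta_raw
    v0 = float(eta0.var())
    rho = config.target_pseudo_r2
    if rho == 0.0 or v0 == 0.0:
        scale_b = 0.0
    else:
        scale_b = math.sqrt(rho / (1.0 - rho) * _LOGISTIC_VAR / v0)
    beta = scale_b * beta_raw
    eta = Xc @ beta
    beta0 = _solve_intercept(
        config.target_prop_treated,
        lambda b: float(_treat_prob(config, b + eta).mean()),
    )
    pz = _treat_prob(config, beta0 + eta)
    Zc = (rng_calib.random(config.calib_n) < pz).astype(float)
    achieved_pseudo = float(eta.var() / (eta.var() + _LOGISTIC_VAR)) if v0 else 0.0

    # outcome model
    pi_raw = rng_coeff.uniform(0.1, 0.8, size=p)
    a = Xc @ pi_raw
    b_part = config.delta * Zc

    def r2_of(c: float) -> float:
        s = c * a + b_part
        v = float(s.var())
        return v / (v + 1.0)

    if config.target_r2 <= r2_of(0.0):
        scale_p = 0.0
    else:
        hi = 1.0
        while r2_of(hi) < config.target_r2:
            hi *= 2.0
            if hi > 1e6:  # pragma: no cover - defensive
                raise RuntimeError("outcome R2 calibration failed")
        scale_p = brentq(lambda c: r2_of(c) - config.target_r2, 0.0, hi, xtol=1e-10)
    pi = scale_p * pi_raw
    achieved_r2 = r2_of(scale_p)

    # missingness models
    gamma: dict[int, np.ndarray] = {}
    gamma0 = np.full(p, np.nan)
    if config.missing_rate > 0.0:
        arity = _gamma_arity(config.mechanism, p)
        needs_aux = config.mechanism in ("FI_MNAR", "DF_MNAR_INT2")
        for k in range(1, p):
            slopes = rng_coeff.uniform(0.1, 0.5, size=arity)
            gamma[k] = slopes
            aux = rng_calib.standard_normal(config.calib_n) if needs_aux else None
            lp = _missing_linear_predictor(config.mechanism, Xc, k, slopes, aux)
            gamma0[k] = _solve_intercept(
                config.missing_rate, lambda g0: float(expit(g0 + lp).mean())
            )

    achieved = {
        "prop_treated": float(pz.mean()),
        "pseudo_r2": achieved_pseudo,
        "r2": float(achieved_r2),
    }
    return ModelParams(
        beta0=float(beta0), beta=beta, pi0=0.0, pi=pi,
        gamma0=gamma0, gamma=gamma, achieved=achieved,
    )


def calibrate_missing_intercept(
    config: SimulationConfig, params: ModelParams, k: int
) -> float:
    """Re-derive the missingness intercept for column ``k`` (0-based) on a
    fresh calibration sample. With all-zero slopes this is exactly
    ``logit(missing_rate)``."""
    slopes = params.gamma[k]
    if not np.any(slopes):
        return float(logit(config.missing_rate))
    rng_calib = _rng(config, _TAG_CALIB, extra=k)
    Xc = draw_covariates(config, config.calib_n, rng_calib)
    aux = (
        rng_calib.standard_normal(config.calib_n)
        if config.mechanism in ("FI_MNAR", "DF_MNAR_INT2")
        else None
    )
    lp = _missing_linear_predictor(config.mechanism, Xc, k, slopes, aux)
    return _solve_intercept(config.missing_rate, lambda g0: float(expit(g0 + lp).mean()))


def generate_dataset(
    config: SimulationConfig,
    params: ModelParams,
    data_seed: Optional[int] = None,
) -> GeneratedDataset:
    """Draw the complete part of one dataset (X, Z, Y); no missingness yet.

    ``data_seed`` optionally replaces the master seed for the data-draw
    stream only, so one calibrated parameter set can generate many datasets.
    """
    if config.n < 2:
        raise ValueError("n must be >= 2")
    seed = config.seed if data_seed is None else data_seed
    rng = np.random.default_rng([int(seed), _TAG_DATA])
    X = draw_covariates(config, config.n, rng)
    eta = params.beta0 + X @ params.beta
    if config.deterministic_threshold:
        Z = (eta > 0.0).astype(float)
    else:
        Z = (rng.random(config.n) < expit(eta)).astype(float)
    Y = params.pi0 + X @ params.pi + config.delta * Z + rng.standard_normal(config.n)
    S = np.zeros_like(X, dtype=bool)
    return GeneratedDataset(
        X_complete=X, Z=Z, Y=Y, X_observed=X.copy(), S=S,
        column_types=column_types(config.p),
    )


def impose_missingness(
    dataset: GeneratedDataset,
    config: SimulationConfig,
    params: ModelParams,
    data_seed: Optional[int] = None,
) -> GeneratedDataset:
    """Mask cells of columns 2..p according to the configured mechanism.

    The latent-score formulation (intercept + slopes + logistic error,
    thresholded at 0) is drawn equivalently as Bernoulli(expit(intercept +
    slopes)). Auxiliary normals for the indirect mechanisms are drawn here and
    never exposed downstream. Column 1 is never masked.
    """
    n, p = dataset.X_complete.shape
    S = np.zeros((n, p), dtype=bool)
    if config.missing_rate > 0.0:
        seed = config.seed if data_seed is None else data_seed
        rng = np.random.default_rng([int(seed), _TAG_MISS])
        needs_aux = config.mechanism in ("FI_MNAR", "DF_MNAR_INT2")
        X = dataset.X_complete
        for k in range(1, p):
            aux = rng.standard_normal(n) if needs_aux else None
            lp = _missing_linear_predictor(config.mechanism, X, k, params.gamma[k], aux)
            pr = expit(params.gamma0[k] + lp)
            S[:, k] = rng.random(n) < pr
    X_obs = dataset.X_complete.copy()
    X_obs[S] = np.nan
    return GeneratedDataset(
        X_complete=dataset.X_complete, Z=dataset.Z, Y=dataset.Y,
        X_observed=X_obs, S=S, column_types=dataset.column_types,
    )


def simulate_dataset(
    config: SimulationConfig,
    params: Optional[ModelParams] = None,
    data_seed: Optional[int] = None,
) -> tuple[GeneratedDataset, ModelParams]:
    """Calibrate (unless given), generate and mask one dataset."""
    if params is None:
        params = calibrate_coefficients(config)
    ds = generate_dataset(config, params, data_seed=data_seed)
    ds = impose_missingness(ds, config, params, data_seed=data_seed)
    return ds, params


def indicator_to_observed_convention(S: np.ndarray) -> np.ndarray:
    """Convert the internal S (1 ⇔ missing) to the R (1 ⇔ observed) coding."""
    return 1 - np.asarray(S, dtype=int)


def observed_to_indicator_convention(R: np.ndarray) -> np.ndarray:
    """Convert R (1 ⇔ observed) coding to the internal S (1 ⇔ missing)."""
    return 1 - np.asarray(R, dtype=int)
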