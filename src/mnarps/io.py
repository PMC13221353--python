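"""CSV dataset I/O and run manifests.

Datasets are plain CSV: covariate columns (empty field = missing cell), a
binary treatment column and a numeric outcome column. Round-trips are
lossless up to float formatting.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .model import infer_column_types
from .simgen import GeneratedDataset


@dataclass
class LoadedDataset:
    X_observed: np.ndarray
    S: np.ndarray
    Z: np.ndarray
    Y: np.ndarray
    covariates: list[str]
    column_types: list[str]


@dataclass
class RunManifest:
    tool_version: str
    config_hash: str
    master_seed: int
    stage_seeds: dict[str, int] = field(default_factory=dict)
    calibration: dict = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    timestamp: float = field(default_factory=time.time)

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2, default=str))


def config_hash(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def load_dataset(
    path,
    covariates: Optional[Sequence[str]] = None,
    treatment: str = "z",
    outcome: str = "y",
    column_types: Optional[Sequence[str]] = None,
) -> LoadedDataset:
    """Read a CSV dataset; empty cells become missing covariate values."""
    df = pd.read_csv(path)
    for col in (treatment, outcome):
        if col not in df.columns:
            raise ValueError(f"missing required column {col!r} in {path}")
    if covariates is None:
        covariates = [c for c in df.columns if c not in (treatment, outcome)]
    X = df[list(covariates)].to_numpy(dtype=float)
    Z = df[treatment].to_numpy(dtype=float)
    Y = df[outcome].to_numpy(dtype=float)
    if np.isnan(Z).any():
        raise ValueError("treatment column has missing values")
    if set(np.unique(Z)) - {0.0, 1.0}:
        raise ValueError("treatment column must be binary 0/1")
    S = np.isnan(X)
    if column_types is None:
        column_types = infer_column_types(X)
    else:
        column_types = list(column_types)
        for j, kind in enumerate(column_types):
            if kind == "binary":
                obs = X[~S[:, j], j]
                bad = ~np.isin(obs, (0.0, 1.0))
                if bad.any():
                    i = int(np.flatnonzero(~S[:, j])[np.flatnonzero(bad)[0]])
                    raise ValueError(
                        f"declared binary column {covariates[j]!r} has non-binary "
                        f"value {X[i, j]!r} at row {i}"
                    )
    return LoadedDataset(
        X_observed=X, S=S, Z=Z, Y=Y,
        covariates=list(covariates), column_types=column_types,
    )


def dataset_to_frame(
    X: np.ndarray, Z: np.ndarray, Y: np.ndarray,
    covariates: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    p = X.shape[1]
    covariates = covariates or [f"x{j + 1}" for j in range(p)]
    df = pd.DataFrame(X, columns=list(covariates))
    df["z"] = Z.astype(int)
    df["y"] = Y
    return df


def save_dataset(path, X, Z, Y, covariates=None) -> None:
    dataset_to_frame(X, Z, Y, covariates).to_csv(path, index=False)


def save_generated(
    ds: GeneratedDataset, out_dir, stem: str
) -> tuple[Path, Path]:
    """Write the observed view and its complete counterpart side by side."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    obs = out_dir / f"{stem}.csv"
    comp = out_dir / f"{stem}_complete.csv"
    save_dataset(obs, ds.X_observed, ds.Z, ds.Y)
    save_dataset(comp, ds.X_complete, ds.Z, ds.Y)
    return obs, comp
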