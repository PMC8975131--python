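"""Linear dimensionality reduction of exogenous risk factors.

Demographic risk factors (age, sex, race, education, ...) are often many and
collinear; the conditional intensities can be regressed on a few principal
component scores instead of the raw covariates.  Categorical factors are
one-hot encoded (and optionally standardized) before projection.  The fitted
model is serializable so that predictions reuse the identical transform.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

__all__ = ["PcaModel", "pca_fit_transform", "explained_variance_report", "one_hot"]


@dataclass
class PcaModel:
    loadings: np.ndarray            # n_components x m, orthonormal rows
    explained_variance_ratio: np.ndarray
    means: np.ndarray
    scales: np.ndarray | None       # None when columns were not standardized

    def transform(self, Z: np.ndarray) -> np.ndarray:
        Z = np.asarray(Z, dtype=float) - self.means
        if self.scales is not None:
            Z = Z / self.scales
        return Z @ self.loadings.T

    def to_dict(self) -> dict:
        return {
            "loadings": self.loadings.tolist(),
            "explained_variance_ratio": self.explained_variance_ratio.tolist(),
            "means": self.means.tolist(),
            "scales": None if self.scales is None else self.scales.tolist(),
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "PcaModel":
        return cls(
            np.asarray(doc["loadings"], dtype=float),
            np.asarray(doc["explained_variance_ratio"], dtype=float),
            np.asarray(doc["means"], dtype=float),
            None if doc["scales"] is None else np.asarray(doc["scales"], dtype=float),
        )

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path) -> "PcaModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def pca_fit_transform(Z: np.ndarray, n_components: int,
                      standardize: bool = False) -> tuple[PcaModel, np.ndarray]:
    """Fit PCA on a subjects-by-covariates matrix and return component scores.

    Columns are centered (and standardized when requested) first.  Loadings
    use a deterministic sign convention: the largest-magnitude entry of each
    component is positive.  If the matrix has lower rank than requested, the
    output is reduced with a warning.
    """
    Z = np.asarray(Z, dtype=float)
    n, m = Z.shape
    if n_components > min(n - 1, m):
        raise ValueError(f"n_components={n_components} exceeds min(n-1, m)={min(n - 1, m)}")
    means = Z.mean(axis=0)
    scales = None
    X = Z - means
    if standardize:
        scales = X.std(axis=0)
        scales[scales < 1e-12] = 1.0
        X = X / scales
    rank = np.linalg.matrix_rank(X)
    k = n_components
    if rank < n_components:
        warnings.warn(
            f"matrix rank {rank} < requested {n_components} components; reducing",
            stacklevel=2,
        )
        k = rank
    pca = PCA(n_components=k, svd_solver="full").fit(X)
    loadings = pca.components_.copy()
    for i in range(k):
        j = np.argmax(np.abs(loadings[i]))
        if loadings[i, j] < 0:
            loadings[i] = -loadings[i]
    model = PcaModel(loadings, pca.explained_variance_ratio_.copy(), means, scales)
    return model, X @ loadings.T


def explained_variance_report(model: PcaModel) -> pd.DataFrame:
    """Per-component and cumulative explained-variance ratios."""
    ratios = model.explained_variance_ratio
    return pd.DataFrame(
        {"ratio": ratios, "cumulative": np.cumsum(ratios)},
        index=[f"PC{i + 1}" for i in range(len(ratios))],
    )


def one_hot(df: pd.DataFrame, categorical: list[str]) -> pd.DataFrame:
    """One-hot encode the named columns, leaving the rest untouched."""
    return pd.get_dummies(df, columns=categorical, dtype=float)
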