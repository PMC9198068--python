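"""First-principal-component deprivation scoring.

The index model follows the asset-index tradition: z-score each indicator,
take the leading eigenvector of the correlation matrix as loadings, and
score each household by the loading-weighted sum of its standardized
indicators.  Because every indicator is deprivation-oriented, the loading
sign is fixed so the loadings sum to a positive number — a higher score
always means more deprivation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ColumnMismatchError, ZeroVarianceError
from .indicators import INDICATOR_COLUMNS


@dataclass
class PdiModel:
    """Standardization parameters and oriented first-component loadings."""

    means: np.ndarray
    sds: np.ndarray
    loadings: np.ndarray
    explained_variance_share: float
    feature_names: tuple[str, ...] = field(default=INDICATOR_COLUMNS)

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        self.loadings = np.asarray(self.loadings, dtype=float)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "loadings": self.loadings.tolist(),
            "explained_variance_share": self.explained_variance_share,
            "feature_names": list(self.feature_names),
        }, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "PdiModel":
        d = json.loads(Path(path).read_text())
        return cls(
            means=np.array(d["means"]), sds=np.array(d["sds"]),
            loadings=np.array(d["loadings"]),
            explained_variance_share=d["explained_variance_share"],
            feature_names=tuple(d["feature_names"]),
        )


def fit_pdi_model(matrix: np.ndarray,
                  feature_names: tuple[str, ...] | None = None) -> PdiModel:
    """Fit the index model on a pooled indicator matrix.

    Columns are z-scored (sample sd, ddof=1); the loadings are the leading
    eigenvector of the resulting correlation matrix, sign-flipped if the
    loading sum is non-positive.  The explained-variance share is the
    leading eigenvalue over the number of indicators.  A zero-variance
    column makes the correlation undefined and raises, naming the column.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ZeroVarianceError("need a 2-D matrix with at least 2 rows")
    p = X.shape[1]
    names = tuple(feature_names) if feature_names is not None else (
        INDICATOR_COLUMNS if p == len(INDICATOR_COLUMNS)
        else tuple(f"x{j}" for j in range(p))
    )
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    dead = np.flatnonzero(sds <= 0)
    if dead.size:
        raise ZeroVarianceError(
            "zero-variance column(s): " + ", ".join(names[j] for j in dead)
        )
    Z = (X - means) / sds
    corr = (Z.T @ Z) / (X.shape[0] - 1)
    eigvals, eigvecs = np.linalg.eigh(corr)
    loadings = eigvecs[:, -1]
    if loadings.sum() <= 0:
        loadings = -loadings
    return PdiModel(
        means=means, sds=sds, loadings=loadings,
        explained_variance_share=float(eigvals[-1] / p),
        feature_names=names,
    )


def score_households(model: PdiModel, matrix: np.ndarray,
                     feature_names: tuple[str, ...] | None = None) -> np.ndarray:
    """Project households onto the fitted first component.

    score_i = sum_j loadings_j * (x_ij - mean_j) / sd_j.  Scores on the
    training matrix are centered at zero by construction.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.loadings.size:
        raise ColumnMismatchError(
            f"matrix has {X.shape[-1] if X.ndim == 2 else '?'} columns; "
            f"model was fitted on {model.loadings.size}"
        )
    if feature_names is not None and tuple(feature_names) != tuple(model.feature_names):
        raise ColumnMismatchError(
            f"column names {tuple(feature_names)} do not match the model's "
            f"{tuple(model.feature_names)}"
        )
    return ((X - model.means) / model.sds) @ model.loadings
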