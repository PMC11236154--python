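"""Principal component analysis of normalized EFD coefficient vectors.

Each specimen is an 80-dimensional point (4 coefficients x 20 harmonics);
PCA compresses the population's shape variation into a few orthogonal
axes. Covariance PCA (mean-centered, unscaled) is used: all coefficients
share units, and correlation scaling would inflate the near-constant
entries left by normalization (a1 = 1, b1 = c1 = 0). The biological
reading of the leading axes for mouse sperm heads: head width loads on
PC1, hook length/direction on PC2.

A fitted model can be pushed back to shape space: displacing the mean
coefficient vector along a loading by a multiple of that component's SD
and running the inverse Fourier series draws the "mean shape" of the PC,
the standard way outline-PCA axes are visualized.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._exceptions import DegenerateVarianceError, FormatError, ParameterError
from .contour_io import Contour
from .efd import reconstruct, unflatten

__all__ = ["ShapePCAModel", "fit_pca", "transform", "score_table", "mean_shape"]


@dataclass(frozen=True)
class ShapePCAModel:
    """Covariance-PCA model over coefficient vectors.

    ``loadings`` rows are orthonormal; ``explained_variance`` are the
    per-component score variances (ddof=1), non-increasing;
    ``explained_variance_ratio`` their fractions of total variance.
    """

    mean: np.ndarray
    loadings: np.ndarray
    explained_variance: np.ndarray
    explained_variance_ratio: np.ndarray
    H: int

    @property
    def n_components(self) -> int:
        return self.loadings.shape[0]

    def to_json(self, path) -> None:
        payload = {
            "mean": self.mean.tolist(),
            "loadings": self.loadings.tolist(),
            "explained_variance": self.explained_variance.tolist(),
            "explained_variance_ratio": self.explained_variance_ratio.tolist(),
            "H": self.H,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "ShapePCAModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            mean=np.asarray(d["mean"], float),
            loadings=np.asarray(d["loadings"], float),
            explained_variance=np.asarray(d["explained_variance"], float),
            explained_variance_ratio=np.asarray(d["explained_variance_ratio"], float),
            H=int(d["H"]),
        )


def fit_pca(matrix, n_components: int = 2) -> ShapePCAModel:
    """Fit covariance PCA to a (specimens x 4H) coefficient matrix.

    Loading signs are made deterministic by forcing the largest-magnitude
    entry of each loading positive, so refits on identical data are
    bit-reproducible.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ParameterError(f"need a 2D matrix with >= 2 specimens, got shape {X.shape}")
    n, p = X.shape
    if p % 4 != 0:
        raise FormatError(f"coefficient vectors must have length 4*H, got {p}")
    if not 1 <= n_components <= min(n - 1, p):
        raise ParameterError(
            f"n_components must be in [1, {min(n - 1, p)}], got {n_components}"
        )
    mean = X.mean(axis=0)
    Xc = X - mean
    if np.allclose(Xc, 0.0):
        raise DegenerateVarianceError("all specimens identical: no variance to decompose")
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    variances = S**2 / (n - 1)
    total = Xc.var(axis=0, ddof=1).sum()
    loadings = Vt[:n_components].copy()
    for row in loadings:
        j = int(np.argmax(np.abs(row)))
        if row[j] < 0:
            row *= -1.0
    return ShapePCAModel(
        mean=mean,
        loadings=loadings,
        explained_variance=variances[:n_components],
        explained_variance_ratio=variances[:n_components] / total,
        H=p // 4,
    )


def transform(model: ShapePCAModel, vectors) -> np.ndarray:
    """Project coefficient vectors onto the model's components.

    Returns an (n, k) score array; a single vector may be passed and
    yields shape (k,).
    """
    V = np.asarray(vectors, dtype=float)
    single = V.ndim == 1
    V = np.atleast_2d(V)
    if V.shape[1] != model.mean.size:
        raise FormatError(
            f"vector length {V.shape[1]} does not match model dimension {model.mean.size}"
        )
    scores = (V - model.mean) @ model.loadings.T
    return scores[0] if single else scores


def score_table(model: ShapePCAModel, vectors, specimen_ids, groups) -> pd.DataFrame:
    """Per-specimen PC scores as a tidy table (specimen_id, group, PC1..)."""
    scores = transform(model, vectors)
    df = pd.DataFrame({"specimen_id": list(specimen_ids), "group": list(groups)})
    for k in range(model.n_components):
        df[f"PC{k + 1}"] = scores[:, k]
    return df


def mean_shape(
    model: ShapePCAModel,
    pc_index: int,
    multiple_of_sd: float = 0.0,
    n_points: int = 256,
) -> Contour:
    """Reconstruct the population mean shape displaced along one PC.

    ``pc_index`` is 1-based; ``multiple_of_sd = 0`` gives the grand mean
    shape regardless of the component. The displacement is
    ``multiple_of_sd * sqrt(var(PC)) * loading``.
    """
    if not 1 <= pc_index <= model.n_components:
        raise ParameterError(
            f"pc_index must be in [1, {model.n_components}], got {pc_index}"
        )
    k = pc_index - 1
    vec = model.mean + multiple_of_sd * np.sqrt(model.explained_variance[k]) * model.loadings[k]
    return reconstruct(unflatten(vec, model.H), n_points)
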