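"""Structure analysis of the feature space: PCA with varimax rotation.

Features carry heterogeneous units (dimensionless amplitudes, seconds,
1/seconds, counts), so the PCA is run on the correlation matrix, i.e. on
columns standardised to zero mean and unit variance.  The retained leading
components are varimax-rotated: an orthogonal rotation maximising the
variance of squared loadings within each component, which pushes each
component toward loading on few features and makes it clinically readable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

logger = logging.getLogger(__name__)


@dataclass
class RotationResult:
    """Outcome of a varimax rotation: ``rotated = loadings @ rotation``."""

    rotated: np.ndarray
    rotation: np.ndarray
    converged: bool
    n_iter: int


@dataclass
class ComponentModel:
    """Fitted PCA with an optional varimax rotation of the retained block.

    ``loadings`` holds the orthonormal eigenvectors of the correlation matrix
    as columns (features x components, eigenvalue-descending);
    ``rotated_loadings`` is the retained features x k block after rotation.
    """

    loadings: np.ndarray
    eigenvalues: np.ndarray
    explained_variance_ratio: np.ndarray
    k: int
    rotated_loadings: np.ndarray
    feature_names: list[str]
    rotation_converged: bool = True
    elbow_degenerate: bool = False
    column_means: np.ndarray = field(default=None)  # type: ignore[assignment]
    column_sds: np.ndarray = field(default=None)  # type: ignore[assignment]

    def scree_frame(self) -> pd.DataFrame:
        ratio = self.explained_variance_ratio
        return pd.DataFrame(
            {
                "component": np.arange(1, len(ratio) + 1),
                "eigenvalue": self.eigenvalues,
                "variance_ratio": ratio,
                "cumulative_ratio": np.cumsum(ratio),
            }
        )

    def loadings_frame(self, rotated: bool = True) -> pd.DataFrame:
        mat = self.rotated_loadings if rotated else self.loadings[:, : self.k]
        cols = [f"PC{i + 1}" for i in range(mat.shape[1])]
        return pd.DataFrame(mat, index=self.feature_names, columns=cols)


def _apply_sign_convention(mat: np.ndarray) -> np.ndarray:
    """Flip each column so its largest-magnitude entry is positive."""
    mat = mat.copy()
    for j in range(mat.shape[1]):
        i = int(np.argmax(np.abs(mat[:, j])))
        if mat[i, j] < 0:
            mat[:, j] = -mat[:, j]
    return mat


def varimax_criterion(loadings: np.ndarray) -> float:
    """Sum over components of the variance of squared loadings."""
    sq = np.asarray(loadings, dtype=float) ** 2
    return float(np.sum(sq.var(axis=0)))


def varimax_rotate(
    loadings: np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 1000,
    kaiser_normalize: bool = False,
) -> RotationResult:
    """Varimax rotation via the SVD-based iterative algorithm.

    Kaiser row normalization (rows scaled to unit communality during the
    iteration) is off by default.  For k = 1 the rotation is undefined and
    the input is returned as-is.  Non-convergence sets ``converged=False``
    on the result rather than raising.  Columns of the result are re-ordered
    by decreasing sum of squared loadings, with the sign convention that each
    column's largest-magnitude entry is positive.
    """
    L = np.asarray(loadings, dtype=float)
    p, k = L.shape
    if k < 2:
        return RotationResult(L.copy(), np.eye(k), True, 0)

    comm = None
    if kaiser_normalize:
        comm = np.sqrt((L**2).sum(axis=1))
        comm[comm == 0] = 1.0
        L = L / comm[:, None]

    R = np.eye(k)
    d = 0.0
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        Lr = L @ R
        u, s, vt = np.linalg.svd(
            L.T @ (Lr**3 - Lr @ np.diag((Lr**2).sum(axis=0)) / p)
        )
        R = u @ vt
        d_new = s.sum()
        if d_new <= d * (1 + tol):
            converged = True
            break
        d = d_new
    if not converged:
        logger.warning("varimax did not converge in %d iterations", max_iter)

    rotated = L @ R
    if kaiser_normalize:
        rotated = rotated * comm[:, None]

    # re-sort by explained loading variance, fix signs; fold both into R so
    # rotated == loadings @ R still holds exactly
    order = np.argsort(-(rotated**2).sum(axis=0), kind="stable")
    rotated = rotated[:, order]
    R = R[:, order]
    signs = np.ones(k)
    for j in range(k):
        i = int(np.argmax(np.abs(rotated[:, j])))
        if rotated[i, j] < 0:
            signs[j] = -1.0
    rotated = rotated * signs
    R = R * signs
    return RotationResult(rotated, R, converged, n_iter)


def select_k_elbow(explained_variance_ratio: np.ndarray) -> tuple[int, bool]:
    """Advisory elbow pick on the scree curve.

    Returns the (1-based) position of the scree point with maximal
    perpendicular distance to the straight line joining the curve's
    endpoints, plus a degeneracy flag (True when the scree is effectively
    linear and the rule carries no information — callers should override).
    """
    r = np.asarray(explained_variance_ratio, dtype=float)
    n = len(r)
    if n < 3:
        raise ValidationError("elbow selection needs >= 3 variance ratios")
    x = np.arange(1, n + 1, dtype=float)
    p0 = np.array([x[0], r[0]])
    p1 = np.array([x[-1], r[-1]])
    line = p1 - p0
    norm = np.linalg.norm(line)
    if norm == 0:
        return 1, True
    # perpendicular distance of every point to the endpoint line
    rel = np.column_stack([x, r]) - p0
    dist = np.abs(rel[:, 0] * line[1] - rel[:, 1] * line[0]) / norm
    degenerate = bool(dist.max() < 1e-12)
    if degenerate:
        logger.warning("scree curve is linear; elbow rule is uninformative")
        return 1, True
    return int(np.argmax(dist)) + 1, False


def fit_pca(
    X: np.ndarray | pd.DataFrame,
    feature_names: list[str] | None = None,
    k: int | None = None,
    kaiser_normalize: bool = False,
) -> ComponentModel:
    """Correlation-matrix PCA with varimax rotation of the retained block.

    Columns are standardised (mean 0, sd 1 with ddof=1); components are the
    eigenvectors of the resulting correlation matrix, eigenvalue-descending,
    signed so each component's largest-magnitude loading is positive.  ``k``
    defaults to the elbow pick of :func:`select_k_elbow` and is always
    overridable.
    """
    if isinstance(X, pd.DataFrame):
        if feature_names is None:
            feature_names = [str(c) for c in X.columns]
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValidationError("PCA needs a 2-D matrix with >= 2 rows and columns")
    if np.isnan(X).any():
        raise ValidationError("PCA input contains missing cells; drop them first")
    n, p = X.shape
    if feature_names is None:
        feature_names = [f"f{i}" for i in range(p)]

    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    zero = np.where(sds <= 1e-12 * np.maximum(1.0, np.abs(means)))[0]
    if len(zero):
        raise ValidationError(
            f"constant feature column(s): {[feature_names[i] for i in zero]}"
        )
    Z = (X - means) / sds
    corr = (Z.T @ Z) / (n - 1)
    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = _apply_sign_convention(eigvecs[:, order])
    ratio = eigvals / eigvals.sum()

    elbow_degenerate = False
    if k is None:
        if p >= 3:
            k, elbow_degenerate = select_k_elbow(ratio)
        else:
            k = p
    if not 1 <= k <= p:
        raise ValidationError(f"k={k} outside [1, {p}]")

    rot = varimax_rotate(eigvecs[:, :k], kaiser_normalize=kaiser_normalize)
    return ComponentModel(
        loadings=eigvecs,
        eigenvalues=eigvals,
        explained_variance_ratio=ratio,
        k=k,
        rotated_loadings=rot.rotated,
        feature_names=list(feature_names),
        rotation_converged=rot.converged,
        elbow_degenerate=elbow_degenerate,
        column_means=means,
        column_sds=sds,
    )
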