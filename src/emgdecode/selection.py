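"""Feature selection and supervised sparse projection.

Sequential forward selection (SFS) is a greedy wrapper: at each step every
remaining feature is evaluated joined to the current subset, the argmax is
accepted only on *strict* improvement of the evaluation, and the search stops
the first time no candidate improves it.  The default evaluation is the
training-set recognition of a Gaussian classifier refit on the candidate
subset.

The sparse-space conversion is a supervised linear projection maximizing the
Fisher criterion (between-class over within-class scatter) with an
element-wise soft-threshold sparsity penalty on the loadings — intended to
increase between-class distances and shrink within-class ones.  With all
components retained and no penalty the map is invertible, so a downstream
QDA is unchanged; fewer components trade information for dimensionality.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import eigh

from . import models

__all__ = ["SfsResult", "SparseSpaceModel", "sfs",
           "sparse_fit", "sparse_transform"]


@dataclass
class SfsResult:
    subset: list[int]        # accepted feature indices, in acceptance order
    best_eval: list[float]   # evaluation value at each accepted step
    n_features: int          # len(subset); the reported N.F count


@dataclass
class SparseSpaceModel:
    mean: np.ndarray         # (d,) training mean used for centering
    components: np.ndarray   # (d, m) projection loadings
    n_components: int
    eigenvalues: np.ndarray  # Fisher ratios of the components


def _training_recognition(kind: str, ridge: float):
    def ev(X: np.ndarray, y: np.ndarray, subset: list[int]) -> float:
        model = models.fit(kind, X[:, subset], y, ridge=ridge)
        return models.recognition(models.predict(model, X[:, subset]), y)
    return ev


def sfs(X: np.ndarray, labels: np.ndarray, model_kind: str = "qda",
        eval_fn=None, ridge: float = 1e-6,
        max_features: int | None = None) -> SfsResult:
    """Greedy forward selection over the columns of X.

    ``eval_fn(X, labels, subset) -> float`` scores a candidate subset; the
    default is training-set recognition of ``model_kind``.  Candidates are
    scanned in ascending index order and argmax ties resolve to the lowest
    index.  ``max_features`` optionally caps the subset size (None = run to
    stagnation).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] < 1:
        raise ValueError("need at least one candidate feature")
    labels = np.asarray(labels).astype(int).ravel()
    if eval_fn is None:
        eval_fn = _training_recognition(model_kind, ridge)

    space = list(range(X.shape[1]))
    subset: list[int] = []
    best_eval: list[float] = []
    current_best = -np.inf
    while space:
        if max_features is not None and len(subset) >= max_features:
            break
        temp = np.empty(len(space))
        for i, feat in enumerate(space):
            val = eval_fn(X, labels, subset + [feat])
            if not np.isfinite(val):
                raise ValueError(
                    f"eval_fn returned non-finite value for feature {feat}")
            temp[i] = val
        best_i = int(np.argmax(temp))  # first maximum = lowest index on ties
        if temp[best_i] > current_best:
            subset.append(space.pop(best_i))
            current_best = float(temp[best_i])
            best_eval.append(current_best)
        else:
            break
    return SfsResult(subset=subset, best_eval=best_eval,
                     n_features=len(subset))


def _scatter_matrices(X: np.ndarray,
                      labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    grand = X.mean(axis=0)
    d = X.shape[1]
    Sw = np.zeros((d, d))
    Sb = np.zeros((d, d))
    for c in np.unique(labels):
        xc = X[labels == c]
        mc = xc.mean(axis=0)
        cen = xc - mc
        Sw += cen.T @ cen
        dm = (mc - grand)[:, None]
        Sb += xc.shape[0] * (dm @ dm.T)
    return Sb, Sw


def sparse_fit(X: np.ndarray, labels: np.ndarray, n_components: int,
               sparsity: float = 0.0, ridge: float = 1e-6) -> SparseSpaceModel:
    """Fit the projection: generalized eigenvectors of (Sb, Sw), loadings
    soft-thresholded by ``sparsity`` and renormalized.  Deterministic."""
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels).astype(int).ravel()
    d = X.shape[1]
    if not 1 <= n_components <= d:
        raise ValueError("n_components must be in [1, n_features]")
    Sb, Sw = _scatter_matrices(X, labels)
    Sw = Sw + (ridge * max(np.trace(Sw), 1.0) / d) * np.eye(d)
    vals, vecs = eigh(Sb, Sw)
    order = np.argsort(vals)[::-1][:n_components]
    W = vecs[:, order]
    vals = vals[order]
    if sparsity > 0:
        W = np.sign(W) * np.maximum(np.abs(W) - sparsity, 0.0)
    norms = np.linalg.norm(W, axis=0)
    norms[norms == 0] = 1.0
    W = W / norms
    # deterministic sign: largest-magnitude loading of each component > 0
    flip = np.sign(W[np.argmax(np.abs(W), axis=0), np.arange(W.shape[1])])
    flip[flip == 0] = 1.0
    W = W * flip
    return SparseSpaceModel(mean=X.mean(axis=0), components=W,
                            n_components=n_components, eigenvalues=vals)


def sparse_transform(model: SparseSpaceModel, X: np.ndarray) -> np.ndarray:
    """Project rows into the learned space (training-mean centered)."""
    X = np.asarray(X, dtype=float)
    if X.shape[1] != model.components.shape[0]:
        raise ValueError("dimension mismatch")
    return (X - model.mean) @ model.components
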