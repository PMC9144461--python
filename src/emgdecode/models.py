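"""Gaussian generative classifiers: naive Bayes, LDA, QDA.

All three realize per-class discriminant functions

    g_k(x) = ln pi_k - 1/2 ln|Sigma_k| - 1/2 (x - mu_k)' Sigma_k^{-1} (x - mu_k)

and differ only in the covariance structure: per-class full (QDA), single
pooled within-class (LDA), or per-class diagonal (naive Bayes, Gaussian per
feature).  Classification is the argmax of the scores, ties broken toward the
lowest class label.  Scores are computed in log space via a triangular
(Cholesky) factorization; a ridge term lambda * trace(Sigma)/d is added to
every covariance diagonal because with 96 features and few windows per class
the sample covariances can be singular.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["GaussianClassifier", "fit", "discriminant_scores", "predict",
           "recognition", "save_model", "load_model", "KINDS"]

KINDS = ("nb", "lda", "qda")


@dataclass
class GaussianClassifier:
    kind: str
    classes: np.ndarray          # sorted ascending
    priors: np.ndarray           # (K,), sums to 1
    means: np.ndarray            # (K, d)
    covariances: np.ndarray      # qda: (K, d, d); lda: (d, d); nb: (K, d)
    ridge: float = 1e-6
    feature_subset: np.ndarray | None = None
    # cached per-class Cholesky factors and log-determinants
    _chol: np.ndarray | None = field(default=None, repr=False)
    _logdet: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_features(self) -> int:
        return self.means.shape[1]


def _ridge_diag(cov: np.ndarray, ridge: float) -> np.ndarray:
    d = cov.shape[-1]
    tr = np.trace(cov, axis1=-2, axis2=-1)
    lam = ridge * np.where(tr > 0, tr, 1.0) / d
    return cov + lam[..., None, None] * np.eye(d)


def fit(kind: str, X: np.ndarray, labels: np.ndarray, ridge: float = 1e-6,
        feature_subset=None) -> GaussianClassifier:
    """Estimate priors (class frequencies), class means and covariances.

    ``feature_subset`` restricts the model to the given column indices; the
    subset is stored so that scoring can accept full-width inputs from the
    caller explicitly sliced the same way.
    """
    kind = kind.lower()
    if kind not in KINDS:
        raise ValueError(f"kind must be one of {KINDS}")
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels).astype(int).ravel()
    if feature_subset is not None:
        feature_subset = np.asarray(feature_subset, dtype=int)
        X = X[:, feature_subset]
    if not np.isfinite(X).all():
        raise ValueError("non-finite feature values")
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("need at least 2 classes")
    n, d = X.shape
    K = classes.size
    priors = np.empty(K)
    means = np.empty((K, d))
    centered = np.empty_like(X)
    counts = np.empty(K, dtype=int)
    for i, c in enumerate(classes):
        sel = labels == c
        counts[i] = sel.sum()
        if counts[i] < 2:
            raise ValueError(f"class {c} has fewer than 2 rows")
        priors[i] = counts[i] / n
        means[i] = X[sel].mean(axis=0)
        centered[sel] = X[sel] - means[i]

    if kind == "qda":
        covs = np.empty((K, d, d))
        for i, c in enumerate(classes):
            xc = centered[labels == c]
            covs[i] = xc.T @ xc / (counts[i] - 1)
        covs = _ridge_diag(covs, ridge)
        chol = np.linalg.cholesky(covs)
        logdet = 2.0 * np.log(np.diagonal(chol, axis1=-2, axis2=-1)).sum(-1)
    elif kind == "lda":
        pooled = centered.T @ centered / (n - K)
        covs = _ridge_diag(pooled, ridge)
        chol = np.linalg.cholesky(covs)
        logdet = np.full(K, 2.0 * np.log(np.diag(chol)).sum())
    else:  # nb: per-class per-feature variances
        covs = np.empty((K, d))
        for i, c in enumerate(classes):
            xc = centered[labels == c]
            covs[i] = (xc * xc).sum(axis=0) / (counts[i] - 1)
        tr = covs.sum(axis=1)
        covs = covs + (ridge * np.where(tr > 0, tr, 1.0) / d)[:, None]
        chol = None
        logdet = np.log(covs).sum(axis=1)

    return GaussianClassifier(kind=kind, classes=classes, priors=priors,
                              means=means, covariances=covs, ridge=ridge,
                              feature_subset=feature_subset,
                              _chol=chol, _logdet=logdet)


def discriminant_scores(model: GaussianClassifier,
                        X: np.ndarray) -> np.ndarray:
    """Per-class scores g_k(x) for each row of X; shape (n, K)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"expected {model.n_features} features, got {X.shape[1]}")
    K = model.classes.size
    n = X.shape[0]
    scores = np.empty((n, K))
    logpri = np.log(model.priors)
    if model.kind == "nb":
        if model._logdet is None:  # deserialized model
            model._logdet = np.log(model.covariances).sum(axis=1)
        for i in range(K):
            z2 = ((X - model.means[i]) ** 2 / model.covariances[i]).sum(1)
            scores[:, i] = logpri[i] - 0.5 * model._logdet[i] - 0.5 * z2
        return scores
    chol = model._chol
    if chol is None:  # deserialized model: refactor
        cov = model.covariances
        chol = np.linalg.cholesky(cov)
        if model.kind == "qda":
            model._chol = chol
            model._logdet = 2.0 * np.log(
                np.diagonal(chol, axis1=-2, axis2=-1)).sum(-1)
        else:
            model._chol = chol
            model._logdet = np.full(K, 2.0 * np.log(np.diag(chol)).sum())
        chol = model._chol
    if model.kind == "lda":
        from scipy.linalg import solve_triangular
        z = solve_triangular(chol, (X[:, None, :] - model.means
                                    ).reshape(-1, model.n_features).T,
                             lower=True)
        z2 = (z * z).sum(axis=0).reshape(n, K)
        scores = logpri - 0.5 * model._logdet - 0.5 * z2
    else:  # qda
        from scipy.linalg import solve_triangular
        for i in range(K):
            z = solve_triangular(chol[i], (X - model.means[i]).T, lower=True)
            scores[:, i] = (logpri[i] - 0.5 * model._logdet[i]
                            - 0.5 * (z * z).sum(axis=0))
    return scores


def predict(model: GaussianClassifier, X: np.ndarray) -> np.ndarray:
    """Argmax-of-score labels; exact ties resolve to the lowest class label."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 0:
        raise ValueError("empty input")
    scores = discriminant_scores(model, X)
    # classes are sorted ascending and np.argmax returns the first maximum,
    # so ties already break toward the lowest label
    return model.classes[np.argmax(scores, axis=1)]


def recognition(pred: np.ndarray, truth: np.ndarray) -> float:
    """Recognition percentage, 100 * (#correct / #rows)."""
    pred = np.asarray(pred).ravel()
    truth = np.asarray(truth).ravel()
    if pred.size == 0 or pred.size != truth.size:
        raise ValueError("prediction/truth size mismatch or empty")
    return 100.0 * float(np.mean(pred == truth))


def save_model(model: GaussianClassifier, path: str | Path) -> None:
    """Persist the discriminant parameters as JSON (priors, means,
    covariances), so the per-class sum-of-multiplications discriminants can
    be exported, e.g. for microcontroller use."""
    doc = {
        "kind": model.kind,
        "classes": model.classes.tolist(),
        "priors": model.priors.tolist(),
        "means": model.means.tolist(),
        "covariances": model.covariances.tolist(),
        "ridge": model.ridge,
        "feature_subset": (None if model.feature_subset is None
                           else model.feature_subset.tolist()),
    }
    Path(path).write_text(json.dumps(doc))


def load_model(path: str | Path) -> GaussianClassifier:
    doc = json.loads(Path(path).read_text())
    return GaussianClassifier(
        kind=doc["kind"],
        classes=np.asarray(doc["classes"], dtype=int),
        priors=np.asarray(doc["priors"], dtype=float),
        means=np.asarray(doc["means"], dtype=float),
        covariances=np.asarray(doc["covariances"], dtype=float),
        ridge=doc["ridge"],
        feature_subset=(None if doc["feature_subset"] is None
                        else np.asarray(doc["feature_subset"], dtype=int)),
    )
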