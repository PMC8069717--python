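"""Spectral Regression Discriminant Analysis (SRDA).

SRDA solves the LDA graph-embedding problem by regression: the spectral
targets of the LDA supervised graph are (orthogonalized) class-indicator
vectors, and each target is fit by ridge regression on the centered
features. This avoids the dense eigendecomposition of classical LDA and is
well-defined for rank-deficient feature matrices as long as the ridge
penalty is positive.

For the binary problem used throughout this package the embedding reduces
to a single ridge regression on a +-1-coded, centered class indicator.
Prediction assigns the nearest class centroid in the projected space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SRDAModel", "srda_fit", "srda_predict", "evaluate"]


@dataclass
class SRDAModel:
    projection: np.ndarray  # (d, c-1)
    class_centroids: np.ndarray  # (c, c-1)
    classes: np.ndarray  # (c,) original labels, sorted
    train_mean: np.ndarray  # (d,)
    reg_alpha: float


def _spectral_targets(y_idx: np.ndarray, c: int) -> np.ndarray:
    """c-1 response vectors: class indicators orthogonalized against the
    constant vector (and each other), i.e. the nontrivial eigenvectors of
    the LDA supervised graph."""
    n = len(y_idx)
    Y = np.zeros((n, c))
    Y[np.arange(n), y_idx] = 1.0
    ones = np.ones((n, 1)) / np.sqrt(n)
    basis = [ones[:, 0]]
    targets = []
    for j in range(c):
        v = Y[:, j].copy()
        for b in basis:
            v -= (v @ b) * b
        norm = np.linalg.norm(v)
        if norm > 1e-10:
            v /= norm
            basis.append(v)
            targets.append(v)
    return np.column_stack(targets[: c - 1])


def srda_fit(X: np.ndarray, y: np.ndarray, reg_alpha: float = 0.01) -> SRDAModel:
    """Fit SRDA on features X (n x d) and labels y (c >= 2 classes).

    reg_alpha is the ridge penalty on the regression coefficients; the
    default 0.01 is a weak regularizer that mainly guards against
    rank deficiency.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y)
    classes = np.unique(y)
    c = len(classes)
    if c < 2:
        raise ValueError("SRDA needs at least 2 classes")
    n, d = X.shape
    if n < c:
        raise ValueError("need at least as many samples as classes")
    y_idx = np.searchsorted(classes, y)

    mean = X.mean(axis=0)
    Xc = X - mean
    if c == 2:
        # centered +-1 indicator; equivalent to the orthogonalized target
        # up to scale, which the nearest-centroid rule ignores
        t = np.where(y_idx == 1, 1.0, -1.0)
        T = (t - t.mean())[:, None]
    else:
        T = _spectral_targets(y_idx, c)

    # ridge: (Xc'Xc + alpha I) w = Xc' t, solved per target
    G = Xc.T @ Xc + reg_alpha * np.eye(d)
    W = np.linalg.solve(G, Xc.T @ T)

    proj = Xc @ W
    centroids = np.vstack([proj[y_idx == j].mean(axis=0) for j in range(c)])
    return SRDAModel(
        projection=W,
        class_centroids=centroids,
        classes=classes,
        train_mean=mean,
        reg_alpha=reg_alpha,
    )


def srda_predict(model: SRDAModel, X: np.ndarray) -> np.ndarray:
    """Predict by nearest class centroid in the projected space; exact
    ties go to the lower class label."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[1] != model.projection.shape[0]:
        raise ValueError(
            f"feature dimension {X.shape[1]} != training dimension "
            f"{model.projection.shape[0]}"
        )
    proj = (X - model.train_mean) @ model.projection
    d2 = ((proj[:, None, :] - model.class_centroids[None, :, :]) ** 2).sum(axis=2)
    return model.classes[d2.argmin(axis=1)]  # argmin takes the first (lower) class


def evaluate(
    y_true: np.ndarray, y_pred: np.ndarray, positive_label: int = 1, macro: bool = False
) -> dict[str, float]:
    """Accuracy, precision and F1.

    Precision/F1 refer to the positive (fatigue = 1) class by default;
    ``macro=True`` averages them over classes. An undefined precision
    (no predicted positives) is reported as 0.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) == 0 or len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred must be equal-length and non-empty")
    from sklearn.metrics import accuracy_score, f1_score, precision_score

    if not macro and positive_label in y_true and positive_label not in y_pred:
        import warnings

        warnings.warn("no predicted positives: precision undefined, reported as 0")
    avg = "macro" if macro else "binary"
    kw = {} if macro else {"pos_label": positive_label}
    return {
        "accuracy": float(accuracy_score(y_true, y_pred)),
        "precision": float(precision_score(y_true, y_pred, average=avg, zero_division=0, **kw)),
        "f1": float(f1_score(y_true, y_pred, average=avg, zero_division=0, **kw)),
    }
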