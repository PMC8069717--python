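"""Sparse multi-feature fusion: OMP coding, K-SVD dictionary learning, and
the concatenation / PCA fusion baselines.

The fused representation of an 80-dimensional feature vector is its sparse
code over an undercomplete dictionary (default 20 atoms) learned by K-SVD
on the training samples. Because the dictionary has fewer atoms than the
input dimension, coding both reduces dimension and fuses the heterogeneous
feature families (band powers, entropy) into a common basis. Features are
z-scored with training statistics first so the families are commensurable.

K-SVD alternates orthogonal matching pursuit (OMP) coding of all training
signals with per-atom rank-1 SVD updates of the restricted residual (the
residual over only the signals that use the atom), which is the optimal
single-atom update by the Eckart-Young theorem.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .features import FeatureMatrix

__all__ = [
    "SparseDictionary",
    "SparseCode",
    "FusionResult",
    "omp_encode",
    "ksvd_atom_update",
    "ksvd_learn",
    "fuse",
    "concat_fusion",
    "pca_fusion",
]


@dataclass
class SparseDictionary:
    """Column-normalized atom matrix D (N x M, M < N for fusion use).

    ``training_error_trace`` is the Frobenius reconstruction error of the
    retained (best-so-far) model after each iteration — non-increasing by
    construction; ``iteration_errors`` is the raw per-iteration error,
    which may bump up in iterations where a stalled atom was replaced
    (those iterations are logged in ``replaced_atoms``).
    """

    D: np.ndarray
    seed: int = 0
    n_iters: int = 0
    training_error_trace: list[float] = field(default_factory=list)
    iteration_errors: list[float] = field(default_factory=list)
    replaced_atoms: list[tuple[int, int]] = field(default_factory=list)  # (iter, atom)

    def __post_init__(self) -> None:
        self.D = np.asarray(self.D, dtype=float)
        if self.D.ndim != 2:
            raise ValueError("D must be 2-D (N, M)")
        norms = np.linalg.norm(self.D, axis=0)
        if not np.allclose(norms, 1.0, atol=1e-8):
            raise ValueError("dictionary atoms must be unit-norm")

    @property
    def n_atoms(self) -> int:
        return self.D.shape[1]


@dataclass
class SparseCode:
    alpha: np.ndarray  # (M,)
    support: np.ndarray  # nonzero atom indices, in selection order
    residual_norm: float


@dataclass
class FusionResult:
    """Fused (sparse-coded) train/test features plus learning metadata."""

    train_codes: np.ndarray  # (n_train, M)
    test_codes: np.ndarray  # (n_test, M)
    dictionary: SparseDictionary | None
    method: str
    train_residuals: np.ndarray | None = None
    test_residuals: np.ndarray | None = None


# ---------------------------------------------------------------------------
# OMP
# ---------------------------------------------------------------------------

def omp_encode(
    D: SparseDictionary | np.ndarray, x: np.ndarray, T0: int, tol: float = 0.0
) -> SparseCode:
    """Orthogonal matching pursuit.

    Greedily selects the atom with maximal |correlation| with the current
    residual (ties: lowest atom index), re-fits all selected coefficients
    by least squares, and stops after T0 atoms or when the residual norm
    drops to ``tol``. Deterministic; a zero input yields an empty code.
    """
    A = D.D if isinstance(D, SparseDictionary) else np.asarray(D, dtype=float)
    x = np.asarray(x, dtype=float)
    if T0 < 1:
        raise ValueError("T0 must be >= 1")
    M = A.shape[1]
    alpha = np.zeros(M)
    support: list[int] = []
    r = x.copy()
    rnorm = float(np.linalg.norm(r))
    if rnorm == 0:
        return SparseCode(alpha=alpha, support=np.array([], dtype=int), residual_norm=0.0)
    coef = np.empty(0)
    while len(support) < min(T0, M) and rnorm > tol:
        corr = np.abs(A.T @ r)
        corr[support] = -np.inf  # never reselect
        j = int(np.argmax(corr))  # argmax -> first (lowest index) on ties
        if not np.isfinite(corr[j]) or corr[j] <= 1e-13 * max(rnorm, 1.0):
            break  # residual orthogonal to all remaining atoms
        support.append(j)
        sub = A[:, support]
        # least squares on the support via the (tiny) normal equations;
        # fall back to lstsq if the support is numerically dependent
        G = sub.T @ sub
        try:
            coef = np.linalg.solve(G, sub.T @ x)
        except np.linalg.LinAlgError:
            coef, *_ = np.linalg.lstsq(sub, x, rcond=None)
        r = x - sub @ coef
        rnorm = float(np.linalg.norm(r))
    if support:
        alpha[support] = coef
    return SparseCode(alpha=alpha, support=np.array(support, dtype=int), residual_norm=rnorm)


def _encode_matrix(D: np.ndarray, Y: np.ndarray, T0: int, tol: float = 0.0) -> np.ndarray:
    """OMP-encode every column of Y; returns the coefficient matrix X (M x n).

    Same greedy selection / support re-fit as :func:`omp_encode` (a test
    pins their agreement), with the per-column bookkeeping stripped for the
    inner K-SVD loop.
    """
    M = D.shape[1]
    T = min(T0, M)
    X = np.zeros((M, Y.shape[1]))
    Dt = D.T.copy()
    for j in range(Y.shape[1]):
        x = Y[:, j]
        r = x
        rnorm = np.linalg.norm(r)
        if rnorm == 0:
            continue
        support: list[int] = []
        coef = None
        while len(support) < T and rnorm > tol:
            corr = np.abs(Dt @ r)
            corr[support] = -np.inf
            k = int(np.argmax(corr))
            if not corr[k] > 1e-13 * max(rnorm, 1.0):
                break
            support.append(k)
            sub = D[:, support]
            G = sub.T @ sub
            try:
                coef = np.linalg.solve(G, sub.T @ x)
            except np.linalg.LinAlgError:
                coef, *_ = np.linalg.lstsq(sub, x, rcond=None)
            r = x - sub @ coef
            rnorm = np.linalg.norm(r)
        if support:
            X[support, j] = coef
    return X


# ---------------------------------------------------------------------------
# K-SVD
# ---------------------------------------------------------------------------

def ksvd_atom_update(
    Y: np.ndarray, D: np.ndarray, X: np.ndarray, k: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Rank-1 update of atom k and its coefficient row.

    Restricted to the signals that use atom k: the residual without atom k
    is formed over those columns and its best rank-1 approximation (leading
    SVD pair) replaces (d_k, x_k). Returns (d_new, x_row_new, used_columns);
    an unused atom raises ValueError (callers handle replacement).

    Sign convention: the largest-magnitude entry of the new atom is positive.
    """
    used = np.flatnonzero(X[k] != 0)
    if used.size == 0:
        raise ValueError(f"atom {k} is unused")
    # residual of the used columns with atom k's contribution removed
    E = Y[:, used] - D @ X[:, used] + np.outer(D[:, k], X[k, used])
    U, s, Vt = np.linalg.svd(E, full_matrices=False)
    d_new = U[:, 0]
    x_new = s[0] * Vt[0]
    pivot = np.argmax(np.abs(d_new))
    if d_new[pivot] < 0:
        d_new, x_new = -d_new, -x_new
    return d_new, x_new, used


def _init_dictionary(Y: np.ndarray, M: int, rng: np.random.Generator) -> np.ndarray:
    """M distinct training columns (excluding near-zero ones), normalized."""
    norms = np.linalg.norm(Y, axis=0)
    usable = np.flatnonzero(norms > 1e-12)
    if usable.size < M:
        raise ValueError("not enough nonzero training signals to seed the dictionary")
    cols = rng.choice(usable, size=M, replace=False)
    D = Y[:, cols] / norms[cols]
    return D


def ksvd_learn(
    Y: np.ndarray,
    M: int = 20,
    T0: int = 8,
    max_iters: int = 50,
    tol: float = 1e-4,
    seed: int = 0,
    usage_threshold: int = 4,
    coherence_threshold: float = 0.95,
    stall_patience: int = 10,
) -> tuple[SparseDictionary, np.ndarray]:
    """Learn an M-atom dictionary for the signal matrix Y (N x n_train).

    Alternates OMP coding of all columns (sparsity T0) with column-by-column
    atom updates. The coding stage keeps a column's previous code when the
    freshly computed one reconstructs it worse, so the objective never
    increases within an alternation.

    Degenerate atoms — unused, used by fewer than ``usage_threshold``
    signals, or nearly collinear with another atom (|correlation| above
    ``coherence_threshold``) — are replaced by the worst-reconstructed
    training column; when an iteration improves the objective by less than
    ``tol`` (relative Frobenius error) the least-used atom is replaced as
    well, a deliberate perturbation to escape the local minima dictionary
    learning is prone to. Learning stops at ``max_iters``, at (numerical)
    exact reconstruction, or after ``stall_patience`` consecutive stalled
    iterations. The best (D, X) pair ever seen is returned.
    """
    Y = np.asarray(Y, dtype=float)
    n_train = Y.shape[1]
    if n_train < M:
        raise ValueError(f"need at least M={M} training signals, got {n_train}")
    rng = np.random.default_rng(seed)
    D = _init_dictionary(Y, M, rng)
    ynorm = float(np.linalg.norm(Y))
    raw_errors: list[float] = []
    best_trace: list[float] = []
    replaced: list[tuple[int, int]] = []
    X = np.zeros((M, n_train))
    best_err, best_D, best_X = np.inf, D.copy(), X.copy()
    prev_err, stall = np.inf, 0
    for it in range(max_iters):
        X_new = _encode_matrix(D, Y, T0)
        worse = np.linalg.norm(Y - D @ X_new, axis=0) > np.linalg.norm(Y - D @ X, axis=0)
        X_new[:, worse] = X[:, worse]
        X = X_new
        for k in range(M):
            try:
                d_new, x_new, used = ksvd_atom_update(Y, D, X, k)
            except ValueError:
                continue  # unused atom; handled by replacement below
            D[:, k] = d_new
            X[k, :] = 0.0
            X[k, used] = x_new
        err = float(np.linalg.norm(Y - D @ X))
        raw_errors.append(err)
        if err < best_err:
            best_err, best_D, best_X = err, D.copy(), X.copy()
        best_trace.append(best_err)

        stalled = prev_err - err < tol * max(ynorm, 1e-300)
        stall = stall + 1 if stalled else 0
        prev_err = err
        if ynorm == 0 or err / ynorm < 1e-8 or stall > stall_patience:
            break

        gram = np.abs(D.T @ D) - np.eye(M)
        usage = (X != 0).sum(axis=1)
        degenerate = {
            k for k in range(M)
            if usage[k] < usage_threshold or gram[k, :k].max(initial=0.0) > coherence_threshold
        }
        if stalled:
            degenerate.add(int(np.argmin(usage)))
        if degenerate:
            col_err = np.linalg.norm(Y - D @ X, axis=0)
            for k in sorted(degenerate):
                worst = int(np.argmax(col_err))
                norm = np.linalg.norm(Y[:, worst])
                if norm > 1e-12:
                    D[:, k] = Y[:, worst] / norm
                    X[k] = 0.0
                    replaced.append((it, int(k)))
                    col_err[worst] = 0.0
    dictionary = SparseDictionary(
        D=best_D, seed=seed, n_iters=len(raw_errors),
        training_error_trace=best_trace, iteration_errors=raw_errors,
        replaced_atoms=replaced,
    )
    return dictionary, best_X


# ---------------------------------------------------------------------------
# Fusion front-ends
# ---------------------------------------------------------------------------

def _check_aligned(train: FeatureMatrix, test: FeatureMatrix) -> None:
    if train.column_index != test.column_index:
        raise ValueError("train and test feature columns differ")


def _standardize(train: FeatureMatrix, test: FeatureMatrix, drop_constant: bool = False):
    """z-score both sets with the training mean/sd."""
    mu = train.values.mean(axis=0)
    sd = train.values.std(axis=0)
    const = sd == 0
    if drop_constant and const.any():
        warnings.warn(f"dropping {const.sum()} constant column(s)")
        keep = ~const
        tr = (train.values[:, keep] - mu[keep]) / sd[keep]
        te = (test.values[:, keep] - mu[keep]) / sd[keep]
        return tr, te
    sd_safe = np.where(const, 1.0, sd)
    return (train.values - mu) / sd_safe, (test.values - mu) / sd_safe


def fuse(
    train: FeatureMatrix,
    test: FeatureMatrix,
    M: int = 20,
    T0: int = 8,
    max_iters: int = 50,
    tol: float = 1e-4,
    seed: int = 0,
) -> FusionResult:
    """Sparse fusion: learn a K-SVD dictionary on the (z-scored) training
    samples and return the OMP codes of train and test samples.

    Signals are the standardized feature vectors (one per epoch), so the
    dictionary is N x M with N the feature dimension (80 in the full
    montage) and M < N.
    """
    _check_aligned(train, test)
    if len(np.unique(train.labels)) < 2:
        raise ValueError("training set must contain both classes")
    tr, te = _standardize(train, test)
    dictionary, Xtr = ksvd_learn(tr.T, M=M, T0=T0, max_iters=max_iters, tol=tol, seed=seed)
    train_codes = _encode_matrix(dictionary.D, tr.T, T0).T
    test_codes = _encode_matrix(dictionary.D, te.T, T0).T
    tr_res = np.linalg.norm(tr.T - dictionary.D @ train_codes.T, axis=0)
    te_res = np.linalg.norm(te.T - dictionary.D @ test_codes.T, axis=0)
    return FusionResult(
        train_codes=train_codes,
        test_codes=test_codes,
        dictionary=dictionary,
        method="sparse",
        train_residuals=tr_res,
        test_residuals=te_res,
    )


def concat_fusion(train: FeatureMatrix, test: FeatureMatrix) -> FusionResult:
    """Concatenation baseline: the standardized features themselves (any
    constant training column is dropped with a warning)."""
    _check_aligned(train, test)
    tr, te = _standardize(train, test, drop_constant=True)
    return FusionResult(train_codes=tr, test_codes=te, dictionary=None, method="concat")


def pca_fusion(
    train: FeatureMatrix, test: FeatureMatrix, n_components: int = 20
) -> FusionResult:
    """PCA baseline: project standardized features onto the training
    principal components. Rank-deficient training data keeps the available
    components with a warning."""
    _check_aligned(train, test)
    from sklearn.decomposition import PCA

    tr, te = _standardize(train, test)
    max_comp = min(tr.shape[0], tr.shape[1])
    if n_components > max_comp:
        warnings.warn(
            f"n_components={n_components} exceeds available rank; using {max_comp}"
        )
        n_components = max_comp
    pca = PCA(n_components=n_components, svd_solver="full")
    train_codes = pca.fit_transform(tr)
    test_codes = pca.transform(te)
    return FusionResult(
        train_codes=train_codes, test_codes=test_codes, dictionary=None, method="pca"
    )
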