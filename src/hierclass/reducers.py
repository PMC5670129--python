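"""The four per-node discriminant / dimensionality-reduction methods.

Each node of the hierarchy is fitted with one of four linear methods behind a
single fit/score interface:

``PLS``
    SIMPLS partial least squares: components maximize covariance between the
    centered data and a one-hot class-indicator matrix (between-class variance,
    ignoring within-class variance).
``MMC-LDA``
    Maximum margin criterion: top eigenvectors of ``S_b - S_w``, maximizing
    between-class scatter while minimizing within-class scatter without
    inverting ``S_w`` (so it tolerates singular within-class scatter).
``PCA-LDA``
    Fisherfaces: PCA to a ``min(n - c, d)``-dimensional subspace where ``S_w``
    is nonsingular, then Fisher LDA (generalized eigenproblem
    ``S_b w = lambda S_w w``), enabling LDA when features outnumber samples.
``SVM``
    One-vs-rest linear support vector machines; scores are the signed
    decision values per class.

All methods are deterministic: eigen/singular-vector sign is fixed by making
each projection column's largest-magnitude element positive.

Scatter matrices use biased (divide-by-n) scaling throughout; only relative
scaling matters to the eigenvectors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
from sklearn.svm import SVC

METHODS = ("PLS", "MMC-LDA", "PCA-LDA", "SVM")
#: tie-break priority, most computationally efficient first
METHOD_PRIORITY = ("PLS", "MMC-LDA", "PCA-LDA", "SVM")


@dataclass
class ReducedModel:
    """A fitted linear reducer: centering + projection (or SVM hyperplanes)."""

    method: str
    W: np.ndarray  # features x k projection (or hyperplane normals for SVM)
    center: np.ndarray  # training column means
    k: int
    intercept: np.ndarray | None = None  # SVM only
    classes: list = field(default_factory=list)
    training_scores: np.ndarray | None = None
    eigenvalues: np.ndarray | None = None

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "W": self.W.tolist(),
            "center": self.center.tolist(),
            "k": self.k,
            "intercept": None if self.intercept is None else self.intercept.tolist(),
            "classes": list(self.classes),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ReducedModel":
        return cls(
            method=d["method"],
            W=np.asarray(d["W"], dtype=float),
            center=np.asarray(d["center"], dtype=float),
            k=int(d["k"]),
            intercept=None
            if d.get("intercept") is None
            else np.asarray(d["intercept"], dtype=float),
            classes=list(d.get("classes", [])),
        )


def _fix_signs(W: np.ndarray) -> np.ndarray:
    """Make each column's largest-magnitude element positive (reproducible sign)."""
    W = np.array(W, dtype=float)
    for j in range(W.shape[1]):
        i = int(np.argmax(np.abs(W[:, j])))
        if W[i, j] < 0:
            W[:, j] = -W[:, j]
    return W


def encode_labels(y) -> tuple[np.ndarray, list]:
    """Map arbitrary (hashable) labels to integer codes.

    Labels may be tuples (node paths), so plain ``np.asarray`` would mangle
    them into 2-D arrays; classes are sorted by string form for determinism.
    """
    ylist = list(y)
    classes = sorted(set(ylist), key=lambda c: str(c))
    lut = {c: j for j, c in enumerate(classes)}
    return np.asarray([lut[v] for v in ylist], dtype=int), classes


def _one_hot(y) -> tuple[np.ndarray, list]:
    codes, classes = encode_labels(y)
    Y = np.zeros((len(codes), len(classes)))
    Y[np.arange(len(codes)), codes] = 1.0
    return Y, classes


def scatter_matrices(X: np.ndarray, y) -> tuple[np.ndarray, np.ndarray]:
    """Between- and within-class scatter ``(S_b, S_w)``, biased divide-by-n."""
    X = np.asarray(X, dtype=float)
    codes, classes = encode_labels(y)
    n, d = X.shape
    mu = X.mean(axis=0)
    S_b = np.zeros((d, d))
    S_w = np.zeros((d, d))
    for j in range(len(classes)):
        Xc = X[codes == j]
        mc = Xc.mean(axis=0)
        dm = mc - mu
        S_b += len(Xc) / n * np.outer(dm, dm)
        R = Xc - mc
        S_w += R.T @ R / n
    return S_b, S_w


# --------------------------------------------------------------------------
# SIMPLS


def fit_simpls(X: np.ndarray, Y: np.ndarray, k: int) -> ReducedModel:
    """SIMPLS partial least squares (de Jong's direct-deflation algorithm).

    Parameters
    ----------
    X : (n, d) data matrix, centered internally.
    Y : (n, c) 0/1 class-indicator matrix (or any response matrix).
    k : number of components; truncated with a warning if it exceeds the rank
        of the centered data.

    Weights are scaled so score vectors have unit norm; score vectors are
    mutually orthogonal.  Deterministic up to the fixed sign convention.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, d = X.shape
    if n < 2 or k < 1:
        raise ValueError("need n >= 2 samples and k >= 1 components")
    center = X.mean(axis=0)
    X0 = X - center
    Y0 = Y - Y.mean(axis=0)
    if not np.any(np.abs(X0) > 1e-12):
        raise ValueError("zero-variance input")
    rank = np.linalg.matrix_rank(X0)
    if k > rank:
        warnings.warn(
            f"requested k={k} exceeds rank {rank} of centered data; truncating",
            stacklevel=2,
        )
        k = rank

    S = X0.T @ Y0
    R = np.zeros((d, k))  # x-weights: T = X0 @ R
    V = np.zeros((d, k))  # orthonormal basis of x-loadings, for deflation
    T = np.zeros((n, k))
    for a in range(k):
        # dominant left singular vector of the (deflated) covariance
        U, sv, _ = np.linalg.svd(S, full_matrices=False)
        r = U[:, 0]
        t = X0 @ r
        nt = np.linalg.norm(t)
        if nt < 1e-12:
            warnings.warn("covariance exhausted; truncating components", stacklevel=2)
            R, T, V = R[:, :a], T[:, :a], V[:, :a]
            k = a
            break
        t /= nt
        r = r / nt
        p = X0.T @ t
        v = p - V[:, :a] @ (V[:, :a].T @ p)
        nv = np.linalg.norm(v)
        if nv < 1e-12:
            R, T, V = R[:, :a], T[:, :a], V[:, :a]
            k = a
            break
        v /= nv
        S = S - np.outer(v, v.T @ S)
        R[:, a], T[:, a], V[:, a] = r, t, v
    if k == 0:
        raise ValueError("zero-variance input")
    # fixed sign convention applied consistently to weights and scores
    signs = np.ones(k)
    for j in range(k):
        i = int(np.argmax(np.abs(R[:, j])))
        if R[i, j] < 0:
            signs[j] = -1.0
    R = R * signs
    # recompute through the scoring path so stored scores match score() bitwise
    return ReducedModel(
        method="PLS", W=R, center=center, k=k, training_scores=(X - center) @ R
    )


# --------------------------------------------------------------------------
# MMC-LDA


def fit_mmc_lda(X: np.ndarray, y, k: int | None = None) -> ReducedModel:
    """Maximum margin criterion LDA: top-k eigenvectors of ``S_b - S_w``.

    Defaults to ``k = n_classes - 1``.  Works even when ``S_w`` is singular
    (one sample per class gives pure between-class directions).
    """
    X = np.asarray(X, dtype=float)
    _, classes = encode_labels(y)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    if k is None:
        k = len(classes) - 1
    k = min(k, X.shape[1])
    S_b, S_w = scatter_matrices(X, y)
    evals, evecs = scipy.linalg.eigh(S_b - S_w)
    order = np.argsort(evals)[::-1][:k]
    W = _fix_signs(evecs[:, order])
    center = X.mean(axis=0)
    return ReducedModel(
        method="MMC-LDA",
        W=W,
        center=center,
        k=k,
        classes=classes,
        eigenvalues=evals[order],
        training_scores=(X - center) @ W,
    )


# --------------------------------------------------------------------------
# PCA-LDA (Fisherfaces)


def fit_pca_lda(X: np.ndarray, y) -> ReducedModel:
    """Fisherfaces: PCA to ``min(n - c, d)`` components, then Fisher LDA.

    The PCA step guarantees a subspace in which the within-class scatter is
    (generically) nonsingular, evading the small-sample-size problem when
    ``d > n``.  Output dimension is ``c - 1``.
    """
    X = np.asarray(X, dtype=float)
    _, classes = encode_labels(y)
    c = len(classes)
    if c < 2:
        raise ValueError("need at least 2 classes")
    n, d = X.shape
    if n <= c:
        raise ValueError("insufficient samples for Fisherfaces (need n > n_classes)")
    center = X.mean(axis=0)
    X0 = X - center
    m = min(n - c, d)
    # PCA via SVD of the centered data
    U, sv, Vt = np.linalg.svd(X0, full_matrices=False)
    nz = sv > 1e-10 * sv[0] if sv[0] > 0 else sv > 0
    W_pca = Vt[nz][:m].T  # d x m'
    Z = X0 @ W_pca
    S_b, S_w = scatter_matrices(Z, y)
    # small ridge guards exact singularity from degenerate class layouts
    ridge = 1e-10 * (np.trace(S_w) / max(S_w.shape[0], 1) + 1.0)
    evals, evecs = scipy.linalg.eigh(S_b, S_w + ridge * np.eye(S_w.shape[0]))
    order = np.argsort(evals)[::-1][: c - 1]
    W_lda = evecs[:, order]
    W = W_pca @ W_lda
    W = W / np.linalg.norm(W, axis=0, keepdims=True)
    W = _fix_signs(W)
    return ReducedModel(
        method="PCA-LDA",
        W=W,
        center=center,
        k=c - 1,
        classes=classes,
        eigenvalues=evals[order],
        training_scores=(X - center) @ W,
    )


# --------------------------------------------------------------------------
# linear SVM


def fit_linear_svm(X: np.ndarray, y, C: float = 1.0) -> ReducedModel:
    """One-vs-rest linear SVMs; one hyperplane per class.

    Hyperplanes are extracted to plain arrays so the model serializes and
    scores without the fitted estimators.  Scores are signed decision values,
    one column per class (class order sorted by name).
    """
    X = np.asarray(X, dtype=float)
    codes, classes = encode_labels(y)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    d = X.shape[1]
    W = np.zeros((d, len(classes)))
    b = np.zeros(len(classes))
    for j, cl in enumerate(classes):
        yy = (codes == j).astype(int)
        svc = SVC(kernel="linear", C=C)
        svc.fit(X, yy)
        w = svc.coef_.ravel()
        bj = float(svc.intercept_[0])
        # libsvm's positive class is its internal label 1 == our class cl
        W[:, j] = w
        b[j] = bj
    return ReducedModel(
        method="SVM",
        W=W,
        center=np.zeros(d),
        k=len(classes),
        intercept=b,
        classes=classes,
        training_scores=X @ W + b,
    )


# --------------------------------------------------------------------------
# shared scoring


def score(model: ReducedModel, X_new: np.ndarray) -> np.ndarray:
    """Apply the stored centering and projection / decision function."""
    X_new = np.asarray(X_new, dtype=float)
    if X_new.ndim == 1:
        X_new = X_new[None, :]
    if X_new.shape[1] != model.W.shape[0]:
        raise ValueError(
            f"feature count mismatch: model expects {model.W.shape[0]}, "
            f"got {X_new.shape[1]}"
        )
    if model.method == "SVM":
        return X_new @ model.W + model.intercept
    return (X_new - model.center) @ model.W


def fit_reducer(
    method: str,
    X: np.ndarray,
    y,
    pls_components: int | None = None,
    svm_C: float = 1.0,
) -> ReducedModel:
    """Dispatch to the reducer named by ``method`` with its default settings."""
    if method == "PLS":
        Y, classes = _one_hot(y)
        n, d = np.asarray(X).shape
        k = pls_components
        if k is None:
            k = max(1, min(15, n - 1, d))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # silent rank truncation at small nodes
            m = fit_simpls(X, Y, k)
        m.classes = classes
        return m
    if method == "MMC-LDA":
        return fit_mmc_lda(X, y)
    if method == "PCA-LDA":
        return fit_pca_lda(X, y)
    if method == "SVM":
        return fit_linear_svm(X, y, C=svm_C)
    raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
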