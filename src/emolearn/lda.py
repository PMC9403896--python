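"""Fisher linear discriminant analysis.

Scatter-matrix machinery and a shared-covariance Gaussian classifier in
the discriminant subspace.  For c classes with per-class means mu_i and
grand mean a_bar,

    S_b = sum_i N_i (mu_i - a_bar)(mu_i - a_bar)^T     (between-class)
    S_w = sum_i sum_{j in C_i} (a_j - mu_i)(a_j - mu_i)^T   (within-class)
    S_m = S_w + S_b = sum_j (a_j - a_bar)(a_j - a_bar)^T    (mixed)

The transformation W maximises the Fisher ratio |W^T S_b W| / |W^T S_w W|;
its columns are the leading eigenvectors of (S_w + ridge I)^{-1} S_b.
Classification uses the linear Gaussian discriminant score in the
projected space:

    score_c(a) = mu_c^T Sigma^{-1} a' - 1/2 mu_c^T Sigma^{-1} mu_c + log p_c

with a' = W^T a, pooled covariance Sigma and class priors p_c.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

__all__ = [
    "ScatterTriple",
    "LDAModel",
    "class_means",
    "scatter_matrices",
    "fit_lda",
    "lda_classify",
    "lda_predict",
]

_SCATTER_TOL = 1e-9


@dataclass
class ScatterTriple:
    """Between-class (S_b), within-class (S_w) and mixed (S_m) scatter
    matrices, with the class statistics they were built from."""

    S_b: np.ndarray
    S_w: np.ndarray
    S_m: np.ndarray
    N: int
    N_i: dict[str, int]
    mu_i: dict[str, np.ndarray]
    a_bar: np.ndarray


def _split_classes(X: np.ndarray, y) -> dict[str, np.ndarray]:
    y = np.asarray(y)
    return {str(c): X[y == c] for c in sorted(np.unique(y).tolist())}


def class_means(X, y, classes=None) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Per-class arithmetic means mu_i and the grand mean a_bar.

    Each class mean divides by its own sample count N_i.  If ``classes``
    is given, every listed class must be present; a missing (empty) class
    raises an error naming it.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 1:
        raise ValueError("X must be a non-empty 2-D matrix")
    groups = _split_classes(X, y)
    if classes is not None:
        for c in classes:
            if str(c) not in groups or len(groups[str(c)]) == 0:
                raise ValueError(f"class {c!r} has no samples")
    mu = {c: rows.mean(axis=0) for c, rows in groups.items()}
    return mu, X.mean(axis=0)


def scatter_matrices(X, y) -> ScatterTriple:
    """Compute S_b, S_w and S_m and verify S_m = S_w + S_b internally."""
    X = np.asarray(X, dtype=float)
    mu, a_bar = class_means(X, y)
    groups = _split_classes(X, y)
    d = X.shape[1]
    S_b = np.zeros((d, d))
    S_w = np.zeros((d, d))
    N_i = {}
    for c, rows in groups.items():
        N_i[c] = len(rows)
        diff_b = (mu[c] - a_bar)[:, None]
        S_b += N_i[c] * (diff_b @ diff_b.T)
        centered = rows - mu[c]
        S_w += centered.T @ centered
    S_m = S_w + S_b
    # conservation check against the direct total-scatter form
    direct = (X - a_bar).T @ (X - a_bar)
    scale = max(1.0, float(np.abs(S_m).max()))
    if np.abs(S_m - direct).max() > _SCATTER_TOL * scale:
        raise AssertionError("scatter identity S_m = S_w + S_b violated")
    return ScatterTriple(
        S_b=S_b, S_w=S_w, S_m=S_m, N=X.shape[0], N_i=N_i, mu_i=mu, a_bar=a_bar
    )


@dataclass
class LDAModel:
    """Fitted Fisher discriminant.

    W projects d-dimensional inputs to r <= c-1 dimensions; the classifier
    stores the projected class means, the pooled projected covariance and
    the class priors.
    """

    W: np.ndarray
    r: int
    classes: list[str]
    class_means_proj: np.ndarray  # (c, r)
    shared_cov_proj: np.ndarray  # (r, r)
    priors: np.ndarray  # (c,)
    ridge: float

    def to_dict(self) -> dict:
        return {
            "W": {"shape": list(self.W.shape), "data": self.W.tolist()},
            "r": self.r,
            "classes": self.classes,
            "class_means_proj": self.class_means_proj.tolist(),
            "shared_cov_proj": self.shared_cov_proj.tolist(),
            "priors": self.priors.tolist(),
            "ridge": self.ridge,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LDAModel":
        return cls(
            W=np.array(d["W"]["data"]).reshape(d["W"]["shape"]),
            r=int(d["r"]),
            classes=list(d["classes"]),
            class_means_proj=np.array(d["class_means_proj"]),
            shared_cov_proj=np.array(d["shared_cov_proj"]),
            priors=np.array(d["priors"]),
            ridge=float(d["ridge"]),
        )


def fit_lda(X, y, r: int | None = None, ridge: float | None = None, priors=None) -> LDAModel:
    """Fit the Fisher discriminant by generalized eigendecomposition.

    Columns of W are the top-r eigenvectors of (S_w + ridge I)^{-1} S_b;
    r must not exceed c - 1.  ``ridge=None`` applies the default
    1e-6 * trace(S_w)/d, which regularises the (typically singular)
    within-class scatter of image data; ``ridge=0`` requires S_w to be
    non-singular.  Priors default to the empirical class frequencies.
    """
    X = np.asarray(X, dtype=float)
    scat = scatter_matrices(X, y)
    classes = sorted(scat.N_i)
    c = len(classes)
    d = X.shape[1]
    if r is None:
        r = c - 1
    if not 1 <= r <= c - 1:
        raise ValueError(f"r must satisfy 1 <= r <= c-1 = {c - 1}, got {r}")
    if ridge is None:
        base = float(np.trace(scat.S_w)) / d
        if base <= 0:  # degenerate: identical samples within every class
            base = max(float(np.trace(scat.S_m)) / d, 1.0)
        ridge = 1e-6 * base
    if ridge < 0:
        raise ValueError("ridge must be >= 0")
    Sw_r = scat.S_w + ridge * np.eye(d)
    if ridge == 0:
        try:
            scipy.linalg.cholesky(Sw_r)
        except scipy.linalg.LinAlgError:
            raise np.linalg.LinAlgError(
                "within-class scatter is singular; refit with ridge > 0"
            ) from None
    evals, evecs = scipy.linalg.eigh(scat.S_b, Sw_r)
    order = np.argsort(evals)[::-1][:r]
    W = evecs[:, order]
    # deterministic sign: largest-magnitude entry of each column positive
    for j in range(W.shape[1]):
        k = np.argmax(np.abs(W[:, j]))
        if W[k, j] < 0:
            W[:, j] = -W[:, j]

    proj = X @ W
    y_arr = np.asarray(y).astype(str)
    means = np.vstack([proj[y_arr == cl].mean(axis=0) for cl in classes])
    # pooled within-class covariance in the projected space
    Sw_proj = W.T @ scat.S_w @ W
    dof = max(scat.N - c, 1)
    cov = Sw_proj / dof
    cov = (cov + cov.T) / 2.0
    cov += 1e-10 * max(1.0, float(np.trace(cov)) / r) * np.eye(r)
    if priors is None:
        pr = np.array([scat.N_i[cl] / scat.N for cl in classes])
    else:
        pr = np.asarray(priors, dtype=float)
        pr = pr / pr.sum()
    return LDAModel(
        W=W,
        r=r,
        classes=classes,
        class_means_proj=means,
        shared_cov_proj=cov,
        priors=pr,
        ridge=float(ridge),
    )


def _scores(model: LDAModel, A: np.ndarray) -> np.ndarray:
    proj = A @ model.W
    Sinv_mu = np.linalg.solve(model.shared_cov_proj, model.class_means_proj.T)  # (r, c)
    lin = proj @ Sinv_mu  # (n, c)
    const = -0.5 * np.sum(model.class_means_proj.T * Sinv_mu, axis=0)
    return lin + const + np.log(model.priors)


def lda_classify(model: LDAModel, a) -> tuple[str, dict[str, float]]:
    """Classify one d-vector; returns (label, per-class log-posterior
    scores).  Ties break to the lexicographically first class label."""
    a = np.asarray(a, dtype=float)
    if a.ndim != 1 or a.shape[0] != model.W.shape[0]:
        raise ValueError(
            f"expected a vector of dimension {model.W.shape[0]}, got shape {a.shape}"
        )
    s = _scores(model, a[None, :])[0]
    # classes are stored sorted, so argmax (first maximum) is the
    # lexicographic tie-break
    label = model.classes[int(np.argmax(s))]
    return label, {cl: float(v) for cl, v in zip(model.classes, s)}


def lda_predict(model: LDAModel, A) -> list[str]:
    """Batch classification of the rows of A."""
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[1] != model.W.shape[0]:
        raise ValueError("dimension mismatch")
    s = _scores(model, A)
    return [model.classes[i] for i in np.argmax(s, axis=1)]
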