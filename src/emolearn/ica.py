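"""Negentropy-driven independent component analysis.

Facial images are centred and PCA-whitened, then unmixing directions are
extracted one at a time by the fixed-point (Newton-type) iteration

    w+  =  E{x g(w^T x)} - E{g'(w^T x)} w,       w+ <- w+ / |w+|

whose fixed points satisfy the stationarity condition
E{x g(w^T x)} = beta w with beta = E{(w0^T x) g(w0^T x)}.  Independence is
judged by non-Gaussianity via the negentropy approximation

    J_G(b) ~= [ E{G(b)} - E{G(v)} ]^2,

v a standard Gaussian and G a non-quadratic contrast (log cosh by
default; a Gaussian-weighted exponential is available).  Negentropy is
used comparatively, for screening and diagnostics — the kurtosis
criterion is deliberately avoided as unstable — so the approximation's
overall scale constant is immaterial and fixed to one.

Deflation with Gram-Schmidt orthogonalisation keeps the unmixing rows
orthonormal in the whitened space.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import scipy.integrate

__all__ = [
    "WhiteningModel",
    "ICAModel",
    "BasisImageICA",
    "center_whiten",
    "negentropy",
    "fixed_point_update",
    "extract_components",
    "fit_basis_image_ica",
    "project",
]

_CONTRASTS = ("logcosh", "exp")


def _G(u: np.ndarray, contrast: str) -> np.ndarray:
    if contrast == "logcosh":
        # stable log cosh: |u| + log1p(exp(-2|u|)) - log 2
        au = np.abs(u)
        return au + np.log1p(np.exp(-2.0 * au)) - np.log(2.0)
    if contrast == "exp":
        return -np.exp(-0.5 * u**2)
    raise ValueError(f"unknown contrast {contrast!r}; expected one of {_CONTRASTS}")


def _g(u: np.ndarray, contrast: str) -> np.ndarray:
    """Derivative of the contrast G."""
    if contrast == "logcosh":
        return np.tanh(u)
    if contrast == "exp":
        return u * np.exp(-0.5 * u**2)
    raise ValueError(f"unknown contrast {contrast!r}")


def _g_prime(u: np.ndarray, contrast: str) -> np.ndarray:
    if contrast == "logcosh":
        return 1.0 - np.tanh(u) ** 2
    if contrast == "exp":
        return (1.0 - u**2) * np.exp(-0.5 * u**2)
    raise ValueError(f"unknown contrast {contrast!r}")


@lru_cache(maxsize=None)
def _gaussian_expectation(contrast: str) -> float:
    """E{G(v)} for v ~ N(0,1), by high-resolution quadrature (cached)."""

    def integrand(u):
        return _G(np.asarray(u), contrast) * np.exp(-0.5 * u * u) / np.sqrt(2 * np.pi)

    val, _ = scipy.integrate.quad(integrand, -np.inf, np.inf, limit=200)
    return float(val)


@dataclass
class WhiteningModel:
    """Centering + PCA whitening: z = V (a - mean).

    V has shape (k, d); k is the number of principal directions whose
    eigenvalue exceeds ``eigenvalue_floor`` times the largest eigenvalue.
    V cov(X_centered) V^T = I_k by construction.
    """

    mean: np.ndarray
    V: np.ndarray
    k: int
    eigenvalue_floor: float
    eigenvalues: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.mean.shape[0]:
            raise ValueError("dimension mismatch in whitening transform")
        return (X - self.mean) @ self.V.T

    def inverse_transform(self, Z: np.ndarray) -> np.ndarray:
        """Map whitened coordinates back to the retained subspace of the
        original space."""
        Z = np.atleast_2d(np.asarray(Z, dtype=float))
        # V^+ = V^T diag(lambda) restricted to retained directions
        Vpinv = np.linalg.pinv(self.V)
        return Z @ Vpinv.T + self.mean

    def to_dict(self) -> dict:
        return {
            "mean": self.mean.tolist(),
            "V": {"shape": list(self.V.shape), "data": self.V.tolist()},
            "k": self.k,
            "eigenvalue_floor": self.eigenvalue_floor,
            "eigenvalues": self.eigenvalues.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "WhiteningModel":
        return cls(
            mean=np.array(d["mean"]),
            V=np.array(d["V"]["data"]).reshape(d["V"]["shape"]),
            k=int(d["k"]),
            eigenvalue_floor=float(d["eigenvalue_floor"]),
            eigenvalues=np.array(d["eigenvalues"]),
        )


def center_whiten(
    X, eigenvalue_floor: float = 1e-6, max_components: int | None = None
) -> tuple[np.ndarray, WhiteningModel]:
    """Centre and PCA-whiten the rows of X.

    Principal directions with eigenvalue below ``eigenvalue_floor`` times
    the largest eigenvalue are dropped; ``max_components`` additionally
    caps the retained dimension at the leading directions (whitening
    equalises variances, so without a cap the low-variance noise floor
    would be amplified to the same scale as the signal subspace).  The
    output has zero column means and identity sample covariance (ddof=1).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("X must be 2-D with at least 2 rows")
    mean = X.mean(axis=0)
    Xc = X - mean
    # economy SVD: eigenvalues of the covariance are s^2 / (n-1)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    evals = s**2 / (X.shape[0] - 1)
    if evals.size == 0 or evals[0] <= 0:
        raise ValueError("input has zero variance; cannot whiten")
    keep = evals > eigenvalue_floor * evals[0]
    k = int(keep.sum())
    if max_components is not None:
        if max_components < 1:
            raise ValueError("max_components must be >= 1")
        k = min(k, max_components)
    V = Vt[:k] / np.sqrt(evals[:k])[:, None]
    model = WhiteningModel(
        mean=mean, V=V, k=k, eigenvalue_floor=eigenvalue_floor, eigenvalues=evals[:k]
    )
    return Xc @ V.T, model


def negentropy(b, contrast: str = "logcosh") -> float:
    """Negentropy approximation J_G(b) = [E{G(b)} - E{G(v)}]^2.

    ``b`` must be standardised (mean 0, variance 1, within 0.05); the
    Gaussian reference expectation is computed once by quadrature and
    cached.  Zero iff b looks Gaussian through the contrast; always >= 0.
    """
    b = np.asarray(b, dtype=float).ravel()
    if b.size < 2:
        raise ValueError("need at least 2 samples")
    m, v = b.mean(), b.var()
    if abs(m) > 0.05 or abs(v - 1.0) > 0.05:
        raise ValueError(
            f"input must be standardised (mean 0, var 1); got mean {m:.3f}, var {v:.3f}"
        )
    diff = float(np.mean(_G(b, contrast))) - _gaussian_expectation(contrast)
    return diff * diff


def fixed_point_update(w, X_white, contrast: str = "logcosh") -> np.ndarray:
    """One Newton-type fixed-point step on a unit direction w.

    w+ = E{x g(w^T x)} - E{g'(w^T x)} w, renormalised to unit length.
    Raises if the update vector vanishes (degenerate direction).
    """
    w = np.asarray(w, dtype=float)
    if abs(np.linalg.norm(w) - 1.0) > 1e-8:
        raise ValueError("w must be unit-norm")
    X = np.asarray(X_white, dtype=float)
    u = X @ w
    w_new = X.T @ _g(u, contrast) / X.shape[0] - np.mean(_g_prime(u, contrast)) * w
    norm = np.linalg.norm(w_new)
    if norm < 1e-12:
        raise FloatingPointError("fixed-point update produced a zero vector")
    return w_new / norm


@dataclass
class ICAModel:
    """Whitening + orthonormal unmixing rows extracted by deflation."""

    whitening: WhiteningModel
    W_unmix: np.ndarray  # (m, k), rows orthonormal
    contrast: str
    converged: list[bool]
    iterations: list[int]

    @property
    def m(self) -> int:
        return self.W_unmix.shape[0]

    def to_dict(self) -> dict:
        return {
            "whitening": self.whitening.to_dict(),
            "W_unmix": {
                "shape": list(self.W_unmix.shape),
                "data": self.W_unmix.tolist(),
            },
            "contrast": self.contrast,
            "converged": self.converged,
            "iterations": self.iterations,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ICAModel":
        return cls(
            whitening=WhiteningModel.from_dict(d["whitening"]),
            W_unmix=np.array(d["W_unmix"]["data"]).reshape(d["W_unmix"]["shape"]),
            contrast=d["contrast"],
            converged=list(d["converged"]),
            iterations=list(d["iterations"]),
        )


def extract_components(
    X,
    m: int,
    tol: float = 1e-6,
    max_iter: int = 200,
    seed: int = 0,
    contrast: str = "logcosh",
    eigenvalue_floor: float = 1e-6,
) -> ICAModel:
    """Extract m independent components by deflation.

    Each unmixing row starts from a seeded random unit vector and iterates
    :func:`fixed_point_update` with Gram-Schmidt orthogonalisation against
    the rows already found; a row stops when |<w_t, w_{t-1}>| > 1 - tol or
    after ``max_iter`` iterations, in which case its ``converged`` flag is
    False (non-convergence is expected, e.g. on Gaussian data, and is not
    an error).

    Whitening retains at most the top-m principal directions (standard
    FastICA dimensionality reduction), so the unmixing matrix is a square
    rotation of the leading signal subspace.
    """
    X_white, whitening = center_whiten(
        X, eigenvalue_floor=eigenvalue_floor, max_components=m
    )
    k = whitening.k
    if m > k:
        raise ValueError(f"m = {m} exceeds the whitened dimension k = {k}")
    rng = np.random.default_rng(seed)
    rows: list[np.ndarray] = []
    converged: list[bool] = []
    iterations: list[int] = []
    for _ in range(m):
        w = rng.normal(size=k)
        if rows:
            W_prev = np.vstack(rows)
            w -= W_prev.T @ (W_prev @ w)
        w /= np.linalg.norm(w)
        ok = False
        it = 0
        for it in range(1, max_iter + 1):
            w_new = fixed_point_update(w, X_white, contrast)
            if rows:
                W_prev = np.vstack(rows)
                w_new -= W_prev.T @ (W_prev @ w_new)
                norm = np.linalg.norm(w_new)
                if norm < 1e-12:
                    break
                w_new /= norm
            if abs(float(w_new @ w)) > 1.0 - tol:
                w = w_new
                ok = True
                break
            w = w_new
        rows.append(w)
        converged.append(ok)
        iterations.append(it)
    return ICAModel(
        whitening=whitening,
        W_unmix=np.vstack(rows),
        contrast=contrast,
        converged=converged,
        iterations=iterations,
    )


@dataclass
class BasisImageICA:
    """Spatially localized ICA representation of a face corpus.

    Instead of treating images as mixtures of independent signals, this
    architecture treats *pixels* as the samples and images as the mixed
    variables: running the fixed-point extraction on the transposed data
    matrix yields independent **basis images** — sparse, spatially
    localized features (mouth region, brow edges, eye area) rather than
    holistic eigenface-like modes.  An image is represented by its
    loadings on these basis images, which is the feature space the
    boosted expression classifier screens: each basis image responds to
    one local facial region, so single-component thresholds carry class
    information.

    ``basis`` has shape (m, d) with unit variance across pixels;
    ``loading_map`` is the pseudo-inverse of the basis, mapping a centred
    image to its m loadings.
    """

    basis: np.ndarray
    mean_image: np.ndarray
    loading_map: np.ndarray
    ica: ICAModel
    restarts: int
    negentropy_total: float

    @property
    def m(self) -> int:
        return self.basis.shape[0]

    def transform(self, X) -> np.ndarray:
        """Loadings of one flattened image (d,) or a batch (n, d)."""
        X = np.asarray(X, dtype=float)
        single = X.ndim == 1
        Xc = np.atleast_2d(X) - self.mean_image
        if Xc.shape[1] != self.mean_image.shape[0]:
            raise ValueError("dimension mismatch in basis-image transform")
        A = Xc @ self.loading_map
        return A[0] if single else A

    def to_dict(self) -> dict:
        return {
            "basis": {"shape": list(self.basis.shape), "data": self.basis.tolist()},
            "mean_image": self.mean_image.tolist(),
            "ica": self.ica.to_dict(),
            "restarts": self.restarts,
            "negentropy_total": self.negentropy_total,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BasisImageICA":
        basis = np.array(d["basis"]["data"]).reshape(d["basis"]["shape"])
        return cls(
            basis=basis,
            mean_image=np.array(d["mean_image"]),
            loading_map=np.linalg.pinv(basis),
            ica=ICAModel.from_dict(d["ica"]),
            restarts=int(d["restarts"]),
            negentropy_total=float(d["negentropy_total"]),
        )


def fit_basis_image_ica(
    X,
    m: int,
    seed: int = 0,
    restarts: int = 5,
    tol: float = 1e-4,
    max_iter: int = 400,
    contrast: str = "logcosh",
    eigenvalue_floor: float = 1e-6,
) -> BasisImageICA:
    """Fit the localized basis-image representation.

    The fixed-point extraction runs on the transposed image matrix (one
    sample per pixel), restarted ``restarts`` times from different seeded
    initialisations; the solution with the largest total negentropy of
    its basis images — the sparsest, most localized one — is kept.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be (n_images, n_pixels)")
    rng = np.random.default_rng(seed)
    best: tuple[float, ICAModel, np.ndarray] | None = None
    for _ in range(max(1, restarts)):
        sub = int(rng.integers(0, 2**31 - 1))
        model = extract_components(
            X.T,
            m=m,
            tol=tol,
            max_iter=max_iter,
            seed=sub,
            contrast=contrast,
            eigenvalue_floor=eigenvalue_floor,
        )
        basis = project(model, X.T).T  # (m, n_pixels), unit variance rows
        J = 0.0
        for row in basis:
            J += negentropy((row - row.mean()) / row.std(), contrast)
        if best is None or J > best[0]:
            best = (J, model, basis)
    J, model, basis = best
    return BasisImageICA(
        basis=basis,
        mean_image=X.mean(axis=0),
        loading_map=np.linalg.pinv(basis),
        ica=model,
        restarts=restarts,
        negentropy_total=float(J),
    )


def project(model: ICAModel, X) -> np.ndarray:
    """Component activations for X: whitening then unmixing.

    Accepts a single d-vector (returns an m-vector) or an (n, d) matrix
    (returns (n, m)).  Deterministic affine map.
    """
    X = np.asarray(X, dtype=float)
    single = X.ndim == 1
    Z = model.whitening.transform(X)
    A = Z @ model.W_unmix.T
    return A[0] if single else A
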