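"""Spatiotemporal and space-only matrix factorizations of trial tensors.

The spatiotemporal decomposition writes each trial's T x N count matrix as
a linear combination of K trial-independent spatiotemporal modules b_k with
trial-dependent activation coefficients h_k^s:

    r^s(t) = sum_k h_k^s b_k(t) + residual,

computed as a factorization R = H B of the (S, T*N) matricization.  The
space-only decomposition factorizes the (S*T, N) matricization instead,
giving L spatial modules with time-resolved activation coefficients.

Four engines solve R = H B: NMF by multiplicative updates minimizing the
Frobenius norm (non-negative modules and coefficients; the update rules
cannot increase the reconstruction error), PCA (orthonormal modules ordered
by explained variance), ICA (Hyvarinen's fixed-point FastICA), and FA
(EM-fit latent factor model with per-variable noise).  PCA/ICA/FA operate
on mean-centred data; the training mean is stored on the decomposition and
reused when inferring coefficients for held-out trials.

All modules are returned with unit Euclidean norm, scales absorbed into
the activation coefficients, so similarity comparisons are scale-free.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA, FactorAnalysis, FastICA

from .core_data import TrialTensor, matricize_spatial, matricize_spatiotemporal

_EPS = np.finfo(float).eps

LINEAR_METHODS = ("pca", "ica", "fa")


@dataclass
class SpatiotemporalDecomposition:
    """K spatiotemporal modules (K, T, N) with trial activations (S, K)."""

    modules: np.ndarray
    activations: np.ndarray
    method: str
    reconstruction_error: float
    mean: np.ndarray | None = None
    objective_history: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_modules(self) -> int:
        return self.modules.shape[0]

    def module_matrix(self) -> np.ndarray:
        """Modules flattened time-major to (K, T*N)."""
        k = self.modules.shape[0]
        return self.modules.reshape(k, -1)

    def reconstruct(self) -> np.ndarray:
        """Reconstructed trials, shape (S, T, N)."""
        flat = self.activations @ self.module_matrix()
        if self.mean is not None:
            flat = flat + self.mean
        s = flat.shape[0]
        return flat.reshape((s,) + self.modules.shape[1:])


@dataclass
class SpaceOnlyDecomposition:
    """L spatial modules (L, N) with time-resolved activations (S, T, L)."""

    spatial_modules: np.ndarray
    activations: np.ndarray
    method: str
    reconstruction_error: float
    mean: np.ndarray | None = None
    objective_history: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_modules(self) -> int:
        return self.spatial_modules.shape[0]


def _normalize_modules(modules: np.ndarray, activations: np.ndarray):
    """Scale each module to unit norm, absorbing scales into activations."""
    norms = np.linalg.norm(modules, axis=1)
    norms[norms == 0] = 1.0
    return modules / norms[:, None], activations * norms[None, :]


def _nmf(X, k, *, max_iter, tol, n_restarts, rng):
    """Multiplicative-update NMF of X ~ H B minimizing ||X - H B||_F^2.

    Returns the best of ``n_restarts`` runs (lowest final error) as
    (H, B, error, history).  The per-iteration objective is recorded; the
    multiplicative updates guarantee it is non-increasing.
    """
    X = np.asarray(X, dtype=float)
    if np.all(X == 0):
        raise ValueError("NMF is undefined for all-zero input")
    if np.any(X < 0):
        raise ValueError("NMF requires non-negative input")
    s, d = X.shape
    if not 1 <= k <= min(s, d):
        raise ValueError(f"module count {k} not in [1, {min(s, d)}]")

    best = None
    for _ in range(n_restarts):
        H = rng.uniform(size=(s, k))
        B = rng.uniform(size=(k, d))
        err = _frob(X - H @ B)
        history = [err]
        for _ in range(max_iter):
            H *= (X @ B.T) / np.maximum(H @ (B @ B.T), _EPS)
            B *= (H.T @ X) / np.maximum((H.T @ H) @ B, _EPS)
            new_err = _frob(X - H @ B)
            history.append(new_err)
            if err > 0 and (err - new_err) <= tol * err:
                err = new_err
                break
            err = new_err
        if best is None or err < best[2]:
            best = (H, B, err, np.asarray(history))
    return best


def _frob(A) -> float:
    return float(np.sum(A * A))


def _fit_linear(X, k, method, rng):
    """Fit PCA/ICA/FA on X (mean-centred internally).

    Returns (scores, modules, mean, error) with X ~ scores @ modules + mean.
    """
    X = np.asarray(X, dtype=float)
    s, d = X.shape
    if method == "pca":
        if k > min(s - 1, d):
            raise ValueError(f"PCA supports at most {min(s - 1, d)} components")
        est = PCA(n_components=k, svd_solver="auto", random_state=_seed_int(rng))
        scores = est.fit_transform(X)
        modules = est.components_
        mean = est.mean_
    elif method == "ica":
        est = FastICA(
            n_components=k,
            whiten="unit-variance",
            max_iter=1000,
            tol=1e-4,
            random_state=_seed_int(rng),
        )
        # modules are the independent components: independent and
        # non-Gaussian across the feature axis, so ICA runs on X^T with
        # the d feature cells as samples and trials as mixtures
        sources = est.fit_transform(X.T)
        modules = sources.T
        mean = X.mean(axis=0)
        scores = None
    elif method == "fa":
        est = FactorAnalysis(n_components=k, random_state=_seed_int(rng))
        scores = est.fit_transform(X)
        modules = est.components_
        mean = est.mean_
    else:
        raise ValueError(f"unknown linear method {method!r}")
    # FA scores are posterior estimates and ICA fits modules only; refit the
    # coefficients by least squares so reconstruction is well defined.
    if method != "pca":
        scores = _lstsq_coefficients(X - mean, modules)
        if np.any(~np.isfinite(scores)):
            raise ValueError("coefficient refit produced non-finite values")
    error = _frob(X - mean - scores @ modules)
    return scores, modules, mean, error


def _lstsq_coefficients(Xc, modules):
    return Xc @ np.linalg.pinv(modules)


def _seed_int(rng: np.random.Generator) -> int:
    return int(rng.integers(0, 2**31 - 1))


def spatiotemporal_nmf(
    tensor: TrialTensor,
    k: int,
    *,
    max_iter: int = 500,
    tol: float = 1e-6,
    n_restarts: int = 5,
    seed=None,
) -> SpatiotemporalDecomposition:
    """Spatiotemporal NMF of the (S, T*N) matricization with K modules."""
    rng = np.random.default_rng(seed)
    X = matricize_spatiotemporal(tensor).astype(float)
    H, B, err, history = _nmf(
        X, k, max_iter=max_iter, tol=tol, n_restarts=n_restarts, rng=rng
    )
    B, H = _normalize_modules(B, H)
    return SpatiotemporalDecomposition(
        modules=B.reshape(k, tensor.n_bins, tensor.n_neurons),
        activations=H,
        method="st-nmf",
        reconstruction_error=err,
        objective_history=history,
    )


def spatiotemporal_linear(
    tensor: TrialTensor, k: int, method: str, seed=None
) -> SpatiotemporalDecomposition:
    """Spatiotemporal PCA/ICA/FA of the (S, T*N) matricization."""
    method = method.lower()
    if method not in LINEAR_METHODS:
        raise ValueError(f"method must be one of {LINEAR_METHODS}")
    rng = np.random.default_rng(seed)
    X = matricize_spatiotemporal(tensor).astype(float)
    scores, modules, mean, err = _fit_linear(X, k, method, rng)
    modules, scores = _normalize_modules(modules, scores)
    return SpatiotemporalDecomposition(
        modules=modules.reshape(k, tensor.n_bins, tensor.n_neurons),
        activations=scores,
        method=f"st-{method}",
        reconstruction_error=err,
        mean=mean,
    )


def space_only_decomposition(
    tensor: TrialTensor,
    l: int,
    method: str = "nmf",
    *,
    max_iter: int = 500,
    tol: float = 1e-6,
    n_restarts: int = 5,
    seed=None,
) -> SpaceOnlyDecomposition:
    """Factorize the (S*T, N) matricization into L spatial modules.

    The chosen engine is applied directly to the spatial matricization, so
    the result coincides with calling that engine on
    :func:`~popfactor.core_data.matricize_spatial` output.  Activation
    coefficients are returned time-resolved with shape (S, T, L).
    """
    method = method.lower()
    if l > tensor.n_neurons:
        raise ValueError("cannot extract more spatial modules than neurons")
    rng = np.random.default_rng(seed)
    X = matricize_spatial(tensor).astype(float)
    mean = None
    history = None
    if method == "nmf":
        H, B, err, history = _nmf(
            X, l, max_iter=max_iter, tol=tol, n_restarts=n_restarts, rng=rng
        )
    elif method in LINEAR_METHODS:
        H, B, mean, err = _fit_linear(X, l, method, rng)
    else:
        raise ValueError(f"method must be 'nmf' or one of {LINEAR_METHODS}")
    B, H = _normalize_modules(B, H)
    return SpaceOnlyDecomposition(
        spatial_modules=B,
        activations=H.reshape(tensor.n_trials, tensor.n_bins, l),
        method=f"space-{method}",
        reconstruction_error=err,
        mean=mean,
        objective_history=history,
    )


def infer_activations(
    decomp: SpatiotemporalDecomposition,
    tensor: TrialTensor,
    *,
    max_iter: int = 500,
    tol: float = 1e-6,
    seed=None,
) -> np.ndarray:
    """Activation coefficients of new trials under frozen modules.

    NMF: H-only multiplicative updates with the module matrix fixed, run
    to tolerance (the frozen-module error can never fall below the error
    of a joint fit on the same data).  PCA/ICA/FA: least-squares projection
    of the mean-centred trials onto the module basis, which for PCA's
    orthonormal modules reduces to inner products.
    """
    X = matricize_spatiotemporal(tensor).astype(float)
    B = decomp.module_matrix()
    if X.shape[1] != B.shape[1]:
        raise ValueError(
            f"trial dimension {X.shape[1]} does not match modules {B.shape[1]}"
        )
    if decomp.method == "st-nmf":
        rng = np.random.default_rng(seed)
        H = rng.uniform(size=(X.shape[0], B.shape[0]))
        BBt = B @ B.T
        XBt = X @ B.T
        err = _frob(X - H @ B)
        for _ in range(max_iter):
            H *= XBt / np.maximum(H @ BBt, _EPS)
            new_err = _frob(X - H @ B)
            if err > 0 and (err - new_err) <= tol * err:
                break
            err = new_err
        return H
    Xc = X - decomp.mean if decomp.mean is not None else X
    return _lstsq_coefficients(Xc, B)
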