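"""Space-by-time (Tucker-2) factorizations of trial tensors.

The space-by-time model factorizes every trial's T x N count matrix into
shared temporal modules, shared spatial modules, and a trial-specific core
of activation coefficients:

    R^s = B_tem H^s B_spa + residual,

with B_tem (T x P, temporal modules in columns), B_spa (L x N, spatial
modules in rows) and H^s (P x L).  Stacking trials, this is the Tucker-2
decomposition of the S x T x N tensor with core H (S x P x L).

Two constraint sets are implemented:

* **space-by-time NMF** (non-negative Tucker-2, a.k.a. sample-based
  non-negative matrix tri-factorization): all factors and cores are
  non-negative, fit by alternating multiplicative updates that minimize
  the summed Frobenius objective sum_s ||R^s - B_tem H^s B_spa||_F^2 and
  can never increase it.  At convergence each temporal module (column) and
  spatial module (row) is scaled to unit norm with the scales absorbed
  into the core, which leaves the reconstruction unchanged.
* **orthogonal Tucker-2**: a tensor generalization of PCA.  Factors are
  orthonormal (B_tem^T B_tem = I_P, B_spa B_spa^T = I_L), fit by
  higher-order orthogonal iteration (HOOI): each factor is the leading
  left singular subspace of the tensor unfolded after projection on the
  other factor, initialized by HOSVD.  The core is the closed-form
  projection H^s = B_tem^T R^s B_spa^T.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from functools import partial

_einsum = partial(np.einsum, optimize=True)

_EPS = np.finfo(float).eps


@dataclass
class SbTDecomposition:
    """Space-by-time factors: temporal (T, P), spatial (L, N), core (S, P, L)."""

    temporal_modules: np.ndarray
    spatial_modules: np.ndarray
    core: np.ndarray
    method: str
    reconstruction_error: float
    objective_history: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_temporal(self) -> int:
        return self.temporal_modules.shape[1]

    @property
    def n_spatial(self) -> int:
        return self.spatial_modules.shape[0]

    def reconstruct(self, core: np.ndarray | None = None) -> np.ndarray:
        """Reconstructed trials B_tem H^s B_spa, shape (S, T, N)."""
        H = self.core if core is None else core
        return _einsum(
            "tp,spl,ln->stn", self.temporal_modules, H, self.spatial_modules
        )

    def expanded_modules(self) -> list[np.ndarray]:
        """The P*L outer-product spatiotemporal modules b_tem_i (b_spa_j)^T."""
        from .similarity import expand_outer_modules

        return expand_outer_modules(self.temporal_modules, self.spatial_modules)


def _as_counts(tensor) -> np.ndarray:
    counts = np.asarray(getattr(tensor, "counts", tensor), dtype=float)
    if counts.ndim != 3:
        raise ValueError("expected a (trials, bins, neurons) tensor")
    return counts


def reconstruction_error(decomp: SbTDecomposition, tensor) -> float:
    """Exact Frobenius objective sum_s ||R^s - B_tem H^s B_spa||_F^2."""
    R = _as_counts(tensor)
    resid = R - decomp.reconstruct()
    return float(np.sum(resid * resid))


def _sbt_objective(R, Btem, H, Bspa) -> float:
    resid = R - _einsum("tp,spl,ln->stn", Btem, H, Bspa)
    return float(np.sum(resid * resid))


def _sbt_updates(R, Btem, H, Bspa):
    """One full sweep of the multiplicative update rules (steps 2-4).

    The intermediates G (temporal modules times core, one T x L matrix per
    trial) and V (core times spatial modules, one P x N matrix per trial)
    are exactly the reshaped products of the published algorithm; the
    per-trial loops are expressed as einsums over the trial axis.
    """
    # step 2: B_spa, via G = B_tem H stacked over trials to (T*S, L)
    G = _einsum("tp,spl->stl", Btem, H)
    num = _einsum("stl,stn->ln", G, R)
    den = _einsum("stl,stm->lm", G, G) @ Bspa
    Bspa = Bspa * num / np.maximum(den, _EPS)

    # step 3: B_tem, via V = H B_spa stacked over trials to (P, N*S)
    V = _einsum("spl,ln->spn", H, Bspa)
    num = _einsum("stn,spn->tp", R, V)
    den = Btem @ _einsum("spn,sqn->pq", V, V)
    Btem = Btem * num / np.maximum(den, _EPS)

    # step 4: per-trial core H^s
    num = _einsum("tp,stn,ln->spl", Btem, R, Bspa)
    den = _einsum(
        "pq,sql,lm->spm", Btem.T @ Btem, H, Bspa @ Bspa.T
    )
    H = H * num / np.maximum(den, _EPS)
    return Btem, H, Bspa


def _normalize_sbt(Btem, H, Bspa):
    """Unit-norm temporal columns and spatial rows, scales into the core."""
    t_norms = np.linalg.norm(Btem, axis=0)
    t_norms[t_norms == 0] = 1.0
    s_norms = np.linalg.norm(Bspa, axis=1)
    s_norms[s_norms == 0] = 1.0
    Btem = Btem / t_norms[None, :]
    Bspa = Bspa / s_norms[:, None]
    H = H * t_norms[None, :, None] * s_norms[None, None, :]
    return Btem, H, Bspa


def space_by_time_nmf(
    tensor,
    p: int,
    l: int,
    *,
    max_iter: int = 500,
    tol: float = 1e-6,
    n_restarts: int = 5,
    seed=None,
) -> SbTDecomposition:
    """Non-negative Tucker-2 fit with P temporal and L spatial modules.

    Factors and core are initialized i.i.d. uniform(0, 1); updates sweep
    B_spa, B_tem, then all H^s; iteration stops when the relative decrease
    of the Frobenius objective falls below ``tol`` or after ``max_iter``
    sweeps.  The best of ``n_restarts`` runs (lowest objective) is
    returned, normalized so modules have unit norm.
    """
    R = _as_counts(tensor)
    if np.all(R == 0):
        raise ValueError("space-by-time NMF is undefined for all-zero input")
    s, t, n = R.shape
    if not 1 <= p <= t:
        raise ValueError(f"temporal module count {p} not in [1, {t}]")
    if not 1 <= l <= n:
        raise ValueError(f"spatial module count {l} not in [1, {n}]")
    rng = np.random.default_rng(seed)

    best = None
    for _ in range(n_restarts):
        Btem = rng.uniform(size=(t, p))
        H = rng.uniform(size=(s, p, l))
        Bspa = rng.uniform(size=(l, n))
        err = _sbt_objective(R, Btem, H, Bspa)
        history = [err]
        for _ in range(max_iter):
            Btem, H, Bspa = _sbt_updates(R, Btem, H, Bspa)
            new_err = _sbt_objective(R, Btem, H, Bspa)
            history.append(new_err)
            if err > 0 and (err - new_err) <= tol * err:
                err = new_err
                break
            err = new_err
        if best is None or err < best[3]:
            best = (Btem, H, Bspa, err, np.asarray(history))

    Btem, H, Bspa, err, history = best
    Btem, H, Bspa = _normalize_sbt(Btem, H, Bspa)
    return SbTDecomposition(
        temporal_modules=Btem,
        spatial_modules=Bspa,
        core=H,
        method="sbt-nmf",
        reconstruction_error=err,
        objective_history=history,
    )


def _leading_left_singular(X, k):
    U, _, _ = np.linalg.svd(X, full_matrices=False)
    return U[:, :k]


def _fix_signs(U):
    """Make the largest-magnitude entry of each column positive."""
    idx = np.argmax(np.abs(U), axis=0)
    signs = np.sign(U[idx, np.arange(U.shape[1])])
    signs[signs == 0] = 1.0
    return U * signs


def orthogonal_tucker2(
    tensor,
    p: int,
    l: int,
    *,
    max_iter: int = 200,
    tol: float = 1e-10,
    seed=None,
) -> SbTDecomposition:
    """Orthogonal Tucker-2 fit by HOOI with HOSVD initialization.

    ``seed`` is accepted for interface parity but unused: the fit is
    deterministic.  Factor columns have their largest-magnitude entry made
    positive to fix the sign indeterminacy.
    """
    R = _as_counts(tensor)
    s, t, n = R.shape
    if not 1 <= p <= min(t, s * n):
        raise ValueError(f"temporal module count {p} exceeds mode rank")
    if not 1 <= l <= min(n, s * t):
        raise ValueError(f"spatial module count {l} exceeds mode rank")

    # HOSVD init: leading singular vectors of the raw unfoldings
    Btem = _leading_left_singular(
        np.transpose(R, (1, 0, 2)).reshape(t, s * n), p
    )
    W = _leading_left_singular(
        np.transpose(R, (2, 0, 1)).reshape(n, s * t), l
    )  # W is (N, L); B_spa = W^T

    total = float(np.sum(R * R))
    fit = -np.inf
    for _ in range(max_iter):
        proj_n = _einsum("stn,nl->stl", R, W)
        Btem = _leading_left_singular(
            np.transpose(proj_n, (1, 0, 2)).reshape(t, s * l), p
        )
        proj_t = _einsum("stn,tp->spn", R, Btem)
        W = _leading_left_singular(
            np.transpose(proj_t, (2, 0, 1)).reshape(n, s * p), l
        )
        core = _einsum("tp,stn,nl->spl", Btem, R, W)
        new_fit = float(np.sum(core * core))
        if new_fit - fit <= tol * max(total, 1.0):
            fit = new_fit
            break
        fit = new_fit

    Btem = _fix_signs(Btem)
    W = _fix_signs(W)
    core = _einsum("tp,stn,nl->spl", Btem, R, W)
    err = total - float(np.sum(core * core))
    return SbTDecomposition(
        temporal_modules=Btem,
        spatial_modules=W.T,
        core=core,
        method="tucker2",
        reconstruction_error=max(err, 0.0),
    )


def infer_core(
    decomp: SbTDecomposition,
    tensor,
    *,
    max_iter: int = 500,
    tol: float = 1e-6,
    seed=None,
) -> np.ndarray:
    """Core slices H^s for new trials with the factors frozen.

    Orthogonal variant: closed-form projection H^s = B_tem^T R^s B_spa^T.
    NMF variant: step-4 multiplicative updates only, run to tolerance; the
    frozen-factor error cannot fall below that of a joint fit.
    """
    R = _as_counts(tensor)
    Btem, Bspa = decomp.temporal_modules, decomp.spatial_modules
    if R.shape[1] != Btem.shape[0] or R.shape[2] != Bspa.shape[1]:
        raise ValueError(
            f"tensor shape {R.shape[1:]} does not match factors "
            f"({Btem.shape[0]}, {Bspa.shape[1]})"
        )
    if decomp.method == "tucker2":
        return _einsum("tp,stn,ln->spl", Btem, R, Bspa)

    rng = np.random.default_rng(seed)
    H = rng.uniform(size=(R.shape[0], Btem.shape[1], Bspa.shape[0]))
    BtB = Btem.T @ Btem
    BsBs = Bspa @ Bspa.T
    num = _einsum("tp,stn,ln->spl", Btem, R, Bspa)
    err = _sbt_objective(R, Btem, H, Bspa)
    for _ in range(max_iter):
        den = _einsum("pq,sql,lm->spm", BtB, H, BsBs)
        H = H * num / np.maximum(den, _EPS)
        new_err = _sbt_objective(R, Btem, H, Bspa)
        if err > 0 and (err - new_err) <= tol * err:
            break
        err = new_err
    return H
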