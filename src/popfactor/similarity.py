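"""Geodesic similarity between firing modules and matched-set recovery scores.

The geodesic similarity between two module vectors u, v is the principal
angle between their directions mapped linearly onto [0, 1]:

    sim(u, v) = 1 - (2/pi) * arccos( <u, v> / (||u|| ||v||) )

It is 1 for identical directions, 0 for orthogonal ones, symmetric, and
invariant to positive rescaling of either argument.  Module *sets* are
compared by finding the one-to-one assignment between found and ground-truth
modules that maximizes total pairwise geodesic similarity (Hungarian
algorithm; provably optimal, and checked against brute-force enumeration in
the test suite for small sets) and reporting the matched-pair mean in
percent — the "module recovery similarity" used throughout.

Sign-indeterminate decompositions (PCA, ICA, FA, orthogonal Tucker-2)
are compared up to sign: each pair is scored as max(sim(u, v), sim(u, -v)).
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linear_sum_assignment


def geodesic_similarity(u, v) -> float:
    """Geodesic similarity in [0, 1] between two module vectors.

    Arrays of any (identical) shape are accepted and flattened.  Raises on
    zero vectors, whose direction is undefined.
    """
    u = np.asarray(u, dtype=float).ravel()
    v = np.asarray(v, dtype=float).ravel()
    if u.shape != v.shape:
        raise ValueError(f"module shapes differ: {u.shape} vs {v.shape}")
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("geodesic similarity is undefined for a zero module")
    cosine = np.clip(u @ v / (nu * nv), -1.0, 1.0)
    return 1.0 - (2.0 / np.pi) * np.arccos(cosine)


def similarity_matrix(found, truth, signed: bool = False) -> np.ndarray:
    """Pairwise geodesic similarities, shape (len(found), len(truth))."""
    mat = np.empty((len(found), len(truth)))
    for i, u in enumerate(found):
        for j, v in enumerate(truth):
            s = geodesic_similarity(u, v)
            if signed:
                s = max(s, geodesic_similarity(u, -np.asarray(v, dtype=float)))
            mat[i, j] = s
    return mat


def match_modules(found, truth, signed: bool = False):
    """Optimal one-to-one assignment of found to ground-truth modules.

    Returns ``(pairs, similarities)`` where ``pairs`` is a list of
    (found_index, truth_index) tuples and ``similarities`` the matched
    per-pair geodesic similarities.
    """
    if len(found) == 0 or len(truth) == 0:
        raise ValueError("module lists must be non-empty")
    if len(found) != len(truth):
        raise ValueError(
            f"module counts differ: {len(found)} found vs {len(truth)} truth"
        )
    mat = similarity_matrix(found, truth, signed=signed)
    rows, cols = linear_sum_assignment(-mat)
    order = np.argsort(rows)  # deterministic, lexicographic in found index
    pairs = [(int(rows[k]), int(cols[k])) for k in order]
    sims = np.array([mat[r, c] for r, c in pairs])
    return pairs, sims


def module_set_similarity(found, truth, signed: bool = False) -> float:
    """Module recovery similarity in percent (matched-pair mean).

    ``found`` and ``truth`` are sequences of equally shaped module arrays.
    Space-by-time decompositions should be expanded to their outer-product
    modules first (see :func:`expand_outer_modules`).
    """
    _, sims = match_modules(found, truth, signed=signed)
    return float(100.0 * sims.mean())


def expand_outer_modules(
    temporal_modules: np.ndarray, spatial_modules: np.ndarray
) -> list[np.ndarray]:
    """All P*L outer products b_tem_i (b_spa_j)^T as (T, N) arrays.

    ``temporal_modules`` has shape (T, P) with modules in columns;
    ``spatial_modules`` has shape (L, N) with modules in rows.  The output
    order is temporal-major: (i=0, j=0), (0, 1), ..., (1, 0), ...
    """
    temporal_modules = np.asarray(temporal_modules, dtype=float)
    spatial_modules = np.asarray(spatial_modules, dtype=float)
    return [
        np.outer(temporal_modules[:, i], spatial_modules[j])
        for i in range(temporal_modules.shape[1])
        for j in range(spatial_modules.shape[0])
    ]
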