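"""Compact pairwise-difference descriptors of connectome pairs.

The sample-selection procedure compresses the tangent matrix between two
connectomes into a feature vector.  Eight modes are supported; the
abbreviations follow the field's convention:

=======  =====================================================  ==========
mode     feature                                                length
=======  =====================================================  ==========
``tm``   upper triangle (incl. diagonal) of the tangent matrix  d(d+1)/2
``dc``   degree centrality of the tangent matrix                d
``ec``   eigenvector centrality of the tangent matrix           d
``cc``   closeness centrality of the tangent matrix             d
``cnu``  concatenation dc | ec | cc, unscaled                   3d
``cns``  concatenation dc | ec | cc, each min-max scaled        3d
``g``    Log-Euclidean geodesic distance                        1
``a``    Euclidean distance of upper-triangular connectomes     1
=======  =====================================================  ==========

Tangent matrices have signed entries, so the centrality measures use the
absolute values of the off-diagonal entries as edge weights (the diagonal is
treated as absent): the magnitude of a connectivity change is the relevant
edge strength and the graph topology itself is unchanged.  Closeness needs
edge *lengths*, which are taken as the reciprocal weights.
"""

from __future__ import annotations

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from . import config
from .exceptions import ConvergenceError, DegenerateInputError, ValidationError
from .geometry import log_euclidean_distance, tangent_at_identity

__all__ = [
    "FEATURE_MODES",
    "feature_length",
    "degree_centrality",
    "eigenvector_centrality",
    "closeness_centrality",
    "minmax_scale",
    "upper_triangle",
    "features_from_tangent",
    "extract_pair_features",
]

FEATURE_MODES = ("tm", "dc", "ec", "cc", "cnu", "cns", "g", "a")


def feature_length(mode: str, d: int) -> int:
    """Length of the feature vector produced by ``mode`` for ``d`` ROIs."""
    if mode == "tm":
        return d * (d + 1) // 2
    if mode in ("dc", "ec", "cc"):
        return d
    if mode in ("cnu", "cns"):
        return 3 * d
    if mode in ("g", "a"):
        return 1
    raise ValidationError(f"unknown feature mode {mode!r}; expected one of {FEATURE_MODES}")


def _abs_adjacency(W, min_d: int = 2) -> np.ndarray:
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValidationError(f"tangent matrix must be square, got shape {W.shape}")
    if W.shape[0] < min_d:
        raise ValidationError(f"need at least {min_d} nodes, got {W.shape[0]}")
    if np.abs(W - W.T).max() > config.SYMMETRY_TOL:
        raise ValidationError("tangent matrix must be symmetric")
    A = np.abs(W)
    np.fill_diagonal(A, 0.0)
    return A


def degree_centrality(W) -> np.ndarray:
    """Mean absolute off-diagonal weight per node: ``sum_j |W_ij| / (d-1)``."""
    A = _abs_adjacency(W)
    return A.sum(axis=1) / (A.shape[0] - 1)


def eigenvector_centrality(W) -> np.ndarray:
    """Principal eigenvector of ``|W|`` (zero diagonal) by power iteration.

    Deterministic: starts from the uniform vector, iterates until the unit
    eigenvector changes by less than ``config.POWER_ITERATION_TOL`` and
    returns it with unit Euclidean norm and non-negative entries.
    """
    A = _abs_adjacency(W)
    if not A.any():
        raise DegenerateInputError("eigenvector centrality of an all-zero graph is undefined")
    d = A.shape[0]
    # diagonal shift: same eigenvectors, but makes the Perron eigenvalue
    # strictly dominant so the iteration cannot oscillate (bipartite graphs
    # have a -lambda_max eigenvalue); max row sum bounds the spectral radius
    A = A + A.sum(axis=1).max() * np.eye(d)
    v = np.full(d, 1.0 / np.sqrt(d))
    for _ in range(config.POWER_ITERATION_MAXITER):
        w = A @ v
        norm = np.linalg.norm(w)
        if norm == 0.0:
            # start vector orthogonal to the Perron space cannot happen for a
            # non-negative matrix with a uniform start; guard anyway
            raise DegenerateInputError("power iteration collapsed to zero")
        w /= norm
        if np.linalg.norm(w - v) < config.POWER_ITERATION_TOL:
            return np.abs(w)
        v = w
    raise ConvergenceError(
        f"power iteration did not converge in {config.POWER_ITERATION_MAXITER} iterations"
    )


def closeness_centrality(W) -> np.ndarray:
    """Weighted closeness centrality with Wasserman–Faust component scaling.

    Edge (i, j) exists iff ``|W_ij| > 0`` with length ``1 / |W_ij|``.  With
    ``delta`` the shortest-path length, ``r_i`` the number of nodes reachable
    from ``i`` (excluding ``i``), node ``i`` scores

        ``(r_i / (d - 1)) * (r_i / sum_j delta(i, j))``

    which reduces to ``(d - 1) / sum_j delta(i, j)`` on a connected graph.
    Isolated nodes score 0.
    """
    A = _abs_adjacency(W)
    d = A.shape[0]
    rows, cols = np.nonzero(A)
    lengths = csr_matrix((1.0 / A[rows, cols], (rows, cols)), shape=(d, d))
    delta = shortest_path(lengths, method="D", directed=False)
    out = np.zeros(d)
    for i in range(d):
        reachable = np.isfinite(delta[i]) & (np.arange(d) != i)
        r = int(reachable.sum())
        if r > 0:
            out[i] = (r / (d - 1)) * (r / delta[i, reachable].sum())
    return out


def minmax_scale(v) -> np.ndarray:
    """Affine rescaling of a vector onto [0, 1]; a constant vector maps to zeros."""
    v = np.asarray(v, dtype=float)
    if v.size == 0:
        raise ValidationError("cannot scale an empty vector")
    lo, hi = v.min(), v.max()
    if hi == lo:
        return np.zeros_like(v)
    return (v - lo) / (hi - lo)


def upper_triangle(M) -> np.ndarray:
    """Row-major upper triangle of a square matrix, including the diagonal."""
    M = np.asarray(M, dtype=float)
    return M[np.triu_indices(M.shape[0])]


def features_from_tangent(S, mode: str) -> np.ndarray:
    """Feature vector of a tangent matrix under modes that only need it.

    Valid for every mode except ``a`` (which needs the raw connectomes);
    mode ``g`` reduces to the Frobenius norm of the tangent matrix.
    """
    if mode == "tm":
        return upper_triangle(S)
    if mode == "dc":
        return degree_centrality(S)
    if mode == "ec":
        return eigenvector_centrality(S)
    if mode == "cc":
        return closeness_centrality(S)
    if mode == "cnu":
        return np.concatenate([degree_centrality(S), eigenvector_centrality(S), closeness_centrality(S)])
    if mode == "cns":
        return np.concatenate(
            [
                minmax_scale(degree_centrality(S)),
                minmax_scale(eigenvector_centrality(S)),
                minmax_scale(closeness_centrality(S)),
            ]
        )
    if mode == "g":
        return np.array([float(np.linalg.norm(np.asarray(S, dtype=float)))])
    raise ValidationError(f"unknown feature mode {mode!r}; expected one of {FEATURE_MODES}")


def extract_pair_features(P_i, P_j, mode: str, *, log_i=None, log_j=None) -> np.ndarray:
    """Feature vector describing the difference between two SPD connectomes.

    Parameters
    ----------
    P_i, P_j
        Regularized (SPD) connectomes of equal dimension.
    mode
        One of :data:`FEATURE_MODES`.
    log_i, log_j
        Optional precomputed matrix logarithms (an optimization for callers
        that evaluate many pairs; they must equal ``matrix_log(P_i/j)``).
    """
    if mode not in FEATURE_MODES:
        raise ValidationError(f"unknown feature mode {mode!r}; expected one of {FEATURE_MODES}")
    P_i = np.asarray(P_i, dtype=float)
    P_j = np.asarray(P_j, dtype=float)
    if P_i.shape != P_j.shape:
        raise ValidationError(f"dimension mismatch: {P_i.shape} vs {P_j.shape}")
    if mode == "a":
        diff = upper_triangle(P_i) - upper_triangle(P_j)
        return np.array([float(np.linalg.norm(diff))])
    if log_i is not None and log_j is not None:
        S = log_j - log_i
    elif mode == "g":
        return np.array([log_euclidean_distance(P_i, P_j)])
    else:
        S = tangent_at_identity(P_i, P_j)
    return features_from_tangent(S, mode)
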