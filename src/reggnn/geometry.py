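"""Log-Euclidean geometry on the cone of symmetric positive definite matrices.

Functional connectomes are correlation matrices and therefore symmetric
positive *semi*-definite; adding a small ridge ``mu * I`` places them strictly
inside the SPD cone, where the Log-Euclidean metric applies.  Under this
metric the matrix logarithm is an isometry onto the flat space of symmetric
matrices, so

* the geodesic distance between ``P`` and ``Q`` is ``||log Q - log P||_F``,
* the tangent matrix of the geodesic from ``P`` to ``Q``, parallel-translated
  to the tangent space at the identity, is simply ``log Q - log P``
  (parallel transport is path independent and acts as a translation in
  log coordinates).

All matrix functions are computed through the symmetric eigendecomposition and
the results are re-symmetrized, so outputs are exactly symmetric.
"""

from __future__ import annotations

import numpy as np

from . import config
from .exceptions import DegenerateInputError, ValidationError

__all__ = [
    "validate_correlation_matrix",
    "is_spd",
    "regularize",
    "matrix_log",
    "matrix_exp",
    "log_euclidean_distance",
    "tangent_at_identity",
]


def _as_square(M, name: str = "matrix") -> np.ndarray:
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValidationError(f"{name} must be square, got shape {M.shape}")
    if not np.isfinite(M).all():
        raise ValidationError(f"{name} contains non-finite entries")
    return M


def _check_symmetric(M: np.ndarray, name: str = "matrix") -> None:
    if np.abs(M - M.T).max() > config.SYMMETRY_TOL:
        raise ValidationError(
            f"{name} is not symmetric within {config.SYMMETRY_TOL:g} "
            f"(max asymmetry {np.abs(M - M.T).max():.3g})"
        )


def validate_correlation_matrix(C, name: str = "correlation matrix") -> np.ndarray:
    """Validate a functional connectome and return it as a float array.

    Checks symmetry, unit diagonal, the [-1, 1] entry range and positive
    semi-definiteness (up to numerical noise).
    """
    C = _as_square(C, name)
    _check_symmetric(C, name)
    if C.shape[0] < 2:
        raise ValidationError(f"{name} must be at least 2x2")
    if np.abs(np.diag(C) - 1.0).max() > config.DIAGONAL_TOL:
        raise ValidationError(f"{name} diagonal deviates from 1 by more than {config.DIAGONAL_TOL:g}")
    if np.abs(C).max() > 1.0 + config.ENTRY_SLACK:
        raise ValidationError(f"{name} has entries outside [-1, 1]")
    lam_min = np.linalg.eigvalsh((C + C.T) / 2.0)[0]
    if lam_min < -config.PSD_TOL:
        raise ValidationError(
            f"{name} is not positive semidefinite (smallest eigenvalue {lam_min:.3g})"
        )
    return C


def is_spd(P) -> bool:
    """True if ``P`` is symmetric with strictly positive eigenvalues."""
    P = np.asarray(P, dtype=float)
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        return False
    if np.abs(P - P.T).max() > config.SYMMETRY_TOL:
        return False
    return bool(np.linalg.eigvalsh((P + P.T) / 2.0)[0] > 0.0)


def regularize(C, mu: float = config.DEFAULT_MU, *, subject_id: str | None = None) -> np.ndarray:
    """Push a correlation matrix into the SPD cone: ``P = C + mu * I``.

    If the result is still numerically singular the ridge is escalated by
    factors of 10 up to ``config.MAX_MU`` before giving up.

    Parameters
    ----------
    C
        A valid correlation matrix (see :func:`validate_correlation_matrix`).
    mu
        Initial ridge, strictly positive.
    subject_id
        Optional label used in error messages.

    Returns
    -------
    numpy.ndarray
        A symmetric positive definite matrix.
    """
    if not mu > 0:
        raise ValidationError(f"mu must be positive, got {mu}")
    C = validate_correlation_matrix(C, name=f"connectome {subject_id}" if subject_id else "correlation matrix")
    current = float(mu)
    while True:
        P = C + current * np.eye(C.shape[0])
        if np.linalg.eigvalsh((P + P.T) / 2.0)[0] > 0.0:
            return P
        if current >= config.MAX_MU:
            who = f" (subject {subject_id})" if subject_id else ""
            raise DegenerateInputError(
                f"matrix not positive definite even with mu={config.MAX_MU:g}{who}"
            )
        current = min(current * 10.0, config.MAX_MU)


def matrix_log(P) -> np.ndarray:
    """Principal matrix logarithm of an SPD matrix via eigendecomposition."""
    P = _as_square(P, "SPD matrix")
    _check_symmetric(P, "SPD matrix")
    lam, U = np.linalg.eigh((P + P.T) / 2.0)
    if lam[0] <= 0.0:
        raise DegenerateInputError(
            f"matrix log requires positive eigenvalues (smallest is {lam[0]:.3g})"
        )
    L = (U * np.log(lam)) @ U.T
    return (L + L.T) / 2.0


def matrix_exp(S) -> np.ndarray:
    """Matrix exponential of a symmetric matrix; the result is SPD."""
    S = _as_square(S, "tangent matrix")
    _check_symmetric(S, "tangent matrix")
    lam, U = np.linalg.eigh((S + S.T) / 2.0)
    E = (U * np.exp(lam)) @ U.T
    return (E + E.T) / 2.0


def _check_same_dim(P: np.ndarray, Q: np.ndarray) -> None:
    if P.shape != Q.shape:
        raise ValidationError(f"dimension mismatch: {P.shape} vs {Q.shape}")


def log_euclidean_distance(P, Q) -> float:
    """Log-Euclidean geodesic distance ``||log Q - log P||_F``."""
    P = _as_square(P, "P")
    Q = _as_square(Q, "Q")
    _check_same_dim(P, Q)
    return float(np.linalg.norm(matrix_log(Q) - matrix_log(P)))


def tangent_at_identity(P, Q) -> np.ndarray:
    """Tangent matrix of the geodesic from ``P`` to ``Q``, at the identity.

    Computes the Riemannian log of ``Q`` at ``P`` and parallel-translates it
    to the tangent space at ``I``; under the Log-Euclidean metric the
    composite is ``log Q - log P``.  Its Frobenius norm equals
    :func:`log_euclidean_distance` and swapping the arguments negates it.
    """
    P = _as_square(P, "P")
    Q = _as_square(Q, "Q")
    _check_same_dim(P, Q)
    return matrix_log(Q) - matrix_log(P)
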