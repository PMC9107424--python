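"""Synthetic cohorts of correlation-matrix connectomes with known ground truth.

Real connectome studies draw on cohorts of a few hundred subjects whose
functional connectomes are d x d Pearson-correlation matrices and whose
targets are IQ scores.  This module generates desk-scale stand-ins with the
same structure so every other module can be exercised — and validated against
planted ground truth — without any external download.

Generation happens in log-matrix coordinates, i.e. exactly the flat
coordinates of the Log-Euclidean geometry the selection method assumes:

* a shared symmetric base log-matrix ``B`` gives all subjects a common
  correlation backbone;
* cluster ``m`` sits at ``B + offset_m * U`` where ``U`` is a random
  zero-diagonal symmetric direction with unit Frobenius norm and the offsets
  place adjacent clusters ``cluster_separation`` apart;
* each subject adds a within-cluster perturbation and is mapped through the
  matrix exponential, then rescaled to a unit diagonal (a correlation
  matrix).  The rescaling slightly distorts the planted log-space geometry;
  all invariants are therefore checked *after* rescaling.

Score models (``coupling``):

``cluster_only``
    score = cluster center + N(0, score_sd); the connectome perturbation is
    an isotropic symmetric log-matrix deviation of Frobenius scale
    ``within_cluster_sd``.
``linear_in_tangent``
    the within-cluster deviation lies *along the cluster axis U*,
    ``t_i * U`` with ``t_i ~ N(0, within_cluster_sd)``, and
    score = cluster center + beta * t_i + N(0, score_sd) with
    ``beta = coupling_score_sd / within_cluster_sd``.  Score differences are
    then exactly linear in the planted tangent coordinates, which is what
    makes parameter-recovery tests meaningful.
``pure_noise``
    scores are drawn independently of the connectomes.

The default score statistics match a neurotypical full-scale-IQ cohort
(mean 111.573, sd 12.056).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import config
from .exceptions import ValidationError
from .geometry import matrix_exp
from .selection import Subject

__all__ = ["CohortSpec", "SyntheticCohort", "make_random_correlation", "generate_cohort", "write_cohort"]

#: Neurotypical full-scale IQ statistics used as default score scale.
DEFAULT_SCORE_MEAN = 111.573
DEFAULT_SCORE_SD = 12.056


@dataclass
class CohortSpec:
    """Study conditions of one synthetic cohort."""

    n_subjects: int = 226
    d: int = 116
    n_clusters: int = 1
    within_cluster_sd: float = 0.2
    cluster_separation: float = 1.0
    score_centers: tuple[float, ...] | None = None
    score_sd: float = DEFAULT_SCORE_SD
    coupling: str = "cluster_only"
    coupling_score_sd: float = 0.1
    base_sd: float = 0.2
    seed: int = 0
    mu: float = config.DEFAULT_MU

    def __post_init__(self) -> None:
        if self.d < 2:
            raise ValidationError(f"d must be >= 2, got {self.d}")
        if not 1 <= self.n_clusters <= self.n_subjects:
            raise ValidationError(
                f"need 1 <= n_clusters <= n_subjects, got {self.n_clusters} vs {self.n_subjects}"
            )
        if self.within_cluster_sd < 0 or self.score_sd < 0:
            raise ValidationError("standard deviations must be non-negative")
        if self.coupling not in ("cluster_only", "linear_in_tangent", "pure_noise"):
            raise ValidationError(f"unknown coupling {self.coupling!r}")
        if self.score_centers is None:
            self.score_centers = tuple(
                DEFAULT_SCORE_MEAN + (m - (self.n_clusters - 1) / 2.0) * 40.0
                for m in range(self.n_clusters)
            )
        self.score_centers = tuple(float(c) for c in self.score_centers)
        if len(self.score_centers) != self.n_clusters:
            raise ValidationError(
                f"{len(self.score_centers)} score centers for {self.n_clusters} clusters"
            )


@dataclass
class SyntheticCohort:
    """Generated subjects plus the planted ground truth per subject id."""

    subjects: list[Subject]
    ground_truth: dict[str, dict] = field(default_factory=dict)
    spec: CohortSpec | None = None


def _random_symmetric(d: int, rng: np.random.Generator, zero_diagonal: bool = True) -> np.ndarray:
    M = rng.standard_normal((d, d))
    M = (M + M.T) / np.sqrt(2.0)
    if zero_diagonal:
        np.fill_diagonal(M, 0.0)
    return M


def _to_correlation(L: np.ndarray) -> np.ndarray:
    """exp(L) rescaled to unit diagonal; a valid correlation matrix."""
    S = matrix_exp(L)
    inv_sqrt = 1.0 / np.sqrt(np.diag(S))
    C = S * inv_sqrt[:, None] * inv_sqrt[None, :]
    C = (C + C.T) / 2.0
    np.fill_diagonal(C, 1.0)
    return np.clip(C, -1.0, 1.0)


def make_random_correlation(d: int, rng: np.random.Generator, sd: float = 0.2) -> np.ndarray:
    """Random correlation matrix: exponential of a random symmetric log-matrix.

    Congruence with the positive diagonal rescaling preserves definiteness,
    so the result is symmetric positive definite with unit diagonal.
    """
    if d < 2:
        raise ValidationError(f"d must be >= 2, got {d}")
    return _to_correlation(sd * _random_symmetric(d, rng, zero_diagonal=False))


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Deterministically generate a cohort from its spec (seeded)."""
    rng = np.random.default_rng(spec.seed)
    d, K = spec.d, spec.n_clusters

    B = spec.base_sd * _random_symmetric(d, rng)
    U = _random_symmetric(d, rng)
    U /= np.linalg.norm(U)
    offsets = (np.arange(K) - (K - 1) / 2.0) * spec.cluster_separation

    labels = np.arange(spec.n_subjects) % K  # round-robin assignment
    # per-entry sd such that the perturbation's expected Frobenius norm
    # matches within_cluster_sd (zero-diagonal symmetric Gaussian)
    entry_sd = spec.within_cluster_sd / np.sqrt(d * (d - 1)) if d > 1 else 0.0
    beta = (
        spec.coupling_score_sd / spec.within_cluster_sd
        if (spec.coupling == "linear_in_tangent" and spec.within_cluster_sd > 0)
        else 0.0
    )

    subjects: list[Subject] = []
    ground_truth: dict[str, dict] = {}
    width = max(3, len(str(spec.n_subjects - 1)))
    for i in range(spec.n_subjects):
        m = int(labels[i])
        sid = f"sub-{i:0{width}d}"
        if spec.coupling == "linear_in_tangent":
            t = spec.within_cluster_sd * rng.standard_normal()
            deviation = t * U
            score = spec.score_centers[m] + beta * t
        else:
            # off-diagonal entries of _random_symmetric have unit variance,
            # so this gives E||deviation||_F^2 = within_cluster_sd^2
            deviation = _random_symmetric(d, rng) * entry_sd
            t = float(np.sum(U * deviation))
            score = spec.score_centers[m]
        if spec.coupling == "pure_noise":
            score = float(np.mean(spec.score_centers))
        score += spec.score_sd * rng.standard_normal()
        L = B + offsets[m] * U + deviation
        C = _to_correlation(L)
        subjects.append(Subject.from_correlation(sid, C, score, mu=spec.mu))
        ground_truth[sid] = {
            "cluster": m,
            "log_matrix": L,
            "axis_coordinate": t,
            "beta": beta,
        }
    return SyntheticCohort(subjects=subjects, ground_truth=ground_truth, spec=spec)


def write_cohort(cohort: SyntheticCohort, directory, score_column: str = "FIQ") -> None:
    """Write a cohort in the pipeline's input format.

    One whitespace-delimited ``<subject id>.txt`` matrix file per subject
    plus a ``scores.csv`` table with columns ``id, FIQ, VIQ`` (the score is
    written to ``score_column``; the other column is left empty).
    """
    import pandas as pd
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if score_column not in ("FIQ", "VIQ"):
        raise ValidationError(f"score_column must be FIQ or VIQ, got {score_column!r}")
    rows = []
    for s in cohort.subjects:
        np.savetxt(directory / f"{s.id}.txt", s.connectome, fmt="%.17e")
        row = {"id": s.id, "FIQ": "", "VIQ": ""}
        row[score_column] = repr(s.score)
        rows.append(row)
    pd.DataFrame(rows, columns=["id", "FIQ", "VIQ"]).to_csv(directory / "scores.csv", index=False)
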