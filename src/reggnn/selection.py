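"""Learning-based selection of the most predictive training samples.

The procedure ranks training subjects by how well their connectome predicts
the cognitive scores of held-out subjects, using only cheap linear models:

i.   For each pair of regularized connectomes, compute the tangent matrix of
     the connecting geodesic, parallel-translated to the identity.
ii.  Compress each tangent matrix into a feature vector (see
     :mod:`reggnn.features`).
iii. Fit a linear map ``f`` from train-in pair features to the absolute score
     difference of the pair.
iv.  For each holdout subject, find the ``k`` train-in subjects with the
     smallest predicted score difference and increment their counters.

Steps i–iv run in a nested N-fold cross-validation over the training set, so
every subject serves in the train-in group exactly N - 1 times; the ``k``
subjects with the highest cumulative frequency are selected.

Selection operates on the ridge-regularized matrices *without* zeroing
negative correlations (negative edges are only dropped later, when the
network is trained).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import LinearRegression

from . import config
from .exceptions import ConfigurationError, ValidationError
from .features import FEATURE_MODES, features_from_tangent, upper_triangle
from .geometry import matrix_log, regularize, validate_correlation_matrix

__all__ = [
    "Subject",
    "SelectionConfig",
    "DifferenceRegressor",
    "SelectionResult",
    "fit_difference_regressor",
    "run_selection_fold",
    "select_samples",
    "select_samples_sweep",
    "write_selection_report",
]


@dataclass
class Subject:
    """One study participant: connectome, its SPD regularization and a score."""

    id: str
    connectome: np.ndarray
    spd: np.ndarray
    score: float

    @classmethod
    def from_correlation(cls, subject_id: str, C, score: float, mu: float = config.DEFAULT_MU) -> "Subject":
        C = validate_correlation_matrix(C, name=f"connectome {subject_id}")
        return cls(id=str(subject_id), connectome=C, spd=regularize(C, mu, subject_id=subject_id), score=float(score))

    @property
    def d(self) -> int:
        return self.connectome.shape[0]


@dataclass
class SelectionConfig:
    """Settings of the sample-selection procedure.

    ``k`` is the number of samples to select (the study varies it over
    2..15); ``n_folds`` is the inner cross-validation depth N; ``mode`` is
    the pairwise feature mode; ``mu`` the SPD ridge.
    """

    k: int = 5
    n_folds: int = 5
    mode: str = "dc"
    seed: int = 0
    mu: float = config.DEFAULT_MU

    def __post_init__(self) -> None:
        if self.mode not in FEATURE_MODES:
            raise ConfigurationError(f"unknown feature mode {self.mode!r}")
        if self.k < 1:
            raise ConfigurationError(f"k must be >= 1, got {self.k}")
        if self.n_folds < 2:
            raise ConfigurationError(f"n_folds must be >= 2, got {self.n_folds}")


@dataclass
class DifferenceRegressor:
    """Affine map from pair features to a predicted absolute score difference."""

    coefficients: np.ndarray
    intercept: float

    def predict(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return X @ self.coefficients + self.intercept


@dataclass
class SelectionResult:
    """Outcome of :func:`select_samples`."""

    selected_ids: list[str]
    frequency: dict[str, int]
    per_fold_log: list[dict] = field(default_factory=list)


def fit_difference_regressor(X, y) -> DifferenceRegressor:
    """Ordinary least squares with intercept on pair features.

    When the feature dimension exceeds the number of pairs (possible for the
    full tangent-matrix mode) the minimum-norm least-squares solution is
    returned.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValidationError("need a non-empty 2-D feature matrix")
    if X.shape[0] != y.shape[0]:
        raise ValidationError(f"{X.shape[0]} feature rows but {y.shape[0]} targets")
    if X.shape[0] < 2:
        raise ValidationError("need at least 2 pairs to fit the difference regressor")
    model = LinearRegression().fit(X, y)
    return DifferenceRegressor(coefficients=np.asarray(model.coef_, dtype=float), intercept=float(model.intercept_))


def _pair_feature(si: Subject, sj: Subject, mode: str, logs: dict[str, np.ndarray]) -> np.ndarray:
    if mode == "a":
        diff = upper_triangle(si.spd) - upper_triangle(sj.spd)
        return np.array([float(np.linalg.norm(diff))])
    S = logs[sj.id] - logs[si.id]
    return features_from_tangent(S, mode)


def _fold_rankings(
    train_in: list[Subject],
    holdout: list[Subject],
    cfg: SelectionConfig,
    logs: dict[str, np.ndarray] | None = None,
) -> dict[str, list[str]]:
    """For each holdout subject, train-in ids sorted by predicted |score diff|.

    Ties in the prediction are broken by ascending subject id.
    """
    if not train_in or not holdout:
        raise ValidationError("train-in and holdout groups must be non-empty")
    if set(s.id for s in train_in) & set(s.id for s in holdout):
        raise ValidationError("train-in and holdout groups must be disjoint")
    if logs is None:
        logs = {}
    if cfg.mode != "a":
        for s in [*train_in, *holdout]:
            if s.id not in logs:
                logs[s.id] = matrix_log(s.spd)

    X_train, y_train = [], []
    for a in range(len(train_in)):
        for b in range(a + 1, len(train_in)):
            X_train.append(_pair_feature(train_in[a], train_in[b], cfg.mode, logs))
            y_train.append(abs(train_in[a].score - train_in[b].score))
    X_train = np.vstack(X_train)
    f = fit_difference_regressor(X_train, np.asarray(y_train))

    X_cross = np.vstack(
        [_pair_feature(sj, sl, cfg.mode, logs) for sl in holdout for sj in train_in]
    )
    if X_cross.shape[1] != X_train.shape[1]:
        raise ValidationError("feature length mismatch between train-in and cross pairs")
    pred = f.predict(X_cross).reshape(len(holdout), len(train_in))

    rankings: dict[str, list[str]] = {}
    for li, sl in enumerate(holdout):
        order = sorted(range(len(train_in)), key=lambda j: (pred[li, j], train_in[j].id))
        rankings[sl.id] = [train_in[j].id for j in order]
    return rankings


def run_selection_fold(
    train_in: list[Subject],
    holdout: list[Subject],
    cfg: SelectionConfig,
    *,
    logs: dict[str, np.ndarray] | None = None,
) -> dict[str, int]:
    """Steps i–iv on one inner split; returns increments per train-in id.

    Each holdout subject contributes one increment to each of the ``k``
    train-in subjects with the smallest predicted absolute score difference,
    so the increments always sum to ``k * len(holdout)``.
    """
    if cfg.k > len(train_in):
        raise ConfigurationError(f"k={cfg.k} exceeds train-in size {len(train_in)}")
    rankings = _fold_rankings(train_in, holdout, cfg, logs)
    increments = {s.id: 0 for s in train_in}
    for ranked in rankings.values():
        for jid in ranked[: cfg.k]:
            increments[jid] += 1
    return increments


def _partition(n: int, n_folds: int, seed: int) -> list[np.ndarray]:
    """Seeded shuffle of positions 0..n-1 into near-equal folds.

    The remainder is distributed to the first folds, as with
    ``numpy.array_split``.
    """
    perm = np.random.default_rng(seed).permutation(n)
    return np.array_split(perm, n_folds)


def select_samples_sweep(
    training_set: list[Subject],
    cfg: SelectionConfig,
    ks: list[int],
) -> dict[int, SelectionResult]:
    """Run the nested selection once and read off results for several ``k``.

    The expensive parts (tangent matrices, features, regressions and the
    per-holdout rankings) do not depend on ``k``; only the top-``k`` cut
    does.  Results are identical to calling :func:`select_samples` per ``k``.
    """
    n = len(training_set)
    if n < cfg.n_folds:
        raise ConfigurationError(f"{n} subjects cannot form {cfg.n_folds} folds")
    folds = _partition(n, cfg.n_folds, cfg.seed)
    min_train_in = n - max(len(f) for f in folds)
    for k in ks:
        if k > min_train_in:
            raise ConfigurationError(
                f"k={k} exceeds the smallest train-in group size {min_train_in}"
            )

    logs: dict[str, np.ndarray] = {}
    fold_rankings = []
    for fold in folds:
        hold_idx = set(fold.tolist())
        holdout = [training_set[i] for i in sorted(hold_idx)]
        train_in = [training_set[i] for i in range(n) if i not in hold_idx]
        fold_rankings.append(
            (holdout, train_in, _fold_rankings(train_in, holdout, cfg, logs))
        )

    out: dict[int, SelectionResult] = {}
    for k in ks:
        frequency = {s.id: 0 for s in training_set}
        per_fold_log = []
        for fold_no, (holdout, train_in, rankings) in enumerate(fold_rankings):
            increments = {s.id: 0 for s in train_in}
            for ranked in rankings.values():
                for jid in ranked[:k]:
                    increments[jid] += 1
            for jid, c in increments.items():
                frequency[jid] += c
            per_fold_log.append(
                {
                    "fold": fold_no,
                    "holdout_ids": [s.id for s in holdout],
                    "increments": increments,
                }
            )
        order = sorted(frequency, key=lambda sid: (-frequency[sid], sid))
        out[k] = SelectionResult(selected_ids=order[:k], frequency=frequency, per_fold_log=per_fold_log)
    return out


def select_samples(training_set: list[Subject], cfg: SelectionConfig) -> SelectionResult:
    """Full nested N-fold selection; returns the top-``k`` subject ids.

    Deterministic given ``cfg.seed``: the fold assignment shuffles subject
    *positions* with a seeded generator, and all ties (predicted differences
    and cumulative frequencies) are broken by ascending subject id.
    """
    return select_samples_sweep(training_set, cfg, [cfg.k])[cfg.k]


def write_selection_report(result: SelectionResult, path) -> None:
    """Write the cumulative frequency table as a delimited file."""
    import pandas as pd

    selected = set(result.selected_ids)
    rows = sorted(result.frequency.items(), key=lambda kv: (-kv[1], kv[0]))
    df = pd.DataFrame(
        {
            "subject_id": [sid for sid, _ in rows],
            "cumulative_frequency": [c for _, c in rows],
            "selected": [int(sid in selected) for sid, _ in rows],
        }
    )
    df.to_csv(path, index=False)
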