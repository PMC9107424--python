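"""End-to-end pipeline: outer split, sample selection, training, evaluation.

For every outer cross-validation fold the training split alone feeds the
sample-selection procedure; the network is then trained only on the selected
``k`` subjects (with negative correlations removed) and evaluated on the
untouched test split.  The sweep over ``k`` and an all-samples baseline give
the summary tables reported by connectome-regression studies: per-``k``
MAE/RMSE averaged over folds, their mean/sd/min/max over the sweep, and a
Welch t-test between the per-subject absolute errors of the best-``k`` model
and the baseline.

One master seed derives the sub-seeds for the outer split, the selection
shuffles and the model initializations by fixed offsets, so each component
is independently reproducible and the whole report is byte-identical across
runs with the same configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import KFold

from .exceptions import ConfigurationError, ValidationError
from .network import RegGNNConfig, average_region_ranking, predict, preprocess_for_gnn, train
from .selection import SelectionConfig, Subject, select_samples_sweep

__all__ = [
    "PipelineConfig",
    "EvaluationReport",
    "load_cohort",
    "kfold_split",
    "compute_mae",
    "compute_rmse",
    "ttest_pvalue",
    "run_pipeline",
]

# fixed offsets deriving component seeds from the master seed
_SPLIT_SEED_OFFSET = 1
_SELECTION_SEED_OFFSET = 2
_MODEL_SEED_OFFSET = 3
_SEED_MOD = 2**31 - 1


@dataclass
class PipelineConfig:
    """Configuration of one full pipeline run."""

    matrix_dir: str | Path | None = None
    scores_path: str | Path | None = None
    stacked_path: str | Path | None = None
    score_column: str = "FIQ"
    outer_folds: int = 3
    k_min: int = 2
    k_max: int = 15
    selection: SelectionConfig = dataclass_field(default_factory=SelectionConfig)
    model: RegGNNConfig = dataclass_field(default_factory=RegGNNConfig)
    output_dir: str | Path | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.outer_folds < 2:
            raise ConfigurationError(f"outer_folds must be >= 2, got {self.outer_folds}")
        if self.k_min > self.k_max or self.k_min < 1:
            raise ConfigurationError(f"invalid k sweep [{self.k_min}, {self.k_max}]")
        if self.score_column not in ("FIQ", "VIQ"):
            raise ConfigurationError(f"score_column must be FIQ or VIQ, got {self.score_column!r}")


@dataclass
class EvaluationReport:
    """All evaluation tables of one pipeline run."""

    cells: pd.DataFrame  # columns: k, fold, mae, rmse, n_test
    per_k: pd.DataFrame  # columns: k, mae, rmse (fold means)
    summary: dict  # mean/sd/min/max of the per-k means, for MAE and RMSE
    baseline: pd.DataFrame  # per-fold MAE/RMSE of the all-samples model
    best_k: int
    ttest_p: float
    selected_ids: dict  # (fold, k) -> selected subject ids
    region_ranking: list  # (roi index, mean |weight|) pairs, best first

    def to_csv(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.cells.to_csv(directory / "cells.csv", index=False)
        self.per_k.to_csv(directory / "per_k.csv", index=False)
        self.baseline.to_csv(directory / "baseline.csv", index=False)
        pd.DataFrame(self.region_ranking, columns=["roi_index", "mean_abs_weight"]).assign(
            rank=lambda df: np.arange(1, len(df) + 1)
        ).to_csv(directory / "region_weights.csv", index=False)
        with open(directory / "summary.txt", "w") as fh:
            fh.write(self.render_summary())

    def render_summary(self) -> str:
        s = self.summary
        lines = [
            "RegGNN evaluation summary",
            "=========================",
            f"k sweep: {self.per_k['k'].min()}..{self.per_k['k'].max()}",
            f"MAE  mean +- sd (min, max) over k: {s['mae_mean']:.3f} +- {s['mae_sd']:.3f} "
            f"({s['mae_min']:.3f}, {s['mae_max']:.3f})",
            f"RMSE mean +- sd (min, max) over k: {s['rmse_mean']:.3f} +- {s['rmse_sd']:.3f} "
            f"({s['rmse_min']:.3f}, {s['rmse_max']:.3f})",
            f"baseline (all training samples): MAE {s['baseline_mae']:.3f}, RMSE {s['baseline_rmse']:.3f}",
            f"best k by mean MAE: {self.best_k}",
            f"Welch t-test p (best-k errors vs baseline errors): {self.ttest_p:.4g}",
        ]
        return "\n".join(lines) + "\n"


def load_cohort(cfg: PipelineConfig) -> list[Subject]:
    """Load and validate subjects from disk.

    Two input layouts are supported: a directory of per-subject delimited
    ``<id>.txt`` matrices, or a single ``.npz`` container with arrays
    ``ids`` and ``matrices``.  Scores come from a CSV with columns
    ``id, FIQ, VIQ``.  All problems found are reported together, naming the
    offending files/ids.
    """
    if cfg.scores_path is None:
        raise ConfigurationError("scores_path is required")
    # read as strings and convert with float() so values round-trip exactly
    scores = pd.read_csv(cfg.scores_path, dtype=str)
    if cfg.score_column not in scores.columns:
        raise ValidationError(f"scores table has no column {cfg.score_column!r}")
    score_map = {
        sid: val
        for sid, val in zip(scores["id"], scores[cfg.score_column])
        if isinstance(val, str) and val.strip()
    }

    matrices: dict[str, np.ndarray] = {}
    problems: list[str] = []
    if cfg.stacked_path is not None:
        with np.load(cfg.stacked_path) as data:
            ids = [str(x) for x in data["ids"]]
            for sid, M in zip(ids, data["matrices"]):
                matrices[sid] = np.asarray(M, dtype=float)
    elif cfg.matrix_dir is not None:
        files = sorted(Path(cfg.matrix_dir).glob("*.txt"))
        if not files:
            raise ValidationError(f"no .txt matrix files found in {cfg.matrix_dir}")
        for f in files:
            try:
                matrices[f.stem] = np.loadtxt(f)
            except Exception as exc:  # noqa: BLE001 - report per-file diagnostics
                problems.append(f"{f.name}: unreadable ({exc})")
    else:
        raise ConfigurationError("either matrix_dir or stacked_path is required")

    dims = set()
    subjects: list[Subject] = []
    for sid in sorted(matrices):
        M = matrices[sid]
        if M.ndim != 2 or M.shape[0] != M.shape[1]:
            problems.append(f"{sid}: matrix is not square (shape {M.shape})")
            continue
        if not np.isfinite(M).all():
            problems.append(f"{sid}: matrix contains NaN/inf entries")
            continue
        dims.add(M.shape[0])
        raw_score = score_map.get(sid)
        if raw_score is None or (isinstance(raw_score, float) and np.isnan(raw_score)):
            problems.append(f"{sid}: missing {cfg.score_column} score")
            continue
        try:
            subjects.append(Subject.from_correlation(sid, M, float(raw_score), mu=cfg.selection.mu))
        except Exception as exc:  # noqa: BLE001
            problems.append(f"{sid}: {exc}")
    if len(dims) > 1:
        problems.append(f"matrix dimensions are not uniform: {sorted(dims)}")
    if problems:
        raise ValidationError("cohort loading failed:\n  " + "\n  ".join(problems))
    return subjects


def kfold_split(n: int, folds: int, seed: int) -> list[tuple[np.ndarray, np.ndarray]]:
    """Seeded shuffled K-fold over ``range(n)``: near-equal, disjoint, exhaustive."""
    if folds > n:
        raise ConfigurationError(f"cannot split {n} subjects into {folds} folds")
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed % _SEED_MOD)
    return [(tr, te) for tr, te in kf.split(np.arange(n))]


def compute_mae(pred, truth) -> float:
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.shape != truth.shape or pred.size == 0:
        raise ValidationError(f"length mismatch or empty input: {pred.shape} vs {truth.shape}")
    return float(np.mean(np.abs(pred - truth)))


def compute_rmse(pred, truth) -> float:
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.shape != truth.shape or pred.size == 0:
        raise ValidationError(f"length mismatch or empty input: {pred.shape} vs {truth.shape}")
    return float(np.sqrt(np.mean((pred - truth) ** 2)))


def ttest_pvalue(errors_a, errors_b) -> float:
    """Two-sided Welch t-test p-value between two error samples.

    By convention two zero-variance samples with equal means give p = 1
    (no evidence of a difference) and with unequal means give p = 0.
    """
    a = np.asarray(errors_a, dtype=float)
    b = np.asarray(errors_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("each error sample needs at least 2 values")
    if np.var(a) == 0.0 and np.var(b) == 0.0:
        return 1.0 if np.mean(a) == np.mean(b) else 0.0
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue)


def _train_and_eval(train_graphs, test_graphs, model_cfg: RegGNNConfig):
    params, _ = train(train_graphs, model_cfg)
    pred = predict(params, test_graphs, model_cfg)
    truth = np.array([g.score for g in test_graphs])
    return params, pred, truth


def run_pipeline(cfg: PipelineConfig, subjects: list[Subject] | None = None) -> EvaluationReport:
    """Run the full split/select/train/evaluate protocol.

    ``subjects`` may be passed directly (e.g. a synthetic cohort); otherwise
    they are loaded from the configured paths.  Subjects are ordered by id
    before splitting, so the report depends on ids, not file order.
    """
    if subjects is None:
        subjects = load_cohort(cfg)
    subjects = sorted(subjects, key=lambda s: s.id)
    n = len(subjects)
    d = subjects[0].d
    if cfg.model.d != d:
        raise ConfigurationError(f"model expects d={cfg.model.d} but cohort has d={d}")
    ks = list(range(cfg.k_min, cfg.k_max + 1))

    splits = kfold_split(n, cfg.outer_folds, cfg.seed + _SPLIT_SEED_OFFSET)
    # validate the k sweep against the smallest inner train-in group
    min_outer_train = min(len(tr) for tr, _ in splits)
    largest_fold = -(-min_outer_train // cfg.selection.n_folds)
    if cfg.k_max > min_outer_train - largest_fold:
        raise ConfigurationError(
            f"k_max={cfg.k_max} exceeds the smallest inner train-in size "
            f"{min_outer_train - largest_fold}"
        )

    graphs = {
        s.id: preprocess_for_gnn(s.connectome, cfg.model, subject_id=s.id, score=s.score)
        for s in subjects
    }

    cells, baseline_rows = [], []
    errors_by_k: dict[int, list[np.ndarray]] = {k: [] for k in ks}
    baseline_errors: list[np.ndarray] = []
    selected_ids: dict[tuple[int, int], list[str]] = {}
    params_by_k: dict[int, list] = {k: [] for k in ks}

    for fold_no, (train_idx, test_idx) in enumerate(splits):
        train_subjects = [subjects[i] for i in train_idx]
        test_graphs = [graphs[subjects[i].id] for i in test_idx]

        sel_cfg = SelectionConfig(
            k=cfg.selection.k,
            n_folds=cfg.selection.n_folds,
            mode=cfg.selection.mode,
            seed=(cfg.seed + _SELECTION_SEED_OFFSET + fold_no) % _SEED_MOD,
            mu=cfg.selection.mu,
        )
        sweep = select_samples_sweep(train_subjects, sel_cfg, ks)

        for k in ks:
            selected = sweep[k].selected_ids
            selected_ids[(fold_no, k)] = selected
            model_cfg = _fold_model_cfg(cfg, fold_no, k)
            params, pred, truth = _train_and_eval(
                [graphs[sid] for sid in selected], test_graphs, model_cfg
            )
            params_by_k[k].append(params)
            errors_by_k[k].append(np.abs(pred - truth))
            cells.append(
                {
                    "k": k,
                    "fold": fold_no,
                    "mae": compute_mae(pred, truth),
                    "rmse": compute_rmse(pred, truth),
                    "n_test": len(test_idx),
                }
            )

        model_cfg = _fold_model_cfg(cfg, fold_no, 0)
        _, pred, truth = _train_and_eval(
            [graphs[s.id] for s in train_subjects], test_graphs, model_cfg
        )
        baseline_errors.append(np.abs(pred - truth))
        baseline_rows.append(
            {
                "fold": fold_no,
                "mae": compute_mae(pred, truth),
                "rmse": compute_rmse(pred, truth),
                "n_test": len(test_idx),
            }
        )

    cells_df = pd.DataFrame(cells)
    per_k = (
        cells_df.groupby("k", as_index=False)[["mae", "rmse"]].mean().sort_values("k").reset_index(drop=True)
    )
    baseline_df = pd.DataFrame(baseline_rows)
    summary = {
        "mae_mean": float(per_k["mae"].mean()),
        "mae_sd": float(per_k["mae"].std(ddof=1)),
        "mae_min": float(per_k["mae"].min()),
        "mae_max": float(per_k["mae"].max()),
        "rmse_mean": float(per_k["rmse"].mean()),
        "rmse_sd": float(per_k["rmse"].std(ddof=1)),
        "rmse_min": float(per_k["rmse"].min()),
        "rmse_max": float(per_k["rmse"].max()),
        "baseline_mae": float(baseline_df["mae"].mean()),
        "baseline_rmse": float(baseline_df["rmse"].mean()),
    }
    best_k = int(per_k.loc[per_k["mae"].idxmin(), "k"])
    pooled_best = np.concatenate(errors_by_k[best_k])
    pooled_baseline = np.concatenate(baseline_errors)
    p = ttest_pvalue(pooled_best, pooled_baseline)

    ranking = average_region_ranking([p for plist in params_by_k.values() for p in plist])

    report = EvaluationReport(
        cells=cells_df,
        per_k=per_k,
        summary=summary,
        baseline=baseline_df,
        best_k=best_k,
        ttest_p=p,
        selected_ids={f"{f}:{k}": v for (f, k), v in selected_ids.items()},
        region_ranking=ranking,
    )
    if cfg.output_dir is not None:
        report.to_csv(cfg.output_dir)
    return report


def _fold_model_cfg(cfg: PipelineConfig, fold_no: int, k: int) -> RegGNNConfig:
    """Model config with a per-(fold, k) derived seed; k=0 marks the baseline."""
    return RegGNNConfig(
        d=cfg.model.d,
        hidden=cfg.model.hidden,
        dropout=cfg.model.dropout,
        learning_rate=cfg.model.learning_rate,
        weight_decay=cfg.model.weight_decay,
        epochs=cfg.model.epochs,
        seed=(cfg.seed + _MODEL_SEED_OFFSET + 1000 * fold_no + k) % _SEED_MOD,
        neg_handling=cfg.model.neg_handling,
        mu=cfg.model.mu,
        bias_init_mean=cfg.model.bias_init_mean,
    )
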