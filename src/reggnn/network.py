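"""RegGNN: a two-layer graph-convolutional regressor for connectomes.

The network receives the (regularized, non-negative) connectome adjacency
``A`` of one subject and predicts a scalar cognitive score.  With
``A~ = A + I`` and ``D~`` its diagonal degree matrix, the symmetrically
normalized operator is ``A^ = D~^{-1/2} A~ D~^{-1/2}`` and the forward pass
is

    H1 = ReLU(A^ @ H0 @ W1),  H0 = I          (d x d1)
    H2 = ReLU(A^ @ H1 @ W2)                   (d x 1)
    y  = fc_w . H2[:, 0] + fc_b               (scalar)

with dropout (inverted scaling) applied to ``H1`` during training only.
Training minimizes the mean squared error with Adam and classical L2 weight
decay folded into the gradient; gradients are computed analytically.  The
absolute weights of the final fully connected layer rank the brain regions
by their influence on the prediction.

Everything is plain NumPy: the model is tiny (two weight matrices and a
linear readout) and full-batch training on at most a few dozen subjects
needs no deep-learning framework.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import config
from .exceptions import ConfigurationError, DivergenceError, ValidationError
from .geometry import regularize, validate_correlation_matrix

__all__ = [
    "RegGNNConfig",
    "RegGNNParameters",
    "PreprocessedGraph",
    "normalized_adjacency",
    "preprocess_for_gnn",
    "gcn_layer",
    "forward",
    "train",
    "predict",
    "region_weights",
    "average_region_ranking",
    "save_parameters",
    "load_parameters",
]


@dataclass
class RegGNNConfig:
    """Architecture and optimization settings.

    Defaults follow the published protocol: 116 ROIs, hidden width 64,
    scalar output, dropout 0.1 after the first convolution, Adam with
    learning rate 1e-3 and weight decay 5e-4 for 100 epochs.  Negative
    correlations are zeroed entrywise before training
    (``neg_handling='zero_entries'``); ``'clamp_eigenvalues'`` instead
    reconstructs the matrix with negative eigenvalues set to zero.
    """

    d: int = 116
    hidden: int = 64
    dropout: float = 0.1
    learning_rate: float = 0.001
    weight_decay: float = 0.0005
    epochs: int = 100
    seed: int = 0
    neg_handling: str = "zero_entries"
    mu: float = config.DEFAULT_MU
    bias_init_mean: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout < 1.0:
            raise ConfigurationError(f"dropout must be in [0, 1), got {self.dropout}")
        if self.epochs < 1:
            raise ConfigurationError(f"epochs must be >= 1, got {self.epochs}")
        if self.neg_handling not in ("zero_entries", "clamp_eigenvalues"):
            raise ConfigurationError(f"unknown neg_handling {self.neg_handling!r}")


@dataclass
class RegGNNParameters:
    """Learnable parameters: two convolution weight matrices and the readout."""

    W1: np.ndarray  # (d, hidden)
    W2: np.ndarray  # (hidden, 1)
    fc_w: np.ndarray  # (d,)
    fc_b: float

    def blocks(self) -> dict[str, np.ndarray]:
        return {"W1": self.W1, "W2": self.W2, "fc_w": self.fc_w, "fc_b": np.array([self.fc_b])}

    def copy(self) -> "RegGNNParameters":
        return RegGNNParameters(self.W1.copy(), self.W2.copy(), self.fc_w.copy(), float(self.fc_b))


@dataclass
class PreprocessedGraph:
    """A subject's non-negative adjacency and its normalized operator."""

    subject_id: str
    adjacency: np.ndarray
    norm_adjacency: np.ndarray
    score: float = field(default=np.nan)


def normalized_adjacency(A) -> np.ndarray:
    """Symmetric GCN normalization with self-loops of a non-negative adjacency."""
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValidationError(f"adjacency must be square, got {A.shape}")
    if np.abs(A - A.T).max() > config.SYMMETRY_TOL:
        raise ValidationError("adjacency must be symmetric")
    if A.min() < 0:
        raise ValidationError("adjacency must be non-negative")
    A_tilde = A + np.eye(A.shape[0])
    inv_sqrt_deg = 1.0 / np.sqrt(A_tilde.sum(axis=1))  # self-loop guarantees degree >= 1
    A_hat = A_tilde * inv_sqrt_deg[:, None] * inv_sqrt_deg[None, :]
    return (A_hat + A_hat.T) / 2.0


def preprocess_for_gnn(
    C,
    cfg: RegGNNConfig,
    *,
    subject_id: str = "",
    score: float = np.nan,
) -> PreprocessedGraph:
    """Regularize a connectome, drop negative values and normalize it.

    ``zero_entries`` sets every negative correlation to zero;
    ``clamp_eigenvalues`` reconstructs the matrix with negative eigenvalues
    clamped to zero and then removes any residual negative entries below
    ``-1e-12`` left by the reconstruction.
    """
    C = validate_correlation_matrix(C, name=f"connectome {subject_id}" if subject_id else "connectome")
    P = regularize(C, cfg.mu, subject_id=subject_id or None)
    if cfg.neg_handling == "zero_entries":
        A = np.where(P < 0.0, 0.0, P)
    else:
        lam, U = np.linalg.eigh(P)
        A = (U * np.clip(lam, 0.0, None)) @ U.T
        A = (A + A.T) / 2.0
        # the reconstruction leaves tiny negative entries; remove them all
        A = np.clip(A, 0.0, None)
    return PreprocessedGraph(
        subject_id=str(subject_id),
        adjacency=A,
        norm_adjacency=normalized_adjacency(A),
        score=float(score),
    )


def gcn_layer(H, A_hat, W) -> np.ndarray:
    """One graph convolution: ``ReLU(A_hat @ H @ W)``."""
    H = np.asarray(H, dtype=float)
    A_hat = np.asarray(A_hat, dtype=float)
    W = np.asarray(W, dtype=float)
    if A_hat.shape[1] != H.shape[0] or H.shape[1] != W.shape[0]:
        raise ValidationError(
            f"incompatible shapes A_hat {A_hat.shape}, H {H.shape}, W {W.shape}"
        )
    return np.maximum(A_hat @ H @ W, 0.0)


def _forward_cached(g: PreprocessedGraph, params: RegGNNParameters, mask: np.ndarray | None):
    """Forward pass keeping intermediates for backprop.

    ``mask`` is the (inverted-scaling) dropout mask for H1, or None in
    evaluation mode.
    """
    A = g.norm_adjacency
    Z1 = A @ params.W1  # H0 = I
    H1 = np.maximum(Z1, 0.0)
    H1d = H1 if mask is None else H1 * mask
    Z2 = A @ H1d @ params.W2
    H2 = np.maximum(Z2, 0.0)
    e = H2[:, 0]
    y = float(params.fc_w @ e + params.fc_b)
    return y, (A, Z1, H1d, Z2, e)


def forward(
    g: PreprocessedGraph,
    params: RegGNNParameters,
    cfg: RegGNNConfig,
    *,
    training_mode: bool = False,
    rng: np.random.Generator | None = None,
) -> float:
    """Predict one subject's score.  Deterministic in evaluation mode."""
    if params.W1.shape != (g.norm_adjacency.shape[0], params.W2.shape[0]):
        raise ValidationError(
            f"parameter shapes {params.W1.shape}/{params.W2.shape} do not match graph "
            f"dimension {g.norm_adjacency.shape[0]}"
        )
    mask = None
    if training_mode and cfg.dropout > 0.0:
        if rng is None:
            rng = np.random.default_rng(cfg.seed)
        keep = 1.0 - cfg.dropout
        mask = (rng.random(params.W1.shape) < keep) / keep
    y, _ = _forward_cached(g, params, mask)
    return y


def _loss_and_grads(
    params: RegGNNParameters,
    samples: list[PreprocessedGraph],
    cfg: RegGNNConfig,
    masks: list[np.ndarray | None],
):
    """Mean-squared-error loss (plus L2 penalty) and its analytic gradients."""
    n = len(samples)
    gW1 = np.zeros_like(params.W1)
    gW2 = np.zeros_like(params.W2)
    gfc = np.zeros_like(params.fc_w)
    gb = 0.0
    mse = 0.0
    for g, mask in zip(samples, masks):
        y, (A, Z1, H1d, Z2, e) = _forward_cached(g, params, mask)
        r = y - g.score
        mse += r * r / n
        gy = 2.0 * r / n
        gfc += gy * e
        gb += gy
        dZ2 = (gy * params.fc_w)[:, None] * (Z2 > 0)
        gW2 += H1d.T @ (A @ dZ2)
        dH1d = A @ dZ2 @ params.W2.T
        dH1 = dH1d if mask is None else dH1d * mask
        dZ1 = dH1 * (Z1 > 0)
        gW1 += A @ dZ1
    wd = cfg.weight_decay
    penalty = 0.0
    if wd:
        penalty = 0.5 * wd * (
            float(np.sum(params.W1**2))
            + float(np.sum(params.W2**2))
            + float(np.sum(params.fc_w**2))
            + params.fc_b**2
        )
        gW1 += wd * params.W1
        gW2 += wd * params.W2
        gfc += wd * params.fc_w
        gb += wd * params.fc_b
    return mse + penalty, mse, {"W1": gW1, "W2": gW2, "fc_w": gfc, "fc_b": gb}


def _init_parameters(cfg: RegGNNConfig, mean_score: float, rng: np.random.Generator) -> RegGNNParameters:
    """Seeded uniform Glorot-style initialization.

    The second convolution has a single output column acting on a
    non-negative input (``A_hat @ H1 >= 0``); a signed random column would
    make all of its pre-activations share one sign, and in the negative case
    the ReLU silences the whole embedding with no gradient to recover.  The
    column is therefore initialized non-negative, ``U(0, glorot limit)``
    (it is free to change sign during training).  The readout bias starts at
    the training-set mean score (or zero when ``bias_init_mean`` is off).
    """

    def glorot(fan_in, fan_out, shape, low_factor=-1.0):
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        return rng.uniform(low_factor * limit, limit, size=shape)

    return RegGNNParameters(
        W1=glorot(cfg.d, cfg.hidden, (cfg.d, cfg.hidden)),
        W2=glorot(cfg.hidden, 1, (cfg.hidden, 1), low_factor=0.0),
        fc_w=glorot(cfg.d, 1, (cfg.d,)),
        fc_b=float(mean_score) if cfg.bias_init_mean else 0.0,
    )


def train(samples: list[PreprocessedGraph], cfg: RegGNNConfig):
    """Full-batch Adam training; returns parameters and the per-epoch MSE.

    Reproducible given ``cfg.seed`` (initialization and dropout masks come
    from one seeded generator).  Raises :class:`DivergenceError` if the loss
    becomes non-finite.
    """
    if not samples:
        raise ValidationError("cannot train on an empty sample list")
    d = samples[0].norm_adjacency.shape[0]
    if d != cfg.d:
        raise ConfigurationError(f"config expects d={cfg.d} but graphs have d={d}")
    if not np.all(np.isfinite([g.score for g in samples])):
        raise ValidationError("all training scores must be finite")

    rng = np.random.default_rng(cfg.seed)
    params = _init_parameters(cfg, float(np.mean([g.score for g in samples])), rng)

    beta1, beta2, eps = 0.9, 0.999, 1e-8
    m = {k: np.zeros_like(v) for k, v in params.blocks().items()}
    v = {k: np.zeros_like(val) for k, val in params.blocks().items()}
    keep = 1.0 - cfg.dropout
    loss_history = []
    for epoch in range(cfg.epochs):
        if cfg.dropout > 0.0:
            masks = [(rng.random(params.W1.shape) < keep) / keep for _ in samples]
        else:
            masks = [None] * len(samples)
        loss, mse, grads = _loss_and_grads(params, samples, cfg, masks)
        if not np.isfinite(loss):
            raise DivergenceError(f"non-finite loss at epoch {epoch}")
        loss_history.append(mse)
        t = epoch + 1
        state = params.blocks()
        new = {}
        for key in state:
            gk = grads[key] if key != "fc_b" else np.array([grads["fc_b"]])
            m[key] = beta1 * m[key] + (1 - beta1) * gk
            v[key] = beta2 * v[key] + (1 - beta2) * gk**2
            m_hat = m[key] / (1 - beta1**t)
            v_hat = v[key] / (1 - beta2**t)
            new[key] = state[key] - cfg.learning_rate * m_hat / (np.sqrt(v_hat) + eps)
        params = RegGNNParameters(W1=new["W1"], W2=new["W2"], fc_w=new["fc_w"], fc_b=float(new["fc_b"][0]))
    return params, loss_history


def predict(params: RegGNNParameters, samples: list[PreprocessedGraph], cfg: RegGNNConfig) -> np.ndarray:
    """Evaluation-mode forward pass per sample, order preserved."""
    return np.array([forward(g, params, cfg, training_mode=False) for g in samples])


def region_weights(params: RegGNNParameters) -> list[tuple[int, float]]:
    """ROI indices ranked by descending absolute readout weight.

    The readout maps the d-dimensional graph embedding to the score, so the
    magnitude of its weights quantifies each region's influence on the
    prediction.  Ties are broken by ascending index.
    """
    w = np.abs(params.fc_w)
    order = sorted(range(w.size), key=lambda i: (-w[i], i))
    return [(i, float(w[i])) for i in order]


def average_region_ranking(params_list: list[RegGNNParameters]) -> list[tuple[int, float]]:
    """Rank ROIs by the mean absolute readout weight over several models.

    Used to aggregate the biomarker ranking across the models trained for
    the different values of ``k``.
    """
    if not params_list:
        raise ValidationError("need at least one parameter set")
    w = np.mean([np.abs(p.fc_w) for p in params_list], axis=0)
    order = sorted(range(w.size), key=lambda i: (-w[i], i))
    return [(i, float(w[i])) for i in order]


def save_parameters(params: RegGNNParameters, path) -> None:
    """Serialize parameters to a single portable ``.npz`` file."""
    np.savez(path, W1=params.W1, W2=params.W2, fc_w=params.fc_w, fc_b=np.array([params.fc_b]))


def load_parameters(path) -> RegGNNParameters:
    with np.load(path) as data:
        return RegGNNParameters(
            W1=data["W1"], W2=data["W2"], fc_w=data["fc_w"], fc_b=float(data["fc_b"][0])
        )
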