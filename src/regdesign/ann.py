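"""Single-hidden-layer backpropagation network for strength prediction.

Architecture: one-hot input (4 bits/base), one logistic hidden layer, one
logistic output neuron. Because the output lies in (0, 1) while strengths
can exceed 1, targets are normalized by the maximum training strength
before fitting and predictions are multiplied back by the same constant.

Training is full-batch gradient descent on the sum-squared error with a
momentum term and an adaptive learning rate: the rate grows by a constant
factor after an epoch that reduces the SSE, and shrinks (with the step
rejected and momentum reset) when the SSE grows beyond a tolerated ratio.
Training stops when the SSE on normalized targets reaches the goal or the
epoch budget is exhausted.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from regdesign.encoding import encode_library

__all__ = [
    "TrainingConfig",
    "TrainedModel",
    "logsig",
    "forward",
    "sse",
    "prediction_error",
    "sse_gradients",
    "train_network",
    "predict_strength",
    "save_model",
    "load_model",
]

_MODEL_FORMAT_VERSION = 1


@dataclass(frozen=True)
class TrainingConfig:
    """Hyperparameters of the gradient-descent trainer.

    Defaults follow the classic momentum + adaptive-learning-rate batch
    trainer: LR 0.01, growth 1.05, decay 0.7, tolerated SSE growth 1.04.
    """

    hidden_neurons: int = 19
    max_epochs: int = 5000
    sse_goal: float = 0.2
    momentum: float = 0.95
    initial_learning_rate: float = 0.01
    lr_increase_factor: float = 1.05
    lr_decrease_factor: float = 0.7
    max_perf_increase: float = 1.04
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hidden_neurons < 1:
            raise ValueError("hidden_neurons must be >= 1")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")
        if self.sse_goal <= 0:
            raise ValueError("sse_goal must be > 0")
        if not 0 <= self.momentum < 1:
            raise ValueError("momentum must lie in [0, 1)")
        if self.initial_learning_rate <= 0:
            raise ValueError("initial_learning_rate must be > 0")
        if self.lr_increase_factor <= 1:
            raise ValueError("lr_increase_factor must be > 1")
        if not 0 < self.lr_decrease_factor < 1:
            raise ValueError("lr_decrease_factor must lie in (0, 1)")
        if self.max_perf_increase <= 1:
            raise ValueError("max_perf_increase must be > 1")


@dataclass
class TrainedModel:
    """Weights, normalization constant and training trace of a fitted network."""

    hidden_weights: np.ndarray  # H x 4L
    hidden_bias: np.ndarray  # H
    output_weights: np.ndarray  # 1 x H
    output_bias: np.ndarray  # 1
    normalization_max: float
    config: TrainingConfig
    training_log: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.hidden_weights = np.atleast_2d(np.asarray(self.hidden_weights, float))
        self.hidden_bias = np.asarray(self.hidden_bias, float).ravel()
        self.output_weights = np.atleast_2d(np.asarray(self.output_weights, float))
        self.output_bias = np.asarray(self.output_bias, float).ravel()
        if self.normalization_max <= 0:
            raise ValueError("normalization_max must be > 0")

    @property
    def input_length(self) -> int:
        """Width of the input layer (4 bits per base)."""
        return self.hidden_weights.shape[1]

    @property
    def sequence_length(self) -> int:
        return self.input_length // 4

    @property
    def final_sse(self) -> float:
        """Last recorded training SSE (normalized-target scale)."""
        if not self.training_log:
            raise ValueError("model carries no training log")
        return self.training_log[-1]


def logsig(x):
    """Logistic sigmoid ``1 / (1 + exp(-x))``, numerically saturation-safe.

    Computed via a piecewise form so large |x| never overflows: exact 0/1
    saturation is replaced by the closest representable value.
    """
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    if out.ndim == 0:
        return float(out)
    return out


def forward(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    """Raw network outputs in (0, 1), one per row of ``X``."""
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[1] != model.input_length:
        raise ValueError(
            f"input width {X.shape[1]} does not match model input layer "
            f"width {model.input_length}"
        )
    hidden = logsig(X @ model.hidden_weights.T + model.hidden_bias)
    out = logsig(hidden @ model.output_weights.T + model.output_bias)
    return out.ravel()


def sse(pred, target) -> float:
    """Sum of squared prediction errors."""
    pred = np.asarray(pred, float).ravel()
    target = np.asarray(target, float).ravel()
    if pred.size == 0:
        raise ValueError("sse of empty vectors is undefined")
    if pred.size != target.size:
        raise ValueError(f"length mismatch: {pred.size} vs {target.size}")
    return float(np.sum((pred - target) ** 2))


def prediction_error(pred, target) -> float:
    """Mean absolute prediction error, sum(|pred - target|) / n."""
    pred = np.asarray(pred, float).ravel()
    target = np.asarray(target, float).ravel()
    if pred.size == 0:
        raise ValueError("prediction_error of empty vectors is undefined")
    if pred.size != target.size:
        raise ValueError(f"length mismatch: {pred.size} vs {target.size}")
    return float(np.mean(np.abs(pred - target)))


def _forward_parts(W1, b1, W2, b2, X):
    hidden = logsig(X @ W1.T + b1)
    out = logsig(hidden @ W2.T + b2).ravel()
    return hidden, out


def sse_gradients(W1, b1, W2, b2, X, t):
    """SSE and its analytic gradients w.r.t. all four parameter arrays.

    Backpropagation through the two logistic layers; exposed separately so
    the analytic gradient can be checked against finite differences.
    """
    X = np.atleast_2d(np.asarray(X, float))
    t = np.asarray(t, float).ravel()
    hidden, out = _forward_parts(W1, b1, W2, b2, X)
    resid = out - t
    loss = float(np.sum(resid**2))
    # output layer: d(loss)/d(z2) = 2 * resid * logsig'(z2)
    delta2 = (2.0 * resid * out * (1.0 - out))[:, None]  # n x 1
    gW2 = delta2.T @ hidden
    gb2 = delta2.sum(axis=0)
    delta1 = (delta2 @ W2) * hidden * (1.0 - hidden)  # n x H
    gW1 = delta1.T @ X
    gb1 = delta1.sum(axis=0)
    return loss, (gW1, gb1, gW2, gb2)


def train_network(X: np.ndarray, y, config: TrainingConfig) -> TrainedModel:
    """Fit the network to encoded sequences ``X`` and strengths ``y``.

    Targets are divided by ``max(y)`` before fitting; the constant is
    stored on the model so predictions return to the measurement scale.
    Fully deterministic given ``config.seed``.

    Raises
    ------
    ValueError
        If ``y`` is all zeros (no normalization constant), shapes disagree,
        or fewer than two training rows are supplied.
    RuntimeError
        If the loss becomes non-finite (the epoch index is reported).
    """
    X = np.atleast_2d(np.asarray(X, float))
    y = np.asarray(y, float).ravel()
    if X.shape[0] != y.size:
        raise ValueError(
            f"row mismatch: X has {X.shape[0]} rows, y has {y.size} values"
        )
    if X.shape[0] < 2:
        raise ValueError("training needs at least 2 rows")
    if np.any(y < 0):
        raise ValueError("strengths must be non-negative")
    y_max = float(np.max(y))
    if y_max <= 0:
        raise ValueError("all-zero strengths: normalization constant undefined")
    t = y / y_max

    H = config.hidden_neurons
    D = X.shape[1]
    rng = np.random.default_rng(config.seed)
    W1 = rng.uniform(-0.5, 0.5, size=(H, D))
    b1 = rng.uniform(-0.5, 0.5, size=H)
    W2 = rng.uniform(-0.5, 0.5, size=(1, H))
    b2 = rng.uniform(-0.5, 0.5, size=1)
    vW1 = np.zeros_like(W1)
    vb1 = np.zeros_like(b1)
    vW2 = np.zeros_like(W2)
    vb2 = np.zeros_like(b2)

    lr = config.initial_learning_rate
    mc = config.momentum
    perf, grads = sse_gradients(W1, b1, W2, b2, X, t)
    log = [perf]
    for epoch in range(config.max_epochs):
        if perf <= config.sse_goal:
            break
        gW1, gb1, gW2, gb2 = grads
        sW1 = mc * vW1 - lr * gW1
        sb1 = mc * vb1 - lr * gb1
        sW2 = mc * vW2 - lr * gW2
        sb2 = mc * vb2 - lr * gb2
        new_perf, new_grads = sse_gradients(
            W1 + sW1, b1 + sb1, W2 + sW2, b2 + sb2, X, t
        )
        if not np.isfinite(new_perf):
            raise RuntimeError(f"non-finite training loss at epoch {epoch + 1}")
        if new_perf > perf * config.max_perf_increase:
            # reject the step, cool the learning rate, drop momentum memory
            lr *= config.lr_decrease_factor
            vW1[:] = 0.0
            vb1[:] = 0.0
            vW2[:] = 0.0
            vb2[:] = 0.0
        else:
            W1 += sW1
            b1 += sb1
            W2 += sW2
            b2 += sb2
            vW1, vb1, vW2, vb2 = sW1, sb1, sW2, sb2
            if new_perf < perf:
                lr *= config.lr_increase_factor
            perf, grads = new_perf, new_grads
        log.append(perf)

    return TrainedModel(
        hidden_weights=W1,
        hidden_bias=b1,
        output_weights=W2,
        output_bias=b2,
        normalization_max=y_max,
        config=config,
        training_log=log,
    )


def predict_strength(model: TrainedModel, seqs) -> np.ndarray:
    """Denormalized strength predictions for sequences or an encoded matrix.

    Accepts a single sequence string, a list of sequences, or an already
    encoded n x 4L matrix. Every prediction lies in (0, normalization_max).
    """
    if isinstance(seqs, str):
        seqs = [seqs]
    if isinstance(seqs, np.ndarray) and seqs.dtype != object:
        X = np.atleast_2d(seqs)
    else:
        lengths = {len(s) for s in seqs}
        if lengths != {model.sequence_length}:
            raise ValueError(
                f"model was trained on {model.sequence_length}-nt sequences, "
                f"got lengths {sorted(lengths)}"
            )
        X = encode_library(list(seqs))
    return forward(model, X) * model.normalization_max


# -- serialization ---------------------------------------------------------


def save_model(model: TrainedModel, path) -> None:
    """Serialize a model to version-tagged JSON."""
    payload = {
        "format_version": _MODEL_FORMAT_VERSION,
        "input_length": model.input_length,
        "hidden_weights": model.hidden_weights.tolist(),
        "hidden_bias": model.hidden_bias.tolist(),
        "output_weights": model.output_weights.tolist(),
        "output_bias": model.output_bias.tolist(),
        "normalization_max": model.normalization_max,
        "config": asdict(model.config),
        "training_log": list(map(float, model.training_log)),
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path) -> TrainedModel:
    """Load a model serialized by :func:`save_model`."""
    payload = json.loads(Path(path).read_text())
    version = payload.get("format_version")
    if version != _MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model format version: {version!r}")
    model = TrainedModel(
        hidden_weights=payload["hidden_weights"],
        hidden_bias=payload["hidden_bias"],
        output_weights=payload["output_weights"],
        output_bias=payload["output_bias"],
        normalization_max=payload["normalization_max"],
        config=TrainingConfig(**payload["config"]),
        training_log=payload["training_log"],
    )
    if model.input_length != payload["input_length"]:
        raise ValueError("model file is inconsistent: input_length mismatch")
    return model
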