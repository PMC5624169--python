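"""Stacked autoencoders for dimensionality reduction of dysphonia features.

A single autoencoder maps an input x0 in R^d0 to a hidden code
x1 = sigmoid(W1' x0 + b1) in R^d1 and back to a reconstruction
x2 = sigmoid(W2' x1 + b2), trained by mini-batch gradient descent on

    L(x0, x2) = mean((x0 - x2)^2) + 0.5 * eps * (||W1||^2 + ||W2||^2),

i.e. mean squared reconstruction error plus L2 weight decay.  A stack is
trained greedily: the first autoencoder on the (min-max scaled) inputs, each
subsequent one on its predecessor's hidden codes; afterwards the whole stack
is fine-tuned — by default as the unrolled deep autoencoder minimising
end-to-end reconstruction, optionally supervised with a softmax head on the
class labels.  The final hidden layer is the reduced representation handed to
the downstream classifier.

Two surfaces are provided: a functional core (:func:`train_autoencoder`,
:func:`stack_train`, :func:`transform`, ...) operating on plain arrays and a
scikit-learn compatible :class:`StackedAutoencoder` transformer wrapping it.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

__all__ = [
    "AutoencoderParams",
    "SAEConfig",
    "SAEModel",
    "StackedAutoencoder",
    "encode",
    "decode",
    "loss",
    "train_autoencoder",
    "stack_train",
    "transform",
    "reconstruct",
]


@dataclass
class AutoencoderParams:
    """One autoencoder's parameters: W1 (d0 x d1), b1, W2 (d1 x d0), b2."""

    W1: np.ndarray
    b1: np.ndarray
    W2: np.ndarray
    b2: np.ndarray
    loss_history: list[float] = field(default_factory=list, compare=False)

    def __post_init__(self) -> None:
        self.W1 = np.asarray(self.W1, dtype=np.float64)
        self.b1 = np.asarray(self.b1, dtype=np.float64)
        self.W2 = np.asarray(self.W2, dtype=np.float64)
        self.b2 = np.asarray(self.b2, dtype=np.float64)
        d0, d1 = self.W1.shape
        if self.b1.shape != (d1,) or self.W2.shape != (d1, d0) or self.b2.shape != (d0,):
            raise ValueError("inconsistent autoencoder parameter shapes")
        for arr in (self.W1, self.b1, self.W2, self.b2):
            if not np.all(np.isfinite(arr)):
                raise ValueError("autoencoder parameters must be finite")

    @property
    def input_dim(self) -> int:
        return self.W1.shape[0]

    @property
    def hidden_dim(self) -> int:
        return self.W1.shape[1]


@dataclass(frozen=True)
class SAEConfig:
    """Stack architecture and training hyper-parameters.

    ``layer_sizes`` are the hidden widths of the successive stages;
    ``l2_eps`` the weight-decay coefficient; batch size 20 and sigmoid
    activations throughout.  ``finetune`` selects the global objective:
    ``"reconstruction"`` (unsupervised, default), ``"supervised"`` (softmax
    head on labels) or ``"none"``.
    """

    layer_sizes: tuple[int, ...] = (9, 7)
    l2_eps: float = 1e-3
    learning_rate: float = 1.0
    epochs_pretrain: int = 400
    epochs_finetune: int = 400
    batch_size: int = 20
    finetune: str = "reconstruction"
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.layer_sizes) == 0 or any(s < 1 for s in self.layer_sizes):
            raise ValueError("layer_sizes must be non-empty with every size >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.l2_eps < 0:
            raise ValueError("l2_eps must be >= 0")
        if self.finetune not in ("reconstruction", "supervised", "none"):
            raise ValueError(f"unknown finetune mode {self.finetune!r}")
        object.__setattr__(self, "layer_sizes", tuple(int(s) for s in self.layer_sizes))


@dataclass
class SAEModel:
    """A trained stack: per-stage parameters plus the input scaler.

    ``scaler_min``/``scaler_range`` hold the training-set min-max statistics
    (range 1 where a feature was constant); they are part of the model so
    that transform-time inputs are scaled exactly as the training data was.
    """

    stages: list[AutoencoderParams]
    input_dim: int
    fine_tuned: bool
    config: SAEConfig
    scaler_min: np.ndarray | None = None
    scaler_range: np.ndarray | None = None
    finetune_loss_history: list[float] = field(default_factory=list, compare=False)

    def __post_init__(self) -> None:
        dim = self.input_dim
        for k, stage in enumerate(self.stages):
            if stage.input_dim != dim:
                raise ValueError(f"stage {k} expects input dim {stage.input_dim}, got {dim}")
            dim = stage.hidden_dim

    @property
    def output_dim(self) -> int:
        return self.stages[-1].hidden_dim

    def to_dict(self) -> dict:
        return {
            "input_dim": self.input_dim,
            "fine_tuned": self.fine_tuned,
            "config": dataclasses.asdict(self.config),
            "scaler_min": None if self.scaler_min is None else self.scaler_min.tolist(),
            "scaler_range": None if self.scaler_range is None else self.scaler_range.tolist(),
            "stages": [
                {
                    "W1": s.W1.tolist(),
                    "b1": s.b1.tolist(),
                    "W2": s.W2.tolist(),
                    "b2": s.b2.tolist(),
                }
                for s in self.stages
            ],
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "SAEModel":
        cfg = dict(payload["config"])
        cfg["layer_sizes"] = tuple(cfg["layer_sizes"])
        return cls(
            stages=[
                AutoencoderParams(
                    W1=np.array(s["W1"]),
                    b1=np.array(s["b1"]),
                    W2=np.array(s["W2"]),
                    b2=np.array(s["b2"]),
                )
                for s in payload["stages"]
            ],
            input_dim=int(payload["input_dim"]),
            fine_tuned=bool(payload["fine_tuned"]),
            config=SAEConfig(**cfg),
            scaler_min=None if payload["scaler_min"] is None else np.array(payload["scaler_min"]),
            scaler_range=None
            if payload["scaler_range"] is None
            else np.array(payload["scaler_range"]),
        )


# ---------------------------------------------------------------------------
# functional core


def encode(params: AutoencoderParams, x0: np.ndarray) -> np.ndarray:
    """Hidden code sigmoid(W1' x0 + b1) for a vector or a row matrix."""
    x0 = np.asarray(x0, dtype=np.float64)
    if x0.shape[-1] != params.input_dim:
        raise ValueError(f"expected input dim {params.input_dim}, got {x0.shape[-1]}")
    return expit(x0 @ params.W1 + params.b1)


def decode(params: AutoencoderParams, x1: np.ndarray) -> np.ndarray:
    """Reconstruction sigmoid(W2' x1 + b2)."""
    x1 = np.asarray(x1, dtype=np.float64)
    if x1.shape[-1] != params.hidden_dim:
        raise ValueError(f"expected hidden dim {params.hidden_dim}, got {x1.shape[-1]}")
    return expit(x1 @ params.W2 + params.b2)


def loss(params: AutoencoderParams, x0: np.ndarray, x2: np.ndarray, l2_eps: float) -> float:
    """Mean squared reconstruction error plus 0.5*eps*(||W1||^2 + ||W2||^2)."""
    x0 = np.asarray(x0, dtype=np.float64)
    x2 = np.asarray(x2, dtype=np.float64)
    if x0.shape != x2.shape:
        raise ValueError("x0 and x2 must have identical shapes")
    reg = 0.5 * l2_eps * (np.sum(params.W1**2) + np.sum(params.W2**2))
    return float(np.mean((x0 - x2) ** 2) + reg)


def _init_weights(d_in: int, d_out: int, rng: np.random.Generator) -> np.ndarray:
    limit = 4.0 * np.sqrt(6.0 / (d_in + d_out))
    return rng.uniform(-limit, limit, size=(d_in, d_out))


def _ae_loss_and_grads(
    params: AutoencoderParams, batch: np.ndarray, l2_eps: float
) -> tuple[float, dict[str, np.ndarray]]:
    """Backprop through one autoencoder on one batch (MSE + L2 objective)."""
    n, d0 = batch.shape
    h = expit(batch @ params.W1 + params.b1)
    x2 = expit(h @ params.W2 + params.b2)
    diff = x2 - batch
    value = float(np.mean(diff**2)) + 0.5 * l2_eps * (
        np.sum(params.W1**2) + np.sum(params.W2**2)
    )
    dz2 = (2.0 / (n * d0)) * diff * x2 * (1.0 - x2)
    dh = dz2 @ params.W2.T
    dz1 = dh * h * (1.0 - h)
    grads = {
        "W2": h.T @ dz2 + l2_eps * params.W2,
        "b2": dz2.sum(axis=0),
        "W1": batch.T @ dz1 + l2_eps * params.W1,
        "b1": dz1.sum(axis=0),
    }
    return value, grads


def train_autoencoder(
    data: np.ndarray,
    d1: int,
    config: SAEConfig,
    rng: np.random.Generator | None = None,
) -> AutoencoderParams:
    """Pretrain one autoencoder stage by mini-batch SGD.

    ``data`` rows are expected on the [0, 1] scale (the decoder output is
    sigmoid-bounded).  Records the full-data loss once per epoch in
    ``loss_history``.  Deterministic given the RNG state.
    """
    data = np.asarray(data, dtype=np.float64)
    if data.ndim != 2 or data.shape[0] < 1:
        raise ValueError("data must be a non-empty 2-D matrix")
    if d1 < 1:
        raise ValueError("hidden size must be >= 1")
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    d0 = data.shape[1]
    params = AutoencoderParams(
        W1=_init_weights(d0, d1, rng),
        b1=np.zeros(d1),
        W2=_init_weights(d1, d0, rng),
        b2=np.zeros(d0),
    )
    n = data.shape[0]
    for _ in range(config.epochs_pretrain):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            batch = data[order[start : start + config.batch_size]]
            value, grads = _ae_loss_and_grads(params, batch, config.l2_eps)
            if not np.isfinite(value):
                raise FloatingPointError(
                    f"non-finite training loss {value}; lower the learning rate"
                    f" (currently {config.learning_rate})"
                )
            params.W1 -= config.learning_rate * grads["W1"]
            params.b1 -= config.learning_rate * grads["b1"]
            params.W2 -= config.learning_rate * grads["W2"]
            params.b2 -= config.learning_rate * grads["b2"]
        epoch_loss, _ = _ae_loss_and_grads(params, data, config.l2_eps)
        params.loss_history.append(epoch_loss)
    return params


def _forward_unrolled(stages: list[AutoencoderParams], x: np.ndarray) -> list[np.ndarray]:
    """Activations through enc_1..enc_k, dec_k..dec_1 of the unrolled stack."""
    acts = [x]
    for stage in stages:
        acts.append(expit(acts[-1] @ stage.W1 + stage.b1))
    for stage in reversed(stages):
        acts.append(expit(acts[-1] @ stage.W2 + stage.b2))
    return acts


def _finetune_reconstruction(
    stages: list[AutoencoderParams],
    data: np.ndarray,
    config: SAEConfig,
    rng: np.random.Generator,
) -> list[float]:
    """End-to-end reconstruction fine-tuning of the unrolled deep autoencoder."""
    n, d0 = data.shape
    k = len(stages)
    weights = [(s, "W1", "b1") for s in stages] + [
        (s, "W2", "b2") for s in reversed(stages)
    ]
    history: list[float] = []
    l2 = config.l2_eps

    def step(batch: np.ndarray, update: bool) -> float:
        acts = _forward_unrolled(stages, batch)
        diff = acts[-1] - batch
        reg = 0.5 * l2 * sum(np.sum(s.W1**2) + np.sum(s.W2**2) for s in stages)
        value = float(np.mean(diff**2)) + reg
        if not update:
            return value
        if not np.isfinite(value):
            raise FloatingPointError("non-finite fine-tuning loss; lower the learning rate")
        delta = (2.0 / (batch.shape[0] * d0)) * diff
        for layer in range(2 * k - 1, -1, -1):
            out = acts[layer + 1]
            dz = delta * out * (1.0 - out)
            stage, w_name, b_name = weights[layer]
            w = getattr(stage, w_name)
            gw = acts[layer].T @ dz + l2 * w
            gb = dz.sum(axis=0)
            delta = dz @ w.T
            setattr(stage, w_name, w - config.learning_rate * gw)
            setattr(stage, b_name, getattr(stage, b_name) - config.learning_rate * gb)
        return value

    for _ in range(config.epochs_finetune):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            step(data[order[start : start + config.batch_size]], update=True)
        history.append(step(data, update=False))
    return history


def _finetune_supervised(
    stages: list[AutoencoderParams],
    data: np.ndarray,
    labels: np.ndarray,
    config: SAEConfig,
    rng: np.random.Generator,
) -> list[float]:
    """Supervised fine-tuning: encoder stack + softmax head, cross-entropy."""
    classes = np.unique(labels)
    y = np.searchsorted(classes, labels)
    n_classes = classes.size
    d_top = stages[-1].hidden_dim
    head_w = _init_weights(d_top, n_classes, rng)
    head_b = np.zeros(n_classes)
    n = data.shape[0]
    l2 = config.l2_eps
    history: list[float] = []

    def forward(batch: np.ndarray) -> list[np.ndarray]:
        acts = [batch]
        for stage in stages:
            acts.append(expit(acts[-1] @ stage.W1 + stage.b1))
        return acts

    def step(batch: np.ndarray, target: np.ndarray, update: bool) -> float:
        nonlocal head_w, head_b
        acts = forward(batch)
        logits = acts[-1] @ head_w + head_b
        logits -= logits.max(axis=1, keepdims=True)
        p = np.exp(logits)
        p /= p.sum(axis=1, keepdims=True)
        m = batch.shape[0]
        value = float(-np.mean(np.log(p[np.arange(m), target] + 1e-12)))
        value += 0.5 * l2 * (sum(np.sum(s.W1**2) for s in stages) + np.sum(head_w**2))
        if not update:
            return value
        if not np.isfinite(value):
            raise FloatingPointError("non-finite fine-tuning loss; lower the learning rate")
        dlogits = p.copy()
        dlogits[np.arange(m), target] -= 1.0
        dlogits /= m
        gw = acts[-1].T @ dlogits + l2 * head_w
        gb = dlogits.sum(axis=0)
        delta = dlogits @ head_w.T
        head_w = head_w - config.learning_rate * gw
        head_b = head_b - config.learning_rate * gb
        for layer in range(len(stages) - 1, -1, -1):
            out = acts[layer + 1]
            dz = delta * out * (1.0 - out)
            stage = stages[layer]
            gw1 = acts[layer].T @ dz + l2 * stage.W1
            gb1 = dz.sum(axis=0)
            delta = dz @ stage.W1.T
            stage.W1 = stage.W1 - config.learning_rate * gw1
            stage.b1 = stage.b1 - config.learning_rate * gb1
        return value

    for _ in range(config.epochs_finetune):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            step(data[idx], y[idx], update=True)
        history.append(step(data, y, update=False))
    return history


def stack_train(
    data: np.ndarray,
    config: SAEConfig,
    labels: np.ndarray | None = None,
    scale: bool = True,
) -> SAEModel:
    """Greedy layer-wise pretraining followed by fine-tuning.

    Stage 1 trains on the (optionally min-max scaled) inputs; every later
    stage on the previous stage's hidden codes.  ``labels`` are only needed
    for supervised fine-tuning.  A single seeded RNG drives initialisation
    and batch order, so the result is a pure function of (data, config).
    """
    data = np.asarray(data, dtype=np.float64)
    if data.ndim != 2 or data.shape[0] < 2:
        raise ValueError("stack_train needs a 2-D matrix with at least 2 rows")
    rng = np.random.default_rng(config.seed)

    if scale:
        lo = data.min(axis=0)
        rng_span = data.max(axis=0) - lo
        rng_span = np.where(rng_span == 0, 1.0, rng_span)
        scaled = (data - lo) / rng_span
        scaler_min, scaler_range = lo, rng_span
    else:
        scaled = data
        scaler_min = scaler_range = None

    stages: list[AutoencoderParams] = []
    hidden = scaled
    for d1 in config.layer_sizes:
        params = train_autoencoder(hidden, d1, config, rng=rng)
        stages.append(params)
        hidden = encode(params, hidden)

    history: list[float] = []
    fine_tuned = False
    if config.finetune != "none" and config.epochs_finetune > 0:
        if config.finetune == "supervised":
            if labels is None:
                raise ValueError("supervised fine-tuning requires labels")
            history = _finetune_supervised(stages, scaled, np.asarray(labels), config, rng)
        else:
            history = _finetune_reconstruction(stages, scaled, config, rng)
        fine_tuned = True

    return SAEModel(
        stages=stages,
        input_dim=data.shape[1],
        fine_tuned=fine_tuned,
        config=config,
        scaler_min=scaler_min,
        scaler_range=scaler_range,
        finetune_loss_history=history,
    )


def _apply_scaler(model: SAEModel, data: np.ndarray) -> np.ndarray:
    if model.scaler_min is None:
        return data
    return (data - model.scaler_min) / model.scaler_range


def transform(model: SAEModel, data: np.ndarray) -> np.ndarray:
    """Reduced representation: every stage encoder applied in order."""
    data = np.asarray(data, dtype=np.float64)
    squeeze = data.ndim == 1
    data = np.atleast_2d(data)
    if data.shape[1] != model.input_dim:
        raise ValueError(f"expected {model.input_dim} feature columns, got {data.shape[1]}")
    hidden = _apply_scaler(model, data)
    for stage in model.stages:
        hidden = encode(stage, hidden)
    return hidden[0] if squeeze else hidden


def reconstruct(model: SAEModel, data: np.ndarray) -> np.ndarray:
    """Round trip through the unrolled stack (on the scaled feature space)."""
    data = np.atleast_2d(np.asarray(data, dtype=np.float64))
    return _forward_unrolled(model.stages, _apply_scaler(model, data))[-1]


# ---------------------------------------------------------------------------
# scikit-learn transformer


class StackedAutoencoder(TransformerMixin, BaseEstimator):
    """Scikit-learn wrapper around the stacked-autoencoder core.

    Parameters mirror :class:`SAEConfig`; ``scale=True`` min-max scales each
    feature to [0, 1] on the training set (required by the sigmoid decoder)
    and remembers the statistics for transform time.

    Attributes set by :meth:`fit`: ``model_`` (the :class:`SAEModel`),
    ``stages_``, ``loss_history_`` (per-stage pretraining and fine-tuning
    loss curves) and ``n_features_in_``.
    """

    def __init__(
        self,
        layer_sizes: tuple[int, ...] = (9, 7),
        l2_eps: float = 1e-3,
        learning_rate: float = 1.0,
        epochs_pretrain: int = 400,
        epochs_finetune: int = 400,
        batch_size: int = 20,
        finetune: str = "reconstruction",
        scale: bool = True,
        random_state: int = 0,
    ) -> None:
        self.layer_sizes = layer_sizes
        self.l2_eps = l2_eps
        self.learning_rate = learning_rate
        self.epochs_pretrain = epochs_pretrain
        self.epochs_finetune = epochs_finetune
        self.batch_size = batch_size
        self.finetune = finetune
        self.scale = scale
        self.random_state = random_state

    def _config(self) -> SAEConfig:
        return SAEConfig(
            layer_sizes=tuple(self.layer_sizes),
            l2_eps=self.l2_eps,
            learning_rate=self.learning_rate,
            epochs_pretrain=self.epochs_pretrain,
            epochs_finetune=self.epochs_finetune,
            batch_size=self.batch_size,
            finetune=self.finetune,
            seed=self.random_state,
        )

    def fit(self, X, y=None) -> "StackedAutoencoder":
        X = check_array(X, dtype=np.float64)
        self.model_ = stack_train(X, self._config(), labels=y, scale=self.scale)
        self.stages_ = self.model_.stages
        self.loss_history_ = {
            f"stage_{k}": list(stage.loss_history) for k, stage in enumerate(self.stages_)
        }
        self.loss_history_["finetune"] = list(self.model_.finetune_loss_history)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        X = check_array(X, dtype=np.float64)
        return transform(self.model_, X)
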