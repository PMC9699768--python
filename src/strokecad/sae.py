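"""Stacked autoencoder (SAE) classifier with metaheuristic refinement.

Training follows the classical two-phase recipe: greedy layerwise
pretraining (each encoder trained, unsupervised, to reconstruct the
previous layer's codes under squared error), then a K-way softmax head is
appended and the whole network is fine-tuned end to end on cross-entropy
by full-batch gradient descent.

On top of the gradient solution, the satin bowerbird optimizer can refine
the *entire* flat weight/bias vector inside a trust region centered on
the current parameters, with classification error rate on a held-out
tuning split as the fitness.  Because the current parameters are injected
into the initial population and the optimizer is elitist, the refined
model is never worse on the tuning split than its input.  Direct weight
search is only tractable for small networks, so the flat dimension is
capped (default 5000); for larger models the dragonfly-based
hyperparameter tuner searches architecture/learning-rate space instead.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping

import numpy as np

from .errors import CapabilityError, InputError
from .optim import Bounds, DFOConfig, SBOConfig, fitness_error_rate, idfo_run, sbo_run

SCHEMA_VERSION = 1
DEFAULT_WEIGHT_CAP = 5000


@dataclass(frozen=True)
class SAEArchitecture:
    """Network shape and training budget.

    ``layer_sizes`` runs input -> hidden_1 -> ... -> hidden_L (the head is
    separate); all sizes strictly positive, ``head_classes`` >= 2.
    """

    layer_sizes: tuple[int, ...]
    head_classes: int
    activation: str = "sigmoid"
    pretrain_epochs: int = 200
    finetune_epochs: int = 300
    learning_rate: float = 0.2

    def __post_init__(self) -> None:
        if any(int(s) != s or s <= 0 for s in self.layer_sizes):
            raise InputError("layer_sizes must be strictly positive integers")
        if len(self.layer_sizes) < 1:
            raise InputError("layer_sizes must at least contain the input size")
        if self.head_classes < 2:
            raise InputError("head_classes must be >= 2")
        if self.activation not in ("sigmoid", "relu"):
            raise InputError("activation must be 'sigmoid' or 'relu'")
        object.__setattr__(self, "layer_sizes", tuple(int(s) for s in self.layer_sizes))


def _act(z: np.ndarray, kind: str) -> np.ndarray:
    if kind == "sigmoid":
        return 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))
    return np.maximum(z, 0.0)


def _act_grad(h: np.ndarray, kind: str) -> np.ndarray:
    # expressed in terms of the activation output
    if kind == "sigmoid":
        return h * (1.0 - h)
    return (h > 0).astype(float)


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


@dataclass
class SAEModel:
    """Encoder stack plus (after fine-tuning) a softmax head."""

    architecture: SAEArchitecture
    encoder_weights: list[np.ndarray]
    encoder_biases: list[np.ndarray]
    head_weights: np.ndarray | None = None
    head_biases: np.ndarray | None = None
    finetune_loss_trace: list[float] = field(default_factory=list)
    # optional input standardization fitted on training data; not part of
    # the flat trainable-parameter vector
    input_mean: np.ndarray | None = None
    input_sd: np.ndarray | None = None

    # -- flat parameter view (the vector SBO searches) ------------------
    def flatten(self) -> np.ndarray:
        parts = []
        for W, b in zip(self.encoder_weights, self.encoder_biases):
            parts.extend([W.ravel(), b.ravel()])
        if self.head_weights is not None:
            parts.extend([self.head_weights.ravel(), self.head_biases.ravel()])
        return np.concatenate(parts) if parts else np.empty(0)

    def unflatten(self, flat: np.ndarray) -> "SAEModel":
        """Reshape a flat vector back into a model (lossless round-trip)."""
        flat = np.asarray(flat, dtype=float)
        expected = self.flatten().size
        if flat.size != expected:
            raise InputError(f"flat vector length {flat.size} != parameter count {expected}")
        out = copy.deepcopy(self)
        pos = 0

        def take(shape):
            nonlocal pos
            size = int(np.prod(shape))
            chunk = flat[pos : pos + size].reshape(shape)
            pos += size
            return chunk.copy()

        ws, bs = [], []
        for W, b in zip(self.encoder_weights, self.encoder_biases):
            ws.append(take(W.shape))
            bs.append(take(b.shape))
        out.encoder_weights, out.encoder_biases = ws, bs
        if self.head_weights is not None:
            out.head_weights = take(self.head_weights.shape)
            out.head_biases = take(self.head_biases.shape)
        return out

    # -- inference ------------------------------------------------------
    def encode(self, X: np.ndarray) -> np.ndarray:
        h = np.asarray(X, dtype=float)
        if h.ndim != 2 or h.shape[1] != self.architecture.layer_sizes[0]:
            raise InputError(
                f"feature dimension {h.shape} does not match input size "
                f"{self.architecture.layer_sizes[0]}"
            )
        if self.input_mean is not None:
            h = (h - self.input_mean) / self.input_sd
        for W, b in zip(self.encoder_weights, self.encoder_biases):
            h = _act(h @ W + b, self.architecture.activation)
        return h

    def scores(self, X: np.ndarray) -> np.ndarray:
        if self.head_weights is None:
            raise InputError("model has no classification head; run fine_tune first")
        return self.encode(X) @ self.head_weights + self.head_biases

    # -- serialization ---------------------------------------------------
    def to_json(self, path: str | Path | None = None) -> str:
        arch = self.architecture
        payload = {
            "schema_version": SCHEMA_VERSION,
            "architecture": {
                "layer_sizes": list(arch.layer_sizes),
                "head_classes": arch.head_classes,
                "activation": arch.activation,
                "pretrain_epochs": arch.pretrain_epochs,
                "finetune_epochs": arch.finetune_epochs,
                "learning_rate": arch.learning_rate,
            },
            "has_head": self.head_weights is not None,
            "flat_parameters": [float(v) for v in self.flatten()],
            "input_mean": None if self.input_mean is None else [float(v) for v in self.input_mean],
            "input_sd": None if self.input_sd is None else [float(v) for v in self.input_sd],
        }
        text = json.dumps(payload)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "SAEModel":
        text = str(source)
        if not text.lstrip().startswith("{"):
            text = Path(source).read_text()
        payload = json.loads(text)
        if payload.get("schema_version") != SCHEMA_VERSION:
            raise InputError(f"unsupported model schema version {payload.get('schema_version')}")
        arch = SAEArchitecture(**payload["architecture"])
        model = _initialize(arch, seed=0)
        if payload["has_head"]:
            model = _attach_head(model, seed=0)
        model = model.unflatten(np.asarray(payload["flat_parameters"]))
        if payload.get("input_mean") is not None:
            model.input_mean = np.asarray(payload["input_mean"], dtype=float)
            model.input_sd = np.asarray(payload["input_sd"], dtype=float)
        return model


def _initialize(arch: SAEArchitecture, seed: int) -> SAEModel:
    rng = np.random.default_rng(seed)
    ws, bs = [], []
    sizes = arch.layer_sizes
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        ws.append(_glorot(rng, fan_in, fan_out))
        bs.append(np.zeros(fan_out))
    return SAEModel(architecture=arch, encoder_weights=ws, encoder_biases=bs)


def _attach_head(model: SAEModel, seed: int) -> SAEModel:
    rng = np.random.default_rng(seed)
    out = copy.deepcopy(model)
    fan_in = out.architecture.layer_sizes[-1]
    K = out.architecture.head_classes
    out.head_weights = _glorot(rng, fan_in, K)
    out.head_biases = np.zeros(K)
    return out


def pretrain(features: np.ndarray, arch: SAEArchitecture, seed: int = 0) -> SAEModel:
    """Greedy layerwise unsupervised pretraining.

    Each encoder layer, together with a throwaway linear decoder, is
    trained by full-batch gradient descent to reconstruct the previous
    layer's codes under mean squared error; labels are never used.  With
    ``pretrain_epochs == 0`` the model equals its seeded initialization.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise InputError("pretraining requires a 2-D feature matrix with >= 2 samples")
    if not np.all(np.isfinite(X)):
        raise InputError("features contain non-finite values")
    if X.shape[1] != arch.layer_sizes[0]:
        raise InputError(
            f"feature dimension {X.shape[1]} != architecture input {arch.layer_sizes[0]}"
        )
    model = _initialize(arch, seed)
    rng = np.random.default_rng(seed + 1)
    codes = X
    lr = arch.learning_rate
    for li, (W, b) in enumerate(zip(model.encoder_weights, model.encoder_biases)):
        in_dim = W.shape[0]
        W_dec = _glorot(rng, W.shape[1], in_dim)
        b_dec = np.zeros(in_dim)
        n = codes.shape[0]
        for _ in range(arch.pretrain_epochs):
            h = _act(codes @ W + b, arch.activation)
            recon = h @ W_dec + b_dec
            err = recon - codes  # (n, in_dim)
            # d MSE/d recon = 2 err / (n * in_dim)
            g_recon = 2.0 * err / (n * in_dim)
            g_Wdec = h.T @ g_recon
            g_bdec = g_recon.sum(axis=0)
            g_h = g_recon @ W_dec.T * _act_grad(h, arch.activation)
            g_W = codes.T @ g_h
            g_b = g_h.sum(axis=0)
            W -= lr * g_W
            b -= lr * g_b
            W_dec -= lr * g_Wdec
            b_dec -= lr * g_bdec
        codes = _act(codes @ W + b, arch.activation)
    return model


def reconstruction_error(features: np.ndarray, arch: SAEArchitecture, model: SAEModel,
                         decoder: tuple[np.ndarray, np.ndarray] | None = None) -> float:
    """Single-layer reconstruction MSE after retraining a fresh linear
    decoder on top of the first encoder layer (diagnostic helper)."""
    X = np.asarray(features, dtype=float)
    h = _act(X @ model.encoder_weights[0] + model.encoder_biases[0], arch.activation)
    # least-squares linear decoder: the best achievable linear readout
    H = np.hstack([h, np.ones((h.shape[0], 1))])
    coef, *_ = np.linalg.lstsq(H, X, rcond=None)
    recon = H @ coef
    return float(np.mean((recon - X) ** 2))


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def fine_tune(model: SAEModel, features: np.ndarray, labels: np.ndarray, seed: int = 0) -> SAEModel:
    """Append a softmax head and fine-tune end to end on cross-entropy.

    Full-batch gradient descent for ``finetune_epochs``; the loss trace is
    stored on the returned model.  With zero epochs only the head
    initialization changes.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    arch = model.architecture
    K = arch.head_classes
    if y.min(initial=0) < 0 or y.max(initial=0) >= K:
        raise InputError(f"labels must lie in 0..{K - 1}")
    out = _attach_head(model, seed)
    n = X.shape[0]
    Y = np.zeros((n, K))
    Y[np.arange(n), y] = 1.0
    lr = arch.learning_rate
    kind = arch.activation
    out.finetune_loss_trace = []
    for _ in range(arch.finetune_epochs):
        # forward, keeping activations
        hs = [X]
        h = X
        for W, b in zip(out.encoder_weights, out.encoder_biases):
            h = _act(h @ W + b, kind)
            hs.append(h)
        logits = h @ out.head_weights + out.head_biases
        probs = _softmax(logits)
        loss = -np.mean(np.log(np.clip(probs[np.arange(n), y], 1e-300, None)))
        out.finetune_loss_trace.append(float(loss))
        # backward
        g_logits = (probs - Y) / n
        g_Wh = h.T @ g_logits
        g_bh = g_logits.sum(axis=0)
        g_h = g_logits @ out.head_weights.T
        for li in range(len(out.encoder_weights) - 1, -1, -1):
            g_z = g_h * _act_grad(hs[li + 1], kind)
            g_W = hs[li].T @ g_z
            g_b = g_z.sum(axis=0)
            g_h = g_z @ out.encoder_weights[li].T
            out.encoder_weights[li] -= lr * g_W
            out.encoder_biases[li] -= lr * g_b
        out.head_weights -= lr * g_Wh
        out.head_biases -= lr * g_bh
    return out


def predict(model: SAEModel, features: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Predicted labels (argmax of head scores, ties toward the smaller
    class index) and the softmax class scores."""
    scores = _softmax(model.scores(features))
    return np.argmax(scores, axis=1), scores


def _stratified_split(y: np.ndarray, test_fraction: float, rng: np.random.Generator):
    test_idx = []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        k = max(1, int(round(test_fraction * idx.size)))
        test_idx.extend(idx[:k])
    test_mask = np.zeros(y.size, dtype=bool)
    test_mask[test_idx] = True
    return ~test_mask, test_mask


def sbo_optimize(
    model: SAEModel,
    features: np.ndarray,
    labels: np.ndarray,
    sbo_config: SBOConfig | None = None,
    trust_radius: float = 0.5,
    tune_fraction: float = 0.2,
    weight_cap: int = DEFAULT_WEIGHT_CAP,
) -> SAEModel:
    """Refine the full flat weight/bias vector with the bowerbird optimizer.

    The search box is ``current parameters +/- trust_radius``; fitness is
    the classification error rate on a held-out tuning split (stratified
    ``tune_fraction`` of the given data).  The input parameters seed the
    initial population, so elitism guarantees the returned model's tuning
    error never exceeds the input model's.  With zero iterations the input
    model is returned unchanged.
    """
    cfg = sbo_config or SBOConfig(n=20, iterations=30)
    if cfg.iterations == 0:
        return model
    flat = model.flatten()
    if flat.size > weight_cap:
        raise CapabilityError(
            f"flat parameter dimension {flat.size} exceeds the direct-weight-search cap "
            f"{weight_cap}; use a smaller architecture or hyperparameter mode "
            f"(idfo_tune_hyperparams)"
        )
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    rng = np.random.default_rng(cfg.seed)
    _, tune_mask = _stratified_split(y, tune_fraction, rng)
    X_tune, y_tune = X[tune_mask], y[tune_mask]

    def objective(vec: np.ndarray) -> float:
        candidate = model.unflatten(vec)
        pred, _ = predict(candidate, X_tune)
        return fitness_error_rate(pred, y_tune)

    bounds = Bounds(flat - trust_radius, flat + trust_radius)
    cfg = copy.copy(cfg)
    cfg.initial_positions = flat[None, :]
    history = sbo_run(objective, bounds, cfg)
    return model.unflatten(history.best_position)


@dataclass(frozen=True)
class HyperRange:
    lo: float
    hi: float
    integer: bool = False


def decode_hyperparams(space: Mapping[str, HyperRange], vector: np.ndarray,
                       free_names: list[str], fixed: Mapping[str, float]) -> dict[str, float]:
    decoded = dict(fixed)
    for name, value in zip(free_names, vector):
        decoded[name] = value
    return {
        name: int(round(v)) if space[name].integer else float(v)
        for name, v in decoded.items()
    }


def idfo_tune_hyperparams(
    search_space: Mapping[str, HyperRange],
    evaluate: Callable[[dict], float],
    config: DFOConfig | None = None,
) -> tuple[dict, "object"]:
    """Search named continuous hyperparameter ranges with the dragonfly
    optimizer; integer-valued entries are decoded by rounding.

    ``evaluate`` maps a decoded hyperparameter dict to a validation error.
    Degenerate (single-point) dimensions are held fixed; an all-fixed
    space returns that point without running the optimizer.
    """
    if not search_space:
        raise InputError("search space must not be empty")
    fixed = {k: (int(r.lo) if r.integer else r.lo) for k, r in search_space.items() if r.lo == r.hi}
    free = [k for k in search_space if k not in fixed]
    if not free:
        params = decode_hyperparams(search_space, np.empty(0), [], fixed)
        return params, None
    bounds = Bounds(
        np.array([search_space[k].lo for k in free]),
        np.array([search_space[k].hi for k in free]),
    )

    def objective(vec: np.ndarray) -> float:
        return float(evaluate(decode_hyperparams(search_space, vec, free, fixed)))

    cfg = config or DFOConfig(n=10, iterations=20)
    history = idfo_run(objective, bounds, cfg)
    best = decode_hyperparams(search_space, history.best_position, free, fixed)
    return best, history


def make_sae_objective(
    train_features: np.ndarray,
    train_labels: np.ndarray,
    val_features: np.ndarray,
    val_labels: np.ndarray,
    base_arch: SAEArchitecture,
    seed: int = 0,
) -> Callable[[dict], float]:
    """Validation-error objective for hyperparameter tuning.

    Recognized keys: ``learning_rate``, ``hidden1``, ``hidden2``,
    ``pretrain_epochs``, ``finetune_epochs``; unspecified ones keep the
    base architecture's values.
    """

    def evaluate(params: dict) -> float:
        hidden = [int(params.get("hidden1", base_arch.layer_sizes[1] if len(base_arch.layer_sizes) > 1 else 16))]
        if "hidden2" in params or len(base_arch.layer_sizes) > 2:
            hidden.append(int(params.get("hidden2", base_arch.layer_sizes[2] if len(base_arch.layer_sizes) > 2 else 8)))
        arch = SAEArchitecture(
            layer_sizes=(base_arch.layer_sizes[0], *hidden),
            head_classes=base_arch.head_classes,
            activation=base_arch.activation,
            pretrain_epochs=int(params.get("pretrain_epochs", base_arch.pretrain_epochs)),
            finetune_epochs=int(params.get("finetune_epochs", base_arch.finetune_epochs)),
            learning_rate=float(params.get("learning_rate", base_arch.learning_rate)),
        )
        model = pretrain(train_features, arch, seed=seed)
        model = fine_tune(model, train_features, train_labels, seed=seed)
        pred, _ = predict(model, val_features)
        return fitness_error_rate(pred, val_labels)

    return evaluate
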