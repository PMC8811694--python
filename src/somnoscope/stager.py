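"""A small template-guided convolutional sleep stager.

Architecture: one 1-D convolution layer whose first filters are initialized
from (refined) clinical template kernels and optionally frozen, followed by
a rectifier, temporal average pooling, two dense layers and a 5-way softmax
over the AASM stages.  This is the smallest network that exposes the three
explanation sources the decision-support layer consumes:

* the template filters themselves,
* pre-nonlinearity activation traces of each template filter, and
* input-gradient saliency maps of the class scores.

Everything is plain numpy: the convolution runs in the FFT domain and the
gradients (for training and for saliency) are computed analytically.  With a
fixed seed, training is bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .synthetic import STAGES, EpochSignal
from .templates import TemplateFilter, ValidationError

__all__ = [
    "StagerConfig",
    "StagePrediction",
    "ActivationTrace",
    "SaliencyMap",
    "StagerModel",
    "TrainingHistory",
    "build_model",
    "train_model",
    "predict_epoch",
    "compute_activation",
    "compute_saliency",
    "save_model",
    "load_model",
]


@dataclass
class StagerConfig:
    n_template_filters: int = 7
    n_free_filters: int = 8
    kernel_len: int = 100
    pool_len: int = 100
    hidden: int = 32
    input_len: int = 3000
    learning_rate: float = 1e-3
    train_epochs: int = 30
    batch_size: int = 64
    freeze_templates: bool = True
    balance_classes: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_template_filters < 0 or self.n_free_filters < 0:
            raise ValidationError("filter counts must be >= 0")
        if self.input_len % self.pool_len != 0:
            raise ValidationError("input_len must be a multiple of pool_len")

    @property
    def n_filters(self) -> int:
        return self.n_template_filters + self.n_free_filters

    @property
    def n_bins(self) -> int:
        return self.input_len // self.pool_len


@dataclass(frozen=True)
class StagePrediction:
    probabilities: np.ndarray  # 5-vector over STAGES
    predicted_stage: str


@dataclass(frozen=True)
class ActivationTrace:
    """Pre-nonlinearity first-layer convolution of one template filter,
    mapped 1:1 onto input samples ('same' alignment, stride 1, zero pad)."""

    values: np.ndarray
    filter_pattern: str
    alignment: dict = field(
        default_factory=lambda: {"padding": "same", "stride": 1, "center_offset": 0}
    )


@dataclass(frozen=True)
class SaliencyMap:
    """Absolute input-gradient of one class's pre-softmax score."""

    values: np.ndarray
    target_stage: str


@dataclass
class TrainingHistory:
    loss: list = field(default_factory=list)
    val_macro_f1: list = field(default_factory=list)
    best_epoch: int = -1
    best_val_macro_f1: float = float("nan")


class StagerModel:
    """Parameter container; functional forward/backward live at module level."""

    def __init__(self, config: StagerConfig, template_patterns: list[str]):
        self.config = config
        self.template_patterns = list(template_patterns)
        K, F, H = config.kernel_len, config.n_filters, config.hidden
        self.conv_w = np.zeros((F, K))
        self.conv_b = np.zeros(F)
        self.w1 = np.zeros((H, F * config.n_bins))
        self.b1 = np.zeros(H)
        self.w2 = np.zeros((5, H))
        self.b2 = np.zeros(5)

    def parameters(self) -> dict[str, np.ndarray]:
        return {
            "conv_w": self.conv_w,
            "conv_b": self.conv_b,
            "w1": self.w1,
            "b1": self.b1,
            "w2": self.w2,
            "b2": self.b2,
        }

    def template_index(self, pattern: str) -> int:
        if pattern not in self.template_patterns:
            raise ValidationError(
                f"pattern {pattern!r} not among model template filters {self.template_patterns}"
            )
        return self.template_patterns.index(pattern)

    def copy_weights(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.parameters().items()}

    def load_weights(self, weights: dict[str, np.ndarray]) -> None:
        for k, v in weights.items():
            getattr(self, k)[...] = v


# ---------------------------------------------------------------------------
# FFT cross-correlation ("same" alignment, stride 1, zero padding)

def _pad_offsets(kernel_len: int) -> tuple[int, int]:
    left = (kernel_len - 1) // 2
    return left, kernel_len - 1 - left


def _fft_len(n: int) -> int:
    from scipy.fft import next_fast_len

    return next_fast_len(n)


def conv_same_batch(x: np.ndarray, kernels: np.ndarray) -> np.ndarray:
    """Cross-correlate each row of ``x`` (B, N) with each kernel (F, K).

    Returns (B, F, N) with a[b, f, i] = sum_k w[f, k] * x[b, i + k - c],
    c = (K - 1) // 2, zero padding outside the signal.
    """
    B, N = x.shape
    F, K = kernels.shape
    left, right = _pad_offsets(K)
    xp = np.pad(x, ((0, 0), (left, right)))
    M = _fft_len(N + K - 1)
    X = np.fft.rfft(xp, n=M)  # (B, Mf)
    W = np.fft.rfft(kernels, n=M)  # (F, Mf)
    out = np.fft.irfft(X[:, None, :] * np.conj(W)[None, :, :], n=M)
    return out[..., :N]


def _conv_backward_w(x: np.ndarray, grad_a: np.ndarray, kernel_len: int) -> np.ndarray:
    """d loss / d kernels given grad on the pre-activations (B, F, N)."""
    B, N = x.shape
    left, right = _pad_offsets(kernel_len)
    xp = np.pad(x, ((0, 0), (left, right)))
    M = _fft_len(N + kernel_len - 1)
    X = np.fft.rfft(xp, n=M)  # (B, Mf)
    G = np.fft.rfft(grad_a, n=M)  # (B, F, Mf)
    prod = (X[:, None, :] * np.conj(G)).sum(axis=0)  # (F, Mf)
    return np.fft.irfft(prod, n=M)[:, :kernel_len]


def _conv_backward_x(grad_a: np.ndarray, kernels: np.ndarray, n_in: int) -> np.ndarray:
    """d loss / d input given grad on the pre-activations (B, F, N)."""
    F, K = kernels.shape
    left, _ = _pad_offsets(K)
    M = _fft_len(n_in + K - 1)
    G = np.fft.rfft(grad_a, n=M)  # (B, F, Mf)
    W = np.fft.rfft(kernels, n=M)  # (F, Mf)
    full = np.fft.irfft((G * W[None]).sum(axis=1), n=M)  # (B, n_in + K - 1)
    return full[:, left : left + n_in]


# ---------------------------------------------------------------------------
# Forward / backward

def _standardize(x: np.ndarray) -> np.ndarray:
    mean = x.mean(axis=-1, keepdims=True)
    sd = x.std(axis=-1, keepdims=True)
    return (x - mean) / np.where(sd > 0, sd, 1.0)


def _forward(model: StagerModel, x: np.ndarray) -> dict:
    """x: standardized batch (B, N).  Returns the cache used by backward."""
    cfg = model.config
    a = conv_same_batch(x, model.conv_w) + model.conv_b[None, :, None]
    h = np.maximum(a, 0.0)
    B = x.shape[0]
    pooled = h.reshape(B, cfg.n_filters, cfg.n_bins, cfg.pool_len).mean(axis=-1)
    feat = pooled.reshape(B, -1)
    z1 = feat @ model.w1.T + model.b1
    r1 = np.maximum(z1, 0.0)
    scores = r1 @ model.w2.T + model.b2
    shifted = scores - scores.max(axis=1, keepdims=True)
    expv = np.exp(shifted)
    probs = expv / expv.sum(axis=1, keepdims=True)
    return {"x": x, "a": a, "feat": feat, "z1": z1, "r1": r1, "scores": scores, "probs": probs}


def _backward(
    model: StagerModel, cache: dict, grad_scores: np.ndarray, need_input_grad: bool = False
) -> dict:
    cfg = model.config
    x, a, feat, z1, r1 = cache["x"], cache["a"], cache["feat"], cache["z1"], cache["r1"]
    B, N = x.shape
    grads: dict[str, np.ndarray] = {}
    grads["w2"] = grad_scores.T @ r1
    grads["b2"] = grad_scores.sum(axis=0)
    dz1 = (grad_scores @ model.w2) * (z1 > 0)
    grads["w1"] = dz1.T @ feat
    grads["b1"] = dz1.sum(axis=0)
    dfeat = dz1 @ model.w1  # (B, F * n_bins)
    dpool = dfeat.reshape(B, cfg.n_filters, cfg.n_bins)
    da = np.repeat(dpool / cfg.pool_len, cfg.pool_len, axis=2) * (a > 0)
    grads["conv_b"] = da.sum(axis=(0, 2))
    grads["conv_w"] = _conv_backward_w(x, da, cfg.kernel_len)
    if need_input_grad:
        grads["x"] = _conv_backward_x(da, model.conv_w, N)
    return grads


# ---------------------------------------------------------------------------
# Public operations

def build_model(
    config: StagerConfig, templates: list[TemplateFilter] | None = None
) -> StagerModel:
    """Initialize the stager; template-designated filters are copied bitwise
    from the supplied kernels, the rest are random from ``config.seed``."""
    templates = templates or []
    if len(templates) > config.n_template_filters:
        raise ValidationError(
            f"{len(templates)} templates supplied but config allows {config.n_template_filters}"
        )
    for tmpl in templates:
        if len(tmpl) != config.kernel_len:
            raise ValidationError(
                f"template {tmpl.pattern!r} has length {len(tmpl)}; config.kernel_len={config.kernel_len}"
            )
    model = StagerModel(config, [t.pattern for t in templates])
    rng = np.random.default_rng(config.seed)
    K = config.kernel_len
    model.conv_w[...] = rng.normal(0, 1.0 / np.sqrt(K), size=model.conv_w.shape)
    for i, tmpl in enumerate(templates):
        model.conv_w[i] = tmpl.kernel
    fan_in = config.n_filters * config.n_bins
    model.w1[...] = rng.normal(0, np.sqrt(2.0 / fan_in), size=model.w1.shape)
    model.w2[...] = rng.normal(0, np.sqrt(2.0 / config.hidden), size=model.w2.shape)
    return model


def _epochs_to_matrix(epochs: list[tuple[EpochSignal, str]], input_len: int) -> tuple[np.ndarray, np.ndarray]:
    xs, ys = [], []
    for epoch, stage in epochs:
        if epoch.signal.size != input_len:
            raise ValidationError(
                f"epoch length {epoch.signal.size} != model input length {input_len}"
            )
        if stage not in STAGES:
            raise ValidationError(f"unknown stage label {stage!r}")
        xs.append(epoch.signal)
        ys.append(STAGES.index(stage))
    return np.asarray(xs, dtype=float), np.asarray(ys, dtype=int)


def _macro_f1_int(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    from sklearn.metrics import f1_score

    labels = np.unique(y_true)
    return float(f1_score(y_true, y_pred, labels=labels, average="macro", zero_division=0))


def train_model(
    model: StagerModel,
    train_epochs: list[tuple[EpochSignal, str]],
    val_epochs: list[tuple[EpochSignal, str]],
    config: StagerConfig | None = None,
) -> tuple[StagerModel, TrainingHistory]:
    """Adam + cross-entropy training; returns the checkpoint with the best
    validation macro-F1.  Deterministic given the config seed."""
    config = config or model.config
    history = TrainingHistory()
    if config.train_epochs == 0:
        return model, history
    if not train_epochs or not val_epochs:
        raise ValidationError("training and validation sets must be non-empty")
    x_train, y_train = _epochs_to_matrix(train_epochs, config.input_len)
    x_val, y_val = _epochs_to_matrix(val_epochs, config.input_len)
    if np.unique(y_train).size < 2:
        raise ValidationError("training set contains a single class; nothing to learn")
    x_train = _standardize(x_train)
    x_val = _standardize(x_val)

    rng = np.random.default_rng(config.seed + 1)
    n = x_train.shape[0]
    if config.balance_classes:
        counts = np.bincount(y_train, minlength=5).astype(float)
        weights = np.where(counts[y_train] > 0, 1.0 / counts[y_train], 0.0)
        weights = weights / weights.sum()
    else:
        weights = np.full(n, 1.0 / n)

    frozen_rows = len(model.template_patterns) if config.freeze_templates else 0
    adam_m = {k: np.zeros_like(v) for k, v in model.parameters().items()}
    adam_v = {k: np.zeros_like(v) for k, v in model.parameters().items()}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0
    best_weights = model.copy_weights()
    best_f1 = -np.inf
    n_batches = max(1, n // config.batch_size)

    for epoch_i in range(config.train_epochs):
        epoch_loss = 0.0
        for _ in range(n_batches):
            idx = rng.choice(n, size=config.batch_size, p=weights)
            xb, yb = x_train[idx], y_train[idx]
            cache = _forward(model, xb)
            probs = cache["probs"]
            B = xb.shape[0]
            epoch_loss += float(-np.log(probs[np.arange(B), yb] + 1e-12).mean())
            grad_scores = probs.copy()
            grad_scores[np.arange(B), yb] -= 1.0
            grad_scores /= B
            grads = _backward(model, cache, grad_scores)
            if frozen_rows:
                grads["conv_w"][:frozen_rows] = 0.0
            step += 1
            for key, param in model.parameters().items():
                g = grads[key]
                adam_m[key] = beta1 * adam_m[key] + (1 - beta1) * g
                adam_v[key] = beta2 * adam_v[key] + (1 - beta2) * g * g
                m_hat = adam_m[key] / (1 - beta1**step)
                v_hat = adam_v[key] / (1 - beta2**step)
                param -= config.learning_rate * m_hat / (np.sqrt(v_hat) + eps)
        val_pred = _forward(model, x_val)["probs"].argmax(axis=1)
        val_f1 = _macro_f1_int(y_val, val_pred)
        history.loss.append(epoch_loss / n_batches)
        history.val_macro_f1.append(val_f1)
        if val_f1 > best_f1:
            best_f1 = val_f1
            best_weights = model.copy_weights()
            history.best_epoch = epoch_i
    model.load_weights(best_weights)
    history.best_val_macro_f1 = float(best_f1)
    return model, history


def predict_epoch(model: StagerModel, epoch: EpochSignal) -> StagePrediction:
    """Stage probabilities for one epoch; ties broken in W<N1<N2<N3<REM order."""
    if epoch.signal.size != model.config.input_len:
        raise ValidationError(
            f"epoch length {epoch.signal.size} != model input length {model.config.input_len}"
        )
    x = _standardize(epoch.signal[None, :])
    probs = _forward(model, x)["probs"][0]
    return StagePrediction(probabilities=probs, predicted_stage=STAGES[int(np.argmax(probs))])


def compute_activation(
    model: StagerModel, epoch: EpochSignal, filter_pattern: str
) -> ActivationTrace:
    """Pre-nonlinearity trace of one template filter, on input coordinates.

    The convolution is applied to the signal exactly as given (no
    standardization), so the trace is linear in the input up to the bias.
    """
    idx = model.template_index(filter_pattern)
    values = conv_same_batch(epoch.signal[None, :], model.conv_w[idx : idx + 1])[0, 0]
    values = values + model.conv_b[idx]
    left, _ = _pad_offsets(model.config.kernel_len)
    return ActivationTrace(
        values=values,
        filter_pattern=filter_pattern,
        alignment={"padding": "same", "stride": 1, "center_offset": left},
    )


def compute_saliency(
    model: StagerModel, epoch: EpochSignal, target_stage: str = "predicted"
) -> SaliencyMap:
    """|d score(target) / d input sample| on the standardized input."""
    if target_stage == "predicted":
        target_stage = predict_epoch(model, epoch).predicted_stage
    if target_stage not in STAGES:
        raise ValidationError(f"unknown target stage {target_stage!r}")
    if epoch.signal.size != model.config.input_len:
        raise ValidationError("epoch length does not match the model input length")
    x = _standardize(epoch.signal[None, :])
    cache = _forward(model, x)
    grad_scores = np.zeros((1, 5))
    grad_scores[0, STAGES.index(target_stage)] = 1.0
    grads = _backward(model, cache, grad_scores, need_input_grad=True)
    return SaliencyMap(values=np.abs(grads["x"][0]), target_stage=target_stage)


def target_score(model: StagerModel, x_std: np.ndarray, target_stage: str) -> float:
    """Pre-softmax score of one stage for an already-standardized input.

    Exposed so the saliency gradient can be checked against finite
    differences on exactly the quantity it differentiates.
    """
    return float(_forward(model, x_std[None, :])["scores"][0, STAGES.index(target_stage)])


# ---------------------------------------------------------------------------
# Checkpoints: one .npz holding config + weights + template bank

def save_model(model: StagerModel, path) -> None:
    meta = {
        "config": asdict(model.config),
        "template_patterns": model.template_patterns,
    }
    np.savez(
        path,
        meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
        **model.parameters(),
    )


def load_model(path) -> StagerModel:
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta"].tobytes()).decode())
        model = StagerModel(StagerConfig(**meta["config"]), meta["template_patterns"])
        model.load_weights({k: data[k] for k in model.parameters()})
    return model
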