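"""Training of the normalizer-free classifier: AGC, Adam, early stopping.

Adaptive gradient clipping (AGC) rescales each unit's gradient whenever
its Frobenius norm exceeds λ times the unit's weight norm (with a floor
ε on the weight norm to escape zero initializations):

    G_i <- λ · max(‖W_i‖_F, ε) / ‖G_i‖_F · G_i   if ‖G_i‖_F / max(‖W_i‖_F, ε) > λ

Units are rows of a weight matrix / output channels of a convolution;
1D parameters (biases, gains) are clipped per element.  Defaults
λ = 0.04, ε = 1e-3.  Optimization is Adam at learning rate 1e-4 with a
weighted cross-entropy loss (inverse class frequency) and early
stopping on validation loss with patience 20; the best-validation
weights are restored.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from .model import NFNet1d

__all__ = [
    "TrainConfig",
    "AttentionMap",
    "agc_clip",
    "class_weights",
    "weighted_cross_entropy",
    "Adam",
    "train_model",
    "predict_epochs",
    "extract_attention",
    "attention_allocation",
]

F32 = np.float32


@dataclass(frozen=True)
class TrainConfig:
    lr: float = 1e-4
    batch_size: int = 32
    patience: int = 20
    max_epochs: int = 200
    agc_lambda: float = 0.04
    agc_eps: float = 1e-3
    seed: int = 42
    val_fraction: float = 0.2

    def __post_init__(self) -> None:
        if self.lr < 0:
            raise ValueError("learning rate must be >= 0")
        if min(self.batch_size, self.patience, self.max_epochs,
               self.agc_lambda, self.agc_eps, self.val_fraction) <= 0:
            raise ValueError("training hyperparameters must be positive")


@dataclass
class AttentionMap:
    """Head-averaged temporal attention of one epoch (sums to 1)."""

    weights: np.ndarray  # (n_tokens,)
    subject_id: str = ""
    epoch_index: int = 0

    def upsampled(self, length: int = 2560) -> np.ndarray:
        """Nearest-neighbour projection onto the raw sample axis (for overlays)."""
        factor = int(np.ceil(length / self.weights.size))
        return np.repeat(self.weights, factor)[:length]


def agc_clip(grad: np.ndarray, weight: np.ndarray, lam: float = 0.04, eps: float = 1e-3) -> np.ndarray:
    """Unit-wise adaptive gradient clipping; never increases a unit's norm."""
    g = np.asarray(grad, dtype=float)
    w = np.asarray(weight, dtype=float)
    if g.shape != w.shape:
        raise ValueError("gradient and weight shapes differ")
    if g.ndim <= 1:
        gn = np.abs(g)
        wn = np.maximum(np.abs(w), eps)
    else:
        flat_g = g.reshape(g.shape[0], -1)
        flat_w = w.reshape(w.shape[0], -1)
        gn = np.linalg.norm(flat_g, axis=1).reshape((-1,) + (1,) * (g.ndim - 1))
        wn = np.maximum(np.linalg.norm(flat_w, axis=1), eps).reshape(gn.shape)
    scale = np.where(gn > lam * wn, lam * wn / np.maximum(gn, 1e-30), 1.0)
    return g * scale


def class_weights(counts: dict | np.ndarray) -> np.ndarray:
    """Inverse-frequency weights w_c = N / (K · n_c); mean ≈ 1."""
    n = np.asarray(list(counts.values()) if isinstance(counts, dict) else counts, dtype=float)
    if np.any(n <= 0):
        raise ValueError("every class needs a positive count")
    return n.sum() / (n.size * n)


def weighted_cross_entropy(
    logits: np.ndarray, labels: np.ndarray, weights: np.ndarray | None = None
) -> tuple[float, np.ndarray]:
    """Mean weighted CE loss and its gradient w.r.t. the logits.

    Normalized by the sum of the per-sample weights, so with uniform
    weights (a balanced set under inverse-frequency weighting) the loss
    reduces exactly to the unweighted mean cross-entropy.
    """
    logits = np.asarray(logits, dtype=float)
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=1, keepdims=True)
    n, k = p.shape
    w = np.ones(k) if weights is None else np.asarray(weights, dtype=float)
    sample_w = w[labels]
    nll = -np.log(np.maximum(p[np.arange(n), labels], 1e-12))
    denom = sample_w.sum()
    loss = float((sample_w * nll).sum() / denom)
    grad = p.copy()
    grad[np.arange(n), labels] -= 1.0
    grad *= (sample_w / denom)[:, None]
    return loss, grad


class Adam:
    def __init__(self, params, lr: float = 1e-4, betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8) -> None:
        self.params = list(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]
        self.t = 0

    def step(self, agc_lambda: float | None = 0.04, agc_eps: float = 1e-3) -> None:
        """One update; AGC is applied to every parameter's gradient first."""
        self.t += 1
        b1, b2 = self.betas
        for i, p in enumerate(self.params):
            g = p.grad
            if agc_lambda is not None:
                g = agc_clip(g, p.value, agc_lambda, agc_eps).astype(F32)
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p.value -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(F32)


def train_model(
    model: NFNet1d,
    train_x: np.ndarray,
    train_y: np.ndarray,
    val_x: np.ndarray,
    val_y: np.ndarray,
    config: TrainConfig | None = None,
    train_subjects: list[str] | None = None,
    val_subjects: list[str] | None = None,
    loss_weights: np.ndarray | None = None,
) -> dict:
    """Train with Adam + AGC, weighted CE and early stopping.

    ``train_subjects`` / ``val_subjects`` carry epoch provenance; if both
    are given, any subject present in both sets raises (leakage guard).
    ``loss_weights`` fixes the cross-entropy class weights; when omitted
    they are inverse frequencies of the training labels.  Under LOSO the
    caller should pass cohort-level weights held constant across folds:
    per-fold weights over-compensate the class the held-out subject was
    removed from and bias every fold toward the test subject's own class.
    Returns a history dict; the model is left holding the weights of the
    best-validation-loss epoch.
    """
    config = config or TrainConfig()
    if train_subjects is not None and val_subjects is not None:
        overlap = set(train_subjects) & set(val_subjects)
        if overlap:
            raise ValueError(f"subject leakage between train and validation: {sorted(overlap)}")
    train_x = train_x.astype(F32, copy=False)
    val_x = val_x.astype(F32, copy=False)
    train_y = np.asarray(train_y)
    val_y = np.asarray(val_y)

    if loss_weights is None:
        counts = np.bincount(train_y, minlength=model.config.n_classes)
        weights = class_weights(np.maximum(counts, 1))
    else:
        weights = np.asarray(loss_weights, dtype=float)
    opt = Adam(model.params(), lr=config.lr)
    rng = np.random.default_rng(config.seed)

    best_loss, best_state, best_epoch = np.inf, model.state(), 0
    since_improve = 0
    history = {"train_loss": [], "val_loss": []}

    for ep in range(1, config.max_epochs + 1):
        order = rng.permutation(train_x.shape[0])
        ep_loss, n_batches = 0.0, 0
        for start in range(0, order.size, config.batch_size):
            idx = order[start : start + config.batch_size]
            model.zero_grad()
            logits = model.forward(train_x[idx], training=True)
            loss, grad = weighted_cross_entropy(logits, train_y[idx], weights)
            model.backward(grad.astype(F32))
            opt.step(config.agc_lambda, config.agc_eps)
            ep_loss += loss
            n_batches += 1
        val_loss = _eval_loss(model, val_x, val_y, weights, config.batch_size)
        history["train_loss"].append(ep_loss / max(n_batches, 1))
        history["val_loss"].append(val_loss)
        if val_loss < best_loss:
            best_loss, best_state, best_epoch = val_loss, model.state(), ep
            since_improve = 0
        else:
            since_improve += 1
            if since_improve >= config.patience:
                break

    model.load_state(best_state)
    history["best_epoch"] = best_epoch
    history["best_val_loss"] = best_loss
    history["n_epochs"] = len(history["val_loss"])
    return history


def _eval_loss(model: NFNet1d, x: np.ndarray, y: np.ndarray, weights: np.ndarray, batch: int) -> float:
    total, wsum = 0.0, 0.0
    for start in range(0, x.shape[0], batch):
        sl = slice(start, start + batch)
        logits = model.forward(x[sl], training=False)
        loss, _ = weighted_cross_entropy(logits, y[sl], weights)
        w = weights[y[sl]].sum()
        total += loss * w
        wsum += w
    return total / max(wsum, 1e-12)


def save_history_tsv(history: dict, path) -> None:
    """Write the per-epoch loss history as a tab-separated table."""
    lines = ["epoch\ttrain_loss\tval_loss"]
    for i, (tr, vl) in enumerate(zip(history["train_loss"], history["val_loss"]), start=1):
        lines.append(f"{i}\t{tr:.6f}\t{vl:.6f}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def predict_epochs(model: NFNet1d, x: np.ndarray, batch_size: int = 32) -> np.ndarray:
    """Per-epoch softmax class probabilities (rows sum to 1)."""
    x = x.astype(F32, copy=False)
    out = []
    for start in range(0, x.shape[0], batch_size):
        logits = model.forward(x[start : start + batch_size], training=False)
        z = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(z)
        out.append(e / e.sum(axis=1, keepdims=True))
    return np.vstack(out)


def extract_attention(model: NFNet1d, epoch: np.ndarray, subject_id: str = "", epoch_index: int = 0) -> AttentionMap:
    """Head-averaged temporal attention for one epoch (model must have MHSA)."""
    if model.attn is None:
        raise ValueError(f"variant {model.config.variant!r} has no attention module")
    x = np.asarray(epoch, dtype=F32)
    if x.ndim == 2:
        x = x[None]
    model.forward(x, training=False)
    weights = model.attn.pooled_attention()[0]
    return AttentionMap(weights=weights, subject_id=subject_id, epoch_index=epoch_index)


def attention_allocation(att: AttentionMap, fused_values: np.ndarray, target_rows) -> float:
    """Share of attention mass attributable to the target fused rows.

    At each time step the attention weight is attributed to the target
    rows in proportion to their share of the total row activity
    (the |r| mass) at that step; the score is the attention-weighted mean
    attribution, in [0, 1].  Steps with zero total activity contribute 0.
    """
    target_rows = sorted(set(int(r) for r in target_rows))
    if not target_rows:
        raise ValueError("empty target row set")
    n_rows, t = fused_values.shape
    if any(r < 0 or r >= n_rows for r in target_rows):
        raise ValueError("target rows out of range")
    a = att.upsampled(t).astype(float)
    a = a / a.sum()
    total = np.abs(fused_values).sum(axis=0)
    target = np.abs(fused_values[target_rows]).sum(axis=0)
    share = np.divide(target, total, out=np.zeros(t), where=total > 0)
    return float((a * share).sum())
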