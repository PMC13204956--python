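"""The normalizer-free 1D convolutional classifier with self-attention.

Architecture (variant ``proposed``)::

    stem conv (k=15, s=2) -> ReLU
    -> NF-ResBlocks (1x1 projection shortcut + two k=7 convs, ReLU)
    -> max-pool (s=4)
    -> multi-head self-attention (4 heads, embed 64)
    -> global average pooling -> dropout (p=0.5) -> linear logits

No normalization layer appears anywhere in the proposed variant;
training stability is delegated to adaptive gradient clipping.  Two
ablation variants are provided: ``conv_bn`` swaps the residual blocks
for plain conv–batch-norm–ReLU stacks, and ``nfnet_no_attn`` drops the
attention module.  A 10 s epoch at 256 Hz (2560 samples) maps to 320
attention tokens (2560 / 2 / 4).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from .layers import (
    MHSA,
    BatchNorm1d,
    Conv1d,
    Dropout,
    GlobalAvgPool,
    Layer,
    Linear,
    MaxPool1d,
    Param,
    ReLU,
    Sequential,
)

__all__ = ["ModelConfig", "NFResBlock", "NFNet1d", "build_model"]

VARIANTS = ("proposed", "conv_bn", "nfnet_no_attn")


@dataclass(frozen=True)
class ModelConfig:
    in_channels: int = 8
    stem_width: int = 32
    stem_kernel: int = 15
    stem_stride: int = 2
    block_kernel: int = 7
    block_widths: tuple[int, ...] = (32, 64, 64)
    pool_stride: int = 4
    attn_heads: int = 4
    attn_embed: int = 64
    dropout: float = 0.5
    n_classes: int = 2
    variant: str = "proposed"

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        if any(w <= 0 for w in (self.stem_width, *self.block_widths)):
            raise ValueError("widths must be positive")
        if self.attn_embed % self.attn_heads:
            raise ValueError("attention embedding must be divisible by the head count")


class NFResBlock(Layer):
    """Normalizer-free residual block.

    out = relu( proj_1x1(x) + conv_k(relu(conv_k(x))) ) with no
    normalization anywhere; the 1x1 projection always carries the
    shortcut so width changes are uniform.
    """

    def __init__(self, cin: int, cout: int, kernel: int, rng: np.random.Generator, name: str) -> None:
        self.proj = Conv1d(cin, cout, 1, rng=rng, name=f"{name}.proj")
        self.conv1 = Conv1d(cin, cout, kernel, rng=rng, name=f"{name}.conv1")
        self.relu1 = ReLU()
        self.conv2 = Conv1d(cout, cout, kernel, rng=rng, name=f"{name}.conv2")
        self.relu_out = ReLU()

    def params(self) -> list[Param]:
        return self.proj.params() + self.conv1.params() + self.conv2.params()

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        shortcut = self.proj.forward(x, training)
        h = self.conv2.forward(self.relu1.forward(self.conv1.forward(x, training), training), training)
        return self.relu_out.forward(shortcut + h, training)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        g = self.relu_out.backward(grad)
        g_main = self.conv1.backward(self.relu1.backward(self.conv2.backward(g)))
        g_short = self.proj.backward(g)
        return g_main + g_short


class NFNet1d:
    """The full classifier; forward maps (B, C_in, T) -> (B, n_classes) logits."""

    def __init__(self, config: ModelConfig, seed: int = 42) -> None:
        self.config = config
        rng = np.random.default_rng(seed)
        self.dropout_rng = np.random.default_rng(rng.integers(2**31))
        c = config

        stem = [Conv1d(c.in_channels, c.stem_width, c.stem_kernel, stride=c.stem_stride, rng=rng, name="stem"), ReLU()]
        blocks: list[Layer] = []
        cin = c.stem_width
        for i, w in enumerate(c.block_widths):
            if c.variant == "conv_bn":
                blocks += [
                    Conv1d(cin, w, c.block_kernel, rng=rng, name=f"block{i}.conv1"),
                    BatchNorm1d(w, name=f"block{i}.bn1"),
                    ReLU(),
                    Conv1d(w, w, c.block_kernel, rng=rng, name=f"block{i}.conv2"),
                    BatchNorm1d(w, name=f"block{i}.bn2"),
                    ReLU(),
                ]
            else:
                blocks.append(NFResBlock(cin, w, c.block_kernel, rng, name=f"block{i}"))
            cin = w
        self.backbone = Sequential(*stem, *blocks, MaxPool1d(c.pool_stride))

        self.attn: MHSA | None = None
        head_in = cin
        if c.variant != "nfnet_no_attn":
            self.attn = MHSA(cin, c.attn_embed, c.attn_heads, rng=rng, name="mhsa")
            head_in = c.attn_embed
        self.head = Sequential(GlobalAvgPool(), Dropout(c.dropout, self.dropout_rng), Linear(head_in, c.n_classes, rng=rng, name="head"))

    # -- introspection ----------------------------------------------------

    def iter_layers(self):
        def walk(layer):
            if isinstance(layer, Sequential):
                for sub in layer.layers:
                    yield from walk(sub)
            elif isinstance(layer, NFResBlock):
                yield layer
                for sub in (layer.proj, layer.conv1, layer.relu1, layer.conv2, layer.relu_out):
                    yield from walk(sub)
            else:
                yield layer

        yield from walk(self.backbone)
        if self.attn is not None:
            yield self.attn
        yield from walk(self.head)

    def params(self) -> list[Param]:
        out = self.backbone.params()
        if self.attn is not None:
            out += self.attn.params()
        return out + self.head.params()

    def n_parameters(self) -> int:
        return sum(p.value.size for p in self.params())

    # -- compute ----------------------------------------------------------

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        h = self.backbone.forward(x, training)
        if self.attn is not None:
            h = self.attn.forward(h, training)
        return self.head.forward(h, training)

    def backward(self, grad_logits: np.ndarray) -> None:
        g = self.head.backward(grad_logits)
        if self.attn is not None:
            g = self.attn.backward(g)
        self.backbone.backward(g)

    def zero_grad(self) -> None:
        for p in self.params():
            p.zero_grad()

    def state(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.params()]

    def load_state(self, state: list[np.ndarray]) -> None:
        for p, v in zip(self.params(), state, strict=True):
            p.value[...] = v

    def token_length(self, t: int) -> int:
        """Temporal length after the stem and pooling for input length t."""
        c = self.config
        stem_out = (t + 2 * (c.stem_kernel // 2) - c.stem_kernel) // c.stem_stride + 1
        return stem_out // c.pool_stride


def build_model(config: ModelConfig | None = None, seed: int = 42) -> NFNet1d:
    """Construct a classifier from its configuration (seeded initialization)."""
    return NFNet1d(config or ModelConfig(), seed=seed)


def save_checkpoint(model: NFNet1d, path) -> None:
    """Store the model configuration (JSON) and all weights in one file."""
    import json
    from dataclasses import asdict

    arrays = {f"param_{i:03d}": p.value for i, p in enumerate(model.params())}
    np.savez_compressed(path, config=json.dumps(asdict(model.config)), **arrays)


def load_checkpoint(path) -> NFNet1d:
    """Rebuild a model from a checkpoint written by :func:`save_checkpoint`."""
    import json

    with np.load(path, allow_pickle=False) as data:
        raw = json.loads(str(data["config"]))
        raw["block_widths"] = tuple(raw["block_widths"])
        model = NFNet1d(ModelConfig(**raw))
        keys = sorted(k for k in data.files if k.startswith("param_"))
        model.load_state([data[k] for k in keys])
    return model
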