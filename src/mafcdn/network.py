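"""Configurable FC-DenseNet segmentation networks and the focal / cross-entropy losses.

The architecture is an encoder-decoder built from dense blocks (DB),
transition-down (TD) and transition-up (TU) layers:

* a dense layer is BN -> ReLU -> 3x3 conv producing ``growth_rate`` new
  feature maps -> dropout (p = 0.2 in the named variants);
* TD is BN -> ReLU -> 1x1 conv -> dropout -> 2x2 max pool;
* TU is a stride-2 transposed 3x3 convolution (zero-insertion upsampling
  followed by a 3x3 convolution, an equivalent parameterization).

Connectivity is asymmetric.  On the downsampling path a dense block's input
is concatenated with its output, so feature-map counts grow linearly
(``out = in + layers * growth``) and the full concatenated stack is both the
skip connection and the TD input.  On the upsampling path the block input is
*not* concatenated into the block output: only the ``layers * growth`` new
maps are forwarded to the next TU, which keeps the decoder's width bounded.
Each TU output is concatenated with the matching-resolution skip.  The final
1x1 convolution maps the last (full) stack to two class channels, and a
per-pixel softmax yields the probability map required by the focal loss.

To counter the extreme MA/background pixel imbalance the training objective
is the focal loss ``-alpha_t * (1 - p_t)^gamma * log(p_t)`` in place of plain
cross-entropy: the ``(1 - p_t)^gamma`` factor down-weights easy
(well-classified, overwhelmingly background) pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .errors import ShapeError, ValidationError
from .image_core import MaskImage, ProbabilityMap
from .nn.layers import (
    DTYPE,
    BatchNorm2d,
    Conv2d,
    Dropout,
    Layer,
    MaxPool2x2,
    ReLU,
    UpsampleZero2x,
)

__all__ = [
    "ArchitectureConfig",
    "FocalConfig",
    "ChannelTrace",
    "FCDenseNet",
    "build_network",
    "preset",
    "PRESETS",
    "focal_loss",
    "cross_entropy_loss",
    "softmax_logits",
    "focal_loss_with_logit_grad",
]

P_CLAMP = 1e-7  # lower clamp on p_t inside the losses; avoids log(0)


@dataclass(frozen=True)
class ArchitectureConfig:
    """Structural description of an FC-DenseNet variant."""

    variant_name: str = "custom"
    first_conv_channels: int = 48
    growth_rate: int = 16
    down_block_layers: tuple[int, ...] = (4, 5, 7, 10, 12)
    bottleneck_layers: int = 15
    up_block_layers: tuple[int, ...] = (12, 10, 7, 5, 4)
    dropout_p: float = 0.2
    num_classes: int = 2

    def __post_init__(self) -> None:
        object.__setattr__(self, "down_block_layers", tuple(self.down_block_layers))
        object.__setattr__(self, "up_block_layers", tuple(self.up_block_layers))
        if len(self.down_block_layers) != len(self.up_block_layers):
            raise ValidationError(
                "down and up paths must mirror each other: "
                f"{len(self.down_block_layers)} down blocks vs {len(self.up_block_layers)} up blocks"
            )
        counts = (*self.down_block_layers, self.bottleneck_layers, *self.up_block_layers)
        if any(c < 1 for c in counts) or self.growth_rate < 1 or self.first_conv_channels < 1:
            raise ValidationError("all layer counts, growth rate and first-conv channels must be >= 1")
        if not (0.0 <= self.dropout_p < 1.0):
            raise ValidationError(f"dropout_p must be in [0, 1); got {self.dropout_p}")
        if self.num_classes < 2:
            raise ValidationError("num_classes must be >= 2")

    @property
    def depth(self) -> int:
        return len(self.down_block_layers)

    @property
    def spatial_divisor(self) -> int:
        return 2 ** self.depth

    def to_dict(self) -> dict:
        d = asdict(self)
        d["down_block_layers"] = list(self.down_block_layers)
        d["up_block_layers"] = list(self.up_block_layers)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ArchitectureConfig":
        return cls(**d)


@dataclass(frozen=True)
class FocalConfig:
    """Focal-loss hyperparameters.

    ``alpha_ma`` weights the MA (positive) class; the background weight is
    ``1 - alpha_ma``.  ``gamma >= 0`` is the focusing exponent; ``gamma = 0``
    with unit alphas reduces the loss to cross-entropy.
    """

    alpha_ma: float = 0.25
    gamma: float = 2.0

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha_ma <= 1.0):
            raise ValidationError(f"alpha_ma must be in (0, 1]; got {self.alpha_ma}")
        if self.gamma < 0:
            raise ValidationError(f"gamma must be >= 0; got {self.gamma}")

    @property
    def alpha_t(self) -> np.ndarray:
        """Per-class weights over (background, MA)."""
        return np.array([1.0 - self.alpha_ma, self.alpha_ma]) if self.alpha_ma < 1.0 else np.array([1.0, 1.0])


ChannelTrace = list  # of (stage label, feature-map count) pairs


PRESETS: dict[str, ArchitectureConfig] = {
    "FC-DenseNet56": ArchitectureConfig(
        variant_name="FC-DenseNet56",
        first_conv_channels=48,
        growth_rate=12,
        down_block_layers=(4, 4, 4, 4, 4),
        bottleneck_layers=4,
        up_block_layers=(4, 4, 4, 4, 4),
    ),
    "FC-DenseNet67": ArchitectureConfig(
        variant_name="FC-DenseNet67",
        first_conv_channels=48,
        growth_rate=16,
        down_block_layers=(5, 5, 5, 5, 5),
        bottleneck_layers=5,
        up_block_layers=(5, 5, 5, 5, 5),
    ),
    "FC-DenseNet103": ArchitectureConfig(
        variant_name="FC-DenseNet103",
        first_conv_channels=48,
        growth_rate=16,
        down_block_layers=(4, 5, 7, 10, 12),
        bottleneck_layers=15,
        up_block_layers=(12, 10, 7, 5, 4),
    ),
    # desk-scale variant used throughout the test harness
    "tiny": ArchitectureConfig(
        variant_name="tiny",
        first_conv_channels=16,
        growth_rate=8,
        down_block_layers=(2, 2),
        bottleneck_layers=2,
        up_block_layers=(2, 2),
    ),
}


def preset(name: str) -> ArchitectureConfig:
    """Look up a named variant configuration."""
    try:
        return PRESETS[name]
    except KeyError:
        raise ValidationError(
            f"unknown variant {name!r}; valid names: {', '.join(sorted(PRESETS))}"
        ) from None


class _DenseLayer:
    """BN -> ReLU -> 3x3 conv (growth maps) -> dropout."""

    def __init__(self, in_ch: int, growth: int, p: float, rng: np.random.Generator):
        self.bn = BatchNorm2d(in_ch)
        self.relu = ReLU()
        self.conv = Conv2d(in_ch, growth, 3, rng)
        self.drop = Dropout(p)
        self.layers = [self.bn, self.relu, self.conv, self.drop]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        for l in self.layers:
            x = l.forward(x, train)
        return x

    def backward(self, g: np.ndarray) -> np.ndarray:
        for l in reversed(self.layers):
            g = l.backward(g)
        return g


class _DenseBlock:
    """A stack of dense layers with intra-block concatenation.

    ``forward`` returns ``(stack, new)``: the input concatenated with every
    layer's output, and the concatenation of the new maps alone.  Down-path
    blocks consume ``stack``; up-path blocks forward only ``new``.
    """

    def __init__(self, in_ch: int, n_layers: int, growth: int, p: float, rng: np.random.Generator):
        self.in_ch, self.growth, self.n_layers = in_ch, growth, n_layers
        self.dense = [_DenseLayer(in_ch + i * growth, growth, p, rng) for i in range(n_layers)]
        self.out_ch = in_ch + n_layers * growth
        self.new_ch = n_layers * growth

    def forward(self, x: np.ndarray, train: bool) -> tuple[np.ndarray, np.ndarray]:
        feats = [x]
        for layer in self.dense:
            y = layer.forward(np.concatenate(feats, axis=1), train)
            feats.append(y)
        stack = np.concatenate(feats, axis=1)
        new = stack[:, self.in_ch:] if self.n_layers else stack[:, :0]
        self._widths = [f.shape[1] for f in feats]
        return stack, new

    def backward(self, g_stack: np.ndarray | None, g_new: np.ndarray | None) -> np.ndarray:
        """Accumulate grads from the full stack and/or the new-maps view; return grad w.r.t. input."""
        widths = self._widths
        bounds = np.cumsum([0] + widths)
        n = g_stack.shape[0] if g_stack is not None else g_new.shape[0]
        sp = (g_stack if g_stack is not None else g_new).shape[2:]
        dt = (g_stack if g_stack is not None else g_new).dtype
        gf = [np.zeros((n, w, *sp), dtype=dt) for w in widths]
        if g_stack is not None:
            for i in range(len(widths)):
                gf[i] += g_stack[:, bounds[i]:bounds[i + 1]]
        if g_new is not None:
            off = 0
            for i in range(1, len(widths)):
                gf[i] += g_new[:, off:off + widths[i]]
                off += widths[i]
        for i in range(self.n_layers, 0, -1):
            g_in = self.dense[i - 1].backward(gf[i])
            # layer i-1 consumed concat(feats[0..i-1])
            for j in range(i):
                gf[j] += g_in[:, bounds[j]:bounds[j + 1]]
        return gf[0]

    def iter_layers(self):
        for d in self.dense:
            yield from d.layers


class _TransitionDown:
    """BN -> ReLU -> 1x1 conv (channel-preserving) -> dropout -> 2x2 max pool."""

    def __init__(self, ch: int, p: float, rng: np.random.Generator):
        self.bn = BatchNorm2d(ch)
        self.relu = ReLU()
        self.conv = Conv2d(ch, ch, 1, rng)
        self.drop = Dropout(p)
        self.pool = MaxPool2x2()
        self.layers = [self.bn, self.relu, self.conv, self.drop, self.pool]

    def forward(self, x, train):
        for l in self.layers:
            x = l.forward(x, train)
        return x

    def backward(self, g):
        for l in reversed(self.layers):
            g = l.backward(g)
        return g


class _TransitionUp:
    """Stride-2 transposed 3x3 convolution (zero-insertion + 3x3 conv)."""

    def __init__(self, ch: int, rng: np.random.Generator):
        self.up = UpsampleZero2x()
        self.conv = Conv2d(ch, ch, 3, rng)
        self.layers = [self.up, self.conv]

    def forward(self, x, train):
        return self.conv.forward(self.up.forward(x, train), train)

    def backward(self, g):
        return self.up.backward(self.conv.backward(g))


class FCDenseNet:
    """A built FC-DenseNet with explicit forward/backward passes.

    Construction records a :data:`ChannelTrace` — the ordered
    ``(stage label, feature-map count)`` pairs — so the asymmetric
    connectivity is auditable without running the network.
    """

    def __init__(self, cfg: ArchitectureConfig, seed: int = 0):
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        g, p = cfg.growth_rate, cfg.dropout_p
        trace: ChannelTrace = [("input", 1)]

        self.first_conv = Conv2d(1, cfg.first_conv_channels, 3, rng)
        ch = cfg.first_conv_channels
        trace.append(("first_conv", ch))

        self.down_blocks: list[_DenseBlock] = []
        self.tds: list[_TransitionDown] = []
        self.skip_channels: list[int] = []
        for i, n in enumerate(cfg.down_block_layers):
            db = _DenseBlock(ch, n, g, p, rng)
            self.down_blocks.append(db)
            ch = db.out_ch  # input concatenated with output: linear growth
            self.skip_channels.append(ch)
            trace.append((f"down_block_{i + 1}", ch))
            self.tds.append(_TransitionDown(ch, p, rng))
            trace.append((f"transition_down_{i + 1}", ch))

        self.bottleneck = _DenseBlock(ch, cfg.bottleneck_layers, g, p, rng)
        fwd = self.bottleneck.new_ch  # up-path rule: only the new maps move on
        trace.append(("bottleneck_new", fwd))

        self.tus: list[_TransitionUp] = []
        self.up_blocks: list[_DenseBlock] = []
        for i, n in enumerate(cfg.up_block_layers):
            self.tus.append(_TransitionUp(fwd, rng))
            skip = self.skip_channels[-(i + 1)]
            trace.append((f"transition_up_{i + 1}", fwd))
            concat_ch = fwd + skip
            trace.append((f"skip_concat_{i + 1}", concat_ch))
            ub = _DenseBlock(concat_ch, n, g, p, rng)
            self.up_blocks.append(ub)
            fwd = ub.new_ch
            trace.append((f"up_block_{i + 1}_new", fwd))
        trace.append(("final_stack", self.up_blocks[-1].out_ch))

        self.final_conv = Conv2d(self.up_blocks[-1].out_ch, cfg.num_classes, 1, rng)
        trace.append(("logits", cfg.num_classes))
        self.channel_trace: ChannelTrace = trace
        self._drop_rng: np.random.Generator | None = None

    # -- bookkeeping ---------------------------------------------------------

    def iter_layers(self) -> list[Layer]:
        layers: list[Layer] = [self.first_conv]
        for db, td in zip(self.down_blocks, self.tds):
            layers.extend(db.iter_layers())
            layers.extend(td.layers)
        layers.extend(self.bottleneck.iter_layers())
        for tu, ub in zip(self.tus, self.up_blocks):
            layers.extend(tu.layers)
            layers.extend(ub.iter_layers())
        layers.append(self.final_conv)
        return layers

    @property
    def n_params(self) -> int:
        return sum(l.n_params for l in self.iter_layers())

    def seed_dropout(self, seed: int) -> None:
        rng = np.random.default_rng(seed)
        self._drop_rng = rng
        for l in self.iter_layers():
            if isinstance(l, Dropout):
                l.rng = rng

    def astype(self, dtype) -> "FCDenseNet":
        for l in self.iter_layers():
            for k in l.params:
                l.params[k] = l.params[k].astype(dtype)
            for k in l.buffers:
                l.buffers[k] = l.buffers[k].astype(dtype)
        return self

    def state_arrays(self) -> dict[str, np.ndarray]:
        out = {}
        for i, l in enumerate(self.iter_layers()):
            for k, v in l.params.items():
                out[f"p_{i}_{k}"] = v
            for k, v in l.buffers.items():
                out[f"b_{i}_{k}"] = v
        return out

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        for i, l in enumerate(self.iter_layers()):
            for k in l.params:
                l.params[k] = np.array(state[f"p_{i}_{k}"])
            for k in l.buffers:
                l.buffers[k] = np.array(state[f"b_{i}_{k}"])

    # -- execution -----------------------------------------------------------

    def _check_spatial(self, h: int, w: int) -> None:
        d = self.cfg.spatial_divisor
        if h % d or w % d:
            raise ShapeError(
                f"input {h}x{w} not divisible by {d} (2^{self.cfg.depth} for "
                f"{self.cfg.depth} down blocks)"
            )

    def forward_logits(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """x: (N, 1, H, W) float in [0, 1] -> logits (N, num_classes, H, W)."""
        if train and self.cfg.dropout_p > 0 and self._drop_rng is None:
            self.seed_dropout(0)
        self._check_spatial(x.shape[2], x.shape[3])
        x = x.astype(self.first_conv.params["weight"].dtype, copy=False)
        s = self.first_conv.forward(x, train)
        skips = []
        for db, td in zip(self.down_blocks, self.tds):
            s, _ = db.forward(s, train)
            skips.append(s)
            s = td.forward(s, train)
        _, new = self.bottleneck.forward(s, train)
        for i, (tu, ub) in enumerate(zip(self.tus, self.up_blocks)):
            u = tu.forward(new, train)
            skip = skips[-(i + 1)]
            s = np.concatenate([u, skip], axis=1)
            stack, new = ub.forward(s, train)
        logits = self.final_conv.forward(stack, train)
        self._skip_widths = [s.shape[1] for s in skips]
        return logits

    def backward(self, g_logits: np.ndarray) -> None:
        """Backpropagate a logits gradient; leaves parameter grads on the layers."""
        g_stack = self.final_conv.backward(g_logits)
        g_skips: list[np.ndarray | None] = [None] * len(self.up_blocks)
        g_new = None
        for i in range(len(self.up_blocks) - 1, -1, -1):
            ub, tu = self.up_blocks[i], self.tus[i]
            g_concat = ub.backward(g_stack if i == len(self.up_blocks) - 1 else None, g_new)
            u_ch = tu.conv.out_ch
            g_u, g_skip = g_concat[:, :u_ch], g_concat[:, u_ch:]
            # up step i consumed the skip from down block (depth - 1 - i)
            g_skips[len(self.up_blocks) - 1 - i] = g_skip
            g_new = tu.backward(g_u)
        # bottleneck got only its "new" view used downstream
        g = self.bottleneck.backward(None, g_new)
        for i in range(len(self.down_blocks) - 1, -1, -1):
            g = self.tds[i].backward(g)
            # down block i's stack fed both TD i and, as a skip, up step (depth - 1 - i)
            g = self.down_blocks[i].backward(g + g_skips[i], None)
        self.first_conv.backward(g)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Inference-mode softmax probabilities, (N, num_classes, H, W)."""
        return softmax_logits(self.forward_logits(x, train=False))

    def predict_proba_map(self, img01: np.ndarray) -> ProbabilityMap:
        """Single-image convenience: (H, W) floats in [0,1] -> ProbabilityMap."""
        p = self.predict_proba(img01[None, None].astype(DTYPE))[0]
        return ProbabilityMap(p.transpose(1, 2, 0).astype(np.float64))


def build_network(cfg: ArchitectureConfig, seed: int = 0) -> tuple[FCDenseNet, ChannelTrace]:
    """Build a network and return it with its channel trace."""
    net = FCDenseNet(cfg, seed=seed)
    return net, net.channel_trace


# -- losses ------------------------------------------------------------------


def softmax_logits(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _p_true(pred: ProbabilityMap, truth: MaskImage) -> np.ndarray:
    if (pred.height, pred.width) != (truth.height, truth.width):
        raise ShapeError(
            f"prediction {pred.height}x{pred.width} does not match mask "
            f"{truth.height}x{truth.width}"
        )
    t = truth.labels.astype(np.intp)
    return np.take_along_axis(pred.probs, t[..., None], axis=2)[..., 0]


def focal_loss(pred: ProbabilityMap, truth: MaskImage, cfg: FocalConfig = FocalConfig()) -> float:
    """Mean over pixels of ``-alpha_t * (1 - p_t)^gamma * ln(p_t)``.

    ``p_t`` is the predicted probability of the pixel's true class and
    ``alpha_t`` the weight of that class; ``p_t`` is clamped to
    ``[1e-7, 1]`` for numerical safety.
    """
    p_t = np.clip(_p_true(pred, truth), P_CLAMP, 1.0)
    a_t = cfg.alpha_t[truth.labels.astype(np.intp)]
    return float(np.mean(-a_t * (1.0 - p_t) ** cfg.gamma * np.log(p_t)))


def cross_entropy_loss(pred: ProbabilityMap, truth: MaskImage) -> float:
    """Mean pixel-wise negative log-likelihood (focal loss with gamma=0, alpha=1)."""
    p_t = np.clip(_p_true(pred, truth), P_CLAMP, 1.0)
    return float(np.mean(-np.log(p_t)))


def focal_loss_with_logit_grad(
    logits: np.ndarray, truth: np.ndarray, alpha_t: np.ndarray, gamma: float
) -> tuple[float, np.ndarray]:
    """Fused softmax + focal loss and its gradient w.r.t. the logits.

    ``logits``: (N, C, H, W); ``truth``: (N, H, W) int labels;
    ``alpha_t``: per-class weights.  With ``p_t`` the softmax probability of
    the true class, dL/dp_t = alpha * (gamma (1-p_t)^(gamma-1) ln p_t
    - (1-p_t)^gamma / p_t) and dp_t/dz_j = p_t (delta_{jt} - p_j); the
    returned gradient is already averaged over pixels.
    """
    p = softmax_logits(logits)
    n, c, h, w = p.shape
    t = truth.astype(np.intp)
    p_t = np.take_along_axis(p, t[:, None], axis=1)[:, 0]
    p_t = np.clip(p_t, P_CLAMP, 1.0)
    a = alpha_t.astype(p.dtype)[t]
    one_m = 1.0 - p_t
    log_p = np.log(p_t)
    loss = float(np.mean(-a * one_m**gamma * log_p))
    if gamma == 0.0:
        dl_dpt = -a / p_t
    else:
        dl_dpt = a * (gamma * one_m ** (gamma - 1.0) * log_p - one_m**gamma / p_t)
    onehot = np.zeros_like(p)
    np.put_along_axis(onehot, t[:, None], 1.0, axis=1)
    g = (dl_dpt * p_t)[:, None] * (onehot - p) / (n * h * w)
    return loss, g.astype(logits.dtype)
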