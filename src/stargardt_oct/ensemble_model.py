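"""Interpretable ensemble of per-feature component U-Nets.

Each component U-Net consumes exactly one en-face feature map and emits raw
2-channel (atrophy / background) activations — there is no per-component
softmax.  The ensemble output is the per-pixel, per-channel maximum of the
component activations,

    g(E(Y)) = max(f1(x1), f2(x2), ..., fn(xn)),

followed by a softmax over the two class channels.  Training minimizes a
weighted two-class logistic loss plus a Dice loss plus an L2 weight-decay
penalty, by stochastic mini-batch gradient descent with momentum; gradients
flow through the max only to the per-pixel arg-max component (split equally
on ties).

Component U-Net architecture: encoder blocks of conv(5x5, same padding) ->
batch norm -> ReLU -> 2x2 max pool (indices retained); a bottleneck conv
block; decoder blocks of max unpool -> concatenation with the corresponding
encoder features -> conv -> batch norm -> ReLU; and a 1x1 conv head to two
channels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage as ndi

from .enface_features import FeatureStack
from .nn import SGD, BatchNorm2d, Conv2d, MaxPool2d, MaxUnpool2d, Param, ReLU

__all__ = [
    "ComponentUNetConfig", "EnsembleConfig", "TrainConfig", "PredictionResult",
    "ComponentUNet", "EnsembleNetwork", "combine_max", "softmax2",
    "boundary_weight_map", "weighted_logloss", "dice_loss", "overall_loss",
    "train",
]

LOG_CLAMP = 1e-7
DICE_EPS = 1e-7


@dataclass(frozen=True)
class ComponentUNetConfig:
    """Architecture of one component U-Net."""

    input_shape: Tuple[int, int] = (128, 128)
    in_channels: int = 1
    depth: int = 4
    widths: Tuple[int, ...] = (16, 32, 64, 128)
    kernel_size: int = 5
    n_classes: int = 2

    def validate(self) -> None:
        h, w = self.input_shape
        f = 2 ** self.depth
        if h % f or w % f:
            raise ValueError(
                f"input dims {self.input_shape} must be divisible by 2^depth = {f}")
        if len(self.widths) != self.depth:
            raise ValueError("need one channel width per encoder level")
        if any(c <= 0 for c in self.widths):
            raise ValueError("channel widths must be positive")


@dataclass(frozen=True)
class EnsembleConfig:
    """One component U-Net per feature, in canonical feature order."""

    features: Tuple[str, ...]
    unet: ComponentUNetConfig = field(default_factory=ComponentUNetConfig)

    def validate(self) -> None:
        if len(self.features) < 1:
            raise ValueError("ensemble needs at least one feature")
        self.unet.validate()


@dataclass(frozen=True)
class TrainConfig:
    """Optimization schedule; defaults follow the published training recipe."""

    batch_size: int = 8
    lr_schedule: Tuple[Tuple[int, float], ...] = ((40, 1e-2), (20, 1e-3))
    momentum: float = 0.95
    weight_decay: float = 1e-4
    region_weight: float = 6.0
    boundary_weight: float = 15.0
    seed: int = 0

    @property
    def epochs(self) -> int:
        return sum(n for n, _ in self.lr_schedule)

    def validate(self) -> None:
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch size and epochs must be positive")
        if min(self.region_weight, self.boundary_weight) <= 0:
            raise ValueError("pixel weights must be positive")
        if self.boundary_weight < self.region_weight:
            raise ValueError("boundary weight must be >= region weight")

    def lr_at(self, epoch: int) -> float:
        """Learning rate for 0-based ``epoch``."""
        e = epoch
        for n, lr in self.lr_schedule:
            if e < n:
                return lr
            e -= n
        return self.lr_schedule[-1][1]


@dataclass
class PredictionResult:
    """Ensemble probabilities plus per-component activations for grading."""

    probabilities: np.ndarray          # (2, H, W), softmax over classes
    mask: np.ndarray                   # (H, W) uint8 argmax binarization
    component_activations: np.ndarray  # (n, 2, H, W) raw logits
    component_sigmoids: np.ndarray     # (n, H, W) sigmoid(atrophy - background)
    features: Tuple[str, ...] = ()


class _ConvBlock:
    """conv -> batch norm -> ReLU."""

    def __init__(self, cin, cout, k, rng, dtype):
        self.conv = Conv2d(cin, cout, k, rng, dtype)
        self.bn = BatchNorm2d(cout, dtype)
        self.relu = ReLU()

    def params(self):
        return self.conv.params() + self.bn.params()

    def forward(self, x, train=True):
        return self.relu.forward(self.bn.forward(self.conv.forward(x, train), train), train)

    def backward(self, dy):
        return self.conv.backward(self.bn.backward(self.relu.backward(dy)))


class ComponentUNet:
    """Encoder-decoder network for a single feature map."""

    def __init__(self, config: ComponentUNetConfig, rng: np.random.Generator,
                 dtype=np.float32):
        config.validate()
        self.config = config
        self.dtype = dtype
        d, w = config.depth, config.widths
        k = config.kernel_size
        self.enc = []
        cin = config.in_channels
        for i in range(d):
            self.enc.append((_ConvBlock(cin, w[i], k, rng, dtype), MaxPool2d()))
            cin = w[i]
        self.bottleneck = _ConvBlock(w[d - 1], w[d - 1], k, rng, dtype)
        self.dec = []
        for i in reversed(range(d)):
            cout = w[i - 1] if i > 0 else w[0]
            self.dec.append((MaxUnpool2d(), _ConvBlock(2 * w[i], cout, k, rng, dtype)))
        self.head = Conv2d(w[0], config.n_classes, 1, rng, dtype)

    def params(self) -> List[Param]:
        ps: List[Param] = []
        for block, _ in self.enc:
            ps += block.params()
        ps += self.bottleneck.params()
        for _, block in self.dec:
            ps += block.params()
        ps += self.head.params()
        return ps

    def n_parameters(self) -> int:
        return sum(p.value.size for p in self.params())

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        """(N, 1, H, W) feature map -> (N, 2, H, W) raw class activations."""
        if x.shape[2:] != self.config.input_shape:
            raise ValueError(f"expected input {self.config.input_shape}, got {x.shape[2:]}")
        h = np.asarray(x, dtype=self.dtype)
        skips = []
        for block, pool in self.enc:
            h = block.forward(h, train)
            skips.append(h)
            h = pool.forward(h, train)
        h = self.bottleneck.forward(h, train)
        d = self.config.depth
        for j, (unpool, block) in enumerate(self.dec):
            i = d - 1 - j
            h = unpool.forward(h, self.enc[i][1].indices, train)
            h = np.concatenate([h, skips[i]], axis=1)
            h = block.forward(h, train)
        return self.head.forward(h, train)

    def backward(self, dy: np.ndarray) -> None:
        """Accumulate parameter gradients from upstream d(loss)/d(activations)."""
        d = self.config.depth
        w = self.config.widths
        dh = self.head.backward(np.asarray(dy, dtype=self.dtype))
        dskips = [None] * d
        for j in reversed(range(len(self.dec))):
            i = d - 1 - j
            unpool, block = self.dec[j]
            dcat = block.backward(dh)
            du, dskips[i] = dcat[:, :w[i]], dcat[:, w[i]:]
            dh = unpool.backward(du)
        dh = self.bottleneck.backward(dh)
        for i in reversed(range(d)):
            block, pool = self.enc[i]
            dh = pool.backward(dh) + dskips[i]
            dh = block.backward(dh)


def combine_max(activations: Sequence[np.ndarray]) -> np.ndarray:
    """Element-wise maximum across components, per pixel and class channel."""
    acts = list(activations)
    if not acts:
        raise ValueError("need at least one component activation")
    shape = acts[0].shape
    if any(a.shape != shape for a in acts):
        raise ValueError("component activations must share dimensions")
    out = acts[0].copy()
    for a in acts[1:]:
        np.maximum(out, a, out=out)
    return out


def _max_routing(activations: Sequence[np.ndarray], combined: np.ndarray):
    """Per-component gradient routing masks; ties share gradient equally."""
    ties = [(a == combined) for a in activations]
    counts = np.zeros(combined.shape, dtype=np.int64)
    for t in ties:
        counts += t
    return [t / counts for t in ties]


def softmax2(z: np.ndarray, axis: int = -3) -> np.ndarray:
    """Numerically stable softmax over the class-channel axis."""
    zs = z - z.max(axis=axis, keepdims=True)
    e = np.exp(zs)
    return e / e.sum(axis=axis, keepdims=True)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * x))


class EnsembleNetwork:
    """The full per-feature ensemble."""

    def __init__(self, config: EnsembleConfig, seed: int = 0, dtype=np.float32):
        config.validate()
        self.config = config
        self.dtype = dtype
        root = np.random.default_rng(seed)
        self.components = [ComponentUNet(config.unet, np.random.default_rng(s), dtype)
                           for s in root.integers(0, 2 ** 31, size=len(config.features))]

    @property
    def features(self) -> Tuple[str, ...]:
        return self.config.features

    def params(self) -> List[Param]:
        ps: List[Param] = []
        for c in self.components:
            ps += c.params()
        return ps

    def n_parameters(self) -> int:
        return sum(p.value.size for p in self.params())

    def forward_components(self, x: np.ndarray, train: bool = True) -> List[np.ndarray]:
        """x: (N, n_features, H, W); returns per-component (N, 2, H, W) logits."""
        if x.shape[1] != len(self.components):
            raise ValueError(
                f"stack has {x.shape[1]} channels, ensemble expects {len(self.components)}")
        return [c.forward(x[:, i:i + 1], train) for i, c in enumerate(self.components)]

    def forward(self, x: np.ndarray, train: bool = True):
        acts = self.forward_components(x, train)
        return combine_max(acts), acts

    def predict(self, stack: FeatureStack | np.ndarray) -> PredictionResult:
        """Inference on one feature stack."""
        data = stack.data if isinstance(stack, FeatureStack) else np.asarray(stack)
        feats = stack.features if isinstance(stack, FeatureStack) else self.features
        x = data[None].astype(self.dtype)
        combined, acts = self.forward(x, train=False)
        p = softmax2(combined, axis=1)[0]
        acts = np.stack([a[0] for a in acts])
        sig = _sigmoid(acts[:, 1] - acts[:, 0])
        mask = (p[1] > p[0]).astype(np.uint8)
        return PredictionResult(p, mask, acts, sig, tuple(feats))

    def state_dict(self) -> dict:
        return {f"p{i}": p.value for i, p in enumerate(self.params())} | {
            f"bn_stats{i}": np.stack([bn.running_mean, bn.running_var])
            for i, bn in enumerate(self._bn_layers())}

    def load_state_dict(self, state: dict) -> None:
        for i, p in enumerate(self.params()):
            p.value = np.asarray(state[f"p{i}"], dtype=self.dtype)
            p.velocity = np.zeros_like(p.value)
        for i, bn in enumerate(self._bn_layers()):
            stats = np.asarray(state[f"bn_stats{i}"])
            bn.running_mean, bn.running_var = stats[0].copy(), stats[1].copy()

    def _bn_layers(self):
        for c in self.components:
            for block, _ in c.enc:
                yield block.bn
            yield c.bottleneck.bn
            for _, block in c.dec:
                yield block.bn


# ---------------------------------------------------------------------------
# losses


def boundary_weight_map(gt: np.ndarray, weights: Tuple[float, float] = (6.0, 15.0)) -> np.ndarray:
    """Pixel weights: ``weights[1]`` on the atrophy/background boundary band
    (3x3 neighborhood contains both classes), ``weights[0]`` elsewhere."""
    g = np.asarray(gt)
    if not np.isin(np.unique(g), (0, 1)).all():
        raise ValueError("ground-truth mask must be binary (0/1)")
    region_w, boundary_w = weights
    gb = g.astype(bool)
    footprint = np.ones((3, 3), dtype=bool)
    if g.ndim == 3:
        dil = np.stack([ndi.binary_dilation(m, footprint) for m in gb])
        ero = np.stack([ndi.binary_erosion(m, footprint, border_value=1) for m in gb])
    else:
        dil = ndi.binary_dilation(gb, footprint)
        ero = ndi.binary_erosion(gb, footprint, border_value=1)
    return np.where(dil != ero, boundary_w, region_w).astype(np.float64)


def _as_batch(p: np.ndarray, gt: np.ndarray):
    p = np.asarray(p, dtype=np.float64)
    gt = np.asarray(gt)
    if p.ndim == 3:
        p, gt = p[None], gt[None]
    if p.ndim != 4 or p.shape[1] != 2 or gt.shape != (p.shape[0],) + p.shape[2:]:
        raise ValueError(f"shape mismatch: probabilities {p.shape}, ground truth {gt.shape}")
    return p, gt


def weighted_logloss(p: np.ndarray, gt: np.ndarray, weightmap: np.ndarray,
                     reduction: str = "mean") -> float:
    """Weighted two-class logistic loss -sum_x sum_l w(x) g_l(x) log p_l(x).

    ``reduction='sum'`` is the published (summed-over-pixels) form;
    ``'mean'`` divides by the pixel count, the form used for optimization.
    """
    p, gt = _as_batch(p, gt)
    w = np.asarray(weightmap, dtype=np.float64)
    if w.ndim == 2:
        w = np.broadcast_to(w, gt.shape)
    if w.shape != gt.shape:
        raise ValueError("weight map shape mismatch")
    g1 = gt.astype(np.float64)
    logp = np.log(np.clip(p, LOG_CLAMP, None))
    total = -(w * ((1.0 - g1) * logp[:, 0] + g1 * logp[:, 1])).sum()
    if reduction == "sum":
        return float(total)
    if reduction == "mean":
        return float(total / gt.size)
    raise ValueError(f"unknown reduction {reduction!r}")


def dice_loss(p_atrophy: np.ndarray, gt: np.ndarray, eps: float = DICE_EPS) -> float:
    """1 - 2*sum(p*g) / (sum(g^2) + sum(p^2)), smoothed; batch-averaged."""
    p = np.asarray(p_atrophy, dtype=np.float64)
    g = np.asarray(gt, dtype=np.float64)
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {g.shape}")
    if p.ndim == 2:
        p, g = p[None], g[None]
    ax = tuple(range(1, p.ndim))
    num = 2.0 * (p * g).sum(axis=ax) + eps
    den = (g ** 2).sum(axis=ax) + (p ** 2).sum(axis=ax) + eps
    return float((1.0 - num / den).mean())


def weight_penalty(params: Sequence[Param]) -> float:
    """Squared Frobenius norm of the decayed (convolution kernel) weights."""
    return float(sum((p.value.astype(np.float64) ** 2).sum() for p in params if p.decay))


def overall_loss(p: np.ndarray, gt: np.ndarray, weightmap: np.ndarray,
                 params: Sequence[Param] = (), weight_decay: float = 1e-4,
                 logloss_reduction: str = "mean") -> float:
    """Weighted log-loss + Dice loss + weight-decay penalty."""
    pb, gb = _as_batch(p, gt)
    return (weighted_logloss(p, gt, weightmap, logloss_reduction)
            + dice_loss(pb[:, 1], gb)
            + weight_decay * weight_penalty(params))


def _loss_and_grad(z: np.ndarray, gt: np.ndarray, weightmap: np.ndarray,
                   logloss_reduction: str = "mean"):
    """Data loss (log-loss + Dice) and its gradient w.r.t. the logits ``z``."""
    p = softmax2(z.astype(np.float64), axis=1)
    N, _, H, W = p.shape
    g1 = np.asarray(gt, dtype=np.float64)
    w = np.asarray(weightmap, dtype=np.float64)
    if w.ndim == 2:
        w = np.broadcast_to(w, g1.shape)
    norm = 1.0 if logloss_reduction == "sum" else g1.size

    loss = weighted_logloss(p, gt, w, logloss_reduction)
    # d(logloss)/dp with the clamp: zero gradient where p was clamped
    pc = np.clip(p, LOG_CLAMP, None)
    active = (p >= LOG_CLAMP).astype(np.float64)
    gl = np.stack([1.0 - g1, g1], axis=1)
    dLdp = -(w[:, None] * gl / pc) * active / norm

    p1 = p[:, 1]
    num = 2.0 * (p1 * g1).sum(axis=(1, 2)) + DICE_EPS
    den = (g1 ** 2).sum(axis=(1, 2)) + (p1 ** 2).sum(axis=(1, 2)) + DICE_EPS
    loss += float((1.0 - num / den).mean())
    dDdp1 = -(2.0 * g1 * den[:, None, None] - num[:, None, None] * 2.0 * p1) \
        / den[:, None, None] ** 2 / N
    dLdp[:, 1] += dDdp1

    # softmax backward
    dz = p * (dLdp - (dLdp * p).sum(axis=1, keepdims=True))
    return loss, dz


# ---------------------------------------------------------------------------
# training


def train(net: EnsembleNetwork, stacks: Sequence[FeatureStack | np.ndarray],
          masks: Sequence[np.ndarray], config: Optional[TrainConfig] = None,
          logloss_reduction: str = "mean", verbose: bool = False):
    """Jointly train all component U-Nets by back-propagation through the max.

    Deterministic for a fixed ``config.seed``.  Returns the per-epoch history
    as a list of dicts (epoch, lr, loss = mean per-batch overall loss).
    Raises ``RuntimeError`` on divergence (non-finite loss).
    """
    config = config or TrainConfig()
    config.validate()
    if len(stacks) == 0 or len(stacks) != len(masks):
        raise ValueError("need a non-empty, aligned training set")
    X = np.stack([s.data if isinstance(s, FeatureStack) else np.asarray(s)
                  for s in stacks]).astype(net.dtype)
    Y = np.stack([np.asarray(m) for m in masks]).astype(np.int8)
    if not np.isin(np.unique(Y), (0, 1)).all():
        raise ValueError("training masks must be binary (0/1)")
    W = np.stack([boundary_weight_map(y, (config.region_weight, config.boundary_weight))
                  for y in Y])

    params = net.params()
    opt = SGD(params, lr=config.lr_at(0), momentum=config.momentum,
              weight_decay=config.weight_decay)
    rng = np.random.default_rng(config.seed)
    n = X.shape[0]
    history = []
    for epoch in range(config.epochs):
        opt.lr = config.lr_at(epoch)
        order = rng.permutation(n)
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            xb, yb, wb = X[idx], Y[idx], W[idx]
            opt.zero_grad()
            combined, acts = net.forward(xb, train=True)
            data_loss, dz = _loss_and_grad(combined, yb, wb, logloss_reduction)
            loss = data_loss + config.weight_decay * weight_penalty(params)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged at epoch {epoch}: loss = {loss}")
            routes = _max_routing(acts, combined)
            for comp, route in zip(net.components, routes):
                comp.backward((dz * route).astype(net.dtype))
            opt.step()
            epoch_loss += loss
            n_batches += 1
        history.append({"epoch": epoch, "lr": opt.lr, "loss": epoch_loss / n_batches})
        if verbose:
            print(f"epoch {epoch + 1}/{config.epochs}  lr={opt.lr:g}  "
                  f"loss={history[-1]['loss']:.4f}")
    return history
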