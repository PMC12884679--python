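"""Residual U-Net vessel segmentation.

Encoder: residual blocks with 2x2 max-pool downsampling, feature channels
doubling per level.  Bottleneck: parallel dilated 3x3 convolutions at the
configured rates, combined by summation.  Decoder: 2x2 transposed
convolutions halving channels, with long skip connections merged by
summation (not concatenation).  Head: 1x1 convolution + sigmoid.  Trained
with binary cross-entropy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn import Tensor

__all__ = [
    "SegNetConfig",
    "TrainConfig",
    "relu",
    "dilated_conv",
    "ResidualBlock",
    "ResUNet",
    "build_model",
    "bce_loss",
    "train_segmenter",
    "predict",
    "binarize",
]


@dataclass
class SegNetConfig:
    depth: int = 4
    base_channels: int = 16
    dilation_rates: tuple[int, ...] = (1, 2, 4)
    use_batch_norm: bool = True
    dropout_rate: float = 0.0
    in_channels: int = 1

    def validate(self) -> None:
        if self.depth < 1:
            raise ValueError(f"depth must be >= 1, got {self.depth}")
        if self.base_channels < 1:
            raise ValueError(f"base_channels must be >= 1, got {self.base_channels}")
        rates = tuple(self.dilation_rates)
        if any(r < 1 for r in rates) or len(set(rates)) != len(rates):
            raise ValueError(f"dilation rates must be distinct integers >= 1, got {rates}")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError(f"dropout_rate must be in [0,1), got {self.dropout_rate}")


@dataclass
class TrainConfig:
    epochs: int = 10
    batch_size: int = 4
    learning_rate: float = 2e-3
    optimizer: str = "adam"
    seed: int = 0
    patch_size: int = 64
    patches_per_image: int = 2

    def validate(self) -> None:
        if self.epochs < 1:
            raise ValueError(f"epochs must be >= 1, got {self.epochs}")
        if self.learning_rate <= 0:
            raise ValueError(f"learning_rate must be positive, got {self.learning_rate}")


def relu(x):
    """Elementwise max(0, x); the two-branch rectifier."""
    return np.maximum(np.asarray(x, dtype=float), 0.0) if not np.isscalar(x) \
        else max(0.0, float(x))


def dilated_conv(x: np.ndarray, w: np.ndarray, r: int,
                 mode: str = "valid") -> np.ndarray:
    """Dilated cross-correlation y[i] = sum_k x[i + r*k] * w[k].

    Supports 1-D and 2-D signals; r = 1 reduces to a standard (valid or
    zero-padded same) convolution.
    """
    if r < 1:
        raise ValueError(f"dilation rate must be >= 1, got {r}")
    x = np.asarray(x, dtype=float)
    w = np.asarray(w, dtype=float)
    # insert r-1 zeros between successive taps of the kernel
    if w.ndim == 1:
        wd = np.zeros((w.shape[0] - 1) * r + 1)
        wd[::r] = w
    elif w.ndim == 2:
        wd = np.zeros(((w.shape[0] - 1) * r + 1, (w.shape[1] - 1) * r + 1))
        wd[::r, ::r] = w
    else:
        raise ValueError("only 1-D and 2-D kernels are supported")
    if x.ndim != w.ndim:
        raise ValueError(f"signal is {x.ndim}-D but kernel is {w.ndim}-D")
    if mode == "same":
        pads = [((s - 1) // 2, s - 1 - (s - 1) // 2) for s in wd.shape]
        x = np.pad(x, pads)
        mode = "valid"
    if mode != "valid":
        raise ValueError(f"unknown mode {mode!r}")
    if x.ndim == 1:
        return np.correlate(x, wd, mode="valid")
    from scipy.signal import correlate2d
    return correlate2d(x, wd, mode="valid")


# -- network building blocks ---------------------------------------------


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> Tensor:
    scale = np.sqrt(2.0 / fan_in)
    return Tensor(rng.normal(0.0, scale, size=shape), requires_grad=True)


class _ConvBNRelu:
    def __init__(self, rng, cin, cout, k=3, dilation=1, use_bn=True,
                 activation=True):
        self.w = _he_init(rng, (cout, cin, k, k), cin * k * k)
        self.b = Tensor(np.zeros(cout), requires_grad=True)
        self.dilation = dilation
        self.use_bn = use_bn
        self.activation = activation
        if use_bn:
            self.gamma = Tensor(np.ones(cout), requires_grad=True)
            self.beta = Tensor(np.zeros(cout), requires_grad=True)
            self.running = {"mean": np.zeros(cout, dtype=np.float32),
                            "var": np.ones(cout, dtype=np.float32)}

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        y = nn.conv2d(x, self.w, self.b, dilation=self.dilation)
        if self.use_bn:
            y = nn.batch_norm(y, self.gamma, self.beta, training=training,
                              running=self.running)
        return nn.relu(y) if self.activation else y

    def parameters(self):
        ps = [self.w, self.b]
        if self.use_bn:
            ps += [self.gamma, self.beta]
        return ps


class ResidualBlock:
    """Two conv->BN->ReLU stages plus an additive shortcut.

    The shortcut is the identity when channel counts match, otherwise a
    1x1 projection.  With all convolution weights at zero (and identity
    shortcut) the block is the identity map.
    """

    def __init__(self, rng, cin, cout, use_bn=True):
        self.stage1 = _ConvBNRelu(rng, cin, cout, use_bn=use_bn)
        self.stage2 = _ConvBNRelu(rng, cout, cout, use_bn=use_bn)
        self.project = None
        if cin != cout:
            self.project = _ConvBNRelu(rng, cin, cout, k=1, use_bn=False,
                                       activation=False)

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        f = self.stage2(self.stage1(x, training), training)
        h = self.project(x, training) if self.project is not None else x
        return f + h

    def parameters(self):
        ps = self.stage1.parameters() + self.stage2.parameters()
        if self.project is not None:
            ps += self.project.parameters()
        return ps


class _DilatedFusion:
    """Parallel dilated 3x3 convolutions combined by summation."""

    def __init__(self, rng, cin, cout, rates, use_bn=True):
        self.branches = [
            _ConvBNRelu(rng, cin, cout, dilation=r, use_bn=use_bn,
                        activation=False)
            for r in rates
        ]

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        out = self.branches[0](x, training)
        for br in self.branches[1:]:
            out = out + br(x, training)
        return nn.relu(out)

    def parameters(self):
        return [p for br in self.branches for p in br.parameters()]


class _UpConv:
    def __init__(self, rng, cin, cout):
        self.w = _he_init(rng, (cin, cout, 2, 2), cin * 4)
        self.b = Tensor(np.zeros(cout), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return nn.conv_transpose2d_2x2(x, self.w, self.b)

    def parameters(self):
        return [self.w, self.b]


class _Head:
    def __init__(self, rng, cin):
        self.w = _he_init(rng, (1, cin, 1, 1), cin)
        self.b = Tensor(np.zeros(1), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return nn.sigmoid(nn.conv2d(x, self.w, self.b))

    def parameters(self):
        return [self.w, self.b]


class ResUNet:
    def __init__(self, cfg: SegNetConfig, seed: int = 0):
        cfg.validate()
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        ch = cfg.base_channels
        use_bn = cfg.use_batch_norm
        self.encoders = []
        cin = cfg.in_channels
        for d in range(cfg.depth):
            cout = ch * 2 ** d
            self.encoders.append(ResidualBlock(rng, cin, cout, use_bn))
            cin = cout
        self.bottleneck = _DilatedFusion(rng, cin, cin * 2,
                                         cfg.dilation_rates, use_bn)
        self.upconvs = []
        self.decoders = []
        cur = cin * 2
        for d in reversed(range(cfg.depth)):
            cout = ch * 2 ** d
            self.upconvs.append(_UpConv(rng, cur, cout))
            self.decoders.append(ResidualBlock(rng, cout, cout, use_bn))
            cur = cout
        self.head = _Head(rng, cur)
        self._dropout_rng = np.random.default_rng(np.random.SeedSequence([seed, 7]))

    # -- forward ----------------------------------------------------------
    def _backbone(self, x: Tensor, training: bool) -> Tensor:
        h, w = x.shape[2], x.shape[3]
        f = 2 ** self.cfg.depth
        if h < f or w < f or h % f or w % f:
            raise ValueError(
                f"input {h}x{w} must be a positive multiple of 2^depth = {f}"
            )
        skips = []
        for enc in self.encoders:
            x = enc(x, training)
            skips.append(x)
            x = nn.max_pool2d_2x2(x)
        x = self.bottleneck(x, training)
        if training and self.cfg.dropout_rate > 0:
            x = nn.dropout(x, self.cfg.dropout_rate, self._dropout_rng)
        for up, dec, skip in zip(self.upconvs, self.decoders, reversed(skips)):
            x = up(x)
            x = x + skip                  # summation fusion, not concatenation
            x = dec(x, training)
        return x

    def forward(self, x: Tensor, training: bool = False) -> Tensor:
        return self.head(self._backbone(x, training))

    def feature_maps(self, img: np.ndarray) -> np.ndarray:
        """Pre-head features of the last decoder block, (C, H, W)."""
        x = Tensor(_pad_to_multiple(img, 2 ** self.cfg.depth)[None, None])
        feats = self._backbone(x, training=False).data[0]
        return feats[:, :img.shape[0], :img.shape[1]]

    def parameters(self):
        ps = []
        for enc in self.encoders:
            ps += enc.parameters()
        ps += self.bottleneck.parameters()
        for up, dec in zip(self.upconvs, self.decoders):
            ps += up.parameters() + dec.parameters()
        ps += self.head.parameters()
        return ps

    # -- persistence ------------------------------------------------------
    def state_arrays(self) -> dict[str, np.ndarray]:
        state = {f"param_{i}": p.data for i, p in enumerate(self.parameters())}
        blocks = [b for b in
                  [s for e in self.encoders for s in (e.stage1, e.stage2)]
                  + list(self.bottleneck.branches)
                  + [s for d in self.decoders for s in (d.stage1, d.stage2)]
                  if b.use_bn]
        for i, b in enumerate(blocks):
            state[f"bn_{i}_mean"] = b.running["mean"]
            state[f"bn_{i}_var"] = b.running["var"]
        return state

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.parameters()):
            p.data = np.asarray(state[f"param_{i}"], dtype=np.float32)
        blocks = [b for b in
                  [s for e in self.encoders for s in (e.stage1, e.stage2)]
                  + list(self.bottleneck.branches)
                  + [s for d in self.decoders for s in (d.stage1, d.stage2)]
                  if b.use_bn]
        for i, b in enumerate(blocks):
            b.running["mean"] = np.asarray(state[f"bn_{i}_mean"], dtype=np.float32)
            b.running["var"] = np.asarray(state[f"bn_{i}_var"], dtype=np.float32)


def build_model(cfg: SegNetConfig, seed: int = 0) -> ResUNet:
    return ResUNet(cfg, seed=seed)


# -- loss and training ---------------------------------------------------


def bce_loss(p, q, eps: float = 1e-7):
    """Binary cross-entropy -(1/n)·Σ[q·log p + (1-q)·log(1-p)].

    Accepts Tensors (for training) or plain arrays (returns a float).
    """
    plain = not isinstance(p, Tensor)
    pt = p if isinstance(p, Tensor) else Tensor(np.asarray(p, dtype=np.float32))
    qa = q.data if isinstance(q, Tensor) else np.asarray(q, dtype=np.float32)
    if pt.data.shape != qa.shape:
        raise ValueError(f"shape mismatch: {pt.data.shape} vs {qa.shape}")
    pc = pt.clip(eps, 1.0 - eps)
    qt = Tensor(qa)
    loss = -((qt * pc.log() + (1.0 - qt) * (1.0 - pc).log()).mean())
    return float(loss.data) if plain else loss


def _pad_to_multiple(img: np.ndarray, f: int) -> np.ndarray:
    h, w = img.shape
    ph, pw = (-h) % f, (-w) % f
    if ph or pw:
        img = np.pad(img, ((0, ph), (0, pw)), mode="reflect")
    return img


def _sample_patches(imgs, masks, patch, rng, per_image):
    xs, ys = [], []
    for img, msk in zip(imgs, masks):
        h, w = img.shape
        for _ in range(per_image):
            if h <= patch or w <= patch:
                xs.append(_pad_to_multiple(img, patch)[:patch, :patch])
                ys.append(_pad_to_multiple(msk.astype(float), patch)[:patch, :patch])
            else:
                r = int(rng.integers(0, h - patch + 1))
                c = int(rng.integers(0, w - patch + 1))
                xs.append(img[r:r + patch, c:c + patch])
                ys.append(msk[r:r + patch, c:c + patch].astype(float))
    return xs, ys


def train_segmenter(samples, cfg: SegNetConfig, tcfg: TrainConfig,
                    val_samples=None):
    """Train a Res-UNet on (enhanced image, vessel mask) pairs.

    Patch-based: each epoch draws random ``patch_size`` crops from every
    image.  Returns (model, trace) where trace rows are dicts with epoch,
    train_loss and optionally val_loss.  Deterministic for a fixed seed.
    """
    if not samples:
        raise ValueError("need at least one training sample")
    cfg.validate()
    tcfg.validate()
    rng = np.random.default_rng(tcfg.seed)
    model = build_model(cfg, seed=tcfg.seed)
    opt = nn.make_optimizer(tcfg.optimizer, model.parameters(), tcfg.learning_rate)
    imgs = [np.asarray(s[0], dtype=np.float32) for s in samples]
    masks = [np.asarray(s[1]).astype(np.float32) for s in samples]
    trace = []
    for epoch in range(tcfg.epochs):
        xs, ys = _sample_patches(imgs, masks, tcfg.patch_size, rng,
                                 tcfg.patches_per_image)
        order = rng.permutation(len(xs))
        losses = []
        for start in range(0, len(order), tcfg.batch_size):
            idx = order[start:start + tcfg.batch_size]
            xb = Tensor(np.stack([xs[i] for i in idx])[:, None])
            yb = np.stack([ys[i] for i in idx])[:, None]
            prob = model.forward(xb, training=True)
            loss = bce_loss(prob, yb)
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        row = {"epoch": epoch + 1, "train_loss": float(np.mean(losses))}
        if val_samples:
            vl = [bce_loss(predict(model, vi), np.asarray(vm, dtype=float))
                  for vi, vm in val_samples]
            row["val_loss"] = float(np.mean(vl))
        trace.append(row)
    return model, trace


def predict(model: ResUNet, img) -> np.ndarray:
    """Per-pixel vessel probability with the input's H×W (reflect-padded
    internally to a multiple of 2^depth)."""
    arr = np.asarray(getattr(img, "pixels", img), dtype=np.float32)
    padded = _pad_to_multiple(arr, 2 ** model.cfg.depth)
    prob = model.forward(Tensor(padded[None, None]), training=False).data[0, 0]
    return prob[:arr.shape[0], :arr.shape[1]].astype(np.float64)


def binarize(p: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Threshold a probability map to a {0,1} mask."""
    if not (0.0 < threshold < 1.0):
        raise ValueError(f"threshold must be in (0,1), got {threshold}")
    return (np.asarray(p) >= threshold).astype(np.uint8)
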