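"""Graph convolutional artery/vein classifier over the vessel pixel graph.

Each layer computes sigma(W_hat · H · W^L) with ReLU activation and the
symmetrically normalised adjacency W_hat; a softmax head yields per-node
class probabilities.  Training minimises a weighted sum of Dice loss and
binary cross-entropy, with undefined-class nodes masked out by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from . import nn
from .graph import PixelGraph, normalize_adjacency
from .labels import ARTERY, BACKGROUND, UNDEFINED, VEIN
from .nn import Tensor

__all__ = [
    "GCNConfig",
    "NodePrediction",
    "GCNParams",
    "init_params",
    "gcn_layer",
    "forward",
    "dice_loss",
    "ce_loss",
    "train_gcn",
    "labels_to_image",
]

# class-index convention: 0 = artery, 1 = vein, (2 = undefined in 3-class mode)
_INDEX_TO_CODE = {0: ARTERY, 1: VEIN, 2: UNDEFINED}
_CODE_TO_INDEX = {v: k for k, v in _INDEX_TO_CODE.items()}


@dataclass
class GCNConfig:
    n_layers: int = 2
    hidden_dim: int = 64
    n_classes: int = 2
    dropout_rate: float = 0.0
    seed: int = 0
    loss_weights: tuple[float, float] = (1.0, 1.0)   # (w_dice, w_ce)

    def validate(self) -> None:
        if self.n_layers < 1:
            raise ValueError(f"n_layers must be >= 1, got {self.n_layers}")
        if self.hidden_dim < 1:
            raise ValueError(f"hidden_dim must be >= 1, got {self.hidden_dim}")
        if self.n_classes not in (2, 3):
            raise ValueError(f"n_classes must be 2 or 3, got {self.n_classes}")
        wd, wc = self.loss_weights
        if wd < 0 or wc < 0 or (wd == 0 and wc == 0):
            raise ValueError("loss weights must be >= 0 and not both zero")


@dataclass
class NodePrediction:
    scores: np.ndarray   # (n, k), rows sum to 1
    labels: np.ndarray   # (n,) label codes (ARTERY / VEIN / UNDEFINED)


@dataclass
class GCNParams:
    weights: list[Tensor]

    def as_list(self) -> list[Tensor]:
        return self.weights


def init_params(cfg: GCNConfig, feature_dim: int) -> GCNParams:
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    dims = [feature_dim] + [cfg.hidden_dim] * (cfg.n_layers - 1) + [cfg.n_classes]
    weights = []
    for din, dout in zip(dims[:-1], dims[1:]):
        scale = np.sqrt(2.0 / (din + dout))
        weights.append(Tensor(rng.normal(0.0, scale, size=(din, dout)),
                              requires_grad=True))
    return GCNParams(weights)


def gcn_layer(h, w_hat: sp.spmatrix, weights) -> Tensor:
    """One propagation step: ReLU(W_hat @ H @ W)."""
    ht = h if isinstance(h, Tensor) else Tensor(np.asarray(h, dtype=np.float32))
    wt = weights if isinstance(weights, Tensor) else \
        Tensor(np.asarray(weights, dtype=np.float32))
    if ht.data.shape[1] != wt.data.shape[0]:
        raise ValueError(
            f"feature dim {ht.data.shape[1]} does not match weight rows "
            f"{wt.data.shape[0]}"
        )
    return nn.relu(nn.spmm(w_hat, ht) @ wt)


def _forward_scores(g: PixelGraph, cfg: GCNConfig, params: GCNParams,
                    training: bool = False,
                    rng: np.random.Generator | None = None) -> Tensor:
    if g.features is None:
        raise ValueError("graph has no node features; run extract_node_features")
    w_hat = normalize_adjacency(g)
    h = Tensor(g.features)
    for i, w in enumerate(params.weights):
        h = gcn_layer(h, w_hat, w)
        if training and cfg.dropout_rate > 0 and i < len(params.weights) - 1:
            h = nn.dropout(h, cfg.dropout_rate, rng)
    return nn.softmax_rows(h)


def forward(g: PixelGraph, cfg: GCNConfig, params: GCNParams) -> NodePrediction:
    """Stacked propagation layers followed by a per-node softmax.

    Argmax ties break toward the artery class (lowest index).
    """
    scores = _forward_scores(g, cfg, params).data
    idx = scores.argmax(axis=1)
    labels = np.array([_INDEX_TO_CODE[int(i)] for i in idx], dtype=np.uint8)
    return NodePrediction(scores=scores.astype(np.float64), labels=labels)


# -- losses --------------------------------------------------------------


def dice_loss(g_true, g_hat, eps: float = 1e-6, eps_placement: str = "symmetric"):
    """1 − (2·Σ g·ĝ + ε) / (Σ g² + Σ ĝ² [+ ε]).

    ``symmetric`` places ε in both numerator and denominator (default);
    ``printed`` places it in the numerator only.
    """
    gt = np.asarray(g_true.data if isinstance(g_true, Tensor) else g_true,
                    dtype=np.float32)
    ht = g_hat if isinstance(g_hat, Tensor) else \
        Tensor(np.asarray(g_hat, dtype=np.float32))
    if gt.shape != ht.data.shape:
        raise ValueError(f"shape mismatch: {gt.shape} vs {ht.data.shape}")
    if eps <= 0:
        raise ValueError("eps must be positive")
    gt_t = Tensor(gt)
    num = (gt_t * ht).sum() * 2.0 + eps
    den = (gt_t * gt_t).sum() + (ht * ht).sum()
    if eps_placement == "symmetric":
        den = den + eps
    elif eps_placement != "printed":
        raise ValueError(f"unknown eps placement {eps_placement!r}")
    inv = Tensor(np.float32(1.0))
    # 1 - num/den, built from autograd primitives
    ratio = num * _reciprocal(den)
    out = inv - ratio
    return out


def _reciprocal(t: Tensor) -> Tensor:
    out = Tensor(1.0 / t.data, t.requires_grad)
    out._parents = (t,)

    def backward(g):
        if t.requires_grad:
            t._accumulate(-g / (t.data * t.data))

    out._backward = backward
    return out


def ce_loss(b_true, b_hat, eps: float = 1e-7):
    """Binary cross-entropy averaged over nodes (Eq.-style two-term form)."""
    bt = np.asarray(b_true.data if isinstance(b_true, Tensor) else b_true,
                    dtype=np.float32)
    ht = b_hat if isinstance(b_hat, Tensor) else \
        Tensor(np.asarray(b_hat, dtype=np.float32))
    if bt.shape != ht.data.shape:
        raise ValueError(f"shape mismatch: {bt.shape} vs {ht.data.shape}")
    if bt.size == 0:
        raise ValueError("no supervised nodes: all nodes are masked out")
    pc = ht.clip(eps, 1.0 - eps)
    btt = Tensor(bt)
    return -((btt * pc.log() + (1.0 - btt) * (1.0 - pc).log()).mean())


def _gather_rows(t: Tensor, idx: np.ndarray) -> Tensor:
    out = Tensor(t.data[idx], t.requires_grad)
    out._parents = (t,)

    def backward(g):
        if t.requires_grad:
            acc = np.zeros_like(t.data)
            np.add.at(acc, idx, g)
            t._accumulate(acc)

    out._backward = backward
    return out


def combined_loss(scores: Tensor, node_codes: np.ndarray, cfg: GCNConfig) -> Tensor:
    """w_dice·Dice + w_ce·CE on artery-vs-vein, masking undefined nodes
    (2-class mode) or training them explicitly (3-class mode)."""
    wd, wc = cfg.loss_weights
    if cfg.n_classes == 2:
        keep = np.isin(node_codes, (ARTERY, VEIN))
        if not keep.any():
            raise ValueError("no supervised nodes: every node is undefined")
        idx = np.nonzero(keep)[0]
        sub = _gather_rows(scores, idx)
        onehot = np.zeros((len(idx), 2), dtype=np.float32)
        onehot[np.arange(len(idx)), [_CODE_TO_INDEX[c] for c in node_codes[idx]]] = 1.0
    else:
        sub = scores
        onehot = np.zeros((len(node_codes), 3), dtype=np.float32)
        onehot[np.arange(len(node_codes)),
               [_CODE_TO_INDEX[c] for c in node_codes]] = 1.0
    loss = None
    if wd > 0:
        loss = dice_loss(onehot, sub) * wd
    if wc > 0:
        p_artery = _gather_cols(sub, 0)
        ce = ce_loss(onehot[:, 0], p_artery) * wc
        loss = ce if loss is None else loss + ce
    return loss


def _gather_cols(t: Tensor, col: int) -> Tensor:
    out = Tensor(t.data[:, col], t.requires_grad)
    out._parents = (t,)

    def backward(g):
        if t.requires_grad:
            acc = np.zeros_like(t.data)
            acc[:, col] = g
            t._accumulate(acc)

    out._backward = backward
    return out


# -- training ------------------------------------------------------------


def train_gcn(samples, cfg: GCNConfig, epochs: int = 60, lr: float = 5e-3,
              optimizer: str = "adam"):
    """Train on a list of (PixelGraph-with-features, node label codes).

    Returns (params, trace); trace rows hold epoch and mean loss.
    Deterministic for a fixed cfg.seed.
    """
    if not samples:
        raise ValueError("need at least one training graph")
    cfg.validate()
    params = init_params(cfg, samples[0][0].features.shape[1])
    opt = nn.make_optimizer(optimizer, params.as_list(), lr)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 11]))
    trace = []
    for epoch in range(epochs):
        losses = []
        for g, codes in samples:
            scores = _forward_scores(g, cfg, params, training=True, rng=rng)
            loss = combined_loss(scores, np.asarray(codes), cfg)
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        trace.append({"epoch": epoch + 1, "loss": float(np.mean(losses))})
    return params, trace


def labels_to_image(pred: NodePrediction, g: PixelGraph,
                    shape: tuple[int, int]) -> np.ndarray:
    """Paint node predictions back into an H×W label-code map."""
    h, w = shape
    if (g.nodes[:, 0] >= h).any() or (g.nodes[:, 1] >= w).any():
        raise ValueError("node coordinates fall outside the requested shape")
    out = np.full(shape, BACKGROUND, dtype=np.uint8)
    out[g.nodes[:, 0], g.nodes[:, 1]] = pred.labels
    return out
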