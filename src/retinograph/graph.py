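"""Pixel graph over a binary vessel mask.

Every vessel pixel is a node; an undirected edge joins every pair of
8-adjacent vessel pixels; every node carries a self-loop.  The adjacency
is kept sparse and symmetrically normalised as W = D^{-1/2} A D^{-1/2},
i.e. W_ij = a_ij / sqrt(d_i d_j).

Background pixels are not materialised by default: under the propagation
rule an isolated self-looped node never exchanges information, so the
vessel-only subgraph is equivalent and far smaller.  ``include_background``
emits the strict full-pixel view when needed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

__all__ = [
    "PixelGraph",
    "build_graph",
    "normalize_adjacency",
    "extract_node_features",
]


@dataclass
class PixelGraph:
    nodes: np.ndarray                 # (n, 2) int (row, col), row-major order
    adjacency: sp.csr_matrix          # symmetric 0/1 with unit diagonal
    shape: tuple[int, int]            # source mask H×W
    features: np.ndarray | None = None  # (n, m)

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def degree(self) -> np.ndarray:
        """Row sums of the adjacency (self-loop included)."""
        return np.asarray(self.adjacency.sum(axis=1)).ravel().astype(int)

    def edge_set(self) -> set[tuple[int, int]]:
        """Unordered node-index pairs, self-loops excluded."""
        coo = self.adjacency.tocoo()
        return {(min(i, j), max(i, j))
                for i, j in zip(coo.row, coo.col) if i != j}


_SHIFTS = [(-1, -1), (-1, 0), (-1, 1), (0, -1)]   # one direction per pair


def build_graph(mask: np.ndarray, include_background: bool = False) -> PixelGraph:
    """Construct the 8-connected self-looped pixel graph of a mask.

    An empty mask yields an empty graph (0 nodes), not an error.
    """
    mask = np.asarray(mask).astype(bool)
    h, w = mask.shape
    if include_background:
        nodes = np.argwhere(np.ones_like(mask))
        index = np.arange(h * w).reshape(h, w)
    else:
        nodes = np.argwhere(mask)
        index = np.full((h, w), -1, dtype=np.int64)
        index[mask] = np.arange(len(nodes))
    n = len(nodes)
    rows, cols = [], []
    for dr, dc in _SHIFTS:
        src = mask[max(0, -dr):h - max(0, dr), max(0, -dc):w - max(0, dc)]
        dst = mask[max(0, dr):h - max(0, -dr), max(0, dc):w - max(0, -dc)]
        both = src & dst
        rr, cc = np.nonzero(both)
        rr_src, cc_src = rr + max(0, -dr), cc + max(0, -dc)
        rr_dst, cc_dst = rr_src + dr, cc_src + dc
        i = index[rr_src, cc_src]
        j = index[rr_dst, cc_dst]
        rows.extend([i, j])
        cols.extend([j, i])
    if rows:
        ri = np.concatenate(rows)
        ci = np.concatenate(cols)
    else:
        ri = ci = np.empty(0, dtype=np.int64)
    data = np.ones(len(ri), dtype=np.float64)
    adj = sp.coo_matrix((data, (ri, ci)), shape=(n, n)).tocsr()
    adj.data[:] = 1.0                       # defensive: edges are 0/1
    adj = adj + sp.identity(n, format="csr")
    adj.data = np.minimum(adj.data, 1.0)
    return PixelGraph(nodes=nodes, adjacency=adj, shape=(h, w))


def normalize_adjacency(g: PixelGraph) -> sp.csr_matrix:
    """W = D^{-1/2} A D^{-1/2}; every degree is >= 1 thanks to self-loops."""
    deg = np.asarray(g.adjacency.sum(axis=1)).ravel()
    assert (deg >= 1).all(), "self-loops guarantee positive degrees"
    dinv = 1.0 / np.sqrt(deg)
    dmat = sp.diags(dinv)
    return (dmat @ g.adjacency @ dmat).tocsr()


def extract_node_features(g: PixelGraph, feature_maps: np.ndarray,
                          standardize: bool = False) -> PixelGraph:
    """Sample multi-channel feature maps at the node positions.

    ``feature_maps`` is (C, H, W) or a single (H, W) channel; H×W must
    match the mask the graph was built from.  Returns the same graph with
    ``features`` of shape (n, C) attached.  ``standardize`` rescales each
    feature channel to zero mean / unit variance over the nodes, which the
    classifier needs since its propagation rule carries no bias terms.
    """
    fm = np.asarray(feature_maps)
    if fm.ndim == 2:
        fm = fm[None]
    if fm.ndim != 3 or fm.shape[1:] != g.shape:
        raise ValueError(
            f"feature maps spatial dims {fm.shape} do not match mask {g.shape}"
        )
    feats = fm[:, g.nodes[:, 0], g.nodes[:, 1]].T.astype(np.float32)
    if standardize and len(feats):
        feats = (feats - feats.mean(axis=0)) / (feats.std(axis=0) + 1e-6)
    g.features = feats
    return g
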