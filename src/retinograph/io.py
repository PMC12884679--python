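"""Readers and writers for images, masks, label maps, graphs and reports."""

from __future__ import annotations

import csv
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
from PIL import Image

from .graph import PixelGraph
from .labels import labels_to_rgb, rgb_to_labels
from .preprocessing import FundusImage
from .synthetic import SyntheticSample, spec_to_dict

__all__ = [
    "write_image", "read_image",
    "write_mask", "read_mask",
    "write_labels", "read_labels",
    "write_graph", "read_graph",
    "write_json", "read_json",
    "save_sample", "load_sample",
]


def write_image(path, pixels: np.ndarray) -> None:
    """Write an 8-bit PNG from a float [0,1] (grey or RGB) or uint8 array."""
    arr = np.asarray(pixels)
    if arr.dtype != np.uint8:
        arr = np.clip(np.rint(arr * 255.0), 0, 255).astype(np.uint8)
    Image.fromarray(arr).save(path)


def read_image(path) -> FundusImage:
    img = Image.open(path)
    if img.mode not in ("RGB", "RGBA"):
        img = img.convert("RGB")
    arr = np.asarray(img)[..., :3]
    return FundusImage(arr)


def write_mask(path, mask: np.ndarray) -> None:
    write_image(path, (np.asarray(mask).astype(bool) * 255).astype(np.uint8))


def read_mask(path) -> np.ndarray:
    arr = np.asarray(Image.open(path).convert("L"))
    return (arr >= 128).astype(np.uint8)


def write_labels(path, codes: np.ndarray) -> None:
    write_image(path, labels_to_rgb(codes))


def read_labels(path) -> np.ndarray:
    arr = np.asarray(Image.open(path).convert("RGB"))
    return rgb_to_labels(arr)


def write_json(path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_jsonable))


def read_json(path):
    return json.loads(Path(path).read_text())


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


# -- graphs --------------------------------------------------------------


def write_graph(prefix, g: PixelGraph) -> None:
    """Export a pixel graph as <prefix>.edges (id id) and <prefix>.nodes.csv
    (id, row, col, feature_0..m)."""
    prefix = Path(prefix)
    with open(prefix.with_suffix(".edges"), "w") as fh:
        for i, j in sorted(g.edge_set()):
            fh.write(f"{i} {j}\n")
    m = 0 if g.features is None else g.features.shape[1]
    with open(prefix.with_suffix(".nodes.csv"), "w", newline="") as fh:
        wr = csv.writer(fh)
        wr.writerow(["id", "row", "col"] + [f"feature_{k}" for k in range(m)])
        for i, (r, c) in enumerate(g.nodes):
            row = [i, int(r), int(c)]
            if m:
                row += [repr(float(v)) for v in g.features[i]]
            wr.writerow(row)
    with open(prefix.with_suffix(".meta.json"), "w") as fh:
        json.dump({"shape": list(g.shape)}, fh)


def read_graph(prefix) -> PixelGraph:
    import scipy.sparse as sp

    prefix = Path(prefix)
    meta = json.loads(prefix.with_suffix(".meta.json").read_text())
    nodes, feats = [], []
    with open(prefix.with_suffix(".nodes.csv")) as fh:
        rd = csv.reader(fh)
        header = next(rd)
        m = len(header) - 3
        for row in rd:
            nodes.append((int(row[1]), int(row[2])))
            if m:
                feats.append([float(v) for v in row[3:]])
    n = len(nodes)
    ri, ci = [], []
    edges_path = prefix.with_suffix(".edges")
    if edges_path.exists():
        for line in edges_path.read_text().splitlines():
            if not line.strip():
                continue
            i, j = map(int, line.split())
            ri.extend([i, j])
            ci.extend([j, i])
    adj = sp.coo_matrix((np.ones(len(ri)), (ri, ci)), shape=(n, n)).tocsr()
    adj = adj + sp.identity(n, format="csr")
    adj.data = np.minimum(adj.data, 1.0)
    g = PixelGraph(nodes=np.array(nodes, dtype=int).reshape(n, 2),
                   adjacency=adj, shape=tuple(meta["shape"]))
    if feats:
        g.features = np.asarray(feats, dtype=np.float32)
    return g


# -- synthetic sample bundles --------------------------------------------


def save_sample(out_dir, sample: SyntheticSample) -> None:
    """Write image.png, mask.png, av.png, widths.csv and meta.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_image(out / "image.png", sample.image.pixels)
    write_mask(out / "mask.png", sample.vessel_mask)
    write_labels(out / "av.png", sample.av_labels)
    rows, cols = np.nonzero(sample.width_map)
    with open(out / "widths.csv", "w", newline="") as fh:
        wr = csv.writer(fh)
        wr.writerow(["row", "col", "width"])
        for r, c in zip(rows, cols):
            wr.writerow([int(r), int(c), float(sample.width_map[r, c])])
    meta = {
        "spec": spec_to_dict(sample.spec),
        "true_crae": sample.true_crae,
        "true_crve": sample.true_crve,
        "true_avr": sample.true_avr,
        "disc_center": list(sample.disc_center),
        "disc_radius": sample.disc_radius,
    }
    write_json(out / "meta.json", meta)


def load_sample(in_dir) -> dict:
    """Read a sample bundle back as a dict of arrays + metadata."""
    d = Path(in_dir)
    out = {
        "image": read_image(d / "image.png"),
        "mask": read_mask(d / "mask.png"),
        "labels": read_labels(d / "av.png"),
        "meta": read_json(d / "meta.json"),
    }
    widths = []
    with open(d / "widths.csv") as fh:
        rd = csv.reader(fh)
        next(rd)
        for row in rd:
            widths.append((int(row[0]), int(row[1]), float(row[2])))
    out["widths"] = widths
    return out
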