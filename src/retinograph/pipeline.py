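"""End-to-end orchestration: preprocess -> segment -> graph -> A/V ->
calibre measurement -> HR grade."""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import gcn as gcn_mod
from . import io as rio
from . import morphometry, segmentation
from .evaluation import confusion_from_masks, compute_metrics, dice_coefficient
from .gcn import GCNConfig
from .grading import classify_binary, grade_from_avr
from .graph import build_graph, extract_node_features
from .preprocessing import FundusImage, enhance
from .segmentation import SegNetConfig, TrainConfig
from .synthetic import SyntheticSample

log = logging.getLogger("retinograph")

__all__ = ["PipelineConfig", "TrainedModels", "train_models", "run_pipeline"]


@dataclass
class PipelineConfig:
    green_mode: str = "normalized"
    clahe_clip: float = 2.0
    clahe_tiles: tuple[int, int] = (8, 8)
    denoise_sigma: float = 0.5
    seg: SegNetConfig = field(default_factory=SegNetConfig)
    # 256x256 preset samples need more patch draws than the 128px fixture
    seg_train: TrainConfig = field(
        default_factory=lambda: TrainConfig(epochs=12, patches_per_image=6))
    gcn: GCNConfig = field(default_factory=GCNConfig)
    gcn_epochs: int = 40
    gcn_lr: float = 5e-3
    threshold: float = 0.5
    annulus: tuple[float, float] = (2.0, 3.0)
    formula_mode: str = "canonical"
    micron_per_pixel: float = 15.0
    seed: int = 0
    out_dir: str | None = None

    def reseeded(self, seed: int) -> "PipelineConfig":
        import copy

        cfg = copy.deepcopy(self)
        cfg.seed = seed
        cfg.seg_train.seed = seed
        cfg.gcn.seed = seed
        return cfg


def load_config(path) -> PipelineConfig:
    """Build a PipelineConfig from a YAML document.

    Top-level keys map to PipelineConfig fields; the nested ``seg``,
    ``seg_train`` and ``gcn`` sections map to the corresponding dataclass
    fields.  Unknown keys raise.
    """
    import yaml

    raw = yaml.safe_load(Path(path).read_text()) or {}
    cfg = PipelineConfig()
    nested = {"seg": cfg.seg, "seg_train": cfg.seg_train, "gcn": cfg.gcn}
    for key, value in raw.items():
        if key in nested:
            for k, v in (value or {}).items():
                if not hasattr(nested[key], k):
                    raise ValueError(f"unknown config key {key}.{k}")
                setattr(nested[key], k, tuple(v) if isinstance(v, list) else v)
        elif hasattr(cfg, key):
            setattr(cfg, key, tuple(value) if isinstance(value, list) else value)
        else:
            raise ValueError(f"unknown config key {key}")
    if cfg.seed:
        return cfg.reseeded(cfg.seed)
    return cfg


@dataclass
class TrainedModels:
    seg_model: segmentation.ResUNet
    gcn_params: gcn_mod.GCNParams
    seg_trace: list = field(default_factory=list)
    gcn_trace: list = field(default_factory=list)


def _enhance(img: FundusImage, cfg: PipelineConfig):
    return enhance(img, green_mode=cfg.green_mode, clip_limit=cfg.clahe_clip,
                   tile_grid=cfg.clahe_tiles, sigma=cfg.denoise_sigma)


def _node_features(model, enhanced: np.ndarray, mask: np.ndarray):
    """Graph node features: enhanced intensity + last-decoder feature maps."""
    g = build_graph(mask)
    fmaps = model.feature_maps(enhanced.astype(np.float32))
    stacked = np.concatenate([enhanced[None].astype(np.float32), fmaps], axis=0)
    return extract_node_features(g, stacked, standardize=True)


def train_models(train_samples: list[SyntheticSample],
                 cfg: PipelineConfig) -> TrainedModels:
    """Fit the segmentation network and the A/V node classifier on
    synthetic samples with known masks and labels."""
    t0 = time.time()
    enhanced = [_enhance(s.image, cfg).pixels for s in train_samples]
    seg_model, seg_trace = segmentation.train_segmenter(
        list(zip(enhanced, [s.vessel_mask for s in train_samples])),
        cfg.seg, cfg.seg_train)
    log.info("segmentation trained in %.1fs (final loss %.4f)",
             time.time() - t0, seg_trace[-1]["train_loss"])

    t1 = time.time()
    graphs = []
    for s, enh in zip(train_samples, enhanced):
        g = _node_features(seg_model, enh, s.vessel_mask)
        codes = s.av_labels[g.nodes[:, 0], g.nodes[:, 1]]
        graphs.append((g, codes))
    gcn_params, gcn_trace = gcn_mod.train_gcn(
        graphs, cfg.gcn, epochs=cfg.gcn_epochs, lr=cfg.gcn_lr)
    log.info("GCN trained in %.1fs (final loss %.4f)",
             time.time() - t1, gcn_trace[-1]["loss"])
    return TrainedModels(seg_model=seg_model, gcn_params=gcn_params,
                         seg_trace=seg_trace, gcn_trace=gcn_trace)


def run_pipeline(image: FundusImage, disc_center, disc_radius,
                 cfg: PipelineConfig, models: TrainedModels,
                 truth: SyntheticSample | None = None) -> dict:
    """Execute every stage on one image and return the run report.

    When ``truth`` is supplied, segmentation Dice and A/V metrics against
    the ground truth are included.
    """
    report: dict = {"seed": cfg.seed, "timings": {}, "artifacts": {}}
    out = Path(cfg.out_dir) if cfg.out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)

    def _stage(name):
        t = time.time()

        def done():
            report["timings"][name] = round(time.time() - t, 3)
            log.info("stage %-10s %.2fs", name, report["timings"][name])
        return done

    fin = _stage("preprocess")
    enh = _enhance(image, cfg)
    fin()

    fin = _stage("segment")
    prob = segmentation.predict(models.seg_model, enh.pixels)
    mask = segmentation.binarize(prob, cfg.threshold)
    fin()
    if mask.sum() == 0:
        raise RuntimeError("segmentation stage produced an empty vessel mask")

    fin = _stage("graph")
    g = _node_features(models.seg_model, enh.pixels, mask)
    fin()
    log.debug("graph: %d nodes, %d edges", g.n_nodes, len(g.edge_set()))

    fin = _stage("classify")
    pred = gcn_mod.forward(g, cfg.gcn, models.gcn_params)
    label_map = gcn_mod.labels_to_image(pred, g, mask.shape)
    fin()

    fin = _stage("measure")
    summary, branches = morphometry.measure_calibres(
        mask, label_map, disc_center, disc_radius, annulus=cfg.annulus,
        formula_mode=cfg.formula_mode, micron_per_pixel=cfg.micron_per_pixel)
    fin()

    fin = _stage("grade")
    grade = grade_from_avr(summary.avr)
    verdict = classify_binary(grade)
    fin()

    report["calibres"] = summary.to_dict()
    report["branches"] = branches
    report["grade"] = grade.grade
    report["verdict"] = verdict
    report["rule_version"] = grade.decision_rule

    if truth is not None:
        report["metrics"] = {
            "seg_dice": dice_coefficient(mask, truth.vessel_mask),
            "true_avr": truth.true_avr,
        }
        try:
            av_cm = confusion_from_masks(label_map, truth.av_labels)
            report["metrics"]["av"] = compute_metrics(av_cm).as_percent()
        except ValueError:
            pass

    if out:
        rio.write_image(out / "enhanced.png", enh.pixels)
        rio.write_image(out / "probability.png", prob)
        rio.write_mask(out / "mask.png", mask)
        rio.write_labels(out / "av_pred.png", label_map)
        rio.write_json(out / "report.json", report)
        for name in ("enhanced.png", "probability.png", "mask.png",
                     "av_pred.png", "report.json"):
            report["artifacts"][name] = str(out / name)
    return report
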