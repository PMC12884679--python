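"""Synthetic fundus generator with known vessel trees and calibres.

Grows artery and vein trees outward from the optic-disc boundary as
midpoint-perturbed polylines, rasterises them as round-capped strokes,
and returns the image together with exact ground truth: binary vessel
mask, artery/vein label map, per-centreline-pixel widths and the true
CRAE/CRVE/AVR implied by the root widths.

Arteries are rendered brighter and thinner with a central reflex stripe;
veins darker and wider.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace

import numpy as np
from skimage.draw import line as _draw_line

from . import morphometry
from .labels import ARTERY, BACKGROUND, VEIN
from .preprocessing import FundusImage

__all__ = [
    "VesselTreeSpec",
    "Segment",
    "SyntheticSample",
    "generate_tree",
    "render_sample",
    "preset_spec",
    "PRESETS",
]


@dataclass(frozen=True)
class VesselTreeSpec:
    seed: int = 0
    image_size: tuple[int, int] = (256, 256)
    disc_center: tuple[float, float] = (128.0, 128.0)
    disc_radius: float = 20.0
    n_arteries: int = 3
    n_veins: int = 3
    root_width_artery: float = 9.0
    root_width_vein: float = 13.0
    branch_depth: int = 2
    width_decay: float = 0.8
    tortuosity: float = 0.15
    artery_intensity: float = 0.85
    vein_intensity: float = 0.55
    background_intensity: float = 0.25
    reflex_strength: float = 0.3
    noise_sd: float = 0.02
    micron_per_pixel: float = 15.0

    def validate(self) -> None:
        if not (0 < self.width_decay < 1):
            raise ValueError(f"width_decay must be in (0,1), got {self.width_decay}")
        if self.root_width_artery <= 0 or self.root_width_vein <= 0:
            raise ValueError("root widths must be strictly positive")
        if self.root_width_vein <= self.root_width_artery:
            raise ValueError("veins must be wider than arteries "
                             f"({self.root_width_vein} <= {self.root_width_artery})")
        if self.artery_intensity <= self.vein_intensity:
            raise ValueError("arteries must be brighter than veins")
        h, w = self.image_size
        cy, cx = self.disc_center
        margin = 3.0 * self.disc_radius       # outer annulus must fit
        if (cy - margin < 0 or cx - margin < 0
                or cy + margin > h - 1 or cx + margin > w - 1):
            raise ValueError(
                f"image_size {self.image_size} too small to contain the disc "
                f"at {self.disc_center} plus a 3x disc-radius annulus"
            )


@dataclass
class Segment:
    """A polyline vessel piece of constant width."""

    points: np.ndarray            # (k, 2) float (row, col)
    width: float
    vessel_class: int             # ARTERY or VEIN
    depth: int
    branch_id: int
    parent_id: int | None = None


@dataclass
class SyntheticSample:
    image: FundusImage
    vessel_mask: np.ndarray       # bool H×W
    av_labels: np.ndarray         # uint8 code H×W
    width_map: np.ndarray         # float H×W, true width at centreline pixels
    true_crae: float
    true_crve: float
    true_avr: float
    disc_center: tuple[float, float]
    disc_radius: float
    spec: VesselTreeSpec
    segments: list[Segment] = field(default_factory=list)


# -- tree growth ---------------------------------------------------------


def _perturb_polyline(p0: np.ndarray, p1: np.ndarray, tortuosity: float,
                      rng: np.random.Generator, rounds: int = 2) -> np.ndarray:
    """Midpoint-displacement polyline between two endpoints; the
    perturbation amplitude scales with tortuosity and local length."""
    pts = [p0, p1]
    for _ in range(rounds):
        nxt = [pts[0]]
        for a, b in zip(pts[:-1], pts[1:]):
            mid = 0.5 * (a + b)
            seg = b - a
            length = float(np.hypot(*seg))
            if length > 1e-9:
                perp = np.array([-seg[1], seg[0]]) / length
                mid = mid + perp * rng.normal(0.0, tortuosity * length * 0.25)
            nxt.extend([mid, b])
        pts = nxt
    return np.array(pts)


def generate_tree(spec: VesselTreeSpec) -> list[Segment]:
    """Grow the artery and vein trees; deterministic for a fixed spec."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_size
    cy, cx = spec.disc_center

    n_total = spec.n_arteries + spec.n_veins
    classes: list[int] = []
    na = nv = 0
    while len(classes) < n_total:       # interleave to separate the trees
        if na < spec.n_arteries:
            classes.append(ARTERY)
            na += 1
        if nv < spec.n_veins and len(classes) < n_total:
            classes.append(VEIN)
            nv += 1

    base_len = 0.30 * min(h, w)
    segments: list[Segment] = []
    counter = 0

    def grow(start: np.ndarray, angle: float, width: float, cls: int,
             depth: int, parent: int | None) -> None:
        nonlocal counter
        length = base_len * (0.65 ** depth)
        end = start + length * np.array([math.sin(angle), math.cos(angle)])
        end = np.clip(end, [0.0, 0.0], [h - 1.0, w - 1.0])
        if np.hypot(*(end - start)) < 2.0:
            return
        pts = _perturb_polyline(start, end, spec.tortuosity, rng)
        pts = np.clip(pts, [0.0, 0.0], [h - 1.0, w - 1.0])
        bid = counter
        counter += 1
        segments.append(Segment(points=pts, width=width, vessel_class=cls,
                                depth=depth, branch_id=bid, parent_id=parent))
        if depth >= spec.branch_depth:
            return
        tip = pts[-1]
        d = pts[-1] - pts[-2]
        out_angle = math.atan2(d[0], d[1]) if np.hypot(*d) > 1e-9 else angle
        for sign in (+1.0, -1.0):
            spread = rng.uniform(0.3, 0.7)
            grow(tip, out_angle + sign * spread, width * spec.width_decay,
                 cls, depth + 1, bid)

    offset = rng.uniform(0.0, 2.0 * math.pi)
    for k, cls in enumerate(classes):
        phi = offset + 2.0 * math.pi * k / n_total + rng.normal(0.0, 0.05)
        start = np.array([cy + spec.disc_radius * math.sin(phi),
                          cx + spec.disc_radius * math.cos(phi)])
        width = (spec.root_width_artery if cls == ARTERY
                 else spec.root_width_vein)
        grow(start, phi, width, cls, 0, None)
    return segments


# -- rasterisation -------------------------------------------------------


def _stamp_capsules(mask: np.ndarray, pts: np.ndarray, radius: float) -> None:
    """Set mask pixels whose centre lies within ``radius`` of the polyline
    (exact point-to-segment distances, no anti-aliasing)."""
    h, w = mask.shape
    for a, b in zip(pts[:-1], pts[1:]):
        r0 = max(0, int(math.floor(min(a[0], b[0]) - radius - 1)))
        r1 = min(h - 1, int(math.ceil(max(a[0], b[0]) + radius + 1)))
        c0 = max(0, int(math.floor(min(a[1], b[1]) - radius - 1)))
        c1 = min(w - 1, int(math.ceil(max(a[1], b[1]) + radius + 1)))
        if r1 < r0 or c1 < c0:
            continue
        rr, cc = np.mgrid[r0:r1 + 1, c0:c1 + 1]
        v = b - a
        vv = float(v @ v)
        if vv < 1e-12:
            d2 = (rr - a[0]) ** 2 + (cc - a[1]) ** 2
        else:
            t = np.clip(((rr - a[0]) * v[0] + (cc - a[1]) * v[1]) / vv, 0.0, 1.0)
            d2 = (rr - (a[0] + t * v[0])) ** 2 + (cc - (a[1] + t * v[1])) ** 2
        mask[r0:r1 + 1, c0:c1 + 1] |= d2 <= radius * radius


def _centreline_pixels(pts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    rows, cols = [], []
    ipts = np.rint(pts).astype(int)
    for a, b in zip(ipts[:-1], ipts[1:]):
        rr, cc = _draw_line(a[0], a[1], b[0], b[1])
        rows.append(rr)
        cols.append(cc)
    return np.concatenate(rows), np.concatenate(cols)


def _true_calibres(spec: VesselTreeSpec, formula_mode: str):
    s = spec.micron_per_pixel
    c_a = morphometry.crae(spec.root_width_artery * s, spec.root_width_artery * s,
                           mode=formula_mode)
    c_v = morphometry.crve(spec.root_width_vein * s, spec.root_width_vein * s,
                           mode=formula_mode)
    return c_a, c_v, morphometry.avr(c_a, c_v)


def render_sample(spec: VesselTreeSpec,
                  formula_mode: str = "canonical") -> SyntheticSample:
    """Rasterise the vessel trees of ``spec`` into a full sample bundle."""
    spec.validate()
    segments = generate_tree(spec)
    h, w = spec.image_size
    artery_mask = np.zeros((h, w), dtype=bool)
    vein_mask = np.zeros((h, w), dtype=bool)
    reflex_mask = np.zeros((h, w), dtype=bool)
    width_map = np.zeros((h, w), dtype=float)

    for seg in segments:
        target = artery_mask if seg.vessel_class == ARTERY else vein_mask
        _stamp_capsules(target, seg.points, seg.width / 2.0)
        if seg.vessel_class == ARTERY:
            _stamp_capsules(reflex_mask, seg.points, max(0.5, seg.width / 6.0))
        rr, cc = _centreline_pixels(seg.points)
        width_map[rr, cc] = np.maximum(width_map[rr, cc], seg.width)

    vein_mask &= ~artery_mask            # arteries painted on top at overlaps
    vessel_mask = artery_mask | vein_mask
    av_labels = np.full((h, w), BACKGROUND, dtype=np.uint8)
    av_labels[vein_mask] = VEIN
    av_labels[artery_mask] = ARTERY
    width_map[~vessel_mask] = 0.0

    # background with a gentle illumination ramp and a bright disc
    rows, cols = np.mgrid[0:h, 0:w]
    gray = spec.background_intensity + 0.06 * (cols / max(w - 1, 1) - 0.5) \
        + 0.04 * (rows / max(h - 1, 1) - 0.5)
    cy, cx = spec.disc_center
    disc = (rows - cy) ** 2 + (cols - cx) ** 2 <= spec.disc_radius ** 2
    gray[disc] = min(1.0, spec.background_intensity + 0.55)

    gray[vein_mask] = spec.vein_intensity
    gray[artery_mask] = spec.artery_intensity
    reflex = reflex_mask & artery_mask
    gray[reflex] = spec.artery_intensity + spec.reflex_strength * (1.0 - spec.artery_intensity)

    if spec.noise_sd > 0:
        noise_rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
        gray = gray + noise_rng.normal(0.0, spec.noise_sd, size=gray.shape)
    gray = np.clip(gray, 0.0, 1.0)

    rgb = np.stack([
        np.clip(0.55 + 0.35 * gray, 0.0, 1.0),
        gray,
        np.clip(0.12 + 0.08 * gray, 0.0, 1.0),
    ], axis=-1)

    c_a, c_v, ratio = _true_calibres(spec, formula_mode)
    return SyntheticSample(
        image=FundusImage(rgb),
        vessel_mask=vessel_mask,
        av_labels=av_labels,
        width_map=width_map,
        true_crae=c_a,
        true_crve=c_v,
        true_avr=ratio,
        disc_center=spec.disc_center,
        disc_radius=spec.disc_radius,
        spec=spec,
        segments=segments,
    )


# -- presets -------------------------------------------------------------

# The hr preset narrows arteries and dilates veins so the canonical-mode
# AVR lands in the hypertensive 0.2-0.5 band; healthy sits near 0.67-0.70.
PRESETS: dict[str, dict] = {
    "healthy": {},
    "hr": {"root_width_artery": 5.0, "root_width_vein": 14.0},
}


def preset_spec(name: str, seed: int = 0, **overrides) -> VesselTreeSpec:
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    kwargs = dict(PRESETS[name])
    kwargs.update(overrides)
    return replace(VesselTreeSpec(seed=seed), **kwargs)


def spec_to_dict(spec: VesselTreeSpec) -> dict:
    return asdict(spec)
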