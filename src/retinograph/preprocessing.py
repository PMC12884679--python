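"""Fundus image normalisation, contrast enhancement and joint augmentation.

The enhancement chain is: green-channel extraction -> CLAHE -> mild
Gaussian denoising.  Global histogram equalisation is provided as a
standalone utility; CLAHE is the tiled, clip-limited version of the same
cumulative-histogram mapping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .labels import BACKGROUND

__all__ = [
    "FundusImage",
    "EnhancedImage",
    "AugmentPlan",
    "extract_green_normalized",
    "histogram_equalize",
    "clahe",
    "denoise",
    "enhance",
    "augment",
]


@dataclass
class FundusImage:
    """RGB fundus photograph with an optional field-of-view mask.

    ``pixels`` is H×W×3, either integer grey levels or floats in [0, 1].
    """

    pixels: np.ndarray
    fov_mask: np.ndarray | None = None
    colourspace: str = "rgb"

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError(
                f"FundusImage requires an H×W×3 array, got {self.pixels.shape}"
            )
        if self.fov_mask is not None:
            self.fov_mask = np.asarray(self.fov_mask)
            if self.fov_mask.shape != self.pixels.shape[:2]:
                raise ValueError("fov_mask shape must match image H×W")

    def as_float(self) -> np.ndarray:
        """Channels rescaled to [0, 1] floats."""
        px = self.pixels
        if np.issubdtype(px.dtype, np.integer):
            gmax = np.iinfo(px.dtype).max
            return px.astype(np.float64) / gmax
        return px.astype(np.float64)


@dataclass
class EnhancedImage:
    """Single-channel real image in [0, 1] with its transform history."""

    pixels: np.ndarray
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError(f"expected single-channel H×W image, got {self.pixels.shape}")

    def derived(self, pixels: np.ndarray, step: str) -> "EnhancedImage":
        return EnhancedImage(pixels, self.provenance + [step])


def extract_green_normalized(img: FundusImage, mode: str = "normalized") -> EnhancedImage:
    """Green-channel extraction.

    ``normalized`` mode computes G / (R + G + B) per pixel, with 0 where
    the denominator vanishes; ``raw`` returns the plain green channel.
    """
    px = img.as_float()
    r, g, b = px[..., 0], px[..., 1], px[..., 2]
    if mode == "raw":
        out = g
    elif mode == "normalized":
        denom = r + g + b
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(denom > 0, g / np.where(denom > 0, denom, 1.0), 0.0)
    else:
        raise ValueError(f"unknown green mode {mode!r}")
    return EnhancedImage(out, [f"green:{mode}"])


def _quantize(pixels: np.ndarray, levels: int) -> np.ndarray:
    return np.clip(np.rint(pixels * (levels - 1)), 0, levels - 1).astype(np.intp)


def _cdf_map(counts: np.ndarray, n0: int, gmax: int) -> np.ndarray:
    """Cumulative-histogram grey mapping: level g -> (gmax/n0)·Σ_{i<=g} counts."""
    return (gmax / n0) * np.cumsum(counts)


def histogram_equalize(img: EnhancedImage, levels: int = 256) -> EnhancedImage:
    """Global histogram equalisation on an L-level quantisation.

    Each input level GA maps to (Gmax/N0)·Σ_{i=0..GA} P_i where P_i are the
    level counts; the result is rescaled to [0, 1].  The mapping is monotone
    non-decreasing by construction.
    """
    if levels < 2:
        raise ValueError(f"levels must be >= 2, got {levels}")
    q = _quantize(img.pixels, levels)
    counts = np.bincount(q.ravel(), minlength=levels)
    lut = _cdf_map(counts, q.size, levels - 1) / (levels - 1)
    return img.derived(lut[q], f"hist_eq:L={levels}")


def _clipped_cdf_lut(counts: np.ndarray, clip_count: float, gmax: int) -> np.ndarray:
    """Per-tile LUT: clip the histogram, redistribute the excess uniformly,
    then apply the cumulative mapping rescaled to [0, 1]."""
    n0 = counts.sum()
    if n0 == 0:
        return np.linspace(0.0, 1.0, gmax + 1)
    clipped = np.minimum(counts, clip_count)
    excess = counts.sum() - clipped.sum()
    clipped = clipped + excess / counts.size
    return _cdf_map(clipped, n0, gmax) / gmax


def clahe(img: EnhancedImage, clip_limit: float = 2.0,
          tile_grid: tuple[int, int] = (8, 8), levels: int = 256) -> EnhancedImage:
    """Contrast-limited adaptive histogram equalisation.

    Applies the cumulative-histogram mapping per tile with histogram counts
    clipped at ``clip_limit`` times the uniform bin count, redistributing
    the excess, and blends neighbouring tile mappings bilinearly.  With one
    tile and an unbounded clip limit this reduces exactly to
    :func:`histogram_equalize`.
    """
    if clip_limit <= 0:
        raise ValueError(f"clip_limit must be positive, got {clip_limit}")
    ty, tx = tile_grid
    if ty < 1 or tx < 1:
        raise ValueError(f"tile grid dims must be >= 1, got {tile_grid}")
    h, w = img.pixels.shape
    q = _quantize(img.pixels, levels)
    gmax = levels - 1

    row_edges = np.linspace(0, h, ty + 1).astype(int)
    col_edges = np.linspace(0, w, tx + 1).astype(int)
    luts = np.empty((ty, tx, levels))
    centers_r = np.empty(ty)
    centers_c = np.empty(tx)
    for i in range(ty):
        centers_r[i] = 0.5 * (row_edges[i] + row_edges[i + 1] - 1)
        for j in range(tx):
            tile = q[row_edges[i]:row_edges[i + 1], col_edges[j]:col_edges[j + 1]]
            counts = np.bincount(tile.ravel(), minlength=levels).astype(float)
            clip_count = clip_limit * tile.size / levels
            luts[i, j] = _clipped_cdf_lut(counts, clip_count, gmax)
    for j in range(tx):
        centers_c[j] = 0.5 * (col_edges[j] + col_edges[j + 1] - 1)

    # bilinear blend of the four surrounding tile mappings
    rows = np.arange(h, dtype=float)
    cols = np.arange(w, dtype=float)
    i1 = np.clip(np.searchsorted(centers_r, rows) - 1, 0, ty - 1)
    i2 = np.clip(i1 + 1, 0, ty - 1)
    j1 = np.clip(np.searchsorted(centers_c, cols) - 1, 0, tx - 1)
    j2 = np.clip(j1 + 1, 0, tx - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        wr = np.where(i2 > i1, (rows - centers_r[i1]) / np.maximum(centers_r[i2] - centers_r[i1], 1e-12), 0.0)
        wc = np.where(j2 > j1, (cols - centers_c[j1]) / np.maximum(centers_c[j2] - centers_c[j1], 1e-12), 0.0)
    wr = np.clip(wr, 0.0, 1.0)[:, None]
    wc = np.clip(wc, 0.0, 1.0)[None, :]

    i1g = np.broadcast_to(i1[:, None], (h, w))
    i2g = np.broadcast_to(i2[:, None], (h, w))
    j1g = np.broadcast_to(j1[None, :], (h, w))
    j2g = np.broadcast_to(j2[None, :], (h, w))
    v11 = luts[i1g, j1g, q]
    v12 = luts[i1g, j2g, q]
    v21 = luts[i2g, j1g, q]
    v22 = luts[i2g, j2g, q]
    out = ((1 - wr) * ((1 - wc) * v11 + wc * v12)
           + wr * ((1 - wc) * v21 + wc * v22))
    return img.derived(out, f"clahe:clip={clip_limit},tiles={ty}x{tx}")


def denoise(img: EnhancedImage, sigma: float = 0.5) -> EnhancedImage:
    """Gaussian smoothing at scale sigma; sigma = 0 is the identity."""
    if sigma < 0:
        raise ValueError(f"sigma must be non-negative, got {sigma}")
    if sigma == 0:
        return img
    return img.derived(ndimage.gaussian_filter(img.pixels, sigma), f"denoise:sigma={sigma}")


def enhance(img: FundusImage, *, green_mode: str = "normalized",
            clip_limit: float = 2.0, tile_grid: tuple[int, int] = (8, 8),
            sigma: float = 0.5) -> EnhancedImage:
    """Full enhancement chain: green channel -> CLAHE -> denoise."""
    out = extract_green_normalized(img, mode=green_mode)
    out = clahe(out, clip_limit=clip_limit, tile_grid=tile_grid)
    return denoise(out, sigma=sigma)


# -- augmentation --------------------------------------------------------


@dataclass
class AugmentPlan:
    """Joint geometric/photometric augmentation recipe.

    The default angle set mixes small and moderate tilts with the three
    exact right-angle rotations.
    """

    angles: tuple[float, ...] = (20.0, -20.0, 40.0, -40.0, 60.0, -60.0,
                                 90.0, 180.0, 270.0)
    horizontal_flip: bool = True
    brightness_range: tuple[float, float] = (1.0, 1.0)
    scale_range: tuple[float, float] = (1.0, 1.0)
    seed: int = 0
    include_identity: bool = True


def _rotate(arr: np.ndarray, angle: float, order: int, cval: float) -> np.ndarray:
    if angle % 90 == 0:
        return np.ascontiguousarray(np.rot90(arr, k=int(angle // 90) % 4, axes=(0, 1)))
    return ndimage.rotate(arr, angle, axes=(1, 0), reshape=False, order=order,
                          cval=cval, prefilter=False)


def _rotate_mask(mask: np.ndarray, angle: float) -> np.ndarray:
    """Binary mask rotation: bilinear on the indicator, thresholded at 0.5.

    Less lossy on round trips than nearest-neighbour resampling, and by
    linearity exactly consistent with :func:`_rotate_labels`.
    """
    soft = _rotate(mask.astype(np.float32), angle, order=1, cval=0.0)
    return (soft >= 0.5).astype(mask.dtype)


def _rotate_labels(labels: np.ndarray, angle: float) -> np.ndarray:
    """Label-map rotation via bilinear one-hot voting.

    The vessel/background decision thresholds the summed vessel-class
    weight — identical to the rotated-mask indicator when the input mask
    equals the label support — and the class within the support is the
    argmax of the per-class weights.
    """
    classes = [c for c in np.unique(labels) if c != BACKGROUND]
    if not classes:
        return _rotate(labels, angle, order=0, cval=BACKGROUND)
    soft = np.stack([
        _rotate((labels == c).astype(np.float32), angle, order=1, cval=0.0)
        for c in classes
    ])
    support = soft.sum(axis=0) >= 0.5
    out = np.full(labels.shape, BACKGROUND, dtype=labels.dtype)
    winner = np.argmax(soft, axis=0)
    for i, c in enumerate(classes):
        out[support & (winner == i)] = c
    return out


def _rescale_keep_shape(arr: np.ndarray, factor: float, order: int,
                        cval: float) -> np.ndarray:
    """Zoom about the image centre, then crop or pad back to the original
    shape so all members of a triple stay aligned."""
    if factor == 1.0:
        return arr
    h, w = arr.shape[:2]
    zoom = [factor, factor] + [1.0] * (arr.ndim - 2)
    z = ndimage.zoom(arr, zoom, order=order, cval=cval, prefilter=False)
    out = np.full_like(arr, cval, shape=(h, w) + arr.shape[2:])
    zh, zw = z.shape[:2]
    r0, c0 = max(0, (zh - h) // 2), max(0, (zw - w) // 2)
    rr, cc = min(h, zh), min(w, zw)
    t0, u0 = max(0, (h - zh) // 2), max(0, (w - zw) // 2)
    out[t0:t0 + rr, u0:u0 + cc] = z[r0:r0 + rr, c0:c0 + cc]
    return out


def augment(img: np.ndarray, mask: np.ndarray, labels: np.ndarray,
            plan: AugmentPlan) -> list[tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Apply the augmentation plan jointly to an image, vessel mask and
    label map.

    Every output triple is transformed by the same geometric map; masks and
    labels are resampled nearest-neighbour, the image bilinearly.
    Brightness jitter affects the image only; scale jitter affects all
    three.  Exposed corners are filled with 0 / background.
    """
    img, mask, labels = np.asarray(img), np.asarray(mask), np.asarray(labels)
    if img.shape[:2] != mask.shape[:2] or mask.shape[:2] != labels.shape[:2]:
        raise ValueError(
            f"image/mask/label shapes differ: {img.shape[:2]} vs "
            f"{mask.shape[:2]} vs {labels.shape[:2]}"
        )
    rng = np.random.default_rng(plan.seed)
    geoms: list[tuple[float, bool]] = []
    if plan.include_identity:
        geoms.append((0.0, False))
    geoms.extend((a, False) for a in plan.angles)
    if plan.horizontal_flip:
        geoms.append((0.0, True))

    out = []
    for angle, flip in geoms:
        gi = np.fliplr(img).copy() if flip else img.copy()
        gm = np.fliplr(mask).copy() if flip else mask.copy()
        gl = np.fliplr(labels).copy() if flip else labels.copy()
        if angle != 0.0:
            gi = _rotate(gi, angle, order=1, cval=0.0)
            gm = _rotate_mask(gm, angle)
            gl = _rotate_labels(gl, angle)
        scale = float(rng.uniform(*plan.scale_range))
        if scale != 1.0:
            gi = _rescale_keep_shape(gi, scale, order=1, cval=0.0)
            gm = _rescale_keep_shape(gm, scale, order=0, cval=0)
            gl = _rescale_keep_shape(gl, scale, order=0, cval=BACKGROUND)
        bright = float(rng.uniform(*plan.brightness_range))
        if bright != 1.0:
            gi = np.clip(gi * bright, 0.0, 1.0)
        out.append((gi, gm, gl))
    return out
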