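"""Vessel calibre morphometry: centrelines, cross-section widths, CRAE,
CRVE and the arteriovenous ratio (AVR).

Widths are measured by marching perpendicular to the local centreline
orientation until the vessel mask is left; the width is the Euclidean
distance between the two opposite edge points.  The two widest artery and
vein branches inside an annulus around the optic disc feed the calibre
formulas.

Two formula modes are provided.  ``paper`` evaluates the combination
formulas exactly as printed in the source reference (no square root,
coefficient 1.00/1.72, constants 10.73/450.02); ``canonical`` evaluates
the classical Parr–Hubbard forms
sqrt(0.87·Da1² + 1.01·Da2² − 0.22·Da1·Da2 − 10.76) and
sqrt(0.72·Dv1² + 0.91·Dv2² + 450.05), which yield clinically plausible
magnitudes when diameters are supplied in micrometres.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from skimage.morphology import skeletonize as _skimage_skeletonize

from .labels import ARTERY, VEIN

__all__ = [
    "Centreline",
    "WidthMeasurement",
    "CalibreSummary",
    "InsufficientVesselsError",
    "skeletonize",
    "find_edge_pair",
    "vessel_width",
    "measure_branch",
    "assign_branch_class",
    "select_branches",
    "crae",
    "crve",
    "avr",
    "measure_calibres",
]


class InsufficientVesselsError(ValueError):
    """Fewer than two artery or vein branches found in the annulus."""


@dataclass
class Centreline:
    """An ordered 8-connected run of skeleton pixels forming one branch."""

    pixels: np.ndarray          # (k, 2) int array of (row, col)
    branch_id: int
    theta: np.ndarray = field(default=None)  # local orientation per pixel, radians
    vessel_class: int | None = None          # ARTERY / VEIN, assigned from labels


@dataclass
class WidthMeasurement:
    centre: tuple[int, int]
    edge_a: tuple[float, float]
    edge_b: tuple[float, float]
    width: float


@dataclass
class CalibreSummary:
    da1: float
    da2: float
    dv1: float
    dv2: float
    crae: float
    crve: float
    avr: float
    formula_mode: str
    micron_per_pixel: float = 1.0

    def to_dict(self) -> dict:
        return {
            "Da1": self.da1, "Da2": self.da2, "Dv1": self.dv1, "Dv2": self.dv2,
            "crae": self.crae, "crve": self.crve, "avr": self.avr,
            "mode": self.formula_mode, "micron_per_pixel": self.micron_per_pixel,
        }


# -- centrelines ---------------------------------------------------------


_NEIGHBOURS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def _order_branch(pixels: set[tuple[int, int]]) -> np.ndarray:
    """Order a set of 8-connected pixels into a path, starting from an
    endpoint when one exists."""
    def nbrs(p):
        return [(p[0] + dr, p[1] + dc) for dr, dc in _NEIGHBOURS
                if (p[0] + dr, p[1] + dc) in pixels]

    start = None
    for p in sorted(pixels):
        if len(nbrs(p)) <= 1:
            start = p
            break
    if start is None:                       # cycle: start anywhere, stable
        start = min(pixels)
    order = [start]
    visited = {start}
    cur = start
    while True:
        nxt = [q for q in nbrs(cur) if q not in visited]
        if not nxt:
            break
        cur = min(nxt, key=lambda q: (abs(q[0] - cur[0]) + abs(q[1] - cur[1]), q))
        order.append(cur)
        visited.add(cur)
    # append any stragglers (tiny side spurs inside the branch component)
    for p in sorted(pixels - visited):
        order.append(p)
    return np.array(order, dtype=int)


def _local_orientation(skel: np.ndarray, pixels: np.ndarray, window: int = 3) -> np.ndarray:
    """Orientation of the principal axis of skeleton pixels in a local
    window, in radians measured in (x=col, y=row) convention."""
    rows, cols = np.nonzero(skel)
    pts = np.column_stack([rows, cols])
    theta = np.zeros(len(pixels))
    for i, (r, c) in enumerate(pixels):
        sel = pts[(np.abs(pts[:, 0] - r) <= window) & (np.abs(pts[:, 1] - c) <= window)]
        if len(sel) < 2:
            theta[i] = 0.0
            continue
        y = sel[:, 0] - sel[:, 0].mean()
        x = sel[:, 1] - sel[:, 1].mean()
        cov = np.array([[x @ x, x @ y], [x @ y, y @ y]])
        vals, vecs = np.linalg.eigh(cov)
        vx, vy = vecs[:, np.argmax(vals)]
        theta[i] = math.atan2(vy, vx)
    return theta


def skeletonize(mask: np.ndarray) -> list[Centreline]:
    """Thin a binary mask to one-pixel centrelines and split them into
    branches at junction pixels (three or more skeleton neighbours)."""
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        return []
    skel = _skimage_skeletonize(mask)
    # neighbour count per skeleton pixel
    from scipy import ndimage
    kernel = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]])
    ncount = ndimage.convolve(skel.astype(int), kernel, mode="constant")
    junctions = skel & (ncount >= 3)
    branches_img = skel & ~junctions
    lab, n = ndimage.label(branches_img, structure=np.ones((3, 3), dtype=int))
    out = []
    for bid in range(1, n + 1):
        pix = set(map(tuple, np.argwhere(lab == bid)))
        ordered = _order_branch(pix)
        theta = _local_orientation(skel, ordered)
        out.append(Centreline(pixels=ordered, branch_id=bid, theta=theta))
    return out


# -- widths --------------------------------------------------------------


def _bilinear(mask: np.ndarray, r: float, c: float) -> float:
    h, w = mask.shape
    if r < -0.5 or c < -0.5 or r > h - 0.5 or c > w - 0.5:
        return 0.0
    r0, c0 = int(np.floor(r)), int(np.floor(c))
    fr, fc = r - r0, c - c0
    val = 0.0
    for dr, wr in ((0, 1 - fr), (1, fr)):
        for dc, wc in ((0, 1 - fc), (1, fc)):
            rr, cc = r0 + dr, c0 + dc
            if 0 <= rr < h and 0 <= cc < w:
                val += wr * wc * float(mask[rr, cc])
    return val


def find_edge_pair(mask: np.ndarray, centre: tuple[int, int], theta: float,
                   subpixel: bool = False, step: float = 0.25,
                   max_march: float = 100.0):
    """March from a centreline pixel perpendicular to the vessel
    orientation in both directions until leaving the mask.

    In pixel mode the last in-mask pixel on each side is returned; in
    subpixel mode the 0.5-crossing of the bilinearly interpolated mask is
    returned, which removes the digitisation bias at oblique orientations.
    """
    mask = np.asarray(mask).astype(bool)
    r0, c0 = centre
    if not mask[r0, c0]:
        raise ValueError(f"centre {centre} is not inside the vessel mask")
    # theta is the tangent angle in (x=col, y=row) convention: tangent
    # (cos t, sin t), perpendicular (-sin t, cos t)
    pdx, pdy = -math.sin(theta), math.cos(theta)
    edges = []
    for sign in (+1.0, -1.0):
        last_in = (float(r0), float(c0))
        t = step
        while t <= max_march:
            rr = r0 + sign * t * pdy
            cc = c0 + sign * t * pdx
            if subpixel:
                inside = _bilinear(mask, rr, cc) >= 0.5
            else:
                ri, ci = int(round(rr)), int(round(cc))
                inside = (0 <= ri < mask.shape[0] and 0 <= ci < mask.shape[1]
                          and mask[ri, ci])
            if not inside:
                break
            last_in = (rr, cc) if subpixel else (float(int(round(rr))), float(int(round(cc))))
            t += step
        edges.append(last_in)
    return tuple(edges)


def vessel_width(edge_a, edge_b) -> float:
    """Euclidean distance between the two opposite edge points."""
    (ra, ca), (rb, cb) = edge_a, edge_b
    return math.hypot(ra - rb, ca - cb)


def measure_branch(mask: np.ndarray, centreline: Centreline,
                   subpixel: bool = True) -> list[WidthMeasurement]:
    out = []
    for (r, c), th in zip(centreline.pixels, centreline.theta):
        try:
            ea, eb = find_edge_pair(mask, (int(r), int(c)), float(th), subpixel=subpixel)
        except ValueError:
            continue
        out.append(WidthMeasurement(centre=(int(r), int(c)), edge_a=ea, edge_b=eb,
                                    width=vessel_width(ea, eb)))
    return out


def assign_branch_class(centreline: Centreline, labels: np.ndarray) -> int | None:
    """Majority artery/vein vote of the label map along the branch."""
    vals = labels[centreline.pixels[:, 0], centreline.pixels[:, 1]]
    n_a = int(np.sum(vals == ARTERY))
    n_v = int(np.sum(vals == VEIN))
    if n_a == 0 and n_v == 0:
        return None
    return ARTERY if n_a >= n_v else VEIN


# -- calibre formulas ----------------------------------------------------


def crae(da1: float, da2: float, mode: str = "paper") -> float:
    """Central retinal artery equivalent from the two widest artery
    diameters (da1 >= da2)."""
    if da1 < 0 or da2 < 0:
        raise ValueError("diameters must be non-negative")
    if mode == "paper":
        return da1 ** 2 + 1.01 * da2 ** 2 - 0.22 * da1 * da2 - 10.73
    if mode == "canonical":
        rad = 0.87 * da1 ** 2 + 1.01 * da2 ** 2 - 0.22 * da1 * da2 - 10.76
        if rad < 0:
            raise ValueError(f"canonical CRAE radicand negative ({rad:.3f}); "
                             "diameters too small")
        return math.sqrt(rad)
    raise ValueError(f"unknown formula mode {mode!r}")


def crve(dv1: float, dv2: float, mode: str = "paper") -> float:
    """Central retinal vein equivalent from the two widest vein diameters."""
    if dv1 < 0 or dv2 < 0:
        raise ValueError("diameters must be non-negative")
    if mode == "paper":
        return 1.72 * dv1 ** 2 + 0.91 * dv2 ** 2 + 450.02
    if mode == "canonical":
        return math.sqrt(0.72 * dv1 ** 2 + 0.91 * dv2 ** 2 + 450.05)
    raise ValueError(f"unknown formula mode {mode!r}")


def avr(crae_value: float, crve_value: float) -> float:
    """Arteriovenous ratio CRAE / CRVE."""
    if crve_value <= 0:
        raise ValueError(f"CRVE must be positive for AVR, got {crve_value}")
    return crae_value / crve_value


# -- branch selection and the full measurement ---------------------------


def select_branches(branch_widths: list[tuple[int, int, float]],
                    ) -> tuple[float, float, float, float]:
    """Pick the two largest artery and vein representative diameters.

    ``branch_widths`` holds (branch_id, vessel_class, median_width) rows for
    branches inside the annulus.  Ties are resolved stably by branch id.
    Raises InsufficientVesselsError when either class has fewer than two
    branches.
    """
    arteries = sorted((w for _, cls, w in sorted(branch_widths) if cls == ARTERY),
                      reverse=True)
    veins = sorted((w for _, cls, w in sorted(branch_widths) if cls == VEIN),
                   reverse=True)
    if len(arteries) < 2 or len(veins) < 2:
        raise InsufficientVesselsError(
            f"need >=2 artery and >=2 vein branches in the annulus, "
            f"found {len(arteries)} artery / {len(veins)} vein"
        )
    return arteries[0], arteries[1], veins[0], veins[1]


def measure_calibres(mask: np.ndarray, labels: np.ndarray,
                     disc_center: tuple[float, float], disc_radius: float,
                     annulus: tuple[float, float] = (2.0, 3.0),
                     formula_mode: str = "paper",
                     micron_per_pixel: float = 1.0,
                     subpixel: bool = True):
    """End-to-end morphometry: skeletonise, measure widths inside the
    annulus, select the two widest branches per class and evaluate the
    calibre formulas.

    Returns (CalibreSummary, branch_table) where branch_table rows are
    dicts with branch_id, class, n_samples, median_width.
    """
    mask = np.asarray(mask).astype(bool)
    labels = np.asarray(labels)
    inner = annulus[0] * disc_radius
    outer = annulus[1] * disc_radius
    cy, cx = disc_center
    rows = []
    for branch in skeletonize(mask):
        cls = assign_branch_class(branch, labels)
        if cls is None:
            continue
        branch.vessel_class = cls
        d = np.hypot(branch.pixels[:, 0] - cy, branch.pixels[:, 1] - cx)
        in_ring = (d >= inner) & (d <= outer)
        if not in_ring.any():
            continue
        sub = Centreline(pixels=branch.pixels[in_ring], branch_id=branch.branch_id,
                         theta=branch.theta[in_ring], vessel_class=cls)
        widths = [m.width for m in measure_branch(mask, sub, subpixel=subpixel)]
        if not widths:
            continue
        rows.append({"branch_id": branch.branch_id, "class": cls,
                     "n_samples": len(widths),
                     "median_width": float(np.median(widths))})
    da1, da2, dv1, dv2 = select_branches(
        [(r["branch_id"], r["class"], r["median_width"]) for r in rows])
    s = micron_per_pixel
    c_a = crae(da1 * s, da2 * s, mode=formula_mode)
    c_v = crve(dv1 * s, dv2 * s, mode=formula_mode)
    summary = CalibreSummary(da1=da1, da2=da2, dv1=dv1, dv2=dv2,
                             crae=c_a, crve=c_v, avr=avr(c_a, c_v),
                             formula_mode=formula_mode, micron_per_pixel=s)
    return summary, rows
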