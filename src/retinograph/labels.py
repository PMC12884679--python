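"""Artery/vein label codes and their RGB colour convention.

Label maps are stored in memory as uint8 code arrays and on disk as RGB
images: artery = red, vein = blue, undefined vessel = green, background =
black.
"""

from __future__ import annotations

import numpy as np

BACKGROUND = 0
ARTERY = 1
VEIN = 2
UNDEFINED = 3

CODE_TO_RGB = {
    BACKGROUND: (0, 0, 0),
    ARTERY: (255, 0, 0),
    VEIN: (0, 0, 255),
    UNDEFINED: (0, 255, 0),
}
RGB_TO_CODE = {v: k for k, v in CODE_TO_RGB.items()}


def labels_to_rgb(codes: np.ndarray) -> np.ndarray:
    """Convert an H×W uint8 code array to an H×W×3 uint8 RGB image."""
    codes = np.asarray(codes)
    rgb = np.zeros(codes.shape + (3,), dtype=np.uint8)
    for code, colour in CODE_TO_RGB.items():
        rgb[codes == code] = colour
    return rgb


def rgb_to_labels(rgb: np.ndarray) -> np.ndarray:
    """Convert an RGB label image back to codes.

    Raises ValueError naming the first offending pixel if a colour outside
    the convention is found.
    """
    rgb = np.asarray(rgb)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError(f"expected H×W×3 RGB label image, got shape {rgb.shape}")
    codes = np.full(rgb.shape[:2], 255, dtype=np.uint8)
    for colour, code in RGB_TO_CODE.items():
        codes[np.all(rgb == colour, axis=2)] = code
    bad = np.argwhere(codes == 255)
    if bad.size:
        r, c = bad[0]
        raise ValueError(
            f"unknown label colour {tuple(int(v) for v in rgb[r, c])} "
            f"at pixel (row={r}, col={c})"
        )
    return codes
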