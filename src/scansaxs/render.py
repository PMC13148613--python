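"""Map rendering: region mosaics, HSV orientation maps, scalar ratio maps.

Orientation maps follow the colourwheel convention: hue encodes the
scattering direction theta_s over the 180-degree wheel; in ``hue-value``
mode saturation is 1 and value encodes the anisotropic amplitude a_asym,
in ``hsv`` mode value encodes a_sym and saturation a_asym.  Channels are
rescaled to configurable percentiles (default 1st-99th) so a few extreme
points cannot flatten the map.
"""

from __future__ import annotations

import numpy as np
from matplotlib.colors import hsv_to_rgb
from PIL import Image

from .scan import (REGION_BACKGROUND, REGION_COLLAGEN, REGION_MUSCLE,
                   REGION_OTHER)

REGION_COLORS = {
    REGION_BACKGROUND: (0, 0, 0),
    REGION_COLLAGEN: (230, 230, 230),
    REGION_MUSCLE: (255, 140, 0),
    REGION_OTHER: (34, 139, 34),
}


def render_region_map(label: np.ndarray) -> np.ndarray:
    """RGB uint8 image of a region label map (row 0 at the top)."""
    out = np.zeros(label.shape + (3,), dtype=np.uint8)
    for code, color in REGION_COLORS.items():
        out[label == code] = color
    return out


def _scale(values: np.ndarray, percentiles: tuple[float, float]) -> np.ndarray:
    finite = values[np.isfinite(values)]
    if finite.size == 0:
        return np.zeros_like(values)
    lo, hi = np.percentile(finite, percentiles)
    if hi <= lo:
        scaled = np.where(np.isfinite(values) & (values >= lo), 1.0, 0.0)
        return scaled
    scaled = np.clip((values - lo) / (hi - lo), 0.0, 1.0)
    return np.where(np.isfinite(values), scaled, 0.0)


def render_orientation_map(theta: np.ndarray, a_asym: np.ndarray,
                           a_sym: np.ndarray | None = None,
                           mode: str = "hue-value",
                           percentiles: tuple[float, float] = (1.0, 99.0),
                           ) -> np.ndarray:
    """RGB uint8 orientation map.

    ``theta`` in degrees [0, 180) (NaN -> black pixel); ``a_asym`` and
    ``a_sym`` congruent amplitude maps.
    """
    hue = np.where(np.isfinite(theta), (theta % 180.0) / 180.0, 0.0)
    if mode == "hue-value":
        sat = np.ones_like(hue)
        val = _scale(a_asym, percentiles)
    elif mode in ("hsv", "hue-saturation-value"):
        if a_sym is None:
            raise ValueError("hsv mode needs a_sym")
        sat = _scale(a_asym, percentiles)
        val = _scale(a_sym, percentiles)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    val = np.where(np.isfinite(theta), val, 0.0)
    rgb = hsv_to_rgb(np.dstack([hue, sat, val]))
    return (rgb * 255).astype(np.uint8)


def render_value_map(values: np.ndarray,
                     percentiles: tuple[float, float] = (1.0, 99.0),
                     ) -> np.ndarray:
    """Grayscale (as RGB) rendering of a scalar per-point map."""
    v = _scale(values, percentiles)
    g = (v * 255).astype(np.uint8)
    return np.dstack([g, g, g])


def save_png(rgb: np.ndarray, path: str) -> None:
    Image.fromarray(rgb, mode="RGB").save(path)
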