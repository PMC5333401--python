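"""Shoot traits from overhead images: leaf area and leaf hue.

Against the white plinth, shoot material is simply the coloured part of
the image: pixels saturated enough not to be white/grey and bright
enough not to be shadow.  ``leaf_area`` is the coloured-pixel count —
the projected rosette area, an underestimate of true leaf area once
leaves overlap.  ``leaf_hue`` is the mean pixel hue on a bounded
red(0)-green(120) axis: hues beyond green toward blue clamp to 120 and
hues wrapping into magenta/red clamp to 0, because healthy-to-stressed
Arabidopsis shoots occupy the red-yellow-green sector.  Hue is a ratio
of chromatic components, so it is invariant under uniform brightness
scaling — a greenness indicator unconfounded by illumination.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.color import rgb2hsv

__all__ = ["ShootTraits", "segment_shoot", "leaf_hue", "analyze_top_well"]


@dataclass
class ShootTraits:
    """Per-well shoot readouts; ``leaf_hue`` is NaN when no shoot is found."""

    leaf_area: int
    leaf_hue: float
    hue_defined: bool
    n_shoot_pixels_used: int

    def to_dict(self) -> dict:
        return {
            "leaf_area": self.leaf_area,
            "leaf_hue": self.leaf_hue if self.hue_defined else float("nan"),
            "hue_defined": self.hue_defined,
        }


def _as_float_rgb(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image)
    if img.dtype == np.uint8:
        img = img.astype(float) / 255.0
    elif img.dtype == np.uint16:
        img = img.astype(float) / 65535.0
    else:
        img = img.astype(float)
    if img.ndim != 3 or img.shape[2] < 3:
        raise ValueError("overhead image must be RGB")
    return img[:, :, :3]


def segment_shoot(
    top_image: np.ndarray,
    saturation_min: float = 0.15,
    value_min: float = 0.05,
) -> np.ndarray:
    """Boolean mask of coloured (shoot) pixels in an overhead image.

    White background, grey shadows and black borders all have low
    saturation; near-black pixels are additionally excluded by the value
    floor because their hue is numerically meaningless.
    """
    hsv = rgb2hsv(_as_float_rgb(top_image))
    return (hsv[:, :, 1] >= saturation_min) & (hsv[:, :, 2] >= value_min)


def leaf_hue(top_image: np.ndarray, shoot_mask: np.ndarray) -> tuple[float, bool]:
    """Mean shoot hue on the red(0)-green(120) scale.

    Per-pixel hue on the 360-degree wheel is clamped into [0, 120]
    (hues in (120, 300] -> 120; hues beyond 300 -> 0) and averaged over
    the mask.  Returns ``(hue, defined)``; an empty mask yields
    ``(nan, False)`` rather than a number.
    """
    mask = np.asarray(shoot_mask, dtype=bool)
    if not mask.any():
        return float("nan"), False
    hsv = rgb2hsv(_as_float_rgb(top_image))
    h = hsv[:, :, 0][mask] * 360.0
    h = np.where(h > 300.0, 0.0, np.minimum(h, 120.0))
    return float(h.mean()), True


def analyze_top_well(
    top_image: np.ndarray,
    saturation_min: float = 0.15,
    value_min: float = 0.05,
) -> ShootTraits:
    """Full overhead chain: shoot mask, area count, mean clamped hue."""
    mask = segment_shoot(top_image, saturation_min, value_min)
    area = int(mask.sum())
    hue, defined = leaf_hue(top_image, mask)
    return ShootTraits(
        leaf_area=area,
        leaf_hue=hue,
        hue_defined=defined,
        n_shoot_pixels_used=area,
    )
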