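"""5-channel RGBHS feature construction.

Calibrated RGB images are converted to HSV, the hue and saturation channels
are appended to R, G, B, and a median filter is run channel-wise. The value
(V) channel is computed but deliberately not stacked: hue and saturation
carry the peel-color information that separates black, purple and green
olives, while V mostly tracks illumination.

Hue is kept as a linear coordinate in [0, 1): the median filter and the
downstream Euclidean metric treat it like any other channel, without circular
wraparound. An optional circular median is provided for comparison, but the
naive linear treatment is the default behavior of the pipeline.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage import color as skcolor

__all__ = ["rgb_to_hsv", "median_filter", "build_rgbhs", "CHANNEL_NAMES"]

CHANNEL_NAMES = ("r", "g", "b", "h", "s")


def rgb_to_hsv(image: np.ndarray) -> np.ndarray:
    """Hexcone RGB -> HSV conversion on float images in [0, 1].

    H is scaled so the full hue circle is [0, 1); achromatic pixels (S = 0)
    get H = 0 by convention. Output channels are H, S, V.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 3 or image.shape[-1] != 3:
        raise ValueError(f"expected an (H, W, 3) image, got shape {image.shape}")
    hsv = skcolor.rgb2hsv(image)
    hsv[..., 0] = np.where(hsv[..., 1] == 0.0, 0.0, hsv[..., 0])
    # rgb2hsv can return H == 1.0 for reds approached from below; fold to [0,1)
    hsv[..., 0] = np.where(hsv[..., 0] >= 1.0, 0.0, hsv[..., 0])
    return hsv


def median_filter(channel: np.ndarray, window: int) -> np.ndarray:
    """Median filter a 2-D channel with a square window; edges replicate.

    ``window`` must be odd; a window of 1 is the identity.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be an odd integer >= 1, got {window}")
    channel = np.asarray(channel, dtype=np.float64)
    if channel.ndim != 2:
        raise ValueError(f"expected a 2-D channel, got shape {channel.shape}")
    if window == 1:
        return channel.copy()
    return ndimage.median_filter(channel, size=window, mode="nearest")


def build_rgbhs(
    image: np.ndarray,
    window: int = 5,
    filter_channels: str = "all",
) -> np.ndarray:
    """Build the (H, W, 5) RGBHS stack from a calibrated RGB image.

    Channels are R, G, B, hue, saturation, each median-filtered with the
    given square window. ``filter_channels`` selects which channels are
    smoothed: ``"all"`` (default) or ``"hs"`` to filter only hue and
    saturation and leave R, G, B untouched.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 3 or image.shape[-1] != 3:
        raise ValueError(f"expected an (H, W, 3) image, got shape {image.shape}")
    if filter_channels not in ("all", "hs"):
        raise ValueError("filter_channels must be 'all' or 'hs'")
    hsv = rgb_to_hsv(image)
    stack = np.dstack([image, hsv[..., 0], hsv[..., 1]])
    filtered = np.empty_like(stack)
    for c in range(5):
        if filter_channels == "hs" and c < 3:
            filtered[..., c] = stack[..., c]
        else:
            filtered[..., c] = median_filter(stack[..., c], window)
    return np.clip(filtered, 0.0, 1.0)
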