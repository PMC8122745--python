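"""Image reading and writing helpers.

All in-memory images are float64 arrays in [0, 1]; 8-bit quantization happens
only on write. Alpha channels are dropped on read.
"""

from __future__ import annotations

import os

import imageio.v3 as iio
import numpy as np

__all__ = ["load_rgb", "save_rgb", "load_labels", "save_labels", "save_gray"]


def load_rgb(path: str | os.PathLike) -> np.ndarray:
    """Read an RGB image (PNG/TIFF/JPEG) as a (H, W, 3) float array in [0, 1]."""
    raw = iio.imread(path)
    if raw.ndim == 2:
        raw = np.stack([raw] * 3, axis=-1)
    if raw.shape[-1] == 4:
        raw = raw[..., :3]
    if raw.shape[-1] != 3:
        raise ValueError(f"expected a 3-channel image, got shape {raw.shape}")
    if raw.dtype == np.uint8:
        return raw.astype(np.float64) / 255.0
    if raw.dtype == np.uint16:
        return raw.astype(np.float64) / 65535.0
    img = raw.astype(np.float64)
    if img.max() > 1.0 + 1e-9:
        img = img / 255.0
    return np.clip(img, 0.0, 1.0)


def save_rgb(path: str | os.PathLike, image: np.ndarray) -> None:
    """Write a float [0, 1] RGB image as 8-bit."""
    arr = np.clip(np.asarray(image, dtype=np.float64), 0.0, 1.0)
    iio.imwrite(path, (np.round(arr * 255.0)).astype(np.uint8))


def save_gray(path: str | os.PathLike, image: np.ndarray) -> None:
    """Write a single-channel uint8 image."""
    iio.imwrite(path, np.asarray(image, dtype=np.uint8))


def save_labels(path: str | os.PathLike, labels: np.ndarray) -> None:
    """Write a label map (small integer codes) as single-channel 8-bit PNG."""
    iio.imwrite(path, np.asarray(labels, dtype=np.uint8))


def load_labels(path: str | os.PathLike) -> np.ndarray:
    """Read a label map written by :func:`save_labels`."""
    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr[..., 0]
    return arr.astype(np.uint8)
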