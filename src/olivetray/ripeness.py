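"""Ripeness statistics from a segmented tray image.

The per-tray statistic is the ripe fraction: the percentage of black-olive
pixels among all olive pixels (black + green + purple). Purple olives count
in the denominator only — they are turning but not yet ripe. A ternary
visualization renders ripe olives white, unripe (green) olives gray and
everything else black.

The classical Jaen maturity index is also provided: 100 fruits are binned
into color categories 0 (deep green) through 7 (fully black), and

    MI = (A*0 + B*1 + C*2 + D*3 + E*4 + F*5 + G*6 + H*7) / 100

with A..H the per-category counts. MI lies in [0, 7].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .segmentation import CLASS_NAMES, OLIVE_CLASSES, class_code

__all__ = [
    "RipenessEstimate",
    "estimate_ripe_fraction",
    "render_ternary_mask",
    "jaen_maturity_index",
    "batch_report",
    "interval_accuracy",
]

TERNARY_WHITE = 255
TERNARY_GRAY = 128
TERNARY_BLACK = 0


@dataclass
class RipenessEstimate:
    """Per-class pixel counts and the ripe-olive percentage for one tray."""

    pixel_counts: dict[str, int]
    olive_pixels: int
    ripe_fraction: float | None  # percentage in [0, 100]; None if no olives
    tray_id: str = ""

    @property
    def defined(self) -> bool:
        return self.ripe_fraction is not None


def estimate_ripe_fraction(segmap: np.ndarray, tray_id: str = "") -> RipenessEstimate:
    """Reduce a 7-class segmentation map to the ripe-olive percentage.

    ripe_fraction = 100 * n(black) / [n(black) + n(green) + n(purple)].
    An image with no olive pixels returns a flagged undefined estimate
    (``ripe_fraction is None``) rather than a silent zero.
    """
    segmap = np.asarray(segmap)
    if segmap.ndim != 2:
        raise ValueError(f"expected a 2-D label map, got shape {segmap.shape}")
    if segmap.size and (segmap.min() < 0 or segmap.max() >= len(CLASS_NAMES)):
        raise ValueError("label map contains codes outside 0-6")
    counts = np.bincount(segmap.ravel(), minlength=len(CLASS_NAMES))
    pixel_counts = {name: int(counts[i]) for i, name in enumerate(CLASS_NAMES)}
    olive = sum(pixel_counts[c] for c in OLIVE_CLASSES)
    if olive == 0:
        frac = None
    else:
        frac = 100.0 * pixel_counts["black_olive"] / olive
    return RipenessEstimate(
        pixel_counts=pixel_counts,
        olive_pixels=olive,
        ripe_fraction=frac,
        tray_id=tray_id,
    )


def render_ternary_mask(segmap: np.ndarray) -> np.ndarray:
    """Render the three-tone visualization of a segmentation map.

    Black-olive pixels become white (255), green-olive pixels gray (128),
    everything else black (0). Returns a uint8 image.
    """
    segmap = np.asarray(segmap)
    out = np.full(segmap.shape, TERNARY_BLACK, dtype=np.uint8)
    out[segmap == class_code("black_olive")] = TERNARY_WHITE
    out[segmap == class_code("green_olive")] = TERNARY_GRAY
    return out


def jaen_maturity_index(counts) -> float:
    """Jaen maturity index from 8 per-category fruit counts.

    ``counts`` maps categories 0-7 (A-H) to fruit counts; accepts a sequence
    of 8 numbers or a mapping with keys ``A``-``H`` or ``category_0``-``7``.
    The canonical sample is 100 fruits; other totals are normalized by the
    actual sum with a warning.
    """
    if isinstance(counts, dict):
        letters = [chr(ord("A") + i) for i in range(8)]
        if all(l in counts for l in letters):
            arr = np.array([counts[l] for l in letters], dtype=np.float64)
        elif all(f"category_{i}" in counts for i in range(8)):
            arr = np.array([counts[f"category_{i}"] for i in range(8)], dtype=np.float64)
        else:
            raise ValueError("count mapping needs keys A-H or category_0-category_7")
    else:
        arr = np.asarray(counts, dtype=np.float64).reshape(-1)
    if arr.shape != (8,):
        raise ValueError(f"expected 8 category counts, got {arr.shape}")
    if np.any(arr < 0):
        raise ValueError("category counts must be non-negative")
    total = arr.sum()
    if total == 0:
        raise ValueError("all category counts are zero")
    if abs(total - 100.0) > 1e-9:
        warnings.warn(
            f"category counts sum to {total:g}, not the canonical 100; "
            "normalizing by the actual sum",
            stacklevel=2,
        )
    return float(np.dot(arr, np.arange(8)) / total)


def batch_report(estimates: list[RipenessEstimate]) -> pd.DataFrame:
    """Tabulate tray estimates, sorted ascending by ripe fraction.

    Undefined (no-olive) estimates sort last and are flagged. The sort is
    stable, so trays with equal fractions keep their input order.
    """
    if not estimates:
        raise ValueError("need at least one estimate")
    rows = []
    for i, est in enumerate(estimates):
        row = {"tray_id": est.tray_id or str(i)}
        for name in CLASS_NAMES:
            row[f"count_{name}"] = est.pixel_counts[name]
        row["olive_pixels"] = est.olive_pixels
        row["ripe_fraction_percent"] = est.ripe_fraction
        row["flags"] = "" if est.defined else "no_olives"
        rows.append(row)
    df = pd.DataFrame(rows)
    return df.sort_values(
        "ripe_fraction_percent", kind="stable", na_position="last"
    ).reset_index(drop=True)


def interval_accuracy(
    estimates: list[float],
    manual_1: list[float],
    manual_2: list[float],
) -> float:
    """Share of trays whose estimate falls inside the two-operator interval.

    Two manual evaluations of the same trays bracket a confidence interval
    per tray; the accuracy is the percentage of trays where the automatic
    ripe-fraction estimate lies within [min, max] of the two manual values.
    """
    est = np.asarray(estimates, dtype=np.float64)
    m1 = np.asarray(manual_1, dtype=np.float64)
    m2 = np.asarray(manual_2, dtype=np.float64)
    if not (est.shape == m1.shape == m2.shape) or est.ndim != 1 or est.size == 0:
        raise ValueError("estimates and both manual columns must be equal-length 1-D")
    lo = np.minimum(m1, m2)
    hi = np.maximum(m1, m2)
    inside = (est >= lo) & (est <= hi)
    return 100.0 * inside.mean()
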