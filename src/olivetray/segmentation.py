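"""k-NN pixel segmentation into the 7 tray-scene classes.

The scene alphabet is fixed: background, yellow tray, red tray, leaves, and
black / purple / green olives. The training set is built from user-annotated
square patches (default 10x10 pixels) of a processed 5-channel image: each
patch contributes one labeled 5-vector, its per-channel mean. Classification
is per pixel: every pixel's 5-vector is assigned the majority class among its
k nearest training vectors under plain Euclidean distance in 5-space (all
channels weighted equally, k = 5 by default).

Tie rules, chosen to make the result deterministic and independent of
training-set order:

* neighbor selection — when several training vectors sit at exactly the
  distance of the k-th neighbor, the ones with lower class code are taken;
* vote ties — broken in favor of the class whose nearest neighbor among the
  tied classes is closest (distance ties again resolved toward the lower
  class code).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CLASS_NAMES",
    "OLIVE_CLASSES",
    "class_code",
    "TrainingPatch",
    "TrainingSet",
    "extract_patches",
    "build_training_set",
    "classify_pixels",
    "save_training_set",
    "load_training_set",
    "PatchBoundsError",
    "TrainingSetError",
]

CLASS_NAMES = (
    "background",
    "yellow_tray",
    "red_tray",
    "leaves",
    "black_olive",
    "purple_olive",
    "green_olive",
)
OLIVE_CLASSES = ("black_olive", "purple_olive", "green_olive")
_CODE = {name: i for i, name in enumerate(CLASS_NAMES)}


def class_code(label: str) -> int:
    """Map a class label to its integer code (0-6)."""
    try:
        return _CODE[label]
    except KeyError:
        raise ValueError(
            f"unknown class label {label!r}; expected one of {CLASS_NAMES}"
        ) from None


class PatchBoundsError(Exception):
    """One or more training patches extend beyond the image."""


class TrainingSetError(Exception):
    """The training set violates an invariant (e.g. an empty class)."""


@dataclass
class TrainingPatch:
    """A labeled mean 5-vector extracted from one square patch."""

    class_label: str
    feature: np.ndarray  # (5,) in [0, 1]
    source: str = ""
    center: tuple[int, int] = (0, 0)
    patch_size: int = 10

    def __post_init__(self) -> None:
        class_code(self.class_label)
        self.feature = np.asarray(self.feature, dtype=np.float64).reshape(5)
        if np.any(self.feature < -1e-9) or np.any(self.feature > 1 + 1e-9):
            raise ValueError("patch feature components must lie in [0, 1]")


@dataclass
class TrainingSet:
    """All training patches, plus dense arrays for classification."""

    patches: list[TrainingPatch]
    features: np.ndarray = field(init=False)  # (n, 5)
    labels: np.ndarray = field(init=False)  # (n,) int codes

    def __post_init__(self) -> None:
        if not self.patches:
            raise TrainingSetError("training set is empty")
        self.features = np.stack([p.feature for p in self.patches])
        self.labels = np.array([class_code(p.class_label) for p in self.patches])

    @property
    def per_class_counts(self) -> dict[str, int]:
        counts = np.bincount(self.labels, minlength=len(CLASS_NAMES))
        return {name: int(counts[i]) for i, name in enumerate(CLASS_NAMES)}

    def require_all_classes(self) -> None:
        missing = [n for n, c in self.per_class_counts.items() if c == 0]
        if missing:
            raise TrainingSetError(
                f"classes {missing} have no training patches; every class "
                "must be represented before classification"
            )

    def __len__(self) -> int:
        return len(self.patches)


def _patch_window(center: tuple[int, int], size: int) -> tuple[int, int, int, int]:
    # center sits at index (size-1)//2 of the window: exact middle for odd
    # sizes, top-left of the central 2x2 for even sizes (10 is the default).
    r, c = center
    r0 = r - (size - 1) // 2
    c0 = c - (size - 1) // 2
    return r0, c0, r0 + size, c0 + size


def extract_patches(
    image5: np.ndarray,
    annotations: list[tuple[tuple[int, int], str]],
    patch_size: int = 10,
    source: str = "",
) -> list[TrainingPatch]:
    """Extract mean 5-vectors from annotated square patches.

    ``annotations`` is a list of ``((row, col), class_label)`` patch centers.
    Every patch must lie fully inside the image.
    """
    image5 = np.asarray(image5, dtype=np.float64)
    if image5.ndim != 3 or image5.shape[-1] != 5:
        raise ValueError(f"expected an (H, W, 5) image, got shape {image5.shape}")
    if patch_size < 1:
        raise ValueError("patch_size must be >= 1")
    H, W = image5.shape[:2]
    offenders = []
    for (center, _label) in annotations:
        r0, c0, r1, c1 = _patch_window(center, patch_size)
        if r0 < 0 or c0 < 0 or r1 > H or c1 > W:
            offenders.append(center)
    if offenders:
        raise PatchBoundsError(
            f"{len(offenders)} patch(es) cross the image border: "
            f"{offenders[:10]}{'...' if len(offenders) > 10 else ''}"
        )
    patches = []
    for (center, label) in annotations:
        r0, c0, r1, c1 = _patch_window(center, patch_size)
        feat = image5[r0:r1, c0:c1].reshape(-1, 5).mean(axis=0)
        patches.append(
            TrainingPatch(
                class_label=label,
                feature=feat,
                source=source,
                center=tuple(center),
                patch_size=patch_size,
            )
        )
    return patches


def build_training_set(patches: list[TrainingPatch]) -> TrainingSet:
    """Assemble patches into a TrainingSet."""
    return TrainingSet(patches=list(patches))


# ---------------------------------------------------------------------------
# Classification


def classify_pixels(
    image5: np.ndarray,
    training: TrainingSet,
    k: int = 5,
    channel_weights: np.ndarray | None = None,
) -> np.ndarray:
    """Label every pixel by k-NN majority vote; returns an (H, W) uint8 map.

    ``channel_weights`` optionally rescales the five feature axes before the
    Euclidean distance is taken (all-ones by default).
    """
    image5 = np.asarray(image5, dtype=np.float64)
    if image5.ndim != 3 or image5.shape[-1] != 5:
        raise ValueError(f"expected an (H, W, 5) image, got shape {image5.shape}")
    training.require_all_classes()
    n = len(training)
    if not (1 <= k <= n):
        raise ValueError(f"k must be in [1, {n}], got {k}")
    H, W = image5.shape[:2]
    X = image5.reshape(-1, 5)
    feats = training.features
    codes = training.labels
    if channel_weights is not None:
        w = np.asarray(channel_weights, dtype=np.float64).reshape(5)
        if np.any(w < 0):
            raise ValueError("channel weights must be non-negative")
        X = X * w
        feats = feats * w
    # sort the training vectors by class code once (stable): a stable
    # distance sort then realizes "distance ties -> lower class code"
    order = np.argsort(codes, kind="stable")
    T = np.ascontiguousarray(feats[order])
    L = codes[order]
    out = np.empty(X.shape[0], dtype=np.uint8)
    chunk = max(1, 8_000_000 // max(1, n))
    for s in range(0, X.shape[0], chunk):
        xb = X[s : s + chunk]
        out[s : s + chunk] = _classify_chunk(xb, T, L, k)
    return out.reshape(H, W)


def _classify_chunk(X: np.ndarray, T: np.ndarray, L: np.ndarray, k: int) -> np.ndarray:
    m, n = X.shape[0], T.shape[0]
    d2 = np.zeros((m, n))
    for c in range(X.shape[1]):
        diff = X[:, c : c + 1] - T[:, c]
        d2 += diff * diff
    if k == n:
        sel = np.broadcast_to(np.arange(n), (m, n)).copy()
        ordd = np.argsort(d2, axis=1, kind="stable")
        sel = ordd[:, :k]
    else:
        part = np.argpartition(d2, k - 1, axis=1)[:, :k]
        part.sort(axis=1)  # ascending index -> stable sort gives (d2, index)
        rows = np.arange(m)[:, None]
        cand = d2[rows, part]
        dk = cand.max(axis=1)
        inner = np.argsort(cand, axis=1, kind="stable")
        sel = part[rows, inner]
        # boundary distance ties: more than k entries at <= d_k; resolve by
        # a full stable sort of those rows only
        ambiguous = np.flatnonzero((d2 <= dk[:, None]).sum(axis=1) > k)
        for i in ambiguous:
            sel[i] = np.argsort(d2[i], kind="stable")[:k]
    neigh = L[sel]  # (m, k) class codes ordered by (distance, class code)
    ncls = len(CLASS_NAMES)
    counts = (neigh[:, :, None] == np.arange(ncls)).sum(axis=1)
    pos = np.arange(k)
    first_pos = np.empty((m, ncls), dtype=np.int64)
    for c in range(ncls):
        hit = neigh == c
        first_pos[:, c] = np.where(hit, pos, k).min(axis=1)
    # lexicographic argmax: vote count, then earliest (nearest) occurrence,
    # then lower class code
    score = (
        counts * (8 * (k + 1))
        + (k - first_pos) * 8
        + (ncls - 1 - np.arange(ncls))
    )
    return np.argmax(score, axis=1).astype(np.uint8)


# ---------------------------------------------------------------------------
# Persistence


_CSV_COLUMNS = [
    "class_label",
    "r",
    "g",
    "b",
    "h",
    "s",
    "source_image",
    "center_row",
    "center_col",
    "patch_size",
]


def save_training_set(training: TrainingSet, path: str | os.PathLike) -> None:
    """Write a training set as CSV; features round-trip bit-identically."""
    rows = []
    for p in training.patches:
        rows.append(
            {
                "class_label": p.class_label,
                # float hex preserves the doubles exactly through text
                "r": p.feature[0].hex(),
                "g": p.feature[1].hex(),
                "b": p.feature[2].hex(),
                "h": p.feature[3].hex(),
                "s": p.feature[4].hex(),
                "source_image": p.source,
                "center_row": p.center[0],
                "center_col": p.center[1],
                "patch_size": p.patch_size,
            }
        )
    pd.DataFrame(rows, columns=_CSV_COLUMNS).to_csv(path, index=False)


def load_training_set(path: str | os.PathLike) -> TrainingSet:
    """Read a training set CSV written by :func:`save_training_set`.

    Plain decimal feature values are accepted too, so hand-edited tables
    work; float-hex values round-trip exactly.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"training CSV is missing columns {missing}")

    def parse_val(text: str, line: int) -> float:
        try:
            return float.fromhex(text) if "0x" in text else float(text)
        except ValueError:
            raise ValueError(f"line {line}: cannot parse feature value {text!r}") from None

    patches = []
    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        label = row["class_label"]
        if label not in _CODE:
            raise ValueError(f"line {line}: unknown class label {label!r}")
        feat = [parse_val(row[c], line) for c in ("r", "g", "b", "h", "s")]
        patches.append(
            TrainingPatch(
                class_label=label,
                feature=np.array(feat),
                source=row["source_image"],
                center=(int(row["center_row"]), int(row["center_col"])),
                patch_size=int(row["patch_size"]),
            )
        )
    return TrainingSet(patches=patches)
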