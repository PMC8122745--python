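"""Shared fixtures: synthetic scenes and training sets built once per session."""

from __future__ import annotations

import numpy as np
import pytest

from olivetray import (
    build_rgbhs,
    build_training_set,
    extract_patches,
    generate_scene,
    make_annotations,
)
from olivetray.synthetic import SceneConfig

# Training-set profile of the reference acquisition campaign: 1025 patches of
# 10x10 px over the 7 classes.
FULL_PROFILE = {
    "background": 138,
    "yellow_tray": 141,
    "red_tray": 121,
    "leaves": 235,
    "black_olive": 138,
    "purple_olive": 131,
    "green_olive": 121,
}


def training_from_scenes(
    yellow_cfg: SceneConfig,
    red_cfg: SceneConfig,
    counts: dict[str, int],
    seed: int,
    window: int = 5,
):
    """Build a training set with the given per-class patch counts.

    A scene has a single tray color, so the yellow-tray scene supplies six
    classes and a companion red-tray scene supplies the red-tray patches.
    Returns (training_set, yellow_image, yellow_truth, yellow_features).
    """
    img_y, truth_y = generate_scene(yellow_cfg)
    img_r, truth_r = generate_scene(red_cfg)
    f5_y = build_rgbhs(img_y, window=window)
    f5_r = build_rgbhs(img_r, window=window)
    counts_y = {k: v for k, v in counts.items() if k != "red_tray"}
    ann_y = make_annotations(truth_y, counts_y, seed=seed)
    ann_r = make_annotations(truth_r, {"red_tray": counts["red_tray"]}, seed=seed + 1)
    patches = extract_patches(f5_y, ann_y, source="yellow") + extract_patches(
        f5_r, ann_r, source="red"
    )
    return build_training_set(patches), img_y, truth_y, f5_y


@pytest.fixture(scope="session")
def small_scene():
    """A quick 240x320 yellow-tray scene with ground truth."""
    cfg = SceneConfig(
        height=240,
        width=320,
        olive_count=12,
        olive_radius_range=(8, 13),
        leaf_count=6,
        tray_border=10,
        seed=11,
    )
    img, truth = generate_scene(cfg)
    return cfg, img, truth


@pytest.fixture(scope="session")
def small_training(small_scene):
    """A ~140-patch training set over all 7 classes, from two small scenes."""
    cfg, _, _ = small_scene
    red_cfg = SceneConfig(
        height=240,
        width=320,
        olive_count=10,
        olive_radius_range=(8, 12),
        leaf_count=4,
        tray_border=10,
        tray_color="red",
        seed=12,
    )
    counts = {name: 20 for name in FULL_PROFILE}
    training, img_y, truth_y, f5_y = training_from_scenes(cfg, red_cfg, counts, seed=13)
    return training, img_y, truth_y, f5_y


@pytest.fixture(scope="session")
def full_profile_training():
    """The full 1025-patch profile from a 480x640 scene pair."""
    yellow_cfg = SceneConfig(seed=3)
    red_cfg = SceneConfig(tray_color="red", seed=4)
    training, img_y, truth_y, f5_y = training_from_scenes(
        yellow_cfg, red_cfg, FULL_PROFILE, seed=5
    )
    return training, img_y, truth_y, f5_y


def knn_oracle(
    X: np.ndarray, feats: np.ndarray, codes: np.ndarray, k: int
) -> np.ndarray:
    """Exhaustive per-point k-NN with the documented tie rules.

    Independent of the production classifier: full distance sort per query
    (distance ties toward lower class code), majority vote, vote ties toward
    the tied class seen earliest in the sorted neighbor list.
    """
    labels = np.empty(X.shape[0], dtype=np.int64)
    for i in range(X.shape[0]):
        d2 = ((feats - X[i]) ** 2).sum(axis=1)
        order = np.lexsort((codes, d2))[:k]
        neigh = codes[order]
        counts = np.bincount(neigh, minlength=7)
        best = counts.max()
        tied = set(np.flatnonzero(counts == best))
        for c in neigh:
            if c in tied:
                labels[i] = c
                break
    return labels


def interior_mask(mask: np.ndarray) -> np.ndarray:
    """True where a pixel is not within 1 px of a class boundary."""
    from scipy import ndimage

    keep = np.ones_like(mask, dtype=bool)
    for c in np.unique(mask):
        region = mask == c
        edge = region ^ ndimage.binary_erosion(region, np.ones((3, 3)))
        keep &= ~edge
    return keep
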