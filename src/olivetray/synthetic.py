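"""Synthetic tray scenes with exact per-pixel ground truth.

Real acquisition photographs a plastic tray of freshly harvested olives,
with leaves mixed in and, every few shots, a 24-patch color checker laid on
the tray. The generator emulates those scenes at a reduced scale: a tray
rectangle (yellow or red) over a background, randomly placed non-overlapping
olive ellipses in three ripeness colors (black / purple / green), elongated
leaf ellipses, i.i.d. Gaussian pixel noise, an optional rendered checker,
and parameterized global color casts standing in for illumination changes.

Every scene comes with its exact class mask, so calibration, segmentation
and ripeness estimation are testable end to end. Everything is deterministic
given the seed in the config.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .calibration import CheckerLayout, load_reference_table
from .segmentation import CLASS_NAMES, class_code

__all__ = [
    "SceneConfig",
    "ColorCast",
    "GroundTruth",
    "PackingError",
    "AnnotationSamplingError",
    "DEFAULT_CLASS_COLORS",
    "generate_scene",
    "apply_cast",
    "make_annotations",
]

# Mutually separated by >= 0.25 in RGB Euclidean norm so that, at the default
# noise level, classes are trivially separable and pipeline errors are
# attributable to the pipeline, not to overlapping class distributions.
DEFAULT_CLASS_COLORS: dict[str, tuple[float, float, float]] = {
    "background": (0.42, 0.38, 0.35),
    "yellow_tray": (0.85, 0.75, 0.20),
    "red_tray": (0.72, 0.15, 0.12),
    "leaves": (0.25, 0.45, 0.15),
    "black_olive": (0.08, 0.06, 0.10),
    "purple_olive": (0.40, 0.12, 0.48),
    "green_olive": (0.55, 0.72, 0.25),
}


class PackingError(Exception):
    """Could not place the requested number of olives without overlap."""


class AnnotationSamplingError(Exception):
    """A class lacks enough pure interior area for the requested patches."""


@dataclass
class SceneConfig:
    """Parameters of one synthetic tray scene.

    Defaults describe a mid-harvest lot at roughly 1/8 of the real
    acquisition scale: a 480x640 tray image with ~40 olives of 12-20 px
    radius, a dozen leaves, and sensor-like noise of sigma 0.012 (~3/255).
    """

    height: int = 480
    width: int = 640
    olive_count: int = 40
    olive_radius_range: tuple[float, float] = (12.0, 20.0)
    olive_aspect_range: tuple[float, float] = (0.7, 1.0)
    olive_mix: tuple[float, float, float] = (0.35, 0.40, 0.25)  # black, green, purple
    leaf_count: int = 12
    leaf_length_range: tuple[float, float] = (14.0, 20.0)
    leaf_aspect: float = 0.45
    tray_color: str = "yellow"  # "yellow" or "red"
    tray_border: int = 14
    class_colors: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_COLORS)
    )
    noise_sigma: float = 0.012
    checker: bool = False
    checker_corner: tuple[int, int] = (20, 20)  # top-left of the rendered chart
    checker_patch_px: int = 18
    checker_gap_px: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tray_color not in ("yellow", "red"):
            raise ValueError("tray_color must be 'yellow' or 'red'")
        if abs(sum(self.olive_mix) - 1.0) > 1e-9:
            raise ValueError("olive_mix fractions must sum to 1")
        if any(f < 0 for f in self.olive_mix):
            raise ValueError("olive_mix fractions must be non-negative")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.olive_radius_range[0] < 2:
            raise ValueError("olive radii must be >= 2 pixels")
        for name in CLASS_NAMES:
            if name not in self.class_colors:
                raise ValueError(f"class_colors is missing {name!r}")


@dataclass
class ColorCast:
    """A global color distortion: affine map plus per-channel gamma.

    Applied as ``clamp(M p + b) ** gamma`` per pixel. Emulates illumination
    or device changes between acquisitions.
    """

    matrix: np.ndarray  # (3, 3)
    offset: np.ndarray  # (3,)
    gamma: np.ndarray | float = 1.0

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64).reshape(3, 3)
        self.offset = np.asarray(self.offset, dtype=np.float64).reshape(3)
        self.gamma = np.broadcast_to(
            np.asarray(self.gamma, dtype=np.float64), (3,)
        ).copy()
        if np.any(self.gamma <= 0):
            raise ValueError("gamma exponents must be > 0")


@dataclass
class GroundTruth:
    """Exact per-pixel class mask and the derived true ripeness numbers."""

    mask: np.ndarray  # (H, W) uint8 class codes
    pixel_counts: dict[str, int]
    olive_pixels: int
    ripe_fraction: float | None
    checker_layout: CheckerLayout | None = None

    def summary(self) -> dict:
        return {
            "pixel_counts": self.pixel_counts,
            "olive_pixels": self.olive_pixels,
            "ripe_fraction": self.ripe_fraction,
        }


def _fill_ellipse(
    mask: np.ndarray,
    img: np.ndarray,
    center: tuple[float, float],
    axes: tuple[float, float],
    angle: float,
    code: int,
    color: tuple[float, float, float],
    clip_region: np.ndarray | None = None,
) -> None:
    cy, cx = center
    a, b = axes
    rmax = max(a, b)
    r0 = max(0, int(np.floor(cy - rmax - 1)))
    r1 = min(mask.shape[0], int(np.ceil(cy + rmax + 2)))
    c0 = max(0, int(np.floor(cx - rmax - 1)))
    c1 = min(mask.shape[1], int(np.ceil(cx + rmax + 2)))
    yy, xx = np.mgrid[r0:r1, c0:c1]
    dy = yy - cy
    dx = xx - cx
    ca, sa = np.cos(angle), np.sin(angle)
    u = dx * ca + dy * sa
    v = -dx * sa + dy * ca
    inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    if clip_region is not None:
        inside &= clip_region[r0:r1, c0:c1]
    mask[r0:r1, c0:c1][inside] = code
    img[r0:r1, c0:c1][inside] = color


def _olive_class_assignment(count: int, mix: tuple[float, float, float]) -> list[str]:
    # largest-remainder apportionment of olives to the three ripeness classes
    names = ["black_olive", "green_olive", "purple_olive"]
    raw = np.array(mix, dtype=np.float64) * count
    base = np.floor(raw).astype(int)
    rem = count - base.sum()
    order = np.argsort(-(raw - base), kind="stable")
    for i in range(rem):
        base[order[i]] += 1
    out: list[str] = []
    for name, n in zip(names, base):
        out.extend([name] * int(n))
    return out


def _render_checker(
    img: np.ndarray,
    mask: np.ndarray,
    cfg: SceneConfig,
    reference: np.ndarray,
) -> CheckerLayout:
    p, g = cfg.checker_patch_px, cfg.checker_gap_px
    r_top, c_left = cfg.checker_corner
    rows, cols = 4, 6
    h_chart = rows * p + (rows + 1) * g
    w_chart = cols * p + (cols + 1) * g
    if r_top + h_chart > cfg.height or c_left + w_chart > cfg.width:
        raise ValueError("checker does not fit at the requested corner")
    # dark chart frame; counts as background class
    img[r_top : r_top + h_chart, c_left : c_left + w_chart] = (0.05, 0.05, 0.05)
    mask[r_top : r_top + h_chart, c_left : c_left + w_chart] = class_code("background")
    rois = []
    idx = 0
    for i in range(rows):
        for j in range(cols):
            r = r_top + g + i * (p + g)
            c = c_left + g + j * (p + g)
            img[r : r + p, c : c + p] = reference[idx]
            rois.append((r, c, p, p))
            idx += 1
    return CheckerLayout(patch_rois=rois, sampling_fraction=0.5)


def generate_scene(config: SceneConfig) -> tuple[np.ndarray, GroundTruth]:
    """Render a tray scene and its exact ground-truth mask.

    Olives are placed by rejection sampling of non-overlapping bounding
    circles inside the tray area (and away from the checker, if rendered);
    a scene too crowded to pack raises :class:`PackingError`.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    H, W = cfg.height, cfg.width
    colors = cfg.class_colors
    img = np.empty((H, W, 3), dtype=np.float64)
    img[:] = colors["background"]
    mask = np.full((H, W), class_code("background"), dtype=np.uint8)

    tray_class = "yellow_tray" if cfg.tray_color == "yellow" else "red_tray"
    b = cfg.tray_border
    if H - 2 * b <= 0 or W - 2 * b <= 0:
        raise ValueError("tray border leaves no tray area")
    tray_region = np.zeros((H, W), dtype=bool)
    tray_region[b : H - b, b : W - b] = True
    img[tray_region] = colors[tray_class]
    mask[tray_region] = class_code(tray_class)

    layout = None
    keep_out = np.zeros((H, W), dtype=bool)
    if cfg.checker:
        layout = _render_checker(img, mask, cfg, load_reference_table())
        p, g = cfg.checker_patch_px, cfg.checker_gap_px
        r_top, c_left = cfg.checker_corner
        h_chart = 4 * p + 5 * g
        w_chart = 6 * p + 7 * g
        keep_out[
            max(0, r_top - 2) : r_top + h_chart + 2,
            max(0, c_left - 2) : c_left + w_chart + 2,
        ] = True

    # leaves: elongated ellipses scattered on the tray, under the olives
    allowed = tray_region & ~keep_out
    for _ in range(cfg.leaf_count):
        length = rng.uniform(*cfg.leaf_length_range)
        axes = (length, max(2.0, length * cfg.leaf_aspect))
        margin = int(np.ceil(length)) + 1
        cy = rng.uniform(b + margin, H - b - margin)
        cx = rng.uniform(b + margin, W - b - margin)
        angle = rng.uniform(0, np.pi)
        _fill_ellipse(
            mask, img, (cy, cx), axes, angle,
            class_code("leaves"), colors["leaves"], clip_region=allowed,
        )

    # olives: non-overlapping bounding circles, on top of everything
    classes = _olive_class_assignment(cfg.olive_count, cfg.olive_mix)
    rng.shuffle(classes)
    placed: list[tuple[float, float, float]] = []  # (cy, cx, bounding r)
    max_tries = 200 * max(1, cfg.olive_count)
    tries = 0
    for cls in classes:
        r = rng.uniform(*cfg.olive_radius_range)
        while True:
            tries += 1
            if tries > max_tries:
                raise PackingError(
                    f"could not place {cfg.olive_count} olives of radius "
                    f"{cfg.olive_radius_range} in a {H}x{W} scene"
                )
            margin = r + 2
            cy = rng.uniform(b + margin, H - b - margin)
            cx = rng.uniform(b + margin, W - b - margin)
            if keep_out[int(cy), int(cx)]:
                continue
            if any(
                (cy - py) ** 2 + (cx - px) ** 2 < (r + pr + 1) ** 2
                for py, px, pr in placed
            ):
                continue
            corners_clear = not (
                keep_out[
                    max(0, int(cy - r)) : int(cy + r) + 1,
                    max(0, int(cx - r)) : int(cx + r) + 1,
                ].any()
            )
            if corners_clear:
                break
        placed.append((cy, cx, r))
        aspect = rng.uniform(*cfg.olive_aspect_range)
        angle = rng.uniform(0, np.pi)
        _fill_ellipse(
            mask, img, (cy, cx), (r, r * aspect), angle,
            class_code(cls), colors[cls],
        )

    if cfg.noise_sigma > 0:
        img = img + rng.normal(0.0, cfg.noise_sigma, img.shape)
    img = np.clip(img, 0.0, 1.0)

    counts = np.bincount(mask.ravel(), minlength=len(CLASS_NAMES))
    pixel_counts = {name: int(counts[i]) for i, name in enumerate(CLASS_NAMES)}
    olive = sum(pixel_counts[c] for c in ("black_olive", "purple_olive", "green_olive"))
    frac = 100.0 * pixel_counts["black_olive"] / olive if olive else None
    truth = GroundTruth(
        mask=mask,
        pixel_counts=pixel_counts,
        olive_pixels=olive,
        ripe_fraction=frac,
        checker_layout=layout,
    )
    return img, truth


def apply_cast(image: np.ndarray, cast: ColorCast) -> np.ndarray:
    """Apply a global color cast: ``clamp(M p + b) ** gamma`` per pixel."""
    image = np.asarray(image, dtype=np.float64)
    out = image @ cast.matrix.T + cast.offset
    out = np.clip(out, 0.0, 1.0)
    return out ** cast.gamma


def make_annotations(
    ground_truth: GroundTruth,
    per_class_count: dict[str, int] | int,
    patch_size: int = 10,
    seed: int = 0,
) -> list[tuple[tuple[int, int], str]]:
    """Sample training-patch centers from pure class interiors of a mask.

    Stands in for the manual patch-annotation step: for each class, draws the
    requested number of distinct centers whose full patch window lies inside
    that class's region. Raises :class:`AnnotationSamplingError`, naming the
    class, when the interior is too small. An integer count applies to every
    class present in the mask (a single scene never contains both tray
    colors); a dict demands exactly the classes it names.
    """
    mask = ground_truth.mask
    if isinstance(per_class_count, int):
        per_class_count = {
            name: per_class_count
            for name in CLASS_NAMES
            if np.any(mask == class_code(name))
        }
    H, W = mask.shape
    rng = np.random.default_rng(seed)
    off = (patch_size - 1) // 2  # window = [r-off, r-off+patch_size)
    annotations: list[tuple[tuple[int, int], str]] = []
    for name in CLASS_NAMES:
        want = per_class_count.get(name, 0)
        if want <= 0:
            continue
        binary = (mask == class_code(name)).astype(np.int64)
        # integral image -> number of class pixels in each patch window
        S = np.zeros((H + 1, W + 1), dtype=np.int64)
        S[1:, 1:] = binary.cumsum(0).cumsum(1)
        r0s = np.arange(0, H - patch_size + 1)
        c0s = np.arange(0, W - patch_size + 1)
        window_sum = (
            S[r0s[:, None] + patch_size, c0s[None, :] + patch_size]
            - S[r0s[:, None] + patch_size, c0s[None, :]]
            - S[r0s[:, None], c0s[None, :] + patch_size]
            + S[r0s[:, None], c0s[None, :]]
        )
        pure = window_sum == patch_size * patch_size
        valid = np.argwhere(pure)
        if len(valid) < want:
            raise AnnotationSamplingError(
                f"class {name!r} has only {len(valid)} pure {patch_size}x"
                f"{patch_size} patch positions, need {want}"
            )
        pick = rng.choice(len(valid), size=want, replace=False)
        for r0, c0 in valid[pick]:
            annotations.append(((int(r0 + off), int(c0 + off)), name))
    return annotations
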