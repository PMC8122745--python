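"""Colorimetric calibration against a 24-patch color checker.

A photograph of a scene taken under uncontrolled illumination carries a global
color cast. To undo it, a standard 24-patch color checker is placed in the
scene; the mean sRGB color of each patch is measured, and a smooth warp of the
3-D color cube is fitted that moves every measured patch color exactly onto
its known reference value. The warp is a thin-plate-spline-style interpolant:
an affine part plus radial-kernel terms anchored at the 24 measured colors,

    f(p) = b + M p + sum_i w_i * phi(||p - c_i||),

subject to the usual side conditions (the radial weights are orthogonal to
constants and to the center coordinates), so that an affine cast is absorbed
entirely by the affine part. The same fitted warp is then applied per pixel to
every image acquired under the same conditions.

Two radial kernels are available: ``"linear"``, phi(r) = r, the natural
biharmonic kernel in three dimensions (default), and ``"thin_plate"``,
phi(r) = r^2 log r, the classical 2-D thin-plate kernel extended verbatim to
color space.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

logger = logging.getLogger(__name__)

__all__ = [
    "CheckerLayout",
    "ControlPointSet",
    "ColorWarp",
    "CalibrationError",
    "RoiBoundsError",
    "DegenerateControlPointsError",
    "WarpFitError",
    "load_reference_table",
    "reference_checksum",
    "measure_checker",
    "fit_warp",
    "apply_warp",
    "KERNELS",
]


class CalibrationError(Exception):
    """Base class for calibration failures."""


class RoiBoundsError(CalibrationError):
    """A checker patch region falls outside the image."""


class DegenerateControlPointsError(CalibrationError):
    """Two or more measured patch colors coincide; the fit is singular."""


class WarpFitError(CalibrationError):
    """The interpolation system is singular; regularization may help."""


# ---------------------------------------------------------------------------
# Reference table


def load_reference_table(path: str | os.PathLike | None = None) -> np.ndarray:
    """Load the 24 reference patch colors as a (24, 3) float array in [0, 1].

    The bundled table holds the nominal sRGB values of the classic 24-patch
    checker (8-bit integers in the file). Pass ``path`` to override with a
    user-measured table in the same CSV format
    (``patch_index,patch_name,r,g,b``).
    """
    if path is None:
        with resources.files("olivetray.data").joinpath("colorchecker24.csv").open() as fh:
            df = pd.read_csv(fh)
    else:
        df = pd.read_csv(path)
    required = {"patch_index", "r", "g", "b"}
    if not required.issubset(df.columns):
        raise ValueError(f"reference table must have columns {sorted(required)}")
    df = df.sort_values("patch_index")
    if len(df) != 24:
        raise ValueError(f"reference table must have 24 rows, got {len(df)}")
    return df[["r", "g", "b"]].to_numpy(dtype=np.float64) / 255.0


def reference_checksum(reference: np.ndarray) -> str:
    """SHA-256 checksum of a reference table, used to tag serialized warps."""
    arr = np.ascontiguousarray(np.asarray(reference, dtype=np.float64))
    return hashlib.sha256(arr.tobytes()).hexdigest()


# ---------------------------------------------------------------------------
# Checker layout


@dataclass
class CheckerLayout:
    """Placement of the 24 checker patches in an image.

    Parameters
    ----------
    patch_rois
        24 rectangles ``(row, col, height, width)`` in pixels, 0-based,
        half-open, ordered left-to-right then top-to-bottom like the chart.
    sampling_fraction
        Central fraction of each rectangle averaged when measuring the patch
        color; defaults to 0.5 to keep clear of patch borders.
    """

    patch_rois: list[tuple[int, int, int, int]]
    sampling_fraction: float = 0.5

    def __post_init__(self) -> None:
        if len(self.patch_rois) != 24:
            raise ValueError(f"expected 24 patch ROIs, got {len(self.patch_rois)}")
        if not (0.0 < self.sampling_fraction <= 1.0):
            raise ValueError("sampling_fraction must be in (0, 1]")
        self.patch_rois = [tuple(int(v) for v in roi) for roi in self.patch_rois]
        for i, (r, c, h, w) in enumerate(self.patch_rois):
            if h <= 0 or w <= 0:
                raise ValueError(f"ROI {i} has non-positive size")

    def validate_bounds(self, image_shape: tuple[int, ...]) -> None:
        H, W = image_shape[:2]
        bad = [
            i
            for i, (r, c, h, w) in enumerate(self.patch_rois)
            if r < 0 or c < 0 or r + h > H or c + w > W
        ]
        if bad:
            raise RoiBoundsError(
                f"patch ROIs {bad} fall outside an image of shape {(H, W)}"
            )

    @classmethod
    def from_corners(
        cls,
        corners: list[tuple[float, float]],
        rows: int = 4,
        cols: int = 6,
        roi_fraction: float = 0.6,
        sampling_fraction: float = 0.5,
    ) -> "CheckerLayout":
        """Build a regular grid of patch ROIs from the chart's 4 corner points.

        ``corners`` are (row, col) points in order top-left, top-right,
        bottom-right, bottom-left of the patch area. Cell centers are placed
        by bilinear interpolation; each ROI is the central ``roi_fraction`` of
        its cell.
        """
        if len(corners) != 4:
            raise ValueError("need exactly 4 corner points (TL, TR, BR, BL)")
        tl, tr, br, bl = (np.asarray(p, dtype=np.float64) for p in corners)
        cell_h = (np.linalg.norm(bl - tl) + np.linalg.norm(br - tr)) / 2.0 / rows
        cell_w = (np.linalg.norm(tr - tl) + np.linalg.norm(br - bl)) / 2.0 / cols
        h = max(1, int(round(cell_h * roi_fraction)))
        w = max(1, int(round(cell_w * roi_fraction)))
        rois = []
        for i in range(rows):
            v = (i + 0.5) / rows
            for j in range(cols):
                u = (j + 0.5) / cols
                center = (
                    (1 - u) * (1 - v) * tl
                    + u * (1 - v) * tr
                    + u * v * br
                    + (1 - u) * v * bl
                )
                rois.append(
                    (int(round(center[0] - h / 2)), int(round(center[1] - w / 2)), h, w)
                )
        return cls(patch_rois=rois, sampling_fraction=sampling_fraction)

    def to_json(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "patch_rois": [list(r) for r in self.patch_rois],
                    "sampling_fraction": self.sampling_fraction,
                },
                fh,
                indent=2,
            )

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "CheckerLayout":
        with open(path) as fh:
            layout_spec = json.load(fh)
        if "patch_rois" in layout_spec:
            return cls(
                patch_rois=[tuple(r) for r in layout_spec["patch_rois"]],
                sampling_fraction=layout_spec.get("sampling_fraction", 0.5),
            )
        if "corners" in layout_spec:
            return cls.from_corners(
                [tuple(p) for p in layout_spec["corners"]],
                rows=layout_spec.get("rows", 4),
                cols=layout_spec.get("cols", 6),
                roi_fraction=layout_spec.get("roi_fraction", 0.6),
                sampling_fraction=layout_spec.get("sampling_fraction", 0.5),
            )
        raise ValueError("layout JSON needs either 'patch_rois' or 'corners'")


# ---------------------------------------------------------------------------
# Control points


@dataclass
class ControlPointSet:
    """Paired measured and reference colors for the 24 checker patches."""

    measured: np.ndarray  # (24, 3)
    reference: np.ndarray  # (24, 3)

    def __post_init__(self) -> None:
        self.measured = np.asarray(self.measured, dtype=np.float64)
        self.reference = np.asarray(self.reference, dtype=np.float64)
        if self.measured.shape != self.reference.shape or self.measured.ndim != 2:
            raise ValueError("measured and reference must have matching (n, 3) shapes")
        d = cdist(self.measured, self.measured)
        np.fill_diagonal(d, np.inf)
        if d.min() <= 1e-9:
            i, j = np.unravel_index(np.argmin(d), d.shape)
            raise DegenerateControlPointsError(
                f"measured colors of patches {i} and {j} coincide "
                f"(distance {d[i, j]:.2e}); the warp fit would be degenerate"
            )


def measure_checker(
    image: np.ndarray,
    layout: CheckerLayout,
    reference: np.ndarray | None = None,
) -> ControlPointSet:
    """Measure the mean color of each checker patch in ``image``.

    The mean is taken over the central ``sampling_fraction`` of each patch
    ROI. Returns the measured colors paired with the reference table.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 3 or image.shape[-1] != 3:
        raise ValueError(f"expected an (H, W, 3) image, got shape {image.shape}")
    layout.validate_bounds(image.shape)
    if reference is None:
        reference = load_reference_table()
    frac = layout.sampling_fraction
    measured = np.empty((24, 3), dtype=np.float64)
    for i, (r, c, h, w) in enumerate(layout.patch_rois):
        hh = max(1, int(round(h * frac)))
        ww = max(1, int(round(w * frac)))
        r0 = r + (h - hh) // 2
        c0 = c + (w - ww) // 2
        measured[i] = image[r0 : r0 + hh, c0 : c0 + ww].reshape(-1, 3).mean(axis=0)
    return ControlPointSet(measured=measured, reference=np.asarray(reference))


# ---------------------------------------------------------------------------
# Thin-plate-spline color warp


def _phi_linear(r: np.ndarray) -> np.ndarray:
    return r


def _phi_thin_plate(r: np.ndarray) -> np.ndarray:
    out = np.zeros_like(r)
    nz = r > 0
    out[nz] = r[nz] * r[nz] * np.log(r[nz])
    return out


KERNELS = {"linear": _phi_linear, "thin_plate": _phi_thin_plate}


@dataclass
class ColorWarp:
    """A fitted warp of the RGB cube.

    ``__call__`` maps colors: for a point p,
    f(p) = affine_offset + affine_matrix @ p
           + sum_i radial_weights[i] * phi(||p - centers[i]||).
    """

    affine_offset: np.ndarray  # (3,)
    affine_matrix: np.ndarray  # (3, 3), applied as matrix @ p
    radial_weights: np.ndarray  # (n, 3)
    centers: np.ndarray  # (n, 3) — the measured patch colors
    kernel_name: str = "linear"
    regularization: float = 0.0
    reference_checksum: str | None = field(default=None)

    def __post_init__(self) -> None:
        self.affine_offset = np.asarray(self.affine_offset, dtype=np.float64).reshape(3)
        self.affine_matrix = np.asarray(self.affine_matrix, dtype=np.float64).reshape(3, 3)
        self.radial_weights = np.asarray(self.radial_weights, dtype=np.float64)
        self.centers = np.asarray(self.centers, dtype=np.float64)
        if self.kernel_name not in KERNELS:
            raise ValueError(f"unknown kernel {self.kernel_name!r}; choose from {list(KERNELS)}")

    def __call__(self, colors: np.ndarray) -> np.ndarray:
        """Apply the warp to an (n, 3) color array or an (H, W, 3) image.

        Output is unclamped; use :func:`apply_warp` for clamped image
        calibration.
        """
        colors = np.asarray(colors, dtype=np.float64)
        flat = colors.reshape(-1, 3)
        phi = KERNELS[self.kernel_name]
        out = self.affine_offset + flat @ self.affine_matrix.T
        # chunked so large images don't allocate an (N, 24) matrix all at once
        n = flat.shape[0]
        step = max(1, 2_000_000 // max(1, self.centers.shape[0]))
        for s in range(0, n, step):
            block = flat[s : s + step]
            out[s : s + step] += phi(cdist(block, self.centers)) @ self.radial_weights
        return out.reshape(colors.shape)

    def to_json(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "kernel_name": self.kernel_name,
                    "regularization": self.regularization,
                    "affine_offset": self.affine_offset.tolist(),
                    "affine_matrix": self.affine_matrix.tolist(),
                    "radial_weights": self.radial_weights.tolist(),
                    "centers": self.centers.tolist(),
                    "reference_checksum": self.reference_checksum,
                },
                fh,
                indent=2,
            )

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "ColorWarp":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            affine_offset=np.array(d["affine_offset"]),
            affine_matrix=np.array(d["affine_matrix"]),
            radial_weights=np.array(d["radial_weights"]),
            centers=np.array(d["centers"]),
            kernel_name=d["kernel_name"],
            regularization=d["regularization"],
            reference_checksum=d.get("reference_checksum"),
        )


def fit_warp(
    points: ControlPointSet,
    kernel_name: str = "linear",
    regularization: float = 0.0,
) -> ColorWarp:
    """Fit the color warp that maps measured patch colors onto references.

    Solves the standard interpolation system

        [K + lambda*I  P] [W]   [Y]
        [P^T           0] [A] = [0]

    with K the kernel matrix over measured centers, P = [1 | centers], and
    Y the reference colors. With ``regularization`` (lambda) = 0 the warp
    interpolates exactly: every measured center maps onto its reference.
    """
    if regularization < 0:
        raise ValueError("regularization must be >= 0")
    if kernel_name not in KERNELS:
        raise ValueError(f"unknown kernel {kernel_name!r}; choose from {list(KERNELS)}")
    centers = points.measured
    n = centers.shape[0]
    phi = KERNELS[kernel_name]
    K = phi(cdist(centers, centers))
    P = np.hstack([np.ones((n, 1)), centers])
    system = np.zeros((n + 4, n + 4))
    system[:n, :n] = K + regularization * np.eye(n)
    system[:n, n:] = P
    system[n:, :n] = P.T
    rhs = np.zeros((n + 4, 3))
    rhs[:n] = points.reference
    try:
        sol = np.linalg.solve(system, rhs)
    except np.linalg.LinAlgError as exc:
        raise WarpFitError(
            "interpolation system is singular (coplanar or near-duplicate "
            "measured colors); try regularization > 0"
        ) from exc
    cond = np.linalg.cond(system)
    if not np.isfinite(cond) or cond > 1e12:
        raise WarpFitError(
            f"interpolation system is ill-conditioned (cond={cond:.2e}); "
            "try regularization > 0"
        )
    W = sol[:n]
    A = sol[n:]
    return ColorWarp(
        affine_offset=A[0],
        affine_matrix=A[1:].T,
        radial_weights=W,
        centers=centers,
        kernel_name=kernel_name,
        regularization=regularization,
    )


def apply_warp(warp: ColorWarp, image: np.ndarray) -> np.ndarray:
    """Calibrate an image: warp each pixel's color and clamp to [0, 1]."""
    if not isinstance(warp, ColorWarp):
        raise TypeError("apply_warp needs a fitted ColorWarp")
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 3 or image.shape[-1] != 3:
        raise ValueError(f"expected an (H, W, 3) image, got shape {image.shape}")
    out = warp(image)
    n_clamped = int(np.count_nonzero((out < 0.0) | (out > 1.0)))
    if n_clamped:
        logger.info(
            "apply_warp: clamped %d of %d out-of-gamut components",
            n_clamped,
            out.size,
        )
    return np.clip(out, 0.0, 1.0)
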