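"""Seeded generators of phantom cell images and clustered point clouds.

The phantom emulates a noisy multi-feature biological image: elliptical
"cells" of distinct gray level (or color) on a uniform background, with
additive Gaussian sensor noise of known variance and exact per-cell ground
truth masks.  The point-cloud generator provides low-dimensional Gaussian
mixtures with optional uniform outliers for exercising the clustering core
in isolation.  Both are pure functions of their spec, seed included.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skimage import color as skcolor

from .image import ImageRaster

__all__ = [
    "PhantomSpec",
    "PointCloudSpec",
    "generate_phantom",
    "generate_point_cloud",
    "indexed_truth",
    "masks_from_indexed",
]

BACKGROUND_GRAY = 64.0


@dataclass
class PhantomSpec:
    """Phantom image description.

    size : edge length of the square image, pixels.
    n_features : number of elliptical cells.
    radius_range : (min, max) semi-axis length in pixels.
    intensity_contrast : gray gap between the dimmest cell and the
        background; with several cells the gray levels spread evenly from
        background + contrast up to 255 so every cell is distinct.
    noise_sigma : standard deviation of the additive Gaussian noise.
    color_mode : 'gray' or 'rgb' (rgb renders each gray level as a distinct
        hue of matching lightness).
    margin : minimum clearance between cells and to the border, pixels.
    """

    size: int = 256
    n_features: int = 10
    radius_range: tuple[float, float] = (8.0, 20.0)
    intensity_contrast: float = 120.0
    noise_sigma: float = 10.0
    color_mode: str = "gray"
    seed: int = 0
    background: float = BACKGROUND_GRAY
    margin: float = 2.0

    def __post_init__(self) -> None:
        if self.n_features < 1:
            raise ValueError("n_features must be at least 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if not (0 < self.radius_range[0] <= self.radius_range[1]):
            raise ValueError("radius_range must be positive and ordered")
        if self.color_mode not in ("gray", "rgb"):
            raise ValueError(f"unknown color_mode {self.color_mode!r}")
        if self.background + self.intensity_contrast > 255:
            raise ValueError("background + contrast exceeds the 8-bit gray range")
        area_cap = 0.4 * self.size**2
        mean_r = 0.5 * (self.radius_range[0] + self.radius_range[1])
        expected_area = self.n_features * math.pi * mean_r**2
        if expected_area >= area_cap:
            raise ValueError(
                "requested blobs would cover >= 40% of the image; placement infeasible"
            )


@dataclass
class PointCloudSpec:
    """Gaussian-mixture point cloud with uniform outliers (2-D)."""

    n_clusters: int = 3
    points_per_cluster: int = 100
    cluster_sigma: float = 0.5
    center_separation: float = 5.0
    n_outliers: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.center_separation <= 0:
            raise ValueError("center_separation must be positive")
        if min(self.n_clusters, self.points_per_cluster, self.n_outliers) < 0:
            raise ValueError("counts must be non-negative")


def _feature_gray_levels(spec: PhantomSpec) -> np.ndarray:
    """Distinct gray levels, evenly spaced upward from background + contrast.

    The top level stays two noise standard deviations below the 8-bit
    ceiling so the additive Gaussian noise model is not distorted by
    saturation clipping inside the features.
    """
    lo = spec.background + spec.intensity_contrast
    hi = max(lo, 255.0 - 2.0 * spec.noise_sigma)
    if spec.n_features == 1:
        return np.array([lo])
    return np.linspace(lo, hi, spec.n_features)


def _place_ellipses(spec: PhantomSpec, rng: np.random.Generator) -> list[tuple]:
    """Rejection-sample non-overlapping ellipses (circumscribed-circle test)."""
    placed: list[tuple] = []
    max_tries = 10 * spec.n_features**2 + 100
    tries = 0
    while len(placed) < spec.n_features:
        if tries >= max_tries:
            raise ValueError(
                f"could not place {spec.n_features} non-overlapping features "
                f"after {max_tries} attempts; relax the spec"
            )
        tries += 1
        a = rng.uniform(*spec.radius_range)
        b = rng.uniform(*spec.radius_range)
        theta = rng.uniform(0, math.pi)
        rmax = max(a, b)
        lo = rmax + spec.margin
        hi = spec.size - rmax - spec.margin
        if hi <= lo:
            raise ValueError("features too large for the image size")
        cy = rng.uniform(lo, hi)
        cx = rng.uniform(lo, hi)
        ok = all(
            math.hypot(cy - py, cx - px) >= rmax + max(pa, pb) + spec.margin
            for (py, px, pa, pb, _) in placed
        )
        if ok:
            placed.append((cy, cx, a, b, theta))
    return placed


def generate_phantom(spec: PhantomSpec) -> tuple[ImageRaster, np.ndarray]:
    """Render the phantom and its ground truth.

    Returns ``(raster, masks)`` where ``masks`` is an (n_features, H, W)
    boolean array of noise-free cell masks.  Cells have a one-pixel sigmoid
    edge ramp; masks cover the interior (ramp weight >= 1/2).
    """
    rng = np.random.default_rng(spec.seed)
    H = W = spec.size
    img = np.full((H, W), float(spec.background))
    masks = np.zeros((spec.n_features, H, W), dtype=bool)
    levels = _feature_gray_levels(spec)
    ellipses = _place_ellipses(spec, rng)
    yy, xx = np.mgrid[0:H, 0:W].astype(np.float64)
    for i, (cy, cx, a, b, theta) in enumerate(ellipses):
        ct, st = math.cos(theta), math.sin(theta)
        u = (yy - cy) * ct + (xx - cx) * st
        v = -(yy - cy) * st + (xx - cx) * ct
        r_ell = np.sqrt((u / a) ** 2 + (v / b) ** 2)
        # signed boundary distance approximated radially; sigmoid ramp about
        # one pixel wide (logistic slope 4 spans 12%-88% over +-0.5 px)
        from scipy.special import expit

        dist = (1.0 - r_ell) * min(a, b)
        alpha = expit(4.0 * dist)
        img += alpha * (levels[i] - spec.background)
        masks[i] = r_ell <= 1.0

    if spec.color_mode == "gray":
        if spec.noise_sigma > 0:
            img = img + rng.normal(0.0, spec.noise_sigma, size=img.shape)
        img = np.clip(img, 0, 255)
        raster = ImageRaster(img.round().astype(np.uint8), "gray")
    else:
        # render each gray level as a distinct hue of matching lightness
        lab = np.zeros((H, W, 3))
        lab[:, :, 0] = img * (100.0 / 255.0)
        hues = np.linspace(0.0, 2.0 * math.pi, spec.n_features, endpoint=False)
        for i in range(spec.n_features):
            lab[:, :, 1][masks[i]] = 40.0 * math.cos(hues[i])
            lab[:, :, 2][masks[i]] = 40.0 * math.sin(hues[i])
        rgb = np.clip(skcolor.lab2rgb(lab) * 255.0, 0, 255)
        if spec.noise_sigma > 0:
            rgb = rgb + rng.normal(0.0, spec.noise_sigma, size=rgb.shape)
        raster = ImageRaster(np.clip(rgb, 0, 255).round().astype(np.uint8), "rgb")
    return raster, masks


def indexed_truth(masks: np.ndarray) -> np.ndarray:
    """Collapse per-feature masks to one indexed grid (0 = background)."""
    masks = np.asarray(masks, dtype=bool)
    out = np.zeros(masks.shape[1:], dtype=np.int64)
    for i in range(masks.shape[0]):
        out[masks[i]] = i + 1
    return out


def masks_from_indexed(truth: np.ndarray) -> np.ndarray:
    """Expand an indexed truth grid (0 = background) to per-feature masks."""
    truth = np.asarray(truth)
    ids = np.unique(truth)
    ids = ids[ids > 0]
    return np.stack([truth == i for i in ids]) if ids.size else np.zeros((0,) + truth.shape, bool)


def _cluster_centers(n: int, separation: float) -> np.ndarray:
    """n centers pairwise-adjacent at the given separation: the vertices of a
    regular n-gon with side length = separation (a single center at the
    origin for n = 1)."""
    if n == 1:
        return np.zeros((1, 2))
    R = separation / (2.0 * math.sin(math.pi / n))
    ang = 2.0 * math.pi * np.arange(n) / n
    return np.stack([R * np.cos(ang), R * np.sin(ang)], axis=1)


def generate_point_cloud(spec: PointCloudSpec) -> tuple[np.ndarray, np.ndarray]:
    """Sample the mixture; outliers get label -1.

    Returns (points, labels) with points of shape (N, 2).
    """
    rng = np.random.default_rng(spec.seed)
    centers = _cluster_centers(max(spec.n_clusters, 1), spec.center_separation)
    pts = []
    labels = []
    for ci in range(spec.n_clusters):
        pts.append(
            centers[ci] + rng.normal(0.0, spec.cluster_sigma, size=(spec.points_per_cluster, 2))
        )
        labels.append(np.full(spec.points_per_cluster, ci))
    if spec.n_outliers > 0:
        span = spec.center_separation * 2.0 + 6.0 * spec.cluster_sigma
        pts.append(rng.uniform(-span, span, size=(spec.n_outliers, 2)))
        labels.append(np.full(spec.n_outliers, -1))
    if not pts:
        return np.zeros((0, 2)), np.zeros(0, dtype=np.int64)
    return np.concatenate(pts), np.concatenate(labels).astype(np.int64)
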