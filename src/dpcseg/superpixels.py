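"""SLIC-style superpixels with the joint color+space distance D_s.

Pixels are grouped by a local k-means in (l, a, b, row, col) using

    D_s = d_lab + (m / S) * d_xy

where S is the grid spacing derived from the requested superpixel count and
m trades color fidelity against spatial compactness.  Each center only
competes for pixels inside its 2S x 2S window, which keeps the assignment
local and fast.  The resulting superpixels carry the aggregates the
density-peak stage consumes: centroid, mean Lab color, and pixel count
(the superpixel's mass, used as the density weight).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .image import FeatureVector, ImageRaster, ModeError, ScalingConfig, scale_features

__all__ = [
    "SuperpixelConfig",
    "SuperpixelMap",
    "init_grid_centers",
    "slic_distance",
    "generate_superpixels",
    "superpixel_features",
    "save_superpixel_map",
]


@dataclass
class SuperpixelConfig:
    """Superpixel generation parameters.

    n_superpixels : requested count; the realized count varies with image
        content (connectivity enforcement merges slivers).
    m : compactness index; larger m yields more regular, grid-like shapes,
        smaller m hugs color edges more tightly.  The default 5 suits the
        native 8-bit lightness scale of embedded gray images (about twice
        the CIELAB L magnitude, hence half the classic Lab default of 10).
    max_iter : local k-means iteration cap.
    min_size_factor : connected components smaller than
        ``min_size_factor * S**2`` are merged into a neighboring superpixel.
    """

    n_superpixels: int = 7000
    m: float = 5.0
    max_iter: int = 10
    min_size_factor: float = 0.25
    displacement_tol: float = 1.0

    def __post_init__(self) -> None:
        if self.n_superpixels < 2:
            raise ValueError("n_superpixels must be at least 2")
        if self.m <= 0:
            raise ValueError("compactness m must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be at least 1")

    def grid_spacing(self, height: int, width: int) -> int:
        """Derived grid spacing S = round(sqrt(H*W / n_superpixels))."""
        S = int(round(math.sqrt(height * width / self.n_superpixels)))
        if S < 1:
            S = 1
        if S > min(height, width):
            raise ValueError(
                f"image {height}x{width} is smaller than one {S}x{S} superpixel cell"
            )
        return S


@dataclass
class SuperpixelMap:
    """Pixel-to-superpixel assignment plus per-superpixel aggregates."""

    labels: np.ndarray          # H x W int grid, values in [0, K)
    K: int
    centroids: np.ndarray       # K x 2 (row, col)
    mean_lab: np.ndarray        # K x 3
    rho_sp: np.ndarray          # K, pixel count per superpixel
    S: int                      # grid spacing used


def _lab_channels(raster: ImageRaster) -> np.ndarray:
    if raster.mode != "lab":
        raise ModeError(
            "superpixel generation expects a lab raster; call to_lab() first"
        )
    return np.asarray(raster.pixels, dtype=np.float64)


def _gradient_magnitude(L: np.ndarray) -> np.ndarray:
    """Sum of absolute central differences of the L channel."""
    gr = np.abs(np.gradient(L, axis=0)) + np.abs(np.gradient(L, axis=1))
    return gr


def init_grid_centers(raster: ImageRaster, cfg: SuperpixelConfig) -> np.ndarray:
    """Seed centers on a regular S-spaced grid, perturbed off edges.

    Each seed moves to the lowest-gradient pixel in its 3x3 neighborhood;
    on a tie (e.g. constant images) the grid node itself is kept.
    """
    lab = _lab_channels(raster)
    H, W = lab.shape[:2]
    S = cfg.grid_spacing(H, W)
    grad = _gradient_magnitude(lab[:, :, 0])
    rows = np.arange(S // 2, (H // S) * S, S)
    cols = np.arange(S // 2, (W // S) * S, S)
    centers = []
    # (0,0) first so strict improvement keeps the grid node on ties
    offsets = [(0, 0)] + [
        (dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)
    ]
    for r in rows:
        for c in cols:
            best = (int(r), int(c))
            best_g = np.inf
            for dr, dc in offsets:
                rr, cc = int(r) + dr, int(c) + dc
                if 0 <= rr < H and 0 <= cc < W and grad[rr, cc] < best_g:
                    best_g = grad[rr, cc]
                    best = (rr, cc)
            centers.append(best)
    return np.asarray(centers, dtype=np.int64)


def slic_distance(pixel, center, m: float, S: int) -> float:
    """Joint distance D_s = d_lab + (m/S) * d_xy between two 5-D points."""
    if m <= 0 or S < 1:
        raise ValueError("require m > 0 and S >= 1")
    px = np.asarray(pixel, dtype=float)
    ct = np.asarray(center, dtype=float)
    d_xy = math.hypot(ct[0] - px[0], ct[1] - px[1])
    d_lab = float(np.linalg.norm(ct[2:5] - px[2:5]))
    return d_lab + (m / S) * d_xy


def _enforce_connectivity(labels: np.ndarray, min_size: int) -> np.ndarray:
    """Merge connected components smaller than min_size into a neighbor.

    Each (superpixel, component) pair is examined; small components adopt
    the most frequent adjacent label outside themselves.
    """
    H, W = labels.shape
    out = labels.copy()
    struct = np.ones((3, 3), dtype=bool)
    for sp in np.unique(out):
        mask = out == sp
        comp, ncomp = ndimage.label(mask, structure=struct)
        if ncomp <= 1:
            continue
        sizes = ndimage.sum_labels(np.ones_like(comp), comp, index=np.arange(1, ncomp + 1))
        order = np.argsort(sizes)[::-1]
        for rank, ci in enumerate(order, start=1):
            size = sizes[ci]
            if rank == 1 or size >= min_size:
                continue
            cmask = comp == (ci + 1)
            ring = ndimage.binary_dilation(cmask, structure=struct) & ~cmask
            neigh_labels = out[ring]
            neigh_labels = neigh_labels[neigh_labels != sp]
            if neigh_labels.size == 0:
                continue
            vals, counts = np.unique(neigh_labels, return_counts=True)
            out[cmask] = vals[np.argmax(counts)]
    return out


def generate_superpixels(raster: ImageRaster, cfg: SuperpixelConfig) -> SuperpixelMap:
    """Run the local k-means and return the superpixel map.

    Pixels join the nearest center by D_s among centers whose 2S x 2S window
    covers them; ties go to the lower center id.  Centers move to their
    cluster means until displacement falls below one pixel or the iteration
    cap is hit.  Orphan pixels (outside every window) attach to the globally
    nearest center, and undersized connected components are merged away.
    """
    lab = _lab_channels(raster)
    H, W = lab.shape[:2]
    if H * W == 0:
        raise ValueError("empty image")
    S = cfg.grid_spacing(H, W)
    seeds = init_grid_centers(raster, cfg)
    # center state: row, col, l, a, b
    centers = np.empty((len(seeds), 5), dtype=np.float64)
    centers[:, 0:2] = seeds
    centers[:, 2:5] = lab[seeds[:, 0], seeds[:, 1]]

    rows_grid, cols_grid = np.mgrid[0:H, 0:W]
    inv_ms = cfg.m / S
    labels = np.full((H, W), -1, dtype=np.int64)

    for _ in range(cfg.max_iter):
        dist = np.full((H, W), np.inf, dtype=np.float64)
        labels.fill(-1)
        for idx in range(len(centers)):
            r0, c0 = centers[idx, 0], centers[idx, 1]
            rlo, rhi = max(0, int(r0) - S), min(H, int(r0) + S + 1)
            clo, chi = max(0, int(c0) - S), min(W, int(c0) + S + 1)
            if rlo >= rhi or clo >= chi:
                continue
            sub = lab[rlo:rhi, clo:chi]
            d_lab = np.sqrt(((sub - centers[idx, 2:5]) ** 2).sum(axis=2))
            d_xy = np.sqrt(
                (rows_grid[rlo:rhi, clo:chi] - r0) ** 2
                + (cols_grid[rlo:rhi, clo:chi] - c0) ** 2
            )
            Ds = d_lab + inv_ms * d_xy
            win = dist[rlo:rhi, clo:chi]
            better = Ds < win  # strict: ties keep the lower center id
            win[better] = Ds[better]
            labels[rlo:rhi, clo:chi][better] = idx

        orphans = labels < 0
        if orphans.any():
            orows = rows_grid[orphans]
            ocols = cols_grid[orphans]
            olab = lab[orphans]
            d_lab = np.sqrt(
                ((olab[:, None, :] - centers[None, :, 2:5]) ** 2).sum(axis=2)
            )
            d_xy = np.sqrt(
                (orows[:, None] - centers[None, :, 0]) ** 2
                + (ocols[:, None] - centers[None, :, 1]) ** 2
            )
            labels[orphans] = np.argmin(d_lab + inv_ms * d_xy, axis=1)

        # recompute centers from their members
        flat = labels.ravel()
        counts = np.bincount(flat, minlength=len(centers)).astype(np.float64)
        nonempty = counts > 0
        new_centers = centers.copy()
        sums = np.empty_like(centers)
        sums[:, 0] = np.bincount(flat, weights=rows_grid.ravel(), minlength=len(centers))
        sums[:, 1] = np.bincount(flat, weights=cols_grid.ravel(), minlength=len(centers))
        for ch in range(3):
            sums[:, 2 + ch] = np.bincount(
                flat, weights=lab[:, :, ch].ravel(), minlength=len(centers)
            )
        new_centers[nonempty] = sums[nonempty] / counts[nonempty, None]
        disp = np.sqrt(((new_centers[:, :2] - centers[:, :2]) ** 2).sum(axis=1))
        centers = new_centers
        if disp.max(initial=0.0) < cfg.displacement_tol:
            break

    min_size = max(1, int(cfg.min_size_factor * S * S))
    labels = _enforce_connectivity(labels, min_size)

    # compact relabeling and final aggregates
    uniq, labels_flat = np.unique(labels, return_inverse=True)
    labels = labels_flat.reshape(H, W)
    K = len(uniq)
    counts = np.bincount(labels.ravel(), minlength=K).astype(np.float64)
    centroids = np.stack(
        [
            np.bincount(labels.ravel(), weights=rows_grid.ravel(), minlength=K) / counts,
            np.bincount(labels.ravel(), weights=cols_grid.ravel(), minlength=K) / counts,
        ],
        axis=1,
    )
    mean_lab = np.stack(
        [
            np.bincount(labels.ravel(), weights=lab[:, :, ch].ravel(), minlength=K) / counts
            for ch in range(3)
        ],
        axis=1,
    )
    return SuperpixelMap(
        labels=labels,
        K=K,
        centroids=centroids,
        mean_lab=mean_lab,
        rho_sp=counts,
        S=S,
    )


def save_superpixel_map(sp: SuperpixelMap, label_path, sidecar_path) -> None:
    """Write the label grid as an integer PNG and the per-superpixel
    aggregates (id, row, col, l, a, b, rho_sp) as a CSV sidecar."""
    from .image import save_label_mask

    save_label_mask(sp.labels, label_path)
    with open(sidecar_path, "w") as fh:
        fh.write("id,row,col,l,a,b,rho_sp\n")
        for i in range(sp.K):
            r, c = sp.centroids[i]
            l, a, b = sp.mean_lab[i]
            fh.write(f"{i},{r:.3f},{c:.3f},{l:.3f},{a:.3f},{b:.3f},{int(sp.rho_sp[i])}\n")


def superpixel_features(
    sp: SuperpixelMap, cfg: ScalingConfig
) -> tuple[list[FeatureVector], np.ndarray]:
    """One scaled (x, y, l, a, b) point per superpixel, plus its pixel mass.

    The masses are the P_i weights of the weighted density kernel; they sum
    to the image pixel count.
    """
    feats = [
        scale_features(tuple(sp.centroids[i]), tuple(sp.mean_lab[i]), cfg)
        for i in range(sp.K)
    ]
    return feats, sp.rho_sp.copy()
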