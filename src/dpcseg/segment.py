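"""End-to-end microfeature segmentation pipeline.

Stages: color conversion -> superpixels -> scaled 5-D features -> improved
density-peak clustering -> superpixel-to-pixel label propagation -> spatial
noise isolation.  The result carries a manifest recording every parameter
the run actually used, so a run is reproducible from the manifest alone.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import density_peak as dp
from .image import ImageRaster, ScalingConfig, to_lab
from .superpixels import SuperpixelConfig, SuperpixelMap, generate_superpixels, superpixel_features

__all__ = [
    "NoiseIsolationConfig",
    "SegmentationConfig",
    "SegmentationResult",
    "segment_image",
    "pixels_from_superpixels",
    "isolate_noise",
]

logger = logging.getLogger("dpcseg")

#: The 8-connected neighborhood offsets (dx, dy) in {-1,0,1}^2 \ {(0,0)}.
NEIGHBORHOOD_8 = tuple(
    (dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)
)


@dataclass
class NoiseIsolationConfig:
    """Spatial noise isolation parameters.

    W : per-channel variance weights of the isolation distance (``None``
        uses the reciprocal per-channel variance of the image).
    threshold : isolation distance beyond which a pixel leaves its region
        (``None`` uses the 95th percentile of own-region distances).
    iterations : refinement sweeps (one by default).
    """

    enabled: bool = True
    W: Optional[tuple] = None
    threshold: Optional[float] = None
    threshold_quantile: float = 0.95
    iterations: int = 1
    neighborhood: tuple = NEIGHBORHOOD_8

    def __post_init__(self) -> None:
        if len(self.neighborhood) != 8:
            raise ValueError("the neighborhood must contain exactly 8 offsets")
        if self.W is not None and any(w <= 0 for w in self.W):
            raise ValueError("variance weights must be positive")


#: Color divisors chosen so the feature-background lightness gap of a
#: high-contrast image spans roughly ten spatial grid units: native 8-bit
#: gray uses 12, CIELAB L (0-100 scale) uses 5.
H_R_GRAY = 12.0
H_R_LAB = 5.0
#: Spatial divisor as a multiple of the superpixel spacing S.  Compressing
#: space relative to color shrinks the incidental separation of background
#: density maxima while color-isolated feature peaks keep their full
#: separation.
H_S_FACTOR = 1.5


@dataclass
class SegmentationConfig:
    """All pipeline parameters; subconfig defaults match the module docs.

    ``scaling=None`` derives the divisors from the image: h_s = 1.5 S and
    h_r = 12 for gray sources (native 8-bit lightness) or 5 for color
    (CIELAB L).  ``dpc.k=None`` retains the maximum admissible number of
    centers (30): for microfeature segmentation a missed feature is
    costlier than a split background, and surplus background centers only
    partition the background.
    """

    superpixel: SuperpixelConfig = field(default_factory=SuperpixelConfig)
    scaling: Optional[ScalingConfig] = None
    dpc: dp.DPCConfig = field(default_factory=dp.DPCConfig)
    noise: NoiseIsolationConfig = field(default_factory=NoiseIsolationConfig)
    seed: int = 0


@dataclass
class SegmentationResult:
    labels: np.ndarray
    k: int
    centers: np.ndarray
    superpixels: SuperpixelMap
    dpc: dp.DPCResult
    manifest: dict


def pixels_from_superpixels(sp: SuperpixelMap, sp_labels: np.ndarray) -> np.ndarray:
    """Expand per-superpixel cluster ids to the pixel grid."""
    sp_labels = np.asarray(sp_labels)
    if sp_labels.shape[0] != sp.K:
        raise ValueError(f"expected {sp.K} superpixel labels, got {sp_labels.shape[0]}")
    if sp_labels.size and (sp_labels.min() < 0):
        raise ValueError("superpixel cluster ids must be non-negative")
    return sp_labels[sp.labels]


def _neighborhood_mean(channels: np.ndarray, offsets) -> np.ndarray:
    """Mean of each pixel's 8 neighbors per channel (borders renormalized)."""
    H, W, C = channels.shape
    acc = np.zeros((H, W, C))
    cnt = np.zeros((H, W, 1))
    for dr, dc in offsets:
        rs = slice(max(0, dr), H + min(0, dr))
        rd = slice(max(0, -dr), H + min(0, -dr))
        cs = slice(max(0, dc), W + min(0, dc))
        cd = slice(max(0, -dc), W + min(0, -dc))
        acc[rd, cd] += channels[rs, cs]
        cnt[rd, cd] += 1.0
    return acc / cnt


def isolate_noise(
    labels: np.ndarray, raster: ImageRaster, cfg: NoiseIsolationConfig
) -> np.ndarray:
    """Reassign pixels whose neighborhood mean is anomalously far from their
    own region.

    For each pixel the 8-neighborhood mean feature x̄ is compared with the
    means of the regions adjacent to it (the regions its 8 neighbors belong
    to, plus its own) through the variance-weighted norm
    d(i, r) = sqrt(sum_c W_c (x̄_ic - μ_rc)^2).  A pixel whose distance to
    its own region exceeds the threshold moves to the adjacent region at
    minimal distance.  Restricting candidates to adjacent regions keeps the
    pass spatial: an isolated noise pixel is absorbed by its surroundings,
    while interior pixels (whose only adjacent region is their own) never
    move.  Labels are only reassigned, never created.
    """
    labels = np.asarray(labels)
    img = np.asarray(raster.pixels, dtype=np.float64)
    if img.ndim == 2:
        img = img[:, :, None]
    if img.shape[:2] != labels.shape:
        raise ValueError("labels and raster shapes differ")
    H, W_img, C = img.shape
    if cfg.W is not None:
        W = np.asarray(cfg.W, dtype=float)
        if W.shape != (C,):
            raise ValueError(f"W must have {C} entries")
    else:
        var = img.reshape(-1, C).var(axis=0)
        W = 1.0 / np.where(var > 0, var, 1.0)

    out = labels.copy()
    for _ in range(max(1, cfg.iterations)):
        xbar = _neighborhood_mean(img, cfg.neighborhood)
        ids = np.unique(out)
        mu = np.stack(
            [img[out == r].mean(axis=0) for r in ids]
        )  # region reference colors from the raw pixels
        # distance of every pixel to every region (k <= 30 regions)
        diff = xbar[:, :, None, :] - mu[None, None, :, :]
        dist = np.sqrt((W[None, None, None, :] * diff**2).sum(axis=3))
        own_idx = np.searchsorted(ids, out)
        d_own = np.take_along_axis(dist, own_idx[:, :, None], axis=2)[:, :, 0]
        if cfg.threshold is not None:
            thr = float(cfg.threshold)
        else:
            thr = float(np.quantile(d_own, cfg.threshold_quantile))
        def neighbor_summary(cur):
            """Best neighboring region by distance, and same-label counts."""
            best_d = np.full_like(d_own, np.inf)
            best_lab = cur.copy()
            same = np.zeros(cur.shape, dtype=np.int64)
            for dr, dc in cfg.neighborhood:
                rs = slice(max(0, dr), H + min(0, dr))
                rd = slice(max(0, -dr), H + min(0, -dr))
                cs = slice(max(0, dc), W_img + min(0, dc))
                cd = slice(max(0, -dc), W_img + min(0, -dc))
                nb_idx = np.searchsorted(ids, cur[rs, cs])
                d_nb = np.take_along_axis(
                    dist[rd, cd], nb_idx[:, :, None], axis=2
                )[:, :, 0]
                better = d_nb < best_d[rd, cd]
                best_d[rd, cd][better] = d_nb[better]
                best_lab[rd, cd][better] = cur[rs, cs][better]
                same[rd, cd] += cur[rs, cs] == cur[rd, cd]
            return best_d, best_lab, same

        best_nb_d, best_nb_lab, _ = neighbor_summary(out)
        move = (d_own > thr) & (best_nb_d < d_own)
        changed = bool(move.any())
        out = np.where(move, best_nb_lab, out)
        # a pixel left with no same-label neighbor is spatially isolated
        # noise: absorb it into its best neighboring region unconditionally
        _, best_nb_lab2, same_nb = neighbor_summary(out)
        isolated = (same_nb == 0) & (best_nb_lab2 != out)
        if isolated.any():
            out = np.where(isolated, best_nb_lab2, out)
            changed = True
        if not changed:
            break
    return out


def _gray_for_entropy(raster: ImageRaster) -> np.ndarray:
    """Gray values (0..255) for the one-dimensional entropy weighting."""
    px = np.asarray(raster.pixels, dtype=np.float64)
    if raster.mode == "gray":
        return px
    if raster.mode == "rgb":
        return px @ np.array([0.299, 0.587, 0.114])
    return px[:, :, 0] * (255.0 / 100.0)  # lab: rescale L


def superpixel_entropy(gray: np.ndarray, labels: np.ndarray, K: int) -> np.ndarray:
    """Per-superpixel gray entropy, vectorized over all superpixels."""
    g = np.clip(np.round(np.asarray(gray)).astype(np.int64), 0, 255)
    counts = np.bincount(
        labels.ravel() * 256 + g.ravel(), minlength=K * 256
    ).reshape(K, 256)
    p = counts / np.maximum(counts.sum(axis=1, keepdims=True), 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log2(p), 0.0)
    return -terms.sum(axis=1)


def segment_image(raster: ImageRaster, cfg: Optional[SegmentationConfig] = None) -> SegmentationResult:
    """Run the full pipeline; deterministic given (raster, cfg, seed)."""
    cfg = cfg or SegmentationConfig()
    t0 = time.perf_counter()

    try:
        lab = to_lab(raster)
    except Exception as exc:
        raise RuntimeError(f"color conversion stage failed: {exc}") from exc
    logger.info("color conversion: %.3fs", time.perf_counter() - t0)

    t1 = time.perf_counter()
    try:
        sp = generate_superpixels(lab, cfg.superpixel)
    except Exception as exc:
        raise RuntimeError(f"superpixel stage failed: {exc}") from exc
    logger.info("superpixels (K=%d, S=%d): %.3fs", sp.K, sp.S, time.perf_counter() - t1)

    if cfg.scaling is not None:
        scaling = cfg.scaling
    else:
        h_r = H_R_GRAY if raster.mode == "gray" else H_R_LAB
        scaling = ScalingConfig(h_s=H_S_FACTOR * float(sp.S), h_r=h_r)
    feats, weights = superpixel_features(sp, scaling)

    entropy = superpixel_entropy(_gray_for_entropy(raster), sp.labels, sp.K)

    dpc_cfg = cfg.dpc
    if dpc_cfg.k is None:
        # retain as many candidate centers as the admissible range allows
        dpc_cfg = dataclasses.replace(
            dpc_cfg, k=max(dp.K_RANGE[0], min(dp.K_RANGE[1], sp.K))
        )

    t2 = time.perf_counter()
    try:
        result = dp.dpc(feats, dpc_cfg, weights=weights, entropy=entropy)
    except Exception as exc:
        raise RuntimeError(f"density-peak clustering stage failed: {exc}") from exc
    k = len(result.centers)
    logger.info("improved DPC (k=%d, d_c=%.4g): %.3fs", k, result.d_c, time.perf_counter() - t2)

    labels = pixels_from_superpixels(sp, result.labels)

    if cfg.noise.enabled:
        t3 = time.perf_counter()
        try:
            labels = isolate_noise(labels, lab, cfg.noise)
        except Exception as exc:
            raise RuntimeError(f"noise isolation stage failed: {exc}") from exc
        logger.info("noise isolation: %.3fs", time.perf_counter() - t3)

    manifest = {
        "seed": cfg.seed,
        "image": {"height": raster.height, "width": raster.width, "mode": raster.mode},
        "superpixel": {
            "n_superpixels": cfg.superpixel.n_superpixels,
            "m": cfg.superpixel.m,
            "max_iter": cfg.superpixel.max_iter,
            "S": sp.S,
            "K": sp.K,
        },
        "scaling": {"h_s": scaling.h_s, "h_r": scaling.h_r},
        "dpc": {
            "d_c": result.d_c,
            "k": k,
            "density_kernel": cfg.dpc.density_kernel,
            "use_entropy_weight": cfg.dpc.use_entropy_weight,
            "decision_rule": cfg.dpc.decision_rule,
            "entropy_per_center": [float(entropy[c]) for c in result.centers],
        },
        "noise_isolation": {
            "enabled": cfg.noise.enabled,
            "iterations": cfg.noise.iterations,
            "threshold": cfg.noise.threshold,
            "threshold_quantile": cfg.noise.threshold_quantile,
        },
    }
    return SegmentationResult(
        labels=labels,
        k=k,
        centers=result.centers,
        superpixels=sp,
        dpc=result,
        manifest=manifest,
    )
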