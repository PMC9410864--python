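# dpcseg — microfeature segmentation by improved density-peak clustering

`dpcseg` segments *microfeatures* — small regions of distinct intensity or
color, such as cells in a noisy micrograph — from 2-D gray or RGB images.
It is aimed at quantitative-imaging work where the questions are "did every
feature get found?" and "how much noise is left?", not just pixel accuracy.

## Method

1. **Superpixels.** A SLIC-style local k-means over (l, a, b, x, y) with the
   joint distance `D_s = d_lab + (m/S)·d_xy` (S the grid spacing, m the
   compactness) tiles the image into a few thousand perceptually uniform
   patches, each summarized by its centroid, mean CIELAB color, and pixel
   mass.
2. **Feature space.** Each superpixel becomes one point
   (x, y, l, a, b) = (row/h_s, col/h_s, L/h_r, a/h_r, b/h_r); the divisors
   balance spatial against chromatic resolution.
3. **Improved density-peak clustering.** Per point: local density
   ρ_i = Σ_j P_j·exp(−(d_ij/d_c)²) (pixel-mass-weighted smooth kernel;
   cutoff ρ_i = #{j : d_ij ≤ d_c} and weighted-cutoff variants available),
   separation δ_i = min distance to a denser point (the global peak takes
   the max distance), and decision score γ_i = ρ_i·δ_i. Candidate centers
   rank by γ·H with H the 1-D gray entropy −Σ p log₂ p of the candidate's
   pixels; the top k (k ∈ [2, 30]) become centers and every point inherits
   its nearest denser neighbor's label, from dense to sparse.
4. **Noise isolation.** Pixels whose 8-neighborhood mean is anomalously far
   (variance-weighted norm, threshold = 95th percentile) from their own
   region's color move to the closest adjacent region; spatially isolated
   single pixels are absorbed.

Evaluation: segmentation integrity rate **R = χ′/χ × 100%** (fraction of
ground-truth features recovered with IoU ≥ 0.7 by some predicted region),
missing-feature count, adjusted Rand index, mean per-feature IoU, and a
block-variance noise estimate (mean of the lowest-1% block variances,
χ²-debiased).

A seeded phantom generator produces noisy multi-feature test images with
exact ground truth, and a point-cloud generator exercises the clustering
core alone.

## Worked example

```sh
python examples/segment_phantom.py
```

```
superpixels: 7225  clusters: 30  d_c used: 1.344
integrity rate R = 100.0% (10/10 features completely segmented at IoU >= 0.7)
missing features: 0
adjusted Rand index: 0.029   mean per-feature IoU: 0.988
estimated noise variance: 102.3 (generator used sigma^2 = 100)
```

The phantom holds ten elliptical "cells" of distinct brightness on a noisy
background (σ = 10). All ten are recovered as whole regions (R = 100%) with
mean feature IoU 0.99, none are missing, and the block-variance estimator
recovers the injected noise variance within a few percent. The 30 clusters
include the 10 cells; the surplus clusters deliberately partition the
background — harmless for feature recovery, but it is why the *whole-image*
adjusted Rand index is near zero here (the truth keeps the background as a
single class). For feature work, read R, the missing count and the
per-feature IoU; the ARI is informative when comparing full partitions of
equal granularity.

The same pipeline is scriptable from the shell:

```sh
dpcseg simulate --n-features 10 --size 256 --noise-sigma 10 --seed 42 \
    --out phantom.png --truth truth.png
dpcseg segment phantom.png --out labels.png --manifest manifest.json
dpcseg evaluate labels.png truth.png --image phantom.png --report report.json
```

Other examples: `examples/dpc_point_cloud.py` (the clustering core on a
Gaussian mixture), `examples/noise_estimation.py` (noise-variance recovery
across noise levels), `examples/cli_workflow.sh`.

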