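# Methods

`dpcseg` segments microfeatures — small, roughly convex regions of distinct
intensity or color, such as cells in a micrograph — out of noisy 2-D images.
The pipeline has four stages: construction of a joint space–color feature
space on superpixels, an improved density-peak clustering (DPC) of those
superpixels, propagation of cluster labels back to pixels, and a spatial
noise-isolation refinement. An evaluation suite scores segmentations against
ground truth, and a phantom generator provides synthetic imagery with exact
truth masks.

## Feature space

Each superpixel contributes one point (x, y, l, a, b): its centroid and mean
CIELAB color, rescaled as (x, y)/h_s and (l, a, b)/h_r. Gray images embed
the raw 8-bit gray value directly into the lightness slot (a = b = 0) rather
than through the CIELAB transform: the gray→L* map is concave and compresses
differences between bright levels, exactly where bright microfeatures live.

The divisors set the relative bandwidth of space and color and are the
pipeline's central calibration:

* `h_s = 1.5 S` (S = superpixel grid spacing), so adjacent superpixels sit
  ~0.67 units apart. Compressing space relative to color shrinks the
  incidental separations among background density maxima while
  color-isolated feature peaks keep their full separation.
* `h_r = 12` for gray sources (5 for CIELAB L, which lives on a 0–100
  scale), so a strong feature–background contrast (~120 gray levels) spans
  ~10 spatial units, and the per-superpixel noise of mean gray
  (σ/S ≈ 0.3 units at σ = 10, S = 3) stays well below the grid spacing.
  With h_r = 1, color noise rivals the spatial grid spacing and local
  densities degenerate.

## Superpixels

A SLIC-style local k-means with the joint distance D_s = d_lab + (m/S)·d_xy:
seeds on a regular S-grid perturbed to the lowest-gradient pixel in a 3×3
neighborhood, each center competing only inside its 2S×2S window, ties going
to the lower center id, iteration until center displacement < 1 px or 10
iterations. Orphan pixels attach to the globally nearest center; connected
components smaller than S²/4 merge into their dominant neighbor. Defaults:
`n_superpixels = 7000` (S = 3 on a 256² image — small enough that features
of radius ≥ 8 px span many superpixels) and compactness `m = 5`: the gray
embedding keeps lightness on the 0–255 scale, about twice the CIELAB L
magnitude, so half the classic Lab default (10) preserves the same
color-versus-space balance and hugs feature edges tighter.

## Improved density-peak clustering

Classic DPC computes per point a local density ρ, the separation δ (distance
to the nearest strictly denser point; the global maximum takes the maximum
pairwise distance), and the decision score γ = ρ·δ; the k top-scoring points
become centers, and every other point inherits the label of its nearest
denser neighbor, visited in decreasing density. Density ties break by point
index, which guarantees an acyclic neighbor forest.

Four density kernels are provided:

* `cutoff` — neighbor count within d_c (indicator closed at d_ij ≤ d_c; a
  strict variant is a flag);
* `gaussian` — Σ exp(−(d_ij/d_c)²), the smooth relaxation for imagery whose
  colors are hard to separate;
* `weighted_cutoff` — the cutoff indicator with each neighbor contributing
  its pixel mass P_j, so superpixel-level density approximates pixel-level
  density;
* `weighted_gaussian` — both combined: Σ P_j exp(−(d_ij/d_c)²). This is the
  image-pipeline default: superpixels tile the plane, so any unweighted or
  hard-window density is nearly constant plus tiling artifacts; the
  mass-weighted smooth kernel varies only where the image content does.

The cutoff distance d_c is constrained to (0, 10] in scaled units. When not
given: cutoff-family kernels use the classic 2% quantile of off-diagonal
distances; gaussian-family kernels treat d_c as a bandwidth and use 1.5× the
median nearest-neighbor distance (the distance quantile grows with image
extent and over-smooths tilings).

Center selection is entropy-weighted: candidates rank by γ·H, where H is the
one-dimensional Shannon entropy (bits, 256 gray bins) of the candidate
superpixel's own pixels, computed on original gray values (or RGB
luminance). Information-rich regions are favored; the weighting is
uninformative on noise-free synthetic images, where every region has H = 0
(switch `use_entropy_weight` off there).

The number of centers k is constrained to [2, 30]. For point clouds, `dpc`
picks k at the largest gap in the sorted log scores. For images,
`segment_image` retains the admissible maximum (30) by default: on
multi-feature images the sorted score curve decays smoothly — local maxima
of the background density field (ridges between the "holes" that features
carve into it) interleave with feature peaks — so a gap criterion lands at
k ≈ 2–8 and misses features. Surplus centers only partition the background,
which is harmless for feature recovery, whereas a missed feature is
unrecoverable. Points with zero cutoff density at d_c are flagged outliers
(they still receive labels through propagation).

## Pixel labels and noise isolation

Pixel labels are the cluster ids of their superpixels. The optional
refinement compares each pixel's 8-neighborhood mean feature x̄ with the
mean color μ_r of each *adjacent* region r through the variance-weighted
norm d(i, r) = √(Σ_c W_c (x̄_ic − μ_rc)²), with W defaulting to reciprocal
per-channel image variance and the threshold to the 95th percentile of
own-region distances. Pixels beyond the threshold move to the closest
adjacent region; pixels left without any same-label neighbor are absorbed
unconditionally (they are spatially isolated noise by definition). One sweep
by default. Restricting candidates to adjacent regions is essential: an
image-wide nearest-mean reassignment lets edge-blend pixels of every feature
migrate to whatever distant region happens to match their blended color.

## Evaluation

* **Integrity rate** R = χ′/χ × 100%: a truth feature counts as completely
  segmented when some predicted region reaches IoU ≥ 0.7 with its mask
  (threshold exposed; "complete" is otherwise a visual judgement). The
  predicted label with the largest overlap with true background is treated
  as background and never matched.
* **Missing features**: features no non-background region covers to ≥ 50%
  recall.
* **Accuracy**: adjusted Rand index over the pixel partitions (via
  scikit-learn) and the mean best-match IoU over truth features.
* **Noise variance**: variance of each non-overlapping block (8×8 default),
  sorted ascending, mean of the lowest 1%. Under Gaussian noise this tail
  mean underestimates σ² by the closed-form factor F_{ν+2}(q)/p (ν = block
  pixel count − 1, q the p-quantile of χ²_ν), ≈ 0.60 for 8×8 blocks at
  p = 0.01; the estimator divides it out by default (`debias=False` returns
  the raw tail mean, which is the quantity bounded by the all-blocks mean).

## Phantom generator

Phantoms emulate noisy micrographs: a uniform background (gray 64) carrying
`n_features` non-overlapping ellipses (semi-axes 8–20 px, rejection-sampled
with a 2 px margin), each with a ~1 px sigmoid edge ramp, plus additive
Gaussian noise clipped to [0, 255]. Feature gray levels are pairwise
distinct: evenly spaced from background + contrast up to 255 − 2σ, the
headroom keeping the additive-noise model valid inside features (a feature
at the ceiling has half its noise clipped, which also collapses its gray
entropy). Truth masks are the noise-free ellipse interiors. The default
conditions (256², 10 features, contrast 120, σ = 10) give features whose
contrast-to-noise ratio is high per pixel but whose sizes (200–1250 px)
are small against the image.

What the phantom does *not* emulate: textured backgrounds, intensity
gradients and vignetting, point-spread blur beyond the 1 px ramp, touching
or overlapping cells, and correlated noise. Passing the phantom suite
therefore demonstrates the pipeline's behavior under additive Gaussian
noise with piecewise-constant structure, not performance on real
micrographs.

The point-cloud generator places isotropic Gaussian clusters at the vertices
of a regular polygon with side length `center_separation`, plus uniform
outliers labeled −1.

## Numerical choices and degeneracies

* Assignment ties in SLIC and density ties in DPC break toward the lower
  id/index — all stages are exactly deterministic; `segment_image` is
  bit-reproducible given (image, config, seed).
* A constant image yields zero entropy everywhere and tied densities;
  centers then fall to the lowest indices and one cluster absorbs
  everything, which is the sensible degenerate answer.
* KDE kernels must pass the moment checks ∫K = 1, ∫uK = 0, ∫u²K > 0
  (numerical tolerance 1e−3); Silverman's rule
  0.9·min(σ̂, IQR/1.34)·n^(−1/5) is the bandwidth helper.
* The block-variance debiasing assumes Gaussian noise; for heavy-tailed
  noise the raw estimate should be preferred and interpreted as a lower
  bound.

## Known limitations

* Features distinguished from each other *only* spatially (identical color)
  merge when closer than roughly the density bandwidth; the phantom gives
  features distinct levels, which is also what separates close pairs.
* The k ≤ 30 cap bounds the number of recoverable features per image at 30
  minus the background centers actually spent (typically ~15–20 available).
* Entropy weighting needs noise or texture to be informative (see above).
* All-pairs distances keep the superpixel count in the few-thousands range;
  the default 7000 superpixels on one CPU core cost a few seconds per
  256² image.
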