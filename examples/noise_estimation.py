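"""Estimate image noise variance with the block-variance method.

Generates phantoms at three known noise levels and compares the
lowest-variance-blocks estimate (chi-square debiased) with the truth.
"""

from dpcseg import PhantomSpec, estimate_noise_variance, generate_phantom

for sigma in (5.0, 10.0, 20.0):
    raster, _ = generate_phantom(
        PhantomSpec(size=256, n_features=5, noise_sigma=sigma, seed=3)
    )
    est = estimate_noise_variance(raster, block=8)
    raw = estimate_noise_variance(raster, block=8, debias=False)
    print(f"sigma={sigma:5.1f}: true var={sigma**2:6.1f}  "
          f"estimate={est:6.1f}  raw tail mean={raw:6.1f}")
# The raw mean of the lowest-1% block variances sits well below the truth
# (order-statistic bias); the debiased estimate recovers it within a few %.
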