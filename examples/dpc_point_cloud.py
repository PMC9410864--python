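"""Density-peak clustering on a 2-D Gaussian-mixture point cloud.

Shows the clustering core in isolation: the per-point density rho,
separation delta, and decision score gamma = rho * delta, with the three
mixture components recovered by the top-3 decision scores.
"""

import numpy as np
from sklearn.metrics import adjusted_rand_score

from dpcseg import DPCConfig, dpc
from dpcseg.synthetic import PointCloudSpec, generate_point_cloud

points, truth = generate_point_cloud(
    PointCloudSpec(n_clusters=3, points_per_cluster=100,
                   cluster_sigma=0.5, center_separation=5.0, seed=1)
)
res = dpc(points, DPCConfig(k=3, density_kernel="cutoff", use_entropy_weight=False))

print(f"cutoff distance d_c = {res.d_c:.3f} (2% quantile of pairwise distances)")
for rank, c in enumerate(res.centers):
    print(f"center {rank}: point {c} at {np.round(points[c], 2)}, "
          f"rho={res.rho[c]:.0f}, delta={res.delta[c]:.2f}, true component {truth[c]}")
print(f"adjusted Rand index vs truth: {adjusted_rand_score(truth, res.labels):.3f}")
# Each center should come from a different true component, and the ARI
# close to 1 confirms the nearest-denser-neighbor propagation recovers them.
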