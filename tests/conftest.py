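import numpy as np
import pytest

from dpcseg.image import ImageRaster


@pytest.fixture
def two_halves_raster():
    """128x128 gray image: dark left half, bright right half."""
    img = np.full((128, 128), 40, dtype=np.uint8)
    img[:, 64:] = 200
    return ImageRaster(img, "gray")


@pytest.fixture
def collinear_points():
    """The hand-checkable 1-D fixture: points at 0, 1, 2, 10 embedded in 5-D."""
    pts = np.zeros((4, 5))
    pts[:, 0] = [0.0, 1.0, 2.0, 10.0]
    return pts


def brute_force_dpc(points, d_c, kernel="cutoff", weights=None):
    """Independent O(n^2)-O(n^3) reference for the DPC per-point quantities.

    Plain Python loops throughout; shares no code with the implementation.
    Returns (rho, delta, neigh) with the same density-tie convention:
    j is denser than i iff rho_j > rho_i, or rho_j == rho_i and j < i.
    """
    pts = [list(map(float, p)) for p in points]
    n = len(pts)
    dist = [[0.0] * n for _ in range(n)]
    for i in range(n):
        for j in range(n):
            dist[i][j] = sum((a - b) ** 2 for a, b in zip(pts[i], pts[j])) ** 0.5
    rho = []
    for i in range(n):
        if kernel == "cutoff":
            r = sum(1 for j in range(n) if j != i and dist[i][j] <= d_c)
        elif kernel == "gaussian":
            r = sum(np.exp(-((dist[i][j] / d_c) ** 2)) for j in range(n) if j != i)
        elif kernel == "weighted_cutoff":
            r = sum(weights[j] for j in range(n) if j != i and dist[i][j] <= d_c)
        else:
            raise ValueError(kernel)
        rho.append(float(r))
    delta, neigh = [], []
    for i in range(n):
        denser = [j for j in range(n) if rho[j] > rho[i] or (rho[j] == rho[i] and j < i)]
        if denser:
            best = min(denser, key=lambda j: (dist[i][j], j))
            delta.append(dist[i][best])
            neigh.append(best)
        else:
            delta.append(max(dist[i]))
            neigh.append(-1)
    return np.array(rho), np.array(delta), np.array(neigh, dtype=np.int64)


def brute_force_labels(rho, neigh, centers):
    """Reference label propagation in descending-density order."""
    n = len(rho)
    labels = [-1] * n
    for rank, c in enumerate(centers):
        labels[c] = rank
    order = sorted(range(n), key=lambda i: (-rho[i], i))
    for i in order:
        if labels[i] < 0:
            labels[i] = labels[neigh[i]]
    return np.array(labels, dtype=np.int64)
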