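"""Independent brute-force oracles used by the test suite.

Deliberately naive implementations (pure-Python loops, textbook formulas)
that share no code with the package, so agreement is meaningful.
"""

from __future__ import annotations

from collections import deque
from itertools import product

import numpy as np


def neighbor_offsets(connectivity: int):
    offs = []
    for d in product((-1, 0, 1), repeat=3):
        if d == (0, 0, 0):
            continue
        manhattan = sum(abs(v) for v in d)
        if connectivity == 6 and manhattan > 1:
            continue
        if connectivity == 18 and manhattan > 2:
            continue
        offs.append(d)
    return offs


def flood_fill_partition(binary: np.ndarray, connectivity: int) -> set[frozenset]:
    """Partition of the True voxels into connected regions via BFS."""
    binary = np.asarray(binary, dtype=bool)
    offs = neighbor_offsets(connectivity)
    seen = np.zeros_like(binary)
    regions = set()
    nx, ny, nz = binary.shape
    for start in zip(*np.nonzero(binary)):
        if seen[start]:
            continue
        queue = deque([start])
        seen[start] = True
        region = []
        while queue:
            v = queue.popleft()
            region.append(v)
            for d in offs:
                w = (v[0] + d[0], v[1] + d[1], v[2] + d[2])
                if 0 <= w[0] < nx and 0 <= w[1] < ny and 0 <= w[2] < nz:
                    if binary[w] and not seen[w]:
                        seen[w] = True
                        queue.append(w)
        regions.add(frozenset(region))
    return regions


def labeling_partition(labels: np.ndarray) -> set[frozenset]:
    """Partition implied by an integer label field (0 = background)."""
    out = set()
    for lab in np.unique(labels):
        if lab == 0:
            continue
        out.add(frozenset(zip(*np.nonzero(labels == lab))))
    return out


def threshold_loop(values: np.ndarray, suv_min: float) -> np.ndarray:
    """Voxel-by-voxel scalar comparison loop."""
    out = np.zeros(values.shape, dtype=np.uint16)
    for i in range(values.shape[0]):
        for j in range(values.shape[1]):
            for k in range(values.shape[2]):
                if values[i, j, k] >= suv_min:
                    out[i, j, k] = 1
    return out


def mip_loop(values: np.ndarray, axis: int) -> np.ndarray:
    """Index-loop maximum projection."""
    kept = [i for i in range(3) if i != axis]
    out_shape = (values.shape[kept[0]], values.shape[kept[1]])
    out = np.full(out_shape, -np.inf)
    for i in range(values.shape[0]):
        for j in range(values.shape[1]):
            for k in range(values.shape[2]):
                idx = (i, j, k)
                key = (idx[kept[0]], idx[kept[1]])
                out[key] = max(out[key], values[i, j, k])
    return out


def sphere_voxel_count(center, radius, grid_shape, spacing, origin=(0.0, 0.0, 0.0)) -> int:
    """Count voxel centers inside a sphere by explicit triple loop."""
    cnt = 0
    for i in range(grid_shape[0]):
        for j in range(grid_shape[1]):
            for k in range(grid_shape[2]):
                x = origin[0] + i * spacing[0] - center[0]
                y = origin[1] + j * spacing[1] - center[1]
                z = origin[2] + k * spacing[2] - center[2]
                if x * x + y * y + z * z <= radius * radius:
                    cnt += 1
    return cnt


def two_pass_mean_sd(xs) -> tuple[float, float]:
    """Textbook two-pass sample mean / sd (ddof=1)."""
    xs = list(map(float, xs))
    n = len(xs)
    mean = sum(xs) / n
    var = sum((x - mean) ** 2 for x in xs) / (n - 1)
    return mean, var**0.5


def icc2_mean_squares(m: np.ndarray) -> float:
    """ICC(2,1) from the two-way ANOVA mean-square decomposition."""
    m = np.asarray(m, dtype=float)
    n, k = m.shape
    grand = m.mean()
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    msr = k * ((row_means - grand) ** 2).sum() / (n - 1)
    msc = n * ((col_means - grand) ** 2).sum() / (k - 1)
    sse = ((m - row_means[:, None] - col_means[None, :] + grand) ** 2).sum()
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
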