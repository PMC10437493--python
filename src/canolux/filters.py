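"""Point-cloud preprocessing: statistical outlier removal, slope-based ground
separation, and voxel downsampling."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .geometry import PointCloud


@dataclass(frozen=True)
class FilterParams:
    """Preprocessing parameters (metres / degrees)."""

    stat_k: int = 12
    stat_std_ratio: float = 2.0
    slope_cell: float = 0.25
    slope_threshold: float = 30.0
    voxel_size: float = 0.02

    def __post_init__(self):
        if self.stat_k < 3:
            raise ValueError("stat_k must be >= 3")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")


def statistical_outlier_filter(cloud: PointCloud, stat_k: int = 12,
                               stat_std_ratio: float = 2.0) -> PointCloud:
    """Remove points whose mean k-NN distance exceeds mean + ratio * std."""
    n = len(cloud)
    if n <= stat_k:
        raise ValueError(f"need more than stat_k={stat_k} points, got {n}")
    tree = cKDTree(cloud.xyz)
    # k+1 neighbours: the first is the point itself
    dists, _ = tree.query(cloud.xyz, k=stat_k + 1)
    mean_d = dists[:, 1:].mean(axis=1)
    thresh = mean_d.mean() + stat_std_ratio * mean_d.std()
    return cloud.select(mean_d <= thresh)


def slope_ground_filter(cloud: PointCloud, slope_cell: float = 0.25,
                        slope_threshold: float = 30.0,
                        z_tolerance: float = 0.03) -> tuple[PointCloud, PointCloud]:
    """Split a cloud into (ground, vegetation) with a grid-based slope test.

    Each point is compared against the lowest point in its 3x3 cell
    neighbourhood: it is ground when its rise over horizontal run stays below
    tan(slope_threshold) (with a small absolute tolerance absorbing sensor
    noise at zero run).  The partition is exhaustive and disjoint.
    """
    n = len(cloud)
    if n == 0:
        raise ValueError("cloud is empty")
    xy = cloud.xyz[:, :2]
    z = cloud.xyz[:, 2]
    origin = xy.min(axis=0)
    cells = np.floor((xy - origin) / slope_cell).astype(np.int64)
    nx = int(cells[:, 0].max()) + 1
    ny = int(cells[:, 1].max()) + 1
    flat = cells[:, 0] * ny + cells[:, 1]

    # per-cell argmin of z
    order = np.argsort(flat, kind="stable")
    sorted_flat = flat[order]
    starts = np.searchsorted(sorted_flat, np.arange(nx * ny))
    minz_idx = np.full(nx * ny, -1, dtype=np.int64)
    ends = np.append(starts[1:], n)
    for c in np.unique(sorted_flat):
        seg = order[starts[c]:ends[c]]
        minz_idx[c] = seg[np.argmin(z[seg])]

    tan_t = np.tan(np.radians(slope_threshold))
    is_ground = np.zeros(n, dtype=bool)
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            ux = cells[:, 0] + dx
            uy = cells[:, 1] + dy
            ok = (ux >= 0) & (ux < nx) & (uy >= 0) & (uy < ny)
            j = np.where(ok, minz_idx[np.clip(ux * ny + uy, 0, nx * ny - 1)], -1)
            ok &= j >= 0
            if not ok.any():
                continue
            i = np.nonzero(ok)[0]
            jj = j[i]
            rise = z[i] - z[jj]
            run = np.linalg.norm(xy[i] - xy[jj], axis=1)
            is_ground[i] |= rise <= z_tolerance + tan_t * run
    return cloud.select(is_ground), cloud.select(~is_ground)


def voxel_downsample(cloud: PointCloud, voxel_size: float = 0.02) -> PointCloud:
    """One centroid per occupied voxel; labels by majority vote within voxel."""
    if voxel_size <= 0:
        raise ValueError("voxel_size must be positive")
    n = len(cloud)
    if n == 0:
        return cloud
    origin = cloud.xyz.min(axis=0)
    keys = np.floor((cloud.xyz - origin) / voxel_size).astype(np.int64)
    _, inv, counts = np.unique(keys, axis=0, return_inverse=True, return_counts=True)
    k = len(counts)
    centroids = np.zeros((k, 3))
    for d in range(3):
        centroids[:, d] = np.bincount(inv, weights=cloud.xyz[:, d], minlength=k)
    centroids /= counts[:, None]

    def majority(lab: np.ndarray) -> np.ndarray:
        pairs, pair_counts = np.unique(
            np.column_stack([inv, lab]), axis=0, return_counts=True)
        # sort by (voxel, count): the last pair per voxel is the mode
        order = np.lexsort((pair_counts, pairs[:, 0]))
        pairs, pair_counts = pairs[order], pair_counts[order]
        last = np.searchsorted(pairs[:, 0], np.arange(k), side="right") - 1
        return pairs[last, 1].astype(np.int32)

    return PointCloud(centroids, majority(cloud.plant_id), majority(cloud.organ),
                      majority(cloud.leaf_id))
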