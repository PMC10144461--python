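"""Lowest pruning-point localization in an accumulated 3D semantic cloud.

Pruning-region points (label 5) are isolated and grouped by Euclidean
cluster extraction: starting from a seed point, all points within a distance
threshold t are pushed onto a stack and expanded until no reachable point
remains — the connected components of the graph linking point pairs at
distance ≤ t.  The threshold scales with the cloud's voxel resolution r as
t = 1.5 × r.  Clusters that are still fragmented across viewpoints are
merged when their closest points fall within a merge distance, small groups
are dropped as noise, and the surviving cluster extremal along the vertical
axis (smallest y by default) marks the lowest petiole; its centroid is the
pruning point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .cloud import SemanticPointCloud
from .semantic2d import LABEL_PRUNING

DEFAULT_T_FACTOR = 1.5
DEFAULT_MERGE_FACTOR = 5.0  # merge_dist default = 5 x r
DEFAULT_MIN_CLUSTER_SIZE = 10

_AXIS_INDEX = {"x": 0, "y": 1, "z": 2}


class NoPruningRegionError(RuntimeError):
    """No pruning-region cluster survives filtering: nothing to prune."""


@dataclass(frozen=True)
class PointCluster:
    """Indices into a point array plus the member centroid."""

    indices: tuple
    centroid: tuple
    size: int = field(init=False)

    def __post_init__(self):
        if len(self.indices) < 1:
            raise ValueError("cluster must contain at least one point")
        object.__setattr__(self, "size", len(self.indices))


def _make_cluster(points: np.ndarray, idx) -> PointCluster:
    idx = tuple(int(i) for i in idx)
    cen = points[list(idx)].mean(axis=0)
    return PointCluster(indices=idx, centroid=tuple(float(c) for c in cen))


@dataclass(frozen=True)
class PruningPoint3D:
    """The reported cut location: centroid of the winning cluster."""

    position: tuple  # (x, y, z) mm
    source_cluster: PointCluster
    frame: str = "world"


def extract_pruning_subcloud(cloud: SemanticPointCloud) -> SemanticPointCloud:
    """Keep only the pruning-region points (label 5)."""
    return cloud.select(cloud.labels == LABEL_PRUNING)


def extract_clusters(points: np.ndarray, t: float) -> list[PointCluster]:
    """Euclidean cluster extraction with inclusive threshold t (mm).

    Implements the seed/stack expansion over a kd-tree radius search; the
    resulting partition equals the connected components of the ≤-t proximity
    graph and is independent of seeding order.  Seeds are taken in ascending
    index order so cluster enumeration is deterministic.
    """
    if t <= 0:
        raise ValueError(f"cluster threshold t must be positive, got {t}")
    pts = np.asarray(points, dtype=np.float64).reshape(-1, 3)
    n = len(pts)
    if n == 0:
        return []
    tree = cKDTree(pts)
    visited = np.zeros(n, dtype=bool)
    clusters = []
    for seed in range(n):
        if visited[seed]:
            continue
        visited[seed] = True
        group = [seed]
        stack = [seed]
        while stack:
            p = stack.pop()
            for nb in tree.query_ball_point(pts[p], t):
                if not visited[nb]:
                    visited[nb] = True
                    group.append(nb)
                    stack.append(nb)
        clusters.append(_make_cluster(pts, sorted(group)))
    return clusters


def merge_close_clusters(
    clusters: list[PointCluster], points: np.ndarray, merge_dist: float
) -> list[PointCluster]:
    """Union clusters (transitively) whose minimum inter-point distance is
    ≤ merge_dist — reconnecting one petiole's pruning region seen as
    disconnected patches from different viewpoints."""
    if merge_dist < 0:
        raise ValueError(f"merge_dist must be >= 0, got {merge_dist}")
    pts = np.asarray(points, dtype=np.float64).reshape(-1, 3)
    k = len(clusters)
    if k <= 1 or merge_dist == 0:
        return list(clusters)

    parent = list(range(k))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)

    trees = [cKDTree(pts[list(c.indices)]) for c in clusters]
    for i in range(k):
        for j in range(i + 1, k):
            if find(i) == find(j):
                continue
            if np.isinf(merge_dist):
                union(i, j)
                continue
            # sparse pair query: any pair within merge_dist suffices
            if trees[i].count_neighbors(trees[j], merge_dist) > 0:
                union(i, j)

    groups: dict[int, list[int]] = {}
    for i in range(k):
        groups.setdefault(find(i), []).append(i)
    merged = []
    for root in sorted(groups):
        idx = sorted(ii for ci in groups[root] for ii in clusters[ci].indices)
        merged.append(_make_cluster(pts, idx))
    return merged


def remove_small_clusters(
    clusters: list[PointCluster], min_size: int
) -> list[PointCluster]:
    """Drop clusters with fewer than ``min_size`` points (viewpoint noise)."""
    if min_size < 1:
        raise ValueError(f"min_size must be >= 1, got {min_size}")
    return [c for c in clusters if c.size >= min_size]


def lowest_cluster(
    clusters: list[PointCluster], axis: str = "y", direction: str = "min"
) -> PointCluster:
    """Cluster whose centroid is extremal along ``axis``.

    Default smallest y, the lowest petiole in a y-up world frame.  Ties are
    broken toward the larger cluster, then the lower list index.
    """
    if not clusters:
        raise NoPruningRegionError("no pruning-region cluster to select from")
    if axis not in _AXIS_INDEX:
        raise ValueError(f"axis must be one of x/y/z, got {axis!r}")
    if direction not in ("min", "max"):
        raise ValueError(f"direction must be 'min' or 'max', got {direction!r}")
    ax = _AXIS_INDEX[axis]
    sign = 1.0 if direction == "min" else -1.0
    best = min(
        range(len(clusters)),
        key=lambda i: (sign * clusters[i].centroid[ax], -clusters[i].size, i),
    )
    return clusters[best]


def find_pruning_point(
    cloud: SemanticPointCloud,
    t_factor: float = DEFAULT_T_FACTOR,
    merge_dist: float | None = None,
    min_size: int = DEFAULT_MIN_CLUSTER_SIZE,
    axis: str = "y",
    direction: str = "min",
) -> tuple[PruningPoint3D, list[PointCluster]]:
    """Chain subcloud extraction → clustering (t = t_factor × r) → merging →
    noise removal → lowest-cluster selection.

    ``merge_dist`` defaults to 5 × r.  Returns the pruning point and the list
    of surviving clusters it was chosen from.  Raises
    :class:`NoPruningRegionError` when nothing survives.
    """
    if cloud.resolution is None:
        raise ValueError("cloud resolution r must be set (voxel_downsample first)")
    r = float(cloud.resolution)
    if merge_dist is None:
        merge_dist = DEFAULT_MERGE_FACTOR * r
    sub = extract_pruning_subcloud(cloud)
    if len(sub) == 0:
        raise NoPruningRegionError("cloud contains no pruning-region points")
    clusters = extract_clusters(sub.points, t_factor * r)
    clusters = merge_close_clusters(clusters, sub.points, merge_dist)
    clusters = remove_small_clusters(clusters, min_size)
    win = lowest_cluster(clusters, axis=axis, direction=direction)
    point = PruningPoint3D(
        position=win.centroid, source_cluster=win, frame=cloud.frame
    )
    return point, clusters
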