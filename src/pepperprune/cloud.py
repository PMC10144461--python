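"""Semantic point clouds from semantic + depth rasters.

Pinhole unprojection of each plant-labeled pixel through its depth value
yields a labeled 3D point; the canonical unit throughout the package is the
millimeter.  ``scaling_factor`` converts depth-raster sensor units to mm
(a RealSense-style depth-in-mm stream has scaling_factor = 1).  Pixels with
zero depth are treated as missing; points beyond ``max_depth`` (default
1500 mm, matching a camera standing about 1 m from the plant) are discarded.

The module also provides voxel-grid downsampling (centroid representative,
majority label), statistical outlier removal, and PLY persistence (ASCII and
binary-little-endian) with an optional display palette.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field, replace
import warnings

import numpy as np
from scipy.spatial import cKDTree

from .semantic2d import LABEL_PRUNING

#: Fig-11-style display palette, label -> (r, g, b)
PALETTE = {
    1: (128, 0, 128),   # stem: purple
    2: (255, 105, 180),  # petiole: pink
    3: (0, 200, 0),      # leaf: green
    4: (255, 165, 0),    # fruit: orange
    5: (0, 0, 255),      # pruning region: blue
}

DEFAULT_MAX_DEPTH_MM = 1500.0


@dataclass(frozen=True)
class CameraIntrinsics:
    """Pinhole parameters.  ``focal_length`` applies to both axes unless a
    distinct ``focal_length_y`` is given."""

    focal_length: float
    center_x: float
    center_y: float
    scaling_factor: float = 1.0  # depth-raster units per millimeter
    focal_length_y: float | None = None

    def __post_init__(self):
        if self.focal_length <= 0:
            raise ValueError("focal_length must be positive")
        if self.scaling_factor <= 0:
            raise ValueError("scaling_factor must be positive")
        if self.focal_length_y is not None and self.focal_length_y <= 0:
            raise ValueError("focal_length_y must be positive")

    @property
    def fy(self) -> float:
        return self.focal_length if self.focal_length_y is None else self.focal_length_y


@dataclass
class SemanticPointCloud:
    """N labeled points in millimeters.

    ``frame`` records whether coordinates are camera- or world-relative;
    ``resolution`` is the voxel size r (mm) once downsampled, else None.
    """

    points: np.ndarray  # (N, 3) float64, mm
    labels: np.ndarray  # (N,) uint8
    frame: str = "camera"
    resolution: float | None = None

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=np.float64).reshape(-1, 3)
        self.labels = np.asarray(self.labels, dtype=np.uint8).reshape(-1)
        if len(self.points) != len(self.labels):
            raise ValueError(
                f"points ({len(self.points)}) and labels ({len(self.labels)}) differ"
            )
        if self.frame not in ("camera", "world"):
            raise ValueError(f"frame must be 'camera' or 'world', got {self.frame!r}")

    def __len__(self) -> int:
        return len(self.points)

    def select(self, mask: np.ndarray) -> "SemanticPointCloud":
        return SemanticPointCloud(
            self.points[mask], self.labels[mask], self.frame, self.resolution
        )


def empty_cloud(frame: str = "camera", resolution: float | None = None) -> SemanticPointCloud:
    return SemanticPointCloud(
        np.empty((0, 3), dtype=np.float64), np.empty(0, dtype=np.uint8), frame, resolution
    )


def concatenate_clouds(clouds: list[SemanticPointCloud]) -> SemanticPointCloud:
    if not clouds:
        return empty_cloud()
    frames = {c.frame for c in clouds}
    if len(frames) > 1:
        raise ValueError(f"cannot concatenate clouds in different frames: {frames}")
    return SemanticPointCloud(
        np.vstack([c.points for c in clouds]),
        np.concatenate([c.labels for c in clouds]),
        clouds[0].frame,
        clouds[0].resolution,
    )


# ---------------------------------------------------------------------------
# unprojection / projection

def unproject(u, v, depth_value, intr: CameraIntrinsics):
    """Pixel (u=column, v=row) + depth (sensor units) -> (x, y, z) mm.

    z = depth / scaling_factor; x = (u - cx) z / f; y = (v - cy) z / fy.
    Non-positive depth is rejected.
    """
    u = np.asarray(u, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    depth_value = np.asarray(depth_value, dtype=np.float64)
    if np.any(depth_value <= 0):
        raise ValueError("depth_value must be positive (0 encodes no measurement)")
    z = depth_value / intr.scaling_factor
    x = (u - intr.center_x) * z / intr.focal_length
    y = (v - intr.center_y) * z / intr.fy
    return x, y, z


def project(points, intr: CameraIntrinsics):
    """Inverse of :func:`unproject`: camera-frame mm -> (u, v, depth units).

    Used by the synthetic renderer and as the round-trip oracle; points must
    be in front of the camera (z > 0).
    """
    pts = np.asarray(points, dtype=np.float64).reshape(-1, 3)
    z = pts[:, 2]
    if np.any(z <= 0):
        raise ValueError("all points must have z > 0 to project")
    u = pts[:, 0] * intr.focal_length / z + intr.center_x
    v = pts[:, 1] * intr.fy / z + intr.center_y
    return u, v, z * intr.scaling_factor


def build_semantic_cloud(
    labels: np.ndarray,
    depth: np.ndarray,
    intr: CameraIntrinsics,
    max_depth: float = DEFAULT_MAX_DEPTH_MM,
) -> SemanticPointCloud:
    """Unproject every plant-labeled pixel (codes 1..5) with valid depth.

    Background pixels and pixels with depth 0 or unprojected z beyond
    ``max_depth`` mm contribute no point.  Output is camera-frame.
    """
    labels = np.asarray(labels)
    depth = np.asarray(depth)
    if labels.shape != depth.shape:
        raise ValueError(
            f"semantic {labels.shape} and depth {depth.shape} dimensions differ"
        )
    mask = (labels >= 1) & (labels <= LABEL_PRUNING) & (depth > 0)
    z_all = depth / intr.scaling_factor
    mask &= z_all <= max_depth
    v, u = np.nonzero(mask)
    if len(v) == 0:
        return empty_cloud("camera")
    x, y, z = unproject(u, v, depth[v, u], intr)
    return SemanticPointCloud(np.column_stack([x, y, z]), labels[v, u], "camera")


def build_depth_cloud(
    depth: np.ndarray, intr: CameraIntrinsics, max_depth: float = DEFAULT_MAX_DEPTH_MM
) -> np.ndarray:
    """Unrestricted cloud from every valid-depth pixel (no label filter);
    the 'normal' cloud a semantic cloud is always a subset of."""
    depth = np.asarray(depth)
    mask = (depth > 0) & (depth / intr.scaling_factor <= max_depth)
    v, u = np.nonzero(mask)
    if len(v) == 0:
        return np.empty((0, 3))
    x, y, z = unproject(u, v, depth[v, u], intr)
    return np.column_stack([x, y, z])


def transform_cloud(cloud: SemanticPointCloud, pose) -> SemanticPointCloud:
    """Apply a camera->world rigid transform; the frame tag becomes 'world'."""
    if cloud.frame != "camera":
        raise ValueError("transform_cloud expects a camera-frame cloud")
    pts = pose.apply(cloud.points)
    return SemanticPointCloud(pts, cloud.labels.copy(), "world", cloud.resolution)


# ---------------------------------------------------------------------------
# filters

def voxel_downsample(cloud: SemanticPointCloud, r: float) -> SemanticPointCloud:
    """Collapse points within each r×r×r voxel to their centroid.

    The representative label is the voxel's majority label, ties resolved
    toward the smallest code.  Centroids are accumulated in double precision,
    so the result is independent of input point order.
    """
    if r <= 0:
        raise ValueError(f"voxel size must be positive, got {r}")
    if len(cloud) == 0:
        out = empty_cloud(cloud.frame)
        out.resolution = float(r)
        return out
    vox = np.floor(cloud.points / r).astype(np.int64)
    _, inv, counts = np.unique(vox, axis=0, return_inverse=True, return_counts=True)
    n_vox = len(counts)
    sums = np.zeros((n_vox, 3), dtype=np.float64)
    np.add.at(sums, inv, cloud.points)
    centroids = sums / counts[:, None]
    # majority label per voxel: count label occurrences on a (voxel, label) grid
    n_lab = int(cloud.labels.max()) + 1
    tally = np.zeros((n_vox, n_lab), dtype=np.int64)
    np.add.at(tally, (inv, cloud.labels.astype(np.int64)), 1)
    maj = np.argmax(tally, axis=1)  # argmax takes the first (smallest) code on ties
    return SemanticPointCloud(centroids, maj.astype(np.uint8), cloud.frame, float(r))


def statistical_outlier_removal(
    cloud: SemanticPointCloud, k: int = 20, std_mult: float = 2.0
) -> SemanticPointCloud:
    """Remove points whose mean k-NN distance exceeds mean + std_mult * std
    of the per-point means (the PCL StatisticalOutlierRemoval rule)."""
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if len(cloud) <= k:
        warnings.warn(
            f"cloud has {len(cloud)} <= k={k} points; outlier removal skipped",
            stacklevel=2,
        )
        return cloud
    tree = cKDTree(cloud.points)
    # k+1 because each point is its own nearest neighbor
    dists, _ = tree.query(cloud.points, k=k + 1)
    mean_d = dists[:, 1:].mean(axis=1)
    thresh = mean_d.mean() + std_mult * mean_d.std()
    return cloud.select(mean_d <= thresh)


# ---------------------------------------------------------------------------
# PLY I/O

def write_cloud(path, cloud: SemanticPointCloud, binary: bool = False,
                with_color: bool = False) -> None:
    """Write x/y/z float32 + label uchar (+ optional palette RGB) PLY."""
    props = ["property float x", "property float y", "property float z",
             "property uchar label"]
    if with_color:
        props += ["property uchar red", "property uchar green", "property uchar blue"]
    fmt = "binary_little_endian" if binary else "ascii"
    header = (
        "ply\n"
        f"format {fmt} 1.0\n"
        f"comment frame {cloud.frame}\n"
        + (f"comment resolution_mm {cloud.resolution}\n" if cloud.resolution else "")
        + f"element vertex {len(cloud)}\n"
        + "\n".join(props)
        + "\nend_header\n"
    )
    pts = cloud.points.astype(np.float32)
    colors = None
    if with_color:
        colors = np.zeros((len(cloud), 3), dtype=np.uint8)
        for code, rgb in PALETTE.items():
            colors[cloud.labels == code] = rgb
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        if binary:
            rec = struct.Struct("<fffB" + ("BBB" if with_color else ""))
            for i in range(len(cloud)):
                vals = [*pts[i], int(cloud.labels[i])]
                if with_color:
                    vals += [int(c) for c in colors[i]]
                fh.write(rec.pack(*vals))
        else:
            lines = []
            for i in range(len(cloud)):
                row = f"{pts[i, 0]:.6g} {pts[i, 1]:.6g} {pts[i, 2]:.6g} {cloud.labels[i]}"
                if with_color:
                    row += " " + " ".join(str(int(c)) for c in colors[i])
                lines.append(row)
            fh.write(("\n".join(lines) + ("\n" if lines else "")).encode("ascii"))


class PLYParseError(ValueError):
    pass


_PLY_TYPES = {"float": ("f", 4), "float32": ("f", 4), "double": ("d", 8),
              "uchar": ("B", 1), "uint8": ("B", 1), "char": ("b", 1),
              "int": ("i", 4), "int32": ("i", 4), "uint": ("I", 4),
              "short": ("h", 2), "ushort": ("H", 2)}


def read_cloud(path) -> SemanticPointCloud:
    """Read a PLY written by :func:`write_cloud` (or compatible)."""
    with open(path, "rb") as fh:
        data = fh.read()
    try:
        head_end = data.index(b"end_header\n") + len(b"end_header\n")
    except ValueError:
        raise PLYParseError("missing 'end_header' line") from None
    header_lines = data[:head_end].decode("ascii", errors="replace").splitlines()
    if not header_lines or header_lines[0].strip() != "ply":
        raise PLYParseError(f"not a PLY file, first line: {header_lines[:1]}")
    fmt = None
    n_vertex = None
    props: list[tuple[str, str]] = []
    frame = "camera"
    resolution = None
    in_vertex = False
    for line in header_lines[1:]:
        tok = line.split()
        if not tok:
            continue
        if tok[0] == "format":
            if len(tok) < 2 or tok[1] not in ("ascii", "binary_little_endian"):
                raise PLYParseError(f"unsupported format line: {line!r}")
            fmt = tok[1]
        elif tok[0] == "comment":
            if len(tok) >= 3 and tok[1] == "frame":
                frame = tok[2]
            elif len(tok) >= 3 and tok[1] == "resolution_mm":
                resolution = float(tok[2])
        elif tok[0] == "element":
            in_vertex = tok[1] == "vertex"
            if in_vertex:
                n_vertex = int(tok[2])
        elif tok[0] == "property" and in_vertex:
            if tok[1] not in _PLY_TYPES:
                raise PLYParseError(f"unsupported property type in line: {line!r}")
            props.append((tok[2], tok[1]))
    if fmt is None:
        raise PLYParseError("header has no 'format' line")
    if n_vertex is None:
        raise PLYParseError("header has no 'element vertex' line")
    names = [name for name, _ in props]
    for need in ("x", "y", "z"):
        if need not in names:
            raise PLYParseError(f"vertex element lacks property {need!r}")

    body = data[head_end:]
    if fmt == "ascii":
        rows = body.decode("ascii").split()
        ncol = len(props)
        if len(rows) < n_vertex * ncol:
            raise PLYParseError(
                f"expected {n_vertex * ncol} values, found {len(rows)}"
            )
        arr = np.array(rows[: n_vertex * ncol], dtype=np.float64).reshape(n_vertex, ncol)
        cols = {name: arr[:, i] for i, (name, _) in enumerate(props)}
    else:
        rec = struct.Struct("<" + "".join(_PLY_TYPES[t][0] for _, t in props))
        need = rec.size * n_vertex
        if len(body) < need:
            raise PLYParseError(f"binary body too short: {len(body)} < {need} bytes")
        raw = [rec.unpack_from(body, i * rec.size) for i in range(n_vertex)]
        arr = np.array(raw, dtype=np.float64).reshape(n_vertex, len(props))
        cols = {name: arr[:, i] for i, (name, _) in enumerate(props)}

    pts = np.column_stack([cols["x"], cols["y"], cols["z"]]) if n_vertex else np.empty((0, 3))
    if "label" in cols:
        labels = cols["label"].astype(np.uint8)
    elif n_vertex and {"red", "green", "blue"} <= set(cols):
        rgb = np.column_stack([cols["red"], cols["green"], cols["blue"]]).astype(int)
        rev = {v: k for k, v in PALETTE.items()}
        labels = np.array([rev.get(tuple(c), 0) for c in rgb], dtype=np.uint8)
    else:
        labels = np.zeros(n_vertex, dtype=np.uint8)
    return SemanticPointCloud(pts, labels, frame, resolution)
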