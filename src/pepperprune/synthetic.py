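"""Synthetic sweet-pepper scenes with known ground truth.

A plant is modeled as a vertical stem capsule with petiole capsules attached
at distinct heights, each carrying a leaf disc at its tip.  The world frame
is y-up with the stem base at the origin, so the physically lowest petiole
is the one with the smallest attachment y — consistent with selecting the
pruning cluster of minimal y downstream.  Cameras follow the pinhole
convention (x right, y down, z forward); a pose is the camera→world rigid
transform.

Frames are rendered by densely sampling the primitive surfaces, projecting
the samples through the pinhole model, and resolving occlusion with a
painter's z-buffer (samples drawn far to near).  Sampling density is tied to
the pixel footprint at the nearest working distance so rasters have no
sampling holes.  Optional Gaussian depth noise, depth dropout, and camera
pose jitter emulate a handheld sensor and a breeze-shaken plant.

The ground-truth pruning point of each petiole is the point where its axis
exits the stem surface — the cut position close to the stem.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import imageio.v3 as iio
import yaml

from .cloud import CameraIntrinsics
from .register import RigidTransform, save_tum_trajectory
from .semantic2d import LABEL_STEM, LABEL_PETIOLE, LABEL_LEAF

DEFAULT_WIDTH = 640
DEFAULT_HEIGHT = 480
DEFAULT_FOCAL = 525.0
DEFAULT_STEM_RADIUS = 6.0
DEFAULT_PETIOLE_RADIUS = 2.0
DEFAULT_PETIOLE_LENGTH = 90.0
DEFAULT_LEAF_RADIUS = 35.0
#: nearest working distance (mm) the sampling density is designed for
MIN_WORKING_DISTANCE = 400.0


class EmptyViewError(RuntimeError):
    """The plant projects to no pixel of the requested view."""


def default_intrinsics() -> CameraIntrinsics:
    """640×480 raster, Kinect-class focal length, depth units of 1 mm."""
    return CameraIntrinsics(
        focal_length=DEFAULT_FOCAL,
        center_x=(DEFAULT_WIDTH - 1) / 2.0,
        center_y=(DEFAULT_HEIGHT - 1) / 2.0,
        scaling_factor=1.0,
    )


@dataclass(frozen=True)
class Petiole:
    attachment: np.ndarray  # axis point on the stem centerline, mm
    direction: np.ndarray   # unit vector pointing away from the stem
    length: float
    radius: float


@dataclass(frozen=True)
class Leaf:
    center: np.ndarray
    normal: np.ndarray
    radius: float


@dataclass(frozen=True)
class PlantModel:
    """Stem + petioles + leaves with per-petiole truth pruning points."""

    stem_base: np.ndarray
    stem_height: float
    stem_radius: float
    petioles: tuple
    leaves: tuple
    truth_pruning_points: np.ndarray  # (n_petioles, 3) mm
    truth_lowest: int

    @property
    def centroid(self) -> np.ndarray:
        return self.stem_base + np.array([0.0, self.stem_height / 2.0, 0.0])


def make_plant(
    n_petioles: int = 3,
    stem_height_mm: float = 400.0,
    spacing_mm: float = 50.0,
    seed: int = 0,
    stem_radius_mm: float = DEFAULT_STEM_RADIUS,
    petiole_radius_mm: float = DEFAULT_PETIOLE_RADIUS,
    petiole_length_mm: float = DEFAULT_PETIOLE_LENGTH,
    leaf_radius_mm: float = DEFAULT_LEAF_RADIUS,
    azimuth_span_deg: float = 100.0,
    axis: str = "y",
    direction: str = "min",
) -> PlantModel:
    """Deterministically generate a plant for a given seed.

    Petioles attach at distinct heights at least ``spacing_mm`` apart,
    point outward with a slight upward tilt, and carry one leaf disc each
    at the tip.  Azimuths are randomized within a ``azimuth_span_deg``-wide
    sector about the lateral (±x) axes, alternating sides, which models the
    capture protocol: the operator frames the plant from a side where stem
    and petioles are visible, and petioles aligned with the camera's depth
    axis appear too steep in the image for junction detection (their painted
    region smears along the invisible depth direction).
    """
    if n_petioles < 1:
        raise ValueError("n_petioles must be >= 1")
    if spacing_mm <= 0:
        raise ValueError("spacing_mm must be positive")
    if n_petioles * spacing_mm > stem_height_mm:
        raise ValueError(
            f"{n_petioles} petioles with {spacing_mm} mm spacing do not fit "
            f"on a {stem_height_mm} mm stem"
        )
    rng = np.random.default_rng(seed)
    # heights: lowest petiole sits in the lower stem, gaps >= spacing
    lo = 0.15 * stem_height_mm
    hi = 0.9 * stem_height_mm
    slack = (hi - lo) - (n_petioles - 1) * spacing_mm
    if slack < 0:
        lo, hi = spacing_mm / 2.0, stem_height_mm
        slack = max(0.0, (hi - lo) - (n_petioles - 1) * spacing_mm)
    u = np.sort(rng.uniform(0.0, 1.0, n_petioles))
    heights = lo + u * slack + np.arange(n_petioles) * spacing_mm

    base = np.zeros(3)
    petioles = []
    leaves = []
    truths = []
    half_span = np.radians(azimuth_span_deg) / 2.0
    sides = rng.permutation(np.arange(n_petioles) % 2)
    for i, h in enumerate(heights):
        # alternate lateral sides; stay off the depth (±z) axis
        az = sides[i] * np.pi + rng.uniform(-half_span, half_span)
        # lower (pruning-age) petioles droop toward horizontal
        tilt = np.radians(rng.uniform(5.0, 25.0))
        d = np.array(
            [np.cos(az) * np.cos(tilt), np.sin(tilt), np.sin(az) * np.cos(tilt)]
        )
        attach = base + np.array([0.0, h, 0.0])
        pet = Petiole(
            attachment=attach,
            direction=d,
            length=petiole_length_mm,
            radius=petiole_radius_mm,
        )
        petioles.append(pet)
        tip = attach + d * petiole_length_mm
        # leaf plane tilted off the petiole axis so it can occlude others
        n = np.array([np.cos(az) * 0.4, 1.0, np.sin(az) * 0.4])
        n /= np.linalg.norm(n)
        leaves.append(Leaf(center=tip + d * leaf_radius_mm * 0.6,
                           normal=n, radius=leaf_radius_mm))
        # axis point where the petiole leaves the stem surface
        horiz = np.hypot(d[0], d[2])
        truths.append(attach + d * (stem_radius_mm / horiz))

    truths = np.asarray(truths)
    ax = {"x": 0, "y": 1, "z": 2}[axis]
    coord = truths[:, ax]
    lowest = int(np.argmin(coord) if direction == "min" else np.argmax(coord))
    return PlantModel(
        stem_base=base,
        stem_height=float(stem_height_mm),
        stem_radius=float(stem_radius_mm),
        petioles=tuple(petioles),
        leaves=tuple(leaves),
        truth_pruning_points=truths,
        truth_lowest=lowest,
    )


# ---------------------------------------------------------------------------
# surface sampling

def _basis(direction: np.ndarray):
    d = direction / np.linalg.norm(direction)
    helper = np.array([0.0, 1.0, 0.0])
    if abs(d @ helper) > 0.99:
        helper = np.array([1.0, 0.0, 0.0])
    e1 = np.cross(d, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(d, e1)
    return d, e1, e2


def _sample_cylinder(p0, direction, length, radius, spacing):
    d, e1, e2 = _basis(direction)
    n_ax = max(2, int(np.ceil(length / spacing)) + 1)
    n_ang = max(6, int(np.ceil(2 * np.pi * radius / spacing)))
    t = np.linspace(0.0, length, n_ax)
    ang = np.linspace(0.0, 2 * np.pi, n_ang, endpoint=False)
    tt, aa = np.meshgrid(t, ang, indexing="ij")
    pts = (
        p0[None, :]
        + tt.ravel()[:, None] * d
        + radius * np.cos(aa.ravel())[:, None] * e1
        + radius * np.sin(aa.ravel())[:, None] * e2
    )
    return pts


def _sample_disc(center, normal, radius, spacing):
    _, e1, e2 = _basis(normal)
    rings = max(1, int(np.ceil(radius / spacing)))
    pts = [center[None, :]]
    for k in range(1, rings + 1):
        rk = radius * k / rings
        n_ang = max(6, int(np.ceil(2 * np.pi * rk / spacing)))
        ang = np.linspace(0.0, 2 * np.pi, n_ang, endpoint=False)
        pts.append(
            center[None, :]
            + rk * np.cos(ang)[:, None] * e1
            + rk * np.sin(ang)[:, None] * e2
        )
    return np.vstack(pts)


def sample_plant_surfaces(
    plant: PlantModel, spacing_mm: float | None = None,
    focal_length: float = DEFAULT_FOCAL,
):
    """Deterministic surface point samples with semantic labels.

    Default spacing is half the pixel footprint at the nearest working
    distance (z_min / f / 2), giving ≥ 4 samples per projected pixel there.
    """
    if spacing_mm is None:
        spacing_mm = MIN_WORKING_DISTANCE / focal_length / 2.0
    chunks = []
    labels = []
    stem_dir = np.array([0.0, 1.0, 0.0])
    stem = _sample_cylinder(
        plant.stem_base, stem_dir, plant.stem_height, plant.stem_radius, spacing_mm
    )
    chunks.append(stem)
    labels.append(np.full(len(stem), LABEL_STEM, dtype=np.uint8))
    for pet in plant.petioles:
        pts = _sample_cylinder(
            pet.attachment, pet.direction, pet.length, pet.radius, spacing_mm
        )
        chunks.append(pts)
        labels.append(np.full(len(pts), LABEL_PETIOLE, dtype=np.uint8))
    for leaf in plant.leaves:
        pts = _sample_disc(leaf.center, leaf.normal, leaf.radius, spacing_mm)
        chunks.append(pts)
        labels.append(np.full(len(pts), LABEL_LEAF, dtype=np.uint8))
    return np.vstack(chunks), np.concatenate(labels)


# ---------------------------------------------------------------------------
# rendering

@dataclass(frozen=True)
class RenderedFrame:
    semantic: np.ndarray   # (H, W) uint8 labels
    depth: np.ndarray      # (H, W) sensor units, 0 = missing
    pose: RigidTransform   # camera -> world
    intrinsics: CameraIntrinsics


def render_frame(
    plant: PlantModel,
    pose: RigidTransform,
    intr: CameraIntrinsics | None = None,
    width: int = DEFAULT_WIDTH,
    height: int = DEFAULT_HEIGHT,
    depth_sigma_mm: float = 0.0,
    dropout_prob: float = 0.0,
    pose_jitter_mm: float = 0.0,
    rng: np.random.Generator | None = None,
    samples=None,
) -> RenderedFrame:
    """Render one semantic + depth frame by z-buffered point splatting.

    ``samples`` may carry precomputed ``sample_plant_surfaces`` output to
    avoid resampling across frames.  Noise (depth jitter, dropout, pose
    jitter) is drawn from ``rng`` and the returned pose is the jittered one
    the renderer actually used — the *reported* pose stays the caller's,
    emulating SLAM pose error.
    """
    if intr is None:
        intr = default_intrinsics()
    if rng is None:
        rng = np.random.default_rng(0)
    if samples is None:
        samples = sample_plant_surfaces(plant, focal_length=intr.focal_length)
    pts_world, labels = samples

    render_pose = pose
    if pose_jitter_mm > 0:
        render_pose = RigidTransform(
            pose.rotation, pose.translation + rng.normal(0.0, pose_jitter_mm, 3)
        )
    cam = render_pose.inverse().apply(pts_world)
    infront = cam[:, 2] > 1e-6
    cam = cam[infront]
    lab = labels[infront]
    if len(cam) == 0:
        raise EmptyViewError("plant is entirely behind the camera")
    z = cam[:, 2]
    u = np.rint(cam[:, 0] * intr.focal_length / z + intr.center_x).astype(np.int64)
    v = np.rint(cam[:, 1] * intr.fy / z + intr.center_y).astype(np.int64)
    ok = (u >= 0) & (u < width) & (v >= 0) & (v < height)
    if not ok.any():
        raise EmptyViewError("plant projects outside the image raster")
    u, v, z, lab = u[ok], v[ok], z[ok], lab[ok]

    # painter's algorithm: draw far to near, nearer samples overwrite
    order = np.argsort(-z, kind="stable")
    semantic = np.zeros((height, width), dtype=np.uint8)
    depth_mm = np.zeros((height, width), dtype=np.float64)
    semantic[v[order], u[order]] = lab[order]
    depth_mm[v[order], u[order]] = z[order]

    covered = depth_mm > 0
    if depth_sigma_mm > 0:
        noise = rng.normal(0.0, depth_sigma_mm, covered.sum())
        depth_mm[covered] = np.maximum(depth_mm[covered] + noise, 1.0)
    if dropout_prob > 0:
        drop = rng.random(covered.sum()) < dropout_prob
        vals = depth_mm[covered]
        vals[drop] = 0.0
        depth_mm[covered] = vals
        semantic[covered & (depth_mm == 0)] = 0

    depth = depth_mm * intr.scaling_factor
    return RenderedFrame(semantic=semantic, depth=depth, pose=pose, intrinsics=intr)


# ---------------------------------------------------------------------------
# camera trajectories

def look_at(position, target, up=(0.0, 1.0, 0.0)) -> RigidTransform:
    """Camera→world pose at ``position`` with the optical axis through
    ``target`` and image rows running against world-up (y-down camera)."""
    position = np.asarray(position, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    up = np.asarray(up, dtype=np.float64)
    zc = target - position
    norm = np.linalg.norm(zc)
    if norm < 1e-9:
        raise ValueError("camera position coincides with the look-at target")
    zc /= norm
    xc = np.cross(zc, up)
    xn = np.linalg.norm(xc)
    if xn < 1e-9:
        raise ValueError("viewing direction is parallel to the up vector")
    xc /= xn
    yc = np.cross(zc, xc)
    R = np.column_stack([xc, yc, zc])
    return RigidTransform(R, position)


def make_trajectory(
    kind: str,
    start_pose: RigidTransform,
    extent_mm: float = 100.0,
    n_frames: int = 12,
    target=None,
) -> list[RigidTransform]:
    """Camera poses sweeping up/left/right (or their concatenation, 'mix')
    from the start pose and returning to it, each oriented toward
    ``target`` when given (otherwise keeping the start orientation)."""
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if kind not in ("up", "left", "right", "mix"):
        raise ValueError(f"unknown trajectory kind {kind!r}")

    def sweep(direction: np.ndarray, n: int) -> list[np.ndarray]:
        if n == 1:
            return [np.zeros(3)]
        # sine arch: out to extent_mm mid-sweep, back to the start at the end
        prof = np.sin(np.pi * np.arange(n) / (n - 1))
        return [extent_mm * p * direction for p in prof]

    up_dir = np.array([0.0, 1.0, 0.0])
    left_dir = np.array([-1.0, 0.0, 0.0])
    right_dir = np.array([1.0, 0.0, 0.0])
    if kind == "mix":
        per = max(1, n_frames // 3)
        offsets = (
            sweep(up_dir, per)
            + sweep(left_dir, per)
            + sweep(right_dir, n_frames - 2 * per)
        )
    else:
        direction = {"up": up_dir, "left": left_dir, "right": right_dir}[kind]
        offsets = sweep(direction, n_frames)

    poses = []
    for off in offsets:
        pos = start_pose.translation + off
        if target is not None:
            poses.append(look_at(pos, target))
        else:
            poses.append(RigidTransform(start_pose.rotation, pos))
    return poses


def default_start_pose(plant: PlantModel, distance_mm: float = 550.0) -> RigidTransform:
    """Camera on the +z side at plant mid-height, facing the plant."""
    target = plant.centroid
    position = target + np.array([0.0, 0.0, distance_mm])
    return look_at(position, target)


# ---------------------------------------------------------------------------
# dataset export

def write_sequence(
    outdir,
    plant: PlantModel,
    poses: list[RigidTransform],
    intr: CameraIntrinsics | None = None,
    depth_sigma_mm: float = 0.0,
    dropout_prob: float = 0.0,
    pose_jitter_mm: float = 0.0,
    seed: int = 0,
    depth_format: str = "png16",
) -> Path:
    """Render a pose sequence into a directory consumable by the pipeline:
    per-frame semantic PNG + depth raster, manifest CSV, TUM trajectory,
    intrinsics/config YAML, and the ground-truth JSON.  Returns the manifest
    path."""
    if intr is None:
        intr = default_intrinsics()
    if depth_format not in ("png16", "npy"):
        raise ValueError("depth_format must be 'png16' or 'npy'")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    samples = sample_plant_surfaces(plant, focal_length=intr.focal_length)

    rows = []
    tum = []
    for i, pose in enumerate(poses):
        frame = render_frame(
            plant, pose, intr,
            depth_sigma_mm=depth_sigma_mm,
            dropout_prob=dropout_prob,
            pose_jitter_mm=pose_jitter_mm,
            rng=rng,
            samples=samples,
        )
        sem_path = outdir / f"semantic_{i:04d}.png"
        iio.imwrite(sem_path, frame.semantic)
        if depth_format == "png16":
            depth_path = outdir / f"depth_{i:04d}.png"
            iio.imwrite(depth_path, np.clip(np.rint(frame.depth), 0, 65535).astype(np.uint16))
        else:
            depth_path = outdir / f"depth_{i:04d}.npy"
            np.save(depth_path, frame.depth)
        ts = float(i)
        rows.append((i, sem_path.name, depth_path.name, ts))
        tum.append((ts, pose))

    manifest = outdir / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["frame_id", "semantic_path", "depth_path", "timestamp"])
        w.writerows(rows)
    save_tum_trajectory(outdir / "trajectory.txt", tum)
    config = {
        "intrinsics": {
            "focal_length": intr.focal_length,
            "center_x": intr.center_x,
            "center_y": intr.center_y,
            "scaling_factor": intr.scaling_factor,
        },
        "trajectory": "trajectory.txt",
    }
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(config, fh)
    truth = {
        "pruning_points_mm": plant.truth_pruning_points.tolist(),
        "lowest_index": plant.truth_lowest,
        "lowest_point_mm": plant.truth_pruning_points[plant.truth_lowest].tolist(),
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=2)
    return manifest
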