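"""End-to-end orchestration: frames in, lowest pruning point out.

Each frame contributes (semantic image, depth image, camera pose).  Per
frame the pipeline (1) detects 2D pruning regions and paints them into the
semantic raster as label 5, (2) unprojects the raster into a camera-frame
semantic cloud, (3) seeds ICP with the SLAM pose — the previous refined pose
composed with the raw pose delta — to register the cloud against the
accumulated world cloud, and (4) concatenates and voxel-downsamples the
result.  On a stop signal the accumulated cloud is optionally denoised and
passed to the 3D lowest-pruning-point search.

The live ROS start/stop loop is replaced by a frame manifest (CSV naming
semantic/depth rasters and timestamps) plus a TUM trajectory file; the
dataflow is otherwise the per-frame loop described above.
"""

from __future__ import annotations

import csv
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import imageio.v3 as iio
import yaml

from . import semantic2d
from .cloud import (
    CameraIntrinsics,
    SemanticPointCloud,
    build_semantic_cloud,
    concatenate_clouds,
    empty_cloud,
    statistical_outlier_removal,
    transform_cloud,
    voxel_downsample,
    write_cloud,
)
from .prune3d import PruningPoint3D, find_pruning_point
from .register import (
    ICPResult,
    NoOverlapError,
    RigidTransform,
    icp_align,
    load_tum_trajectory,
    pose_delta,
)

logger = logging.getLogger("pepperprune")


class EmptySequenceError(RuntimeError):
    pass


@dataclass(frozen=True)
class FrameRecord:
    frame_id: int
    semantic_path: Path
    depth_path: Path
    pose: RigidTransform
    timestamp: float = 0.0


@dataclass
class ICPConfig:
    enabled: bool = True
    max_iterations: int = 50
    max_correspondence_distance_mm: float | None = None  # None -> 30 x r
    convergence_delta_mm: float = 0.01
    match_labels: bool = False
    frame_to_frame: bool = False  # default: frame-to-model


@dataclass
class OutlierConfig:
    enabled: bool = True
    k: int = 20
    std_mult: float = 2.0


@dataclass
class PipelineConfig:
    """All tunables of the detection pipeline, in millimeters and pixels."""

    intrinsics: CameraIntrinsics = field(
        default_factory=lambda: CameraIntrinsics(525.0, 319.5, 239.5, 1.0)
    )
    resolution_mm: float = 1.0
    max_depth_mm: float = 1500.0
    kernel_size: int = 7
    min_area_2d: int | None = None  # None -> 50 scaled by raster area
    t_factor: float = 1.5
    merge_dist_mm: float | None = None  # None -> 5 x r
    min_cluster_size: int = 10
    axis: str = "y"
    direction: str = "min"
    icp: ICPConfig = field(default_factory=ICPConfig)
    outlier_removal: OutlierConfig = field(default_factory=OutlierConfig)
    random_seed: int = 0

    def __post_init__(self):
        if self.resolution_mm <= 0 or self.max_depth_mm <= 0 or self.t_factor <= 0:
            raise ValueError("resolution_mm, max_depth_mm and t_factor must be positive")
        if self.kernel_size < 1 or self.kernel_size % 2 == 0:
            raise ValueError("kernel_size must be odd and positive")

    @property
    def icp_capture_radius(self) -> float:
        if self.icp.max_correspondence_distance_mm is not None:
            return self.icp.max_correspondence_distance_mm
        return 30.0 * self.resolution_mm

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        if "intrinsics" in raw:
            kwargs["intrinsics"] = CameraIntrinsics(**raw["intrinsics"])
        if "icp" in raw:
            kwargs["icp"] = ICPConfig(**raw["icp"])
        if "outlier_removal" in raw:
            kwargs["outlier_removal"] = OutlierConfig(**raw["outlier_removal"])
        for key in (
            "resolution_mm", "max_depth_mm", "kernel_size", "min_area_2d",
            "t_factor", "merge_dist_mm", "min_cluster_size", "axis",
            "direction", "random_seed",
        ):
            if key in raw:
                kwargs[key] = raw[key]
        return cls(**kwargs)


@dataclass
class PipelineState:
    """Accumulated world cloud plus the pose bookkeeping ICP seeding needs."""

    cloud: SemanticPointCloud = field(default_factory=lambda: empty_cloud("world"))
    prev_frame_cloud: SemanticPointCloud | None = None
    prev_raw_pose: RigidTransform | None = None
    prev_refined_pose: RigidTransform | None = None
    n_frames: int = 0
    dropped_frames: list = field(default_factory=list)
    last_icp: ICPResult | None = None


def read_semantic_image(path) -> np.ndarray:
    labels = np.asarray(iio.imread(path))
    if labels.ndim == 3:  # palette/color PNG: collapse if grayscale-equal
        if not (labels[..., 0] == labels[..., 1]).all():
            raise ValueError(f"{path}: color semantic PNGs need a palette mapping")
        labels = labels[..., 0]
    return labels.astype(np.uint8)


def read_depth_image(path) -> np.ndarray:
    path = Path(path)
    if path.suffix == ".npy":
        return np.load(path).astype(np.float64)
    return np.asarray(iio.imread(path)).astype(np.float64)


def load_manifest(manifest_path, trajectory_path) -> list[FrameRecord]:
    """Join a frame manifest CSV with a TUM trajectory by nearest timestamp."""
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    poses = load_tum_trajectory(trajectory_path)
    if not poses:
        raise EmptySequenceError(f"no poses in trajectory {trajectory_path}")
    ts_arr = np.array([t for t, _ in poses])
    records = []
    with open(manifest_path, newline="") as fh:
        for row in csv.DictReader(fh):
            ts = float(row["timestamp"])
            j = int(np.argmin(np.abs(ts_arr - ts)))
            records.append(
                FrameRecord(
                    frame_id=int(row["frame_id"]),
                    semantic_path=base / row["semantic_path"],
                    depth_path=base / row["depth_path"],
                    pose=poses[j][1],
                    timestamp=ts,
                )
            )
    records.sort(key=lambda r: r.frame_id)
    return records


def process_frame(
    state: PipelineState, frame: FrameRecord, cfg: PipelineConfig
) -> PipelineState:
    """Fold one frame into the accumulated semantic cloud (mutates state)."""
    t0 = time.perf_counter()
    for p in (frame.semantic_path, frame.depth_path):
        if not Path(p).is_file():
            raise FileNotFoundError(f"frame {frame.frame_id}: missing input file {p}")
    labels = read_semantic_image(frame.semantic_path)
    depth = read_depth_image(frame.depth_path)

    regions = semantic2d.detect_pruning_regions(
        labels, min_area=cfg.min_area_2d, kernel_size=cfg.kernel_size
    )
    painted = semantic2d.paint_pruning_regions(labels, regions)
    cam_cloud = build_semantic_cloud(painted, depth, cfg.intrinsics, cfg.max_depth_mm)
    cam_cloud = voxel_downsample(cam_cloud, cfg.resolution_mm)

    if state.n_frames == 0 or not cfg.icp.enabled:
        refined_pose = frame.pose
        icp_res = None
    else:
        # seed with the SLAM motion: refined previous pose ∘ raw pose delta
        init = state.prev_refined_pose.compose(
            pose_delta(state.prev_raw_pose, frame.pose)
        )
        target = (
            state.prev_frame_cloud if cfg.icp.frame_to_frame else state.cloud
        )
        try:
            icp_res = icp_align(
                cam_cloud,
                target,
                init=init,
                max_iterations=cfg.icp.max_iterations,
                max_correspondence_distance=cfg.icp_capture_radius,
                convergence_delta=cfg.icp.convergence_delta_mm,
                match_labels=cfg.icp.match_labels,
            )
            refined_pose = icp_res.transform
        except NoOverlapError as err:
            logger.warning("frame %d dropped: %s", frame.frame_id, err)
            state.dropped_frames.append(frame.frame_id)
            return state

    world_cloud = transform_cloud(cam_cloud, refined_pose)
    merged = (
        world_cloud
        if state.n_frames == 0
        else concatenate_clouds([state.cloud, world_cloud])
    )
    state.cloud = voxel_downsample(merged, cfg.resolution_mm)
    state.prev_frame_cloud = world_cloud
    state.prev_raw_pose = frame.pose
    state.prev_refined_pose = refined_pose
    state.n_frames += 1
    state.last_icp = icp_res
    logger.info(
        "frame %d: %d regions, %d pts, cloud %d pts (%.3f s)",
        frame.frame_id, len(regions), len(cam_cloud), len(state.cloud),
        time.perf_counter() - t0,
    )
    return state


def finalize(state: PipelineState, cfg: PipelineConfig):
    """Run the 3D lowest-pruning-point search on the accumulated cloud.

    Returns (PruningPoint3D, report dict).
    """
    if state.n_frames == 0:
        raise EmptySequenceError("no frames were processed")
    cloud = state.cloud
    if cfg.outlier_removal.enabled and len(cloud) > cfg.outlier_removal.k:
        cloud = statistical_outlier_removal(
            cloud, k=cfg.outlier_removal.k, std_mult=cfg.outlier_removal.std_mult
        )
    point, clusters = find_pruning_point(
        cloud,
        t_factor=cfg.t_factor,
        merge_dist=cfg.merge_dist_mm,
        min_size=cfg.min_cluster_size,
        axis=cfg.axis,
        direction=cfg.direction,
    )
    x, y, z = point.position
    report = {
        "x_mm": round(x, 6),
        "y_mm": round(y, 6),
        "z_mm": round(z, 6),
        "cluster_size": point.source_cluster.size,
        "n_clusters_considered": len(clusters),
        "n_frames": state.n_frames,
        "n_points": len(state.cloud),
        "dropped_frames": list(state.dropped_frames),
    }
    return point, report, cloud


def run_pipeline(
    frames: list[FrameRecord],
    cfg: PipelineConfig,
    report_path=None,
    ply_path=None,
):
    """Process a full frame sequence and emit the report (and optional
    annotated PLY, pruning cluster painted as label 5 around the point)."""
    if not frames:
        raise EmptySequenceError("frame sequence is empty")
    state = PipelineState()
    for frame in frames:
        process_frame(state, frame, cfg)
    point, report, final_cloud = finalize(state, cfg)
    if report_path is not None:
        with open(report_path, "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
            fh.write("\n")
    if ply_path is not None:
        write_cloud(ply_path, final_cloud, with_color=True)
    return point, report
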