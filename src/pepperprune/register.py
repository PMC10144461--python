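"""Rigid registration of semantic point clouds.

Successive per-frame clouds are aligned by point-to-point ICP: alternate
nearest-neighbor correspondence within a capture radius and the closed-form
least-squares rigid fit (cross-covariance SVD with reflection correction),
seeded by the visual-SLAM pose delta so only residual drift remains to be
estimated.  ICP runs on voxel-downsampled semantic clouds, which are small
enough for the kd-tree query to dominate the cost.

Camera poses are exchanged in TUM trajectory format
(``timestamp tx ty tz qx qy qz qw``, translation in meters, Hamilton
quaternion with w last); translations convert to millimeters on load.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .cloud import SemanticPointCloud

_ORTHO_TOL = 1e-6


class DegenerateGeometryError(ValueError):
    """Correspondences do not constrain a unique rigid transform."""


class NoOverlapError(RuntimeError):
    """No correspondence found within the capture radius."""


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion p -> R p + t (rotation 3x3, translation mm)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=np.float64).reshape(3, 3)
        t = np.asarray(self.translation, dtype=np.float64).reshape(3)
        err = np.abs(R.T @ R - np.eye(3)).max()
        if err > _ORTHO_TOL:
            raise ValueError(f"rotation is not orthonormal (max |R'R - I| = {err:.3g})")
        det = np.linalg.det(R)
        if abs(det - 1.0) > _ORTHO_TOL:
            raise ValueError(f"rotation must have det +1, got {det:.9f}")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_matrix(cls, m: np.ndarray) -> "RigidTransform":
        m = np.asarray(m, dtype=np.float64).reshape(4, 4)
        return cls(m[:3, :3], m[:3, 3])

    def matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=np.float64)
        return pts @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other: apply ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation)

    def rotation_angle_deg(self) -> float:
        """Magnitude of the rotation, in degrees."""
        cos = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.degrees(np.arccos(np.clip(cos, -1.0, 1.0))))


@dataclass(frozen=True)
class ICPResult:
    transform: RigidTransform
    rms_error: float
    iterations: int
    converged: bool
    correspondence_count: int
    rms_trace: tuple = field(default=(), repr=False)


def pose_delta(prev_pose: RigidTransform, curr_pose: RigidTransform) -> RigidTransform:
    """Transform mapping the current camera frame into the previous one:
    prev_pose⁻¹ ∘ curr_pose."""
    return prev_pose.inverse().compose(curr_pose)


def best_fit_transform(
    source_pts: np.ndarray, target_pts: np.ndarray, correspondences=None
) -> RigidTransform:
    """Least-squares rigid transform minimizing Σ‖R s_i + t − t_i‖².

    Solved by SVD of the centered cross-covariance (Kabsch), with the
    determinant-correction that excludes reflections.  At least three
    correspondence pairs spanning a plane (rank ≥ 2) are required.
    """
    src = np.asarray(source_pts, dtype=np.float64).reshape(-1, 3)
    dst = np.asarray(target_pts, dtype=np.float64).reshape(-1, 3)
    if correspondences is not None:
        idx = np.asarray(correspondences)
        src = src[idx[:, 0]]
        dst = dst[idx[:, 1]]
    if len(src) != len(dst):
        raise ValueError("source and target correspondence counts differ")
    if len(src) < 3:
        raise DegenerateGeometryError(
            f"need >= 3 correspondence pairs, got {len(src)}"
        )
    src_c = src - src.mean(axis=0)
    dst_c = dst - dst.mean(axis=0)
    H = src_c.T @ dst_c
    U, S, Vt = np.linalg.svd(H)
    scale = max(S[0], 1.0)
    if S[1] < 1e-9 * scale:  # points (near-)collinear: rotation not unique
        raise DegenerateGeometryError(
            "correspondences are collinear; rigid transform is not unique"
        )
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = dst.mean(axis=0) - R @ src.mean(axis=0)
    return RigidTransform(R, t)


def icp_align(
    source: SemanticPointCloud,
    target: SemanticPointCloud,
    init: RigidTransform | None = None,
    max_iterations: int = 50,
    max_correspondence_distance: float = 30.0,
    convergence_delta: float = 0.01,
    match_labels: bool = False,
) -> ICPResult:
    """Point-to-point ICP aligning ``source`` onto ``target``.

    Iterates nearest-neighbor matching within ``max_correspondence_distance``
    (mm) against the fixed target kd-tree, then the closed-form rigid fit on
    the matched pairs.  Stops when the change in rms residual falls below
    ``convergence_delta`` mm or after ``max_iterations``.  The returned
    transform maps original source coordinates into the target frame
    (the initial guess is composed in).

    With ``match_labels`` correspondences are restricted to points of the
    same semantic class.
    """
    if len(source) == 0 or len(target) == 0:
        raise ValueError("ICP requires nonempty source and target clouds")
    if init is None:
        init = RigidTransform.identity()

    if match_labels:
        trees = {
            int(lab): (cKDTree(target.points[target.labels == lab]),
                       np.nonzero(target.labels == lab)[0])
            for lab in np.unique(target.labels)
        }
    else:
        tree = cKDTree(target.points)

    current = init
    prev_rms = np.inf
    rms = np.inf
    trace = []
    n_corr = 0
    converged = False
    iterations = 0
    for iterations in range(1, max_iterations + 1):
        moved = current.apply(source.points)
        if match_labels:
            dists = np.full(len(moved), np.inf)
            nn = np.zeros(len(moved), dtype=np.int64)
            for lab, (ltree, lidx) in trees.items():
                sel = source.labels == lab
                if not sel.any() or ltree.n == 0:
                    continue
                d, j = ltree.query(moved[sel])
                dists[sel] = d
                nn[sel] = lidx[j]
        else:
            dists, nn = tree.query(moved)
        good = dists <= max_correspondence_distance
        n_corr = int(good.sum())
        if n_corr == 0:
            raise NoOverlapError(
                "no correspondences within "
                f"{max_correspondence_distance} mm at iteration {iterations}"
            )
        rms = float(np.sqrt(np.mean(dists[good] ** 2)))
        trace.append(rms)
        # stop before stepping: residual already below the tolerance, or no
        # longer improving by more than it
        if rms < convergence_delta or abs(prev_rms - rms) < convergence_delta:
            converged = True
            break
        step = best_fit_transform(moved[good], target.points[nn[good]])
        current = step.compose(current)
        prev_rms = rms

    return ICPResult(
        transform=current,
        rms_error=rms,
        iterations=iterations,
        converged=converged,
        correspondence_count=n_corr,
        rms_trace=tuple(trace),
    )


# ---------------------------------------------------------------------------
# TUM trajectory I/O

def load_tum_trajectory(path) -> list[tuple[float, RigidTransform]]:
    """Read (timestamp, pose) pairs from a TUM-format file.

    Lines are ``timestamp tx ty tz qx qy qz qw`` with translation in meters
    (converted to mm) and a Hamilton quaternion, w last.  '#' lines are
    comments.
    """
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            tok = line.split()
            if len(tok) != 8:
                raise ValueError(
                    f"{path}:{ln}: expected 8 fields (t tx ty tz qx qy qz qw), "
                    f"got {len(tok)}"
                )
            vals = [float(x) for x in tok]
            ts = vals[0]
            t_mm = np.array(vals[1:4]) * 1000.0
            R = Rotation.from_quat(vals[4:8]).as_matrix()  # scipy: w last
            out.append((ts, RigidTransform(R, t_mm)))
    return out


def save_tum_trajectory(path, poses: list[tuple[float, RigidTransform]]) -> None:
    with open(path, "w") as fh:
        fh.write("# timestamp tx ty tz qx qy qz qw (meters)\n")
        for ts, pose in poses:
            q = Rotation.from_matrix(pose.rotation).as_quat()
            t = pose.translation / 1000.0
            fh.write(
                f"{ts:.6f} {t[0]:.9f} {t[1]:.9f} {t[2]:.9f} "
                f"{q[0]:.9f} {q[1]:.9f} {q[2]:.9f} {q[3]:.9f}\n"
            )
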