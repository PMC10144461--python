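"""Unprojection, semantic-cloud construction, filters, and PLY round trips."""

import numpy as np
import pytest

import pepperprune as pp
from pepperprune.cloud import (
    PLYParseError,
    build_depth_cloud,
    concatenate_clouds,
    empty_cloud,
    project,
)
from conftest import random_cloud

INTR = pp.CameraIntrinsics(focal_length=525.0, center_x=319.5, center_y=239.5,
                           scaling_factor=1.0)


class TestUnproject:
    def test_principal_point_ray(self):
        x, y, z = pp.unproject(319.5, 239.5, 800.0, INTR)
        assert (x, y, z) == (0.0, 0.0, 800.0)

    def test_depth_scaling_is_similarity(self):
        x1, y1, z1 = pp.unproject(100, 50, 400.0, INTR)
        x2, y2, z2 = pp.unproject(100, 50, 800.0, INTR)
        assert np.allclose([x2, y2, z2], [2 * x1, 2 * y1, 2 * z1])

    def test_project_unproject_round_trip(self):
        rng = np.random.default_rng(1)
        pts = np.column_stack([
            rng.uniform(-300, 300, 1000),
            rng.uniform(-300, 300, 1000),
            rng.uniform(200, 1400, 1000),
        ])
        u, v, d = project(pts, INTR)
        x, y, z = pp.unproject(u, v, d, INTR)
        rec = np.column_stack([x, y, z])
        rel = np.abs(rec - pts) / np.abs(pts).clip(min=1e-9)
        assert rel.max() < 1e-6

    def test_rejects_nonpositive_depth(self):
        with pytest.raises(ValueError):
            pp.unproject(10, 10, 0.0, INTR)

    def test_scaling_factor_units(self):
        # depth raster in 0.1mm units: scaling_factor = 10 per mm
        intr = pp.CameraIntrinsics(525.0, 319.5, 239.5, scaling_factor=10.0)
        _, _, z = pp.unproject(0, 0, 5000.0, intr)
        assert z == 500.0


class TestBuildSemanticCloud:
    def test_empty_image(self):
        cloud = pp.build_semantic_cloud(
            np.zeros((10, 10), np.uint8), np.full((10, 10), 500.0), INTR
        )
        assert len(cloud) == 0

    def test_four_petiole_pixels(self):
        intr = pp.CameraIntrinsics(100.0, 5.0, 5.0, 1.0)
        sem = np.zeros((10, 10), np.uint8)
        depth = np.zeros((10, 10))
        for r, c in [(2, 2), (2, 3), (3, 2), (3, 3)]:
            sem[r, c] = 2
            depth[r, c] = 500.0
        cloud = pp.build_semantic_cloud(sem, depth, intr)
        assert len(cloud) == 4
        assert np.all(cloud.labels == 2)
        assert np.allclose(cloud.points[:, 2], 500.0)
        # hand unprojection of pixel (row 2, col 3): x=(3-5)*5, y=(2-5)*5
        match = np.isclose(cloud.points[:, 0], -10) & np.isclose(cloud.points[:, 1], -15)
        assert match.sum() == 1

    def test_max_depth_filter(self):
        sem = np.full((10, 10), 2, np.uint8)
        depth = np.full((10, 10), 1600.0)
        assert len(pp.build_semantic_cloud(sem, depth, INTR)) == 0
        assert len(pp.build_semantic_cloud(sem, depth, INTR, max_depth=1700)) == 100

    def test_zero_depth_pixels_skipped(self):
        sem = np.full((8, 8), 1, np.uint8)
        depth = np.zeros((8, 8))
        depth[0, 0] = 700.0
        assert len(pp.build_semantic_cloud(sem, depth, INTR)) == 1

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            pp.build_semantic_cloud(np.zeros((8, 8), np.uint8), np.zeros((8, 9)), INTR)

    def test_semantic_subset_of_depth_cloud(self):
        rng = np.random.default_rng(2)
        sem = rng.integers(0, 5, (30, 30)).astype(np.uint8)
        depth = rng.uniform(100, 2000, (30, 30))
        semantic = pp.build_semantic_cloud(sem, depth, INTR)
        normal = build_depth_cloud(depth, INTR)
        assert len(semantic) <= len(normal)
        valid = (sem >= 1) & (depth > 0) & (depth <= 1500.0)
        assert len(semantic) == valid.sum()


class TestTransformCloud:
    def test_identity_and_translation(self):
        cloud = random_cloud(50, 7)
        cloud.frame = "camera"
        out = pp.transform_cloud(cloud, pp.RigidTransform.identity())
        assert np.allclose(out.points, cloud.points)
        assert out.frame == "world"
        shifted = pp.transform_cloud(
            cloud, pp.RigidTransform(np.eye(3), [10, 0, 0])
        )
        assert np.allclose(shifted.points[:, 0], cloud.points[:, 0] + 10)
        assert np.array_equal(shifted.labels, cloud.labels)

    def test_composition_matches_sequential_application(self):
        rng = np.random.default_rng(3)
        from scipy.spatial.transform import Rotation
        t1 = pp.RigidTransform(Rotation.random(random_state=1).as_matrix(),
                               rng.uniform(-50, 50, 3))
        t2 = pp.RigidTransform(Rotation.random(random_state=2).as_matrix(),
                               rng.uniform(-50, 50, 3))
        pts = rng.uniform(-100, 100, (20, 3))
        assert np.allclose(t2.compose(t1).apply(pts), t2.apply(t1.apply(pts)),
                           atol=1e-9)

    def test_rejects_non_orthonormal_rotation(self):
        with pytest.raises(ValueError):
            pp.RigidTransform(np.eye(3) * 1.01, np.zeros(3))


class TestVoxelDownsample:
    def test_merge_to_midpoint(self):
        cloud = pp.SemanticPointCloud(
            [[0.0, 0.0, 0.0], [0.1, 0.0, 0.0]], [2, 2], "world"
        )
        out = pp.voxel_downsample(cloud, 1.0)
        assert len(out) == 1
        assert np.allclose(out.points[0], [0.05, 0, 0])
        assert out.resolution == 1.0

    def test_grid_points_unchanged(self):
        xs = np.arange(0, 10, 2.0)
        pts = np.array([[x, 0.5, 0.5] for x in xs])
        cloud = pp.SemanticPointCloud(pts, np.ones(len(pts)), "world")
        assert len(pp.voxel_downsample(cloud, 1.0)) == len(pts)

    def test_count_matches_voxel_hash_oracle(self):
        cloud = random_cloud(1000, 9)
        r = 5.0
        out = pp.voxel_downsample(cloud, r)
        occupied = {tuple(v) for v in np.floor(cloud.points / r).astype(int)}
        assert len(out) == len(occupied)

    def test_permutation_invariance(self):
        cloud = random_cloud(500, 4)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(cloud))
        shuffled = pp.SemanticPointCloud(
            cloud.points[perm], cloud.labels[perm], "world"
        )
        a = pp.voxel_downsample(cloud, 3.0)
        b = pp.voxel_downsample(shuffled, 3.0)
        ia = np.lexsort(a.points.T)
        ib = np.lexsort(b.points.T)
        assert np.allclose(a.points[ia], b.points[ib])
        assert np.array_equal(a.labels[ia], b.labels[ib])

    def test_majority_label_with_smallest_code_tie_break(self):
        cloud = pp.SemanticPointCloud(
            [[0.1, 0.1, 0.1], [0.2, 0.2, 0.2], [0.3, 0.3, 0.3], [0.4, 0.4, 0.4]],
            [3, 3, 1, 1], "world",
        )
        out = pp.voxel_downsample(cloud, 1.0)
        assert out.labels[0] == 1  # tie 2-2 resolved toward smaller code

    def test_rejects_nonpositive_resolution(self):
        with pytest.raises(ValueError):
            pp.voxel_downsample(random_cloud(5, 0), 0.0)


class TestStatisticalOutlierRemoval:
    def test_single_far_point_removed(self):
        rng = np.random.default_rng(6)
        tight = rng.normal(0, 2.0, (100, 3))
        pts = np.vstack([tight, [[500.0, 0.0, 0.0]]])
        cloud = pp.SemanticPointCloud(pts, np.ones(101), "world")
        out = pp.statistical_outlier_removal(cloud, k=10, std_mult=1.0)
        assert len(out) == 100
        assert np.abs(out.points).max() < 100

    def test_identical_points_kept(self):
        cloud = pp.SemanticPointCloud(np.zeros((30, 3)), np.ones(30), "world")
        out = pp.statistical_outlier_removal(cloud, k=5, std_mult=1.0)
        assert len(out) == 30

    def test_monotone_in_std_mult(self):
        cloud = random_cloud(300, 12)
        kept = [
            len(pp.statistical_outlier_removal(cloud, k=10, std_mult=m))
            for m in (0.5, 1.0, 2.0, 4.0)
        ]
        assert kept == sorted(kept)

    def test_small_cloud_returned_with_warning(self):
        cloud = random_cloud(5, 1)
        with pytest.warns(UserWarning):
            out = pp.statistical_outlier_removal(cloud, k=10)
        assert len(out) == 5


class TestPLYRoundTrip:
    @pytest.mark.parametrize("binary", [False, True])
    def test_empty_cloud(self, tmp_path, binary):
        path = tmp_path / "empty.ply"
        pp.write_cloud(path, empty_cloud("world"), binary=binary)
        back = pp.read_cloud(path)
        assert len(back) == 0 and back.frame == "world"

    @pytest.mark.parametrize("binary", [False, True])
    @pytest.mark.parametrize("with_color", [False, True])
    def test_three_point_round_trip(self, tmp_path, binary, with_color):
        cloud = pp.SemanticPointCloud(
            [[1.25, -2.5, 300.0], [0.0, 0.125, 999.5], [-7.0, 8.0, 9.0]],
            [1, 2, 5], "world", resolution=1.0,
        )
        path = tmp_path / "c.ply"
        pp.write_cloud(path, cloud, binary=binary, with_color=with_color)
        back = pp.read_cloud(path)
        assert np.array_equal(back.labels, cloud.labels)
        assert np.abs(back.points - cloud.points).max() <= 1e-5
        assert back.resolution == 1.0

    def test_palette_color_reimport(self, tmp_path):
        cloud = pp.SemanticPointCloud([[1.0, 2.0, 3.0]], [2], "world")
        path = tmp_path / "pal.ply"
        pp.write_cloud(path, cloud, with_color=True)
        text = path.read_text()
        r, g, b = pp.cloud.PALETTE[2]
        assert f"{r} {g} {b}" in text
        assert pp.read_cloud(path).labels[0] == 2

    def test_malformed_header_names_offender(self, tmp_path):
        path = tmp_path / "bad.ply"
        path.write_bytes(b"ply\nformat binary_big_endian 1.0\nend_header\n")
        with pytest.raises(PLYParseError, match="format"):
            pp.read_cloud(path)
        path.write_bytes(b"not a ply\n")
        with pytest.raises(PLYParseError):
            pp.read_cloud(path)


def test_concatenate_rejects_mixed_frames():
    a = random_cloud(5, 0)
    b = random_cloud(5, 1)
    b.frame = "camera"
    with pytest.raises(ValueError):
        concatenate_clouds([a, b])
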