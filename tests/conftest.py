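import numpy as np
import pytest

import pepperprune as pp


@pytest.fixture
def toy_junction_image():
    """40x40 raster: vertical stem bar (cols 18-21) touched by a horizontal
    petiole bar (rows 18-21, cols 22-35)."""
    img = np.zeros((40, 40), dtype=np.uint8)
    img[:, 18:22] = 1
    img[18:22, 22:36] = 2
    return img


@pytest.fixture(scope="session")
def plant0():
    """The committed acceptance plant: 3 petioles, 50 mm spacing, seed 0."""
    return pp.make_plant(n_petioles=3, spacing_mm=50, seed=0)


@pytest.fixture(scope="session")
def mix_frames(plant0):
    """Noise-free 12-frame mix-trajectory renders of the acceptance plant."""
    start = pp.default_start_pose(plant0)
    poses = pp.make_trajectory(
        "mix", start, extent_mm=100, n_frames=12, target=plant0.centroid
    )
    samples = pp.sample_plant_surfaces(plant0)
    return [
        pp.render_frame(plant0, pose, samples=samples) for pose in poses
    ]


@pytest.fixture(scope="session")
def mix_sequence_dir(tmp_path_factory, plant0):
    """The same sequence written to disk in pipeline-consumable layout."""
    out = tmp_path_factory.mktemp("mixseq")
    start = pp.default_start_pose(plant0)
    poses = pp.make_trajectory(
        "mix", start, extent_mm=100, n_frames=12, target=plant0.centroid
    )
    manifest = pp.write_sequence(out, plant0, poses, seed=0)
    return out, manifest


def random_cloud(n, seed, extent=50.0):
    rng = np.random.default_rng(seed)
    pts = rng.uniform(0.0, extent, (n, 3))
    labels = rng.integers(1, 6, n).astype(np.uint8)
    return pp.SemanticPointCloud(pts, labels, "world")
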