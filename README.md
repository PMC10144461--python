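# pepperprune

Detects the pruning point of the lowest sweet-pepper petiole in 3D from
multi-view semantic RGB-D frames.

Greenhouse sweet pepper is pruned by cutting the lowest leaves' petioles
close to the stem. Given per-frame triplets of (semantic label image, depth
image, camera pose) — the outputs of an upstream segmentation network and a
visual-SLAM system, neither of which is part of this package — the library:

1. finds stem–petiole junctions in each 2D semantic image by layer
   separation, connected-component denoising, 7×7 dilation and
   intersection (pixel codes: 1 stem, 2 petiole, 3 leaf, 4 fruit, 5
   detected pruning region);
2. unprojects plant-labeled pixels into a labeled point cloud
   (z = depth/s, x = (u−cx)·z/f, y = (v−cy)·z/f, millimeters, 1.5 m depth
   cut) and voxel-downsamples at resolution r (default 1 mm);
3. fuses the per-frame clouds across viewpoints, refining the SLAM poses
   with point-to-point ICP (SVD/Kabsch inner step, kd-tree
   correspondences, seeded by the pose delta);
4. clusters the pruning-labeled points with a Euclidean threshold
   t = 1.5·r, merges cross-viewpoint patches, drops small clusters, and
   reports the centroid of the cluster lowest along the vertical axis.

A synthetic plant generator (stem/petiole capsules + leaf discs, z-buffer
renderer, up/left/right/mix camera arcs, depth noise / dropout / pose
jitter) provides ground-truth scenes so the whole chain is testable without
a camera, a robot, or a trained network. See `docs/methods.md` for the
model, parameters, and known limitations.

## Worked example

```sh
# render a 12-frame mixed-trajectory sequence of a synthetic plant
detect-pruning synth --plant-seed 1 --trajectory mix --frames 12 --out demo/

# run the detection pipeline on it
detect-pruning run --manifest demo/manifest.csv --config demo/config.yaml \
    --out demo/report.json --ply demo/cloud.ply
```

prints

```json
{
  "cluster_size": 74,
  "dropped_frames": [],
  "n_clusters_considered": 3,
  "n_frames": 12,
  "n_points": 19673,
  "x_mm": -8.742211,
  "y_mm": 91.43845,
  "z_mm": 4.778317
}
```

Three pruning-region clusters survived (one per petiole of the synthetic
plant); the lowest one, 74 points strong, has its centroid at
(−8.7, 91.4, 4.8) mm in the world frame — the recommended cut position,
4.3 mm from the generator's ground-truth attachment point of the lowest
petiole. `demo/cloud.ply` holds the fused semantic cloud with the standard
palette (stem purple, petiole pink, leaf green, pruning regions blue).

The same steps are available as library calls (`make_plant`,
`write_sequence`, `load_manifest`, `run_pipeline`); `detect-pruning
regions2d --semantic img.png` runs just the 2D junction detector on one
image.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

regenerates the seeded synthetic sequence, runs the full pipeline on it,
prints the detected pruning point alongside its distance to the generator's
ground truth, and writes the acceptance JSON to `--out`.
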