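# livestock3d

Multi-view 3D reconstruction of livestock from synchronized depth
cameras in fenced environments.

Body measurements of cattle — weight estimates, conformation traits —
can be derived from an accurate 3D surface model, but capturing one on
a working farm is hard: fences occlude the animal and create noisy
rims in every camera's data, and the camera rig's calibrated poses
drift with wind and vibration, so the per-camera clouds no longer agree
when mapped into world coordinates.  `livestock3d` implements the full
processing chain for such a rig:

- **Depth ingestion** — pinhole back-projection of 16-bit depth PNGs
  (millimeters) into organized clouds, grid triangulation into
  counter-clockwise meshes, per-vertex normals.
- **Segmentation** — background subtraction against a KD-tree of an
  animal-free capture, long-edge triangle removal at depth
  discontinuities, iterative half-edge boundary erosion, noise-blob
  filtering.
- **Sphere-target calibration** — per-camera sphere fits, center
  correspondence via a distinct pairwise-distance pattern, closed-form
  (Kabsch) pairwise extrinsics chained to a reference camera.
- **Pose-anchored interleaved registration** — the core: minimize

      E(T) = Σᵢ Σ_{p∈Pᵢ} Dist(M, Tᵢ p)² + Σᵢ Γ(Tᵢ, Tᵢ⁰),
      Γ(T, T⁰) = k_r‖r‖² + k_t‖t‖²,

  alternating between rebuilding the global surface M from all cameras
  and aligning each camera to M by Gauss-Newton on a small-angle
  6-parameter increment (point-to-plane residuals, 0.14 m validity
  cutoff, at most 25 iterations).  The anchor Γ keeps every camera near
  its calibrated pose and removes the gauge freedom of the data term.
- **Surface reconstruction** — watertight meshing of the pooled
  oriented points via an implicit moving-least-squares signed field on
  a 2^depth grid with marching cubes (depth 8 intermediate / 9 final at
  full scale), with occlusion holes bridged and low-density fringes
  trimmed.
- **Synthetic scene simulator** — a parametric animal body, floor,
  fence bars and a 10-camera ring with ray-cast-equivalent depth
  rendering, ground-truth poses and per-pixel labels; every stage of
  the pipeline is tested against it.

A seeded population optimizer over all pose parameters (bounds ±3°,
±0.1 m) is included as the global-optimization baseline the interleaved
method is compared against.

## Worked example

```bash
python examples/simulate_and_reconstruct.py
```

builds a 10-camera synthetic scene, perturbs each camera pose by up to
±2° / ±5 cm per axis, adds 1 mm depth noise, and registers everything:

```
initial pose error : 1.98 deg / 92.2 mm (mean over 10 cameras)
after 21 interleaved iterations:
  pose error       : 0.79 deg / 22.7 mm
  residual         : 6.98 mm -> 0.97 mm (mean point-to-plane of overlap points)
  final mesh       : 32015 vertices, 63826 triangles, watertight=True
```

The residual line is the mean point-to-plane distance of the overlap
points to the reconstructed model — the quantity the optimization
drives down; its drop to the 1 mm sensor-noise floor means the clouds
agree with the model about as well as the data allows.  The pose error
compares refined extrinsics to the simulator's ground truth after
removing the global gauge: most of the (deliberately large) initial
error is recovered, and the remaining part is a tangential slide the
point-to-plane objective is nearly blind to on a smooth body — see
`docs/methods.md` for the analysis, and for the sub-millimeter behavior
in the calibration-quality regime the rig actually operates in.

The other examples (`segment_single_camera.py`, `sphere_calibration.py`,
`surface_from_points.py`) each exercise one stage in isolation.

A thin CLI mirrors the stages for shell use:

```bash
livestock3d simulate --seed 7 --n-cameras 10 -o scene/
livestock3d run scene/ -o out/          # segment + register + surface
livestock3d segment --frame scene/depth_0.png \
    --background scene/environment_0.png --rig scene/rig.yaml -o cow0.ply
```

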