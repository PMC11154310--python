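"""End-to-end reconstruction of a synthetic farm capture.

Builds a 10-camera ring scene around a parametric animal body, perturbs
the camera poses (emulating calibration drift / rig vibration), degrades
the rendered depth with sensor noise, then runs the pose-anchored
interleaved registration and reports how much of the pose error was
recovered and how far the residual fell.
"""

import warnings

import numpy as np

from livestock3d.evaluate import pose_set_error
from livestock3d.registration import RegistrationConfig, run_interleaved
from livestock3d.simulate import SceneConfig, generate_scene, perturb_and_degrade
from livestock3d.surfacing import mesh_stats


def main():
    cfg = SceneConfig(width=160, height=120)  # desk-scale renders
    scene = generate_scene(cfg, seed=1)
    rig = perturb_and_degrade(
        scene, rot_max_deg=2.0, trans_max=0.05, depth_sigma=0.001, seed=11
    )
    truth = [c.T_true for c in rig.cameras]

    e0 = pose_set_error([c.T_init for c in rig.cameras], truth)
    print(f"initial pose error : {e0.mean_rotation_deg:.2f} deg / "
          f"{e0.mean_translation_mm:.1f} mm (mean over 10 cameras)")

    rcfg = RegistrationConfig(
        depth_intermediate=7, depth_final=7, max_points_per_camera=1500
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = run_interleaved(rig, rcfg)

    e1 = pose_set_error(res.poses, truth)
    tr = res.residual_trace_mm
    st = mesh_stats(res.mesh)
    print(f"after {res.iterations} interleaved iterations:")
    print(f"  pose error       : {e1.mean_rotation_deg:.2f} deg / "
          f"{e1.mean_translation_mm:.1f} mm")
    print(f"  residual         : {tr[0]:.2f} mm -> {tr[-1]:.2f} mm "
          f"(mean point-to-plane of overlap points)")
    print(f"  final mesh       : {st.n_vertices} vertices, "
          f"{st.n_triangles} triangles, watertight={st.watertight}")
    print("The residual measures cloud-to-model agreement; the pose error "
          "is judged against the simulator's ground-truth extrinsics after "
          "removing the global gauge.")


if __name__ == "__main__":
    main()
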