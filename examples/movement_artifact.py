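"""Detect a radiograph pair in which the foot moved between exposures.

The biplanar principle requires both views to show the same rigid pose.
Here the lateral view is rendered after a 10-degree rotation about the
longitudinal axis; the view-consistency check reveals that the AP and
lateral views prefer different axial rotations, which no single pose can
reconcile.
"""

from tarpose import BiplanarRig, fit_pose
from tarpose.registration import view_consistency
from tarpose.synthetic import make_case, make_movement_artifact_case

rig = BiplanarRig()
for label, case in (
    ("matched pair ", make_case(seed=42)),
    ("moved foot   ", make_movement_artifact_case(inter_view_rotation=10.0, seed=42)),
):
    targets = case.contour_targets("talar", source="exact")
    res = fit_pose(case.talar_mesh, targets, rig, init=case.true_poses[1],
                   n_starts=1, seed=0)
    vc = view_consistency(case.talar_mesh, targets, rig, res)
    print(f"{label}: residual {res.cost:.3f} mm | per-view preferred axial rotation "
          f"AP {vc.preferred_rx['AP']:+.1f} deg / LAT {vc.preferred_rx['LAT']:+.1f} deg "
          f"| inconsistent={vc.inconsistent}")
print("-> the 10 deg inter-view twist surfaces as a ~10 deg disagreement between")
print("   the views' preferred axial rotations and the pair is flagged.")
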