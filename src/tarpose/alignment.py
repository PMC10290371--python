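"""Clinical alignment parameters, the accuracy metric, and migration deltas.

A fitted pose is converted into the quantities a clinician reports:

* **component angles** per anatomical plane, measured against the tibial
  reference axis — coronal (varus/valgus, read in the AP view), sagittal
  (anterior/posterior tilt, read in the lateral view), and axial (rotation
  about the longitudinal axis, the parameter a single radiograph cannot
  provide; it is read directly from the 3D pose).
* **inter-component distances**: offsets of the talar contour centroid
  relative to the tibial contour centroid, per view.
* the **accuracy** of an observed value against a reference ("accepted")
  value, as a percentage.
* **migration deltas** between timepoints of the same patient, with
  automatic flagging of changes beyond a threshold.

Sign conventions (documented because only magnitudes are clinically
conventional): positive coronal angle = plateau tilted with its medial
edge superior; positive sagittal = posterior tilt; positive axial =
external-style rotation about +x by the right-hand rule.  Distances:
medial, anterior and distal offsets of the talar component are positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Any

import numpy as np

from .geometry import ComponentMesh, Pose, rotation_matrix
from .axis import TibialAxis2D
from .projection import BiplanarRig, ContourSet, project_silhouette

__all__ = [
    "AlignmentMeasurement",
    "AccuracyResult",
    "MigrationDelta",
    "ANGLE_PARAMS",
    "DISTANCE_PARAMS",
    "component_angles",
    "intercomponent_distance",
    "accuracy",
    "migration_delta",
    "build_measurement",
]

ANGLE_PARAMS = (
    "tibial_coronal",
    "tibial_sagittal",
    "tibial_axial",
    "talar_coronal",
    "talar_sagittal",
    "talar_axial",
)
# four explicit distances: in-plane horizontal offsets (ML from the AP
# view, AP from the lateral view) and the longitudinal offset as read in
# each view.  Naming follows the view of origin to avoid the ambiguity of
# calling them simply "x" and "y" distances.
DISTANCE_PARAMS = ("d_ml_x", "d_ap_x", "d_ml_y", "d_ap_y")


@dataclass(frozen=True)
class AlignmentMeasurement:
    """One patient/timepoint/observer alignment record."""

    patient_id: str
    timepoint: Any
    observer_id: str
    tibial_coronal: float
    tibial_sagittal: float
    tibial_axial: float
    talar_coronal: float
    talar_sagittal: float
    talar_axial: float
    d_ml_x: float
    d_ap_x: float
    d_ml_y: float
    d_ap_y: float
    method: str = "manual"
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.method not in ("manual", "semi-automatic", "ct"):
            raise ValueError("method must be manual, semi-automatic or ct")
        for name in ANGLE_PARAMS + DISTANCE_PARAMS:
            v = float(getattr(self, name))
            if not np.isfinite(v):
                raise ValueError(f"{name} must be finite")
            object.__setattr__(self, name, v)
        for name in ANGLE_PARAMS:
            a = getattr(self, name)
            if not -180.0 < a <= 180.0:
                raise ValueError(f"{name} must lie in (-180, 180]")

    def parameters(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in ANGLE_PARAMS + DISTANCE_PARAMS}

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AlignmentMeasurement":
        return cls(**d)


@dataclass(frozen=True)
class AccuracyResult:
    """Percent accuracy of an observed value against an accepted reference.

    ``percent = (1 - |V_A - V_O| / |V_A|) * 100``.  The value can be
    negative when the observation is off by more than the reference itself;
    negative values are retained (clamping would silently bias means).
    """

    V_A: float
    V_O: float
    percent: float

    def __post_init__(self) -> None:
        if self.percent > 100.0 + 1e-12:
            raise ValueError("accuracy cannot exceed 100%")


def accuracy(V_A: float, V_O: float) -> AccuracyResult:
    """Percent accuracy of observed ``V_O`` against accepted ``V_A``."""
    if V_A == 0:
        raise ZeroDivisionError("accuracy is undefined for an accepted value of 0")
    pct = (1.0 - abs((V_A - V_O) / V_A)) * 100.0
    return AccuracyResult(V_A=float(V_A), V_O=float(V_O), percent=float(pct))


def _signed_plane_angle(ref: np.ndarray, vec: np.ndarray) -> float:
    """Signed angle (deg) from ``ref`` to ``vec`` in the (u, v) image plane,
    with the sign convention that an axis tilt of +theta shifts the result
    by -theta."""
    cross = ref[1] * vec[0] - ref[0] * vec[1]
    dot = ref[0] * vec[0] + ref[1] * vec[1]
    return float(np.degrees(np.arctan2(cross, dot)))


def component_angles(
    pose: Pose,
    axes: dict[str, TibialAxis2D | None],
) -> tuple[float | None, float | None, float]:
    """Coronal, sagittal and axial angles of a component against the
    per-view tibial axes.

    The component's plateau direction (its canonical in-plane axis) is
    projected into each view and compared with the perpendicular of the
    tibial axis in that view; in neutral alignment the plateau is
    perpendicular to the axis and both angles are zero.  Axial rotation is
    not measurable against a 2D reference line and is reported from the
    pose directly.  A view without an axis yields ``None`` for its plane.
    """
    R = rotation_matrix(pose)
    out: list[float | None] = []
    for view, local_dir in (("AP", np.array([0.0, 0.0, 1.0])), ("LAT", np.array([0.0, 1.0, 0.0]))):
        axis = axes.get(view)
        if axis is None:
            out.append(None)
            continue
        d = R @ local_dir
        # in-plane direction: u along columns (AP: z, LAT: y), v = -x
        u = d[2] if view == "AP" else d[1]
        v = -d[0]
        a = axis.direction
        perp = np.array([a[1], -a[0]])  # axis rotated -90 deg: neutral plateau dir
        out.append(_signed_plane_angle(perp, np.array([u, v])))
    coronal, sagittal = out
    return coronal, sagittal, float(pose.rx)


def intercomponent_distance(
    tibial_contours,
    talar_contours,
) -> dict[str, float]:
    """Centroid offsets of the talar relative to the tibial contours.

    ``tibial_contours`` / ``talar_contours`` are (AP, LAT) pairs of
    :class:`ContourSet`.  Returns the four named distances (mm):
    ``d_ml_x`` medial-lateral (AP columns, medial positive), ``d_ap_x``
    anterior-posterior (LAT columns, anterior positive), ``d_ml_y`` and
    ``d_ap_y`` longitudinal separation as read in the AP and LAT view
    respectively (distal positive).
    """
    from .registration import _as_view_dict

    tib = _as_view_dict(tibial_contours, "tibial_contours")
    tal = _as_view_dict(talar_contours, "talar_contours")
    for d in (tib, tal):
        for v, c in d.items():
            if not isinstance(c, ContourSet):
                raise ValueError("contour sets required for both components and views")
    return {
        "d_ml_x": float(tal["AP"].centroid[0] - tib["AP"].centroid[0]),
        "d_ap_x": float(tal["LAT"].centroid[0] - tib["LAT"].centroid[0]),
        "d_ml_y": float(tal["AP"].centroid[1] - tib["AP"].centroid[1]),
        "d_ap_y": float(tal["LAT"].centroid[1] - tib["LAT"].centroid[1]),
    }


@dataclass(frozen=True)
class MigrationDelta:
    """Per-parameter change between two timepoints of one patient."""

    patient_id: str
    earlier_timepoint: Any
    later_timepoint: Any
    deltas: dict[str, float]
    flags: dict[str, bool]
    angle_threshold: float
    distance_threshold: float

    @property
    def flagged(self) -> bool:
        return any(self.flags.values())


def migration_delta(
    earlier: AlignmentMeasurement,
    later: AlignmentMeasurement,
    angle_threshold: float = 2.0,
    distance_threshold: float = 2.0,
) -> MigrationDelta:
    """Later-minus-earlier parameter differences with threshold flags.

    Records must belong to the same patient and measurement method, with
    ``earlier.timepoint < later.timepoint``.  Any parameter whose absolute
    change exceeds the threshold (default 2 degrees / 2 mm) is flagged —
    the automatic migration-detection rule applied whenever a new record
    of a known patient is stored.
    """
    if earlier.patient_id != later.patient_id:
        raise ValueError("migration deltas require records of the same patient")
    if earlier.method != later.method:
        raise ValueError("migration deltas require records of the same method")
    if not earlier.timepoint < later.timepoint:
        raise ValueError("earlier.timepoint must precede later.timepoint")
    deltas = {
        k: later.parameters()[k] - earlier.parameters()[k]
        for k in ANGLE_PARAMS + DISTANCE_PARAMS
    }
    flags = {
        k: abs(v) > (angle_threshold if k in ANGLE_PARAMS else distance_threshold)
        for k, v in deltas.items()
    }
    return MigrationDelta(
        patient_id=earlier.patient_id,
        earlier_timepoint=earlier.timepoint,
        later_timepoint=later.timepoint,
        deltas=deltas,
        flags=flags,
        angle_threshold=angle_threshold,
        distance_threshold=distance_threshold,
    )


def build_measurement(
    tibial: ComponentMesh,
    talar: ComponentMesh,
    tibial_pose: Pose,
    talar_pose: Pose,
    rig: BiplanarRig,
    axes: dict[str, TibialAxis2D | None],
    patient_id: str = "anonymous",
    timepoint: Any = 0,
    observer_id: str = "observer",
    method: str = "manual",
    provenance: dict | None = None,
) -> AlignmentMeasurement:
    """Assemble a full alignment record from a pose pair.

    Projects both components into both views (for the centroid distances),
    measures the per-plane angles against the supplied axes, and packs the
    result with its provenance.
    """
    tib_ang = component_angles(tibial_pose, axes)
    tal_ang = component_angles(talar_pose, axes)
    tib_contours = {
        v: project_silhouette(tibial, tibial_pose, rig, v) for v in ("AP", "LAT")
    }
    tal_contours = {
        v: project_silhouette(talar, talar_pose, rig, v) for v in ("AP", "LAT")
    }
    dists = intercomponent_distance(tib_contours, tal_contours)
    prov = dict(provenance or {})
    prov.setdefault("pixel_spacing", rig.pixel_spacing)
    prov.setdefault("image_shape", rig.image_shape)

    def _deg(x):  # unmeasurable planes recorded as 0 with a provenance note
        return 0.0 if x is None else float(x)

    if tib_ang[0] is None or tib_ang[1] is None:
        prov["missing_axis_views"] = [
            v for v in ("AP", "LAT") if axes.get(v) is None
        ]
    return AlignmentMeasurement(
        patient_id=patient_id,
        timepoint=timepoint,
        observer_id=observer_id,
        tibial_coronal=_deg(tib_ang[0]),
        tibial_sagittal=_deg(tib_ang[1]),
        tibial_axial=tib_ang[2],
        talar_coronal=_deg(tal_ang[0]),
        talar_sagittal=_deg(tal_ang[1]),
        talar_axial=tal_ang[2],
        method=method,
        provenance=prov,
        **dists,
    )
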