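import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tarpose.alignment import (
    ANGLE_PARAMS,
    DISTANCE_PARAMS,
    AlignmentMeasurement,
    accuracy,
    build_measurement,
    component_angles,
    intercomponent_distance,
    migration_delta,
)
from tarpose.axis import TibialAxis2D
from tarpose.geometry import Pose, rotation_matrix
from tarpose.projection import project_silhouette
from tarpose.synthetic import default_talar_offset


def vertical_axes(rig):
    out = {}
    for v in ("AP", "LAT"):
        w, h = rig.extent_mm(v)
        out[v] = TibialAxis2D(
            view_label=v, point=np.array([w / 2, h / 2]), direction=np.array([0.0, 1.0])
        )
    return out


def tilted_axis(view, deg):
    return TibialAxis2D(
        view_label=view,
        point=np.zeros(2),
        direction=np.array([np.sin(np.radians(deg)), np.cos(np.radians(deg))]),
    )


def make_measurement(**overrides):
    base = dict(
        patient_id="p1",
        timepoint=0,
        observer_id="o1",
        tibial_coronal=4.0,
        tibial_sagittal=3.0,
        tibial_axial=1.0,
        talar_coronal=2.0,
        talar_sagittal=1.5,
        talar_axial=0.5,
        d_ml_x=2.0,
        d_ap_x=5.0,
        d_ml_y=18.0,
        d_ap_y=19.0,
        method="manual",
    )
    base.update(overrides)
    return AlignmentMeasurement(**base)


class TestComponentAngles:
    def test_neutral(self, rig):
        cor, sag, axi = component_angles(Pose(), vertical_axes(rig))
        assert (cor, sag, axi) == (pytest.approx(0), pytest.approx(0), 0.0)

    def test_axis_tilt_shifts_angle(self, rig):
        axes = {"AP": tilted_axis("AP", 3.0), "LAT": vertical_axes(rig)["LAT"]}
        cor, sag, _ = component_angles(Pose(), axes)
        assert cor == pytest.approx(-3.0, abs=1e-9)
        assert sag == pytest.approx(0.0, abs=1e-9)

    def test_matches_matrix_decomposition(self, rig):
        # independent oracle: read the plateau directions off the rotation
        # matrix and measure their in-plane angles directly
        pose = Pose(ry=4, rz=6)
        cor, sag, axi = component_angles(pose, vertical_axes(rig))
        R = rotation_matrix(pose)
        pz, py = R @ [0, 0, 1], R @ [0, 1, 0]
        cor_o = np.degrees(np.arctan2(pz[0], pz[2]))
        sag_o = np.degrees(np.arctan2(py[0], py[1]))
        assert cor == pytest.approx(cor_o, abs=0.1)
        assert sag == pytest.approx(sag_o, abs=0.1)
        assert axi == pose.rx

    def test_missing_axis_reports_none(self):
        cor, sag, axi = component_angles(Pose(rx=5), {"AP": None, "LAT": None})
        assert cor is None and sag is None and axi == 5.0

    @settings(derandomize=True, max_examples=25)
    @given(theta=st.floats(-15, 15), ry=st.floats(-10, 10))
    def test_axis_tilt_offset_property(self, theta, ry, rig):
        axes0 = vertical_axes(rig)
        cor0, _, _ = component_angles(Pose(ry=ry), axes0)
        axes1 = {"AP": tilted_axis("AP", theta), "LAT": axes0["LAT"]}
        cor1, _, _ = component_angles(Pose(ry=ry), axes1)
        assert cor1 - cor0 == pytest.approx(-theta, abs=1e-6)


class TestIntercomponentDistance:
    def test_identical_centroids(self, tibial_mesh, rig):
        c = {v: project_silhouette(tibial_mesh, Pose(), rig, v) for v in ("AP", "LAT")}
        d = intercomponent_distance(c, c)
        assert all(v == pytest.approx(0.0) for v in d.values())

    def test_constructed_medial_offset(self, tibial_mesh, talar_mesh, rig):
        off = default_talar_offset(tibial_mesh, talar_mesh)
        tib = {v: project_silhouette(tibial_mesh, Pose(), rig, v) for v in ("AP", "LAT")}
        tal = {
            v: project_silhouette(talar_mesh, Pose(tx=off, tz=3.0), rig, v)
            for v in ("AP", "LAT")
        }
        d = intercomponent_distance(tib, tal)
        base = intercomponent_distance(
            tib, {v: project_silhouette(talar_mesh, Pose(tx=off), rig, v) for v in ("AP", "LAT")}
        )
        assert d["d_ml_x"] - base["d_ml_x"] == pytest.approx(3.0, abs=0.5)
        assert d["d_ap_x"] == pytest.approx(base["d_ap_x"], abs=0.5)

    def test_matches_shoelace_centroid_oracle(self, tibial_mesh, talar_mesh, rig):
        def ring_moments(poly):
            x, y = poly[:-1, 0], poly[:-1, 1]
            xn, yn = poly[1:, 0], poly[1:, 1]
            cross = x * yn - xn * y
            a = cross.sum() / 2  # signed: holes wind opposite to exteriors
            mx = ((x + xn) * cross).sum() / 6
            my = ((y + yn) * cross).sum() / 6
            return a, mx, my

        def shoelace_centroid(contour_set):
            a = mx = my = 0.0
            for ring in contour_set.polygons:
                ai, mxi, myi = ring_moments(ring)
                a, mx, my = a + ai, mx + mxi, my + myi
            return np.array([mx / a, my / a]), abs(a)

        tib = {v: project_silhouette(tibial_mesh, Pose(rx=4, ry=2), rig, v) for v in ("AP", "LAT")}
        tal = {
            v: project_silhouette(talar_mesh, Pose(rz=3, tx=-35, ty=1), rig, v)
            for v in ("AP", "LAT")
        }
        d = intercomponent_distance(tib, tal)
        for view, key in (("AP", "d_ml_x"), ("LAT", "d_ap_x")):
            ct, _ = shoelace_centroid(tib[view])
            ca, _ = shoelace_centroid(tal[view])
            assert d[key] == pytest.approx(ca[0] - ct[0], abs=1e-6)


class TestAccuracy:
    def test_identity_is_100(self):
        assert accuracy(4.0, 4.0).percent == pytest.approx(100.0)

    def test_direct_formula(self):
        assert accuracy(4.0, 5.0).percent == pytest.approx(75.0)

    def test_negative_values_retained(self):
        assert accuracy(2.0, 5.0).percent == pytest.approx(-50.0)

    def test_zero_reference_rejected(self):
        with pytest.raises(ZeroDivisionError):
            accuracy(0.0, 1.0)

    @settings(derandomize=True, max_examples=30)
    @given(
        va=st.floats(-20, 20).filter(lambda v: abs(v) > 0.1),
        d1=st.floats(0.0, 10),
        d2=st.floats(0.0, 10),
    )
    def test_monotone_in_error(self, va, d1, d2):
        lo, hi = sorted([d1, d2])
        assert accuracy(va, va + hi).percent <= accuracy(va, va + lo).percent + 1e-9
        assert accuracy(va, va).percent == pytest.approx(100.0)


class TestMigrationDelta:
    def test_identical_measurements_no_flags(self):
        a = make_measurement(timepoint=0)
        b = make_measurement(timepoint=1)
        d = migration_delta(a, b)
        assert all(v == 0 for v in d.deltas.values())
        assert not d.flagged

    def test_coronal_shift_flagged(self):
        a = make_measurement(timepoint=0, tibial_coronal=4.0)
        b = make_measurement(timepoint=1, tibial_coronal=7.0)
        d = migration_delta(a, b)
        assert d.deltas["tibial_coronal"] == pytest.approx(3.0)
        assert d.flags["tibial_coronal"]
        assert sum(d.flags.values()) == 1

    def test_antisymmetry(self, rng):
        vals = {k: float(rng.uniform(-5, 5)) for k in ANGLE_PARAMS + DISTANCE_PARAMS}
        a = make_measurement(timepoint=0)
        b = make_measurement(timepoint=1, **vals)
        fwd = migration_delta(a, b)
        # reversing the records flips every delta (construct with swapped stamps)
        a2 = make_measurement(timepoint=1)
        b2 = make_measurement(timepoint=0, **vals)
        rev = migration_delta(b2, a2)
        for k in fwd.deltas:
            assert fwd.deltas[k] == pytest.approx(-rev.deltas[k])

    def test_mismatched_patient_rejected(self):
        a = make_measurement(patient_id="p1", timepoint=0)
        b = make_measurement(patient_id="p2", timepoint=1)
        with pytest.raises(ValueError):
            migration_delta(a, b)

    def test_mismatched_method_rejected(self):
        a = make_measurement(timepoint=0, method="manual")
        b = make_measurement(timepoint=1, method="ct")
        with pytest.raises(ValueError):
            migration_delta(a, b)

    def test_timepoint_order_enforced(self):
        a = make_measurement(timepoint=1)
        b = make_measurement(timepoint=0)
        with pytest.raises(ValueError):
            migration_delta(a, b)


class TestBuildMeasurement:
    def test_end_to_end_parameters(self, tibial_mesh, talar_mesh, rig):
        off = default_talar_offset(tibial_mesh, talar_mesh)
        m = build_measurement(
            tibial_mesh,
            talar_mesh,
            Pose(ry=7.0),
            Pose(tx=off),
            rig,
            vertical_axes(rig),
            patient_id="px",
            method="semi-automatic",
        )
        assert m.tibial_coronal == pytest.approx(7.0, abs=1e-6)
        assert m.method == "semi-automatic"
        assert m.d_ml_y > 0  # talar sits distal to the tibial component

    def test_missing_axis_recorded_in_provenance(self, tibial_mesh, talar_mesh, rig):
        axes = {"AP": None, "LAT": vertical_axes(rig)["LAT"]}
        m = build_measurement(
            tibial_mesh, talar_mesh, Pose(), Pose(tx=-35), rig, axes
        )
        assert m.provenance["missing_axis_views"] == ["AP"]
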