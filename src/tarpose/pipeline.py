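"""End-to-end orchestration: axis -> registration -> alignment -> store,
and the validation report (accuracy + reliability).

``run_measure`` executes one measurement run from a configuration mapping
(the same structure a JSON/TOML config file would hold), in either manual
mode (pose pair given directly) or automatic mode (pose recovered by
biplanar registration against detected edges).  ``run_validate`` compares
stored tool measurements against reference (CT-method) records and against
a second method, reproducing the shape of a clinical validation report:
per-plane accuracy percentages, per-method means, observer ICC tables.
"""

from __future__ import annotations

from typing import Any, Sequence

import numpy as np
import pandas as pd

from .alignment import (
    AlignmentMeasurement,
    accuracy,
    build_measurement,
)
from .axis import TibialAxis2D, fit_circle, tibial_axis_2d
from .geometry import Pose, load_mesh
from .projection import BiplanarRig, extract_edges, read_image
from .registration import (
    RegistrationResult,
    assign_edges,
    fit_pose,
    view_consistency,
)
from .stats import paired_t, summarize_observers
from .store import MeasurementStore
from .synthetic import SyntheticCase

__all__ = ["run_measure", "run_validate", "mean_accuracy", "axes_from_annotations"]


def axes_from_annotations(annotations: dict) -> dict[str, TibialAxis2D]:
    """Two-circle axis per view from clicked shaft edge points.

    ``annotations[view]`` maps ``"proximal"`` and ``"distal"`` to point
    lists (mm); a circle is fitted to each band and the axis drawn through
    the centres.
    """
    axes = {}
    for view, bands in annotations.items():
        prox = fit_circle(np.asarray(bands["proximal"], dtype=float))
        dist = fit_circle(np.asarray(bands["distal"], dtype=float))
        axes[view] = tibial_axis_2d(prox, dist, view=view)
    return axes


def _vertical_axes(rig: BiplanarRig) -> dict[str, TibialAxis2D]:
    axes = {}
    for view in ("AP", "LAT"):
        w, h = rig.extent_mm(view)
        axes[view] = TibialAxis2D(
            view_label=view,
            point=np.array([w / 2, h / 2]),
            direction=np.array([0.0, 1.0]),
        )
    return axes


def run_measure(
    config: dict[str, Any],
    case: SyntheticCase | None = None,
) -> tuple[AlignmentMeasurement, dict[str, RegistrationResult | None]]:
    """Execute one measurement run.

    Config keys (paths may be replaced by in-memory objects, and a
    :class:`SyntheticCase` supplies meshes, images, rig and axes in one go):

    ``tibial_mesh``, ``talar_mesh`` : STL/PLY paths or ComponentMesh;
    ``ap_image``, ``lat_image`` : image paths or arrays;
    ``pixel_spacing``, ``image_shape`` : rig geometry;
    ``mode`` : ``"manual"`` (uses ``tibial_pose``/``talar_pose``) or
    ``"automatic"`` (edge detection + biplanar fit from ``init`` poses);
    ``axes`` : per-view axis annotations or TibialAxis2D (default: image
    vertical); ``seed`` : drives the multi-start optimiser;
    ``patient_id``, ``timepoint``, ``observer_id`` : record identity;
    ``store`` : optional path — the record is appended and migration
    deltas computed.

    Returns the measurement and the per-component registration results
    (``None`` in manual mode).  A fit whose residual exceeds the
    plausibility threshold is still recorded, flagged in provenance.
    """
    if case is not None:
        tibial, talar = case.tibial_mesh, case.talar_mesh
        rig = case.rig
        images = {"AP": case.ap_image, "LAT": case.lat_image}
        axes = dict(case.true_axis_2d)
    else:
        tibial = config["tibial_mesh"]
        talar = config["talar_mesh"]
        if isinstance(tibial, str):
            tibial = load_mesh(tibial, "tibial")
        if isinstance(talar, str):
            talar = load_mesh(talar, "talar")
        rig = BiplanarRig(
            pixel_spacing=config.get("pixel_spacing", 0.5),
            image_shape=config.get("image_shape", (512, 512)),
        )
        images = {}
        for view, key in (("AP", "ap_image"), ("LAT", "lat_image")):
            img = config.get(key)
            if isinstance(img, str):
                img = read_image(img)
            images[view] = img
        axes_cfg = config.get("axes")
        if axes_cfg is None:
            axes = _vertical_axes(rig)
        elif all(isinstance(v, TibialAxis2D) for v in axes_cfg.values()):
            axes = dict(axes_cfg)
        else:
            axes = axes_from_annotations(axes_cfg)

    mode = config.get("mode", "manual")
    seed = int(config.get("seed", 0))
    reg: dict[str, RegistrationResult | None] = {"tibial": None, "talar": None}
    suspect = False

    if mode == "manual":
        tib_pose = config["tibial_pose"]
        tal_pose = config["talar_pose"]
        method = config.get("method", "manual")
    elif mode == "automatic":
        edge_params = config.get("edge_params", {})
        targets = {
            view: extract_edges(
                images[view],
                rig.spacing(view),
                view_label=view,
                **edge_params,
            )
            for view in ("AP", "LAT")
        }
        fit_kwargs = dict(config.get("fit_params", {}))
        margin = float(config.get("gate_margin_mm", 10.0))
        from .synthetic import default_talar_offset

        init_tib = config.get("init_tibial", Pose())
        init_tal = config.get(
            "init_talar", Pose(tx=default_talar_offset(tibial, talar))
        )
        tib_targets, tal_targets = {}, {}
        for v, t in targets.items():
            split = assign_edges(
                t,
                {"tibial": (tibial, init_tib), "talar": (talar, init_tal)},
                rig,
                margin,
            )
            tib_targets[v] = split["tibial"]
            tal_targets[v] = split["talar"]
        reg["tibial"] = fit_pose(
            tibial, tib_targets, rig, init=init_tib, seed=seed, **fit_kwargs
        )
        reg["talar"] = fit_pose(
            talar, tal_targets, rig, init=init_tal, seed=seed + 1, **fit_kwargs
        )
        tib_pose = reg["tibial"].pose
        tal_pose = reg["talar"].pose
        # biplanar consistency: a foot moved between exposures makes the
        # two views prefer different axial rotations for both components
        consistency = {
            "tibial": view_consistency(tibial, tib_targets, rig, reg["tibial"]),
            "talar": view_consistency(talar, tal_targets, rig, reg["talar"]),
        }
        inconsistent = any(c.inconsistent for c in consistency.values())
        suspect = reg["tibial"].suspect or reg["talar"].suspect or inconsistent
        method = config.get("method", "semi-automatic")
    else:
        raise ValueError("mode must be 'manual' or 'automatic'")

    provenance = {
        "mode": mode,
        "seed": seed,
        "suspect_fit": suspect,
    }
    if mode == "automatic":
        provenance["view_consistency"] = {
            label: {
                "disagreement_deg": c.disagreement_deg,
                "improvement": c.improvement,
                "inconsistent": c.inconsistent,
            }
            for label, c in consistency.items()
        }
    for label, r in reg.items():
        if r is not None:
            provenance[f"{label}_fit"] = {
                "cost": r.cost,
                "converged": r.converged,
                "n_evaluations": r.n_evaluations,
                "suspect": r.suspect,
                "ambiguous": r.ambiguous,
            }
    measurement = build_measurement(
        tibial,
        talar,
        tib_pose,
        tal_pose,
        rig,
        axes,
        patient_id=config.get("patient_id", "anonymous"),
        timepoint=config.get("timepoint", 0),
        observer_id=config.get("observer_id", "observer"),
        method=method,
        provenance=provenance,
    )
    store_path = config.get("store")
    if store_path is not None:
        MeasurementStore(store_path).append(measurement)
    return measurement, reg


def mean_accuracy(per_plane_percent: Sequence[float]) -> float:
    """Average of per-plane accuracy percentages (plain arithmetic mean)."""
    return float(np.mean(np.asarray(per_plane_percent, dtype=float)))


_ACCURACY_PLANES = ("tibial_coronal", "tibial_sagittal")


def run_validate(
    store: MeasurementStore | Sequence[AlignmentMeasurement],
    reference: Sequence[AlignmentMeasurement],
) -> dict[str, Any]:
    """Accuracy and reliability report of stored measurements against a
    CT-derived reference.

    For every patient present in both sets, per-plane percent accuracy of
    each non-reference method is computed (tibial coronal and sagittal —
    the planes a CT reference supports), then averaged per plane and per
    method.  Observer agreement (ICC) and a paired method comparison are
    included when the stored data allow.
    """
    records = list(store.records if isinstance(store, MeasurementStore) else store)
    ref_by_patient = {r.patient_id: r for r in reference}
    methods = sorted({r.method for r in records})
    if not any(r.patient_id in ref_by_patient for r in records):
        raise ValueError("no overlapping patients between store and reference")

    report: dict[str, Any] = {"accuracy": {}, "mean_accuracy": {}}
    for method in methods:
        rows = []
        for r in records:
            ref = ref_by_patient.get(r.patient_id)
            if ref is None or r.method != method:
                continue
            row = {"patient_id": r.patient_id, "observer_id": r.observer_id}
            for plane in _ACCURACY_PLANES:
                va = getattr(ref, plane)
                vo = getattr(r, plane)
                row[plane] = accuracy(va, vo).percent if va != 0 else np.nan
            rows.append(row)
        if not rows:
            continue
        df = pd.DataFrame(rows)
        per_plane = {p: float(df[p].mean()) for p in _ACCURACY_PLANES}
        report["accuracy"][method] = df
        report["mean_accuracy"][method] = {
            **per_plane,
            "overall": mean_accuracy(list(per_plane.values())),
        }

    # observer reliability per method where two observers are available
    report["reliability"] = {}
    for method in methods:
        sub = [r for r in records if r.method == method]
        observers = {r.observer_id for r in sub}
        if len(observers) >= 2:
            try:
                report["reliability"][method] = summarize_observers(sub)
            except ValueError:
                pass

    # paired comparison of per-patient means between the first two methods
    if len(methods) >= 2:
        m1, m2 = methods[0], methods[1]
        report["method_comparison"] = {}
        for plane in _ACCURACY_PLANES + ("talar_coronal",):
            a, b = [], []
            for pid in sorted({r.patient_id for r in records}):
                v1 = [getattr(r, plane) for r in records if r.method == m1 and r.patient_id == pid]
                v2 = [getattr(r, plane) for r in records if r.method == m2 and r.patient_id == pid]
                if v1 and v2:
                    a.append(float(np.mean(v1)))
                    b.append(float(np.mean(v2)))
            if len(a) >= 2:
                t = paired_t(a, b)
                report["method_comparison"][plane] = {
                    "methods": (m1, m2),
                    "t": t.t,
                    "p": t.p,
                    "mean_difference": t.mean_difference,
                    "delta": abs(t.mean_difference),
                }
    return report
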