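"""Biplanar 2D/3D registration: find the rigid pose whose coupled AP and
lateral silhouettes match the target outlines in both views at once.

The cost is a symmetric chamfer distance: model contours are resampled at
fine arc-length steps and the mean bidirectional nearest-neighbour distance
to the target contour (or detected edge pixels) is averaged over the two
views.  No point correspondence is needed and partial edge dropout only
weakens, never breaks, the match.  When the target is an edge map — which
may contain edges of *other* structures — distances are truncated so that
unexplained clutter far from the model cannot dominate.

Optimisation treats the match as a nonlinear least-squares problem: the
per-point *signed* distances (negative inside the target silhouette) form
the residual vector, and a trust-region reflective solver with
finite-difference Jacobians refines the pose.  Signed distances matter:
unsigned ones have a V-kink exactly at the optimum, which defeats both
finite differences and direct-search methods in the narrow valley of the
weakly observable axial rotation.  Globalisation is by closed-form
centroid translation seeding (each view observes two of the three
translations), multi-start over seeded rotation perturbations, and a 1D
scan over the axial rotation that guards against the near-mirror local
minimum of almost-symmetric components.  The model silhouette is computed
analytically, so every residual varies smoothly with the pose and
sub-degree refinement is meaningful.

A single view cannot do this job: depth translation along the beam is
exactly invisible, and rotation about the longitudinal axis moves the
silhouette only at second order.  The perpendicular second view restores
both, which is why the two views are always optimised jointly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely
from scipy.optimize import least_squares
from scipy.spatial import cKDTree

from .geometry import ComponentMesh, Pose
from .projection import (
    BiplanarRig,
    ContourSet,
    EdgeMap,
    VIEWS,
    project_silhouette,
    silhouette_geometry,
)

__all__ = [
    "RegistrationResult",
    "contour_cost",
    "fit_pose",
    "manual_pose_measurement",
    "DEFAULT_BOUNDS",
]

# generous envelopes around clinically plausible malalignment
DEFAULT_BOUNDS = ((-25.0, 25.0),) * 3 + ((-20.0, 20.0),) * 3

#: fits whose final cost exceeds this many pixels are flagged as suspect
#: (e.g. an inconsistent AP/LAT pair from foot movement between exposures)
SUSPECT_COST_PIXELS = 2.0

#: distance truncation (mm) applied when matching against edge maps
EDGE_TRUNCATION_MM = 6.0

#: inlier truncation (mm) for the final edge-matching refinement stage
EDGE_INLIER_MM = 1.5


@dataclass(frozen=True)
class RegistrationResult:
    """Outcome of a biplanar pose fit.

    ``cost`` is the mean symmetric contour distance (mm) across both
    views; ``suspect`` marks fits whose residual exceeds the plausibility
    threshold; ``ambiguous`` marks cost ties between well-separated poses
    (mirror-symmetric components).
    """

    pose: Pose
    cost: float
    converged: bool
    n_evaluations: int
    multistart_costs: tuple[float, ...] = ()
    suspect: bool = False
    ambiguous: bool = False

    def __post_init__(self) -> None:
        if self.cost < 0:
            raise ValueError("cost must be non-negative")


def _fixed_count_samples(geometry, n: int) -> np.ndarray:
    """``n`` points along a region boundary at fixed arc-length fractions.

    The count is fixed (and positions vary continuously with the region) so
    that these points can serve as a residual vector for least squares.
    """
    b = geometry.boundary
    lines = sorted(getattr(b, "geoms", [b]), key=lambda l: -l.length)
    total = sum(l.length for l in lines)
    pts = []
    remaining = n
    for i, line in enumerate(lines):
        k = remaining if i == len(lines) - 1 else max(int(round(n * line.length / total)), 1)
        k = min(k, remaining)
        if k <= 0:
            break
        d = (np.arange(k) + 0.5) / k * line.length
        pts.append(shapely.get_coordinates(shapely.line_interpolate_point(line, d)))
        remaining -= k
    out = np.vstack(pts)
    if len(out) < n:  # degenerate ring split; pad by repetition
        out = np.vstack([out, out[: n - len(out)]])
    return out[:n]


class _TargetView:
    """Pre-processed matching target for one view."""

    def __init__(self, target: ContourSet | EdgeMap, sample_step: float):
        if isinstance(target, ContourSet):
            self.kind = "contour"
            self.region = target.geometry
            self.boundary = target.geometry.boundary
            self.region_centroid = np.asarray(target.centroid, dtype=float)
            self.points = target.sample_points(sample_step)
            self.tree = cKDTree(self.points)
            self.truncation = np.inf
        elif isinstance(target, EdgeMap):
            if target.n_edge_pixels == 0:
                raise ValueError("empty edge map target")
            self.kind = "edges"
            self.boundary = None
            self.points = target.points_mm()
            self.tree = cKDTree(self.points)
            self.truncation = EDGE_TRUNCATION_MM
        else:
            raise TypeError("target must be a ContourSet or an EdgeMap")

    def cost_against(self, model: ContourSet, sample_step: float) -> float:
        mpts = model.sample_points(sample_step)
        if self.kind == "contour":
            # symmetric chamfer between the two outlines
            d1 = shapely.distance(shapely.points(mpts), self.boundary)
            d2 = shapely.distance(shapely.points(self.points), model.geometry.boundary)
            return 0.5 * (float(np.mean(d1)) + float(np.mean(d2)))
        # Edge targets are matched in the edges -> model direction only:
        # that direction measures point-to-curve distances, whereas
        # model -> edge-pixel distances carry the tangential spacing of
        # the edge chains, which varies with contour orientation and
        # biases rotations.  Truncation keeps unrelated edges to a
        # constant contribution.
        d2 = shapely.distance(shapely.points(self.points), model.geometry.boundary)
        return float(np.mean(np.minimum(d2, self.truncation)))


def _as_view_dict(pair, name: str) -> dict:
    if isinstance(pair, dict):
        missing = [v for v in VIEWS if v not in pair]
        if missing:
            raise ValueError(f"{name} missing views {missing}: both views are required")
        return pair
    try:
        ap, lat = pair
    except Exception as exc:  # noqa: BLE001
        raise ValueError(f"{name} must be an (AP, LAT) pair or dict") from exc
    return {"AP": ap, "LAT": lat}


def contour_cost(
    model,
    target,
    rig: BiplanarRig | None = None,
    sample_step: float = 0.5,
) -> float:
    """Mean symmetric contour distance (mm) between model and target,
    averaged over the AP and LAT views.

    ``model`` and ``target`` are (AP, LAT) pairs (tuple or dict keyed by
    view); targets may be :class:`ContourSet` or :class:`EdgeMap`.  Both
    views must be present — the biplanar coupling is the point.
    """
    model = _as_view_dict(model, "model")
    target = _as_view_dict(target, "target")
    per_view = []
    for view in VIEWS:
        tv = _TargetView(target[view], sample_step)
        per_view.append(tv.cost_against(model[view], sample_step))
    return float(np.mean(per_view))


def _centroid_translation_init(
    mesh: ComponentMesh,
    targets: dict[str, "_TargetView"],
    rig: BiplanarRig,
    x0: np.ndarray,
) -> np.ndarray:
    """Closed-form translation seeding by matching silhouette centroids.

    The AP view observes (tz, tx) through its (column, row) centroid, the
    LAT view (ty, tx); the shared longitudinal estimate is averaged.  Only
    applied to contour targets — an edge map may contain other structures
    whose pixels would bias the centroid.
    """
    x = x0.copy()
    tx_est = []
    for view, tv in targets.items():
        if tv.kind != "contour":
            return x0
        model = project_silhouette(mesh, Pose.from_array(x), rig, view, method="exact")
        mc = np.asarray(model.geometry.centroid.coords[0])
        tc = tv.points.mean(axis=0) if tv.boundary is None else np.asarray(
            tv.region_centroid
        )
        du, dv = tc[0] - mc[0], tc[1] - mc[1]
        if view == "AP":
            x[5] += du
        else:
            x[4] += du
        tx_est.append(-dv)  # image v runs opposite to anatomical x
    x[3] += float(np.mean(tx_est))
    return x


def gate_edges(
    edge_map: EdgeMap,
    mesh: ComponentMesh,
    init: Pose,
    rig: BiplanarRig,
    margin_mm: float = 10.0,
) -> EdgeMap:
    """Restrict an edge map to the neighbourhood of a component's expected
    outline.

    When several components appear in one radiograph, each component is
    fitted against the edges within ``margin_mm`` of its initial-pose
    silhouette; edges of the other component (or other structures) outside
    that band are removed so they can neither attract nor penalise the fit.
    """
    geom = silhouette_geometry(mesh, init, rig, edge_map.view_label)
    region = geom.buffer(margin_mm)
    pts = edge_map.points_mm()
    inside = shapely.contains_xy(region, pts[:, 0], pts[:, 1])
    rows, cols = np.nonzero(edge_map.edges)
    gated = np.zeros_like(edge_map.edges)
    gated[rows[inside], cols[inside]] = True
    refined = None if edge_map.refined is None else edge_map.refined[inside]
    return EdgeMap(
        view_label=edge_map.view_label,
        edges=gated,
        pixel_spacing=edge_map.pixel_spacing,
        refined=refined,
    )


def assign_edges(
    edge_map: EdgeMap,
    components: dict[str, tuple[ComponentMesh, Pose]],
    rig: BiplanarRig,
    margin_mm: float = 10.0,
) -> dict[str, EdgeMap]:
    """Partition an edge map between components by nearest expected outline.

    Each edge pixel is assigned to the component whose initial-pose
    silhouette boundary lies closest (and within ``margin_mm``); edges far
    from every component are dropped.  Unlike a plain per-component margin
    gate, this keeps one component's edges out of a neighbour's target
    even where the two silhouettes come close.
    """
    pts = edge_map.points_mm()
    P = shapely.points(pts)
    dists = {}
    for label, (mesh, init) in components.items():
        geom = silhouette_geometry(mesh, init, rig, edge_map.view_label)
        dists[label] = shapely.distance(P, geom.boundary)
    labels = list(components)
    D = np.stack([dists[l] for l in labels])
    owner = np.argmin(D, axis=0)
    close = D.min(axis=0) <= margin_mm
    rows, cols = np.nonzero(edge_map.edges)
    out = {}
    for k, label in enumerate(labels):
        keep = close & (owner == k)
        gated = np.zeros_like(edge_map.edges)
        gated[rows[keep], cols[keep]] = True
        refined = None if edge_map.refined is None else edge_map.refined[keep]
        out[label] = EdgeMap(
            view_label=edge_map.view_label,
            edges=gated,
            pixel_spacing=edge_map.pixel_spacing,
            refined=refined,
        )
    return out


def fit_pose(
    mesh: ComponentMesh,
    target,
    rig: BiplanarRig,
    init: Pose | None = None,
    bounds=None,
    n_starts: int = 8,
    seed: int = 0,
    sample_step: float = 0.5,
    xtol: float = 1e-3,
    maxfev: int = 1200,
    views: tuple[str, ...] = VIEWS,
    perturbation: tuple[float, float] = (5.0, 5.0),
    axial_scan_step: float = 2.0,
) -> RegistrationResult:
    """Recover the six pose parameters of one component from its biplanar
    silhouette targets.

    Strategy: ``n_starts`` trust-region least-squares refinements (signed
    contour distances as residuals) run from ``init``, from a variant of
    it with translations seeded in closed form from contour centroids,
    and from deterministic perturbations (degrees/mm amplitudes in
    ``perturbation``) drawn from ``seed``.  A 1D scan along the direction
    the silhouettes constrain least (smallest singular vector of the
    residual Jacobian; offsets below ``axial_scan_step`` are skipped)
    guards against the near-mirror local minimum of almost-symmetric
    components.  Among cost ties the pose closest to ``init`` in max-norm
    is returned and the tie is flagged as ambiguous.

    ``views`` restricts matching to a subset (used to demonstrate why a
    single view under-determines the pose); by default both views are used.
    """
    init = init or Pose()
    target = {v: t for v, t in _as_view_dict(target, "target").items() if v in views}
    targets = {v: _TargetView(t, sample_step) for v, t in target.items()}
    if bounds is None:
        # default envelopes are centred on the initial guess: the guess
        # carries the anatomical placement, the bounds the plausible
        # malalignment around it
        bounds = tuple(
            (c + lo_, c + hi_)
            for c, (lo_, hi_) in zip(init.as_array(), DEFAULT_BOUNDS)
        )
    bounds = tuple(tuple(map(float, b)) for b in bounds)
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    x0 = init.as_array()
    if np.any(x0 < lo) or np.any(x0 > hi):
        raise ValueError("init must lie within bounds")

    n_eval = 0

    def objective(p: np.ndarray) -> float:
        nonlocal n_eval
        n_eval += 1
        pose = Pose.from_array(p)
        per_view = []
        for view, tv in targets.items():
            model = project_silhouette(mesh, pose, rig, view, method="exact")
            per_view.append(tv.cost_against(model, sample_step))
        return float(np.mean(per_view))

    init_cost = objective(x0)
    x_seed = np.clip(_centroid_translation_init(mesh, targets, rig, x0), lo, hi)

    # the raw init and the centroid-seeded init are both first-class
    # starts: centroid matching helps when the component sits far from the
    # guess, but with a large rotation offset it can lock a wrong-overlap
    # basin that the raw init avoids
    rng = np.random.default_rng(seed)
    starts = [x0]
    if np.max(np.abs(x_seed - x0)) > 1e-9:
        starts.append(x_seed)
    rot_amp, trans_amp = perturbation
    while len(starts) < max(n_starts, 1):
        d = np.concatenate(
            [rng.uniform(-rot_amp, rot_amp, 3), rng.uniform(-trans_amp, trans_amp, 3)]
        )
        starts.append(np.clip(x_seed + d, lo, hi))
    starts = starts[: max(n_starts, 2)]

    # residual vector for least squares: fixed-count model boundary samples
    # matched to the target, plus fixed target samples matched to the model;
    # every entry is a smooth function of the pose.
    n_model_samples = 192

    def residuals(p: np.ndarray, edge_trunc: float = EDGE_TRUNCATION_MM) -> np.ndarray:
        # Signed distances where a region is available: an unsigned distance
        # has a V-kink exactly at the optimum, which wrecks finite-difference
        # Jacobians; the signed version is smooth through the boundary.
        nonlocal n_eval
        n_eval += 1
        pose = Pose.from_array(p)
        res = []
        for view, tv in targets.items():
            geom = silhouette_geometry(mesh, pose, rig, view)
            mpts = _fixed_count_samples(geom, n_model_samples)
            if tv.kind == "contour":
                d1 = shapely.distance(shapely.points(mpts), tv.boundary)
                d1 = d1 * np.where(
                    shapely.contains_xy(tv.region, mpts[:, 0], mpts[:, 1]), -1.0, 1.0
                )
                d2 = shapely.distance(shapely.points(tv.points), geom.boundary)
                d2 = d2 * np.where(
                    shapely.contains_xy(geom, tv.points[:, 0], tv.points[:, 1]),
                    -1.0,
                    1.0,
                )
                res.append(d1)
                res.append(d2)
            else:
                # Edges -> model boundary only.  This direction measures
                # point-to-curve distances and is bias-free; the reverse
                # (model samples to discrete edge pixels) carries the
                # tangential spacing of the edge chains, which varies with
                # contour orientation and visibly biases rotations.
                # Truncation keeps distant clutter to a constant residual
                # while preserving pull over the initialisation range.
                d2 = shapely.distance(shapely.points(tv.points), geom.boundary)
                res.append(np.minimum(d2, edge_trunc))
        return np.concatenate(res)

    robust = any(tv.kind == "edges" for tv in targets.values())

    def _ls(x: np.ndarray, edge_trunc: float):
        return least_squares(
            residuals,
            np.clip(x, lo + 1e-9, hi - 1e-9),
            kwargs={"edge_trunc": edge_trunc},
            method="trf",
            bounds=(lo, hi),
            diff_step=1e-3,
            xtol=xtol * 1e-3,
            ftol=1e-10,
            gtol=None,
            max_nfev=maxfev // 7,
            # soften outliers (occluded stretches, residual clutter) when
            # matching detected edges; the scale is about one pixel of
            # edge-localisation noise
            loss="soft_l1" if robust else "linear",
            f_scale=0.5,
        )

    def _refine(x: np.ndarray):
        # for edge targets: coarse pull-in with a wide truncation, then an
        # inlier-only polish that rejects spurious edges from image noise
        res = _ls(x, EDGE_TRUNCATION_MM)
        if robust:
            res = _ls(res.x, EDGE_INLIER_MM)
        return res

    stage = [_refine(s) for s in starts]
    stage_costs = [objective(r.x) for r in stage]
    best_i = int(np.argmin(stage_costs))
    best = stage[best_i]
    best_x = best.x
    best_cost = stage_costs[best_i]

    # soft-mode basin scan: the direction the silhouettes constrain least
    # (typically a rotation near the component's long/stem axis) is the
    # smallest right singular vector of the residual Jacobian; a competing
    # near-mirror minimum, if any, lies along it.
    xs = [best_x]
    cs = [best_cost]
    try:
        soft = np.linalg.svd(best.jac)[2][-1]
    except np.linalg.LinAlgError:
        soft = np.eye(6)[0]
    ts = np.linspace(-30.0, 30.0, 25)
    scan = [
        np.clip(best_x + t * soft, lo, hi) for t in ts if abs(t) > axial_scan_step / 2
    ]
    scan_costs = [objective(q) for q in scan]
    k = int(np.argmin(scan_costs))
    if scan_costs[k] < max(2.0 * best_cost, best_cost + 0.05):
        r = _refine(scan[k])
        xs.append(r.x)
        cs.append(objective(r.x))
    for i, r in enumerate(stage):
        if i != best_i:
            xs.append(r.x)
            cs.append(stage_costs[i])

    cs = np.asarray(cs)
    best_cost = float(cs.min())
    tie_tol = max(1e-3, 0.02 * best_cost)
    tied = [x for x, c in zip(xs, cs) if c <= best_cost + tie_tol]
    winner = min(tied, key=lambda x: np.max(np.abs(x - x0)))
    ambiguous = any(np.max(np.abs(x - winner)) > 1.0 for x in tied)

    pose = Pose.from_array(winner)
    cost = float(objective(winner))
    spacing = np.mean([rig.spacing(v) for v in targets])
    return RegistrationResult(
        pose=pose,
        cost=cost,
        converged=bool(cost <= init_cost + 1e-12),
        n_evaluations=n_eval,
        multistart_costs=tuple(float(c) for c in stage_costs),
        suspect=bool(cost > SUSPECT_COST_PIXELS * spacing),
        ambiguous=ambiguous,
    )


@dataclass(frozen=True)
class ViewConsistency:
    """Outcome of the biplanar consistency check.

    ``preferred_rx`` holds the axial rotation each view would choose on
    its own (others fixed at the joint optimum); ``improvement`` the cost
    each view gains by deviating.  A genuine radiograph pair agrees; a
    pair with the foot moved between exposures pulls the axial rotation in
    opposite directions with real cost improvements, and is flagged.
    """

    joint_cost: float
    joint_view_costs: dict[str, float]
    preferred_rx: dict[str, float]
    improvement: dict[str, float]
    disagreement_deg: float
    single_view_costs: dict[str, float]
    inconsistent: bool


def view_consistency(
    mesh: ComponentMesh,
    target,
    rig: BiplanarRig,
    result: RegistrationResult,
    sample_step: float = 0.5,
    scan_halfwidth: float = 15.0,
    disagreement_threshold: float = 4.0,
    improvement_threshold: float = 0.03,
) -> ViewConsistency:
    """Check that both views agree on one rigid pose.

    A movement artifact between the AP and lateral exposure is a rotation
    of the anatomy about the longitudinal axis, so it surfaces as the two
    views preferring different axial rotations.  For each view alone, the
    axial rotation is rescanned (all other parameters held at the joint
    optimum); the pair is inconsistent when the per-view preferences
    disagree by more than ``disagreement_threshold`` degrees and at least
    one view gains more than ``improvement_threshold`` mm of cost by
    deviating (the view that dominates the joint fit may gain little).

    Two complementary residual tests cover twists the conditional scan can
    absorb.  Each view is refitted *alone* from the joint solution; when
    the joint residual exceeds three times what the views achieve
    individually (by at least ``improvement_threshold``), no single pose
    explains both views.  And when the joint optimum fits one view nearly
    perfectly while leaving a large residual in the other (imbalance
    > 0.1 mm and > 3x), the fit has collapsed into a single view's basin —
    the other view is unexplainable from there.  Any of the three flags
    marks the pair inconsistent.
    """
    target = _as_view_dict(target, "target")
    targets = {v: _TargetView(t, sample_step) for v, t in target.items()}
    x = result.pose.as_array()

    def view_cost(rx: float, view: str) -> float:
        q = x.copy()
        q[0] = rx
        model = project_silhouette(mesh, Pose.from_array(q), rig, view, method="exact")
        return targets[view].cost_against(model, sample_step)

    preferred: dict[str, float] = {}
    improvement: dict[str, float] = {}
    for view in targets:
        grid = np.linspace(x[0] - scan_halfwidth, x[0] + scan_halfwidth, 31)
        costs = [view_cost(r, view) for r in grid]
        k = int(np.argmin(costs))
        # parabolic sub-step refinement around the grid minimum
        if 0 < k < len(grid) - 1:
            c0, c1, c2 = costs[k - 1], costs[k], costs[k + 1]
            denom = c0 - 2 * c1 + c2
            delta = 0.5 * (c0 - c2) / denom if abs(denom) > 1e-12 else 0.0
            rx_star = grid[k] + np.clip(delta, -1, 1) * (grid[1] - grid[0])
        else:
            rx_star = grid[k]
        joint_view_cost = view_cost(x[0], view)
        preferred[view] = float(rx_star)
        improvement[view] = float(joint_view_cost - min(costs))

    views = list(targets)
    disagreement = (
        abs(preferred[views[0]] - preferred[views[1]]) if len(views) == 2 else 0.0
    )
    scan_flag = bool(
        disagreement > disagreement_threshold
        and max(improvement.values()) > improvement_threshold
    )

    single_costs: dict[str, float] = {}
    for view in views:
        solo = fit_pose(
            mesh,
            target,
            rig,
            init=result.pose,
            n_starts=1,
            seed=0,
            sample_step=sample_step,
            maxfev=600,  # a local refit to the single-view floor suffices
            views=(view,),
        )
        single_costs[view] = solo.cost
    achievable = float(np.mean(list(single_costs.values())))
    residual_flag = bool(
        result.cost > 3.0 * achievable
        and result.cost - achievable > improvement_threshold
    )

    joint_view = {v: view_cost(x[0], v) for v in views}
    hi, lo_c = max(joint_view.values()), min(joint_view.values())
    imbalance_flag = bool(hi - lo_c > 0.1 and hi > 3.0 * lo_c)

    return ViewConsistency(
        joint_cost=result.cost,
        joint_view_costs=joint_view,
        preferred_rx=preferred,
        improvement=improvement,
        disagreement_deg=disagreement,
        single_view_costs=single_costs,
        inconsistent=scan_flag or residual_flag or imbalance_flag,
    )


def manual_pose_measurement(
    meshes,
    poses,
    rig: BiplanarRig,
    axes,
    patient_id: str = "anonymous",
    timepoint=0,
    observer_id: str = "observer",
    method: str = "manual",
    provenance: dict | None = None,
):
    """Turn a directly supplied pose pair into an alignment measurement.

    The programmatic analogue of reading off an observer's final manual
    adjustment: no optimisation is performed, the poses are forwarded to
    the alignment computations as-is.
    """
    from .alignment import build_measurement

    tibial, talar = meshes
    tib_pose, tal_pose = poses
    return build_measurement(
        tibial,
        talar,
        tib_pose,
        tal_pose,
        rig,
        axes,
        patient_id=patient_id,
        timepoint=timepoint,
        observer_id=observer_id,
        method=method,
        provenance=provenance,
    )
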