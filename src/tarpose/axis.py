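"""Tibial reference-axis estimation.

Alignment angles are measured against the longitudinal axis of the tibia.
Two estimators are provided:

* the **2D radiographic method**: a circle is fitted to the shaft outline
  proximally and another distally; the line through the two centres is the
  anatomical axis in that view.  This replaces the interactive
  circle-alignment step of a reading clinician with a deterministic
  algebraic (Pratt) least-squares fit.
* the **3D gold-standard method**: a segmented tibia mesh is sliced
  perpendicular to the shaft, the area centroid of each cross-section is
  computed, and a total-least-squares line through the centroids gives the
  axis — the reference against which radiographic measurements are scored.

Too-distal radiographs constrain the axis poorly, so the shaft span each
estimate used is recorded alongside the result.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .geometry import ComponentMesh

__all__ = [
    "CircleFit",
    "TibialAxis2D",
    "TibialAxis3D",
    "PlateauAngle",
    "fit_circle",
    "tibial_axis_2d",
    "tibial_axis_3d",
    "plateau_angle_3d",
    "load_circle_annotations",
]


class DegenerateInputError(ValueError):
    """Raised for inputs that cannot support the requested fit."""


@dataclass(frozen=True)
class CircleFit:
    center: np.ndarray  # (2,) mm
    radius: float
    rms_residual: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.rms_residual < 0:
            raise ValueError("rms_residual must be non-negative")


@dataclass(frozen=True)
class TibialAxis2D:
    """Reference line in one view; direction oriented proximal -> distal
    (increasing row coordinate v, i.e. pointing inferiorly)."""

    view_label: str
    point: np.ndarray  # (2,) mm (u, v)
    direction: np.ndarray  # unit (2,)

    def __post_init__(self) -> None:
        d = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(d)
        if n == 0:
            raise ValueError("direction must be non-zero")
        object.__setattr__(self, "direction", d / n)
        object.__setattr__(self, "point", np.asarray(self.point, dtype=float))

    def angle_to_vertical(self) -> float:
        """Signed angle (degrees) between the axis and the image vertical."""
        return float(np.degrees(np.arctan2(self.direction[0], self.direction[1])))


@dataclass(frozen=True)
class TibialAxis3D:
    point: np.ndarray  # (3,) mm
    direction: np.ndarray  # unit (3,)
    n_slices: int
    fit_rms: float
    span_mm: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        d = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(d)
        if n == 0:
            raise ValueError("direction must be non-zero")
        object.__setattr__(self, "direction", d / n)
        object.__setattr__(self, "point", np.asarray(self.point, dtype=float))


def fit_circle(points: np.ndarray) -> CircleFit:
    """Algebraic least-squares circle through 2D points (Pratt normalisation).

    Deterministic and iteration-free: the circle ``A(x^2+y^2)+Bx+Cy+D=0``
    minimising the algebraic residual subject to Pratt's constraint
    ``B^2+C^2-4AD=1`` is found from a generalised eigenproblem.  Needs at
    least three non-collinear points.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
        raise DegenerateInputError("need at least 3 two-dimensional points")
    # collinearity check via the smaller singular value of centred points
    centred = pts - pts.mean(axis=0)
    sv = np.linalg.svd(centred, compute_uv=False)
    if sv[-1] < 1e-9 * max(sv[0], 1.0):
        raise DegenerateInputError("points are collinear; no circle is defined")

    # centre and scale for numerical conditioning (the algebraic system is
    # badly scaled for circles far from the origin)
    shift = pts.mean(axis=0)
    scale = float(np.sqrt(np.mean(np.sum(centred**2, axis=1)))) or 1.0
    x, y = centred[:, 0] / scale, centred[:, 1] / scale
    z = x**2 + y**2
    Z = np.stack([z, x, y, np.ones_like(x)], axis=-1)
    M = (Z.T @ Z) / len(pts)
    B = np.array(
        [
            [0.0, 0.0, 0.0, -2.0],
            [0.0, 1.0, 0.0, 0.0],
            [0.0, 0.0, 1.0, 0.0],
            [-2.0, 0.0, 0.0, 0.0],
        ]
    )
    from scipy.linalg import eig

    w, v = eig(M, B)
    w = np.real(w)
    # smallest positive eigenvalue gives the Pratt solution
    w[~np.isfinite(w)] = np.inf
    w[w < -1e-11] = np.inf
    k = int(np.argmin(w))
    A, Bc, Cc, D = np.real(v[:, k])
    if abs(A) < 1e-14:
        raise DegenerateInputError("degenerate circle fit (infinite radius)")
    cx, cy = -Bc / (2 * A), -Cc / (2 * A)
    r2 = (Bc**2 + Cc**2 - 4 * A * D) / (4 * A**2)
    if r2 <= 0:
        raise DegenerateInputError("degenerate circle fit (non-positive radius)")
    r = float(np.sqrt(r2)) * scale
    center = np.array([cx, cy]) * scale + shift
    d = np.hypot(pts[:, 0] - center[0], pts[:, 1] - center[1]) - r
    return CircleFit(
        center=center, radius=r, rms_residual=float(np.sqrt(np.mean(d**2)))
    )


def tibial_axis_2d(
    proximal: CircleFit, distal: CircleFit, view: str = "AP"
) -> TibialAxis2D:
    """Anatomical axis in one view: the line through the two circle centres."""
    delta = distal.center - proximal.center
    if np.linalg.norm(delta) <= 1.0:
        raise DegenerateInputError(
            "circle centres coincide (< 1 mm apart); axis undefined"
        )
    return TibialAxis2D(view_label=view, point=proximal.center, direction=delta)


def _section_centroid(tm, origin: np.ndarray, normal: np.ndarray):
    """Area centroid of a mesh/plane cross-section, or None if empty."""
    sec = tm.section(plane_origin=origin, plane_normal=normal)
    if sec is None:
        return None
    try:
        planar, T = sec.to_2D()
    except Exception:  # noqa: BLE001 - ragged sections on rough meshes
        return None
    polys = planar.polygons_full
    if not polys:
        return None
    areas = np.array([p.area for p in polys])
    cents = np.array([[p.centroid.x, p.centroid.y] for p in polys])
    c2 = (cents * areas[:, None]).sum(axis=0) / areas.sum()
    c3 = T @ np.array([c2[0], c2[1], 0.0, 1.0])
    return c3[:3]


def tibial_axis_3d(
    tibia_mesh: ComponentMesh,
    slice_axis: np.ndarray = (1.0, 0.0, 0.0),
    n_slices: int = 20,
    span: tuple[float, float] = (0.2, 0.8),
) -> TibialAxis3D:
    """Axis from cross-section centroids of a segmented tibia mesh.

    The mesh is cut by ``n_slices`` equally spaced planes orthogonal to
    ``slice_axis``, restricted to the fractional ``span`` of the mesh
    extent along that axis (default: the central 60 %, avoiding the
    metaphyseal flare).  A total-least-squares 3D line through the
    cross-section area centroids is returned; empty slices are skipped
    with a warning and at least three usable slices are required.
    """
    if n_slices < 3:
        raise DegenerateInputError("n_slices must be >= 3")
    axis = np.asarray(slice_axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    tm = tibia_mesh.as_trimesh()
    proj = tibia_mesh.vertices @ axis
    lo, hi = proj.min(), proj.max()
    s0 = lo + span[0] * (hi - lo)
    s1 = lo + span[1] * (hi - lo)
    offsets = np.linspace(s0, s1, n_slices)

    centroids = []
    for s in offsets:
        c = _section_centroid(tm, origin=axis * s, normal=axis)
        if c is None:
            warnings.warn(f"empty shaft slice at offset {s:.1f} mm; skipped", stacklevel=2)
            continue
        centroids.append(c)
    if len(centroids) < 3:
        raise DegenerateInputError("fewer than 3 usable shaft slices")
    C = np.asarray(centroids)
    mean = C.mean(axis=0)
    _, _, Vt = np.linalg.svd(C - mean)
    direction = Vt[0]
    if np.dot(direction, axis) < 0:
        direction = -direction
    resid = (C - mean) - np.outer((C - mean) @ direction, direction)
    rms = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return TibialAxis3D(
        point=mean,
        direction=direction,
        n_slices=len(centroids),
        fit_rms=rms,
        span_mm=(float(s0), float(s1)),
    )


@dataclass(frozen=True)
class PlateauAngle:
    """Axis-to-plateau angle in one anatomical plane.

    ``angle_deg`` is the absolute angle between the projected axis and
    plateau lines, in [0, 90]; ``deviation_deg = 90 - angle_deg`` is the
    departure from perpendicularity — the alignment error.
    """

    plane: str
    angle_deg: float
    deviation_deg: float


_PLANE_AXES = {"coronal": (0, 2), "sagittal": (0, 1)}  # (x, z) and (x, y)


def plateau_angle_3d(
    axis: TibialAxis3D,
    plateau_points: np.ndarray,
    plane: str = "coronal",
) -> PlateauAngle:
    """Angle between the 3D tibial axis and the component plateau, measured
    in the coronal (x-z) or sagittal (x-y) anatomical plane.

    The plateau is summarised by the total-least-squares line through
    ``plateau_points`` projected into the named plane.  In neutral
    alignment the plateau is perpendicular to the axis, so the deviation
    from 90 degrees is reported as the alignment error.
    """
    if plane not in _PLANE_AXES:
        raise ValueError("plane must be 'coronal' or 'sagittal'")
    i, j = _PLANE_AXES[plane]
    pts = np.asarray(plateau_points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 2:
        raise DegenerateInputError("need at least two 3D plateau points")
    P = pts[:, [i, j]]
    P = P - P.mean(axis=0)
    sv = np.linalg.svd(P, compute_uv=False)
    if sv[0] < 1e-12:
        raise DegenerateInputError("plateau points project to a single point")
    _, _, Vt = np.linalg.svd(P)
    plateau_dir = Vt[0]
    axis_dir = np.asarray(axis.direction, dtype=float)[[i, j]]
    na = np.linalg.norm(axis_dir)
    if na < 1e-12:
        raise DegenerateInputError("axis projects to a point in this plane")
    axis_dir = axis_dir / na
    cosang = abs(float(np.dot(plateau_dir, axis_dir)))
    angle = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
    return PlateauAngle(plane=plane, angle_deg=angle, deviation_deg=90.0 - angle)


def load_circle_annotations(path: str | Path) -> dict[str, dict[str, np.ndarray]]:
    """Read clicked shaft edge points from a JSON annotation file.

    Expected structure::

        {"AP": {"proximal": [[u, v], ...], "distal": [[u, v], ...]},
         "LAT": {...}}

    Coordinates in mm.  Emulates the interactive circle-seeding step.
    """
    with open(path) as fh:
        raw = json.load(fh)
    out: dict[str, dict[str, np.ndarray]] = {}
    for view, bands in raw.items():
        out[view] = {band: np.asarray(pts, dtype=float) for band, pts in bands.items()}
    return out
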