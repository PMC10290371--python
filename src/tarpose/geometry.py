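"""Rigid implant meshes, the shared anatomical frame, and rigid transforms.

Coordinate convention (right-handed, millimetres):

* ``x`` — longitudinal, pointing superiorly; coincides with the tibial axis
  in neutral alignment,
* ``y`` — anterior,
* ``z`` — lateral-to-medial.

A component mesh lives in its *canonical* frame: neutral alignment, origin
at the bounding-box centroid.  A :class:`Pose` carries the six rigid-body
parameters that place a component into the shared anatomical frame.

Rotation convention: extrinsic fixed-axis composition
``R = Rz(rz) @ Ry(ry) @ Rx(rx)``, angles in degrees.  Reported alignment
angles depend on this order, so it is fixed here once and documented.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import trimesh

__all__ = [
    "ComponentMesh",
    "Pose",
    "load_mesh",
    "rotation_matrix",
    "apply_pose",
    "pose_transform",
]

_VALID_LABELS = ("tibial", "talar", "liner")


class MeshFormatError(ValueError):
    """Raised when a mesh file cannot be read or is empty."""


@dataclass(frozen=True)
class ComponentMesh:
    """Triangulated rigid implant geometry in its canonical frame.

    Parameters
    ----------
    vertices : (n, 3) float array, millimetres.
    faces : (m, 3) int array of vertex indices.
    component_label : one of ``tibial``, ``talar``, ``liner``.
    asymmetric : True when the mesh has at most one mirror-symmetry plane,
        the geometric condition under which biplanar silhouettes determine
        the pose uniquely.
    closed : True when the mesh is a closed surface with consistent
        outward orientation (enables exact front-face silhouette culling);
        loaders clear it for non-manifold input.
    """

    vertices: np.ndarray
    faces: np.ndarray
    component_label: str
    asymmetric: bool = True
    closed: bool = True

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        f = np.asarray(self.faces, dtype=np.int64)
        if v.ndim != 2 or v.shape[1] != 3 or len(v) == 0:
            raise ValueError("vertices must be a non-empty (n, 3) array")
        if f.ndim != 2 or f.shape[1] != 3 or len(f) == 0:
            raise ValueError("faces must be a non-empty (m, 3) array")
        if not np.all(np.isfinite(v)):
            raise ValueError("vertex coordinates must be finite")
        if f.min() < 0 or f.max() >= len(v):
            raise ValueError("face indices must address existing vertices")
        if self.component_label not in _VALID_LABELS:
            raise ValueError(f"component_label must be one of {_VALID_LABELS}")
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "faces", f)

    @property
    def bbox_centroid(self) -> np.ndarray:
        lo = self.vertices.min(axis=0)
        hi = self.vertices.max(axis=0)
        return (lo + hi) / 2.0

    def recentered(self) -> "ComponentMesh":
        """Return a copy translated so the bounding-box centroid is at the origin."""
        return replace(self, vertices=self.vertices - self.bbox_centroid)

    def as_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(vertices=self.vertices, faces=self.faces, process=False)

    def is_watertight(self) -> bool:
        return bool(self.as_trimesh().is_watertight)

    def save(self, path: str | Path) -> None:
        """Write the mesh as STL or PLY (by file extension)."""
        self.as_trimesh().export(str(path))


@dataclass(frozen=True)
class Pose:
    """Six rigid-body parameters of a component in the anatomical frame.

    Rotations ``rx, ry, rz`` in degrees about the anatomical x, y, z axes
    (extrinsic, applied x then y then z); translations ``tx, ty, tz`` in mm.
    Rotations are normalised into (-180, 180].
    """

    rx: float = 0.0
    ry: float = 0.0
    rz: float = 0.0
    tx: float = 0.0
    ty: float = 0.0
    tz: float = 0.0

    def __post_init__(self) -> None:
        for name in ("rx", "ry", "rz"):
            a = float(getattr(self, name))
            if not np.isfinite(a):
                raise ValueError(f"{name} must be finite")
            a = ((a + 180.0) % 360.0) - 180.0
            if a == -180.0:
                a = 180.0
            object.__setattr__(self, name, a)
        for name in ("tx", "ty", "tz"):
            t = float(getattr(self, name))
            if not np.isfinite(t):
                raise ValueError(f"{name} must be finite")
            object.__setattr__(self, name, t)

    @property
    def rotations(self) -> np.ndarray:
        return np.array([self.rx, self.ry, self.rz], dtype=float)

    @property
    def translation(self) -> np.ndarray:
        return np.array([self.tx, self.ty, self.tz], dtype=float)

    def as_array(self) -> np.ndarray:
        return np.array([self.rx, self.ry, self.rz, self.tx, self.ty, self.tz])

    @classmethod
    def from_array(cls, p: np.ndarray) -> "Pose":
        p = np.asarray(p, dtype=float)
        return cls(*p[:6])

    def inverse(self) -> "Pose":
        """The pose whose transform undoes this one.

        The inverse of ``v -> R v + t`` is ``v -> R^T v - R^T t``; the
        Euler angles of ``R^T`` are recovered by decomposition.
        """
        R = rotation_matrix(self)
        Rinv = R.T
        rx, ry, rz = _decompose_xyz(Rinv)
        tinv = -Rinv @ self.translation
        return Pose(rx, ry, rz, *tinv)


def _rot_x(deg: float) -> np.ndarray:
    c, s = np.cos(np.radians(deg)), np.sin(np.radians(deg))
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])


def _rot_y(deg: float) -> np.ndarray:
    c, s = np.cos(np.radians(deg)), np.sin(np.radians(deg))
    return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])


def _rot_z(deg: float) -> np.ndarray:
    c, s = np.cos(np.radians(deg)), np.sin(np.radians(deg))
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])


def rotation_matrix(pose: Pose) -> np.ndarray:
    """Rotation matrix of a pose: extrinsic ``Rz(rz) @ Ry(ry) @ Rx(rx)``."""
    return _rot_z(pose.rz) @ _rot_y(pose.ry) @ _rot_x(pose.rx)


def _decompose_xyz(R: np.ndarray) -> tuple[float, float, float]:
    """Euler angles (degrees) such that Rz(rz)Ry(ry)Rx(rx) = R.

    Standard extraction for the extrinsic x-y-z convention; at gimbal lock
    (|ry| = 90 deg) rx is set to 0 and the remaining freedom goes to rz.
    """
    sy = -R[2, 0]
    sy = np.clip(sy, -1.0, 1.0)
    ry = np.arcsin(sy)
    if abs(sy) < 1.0 - 1e-12:
        rx = np.arctan2(R[2, 1], R[2, 2])
        rz = np.arctan2(R[1, 0], R[0, 0])
    else:  # gimbal lock
        rx = 0.0
        rz = np.arctan2(-R[0, 1], R[1, 1]) * np.sign(sy)
    return float(np.degrees(rx)), float(np.degrees(ry)), float(np.degrees(rz))


def pose_from_matrix(R: np.ndarray, t: np.ndarray | None = None) -> Pose:
    """Build a :class:`Pose` from a rotation matrix and translation."""
    rx, ry, rz = _decompose_xyz(np.asarray(R, dtype=float))
    t = np.zeros(3) if t is None else np.asarray(t, dtype=float)
    return Pose(rx, ry, rz, *t)


def pose_transform(pose: Pose) -> np.ndarray:
    """4x4 homogeneous transform of a pose."""
    T = np.eye(4)
    T[:3, :3] = rotation_matrix(pose)
    T[:3, 3] = pose.translation
    return T


def apply_pose(mesh: ComponentMesh, pose: Pose) -> ComponentMesh:
    """Apply a rigid pose to a mesh: ``v' = R v + t`` for every vertex."""
    R = rotation_matrix(pose)
    v = mesh.vertices @ R.T + pose.translation
    return replace(mesh, vertices=v)


def load_mesh(path: str | Path, component_label: str = "tibial") -> ComponentMesh:
    """Load an STL (binary or ASCII) or PLY mesh, re-centred to the canonical origin.

    Non-manifold meshes are accepted with a warning — silhouette projection
    tolerates them.  Empty or unreadable files raise :class:`MeshFormatError`.
    """
    path = Path(path)
    if not path.exists():
        raise MeshFormatError(f"mesh file not found: {path}")
    try:
        tm = trimesh.load_mesh(str(path), process=False)
    except Exception as exc:  # noqa: BLE001 - normalise loader errors
        raise MeshFormatError(f"could not read mesh {path}: {exc}") from exc
    if isinstance(tm, trimesh.Scene):
        geoms = list(tm.geometry.values())
        if not geoms:
            raise MeshFormatError(f"mesh file contains no geometry: {path}")
        tm = trimesh.util.concatenate(geoms)
    if tm.vertices is None or len(tm.vertices) == 0 or len(tm.faces) == 0:
        raise MeshFormatError(f"mesh file contains no geometry: {path}")
    tm.merge_vertices()  # STL stores per-facet vertices; re-weld the surface
    closed = bool(tm.is_watertight)
    if not closed:
        warnings.warn(
            f"mesh {path.name} is not a closed 2-manifold; silhouettes will "
            "still be computed",
            stacklevel=2,
        )
    mesh = ComponentMesh(
        vertices=np.asarray(tm.vertices, dtype=float),
        faces=np.asarray(tm.faces, dtype=np.int64),
        component_label=component_label,
        closed=closed,
    )
    return mesh.recentered()
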