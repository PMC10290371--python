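"""Ground-truth fixture generation: parametric implant meshes, synthetic
tibia shafts, and rendered biplanar silhouette image pairs at known poses.

Clinical validation of a biplanar pose-measurement tool needs radiograph
pairs with *known* component poses — which real radiographs never provide.
This module substitutes a fully parametric world:

* implant components whose shape is a deliberate stand-in (a plate-and-stem
  tibial tray, a dome-and-fin talar body) — no claim of fidelity to any
  commercial implant geometry;
* tibia shafts with an analytically known centreline;
* rendered AP/lateral silhouette images with controllable blur, noise and
  occlusion, all driven by a single seed.

The one geometric property the stand-ins are designed to carry faithfully
is the symmetry condition: with ``asymmetric=True`` the stem/fin is oblique
in the coronal (x–z) plane, leaving the component with no mirror plane, so
its biplanar silhouettes determine the pose uniquely; with
``asymmetric=False`` the component has sagittal and coronal mirror planes
and mirrored poses become indistinguishable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh
from shapely.geometry import Polygon

from .geometry import ComponentMesh, Pose, rotation_matrix, pose_from_matrix, _rot_x
from .projection import (
    BiplanarRig,
    VIEWS,
    rasterize_silhouette,
)
from .axis import TibialAxis2D, TibialAxis3D

__all__ = [
    "NoiseParams",
    "SyntheticCase",
    "make_implant_mesh",
    "make_tibia_shaft",
    "make_case",
    "make_movement_artifact_case",
]

# image grey levels: implant dark on a light background, as on a radiograph
# where the metal component is the most radio-opaque structure.
_BACKGROUND = 0.85
_IMPLANT = 0.15


def _extrude_profile(profile_xy: np.ndarray, z0: float, z1: float) -> trimesh.Trimesh:
    """Closed prism from a star-shaped 2D profile in the (x, y) plane,
    extruded along z.  Caps are triangulated as fans around the profile
    centroid (sufficient for the convex profiles used here)."""
    p = np.asarray(profile_xy, dtype=float)
    if np.allclose(p[0], p[-1]):
        p = p[:-1]
    poly = Polygon(p)
    if not Polygon(p).exterior.is_ccw:
        p = p[::-1]
    n = len(p)
    c = np.array([poly.centroid.x, poly.centroid.y])
    bot = np.column_stack([p, np.full(n, z0)])
    top = np.column_stack([p, np.full(n, z1)])
    cb = np.array([c[0], c[1], z0])
    ct = np.array([c[0], c[1], z1])
    verts = np.vstack([bot, top, cb, ct])
    icb, ict = 2 * n, 2 * n + 1
    faces = []
    for i in range(n):
        j = (i + 1) % n
        faces.append([i, j, n + j])       # side, outward for CCW profile
        faces.append([i, n + j, n + i])
        faces.append([icb, j, i])          # bottom cap (normal -z)
        faces.append([ict, n + i, n + j])  # top cap (normal +z)
    return trimesh.Trimesh(vertices=verts, faces=np.asarray(faces), process=False)


def _ellipse_profile(a: float, b: float, n: int = 36) -> np.ndarray:
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.stack([a * np.cos(t), b * np.sin(t)], axis=-1)


def _oblique_cylinder(
    radius: float,
    length: float,
    obliquity_deg: float,
    base: np.ndarray,
    sections: int = 12,
    obliquity_y_deg: float = 0.0,
) -> trimesh.Trimesh:
    """Closed cylinder from ``base`` along a direction tilted from +x
    toward +z (``obliquity_deg``) and optionally toward +y."""
    cyl = trimesh.creation.cylinder(radius=radius, height=length, sections=sections)
    # cylinder is centred on z; align its axis with the tilted direction
    b = np.radians(obliquity_deg)
    by = np.radians(obliquity_y_deg)
    direction = np.array([1.0, np.tan(by), np.tan(b)])
    direction /= np.linalg.norm(direction)
    T = trimesh.geometry.align_vectors([0, 0, 1], direction)
    cyl.apply_transform(T)
    cyl.apply_translation(base + direction * (length / 2.0))
    return cyl


def make_implant_mesh(
    kind: str = "tibial",
    size: float = 30.0,
    asymmetric: bool = True,
) -> ComponentMesh:
    """Parametric TAR component stand-in in its canonical (neutral) frame.

    ``size`` is the medial-lateral width of the component in mm (default
    30 mm, a typical tibial tray footprint); all other dimensions scale
    proportionally.

    tibial : an elliptic plateau plate with a superior fixation stem.  With
        ``asymmetric=True`` the stem is oblique at 25 degrees in the
        coronal plane, which removes the sagittal mirror plane.
    talar : a superiorly convex dome (circular-arc profile extruded
        medial-laterally) with an inferior fixation fin, oblique when
        asymmetric.

    The same parameters always produce the same vertex arrays.
    """
    if size <= 0:
        raise ValueError("size must be positive")
    s = size / 30.0
    if kind == "tibial":
        # plateau: elliptic cross-section (z semi-axis 15 mm, y 12.5 mm),
        # 4 mm thick, top face at x = 0.
        prof = _ellipse_profile(15.0 * s, 12.5 * s)  # (z, y)
        plate = _extrude_profile(prof, -4.0 * s, 0.0)
        # built in (z, y, x) scratch axes -> remap to anatomical (x, y, z)
        plate.vertices = plate.vertices[:, [2, 1, 0]]
        plate.invert()  # axis swap flips orientation; restore outward normals
        stem = _oblique_cylinder(
            radius=4.0 * s,
            length=38.0 * s,
            obliquity_deg=30.0 if asymmetric else 0.0,
            obliquity_y_deg=12.0 if asymmetric else 0.0,
            base=np.array([-1.0 * s, 0.0, 0.0]),
        )
        # anterior fixation peg: offset from the stem so that no rotation
        # axis leaves the silhouette (near-)invariant — without it, rotation
        # about the stem's own axis is a soft mode the views barely see
        peg = _oblique_cylinder(
            radius=2.5 * s,
            length=14.0 * s,
            obliquity_deg=0.0,
            base=np.array([-1.0 * s, 0.0, 0.0]),
        )
        peg.apply_translation([0.0, 7.5 * s, 0.0])
        tm = trimesh.util.concatenate([plate, stem, peg])
        label = "tibial"
    elif kind == "talar":
        # dome: superior circular arc (radius 11 mm about a centre 4 mm
        # below the equator, spanning +-65 degrees) closed by a gently
        # convex inferior arc through (-3, 0) — a smooth convex profile,
        # extruded medial-laterally.  Smoothness keeps foreshortening
        # rotations second-order in the silhouette, as for real rounded
        # components; the flat medial/lateral end caps are what make
        # axial rotation observable.
        r, drop, half = 11.0 * s, 4.0 * s, np.radians(65.0)
        psi = np.linspace(-half, half, 25)
        arc = np.stack([-drop + r * np.cos(psi), r * np.sin(psi)], axis=-1)  # (x, y)
        x_end, y_end = arc[-1]  # arc endpoint at psi = +65 deg
        x_bot = -3.0 * s
        # circle through (x_end, +-y_end) and (x_bot, 0), centre on the x axis
        c = (x_end**2 + y_end**2 - x_bot**2) / (2.0 * (x_end - x_bot))
        rb = c - x_bot
        a0 = np.arctan2(y_end, x_end - c)  # ~140 deg: arc runs through 180 deg
        a = np.linspace(a0, 2.0 * np.pi - a0, 17)[1:-1]
        bottom = np.stack([c + rb * np.cos(a), rb * np.sin(a)], axis=-1)
        prof = np.vstack([arc, bottom])
        dome = _extrude_profile(prof[:, ::-1], -13.0 * s, 13.0 * s)  # profile (y, x)
        dome.vertices = dome.vertices[:, [1, 0, 2]]  # (y, x, z) -> (x, y, z)
        dome.invert()
        obliquity = -20.0 if asymmetric else 0.0
        fin = _oblique_cylinder(
            radius=3.0 * s,
            length=12.0 * s,
            obliquity_deg=180.0 - obliquity,  # points inferiorly (-x)
            base=np.array([x_bot + 1.0 * s, 0.0, 0.0]),
        )
        tm = trimesh.util.concatenate([dome, fin])
        label = "talar"
    else:
        raise ValueError("kind must be 'tibial' or 'talar'")
    mesh = ComponentMesh(
        vertices=np.asarray(tm.vertices, dtype=float),
        faces=np.asarray(tm.faces, dtype=np.int64),
        component_label=label,
        asymmetric=asymmetric,
    )
    return mesh.recentered()


def default_talar_offset(
    tibial: ComponentMesh, talar: ComponentMesh, liner_gap: float = 6.0
) -> float:
    """Longitudinal talar translation placing the dome apex ``liner_gap``
    mm below the tibial plate, as the radiolucent polyethylene liner would.
    """
    plate_bottom = float(tibial.vertices[:, 0].min())
    dome_top = float(talar.vertices[:, 0].max())
    return plate_bottom - dome_top - liner_gap


@dataclass(frozen=True)
class Centerline:
    """Analytic straight centreline of a synthetic shaft."""

    point: np.ndarray
    direction: np.ndarray  # unit vector


def make_tibia_shaft(
    length: float = 200.0,
    radius_prox: float = 14.0,
    radius_dist: float = 11.0,
    axis_tilt: tuple[float, float] = (0.0, 0.0),
    roughness: float = 0.0,
    radius_modulation: tuple[float, int] | None = None,
    seed: int = 0,
    n_rings: int = 64,
    n_around: int = 32,
) -> tuple[ComponentMesh, Centerline]:
    """Tapered tubular shaft with an analytically known centreline.

    ``axis_tilt = (toward_y_deg, toward_z_deg)`` tilts the centreline away
    from the longitudinal x axis; ``roughness`` adds seeded radial surface
    noise (mm, standard deviation); ``radius_modulation = (amplitude_mm,
    n_periods)`` imposes a sinusoidal radius along the shaft, emulating
    shaft waviness, without moving the cross-section centroids off the
    centreline.  Returns the mesh and the exact centreline.
    """
    if length <= 0 or radius_prox <= 0 or radius_dist <= 0:
        raise ValueError("length and radii must be positive")
    rng = np.random.default_rng(seed)
    ty, tz = np.radians(axis_tilt[0]), np.radians(axis_tilt[1])
    direction = np.array([1.0, np.tan(ty), np.tan(tz)])
    direction /= np.linalg.norm(direction)

    x = np.linspace(-length / 2.0, length / 2.0, n_rings)
    frac = (x + length / 2.0) / length
    radii = radius_dist + (radius_prox - radius_dist) * frac
    if radius_modulation is not None:
        amp, periods = radius_modulation
        radii = radii + amp * np.sin(2 * np.pi * periods * frac)
    centres = np.outer(x, direction / direction[0])  # centreline parametrised by x

    theta = np.linspace(0, 2 * np.pi, n_around, endpoint=False)
    verts = []
    for i in range(n_rings):
        r = radii[i] + (rng.normal(0.0, roughness, n_around) if roughness > 0 else 0.0)
        ring = centres[i] + np.stack(
            [np.zeros(n_around), r * np.cos(theta), r * np.sin(theta)], axis=-1
        )
        verts.append(ring)
    verts = np.vstack(verts)

    faces = []
    for i in range(n_rings - 1):
        for j in range(n_around):
            a = i * n_around + j
            b = i * n_around + (j + 1) % n_around
            c = a + n_around
            d = b + n_around
            faces.append([a, b, d])
            faces.append([a, d, c])
    # end caps (fans around the ring centroids)
    lo = len(verts)
    verts = np.vstack([verts, centres[0], centres[-1]])
    for j in range(n_around):
        faces.append([lo, (j + 1) % n_around, j])
        base = (n_rings - 1) * n_around
        faces.append([lo + 1, base + j, base + (j + 1) % n_around])

    mesh = ComponentMesh(
        vertices=verts,
        faces=np.asarray(faces, dtype=np.int64),
        component_label="tibial",
        asymmetric=False,
    )
    return mesh, Centerline(point=np.zeros(3), direction=direction)


def shaft_edge_annotations(
    shaft: ComponentMesh,
    rig: BiplanarRig | None = None,
    view: str = "AP",
    pose: Pose | None = None,
    bands: tuple[tuple[float, float], tuple[float, float]] = ((0.08, 0.3), (0.7, 0.92)),
    n_lines: int = 8,
) -> dict[str, np.ndarray]:
    """Emulated shaft-edge click points for the two-circle axis method.

    The shaft silhouette is projected into the requested view and its
    boundary intersected with horizontal lines inside a proximal and a
    distal band (fractions of the silhouette height).  The resulting
    left/right edge points are what a reader would click when aligning a
    circle to the cortical outline.  Returns ``{"proximal": (n, 2),
    "distal": (n, 2)}`` point arrays in mm.
    """
    import shapely as _shapely

    from .projection import project_silhouette

    rig = rig or BiplanarRig(pixel_spacing=0.5, image_shape=(640, 512))
    pose = pose or Pose()
    contour = project_silhouette(shaft, pose, rig, view)
    boundary = contour.geometry.boundary
    u_lo, v_lo, u_hi, v_hi = contour.geometry.bounds
    out = {}
    for name, (f0, f1) in zip(("proximal", "distal"), bands):
        pts = []
        for f in np.linspace(f0, f1, n_lines):
            v = v_lo + f * (v_hi - v_lo)
            line = _shapely.LineString([(u_lo - 1, v), (u_hi + 1, v)])
            hits = line.intersection(boundary)
            coords = _shapely.get_coordinates(hits)
            if len(coords) >= 2:
                pts.append(coords[np.argmin(coords[:, 0])])
                pts.append(coords[np.argmax(coords[:, 0])])
        out[name] = np.asarray(pts)
    return out


@dataclass(frozen=True)
class NoiseParams:
    """Image degradation applied to rendered silhouette images.

    blur_sigma_px : Gaussian blur standard deviation in pixels.
    noise_fraction : additive Gaussian noise, standard deviation as a
        fraction of the image dynamic range.
    occlusion_fraction : fraction of the silhouette boundary hidden by
        background-coloured discs (emulating overlying structures).
    """

    blur_sigma_px: float = 0.0
    noise_fraction: float = 0.0
    occlusion_fraction: float = 0.0


@dataclass(frozen=True)
class SyntheticCase:
    """A biplanar radiograph pair with complete ground truth."""

    tibial_mesh: ComponentMesh
    talar_mesh: ComponentMesh
    true_poses: tuple[Pose, Pose]
    rig: BiplanarRig
    ap_image: np.ndarray
    lat_image: np.ndarray
    true_axis_2d: dict[str, TibialAxis2D]
    true_axis_3d: TibialAxis3D
    noise_params: NoiseParams
    seed: int
    # extra rotation about x applied before rendering the LAT view only;
    # nonzero means the two views are deliberately inconsistent
    inter_view_rotation: float = 0.0

    def image(self, view: str) -> np.ndarray:
        return self.ap_image if view == "AP" else self.lat_image

    def component_mesh(self, component: str) -> ComponentMesh:
        return self.tibial_mesh if component == "tibial" else self.talar_mesh

    def component_pose(self, component: str) -> Pose:
        return self.true_poses[0] if component == "tibial" else self.true_poses[1]

    def contour_targets(self, component: str, source: str = "image"):
        """Per-component, per-view silhouette contour targets.

        ``source="image"``: threshold the (noise-free) rendered images and
        trace sub-pixel contours, keeping the rings near the component's
        true silhouette — the evidence an ideal segmentation would give.
        ``source="exact"``: the analytic silhouettes themselves (for the
        LAT view, of the pose actually rendered there, i.e. including any
        inter-view movement).  Raises if the images carry noise in image
        mode.
        """
        import shapely as _shapely

        from .projection import (
            ContourSet,
            mask_to_contours,
            silhouette_geometry,
            project_silhouette,
            _polygons_to_geometry,
        )

        mesh = self.component_mesh(component)
        pose = self.component_pose(component)
        out = {}
        for view in VIEWS:
            shown = pose if view == "AP" else _lat_pose(pose, self.inter_view_rotation)
            if source == "exact":
                out[view] = project_silhouette(mesh, shown, self.rig, view)
                continue
            if source != "image":
                raise ValueError("source must be 'image' or 'exact'")
            if self.noise_params.noise_fraction > 0:
                raise ValueError("image contour targets require a noise-free case")
            img = self.image(view)
            mask = img < (_IMPLANT + _BACKGROUND) / 2.0
            cs = mask_to_contours(mask, self.rig.spacing(view), view)
            region = silhouette_geometry(mesh, shown, self.rig, view).buffer(5.0)
            keep = [
                p
                for p in cs.polygons
                if region.contains(_shapely.Point(p.mean(axis=0)))
            ]
            if not keep:
                raise ValueError(f"no contour rings near {component} in {view} view")
            out[view] = ContourSet.from_shapely(_polygons_to_geometry(keep), view)
        return out


def _lat_pose(pose: Pose, extra_rx_deg: float) -> Pose:
    """Pose as seen in the LAT view after a foot rotation between exposures."""
    if extra_rx_deg == 0.0:
        return pose
    Rx = _rot_x(extra_rx_deg)
    R = Rx @ rotation_matrix(pose)
    t = Rx @ pose.translation
    return pose_from_matrix(R, t)


def _render_view(
    case_meshes: list[tuple[ComponentMesh, Pose]],
    rig: BiplanarRig,
    view: str,
    noise: NoiseParams,
    rng: np.random.Generator,
    oversample: int = 4,
) -> np.ndarray:
    from scipy import ndimage

    # render with partial-volume anti-aliasing: a real detector integrates
    # flux over each pixel, so boundary pixels take intermediate grey
    # values that carry sub-pixel edge position — a binary mask would
    # quantise the contour evidence at the pixel grid
    rows, cols = rig.shape(view)
    fine = np.zeros((rows * oversample, cols * oversample), dtype=bool)
    for mesh, pose in case_meshes:
        fine |= rasterize_silhouette(mesh, pose, rig, view, oversample=oversample)
    coverage = fine.reshape(rows, oversample, cols, oversample).mean(axis=(1, 3))
    img = _BACKGROUND + (_IMPLANT - _BACKGROUND) * coverage
    mask = coverage > 0.5

    if noise.occlusion_fraction > 0:
        # wash out local contrast in feathered discs centred on boundary
        # pixels: the contour evidence disappears (as under an overlapping
        # structure of similar opacity) without fabricating sharp rim edges
        boundary = mask ^ ndimage.binary_erosion(mask)
        br, bc = np.nonzero(boundary)
        n_b = len(br)
        if n_b:
            disc_r = 8.0
            n_discs = max(1, int(noise.occlusion_fraction * n_b / (2 * disc_r)))
            idx = rng.choice(n_b, size=n_discs, replace=False)
            rr = np.arange(img.shape[0])[:, None]
            cc = np.arange(img.shape[1])[None, :]
            flat = ndimage.gaussian_filter(img, disc_r)
            weight = np.zeros(img.shape)
            for i in idx:
                r = np.sqrt((rr - br[i]) ** 2 + (cc - bc[i]) ** 2) / disc_r
                w = np.clip((1.0 - r) / 0.4, 0.0, 1.0)  # 1 inside 0.6R, 0 at R
                weight = np.maximum(weight, w * w * (3 - 2 * w))
            img = weight * flat + (1.0 - weight) * img
    if noise.blur_sigma_px > 0:
        img = ndimage.gaussian_filter(img, noise.blur_sigma_px)
    if noise.noise_fraction > 0:
        img = img + rng.normal(
            0.0, noise.noise_fraction * (_BACKGROUND - _IMPLANT), img.shape
        )
    return img


def make_case(
    true_poses: tuple[Pose, Pose] | None = None,
    rig: BiplanarRig | None = None,
    noise_params: NoiseParams | None = None,
    seed: int = 0,
    size: float = 30.0,
    asymmetric: bool = True,
    inter_view_rotation: float = 0.0,
    components: str = "both",
) -> SyntheticCase:
    """Render a biplanar silhouette case with full ground truth.

    Default rig: 0.5 mm/px, 512 x 512 per view — fine enough to resolve
    0.5 degree pose differences of a 30 mm component.  The talar component
    is placed 18 mm distal to the tibial one (typical centre separation on
    the rendered views) unless explicit poses are given.

    ``components`` selects what is rendered into the images ("both",
    "tibial" or "talar"); single-component images isolate one component's
    edge evidence for per-component robustness experiments.
    """
    rig = rig or BiplanarRig()
    noise = noise_params or NoiseParams()
    rng = np.random.default_rng(seed)

    tibial = make_implant_mesh("tibial", size=size, asymmetric=asymmetric)
    talar = make_implant_mesh("talar", size=size * 0.9, asymmetric=asymmetric)
    if true_poses is None:
        true_poses = (Pose(), Pose(tx=default_talar_offset(tibial, talar)))

    # field-of-view check: every component centre must project inside both views
    for pose in true_poses:
        for view in VIEWS:
            uv = rig.world_to_view(pose.translation, view)
            w, h = rig.extent_mm(view)
            if not (0 <= uv[0] <= w and 0 <= uv[1] <= h):
                raise ValueError("component outside the field of view")

    tib_pose, tal_pose = true_poses
    render_list = {
        "both": [(tibial, tib_pose), (talar, tal_pose)],
        "tibial": [(tibial, tib_pose)],
        "talar": [(talar, tal_pose)],
    }[components]
    ap = _render_view(render_list, rig, "AP", noise, rng)
    lat = _render_view(
        [(mesh, _lat_pose(pose, inter_view_rotation)) for mesh, pose in render_list],
        rig,
        "LAT",
        noise,
        rng,
    )

    axes = {}
    for view in VIEWS:
        uv = rig.world_to_view(tib_pose.translation, view)
        axes[view] = TibialAxis2D(
            view_label=view, point=uv, direction=np.array([0.0, 1.0])
        )
    axis3d = TibialAxis3D(
        point=np.zeros(3),
        direction=np.array([1.0, 0.0, 0.0]),
        n_slices=0,
        fit_rms=0.0,
    )
    return SyntheticCase(
        tibial_mesh=tibial,
        talar_mesh=talar,
        true_poses=true_poses,
        rig=rig,
        ap_image=ap,
        lat_image=lat,
        true_axis_2d=axes,
        true_axis_3d=axis3d,
        noise_params=noise,
        seed=seed,
        inter_view_rotation=inter_view_rotation,
    )


def make_movement_artifact_case(
    true_poses: tuple[Pose, Pose] | None = None,
    rig: BiplanarRig | None = None,
    inter_view_rotation: float = 10.0,
    noise_params: NoiseParams | None = None,
    seed: int = 0,
    **kwargs,
) -> SyntheticCase:
    """A deliberately inconsistent view pair: the foot rotated about the
    longitudinal axis between the AP and lateral exposures.

    The AP view is rendered at ``true_poses``; the LAT view after an extra
    rotation of ``inter_view_rotation`` degrees about x.  No single rigid
    pose can explain both silhouettes, so the best achievable registration
    cost stays high — the signature by which such pairs are detected.
    """
    return make_case(
        true_poses=true_poses,
        rig=rig,
        noise_params=noise_params,
        seed=seed,
        inter_view_rotation=inter_view_rotation,
        **kwargs,
    )
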