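"""Orthographic silhouette projection onto the coupled biplanar image planes.

The two radiographic views are modelled as parallel (orthographic)
projections along perpendicular directions:

* **AP** (anteroposterior): beam along anatomical ``-y``; the image plane is
  spanned by ``z`` (columns, medial to the right) and ``x`` (rows, superior
  up — i.e. row index increases inferiorly).
* **LAT** (lateral): beam along anatomical ``-z``; the image plane is
  spanned by ``y`` (columns, anterior to the right) and ``x`` (rows).

Both views therefore share the anatomical ``x`` (longitudinal) axis as
their row axis: this is the geometric coupling that lets one rigid pose
explain both radiographs simultaneously.  A clinical X-ray beam diverges,
but the contour-overlay principle implemented here uses no magnification
model, so orthographic projection with a calibrated pixel spacing is the
faithful reading; this approximation is stated, not hidden.

Image coordinate conventions: 0-based pixel indices, origin at the top-left
pixel, the centre of pixel ``(i, j)`` at physical position
``((j + 0.5) s, (i + 0.5) s)`` millimetres where ``s`` is the pixel
spacing.  Contour coordinates are always physical ``(u, v)`` mm with ``u``
along columns and ``v`` along rows (``v`` increases inferiorly).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import shapely
from shapely.geometry import MultiPolygon, Polygon

from .geometry import ComponentMesh, Pose, apply_pose

__all__ = [
    "BiplanarRig",
    "ContourSet",
    "EdgeMap",
    "project_silhouette",
    "render_biplanar",
    "rasterize_silhouette",
    "extract_edges",
    "read_image",
]

VIEWS = ("AP", "LAT")


class DegenerateProjectionError(ValueError):
    """Raised when a mesh projects to a (near-)zero-area silhouette."""


@dataclass(frozen=True)
class BiplanarRig:
    """Geometry of the coupled AP/lateral projection pair.

    Parameters
    ----------
    pixel_spacing : mm per pixel; a scalar applied to both views or a
        ``(ap, lat)`` pair.
    image_shape : ``(rows, cols)`` per view, again shared or a pair.

    The projection directions are fixed by the anatomical frame
    (``ap_direction = -y``, ``lat_direction = -z``) and are perpendicular
    by construction, mirroring the perpendicular acquisition of the AP and
    lateral radiographs.
    """

    pixel_spacing: float | tuple[float, float] = 0.5
    image_shape: tuple[int, int] | tuple[tuple[int, int], tuple[int, int]] = (512, 512)

    ap_direction: np.ndarray = field(
        default_factory=lambda: np.array([0.0, -1.0, 0.0]), repr=False
    )
    lat_direction: np.ndarray = field(
        default_factory=lambda: np.array([0.0, 0.0, -1.0]), repr=False
    )

    def __post_init__(self) -> None:
        if abs(float(np.dot(self.ap_direction, self.lat_direction))) > 1e-9:
            raise ValueError("AP and lateral view directions must be perpendicular")
        for v in VIEWS:
            if self.spacing(v) <= 0:
                raise ValueError("pixel_spacing must be positive")

    def spacing(self, view: str) -> float:
        s = self.pixel_spacing
        if np.isscalar(s):
            return float(s)
        return float(s[0] if view == "AP" else s[1])

    def shape(self, view: str) -> tuple[int, int]:
        sh = self.image_shape
        if len(sh) == 2 and np.isscalar(sh[0]):
            return (int(sh[0]), int(sh[1]))
        pair = sh[0] if view == "AP" else sh[1]
        return (int(pair[0]), int(pair[1]))

    def extent_mm(self, view: str) -> tuple[float, float]:
        """Physical (width, height) of a view's image in mm."""
        rows, cols = self.shape(view)
        s = self.spacing(view)
        return cols * s, rows * s

    # --- world <-> image-plane maps -------------------------------------
    def world_to_view(self, points: np.ndarray, view: str) -> np.ndarray:
        """Map 3D anatomical points (mm) to in-plane ``(u, v)`` mm coordinates.

        ``u`` runs along columns (AP: +z medial; LAT: +y anterior), ``v``
        along rows (both views: -x, so superior structures sit at small v).
        The anatomical origin maps to the image centre.
        """
        points = np.asarray(points, dtype=float)
        w, h = self.extent_mm(view)
        if view == "AP":
            u = points[..., 2] + w / 2.0
        elif view == "LAT":
            u = points[..., 1] + w / 2.0
        else:
            raise ValueError(f"view must be one of {VIEWS}")
        v = h / 2.0 - points[..., 0]
        return np.stack([u, v], axis=-1)

    def view_to_pixels(self, uv: np.ndarray, view: str) -> np.ndarray:
        """(u, v) mm -> fractional (row, col) pixel indices."""
        uv = np.asarray(uv, dtype=float)
        s = self.spacing(view)
        col = uv[..., 0] / s - 0.5
        row = uv[..., 1] / s - 0.5
        return np.stack([row, col], axis=-1)

    def pixels_to_view(self, rc: np.ndarray, view: str) -> np.ndarray:
        """Fractional (row, col) pixel indices -> (u, v) mm."""
        rc = np.asarray(rc, dtype=float)
        s = self.spacing(view)
        u = (rc[..., 1] + 0.5) * s
        v = (rc[..., 0] + 0.5) * s
        return np.stack([u, v], axis=-1)


@dataclass(frozen=True)
class ContourSet:
    """Closed silhouette outline(s) of one component in one view.

    ``polygons`` are closed ``(k, 2)`` arrays of ``(u, v)`` mm points
    (first point repeated last); ``centroid`` is the area-weighted centroid
    of the enclosed region (holes subtract).
    """

    view_label: str
    polygons: tuple[np.ndarray, ...]
    centroid: np.ndarray
    _geometry: Polygon | MultiPolygon | None = field(
        default=None, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        if self.view_label not in VIEWS:
            raise ValueError(f"view_label must be one of {VIEWS}")
        if not self.polygons:
            raise ValueError("ContourSet requires at least one polygon")
        for p in self.polygons:
            if len(p) < 4 or not np.allclose(p[0], p[-1]):
                raise ValueError("each polygon must be closed with >= 3 distinct points")

    @classmethod
    def from_shapely(cls, geom, view_label: str) -> "ContourSet":
        geom = _clean_geometry(geom)
        polys = _geometry_polygons(geom)
        rings = []
        for poly in polys:
            rings.append(np.asarray(poly.exterior.coords, dtype=float))
            for hole in poly.interiors:
                rings.append(np.asarray(hole.coords, dtype=float))
        c = geom.centroid
        return cls(
            view_label=view_label,
            polygons=tuple(rings),
            centroid=np.array([c.x, c.y]),
            _geometry=geom,
        )

    @property
    def geometry(self) -> Polygon | MultiPolygon:
        """Shapely region enclosed by the contours (cached when available)."""
        if self._geometry is not None:
            return self._geometry
        geom = _polygons_to_geometry(self.polygons)
        object.__setattr__(self, "_geometry", geom)
        return geom

    @property
    def boundary(self):
        return self.geometry.boundary

    def sample_points(self, step: float = 0.5) -> np.ndarray:
        """Points sampled along every contour at <= ``step`` mm arc length."""
        pts = []
        b = self.geometry.boundary
        lines = getattr(b, "geoms", [b])
        for line in lines:
            n = max(int(np.ceil(line.length / step)), 4)
            d = np.linspace(0.0, line.length, n, endpoint=False)
            p = shapely.line_interpolate_point(line, d)
            pts.append(shapely.get_coordinates(p))
        return np.vstack(pts)

    @property
    def area(self) -> float:
        return float(self.geometry.area)


@dataclass(frozen=True)
class EdgeMap:
    """Binary image of candidate implant edges for one view.

    ``refined`` optionally carries sub-pixel edge positions (fractional
    (row, col) indices, one per edge pixel); when present they are used by
    :meth:`points_mm` instead of the pixel centres.
    """

    view_label: str
    edges: np.ndarray  # bool (rows, cols)
    pixel_spacing: float
    refined: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.view_label not in VIEWS:
            raise ValueError(f"view_label must be one of {VIEWS}")
        object.__setattr__(self, "edges", np.asarray(self.edges, dtype=bool))

    @property
    def n_edge_pixels(self) -> int:
        return int(self.edges.sum())

    def points_mm(self) -> np.ndarray:
        """Edge positions as (u, v) mm points (sub-pixel when available)."""
        s = self.pixel_spacing
        if self.refined is not None:
            rc = self.refined
        else:
            rows, cols = np.nonzero(self.edges)
            rc = np.stack([rows, cols], axis=-1).astype(float)
        return np.stack([(rc[:, 1] + 0.5) * s, (rc[:, 0] + 0.5) * s], axis=-1)

    def save(self, path: str | Path) -> None:
        import imageio.v3 as iio

        iio.imwrite(str(path), (self.edges * np.uint8(255)))


# ---------------------------------------------------------------------------
# silhouette computation
# ---------------------------------------------------------------------------


def _clean_geometry(geom):
    if not geom.is_valid:
        geom = geom.buffer(0)
    return geom


def _drop_slivers(geom, min_area: float = 0.05):
    """Remove numerically spurious interior rings and fragments.

    Unioning triangle fans that share edges leaves zero-width sliver holes
    that appear and disappear as the pose changes; they carry no geometric
    information but inject noise into boundary sampling, so any hole or
    component below ``min_area`` (mm^2) is discarded.
    """
    polys = []
    for p in _geometry_polygons(geom):
        if p.area < min_area:
            continue
        holes = [h for h in p.interiors if Polygon(h).area >= min_area]
        polys.append(Polygon(p.exterior, holes) if len(holes) != len(p.interiors) else p)
    if not polys:
        raise DegenerateProjectionError("projection produced no area")
    return polys[0] if len(polys) == 1 else MultiPolygon(polys)


def _geometry_polygons(geom) -> list[Polygon]:
    if isinstance(geom, Polygon):
        return [geom]
    if isinstance(geom, MultiPolygon):
        return list(geom.geoms)
    polys = [g for g in getattr(geom, "geoms", []) if isinstance(g, Polygon)]
    if not polys:
        raise DegenerateProjectionError("projection produced no area")
    return polys


def _polygons_to_geometry(polygons) -> Polygon | MultiPolygon:
    """Rebuild a region from closed rings; contained rings become holes."""
    polys = [Polygon(p) for p in polygons]
    polys = [p if p.is_valid else p.buffer(0) for p in polys]
    order = np.argsort([-p.area for p in polys])
    result = None
    for i in order:
        p = polys[i]
        if result is None:
            result = p
        elif result.contains(p.representative_point()):
            result = result.difference(p)
        else:
            result = result.union(p)
    return _clean_geometry(result)


def silhouette_geometry(
    mesh: ComponentMesh,
    pose: Pose,
    rig: BiplanarRig,
    view: str,
) -> Polygon | MultiPolygon:
    """Exact orthographic silhouette of a posed mesh as a shapely region.

    All triangles are projected along the view direction and their union
    taken; for a closed mesh this union is the exact silhouette, and
    unlike a raster it varies continuously with the pose — which is what
    makes sub-pixel pose refinement possible.
    """
    posed = apply_pose(mesh, pose)
    uv = rig.world_to_view(posed.vertices, view)
    tris = uv[mesh.faces]  # (m, 3, 2)
    e1 = tris[:, 1] - tris[:, 0]
    e2 = tris[:, 2] - tris[:, 0]
    area2 = e1[:, 0] * e2[:, 1] - e1[:, 1] * e2[:, 0]
    # For a closed, consistently oriented mesh the front-facing triangles
    # alone cover the silhouette, halving the union work; degenerate
    # (edge-on) triangles contribute no area either way.
    keep = area2 > 1e-9 if mesh.closed else np.abs(area2) > 1e-9
    if not np.any(keep):
        keep = np.abs(area2) > 1e-9
    if not np.any(keep):
        raise DegenerateProjectionError(
            f"mesh projects to zero area in {view} view (collinear along the beam)"
        )
    geom = shapely.union_all(shapely.polygons(tris[keep]))
    geom = _drop_slivers(_clean_geometry(geom))
    if geom.area <= 0:
        raise DegenerateProjectionError(f"zero-area silhouette in {view} view")
    return geom


def rasterize_silhouette(
    mesh: ComponentMesh,
    pose: Pose,
    rig: BiplanarRig,
    view: str,
    oversample: int = 1,
) -> np.ndarray:
    """Binary occupancy mask of the silhouette at rig resolution.

    ``oversample`` renders on a grid ``oversample`` times finer than the
    rig's pixel grid (used by convergence checks and image synthesis).
    """
    from skimage.draw import polygon as draw_polygon

    rows, cols = rig.shape(view)
    rows *= oversample
    cols *= oversample
    s = rig.spacing(view) / oversample
    posed = apply_pose(mesh, pose)
    uv = rig.world_to_view(posed.vertices, view)
    r = uv[:, 1] / s - 0.5
    c = uv[:, 0] / s - 0.5
    mask = np.zeros((rows, cols), dtype=bool)
    for f in mesh.faces:
        rr, cc = draw_polygon(r[f], c[f], shape=mask.shape)
        mask[rr, cc] = True
    return mask


def mask_to_contours(
    mask: np.ndarray, spacing: float, view: str, min_area_px: float = 4.0
) -> ContourSet:
    """Trace sub-pixel boundaries of a binary mask (marching squares) in mm."""
    from skimage import measure

    padded = np.pad(mask.astype(float), 1)
    raw = measure.find_contours(padded, 0.5)
    rings = []
    for contour in raw:
        rc = contour - 1.0  # undo padding
        uv = np.stack([(rc[:, 1] + 0.5) * spacing, (rc[:, 0] + 0.5) * spacing], axis=-1)
        if not np.allclose(uv[0], uv[-1]):
            uv = np.vstack([uv, uv[:1]])
        if len(uv) >= 4:
            poly = Polygon(uv)
            if poly.area >= min_area_px * spacing**2:
                rings.append(uv)
    if not rings:
        raise DegenerateProjectionError("mask contains no traceable region")
    geom = _polygons_to_geometry(rings)
    return ContourSet.from_shapely(geom, view)


def project_silhouette(
    mesh: ComponentMesh,
    pose: Pose,
    rig: BiplanarRig,
    view: str,
    method: str = "exact",
    oversample: int = 1,
) -> ContourSet:
    """Silhouette contours of a posed component in one view.

    ``method="exact"`` computes the analytic union of projected triangles
    (continuous in the pose; used during registration).  ``method="raster"``
    rasterises the projection at rig resolution and traces the boundary
    with marching squares — the route a scanned, imperfect mesh or a
    segmented image would take.  Both agree to within one pixel.
    """
    if view not in VIEWS:
        raise ValueError(f"view must be one of {VIEWS}")
    if method == "exact":
        geom = silhouette_geometry(mesh, pose, rig, view)
        return ContourSet.from_shapely(geom, view)
    if method == "raster":
        mask = rasterize_silhouette(mesh, pose, rig, view, oversample=oversample)
        if not mask.any():
            raise DegenerateProjectionError(f"empty raster silhouette in {view} view")
        return mask_to_contours(mask, rig.spacing(view) / oversample, view)
    raise ValueError("method must be 'exact' or 'raster'")


def render_biplanar(
    tibial: ComponentMesh,
    talar: ComponentMesh,
    poses: tuple[Pose, Pose],
    rig: BiplanarRig,
    method: str = "exact",
) -> dict[tuple[str, str], ContourSet]:
    """Project both components into both views from one shared pose pair.

    Returns a dict keyed by ``(view, component_label)``.  All four contour
    sets derive from the same two poses, so any pose change moves the
    outlines in both views together — the coupling that underpins biplanar
    pose recovery.
    """
    tib_pose, tal_pose = poses
    out: dict[tuple[str, str], ContourSet] = {}
    for view in VIEWS:
        out[(view, "tibial")] = project_silhouette(tibial, tib_pose, rig, view, method)
        out[(view, "talar")] = project_silhouette(talar, tal_pose, rig, view, method)
    return out


# ---------------------------------------------------------------------------
# image-side operations
# ---------------------------------------------------------------------------


def extract_edges(
    image: np.ndarray,
    pixel_spacing: float,
    low: float = 0.1,
    high: float = 0.2,
    view_label: str = "AP",
    sigma: float = 1.0,
    subpixel: bool = True,
) -> EdgeMap:
    """Gradient edge detection with hysteresis thresholds (Canny).

    ``low`` and ``high`` are fractions of the image dynamic range.  A
    constant image yields an empty edge map, not an error.  With
    ``subpixel`` (default) each edge pixel is refined along its gradient
    direction by parabolic interpolation of the gradient magnitude, which
    reduces edge-localisation noise well below the pixel grid — the
    limiting factor for the weakly observable pose parameters.
    """
    from scipy import ndimage
    from skimage import feature

    image = np.asarray(image, dtype=float)
    if not np.all(np.isfinite(image)):
        raise ValueError("image must be finite")
    if not 0 <= low < high:
        raise ValueError("thresholds must satisfy 0 <= low < high")
    rng_ = image.max() - image.min()
    if rng_ == 0:
        return EdgeMap(view_label=view_label, edges=np.zeros(image.shape, bool),
                       pixel_spacing=pixel_spacing)
    norm = (image - image.min()) / rng_
    edges = feature.canny(norm, sigma=sigma, low_threshold=low, high_threshold=high)
    refined = None
    if subpixel and edges.any():
        smooth = ndimage.gaussian_filter(norm, sigma)
        gr = ndimage.sobel(smooth, axis=0)
        gc = ndimage.sobel(smooth, axis=1)
        mag = np.hypot(gr, gc)
        rows, cols = np.nonzero(edges)
        g = np.stack([gr[rows, cols], gc[rows, cols]], axis=-1)
        gn = np.linalg.norm(g, axis=1)
        d = g / np.maximum(gn[:, None], 1e-12)
        base = np.stack([rows, cols], axis=-1).astype(float)
        m0 = mag[rows, cols]
        mp = ndimage.map_coordinates(mag, (base + d).T, order=1, mode="nearest")
        mm = ndimage.map_coordinates(mag, (base - d).T, order=1, mode="nearest")
        denom = mm - 2 * m0 + mp
        t = np.where(np.abs(denom) > 1e-12, 0.5 * (mm - mp) / denom, 0.0)
        t = np.clip(t, -0.75, 0.75)
        refined = base + t[:, None] * d
    return EdgeMap(view_label=view_label, edges=edges, pixel_spacing=pixel_spacing,
                   refined=refined)


def save_overlay(
    image: np.ndarray,
    contours: list[ContourSet] | ContourSet,
    pixel_spacing: float,
    path: str | Path,
) -> None:
    """Write a QC overlay: model contours burned in red onto the image."""
    import imageio.v3 as iio

    img = np.asarray(image, dtype=float)
    lo, hi = img.min(), img.max()
    norm = (img - lo) / (hi - lo) if hi > lo else np.zeros_like(img)
    rgb = np.stack([norm] * 3, axis=-1)
    if isinstance(contours, ContourSet):
        contours = [contours]
    for cs in contours:
        pts = cs.sample_points(pixel_spacing / 2.0)
        rows = np.clip((pts[:, 1] / pixel_spacing - 0.5).round().astype(int), 0, img.shape[0] - 1)
        cols = np.clip((pts[:, 0] / pixel_spacing - 0.5).round().astype(int), 0, img.shape[1] - 1)
        rgb[rows, cols] = [1.0, 0.1, 0.1]
    iio.imwrite(str(path), (rgb * 255).astype(np.uint8))


def read_image(path: str | Path) -> np.ndarray:
    """Read an 8/16-bit grayscale PNG or TIFF as a float array in [0, 1]."""
    import imageio.v3 as iio

    img = np.asarray(iio.imread(str(path)))
    if img.ndim == 3:
        img = img[..., :3].mean(axis=-1)
    img = img.astype(float)
    if img.max() > 1.0:
        img /= 255.0 if img.max() <= 255 else 65535.0
    return img
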