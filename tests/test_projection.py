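import numpy as np
import pytest
import shapely
import trimesh

from tarpose.geometry import ComponentMesh, Pose
from tarpose.projection import (
    BiplanarRig,
    DegenerateProjectionError,
    extract_edges,
    project_silhouette,
    rasterize_silhouette,
    render_biplanar,
)
from tarpose.synthetic import NoiseParams, make_case


def as_component(tm, label="tibial"):
    return ComponentMesh(
        vertices=np.asarray(tm.vertices, float),
        faces=np.asarray(tm.faces),
        component_label=label,
    )


@pytest.fixture(scope="module")
def cube():
    return as_component(trimesh.creation.box((10, 10, 10)))


@pytest.fixture(scope="module")
def sphere():
    return as_component(trimesh.creation.icosphere(subdivisions=3, radius=10))


class TestRig:
    def test_perpendicular_views_enforced(self):
        with pytest.raises(ValueError):
            BiplanarRig(ap_direction=np.array([0.0, -1.0, 0.0]),
                        lat_direction=np.array([0.0, -1.0, 0.0]))

    def test_positive_spacing_enforced(self):
        with pytest.raises(ValueError):
            BiplanarRig(pixel_spacing=0.0)

    def test_pixel_roundtrip(self, rig):
        uv = np.array([[10.0, 20.0], [100.0, 5.0]])
        back = rig.pixels_to_view(rig.view_to_pixels(uv, "AP"), "AP")
        np.testing.assert_allclose(back, uv)


class TestProjectSilhouette:
    @pytest.mark.parametrize("method", ["exact", "raster"])
    def test_cube_projects_to_square(self, cube, rig, method):
        cs = project_silhouette(cube, Pose(), rig, "AP", method=method)
        minx, miny, maxx, maxy = cs.geometry.bounds
        assert maxx - minx == pytest.approx(10, abs=rig.spacing("AP"))
        assert maxy - miny == pytest.approx(10, abs=rig.spacing("AP"))

    def test_sphere_silhouette_rotation_invariant(self, sphere, rig):
        a0 = project_silhouette(sphere, Pose(), rig, "AP").area
        for pose in (Pose(rx=30), Pose(ry=45, rz=10), Pose(rx=-60, ry=20)):
            a = project_silhouette(sphere, pose, rig, "AP").area
            assert a == pytest.approx(a0, rel=0.02)
            assert a == pytest.approx(np.pi * 100, rel=0.02)

    def test_inplane_rotation_rotates_contour(self, rig):
        # L-shaped prism (two joined boxes): rotation about the LAT view
        # axis (z) must rotate the contour in-plane
        a = trimesh.creation.box((8, 3, 4))
        b = trimesh.creation.box((3, 7, 4))
        b.apply_translation([-2.5, 5, 0])
        mesh = as_component(trimesh.util.concatenate([a, b]))
        alpha = 25.0
        neutral = project_silhouette(mesh, Pose(), rig, "LAT", method="raster")
        rotated = project_silhouette(mesh, Pose(rz=alpha), rig, "LAT", method="raster")
        # rotation about the view axis pivots at the anatomical origin,
        # which maps to the image centre; in (u, v) the angle is +alpha
        w, h = rig.extent_mm("LAT")
        c = np.array([w / 2, h / 2])
        th = np.radians(alpha)
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        pts = (neutral.sample_points(0.25) - c) @ R.T + c
        d = shapely.distance(shapely.points(pts), rotated.geometry.boundary)
        assert d.max() <= 2 * rig.spacing("LAT")

    def test_translation_linearity(self, cube, rig):
        base = project_silhouette(cube, Pose(), rig, "AP")
        moved = project_silhouette(cube, Pose(tz=7.0), rig, "AP")
        np.testing.assert_allclose(
            moved.centroid - base.centroid, [7.0, 0.0], atol=1e-9
        )

    def test_out_of_plane_translation_invisible(self, cube, rig):
        base = project_silhouette(cube, Pose(), rig, "AP")
        moved = project_silhouette(cube, Pose(ty=5.0), rig, "AP")
        np.testing.assert_allclose(moved.centroid, base.centroid, atol=1e-9)

    def test_exact_and_raster_agree(self, tibial_mesh, rig):
        pose = Pose(rx=5, ry=-3, rz=2)
        exact = project_silhouette(tibial_mesh, pose, rig, "AP")
        rast = project_silhouette(tibial_mesh, pose, rig, "AP", method="raster")
        pts = exact.sample_points(0.5)
        d = shapely.distance(shapely.points(pts), rast.geometry.boundary)
        assert d.max() <= 2 * rig.spacing("AP")

    def test_raster_resolution_convergence(self, talar_mesh, rig):
        pose = Pose(rx=4, ry=2, rz=-3)
        exact = project_silhouette(talar_mesh, pose, rig, "LAT")
        errs = []
        for oversample in (1, 2):
            rast = project_silhouette(
                talar_mesh, pose, rig, "LAT", method="raster", oversample=oversample
            )
            pts = rast.sample_points(0.25)
            errs.append(
                shapely.distance(shapely.points(pts), exact.geometry.boundary).max()
            )
        assert errs[1] < errs[0]
        assert errs[0] - errs[1] < rig.spacing("LAT")

    def test_degenerate_projection_raises(self, rig):
        # flat plate in the x-y plane has a line shadow in the AP view
        v = np.array([[0, 0, 0], [10, 0, 0], [10, 10, 0], [0, 10, 0.0]])
        f = np.array([[0, 1, 2], [0, 2, 3]])
        plate = ComponentMesh(vertices=v, faces=f, component_label="tibial", closed=False)
        with pytest.raises(DegenerateProjectionError):
            project_silhouette(plate, Pose(), rig, "AP")


class TestRenderBiplanar:
    def test_row_extents_shared_across_views(self, tibial_mesh, talar_mesh, rig):
        out = render_biplanar(tibial_mesh, talar_mesh, (Pose(), Pose(tx=-30)), rig)
        for comp in ("tibial", "talar"):
            ap = out[("AP", comp)].geometry.bounds
            lat = out[("LAT", comp)].geometry.bounds
            assert abs(ap[1] - lat[1]) <= rig.spacing("AP")
            assert abs(ap[3] - lat[3]) <= rig.spacing("AP")

    def test_out_of_plane_shift_visible_in_one_view_only(
        self, tibial_mesh, talar_mesh, rig
    ):
        base = render_biplanar(tibial_mesh, talar_mesh, (Pose(), Pose(tx=-30)), rig)
        moved = render_biplanar(
            tibial_mesh, talar_mesh, (Pose(), Pose(tx=-30, tz=3)), rig
        )
        d_ap = moved[("AP", "talar")].centroid - base[("AP", "talar")].centroid
        d_lat = moved[("LAT", "talar")].centroid - base[("LAT", "talar")].centroid
        np.testing.assert_allclose(d_ap, [3.0, 0.0], atol=1e-9)
        np.testing.assert_allclose(d_lat, [0.0, 0.0], atol=1e-9)

    def test_matches_independent_per_view_projection(
        self, tibial_mesh, talar_mesh, rig, rng
    ):
        poses = (Pose(3, -2, 1, 0.5, -0.5, 1), Pose(1, 2, -1, -30, 1, 0))
        out = render_biplanar(tibial_mesh, talar_mesh, poses, rig)
        for view in ("AP", "LAT"):
            solo = project_silhouette(tibial_mesh, poses[0], rig, view)
            np.testing.assert_allclose(
                out[(view, "tibial")].centroid, solo.centroid, atol=1e-12
            )
            assert out[(view, "tibial")].area == pytest.approx(solo.area)


class TestExtractEdges:
    def test_noise_free_edges_near_contour(self):
        case = make_case(seed=0, components="tibial")
        edges = extract_edges(case.ap_image, case.rig.spacing("AP"), view_label="AP")
        contour = project_silhouette(
            case.tibial_mesh, case.true_poses[0], case.rig, "AP"
        )
        d = shapely.distance(
            shapely.points(edges.points_mm()), contour.geometry.boundary
        )
        assert np.median(d) <= case.rig.spacing("AP")

    def test_constant_image_has_no_edges(self):
        edges = extract_edges(np.full((64, 64), 0.5), 0.5)
        assert edges.n_edge_pixels == 0

    def test_noisy_recall(self):
        case = make_case(
            seed=1, components="tibial", noise_params=NoiseParams(1.0, 0.05, 0.0)
        )
        edges = extract_edges(case.ap_image, case.rig.spacing("AP"), view_label="AP")
        contour = project_silhouette(
            case.tibial_mesh, case.true_poses[0], case.rig, "AP"
        )
        true_pts = contour.sample_points(case.rig.spacing("AP"))
        from scipy.spatial import cKDTree

        d, _ = cKDTree(edges.points_mm()).query(true_pts)
        frac = np.mean(d <= 2 * case.rig.spacing("AP"))
        assert frac >= 0.90

    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            extract_edges(np.zeros((8, 8)), 0.5, low=0.5, high=0.2)


def test_overlay_writer(tmp_path, tibial_mesh, rig):
    from tarpose.projection import save_overlay

    case_img = np.full(rig.shape("AP"), 0.8)
    contour = project_silhouette(tibial_mesh, Pose(), rig, "AP")
    out = tmp_path / "overlay.png"
    save_overlay(case_img, contour, rig.spacing("AP"), out)
    assert out.exists() and out.stat().st_size > 0
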