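import math

import numpy as np
import pytest
from scipy import ndimage
from scipy.spatial.transform import Rotation

from wmhshape.lesion_extraction import (
    LesionMesh,
    LesionVoxelSet,
    build_lesion_mesh,
    label_components,
)
from wmhshape.shape_features import (
    ISOPERIMETRIC_BOUND,
    compactness_features,
    compute_shape_features,
    eccentricity,
    fractal_dimension,
    max_diameter,
    min_orthogonal_diameter,
    principal_curvature_field,
    principal_curvatures,
    shape_index_curvedness,
    shape_index_from_curvatures,
)
from wmhshape.synthetic_data import PhantomSpec, make_phantom
from wmhshape.volume_io import VolumeGrid


def brute_force_max_diameter(verts):
    """Exhaustive vertex-pair search oracle."""
    best = 0.0
    for i in range(len(verts)):
        d = np.linalg.norm(verts[i + 1 :] - verts[i], axis=1)
        if len(d):
            best = max(best, d.max())
    return best


def _rotated(mesh, R):
    return LesionMesh(vertices=mesh.vertices @ R.T, faces=mesh.faces)


class TestMaxDiameter:
    def test_sphere_diameter(self):
        trimesh = pytest.importorskip("trimesh")
        ico = trimesh.creation.icosphere(subdivisions=3, radius=5.0)
        mesh = LesionMesh(vertices=np.asarray(ico.vertices), faces=np.asarray(ico.faces))
        length, direction = max_diameter(mesh)
        assert length == pytest.approx(10.0, rel=0.05)
        assert length == pytest.approx(brute_force_max_diameter(mesh.vertices), abs=1e-9)
        assert np.linalg.norm(direction) == pytest.approx(1.0, abs=1e-12)

    def test_matches_exhaustive_search(self, sphere10, ellipsoid_21_5_5):
        for _, _, mesh in (sphere10, ellipsoid_21_5_5):
            length, _ = max_diameter(mesh)
            assert length == pytest.approx(brute_force_max_diameter(mesh.vertices), abs=1e-9)

    def test_ellipsoid_major_axis(self, ellipsoid_21_5_5):
        _, _, mesh = ellipsoid_21_5_5
        length, direction = max_diameter(mesh)
        assert length == pytest.approx(42.0, rel=0.05)
        assert abs(direction[0]) > 0.99  # along x

    def test_scaling(self, ellipsoid_21_5_5):
        _, _, mesh = ellipsoid_21_5_5
        l1, d1 = max_diameter(mesh)
        l3, d3 = max_diameter(LesionMesh(vertices=mesh.vertices * 3.0, faces=mesh.faces))
        assert l3 == pytest.approx(3.0 * l1, rel=1e-12)
        assert np.allclose(d1, d3)


class TestMinOrthogonalDiameter:
    def test_sphere_any_axis(self, sphere10):
        _, _, mesh = sphere10
        for axis in (np.array([1.0, 0, 0]), np.array([0, 0.6, 0.8])):
            assert min_orthogonal_diameter(mesh, axis) == pytest.approx(20.0, rel=0.05)

    def test_box_calipers(self):
        # axis-aligned 10 x 4 x 2 box, exact vertices
        v = np.array([[x, y, z] for x in (0, 10.0) for y in (0, 4.0) for z in (0, 2.0)])
        f = np.zeros((12, 3), dtype=int)  # faces unused by the caliper
        mesh = LesionMesh(vertices=v, faces=f)
        assert min_orthogonal_diameter(mesh, np.array([1.0, 0, 0])) == pytest.approx(2.0, abs=1e-9)

    def test_rotation_invariance(self, ellipsoid_21_5_5):
        # rotating mesh, axis and the in-plane angular grid together is exact
        from wmhshape.shape_features import _orthonormal_plane

        _, _, mesh = ellipsoid_21_5_5
        axis = np.array([1.0, 0.0, 0.0])
        u, v = _orthonormal_plane(axis)
        d0 = min_orthogonal_diameter(mesh, axis, basis=(u, v))
        R = Rotation.from_euler("xyz", [20, 35, 50], degrees=True).as_matrix()
        d1 = min_orthogonal_diameter(_rotated(mesh, R), R @ axis, basis=(R @ u, R @ v))
        assert d1 == pytest.approx(d0, abs=1e-6)

    def test_collinear_vertices_rejected(self):
        v = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3.0, 0, 0]])
        mesh = LesionMesh(vertices=v, faces=np.zeros((1, 3), int))
        with pytest.raises(ValueError):
            min_orthogonal_diameter(mesh, np.array([1.0, 0, 0]))

    @pytest.mark.parametrize("seed", range(4))
    def test_one_degree_grid_close_to_fine_grid(self, seed):
        rng = np.random.default_rng(seed)
        axes = rng.uniform(4.0, 16.0, size=3)
        side = int(2 * axes.max() + 12)
        grid = make_phantom(
            PhantomSpec(
                kind="ellipsoid",
                size_mm=tuple(axes),
                grid_shape=(side, side, side),
                orientation=Rotation.random(rng=rng).as_matrix(),
            )
        )
        mesh = build_lesion_mesh(label_components(grid)[0], grid)
        _, direction = max_diameter(mesh)
        coarse = min_orthogonal_diameter(mesh, direction, step_deg=1.0)
        fine = min_orthogonal_diameter(mesh, direction, step_deg=0.1)
        assert coarse == pytest.approx(fine, rel=0.01)


class TestEccentricity:
    def test_sphere_is_one(self, sphere10):
        _, _, mesh = sphere10
        assert eccentricity(mesh) == pytest.approx(1.0, abs=0.1)

    def test_elongated_ellipsoid(self, ellipsoid_21_5_5):
        _, _, mesh = ellipsoid_21_5_5
        assert eccentricity(mesh) == pytest.approx(4.2, abs=0.3)

    def test_scale_invariance(self, ellipsoid_21_5_5):
        _, _, mesh = ellipsoid_21_5_5
        e = eccentricity(mesh)
        scaled = LesionMesh(vertices=mesh.vertices * 7.3, faces=mesh.faces)
        assert eccentricity(scaled) == pytest.approx(e, rel=1e-9)

    def test_rotation_invariance(self, ellipsoid_21_5_5):
        _, _, mesh = ellipsoid_21_5_5
        e = eccentricity(mesh)
        R = Rotation.from_euler("zyx", [33, 12, 71], degrees=True).as_matrix()
        assert eccentricity(_rotated(mesh, R)) == pytest.approx(e, abs=1e-3 * e + 0.02)

    def test_at_least_one(self, sphere10, ellipsoid_21_5_5):
        for _, _, mesh in (sphere10, ellipsoid_21_5_5):
            assert eccentricity(mesh) >= 1.0 - 1e-9

    def test_stretching_never_decreases_eccentricity(self):
        prev = 0.0
        for a in (6.0, 9.0, 12.0, 15.0):
            grid = make_phantom(
                PhantomSpec(kind="ellipsoid", size_mm=(a, 5.0, 5.0), grid_shape=(int(2 * a + 10), 24, 24))
            )
            mesh = build_lesion_mesh(label_components(grid)[0], grid)
            e = eccentricity(mesh)
            assert e >= prev - 1e-6
            prev = e


class TestCompactness:
    def test_exact_cube_closed_forms(self, unit_cube_mesh):
        c1, c2, c3 = compactness_features(unit_cube_mesh)
        assert c1 == pytest.approx(1.0 / 216.0, abs=1e-12)  # s^6 / (6 s^2)^3
        assert c2 == pytest.approx(1.0, abs=1e-12)
        assert c3 == pytest.approx(1.0, abs=1e-12)

    def test_digital_box_compactness2_near_one(self):
        grid = make_phantom(PhantomSpec(kind="box", size_mm=(10, 4, 2), grid_shape=(20, 14, 12)))
        mesh = build_lesion_mesh(label_components(grid)[0], grid)
        _, c2, _ = compactness_features(mesh)
        assert c2 == pytest.approx(1.0, abs=0.15)

    def test_ball_approaches_isoperimetric_bound_from_below(self, sphere10):
        _, _, mesh = sphere10
        c1, c2, c3 = compactness_features(mesh)
        assert 0.6 * ISOPERIMETRIC_BOUND < c1 <= ISOPERIMETRIC_BOUND + 1e-6
        assert 0 < c2 <= 1
        assert 0 < c3 <= 1

    def test_convex_bodies_respect_isoperimetric_bound(self, ellipsoid_21_5_5, unit_cube_mesh):
        for mesh in (ellipsoid_21_5_5[2], unit_cube_mesh):
            c1, _, _ = compactness_features(mesh)
            assert c1 <= ISOPERIMETRIC_BOUND + 1e-6


class TestFractalDimension:
    def test_straight_line_has_dimension_one(self):
        vox = np.array([[i, 0, 0] for i in range(64)])
        fd = fractal_dimension(LesionVoxelSet(1, vox))
        assert fd == pytest.approx(1.0, abs=0.25)

    def test_cube_boundary_has_dimension_two(self):
        ii = np.arange(32)
        vox = np.array(np.meshgrid(ii, ii, ii, indexing="ij")).reshape(3, -1).T
        fd = fractal_dimension(LesionVoxelSet(1, vox))
        assert fd == pytest.approx(2.0, abs=0.3)

    def test_tiny_lesion_is_undefined(self):
        vox = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1], [1, 1, 0]])
        assert math.isnan(fractal_dimension(LesionVoxelSet(1, vox)))


def _blurred_ball(radius, grid_size, presmooth=1.5):
    grid = make_phantom(PhantomSpec(kind="sphere", size_mm=(radius,), grid_shape=(grid_size,) * 3))
    img = ndimage.gaussian_filter(np.asarray(grid.data, float), presmooth)
    return grid, VolumeGrid(img, spacing=grid.spacing)


class TestCurvature:
    def test_blurred_ball_surface_curvature(self):
        r = 8.0
        mask, img = _blurred_ball(r, 36)
        lesion = label_components(mask)[0]
        # a voxel on the surface, on the +x axis through the center
        center = (np.asarray(mask.shape) - 1) // 2
        at = (int(center[0] + r), int(center[1]), int(center[2]))
        pair = principal_curvatures(img, at)
        assert pair.defined
        assert pair.k1 >= pair.k2
        assert pair.k1 == pytest.approx(1.0 / r, rel=0.30)
        assert pair.k2 == pytest.approx(1.0 / r, rel=0.30)

    def test_flat_interface_has_zero_curvature(self):
        img = np.zeros((24, 24, 24))
        img[12:] = 1.0
        img = ndimage.gaussian_filter(img, 1.5)
        grid = VolumeGrid(img, spacing=(1, 1, 1))
        pair = principal_curvatures(grid, (12, 12, 12))
        assert pair.defined
        assert abs(pair.k1) < 0.05 and abs(pair.k2) < 0.05

    def test_constant_region_is_undefined(self):
        grid = VolumeGrid(np.zeros((16, 16, 16)), spacing=(1, 1, 1))
        assert not principal_curvatures(grid, (8, 8, 8)).defined

    def test_voxel_outside_image_rejected(self):
        grid = VolumeGrid(np.zeros((4, 4, 4)), spacing=(1, 1, 1))
        with pytest.raises(ValueError):
            principal_curvatures(grid, (9, 0, 0))


class TestShapeIndexCurvedness:
    def test_ball_shell_is_cap_like(self):
        r = 8.0
        mask, img = _blurred_ball(r, 36)
        lesion = label_components(mask)[0]
        from wmhshape.shape_features import _boundary_voxels

        shell = LesionVoxelSet(1, _boundary_voxels(lesion))
        si, curv = shape_index_curvedness(shell, image=img)
        assert abs(si) == pytest.approx(1.0, abs=0.15)
        assert curv == pytest.approx(math.sqrt(2.0) / r, rel=0.30)

    def test_perfect_saddle_has_zero_shape_index(self):
        assert shape_index_from_curvatures(1.0, -1.0) == pytest.approx(0.0, abs=1e-12)

    def test_umbilic_limit_and_flat_case(self):
        assert shape_index_from_curvatures(0.5, 0.5) == 1.0
        assert shape_index_from_curvatures(-0.5, -0.5) == -1.0
        assert shape_index_from_curvatures(0.0, 0.0) == 0.0

    def test_intensity_scaling_invariance_of_shape_index(self):
        r = 8.0
        mask, img = _blurred_ball(r, 36)
        lesion = label_components(mask)[0]
        si1, _ = shape_index_curvedness(lesion, image=img)
        scaled = VolumeGrid(np.asarray(img.data) * 37.0, spacing=img.spacing)
        si2, _ = shape_index_curvedness(lesion, image=scaled)
        assert si2 == pytest.approx(si1, abs=1e-9)

    def test_default_mask_image_gives_bounded_values(self, sphere10):
        _, lesion, _ = sphere10
        si, curv = shape_index_curvedness(lesion)
        assert -1.0 <= si <= 1.0
        assert curv >= 0.0

    def test_no_defined_voxels_flags_nan(self):
        # single voxel deep inside a large constant block
        vox = np.array([[8, 8, 8]])
        img = VolumeGrid(np.ones((17, 17, 17)), spacing=(1, 1, 1))
        si, curv = shape_index_curvedness(LesionVoxelSet(1, vox), image=img)
        assert math.isnan(si) and math.isnan(curv)


class TestComputeShapeFeatures:
    def test_full_feature_set_on_ellipsoid(self, ellipsoid_21_5_5):
        grid, lesion, mesh = ellipsoid_21_5_5
        fs = compute_shape_features(lesion, mesh, icv_ml=1500.0)
        assert fs.eccentricity == pytest.approx(4.2, abs=0.3)
        assert fs.surface_area_icv == pytest.approx(fs.surface_area_mm2 / 1500.0)
        assert fs.max_diameter_mm == pytest.approx(42.0, rel=0.05)
        assert fs.bbox_dims_mm[0] == pytest.approx(42.0, abs=2.5)
        assert 0 < fs.compactness1 <= ISOPERIMETRIC_BOUND + 1e-6
        assert 0 < fs.compactness2 <= 1 and 0 < fs.compactness3 <= 1
        assert -1 <= fs.shape_index <= 1
        assert fs.curvedness >= 0
        # max diameter bounds relative to the bounding box
        bb = np.asarray(fs.bbox_dims_mm)
        assert fs.max_diameter_mm >= bb.max() / math.sqrt(3.0)
        assert fs.max_diameter_mm <= np.linalg.norm(bb) + 1e-9

    def test_invalid_icv_rejected(self, sphere10):
        _, lesion, mesh = sphere10
        with pytest.raises(ValueError):
            compute_shape_features(lesion, mesh, icv_ml=0.0)
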