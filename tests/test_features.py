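import numpy as np
import pytest
from scipy.interpolate import BSpline

import crownclust as cc
from crownclust.errors import DegenerateTreeError, ValidationError
from crownclust.features import (
    _bspline_design,
    extract_features,
    fit_profile_spline,
    jaccard,
    pca_feature,
    slice_profiles,
    symmetrize,
    symmetry_feature,
    voxelize,
)


def _random_rotation(rng):
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


class TestPcaFeature:
    def test_vertical_segment_with_std_two(self):
        z = np.array([-2.0, 2.0] * 50)
        pts = np.column_stack([np.zeros(100), np.zeros(100), z])
        f1 = pca_feature(cc.TreePointCloud("seg", pts))
        np.testing.assert_allclose(f1, [2.0, 2.0, 0.0], atol=1e-12)

    def test_isotropic_gaussian_is_near_zero(self, rng):
        pts = rng.normal(0.0, 1.0, size=(100_000, 3))
        f1 = pca_feature(cc.TreePointCloud("iso", pts))
        assert np.all(np.abs(f1) < 0.05)

    def test_anisotropic_gaussian_matches_bruteforce_pca(self, rng):
        pts = rng.normal(0.0, 1.0, size=(100_000, 3)) * np.array([3.0, 2.0, 1.0])
        tree = cc.TreePointCloud("aniso", pts)
        f1 = pca_feature(tree)
        # independent oracle: eigen-decomposition of the covariance matrix
        centred = pts - pts.mean(axis=0)
        eigvals = np.sort(np.linalg.eigvalsh(centred.T @ centred / len(pts)))[::-1]
        d = np.sqrt(eigvals)
        np.testing.assert_allclose(
            f1, [d[0] - d[1], d[0] - d[2], d[1] - d[2]], atol=1e-9)
        np.testing.assert_allclose(f1, [1.0, 2.0, 1.0], atol=0.05)

    def test_rigid_motion_invariance(self, rng, sample_trees):
        tree = sample_trees[0]
        base = pca_feature(tree)
        for _ in range(20):
            rot = _random_rotation(rng)
            shift = rng.uniform(-100, 100, 3)
            moved = cc.TreePointCloud(tree.tree_id, tree.points @ rot.T + shift)
            np.testing.assert_allclose(pca_feature(moved), base, atol=1e-9)

    def test_single_point_rejected(self):
        with pytest.raises(DegenerateTreeError):
            pca_feature(cc.TreePointCloud("p", np.zeros((1, 3))))


class TestVoxelize:
    def test_eight_points_in_eight_voxels(self):
        centres = np.array([[i + 0.5, j + 0.5, k + 0.5]
                            for i in range(2) for j in range(2) for k in range(2)])
        grid = voxelize(cc.TreePointCloud("8", centres), delta=1.0)
        assert np.count_nonzero(grid.counts) == 8
        assert grid.counts.max() == 1

    def test_half_open_boundary_convention(self):
        # two points; the second sits exactly on the first's upper z-boundary
        pts = np.array([[0.1, 0.1, 0.0], [0.1, 0.1, 1.0]])
        grid = voxelize(cc.TreePointCloud("b", pts), delta=1.0)
        occupied_z = np.nonzero(grid.counts.sum(axis=(0, 1)))[0]
        assert len(occupied_z) == 2  # boundary point went to the upper voxel

    def test_point_count_conservation(self, sample_trees):
        for tree in sample_trees:
            grid = voxelize(tree, 0.5)
            assert grid.counts.sum() == tree.n_points

    def test_centre_of_mass_snapped_to_voxel_centre(self, sample_trees):
        grid = voxelize(sample_trees[0], 0.5)
        i, j = grid.centre_index_xy
        for axis, idx in ((0, i), (1, j)):
            centre_coord = grid.origin[axis] + (idx + 0.5) * grid.delta
            assert abs(centre_coord - grid.centre[axis]) < 1e-9


class TestSymmetrize:
    def test_axis_only_tree_is_perfectly_symmetric(self):
        z = np.linspace(0.0, 5.0, 200)
        pts = np.column_stack([np.zeros(200), np.zeros(200), z])
        tree = cc.TreePointCloud("axis", pts)
        grid = voxelize(tree, 0.5)
        sym = symmetrize(tree, grid)
        assert symmetry_feature(grid, sym) == 1.0

    def test_against_exhaustive_voxel_scan(self, rng):
        """Every S count equals a brute-force scan of the two inequalities
        over all voxels and points."""
        pts = rng.uniform(0, 4, size=(60, 3))
        tree = cc.TreePointCloud("brute", pts)
        grid = voxelize(tree, 0.5)
        sym = symmetrize(tree, grid)
        delta = grid.delta
        c = grid.centre
        K = (sym.dims[0] - 1) // 2
        brute = np.zeros(sym.dims, dtype=int)
        for i in range(sym.dims[0]):
            for j in range(sym.dims[1]):
                sx = c[0] + (i - K) * delta
                sy = c[1] + (j - K) * delta
                rho = np.hypot(sx - c[0], sy - c[1])
                for k in range(sym.dims[2]):
                    sz = sym.origin[2] + (k + 0.5) * delta
                    for p in pts:
                        r_l = np.hypot(p[0] - c[0], p[1] - c[1])
                        # radial condition strict; z band half-open (the
                        # lowest point always sits exactly on the grid edge)
                        if (abs(r_l - rho) < delta
                                and sz - 0.5 * delta <= p[2] < sz + 0.5 * delta):
                            brute[i, j, k] += 1
        np.testing.assert_array_equal(sym.counts, brute)

    def test_single_offaxis_point_forms_ring(self):
        # anchor the centre of mass with a tight on-axis cluster, one point out
        delta = 0.5
        n_axis = 200
        pts = np.vstack([
            np.column_stack([np.zeros(n_axis), np.zeros(n_axis),
                             np.full(n_axis, 0.25)]),
            [[2 * delta, 0.0, 0.25 + delta]],
        ])
        tree = cc.TreePointCloud("ring", pts)
        grid = voxelize(tree, delta)
        sym = symmetrize(tree, grid)
        top_layer = int(np.floor((0.25 + delta - grid.origin[2]) / delta))
        ring = sym.counts[:, :, top_layer]
        K = (sym.dims[0] - 1) // 2
        offs = (np.arange(sym.dims[0]) - K) * delta
        rho = np.hypot(offs[:, None], offs[None, :])
        r_l = np.hypot(pts[-1, 0] - grid.centre[0], pts[-1, 1] - grid.centre[1])
        np.testing.assert_array_equal(ring, (np.abs(rho - r_l) < delta).astype(int))

    def test_binarised_v_subset_of_s(self, sample_trees):
        for tree in sample_trees:
            grid = voxelize(tree, 0.5)
            sym = symmetrize(tree, grid)
            assert grid.occupied() <= sym.occupied()


class TestJaccard:
    @pytest.mark.parametrize("a, b, expected", [
        ({1, 2, 3}, {1, 2, 3}, 1.0),
        ({1, 2}, {3, 4}, 0.0),
        ({"a", "b", "c"}, {"b", "c", "d"}, 0.5),
        (set(), set(), 1.0),
    ])
    def test_known_values(self, a, b, expected):
        assert jaccard(a, b) == expected


class TestSymmetryFeature:
    def test_equals_ratio_form_on_generated_trees(self, sample_trees):
        for tree in sample_trees:
            grid = voxelize(tree, 0.5)
            sym = symmetrize(tree, grid)
            f2 = symmetry_feature(grid, sym)
            ratio = len(grid.occupied()) / len(sym.occupied())
            assert f2 == pytest.approx(ratio, abs=1e-12)
            assert 0.0 < f2 <= 1.0

    def test_single_offaxis_point_inverse_ring_size(self):
        delta = 0.5
        n_axis = 200
        pts = np.vstack([
            np.column_stack([np.zeros(n_axis), np.zeros(n_axis),
                             np.full(n_axis, 0.25)]),
            [[2 * delta, 0.0, 0.25 + delta]],
        ])
        tree = cc.TreePointCloud("ring", pts)
        grid = voxelize(tree, delta)
        sym = symmetrize(tree, grid)
        top_layer = int(np.floor((0.25 + delta - grid.origin[2]) / delta))
        ring_size = int(np.count_nonzero(sym.counts[:, :, top_layer]))
        # V has 2 occupied voxels; S has the bottom axis region + the ring
        bottom = int(np.count_nonzero(sym.counts[:, :, 0]))
        assert symmetry_feature(grid, sym) == pytest.approx(
            2 / (bottom + ring_size))


class TestSliceProfiles:
    def test_lengths_equal_occupied_layer_count(self, sample_trees):
        tree = sample_trees[0]
        grid = voxelize(tree, 0.5)
        sym = symmetrize(tree, grid)
        prof = slice_profiles(tree, grid, sym)
        occupied = int(np.count_nonzero(grid.counts.sum(axis=(0, 1))))
        assert len(prof.jaccard_per_slice) == occupied
        assert np.all((prof.jaccard_per_slice > 0)
                      & (prof.jaccard_per_slice <= 1))

    def test_point_count_conservation_in_s_slices(self, sample_trees):
        for tree in sample_trees:
            grid = voxelize(tree, 0.5)
            sym = symmetrize(tree, grid)
            prof = slice_profiles(tree, grid, sym)
            assert prof.points_per_slice.sum() == sym.counts.sum()

    def test_axis_only_tree_profiles(self):
        z = np.linspace(0.0, 5.0, 500)
        pts = np.column_stack([np.zeros(500), np.zeros(500), z])
        tree = cc.TreePointCloud("axis", pts)
        grid = voxelize(tree, 0.5)
        sym = symmetrize(tree, grid)
        prof = slice_profiles(tree, grid, sym)
        np.testing.assert_array_equal(prof.jaccard_per_slice, 1.0)
        assert np.all(prof.max_radius_per_slice < 0.5 / np.sqrt(2))


class TestSplineFit:
    def test_profile_in_basis_span_has_zero_residual(self, rng):
        x = (np.arange(40) + 0.5) / 40
        design = _bspline_design(x, 6)
        true_coef = rng.normal(size=6)
        y = design @ true_coef
        coef, res = fit_profile_spline(y, 6)
        assert res <= 1e-8
        np.testing.assert_allclose(coef, true_coef, atol=1e-8)

    def test_constant_profile_gives_constant_coefficients(self):
        coef, res = fit_profile_spline(np.full(25, 3.7), 6)
        np.testing.assert_allclose(coef, 3.7, atol=1e-8)  # partition of unity
        assert res < 1e-8

    def test_matches_normal_equations_oracle(self, rng):
        y = rng.normal(size=40)
        x = (np.arange(40) + 0.5) / 40
        coef, res = fit_profile_spline(y, 6)
        design = _bspline_design(x, 6)
        oracle = np.linalg.solve(design.T @ design, design.T @ y)
        np.testing.assert_allclose(coef, oracle, atol=1e-8)
        assert res == pytest.approx(np.abs(design @ coef - y).sum(), abs=1e-10)

    def test_six_basis_functions_partition_unity(self, rng):
        x = rng.uniform(0, 1, 200)
        design = _bspline_design(x, 6)
        assert design.shape == (200, 6)
        np.testing.assert_allclose(design.sum(axis=1), 1.0, atol=1e-12)

    def test_empty_profile_rejected(self):
        with pytest.raises(ValidationError):
            fit_profile_spline(np.array([]))


class TestExtractFeatures:
    def test_23_finite_components(self, sample_trees):
        fv = extract_features(sample_trees[0])
        arr = fv.as_array()
        assert arr.shape == (23,)
        assert np.all(np.isfinite(arr))

    def test_translation_invariance(self, sample_trees):
        tree = sample_trees[1]
        moved = tree.translated((100.0, -50.0, 7.0))
        a = extract_features(tree).as_array()
        b = extract_features(moved).as_array()
        np.testing.assert_allclose(a, b, atol=1e-6)

    def test_vertical_rotation_quarter_turn(self, sample_trees):
        tree = sample_trees[2]
        rot = tree.rotated_z(np.pi / 2)
        a = extract_features(tree)
        b = extract_features(rot)
        np.testing.assert_allclose(a.f1, b.f1, atol=1e-9)
        # voxel features are robust, not exact, under rotation
        for name in ("f2", "f3", "f4", "f5"):
            va = np.atleast_1d(a.component(name))
            vb = np.atleast_1d(b.component(name))
            assert np.linalg.norm(va - vb) <= 0.05 * np.linalg.norm(va) + 1e-9

    def test_duplicating_points_scales_only_f4(self, sample_trees):
        tree = sample_trees[0]
        doubled = cc.TreePointCloud(
            tree.tree_id, np.vstack([tree.points, tree.points]))
        a = extract_features(tree)
        b = extract_features(doubled)
        np.testing.assert_allclose(b.f2, a.f2, atol=1e-12)
        np.testing.assert_allclose(b.f3, a.f3, atol=1e-9)
        np.testing.assert_allclose(b.f4, 2.0 * a.f4, atol=1e-6)
        np.testing.assert_allclose(b.f5, a.f5, atol=1e-9)
        np.testing.assert_allclose(b.f6, a.f6, atol=1e-9)

    def test_too_few_points_rejected(self):
        with pytest.raises(DegenerateTreeError, match="points"):
            extract_features(cc.TreePointCloud("tiny", np.random.rand(5, 3)))

    def test_flat_tree_rejected(self):
        pts = np.random.default_rng(0).uniform(0, 3, (50, 3))
        pts[:, 2] = 0.1
        with pytest.raises(DegenerateTreeError, match="slices"):
            extract_features(cc.TreePointCloud("flat", pts))
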