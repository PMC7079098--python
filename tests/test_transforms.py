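import numpy as np
import pytest
from scipy import ndimage

from propnet.errors import LatticeError, MaskTypeError, RegionError, ShapeError
from propnet.transforms import (
    BSplineTransform,
    CompositeTransform,
    DisplacementField,
    RigidTransform,
    ScalingTransform,
    _grid_points,
    compose_fields,
    folding_fraction,
    jacobian_determinant,
    sample_augmentation_transform,
    sample_bspline,
    sample_learned_transform,
    to_dense_field,
    warp_image,
    warp_mask,
)
from propnet.volume import Volume3D


GRID = (12, 12, 12)


def random_image(shape=GRID, seed=0):
    # smooth so spline interpolation error terms stay small
    rng = np.random.default_rng(seed)
    return Volume3D(ndimage.gaussian_filter(rng.random(shape), 1.5))


def random_mask(shape=GRID, seed=0):
    rng = np.random.default_rng(seed)
    return Volume3D((rng.random(shape) > 0.5).astype(np.uint8), is_mask=True)


class TestRigid:
    def test_identity(self):
        t = RigidTransform((0, 0, 0), (0, 0, 0), GRID)
        pts = _grid_points(GRID)
        np.testing.assert_allclose(t.map(pts), pts)

    def test_pure_translation(self):
        t = RigidTransform((0, 0, 0), (1.0, -2.0, 0.5), GRID)
        pts = _grid_points(GRID)
        np.testing.assert_allclose(t.map(pts) - pts, np.broadcast_to(
            np.array([1.0, -2.0, 0.5]).reshape(3, 1, 1, 1), pts.shape))

    def test_rotation_preserves_center_and_distance(self):
        t = RigidTransform((0.3, -0.2, 0.1), (0, 0, 0), GRID)
        c = (np.array(GRID, float) - 1) / 2
        np.testing.assert_allclose(t.map(c.reshape(3, 1)).ravel(), c)
        p = np.array([7.0, 3.0, 9.0]).reshape(3, 1)
        assert np.linalg.norm(t.map(p).ravel() - c) == pytest.approx(
            np.linalg.norm(p.ravel() - c))


class TestBSpline:
    def test_constant_coefficients_give_constant_displacement(self):
        coeffs = np.tile(np.array([0.5, -1.0, 2.0]), (3, 3, 3, 1))
        t = BSplineTransform(coeffs, GRID)
        pts = _grid_points(GRID)
        u = t.displacement(pts)
        np.testing.assert_allclose(u[0], 0.5, atol=1e-12)
        np.testing.assert_allclose(u[1], -1.0, atol=1e-12)
        np.testing.assert_allclose(u[2], 2.0, atol=1e-12)

    def test_matches_scipy_spline_reference(self):
        """The evaluation equals cubic-spline interpolation of the (padded)
        coefficient lattice without prefiltering."""
        rng = np.random.default_rng(3)
        coeffs = rng.normal(size=(4, 5, 6, 3))
        t = BSplineTransform(coeffs, GRID)
        pts = rng.uniform(0, 11, size=(3, 200))
        u = t.displacement(pts)
        lat = t._lattice_coords(pts) + BSplineTransform._PAD
        for comp in range(3):
            ref = ndimage.map_coordinates(
                t._padded[..., comp], lat, order=3, prefilter=False,
                mode="nearest")
            np.testing.assert_allclose(u[comp], ref, atol=1e-10)

    def test_smoothness_partition_of_unity(self):
        # all-ones coefficients -> displacement exactly 1 everywhere
        t = BSplineTransform(np.ones((2, 2, 2, 3)), GRID)
        u = t.displacement(_grid_points(GRID))
        np.testing.assert_allclose(u, 1.0, atol=1e-12)

    def test_lattice_validation(self):
        with pytest.raises(LatticeError):
            BSplineTransform(np.zeros((1, 2, 2, 3)), GRID)
        with pytest.raises(LatticeError):
            sample_bspline(2, -1.0, GRID, np.random.default_rng(0))


class TestComposition:
    def test_composite_order(self):
        """T = c1 ∘ c2 applies c2 to the points first."""
        c1 = ScalingTransform((2.0, 2.0, 2.0), GRID)
        c2 = RigidTransform((0, 0, 0), (1.0, 0, 0), GRID)
        t = CompositeTransform([c1, c2])
        p = np.zeros((3, 1))
        np.testing.assert_allclose(t.map(p), c1.map(c2.map(p)))

    def test_dense_field_of_translation(self):
        t = RigidTransform((0, 0, 0), (2.0, 0.0, -1.0), GRID)
        f = to_dense_field(t, GRID)
        assert f.u[0].max() == f.u[0].min() == 2.0
        assert f.u[2].max() == -1.0

    def test_compose_fields_translations_exact(self):
        ta = to_dense_field(RigidTransform((0, 0, 0), (1.0, 2.0, 0.0), GRID), GRID)
        tb = to_dense_field(RigidTransform((0, 0, 0), (0.5, -1.0, 1.0), GRID), GRID)
        comp = compose_fields(ta, tb)
        np.testing.assert_allclose(comp.u[0], 1.5)
        np.testing.assert_allclose(comp.u[1], 1.0)
        np.testing.assert_allclose(comp.u[2], 1.0)

    def test_composed_warp_equals_sequential_translations(self):
        img = random_image()
        t1 = RigidTransform((0, 0, 0), (2.0, 0.0, 0.0), GRID)
        t2 = RigidTransform((0, 0, 0), (0.0, 1.0, 0.0), GRID)
        f1, f2 = to_dense_field(t1, GRID), to_dense_field(t2, GRID)
        once = warp_image(img, compose_fields(f1, f2), order=1)
        seq = warp_image(warp_image(img, f1, order=1), f2, order=1)
        # integer translations: interior voxels agree exactly; borders differ
        # only where the sequential warp loses data to the fill value
        interior = seq.data[3:-3, 3:-3, 3:-3]
        np.testing.assert_allclose(once.data[3:-3, 3:-3, 3:-3], interior,
                                   atol=1e-12)

    def test_composed_warp_close_for_smooth_fields(self):
        img = random_image(seed=4)
        rng = np.random.default_rng(5)
        t1 = sample_bspline(2, 0.8, GRID, rng)
        t2 = sample_bspline(2, 0.8, GRID, rng)
        f1, f2 = to_dense_field(t1, GRID), to_dense_field(t2, GRID)
        once = warp_image(img, compose_fields(f1, f2), order=1)
        seq = warp_image(warp_image(img, f1, order=1), f2, order=1)
        assert np.abs(once.data[2:-2, 2:-2, 2:-2]
                      - seq.data[2:-2, 2:-2, 2:-2]).max() < 1e-2


class TestWarping:
    def test_warp_brute_force_nearest(self):
        m = random_mask((8, 8, 8), seed=1)
        rng = np.random.default_rng(2)
        f = DisplacementField(rng.uniform(-2, 2, size=(3, 8, 8, 8)))
        out = warp_mask(m, f)
        for idx in np.ndindex(8, 8, 8):
            src = [idx[a] + f.u[a][idx] for a in range(3)]
            # nearest neighbor: round half up, inside iff coord in [-0.5, n-0.5)
            nn = [int(np.floor(s + 0.5)) for s in src]
            expect = 0
            if all(-0.5 <= src[a] and src[a] < 7.5 for a in range(3)):
                expect = m.data[nn[0], nn[1], nn[2]]
            assert out.data[idx] == expect

    def test_warp_brute_force_linear(self):
        img = random_image((6, 6, 6), seed=3)
        rng = np.random.default_rng(4)
        f = DisplacementField(rng.uniform(-1, 1, size=(3, 6, 6, 6)))
        out = warp_image(img, f, order=1)
        for idx in np.ndindex(6, 6, 6):
            src = np.array([idx[a] + f.u[a][idx] for a in range(3)])
            lo = np.floor(src).astype(int)
            frac = src - lo
            acc = 0.0
            for corner in np.ndindex(2, 2, 2):
                pos = lo + np.array(corner)
                w = np.prod([frac[a] if corner[a] else 1 - frac[a]
                             for a in range(3)])
                val = 0.0
                if all(0 <= pos[a] < 6 for a in range(3)):
                    val = img.data[tuple(pos)]
                acc += w * val
            assert out.data[idx] == pytest.approx(acc, abs=1e-10)

    def test_mask_refuses_spline(self):
        with pytest.raises(MaskTypeError):
            warp_image(random_mask(), RigidTransform((0, 0, 0), (1, 0, 0), GRID))
        with pytest.raises(MaskTypeError):
            warp_mask(random_image(), RigidTransform((0, 0, 0), (1, 0, 0), GRID))

    def test_zero_field_identity(self):
        m = random_mask(seed=7)
        f = DisplacementField(np.zeros((3,) + GRID))
        assert (warp_mask(m, f).data == m.data).all()


class TestSampledTransforms:
    def test_learned_field_respects_bound(self, subtests=None):
        rng = np.random.default_rng(0)
        worst = 0.0
        for _ in range(50):
            t = sample_learned_transform(GRID, rng)
            f = to_dense_field(t, GRID)
            worst = max(worst, np.abs(f.u).max())
        assert worst <= 12.0

    def test_amplitude_scale(self):
        rng1, rng2 = np.random.default_rng(9), np.random.default_rng(9)
        full = sample_learned_transform(GRID, rng1, amplitude_scale=1.0)
        quarter = sample_learned_transform(GRID, rng2, amplitude_scale=0.25)
        for a, b in zip(full.components, quarter.components):
            np.testing.assert_allclose(b.coefficients, 0.25 * a.coefficients)

    def test_augmentation_structure(self):
        t = sample_augmentation_transform(GRID, np.random.default_rng(1))
        assert isinstance(t.components[0], RigidTransform)
        assert isinstance(t.components[1], BSplineTransform)
        assert np.abs(t.components[0].angles).max() <= 0.1
        assert np.abs(t.components[0].translation).max() <= 12.8


class TestJacobian:
    def test_zero_field(self):
        f = DisplacementField(np.zeros((3,) + GRID))
        np.testing.assert_allclose(jacobian_determinant(f), 1.0)
        assert folding_fraction(f) == 0.0

    def test_linear_scaling_field(self):
        pts = _grid_points(GRID)
        u = np.zeros((3,) + GRID)
        u[0] = 0.1 * pts[0]
        det = jacobian_determinant(DisplacementField(u))
        np.testing.assert_allclose(det, 1.1, atol=1e-9)

    def test_reflection_full_folding(self):
        pts = _grid_points(GRID)
        u = np.zeros((3,) + GRID)
        u[0] = (GRID[0] - 1) - 2.0 * pts[0]  # x -> (D-1) - x
        f = DisplacementField(u)
        assert folding_fraction(f) == 100.0

    def test_region_folding(self):
        pts = _grid_points(GRID)
        u = np.zeros((3,) + GRID)
        u[0] = (GRID[0] - 1) - 2.0 * pts[0]
        region = np.zeros(GRID, bool)
        region[2:5, 2:5, 2:5] = True
        assert folding_fraction(DisplacementField(u), region) == 100.0
        with pytest.raises(RegionError):
            folding_fraction(DisplacementField(u), np.zeros(GRID, bool))

    def test_small_grid_rejected(self):
        with pytest.raises(ShapeError):
            jacobian_determinant(DisplacementField(np.zeros((3, 2, 4, 4))))
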