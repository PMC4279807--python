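import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import atlaslink as al
from atlaslink.transforms import compose, compose_chain, identity_field


def naive_bspline_displacement(t: al.BSplineTransform, pts: np.ndarray) -> np.ndarray:
    """Independent oracle: explicit cubic basis summation, point by point."""

    def basis(a, x):
        return (
            (1 - x) ** 3 / 6,
            (3 * x**3 - 6 * x**2 + 4) / 6,
            (-3 * x**3 + 3 * x**2 + 3 * x + 1) / 6,
            x**3 / 6,
        )[a]

    out = np.zeros_like(pts)
    for n, p in enumerate(pts):
        u = (p - np.array(t.control_origin)) / np.array(t.control_spacing)
        cell = np.floor(u).astype(int)
        frac = u - cell
        acc = np.zeros(3)
        for a in range(4):
            for b in range(4):
                for c in range(4):
                    w = basis(a, frac[0]) * basis(b, frac[1]) * basis(c, frac[2])
                    acc += w * t.coefficients[cell[0] + a - 1, cell[1] + b - 1, cell[2] + c - 1]
        out[n] = acc
    return out


@pytest.fixture
def domain():
    return al.ImageGrid((16, 16, 12), (2.0, 2.0, 3.0))


def random_ffd_on(domain, spacing, sd, seed):
    t = al.BSplineTransform.covering(domain, spacing)
    t.coefficients[:] = np.random.default_rng(seed).normal(0, sd, t.coefficients.shape)
    return t


def in_domain_points(domain, n, seed):
    rng = np.random.default_rng(seed)
    lo = np.asarray(domain.origin)
    return rng.uniform(lo, lo + np.asarray(domain.extent), (n, 3))


class TestBSplineEvaluate:
    def test_zero_coefficients_are_identity(self, domain):
        t = al.BSplineTransform.covering(domain, 8.0)
        pts = in_domain_points(domain, 100, 0)
        np.testing.assert_array_equal(t.evaluate(pts), pts)

    def test_constant_coefficients_translate(self, domain):
        """Partition of unity: a constant lattice is an exact translation."""
        t = al.BSplineTransform.covering(domain, 8.0)
        t.coefficients[:] = [1.5, -2.0, 0.25]
        pts = in_domain_points(domain, 10_000, 1)
        np.testing.assert_allclose(
            t.evaluate(pts) - pts, np.broadcast_to([1.5, -2.0, 0.25], (10_000, 3)),
            atol=1e-12,
        )

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(
        st.floats(0.0, 30.0), st.floats(0.0, 30.0), st.floats(0.0, 33.0)
    )
    def test_partition_of_unity_at_arbitrary_points(self, x, y, z):
        """A constant coefficient lattice translates every in-domain point by
        exactly that constant — the basis weights sum to one everywhere."""
        domain = al.ImageGrid((16, 16, 12), (2.0, 2.0, 3.0))
        t = al.BSplineTransform.covering(domain, 8.0)
        t.coefficients[:] = [0.7, -1.3, 2.1]
        np.testing.assert_allclose(
            t.displacement(np.array([[x, y, z]]))[0], [0.7, -1.3, 2.1], atol=1e-12
        )

    def test_matches_basis_expansion_oracle(self, domain):
        t = random_ffd_on(domain, 8.0, 2.0, 2)
        pts = in_domain_points(domain, 200, 3)
        expected = naive_bspline_displacement(t, pts)
        np.testing.assert_allclose(t.displacement(pts), expected, atol=1e-10)

    def test_out_of_support_is_zero_displacement(self, domain):
        t = random_ffd_on(domain, 8.0, 2.0, 4)
        far = np.array([[1e4, 1e4, 1e4], [-1e4, 0.0, 0.0]])
        np.testing.assert_array_equal(t.displacement(far), np.zeros((2, 3)))


class TestDisplacementField:
    def test_values_at_voxel_centers_are_exact(self, domain):
        rng = np.random.default_rng(5)
        field = al.DisplacementField(domain, rng.normal(0, 2, (*domain.shape, 3)))
        pts = domain.voxel_centers().reshape(-1, 3)
        np.testing.assert_allclose(
            field.displacement(pts), field.vectors.reshape(-1, 3), atol=1e-12
        )

    def test_midpoint_is_average_of_neighbours(self, domain):
        rng = np.random.default_rng(6)
        field = al.DisplacementField(domain, rng.normal(0, 2, (*domain.shape, 3)))
        p0 = domain.world_from_index(np.array([2, 3, 4]))
        p1 = domain.world_from_index(np.array([3, 3, 4]))
        mid = (p0 + p1) / 2
        expected = (field.vectors[2, 3, 4] + field.vectors[3, 3, 4]) / 2
        np.testing.assert_allclose(field.displacement(mid), expected, atol=1e-12)

    def test_outside_clamps_to_border_vector(self, domain):
        rng = np.random.default_rng(7)
        field = al.DisplacementField(domain, rng.normal(0, 2, (*domain.shape, 3)))
        outside = np.array([domain.origin]) - 100.0
        np.testing.assert_allclose(
            field.displacement(outside)[0], field.vectors[0, 0, 0]
        )


class TestCompose:
    def test_identity_composed_with_transform(self, domain):
        t = random_ffd_on(domain, 8.0, 1.5, 8)
        field = compose(identity_field(domain), t, domain)
        pts = domain.voxel_centers().reshape(-1, 3)
        np.testing.assert_allclose(
            field.vectors.reshape(-1, 3), t.displacement(pts), atol=1e-12
        )

    def test_translations_add(self, domain):
        t1 = al.BSplineTransform.covering(domain, 8.0)
        t1.coefficients[:] = [1.0, 0.0, 2.0]
        t2 = al.BSplineTransform.covering(domain, 8.0)
        t2.coefficients[:] = [0.5, -1.0, 0.0]
        field = compose(t1, t2, domain)
        np.testing.assert_allclose(
            field.vectors, np.broadcast_to([1.5, -1.0, 2.0], field.vectors.shape),
            atol=1e-10,
        )

    def test_against_exact_functional_composition(self, domain):
        """Interpolated composition tracks exact B-spline-of-B-spline maps."""
        outer = random_ffd_on(domain, 12.0, 1.0, 9)
        inner = random_ffd_on(domain, 12.0, 1.0, 10)
        field = compose(outer, inner, domain)
        pts = in_domain_points(domain, 1000, 11)
        exact = outer.evaluate(inner.evaluate(pts))
        approx = field.evaluate(pts)
        # tolerance scales with field curvature x voxel size; these are
        # gentle 1 mm-sd fields on a 2-3 mm grid
        assert np.abs(approx - exact).max() < 0.2

    def test_chain_of_identities(self, domain):
        chain = al.TransformChain([identity_field(domain)] * 3)
        field = compose_chain(chain, domain)
        np.testing.assert_allclose(field.vectors, 0.0, atol=1e-12)

    def test_chain_of_translations_sums(self, domain):
        ts = []
        for shift in ([1, 0, 0], [0, 2, 0], [0, 0, -1.5]):
            t = al.BSplineTransform.covering(domain, 8.0)
            t.coefficients[:] = shift
            ts.append(t)
        field = compose_chain(al.TransformChain(ts), domain)
        np.testing.assert_allclose(
            field.vectors, np.broadcast_to([1.0, 2.0, -1.5], field.vectors.shape),
            atol=1e-9,
        )

    def test_associativity_within_interpolation_tolerance(self, domain):
        a = random_ffd_on(domain, 12.0, 0.8, 12)
        b = random_ffd_on(domain, 12.0, 0.8, 13)
        c = random_ffd_on(domain, 12.0, 0.8, 14)
        left = compose(compose(a, b, domain), c, domain)
        right = compose(a, compose(b, c, domain), domain)
        # compare away from the border where clamping differs
        diff = np.abs(left.vectors - right.vectors)[2:-2, 2:-2, 2:-2]
        assert diff.max() < 0.2

    def test_empty_chain_rejected(self, domain):
        with pytest.raises(ValueError):
            al.TransformChain([])
        with pytest.raises(ValueError):
            compose_chain([], domain)

    def test_single_transform_chain_resamples(self, domain):
        t = random_ffd_on(domain, 8.0, 1.0, 15)
        field = compose_chain([t], domain)
        pts = domain.voxel_centers().reshape(-1, 3)
        np.testing.assert_allclose(
            field.vectors.reshape(-1, 3), t.displacement(pts), atol=1e-12
        )


def trilinear_oracle(values, grid, pts):
    """Independent per-point trilinear interpolation with edge clamping."""
    out = np.empty(len(pts))
    idx = grid.index_from_world(pts)
    idx = np.clip(idx, 0, np.asarray(grid.shape) - 1)
    for n, u in enumerate(idx):
        base = np.floor(u).astype(int)
        base = np.minimum(base, np.asarray(grid.shape) - 2)
        base = np.maximum(base, 0)
        f = u - base
        acc = 0.0
        for da in (0, 1):
            for db in (0, 1):
                for dc in (0, 1):
                    w = (
                        (f[0] if da else 1 - f[0])
                        * (f[1] if db else 1 - f[1])
                        * (f[2] if dc else 1 - f[2])
                    )
                    acc += w * values[base[0] + da, base[1] + db, base[2] + dc]
        out[n] = acc
    return out


class TestWarp:
    def test_identity_reproduces_image(self, domain):
        rng = np.random.default_rng(16)
        img = al.ScalarImage(domain, rng.normal(0, 50, domain.shape))
        out = al.warp_image(img, identity_field(domain))
        np.testing.assert_array_equal(out.values, img.values)

    def test_one_voxel_translation_shifts_values(self, domain):
        rng = np.random.default_rng(17)
        img = al.ScalarImage(domain, rng.normal(0, 50, domain.shape))
        t = al.BSplineTransform.covering(domain, 8.0)
        t.coefficients[:] = [domain.spacing[0], 0, 0]  # +1 voxel along x
        out = al.warp_image(img, t)
        np.testing.assert_allclose(out.values[:-1], img.values[1:], atol=1e-9)

    def test_linear_warp_matches_scatter_oracle(self, domain):
        rng = np.random.default_rng(18)
        img = al.ScalarImage(domain, rng.normal(0, 50, domain.shape))
        t = random_ffd_on(domain, 12.0, 1.5, 19)
        out = al.warp_image(img, t, interpolation="linear")
        pts = domain.voxel_centers().reshape(-1, 3)
        mapped = t.evaluate(pts)
        expected = trilinear_oracle(img.values, domain, mapped)
        np.testing.assert_allclose(out.values.reshape(-1), expected, atol=1e-10)

    def test_mask_identity_and_translation(self, domain):
        inside = np.zeros(domain.shape, bool)
        inside[4:8, 5:9, 3:6] = True
        mask = al.BinaryMask(domain, inside)
        same = al.warp_mask(mask, identity_field(domain))
        assert np.array_equal(same.inside, inside)
        t = al.BSplineTransform.covering(domain, 8.0)
        t.coefficients[:] = [2.0, 0.0, 0.0]  # one voxel
        shifted = al.warp_mask(mask, t)
        assert shifted.inside.sum() == inside.sum()
        assert np.array_equal(shifted.inside[3:7], inside[4:8])

    def test_warped_sphere_volume_tracks_jacobian(self):
        """The warped mask's volume matches the analytic measure of the
        pulled-back sphere, estimated on a twice-finer sampling."""
        grid = al.ImageGrid((32, 32, 32), (1.0, 1.0, 1.0))
        center = np.array([15.5, 15.5, 15.5])
        t = random_ffd_on(grid, 10.0, 1.5, 20)

        def sphere_indicator(pts):
            return np.sum((pts - center) ** 2, axis=1) <= 8.0**2

        mask = al.BinaryMask(
            grid,
            sphere_indicator(grid.voxel_centers().reshape(-1, 3)).reshape(grid.shape),
        )
        warped = al.warp_mask(mask, t)
        fine = al.ImageGrid((64, 64, 64), (0.5, 0.5, 0.5), (-0.25, -0.25, -0.25))
        fine_pts = fine.voxel_centers().reshape(-1, 3)
        fine_volume = sphere_indicator(t.evaluate(fine_pts)).sum() * fine.voxel_volume
        assert warped.volume_mm3 == pytest.approx(fine_volume, rel=0.10)

    def test_cubic_interpolation_reproduces_smooth_field(self, domain):
        xs = domain.voxel_centers()
        img = al.ScalarImage(domain, 0.1 * xs[..., 0] + 0.2 * xs[..., 1] - xs[..., 2])
        out = al.warp_image(img, identity_field(domain), interpolation="cubic_bspline")
        np.testing.assert_allclose(out.values, img.values, atol=1e-8)


def test_error_accumulation_grows_with_chain_length():
    """Composing independent noisy perturbations of identity increases the
    RMS point-mapping error with the number of links."""
    domain = al.ImageGrid((20, 20, 16), (2.0, 2.0, 3.0))
    rng = np.random.default_rng(21)
    noises = [
        al.synthetic.random_ffd(domain, 12.0, 1.5, rng) for _ in range(5)
    ]
    pts = domain.voxel_centers()[4:-4, 4:-4, 4:-4].reshape(-1, 3)
    rms = []
    for n in range(1, 6):
        field = compose_chain(al.TransformChain(noises[:n]), domain)
        err = field.evaluate(pts) - pts
        rms.append(float(np.sqrt(np.mean(np.sum(err**2, axis=1)))))
    assert all(b > a for a, b in zip(rms, rms[1:]))
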