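"""Phantom generator: gamma ground truth, composition, noise model."""

import numpy as np
import pytest

from axsize.phantom import (
    BundleSpec,
    PhantomConfigError,
    REGION_A,
    REGION_B,
    REGION_CROSSING,
    add_rician_noise,
    build_phantom,
    default_bundles,
    tortuosity_perpendicular_diffusivity,
    track_surrogate,
)
from axsize.signals import D_PARALLEL, ZeppelinSpec, cylinder_attenuation, zeppelin_signal


class TestBundleSpecs:
    def test_default_volume_weighted_mean_diameters(self):
        a, b = default_bundles()
        assert a.volume_weighted_mean_diameter == pytest.approx(2.70, rel=0.01)
        assert b.volume_weighted_mean_diameter == pytest.approx(4.00, rel=0.01)
        assert a.intra_fraction == 0.3 and b.intra_fraction == 0.6

    def test_crossing_angle_is_45_degrees(self):
        a, b = default_bundles()
        cos = np.dot(a.orientation, b.orientation)
        assert np.degrees(np.arccos(cos)) == pytest.approx(45.0, abs=1e-6)

    def test_monte_carlo_moment_matches_closed_form(self):
        # E[r^3]/E[r^2] = scale * (shape + 2), checked by brute force
        rng = np.random.default_rng(0)
        for shape, scale in [(3.2734, 0.2556), (3.5027, 0.3655)]:
            r = rng.gamma(shape, scale, 1_000_000)
            mc = np.sum(r**3) / np.sum(r**2)
            assert mc == pytest.approx(scale * (shape + 2), rel=0.005)

    def test_diameter_draws_reproduce_volume_weighted_mean(self):
        for b in default_bundles():
            d = b.diameter_draws()
            assert len(d) == b.n_diameter_draws
            assert d.mean() == pytest.approx(b.volume_weighted_mean_diameter, rel=0.005)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            BundleSpec("x", (0, 1, 0), 3.0, 0.3, 1.5)
        with pytest.raises(ValueError):
            BundleSpec("x", (0, 1, 0), -1.0, 0.3, 0.5)


class TestTortuosity:
    def test_single_fiber_fractions(self):
        assert tortuosity_perpendicular_diffusivity(0.3) == pytest.approx(0.7 * D_PARALLEL)
        assert tortuosity_perpendicular_diffusivity(0.6) == pytest.approx(0.4 * D_PARALLEL)
        assert tortuosity_perpendicular_diffusivity(0.9) == pytest.approx(0.1 * D_PARALLEL)

    def test_out_of_range_fraction(self):
        with pytest.raises(ValueError):
            tortuosity_perpendicular_diffusivity(1.2)


class TestComposition:
    def test_fraction_conservation_everywhere(self, phantom1):
        total = phantom1.intra_fractions.sum(-1) + phantom1.extra_fractions.sum(-1)
        np.testing.assert_allclose(total[phantom1.mask], 1.0, atol=1e-12)
        assert np.all(total[~phantom1.mask] == 0.0)

    def test_b0_signal_is_one_in_tissue(self, phantom1):
        b0 = phantom1.signal[phantom1.mask][:, phantom1.scheme.b0_mask]
        np.testing.assert_allclose(b0, 1.0, atol=1e-12)

    def test_crossing_voxels_carry_09_intra(self, phantom1):
        crossing = phantom1.region_labels == REGION_CROSSING
        np.testing.assert_allclose(
            phantom1.intra_fractions[crossing].sum(-1), 0.9, atol=1e-12
        )
        np.testing.assert_allclose(
            phantom1.extra_dperp[crossing], 0.1 * D_PARALLEL, atol=1e-18
        )

    def test_region_sizes_at_least_100(self, phantom1):
        for code in (REGION_A, REGION_B, REGION_CROSSING):
            assert (phantom1.region_labels == code).sum() >= 100

    def test_too_small_grid_names_the_region(self):
        with pytest.raises(PhantomConfigError, match="region"):
            build_phantom(grid=(12, 12, 1))

    def test_single_fiber_voxel_equals_mixture_of_compartments(self, phantom1):
        """Region-A voxel signal re-derived independently from the signal
        module: f * volume-weighted cylinder mixture + (1-f) * tortuosity
        zeppelin."""
        a, _ = phantom1.bundles
        mu = np.asarray(a.orientation)
        mix = cylinder_attenuation(
            a.diameter_draws() * 1e-6, mu, phantom1.scheme
        ).mean(axis=0)
        zep = zeppelin_signal(
            ZeppelinSpec(D_PARALLEL, 0.7 * D_PARALLEL, tuple(mu)), phantom1.scheme
        )
        expected = 0.3 * mix + 0.7 * zep
        vox = phantom1.region_voxels(REGION_A)[0]
        np.testing.assert_allclose(phantom1.signal[tuple(vox)], expected, atol=1e-12)

    def test_streamlines_span_the_bands(self, phantom1):
        nx, ny, nz = phantom1.shape
        vs = phantom1.voxel_size
        for sl in phantom1.streamlines["bundleA"]:
            assert sl[:, 1].min() <= vs and sl[:, 1].max() >= (ny - 1) * vs
        assert len(phantom1.streamlines["bundleA"]) == 30
        assert len(phantom1.streamlines["bundleB"]) == 30

    def test_dispersion_build_is_deterministic(self):
        kw = dict(grid=(16, 16, 1), dispersion_kappa=8.0, seed=9,
                  n_streamlines=4, min_region_voxels=1)
        p1 = build_phantom(**kw)
        p2 = build_phantom(**kw)
        np.testing.assert_array_equal(p1.signal, p2.signal)


class TestRicianNoise:
    def test_infinite_snr_is_identity(self, phantom1):
        out = add_rician_noise(phantom1.signal, np.inf, rng=0)
        np.testing.assert_array_equal(out, phantom1.signal)

    def test_zero_signal_mean_is_rayleigh(self):
        # S = 0: mean of sqrt(e1^2 + e2^2) = sigma * sqrt(pi/2)
        snr = 30.0
        sigma = 1.0 / snr
        draws = add_rician_noise(np.zeros(100_000), snr, rng=123)
        assert draws.mean() == pytest.approx(sigma * np.sqrt(np.pi / 2), rel=0.01)

    def test_seed_determinism(self, phantom1):
        a = add_rician_noise(phantom1.signal, 50, rng=5)
        b = add_rician_noise(phantom1.signal, 50, rng=5)
        np.testing.assert_array_equal(a, b)

    def test_invalid_snr(self):
        with pytest.raises(ValueError):
            add_rician_noise(np.ones(3), 0.0)


class TestSurrogateTracker:
    def test_infinite_kappa_gives_straight_trajectories(self, phantom1):
        sls = track_surrogate(phantom1, 0, np.inf, 3, seed=0)
        for sl in sls:
            d = np.diff(sl, axis=0)
            d /= np.linalg.norm(d, axis=1, keepdims=True)
            assert np.allclose(d, d[0], atol=1e-9)

    def test_finite_kappa_disperses_and_is_seeded(self, phantom1):
        a = track_surrogate(phantom1, 0, 8.0, 3, seed=4)
        b = track_surrogate(phantom1, 0, 8.0, 3, seed=4)
        assert all(np.array_equal(x, y) for x, y in zip(a, b))
        d = np.diff(a[0], axis=0)
        d /= np.linalg.norm(d, axis=1, keepdims=True)
        assert np.ptp(d, axis=0).max() > 1e-3  # direction actually varies
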