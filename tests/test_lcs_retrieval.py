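"""LCS retrieval against generative oracles.

The oracle is the warp generator (or hand-built warped stacks): fields with
known absorption, displacement and blur are synthesized, retrieved, and the
parameters compared with the generating values.
"""

import math

import numpy as np
import pytest
from scipy import ndimage

from mobi import ImagePairSet, LcsModel
from mobi.lcs_retrieval import (
    build_lcs_system,
    directional_darkfield,
    integrate_phase,
    solve_lcs,
)


def make_pairs(I_r, I_s, geometry):
    K = I_r.shape[0]
    return ImagePairSet(I_r=I_r, I_s=I_s, shifts=np.zeros((K, 2), int),
                        geometry=geometry)


def warp_stack(patterns, dx, dy):
    """Shift each pattern by the (possibly per-pixel) displacement field."""
    out = np.empty_like(patterns)
    H, W = patterns.shape[1:]
    yy, xx = np.meshgrid(np.arange(H, dtype=float), np.arange(W, dtype=float),
                         indexing="ij")
    for k, p in enumerate(patterns):
        out[k] = ndimage.map_coordinates(p, [yy - dy, xx - dx], order=3,
                                         mode="nearest")
    return out


class TestSystemAssembly:
    def test_identical_images_zero_rhs(self, geometry, smooth_pattern_stack):
        pairs = make_pairs(smooth_pattern_stack, smooth_pattern_stack, geometry)
        system = build_lcs_system(pairs)
        np.testing.assert_allclose(system.rhs, 0.0, atol=1e-4)

    def test_too_few_pairs_rejected(self, geometry, smooth_pattern_stack):
        pairs = make_pairs(smooth_pattern_stack[:3], smooth_pattern_stack[:3],
                           geometry)
        with pytest.raises(ValueError, match="four|4"):
            build_lcs_system(pairs)
        pairs6 = make_pairs(smooth_pattern_stack[:5], smooth_pattern_stack[:5],
                            geometry)
        with pytest.raises(ValueError, match="6"):
            build_lcs_system(pairs6, tensor=True)

    def test_uniform_reference_rank_deficient_and_flagged(self, geometry):
        I_r = np.full((5, 32, 32), 1000.0, np.float32)
        pairs = make_pairs(I_r, 0.9 * I_r, geometry)
        res = LcsModel(pairs).fit()
        inner = res.rank_deficient[2:-2, 2:-2]
        assert inner.all()
        assert res.n_masked > 0

    def test_pure_absorber_rhs_fraction_of_reference(
            self, geometry, smooth_pattern_stack):
        pairs = make_pairs(smooth_pattern_stack, 0.9 * smooth_pattern_stack,
                           geometry)
        system = build_lcs_system(pairs)
        np.testing.assert_allclose(system.rhs, 0.1 * smooth_pattern_stack,
                                   rtol=1e-5)
        res = solve_lcs(system)
        inner = res.I_obj[5:-5, 5:-5]
        assert np.median(inner) == pytest.approx(0.1, rel=0.02)


class TestParameterRecovery:
    def test_zero_rhs_gives_zero_maps(self, geometry, smooth_pattern_stack):
        pairs = make_pairs(smooth_pattern_stack, smooth_pattern_stack, geometry)
        res = LcsModel(pairs).fit()
        for m in (res.I_obj, res.D_x, res.D_y, res.D_f):
            np.testing.assert_allclose(m, 0.0, atol=1e-6)

    def test_constant_displacement_recovered(self, geometry):
        # smoother oracle pattern: keeps the finite-difference stencil in its
        # validity range so the bias budget is the solver's, not the stencil's
        rng = np.random.default_rng(5)
        pats = np.stack([
            1000.0 * (1.0 + 0.5 * _smooth(rng, 96, 96, 2.5)) for _ in range(8)
        ])
        dx, dy = 0.3, -0.2
        I_s = warp_stack(pats, dx, dy)
        res = LcsModel(make_pairs(pats, I_s, geometry)).fit()
        sl = (slice(8, -8), slice(8, -8))
        assert res.D_x[sl].mean() == pytest.approx(dx, rel=0.05)
        assert res.D_y[sl].mean() == pytest.approx(dy, rel=0.05)
        assert np.sqrt(np.mean((res.D_x[sl] - dx) ** 2)) < 0.05 * abs(dx) + 0.01
        assert np.sqrt(np.mean((res.D_y[sl] - dy) ** 2)) < 0.05 * abs(dy) + 0.01

    def test_displacement_linearity(self, geometry, smooth_pattern_stack):
        sl = (slice(8, -8), slice(8, -8))
        means = []
        for scale in (1.0, 2.0):
            I_s = warp_stack(smooth_pattern_stack, 0.15 * scale, 0.0)
            res = LcsModel(make_pairs(smooth_pattern_stack, I_s, geometry)).fit()
            means.append(res.D_x[sl].mean())
        assert means[1] / means[0] == pytest.approx(2.0, rel=0.05)

    def test_blur_only_yields_positive_darkfield(self, geometry,
                                                 smooth_pattern_stack):
        sigma = 0.5
        I_s = np.stack([ndimage.gaussian_filter(p, sigma)
                        for p in smooth_pattern_stack])
        res = LcsModel(make_pairs(smooth_pattern_stack, I_s, geometry)).fit()
        sl = (slice(8, -8), slice(8, -8))
        # linearized diffusion: D_f ~ sigma^2/2; displacement stays at zero
        assert np.median(res.D_f[sl]) == pytest.approx(sigma**2 / 2, rel=0.35)
        assert np.all(np.median(res.D_f[sl]) > 0)
        assert abs(res.D_x[sl].mean()) < 0.01
        assert abs(res.D_y[sl].mean()) < 0.01

    def test_blur_does_not_leak_into_displacement(self, geometry,
                                                  smooth_pattern_stack):
        # empty-field noise floor for D
        rng = np.random.default_rng(0)
        noisy = smooth_pattern_stack + rng.normal(0, 1.0,
                                                  smooth_pattern_stack.shape)
        res0 = LcsModel(make_pairs(
            smooth_pattern_stack, noisy.astype(np.float32), geometry)).fit()
        sl = (slice(8, -8), slice(8, -8))
        floor = res0.D_x[sl].std()
        I_s = np.stack([ndimage.gaussian_filter(p, 0.5)
                        for p in smooth_pattern_stack])
        res = LcsModel(make_pairs(smooth_pattern_stack, I_s, geometry)).fit()
        assert res.D_x[sl].std() < max(3 * floor, 0.01)

    def test_joint_field_recovery_under_poisson_noise(self, geometry):
        # smooth random I_obj <= 0.2, |D| <= 1 px, sigma <= 1 px at
        # 75000-count noise, K = 10: each field recovered within 10 % of its
        # dynamic range (RMS)
        rng = np.random.default_rng(7)
        K, H, W = 10, 96, 96
        pats = np.stack([
            75000.0 * (1.0 + 0.4 * _smooth(rng, H, W, 1.2))
            for _ in range(K)
        ])
        a = 0.1 * (1.0 + _smooth(rng, H, W, 6.0))            # absorption
        dx = 0.5 * _smooth(rng, H, W, 6.0)
        dy = 0.5 * _smooth(rng, H, W, 6.0)
        I_s = warp_stack(pats, dx, dy) * (1.0 - a)
        I_r = rng.poisson(pats).astype(np.float32)
        I_s = rng.poisson(np.clip(I_s, 0, None)).astype(np.float32)
        res = LcsModel(make_pairs(I_r, I_s, geometry)).fit()
        sl = (slice(6, -6), slice(6, -6))
        for est, true in ((res.I_obj, a), (res.D_x, dx), (res.D_y, dy)):
            rms = np.sqrt(np.mean((est[sl] - true[sl]) ** 2))
            assert rms <= 0.10 * np.ptp(true)

    def test_noise_scaling_inverse_sqrt_counts(self, geometry):
        rng = np.random.default_rng(11)
        K, H, W = 8, 96, 96
        base = np.stack([1.0 + 0.4 * _smooth(rng, H, W, 1.2)
                         for _ in range(K)])
        stds = []
        for counts in (75000.0, 4 * 75000.0):
            pats = counts * base
            I_r = rng.poisson(pats).astype(np.float32)
            I_s = rng.poisson(pats).astype(np.float32)
            res = LcsModel(make_pairs(I_r, I_s, geometry)).fit()
            stds.append(res.D_y[8:-8, 8:-8].std())
        assert stds[0] / stds[1] == pytest.approx(2.0, rel=0.2)


class TestPhaseIntegration:
    def test_zero_displacement_zero_phase(self, geometry):
        phi = integrate_phase(np.zeros((32, 32)), np.zeros((32, 32)), geometry)
        np.testing.assert_allclose(phi, 0.0, atol=1e-12)

    def test_angle_conversion_from_table_values(self, geometry):
        res = _dummy_results(geometry, D_y=np.ones((8, 8)))
        _, ay = res.refraction_angles()
        # 1 px * 75 um / 0.80 m = 93.75 urad
        np.testing.assert_allclose(ay, 93.75e-6, rtol=1e-9)

    def test_reintegration_of_known_potential(self, geometry):
        # build a smooth potential, differentiate, convert to displacement,
        # re-integrate: < 1 % RMS of the potential's range
        H, W = 96, 96
        y, x = np.mgrid[0:H, 0:W]
        phi = (np.sin(2 * np.pi * x / 48.0) * np.cos(2 * np.pi * y / 32.0)
               + 0.5 * np.sin(2 * np.pi * (x + y) / 48.0))
        gy, gx = np.gradient(phi)
        g = geometry
        conv = (g.pixel_size * 1e-6 / g.d_sample_detector
                * 2 * math.pi / g.wavelength
                * g.pixel_size * 1e-6 / g.m_sample)
        D_x, D_y = gx / conv, gy / conv
        phi_hat = integrate_phase(D_x, D_y, g)
        rms = np.sqrt(np.mean((phi_hat - (phi - phi.mean())) ** 2))
        assert rms < 0.01 * np.ptp(phi)


class TestDirectionalDarkfield:
    def test_anisotropic_blur_orientation(self, geometry, smooth_pattern_stack):
        # blur along x only: major scattering axis at psi = 0 (mod pi)
        I_s = np.stack([ndimage.gaussian_filter1d(p, 1.0, axis=1)
                        for p in smooth_pattern_stack])
        res = directional_darkfield(make_pairs(smooth_pattern_stack, I_s,
                                               geometry))
        a, b, psi = res.tensor_eigen()
        sl = (slice(8, -8), slice(8, -8))
        strong = a[sl] > np.percentile(a[sl], 60)
        ang = psi[sl][strong]
        dev = np.minimum(ang, math.pi - ang)
        assert np.median(dev) < 0.2
        assert np.median(a[sl][strong]) > 2 * np.median(b[sl][strong])

    def test_isotropic_blur_degenerate_axes(self, geometry,
                                            smooth_pattern_stack):
        I_s = np.stack([ndimage.gaussian_filter(p, 0.8)
                        for p in smooth_pattern_stack])
        res = directional_darkfield(make_pairs(smooth_pattern_stack, I_s,
                                               geometry))
        a, b, _ = res.tensor_eigen()
        sl = (slice(8, -8), slice(8, -8))
        assert np.median(a[sl]) == pytest.approx(np.median(b[sl]), rel=0.3)

    def test_no_blur_zero_tensor_norm(self, geometry, smooth_pattern_stack):
        res = directional_darkfield(make_pairs(
            smooth_pattern_stack, smooth_pattern_stack, geometry))
        a, b, _ = res.tensor_eigen()
        assert np.median(np.hypot(a, b)) < 1e-3

    def test_hsv_encoding_channels(self, geometry, smooth_pattern_stack):
        I_s = np.stack([ndimage.gaussian_filter1d(p, 1.0, axis=1)
                        for p in smooth_pattern_stack])
        res = directional_darkfield(make_pairs(smooth_pattern_stack, I_s,
                                               geometry))
        hsv = res.darkfield_hsv()
        assert hsv.shape == smooth_pattern_stack.shape[1:] + (3,)
        assert hsv.min() >= 0.0 and hsv.max() <= 1.0
        rgb = res.darkfield_rgb()
        assert rgb.dtype == np.uint8


class TestResultsObject:
    def test_summary_mentions_unknowns_and_masked(self, geometry,
                                                  smooth_pattern_stack):
        res = LcsModel(make_pairs(smooth_pattern_stack,
                                  0.95 * smooth_pattern_stack, geometry)).fit()
        s = res.summary()
        for name in ("I_obj", "D_x", "D_y", "D_f", "rank-deficient"):
            assert name in s

    def test_hdf5_export(self, tmp_path, geometry, smooth_pattern_stack):
        res = LcsModel(make_pairs(smooth_pattern_stack,
                                  0.95 * smooth_pattern_stack, geometry)).fit()
        res.to_hdf5(tmp_path / "res.h5")
        import h5py

        with h5py.File(tmp_path / "res.h5") as f:
            assert set(f.keys()) >= {"I_obj", "D_x", "D_y", "D_f",
                                     "residual", "phase"}


def _smooth(rng, H, W, sigma):
    f = ndimage.gaussian_filter(rng.normal(size=(H, W)), sigma)
    return f / np.abs(f).max()


def _dummy_results(geometry, D_y):
    from mobi.lcs_retrieval import LcsResults, SCALAR_UNKNOWNS

    z = np.zeros_like(np.asarray(D_y, float))
    return LcsResults(
        geometry=geometry, unknowns=SCALAR_UNKNOWNS, I_obj=z, D_x=z,
        D_y=np.asarray(D_y, float), D_f=z, residual=z,
        rank_deficient=np.zeros_like(z, bool), n_masked=0,
        border=np.zeros_like(z, bool), regularization=0.0, window=1, K=4,
        tensor=False,
    )
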