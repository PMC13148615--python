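"""Phantoms, screens and the two forward models against closed-form oracles."""

import math

import numpy as np
import pytest
from scipy import ndimage

from mobi import (
    AcquisitionGeometry,
    ImagePairSet,
    ThicknessMap,
    acquire_series,
    forward_image,
    phantom_thickness,
    screen_from_thickness,
)
from mobi.constants import optical_constants
from mobi.synthetic_data import _Scene, refraction_displacement


class TestGeometry:
    def test_magnifications_and_zeff(self, geometry):
        assert geometry.m_sample == pytest.approx(1.35 / 0.55)
        assert geometry.m_membrane == pytest.approx(1.35 / 0.33)
        assert geometry.z_eff == pytest.approx(0.80 * 0.55 / 1.35)

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            AcquisitionGeometry(d_source_membrane=0.7, d_source_sample=0.55)

    def test_wavelength(self, geometry):
        assert geometry.wavelength == pytest.approx(1.4417e-10, rel=1e-3)


class TestPhantoms:
    PITCH = 60.0  # um per cell

    def grid(self, mm=20.0):
        n = int(mm * 1000 / self.PITCH)
        return (n, n)

    def test_wire_max_thickness_on_axis(self):
        t = phantom_thickness("wire", self.grid(4.0), self.PITCH)
        assert t.thickness.max() == pytest.approx(1.5, rel=1e-3)
        # cylinder along x: thickness constant along the axis direction
        row = t.thickness[t.thickness.shape[0] // 2]
        assert np.ptp(row) < 1e-6

    def test_sphere_chord_at_half_radius(self):
        t = phantom_thickness("sphere", self.grid(), self.PITCH)
        h, w = t.shape
        # point 3 mm from center along x
        j = w // 2 + int(3000 / self.PITCH)
        expected = 2.0 * math.sqrt(6.0**2 - 3.0**2)
        assert t.thickness[h // 2, j] == pytest.approx(expected, rel=0.01)

    def test_cube_constant_thickness(self):
        t = phantom_thickness("cube", self.grid(), self.PITCH)
        vals = np.unique(t.thickness)
        assert set(np.round(vals, 6)) <= {0.0, 7.0}

    def test_torus_max_thickness_on_centerline(self):
        t = phantom_thickness("torus", self.grid(), self.PITCH)
        assert t.thickness.max() == pytest.approx(3.0, rel=0.01)
        h, w = t.shape
        assert t.thickness[h // 2, w // 2] == 0.0  # hole in the middle

    def test_shepp_logan_thickness_range(self):
        t = phantom_thickness("shepp_logan", self.grid(22.0), self.PITCH)
        inside = t.thickness[t.thickness > 0]
        assert inside.min() == pytest.approx(1.0, abs=0.05)
        assert inside.max() == pytest.approx(5.0, abs=0.05)
        # landscape orientation: wider than tall
        sup = t.support
        rows = np.where(sup.any(axis=1))[0]
        cols = np.where(sup.any(axis=0))[0]
        assert np.ptp(cols) > np.ptp(rows)

    def test_julia_height_normalization(self):
        t = phantom_thickness("julia", self.grid(20.0), self.PITCH)
        assert t.thickness.max() == pytest.approx(5.0, rel=1e-6)
        assert t.thickness.min() == 0.0

    def test_unknown_phantom_rejected(self):
        with pytest.raises(ValueError):
            phantom_thickness("banana", (32, 32), 30.0)


class TestScreens:
    def test_zero_thickness_unit_screen(self, geometry):
        t = ThicknessMap(thickness=np.zeros((8, 8), np.float32), pitch=30.0)
        s = screen_from_thickness(t, geometry.energy)
        np.testing.assert_allclose(s, 1.0 + 0.0j)

    def test_beer_lambert_doubling(self, geometry):
        t1 = ThicknessMap(thickness=np.full((4, 4), 1.0, np.float32), pitch=30.0)
        t2 = ThicknessMap(thickness=np.full((4, 4), 2.0, np.float32), pitch=30.0)
        i1 = np.abs(screen_from_thickness(t1, geometry.energy)) ** 2
        i2 = np.abs(screen_from_thickness(t2, geometry.energy)) ** 2
        np.testing.assert_allclose(i2, i1**2, rtol=1e-10)

    def test_nylon_5mm_transmission_matches_table(self, geometry):
        mu = optical_constants("nylon", geometry.energy).mu  # 1/um
        t = ThicknessMap(thickness=np.full((2, 2), 5.0, np.float32), pitch=30.0)
        s = screen_from_thickness(t, geometry.energy)
        np.testing.assert_allclose(np.abs(s) ** 2, math.exp(-mu * 5000.0), rtol=1e-9)

    def test_unknown_material_rejected(self, geometry):
        t = ThicknessMap(thickness=np.zeros((2, 2), np.float32),
                         material="unobtainium", pitch=30.0)
        with pytest.raises(KeyError):
            screen_from_thickness(t, geometry.energy)


class TestForwardModels:
    def test_flat_field_without_mask(self, geometry):
        img = forward_image(None, None, geometry, shift=(0, 0), noise=False,
                            field_shape=(32, 32))
        np.testing.assert_allclose(img, geometry.mean_counts, rtol=1e-9)

    def test_poisson_variance_matches_mean(self, geometry):
        img = forward_image(None, None, geometry, seed=1, noise=True,
                            field_shape=(128, 128))
        assert img.var() == pytest.approx(img.mean(), rel=0.05)

    def test_warp_identity_for_zero_thickness_sample(self, small_cfg, spiral_mask):
        cfg = small_cfg
        os_ = spiral_mask.meta["oversample"]
        empty = ThicknessMap(
            thickness=np.zeros((os_ * 128, os_ * 128), np.float32),
            pitch=cfg.geometry.sample_pitch(os_),
        )
        pairs = acquire_series(spiral_mask, empty, cfg.geometry, K=1,
                               shift_range=(20, 40), seed=0, noise=False,
                               model="warp", field_shape=(128, 128))
        np.testing.assert_allclose(pairs.I_s[0], pairs.I_r[0], rtol=1e-6)

    def test_energy_conservation_phase_only_fresnel(self, geometry):
        # phase-only membrane: free-space propagation conserves photons, so
        # the mean intensity must not depend on the membrane shift
        from mobi.mask_patterns import make_design_mask

        mask = make_design_mask("spiral", 4.0, geometry, (96, 96),
                                margin_px=24, oversample=2, seed=2)
        scene = _Scene(mask, None, geometry, (96, 96), model="fresnel",
                       source_blur=False)
        scene.pattern_full = np.exp(1j * np.angle(scene.pattern_full))
        m0 = scene.reference((0, 0)).mean()
        m1 = scene.reference((15, -10)).mean()
        assert abs(m1 - m0) / m0 < 1e-3

    def test_membrane_feature_magnification(self, geometry):
        # one cone of physical size d at the membrane spans d*M/p detector px
        from mobi.mask_patterns import (ConeProfile, PointSet, rasterize_mask)

        d_um = 300.0
        margin, field = 8, 64
        p_mem = geometry.pixel_size / geometry.m_membrane
        extent = ((field + 2 * margin) * p_mem,) * 2
        ps = PointSet(np.array([[extent[0] / 2, extent[1] / 2]]), d_um,
                      extent, "random")
        mask = rasterize_mask(ps, ConeProfile(100.0), "sio2", p_mem / 2,
                              shape=(2 * (field + 2 * margin),) * 2)
        mask.meta.update(oversample=2, margin_px=margin, field_shape=[field, field])
        img = forward_image(mask, None, geometry, noise=False, kind="reference")
        dip = img.min(axis=0)
        depth = geometry.mean_counts - dip.min()
        width = float((dip < geometry.mean_counts - depth / 2).sum())
        # half-depth width of a linear cone profile = half its diameter
        expected = d_um / 2 * geometry.m_membrane / geometry.pixel_size
        assert width == pytest.approx(expected, rel=0.3)

    def test_warp_fresnel_displacement_consistency(self, geometry):
        # a wedge of constant theoretical displacement: both forward models
        # must move the pattern by the same amount (one-parameter optical
        # flow used as the independent meter)
        from mobi.mask_patterns import make_design_mask

        os_ = 6
        field = 96
        mask = make_design_mask("spiral", 4.0, geometry, (field, field),
                                margin_px=8, oversample=os_, seed=2)
        oc = optical_constants("nylon", geometry.energy)
        target = 0.05  # px
        slope = target * geometry.pixel_size / (
            geometry.d_sample_detector * 1e6 * oc.delta)
        pitch = geometry.sample_pitch(os_)
        y = np.arange(os_ * field)[:, None] * pitch
        t_um = slope * y * np.ones((1, os_ * field))
        wedge = ThicknessMap(thickness=(t_um * 1e-3).astype(np.float32),
                             pitch=pitch)
        d0x, d0y = refraction_displacement(wedge, geometry)
        assert d0y[10, 10] == pytest.approx(-target, rel=1e-3)
        est = {}
        for model in ("warp", "fresnel"):
            sc = _Scene(mask, wedge, geometry, (field, field), model, True)
            Ir, Is = sc.reference((0, 0)), sc.sample_image((0, 0))
            T = ndimage.gaussian_filter(Is / np.maximum(Ir, 1e-9), 8)
            Isc = Is / T
            w = (slice(20, 76), slice(20, 76))
            gy, _ = np.gradient(Ir)
            est[model] = float(((Ir - Isc) * gy)[w].sum() / (gy * gy)[w].sum())
        assert est["fresnel"] == pytest.approx(est["warp"], rel=0.2)
        assert est["fresnel"] == pytest.approx(-target, rel=0.45)


class TestAcquireSeries:
    def test_shift_protocol_and_determinism(self, small_cfg, spiral_mask):
        cfg = small_cfg
        a = acquire_series(spiral_mask, None, cfg.geometry, K=5,
                           shift_axes="x", shift_range=(50, 150), seed=3,
                           model="warp", field_shape=(128, 128))
        b = acquire_series(spiral_mask, None, cfg.geometry, K=5,
                           shift_axes="x", shift_range=(50, 150), seed=3,
                           model="warp", field_shape=(128, 128))
        np.testing.assert_array_equal(a.shifts, b.shifts)
        np.testing.assert_array_equal(a.I_r, b.I_r)
        assert np.all(a.shifts[:, 1] == 0)  # x-only protocol
        mags = np.abs(a.shifts[:, 0])
        assert np.all((mags >= 50) & (mags <= 150))

    def test_two_axis_shifts(self, small_cfg, spiral_mask):
        a = acquire_series(spiral_mask, None, small_cfg.geometry, K=8,
                           shift_axes="xy", shift_range=(50, 150), seed=4,
                           model="warp", field_shape=(128, 128))
        mags = np.abs(a.shifts)
        assert np.all((mags >= 50) & (mags <= 150))

    def test_zero_shift_range_reproduces_unshifted_reference(
            self, small_cfg, spiral_mask):
        a = acquire_series(spiral_mask, None, small_cfg.geometry, K=1,
                           shift_range=(0, 0), seed=5, noise=False,
                           model="warp", field_shape=(128, 128))
        ref = forward_image(spiral_mask, None, small_cfg.geometry,
                            shift=(0, 0), noise=False, kind="reference")
        np.testing.assert_allclose(a.I_r[0], ref, rtol=1e-6)

    def test_shift_exceeding_margin_raises(self, small_cfg, spiral_mask):
        margin = spiral_mask.meta["margin_px"]
        with pytest.raises(ValueError, match="margin"):
            forward_image(spiral_mask, None, small_cfg.geometry,
                          shift=(margin + 5, 0), noise=False)

    def test_hdf5_roundtrip(self, tmp_path, reference_series):
        p = tmp_path / "pairs.h5"
        reference_series.to_hdf5(p)
        back = ImagePairSet.from_hdf5(p)
        np.testing.assert_array_equal(back.I_r, reference_series.I_r)
        np.testing.assert_array_equal(back.shifts, reference_series.shifts)
        assert back.geometry == reference_series.geometry

    def test_tiff_dir_roundtrip(self, tmp_path, reference_series):
        d = tmp_path / "frames"
        reference_series.to_tiff_dir(d)
        back = ImagePairSet.from_tiff_dir(d)
        np.testing.assert_array_equal(back.I_s, reference_series.I_s)
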