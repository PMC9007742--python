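"""Deskew transform, synthetic forward model, and view orientation."""

import math

import numpy as np
import pytest

from opmkit.geometry import (
    AcquisitionGeometry,
    ObliqueStack,
    OrthoVolume,
    default_voxel_size,
    deskew,
    flip_view,
    forward_sample,
    overlap_crop,
)
from opmkit.synthesis import BeadPhantomSpec, ScenePhantom, make_bead_phantom, make_two_view_scene

from conftest import two_view_geometries


class TestAcquisitionGeometry:
    @pytest.mark.parametrize("bad", [{"tilt_angle_deg": 0.0}, {"tilt_angle_deg": 90.0},
                                     {"scan_step_um": -1.0}, {"pixel_size_um": 0.0},
                                     {"view_id": 3}, {"scan_mode": "spiral"}])
    def test_invalid_parameters_rejected(self, bad):
        with pytest.raises(ValueError):
            AcquisitionGeometry(**bad)

    def test_sigma_sign_follows_view(self):
        assert AcquisitionGeometry(view_id=1).sigma == 1
        assert AcquisitionGeometry(view_id=2).sigma == -1

    def test_default_voxel_size(self):
        g = AcquisitionGeometry(tilt_angle_deg=45, scan_step_um=2.0, pixel_size_um=0.44)
        vz, vy, vx = default_voxel_size(g)
        assert vx == 2.0
        assert vy == 0.44
        assert vz == pytest.approx(0.44 * math.sin(math.radians(45)))


class TestDeskew:
    def test_origin_fixed_point(self):
        """A sample at scan 0, x'=0 maps to world (x=0, y=y*p, z=0)."""
        g = AcquisitionGeometry(scan_step_um=1.0, pixel_size_um=1.0, frame_shape=(32, 24))
        frames = np.zeros((10, 32, 24))
        frames[0, 10, 0] = 100.0
        vol = deskew(ObliqueStack(frames, g))
        assert vol.origin_um == (0.0, 0.0, 0.0)
        zc, yc, xc = np.unravel_index(np.argmax(vol.data), vol.shape)
        assert (zc, xc) == (0, 0)
        assert yc == 10

    def test_oblique_field_implies_printed_depth(self):
        """A 420 um in-sheet field at 45 deg covers 300 um of depth (nearest 10)."""
        depth = 420.0 * math.sin(math.radians(45.0))
        assert round(depth, 0) == 297
        assert round(depth / 10.0) * 10 == 300
        # the deskewed grid reproduces the same extent
        p = 0.44
        n_xp = int(420.0 / p)
        g = AcquisitionGeometry(pixel_size_um=p, scan_step_um=1.0, frame_shape=(8, n_xp))
        vol = deskew(ObliqueStack(np.ones((4, 8, n_xp)), g))
        z_extent = vol.shape[0] * vol.voxel_size_um[0]
        assert z_extent == pytest.approx(depth, rel=0.01)

    def test_degenerate_tilt_rejected(self):
        g = AcquisitionGeometry(frame_shape=(8, 8))
        object.__setattr__(g, "tilt_angle_deg", 0.0)
        with pytest.raises(ValueError, match="degenerate"):
            deskew(ObliqueStack(np.ones((4, 8, 8)), g))

    def test_non_finite_input_rejected(self):
        g = AcquisitionGeometry(frame_shape=(8, 8))
        bad = np.ones((4, 8, 8))
        bad[0, 0, 0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            ObliqueStack(bad, g)

    def test_linearity(self):
        g = AcquisitionGeometry(scan_step_um=1.0, pixel_size_um=1.0, frame_shape=(12, 16))
        rng = np.random.default_rng(0)
        s1 = rng.uniform(0, 100, (10, 12, 16))
        s2 = rng.uniform(0, 100, (10, 12, 16))
        lhs = deskew(ObliqueStack(2.0 * s1 + 3.0 * s2, g)).data
        rhs = 2.0 * deskew(ObliqueStack(s1, g)).data + 3.0 * deskew(ObliqueStack(s2, g)).data
        np.testing.assert_allclose(lhs, rhs, rtol=1e-5, atol=1e-3)


class TestForwardSample:
    def test_uniform_volume_samples_constant(self):
        g = AcquisitionGeometry(scan_step_um=1.0, pixel_size_um=1.0, frame_shape=(16, 20))
        vol = OrthoVolume(np.full((14, 16, 40), 55.0), (math.sin(math.pi / 4), 1.0, 1.0))
        stack = forward_sample(vol, g)
        # interior frames and interior x' (fully inside the volume)
        interior = stack.data[18:24, :, 2:12]
        np.testing.assert_allclose(interior, 55.0, rtol=1e-5)

    def test_impulse_lights_only_nearby_planes(self):
        """Only frames whose oblique plane passes near the impulse are nonzero."""
        g = AcquisitionGeometry(scan_step_um=1.0, pixel_size_um=1.0, frame_shape=(16, 20))
        vz = math.sin(math.pi / 4)
        vol = OrthoVolume(np.zeros((14, 16, 40)), (vz, 1.0, 1.0))
        z_idx, y_idx, x_idx = 6, 8, 20
        vol.data[z_idx, y_idx, x_idx] = 1000.0
        stack = forward_sample(vol, g)
        # analytic scan position of the sheet through the impulse:
        # x = s0 + s*ds + x'*p*cos(t), with x' = z/(p*sin(t))
        z_um = z_idx * vz
        xp = z_um / (1.0 * math.sin(math.pi / 4))
        s0 = stack.geometry.scan_origin_um
        s_star = (x_idx * 1.0 - s0 - xp * 1.0 * math.cos(math.pi / 4)) / 1.0
        lit = np.nonzero(stack.data.sum(axis=(1, 2)))[0]
        assert len(lit) > 0
        assert np.all(np.abs(lit - s_star) <= 2.0)

    def test_roundtrip_bead_centroids(self):
        """forward model then deskew recovers bead positions to < 0.5 voxel."""
        rng_spec = BeadPhantomSpec(
            n_beads=22, fwhm_um=(2.5, 2.5, 2.5), psf_tilt_deg=0.0,
            min_separation_voxels=10, peak_counts=1000, background_counts=0, seed=4,
        )
        vz = math.sin(math.pi / 4)
        vol, positions = make_bead_phantom(rng_spec, (36, 64, 64), (vz, 1.0, 1.0))
        g = AcquisitionGeometry(scan_step_um=1.0, pixel_size_um=1.0, frame_shape=(64, 52))
        back = deskew(forward_sample(vol, g))
        assert back.voxel_size_um == pytest.approx(vol.voxel_size_um)
        # bead positions expressed on the deskewed grid (origins differ in x)
        offset = -np.array(back.origin_um) / np.array(back.voxel_size_um)
        errs = []
        for pos in positions:
            pos_b = pos + offset
            c = np.round(pos_b).astype(int)
            lo = np.maximum(c - 5, 0)
            hi = np.minimum(c + 6, back.shape)
            win = back.data[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
            idx = np.indices(win.shape).reshape(3, -1)
            w = win.reshape(-1)
            centroid = (idx * w).sum(axis=1) / w.sum() + lo
            errs.append(np.abs(centroid - pos_b))
        assert np.max(errs) < 0.5

    def test_roundtrip_preserves_total_intensity(self):
        """Interior content keeps total intensity within 2% through the round trip."""
        spec = BeadPhantomSpec(
            n_beads=5, fwhm_um=(3.0, 3.0, 3.0), psf_tilt_deg=0.0,
            min_separation_voxels=12, peak_counts=500, background_counts=0, seed=9,
        )
        vz = math.sin(math.pi / 4)
        vol, _ = make_bead_phantom(spec, (36, 48, 48), (vz, 1.0, 1.0))
        g = AcquisitionGeometry(scan_step_um=1.0, pixel_size_um=1.0, frame_shape=(48, 52))
        back = deskew(forward_sample(vol, g))
        assert back.data.sum() == pytest.approx(vol.data.sum(), rel=0.02)

    def test_roundtrip_smooth_phantom_rms(self):
        """deskew(forward_sample(V)) matches V to < 5% relative RMS inside."""
        vz = math.sin(math.pi / 4)
        zz, yy, xx = np.indices((30, 40, 40))
        data = 500 * np.exp(-((zz - 15.0) ** 2 / 60 + (yy - 20.0) ** 2 / 90
                              + (xx - 20.0) ** 2 / 90))
        vol = OrthoVolume(data, (vz, 1.0, 1.0))
        g = AcquisitionGeometry(scan_step_um=1.0, pixel_size_um=1.0, frame_shape=(40, 44))
        back = deskew(forward_sample(vol, g))
        x_off = int(round(-back.origin_um[2] / back.voxel_size_um[2]))
        inner = (slice(4, 26), slice(4, 36), slice(4, 36))
        sub = back.data[inner[0], inner[1], x_off + 4:x_off + 36]
        ref = vol.data[inner]
        rel_rms = np.sqrt(np.mean((sub - ref) ** 2)) / np.sqrt(np.mean(ref**2))
        assert rel_rms < 0.05


class TestFlipView:
    def test_involution_is_bitwise(self, texture_volume):
        twice = flip_view(flip_view(texture_volume))
        assert np.array_equal(twice.data, texture_volume.data)

    def test_impulse_mirrors_x_index(self):
        vol = OrthoVolume(np.zeros((4, 4, 9)), (1.0, 1.0, 1.0))
        vol.data[1, 2, 3] = 7.0
        flipped = flip_view(vol)
        assert flipped.data[1, 2, 9 - 1 - 3] == 7.0
        assert flipped.data.sum() == 7.0


class TestTwoViewAlignment:
    def test_views_land_on_common_grid(self, texture_volume):
        """After per-view deskew, the residual offset between views is tiny.

        The view-2 transform restores the common orientation; cropping to the
        shared world support leaves a gross offset far below 10% of the
        volume extent.
        """
        from opmkit.registration import phase_correlation

        g1, g2 = two_view_geometries(texture_volume.shape)
        phantom = ScenePhantom(truth=texture_volume, attenuation_mu_per_um=0.0)
        s1, s2, _ = make_two_view_scene(phantom, g1, g2)
        c1, c2 = overlap_crop(deskew(s1), deskew(s2))
        shift, conf = phase_correlation(c1.data, c2.data)
        assert conf > 0.5
        extent = np.array(c1.shape)
        assert np.all(np.abs(shift) < 0.10 * extent)
        # in fact the alignment is subvoxel by construction
        assert np.all(np.abs(shift) < 0.5)
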