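"""Phantom generation, projection geometry and bandpass emulation."""

import numpy as np
import pytest
from scipy.ndimage import affine_transform
from scipy.spatial.transform import Rotation

from ptychospa.core import Pose, Volume3D
from ptychospa.phantom import (
    make_bandpassed_map,
    make_blob_phantom,
    make_virus_phantom,
    place_projections,
    project_volume,
    projection_to_object_wave,
)
from tests.conftest import pearson

BLOBS = [((1.0, -2.0, 1.5), 2.0, 1.0), ((-3.0, 2.0, -1.0), 1.5, 0.7)]


@pytest.fixture(scope="module")
def blob_phantom():
    return make_blob_phantom(
        64, 0.5, [b[0] for b in BLOBS], [b[1] for b in BLOBS], [b[2] for b in BLOBS]
    )


class TestVirusPhantom:
    def test_plain_shell_is_annular_and_bounded(self):
        vol = make_virus_phantom(64, 0.5, 10.0, 2.0, n_bumps=0, seed=1)
        n = 64
        ax = (np.arange(n) - n // 2) * 0.5
        z, y, x = np.meshgrid(ax, ax, ax, indexing="ij")
        r = np.sqrt(z**2 + y**2 + x**2)
        assert vol.values.min() >= 0 and vol.values.max() <= 1
        # interior plateau of the annulus is filled, outside is empty
        assert vol.values[(r > 8.8) & (r < 9.2)].min() > 0.9
        assert np.all(vol.values[r > 11.0] == 0)
        assert np.all(vol.values[r < 7.0] == 0)

    def test_same_seed_is_bit_identical(self):
        a = make_virus_phantom(48, 0.5, 8.0, 2.0, n_bumps=12, seed=7)
        b = make_virus_phantom(48, 0.5, 8.0, 2.0, n_bumps=12, seed=7)
        assert np.array_equal(a.values, b.values)
        c = make_virus_phantom(48, 0.5, 8.0, 2.0, n_bumps=12, seed=8)
        assert not np.array_equal(a.values, c.values)

    def test_oversized_geometry_rejected(self):
        with pytest.raises(ValueError, match="fit"):
            make_virus_phantom(32, 0.5, 7.5, 1.0, n_bumps=0, seed=0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_projection_conserves_mass_at_any_pose(self, virus_phantom, seed):
        pose = Pose(Rotation.random(rng=np.random.default_rng(seed)))
        proj = project_volume(virus_phantom, pose)
        total = virus_phantom.values.sum()
        assert abs(proj.values.sum() - total) / total <= 1e-6


class TestProjection:
    def test_single_bright_voxel_projects_to_single_pixel(self):
        vals = np.zeros((32, 32, 32))
        vals[16, 20, 9] = 1.0
        proj = project_volume(Volume3D(vals, 1.0), Pose.identity(), order=1)
        assert proj.values[20, 9] == pytest.approx(1.0)
        assert proj.values.sum() == pytest.approx(1.0)

    def test_matches_analytic_gaussian_projection(self, blob_phantom):
        """Closed-form oracle: a Gaussian's line integral is a 2D Gaussian
        at the rotated centre."""
        pose = Pose(Rotation.from_euler("ZYZ", [0.3, 0.7, -0.4]))
        proj = project_volume(blob_phantom, pose)
        n, vs = 64, 0.5
        ax = (np.arange(n) - n // 2) * vs
        yy, xx = np.meshgrid(ax, ax, indexing="ij")
        rot = pose.matrix()
        expected = np.zeros((n, n))
        for (cz, cy, cx), s, a in BLOBS:
            lab = rot @ np.array([cx, cy, cz])
            d2 = (xx - lab[0]) ** 2 + (yy - lab[1]) ** 2
            expected += a * np.sqrt(2 * np.pi) * s / vs * np.exp(-0.5 * d2 / s**2)
        err = np.linalg.norm(proj.values - expected) / np.linalg.norm(expected)
        assert err <= 1e-3

    def test_fourier_slice_theorem(self, blob_phantom):
        """2D transform of the projection equals the 3D transform of the
        volume on the rotated central plane (analytic Gaussian transform)."""
        pose = Pose(Rotation.from_euler("ZYZ", [0.3, 0.7, -0.4]))
        proj = project_volume(blob_phantom, pose)
        n, vs = 64, 0.5
        k = np.fft.fftfreq(n, d=vs)
        ky, kx = np.meshgrid(k, k, indexing="ij")
        q3 = pose.matrix().T @ np.stack([kx.ravel(), ky.ravel(), np.zeros(kx.size)])
        expected = np.zeros(kx.size, dtype=complex)
        for (cz, cy, cx), s, a in BLOBS:
            amp = a * (2 * np.pi) ** 1.5 * s**3
            phase = np.exp(-2j * np.pi * (q3[0] * cx + q3[1] * cy + q3[2] * cz))
            expected += amp * np.exp(-2 * np.pi**2 * s**2 * np.sum(q3**2, axis=0)) * phase
        expected /= vs**3
        f2 = np.fft.fft2(np.fft.ifftshift(proj.values)).ravel()
        assert np.linalg.norm(f2 - expected) / np.linalg.norm(expected) <= 1e-3

    def test_in_plane_rotation_relates_projections(self, blob_phantom):
        gamma = np.deg2rad(25.0)
        p1 = project_volume(blob_phantom, Pose.identity())
        p2 = project_volume(blob_phantom, Pose(Rotation.from_euler("z", gamma)))
        c, s = np.cos(gamma), np.sin(gamma)
        m = np.array([[c, s], [-s, c]]).T
        centre = np.array([32.0, 32.0])
        rotated = affine_transform(p1.values, m, offset=centre - m @ centre, order=3)
        assert pearson(rotated, p2.values) >= 0.999


class TestObjectWave:
    def test_zero_scales_give_unit_transmission(self):
        proj = project_volume(make_virus_phantom(32, 0.5, 5.0, 1.5, 0, 0), Pose.identity())
        wave = projection_to_object_wave(proj, 0.0, 0.0)
        assert np.allclose(wave.values, 1.0)

    def test_pure_phase_object_has_unit_modulus(self, virus_phantom):
        proj = project_volume(virus_phantom, Pose.identity())
        wave = projection_to_object_wave(proj, 0.05, 0.0)
        assert np.allclose(np.abs(wave.values), 1.0)
        assert np.allclose(wave.phase, 0.05 * proj.values, atol=1e-12)

    def test_attenuation_bounds_modulus(self, virus_phantom):
        proj = project_volume(virus_phantom, Pose.identity())
        wave = projection_to_object_wave(proj, 0.05, 0.01)
        assert np.all(np.abs(wave.values) <= 1.0 + 1e-12)

    def test_negative_scales_rejected(self, virus_phantom):
        proj = project_volume(virus_phantom, Pose.identity())
        with pytest.raises(ValueError):
            projection_to_object_wave(proj, -0.1)


class TestBandpassEmulation:
    def test_full_band_is_identity(self, virus_phantom):
        out = make_bandpassed_map(virus_phantom, 0.0, virus_phantom.nyquist)
        assert np.abs(out.values - virus_phantom.values).max() <= 1e-10

    def test_hard_edge_partition_sums_to_input(self, virus_phantom):
        nyq = virus_phantom.nyquist
        parts = [(0.0, 0.3), (0.3, 0.7), (0.7, nyq)]
        total = sum(make_bandpassed_map(virus_phantom, lo, hi).values for lo, hi in parts)
        assert np.abs(total - virus_phantom.values).max() <= 1e-6

    def test_radial_spectrum_never_amplified(self, virus_phantom):
        from ptychospa.bandsynth import radial_amplitude_spectrum

        out = make_bandpassed_map(virus_phantom, 0.2, 0.6)
        s_in = radial_amplitude_spectrum(virus_phantom)
        s_out = radial_amplitude_spectrum(out)
        assert np.all(s_out.l_values <= s_in.l_values + 1e-9)

    def test_noise_seed_reproducible(self, virus_phantom):
        a = make_bandpassed_map(virus_phantom, 0.0, 0.5, noise_rms=0.01, seed=3)
        b = make_bandpassed_map(virus_phantom, 0.0, 0.5, noise_rms=0.01, seed=3)
        assert np.array_equal(a.values, b.values)

    def test_q_hi_beyond_nyquist_rejected(self, virus_phantom):
        with pytest.raises(ValueError, match="Nyquist"):
            make_bandpassed_map(virus_phantom, 0.0, 2 * virus_phantom.nyquist)

    def test_raised_cosine_attenuates_smoothly(self, virus_phantom):
        hard = make_bandpassed_map(virus_phantom, 0.2, 0.6)
        soft = make_bandpassed_map(virus_phantom, 0.2, 0.6, rolloff_width=0.1)
        assert not np.allclose(hard.values, soft.values)


class TestScene:
    def test_projection_placement_and_background(self):
        img = np.ones((8, 8))
        from ptychospa.core import Projection2D

        scene = place_projections([Projection2D(img, 1.0)], [(16, 16)], 32, 1.0)
        assert scene.values[16, 16] == 1.0
        assert scene.values.sum() == pytest.approx(64.0)
        noisy = place_projections(
            [Projection2D(img, 1.0)], [(16, 16)], 32, 1.0, background_rms=0.3, seed=2
        )
        assert noisy.values.min() >= 0
        assert noisy.values.std() > 0.2

    def test_out_of_canvas_rejected(self):
        from ptychospa.core import Projection2D

        with pytest.raises(ValueError, match="canvas"):
            place_projections([Projection2D(np.ones((16, 16)), 1.0)], [(2, 2)], 32, 1.0)
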