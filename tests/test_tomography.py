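"""Radon forward model, ramp filtering, FBP and SART."""

import numpy as np
import pytest
import scipy.sparse as sp

from mesr.metrics import psnr
from mesr.phantoms import (
    EllipseSpec,
    default_shepp_logan,
    rasterize_ellipse_phantom,
    to_display_range,
)
from mesr.tomography import (
    SartConfig,
    Sinogram,
    add_projection_noise,
    default_radial_offsets,
    fbp_reconstruct,
    radon_forward,
    ramp_filter_projections,
    sart_reconstruct,
)

ANGLES32 = np.arange(32) * 180.0 / 32


class TestRadonForward:
    def test_zero_image_gives_zero_sinogram(self):
        sino = radon_forward(np.zeros((32, 32)), ANGLES32)
        assert np.all(sino.values == 0.0)

    def test_linearity(self, rng):
        a = rng.random((48, 48))
        b = rng.random((48, 48))
        sab = radon_forward(2.0 * a - 3.0 * b, ANGLES32)
        sa = radon_forward(a, ANGLES32)
        sb = radon_forward(b, ANGLES32)
        np.testing.assert_allclose(
            sab.values, 2.0 * sa.values - 3.0 * sb.values, atol=1e-10
        )

    def test_central_chord_of_disk(self, disk128):
        # the central ray crosses the R=0.5 disk over a chord of length 1
        sino = radon_forward(disk128, ANGLES32)
        ctr = sino.values[:, sino.radial_offsets.size // 2]
        np.testing.assert_allclose(ctr, 1.0, rtol=0.02)

    def test_chord_length_profile(self, disk128):
        # g(theta, r) = 2 sqrt(R^2 - r^2) for the uniform disk
        sino = radon_forward(disk128, ANGLES32)
        r = sino.radial_offsets
        inside = np.abs(r) <= 0.45
        expected = 2.0 * np.sqrt(0.25 - r[inside] ** 2)
        np.testing.assert_allclose(sino.values[0, inside], expected, rtol=0.05)

    def test_mass_conservation_per_angle(self):
        img = rasterize_ellipse_phantom(default_shepp_logan(), 128)
        sino = radon_forward(img, ANGLES32)
        mass = img.pixels.sum() * (2.0 / 128) ** 2
        per_angle = sino.values.sum(axis=1) * sino.radial_spacing
        np.testing.assert_allclose(per_angle, mass, rtol=0.01)

    def test_rotational_symmetry_of_disk(self, disk128):
        sino = radon_forward(disk128, ANGLES32)
        mean_row = sino.values.mean(axis=0)
        for row in sino.values:
            assert np.linalg.norm(row - mean_row) <= 0.01 * np.linalg.norm(mean_row)

    def test_matches_skimage_radon(self):
        # independent oracle: skimage's projector in pixel units (odd size so
        # the two center-of-rotation conventions coincide)
        from skimage.transform import radon as sk_radon

        disk = rasterize_ellipse_phantom([EllipseSpec(0, 0, 0.5, 0.5, 0, 1.0)], 129)
        angles = np.array([0.0, 45.0, 90.0])
        mine = radon_forward(disk, angles)
        ours = mine.values / mine.radial_spacing  # frame units -> pixel units
        theirs = sk_radon(disk.pixels, theta=angles).T
        for k in range(angles.size):
            b = np.interp(
                mine.radial_offsets / mine.radial_spacing,
                np.arange(theirs.shape[1]) - (theirs.shape[1] - 1) / 2.0,
                theirs[k],
            )
            assert np.abs(ours[k] - b).max() <= 0.03 * np.abs(b).max()

    def test_errors(self):
        with pytest.raises(ValueError):
            radon_forward(np.zeros((16, 16)), [])
        with pytest.raises(ValueError):
            radon_forward(np.zeros((8, 4)), ANGLES32)
        with pytest.raises(ValueError):
            default_radial_offsets(16, 1)


class TestRampFilter:
    def _sino(self, values):
        values = np.atleast_2d(values)
        n = values.shape[1]
        return Sinogram(values, np.zeros(values.shape[0]), default_radial_offsets(n, n))

    def test_zero_in_zero_out(self):
        out = ramp_filter_projections(self._sino(np.zeros((3, 33))))
        assert np.all(out.values == 0.0)

    def test_constant_row_suppressed(self):
        out = ramp_filter_projections(self._sino(np.full((1, 65), 7.0)))
        interior = out.values[0, 8:-8]
        assert np.abs(interior).max() < 0.05 * 7.0 / (2.0 / 65)

    def test_impulse_gives_discrete_ramp_kernel(self):
        # oracle: inverse DFT of |omega| with the same padding/discretization
        n, mid = 33, 16
        row = np.zeros((1, n))
        row[0, mid] = 1.0
        sino = self._sino(row)
        out = ramp_filter_projections(sino)
        dr = sino.radial_spacing
        pad = 1 << max(6, int(np.ceil(np.log2(2 * n))))
        kernel = np.real(np.fft.ifft(np.abs(np.fft.fftfreq(pad, d=dr))))
        expected = np.array([kernel[(k - mid) % pad] for k in range(n)])
        np.testing.assert_allclose(out.values[0], expected, atol=1e-12)

    def test_hann_window_tames_high_frequencies(self):
        rng = np.random.default_rng(0)
        noisy = self._sino(rng.standard_normal((1, 65)))
        pure = ramp_filter_projections(noisy, window="ramp")
        hann = ramp_filter_projections(noisy, window="hann")
        assert np.linalg.norm(hann.values) < np.linalg.norm(pure.values)

    def test_unknown_window(self):
        with pytest.raises(ValueError):
            ramp_filter_projections(self._sino(np.ones((1, 9))), window="blackman")


class TestFBP:
    def test_zero_sinogram(self):
        sino = radon_forward(np.zeros((32, 32)), ANGLES32)
        rec = fbp_reconstruct(sino, 32)
        assert np.all(rec.pixels == 0.0)

    def test_disk_density_recovery(self, disk128):
        angles = np.arange(90) * 2.0
        rec = fbp_reconstruct(radon_forward(disk128, angles), 128)
        mask = disk128.pixels > 0.5
        # erode to the disk interior to avoid edge ringing
        interior = mask & (np.roll(mask, 8, 0) & np.roll(mask, -8, 0))
        assert abs(rec.pixels[interior].mean() - 1.0) < 0.05

    def test_shepp_roundtrip_psnr(self):
        img = rasterize_ellipse_phantom(default_shepp_logan(), 256)
        angles = np.arange(180.0)
        rec = fbp_reconstruct(radon_forward(img, angles, n_radial=363), 256)
        ref8 = to_display_range(img.pixels)
        out8 = to_display_range(rec.pixels, img.pixels.min(), img.pixels.max())
        assert psnr(ref8, out8) >= 25.0

    def test_quality_improves_with_angles(self, disk128):
        scores = []
        for n_ang in (45, 90, 180):
            angles = np.arange(n_ang) * 180.0 / n_ang
            rec = fbp_reconstruct(radon_forward(disk128, angles), 128)
            ref8 = to_display_range(disk128.pixels)
            out8 = to_display_range(rec.pixels, 0.0, 1.0)
            scores.append(psnr(ref8, out8))
        assert scores[0] <= scores[1] <= scores[2]

    def test_errors(self):
        sino = radon_forward(np.ones((32, 32)), [0.0])
        with pytest.raises(ValueError):
            fbp_reconstruct(sino, 32)  # one angle is not enough
        narrow = Sinogram(
            np.ones((2, 5)), [0.0, 90.0], default_radial_offsets(32, 5)
        )
        with pytest.raises(ValueError):
            fbp_reconstruct(narrow, 32)  # radial extent cannot cover the frame


class _SingleRaySystem:
    """One ray, one pixel, intersection length a."""

    def __init__(self, a=1.0):
        self.size = 1
        self.matrices = [sp.csr_matrix(np.array([[a]]))]
        self.col_sum = [np.array([a])]

    def forward(self, pixels):
        return np.array([[self.matrices[0][0, 0] * pixels.ravel()[0]]])


class TestSART:
    def test_single_ray_hand_example(self):
        # a=1, p=5, f0=0, lambda=1: the first sweep sets f = 5
        sino = Sinogram(np.array([[5.0]]), [0.0], np.array([0.0]))
        rec = sart_reconstruct(
            sino, SartConfig(1.0, 1), 1, system=_SingleRaySystem(1.0)
        )
        assert np.isclose(rec.pixels[0, 0], 5.0)

    def test_consistent_data_is_fixed_point(self, disk64):
        sino = radon_forward(disk64, ANGLES32, oversample=1)
        rec = sart_reconstruct(
            sino, SartConfig(1.0, 2), 64, initial=disk64.pixels
        )
        np.testing.assert_allclose(rec.pixels, disk64.pixels, atol=1e-9)

    def test_residual_non_increasing(self):
        img = rasterize_ellipse_phantom(default_shepp_logan(), 128)
        angles = np.arange(64) * 180.0 / 64
        sino = radon_forward(img, angles)
        _, info = sart_reconstruct(
            sino, SartConfig(1.0, 10), 128, return_info=True
        )
        res = np.array(info["residual_norms"])
        assert np.all(np.diff(res) <= 1e-9 * res[0])

    def test_relaxation_validated(self):
        with pytest.raises(ValueError):
            SartConfig(relaxation=2.5)
        with pytest.raises(ValueError):
            SartConfig(iterations=0)

    def test_noise_injection_seeded(self, disk64):
        sino = radon_forward(disk64, ANGLES32)
        n1 = add_projection_noise(sino, 0.01, 42)
        n2 = add_projection_noise(sino, 0.01, 42)
        np.testing.assert_array_equal(n1.values, n2.values)
        sigma = 0.01 * np.abs(sino.values).max()
        resid = (n1.values - sino.values).ravel()
        assert abs(resid.std() - sigma) < 0.1 * sigma
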