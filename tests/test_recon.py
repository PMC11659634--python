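import numpy as np
import pytest
from scipy import ndimage

from dmirelax.encoding import DriftModel, hamming_filter, scheme_weight_field
from dmirelax.phantom import make_two_compartment, signal_series
from dmirelax.recon import (
    ImageSeries,
    KSpaceSeries,
    central_crop,
    downsample_fractions,
    downsample_hamming,
    forward_ft,
    inverse_ft,
    nudft_adjoint,
)


class TestForwardFT:
    def test_constant_image_concentrates_at_dc(self):
        img = np.full((8, 8, 8), 3.0)
        k = forward_ft(img)
        dc = k[4, 4, 4]
        assert dc == pytest.approx(3.0 * np.sqrt(512))
        off = k.copy()
        off[4, 4, 4] = 0.0
        assert np.max(np.abs(off)) < 1e-10

    def test_parseval(self, rng):
        img = rng.normal(size=(9, 8, 7))
        k = forward_ft(img)
        assert np.sum(np.abs(img) ** 2) == pytest.approx(
            np.sum(np.abs(k) ** 2), rel=1e-10
        )

    def test_point_source_phase_ramp_matches_brute_force_dft(self, rng):
        """A shifted delta gives a pure phase ramp; check against the
        explicit DFT sum at a handful of k-points."""
        shape = (8, 8, 8)
        img = np.zeros(shape)
        pos = (5, 2, 6)
        img[pos] = 1.0
        k = forward_ft(img)
        centers = [n // 2 for n in shape]
        for _ in range(5):
            kidx = tuple(rng.integers(0, n) for n in shape)
            koff = [ki - c for ki, c in zip(kidx, centers)]
            phase = sum(ko * (p - c) / n
                        for ko, p, c, n in zip(koff, pos, centers, shape))
            expected = np.exp(-2j * np.pi * phase) / np.sqrt(np.prod(shape))
            assert k[kidx] == pytest.approx(expected, abs=1e-12)

    def test_round_trip_identity(self, rng):
        img = rng.normal(size=(10, 11, 12))
        back = inverse_ft(forward_ft(img))
        np.testing.assert_allclose(back.real, img, atol=1e-10)
        assert np.max(np.abs(back.imag)) < 1e-10


class TestNudftAdjoint:
    @staticmethod
    def _cartesian_coords(shape):
        mesh = np.meshgrid(*[np.arange(n) - n // 2 for n in shape],
                           indexing="ij")
        return np.column_stack([m.ravel() for m in mesh]).astype(float)

    def test_cartesian_coverage_equals_inverse_fft(self, rng):
        shape = (8, 8, 8)
        img = rng.normal(size=shape) + 1j * rng.normal(size=shape)
        k = forward_ft(img)
        coords = self._cartesian_coords(shape)
        series = KSpaceSeries(k.ravel()[None], coords)
        out = nudft_adjoint(series, shape)
        np.testing.assert_allclose(out.volumes[0], img, atol=1e-8)

    def test_duplicate_sample_adds_without_compensation(self):
        shape = (4, 4, 4)
        coord = np.array([[1.0, 0.0, -1.0]])
        single = nudft_adjoint(KSpaceSeries([[2.0 + 0j]], coord), shape)
        doubled = nudft_adjoint(
            KSpaceSeries([[1.0 + 0j, 1.0 + 0j]],
                         np.vstack([coord, coord])), shape
        )
        np.testing.assert_allclose(doubled.volumes, single.volumes, atol=1e-12)

    def test_random_coords_match_triple_loop_oracle(self, rng):
        shape = (8, 8, 8)
        m = 50
        coords = rng.uniform(-4, 4, size=(m, 3))
        samples = rng.normal(size=m) + 1j * rng.normal(size=m)
        out = nudft_adjoint(KSpaceSeries(samples[None], coords), shape)
        expected = np.zeros(shape, complex)
        for x in range(8):
            for y in range(8):
                for z in range(8):
                    acc = 0.0 + 0.0j
                    for j in range(m):
                        ph = (coords[j, 0] * (x - 4) + coords[j, 1] * (y - 4)
                              + coords[j, 2] * (z - 4)) / 8.0
                        acc += samples[j] * np.exp(2j * np.pi * ph)
                    expected[x, y, z] = acc / np.sqrt(512)
        np.testing.assert_allclose(out.volumes[0], expected, atol=1e-10)

    def test_out_of_band_coords_warn_but_run(self):
        series = KSpaceSeries([[1.0 + 0j]], [[10.0, 0.0, 0.0]])
        with pytest.warns(UserWarning, match="Nyquist"):
            nudft_adjoint(series, (4, 4, 4))


class TestDownsample:
    def test_constant_image_dc_gain_one(self):
        img = np.full((16, 16, 16), 2.5)
        series = ImageSeries(img[None], (1, 1, 1), (0.0,))
        low = downsample_hamming(series, (4, 4, 4))
        np.testing.assert_allclose(low.volumes[0], 2.5, atol=1e-10)

    def test_target_larger_than_source_rejected(self):
        series = ImageSeries(np.zeros((1, 8, 8, 8)), (1, 1, 1), (0.0,))
        with pytest.raises(ValueError, match="exceeds"):
            downsample_hamming(series, (16, 16, 16))

    def test_linearity_in_image(self, rng):
        a = rng.normal(size=(16, 16, 16))
        b = rng.normal(size=(16, 16, 16))
        low = lambda x: downsample_hamming(
            ImageSeries(x[None], (1, 1, 1), (0.0,)), (6, 6, 6)
        ).volumes[0]
        np.testing.assert_allclose(
            low(2.0 * a + 0.5 * b), 2.0 * low(a) + 0.5 * low(b), atol=1e-10
        )

    def test_partial_volume_structure(self):
        """Interior voxels keep the pure compartment value within 1%;
        boundary voxels become intermediate.  Interior/boundary labels
        come from an independent morphological-erosion oracle."""
        ph = make_two_compartment((64, 64, 64))
        core = ph.fractions["sWM"].astype(bool)
        series = ImageSeries(ph.fractions["sWM"][None], (1, 1, 1), (0.0,))
        low = downsample_hamming(series, (16, 16, 16)).volumes[0]
        block = 4  # downsampling ratio
        core_low = core.reshape(16, block, 16, block, 16, block).mean(
            axis=(1, 3, 5))
        # PSF main lobe of the Hamming-apodized crop spans ~2 low-res voxels
        interior = ndimage.binary_erosion(core_low == 1.0, iterations=2)
        boundary = (core_low > 0.2) & (core_low < 0.8)
        assert interior.sum() > 0 and boundary.sum() > 0
        assert np.all(np.abs(low[interior] - 1.0) < 0.01)
        assert np.all((low[boundary] > 0.05) & (low[boundary] < 0.95))

    def test_fraction_maps_sum_to_at_most_one(self):
        ph = make_two_compartment((32, 32, 32))
        low = downsample_fractions(ph.fractions, (8, 8, 8))
        total = sum(low.values())
        assert total.max() <= 1.0 + 1e-6

    def test_constant_fraction_stays_one(self):
        low = downsample_fractions({"a": np.ones((12, 12, 12))}, (4, 4, 4))
        np.testing.assert_allclose(low["a"], 1.0, atol=1e-9)

    def test_boundary_values_match_explicit_psf_convolution(self):
        """Direct-sum oracle: the low-res image equals the circular
        convolution of the image with the explicitly computed PSF kernel,
        sampled on the coarse lattice."""
        n, m = 8, 4
        rng = np.random.default_rng(7)
        img = np.zeros((n, n, n))
        img[2:6, 2:6, 2:6] = 1.0
        img += 0.1 * rng.normal(size=img.shape)
        series = ImageSeries(img[None], (1, 1, 1), (0.0,))
        low = downsample_hamming(series, (m, m, m)).volumes[0]

        win = hamming_filter((m, m, m))
        win = win.copy()
        win[0, :, :] = 0.0  # unpaired Nyquist planes (even target)
        win[:, 0, :] = 0.0
        win[:, :, 0] = 0.0
        start = n // 2 - m // 2
        koffs = np.arange(m) - m // 2

        # explicit PSF kernel tabulated on all n^3 circular offsets
        psf = np.zeros((n, n, n), complex)
        for v0 in range(n):
            for v1 in range(n):
                for v2 in range(n):
                    acc = 0.0 + 0.0j
                    for a in range(m):
                        for b in range(m):
                            for c in range(m):
                                ph = (koffs[a] * v0 + koffs[b] * v1
                                      + koffs[c] * v2) / n
                                acc += win[a, b, c] * np.exp(2j * np.pi * ph)
                    psf[v0, v1, v2] = acc

        r = n // m
        cm, cn = m // 2, n // 2
        expected = np.zeros((m, m, m))
        for y0 in range(m):
            for y1 in range(m):
                for y2 in range(m):
                    x = (cn + r * (y0 - cm), cn + r * (y1 - cm),
                         cn + r * (y2 - cm))
                    acc = 0.0 + 0.0j
                    for u0 in range(n):
                        for u1 in range(n):
                            for u2 in range(n):
                                acc += img[u0, u1, u2] * psf[
                                    (x[0] - u0) % n, (x[1] - u1) % n,
                                    (x[2] - u2) % n]
                    expected[y0, y1, y2] = acc.real / n**3
        np.testing.assert_allclose(low, expected, atol=1e-8)


class TestReorderedProportionality:
    def test_single_tissue_series_proportional_under_reordered_drift(
        self, uniform_phantom, se_schedule
    ):
        """For a homogeneous tissue, reordered drift weighting scales every
        voxel's time series by one voxel-specific constant, leaving
        relaxation fits untouched."""
        series = signal_series(uniform_phantom, se_schedule)
        target = (8, 8, 8)
        wf = scheme_weight_field(target, series.n_times, "reordered",
                                 DriftModel(-1, 0.35))
        plain = downsample_hamming(series, target)
        weighted = downsample_hamming(series, target, weights=wf)
        keep = np.abs(plain.volumes[0]) > 1e-3 * np.abs(plain.volumes[0]).max()
        ratio = weighted.volumes[:, keep] / plain.volumes[:, keep]
        spread = ratio.max(axis=0) - ratio.min(axis=0)
        assert np.max(np.abs(spread / ratio.mean(axis=0))) < 1e-9


class TestCrop:
    def test_even_crop_keeps_dc_centered(self):
        k = np.zeros((8, 8, 8), complex)
        k[4, 4, 4] = 1.0
        c = central_crop(k, (4, 4, 4))
        assert c[2, 2, 2] == 1.0
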