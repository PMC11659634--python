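import numpy as np
import pytest

from dmirelax.spectra import (
    Resonance,
    ResonanceBasis,
    build_basis,
    lc_fit,
    phase_align_average,
    spectrum_from_fid,
    spectrum_quality,
)

BW = 4800.0
NPTS = 96


def single_line_basis(delay_ms=0.0, lw=12.0, ppm=4.8, **kw):
    return build_basis([("water", ppm, lw)], n_points=NPTS, bandwidth_hz=BW,
                       acquisition_delay_ms=delay_ms, **kw)


class TestBuildBasis:
    def test_zero_delay_line_is_absorptive_at_peak(self):
        basis = single_line_basis()
        spec = basis.members["water"]
        peak = np.argmax(np.abs(spec))
        assert np.angle(spec[peak]) == pytest.approx(0.0, abs=1e-9)
        assert spec[peak].real == np.abs(spec).max()

    def test_phase_flip_members_are_negated_copies(self):
        basis = single_line_basis(phase_flip=True)
        assert set(basis.flipped) == set(basis.members)
        np.testing.assert_array_equal(basis.flipped["water"],
                                      -basis.members["water"])

    def test_acquisition_delay_sets_first_order_phase(self):
        # 100 Hz offset (on-bin: df = 50 Hz) with 2 ms delay
        offset_ppm = 4.8 + 100.0 / 45.7
        basis = build_basis([("x", offset_ppm, 10.0)], n_points=NPTS,
                            bandwidth_hz=BW, acquisition_delay_ms=2.0)
        spec = basis.members["x"]
        peak = np.argmax(np.abs(spec))
        expected = 2 * np.pi * 100.0 * 0.002
        assert np.angle(spec[peak]) == pytest.approx(expected, abs=1e-6)

    def test_duplicate_names_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            build_basis([("water", 4.8, 12.0), ("water", 3.9, 12.0)])

    def test_duplicate_positions_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            build_basis([("a", 4.8, 12.0), ("b", 4.8, 12.0)])

    def test_nonpositive_linewidth_rejected(self):
        with pytest.raises(ValueError, match="linewidth"):
            Resonance("x", 4.8, 0.0)


class TestLcFit:
    def test_self_fit_recovers_scale(self):
        basis = single_line_basis()
        fit = lc_fit(3.7 * basis.members["water"], basis)
        assert fit.amplitudes["water"] == pytest.approx(3.7, abs=1e-9)
        assert fit.crlb_percent["water"] < 1e-6

    def test_inverted_line_reports_negative_amplitude(self):
        basis = single_line_basis()
        up = lc_fit(2.0 * basis.members["water"], basis)
        down = lc_fit(-2.0 * basis.members["water"], basis)
        assert down.amplitudes["water"] == pytest.approx(
            -up.amplitudes["water"], rel=1e-12
        )

    def test_two_overlapping_lines_match_normal_equations_oracle(self):
        basis = build_basis([("a", 4.8, 30.0), ("b", 4.95, 30.0)],
                            n_points=NPTS, bandwidth_hz=BW)
        spec = 2.0 * basis.members["a"] + 1.0 * basis.members["b"]
        fit = lc_fit(spec, basis)
        # independent 2x2 normal-equations solution on stacked re/im
        a = np.concatenate([basis.members["a"].real, basis.members["a"].imag])
        b = np.concatenate([basis.members["b"].real, basis.members["b"].imag])
        y = np.concatenate([spec.real, spec.imag])
        g11, g12, g22 = a @ a, a @ b, b @ b
        r1, r2 = a @ y, b @ y
        det = g11 * g22 - g12**2
        amp_a = (g22 * r1 - g12 * r2) / det
        amp_b = (g11 * r2 - g12 * r1) / det
        assert fit.amplitudes["a"] == pytest.approx(amp_a, rel=1e-10)
        assert fit.amplitudes["b"] == pytest.approx(amp_b, rel=1e-10)
        assert fit.amplitudes["a"] == pytest.approx(2.0, abs=1e-9)
        assert fit.amplitudes["b"] == pytest.approx(1.0, abs=1e-9)

    def test_scale_equivariance(self, rng):
        basis = build_basis(n_points=NPTS, bandwidth_hz=BW)
        spec = sum(c * m for c, m in zip((1.5, -0.7, 0.3),
                                         basis.members.values()))
        spec = spec + 0.01 * (rng.normal(size=NPTS)
                              + 1j * rng.normal(size=NPTS))
        f1 = lc_fit(spec, basis)
        f2 = lc_fit(5.0 * spec, basis)
        for name in f1.amplitudes:
            assert f2.amplitudes[name] == pytest.approx(
                5.0 * f1.amplitudes[name], rel=1e-9
            )
            # CRLB percent invariant when signal and noise scale together
            assert f2.crlb_percent[name] == pytest.approx(
                f1.crlb_percent[name], rel=1e-6
            )

    def test_singular_design_rejected(self):
        basis = single_line_basis()
        # hand-build a basis with two identical members
        bad = ResonanceBasis(
            resonances=(Resonance("a", 4.8, 12.0), Resonance("b", 4.0, 12.0)),
            n_points=basis.n_points, bandwidth_hz=basis.bandwidth_hz,
            reference_freq_mhz=basis.reference_freq_mhz,
            center_ppm=basis.center_ppm, acquisition_delay_ms=0.0,
            phase_flip=False,
            members={"a": basis.members["water"],
                     "b": basis.members["water"].copy()},
        )
        with pytest.raises(ValueError, match="singular"):
            lc_fit(basis.members["water"], bad)

    def test_length_mismatch_rejected(self):
        basis = single_line_basis()
        with pytest.raises(ValueError, match="length"):
            lc_fit(np.zeros(10, complex), basis)


class TestPhaseAlignAverage:
    def test_random_phases_average_coherently(self, rng):
        basis = single_line_basis()
        spec = basis.members["water"]
        phases = rng.uniform(-np.pi, np.pi, size=24)
        stack = np.array([spec * np.exp(1j * p) for p in phases])
        avg, est_phases, shifts = phase_align_average(stack)
        np.testing.assert_allclose(avg, spec, atol=1e-9)
        assert np.all(shifts == 0)

    def test_snr_gain_sqrt_n(self, rng):
        basis = single_line_basis()
        spec = basis.members["water"]
        n_vox = 64
        sigma = 0.05
        stack = np.array([
            spec + sigma * (rng.normal(size=NPTS) + 1j * rng.normal(size=NPTS))
            for _ in range(n_vox)
        ])
        avg, _, _ = phase_align_average(stack, align_frequency=False)
        resid = avg - spec
        # complex noise SD of the mean should shrink by ~sqrt(n)
        assert np.std(resid.real) < 2.5 * sigma / np.sqrt(n_vox)

    def test_shift_pair_realigns_to_single_width(self):
        # majority of voxels on-frequency so the median reference is peaked
        basis = single_line_basis(lw=60.0)
        spec = basis.members["water"]
        stack = np.array([np.roll(spec, +1), np.roll(spec, -1),
                          spec, spec, spec])
        avg, _, shifts = phase_align_average(stack)
        assert sorted(shifts.tolist()) == [-1, 0, 0, 0, 1]

        def fwhm_bins(s):
            mag = np.abs(s)
            return np.count_nonzero(mag >= mag.max() / 2)

        assert fwhm_bins(avg) == fwhm_bins(spec)

    def test_empty_input_raises(self):
        with pytest.raises(ValueError, match="dominance"):
            phase_align_average(np.zeros((0, NPTS), complex))


class TestSpectrumQuality:
    def test_known_height_to_noise_ratio(self, rng):
        n = 4096
        basis = build_basis([("water", 4.8, 10.0)], n_points=n,
                            bandwidth_hz=2000.0)
        sigma = 0.02
        clean = 3.0 * basis.members["water"]
        noise = sigma * (rng.normal(size=n) + 1j * rng.normal(size=n))
        spec = clean + noise
        fit = lc_fit(spec, basis, noise_window_ppm=(-30.0, -10.0))
        snr, _ = spectrum_quality(spec, fit, basis)
        expected = np.abs(clean).max() / sigma
        assert snr == pytest.approx(expected, rel=0.10)

    def test_lorentzian_fwhm_matches_linewidth(self):
        basis = build_basis([("water", 4.8, 10.0)], n_points=2048,
                            bandwidth_hz=2000.0)
        fit = lc_fit(basis.members["water"], basis)
        _, fwhm = spectrum_quality(basis.members["water"], fit, basis)
        assert fwhm == pytest.approx(10.0, rel=0.10)

    def test_pure_noise_snr_near_zero(self, rng):
        basis = single_line_basis()
        spec = 0.01 * (rng.normal(size=NPTS) + 1j * rng.normal(size=NPTS))
        fit = lc_fit(spec, basis)
        snr, _ = spectrum_quality(spec, fit, basis)
        assert snr < 5.0


class TestSpectrumFromFid:
    def test_dc_fid_maps_to_center_bin(self):
        fid = np.ones(16, complex)
        spec = spectrum_from_fid(fid)
        assert np.argmax(np.abs(spec)) == 8
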