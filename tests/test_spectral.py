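import numpy as np
import pytest

from doafuse.preprocess import Epoch
from doafuse.spectral import (
    PowerSpectrum,
    SpectralConfig,
    beta_ratio,
    bispectrum_direct,
    extract_features,
    sef95,
    synch_fast_slow,
    welch_psd,
)

FS = 100.0
T = np.arange(6000) / FS


def flat_spectrum(df=0.25):
    f = np.arange(0.0, 50.0 + df, df)
    psd = np.where((f >= 0.5) & (f <= 47.0), 1.0, 0.0)
    return PowerSpectrum(freqs=f, psd=psd, fs=FS)


class TestWelch:
    def test_tone_power_concentrated(self):
        ps = welch_psd(np.sin(2 * np.pi * 10 * T), FS)
        near = np.abs(ps.freqs - 10.0) <= ps.resolution
        assert ps.psd[near].sum() / ps.psd.sum() >= 0.95

    def test_parseval(self, rng):
        x = rng.standard_normal(6000) * 3.0
        ps = welch_psd(x, FS)
        assert ps.psd.sum() * ps.resolution == pytest.approx(x.var(), rel=0.05)

    def test_zero_signal_zero_psd(self):
        ps = welch_psd(np.zeros(6000), FS)
        assert np.all(ps.psd == 0)


class TestBetaRatio:
    def test_flat_spectrum_matches_bandwidth_ratio(self):
        br, flags = beta_ratio(flat_spectrum())
        assert br == pytest.approx(np.log10(17 / 9), abs=0.02)
        assert not flags

    def test_equal_power_tones_cancel(self):
        ps = welch_psd(np.sin(2 * np.pi * 15 * T) + np.sin(2 * np.pi * 35 * T), FS)
        br, _ = beta_ratio(ps)
        assert br == pytest.approx(0.0, abs=0.05)

    def test_pure_spindle_tone_negative(self):
        br, flags = beta_ratio(welch_psd(np.sin(2 * np.pi * 15 * T), FS))
        assert br < 0

    def test_insufficient_coverage_rejected(self):
        ps = PowerSpectrum(freqs=np.arange(0.0, 20.0, 0.5), psd=np.ones(40), fs=40.0)
        with pytest.raises(ValueError, match="cover"):
            beta_ratio(ps)


class TestSef95:
    def test_flat_spectrum_analytic_edge(self):
        ps = flat_spectrum()
        assert sef95(ps) == pytest.approx(0.5 + 0.95 * 46.5, abs=ps.resolution)

    def test_tone_point_mass(self):
        ps = welch_psd(np.sin(2 * np.pi * 10 * T), FS)
        assert sef95(ps) == pytest.approx(10.0, abs=ps.resolution)

    def test_two_tone_edge_at_upper_tone(self):
        ps = welch_psd(np.sin(2 * np.pi * 5 * T) + np.sin(2 * np.pi * 40 * T), FS)
        assert sef95(ps) == pytest.approx(40.0, abs=ps.resolution)

    def test_scale_invariance(self, rng):
        x = rng.standard_normal(6000)
        assert sef95(welch_psd(x, FS)) == pytest.approx(sef95(welch_psd(7.3 * x, FS)), abs=1e-9)


def coupled_triad(rng, n=6000, coupled=True, block=256):
    """Triads with per-block random phases; φ3 = φ1 + φ2 only when coupled."""
    x = np.zeros(n)
    t = np.arange(block) / FS
    for start in range(0, n - block + 1, block):
        p1, p2, p3 = rng.uniform(0, 2 * np.pi, 3)
        if coupled:
            p3 = p1 + p2
        x[start : start + block] = (
            np.cos(2 * np.pi * 5 * t + p1)
            + np.cos(2 * np.pi * 8 * t + p2)
            + np.cos(2 * np.pi * 13 * t + p3)
        )
    return x + 0.1 * rng.standard_normal(n)


def peak_at(bispec, f1, f2):
    i = int(np.argmin(np.abs(bispec.f1_grid - f1)))
    j = int(np.argmin(np.abs(bispec.f2_grid - f2)))
    return bispec.magnitude[max(i, j), min(i, j)]


class TestBispectrum:
    def test_coupled_triad_peak_dominates_background(self, rng):
        # non-overlapping segments aligned with the phase blocks
        cfg = SpectralConfig(bispec_overlap=0.0)
        b = bispectrum_direct(coupled_triad(rng, coupled=True), FS, cfg)
        assert peak_at(b, 5, 8) >= 10 * np.nanmedian(b.magnitude)

    def test_phase_randomized_control_collapses(self, rng):
        cfg = SpectralConfig(bispec_overlap=0.0)
        b_c = bispectrum_direct(coupled_triad(rng, coupled=True), FS, cfg)
        b_u = bispectrum_direct(coupled_triad(rng, coupled=False), FS, cfg)
        assert b_c.n_segments >= 20
        assert peak_at(b_u, 5, 8) <= 0.2 * peak_at(b_c, 5, 8)

    def test_zero_signal_zero_magnitude(self):
        b = bispectrum_direct(np.zeros(6000), FS)
        assert np.nansum(b.magnitude) == 0

    def test_principal_domain_restriction(self, rng):
        b = bispectrum_direct(rng.standard_normal(6000), FS)
        f1 = b.f1_grid[:, None]
        f2 = b.f2_grid[None, :]
        outside = (f2 > f1) | (f1 + f2 > FS / 2)
        assert np.all(~np.isfinite(b.magnitude[outside]))

    def test_full_plane_symmetry_oracle(self, rng):
        # tiny instance: full-plane double loop satisfies |B(f1,f2)|=|B(f2,f1)|
        x = rng.standard_normal(256)
        seg = 64
        segs = [x[i : i + seg] for i in range(0, 256 - seg + 1, seg // 2)]
        w = np.hanning(seg)
        acc = np.zeros((seg // 2 + 1, seg // 2 + 1), complex)
        for s in segs:
            X = np.fft.rfft((s - s.mean()) * w)
            for i in range(seg // 2 + 1):
                for j in range(seg // 2 + 1):
                    if i + j < seg // 2 + 1:
                        acc[i, j] += X[i] * X[j] * np.conj(X[i + j])
        mag = np.abs(acc)
        np.testing.assert_allclose(mag, mag.T, rtol=1e-10)

    def test_too_short_signal_rejected(self):
        with pytest.raises(ValueError, match="segments"):
            bispectrum_direct(np.zeros(100), FS)


class TestSynchFastSlow:
    def test_nonnegative_for_random_epochs(self, rng):
        for _ in range(5):
            b = bispectrum_direct(rng.standard_normal(6000), FS)
            sfs, _ = synch_fast_slow(b)
            assert sfs >= 0

    def test_matches_brute_force_region_sum(self, rng):
        cfg = SpectralConfig(bispec_segment=64)
        b = bispectrum_direct(rng.standard_normal(2000), FS, cfg)
        num = den = 0.0
        for i in range(b.f1_grid.size):
            for j in range(b.f2_grid.size):
                if np.isfinite(b.magnitude[i, j]):
                    fsum = b.f1_grid[i] + b.f2_grid[j]
                    if 0.5 <= fsum <= 47.0:
                        num += b.magnitude[i, j]
                    if 40.0 <= fsum <= 47.0:
                        den += b.magnitude[i, j]
        sfs, _ = synch_fast_slow(b)
        assert sfs == pytest.approx(np.log10(num / den), abs=1e-10)

    def test_slow_only_signal_capped_and_flagged(self):
        x = np.sin(2 * np.pi * 5 * T)  # all power far below 20 Hz
        b = bispectrum_direct(x, FS)
        sfs, flags = synch_fast_slow(b)
        assert sfs >= 5
        assert flags


class TestExtractFeatures:
    def test_state_separation_directions(self, awake_epoch, deep_epoch):
        fa = extract_features(awake_epoch)
        fd = extract_features(deep_epoch)
        assert fa.br > fd.br  # high-frequency share falls with depth
        assert fa.sef95 > fd.sef95  # spectrum slows with depth
        assert np.all(np.isfinite(fa.as_array()))
        assert np.all(np.isfinite(fd.as_array()))

    def test_zero_epoch_degenerate_flags(self):
        fv = extract_features(Epoch(np.zeros(6000), 0))
        assert "degenerate" in fv.flags
        assert np.all(np.isfinite(fv.as_array()))

    def test_amplitude_scale_invariance(self, awake_epoch):
        f1 = extract_features(awake_epoch)
        f2 = extract_features(Epoch(awake_epoch.samples * 12.5, awake_epoch.minute_index))
        np.testing.assert_allclose(f1.as_array(), f2.as_array(), atol=1e-8)
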