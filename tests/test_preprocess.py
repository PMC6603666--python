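import numpy as np
import pytest
from scipy import signal as sps

from doafuse.io import EegRecord
from doafuse.preprocess import (
    PreprocessConfig,
    bandpass_fir,
    design_bandpass,
    epoch_record,
    inverse_filter_remove_emg,
    preprocess_pipeline,
    remove_outliers,
    resample,
    swt_remove_eog,
)
from doafuse.synthetic import generate_patient, generate_state_eeg, inject_artifacts

FS = 128.0


def tone(freq, seconds=30, fs=FS, amp=1.0):
    t = np.arange(int(seconds * fs)) / fs
    return EegRecord(amp * np.sin(2 * np.pi * freq * t), fs)


class TestRemoveOutliers:
    def test_clean_gaussian_untouched(self, rng):
        # P(|z| > 6) ≈ 2e-9: expected flags per minute ≪ 1
        rec = EegRecord(rng.standard_normal(int(FS * 60)) * 20, FS)
        out, mask = remove_outliers(rec, k=6)
        assert mask.sum() == 0
        np.testing.assert_array_equal(out.samples, rec.samples)

    def test_single_spike_replaced(self, rng):
        x = rng.standard_normal(int(FS * 60)) * 20
        x[1000] += 20 * x.std()
        out, mask = remove_outliers(EegRecord(x, FS), k=6)
        assert mask[1000] and mask.sum() == 1
        others = np.arange(x.size) != 1000
        np.testing.assert_array_equal(out.samples[others], x[others])
        assert abs(out.samples[1000]) < 5 * x.std()

    def test_constant_signal_identity(self):
        rec = EegRecord(np.full(2000, 7.0), FS)
        out, mask = remove_outliers(rec, k=6)
        assert mask.sum() == 0
        np.testing.assert_array_equal(out.samples, rec.samples)


class TestBandpassFir:
    def test_mains_tone_suppressed(self):
        rec = tone(60.0)
        out = bandpass_fir(rec).samples
        assert out[500:-500].std() <= 0.01 * rec.samples.std()

    def test_alpha_band_tone_preserved(self):
        rec = tone(10.0)
        out = bandpass_fir(rec).samples
        assert out.std() == pytest.approx(rec.samples.std(), rel=0.05)

    def test_dc_offset_removed(self):
        rec = EegRecord(np.full(int(FS * 30), 100.0), FS)
        out = bandpass_fir(rec).samples
        assert np.abs(out).mean() < 1.0

    def test_stopband_attenuation_of_default_design(self):
        taps = design_bandpass((0.5, 47.0), 513, FS)
        w, h = sps.freqz(taps, worN=[0.1, 55.0], fs=FS)
        atten_db = -20 * np.log10(np.abs(h))
        assert atten_db[0] >= 40  # drift side
        assert atten_db[1] >= 40  # mains side

    def test_undersized_order_rejected(self):
        with pytest.raises(ValueError, match="at least"):
            design_bandpass((0.5, 47.0), 31, FS)

    def test_phase_alignment(self):
        # group-delay compensation: filtered passband tone stays in phase
        rec = tone(10.0)
        out = bandpass_fir(rec).samples
        mid = slice(1000, 2000)
        assert np.corrcoef(out[mid], rec.samples[mid])[0, 1] > 0.999


class TestSwtRemoveEog:
    def test_clean_beta_signal_preserved(self, beta_only_spec):
        clean = generate_state_eeg(beta_only_spec, 60, FS, seed=1)
        out, _ = swt_remove_eog(clean)
        assert np.corrcoef(out.samples, clean.samples)[0, 1] >= 0.99
        assert out.samples.size == clean.samples.size

    def test_eog_removal_improves_correlation(self, beta_only_spec):
        clean = generate_state_eeg(beta_only_spec, 60, FS, seed=2)
        dirty, _ = inject_artifacts(clean, eog_rate=4, seed=3)
        out, shrunk = swt_remove_eog(dirty)
        before = np.corrcoef(dirty.samples, clean.samples)[0, 1]
        after = np.corrcoef(out.samples, clean.samples)[0, 1]
        assert after > before
        assert shrunk > 0

    def test_zero_signal(self):
        out, shrunk = swt_remove_eog(EegRecord(np.zeros(4096), FS))
        assert np.abs(out.samples).max() == 0
        assert shrunk == 0

    def test_unknown_wavelet_rejected(self):
        with pytest.raises(ValueError, match="wavelet"):
            swt_remove_eog(EegRecord(np.zeros(4096), FS), wavelet="nosuchwav")


class TestInverseFilter:
    def test_stationary_ar_surrogate_rarely_flagged(self, rng):
        x = sps.lfilter([1.0], [1, -1.1, 0.4, 0.1, -0.08, 0.02, -0.01], rng.standard_normal(int(FS * 60)))
        _, mask = inverse_filter_remove_emg(EegRecord(x, FS))
        assert mask.mean() <= 0.01

    def test_broadband_burst_flagged_and_repaired(self, specs):
        clean = generate_state_eeg(specs["general"], 60, FS, seed=3)
        x = clean.samples.copy()
        # 0.5-s constant-envelope broadband burst at 10x RMS
        rng = np.random.default_rng(0)
        sos = sps.butter(4, 30, btype="highpass", fs=FS, output="sos")
        burst = sps.sosfiltfilt(sos, rng.standard_normal(int(0.5 * FS)))
        burst = burst / burst.std() * 10 * x.std()
        i0 = int(20 * FS)
        x[i0 : i0 + burst.size] += burst
        out, mask = inverse_filter_remove_emg(EegRecord(x, FS))
        assert mask[i0 : i0 + burst.size].mean() >= 0.8
        err_before = np.abs(x - clean.samples)[i0 : i0 + burst.size].mean()
        err_after = np.abs(out.samples - clean.samples)[i0 : i0 + burst.size].mean()
        assert err_after < 0.5 * err_before

    def test_zero_signal_identity(self):
        rec = EegRecord(np.zeros(int(FS * 10)), FS)
        out, mask = inverse_filter_remove_emg(rec)
        np.testing.assert_array_equal(out.samples, rec.samples)
        assert mask.sum() == 0


class TestResample:
    def test_length_arithmetic(self, rng):
        rec = EegRecord(rng.standard_normal(1280), 128.0)
        assert resample(rec, 100.0).samples.size == 1000

    def test_tone_amplitude_preserved(self):
        rec = tone(10.0, seconds=100)
        out = resample(rec, 100.0)
        assert out.fs == 100.0
        assert out.samples[200:-200].std() == pytest.approx(rec.samples.std(), rel=0.02)

    def test_identity_when_rates_match(self, rng):
        rec = EegRecord(rng.standard_normal(1000), 100.0)
        np.testing.assert_array_equal(resample(rec, 100.0).samples, rec.samples)

    def test_upsampling_rejected(self, rng):
        with pytest.raises(ValueError):
            resample(EegRecord(rng.standard_normal(1000), 100.0), 128.0)


class TestEpoching:
    def test_trailing_partial_minute_dropped(self, rng):
        rec = EegRecord(rng.standard_normal(int(100 * 60 * 2.5)), 100.0)
        epochs, excluded = epoch_record(rec)
        assert len(epochs) == 2
        assert excluded == 0

    def test_sub_minute_record_empty(self, rng):
        rec = EegRecord(rng.standard_normal(5900), 100.0)
        epochs, _ = epoch_record(rec)
        assert epochs == []

    def test_heavily_corrected_minutes_excluded(self, rng):
        rec = EegRecord(rng.standard_normal(100 * 60 * 3), 100.0)
        mask = np.zeros(rec.samples.size, bool)
        mask[6000 : 6000 + 3000] = True  # 50% of minute 1 corrected
        epochs, excluded = epoch_record(rec, corrected_mask=mask)
        assert excluded == 1
        assert [e.minute_index for e in epochs] == [0, 2]


@pytest.fixture(scope="module")
def patient(specs):
    return generate_patient(
        [(specs["awake"], 3), (specs["general"], 4), (specs["deep"], 3)], FS, seed=11
    )


class TestPipeline:

    def test_clean_record_keeps_all_minutes(self, patient):
        epochs, log = preprocess_pipeline(patient.record)
        assert len(epochs) == 10
        assert log.minutes_excluded == 0
        assert log.steps == [
            "remove_outliers", "bandpass_fir", "swt_remove_eog",
            "inverse_filter_remove_emg", "resample", "epoch_record",
        ]

    def test_artifacted_record_yields_finite_epochs(self, patient):
        dirty, _ = inject_artifacts(patient.record, 2, 1, 1, seed=5)
        epochs, _ = preprocess_pipeline(dirty)
        assert len(epochs) >= 1
        for ep in epochs:
            assert np.all(np.isfinite(ep.samples))

    def test_energy_never_increased(self, patient):
        dirty, _ = inject_artifacts(patient.record, 2, 1, 1, seed=5)
        epochs, _ = preprocess_pipeline(dirty)
        out_power = np.var(np.concatenate([e.samples for e in epochs]))
        assert out_power <= 1.01 * np.var(dirty.samples)

    def test_determinism(self, patient):
        a, _ = preprocess_pipeline(patient.record)
        b, _ = preprocess_pipeline(patient.record)
        for ea, eb in zip(a, b):
            np.testing.assert_array_equal(ea.samples, eb.samples)

    def test_too_short_record_rejected(self, rng):
        with pytest.raises(ValueError, match="2 minutes"):
            preprocess_pipeline(EegRecord(rng.standard_normal(int(FS * 90)), FS))

    def test_invalid_config_rejected(self, patient):
        with pytest.raises(ValueError, match="odd"):
            preprocess_pipeline(patient.record, PreprocessConfig(fir_order=512))
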