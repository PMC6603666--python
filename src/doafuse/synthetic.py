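"""Synthetic anesthesia EEG with known ground truth.

Real depth-of-anesthesia recordings are rarely shareable, so this module
generates surrogate frontal EEG whose statistical structure matches what
the downstream estimators measure: band-limited power with state-dependent
proportions, quadratically phase-coupled oscillation triads (which make the
bispectrum non-trivial), burst suppression in deep anesthesia, and the
classic artifact classes (ocular deflections, muscle bursts, single-sample
spikes).  Alongside each signal it produces a smooth per-minute reference
index (0–100, BIS-like) consistent with the anesthesia-state labels.

The signal model is deliberately simple: a weighted sum of band-limited
Gaussian noise processes, plus sinusoidal coupled triads, gated by a
suppression envelope, scaled to a 20 µV RMS.  It exposes every feature the
estimators look for without attempting physiological realism.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .io import EegRecord, IndexSeries

__all__ = [
    "BANDS",
    "StateSpec",
    "SyntheticPatient",
    "ArtifactEvents",
    "default_state_specs",
    "generate_state_eeg",
    "generate_patient",
    "inject_artifacts",
]

#: Canonical EEG bands (Hz), delta through gamma, capped at the 47 Hz
#: analysis edge used throughout the package.
BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 47.0),
}

#: Index bands per anesthesia state (half-open downward, awake closed above).
STATE_INDEX_BANDS: dict[str, tuple[float, float]] = {
    "awake": (80.0, 100.0),
    "light": (60.0, 80.0),
    "general": (40.0, 60.0),
    "deep": (0.0, 40.0),
}

CLEAN_RMS_UV = 20.0  # target RMS of the clean signal, typical frontal EEG
SUPPRESSION_GAIN = 0.005  # residual amplitude during iso-electric suppression


@dataclass(frozen=True)
class StateSpec:
    """Spectral recipe for one anesthesia state.

    ``band_weights`` are relative band-power proportions over the canonical
    bands; they must be nonnegative and are normalized to sum to 1.
    ``coupling_triads`` lists ``(f1, f2, strength)`` quadratically
    phase-coupled triples (the third component sits at ``f1 + f2`` with
    phase ``φ1 + φ2``).  ``suppression_fraction`` is the expected fraction
    of time spent in iso-electric suppression.  ``ref_index_range`` is the
    interval reference-index values are drawn from and must sit inside the
    state's 0–100 index band.
    """

    state: str
    band_weights: dict[str, float]
    coupling_triads: tuple[tuple[float, float, float], ...] = ()
    suppression_fraction: float = 0.0
    ref_index_range: tuple[float, float] = (40.0, 60.0)

    def __post_init__(self) -> None:
        if self.state not in STATE_INDEX_BANDS:
            raise ValueError(f"unknown state {self.state!r}")
        w = np.array([self.band_weights.get(b, 0.0) for b in BANDS], float)
        if np.any(w < 0) or not np.isfinite(w).all() or w.sum() <= 0:
            raise ValueError("band_weights must be nonnegative with positive sum")
        if not 0.0 <= self.suppression_fraction <= 1.0:
            raise ValueError("suppression_fraction must lie in [0, 1]")
        lo, hi = self.ref_index_range
        blo, bhi = STATE_INDEX_BANDS[self.state]
        if not (blo <= lo <= hi <= bhi):
            raise ValueError(
                f"ref_index_range {self.ref_index_range} outside the "
                f"{self.state!r} index band [{blo}, {bhi}]"
            )
        for f1, f2, c in self.coupling_triads:
            if not (0 < f1 and 0 < f2 and 0.0 <= c <= 1.0):
                raise ValueError(f"invalid coupling triad {(f1, f2, c)}")

    @property
    def normalized_weights(self) -> np.ndarray:
        w = np.array([self.band_weights.get(b, 0.0) for b in BANDS], float)
        return w / w.sum()


def default_state_specs() -> dict[str, StateSpec]:
    """Default recipes for the four states.

    Awake EEG is beta-dominated; with deepening anesthesia power shifts
    toward the low frequencies, phase coupling appears, and deep anesthesia
    adds burst suppression.  The weights are design choices emulating that
    qualitative slowing, not a calibration to any clinical cohort.
    """
    return {
        "awake": StateSpec(
            state="awake",
            band_weights={"delta": 0.05, "theta": 0.10, "alpha": 0.22, "beta": 0.45, "gamma": 0.18},
            ref_index_range=(84.0, 97.0),
        ),
        "light": StateSpec(
            state="light",
            band_weights={"delta": 0.15, "theta": 0.18, "alpha": 0.34, "beta": 0.25, "gamma": 0.08},
            coupling_triads=((5.0, 7.0, 0.25),),
            ref_index_range=(63.0, 77.0),
        ),
        "general": StateSpec(
            state="general",
            band_weights={"delta": 0.34, "theta": 0.27, "alpha": 0.25, "beta": 0.10, "gamma": 0.04},
            coupling_triads=((4.0, 6.5, 0.5),),
            ref_index_range=(43.0, 57.0),
        ),
        "deep": StateSpec(
            state="deep",
            band_weights={"delta": 0.58, "theta": 0.22, "alpha": 0.13, "beta": 0.05, "gamma": 0.02},
            coupling_triads=((3.0, 5.0, 0.6),),
            suppression_fraction=0.25,
            ref_index_range=(12.0, 37.0),
        ),
    }


@dataclass
class SyntheticPatient:
    """One synthetic subject: signal plus per-minute ground truth."""

    record: EegRecord
    ref_index: IndexSeries
    state_labels: list[str]
    seed: int

    def __post_init__(self) -> None:
        if len(self.ref_index) != len(self.state_labels):
            raise ValueError("ref_index and state_labels lengths differ")


@dataclass
class ArtifactEvents:
    """Timestamps (seconds) of injected artifacts, for oracle comparisons."""

    eog: list[float] = field(default_factory=list)
    emg: list[float] = field(default_factory=list)
    outliers: list[int] = field(default_factory=list)  # sample indices
    clean: EegRecord | None = None


def _band_noise(n: int, fs: float, band: tuple[float, float], rng: np.random.Generator) -> np.ndarray:
    """Unit-variance Gaussian noise band-limited to ``band``."""
    lo, hi = band
    nyq = fs / 2.0
    hi = min(hi, 0.99 * nyq)
    white = rng.standard_normal(n)
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, white)
    sd = x.std()
    return x / sd if sd > 0 else x


def _suppression_envelope(
    n: int, fs: float, fraction: float, rng: np.random.Generator
) -> np.ndarray:
    """Multiplicative burst-suppression gate alternating 1 and a small gain.

    Segment lengths are exponential (mean 2 s bursts; suppression mean
    scaled so the long-run suppressed fraction matches ``fraction``).
    """
    if fraction <= 0:
        return np.ones(n)
    if fraction >= 1:
        return np.full(n, SUPPRESSION_GAIN)
    mean_burst = 2.0
    mean_supp = mean_burst * fraction / (1.0 - fraction)
    env = np.ones(n)
    pos = 0
    suppressed = rng.random() < fraction
    while pos < n:
        mean = mean_supp if suppressed else mean_burst
        seg = max(int(rng.exponential(mean) * fs), int(0.25 * fs))
        if suppressed:
            env[pos : pos + seg] = SUPPRESSION_GAIN
        pos += seg
        suppressed = not suppressed
    # smooth the gate edges (50 ms) to avoid broadband clicks
    k = max(int(0.05 * fs), 1)
    kernel = np.hanning(2 * k + 1)
    kernel /= kernel.sum()
    return np.convolve(env, kernel, mode="same")


def generate_state_eeg(
    spec: StateSpec, duration_s: float, fs: float, seed: int
) -> EegRecord:
    """Generate a stationary segment of synthetic EEG for one state.

    The output has ``duration_s * fs`` samples, band-power proportions
    approximating ``spec.band_weights``, deterministic phase-coupled triads
    (``φ3 = φ1 + φ2``), and optional burst suppression.  Identical
    arguments yield bit-identical output.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if fs < 100:
        raise ValueError("fs must be at least 100 Hz")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    weights = spec.normalized_weights

    x = np.zeros(n)
    for w, band in zip(weights, BANDS.values()):
        if w > 0:
            x += np.sqrt(w) * _band_noise(n, fs, band, rng)

    t = np.arange(n) / fs
    for f1, f2, strength in spec.coupling_triads:
        phi1 = rng.uniform(0, 2 * np.pi)
        phi2 = rng.uniform(0, 2 * np.pi)
        amp = strength * 0.5  # relative to the unit-variance noise mixture
        x += amp * np.cos(2 * np.pi * f1 * t + phi1)
        x += amp * np.cos(2 * np.pi * f2 * t + phi2)
        x += amp * np.cos(2 * np.pi * (f1 + f2) * t + phi1 + phi2)

    env = _suppression_envelope(n, fs, spec.suppression_fraction, rng)
    x *= env

    # scale the *unsuppressed* portion to the nominal RMS so suppression
    # actually lowers amplitude instead of being renormalized away
    unsupp = env > 0.5
    if unsupp.any():
        ref_rms = np.sqrt(np.mean(x[unsupp] ** 2))
    else:
        ref_rms = np.sqrt(np.mean(x**2)) / SUPPRESSION_GAIN
    x *= CLEAN_RMS_UV / max(ref_rms, 1e-12)
    return EegRecord(samples=x, fs=fs, channel_label=f"SYN {spec.state}")


def _smooth_ref_index(values: np.ndarray, window: int = 3) -> np.ndarray:
    """Centered moving average with edge shrinkage (BIS trends are smooth)."""
    kernel = np.ones(window) / window
    padded = np.concatenate([values[:1].repeat(window // 2), values, values[-1:].repeat(window // 2)])
    return np.convolve(padded, kernel, mode="valid")


def generate_patient(
    profile: list[tuple[StateSpec, int]], fs: float, seed: int
) -> SyntheticPatient:
    """Generate a whole synthetic subject from an ordered state profile.

    ``profile`` is a list of ``(StateSpec, minutes)``; segments are
    concatenated with a short cross-fade.  The per-minute reference index
    is drawn inside each state's ``ref_index_range`` with jitter, smoothed
    with a 3-minute moving average, then clipped back into each state's
    index band so labels stay consistent with the index.
    """
    if not profile:
        raise ValueError("profile must contain at least one (StateSpec, minutes) entry")
    total_minutes = sum(m for _, m in profile)
    if total_minutes < 2:
        raise ValueError("profile must cover at least 2 minutes")

    rng = np.random.default_rng(seed)
    segments: list[np.ndarray] = []
    labels: list[str] = []
    raw_index: list[float] = []
    for i, (spec, minutes) in enumerate(profile):
        if minutes <= 0:
            raise ValueError("each profile entry needs a positive minute count")
        seg_seed = int(rng.integers(0, 2**31 - 1))
        seg = generate_state_eeg(spec, minutes * 60.0, fs, seg_seed).samples
        segments.append(seg)
        labels.extend([spec.state] * minutes)
        lo, hi = spec.ref_index_range
        mid, half = (lo + hi) / 2.0, (hi - lo) / 2.0
        draws = mid + rng.uniform(-1, 1, size=minutes) * half * 0.8
        raw_index.extend(draws.tolist())

    # cross-fade 1 s at each boundary for smooth transitions
    fade = int(fs)
    out = segments[0]
    for seg in segments[1:]:
        ramp = np.linspace(0, 1, fade)
        overlap = out[-fade:] * (1 - ramp) + seg[:fade] * ramp
        out = np.concatenate([out[:-fade], overlap, seg[fade:]])
    # keep exact length bookkeeping: each boundary loses `fade` samples
    expected = int(total_minutes * 60 * fs)
    if out.size < expected:
        out = np.concatenate([out, np.full(expected - out.size, out[-1])])
    out = out[:expected]

    smoothed = _smooth_ref_index(np.asarray(raw_index))
    # clip back into each minute's state band so classify_state(ref) == label
    for i, lab in enumerate(labels):
        lo, hi = STATE_INDEX_BANDS[lab]
        smoothed[i] = np.clip(smoothed[i], lo + 0.5 if lo > 0 else lo, hi - 0.5 if hi < 100 else hi)

    record = EegRecord(samples=out, fs=fs, channel_label="SYN patient")
    ref = IndexSeries(values=smoothed, minute_offsets=np.arange(total_minutes))
    return SyntheticPatient(record=record, ref_index=ref, state_labels=labels, seed=seed)


def _eog_waveform(fs: float, rng: np.random.Generator) -> np.ndarray:
    """A smooth ~1 s monophasic deflection; spectral content < 4 Hz."""
    dur = rng.uniform(0.8, 1.4)
    n = int(dur * fs)
    shape = np.hanning(n) ** 2
    amp = rng.uniform(120.0, 250.0) * rng.choice([-1.0, 1.0])
    return amp * shape


def _emg_waveform(fs: float, rms: float, rng: np.random.Generator) -> np.ndarray:
    """A ~0.5 s broadband burst, dominant power above 30 Hz, 10× signal RMS."""
    n = int(0.5 * fs)
    noise = rng.standard_normal(n)
    sos = sps.butter(4, 30.0, btype="highpass", fs=fs, output="sos")
    burst = sps.sosfiltfilt(sos, noise)
    burst *= np.hanning(n)
    sd = burst.std()
    return burst / sd * 10.0 * rms if sd > 0 else burst


def inject_artifacts(
    record: EegRecord,
    eog_rate: float = 0.0,
    emg_rate: float = 0.0,
    outlier_rate: float = 0.0,
    seed: int = 0,
) -> tuple[EegRecord, ArtifactEvents]:
    """Add ocular, muscle, and spike artifacts at the given rates (events/min).

    Event counts are ``round(rate × minutes)`` with uniformly random,
    non-overlapping placement.  Returns the contaminated record together
    with the event timestamps and the untouched clean record, so tests can
    compare artifact removal against ground truth.
    """
    for name, rate in (("eog_rate", eog_rate), ("emg_rate", emg_rate), ("outlier_rate", outlier_rate)):
        if rate < 0:
            raise ValueError(f"{name} must be nonnegative")
    rng = np.random.default_rng(seed)
    x = record.samples.copy()
    n = x.size
    fs = record.fs
    minutes = n / fs / 60.0
    clean_sd = record.samples.std()
    events = ArtifactEvents(clean=record.copy())

    n_eog = int(round(eog_rate * minutes))
    n_emg = int(round(emg_rate * minutes))
    n_out = int(round(outlier_rate * minutes))

    occupied = np.zeros(n, bool)

    def place(length: int) -> int | None:
        for _ in range(200):
            start = int(rng.integers(0, max(n - length, 1)))
            if not occupied[start : start + length].any():
                occupied[start : start + length] = True
                return start
        return None

    for _ in range(n_eog):
        wf = _eog_waveform(fs, rng)
        start = place(wf.size)
        if start is not None:
            x[start : start + wf.size] += wf
            events.eog.append(start / fs)
    for _ in range(n_emg):
        wf = _emg_waveform(fs, clean_sd, rng)
        start = place(wf.size)
        if start is not None:
            x[start : start + wf.size] += wf
            events.emg.append(start / fs)
    for _ in range(n_out):
        start = place(1)
        if start is not None:
            x[start] += 10.0 * clean_sd * rng.choice([-1.0, 1.0])
            events.outliers.append(start)

    events.eog.sort()
    events.emg.sort()
    events.outliers.sort()
    return record.copy(samples=x), events
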