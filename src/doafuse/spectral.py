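"""Power-spectral and bispectral EEG features.

Three features are computed from each 1-minute epoch:

* **BetaRatio (BR)** — ``log10( SP(30–47 Hz) / SP(11–20 Hz) )``, the log
  ratio of high-beta/gamma to spindle-band spectral power.  It rises with
  high-frequency activity and is most informative near the awake end of
  the scale.
* **SEF95** — the frequency below which 95% of the 0.5–47 Hz spectral
  power lies.  It slides downward as anesthesia deepens and cortical
  rhythms slow.
* **SynchFastSlow (SFS)** — ``log10`` of the ratio of summed bispectral
  magnitude over the 0.5–47 Hz bifrequency region to the 40–47 Hz region.
  The bispectrum ``B(f1,f2) = E[X(f1) X(f2) X*(f1+f2)]`` is estimated by
  the direct (FFT segment-averaging) method and is sensitive to quadratic
  phase coupling, which grows under anesthesia.

Band ranges are interpreted as constraints on the bifrequency sum
``f1 + f2`` for SFS, and band sums are inclusive of bins whose center
falls in ``[lo, hi]``.  All three features, like PE, are invariant under
amplitude scaling of the input.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .entropy import PeConfig, pe_per_minute
from .preprocess import Epoch

__all__ = [
    "PowerSpectrum",
    "Bispectrum",
    "SpectralConfig",
    "FeatureVector",
    "welch_psd",
    "band_power",
    "beta_ratio",
    "sef95",
    "bispectrum_direct",
    "synch_fast_slow",
    "extract_features",
]

ANALYSIS_BAND = (0.5, 47.0)
BR_NUM_BAND = (30.0, 47.0)
BR_DEN_BAND = (11.0, 20.0)
SFS_NUM_BAND = (0.5, 47.0)
SFS_DEN_BAND = (40.0, 47.0)


@dataclass
class PowerSpectrum:
    freqs: np.ndarray
    psd: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, float)
        self.psd = np.asarray(self.psd, float)
        if self.freqs.shape != self.psd.shape:
            raise ValueError("freqs and psd must have equal shape")
        if np.any(self.psd < 0):
            raise ValueError("psd must be nonnegative")
        if self.freqs.size > 1 and np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be strictly increasing")

    @property
    def resolution(self) -> float:
        return float(self.freqs[1] - self.freqs[0]) if self.freqs.size > 1 else 0.0


@dataclass
class Bispectrum:
    """Direct-method bispectral magnitude on the principal domain.

    ``magnitude[i, j]`` is ``|B(f1_grid[i], f2_grid[j])|`` for the
    principal triangular region ``0 ≤ f2 ≤ f1``, ``f1 + f2 ≤ Nyquist``;
    entries outside the region are NaN.
    """

    f1_grid: np.ndarray
    f2_grid: np.ndarray
    magnitude: np.ndarray
    n_segments: int

    def valid_mask(self) -> np.ndarray:
        return np.isfinite(self.magnitude)


@dataclass
class SpectralConfig:
    """Estimator parameters.

    Welch: 4-s Hann segments with 50% overlap (0.25 Hz resolution inside a
    1-min epoch).  Bispectrum: 256-sample (2.56 s at 100 Hz) Hann segments
    with 50% overlap.  ``power_floor`` guards the log ratios against empty
    bands; ``sfs_cap`` is the value reported when the SFS denominator sits
    at the floor.
    """

    welch_segment_s: float = 4.0
    welch_overlap: float = 0.5
    window: str = "hann"
    bispec_segment: int = 256
    bispec_overlap: float = 0.5
    power_floor: float = 1e-12
    sfs_cap: float = 12.0

    def __post_init__(self) -> None:
        if not 0 <= self.welch_overlap < 1 or not 0 <= self.bispec_overlap < 1:
            raise ValueError("overlaps must lie in [0, 1)")


@dataclass
class FeatureVector:
    """The four per-minute inputs to the fusion model."""

    pe: float
    br: float
    sef95: float
    sfs: float
    minute_index: int = 0
    flags: set[str] = field(default_factory=set)

    def as_array(self) -> np.ndarray:
        return np.array([self.pe, self.br, self.sef95, self.sfs], float)

    FEATURE_NAMES = ("pe", "br", "sef95", "sfs")


def welch_psd(samples: np.ndarray, fs: float, config: SpectralConfig | None = None) -> PowerSpectrum:
    """Welch averaged modified periodogram (density scaling)."""
    config = config or SpectralConfig()
    x = np.asarray(samples, float)
    nperseg = min(int(config.welch_segment_s * fs), x.size)
    noverlap = int(nperseg * config.welch_overlap)
    freqs, psd = sps.welch(
        x, fs=fs, window=config.window, nperseg=nperseg, noverlap=noverlap, detrend=False
    )
    return PowerSpectrum(freqs=freqs, psd=psd, fs=fs)


def band_power(spectrum: PowerSpectrum, band: tuple[float, float]) -> float:
    """Sum of PSD bins with centers inside ``[lo, hi]`` (inclusive), × Δf."""
    lo, hi = band
    sel = (spectrum.freqs >= lo) & (spectrum.freqs <= hi)
    return float(spectrum.psd[sel].sum() * (spectrum.resolution or 1.0))


def beta_ratio(
    spectrum: PowerSpectrum, power_floor: float = 1e-12
) -> tuple[float, set[str]]:
    """BetaRatio ``log10(SP(30–47)/SP(11–20))`` with a floor on both sums."""
    if spectrum.freqs[-1] < BR_NUM_BAND[1]:
        raise ValueError("spectrum does not cover 11–47 Hz")
    num = max(band_power(spectrum, BR_NUM_BAND), power_floor)
    den = max(band_power(spectrum, BR_DEN_BAND), power_floor)
    flags: set[str] = set()
    if num == power_floor and den == power_floor:
        return 0.0, {"br_degenerate"}
    if num == power_floor or den == power_floor:
        flags.add("br_floor")
    return float(np.log10(num / den)), flags


def sef95(
    spectrum: PowerSpectrum, band: tuple[float, float] = ANALYSIS_BAND, quantile: float = 0.95
) -> float:
    """Spectral edge frequency: the ``quantile`` point of in-band power.

    Linear interpolation between bin centers; a spectrum with no in-band
    power returns the lower band edge.
    """
    lo, hi = band
    sel = (spectrum.freqs >= lo) & (spectrum.freqs <= hi)
    f = spectrum.freqs[sel]
    p = spectrum.psd[sel]
    total = p.sum()
    if total <= 0 or f.size == 0:
        return float(lo)
    cum = np.cumsum(p) / total
    i = int(np.searchsorted(cum, quantile))
    if i == 0:
        return float(f[0])
    if i >= f.size:
        return float(f[-1])
    # interpolate inside the bin that crosses the quantile
    c0, c1 = cum[i - 1], cum[i]
    frac = (quantile - c0) / (c1 - c0) if c1 > c0 else 0.0
    return float(f[i - 1] + frac * (f[i] - f[i - 1]))


def bispectrum_direct(
    samples: np.ndarray, fs: float, config: SpectralConfig | None = None
) -> Bispectrum:
    """Direct-method bispectrum estimate on the principal domain.

    Per Hann-windowed segment ``s``: ``B_s(f1, f2) = X_s(f1) X_s(f2)
    X_s*(f1 + f2)``; the magnitude of the segment average is reported for
    ``0 ≤ f2 ≤ f1`` with ``f1 + f2 ≤`` Nyquist.  Averaging over segments
    preserves phase-coupled triads (whose ``B_s`` align in phase) while
    incoherent background averages toward zero.
    """
    config = config or SpectralConfig()
    x = np.asarray(samples, float)
    nseg = config.bispec_segment
    step = max(int(nseg * (1 - config.bispec_overlap)), 1)
    n_segments = (x.size - nseg) // step + 1 if x.size >= nseg else 0
    if n_segments < 2:
        raise ValueError(
            f"signal of length {x.size} yields {n_segments} segments of {nseg}; need ≥ 2"
        )
    window = np.hanning(nseg)
    nfreq = nseg // 2 + 1
    acc = np.zeros((nfreq, nfreq), complex)
    i1 = np.arange(nfreq)[:, None]
    i2 = np.arange(nfreq)[None, :]
    isum = i1 + i2
    valid = (i2 <= i1) & (isum < nfreq)
    i_sum_safe = np.where(valid, isum, 0)
    for s in range(n_segments):
        seg = x[s * step : s * step + nseg]
        seg = (seg - seg.mean()) * window
        X = np.fft.rfft(seg)
        acc += np.where(valid, np.outer(X, X) * np.conj(X[i_sum_safe]), 0)
    mag = np.abs(acc / n_segments)
    mag[~valid] = np.nan
    freqs = np.fft.rfftfreq(nseg, d=1.0 / fs)
    return Bispectrum(f1_grid=freqs, f2_grid=freqs, magnitude=mag, n_segments=n_segments)


def _region_sum(bispec: Bispectrum, band: tuple[float, float]) -> float:
    """Sum of |B| over principal-domain pairs with ``f1+f2`` in ``[lo, hi]``."""
    lo, hi = band
    fsum = bispec.f1_grid[:, None] + bispec.f2_grid[None, :]
    sel = bispec.valid_mask() & (fsum >= lo) & (fsum <= hi)
    return float(bispec.magnitude[sel].sum())


def synch_fast_slow(
    bispec: Bispectrum, power_floor: float = 1e-12, cap: float = 12.0
) -> tuple[float, set[str]]:
    """SFS = log10 of the 0.5–47 Hz to 40–47 Hz bifrequency-sum ratio.

    The denominator region is a subset of the numerator region, so
    SFS ≥ 0 always.  A denominator at the floor (no fast bispectral
    content) returns the configured cap with a flag.
    """
    num = _region_sum(bispec, SFS_NUM_BAND)
    den = _region_sum(bispec, SFS_DEN_BAND)
    flags: set[str] = set()
    if num <= power_floor and den <= power_floor:
        return 0.0, {"sfs_degenerate"}
    if den <= power_floor:
        return cap, {"sfs_floor"}
    return float(np.log10(max(num, power_floor) / den)), flags


def extract_features(
    epoch: Epoch,
    pe_config: PeConfig | None = None,
    spec_config: SpectralConfig | None = None,
) -> FeatureVector:
    """Compute the (PE, BR, SEF95, SFS) feature vector for one epoch."""
    pe_config = pe_config or PeConfig()
    spec_config = spec_config or SpectralConfig()
    fs = 100.0
    flags: set[str] = set(epoch.quality_flags)

    if np.ptp(epoch.samples) == 0:
        # flat epoch: every estimator is degenerate
        return FeatureVector(
            pe=0.0, br=0.0, sef95=ANALYSIS_BAND[0], sfs=0.0,
            minute_index=epoch.minute_index,
            flags=flags | {"degenerate", "br_degenerate", "sfs_degenerate"},
        )

    pe = pe_per_minute(epoch, pe_config)
    spectrum = welch_psd(epoch.samples, fs, spec_config)
    br, br_flags = beta_ratio(spectrum, spec_config.power_floor)
    edge = sef95(spectrum)
    bispec = bispectrum_direct(epoch.samples, fs, spec_config)
    sfs, sfs_flags = synch_fast_slow(bispec, spec_config.power_floor, spec_config.sfs_cap)
    return FeatureVector(
        pe=pe, br=br, sef95=edge, sfs=sfs,
        minute_index=epoch.minute_index,
        flags=flags | br_flags | sfs_flags,
    )
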