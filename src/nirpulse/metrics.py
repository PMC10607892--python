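"""Evaluation metrics: spectral SNR, Pearson correlation, heart-rate AER.

The spectral SNR splits the unwindowed Fourier magnitude spectrum of a
pulse signal into a "Signal" band (0.5-15 Hz) and a "Noise" band (above
15 Hz up to Nyquist) and reports 20 log10 of the root-sum-square ratio.
AER is the absolute heart-rate error relative to a ground-truth rate, in
percent.  Correlation is the ordinary Pearson coefficient against a
reference pulse-meter signal resampled onto the camera frame grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.signal
import scipy.stats

from .errors import InputError
from .signal_processing import PulseSignal

__all__ = [
    "MetricsReport",
    "snr_spectral",
    "spectral_peak_contrast",
    "pearson_correlation",
    "absolute_error_rate",
    "align_reference",
]


@dataclass(frozen=True)
class MetricsReport:
    """Per-(method, stage) evaluation mirroring a results-table row."""

    method: str
    stage: str
    correlation: float
    snr_db: float
    snr_unbounded: bool = False
    aer_percent: float | None = None
    hr_estimated: float | None = None
    hr_reference: float | None = None

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "stage": self.stage,
            "correlation": self.correlation,
            "snr_db": None if self.snr_unbounded else self.snr_db,
            "snr_unbounded": self.snr_unbounded,
            "aer_percent": self.aer_percent,
            "hr_estimated": self.hr_estimated,
            "hr_reference": self.hr_reference,
        }


def _band_rss(mag: np.ndarray, freqs: np.ndarray, lo: float, hi: float,
              lo_open: bool = False) -> float:
    if lo_open:
        mask = (freqs > lo) & (freqs <= hi)
    else:
        mask = (freqs >= lo) & (freqs <= hi)
    return float(np.sqrt(np.sum(mag[mask] ** 2)))


def _magnitude_spectrum(x: PulseSignal, taper_alpha: float) -> tuple[np.ndarray, np.ndarray]:
    values = x.values
    if taper_alpha > 0:
        values = values * scipy.signal.windows.tukey(x.n, taper_alpha)
    mag = np.abs(np.fft.rfft(values))
    freqs = np.fft.rfftfreq(x.n, d=1.0 / x.frame_rate)
    return mag, freqs


def snr_spectral(
    x: PulseSignal,
    signal_band: tuple[float, float] = (0.5, 15.0),
    noise_band_start: float = 15.0,
    taper_alpha: float = 0.1,
) -> float:
    """Spectral SNR in dB: 20 log10(rss of signal band / rss of noise band).

    The spectrum is the DFT magnitude of the full signal after a light
    Tukey edge taper (``taper_alpha`` fraction of the record; 0 disables
    it).  Without the taper the noise band of a filtered record is
    dominated by the boundary transients of detrending and zero-phase
    filtering — a handful of effective degrees of freedom that swamp the
    quantity of interest.  The DC bin and frequencies below the signal
    band belong to neither band.  Returns +inf when the noise band is
    numerically empty (below the taper's own leakage floor).
    """
    nyquist = x.frame_rate / 2.0
    if nyquist <= noise_band_start:
        raise InputError(
            f"Nyquist {nyquist} Hz must exceed noise_band_start {noise_band_start} Hz"
        )
    mag, freqs = _magnitude_spectrum(x, taper_alpha)
    signal = _band_rss(mag, freqs, signal_band[0], signal_band[1])
    noise = _band_rss(mag, freqs, noise_band_start, nyquist, lo_open=True)
    if noise <= 1e-5 * signal:  # numerically zero noise band
        return math.inf
    return float(20.0 * np.log10(signal / noise))


def spectral_peak_contrast(
    x: PulseSignal, band: tuple[float, float] = (0.5, 15.0), taper_alpha: float = 0.1
) -> float:
    """Peak-to-median ratio of the magnitude spectrum within a band.

    A dominant cardiac peak yields a large ratio; a pulse buried in
    broadband noise yields a ratio near the Rayleigh-statistics level of
    pure noise (about 1-3).
    """
    mag, freqs = _magnitude_spectrum(x, taper_alpha)
    mask = (freqs >= band[0]) & (freqs <= band[1])
    if not np.any(mask):
        raise InputError("band contains no spectral bins")
    band_mag = mag[mask]
    med = float(np.median(band_mag))
    if med == 0.0:
        return math.inf
    return float(band_mag.max() / med)


def pearson_correlation(a: PulseSignal, b: PulseSignal) -> float:
    """Signed Pearson product-moment correlation of two equal-length signals."""
    if a.n != b.n:
        raise InputError(f"signal lengths differ: {a.n} vs {b.n}")
    if a.n < 2:
        raise InputError("correlation needs >= 2 samples")
    if np.ptp(a.values) == 0 or np.ptp(b.values) == 0:
        raise InputError("correlation undefined for a constant signal")
    r = scipy.stats.pearsonr(a.values, b.values).statistic
    return float(r)


def absolute_error_rate(hr_gt: float, hr_ev: float) -> float:
    """AER in percent: |HR_gt - HR_ev| / HR_gt * 100."""
    if hr_gt <= 0:
        raise InputError(f"ground-truth heart rate must be positive, got {hr_gt}")
    return float(abs(hr_gt - hr_ev) / hr_gt * 100.0)


def align_reference(
    ref_values: np.ndarray,
    ref_rate: float,
    target_rate: float,
    duration_s: float,
) -> PulseSignal:
    """Resample a reference pulse-meter series onto the camera frame grid.

    Linear interpolation onto floor(duration_s * target_rate) frames; the
    reference must cover the requested duration.
    """
    if ref_rate <= 0 or target_rate <= 0:
        raise InputError("sampling rates must be positive")
    ref_values = np.asarray(ref_values, dtype=float).ravel()
    ref_t = np.arange(ref_values.size) / ref_rate
    n_out = int(np.floor(duration_s * target_rate + 1e-9))
    out_t = np.arange(n_out) / target_rate
    if ref_t[-1] < out_t[-1] - 1e-9:
        raise InputError(
            f"reference covers {ref_t[-1]:.3f} s < requested {out_t[-1]:.3f} s"
        )
    values = np.interp(out_t, ref_t, ref_values)
    return PulseSignal(values=values, frame_rate=target_rate, stage="raw")
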