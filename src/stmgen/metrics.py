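"""Spectral-envelope metrics and cross-method comparison diagnostics.

For pure spectral modulation the modulation envelope is inscribed directly
into the magnitude spectrum, so envelope fidelity can be quantified on the
in-band DFT magnitudes: the normalized fourth moment measures fluctuation
strength, the crest factor measures extrema.  A short-time spectrogram
power ratio compares two renderings of the same stimulus bin by bin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as _signal

__all__ = [
    "SpectralEnvelope",
    "spectrum",
    "normalized_fourth_moment",
    "crest_factor",
    "spectrogram_power_ratio",
]


@dataclass(frozen=True)
class SpectralEnvelope:
    """Non-negative magnitude values per analysis frequency."""

    frequency_hz: np.ndarray
    magnitude: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.frequency_hz, dtype=float)
        e = np.asarray(self.magnitude, dtype=float)
        if f.shape != e.shape:
            raise ValueError("frequency and magnitude arrays must match in shape")
        if np.any(e < 0):
            raise ValueError("magnitudes must be non-negative")
        object.__setattr__(self, "frequency_hz", f)
        object.__setattr__(self, "magnitude", e)

    def __len__(self) -> int:
        return len(self.magnitude)


def spectrum(
    waveform: np.ndarray,
    sample_rate: float,
    band: tuple[float, float] | None = None,
) -> SpectralEnvelope:
    """Magnitude of the full-length DFT, restricted to an analysis band.

    No smoothing is applied; band limits are inclusive.
    """
    waveform = np.asarray(waveform, dtype=float)
    if waveform.ndim != 1 or waveform.size < 2:
        raise ValueError("waveform must be a 1-D array of length >= 2")
    mag = np.abs(np.fft.rfft(waveform))
    freqs = np.fft.rfftfreq(waveform.size, d=1.0 / sample_rate)
    if band is not None:
        lo, hi = band
        keep = (freqs >= lo) & (freqs <= hi)
        if not np.any(keep):
            raise ValueError(f"no DFT bins inside the band {band}")
        freqs, mag = freqs[keep], mag[keep]
    return SpectralEnvelope(freqs, mag)


def _magnitudes(env) -> np.ndarray:
    e = env.magnitude if isinstance(env, SpectralEnvelope) else np.asarray(env, dtype=float)
    if e.size == 0 or not np.any(e):
        raise ValueError("envelope is empty or all zero")
    return e


def normalized_fourth_moment(env) -> float:
    """``mean(E**4) / mean(E**2)**2`` of a magnitude envelope.

    Scale-invariant; equals 1 iff the envelope is constant, 2 for Rayleigh
    magnitudes, and grows with the depth of spectral fluctuation.
    """
    e = _magnitudes(env)
    # factor out the scale first so fourth powers cannot overflow
    e = e / np.max(e)
    return float(np.mean(e**4) / np.mean(e**2) ** 2)


def crest_factor(env) -> float:
    """Peak-to-RMS ratio of a magnitude envelope (>= 1)."""
    e = _magnitudes(env)
    return float(np.max(e) / np.sqrt(np.mean(np.square(e))))


def spectrogram_power_ratio(
    waveform_a: np.ndarray,
    waveform_b: np.ndarray,
    sample_rate: float,
    window_len: int = 1024,
    hop: int | None = None,
    floor_rel: float = 1e-12,
):
    """Short-time power ratio ``10*log10(P_a / P_b)`` of two waveforms.

    Both signals are analysed with the same Hann window (default length
    1024, 50% hop).  Bins where *both* powers fall below ``floor_rel``
    times the global maximum are masked to NaN instead of reported as
    huge or infinite ratios.  Returns ``(freqs, times, ratio_db)``.
    """
    a = np.asarray(waveform_a, dtype=float)
    b = np.asarray(waveform_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("waveforms must have equal length")
    if hop is None:
        hop = window_len // 2
    freqs, times, p_a = _signal.spectrogram(
        a, fs=sample_rate, window="hann", nperseg=window_len,
        noverlap=window_len - hop, mode="psd",
    )
    _, _, p_b = _signal.spectrogram(
        b, fs=sample_rate, window="hann", nperseg=window_len,
        noverlap=window_len - hop, mode="psd",
    )
    floor = floor_rel * max(float(np.max(p_a)), float(np.max(p_b)))
    masked = (p_a < floor) & (p_b < floor)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio_db = 10.0 * np.log10(p_a / p_b)
    ratio_db[masked] = np.nan
    return freqs, times, ratio_db
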