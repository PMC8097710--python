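"""WAV reading and writing (mono, float32 or 16-bit PCM)."""

from __future__ import annotations

import numpy as np
from scipy.io import wavfile

__all__ = ["write_wav", "read_wav", "ClippingError"]


class ClippingError(ValueError):
    """Raised when PCM export would clip; carries the offending peak."""

    def __init__(self, peak: float):
        self.peak = peak
        super().__init__(
            f"waveform peak {peak:.6g} exceeds full scale 1.0; "
            "normalize before 16-bit PCM export"
        )


def write_wav(path, waveform: np.ndarray, sample_rate: float, pcm16: bool = False) -> None:
    """Write a mono WAV file.

    Default subtype is 32-bit float (no quantization).  With ``pcm16`` the
    samples are scaled by 32767 and must already lie within [-1, 1];
    otherwise :class:`ClippingError` is raised rather than silently wrapping.
    """
    waveform = np.asarray(waveform, dtype=float)
    if pcm16:
        peak = float(np.max(np.abs(waveform))) if waveform.size else 0.0
        if peak > 1.0:
            raise ClippingError(peak)
        data = np.round(waveform * 32767.0).astype(np.int16)
    else:
        data = waveform.astype(np.float32)
    wavfile.write(str(path), int(round(sample_rate)), data)


def read_wav(path) -> tuple[int, np.ndarray]:
    """Read a mono WAV; returns (sample_rate, float array).

    16-bit PCM data is rescaled to [-1, 1]; float data is returned as-is.
    """
    sr, data = wavfile.read(str(path))
    if data.dtype == np.int16:
        data = data.astype(np.float64) / 32767.0
    else:
        data = data.astype(np.float64)
    return sr, data
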