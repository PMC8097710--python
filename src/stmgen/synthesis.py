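"""Carrier expansion and waveform rendering.

Two renderers produce the same stimulus:

* :func:`render_frequency_domain` — bind the sideband template to each
  carrier, accumulate every resulting pure tone into a half-spectrum as a
  complex phasor, and run **one** inverse DFT.  This is the fast path.
* :func:`render_explicit` — evaluate carrier-times-modulator sample by
  sample.  Slow, but exact; it is the ground-truth oracle the sideband
  path is validated against.

All tones follow the sine convention ``a * sin(2*pi*f*t + p)`` with
``t = 0 .. (n_samples-1)/sample_rate``, identical for both renderers so the
outputs are sample-aligned.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .sidebands import (
    Depth,
    ExponentialDepth,
    LinearDepth,
    SidebandTemplate,
    energy_deficiency_db,
    exponential_template,
    linear_template,
    resolve_extent,
)

__all__ = [
    "CarrierSet",
    "ModulationParams",
    "RenderConfig",
    "ComponentSet",
    "RenderResult",
    "envelope_phase",
    "expand_carriers",
    "render_frequency_domain",
    "render_explicit",
    "rms_normalize",
    "synthesize",
]

logger = logging.getLogger(__name__)

_F_EPS = 1e-9  # Hz below which a component frequency counts as DC


@dataclass(frozen=True)
class CarrierSet:
    """The stationary carrier tones of a multi-tone noise.

    Arrays of equal length ``N >= 1``: frequencies (Hz, > 0), non-negative
    linear amplitudes, and phases (radians).
    """

    frequency_hz: np.ndarray
    amplitude: np.ndarray
    phase_rad: np.ndarray

    def __post_init__(self) -> None:
        f = np.atleast_1d(np.asarray(self.frequency_hz, dtype=float))
        a = np.atleast_1d(np.asarray(self.amplitude, dtype=float))
        p = np.atleast_1d(np.asarray(self.phase_rad, dtype=float))
        if not (len(f) == len(a) == len(p)) or len(f) < 1:
            raise ValueError("carrier arrays must share a common length >= 1")
        if np.any(f <= 0):
            raise ValueError("carrier frequencies must be positive")
        if np.any(a < 0):
            raise ValueError("carrier amplitudes must be non-negative")
        object.__setattr__(self, "frequency_hz", f)
        object.__setattr__(self, "amplitude", a)
        object.__setattr__(self, "phase_rad", p)

    def __len__(self) -> int:
        return len(self.frequency_hz)


@dataclass(frozen=True)
class ModulationParams:
    """Definition of the modulator ``M(f, t)``.

    ``kind`` selects exponential (``10**((m/20)*sin(...))``), linear
    (``1 + m*sin(...)``) or no modulation.  ``rate_hz`` is the temporal
    modulation rate ``omega`` (0 for pure spectral modulation);
    ``density_cpo`` the spectral density ``Omega`` in cycles per octave
    (0 for pure temporal modulation); ``phase0_rad`` the global envelope
    phase; ``ref_hz`` the reference frequency receiving exactly that phase.
    """

    kind: str = "exponential"
    depth: Depth | None = None
    rate_hz: float = 0.0
    density_cpo: float = 0.0
    phase0_rad: float = 0.0
    ref_hz: float = 1000.0

    def __post_init__(self) -> None:
        if self.kind not in ("exponential", "linear", "none"):
            raise ValueError(f"unknown modulator kind {self.kind!r}")
        if self.rate_hz < 0 or self.density_cpo < 0:
            raise ValueError("rate_hz and density_cpo must be >= 0")
        if self.ref_hz <= 0:
            raise ValueError("ref_hz must be positive")
        if self.kind == "exponential" and not isinstance(self.depth, ExponentialDepth):
            raise TypeError("exponential modulation requires an ExponentialDepth")
        if self.kind == "linear" and not isinstance(self.depth, LinearDepth):
            raise TypeError("linear modulation requires a LinearDepth")

    def envelope_phase(self, f) -> np.ndarray:
        return envelope_phase(f, self)


def envelope_phase(f, params: ModulationParams) -> np.ndarray:
    """Envelope phase ``Phi(f) = 2*pi*Omega*log2(f/f0) + Phi0`` (radians)."""
    f = np.asarray(f, dtype=float)
    if np.any(f <= 0):
        raise ValueError("envelope phase is defined for positive frequencies only")
    return 2.0 * math.pi * params.density_cpo * np.log2(f / params.ref_hz) + params.phase0_rad


@dataclass(frozen=True)
class RenderConfig:
    """Render settings shared by both synthesis paths."""

    sample_rate: float
    n_samples: int
    method: str = "sideband"            # "sideband" | "explicit"
    extent: int | None = None           # sideband extent K ...
    tolerance_db: float | None = None   # ... or an energy-deficiency tolerance
    normalize_dbfs: float | None = None # target RMS in dB FS; None = no scaling
    grid_policy: str = "strict"         # "strict" | "quantize"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.method not in ("sideband", "explicit"):
            raise ValueError(f"unknown render method {self.method!r}")
        if self.grid_policy not in ("strict", "quantize"):
            raise ValueError(f"unknown grid policy {self.grid_policy!r}")

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate

    @classmethod
    def from_duration(cls, sample_rate: float, duration_s: float, **kw) -> "RenderConfig":
        return cls(sample_rate=sample_rate, n_samples=round(sample_rate * duration_s), **kw)


@dataclass(frozen=True)
class ComponentSet:
    """Flat list of pure sine components ready for spectral assembly.

    Amplitudes are non-negative (sign folded into the phase); provenance
    columns record which carrier and which template entry produced each
    component.
    """

    frequency_hz: np.ndarray
    amplitude: np.ndarray
    phase_rad: np.ndarray
    carrier_index: np.ndarray
    offset_k: np.ndarray
    side: np.ndarray

    def __len__(self) -> int:
        return len(self.frequency_hz)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "carrier_index": self.carrier_index,
                "k": self.offset_k,
                "side": self.side,
                "frequency_hz": self.frequency_hz,
                "amplitude": self.amplitude,
                "phase_rad": self.phase_rad,
            }
        )

    @classmethod
    def from_carriers(cls, carriers: CarrierSet) -> "ComponentSet":
        n = len(carriers)
        return cls(
            frequency_hz=carriers.frequency_hz.copy(),
            amplitude=carriers.amplitude.copy(),
            phase_rad=carriers.phase_rad.copy(),
            carrier_index=np.arange(n),
            offset_k=np.zeros(n, dtype=int),
            side=np.full(n, "base"),
        )


def _build_template(params: ModulationParams, extent: int | None,
                    tolerance_db: float | None) -> SidebandTemplate:
    if params.kind == "linear":
        return linear_template(params.depth)
    k = resolve_extent(params.depth, extent, tolerance_db)
    return exponential_template(params.depth, k)


def expand_carriers(
    carriers: CarrierSet,
    params: ModulationParams,
    template: SidebandTemplate | None = None,
    *,
    extent: int | None = None,
    tolerance_db: float | None = None,
) -> ComponentSet:
    """Bind a sideband template to every carrier.

    Each template entry applied to carrier ``n`` yields a component at
    ``f_n + side*k*omega`` with amplitude ``A_n * |amp_factor|`` and phase
    ``phi_n + env_coeff*Phi(f_n) + quad_phase`` (plus ``pi`` when the
    amplitude factor is negative).  Components whose frequency falls below
    zero are algebraically reflected, ``sin(-2*pi*f*t + p) ==
    sin(2*pi*f*t + pi - p)``; exact-DC components vanish and are dropped.
    With ``omega = 0`` all entries of a carrier collapse onto ``f_n`` and
    are combined by phasor summation into a single component.
    """
    if params.kind == "none" or (
        isinstance(params.depth, ExponentialDepth) and params.depth.depth_db == 0
    ) or (isinstance(params.depth, LinearDepth) and params.depth.m == 0):
        return ComponentSet.from_carriers(carriers)

    if template is None:
        template = _build_template(params, extent, tolerance_db)
    elif template.kind != params.kind:
        raise ValueError(
            f"template kind {template.kind!r} does not match params kind {params.kind!r}"
        )

    f = carriers.frequency_hz
    a = carriers.amplitude
    phi = carriers.phase_rad
    env = envelope_phase(f, params)
    n = len(carriers)

    if params.rate_hz == 0.0:
        # Pure spectral modulation: every entry lands on the carrier
        # frequency; the phasor sum is the truncated modulator value.
        z = np.zeros(n, dtype=complex)
        for e in template.entries:
            z += e.amp_factor * np.exp(1j * (phi + e.env_coeff * env + e.quad_phase))
        return ComponentSet(
            frequency_hz=f.copy(),
            amplitude=a * np.abs(z),
            phase_rad=np.angle(z),
            carrier_index=np.arange(n),
            offset_k=np.zeros(n, dtype=int),
            side=np.full(n, "base"),
        )

    freqs, amps, phases, c_idx, ks, sides = [], [], [], [], [], []
    for e in template.entries:
        comp_f = f + e.side_sign * e.k * params.rate_hz
        comp_p = phi + e.env_coeff * env + e.quad_phase
        comp_a = a * abs(e.amp_factor)
        if e.amp_factor < 0:
            comp_p = comp_p + math.pi
        freqs.append(comp_f)
        amps.append(comp_a)
        phases.append(comp_p)
        c_idx.append(np.arange(n))
        ks.append(np.full(n, e.k))
        sides.append(np.full(n, e.side))

    freq = np.concatenate(freqs)
    amp = np.concatenate(amps)
    phase = np.concatenate(phases)
    cidx = np.concatenate(c_idx)
    kk = np.concatenate(ks)
    sd = np.concatenate(sides)

    dc = np.abs(freq) < _F_EPS
    if np.any(dc):
        logger.warning("dropping %d DC component(s) produced by sideband reflection",
                       int(np.sum(dc)))
        keep = ~dc
        freq, amp, phase, cidx, kk, sd = (
            x[keep] for x in (freq, amp, phase, cidx, kk, sd)
        )
    neg = freq < 0
    if np.any(neg):
        logger.warning("reflecting %d negative-frequency sideband(s) about 0 Hz",
                       int(np.sum(neg)))
        phase = np.where(neg, math.pi - phase, phase)
        freq = np.abs(freq)

    phase = np.mod(phase + math.pi, 2.0 * math.pi) - math.pi
    return ComponentSet(freq, amp, phase, cidx, kk.astype(int), sd)


def render_frequency_domain(components: ComponentSet, config: RenderConfig) -> np.ndarray:
    """Assemble components into a half-spectrum and inverse-transform once.

    A component ``a*sin(2*pi*f*t + p)`` on DFT bin ``b`` contributes the
    phasor ``a * exp(1j*(p - pi/2)) * n/2`` so that the real inverse DFT
    reproduces the sine exactly for on-bin frequencies.  ``strict`` grid
    policy requires every frequency to sit on a bin and below Nyquist;
    ``quantize`` rounds to the nearest bin (worst-case error logged) and
    drops out-of-range components with a warning.
    """
    n = config.n_samples
    sr = config.sample_rate
    df = sr / n
    max_bin = (n - 1) // 2  # highest bin strictly below Nyquist

    b_float = components.frequency_hz / df
    b = np.rint(b_float).astype(int)
    if config.grid_policy == "strict":
        off = np.abs(b_float - b)
        if np.any(off > 1e-6):
            worst = float(np.max(off) * df)
            raise ValueError(
                f"off-bin component under strict grid policy "
                f"(worst offset {worst:.6g} Hz with bin width {df:.6g} Hz)"
            )
        if np.any((b < 1) | (b > max_bin)):
            raise ValueError("component at DC or at/above Nyquist under strict policy")
        amp, phase = components.amplitude, components.phase_rad
    else:
        err = float(np.max(np.abs(b_float - b) * df)) if len(b) else 0.0
        if err > 1e-9:
            logger.warning("quantized component frequencies to bins "
                           "(max rounding error %.6g Hz)", err)
        keep = (b >= 1) & (b <= max_bin)
        if not np.all(keep):
            logger.warning("dropping %d component(s) at DC or beyond Nyquist",
                           int(np.sum(~keep)))
        b = b[keep]
        amp = components.amplitude[keep]
        phase = components.phase_rad[keep]

    spectrum = np.zeros(n // 2 + 1, dtype=complex)
    np.add.at(spectrum, b, amp * np.exp(1j * (phase - math.pi / 2)) * (n / 2.0))
    return np.fft.irfft(spectrum, n)


def _modulator(params: ModulationParams, t: np.ndarray, env_phase: np.ndarray) -> np.ndarray:
    """Modulator matrix ``M(f_n, t)``; ``env_phase`` is per-carrier Phi(f_n)."""
    theta = 2.0 * math.pi * params.rate_hz * t[None, :] + env_phase[:, None]
    if params.kind == "exponential":
        return 10.0 ** ((params.depth.depth_db / 20.0) * np.sin(theta))
    if params.kind == "linear":
        return 1.0 + params.depth.m * np.sin(theta)
    return np.ones_like(theta)


def render_explicit(
    carriers: CarrierSet, params: ModulationParams, config: RenderConfig,
    chunk: int = 64,
) -> np.ndarray:
    """Direct time-domain evaluation of carrier-times-modulator (the oracle).

    Carriers are processed in chunks to bound memory; with a zero temporal
    rate the modulator is time-constant per carrier and collapses to an
    amplitude scale, which is its exact value in that case.
    """
    t = np.arange(config.n_samples) / config.sample_rate
    out = np.zeros(config.n_samples)
    f, a, phi = carriers.frequency_hz, carriers.amplitude, carriers.phase_rad
    modulated = params.kind in ("exponential", "linear")
    env = envelope_phase(f, params) if modulated else np.zeros(len(f))
    for i in range(0, len(f), chunk):
        sl = slice(i, i + chunk)
        carr = np.sin(2.0 * math.pi * f[sl, None] * t[None, :] + phi[sl, None])
        if not modulated:
            out += a[sl] @ carr
        elif params.rate_hz == 0.0:
            theta = env[sl]
            if params.kind == "exponential":
                m_const = 10.0 ** ((params.depth.depth_db / 20.0) * np.sin(theta))
            else:
                m_const = 1.0 + params.depth.m * np.sin(theta)
            out += (a[sl] * m_const) @ carr
        else:
            out += a[sl] @ (carr * _modulator(params, t, env[sl]))
    return out


def rms_normalize(waveform: np.ndarray, target_rms: float) -> np.ndarray:
    """Scale a waveform to the requested RMS (linear units)."""
    if target_rms <= 0:
        raise ValueError("target RMS must be positive")
    rms = float(np.sqrt(np.mean(np.square(waveform))))
    if rms == 0.0:
        raise ValueError("cannot normalize a silent waveform")
    return waveform * (target_rms / rms)


@dataclass(frozen=True)
class RenderResult:
    """Waveform plus the bookkeeping a caller may want to audit."""

    waveform: np.ndarray
    components: ComponentSet | None
    extent: int | None
    deficiency_db: float | None

    @property
    def rms(self) -> float:
        return float(np.sqrt(np.mean(np.square(self.waveform))))


def synthesize(
    carriers: CarrierSet, params: ModulationParams, config: RenderConfig
) -> RenderResult:
    """Render a stimulus with the method selected in ``config``.

    The sideband path reports the extent used and its energy deficiency;
    optional RMS normalization (``normalize_dbfs`` re 1.0 full scale) is
    applied identically for either method.
    """
    extent = deficiency = components = None
    if config.method == "explicit":
        waveform = render_explicit(carriers, params, config)
    else:
        if params.kind == "exponential":
            extent = resolve_extent(params.depth, config.extent, config.tolerance_db)
            deficiency = energy_deficiency_db(params.depth, extent).deficiency_db
            template = exponential_template(params.depth, extent)
        elif params.kind == "linear":
            extent, template = 1, linear_template(params.depth)
        else:
            template = None
        components = expand_carriers(carriers, params, template)
        waveform = render_frequency_domain(components, config)
    if config.normalize_dbfs is not None:
        waveform = rms_normalize(waveform, 10.0 ** (config.normalize_dbfs / 20.0))
    return RenderResult(waveform, components, extent, deficiency)
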