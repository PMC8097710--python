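"""Noise-carrier design and the spectral-modulation validation sweep.

Builds the carrier populations used to validate the sideband renderer: a
band of on-bin tones with Rayleigh (or equal) amplitudes shaped by a
bandpass roll-off, pure-SM / pure-TM / joint-STM parameter helpers, and a
paired sweep that renders the same exemplar with both the sideband and
explicit methods and measures the spectral-envelope metrics of each.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .metrics import crest_factor, normalized_fourth_moment, spectrum
from .sidebands import ExponentialDepth
from .synthesis import CarrierSet, ModulationParams, RenderConfig, synthesize

__all__ = [
    "NoiseSpec",
    "SweepSpec",
    "generate_noise_carriers",
    "sm_params",
    "tm_params",
    "stm_params",
    "run_validation_sweep",
    "summarize_sweep",
]


@dataclass(frozen=True)
class NoiseSpec:
    """A band of stationary, uncorrelated tones with spectral shaping.

    Unity gain inside ``[band_lo, band_hi]`` Hz; outside, level falls at
    ``slope_db_per_octave`` until ``rolloff_floor_db`` of attenuation, past
    which no carriers are placed.  ``density`` is the fraction of DFT bins
    in the shaped region that receive a carrier (1 = one tone per bin,
    maximum density).
    """

    band_lo: float = 400.0
    band_hi: float = 3200.0
    slope_db_per_octave: float = 32.0
    amplitude_law: str = "rayleigh"     # "rayleigh" | "equal"
    density: float = 1.0
    rolloff_floor_db: float = 60.0

    def __post_init__(self) -> None:
        if not (0 < self.band_lo < self.band_hi):
            raise ValueError("need 0 < band_lo < band_hi")
        if not (0 < self.density <= 1):
            raise ValueError("density must lie in (0, 1]")
        if self.amplitude_law not in ("rayleigh", "equal"):
            raise ValueError(f"unknown amplitude law {self.amplitude_law!r}")
        if self.slope_db_per_octave < 0 or self.rolloff_floor_db < 0:
            raise ValueError("slope and roll-off floor must be >= 0 dB")


def band_gain(f, spec: NoiseSpec) -> np.ndarray:
    """Linear band-shaping gain at frequency ``f`` (0 beyond the floor)."""
    f = np.asarray(f, dtype=float)
    atten_db = np.zeros_like(f)
    below = f < spec.band_lo
    above = f > spec.band_hi
    with np.errstate(divide="ignore"):
        atten_db[below] = spec.slope_db_per_octave * np.log2(spec.band_lo / f[below])
        atten_db[above] = spec.slope_db_per_octave * np.log2(f[above] / spec.band_hi)
    gain = 10.0 ** (-atten_db / 20.0)
    gain[atten_db > spec.rolloff_floor_db] = 0.0
    return gain


def generate_noise_carriers(
    spec: NoiseSpec,
    config: RenderConfig,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> CarrierSet:
    """Draw one carrier per selected on-bin frequency of the shaped band.

    Amplitudes are i.i.d. Rayleigh(scale 1) or all-equal, multiplied by the
    band-shaping gain; phases are i.i.d. uniform on [0, 2*pi).  Fully
    deterministic given a seed or generator.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if spec.band_hi >= config.sample_rate / 2:
        raise ValueError("band must lie below the Nyquist frequency")
    df = config.sample_rate / config.n_samples
    freqs = df * np.arange(1, (config.n_samples - 1) // 2 + 1)
    gain = band_gain(freqs, spec)
    candidate = np.flatnonzero(gain > 0)
    if candidate.size == 0:
        raise ValueError("no DFT bins fall inside the shaped band")
    if spec.density < 1.0:
        n_keep = max(1, round(spec.density * candidate.size))
        candidate = np.sort(rng.choice(candidate, size=n_keep, replace=False))
    f = freqs[candidate]
    base = (
        rng.rayleigh(1.0, size=f.size)
        if spec.amplitude_law == "rayleigh"
        else np.ones(f.size)
    )
    phases = rng.uniform(0.0, 2.0 * np.pi, size=f.size)
    return CarrierSet(f, base * gain[candidate], phases)


def sm_params(
    depth_db: float, density_cpo: float = 2.0, phase0_rad: float = 0.0,
    ref_hz: float = 400.0, kind: str = "exponential",
) -> ModulationParams:
    """Pure spectral modulation: temporal rate 0, ripple across frequency."""
    return _mod_params(kind, depth_db, 0.0, density_cpo, phase0_rad, ref_hz)


def tm_params(
    depth_db: float, rate_hz: float = 4.0, phase0_rad: float = 0.0,
    ref_hz: float = 400.0, kind: str = "exponential",
) -> ModulationParams:
    """Pure temporal modulation: constant envelope phase across frequency."""
    return _mod_params(kind, depth_db, rate_hz, 0.0, phase0_rad, ref_hz)


def stm_params(
    depth_db: float, rate_hz: float = 4.0, density_cpo: float = 2.0,
    phase0_rad: float = 0.0, ref_hz: float = 400.0, kind: str = "exponential",
) -> ModulationParams:
    """Joint spectro-temporal modulation (a moving ripple)."""
    return _mod_params(kind, depth_db, rate_hz, density_cpo, phase0_rad, ref_hz)


def _mod_params(kind, depth_db, rate_hz, density_cpo, phase0_rad, ref_hz):
    from .sidebands import LinearDepth

    depth = (
        ExponentialDepth(depth_db) if kind == "exponential"
        else LinearDepth.from_db(depth_db) if kind == "linear"
        else None
    )
    return ModulationParams(
        kind=kind, depth=depth, rate_hz=rate_hz, density_cpo=density_cpo,
        phase0_rad=phase0_rad, ref_hz=ref_hz,
    )


@dataclass(frozen=True)
class SweepSpec:
    """A paired SM validation sweep over modulation depths.

    ``depths_p2v_db`` are *peak-to-valley* depths in dB (the Eq.-4 depth is
    half of each); every exemplar draws fresh carriers and a fresh envelope
    phase, shared exactly between the methods being compared.
    """

    depths_p2v_db: tuple = tuple(np.linspace(0.0, 50.0, 20))
    n_exemplars: int = 100
    methods: tuple = ("explicit", "sideband")
    density_cpo: float = 2.0
    tolerance_db: float = 1e-8

    def __post_init__(self) -> None:
        if self.n_exemplars < 1:
            raise ValueError("n_exemplars must be >= 1")
        if any(d < 0 for d in self.depths_p2v_db):
            raise ValueError("depths must be non-negative")
        if not set(self.methods) <= {"explicit", "sideband"}:
            raise ValueError("methods must be a subset of {'explicit', 'sideband'}")


def default_sweep_config(**kw) -> RenderConfig:
    """The sweep's default render grid: 1 s at 44.1 kHz, bin-quantized."""
    return RenderConfig(sample_rate=44100.0, n_samples=44100, **kw)


def run_validation_sweep(
    noise: NoiseSpec,
    sweep: SweepSpec,
    config: RenderConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Render every (depth, exemplar, method) cell and measure M4 and CF.

    Each (depth, exemplar) pair spawns its own random stream from the
    master seed, so all requested methods see byte-identical carriers and
    envelope phase and the comparison is fully paired.  Returns a
    long-format table with columns depth_db (peak-to-valley), method,
    exemplar, m4, crest_factor.
    """
    if config is None:
        config = default_sweep_config()
    rows = []
    for d_idx, p2v in enumerate(sweep.depths_p2v_db):
        for ex in range(sweep.n_exemplars):
            ss = np.random.SeedSequence([int(seed), d_idx, ex])
            rng = np.random.default_rng(ss)
            carriers = generate_noise_carriers(noise, config, rng=rng)
            phase0 = float(rng.uniform(0.0, 2.0 * np.pi))
            params = sm_params(
                p2v / 2.0, sweep.density_cpo, phase0, ref_hz=noise.band_lo
            )
            for method in sweep.methods:
                cfg = RenderConfig(
                    sample_rate=config.sample_rate,
                    n_samples=config.n_samples,
                    method=method,
                    tolerance_db=sweep.tolerance_db if method == "sideband" else None,
                    grid_policy=config.grid_policy,
                )
                result = synthesize(carriers, params, cfg)
                env = spectrum(
                    result.waveform, config.sample_rate, (noise.band_lo, noise.band_hi)
                )
                rows.append(
                    {
                        "depth_db": float(p2v),
                        "method": method,
                        "exemplar": ex,
                        "m4": normalized_fourth_moment(env),
                        "crest_factor": crest_factor(env),
                    }
                )
    return pd.DataFrame(rows)


def summarize_sweep(table: pd.DataFrame) -> pd.DataFrame:
    """Per-(depth, method) mean and standard deviation of both metrics."""
    return (
        table.groupby(["depth_db", "method"], as_index=False)
        .agg(
            m4_mean=("m4", "mean"),
            m4_std=("m4", "std"),
            cf_mean=("crest_factor", "mean"),
            cf_std=("crest_factor", "std"),
        )
        .sort_values(["depth_db", "method"], ignore_index=True)
    )
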