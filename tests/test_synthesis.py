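"""Carrier expansion and the two renderers (sideband vs explicit oracle)."""

import math

import numpy as np
import pytest
from scipy.special import iv

from oracles import evaluate_components
from stmgen.sidebands import (
    ExponentialDepth,
    LinearDepth,
    exponential_template,
    min_extent_for_tolerance,
)
from stmgen.synthesis import (
    CarrierSet,
    ComponentSet,
    ModulationParams,
    RenderConfig,
    envelope_phase,
    expand_carriers,
    render_explicit,
    render_frequency_domain,
    rms_normalize,
    synthesize,
)


def truncation_bound(carriers: CarrierSet, depth: ExponentialDepth, extent: int) -> float:
    """Rigorous max-abs bound on the omitted-sideband error of a render.

    Per carrier the omitted modulator terms are bounded by
    ``2 * sum_{k > K} I_k(M')``; the waveform error is at most the
    amplitude-weighted sum over carriers.
    """
    ks = np.arange(extent + 1, extent + 200)
    omitted = 2.0 * float(np.sum(iv(ks, depth.m_prime)))
    return float(np.sum(carriers.amplitude)) * omitted


@pytest.fixture
def config():
    return RenderConfig(sample_rate=8000.0, n_samples=8000)


class TestEnvelopePhase:
    def test_reference_frequency_gets_global_phase(self):
        p = ModulationParams(kind="none", density_cpo=3.0, phase0_rad=0.7, ref_hz=500.0)
        assert envelope_phase(500.0, p) == pytest.approx(0.7)

    def test_zero_density_is_constant(self):
        p = ModulationParams(kind="none", density_cpo=0.0, phase0_rad=1.1, ref_hz=500.0)
        np.testing.assert_allclose(envelope_phase([100.0, 900.0, 4000.0], p), 1.1)

    def test_one_octave_one_cycle(self):
        p = ModulationParams(kind="none", density_cpo=1.0, phase0_rad=0.0, ref_hz=440.0)
        assert envelope_phase(880.0, p) == pytest.approx(2 * math.pi)

    def test_non_positive_frequency_rejected(self):
        p = ModulationParams(kind="none")
        with pytest.raises(ValueError):
            envelope_phase(0.0, p)


class TestExpandCarriers:
    def test_no_modulation_passthrough(self):
        c = CarrierSet([440.0, 600.0], [1.0, 2.0], [0.1, 0.2])
        for params in (
            ModulationParams(kind="none"),
            ModulationParams(kind="exponential", depth=ExponentialDepth(0.0), rate_hz=4.0),
            ModulationParams(kind="linear", depth=LinearDepth(0.0), rate_hz=4.0),
        ):
            comp = expand_carriers(c, params)
            np.testing.assert_allclose(comp.frequency_hz, c.frequency_hz)
            np.testing.assert_allclose(comp.amplitude, c.amplitude)
            np.testing.assert_allclose(comp.phase_rad, c.phase_rad)

    def test_linear_modulation_gives_three_tones(self):
        c = CarrierSet([1000.0], [2.0], [0.3])
        params = ModulationParams(
            kind="linear", depth=LinearDepth(0.5), rate_hz=8.0, ref_hz=1000.0
        )
        comp = expand_carriers(c, params)
        assert len(comp) == 3
        order = np.argsort(comp.frequency_hz)
        np.testing.assert_allclose(comp.frequency_hz[order], [992.0, 1000.0, 1008.0])
        np.testing.assert_allclose(comp.amplitude[order], [0.5, 2.0, 0.5])

    def test_spectral_modulation_collapses_to_one_component(self):
        # omega = 0 at the envelope peak: amplitude approaches A * 10**(m/20)
        c = CarrierSet([700.0], [3.0], [0.4])
        params = ModulationParams(
            kind="exponential", depth=ExponentialDepth(20.0), rate_hz=0.0,
            density_cpo=1.0, phase0_rad=math.pi / 2, ref_hz=700.0,
        )
        comp = expand_carriers(c, params, extent=30)
        assert len(comp) == 1
        assert comp.frequency_hz[0] == 700.0
        assert comp.amplitude[0] == pytest.approx(30.0, rel=1e-10)

    @pytest.mark.parametrize("phi_env", [0.0, 0.9, 2.5, 4.4])
    def test_spectral_modulation_matches_direct_modulator(self, phi_env):
        c = CarrierSet([700.0], [1.0], [1.2])
        params = ModulationParams(
            kind="exponential", depth=ExponentialDepth(14.0), rate_hz=0.0,
            density_cpo=0.0, phase0_rad=phi_env, ref_hz=700.0,
        )
        comp = expand_carriers(c, params, extent=30)
        direct = 10.0 ** ((14.0 / 20.0) * math.sin(phi_env))
        assert comp.amplitude[0] == pytest.approx(direct, rel=1e-10)
        # phasor sum must preserve the carrier phase
        assert comp.phase_rad[0] == pytest.approx(1.2, abs=1e-9)

    def test_negative_frequency_sidebands_are_reflected(self, config):
        # a low carrier with deep modulation pushes lower sidebands past 0 Hz;
        # the reflected assembly must still agree with the explicit oracle
        c = CarrierSet([5.0], [1.0], [0.8])
        params = ModulationParams(
            kind="exponential", depth=ExponentialDepth(5.0), rate_hz=4.0,
            density_cpo=0.0, phase0_rad=0.3, ref_hz=5.0,
        )
        comp = expand_carriers(c, params, extent=25)
        assert np.all(comp.frequency_hz > 0)
        wave = render_frequency_domain(comp, config)
        oracle = render_explicit(c, params, config)
        assert np.max(np.abs(wave - oracle)) < 1e-9 * np.sqrt(np.mean(oracle**2))

    def test_component_table_columns(self):
        c = CarrierSet([440.0], [1.0], [0.0])
        params = ModulationParams(
            kind="exponential", depth=ExponentialDepth(10.0), rate_hz=4.0, ref_hz=440.0
        )
        frame = expand_carriers(c, params, extent=3).to_frame()
        assert list(frame.columns) == [
            "carrier_index", "k", "side", "frequency_hz", "amplitude", "phase_rad",
        ]
        assert len(frame) == 7
        assert (frame["amplitude"] >= 0).all()


class TestFrequencyDomainRender:
    def test_single_on_bin_sine_is_exact(self, config):
        comp = ComponentSet(
            np.array([440.0]), np.array([1.0]), np.array([0.0]),
            np.array([0]), np.array([0]), np.array(["base"]),
        )
        wave = render_frequency_domain(comp, config)
        t = np.arange(config.n_samples) / config.sample_rate
        assert np.max(np.abs(wave - np.sin(2 * np.pi * 440.0 * t))) < 1e-12

    def test_parseval_energy(self, config):
        rng = np.random.default_rng(7)
        n = 40
        f = rng.choice(np.arange(100, 3000), size=n, replace=False).astype(float)
        a = rng.uniform(0.2, 2.0, n)
        comp = ComponentSet(f, a, rng.uniform(-np.pi, np.pi, n),
                            np.arange(n), np.zeros(n, int), np.full(n, "base"))
        wave = render_frequency_domain(comp, config)
        expected = np.sum(a**2) / 2.0
        assert np.mean(wave**2) == pytest.approx(expected, rel=1e-10)

    def test_strict_policy_rejects_off_bin(self, config):
        comp = ComponentSet(np.array([440.5]), np.array([1.0]), np.array([0.0]),
                            np.array([0]), np.array([0]), np.array(["base"]))
        with pytest.raises(ValueError, match="off-bin"):
            render_frequency_domain(comp, config)

    def test_strict_policy_rejects_nyquist_and_above(self, config):
        comp = ComponentSet(np.array([4000.0]), np.array([1.0]), np.array([0.0]),
                            np.array([0]), np.array([0]), np.array(["base"]))
        with pytest.raises(ValueError, match="Nyquist"):
            render_frequency_domain(comp, config)

    def test_quantize_policy_rounds_and_drops(self, config):
        cfg = RenderConfig(config.sample_rate, config.n_samples, grid_policy="quantize")
        comp = ComponentSet(np.array([440.4, 5000.0]), np.array([1.0, 1.0]),
                            np.array([0.0, 0.0]), np.array([0, 1]),
                            np.array([0, 0]), np.array(["base", "base"]))
        wave = render_frequency_domain(comp, cfg)
        t = np.arange(cfg.n_samples) / cfg.sample_rate
        assert np.max(np.abs(wave - np.sin(2 * np.pi * 440.0 * t))) < 1e-12

    def test_overlapping_bins_accumulate(self, config):
        comp = ComponentSet(np.array([440.0, 440.0]), np.array([1.0, 1.0]),
                            np.array([0.0, np.pi]), np.array([0, 1]),
                            np.array([0, 0]), np.array(["base", "base"]))
        wave = render_frequency_domain(comp, config)
        assert np.max(np.abs(wave)) < 1e-12  # antiphase pair cancels


class TestOracleEquivalence:
    def test_explicit_without_modulation_is_carrier_sum(self, config):
        rng = np.random.default_rng(1)
        c = CarrierSet(np.array([200.0, 450.0, 999.0]), rng.uniform(0.5, 2, 3),
                       rng.uniform(0, 2 * np.pi, 3))
        wave = render_explicit(c, ModulationParams(kind="none"), config)
        brute = evaluate_components(c.frequency_hz, c.amplitude, c.phase_rad,
                                    config.sample_rate, config.n_samples)
        np.testing.assert_allclose(wave, brute, atol=1e-10)

    def test_explicit_envelope_peak_factor(self):
        # at the envelope peak the instantaneous factor is 10**(m/20) = 10
        cfg = RenderConfig(sample_rate=1000.0, n_samples=1000)
        c = CarrierSet([250.0], [1.0], [np.pi / 2])  # carrier at +1 when t=0
        params = ModulationParams(
            kind="exponential", depth=ExponentialDepth(20.0), rate_hz=2.0,
            density_cpo=0.0, phase0_rad=np.pi / 2, ref_hz=250.0,
        )
        wave = render_explicit(c, params, cfg)
        assert wave[0] == pytest.approx(10.0, rel=1e-12)

    @pytest.mark.parametrize("seed", range(6))
    def test_sideband_matches_oracle_within_truncation_bound(self, seed, config):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 12))
        depth = ExponentialDepth(float(rng.uniform(1.0, 40.0)))
        c = CarrierSet(
            rng.choice(np.arange(300, 3000), size=n, replace=False).astype(float),
            rng.rayleigh(1.0, n), rng.uniform(0, 2 * np.pi, n),
        )
        params = ModulationParams(
            kind="exponential", depth=depth, rate_hz=float(rng.integers(1, 9)),
            density_cpo=float(rng.uniform(0, 4)),
            phase0_rad=float(rng.uniform(0, 2 * np.pi)), ref_hz=300.0,
        )
        extent = min_extent_for_tolerance(depth, 1e-8)
        cfg = RenderConfig(config.sample_rate, config.n_samples, extent=extent)
        wave = synthesize(c, params, cfg).waveform
        oracle = render_explicit(c, params, config)
        bound = truncation_bound(c, depth, extent) + 1e-9
        assert np.max(np.abs(wave - oracle)) <= bound

    def test_linear_modulation_exact_equivalence(self, config):
        # the linear expansion has no truncation: methods agree to roundoff
        rng = np.random.default_rng(3)
        c = CarrierSet(np.array([500.0, 1200.0]), np.array([1.0, 0.7]),
                       rng.uniform(0, 2 * np.pi, 2))
        params = ModulationParams(
            kind="linear", depth=LinearDepth(0.8), rate_hz=4.0,
            density_cpo=2.0, phase0_rad=0.5, ref_hz=500.0,
        )
        wave = synthesize(c, params, config).waveform
        oracle = render_explicit(c, params, config)
        rms = np.sqrt(np.mean(oracle**2))
        assert np.max(np.abs(wave - oracle)) < 1e-11 * rms

    def test_error_decreases_with_extent(self, config):
        c = CarrierSet([1000.0], [1.0], [0.0])
        params = ModulationParams(
            kind="exponential", depth=ExponentialDepth(20.0), rate_hz=4.0,
            density_cpo=0.0, phase0_rad=0.9, ref_hz=1000.0,
        )
        oracle = render_explicit(c, params, config)
        errs = []
        for extent in (1, 2, 4, 8, 16):
            cfg = RenderConfig(config.sample_rate, config.n_samples, extent=extent)
            wave = synthesize(c, params, cfg).waveform
            errs.append(np.max(np.abs(wave - oracle)))
        assert all(b < a for a, b in zip(errs, errs[1:]))

    def test_spectral_modulation_stationary_spectrum(self, config):
        # omega = 0: each carrier amplitude is scaled by the envelope value
        rng = np.random.default_rng(5)
        f = np.array([400.0, 800.0, 1600.0])
        c = CarrierSet(f, np.ones(3), rng.uniform(0, 2 * np.pi, 3))
        params = ModulationParams(
            kind="exponential", depth=ExponentialDepth(12.0), rate_hz=0.0,
            density_cpo=2.0, phase0_rad=0.3, ref_hz=400.0,
        )
        wave = synthesize(c, params, RenderConfig(
            config.sample_rate, config.n_samples, extent=30)).waveform
        mags = np.abs(np.fft.rfft(wave)) / (config.n_samples / 2)
        phi = envelope_phase(f, params)
        expected = 10.0 ** ((12.0 / 20.0) * np.sin(phi))
        bins = (f * config.n_samples / config.sample_rate).astype(int)
        np.testing.assert_allclose(mags[bins], expected, rtol=1e-9)

    def test_linearity_in_carrier_amplitude(self, config):
        rng = np.random.default_rng(9)
        c1 = CarrierSet([300.0, 900.0], [1.0, 0.5], rng.uniform(0, 2 * np.pi, 2))
        c2 = CarrierSet(c1.frequency_hz, 2.0 * c1.amplitude, c1.phase_rad)
        params = ModulationParams(
            kind="exponential", depth=ExponentialDepth(10.0), rate_hz=4.0,
            density_cpo=1.0, ref_hz=300.0,
        )
        cfg = RenderConfig(config.sample_rate, config.n_samples, extent=8)
        w1 = synthesize(c1, params, cfg).waveform
        w2 = synthesize(c2, params, cfg).waveform
        np.testing.assert_array_equal(w2, 2.0 * w1)


class TestNormalization:
    def test_identity_at_current_rms(self):
        x = np.sin(np.linspace(0, 20 * np.pi, 4000))
        rms = float(np.sqrt(np.mean(x**2)))
        np.testing.assert_allclose(rms_normalize(x, rms), x, rtol=1e-14)

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=2048)
        np.testing.assert_allclose(
            rms_normalize(2 * x, 0.1), rms_normalize(x, 0.1), rtol=1e-12
        )

    def test_target_rms_reached(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=4096)
        y = rms_normalize(x, 0.1)  # -20 dB FS
        assert np.sqrt(np.mean(y**2)) == pytest.approx(0.1, abs=1e-12)

    def test_silent_input_rejected(self):
        with pytest.raises(ValueError):
            rms_normalize(np.zeros(128), 0.1)


class TestValidation:
    def test_carrier_set_validation(self):
        with pytest.raises(ValueError):
            CarrierSet([0.0], [1.0], [0.0])
        with pytest.raises(ValueError):
            CarrierSet([100.0], [-1.0], [0.0])
        with pytest.raises(ValueError):
            CarrierSet([100.0, 200.0], [1.0], [0.0, 0.0])

    def test_modulation_params_validation(self):
        with pytest.raises(TypeError):
            ModulationParams(kind="exponential", depth=LinearDepth(0.5))
        with pytest.raises(ValueError):
            ModulationParams(kind="none", rate_hz=-1.0)

    def test_render_config_validation(self):
        with pytest.raises(ValueError):
            RenderConfig(sample_rate=0.0, n_samples=10)
        with pytest.raises(ValueError):
            RenderConfig(sample_rate=8000.0, n_samples=0)
        with pytest.raises(ValueError):
            RenderConfig(sample_rate=8000.0, n_samples=10, method="other")
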