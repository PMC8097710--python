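# Methods

## The model

`stmgen` synthesises spectro-temporally modulated (STM) noise — "moving
ripple" stimuli — from a sum of `N` stationary carrier tones

    S(t) = sum_n  A_n sin(2*pi*f_n*t + phi_n) * M(f_n, t)

where the modulator is either *exponential* (sinusoidal on a dB scale),

    M_exp(f, t) = 10**((m/20) * sin(2*pi*omega*t + Phi(f))),

or *linear*, `M_lin = 1 + m*sin(...)`.  The envelope phase
`Phi(f) = 2*pi*Omega*log2(f/f0) + Phi0` makes the ripple periodic on a
log-frequency (octave) axis with density `Omega` cycles/octave; `omega`
is the temporal rate in Hz.  Setting `omega = 0` gives pure spectral
modulation (SM), `Omega = 0` pure temporal modulation (TM).

For the exponential modulator, `m` is the **midpoint-to-peak** depth in
decibels; the peak-to-valley swing is `2*m`.  At `m = 0` the modulator
is exactly 1.

## Sideband expansion

Writing `M' = (m/20)*ln(10)`, the exponential modulator has the exact
Fourier series (a Jacobi–Anger-type expansion in modified Bessel
functions)

    exp(M' sin(theta)) = I0(M')
        + 2 * sum_{even k>=2} (-1)^(k/2)    I_k(M') cos(k*theta)
        + 2 * sum_{odd  k>=1} (-1)^((k-1)/2) I_k(M') sin(k*theta).

Multiplying by the carrier and applying the product rules turns each
carrier into a base tone of amplitude `I0(M')*A_n` plus sideband pairs
at `f_n ± k*omega` with amplitudes `I_k(M')*A_n`, parity-dependent signs
and quadratures, and envelope-phase offsets `± k*Phi(f_n)`.
`stmgen.sidebands` builds this expansion as a `SidebandTemplate`;
`stmgen.synthesis.expand_carriers` binds it to a carrier set;
`render_frequency_domain` accumulates the resulting pure tones into a
half-spectrum as complex phasors and performs **one** inverse real FFT.
`render_explicit` evaluates the time-domain product directly and serves
as the ground-truth oracle throughout the test suite.

Conventions worth stating explicitly, because they are where
independent implementations usually disagree:

- Every component is stored as `a * sin(2*pi*f*t + p)` with `a >= 0`;
  cosine quadrature becomes `p + pi/2`, negative expansion signs become
  `p + pi`, and phases are wrapped to `(-pi, pi]`.  A component on bin
  `b` contributes the phasor `a * exp(1j*(p - pi/2)) * n/2` to the
  positive-frequency half-spectrum, which makes `irfft` reproduce the
  sine exactly for on-bin frequencies.
- Time runs `t = 0 .. (n_samples-1)/sample_rate` in both renderers, so
  their outputs are sample-aligned.
- Lower sidebands pushed below 0 Hz are algebraically reflected
  (`sin(-2*pi*f*t + p) = sin(2*pi*f*t + pi - p)`) rather than dropped,
  preserving oracle equivalence for very low carriers; exact-DC
  components are identically zero and are dropped with a warning.
- With `omega = 0` all sidebands of a carrier land on its own
  frequency; they are combined by phasor summation, which equals the
  truncated modulator value at that carrier's envelope phase.
- The single-IDFT guarantee requires on-bin frequencies.  `grid_policy`
  `"strict"` (library default) raises on off-bin components;
  `"quantize"` (CLI default) rounds to the nearest bin and logs the
  worst-case rounding error.  Components at or above Nyquist raise
  under `strict` and are dropped with a warning under `quantize`.
- No normalization or onset ramping is applied unless requested, so the
  rendered waveform is the expansion itself.

## Truncation error and extent selection

The infinite sideband sum is truncated at extent `K` (offsets
`|k| <= K`).  The omitted energy is quantified by the deficiency

    deficiency_db = 10*log10( partial / total ),
    partial = I0(M')^2 + 2*sum_{k=1..K} I_k(M')^2,
    total   = I0(2*M')            (closed form of the full sum),

computed from the complementary tail through `log1p` so values near
0 dB retain full relative precision (a plain `log10(partial/total)`
loses all accuracy below ~1e-12 dB).  The closed form is cross-checked
against a large-`K` partial sum in the tests.  Representative values,
which the test suite and `scripts/acceptance.py` recompute: at `m = 40`
(80 dB peak-to-valley), extent 10 — 21 series terms — leaves
|deficiency| = 9.4e-10 dB; at `m = 20` (40 dB peak-to-valley), extent 4
leaves 2.1e-4 dB; at `m = 40`, extent 4 leaves 1.1e-2 dB.

`min_extent_for_tolerance` selects the smallest `K` meeting a
deficiency tolerance by forward search.  When the caller specifies
neither an extent nor a tolerance, the default is the extent for
1e-4 dB, capped at 50 — far below plausible perceptual relevance at
negligible cost.

**What a deficiency tolerance does and does not bound.**  Deficiency is
an *energy* ratio; the corresponding amplitude-scale error of the
waveform goes like its square root.  A deficiency of `d` dB implies an
omitted energy fraction `eps ≈ d*ln(10)/10` and a max-abs waveform
error on the order of `2*sqrt(eps)` relative to RMS — about 1e-4 at
`d = 1e-8` dB, *independent of depth*.  The unit tests therefore assert
cross-renderer agreement against the rigorous per-draw amplitude bound
`sum_n A_n * 2 * sum_{k>K} I_k(M')`, and the truncated-series tests
bound the modulator error relative to the envelope's peak value
`10**(m/20)`.  Pointwise *relative* error at the envelope valley is
dominated by the same absolute residue divided by the tiny valley value
`10**(-m/20)`; it is the wrong yardstick for a stimulus whose
audibility scales with the peak, and at deep depths it can only be
driven down by taking a much larger extent (e.g. `K = 30` puts the
identity at ~1e-9 relative even for `m = 40`).  Users who need a given
waveform accuracy should pick the extent from the square-root
relationship above, not from the raw deficiency number.

## Carrier design and the validation sweep

`generate_noise_carriers` places one tone per DFT bin (or a random
`density` fraction of bins) across a band, with i.i.d. Rayleigh(1) or
equal amplitudes and uniform phases, shaped by unity gain inside
`[band_lo, band_hi]` and a roll-off of `slope_db_per_octave` outside.
The roll-off is interpreted as out-of-band attenuation (not an in-band
tilt), the usual bandpass reading; it is truncated where attenuation
exceeds `rolloff_floor_db` (default 60 dB) or at the Nyquist grid,
whichever comes first.  Defaults: 400–3200 Hz, −32 dB/octave, Rayleigh
amplitudes, maximum density.

The validation sweep renders pure-SM stimuli (the STM special case
whose envelope is inscribed directly into the magnitude spectrum) with
*both* renderers at a grid of peak-to-valley depths, 2 cycles/octave
ripple, and a randomized global envelope phase per exemplar, and
measures two scale-invariant statistics on the in-band DFT magnitudes
`E`:

- normalized fourth moment `M4 = mean(E^4) / mean(E^2)^2` (fluctuation
  strength; 1 for a flat envelope, 2 for Rayleigh noise, rising with
  ripple depth), with the magnitudes pre-scaled by their maximum so
  fourth powers cannot overflow;
- crest factor `CF = max(E) / rms(E)` (extrema; always >= 1).

Seeding: a master seed plus (depth index, exemplar index) feeds a
`numpy` `SeedSequence`, so every method sees byte-identical carriers
and envelope phase and the comparison is fully paired.  Library sweep
defaults are 1 s at 44.1 kHz with 100 exemplars at 20 depths from 0 to
50 dB peak-to-valley (the depth grid is an even-spacing package choice
and is overridable).  The acceptance-scale run uses 0.5 s at 16 384 Hz
with 5 depths × 20 exemplars (≈4 000 carriers per exemplar, ≈1 400
in-band analysis bins), this package's standard reduced configuration;
at those sizes the paired per-depth means of M4 and CF agree between
renderers to a few parts in 1e6 and both rise strictly with depth.

## What the synthetic conditions do not show

The generator emulates the carrier statistics (Rayleigh amplitudes,
uniform phases, bandpass shaping) and modulation geometry of typical
psychoacoustic ripple stimuli.  It does not model auditory-filter
excitation, nonstationary real-world noise, playback-chain transfer
functions, or perceptual detectability of the residual truncation
error; agreement between the two renderers demonstrates numerical, not
perceptual, equivalence.

## Numerical choices and degenerate inputs

- `I_nu(z)` is delegated to `scipy.special.iv`; a direct power-series
  summation lives in the test suite as an independent oracle
  (agreement to 1e-12 relative).
- Deficiency at `m = 0` is exactly 0 dB at any extent; the extent
  search terminates there immediately.
- Strict on-bin checking uses a 1e-6-bin tolerance to absorb float
  division noise.
- RMS normalization refuses silent input; PCM16 export refuses peaks
  above full scale (raising with the measured peak) instead of
  wrapping.
- The explicit renderer processes carriers in chunks of 64 to bound
  memory; with `omega = 0` the modulator is time-constant per carrier
  and is applied as an exact amplitude scale.

## Known limitations

- Only sinusoidal (linear or exponential) modulators; arbitrary
  envelope shapes are out of scope.
- The frequency-domain path requires (or quantizes to) on-bin
  component frequencies; off-grid carriers need the explicit renderer.
- The spectrogram power-ratio diagnostic is window-dependent; it is
  used for property checks (the ratio shrinking with extent), not for
  absolute values.
- Stimuli are mono; no streaming or real-time scheduling is provided.
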