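"""Independent reference implementations used only by the test suite.

These deliberately avoid the code paths they check: the Bessel oracle is a
direct power-series summation, and the component evaluator is a brute-force
time-domain sum of sines.
"""

from __future__ import annotations

import math

import numpy as np


def bessel_series(order: int, z: float) -> float:
    """``I_order(z)`` by direct series summation.

    ``I_v(z) = (z/2)**v * sum_j (z**2j) / (2**2j * j! * (v+j)!)``, with terms
    added until the next term falls below 1e-16 of the running sum.
    """
    if order < 0 or z < 0:
        raise ValueError("series oracle requires non-negative order and argument")
    if z == 0.0:
        return 1.0 if order == 0 else 0.0
    lead = (z / 2.0) ** order / math.factorial(order)
    total = term = 1.0
    j = 0
    while True:
        j += 1
        term *= (z * z / 4.0) / (j * (order + j))
        total += term
        if term < 1e-16 * total:
            return lead * total


def evaluate_components(frequency_hz, amplitude, phase_rad, sample_rate, n_samples):
    """Brute-force time-domain evaluation of a list of sine components."""
    t = np.arange(n_samples) / sample_rate
    out = np.zeros(n_samples)
    for f, a, p in zip(np.asarray(frequency_hz), np.asarray(amplitude),
                       np.asarray(phase_rad)):
        out += a * np.sin(2.0 * np.pi * f * t + p)
    return out


def exponential_modulator(depth_db: float, theta) -> np.ndarray:
    """Direct evaluation ``10**((m/20) * sin(theta))``."""
    return 10.0 ** ((depth_db / 20.0) * np.sin(np.asarray(theta, dtype=float)))
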