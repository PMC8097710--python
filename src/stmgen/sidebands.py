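"""Modified-Bessel sideband expansion of sinusoidal amplitude modulators.

A carrier tone multiplied by an *exponential* (log-amplitude sinusoidal)
modulator ``10**((m/20) * sin(theta))`` is exactly equal to an infinite sum
of pure-tone sidebands whose amplitudes are values of the modified Bessel
function of the first kind, ``I_k(M')`` with ``M' = (m/20) * ln(10)``.  The
*linear* modulator ``1 + m * sin(theta)`` is the familiar three-tone
special case.  This module computes those sideband templates, evaluates the
truncated modulator Fourier series, and quantifies the energy omitted by
truncating the expansion at a finite sideband extent.

The templates produced here are carrier-agnostic: each entry is a recipe
(offset index, side, amplitude factor, quadrature phase, envelope-phase
coefficient) that :mod:`stmgen.synthesis` binds to concrete carriers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Union

import numpy as np
from scipy.special import iv as _scipy_iv

__all__ = [
    "ExponentialDepth",
    "LinearDepth",
    "SidebandEntry",
    "SidebandTemplate",
    "DeficiencyReport",
    "modified_bessel_i",
    "exponential_template",
    "linear_template",
    "template_eval",
    "energy_deficiency_db",
    "min_extent_for_tolerance",
    "resolve_extent",
]

_LN10 = math.log(10.0)

#: Default energy-deficiency tolerance (dB) used when a caller gives neither
#: an explicit sideband extent nor a tolerance.
DEFAULT_TOLERANCE_DB = 1e-4

#: Hard cap on the automatically selected sideband extent.
DEFAULT_MAX_EXTENT = 50


# ---------------------------------------------------------------------------
# depth parameterisations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExponentialDepth:
    """Depth of an exponential (log-amplitude sinusoidal) modulator.

    Parameters
    ----------
    depth_db:
        Midpoint-to-peak modulation depth in decibels, ``m >= 0``.  The
        peak-to-valley depth of the resulting envelope is ``2 * m`` dB.
    """

    depth_db: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.depth_db) or self.depth_db < 0:
            raise ValueError(
                f"exponential depth must be a finite value >= 0 dB, got {self.depth_db}"
            )

    @property
    def m_prime(self) -> float:
        """Unitless exponent scale ``M' = (m/20) * ln(10)``."""
        return self.depth_db / 20.0 * _LN10

    @property
    def peak_to_valley_db(self) -> float:
        return 2.0 * self.depth_db

    @classmethod
    def from_peak_to_valley(cls, depth_db: float) -> "ExponentialDepth":
        """Build from a peak-to-valley depth in dB (half of it is ``m``)."""
        return cls(depth_db / 2.0)


@dataclass(frozen=True)
class LinearDepth:
    """Depth of a linear sinusoidal modulator ``1 + m * sin(theta)``.

    ``m`` is unitless in ``[0, 1)``; the literature often reports it as
    ``20*log10(m)``, accepted via :meth:`from_db`.
    """

    m: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.m < 1.0):
            raise ValueError(f"linear modulation depth must lie in [0, 1), got {self.m}")

    @classmethod
    def from_db(cls, depth_db: float) -> "LinearDepth":
        return cls(10.0 ** (depth_db / 20.0))


Depth = Union[ExponentialDepth, LinearDepth]


# ---------------------------------------------------------------------------
# modified Bessel function
# ---------------------------------------------------------------------------

def modified_bessel_i(order: int, argument: float) -> float:
    """Modified Bessel function of the first kind, ``I_order(argument)``.

    Restricted to non-negative integer order and non-negative real argument,
    which is the only regime the sideband expansion needs.  Delegates to
    :func:`scipy.special.iv`.
    """
    if order != int(order) or order < 0:
        raise ValueError(f"order must be a non-negative integer, got {order}")
    if argument < 0:
        raise ValueError(f"argument must be non-negative, got {argument}")
    return float(_scipy_iv(int(order), float(argument)))


# ---------------------------------------------------------------------------
# sideband templates
# ---------------------------------------------------------------------------

class SidebandEntry(NamedTuple):
    """One sideband recipe of a template.

    Applied to a carrier (``A``, ``f``, ``phi``) with temporal rate ``omega``
    and envelope phase ``Phi`` it denotes the tone

    ``amp_factor * A * sin(2*pi*(f + side_sign*k*omega)*t
                           + phi + env_coeff*Phi + quad_phase)``

    where cosine terms of the expansion are stored in sine convention via
    ``quad_phase = +pi/2``, and a negative ``amp_factor`` is normalised to a
    positive amplitude plus ``pi`` when components are emitted.
    """

    k: int                 # non-negative offset index (0 for the base tone)
    side: str              # "base" | "upper" | "lower"
    amp_factor: float      # signed multiplier of the carrier amplitude
    quad_phase: float      # 0 for sine terms, +pi/2 for cosine terms
    env_coeff: int         # multiplies the envelope phase: 0, +k, or -k

    @property
    def side_sign(self) -> int:
        return {"base": 0, "upper": +1, "lower": -1}[self.side]


@dataclass(frozen=True)
class SidebandTemplate:
    """Sideband expansion of a modulator at a fixed depth.

    Contains exactly one ``base`` entry plus an upper/lower pair for each
    offset index ``k = 1..extent``.
    """

    kind: str                      # "exponential" | "linear"
    depth: Depth
    entries: tuple[SidebandEntry, ...] = field(repr=False)

    @property
    def extent(self) -> int:
        return max((e.k for e in self.entries), default=0)

    def __len__(self) -> int:
        return len(self.entries)

    def evaluate(self, theta) -> np.ndarray:
        """Evaluate the (truncated) modulator Fourier series at ``theta``.

        For the exponential kind this is the partial sum approximating
        ``exp(M' * sin(theta))``; for the linear kind it reproduces
        ``1 + m * sin(theta)`` exactly.
        """
        return template_eval(self, theta)


def template_eval(template: SidebandTemplate, theta) -> np.ndarray:
    """Evaluate a template's modulator series on an angle grid (radians).

    The lower-side entries carry exactly the Fourier coefficients of the
    modulator: for each ``k`` the even-``k`` pair contributes
    ``2 * a_lower * cos(k*theta)`` and the odd-``k`` pair
    ``2 * a_lower * sin(k*theta)``, on top of the base coefficient.
    """
    theta = np.asarray(theta, dtype=float)
    base = next(e for e in template.entries if e.side == "base")
    out = np.full(theta.shape, base.amp_factor, dtype=float)
    for e in template.entries:
        if e.side != "lower":
            continue
        if e.quad_phase == 0.0:          # even k: cosine term
            out += 2.0 * e.amp_factor * np.cos(e.k * theta)
        else:                            # odd k: sine term
            out += 2.0 * e.amp_factor * np.sin(e.k * theta)
    return out


def exponential_template(depth: ExponentialDepth, extent: int) -> SidebandTemplate:
    """Sideband template of the exponential modulator up to offset ``extent``.

    The base tone carries ``I_0(M')``; for each ``k >= 1`` the upper and
    lower sidebands carry ``I_k(M')`` with parity-dependent signs and, for
    odd ``k``, a ``+pi/2`` quadrature phase (cosine stored as shifted sine):

    * even ``k``: sign ``(-1)**(k/2)`` on both sides, sine quadrature;
    * odd ``k``: upper sign ``(-1)**((k+1)/2)``, lower sign
      ``(-1)**((k-1)/2)``, cosine quadrature.
    """
    if not isinstance(depth, ExponentialDepth):
        raise TypeError("exponential_template requires an ExponentialDepth")
    extent = int(extent)
    if extent < 0:
        raise ValueError(f"extent must be >= 0, got {extent}")
    mp = depth.m_prime
    orders = np.arange(extent + 1)
    ik = _scipy_iv(orders, mp) if mp > 0 else np.concatenate(([1.0], np.zeros(extent)))
    entries = [SidebandEntry(0, "base", float(ik[0]), 0.0, 0)]
    for k in range(1, extent + 1):
        if k % 2 == 0:
            s = (-1) ** (k // 2)
            entries.append(SidebandEntry(k, "upper", s * float(ik[k]), 0.0, +k))
            entries.append(SidebandEntry(k, "lower", s * float(ik[k]), 0.0, -k))
        else:
            su = (-1) ** ((k + 1) // 2)
            sl = (-1) ** ((k - 1) // 2)
            entries.append(SidebandEntry(k, "upper", su * float(ik[k]), math.pi / 2, +k))
            entries.append(SidebandEntry(k, "lower", sl * float(ik[k]), math.pi / 2, -k))
    return SidebandTemplate("exponential", depth, tuple(entries))


def linear_template(depth: LinearDepth) -> SidebandTemplate:
    """Three-entry template of the linear modulator ``1 + m * sin(theta)``.

    Base at amplitude 1; sidebands at ``m/2`` in cosine quadrature with the
    upper side negated, the textbook double-sideband decomposition.
    """
    if not isinstance(depth, LinearDepth):
        raise TypeError("linear_template requires a LinearDepth")
    m = depth.m
    entries = [SidebandEntry(0, "base", 1.0, 0.0, 0)]
    if m > 0:
        entries.append(SidebandEntry(1, "upper", -m / 2.0, math.pi / 2, +1))
        entries.append(SidebandEntry(1, "lower", +m / 2.0, math.pi / 2, -1))
    return SidebandTemplate("linear", depth, tuple(entries))


# ---------------------------------------------------------------------------
# truncation-error diagnostics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DeficiencyReport:
    """Energy omitted by truncating the sideband expansion at extent ``K``.

    ``deficiency_db = 10*log10(partial_energy / total_energy) <= 0``; the
    magnitude is the decibel-scale energy "missing" from the truncated sum.
    """

    extent: int
    partial_energy: float
    total_energy: float
    deficiency_db: float


def _tail_energy(m_prime: float, extent: int) -> float:
    """``2 * sum_{k > extent} I_k(M')**2``, summed to numerical exhaustion."""
    total = 0.0
    k = extent + 1
    while True:
        orders = np.arange(k, k + 64)
        terms = 2.0 * _scipy_iv(orders, m_prime) ** 2
        block = float(np.sum(terms))
        total += block
        if block == 0.0 or terms[-1] < 1e-30 * max(total, 1.0):
            return total
        k += 64


def energy_deficiency_db(depth: ExponentialDepth, extent: int) -> DeficiencyReport:
    """Truncation energy deficiency of the exponential expansion.

    partial = ``I0(M')**2 + 2*sum_{k=1..K} I_k(M')**2``; total uses the
    closed form ``sum_{k=-inf..inf} I_k(z)**2 = I0(2z)``.  The decibel value
    is computed from the complementary tail through ``log1p`` so that
    deficiencies far below 1e-9 dB keep full relative precision.
    """
    extent = int(extent)
    if extent < 0:
        raise ValueError(f"extent must be >= 0, got {extent}")
    mp = depth.m_prime
    if mp == 0.0:
        return DeficiencyReport(extent, 1.0, 1.0, 0.0)
    orders = np.arange(0, extent + 1)
    ik = _scipy_iv(orders, mp)
    partial = float(ik[0] ** 2 + 2.0 * np.sum(ik[1:] ** 2))
    total = float(_scipy_iv(0, 2.0 * mp))
    tail = _tail_energy(mp, extent)
    ratio_tail = min(tail / total, 1.0 - 1e-300)
    deficiency_db = 10.0 / _LN10 * math.log1p(-ratio_tail)
    return DeficiencyReport(extent, partial, total, deficiency_db)


def min_extent_for_tolerance(
    depth: ExponentialDepth, tol_db: float, max_extent: int = 1000
) -> int:
    """Smallest extent whose energy deficiency magnitude is within ``tol_db``."""
    if tol_db <= 0:
        raise ValueError(f"tolerance must be positive, got {tol_db}")
    for extent in range(max_extent + 1):
        if abs(energy_deficiency_db(depth, extent).deficiency_db) <= tol_db:
            return extent
    raise RuntimeError(
        f"no extent <= {max_extent} meets {tol_db} dB at m = {depth.depth_db} dB"
    )


def resolve_extent(
    depth: Depth,
    extent: int | None = None,
    tolerance_db: float | None = None,
) -> int:
    """Pick a sideband extent from an explicit value or a tolerance.

    Linear modulators always have extent 1.  With neither argument given,
    the extent meeting ``DEFAULT_TOLERANCE_DB`` is used, capped at
    ``DEFAULT_MAX_EXTENT``.
    """
    if isinstance(depth, LinearDepth):
        return 1
    if extent is not None and tolerance_db is not None:
        raise ValueError("give either an extent or a tolerance, not both")
    if extent is not None:
        return int(extent)
    if tolerance_db is not None:
        return min_extent_for_tolerance(depth, tolerance_db)
    return min(
        min_extent_for_tolerance(depth, DEFAULT_TOLERANCE_DB), DEFAULT_MAX_EXTENT
    )
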