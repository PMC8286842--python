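"""Nernst models for the spectroelectrochemical (OTTLE) titration of a
flavoprotein, monitored by the oxidised-flavin absorbance.

Two competing equilibrium models describe the oxidised fraction y as a
function of applied potential x (mV vs NHE):

* two sequential one-electron steps, with a semiquinone intermediate whose
  relative absorbance is b:

      y = (10^((x-E1)/59) + b) / (1 + 10^((x-E1)/59) + 10^((E2-x)/59))

* a concerted two-electron step:

      y = 1 / (1 + 10^((Em-x)/29.5))

The Nernst slopes are fixed at 59 and 29.5 mV/decade.  The two-step formula
is implemented exactly as written above: the term carrying E1 grows with
oxidising potential.  Note that under the usual couple naming (E1 =
semiquinone/hydroquinone, E2 = oxidised/semiquinone) the labels in this
formula are interchanged; with nearly equal potentials, as for free NfsA,
the distinction is immaterial, and :func:`species_fractions_two_step`
documents the population reading used throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .rate_models import InputDomainError, ParameterDomainError

__all__ = [
    "TitrationPoint",
    "RedoxTwoStepParams",
    "RedoxConcertedParams",
    "NernstConstants",
    "NERNST",
    "DegenerateEndpointError",
    "fraction_oxidised_two_step",
    "fraction_oxidised_concerted",
    "species_fractions_two_step",
    "normalise_titration",
]


class DegenerateEndpointError(ValueError):
    """Oxidised and reduced endpoint absorbances coincide."""


@dataclass(frozen=True)
class TitrationPoint:
    """One equilibrated titration observation: applied potential (mV vs
    NHE), absorbance at the monitored wavelength, and which half of the
    titration (cycle) it belongs to."""

    potential: float  # mV vs NHE
    absorbance: float  # AU
    cycle: str = "reductive"  # "oxidative" | "reductive"
    replicate: str = "1"

    def __post_init__(self) -> None:
        if not math.isfinite(self.potential):
            raise InputDomainError("potential must be finite")
        if self.absorbance < 0:
            raise InputDomainError("absorbance must be >= 0")


@dataclass(frozen=True)
class RedoxTwoStepParams:
    """Two one-electron-step model parameters: the two redox potentials
    (mV vs NHE) and the relative semiquinone absorbance b (dimensionless)."""

    E1: float
    E2: float
    b: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.E1) and math.isfinite(self.E2)):
            raise ParameterDomainError("E1 and E2 must be finite")
        if not self.b >= 0:
            raise ParameterDomainError(f"b must be >= 0, got {self.b}")


@dataclass(frozen=True)
class RedoxConcertedParams:
    """Concerted two-electron model: a single midpoint potential (mV)."""

    Em: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.Em):
            raise ParameterDomainError("Em must be finite")


@dataclass(frozen=True)
class NernstConstants:
    """Nernst slopes (mV/decade) for one- and two-electron transfers."""

    slope_1e: float = 59.0
    slope_2e: float = 29.5

    def __post_init__(self) -> None:
        if self.slope_1e <= 0 or self.slope_2e <= 0:
            raise ParameterDomainError("Nernst slopes must be positive")


NERNST = NernstConstants()

# Exponents are clamped to +/-300 decades: far beyond any physical potential
# range, so clamping never alters a result within fitting range, but it keeps
# 10**x finite for arbitrary optimizer excursions.
_EXP_CLAMP = 300.0


def _pow10(exponent):
    return np.power(10.0, np.clip(exponent, -_EXP_CLAMP, _EXP_CLAMP))


def fraction_oxidised_two_step(params: RedoxTwoStepParams, potential,
                               constants: NernstConstants = NERNST):
    """Oxidised-absorbance fraction y for the two one-electron-step model.

    y -> 1 as x -> +inf and y -> 0 as x -> -inf; lies in [0, 1] for b <= 1.
    Accepts scalar or array potentials; stable for |x - E| up to ~1000 mV
    and beyond.
    """
    x = np.asarray(potential, dtype=float)
    t_ox = _pow10((x - params.E1) / constants.slope_1e)
    t_red = _pow10((params.E2 - x) / constants.slope_1e)
    y = (t_ox + params.b) / (1.0 + t_ox + t_red)
    return float(y) if y.ndim == 0 else y


def fraction_oxidised_concerted(params: RedoxConcertedParams, potential,
                                constants: NernstConstants = NERNST):
    """Oxidised fraction y for a concerted two-electron transfer; symmetric
    about the midpoint: y(Em+d) + y(Em-d) = 1."""
    x = np.asarray(potential, dtype=float)
    y = 1.0 / (1.0 + _pow10((params.Em - x) / constants.slope_2e))
    return float(y) if y.ndim == 0 else y


def species_fractions_two_step(params: RedoxTwoStepParams, potential,
                               constants: NernstConstants = NERNST):
    """Population fractions (f_ox, f_sq, f_red) of the three redox states.

    The three denominator terms of the two-step model are read as relative
    populations oxidised : semiquinone : reduced =
    10^((x-E1)/59) : 1 : 10^((E2-x)/59).  The fractions sum to 1, and the
    semiquinone fraction peaks at x = (E1+E2)/2 with maximum
    1 / (1 + 2*10^((E2-E1)/118)) — large when E1 >> E2 (in this formula's
    orientation a strongly stabilised semiquinone), below 1/2 when E2
    exceeds E1 by more than ~35.5 mV.
    """
    x = np.asarray(potential, dtype=float)
    w_ox = _pow10((x - params.E1) / constants.slope_1e)
    w_red = _pow10((params.E2 - x) / constants.slope_1e)
    den = 1.0 + w_ox + w_red
    f_ox, f_sq, f_red = w_ox / den, 1.0 / den, w_red / den
    if x.ndim == 0:
        return float(f_ox), float(f_sq), float(f_red)
    return f_ox, f_sq, f_red


def normalise_titration(points: list[TitrationPoint],
                        endpoints: tuple[float, float]
                        ) -> list[tuple[float, float, bool]]:
    """Scale absorbances to oxidised fractions using endpoint absorbances.

    Parameters
    ----------
    points : list of TitrationPoint
    endpoints : (A_ox, A_red)
        Absorbance of the fully oxidised and fully reduced solution.

    Returns
    -------
    list of (potential, y, in_range)
        y = (A - A_red) / (A_ox - A_red).  Values outside [0, 1] are
        retained, not clipped; ``in_range`` flags them.
    """
    a_ox, a_red = endpoints
    if a_ox == a_red:
        raise DegenerateEndpointError("endpoint absorbances must differ")
    out = []
    for p in points:
        y = (p.absorbance - a_red) / (a_ox - a_red)
        out.append((p.potential, y, 0.0 <= y <= 1.0))
    return out
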