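"""Steady-state rate laws for a substituted-enzyme (ping-pong) nitroreductase
and the spectrophotometric arithmetic behind them.

The two-substrate rate law for a ping-pong mechanism, per enzyme,

    v/[E] = kcat [A][B] / (KmA [B] + KmB [A] + [A][B])

and its extension for an inhibitor that competes in both half-reactions,

    v/[E] = kcat [A][B] / (KmA [B](1 + [I]/KiA) + KmB [A](1 + [I]/KiB) + [A][B])

are evaluated here as pure functions, together with the helpers that turn a
raw absorbance-vs-time assay trace into a molar rate (Beer-Lambert, via a
table of reaction extinction-coefficient changes) and the two-wavelength
correction that separates holo-enzyme from free FMN in a protein prep.

Units are fixed package-wide: concentrations in uM, per-enzyme rates in s-1,
absolute rates in uM s-1, extinction coefficients in M-1 cm-1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "KineticObservation",
    "KineticParams",
    "InhibitionParams",
    "ExtinctionEntry",
    "AssayTrace",
    "ParameterDomainError",
    "InputDomainError",
    "InsufficientDataError",
    "InconsistentAbsorbanceError",
    "NO_INHIBITION",
    "EXTINCTION_TABLE",
    "EPS_FMN_454",
    "EPS_FMN_280",
    "EPS_NFSA_280",
    "pingpong_rate",
    "pingpong_inhibited_rate",
    "initial_rate_from_trace",
    "absorbance_rate_to_molar_rate",
    "protein_concentration",
    "find_extinction",
]


class ParameterDomainError(ValueError):
    """A model parameter is outside its physical domain."""


class InputDomainError(ValueError):
    """An input (concentration, potential, ...) is outside its domain."""


class InsufficientDataError(ValueError):
    """Too few points for the requested operation."""


class InconsistentAbsorbanceError(ValueError):
    """Two-wavelength absorbances are mutually inconsistent."""


#: Sentinel for "no inhibition in this half-reaction": the (1 + I/Ki)
#: factor is exactly 1 for any inhibitor concentration.
NO_INHIBITION = math.inf


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KineticObservation:
    """One initial-rate measurement.

    Parameters
    ----------
    conc_A, conc_B : float
        Substrate concentrations (uM). By convention A is the varied or
        nitroaromatic substrate and B the NADPH cofactor, but the rate law
        is symmetric under relabelling.
    conc_I : float
        Inhibitor concentration (uM); 0 when no inhibitor is present.
    conc_E : float
        Enzyme concentration (uM); must be positive so the rate can be
        normalised per enzyme at fit time.
    rate : float
        Measured initial rate v_i (uM s-1, absolute).
    label : str
        Optional substrate identity tag.
    """

    conc_A: float
    conc_B: float
    conc_I: float
    conc_E: float
    rate: float
    label: str = ""

    def __post_init__(self) -> None:
        for name in ("conc_A", "conc_B", "conc_I"):
            if getattr(self, name) < 0:
                raise InputDomainError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.conc_E <= 0:
            raise InputDomainError(f"conc_E must be > 0, got {self.conc_E}")
        if not math.isfinite(self.rate):
            raise InputDomainError("rate must be finite")


@dataclass(frozen=True)
class KineticParams:
    """Ping-pong rate-law parameters: turnover number and the two Michaelis
    constants.  kcat in s-1, Km_A and Km_B in uM; all strictly positive."""

    kcat: float
    Km_A: float
    Km_B: float

    def __post_init__(self) -> None:
        for name in ("kcat", "Km_A", "Km_B"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ParameterDomainError(f"{name} must be finite and > 0, got {v}")


@dataclass(frozen=True)
class InhibitionParams:
    """Mixed-inhibition extension: one dissociation constant per half-reaction.

    ``Ki_A`` or ``Ki_B`` may be the sentinel :data:`NO_INHIBITION`
    (``math.inf``) to encode that the inhibitor does not compete in that
    half-reaction; the corresponding (1 + I/Ki) factor is then exactly 1.
    """

    base: KineticParams
    Ki_A: float
    Ki_B: float

    def __post_init__(self) -> None:
        for name in ("Ki_A", "Ki_B"):
            v = getattr(self, name)
            if not v > 0 or math.isnan(v):
                raise ParameterDomainError(f"{name} must be > 0 (math.inf allowed), got {v}")


@dataclass(frozen=True)
class ExtinctionEntry:
    """Molar absorbance change for one assay readout.

    ``per_nadph`` marks coupled assays whose absorbance change is expressed
    per NADPH oxidised rather than per substrate converted; rates computed
    through such an entry are in NADPH-equivalents.
    """

    species: str
    wavelength: float  # nm
    delta_eps: float  # M-1 cm-1
    per_nadph: bool = False

    def __post_init__(self) -> None:
        if self.delta_eps <= 0:
            raise ParameterDomainError(f"delta_eps must be > 0, got {self.delta_eps}")
        if self.wavelength <= 0:
            raise ParameterDomainError(f"wavelength must be > 0, got {self.wavelength}")


@dataclass(frozen=True)
class AssayTrace:
    """A raw absorbance-vs-time trace from a spectrophotometric assay."""

    times: tuple  # s, strictly increasing
    absorbances: tuple  # AU
    wavelength: float  # nm
    path_length: float = 1.0  # cm

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        a = np.asarray(self.absorbances, dtype=float)
        if t.size < 3:
            raise InsufficientDataError("a trace needs at least 3 points")
        if t.size != a.size:
            raise InputDomainError("times and absorbances must have equal length")
        if not np.all(np.diff(t) > 0):
            raise InputDomainError("times must be strictly increasing")
        if self.path_length <= 0:
            raise ParameterDomainError("path_length must be > 0")
        object.__setattr__(self, "times", tuple(t))
        object.__setattr__(self, "absorbances", tuple(a))


#: Built-in reaction extinction-coefficient changes (M-1 cm-1).  User code may
#: extend this list or pass its own entries anywhere an ExtinctionEntry is
#: accepted.
EXTINCTION_TABLE: list[ExtinctionEntry] = [
    ExtinctionEntry("nitrofurazone", 420.0, 4300.0),
    ExtinctionEntry("nitrofurazone", 440.0, 880.0),
    ExtinctionEntry("nitrofurantoin", 400.0, 13807.0),
    ExtinctionEntry("nitrofurantoin", 420.0, 7970.0),
    ExtinctionEntry("CB1954", 420.0, 1200.0),
    ExtinctionEntry("cytochrome_c", 550.0, 13500.0, per_nadph=True),
    ExtinctionEntry("NADPH", 340.0, 6200.0),
]

# Molar absorbances for the protein-concentration correction (M-1 cm-1).
EPS_FMN_454 = 12200.0
EPS_FMN_280 = 20970.0
EPS_NFSA_280 = 31190.0


def find_extinction(species: str, wavelength: float,
                    table: list[ExtinctionEntry] | None = None) -> ExtinctionEntry:
    """Look up the extinction entry for *species* at *wavelength* (nm)."""
    for entry in (EXTINCTION_TABLE if table is None else table):
        if entry.species == species and entry.wavelength == wavelength:
            return entry
    raise KeyError(f"no extinction entry for {species!r} at {wavelength} nm")


# ---------------------------------------------------------------------------
# Rate laws
# ---------------------------------------------------------------------------

def pingpong_rate(params: KineticParams, conc_A, conc_B):
    """Per-enzyme rate (s-1) of the two-substrate ping-pong rate law.

    Accepts scalars or numpy arrays for the concentrations (broadcast).
    Returns 0 wherever A*B = 0; the result lies in [0, kcat).
    """
    A = np.asarray(conc_A, dtype=float)
    B = np.asarray(conc_B, dtype=float)
    if np.any(A < 0) or np.any(B < 0):
        raise InputDomainError("concentrations must be >= 0")
    num = params.kcat * A * B
    den = params.Km_A * B + params.Km_B * A + A * B
    with np.errstate(invalid="ignore"):
        v = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    return float(v) if v.ndim == 0 else v


def pingpong_inhibited_rate(iparams: InhibitionParams, conc_A, conc_B, conc_I):
    """Per-enzyme rate (s-1) with an inhibitor binding in one or both
    half-reactions.  Reduces exactly to :func:`pingpong_rate` at [I] = 0 and
    for ``Ki = NO_INHIBITION``; monotone non-increasing in [I]."""
    A = np.asarray(conc_A, dtype=float)
    B = np.asarray(conc_B, dtype=float)
    I = np.asarray(conc_I, dtype=float)
    if np.any(A < 0) or np.any(B < 0) or np.any(I < 0):
        raise InputDomainError("concentrations must be >= 0")
    p = iparams.base
    # inf Ki gives I/Ki == 0 exactly for finite I
    fac_A = 1.0 + I / iparams.Ki_A
    fac_B = 1.0 + I / iparams.Ki_B
    num = p.kcat * A * B
    den = p.Km_A * B * fac_A + p.Km_B * A * fac_B + A * B
    with np.errstate(invalid="ignore"):
        v = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    return float(v) if v.ndim == 0 else v


# ---------------------------------------------------------------------------
# Absorbance arithmetic
# ---------------------------------------------------------------------------

def initial_rate_from_trace(trace: AssayTrace,
                            window: tuple[float, float] | None = None
                            ) -> tuple[float, float]:
    """Ordinary least-squares slope (AU s-1) of a trace over a time window,
    with its standard error.

    The window defaults to the first 20% of the trace or the first 15 s,
    whichever is longer.  The slope's sign is preserved: assays followed by
    substrate disappearance give negative slopes.
    """
    t = np.asarray(trace.times)
    a = np.asarray(trace.absorbances)
    if window is None:
        t_end = t[0] + max(0.2 * (t[-1] - t[0]), 15.0)
        window = (t[0], t_end)
    lo, hi = window
    mask = (t >= lo) & (t <= hi)
    if mask.sum() < 3:
        raise InsufficientDataError(
            f"window [{lo}, {hi}] contains {int(mask.sum())} points; need >= 3")
    tw, aw = t[mask], a[mask]
    n = tw.size
    X = np.column_stack([np.ones(n), tw])
    coef, rss, _, _ = np.linalg.lstsq(X, aw, rcond=None)
    slope = float(coef[1])
    resid = aw - X @ coef
    s2 = float(resid @ resid) / (n - 2)
    sxx = float(np.sum((tw - tw.mean()) ** 2))
    se = math.sqrt(s2 / sxx)
    return slope, se


def absorbance_rate_to_molar_rate(slope: float, entry: ExtinctionEntry,
                                  path_length: float = 1.0) -> float:
    """Convert an absorbance rate (AU s-1) to a molar rate (uM s-1) through
    Beer-Lambert with the reaction's extinction-coefficient change.

    The magnitude of the slope is used, so decreasing traces give positive
    rates.  For ``per_nadph`` entries the result is in NADPH-equivalents.
    """
    if entry.delta_eps <= 0:
        raise ParameterDomainError("delta_eps must be > 0")
    if path_length <= 0:
        raise ParameterDomainError("path_length must be > 0")
    return abs(slope) / (entry.delta_eps * path_length) * 1e6


def protein_concentration(a280: float, a454: float,
                          path_length: float = 1.0) -> tuple[float, float]:
    """Holo-enzyme and free-FMN concentrations (uM) from absorbances at
    280 and 454 nm.

    Free FMN is read off A454 alone; its contribution at 280 nm is then
    subtracted before dividing by the enzyme's 280 nm molar absorbance.
    A negative corrected enzyme concentration is an error, never clipped.
    """
    if a280 < 0 or a454 < 0:
        raise InputDomainError("absorbances must be >= 0")
    if path_length <= 0:
        raise ParameterDomainError("path_length must be > 0")
    free_fmn_M = a454 / (EPS_FMN_454 * path_length)
    a280_fmn = free_fmn_M * EPS_FMN_280 * path_length
    if a280 < a280_fmn:
        raise InconsistentAbsorbanceError(
            f"A280={a280} is below the free-FMN contribution {a280_fmn:.4f}")
    nfsa_M = (a280 - a280_fmn) / (EPS_NFSA_280 * path_length)
    return nfsa_M * 1e6, free_fmn_M * 1e6
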