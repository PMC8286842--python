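"""Forward simulation of every input the analysis consumes: initial-rate
surfaces from the ping-pong rate laws, spectroelectrochemical titration
curves from the Nernst models, and raw absorbance traces.

The defaults emulate the experimental designs behind the analysis: full
factorial substrate grids spanning 0.25-8x each Michaelis constant, ~10 nM
enzyme, 3% multiplicative measurement noise (matching the few-percent
standard errors typical of such fits), inhibitor at zero and two nonzero
levels around Ki, and the down-then-up 20 mV potential-step schedule of an
OTTLE titration from -50 to -350 mV.  Every generator is deterministic
given its seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .rate_models import (
    AssayTrace,
    ExtinctionEntry,
    InhibitionParams,
    InputDomainError,
    KineticObservation,
    KineticParams,
    pingpong_inhibited_rate,
    pingpong_rate,
)
from .redox_models import (
    DegenerateEndpointError,
    RedoxConcertedParams,
    RedoxTwoStepParams,
    TitrationPoint,
    fraction_oxidised_concerted,
    fraction_oxidised_two_step,
)
from .fitting import DesignDeficientError

__all__ = [
    "NoiseModel",
    "DesignGrid",
    "NOISELESS",
    "default_kinetics_grid",
    "default_inhibition_design",
    "ottle_potential_schedule",
    "simulate_kinetics",
    "simulate_inhibition",
    "simulate_titration",
    "simulate_assay_trace",
]

#: Km multipliers of the default factorial design: spans the
#: information-rich region around each Michaelis constant.
_KM_MULTIPLIERS = (0.25, 0.5, 1.0, 2.0, 4.0, 8.0)

#: Default enzyme concentration, uM (assays are started with ~10 nM enzyme).
_DEFAULT_CONC_E = 0.01


@dataclass(frozen=True)
class NoiseModel:
    """Measurement-noise description.

    kind : 'multiplicative-Gaussian' scales each value by (1 + cv*z);
           'additive-Gaussian' adds sigma_abs*z; 'mixed' does both.
    cv : coefficient of variation of the multiplicative part (default 3%).
    sigma_abs : additive floor in the observable's units (AU for
           titrations/traces; default 1e-4).
    seed : RNG seed, recorded in the provenance of everything generated.
    """

    kind: str = "multiplicative-Gaussian"
    cv: float = 0.03
    sigma_abs: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("multiplicative-Gaussian", "additive-Gaussian",
                             "mixed", "none"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.cv < 0 or self.sigma_abs < 0:
            raise ValueError("cv and sigma_abs must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def apply(self, values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        out = np.asarray(values, dtype=float).copy()
        if self.kind in ("multiplicative-Gaussian", "mixed") and self.cv > 0:
            out = out * (1.0 + self.cv * rng.standard_normal(out.shape))
        if self.kind in ("additive-Gaussian", "mixed") and self.sigma_abs > 0:
            out = out + self.sigma_abs * rng.standard_normal(out.shape)
        return out


NOISELESS = NoiseModel(kind="none", cv=0.0, sigma_abs=0.0)


@dataclass(frozen=True)
class DesignGrid:
    """Concentration design for a simulated rate experiment (all uM)."""

    conc_A_levels: tuple
    conc_B_levels: tuple
    conc_I_levels: tuple = (0.0,)
    conc_E: float = _DEFAULT_CONC_E
    replicates: int = 1

    def __post_init__(self) -> None:
        for name in ("conc_A_levels", "conc_B_levels", "conc_I_levels"):
            levels = tuple(float(v) for v in getattr(self, name))
            if any(v < 0 for v in levels):
                raise InputDomainError(f"{name} must all be >= 0")
            object.__setattr__(self, name, levels)
        if self.conc_E <= 0:
            raise InputDomainError("conc_E must be > 0")
        if self.replicates < 1:
            raise InputDomainError("replicates must be >= 1")
        if not self.conc_A_levels or not self.conc_B_levels:
            raise DesignDeficientError("empty concentration grid")


def default_kinetics_grid(params: KineticParams,
                          conc_E: float = _DEFAULT_CONC_E,
                          replicates: int = 1) -> DesignGrid:
    """Full factorial 6x6 grid at 0.25-8x each Km, one replicate."""
    return DesignGrid(
        conc_A_levels=tuple(params.Km_A * m for m in _KM_MULTIPLIERS),
        conc_B_levels=tuple(params.Km_B * m for m in _KM_MULTIPLIERS),
        conc_E=conc_E, replicates=replicates)


def simulate_kinetics(params: KineticParams, grid: DesignGrid,
                      noise: NoiseModel = NOISELESS
                      ) -> list[KineticObservation]:
    """Initial rates on a factorial grid from the ping-pong rate law, with
    measurement noise applied to the absolute rates."""
    if len(grid.conc_A_levels) < 2 or len(grid.conc_B_levels) < 2:
        raise DesignDeficientError(
            "grid must span >= 2 levels of each substrate")
    rng = noise.rng()
    obs = []
    A_levels, B_levels = grid.conc_A_levels, grid.conc_B_levels
    AA, BB = np.meshgrid(A_levels, B_levels, indexing="ij")
    AA, BB = AA.ravel(), BB.ravel()
    for _ in range(grid.replicates):
        rates = pingpong_rate(params, AA, BB) * grid.conc_E
        rates = noise.apply(rates, rng)
        for a, b, r in zip(AA, BB, rates):
            obs.append(KineticObservation(
                conc_A=float(a), conc_B=float(b), conc_I=0.0,
                conc_E=grid.conc_E, rate=float(r)))
    return obs


def default_inhibition_design(iparams: InhibitionParams,
                              fixed_A: float = 97.0, fixed_B: float = 99.0,
                              conc_E: float = _DEFAULT_CONC_E) -> DesignGrid:
    """The inhibition protocol's design: one substrate varied at a fixed,
    near-saturating co-substrate concentration, inhibitor at 0 and two
    nonzero levels ({0, Ki, 2.5 Ki} around the smaller finite Ki).

    The returned grid's A levels are used with B fixed at ``fixed_B`` and
    vice versa by :func:`simulate_inhibition`.
    """
    finite = [k for k in (iparams.Ki_A, iparams.Ki_B) if math.isfinite(k)]
    ki = min(finite) if finite else 10.0
    p = iparams.base
    return DesignGrid(
        conc_A_levels=tuple(p.Km_A * m for m in _KM_MULTIPLIERS),
        conc_B_levels=tuple(p.Km_B * m for m in _KM_MULTIPLIERS),
        conc_I_levels=(0.0, ki, 2.5 * ki),
        conc_E=conc_E)


def simulate_inhibition(iparams: InhibitionParams, grid: DesignGrid,
                        noise: NoiseModel = NOISELESS,
                        fixed_A: float = 97.0, fixed_B: float = 99.0
                        ) -> list[KineticObservation]:
    """Mixed-inhibition dataset in the experimental layout: series varying
    A at fixed B and series varying B at fixed A, each at every inhibitor
    level (which must include 0)."""
    I_levels = grid.conc_I_levels
    if 0.0 not in I_levels:
        raise DesignDeficientError("inhibitor levels must include 0")
    if len(I_levels) < 2:
        raise DesignDeficientError("need >= 2 inhibitor levels")
    rng = noise.rng()
    A = np.concatenate([np.asarray(grid.conc_A_levels, dtype=float),
                        np.full(len(grid.conc_B_levels), fixed_A)])
    B = np.concatenate([np.full(len(grid.conc_A_levels), fixed_B),
                        np.asarray(grid.conc_B_levels, dtype=float)])
    obs = []
    for _ in range(grid.replicates):
        for conc_i in I_levels:
            rates = pingpong_inhibited_rate(iparams, A, B, conc_i) * grid.conc_E
            rates = noise.apply(rates, rng)
            for a, b, r in zip(A, B, rates):
                obs.append(KineticObservation(
                    conc_A=float(a), conc_B=float(b), conc_I=float(conc_i),
                    conc_E=grid.conc_E, rate=float(r)))
    return obs


def ottle_potential_schedule() -> tuple[tuple[float, ...], tuple[float, ...]]:
    """The OTTLE stepping protocol: a reductive sweep from -50 to -350 mV
    in 20 mV steps, then a reversed (oxidative) sweep at -335 and from
    -320 to -90 mV in 20 mV steps, finishing at -60 mV."""
    down = tuple(float(v) for v in range(-50, -351, -20))
    up = (-335.0,) + tuple(float(v) for v in range(-320, -89, 20)) + (-60.0,)
    return down, up


def simulate_titration(truth, potentials=None,
                       endpoints: tuple[float, float] = (0.8, 0.1),
                       noise: NoiseModel = NOISELESS,
                       cycles: str = "both",
                       replicate: str = "1") -> list[TitrationPoint]:
    """Titration points from a Nernst model truth (two-step or concerted).

    absorbance = A_red + y(x) (A_ox - A_red) + noise.  With the default
    ``potentials=None`` the stepping protocol of
    :func:`ottle_potential_schedule` is used; ``cycles`` selects both
    sweeps or only the reductive one.
    """
    a_ox, a_red = endpoints
    if a_ox == a_red:
        raise DegenerateEndpointError("endpoint absorbances must differ")
    if isinstance(truth, RedoxTwoStepParams):
        y_of = lambda x: fraction_oxidised_two_step(truth, x)
    elif isinstance(truth, RedoxConcertedParams):
        y_of = lambda x: fraction_oxidised_concerted(truth, x)
    else:
        raise TypeError("truth must be RedoxTwoStepParams or RedoxConcertedParams")
    if cycles not in ("both", "single"):
        raise ValueError("cycles must be 'both' or 'single'")
    if potentials is None:
        down, up = ottle_potential_schedule()
        sweeps = [("reductive", down)] + ([("oxidative", up)] if cycles == "both" else [])
    else:
        sweeps = [("reductive", tuple(float(v) for v in potentials))]
        if not sweeps[0][1]:
            raise InputDomainError("potentials must be non-empty")
    rng = noise.rng()
    points = []
    for cycle, xs in sweeps:
        x = np.asarray(xs, dtype=float)
        a = a_red + np.asarray(y_of(x)) * (a_ox - a_red)
        # titration noise is dominated by the additive absorbance floor
        a = noise.apply(a, rng)
        for xi, ai in zip(x, a):
            points.append(TitrationPoint(potential=float(xi),
                                         absorbance=float(max(ai, 0.0)),
                                         cycle=cycle, replicate=replicate))
    return points


def simulate_assay_trace(molar_rate: float, entry: ExtinctionEntry,
                         duration: float = 60.0, dt: float = 1.0,
                         noise: NoiseModel = NOISELESS,
                         a0: float = 1.0, increasing: bool = False
                         ) -> AssayTrace:
    """A linear absorbance trace whose slope encodes a molar rate through
    the extinction-coefficient change (slope = rate * delta_eps in AU s-1
    for a 1 cm path; decreasing by default, as for substrate-depletion
    assays)."""
    if not duration > dt > 0:
        raise InputDomainError("need duration > dt > 0")
    t = np.arange(0.0, duration + dt / 2, dt)
    slope = molar_rate * 1e-6 * entry.delta_eps * (1.0 if increasing else -1.0)
    a = a0 + slope * t
    rng = noise.rng()
    if noise.kind in ("additive-Gaussian", "mixed") and noise.sigma_abs > 0:
        a = a + noise.sigma_abs * rng.standard_normal(a.shape)
    elif noise.kind == "multiplicative-Gaussian" and noise.cv > 0:
        a = a * (1.0 + noise.cv * rng.standard_normal(a.shape))
    return AssayTrace(times=tuple(t), absorbances=tuple(a),
                      wavelength=entry.wavelength)
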