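"""Global nonlinear least-squares estimation for the kinetic and redox
models, with uncertainty statistics, nested-model comparison and
derived-parameter error propagation.

All fits minimise an unweighted residual sum of squares (the experimental
protocol weights all points equally), use a trust-region least-squares
optimiser with multi-start refinement, and fit strictly positive parameters
(kcat, Km, Ki, b) in log-space so positivity is structural rather than
enforced by bounds; potentials are fitted in natural space.  Standard
errors come from the Gauss-Newton covariance s^2 (J^T J)^-1 evaluated at
the optimum in natural parameter space, and per-parameter P values are
two-sided t tests of the estimate against zero on the residual degrees of
freedom.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .rate_models import (
    NO_INHIBITION,
    InhibitionParams,
    KineticObservation,
    KineticParams,
    pingpong_inhibited_rate,
    pingpong_rate,
)
from .redox_models import (
    RedoxConcertedParams,
    RedoxTwoStepParams,
    TitrationPoint,
    fraction_oxidised_concerted,
    fraction_oxidised_two_step,
    normalise_titration,
)

__all__ = [
    "FitResult",
    "ModelComparison",
    "RedoxFit",
    "DesignDeficientError",
    "NonNestedModelsError",
    "fit_pingpong_global",
    "fit_single_substrate",
    "fit_inhibition_global",
    "fit_redox",
    "compare_nested",
    "compare_aicc",
    "derived_efficiency",
    "parameter_significance",
    "aicc",
]

# Convergence tolerances for all fits: cost and parameter tolerances chosen
# well below any reported precision.
_FTOL = 1e-12
_XTOL = 1e-10
_COST_TIE = 1e-9
_DEFAULT_STARTS = 8


class DesignDeficientError(ValueError):
    """The experimental design cannot identify the requested parameters."""


class NonNestedModelsError(ValueError):
    """compare_nested was given fits that are not a nested pair."""


# ---------------------------------------------------------------------------
# Result containers
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """A converged (or flagged) least-squares fit.

    ``estimates``, ``standard_errors`` and ``p_values`` are keyed by
    parameter name; ``covariance`` is ordered as ``param_names`` restricted
    to the free parameters.  ``dof`` is n_points minus the number of free
    parameters.
    """

    model_id: str
    param_names: tuple
    estimates: dict
    standard_errors: dict
    p_values: dict
    rss: float
    dof: int
    covariance: np.ndarray
    converged: bool
    n_points: int
    free_names: tuple = ()
    warnings: tuple = ()
    provenance: dict = field(default_factory=dict)

    @property
    def aicc(self) -> float:
        return aicc(self.rss, self.n_points, len(self.free_names))

    def params_kinetic(self) -> KineticParams:
        e = self.estimates
        return KineticParams(kcat=e["kcat"], Km_A=e["Km_A"], Km_B=e["Km_B"])


@dataclass
class ModelComparison:
    """Extra-sum-of-squares comparison between a full and a nested reduced
    model, optionally backed by a small-sample information criterion."""

    full_model: FitResult
    reduced_model: FitResult
    f_statistic: float
    p_value: float
    preferred: str
    alpha: float = 0.05
    approximate: bool = False
    aicc_full: float | None = None
    aicc_reduced: float | None = None


@dataclass
class RedoxFit:
    """Output of the two-stage titration analysis: both model fits, their
    comparison, the per-cycle endpoint estimates and any warnings."""

    two_step: FitResult
    concerted: FitResult
    comparison: ModelComparison
    endpoints: dict
    scaled: list
    warnings: tuple = ()


# ---------------------------------------------------------------------------
# Generic multi-start driver
# ---------------------------------------------------------------------------

def _multistart_fit(residual_fn, starts, log_mask, bounds=None):
    """Run `least_squares` from each start and keep the best optimum.

    ``log_mask[j]`` fits parameter j as log10 (positivity without bounds);
    ``bounds`` applies in internal space when given.  Ties within a cost of
    1e-9 are broken by the smaller natural-parameter norm, for determinism.
    Returns (theta_natural, rss, J_natural, converged, n_evals).
    """
    log_mask = np.asarray(log_mask, dtype=bool)

    def to_internal(theta):
        u = np.array(theta, dtype=float)
        u[log_mask] = np.log(u[log_mask])
        return u

    def to_natural(u):
        theta = np.array(u, dtype=float)
        theta[log_mask] = np.exp(theta[log_mask])
        return theta

    def resid_internal(u):
        return residual_fn(to_natural(u))

    best = None
    n_evals = 0
    for start in starts:
        try:
            res = optimize.least_squares(
                resid_internal, to_internal(start), method="trf",
                ftol=_FTOL, xtol=_XTOL, gtol=1e-12,
                bounds=bounds if bounds is not None else (-np.inf, np.inf))
        except Exception:
            continue
        n_evals += res.nfev
        theta = to_natural(res.x)
        cand = (2.0 * res.cost, float(np.linalg.norm(theta)), theta, res)
        if best is None or cand[0] < best[0] - _COST_TIE or (
                abs(cand[0] - best[0]) <= _COST_TIE and cand[1] < best[1]):
            best = cand
    if best is None:
        raise RuntimeError("all optimizer starts failed")
    rss, _, theta, res = best
    # chain rule: column j of dr/dtheta is dr/du / theta_j for log params
    J = np.array(res.jac, dtype=float)
    J[:, log_mask] = J[:, log_mask] / theta[log_mask]
    return theta, float(rss), J, res.status > 0, n_evals


def _covariance(J, rss, dof):
    """Gauss-Newton parameter covariance s^2 (J^T J)^-1 (pinv if singular)."""
    s2 = rss / dof if dof > 0 else np.nan
    JtJ = J.T @ J
    try:
        inv = np.linalg.inv(JtJ)
    except np.linalg.LinAlgError:
        inv = np.linalg.pinv(JtJ)
    return s2 * inv


def _build_result(model_id, free_names, theta, rss, J, converged, n_points,
                  fixed=None, warnings=(), provenance=None):
    dof = n_points - len(free_names)
    if dof <= 0:
        raise DesignDeficientError(
            f"{n_points} points cannot constrain {len(free_names)} parameters")
    cov = _covariance(J, rss, dof)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    estimates = dict(zip(free_names, (float(v) for v in theta)))
    ses = dict(zip(free_names, (float(v) for v in se)))
    pvals = {name: parameter_significance(estimates[name], ses[name], dof)
             for name in free_names}
    names = tuple(free_names)
    if fixed:
        for k, v in fixed.items():
            estimates[k] = v
            ses[k] = float("nan")
            pvals[k] = float("nan")
        names = names + tuple(fixed)
    return FitResult(
        model_id=model_id, param_names=names, estimates=estimates,
        standard_errors=ses, p_values=pvals, rss=rss, dof=dof,
        covariance=cov, converged=converged, n_points=n_points,
        free_names=tuple(free_names), warnings=tuple(warnings),
        provenance=provenance or {})


def _starts_around(theta0, n_starts, rng, log_mask, spread=0.7):
    """The heuristic start plus seeded log-normal / normal perturbations."""
    theta0 = np.asarray(theta0, dtype=float)
    starts = [theta0.copy()]
    log_mask = np.asarray(log_mask, dtype=bool)
    for _ in range(n_starts - 1):
        t = theta0.copy()
        t[log_mask] = t[log_mask] * np.exp(rng.normal(0.0, spread, log_mask.sum()))
        t[~log_mask] = t[~log_mask] + rng.normal(0.0, 30.0, (~log_mask).sum())
        starts.append(t)
    return starts


# ---------------------------------------------------------------------------
# Kinetic fits
# ---------------------------------------------------------------------------

def _weights(v, weighting):
    """Residual weights: unit by default; 'relative' divides by the
    observed rate (guarded against zeros)."""
    if weighting == "unit":
        return 1.0
    if weighting == "relative":
        return 1.0 / np.maximum(np.abs(v), 1e-12)
    raise ValueError("weighting must be 'unit' or 'relative'")


def _kinetic_arrays(data):
    A = np.array([o.conc_A for o in data])
    B = np.array([o.conc_B for o in data])
    I = np.array([o.conc_I for o in data])
    v = np.array([o.rate / o.conc_E for o in data])  # per-enzyme, s-1
    return A, B, I, v


def fit_pingpong_global(data: list[KineticObservation],
                        n_starts: int = _DEFAULT_STARTS,
                        seed: int = 0,
                        weighting: str = "unit") -> FitResult:
    """Fit the ping-pong rate law globally to rates over both substrates.

    Rates are normalised by the enzyme concentration of each observation and
    fitted with unit weights by default (``weighting="relative"`` divides
    each residual by the observed rate instead).  Needs at least 4
    observations spanning at least 2 distinct concentrations of each
    substrate.
    """
    if len(data) < 4:
        raise DesignDeficientError("need >= 4 observations")
    A, B, I, v = _kinetic_arrays(data)
    if np.unique(A).size < 2 or np.unique(B).size < 2:
        raise DesignDeficientError(
            "both substrates must take >= 2 distinct concentrations")
    w = _weights(v, weighting)

    def residual(theta):
        p = KineticParams(*theta)
        return (v - pingpong_rate(p, A, B)) * w

    rng = np.random.default_rng(seed)
    theta0 = [max(v.max(), 1e-6), np.median(A[A > 0]), np.median(B[B > 0])]
    starts = _starts_around(theta0, n_starts, rng, [True] * 3)
    theta, rss, J, conv, nev = _multistart_fit(residual, starts, [True] * 3)
    return _build_result(
        "pingpong", ("kcat", "Km_A", "Km_B"), theta, rss, J, conv, len(data),
        provenance={"seed": seed, "n_starts": n_starts, "n_evals": nev})


def fit_single_substrate(data: list[KineticObservation],
                         substrate: str = "A",
                         n_starts: int = _DEFAULT_STARTS,
                         seed: int = 0) -> FitResult:
    """Apparent-parameter fit at fixed co-substrate: a single-substrate
    saturation hyperbola v/[E] = kcat_app S / (Km_app + S)."""
    if substrate not in ("A", "B"):
        raise ValueError("substrate must be 'A' or 'B'")
    A, B, I, v = _kinetic_arrays(data)
    S = A if substrate == "A" else B
    if np.unique(S).size < 3:
        raise DesignDeficientError(
            "need >= 3 distinct concentrations of the varied substrate")

    def residual(theta):
        kcat_app, km_app = theta
        return v - kcat_app * S / (km_app + S)

    rng = np.random.default_rng(seed)
    theta0 = [max(v.max(), 1e-6), np.median(S[S > 0])]
    starts = _starts_around(theta0, n_starts, rng, [True] * 2)
    theta, rss, J, conv, nev = _multistart_fit(residual, starts, [True] * 2)
    return _build_result(
        "single_substrate", ("kcat_app", "Km_app"), theta, rss, J, conv,
        len(data),
        provenance={"seed": seed, "n_starts": n_starts, "n_evals": nev,
                    "substrate": substrate})


_INHIBITION_MODES = ("both_halves", "half_A_only", "half_B_only")


def fit_inhibition_global(data: list[KineticObservation],
                          mode: str = "both_halves",
                          n_starts: int = _DEFAULT_STARTS,
                          seed: int = 0,
                          weighting: str = "unit") -> FitResult:
    """Simultaneous fit of the dual-half-reaction inhibition rate law to all
    series (each substrate varied, with and without inhibitor).

    ``mode`` selects which half-reactions the inhibitor competes in; in the
    half-only modes the excluded Ki is fixed at the no-inhibition sentinel
    (the corresponding factor is exactly 1) and not fitted.
    """
    if mode not in _INHIBITION_MODES:
        raise ValueError(f"mode must be one of {_INHIBITION_MODES}")
    A, B, I, v = _kinetic_arrays(data)
    w = _weights(v, weighting)
    if not np.any(I == 0):
        raise DesignDeficientError("need an inhibitor-free series (I = 0)")
    if np.unique(I).size < 2:
        raise DesignDeficientError("need >= 2 inhibitor levels including 0")
    if np.unique(A).size < 2 or np.unique(B).size < 2:
        raise DesignDeficientError(
            "both substrates must take >= 2 distinct concentrations")

    fit_ki_a = mode in ("both_halves", "half_A_only")
    fit_ki_b = mode in ("both_halves", "half_B_only")
    free = ["kcat", "Km_A", "Km_B"] + (["Ki_A"] if fit_ki_a else []) \
        + (["Ki_B"] if fit_ki_b else [])

    def residual(theta):
        kcat, km_a, km_b = theta[:3]
        j = 3
        ki_a = theta[j] if fit_ki_a else NO_INHIBITION
        j += fit_ki_a
        ki_b = theta[j] if fit_ki_b else NO_INHIBITION
        ip = InhibitionParams(KineticParams(kcat, km_a, km_b), ki_a, ki_b)
        return (v - pingpong_inhibited_rate(ip, A, B, I)) * w

    rng = np.random.default_rng(seed)
    ki0 = np.median(I[I > 0])
    theta0 = [max(v.max(), 1e-6), np.median(A[A > 0]), np.median(B[B > 0])] \
        + [ki0] * (fit_ki_a + fit_ki_b)
    k = len(theta0)
    starts = _starts_around(theta0, n_starts, rng, [True] * k)
    theta, rss, J, conv, nev = _multistart_fit(residual, starts, [True] * k)
    fixed = {}
    if not fit_ki_a:
        fixed["Ki_A"] = NO_INHIBITION
    if not fit_ki_b:
        fixed["Ki_B"] = NO_INHIBITION
    return _build_result(
        f"pingpong_inhibited/{mode}", tuple(free), theta, rss, J, conv,
        len(data), fixed=fixed,
        provenance={"seed": seed, "n_starts": n_starts, "n_evals": nev,
                    "mode": mode})


# ---------------------------------------------------------------------------
# Redox titration fits
# ---------------------------------------------------------------------------

def _fit_cycle_endpoints(x, a, n_starts, rng):
    """Stage 1: estimate (A_ox, A_red) of one half-titration.

    Both candidate models are fitted with free endpoint absorbances and the
    endpoints of the better-fitting one are adopted, so that noiseless data
    of either shape yields exact endpoints.
    """
    a_ox0, a_red0 = float(a.max()), float(a.min())
    em0 = float(x[np.argmin(np.abs(a - 0.5 * (a_ox0 + a_red0)))])
    # endpoints may extrapolate up to 2x the observed absorbance span
    span = 2.0 * max(a_ox0 - a_red0, 1e-6)

    def resid_concerted(theta):
        em, aox, ared = theta
        y = fraction_oxidised_concerted(RedoxConcertedParams(em), x)
        return a - (ared + (aox - ared) * y)

    def resid_two_step(theta):
        e1, e2, b, aox, ared = theta
        y = fraction_oxidised_two_step(RedoxTwoStepParams(e1, e2, max(b, 0.0)), x)
        return a - (ared + (aox - ared) * y)

    starts_c = [[em0 + rng.normal(0.0, 20.0) * (i > 0), a_ox0, a_red0]
                for i in range(n_starts)]
    lo = [-np.inf, a_red0 - span, a_red0 - span]
    hi = [np.inf, a_ox0 + span, a_ox0 + span]
    best = None
    theta_c, rss_c, _, conv_c, _ = _multistart_fit(
        resid_concerted, starts_c, [False] * 3, bounds=(lo, hi))
    best = ("concerted", rss_c, theta_c[1], theta_c[2], conv_c)
    if x.size >= 7:
        starts_t = [[em0 + rng.normal(0.0, 20.0) * (i > 0),
                     em0 + rng.normal(0.0, 20.0) * (i > 0),
                     0.3, a_ox0, a_red0] for i in range(n_starts)]
        lo_t = [-np.inf, -np.inf, 0.0, a_red0 - span, a_red0 - span]
        hi_t = [np.inf, np.inf, 5.0, a_ox0 + span, a_ox0 + span]
        try:
            theta_t, rss_t, _, conv_t, _ = _multistart_fit(
                resid_two_step, starts_t, [False] * 5, bounds=(lo_t, hi_t))
            if rss_t < rss_c:
                best = ("two_step", rss_t, theta_t[3], theta_t[4], conv_t)
        except RuntimeError:
            pass
    model, rss, a_ox, a_red, conv = best
    return {"A_ox": float(a_ox), "A_red": float(a_red),
            "stage1_model": model, "stage1_rss": float(rss),
            "converged": bool(conv)}


def fit_redox(points: list[TitrationPoint], alpha: float = 0.05,
              n_starts: int = _DEFAULT_STARTS, seed: int = 0) -> RedoxFit:
    """Two-stage analysis of a spectroelectrochemical titration.

    Stage 1 fits each half-titration (grouped by replicate and cycle)
    separately with free endpoint absorbances to estimate the fully
    oxidised and fully reduced absorbance of that cycle.  Stage 2 scales
    every point to an oxidised fraction with its cycle's endpoints, pools
    all cycles, and fits both the two-step and the concerted Nernst model
    to the pooled scaled data.  The models are compared by small-sample
    corrected information criterion (primary) and by an approximate
    extra-sum-of-squares F test.
    """
    if len(points) < 5:
        raise DesignDeficientError("need >= 5 titration points")
    rng = np.random.default_rng(seed)
    groups: dict[tuple, list[TitrationPoint]] = {}
    for p in points:
        groups.setdefault((p.replicate, p.cycle), []).append(p)

    warnings: list[str] = []
    endpoints: dict[tuple, dict] = {}
    scaled: list[tuple[float, float, bool]] = []
    for key, pts in groups.items():
        x = np.array([p.potential for p in pts])
        a = np.array([p.absorbance for p in pts])
        ep = _fit_cycle_endpoints(x, a, n_starts, rng)
        endpoints[key] = ep
        scaled.extend(normalise_titration(pts, (ep["A_ox"], ep["A_red"])))

    xs = np.array([s[0] for s in scaled])
    ys = np.array([s[1] for s in scaled])
    if ys.max() - ys.min() < 0.5:
        warnings.append(
            "poorly-anchored endpoints: scaled titration spans "
            f"{ys.max() - ys.min():.2f} < 0.5 of the oxidised-fraction range")
    if any(not s[2] for s in scaled):
        warnings.append("scaled oxidised fractions outside [0, 1] retained")

    em0 = float(xs[np.argmin(np.abs(ys - 0.5))])

    def resid_two_step(theta):
        e1, e2, b = theta
        return ys - fraction_oxidised_two_step(
            RedoxTwoStepParams(e1, e2, max(b, 0.0)), xs)

    def resid_concerted(theta):
        return ys - fraction_oxidised_concerted(RedoxConcertedParams(theta[0]), xs)

    starts_t = [[em0 + rng.normal(0.0, 25.0) * (i > 0),
                 em0 + rng.normal(0.0, 25.0) * (i > 0),
                 min(0.3 * math.exp(rng.normal(0.0, 0.5) * (i > 0)), 4.0)]
                for i in range(n_starts)]
    theta_t, rss_t, J_t, conv_t, nev_t = _multistart_fit(
        resid_two_step, starts_t, [False] * 3,
        bounds=([-np.inf, -np.inf, 0.0], [np.inf, np.inf, 5.0]))
    two_step = _build_result(
        "nernst_two_step", ("E1", "E2", "b"), theta_t, rss_t, J_t, conv_t,
        xs.size, warnings=warnings,
        provenance={"seed": seed, "n_starts": n_starts, "n_evals": nev_t})

    starts_c = [[em0 + rng.normal(0.0, 25.0) * (i > 0)] for i in range(n_starts)]
    theta_c, rss_c, J_c, conv_c, nev_c = _multistart_fit(
        resid_concerted, starts_c, [False])
    concerted = _build_result(
        "nernst_concerted", ("Em",), theta_c, rss_c, J_c, conv_c,
        xs.size, warnings=warnings,
        provenance={"seed": seed, "n_starts": n_starts, "n_evals": nev_c})

    comparison = compare_nested(two_step, concerted, alpha=alpha,
                                approximate=True, use_aicc=True)
    return RedoxFit(two_step=two_step, concerted=concerted,
                    comparison=comparison, endpoints=endpoints,
                    scaled=scaled, warnings=tuple(warnings))


# ---------------------------------------------------------------------------
# Model comparison and derived statistics
# ---------------------------------------------------------------------------

def aicc(rss: float, n: int, n_params: int) -> float:
    """Small-sample corrected Akaike information criterion of a Gaussian
    least-squares fit; k counts the fitted parameters plus the variance."""
    k = n_params + 1
    if n - k - 1 <= 0:
        return math.inf
    return n * math.log(max(rss, 1e-300) / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def compare_nested(full: FitResult, reduced: FitResult, alpha: float = 0.05,
                   approximate: bool = False,
                   use_aicc: bool = False) -> ModelComparison:
    """Extra-sum-of-squares F test between a full model and a reduced model
    fitted to the same data.

    F = ((rss_r - rss_f) / (df_r - df_f)) / (rss_f / df_f), with the
    p-value from the upper F tail; the full model is preferred when
    p < alpha.  With ``use_aicc`` the preference is instead decided by the
    small-sample information criterion (used when the pair is only
    approximately nested) and the F test is reported alongside, flagged
    approximate.
    """
    if full.n_points != reduced.n_points:
        raise NonNestedModelsError("fits are not on the same data")
    if len(reduced.free_names) >= len(full.free_names):
        raise NonNestedModelsError(
            "reduced model must have fewer free parameters than the full model")
    df_f, df_r = full.dof, reduced.dof
    rss_f, rss_r = full.rss, reduced.rss
    num = max(rss_r - rss_f, 0.0) / (df_r - df_f)
    if rss_f <= 0:
        f_stat = math.inf if rss_r > rss_f else 0.0
        p = 0.0 if rss_r > rss_f else 1.0
    else:
        f_stat = num / (rss_f / df_f)
        p = float(stats.f.sf(f_stat, df_r - df_f, df_f))
    if use_aicc:
        a_full, a_red = full.aicc, reduced.aicc
        preferred = full.model_id if a_full < a_red else reduced.model_id
    else:
        a_full = a_red = None
        preferred = full.model_id if p < alpha else reduced.model_id
    return ModelComparison(
        full_model=full, reduced_model=reduced, f_statistic=float(f_stat),
        p_value=p, preferred=preferred, alpha=alpha,
        approximate=approximate, aicc_full=a_full, aicc_reduced=a_red)


def compare_aicc(fit_a: FitResult, fit_b: FitResult) -> str:
    """Model id of the fit with the lower small-sample information
    criterion (non-nested comparison)."""
    return fit_a.model_id if fit_a.aicc < fit_b.aicc else fit_b.model_id


def derived_efficiency(kcat: float, km: float,
                       var_kcat: float = 0.0, var_km: float = 0.0,
                       cov_kcat_km: float | None = None
                       ) -> tuple[float, float, bool]:
    """Catalytic efficiency kcat/Km (s-1 uM-1) with first-order propagated
    standard error.

    The gradient of kcat/Km is (1/Km, -kcat/Km^2); the propagated variance
    uses both parameter variances and, when supplied, their covariance.
    Returns (efficiency, standard error, covariance_used).
    """
    if km <= 0:
        raise ValueError("Km must be > 0")
    eff = kcat / km
    g = np.array([1.0 / km, -kcat / km ** 2])
    used_cov = cov_kcat_km is not None
    c = cov_kcat_km if used_cov else 0.0
    var = g[0] ** 2 * var_kcat + g[1] ** 2 * var_km + 2 * g[0] * g[1] * c
    return eff, math.sqrt(max(var, 0.0)), used_cov


def efficiency_from_fit(fit: FitResult, kcat_name: str = "kcat",
                        km_name: str = "Km_A") -> tuple[float, float, bool]:
    """Catalytic efficiency for a fitted parameter pair, using the fit's
    covariance between kcat and Km."""
    i = fit.free_names.index(kcat_name)
    j = fit.free_names.index(km_name)
    return derived_efficiency(
        fit.estimates[kcat_name], fit.estimates[km_name],
        var_kcat=float(fit.covariance[i, i]),
        var_km=float(fit.covariance[j, j]),
        cov_kcat_km=float(fit.covariance[i, j]))


def parameter_significance(estimate: float, se: float, dof: int) -> float:
    """Two-sided p-value of t = estimate/SE against zero with `dof` residual
    degrees of freedom; SE = 0 with a nonzero estimate gives p = 0."""
    if dof <= 0:
        return float("nan")
    if se == 0:
        return 1.0 if estimate == 0 else 0.0
    t = abs(estimate / se)
    return float(2.0 * stats.t.sf(t, dof))
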