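"""Least-squares estimation, nested comparison and derived statistics.

Every self-consistency test fits noiseless data generated by the same model
and demands recovery of the generating parameters; stochastic recovery and
the Monte-Carlo propagation oracle use fixed seeds.
"""

import math

import numpy as np
import pytest
from scipy import stats

from nitrokin import (
    InhibitionParams,
    KineticObservation,
    KineticParams,
    NoiseModel,
    RedoxConcertedParams,
    RedoxTwoStepParams,
    compare_nested,
    default_inhibition_design,
    default_kinetics_grid,
    derived_efficiency,
    efficiency_from_fit,
    fit_inhibition_global,
    fit_pingpong_global,
    fit_redox,
    fit_single_substrate,
    parameter_significance,
    simulate_inhibition,
    simulate_kinetics,
    simulate_titration,
)
from nitrokin.fitting import (
    DesignDeficientError,
    FitResult,
    NonNestedModelsError,
)
from nitrokin.synthetic_data import DesignGrid


def _fake_fit(model_id, rss, dof, n_free, n_points):
    names = tuple(f"p{i}" for i in range(n_free))
    return FitResult(
        model_id=model_id, param_names=names,
        estimates={n: 1.0 for n in names},
        standard_errors={n: 0.1 for n in names},
        p_values={n: 0.01 for n in names},
        rss=rss, dof=dof, covariance=np.eye(n_free), converged=True,
        n_points=n_points, free_names=names)


class TestPingPongGlobal:
    def test_noiseless_self_consistency(self, nitrofurantoin_params):
        obs = simulate_kinetics(nitrofurantoin_params,
                                default_kinetics_grid(nitrofurantoin_params))
        fit = fit_pingpong_global(obs, seed=0)
        assert fit.converged
        for name, truth in [("kcat", 81.0), ("Km_A", 20.6), ("Km_B", 10.9)]:
            assert fit.estimates[name] == pytest.approx(truth, rel=1e-6)
        assert fit.dof == len(obs) - 3
        assert all(se >= 0 for se in fit.standard_errors.values())

    def test_stochastic_recovery_small_median_bias(self, nitrofurazone_params):
        grid = default_kinetics_grid(nitrofurazone_params)
        bias = {"kcat": [], "Km_A": [], "Km_B": []}
        truth = {"kcat": 29.6, "Km_A": 13.0, "Km_B": 34.0}
        for seed in range(20):
            obs = simulate_kinetics(nitrofurazone_params, grid,
                                    NoiseModel(cv=0.03, seed=seed))
            fit = fit_pingpong_global(obs, seed=seed)
            for k in bias:
                bias[k].append(abs(fit.estimates[k] - truth[k]) / truth[k])
        for k, values in bias.items():
            assert np.median(values) < 0.05, k

    def test_relative_weighting_agrees_on_noiseless_data(self, nitrofurantoin_params):
        obs = simulate_kinetics(nitrofurantoin_params,
                                default_kinetics_grid(nitrofurantoin_params))
        unit = fit_pingpong_global(obs, seed=0)
        rel = fit_pingpong_global(obs, seed=0, weighting="relative")
        for name in ("kcat", "Km_A", "Km_B"):
            assert rel.estimates[name] == pytest.approx(
                unit.estimates[name], rel=1e-6)
        with pytest.raises(ValueError):
            fit_pingpong_global(obs, weighting="bogus")

    def test_single_cosubstrate_level_is_design_deficient(self):
        p = KineticParams(10.0, 5.0, 5.0)
        obs = [KineticObservation(a, 10.0, 0.0, 0.01, 0.05)
               for a in (1.0, 2.0, 5.0, 10.0)]
        with pytest.raises(DesignDeficientError):
            fit_pingpong_global(obs)

    def test_standard_errors_shrink_with_replication(self, nitrofurantoin_params):
        ses = []
        for k in (1, 4, 16):
            grid = default_kinetics_grid(nitrofurantoin_params, replicates=k)
            obs = simulate_kinetics(nitrofurantoin_params, grid,
                                    NoiseModel(cv=0.03, seed=7))
            fit = fit_pingpong_global(obs, seed=7)
            ses.append(fit.standard_errors["kcat"])
        # information scaling: SE ~ 1/sqrt(n)
        assert ses[1] == pytest.approx(ses[0] / 2, rel=0.2)
        assert ses[2] == pytest.approx(ses[0] / 4, rel=0.2)


class TestSingleSubstrate:
    def test_noiseless_self_consistency(self):
        S = np.array([1.0, 2.0, 5.0, 11.0, 25.0, 60.0])
        conc_E = 0.01
        v = 9.0 * S / (11.0 + S) * conc_E
        obs = [KineticObservation(s, 100.0, 0.0, conc_E, r)
               for s, r in zip(S, v)]
        fit = fit_single_substrate(obs, substrate="A")
        assert fit.estimates["kcat_app"] == pytest.approx(9.0, rel=1e-7)
        assert fit.estimates["Km_app"] == pytest.approx(11.0, rel=1e-7)

    def test_rate_at_km_is_half_maximal(self):
        S = np.array([0.5, 1.5, 3.0, 6.0, 12.0, 48.0])
        v = 24.0 * S / (3.0 + S) * 0.01
        obs = [KineticObservation(s, 50.0, 0.0, 0.01, r) for s, r in zip(S, v)]
        fit = fit_single_substrate(obs)
        kcat, km = fit.estimates["kcat_app"], fit.estimates["Km_app"]
        assert kcat * km / (km + km) == pytest.approx(kcat / 2)

    def test_noisy_recovery_within_three_standard_errors(self):
        rng = np.random.default_rng(3)
        S = np.array([0.75, 1.5, 3.0, 6.0, 12.0, 24.0])
        v = 24.0 * S / (3.0 + S) * 0.01 * (1 + 0.03 * rng.standard_normal(S.size))
        obs = [KineticObservation(s, 50.0, 0.0, 0.01, r) for s, r in zip(S, v)]
        fit = fit_single_substrate(obs, seed=3)
        assert abs(fit.estimates["kcat_app"] - 24.0) < \
            3 * fit.standard_errors["kcat_app"]

    def test_too_few_concentrations(self):
        obs = [KineticObservation(1.0, 10.0, 0.0, 0.01, 0.02),
               KineticObservation(5.0, 10.0, 0.0, 0.01, 0.05),
               KineticObservation(5.0, 10.0, 0.0, 0.01, 0.05)]
        with pytest.raises(DesignDeficientError):
            fit_single_substrate(obs)


class TestInhibitionGlobal:
    def test_noiseless_self_consistency_both_halves(self, fmn_inhibition_params):
        obs = simulate_inhibition(fmn_inhibition_params,
                                  default_inhibition_design(fmn_inhibition_params))
        fit = fit_inhibition_global(obs, mode="both_halves", seed=0)
        truth = {"kcat": 21.4, "Km_A": 62.0, "Km_B": 11.0,
                 "Ki_A": 8.0, "Ki_B": 7.0}
        for name, value in truth.items():
            assert fit.estimates[name] == pytest.approx(value, rel=1e-6), name

    def test_half_only_restriction_fits_worse(self, fmn_inhibition_params):
        obs = simulate_inhibition(fmn_inhibition_params,
                                  default_inhibition_design(fmn_inhibition_params),
                                  NoiseModel(cv=0.02, seed=11))
        full = fit_inhibition_global(obs, mode="both_halves", seed=1)
        half = fit_inhibition_global(obs, mode="half_A_only", seed=1)
        assert math.isinf(half.estimates["Ki_B"])
        assert half.rss > full.rss * (1 - 1e-9)
        cmp = compare_nested(full, half)
        assert cmp.f_statistic >= 0

    def test_no_inhibitor_free_series_is_design_deficient(self, fmn_inhibition_params):
        grid = DesignGrid(conc_A_levels=(10.0, 50.0, 200.0),
                          conc_B_levels=(3.0, 11.0, 44.0),
                          conc_I_levels=(5.0, 20.0))
        with pytest.raises(DesignDeficientError):
            simulate_inhibition(fmn_inhibition_params, grid)
        obs = [KineticObservation(a, 99.0, 10.0, 0.01, 0.05)
               for a in (5.0, 20.0, 80.0, 160.0)]
        with pytest.raises(DesignDeficientError):
            fit_inhibition_global(obs)

    def test_inhibitor_only_at_zero_is_design_deficient(self, fmn_inhibition_params):
        obs = simulate_inhibition(
            fmn_inhibition_params,
            default_inhibition_design(fmn_inhibition_params))
        zero_only = [o for o in obs if o.conc_I == 0.0]
        with pytest.raises(DesignDeficientError):
            fit_inhibition_global(zero_only)

    def test_stochastic_ki_recovery(self, fmn_inhibition_params):
        obs = simulate_inhibition(fmn_inhibition_params,
                                  default_inhibition_design(fmn_inhibition_params),
                                  NoiseModel(cv=0.03, seed=21))
        fit = fit_inhibition_global(obs, seed=21)
        assert abs(fit.estimates["Ki_A"] - 8.0) < 3 * fit.standard_errors["Ki_A"]


class TestRedoxFit:
    def test_concerted_self_consistency(self):
        pts = simulate_titration(RedoxConcertedParams(-264.0))
        result = fit_redox(pts, seed=0)
        assert result.concerted.estimates["Em"] == pytest.approx(-264.0, abs=1e-4)

    def test_two_step_self_consistency(self, two_step_truth):
        pts = simulate_titration(two_step_truth)
        result = fit_redox(pts, seed=0)
        assert result.two_step.estimates["E1"] == pytest.approx(-272.0, abs=1e-4)
        assert result.two_step.estimates["E2"] == pytest.approx(-268.0, abs=1e-4)
        assert result.two_step.estimates["b"] == pytest.approx(0.3, abs=1e-5)

    def test_cycle_specific_endpoints_do_not_bias_the_pooled_fit(self, two_step_truth):
        pts_one = simulate_titration(two_step_truth, endpoints=(0.8, 0.1),
                                     cycles="single", replicate="1")
        # second cycle with different optical endpoints, same underlying y(x)
        pts_two = simulate_titration(two_step_truth, endpoints=(0.55, 0.22),
                                     cycles="single", replicate="2")
        joint = fit_redox(pts_one + pts_two, seed=0)
        alone = fit_redox(pts_one, seed=0)
        for name in ("E1", "E2", "b"):
            assert joint.two_step.estimates[name] == pytest.approx(
                alone.two_step.estimates[name], abs=1e-4)

    def test_unanchored_titration_warns(self):
        # sweep covers only the middle of the wave: scaled fractions span
        # well under half of the oxidised-fraction range
        pts = simulate_titration(RedoxConcertedParams(-264.0),
                                 potentials=np.linspace(-272, -256, 9))
        result = fit_redox(pts, seed=0)
        assert any("poorly-anchored" in w for w in result.warnings)


class TestModelSelection:
    def test_two_step_truth_prefers_two_step(self):
        # strongly stabilised semiquinone: clear plateau between two waves
        truth = RedoxTwoStepParams(E1=-210.0, E2=-330.0, b=0.6)
        pts = simulate_titration(
            truth, potentials=np.arange(-450.0, -89.0, 20.0),
            noise=NoiseModel(kind="additive-Gaussian", sigma_abs=0.003, seed=2))
        result = fit_redox(pts, seed=2)
        assert result.comparison.preferred == "nernst_two_step"
        assert result.comparison.aicc_full < result.comparison.aicc_reduced

    def test_concerted_truth_prefers_concerted(self):
        pts = simulate_titration(
            RedoxConcertedParams(-264.0),
            noise=NoiseModel(kind="additive-Gaussian", sigma_abs=0.003, seed=3))
        result = fit_redox(pts, seed=3)
        assert result.comparison.preferred == "nernst_concerted"


class TestCompareNested:
    def test_hand_computed_f_statistic(self):
        full = _fake_fit("full", rss=1.0, dof=10, n_free=2, n_points=12)
        red = _fake_fit("reduced", rss=2.0, dof=11, n_free=1, n_points=12)
        cmp = compare_nested(full, red)
        assert cmp.f_statistic == pytest.approx(10.0)
        assert cmp.p_value == pytest.approx(float(stats.f.sf(10.0, 1, 10)))

    def test_no_improvement_prefers_reduced(self):
        full = _fake_fit("full", rss=1.0, dof=10, n_free=2, n_points=12)
        red = _fake_fit("reduced", rss=1.0, dof=11, n_free=1, n_points=12)
        cmp = compare_nested(full, red)
        assert cmp.f_statistic == pytest.approx(0.0, abs=1e-12)
        assert cmp.p_value == pytest.approx(1.0)
        assert cmp.preferred == "reduced"

    def test_non_nested_inputs_rejected(self):
        a = _fake_fit("a", rss=1.0, dof=10, n_free=2, n_points=12)
        b = _fake_fit("b", rss=1.0, dof=10, n_free=2, n_points=12)
        with pytest.raises(NonNestedModelsError):
            compare_nested(a, b)
        c = _fake_fit("c", rss=1.0, dof=11, n_free=1, n_points=13)
        with pytest.raises(NonNestedModelsError):
            compare_nested(a, c)


class TestDerivedEfficiency:
    @pytest.mark.parametrize("kcat,km,expected", [
        (42.0, 12.0, 3.5),    # CB1954 surface, NADPH efficiency
        (24.0, 3.0, 8.0),     # 1,4-benzoquinone apparent fit
        (81.0, 20.6, 81.0 / 20.6),
    ])
    def test_ratio(self, kcat, km, expected):
        eff, se, _ = derived_efficiency(kcat, km)
        assert eff == pytest.approx(expected, rel=1e-12)
        assert se == 0.0

    def test_zero_variance_gives_zero_error(self):
        assert derived_efficiency(1.0, 1.0) == (1.0, 0.0, False)

    def test_covariance_flag(self):
        _, _, used = derived_efficiency(10.0, 2.0, 1.0, 0.1, cov_kcat_km=0.05)
        assert used
        _, _, used = derived_efficiency(10.0, 2.0, 1.0, 0.1)
        assert not used

    def test_propagated_error_matches_monte_carlo(self):
        kcat, km = 29.6, 13.0
        cov = np.array([[0.9 ** 2, 0.6], [0.6, 2.0 ** 2]])
        _, se, _ = derived_efficiency(kcat, km, cov[0, 0], cov[1, 1],
                                      cov_kcat_km=cov[0, 1])
        rng = np.random.default_rng(12345)
        draws = rng.multivariate_normal([kcat, km], cov, size=10_000)
        mc = np.std(draws[:, 0] / draws[:, 1], ddof=1)
        assert se == pytest.approx(mc, rel=0.10)

    def test_from_fit_uses_fitted_covariance(self, nitrofurantoin_params):
        obs = simulate_kinetics(nitrofurantoin_params,
                                default_kinetics_grid(nitrofurantoin_params),
                                NoiseModel(cv=0.03, seed=9))
        fit = fit_pingpong_global(obs, seed=9)
        eff, se, used = efficiency_from_fit(fit, km_name="Km_A")
        assert used and se > 0
        assert eff == pytest.approx(81.0 / 20.6, rel=0.1)


class TestParameterSignificance:
    def test_strong_effect(self):
        assert parameter_significance(10.0, 1.0, 30) < 1e-4

    def test_null_estimate(self):
        assert parameter_significance(0.0, 1.0, 10) == pytest.approx(1.0)

    def test_t_distribution_tail(self):
        assert parameter_significance(2.0, 1.0, 10) == pytest.approx(0.0734, abs=5e-4)

    def test_degenerate_zero_se(self):
        assert parameter_significance(3.0, 0.0, 10) == 0.0
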