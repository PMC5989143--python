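"""Parameter specs, scenario loading, calibration and serialization."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import integrate, stats

from sepcea import (
    ParameterSpec,
    default_rrt_calibration,
    derive_overall_mortality,
    load_scenario,
    moment_match,
    read_parameter_table,
    write_parameter_table,
)
from sepcea.parameters import (
    ARMS,
    RRT_COST_TARGETS,
    InfeasibleMomentsError,
    ParameterError,
)
from sepcea.tree import DecisionTree, calibrate_rrt_probability, roll_back


# -- scenario loading ------------------------------------------------------


def test_baseline_transition_probabilities(baseline):
    assert baseline.spec("p_mort", "standard").point == 0.404
    assert baseline.spec("p_mort", "standard").dispersion == 0.071
    assert baseline.spec("p_mort", "bundle").point == 0.085
    assert baseline.spec("p_arf", "standard").point == 0.234
    assert baseline.spec("p_arf", "bundle").point == 0.097


def test_scenario1_replaces_standard_arm_only(scenario1, baseline):
    assert scenario1.spec("p_mort", "standard").point == 0.255
    assert scenario1.spec("p_arf", "standard").point == 0.170
    assert scenario1.arm_specs["bundle"] == baseline.arm_specs["bundle"]


def test_scenario2_arms_share_probabilities(scenario2):
    for name in ("p_mort", "p_arf", "p_rrt_given_arf_survivor"):
        assert scenario2.spec(name, "standard") == scenario2.spec(name, "bundle")
    assert scenario2.spec("p_mort", "standard").point == 0.255
    assert scenario2.spec("p_arf", "standard").point == 0.170


def test_zero_dispersion_calibration_makes_point_masses():
    pset = load_scenario("baseline", calibration={"dispersion_scale": 0.0})
    for _, spec in pset.iter_specs():
        assert spec.family == "point_mass"
        assert spec.dispersion == 0.0


def test_unknown_scenario_error_names_options():
    with pytest.raises(ParameterError, match="baseline"):
        load_scenario("scenario9")


def test_calibration_missing_arm_is_an_error():
    with pytest.raises(ParameterError, match="bundle"):
        load_scenario("baseline", calibration={"standard": 0.1})


def test_calibration_overrides_rrt_branch():
    pset = load_scenario("baseline", calibration={"standard": 0.2, "bundle": (0.1, 0.02)})
    assert pset.spec("p_rrt_given_arf_survivor", "standard").point == 0.2
    assert pset.spec("p_rrt_given_arf_survivor", "bundle").dispersion == 0.02


def test_loading_is_deterministic_and_self_contained():
    for scenario in ("baseline", "scenario1", "scenario2"):
        assert load_scenario(scenario) == load_scenario(scenario)


# -- overall-mortality calibration ----------------------------------------


def test_overall_mortality_reproduces_scenario1_rate():
    assert round(derive_overall_mortality(0.212, 0.170), 3) == 0.255


@pytest.mark.parametrize(
    "m,a,expected", [(0.212, 0.0, 0.212), (0.0, 0.5, 0.0), (0.9, 0.5, 1.0)]
)
def test_overall_mortality_edge_cases(m, a, expected):
    assert derive_overall_mortality(m, a) == pytest.approx(expected)


def test_overall_mortality_domain_errors():
    with pytest.raises(ParameterError):
        derive_overall_mortality(0.2, 1.0)
    with pytest.raises(ParameterError):
        derive_overall_mortality(-0.1, 0.2)


@given(
    m=st.floats(0.0, 0.99),
    a=st.floats(0.0, 0.95),
    dm=st.floats(0.0, 0.01),
    da=st.floats(0.0, 0.04),
)
def test_overall_mortality_monotone(m, a, dm, da):
    base = derive_overall_mortality(m, a)
    assert derive_overall_mortality(min(m + dm, 1.0), a) >= base
    assert derive_overall_mortality(m, a + da) >= base


# -- moment matching -------------------------------------------------------


def test_beta_moment_match_against_numerical_integration():
    spec = ParameterSpec("p", "probability", 0.085, 0.041, "se", "beta", (0.0, 1.0))
    params = moment_match(spec)
    assert params["alpha"] == pytest.approx(3.85, rel=0.01)
    assert params["beta"] == pytest.approx(41.4, rel=0.01)
    pdf = stats.beta(params["alpha"], params["beta"]).pdf
    mean, _ = integrate.quad(lambda x: x * pdf(x), 0, 1)
    second, _ = integrate.quad(lambda x: x * x * pdf(x), 0, 1)
    assert mean == pytest.approx(0.085, abs=1e-9)
    assert math.sqrt(second - mean**2) == pytest.approx(0.041, abs=1e-9)


def test_gamma_moment_match_analytic_and_empirical():
    spec = ParameterSpec("c", "cost_usd", 32421.0, 15051.0, "sd", "gamma")
    params = moment_match(spec)
    assert params["shape"] == pytest.approx(4.64, rel=0.01)
    assert params["scale"] == pytest.approx(6988.0, rel=0.01)
    n = 10**6
    draws = np.random.default_rng(7).gamma(params["shape"], params["scale"], n)
    se_mean = 15051.0 / math.sqrt(n)
    # SE of the sample SD from the gamma's excess kurtosis 6/shape
    kurt = 6.0 / params["shape"]
    se_sd = 15051.0 * math.sqrt((kurt + 2.0) / (4.0 * n))
    assert abs(draws.mean() - 32421.0) < 3 * se_mean
    assert abs(draws.std(ddof=1) - 15051.0) < 3 * se_sd


def test_all_model_distributions_match_moments_analytically():
    for scenario in ("baseline", "scenario1", "scenario2"):
        for _, spec in load_scenario(scenario).iter_specs():
            params = moment_match(spec)
            if params["family"] == "beta":
                dist = stats.beta(params["alpha"], params["beta"])
            elif params["family"] == "gamma":
                dist = stats.gamma(params["shape"], scale=params["scale"])
            else:
                continue
            assert float(dist.mean()) == pytest.approx(spec.point, abs=1e-9)
            assert float(dist.std()) == pytest.approx(spec.dispersion, abs=1e-9)


def test_zero_dispersion_is_point_mass():
    spec = ParameterSpec("u_death", "utility", 0.0, support=(0.0, 1.0))
    assert moment_match(spec) == {"family": "point_mass", "value": 0.0}


def test_infeasible_beta_moments_raise():
    spec = ParameterSpec("p", "probability", 0.5, 0.6, "sd", "beta", (0.0, 1.0))
    with pytest.raises(InfeasibleMomentsError):
        moment_match(spec)


def test_truncated_normal_reports_moment_shift():
    spec = ParameterSpec(
        "u", "utility", 0.9, 0.3, "sd", "normal_truncated", (0.0, 1.0)
    )
    params = moment_match(spec)
    # truncation pulls the realized mean below the pre-truncation location
    assert params["truncated_mean"] < 0.9
    assert params["truncated_sd"] < 0.3


# -- spec validation -------------------------------------------------------


def test_spec_invariants_rejected():
    with pytest.raises(ParameterError):
        ParameterSpec("p", "probability", 1.2, 0.1, "se", "beta", (0.0, 1.0))
    with pytest.raises(ParameterError):
        ParameterSpec("c", "cost_usd", -5.0, 1.0, "sd", "gamma")
    with pytest.raises(ParameterError):  # dispersion 0 with non-point-mass family
        ParameterSpec("p", "probability", 0.5, 0.0, "se", "beta", (0.0, 1.0))


# -- RRT calibration -------------------------------------------------------


def test_closed_form_calibration_agrees_with_rollback_root_find(tree):
    defaults = default_rrt_calibration()
    for (scenario, arm), target in RRT_COST_TARGETS.items():
        pset = load_scenario(scenario)
        assert calibrate_rrt_probability(pset, arm, target) == pytest.approx(
            defaults[(scenario, arm)], abs=1e-9
        )


def test_calibrated_defaults_reproduce_target_costs(tree):
    for (scenario, arm), target in RRT_COST_TARGETS.items():
        outcome = roll_back(tree, load_scenario(scenario))[arm]
        assert outcome.expected_cost == pytest.approx(target, abs=1e-6)


def test_unattainable_calibration_target_raises(tree, baseline):
    with pytest.raises(ValueError, match="not attainable"):
        calibrate_rrt_probability(baseline, "standard", 1e7)


# -- serialization ---------------------------------------------------------


def test_parameter_table_round_trip_is_exact(tmp_path, baseline):
    path = tmp_path / "params.csv"
    write_parameter_table(baseline, path)
    assert read_parameter_table(path) == baseline


def test_missing_parameter_is_reported(tmp_path, baseline):
    path = tmp_path / "params.csv"
    write_parameter_table(baseline, path)
    lines = [
        l for l in path.read_text().splitlines()
        if "p_rrt_given_arf_survivor" not in l
    ]
    path.write_text("\n".join(lines) + "\n")
    with pytest.raises(ParameterError, match="p_rrt_given_arf_survivor"):
        read_parameter_table(path)


def test_malformed_row_reports_row_number(tmp_path, baseline):
    path = tmp_path / "params.csv"
    write_parameter_table(baseline, path)
    lines = path.read_text().splitlines()
    lines[3] = lines[3].replace(lines[3].split(",")[4], "not-a-number", 1)
    path.write_text("\n".join(lines) + "\n")
    with pytest.raises(ParameterError, match="row 4"):
        read_parameter_table(path)


def test_unknown_family_is_named(tmp_path, baseline):
    path = tmp_path / "params.csv"
    write_parameter_table(baseline, path)
    path.write_text(path.read_text().replace("gamma", "lognormal"))
    with pytest.raises(ParameterError, match="lognormal"):
        read_parameter_table(path)
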