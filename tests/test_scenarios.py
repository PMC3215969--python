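"""Enhancement scenarios, flux-change summaries and the two-phase batch."""

import math

import pytest

from electrofba.errors import ValidationError
from electrofba.fba_engine import Envelope, resolve_fluxes, solve_fba
from electrofba.model_io import Condition
from electrofba.scenarios import (
    PathwayGroups,
    TwoPhaseParams,
    atp_max_scenario,
    biomass_scenario,
    flux_change_summary,
    two_phase_productivity,
)
from electrofba.synthetic_model import ToyConfig, make_toy_model

GLC10 = {"EX_sub_e": 10.0}


def test_atp_scenario_zero_bound_means_zero_delta(toy_default):
    result = atp_max_scenario(toy_default, Condition(substrate_uptakes=GLC10, electron_uptake_max=0.0))
    assert result.delta_abs == pytest.approx(0.0, abs=1e-9)
    assert result.base.objective_value == pytest.approx(70.0 / 3.0, abs=1e-8)


def test_atp_scenario_single_compartment_gains_nothing(toy_default):
    """Without a proton-coupled ATP synthase, surplus electrode NADH only
    forces carbon into the reduced product, so max ATP does not move."""
    result = atp_max_scenario(toy_default, Condition(substrate_uptakes=GLC10, electron_uptake_max=30.0))
    assert result.delta_abs == pytest.approx(0.0, abs=1e-8)


def test_atp_scenario_two_compartment_synthase_gain(toy_two_compartment):
    """Proton influx through ATP synthase converts 30 mmol e- into exactly
    (30/2)/4 = 3.75 mmol extra ATP."""
    result = atp_max_scenario(
        toy_two_compartment, Condition(substrate_uptakes=GLC10, electron_uptake_max=30.0)
    )
    assert result.base.objective_value == pytest.approx(30.0, abs=1e-8)
    assert result.delta_abs == pytest.approx(3.75, abs=1e-8)
    assert result.delta_pct == pytest.approx(12.5, abs=1e-6)


def test_atp_delta_proportional_to_current(toy_two_compartment):
    """The ATP gain is linear in the electron bound: delta = e/8."""
    for e in (0.0, 8.0, 16.0, 24.0):
        result = atp_max_scenario(
            toy_two_compartment, Condition(substrate_uptakes=GLC10, electron_uptake_max=e)
        )
        assert result.delta_abs == pytest.approx(e / 8.0, abs=1e-8)


def test_biomass_scenario_regimes():
    surplus = make_toy_model(ToyConfig())  # biomass NADH demand below supply
    r = biomass_scenario(surplus, Condition(substrate_uptakes=GLC10, electron_uptake_max=30.0))
    assert r.delta_abs == pytest.approx(0.0, abs=1e-8)

    limited = make_toy_model(ToyConfig(biomass_nadh=4.0))
    r = biomass_scenario(limited, Condition(substrate_uptakes=GLC10, electron_uptake_max=30.0))
    assert r.base.objective_value == pytest.approx(5.0, abs=1e-8)
    assert r.enhanced.objective_value == pytest.approx(8.75, abs=1e-8)
    assert r.delta_abs > 0


def test_enhanced_never_below_base(toy_default, toy_two_compartment):
    for model in (toy_default, toy_two_compartment):
        for e in (0.0, 15.0, 30.0):
            cond = Condition(substrate_uptakes=GLC10, electron_uptake_max=e)
            for runner in (atp_max_scenario, biomass_scenario):
                result = runner(model, cond)
                assert result.enhanced.objective_value >= result.base.objective_value - 1e-9


def test_flux_change_summary_identity_and_refusals(toy_default):
    groups = PathwayGroups({"product_branch": {"PRED": 1}, "atp_branch": {"POX": 1}})
    resolved = resolve_fluxes(toy_default, "EX_pred_e", "max")
    table = flux_change_summary(resolved, resolved, groups)
    assert (table["change_pct"].abs() < 1e-9).all()

    raw = solve_fba(toy_default, "EX_pred_e", "max")
    with pytest.raises(ValidationError, match="resolved"):
        flux_change_summary(raw, resolved, groups)

    with pytest.raises(ValidationError):
        PathwayGroups({"a": {"PRED": 1}, "b": {"PRED": 1}})  # non-disjoint


def test_flux_change_direction_weights(toy_default):
    cond0 = Condition(substrate_uptakes=GLC10, electron_uptake_max=0.0)
    cond30 = Condition(substrate_uptakes=GLC10, electron_uptake_max=30.0)
    from electrofba.model_io import apply_condition

    base = resolve_fluxes(apply_condition(toy_default, cond0), "EX_pred_e", "max")
    enhanced = resolve_fluxes(apply_condition(toy_default, cond30), "EX_pred_e", "max")
    groups = PathwayGroups({"reduced_branch": {"PRED": 1}, "oxidized_branch": {"POX": 1}})
    table = flux_change_summary(base, enhanced, groups).set_index("group")
    # 20/3 -> 10 is a +50% swing through the reduced branch
    assert table.loc["reduced_branch", "change_pct"] == pytest.approx(50.0, abs=1e-6)
    assert table.loc["oxidized_branch", "change_pct"] == pytest.approx(-100.0, abs=1e-6)


def _growth_env():
    # mu_max 5 /hr with a coupled product rate of 5 mmol/gDW-hr
    return Envelope([(0.0, 0.0, 20.0 / 3.0), (5.0, 5.0, 5.0)], 0.0, "EX_pred_e", "BIOMASS")


def _prod_env():
    return Envelope([(0.0, 0.0, 10.0), (5.0, 5.0, 5.0)], 30.0, "EX_pred_e", "BIOMASS")


def test_two_phase_matches_hand_integration():
    params = TwoPhaseParams(0.01, 100.0, 1.0, 10.0)
    result = two_phase_productivity(_growth_env(), _prod_env(), params)
    # phase 1: substrate 10*(1-0.01)/5 = 1.98, product 5*(0.99)/5 = 0.99
    # phase 2: 98.02 mmol at yield 10/10 -> 98.02
    assert result.growth_phase_product == pytest.approx(0.99, abs=1e-12)
    assert result.production_phase_product == pytest.approx(98.02, abs=1e-12)
    assert result.total_product_mmol_per_l == pytest.approx(99.01, abs=1e-12)
    assert result.batch_time_hr == pytest.approx(math.log(100.0) / 5.0 + 9.802, abs=1e-12)


def test_two_phase_degenerate_cases():
    # switch at the inoculum: pure production phase
    params = TwoPhaseParams(0.01, 100.0, 0.01, 10.0)
    result = two_phase_productivity(_growth_env(), _prod_env(), params)
    assert result.total_product_mmol_per_l == pytest.approx(100.0 * 10.0 / 10.0, abs=1e-9)
    # switch never reached: single-phase growth operation
    params = TwoPhaseParams(0.01, 100.0, 1000.0, 10.0)
    result = two_phase_productivity(_growth_env(), _prod_env(), params)
    x_end = 0.01 + 100.0 * 5.0 / 10.0
    assert result.final_biomass_gdw_per_l == pytest.approx(x_end, abs=1e-9)
    assert result.total_product_mmol_per_l == pytest.approx(5.0 * (x_end - 0.01) / 5.0, abs=1e-9)
    with pytest.raises(ValidationError):
        TwoPhaseParams(1.0, 100.0, 0.5, 10.0)


def test_two_phase_productivity_optimum_is_interior():
    """Volumetric productivity (product/time) peaks at an intermediate switch
    density, beating both single-phase extremes."""
    def productivity(switch):
        params = TwoPhaseParams(0.01, 100.0, switch, 10.0)
        r = two_phase_productivity(_growth_env(), _prod_env(), params)
        return r.total_product_mmol_per_l / r.batch_time_hr

    switches = [0.01, 1.0, 5.0, 10.0, 20.0, 30.0, 40.0, 50.0]
    values = [productivity(s) for s in switches]
    best = max(range(len(values)), key=values.__getitem__)
    assert 0 < best < len(values) - 1
    assert values[best] > values[0] and values[best] > values[-1]
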