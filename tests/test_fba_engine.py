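"""The LP engine against hand-derived optima and the brute-force oracle."""

import cobra
import numpy as np
import pytest

from conftest import brute_force_optimum

from electrofba.errors import SolverError, ValidationError
from electrofba.fba_engine import (
    max_theoretical_yield,
    production_envelope,
    resolve_fluxes,
    solve_fba,
)
from electrofba.model_io import Condition
from electrofba.synthetic_model import ToyConfig, make_toy_model, toy_reference_optima


def _with_electron_bound(model, bound):
    model.reactions.EX_e_el_e.lower_bound = -bound
    return model


def test_toy_reduced_product_optimum_matches_hand_lp(toy_default):
    """Redox balance caps P_red at n*U/k = 20/3 without the electrode and at
    the substrate-carbon limit 10 once electrons cover the NADH deficit."""
    assert solve_fba(
        _with_electron_bound(toy_default.copy(), 0.0), "EX_pred_e", "max"
    ).objective_value == pytest.approx(20.0 / 3.0, abs=1e-9)
    assert solve_fba(toy_default, "EX_pred_e", "max").objective_value == pytest.approx(10.0, abs=1e-9)


def test_steady_state_and_bounds_hold_at_optimum(toy_default):
    result = resolve_fluxes(toy_default, "EX_pred_e", "max")
    S = cobra.util.array.create_stoichiometric_matrix(toy_default)
    order = [r.id for r in toy_default.reactions]
    v = result.fluxes.reindex(order).to_numpy()
    assert np.max(np.abs(S @ v)) < 1e-6
    for rxn in toy_default.reactions:
        assert rxn.lower_bound - 1e-6 <= result.fluxes[rxn.id] <= rxn.upper_bound + 1e-6


@pytest.mark.parametrize(
    "config",
    [
        ToyConfig(),
        ToyConfig(nadh_per_reduced_product=4),
        ToyConfig(nadh_per_substrate=0, atp_per_substrate=3),
        ToyConfig(substrate_uptake_max=5.0, electron_uptake_max=10.0),
    ],
)
@pytest.mark.parametrize("objective", ["EX_pred_e", "ATPM", "BIOMASS"])
def test_vertex_enumeration_oracle_agrees(config, objective):
    """solve_fba equals exhaustive vertex enumeration on toy networks."""
    model = make_toy_model(config)
    expected = brute_force_optimum(model, objective, "max")
    got = solve_fba(model, objective, "max").objective_value
    assert expected is not None
    assert got == pytest.approx(expected, abs=1e-6)


def test_parsimonious_resolution_avoids_detours(toy_default):
    """A redundant two-step copy of the product branch carries zero flux in
    the parsimonious distribution, at an unchanged optimum."""
    model = toy_default.copy()
    x = cobra.Metabolite("x_c", compartment="c", formula="C6H10O6", charge=0)
    alt1 = cobra.Reaction("PRED_ALT1")
    alt1.add_metabolites({model.metabolites.b_c: -1, x: 1})
    alt2 = cobra.Reaction("PRED_ALT2")
    alt2.add_metabolites(
        {
            x: -1,
            model.metabolites.nadh_c: -3,
            model.metabolites.nad_c: 3,
            model.metabolites.pred_e: 1,
        }
    )
    for r in (alt1, alt2):
        r.bounds = (0.0, 1000.0)
    model.add_reactions([alt1, alt2])

    raw = solve_fba(model, "EX_pred_e", "max")
    resolved = resolve_fluxes(model, "EX_pred_e", "max")
    assert resolved.objective_value == pytest.approx(raw.objective_value, abs=1e-8)
    assert resolved.parsimonious
    assert abs(resolved.fluxes["PRED_ALT1"]) < 1e-6
    assert abs(resolved.fluxes["PRED_ALT2"]) < 1e-6


def test_resolve_matches_solve_objective_for_all_toy_objectives(toy_default):
    for objective in ("EX_pred_e", "EX_pox_e", "ATPM", "BIOMASS"):
        a = solve_fba(toy_default, objective, "max").objective_value
        b = resolve_fluxes(toy_default, objective, "max").objective_value
        assert b == pytest.approx(a, abs=1e-8)


def test_theoretical_yield_improves_by_half_with_electrode(toy_default):
    cond0 = Condition(substrate_uptakes={"EX_sub_e": 10.0}, electron_uptake_max=0.0)
    cond30 = Condition(substrate_uptakes={"EX_sub_e": 10.0}, electron_uptake_max=30.0)
    base = max_theoretical_yield(toy_default, "EX_pred_e", cond0)
    enhanced = max_theoretical_yield(toy_default, "EX_pred_e", cond30)
    assert base.yield_per_substrate == pytest.approx(2.0 / 3.0, abs=1e-9)
    assert enhanced.yield_per_substrate == pytest.approx(1.0, abs=1e-9)


def test_unknown_product_exchange_raises(toy_default):
    with pytest.raises(ValidationError):
        max_theoretical_yield(toy_default, "EX_missing_e")


def test_envelope_grid_shape_and_known_corner(toy_default):
    cond = Condition(substrate_uptakes={"EX_sub_e": 10.0}, electron_uptake_max=0.0)
    env = production_envelope(toy_default, "EX_pred_e", "BIOMASS", n_points=9, condition=cond)
    growths = [p[0] for p in env.points]
    assert len(env.points) == 9
    assert growths == sorted(growths)
    assert env.mu_max == pytest.approx(5.0, abs=1e-8)
    assert all(lo <= hi + 1e-9 for _, lo, hi in env.points)
    # at zero growth the product maximum is the redox-limited 20/3
    assert env.points[0][2] == pytest.approx(20.0 / 3.0, abs=1e-6)


def test_envelope_containment_under_relaxed_electron_bound(toy_default):
    conds = [
        Condition(substrate_uptakes={"EX_sub_e": 10.0}, electron_uptake_max=e) for e in (0.0, 10.0, 30.0)
    ]
    envs = [production_envelope(toy_default, "EX_pred_e", "BIOMASS", 7, c) for c in conds]
    assert envs[1].contains(envs[0])
    assert envs[2].contains(envs[1])


def test_optimum_monotone_in_electron_bound(toy_default):
    values = []
    for bound in (0.0, 5.0, 10.0, 20.0, 30.0):
        model = _with_electron_bound(toy_default.copy(), bound)
        values.append(solve_fba(model, "EX_pred_e", "max").objective_value)
    assert all(b >= a - 1e-9 for a, b in zip(values, values[1:]))


def test_envelope_requires_feasible_base(toy_default):
    model = toy_default.copy()
    model.reactions.ATPM.lower_bound = 50.0  # beyond the maximal ATP supply
    with pytest.raises(SolverError):
        production_envelope(model, "EX_pred_e", "BIOMASS", 5)


def test_closed_form_family_agrees_small_sample():
    for cfg in (ToyConfig(), ToyConfig(nadh_per_reduced_product=4, biomass_nadh=4.0)):
        model = make_toy_model(cfg)
        ref = toy_reference_optima(cfg)
        assert solve_fba(model, "EX_pred_e", "max").objective_value == pytest.approx(
            ref.max_reduced_product, abs=1e-9
        )
        assert solve_fba(model, "BIOMASS", "max").objective_value == pytest.approx(
            ref.max_biomass, abs=1e-9
        )
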