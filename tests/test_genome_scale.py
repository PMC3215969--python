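"""Full-pipeline checks on the bundled genome-scale E. coli model (iJO1366).

These verify the electrosynthesis mechanisms at genome scale: SPEEQ-ordered
yield enhancement, ppc (PPC) stimulation with ATP-synthase sign change under
reductive product maximization, Wood-Ljungdahl CO2 co-utilization, electrons-
plus-CO2-only growth, and growth-coupled designs with enlarged envelopes.
"""

import pytest

from conftest import IJO_BIOMASS

from electrofba.fba_engine import max_theoretical_yield, production_envelope, solve_fba
from electrofba.model_io import Condition, apply_condition
from electrofba.pathways import add_pathway, example_strain_designs, coupling_report, pathway_library
from electrofba.scenarios import co2_scenarios, ecoli_pathway_groups, flux_change_summary
from electrofba.speeq import speeq

GLC = "EX_glc__D_e"


def _cond(electron_bound, uptakes=None):
    return Condition(
        substrate_uptakes={GLC: 10.0} if uptakes is None else uptakes,
        aerobic=False,
        electron_uptake_max=electron_bound,
    )


@pytest.fixture(scope="module")
def yields(ijo):
    """Anaerobic theoretical maxima, base vs enhanced, for three products."""
    out = {}
    for product in ("EX_succ_e", "EX_etoh_e", "EX_ac_e"):
        pair = []
        for bound in (0.0, 30.0):
            res = max_theoretical_yield(ijo, product, _cond(bound))
            assert res.optimal
            pair.append(res)
        out[product] = pair
    return out


def test_condition_defines_single_substrate_anaerobic_medium(ijo):
    prepared = apply_condition(ijo, _cond(30.0))
    assert prepared.reactions.get_by_id(GLC).lower_bound == -10.0
    assert prepared.reactions.EX_o2_e.lower_bound == 0.0
    for other_sugar in ("EX_xyl__D_e", "EX_fru_e", "EX_glyc_e", "EX_ac_e"):
        assert prepared.reactions.get_by_id(other_sugar).lower_bound == 0.0
    assert prepared.reactions.EX_co2_e.lower_bound < 0  # inorganic carbon stays open
    assert prepared.reactions.EX_e_el_e.lower_bound == -30.0


def test_yield_enhancement_follows_speeq_order(yields):
    """Reduced products gain from the cathode, the oxidized one does not:
    succinate and ethanol (SPEEQ < 1 on glucose) improve, acetate is flat."""
    succ = [r.yield_per_substrate for r in yields["EX_succ_e"]]
    etoh = [r.yield_per_substrate for r in yields["EX_etoh_e"]]
    ac = [r.yield_per_substrate for r in yields["EX_ac_e"]]
    assert speeq("glucose", "succinate") < 1 and speeq("glucose", "ethanol") < 1
    assert succ[1] > succ[0] * 1.05
    assert etoh[1] > etoh[0] * 1.05
    assert ac[1] == pytest.approx(ac[0], rel=1e-6)
    # ethanol: the classic 2 mol/mol fermentation ceiling is broken
    assert etoh[0] == pytest.approx(2.0, abs=1e-6)
    assert etoh[1] == pytest.approx(2.25, abs=1e-3)


def test_ppc_stimulated_and_atp_synthase_reverses_for_succinate(yields):
    """Extra cathodic NADH pushes flux through the CO2-fixing PPC and flips
    ATP synthase from proton pumping to synthesis during succinate
    overproduction."""
    base, enhanced = yields["EX_succ_e"]
    assert enhanced.fluxes["PPC"] > base.fluxes["PPC"] * 1.1
    assert base.fluxes["ATPS4rpp"] < 0 < enhanced.fluxes["ATPS4rpp"]


def test_group_flux_summary_on_succinate_maximization(yields):
    base, enhanced = yields["EX_succ_e"]
    table = flux_change_summary(base, enhanced, ecoli_pathway_groups()).set_index("group")
    assert table.loc["reductive_tca", "change_pct"] > 0
    assert table.loc["atp_synthase", "flux_enhanced_mmol_per_gDW_hr"] > 0


def test_wood_ljungdahl_co2_scenarios(ijo):
    table = co2_scenarios(ijo).set_index("scenario")
    mu = table["growth_rate_per_hr"]
    assert mu["glucose_wl"] > mu["wild_type"] * 1.2  # CO2 refixation pays
    assert mu["glucose_wl_enhanced"] > mu["glucose_wl"]  # electrons pay on top
    assert mu["glucose_enhanced"] >= mu["wild_type"] - 1e-9
    # electrons + CO2 alone sustain (slow) growth, an order of magnitude down
    assert 1e-4 < mu["co2_only_enhanced"] < 0.1 * mu["wild_type"]
    # enhanced co-utilization fixes net CO2 (more than 60 C-mmol in)
    assert table.loc["glucose_wl_enhanced", "carbon_uptake_mmolC_per_gDW_hr"] > 60.0 + 1.0


def test_co2_only_growth_needs_the_fixation_pathway(ijo):
    prepared = apply_condition(ijo, _cond(30.0, uptakes={}))
    prepared.reactions.EX_co2_e.lower_bound = -1000.0
    result = solve_fba(prepared, IJO_BIOMASS, "max")
    assert (not result.optimal) or result.objective_value == pytest.approx(0.0, abs=1e-6)


def test_wood_ljungdahl_balances_in_genome_scale_namespace(ijo):
    """Adding the pathway must pass the C/H/O balance check against the
    model's own formulas, and enable positive 1,4-BDO flux from glucose."""
    lib = {s.name: s for s in pathway_library()}
    with_wl = add_pathway(ijo, lib["wood_ljungdahl"])
    assert len(with_wl.reactions) == len(ijo.reactions) + len(lib["wood_ljungdahl"].reactions)
    with_bdo = add_pathway(ijo, lib["14bdo"])
    res = max_theoretical_yield(with_bdo, "EX_14btd_e", _cond(0.0))
    assert res.optimal and res.objective_value > 0.1


def test_ethanol_design_couples_and_envelope_grows(ijo):
    design = next(d for d in example_strain_designs() if d.name == "ethanol_3ko")
    report = coupling_report(ijo, design, _cond(0.0))
    assert report.coupled and report.mu_max > 0.05

    envs = {}
    for bound in (0.0, 30.0):
        cond = Condition(substrate_uptakes={GLC: 10.0}, knockouts=design.knockouts, electron_uptake_max=bound)
        envs[bound] = production_envelope(ijo, "EX_etoh_e", IJO_BIOMASS, 5, cond)
    assert envs[30.0].mu_max >= envs[0.0].mu_max - 1e-9
    # pointwise containment on the shared relative grid is guaranteed only
    # for identical grids; compare the growth-0 and mu_max corners instead
    assert envs[30.0].points[0][2] >= envs[0.0].points[0][2] - 1e-6
    assert envs[30.0].points[-1][2] >= envs[0.0].points[-1][2] - 1e-6
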