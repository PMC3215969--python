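"""Named simulation scenarios: ATP and biomass enhancement, CO2 co-utilization
and CO2-only growth, pathway-level flux-change summaries, and the two-phase
(growth, then production) operating-strategy calculator.

Every scenario solves the same model twice - once with the electron exchange
closed and once at the condition's electron bound - and reports the change.
Because electrical enhancement only relaxes a bound, the enhanced optimum is
never below the base optimum, and equals it when the bound is zero.
"""

from __future__ import annotations

import dataclasses
import math
from collections.abc import Mapping

import cobra
import pandas as pd

from .electrosynthesis import DEFAULT_ELECTRON_EXCHANGE_ID
from .errors import ConfigurationError, SolverError, ValidationError
from .fba_engine import Envelope, FBAResult, resolve_fluxes
from .model_io import Condition, apply_condition

__all__ = [
    "ScenarioResult",
    "PathwayGroups",
    "atp_max_scenario",
    "biomass_scenario",
    "co2_scenarios",
    "flux_change_summary",
    "two_phase_productivity",
    "TwoPhaseParams",
    "TwoPhaseResult",
    "ecoli_pathway_groups",
]


@dataclasses.dataclass(frozen=True)
class ScenarioResult:
    """Base vs electrically enhanced optimum for one scenario."""

    scenario: str
    condition: Condition
    base: FBAResult
    enhanced: FBAResult

    @property
    def delta_abs(self) -> float:
        return self.enhanced.objective_value - self.base.objective_value

    @property
    def delta_pct(self) -> float:
        if not self.base.optimal or self.base.objective_value == 0:
            return float("nan")
        return 100.0 * self.delta_abs / self.base.objective_value


def _electron_exchange(model: cobra.Model) -> cobra.Reaction:
    if DEFAULT_ELECTRON_EXCHANGE_ID not in model.reactions:
        raise ConfigurationError(
            "scenario needs an electrode-augmented model (electrosynthesis.add_electrode_reactions)"
        )
    return model.reactions.get_by_id(DEFAULT_ELECTRON_EXCHANGE_ID)


def _paired_solve(model: cobra.Model, objective_id: str, electron_bound: float) -> tuple[FBAResult, FBAResult]:
    exchange = _electron_exchange(model)
    with model:
        exchange.lower_bound = 0.0
        base = resolve_fluxes(model, objective_id, "max")
    with model:
        exchange.lower_bound = -electron_bound
        enhanced = resolve_fluxes(model, objective_id, "max")
    return base, enhanced


def _single_objective_id(model: cobra.Model) -> str:
    ids = [r.id for r in model.reactions if r.objective_coefficient]
    if len(ids) != 1:
        raise ConfigurationError("model must carry a single-reaction objective")
    return ids[0]


def atp_max_scenario(
    model: cobra.Model,
    condition: Condition,
    atp_drain_id: str = "ATPM",
    biomass_id: str | None = None,
    zero_maintenance: bool = False,
) -> ScenarioResult:
    """Maximal ATP-hydrolysis flux at zero growth, base vs enhanced.

    The maintenance-type ATP drain is the objective; its maintenance lower
    bound is retained unless ``zero_maintenance`` is set.
    """
    prepared = apply_condition(model, condition)
    if atp_drain_id not in prepared.reactions:
        raise ConfigurationError(f"model has no ATP maintenance drain {atp_drain_id!r}")
    biomass_id = biomass_id or _single_objective_id(prepared)
    prepared.reactions.get_by_id(biomass_id).bounds = (0.0, 0.0)
    if zero_maintenance:
        prepared.reactions.get_by_id(atp_drain_id).lower_bound = 0.0
    base, enhanced = _paired_solve(prepared, atp_drain_id, condition.electron_uptake_max)
    return ScenarioResult("atp_max", condition, base, enhanced)


def biomass_scenario(model: cobra.Model, condition: Condition, biomass_id: str | None = None) -> ScenarioResult:
    """Maximal growth rate, base vs enhanced."""
    prepared = apply_condition(model, condition)
    biomass_id = biomass_id or _single_objective_id(prepared)
    base, enhanced = _paired_solve(prepared, biomass_id, condition.electron_uptake_max)
    if not base.optimal:
        raise SolverError(f"base biomass problem is {base.status}")
    return ScenarioResult("biomass", condition, base, enhanced)


def _carbon_uptake(model: cobra.Model, result: FBAResult) -> float:
    """Total incoming carbon, mmol C/gDW-hr, from a resolved flux vector."""
    total = 0.0
    for exchange in model.exchanges:
        flux = result.fluxes.get(exchange.id, 0.0)
        if flux < 0:
            met = next(iter(exchange.metabolites))
            total += -flux * met.elements.get("C", 0)
    return total


def co2_scenarios(
    model: cobra.Model,
    glucose_exchange: str = "EX_glc__D_e",
    co2_exchange: str = "EX_co2_e",
    glucose_uptake: float = 10.0,
    electron_bound: float = 30.0,
    biomass_id: str | None = None,
) -> pd.DataFrame:
    """Growth under the five CO2-fixation columns: wild type, +enhancement,
    +Wood-Ljungdahl, +Wood-Ljungdahl+enhancement, and CO2-only+enhancement.

    Returns growth rate (1/hr) and growth yield per total incoming carbon
    (gDW/mol C) per column; all runs are anaerobic and maximize biomass.
    """
    glc = {glucose_exchange: glucose_uptake}
    columns = [
        ("wild_type", glc, (), 0.0, False),
        ("glucose_enhanced", glc, (), electron_bound, False),
        ("glucose_wl", glc, ("wood_ljungdahl",), 0.0, False),
        ("glucose_wl_enhanced", glc, ("wood_ljungdahl",), electron_bound, False),
        ("co2_only_enhanced", {}, ("wood_ljungdahl",), electron_bound, True),
    ]
    rows = []
    for name, substrates, pathways, ebound, co2_only in columns:
        condition = Condition(
            substrate_uptakes=substrates,
            aerobic=False,
            electron_uptake_max=ebound,
            pathway_additions=pathways,
        )
        prepared = apply_condition(model, condition)
        if co2_only:
            prepared.reactions.get_by_id(co2_exchange).lower_bound = -1000.0
        objective = biomass_id or _single_objective_id(prepared)
        result = resolve_fluxes(prepared, objective, "max")
        if result.optimal:
            carbon = _carbon_uptake(prepared, result)
            growth_yield = result.objective_value / (carbon * 1e-3) if carbon > 0 else float("nan")
            rows.append((name, result.objective_value, growth_yield, carbon))
        else:
            rows.append((name, 0.0, float("nan"), float("nan")))
    return pd.DataFrame(
        rows,
        columns=["scenario", "growth_rate_per_hr", "growth_yield_gDW_per_molC", "carbon_uptake_mmolC_per_gDW_hr"],
    )


@dataclasses.dataclass(frozen=True)
class PathwayGroups:
    """Named, disjoint groups of reaction ids with per-reaction direction
    weights (+1/-1) defining the group's positive flux direction."""

    groups: Mapping[str, Mapping[str, float]]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for name, members in self.groups.items():
            overlap = seen & set(members)
            if overlap:
                raise ValidationError(f"group {name!r} reuses reaction(s) {sorted(overlap)}")
            seen |= set(members)


def ecoli_pathway_groups() -> PathwayGroups:
    """Default central-metabolism groups for BiGG *E. coli* reconstructions.

    Weights orient each group along its conventional direction (glycolytic
    flow, oxidative TCA toward 2-oxoglutarate, reductive TCA toward
    succinate, ATP synthase toward synthesis)."""
    return PathwayGroups(
        {
            "upper_glycolysis": {"PGI": 1, "PFK": 1, "FBA": 1, "TPI": 1},
            "lower_glycolysis": {"GAPD": 1, "PGK": -1, "PGM": -1, "ENO": 1, "PYK": 1},
            "oxidative_tca": {"CS": 1, "ACONTa": 1, "ACONTb": 1, "ICDHyr": 1},
            "reductive_tca": {"MDH": -1, "FUM": -1, "FRD2": 1, "FRD3": 1},
            "oxidative_ppp": {"G6PDH2r": 1, "PGL": 1, "GND": 1},
            "nonoxidative_ppp": {"TKT1": 1, "TKT2": 1, "TALA": 1},
            "atp_synthase": {"ATPS4rpp": 1},
        }
    )


def flux_change_summary(base: FBAResult, enhanced: FBAResult, groups: PathwayGroups) -> pd.DataFrame:
    """Percent change of direction-weighted group fluxes, enhanced vs base.

    Both inputs must be parsimonious (degeneracy-resolved) distributions;
    raw alternate-optimum vectors are refused because single-reaction fluxes
    are not unique at an LP optimum.
    """
    for label, result in (("base", base), ("enhanced", enhanced)):
        if not result.optimal:
            raise ValidationError(f"{label} result is {result.status}")
        if not result.parsimonious:
            raise ValidationError(f"{label} fluxes are not degeneracy-resolved; use resolve_fluxes")
    rows = []
    for name, members in groups.groups.items():
        missing = [rid for rid in members if rid not in base.fluxes.index or rid not in enhanced.fluxes.index]
        if missing:
            raise ValidationError(f"group {name!r} references unknown reaction(s) {missing}")
        flux_base = float(sum(w * base.fluxes[rid] for rid, w in members.items()))
        flux_enh = float(sum(w * enhanced.fluxes[rid] for rid, w in members.items()))
        if abs(flux_base) > 1e-9:
            pct = 100.0 * (flux_enh - flux_base) / abs(flux_base)
        else:
            pct = 0.0 if abs(flux_enh) <= 1e-9 else float("inf")
        rows.append((name, flux_base, flux_enh, pct))
    return pd.DataFrame(
        rows, columns=["group", "flux_base_mmol_per_gDW_hr", "flux_enhanced_mmol_per_gDW_hr", "change_pct"]
    )


@dataclasses.dataclass(frozen=True)
class TwoPhaseParams:
    """Batch parameters for the two-phase operating strategy."""

    inoculum_gdw_per_l: float = 0.01
    substrate_pool_mmol_per_l: float = 100.0
    switch_biomass_gdw_per_l: float = 1.0
    substrate_uptake_mmol_per_gdw_hr: float = 10.0

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            if getattr(self, f.name) <= 0:
                raise ValidationError(f"{f.name} must be > 0")
        if self.switch_biomass_gdw_per_l < self.inoculum_gdw_per_l:
            raise ValidationError("switch biomass must be at least the inoculum")


@dataclasses.dataclass(frozen=True)
class TwoPhaseResult:
    total_product_mmol_per_l: float
    batch_time_hr: float
    growth_phase_product: float
    production_phase_product: float
    final_biomass_gdw_per_l: float


def two_phase_productivity(
    envelope_growth: Envelope, envelope_prod: Envelope, params: TwoPhaseParams
) -> TwoPhaseResult:
    """Closed-form batch total for grow-then-produce operation.

    Phase 1 grows exponentially at the growth envelope's maximum rate with
    its growth-coupled (minimum) product flux until the switch density or
    substrate exhaustion; phase 2 holds biomass fixed at the production
    envelope's maximum-product operating point until the substrate pool is
    gone.  An operating-point calculator: no product inhibition, no
    maintenance decay, substrate uptake at the stated rate in both phases.
    """
    mu = envelope_growth.mu_max
    if mu <= 0:
        raise ValidationError("growth envelope has non-positive maximal growth rate")
    q_p1 = envelope_growth.points[-1][1]  # coupled product rate at mu_max
    q_p2 = max(hi for _, _, hi in envelope_prod.points)
    U = params.substrate_uptake_mmol_per_gdw_hr
    x0, xs, pool = (
        params.inoculum_gdw_per_l,
        params.switch_biomass_gdw_per_l,
        params.substrate_pool_mmol_per_l,
    )

    # integral of U*X(t)dt from X0 to X is U*(X - X0)/mu under X' = mu*X
    substrate_to_switch = U * (xs - x0) / mu
    if substrate_to_switch >= pool:  # switch never reached
        x_end = x0 + pool * mu / U
        product = q_p1 * (x_end - x0) / mu
        time = math.log(x_end / x0) / mu
        return TwoPhaseResult(product, time, product, 0.0, x_end)

    product1 = q_p1 * (xs - x0) / mu
    t1 = math.log(xs / x0) / mu if xs > x0 else 0.0
    remaining = pool - substrate_to_switch
    t2 = remaining / (U * xs)
    product2 = q_p2 * remaining / U
    return TwoPhaseResult(product1 + product2, t1 + t2, product1, product2, xs)
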