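"""Heterologous production pathways, Wood-Ljungdahl CO2 fixation and
growth-coupled strain-design handling.

The built-in pathway stoichiometries follow the metabolic engineering
literature: 1,3-propanediol via B12-dependent glycerol dehydratase plus an
NADH-linked oxidoreductase; 1,4-butanediol via the succinyl-CoA ->
succinate semialdehyde -> 4-hydroxybutyrate -> 4HB-CoA -> 4-hydroxybutanal
route; n-butanol via the clostridial acetyl-CoA condensation route with an
NADH-specific trans-enoyl-CoA reductase; and Wood-Ljungdahl with NADH for
every reduction step and one ATP invested at formyl-THF ligase.  Metabolite
ids and formulas use BiGG conventions so the pathways drop into the standard
*E. coli* reconstructions; metabolites absent from a target model are created
on addition.

Knockout sets are *inputs*, not computed: strain-design algorithms are out of
scope.  The shipped designs are illustrative Feist-style defaults for
anaerobic ethanol and succinate coupling in genome-scale *E. coli* models.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Mapping

import cobra
from cobra import Metabolite, Reaction

from .errors import ValidationError
from .fba_engine import solve_fba
from .model_io import Condition, apply_condition

__all__ = [
    "MetDef",
    "ReactionDef",
    "PathwaySpec",
    "StrainDesign",
    "pathway_library",
    "add_pathway",
    "example_strain_designs",
    "coupling_report",
    "CouplingReport",
    "COUPLING_TOLERANCE",
]

#: minimum product flux at maximal growth counted as growth coupling
COUPLING_TOLERANCE = 1e-6


@dataclasses.dataclass(frozen=True)
class MetDef:
    id: str
    name: str
    formula: str
    charge: int
    compartment: str


@dataclasses.dataclass(frozen=True)
class ReactionDef:
    id: str
    name: str
    stoichiometry: Mapping[str, float]
    lower_bound: float = 0.0
    upper_bound: float = 1000.0


@dataclasses.dataclass(frozen=True)
class PathwaySpec:
    name: str
    reactions: tuple[ReactionDef, ...]
    metabolites: tuple[MetDef, ...] = ()
    product_exchange_id: str | None = None

    def net_stoichiometry(self, interior_only: bool = True) -> dict[str, float]:
        """Sum of reaction stoichiometries at unit flux through each step
        (transport and exchange steps excluded by default); used to verify
        net cofactor demand, e.g. 4 NADH per n-butanol from 2 acetyl-CoA."""
        net: dict[str, float] = {}
        for rdef in self.reactions:
            if interior_only and (len(rdef.stoichiometry) == 1 or _is_transport(rdef)):
                continue
            for mid, coef in rdef.stoichiometry.items():
                net[mid] = net.get(mid, 0.0) + coef
        return {mid: c for mid, c in net.items() if abs(c) > 1e-9}


def _is_transport(rdef: ReactionDef) -> bool:
    stems = {mid.rsplit("_", 1)[0] for mid in rdef.stoichiometry}
    return len(stems) < len(rdef.stoichiometry)


@dataclasses.dataclass(frozen=True)
class StrainDesign:
    """A named knockout set targeting one product exchange."""

    name: str
    knockouts: frozenset[str]
    target_product: str
    source: str = ""

    def __post_init__(self) -> None:
        if not self.knockouts:
            raise ValidationError("a strain design needs a non-empty knockout set")
        object.__setattr__(self, "knockouts", frozenset(self.knockouts))


def _pdo13() -> PathwaySpec:
    return PathwaySpec(
        name="13pdo",
        metabolites=(
            MetDef("3hppnl_c", "3-hydroxypropanal", "C3H6O2", 0, "c"),
            MetDef("13ppd_c", "1,3-propanediol", "C3H8O2", 0, "c"),
            MetDef("13ppd_e", "1,3-propanediol", "C3H8O2", 0, "e"),
        ),
        reactions=(
            ReactionDef("GLYCDHT", "glycerol dehydratase", {"glyc_c": -1, "3hppnl_c": 1, "h2o_c": 1}),
            ReactionDef(
                "PDOOR",
                "1,3-propanediol oxidoreductase (NADH)",
                {"3hppnl_c": -1, "nadh_c": -1, "h_c": -1, "13ppd_c": 1, "nad_c": 1},
            ),
            ReactionDef("PDOt", "1,3-propanediol transport", {"13ppd_c": -1, "13ppd_e": 1}),
            ReactionDef("EX_13ppd_e", "1,3-propanediol exchange", {"13ppd_e": -1}),
        ),
        product_exchange_id="EX_13ppd_e",
    )


def _bdo14() -> PathwaySpec:
    return PathwaySpec(
        name="14bdo",
        metabolites=(
            MetDef("sucsal_c", "succinate semialdehyde", "C4H5O3", -1, "c"),
            MetDef("ghb_c", "4-hydroxybutyrate", "C4H7O3", -1, "c"),
            MetDef("4hbcoa_c", "4-hydroxybutyryl-CoA", "C25H38N7O18P3S", -4, "c"),
            MetDef("4hbal_c", "4-hydroxybutanal", "C4H8O2", 0, "c"),
            MetDef("14btd_c", "1,4-butanediol", "C4H10O2", 0, "c"),
            MetDef("14btd_e", "1,4-butanediol", "C4H10O2", 0, "e"),
        ),
        reactions=(
            ReactionDef(
                "SSCOARx",
                "succinyl-CoA reductase (NADH)",
                {"succoa_c": -1, "nadh_c": -1, "h_c": -1, "sucsal_c": 1, "coa_c": 1, "nad_c": 1},
            ),
            ReactionDef(
                "BDO4HBD",
                "4-hydroxybutyrate dehydrogenase",
                {"sucsal_c": -1, "nadh_c": -1, "h_c": -1, "ghb_c": 1, "nad_c": 1},
            ),
            ReactionDef(
                "BDOCAT2",
                "4-hydroxybutyryl-CoA transferase",
                {"ghb_c": -1, "accoa_c": -1, "4hbcoa_c": 1, "ac_c": 1},
            ),
            ReactionDef(
                "BDOALDD",
                "4-hydroxybutyryl-CoA reductase (NADH)",
                {"4hbcoa_c": -1, "nadh_c": -1, "h_c": -1, "4hbal_c": 1, "coa_c": 1, "nad_c": 1},
            ),
            ReactionDef(
                "BDOADH",
                "1,4-butanediol dehydrogenase",
                {"4hbal_c": -1, "nadh_c": -1, "h_c": -1, "14btd_c": 1, "nad_c": 1},
            ),
            ReactionDef("BDOt", "1,4-butanediol transport", {"14btd_c": -1, "14btd_e": 1}),
            ReactionDef("EX_14btd_e", "1,4-butanediol exchange", {"14btd_e": -1}),
        ),
        product_exchange_id="EX_14btd_e",
    )


def _nbutanol() -> PathwaySpec:
    return PathwaySpec(
        name="nbutanol",
        metabolites=(
            MetDef("aacoa_c", "acetoacetyl-CoA", "C25H36N7O18P3S", -4, "c"),
            MetDef("3hbcoa_c", "(S)-3-hydroxybutyryl-CoA", "C25H38N7O18P3S", -4, "c"),
            MetDef("b2coa_c", "crotonyl-CoA", "C25H36N7O17P3S", -4, "c"),
            MetDef("btcoa_c", "butyryl-CoA", "C25H38N7O17P3S", -4, "c"),
            MetDef("btal_c", "butanal", "C4H8O", 0, "c"),
            MetDef("btoh_c", "1-butanol", "C4H10O", 0, "c"),
            MetDef("btoh_e", "1-butanol", "C4H10O", 0, "e"),
        ),
        reactions=(
            ReactionDef("BUTTHL", "acetyl-CoA thiolase", {"accoa_c": -2, "aacoa_c": 1, "coa_c": 1}),
            ReactionDef(
                "BUTHBD",
                "3-hydroxybutyryl-CoA dehydrogenase (NADH)",
                {"aacoa_c": -1, "nadh_c": -1, "h_c": -1, "3hbcoa_c": 1, "nad_c": 1},
            ),
            ReactionDef("BUTCRT", "crotonase", {"3hbcoa_c": -1, "b2coa_c": 1, "h2o_c": 1}),
            ReactionDef(
                "BUTTER",
                "trans-enoyl-CoA reductase (NADH)",
                {"b2coa_c": -1, "nadh_c": -1, "h_c": -1, "btcoa_c": 1, "nad_c": 1},
            ),
            ReactionDef(
                "BUTALD",
                "butyraldehyde dehydrogenase (NADH)",
                {"btcoa_c": -1, "nadh_c": -1, "h_c": -1, "btal_c": 1, "coa_c": 1, "nad_c": 1},
            ),
            ReactionDef(
                "BUTADH",
                "butanol dehydrogenase (NADH)",
                {"btal_c": -1, "nadh_c": -1, "h_c": -1, "btoh_c": 1, "nad_c": 1},
            ),
            ReactionDef("BUTt", "1-butanol transport", {"btoh_c": -1, "btoh_e": 1}),
            ReactionDef("EX_btoh_e", "1-butanol exchange", {"btoh_e": -1}),
        ),
        product_exchange_id="EX_btoh_e",
    )


def _wood_ljungdahl() -> PathwaySpec:
    return PathwaySpec(
        name="wood_ljungdahl",
        metabolites=(MetDef("co_c", "carbon monoxide", "CO", 0, "c"),),
        reactions=(
            ReactionDef(
                "WLFDH",
                "formate dehydrogenase (CO2-reducing, NADH)",
                {"co2_c": -1, "nadh_c": -1, "for_c": 1, "nad_c": 1},
            ),
            ReactionDef(
                "WLFHS",
                "formyl-THF ligase (ATP)",
                {"for_c": -1, "thf_c": -1, "atp_c": -1, "10fthf_c": 1, "adp_c": 1, "pi_c": 1},
            ),
            ReactionDef(
                "WLMTHFC",
                "methenyl-THF cyclohydrolase",
                {"10fthf_c": -1, "h_c": -1, "methf_c": 1, "h2o_c": 1},
                lower_bound=-1000.0,
            ),
            ReactionDef(
                "WLMTHFD",
                "methylene-THF dehydrogenase (NADH)",
                {"methf_c": -1, "nadh_c": -1, "mlthf_c": 1, "nad_c": 1},
                lower_bound=-1000.0,
            ),
            ReactionDef(
                "WLMTHFR",
                "methylene-THF reductase (NADH)",
                {"mlthf_c": -1, "nadh_c": -1, "h_c": -2, "5mthf_c": 1, "nad_c": 1},
            ),
            ReactionDef(
                "WLCODH",
                "CO dehydrogenase (CO2-reducing, NADH)",
                {"co2_c": -1, "nadh_c": -1, "h_c": -1, "co_c": 1, "nad_c": 1, "h2o_c": 1},
            ),
            ReactionDef(
                "WLACS",
                "acetyl-CoA synthase",
                {"5mthf_c": -1, "co_c": -1, "coa_c": -1, "accoa_c": 1, "thf_c": 1, "h_c": 1},
            ),
        ),
        product_exchange_id=None,
    )


def pathway_library() -> list[PathwaySpec]:
    """The built-in pathway set: 13pdo, 14bdo, nbutanol, wood_ljungdahl."""
    return [_pdo13(), _bdo14(), _nbutanol(), _wood_ljungdahl()]


def add_pathway(model: cobra.Model, spec: PathwaySpec) -> cobra.Model:
    """Return a copy of ``model`` with the pathway added.

    New metabolites are created from the spec's definitions; metabolites
    already in the model are reused as-is.  Reaction id collisions are
    errors.  The product exchange, if any, is opened for secretion only.
    Every interior reaction is checked for C/H/O balance against the model's
    formulas (metabolites without a formula are skipped).
    """
    collisions = [r.id for r in spec.reactions if r.id in model.reactions]
    if collisions:
        raise ValidationError(f"pathway {spec.name!r} collides with existing reaction id(s) {collisions}")
    new = model.copy()
    defs = {m.id: m for m in spec.metabolites}
    for rdef in spec.reactions:
        for mid in rdef.stoichiometry:
            if mid in new.metabolites or mid in defs:
                continue
            raise ValidationError(
                f"pathway {spec.name!r} references {mid!r}, absent from both the model and the spec"
            )
    to_create = [
        Metabolite(d.id, name=d.name, formula=d.formula, charge=d.charge, compartment=d.compartment)
        for d in spec.metabolites
        if d.id not in new.metabolites
    ]
    if to_create:
        new.add_metabolites(to_create)
    reactions = []
    for rdef in spec.reactions:
        rxn = Reaction(rdef.id, name=rdef.name)
        rxn.add_metabolites({new.metabolites.get_by_id(mid): c for mid, c in rdef.stoichiometry.items()})
        if len(rdef.stoichiometry) == 1:  # exchange: secretion only
            rxn.bounds = (0.0, 1000.0)
        else:
            rxn.bounds = (rdef.lower_bound, rdef.upper_bound)
        reactions.append(rxn)
    new.add_reactions(reactions)
    _check_elemental_balance(new, spec)
    return new


def _check_elemental_balance(model: cobra.Model, spec: PathwaySpec, elements=("C", "H", "O")) -> None:
    for rdef in spec.reactions:
        if len(rdef.stoichiometry) == 1:
            continue
        rxn = model.reactions.get_by_id(rdef.id)
        if any(not met.formula for met in rxn.metabolites):
            continue
        imbalance = rxn.check_mass_balance()
        bad = {el: v for el, v in imbalance.items() if el in elements and abs(v) > 1e-6}
        if bad:
            raise ValidationError(f"pathway reaction {rdef.id!r} is elementally unbalanced: {bad}")


def example_strain_designs() -> list[StrainDesign]:
    """Illustrative Feist-style growth-coupled designs for anaerobic
    *E. coli* genome-scale models (BiGG reaction ids).

    These stand in for literature knockout sets supplied as configuration;
    they progressively remove the competing NAD+-regenerating fermentation
    routes so the target product carries the redox burden at maximal growth.
    """
    return [
        StrainDesign(
            "ethanol_3ko",
            frozenset({"ACKr", "LDH_D", "FRD2"}),
            "EX_etoh_e",
            source="Feist-style illustrative set (3 knockouts)",
        ),
        StrainDesign(
            "ethanol_5ko",
            frozenset({"ACKr", "PTAr", "LDH_D", "FRD2", "FRD3"}),
            "EX_etoh_e",
            source="Feist-style illustrative set (5 knockouts)",
        ),
        StrainDesign(
            "ethanol_10ko",
            frozenset(
                {"ACKr", "PTAr", "LDH_D", "FRD2", "FRD3", "PFL", "ME1", "ME2", "MGSA", "GLYCDx"}
            ),
            "EX_etoh_e",
            source="Feist-style illustrative set (10 knockouts)",
        ),
        StrainDesign(
            "succinate_3ko",
            frozenset({"ACALD", "LDH_D", "PFL"}),
            "EX_succ_e",
            source="illustrative anaerobic succinate coupling set",
        ),
    ]


@dataclasses.dataclass(frozen=True)
class CouplingReport:
    design: str
    mu_max: float
    product_min_at_mu_max: float
    product_max_at_mu_max: float
    coupled: bool


def coupling_report(model: cobra.Model, design: StrainDesign, condition: Condition) -> CouplingReport:
    """Apply a design under a condition, maximize biomass, and report the
    product flux range at maximal growth.  Coupled means the *minimum*
    product flux at mu_max exceeds :data:`COUPLING_TOLERANCE`."""
    merged = dataclasses.replace(condition, knockouts=condition.knockouts | design.knockouts)
    prepared = apply_condition(model, merged)
    if design.target_product not in prepared.reactions:
        raise ValidationError(f"design target {design.target_product!r} missing after preparation")
    biomass = [r.id for r in prepared.reactions if r.objective_coefficient]
    if len(biomass) != 1:
        raise ValidationError("coupling_report needs a model with a single biomass objective")
    base = solve_fba(prepared, biomass[0], "max")
    if not base.optimal or base.objective_value <= COUPLING_TOLERANCE:
        return CouplingReport(design.name, 0.0, 0.0, 0.0, False)
    mu = base.objective_value
    with prepared:
        prepared.reactions.get_by_id(biomass[0]).bounds = (mu - 1e-9, mu + 1e-9)
        lo = solve_fba(prepared, design.target_product, "min")
        hi = solve_fba(prepared, design.target_product, "max")
    pmin = lo.objective_value if lo.optimal else 0.0
    pmax = hi.objective_value if hi.optimal else 0.0
    return CouplingReport(design.name, mu, pmin, pmax, pmin > COUPLING_TOLERANCE)
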