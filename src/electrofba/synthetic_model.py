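"""Deterministic toy fermentation networks with analytically known LP optima.

The toy emulates the minimal structure every pipeline stage needs: a single
substrate feeding a lumped glycolysis ``A -> B + n NADH + m ATP``, a reduced
product branch ``B + k NADH -> P_red``, an oxidized, ATP-yielding branch
``B + ADP -> P_ox + ATP``, a biomass drain on B/ATP/NADH, an ATP maintenance
drain, conserved NAD(H) and A(D/T)P couples, and the electrode pair from
:mod:`electrofba.electrosynthesis`.

Optional features mirror the mechanisms studied at genome scale:

* ``two_compartment`` adds a periplasm, a proton porin, an ATP synthase
  (``4 H+p + ADP <-> ATP + 4 H+c``) and an NADH-disposing hydrogenase, and
  wires the electrode proton to the cytosol, whose *only* import route is the
  synthase - so forced electron uptake ``e`` yields exactly ``(e/2)/4`` extra
  ATP (four protons in per ATP).
* ``include_co2_fixing_branch`` adds ``B + CO2 + NADH -> P_fix``, the minimal
  analogue of ppc-dependent reductive carboxylation.

Closed-form optima for the single-compartment family are provided by
:func:`toy_reference_optima`; they are derived by hand from the three balance
equations (B, NADH, ATP) and serve as the oracle for the LP engine.

Elemental bookkeeping: NAD/NADH carry the pseudo-element ``Nad`` (NADH has
one extra H, the hydride), ADP and ATP share the pseudo-formula ``Anp`` so
phosphoryl transfer is mass-silent, and B's hydrogen count is computed from
``n`` so every interior reaction balances C, H and O exactly.
"""

from __future__ import annotations

import dataclasses
import itertools

import cobra
from cobra import Metabolite, Reaction

from .electrosynthesis import ElectrodeSpec, add_electrode_reactions
from .errors import UnsupportedConfigError, ValidationError

__all__ = ["ToyConfig", "ToyOptima", "make_toy_model", "toy_reference_optima"]

BIOMASS_ID = "BIOMASS"
ATP_MAINTENANCE_ID = "ATPM"
REDUCED_PRODUCT_EXCHANGE = "EX_pred_e"
OXIDIZED_PRODUCT_EXCHANGE = "EX_pox_e"
SUBSTRATE_EXCHANGE = "EX_sub_e"
FIXED_PRODUCT_EXCHANGE = "EX_pfix_e"


@dataclasses.dataclass(frozen=True)
class ToyConfig:
    """Parameters of the toy network (all fluxes in mmol/gDW-hr)."""

    substrate_uptake_max: float = 10.0
    nadh_per_substrate: int = 2
    nadh_per_reduced_product: int = 3
    atp_per_substrate: int = 2
    biomass_atp: float = 2.0
    biomass_nadh: float = 1.0
    two_compartment: bool = False
    include_co2_fixing_branch: bool = False
    electron_uptake_max: float = 30.0

    def __post_init__(self) -> None:
        if self.substrate_uptake_max <= 0:
            raise ValidationError("substrate_uptake_max must be > 0")
        for field in ("nadh_per_substrate", "nadh_per_reduced_product", "atp_per_substrate"):
            if getattr(self, field) < 0:
                raise ValidationError(f"{field} must be >= 0")
        if self.biomass_atp < 0 or self.biomass_nadh < 0 or self.electron_uptake_max < 0:
            raise ValidationError("biomass coefficients and electron bound must be >= 0")


def make_toy_model(config: ToyConfig | None = None) -> cobra.Model:
    """Build the toy network for ``config`` (deterministic, no randomness)."""
    cfg = config or ToyConfig()
    n, k, m = cfg.nadh_per_substrate, cfg.nadh_per_reduced_product, cfg.atp_per_substrate
    if n > 12:
        raise ValidationError("nadh_per_substrate > 12 breaks the synthetic hydrogen bookkeeping")

    model = cobra.Model("toy_fermenter")
    model.compartments = {"c": "cytosol", "e": "extracellular"}

    b_formula = f"C6H{12 - n}O6"
    mets = {
        "sub_e": Metabolite("sub_e", name="substrate", formula="C6H12O6", charge=0, compartment="e"),
        "b_c": Metabolite("b_c", name="central intermediate B", formula=b_formula, charge=0, compartment="c"),
        "pred_e": Metabolite("pred_e", name="reduced product", formula=f"C6H{12 - n + k}O6", charge=0, compartment="e"),
        "pox_e": Metabolite("pox_e", name="oxidized product", formula=b_formula, charge=0, compartment="e"),
        "nad_c": Metabolite("nad_c", name="NAD+", formula="Nad", charge=0, compartment="c"),
        "nadh_c": Metabolite("nadh_c", name="NADH", formula="NadH", charge=0, compartment="c"),
        "adp_c": Metabolite("adp_c", name="ADP", formula="Anp", charge=0, compartment="c"),
        "atp_c": Metabolite("atp_c", name="ATP", formula="Anp", charge=0, compartment="c"),
        "h_c": Metabolite("h_c", name="proton (cytosol)", formula="H", charge=1, compartment="c"),
    }
    model.add_metabolites(list(mets.values()))

    def rxn(rid, name, stoich, lb, ub):
        r = Reaction(rid, name=name)
        r.add_metabolites({mets[mid]: c for mid, c in stoich.items() if c != 0})
        r.bounds = (lb, ub)
        return r

    reactions = [
        rxn(SUBSTRATE_EXCHANGE, "substrate exchange", {"sub_e": -1}, -cfg.substrate_uptake_max, 1000.0),
        rxn(
            "GLYC",
            "lumped glycolysis",
            {"sub_e": -1, "nad_c": -n, "adp_c": -m, "b_c": 1, "nadh_c": n, "atp_c": m},
            0.0,
            1000.0,
        ),
        rxn(
            "PRED",
            "reduced product synthesis",
            {"b_c": -1, "nadh_c": -k, "pred_e": 1, "nad_c": k},
            0.0,
            1000.0,
        ),
        rxn("POX", "oxidized product synthesis", {"b_c": -1, "adp_c": -1, "pox_e": 1, "atp_c": 1}, 0.0, 1000.0),
        rxn(
            BIOMASS_ID,
            "biomass drain",
            {
                "b_c": -1,
                "atp_c": -cfg.biomass_atp,
                "nadh_c": -cfg.biomass_nadh,
                "adp_c": cfg.biomass_atp,
                "nad_c": cfg.biomass_nadh,
            },
            0.0,
            1000.0,
        ),
        rxn(ATP_MAINTENANCE_ID, "ATP maintenance drain", {"atp_c": -1, "adp_c": 1}, 0.0, 1000.0),
        rxn(REDUCED_PRODUCT_EXCHANGE, "reduced product exchange", {"pred_e": -1}, 0.0, 1000.0),
        rxn(OXIDIZED_PRODUCT_EXCHANGE, "oxidized product exchange", {"pox_e": -1}, 0.0, 1000.0),
    ]

    if cfg.two_compartment:
        model.compartments = {**model.compartments, "p": "periplasm"}
        extra = {
            "h_e": Metabolite("h_e", name="proton (external)", formula="H", charge=1, compartment="e"),
            "h_p": Metabolite("h_p", name="proton (periplasm)", formula="H", charge=1, compartment="p"),
            "h2_e": Metabolite("h2_e", name="hydrogen", formula="H2", charge=0, compartment="e"),
        }
        model.add_metabolites(list(extra.values()))
        mets.update(extra)
        reactions += [
            rxn("EX_h_e", "proton exchange", {"h_e": -1}, -1000.0, 1000.0),
            rxn("HPORIN", "outer membrane proton diffusion", {"h_e": -1, "h_p": 1}, -1000.0, 1000.0),
            rxn(
                "ATPS",
                "ATP synthase (4 H+ per ATP)",
                {"h_p": -4, "adp_c": -1, "atp_c": 1, "h_c": 4},
                -1000.0,
                1000.0,
            ),
            rxn("HYD", "fermentative hydrogenase", {"nadh_c": -1, "h_p": -1, "nad_c": 1, "h2_e": 1}, 0.0, 1000.0),
            rxn("EX_h2_e", "hydrogen exchange", {"h2_e": -1}, 0.0, 1000.0),
        ]
    else:
        # single compartment: cytosolic protons exchange freely
        reactions.append(rxn("EX_h_c", "proton exchange", {"h_c": -1}, -1000.0, 1000.0))

    if cfg.include_co2_fixing_branch:
        extra = {
            "co2_e": Metabolite("co2_e", name="CO2", formula="CO2", charge=0, compartment="e"),
            "pfix_e": Metabolite(
                "pfix_e", name="carboxylated product", formula=f"C7H{12 - n + k}O8", charge=0, compartment="e"
            ),
        }
        model.add_metabolites(list(extra.values()))
        mets.update(extra)
        reactions += [
            rxn("EX_co2_e", "CO2 exchange", {"co2_e": -1}, -1000.0, 1000.0),
            # carboxylation plus reduction (k NADH), the ppc-dependent
            # succinate analogue: CO2 entry must be paid for in redox, which
            # is exactly what the electrode supplies
            rxn(
                "PFIX",
                "carboxylating product synthesis",
                {"b_c": -1, "co2_e": -1, "nadh_c": -k, "pfix_e": 1, "nad_c": k},
                0.0,
                1000.0,
            ),
            rxn(FIXED_PRODUCT_EXCHANGE, "carboxylated product exchange", {"pfix_e": -1}, 0.0, 1000.0),
        ]

    model.add_reactions(reactions)
    model.objective = BIOMASS_ID

    spec = ElectrodeSpec(proton_compartment="cytosol", electron_uptake_max=cfg.electron_uptake_max)
    model = add_electrode_reactions(model, spec)
    model.objective = BIOMASS_ID
    return model


@dataclasses.dataclass(frozen=True)
class ToyOptima:
    """Closed-form optima for a single-compartment toy configuration."""

    max_reduced_product: float
    max_oxidized_product: float
    max_atp: float
    max_biomass: float
    reduced_product_yield_base: float
    reduced_product_yield_enhanced: float
    yield_improvement: float


def toy_reference_optima(config: ToyConfig | None = None) -> ToyOptima:
    """Analytic optima for the closed-form toy family.

    Supported family: single compartment, no CO2 branch, and a reduced-product
    NADH demand at least the glycolytic NADH yield (``k >= n``; with ``k = 0``
    only ``n = 0``), so that redox balance is always attainable.  Everything
    follows from the three balances (with ``a`` the substrate flux, ``w`` the
    NADH delivered by the electrode, i.e. half the electron uptake):

    * B:     ``a = p_red + p_ox + v_bio``
    * NADH:  ``n a + w = k p_red + beta_n v_bio``
    * ATP:   ``m a + p_ox >= beta_a v_bio``
    """
    cfg = config or ToyConfig()
    if cfg.two_compartment or cfg.include_co2_fixing_branch:
        raise UnsupportedConfigError("closed forms cover the single-compartment, no-CO2 family only")
    n, k, m = cfg.nadh_per_substrate, cfg.nadh_per_reduced_product, cfg.atp_per_substrate
    U, E = cfg.substrate_uptake_max, cfg.electron_uptake_max
    if k < n or (k == 0 and n > 0):
        raise UnsupportedConfigError("closed forms require k >= n (redox-balanceable product branch)")

    ba, bn = cfg.biomass_atp, cfg.biomass_nadh

    def max_pred(e_bound: float) -> float:
        # biomass competes for both B and NADH, so it stays off at this optimum
        if k == 0:  # n == 0 here: no redox coupling at all
            return U
        return min(U, (n * U + e_bound / 2.0) / k)

    p_base = max_pred(0.0)
    p_enh = max_pred(E)

    # P_ox and ATP maxima: the glycolytic NADH (n*U, electrode off - extra
    # NADH only raises the disposal bill) must be burned either by the
    # reduced branch (1/k B per NADH) or by the biomass drain (1/bn B plus
    # ba/bn ATP per NADH); enumerate the reduced LP in (p_red, v_bio)
    nadh_eq = [(k, bn, n * U), (-k, -bn, -n * U)]  # k*p_red + bn*v = n*U
    positivity = [(-1.0, 0.0, 0.0), (0.0, -1.0, 0.0)]
    b_balance = (1.0, 1.0, U)  # p_ox >= 0
    atp_balance = (1.0, 1.0 + ba, (m + 1.0) * U)  # maintenance drain >= 0
    max_pox = U + _analytic_lp_max(
        nadh_eq + positivity + [b_balance, atp_balance], (-1.0, -1.0)
    )
    max_atp = (m + 1.0) * U + _analytic_lp_max(
        nadh_eq + positivity + [b_balance], (-1.0, -(1.0 + ba))
    )

    return ToyOptima(
        max_reduced_product=p_enh,
        max_oxidized_product=max_pox,
        max_atp=max_atp,
        max_biomass=_max_biomass_closed_form(cfg),
        reduced_product_yield_base=p_base / U,
        reduced_product_yield_enhanced=p_enh / U,
        yield_improvement=(p_enh - p_base) / p_base if p_base > 0 else float("nan"),
    )


def _analytic_lp_max(cons: list[tuple[float, float, float]], c: tuple[float, float]) -> float:
    """Maximize ``c.(x, y)`` over ``{a x + b y <= g}`` by enumerating the
    pairwise intersections of the constraint lines (pure linear algebra, no
    LP solver; regions here are always bounded)."""

    def feasible(x: float, y: float) -> bool:
        return all(a * x + b * y <= g + 1e-9 for a, b, g in cons)

    best = c[0] * 0.0 + c[1] * 0.0 if feasible(0.0, 0.0) else float("-inf")
    for (a1, b1, g1), (a2, b2, g2) in itertools.combinations(cons, 2):
        det = a1 * b2 - a2 * b1
        if abs(det) < 1e-12:
            continue
        x = (g1 * b2 - g2 * b1) / det
        y = (a1 * g2 - a2 * g1) / det
        if feasible(x, y):
            best = max(best, c[0] * x + c[1] * y)
    return best


def _max_biomass_closed_form(cfg: ToyConfig) -> float:
    """Maximum biomass flux by analytic vertex enumeration of the reduced
    two-variable LP in (v, w): v the biomass flux, w the electrode NADH.

    After substituting the B and NADH balances at full substrate uptake
    (optimal for k >= n), the feasible region is cut by p_red >= 0,
    p_ox >= 0, the ATP balance, 0 <= w <= E/2 and v >= 0 - all linear in
    (v, w).  The optimum sits on a pairwise intersection of these lines.
    """
    n, k, m = cfg.nadh_per_substrate, cfg.nadh_per_reduced_product, cfg.atp_per_substrate
    U, E = cfg.substrate_uptake_max, cfg.electron_uptake_max
    ba, bn = cfg.biomass_atp, cfg.biomass_nadh

    # constraints as alpha*v + beta*w <= gamma
    cons: list[tuple[float, float, float]] = []
    if k > 0:
        # p_red = (nU + w - bn*v)/k >= 0
        cons.append((bn, -1.0, n * U))
        # p_ox = U - v - p_red >= 0  ->  (k - bn) v + w <= U(k - n)
        cons.append((k - bn, 1.0, U * (k - n)))
        # ATP: mU + p_ox >= ba*v  ->  (k(1+ba) - bn) v + w <= kU(m+1) - nU
        cons.append((k * (1.0 + ba) - bn, 1.0, k * U * (m + 1.0) - n * U))
    else:  # k == 0, n == 0: NADH balance w = bn*v exactly
        if bn > 0:
            cons.append((bn, -1.0, 0.0))  # w >= bn*v
            cons.append((-bn, 1.0, 0.0))  # w <= bn*v
        # p_red free drain of B: p_ox can be 0..U-v; ATP: mU + (U - v) >= ba*v
        cons.append((1.0 + ba, 0.0, U * (m + 1.0)))
        cons.append((1.0, 0.0, U))  # v <= U (B balance)
    cons.append((0.0, 1.0, E / 2.0))  # w <= E/2
    cons.append((0.0, -1.0, 0.0))  # w >= 0
    cons.append((-1.0, 0.0, 0.0))  # v >= 0

    def feasible(v: float, w: float) -> bool:
        return all(a * v + b * w <= g + 1e-9 for a, b, g in cons)

    best = 0.0 if feasible(0.0, 0.0) else float("nan")
    for (a1, b1, g1), (a2, b2, g2) in itertools.combinations(cons, 2):
        det = a1 * b2 - a2 * b1
        if abs(det) < 1e-12:
            continue
        v = (g1 * b2 - g2 * b1) / det
        w = (a1 * g2 - a2 * g1) / det
        if feasible(v, w) and v > best:
            best = v
    return best
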