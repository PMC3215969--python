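"""The cathode model: electrode reactions, electron bounds and unit conversions.

Electron uptake from a cathode is represented by two reactions:

* an electron exchange ``EX_e_el_e`` whose lower bound limits uptake
  (default 30 mmol e-/gDW-hr, the literature-consistent bound of roughly
  800 mA/gDW), and
* a cytoplasmic NADH regeneration reaction
  ``NADHR: 2 e- + NAD+ + H+ -> NADH``
  lumping the electrode -> quinone pool -> NAD+ electron path.

The proton consumed by NADHR is configurable between the periplasm and the
cytosol.  With a cytosolic proton whose only import route is ATP synthase,
forced electron uptake ``e`` drives an ATP synthesis flux of exactly
``(e/2)/4`` - the proton-influx/ATP-synthase coupling motif (four protons
translocated per ATP).
"""

from __future__ import annotations

import dataclasses

import cobra
import numpy as np
from cobra import Metabolite, Reaction

from .errors import SolverError, ValidationError

__all__ = [
    "FARADAY_C_PER_MOL",
    "SECONDS_PER_HOUR",
    "DEFAULT_ELECTRON_UPTAKE_MAX",
    "ElectrodeSpec",
    "UnitConstants",
    "add_electrode_reactions",
    "flux_to_current",
    "current_to_flux",
    "current_density",
    "glucose_equivalent_electron_flux",
    "optimal_electron_uptake",
    "ElectronOptimum",
    "DEFAULT_ELECTRON_EXCHANGE_ID",
    "DEFAULT_NADH_REGEN_ID",
]

FARADAY_C_PER_MOL = 96485.0
SECONDS_PER_HOUR = 3600.0
#: electrons released by complete oxidation of one glucose to CO2
ELECTRONS_PER_GLUCOSE = 24
DEFAULT_ELECTRON_UPTAKE_MAX = 30.0

DEFAULT_ELECTRON_METABOLITE_ID = "e_el_e"
DEFAULT_ELECTRON_EXCHANGE_ID = "EX_e_el_e"
DEFAULT_NADH_REGEN_ID = "NADHR"


@dataclasses.dataclass(frozen=True)
class ElectrodeSpec:
    """Specification of the two electrode reactions added to a model."""

    electron_metabolite_id: str = DEFAULT_ELECTRON_METABOLITE_ID
    electron_exchange_id: str = DEFAULT_ELECTRON_EXCHANGE_ID
    nadh_regen_id: str = DEFAULT_NADH_REGEN_ID
    nad_id: str = "nad_c"
    nadh_id: str = "nadh_c"
    #: 'periplasm' or 'cytosol'; which proton pool the NADH regeneration draws
    proton_compartment: str = "periplasm"
    proton_id: str | None = None
    electron_compartment: str = "e"
    electron_uptake_max: float = DEFAULT_ELECTRON_UPTAKE_MAX

    def __post_init__(self) -> None:
        if self.electron_uptake_max < 0:
            raise ValidationError("electron_uptake_max must be >= 0")
        if self.proton_compartment not in ("periplasm", "cytosol"):
            raise ValidationError("proton_compartment must be 'periplasm' or 'cytosol'")

    def resolved_proton_id(self) -> str:
        if self.proton_id is not None:
            return self.proton_id
        return "h_p" if self.proton_compartment == "periplasm" else "h_c"


@dataclasses.dataclass(frozen=True)
class UnitConstants:
    """Physical constants and the literature reference pair used to convert a
    per-biomass current (A/gDW) into an areal current density (A/m2)."""

    faraday: float = FARADAY_C_PER_MOL
    seconds_per_hour: float = SECONDS_PER_HOUR
    #: (A/gDW, A/m2) measured for the same biofilm; defaults are the published
    #: electricigen reference values (1.07 A/gDW at 1.143 A/m2)
    area_density_reference: tuple[float, float] = (1.07, 1.143)

    def __post_init__(self) -> None:
        if self.faraday <= 0 or self.seconds_per_hour <= 0:
            raise ValidationError("unit constants must be strictly positive")
        a, b = self.area_density_reference
        if a <= 0 or b <= 0:
            raise ValidationError("area/density reference pair must be strictly positive")


def add_electrode_reactions(model: cobra.Model, spec: ElectrodeSpec | None = None) -> cobra.Model:
    """Return a copy of ``model`` augmented with the electron exchange and the
    NADH regeneration reaction ``2 e- + NAD+ + H+ -> NADH``.

    Adds exactly two reactions and one metabolite (the electron species, which
    appears only in these two reactions).  Electron donation to an anode is
    not modelled: the exchange upper bound is zero.
    """
    spec = spec or ElectrodeSpec()
    for mid in (spec.nad_id, spec.nadh_id, spec.resolved_proton_id()):
        if mid not in model.metabolites:
            raise ValidationError(f"model lacks metabolite {mid!r} required by the electrode reactions")
    for rid in (spec.electron_exchange_id, spec.nadh_regen_id):
        if rid in model.reactions:
            raise ValidationError(f"model already contains reaction {rid!r}")

    new = model.copy()
    electron = Metabolite(
        spec.electron_metabolite_id,
        name="electrode electron",
        compartment=spec.electron_compartment,
        charge=-1,
        formula=None,  # formula-free so elemental balance checks skip it
    )
    exchange = Reaction(spec.electron_exchange_id, name="electrode electron exchange")
    exchange.add_metabolites({electron: -1})
    exchange.bounds = (-spec.electron_uptake_max, 0.0)

    regen = Reaction(spec.nadh_regen_id, name="electrode NADH regeneration")
    regen.add_metabolites(
        {
            electron: -2,
            new.metabolites.get_by_id(spec.nad_id): -1,
            new.metabolites.get_by_id(spec.resolved_proton_id()): -1,
            new.metabolites.get_by_id(spec.nadh_id): 1,
        }
    )
    regen.bounds = (0.0, 1000.0)
    _check_regen_stoichiometry(regen, spec)
    new.add_reactions([exchange, regen])
    return new


def _check_regen_stoichiometry(regen: cobra.Reaction, spec: ElectrodeSpec) -> None:
    coeffs = {met.id: coef for met, coef in regen.metabolites.items()}
    if not (
        coeffs.get(spec.electron_metabolite_id) == -2
        and coeffs.get(spec.nad_id) == -1
        and coeffs.get(spec.nadh_id) == 1
    ):
        raise ValidationError(
            "NADH regeneration must consume exactly 2 electrons and 1 NAD+ and produce 1 NADH"
        )


def flux_to_current(v_e: float) -> float:
    """Convert an electron flux (mmol e-/gDW-hr) to a current (A/gDW).

    30 mmol e-/gDW-hr corresponds to 0.804 A/gDW (ca. 800 mA/gDW).
    """
    if v_e < 0:
        raise ValidationError("electron flux must be >= 0")
    return v_e * 1e-3 * FARADAY_C_PER_MOL / SECONDS_PER_HOUR


def current_to_flux(current: float) -> float:
    """Exact inverse of :func:`flux_to_current` (A/gDW -> mmol e-/gDW-hr)."""
    if current < 0:
        raise ValidationError("current must be >= 0")
    return current * SECONDS_PER_HOUR / (1e-3 * FARADAY_C_PER_MOL)


def current_density(v_e: float, constants: UnitConstants | None = None) -> float:
    """Convert an electron flux to an areal current density (A/m2) through the
    biofilm reference pair in ``constants``."""
    constants = constants or UnitConstants()
    per_mass, per_area = constants.area_density_reference
    return flux_to_current(v_e) * per_area / per_mass


def glucose_equivalent_electron_flux(glc_uptake: float) -> float:
    """Electron flux (mmol e-/gDW-hr) equivalent to fully oxidizing the given
    glucose uptake (24 e- per glucose): 10 mmol/gDW-hr -> 240."""
    if glc_uptake < 0:
        raise ValidationError("uptake must be >= 0")
    return ELECTRONS_PER_GLUCOSE * glc_uptake


@dataclasses.dataclass(frozen=True)
class ElectronOptimum:
    """Best point of an electron-uptake scan (see :func:`optimal_electron_uptake`)."""

    electron_uptake: float
    growth_rate: float
    product_flux: float
    scanned: "np.ndarray | None" = None  # (bound, growth, product) per feasible grid point


def optimal_electron_uptake(
    model: cobra.Model,
    product_exchange_id: str,
    biomass_id: str,
    grid=None,
    electron_exchange_id: str = DEFAULT_ELECTRON_EXCHANGE_ID,
) -> ElectronOptimum:
    """Scan fixed electron-uptake rates, maximizing biomass at each, and return
    the rate whose (growth-coupled, parsimonious) product flux is largest.

    Ties in product flux are broken toward higher growth.  The default grid is
    0 to 30 mmol e-/gDW-hr in steps of 0.2.
    """
    from .fba_engine import resolve_fluxes

    if grid is None:
        grid = np.arange(0.0, DEFAULT_ELECTRON_UPTAKE_MAX + 1e-9, 0.2)
    grid = np.asarray(list(grid), dtype=float)
    if grid.size == 0:
        raise ValidationError("electron uptake grid must be non-empty")
    if product_exchange_id not in model.reactions:
        raise ValidationError(f"unknown product exchange {product_exchange_id!r}")
    exchange = model.reactions.get_by_id(electron_exchange_id)

    rows = []
    for bound in grid:
        with model:
            exchange.bounds = (-bound, -bound)
            result = resolve_fluxes(model, biomass_id, "max")
            if result.status != "optimal":
                continue
            rows.append((bound, result.objective_value, result.fluxes[product_exchange_id]))
    if not rows:
        raise SolverError("no feasible point on the electron-uptake grid")
    scanned = np.array(rows)
    best = max(rows, key=lambda r: (round(r[2], 9), round(r[1], 9)))
    return ElectronOptimum(best[0], best[1], best[2], scanned)
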