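"""Reading, writing and editing stoichiometric models and run configurations.

Models are held as :class:`cobra.Model` instances (metabolites, reactions,
bounds and objective map one-to-one onto the stoichiometric matrix ``S``, the
bound vectors and the objective vector of the flux balance problem).  All
editing operations here are pure: they return a modified copy and leave the
input model untouched.

Sign convention: exchange fluxes are negative for uptake.  A
:class:`Condition` stores positive uptake magnitudes and
:func:`apply_condition` sets ``lower_bound = -magnitude``.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
from collections.abc import Iterable, Mapping
from pathlib import Path

import cobra
import cobra.io
import yaml

from .errors import ConfigurationError, FormatError, ValidationError

__all__ = [
    "Condition",
    "load_model",
    "save_model",
    "load_bundled_ecoli",
    "apply_condition",
    "knockout",
    "validate_model",
    "is_carbon_source_exchange",
]

#: exchanged species that carry carbon but are treated as inorganic medium
#: components and therefore stay open when a single-substrate medium is set up
_INORGANIC_CARBON = {"co2", "hco3", "co3"}


@dataclasses.dataclass(frozen=True)
class Condition:
    """Medium, uptake-rate and electron-bound specification of one simulation.

    Parameters
    ----------
    substrate_uptakes
        Map from exchange reaction id to the maximum uptake rate
        (mmol/gDW-hr, positive magnitude).
    aerobic
        When ``False`` the oxygen exchange is closed for uptake (secretion
        stays allowed).
    electron_uptake_max
        Upper bound on cathodic electron uptake, mmol e-/gDW-hr.  The model
        is free to use any uptake in ``[0, electron_uptake_max]``.
    knockouts
        Reaction ids whose bounds are forced to zero.
    pathway_additions
        Names of heterologous pathways (see :mod:`electrofba.pathways`) to
        add before the medium is applied.
    """

    substrate_uptakes: Mapping[str, float] = dataclasses.field(default_factory=dict)
    aerobic: bool = False
    electron_uptake_max: float = 0.0
    knockouts: frozenset[str] = frozenset()
    pathway_additions: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for rid, rate in self.substrate_uptakes.items():
            if rate < 0:
                raise ValidationError(f"uptake rate for {rid!r} must be >= 0, got {rate}")
        if self.electron_uptake_max < 0:
            raise ValidationError("electron_uptake_max must be >= 0")
        object.__setattr__(self, "substrate_uptakes", dict(self.substrate_uptakes))
        object.__setattr__(self, "knockouts", frozenset(self.knockouts))
        object.__setattr__(self, "pathway_additions", tuple(self.pathway_additions))

    @classmethod
    def from_file(cls, path: str | Path) -> "Condition":
        """Load a condition from a YAML file with keys ``substrates``,
        ``aerobic``, ``electron_uptake_max``, ``knockouts``, ``pathways``."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise FormatError(f"condition file {path} is not a mapping")
        return cls(
            substrate_uptakes=raw.get("substrates", {}),
            aerobic=bool(raw.get("aerobic", False)),
            electron_uptake_max=float(raw.get("electron_uptake_max", 0.0)),
            knockouts=frozenset(raw.get("knockouts", ())),
            pathway_additions=tuple(raw.get("pathways", ())),
        )


def load_model(path: str | Path, format: str | None = None) -> cobra.Model:
    """Read a metabolic model from SBML (Level 3 / FBC) or BiGG-style JSON.

    ``format`` is inferred from the file suffix when not given.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"model file not found: {path}")
    if format is None:
        name = path.name.lower()
        format = "json" if name.endswith(".json") else "sbml"
    if format not in ("sbml", "json"):
        raise ValidationError(f"unknown model format {format!r} (expected 'sbml' or 'json')")
    try:
        if format == "json":
            model = cobra.io.load_json_model(str(path))
        else:
            model = cobra.io.read_sbml_model(str(path))
    except Exception as exc:  # cobra raises many parser-specific types
        raise FormatError(f"could not parse {path} as {format}: {exc}") from exc
    validate_model(model)
    return model


def save_model(model: cobra.Model, path: str | Path, format: str | None = None) -> None:
    """Write a model as SBML L3/FBC or BiGG-style JSON (inferred from suffix)."""
    path = Path(path)
    if format is None:
        format = "json" if path.name.lower().endswith(".json") else "sbml"
    if format == "json":
        cobra.io.save_json_model(model, str(path))
    elif format == "sbml":
        cobra.io.write_sbml_model(model, str(path))
    else:
        raise ValidationError(f"unknown model format {format!r}")


def load_bundled_ecoli(name: str = "iJO1366") -> cobra.Model:
    """Load one of the *E. coli* reconstructions distributed with cobrapy.

    ``iJO1366`` (genome-scale) and ``textbook`` (core network) ship inside the
    installed cobra package and need no network access.
    """
    data = importlib.resources.files("cobra.data")
    candidates = [f"{name}.xml.gz", f"{name}.xml", f"{name}.json"]
    for cand in candidates:
        resource = data / cand
        if resource.is_file():
            with importlib.resources.as_file(resource) as p:
                return cobra.io.read_sbml_model(str(p)) if "xml" in cand else cobra.io.load_json_model(str(p))
    raise FormatError(f"no bundled model named {name!r} in cobra.data")


def validate_model(model: cobra.Model) -> None:
    """Check structural invariants: non-empty stoichiometries, no all-zero
    columns, exchange reactions touching exactly one metabolite."""
    for rxn in model.reactions:
        if not rxn.metabolites:
            raise ValidationError(f"reaction {rxn.id!r} has an empty (all-zero) stoichiometry")
        if rxn.lower_bound > rxn.upper_bound:
            raise ValidationError(f"reaction {rxn.id!r} has lower_bound > upper_bound")
        if rxn.boundary and len(rxn.metabolites) != 1:
            raise ValidationError(f"exchange reaction {rxn.id!r} touches {len(rxn.metabolites)} metabolites")


def _sole_metabolite(exchange: cobra.Reaction) -> cobra.Metabolite:
    return next(iter(exchange.metabolites))


def is_carbon_source_exchange(exchange: cobra.Reaction) -> bool:
    """True for exchanges of organic (carbon-containing, non-CO2/bicarbonate)
    species; these are the exchanges closed for uptake when a defined medium
    with a stated substrate is applied."""
    met = _sole_metabolite(exchange)
    stem = met.id.rsplit("_", 1)[0].lower()
    if stem in _INORGANIC_CARBON:
        return False
    if not met.formula:
        return False
    return met.elements.get("C", 0) > 0


def apply_condition(model: cobra.Model, condition: Condition) -> cobra.Model:
    """Return a copy of ``model`` with ``condition`` applied.

    The named substrate exchanges are opened to the stated uptake magnitude,
    every other organic carbon exchange is closed for uptake (the substrate is
    the sole carbon source; inorganic exchanges stay open), oxygen uptake is
    closed when anaerobic, knockouts are applied and listed pathways added.
    """
    new = model.copy()
    if condition.pathway_additions:
        from .pathways import add_pathway, pathway_library

        library = {spec.name: spec for spec in pathway_library()}
        for name in condition.pathway_additions:
            if name not in library:
                raise ConfigurationError(f"unknown pathway {name!r}; known: {sorted(library)}")
            new = add_pathway(new, library[name])

    for rid in condition.substrate_uptakes:
        if rid not in new.reactions:
            raise ValidationError(f"condition names unknown exchange {rid!r}")
    for rid in condition.knockouts:
        if rid not in new.reactions:
            raise ValidationError(f"condition names unknown knockout reaction {rid!r}")

    for exchange in new.exchanges:
        if exchange.id in condition.substrate_uptakes:
            continue
        if is_carbon_source_exchange(exchange):
            exchange.lower_bound = max(exchange.lower_bound, 0.0)
    for rid, magnitude in condition.substrate_uptakes.items():
        new.reactions.get_by_id(rid).lower_bound = -magnitude

    if not condition.aerobic:
        for exchange in new.exchanges:
            if _sole_metabolite(exchange).elements == {"O": 2}:
                exchange.lower_bound = max(exchange.lower_bound, 0.0)

    for rid in condition.knockouts:
        new.reactions.get_by_id(rid).bounds = (0.0, 0.0)

    from .electrosynthesis import DEFAULT_ELECTRON_EXCHANGE_ID

    if DEFAULT_ELECTRON_EXCHANGE_ID in new.reactions:
        new.reactions.get_by_id(DEFAULT_ELECTRON_EXCHANGE_ID).lower_bound = -condition.electron_uptake_max
    elif condition.electron_uptake_max > 0:
        raise ConfigurationError(
            "condition requests electron uptake but the model has no electrode; "
            "augment it first with electrosynthesis.add_electrode_reactions"
        )
    return new


def knockout(model: cobra.Model, reaction_ids: Iterable[str]) -> cobra.Model:
    """Return a copy of ``model`` with the listed reactions' bounds set to zero."""
    ids = list(reaction_ids)
    missing = [rid for rid in ids if rid not in model.reactions]
    if missing:
        raise ValidationError(f"unknown reaction id(s): {missing}")
    new = model.copy()
    for rid in ids:
        new.reactions.get_by_id(rid).bounds = (0.0, 0.0)
    return new
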