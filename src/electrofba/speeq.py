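"""Degree of reduction and the SPEEQ metric, plus the substrate x product
theoretical-yield-improvement grid.

The degree of reduction used here is pyruvate-referenced, not the classical
electron-per-carbon formula: it is the number of NADH equivalents produced
oxidizing a substrate to pyruvate, or consumed forming a product from
pyruvate, divided by the compound's carbon count.  SPEEQ (Substrate Product
Electron Equivalence Quotient) divides the substrate's degree of reduction by
the product's; values above one mean the substrate is more reduced than the
product, and electrical enhancement matters most when SPEEQ is small.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Mapping

import cobra
import pandas as pd

from .errors import ValidationError
from .fba_engine import max_theoretical_yield
from .model_io import Condition

__all__ = [
    "SPEEQRecord",
    "degree_of_reduction",
    "speeq",
    "register_compound",
    "known_compounds",
    "yield_improvement_grid",
    "grid_to_frame",
]

#: compound -> (NADH equivalents to/from pyruvate, carbon count).  The panel
#: covers the standard fermentation substrate/product set; degree of
#: reduction is reported at two decimals, the panel's printed precision.
_PANEL: dict[str, tuple[float, int]] = {
    # products (NADH consumed from pyruvate)
    "succinate": (2.0, 4),
    "1,3-propanediol": (3.0, 3),
    "1,4-butanediol": (6.0, 4),
    "n-butanol": (4.0, 4),
    "ethanol": (2.0, 2),
    # substrates (NADH produced en route to pyruvate)
    "glucose": (2.0, 6),
    "xylose": (1.67, 5),
    "glycerol": (2.0, 3),
    "maltose": (4.0, 12),
    "sorbitol": (3.0, 6),
    "gluconate": (1.0, 6),
}

_USER_PANEL: dict[str, tuple[float, int]] = {}


def register_compound(name: str, nadh_equivalents: float, carbons: int) -> None:
    """Register a user compound for degree-of-reduction lookups."""
    if carbons <= 0:
        raise ValidationError("carbon count must be positive")
    _USER_PANEL[name.lower()] = (float(nadh_equivalents), int(carbons))


def known_compounds() -> list[str]:
    return sorted(set(_PANEL) | set(_USER_PANEL))


def _lookup(name: str) -> tuple[float, int]:
    key = name.lower()
    if key in _USER_PANEL:
        return _USER_PANEL[key]
    if key in _PANEL:
        return _PANEL[key]
    raise ValidationError(f"unknown compound {name!r}; known: {known_compounds()}")


def degree_of_reduction(compound: str) -> float:
    """NADH equivalents per carbon, at the panel's two-decimal precision."""
    nadh, carbons = _lookup(compound)
    return round(nadh / carbons, 2)


def speeq(substrate: str, product: str) -> float:
    """Degree of reduction of the substrate over that of the product."""
    dor_p = degree_of_reduction(product)
    if dor_p <= 0:
        raise ValidationError(f"product {product!r} has non-positive degree of reduction")
    return degree_of_reduction(substrate) / dor_p


@dataclasses.dataclass(frozen=True)
class SPEEQRecord:
    """One substrate-product cell of the yield-improvement grid."""

    substrate: str
    product: str
    dor_substrate: float | None
    dor_product: float | None
    speeq: float | None
    yield_base: float
    yield_enhanced: float
    improvement: float
    feasible: bool = True


def _dor_or_none(name: str) -> float | None:
    try:
        return degree_of_reduction(name)
    except ValidationError:
        return None


def yield_improvement_grid(
    model: cobra.Model,
    substrates: Mapping[str, tuple[str, float]],
    products: Mapping[str, str],
    electron_bound: float = 30.0,
    aerobic: bool = False,
    pathway_additions: Mapping[str, tuple[str, ...]] | None = None,
) -> list[SPEEQRecord]:
    """Maximum theoretical yield with and without electrical enhancement for
    every substrate x product pair.

    ``substrates`` maps a compound name to ``(exchange_id, uptake_rate)``
    (equal-carbon uptake rates by convention); ``products`` maps a compound
    name to its exchange id; ``pathway_additions`` optionally lists the
    heterologous pathways a product needs.  Infeasible pairs are flagged, not
    dropped.  Records are sorted by SPEEQ (unknown-SPEEQ pairs last).
    """
    records: list[SPEEQRecord] = []
    for sub_name, (sub_exchange, uptake) in substrates.items():
        for prod_name, prod_exchange in products.items():
            pathways = tuple((pathway_additions or {}).get(prod_name, ()))
            yields = {}
            feasible = True
            for label, bound in (("base", 0.0), ("enhanced", electron_bound)):
                condition = Condition(
                    substrate_uptakes={sub_exchange: uptake},
                    aerobic=aerobic,
                    electron_uptake_max=bound,
                    pathway_additions=pathways,
                )
                result = max_theoretical_yield(model, prod_exchange, condition)
                if not result.optimal or result.yield_per_substrate is None:
                    feasible = False
                    yields[label] = float("nan")
                else:
                    yields[label] = result.yield_per_substrate
            base, enhanced = yields["base"], yields["enhanced"]
            improvement = (enhanced - base) / base if feasible and base > 0 else float("nan")
            sp = None
            dor_s, dor_p = _dor_or_none(sub_name), _dor_or_none(prod_name)
            if dor_s is not None and dor_p:
                sp = dor_s / dor_p
            records.append(
                SPEEQRecord(sub_name, prod_name, dor_s, dor_p, sp, base, enhanced, improvement, feasible)
            )
    records.sort(key=lambda r: (r.speeq is None, r.speeq if r.speeq is not None else 0.0))
    return records


def grid_to_frame(records: list[SPEEQRecord]) -> pd.DataFrame:
    """Tabular form of a yield-improvement grid (TSV-ready)."""
    rows = [
        {
            "substrate": r.substrate,
            "product": r.product,
            "speeq": r.speeq,
            "yield_base_mol_per_mol": r.yield_base,
            "yield_enhanced_mol_per_mol": r.yield_enhanced,
            "improvement_pct": 100.0 * r.improvement,
            "feasible": r.feasible,
        }
        for r in records
    ]
    return pd.DataFrame(rows)
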