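"""Linear programs behind every result: FBA optima, parsimonious flux
distributions, theoretical yields and production envelopes.

The flux balance problem is ``max/min c.v`` subject to ``S.v = 0`` and
``lb <= v <= ub``.  The LP optimum is unique even when the optimizer is not,
so objective values are deterministic; reported flux *distributions* always
come from :func:`resolve_fluxes`, which re-minimizes total absolute flux at
the fixed optimum (parsimonious resolution) to strip alternate-optimum noise.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import cobra
import numpy as np
import pandas as pd
from cobra.flux_analysis.parsimonious import add_pfba

from .errors import SolverError, ValidationError
from .model_io import Condition, apply_condition

__all__ = [
    "FBAResult",
    "Envelope",
    "solve_fba",
    "resolve_fluxes",
    "max_theoretical_yield",
    "production_envelope",
]

#: tolerance inside which the objective is held fixed while re-minimizing |v|
OPTIMUM_TOLERANCE = 1e-9
#: tolerance asserted on steady state and bound satisfaction in reports
FEASIBILITY_TOLERANCE = 1e-6


@dataclasses.dataclass
class FBAResult:
    """Outcome of one LP solve.

    ``objective_value`` is in the objective reaction's units (1/hr for a
    biomass reaction, mmol/gDW-hr otherwise).  ``fluxes`` is empty unless the
    status is optimal.  ``parsimonious`` records whether the distribution came
    from :func:`resolve_fluxes`.
    """

    status: str
    objective_value: float
    fluxes: pd.Series
    objective_id: str | None = None
    direction: str = "max"
    parsimonious: bool = False
    substrate_uptake: float | None = None
    yield_per_substrate: float | None = None

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"

    def to_tsv(self, path: str | Path) -> None:
        frame = self.fluxes.rename("flux_mmol_per_gDW_hr").to_frame()
        frame.index.name = "reaction_id"
        frame.to_csv(path, sep="\t", float_format="%.12g")

    def to_json_report(self) -> dict:
        return {
            "status": self.status,
            "objective_id": self.objective_id,
            "direction": self.direction,
            "objective_value": None if np.isnan(self.objective_value) else self.objective_value,
            "parsimonious": self.parsimonious,
            "substrate_uptake_mmol_per_gDW_hr": self.substrate_uptake,
            "yield_mol_per_mol_substrate": self.yield_per_substrate,
        }


@dataclasses.dataclass
class Envelope:
    """Production envelope: (growth, min product, max product) triples on an
    ascending growth grid whose last point is exactly the growth maximum."""

    points: list[tuple[float, float, float]]
    electron_uptake_max: float
    product_id: str
    biomass_id: str

    @property
    def mu_max(self) -> float:
        return self.points[-1][0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.points,
            columns=["growth_rate_per_hr", "product_min_mmol_per_gDW_hr", "product_max_mmol_per_gDW_hr"],
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.12g")

    def to_json_report(self) -> dict:
        return {
            "product_id": self.product_id,
            "biomass_id": self.biomass_id,
            "electron_uptake_max_mmol_per_gDW_hr": self.electron_uptake_max,
            "mu_max_per_hr": self.mu_max,
            "points": self.points,
        }

    def contains(self, other: "Envelope", tol: float = 1e-6) -> bool:
        """Pointwise containment on a shared growth grid (used to test that a
        relaxed electron bound enlarges the envelope)."""
        if len(self.points) != len(other.points):
            raise ValidationError("envelopes must share a grid length for containment checks")
        for (_, lo_a, hi_a), (_, lo_b, hi_b) in zip(self.points, other.points):
            if lo_a > lo_b + tol or hi_a < hi_b - tol:
                return False
        return True


_STATUS_MAP = {
    "optimal": "optimal",
    "infeasible": "infeasible",
    "unbounded": "unbounded",
    "undefined": "infeasible",
    "infeasible_or_unbounded": "infeasible",
}


def _status(raw: str | None) -> str:
    return _STATUS_MAP.get(str(raw), "infeasible")


def solve_fba(model: cobra.Model, objective_id: str | None = None, direction: str = "max") -> FBAResult:
    """Solve one FBA problem and return the optimum with raw solver fluxes.

    The returned flux vector is one of possibly many alternate optima; use
    :func:`resolve_fluxes` whenever individual fluxes will be reported.
    """
    if direction not in ("max", "min"):
        raise ValidationError("direction must be 'max' or 'min'")
    if objective_id is not None and objective_id not in model.reactions:
        raise ValidationError(f"unknown objective reaction {objective_id!r}")
    with model:
        if objective_id is not None:
            model.objective = model.reactions.get_by_id(objective_id)
        model.objective_direction = direction
        solution = model.optimize(raise_error=False)
        status = _status(solution.status)
        if status != "optimal":
            return FBAResult(status, float("nan"), pd.Series(dtype=float), objective_id, direction)
        return FBAResult(status, float(solution.objective_value), solution.fluxes, objective_id, direction)


def resolve_fluxes(model: cobra.Model, objective_id: str | None = None, direction: str = "max") -> FBAResult:
    """Solve, then re-minimize total absolute flux with the objective fixed at
    its optimum (pFBA).  Objective value identical to :func:`solve_fba`'s."""
    if objective_id is None:
        objective_rxns = [r for r in model.reactions if r.objective_coefficient]
        if len(objective_rxns) != 1:
            raise ValidationError("resolve_fluxes needs a single-reaction objective; pass objective_id")
        objective_id = objective_rxns[0].id
    first = solve_fba(model, objective_id, direction)
    if not first.optimal:
        return first
    opt = first.objective_value
    with model:
        rxn = model.reactions.get_by_id(objective_id)
        rxn.bounds = (opt - OPTIMUM_TOLERANCE, opt + OPTIMUM_TOLERANCE)
        add_pfba(model, fraction_of_optimum=1.0)
        solution = model.optimize(raise_error=False)
        if _status(solution.status) != "optimal":
            raise SolverError(f"parsimonious resolution failed with status {solution.status!r}")
        fluxes = solution.fluxes
    return FBAResult("optimal", opt, fluxes, objective_id, direction, parsimonious=True)


def max_theoretical_yield(
    model: cobra.Model,
    product_exchange_id: str,
    condition: Condition | None = None,
    substrate_exchange_ids: tuple[str, ...] | None = None,
) -> FBAResult:
    """Maximize a product exchange with growth optional (biomass lower bound
    untouched, typically 0) and electron uptake free inside the condition's
    bound; the yield is the product flux over the substrate uptake flux."""
    prepared = apply_condition(model, condition) if condition is not None else model
    if product_exchange_id not in prepared.reactions:
        raise ValidationError(f"unknown product exchange {product_exchange_id!r}")
    result = resolve_fluxes(prepared, product_exchange_id, "max")
    if not result.optimal:
        return result
    if substrate_exchange_ids is None and condition is not None:
        substrate_exchange_ids = tuple(condition.substrate_uptakes)
    if substrate_exchange_ids:
        uptake = float(sum(max(0.0, -result.fluxes[rid]) for rid in substrate_exchange_ids))
        result.substrate_uptake = uptake
        result.yield_per_substrate = result.objective_value / uptake if uptake > 0 else float("nan")
    return result


def production_envelope(
    model: cobra.Model,
    product_exchange_id: str,
    biomass_id: str,
    n_points: int = 50,
    condition: Condition | None = None,
) -> Envelope:
    """Min/max product flux over ``n_points`` growth values evenly spaced on
    ``[0, mu_max]`` (the maximum included exactly, never interpolated)."""
    if n_points < 2:
        raise ValidationError("n_points must be >= 2")
    prepared = apply_condition(model, condition) if condition is not None else model
    for rid in (product_exchange_id, biomass_id):
        if rid not in prepared.reactions:
            raise ValidationError(f"unknown reaction {rid!r}")
    base = solve_fba(prepared, biomass_id, "max")
    if not base.optimal:
        raise SolverError(f"base model is {base.status}; cannot sample an envelope")
    mu_max = base.objective_value
    grid = np.linspace(0.0, mu_max, n_points)
    grid[-1] = mu_max

    from .electrosynthesis import DEFAULT_ELECTRON_EXCHANGE_ID

    if condition is not None:
        electron_bound = condition.electron_uptake_max
    elif DEFAULT_ELECTRON_EXCHANGE_ID in prepared.reactions:
        electron_bound = -prepared.reactions.get_by_id(DEFAULT_ELECTRON_EXCHANGE_ID).lower_bound
    else:
        electron_bound = 0.0

    points: list[tuple[float, float, float]] = []
    biomass = prepared.reactions.get_by_id(biomass_id)
    for mu in grid:
        with prepared:
            biomass.bounds = (mu - OPTIMUM_TOLERANCE, mu + OPTIMUM_TOLERANCE)
            lo = solve_fba(prepared, product_exchange_id, "min")
            hi = solve_fba(prepared, product_exchange_id, "max")
        if not (lo.optimal and hi.optimal):
            raise SolverError(f"envelope point at growth {mu:.6g} is infeasible")
        pmin, pmax = lo.objective_value, hi.objective_value
        if pmin > pmax:  # solver jitter at degenerate vertices
            pmin = pmax = 0.5 * (pmin + pmax)
        points.append((float(mu), float(pmin), float(pmax)))
    return Envelope(points, electron_bound, product_exchange_id, biomass_id)


def write_json_report(path: str | Path, payload: dict) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
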