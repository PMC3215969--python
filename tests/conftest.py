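"""Shared fixtures and the brute-force LP oracle used against the engine."""

import itertools
import warnings

import numpy as np
import pytest

warnings.filterwarnings("ignore", category=UserWarning)
warnings.filterwarnings("ignore", category=FutureWarning)
warnings.filterwarnings("ignore", category=DeprecationWarning)

from electrofba.model_io import load_bundled_ecoli  # noqa: E402
from electrofba.electrosynthesis import add_electrode_reactions  # noqa: E402
from electrofba.synthetic_model import ToyConfig, make_toy_model  # noqa: E402

IJO_BIOMASS = "BIOMASS_Ec_iJO1366_core_53p95M"


@pytest.fixture()
def toy_default():
    return make_toy_model(ToyConfig())


@pytest.fixture()
def toy_two_compartment():
    return make_toy_model(ToyConfig(two_compartment=True))


@pytest.fixture(scope="session")
def ijo():
    """Genome-scale E. coli model bundled with cobra, electrode-augmented."""
    model = load_bundled_ecoli("iJO1366")
    model.objective = IJO_BIOMASS
    return add_electrode_reactions(model)


def brute_force_optimum(model, objective_id, direction="max", tol=1e-6):
    """Independent LP oracle: enumerate candidate vertices of the flux
    polytope by activating every subset of ``n - rank(S)`` finite bounds and
    solving the resulting linear system with plain numpy.  No LP solver.

    Only suitable for toy networks (combinatorial in the reaction count).
    """
    rxns = list(model.reactions)
    mets = list(model.metabolites)
    met_index = {m.id: i for i, m in enumerate(mets)}
    n = len(rxns)
    S = np.zeros((len(mets), n))
    for j, rxn in enumerate(rxns):
        for met, coef in rxn.metabolites.items():
            S[met_index[met.id], j] = coef
    lb = np.array([r.lower_bound for r in rxns])
    ub = np.array([r.upper_bound for r in rxns])
    obj = next(j for j, r in enumerate(rxns) if r.id == objective_id)

    rank = np.linalg.matrix_rank(S)
    deficit = n - rank
    candidates = []
    for j in range(n):
        candidates.append((j, lb[j]))
        if ub[j] != lb[j]:
            candidates.append((j, ub[j]))

    best = None
    sign = 1.0 if direction == "max" else -1.0
    for subset in itertools.combinations(candidates, deficit):
        js = [j for j, _ in subset]
        if len(set(js)) < deficit:
            continue
        rows = np.zeros((deficit, n))
        rhs = np.zeros(deficit)
        for i, (j, val) in enumerate(subset):
            rows[i, j] = 1.0
            rhs[i] = val
        A = np.vstack([S, rows])
        b = np.concatenate([np.zeros(len(mets)), rhs])
        v, _, rk, _ = np.linalg.lstsq(A, b, rcond=None)
        if rk < n:
            continue
        if np.max(np.abs(A @ v - b)) > tol:
            continue
        if np.any(v < lb - tol) or np.any(v > ub + tol):
            continue
        value = sign * v[obj]
        if best is None or value > best:
            best = value
    return None if best is None else sign * best
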