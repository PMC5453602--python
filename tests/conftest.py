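"""Shared fixtures and independent oracles for the test suite.

The LP oracles here are deliberately independent of the package's solver
path: ``cobra_optimum``/``cobra_fva_range`` rebuild the model in cobrapy
(GLPK backend), and ``vertex_optimum`` enumerates basic feasible points of
tiny models directly from the constraint system.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from scipy import sparse

from regflux.model_io import StoichiometricModel
from regflux.synth import make_ground_truth


def build_model(reactions, objective):
    """Compact model builder: ``reactions`` is a list of
    (id, {met: coef}, lb, ub, gpr, exchange) tuples."""
    mets: dict[str, int] = {}
    for _, stoich, *_ in reactions:
        for met in stoich:
            mets.setdefault(met, len(mets))
    rows, cols, vals = [], [], []
    for j, (_, stoich, *_) in enumerate(reactions):
        for met, coef in stoich.items():
            rows.append(mets[met])
            cols.append(j)
            vals.append(float(coef))
    return StoichiometricModel(
        metabolite_ids=list(mets),
        reaction_ids=[r[0] for r in reactions],
        stoichiometry=sparse.csr_matrix(
            (vals, (rows, cols)), shape=(len(mets), len(reactions))
        ),
        lower_bound=np.array([r[2] for r in reactions], dtype=float),
        upper_bound=np.array([r[3] for r in reactions], dtype=float),
        gpr=[r[4] for r in reactions],
        objective_reaction=objective,
        exchange_flags=np.array([r[5] for r in reactions], dtype=bool),
    )


def linear_model(cap: float = 5.0) -> StoichiometricModel:
    """EX_in (ub 10) -> A; A -> B (ub ``cap``, gene g1); B -> biomass."""
    return build_model(
        [
            ("EX_in", {"A": 1.0}, 0.0, 10.0, "", True),
            ("AtoB", {"A": -1.0, "B": 1.0}, 0.0, cap, "g1", False),
            ("BIOMASS", {"B": -1.0}, 0.0, 1000.0, "", False),
        ],
        "BIOMASS",
    )


def branched_model() -> StoichiometricModel:
    """Intake ub 10 feeding two routes (ub 3 and ub 4) that converge on
    biomass: optimum 7."""
    return build_model(
        [
            ("EX_in", {"A": 1.0}, 0.0, 10.0, "", True),
            ("R1", {"A": -1.0, "B": 1.0}, 0.0, 3.0, "g1", False),
            ("R2", {"A": -1.0, "B": 1.0}, 0.0, 4.0, "g2", False),
            ("BIOMASS", {"B": -1.0}, 0.0, 1000.0, "", False),
        ],
        "BIOMASS",
    )


def isozyme_model(cap: float = 6.0) -> StoichiometricModel:
    """Single conversion gated by an isozyme pair (g1 or g2)."""
    return build_model(
        [
            ("EX_in", {"A": 1.0}, 0.0, 10.0, "", True),
            ("ISO", {"A": -1.0, "B": 1.0}, 0.0, cap, "g1 or g2", False),
            ("BIOMASS", {"B": -1.0}, 0.0, 1000.0, "", False),
        ],
        "BIOMASS",
    )


@pytest.fixture
def linear():
    return linear_model()


@pytest.fixture
def branched():
    return branched_model()


@pytest.fixture
def isozyme():
    return isozyme_model()


@pytest.fixture(scope="session")
def default_truth():
    """One default synthetic study shared across tests (seed 11)."""
    return make_ground_truth(seed=11)


# ---------------------------------------------------------------------------
# Independent LP oracles
# ---------------------------------------------------------------------------

def to_cobra(model: StoichiometricModel):
    import cobra

    cm = cobra.Model("oracle")
    cmets = {m: cobra.Metabolite(m) for m in model.metabolite_ids}
    reactions = []
    coo = model.stoichiometry.tocoo()
    per_rxn: list[dict] = [{} for _ in model.reaction_ids]
    for i, j, v in zip(coo.row, coo.col, coo.data):
        per_rxn[int(j)][cmets[model.metabolite_ids[int(i)]]] = float(v)
    for j, rid in enumerate(model.reaction_ids):
        rxn = cobra.Reaction(rid)
        rxn.lower_bound = float(model.lower_bound[j])
        rxn.upper_bound = float(model.upper_bound[j])
        rxn.add_metabolites(per_rxn[j])
        reactions.append(rxn)
    cm.add_reactions(reactions)
    cm.objective = model.objective_reaction
    return cm


def cobra_optimum(model: StoichiometricModel) -> float:
    """FBA optimum via cobrapy/GLPK (independent of the package solver)."""
    return float(to_cobra(model).slim_optimize())


def cobra_fva_range(model: StoichiometricModel, reaction_id: str, fraction: float):
    from cobra.flux_analysis import flux_variability_analysis

    cm = to_cobra(model)
    out = flux_variability_analysis(
        cm, [cm.reactions.get_by_id(reaction_id)], fraction_of_optimum=fraction
    )
    return float(out["minimum"].iloc[0]), float(out["maximum"].iloc[0])


def vertex_optimum(model: StoichiometricModel, tol: float = 1e-9) -> float:
    """Brute-force LP oracle for tiny models: enumerate candidate vertices
    of {S v = 0, lb <= v <= ub} by fixing free dimensions at bounds and
    solving the equality system; return the best feasible objective."""
    S = model.stoichiometry.toarray()
    n = S.shape[1]
    rank = np.linalg.matrix_rank(S)
    d = n - rank  # dimension of the feasible polytope
    lb, ub = model.lower_bound, model.upper_bound
    j_obj = model.reaction_ids.index(model.objective_reaction)
    best = -np.inf
    for fixed in itertools.combinations(range(n), d):
        free = [j for j in range(n) if j not in fixed]
        for bounds_choice in itertools.product(*[(lb[j], ub[j]) for j in fixed]):
            rhs = -S[:, fixed] @ np.array(bounds_choice)
            sol, *_ = np.linalg.lstsq(S[:, free], rhs, rcond=None)
            v = np.zeros(n)
            v[list(fixed)] = bounds_choice
            v[free] = sol
            if (
                np.all(np.abs(S @ v) < 1e-7)
                and np.all(v >= lb - 1e-7)
                and np.all(v <= ub + 1e-7)
            ):
                best = max(best, v[j_obj])
    return best
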