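"""Flux balance analysis, flux variability analysis, and GPR-aware gene
deletion on :class:`~regflux.model_io.StoichiometricModel`.

FBA maximises flux through the biomass objective subject to steady-state
mass balance S.v = 0 and the per-reaction bounds; FVA reports the attainable
flux range of every reaction while the objective is held at a required
fraction of its optimum. LPs are solved with scipy's HiGHS backend.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from .model_io import ParseError, StoichiometricModel, ValidationError

#: primal feasibility tolerance handed to the LP solver
SOLVER_TOL = 1e-9
#: tolerance at which solutions are asserted to satisfy S.v = 0 and bounds
ASSERT_TOL = 1e-6


# ---------------------------------------------------------------------------
# GPR rule parsing and evaluation
# ---------------------------------------------------------------------------

class GPRParseError(ParseError):
    """A gene-protein-reaction rule could not be parsed."""


def _tokenize(rule: str) -> list[str]:
    tokens: list[str] = []
    i, n = 0, len(rule)
    while i < n:
        ch = rule[i]
        if ch.isspace():
            i += 1
        elif ch in "()":
            tokens.append(ch)
            i += 1
        else:
            j = i
            while j < n and not rule[j].isspace() and rule[j] not in "()":
                j += 1
            tokens.append(rule[i:j])
            i = j
    return tokens


@functools.lru_cache(maxsize=4096)
def parse_gpr(rule: str):
    """Parse a GPR rule into an AST of nested tuples.

    Grammar: ``expr := term ('or' term)* ; term := atom ('and' atom)* ;
    atom := gene | '(' expr ')'``. Keywords are case-insensitive. Returns
    ``None`` for an empty rule, otherwise nested
    ``('or'|'and', (children...))`` / ``('gene', name)`` tuples.
    """
    if not rule or not rule.strip():
        return None
    tokens = _tokenize(rule)
    pos = 0

    def peek() -> str | None:
        return tokens[pos] if pos < len(tokens) else None

    def take() -> str:
        nonlocal pos
        tok = tokens[pos]
        pos += 1
        return tok

    def parse_expr():
        terms = [parse_term()]
        while peek() is not None and peek().lower() == "or":
            take()
            terms.append(parse_term())
        return terms[0] if len(terms) == 1 else ("or", tuple(terms))

    def parse_term():
        atoms = [parse_atom()]
        while peek() is not None and peek().lower() == "and":
            take()
            atoms.append(parse_atom())
        return atoms[0] if len(atoms) == 1 else ("and", tuple(atoms))

    def parse_atom():
        tok = peek()
        if tok is None:
            raise GPRParseError(f"unexpected end of GPR rule {rule!r}")
        if tok == "(":
            take()
            node = parse_expr()
            if peek() != ")":
                raise GPRParseError(f"unbalanced parentheses in GPR rule {rule!r}")
            take()
            return node
        if tok == ")" or tok.lower() in ("and", "or"):
            raise GPRParseError(f"unexpected token {tok!r} in GPR rule {rule!r}")
        return ("gene", take())

    tree = parse_expr()
    if pos != len(tokens):
        raise GPRParseError(f"trailing tokens in GPR rule {rule!r}")
    return tree


def gpr_value(
    rule: str,
    gene_values: Mapping[str, float],
    *,
    missing: float | None = 1.0,
    and_op: Callable = min,
    or_op: Callable = max,
) -> float:
    """Evaluate a GPR rule over per-gene values with AND->min, OR->max.

    ``missing`` is the value used for genes absent from ``gene_values``;
    pass ``missing=None`` to make absent genes an error. An empty rule
    evaluates to 1 (the reaction is not gene-associated).
    """
    tree = parse_gpr(rule)
    if tree is None:
        return 1.0

    def ev(node):
        kind = node[0]
        if kind == "gene":
            gene = node[1]
            if gene in gene_values:
                return gene_values[gene]
            if missing is None:
                raise KeyError(f"gene {gene!r} in rule {rule!r} has no assigned value")
            return missing
        op = and_op if kind == "and" else or_op
        return op(ev(child) for child in node[1])

    return ev(tree)


def evaluate_gpr(rule: str, gene_states: Mapping[str, int]) -> int:
    """Boolean GPR evaluation: 1 if the reaction retains enzyme function.

    Every gene in the rule must be present in ``gene_states``; an empty rule
    returns 1 (no gene association).
    """
    value = gpr_value(rule, gene_states, missing=None)
    return 1 if value > 0 else 0


# ---------------------------------------------------------------------------
# FBA
# ---------------------------------------------------------------------------

@dataclass
class FluxResult:
    status: str  # optimal | infeasible | unbounded
    objective_value: float
    fluxes: np.ndarray | None

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


_LP_STATUS = {0: "optimal", 2: "infeasible", 3: "unbounded"}


def _solve_lp(c, A_ub, b_ub, A_eq, b_eq, bounds) -> tuple[str, float, np.ndarray | None]:
    res = linprog(
        c,
        A_ub=A_ub,
        b_ub=b_ub,
        A_eq=A_eq,
        b_eq=b_eq,
        bounds=bounds,
        method="highs",
        options={"primal_feasibility_tolerance": SOLVER_TOL},
    )
    status = _LP_STATUS.get(res.status, "infeasible")
    if status != "optimal":
        return status, float("nan"), None
    return status, float(res.fun), np.asarray(res.x)


def fba_optimize(model: StoichiometricModel) -> FluxResult:
    """Maximise the objective reaction flux subject to S.v = 0 and bounds."""
    n = len(model.reaction_ids)
    c = np.zeros(n)
    c[model.reaction_index(model.objective_reaction)] = -1.0
    bounds = list(zip(model.lower_bound, model.upper_bound))
    status, fun, x = _solve_lp(
        c, None, None, model.stoichiometry, np.zeros(len(model.metabolite_ids)), bounds
    )
    if status != "optimal":
        return FluxResult(status=status, objective_value=float("nan"), fluxes=None)
    return FluxResult(status="optimal", objective_value=-fun, fluxes=x)


# ---------------------------------------------------------------------------
# FVA
# ---------------------------------------------------------------------------

@dataclass
class FVAResult:
    reaction_ids: list[str]
    minimum: np.ndarray
    maximum: np.ndarray
    fraction_of_optimum: float

    def range_of(self, reaction_id: str) -> tuple[float, float]:
        j = self.reaction_ids.index(reaction_id)
        return float(self.minimum[j]), float(self.maximum[j])


class InfeasibleModelError(RuntimeError):
    def __init__(self, status: str):
        super().__init__(f"FBA on the input model returned status {status!r}")
        self.status = status


def fva(model: StoichiometricModel, fraction_of_optimum: float = 0.0) -> FVAResult:
    """Per-reaction attainable flux range at a required objective fraction.

    ``fraction_of_optimum=0`` gives the attainable range under stoichiometry
    and bounds alone, the effective capacity of each reaction within the
    network; ``1`` restricts to the optimal face.
    """
    if not 0.0 <= fraction_of_optimum <= 1.0:
        raise ValidationError("fraction_of_optimum must lie in [0,1]")
    n = len(model.reaction_ids)
    lb = model.lower_bound.copy()
    ub = model.upper_bound.copy()
    if fraction_of_optimum > 0.0:
        wt = fba_optimize(model)
        if not wt.optimal:
            raise InfeasibleModelError(wt.status)
        j_obj = model.reaction_index(model.objective_reaction)
        # small slack keeps the pinned problem numerically feasible
        lb[j_obj] = max(lb[j_obj], fraction_of_optimum * wt.objective_value - 1e-9)
        if lb[j_obj] > ub[j_obj]:
            lb[j_obj] = ub[j_obj]
    bounds = list(zip(lb, ub))
    A_eq = model.stoichiometry
    b_eq = np.zeros(len(model.metabolite_ids))
    vmin = np.empty(n)
    vmax = np.empty(n)
    for j in range(n):
        c = np.zeros(n)
        c[j] = 1.0
        status, fun, _ = _solve_lp(c, None, None, A_eq, b_eq, bounds)
        if status != "optimal":
            raise InfeasibleModelError(status)
        vmin[j] = fun
        c[j] = -1.0
        status, fun, _ = _solve_lp(c, None, None, A_eq, b_eq, bounds)
        if status != "optimal":
            raise InfeasibleModelError(status)
        vmax[j] = -fun
    # clip solver jitter back into the declared bounds
    vmin = np.clip(vmin, model.lower_bound, model.upper_bound)
    vmax = np.clip(vmax, model.lower_bound, model.upper_bound)
    vmin, vmax = np.minimum(vmin, vmax), np.maximum(vmin, vmax)
    return FVAResult(
        reaction_ids=list(model.reaction_ids),
        minimum=vmin,
        maximum=vmax,
        fraction_of_optimum=fraction_of_optimum,
    )


# ---------------------------------------------------------------------------
# Gene deletion
# ---------------------------------------------------------------------------

def delete_genes(model: StoichiometricModel, genes) -> StoichiometricModel:
    """Copy of the model with every reaction whose GPR evaluates to 0 under
    the deletion closed (lb = ub = 0)."""
    genes = set(genes)
    unknown = genes - set(model.genes)
    if unknown:
        raise KeyError(f"genes not in model: {sorted(unknown)}")
    out = model.copy()
    if not genes:
        return out
    for j, rule in enumerate(model.gpr):
        if not rule:
            continue
        states = {g: (0 if g in genes else 1) for g in model.genes}
        if evaluate_gpr(rule, states) == 0:
            out.lower_bound[j] = 0.0
            out.upper_bound[j] = 0.0
    return out
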