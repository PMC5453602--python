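"""Probability-scaled flux constraints and TF-knockout growth prediction.

Three model variants share one mechanism: when a TF is knocked out, every
target gene keeps a retention probability Prob(gene ON | TF OFF) in [0,1],
probabilities propagate through GPR rules (AND -> min, OR -> max) onto
reactions, and each affected reaction's bound is scaled to Vmax*Prob, where
Vmax is the reaction's effective capacity from flux variability analysis.

Variants differ only in where the gene probability comes from:

* ``PROM``          - conditional probability P(ON|OFF) for every edge;
* ``IDREAM``        - bootstrap FDR for direct activator edges, 1-FDR for
                      direct repressor edges, indirect edges unconstrained;
* ``IDREAM_hybrid`` - direct edges as IDREAM, indirect edges as PROM.

Knockout growth is computed either with the scaled bounds enforced exactly
("hard") or as soft constraints whose violation is charged to the objective
at a rate kappa per flux unit ("soft", the PROM lineage default).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .fba import FluxResult, FVAResult, _solve_lp, fba_optimize, fva, gpr_value
from .model_io import (
    ConfigurationError,
    InfluenceNetwork,
    RegulatoryEdge,
    StoichiometricModel,
    ValidationError,
)

VARIANTS = ("PROM", "IDREAM", "IDREAM_hybrid")

DEFAULT_MODE = "soft"
DEFAULT_KAPPA = 1.0
DEFAULT_FVA_FRACTION = 0.0


def gene_probability(edge: RegulatoryEdge, variant: str) -> float:
    """Retention probability Prob(gene ON | TF OFF) for one edge.

    IDREAM: direct activator -> FDR, direct repressor -> 1-FDR, indirect
    -> 1 (no effect of the knockout on flux constraints). IDREAM_hybrid:
    direct as IDREAM, indirect -> PROM conditional probability. PROM: the
    conditional probability for every edge.
    """
    if variant not in VARIANTS:
        raise ConfigurationError(f"unknown variant {variant!r}")
    if variant == "PROM":
        if edge.prom_prob is None:
            raise ConfigurationError(
                f"edge {edge.tf}->{edge.target}: prom_prob required for PROM"
            )
        return edge.prom_prob
    if edge.evidence == "direct":
        if edge.fdr is None:
            raise ConfigurationError(
                f"edge {edge.tf}->{edge.target}: fdr required for a direct edge "
                f"under {variant}"
            )
        if edge.sign == "repressor":
            return 1.0 - edge.fdr
        return edge.fdr
    # indirect edge
    if variant == "IDREAM":
        return 1.0
    if edge.prom_prob is None:
        raise ConfigurationError(
            f"edge {edge.tf}->{edge.target}: prom_prob required for an indirect "
            "edge under IDREAM_hybrid"
        )
    return edge.prom_prob


def map_gene_probs_to_reactions(
    model: StoichiometricModel, gene_probs: Mapping[str, float]
) -> dict[str, float]:
    """Propagate per-gene retention probabilities onto reactions through the
    GPR rules: AND -> min, OR -> max, genes without a probability -> 1,
    reactions without a rule -> 1."""
    for g, p in gene_probs.items():
        if not 0.0 <= p <= 1.0:
            raise ValidationError(f"gene probability {g}={p} outside [0,1]")
    out = {}
    for rid, rule in zip(model.reaction_ids, model.gpr):
        out[rid] = float(gpr_value(rule, gene_probs)) if rule else 1.0
    return out


@dataclass
class ConstraintMap:
    """Per-TF retention probabilities on genes and (via GPR) on reactions."""

    variant: str
    gene_probs: dict[str, dict[str, float]]
    reaction_probs: dict[str, dict[str, float]]
    vmax_source: FVAResult

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ConfigurationError(f"unknown variant {self.variant!r}")
        known = set(self.vmax_source.reaction_ids)
        for tf, rmap in self.reaction_probs.items():
            for rid, p in rmap.items():
                if rid not in known:
                    raise ValidationError(f"constraint on unknown reaction {rid!r}")
                if not 0.0 <= p <= 1.0:
                    raise ValidationError(
                        f"probability {p} for {tf}/{rid} outside [0,1]"
                    )

    @property
    def tf_ids(self) -> list[str]:
        return list(self.reaction_probs)


def build_constraint_map(
    model: StoichiometricModel,
    network: InfluenceNetwork,
    variant: str,
    fva_fraction: float = DEFAULT_FVA_FRACTION,
    vmax_source: FVAResult | None = None,
) -> ConstraintMap:
    """Assemble the per-TF constraint map for one model variant.

    ``vmax_source`` lets callers reuse a precomputed FVA; otherwise FVA runs
    once at ``fva_fraction`` of the optimum.
    """
    if vmax_source is None:
        vmax_source = fva(model, fraction_of_optimum=fva_fraction)
    gene_probs: dict[str, dict[str, float]] = {}
    reaction_probs: dict[str, dict[str, float]] = {}
    for tf in network.tf_ids:
        gp = {
            e.target: gene_probability(e, variant) for e in network.edges_for_tf(tf)
        }
        gene_probs[tf] = gp
        rp = map_gene_probs_to_reactions(model, gp)
        reaction_probs[tf] = {rid: p for rid, p in rp.items() if p < 1.0}
    return ConstraintMap(
        variant=variant,
        gene_probs=gene_probs,
        reaction_probs=reaction_probs,
        vmax_source=vmax_source,
    )


@dataclass
class GrowthPrediction:
    tf: str
    growth: float
    wt_growth: float
    ratio: float
    infeasible: bool = False
    error: str | None = None


def _scaled_bounds(
    model: StoichiometricModel,
    rxn_probs: Mapping[str, float],
    fva_res: FVAResult,
) -> tuple[np.ndarray, np.ndarray, list[int]]:
    """Bounds with each affected reaction scaled to Vmax*Prob.

    Forward capacity vmax > 0 scales to prob*vmax; a reversible reaction's
    backward capacity vmin < 0 scales symmetrically to prob*vmin. Bounds
    only ever tighten toward zero (a dead reaction is never resurrected).
    """
    lb = model.lower_bound.copy()
    ub = model.upper_bound.copy()
    affected: list[int] = []
    fva_index = {rid: j for j, rid in enumerate(fva_res.reaction_ids)}
    for rid, prob in rxn_probs.items():
        j = model.reaction_index(rid)
        k = fva_index[rid]
        vmax = fva_res.maximum[k]
        vmin = fva_res.minimum[k]
        if vmax >= 0.0:
            ub[j] = min(ub[j], prob * vmax)
        if vmin <= 0.0:
            lb[j] = max(lb[j], prob * vmin)
        affected.append(j)
    return lb, ub, affected


def _soft_constrained_growth(
    model: StoichiometricModel,
    lb_soft: np.ndarray,
    ub_soft: np.ndarray,
    affected: list[int],
    kappa: float,
) -> FluxResult:
    """Maximise biomass minus kappa times the total violation of the soft
    bounds; hard bounds stay at the model's own lb/ub."""
    n = len(model.reaction_ids)
    k = len(affected)
    j_obj = model.reaction_index(model.objective_reaction)
    # variables: [v (n), s_ub (k), s_lb (k)] with s >= 0
    c = np.zeros(n + 2 * k)
    c[j_obj] = -1.0
    c[n:] = kappa
    S = model.stoichiometry
    A_eq = np.zeros((S.shape[0], n + 2 * k))
    A_eq[:, :n] = S.toarray()
    b_eq = np.zeros(S.shape[0])
    A_ub = np.zeros((2 * k, n + 2 * k))
    b_ub = np.zeros(2 * k)
    for i, j in enumerate(affected):
        A_ub[i, j] = 1.0          # v_j - s_ub_i <= ub_soft_j
        A_ub[i, n + i] = -1.0
        b_ub[i] = ub_soft[j]
        A_ub[k + i, j] = -1.0     # -v_j - s_lb_i <= -lb_soft_j
        A_ub[k + i, n + k + i] = -1.0
        b_ub[k + i] = -lb_soft[j]
    bounds = list(zip(model.lower_bound, model.upper_bound)) + [(0, None)] * (2 * k)
    status, fun, x = _solve_lp(c, A_ub, b_ub, A_eq, b_eq, bounds)
    if status != "optimal":
        return FluxResult(status=status, objective_value=float("nan"), fluxes=None)
    return FluxResult(
        status="optimal", objective_value=float(x[j_obj]), fluxes=x[:n]
    )


def growth_with_reaction_probs(
    model: StoichiometricModel,
    rxn_probs: Mapping[str, float],
    vmax_source: FVAResult,
    mode: str = DEFAULT_MODE,
    kappa: float = DEFAULT_KAPPA,
) -> FluxResult:
    """Growth under explicit per-reaction retention probabilities.

    This is the shared core of single-knockout prediction and the
    double-perturbation scan (which recomputes reaction probabilities with
    the deleted gene forced to 0 so the TF constraint and the deletion
    compose through the GPRs).
    """
    if mode not in ("hard", "soft"):
        raise ConfigurationError(f"unknown mode {mode!r}")
    lb, ub, affected = _scaled_bounds(model, rxn_probs, vmax_source)
    if not affected:
        return fba_optimize(model)
    if mode == "hard":
        if np.any(lb > ub + 1e-12):
            # a scaled bound fell below a hard flux floor: no feasible flux state
            return FluxResult(status="infeasible", objective_value=float("nan"), fluxes=None)
        lb = np.minimum(lb, ub)  # tolerance-level crossings only
        mutant = model.copy()
        mutant.lower_bound = lb
        mutant.upper_bound = ub
        return fba_optimize(mutant)
    return _soft_constrained_growth(model, lb, ub, affected, kappa)


def constrained_growth(
    model: StoichiometricModel,
    constraints: ConstraintMap,
    tf: str,
    mode: str = DEFAULT_MODE,
    kappa: float = DEFAULT_KAPPA,
) -> FluxResult:
    """Growth of the model under one TF's probability constraints."""
    return growth_with_reaction_probs(
        model,
        constraints.reaction_probs.get(tf, {}),
        constraints.vmax_source,
        mode=mode,
        kappa=kappa,
    )


def tf_knockout_growth(
    model: StoichiometricModel,
    constraints: ConstraintMap,
    tf: str,
    mode: str = DEFAULT_MODE,
    kappa: float = DEFAULT_KAPPA,
    wt: FluxResult | None = None,
) -> GrowthPrediction:
    """Predicted mutant/wild-type growth ratio for one TF knockout.

    A TF without constraints predicts ratio 1. An infeasible hard-mode
    mutant LP reports growth 0 with the ``infeasible`` flag set.
    """
    if wt is None:
        wt = fba_optimize(model)
    if not wt.optimal:
        raise ConfigurationError(f"wild-type FBA is {wt.status}, cannot form ratios")
    wt_growth = wt.objective_value
    result = constrained_growth(model, constraints, tf, mode=mode, kappa=kappa)
    if not result.optimal:
        return GrowthPrediction(
            tf=tf, growth=0.0, wt_growth=wt_growth,
            ratio=0.0 if wt_growth > 0 else float("nan"),
            infeasible=True,
        )
    growth = max(result.objective_value, 0.0) + 0.0  # normalise -0.0
    ratio = growth / wt_growth + 0.0 if wt_growth > 0 else float("nan")
    return GrowthPrediction(tf=tf, growth=growth, wt_growth=wt_growth, ratio=ratio)


def predict_all_tfs(
    model: StoichiometricModel,
    constraints: ConstraintMap,
    tf_list: Iterable[str],
    mode: str = DEFAULT_MODE,
    kappa: float = DEFAULT_KAPPA,
) -> list[GrowthPrediction]:
    """Batch knockout prediction; the wild type is solved once, per-TF
    failures are recorded on the prediction rather than raised."""
    wt = fba_optimize(model)
    out: list[GrowthPrediction] = []
    for tf in tf_list:
        try:
            out.append(
                tf_knockout_growth(model, constraints, tf, mode=mode, kappa=kappa, wt=wt)
            )
        except Exception as exc:
            out.append(
                GrowthPrediction(
                    tf=tf, growth=float("nan"), wt_growth=wt.objective_value,
                    ratio=float("nan"), error=str(exc),
                )
            )
    return out
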