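"""Double-perturbation scanning for synthetic (aggravating) interactions.

A TF knockout (probability-scaled flux bounds) is combined with a hard
metabolic gene deletion, and the interaction is scored by the variation
statistic::

    Diff1 = g_tf   - g_double      (TF single minus double)
    Diff2 = g_gene - g_double      (gene single minus double)
    variation = ((Diff1 + Diff2) / 2) / g_wt

A synthetic-lethal/sick pair shows variation above a high threshold
(default > 0.9) while both single perturbations retain most of wild-type
growth (default >= 0.95).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .fba import delete_genes, fba_optimize
from .integration import (
    ConstraintMap,
    DEFAULT_KAPPA,
    DEFAULT_MODE,
    growth_with_reaction_probs,
    map_gene_probs_to_reactions,
    tf_knockout_growth,
)
from .model_io import StoichiometricModel, ValidationError

log = logging.getLogger(__name__)

DEFAULT_VARIATION_THRESHOLD = 0.9
DEFAULT_SINGLE_RETENTION = 0.95


@dataclass
class InteractionScore:
    tf: str
    gene: str
    g_wt: float
    g_tf: float
    g_gene: float
    g_double: float

    @property
    def diff1(self) -> float:
        return self.g_tf - self.g_double

    @property
    def diff2(self) -> float:
        return self.g_gene - self.g_double

    @property
    def variation(self) -> float:
        return interaction_variation(self.g_wt, self.g_tf, self.g_gene, self.g_double)


def interaction_variation(
    g_wt: float, g_tf: float, g_gene: float, g_double: float
) -> float:
    """Mean of Diff1 and Diff2 over the wild-type growth rate."""
    if not g_wt > 0:
        raise ValidationError(f"wild-type growth must be positive, got {g_wt}")
    diff1 = g_tf - g_double
    diff2 = g_gene - g_double
    return ((diff1 + diff2) / 2.0) / g_wt


def double_deletion_growth(
    model: StoichiometricModel,
    constraints: ConstraintMap,
    tf: str,
    gene: str,
    mode: str = DEFAULT_MODE,
    kappa: float = DEFAULT_KAPPA,
) -> float:
    """Growth with the TF's probability constraints applied on top of a hard
    deletion of one metabolic gene. Infeasible -> 0.

    The deleted gene's retention probability is forced to 0 before GPR
    propagation, so a TF constraint on an isozyme becomes binding once its
    OR-partner is deleted (constraints and deletions compose).
    """
    gene_probs = dict(constraints.gene_probs.get(tf, {}))
    gene_probs[gene] = 0.0
    rxn_probs = {
        rid: p
        for rid, p in map_gene_probs_to_reactions(model, gene_probs).items()
        if p < 1.0
    }
    deleted = delete_genes(model, {gene})
    result = growth_with_reaction_probs(
        deleted, rxn_probs, constraints.vmax_source, mode=mode, kappa=kappa
    )
    if not result.optimal:
        return 0.0
    return max(result.objective_value, 0.0) + 0.0


def scan_synthetic_pairs(
    model: StoichiometricModel,
    constraints: ConstraintMap,
    tf_list: Sequence[str],
    gene_list: Sequence[str],
    variation_threshold: float = DEFAULT_VARIATION_THRESHOLD,
    single_retention: float = DEFAULT_SINGLE_RETENTION,
    mode: str = DEFAULT_MODE,
    kappa: float = DEFAULT_KAPPA,
    return_matrix: bool = False,
):
    """Scan all TF x gene pairs for synthetic interactions.

    Returns the pairs with ``variation > variation_threshold`` whose single
    perturbations both retain at least ``single_retention`` of wild-type
    growth, sorted by variation (descending). With ``return_matrix=True``
    also returns the full list of scores for every scanned pair.
    """
    if not tf_list or not gene_list:
        raise ValidationError("tf_list and gene_list must be nonempty")
    wt = fba_optimize(model)
    if not wt.optimal or not wt.objective_value > 0:
        raise ValidationError("wild-type model must grow to scan for interactions")
    g_wt = wt.objective_value

    g_tf: dict[str, float] = {}
    for tf in tf_list:
        pred = tf_knockout_growth(model, constraints, tf, mode=mode, kappa=kappa, wt=wt)
        g_tf[tf] = pred.growth
    g_gene: dict[str, float] = {}
    for gene in gene_list:
        res = fba_optimize(delete_genes(model, {gene}))
        g_gene[gene] = max(res.objective_value, 0.0) + 0.0 if res.optimal else 0.0

    matrix: list[InteractionScore] = []
    for tf in tf_list:
        for gene in gene_list:
            try:
                g_double = double_deletion_growth(
                    model, constraints, tf, gene, mode=mode, kappa=kappa
                )
            except Exception as exc:
                log.warning("pair (%s, %s) skipped: %s", tf, gene, exc)
                continue
            matrix.append(
                InteractionScore(
                    tf=tf, gene=gene, g_wt=g_wt, g_tf=g_tf[tf],
                    g_gene=g_gene[gene], g_double=g_double,
                )
            )
    hits = [
        s
        for s in matrix
        if s.variation > variation_threshold
        and s.g_tf / g_wt >= single_retention
        and s.g_gene / g_wt >= single_retention
    ]
    hits.sort(key=lambda s: (-s.variation, s.tf, s.gene))
    if return_matrix:
        return hits, matrix
    return hits


def control_pairs(
    matrix: Iterable[InteractionScore],
    n: int = 8,
    max_variation: float = 0.1,
    seed: int | None = None,
) -> list[InteractionScore]:
    """Seeded uniform draw of non-interacting control pairs (variation below
    ``max_variation``) for benchmarking against predicted hits."""
    pool = [s for s in matrix if s.variation < max_variation]
    rng = np.random.default_rng(seed)
    if len(pool) <= n:
        return pool
    idx = rng.choice(len(pool), size=n, replace=False)
    return [pool[i] for i in sorted(idx)]
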