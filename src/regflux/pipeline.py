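"""End-to-end wiring: inference -> probabilities -> constraints ->
knockout predictions -> evaluation, on a synthetic ground-truth study.

This is the glue the command-line interface and the evaluation harness
share; every step is an ordinary call into the component modules.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import inference, prom, stats
from .integration import (
    ConstraintMap,
    DEFAULT_FVA_FRACTION,
    DEFAULT_KAPPA,
    build_constraint_map,
    predict_all_tfs,
)
from .model_io import ExpressionMatrix, InfluenceNetwork
from .synth import GroundTruth

#: constraint mode used for pipeline growth predictions; hard "Vmax*Prob"
#: bounds keep toy-model predictions free of penalty/gain degeneracies
PIPELINE_MODE = "hard"


@dataclass
class PipelineResult:
    variant: str
    network: InfluenceNetwork
    constraints: ConstraintMap
    tf_ids: list[str]
    pred_ratios: np.ndarray
    true_ratios: np.ndarray

    @property
    def pcc(self) -> float:
        return stats.pearson_with_pvalue(self.pred_ratios, self.true_ratios)[0]

    def auc(self, threshold: float = 0.5) -> float:
        labels = stats.binarize_growth_calls(self.true_ratios, threshold)
        return stats.roc_auc(-self.pred_ratios, labels)

    def mcc(self, threshold: float = 0.5) -> float:
        return stats.mcc_from_calls(
            stats.binarize_growth_calls(self.pred_ratios, threshold),
            stats.binarize_growth_calls(self.true_ratios, threshold),
        )


def annotate_evidence_from_truth(
    inferred: InfluenceNetwork, truth: InfluenceNetwork
) -> InfluenceNetwork:
    """Copy the planted evidence class onto recovered edges (an inferred
    edge that was not planted stays "indirect")."""

    def fix(e):
        planted = truth.get(e.tf, e.target)
        return replace(e, evidence=planted.evidence) if planted is not None else e

    return inferred.map_edges(fix)


def infer_annotated_network(
    truth: GroundTruth,
    n_subsets: int = 50,
    seed: int | None = None,
    fdr_cutoff: float = inference.DEFAULT_FDR_CUTOFF,
    subset_fraction: float = inference.DEFAULT_SUBSET_FRACTION,
    binarize_quantile: float = prom.DEFAULT_BINARIZE_QUANTILE,
) -> InfluenceNetwork:
    """Bootstrap-infer the influence network from the study's expression,
    annotate evidence from the planted network, and attach PROM conditional
    probabilities to every edge."""
    tfs = truth.tf_ids
    targets = [g for g in truth.expression.gene_ids if g not in set(tfs)]
    net = inference.infer_network(
        truth.expression,
        tfs,
        targets,
        n_subsets=n_subsets,
        fdr_cutoff=fdr_cutoff,
        seed=seed,
        subset_fraction=subset_fraction,
    )
    net = annotate_evidence_from_truth(net, truth.network)
    binary = prom.binarize_expression(truth.expression, binarize_quantile)
    return prom.annotate_prom_probabilities(net, binary)


def predict_from_network(
    truth: GroundTruth,
    network: InfluenceNetwork,
    variant: str,
    mode: str = PIPELINE_MODE,
    kappa: float = DEFAULT_KAPPA,
    fva_fraction: float = DEFAULT_FVA_FRACTION,
    constraints: ConstraintMap | None = None,
) -> PipelineResult:
    """Constraint construction and knockout prediction for one variant."""
    if constraints is None:
        constraints = build_constraint_map(
            truth.model, network, variant, fva_fraction=fva_fraction
        )
    tf_ids = truth.tf_ids
    preds = predict_all_tfs(truth.model, constraints, tf_ids, mode=mode, kappa=kappa)
    pred_ratios = np.array([p.ratio for p in preds])
    true_ratios = np.array([truth.true_growth_ratios[tf] for tf in tf_ids])
    return PipelineResult(
        variant=variant,
        network=network,
        constraints=constraints,
        tf_ids=tf_ids,
        pred_ratios=pred_ratios,
        true_ratios=true_ratios,
    )


def run_pipeline(
    truth: GroundTruth,
    variant: str = "IDREAM",
    n_subsets: int = 50,
    seed: int | None = None,
    mode: str = PIPELINE_MODE,
    kappa: float = DEFAULT_KAPPA,
    fdr_cutoff: float = inference.DEFAULT_FDR_CUTOFF,
) -> PipelineResult:
    """Full chain on a synthetic study: infer, annotate, constrain, predict."""
    network = infer_annotated_network(
        truth, n_subsets=n_subsets, seed=seed, fdr_cutoff=fdr_cutoff
    )
    return predict_from_network(truth, network, variant, mode=mode, kappa=kappa)


def edge_recovery(
    inferred: InfluenceNetwork, truth: InfluenceNetwork, n_candidate_pairs: int
) -> dict[str, float]:
    """Planted-edge recovery: sensitivity = recovered planted edges over
    planted edges; false-edge rate = unplanted recovered edges over
    unplanted candidate (tf, target) pairs."""
    planted = {(e.tf, e.target) for e in truth.edges}
    recovered = {(e.tf, e.target) for e in inferred.edges}
    tp = len(planted & recovered)
    fp = len(recovered - planted)
    n_unplanted = n_candidate_pairs - len(planted)
    return {
        "sensitivity": tp / len(planted) if planted else float("nan"),
        "false_edge_rate": fp / n_unplanted if n_unplanted else float("nan"),
        "n_planted": len(planted),
        "n_recovered": len(recovered),
        "n_false": fp,
    }
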