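"""PROM-style conditional probabilities P(target ON | TF OFF).

Expression is binarised per gene at a quantile threshold (ON when strictly
above the gene's own quantile), and the probability of a target being ON in
the samples where its TF is OFF estimates how much of the target's activity
would survive a TF knockout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .model_io import ExpressionMatrix, InfluenceNetwork, ValidationError

log = logging.getLogger(__name__)

#: quantile separating OFF from ON per gene (conventional PROM choice)
DEFAULT_BINARIZE_QUANTILE = 0.33
#: minimum number of TF-OFF samples needed to estimate a probability
DEFAULT_MIN_OFF_SAMPLES = 5


@dataclass
class BinaryExpression:
    """ON/OFF gene states, binarised per gene at a quantile threshold."""

    gene_ids: list[str]
    sample_ids: list[str]
    states: np.ndarray
    threshold_quantile: float

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states)
        if self.states.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError("binary states shape does not match ids")
        if not np.isin(self.states, (0, 1)).all():
            raise ValidationError("binary states must be 0/1")

    def row(self, gene: str) -> np.ndarray:
        try:
            return self.states[self.gene_ids.index(gene)]
        except ValueError:
            raise KeyError(f"unknown gene {gene!r}") from None


def binarize_expression(
    expression: ExpressionMatrix,
    threshold_quantile: float = DEFAULT_BINARIZE_QUANTILE,
) -> BinaryExpression:
    """Binarise each gene at its own expression quantile (ON iff strictly
    above). A constant gene is therefore OFF everywhere."""
    if not 0.0 < threshold_quantile < 1.0:
        raise ValidationError("threshold_quantile must lie in (0,1)")
    thresholds = np.quantile(expression.values, threshold_quantile, axis=1)
    states = (expression.values > thresholds[:, None]).astype(np.int8)
    return BinaryExpression(
        gene_ids=list(expression.gene_ids),
        sample_ids=list(expression.sample_ids),
        states=states,
        threshold_quantile=threshold_quantile,
    )


def conditional_probability(
    binary: BinaryExpression,
    tf: str,
    target: str,
    min_off_samples: int = DEFAULT_MIN_OFF_SAMPLES,
) -> float:
    """P(target ON | TF OFF) over the binarised samples.

    With fewer than ``min_off_samples`` TF-OFF samples the estimate is
    unreliable and the pair is left unconstrained (probability 1), with a
    logged warning.
    """
    off = binary.row(tf) == 0
    n_off = int(off.sum())
    if n_off < min_off_samples:
        log.warning(
            "only %d TF-OFF samples for %r (min %d); leaving %r -> %r unconstrained",
            n_off, tf, min_off_samples, tf, target,
        )
        return 1.0
    return float(binary.row(target)[off].mean())


def annotate_prom_probabilities(
    network: InfluenceNetwork,
    binary: BinaryExpression,
    min_off_samples: int = DEFAULT_MIN_OFF_SAMPLES,
) -> InfluenceNetwork:
    """Network copy with ``prom_prob`` filled in on every edge."""
    return network.map_edges(
        lambda e: replace(
            e,
            prom_prob=conditional_probability(
                binary, e.tf, e.target, min_off_samples=min_off_samples
            ),
        )
    )
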