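"""Scoring of predicted versus observed knockout phenotypes.

Covers the Matthews correlation coefficient over binarised growth calls
(defect iff ratio strictly below a threshold), threshold sweeps, Pearson
correlation with Fisher-Z comparison of correlations, paired t-tests on
absolute residuals, ROC/AUC, and permutation significance tests that rerun
a caller-supplied pipeline closure on permuted expression or rewired
networks.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import stats as sps
from sklearn.metrics import roc_auc_score

from .model_io import (
    ExpressionMatrix,
    InfluenceNetwork,
    ValidationError,
)

log = logging.getLogger(__name__)

#: default growth-ratio thresholds for MCC/AUC sweeps (0.1 .. 0.95)
DEFAULT_THRESHOLDS = tuple(np.round(np.arange(0.10, 0.951, 0.05), 2))
#: the three representative thresholds highlighted in cross-model comparisons
REPRESENTATIVE_THRESHOLDS = (0.2, 0.5, 0.95)
DEFAULT_N_PERMUTATIONS = 500


# ---------------------------------------------------------------------------
# Matthews correlation coefficient
# ---------------------------------------------------------------------------

def mcc(tp: int, tn: int, fp: int, fn: int) -> float:
    """Matthews correlation coefficient of a 2x2 confusion matrix.

    (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)); ranges from -1
    (predictions exactly opposite) to +1 (exact match). A zero factor in
    the denominator yields 0 by the standard convention (logged).
    """
    counts = (tp, tn, fp, fn)
    if any(c < 0 for c in counts):
        raise ValidationError(f"negative confusion counts {counts}")
    if all(c == 0 for c in counts):
        raise ValidationError("empty confusion matrix")
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        log.debug("MCC denominator zero for counts %s; returning 0", counts)
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


def binarize_growth_calls(ratios, threshold: float) -> np.ndarray:
    """Growth-defect calls: 1 iff the ratio is strictly below the threshold."""
    if not 0.0 < threshold < 1.0:
        raise ValidationError("threshold must lie in (0,1)")
    return (np.asarray(ratios, dtype=float) < threshold).astype(int)


def mcc_from_calls(pred_calls, obs_calls) -> float:
    pred = np.asarray(pred_calls, dtype=int)
    obs = np.asarray(obs_calls, dtype=int)
    tp = int(np.sum((pred == 1) & (obs == 1)))
    tn = int(np.sum((pred == 0) & (obs == 0)))
    fp = int(np.sum((pred == 1) & (obs == 0)))
    fn = int(np.sum((pred == 0) & (obs == 1)))
    return mcc(tp, tn, fp, fn)


def mcc_threshold_sweep(
    pred_ratios,
    obs_ratios,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
) -> dict[float, float]:
    """MCC of defect calls at each binarisation threshold.

    A threshold at which the observed calls are single-class has no defined
    MCC and is reported as NaN (never silently 0).
    """
    pred = np.asarray(pred_ratios, dtype=float)
    obs = np.asarray(obs_ratios, dtype=float)
    if pred.shape != obs.shape:
        raise ValidationError("prediction and observation vectors differ in length")
    out: dict[float, float] = {}
    for thr in thresholds:
        obs_calls = binarize_growth_calls(obs, thr)
        if obs_calls.min() == obs_calls.max():
            out[float(thr)] = float("nan")
            continue
        out[float(thr)] = mcc_from_calls(binarize_growth_calls(pred, thr), obs_calls)
    return out


# ---------------------------------------------------------------------------
# Correlation / residual statistics
# ---------------------------------------------------------------------------

def pearson_with_pvalue(x, y) -> tuple[float, float]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 4:
        raise ValidationError("Pearson correlation requires n >= 4")
    if np.std(x) < 1e-15 or np.std(y) < 1e-15:
        raise ValidationError("degenerate (constant) series")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def residual_ttest(pred_a, pred_b, obs) -> float:
    """Two-tailed paired t-test of the absolute residuals |pred-obs| of two
    prediction sets against the same observations."""
    ra = np.abs(np.asarray(pred_a, float) - np.asarray(obs, float))
    rb = np.abs(np.asarray(pred_b, float) - np.asarray(obs, float))
    if ra.size < 4:
        raise ValidationError("residual t-test requires n >= 4")
    diff = ra - rb
    if np.std(diff) < 1e-15:
        raise ValidationError("degenerate residual differences")
    return float(sps.ttest_rel(ra, rb).pvalue)


def fisher_z_compare(r1: float, n1: int, r2: float, n2: int) -> float:
    """Two-tailed p-value for equality of two independent correlations via
    the Fisher Z transform: z = atanh(r), SE = sqrt(1/(n1-3) + 1/(n2-3))."""
    for r in (r1, r2):
        if not -1.0 < r < 1.0:
            raise ValidationError(f"|r| must be < 1 for the Fisher Z transform, got {r}")
    for n in (n1, n2):
        if n < 4:
            raise ValidationError("Fisher Z comparison requires n >= 4")
    z = (math.atanh(r1) - math.atanh(r2)) / math.sqrt(1 / (n1 - 3) + 1 / (n2 - 3))
    return float(2.0 * sps.norm.sf(abs(z)))


def sse_report(pred, obs) -> dict[str, float]:
    """Sum of squared errors in three labelled normalisations (raw, per
    observation, and relative to total observed variance)."""
    pred = np.asarray(pred, float)
    obs = np.asarray(obs, float)
    sse = float(np.sum((pred - obs) ** 2))
    tss = float(np.sum((obs - obs.mean()) ** 2))
    return {
        "sse": sse,
        "sse_per_n": sse / obs.size,
        "sse_over_tss": sse / tss if tss > 0 else float("nan"),
    }


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------

def roc_auc(scores, labels) -> float:
    """Area under the ROC curve (Mann-Whitney U normalised, ties half)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if labels.min() == labels.max():
        raise ValidationError("ROC AUC undefined with a single class")
    return float(roc_auc_score(labels, scores))


def auc_threshold_sweep(
    pred_ratios,
    obs_ratios,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
) -> dict[float, float]:
    """AUC of predicted growth ratios as a defect score (lower ratio = more
    defective) against observed defect calls at each threshold; single-class
    thresholds are NaN."""
    pred = np.asarray(pred_ratios, dtype=float)
    obs = np.asarray(obs_ratios, dtype=float)
    out: dict[float, float] = {}
    for thr in thresholds:
        labels = binarize_growth_calls(obs, thr)
        if labels.min() == labels.max():
            out[float(thr)] = float("nan")
            continue
        out[float(thr)] = roc_auc(-pred, labels)
    return out


# ---------------------------------------------------------------------------
# Permutation significance
# ---------------------------------------------------------------------------

def permute_expression(
    expression: ExpressionMatrix,
    rng: np.random.Generator,
    whole_matrix: bool = False,
) -> ExpressionMatrix:
    """Permuted copy of the expression matrix: each gene's values shuffled
    independently across samples (gene count fixed), or the whole matrix
    shuffled when ``whole_matrix``."""
    values = expression.values.copy()
    if whole_matrix:
        flat = values.ravel()
        rng.shuffle(flat)
        values = flat.reshape(values.shape)
    else:
        for i in range(values.shape[0]):
            rng.shuffle(values[i])
    return ExpressionMatrix(
        gene_ids=list(expression.gene_ids),
        sample_ids=list(expression.sample_ids),
        values=values,
    )


def rewire_network(
    network: InfluenceNetwork,
    rng: np.random.Generator,
    max_tries: int = 1000,
) -> InfluenceNetwork:
    """Randomly rewired copy of the network: the TF set, target set and edge
    count are fixed while connections are permuted (targets shuffled across
    edges; self-loops and duplicate pairs rejected by reshuffling)."""
    edges = list(network.edges)
    targets = [e.target for e in edges]
    for _ in range(max_tries):
        perm = rng.permutation(len(targets))
        new_targets = [targets[i] for i in perm]
        pairs = [(e.tf, t) for e, t in zip(edges, new_targets)]
        if len(set(pairs)) == len(pairs) and all(tf != t for tf, t in pairs):
            return InfluenceNetwork(
                edges=[replace(e, target=t) for e, t in zip(edges, new_targets)]
            )
    raise RuntimeError("could not rewire network without collisions")


def permutation_test(
    pipeline_mcc: float,
    score_fn: Callable[[ExpressionMatrix, InfluenceNetwork], float],
    expression: ExpressionMatrix,
    network: InfluenceNetwork,
    regenerate: str = "expression",
    n_perm: int = DEFAULT_N_PERMUTATIONS,
    seed: int | None = None,
    whole_matrix: bool = False,
) -> float:
    """Fraction of permutations whose pipeline score exceeds the observed one.

    ``score_fn(expression, network)`` must rerun the pipeline (inference
    and/or probabilities -> constraints -> predictions -> MCC) on the
    permuted inputs. ``regenerate`` chooses what is permuted: per-gene
    expression values, or the network's connections.
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    if regenerate not in ("expression", "network"):
        raise ValidationError(f"unknown permutation mode {regenerate!r}")
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        if regenerate == "expression":
            score = score_fn(
                permute_expression(expression, rng, whole_matrix=whole_matrix), network
            )
        else:
            score = score_fn(expression, rewire_network(network, rng))
        if score > pipeline_mcc:
            exceed += 1
    return exceed / n_perm


# ---------------------------------------------------------------------------
# Report bundle
# ---------------------------------------------------------------------------

@dataclass
class EvalReport:
    """Bundle of all phenotype-prediction scores."""

    mcc_by_threshold: dict[float, float]
    pcc: float
    pcc_pvalue: float
    sse: float
    sse_per_n: float
    sse_over_tss: float
    mean_abs_residual: float
    auc_by_threshold: dict[float, float]
    permutation_pvalues: dict[str, float] = field(default_factory=dict)
    n: int = 0

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "pcc": self.pcc,
            "pcc_pvalue": self.pcc_pvalue,
            "sse": self.sse,
            "sse_per_n": self.sse_per_n,
            "sse_over_tss": self.sse_over_tss,
            "mean_abs_residual": self.mean_abs_residual,
            "mcc_by_threshold": {str(k): v for k, v in self.mcc_by_threshold.items()},
            "auc_by_threshold": {str(k): v for k, v in self.auc_by_threshold.items()},
            "permutation_pvalues": dict(self.permutation_pvalues),
        }


def evaluate_predictions(
    pred_ratios,
    obs_ratios,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    permutation_pvalues: Mapping[str, float] | None = None,
) -> EvalReport:
    """Score predicted against observed growth ratios with every statistic
    in the toolkit's repertoire."""
    pred = np.asarray(pred_ratios, dtype=float)
    obs = np.asarray(obs_ratios, dtype=float)
    if pred.shape != obs.shape:
        raise ValidationError("prediction and observation vectors differ in length")
    pcc, pval = pearson_with_pvalue(pred, obs)
    sse = sse_report(pred, obs)
    return EvalReport(
        mcc_by_threshold=mcc_threshold_sweep(pred, obs, thresholds),
        pcc=pcc,
        pcc_pvalue=pval,
        sse=sse["sse"],
        sse_per_n=sse["sse_per_n"],
        sse_over_tss=sse["sse_over_tss"],
        mean_abs_residual=float(np.mean(np.abs(pred - obs))),
        auc_by_threshold=auc_threshold_sweep(pred, obs, thresholds),
        permutation_pvalues=dict(permutation_pvalues or {}),
        n=int(obs.size),
    )
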