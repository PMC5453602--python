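"""Evaluation statistics: MCC against a brute-force phi oracle, threshold
sweeps, correlation comparisons, AUC against pair counting, and the
permutation machinery."""

import math

import numpy as np
import pytest

from regflux.model_io import ExpressionMatrix, InfluenceNetwork, RegulatoryEdge, ValidationError
from regflux.stats import (
    auc_threshold_sweep,
    binarize_growth_calls,
    evaluate_predictions,
    fisher_z_compare,
    mcc,
    mcc_from_calls,
    mcc_threshold_sweep,
    pearson_with_pvalue,
    permutation_test,
    permute_expression,
    residual_ttest,
    rewire_network,
    roc_auc,
)


def phi_oracle(pred: np.ndarray, obs: np.ndarray) -> float:
    """Pearson correlation of two binary vectors (the phi coefficient)."""
    if pred.std() == 0 or obs.std() == 0:
        return 0.0
    return float(np.corrcoef(pred, obs)[0, 1])


# --- MCC ---

def test_mcc_extremes_and_worked_value():
    assert mcc(5, 5, 0, 0) == 1.0
    assert mcc(0, 0, 5, 5) == -1.0
    assert mcc(2, 3, 1, 4) == pytest.approx(2 / math.sqrt(504), abs=1e-12)


def test_mcc_zero_denominator_convention():
    assert mcc(3, 0, 0, 2) == 0.0  # no negative predictions or observations... tn+fp = 0
    with pytest.raises(ValidationError):
        mcc(0, 0, 0, 0)
    with pytest.raises(ValidationError):
        mcc(-1, 1, 1, 1)


def test_mcc_matches_phi_on_random_vectors():
    rng = np.random.default_rng(17)
    for _ in range(200):
        n = rng.integers(4, 40)
        pred = rng.integers(0, 2, n)
        obs = rng.integers(0, 2, n)
        tp = int(np.sum((pred == 1) & (obs == 1)))
        tn = int(np.sum((pred == 0) & (obs == 0)))
        fp = int(np.sum((pred == 1) & (obs == 0)))
        fn = int(np.sum((pred == 0) & (obs == 1)))
        assert mcc(tp, tn, fp, fn) == pytest.approx(phi_oracle(pred, obs), abs=1e-9)


# --- binarisation and sweeps ---

def test_defect_call_is_strictly_below_threshold():
    calls = binarize_growth_calls([0.4, 0.5, 0.6], 0.5)
    np.testing.assert_array_equal(calls, [1, 0, 0])


def test_defect_count_monotone_in_threshold():
    rng = np.random.default_rng(2)
    ratios = rng.uniform(0, 1, 50)
    counts = [binarize_growth_calls(ratios, t).sum() for t in np.arange(0.1, 0.951, 0.05)]
    assert all(b >= a for a, b in zip(counts, counts[1:]))


def test_perfect_prediction_sweeps_to_one():
    rng = np.random.default_rng(3)
    obs = rng.uniform(0, 1, 60)
    sweep = mcc_threshold_sweep(obs, obs)
    for thr, value in sweep.items():
        if not math.isnan(value):
            assert value == pytest.approx(1.0)


def test_single_class_threshold_reported_undefined():
    obs = np.array([0.8, 0.9, 0.85, 0.95])  # no defects below 0.5
    sweep = mcc_threshold_sweep(obs, obs, thresholds=[0.5])
    assert math.isnan(sweep[0.5])
    aucs = auc_threshold_sweep(obs, obs, thresholds=[0.5])
    assert math.isnan(aucs[0.5])


def test_independent_predictions_score_near_zero():
    rng = np.random.default_rng(5)
    obs = rng.uniform(0, 1, 50)
    pred = rng.permutation(obs)
    sweep = mcc_threshold_sweep(pred, obs)
    finite = [v for v in sweep.values() if not math.isnan(v)]
    assert max(abs(v) for v in finite) <= 0.45  # null MCC stays small at n=50


def test_representative_thresholds_selectable():
    rng = np.random.default_rng(6)
    obs = rng.uniform(0, 1, 40)
    sweep = mcc_threshold_sweep(obs, obs, thresholds=(0.2, 0.5, 0.95))
    assert set(sweep) == {0.2, 0.5, 0.95}


# --- correlation statistics ---

def test_fisher_z_identical_correlations_p_one():
    assert fisher_z_compare(0.5, 50, 0.5, 50) == pytest.approx(1.0)


def test_fisher_z_separated_correlations_significant():
    assert fisher_z_compare(0.8, 100, 0.0, 100) < 1e-3


def test_fisher_z_validates_inputs():
    with pytest.raises(ValidationError):
        fisher_z_compare(1.0, 50, 0.5, 50)
    with pytest.raises(ValidationError):
        fisher_z_compare(0.5, 3, 0.5, 50)


def test_residual_ttest_detects_biased_predictor():
    rng = np.random.default_rng(8)
    obs = rng.uniform(0, 1, 30)
    pred_a = obs + rng.normal(0, 0.01, 30)
    pred_b = obs + 0.5
    assert residual_ttest(pred_a, pred_b, obs) < 0.01


def test_pearson_guards():
    with pytest.raises(ValidationError):
        pearson_with_pvalue([1, 2, 3], [1, 2, 3])
    with pytest.raises(ValidationError):
        pearson_with_pvalue([1, 1, 1, 1], [1, 2, 3, 4])


# --- AUC ---

def test_auc_known_values():
    assert roc_auc([3, 2, 1, 0.5], [1, 1, 0, 0]) == 1.0
    assert roc_auc([1, 1, 1, 1], [1, 0, 1, 0]) == 0.5
    assert roc_auc([0.9, 0.8, 0.3, 0.2], [1, 0, 1, 0]) == pytest.approx(0.75)
    with pytest.raises(ValidationError):
        roc_auc([1, 2, 3], [1, 1, 1])


def test_auc_matches_pair_counting_oracle():
    rng = np.random.default_rng(21)
    for _ in range(30):
        n = int(rng.integers(4, 12))
        scores = np.round(rng.uniform(0, 1, n), 1)  # force some ties
        labels = rng.integers(0, 2, n)
        if labels.min() == labels.max():
            continue
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
        assert roc_auc(scores, labels) == pytest.approx(
            wins / (len(pos) * len(neg)), abs=1e-12
        )


# --- permutation machinery ---

def _tiny_inputs(seed=0, n_genes=3, n_samples=30):
    rng = np.random.default_rng(seed)
    expr = ExpressionMatrix(
        gene_ids=[f"g{i}" for i in range(n_genes)],
        sample_ids=[f"s{j}" for j in range(n_samples)],
        values=rng.standard_normal((n_genes, n_samples)),
    )
    net = InfluenceNetwork(
        edges=[RegulatoryEdge(tf="TFa", target="g0"), RegulatoryEdge(tf="TFb", target="g1")]
    )
    return expr, net


def test_row_permutation_preserves_rows_as_multisets():
    expr, _ = _tiny_inputs()
    out = permute_expression(expr, np.random.default_rng(4))
    for i in range(len(expr.gene_ids)):
        assert sorted(out.values[i]) == pytest.approx(sorted(expr.values[i]))
    assert out.gene_ids == expr.gene_ids


def test_rewire_preserves_degree_and_target_multiset():
    expr, net = _tiny_inputs()
    out = rewire_network(net, np.random.default_rng(4))
    assert sorted(e.tf for e in out.edges) == sorted(e.tf for e in net.edges)
    assert sorted(e.target for e in out.edges) == sorted(e.target for e in net.edges)
    assert len({(e.tf, e.target) for e in out.edges}) == len(net.edges)


def test_permutation_p_is_one_for_unbeatable_low_score():
    expr, net = _tiny_inputs()
    p = permutation_test(-1.0, lambda e, n: 0.0, expr, net, n_perm=20, seed=1)
    assert p == 1.0


def test_permutation_deterministic_given_seed():
    expr, net = _tiny_inputs()

    def score(e, n):
        return float(np.corrcoef(e.values[0], e.values[1])[0, 1])

    obs = score(expr, net)
    kw = dict(n_perm=40, seed=9)
    assert permutation_test(obs, score, expr, net, **kw) == permutation_test(
        obs, score, expr, net, **kw
    )


def test_null_permutation_pvalues_approximately_uniform():
    """With the observed score drawn from the same null as the permuted
    scores, permutation p-values are ~uniform (KS at alpha 0.01)."""
    from scipy import stats as sps

    rng = np.random.default_rng(33)
    w = rng.standard_normal(30)

    def score(e, n):
        return float(np.corrcoef(e.values[0], w)[0, 1])

    pvals = []
    for rep in range(100):
        expr, net = _tiny_inputs(seed=1000 + rep, n_genes=1)
        pvals.append(
            permutation_test(score(expr, net), score, expr, net, n_perm=60, seed=rep)
        )
    assert sps.kstest(pvals, "uniform").pvalue > 0.01


# --- report bundle ---

def test_evaluate_predictions_report_shape():
    rng = np.random.default_rng(12)
    obs = rng.uniform(0, 1, 40)
    pred = np.clip(obs + rng.normal(0, 0.1, 40), 0, 1)
    report = evaluate_predictions(pred, obs)
    assert report.n == 40
    assert -1 <= report.pcc <= 1
    assert report.sse >= 0 and report.sse_per_n == pytest.approx(report.sse / 40)
    d = report.to_dict()
    assert set(d["mcc_by_threshold"]) == set(d["auc_by_threshold"])
    finite_mcc = [v for v in report.mcc_by_threshold.values() if not math.isnan(v)]
    assert all(-1 <= v <= 1 for v in finite_mcc)
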