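"""Bootstrap-lasso inference: FDR tallying, sign calls, and planted-network
recovery on seeded simulations."""

import numpy as np
import pytest

from regflux.inference import (
    bootstrap_tally,
    classify_sign,
    fdr_from_tally,
    fit_regulator_model,
    infer_network,
)
from regflux.model_io import ExpressionMatrix, ValidationError
from regflux.synth import Regulon, make_regulon, simulate_expression


def planted_expression(n_samples=100, noise_sd=0.05, n_decoys=5, effect=2.0, seed=1):
    """One target driven by tf1 among decoy TFs."""
    rng = np.random.default_rng(seed)
    tfs = [f"tf{i+1}" for i in range(n_decoys + 1)]
    X = rng.standard_normal((len(tfs), n_samples))
    y = effect * X[0] + rng.normal(0, noise_sd, n_samples)
    return ExpressionMatrix(
        gene_ids=tfs + ["target"],
        sample_ids=[f"s{j}" for j in range(n_samples)],
        values=np.vstack([X, y]),
    )


# --- fdr_from_tally ---

def test_fdr_tally_rule():
    assert fdr_from_tally(191, 200) == pytest.approx(0.045, abs=1e-12)
    assert fdr_from_tally(200, 200) == 0.0
    assert fdr_from_tally(0, 200) == 1.0


def test_fdr_tally_is_strictly_decreasing_in_count():
    fdrs = [fdr_from_tally(c, 50) for c in range(51)]
    assert all(a > b for a, b in zip(fdrs, fdrs[1:]))
    assert all(0.0 <= f <= 1.0 for f in fdrs)


def test_fdr_tally_range_checks():
    with pytest.raises(ValidationError):
        fdr_from_tally(-1, 200)
    with pytest.raises(ValidationError):
        fdr_from_tally(201, 200)
    with pytest.raises(ValidationError):
        fdr_from_tally(0, 0)


# --- fit_regulator_model ---

def test_planted_regulator_selected_with_positive_sign():
    expr = planted_expression(seed=1)
    sel = fit_regulator_model(expr, [f"tf{i+1}" for i in range(6)], "target", range(100))
    assert "tf1" in sel and sel["tf1"] > 0


def test_exact_anticorrelation_selected_negative():
    rng = np.random.default_rng(2)
    x = rng.standard_normal(60)
    expr = ExpressionMatrix(
        gene_ids=["tf1", "target"],
        sample_ids=[f"s{j}" for j in range(60)],
        values=np.vstack([x, -x]),
    )
    sel = fit_regulator_model(expr, ["tf1"], "target", range(60))
    assert sel["tf1"] < 0


def test_null_target_rarely_selects_regulators():
    """With the target independent of every TF, selections stay sparse."""
    n_selected = []
    for seed in range(15):
        rng = np.random.default_rng(100 + seed)
        tfs = [f"tf{i+1}" for i in range(5)]
        expr = ExpressionMatrix(
            gene_ids=tfs + ["target"],
            sample_ids=[f"s{j}" for j in range(100)],
            values=rng.standard_normal((6, 100)),
        )
        n_selected.append(len(fit_regulator_model(expr, tfs, "target", range(100))))
    assert np.mean(n_selected) <= 1.5  # far below the 5 candidates on offer


def test_constant_target_yields_empty_selection():
    expr = planted_expression()
    values = expr.values.copy()
    values[-1] = 3.14
    const = ExpressionMatrix(expr.gene_ids, expr.sample_ids, values)
    assert fit_regulator_model(const, ["tf1"], "target", range(100)) == {}


def test_too_few_samples_rejected():
    expr = planted_expression()
    with pytest.raises(ValidationError, match="minimum"):
        fit_regulator_model(expr, ["tf1"], "target", range(5))


# --- bootstrap_tally ---

def test_tally_planted_regulator_dominates():
    expr = planted_expression(seed=7)
    tally = bootstrap_tally(
        expr, [f"tf{i+1}" for i in range(6)], "target", n_subsets=50, seed=7
    )
    assert tally.counts["tf1"] / 50 >= 0.9
    assert "tf1" in tally.full_model_regulators


def test_single_subset_counts_are_binary():
    expr = planted_expression()
    tally = bootstrap_tally(expr, ["tf1", "tf2"], "target", n_subsets=1, seed=0)
    assert set(tally.counts.values()) <= {0, 1}


def test_tally_deterministic_given_seed():
    expr = planted_expression()
    kw = dict(n_subsets=8, seed=42)
    t1 = bootstrap_tally(expr, ["tf1", "tf2", "tf3"], "target", **kw)
    t2 = bootstrap_tally(expr, ["tf1", "tf2", "tf3"], "target", **kw)
    assert t1.counts == t2.counts


# --- classify_sign ---

def test_sign_calls():
    rng = np.random.default_rng(5)
    x = rng.standard_normal(80)
    expr = ExpressionMatrix(
        gene_ids=["tf", "up", "down", "flat"],
        sample_ids=[f"s{j}" for j in range(80)],
        values=np.vstack([x, x + rng.normal(0, 0.2, 80), -x, np.zeros(80)]),
    )
    assert classify_sign(expr, "tf", "up") == "activator"
    assert classify_sign(expr, "tf", "down") == "repressor"
    with pytest.raises(ValidationError, match="constant"):
        classify_sign(expr, "tf", "flat")


# --- infer_network ---

@pytest.fixture(scope="module")
def planted_network_fixture():
    regulon = make_regulon(3, 4, activator_fraction=0.7, effect_size=2.0, seed=11)
    expr = simulate_expression(
        regulon, n_samples=200, noise_sd=0.1, knockout_fraction=0.1,
        decoy_genes=3, seed=11,
    )
    return regulon, expr


def test_planted_edges_recovered(planted_network_fixture):
    regulon, expr = planted_network_fixture
    tfs = regulon.tf_ids
    targets = [g for g in expr.gene_ids if g not in set(tfs)]
    net = infer_network(expr, tfs, targets, n_subsets=30, fdr_cutoff=0.05, seed=11)
    planted = {(e.tf, e.target) for e in regulon.network.edges}
    recovered = {(e.tf, e.target) for e in net.edges}
    assert planted <= recovered
    # signs of recovered planted edges match the planted signs
    for e in regulon.network.edges:
        assert net.get(e.tf, e.target).sign == e.sign


def test_pure_noise_expression_yields_no_edges():
    rng = np.random.default_rng(23)
    genes = ["tf1", "tf2", "t1", "t2", "t3"]
    expr = ExpressionMatrix(
        gene_ids=genes,
        sample_ids=[f"s{j}" for j in range(120)],
        values=rng.standard_normal((5, 120)),
    )
    net = infer_network(
        expr, ["tf1", "tf2"], ["t1", "t2", "t3"], n_subsets=20, seed=23
    )
    assert len(net) == 0


def test_cutoff_zero_keeps_only_unanimous_edges(planted_network_fixture):
    regulon, expr = planted_network_fixture
    tfs = regulon.tf_ids
    targets = [g for g in expr.gene_ids if g not in set(tfs)][:4]
    net = infer_network(expr, tfs, targets, n_subsets=10, fdr_cutoff=0.0, seed=3)
    assert all(e.fdr == 0.0 for e in net.edges)


def test_inference_invariant_to_sample_order(planted_network_fixture):
    regulon, expr = planted_network_fixture
    tfs = regulon.tf_ids
    targets = [g for g in expr.gene_ids if g not in set(tfs)][:3]
    kw = dict(n_subsets=10, seed=9)
    net_a = infer_network(expr, tfs, targets, **kw)
    perm = np.random.default_rng(0).permutation(len(expr.sample_ids))
    shuffled = ExpressionMatrix(
        gene_ids=list(expr.gene_ids),
        sample_ids=[expr.sample_ids[i] for i in perm],
        values=expr.values[:, perm],
    )
    net_b = infer_network(shuffled, tfs, targets, **kw)
    assert [(e.tf, e.target, e.fdr, e.sign) for e in net_a.edges] == [
        (e.tf, e.target, e.fdr, e.sign) for e in net_b.edges
    ]
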