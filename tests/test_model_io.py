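"""I/O round trips and invariant enforcement for all four file formats."""

import json

import numpy as np
import pytest

from regflux.model_io import (
    ExpressionMatrix,
    InfluenceNetwork,
    ParseError,
    PhenotypeTable,
    RegulatoryEdge,
    ValidationError,
    read_expression,
    read_model,
    read_network,
    read_phenotypes,
    write_expression,
    write_model,
    write_network,
    write_phenotypes,
)

MINIMAL_MODEL = {
    "metabolites": ["A", "B"],
    "reactions": [
        {"id": "EX_in", "stoich": {"A": 1}, "lb": 0, "ub": 10, "gpr": "", "exchange": True},
        {"id": "AtoB", "stoich": {"A": -1, "B": 1}, "lb": 0, "ub": 5, "gpr": "g1", "exchange": False},
        {"id": "BIOMASS", "stoich": {"B": -1}, "lb": 0, "ub": 1000, "gpr": "", "exchange": False},
    ],
    "objective": "BIOMASS",
}


def test_minimal_model_reads(tmp_path):
    p = tmp_path / "m.json"
    p.write_text(json.dumps(MINIMAL_MODEL))
    model = read_model(p)
    assert model.reaction_ids == ["EX_in", "AtoB", "BIOMASS"]
    assert model.genes == {"g1"}
    assert model.stoichiometry.shape == (2, 3)


def test_model_round_trip(tmp_path):
    p1, p2 = tmp_path / "m1.json", tmp_path / "m2.json"
    p1.write_text(json.dumps(MINIMAL_MODEL))
    model = read_model(p1)
    write_model(model, p2)
    again = read_model(p2)
    assert again.reaction_ids == model.reaction_ids
    assert again.metabolite_ids == model.metabolite_ids
    assert again.gpr == model.gpr
    assert np.array_equal(again.lower_bound, model.lower_bound)
    assert np.array_equal(again.upper_bound, model.upper_bound)
    assert (again.stoichiometry != model.stoichiometry).nnz == 0


def test_inverted_bounds_rejected(tmp_path):
    doc = json.loads(json.dumps(MINIMAL_MODEL))
    doc["reactions"][1]["lb"] = 7  # above its ub of 5
    p = tmp_path / "bad.json"
    p.write_text(json.dumps(doc))
    with pytest.raises(ValidationError, match="AtoB"):
        read_model(p)


def test_missing_objective_is_configuration_error(tmp_path):
    doc = json.loads(json.dumps(MINIMAL_MODEL))
    doc["objective"] = "NOPE"
    p = tmp_path / "bad.json"
    p.write_text(json.dumps(doc))
    with pytest.raises(ValueError, match="NOPE"):
        read_model(p)


def test_malformed_json_names_file(tmp_path):
    p = tmp_path / "broken.json"
    p.write_text("{not json")
    with pytest.raises(ParseError, match="broken.json"):
        read_model(p)


# --- network TSV ---

NETWORK_TSV = (
    "tf\ttarget\tevidence\tsign\tfdr\tprom_prob\n"
    "TF1\tg1\tdirect\tactivator\t0.045\t0.2\n"
    "TF1\tg2\tindirect\trepressor\t0.01\t\n"
    "TF2\tg1\tindirect\tunknown\t\t0.9\n"
)


def test_network_reads_and_round_trips(tmp_path):
    p = tmp_path / "net.tsv"
    p.write_text(NETWORK_TSV)
    net = read_network(p)
    assert len(net) == 3
    assert net.get("TF1", "g1").fdr == 0.045
    assert net.get("TF1", "g2").prom_prob is None
    p2 = tmp_path / "net2.tsv"
    write_network(net, p2)
    again = read_network(p2)
    assert again.edges == net.edges


def test_duplicate_edge_rejected(tmp_path):
    p = tmp_path / "net.tsv"
    p.write_text(NETWORK_TSV + "TF1\tg1\tdirect\tactivator\t0.1\t0.1\n")
    with pytest.raises(ParseError, match="duplicate"):
        read_network(p)


@pytest.mark.parametrize(
    "row, message",
    [
        ("TF1\tg9\tdirect\tactivator\t1.2\t", "fdr"),  # fdr out of range
        ("TF1\tg9\tsomething\tactivator\t0.1\t", "evidence"),
        ("TF1\tg9\tdirect\tupward\t0.1\t", "sign"),
    ],
)
def test_bad_network_rows_carry_line_number(tmp_path, row, message):
    p = tmp_path / "net.tsv"
    p.write_text("tf\ttarget\tevidence\tsign\tfdr\tprom_prob\n" + row + "\n")
    with pytest.raises(ParseError, match=r":2:") as err:
        read_network(p)
    assert message in str(err.value)


def test_self_edge_rejected():
    with pytest.raises(ValidationError, match="self-edge"):
        RegulatoryEdge(tf="g1", target="g1")


# --- expression / phenotypes ---

def test_expression_round_trip(tmp_path):
    rng = np.random.default_rng(0)
    expr = ExpressionMatrix(
        gene_ids=[f"g{i}" for i in range(5)],
        sample_ids=[f"s{j}" for j in range(10)],
        values=rng.standard_normal((5, 10)),
    )
    p = tmp_path / "expr.tsv"
    write_expression(expr, p)
    again = read_expression(p)
    assert again.gene_ids == expr.gene_ids
    assert again.sample_ids == expr.sample_ids
    np.testing.assert_allclose(again.values, expr.values, rtol=1e-9)


def test_duplicate_gene_id_rejected(tmp_path):
    p = tmp_path / "expr.tsv"
    p.write_text("gene\ts1\ts2\ng1\t1\t2\ng1\t3\t4\n")
    with pytest.raises(ParseError, match="duplicate"):
        read_expression(p)


def test_missing_cell_rejected(tmp_path):
    p = tmp_path / "expr.tsv"
    p.write_text("gene\ts1\ts2\ng1\t1\t\ng2\t3\t4\n")
    with pytest.raises(ParseError):
        read_expression(p)


def test_phenotype_round_trip_and_negative_ratio(tmp_path):
    table = PhenotypeTable(
        tf=["TF1", "TF2"], condition=["glc", "glc"], growth_ratio=np.array([0.5, 1.0])
    )
    p = tmp_path / "phen.tsv"
    write_phenotypes(table, p)
    again = read_phenotypes(p)
    assert again.tf == table.tf
    np.testing.assert_allclose(again.growth_ratio, table.growth_ratio)

    bad = tmp_path / "bad.tsv"
    bad.write_text("tf\tcondition\tgrowth_ratio\nTF1\tglc\t-0.2\n")
    with pytest.raises(ParseError, match="negative"):
        read_phenotypes(bad)


def test_network_targets_preserve_order():
    net = InfluenceNetwork(
        edges=[
            RegulatoryEdge(tf="TF2", target="b"),
            RegulatoryEdge(tf="TF1", target="a"),
            RegulatoryEdge(tf="TF1", target="b"),
        ]
    )
    assert net.tf_ids == ["TF2", "TF1"]
    assert net.target_ids == ["b", "a"]
    assert len(net.edges_for_tf("TF1")) == 2


def test_sbml_ingestion_maps_onto_native_model(tmp_path):
    cobra = pytest.importorskip("cobra")
    from conftest import linear_model, to_cobra

    native = linear_model()
    cm = to_cobra(native)
    for met in cm.metabolites:
        met.compartment = "c"  # SBML requires a compartment
    cm.reactions.get_by_id("AtoB").gene_reaction_rule = "g1"
    path = tmp_path / "model.xml"
    cobra.io.write_sbml_model(cm, str(path))
    model = read_model(path, format="sbml")
    assert set(model.reaction_ids) == set(native.reaction_ids)
    assert model.objective_reaction == "BIOMASS"
    assert model.genes == {"g1"}
    j = model.reaction_index("AtoB")
    assert model.upper_bound[j] == 5.0
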