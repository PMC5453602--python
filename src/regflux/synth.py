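"""Seeded generators for toy regulatory-metabolic systems.

Everything the pipeline consumes can be generated here at desk scale: a
small metabolic network with GPR rules and a biomass objective, a planted
TF -> target regulon with signed linear influences, a linear-Gaussian
expression compendium with TF-knockout samples, and ground-truth mutant
growth ratios computed from the planted (not inferred) network.

The expression model is deliberately favourable to the inference stage
(targets are noisy linear functions of their TFs), with noise level and
decoy count as the difficulty dials. Evidence labels encode a causal
distinction: a *direct* edge means the TF is physically required for the
target enzyme's expression, so knocking out the TF silences the gene; an
*indirect* edge is correlational only - expression tracks the TF, but the
enzyme remains functional when the TF is deleted. Ground-truth phenotypes
therefore apply direct activator edges as gene losses, which is exactly the
failure mode that separates evidence-aware integration from constraining
every correlated edge.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .fba import delete_genes, fba_optimize
from .model_io import (
    ExpressionMatrix,
    InfluenceNetwork,
    RegulatoryEdge,
    StoichiometricModel,
    ValidationError,
)
from scipy import sparse

DEFAULT_EFFECT_SIZE = 2.0
DEFAULT_NOISE_SD = 0.2
DEFAULT_N_SAMPLES = 200
DEFAULT_KNOCKOUT_FRACTION = 0.2
DEFAULT_DECOY_GENES = 6
DEFAULT_ACTIVATOR_FRACTION = 0.75
DEFAULT_DIRECT_FRACTION = 0.5


# ---------------------------------------------------------------------------
# Toy metabolic models
# ---------------------------------------------------------------------------

def make_toy_model(
    n_linear: int,
    n_isozyme_pairs: int,
    n_branches: int,
    seed: int | None = None,
) -> StoichiometricModel:
    """A connected toy model: exchange intake (ub 10), serial gene-gated
    conversions, "or" isozyme steps, redundant branch pairs, and a biomass
    sink objective.

    Serial capacities are drawn in [6, 9) so the chain bottleneck, not the
    intake, limits growth; every third serial reaction is gated by a
    two-gene "and" complex. Branch routes are sized so either alone can
    carry the full flux (single branch genes are dispensable). FBA optimum
    is positive by construction.
    """
    if n_linear < 0 or n_isozyme_pairs < 0 or n_branches < 0:
        raise ValidationError("block counts must be >= 0")
    rng = np.random.default_rng(seed)

    metabolites = ["M0"]
    reactions: list[dict] = [
        {"id": "EX_in", "stoich": {"M0": 1.0}, "lb": 0.0, "ub": 10.0,
         "gpr": "", "exchange": True}
    ]

    def advance(rid: str, gpr: str, ub: float) -> None:
        prev = metabolites[-1]
        nxt = f"M{len(metabolites)}"
        metabolites.append(nxt)
        reactions.append(
            {"id": rid, "stoich": {prev: -1.0, nxt: 1.0}, "lb": 0.0, "ub": ub,
             "gpr": gpr, "exchange": False}
        )

    for i in range(n_linear):
        gpr = f"gl{i}a and gl{i}b" if i % 3 == 2 else f"gl{i}"
        advance(f"L{i}", gpr, float(rng.uniform(6.0, 9.0)))
    for j in range(n_isozyme_pairs):
        advance(f"I{j}", f"gi{j}a or gi{j}b", float(rng.uniform(6.0, 9.0)))
    for b in range(n_branches):
        prev = metabolites[-1]
        nxt = f"M{len(metabolites)}"
        metabolites.append(nxt)
        for leaf in ("a", "b"):
            reactions.append(
                {"id": f"B{b}{leaf}", "stoich": {prev: -1.0, nxt: 1.0},
                 "lb": 0.0, "ub": float(rng.uniform(10.0, 12.0)),
                 "gpr": f"gb{b}{leaf}", "exchange": False}
            )
    last = metabolites[-1]
    reactions.append(
        {"id": "BIOMASS", "stoich": {last: -1.0}, "lb": 0.0, "ub": 1000.0,
         "gpr": "", "exchange": False}
    )

    met_index = {m: i for i, m in enumerate(metabolites)}
    rows, cols, vals = [], [], []
    for jdx, rec in enumerate(reactions):
        for met, coef in rec["stoich"].items():
            rows.append(met_index[met])
            cols.append(jdx)
            vals.append(coef)
    return StoichiometricModel(
        metabolite_ids=metabolites,
        reaction_ids=[r["id"] for r in reactions],
        stoichiometry=sparse.csr_matrix(
            (vals, (rows, cols)), shape=(len(metabolites), len(reactions))
        ),
        lower_bound=np.array([r["lb"] for r in reactions]),
        upper_bound=np.array([r["ub"] for r in reactions]),
        gpr=[r["gpr"] for r in reactions],
        objective_reaction="BIOMASS",
        exchange_flags=np.array([r["exchange"] for r in reactions], dtype=bool),
    )


# ---------------------------------------------------------------------------
# Planted regulons
# ---------------------------------------------------------------------------

@dataclass
class Regulon:
    """A planted influence network with true signed strengths per edge."""

    network: InfluenceNetwork
    strengths: dict[tuple[str, str], float]

    @property
    def tf_ids(self) -> list[str]:
        return self.network.tf_ids


def make_regulon(
    tfs: int,
    targets_per_tf: int,
    activator_fraction: float = DEFAULT_ACTIVATOR_FRACTION,
    effect_size: float = DEFAULT_EFFECT_SIZE,
    seed: int | None = None,
    direct_fraction: float = DEFAULT_DIRECT_FRACTION,
    target_pool: Sequence[str] | None = None,
    tf_names: Sequence[str] | None = None,
) -> Regulon:
    """Random planted regulon: each TF regulates ``targets_per_tf`` targets
    with strength +/- ``effect_size``; edges are labelled direct/indirect at
    ``direct_fraction`` to exercise the evidence split."""
    if not 0.0 <= activator_fraction <= 1.0:
        raise ValidationError("activator_fraction must lie in [0,1]")
    if not 0.0 <= direct_fraction <= 1.0:
        raise ValidationError("direct_fraction must lie in [0,1]")
    rng = np.random.default_rng(seed)
    names = list(tf_names) if tf_names is not None else [f"TF{i+1}" for i in range(tfs)]
    n_targets = tfs * targets_per_tf
    if target_pool is not None:
        if len(target_pool) < n_targets:
            raise ValidationError("target_pool smaller than tfs * targets_per_tf")
        pool = [target_pool[i] for i in rng.permutation(len(target_pool))[:n_targets]]
    else:
        pool = [f"t{k+1}" for k in range(n_targets)]
    edges, strengths = [], {}
    k = 0
    for tf in names:
        for _ in range(targets_per_tf):
            target = pool[k]
            k += 1
            sign = "activator" if rng.random() < activator_fraction else "repressor"
            evidence = "direct" if rng.random() < direct_fraction else "indirect"
            edges.append(
                RegulatoryEdge(tf=tf, target=target, evidence=evidence, sign=sign)
            )
            strengths[(tf, target)] = effect_size if sign == "activator" else -effect_size
    return Regulon(network=InfluenceNetwork(edges=edges), strengths=strengths)


# ---------------------------------------------------------------------------
# Expression compendium
# ---------------------------------------------------------------------------

def simulate_expression(
    regulon: Regulon,
    n_samples: int = DEFAULT_N_SAMPLES,
    noise_sd: float = DEFAULT_NOISE_SD,
    knockout_fraction: float = DEFAULT_KNOCKOUT_FRACTION,
    decoy_genes: int = DEFAULT_DECOY_GENES,
    seed: int | None = None,
) -> ExpressionMatrix:
    """Linear-Gaussian expression for the planted regulon.

    TF rows are standard normal per sample; in a ``knockout_fraction`` of
    samples one random TF is clamped to its own sample minimum (emulating a
    perturbation experiment while keeping binarisation meaningful); each
    target is the signed-strength sum of its TFs plus N(0, noise_sd) noise;
    decoy genes are pure noise.
    """
    if n_samples < 1:
        raise ValidationError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    tf_ids = regulon.tf_ids
    target_ids = regulon.network.target_ids
    tf_values = rng.standard_normal((len(tf_ids), n_samples))
    n_ko = int(round(knockout_fraction * n_samples))
    if n_ko and tf_ids:
        ko_samples = rng.choice(n_samples, size=n_ko, replace=False)
        row_min = tf_values.min(axis=1)
        for s in ko_samples:
            i = rng.integers(len(tf_ids))
            tf_values[i, s] = row_min[i]
    tf_index = {tf: i for i, tf in enumerate(tf_ids)}
    target_values = rng.normal(0.0, noise_sd, (len(target_ids), n_samples))
    for t_idx, target in enumerate(target_ids):
        for e in regulon.network.edges:
            if e.target == target:
                w = regulon.strengths[(e.tf, e.target)]
                target_values[t_idx] += w * tf_values[tf_index[e.tf]]
    decoys = rng.standard_normal((decoy_genes, n_samples))
    gene_ids = tf_ids + target_ids + [f"dec{k+1}" for k in range(decoy_genes)]
    values = np.vstack([tf_values, target_values, decoys]) if decoy_genes else np.vstack(
        [tf_values, target_values]
    )
    return ExpressionMatrix(
        gene_ids=gene_ids,
        sample_ids=[f"s{j+1}" for j in range(n_samples)],
        values=values,
    )


# ---------------------------------------------------------------------------
# Ground-truth phenotypes
# ---------------------------------------------------------------------------

def simulate_truth_phenotypes(
    model: StoichiometricModel,
    network: InfluenceNetwork,
    evidence: tuple[str, ...] = ("direct",),
    tf_list: Sequence[str] | None = None,
) -> dict[str, float]:
    """Ground-truth knockout growth ratios from the planted network.

    Deleting a TF silences the enzyme genes it causally activates (its
    activator edges whose evidence class is in ``evidence``; the generator
    treats indirect edges as correlational only). Those genes are removed
    through the GPRs and the mutant/wild-type FBA ratio recorded.
    """
    wt = fba_optimize(model)
    if not wt.optimal or not wt.objective_value > 0:
        raise ValidationError("toy model must grow to define phenotype ratios")
    model_genes = model.genes
    out: dict[str, float] = {}
    for tf in (tf_list if tf_list is not None else network.tf_ids):
        lost = {
            e.target
            for e in network.edges_for_tf(tf)
            if e.sign == "activator" and e.evidence in evidence and e.target in model_genes
        }
        if not lost:
            out[tf] = 1.0
            continue
        res = fba_optimize(delete_genes(model, lost))
        growth = max(res.objective_value, 0.0) if res.optimal else 0.0
        out[tf] = growth / wt.objective_value + 0.0  # normalise -0.0
    return out


# ---------------------------------------------------------------------------
# The default end-to-end fixture
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """A complete synthetic study: model, planted network with strengths,
    expression compendium, and true knockout growth ratios."""

    model: StoichiometricModel
    network: InfluenceNetwork
    strengths: dict[tuple[str, str], float]
    expression: ExpressionMatrix
    true_growth_ratios: dict[str, float]
    generator_config: dict = field(default_factory=dict)

    @property
    def tf_ids(self) -> list[str]:
        return self.network.tf_ids

    @property
    def regulon(self) -> Regulon:
        return Regulon(network=self.network, strengths=self.strengths)


def make_ground_truth(
    n_tfs: int = 5,
    targets_per_tf: int = 8,
    decoy_genes: int = DEFAULT_DECOY_GENES,
    effect_size: float = DEFAULT_EFFECT_SIZE,
    noise_sd: float = DEFAULT_NOISE_SD,
    n_samples: int = DEFAULT_N_SAMPLES,
    knockout_fraction: float = DEFAULT_KNOCKOUT_FRACTION,
    activator_fraction: float = DEFAULT_ACTIVATOR_FRACTION,
    seed: int | None = None,
) -> GroundTruth:
    """The default synthetic study used throughout testing and evaluation.

    Half of each TF's targets are *direct* (causal) edges onto enzyme
    genes, half are *indirect*. Odd-numbered TFs are planted lethal: two of
    their direct activator targets are individually essential enzyme genes
    (chain steps or "and"-complex members). Even-numbered TFs are planted
    benign: their direct targets are redundant enzymes (isozyme/branch
    genes, never both members of one redundant unit), while two of their
    indirect edges point at essential bystander enzymes - genes whose
    expression tracks the TF but which stay functional when the TF is
    deleted. A method that constrains every correlated edge will falsely
    call those TFs growth-defective; an evidence-aware method will not.
    """
    if n_tfs < 2 or targets_per_tf < 4:
        raise ValidationError("fixture needs >= 2 TFs and >= 4 targets per TF")
    root = np.random.SeedSequence(seed)
    s_model, s_assign, s_expr = root.spawn(3)
    model = make_toy_model(n_linear=12, n_isozyme_pairs=6, n_branches=4, seed=s_model)
    rng = np.random.default_rng(s_assign)

    essential = [f"gl{i}" for i in range(12) if i % 3 != 2]
    essential += [f"gl{i}{ab}" for i in range(2, 12, 3) for ab in "ab"]
    redundant_units = [(f"gi{j}a", f"gi{j}b") for j in range(6)]
    redundant_units += [(f"gb{b}a", f"gb{b}b") for b in range(4)]
    essential = [essential[i] for i in rng.permutation(len(essential))]
    ess_iter = iter(essential)

    n_direct = targets_per_tf // 2
    n_indirect = targets_per_tf - n_direct
    edges: list[RegulatoryEdge] = []
    strengths: dict[tuple[str, str], float] = {}
    aux_counter = 0

    def add(tf: str, target: str, sign: str, evidence: str) -> None:
        edges.append(RegulatoryEdge(tf=tf, target=target, evidence=evidence, sign=sign))
        strengths[(tf, target)] = effect_size if sign == "activator" else -effect_size

    def draw_redundant(k: int) -> list[str]:
        units = rng.choice(len(redundant_units), size=k, replace=False)
        return [redundant_units[u][rng.integers(2)] for u in units]

    def rand_sign() -> str:
        return "activator" if rng.random() < activator_fraction else "repressor"

    for i in range(n_tfs):
        tf = f"TF{i+1}"
        lethal = i % 2 == 0
        if lethal:
            for g in (next(ess_iter), next(ess_iter)):
                add(tf, g, "activator", "direct")
            for g in draw_redundant(n_direct - 2):
                add(tf, g, rand_sign(), "direct")
            for _ in range(n_indirect):
                aux_counter += 1
                add(tf, f"aux{aux_counter}", rand_sign(), "indirect")
        else:
            for g in draw_redundant(n_direct):
                add(tf, g, rand_sign(), "direct")
            for g in (next(ess_iter), next(ess_iter)):
                # essential bystanders: correlated with the TF, causally independent
                add(tf, g, "activator", "indirect")
            for _ in range(n_indirect - 2):
                aux_counter += 1
                add(tf, f"aux{aux_counter}", rand_sign(), "indirect")

    network = InfluenceNetwork(edges=edges)
    regulon = Regulon(network=network, strengths=strengths)
    expression = simulate_expression(
        regulon,
        n_samples=n_samples,
        noise_sd=noise_sd,
        knockout_fraction=knockout_fraction,
        decoy_genes=decoy_genes,
        seed=s_expr,
    )
    true_ratios = simulate_truth_phenotypes(model, network)
    config = {
        "n_tfs": n_tfs,
        "targets_per_tf": targets_per_tf,
        "decoy_genes": decoy_genes,
        "effect_size": effect_size,
        "noise_sd": noise_sd,
        "n_samples": n_samples,
        "knockout_fraction": knockout_fraction,
        "activator_fraction": activator_fraction,
        "seed": seed,
    }
    return GroundTruth(
        model=model,
        network=network,
        strengths=strengths,
        expression=expression,
        true_growth_ratios=true_ratios,
        generator_config=config,
    )
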