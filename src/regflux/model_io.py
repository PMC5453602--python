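"""Domain types and file I/O for metabolic models, regulatory networks,
expression matrices, and knockout phenotype tables.

The native model interchange format is JSON::

    {"metabolites": [...],
     "reactions": [{"id": ..., "stoich": {met: coef}, "lb": ..., "ub": ...,
                    "gpr": ..., "exchange": ...}],
     "objective": "rxn_id"}

SBML Level 3 (+fbc gene associations) is accepted read-only through cobrapy
when it is installed. Networks, expression matrices and phenotype tables are
plain TSV. All readers validate their invariants and refuse to repair broken
input silently.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import sparse


class ParseError(ValueError):
    """A file could not be parsed under its declared format."""


class ValidationError(ValueError):
    """Parsed content violates a domain invariant."""


class ConfigurationError(ValueError):
    """A required field or setting is missing or inconsistent."""


EVIDENCE_LEVELS = ("direct", "indirect")
SIGNS = ("activator", "repressor", "unknown")

_GENE_TOKEN = re.compile(r"[A-Za-z0-9_.\-]+")
_GPR_KEYWORDS = frozenset({"and", "or"})


def gpr_genes(rule: str) -> frozenset[str]:
    """Gene identifiers appearing in a boolean gene-protein-reaction rule."""
    if not rule:
        return frozenset()
    return frozenset(
        tok for tok in _GENE_TOKEN.findall(rule) if tok.lower() not in _GPR_KEYWORDS
    )


# ---------------------------------------------------------------------------
# Stoichiometric model
# ---------------------------------------------------------------------------

@dataclass
class StoichiometricModel:
    """A constraint-based metabolic model.

    Attributes
    ----------
    metabolite_ids, reaction_ids
        Identifier lists; row/column labels of `stoichiometry`.
    stoichiometry
        Sparse metabolites x reactions coefficient matrix.
    lower_bound, upper_bound
        Per-reaction flux bounds (mmol/gDW/h, nominal).
    gpr
        Per-reaction boolean gene rule (``and``/``or``/parentheses) or "".
    objective_reaction
        Identifier of the biomass (objective) reaction.
    exchange_flags
        Per-reaction boolean marking boundary/exchange reactions.
    """

    metabolite_ids: list[str]
    reaction_ids: list[str]
    stoichiometry: sparse.csr_matrix
    lower_bound: np.ndarray
    upper_bound: np.ndarray
    gpr: list[str]
    objective_reaction: str
    exchange_flags: np.ndarray

    def __post_init__(self) -> None:
        self.stoichiometry = sparse.csr_matrix(self.stoichiometry)
        self.lower_bound = np.asarray(self.lower_bound, dtype=float)
        self.upper_bound = np.asarray(self.upper_bound, dtype=float)
        self.exchange_flags = np.asarray(self.exchange_flags, dtype=bool)
        self.validate()

    def validate(self) -> None:
        n_met, n_rxn = len(self.metabolite_ids), len(self.reaction_ids)
        if self.stoichiometry.shape != (n_met, n_rxn):
            raise ValidationError(
                f"stoichiometry shape {self.stoichiometry.shape} does not match "
                f"{n_met} metabolites x {n_rxn} reactions"
            )
        for arr, name in (
            (self.lower_bound, "lower_bound"),
            (self.upper_bound, "upper_bound"),
            (self.exchange_flags, "exchange_flags"),
        ):
            if arr.shape != (n_rxn,):
                raise ValidationError(f"{name} length {arr.shape} != {n_rxn} reactions")
        if len(self.gpr) != n_rxn:
            raise ValidationError("gpr list length does not match reaction count")
        bad = np.nonzero(self.lower_bound > self.upper_bound)[0]
        if bad.size:
            rid = self.reaction_ids[int(bad[0])]
            raise ValidationError(f"reaction {rid!r}: lower_bound > upper_bound")
        if len(set(self.reaction_ids)) != n_rxn:
            raise ValidationError("duplicate reaction identifiers")
        if len(set(self.metabolite_ids)) != n_met:
            raise ValidationError("duplicate metabolite identifiers")
        if self.objective_reaction not in self.reaction_ids:
            raise ConfigurationError(
                f"objective reaction {self.objective_reaction!r} not in model"
            )

    @property
    def genes(self) -> frozenset[str]:
        """All gene identifiers referenced by any GPR rule."""
        out: set[str] = set()
        for rule in self.gpr:
            out |= gpr_genes(rule)
        return frozenset(out)

    def reaction_index(self, reaction_id: str) -> int:
        try:
            return self.reaction_ids.index(reaction_id)
        except ValueError:
            raise KeyError(f"unknown reaction {reaction_id!r}") from None

    def copy(self) -> "StoichiometricModel":
        return StoichiometricModel(
            metabolite_ids=list(self.metabolite_ids),
            reaction_ids=list(self.reaction_ids),
            stoichiometry=self.stoichiometry.copy(),
            lower_bound=self.lower_bound.copy(),
            upper_bound=self.upper_bound.copy(),
            gpr=list(self.gpr),
            objective_reaction=self.objective_reaction,
            exchange_flags=self.exchange_flags.copy(),
        )


# ---------------------------------------------------------------------------
# Expression matrix
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of (log-scale) expression values."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError("duplicate gene identifiers in expression matrix")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("expression matrix contains non-finite values")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def row(self, gene: str) -> np.ndarray:
        try:
            return self.values[self.gene_ids.index(gene)]
        except ValueError:
            raise KeyError(f"unknown gene {gene!r}") from None

    def subset_samples(self, idx: Sequence[int]) -> "ExpressionMatrix":
        idx = list(idx)
        return ExpressionMatrix(
            gene_ids=list(self.gene_ids),
            sample_ids=[self.sample_ids[i] for i in idx],
            values=self.values[:, idx],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


# ---------------------------------------------------------------------------
# Regulatory network
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegulatoryEdge:
    """A TF -> target influence with evidence class and optional statistics.

    ``fdr`` is the bootstrap false discovery rate (1 minus the fraction of
    subset models selecting the TF); ``prom_prob`` is the PROM conditional
    probability P(target ON | TF OFF).
    """

    tf: str
    target: str
    evidence: str = "indirect"
    sign: str = "unknown"
    fdr: float | None = None
    prom_prob: float | None = None

    def __post_init__(self) -> None:
        if self.tf == self.target:
            raise ValidationError(f"self-edge {self.tf!r} -> {self.target!r}")
        if self.evidence not in EVIDENCE_LEVELS:
            raise ValidationError(f"unknown evidence {self.evidence!r}")
        if self.sign not in SIGNS:
            raise ValidationError(f"unknown sign {self.sign!r}")
        for name, value in (("fdr", self.fdr), ("prom_prob", self.prom_prob)):
            if value is not None and not (0.0 <= value <= 1.0):
                raise ValidationError(
                    f"{name}={value} outside [0,1] on edge {self.tf}->{self.target}"
                )


@dataclass
class InfluenceNetwork:
    """A set of TF -> target edges, unique per (tf, target) pair."""

    edges: list[RegulatoryEdge] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._by_pair: dict[tuple[str, str], RegulatoryEdge] = {}
        for e in self.edges:
            key = (e.tf, e.target)
            if key in self._by_pair:
                raise ValidationError(f"duplicate edge {e.tf!r} -> {e.target!r}")
            self._by_pair[key] = e

    @property
    def tf_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for e in self.edges:
            seen.setdefault(e.tf)
        return list(seen)

    @property
    def target_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for e in self.edges:
            seen.setdefault(e.target)
        return list(seen)

    def get(self, tf: str, target: str) -> RegulatoryEdge | None:
        return self._by_pair.get((tf, target))

    def edges_for_tf(self, tf: str) -> list[RegulatoryEdge]:
        return [e for e in self.edges if e.tf == tf]

    def __len__(self) -> int:
        return len(self.edges)

    def __iter__(self):
        return iter(self.edges)

    def with_edges(self, edges: Iterable[RegulatoryEdge]) -> "InfluenceNetwork":
        return InfluenceNetwork(edges=list(edges))

    def map_edges(self, fn) -> "InfluenceNetwork":
        """New network with ``fn(edge) -> edge`` applied to every edge."""
        return InfluenceNetwork(edges=[fn(e) for e in self.edges])


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

@dataclass
class PhenotypeTable:
    """Observed mutant/wild-type growth ratios per TF knockout."""

    tf: list[str]
    condition: list[str]
    growth_ratio: np.ndarray

    def __post_init__(self) -> None:
        self.growth_ratio = np.asarray(self.growth_ratio, dtype=float)
        n = len(self.tf)
        if len(self.condition) != n or self.growth_ratio.shape != (n,):
            raise ValidationError("phenotype table columns have mismatched lengths")
        if not np.all(np.isfinite(self.growth_ratio)):
            raise ValidationError("non-finite growth ratio")
        if np.any(self.growth_ratio < 0):
            raise ValidationError("negative growth ratio")

    def __len__(self) -> int:
        return len(self.tf)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"tf": self.tf, "condition": self.condition, "growth_ratio": self.growth_ratio}
        )

    def ratios_for(self, tfs: Sequence[str], condition: str | None = None) -> np.ndarray:
        """Growth ratios aligned to ``tfs`` (first match per TF)."""
        frame = self.to_frame()
        if condition is not None:
            frame = frame[frame["condition"] == condition]
        lookup = {t: r for t, r in zip(frame["tf"], frame["growth_ratio"])}
        missing = [t for t in tfs if t not in lookup]
        if missing:
            raise KeyError(f"phenotypes missing for TFs: {missing}")
        return np.array([lookup[t] for t in tfs], dtype=float)


# ---------------------------------------------------------------------------
# Model JSON I/O
# ---------------------------------------------------------------------------

def read_model(path: str | Path, format: str = "native-json") -> StoichiometricModel:
    """Read a metabolic model from native JSON or (optionally) SBML."""
    path = Path(path)
    if format == "native-json":
        return _read_model_json(path)
    if format == "sbml":
        return _read_model_sbml(path)
    raise ConfigurationError(f"unknown model format {format!r}")


def _read_model_json(path: Path) -> StoichiometricModel:
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path}: invalid JSON ({exc})") from exc
    for key in ("metabolites", "reactions", "objective"):
        if key not in doc:
            raise ParseError(f"{path}: missing top-level key {key!r}")
    metabolite_ids = list(doc["metabolites"])
    met_index = {m: i for i, m in enumerate(metabolite_ids)}
    reaction_ids, gpr, lb, ub, exchange = [], [], [], [], []
    rows, cols, vals = [], [], []
    for j, rec in enumerate(doc["reactions"]):
        try:
            rid = rec["id"]
            reaction_ids.append(rid)
            lb.append(float(rec["lb"]))
            ub.append(float(rec["ub"]))
            gpr.append(str(rec.get("gpr", "")))
            exchange.append(bool(rec.get("exchange", False)))
            for met, coef in rec.get("stoich", {}).items():
                if met not in met_index:
                    raise ParseError(
                        f"{path}: reaction {rid!r} references unknown metabolite {met!r}"
                    )
                rows.append(met_index[met])
                cols.append(j)
                vals.append(float(coef))
        except (KeyError, TypeError, ValueError) as exc:
            if isinstance(exc, ParseError):
                raise
            raise ParseError(f"{path}: malformed reaction record #{j}: {exc}") from exc
    stoich = sparse.csr_matrix(
        (vals, (rows, cols)), shape=(len(metabolite_ids), len(reaction_ids))
    )
    return StoichiometricModel(
        metabolite_ids=metabolite_ids,
        reaction_ids=reaction_ids,
        stoichiometry=stoich,
        lower_bound=np.array(lb),
        upper_bound=np.array(ub),
        gpr=gpr,
        objective_reaction=str(doc["objective"]),
        exchange_flags=np.array(exchange, dtype=bool),
    )


def _read_model_sbml(path: Path) -> StoichiometricModel:
    try:
        import cobra.io
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ConfigurationError("SBML ingestion requires the 'cobra' package") from exc
    cm = cobra.io.read_sbml_model(str(path))
    metabolite_ids = [m.id for m in cm.metabolites]
    met_index = {m: i for i, m in enumerate(metabolite_ids)}
    reaction_ids, gpr, lb, ub, exchange = [], [], [], [], []
    rows, cols, vals = [], [], []
    objective = None
    for j, rxn in enumerate(cm.reactions):
        reaction_ids.append(rxn.id)
        lb.append(rxn.lower_bound)
        ub.append(rxn.upper_bound)
        gpr.append(rxn.gene_reaction_rule or "")
        exchange.append(rxn.boundary)
        if rxn.objective_coefficient:
            objective = rxn.id
        for met, coef in rxn.metabolites.items():
            rows.append(met_index[met.id])
            cols.append(j)
            vals.append(float(coef))
    if objective is None:
        raise ConfigurationError(f"{path}: SBML model declares no objective reaction")
    stoich = sparse.csr_matrix(
        (vals, (rows, cols)), shape=(len(metabolite_ids), len(reaction_ids))
    )
    return StoichiometricModel(
        metabolite_ids=metabolite_ids,
        reaction_ids=reaction_ids,
        stoichiometry=stoich,
        lower_bound=np.array(lb),
        upper_bound=np.array(ub),
        gpr=gpr,
        objective_reaction=objective,
        exchange_flags=np.array(exchange, dtype=bool),
    )


def write_model(model: StoichiometricModel, path: str | Path) -> None:
    """Write a model in the native JSON interchange format."""
    coo = model.stoichiometry.tocoo()
    stoich_by_rxn: list[dict[str, float]] = [{} for _ in model.reaction_ids]
    for i, j, v in zip(coo.row, coo.col, coo.data):
        stoich_by_rxn[int(j)][model.metabolite_ids[int(i)]] = float(v)
    doc = {
        "metabolites": list(model.metabolite_ids),
        "reactions": [
            {
                "id": rid,
                "stoich": stoich_by_rxn[j],
                "lb": float(model.lower_bound[j]),
                "ub": float(model.upper_bound[j]),
                "gpr": model.gpr[j],
                "exchange": bool(model.exchange_flags[j]),
            }
            for j, rid in enumerate(model.reaction_ids)
        ],
        "objective": model.objective_reaction,
    }
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# Network TSV I/O
# ---------------------------------------------------------------------------

_NETWORK_COLS = ("tf", "target", "evidence", "sign", "fdr", "prom_prob")


def read_network(path: str | Path) -> InfluenceNetwork:
    """Read a TF->target edge list TSV (columns tf, target, evidence, sign
    and optionally fdr, prom_prob)."""
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        required = ("tf", "target", "evidence", "sign")
        for col in required:
            if col not in header:
                raise ParseError(f"{path}: missing column {col!r}")
        idx = {c: header.index(c) for c in header}
        edges = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            cells = line.rstrip("\n").split("\t")
            if len(cells) != len(header):
                raise ParseError(f"{path}:{lineno}: expected {len(header)} columns")

            def cell(col: str) -> str | None:
                if col not in idx:
                    return None
                v = cells[idx[col]].strip()
                return v if v not in ("", "NA", "nan") else None

            try:
                edge = RegulatoryEdge(
                    tf=cells[idx["tf"]].strip(),
                    target=cells[idx["target"]].strip(),
                    evidence=cells[idx["evidence"]].strip(),
                    sign=cells[idx["sign"]].strip(),
                    fdr=None if cell("fdr") is None else float(cell("fdr")),
                    prom_prob=None if cell("prom_prob") is None else float(cell("prom_prob")),
                )
            except (ValidationError, ValueError) as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            edges.append(edge)
    try:
        return InfluenceNetwork(edges=edges)
    except ValidationError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_network(network: InfluenceNetwork, path: str | Path) -> None:
    def fmt(v: float | None) -> str:
        return "" if v is None else repr(float(v))

    lines = ["\t".join(_NETWORK_COLS)]
    for e in network:
        lines.append(
            "\t".join([e.tf, e.target, e.evidence, e.sign, fmt(e.fdr), fmt(e.prom_prob)])
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Expression / phenotype TSV I/O
# ---------------------------------------------------------------------------

def read_expression(path: str | Path) -> ExpressionMatrix:
    """Read a genes x samples TSV (first column gene id, rest samples)."""
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if frame.index.has_duplicates:
        dup = frame.index[frame.index.duplicated()][0]
        raise ParseError(f"{path}: duplicate gene id {dup!r}")
    values = frame.to_numpy(dtype=float, na_value=np.nan)
    if not np.all(np.isfinite(values)):
        raise ParseError(f"{path}: non-numeric or missing expression values")
    return ExpressionMatrix(
        gene_ids=[str(g) for g in frame.index],
        sample_ids=[str(s) for s in frame.columns],
        values=values,
    )


def write_expression(expression: ExpressionMatrix, path: str | Path) -> None:
    frame = expression.to_frame()
    frame.index.name = "gene"
    frame.to_csv(path, sep="\t", float_format="%.10g")


def read_phenotypes(path: str | Path) -> PhenotypeTable:
    """Read a TSV with columns tf, condition, growth_ratio."""
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep="\t")
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc
    for col in ("tf", "condition", "growth_ratio"):
        if col not in frame.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    ratios = pd.to_numeric(frame["growth_ratio"], errors="coerce").to_numpy()
    if not np.all(np.isfinite(ratios)):
        raise ParseError(f"{path}: non-numeric growth_ratio")
    try:
        return PhenotypeTable(
            tf=[str(t) for t in frame["tf"]],
            condition=[str(c) for c in frame["condition"]],
            growth_ratio=ratios,
        )
    except ValidationError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_phenotypes(table: PhenotypeTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")
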