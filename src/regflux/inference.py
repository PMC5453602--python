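"""Bootstrap sparse-regression inference of TF -> target influences.

For every target gene, a lasso regression of its expression on candidate TF
expressions is fitted on many random sample subsets plus once on the full
compendium. A TF counts as "identified as a regulator" in a subset model
when its coefficient is nonzero at the cross-validated regularisation. The
per-edge false discovery rate is one minus the fraction of subset models
selecting the TF; edges passing an FDR cutoff (default 0.05) enter the
influence network, signed activator/repressor by the marginal Pearson
correlation between TF and target.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LassoCV

from .model_io import (
    ExpressionMatrix,
    InfluenceNetwork,
    RegulatoryEdge,
    ValidationError,
)

#: number of random sample subsets (plus one full-data model)
DEFAULT_N_SUBSETS = 200
#: fraction of samples drawn (without replacement) into each subset;
#: ~63.2% mimics the unique-sample coverage of a bootstrap resample
DEFAULT_SUBSET_FRACTION = 0.632
DEFAULT_FDR_CUTOFF = 0.05
#: size of the log-spaced regularisation grid searched by cross-validation;
#: the grid spans [ALPHA_EPS * alpha_max, alpha_max]
DEFAULT_N_ALPHAS = 16
ALPHA_EPS = 0.01
#: coefficients below this magnitude count as zero (lasso returns exact
#: zeros, this only guards against float noise)
COEF_TOL = 1e-8


@dataclass
class BootstrapTally:
    """Selection counts for one target across the subset models."""

    target: str
    counts: dict[str, int]
    n_subsets: int
    full_model_regulators: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_subsets < 1:
            raise ValidationError("n_subsets must be >= 1")
        bad = {tf: c for tf, c in self.counts.items() if not 0 <= c <= self.n_subsets}
        if bad:
            raise ValidationError(f"counts outside [0, n_subsets]: {bad}")


def fdr_from_tally(count: int, n_subsets: int) -> float:
    """False discovery rate from a bootstrap selection tally: 1 - count/n.

    A factor selected in 191 of 200 subset models gets
    FDR = 1 - 191/200 = 0.045.
    """
    if n_subsets < 1:
        raise ValidationError("n_subsets must be >= 1")
    if not 0 <= count <= n_subsets:
        raise ValidationError(f"count {count} outside [0, {n_subsets}]")
    return 1.0 - count / n_subsets


def fit_regulator_model(
    expression: ExpressionMatrix,
    candidate_tfs: list[str],
    target: str,
    sample_subset,
    *,
    cv: int = 5,
    n_alphas: int = DEFAULT_N_ALPHAS,
) -> dict[str, float]:
    """Sparse linear model of one target on candidate TF expressions.

    Returns ``{tf: coefficient}`` for the TFs with nonzero lasso
    coefficients at the regularisation chosen by ``cv``-fold
    cross-validation over the given sample subset. A target that is
    (numerically) constant across the subset yields an empty selection.
    """
    if target in candidate_tfs:
        raise ValidationError(f"target {target!r} may not be its own candidate TF")
    subset = np.asarray(list(sample_subset), dtype=int)
    min_n = max(10, math.ceil(len(candidate_tfs) / 2))
    if subset.size < min_n:
        raise ValidationError(
            f"subset of {subset.size} samples is below the minimum {min_n}"
        )
    y = expression.row(target)[subset]
    if np.std(y) < 1e-12:
        return {}
    X = np.column_stack([expression.row(tf)[subset] for tf in candidate_tfs])
    # standardise so the lasso penalty treats regulators symmetrically
    sd = X.std(axis=0)
    sd[sd < 1e-12] = 1.0
    Xs = (X - X.mean(axis=0)) / sd
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        fit = LassoCV(cv=cv, alphas=n_alphas, eps=ALPHA_EPS, max_iter=5000).fit(Xs, y)
    return {
        tf: float(coef / s)
        for tf, coef, s in zip(candidate_tfs, fit.coef_, sd)
        if abs(coef) > COEF_TOL
    }


def _canonical_sample_order(expression: ExpressionMatrix) -> np.ndarray:
    """Stable order of sample indices by sample id, so results do not depend
    on the column order of the input matrix."""
    return np.argsort(np.asarray(expression.sample_ids, dtype=object), kind="stable")


def bootstrap_tally(
    expression: ExpressionMatrix,
    candidate_tfs: list[str],
    target: str,
    n_subsets: int = DEFAULT_N_SUBSETS,
    subset_fraction: float = DEFAULT_SUBSET_FRACTION,
    seed: int | None = None,
    *,
    cv: int = 5,
    n_alphas: int = DEFAULT_N_ALPHAS,
) -> BootstrapTally:
    """Fit the regulator model on ``n_subsets`` random sample subsets plus
    once on all samples, and tally per-TF selection counts."""
    if n_subsets < 1:
        raise ValidationError("n_subsets must be >= 1")
    if not 0.0 < subset_fraction <= 1.0:
        raise ValidationError("subset_fraction must lie in (0,1]")
    rng = np.random.default_rng(seed)
    canon = _canonical_sample_order(expression)
    n = canon.size
    k = max(1, math.ceil(subset_fraction * n))
    counts = {tf: 0 for tf in candidate_tfs}
    for b in range(n_subsets):
        subset = canon[rng.choice(n, size=k, replace=False)]
        try:
            selected = fit_regulator_model(
                expression, candidate_tfs, target, subset, cv=cv, n_alphas=n_alphas
            )
        except ValidationError:
            raise
        except Exception as exc:  # pragma: no cover - defensive
            raise RuntimeError(f"subset model {b} for target {target!r} failed") from exc
        for tf in selected:
            counts[tf] += 1
    full = fit_regulator_model(
        expression, candidate_tfs, target, canon, cv=cv, n_alphas=n_alphas
    )
    return BootstrapTally(
        target=target, counts=counts, n_subsets=n_subsets, full_model_regulators=full
    )


def classify_sign(
    expression: ExpressionMatrix,
    tf: str,
    target: str,
    sample_mask=None,
) -> str:
    """Activator/repressor call from the marginal Pearson correlation of TF
    and target expression (positive -> activator, negative -> repressor).

    ``sample_mask`` restricts the correlation to a condition-relevant subset
    of samples.
    """
    x = expression.row(tf)
    y = expression.row(target)
    if sample_mask is not None:
        mask = np.asarray(sample_mask)
        x, y = x[mask], y[mask]
    if x.size < 3:
        raise ValidationError("sign classification requires at least 3 samples")
    if np.std(x) < 1e-12 or np.std(y) < 1e-12:
        raise ValidationError(
            f"sign of {tf!r} -> {target!r} undefined: constant expression series"
        )
    r = float(stats.pearsonr(x, y).statistic)
    if r > 0:
        return "activator"
    if r < 0:
        return "repressor"
    raise ValidationError(f"sign of {tf!r} -> {target!r} undefined: correlation is 0")


def infer_network(
    expression: ExpressionMatrix,
    tfs: list[str],
    targets: list[str],
    n_subsets: int = DEFAULT_N_SUBSETS,
    fdr_cutoff: float = DEFAULT_FDR_CUTOFF,
    seed: int | None = None,
    subset_fraction: float = DEFAULT_SUBSET_FRACTION,
    *,
    cv: int = 5,
    n_alphas: int = DEFAULT_N_ALPHAS,
) -> InfluenceNetwork:
    """Infer a TF -> target influence network by bootstrap tallying.

    Edges are exactly the (tf, target) pairs whose tally FDR is <= the
    cutoff; each carries its FDR and the activator/repressor sign from the
    full-sample correlation. Evidence defaults to "indirect" until annotated
    by the caller. Self-edges are excluded. Deterministic given ``seed``
    (one child seed per target, independent of target order).
    """
    if not 0.0 <= fdr_cutoff <= 1.0:
        raise ValidationError("fdr_cutoff must lie in [0,1]")
    root = np.random.SeedSequence(seed)
    # one named child stream per target: stable under target reordering
    child_seeds = {
        t: np.random.SeedSequence(
            entropy=root.entropy, spawn_key=(hash_target(t),)
        )
        for t in targets
    }
    edges: list[RegulatoryEdge] = []
    for target in targets:
        candidates = [tf for tf in tfs if tf != target]
        if not candidates:
            continue
        tally = bootstrap_tally(
            expression,
            candidates,
            target,
            n_subsets=n_subsets,
            subset_fraction=subset_fraction,
            seed=child_seeds[target],
            cv=cv,
            n_alphas=n_alphas,
        )
        for tf, count in tally.counts.items():
            fdr = fdr_from_tally(count, n_subsets)
            if fdr <= fdr_cutoff:
                edges.append(
                    RegulatoryEdge(
                        tf=tf,
                        target=target,
                        evidence="indirect",
                        sign=classify_sign(expression, tf, target),
                        fdr=fdr,
                    )
                )
    edges.sort(key=lambda e: (e.tf, e.target))
    return InfluenceNetwork(edges=edges)


def hash_target(target: str) -> int:
    """Stable non-negative 32-bit hash of a gene id (used to derive
    per-target random substreams)."""
    h = 2166136261
    for byte in target.encode():
        h = ((h ^ byte) * 16777619) & 0xFFFFFFFF
    return h
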