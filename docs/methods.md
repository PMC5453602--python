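# Methods

## Overview

`regflux` couples two model classes that are usually fitted separately:

1. a **constraint-based metabolic model** — a stoichiometric matrix *S*
   over reactions with flux bounds, boolean gene–protein–reaction (GPR)
   rules and a biomass objective, analysed by flux balance analysis
   (FBA: maximise biomass flux subject to *S·v = 0*, *lb ≤ v ≤ ub*) and
   flux variability analysis (FVA: per-reaction attainable flux range at a
   required fraction of the optimum); and
2. a **transcription-factor influence network** — TF→target edges with an
   activator/repressor sign, an evidence class (*direct* = supported by
   TF-binding evidence, *indirect* = association only), and per-edge
   statistics: a bootstrap false discovery rate (FDR) from sparse
   regression, and/or a PROM conditional probability P(target ON | TF OFF)
   estimated from binarised expression.

The coupling mechanism is shared by all three variants. Simulating the
knockout of TF *f*, every target gene *g* of *f* keeps a retention
probability Prob(*g* ON | *f* OFF) ∈ [0,1]; gene probabilities propagate
through GPR rules with AND→min and OR→max onto reactions; and each
affected reaction's bound is scaled to `Vmax·Prob`, where `Vmax` is the
reaction's *effective* capacity from FVA (the attainable extreme given
constraints throughout the network, not the nominal bound). The variants
differ only in the source of the gene probability:

| variant        | direct edge                        | indirect edge        |
|----------------|------------------------------------|----------------------|
| `PROM`         | P(ON \| OFF)                       | P(ON \| OFF)         |
| `IDREAM`       | FDR (activator), 1−FDR (repressor) | 1 (unconstrained)    |
| `IDREAM_hybrid`| FDR (activator), 1−FDR (repressor) | P(ON \| OFF)         |

The FDR-as-probability reading: if a factor is selected as a regulator of
a target in 191 of 200 bootstrap models, its FDR is 1 − 191/200 = 0.045,
and on deletion of an activating factor only 4.5% of the target's
activity is expected to remain. For a repressing factor the complement
1 − FDR (95.5%) is used: the target is disturbed but not shut down.

## Network inference (bootstrap sparse regression)

For each target gene, a lasso regression of its expression on candidate TF
expressions is fitted on `n_subsets` random sample subsets plus once on
the full compendium. A TF is *identified as a regulator* in one subset
model when its coefficient is nonzero at the regularisation chosen by
5-fold cross-validation within that subset. The per-pair FDR is
1 − count/`n_subsets`; pairs with FDR ≤ 0.05 enter the network. Edge sign
is the sign of the marginal Pearson correlation between TF and target over
all samples (a sample mask can restrict this to condition-relevant
samples).

Choices that the procedure leaves open, and what this package does:

* **Subset construction** — each subset draws ⌈63.2%⌉ of the samples
  without replacement (the unique-sample coverage of a bootstrap
  resample); exposed as `subset_fraction`.
* **Full-data model** — the 201st (full-sample) fit contributes signs and
  coefficients for reporting only; the FDR denominator is exactly the
  subset count.
* **Regularisation grid** — 16 log-spaced penalties spanning
  [0.01·α_max, α_max]. A coarse grid keeps the bootstrap affordable; with
  the favourable signal-to-noise of the synthetic compendium the selected
  support is insensitive to a finer grid.
* **Order invariance** — subsets are drawn over a canonical (sorted by
  sample id) ordering, so inference is invariant to the column order of
  the input matrix; per-target seeds are derived from a stable hash, so it
  is also invariant to target order.

## PROM probabilities

Expression is binarised per gene at its own `threshold_quantile` quantile
(default 0.33, the conventional PROM choice; ON strictly above). The
conditional probability is the ON-frequency of the target within the
TF-OFF samples. With fewer than `min_off_samples = 5` TF-OFF samples the
estimate is left at 1 (unconstrained) with a logged warning. No
significance filter is applied: every supplied edge receives a
probability.

## Knockout growth

Two constraint modes are provided. **hard** imposes `ub' = Prob·v_max`
(and `lb' = Prob·v_min` for a reversible reaction with `v_min < 0`)
exactly; an infeasible mutant LP is reported as growth 0 with a flag.
**soft** (default, the PROM lineage) keeps the model's own bounds hard but
charges violations of the scaled bounds to the objective at κ per flux
unit, via slack variables; as κ → ∞ it converges to hard mode (asserted
to 1e−4 on the test fixtures). Bounds only ever tighten toward zero: an
FVA capacity of exactly 0 stays 0 regardless of the probability (no
resurrection of dead reactions). `Vmax` is taken from FVA at
`fraction_of_optimum = 0` — the attainable range under stoichiometry and
bounds alone — configurable. Only the deleted TF's edges apply in a
single-knockout simulation; when several targets of one TF hit the same
reaction through different GPR leaves, min/max propagation resolves the
combination (no multiplicative stacking).

The end-to-end pipeline helper (`regflux.pipeline`) runs its growth
predictions in hard mode. On toy networks with near-unit biomass yield the
soft penalty at κ = 1 can sit exactly on the gain/penalty tie of the LP,
where reported growth depends on which optimal vertex the solver returns;
the hard bounds are free of that degeneracy while agreeing with soft mode
at large κ.

## Double perturbations and synthetic interactions

A TF knockout (probability constraints) is combined with a hard deletion
of one metabolic gene. The deleted gene's retention probability is forced
to 0 *before* GPR propagation, so the two perturbations compose: a TF
constraint parked on one isozyme becomes binding exactly when the
OR-partner is deleted. Each pair is scored by

    Diff1 = g_TF − g_double,  Diff2 = g_gene − g_double,
    variation = ((Diff1 + Diff2)/2) / g_WT

and called synthetic when variation > 0.9 (strict, "greater than 90%")
while both singles retain ≥ 0.95 of wild-type growth. Control pairs for
benchmarking are a seeded uniform draw from pairs with variation < 0.1.

## Evaluation statistics

* **MCC** (phi coefficient of the 2×2 confusion matrix) over growth-defect
  calls, where a knockout is *defective* iff its growth ratio is strictly
  below the threshold; thresholds sweep 0.1–0.95 in steps of 0.05, with
  0.2/0.5/0.95 highlighted. A zero factor in the denominator returns 0 by
  the standard convention (logged); a threshold at which the observed
  calls are single-class is reported as NaN, never silently 0.
* **PCC** with its p-value; two independent correlations are compared by
  the Fisher Z transform, z = atanh(r), SE = √(1/(n₁−3) + 1/(n₂−3)),
  two-tailed normal p.
* **Residual t-test** — paired two-tailed t-test on absolute residuals
  |pred − obs| of two prediction sets against the same observations.
* **SSE** is reported raw, per-observation, and relative to the total
  observed variance, each labelled, because a single canonical
  normalisation is not fixed by the procedure.
* **ROC/AUC** — Mann–Whitney normalisation with ties counted half, with
  the (negated) predicted ratio as the defect score.
* **Permutation significance** — the pipeline closure is rerun on
  permuted inputs; p is the fraction of permutations whose score strictly
  exceeds the observed one. Expression mode permutes each gene's values
  independently across samples (gene count fixed; a whole-matrix shuffle
  is available by flag); network mode shuffles the target column across
  edges, rejecting self-loops and duplicate pairs, which preserves the TF
  set, target multiset and edge count.

## Synthetic data: what it emulates and what it does not

The generator stands in for a microarray compendium, a curated regulatory
network and measured knockout growth rates, at desk scale.

* **Toy metabolic models** — an exchange intake (ub 10), serial gene-gated
  conversions with capacities drawn in [6, 9) so the chain bottleneck (not
  the intake) limits growth, every third serial step gated by a two-gene
  AND complex, OR-isozyme steps, redundant branch pairs sized in [10, 12)
  so either route alone suffices, and a biomass sink.
* **Expression** — linear-Gaussian: TF rows are standard normal; each
  target is the signed-strength sum of its TFs (±2.0 by default) plus
  N(0, 0.2) noise; decoys are pure noise. In 20% of samples one random TF
  is clamped to its own sample minimum, emulating perturbation
  experiments while keeping quantile binarisation meaningful (clamping to
  zero would distort the quantiles).
* **Evidence semantics** — *direct* edges are causal: the TF is required
  for its target enzyme's expression, so the knockout silences the gene.
  *Indirect* edges are correlational only: expression tracks the TF, but
  the enzyme stays functional when the TF is deleted. Ground-truth
  phenotypes therefore delete the genes behind direct activator edges
  (through the GPRs) and run FBA. This is the failure mode that separates
  evidence-aware integration from constraining every correlated edge: a
  method that constrains indirect edges falsely calls their TFs
  growth-defective.
* **Default study** (`make_ground_truth`) — 5 TFs × 8 targets, 6 decoy
  genes, 200 samples, effect 2.0, noise 0.2, on a 12/6/4
  (serial/isozyme/branch) model with 36 enzyme genes. Odd-numbered TFs
  are planted lethal (two individually essential direct activator
  targets); even-numbered TFs are planted benign (redundant direct
  targets, never both members of one isozyme/branch unit) but carry two
  indirect edges onto essential *bystander* enzymes.

Because targets are exact noisy-linear functions of their TFs, this is a
deliberately favourable case for lasso inference; `noise_sd` and the
decoy count are the difficulty dials. Passing recovery tests therefore
demonstrates the correctness of the pipeline's plumbing and the
direction of the evidence-split advantage — not expected performance on
real compendia, which have correlated noise, indirect cascades,
condition-specific regulation and non-linear effects the generator does
not model. The generator also makes no attempt to mimic real metabolic
network topology or compendium covariance.

## Numerical choices

* LP solving: scipy's HiGHS with primal feasibility 1e−9; solutions are
  asserted to satisfy mass balance and bounds at 1e−6. Only objective
  values are contractual — degenerate alternate optima are accepted.
* FVA at a positive optimality fraction subtracts a 1e−9 slack from the
  pinned objective bound to avoid spurious infeasibility, and clips
  solver jitter back into the declared bounds.
* GPR grammar: identifiers plus case-insensitive `and`/`or` and
  parentheses; AND binds tighter than OR; unknown genes are an error in
  boolean (deletion) evaluation and default to probability 1 in
  probability propagation.
* Gene identifiers are case-sensitive opaque strings; no name mapping is
  attempted.
* Lasso coefficients below 1e−8 count as zero (guarding float noise on
  top of the lasso's exact zeros).

## Problem sizes used by the test suite

The recovery study runs the default fixture with 50 bootstrap subsets
over 10 seeds; the permutation study runs a 3-TF fixture (60 samples,
8 subsets) with 100 permutations per mode, scaled down from the 500 used
at compendium scale, plus a 60-replicate uniformity check of the
permutation p-value under a null pipeline at 40 permutations each. These
sizes are the package's chosen desk-scale study conditions; all are
plain arguments and can be raised.

## Known limitations

* SBML ingestion is read-only and requires cobrapy; the native format is
  JSON.
* No parsimonious FBA, MOMA, or thermodynamic loop removal; no TF dosage
  (partial knockdown) modelling; no triple deletions.
* The PROM significance filter (KS-test gating of conditional
  probabilities) is omitted; every supplied edge receives a probability.
* The interaction scan reports the prediction side only; growth-curve
  analysis of validation experiments is out of scope.
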