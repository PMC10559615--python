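# Methods

This note documents the models and procedures implemented in `genesim`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic benchmarks do and do not show.

## Ontology model

The term graph is a DAG with child → parent edges tagged by relation kind.
Only `is_a` and `part_of` relationships are retained (the two relations the
Wang family of measures traverses); all other GO relations are dropped at
parse time. Obsolete terms are discarded. Multiple edges between the same
pair collapse to one per relation kind, and term ids are opaque strings.

A term's **children count** — the driver of the hybrid edge weight — is the
number of distinct terms with an edge into it, over both retained relation
kinds, counted on the *full* ontology rather than inside a gene's ancestor
subgraph. The weight expresses how specific a term is, which is a property
of the term itself; a per-subgraph count would make term–term similarity
depend on which gene queried it.

## Hybrid semantic similarity

Edge weight: `w = min(w_max, 1/(children + c) + d[relation])`.

| parameter | default | role |
|---|---|---|
| `c` | 2.0 | damping constant in the denominator (> 0) |
| `d[is_a]` | 0.3 | additive offset for `is_a` edges, in [0, 1) |
| `d[part_of]` | 0.2 | additive offset for `part_of` edges |
| `w_max` | 0.9 | upper clip, keeps every weight strictly below 1 |
| `weight_on` | `child` | whose children count feeds the weight |

The defaults are this package's choices: they keep every weight strictly
below 1, so semantic values decay along the ancestor direction and all
similarities stay inside [0, 1]. `is_a` carries a slightly larger offset
than `part_of`, mirroring the convention of fixed-weight Wang similarity
(0.8 vs 0.6) that subclass relations transmit more meaning than
part-whole relations. All four are exposed in `HGSConfig` and on the CLI.

For an edge t′ → t the recursion `S_X(t) = max(w · S_X(t′))` leaves open
whose children count parameterises `w`. The default uses the child t′ — the
term whose contribution is being propagated, and the term whose specificity
the weight is meant to discount. `weight_on="parent"` selects the other
reading; it is also what makes the fixed-weight equivalence check possible
(on a uniform-fanout DAG with `weight_on="parent"`, every traversed edge
has the same weight, and HGS must reproduce a fixed-weight Wang
implementation exactly).

Term-pair aggregation uses the shared-ancestor form
`sim(a,b) = Σ_{t∈T_a∩T_b}(S_a(t)+S_b(t)) / (SV(a)+SV(b))`; gene-pair
similarity is the best-match average over the two term sets. `sim(a,a)`
short-circuits to exactly 1.0 (the analytic value) to avoid 1-ulp drift
from summation order. Term-pair similarities are cached per unordered pair
when building the GFS matrix; gene order in the matrix is input order, so
output files are deterministic.

Genes whose annotations are all obsolete or out-of-namespace are rejected
with an error naming them; `drop_unannotated=True` downgrades this to a
logged warning, because silently losing cohort members is the kind of
thing that should never happen by accident.

## Resampling

SMOTE follows the classic construction: for each required synthetic row,
a base minority sample x_i, a neighbour x′ drawn uniformly from its k = 5
nearest minority neighbours (Euclidean distance, ties broken by lower
original index for determinism), and `x_s = x_i + u(x′ − x_i)` with
u ~ U(0,1). Base points cycle through the minority class in order; the
remainder is drawn uniformly without replacement. Neighbour search is
restricted to the minority class. Originals are never mutated, and every
synthetic row carries a `synthetic` flag that the evaluation layer uses to
audit leakage. If k exceeds the available neighbours it is reduced with a
logged warning; zero-length segments (duplicate rows) reproduce the point.

RUS subsamples the majority class uniformly without replacement, keeping
original row order. SMOTE-RUS first oversamples the minority to an
intermediate ratio r₁, then trims the majority to the target; r₁ defaults
to the geometric midpoint `sqrt(r₀ · target)` between the initial ratio r₀
and the target, a symmetric split in log-ratio space, and is configurable
because no canonical split exists.

## GBBRF

Gradient boosting under binary log-loss with a random forest as the
per-round weak learner. Defaults: 500 rounds, learning rate 0.1, λ = 5,
tree depth 3 — the published regularisation for this classifier — plus
10 trees per round, bootstrap row sampling and sqrt(p) features per split,
which are this package's realisation of the (undefined) forest internals.

Each round: p = σ(F), residuals r = y − p, Hessian h = p(1−p); every tree
is grown on a bootstrap sample of (x, r) by variance-reduction splits with
a 2-sample minimum leaf; every leaf value is then replaced by the one-step
Newton estimate `γ = Σ r / (Σ h + λ)`. Two declared choices:

* **λ sits in the Newton denominator** (XGBoost-style leaf regularisation),
  the standard placement for a leaf-value regulariser.
* **Leaf γ uses all training rows routed to the leaf**, not just the
  bootstrap rows that grew it. The full-data γ is the exact minimiser of
  the current loss's per-leaf quadratic model, which is what makes the
  recorded training log-loss non-increasing at small learning rates — a
  property the test suite asserts over all 500 rounds. (Every leaf of a
  fitted tree contains at least one training row, so the estimate is
  always defined.)

With one tree per round, no bootstrap and all features, the algorithm
reduces to classic gradient tree boosting; the suite verifies the loss
trace against an independently coded single-tree booster to 1e-9. The
model serialises to JSON (flat split/leaf arrays per tree) and predicts by
its own vectorised tree traversal, so a deserialised model needs nothing
beyond numpy. The decision threshold is fixed at 0.5; class imbalance is
handled upstream by resampling, not by class weights.

## Stacking

Level-0 learners produce **positive-class probabilities** as meta-features
(not hard labels — probabilities preserve ranking information; hard labels
are selectable via `meta_features="label"`). Out-of-fold protocol:
stratified `oof_folds` = 5 splits; each learner is trained on four folds
and scores the fifth, so no sample's meta-feature comes from a model that
saw its label (a spy-learner test asserts this structurally). The level-1
learner sees only the meta-features. For deployment, level-0 learners are
refit on the full training set — the standard stacked-generalisation
recipe. Base learners are scikit-learn implementations with conventional
defaults behind a uniform factory interface; SVM probabilities come from a
logistic link on the decision values rather than Platt-scaling CV.

## Evaluation

Stratified k-fold assignment delegates to scikit-learn's `StratifiedKFold`
(shuffled, seeded). Metrics are the confusion-matrix definitions with
precision/recall computed for the positive class only; degenerate
denominators report 0.0 with a logged warning. AUC-ROC is the
Mann–Whitney probability (ties counted ½), computed via
`sklearn.roc_auc_score` and cross-checked in the tests against a
brute-force pairwise-rank oracle. Aggregation over folds is an unweighted
mean by default; pooled-confusion aggregation is available
(`pooling="pooled"`).

`cross_validate` supports two pipeline orders. The default **safe** mode
splits first and resamples only the training folds, so evaluation rows are
always untouched originals — the report's `n_synthetic_in_test` field is
asserted to be zero. The **paper** mode resamples the whole dataset,
shuffles, then splits; synthetic near-copies of test points then appear in
training, which typically inflates scores. The mode is recorded in every
report so the two can never be confused. Per-fold resampling seeds are
derived as `seed + 7919·fold` to decorrelate folds.

## Synthetic data

The DAG generator builds a single-root layered graph: layer sizes grow
geometrically toward the leaves, every non-root term draws 1..`max_parents`
parents from the previous layer (acyclic by construction; parent counts are
skewed toward 1, as in real ontologies), and each edge is `part_of` with
probability 0.2, else `is_a`. Defaults — 300 terms, 6 layers, ≤ 2 parents —
give a graph whose depth and fan-out are in the range of a small
ontology branch.

The cohort generator plants a class signal: leaves are partitioned into a
"disease" pool (one side of a balanced split of root-child subtrees; every
leaf is assigned to a single primary subtree) and a "background" pool.
Positive genes draw `⌈signal · terms_per_gene⌉` terms from the disease
pool and the rest from background; negative genes draw only from
background. At `signal=0` the two classes are exchangeable (asserted up to
a 0.05 tolerance on mean similarities); at `signal=0.8` — the setting used
by the recovery tests — within-positive similarity clearly exceeds
between-class similarity. Cohort defaults (40 positive / 160 negative
genes, 8 terms per gene) emulate a high-confidence disease gene set
against a 4× background at annotation densities typical of
biological-process annotation.

The blob generator produces two spherical unit-variance Gaussians a given
distance apart, with requested class counts — the testbed for the
resamplers and boosting behaviour.

What these generators do **not** emulate: real GO's term-depth and fan-out
statistics, annotation-count skew across genes, correlated annotations
from shared literature, or any biological structure in the negative class.
Passing the recovery tests shows that the pipeline can exploit a planted
similarity signal at realistic sizes — not that it attains any particular
accuracy on real disease-gene data, which depends on database snapshots
this package deliberately does not bundle.

## Problem sizes

The test suite and the acceptance script run the full pipeline at
300 ontology terms and 200 genes with a reduced boosting budget inside
stacking (25 rounds × 5 trees); these sizes give stable results in minutes
on one CPU while exercising every code path. The GBBRF behavioural checks
(monotone loss over the full 500 rounds, log-odds initialisation, separable
-toy accuracy) run at the full default configuration on 200-sample blob
datasets.

## Known limitations

* The HGS weight parameters (c, d, w_max) have no published reference
  values; results on real data will depend on them.
* SMOTE interpolates in the GFS feature space, where synthetic rows are
  not themselves valid similarity profiles of any gene; this is inherent
  to applying SMOTE to similarity features.
* `paper` mode is provided for comparability, not recommended use.
* Single-label binary classification only; no multi-disease extension.
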