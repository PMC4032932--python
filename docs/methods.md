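# Methods

## Model and procedure

`netassess` measures the contribution of association networks to
guilt-by-association (GBA) gene function prediction. The unit of analysis is
one function label (e.g. a GO term) with its annotated gene set; the output
is the per-label relative change of three cross-validation ranking metrics
between a baseline and a subject network set.

### Gene universe and resolution

The gene universe of a run is the union of genes appearing in any selected
network (baseline or subject), so both rounds are evaluated over the same
candidate space. Identifiers are canonicalized by trimming whitespace and
case-folding. An optional two-column synonym table maps alternate to
canonical identifiers before resolution; an alternate mapping to more than
one canonical identifier is ambiguous and is removed outright together with
its edges, the conservative rule that avoids silently mis-assigning
associations. Annotation genes outside the universe are dropped; term sizes
for filtering are the sizes *after* resolution.

### Network normalization and integration

Each network is symmetrically degree-normalized, w′ᵢⱼ = wᵢⱼ/√(dᵢdⱼ) with
dᵢ the weighted degree, before any combination. This makes every
combination invariant to per-network rescaling and keeps hub rows from
dominating the composite.

Per-network combination weights solve an ordinary least-squares regression
of label-derived pair targets on network entries. With n genes, n₊
positives and n₋ negatives, the centered label vector is ȳᵢ = n₋/n for
positives and −n₊/n for negatives, and the target for gene pair (i,j) is
ȳᵢȳⱼ — large and positive for within-class pairs, negative for mixed pairs.
Regression rows are the off-diagonal upper-triangle pairs where at least
one candidate network has a nonzero normalized entry, plus an intercept
column; restricting to the union support keeps the (overwhelmingly) all-zero
pairs from flooding the fit. The system is solved through its normal
equations; for the "simultaneous" variant the rows are stacked over every
term of a collection (by default the run's own gold standard restricted to
terms of 3–300 genes), which reduces to multiplying the Gram matrix by the
term count and summing the right-hand sides.

Networks receiving a weight ≤ 0 are all removed and the system re-solved,
iterating until every surviving weight is positive — a deterministic,
order-free variant of non-negative weight fitting. Exact-duplicate entry
vectors are collapsed beforehand (the lexicographically first name
survives). If the design is singular (condition number above 1e12), or no
network survives elimination, the combiner falls back to equal weights 1/k;
with a single uninformative candidate this reproduces the plain normalized
network, which is the sensible neutral behavior.

The automatic selector uses the simultaneous algorithm for queries with
fewer than five **training** positives and the per-query unregularized
algorithm otherwise; small queries carry too little signal to fit weights
on their own. Because the simultaneous weights do not depend on the query,
the assessment driver computes them once per round and reuses them.

### Label propagation

Scores minimize Σᵢ(fᵢ−yᵢ)² + Σᵢⱼ wᵢⱼ(fᵢ−fⱼ)², i.e. solve (I+L)f = y with
L = D−W the combinatorial Laplacian of the composite and y the ±1 bias
(+1 training positives; −1 everything else under the auto-negatives
convention). The trade-off parameter between fitting the bias and
smoothness over the graph is fixed at 1: downstream ranking metrics are
invariant to affine rescalings of y, so the constant is not identifiable
from the outputs and is not exposed. (I+L) is symmetric positive definite;
the system is solved directly (dense) below 500 genes and by conjugate
gradients (relative tolerance 1e-9, at most 10,000 iterations) above.
Isolated genes get fᵢ = yᵢ exactly. Candidates are ranked by descending
score with ties broken by ascending identifier, making the realized order —
and hence every metric — fully deterministic.

### Cross-validation and %ERR

Positives of each term are shuffled by a per-term RNG seeded from
SHA-256(global seed, term id) and dealt round-robin into K folds (default
K=5). Seeding per term rather than from one global stream is what makes
results identical across thread counts and across partitions of the gold
standard into separate files, and guarantees the baseline and subject
rounds use byte-identical fold plans. Folds that hold out no positive — or
that would leave no training positive — are skipped.

For each evaluated fold: integrate on the training labels, propagate, rank
all genes except the training positives, and score the held-out positives
against all non-term genes. Metrics per fold:

* **AUROC** — probability a random positive precedes a random negative
  (rank-sum form on the realized order);
* **AUPR** — average precision: the mean, over positives in rank order, of
  the precision at each positive's rank (step-wise, no interpolation; exact
  for small worked examples and standard for function-prediction CV);
* **precision at 10% recall** — precision at the smallest cutoff whose
  recall reaches 0.10 (with ≤10 positives, the precision at the first
  retrieved positive).

Metrics are undefined (reported `NA`) when an evaluation class is empty.
Per-term values are unweighted means over evaluated folds, and
%ERR = subject/baseline − 1, undefined when the baseline mean is 0 or
undefined. Reports are sorted by descending %ERR-AUC-ROC with ties broken
by term id; metric columns print with nine significant digits and %ERR
columns with six decimals (trailing zeros trimmed), matching the
tool-style table layout. A seed of 0 (or none) draws a time-based seed and
logs it, so unseeded runs differ only in fold randomization.

### Summaries

`summarize` groups per-term records into term-size bins (canonically 3–10
and 11–300 annotations) and tabulates, per metric, the median and half the
spread between the 2.5th and 97.5th percentiles. The percentile half-width
is used as the 95% interval; it is a robust descriptive spread, not a
standard error of the median.

## Synthetic data

The generator plants GBA structure by a co-annotation (planted-partition)
construction: after drawing overlapping terms (sizes uniform in a range,
members sampled without replacement — overlap is allowed, as in GO), gene
pairs sharing a term receive an edge with probability `p_in` and all other
pairs with probability `p_out`; `p_in = p_out` yields a pure-noise network.
Edge weights default to uniform(0.1, 1.0) so that normalization is
exercised rather than trivial. Default scenario: 300 genes, 30 terms of
5–10 genes, `p_in` = 0.8, `p_out` = 0.02, 5-fold CV — sizes chosen so the
full differential assessment runs in seconds while each term still has
enough folds and negatives for stable metrics. An overlap trio (A, B
connected blocks on disjoint gene sets; C bridging both) reproduces the
synergy situation where a network's value appears only in combination.

What the generator does **not** emulate: heavy-tailed degree distributions,
group-correlated edge noise, biased annotation incompleteness, or the scale
of real compendia (hundreds of networks, 10⁴–10⁵ genes). Passing the
planted-signal tests therefore demonstrates that the pipeline detects and
quantifies genuine co-annotation signal and stays calibrated on noise — not
that any particular real network will show a given %ERR.

## Numerical choices and edge cases

* Duplicate undirected edges within a file collapse to the **maximum**
  weight (deterministic and order-free); self-loops are dropped with a
  warning; two-column rows default to weight 1.0.
* Edgeless networks are legal throughout: normalization is a no-op, the
  regression support is empty, integration falls back to equal weights, and
  propagation returns the bias — giving tie-rule-driven (i.e. random-like)
  rankings, which is the correct degenerate behavior.
* The regression Gram matrix is tiny ((k+1)² for k networks), so dense
  solves with an explicit condition-number guard are cheaper and more
  transparent than iterative or pseudo-inverse alternatives.
* Normalized matrices are scaled entry-wise by the single product
  1/√dᵢ·1/√dⱼ so that exact symmetry is preserved bit-for-bit.
* Per-term failures during a run are logged and omitted from the report
  rather than aborting the whole assessment.

## Known limitations

* The regression-based weighting assumes networks act additively on the
  pair targets; strongly redundant informative networks split weight in a
  data-dependent way (only exact duplicates are collapsed).
* Precision at 10% recall is coarse for terms with few positives (it is
  then just the reciprocal rank of the first hit).
* The percentile "95% interval" in summaries describes per-term spread;
  it is not a confidence interval for the median.
* No significance test is attached to %ERR differences; the report is
  descriptive and the intended use is ranking and triage of networks.
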