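# Methods

This note records the model assumptions, parameter choices and numerical
decisions behind `mlclust`, in the spirit of the methods documentation of
packages such as statsmodels or msprime.

## Similarity from an artificial contrast

The similarity of two examples is defined operationally: how often are
they treated alike by classifiers that separate the real data from a
structure-free copy of it? Negatives are built by permuting each
attribute column independently, so they have exactly the original
marginal distributions but no joint structure; any rule that beats the
class prior must therefore exploit *joint* patterns among attributes,
and two examples co-covered by many such rules share those patterns.
Nominal and numeric attributes, and missing values, are handled
uniformly: a rule condition on a missing value is simply not satisfied.

**Negatives ratio.** Problems with up to 200 examples get four negatives
per positive (stabilising the precision filter on small data); larger
problems get one per positive. Negatives are generated once per
similarity table.

**Rule sampler.** Each candidate rule draws k ~ uniform{1..max_conditions}
distinct attributes and anchors each condition at the values of one
randomly chosen positive example: nominal conditions are equality with
the anchor's category; numeric conditions are `x ≤ v` at the anchor's
value, or `x > m` with m the midpoint between the anchor's value and the
next lower observed value (decision-tree style, so the anchor itself is
always covered — anchoring `>` at the raw value would exclude the anchor
and, on separable data, yield no retainable rules at all). A candidate
is retained iff it covers ≥ 1 positive and its precision strictly
exceeds the positive class prior. Sampling stops at `n_rules` retained
rules or after `50 · n_rules` attempts.

A consequence worth knowing: when negatives are exact column
permutations, a single-condition rule covers negatives in exactly the
positive proportion, so its precision *equals* the prior and it is
always rejected — only conjunctions of two or more conditions, which can
exploit joint structure, enter the ensemble. The strict filter is thus
also a structure filter.

**Defaults.** `n_rules = 50,000` (the recommended ensemble size for
stable co-coverage statistics), `max_conditions = 3` (rules general
enough to co-cover many pairs; longer conjunctions cover too few
examples to contribute counts), seed-derived substreams for shuffling
and sampling so a rerun is bit-identical.

**Normalization.** Counts are divided by the global maximum of the count
matrix, diagonal included (the diagonal holds per-example coverage and
always attains the maximum, since co-coverage cannot exceed individual
coverage).

## The CRV score and the greedy merge criterion

CRV treats each row of the similarity table as data whose dispersion a
clustering should explain: if a cluster is right, the row values toward
co-members are alike, and the row values toward outsiders are alike.
CRV_i is the within-cluster plus outside-cluster sum of squared
deviations, each around its own mean; the diagonal x_ii is excluded
everywhere. The outside term pools *all* non-members, which makes CRV_i
independent of how the rest of the partition is arranged — so the merge
reduction (CRV_A + CRV_B) − CRV_{A∪B} is local, and equals the global
drop in Σ_C CRV_C. All means are kept in full precision; no intermediate
rounding.

Two structural facts shape the algorithm's behaviour:

- Merging two singletons can never increase CRV: the within term of a
  size-2 cluster is zero and removing a point from an outside set never
  increases its sum of squares. Reductions become negative only once the
  within-cluster term of larger clusters penalises heterogeneous merges
  — which is what finally stops the agglomeration.
- With several layers the merge condition is a conjunction: the pair's
  score is its *minimum* per-layer reduction, so structure present in
  one layer alone cannot force a merge. Multi-layer clusters are
  typically smaller than single-layer ones.

**Numerical choices.** A merge requires a reduction greater than
`epsilon = 1e-12` (floating-point guard on the strict inequality).
Pairs whose scores differ by less than `1e-9` are treated as tied and
broken by the lexicographically smallest sorted list of merged example
IDs; mathematically equal reductions computed along different float
routes differ at ~1e-16, and without the tie window the chosen merge
order would depend on rounding noise. Merges are strictly agglomerative
and the full merge hierarchy is kept in the trace, though only the final
partition is reported.

## Characterization statistics

Mann–Whitney z uses the normal approximation with tie correction and a
0.5 continuity correction, signed positive when the cluster tends
larger; the exact enumeration of the U null distribution appears only as
a test oracle. Only |z| and the direction are interpreted; **no
multiple-testing correction is applied when ranking features** — the
ranking is a screening device, not a set of confirmatory p-values.
Spearman correlations use average ranks for ties and pairwise-complete
observations. Nominal and constant attributes are skipped with a log
note rather than silently dropped.

## Skewness-reducing transforms

`log x`, `logit x` and `1/x` are available per numeric attribute and are
selected manually in the configuration: the appropriate transform
depends on what the variable measures, and no automatic skewness rule is
applied. Domain violations (log of a non-positive value, logit outside
(0, 1), reciprocal of zero) are errors naming the attribute and value;
missing values pass through untouched.

## The synthetic generator

`mlclust.synth` plants clusters that are coherent in every layer — the
structural assumption the multi-layer method exploits. Per layer and
numeric attribute, each of the K clusters receives a center on a grid
with spacing `signal · noise_sd` (grid positions permuted at random per
attribute), and members sample Gaussian around it with spread
`noise_sd`; per nominal attribute each cluster prefers one category with
probability 0.8, others uniform. Noise examples draw each attribute
independently from the pooled member values, mimicking the shuffled
contrast class. Missing values can be injected at a configurable rate
(default 0).

Defaults emulate a small multi-layer study: three clusters of 15
examples, two layers of ten numeric attributes, `signal = 4` (clearly
separated subgroups), `noise_sd = 1`. What the generator does *not*
emulate: realistic inter-attribute correlation structure within a
cluster, heavy-tailed or skewed marginals, informative missingness, or
layers of very unequal dimensionality. Tests passing on this generator
show the pipeline recovers clean planted joint structure; they do not
show robustness to the messiness of real cohort data.

At `signal = 0` the pipeline finds no planted structure (adjusted Rand
index near zero against the planted labels) although some merges still
occur — on pure noise many tiny positive reductions exist, and the
stopping rule only requires positivity. Recovery quality, not merge
count, is the meaningful null behaviour.

## Problem sizes in the tests

The test and acceptance suites run the full pipeline at 45 examples
(3 × 15), two layers of 10 numeric attributes, and ensembles of
1,500–5,000 rules over 5 seeds — small enough for a laptop-class single
CPU in well under a minute per configuration, large enough that the
recovery results (median adjusted Rand index at `signal = 4`) are
stable. Oracle-equivalence checks of the greedy engine use exhaustive
brute force at N = 8, where full enumeration is cheap.

## Known limitations

- The pair scan is O(K²) per iteration with cached cluster scores;
  fine into the low thousands of examples, not engineered beyond that.
- The stopping criterion is strictly greedy; it does not look ahead, and
  a merge that would pay off only after an intermediate
  variability-increasing step is never found.
- Rule-ensemble similarity is stochastic: different seeds give slightly
  different ESTs, and borderline merges near the stopping point can
  differ between seeds. Increase `n_rules` to stabilise.
- Characterization assumes numeric attributes for both the Mann–Whitney
  ranking and the Spearman screen; nominal attributes are only used in
  the similarity construction and the cross-tabulation.
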