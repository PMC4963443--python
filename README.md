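# mlclust

Multi-layer agglomerative clustering of examples (typically patients)
described by several disjoint groups of attributes ("layers", e.g. one
layer of biological measurements and one of clinical scores). The goal
is to find clusters that are coherent in *every* layer without choosing
a distance measure, the number of clusters, or their sizes.

## Method

For each layer an **example similarity table** (EST) is built through an
artificial classification task:

1. The N original examples are the positives. Negatives are made by
   shuffling each attribute column independently (4N of them for N ≤ 200,
   N otherwise) — same marginal values, destroyed joint structure.
2. An ensemble of random conjunctive rules (by default about 50,000) is
   sampled; a rule is kept only if it covers at least one positive and
   its precision on positives ∪ negatives strictly exceeds the positive
   class prior ("better than random").
3. For every pair of examples the number of retained rules covering both
   is counted; dividing all counts by the global maximum (the diagonal
   holds per-example coverage) gives the symmetric EST with values in
   [0, 1]. Similar examples — those whose attribute values co-occur in
   genuine joint patterns — are co-covered by many rules.

Clustering is guided by the **clustering-related variability** (CRV)
score. For example *i* in cluster *C*, with x_ij the EST row of *i*
(diagonal excluded):

    CRV_i = Σ_{j∈C, j≠i} (x_ij − x̄_wc)²  +  Σ_{j∉C} (x_ij − x̄_oc)²
    CRV_C = Σ_{i∈C} CRV_i

where x̄_wc and x̄_oc are the means of the within-cluster and
outside-cluster values of row *i*. Greedy bottom-up clustering starts
from singletons and repeatedly merges the pair of clusters with the
largest *merge reduction* CRV_A + CRV_B − CRV_{A∪B}; with several
layers, each pair is scored by its smallest per-layer reduction, so a
merge must reduce variability in all layers at once. The process stops
by itself when no pair gives a positive reduction — unclustered examples
simply remain singletons.

Clusters are then characterized by Mann–Whitney z-ranked distinguishing
features against a reference group, Spearman-correlated cross-layer
attribute pairs, and cross-tabulation against an external label.

## Worked example

The package ships a hand-checkable six-example similarity table
(`mlclust.datasets.six_example_est`) with two very similar examples
(ex2, ex5), three similar ones (ex1, ex3, ex4) and one outlier (ex6):

```python
from mlclust.datasets import six_example_est
from mlclust.crv import crv_example
from mlclust.clustering import cluster_single, report_clusters

est = six_example_est()
i = est.index_of("ex1")
for members in ({"ex1"}, {"ex1", "ex3"}, {"ex1", "ex3", "ex4"}):
    cluster = {est.index_of(m) for m in members}
    print(f"CRV(ex1 | {sorted(members)}) = {crv_example(est, i, cluster):.4f}")

partition, trace = cluster_single(est)
for record in trace:
    print(f"merge {record.iteration}: {record.members_a} + {record.members_b} "
          f"(reduction {record.min_reduction:.4f})")
print("final clusters:", report_clusters(partition))
```

prints

```
CRV(ex1 | ['ex1']) = 0.0855
CRV(ex1 | ['ex1', 'ex3']) = 0.0566
CRV(ex1 | ['ex1', 'ex3', 'ex4']) = 0.0033
merge 1: ('ex2',) + ('ex5',) (reduction 1.5445)
merge 2: ('ex1',) + ('ex4',) (reduction 0.0770)
merge 3: ('ex3',) + ('ex1', 'ex4') (reduction 0.1020)
final clusters: [['ex1', 'ex3', 'ex4'], ['ex2', 'ex5'], ['ex6']]
```

The CRV of ex1 falls as the examples it genuinely resembles join its
cluster, and the algorithm stops at three clusters on its own: merging
any two of the remaining clusters would *increase* variability in the
similarity table, so no further merge is attempted.

## Command line

```sh
mlclust synth --spec spec.yaml --out-dir data/          # planted-cluster data
mlclust est --layer data/layer1.csv --n-rules 50000 --seed 1 --out est1.csv
mlclust cluster --layers data/layer1.csv --layers data/layer2.csv \
        --n-rules 50000 --seed 1 --min-size 4 \
        --out clusters.json --trace trace.json
mlclust characterize --clusters clusters.json \
        --layers data/layer1.csv --layers data/layer2.csv \
        --labels data/labels.csv --out report.json
```

Every run logs its resolved configuration and seeds; identical inputs
and seeds give byte-identical outputs. `--est-cache DIR` caches ESTs
keyed by layer content and parameters, so clustering reruns skip the
(dominant) ensemble-learning cost.

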