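"""Clustering-related variability (CRV) of similarity-table rows.

For an example *i* in cluster *C*, the CRV score splits the squared
deviations of row *i* of the similarity table into a within-cluster part
(over members of *C* other than *i*, around their own mean) and an
outside-cluster part (over non-members, around the non-members' mean);
the diagonal entry x_ii is excluded throughout.  The cluster score
CRV_C sums the member scores.  Merging two clusters is worthwhile when
it lowers CRV_A + CRV_B, which is what greedy agglomeration maximises.

Because the outside-cluster term pools *all* non-members, CRV_i depends
only on the membership of i's own cluster — so the merge reduction is a
purely local quantity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import AbstractSet, Iterable

import numpy as np

from .est import SimilarityTable

Cluster = frozenset[int]


@dataclass
class Partition:
    """Disjoint non-empty clusters of example indices covering 0..N-1."""

    clusters: list[Cluster]
    example_ids: list[str]

    def __post_init__(self) -> None:
        self.clusters = [frozenset(c) for c in self.clusters]
        n = len(self.example_ids)
        seen: set[int] = set()
        for c in self.clusters:
            if not c:
                raise ValueError("empty cluster")
            if c & seen:
                raise ValueError("clusters are not disjoint")
            seen |= c
        if seen != set(range(n)):
            raise ValueError("clusters must cover every example exactly once")

    def labels(self) -> np.ndarray:
        """Integer cluster label per example (order of ``clusters``)."""
        out = np.empty(len(self.example_ids), dtype=int)
        for lab, c in enumerate(self.clusters):
            for i in c:
                out[i] = lab
        return out

    def member_ids(self, cluster: AbstractSet[int]) -> list[str]:
        return sorted(self.example_ids[i] for i in cluster)


def _check_member(i: int, cluster: AbstractSet[int]) -> None:
    if i not in cluster:
        raise ValueError(f"example index {i} is not in the cluster")


def crv_within(est: SimilarityTable, i: int, cluster: AbstractSet[int]) -> float:
    """Sum of squared deviations of x_ij over cluster co-members j != i.

    Zero for clusters of size one (no co-members) and size two (a single
    value equals its own mean).
    """
    _check_member(i, cluster)
    others = [j for j in cluster if j != i]
    if len(others) < 2:
        return 0.0
    vals = est.values[i, others]
    return float(np.sum((vals - vals.mean()) ** 2))


def crv_outside(est: SimilarityTable, i: int, cluster: AbstractSet[int]) -> float:
    """Sum of squared deviations of x_ij over non-members j (x_ii excluded)."""
    _check_member(i, cluster)
    outside = [j for j in range(est.n) if j not in cluster]
    if len(outside) < 2:
        return 0.0
    vals = est.values[i, outside]
    return float(np.sum((vals - vals.mean()) ** 2))


def crv_example(est: SimilarityTable, i: int, cluster: AbstractSet[int]) -> float:
    """CRV_i = within-cluster + outside-cluster squared deviations."""
    return crv_within(est, i, cluster) + crv_outside(est, i, cluster)


def crv_cluster(est: SimilarityTable, cluster: AbstractSet[int]) -> float:
    """CRV_C: sum of CRV_i over the members of the cluster."""
    if not cluster:
        raise ValueError("empty cluster")
    members = sorted(cluster)
    inside = np.array(members)
    mask = np.zeros(est.n, dtype=bool)
    mask[inside] = True
    outside = np.flatnonzero(~mask)
    total = 0.0
    for i in members:
        co = inside[inside != i]
        if len(co) >= 2:
            v = est.values[i, co]
            total += float(np.sum((v - v.mean()) ** 2))
        if len(outside) >= 2:
            v = est.values[i, outside]
            total += float(np.sum((v - v.mean()) ** 2))
    return total


def merge_reduction_free(est: SimilarityTable, a: AbstractSet[int], b: AbstractSet[int]) -> float:
    """Merge reduction without partition bookkeeping: CRV_A + CRV_B - CRV_{A∪B}."""
    if frozenset(a) == frozenset(b):
        raise ValueError("cannot merge a cluster with itself")
    if set(a) & set(b):
        raise ValueError("clusters overlap")
    return crv_cluster(est, a) + crv_cluster(est, b) - crv_cluster(est, set(a) | set(b))


def merge_reduction(
    est: SimilarityTable,
    partition: Partition,
    a: AbstractSet[int],
    b: AbstractSet[int],
) -> float:
    """Drop in summed CRV achieved by fusing clusters ``a`` and ``b``.

    Positive iff merging reduces variability.  ``a`` and ``b`` must be
    distinct clusters of ``partition``.
    """
    fa, fb = frozenset(a), frozenset(b)
    if fa == fb:
        raise ValueError("cannot merge a cluster with itself")
    if fa not in partition.clusters or fb not in partition.clusters:
        raise ValueError("both arguments must be clusters of the partition")
    return merge_reduction_free(est, fa, fb)
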