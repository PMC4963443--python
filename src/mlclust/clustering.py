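"""Greedy bottom-up clustering with an automatic stopping criterion.

Starting from singletons, each iteration merges the pair of clusters
whose merge most reduces the summed CRV score.  In the multi-layer case
the reduction is computed in every layer, the pair's score is the
*smallest* per-layer reduction, and the pair with the largest such
minimum is merged — so a merge must pay off in all layers at once.  The
process stops as soon as no pair gives a positive reduction; examples
that never merge simply remain singleton clusters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .crv import Cluster, Partition, crv_cluster
from .est import SimilarityTable

log = logging.getLogger(__name__)

#: Floating-point guard on the strictly-positive-reduction stopping test.
DEFAULT_EPSILON = 1e-12

#: Reductions closer than this are treated as tied, so the deterministic
#: lexicographic tie-break does not depend on the float route used to
#: compute a mathematically identical value.
TIE_TOLERANCE = 1e-9


@dataclass(frozen=True)
class MergeRecord:
    iteration: int
    members_a: tuple[str, ...]
    members_b: tuple[str, ...]
    reductions: tuple[float, ...]  # one per layer
    min_reduction: float

    def to_dict(self) -> dict:
        return {
            "iteration": self.iteration,
            "cluster_a": list(self.members_a),
            "cluster_b": list(self.members_b),
            "reductions": list(self.reductions),
            "min_reduction": self.min_reduction,
        }


@dataclass
class MergeTrace:
    """Ordered merge history; retains the full hierarchy of merges."""

    records: list[MergeRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, k):
        return self.records[k]

    def to_list(self) -> list[dict]:
        return [r.to_dict() for r in self.records]


def _greedy_merge(
    ests: list[SimilarityTable], epsilon: float
) -> tuple[Partition, MergeTrace]:
    ids = ests[0].example_ids
    n = len(ids)
    clusters: list[Cluster] = [frozenset({i}) for i in range(n)]
    trace = MergeTrace()
    if n < 2:
        return Partition(clusters, list(ids)), trace

    # CRV_i depends only on i's own cluster, so per-cluster scores are
    # cacheable across iterations.
    caches: list[dict[Cluster, float]] = [
        {c: crv_cluster(e, c) for c in clusters} for e in ests
    ]

    iteration = 0
    while len(clusters) > 1:
        best = None  # (min_reduction, tie_key, ia, ib, reductions, union_scores)
        for ia in range(len(clusters)):
            for ib in range(ia + 1, len(clusters)):
                a, b = clusters[ia], clusters[ib]
                union = a | b
                reds = []
                union_scores = []
                minimal = None
                for cache, e in zip(caches, ests):
                    u = cache.get(union)
                    if u is None:
                        u = crv_cluster(e, union)
                    union_scores.append(u)
                    r = cache[a] + cache[b] - u
                    reds.append(r)
                    minimal = r if minimal is None else min(minimal, r)
                if minimal <= epsilon:
                    continue
                key = tuple(sorted(ids[i] for i in union))
                if (
                    best is None
                    or minimal > best[0] + TIE_TOLERANCE
                    or (minimal > best[0] - TIE_TOLERANCE and key < best[1])
                ):
                    value = minimal if best is None else max(minimal, best[0])
                    best = (value, key, ia, ib, reds, union_scores)
        if best is None:
            break
        _, _, ia, ib, reds, union_scores = best
        a, b = clusters[ia], clusters[ib]
        union = a | b
        iteration += 1
        trace.records.append(
            MergeRecord(
                iteration=iteration,
                members_a=tuple(sorted(ids[i] for i in a)),
                members_b=tuple(sorted(ids[i] for i in b)),
                reductions=tuple(reds),
                min_reduction=min(reds),
            )
        )
        log.debug("merge %d: %s + %s (min reduction %.3g)",
                  iteration, sorted(a), sorted(b), min(reds))
        clusters = [c for k, c in enumerate(clusters) if k not in (ia, ib)]
        clusters.append(union)
        for cache, u in zip(caches, union_scores):
            cache[union] = u
    return Partition(clusters, list(ids)), trace


def cluster_single(
    est: SimilarityTable, epsilon: float = DEFAULT_EPSILON
) -> tuple[Partition, MergeTrace]:
    """Single-layer greedy agglomeration driven by CRV reduction."""
    return _greedy_merge([est], epsilon)


def cluster_multi(
    ests: list[SimilarityTable], epsilon: float = DEFAULT_EPSILON
) -> tuple[Partition, MergeTrace]:
    """Multi-layer agglomeration: a merge must reduce CRV in every layer."""
    if not ests:
        raise ValueError("need at least one similarity table")
    ids0 = ests[0].example_ids
    for e in ests[1:]:
        if e.example_ids != ids0:
            raise ValueError("all similarity tables must share example IDs in order")
    return _greedy_merge(list(ests), epsilon)


def report_clusters(partition: Partition, min_size: int = 1) -> list[list[str]]:
    """Clusters with at least ``min_size`` members, largest first.

    Members are listed by ID; ties in size are ordered by smallest
    member ID.
    """
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    rows = [partition.member_ids(c) for c in partition.clusters if len(c) >= min_size]
    rows.sort(key=lambda m: (-len(m), m[0]))
    return rows
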