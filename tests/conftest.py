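"""Shared fixtures and independent reference implementations.

The ``ref_*`` functions are deliberately plain-Python re-derivations of
the CRV arithmetic (explicit loops, no shared code with the package) so
that package results can be checked against an independent route.
"""

from __future__ import annotations

import numpy as np
import pytest

from mlclust.datasets import six_example_counts, six_example_est
from mlclust.est import SimilarityTable


@pytest.fixture
def six_est() -> SimilarityTable:
    return six_example_est()


@pytest.fixture
def six_counts():
    return six_example_counts()


def random_est(rng: np.random.Generator, n: int, n_rules: int = 60) -> SimilarityTable:
    """A valid similarity table from a random boolean coverage matrix."""
    p = rng.uniform(0.2, 0.8, size=(n_rules, 1))
    cov = rng.random((n_rules, n)) < p
    counts = cov.astype(int).T @ cov.astype(int)
    if counts.max() == 0:
        counts[0, 0] = 1
    return SimilarityTable(counts / counts.max(), [f"e{i:02d}" for i in range(n)])


# ---------------------------------------------------------------- reference CRV

def _ref_ss(values: list[float]) -> float:
    if len(values) < 2:
        return 0.0
    m = sum(values) / len(values)
    return sum((v - m) ** 2 for v in values)


def ref_crv_example(matrix, i: int, cluster: set[int]) -> float:
    n = len(matrix)
    inside = [float(matrix[i][j]) for j in sorted(cluster) if j != i]
    outside = [float(matrix[i][j]) for j in range(n) if j not in cluster]
    return _ref_ss(inside) + _ref_ss(outside)


def ref_crv_cluster(matrix, cluster: set[int]) -> float:
    return sum(ref_crv_example(matrix, i, cluster) for i in cluster)


def ref_total_crv(matrix, clusters: list[set[int]]) -> float:
    return sum(ref_crv_cluster(matrix, c) for c in clusters)


def ref_greedy(matrices, ids: list[str], epsilon: float = 1e-12, tie_tol: float = 1e-9):
    """Brute-force greedy agglomeration: at each step scan all pairs,
    score each by the global drop in total CRV per layer, take the pair
    with the largest minimal drop (drops within ``tie_tol`` are tied and
    broken by the lexicographically smallest merged ID list), stop when
    no pair's minimal drop exceeds epsilon.
    """
    clusters = [{i} for i in range(len(ids))]
    merges = []
    while len(clusters) > 1:
        best = None
        for x in range(len(clusters)):
            for y in range(x + 1, len(clusters)):
                drops = []
                for mat in matrices:
                    before = ref_total_crv(mat, clusters)
                    after_clusters = (
                        [c for k, c in enumerate(clusters) if k not in (x, y)]
                        + [clusters[x] | clusters[y]]
                    )
                    drops.append(before - ref_total_crv(mat, after_clusters))
                worst = min(drops)
                if worst <= epsilon:
                    continue
                key = tuple(sorted(ids[i] for i in clusters[x] | clusters[y]))
                if (
                    best is None
                    or worst > best[0] + tie_tol
                    or (worst > best[0] - tie_tol and key < best[1])
                ):
                    value = worst if best is None else max(worst, best[0])
                    best = (value, key, x, y)
        if best is None:
            break
        _, _, x, y = best
        merges.append((sorted(clusters[x]), sorted(clusters[y])))
        merged = clusters[x] | clusters[y]
        clusters = [c for k, c in enumerate(clusters) if k not in (x, y)] + [merged]
    return clusters, merges
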