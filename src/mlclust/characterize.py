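"""Cluster characterization: distinguishing features, correlations, cross-tabs.

A constructed cluster is described by (a) ranking numeric attributes by
the standardized Mann-Whitney statistic of cluster vs reference group,
(b) the most Spearman-correlated pairs of attributes across two layers
within the cluster, and (c) a contingency table of clusters against an
external categorical label.  Raw z-scores are reported without
multiple-testing correction — the ranking is exploratory, not
confirmatory.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .crv import Partition
from .data_io import DataLayer

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class FeatureScore:
    attribute: str
    z: float
    direction: int  # +1 cluster higher, -1 lower, 0 tied
    n_cluster: int
    n_reference: int

    def to_dict(self) -> dict:
        return {
            "attribute": self.attribute,
            "z": self.z,
            "direction": self.direction,
            "n_cluster": self.n_cluster,
            "n_reference": self.n_reference,
        }


@dataclass(frozen=True)
class PairCorrelation:
    biological: str
    clinical: str
    r_s: float
    n: int

    def to_dict(self) -> dict:
        return {
            "biological": self.biological,
            "clinical": self.clinical,
            "r_s": self.r_s,
            "n": self.n,
        }


def mannwhitney_z(a: Sequence[float], b: Sequence[float]) -> float:
    """Standardized Mann-Whitney U with tie and continuity corrections.

    Positive when group ``a`` tends to take larger values.  Missing
    values are dropped; each group must keep at least two observations.
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    na, nb = len(x), len(y)
    if na < 2 or nb < 2:
        raise ValueError("each group needs at least 2 non-missing values")
    n = na + nb
    ranks = stats.rankdata(np.concatenate([x, y]))
    u_a = ranks[:na].sum() - na * (na + 1) / 2.0
    mu = na * nb / 2.0
    _, tie_counts = np.unique(np.concatenate([x, y]), return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var = na * nb / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:  # every observation tied
        return 0.0
    d = u_a - mu
    if d == 0:
        return 0.0
    return float((d - 0.5 * math.copysign(1.0, d)) / math.sqrt(var))


def rank_features(
    cluster_ids: Iterable[str],
    reference_ids: Iterable[str],
    layer: DataLayer,
    top_k: int | None = None,
) -> list[FeatureScore]:
    """Numeric attributes ranked by |z| of cluster vs reference.

    Nominal attributes, and attributes with fewer than two non-missing
    values in either group, are skipped with a log note.  ``top_k``
    larger than the attribute count returns everything.
    """
    cset, rset = set(cluster_ids), set(reference_ids)
    if cset & rset:
        raise ValueError(f"cluster and reference overlap: {sorted(cset & rset)[:5]}")
    missing = (cset | rset) - set(layer.example_ids)
    if missing:
        raise ValueError(f"IDs not present in layer {layer.name!r}: {sorted(missing)[:5]}")
    scores: list[FeatureScore] = []
    for spec in layer.attributes:
        if spec.kind != "numeric":
            log.info("rank_features: skipping nominal attribute %r", spec.name)
            continue
        col = layer.data[spec.name]
        a = col.loc[sorted(cset)].to_numpy(dtype=float)
        b = col.loc[sorted(rset)].to_numpy(dtype=float)
        try:
            z = mannwhitney_z(a, b)
        except ValueError:
            log.info("rank_features: skipping %r (too few non-missing values)", spec.name)
            continue
        direction = 0 if z == 0 else (1 if z > 0 else -1)
        scores.append(FeatureScore(spec.name, z,
                                   direction,
                                   int(np.sum(~np.isnan(a))),
                                   int(np.sum(~np.isnan(b)))))
    scores.sort(key=lambda s: (-abs(s.z), s.attribute))
    if top_k is not None:
        scores = scores[:top_k]
    return scores


def spearman_best_pairs(
    bio: DataLayer,
    clin: DataLayer,
    subset_ids: Iterable[str],
    top_k: int | None = None,
) -> list[PairCorrelation]:
    """Spearman rank correlation for every cross-layer attribute pair.

    Computed over ``subset_ids`` (at least 3), with average ranks for
    ties and pairwise-complete observations; constant or nominal
    attributes are skipped with a log note.  Sorted by |r_s| descending.
    """
    subset = sorted(set(subset_ids))
    if len(subset) < 3:
        raise ValueError("need at least 3 examples for a rank correlation")
    for lay in (bio, clin):
        missing = set(subset) - set(lay.example_ids)
        if missing:
            raise ValueError(f"IDs not in layer {lay.name!r}: {sorted(missing)[:5]}")
    out: list[PairCorrelation] = []
    bio_cols = {
        a: bio.data[a].loc[subset].to_numpy(dtype=float)
        for a in bio.numeric_attributes()
    }
    clin_cols = {
        a: clin.data[a].loc[subset].to_numpy(dtype=float)
        for a in clin.numeric_attributes()
    }
    for a in bio.nominal_attributes():
        log.info("spearman_best_pairs: skipping nominal attribute %r", a)
    for a in clin.nominal_attributes():
        log.info("spearman_best_pairs: skipping nominal attribute %r", a)
    for ba, bv in bio_cols.items():
        for ca, cv in clin_cols.items():
            ok = ~np.isnan(bv) & ~np.isnan(cv)
            if ok.sum() < 3:
                log.info("spearman_best_pairs: skipping %r vs %r (n < 3)", ba, ca)
                continue
            if np.unique(bv[ok]).size < 2 or np.unique(cv[ok]).size < 2:
                log.info("spearman_best_pairs: skipping %r vs %r (constant values)", ba, ca)
                continue
            r, _ = stats.spearmanr(bv[ok], cv[ok])
            out.append(PairCorrelation(ba, ca, float(r), int(ok.sum())))
    out.sort(key=lambda p: (-abs(p.r_s), p.biological, p.clinical))
    if top_k is not None:
        out = out[:top_k]
    return out


def crosstab_labels(partition: Partition, labels: Mapping[str, str]) -> pd.DataFrame:
    """Clusters x label-categories contingency counts, largest cluster first.

    Every member ID must have a label; columns cover only the categories
    actually present.  Row sums equal cluster sizes by construction.
    """
    rows = []
    for c in partition.clusters:
        members = partition.member_ids(c)
        for m in members:
            if m not in labels:
                raise ValueError(f"no label for example ID {m!r}")
        rows.append(members)
    rows.sort(key=lambda m: (-len(m), m[0]))
    cluster_col, label_col = [], []
    for k, members in enumerate(rows):
        for m in members:
            cluster_col.append(f"cluster_{k + 1}")
            label_col.append(labels[m])
    table = pd.crosstab(
        pd.Series(cluster_col, name="cluster"),
        pd.Series(label_col, name="label"),
    )
    order = [f"cluster_{k + 1}" for k in range(len(rows))]
    return table.loc[order]
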