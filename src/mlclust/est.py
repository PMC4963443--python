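"""Example similarity tables (EST) from random-rule ensembles.

The similarity of examples within one layer is estimated through an
artificial classification task: the original examples are the positives,
and negatives are built by independently shuffling each attribute column
(preserving marginals, destroying inter-attribute structure).  An ensemble
of random conjunctive rules is kept only where a rule is better than
random at separating positives from negatives.  Examples covered together
by many rules are similar; pairwise co-coverage counts, normalized by the
largest count (diagonal included), give the EST — a symmetric N x N
matrix with values in [0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .data_io import NOMINAL, NUMERIC, DataLayer

log = logging.getLogger(__name__)

LE, GT, EQ = "<=", ">", "=="


@dataclass(frozen=True)
class Condition:
    attribute: str
    operator: str  # "<=", ">" for numeric; "==" for nominal
    constant: object

    def __str__(self) -> str:
        return f"{self.attribute} {self.operator} {self.constant!r}"


@dataclass(frozen=True)
class Rule:
    """Conjunction of attribute conditions.

    An example satisfies the rule iff it satisfies every condition; a
    missing value on any conditioned attribute means the example is not
    covered.
    """

    conditions: tuple[Condition, ...]

    def __post_init__(self) -> None:
        if not self.conditions:
            raise ValueError("a rule needs at least one condition")
        attrs = [c.attribute for c in self.conditions]
        if len(set(attrs)) != len(attrs):
            raise ValueError("at most one condition per attribute")

    def covers(self, layer: DataLayer) -> np.ndarray:
        """Boolean coverage vector over the layer's examples."""
        out = np.ones(layer.n_examples, dtype=bool)
        for cond in self.conditions:
            col = layer.data[cond.attribute]
            if cond.operator == EQ:
                out &= (col == cond.constant).to_numpy()
            else:
                vals = col.to_numpy(dtype=float)
                with np.errstate(invalid="ignore"):
                    hit = vals <= cond.constant if cond.operator == LE else vals > cond.constant
                out &= hit & ~np.isnan(vals)
        return out

    def __str__(self) -> str:
        return " AND ".join(str(c) for c in self.conditions)


@dataclass
class RuleEnsemble:
    rules: list[Rule]
    seed: int
    n_requested: int

    def __len__(self) -> int:
        return len(self.rules)


@dataclass
class CountMatrix:
    """Pairwise rule co-coverage counts; diagonal = per-example coverage."""

    counts: np.ndarray
    example_ids: list[str]

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 2 or c.shape[0] != c.shape[1] or c.shape[0] != len(self.example_ids):
            raise ValueError("counts must be square and match example_ids")
        if (c < 0).any() or not np.array_equal(c, c.T):
            raise ValueError("counts must be symmetric and non-negative")
        # co-coverage of (i, j) can never exceed the coverage of i alone
        if (c > np.diag(c)[:, None]).any():
            raise ValueError("off-diagonal count exceeds a diagonal count")
        self.counts = c.astype(np.int64)


@dataclass
class SimilarityTable:
    """Symmetric similarity matrix with entries in [0, 1]."""

    values: np.ndarray
    example_ids: list[str]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] != len(self.example_ids):
            raise ValueError("values must be square and match example_ids")
        if not np.allclose(v, v.T):
            raise ValueError("similarity table must be symmetric")
        if (v < 0).any() or (v > 1).any():
            raise ValueError("similarity values must lie in [0, 1]")
        self.values = v

    @property
    def n(self) -> int:
        return len(self.example_ids)

    def index_of(self, example_id: str) -> int:
        return self.example_ids.index(example_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.example_ids, columns=self.example_ids)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index_label="id")

    @classmethod
    def from_csv(cls, path: str | Path) -> "SimilarityTable":
        frame = pd.read_csv(path, index_col=0)
        ids = [str(i) for i in frame.index]
        if [str(c) for c in frame.columns] != ids:
            raise ValueError(f"{path}: row and column IDs differ")
        return cls(frame.to_numpy(dtype=float), ids)


@dataclass(frozen=True)
class ESTParams:
    """Knobs of the EST computation.

    ``n_rules`` follows the recommended ensemble size of about 50,000;
    ``max_conditions`` keeps rules general enough to co-cover pairs;
    ``attempt_factor`` bounds rejected candidates per retained rule.
    """

    n_rules: int = 50_000
    max_conditions: int = 3
    seed: int = 0
    attempt_factor: int = 50


def shuffle_negatives(layer: DataLayer, seed: int) -> DataLayer:
    """Build artificial negative examples by column-wise shuffling.

    Each attribute column of the negatives holds a random permutation of
    pooled copies of the original column (missing values shuffled along),
    so marginal value multisets are preserved while joint structure is
    destroyed.  Small problems (N <= 200) get 4N negatives, larger ones N.
    """
    n = layer.n_examples
    reps = 4 if n <= 200 else 1
    n_neg = reps * n
    rng = np.random.default_rng(seed)
    cols = {}
    for spec in layer.attributes:
        pool = np.tile(layer.data[spec.name].to_numpy(), reps)
        cols[spec.name] = rng.permutation(pool)
    ids = [f"neg{k:06d}" for k in range(n_neg)]
    frame = pd.DataFrame(cols, index=pd.Index(ids, name=layer.data.index.name))
    return DataLayer(f"{layer.name}__negatives", frame, list(layer.attributes))


def _coverage_of(conditions: list[tuple[str, str, object]], columns: dict, n: int) -> np.ndarray:
    out = np.ones(n, dtype=bool)
    for attr, op, const in conditions:
        kind, vals = columns[attr]
        if op == EQ:
            out &= vals == const
        elif op == LE:
            out &= vals <= const
        else:
            out &= vals > const
    return out


def _prep_columns(pos: DataLayer, neg: DataLayer) -> dict:
    """Stack positive and negative columns once for fast rule screening."""
    cols = {}
    for spec in pos.attributes:
        if spec.kind == NUMERIC:
            v = np.concatenate([
                pos.data[spec.name].to_numpy(dtype=float),
                neg.data[spec.name].to_numpy(dtype=float),
            ])
            # NaN compares False under <= and >, so missing is never covered
            cols[spec.name] = (NUMERIC, v)
        else:
            v = np.concatenate([
                pos.data[spec.name].to_numpy(dtype=object),
                neg.data[spec.name].to_numpy(dtype=object),
            ])
            cols[spec.name] = (NOMINAL, v)
    return cols


def learn_random_rules(
    pos: DataLayer,
    neg: DataLayer,
    n_rules: int,
    max_conditions: int = 3,
    seed: int = 0,
    attempt_factor: int = 50,
) -> RuleEnsemble:
    """Sample random conjunctive rules, keeping the better-than-random ones.

    Each candidate draws k ~ uniform{1..max_conditions} distinct
    attributes and anchors every threshold/category at the values of one
    randomly chosen positive example.  A candidate is retained only if it
    covers at least one positive and its precision on positives+negatives
    strictly exceeds the positive class prior.  Sampling stops after
    ``n_rules`` retained rules or ``attempt_factor * n_rules`` attempts
    (then fewer rules are returned with a warning).
    """
    if n_rules < 1:
        raise ValueError("n_rules must be >= 1")
    if [a.name for a in pos.attributes] != [a.name for a in neg.attributes]:
        raise ValueError("positives and negatives must share the attribute schema")
    rng = np.random.default_rng(seed)
    attrs = list(pos.attributes)
    m = len(attrs)
    n_pos, n_neg = pos.n_examples, neg.n_examples
    prior = n_pos / (n_pos + n_neg)
    columns = _prep_columns(pos, neg)
    pos_values = {a.name: pos.data[a.name].to_numpy() for a in attrs}
    non_missing = {
        a.name: pos.data[a.name].dropna().to_numpy() for a in attrs
    }
    # sorted unique observed values per numeric attribute, for midpoint
    # thresholds: "> v" anchored at value v uses the midpoint between v
    # and its predecessor so the anchoring example itself is covered
    sorted_uniques = {}
    for a in attrs:
        if a.kind == NUMERIC:
            v = columns[a.name][1]
            sorted_uniques[a.name] = np.unique(v[~np.isnan(v)])

    rules: list[Rule] = []
    budget = attempt_factor * n_rules
    attempts = 0
    n_total = n_pos + n_neg
    while len(rules) < n_rules and attempts < budget:
        attempts += 1
        k = int(rng.integers(1, max_conditions + 1))
        k = min(k, m)
        chosen = rng.choice(m, size=k, replace=False)
        anchor = int(rng.integers(n_pos))
        conditions: list[tuple[str, str, object]] = []
        for ai in chosen:
            spec = attrs[ai]
            v = pos_values[spec.name][anchor]
            if (isinstance(v, float) and np.isnan(v)) or v is None:
                pool = non_missing[spec.name]
                if len(pool) == 0:
                    continue
                v = pool[int(rng.integers(len(pool)))]
            if spec.kind == NUMERIC:
                v = float(v)
                if rng.random() < 0.5:
                    conditions.append((spec.name, LE, v))
                else:
                    uniq = sorted_uniques[spec.name]
                    k_lo = int(np.searchsorted(uniq, v)) - 1
                    if k_lo < 0:  # v is the minimum: no room below, keep the anchor covered
                        conditions.append((spec.name, LE, v))
                    else:
                        conditions.append((spec.name, GT, (uniq[k_lo] + v) / 2.0))
            else:
                conditions.append((spec.name, EQ, v))
        if not conditions:
            continue
        cov = _coverage_of(conditions, columns, n_total)
        pos_cov = int(cov[:n_pos].sum())
        if pos_cov == 0:
            continue
        total_cov = int(cov.sum())
        if pos_cov / total_cov <= prior:
            continue
        rules.append(Rule(tuple(Condition(*c) for c in conditions)))
    if len(rules) < n_rules:
        log.warning(
            "attempt budget exhausted: retained %d of %d requested rules",
            len(rules), n_rules,
        )
    return RuleEnsemble(rules, seed=seed, n_requested=n_rules)


def coverage_counts(ensemble: RuleEnsemble, pos: DataLayer) -> CountMatrix:
    """Count, for each example pair, the rules covering both examples."""
    if not ensemble.rules:
        raise ValueError("empty rule ensemble")
    cov = np.stack([r.covers(pos) for r in ensemble.rules])  # rules x N
    counts = cov.astype(np.int64).T @ cov.astype(np.int64)
    return CountMatrix(counts, pos.example_ids)


def normalize_counts(counts: CountMatrix) -> SimilarityTable:
    """Divide every count by the global maximum (diagonal included)."""
    peak = int(counts.counts.max())
    if peak == 0:
        raise ValueError("no rule covered any example")
    return SimilarityTable(counts.counts / peak, list(counts.example_ids),
                           meta={"max_count": peak})


def compute_est(layer: DataLayer, params: ESTParams = ESTParams()) -> SimilarityTable:
    """Full EST computation for one layer.

    Negatives are generated once per table; the shuffling and the rule
    sampler use seeds derived deterministically from ``params.seed`` so a
    rerun with the same layer and parameters is bit-identical.
    """
    ss = np.random.SeedSequence(params.seed)
    shuffle_seed, rule_seed = (int(s) for s in ss.generate_state(2) % (2**31))
    neg = shuffle_negatives(layer, shuffle_seed)
    ensemble = learn_random_rules(
        layer, neg,
        n_rules=params.n_rules,
        max_conditions=params.max_conditions,
        seed=rule_seed,
        attempt_factor=params.attempt_factor,
    )
    table = normalize_counts(coverage_counts(ensemble, layer))
    table.meta.update(
        layer=layer.name,
        seed=params.seed,
        shuffle_seed=shuffle_seed,
        rule_seed=rule_seed,
        n_rules_requested=params.n_rules,
        n_rules_retained=len(ensemble),
        max_conditions=params.max_conditions,
    )
    return table
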