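"""Example similarity tables: shuffled negatives, rule ensembles, co-coverage."""

import collections

import numpy as np
import pandas as pd
import pytest

from mlclust.data_io import AttributeSpec, DataLayer
from mlclust.est import (
    Condition,
    CountMatrix,
    ESTParams,
    Rule,
    RuleEnsemble,
    compute_est,
    coverage_counts,
    learn_random_rules,
    normalize_counts,
    shuffle_negatives,
)
from mlclust.synth import SynthSpec, generate_layered


def numeric_layer(values: np.ndarray, name="layer", prefix="a") -> DataLayer:
    ids = [f"p{i:03d}" for i in range(values.shape[0])]
    cols = {f"{prefix}{j}": values[:, j] for j in range(values.shape[1])}
    frame = pd.DataFrame(cols, index=pd.Index(ids, name="id"))
    return DataLayer(name, frame, [AttributeSpec(c, "numeric") for c in cols])


class TestShuffleNegatives:
    def test_small_problems_get_four_times_as_many(self):
        rng = np.random.default_rng(0)
        layer = numeric_layer(rng.normal(size=(150, 2)))
        neg = shuffle_negatives(layer, seed=1)
        assert neg.n_examples == 600

    def test_large_problems_get_the_same_number(self):
        rng = np.random.default_rng(0)
        layer = numeric_layer(rng.normal(size=(201, 2)))
        neg = shuffle_negatives(layer, seed=1)
        assert neg.n_examples == 201

    def test_column_multisets_preserved(self):
        rng = np.random.default_rng(2)
        layer = numeric_layer(rng.integers(0, 5, size=(20, 3)).astype(float))
        neg = shuffle_negatives(layer, seed=3)
        for col in layer.data.columns:
            orig = collections.Counter(layer.data[col])
            shuf = collections.Counter(neg.data[col])
            assert shuf == {k: 4 * v for k, v in orig.items()}

    def test_missing_values_shuffled_along(self):
        vals = np.array([[1.0], [np.nan], [3.0], [np.nan]])
        layer = numeric_layer(vals)
        neg = shuffle_negatives(layer, seed=0)
        assert int(neg.data["a0"].isna().sum()) == 8


class TestLearnRandomRules:
    def _separable(self):
        """Positives all have a=1; hand-built negatives all have a=0."""
        pos = numeric_layer(np.ones((10, 1)))
        neg = numeric_layer(np.zeros((40, 1)), name="neg")
        return pos, neg

    def test_separable_rules_cover_only_positives(self):
        pos, neg = self._separable()
        ens = learn_random_rules(pos, neg, n_rules=30, max_conditions=1, seed=0)
        assert len(ens) == 30
        for rule in ens.rules:
            assert rule.covers(pos).sum() >= 1
            assert rule.covers(neg).sum() == 0

    def test_retained_rules_beat_the_class_prior(self):
        ds, _ = generate_layered(SynthSpec(cluster_sizes=(8, 8), n_noise=4,
                                           attrs_per_layer=((3, 1),), seed=5))
        pos = ds.layers[0]
        neg = shuffle_negatives(pos, seed=6)
        prior = pos.n_examples / (pos.n_examples + neg.n_examples)
        ens = learn_random_rules(pos, neg, n_rules=200, seed=7)
        for rule in ens.rules:
            p = rule.covers(pos).sum()
            n = rule.covers(neg).sum()
            assert p >= 1 and p / (p + n) > prior

    def test_zero_rules_requested_errors(self):
        pos, neg = self._separable()
        with pytest.raises(ValueError, match="n_rules"):
            learn_random_rules(pos, neg, n_rules=0)

    def test_exhausted_budget_returns_fewer_with_warning(self, caplog):
        # a one-attribute constant layer: every candidate covers everything,
        # so precision always equals the prior and nothing is retained
        pos = numeric_layer(np.ones((5, 1)))
        neg = shuffle_negatives(pos, seed=0)
        with caplog.at_level("WARNING"):
            ens = learn_random_rules(pos, neg, n_rules=10, seed=1, attempt_factor=5)
        assert len(ens) < 10
        assert "budget" in caplog.text

    def test_rule_rejects_duplicate_attribute_conditions(self):
        with pytest.raises(ValueError, match="one condition"):
            Rule((Condition("a", "<=", 1.0), Condition("a", ">", 0.0)))


class TestCoverageCounts:
    def test_single_rule_covering_two_examples(self):
        layer = numeric_layer(np.array([[1.0], [1.0], [5.0]]))
        rule = Rule((Condition("a0", "<=", 2.0),))
        ens = RuleEnsemble([rule], seed=0, n_requested=1)
        counts = coverage_counts(ens, layer).counts
        expected = np.zeros((3, 3), dtype=int)
        expected[:2, :2] = 1
        assert np.array_equal(counts, expected)

    def test_missing_value_is_never_covered(self):
        layer = numeric_layer(np.array([[np.nan], [1.0]]))
        rule = Rule((Condition("a0", "<=", 2.0),))
        assert rule.covers(layer).tolist() == [False, True]

    def test_brute_force_recount_matches(self):
        """Independent double loop over rules x pairs on a 5-example instance."""
        rng = np.random.default_rng(11)
        layer = numeric_layer(rng.normal(size=(5, 3)))
        neg = shuffle_negatives(layer, seed=12)
        ens = learn_random_rules(layer, neg, n_rules=20, seed=13)
        counts = coverage_counts(ens, layer).counts
        for i in range(5):
            for j in range(5):
                manual = sum(
                    1 for r in ens.rules
                    if r.covers(layer)[i] and r.covers(layer)[j]
                )
                assert counts[i, j] == manual

    def test_diagonal_dominates_rows_on_random_layers(self):
        for seed in range(5):
            ds, _ = generate_layered(SynthSpec(cluster_sizes=(6, 6),
                                               attrs_per_layer=((2, 2),), seed=seed))
            pos = ds.layers[0]
            neg = shuffle_negatives(pos, seed=seed)
            ens = learn_random_rules(pos, neg, n_rules=100, seed=seed)
            c = coverage_counts(ens, pos).counts
            assert (np.diag(c)[:, None] >= c).all()

    def test_count_matrix_invariants_enforced(self):
        with pytest.raises(ValueError, match="exceeds"):
            CountMatrix(np.array([[1, 2], [2, 3]]), ["a", "b"])


class TestNormalizeCounts:
    def test_six_example_entries_at_two_decimals(self, six_counts):
        est = normalize_counts(six_counts)
        assert round(est.values[0, 3], 2) == 0.29  # count 28 / max 97
        assert round(est.values[2, 2], 2) == 0.48  # count 47 / max 97
        assert est.meta["max_count"] == 97

    def test_single_nonzero_entry_becomes_one(self):
        c = np.zeros((3, 3), dtype=int)
        c[1, 1] = 5
        est = normalize_counts(CountMatrix(c, ["a", "b", "c"]))
        assert est.values[1, 1] == 1.0 and est.values.sum() == 1.0

    def test_all_zero_matrix_errors(self):
        with pytest.raises(ValueError, match="no rule"):
            normalize_counts(CountMatrix(np.zeros((2, 2), dtype=int), ["a", "b"]))


class TestComputeEst:
    PARAMS = ESTParams(n_rules=400, seed=42)

    def test_same_seed_is_bit_identical(self):
        ds, _ = generate_layered(SynthSpec(cluster_sizes=(8, 8),
                                           attrs_per_layer=((4, 0),), seed=1))
        a = compute_est(ds.layers[0], self.PARAMS)
        b = compute_est(ds.layers[0], self.PARAMS)
        assert np.array_equal(a.values, b.values)

    def test_identical_examples_share_the_diagonal_value(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(size=(8, 3))
        vals[1] = vals[0]  # two identical examples
        est = compute_est(numeric_layer(vals), self.PARAMS)
        assert est.values[0, 1] == est.values[0, 0] == est.values[1, 1]

    def test_two_blobs_are_more_similar_within_than_between(self):
        rng = np.random.default_rng(4)
        blob1 = rng.normal(0.0, 0.5, size=(10, 4))
        blob2 = rng.normal(6.0, 0.5, size=(10, 4))
        est = compute_est(numeric_layer(np.vstack([blob1, blob2])), self.PARAMS)
        v = est.values
        within = (v[:10, :10].mean() + v[10:, 10:].mean()) / 2
        between = v[:10, 10:].mean()
        assert within > between

    def test_output_invariants(self):
        ds, _ = generate_layered(SynthSpec(cluster_sizes=(6, 6),
                                           attrs_per_layer=((3, 1),), seed=9))
        est = compute_est(ds.layers[0], self.PARAMS)
        v = est.values
        assert np.allclose(v, v.T) and v.min() >= 0 and v.max() == 1.0
        assert v.max() == np.diag(v).max()  # peak attained on the diagonal

    def test_csv_round_trip(self, tmp_path, six_est):
        path = tmp_path / "est.csv"
        six_est.to_csv(path)
        again = type(six_est).from_csv(path)
        assert again.example_ids == six_est.example_ids
        np.testing.assert_allclose(again.values, six_est.values)
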