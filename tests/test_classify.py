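import numpy as np
import pandas as pd
import pytest

from anrs import (
    ConfigurationError,
    HybridRecord,
    HybridSchema,
    HybridTable,
    SyntheticSpec,
    evaluate_holdout,
    evaluate_kfold,
    fit_distance_params,
    generate_hybrid_dataset,
    predict,
    radius_sweep,
)
from conftest import random_hybrid_table
from oracles import brute_nearest_neighbor


class TestPredict:
    def test_exact_match_dominates(self, toy_table):
        params = fit_distance_params(toy_table)
        pred = predict(toy_table.record(4), toy_table, params, r=0.002)
        assert pred.label == "n"
        assert not pred.tie_broken
        assert sum(pred.votes.values()) == len(pred.neighborhood.members)

    def test_tie_broken_by_mean_member_distance(self):
        # 2-vs-2 vote: class "a" members near the query, class "b" far;
        # r = 1 puts all four in the neighborhood.
        schema = HybridSchema(attributes=(("v", "numeric"),), decision="cls")
        train = HybridTable(
            schema,
            pd.DataFrame({"v": [0.9, 1.1, 2.9, 3.1], "cls": ["a", "a", "b", "b"]}),
        )
        params = fit_distance_params(train)
        pred = predict(HybridRecord({"v": 1.0}), train, params, r=1.0)
        assert pred.votes == {"a": 2, "b": 2}
        assert pred.label == "a"
        assert pred.tie_broken

    def test_lexical_tie_break_when_distances_equal(self):
        schema = HybridSchema(attributes=(("v", "numeric"),), decision="cls")
        train = HybridTable(
            schema, pd.DataFrame({"v": [0.0, 2.0], "cls": ["b", "a"]})
        )
        params = fit_distance_params(train)
        pred = predict(HybridRecord({"v": 1.0}), train, params, r=1.0)
        assert pred.label == "a"  # equal votes, equal mean distance
        assert pred.tie_broken

    @pytest.mark.parametrize("seed", range(10))
    def test_r_zero_equals_nearest_neighbor_oracle(self, seed):
        rng = np.random.default_rng(seed)
        train = random_hybrid_table(rng, n=int(rng.integers(5, 20)))
        params = fit_distance_params(train)
        for _ in range(5):
            query = HybridRecord(
                {
                    "x0": float(rng.normal()),
                    "x1": float(rng.normal()),
                    "s0": ["ab", "abc", "xyz"][int(rng.integers(0, 3))],
                    "s1": ["ab", "abc", "xyz"][int(rng.integers(0, 3))],
                }
            )
            pred = predict(query, train, params, r=0.0)
            assert pred.label == brute_nearest_neighbor(train, query, params)


class TestKFold:
    def test_fold_shapes_and_mean(self):
        table = generate_hybrid_dataset(SyntheticSpec(n=100, seed=4))
        report = evaluate_kfold(table, k=10, seed=1)
        assert report.k == 10 and len(report.fold_accuracies) == 10
        assert report.mean_accuracy == pytest.approx(
            float(np.mean(report.fold_accuracies))
        )
        assert all(0.0 <= a <= 1.0 for a in report.fold_accuracies)

    def test_separable_table_is_perfect(self):
        spec = SyntheticSpec(
            n=200, separation=8.0, cat_fidelity=1.0, label_noise=0.0, seed=7
        )
        table = generate_hybrid_dataset(spec)
        report = evaluate_kfold(table, k=10, r=0.002, seed=7)
        assert report.mean_accuracy == 1.0

    def test_reproducible_bit_identical(self):
        table = generate_hybrid_dataset(SyntheticSpec(n=80, seed=2))
        a = evaluate_kfold(table, k=5, r=0.002, seed=9)
        b = evaluate_kfold(table, k=5, r=0.002, seed=9)
        assert a == b and a.to_json() == b.to_json()

    def test_k_larger_than_table_rejected(self):
        table = generate_hybrid_dataset(SyntheticSpec(n=8, seed=0))
        with pytest.raises(ConfigurationError):
            evaluate_kfold(table, k=9)

    def test_label_shuffled_data_near_majority_rate(self):
        # fully noisy labels: accuracy should sit near the majority-class rate
        table = generate_hybrid_dataset(
            SyntheticSpec(n=400, separation=3.0, label_noise=0.0, seed=3)
        )
        rng = np.random.default_rng(12)
        df = table.df.copy()
        df["class"] = rng.permutation(df["class"].to_numpy())
        shuffled = HybridTable(table.schema, df)
        majority = max(np.bincount(pd.factorize(df["class"])[0])) / len(df)
        report = evaluate_kfold(shuffled, k=10, seed=12)
        assert abs(report.mean_accuracy - majority) <= 0.1


class TestHoldout:
    def test_duplicate_queries_are_perfect_at_r0(self):
        # querying with an exact copy of the training table: every query has
        # a zero-distance twin, so r = 0 recovers the original labels
        table = generate_hybrid_dataset(SyntheticSpec(n=60, seed=5))
        params = fit_distance_params(table)
        labels = table.labels
        for i in range(len(table)):
            assert predict(table.record(i), table, params, r=0.0).label == labels[i]

    def test_counts_exceeding_table_rejected(self):
        table = generate_hybrid_dataset(SyntheticSpec(n=30, seed=1))
        with pytest.raises(ConfigurationError):
            evaluate_holdout(table, n_train=20, n_test=15)

    def test_bupa_shaped_split_runs(self):
        table = generate_hybrid_dataset(SyntheticSpec(n=345, separation=4.0, seed=8))
        acc = evaluate_holdout(table, n_train=200, n_test=145, r=0.002, seed=8)
        assert 0.0 <= acc <= 1.0


class TestRadiusSweep:
    def test_entry_count_and_types(self):
        table = generate_hybrid_dataset(SyntheticSpec(n=60, seed=6))
        out = radius_sweep(table, [0.0, 0.002, 0.5], k=5, seed=6)
        assert sorted(out) == [0.0, 0.002, 0.5]
        assert all(0.0 <= v <= 1.0 for v in out.values())

    def test_r_zero_entry_matches_standalone_kfold(self):
        table = generate_hybrid_dataset(SyntheticSpec(n=60, seed=6))
        out = radius_sweep(table, [0.0, 0.01], k=5, seed=6)
        solo = evaluate_kfold(table, k=5, r=0.0, seed=6)
        assert out[0.0] == solo.mean_accuracy  # identical folds, same seed

    def test_duplicates_rejected(self):
        table = generate_hybrid_dataset(SyntheticSpec(n=30, seed=1))
        with pytest.raises(ConfigurationError):
            radius_sweep(table, [0.002, 0.002])


class TestNoiseDegradation:
    def test_accuracy_degrades_with_label_noise(self):
        accs = []
        for noise in (0.0, 0.2, 0.4):
            spec = SyntheticSpec(
                n=200, separation=6.0, cat_fidelity=1.0, label_noise=noise, seed=21
            )
            table = generate_hybrid_dataset(spec)
            accs.append(evaluate_kfold(table, k=10, r=0.002, seed=21).mean_accuracy)
        assert accs[1] <= accs[0] + 0.03
        assert accs[2] <= accs[1] + 0.03
        assert accs[2] < accs[0]
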