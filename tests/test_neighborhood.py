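import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from anrs import (
    ConfigurationError,
    ContractViolation,
    HybridRecord,
    HybridSchema,
    HybridTable,
    adaptive_threshold,
    boundary_region,
    build_neighborhood,
    class_approximations,
    fit_distance_params,
)
from conftest import random_hybrid_table
from oracles import brute_approximations


class TestAdaptiveThreshold:
    def test_blends_min_and_range(self):
        delta, min_d, range_d = adaptive_threshold([0.2, 0.7, 1.2], r=0.002)
        assert (min_d, range_d) == (0.2, 1.0)
        assert delta == pytest.approx(0.202)

    def test_r_zero_is_min_only(self):
        delta, min_d, _ = adaptive_threshold([0.5, 0.9], r=0.0)
        assert delta == min_d == 0.5

    def test_degenerate_range(self):
        delta, _, range_d = adaptive_threshold([0.4, 0.4, 0.4], r=5.0)
        assert range_d == 0.0 and delta == 0.4

    def test_empty_list_rejected(self):
        with pytest.raises(ContractViolation):
            adaptive_threshold([], r=0.1)

    @given(
        ds=st.lists(st.floats(0, 100), min_size=1, max_size=30),
        r=st.floats(0, 3),
    )
    @settings(max_examples=200, deadline=None)
    def test_law_holds_exactly(self, ds, r):
        delta, min_d, range_d = adaptive_threshold(ds, r)
        assert min_d == min(ds)
        assert range_d == max(ds) - min(ds)
        assert delta == min_d + r * range_d
        assert delta >= min_d


def _numeric_table(values, labels):
    schema = HybridSchema(attributes=(("v", "numeric"),), decision="cls")
    return HybridTable(schema, pd.DataFrame({"v": values, "cls": labels}))


class TestBuildNeighborhood:
    def test_small_r_keeps_only_argmin(self):
        table = _numeric_table([0.5, 2.1, 3.7], ["p", "p", "n"])
        params = fit_distance_params(table)
        sigma = params.sigmas["v"]
        query = HybridRecord({"v": 0.5 + 0.1 * 4 * sigma})  # distance 0.1 to row 0
        from anrs import distances_to_query

        dists = distances_to_query(table, query, params)
        nbhd = build_neighborhood(query, table, params, r=0.002)
        assert nbhd.members == (0,)
        assert nbhd.min_d == pytest.approx(0.1)
        assert nbhd.delta == pytest.approx(0.1 + 0.002 * (dists.max() - 0.1))

    def test_r_at_least_one_swallows_table(self):
        table = _numeric_table([0.0, 1.0, 5.0], ["p", "n", "n"])
        params = fit_distance_params(table)
        nbhd = build_neighborhood(HybridRecord({"v": 2.0}), table, params, r=1.0)
        assert nbhd.members == (0, 1, 2)

    def test_single_record_table(self):
        table = _numeric_table([3.0], ["p"])
        params = fit_distance_params(table)
        nbhd = build_neighborhood(HybridRecord({"v": -10.0}), table, params, r=0.0)
        assert nbhd.members == (0,)

    def test_membership_monotone_in_r(self):
        rng = np.random.default_rng(11)
        table = random_hybrid_table(rng, n=20)
        params = fit_distance_params(table)
        query = HybridRecord(dict(table.record(0).values))
        previous: set[int] = set()
        for r in (0.0, 0.01, 0.1, 0.5, 1.0):
            members = set(build_neighborhood(query, table, params, r=r).members)
            assert previous <= members
            assert members  # never empty
            previous = members


class TestApproximations:
    def test_discrete_granulation_splits_cleanly(self):
        table = _numeric_table([0.0, 0.0, 10.0, 10.0], ["p", "p", "n", "n"])
        params = fit_distance_params(table)
        approx = class_approximations(table, params, r=0.002)
        assert approx.lower["p"] == approx.upper["p"] == frozenset({0, 1})
        assert approx.lower["n"] == approx.upper["n"] == frozenset({2, 3})
        assert approx.boundary == frozenset()

    def test_straddling_record_lands_in_boundary(self, toy_table):
        params = fit_distance_params(toy_table)
        # r large enough that row 2 (v=0.5, tag=ab) reaches both clusters
        approx = class_approximations(toy_table, params, r=0.92)
        assert 2 in approx.upper["p"] and 2 in approx.upper["n"]
        assert 2 not in approx.lower["p"] and 2 not in approx.lower["n"]
        assert 2 in approx.boundary
        lower, upper, boundary = brute_approximations(toy_table, params, r=0.92)
        assert approx.boundary == frozenset(boundary)

    def test_single_class_universe(self):
        table = _numeric_table([0.0, 1.0, 2.0], ["p", "p", "p"])
        params = fit_distance_params(table)
        approx = class_approximations(table, params, r=0.5)
        assert approx.lower["p"] == approx.upper["p"] == frozenset({0, 1, 2})
        assert approx.boundary == frozenset()

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 26))
        table = random_hybrid_table(rng, n=n)
        params = fit_distance_params(table)
        r = float(rng.uniform(0, 0.5))
        approx = class_approximations(table, params, r=r)
        lower, upper, boundary = brute_approximations(table, params, r=r)
        assert {c: set(v) for c, v in approx.lower.items()} == lower
        assert {c: set(v) for c, v in approx.upper.items()} == upper
        assert set(approx.boundary) == boundary

    @pytest.mark.parametrize("seed", range(5))
    def test_containment_invariants(self, seed):
        rng = np.random.default_rng(100 + seed)
        table = random_hybrid_table(rng, n=18, n_classes=3)
        params = fit_distance_params(table)
        approx = class_approximations(table, params, r=0.05)
        labels = table.labels
        lowers = list(approx.lower.values())
        for c in approx.lower:
            assert approx.lower[c] <= approx.upper[c]
            assert all(labels[i] == c for i in approx.lower[c])
        for i, a in enumerate(lowers):
            for b in lowers[i + 1 :]:
                assert not (a & b)
        assert frozenset().union(*approx.upper.values()) == frozenset(range(len(table)))
        assert approx.boundary == boundary_region(approx)

    def test_large_r_mixed_table_boundary_is_universe(self):
        rng = np.random.default_rng(42)
        table = random_hybrid_table(rng, n=15)
        assert len(set(table.labels)) > 1
        params = fit_distance_params(table)
        approx = class_approximations(table, params, r=5.0)
        assert approx.boundary == frozenset(range(len(table)))

    def test_unlabeled_table_rejected(self):
        schema = HybridSchema(attributes=(("v", "numeric"),), decision="cls")
        table = HybridTable(schema, pd.DataFrame({"v": [1.0, 2.0]}))
        params = fit_distance_params(table)
        with pytest.raises(ContractViolation):
            class_approximations(table, params)

    def test_subset_containing_decision_rejected(self):
        table = _numeric_table([0.0, 1.0], ["p", "n"])
        params = fit_distance_params(table)
        with pytest.raises(ConfigurationError):
            class_approximations(table, params, attribute_subset=("v", "cls"))
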