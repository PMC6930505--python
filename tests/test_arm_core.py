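"""Unit and property tests for the miner and the rule statistics."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from ckdrules import (
    MiningParams,
    TransactionSet,
    apriori_mine,
    brute_force_oracle,
    generate_rules,
    rule_metrics,
    support_of,
)
from ckdrules.arm_core import DegenerateInputError, UndefinedMetricError

from conftest import random_transaction_set


class TestSupport:
    @pytest.mark.parametrize(
        "items, exp_support, exp_count",
        [
            ({"a", "b"}, 0.6, 3),
            ({"a", "b", "c"}, 0.2, 1),
            (set(), 1.0, 5),
            ({"c"}, 0.4, 2),
        ],
    )
    def test_exhaustive_counts(self, toy_db, items, exp_support, exp_count):
        assert support_of(items, toy_db) == (exp_support, exp_count)

    def test_empty_database_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            support_of({"a"}, TransactionSet([], catalog=["a"]))

    def test_unknown_item_raises(self, toy_db):
        with pytest.raises(KeyError):
            support_of({"zzz"}, toy_db)


class TestRuleMetrics:
    def test_hand_computed_rules(self, toy_db):
        r = rule_metrics({"c"}, {"a"}, toy_db)
        assert (r.support, r.confidence, r.lift) == (0.4, 1.0, 1.25)
        r = rule_metrics({"a"}, {"b"}, toy_db)
        assert (r.support, r.confidence, r.lift) == (0.6, 0.75, 0.9375)

    def test_confidence_one_when_counts_equal(self, toy_db):
        # every transaction with c also contains a
        assert rule_metrics({"c"}, {"a"}, toy_db).confidence == 1.0

    def test_zero_support_antecedent_is_error_not_nan(self):
        t = TransactionSet([{"a"}, {"b"}], catalog=["a", "b", "c"])
        with pytest.raises(UndefinedMetricError):
            rule_metrics({"c"}, {"a"}, t)
        with pytest.raises(UndefinedMetricError):
            rule_metrics({"a"}, {"c"}, t)

    def test_overlapping_sides_rejected(self, toy_db):
        with pytest.raises(ValueError):
            rule_metrics({"a"}, {"a", "b"}, toy_db)


class TestApriori:
    def test_toy_db_frequent_itemsets(self, toy_db):
        freq = apriori_mine(toy_db, MiningParams(min_support=0.4, max_len=3))
        got = {s.items: s.support for s in freq}
        assert got == {
            ("a",): 0.8,
            ("b",): 0.8,
            ("c",): 0.4,
            ("a", "b"): 0.6,
            ("a", "c"): 0.4,
        }

    def test_single_transaction_full_support(self):
        t = TransactionSet([{"a", "b"}])
        freq = apriori_mine(t, MiningParams(min_support=1.0, max_len=5))
        assert {s.items for s in freq} == {("a",), ("b",), ("a", "b")}

    def test_empty_db_raises(self):
        with pytest.raises(DegenerateInputError):
            apriori_mine(TransactionSet([]), MiningParams(0.5))

    @pytest.mark.parametrize("seed", range(1, 21))
    def test_matches_oracle_on_random_instances(self, seed):
        t = random_transaction_set(seed)
        min_support = [0.05, 0.1, 0.2, 0.3][seed % 4]
        assert apriori_mine(t, MiningParams(min_support, max_len=12)) == (
            brute_force_oracle(t, min_support, max_len=12)
        )

    @pytest.mark.parametrize("seed", range(1, 11))
    def test_anti_monotonicity(self, seed):
        """Every subset of a reported frequent itemset is reported, with
        support at least as large."""
        t = random_transaction_set(seed)
        freq = apriori_mine(t, MiningParams(0.1, max_len=12))
        supp = {frozenset(s.items): s.support for s in freq}
        for items, s in supp.items():
            for item in items:
                sub = items - {item}
                if sub:
                    assert sub in supp and supp[sub] >= s

    def test_determinism(self, toy_db):
        p = MiningParams(0.2, max_len=4)
        assert apriori_mine(toy_db, p) == apriori_mine(toy_db, p)


class TestOracle:
    def test_min_support_above_max_yields_empty(self, toy_db):
        assert brute_force_oracle(toy_db, 0.81) == []

    def test_min_support_at_one_over_n_returns_everything_present(self, toy_db):
        freq = brute_force_oracle(toy_db, 1 / toy_db.n)
        # every itemset occurring at least once: subsets of the transactions
        present = set()
        for tx in toy_db.transactions:
            from itertools import combinations

            for k in range(1, len(tx) + 1):
                present.update(combinations(sorted(tx), k))
        assert {s.items for s in freq} == present

    def test_catalog_guard(self):
        t = TransactionSet([set()], catalog=[f"i{j}" for j in range(17)])
        with pytest.raises(ValueError):
            brute_force_oracle(t, 0.5)


class TestGenerateRules:
    def test_toy_db_rule_induction(self, toy_db):
        params = MiningParams(0.4, min_confidence=0.7, max_len=3)
        freq = apriori_mine(toy_db, params)
        rules = {r.rule_str(): r for r in generate_rules(freq, toy_db, params)}
        assert rules["{a} => {b}"].confidence == 0.75
        assert rules["{c} => {a}"].confidence == 1.0
        assert "{b} => {c}" not in rules  # {b,c} has support 0.2, infrequent

    def test_min_confidence_zero_emits_all_partitions(self, toy_db):
        params = MiningParams(0.4, min_confidence=0.0, max_len=3)
        freq = apriori_mine(toy_db, params)
        rules = generate_rules(freq, toy_db, params)
        # frequent 2-itemsets {a,b} and {a,c} -> 2 single-consequent rules each
        assert len(rules) == 4

    def test_min_confidence_one_keeps_only_certain_rules(self, toy_db):
        params = MiningParams(0.4, min_confidence=1.0, max_len=3)
        freq = apriori_mine(toy_db, params)
        rules = generate_rules(freq, toy_db, params)
        assert {r.rule_str() for r in rules} == {"{c} => {a}"}
        assert all(r.confidence == 1.0 for r in rules)

    def test_non_closed_collection_raises(self, toy_db):
        params = MiningParams(0.4, max_len=3)
        freq = [s for s in apriori_mine(toy_db, params) if s.k == 2]
        with pytest.raises(ValueError, match="not closed"):
            generate_rules(freq, toy_db, params)

    @pytest.mark.parametrize("seed", range(1, 11))
    def test_metric_identities_on_random_data(self, seed):
        """confidence >= support; lift * supp(consequent) = confidence;
        supp(m => n) = supp(n => m)."""
        t = random_transaction_set(seed)
        params = MiningParams(0.05, max_len=12)
        freq = apriori_mine(t, params)
        rules = generate_rules(freq, t, params)
        assert rules, "expected some rules on this instance"
        for r in rules:
            assert r.confidence >= r.support
            supp_cons, _ = support_of(r.consequent, t)
            assert math.isclose(r.lift * supp_cons, r.confidence, abs_tol=1e-12)
            reverse = rule_metrics(set(r.consequent), set(r.antecedent), t)
            assert reverse.support == r.support and reverse.count == r.count


@settings(derandomize=True, max_examples=40, deadline=None)
@given(st.integers(min_value=1, max_value=10_000), st.sampled_from([0.05, 0.15, 0.3]))
def test_oracle_equivalence_property(seed, min_support):
    t = random_transaction_set(seed, max_items=8, max_n=60)
    assert apriori_mine(t, MiningParams(min_support, max_len=8)) == (
        brute_force_oracle(t, min_support, max_len=8)
    )
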