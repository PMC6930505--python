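"""Predication loading, semantic filtering and pairwise rule mining."""

import numpy as np
import pytest

from ckdrules.litmine import (
    PredicationRecord,
    SemanticFilterConfig,
    filter_predications,
    lifestyle_filter,
    load_predications,
    mine_pair_rules,
    predications_to_transactions,
    write_predications_csv,
)
from ckdrules.synthetic import (
    SyntheticPredicationSpec,
    default_predication_spec,
    generate_predications,
)


def rec(s, p, o, s_t="dsyn", o_t="dsyn"):
    return PredicationRecord(
        subject=s, subject_semtype=s_t, predicate=p, object=o, object_semtype=o_t
    )


CFG = SemanticFilterConfig(
    semtype_whitelist=frozenset({"dsyn", "fndg", "inbe", "topp"}),
    term_blacklist=frozenset({"patients"}),
    focus_semtypes=frozenset({"inbe", "fndg"}),
)


class TestPredicationRecords:
    def test_negation_follows_predicate_prefix(self):
        assert not rec("Iron deficiency", "ASSOCIATED_WITH", "Anemia").negated
        assert rec("Diet; Protein-Restricted", "NEG_TREATS", "CKD").negated

    def test_empty_term_rejected(self):
        with pytest.raises(ValueError):
            rec("", "TREATS", "CKD")

    def test_csv_round_trip(self, tmp_path):
        records = [
            rec("Diet Therapy", "TREATS", "CKD", "topp", "dsyn"),
            rec("Dietary intake", "NEG_ASSOCIATED_WITH", "CKD", "fndg", "dsyn"),
        ]
        p = tmp_path / "pred.csv"
        write_predications_csv(records, p)
        assert load_predications(p) == records

    def test_missing_column_is_error(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("subject,predicate,object\nA,TREATS,B\n")
        with pytest.raises(ValueError, match="missing columns"):
            load_predications(p)

    def test_empty_file_gives_empty_collection(self, tmp_path):
        p = tmp_path / "empty.csv"
        write_predications_csv([], p)
        assert load_predications(p) == []


class TestFilterPredications:
    def test_blacklisted_generic_term_removed(self):
        records = [rec("patients", "PROCESS_OF", "CKD"), rec("Anemia", "COEXISTS_WITH", "CKD")]
        out = filter_predications(records, CFG, seed_terms=["CKD"])
        assert out == [records[1]]

    def test_seed_adjacency(self):
        records = [rec("Anemia", "COEXISTS_WITH", "CKD"), rec("Anemia", "COEXISTS_WITH", "Obesity")]
        assert filter_predications(records, CFG, seed_terms=["CKD"]) == [records[0]]
        assert filter_predications(records, CFG, seed_terms=["nothing"]) == []

    def test_whitelist_applies_to_both_sides(self):
        r = rec("Gene X", "AFFECTS", "CKD", s_t="gngm")
        assert filter_predications([r], CFG, seed_terms=["CKD"]) == []

    def test_negated_kept_by_default_dropped_on_request(self):
        r = rec("Diet; Protein-Restricted", "NEG_TREATS", "CKD", "topp", "dsyn")
        assert filter_predications([r], CFG, seed_terms=["CKD"]) == [r]
        strict = SemanticFilterConfig(
            semtype_whitelist=CFG.semtype_whitelist,
            focus_semtypes=CFG.focus_semtypes,
            keep_negated=False,
        )
        assert filter_predications([r], strict, seed_terms=["CKD"]) == []

    def test_focus_must_be_subset_of_whitelist(self):
        with pytest.raises(ValueError):
            SemanticFilterConfig(
                semtype_whitelist=frozenset({"dsyn"}),
                focus_semtypes=frozenset({"inbe"}),
            )

    def test_never_increases_record_count(self):
        records = generate_predications(default_predication_spec(), seed=5)
        assert len(filter_predications(records, CFG)) <= len(records)


class TestPairTransactions:
    def test_direct_mapping_preserves_duplicates(self):
        records = [rec("A", "X", "B"), rec("A", "X", "B"), rec("C", "X", "D")]
        t = predications_to_transactions(records)
        assert t.n == 3
        assert t.catalog == {"A", "B", "C", "D"}

    def test_self_loop_dropped(self):
        t = predications_to_transactions([rec("A", "X", "A")])
        assert t.n == 0

    def test_pair_density(self):
        records = generate_predications(default_predication_spec(n=100), seed=2)
        t = predications_to_transactions(records)
        assert t.n == 100
        assert all(len(tx) == 2 for tx in t.transactions)


class TestMinePairRules:
    def test_planted_pair_closed_form_lift(self):
        """A pair planted 3 times among 60 otherwise-unique records has
        count 3, confidence 1 and lift n*c(A,B)/(c(A)c(B)) = 60/3 = 20."""
        records = generate_predications(default_predication_spec(n=60), seed=1)
        t = predications_to_transactions(records)
        rules, report = mine_pair_rules(t, min_count=2)
        by_str = {r.rule_str(): r for r in rules}
        top = by_str["{Iron deficiency} => {Anemia}"]
        assert top.count == 3 and top.confidence == 1.0 and top.lift == 20.0
        assert report.support_lower_bound == pytest.approx(2 / 60)

    def test_single_occurrence_excluded_at_min_count_two(self):
        spec = SyntheticPredicationSpec(planted={("A", "B"): 2}, n=10)
        records = generate_predications(spec, seed=0) + [rec("P", "X", "Q")]
        t = predications_to_transactions(records)
        rules, _ = mine_pair_rules(t, min_count=2)
        items = {i for r in rules for i in r.items}
        assert "P" not in items and "Q" not in items

    def test_boundary_count_two_survives(self):
        # second planted pair at lower lift keeps the mean-lift stage
        # non-degenerate; the count-2 pair (lift 15 > mean) must survive
        spec = SyntheticPredicationSpec(planted={("A", "B"): 2, ("C", "D"): 4}, n=30)
        t = predications_to_transactions(generate_predications(spec, seed=0))
        rules, _ = mine_pair_rules(t, min_count=2)
        assert any(r.count == 2 and set(r.items) == {"A", "B"} for r in rules)

    def test_independent_frequent_terms_removed_by_lift_filter(self):
        # X and Y co-occur at roughly their product rate within a uniform
        # background vocabulary -> lift ~ 1 -> dropped by the lift>1 stage
        rng = np.random.default_rng(4)
        vocab = [f"t{i}" for i in range(4)]
        records = []
        for i in range(400):
            a, b = rng.choice(4, size=2, replace=False)
            records.append(rec(vocab[a], "X", vocab[b]))
        t = predications_to_transactions(records)
        rules, _ = mine_pair_rules(t, min_count=2)
        assert all(r.lift > 1 for r in rules)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_pair_lift_identity_and_symmetry(self, seed):
        """lift({X}=>{Y}) = n*c(X,Y)/(c(X)c(Y)) and equals lift({Y}=>{X})."""
        rng = np.random.default_rng(seed)
        vocab = [f"t{i}" for i in range(8)]
        records = []
        for _ in range(120):
            a, b = rng.choice(8, size=2, replace=False)
            records.append(rec(vocab[a], "X", vocab[b]))
        t = predications_to_transactions(records)
        rules, _ = mine_pair_rules(t, min_count=2)
        counts = {item: len(tids) for item, tids in t.tidsets().items()}
        by_pair = {(r.antecedent[0], r.consequent[0]): r for r in rules}
        for (x, y), r in by_pair.items():
            assert r.lift == pytest.approx(t.n * r.count / (counts[x] * counts[y]))
            if (y, x) in by_pair:
                assert by_pair[(y, x)].lift == pytest.approx(r.lift)

    def test_empty_store_is_error(self):
        from ckdrules.arm_core import DegenerateInputError
        from ckdrules.transactions import TransactionSet

        with pytest.raises(DegenerateInputError):
            mine_pair_rules(TransactionSet([]), min_count=2)


class TestLifestyleFilter:
    def test_focus_type_side_retained(self):
        r_rules, _ = _mined_default()
        semtypes = _semtypes_default()
        kept, keywords = lifestyle_filter(r_rules, CFG, semtypes)
        assert any("Iron deficiency" in r.items for r in kept)
        assert keywords == sorted(set(keywords))
        assert all(semtypes[k] in CFG.focus_semtypes for k in keywords)

    def test_rule_without_focus_side_dropped(self):
        r = _pair_rule("Anemia", "Obesity")
        kept, keywords = lifestyle_filter([r], CFG, {"Anemia": "dsyn", "Obesity": "dsyn"})
        assert kept == [] and keywords == []

    def test_unmapped_term_is_named(self):
        r = _pair_rule("A", "B")
        with pytest.raises(KeyError, match="B"):
            lifestyle_filter([r], CFG, {"A": "fndg"})


def _pair_rule(a, b):
    from ckdrules import AssociationRule

    return AssociationRule(
        antecedent=(a,), consequent=(b,), support=0.05, confidence=1.0, lift=20.0, count=3
    )


def _mined_default():
    records = generate_predications(default_predication_spec(), seed=1)
    t = predications_to_transactions(records)
    return mine_pair_rules(t, min_count=2)


def _semtypes_default():
    records = generate_predications(default_predication_spec(), seed=1)
    out = {}
    for r in records:
        out[r.subject] = r.subject_semtype
        out[r.object] = r.object_semtype
    return out
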