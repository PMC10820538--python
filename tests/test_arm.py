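"""Apriori mining, rule generation, measure suite, oracles and invariants."""

import math

import numpy as np
import pytest

from comorbnet.arm import (
    MiningConfig,
    TransactionDB,
    apriori,
    brute_force_rules,
    build_transactions,
    eclat,
    generate_rules,
    is_measure,
    rank_rules,
    round_half_up,
)
from conftest import make_record, random_tdb


def rule_map(rules):
    return {(tuple(sorted(r.antecedent)), tuple(sorted(r.consequent))): r for r in rules}


class TestTransactions:
    def test_items_are_secondary_categories_deduplicated(self):
        rec = make_record(principal="E05", secondary=["E11.9", "I10", "E11.2"])
        tdb = build_transactions([rec])
        assert list(tdb.transactions.values()) == [frozenset({"E11", "I10"})]

    def test_principal_category_excluded_from_own_itemset(self):
        rec = make_record(principal="E11", secondary=["E11.9"])
        tdb = build_transactions([rec])
        assert list(tdb.transactions.values()) == [frozenset()]
        tdb2 = build_transactions([rec], include_principal=True)
        assert list(tdb2.transactions.values()) == [frozenset({"E11"})]

    def test_total_counts_every_record(self):
        records = [
            make_record(patient_id="a", secondary=["I10"]),
            make_record(patient_id="b", secondary=[]),
            make_record(patient_id="c", secondary=["I10", "N18"]),
            make_record(patient_id="d", secondary=["K29"]),
            make_record(patient_id="e", secondary=[]),
        ]
        tdb = build_transactions(records)
        assert tdb.total == 5
        assert sorted(tdb.items) == ["I10", "K29", "N18"]


class TestApriori:
    def test_toy_db_frequent_itemsets(self, toy_tdb, toy_cfg):
        # brute-force-derived expectation over the 2^3 - 1 itemsets
        expected = {
            frozenset({"A11"}): 5,
            frozenset({"B22"}): 5,
            frozenset({"C33"}): 3,
            frozenset({"A11", "B22"}): 4,
            frozenset({"B22", "C33"}): 2,
        }
        got = {s.items: s.count for s in apriori(toy_tdb, toy_cfg)}
        assert got == expected

    def test_empty_transactions_yield_nothing(self):
        tdb = TransactionDB(transactions={"a": frozenset(), "b": frozenset()}, total=2)
        assert apriori(tdb, MiningConfig()) == []

    def test_support_threshold_is_strict(self):
        tdb = TransactionDB(
            transactions={str(i): frozenset({"A11"}) for i in range(2)}
            | {"x": frozenset(), "y": frozenset()},
            total=4,
        )
        # support 0.5 not > 0.5
        assert apriori(tdb, MiningConfig(min_support=0.5)) == []
        assert len(apriori(tdb, MiningConfig(min_support=0.49))) == 1

    def test_downward_closure(self, toy_tdb, toy_cfg):
        from itertools import combinations

        frequent = {s.items for s in apriori(toy_tdb, toy_cfg)}
        for s in frequent:
            for k in range(1, len(s)):
                for sub in combinations(s, k):
                    assert frozenset(sub) in frequent

    def test_monotonicity_in_min_support(self, toy_tdb):
        prev = None
        for ms in (0.05, 0.1, 0.2, 0.3, 0.5):
            cur = {s.items for s in apriori(toy_tdb, MiningConfig(min_support=ms))}
            if prev is not None:
                assert cur <= prev
            prev = cur

    def test_max_len_caps_itemset_size(self, toy_tdb):
        frequent = apriori(toy_tdb, MiningConfig(min_support=0.1, max_len=1))
        assert all(len(s.items) == 1 for s in frequent)


class TestRules:
    def test_toy_rule_measures(self, toy_tdb, toy_cfg):
        # hand arithmetic: A -> B support 4/8, confidence 4/5, lift 0.8/(5/8)
        rules = rule_map(generate_rules(apriori(toy_tdb, toy_cfg), toy_tdb, toy_cfg))
        r = rules[(("A11",), ("B22",))]
        assert r.support == pytest.approx(0.5)
        assert r.confidence == pytest.approx(0.8)
        assert r.lift == pytest.approx(1.28)
        assert r.is_measure == pytest.approx(0.8)
        # cosine identity cross-check: 0.5 / sqrt(0.625 * 0.625)
        assert r.is_measure == pytest.approx(0.5 / math.sqrt(0.625 * 0.625))

    def test_both_directions_are_distinct_rules(self, toy_tdb, toy_cfg):
        rules = rule_map(generate_rules(apriori(toy_tdb, toy_cfg), toy_tdb, toy_cfg))
        fwd = rules[(("A11",), ("B22",))]
        rev = rules[(("B22",), ("A11",))]
        assert fwd.support == rev.support
        assert fwd.lift == rev.lift
        assert fwd.is_measure == rev.is_measure

    def test_lift_exactly_one_is_excluded(self):
        # two independent items: P(A)=P(B)=1/2, P(AB)=1/4 -> lift exactly 1
        baskets = [{"A11", "B22"}, {"A11"}, {"B22"}, set()]
        tdb = TransactionDB(
            transactions={str(i): frozenset(b) for i, b in enumerate(baskets)}, total=4
        )
        cfg = MiningConfig(min_support=0.1, min_confidence=0.0)
        assert generate_rules(apriori(tdb, cfg), tdb, cfg) == []
        inclusive = MiningConfig(min_support=0.1, min_confidence=0.0, lift_strict=False)
        assert len(generate_rules(apriori(tdb, inclusive), tdb, inclusive)) == 2

    def test_single_item_db_has_no_rules(self):
        tdb = TransactionDB(transactions={"a": frozenset({"A11"})}, total=1)
        cfg = MiningConfig(min_support=0.1)
        assert generate_rules(apriori(tdb, cfg), tdb, cfg) == []

    def test_confidence_threshold_is_strict(self, toy_tdb):
        cfg = MiningConfig(min_support=0.2, min_confidence=0.8)
        rules = generate_rules(apriori(toy_tdb, cfg), toy_tdb, cfg)
        # A -> B has confidence exactly 0.8: excluded under strict >
        assert (("A11",), ("B22",)) not in rule_map(rules)


class TestMeasures:
    @pytest.mark.parametrize(
        "n,lift,expected_support,expected_is",
        [
            (3523, 5.239, 0.051, 0.519),
            (12259, 1.217, 0.179, 0.467),
            (2683, 6.017, 0.039, 0.485),
            (1778, 2.275, 0.026, 0.243),
        ],
    )
    def test_is_measure_reproduces_published_rows(self, n, lift, expected_support, expected_is):
        """Counts and lifts from the published registry rule table reproduce
        the printed 3-decimal support and IS only when IS uses the unrounded
        support."""
        support = n / 68_515
        assert round_half_up(support, 3) == expected_support
        assert round_half_up(is_measure(support, lift), 3) == expected_is

    def test_is_zero_when_support_zero(self):
        assert is_measure(0.0, 3.7) == 0.0

    def test_is_rejects_invalid_inputs(self):
        with pytest.raises(ValueError):
            is_measure(1.5, 1.0)
        with pytest.raises(ValueError):
            is_measure(0.5, -0.1)

    def test_round_half_up_convention(self):
        assert round_half_up(0.0515, 3) == 0.052
        assert round_half_up(0.0514, 3) == 0.051
        assert round_half_up(62.35, 1) == 62.4


class TestRanking:
    def test_rank_by_is_then_support_then_lexicographic(self, toy_tdb, toy_cfg):
        rules = generate_rules(apriori(toy_tdb, toy_cfg), toy_tdb, toy_cfg)
        ranked = rank_rules(rules)
        keys = [(r.is_measure, r.support) for r in ranked]
        assert keys == sorted(keys, key=lambda t: (-t[0], -t[1]))
        # equal-IS pairs fall back to lexicographic order
        assert ranked[0].sort_key() < ranked[1].sort_key()

    def test_ranking_is_permutation_invariant(self, toy_tdb, toy_cfg):
        rules = generate_rules(apriori(toy_tdb, toy_cfg), toy_tdb, toy_cfg)
        rng = np.random.default_rng(0)
        for _ in range(5):
            shuffled = list(rules)
            rng.shuffle(shuffled)
            assert rank_rules(shuffled) == rank_rules(rules)


class TestOracles:
    def test_brute_force_matches_pipeline_on_toy(self, toy_tdb, toy_cfg):
        pipeline = rule_map(generate_rules(apriori(toy_tdb, toy_cfg), toy_tdb, toy_cfg))
        oracle = rule_map(brute_force_rules(toy_tdb, toy_cfg))
        assert pipeline.keys() == oracle.keys()

    def test_brute_force_refuses_large_vocabularies(self):
        tx = {"0": frozenset(f"A{i:02d}" for i in range(15))}
        with pytest.raises(ValueError, match="brute force"):
            brute_force_rules(TransactionDB(transactions=tx, total=1), MiningConfig())

    @pytest.mark.parametrize("seed", range(20))
    def test_oracle_equivalence_on_random_dbs(self, seed):
        """Apriori + rule generation equals exhaustive enumeration (and the
        Eclat backend) on random instances with random thresholds."""
        rng = np.random.default_rng(1000 + seed)
        tdb = random_tdb(rng)
        cfg = MiningConfig(
            min_support=float(rng.uniform(0.02, 0.3)),
            min_confidence=float(rng.uniform(0.0, 0.5)),
            min_lift=float(rng.choice([0.0, 1.0])),
        )
        frequent = apriori(tdb, cfg)
        pipeline = rule_map(generate_rules(frequent, tdb, cfg))
        oracle = rule_map(brute_force_rules(tdb, cfg))
        assert pipeline.keys() == oracle.keys()
        for key, r in pipeline.items():
            o = oracle[key]
            assert r.count == o.count
            for f in ("support", "confidence", "lift", "is_measure"):
                assert getattr(r, f) == pytest.approx(getattr(o, f), abs=1e-9)
        # independent Eclat route agrees on itemsets and counts
        assert {(s.items, s.count) for s in eclat(tdb, cfg)} == {
            (s.items, s.count) for s in frequent
        }

    def test_cosine_identity_on_random_dbs(self):
        rng = np.random.default_rng(7)
        tdb = random_tdb(rng)
        cfg = MiningConfig(min_support=0.05, min_confidence=0.0, min_lift=0.0)
        frequent = {s.items: s for s in apriori(tdb, cfg)}
        for r in generate_rules(list(frequent.values()), tdb, cfg):
            cosine = r.support / math.sqrt(
                frequent[r.antecedent].support * frequent[r.consequent].support
            )
            assert abs(r.is_measure - cosine) < 1e-12
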