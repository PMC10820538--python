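"""Association-rule mining over per-patient comorbidity itemsets.

The transaction database maps each patient to the set of 3-character ICD-10
categories coded as secondary diagnoses on their discharge record. Support
uses the full-cohort denominator (patients with no comorbidities count in
the total). Frequent itemsets come from a level-wise Apriori search; rules
A -> B are scored with

    support(A -> B)    = N(A and B) / N_total
    confidence(A -> B) = support(A u B) / support(A)
    lift(A -> B)       = support(A u B) / (support(A) * support(B))
    IS(A -> B)         = sqrt(support * lift)
                       = support(A u B) / sqrt(support(A) * support(B))

IS (interest support, the cosine measure) balances rarity-inflated lift
against raw support and is the ranking criterion. Retention thresholds are
strict by default: support > 0.02, confidence > 0.1, lift > 1.

Two independent implementations ship alongside the pipeline for
verification: an exhaustive brute-force enumerator (small vocabularies) and
an Eclat miner (vertical TID-set intersection), both contract-equivalent to
``apriori`` + ``generate_rules``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TransactionDB",
    "Itemset",
    "AssociationRule",
    "MiningConfig",
    "build_transactions",
    "apriori",
    "eclat",
    "generate_rules",
    "brute_force_rules",
    "is_measure",
    "rank_rules",
    "round_half_up",
    "rules_to_dataframe",
    "write_rules_csv",
    "read_rules_csv",
    "write_baskets",
]


def round_half_up(x: float, decimals: int = 3) -> float:
    """Round half away from zero at the given number of decimals."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class TransactionDB:
    """Per-patient comorbidity itemsets plus the total-patient denominator.

    ``total`` counts every patient, including those with an empty itemset;
    it is the denominator of every support in the analysis.
    """

    transactions: Mapping[str, frozenset[str]]
    total: int

    def __post_init__(self) -> None:
        if self.total < len([t for t in self.transactions.values() if t]):
            raise ValueError("total below the number of non-empty transactions")

    @property
    def items(self) -> list[str]:
        """Sorted vocabulary of items observed in any transaction."""
        vocab: set[str] = set()
        for t in self.transactions.values():
            vocab |= t
        return sorted(vocab)

    def to_matrix(self) -> tuple[np.ndarray, list[str]]:
        """Dense boolean patient x item incidence matrix (observed items only)."""
        items = self.items
        index = {c: j for j, c in enumerate(items)}
        X = np.zeros((len(self.transactions), len(items)), dtype=bool)
        for i, t in enumerate(self.transactions.values()):
            for c in t:
                X[i, index[c]] = True
        return X, items


def build_transactions(
    records: Sequence, *, include_principal: bool = False
) -> TransactionDB:
    """Build the transaction database from cohort-filtered discharge records.

    Items are the 3-character categories of secondary diagnoses. By default
    a record's own principal-diagnosis category is excluded from its itemset
    so that "comorbidity" means conditions other than the admitting
    diagnosis; set ``include_principal`` to keep it.
    """
    transactions: dict[str, frozenset[str]] = {}
    for i, r in enumerate(records):
        items = set(r.secondary_categories)
        if not include_principal:
            items.discard(r.principal_dx.category)
        # patient_id may repeat across admissions in raw registries; key rows uniquely
        transactions[f"{i}:{r.patient_id}"] = frozenset(items)
    return TransactionDB(transactions=transactions, total=len(records))


@dataclass(frozen=True)
class Itemset:
    items: frozenset[str]
    count: int
    support: float

    def __post_init__(self) -> None:
        if not self.items:
            raise ValueError("empty itemset")


@dataclass(frozen=True)
class AssociationRule:
    """A directed rule A -> B between disjoint comorbidity itemsets."""

    antecedent: frozenset[str]
    consequent: frozenset[str]
    count: int
    support: float
    confidence: float
    lift: float
    is_measure: float

    def __post_init__(self) -> None:
        if self.antecedent & self.consequent:
            raise ValueError("antecedent and consequent overlap")
        if not self.antecedent or not self.consequent:
            raise ValueError("antecedent and consequent must be non-empty")

    @property
    def items(self) -> frozenset[str]:
        return self.antecedent | self.consequent

    def sort_key(self) -> tuple:
        return (tuple(sorted(self.antecedent)), tuple(sorted(self.consequent)))

    def label(self) -> str:
        return (
            ", ".join(sorted(self.antecedent))
            + " → "
            + ", ".join(sorted(self.consequent))
        )


@dataclass(frozen=True)
class MiningConfig:
    """Retention thresholds and reporting conventions.

    Thresholds are strict inequalities (support > min_support, confidence >
    min_confidence, lift > min_lift) matching the convention that a rule
    must exceed — not merely reach — each cutoff; ``lift_strict=False``
    switches the lift test to >=. ``max_len`` caps itemset size (None =
    unbounded). ``rounding`` is the number of decimals used when measures
    are reported; all filtering and the IS computation use unrounded values.
    """

    min_support: float = 0.02
    min_confidence: float = 0.1
    min_lift: float = 1.0
    lift_strict: bool = True
    max_len: int | None = None
    rounding: int = 3

    def __post_init__(self) -> None:
        if not (0 < self.min_support <= 1):
            raise ValueError(f"min_support must be in (0, 1]: {self.min_support}")
        if not (0 <= self.min_confidence <= 1):
            raise ValueError(f"min_confidence must be in [0, 1]: {self.min_confidence}")
        if self.min_lift < 0:
            raise ValueError(f"min_lift must be >= 0: {self.min_lift}")
        if self.max_len is not None and self.max_len < 1:
            raise ValueError("max_len must be >= 1 or None")

    def lift_passes(self, lift: float) -> bool:
        return lift > self.min_lift if self.lift_strict else lift >= self.min_lift


def is_measure(support: float, lift: float) -> float:
    """Interest support IS = sqrt(support * lift), from unrounded inputs."""
    if not (0 <= support <= 1):
        raise ValueError(f"support out of [0, 1]: {support}")
    if lift < 0:
        raise ValueError(f"negative lift: {lift}")
    return math.sqrt(support * lift)


def apriori(tdb: TransactionDB, cfg: MiningConfig) -> list[Itemset]:
    """Level-wise frequent-itemset mining with strict support threshold.

    Size-k candidates are joined from frequent (k-1)-itemsets sharing a
    (k-2)-prefix and pruned when any (k-1)-subset is infrequent (downward
    closure). Counting scans a boolean incidence matrix. Output is sorted
    by (size, lexicographic items).
    """
    if tdb.total == 0:
        return []
    X, items = tdb.to_matrix()
    n_items = len(items)
    counts = X.sum(axis=0)

    def frequent(count: int) -> bool:
        return count / tdb.total > cfg.min_support

    result: list[Itemset] = []
    # level 1
    level: list[tuple[int, ...]] = []
    for j in range(n_items):
        if frequent(int(counts[j])):
            level.append((j,))
            result.append(
                Itemset(
                    items=frozenset([items[j]]),
                    count=int(counts[j]),
                    support=int(counts[j]) / tdb.total,
                )
            )
    k = 2
    frequent_sets = {frozenset(t) for t in level}
    while level and (cfg.max_len is None or k <= cfg.max_len):
        # prefix join: both parents sorted, share first k-2 indices
        candidates: list[tuple[int, ...]] = []
        level_sorted = sorted(level)
        for a_idx, a in enumerate(level_sorted):
            for b in level_sorted[a_idx + 1 :]:
                if a[:-1] != b[:-1]:
                    break
                cand = a + (b[-1],)
                # downward-closure prune
                if all(
                    frozenset(cand[:m] + cand[m + 1 :]) in frequent_sets
                    for m in range(k)
                ):
                    candidates.append(cand)
        next_level = []
        for cand in candidates:
            count = int(X[:, cand].all(axis=1).sum())
            if frequent(count):
                next_level.append(cand)
                result.append(
                    Itemset(
                        items=frozenset(items[j] for j in cand),
                        count=count,
                        support=count / tdb.total,
                    )
                )
        frequent_sets |= {frozenset(t) for t in next_level}
        level = next_level
        k += 1
    result.sort(key=lambda s: (len(s.items), tuple(sorted(s.items))))
    return result


def eclat(tdb: TransactionDB, cfg: MiningConfig) -> list[Itemset]:
    """Independent frequent-itemset miner using vertical TID-set intersection.

    Depth-first over the item lattice, intersecting sets of transaction ids;
    a deliberately different search order and counting mechanism from
    ``apriori``, used as a cross-check. Same contract and output ordering.
    """
    if tdb.total == 0:
        return []
    tidsets: dict[str, frozenset[str]] = {}
    for tid, t in tdb.transactions.items():
        for c in t:
            tidsets.setdefault(c, set()).add(tid)  # type: ignore[arg-type]
    tidsets = {c: frozenset(s) for c, s in tidsets.items()}

    def frequent(count: int) -> bool:
        return count / tdb.total > cfg.min_support

    items = sorted(c for c, s in tidsets.items() if frequent(len(s)))
    result: list[Itemset] = []

    def recurse(prefix: tuple[str, ...], prefix_tids: frozenset[str], tail: list[str]):
        for i, c in enumerate(tail):
            tids = prefix_tids & tidsets[c] if prefix else tidsets[c]
            if not frequent(len(tids)):
                continue
            itemset = prefix + (c,)
            result.append(
                Itemset(
                    items=frozenset(itemset),
                    count=len(tids),
                    support=len(tids) / tdb.total,
                )
            )
            if cfg.max_len is None or len(itemset) < cfg.max_len:
                recurse(itemset, tids, tail[i + 1 :])

    recurse((), frozenset(), items)
    result.sort(key=lambda s: (len(s.items), tuple(sorted(s.items))))
    return result


def generate_rules(
    frequent: list[Itemset], tdb: TransactionDB, cfg: MiningConfig
) -> list[AssociationRule]:
    """Emit A -> S\\A for every frequent S (|S| >= 2) and non-empty proper A.

    Retains rules with confidence and lift beyond the configured thresholds.
    Both directions of a pair are distinct rules (their confidences differ).
    """
    support_of: dict[frozenset[str], Itemset] = {s.items: s for s in frequent}
    rules: list[AssociationRule] = []
    for s in frequent:
        if len(s.items) < 2:
            continue
        items = sorted(s.items)
        for r in range(1, len(items)):
            for ant_tuple in combinations(items, r):
                ant = frozenset(ant_tuple)
                cons = s.items - ant
                ant_set = support_of.get(ant)
                cons_set = support_of.get(cons)
                if ant_set is None or cons_set is None:
                    # downward closure guarantees both are frequent
                    raise ValueError(
                        "frequent itemsets inconsistent with the transaction DB: "
                        f"missing subset of {sorted(s.items)}"
                    )
                confidence = s.support / ant_set.support
                lift = s.support / (ant_set.support * cons_set.support)
                if confidence > cfg.min_confidence and cfg.lift_passes(lift):
                    rules.append(
                        AssociationRule(
                            antecedent=ant,
                            consequent=cons,
                            count=s.count,
                            support=s.support,
                            confidence=confidence,
                            lift=lift,
                            is_measure=is_measure(s.support, lift),
                        )
                    )
    return rules


def rank_rules(rules: Iterable[AssociationRule]) -> list[AssociationRule]:
    """Sort rules by IS descending; ties by support descending, then lexicographic."""
    return sorted(
        rules, key=lambda r: (-r.is_measure, -r.support, r.sort_key())
    )


def brute_force_rules(tdb: TransactionDB, cfg: MiningConfig) -> list[AssociationRule]:
    """Exhaustive oracle: enumerate every itemset over the observed vocabulary.

    Counts each subset by direct containment scan and emits every qualifying
    rule; no pruning, no shared code with the Apriori path. Guarded to <= 14
    distinct items.
    """
    items = tdb.items
    if len(items) > 14:
        raise ValueError(f"brute force refused for {len(items)} items (> 14)")
    if tdb.total == 0:
        return []
    tlist = list(tdb.transactions.values())

    def count(itemset: frozenset[str]) -> int:
        return sum(1 for t in tlist if itemset <= t)

    supports: dict[frozenset[str], tuple[int, float]] = {}
    for size in range(1, len(items) + 1):
        if cfg.max_len is not None and size > cfg.max_len:
            break
        for combo in combinations(items, size):
            s = frozenset(combo)
            c = count(s)
            if c / tdb.total > cfg.min_support:
                supports[s] = (c, c / tdb.total)
    rules = []
    for s, (c, sup) in supports.items():
        if len(s) < 2:
            continue
        for r in range(1, len(s)):
            for ant_tuple in combinations(sorted(s), r):
                ant = frozenset(ant_tuple)
                cons = s - ant
                conf = sup / supports[ant][1]
                lift = sup / (supports[ant][1] * supports[cons][1])
                if conf > cfg.min_confidence and cfg.lift_passes(lift):
                    rules.append(
                        AssociationRule(
                            antecedent=ant,
                            consequent=cons,
                            count=c,
                            support=sup,
                            confidence=conf,
                            lift=lift,
                            is_measure=is_measure(sup, lift),
                        )
                    )
    return rules


def rules_to_dataframe(
    rules: Sequence[AssociationRule], decimals: int = 3
) -> pd.DataFrame:
    """Ranked rule table: rank, antecedent, consequent, N, and rounded measures."""
    ranked = rank_rules(rules)
    return pd.DataFrame(
        {
            "rank": range(1, len(ranked) + 1),
            "antecedent": [", ".join(sorted(r.antecedent)) for r in ranked],
            "consequent": [", ".join(sorted(r.consequent)) for r in ranked],
            "n": [r.count for r in ranked],
            "support": [round_half_up(r.support, decimals) for r in ranked],
            "confidence": [round_half_up(r.confidence, decimals) for r in ranked],
            "lift": [round_half_up(r.lift, decimals) for r in ranked],
            "is": [round_half_up(r.is_measure, decimals) for r in ranked],
        }
    )


def write_rules_csv(rules: Sequence[AssociationRule], path, decimals: int = 3) -> None:
    rules_to_dataframe(rules, decimals).to_csv(path, index=False)


def read_rules_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, keep_default_na=False)


def write_baskets(tdb: TransactionDB, path) -> None:
    """Single-line basket export: one patient per line, items space-separated."""
    with open(path, "w", encoding="utf-8") as fh:
        for t in tdb.transactions.values():
            fh.write(" ".join(sorted(t)) + "\n")
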