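"""Age-group-stratified rule mining, presence matrices and rule composition.

The cohort is partitioned into the four life-cycle strata (19-44, 45-64,
65-74, >=75); each stratum is mined with its own stratum-local support
denominator and the same thresholds as the pooled run. The presence matrix
marks, per comorbidity category and stratum, whether the category
participates in at least one retained rule — the compact summary of which
comorbidity associations are specific to which stage of life.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .arm import (
    AssociationRule,
    MiningConfig,
    apriori,
    build_transactions,
    generate_rules,
    rank_rules,
    round_half_up,
)
from .records import AGE_GROUPS, DischargeRecord

__all__ = [
    "ALL_STRATUM",
    "StratifiedRuleSets",
    "CompositionStats",
    "mine_by_age_group",
    "presence_matrix",
    "write_presence_csv",
    "composition_stats",
]

#: Label for the pooled (all ages) stratum.
ALL_STRATUM = "all"


@dataclass(frozen=True)
class StratifiedRuleSets:
    """IS-ranked rule lists and denominators per stratum plus the pooled run."""

    rules: Mapping[str, tuple[AssociationRule, ...]]
    totals: Mapping[str, int]

    def strata(self) -> list[str]:
        return [g for g in (*AGE_GROUPS, ALL_STRATUM) if g in self.rules]


def mine_by_age_group(
    records: Sequence[DischargeRecord],
    cfg: MiningConfig | None = None,
    *,
    include_principal: bool = False,
) -> StratifiedRuleSets:
    """Run the full mining pipeline per age stratum and pooled.

    Each stratum uses its own patient total as the support denominator; the
    pooled ``all`` run is identical to mining the full cohort directly.
    Empty strata yield empty rule lists with a warning.
    """
    cfg = cfg or MiningConfig()
    partitions: dict[str, list[DischargeRecord]] = {g: [] for g in AGE_GROUPS}
    for r in records:
        partitions[r.age_group].append(r)
    partitions[ALL_STRATUM] = list(records)

    rules: dict[str, tuple[AssociationRule, ...]] = {}
    totals: dict[str, int] = {}
    for stratum, part in partitions.items():
        totals[stratum] = len(part)
        if not part:
            warnings.warn(f"age stratum {stratum} has no records", stacklevel=2)
            rules[stratum] = ()
            continue
        tdb = build_transactions(part, include_principal=include_principal)
        frequent = apriori(tdb, cfg)
        rules[stratum] = tuple(rank_rules(generate_rules(frequent, tdb, cfg)))
    return StratifiedRuleSets(rules=rules, totals=totals)


def presence_matrix(srs: StratifiedRuleSets) -> pd.DataFrame:
    """Code x stratum boolean table of rule participation.

    A cell is True iff the code occurs in the antecedent or consequent of at
    least one retained rule in that stratum. Rows are sorted by code;
    columns follow the life-cycle order with the pooled column last.
    """
    strata = srs.strata()
    codes: set[str] = set()
    for stratum in strata:
        for rule in srs.rules[stratum]:
            codes |= rule.items
    rows = sorted(codes)
    data = {
        stratum: [
            any(code in rule.items for rule in srs.rules[stratum]) for code in rows
        ]
        for stratum in strata
    }
    return pd.DataFrame(data, index=rows, columns=strata)


def write_presence_csv(matrix: pd.DataFrame, path) -> None:
    """Render the presence matrix with ``O`` marks and blank cells."""
    rendered = matrix.map(lambda v: "O" if v else "")
    rendered.to_csv(path, index_label="code")


@dataclass(frozen=True)
class CompositionStats:
    """Share of rules that involve given codes (percentages, 1 decimal)."""

    n_rules: int
    frac_with_code: Mapping[str, float]
    frac_with_all_of: Mapping[frozenset, float]


def composition_stats(
    rules: Sequence[AssociationRule],
    codes: Iterable[str],
    code_sets: Iterable[frozenset | set] = (),
) -> CompositionStats:
    """Percentage of rules whose items include each code / every code of a set."""
    rules = list(rules)
    if not rules:
        raise ValueError("empty rule list")
    n = len(rules)
    frac_code = {
        c: round_half_up(100.0 * sum(1 for r in rules if c in r.items) / n, 1)
        for c in codes
    }
    frac_sets = {
        frozenset(s): round_half_up(
            100.0 * sum(1 for r in rules if frozenset(s) <= r.items) / n, 1
        )
        for s in code_sets
    }
    return CompositionStats(n_rules=n, frac_with_code=frac_code, frac_with_all_of=frac_sets)
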