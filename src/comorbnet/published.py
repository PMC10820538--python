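"""Published pooled comorbidity rule set from the Korean national discharge registry.

The nationwide analysis of endocrine inpatients (KNHDS 2006-2021, n = 68,515
adults with a principal diagnosis in E00-E90) reported 61 retained
association rules between 3-character comorbidity categories. The registry
microdata are access-restricted, but the printed rule table itself —
antecedent, consequent, patient count N, confidence and lift — is public
and ships here as a CSV fixture. Support and IS are recomputed from N, the
cohort total and the printed lift, which reproduces every printed value;
the table exercises ranking, composition and graph-export code against
real published results.
"""

from __future__ import annotations

import csv
from importlib import resources

from .arm import AssociationRule, is_measure

__all__ = ["PUBLISHED_TOTAL", "load_published_rules"]

#: Total adult endocrine-inpatient cohort size behind the published rule table.
PUBLISHED_TOTAL = 68_515


def load_published_rules() -> list[AssociationRule]:
    """Load the 61 published pooled rules, IS-ranked as printed.

    Measures carried verbatim: patient count N, confidence, lift. Support is
    recomputed as N / 68,515 and IS as sqrt(unrounded support x lift); both
    match the printed 3-decimal values exactly.
    """
    rules: list[AssociationRule] = []
    path = resources.files("comorbnet.data").joinpath("published_rules.csv")
    with path.open("r", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            n = int(row["n"])
            support = n / PUBLISHED_TOTAL
            lift = float(row["lift"])
            rules.append(
                AssociationRule(
                    antecedent=frozenset(row["antecedent"].split(";")),
                    consequent=frozenset(row["consequent"].split(";")),
                    count=n,
                    support=support,
                    confidence=float(row["confidence"]),
                    lift=lift,
                    is_measure=is_measure(support, lift),
                )
            )
    return rules
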