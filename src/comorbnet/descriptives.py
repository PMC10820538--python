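"""Baseline-characteristics summaries by sex and comorbidity item frequencies.

Categorical variables are compared between sexes with Pearson's chi-squared
test (no continuity correction, the large-sample registry convention);
continuous variables are reported as mean ± SD. Item frequencies count each
3-character comorbidity category over all patients, with the full-cohort
denominator.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .arm import TransactionDB, round_half_up
from .records import AGE_GROUPS, BED_SIZES, DischargeRecord

logger = logging.getLogger(__name__)

__all__ = [
    "ContingencyTable",
    "ChiSquaredResult",
    "ItemFrequency",
    "chi_squared",
    "summarize_by_sex",
    "item_frequencies",
    "format_p",
]


@dataclass(frozen=True)
class ContingencyTable:
    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("counts shape does not match labels")
        if (counts < 0).any():
            raise ValueError("negative cell count")


@dataclass(frozen=True)
class ChiSquaredResult:
    statistic: float
    df: int
    p_value: float


def chi_squared(table: ContingencyTable) -> ChiSquaredResult:
    """Pearson chi-squared test of independence, without Yates correction."""
    counts = np.asarray(table.counts, dtype=float)
    if counts.shape[0] < 2 or counts.shape[1] < 2:
        raise ValueError("need at least a 2x2 table")
    row_tot = counts.sum(axis=1)
    col_tot = counts.sum(axis=0)
    if (row_tot == 0).any():
        bad = [table.row_labels[i] for i in np.flatnonzero(row_tot == 0)]
        raise ValueError(f"degenerate row(s) with zero total: {', '.join(bad)}")
    if (col_tot == 0).any():
        bad = [table.col_labels[j] for j in np.flatnonzero(col_tot == 0)]
        raise ValueError(f"degenerate column(s) with zero total: {', '.join(bad)}")
    stat, p, df, _ = stats.chi2_contingency(counts, correction=False)
    return ChiSquaredResult(statistic=float(stat), df=int(df), p_value=float(p))


def format_p(p: float, floor: float = 0.001) -> str:
    """Render a p-value the way registry tables print it (``<0.001`` below the floor)."""
    return f"<{floor}" if p < floor else f"{p:.3f}"


_CATEGORICAL = {
    "Age group": lambda r: r.age_group,
    "Insurance type": lambda r: r.insurance_type,
    "Admission route": lambda r: r.admission_route,
    "Treatment outcome": lambda r: r.treatment_outcome,
    "Death Y/N": lambda r: "yes" if r.death else "no",
    "Operation Y/N": lambda r: "yes" if r.surgery else "no",
    "Comorbidity Y/N": lambda r: "yes" if r.secondary_dx else "no",
    "Bed size": lambda r: r.bed_size,
}

_LEVEL_ORDER = {
    "Age group": list(AGE_GROUPS),
    "Insurance type": ["national_health", "medicaid1", "medicaid2", "other"],
    "Admission route": ["emergency", "outpatient", "other"],
    "Treatment outcome": ["improved", "not_improved", "death", "other"],
    "Death Y/N": ["yes", "no"],
    "Operation Y/N": ["yes", "no"],
    "Comorbidity Y/N": ["yes", "no"],
    "Bed size": list(BED_SIZES),
}

_CONTINUOUS = {
    "Age (year)": lambda r: r.age,
    "Length of stay (day)": lambda r: r.length_of_stay,
}


def summarize_by_sex(records: list[DischargeRecord]) -> pd.DataFrame:
    """Baseline-characteristics table by sex with chi-squared p per variable.

    Returns a long-format frame with columns ``variable``, ``level``, one
    count-(percent) column per sex present, and ``p``. Percentages are
    within-sex and rounded to 1 decimal; continuous variables appear as
    mean ± SD rows (Welch-style testing is not performed; the registry
    convention compares categoricals only, so continuous rows carry no p).
    """
    if not records:
        raise ValueError("empty cohort")
    sexes = [s for s in ("male", "female") if any(r.sex == s for r in records)]
    if len(sexes) < 2:
        warnings.warn(
            f"only one sex level present ({sexes}); no between-sex test performed",
            stacklevel=2,
        )
    by_sex = {s: [r for r in records if r.sex == s] for s in sexes}
    n_by_sex = {s: len(v) for s, v in by_sex.items()}

    rows: list[dict] = []
    rows.append(
        {"variable": "N", "level": "", **{s: str(n_by_sex[s]) for s in sexes}, "p": ""}
    )
    for var, getter in _CONTINUOUS.items():
        row = {"variable": var, "level": "", "p": ""}
        for s in sexes:
            vals = np.array([getter(r) for r in by_sex[s]], dtype=float)
            row[s] = f"{vals.mean():.1f} ± {vals.std(ddof=1):.1f}"
        rows.append(row)
    for var, getter in _CATEGORICAL.items():
        levels = [
            lv
            for lv in _LEVEL_ORDER[var]
            if any(getter(r) == lv for r in records)
        ]
        counts = {
            s: Counter(getter(r) for r in by_sex[s]) for s in sexes
        }
        p_str = ""
        if len(sexes) == 2 and len(levels) >= 2:
            table = ContingencyTable(
                row_labels=tuple(levels),
                col_labels=tuple(sexes),
                counts=np.array([[counts[s][lv] for s in sexes] for lv in levels]),
            )
            p_str = format_p(chi_squared(table).p_value)
        rows.append({"variable": var, "level": "", **{s: "" for s in sexes}, "p": p_str})
        for lv in levels:
            row = {"variable": var, "level": lv, "p": ""}
            for s in sexes:
                c = counts[s][lv]
                pct = round_half_up(100.0 * c / n_by_sex[s], 1)
                row[s] = f"{c} ({pct}%)"
            rows.append(row)
    return pd.DataFrame(rows, columns=["variable", "level", *sexes, "p"])


@dataclass(frozen=True)
class ItemFrequency:
    code: str
    count: int
    proportion: float


def item_frequencies(tdb: TransactionDB, top_n: int | None = None) -> list[ItemFrequency]:
    """Per-category occurrence counts over all transactions, descending.

    Proportions use the total-patient denominator; ties break
    lexicographically by code.
    """
    counter: Counter[str] = Counter()
    for t in tdb.transactions.values():
        counter.update(t)
    freqs = [
        ItemFrequency(code=c, count=n, proportion=n / tdb.total)
        for c, n in counter.items()
    ]
    freqs.sort(key=lambda f: (-f.count, f.code))
    return freqs[:top_n] if top_n is not None else freqs


def item_frequencies_to_dataframe(freqs: list[ItemFrequency]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "code": [f.code for f in freqs],
            "count": [f.count for f in freqs],
            "proportion": [f.proportion for f in freqs],
        }
    )
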