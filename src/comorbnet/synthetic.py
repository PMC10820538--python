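"""Synthetic discharge cohorts from a latent-class comorbidity model.

The source registry behind the analysis (the Korean national hospital
discharge survey) is access-restricted, so every downstream stage is
exercised on generated cohorts with the same statistical structure: a
finite mixture of independent-Bernoulli item profiles. Each patient draws
a latent class k with probability pi_k and then carries each comorbidity
category c independently with probability p[k][c]. The mixture yields
closed-form marginal and joint probabilities for any itemset,

    P(S) = sum_k pi_k * prod_{c in S} p[k][c],

hence exact true support, confidence, lift and IS for parameter-recovery
tests. Within a single class items are independent, so K = 1 models have
true lift 1 for every pair; planted co-occurrence comes from mixing
classes with contrasting profiles.

Demographics are drawn independently of the comorbidity process. An
optional age-shift hook multiplies per-item odds by an age-group factor,
creating stratum-specific comorbidities (e.g. type 1 diabetes only in the
youngest stratum) for testing the stratified pipeline; the closed-form
measures refer to the unshifted model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import yaml

from .records import AGE_GROUPS, DischargeRecord, Icd10Code, parse_icd10

__all__ = [
    "LatentClassModel",
    "TrueMeasures",
    "default_model",
    "sample_cohort",
    "true_measures",
    "load_model",
    "save_model",
    "DEFAULT_N",
]

#: Default cohort size, matching the adult endocrine-inpatient registry extract.
DEFAULT_N = 68_515

_AGE_BOUNDS = {"19–44": (19, 44), "45–64": (45, 64), "65–74": (65, 74), "≥75": (75, 94)}


@dataclass
class LatentClassModel:
    """Finite mixture of independent Bernoulli comorbidity profiles.

    ``item_probs[k][c]`` is the within-class prevalence of category ``c``;
    ``class_probs`` are the mixing weights. ``age_shift`` optionally maps a
    category to per-age-group odds multipliers (1 = no shift, 0 = absent in
    that stratum). Demographic marginals are categorical distributions over
    the serialized record labels; length of stay is log-normal (rounded).
    """

    class_probs: list[float]
    item_probs: list[dict[str, float]]
    vocabulary: list[str]
    principal_pool: dict[str, float]
    sex_probs: dict[str, float]
    age_group_probs: dict[str, float]
    insurance_probs: dict[str, float]
    route_probs: dict[str, float]
    outcome_probs: dict[str, float]
    bed_size_probs: dict[str, float]
    surgery_prob: float = 0.176
    los_log_mean: float = 1.9
    los_log_sd: float = 1.0
    age_shift: dict[str, dict[str, float]] = field(default_factory=dict)

    def validate(self) -> None:
        if not math.isclose(sum(self.class_probs), 1.0, abs_tol=1e-9):
            raise ValueError("class_probs must sum to 1")
        if any(p < 0 for p in self.class_probs):
            raise ValueError("class_probs must be non-negative")
        if len(self.item_probs) != len(self.class_probs):
            raise ValueError("item_probs rows must match the number of classes")
        for row in self.item_probs:
            for c, p in row.items():
                if c not in self.vocabulary:
                    raise ValueError(f"item {c} outside the vocabulary")
                if not 0 <= p <= 1:
                    raise ValueError(f"prevalence out of [0, 1] for {c}: {p}")
        for c in self.vocabulary:
            parse_icd10(c)
        for c in self.principal_pool:
            code = parse_icd10(c)
            if not "E00" <= code.category <= "E90":
                raise ValueError(f"principal {c} outside E00–E90")
        for name, probs in [
            ("sex", self.sex_probs),
            ("age_group", self.age_group_probs),
            ("insurance", self.insurance_probs),
            ("route", self.route_probs),
            ("outcome", self.outcome_probs),
            ("bed_size", self.bed_size_probs),
        ]:
            if not math.isclose(sum(probs.values()), 1.0, abs_tol=1e-6):
                raise ValueError(f"{name} probabilities must sum to 1")

    def prevalence_matrix(self) -> np.ndarray:
        """K x M matrix of within-class prevalences in vocabulary order."""
        return np.array(
            [[row.get(c, 0.0) for c in self.vocabulary] for row in self.item_probs]
        )


@dataclass(frozen=True)
class TrueMeasures:
    """Closed-form probabilities and rule measures under a latent-class model."""

    pA: float
    pB: float
    pAB: float
    support: float
    confidence: float
    lift: float
    is_measure: float


def _itemset_prob(model: LatentClassModel, items: frozenset[str]) -> float:
    total = 0.0
    for pi, row in zip(model.class_probs, model.item_probs):
        prod = 1.0
        for c in items:
            prod *= row.get(c, 0.0)
        total += pi * prod
    return total


def true_measures(
    model: LatentClassModel, A: frozenset[str] | set[str], B: frozenset[str] | set[str]
) -> TrueMeasures:
    """Exact support/confidence/lift/IS of A -> B under the mixture model."""
    A, B = frozenset(A), frozenset(B)
    if not A or not B:
        raise ValueError("antecedent and consequent must be non-empty")
    if A & B:
        raise ValueError(f"overlapping itemsets: {sorted(A & B)}")
    unknown = (A | B) - set(model.vocabulary)
    if unknown:
        raise ValueError(f"items outside the vocabulary: {sorted(unknown)}")
    pA = _itemset_prob(model, A)
    pB = _itemset_prob(model, B)
    pAB = _itemset_prob(model, A | B)
    confidence = pAB / pA if pA > 0 else float("nan")
    lift = pAB / (pA * pB) if pA > 0 and pB > 0 else float("nan")
    return TrueMeasures(
        pA=pA,
        pB=pB,
        pAB=pAB,
        support=pAB,
        confidence=confidence,
        lift=lift,
        is_measure=math.sqrt(pAB * lift) if lift == lift else float("nan"),
    )


def _shifted_prob(p: float, multiplier: float) -> float:
    """Apply an odds multiplier to a Bernoulli probability."""
    if multiplier == 1.0 or p == 0.0:
        return p if multiplier > 0 else 0.0
    if multiplier == 0.0:
        return 0.0
    odds = p / (1.0 - p) * multiplier
    return odds / (1.0 + odds)


def sample_cohort(
    model: LatentClassModel, n: int, seed: int
) -> list[DischargeRecord]:
    """Draw a synthetic cohort of n discharge records; bit-reproducible per seed.

    Per patient: latent class ~ class_probs, then each vocabulary item
    independently Bernoulli (with age-group odds shift when configured);
    principal diagnosis from the principal pool; demographics from their
    marginals; death flag tied to the sampled treatment outcome.
    """
    if n < 1:
        raise ValueError(f"cohort size must be >= 1: {n}")
    model.validate()
    rng = np.random.default_rng(seed)
    M = len(model.vocabulary)
    P = model.prevalence_matrix()

    classes = rng.choice(len(model.class_probs), size=n, p=model.class_probs)

    groups = list(model.age_group_probs)
    group_idx = rng.choice(len(groups), size=n, p=list(model.age_group_probs.values()))
    ages = np.empty(n, dtype=int)
    for g, label in enumerate(groups):
        lo, hi = _AGE_BOUNDS[label]
        mask = group_idx == g
        ages[mask] = rng.integers(lo, hi + 1, size=int(mask.sum()))

    # per-record item prevalences, with optional age-group odds shift
    probs = P[classes]  # n x M
    if model.age_shift:
        probs = probs.copy()
        for c, by_group in model.age_shift.items():
            j = model.vocabulary.index(c)
            for g, label in enumerate(groups):
                m = by_group.get(label, 1.0)
                if m == 1.0:
                    continue
                mask = group_idx == g
                p = probs[mask, j]
                if m == 0.0:
                    probs[mask, j] = 0.0
                else:
                    odds = p / (1.0 - p) * m
                    probs[mask, j] = odds / (1.0 + odds)
    items = rng.random((n, M)) < probs

    def draw(levels: dict[str, float]) -> np.ndarray:
        labels = list(levels)
        idx = rng.choice(len(labels), size=n, p=list(levels.values()))
        return np.array(labels, dtype=object)[idx]

    principal = draw(model.principal_pool)
    sexes = draw(model.sex_probs)
    insurance = draw(model.insurance_probs)
    route = draw(model.route_probs)
    outcome = draw(model.outcome_probs)
    bed = draw(model.bed_size_probs)
    surgery = rng.random(n) < model.surgery_prob
    los = np.rint(rng.lognormal(model.los_log_mean, model.los_log_sd, size=n)).astype(int)
    los = np.maximum(los, 0)

    vocab_codes = [Icd10Code(raw=c, category=c) for c in model.vocabulary]
    records = []
    for i in range(n):
        records.append(
            DischargeRecord(
                patient_id=f"P{i:07d}",
                sex=str(sexes[i]),
                age=int(ages[i]),
                insurance_type=str(insurance[i]),
                admission_route=str(route[i]),
                treatment_outcome=str(outcome[i]),
                length_of_stay=int(los[i]),
                death=str(outcome[i]) == "death",
                surgery=bool(surgery[i]),
                bed_size=str(bed[i]),
                principal_dx=parse_icd10(str(principal[i])),
                secondary_dx=tuple(
                    vocab_codes[j] for j in np.flatnonzero(items[i])
                ),
            )
        )
    return records


# ---------------------------------------------------------------------------
# Default registry-emulation configuration
# ---------------------------------------------------------------------------

_VOCABULARY = [
    "D64", "E03", "E04", "E05", "E10", "E11", "E14", "E16", "E27", "E78",
    "E87", "G63", "H36", "I10", "I20", "I25", "I69", "K21", "K29", "K70",
    "K76", "M81", "N08", "N17", "N18", "N39",
]

# Four latent profiles: essentially comorbidity-free admissions, a mild
# metabolic profile, a cardio-metabolic profile (diabetes + hypertension +
# dyslipidemia), and a metabolic-renal profile concentrating glomerular
# disease and chronic kidney disease so the N08/N18 pair carries strong
# planted co-occurrence (true lift ~5-6).
_CLASS_PROBS = [0.13, 0.38, 0.33, 0.16]

_BACKGROUND = {
    "none": {
        "E11": 0.02, "I10": 0.01, "E14": 0.01, "E87": 0.02, "K29": 0.02,
        "K21": 0.015, "D64": 0.005, "E03": 0.005, "E05": 0.005, "K70": 0.005,
        "K76": 0.005, "N39": 0.005,
    },
    "mild": {
        "E11": 0.46, "I10": 0.20, "E14": 0.21, "E78": 0.08, "E87": 0.09,
        "H36": 0.05, "G63": 0.04, "K29": 0.07, "K21": 0.05, "N08": 0.012,
        "N18": 0.010, "D64": 0.02, "E03": 0.02, "E04": 0.01, "E05": 0.02,
        "E10": 0.02, "E16": 0.01, "E27": 0.01, "I20": 0.02, "I25": 0.02,
        "I69": 0.01, "K70": 0.015, "K76": 0.02, "M81": 0.02, "N17": 0.01,
        "N39": 0.015,
    },
    "cardio": {
        "E11": 0.80, "I10": 0.48, "E14": 0.25, "E78": 0.17, "E87": 0.13,
        "H36": 0.14, "G63": 0.10, "K29": 0.07, "K21": 0.05, "N08": 0.022,
        "N18": 0.015, "D64": 0.03, "E03": 0.02, "E04": 0.01, "E05": 0.015,
        "E10": 0.015, "E16": 0.01, "E27": 0.01, "I20": 0.03, "I25": 0.04,
        "I69": 0.02, "K70": 0.02, "K76": 0.025, "M81": 0.03, "N17": 0.015,
        "N39": 0.02,
    },
    "renal": {
        "E11": 0.85, "I10": 0.55, "E14": 0.20, "E78": 0.15, "E87": 0.25,
        "H36": 0.30, "G63": 0.22, "K29": 0.07, "K21": 0.04, "N08": 0.62,
        "N18": 0.55, "D64": 0.05, "E03": 0.02, "E04": 0.01, "E05": 0.01,
        "E10": 0.02, "E16": 0.01, "E27": 0.01, "I20": 0.03, "I25": 0.04,
        "I69": 0.02, "K70": 0.02, "K76": 0.02, "M81": 0.03, "N17": 0.04,
        "N39": 0.02,
    },
}

# Stratum-selective comorbidities for the stratified pipeline: type 1
# diabetes concentrated in the youngest stratum, reflux disease in midlife,
# electrolyte disorders / cerebrovascular sequelae / osteoporosis in the
# elderly, ischemic heart disease and urinary disorders in the oldest.
_AGE_SHIFT = {
    "E10": {"19–44": 6.0, "45–64": 0.15, "65–74": 0.0, "≥75": 0.0},
    "K21": {"19–44": 0.3, "45–64": 2.2, "65–74": 0.3, "≥75": 0.2},
    "K76": {"19–44": 1.5, "45–64": 1.5, "65–74": 0.2, "≥75": 0.1},
    "E87": {"19–44": 0.25, "45–64": 0.5, "65–74": 1.8, "≥75": 2.2},
    "I69": {"19–44": 0.1, "45–64": 0.4, "65–74": 2.0, "≥75": 2.5},
    "M81": {"19–44": 0.1, "45–64": 0.4, "65–74": 2.0, "≥75": 2.5},
    "I25": {"19–44": 0.2, "45–64": 0.6, "65–74": 1.5, "≥75": 2.5},
    "N39": {"19–44": 0.2, "45–64": 0.5, "65–74": 1.0, "≥75": 2.5},
}


def default_model(age_shift: bool = True) -> LatentClassModel:
    """Default registry-emulation model.

    Calibrated so that type 2 diabetes (E11) and essential hypertension
    (I10) are the two most frequent comorbidities, roughly four patients in
    five carry at least one comorbidity, and the glomerular-disorder /
    chronic-kidney-disease pair has true lift in the 5-6 range.
    """
    model = LatentClassModel(
        class_probs=list(_CLASS_PROBS),
        item_probs=[dict(_BACKGROUND[k]) for k in ("none", "mild", "cardio", "renal")],
        vocabulary=list(_VOCABULARY),
        principal_pool={
            "E11": 0.55, "E05": 0.08, "E14": 0.06, "E10": 0.05, "E03": 0.05,
            "E87": 0.05, "E16": 0.04, "E78": 0.04, "E04": 0.03, "E27": 0.03,
            "E66": 0.02,
        },
        sex_probs={"male": 0.469, "female": 0.531},
        age_group_probs={
            "19–44": 0.1785, "45–64": 0.3844, "65–74": 0.2243, "≥75": 0.2128,
        },
        insurance_probs={
            "national_health": 0.8311, "medicaid1": 0.1396,
            "medicaid2": 0.0184, "other": 0.0109,
        },
        route_probs={"emergency": 0.3043, "outpatient": 0.6947, "other": 0.0010},
        outcome_probs={
            "improved": 0.9564, "not_improved": 0.0309,
            "death": 0.0117, "other": 0.0010,
        },
        bed_size_probs={
            "100–299": 0.2804, "300–499": 0.1402,
            "500–999": 0.4392, "≥1000": 0.1402,
        },
        surgery_prob=0.1757,
        age_shift=dict(_AGE_SHIFT) if age_shift else {},
    )
    model.validate()
    return model


def save_model(model: LatentClassModel, path) -> None:
    """Serialize a model to YAML."""
    payload = {k: getattr(model, k) for k in model.__dataclass_fields__}
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(payload, fh, allow_unicode=True, sort_keys=False)


def load_model(path) -> LatentClassModel:
    """Load and validate a model from YAML."""
    with open(path, encoding="utf-8") as fh:
        payload = yaml.safe_load(fh)
    model = LatentClassModel(**payload)
    model.validate()
    return model
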