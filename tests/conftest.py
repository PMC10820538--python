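import numpy as np
import pytest

from comorbnet.arm import MiningConfig, TransactionDB
from comorbnet.records import DischargeRecord, parse_icd10


def make_record(
    patient_id="p1",
    sex="male",
    age=60,
    principal="E11",
    secondary=(),
    outcome="improved",
    los=5,
    **kw,
):
    return DischargeRecord(
        patient_id=patient_id,
        sex=sex,
        age=age,
        insurance_type=kw.get("insurance_type", "national_health"),
        admission_route=kw.get("admission_route", "outpatient"),
        treatment_outcome=outcome,
        length_of_stay=los,
        death=outcome == "death",
        surgery=kw.get("surgery", False),
        bed_size=kw.get("bed_size", "500–999"),
        principal_dx=parse_icd10(principal),
        secondary_dx=tuple(parse_icd10(c) for c in secondary),
    ).normalized()


@pytest.fixture
def toy_tdb():
    """8 patients over items {A11, B22, C33}: AB, AB, AB, ABC, BC, C, A, empty."""
    baskets = [
        {"A11", "B22"},
        {"A11", "B22"},
        {"A11", "B22"},
        {"A11", "B22", "C33"},
        {"B22", "C33"},
        {"C33"},
        {"A11"},
        set(),
    ]
    return TransactionDB(
        transactions={str(i): frozenset(b) for i, b in enumerate(baskets)}, total=8
    )


@pytest.fixture
def toy_cfg():
    return MiningConfig(min_support=0.2, min_confidence=0.1)


def random_tdb(rng: np.random.Generator, max_items=10, max_tx=200):
    """Random transaction DB for oracle-equivalence property suites."""
    n_items = int(rng.integers(2, max_items + 1))
    items = [f"{chr(65 + i)}{i:02d}" for i in range(n_items)]
    n_tx = int(rng.integers(5, max_tx + 1))
    density = rng.uniform(0.05, 0.5)
    tx = {}
    for i in range(n_tx):
        basket = frozenset(c for c in items if rng.random() < density)
        tx[str(i)] = basket
    return TransactionDB(transactions=tx, total=n_tx)
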