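import datetime as dt

import numpy as np
import pytest

from mhamfd.claims import ClaimRecord, FeatureMatrix


def record(p, date, dept, meds=(), label=None):
    return ClaimRecord(p, dt.date.fromisoformat(date), dept, frozenset(meds), label)


@pytest.fixture
def three_patient_claims():
    """p1/p2 share a full co-visit; p3 shares only the department with p1."""
    return [
        record("p1", "2018-01-05", "d1", {"m1"}, 1),
        record("p2", "2018-01-05", "d1", {"m1"}, 1),
        record("p3", "2018-01-06", "d1", {"m2"}, 0),
    ]


@pytest.fixture
def three_patient_features():
    rng = np.random.default_rng(7)
    return FeatureMatrix(["p1", "p2", "p3"], rng.standard_normal((3, 4)))


def random_claims(rng, n_patients=8, n_visits_max=4, n_depts=3, n_dates=4, n_meds=4):
    """Small random claim population for property tests."""
    claims = []
    for i in range(n_patients):
        label = int(rng.integers(0, 2))
        for _ in range(int(rng.integers(1, n_visits_max + 1))):
            meds = frozenset(
                f"m{j}" for j in rng.choice(n_meds, size=int(rng.integers(0, 3)), replace=False)
            )
            claims.append(
                ClaimRecord(
                    f"p{i}",
                    dt.date(2018, 1, 1) + dt.timedelta(days=int(rng.integers(n_dates))),
                    f"d{int(rng.integers(n_depts))}",
                    meds,
                    label,
                )
            )
    return claims
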