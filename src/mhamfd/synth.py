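"""Synthetic claim populations with planted fraud rings.

Real claim data of this kind is private, so every stage of the pipeline is
exercised on simulated populations that reproduce its structure: four entity
universes (patients, calendar dates, medicines, departments), a configurable
fraud ratio, and fraud that clusters through shared co-visits rather than
through per-patient attributes.  Fraud patients are partitioned into rings;
each ring receives co-visit events in which all members appear in the same
department on the same date (the entity types shared are set by
``signal_level``), on top of uniform background visits for everyone.  With
``feature_shift = 0`` the feature matrix is pure noise, so any classifier
signal must come from the visit structure.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np

from .claims import ClaimRecord, FeatureMatrix

__all__ = ["SynthConfig", "generate_claims", "generate_features", "ring_membership"]

_EPOCH = _dt.date(2018, 1, 1)  # arbitrary calendar anchor for date tokens


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for the simulated claim population.

    Defaults emulate the balanced regime: ~300 patients at a 1:2
    fraud:non-fraud ratio, entity universes scaled down from the thousands of
    medicines / hundreds of departments of a municipal claims year, rings of
    6 fraudsters with 3 joint co-visits each, and 2 background visits per
    patient.  The universe sizes are set so that the single-entity relations
    (PDP, PTP, PMP) are dense with coincidental overlaps and therefore
    weakly informative, while conjunction relations (same department AND
    same day) almost never arise by chance and stay sparse and
    fraud-enriched.
    """

    n_fraud: int = 100
    n_normal: int = 200
    n_departments: int = 60
    n_dates: int = 180
    n_medicines: int = 200
    ring_size: int = 6
    co_visits_per_ring: int = 3
    background_visits_per_patient: int = 2
    medicines_per_visit: int = 2
    signal_level: int = 2  # 1: rings share T only; 2: D and T; 3: D, T and M
    feature_dim: int = 32
    feature_shift: float = 0.0  # per-class mean shift mu; 0 = structure-only signal
    seed: int = 0

    def __post_init__(self):
        for name in (
            "n_fraud",
            "n_normal",
            "n_departments",
            "n_dates",
            "n_medicines",
            "ring_size",
            "co_visits_per_ring",
            "background_visits_per_patient",
            "medicines_per_visit",
            "feature_dim",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.feature_shift < 0:
            raise ValueError("feature_shift must be >= 0")
        if self.signal_level not in (1, 2, 3):
            raise ValueError("signal_level must be 1, 2 or 3")
        if self.ring_size > self.n_fraud:
            raise ValueError("ring_size cannot exceed n_fraud")
        if self.medicines_per_visit > self.n_medicines:
            raise ValueError("universe too small: medicines_per_visit > n_medicines")

    def with_seed(self, seed: int) -> "SynthConfig":
        return replace(self, seed=seed)


def _date_token(day: int) -> _dt.date:
    return _EPOCH + _dt.timedelta(days=int(day))


def ring_membership(config: SynthConfig) -> list[list[str]]:
    """Ring partition of the fraud patients (last ring may be smaller)."""
    fraud = [f"f{i:04d}" for i in range(config.n_fraud)]
    return [fraud[i : i + config.ring_size] for i in range(0, len(fraud), config.ring_size)]


def generate_claims(
    config: SynthConfig, seed: int | None = None
) -> tuple[list[ClaimRecord], Mapping[str, int]]:
    """Simulate a claim population; returns the records and a label map.

    Deterministic under a fixed seed (``seed`` overrides ``config.seed``).
    """
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    rings = ring_membership(config)
    fraud = [p for ring in rings for p in ring]
    normal = [f"n{i:04d}" for i in range(config.n_normal)]
    labels = {**{p: 1 for p in fraud}, **{p: 0 for p in normal}}

    records: list[ClaimRecord] = []

    def draw_meds() -> frozenset[str]:
        meds = rng.choice(config.n_medicines, size=config.medicines_per_visit, replace=False)
        return frozenset(f"m{m:04d}" for m in meds)

    # planted ring co-visits: the entity types shared across members follow
    # signal_level; unshared entity types are drawn independently per member
    for ring in rings:
        for _ in range(config.co_visits_per_ring):
            date = _date_token(rng.integers(config.n_dates))
            dept = f"d{rng.integers(config.n_departments):04d}"
            meds = draw_meds()
            for p in ring:
                r_dept = dept if config.signal_level >= 2 else f"d{rng.integers(config.n_departments):04d}"
                r_meds = meds if config.signal_level == 3 else draw_meds()
                records.append(ClaimRecord(p, date, r_dept, r_meds, labels[p]))

    # background visits for everyone: uniform entities, no planted structure
    for p in fraud + normal:
        for _ in range(config.background_visits_per_patient):
            records.append(
                ClaimRecord(
                    p,
                    _date_token(rng.integers(config.n_dates)),
                    f"d{rng.integers(config.n_departments):04d}",
                    draw_meds(),
                    labels[p],
                )
            )
    return records, labels


def generate_features(
    labels: Mapping[str, int], config: SynthConfig, seed: int | None = None
) -> FeatureMatrix:
    """Standard-normal attributes, mean-shifted by ``feature_shift`` for fraud.

    With the default shift of 0 the matrix carries no label information at
    all; it stands in for the real per-patient attribute matrix X whose
    content the private data never exposes.
    """
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    patients = sorted(labels)
    values = rng.standard_normal((len(patients), config.feature_dim))
    if config.feature_shift:
        is_fraud = np.array([labels[p] == 1 for p in patients])
        values[is_fraud] += config.feature_shift
    return FeatureMatrix(patients, values)
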