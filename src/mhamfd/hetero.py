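"""Attributed heterogeneous information network built from claim records.

Four node types: Patient (P), Time (T, calendar dates at day granularity),
Medicine (M) and Department (D).  Every visit contributes a P–D edge, a P–T
edge and one P–M edge per medicine, all tagged with the visit they came from
so that downstream conjunction relations can require co-occurrence within a
single visit.  Only patient nodes carry features.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .claims import ClaimRecord, FeatureMatrix

__all__ = ["Visit", "HeteroGraph", "TypeCounts", "build_hetero_graph", "graph_summary"]


@dataclass(frozen=True)
class Visit:
    """One visit event, in integer index space."""

    patient: int
    date: int
    department: int
    medicines: frozenset[int]


@dataclass
class TypeCounts:
    """Composition report of a heterogeneous graph."""

    nodes: dict[str, int]  # per node type P/T/M/D
    edges: dict[str, int]  # per link type P-D/P-T/P-M
    positive: int
    negative: int
    unlabelled: int

    @property
    def n_patients(self) -> int:
        return self.nodes["P"]

    def as_dict(self) -> dict:
        return {
            "nodes": dict(self.nodes),
            "edges": dict(self.edges),
            "labels": {
                "positive": self.positive,
                "negative": self.negative,
                "unlabelled": self.unlabelled,
            },
        }


class HeteroGraph:
    """G = {V, eps, X}: typed node sets, visit-tagged typed edges, patient features.

    Node identity is set-like: rebuilding from a shuffled copy of the same
    claims yields the same graph.  Tokens are kept sorted so integer indices
    are reproducible.
    """

    def __init__(
        self,
        patients: list[str],
        dates: list[_dt.date],
        medicines: list[str],
        departments: list[str],
        visits: list[Visit],
        features: FeatureMatrix,
        labels: np.ndarray,
    ):
        self.patients = patients
        self.dates = dates
        self.medicines = medicines
        self.departments = departments
        self.visits = visits
        self.features = features
        self.labels = np.asarray(labels)  # 1 fraud / 0 non-fraud / -1 unlabelled
        self._check()

    def _check(self) -> None:
        n = len(self.patients)
        if self.labels.shape != (n,):
            raise ValueError("labels must align with patients")
        if self.features.patient_ids != self.patients:
            raise ValueError("feature matrix must be indexed by the graph's patients")
        for v in self.visits:
            if not (0 <= v.patient < n and 0 <= v.date < len(self.dates)):
                raise ValueError("visit references an unknown node")
            if not 0 <= v.department < len(self.departments):
                raise ValueError("visit references an unknown department")
            if any(not 0 <= m < len(self.medicines) for m in v.medicines):
                raise ValueError("visit references an unknown medicine")
        # heterogeneity condition |A| + |R| > 2: four node types, three link types
        if len(self.node_types) + len(self.link_types) <= 2:
            raise ValueError("graph is not heterogeneous")

    node_types = ("P", "T", "M", "D")
    link_types = ("P-D", "P-T", "P-M")

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    def to_json(self, path: str | Path) -> None:
        obj = {
            "patients": self.patients,
            "dates": [d.isoformat() for d in self.dates],
            "medicines": self.medicines,
            "departments": self.departments,
            "visits": [
                {
                    "patient": v.patient,
                    "date": v.date,
                    "department": v.department,
                    "medicines": sorted(v.medicines),
                }
                for v in self.visits
            ],
            "labels": self.labels.tolist(),
        }
        Path(path).write_text(json.dumps(obj, indent=2) + "\n", encoding="utf-8")


def build_hetero_graph(
    claims: Sequence[ClaimRecord], features: FeatureMatrix | None = None
) -> HeteroGraph:
    """Construct the AHIN from claim records.

    One node per distinct patient / date / medicine / department token.  When
    ``features`` is None, structural fallback features are generated.
    """
    from .claims import structural_features

    if not claims:
        raise ValueError("claims must be non-empty")
    patients = sorted({r.patient_id for r in claims})
    dates = sorted({r.visit_date for r in claims})
    medicines = sorted(set().union(*[r.medicine_ids for r in claims]))
    departments = sorted({r.department_id for r in claims})
    p_idx = {p: i for i, p in enumerate(patients)}
    t_idx = {t: i for i, t in enumerate(dates)}
    m_idx = {m: i for i, m in enumerate(medicines)}
    d_idx = {d: i for i, d in enumerate(departments)}

    seen: set[tuple] = set()
    visits: list[Visit] = []
    labels = np.full(len(patients), -1, dtype=np.int64)
    for r in sorted(
        claims,
        key=lambda r: (r.patient_id, r.visit_date, r.department_id, tuple(sorted(r.medicine_ids))),
    ):
        key = (r.patient_id, r.visit_date, r.department_id, r.medicine_ids)
        if key not in seen:
            seen.add(key)
            visits.append(
                Visit(
                    p_idx[r.patient_id],
                    t_idx[r.visit_date],
                    d_idx[r.department_id],
                    frozenset(m_idx[m] for m in r.medicine_ids),
                )
            )
        if r.label is not None:
            if labels[p_idx[r.patient_id]] not in (-1, r.label):
                raise ValueError(f"patient {r.patient_id!r} carries conflicting labels")
            labels[p_idx[r.patient_id]] = r.label

    if features is None:
        features = structural_features(claims)
    features = features.reindex(patients)
    return HeteroGraph(patients, dates, medicines, departments, visits, features, labels)


def graph_summary(g: HeteroGraph) -> TypeCounts:
    """Exact node, edge and label-class counts of the network."""
    return TypeCounts(
        nodes={
            "P": len(g.patients),
            "T": len(g.dates),
            "M": len(g.medicines),
            "D": len(g.departments),
        },
        edges={
            "P-D": len(g.visits),
            "P-T": len(g.visits),
            "P-M": sum(len(v.medicines) for v in g.visits),
        },
        positive=int((g.labels == 1).sum()),
        negative=int((g.labels == 0).sum()),
        unlabelled=int((g.labels == -1).sum()),
    )
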