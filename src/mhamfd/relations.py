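"""Behavioural-relationship paths and patient-patient relation graphs.

A behavioural relationship links two patients who share a set of entity
types within a *single pair of visits*: department (D), date (T) and/or a
common medicine (M), all conditions holding jointly on that visit pair.  The
seven paths are PDP, PTP, PMP (single level), PDTP, PDMP, PTMP (dual level)
and PDTMP (triple level); a path's level is the number of shared entity
types, and conjunction makes higher levels strictly sparser.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from .hetero import HeteroGraph, Visit

__all__ = [
    "RelationPath",
    "RelationAdjacency",
    "enumerate_relation_paths",
    "build_relation_adjacency",
    "build_all_relation_graphs",
    "group_by_level",
]

_CANONICAL_ORDER = "DTM"  # D before T before M in path names


@dataclass(frozen=True)
class RelationPath:
    """A patient-X-patient behavioural relationship and its level."""

    name: str
    shared_types: frozenset[str]
    level: int

    @classmethod
    def from_shared(cls, shared: Iterable[str]) -> "RelationPath":
        shared = frozenset(shared)
        if not shared or not shared <= set(_CANONICAL_ORDER):
            raise ValueError(f"shared types must be a non-empty subset of D/T/M, got {shared}")
        middle = "".join(c for c in _CANONICAL_ORDER if c in shared)
        return cls(name=f"P{middle}P", shared_types=shared, level=len(shared))

    @classmethod
    def from_name(cls, name: str) -> "RelationPath":
        if len(name) < 3 or name[0] != "P" or name[-1] != "P":
            raise ValueError(f"path name must start and end with P, got {name!r}")
        path = cls.from_shared(name[1:-1])
        if path.name != name:
            raise ValueError(f"non-canonical path name {name!r} (expected {path.name!r})")
        return path


def enumerate_relation_paths(max_level: int = 3) -> list[RelationPath]:
    """All behavioural relationships up to ``max_level``, grouped by level.

    ``max_level=3`` yields the full family of seven.
    """
    if max_level not in (1, 2, 3):
        raise ValueError(f"max_level must be 1, 2 or 3, got {max_level}")
    paths = []
    for level in range(1, max_level + 1):
        for combo in combinations(_CANONICAL_ORDER, level):
            paths.append(RelationPath.from_shared(combo))
    return paths


@dataclass
class RelationAdjacency:
    """Patient-patient neighbour sets under one behavioural relationship.

    ``neighbors[i]`` is the set of patients j != i connected to i;
    ``multiplicity[(i, j)]`` (i < j) counts witnessing visit pairs and is
    diagnostic only — the model attends over the unweighted adjacency.
    """

    path: RelationPath
    n: int
    neighbors: list[set[int]]
    multiplicity: dict[tuple[int, int], int] = field(default_factory=dict)
    _mask: np.ndarray | None = field(default=None, repr=False, compare=False)
    _addmask: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        if len(self.neighbors) != self.n:
            raise ValueError("neighbour list length must equal n")
        for i, ns in enumerate(self.neighbors):
            if i in ns:
                raise ValueError("adjacency must be irreflexive")
            for j in ns:
                if i not in self.neighbors[j]:
                    raise ValueError("adjacency must be symmetric")

    def attended_mask(self) -> np.ndarray:
        """Dense boolean (n, n) mask of neighbours plus self-loops (cached)."""
        if self._mask is None:
            m = np.eye(self.n, dtype=bool)
            for i, ns in enumerate(self.neighbors):
                for j in ns:
                    m[i, j] = True
            self._mask = m
        return self._mask

    def additive_mask(self) -> np.ndarray:
        """(n, n) mask: 0 on attended entries, -inf elsewhere (cached).

        Stored as float32 — both values are exact, and adding it never
        upcasts a float32 score matrix.
        """
        if self._addmask is None:
            self._addmask = np.where(self.attended_mask(), 0.0, -np.inf).astype(np.float32)
        return self._addmask

    def n_edges(self) -> int:
        return sum(len(ns) for ns in self.neighbors) // 2

    def to_tsv(self, path: str | Path, patient_ids: list[str]) -> None:
        with Path(path).open("w", encoding="utf-8") as fh:
            fh.write("patient_a\tpatient_b\tpath\tmultiplicity\n")
            for i in range(self.n):
                for j in sorted(self.neighbors[i]):
                    if i < j:
                        mult = self.multiplicity.get((i, j), 1)
                        fh.write(
                            f"{patient_ids[i]}\t{patient_ids[j]}\t{self.path.name}\t{mult}\n"
                        )


def _visit_keys(v: Visit, shared: frozenset[str]) -> list[tuple]:
    """Bucket keys for a visit: two visits collide iff they satisfy the
    conjunction of shared conditions (medicine = non-empty intersection,
    realised by one key per medicine)."""
    base = []
    if "D" in shared:
        base.append(v.department)
    if "T" in shared:
        base.append(v.date)
    if "M" in shared:
        return [tuple(base + [m]) for m in v.medicines]
    return [tuple(base)]


def build_relation_adjacency(
    g: HeteroGraph,
    path: RelationPath,
    max_neighbors: int | None = None,
    seed: int | None = None,
) -> RelationAdjacency:
    """Materialise the patient-patient adjacency of one behavioural path.

    Patients i and j are neighbours iff some visit of i and some visit of j
    jointly match on every shared entity type of the path.  With
    ``max_neighbors`` set, each over-full neighbour set is randomly
    down-sampled (seeded); symmetry is restored by keeping the union of
    surviving directions.
    """
    n = g.n_patients
    buckets: dict[tuple, list[int]] = {}
    for vid, v in enumerate(g.visits):
        for key in _visit_keys(v, path.shared_types):
            buckets.setdefault(key, []).append(vid)

    witnesses: dict[tuple[int, int], set[tuple[int, int]]] = {}
    for vids in buckets.values():
        if len(vids) < 2:
            continue
        for a, b in combinations(vids, 2):
            pa, pb = g.visits[a].patient, g.visits[b].patient
            if pa == pb:
                continue
            pair = (min(pa, pb), max(pa, pb))
            vpair = (min(a, b), max(a, b))
            witnesses.setdefault(pair, set()).add(vpair)

    neighbors: list[set[int]] = [set() for _ in range(n)]
    for (i, j) in witnesses:
        neighbors[i].add(j)
        neighbors[j].add(i)

    if max_neighbors is not None:
        rng = np.random.default_rng(seed)
        kept: set[tuple[int, int]] = set()
        for i in range(n):
            ns = sorted(neighbors[i])
            if len(ns) > max_neighbors:
                ns = list(rng.choice(ns, size=max_neighbors, replace=False))
            kept.update((min(i, j), max(i, j)) for j in ns)
        neighbors = [set() for _ in range(n)]
        for (i, j) in kept:
            neighbors[i].add(j)
            neighbors[j].add(i)
        witnesses = {p: w for p, w in witnesses.items() if p in kept}

    multiplicity = {pair: len(w) for pair, w in witnesses.items()}
    return RelationAdjacency(path=path, n=n, neighbors=neighbors, multiplicity=multiplicity)


def build_all_relation_graphs(
    g: HeteroGraph,
    max_level: int = 3,
    max_neighbors: int | None = None,
    seed: int | None = None,
) -> dict[str, RelationAdjacency]:
    """One adjacency per enumerated behavioural path, keyed by path name."""
    return {
        p.name: build_relation_adjacency(g, p, max_neighbors=max_neighbors, seed=seed)
        for p in enumerate_relation_paths(max_level)
    }


def group_by_level(
    adjacencies: Mapping[str, RelationAdjacency]
) -> dict[int, list[RelationAdjacency]]:
    """Group adjacencies by relationship level, each level name-sorted."""
    levels: dict[int, list[RelationAdjacency]] = {}
    for adj in adjacencies.values():
        levels.setdefault(adj.path.level, []).append(adj)
    return {
        lvl: sorted(adjs, key=lambda a: a.path.name)
        for lvl, adjs in sorted(levels.items())
    }
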