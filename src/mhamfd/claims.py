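"""Reading, validating and writing medical claim tables and patient features.

A claim file is delimited text (CSV or TSV, autodetected by extension) with a
header naming the five columns ``patient_id, visit_date, department_id,
medicine_ids, label``.  One row is one visit; a visit that dispenses several
medicines is a single row whose ``medicine_ids`` cell holds a separated list
(default separator ``;``).  Labels are ``1`` (fraud), ``0`` (non-fraud) or
empty (unlabelled).
"""

from __future__ import annotations

import csv
import datetime as _dt
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ClaimRecord",
    "FeatureMatrix",
    "ClaimsSchemaError",
    "ClaimsRowError",
    "LabelConsistencyError",
    "read_claims",
    "write_claims",
    "read_features",
    "write_features",
    "structural_features",
]

CLAIM_COLUMNS = ("patient_id", "visit_date", "department_id", "medicine_ids", "label")

#: number of structural summary columns produced by :func:`structural_features`
N_STRUCTURAL = 5


class ClaimsSchemaError(ValueError):
    """The claim table is missing a required column."""


class ClaimsRowError(ValueError):
    """A data row could not be parsed; carries the 1-based line number."""

    def __init__(self, line: int, message: str):
        super().__init__(f"line {line}: {message}")
        self.line = line


class LabelConsistencyError(ValueError):
    """A patient carries more than one distinct label across its records."""


@dataclass(frozen=True)
class ClaimRecord:
    """One patient visit event."""

    patient_id: str
    visit_date: _dt.date
    department_id: str
    medicine_ids: frozenset[str]
    label: int | None = None  # 1 fraud, 0 non-fraud, None unlabelled

    def __post_init__(self):
        if not self.patient_id or not self.department_id:
            raise ValueError("patient_id and department_id must be non-empty")
        if self.label not in (None, 0, 1):
            raise ValueError(f"label must be 0, 1 or None, got {self.label!r}")


@dataclass
class FeatureMatrix:
    """Per-patient attribute matrix X, one row per distinct patient."""

    patient_ids: list[str]
    values: np.ndarray  # (n_patients, k)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[0] != len(self.patient_ids):
            raise ValueError("values must be 2-D with one row per patient")
        if len(set(self.patient_ids)) != len(self.patient_ids):
            raise ValueError("duplicate patient ids in feature matrix")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite feature value for patient "
                f"{self.patient_ids[bad[0]]!r}, column {bad[1]}"
            )

    @property
    def k(self) -> int:
        return self.values.shape[1]

    def reindex(self, patients: Sequence[str]) -> "FeatureMatrix":
        pos = {p: i for i, p in enumerate(self.patient_ids)}
        missing = [p for p in patients if p not in pos]
        if missing:
            raise ValueError(f"patients missing from feature table: {missing}")
        idx = [pos[p] for p in patients]
        return FeatureMatrix(list(patients), self.values[idx])


def _delimiter_for(path: Path, dialect: str | None) -> str:
    if dialect is not None:
        return dialect
    return "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","


def _parse_label(cell: str) -> int | None:
    cell = cell.strip()
    if cell in {"", "NA", "NaN", "nan", "None"}:
        return None
    if cell in {"0", "1"}:
        return int(cell)
    raise ValueError(f"label must be 0, 1 or empty, got {cell!r}")


def read_claims(
    path: str | Path,
    dialect: str | None = None,
    medicine_sep: str = ";",
) -> list[ClaimRecord]:
    """Parse a claim table into :class:`ClaimRecord` objects, preserving row order.

    Identical rows (same patient, date, department and medicine set) collapse
    to a single visit; a patient with conflicting labels raises
    :class:`LabelConsistencyError`.
    """
    path = Path(path)
    delim = _delimiter_for(path, dialect)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter=delim)
        try:
            header = next(reader)
        except StopIteration as exc:
            raise ClaimsSchemaError("empty file: no header row") from exc
        header = [h.strip() for h in header]
        col = {name: i for i, name in enumerate(header)}
        for name in CLAIM_COLUMNS:
            if name not in col:
                raise ClaimsSchemaError(f"missing required column {name!r}")
        records: list[ClaimRecord] = []
        seen: set[tuple] = set()
        labels: dict[str, int] = {}
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            try:
                pid = row[col["patient_id"]].strip()
                date_cell = row[col["visit_date"]].strip()
                dept = row[col["department_id"]].strip()
                med_cell = row[col["medicine_ids"]].strip()
                label = _parse_label(row[col["label"]])
                if not pid:
                    raise ValueError("empty patient_id")
                if not dept:
                    raise ValueError("empty department_id")
                date = _dt.date.fromisoformat(date_cell)
                meds = frozenset(m.strip() for m in med_cell.split(medicine_sep) if m.strip())
            except ClaimsRowError:
                raise
            except (ValueError, IndexError) as exc:
                raise ClaimsRowError(lineno, str(exc)) from exc
            if label is not None:
                if labels.setdefault(pid, label) != label:
                    raise LabelConsistencyError(
                        f"patient {pid!r} carries conflicting labels"
                    )
            key = (pid, date, dept, meds)
            if key in seen:  # identical row = same visit, keep once
                continue
            seen.add(key)
            records.append(ClaimRecord(pid, date, dept, meds, label))
    # a labelled and an unlabelled row for the same patient are consistent;
    # propagate the known label onto every record of that patient
    out = []
    for r in records:
        known = labels.get(r.patient_id)
        if r.label is None and known is not None:
            r = ClaimRecord(r.patient_id, r.visit_date, r.department_id, r.medicine_ids, known)
        out.append(r)
    return out


def write_claims(
    records: Iterable[ClaimRecord],
    path: str | Path,
    dialect: str | None = None,
    medicine_sep: str = ";",
) -> None:
    path = Path(path)
    delim = _delimiter_for(path, dialect)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=delim)
        writer.writerow(CLAIM_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.patient_id,
                    r.visit_date.isoformat(),
                    r.department_id,
                    medicine_sep.join(sorted(r.medicine_ids)),
                    "" if r.label is None else r.label,
                ]
            )


def read_features(path: str | Path, patients: Sequence[str]) -> FeatureMatrix:
    """Read a delimited feature table and reindex its rows to ``patients``.

    The first column must be ``patient_id``; every other column must be
    numeric and finite.
    """
    path = Path(path)
    delim = _delimiter_for(path, None)
    df = pd.read_csv(path, sep=delim, dtype={0: str})
    if df.columns[0] != "patient_id":
        raise ClaimsSchemaError("first column of a feature table must be patient_id")
    ids = df["patient_id"].tolist()
    values = df.drop(columns="patient_id")
    numeric = values.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & ~values.isna()
    if bad.any().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric feature cell at patient {ids[r]!r}, column {values.columns[c]!r}"
        )
    if numeric.isna().any().any():
        r, c = np.argwhere(numeric.isna().to_numpy())[0]
        raise ValueError(
            f"missing feature value at patient {ids[r]!r}, column {numeric.columns[c]!r}"
        )
    return FeatureMatrix(ids, numeric.to_numpy(dtype=np.float64)).reindex(patients)


def write_features(features: FeatureMatrix, path: str | Path) -> None:
    df = pd.DataFrame(
        features.values, columns=[f"x{i}" for i in range(features.k)]
    )
    df.insert(0, "patient_id", features.patient_ids)
    df.to_csv(path, sep=_delimiter_for(Path(path), None), index=False)


def structural_features(
    claims: Sequence[ClaimRecord], k: int = N_STRUCTURAL, seed: int | None = None
) -> FeatureMatrix:
    """Fallback attributes when no feature table is supplied.

    Per patient: visit count, distinct departments, distinct medicines,
    distinct dates, mean medicines per visit — z-scored column-wise and
    zero-padded (or truncated) to ``k`` columns.  Deterministic; ``seed`` is
    accepted for interface symmetry but unused.
    """
    if not claims:
        raise ValueError("claims must be non-empty")
    patients = list(dict.fromkeys(r.patient_id for r in claims))
    rows = {p: [] for p in patients}
    for r in claims:
        rows[r.patient_id].append(r)
    raw = np.zeros((len(patients), N_STRUCTURAL))
    for i, p in enumerate(patients):
        rs = rows[p]
        raw[i] = [
            len(rs),
            len({r.department_id for r in rs}),
            len(set().union(*[r.medicine_ids for r in rs])),
            len({r.visit_date for r in rs}),
            float(np.mean([len(r.medicine_ids) for r in rs])),
        ]
    std = raw.std(axis=0)
    std[std == 0] = 1.0
    z = (raw - raw.mean(axis=0)) / std
    if k <= N_STRUCTURAL:
        mat = z[:, :k]
    else:
        mat = np.hstack([z, np.zeros((len(patients), k - N_STRUCTURAL))])
    return FeatureMatrix(patients, mat)


def write_json(obj: Mapping, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=float) + "\n", encoding="utf-8")
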