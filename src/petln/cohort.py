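"""Cohort data model, CSV I/O, contingency tables, and bundled reference data.

The analysis unit is a histologically confirmed thoracic lymph node described
by its SUV metrics plus patient-level reference uptakes (primary tumor, liver,
brainstem, contralateral lung).  Cohorts are stored as flat CSV tables, one
row per node with patient-level fields repeated, which keeps the files easy to
validate and diff.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GLUCOSE_LIMIT_MMOL_PER_L",
    "UPTAKE_TIME_WINDOW_MIN",
    "VALID_STATIONS",
    "COHORT_COLUMNS",
    "PatientRecord",
    "ReferenceUptake",
    "NodeRecord",
    "CohortTable",
    "ContingencyTable",
    "CohortValidationError",
    "read_cohort",
    "write_cohort",
    "build_contingency",
    "reference_cross_tables",
    "reference_data",
]

#: Inclusion criteria of the underlying clinical protocol.
GLUCOSE_LIMIT_MMOL_PER_L = 8.3
UPTAKE_TIME_WINDOW_MIN = (45.0, 70.0)

#: Mountain-Dresler nodal stations observed in the cohort (side-agnostic).
VALID_STATIONS = (2, 4, 5, 6, 7, 10, 11, 12)

HISTOLOGY_SUBTYPES = ("AC", "SCC", "SCLC", "NSCLC_NOS")
SEXES = ("f", "m")

#: Fixed flat-CSV schema: one row per lymph node, patient fields repeated.
COHORT_COLUMNS = [
    "patient_id", "node_id", "station", "short_axis_mm",
    "suvmax", "suvmean", "suvpeak", "histology",
    "primary_suvmax", "liver_suvmax", "brainstem_suvmax", "lung_suvmax",
    "glucose_mmol_per_l", "uptake_time_min", "injected_activity_mbq",
    "body_weight_kg", "age_years", "sex", "histology_subtype",
]


class CohortValidationError(ValueError):
    """Raised when a cohort file or table violates the data-model invariants.

    ``errors`` carries one human-readable diagnostic per offending row/field.
    """

    def __init__(self, errors: Sequence[str]):
        self.errors = list(errors)
        super().__init__("; ".join(self.errors))


@dataclass(frozen=True)
class ReferenceUptake:
    """Patient-level SUVmax of the four reference regions used for ratios."""

    primary_suvmax: float
    liver_suvmax: float
    brainstem_suvmax: float
    lung_suvmax: float

    def __post_init__(self) -> None:
        for name in ("primary_suvmax", "liver_suvmax", "brainstem_suvmax", "lung_suvmax"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise CohortValidationError([f"reference uptake {name} must be finite and > 0, got {v}"])


@dataclass(frozen=True)
class PatientRecord:
    """One included patient with scan covariates and reference uptakes."""

    patient_id: str
    age_years: int
    sex: str
    glucose_mmol_per_l: float
    uptake_time_min: float
    injected_activity_mbq: float
    body_weight_kg: float
    histology_subtype: str
    reference: ReferenceUptake

    def __post_init__(self) -> None:
        errs = []
        if self.glucose_mmol_per_l > GLUCOSE_LIMIT_MMOL_PER_L:
            errs.append(
                f"patient {self.patient_id}: glucose {self.glucose_mmol_per_l} mmol/L "
                f"exceeds the inclusion limit of {GLUCOSE_LIMIT_MMOL_PER_L} mmol/L"
            )
        lo, hi = UPTAKE_TIME_WINDOW_MIN
        if not (lo <= self.uptake_time_min <= hi):
            errs.append(
                f"patient {self.patient_id}: uptake time {self.uptake_time_min} min "
                f"outside the inclusion window {lo}-{hi} min"
            )
        if self.injected_activity_mbq <= 0:
            errs.append(f"patient {self.patient_id}: injected activity must be > 0")
        if self.body_weight_kg <= 0:
            errs.append(f"patient {self.patient_id}: body weight must be > 0")
        if self.sex not in SEXES:
            errs.append(f"patient {self.patient_id}: sex must be one of {SEXES}, got {self.sex!r}")
        if self.histology_subtype not in HISTOLOGY_SUBTYPES:
            errs.append(
                f"patient {self.patient_id}: histology_subtype must be one of "
                f"{HISTOLOGY_SUBTYPES}, got {self.histology_subtype!r}"
            )
        if errs:
            raise CohortValidationError(errs)


@dataclass(frozen=True)
class NodeRecord:
    """One lymph node: SUV metrics and the binary histology reference."""

    patient_id: str
    node_id: str
    station: int
    short_axis_mm: float
    suvmax: float
    suvmean: float
    suvpeak: float
    histology: str  # "benign" | "malignant"

    def __post_init__(self) -> None:
        errs = []
        if self.station not in VALID_STATIONS:
            errs.append(
                f"node {self.node_id}: station {self.station} not in {VALID_STATIONS}"
            )
        if self.short_axis_mm < 0:
            errs.append(f"node {self.node_id}: short_axis_mm must be >= 0")
        for name in ("suvmax", "suvmean", "suvpeak"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                errs.append(f"node {self.node_id}: {name} must be finite and > 0, got {v}")
        # suvmean <= suvpeak is not required in general, but neither may
        # exceed the voxel maximum.
        if np.isfinite(self.suvmean) and self.suvmean > self.suvmax:
            errs.append(f"node {self.node_id}: suvmean {self.suvmean} exceeds suvmax {self.suvmax}")
        if np.isfinite(self.suvpeak) and self.suvpeak > self.suvmax:
            errs.append(f"node {self.node_id}: suvpeak {self.suvpeak} exceeds suvmax {self.suvmax}")
        if self.histology not in ("benign", "malignant"):
            errs.append(
                f"node {self.node_id}: histology must be 'benign' or 'malignant', got {self.histology!r}"
            )
        if errs:
            raise CohortValidationError(errs)

    @property
    def malignant(self) -> bool:
        return self.histology == "malignant"


MAX_NODES_PER_PATIENT = 6


@dataclass
class CohortTable:
    """A validated cohort: patients plus their lymph nodes."""

    patients: list[PatientRecord] = field(default_factory=list)
    nodes: list[NodeRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        errs = []
        by_id: dict[str, PatientRecord] = {}
        for p in self.patients:
            if p.patient_id in by_id:
                errs.append(f"duplicate patient_id {p.patient_id!r}")
            by_id[p.patient_id] = p
        counts: dict[str, int] = {}
        for nd in self.nodes:
            if nd.patient_id not in by_id:
                errs.append(f"node {nd.node_id}: unknown patient_id {nd.patient_id!r}")
            counts[nd.patient_id] = counts.get(nd.patient_id, 0) + 1
        for pid, c in counts.items():
            if not (1 <= c <= MAX_NODES_PER_PATIENT):
                errs.append(
                    f"patient {pid}: {c} nodes, outside the allowed 1-{MAX_NODES_PER_PATIENT}"
                )
        if errs:
            raise CohortValidationError(errs)
        self._patients_by_id = by_id

    def patient(self, patient_id: str) -> PatientRecord:
        return self._patients_by_id[patient_id]

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    @property
    def prevalence(self) -> float:
        """Node-level malignancy prevalence."""
        return sum(nd.malignant for nd in self.nodes) / len(self.nodes)

    def labels(self) -> np.ndarray:
        """Histology labels as a boolean array (True = malignant)."""
        return np.array([nd.malignant for nd in self.nodes], dtype=bool)

    def to_frame(self) -> pd.DataFrame:
        """Flatten to the fixed one-row-per-node CSV schema."""
        rows = []
        for nd in self.nodes:
            p = self.patient(nd.patient_id)
            r = p.reference
            rows.append({
                "patient_id": p.patient_id, "node_id": nd.node_id,
                "station": nd.station, "short_axis_mm": nd.short_axis_mm,
                "suvmax": nd.suvmax, "suvmean": nd.suvmean, "suvpeak": nd.suvpeak,
                "histology": nd.histology,
                "primary_suvmax": r.primary_suvmax, "liver_suvmax": r.liver_suvmax,
                "brainstem_suvmax": r.brainstem_suvmax, "lung_suvmax": r.lung_suvmax,
                "glucose_mmol_per_l": p.glucose_mmol_per_l,
                "uptake_time_min": p.uptake_time_min,
                "injected_activity_mbq": p.injected_activity_mbq,
                "body_weight_kg": p.body_weight_kg,
                "age_years": p.age_years, "sex": p.sex,
                "histology_subtype": p.histology_subtype,
            })
        return pd.DataFrame(rows, columns=COHORT_COLUMNS)


_NUMERIC_COLUMNS = [
    "station", "short_axis_mm", "suvmax", "suvmean", "suvpeak",
    "primary_suvmax", "liver_suvmax", "brainstem_suvmax", "lung_suvmax",
    "glucose_mmol_per_l", "uptake_time_min", "injected_activity_mbq",
    "body_weight_kg", "age_years",
]


def _cohort_from_frame(df: pd.DataFrame) -> CohortTable:
    errs: list[str] = []
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise CohortValidationError([f"missing mandatory column(s): {', '.join(missing)}"])

    for col in _NUMERIC_COLUMNS:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[converted.isna() & df[col].notna()]
        for i in bad:
            errs.append(f"row {i}: non-numeric value {df.at[i, col]!r} in field {col!r}")
        nan = df.index[df[col].isna()]
        for i in nan:
            errs.append(f"row {i}: missing value in field {col!r}")
        df = df.assign(**{col: converted})
    if errs:
        raise CohortValidationError(errs)

    patients: dict[str, PatientRecord] = {}
    nodes: list[NodeRecord] = []
    for i, row in df.iterrows():
        pid = str(row["patient_id"])
        try:
            if pid not in patients:
                patients[pid] = PatientRecord(
                    patient_id=pid,
                    age_years=int(row["age_years"]),
                    sex=str(row["sex"]),
                    glucose_mmol_per_l=float(row["glucose_mmol_per_l"]),
                    uptake_time_min=float(row["uptake_time_min"]),
                    injected_activity_mbq=float(row["injected_activity_mbq"]),
                    body_weight_kg=float(row["body_weight_kg"]),
                    histology_subtype=str(row["histology_subtype"]),
                    reference=ReferenceUptake(
                        primary_suvmax=float(row["primary_suvmax"]),
                        liver_suvmax=float(row["liver_suvmax"]),
                        brainstem_suvmax=float(row["brainstem_suvmax"]),
                        lung_suvmax=float(row["lung_suvmax"]),
                    ),
                )
            nodes.append(NodeRecord(
                patient_id=pid,
                node_id=str(row["node_id"]),
                station=int(row["station"]),
                short_axis_mm=float(row["short_axis_mm"]),
                suvmax=float(row["suvmax"]),
                suvmean=float(row["suvmean"]),
                suvpeak=float(row["suvpeak"]),
                histology=str(row["histology"]),
            ))
        except CohortValidationError as e:
            errs.extend(f"row {i}: {msg}" for msg in e.errors)
    if errs:
        raise CohortValidationError(errs)
    return CohortTable(patients=list(patients.values()), nodes=nodes)


def read_cohort(path, schema: Mapping[str, str] | None = None) -> CohortTable:
    """Read and validate a cohort CSV (comma-separated, UTF-8, header row).

    Parameters
    ----------
    path:
        CSV file with one row per lymph node and the fixed column schema
        (:data:`COHORT_COLUMNS`).
    schema:
        Optional mapping from the file's column names to the canonical ones,
        for tables exported under different headers.

    Raises
    ------
    CohortValidationError
        With one row-indexed diagnostic per violation (missing columns,
        non-numeric SUV, inclusion-criterion breaches, dangling patient ids).
    """
    # round_trip parsing: the default fast parser can lose the last bit of
    # a float, breaking the write-read identity
    df = pd.read_csv(path, encoding="utf-8", float_precision="round_trip")
    if schema:
        df = df.rename(columns=dict(schema))
    return _cohort_from_frame(df)


def write_cohort(cohort: CohortTable, path) -> None:
    """Write a cohort to CSV in the canonical flat schema (lossless round-trip)."""
    cohort.to_frame().to_csv(path, index=False, encoding="utf-8")


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts of histology (rows) against test result (columns).

    ``tp`` counts malignant nodes called positive, ``tn`` benign nodes called
    negative; the test is positive when the feature value is >= the cut-off.
    """

    tn: int
    fp: int
    fn: int
    tp: int

    def __post_init__(self) -> None:
        cells = (self.tn, self.fp, self.fn, self.tp)
        if any(c < 0 or c != int(c) for c in cells):
            raise ValueError(f"contingency cells must be nonnegative integers, got {cells}")
        if sum(cells) < 1:
            raise ValueError("contingency table must contain at least one observation")

    @property
    def n(self) -> int:
        return self.tn + self.fp + self.fn + self.tp

    @property
    def n_malignant(self) -> int:
        return self.tp + self.fn

    @property
    def n_benign(self) -> int:
        return self.tn + self.fp

    def as_dict(self) -> dict[str, int]:
        return {"tn": self.tn, "fp": self.fp, "fn": self.fn, "tp": self.tp}


def build_contingency(
    values: Iterable[float],
    labels: Iterable[bool | str],
    cutoff: float,
) -> ContingencyTable:
    """Cross-tabulate a feature against histology at an inclusive cut-off.

    A node tests positive when ``value >= cutoff``; labels may be booleans
    (True = malignant) or the strings ``"benign"``/``"malignant"``.
    """
    v = np.asarray(list(values), dtype=float)
    lab = _as_bool_labels(labels)
    if v.size == 0:
        raise ValueError("cannot build a contingency table from empty input")
    if v.size != lab.size:
        raise ValueError(f"values ({v.size}) and labels ({lab.size}) differ in length")
    if not np.all(np.isfinite(v)):
        raise ValueError("feature values must be finite")
    pos = v >= cutoff
    return ContingencyTable(
        tn=int(np.sum(~lab & ~pos)),
        fp=int(np.sum(~lab & pos)),
        fn=int(np.sum(lab & ~pos)),
        tp=int(np.sum(lab & pos)),
    )


def _as_bool_labels(labels: Iterable[bool | str]) -> np.ndarray:
    out = []
    for l in labels:
        if isinstance(l, str):
            if l not in ("benign", "malignant"):
                raise ValueError(f"label must be 'benign' or 'malignant', got {l!r}")
            out.append(l == "malignant")
        else:
            out.append(bool(l))
    return np.asarray(out, dtype=bool)


def reference_data() -> dict:
    """The bundled reference dataset from the original clinical cohort.

    Contains the five published 2x2 cross tables, the printed performance
    metrics, the per-class median/range summaries used to calibrate the
    synthetic generator, station counts, and the two known misprints in the
    published metrics table.
    """
    with resources.files("petln.data").joinpath("reference_tables.json").open("r") as fh:
        return json.load(fh)


def reference_cross_tables() -> dict[str, ContingencyTable]:
    """The five published cross tables, keyed by feature name.

    Keys: ``suvmax``, ``ratio_primary``, ``ratio_liver``, ``ratio_brainstem``,
    ``ratio_lung``.  Each table covers all 101 nodes (29 malignant, 72 benign)
    at the feature's published cut-off.
    """
    raw = reference_data()["cross_tables"]
    return {
        name: ContingencyTable(tn=d["tn"], fp=d["fp"], fn=d["fn"], tp=d["tp"])
        for name, d in raw.items()
    }
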