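"""Event-record PK datasets: domain types, NONMEM-style CSV I/O and record filters.

The in-memory model mirrors the standard pharmacometric event-record layout
(one row per dose or observation).  Internal units are fixed: hours for time,
mg for dose amounts, mg/l (= ug/ml) for concentrations.  Clearances elsewhere
in the package are therefore l/h.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
import numpy as np
import pandas as pd

__all__ = [
    "DoseEvent",
    "Observation",
    "CovariateSet",
    "SubjectRecord",
    "PKDataset",
    "ExclusionReport",
    "read_dataset",
    "write_dataset",
    "exclude_predose_positive",
    "DatasetFormatError",
    "DatasetValidationError",
]

#: default lower limit of quantitation of the meropenem assay, mg/l
DEFAULT_LLOQ = 0.1

_MANDATORY_COLUMNS = ("ID", "TIME", "AMT", "RATE", "DV", "EVID", "MDV")
_RESERVED_COLUMNS = set(_MANDATORY_COLUMNS) | {"EXCL", "EXCLRSN", "BLQ"}


class DatasetFormatError(ValueError):
    """A table is missing mandatory structure (columns, header)."""


class DatasetValidationError(ValueError):
    """A row carries a physically impossible value."""


@dataclass(frozen=True)
class DoseEvent:
    """One zero-order infusion.

    Attributes
    ----------
    start_time : float
        Hours since the first record of the subject.
    amount : float
        Dose in mg.
    duration : float
        Infusion length in hours.
    """

    start_time: float
    amount: float
    duration: float

    def __post_init__(self):
        if self.amount <= 0:
            raise DatasetValidationError(f"dose amount must be > 0, got {self.amount}")
        if self.duration <= 0:
            raise DatasetValidationError(f"infusion duration must be > 0, got {self.duration}")
        if self.start_time < 0:
            raise DatasetValidationError(f"dose start time must be >= 0, got {self.start_time}")

    @property
    def rate(self) -> float:
        """Infusion rate in mg/h."""
        return self.amount / self.duration


@dataclass(frozen=True)
class Observation:
    """One measured plasma concentration."""

    time: float
    concentration: float
    below_lloq: bool = False
    excluded: bool = False
    exclusion_reason: str = ""

    def __post_init__(self):
        if self.time < 0:
            raise DatasetValidationError(f"observation time must be >= 0, got {self.time}")
        if not np.isnan(self.concentration) and self.concentration < 0:
            raise DatasetValidationError(
                f"concentration must be >= 0, got {self.concentration}"
            )


@dataclass(frozen=True)
class CovariateSet:
    """Named covariates of one subject.

    ``values`` maps covariate name to numeric value (categoricals are coded
    0/1).  Serum albumin (g/l) is the covariate of the final model; weight
    (kg), age (years) and sepsis status are carried for the covariate search.
    """

    values: dict = field(default_factory=dict)

    def __post_init__(self):
        alb = self.values.get("albumin")
        if alb is not None and alb <= 0:
            raise DatasetValidationError(f"albumin must be > 0, got {alb}")

    def get(self, name: str, default=None):
        return self.values.get(name, default)

    def __contains__(self, name: str) -> bool:
        return name in self.values

    @property
    def albumin(self):
        return self.values.get("albumin")

    @property
    def weight(self):
        return self.values.get("weight")

    @property
    def age(self):
        return self.values.get("age")

    @property
    def sepsis(self):
        return self.values.get("sepsis")


@dataclass(frozen=True)
class SubjectRecord:
    subject_id: str
    doses: tuple[DoseEvent, ...]
    observations: tuple[Observation, ...]
    covariates: CovariateSet = field(default_factory=CovariateSet)

    def __post_init__(self):
        object.__setattr__(self, "doses", tuple(self.doses))
        object.__setattr__(self, "observations", tuple(self.observations))
        for seq, attr in ((self.doses, "start_time"), (self.observations, "time")):
            times = [getattr(x, attr) for x in seq]
            if any(b < a for a, b in zip(times, times[1:])):
                raise DatasetValidationError(
                    f"subject {self.subject_id}: {attr} values must be sorted"
                )

    @property
    def first_dose_time(self) -> float | None:
        return self.doses[0].start_time if self.doses else None

    def active_observations(self) -> tuple[Observation, ...]:
        """Observations usable for fitting (not excluded, not below LLOQ)."""
        return tuple(
            o for o in self.observations if not o.excluded and not o.below_lloq
        )


@dataclass(frozen=True)
class PKDataset:
    subjects: tuple[SubjectRecord, ...]
    lloq: float = DEFAULT_LLOQ
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "subjects", tuple(self.subjects))
        ids = [s.subject_id for s in self.subjects]
        if len(set(ids)) != len(ids):
            raise DatasetValidationError("subject ids must be unique")
        if self.subjects and not any(s.observations for s in self.subjects):
            raise DatasetValidationError("dataset must contain at least one observation")

    def __len__(self) -> int:
        return len(self.subjects)

    def subject(self, subject_id: str) -> SubjectRecord:
        for s in self.subjects:
            if s.subject_id == subject_id:
                return s
        raise KeyError(subject_id)

    def n_observations(self, active_only: bool = False) -> int:
        if active_only:
            return sum(len(s.active_observations()) for s in self.subjects)
        return sum(len(s.observations) for s in self.subjects)


@dataclass(frozen=True)
class ExclusionReport:
    """Which records a filter removed and why."""

    rule: str
    records: tuple[tuple[str, float, float], ...]  # (subject_id, time, value)

    def __len__(self) -> int:
        return len(self.records)


def _to_float(x) -> float:
    if x is None or (isinstance(x, str) and x.strip() in (".", "")):
        return np.nan
    return float(x)


def read_dataset(path, lloq: float = DEFAULT_LLOQ, time_unit: str = "h") -> PKDataset:
    """Read a NONMEM-style event-record CSV.

    Mandatory columns: ID, TIME, AMT, RATE, DV, EVID, MDV.  Every other
    column is treated as a covariate (constant within subject) except the
    bookkeeping columns EXCL/EXCLRSN/BLQ written by :func:`write_dataset`.
    ``"."`` or an empty cell denotes a missing value.

    Parameters
    ----------
    path : path-like
    lloq : float
        Lower limit of quantitation in mg/l; observations with
        0 < DV < lloq are flagged ``below_lloq``.
    time_unit : {"h", "min"}
        Unit of the TIME column; minutes are converted to hours on input.
    """
    if time_unit not in ("h", "min"):
        raise ValueError(f"time_unit must be 'h' or 'min', got {time_unit!r}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise DatasetFormatError(f"missing mandatory column(s): {', '.join(missing)}")

    scale = 1.0 / 60.0 if time_unit == "min" else 1.0
    cov_cols = [c for c in df.columns if c not in _RESERVED_COLUMNS]
    subjects = []
    for sid, grp in df.groupby("ID", sort=False):
        doses, observations = [], []
        cov: dict = {}
        for row_no, row in grp.iterrows():
            time = _to_float(row["TIME"]) * scale
            evid = int(_to_float(row["EVID"]))
            amt = _to_float(row["AMT"])
            dv = _to_float(row["DV"])
            if not np.isnan(amt) and amt < 0:
                raise DatasetValidationError(f"row {row_no}: negative AMT {amt}")
            if not np.isnan(dv) and dv < 0:
                raise DatasetValidationError(f"row {row_no}: negative DV {dv}")
            for c in cov_cols:
                v = _to_float(row[c])
                if not np.isnan(v):
                    cov.setdefault(_canonical_covariate(c), v)
            if evid == 1:
                rate = _to_float(row["RATE"]) * (1.0 / scale)
                if np.isnan(rate) or rate <= 0:
                    raise DatasetValidationError(
                        f"row {row_no}: dose row requires a positive RATE"
                    )
                doses.append(DoseEvent(start_time=time, amount=amt, duration=amt / rate))
            elif evid == 0:
                if int(_to_float(row.get("MDV", "0")) or 0) == 1 or np.isnan(dv):
                    continue
                excl = bool(int(_to_float(row.get("EXCL", "0")) or 0)) if "EXCL" in row else False
                reason = row.get("EXCLRSN", "") if "EXCLRSN" in row else ""
                reason = "" if reason.strip() == "." else reason
                observations.append(
                    Observation(
                        time=time,
                        concentration=dv,
                        below_lloq=bool(0 < dv < lloq),
                        excluded=excl,
                        exclusion_reason=reason,
                    )
                )
            else:
                raise DatasetFormatError(f"row {row_no}: unsupported EVID {evid}")
        subjects.append(
            SubjectRecord(
                subject_id=str(sid),
                doses=tuple(doses),
                observations=tuple(observations),
                covariates=CovariateSet(cov),
            )
        )
    return PKDataset(
        subjects=tuple(subjects),
        lloq=lloq,
        metadata={"source": str(path), "time_unit": "h"},
    )


_COVARIATE_ALIASES = {
    "ALB": "albumin",
    "WT": "weight",
    "AGE": "age",
    "SEPSIS": "sepsis",
    "CREA": "creatinine",
    "DAY": "therapy_day",
}
_COVARIATE_COLUMNS = {v: k for k, v in _COVARIATE_ALIASES.items()}


def _canonical_covariate(column: str) -> str:
    return _COVARIATE_ALIASES.get(column, column.lower())


def write_dataset(dataset: PKDataset, path) -> None:
    """Write a dataset back to event-record CSV (hours, mg, mg/l).

    Round-trips through :func:`read_dataset`: numeric fields to full float
    precision, exclusion flags in EXCL/EXCLRSN, BLQ recomputable from DV.
    """
    cov_names = sorted({k for s in dataset.subjects for k in s.covariates.values})
    cov_cols = [_COVARIATE_COLUMNS.get(n, n.upper()) for n in cov_names]
    rows = []
    for s in dataset.subjects:
        events: list[tuple[float, int, dict]] = []
        for d in s.doses:
            events.append(
                (d.start_time, 0, {"AMT": repr(d.amount), "RATE": repr(d.rate), "EVID": 1})
            )
        for o in s.observations:
            events.append(
                (
                    o.time,
                    1,
                    {
                        "DV": repr(o.concentration),
                        "EVID": 0,
                        "EXCL": int(o.excluded),
                        "EXCLRSN": o.exclusion_reason or ".",
                    },
                )
            )
        events.sort(key=lambda e: (e[0], e[1]))
        for time, _, payload in events:
            row = {
                "ID": s.subject_id,
                "TIME": repr(time),
                "AMT": ".",
                "RATE": ".",
                "DV": ".",
                "EVID": payload["EVID"],
                "MDV": 0 if payload["EVID"] == 0 else 1,
                "EXCL": payload.get("EXCL", 0),
                "EXCLRSN": payload.get("EXCLRSN", "."),
            }
            row.update({k: v for k, v in payload.items() if k in ("AMT", "RATE", "DV")})
            for name, col in zip(cov_names, cov_cols):
                v = s.covariates.get(name)
                row[col] = "." if v is None else repr(float(v))
            rows.append(row)
    columns = list(_MANDATORY_COLUMNS) + cov_cols + ["EXCL", "EXCLRSN"]
    pd.DataFrame(rows, columns=columns).to_csv(path, index=False)


def exclude_predose_positive(dataset: PKDataset) -> tuple[PKDataset, ExclusionReport]:
    """Flag positive concentrations measured at the time of a subject's first dose.

    A sample drawn at the start of the very first infusion of a subject who
    has no recorded prior dose cannot contain drug; a positive value there is
    an outlier (carry-over, mislabeling) and is flagged ``excluded`` with
    reason ``"predose-positive"``.  Subjects sampled during ongoing therapy
    (prior doses on record) keep their time-zero samples.  Idempotent; no
    record is deleted, only flagged.
    """
    flagged = []
    new_subjects = []
    for s in dataset.subjects:
        t_first = s.first_dose_time
        if t_first is None:
            new_subjects.append(s)
            continue
        has_prior_dose = any(d.start_time < t_first - 1e-9 for d in s.doses)
        new_obs = []
        for o in s.observations:
            hit = (
                not has_prior_dose
                and abs(o.time - t_first) <= 1e-9
                and not np.isnan(o.concentration)
                and o.concentration > 0
            )
            if hit:
                if not o.excluded:
                    o = replace(o, excluded=True, exclusion_reason="predose-positive")
                flagged.append((s.subject_id, o.time, o.concentration))
            new_obs.append(o)
        new_subjects.append(dataclasses.replace(s, observations=tuple(new_obs)))
    report = ExclusionReport(rule="predose-positive", records=tuple(flagged))
    return dataclasses.replace(dataset, subjects=tuple(new_subjects)), report
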