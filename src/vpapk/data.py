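"""Core domain types and NONMEM-style dataset I/O.

The row unit of an external evaluation is one pediatric patient on oral
valproic acid (VPA) therapy: their covariates, a steady-state dosing
regimen, and one or more trough concentrations drawn during routine
therapeutic drug monitoring (TDM).

Datasets follow the NONMEM flat-event convention: dose rows (EVID=1) and
observation rows (EVID=0, MDV=0) discriminated by an event-type column,
with covariates repeated on every row.  Units are fixed at parse time:
time in hours, concentrations in mg/L, doses in mg, weight in kg, age in
years, albumin in g/L.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "Covariates",
    "DoseEvent",
    "ObservationEvent",
    "SubjectRecord",
    "PKDataset",
    "ValidationViolation",
    "DatasetError",
    "FORMULATIONS",
    "DEFAULT_BOUNDS",
    "read_dataset",
    "write_dataset",
    "validate_dataset",
]

#: Oral formulations recognised by the model library's absorption rules.
FORMULATIONS = (
    "syrup",
    "sustained_release",
    "conventional_tablet",
    "enteric_coated",
    "capsule",
    "sprinkle",
)

#: Weeks per year, used to derive postmenstrual age from postnatal age.
_WEEKS_PER_YEAR = 365.25 / 7.0
#: Term gestation assumed when gestational age is unrecorded (weeks).
_TERM_GESTATION_WEEKS = 40.0


class DatasetError(ValueError):
    """Raised when a dataset or record violates a structural invariant."""


@dataclass(frozen=True)
class Covariates:
    """One subject's covariates, in the units the model library expects.

    ``daily_dose`` is total mg/day; ``daily_dose_per_kg`` (DDW, mg/kg/day)
    must equal ``daily_dose / weight``.  ``pma`` is postmenstrual age in
    weeks; when not recorded it is derived as postnatal age + 40 weeks
    (term-birth default) and ``pma_derived`` is set so reports can flag it.
    """

    sex: str  # "male" | "female"
    age: float  # years
    weight: float  # kg
    albumin: float  # g/L
    daily_dose: float  # mg/day
    formulation: str
    daily_dose_per_kg: float | None = None  # mg/kg/day; derived if omitted
    cbz: bool = False  # carbamazepine
    pb: bool = False  # phenobarbital
    pht: bool = False  # phenytoin
    ltg: bool = False  # lamotrigine
    clb: bool = False  # clobazam
    other_comed: bool = False
    uncontrolled_epilepsy: bool = False
    pma: float | None = None  # weeks
    pma_derived: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise DatasetError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if self.formulation not in FORMULATIONS:
            raise DatasetError(
                f"unknown formulation {self.formulation!r}; expected one of {FORMULATIONS}"
            )
        if self.age < 0:
            raise DatasetError(f"age must be >= 0, got {self.age}")
        if self.weight <= 0:
            raise DatasetError(f"weight must be > 0, got {self.weight}")
        if self.albumin <= 0:
            raise DatasetError(f"albumin must be > 0, got {self.albumin}")
        if self.daily_dose <= 0:
            raise DatasetError(f"daily_dose must be > 0, got {self.daily_dose}")
        ddw = self.daily_dose / self.weight
        if self.daily_dose_per_kg is None:
            object.__setattr__(self, "daily_dose_per_kg", ddw)
        elif abs(self.daily_dose_per_kg - ddw) > 1e-9 * max(1.0, abs(ddw)):
            raise DatasetError(
                f"daily_dose_per_kg={self.daily_dose_per_kg} inconsistent with "
                f"daily_dose/weight={ddw}"
            )
        if self.pma is None:
            object.__setattr__(
                self, "pma", self.age * _WEEKS_PER_YEAR + _TERM_GESTATION_WEEKS
            )
            object.__setattr__(self, "pma_derived", True)

    @property
    def comedication(self) -> bool:
        """Any co-medication flag set (the Jiang model's CO indicator)."""
        return any((self.cbz, self.pb, self.pht, self.ltg, self.clb, self.other_comed))


@dataclass(frozen=True)
class DoseEvent:
    """One dose row.  A steady-state trough regimen is represented as a
    single dose with ``steady_state=True`` and its interdose interval,
    not as an explicit dose history."""

    time: float  # h
    amount: float  # mg
    interdose_interval: float | None = None  # h
    steady_state: bool = False

    def __post_init__(self) -> None:
        if self.amount <= 0:
            raise DatasetError(f"dose amount must be > 0, got {self.amount}")
        if self.steady_state and (
            self.interdose_interval is None or self.interdose_interval <= 0
        ):
            raise DatasetError(
                "steady-state dose requires a positive interdose_interval"
            )


@dataclass(frozen=True)
class ObservationEvent:
    """One measured total plasma concentration."""

    time: float  # h
    concentration: float  # mg/L
    time_after_dose: float  # h
    below_loq: bool = False

    def __post_init__(self) -> None:
        if self.concentration <= 0:
            raise DatasetError(
                f"observed concentration must be > 0, got {self.concentration}"
            )
        if self.time_after_dose < 0:
            raise DatasetError(
                f"time_after_dose must be >= 0, got {self.time_after_dose}"
            )


@dataclass(frozen=True)
class SubjectRecord:
    """One patient: covariates plus ordered dose and observation events."""

    id: str
    covariates: Covariates
    doses: tuple[DoseEvent, ...]
    observations: tuple[ObservationEvent, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "doses", tuple(self.doses))
        object.__setattr__(self, "observations", tuple(self.observations))
        for events, label in ((self.doses, "dose"), (self.observations, "observation")):
            times = [e.time for e in events]
            if any(b < a for a, b in zip(times, times[1:])):
                raise DatasetError(f"subject {self.id}: {label} times must be non-decreasing")
        if self.observations:
            if not self.doses:
                raise DatasetError(
                    f"subject {self.id} has observations but no dose events"
                )
            if self.doses[0].time > self.observations[0].time:
                raise DatasetError(
                    f"subject {self.id}: first observation precedes any dose"
                )


@dataclass(frozen=True)
class PKDataset:
    """A validated collection of subjects."""

    subjects: tuple[SubjectRecord, ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "subjects", tuple(self.subjects))
        ids = [s.id for s in self.subjects]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise DatasetError(f"duplicate subject ids: {dupes}")
        n_obs = sum(len(s.observations) for s in self.subjects)
        if self.subjects and n_obs < len(self.subjects):
            raise DatasetError(
                f"dataset has {n_obs} observations for {len(self.subjects)} subjects; "
                "every subject needs at least one observation"
            )

    def __len__(self) -> int:
        return len(self.subjects)

    @property
    def n_observations(self) -> int:
        return sum(len(s.observations) for s in self.subjects)

    def subject(self, subject_id: str) -> SubjectRecord:
        for s in self.subjects:
            if s.id == subject_id:
                return s
        raise KeyError(subject_id)


# ---------------------------------------------------------------------------
# CSV I/O (NONMEM-style event records)
# ---------------------------------------------------------------------------

#: Canonical column names; a ``column_map`` may rename any of them.
_CANONICAL_COLUMNS = (
    "ID", "TIME", "AMT", "DV", "EVID", "MDV", "II", "SS", "TAD",
    "WT", "AGE", "SEX", "ALB", "DD", "FORM",
    "CBZ", "PB", "PHT", "LTG", "CLB", "OTHERCM", "UNCTRL", "PMA", "BLQ",
)

_REQUIRED_COVARIATES = ("WT", "AGE", "SEX", "ALB", "DD", "FORM")

_SEX_CODES = {"0": "male", "1": "female", "male": "male", "female": "female",
              "m": "male", "f": "female"}


def _resolve_columns(df: pd.DataFrame, column_map: Mapping[str, str] | None) -> pd.DataFrame:
    """Rename file columns to canonical names via ``column_map`` (canonical -> file)."""
    if column_map:
        rename = {v: k for k, v in column_map.items()}
        df = df.rename(columns=rename)
    df = df.rename(columns={c: c.upper() for c in df.columns})
    missing = [c for c in ("ID", "TIME", "EVID") if c not in df.columns]
    if missing:
        raise DatasetError(f"required columns missing and not in column_map: {missing}")
    return df


def _parse_sex(value) -> str:
    key = str(value).strip().lower()
    if key.endswith(".0"):
        key = key[:-2]
    if key not in _SEX_CODES:
        raise DatasetError(f"unrecognised sex code {value!r}")
    return _SEX_CODES[key]


def _parse_formulation(value) -> str:
    key = str(value).strip().lower()
    aliases = {
        "syr": "syrup", "sr": "sustained_release", "sr-tablet": "sustained_release",
        "tab": "conventional_tablet", "tablet": "conventional_tablet",
        "ec": "enteric_coated", "ec-tablet": "enteric_coated",
    }
    key = aliases.get(key, key)
    if key not in FORMULATIONS:
        raise DatasetError(f"unrecognised formulation {value!r}")
    return key


def _truthy(value) -> bool:
    if pd.isna(value):
        return False
    return str(value).strip().lower() in ("1", "1.0", "true", "yes")


def read_dataset(path, column_map: Mapping[str, str] | None = None) -> PKDataset:
    """Read a NONMEM-style CSV event file into a :class:`PKDataset`.

    Subjects whose rows are missing a required covariate (WT, AGE, SEX,
    ALB, DD, FORM) are dropped and counted in the dataset provenance,
    mirroring routine-TDM curation where incomplete charts are excluded.

    Parameters
    ----------
    path:
        CSV file with at least ID, TIME, EVID plus AMT (dose rows), DV/MDV
        (observation rows), and covariate columns.
    column_map:
        Optional mapping ``canonical name -> file column`` for files in a
        different dialect.

    Raises
    ------
    DatasetError
        On malformed structure: conflicting covariates within a subject,
        observations without any dose, unknown codes.
    OSError
        If the file cannot be read.
    """
    df = pd.read_csv(path)
    df = _resolve_columns(df, column_map)

    subjects: list[SubjectRecord] = []
    n_dropped = 0
    for sid, rows in df.groupby("ID", sort=False):
        try:
            subjects.append(_subject_from_rows(str(sid), rows))
        except _MissingCovariate:
            n_dropped += 1
    provenance = f"read_dataset({path})"
    if n_dropped:
        provenance += f"; dropped {n_dropped} subject(s) with missing required covariates"
    return PKDataset(subjects=tuple(subjects), provenance=provenance)


class _MissingCovariate(Exception):
    pass


def _covariate_value(rows: pd.DataFrame, col: str):
    """Unique non-null value of a covariate column across a subject's rows."""
    if col not in rows.columns:
        raise _MissingCovariate(col)
    vals = rows[col].dropna().unique()
    if len(vals) == 0:
        raise _MissingCovariate(col)
    if len(vals) > 1:
        raise DatasetError(
            f"subject {rows['ID'].iloc[0]}: conflicting values for {col}: {list(vals)}"
        )
    return vals[0]


def _subject_from_rows(sid: str, rows: pd.DataFrame) -> SubjectRecord:
    weight = float(_covariate_value(rows, "WT"))
    cov = Covariates(
        sex=_parse_sex(_covariate_value(rows, "SEX")),
        age=float(_covariate_value(rows, "AGE")),
        weight=weight,
        albumin=float(_covariate_value(rows, "ALB")),
        daily_dose=float(_covariate_value(rows, "DD")),
        formulation=_parse_formulation(_covariate_value(rows, "FORM")),
        cbz=_truthy(rows["CBZ"].iloc[0]) if "CBZ" in rows else False,
        pb=_truthy(rows["PB"].iloc[0]) if "PB" in rows else False,
        pht=_truthy(rows["PHT"].iloc[0]) if "PHT" in rows else False,
        ltg=_truthy(rows["LTG"].iloc[0]) if "LTG" in rows else False,
        clb=_truthy(rows["CLB"].iloc[0]) if "CLB" in rows else False,
        other_comed=_truthy(rows["OTHERCM"].iloc[0]) if "OTHERCM" in rows else False,
        uncontrolled_epilepsy=_truthy(rows["UNCTRL"].iloc[0]) if "UNCTRL" in rows else False,
        pma=float(rows["PMA"].iloc[0]) if "PMA" in rows and pd.notna(rows["PMA"].iloc[0]) else None,
    )

    doses: list[DoseEvent] = []
    observations: list[ObservationEvent] = []
    for _, row in rows.iterrows():
        evid = int(row["EVID"])
        t = float(row["TIME"])
        if evid == 1:
            ss = _truthy(row["SS"]) if "SS" in rows.columns else False
            ii = float(row["II"]) if "II" in rows.columns and pd.notna(row.get("II")) else None
            doses.append(DoseEvent(time=t, amount=float(row["AMT"]),
                                   interdose_interval=ii, steady_state=ss))
        elif evid == 0:
            if "MDV" in rows.columns and _truthy(row["MDV"]):
                continue
            tad = float(row["TAD"]) if "TAD" in rows.columns and pd.notna(row.get("TAD")) else t
            blq = _truthy(row["BLQ"]) if "BLQ" in rows.columns else False
            observations.append(ObservationEvent(
                time=t, concentration=float(row["DV"]),
                time_after_dose=tad, below_loq=blq))
    if observations and not doses:
        raise DatasetError(f"subject {sid} has observations but no dose events")
    return SubjectRecord(id=sid, covariates=cov, doses=tuple(doses),
                         observations=tuple(observations))


def write_dataset(ds: PKDataset, path) -> None:
    """Write a dataset back to the canonical NONMEM-style CSV layout.

    ``read_dataset(write_dataset(ds))`` is an identity field-for-field.
    """
    records = []
    for s in ds.subjects:
        cov = s.covariates
        base = {
            "ID": s.id,
            "WT": cov.weight, "AGE": cov.age,
            "SEX": 0 if cov.sex == "male" else 1,
            "ALB": cov.albumin, "DD": cov.daily_dose, "FORM": cov.formulation,
            "CBZ": int(cov.cbz), "PB": int(cov.pb), "PHT": int(cov.pht),
            "LTG": int(cov.ltg), "CLB": int(cov.clb),
            "OTHERCM": int(cov.other_comed), "UNCTRL": int(cov.uncontrolled_epilepsy),
            "PMA": cov.pma,
        }
        for d in s.doses:
            records.append({**base, "TIME": d.time, "EVID": 1, "AMT": d.amount,
                            "DV": "", "MDV": 1,
                            "II": d.interdose_interval if d.interdose_interval is not None else "",
                            "SS": int(d.steady_state), "TAD": "", "BLQ": ""})
        for o in s.observations:
            records.append({**base, "TIME": o.time, "EVID": 0, "AMT": "",
                            "DV": o.concentration, "MDV": 0, "II": "", "SS": "",
                            "TAD": o.time_after_dose, "BLQ": int(o.below_loq)})
    pd.DataFrame.from_records(records).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Plausibility validation
# ---------------------------------------------------------------------------

#: Default plausibility bounds for a pediatric VPA TDM cohort
#: (age and weight ranges of a typical external-evaluation dataset).
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "age": (0.17, 15.0),          # years
    "weight": (4.0, 70.0),        # kg
    "albumin": (25.0, 75.0),      # g/L
    "daily_dose_per_kg": (5.0, 60.0),  # mg/kg/day
}


@dataclass(frozen=True)
class ValidationViolation:
    subject_id: str
    field: str
    value: float
    lower: float
    upper: float

    def __str__(self) -> str:
        return (f"subject {self.subject_id}: {self.field}={self.value} outside "
                f"[{self.lower}, {self.upper}]")


def validate_dataset(
    ds: PKDataset,
    bounds: Mapping[str, tuple[float, float]] | None = None,
) -> list[ValidationViolation]:
    """Report covariates outside plausibility bounds.  Never mutates ``ds``.

    ``bounds`` maps covariate field name to (lower, upper) inclusive; the
    defaults reflect a pediatric TDM population.  Widening any bound can
    only remove violations.
    """
    bounds = dict(DEFAULT_BOUNDS if bounds is None else bounds)
    violations: list[ValidationViolation] = []
    for s in ds.subjects:
        for fname, (lo, hi) in bounds.items():
            value = getattr(s.covariates, fname, None)
            if value is None:
                continue
            if not (lo <= value <= hi):
                violations.append(ValidationViolation(s.id, fname, float(value), lo, hi))
    return violations
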