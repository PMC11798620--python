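"""Patient cohort model, the bundled nine-patient scenario cohort, synthetic
cohort generation, and cohort file I/O.

A cohort is a list of :class:`Patient` records competing for ventilators under
crisis standards of care.  Each patient carries the covariates the triage
protocols consume -- age, sex, a SOFA total, a single coded comorbidity,
gestational age when pregnant, and a frontline-occupation flag -- plus an
``arrival_rank`` used by first-come-first-served tie-breaking.  Socioeconomic
status is recorded as metadata but is never consumed by any triage rule.
"""

from __future__ import annotations

import csv
import io
import json
from enum import Enum
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from pydantic import (
    BaseModel,
    ConfigDict,
    Field,
    ValidationError,
    field_validator,
    model_validator,
)

__all__ = [
    "Sex",
    "Occupation",
    "SesFlag",
    "Severity",
    "ComorbidityCode",
    "DEFAULT_SEVERITY",
    "Patient",
    "CohortError",
    "CohortGeneratorConfig",
    "validate_cohort",
    "load_fixture_cohort",
    "FIXTURE_ARRIVAL_ORDER",
    "generate_cohort",
    "read_cohort",
    "write_cohort",
    "cohort_digest",
]


class Sex(str, Enum):
    female = "female"
    male = "male"


class Occupation(str, Enum):
    none = "none"
    healthcare_worker = "healthcare_worker"
    first_responder = "first_responder"


class SesFlag(str, Enum):
    unspecified = "unspecified"
    low = "low"


class Severity(str, Enum):
    """Severity class of a comorbidity as triage point systems see it."""

    none = "none"
    minor = "minor"
    severe_life_limiting = "severe_life_limiting"


class ComorbidityCode(str, Enum):
    none_significant = "none_significant"
    esrd = "esrd"
    htn_controlled = "htn_controlled"
    dementia = "dementia"
    metastatic_cancer = "metastatic_cancer"
    ms_late_stage = "ms_late_stage"
    hf_nyha_iv = "hf_nyha_iv"


#: Default severity class per comorbidity code.  Late-stage dementia defaults to
#: severe/life-limiting; protocols that treat it as non-qualifying override its
#: point value in their own configuration rather than here.
DEFAULT_SEVERITY: dict[ComorbidityCode, Severity] = {
    ComorbidityCode.none_significant: Severity.none,
    ComorbidityCode.htn_controlled: Severity.minor,
    ComorbidityCode.esrd: Severity.severe_life_limiting,
    ComorbidityCode.dementia: Severity.severe_life_limiting,
    ComorbidityCode.metastatic_cancer: Severity.severe_life_limiting,
    ComorbidityCode.ms_late_stage: Severity.severe_life_limiting,
    ComorbidityCode.hf_nyha_iv: Severity.severe_life_limiting,
}


class CohortError(ValueError):
    """A cohort record or cohort-level invariant failed validation."""


class Patient(BaseModel):
    """One critically ill patient awaiting ventilator triage.

    Attributes
    ----------
    id : int
        Positive integer label, unique within a cohort.
    age : int
        Age in whole years; adults only (>= 18).
    sex : Sex
    sofa_total : int
        Sequential Organ Failure Assessment total, 0-24.
    comorbidity : ComorbidityCode
        A single coded past-medical-history entry (multi-morbidity is out of
        scope; the worst condition is recorded).
    pregnancy_weeks : int, optional
        Gestational age in weeks if pregnant; requires ``sex == female``.
    occupation : Occupation
        Frontline-occupation flag consumed by protocols that exempt or
        tie-break on healthcare workers / first responders.
    ses_flag : SesFlag
        Socioeconomic-status marker; recorded, never used in triage.
    arrival_rank : int
        Order of presentation to hospital (1 = first); unique per cohort and
        the key for first-come-first-served tie-breaks.
    """

    model_config = ConfigDict(frozen=True)

    id: int = Field(gt=0)
    age: int = Field(ge=18, le=120)
    sex: Sex
    sofa_total: int = Field(ge=0, le=24)
    comorbidity: ComorbidityCode = ComorbidityCode.none_significant
    pregnancy_weeks: Optional[int] = Field(default=None, ge=1, le=42)
    occupation: Occupation = Occupation.none
    ses_flag: SesFlag = SesFlag.unspecified
    arrival_rank: int = Field(gt=0)

    @model_validator(mode="after")
    def _pregnancy_requires_female(self) -> "Patient":
        if self.pregnancy_weeks is not None and self.sex is not Sex.female:
            raise ValueError("pregnancy_weeks set on a non-female patient")
        return self

    @property
    def frontline(self) -> bool:
        return self.occupation is not Occupation.none


def validate_cohort(cohort: Sequence[Patient]) -> list[Patient]:
    """Check cohort-level invariants: unique ids, arrival ranks a permutation of 1..n."""
    ids = [p.id for p in cohort]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise CohortError(f"duplicate patient ids: {dupes}")
    ranks = sorted(p.arrival_rank for p in cohort)
    if ranks != list(range(1, len(cohort) + 1)):
        raise CohortError(
            f"arrival_rank values must be a permutation of 1..{len(cohort)}, got {ranks}"
        )
    return list(cohort)


# ---------------------------------------------------------------------------
# Bundled scenario cohort
# ---------------------------------------------------------------------------

#: Patient ids in order of hospital arrival.  The scenario narrative fixes no
#: arrival times, so this order is a modelling assumption of the package:
#: patient 4 presents last, which is what lets first-come-first-served
#: tie-breaking single him out at the capacity boundary.  Override per scenario
#: via ``ScenarioConfig.arrival_order``.
FIXTURE_ARRIVAL_ORDER: tuple[int, ...] = (1, 2, 3, 5, 6, 7, 8, 9, 4)

_FIXTURE_ROWS = [
    # id, age, sex, sofa, comorbidity, pregnancy_weeks, occupation, ses
    (1, 45, "female", 14, "none_significant", None, "healthcare_worker", "unspecified"),
    (2, 65, "male", 10, "esrd", None, "none", "unspecified"),
    (3, 27, "female", 10, "none_significant", 30, "none", "unspecified"),
    (4, 50, "male", 6, "htn_controlled", None, "none", "low"),
    (5, 92, "male", 4, "dementia", None, "none", "unspecified"),
    (6, 40, "male", 8, "metastatic_cancer", None, "none", "unspecified"),
    (7, 28, "female", 5, "none_significant", None, "first_responder", "unspecified"),
    (8, 57, "male", 2, "ms_late_stage", None, "none", "unspecified"),
    (9, 75, "female", 8, "hf_nyha_iv", None, "none", "unspecified"),
]


def load_fixture_cohort() -> list[Patient]:
    """Return the nine-patient scenario cohort with the default arrival order."""
    rank = {pid: i + 1 for i, pid in enumerate(FIXTURE_ARRIVAL_ORDER)}
    cohort = [
        Patient(
            id=pid,
            age=age,
            sex=sex,
            sofa_total=sofa,
            comorbidity=com,
            pregnancy_weeks=preg,
            occupation=occ,
            ses_flag=ses,
            arrival_rank=rank[pid],
        )
        for pid, age, sex, sofa, com, preg, occ, ses in _FIXTURE_ROWS
    ]
    return validate_cohort(cohort)


# ---------------------------------------------------------------------------
# Synthetic cohort generation
# ---------------------------------------------------------------------------

_DEFAULT_PREVALENCES: dict[str, float] = {
    "none_significant": 0.50,
    "htn_controlled": 0.20,
    "esrd": 0.06,
    "dementia": 0.06,
    "metastatic_cancer": 0.06,
    "ms_late_stage": 0.06,
    "hf_nyha_iv": 0.06,
}


class CohortGeneratorConfig(BaseModel):
    """Parameters for synthetic cohort generation.

    Defaults mirror the bundled scenario cohort: adult ages 27-92, both sexes,
    SOFA totals uniform on 0-24, a small comorbidity vocabulary dominated by
    benign histories, pregnancy restricted to reproductive-age females, and
    roughly one in five patients in a frontline occupation.
    """

    model_config = ConfigDict(frozen=True)

    n: int = Field(ge=0)
    age_range: tuple[int, int] = (27, 92)
    sofa_distribution: Optional[dict[int, float]] = None  # None -> uniform on 0-24
    comorbidity_prevalences: dict[ComorbidityCode, float] = Field(
        default_factory=lambda: {
            ComorbidityCode(k): v for k, v in _DEFAULT_PREVALENCES.items()
        }
    )
    pregnancy_rate: float = Field(default=0.10, ge=0.0, le=1.0)
    frontline_fraction: float = Field(default=0.20, ge=0.0, le=1.0)
    female_fraction: float = Field(default=0.50, ge=0.0, le=1.0)
    low_ses_fraction: float = Field(default=0.10, ge=0.0, le=1.0)
    seed: int = 0

    @field_validator("age_range")
    @classmethod
    def _age_range_valid(cls, v: tuple[int, int]) -> tuple[int, int]:
        lo, hi = v
        if not (18 <= lo <= hi <= 120):
            raise ValueError(f"age_range must satisfy 18 <= lo <= hi <= 120, got {v}")
        return v

    @field_validator("sofa_distribution")
    @classmethod
    def _sofa_dist_valid(
        cls, v: Optional[dict[int, float]]
    ) -> Optional[dict[int, float]]:
        if v is None:
            return v
        if not v:
            raise ValueError("sofa_distribution must be non-empty or None")
        if any(k < 0 or k > 24 for k in v):
            raise ValueError("sofa_distribution keys must lie in 0..24")
        if any(p < 0 for p in v.values()):
            raise ValueError("sofa_distribution probabilities must be >= 0")
        if abs(sum(v.values()) - 1.0) > 1e-9:
            raise ValueError("sofa_distribution probabilities must sum to 1")
        return v

    @field_validator("comorbidity_prevalences")
    @classmethod
    def _prevalences_valid(
        cls, v: dict[ComorbidityCode, float]
    ) -> dict[ComorbidityCode, float]:
        if any(p < 0 or p > 1 for p in v.values()):
            raise ValueError("comorbidity prevalences must lie in [0, 1]")
        if abs(sum(v.values()) - 1.0) > 1e-9:
            raise ValueError("comorbidity prevalences must sum to 1")
        return v


def generate_cohort(config: CohortGeneratorConfig) -> list[Patient]:
    """Draw a synthetic cohort; deterministic for a fixed ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    n = config.n
    if n == 0:
        return []

    lo, hi = config.age_range
    ages = rng.integers(lo, hi + 1, size=n)
    sexes = np.where(rng.random(n) < config.female_fraction, "female", "male")

    if config.sofa_distribution is None:
        sofas = rng.integers(0, 25, size=n)
    else:
        keys = np.array(sorted(config.sofa_distribution))
        probs = np.array([config.sofa_distribution[int(k)] for k in keys], dtype=float)
        sofas = rng.choice(keys, size=n, p=probs / probs.sum())

    codes = sorted(config.comorbidity_prevalences, key=lambda c: c.value)
    prev = np.array([config.comorbidity_prevalences[c] for c in codes], dtype=float)
    comorbidities = rng.choice(np.array([c.value for c in codes]), size=n, p=prev / prev.sum())

    arrival = rng.permutation(n) + 1

    patients = []
    for i in range(n):
        sex = Sex(sexes[i])
        age = int(ages[i])
        preg = None
        if sex is Sex.female and 18 <= age <= 45 and rng.random() < config.pregnancy_rate:
            preg = int(rng.integers(1, 41))
        occ = Occupation.none
        if rng.random() < config.frontline_fraction:
            occ = Occupation.healthcare_worker if rng.random() < 0.5 else Occupation.first_responder
        ses = SesFlag.low if rng.random() < config.low_ses_fraction else SesFlag.unspecified
        patients.append(
            Patient(
                id=i + 1,
                age=age,
                sex=sex,
                sofa_total=int(sofas[i]),
                comorbidity=ComorbidityCode(comorbidities[i]),
                pregnancy_weeks=preg,
                occupation=occ,
                ses_flag=ses,
                arrival_rank=int(arrival[i]),
            )
        )
    return validate_cohort(patients)


# ---------------------------------------------------------------------------
# Cohort I/O
# ---------------------------------------------------------------------------

_CSV_COLUMNS = [
    "id",
    "age",
    "sex",
    "sofa",
    "comorbidity",
    "pregnancy_weeks",
    "occupation",
    "ses",
    "arrival_rank",
]


def _patient_to_record(p: Patient) -> dict:
    return {
        "id": p.id,
        "age": p.age,
        "sex": p.sex.value,
        "sofa": p.sofa_total,
        "comorbidity": p.comorbidity.value,
        "pregnancy_weeks": p.pregnancy_weeks,
        "occupation": p.occupation.value,
        "ses": p.ses_flag.value,
        "arrival_rank": p.arrival_rank,
    }


def _record_to_patient(rec: dict, where: str) -> Patient:
    missing = [c for c in _CSV_COLUMNS if c not in rec]
    if missing:
        raise CohortError(f"{where}: missing column(s) {missing}")
    try:
        return Patient(
            id=rec["id"],
            age=rec["age"],
            sex=rec["sex"],
            sofa_total=rec["sofa"],
            comorbidity=rec["comorbidity"],
            pregnancy_weeks=rec["pregnancy_weeks"],
            occupation=rec["occupation"] or "none",
            ses_flag=rec["ses"] or "unspecified",
            arrival_rank=rec["arrival_rank"],
        )
    except ValidationError as exc:
        raise CohortError(f"{where} (id={rec.get('id')!r}): {exc}") from exc


def _infer_format(path: Path, fmt: Optional[str]) -> str:
    if fmt is not None:
        return fmt
    suffix = path.suffix.lower().lstrip(".")
    if suffix in {"csv", "json"}:
        return suffix
    raise CohortError(f"cannot infer cohort format from {path.name}; pass format=")


def write_cohort(cohort: Sequence[Patient], path: str | Path, fmt: Optional[str] = None) -> None:
    """Write a cohort as CSV (header ``id,age,sex,sofa,...``) or a JSON array.

    Empty CSV fields / JSON nulls denote absent optional values.
    """
    path = Path(path)
    fmt = _infer_format(path, fmt)
    records = [_patient_to_record(p) for p in cohort]
    if fmt == "csv":
        buf = io.StringIO()
        writer = csv.DictWriter(buf, fieldnames=_CSV_COLUMNS, lineterminator="\n")
        writer.writeheader()
        for rec in records:
            writer.writerow({k: ("" if v is None else v) for k, v in rec.items()})
        path.write_text(buf.getvalue())
    elif fmt == "json":
        path.write_text(json.dumps(records, indent=2) + "\n")
    else:
        raise CohortError(f"unknown cohort format {fmt!r}")


def read_cohort(path: str | Path, fmt: Optional[str] = None) -> list[Patient]:
    """Read a cohort from CSV or JSON, validating every record and the cohort
    invariants; errors name the offending record."""
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt == "csv":
        with open(path, newline="") as fh:
            rows = list(csv.DictReader(fh))
        records = []
        for i, row in enumerate(rows):
            rec = {k: (None if v == "" or v is None else v) for k, v in row.items()}
            records.append((rec, f"{path.name} row {i + 2}"))
    elif fmt == "json":
        data = json.loads(path.read_text())
        if not isinstance(data, list):
            raise CohortError(f"{path.name}: expected a JSON array of patient objects")
        records = [(rec, f"{path.name} entry {i}") for i, rec in enumerate(data)]
    else:
        raise CohortError(f"unknown cohort format {fmt!r}")
    cohort = [_record_to_patient(rec, where) for rec, where in records]
    return validate_cohort(cohort)


def cohort_digest(cohort: Sequence[Patient]) -> str:
    """Stable SHA-256 digest of a cohort's canonical JSON form (provenance)."""
    import hashlib

    canonical = json.dumps([_patient_to_record(p) for p in cohort], sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()
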