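"""Declarative triage-protocol rule sets and their evaluation.

A :class:`ProtocolRuleSet` captures one ventilator-triage protocol as data:
exclusion screening (comorbidity lists and/or a SOFA cutoff), a priority point
system (SOFA bands, comorbidity severity points, age bands, a pregnancy
modifier), a frontline-worker policy, an optional qualification cutoff for
protocols that only screen, and an ordered tie-break chain.

Scores are oriented so that **lower = higher priority** throughout the
package; protocol sources that rank the other way are re-oriented in their
configuration files, never in code.

Six calibrated rule sets ship under ``protocols/``: MD, PA, FL, NY, CA and NE,
named for the state or institution whose early-pandemic crisis-standards
protocol each reconstructs.  The protocol documents themselves publish
qualitative rules, not point tables; the shipped numbers were recovered by
exhaustive search (see :mod:`triagesim.calibrate`) constrained to reproduce
the reference allocation outcomes of the nine-patient scenario.
"""

from __future__ import annotations

from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Literal, Optional, Sequence, Union

import yaml
from pydantic import (
    BaseModel,
    ConfigDict,
    Field,
    ValidationError,
    field_validator,
    model_validator,
)

from .cohort import (
    DEFAULT_SEVERITY,
    ComorbidityCode,
    Patient,
    Severity,
)

__all__ = [
    "TiebreakStep",
    "FrontlinePolicy",
    "Comparator",
    "SofaExclusion",
    "Band",
    "ProtocolRuleSet",
    "Status",
    "TraceEntry",
    "PriorityAssignment",
    "PriorityGroup",
    "Ranking",
    "ConfigurationError",
    "screen_exclusions",
    "compute_priority",
    "rank_cohort",
    "load_protocol",
    "list_protocols",
    "protocol_features",
    "SHIPPED_PROTOCOLS",
]


class ConfigurationError(ValueError):
    """A protocol configuration is malformed or does not cover an input."""


class TiebreakStep(str, Enum):
    younger_age = "younger_age"
    frontline = "frontline"
    fcfs = "fcfs"
    lottery = "lottery"


class FrontlinePolicy(str, Enum):
    ignored = "ignored"
    exemption = "exemption"
    tiebreak_only = "tiebreak_only"


class Comparator(str, Enum):
    gt = ">"
    ge = ">="


class SofaExclusion(BaseModel):
    """Exclude when ``sofa_total <comparator> cutoff`` holds."""

    model_config = ConfigDict(frozen=True)

    comparator: Comparator
    cutoff: int = Field(ge=0, le=24)

    def triggered(self, sofa_total: int) -> bool:
        if self.comparator is Comparator.gt:
            return sofa_total > self.cutoff
        return sofa_total >= self.cutoff


class Band(BaseModel):
    """A closed integer interval ``[lo, hi]`` mapped to points; ``hi`` absent
    means unbounded above."""

    model_config = ConfigDict(frozen=True)

    lo: int = Field(ge=0)
    hi: Optional[int] = None
    points: int

    @model_validator(mode="after")
    def _ordered(self) -> "Band":
        if self.hi is not None and self.hi < self.lo:
            raise ValueError(f"band hi {self.hi} < lo {self.lo}")
        return self

    def contains(self, value: int) -> bool:
        return value >= self.lo and (self.hi is None or value <= self.hi)


def _validate_bands(bands: Sequence[Band], what: str) -> None:
    ordered = sorted(bands, key=lambda b: b.lo)
    for a, b in zip(ordered, ordered[1:]):
        if a.hi is None:
            raise ConfigurationError(f"{what}: unbounded band {a} is not last")
        if b.lo <= a.hi:
            raise ConfigurationError(f"{what}: bands {a} and {b} overlap")
        if b.lo != a.hi + 1:
            raise ConfigurationError(f"{what}: gap between bands {a} and {b}")


class ProtocolRuleSet(BaseModel):
    """One triage protocol, fully declarative.

    ``sofa_bands`` takes three forms: an ordered band list (points per SOFA
    interval), the literal ``"raw"`` (the SOFA total itself is the score), or
    ``None`` (no severity scoring at all -- qualification-only protocols such
    as NE, whose qualifying patients form a single undifferentiated group).
    """

    model_config = ConfigDict(frozen=True)

    id: str
    name: str = ""
    sofa_exclusion: Optional[SofaExclusion] = None
    excluded_comorbidities: tuple[ComorbidityCode, ...] = ()
    sofa_bands: Union[tuple[Band, ...], Literal["raw"], None] = None
    comorbidity_points: dict[Severity, int] = Field(default_factory=dict)
    comorbidity_point_overrides: dict[ComorbidityCode, int] = Field(default_factory=dict)
    age_bands: Optional[tuple[Band, ...]] = None
    pregnancy_modifier: Optional[int] = Field(default=None, le=0)
    frontline_policy: FrontlinePolicy = FrontlinePolicy.ignored
    qualification_sofa_cutoff: Optional[int] = Field(default=None, ge=0, le=25)
    tiebreak_chain: tuple[TiebreakStep, ...] = ()

    @model_validator(mode="after")
    def _bands_valid(self) -> "ProtocolRuleSet":
        if isinstance(self.sofa_bands, tuple):
            _validate_bands(self.sofa_bands, f"{self.id} sofa_bands")
        if self.age_bands is not None:
            _validate_bands(self.age_bands, f"{self.id} age_bands")
        return self

    @property
    def scored(self) -> bool:
        """Whether the protocol differentiates qualifying patients at all."""
        return self.sofa_bands is not None


class Status(str, Enum):
    excluded = "excluded"
    eligible = "eligible"
    exempt_frontline = "exempt_frontline"


class TraceEntry(BaseModel):
    """One audited rule application; ``points`` is set for scoring terms."""

    model_config = ConfigDict(frozen=True)

    rule: str
    points: Optional[int] = None

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        if self.points is None:
            return self.rule
        return f"{self.rule}: {self.points:+d}"


class PriorityAssignment(BaseModel):
    """Result of applying one rule set to one patient.

    A score is present exactly for eligible patients of a scoring protocol;
    excluded and frontline-exempt patients carry none.  The trace itemizes
    every rule applied, and for eligible patients the score equals the sum of
    the point terms in its own trace (self-audit invariant).
    """

    model_config = ConfigDict(frozen=True)

    patient_id: int
    status: Status
    score: Optional[int] = None
    trace: tuple[TraceEntry, ...] = ()

    @model_validator(mode="after")
    def _score_iff_eligible(self) -> "PriorityAssignment":
        if self.score is not None and self.status is not Status.eligible:
            raise ValueError("score present on a non-eligible assignment")
        return self


def screen_exclusions(ruleset: ProtocolRuleSet, patient: Patient) -> PriorityAssignment:
    """Exclusion screening only: comorbidity list, SOFA exclusion cutoff, and
    qualification cutoff (for screening-only protocols).  The returned
    assignment carries status and trace, never a score."""
    trace: list[TraceEntry] = []
    if patient.comorbidity in ruleset.excluded_comorbidities:
        trace.append(TraceEntry(rule=f"excluded comorbidity: {patient.comorbidity.value}"))
        return PriorityAssignment(patient_id=patient.id, status=Status.excluded, trace=tuple(trace))
    if ruleset.sofa_exclusion is not None and ruleset.sofa_exclusion.triggered(patient.sofa_total):
        excl = ruleset.sofa_exclusion
        trace.append(
            TraceEntry(rule=f"SOFA exclusion: {patient.sofa_total} {excl.comparator.value} {excl.cutoff}")
        )
        return PriorityAssignment(patient_id=patient.id, status=Status.excluded, trace=tuple(trace))
    if (
        ruleset.qualification_sofa_cutoff is not None
        and patient.sofa_total >= ruleset.qualification_sofa_cutoff
    ):
        trace.append(
            TraceEntry(
                rule=(
                    f"did not qualify: SOFA {patient.sofa_total} >= "
                    f"{ruleset.qualification_sofa_cutoff}"
                )
            )
        )
        return PriorityAssignment(patient_id=patient.id, status=Status.excluded, trace=tuple(trace))
    trace.append(TraceEntry(rule="passed exclusion screening"))
    return PriorityAssignment(patient_id=patient.id, status=Status.eligible, trace=tuple(trace))


def _band_points(bands: Sequence[Band], value: int, what: str, ruleset_id: str) -> Band:
    for band in bands:
        if band.contains(value):
            return band
    raise ConfigurationError(f"{ruleset_id}: {what} {value} outside band coverage")


def compute_priority(ruleset: ProtocolRuleSet, patient: Patient) -> PriorityAssignment:
    """Full rule application: screening, frontline exemption, then the point
    system.  Lower scores mean higher priority."""
    screened = screen_exclusions(ruleset, patient)
    if screened.status is Status.excluded:
        return screened
    trace = list(screened.trace)

    if ruleset.frontline_policy is FrontlinePolicy.exemption and patient.frontline:
        trace.append(TraceEntry(rule=f"frontline exemption: {patient.occupation.value}"))
        return PriorityAssignment(
            patient_id=patient.id, status=Status.exempt_frontline, trace=tuple(trace)
        )

    terms: list[TraceEntry] = []
    if ruleset.sofa_bands == "raw":
        terms.append(TraceEntry(rule=f"SOFA (raw) {patient.sofa_total}", points=patient.sofa_total))
    elif isinstance(ruleset.sofa_bands, tuple):
        band = _band_points(ruleset.sofa_bands, patient.sofa_total, "SOFA", ruleset.id)
        hi = "inf" if band.hi is None else band.hi
        terms.append(
            TraceEntry(rule=f"SOFA band {band.lo}-{hi} (SOFA {patient.sofa_total})", points=band.points)
        )
    else:
        # qualification-only protocol: all qualifying patients score alike
        terms.append(TraceEntry(rule="qualification only (no severity scoring)", points=0))

    if ruleset.comorbidity_points or ruleset.comorbidity_point_overrides:
        if patient.comorbidity in ruleset.comorbidity_point_overrides:
            pts = ruleset.comorbidity_point_overrides[patient.comorbidity]
            terms.append(
                TraceEntry(rule=f"comorbidity override {patient.comorbidity.value}", points=pts)
            )
        else:
            severity = DEFAULT_SEVERITY[patient.comorbidity]
            pts = ruleset.comorbidity_points.get(severity, 0)
            if pts:
                terms.append(
                    TraceEntry(
                        rule=f"comorbidity {patient.comorbidity.value} ({severity.value})",
                        points=pts,
                    )
                )

    if ruleset.age_bands is not None:
        band = _band_points(ruleset.age_bands, patient.age, "age", ruleset.id)
        hi = "inf" if band.hi is None else band.hi
        terms.append(TraceEntry(rule=f"age band {band.lo}-{hi} (age {patient.age})", points=band.points))

    if ruleset.pregnancy_modifier is not None and patient.pregnancy_weeks is not None:
        terms.append(
            TraceEntry(
                rule=f"pregnancy modifier ({patient.pregnancy_weeks} weeks)",
                points=ruleset.pregnancy_modifier,
            )
        )

    score = sum(t.points for t in terms if t.points is not None)
    return PriorityAssignment(
        patient_id=patient.id,
        status=Status.eligible,
        score=score,
        trace=tuple(trace + terms),
    )


class PriorityGroup(BaseModel):
    """Patients sharing one priority score (lower score = higher priority)."""

    model_config = ConfigDict(frozen=True)

    score: int
    member_ids: tuple[int, ...]


class Ranking(BaseModel):
    """Output of :func:`rank_cohort`: frontline-exempt patients first, then
    eligible patients grouped by equal score (ascending), then excluded."""

    model_config = ConfigDict(frozen=True)

    ruleset_id: str
    exempt_ids: tuple[int, ...]
    groups: tuple[PriorityGroup, ...]
    excluded_ids: tuple[int, ...]
    assignments: dict[int, PriorityAssignment]

    @property
    def eligible_ids(self) -> tuple[int, ...]:
        return tuple(pid for g in self.groups for pid in g.member_ids)


def rank_cohort(ruleset: ProtocolRuleSet, cohort: Sequence[Patient]) -> Ranking:
    """Apply a rule set to every patient and group by priority.

    Qualification-only rule sets (no severity scoring) place all qualifying
    patients in a single undifferentiated group.
    """
    assignments = {p.id: compute_priority(ruleset, p) for p in cohort}
    exempt = tuple(
        p.id for p in cohort if assignments[p.id].status is Status.exempt_frontline
    )
    excluded = tuple(p.id for p in cohort if assignments[p.id].status is Status.excluded)
    by_score: dict[int, list[int]] = {}
    for p in cohort:
        a = assignments[p.id]
        if a.status is Status.eligible:
            by_score.setdefault(a.score, []).append(p.id)  # type: ignore[arg-type]
    groups = tuple(
        PriorityGroup(score=s, member_ids=tuple(sorted(by_score[s])))
        for s in sorted(by_score)
    )
    return Ranking(
        ruleset_id=ruleset.id,
        exempt_ids=exempt,
        groups=groups,
        excluded_ids=excluded,
        assignments=assignments,
    )


# ---------------------------------------------------------------------------
# Shipped protocol configurations
# ---------------------------------------------------------------------------

SHIPPED_PROTOCOLS = ("MD", "PA", "FL", "NY", "CA", "NE")


def list_protocols() -> tuple[str, ...]:
    """Ids of the six shipped protocol configurations."""
    return SHIPPED_PROTOCOLS


def load_protocol(id_or_path: str | Path) -> ProtocolRuleSet:
    """Load a rule set by shipped id (``"MD"`` ... ``"NE"``) or from a YAML
    file path; validation errors name the offending file."""
    key = str(id_or_path)
    if key.upper() in SHIPPED_PROTOCOLS:
        text = (
            resources.files("triagesim")
            .joinpath(f"protocols/{key.lower()}.yaml")
            .read_text()
        )
        source = f"shipped protocol {key.upper()}"
    else:
        path = Path(id_or_path)
        if not path.exists():
            raise ConfigurationError(
                f"{id_or_path!r} is neither a shipped protocol id {SHIPPED_PROTOCOLS} nor a file"
            )
        text = path.read_text()
        source = str(path)
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigurationError(f"{source}: YAML parse error: {exc}") from exc
    return parse_ruleset(data, source=source)


def parse_ruleset(data: dict, source: str = "<inline>") -> ProtocolRuleSet:
    """Validate a mapping into a :class:`ProtocolRuleSet`."""
    if not isinstance(data, dict):
        raise ConfigurationError(f"{source}: expected a mapping, got {type(data).__name__}")
    try:
        return ProtocolRuleSet(**data)
    except (ValidationError, ConfigurationError) as exc:
        raise ConfigurationError(f"{source}: {exc}") from exc


def protocol_features(ruleset: ProtocolRuleSet) -> dict[str, str]:
    """Summarize which triage components a rule set uses, for cross-protocol
    comparison grids.  Values are ``"yes"``, ``"ties_only"`` or ``"no"``."""

    def flag(cond: bool) -> str:
        return "yes" if cond else "no"

    age = "no"
    if ruleset.age_bands is not None and any(b.points for b in ruleset.age_bands):
        age = "yes"
    elif TiebreakStep.younger_age in ruleset.tiebreak_chain:
        age = "ties_only"
    frontline = "no"
    if ruleset.frontline_policy is FrontlinePolicy.exemption:
        frontline = "yes"
    elif (
        ruleset.frontline_policy is FrontlinePolicy.tiebreak_only
        or TiebreakStep.frontline in ruleset.tiebreak_chain
    ):
        frontline = "ties_only"
    return {
        "sofa": "yes",  # every protocol consumes the SOFA total somewhere
        "exclusion_criteria": flag(
            ruleset.sofa_exclusion is not None or bool(ruleset.excluded_comorbidities)
        ),
        "age": age,
        "pregnancy": flag(ruleset.pregnancy_modifier is not None),
        "frontline": frontline,
        "tiebreak": flag(bool(ruleset.tiebreak_chain)),
    }
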