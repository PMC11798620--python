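"""Capacity-constrained ventilator allocation over a ranked cohort.

Given a :class:`~triagesim.rules.Ranking`, a scenario (capacity, arrival
order, RNG seed) and the protocol's tie-break chain, :func:`allocate` assigns
each patient one of five outcomes:

* ``allocated`` -- received a ventilator (rendered ``***``),
* ``tied_lost`` -- tied at the capacity boundary and lost the tie-break
  (``**``),
* ``qualified_undetermined`` -- qualifies but the protocol supplies no way to
  choose among equals (``*``),
* ``not_allocated`` -- eligible but outranked (``O``),
* ``excluded`` -- screened out (``O``).

Frontline-exempt patients are served before any scored group and consume
capacity.  A priority group that fits the remaining capacity is allocated
wholly; a group straddling the boundary is resolved by the tie-break chain in
order (younger age, frontline status, first-come-first-served, seeded
lottery).  Protocols with no severity scoring and no tie-break chain leave
every qualifying patient undetermined and assign nothing.
"""

from __future__ import annotations

from enum import Enum
from typing import Optional, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .cohort import Patient
from .rules import ProtocolRuleSet, Ranking, TiebreakStep

__all__ = [
    "ScenarioConfig",
    "OutcomeStatus",
    "AllocationOutcome",
    "ContractError",
    "UnresolvedTieError",
    "SYMBOLS",
    "allocate",
    "resolve_tie",
    "arrival_positions",
]


class ContractError(ValueError):
    """Ranking, cohort and scenario inputs do not belong together."""


class UnresolvedTieError(RuntimeError):
    """The tie-break chain was exhausted (or empty) with the tie unresolved."""


class ScenarioConfig(BaseModel):
    """One allocation scenario: capacity, protocols, arrival order, seed.

    The default mirrors the study setting: three of a hospital's thirty
    ventilators remain available.  ``arrival_order``, when given, is an
    explicit permutation of cohort patient ids (first to present first) and
    overrides the cohort's own ``arrival_rank`` field.
    """

    model_config = ConfigDict(frozen=True)

    n_ventilators: int = Field(default=3, ge=0)
    protocols: tuple[str, ...] = ("MD", "PA", "FL", "NY", "CA", "NE")
    rng_seed: int = 0
    arrival_order: Optional[tuple[int, ...]] = None

    @field_validator("arrival_order")
    @classmethod
    def _unique(cls, v: Optional[tuple[int, ...]]) -> Optional[tuple[int, ...]]:
        if v is not None and len(set(v)) != len(v):
            raise ValueError("arrival_order contains duplicate patient ids")
        return v


class OutcomeStatus(str, Enum):
    allocated = "allocated"
    tied_lost = "tied_lost"
    qualified_undetermined = "qualified_undetermined"
    not_allocated = "not_allocated"
    excluded = "excluded"


#: Fixed rendering of outcomes in comparison tables.
SYMBOLS: dict[OutcomeStatus, str] = {
    OutcomeStatus.allocated: "***",
    OutcomeStatus.tied_lost: "**",
    OutcomeStatus.qualified_undetermined: "*",
    OutcomeStatus.not_allocated: "O",
    OutcomeStatus.excluded: "O",
}


class AllocationOutcome(BaseModel):
    model_config = ConfigDict(frozen=True)

    patient_id: int
    status: OutcomeStatus
    tiebreak_applied: Optional[str] = None

    @property
    def symbol(self) -> str:
        return SYMBOLS[self.status]


def arrival_positions(
    cohort: Sequence[Patient], scenario: ScenarioConfig
) -> dict[int, int]:
    """Patient id -> arrival position (1 = first), from the scenario's explicit
    order when given, else the cohort's ``arrival_rank`` field."""
    ids = {p.id for p in cohort}
    if scenario.arrival_order is not None:
        if set(scenario.arrival_order) != ids:
            raise ContractError(
                "scenario arrival_order is not a permutation of cohort patient ids"
            )
        return {pid: i + 1 for i, pid in enumerate(scenario.arrival_order)}
    return {p.id: p.arrival_rank for p in cohort}


def _step_key(step: TiebreakStep, patient: Patient, arrival: dict[int, int]):
    if step is TiebreakStep.younger_age:
        return patient.age
    if step is TiebreakStep.frontline:
        return 0 if patient.frontline else 1
    if step is TiebreakStep.fcfs:
        return arrival[patient.id]
    raise AssertionError(step)  # lottery handled separately


def resolve_tie(
    members: Sequence[Patient],
    chain: Sequence[TiebreakStep],
    capacity: int,
    arrival: dict[int, int],
    rng: np.random.Generator,
) -> tuple[list[int], list[int], str]:
    """Split a straddling group into winners and losers.

    Requires ``len(members) > capacity > 0``.  Each chain step is applied only
    to break ties surviving earlier steps; a lottery samples uniformly without
    replacement from the surviving tied set.  Returns ``(winner_ids,
    loser_ids, applied_step)`` where ``applied_step`` names the step that
    finally discriminated at the capacity boundary.

    Raises
    ------
    UnresolvedTieError
        If the chain is empty or exhausted while members remain tied at the
        boundary.
    """
    if not (len(members) > capacity > 0):
        raise ContractError(
            f"resolve_tie requires group size > capacity > 0, got {len(members)} vs {capacity}"
        )
    if not chain:
        raise UnresolvedTieError("no tie-break steps remain")
    step = chain[0]
    if step is TiebreakStep.lottery:
        order = rng.permutation(len(members))
        winners = [members[i].id for i in order[:capacity]]
        losers = [members[i].id for i in order[capacity:]]
        return winners, losers, TiebreakStep.lottery.value

    buckets: dict[object, list[Patient]] = {}
    for p in members:
        buckets.setdefault(_step_key(step, p, arrival), []).append(p)
    winners: list[int] = []
    losers: list[int] = []
    applied = step.value
    for key in sorted(buckets):  # ascending key = higher priority
        bucket = buckets[key]
        slots = capacity - len(winners)
        if slots == 0:
            losers.extend(p.id for p in bucket)
        elif len(bucket) <= slots:
            winners.extend(p.id for p in bucket)
        else:
            sub_w, sub_l, applied = resolve_tie(bucket, chain[1:], slots, arrival, rng)
            winners.extend(sub_w)
            losers.extend(sub_l)
    return winners, losers, applied


def allocate(
    ranking: Ranking,
    ruleset: ProtocolRuleSet,
    cohort: Sequence[Patient],
    scenario: ScenarioConfig,
    rng: Optional[np.random.Generator] = None,
    resolve_unscored_by_lottery: bool = False,
) -> list[AllocationOutcome]:
    """Allocate ``scenario.n_ventilators`` ventilators over a ranked cohort.

    Outcomes are returned in cohort order.  ``resolve_unscored_by_lottery``
    is a sensitivity override: protocols with neither severity scoring nor a
    tie-break chain normally leave every qualifier undetermined; with the
    override their single qualifying group is resolved by a seeded lottery
    instead.
    """
    if ranking.ruleset_id != ruleset.id:
        raise ContractError(
            f"ranking was produced for {ranking.ruleset_id!r}, not {ruleset.id!r}"
        )
    by_id = {p.id: p for p in cohort}
    if set(ranking.assignments) != set(by_id):
        raise ContractError("ranking and cohort cover different patient ids")
    arrival = arrival_positions(cohort, scenario)
    if rng is None:
        rng = np.random.default_rng(scenario.rng_seed)

    outcomes: dict[int, AllocationOutcome] = {}
    for pid in ranking.excluded_ids:
        outcomes[pid] = AllocationOutcome(patient_id=pid, status=OutcomeStatus.excluded)

    chain = list(ruleset.tiebreak_chain)
    unscored_undetermined = not ruleset.scored and not chain and not resolve_unscored_by_lottery
    if unscored_undetermined:
        # No severity scoring and no tie-break mechanism: the protocol gives
        # no way to choose among qualifiers, so none receives a ventilator.
        for pid in ranking.exempt_ids + ranking.eligible_ids:
            outcomes[pid] = AllocationOutcome(
                patient_id=pid, status=OutcomeStatus.qualified_undetermined
            )
        return [outcomes[p.id] for p in cohort]
    if not ruleset.scored and not chain and resolve_unscored_by_lottery:
        chain = [TiebreakStep.lottery]

    remaining = scenario.n_ventilators
    halted = False  # an unresolved straddle stops all further assignment

    def serve_group(member_ids: tuple[int, ...]) -> None:
        nonlocal remaining, halted
        if halted or remaining == 0 or not member_ids:
            for pid in member_ids:
                if pid not in outcomes:
                    outcomes[pid] = AllocationOutcome(
                        patient_id=pid, status=OutcomeStatus.not_allocated
                    )
            return
        if len(member_ids) <= remaining:
            for pid in member_ids:
                outcomes[pid] = AllocationOutcome(
                    patient_id=pid, status=OutcomeStatus.allocated
                )
            remaining -= len(member_ids)
            return
        members = [by_id[pid] for pid in member_ids]
        try:
            winners, losers, applied = resolve_tie(members, chain, remaining, arrival, rng)
        except UnresolvedTieError:
            for pid in member_ids:
                outcomes[pid] = AllocationOutcome(
                    patient_id=pid, status=OutcomeStatus.qualified_undetermined
                )
            halted = True
            return
        for pid in winners:
            outcomes[pid] = AllocationOutcome(
                patient_id=pid, status=OutcomeStatus.allocated, tiebreak_applied=applied
            )
        for pid in losers:
            outcomes[pid] = AllocationOutcome(
                patient_id=pid, status=OutcomeStatus.tied_lost, tiebreak_applied=applied
            )
        remaining = 0

    serve_group(ranking.exempt_ids)
    for group in ranking.groups:
        serve_group(group.member_ids)

    assert sum(o.status is OutcomeStatus.allocated for o in outcomes.values()) <= scenario.n_ventilators
    return [outcomes[p.id] for p in cohort]
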