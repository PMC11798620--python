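"""Exhaustive grid search recovering rule-set parameters from a target
allocation column.

The six shipped protocol configurations reconstruct documents that publish
qualitative rules but not point tables.  This module is the oracle that
justifies those reconstructions: given a finite grid of candidate parameter
values around a base rule set, it simulates every grid point against a cohort
and returns *all* points whose allocation outcomes match a target column of
symbols.  The search is plain enumeration -- no pruning -- so a returned
(or missing) match is trivially trustworthy, and non-uniqueness is surfaced
as a multi-element result set rather than hidden.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Any, Iterator, Mapping, Sequence

from .allocator import ScenarioConfig, allocate
from .cohort import Patient
from .rules import ConfigurationError, ProtocolRuleSet, parse_ruleset, rank_cohort

__all__ = [
    "ParameterGrid",
    "GridTooLargeError",
    "calibrate",
    "simulate_column",
    "roundtrip_recovery",
    "neighborhood_grid",
]

DEFAULT_GRID_CAP = 1_000_000

_SYMBOL_ALPHABET = {"***", "**", "*", "O"}


class GridTooLargeError(ValueError):
    """The grid exceeds the enumeration cap; tighten the axes."""


@dataclass(frozen=True)
class ParameterGrid:
    """A finite grid: a base rule set plus per-field candidate lists.

    Each axis names a :class:`ProtocolRuleSet` field and lists candidate
    values for it (raw mappings are accepted and validated through the model).
    The grid enumerates the cartesian product of all axes applied to the base.
    """

    base: ProtocolRuleSet
    axes: Mapping[str, Sequence[Any]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.axes) - set(ProtocolRuleSet.model_fields)
        if unknown:
            raise ConfigurationError(f"grid axes name unknown fields: {sorted(unknown)}")
        for name, candidates in self.axes.items():
            if len(candidates) == 0:
                raise ConfigurationError(f"grid axis {name!r} has no candidates")

    @property
    def size(self) -> int:
        n = 1
        for candidates in self.axes.values():
            n *= len(candidates)
        return n

    def points(self) -> Iterator[ProtocolRuleSet]:
        names = list(self.axes)
        for combo in product(*(self.axes[n] for n in names)):
            update = dict(zip(names, combo))
            data = {**self.base.model_dump(mode="python"), **update}
            yield parse_ruleset(data, source=f"grid point over {self.base.id}")


def simulate_column(
    ruleset: ProtocolRuleSet,
    cohort: Sequence[Patient],
    scenario: ScenarioConfig,
) -> dict[int, str]:
    """Allocation symbols per patient id for one rule set (one scenario run)."""
    ranking = rank_cohort(ruleset, cohort)
    return {o.patient_id: o.symbol for o in allocate(ranking, ruleset, cohort, scenario)}


def calibrate(
    grid: ParameterGrid,
    cohort: Sequence[Patient],
    scenario: ScenarioConfig,
    target: Mapping[int, str],
    cap: int = DEFAULT_GRID_CAP,
) -> list[ProtocolRuleSet]:
    """Return every grid point whose simulated allocation equals ``target``.

    ``target`` maps patient ids to symbols; comparison is restricted to the
    ids present in the target, so a target may cover only part of the cohort.
    Refuses grids larger than ``cap``.
    """
    bad = {s for s in target.values()} - _SYMBOL_ALPHABET
    if bad:
        raise ConfigurationError(f"target contains unknown symbols: {sorted(bad)}")
    unknown_ids = set(target) - {p.id for p in cohort}
    if unknown_ids:
        raise ConfigurationError(f"target names patient ids not in cohort: {sorted(unknown_ids)}")
    if grid.size > cap:
        raise GridTooLargeError(
            f"grid has {grid.size} points, above the cap of {cap}; tighten the axes"
        )
    matches = []
    for candidate in grid.points():
        column = simulate_column(candidate, cohort, scenario)
        if all(column[pid] == sym for pid, sym in target.items()):
            matches.append(candidate)
    return matches


def roundtrip_recovery(
    ruleset: ProtocolRuleSet,
    cohort: Sequence[Patient],
    scenario: ScenarioConfig,
    grid: ParameterGrid,
) -> bool:
    """Generate the target from ``ruleset`` itself, search the grid, and check
    the generator is among the matches (it must be, when the grid contains it)."""
    target = simulate_column(ruleset, cohort, scenario)
    return ruleset in calibrate(grid, cohort, scenario, target)


def neighborhood_grid(ruleset: ProtocolRuleSet) -> ParameterGrid:
    """A modest grid around a rule set, varying the parameters that were
    genuinely uncertain in its reconstruction.

    Cutoffs move by +/-1, pregnancy modifiers sweep -1..-3, comorbidity point
    weights sweep 3..5, and exclusion lists toggle metastatic cancer (the one
    condition whose exclusion status differs between the qualitative
    descriptions and the reference outcomes).
    """
    axes: dict[str, list[Any]] = {}
    if ruleset.sofa_exclusion is not None:
        cut = ruleset.sofa_exclusion.cutoff
        axes["sofa_exclusion"] = [
            {"comparator": ruleset.sofa_exclusion.comparator.value, "cutoff": c}
            for c in (cut - 1, cut, cut + 1)
        ]
    if ruleset.qualification_sofa_cutoff is not None:
        cut = ruleset.qualification_sofa_cutoff
        axes["qualification_sofa_cutoff"] = [cut - 1, cut, cut + 1]
    if ruleset.pregnancy_modifier is not None:
        axes["pregnancy_modifier"] = [-1, -2, -3]
    if ruleset.comorbidity_points:
        axes["comorbidity_points"] = [
            {sev.value: pts for sev, pts in ruleset.comorbidity_points.items()} | {"severe_life_limiting": w}
            for w in (3, 4, 5)
        ]
    if ruleset.excluded_comorbidities:
        base_list = [c.value for c in ruleset.excluded_comorbidities]
        with_cancer = sorted(set(base_list) | {"metastatic_cancer"})
        without_cancer = sorted(set(base_list) - {"metastatic_cancer"})
        variants = [base_list]
        for v in (with_cancer, without_cancer):
            if v != base_list and v not in variants:
                variants.append(v)
        axes["excluded_comorbidities"] = variants
    return ParameterGrid(base=ruleset, axes=axes)
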