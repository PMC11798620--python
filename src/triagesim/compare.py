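"""Cross-protocol analysis: the allocation matrix, concordance metrics, and
Monte-Carlo estimation of allocation probability under randomized tie-breaks
and arrival orders.

The allocation matrix is the patients x protocols grid of four-symbol
outcomes (``***`` allocated, ``**`` tied-lost, ``*`` qualified-undetermined,
``O`` not allocated / excluded).  Concordance is assessed at two levels:

* **vector level** -- two protocols agree iff their full five-valued status
  vectors over the cohort are identical (``excluded`` and ``not_allocated``
  both print ``O`` but are different statuses);
* **set level** -- two protocols agree iff the sets of patients they
  definitively allocate are equal.

Two protocols can share a definitive-allocation set while their status
vectors differ, so both metrics are always reported.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .allocator import AllocationOutcome, OutcomeStatus, ScenarioConfig, allocate
from .cohort import Patient, cohort_digest
from .rules import ProtocolRuleSet, rank_cohort

__all__ = [
    "AllocationMatrix",
    "ConcordanceReport",
    "build_matrix",
    "allocation_counts",
    "concordance",
    "chance_analysis",
]


@dataclass(frozen=True)
class AllocationMatrix:
    """Patients x protocols outcome grid with provenance.

    ``table`` has one row per patient (id index; ``age``, ``sex``, ``sofa``
    echo columns) and one symbol column per protocol.  ``outcomes`` retains
    the full per-protocol :class:`AllocationOutcome` objects.
    """

    table: pd.DataFrame
    outcomes: dict[str, dict[int, AllocationOutcome]]
    provenance: dict = field(default_factory=dict)

    @property
    def protocol_ids(self) -> list[str]:
        return list(self.outcomes)

    def status(self, protocol_id: str, patient_id: int) -> OutcomeStatus:
        return self.outcomes[protocol_id][patient_id].status

    def definitive_set(self, protocol_id: str) -> frozenset[int]:
        """Patients definitively allocated a ventilator under one protocol."""
        return frozenset(
            pid
            for pid, o in self.outcomes[protocol_id].items()
            if o.status is OutcomeStatus.allocated
        )

    def status_vector(self, protocol_id: str) -> tuple[str, ...]:
        return tuple(
            self.outcomes[protocol_id][pid].status.value for pid in self.table.index
        )

    def to_markdown(self) -> str:
        """Render the grid as a Markdown table (Patient, Age, Sex, SOFA, then
        one symbol column per protocol)."""
        cols = ["Patient", "Age", "Sex", "SOFA", *self.protocol_ids]
        lines = ["| " + " | ".join(cols) + " |", "|" + "---|" * len(cols)]
        for pid, row in self.table.iterrows():
            cells = [str(pid), str(row["age"]), row["sex"][0].upper(), str(row["sofa"])]
            cells += [row[proto] for proto in self.protocol_ids]
            lines.append("| " + " | ".join(cells) + " |")
        return "\n".join(lines) + "\n"

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index_label="patient")


def build_matrix(
    cohort: Sequence[Patient],
    rulesets: Sequence[ProtocolRuleSet],
    scenario: ScenarioConfig,
    resolve_unscored_by_lottery: bool = False,
) -> AllocationMatrix:
    """Run every rule set over the cohort at the scenario capacity.

    Each protocol draws from its own RNG stream spawned from the scenario
    seed, so results are deterministic given the seed and independent of
    protocol order.
    """
    streams = np.random.SeedSequence(scenario.rng_seed).spawn(len(rulesets))
    outcomes: dict[str, dict[int, AllocationOutcome]] = {}
    for ruleset, stream in zip(rulesets, streams):
        ranking = rank_cohort(ruleset, cohort)
        result = allocate(
            ranking,
            ruleset,
            cohort,
            scenario,
            rng=np.random.default_rng(stream),
            resolve_unscored_by_lottery=resolve_unscored_by_lottery,
        )
        outcomes[ruleset.id] = {o.patient_id: o for o in result}

    index = [p.id for p in cohort]
    data = {
        "age": [p.age for p in cohort],
        "sex": [p.sex.value for p in cohort],
        "sofa": [p.sofa_total for p in cohort],
    }
    for ruleset in rulesets:
        data[ruleset.id] = [outcomes[ruleset.id][pid].symbol for pid in index]
    table = pd.DataFrame(data, index=pd.Index(index, name="patient"))
    provenance = {
        "n_ventilators": scenario.n_ventilators,
        "rng_seed": scenario.rng_seed,
        "protocols": [r.id for r in rulesets],
        "cohort_sha256": cohort_digest(cohort),
    }
    return AllocationMatrix(table=table, outcomes=outcomes, provenance=provenance)


def allocation_counts(matrix: AllocationMatrix) -> pd.DataFrame:
    """Per-patient counts across protocols: definitive allocations (``***``)
    and qualified-undetermined outcomes (``*``)."""
    rows = {}
    for pid in matrix.table.index:
        statuses = [matrix.status(proto, pid) for proto in matrix.protocol_ids]
        rows[pid] = {
            "n_allocated": sum(s is OutcomeStatus.allocated for s in statuses),
            "n_qualified_undetermined": sum(
                s is OutcomeStatus.qualified_undetermined for s in statuses
            ),
        }
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("patient")


@dataclass(frozen=True)
class ConcordanceReport:
    """Pairwise protocol agreement on one allocation matrix."""

    n_protocols: int
    pair_count: int
    vector_identical_pairs: tuple[tuple[str, str], ...]
    set_identical_pairs: tuple[tuple[str, str], ...]
    definitive_sets: dict[str, frozenset[int]]
    allocated_counts: dict[int, int]
    qualified_counts: dict[int, int]

    @property
    def n_vector_identical(self) -> int:
        return len(self.vector_identical_pairs)

    @property
    def n_set_identical(self) -> int:
        return len(self.set_identical_pairs)

    def to_json(self) -> str:
        payload = {
            "n_protocols": self.n_protocols,
            "pair_count": self.pair_count,
            "vector_identical_pairs": [list(p) for p in self.vector_identical_pairs],
            "n_vector_identical": self.n_vector_identical,
            "set_identical_pairs": [list(p) for p in self.set_identical_pairs],
            "n_set_identical": self.n_set_identical,
            "definitive_sets": {k: sorted(v) for k, v in self.definitive_sets.items()},
            "allocated_counts": {str(k): v for k, v in self.allocated_counts.items()},
            "qualified_counts": {str(k): v for k, v in self.qualified_counts.items()},
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def concordance(matrix: AllocationMatrix) -> ConcordanceReport:
    """Count protocol pairs with identical status vectors and with identical
    definitive-allocation sets."""
    protos = matrix.protocol_ids
    if len(protos) < 2:
        raise ValueError("concordance needs at least two protocol columns")
    vectors = {p: matrix.status_vector(p) for p in protos}
    sets = {p: matrix.definitive_set(p) for p in protos}
    vec_pairs = tuple(
        (a, b) for a, b in combinations(protos, 2) if vectors[a] == vectors[b]
    )
    set_pairs = tuple((a, b) for a, b in combinations(protos, 2) if sets[a] == sets[b])
    counts = allocation_counts(matrix)
    return ConcordanceReport(
        n_protocols=len(protos),
        pair_count=math.comb(len(protos), 2),
        vector_identical_pairs=vec_pairs,
        set_identical_pairs=set_pairs,
        definitive_sets=sets,
        allocated_counts=counts["n_allocated"].to_dict(),
        qualified_counts=counts["n_qualified_undetermined"].to_dict(),
    )


def chance_analysis(
    cohort: Sequence[Patient],
    ruleset: ProtocolRuleSet,
    scenario: ScenarioConfig,
    n_reps: int = 10_000,
    seed: Optional[int] = None,
    randomize: str = "lottery",
) -> pd.DataFrame:
    """Monte-Carlo allocation probability per patient under one protocol.

    ``randomize`` selects the chance source re-drawn each replicate:
    ``"lottery"`` (fresh lottery stream, arrival order fixed), ``"arrival"``
    (arrival order permuted uniformly), or ``"both"``.  Returns a DataFrame
    indexed by patient id with columns ``prob`` (empirical allocation
    probability) and ``se`` (binomial standard error).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if randomize not in {"lottery", "arrival", "both"}:
        raise ValueError(f"randomize must be lottery|arrival|both, got {randomize!r}")
    master = np.random.default_rng(scenario.rng_seed if seed is None else seed)
    ranking = rank_cohort(ruleset, cohort)
    ids = [p.id for p in cohort]
    wins = {pid: 0 for pid in ids}
    for _ in range(n_reps):
        if randomize in {"arrival", "both"}:
            order = master.permutation(ids)
            rep_scenario = scenario.model_copy(update={"arrival_order": tuple(int(i) for i in order)})
        else:
            rep_scenario = scenario
        rep_rng = np.random.default_rng(master.integers(0, 2**31))
        for o in allocate(ranking, ruleset, cohort, rep_scenario, rng=rep_rng):
            if o.status is OutcomeStatus.allocated:
                wins[o.patient_id] += 1
    probs = {pid: wins[pid] / n_reps for pid in ids}
    se = {pid: math.sqrt(probs[pid] * (1 - probs[pid]) / n_reps) for pid in ids}
    return pd.DataFrame(
        {"prob": pd.Series(probs), "se": pd.Series(se)}
    ).rename_axis("patient")
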