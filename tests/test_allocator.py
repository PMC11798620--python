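import numpy as np
import pytest

from triagesim.allocator import (
    ContractError,
    OutcomeStatus,
    ScenarioConfig,
    UnresolvedTieError,
    allocate,
    resolve_tie,
)
from triagesim.cohort import CohortGeneratorConfig, Patient, generate_cohort
from triagesim.rules import TiebreakStep, rank_cohort


def _outcomes_by_id(results):
    return {o.patient_id: o for o in results}


def _statuses(results, status):
    return {o.patient_id for o in results if o.status is status}


class TestAllocate:
    def test_md_column(self, rulesets_by_id, fixture_cohort, scenario):
        md = rulesets_by_id["MD"]
        out = allocate(rank_cohort(md, fixture_cohort), md, fixture_cohort, scenario)
        assert _statuses(out, OutcomeStatus.allocated) == {3, 6, 7}
        assert _statuses(out, OutcomeStatus.tied_lost) == {5}
        by_id = _outcomes_by_id(out)
        assert by_id[5].tiebreak_applied == "younger_age"
        for pid in (1, 4):
            assert by_id[pid].status is OutcomeStatus.not_allocated
        for pid in (2, 8, 9):
            assert by_id[pid].status is OutcomeStatus.excluded

    def test_ny_column_fcfs(self, rulesets_by_id, fixture_cohort, scenario):
        ny = rulesets_by_id["NY"]
        out = allocate(rank_cohort(ny, fixture_cohort), ny, fixture_cohort, scenario)
        assert _statuses(out, OutcomeStatus.allocated) == {5, 7, 8}
        by_id = _outcomes_by_id(out)
        assert by_id[4].status is OutcomeStatus.tied_lost
        assert by_id[4].tiebreak_applied == "fcfs"

    def test_ne_leaves_all_qualifiers_undetermined(self, rulesets_by_id, fixture_cohort, scenario):
        ne = rulesets_by_id["NE"]
        out = allocate(rank_cohort(ne, fixture_cohort), ne, fixture_cohort, scenario)
        assert _statuses(out, OutcomeStatus.qualified_undetermined) == {4, 5, 6, 7, 8, 9}
        assert not _statuses(out, OutcomeStatus.allocated)

    def test_ne_lottery_override_allocates_to_capacity(self, rulesets_by_id, fixture_cohort, scenario):
        ne = rulesets_by_id["NE"]
        out = allocate(
            rank_cohort(ne, fixture_cohort), ne, fixture_cohort, scenario,
            resolve_unscored_by_lottery=True,
        )
        assert len(_statuses(out, OutcomeStatus.allocated)) == 3

    def test_zero_capacity(self, rulesets, fixture_cohort):
        empty = ScenarioConfig(n_ventilators=0)
        for ruleset in rulesets:
            out = allocate(rank_cohort(ruleset, fixture_cohort), ruleset, fixture_cohort, empty)
            assert not _statuses(out, OutcomeStatus.allocated)
            # exclusion/qualification semantics survive a capacity of zero
            screened_out = _statuses(out, OutcomeStatus.excluded)
            assert screened_out == {
                p.id for p in fixture_cohort
                if rank_cohort(ruleset, fixture_cohort).assignments[p.id].status.value == "excluded"
            }

    def test_frontline_exemption_consumes_capacity(self, rulesets_by_id, fixture_cohort):
        ca = rulesets_by_id["CA"]
        tight = ScenarioConfig(n_ventilators=2)
        out = allocate(rank_cohort(ca, fixture_cohort), ca, fixture_cohort, tight)
        assert _statuses(out, OutcomeStatus.allocated) == {1, 7}

    def test_ranking_cohort_mismatch_rejected(self, rulesets_by_id, fixture_cohort, scenario):
        md = rulesets_by_id["MD"]
        ranking = rank_cohort(md, fixture_cohort)
        with pytest.raises(ContractError):
            allocate(ranking, md, fixture_cohort[:5], scenario)
        with pytest.raises(ContractError):
            allocate(ranking, rulesets_by_id["PA"], fixture_cohort, scenario)

    def test_seeded_reproducibility(self, rulesets, fixture_cohort):
        scen = ScenarioConfig(n_ventilators=3, rng_seed=123)
        for ruleset in rulesets:
            ranking = rank_cohort(ruleset, fixture_cohort)
            first = allocate(ranking, ruleset, fixture_cohort, scen)
            second = allocate(ranking, ruleset, fixture_cohort, scen)
            assert first == second


class TestResolveTie:
    def test_fcfs_by_arrival_position(self, fixture_cohort):
        members = [p for p in fixture_cohort if p.id in {4, 5, 7, 8}]
        arrival = {p.id: p.arrival_rank for p in fixture_cohort}
        winners, losers, applied = resolve_tie(
            members, [TiebreakStep.fcfs], 3, arrival, np.random.default_rng(0)
        )
        assert set(winners) == {5, 7, 8} and losers == [4] and applied == "fcfs"

    def test_younger_age_discriminates_before_fcfs(self, fixture_cohort):
        members = [p for p in fixture_cohort if p.id in {5, 6}]
        arrival = {p.id: p.arrival_rank for p in fixture_cohort}
        winners, losers, applied = resolve_tie(
            members, [TiebreakStep.younger_age, TiebreakStep.fcfs], 1, arrival,
            np.random.default_rng(0),
        )
        assert winners == [6] and losers == [5] and applied == "younger_age"

    def test_lottery_is_seeded(self, fixture_cohort):
        members = [p for p in fixture_cohort if p.id in {2, 4, 6}]
        arrival = {p.id: p.arrival_rank for p in fixture_cohort}
        draws = {
            resolve_tie(members, [TiebreakStep.lottery], 1, arrival,
                        np.random.default_rng(99))[0][0]
            for _ in range(5)
        }
        assert len(draws) == 1

    def test_empty_chain_signals_unresolved(self, fixture_cohort):
        members = fixture_cohort[:3]
        with pytest.raises(UnresolvedTieError):
            resolve_tie(members, [], 2, {p.id: p.arrival_rank for p in fixture_cohort},
                        np.random.default_rng(0))

    def test_precondition_enforced(self, fixture_cohort):
        arrival = {p.id: p.arrival_rank for p in fixture_cohort}
        with pytest.raises(ContractError):
            resolve_tie(fixture_cohort[:2], [TiebreakStep.fcfs], 2, arrival,
                        np.random.default_rng(0))
        with pytest.raises(ContractError):
            resolve_tie(fixture_cohort[:2], [TiebreakStep.fcfs], 0, arrival,
                        np.random.default_rng(0))


@pytest.mark.parametrize("seed", range(5))
def test_conservation_and_no_leapfrogging(rulesets, seed):
    """On random synthetic cohorts: never more ventilators than capacity;
    capacity saturated when enough eligible patients and a tie-break chain
    exists; no patient allocated while a strictly higher-priority eligible
    patient is not."""
    cohort = generate_cohort(CohortGeneratorConfig(n=20, seed=seed))
    scen = ScenarioConfig(n_ventilators=4, rng_seed=seed)
    for ruleset in rulesets:
        ranking = rank_cohort(ruleset, cohort)
        out = allocate(ranking, ruleset, cohort, scen)
        allocated = _statuses(out, OutcomeStatus.allocated)
        assert len(allocated) <= scen.n_ventilators
        n_eligible = len(ranking.exempt_ids) + len(ranking.eligible_ids)
        if ruleset.tiebreak_chain and n_eligible >= scen.n_ventilators:
            assert len(allocated) == scen.n_ventilators
        scores = {
            pid: ranking.assignments[pid].score
            for g in ranking.groups for pid in g.member_ids
        }
        for winner in allocated - set(ranking.exempt_ids):
            for pid, score in scores.items():
                if score < scores[winner]:
                    assert pid in allocated, (
                        f"{ruleset.id}: patient {winner} (score {scores[winner]}) allocated "
                        f"while higher-priority patient {pid} (score {score}) was not"
                    )
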