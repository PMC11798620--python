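import pytest

from triagesim.rules import (
    ConfigurationError,
    FrontlinePolicy,
    ProtocolRuleSet,
    Status,
    compute_priority,
    list_protocols,
    load_protocol,
    parse_ruleset,
    protocol_features,
    rank_cohort,
    screen_exclusions,
)

from conftest import PROTOCOL_IDS


def _patient(cohort, pid):
    return next(p for p in cohort if p.id == pid)


class TestLoadProtocols:
    def test_six_shipped_ids(self):
        assert list_protocols() == PROTOCOL_IDS

    def test_md_structure(self, rulesets_by_id):
        md = rulesets_by_id["MD"]
        assert md.sofa_exclusion is not None and md.excluded_comorbidities
        assert md.age_bands is not None and md.pregnancy_modifier is not None
        assert md.frontline_policy is FrontlinePolicy.ignored

    def test_ne_has_no_tiebreak(self, rulesets_by_id):
        assert rulesets_by_id["NE"].tiebreak_chain == ()
        assert not rulesets_by_id["NE"].scored

    def test_unknown_id_rejected(self):
        with pytest.raises(ConfigurationError):
            load_protocol("XX")

    def test_overlapping_bands_rejected(self):
        with pytest.raises(ConfigurationError, match="overlap"):
            parse_ruleset({
                "id": "bad",
                "sofa_bands": [
                    {"lo": 0, "hi": 6, "points": 1},
                    {"lo": 6, "hi": 10, "points": 2},
                ],
            })

    def test_band_gap_rejected(self):
        with pytest.raises(ConfigurationError, match="gap"):
            parse_ruleset({
                "id": "bad",
                "sofa_bands": [
                    {"lo": 0, "hi": 4, "points": 1},
                    {"lo": 6, "hi": 10, "points": 2},
                ],
            })

    def test_unknown_tiebreak_rejected(self):
        with pytest.raises(ConfigurationError):
            parse_ruleset({"id": "bad", "tiebreak_chain": ["coin_flip"]})


class TestScreening:
    def test_fl_excludes_late_stage_ms(self, rulesets_by_id, fixture_cohort):
        """The multiple-sclerosis patient is screened out by FL despite the
        lowest SOFA in the cohort."""
        result = screen_exclusions(rulesets_by_id["FL"], _patient(fixture_cohort, 8))
        assert result.status is Status.excluded
        assert any("ms_late_stage" in t.rule for t in result.trace)

    def test_ny_keeps_same_patient(self, rulesets_by_id, fixture_cohort):
        result = screen_exclusions(rulesets_by_id["NY"], _patient(fixture_cohort, 8))
        assert result.status is Status.eligible

    def test_pa_excludes_nobody(self, rulesets_by_id, fixture_cohort):
        for p in fixture_cohort:
            assert screen_exclusions(rulesets_by_id["PA"], p).status is Status.eligible

    def test_ne_qualification_cutoff(self, rulesets_by_id, fixture_cohort):
        ne = rulesets_by_id["NE"]
        statuses = {p.id: screen_exclusions(ne, p).status for p in fixture_cohort}
        qualified = {pid for pid, s in statuses.items() if s is Status.eligible}
        assert qualified == {4, 5, 6, 7, 8, 9}


class TestPriority:
    def test_ca_exempts_frontline(self, rulesets_by_id, fixture_cohort):
        res = compute_priority(rulesets_by_id["CA"], _patient(fixture_cohort, 1))
        assert res.status is Status.exempt_frontline and res.score is None

    def test_md_pregnancy_outranks_older_hypertensive(self, rulesets_by_id, fixture_cohort):
        md = rulesets_by_id["MD"]
        s3 = compute_priority(md, _patient(fixture_cohort, 3)).score
        s4 = compute_priority(md, _patient(fixture_cohort, 4)).score
        assert s3 < s4  # lower = better

    def test_pa_score_of_young_low_sofa_patient(self, rulesets_by_id, fixture_cohort):
        assert compute_priority(rulesets_by_id["PA"], _patient(fixture_cohort, 7)).score == 1

    def test_pa_dementia_not_a_qualifying_comorbidity(self, rulesets_by_id, fixture_cohort):
        res = compute_priority(rulesets_by_id["PA"], _patient(fixture_cohort, 5))
        assert res.score == 1  # SOFA band only; dementia scored 0 via override

    def test_trace_self_audit(self, rulesets, fixture_cohort):
        """Every eligible score equals the sum of the point terms recorded in
        its own trace."""
        for ruleset in rulesets:
            for p in fixture_cohort:
                res = compute_priority(ruleset, p)
                if res.status is Status.eligible:
                    assert res.score == sum(
                        t.points for t in res.trace if t.points is not None
                    )

    def test_determinism_and_order_independence(self, rulesets, fixture_cohort):
        for ruleset in rulesets:
            first = rank_cohort(ruleset, fixture_cohort)
            again = rank_cohort(ruleset, list(reversed(fixture_cohort)))
            assert first.groups == again.groups
            assert set(first.excluded_ids) == set(again.excluded_ids)
            assert first.assignments == again.assignments

    def test_band_coverage_gap_is_configuration_error(self, fixture_cohort):
        narrow = parse_ruleset({
            "id": "narrow",
            "sofa_bands": [{"lo": 0, "hi": 5, "points": 1}],
        })
        with pytest.raises(ConfigurationError, match="outside band coverage"):
            compute_priority(narrow, _patient(fixture_cohort, 2))


class TestRanking:
    def test_ny_top_group(self, rulesets_by_id, fixture_cohort):
        ranking = rank_cohort(rulesets_by_id["NY"], fixture_cohort)
        assert ranking.groups[0].member_ids == (4, 5, 7, 8)

    def test_ne_single_undifferentiated_group(self, rulesets_by_id, fixture_cohort):
        ranking = rank_cohort(rulesets_by_id["NE"], fixture_cohort)
        assert len(ranking.groups) == 1
        assert set(ranking.groups[0].member_ids) == {4, 5, 6, 7, 8, 9}

    def test_empty_cohort(self, rulesets_by_id):
        ranking = rank_cohort(rulesets_by_id["MD"], [])
        assert ranking.groups == () and ranking.excluded_ids == ()


# yes / ties_only / no per component, one row per shipped protocol:
# (exclusion criteria, age, pregnancy, frontline, tie-break system)
EXPECTED_FEATURES = {
    "MD": ("yes", "yes", "yes", "no", "yes"),
    "PA": ("no", "ties_only", "no", "ties_only", "yes"),
    "FL": ("yes", "no", "no", "no", "yes"),
    "NY": ("yes", "no", "no", "no", "yes"),
    "CA": ("no", "yes", "yes", "yes", "yes"),
    "NE": ("no", "no", "no", "no", "no"),
}


@pytest.mark.parametrize("protocol_id", PROTOCOL_IDS)
def test_feature_matrix_conformance(rulesets_by_id, protocol_id):
    """Presence/absence of each triage component matches the cross-protocol
    comparison grid."""
    f = protocol_features(rulesets_by_id[protocol_id])
    assert (
        f["exclusion_criteria"], f["age"], f["pregnancy"], f["frontline"], f["tiebreak"]
    ) == EXPECTED_FEATURES[protocol_id]
    assert f["sofa"] == "yes"
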