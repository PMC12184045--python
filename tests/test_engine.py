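from __future__ import annotations

import random

import pytest

from amyelig.engine import (
    AMYLOID_STEP,
    BUNDLED_PROFILE_IDS,
    CriteriaProfile,
    CriterionRule,
    MissingPolicy,
    Phase,
    Predicate,
    ProfileError,
    RuleOutcome,
    StageReached,
    TAU_STEP,
    apply_profile,
    bundled_profiles,
    evaluate_rule,
    funnel_counts,
    load_profile,
)
from amyelig.staging import AmyloidMode
from amyelig.syndrome import base_population
from amyelig.synthetic import SyntheticCohortConfig, generate_cohort

from conftest import make_cohort, make_neuropath, make_participant


def rule(rule_id, phase, field, **pred):
    return CriterionRule(rule_id, phase, field, _predicate(**pred))


def _predicate(**pred):
    kind, body = next(iter(pred.items()))
    if kind == "range":
        return Predicate("range", lo=body[0], hi=body[1])
    if kind == "in_set":
        return Predicate("in_set", values=frozenset(body))
    if kind == "equals":
        return Predicate("equals", value=body)
    return Predicate(kind)


@pytest.fixture
def toy_profile():
    """Two inclusion rules + one exclusion rule, PET-equivalent amyloid."""
    return CriteriaProfile(
        profile_id="toy",
        inclusion_rules=(
            rule("mmse_window", Phase.INCLUSION, "mmse", range=(20, 30)),
            rule("cdr_stage", Phase.INCLUSION, "cdr_global", in_set=(0.5, 1.0)),
        ),
        exclusion_rules=(
            rule("no_anticoagulants", Phase.EXCLUSION, "medication.anticoagulant_use",
                 flag_false=True),
        ),
    )


@pytest.fixture
def toy_cohort():
    """Six hand-traced records spanning every funnel stage.

    P1 eligible; P2 eligible; P3 fails exclusion (anticoagulant);
    P4 fails amyloid (Thal 1); P5 fails inclusion (MMSE 15);
    P6 fails inclusion (CDR 2).
    """
    spec = [
        ("P1", dict(mmse=25, cdr_global=0.5), dict(thal_phase=4), False),
        ("P2", dict(mmse=28, cdr_global=1.0), dict(thal_phase=5), False),
        ("P3", dict(mmse=25, cdr_global=0.5), dict(thal_phase=5), True),
        ("P4", dict(mmse=25, cdr_global=1.0), dict(thal_phase=1), False),
        ("P5", dict(mmse=15, cdr_global=0.5), dict(thal_phase=5), False),
        ("P6", dict(mmse=25, cdr_global=2.0), dict(thal_phase=5), False),
    ]
    pairs = []
    for pid, clin_kw, np_kw, anticoag in spec:
        pairs.append(
            (
                make_participant(pid, medication_flags={"anticoagulant_use": anticoag},
                                 **clin_kw),
                make_neuropath(pid, **np_kw),
            )
        )
    return make_cohort(pairs)


class TestLoadProfile:
    def test_all_bundled_profiles_load(self):
        profiles = bundled_profiles()
        assert set(profiles) == set(BUNDLED_PROFILE_IDS)

    def test_lecanemab_cdr_rule_admits_both_stages(self):
        profile = load_profile("clarity_ad_lecanemab")
        (cdr_rule,) = [r for r in profile.inclusion_rules if r.field_path == "cdr_global"]
        assert cdr_rule.predicate.kind == "in_set"
        assert cdr_rule.predicate.values == frozenset({0.5, 1})

    def test_aducanumab_trial_cdr_rule_is_mci_only(self):
        profile = load_profile("emerge_engage_aducanumab")
        (cdr_rule,) = [r for r in profile.inclusion_rules if r.field_path == "cdr_global"]
        assert cdr_rule.predicate.kind == "equals"
        assert cdr_rule.predicate.value == 0.5

    def test_donanemab_tau_stage_disabled_by_default(self):
        profile = load_profile("trailblazer_alz2_donanemab")
        assert profile.tau_rule_enabled is False
        assert profile.with_options(tau_rule_enabled=True).tau_rule_enabled is True

    def test_inverted_range_is_hard_error(self):
        config = {
            "profile_id": "bad",
            "inclusion": [
                {"rule_id": "r1", "field": "mmse", "range": {"lo": 30, "hi": 24}}
            ],
        }
        with pytest.raises(ProfileError, match="lo"):
            load_profile(config)

    def test_unknown_field_is_hard_error(self):
        config = {
            "profile_id": "bad",
            "inclusion": [{"rule_id": "r1", "field": "shoe_size", "equals": 42}],
        }
        with pytest.raises(ProfileError, match="shoe_size"):
            load_profile(config)

    def test_duplicate_rule_id_is_hard_error(self):
        config = {
            "profile_id": "bad",
            "inclusion": [
                {"rule_id": "r1", "field": "mmse", "range": {"lo": 0, "hi": 30}},
                {"rule_id": "r1", "field": "age_years", "range": {"lo": 0, "hi": 90}},
            ],
        }
        with pytest.raises(ProfileError, match="duplicate"):
            load_profile(config)

    def test_from_file(self, tmp_path):
        path = tmp_path / "p.yaml"
        path.write_text(
            "profile_id: custom\n"
            "inclusion:\n"
            "  - {rule_id: r1, field: mmse, range: {lo: 22, hi: 30}}\n",
            encoding="utf-8",
        )
        profile = load_profile(path)
        assert profile.profile_id == "custom"
        assert profile.amyloid_mode is AmyloidMode.PET_EQUIVALENT


class TestEvaluateRule:
    def test_range_pass(self):
        record = (make_participant("P1", mmse=26), make_neuropath("P1"))
        r = rule("r", Phase.INCLUSION, "mmse", range=(22, 30))
        assert evaluate_rule(r, record) is RuleOutcome.PASS

    def test_flag_false_fails_on_true_flag(self):
        record = (
            make_participant("P1", medication_flags={"anticoagulant_use": True}),
            make_neuropath("P1"),
        )
        r = rule("r", Phase.EXCLUSION, "medication.anticoagulant_use", flag_false=True)
        assert evaluate_rule(r, record) is RuleOutcome.FAIL

    def test_missing_field_is_unevaluable(self):
        record = (make_participant("P1", mmse=None), make_neuropath("P1"))
        r = rule("r", Phase.INCLUSION, "mmse", range=(22, 30))
        assert evaluate_rule(r, record) is RuleOutcome.UNEVALUABLE

    def test_missing_flag_key_is_unevaluable(self):
        record = (make_participant("P1", comorbidity_flags={}), make_neuropath("P1"))
        r = rule("r", Phase.EXCLUSION, "comorbidity.stroke_or_tia", flag_false=True)
        assert evaluate_rule(r, record) is RuleOutcome.UNEVALUABLE

    def test_copath_tristate_resolution(self):
        from amyelig.cohort_io import TriState

        r = rule("r", Phase.EXCLUSION, "copath.lewy_body", flag_false=True)
        for state, expected in [
            (TriState.PRESENT, RuleOutcome.FAIL),
            (TriState.ABSENT, RuleOutcome.PASS),
            (TriState.NOT_REPORTED, RuleOutcome.UNEVALUABLE),
        ]:
            record = (
                make_participant("P1"),
                make_neuropath("P1", copathology_flags={"lewy_body": state}),
            )
            assert evaluate_rule(r, record) is expected


class TestApplyProfile:
    def test_hand_traced_six_record_fixture(self, toy_profile, toy_cohort):
        base = set(toy_cohort.ids)
        traces, eligible = apply_profile(toy_profile, toy_cohort, base)
        assert eligible == {"P1", "P2"}
        by_id = {t.participant_id: t for t in traces}
        assert by_id["P1"].stage_reached is StageReached.ELIGIBLE
        assert by_id["P2"].stage_reached is StageReached.ELIGIBLE
        assert by_id["P3"].stage_reached is StageReached.FAILED_EXCLUSION
        assert by_id["P3"].failing_rule_ids == ("no_anticoagulants",)
        assert by_id["P4"].stage_reached is StageReached.FAILED_AMYLOID
        assert AMYLOID_STEP in by_id["P4"].failing_rule_ids
        assert by_id["P5"].stage_reached is StageReached.FAILED_INCLUSION
        assert "mmse_window" in by_id["P5"].failing_rule_ids
        assert by_id["P6"].stage_reached is StageReached.FAILED_INCLUSION
        assert "cdr_stage" in by_id["P6"].failing_rule_ids

    def test_funnel_counts_from_hand_trace(self, toy_profile, toy_cohort):
        counts = funnel_counts(toy_profile, toy_cohort, set(toy_cohort.ids))
        assert counts.counts == (6, 4, 3, 2)
        assert counts.labels == ("base", "clinical_inclusion", "amyloid_positive",
                                 "eligible")

    def test_zero_rule_profile_any_amyloid_everyone_eligible(self):
        profile = CriteriaProfile("vacuous", (), (),
                                  amyloid_mode=AmyloidMode.ANY_AMYLOID)
        pairs = [
            (make_participant(f"P{i}"), make_neuropath(f"P{i}", thal_phase=1 + i % 5))
            for i in range(5)
        ]
        cohort = make_cohort(pairs)
        _, eligible = apply_profile(profile, cohort, set(cohort.ids))
        assert eligible == set(cohort.ids)
        counts = funnel_counts(profile, cohort, set(cohort.ids))
        assert len(set(counts.counts)) == 1

    def test_missing_policy_single_difference(self, toy_profile):
        pairs = [
            (make_participant("P1", mmse=None), make_neuropath("P1", thal_phase=4)),
            (make_participant("P2", mmse=25), make_neuropath("P2", thal_phase=4)),
        ]
        cohort = make_cohort(pairs)
        base = {"P1", "P2"}
        _, closed = apply_profile(toy_profile, cohort, base,
                                  MissingPolicy.FAIL_CLOSED)
        _, open_ = apply_profile(toy_profile, cohort, base, MissingPolicy.FAIL_OPEN)
        assert open_ - closed == {"P1"}
        assert closed == {"P2"}

    def test_tau_stage_when_enabled(self, toy_profile):
        profile = toy_profile.with_options(tau_rule_enabled=True)
        pairs = [
            (make_participant("P1"), make_neuropath("P1", thal_phase=4, braak_stage=3)),
            (make_participant("P2"), make_neuropath("P2", thal_phase=4, braak_stage=6)),
        ]
        cohort = make_cohort(pairs)
        traces, eligible = apply_profile(profile, cohort, {"P1", "P2"})
        assert eligible == {"P1"}
        by_id = {t.participant_id: t for t in traces}
        assert by_id["P2"].stage_reached is StageReached.FAILED_TAU
        assert TAU_STEP in by_id["P2"].failing_rule_ids

    def test_base_must_be_subset_of_cohort(self, toy_profile, toy_cohort):
        with pytest.raises(KeyError):
            apply_profile(toy_profile, toy_cohort, {"P1", "GHOST"})


class TestEngineProperties:
    @pytest.mark.parametrize("seed", range(5))
    def test_funnel_monotone_on_synthetic_cohorts(self, seed):
        cohort = generate_cohort(SyntheticCohortConfig(n=300, seed=seed))
        base = base_population(cohort)
        for profile in bundled_profiles().values():
            counts = funnel_counts(profile, cohort, base).counts
            assert all(a >= b for a, b in zip(counts, counts[1:]))

    @pytest.mark.parametrize("seed", range(3))
    def test_pet_eligible_subset_of_any_amyloid_eligible(self, seed):
        cohort = generate_cohort(SyntheticCohortConfig(n=300, seed=100 + seed))
        base = base_population(cohort)
        for profile in bundled_profiles().values():
            _, pet = apply_profile(
                profile.with_options(amyloid_mode=AmyloidMode.PET_EQUIVALENT),
                cohort, base)
            _, any_ = apply_profile(
                profile.with_options(amyloid_mode=AmyloidMode.ANY_AMYLOID),
                cohort, base)
            assert pet <= any_

    def test_aducanumab_trial_eligible_set_is_pure_cdr_half(self):
        cohort = generate_cohort(SyntheticCohortConfig(n=2000, seed=5))
        base = base_population(cohort)
        profile = load_profile("emerge_engage_aducanumab")
        _, eligible = apply_profile(profile, cohort, base)
        assert eligible
        assert all(cohort.get(pid)[0].cdr_global == 0.5 for pid in eligible)

    def test_rule_order_insensitivity(self, toy_cohort):
        rng = random.Random(0)
        inclusion = [
            rule("mmse_window", Phase.INCLUSION, "mmse", range=(20, 30)),
            rule("cdr_stage", Phase.INCLUSION, "cdr_global", in_set=(0.5, 1.0)),
            rule("age_window", Phase.INCLUSION, "age_years", range=(50, 90)),
        ]
        exclusion = [
            rule("no_anticoagulants", Phase.EXCLUSION,
                 "medication.anticoagulant_use", flag_false=True),
            rule("no_seizures", Phase.EXCLUSION, "comorbidity.seizures",
                 flag_false=True),
        ]
        reference = None
        for _ in range(5):
            rng.shuffle(inclusion)
            rng.shuffle(exclusion)
            profile = CriteriaProfile("shuffled", tuple(inclusion), tuple(exclusion))
            _, eligible = apply_profile(profile, toy_cohort, set(toy_cohort.ids))
            if reference is None:
                reference = eligible
            assert eligible == reference

    def test_audit_completeness_every_non_eligible_trace_names_a_cause(self):
        cohort = generate_cohort(SyntheticCohortConfig(n=500, seed=9))
        base = base_population(cohort)
        for profile in bundled_profiles().values():
            traces, eligible = apply_profile(profile, cohort, base)
            for trace in traces:
                if trace.participant_id not in eligible:
                    assert trace.failing_rule_ids
                else:
                    assert trace.stage_reached is StageReached.ELIGIBLE
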