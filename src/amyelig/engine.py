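"""Declarative eligibility criteria and their staged application.

A :class:`CriteriaProfile` bundles inclusion rules, exclusion rules, an
amyloid-positivity mode and an optional tau-spread stage.  Applying a
profile to the base population walks each participant through the staged
funnel — clinical inclusion, amyloid positivity, optional intermediate
tau spread, exclusion criteria — and records a per-rule audit trail.

Criteria content is data, not code: bundled profiles live under
``amyelig/data/profiles`` as editable config files with per-rule
provenance labels.  The amyloid and tau steps are dedicated stages (not
ordinary rules) so funnel counts align with the reporting order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

import yaml

from .cohort_io import Cohort, NeuropathRecord, ParticipantRecord, TriState
from .staging import AmyloidMode, amyloid_positive, tau_intermediate

#: stage ids used in traces for the dedicated non-rule steps
AMYLOID_STEP = "amyloid_positivity"
TAU_STEP = "tau_intermediate"

BUNDLED_PROFILE_IDS = (
    "emerge_engage_aducanumab",
    "clarity_ad_lecanemab",
    "trailblazer_alz2_donanemab",
    "aur_aducanumab",
    "aur_lecanemab",
)


class ProfileError(ValueError):
    """Malformed criteria profile or rule."""


class Phase(str, Enum):
    INCLUSION = "inclusion"
    EXCLUSION = "exclusion"


class RuleOutcome(str, Enum):
    PASS = "pass"
    FAIL = "fail"
    UNEVALUABLE = "unevaluable"


class MissingPolicy(str, Enum):
    """How unevaluable rules behave: fail-closed treats them as failures
    (an exclusion that cannot be ruled out excludes); fail-open as passes."""

    FAIL_CLOSED = "fail_closed"
    FAIL_OPEN = "fail_open"


class StageReached(str, Enum):
    FAILED_INCLUSION = "failed_inclusion"
    FAILED_AMYLOID = "failed_amyloid"
    FAILED_TAU = "failed_tau"
    FAILED_EXCLUSION = "failed_exclusion"
    ELIGIBLE = "eligible"


# ---------------------------------------------------------------------------
# Predicates and rules

_PREDICATE_KINDS = ("equals", "in_set", "range", "flag_true", "flag_false")

#: canonical scalar fields rules may address (flags are prefix-addressed)
_CLINICAL_RULE_FIELDS = (
    "age_years", "sex", "mmse", "cdr_global", "cdr_memory_box", "etiologic_ad_dx",
)
_NEUROPATH_RULE_FIELDS = ("thal_phase", "braak_stage", "cerad_score")
_FLAG_PREFIXES = ("comorbidity.", "medication.", "copath.")


@dataclass(frozen=True)
class Predicate:
    kind: str
    value: Any = None
    values: frozenset | None = None
    lo: float | None = None
    hi: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in _PREDICATE_KINDS:
            raise ProfileError(f"unknown predicate kind {self.kind!r}")
        if self.kind == "range":
            if self.lo is None or self.hi is None:
                raise ProfileError("range predicate requires lo and hi")
            if self.lo > self.hi:
                raise ProfileError(f"range lo {self.lo} > hi {self.hi}")
        if self.kind == "in_set" and not self.values:
            raise ProfileError("in_set predicate requires a non-empty set")

    def evaluate(self, value: Any) -> bool:
        if self.kind == "equals":
            return value == self.value
        if self.kind == "in_set":
            return value in self.values
        if self.kind == "range":
            return self.lo <= value <= self.hi
        if self.kind == "flag_true":
            return bool(value)
        return not value  # flag_false


@dataclass(frozen=True)
class CriterionRule:
    rule_id: str
    phase: Phase
    field_path: str
    predicate: Predicate
    provenance: str = ""

    def __post_init__(self) -> None:
        bare = self.field_path
        if bare.startswith("neuropath."):
            bare = bare.split(".", 1)[1]
        known = (
            bare in _CLINICAL_RULE_FIELDS
            or bare in _NEUROPATH_RULE_FIELDS
            or self.field_path.startswith(_FLAG_PREFIXES)
        )
        if not known:
            raise ProfileError(f"rule {self.rule_id!r}: unknown field {self.field_path!r}")


@dataclass(frozen=True)
class CriteriaProfile:
    profile_id: str
    inclusion_rules: tuple[CriterionRule, ...]
    exclusion_rules: tuple[CriterionRule, ...]
    amyloid_mode: AmyloidMode = AmyloidMode.PET_EQUIVALENT
    tau_rule_enabled: bool = False
    description: str = ""

    def __post_init__(self) -> None:
        ids = [r.rule_id for r in self.inclusion_rules + self.exclusion_rules]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ProfileError(f"duplicate rule ids in {self.profile_id!r}: {sorted(dupes)}")
        for rule, phase in [(r, Phase.INCLUSION) for r in self.inclusion_rules] + [
            (r, Phase.EXCLUSION) for r in self.exclusion_rules
        ]:
            if rule.phase is not phase:
                raise ProfileError(
                    f"rule {rule.rule_id!r} declared {rule.phase.value} but listed "
                    f"under {phase.value}"
                )

    def with_options(
        self,
        amyloid_mode: AmyloidMode | None = None,
        tau_rule_enabled: bool | None = None,
    ) -> "CriteriaProfile":
        return CriteriaProfile(
            profile_id=self.profile_id,
            inclusion_rules=self.inclusion_rules,
            exclusion_rules=self.exclusion_rules,
            amyloid_mode=self.amyloid_mode if amyloid_mode is None else amyloid_mode,
            tau_rule_enabled=(
                self.tau_rule_enabled if tau_rule_enabled is None else tau_rule_enabled
            ),
            description=self.description,
        )


@dataclass(frozen=True)
class EligibilityTrace:
    participant_id: str
    profile_id: str
    rule_outcomes: Mapping[str, RuleOutcome]
    stage_reached: StageReached
    failing_rule_ids: tuple[str, ...]


# ---------------------------------------------------------------------------
# Profile loading


def _parse_predicate(spec: Mapping[str, Any], rule_id: str) -> Predicate:
    present = [k for k in _PREDICATE_KINDS if k in spec]
    if len(present) != 1:
        raise ProfileError(
            f"rule {rule_id!r}: exactly one predicate required, got {present}"
        )
    kind = present[0]
    body = spec[kind]
    if kind == "equals":
        return Predicate("equals", value=body)
    if kind == "in_set":
        if not isinstance(body, (list, tuple)):
            raise ProfileError(f"rule {rule_id!r}: in_set requires a list")
        return Predicate("in_set", values=frozenset(body))
    if kind == "range":
        if not isinstance(body, Mapping) or "lo" not in body or "hi" not in body:
            raise ProfileError(f"rule {rule_id!r}: range requires lo and hi")
        return Predicate("range", lo=body["lo"], hi=body["hi"])
    return Predicate(kind)  # flag_true / flag_false take no argument


def _parse_rules(raw: Any, phase: Phase) -> tuple[CriterionRule, ...]:
    rules = []
    for spec in raw or []:
        if not isinstance(spec, Mapping) or "rule_id" not in spec or "field" not in spec:
            raise ProfileError(f"{phase.value} rule needs rule_id and field: {spec!r}")
        extra = set(spec) - {"rule_id", "field", "provenance", *_PREDICATE_KINDS}
        if extra:
            raise ProfileError(f"rule {spec['rule_id']!r}: unknown keys {sorted(extra)}")
        rules.append(
            CriterionRule(
                rule_id=str(spec["rule_id"]),
                phase=phase,
                field_path=str(spec["field"]),
                predicate=_parse_predicate(spec, str(spec["rule_id"])),
                provenance=str(spec.get("provenance", "")),
            )
        )
    return tuple(rules)


def load_profile(source: str | Path | Mapping[str, Any]) -> CriteriaProfile:
    """Load a criteria profile from a bundled id, a config file, or a dict."""
    if isinstance(source, Mapping):
        raw = source
    else:
        text = None
        if isinstance(source, str) and source in BUNDLED_PROFILE_IDS:
            text = (
                resources.files("amyelig.data.profiles")
                .joinpath(f"{source}.yaml")
                .read_text(encoding="utf-8")
            )
        else:
            with open(source, encoding="utf-8") as fh:
                text = fh.read()
        raw = yaml.safe_load(text)
    if not isinstance(raw, Mapping) or "profile_id" not in raw:
        raise ProfileError("profile config must be a mapping with a profile_id")
    known = {
        "profile_id", "description", "amyloid_mode", "tau_rule_enabled",
        "inclusion", "exclusion",
    }
    extra = set(raw) - known
    if extra:
        raise ProfileError(f"unknown profile keys: {sorted(extra)}")
    try:
        mode = AmyloidMode(raw.get("amyloid_mode", "pet_equivalent"))
    except ValueError as exc:
        raise ProfileError(str(exc)) from exc
    return CriteriaProfile(
        profile_id=str(raw["profile_id"]),
        inclusion_rules=_parse_rules(raw.get("inclusion"), Phase.INCLUSION),
        exclusion_rules=_parse_rules(raw.get("exclusion"), Phase.EXCLUSION),
        amyloid_mode=mode,
        tau_rule_enabled=bool(raw.get("tau_rule_enabled", False)),
        description=str(raw.get("description", "")),
    )


def bundled_profiles() -> dict[str, CriteriaProfile]:
    return {pid: load_profile(pid) for pid in BUNDLED_PROFILE_IDS}


# ---------------------------------------------------------------------------
# Evaluation

_MISSING = object()


def _resolve_field(
    field_path: str, clinical: ParticipantRecord, neuropath: NeuropathRecord
) -> Any:
    prefix, _, name = field_path.partition(".")
    if prefix == "comorbidity" and name:
        return clinical.comorbidity_flags.get(name, _MISSING)
    if prefix == "medication" and name:
        return clinical.medication_flags.get(name, _MISSING)
    if prefix == "copath" and name:
        state = neuropath.copathology_flags.get(name, _MISSING)
        if state is TriState.NOT_REPORTED:
            return _MISSING
        if isinstance(state, TriState):
            return state is TriState.PRESENT
        return state
    bare = name if prefix == "neuropath" else field_path
    if bare in _NEUROPATH_RULE_FIELDS:
        value = getattr(neuropath, bare)
    else:
        value = getattr(clinical, bare)
    return _MISSING if value is None else value


def evaluate_rule(
    rule: CriterionRule,
    record: tuple[ParticipantRecord, NeuropathRecord],
) -> RuleOutcome:
    """Evaluate one rule on a joined record; missing field -> unevaluable."""
    clinical, neuropath = record
    value = _resolve_field(rule.field_path, clinical, neuropath)
    if value is _MISSING:
        return RuleOutcome.UNEVALUABLE
    return RuleOutcome.PASS if rule.predicate.evaluate(value) else RuleOutcome.FAIL


def _effective_pass(outcome: RuleOutcome, policy: MissingPolicy) -> bool:
    if outcome is RuleOutcome.UNEVALUABLE:
        return policy is MissingPolicy.FAIL_OPEN
    return outcome is RuleOutcome.PASS


def _step_outcome(value: bool | None) -> RuleOutcome:
    if value is None:
        return RuleOutcome.UNEVALUABLE
    return RuleOutcome.PASS if value else RuleOutcome.FAIL


def apply_profile(
    profile: CriteriaProfile,
    cohort: Cohort,
    base: Iterable[str],
    missing_policy: MissingPolicy = MissingPolicy.FAIL_CLOSED,
) -> tuple[list[EligibilityTrace], set[str]]:
    """Apply a profile to every base member; return traces and eligible ids.

    Evaluation order: inclusion rules, amyloid step, tau step (when
    enabled), exclusion rules.  All rules are evaluated for audit
    completeness; ``stage_reached`` records the first failing stage.
    """
    base_ids = sorted(set(base))
    cohort_ids = set(cohort.ids)
    stray = [pid for pid in base_ids if pid not in cohort_ids]
    if stray:
        raise KeyError(f"base ids not in cohort: {stray[:5]}")

    traces: list[EligibilityTrace] = []
    eligible: set[str] = set()
    for pid in base_ids:
        record = cohort.get(pid)
        _, neuropath = record
        outcomes: dict[str, RuleOutcome] = {}
        failing: list[str] = []

        inclusion_ok = True
        for rule in profile.inclusion_rules:
            out = evaluate_rule(rule, record)
            outcomes[rule.rule_id] = out
            if not _effective_pass(out, missing_policy):
                inclusion_ok = False
                failing.append(rule.rule_id)

        amy = _step_outcome(
            amyloid_positive(neuropath.thal_phase, profile.amyloid_mode)
        )
        outcomes[AMYLOID_STEP] = amy
        amyloid_ok = _effective_pass(amy, missing_policy)
        if not amyloid_ok:
            failing.append(AMYLOID_STEP)

        tau_ok = True
        if profile.tau_rule_enabled:
            tau = _step_outcome(tau_intermediate(neuropath.braak_stage))
            outcomes[TAU_STEP] = tau
            tau_ok = _effective_pass(tau, missing_policy)
            if not tau_ok:
                failing.append(TAU_STEP)

        exclusion_ok = True
        for rule in profile.exclusion_rules:
            out = evaluate_rule(rule, record)
            outcomes[rule.rule_id] = out
            if not _effective_pass(out, missing_policy):
                exclusion_ok = False
                failing.append(rule.rule_id)

        if not inclusion_ok:
            stage = StageReached.FAILED_INCLUSION
        elif not amyloid_ok:
            stage = StageReached.FAILED_AMYLOID
        elif not tau_ok:
            stage = StageReached.FAILED_TAU
        elif not exclusion_ok:
            stage = StageReached.FAILED_EXCLUSION
        else:
            stage = StageReached.ELIGIBLE
            eligible.add(pid)

        traces.append(
            EligibilityTrace(
                participant_id=pid,
                profile_id=profile.profile_id,
                rule_outcomes=outcomes,
                stage_reached=stage,
                failing_rule_ids=tuple(failing),
            )
        )
    return traces, eligible


_STAGE_RANK = {
    StageReached.FAILED_INCLUSION: 0,
    StageReached.FAILED_AMYLOID: 1,
    StageReached.FAILED_TAU: 2,
    StageReached.FAILED_EXCLUSION: 3,
    StageReached.ELIGIBLE: 4,
}


@dataclass(frozen=True)
class FunnelCounts:
    """Ordered attrition counts through the staged funnel."""

    profile_id: str
    stages: tuple[tuple[str, int], ...]

    @property
    def counts(self) -> tuple[int, ...]:
        return tuple(count for _, count in self.stages)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(label for label, _ in self.stages)


def funnel_counts(
    profile: CriteriaProfile,
    cohort: Cohort,
    base: Iterable[str],
    missing_policy: MissingPolicy = MissingPolicy.FAIL_CLOSED,
) -> FunnelCounts:
    """Staged counts: base, clinical inclusion, amyloid, (tau,) eligible."""
    traces, _ = apply_profile(profile, cohort, base, missing_policy)
    ranks = [_STAGE_RANK[t.stage_reached] for t in traces]
    stages = [
        ("base", len(traces)),
        ("clinical_inclusion", sum(r >= 1 for r in ranks)),
        ("amyloid_positive", sum(r >= 2 for r in ranks)),
    ]
    if profile.tau_rule_enabled:
        stages.append(("tau_intermediate", sum(r >= 3 for r in ranks)))
    stages.append(("eligible", sum(r >= 4 for r in ranks)))
    return FunnelCounts(profile.profile_id, tuple(stages))
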