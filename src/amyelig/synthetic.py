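"""Synthetic cohort generation with joint clinical-neuropathology structure.

A single latent severity scalar drives Thal, Braak, and CERAD through
monotone threshold maps with independent ordinal jitter.  That shared
scalar is what produces the two conditional facts the analysis relies
on: clinical includees are overwhelmingly amyloid positive (~90%), and
amyloid-positive eligibles almost always carry intermediate/high ABC
pathology (~98-99%).  Independent marginals cannot produce either.

The generator makes no claim to reproduce source-registry counts — only
the conditional proportions used as calibration targets.  Co-pathology
and comorbidity flags are independent Bernoulli draws by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .cohort_io import (
    Cohort,
    NeuropathRecord,
    ParticipantRecord,
    Sex,
    TriState,
)
from .engine import CriteriaProfile, MissingPolicy, StageReached, apply_profile
from .staging import abc_profile, amyloid_positive, has_ad_pathology
from .syndrome import base_population

DEFAULT_COPATHOLOGY_PREVALENCES: dict[str, float] = {
    "lewy_body": 0.52,
    "hippocampal_sclerosis": 0.18,
    "infarcts_lacunes": 0.11,
    "old_hemorrhages": 0.02,
    "ftld_tau": 0.05,
    "ftld_tau_picks": 0.005,
    "other_tauopathy": 0.03,
}

DEFAULT_COMORBIDITY_PREVALENCES: dict[str, float] = {
    "stroke_or_tia": 0.07,
    "seizures": 0.03,
    "unstable_psychiatric": 0.05,
    "bleeding_disorder": 0.02,
    "cancer_active": 0.04,
}

DEFAULT_MEDICATION_PREVALENCES: dict[str, float] = {
    "anticoagulant_use": 0.10,
}

# cdr level distributions by latent affected status
_DEFAULT_CDR_AFFECTED = {0.0: 0.05, 0.5: 0.42, 1.0: 0.33, 2.0: 0.13, 3.0: 0.07}
_DEFAULT_CDR_UNAFFECTED = {0.0: 0.50, 0.5: 0.32, 1.0: 0.12, 2.0: 0.04, 3.0: 0.02}

# memory box conditional on global cdr
_DEFAULT_MEMORY_GIVEN_CDR = {
    0.0: {0.0: 0.90, 0.5: 0.10},
    0.5: {0.0: 0.06, 0.5: 0.74, 1.0: 0.20},
    1.0: {0.5: 0.15, 1.0: 0.70, 2.0: 0.15},
    2.0: {1.0: 0.25, 2.0: 0.60, 3.0: 0.15},
    3.0: {2.0: 0.25, 3.0: 0.75},
}

_DEFAULT_MMSE_MEAN_BY_CDR = {0.0: 28.8, 0.5: 26.3, 1.0: 23.3, 2.0: 17.5, 3.0: 10.0}


class ConfigError(ValueError):
    """Invalid generator configuration (raised before any sampling)."""


@dataclass(frozen=True)
class SyntheticCohortConfig:
    n: int = 1000
    seed: int = 0
    # clinical model
    p_affected: float = 0.80
    cdr_probs_affected: Mapping[float, float] = field(
        default_factory=lambda: dict(_DEFAULT_CDR_AFFECTED)
    )
    cdr_probs_unaffected: Mapping[float, float] = field(
        default_factory=lambda: dict(_DEFAULT_CDR_UNAFFECTED)
    )
    memory_given_cdr: Mapping[float, Mapping[float, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in _DEFAULT_MEMORY_GIVEN_CDR.items()}
    )
    p_ad_dx_affected: float = 0.92
    p_ad_dx_unaffected: float = 0.10
    mmse_mean_by_cdr: Mapping[float, float] = field(
        default_factory=lambda: dict(_DEFAULT_MMSE_MEAN_BY_CDR)
    )
    mmse_sd: float = 2.0
    p_missing_mmse: float = 0.01
    age_mean: float = 76.0
    age_sd: float = 8.0
    age_bounds: tuple[int, int] = (50, 102)
    p_female: float = 0.52
    # latent severity model
    severity_mean_affected: float = 2.90
    severity_sd_affected: float = 1.0
    severity_mean_unaffected: float = 0.0
    severity_sd_unaffected: float = 1.0
    thal_thresholds: Sequence[float] = (0.5, 1.0, 1.5, 2.0, 2.5)
    braak_thresholds: Sequence[float] = (0.4, 0.9, 1.4, 1.9, 2.4, 2.9)
    cerad_thresholds: Sequence[float] = (0.7, 1.5, 2.3)
    ordinal_jitter_p: float = 0.08
    # calibration targets (reported, not enforced per-draw)
    target_p_amyloid_given_inclusion: float = 0.90
    target_p_full_ad_given_eligible: float = 0.98
    # flags
    copathology_prevalences: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COPATHOLOGY_PREVALENCES)
    )
    p_copathology_not_reported: float = 0.01
    comorbidity_prevalences: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COMORBIDITY_PREVALENCES)
    )
    medication_prevalences: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MEDICATION_PREVALENCES)
    )

    def validate(self) -> None:
        if self.n < 0:
            raise ConfigError(f"n must be >= 0, got {self.n}")
        probs = {
            "p_affected": self.p_affected,
            "p_ad_dx_affected": self.p_ad_dx_affected,
            "p_ad_dx_unaffected": self.p_ad_dx_unaffected,
            "p_missing_mmse": self.p_missing_mmse,
            "p_female": self.p_female,
            "ordinal_jitter_p": self.ordinal_jitter_p,
            "p_copathology_not_reported": self.p_copathology_not_reported,
            "target_p_amyloid_given_inclusion": self.target_p_amyloid_given_inclusion,
            "target_p_full_ad_given_eligible": self.target_p_full_ad_given_eligible,
        }
        for mapping, label in (
            (self.copathology_prevalences, "copathology_prevalences"),
            (self.comorbidity_prevalences, "comorbidity_prevalences"),
            (self.medication_prevalences, "medication_prevalences"),
        ):
            for key, value in mapping.items():
                probs[f"{label}[{key}]"] = value
        for name, value in probs.items():
            if not 0.0 <= value <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {value}")
        if self.ordinal_jitter_p > 0.5:
            raise ConfigError("ordinal_jitter_p must be <= 0.5")
        for name, dist in (
            ("cdr_probs_affected", self.cdr_probs_affected),
            ("cdr_probs_unaffected", self.cdr_probs_unaffected),
        ):
            if not math.isclose(sum(dist.values()), 1.0, abs_tol=1e-9):
                raise ConfigError(f"{name} must sum to 1")
        for level, dist in self.memory_given_cdr.items():
            if not math.isclose(sum(dist.values()), 1.0, abs_tol=1e-9):
                raise ConfigError(f"memory_given_cdr[{level}] must sum to 1")
        for name, thresholds in (
            ("thal_thresholds", self.thal_thresholds),
            ("braak_thresholds", self.braak_thresholds),
            ("cerad_thresholds", self.cerad_thresholds),
        ):
            ts = list(thresholds)
            if any(b < a for a, b in zip(ts, ts[1:])):
                raise ConfigError(f"{name} must be weakly increasing")
        expected = {"thal_thresholds": 5, "braak_thresholds": 6, "cerad_thresholds": 3}
        for name, count in expected.items():
            if len(list(getattr(self, name))) != count:
                raise ConfigError(f"{name} must have {count} cut points")
        if self.age_bounds[0] > self.age_bounds[1]:
            raise ConfigError("age_bounds must be ordered")


def _sample_categorical(
    rng: np.random.Generator, dist: Mapping[float, float], size: int
) -> np.ndarray:
    levels = np.array(sorted(dist))
    probs = np.array([dist[lv] for lv in levels])
    probs = probs / probs.sum()
    return rng.choice(levels, size=size, p=probs)


def _ordinal_from_severity(
    rng: np.random.Generator,
    severity: np.ndarray,
    thresholds: Sequence[float],
    jitter_p: float,
) -> np.ndarray:
    cuts = np.asarray(list(thresholds), dtype=float)
    level = (severity[:, None] > cuts[None, :]).sum(axis=1)
    if jitter_p > 0:
        jitter = rng.choice(
            [-1, 0, 1], size=level.shape, p=[jitter_p, 1 - 2 * jitter_p, jitter_p]
        )
        level = level + jitter
    return np.clip(level, 0, len(cuts))


def generate_cohort(
    config: SyntheticCohortConfig, seed: int | None = None
) -> Cohort:
    """Deterministically generate a validated synthetic cohort.

    ``seed`` overrides ``config.seed`` when given.  Every record passes
    ``validate_cohort`` with no special-casing downstream.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n

    affected = rng.random(n) < config.p_affected
    severity = np.where(
        affected,
        rng.normal(config.severity_mean_affected, config.severity_sd_affected, n),
        rng.normal(config.severity_mean_unaffected, config.severity_sd_unaffected, n),
    )

    age = np.clip(
        np.rint(rng.normal(config.age_mean, config.age_sd, n)),
        config.age_bounds[0],
        config.age_bounds[1],
    ).astype(int)
    female = rng.random(n) < config.p_female

    cdr = np.empty(n)
    idx_a = np.flatnonzero(affected)
    idx_u = np.flatnonzero(~affected)
    cdr[idx_a] = _sample_categorical(rng, config.cdr_probs_affected, idx_a.size)
    cdr[idx_u] = _sample_categorical(rng, config.cdr_probs_unaffected, idx_u.size)

    memory = np.empty(n)
    for level, dist in config.memory_given_cdr.items():
        mask = np.flatnonzero(cdr == level)
        if mask.size:
            memory[mask] = _sample_categorical(rng, dist, mask.size)

    ad_dx = rng.random(n) < np.where(
        affected, config.p_ad_dx_affected, config.p_ad_dx_unaffected
    )

    mmse_mean = np.array([config.mmse_mean_by_cdr[lv] for lv in cdr])
    mmse = np.clip(
        np.rint(rng.normal(mmse_mean, config.mmse_sd, n)), 0, 30
    ).astype(int)
    mmse_missing = rng.random(n) < config.p_missing_mmse

    thal = _ordinal_from_severity(
        rng, severity, config.thal_thresholds, config.ordinal_jitter_p
    )
    braak = _ordinal_from_severity(
        rng, severity, config.braak_thresholds, config.ordinal_jitter_p
    )
    cerad = _ordinal_from_severity(
        rng, severity, config.cerad_thresholds, config.ordinal_jitter_p
    )

    comorbidity = {
        key: rng.random(n) < p for key, p in sorted(config.comorbidity_prevalences.items())
    }
    medication = {
        key: rng.random(n) < p for key, p in sorted(config.medication_prevalences.items())
    }
    copath_present = {
        key: rng.random(n) < p for key, p in sorted(config.copathology_prevalences.items())
    }
    copath_nr = {
        key: rng.random(n) < config.p_copathology_not_reported
        for key in sorted(config.copathology_prevalences)
    }

    records = []
    for i in range(n):
        pid = f"SYN{i:06d}"
        clinical = ParticipantRecord(
            participant_id=pid,
            age_years=int(age[i]),
            sex=Sex.FEMALE if female[i] else Sex.MALE,
            mmse=None if mmse_missing[i] else int(mmse[i]),
            cdr_global=float(cdr[i]),
            cdr_memory_box=float(memory[i]),
            etiologic_ad_dx=bool(ad_dx[i]),
            comorbidity_flags={k: bool(v[i]) for k, v in comorbidity.items()},
            medication_flags={k: bool(v[i]) for k, v in medication.items()},
        )
        copath = {}
        for key in copath_present:
            if copath_nr[key][i]:
                copath[key] = TriState.NOT_REPORTED
            elif copath_present[key][i]:
                copath[key] = TriState.PRESENT
            else:
                copath[key] = TriState.ABSENT
        neuropath = NeuropathRecord(
            participant_id=pid,
            thal_phase=int(thal[i]),
            braak_stage=int(braak[i]),
            cerad_score=int(cerad[i]),
            copathology_flags=copath,
        )
        records.append((clinical, neuropath))

    return Cohort(records=records, provenance=f"synthetic(seed={config.seed if seed is None else seed}, n={n})")


# ---------------------------------------------------------------------------
# Calibration reporting


@dataclass(frozen=True)
class CalibrationRow:
    metric: str
    profile_id: str
    target: float | None
    realized: float | None
    n: int
    tolerance_3se: float | None
    within: bool | None
    comparison: str = "two_sided"  # or "floor": exceeding the target is fine


def _row(
    metric: str,
    profile_id: str,
    target: float | None,
    count: int,
    denom: int,
    comparison: str = "two_sided",
) -> CalibrationRow:
    realized = count / denom if denom else None
    if target is None or realized is None:
        return CalibrationRow(
            metric, profile_id, target, realized, denom, None, None, comparison
        )
    se3 = 3.0 * math.sqrt(max(target * (1.0 - target), 0.0) / denom)
    if comparison == "floor":
        within = realized >= target - se3
    else:
        within = abs(realized - target) <= se3
    return CalibrationRow(
        metric, profile_id, target, realized, denom, se3, within, comparison
    )


def calibration_report(
    cohort: Cohort,
    profiles: Sequence[CriteriaProfile],
    config: SyntheticCohortConfig,
    missing_policy: MissingPolicy = MissingPolicy.FAIL_CLOSED,
) -> list[CalibrationRow]:
    """Realized vs configured conditional proportions, with 3-SE bands.

    Per profile: P(amyloid positive | clinical inclusion) and
    P(full AD pathology | eligible).  Co-pathology prevalences and the
    CDR-0.5 share are reported on the first profile's eligible set.
    """
    base = base_population(cohort)
    rows: list[CalibrationRow] = []
    first_eligible: set[str] | None = None
    for profile in profiles:
        traces, eligible = apply_profile(profile, cohort, base, missing_policy)
        included = [
            t.participant_id
            for t in traces
            if t.stage_reached is not StageReached.FAILED_INCLUSION
        ]
        n_amy = 0
        for pid in included:
            _, neuro = cohort.get(pid)
            if amyloid_positive(neuro.thal_phase, profile.amyloid_mode):
                n_amy += 1
        rows.append(
            _row(
                "p_amyloid_given_inclusion",
                profile.profile_id,
                config.target_p_amyloid_given_inclusion,
                n_amy,
                len(included),
            )
        )
        n_full = 0
        for pid in eligible:
            _, neuro = cohort.get(pid)
            prof = abc_profile(neuro.thal_phase, neuro.braak_stage, neuro.cerad_score)
            if prof is not None and has_ad_pathology(prof.summary):
                n_full += 1
        rows.append(
            _row(
                "p_full_ad_given_eligible",
                profile.profile_id,
                config.target_p_full_ad_given_eligible,
                n_full,
                len(eligible),
                comparison="floor",
            )
        )
        if first_eligible is None:
            first_eligible = eligible

    if profiles and first_eligible is not None:
        pid0 = profiles[0].profile_id
        members = sorted(first_eligible)
        for key, target in sorted(config.copathology_prevalences.items()):
            present = 0
            for pid in members:
                _, neuro = cohort.get(pid)
                if neuro.copathology_flags.get(key) is TriState.PRESENT:
                    present += 1
            rows.append(
                _row(f"copathology[{key}]", pid0, target, present, len(members))
            )
        n_half = sum(
            1 for pid in members if cohort.get(pid)[0].cdr_global == 0.5
        )
        rows.append(_row("cdr_half_share", pid0, None, n_half, len(members)))
    return rows
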