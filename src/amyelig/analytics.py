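"""Reporting analytics: funnel reports, set overlaps, co-pathology tables.

Percent convention throughout: nearest integer, halves rounded away from
zero.  The "% of the full sample" denominator is always the
amnestic-syndrome base population, carried as a named denominator so it
cannot silently be swapped for the autopsy cohort.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

from .cohort_io import Cohort, COPATHOLOGY_KEYS, TriState
from .staging import ABCMatrix, abc_profile, default_matrix, has_ad_pathology

FULL_SAMPLE = "full_sample"


def percent_int(numerator: int, denominator: int) -> int | None:
    """Integer percent, halves away from zero; ``None`` when undefined."""
    if denominator == 0:
        return None
    if numerator < 0 or denominator < 0:
        raise ValueError("counts must be non-negative")
    # exact integer arithmetic: floor(100*n/d + 1/2)
    return (200 * numerator + denominator) // (2 * denominator)


# ---------------------------------------------------------------------------
# Funnel report


@dataclass(frozen=True)
class FunnelStage:
    label: str
    count: int
    percent_of_previous: int | None
    percent_of: dict[str, int | None] = field(default_factory=dict)


@dataclass(frozen=True)
class FunnelReport:
    profile_id: str
    stages: tuple[FunnelStage, ...]
    denominators: dict[str, int]

    def stage(self, label: str) -> FunnelStage:
        for s in self.stages:
            if s.label == label:
                return s
        raise KeyError(label)

    def to_rows(self) -> list[dict[str, object]]:
        rows = []
        for s in self.stages:
            row: dict[str, object] = {
                "profile_id": self.profile_id,
                "stage": s.label,
                "count": s.count,
                "percent_of_previous": s.percent_of_previous,
            }
            for name, pct in s.percent_of.items():
                row[f"percent_of_{name}"] = pct
            rows.append(row)
        return rows

    def to_json(self) -> str:
        return json.dumps(self.to_rows(), indent=2, sort_keys=True)


def build_funnel_report(
    counts: Sequence[tuple[str, int]] | "FunnelCountsLike",
    denominators: Mapping[str, int],
    profile_id: str = "",
) -> FunnelReport:
    """Annotate ordered stage counts with the printed percent conventions.

    Each stage after the first carries percent-of-previous-stage and a
    percent against every named denominator.  Non-monotone counts signal
    an engine bug and raise ``ValueError``.
    """
    if hasattr(counts, "stages"):
        profile_id = profile_id or getattr(counts, "profile_id", "")
        counts = counts.stages
    pairs = [(str(label), int(count)) for label, count in counts]
    values = [count for _, count in pairs]
    if any(b > a for a, b in zip(values, values[1:])):
        raise ValueError(f"funnel counts must be weakly decreasing: {values}")
    if any(v < 0 for v in values):
        raise ValueError("funnel counts must be non-negative")

    stages = []
    previous: int | None = None
    for label, count in pairs:
        stages.append(
            FunnelStage(
                label=label,
                count=count,
                percent_of_previous=(
                    None if previous is None else percent_int(count, previous)
                ),
                percent_of={
                    name: percent_int(count, den) if previous is not None else None
                    for name, den in denominators.items()
                },
            )
        )
        previous = count
    return FunnelReport(profile_id, tuple(stages), dict(denominators))


# ---------------------------------------------------------------------------
# Set overlap (Euler regions)


@dataclass(frozen=True)
class OverlapSet:
    """Exact region counts of the membership-signature partition."""

    profile_ids: tuple[str, ...]
    region_counts: dict[frozenset, int]

    @property
    def union_size(self) -> int:
        return sum(self.region_counts.values())

    def marginal(self, profile_id: str) -> int:
        return sum(
            count for sig, count in self.region_counts.items() if profile_id in sig
        )


def euler_regions(eligible_sets: Mapping[str, Iterable[str]]) -> OverlapSet:
    """Partition the union of 1-5 id-sets by exact membership signature."""
    names = tuple(eligible_sets)
    if not 1 <= len(names) <= 5:
        raise ValueError("euler_regions supports 1-5 sets")
    sets = {name: set(ids) for name, ids in eligible_sets.items()}
    regions: dict[frozenset, int] = {
        frozenset(combo): 0
        for r in range(1, len(names) + 1)
        for combo in combinations(names, r)
    }
    union = set().union(*sets.values())
    for member in union:
        signature = frozenset(name for name in names if member in sets[name])
        regions[signature] += 1
    return OverlapSet(names, regions)


# ---------------------------------------------------------------------------
# Group composition tables


@dataclass(frozen=True)
class PrevalenceRow:
    copathology: str
    present: int
    absent: int
    not_reported: int
    percent_present: int | None


@dataclass(frozen=True)
class PrevalenceTable:
    group_label: str
    group_size: int
    rows: tuple[PrevalenceRow, ...]

    def row(self, copathology: str) -> PrevalenceRow:
        for r in self.rows:
            if r.copathology == copathology:
                return r
        raise KeyError(copathology)


def copathology_prevalence(
    group: Iterable[str],
    cohort: Cohort,
    *,
    group_label: str = "",
    keys: Sequence[str] = COPATHOLOGY_KEYS,
    complete_case: bool = False,
) -> PrevalenceTable:
    """Per-co-pathology counts and percent present within a group.

    not_reported states are never imputed: by default they stay in the
    denominator (percent of group); ``complete_case=True`` restricts the
    denominator to reported states for sensitivity analysis.
    """
    members = sorted(set(group))
    rows = []
    for key in keys:
        present = absent = not_reported = 0
        for pid in members:
            _, neuro = cohort.get(pid)
            state = neuro.copathology_flags.get(key, TriState.NOT_REPORTED)
            if state is TriState.PRESENT:
                present += 1
            elif state is TriState.ABSENT:
                absent += 1
            else:
                not_reported += 1
        denominator = present + absent if complete_case else len(members)
        rows.append(
            PrevalenceRow(key, present, absent, not_reported,
                          percent_int(present, denominator))
        )
    return PrevalenceTable(group_label, len(members), tuple(rows))


@dataclass(frozen=True)
class CdrComposition:
    group_size: int
    n_cdr_half: int
    n_missing: int
    percent_cdr_half: int | None


def cdr_composition(group: Iterable[str], cohort: Cohort) -> CdrComposition:
    """Share of a group at global CDR 0.5; missing CDR counted separately."""
    members = sorted(set(group))
    n_half = n_missing = 0
    for pid in members:
        clin, _ = cohort.get(pid)
        if clin.cdr_global is None:
            n_missing += 1
        elif clin.cdr_global == 0.5:
            n_half += 1
    return CdrComposition(
        group_size=len(members),
        n_cdr_half=n_half,
        n_missing=n_missing,
        percent_cdr_half=percent_int(n_half, len(members)),
    )


@dataclass(frozen=True)
class AdPathologyShare:
    group_size: int
    n_full_ad: int
    n_missing_staging: int
    percent_full_ad: int | None


def full_ad_pathology_share(
    group: Iterable[str], cohort: Cohort, matrix: ABCMatrix | None = None
) -> AdPathologyShare:
    """Count and percent of a group with intermediate/high ABC summary."""
    m = matrix or default_matrix()
    members = sorted(set(group))
    n_full = n_missing = 0
    for pid in members:
        _, neuro = cohort.get(pid)
        profile = abc_profile(
            neuro.thal_phase, neuro.braak_stage, neuro.cerad_score, m
        )
        if profile is None:
            n_missing += 1
        elif has_ad_pathology(profile.summary):
            n_full += 1
    return AdPathologyShare(
        group_size=len(members),
        n_full_ad=n_full,
        n_missing_staging=n_missing,
        percent_full_ad=percent_int(n_full, len(members)),
    )
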