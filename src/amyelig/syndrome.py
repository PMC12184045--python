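"""Baseline amnestic-AD-syndrome classification.

The base population for every eligibility analysis: participants with
(i) a global CDR of 0.5 (MCI) or 1 (mild dementia), (ii) at least mild
memory impairment on the CDR memory box, and (iii) a clinician rating of
AD as the most likely etiology.  Missing required fields fail closed —
a syndrome that cannot be confirmed does not enter the base population.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from .cohort_io import Cohort, ParticipantRecord


class SyndromeStage(str, Enum):
    MCI = "mci"
    MILD_DEMENTIA = "mild_dementia"
    NOT_APPLICABLE = "not_applicable"


#: component labels recorded when classification fails
CDR_STAGE = "cdr_stage"
MEMORY_IMPAIRMENT = "memory_impairment"
ETIOLOGIC_DX = "etiologic_dx"
MISSING_DATA = "missing_data"


@dataclass(frozen=True)
class SyndromeResult:
    participant_id: str
    is_amnestic_ad: bool
    stage: SyndromeStage
    failed_components: frozenset[str]


def classify_syndrome(
    record: ParticipantRecord, memory_threshold: float = 0.5
) -> SyndromeResult:
    """Classify one validated baseline record.

    ``memory_threshold`` is the minimal CDR memory box level counting as
    "at least mild memory impairment" (default 0.5, questionable-or-worse).
    """
    failed: set[str] = set()

    if record.cdr_global is None:
        failed.add(MISSING_DATA)
        stage = SyndromeStage.NOT_APPLICABLE
    else:
        if record.cdr_global == 0.5:
            stage = SyndromeStage.MCI
        elif record.cdr_global == 1.0:
            stage = SyndromeStage.MILD_DEMENTIA
        else:
            stage = SyndromeStage.NOT_APPLICABLE
            failed.add(CDR_STAGE)

    if record.cdr_memory_box is None:
        failed.add(MISSING_DATA)
    elif record.cdr_memory_box < memory_threshold:
        failed.add(MEMORY_IMPAIRMENT)

    if record.etiologic_ad_dx is None:
        failed.add(MISSING_DATA)
    elif not record.etiologic_ad_dx:
        failed.add(ETIOLOGIC_DX)

    return SyndromeResult(
        participant_id=record.participant_id,
        is_amnestic_ad=not failed,
        stage=stage,
        failed_components=frozenset(failed),
    )


def base_population(cohort: Cohort, memory_threshold: float = 0.5) -> set[str]:
    """Ids of all amnestic-AD-syndrome participants.

    This set is the denominator for every percent-of-full-sample figure.
    """
    return {
        clin.participant_id
        for clin, _ in cohort
        if classify_syndrome(clin, memory_threshold).is_amnestic_ad
    }
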