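"""NIA-AA ABC neuropathologic staging and amyloid/tau operationalizations.

A (from Thal amyloid phase), B (from Braak tangle stage) and C (from the
CERAD neuritic plaque score) are each binned to 0-3 and combined by a
lookup matrix into the four-level summary not/low/intermediate/high.
The matrix and binnings ship as an editable data file transcribed from
the 2012 NIA-AA guideline; the loader verifies completeness (64 cells)
and the structural invariants (A0 forces "not"; monotone in each score).

Missing inputs propagate as ``None`` — resolution of missingness is an
eligibility-layer policy, never a staging guess.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from functools import lru_cache
from importlib import resources
from pathlib import Path

import yaml


class ABCSummary(str, Enum):
    NOT = "not"
    LOW = "low"
    INTERMEDIATE = "intermediate"
    HIGH = "high"


#: rank order used for monotonicity checks and reporting
SUMMARY_ORDER = (
    ABCSummary.NOT,
    ABCSummary.LOW,
    ABCSummary.INTERMEDIATE,
    ABCSummary.HIGH,
)


class AmyloidMode(str, Enum):
    """Amyloid-positivity operationalization for an analysis run.

    ``PET_EQUIVALENT``: Thal phase 3-5 corresponds to a positive amyloid
    PET in life.  ``ANY_AMYLOID``: any amyloid at autopsy (Thal > 0), the
    wider sensitivity definition.
    """

    PET_EQUIVALENT = "pet_equivalent"
    ANY_AMYLOID = "any_amyloid"


@dataclass(frozen=True)
class ABCProfile:
    a_score: int
    b_score: int
    c_score: int
    summary: ABCSummary


class StagingError(ValueError):
    """Out-of-range staging input or malformed matrix file."""


@dataclass(frozen=True)
class ABCMatrix:
    """Validated A/B/C binnings plus the 4x4x4 summary lookup."""

    a_from_thal: dict[int, int]
    b_from_braak: dict[int, int]
    c_from_cerad: dict[int, int]
    summary_cells: dict[tuple[int, int, int], ABCSummary]
    version: str = ""

    def __post_init__(self) -> None:
        for name, mapping, domain in (
            ("a_from_thal", self.a_from_thal, range(6)),
            ("b_from_braak", self.b_from_braak, range(7)),
            ("c_from_cerad", self.c_from_cerad, range(4)),
        ):
            if sorted(mapping) != list(domain):
                raise StagingError(f"{name}: domain must be {list(domain)}")
            values = [mapping[k] for k in sorted(mapping)]
            if any(v not in range(4) for v in values):
                raise StagingError(f"{name}: scores must lie in 0-3")
            if any(b < a for a, b in zip(values, values[1:])):
                raise StagingError(f"{name}: binning must be weakly increasing")
            if set(values) != {0, 1, 2, 3}:
                raise StagingError(f"{name}: binning must be surjective onto 0-3")
        cells = self.summary_cells
        expected = {(a, b, c) for a in range(4) for b in range(4) for c in range(4)}
        if set(cells) != expected:
            raise StagingError(
                f"summary matrix must define all 64 cells, got {len(cells)}"
            )
        rank = {level: i for i, level in enumerate(SUMMARY_ORDER)}
        for (a, b, c), level in cells.items():
            if a == 0 and level is not ABCSummary.NOT:
                raise StagingError(f"cell (0,{b},{c}) must be 'not', got {level.value}")
        for a, b, c in expected:
            here = rank[cells[(a, b, c)]]
            for da, db, dc in ((1, 0, 0), (0, 1, 0), (0, 0, 1)):
                nxt = (a + da, b + db, c + dc)
                if nxt in cells and rank[cells[nxt]] < here:
                    raise StagingError(
                        f"summary matrix not monotone at {(a, b, c)} -> {nxt}"
                    )


def load_abc_matrix(path: str | Path | None = None) -> ABCMatrix:
    """Load and validate an ABC matrix file (bundled file by default)."""
    if path is None:
        source = resources.files("amyelig.data").joinpath("abc_matrix.yaml")
        raw = yaml.safe_load(source.read_text(encoding="utf-8"))
    else:
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
    try:
        cells = {
            (int(cell["a"]), int(cell["b"]), int(cell["c"])): ABCSummary(cell["level"])
            for cell in raw["summary_cells"]
        }
        return ABCMatrix(
            a_from_thal={int(k): int(v) for k, v in raw["a_from_thal"].items()},
            b_from_braak={int(k): int(v) for k, v in raw["b_from_braak"].items()},
            c_from_cerad={int(k): int(v) for k, v in raw["c_from_cerad"].items()},
            summary_cells=cells,
            version=str(raw.get("version", "")),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise StagingError(f"malformed ABC matrix file: {exc}") from exc


@lru_cache(maxsize=1)
def default_matrix() -> ABCMatrix:
    return load_abc_matrix()


def _check_range(name: str, value: int, lo: int, hi: int) -> None:
    if not isinstance(value, int) or not lo <= value <= hi:
        raise StagingError(f"{name} must be an integer in [{lo}, {hi}], got {value!r}")


def a_score(thal_phase: int | None, matrix: ABCMatrix | None = None) -> int | None:
    if thal_phase is None:
        return None
    _check_range("thal_phase", thal_phase, 0, 5)
    return (matrix or default_matrix()).a_from_thal[thal_phase]


def b_score(braak_stage: int | None, matrix: ABCMatrix | None = None) -> int | None:
    if braak_stage is None:
        return None
    _check_range("braak_stage", braak_stage, 0, 6)
    return (matrix or default_matrix()).b_from_braak[braak_stage]


def c_score(cerad: int | None, matrix: ABCMatrix | None = None) -> int | None:
    if cerad is None:
        return None
    _check_range("cerad_score", cerad, 0, 3)
    return (matrix or default_matrix()).c_from_cerad[cerad]


def abc_summary(
    a: int | None, b: int | None, c: int | None, matrix: ABCMatrix | None = None
) -> ABCSummary | None:
    """Four-level summary from A/B/C scores; missing inputs propagate."""
    if a is None or b is None or c is None:
        return None
    for name, value in (("a_score", a), ("b_score", b), ("c_score", c)):
        _check_range(name, value, 0, 3)
    return (matrix or default_matrix()).summary_cells[(a, b, c)]


def abc_profile(
    thal_phase: int | None,
    braak_stage: int | None,
    cerad: int | None,
    matrix: ABCMatrix | None = None,
) -> ABCProfile | None:
    """Full staging from raw Thal/Braak/CERAD; ``None`` if any input missing."""
    m = matrix or default_matrix()
    a = a_score(thal_phase, m)
    b = b_score(braak_stage, m)
    c = c_score(cerad, m)
    summary = abc_summary(a, b, c, m)
    if summary is None:
        return None
    return ABCProfile(a, b, c, summary)


def has_ad_pathology(summary: ABCSummary | None) -> bool | None:
    """Intermediate/high summary counts as the presence of AD pathology."""
    if summary is None:
        return None
    return summary in (ABCSummary.INTERMEDIATE, ABCSummary.HIGH)


def amyloid_positive(
    thal_phase: int | None, mode: AmyloidMode = AmyloidMode.PET_EQUIVALENT
) -> bool | None:
    if thal_phase is None:
        return None
    _check_range("thal_phase", thal_phase, 0, 5)
    if mode is AmyloidMode.PET_EQUIVALENT:
        return thal_phase >= 3
    return thal_phase >= 1


def tau_intermediate(braak_stage: int | None) -> bool | None:
    """Intermediate tau spread: Braak stage 3 or 4."""
    if braak_stage is None:
        return None
    _check_range("braak_stage", braak_stage, 0, 6)
    return braak_stage in (3, 4)
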