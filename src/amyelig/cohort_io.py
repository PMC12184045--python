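"""Harmonized participant data model and delimited-text cohort I/O.

A cohort joins one clinical baseline record and one autopsy record per
participant.  Files are plain delimited text (comma by default, tab
selectable) with a header row; a :class:`Codebook` translates source
dialects (column names, coded values, numeric missing codes) into the
canonical schema.  Missing values are ``None`` in memory and a single
configurable token (default: empty field) on disk.
"""

from __future__ import annotations

import csv
import datetime as _dt
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Any, Iterator, Mapping

import yaml

CDR_LEVELS = (0.0, 0.5, 1.0, 2.0, 3.0)

COPATHOLOGY_KEYS = (
    "lewy_body",
    "hippocampal_sclerosis",
    "infarcts_lacunes",
    "old_hemorrhages",
    "ftld_tau",
    "ftld_tau_picks",
    "other_tauopathy",
)

#: canonical scalar columns of the clinical table, in file order
CLINICAL_FIELDS = (
    "participant_id",
    "age_years",
    "sex",
    "mmse",
    "cdr_global",
    "cdr_memory_box",
    "etiologic_ad_dx",
    "baseline_date",
)

#: canonical scalar columns of the neuropathology table, in file order
NEUROPATH_FIELDS = (
    "participant_id",
    "thal_phase",
    "braak_stage",
    "cerad_score",
    "death_date",
)


class Sex(str, Enum):
    FEMALE = "female"
    MALE = "male"
    OTHER_UNKNOWN = "other_unknown"


class TriState(str, Enum):
    """State of a co-pathology finding in the autopsy report."""

    PRESENT = "present"
    ABSENT = "absent"
    NOT_REPORTED = "not_reported"


class CohortError(Exception):
    """Hard error while reading, writing, or joining cohort tables."""


class CodebookError(CohortError):
    """Codebook is malformed or inconsistent with the source table."""


@dataclass(frozen=True)
class Violation:
    """One record-level invariant violation (report entry, not an exception)."""

    participant_id: str
    field: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.participant_id}: {self.field}: {self.message}"


class ValidationError(CohortError):
    def __init__(self, violations: list[Violation]):
        self.violations = violations
        lines = "; ".join(str(v) for v in violations[:10])
        more = "" if len(violations) <= 10 else f" (+{len(violations) - 10} more)"
        super().__init__(f"{len(violations)} validation violation(s): {lines}{more}")


@dataclass
class ParticipantRecord:
    """One person's baseline clinical measurements and flags."""

    participant_id: str
    age_years: int | None = None
    sex: Sex = Sex.OTHER_UNKNOWN
    mmse: int | None = None
    cdr_global: float | None = None
    cdr_memory_box: float | None = None
    etiologic_ad_dx: bool | None = None
    comorbidity_flags: dict[str, bool] = field(default_factory=dict)
    medication_flags: dict[str, bool] = field(default_factory=dict)
    baseline_date: _dt.date | None = None


@dataclass
class NeuropathRecord:
    """One person's autopsy staging scores and co-pathology flags."""

    participant_id: str
    thal_phase: int | None = None
    braak_stage: int | None = None
    cerad_score: int | None = None
    copathology_flags: dict[str, TriState] = field(default_factory=dict)
    death_date: _dt.date | None = None


@dataclass
class Cohort:
    """Clinical and neuropathology records joined 1:1 on participant id.

    ``unmatched_clinical`` / ``unmatched_neuropath`` report ids present in
    only one source table; the join never drops them silently.
    """

    records: list[tuple[ParticipantRecord, NeuropathRecord]]
    provenance: str = ""
    unmatched_clinical: tuple[str, ...] = ()
    unmatched_neuropath: tuple[str, ...] = ()
    violations: list[Violation] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[tuple[ParticipantRecord, NeuropathRecord]]:
        return iter(self.records)

    @property
    def ids(self) -> list[str]:
        return [c.participant_id for c, _ in self.records]

    def get(self, participant_id: str) -> tuple[ParticipantRecord, NeuropathRecord]:
        try:
            return self._index[participant_id]
        except AttributeError:
            self._index = {c.participant_id: (c, n) for c, n in self.records}
            return self._index[participant_id]


# ---------------------------------------------------------------------------
# Codebook


@dataclass
class TableCodebook:
    """Column and value translation for one source table.

    ``column_map`` maps canonical names (scalar fields, plus dotted flag
    names like ``comorbidity.stroke_or_tia`` or ``copath.lewy_body``) to
    source column names.  Canonical fields absent from the map are treated
    as declared-absent and read as missing.  ``value_map`` maps source
    tokens to canonical values per field; ``None`` marks a missing code.
    """

    column_map: dict[str, str]
    value_map: dict[str, dict[str, Any]] = field(default_factory=dict)

    def source_column(self, canonical: str) -> str | None:
        return self.column_map.get(canonical)

    def translate(self, canonical: str, token: str) -> Any:
        vmap = self.value_map.get(canonical)
        if vmap is not None and token in vmap:
            return vmap[token]
        return token


@dataclass
class Codebook:
    clinical: TableCodebook
    neuropath: TableCodebook
    missing_tokens: tuple[str, ...] = ("",)

    @classmethod
    def identity(cls) -> "Codebook":
        """Codebook for tables already in the canonical dialect.

        Column discovery is by header: canonical scalar names plus any
        ``comorbidity.*`` / ``medication.*`` / ``copath.*`` columns.
        """
        return cls(TableCodebook({}, {}), TableCodebook({}, {}))

    @classmethod
    def from_file(cls, path: str | Path) -> "Codebook":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, Mapping):
            raise CodebookError(f"codebook {path} is not a mapping")
        tables = {}
        for key in ("clinical", "neuropath"):
            spec = raw.get(key) or {}
            columns = {str(k): str(v) for k, v in (spec.get("columns") or {}).items()}
            values = {
                str(fld): {str(tok): val for tok, val in (vm or {}).items()}
                for fld, vm in (spec.get("values") or {}).items()
            }
            if columns and "participant_id" not in columns:
                raise CodebookError(
                    f"codebook table '{key}' must map participant_id"
                )
            tables[key] = TableCodebook(columns, values)
        missing = tuple(str(t) for t in raw.get("missing_tokens", [""]))
        return cls(tables["clinical"], tables["neuropath"], missing or ("",))


# ---------------------------------------------------------------------------
# Value parsing

_BOOL_TOKENS = {
    "true": True, "1": True, "yes": True,
    "false": False, "0": False, "no": False,
}


def _parse_int(value: Any) -> int:
    if isinstance(value, bool):
        raise ValueError("expected integer, got boolean")
    if isinstance(value, int):
        return value
    if isinstance(value, float) and value.is_integer():
        return int(value)
    return int(str(value).strip())


def _parse_cdr(value: Any) -> float:
    v = float(value) if not isinstance(value, str) else float(value.strip())
    return v


def _parse_bool(value: Any) -> bool:
    if isinstance(value, bool):
        return value
    token = str(value).strip().lower()
    if token in _BOOL_TOKENS:
        return _BOOL_TOKENS[token]
    raise ValueError(f"not a boolean token: {value!r}")


def _parse_sex(value: Any) -> Sex:
    if isinstance(value, Sex):
        return value
    return Sex(str(value).strip().lower())


def _parse_date(value: Any) -> _dt.date:
    if isinstance(value, _dt.date):
        return value
    return _dt.date.fromisoformat(str(value).strip())


def _parse_tristate(value: Any) -> TriState:
    if isinstance(value, TriState):
        return value
    return TriState(str(value).strip().lower())


_CLINICAL_PARSERS = {
    "age_years": _parse_int,
    "sex": _parse_sex,
    "mmse": _parse_int,
    "cdr_global": _parse_cdr,
    "cdr_memory_box": _parse_cdr,
    "etiologic_ad_dx": _parse_bool,
    "baseline_date": _parse_date,
}

_NEUROPATH_PARSERS = {
    "thal_phase": _parse_int,
    "braak_stage": _parse_int,
    "cerad_score": _parse_int,
    "death_date": _parse_date,
}


# ---------------------------------------------------------------------------
# Reading


def _read_table(
    path: str | Path,
    table_cb: TableCodebook,
    missing_tokens: tuple[str, ...],
    scalar_fields: tuple[str, ...],
    parsers: Mapping[str, Any],
    flag_prefixes: tuple[str, ...],
    delimiter: str,
) -> tuple[list[dict[str, Any]], list[Violation]]:
    path = Path(path)
    if not path.exists():
        raise CohortError(f"table not found: {path}")
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        header = reader.fieldnames or []
        if table_cb.column_map:
            field_to_col = dict(table_cb.column_map)
            for canonical, col in field_to_col.items():
                if col not in header:
                    raise CodebookError(
                        f"{path.name}: mapped column {col!r} for field "
                        f"{canonical!r} not in header"
                    )
        else:
            field_to_col = {f: f for f in scalar_fields if f in header}
            for col in header:
                if col.startswith(flag_prefixes):
                    field_to_col[col] = col
        if "participant_id" not in field_to_col:
            raise CohortError(f"{path.name}: no participant_id column")

        rows: list[dict[str, Any]] = []
        violations: list[Violation] = []
        for raw in reader:
            row: dict[str, Any] = {}
            pid = (raw.get(field_to_col["participant_id"]) or "").strip()
            row["participant_id"] = pid
            for canonical, col in field_to_col.items():
                if canonical == "participant_id":
                    continue
                token = raw.get(col)
                token = "" if token is None else token.strip()
                value = table_cb.translate(canonical, token)
                if isinstance(value, str) and value in missing_tokens:
                    value = None
                if value is None:
                    row[canonical] = None
                    continue
                parser = parsers.get(canonical)
                if parser is None and canonical.partition(".")[0] in (
                    "comorbidity",
                    "medication",
                ):
                    parser = _parse_bool
                elif parser is None and canonical.startswith("copath."):
                    parser = _parse_tristate
                try:
                    row[canonical] = parser(value) if parser else value
                except (ValueError, KeyError):
                    violations.append(
                        Violation(pid, canonical, f"unparseable value {value!r}")
                    )
                    row[canonical] = None
            rows.append(row)
    return rows, violations


def _row_to_clinical(row: Mapping[str, Any]) -> ParticipantRecord:
    comorbidity = {}
    medication = {}
    for key, value in row.items():
        prefix, _, name = key.partition(".")
        if prefix == "comorbidity" and name:
            if value is not None:
                comorbidity[name] = value
        elif prefix == "medication" and name:
            if value is not None:
                medication[name] = value
    return ParticipantRecord(
        participant_id=row["participant_id"],
        age_years=row.get("age_years"),
        sex=row.get("sex") or Sex.OTHER_UNKNOWN,
        mmse=row.get("mmse"),
        cdr_global=row.get("cdr_global"),
        cdr_memory_box=row.get("cdr_memory_box"),
        etiologic_ad_dx=row.get("etiologic_ad_dx"),
        comorbidity_flags=comorbidity,
        medication_flags=medication,
        baseline_date=row.get("baseline_date"),
    )


def _row_to_neuropath(row: Mapping[str, Any]) -> NeuropathRecord:
    copath = {}
    for key, value in row.items():
        prefix, _, name = key.partition(".")
        if prefix == "copath" and name:
            copath[name] = value if value is not None else TriState.NOT_REPORTED
    return NeuropathRecord(
        participant_id=row["participant_id"],
        thal_phase=row.get("thal_phase"),
        braak_stage=row.get("braak_stage"),
        cerad_score=row.get("cerad_score"),
        copathology_flags=copath,
        death_date=row.get("death_date"),
    )


def read_cohort(
    clinical_table: str | Path,
    neuropath_table: str | Path,
    codebook: Codebook | None = None,
    *,
    delimiter: str = ",",
    provenance: str = "",
    strict: bool = True,
) -> Cohort:
    """Read, translate, join, and validate a two-table cohort.

    Hard errors (missing id column, duplicated ids, codebook/table
    mismatch) raise :class:`CohortError`.  Record-level invariant
    violations raise :class:`ValidationError` under ``strict=True`` and
    are otherwise collected on ``Cohort.violations``.
    """
    cb = codebook or Codebook.identity()
    clin_rows, v1 = _read_table(
        clinical_table, cb.clinical, cb.missing_tokens, CLINICAL_FIELDS,
        _CLINICAL_PARSERS, ("comorbidity.", "medication."), delimiter,
    )
    np_rows, v2 = _read_table(
        neuropath_table, cb.neuropath, cb.missing_tokens, NEUROPATH_FIELDS,
        _NEUROPATH_PARSERS, ("copath.",), delimiter,
    )

    for name, rows in (("clinical", clin_rows), ("neuropath", np_rows)):
        seen: set[str] = set()
        for row in rows:
            pid = row["participant_id"]
            if not pid:
                raise CohortError(f"{name} table: empty participant_id")
            if pid in seen:
                raise CohortError(f"{name} table: duplicate participant_id {pid!r}")
            seen.add(pid)

    clinical = {r["participant_id"]: _row_to_clinical(r) for r in clin_rows}
    neuropath = {r["participant_id"]: _row_to_neuropath(r) for r in np_rows}
    shared = [pid for pid in clinical if pid in neuropath]
    cohort = Cohort(
        records=[(clinical[pid], neuropath[pid]) for pid in shared],
        provenance=provenance,
        unmatched_clinical=tuple(p for p in clinical if p not in neuropath),
        unmatched_neuropath=tuple(p for p in neuropath if p not in clinical),
        violations=v1 + v2,
    )
    cohort.violations.extend(validate_cohort(cohort))
    if strict and cohort.violations:
        raise ValidationError(cohort.violations)
    return cohort


# ---------------------------------------------------------------------------
# Validation


def validate_cohort(cohort: Cohort) -> list[Violation]:
    """Check every record-level invariant; empty report iff the cohort is valid."""
    out: list[Violation] = []
    seen: set[str] = set()
    for clin, neuro in cohort.records:
        pid = clin.participant_id
        if not pid:
            out.append(Violation(pid, "participant_id", "empty id"))
        if pid in seen:
            out.append(Violation(pid, "participant_id", "duplicate id"))
        seen.add(pid)
        if neuro.participant_id != pid:
            out.append(
                Violation(pid, "participant_id",
                          f"join mismatch with neuropath id {neuro.participant_id!r}")
            )
        if clin.age_years is not None and clin.age_years < 0:
            out.append(Violation(pid, "age_years", f"negative age {clin.age_years}"))
        if clin.mmse is not None and not 0 <= clin.mmse <= 30:
            out.append(Violation(pid, "mmse", f"{clin.mmse} outside [0, 30]"))
        for fname in ("cdr_global", "cdr_memory_box"):
            value = getattr(clin, fname)
            if value is not None and value not in CDR_LEVELS:
                out.append(Violation(pid, fname, f"{value} not a CDR level"))
        if neuro.thal_phase is not None and not 0 <= neuro.thal_phase <= 5:
            out.append(Violation(pid, "thal_phase", f"{neuro.thal_phase} outside [0, 5]"))
        if neuro.braak_stage is not None and not 0 <= neuro.braak_stage <= 6:
            out.append(Violation(pid, "braak_stage", f"{neuro.braak_stage} outside [0, 6]"))
        if neuro.cerad_score is not None and not 0 <= neuro.cerad_score <= 3:
            out.append(Violation(pid, "cerad_score", f"{neuro.cerad_score} outside [0, 3]"))
        for key, state in neuro.copathology_flags.items():
            if not isinstance(state, TriState):
                out.append(Violation(pid, f"copath.{key}", f"invalid state {state!r}"))
        for mapname in ("comorbidity_flags", "medication_flags"):
            for key, flag in getattr(clin, mapname).items():
                if not isinstance(flag, bool):
                    out.append(
                        Violation(pid, f"{mapname}.{key}", f"non-boolean flag {flag!r}")
                    )
    return out


# ---------------------------------------------------------------------------
# Writing


def _format(value: Any, missing_token: str) -> str:
    if value is None:
        return missing_token
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, float):
        return f"{value:g}"
    if isinstance(value, Enum):
        return value.value
    return str(value)


def write_cohort(
    cohort: Cohort,
    path: str | Path,
    *,
    delimiter: str = ",",
    missing_token: str = "",
    clinical_name: str = "clinical.csv",
    neuropath_name: str = "neuropath.csv",
) -> tuple[Path, Path]:
    """Write the two canonical tables; ``read_cohort`` round-trips them."""
    outdir = Path(path)
    outdir.mkdir(parents=True, exist_ok=True)

    comorbidity_keys = sorted({k for c, _ in cohort for k in c.comorbidity_flags})
    medication_keys = sorted({k for c, _ in cohort for k in c.medication_flags})
    copath_keys = sorted({k for _, n in cohort for k in n.copathology_flags})

    clin_path = outdir / clinical_name
    header = list(CLINICAL_FIELDS)
    header += [f"comorbidity.{k}" for k in comorbidity_keys]
    header += [f"medication.{k}" for k in medication_keys]
    with open(clin_path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(header)
        for clin, _ in cohort:
            row = [_format(getattr(clin, f), missing_token) for f in CLINICAL_FIELDS]
            row += [
                _format(clin.comorbidity_flags.get(k), missing_token)
                for k in comorbidity_keys
            ]
            row += [
                _format(clin.medication_flags.get(k), missing_token)
                for k in medication_keys
            ]
            writer.writerow(row)

    np_path = outdir / neuropath_name
    header = list(NEUROPATH_FIELDS) + [f"copath.{k}" for k in copath_keys]
    with open(np_path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(header)
        for _, neuro in cohort:
            row = [_format(getattr(neuro, f), missing_token) for f in NEUROPATH_FIELDS]
            row += [
                _format(neuro.copathology_flags.get(k), missing_token)
                for k in copath_keys
            ]
            writer.writerow(row)

    return clin_path, np_path
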