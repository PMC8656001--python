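"""The common data model (CDM): typed records, strict CSV dialect, validation.

Every participating site fills four linked tables — patients, care
providers, episodes and events — from its local information systems; the
tables, not the systems, are the interface of the analysis.  The exchange
dialect is deliberately minimal so that files are bit-comparable across
sites: comma-separated, **no quoting or escaping**, UTF-8, one preset
header line per table.  A field value containing the separator is an
error, never silently escaped.

Timestamps are ISO-8601 text (``YYYY-MM-DD`` or ``YYYY-MM-DDTHH:MM:SS``).
Event rows carry an explicit granularity column (``date`` /``datetime``)
which is authoritative over the textual form.  Missing values serialize
as the empty string.

The residence/healthcare-area entity is folded into attributes
(``residence_area_id`` on patients, ``area_id`` on providers).
"""

from __future__ import annotations

import dataclasses
import importlib.resources
import re
from datetime import datetime
from pathlib import Path
from typing import Iterable, Literal, Sequence

import yaml

from .activities import Setting
from .errors import (
    CdmDialectError,
    CdmEncodingError,
    CdmRowError,
    CdmSchemaError,
    TimestampFormatError,
    UnmappedValueError,
)

_DATE_RE = re.compile(r"^\d{4}-\d{2}-\d{2}$")
_DATETIME_RE = re.compile(r"^\d{4}-\d{2}-\d{2}T\d{2}:\d{2}:\d{2}$")

#: Separator for list-valued fields (the unquoted dialect rules out commas).
CODE_SEP = "|"


def parse_timestamp(text: str) -> datetime:
    """Parse ISO-8601 ``YYYY-MM-DD`` or ``YYYY-MM-DDTHH:MM:SS`` text.

    Raises :class:`TimestampFormatError` for any other form (including
    locale forms like ``05/03/2019``).
    """
    if _DATE_RE.match(text) or _DATETIME_RE.match(text):
        try:
            return datetime.fromisoformat(text)
        except ValueError as exc:
            raise TimestampFormatError(f"invalid timestamp {text!r}: {exc}") from exc
    raise TimestampFormatError(f"invalid timestamp {text!r} (expected ISO-8601)")


def format_timestamp(ts: datetime, granularity: str = "datetime") -> str:
    if granularity == "date":
        return ts.date().isoformat()
    return ts.strftime("%Y-%m-%dT%H:%M:%S")


# ---------------------------------------------------------------------------
# Records
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class PatientRecord:
    patient_id: str
    sex: str
    birth_year: int
    residence_area_id: str


@dataclasses.dataclass(frozen=True)
class ProviderRecord:
    provider_id: str
    setting: Setting
    area_id: str


@dataclasses.dataclass(frozen=True)
class EpisodeRecord:
    episode_id: str
    patient_id: str
    provider_id: str
    setting: Setting
    admission_ts: datetime
    discharge_ts: datetime | None
    diagnosis_codes: tuple[str, ...]
    coding_system: Literal["ICD9", "ICD10"]
    discharge_code: str


@dataclasses.dataclass(frozen=True)
class EventRecord:
    event_id: str
    episode_id: str
    source_code: str
    ts_raw: str
    granularity: Literal["date", "datetime"]


@dataclasses.dataclass
class CdmDataset:
    """The four linked record tables of one site plus dataset metadata."""

    patients: list[PatientRecord]
    providers: list[ProviderRecord]
    episodes: list[EpisodeRecord]
    events: list[EventRecord]
    cdm_version: str = "14.0"
    site_id: str = "unknown"


TableKind = Literal["patients", "providers", "episodes", "events"]
TABLE_KINDS: tuple[TableKind, ...] = ("patients", "providers", "episodes", "events")


def load_schema() -> dict:
    """Load the packaged preset-header schema for the current CDM revision."""
    text = (
        importlib.resources.files("carepath.schemas")
        .joinpath("cdm_v14.yaml")
        .read_text(encoding="utf-8")
    )
    return yaml.safe_load(text)


_SCHEMA = load_schema()
CDM_VERSION: str = _SCHEMA["cdm_version"]
HEADERS: dict[str, list[str]] = _SCHEMA["headers"]


# ---------------------------------------------------------------------------
# Row <-> record converters
# ---------------------------------------------------------------------------

def _parse_setting(text: str) -> Setting:
    try:
        return Setting(text)
    except ValueError:
        raise CdmRowError(f"unknown setting {text!r}")


def _patient_from_row(row: Sequence[str]) -> PatientRecord:
    pid, sex, birth_year, area = row
    try:
        year = int(birth_year)
    except ValueError:
        raise CdmRowError(f"birth_year {birth_year!r} is not an integer")
    return PatientRecord(pid, sex, year, area)


def _provider_from_row(row: Sequence[str]) -> ProviderRecord:
    pid, setting, area = row
    return ProviderRecord(pid, _parse_setting(setting), area)


def _episode_from_row(row: Sequence[str]) -> EpisodeRecord:
    (eid, pat, prov, setting, adm, dis, codes, system, dcode) = row
    if system not in ("ICD9", "ICD10"):
        raise CdmRowError(f"unknown coding_system {system!r}")
    return EpisodeRecord(
        episode_id=eid,
        patient_id=pat,
        provider_id=prov,
        setting=_parse_setting(setting),
        admission_ts=parse_timestamp(adm),
        discharge_ts=parse_timestamp(dis) if dis else None,
        diagnosis_codes=tuple(c for c in codes.split(CODE_SEP) if c),
        coding_system=system,
        discharge_code=dcode,
    )


def _event_from_row(row: Sequence[str]) -> EventRecord:
    eid, epid, code, ts_raw, gran = row
    if gran not in ("date", "datetime"):
        raise CdmRowError(f"unknown granularity {gran!r}")
    return EventRecord(eid, epid, code, ts_raw, gran)


def _patient_to_row(r: PatientRecord) -> list[str]:
    return [r.patient_id, r.sex, str(r.birth_year), r.residence_area_id]


def _provider_to_row(r: ProviderRecord) -> list[str]:
    return [r.provider_id, r.setting.value, r.area_id]


def _episode_to_row(r: EpisodeRecord) -> list[str]:
    return [
        r.episode_id,
        r.patient_id,
        r.provider_id,
        r.setting.value,
        format_timestamp(r.admission_ts),
        format_timestamp(r.discharge_ts) if r.discharge_ts is not None else "",
        CODE_SEP.join(r.diagnosis_codes),
        r.coding_system,
        r.discharge_code,
    ]


def _event_to_row(r: EventRecord) -> list[str]:
    return [r.event_id, r.episode_id, r.source_code, r.ts_raw, r.granularity]


_FROM_ROW = {
    "patients": _patient_from_row,
    "providers": _provider_from_row,
    "episodes": _episode_from_row,
    "events": _event_from_row,
}
_TO_ROW = {
    "patients": _patient_to_row,
    "providers": _provider_to_row,
    "episodes": _episode_to_row,
    "events": _event_to_row,
}


# ---------------------------------------------------------------------------
# Strict-dialect table IO
# ---------------------------------------------------------------------------

def read_cdm_table(path: str | Path, table_kind: TableKind) -> list:
    """Read one CDM table under the strict unquoted dialect.

    The first line must equal the preset header for ``table_kind`` exactly
    (case-sensitive).  Row order is preserved.

    Raises :class:`CdmSchemaError` on header mismatch, :class:`CdmRowError`
    (with line number) on an unparseable row, :class:`CdmEncodingError` on
    non-UTF-8 bytes.
    """
    path = Path(path)
    try:
        text = path.read_bytes().decode("utf-8")
    except UnicodeDecodeError as exc:
        raise CdmEncodingError(f"{path}: not valid UTF-8 ({exc})") from exc
    lines = text.splitlines()
    if not lines:
        raise CdmSchemaError(f"{path}: empty file, expected header line")
    expected = HEADERS[table_kind]
    got = lines[0].split(",")
    if got != expected:
        unexpected = [c for c in got if c not in expected]
        missing = [c for c in expected if c not in got]
        detail = []
        if unexpected:
            detail.append(f"unexpected column(s) {unexpected}")
        if missing:
            detail.append(f"missing column(s) {missing}")
        if not detail:
            detail.append(f"column order {got} != {expected}")
        raise CdmSchemaError(f"{path}: header mismatch: " + "; ".join(detail))
    converter = _FROM_ROW[table_kind]
    records = []
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.split(",")
        if len(fields) != len(expected):
            raise CdmRowError(
                f"{path}:{lineno}: expected {len(expected)} fields, got {len(fields)}",
                line_number=lineno,
            )
        try:
            records.append(converter(fields))
        except CdmRowError as exc:
            raise CdmRowError(f"{path}:{lineno}: {exc}", line_number=lineno) from exc
        except TimestampFormatError as exc:
            raise CdmRowError(f"{path}:{lineno}: {exc}", line_number=lineno) from exc
    return records


def write_cdm_table(records: Iterable, path: str | Path, table_kind: TableKind) -> None:
    """Write one CDM table under the strict unquoted dialect.

    A field value containing a comma or newline cannot be represented
    (quoting is forbidden) and raises :class:`CdmDialectError`.
    """
    path = Path(path)
    to_row = _TO_ROW[table_kind]
    lines = [",".join(HEADERS[table_kind])]
    for rec in records:
        row = to_row(rec)
        for value in row:
            if "," in value or "\n" in value or "\r" in value:
                raise CdmDialectError(
                    f"value {value!r} in table {table_kind} contains the separator "
                    "or a newline; the unquoted dialect cannot represent it"
                )
        lines.append(",".join(row))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_cdm_dir(dataset: CdmDataset, data_dir: str | Path) -> None:
    """Write the four CDM tables plus a small site metadata file."""
    data_dir = Path(data_dir)
    data_dir.mkdir(parents=True, exist_ok=True)
    write_cdm_table(dataset.patients, data_dir / "patients.csv", "patients")
    write_cdm_table(dataset.providers, data_dir / "providers.csv", "providers")
    write_cdm_table(dataset.episodes, data_dir / "episodes.csv", "episodes")
    write_cdm_table(dataset.events, data_dir / "events.csv", "events")
    meta = {"site_id": dataset.site_id, "cdm_version": dataset.cdm_version}
    (data_dir / "site.yaml").write_text(
        yaml.safe_dump(meta, sort_keys=True), encoding="utf-8"
    )


def read_cdm_dir(data_dir: str | Path) -> CdmDataset:
    """Read a CDM dataset from a directory of the four tables.

    Site metadata comes from ``site.yaml`` when present, else the directory
    name is used as the site id.
    """
    data_dir = Path(data_dir)
    meta_path = data_dir / "site.yaml"
    if meta_path.exists():
        meta = yaml.safe_load(meta_path.read_text(encoding="utf-8")) or {}
    else:
        meta = {}
    return CdmDataset(
        patients=read_cdm_table(data_dir / "patients.csv", "patients"),
        providers=read_cdm_table(data_dir / "providers.csv", "providers"),
        episodes=read_cdm_table(data_dir / "episodes.csv", "episodes"),
        events=read_cdm_table(data_dir / "events.csv", "events"),
        cdm_version=str(meta.get("cdm_version", CDM_VERSION)),
        site_id=str(meta.get("site_id", data_dir.name)),
    )


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class ValidationIssue:
    kind: str          # duplicate_id | dangling_reference | discharge_before_admission | ...
    table: str
    record_id: str
    message: str


@dataclasses.dataclass
class ValidationReport:
    issues: list[ValidationIssue] = dataclasses.field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.issues

    def kinds(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for issue in self.issues:
            counts[issue.kind] = counts.get(issue.kind, 0) + 1
        return counts


def validate_cdm(dataset: CdmDataset, study_end_year: int = 2100) -> ValidationReport:
    """Check referential integrity and record-level invariants.

    Problems are report entries, never exceptions; the report is empty iff
    the dataset is valid.
    """
    report = ValidationReport()
    add = report.issues.append

    def check_unique(ids: list[str], table: str) -> set[str]:
        seen: set[str] = set()
        for i in ids:
            if i in seen:
                add(ValidationIssue("duplicate_id", table, i, f"duplicate id {i!r}"))
            seen.add(i)
        return seen

    patient_ids = check_unique([p.patient_id for p in dataset.patients], "patients")
    provider_ids = check_unique([p.provider_id for p in dataset.providers], "providers")
    episode_ids = check_unique([e.episode_id for e in dataset.episodes], "episodes")
    check_unique([e.event_id for e in dataset.events], "events")

    for p in dataset.patients:
        if not p.patient_id:
            add(ValidationIssue("empty_id", "patients", "", "empty patient_id"))
        if not (1900 <= p.birth_year <= study_end_year):
            add(ValidationIssue(
                "birth_year_out_of_range", "patients", p.patient_id,
                f"birth_year {p.birth_year} outside [1900, {study_end_year}]",
            ))

    for e in dataset.episodes:
        if e.patient_id not in patient_ids:
            add(ValidationIssue(
                "dangling_reference", "episodes", e.episode_id,
                f"patient_id {e.patient_id!r} not in patients",
            ))
        if e.provider_id not in provider_ids:
            add(ValidationIssue(
                "dangling_reference", "episodes", e.episode_id,
                f"provider_id {e.provider_id!r} not in providers",
            ))
        if e.discharge_ts is not None and e.discharge_ts < e.admission_ts:
            add(ValidationIssue(
                "discharge_before_admission", "episodes", e.episode_id,
                f"discharge {e.discharge_ts} before admission {e.admission_ts}",
            ))

    for ev in dataset.events:
        if ev.episode_id not in episode_ids:
            add(ValidationIssue(
                "dangling_reference", "events", ev.event_id,
                f"episode_id {ev.episode_id!r} not in episodes",
            ))
        try:
            ts = parse_timestamp(ev.ts_raw)
        except TimestampFormatError:
            add(ValidationIssue(
                "bad_timestamp", "events", ev.event_id,
                f"unparseable ts_raw {ev.ts_raw!r}",
            ))
            continue
        if ev.granularity == "datetime" and "T" not in ev.ts_raw:
            add(ValidationIssue(
                "granularity_mismatch", "events", ev.event_id,
                "granularity=datetime but ts_raw has no time of day",
            ))
        del ts
    return report


# ---------------------------------------------------------------------------
# Normalized dictionaries
# ---------------------------------------------------------------------------

def normalize_code(raw_value: str, concept: str, dictionary: dict) -> str:
    """Map a site-local coded value to its canonical category.

    ``dictionary`` maps concept name -> {site-local synonym -> canonical}.
    Canonical values map to themselves when listed in the synonym map.
    Raises :class:`UnmappedValueError` for values absent from the map.
    """
    try:
        synonyms = dictionary[concept]
    except KeyError:
        raise UnmappedValueError(concept, raw_value)
    try:
        return synonyms[raw_value]
    except KeyError:
        raise UnmappedValueError(concept, raw_value)
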