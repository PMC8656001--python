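"""The event-log builder: from linked CDM records to mineable cases.

One *case* is one patient's acute-stroke care journey: the chain of
episodes that starts at an ER attendance (or a direct hospital admission)
and continues while each next admission begins within a configurable gap
threshold of the previous discharge, progressing through the settings
ER -> acute hospital -> long-stay hospital.  The linkage rule itself is a
reconstruction and is part of the configuration fingerprint, so the hub
can verify all sites chained episodes identically.

Within a case:

* episode admission/discharge timestamps contribute the administrative
  activities of their setting (e.g. an ER episode yields *ER Admission*
  and *ER Discharge*);
* event rows contribute clinical activities through the configured
  activity map; unmapped (setting, source_code) pairs are dropped with a
  warning, never fatal;
* timestamps are normalized to date-time granularity — a date-only
  timestamp becomes that date at 00:00:00 — and events are ordered by
  (normalized timestamp, canonical activity rank, source row id), a
  deterministic total order: the canonical pathway rank breaks the
  midnight ties that date-only granularity creates.
"""

from __future__ import annotations

import dataclasses
from datetime import datetime, timedelta
from pathlib import Path
from typing import Iterable, Mapping

from .activities import (
    ADMISSION_ACTIVITY,
    DISCHARGE_ACTIVITY,
    Activity,
    Setting,
)
from .cdm import CdmDataset, EpisodeRecord, parse_timestamp
from .cohort import StrokeClass, classify_stroke
from .config import AnalysisConfig
from .errors import TimestampFormatError


def normalize_timestamp(ts_raw: str, granularity: str) -> datetime:
    """Normalize a raw timestamp to full date-time granularity.

    Date-only input yields that date at 00:00:00; date-time input is
    returned unchanged.  The declared granularity is authoritative: a
    date-time text declared ``date`` is truncated to midnight.  Idempotent.
    """
    ts = parse_timestamp(ts_raw)
    if granularity == "date":
        return datetime(ts.year, ts.month, ts.day)
    if granularity == "datetime":
        return ts
    raise TimestampFormatError(f"unknown granularity {granularity!r}")


@dataclasses.dataclass(frozen=True)
class CaseEvent:
    """One timestamped activity instance inside a case."""

    activity: Activity
    ts: datetime
    provider_id: str
    granularity: str
    source_id: str      # episode_id#adm / episode_id#dis / event_id


@dataclasses.dataclass
class Case:
    """One linked care journey of one patient."""

    case_id: str
    patient_id: str
    stroke_class: StrokeClass
    events: list[CaseEvent]
    episode_ids: tuple[str, ...]

    @property
    def trace(self) -> tuple[str, ...]:
        """The activity-name sequence of the case."""
        return tuple(e.activity.value for e in self.events)


@dataclasses.dataclass
class EventLog:
    cases: list[Case]
    site_id: str
    fingerprint: str

    def __len__(self) -> int:
        return len(self.cases)

    def subset(self, stroke_class: StrokeClass | None) -> "EventLog":
        """The sub-log of one stroke class (None keeps every case)."""
        if stroke_class is None:
            return EventLog(list(self.cases), self.site_id, self.fingerprint)
        kept = [c for c in self.cases if c.stroke_class is stroke_class]
        return EventLog(kept, self.site_id, self.fingerprint)


@dataclasses.dataclass
class BuildReport:
    n_cases: int = 0
    n_events: int = 0
    n_dropped_events: int = 0
    dropped: list[tuple[str, str, str]] = dataclasses.field(default_factory=list)
    warnings: list[str] = dataclasses.field(default_factory=list)

    def warning_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for w in self.warnings:
            kind = w.split(":", 1)[0]
            counts[kind] = counts.get(kind, 0) + 1
        return counts


_SETTING_ORDER = {
    Setting.ER: 0,
    Setting.ACUTE_HOSPITAL: 1,
    Setting.LONGSTAY_HOSPITAL: 2,
}


def link_cases(
    cohort_episode_ids: set[str],
    episodes: Iterable[EpisodeRecord],
    gap_threshold: timedelta,
) -> tuple[list[list[EpisodeRecord]], list[str]]:
    """Chain episodes into cases.

    Episodes of one patient are chained when each next admission starts
    within ``gap_threshold`` of the previous discharge and the settings
    progress ER -> acute hospital -> long-stay hospital (an acute-hospital
    episode may repeat, covering inter-hospital transfers).  A missing
    discharge timestamp on a non-terminal episode splits the chain there,
    with a warning.  Only chains containing at least one cohort episode are
    returned; every cohort episode belongs to exactly one chain.
    """
    if gap_threshold <= timedelta(0):
        raise ValueError("gap_threshold must be positive")
    by_patient: dict[str, list[EpisodeRecord]] = {}
    for ep in episodes:
        by_patient.setdefault(ep.patient_id, []).append(ep)

    chains: list[list[EpisodeRecord]] = []
    warnings: list[str] = []
    for patient_id in sorted(by_patient):
        eps = sorted(by_patient[patient_id], key=lambda e: (e.admission_ts, e.episode_id))
        current: list[EpisodeRecord] = []
        for ep in eps:
            if not current:
                current = [ep]
                continue
            prev = current[-1]
            order_ok = (
                _SETTING_ORDER[ep.setting] > _SETTING_ORDER[prev.setting]
                or (ep.setting is prev.setting and ep.setting is Setting.ACUTE_HOSPITAL)
            )
            if prev.discharge_ts is None:
                warnings.append(
                    "missing_discharge_split: non-terminal episode without "
                    "discharge timestamp; chain split"
                )
                gap_ok = False
            else:
                gap_ok = ep.admission_ts - prev.discharge_ts <= gap_threshold
            if order_ok and gap_ok:
                current.append(ep)
            else:
                chains.append(current)
                current = [ep]
        if current:
            chains.append(current)

    kept = [c for c in chains if any(e.episode_id in cohort_episode_ids for e in c)]
    return kept, warnings


def map_activity(
    source_code: str,
    setting: Setting,
    activity_map: Mapping[tuple[Setting, str], Activity],
) -> Activity | None:
    """Map a site-local event code to a pathway activity.

    Returns None for pairs absent from the map; the caller records the
    drop in the build report.
    """
    return activity_map.get((setting, source_code))


def build_event_log(
    dataset: CdmDataset,
    cohort_episode_ids: set[str],
    config: AnalysisConfig,
) -> tuple[EventLog, BuildReport]:
    """Assemble the event log from a validated dataset and selected cohort.

    Deterministic: permuting input row order never changes the built log.
    An empty cohort yields an empty log.
    """
    report = BuildReport()
    chains, link_warnings = link_cases(
        cohort_episode_ids,
        dataset.episodes,
        timedelta(hours=config.gap_threshold_hours),
    )
    report.warnings.extend(link_warnings)

    events_by_episode: dict[str, list] = {}
    for ev in dataset.events:
        events_by_episode.setdefault(ev.episode_id, []).append(ev)

    case_index: dict[str, int] = {}
    cases: list[Case] = []
    chains.sort(key=lambda ch: (ch[0].patient_id, ch[0].admission_ts, ch[0].episode_id))
    for chain in chains:
        patient_id = chain[0].patient_id
        k = case_index.get(patient_id, 0)
        case_index[patient_id] = k + 1
        case_id = f"{patient_id}#{k}"

        case_events: list[CaseEvent] = []
        for ep in chain:
            # episode timestamps are parsed datetimes; a date-only source form
            # is already midnight, so they carry datetime granularity here
            case_events.append(CaseEvent(
                activity=ADMISSION_ACTIVITY[ep.setting],
                ts=ep.admission_ts,
                provider_id=ep.provider_id,
                granularity="datetime",
                source_id=f"{ep.episode_id}#adm",
            ))
            if ep.discharge_ts is not None:
                case_events.append(CaseEvent(
                    activity=DISCHARGE_ACTIVITY[ep.setting],
                    ts=ep.discharge_ts,
                    provider_id=ep.provider_id,
                    granularity="datetime",
                    source_id=f"{ep.episode_id}#dis",
                ))
            for ev in events_by_episode.get(ep.episode_id, []):
                activity = map_activity(ev.source_code, ep.setting, config.activity_map)
                if activity is None:
                    report.n_dropped_events += 1
                    report.dropped.append((ev.event_id, ep.setting.value, ev.source_code))
                    report.warnings.append(
                        f"unmapped_event: ({ep.setting.value}, {ev.source_code})"
                    )
                    continue
                try:
                    ts = normalize_timestamp(ev.ts_raw, ev.granularity)
                except TimestampFormatError:
                    report.n_dropped_events += 1
                    report.dropped.append((ev.event_id, ep.setting.value, ev.source_code))
                    report.warnings.append("bad_timestamp: event dropped")
                    continue
                case_events.append(CaseEvent(
                    activity=activity,
                    ts=ts,
                    provider_id=ep.provider_id,
                    granularity=ev.granularity,
                    source_id=ev.event_id,
                ))

        case_events.sort(key=lambda e: (e.ts, e.activity.rank, e.source_id))

        codes: list[str] = []
        coding_system = chain[0].coding_system
        for ep in chain:
            codes.extend(ep.diagnosis_codes)
        stroke_class = classify_stroke(codes, coding_system, config.code_lists)

        cases.append(Case(
            case_id=case_id,
            patient_id=patient_id,
            stroke_class=stroke_class,
            events=case_events,
            episode_ids=tuple(e.episode_id for e in chain),
        ))
        report.n_events += len(case_events)

    report.n_cases = len(cases)
    log = EventLog(cases=cases, site_id=dataset.site_id, fingerprint=config.fingerprint())
    return log, report


def check_sequence_consistency(case: Case) -> list[dict]:
    """Flag timestamp irregularities against the expected pathway order.

    In the (timestamp, canonical rank) ordering of a well-formed case the
    canonical rank never decreases along distinct timestamps; every
    adjacent pair where it does — a discharge timestamped before its
    admission, a hospital admission before the ER admission — yields one
    flag.  Flags never mutate the case.
    """
    flags = []
    for prev, cur in zip(case.events, case.events[1:]):
        if cur.activity.rank < prev.activity.rank:
            flags.append({
                "case_id": case.case_id,
                "before": prev.activity.value,
                "after": cur.activity.value,
                "ts_before": prev.ts.isoformat(),
                "ts_after": cur.ts.isoformat(),
            })
    return flags


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def write_event_log_csv(log: EventLog, path: str | Path) -> None:
    """Export the log as case_id,activity,timestamp,provider_id rows.

    Activity names contain no commas, so the normalized unquoted dialect
    applies unchanged.
    """
    lines = ["case_id,activity,timestamp,provider_id"]
    for case in log.cases:
        for e in case.events:
            lines.append(
                f"{case.case_id},{e.activity.value},"
                f"{e.ts.strftime('%Y-%m-%dT%H:%M:%S')},{e.provider_id}"
            )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_event_log_xes(log: EventLog, path: str | Path) -> None:
    """Export the log in the IEEE XES event-log format for external tools."""
    import xml.etree.ElementTree as ET

    root = ET.Element("log", attrib={"xes.version": "1.0", "xes.features": ""})
    for case in log.cases:
        trace = ET.SubElement(root, "trace")
        ET.SubElement(trace, "string", key="concept:name", value=case.case_id)
        for e in case.events:
            ev = ET.SubElement(trace, "event")
            ET.SubElement(ev, "string", key="concept:name", value=e.activity.value)
            ET.SubElement(ev, "date", key="time:timestamp",
                          value=e.ts.strftime("%Y-%m-%dT%H:%M:%S"))
            ET.SubElement(ev, "string", key="org:resource", value=e.provider_id)
    ET.ElementTree(root).write(path, encoding="utf-8", xml_declaration=True)
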