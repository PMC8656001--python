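"""Event-log builder: timestamps, case linkage, activity mapping, ordering."""

from __future__ import annotations

import dataclasses
from datetime import datetime, timedelta

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from carepath import (
    Activity,
    build_event_log,
    check_sequence_consistency,
    generate_dataset,
    link_cases,
    map_activity,
    normalize_timestamp,
    select_cohort,
)
from carepath.activities import Setting
from carepath.cdm import CdmDataset, EpisodeRecord, EventRecord, PatientRecord, ProviderRecord
from carepath.config import DEFAULT_ACTIVITY_MAP
from carepath.errors import TimestampFormatError
from carepath.synthdata import NO_DEFECTS
from conftest import make_case


def test_date_only_maps_to_midnight():
    assert normalize_timestamp("2019-03-05", "date") == datetime(2019, 3, 5, 0, 0, 0)


def test_datetime_passes_through_unchanged():
    ts = normalize_timestamp("2019-03-05T14:30:00", "datetime")
    assert ts == datetime(2019, 3, 5, 14, 30, 0)


def test_non_iso_text_is_an_error():
    with pytest.raises(TimestampFormatError):
        normalize_timestamp("05/03/2019", "date")


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.datetimes(min_value=datetime(1990, 1, 1), max_value=datetime(2030, 1, 1)),
       st.sampled_from(["date", "datetime"]))
def test_normalize_timestamp_is_idempotent(ts, granularity):
    text = ts.strftime("%Y-%m-%dT%H:%M:%S") if granularity == "datetime" \
        else ts.strftime("%Y-%m-%d")
    once = normalize_timestamp(text, granularity)
    twice = normalize_timestamp(once.strftime("%Y-%m-%dT%H:%M:%S"), "datetime")
    assert once == twice
    if granularity == "date":
        assert (once.hour, once.minute, once.second) == (0, 0, 0)


def _episode(eid, pid, setting, adm, dis, provider="pr"):
    return EpisodeRecord(eid, pid, provider, setting, adm, dis,
                         ("I63.0",), "ICD10", "home")


def test_er_to_hospital_within_threshold_is_one_case():
    er = _episode("e1", "p", Setting.ER,
                  datetime(2019, 1, 1, 8, 0), datetime(2019, 1, 1, 10, 0))
    hosp = _episode("e2", "p", Setting.ACUTE_HOSPITAL,
                    datetime(2019, 1, 1, 11, 0), datetime(2019, 1, 5, 10, 0))
    chains, warnings = link_cases({"e1"}, [er, hosp], timedelta(hours=24))
    assert [[e.episode_id for e in c] for c in chains] == [["e1", "e2"]]
    assert warnings == []


def test_long_gap_splits_into_two_cases():
    er = _episode("e1", "p", Setting.ER,
                  datetime(2019, 1, 1, 8, 0), datetime(2019, 1, 1, 10, 0))
    hosp = _episode("e2", "p", Setting.ACUTE_HOSPITAL,
                    datetime(2019, 2, 10, 11, 0), datetime(2019, 2, 15, 10, 0))
    chains, _ = link_cases({"e1", "e2"}, [er, hosp], timedelta(hours=24))
    assert [[e.episode_id for e in c] for c in chains] == [["e1"], ["e2"]]


def test_missing_discharge_on_non_terminal_episode_splits_with_warning():
    er = _episode("e1", "p", Setting.ER, datetime(2019, 1, 1, 8, 0), None)
    hosp = _episode("e2", "p", Setting.ACUTE_HOSPITAL,
                    datetime(2019, 1, 1, 11, 0), datetime(2019, 1, 5, 10, 0))
    chains, warnings = link_cases({"e1"}, [er, hosp], timedelta(hours=24))
    assert [[e.episode_id for e in c] for c in chains] == [["e1"]]
    assert any(w.startswith("missing_discharge_split") for w in warnings)


def test_generator_known_chains_are_recovered(config):
    ds, truth = generate_dataset(200, seed=17, defects=NO_DEFECTS)
    chains, _ = link_cases(
        select_cohort(ds, config.code_lists), ds.episodes,
        timedelta(hours=config.gap_threshold_hours),
    )
    got = {tuple(e.episode_id for e in c) for c in chains}
    assert got == {c.episode_ids for c in truth.cases}


def test_map_activity_defaults_and_unmapped():
    assert map_activity("CT_SCAN", Setting.ER, DEFAULT_ACTIVITY_MAP) is Activity.ER_CT
    assert map_activity("FIBRINOLYSIS", Setting.ER, DEFAULT_ACTIVITY_MAP) \
        is Activity.ER_FIBRINOLYSIS
    assert map_activity("FIBRINOLYSIS", Setting.ACUTE_HOSPITAL, DEFAULT_ACTIVITY_MAP) \
        is Activity.HOSPITAL_FIBRINOLYSIS
    assert map_activity("UNKNOWN_PROC", Setting.ER, DEFAULT_ACTIVITY_MAP) is None


def _tiny_dataset() -> CdmDataset:
    return CdmDataset(
        patients=[PatientRecord("p1", "male", 1950, "a")],
        providers=[ProviderRecord("pr", Setting.ER, "a")],
        episodes=[_episode("e1", "p1", Setting.ER,
                           datetime(2019, 3, 5, 10, 0), datetime(2019, 3, 5, 18, 0))],
        events=[EventRecord("ev1", "e1", "CT_SCAN", "2019-03-05T11:00:00", "datetime")],
        site_id="T",
    )


def test_er_episode_composes_admission_event_discharge(config):
    log, report = build_event_log(_tiny_dataset(), {"e1"}, config)
    (case,) = log.cases
    assert case.trace == ("ER Admission", "ER CT", "ER Discharge")
    assert report.n_cases == 1 and report.n_dropped_events == 0


def test_date_only_event_sorts_by_canonical_rank_on_admission_day(config):
    """A midnight-normalized CT on the admission date lands after the
    same-timestamp admission because rank breaks the tie."""
    ds = _tiny_dataset()
    ds.episodes[0] = dataclasses.replace(
        ds.episodes[0], admission_ts=datetime(2019, 3, 5, 0, 0, 0)
    )
    ds.events[0] = dataclasses.replace(
        ds.events[0], ts_raw="2019-03-05", granularity="date"
    )
    log, _ = build_event_log(ds, {"e1"}, config)
    assert log.cases[0].trace == ("ER Admission", "ER CT", "ER Discharge")


def test_unmapped_events_dropped_with_warning(config):
    ds = _tiny_dataset()
    ds.events.append(EventRecord("ev2", "e1", "UNKNOWN_PROC",
                                 "2019-03-05T12:00:00", "datetime"))
    log, report = build_event_log(ds, {"e1"}, config)
    assert report.n_dropped_events == 1
    assert report.dropped[0][0] == "ev2"
    assert log.cases[0].trace == ("ER Admission", "ER CT", "ER Discharge")


def test_build_is_invariant_to_input_row_order(config):
    ds, _ = generate_dataset(60, seed=5, defects=NO_DEFECTS)
    cohort = select_cohort(ds, config.code_lists)
    log1, _ = build_event_log(ds, cohort, config)
    rng = np.random.default_rng(0)
    shuffled = CdmDataset(
        patients=list(ds.patients), providers=list(ds.providers),
        episodes=[ds.episodes[i] for i in rng.permutation(len(ds.episodes))],
        events=[ds.events[i] for i in rng.permutation(len(ds.events))],
        cdm_version=ds.cdm_version, site_id=ds.site_id,
    )
    log2, _ = build_event_log(shuffled, cohort, config)
    assert [(c.case_id, c.trace, tuple(e.ts for e in c.events)) for c in log1.cases] \
        == [(c.case_id, c.trace, tuple(e.ts for e in c.events)) for c in log2.cases]


def test_no_event_is_assigned_to_two_cases(config):
    ds, _ = generate_dataset(80, seed=9, defects=NO_DEFECTS)
    log, report = build_event_log(ds, select_cohort(ds, config.code_lists), config)
    sources = [e.source_id for c in log.cases for e in c.events]
    assert len(sources) == len(set(sources))
    assert report.n_events == sum(len(c.events) for c in log.cases)


def test_discharge_before_admission_is_flagged():
    case = make_case("x", [
        ("ER Admission", datetime(2019, 1, 1, 10, 0)),
        ("ER Discharge", datetime(2019, 1, 1, 9, 0)),
    ])
    case.events.sort(key=lambda e: (e.ts, e.activity.rank))
    flags = check_sequence_consistency(case)
    assert len(flags) == 1
    assert flags[0]["before"] == "ER Discharge" and flags[0]["after"] == "ER Admission"


def test_canonical_sequence_yields_no_flags():
    case = make_case("ok", [
        "ER Admission", "ER First Attention", "ER CT", "ER Fibrinolysis",
        "ER Discharge", "ER Exit", "Hospital Admission", "Hospital Discharge",
    ])
    assert check_sequence_consistency(case) == []
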