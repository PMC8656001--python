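"""Shared fixtures and event-log construction helpers."""

from __future__ import annotations

from datetime import datetime, timedelta

import numpy as np
import pytest

from carepath import Activity, AnalysisConfig
from carepath.cohort import StrokeClass
from carepath.eventlog import Case, CaseEvent, EventLog

#: Short aliases used by tests that need abstract traces; they still live in
#: the closed activity vocabulary so every pipeline view accepts them.
ABC = {
    "A": Activity.ER_ADMISSION.value,
    "B": Activity.ER_CT.value,
    "C": Activity.ER_DISCHARGE.value,
    "D": Activity.ER_EXIT.value,
    "E": Activity.HOSPITAL_ADMISSION.value,
}


def make_case(case_id: str, steps, start=None, gap_hours=1.0) -> Case:
    """Build a case from [(activity_name, ts)] or plain activity names."""
    start = start or datetime(2019, 3, 5, 10, 0, 0)
    events = []
    for i, step in enumerate(steps):
        if isinstance(step, tuple):
            name, ts = step
        else:
            name, ts = step, start + timedelta(hours=gap_hours * i)
        events.append(CaseEvent(
            activity=Activity(name), ts=ts, provider_id="P1",
            granularity="datetime", source_id=f"{case_id}-{i}",
        ))
    return Case(
        case_id=case_id, patient_id=f"pt-{case_id}",
        stroke_class=StrokeClass.UNCLASSIFIED,
        events=events, episode_ids=(f"ep-{case_id}",),
    )


def make_log(traces, site_id="T", fingerprint="f") -> EventLog:
    """Build an event log from a list of activity-name traces (aliases ok)."""
    cases = []
    for i, trace in enumerate(traces):
        names = [ABC.get(t, t) for t in trace]
        cases.append(make_case(f"c{i}", names))
    return EventLog(cases=cases, site_id=site_id, fingerprint=fingerprint)


def random_log(rng: np.random.Generator, max_cases=50, max_len=12) -> EventLog:
    """A random log over a 6-activity alphabet, arbitrary sequences."""
    alphabet = [a.value for a in list(Activity)[:6]]
    n = int(rng.integers(1, max_cases + 1))
    traces = []
    for _ in range(n):
        length = int(rng.integers(1, max_len + 1))
        traces.append([alphabet[int(rng.integers(0, len(alphabet)))]
                       for _ in range(length)])
    return make_log(traces)


@pytest.fixture
def config() -> AnalysisConfig:
    return AnalysisConfig()
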