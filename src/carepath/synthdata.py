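"""Synthetic multi-site stroke-care datasets with known ground truth.

No real administrative health data can ship with this package, so every
other module is exercised on data drawn from a configurable *pathway
model*: a timed Markov chain over the 14-activity vocabulary emulating a
Code-Stroke-like flow — ER admission, first medical contact, CT imaging,
reperfusion treatment (fibrinolysis and/or thrombectomy, ischemic cases
only), observation, discharge, possible transfer to acute hospital and
long-stay recovery care.  All branch probabilities and delay
distributions are explicitly fictitious defaults, editable in one place;
no calibration to real stroke epidemiology is claimed.

Delays are log-normal for hyper-acute in-episode steps (positive,
right-skewed, minutes-to-hours) and exponential for inter-episode gaps.
Gap delays are sampled with a rejection cap below the default case-
linkage threshold so that generated transfer chains are linkable by
construction; :meth:`PathwayModel.delay_mean` returns the exact mean of
the truncated sampling distribution, so recovery tests compare against
the true generating mean.

The generator also injects the timestamp-quality defects routine data
shows — date-only granularity, swapped timestamps, unmappable local
codes, missing discharges — and records every injected defect in a
ground-truth ledger so recovery is testable one-for-one.

Each synthetic patient carries exactly one care journey; pseudonyms are
drawn from the seeded stream and are disjoint across sites.
"""

from __future__ import annotations

import dataclasses
import math
from datetime import date, datetime, timedelta
from pathlib import Path

import numpy as np

from .activities import Activity, Setting
from .cdm import (
    CdmDataset,
    CDM_VERSION,
    EpisodeRecord,
    EventRecord,
    PatientRecord,
    ProviderRecord,
    write_cdm_dir,
)
from .cohort import StrokeClass

# ---------------------------------------------------------------------------
# Delay distributions
# ---------------------------------------------------------------------------


def _phi(x: float) -> float:
    return 0.5 * (1.0 + math.erf(x / math.sqrt(2.0)))


@dataclasses.dataclass(frozen=True)
class Delay:
    """A transition delay distribution in hours, optionally right-truncated.

    ``lognormal`` takes (mu, sigma) of the underlying normal; ``exponential``
    takes the (untruncated) mean.  ``cap`` rejects samples above it.
    """

    family: str                 # "lognormal" | "exponential"
    params: tuple[float, ...]
    cap: float | None = None

    def sample(self, rng: np.random.Generator) -> float:
        while True:
            if self.family == "lognormal":
                x = float(rng.lognormal(self.params[0], self.params[1]))
            elif self.family == "exponential":
                x = float(rng.exponential(self.params[0]))
            else:
                raise ValueError(f"unknown delay family {self.family!r}")
            if self.cap is None or x <= self.cap:
                return x

    def mean(self) -> float:
        """Exact mean of the (truncated) sampling distribution."""
        return self._moment(1)

    def sd(self) -> float:
        """Exact standard deviation of the (truncated) sampling distribution."""
        m1, m2 = self._moment(1), self._moment(2)
        return math.sqrt(max(m2 - m1 * m1, 0.0))

    def _moment(self, k: int) -> float:
        if self.family == "exponential":
            m = self.params[0]
            if self.cap is None:
                return m if k == 1 else 2.0 * m * m
            c = self.cap
            q = math.exp(-c / m)
            if k == 1:
                return m - c * q / (1.0 - q)
            # second raw moment of the right-truncated exponential
            return (2.0 * m * m - q * (c * c + 2.0 * m * c + 2.0 * m * m)) / (1.0 - q)
        mu, s = self.params
        untrunc = math.exp(k * mu + k * k * s * s / 2.0)
        if self.cap is None:
            return untrunc
        z = (math.log(self.cap) - mu) / s
        return untrunc * _phi(z - k * s) / _phi(z)


def _logn(median: float, sigma: float, cap: float | None = None) -> Delay:
    return Delay("lognormal", (math.log(median), sigma), cap)


def _expo(mean: float, cap: float | None = None) -> Delay:
    return Delay("exponential", (mean,), cap)


A = Activity  # local alias

#: Per-transition delay distributions (hours).  Inter-episode gaps are
#: capped so that chains stay within the default 24 h linkage threshold
#: (2 h + 19 h from ER discharge to hospital admission; 21 h to long-stay).
DEFAULT_DELAYS: dict[tuple[str, str], Delay] = {
    (A.ER_ADMISSION.value, A.ER_FIRST_ATTENTION.value): _logn(0.25, 0.5),
    (A.ER_FIRST_ATTENTION.value, A.ER_CT.value): _logn(0.5, 0.5),
    (A.ER_FIRST_ATTENTION.value, A.ER_OBSERVATION_ROOM.value): _logn(2.0, 0.5),
    (A.ER_FIRST_ATTENTION.value, A.ER_DISCHARGE.value): _logn(3.0, 0.5),
    (A.ER_CT.value, A.ER_FIBRINOLYSIS.value): _logn(0.5, 0.4),
    (A.ER_CT.value, A.ER_THROMBECTOMY.value): _logn(1.0, 0.4),
    (A.ER_CT.value, A.ER_OBSERVATION_ROOM.value): _logn(1.5, 0.5),
    (A.ER_CT.value, A.ER_DISCHARGE.value): _logn(3.0, 0.5),
    (A.ER_FIBRINOLYSIS.value, A.ER_THROMBECTOMY.value): _logn(1.0, 0.4),
    (A.ER_FIBRINOLYSIS.value, A.ER_OBSERVATION_ROOM.value): _logn(1.0, 0.5),
    (A.ER_FIBRINOLYSIS.value, A.ER_DISCHARGE.value): _logn(4.0, 0.5),
    (A.ER_THROMBECTOMY.value, A.ER_OBSERVATION_ROOM.value): _logn(2.0, 0.5),
    (A.ER_THROMBECTOMY.value, A.ER_DISCHARGE.value): _logn(4.0, 0.5),
    (A.ER_OBSERVATION_ROOM.value, A.ER_DISCHARGE.value): _logn(6.0, 0.6),
    (A.ER_DISCHARGE.value, A.ER_EXIT.value): _logn(0.5, 0.5, cap=2.0),
    (A.ER_EXIT.value, A.HOSPITAL_ADMISSION.value): _expo(3.0, cap=19.0),
    (A.HOSPITAL_ADMISSION.value, A.HOSPITAL_FIBRINOLYSIS.value): _logn(4.0, 0.5),
    (A.HOSPITAL_ADMISSION.value, A.HOSPITAL_THROMBECTOMY.value): _logn(6.0, 0.5),
    (A.HOSPITAL_ADMISSION.value, A.HOSPITAL_DISCHARGE.value): _expo(96.0),
    (A.HOSPITAL_FIBRINOLYSIS.value, A.HOSPITAL_THROMBECTOMY.value): _logn(4.0, 0.5),
    (A.HOSPITAL_FIBRINOLYSIS.value, A.HOSPITAL_DISCHARGE.value): _expo(72.0),
    (A.HOSPITAL_THROMBECTOMY.value, A.HOSPITAL_DISCHARGE.value): _expo(96.0),
    (A.HOSPITAL_DISCHARGE.value, A.LONGSTAY_ADMISSION.value): _expo(4.0, cap=21.0),
    (A.LONGSTAY_ADMISSION.value, A.LONGSTAY_DISCHARGE.value): _expo(336.0),
}

#: Terminal marker inside transition tables.
END_STATE = "END"

Branches = dict[str, list[tuple[str, float]]]

# Per-class transition structure.  All paths are monotone in canonical rank
# (the pathway never moves backwards), which keeps canonical-rank tie-breaks
# and consistency checking well-behaved.  Hemorrhagic cases are barred from
# fibrinolysis (contraindicated); reperfusion branches are ischemic-only.
_ISCHEMIC: Branches = {
    A.ER_ADMISSION.value: [(A.ER_FIRST_ATTENTION.value, 1.0)],
    A.ER_FIRST_ATTENTION.value: [
        (A.ER_CT.value, 0.90), (A.ER_OBSERVATION_ROOM.value, 0.05),
        (A.ER_DISCHARGE.value, 0.05),
    ],
    A.ER_CT.value: [
        (A.ER_FIBRINOLYSIS.value, 0.18), (A.ER_THROMBECTOMY.value, 0.07),
        (A.ER_OBSERVATION_ROOM.value, 0.35), (A.ER_DISCHARGE.value, 0.40),
    ],
    A.ER_FIBRINOLYSIS.value: [
        (A.ER_THROMBECTOMY.value, 0.10), (A.ER_OBSERVATION_ROOM.value, 0.50),
        (A.ER_DISCHARGE.value, 0.40),
    ],
    A.ER_THROMBECTOMY.value: [
        (A.ER_OBSERVATION_ROOM.value, 0.60), (A.ER_DISCHARGE.value, 0.40),
    ],
    A.ER_OBSERVATION_ROOM.value: [(A.ER_DISCHARGE.value, 1.0)],
    A.ER_DISCHARGE.value: [(A.ER_EXIT.value, 1.0)],
    A.ER_EXIT.value: [(A.HOSPITAL_ADMISSION.value, 0.75), (END_STATE, 0.25)],
    A.HOSPITAL_ADMISSION.value: [
        (A.HOSPITAL_FIBRINOLYSIS.value, 0.05),
        (A.HOSPITAL_THROMBECTOMY.value, 0.04),
        (A.HOSPITAL_DISCHARGE.value, 0.91),
    ],
    A.HOSPITAL_FIBRINOLYSIS.value: [
        (A.HOSPITAL_THROMBECTOMY.value, 0.10), (A.HOSPITAL_DISCHARGE.value, 0.90),
    ],
    A.HOSPITAL_THROMBECTOMY.value: [(A.HOSPITAL_DISCHARGE.value, 1.0)],
    A.HOSPITAL_DISCHARGE.value: [
        (A.LONGSTAY_ADMISSION.value, 0.20), (END_STATE, 0.80),
    ],
    A.LONGSTAY_ADMISSION.value: [(A.LONGSTAY_DISCHARGE.value, 1.0)],
    A.LONGSTAY_DISCHARGE.value: [(END_STATE, 1.0)],
}

_HEMORRHAGIC: Branches = {
    A.ER_ADMISSION.value: [(A.ER_FIRST_ATTENTION.value, 1.0)],
    A.ER_FIRST_ATTENTION.value: [
        (A.ER_CT.value, 0.95), (A.ER_DISCHARGE.value, 0.05),
    ],
    A.ER_CT.value: [
        (A.ER_OBSERVATION_ROOM.value, 0.55), (A.ER_DISCHARGE.value, 0.45),
    ],
    A.ER_OBSERVATION_ROOM.value: [(A.ER_DISCHARGE.value, 1.0)],
    A.ER_DISCHARGE.value: [(A.ER_EXIT.value, 1.0)],
    A.ER_EXIT.value: [(A.HOSPITAL_ADMISSION.value, 0.85), (END_STATE, 0.15)],
    A.HOSPITAL_ADMISSION.value: [(A.HOSPITAL_DISCHARGE.value, 1.0)],
    A.HOSPITAL_DISCHARGE.value: [
        (A.LONGSTAY_ADMISSION.value, 0.30), (END_STATE, 0.70),
    ],
    A.LONGSTAY_ADMISSION.value: [(A.LONGSTAY_DISCHARGE.value, 1.0)],
    A.LONGSTAY_DISCHARGE.value: [(END_STATE, 1.0)],
}

_SUSPECTED: Branches = {
    A.ER_ADMISSION.value: [(A.ER_FIRST_ATTENTION.value, 1.0)],
    A.ER_FIRST_ATTENTION.value: [
        (A.ER_CT.value, 0.70), (A.ER_DISCHARGE.value, 0.30),
    ],
    A.ER_CT.value: [
        (A.ER_OBSERVATION_ROOM.value, 0.40), (A.ER_DISCHARGE.value, 0.60),
    ],
    A.ER_OBSERVATION_ROOM.value: [(A.ER_DISCHARGE.value, 1.0)],
    A.ER_DISCHARGE.value: [(A.ER_EXIT.value, 1.0)],
    A.ER_EXIT.value: [(A.HOSPITAL_ADMISSION.value, 0.25), (END_STATE, 0.75)],
    A.HOSPITAL_ADMISSION.value: [(A.HOSPITAL_DISCHARGE.value, 1.0)],
    A.HOSPITAL_DISCHARGE.value: [(END_STATE, 1.0)],
}


@dataclasses.dataclass(frozen=True)
class PathwayModel:
    """Timed Markov chain over the activity vocabulary, per stroke class."""

    class_mix: dict[StrokeClass, float] = dataclasses.field(
        default_factory=lambda: {
            StrokeClass.ISCHEMIC: 0.60,
            StrokeClass.HEMORRHAGIC: 0.20,
            StrokeClass.SUSPECTED: 0.20,
        }
    )
    # entry distribution: ER attendance vs direct hospital admission
    init: dict[StrokeClass, list[tuple[str, float]]] = dataclasses.field(
        default_factory=lambda: {
            StrokeClass.ISCHEMIC: [
                (A.ER_ADMISSION.value, 0.90), (A.HOSPITAL_ADMISSION.value, 0.10),
            ],
            StrokeClass.HEMORRHAGIC: [
                (A.ER_ADMISSION.value, 0.92), (A.HOSPITAL_ADMISSION.value, 0.08),
            ],
            StrokeClass.SUSPECTED: [(A.ER_ADMISSION.value, 1.0)],
        }
    )
    transitions: dict[StrokeClass, Branches] = dataclasses.field(
        default_factory=lambda: {
            StrokeClass.ISCHEMIC: _ISCHEMIC,
            StrokeClass.HEMORRHAGIC: _HEMORRHAGIC,
            StrokeClass.SUSPECTED: _SUSPECTED,
        }
    )
    delays: dict[tuple[str, str], Delay] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_DELAYS)
    )
    default_delay: Delay = _logn(1.0, 0.5)

    def __post_init__(self):
        for cls, table in self.transitions.items():
            for src, branches in table.items():
                total = sum(p for _, p in branches)
                if abs(total - 1.0) > 1e-9:
                    raise ValueError(
                        f"branch probabilities at {cls.value}/{src} sum to {total}"
                    )
        for cls, branches in self.init.items():
            total = sum(p for _, p in branches)
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"init probabilities for {cls.value} sum to {total}")

    def delay_for(self, a: str, b: str) -> Delay:
        return self.delays.get((a, b), self.default_delay)

    def delay_mean(self, a: str, b: str) -> float:
        """Exact mean (hours) of the generating delay distribution of a->b."""
        return self.delay_for(a, b).mean()

    def branch_probability(self, stroke_class: StrokeClass, a: str, b: str) -> float:
        """True transition probability a->b for one class (b may be END)."""
        for target, p in self.transitions[stroke_class].get(a, []):
            if target == b:
                return p
        return 0.0


@dataclasses.dataclass(frozen=True)
class DefectConfig:
    """Rates of the timestamp/coding quality defects routine data shows."""

    date_only_rate: float = 0.10
    inversion_rate: float = 0.03
    unmappable_rate: float = 0.02
    missing_discharge_rate: float = 0.02

    def __post_init__(self):
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{f.name} must be in [0, 1], got {v}")


#: Convenience: defect-free generation (lossless round trips).
NO_DEFECTS = DefectConfig(0.0, 0.0, 0.0, 0.0)


# ---------------------------------------------------------------------------
# Ground truth
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class TrueCase:
    case_id: str
    patient_id: str
    stroke_class: StrokeClass
    events: list[tuple[Activity, datetime]]   # pre-defect truth
    episode_ids: tuple[str, ...]


@dataclasses.dataclass
class GroundTruth:
    """Everything the generator knows: true cases and injected defects."""

    cases: list[TrueCase]
    defects: list[dict]     # {kind, case_id, target_id}

    def defect_ids(self, kind: str) -> set[str]:
        return {d["target_id"] for d in self.defects if d["kind"] == kind}


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------

def _choose(rng: np.random.Generator, branches: list[tuple[str, float]]) -> str:
    r = float(rng.random())
    acc = 0.0
    for target, p in branches:
        acc += p
        if r < acc:
            return target
    return branches[-1][0]


def sample_case(
    model: PathwayModel,
    rng: np.random.Generator,
    start_ts: datetime,
    stroke_class: StrokeClass | None = None,
) -> tuple[StrokeClass, list[tuple[Activity, datetime]]]:
    """Sample one timed activity sequence from the pathway model.

    Timestamps strictly increase (delays are rounded to whole seconds with
    a one-second floor).  Deterministic given the generator state.
    """
    if stroke_class is None:
        classes = list(model.class_mix)
        probs = [model.class_mix[c] for c in classes]
        stroke_class = classes[int(rng.choice(len(classes), p=np.asarray(probs) / sum(probs)))]
    current = _choose(rng, model.init[stroke_class])
    ts = start_ts.replace(microsecond=0)
    events: list[tuple[Activity, datetime]] = [(Activity(current), ts)]
    table = model.transitions[stroke_class]
    while True:
        nxt = _choose(rng, table[current])
        if nxt == END_STATE:
            break
        hours = model.delay_for(current, nxt).sample(rng)
        ts = ts + timedelta(seconds=max(1, round(hours * 3600.0)))
        events.append((Activity(nxt), ts))
        current = nxt
    return stroke_class, events


_DX_CODES = {
    "ICD10": {
        StrokeClass.ISCHEMIC: ["I63.0", "I63.3", "I63.4", "I63.5", "I63.9"],
        StrokeClass.HEMORRHAGIC: ["I60.1", "I61.0", "I61.9", "I62.9"],
        StrokeClass.SUSPECTED: ["I64", "G45.9"],
    },
    "ICD9": {
        StrokeClass.ISCHEMIC: ["433.01", "433.11", "434.01", "434.91"],
        StrokeClass.HEMORRHAGIC: ["430", "431", "432.1"],
        StrokeClass.SUSPECTED: ["435.9", "436"],
    },
}
_COMORBIDITY = {"ICD10": "I10", "ICD9": "401.9"}

#: Site-local event code emitted for each clinical activity (the reverse of
#: the default activity map).
_SOURCE_CODES = {
    A.ER_FIRST_ATTENTION: "FIRST_ATTENTION",
    A.ER_CT: "CT_SCAN",
    A.ER_FIBRINOLYSIS: "FIBRINOLYSIS",
    A.ER_THROMBECTOMY: "THROMBECTOMY",
    A.ER_OBSERVATION_ROOM: "OBSERVATION_ROOM",
    A.ER_EXIT: "ER_EXIT",
    A.HOSPITAL_FIBRINOLYSIS: "FIBRINOLYSIS",
    A.HOSPITAL_THROMBECTOMY: "THROMBECTOMY",
}

_SEG_SETTING = {
    Setting.ER: (1, 8),
    Setting.ACUTE_HOSPITAL: (9, 12),
    Setting.LONGSTAY_HOSPITAL: (13, 14),
}


def _setting_of(activity: Activity) -> Setting:
    return activity.setting


def generate_dataset(
    n_cases: int,
    model: PathwayModel | None = None,
    defects: DefectConfig | None = None,
    site_id: str = "S1",
    seed: int = 0,
    coding_system: str = "ICD10",
    period: tuple[date, date] = (date(2019, 1, 1), date(2020, 12, 31)),
) -> tuple[CdmDataset, GroundTruth]:
    """Generate a CDM-conformant site dataset plus its ground-truth ledger.

    Structurally valid before defect injection; byte-identical files for
    identical inputs.  The ledger records every true case (class, timed
    sequence, episode chain) and every injected defect.
    """
    model = model or PathwayModel()
    defects = defects if defects is not None else DefectConfig()
    rng = np.random.default_rng(seed)

    providers = [
        ProviderRecord(f"{site_id}-ER1", Setting.ER, f"{site_id}-AREA1"),
        ProviderRecord(f"{site_id}-H1", Setting.ACUTE_HOSPITAL, f"{site_id}-AREA1"),
        ProviderRecord(f"{site_id}-H2", Setting.ACUTE_HOSPITAL, f"{site_id}-AREA2"),
        ProviderRecord(f"{site_id}-LS1", Setting.LONGSTAY_HOSPITAL, f"{site_id}-AREA1"),
    ]
    acute_ids = [p.provider_id for p in providers if p.setting is Setting.ACUTE_HOSPITAL]
    er_id = providers[0].provider_id
    ls_id = providers[3].provider_id

    patients: list[PatientRecord] = []
    episodes: list[EpisodeRecord] = []
    events: list[EventRecord] = []
    truth_cases: list[TrueCase] = []
    defect_entries: list[dict] = []
    seen_pseudonyms: set[str] = set()
    unmappable_counter = 0

    start_day, end_day = period
    n_days = (end_day - start_day).days

    for i in range(n_cases):
        # pseudonym from the seeded stream, unique within the site
        while True:
            token = "".join(rng.choice(list("0123456789abcdef"), size=8))
            if token not in seen_pseudonyms:
                seen_pseudonyms.add(token)
                break
        patient_id = f"{site_id}-PT{token}"
        case_id = f"{patient_id}#0"
        patients.append(PatientRecord(
            patient_id=patient_id,
            sex="male" if rng.random() < 0.52 else "female",
            birth_year=int(rng.integers(1930, 2001)),
            residence_area_id=f"{site_id}-AREA{int(rng.integers(1, 4))}",
        ))

        onset = datetime.combine(
            start_day + timedelta(days=int(rng.integers(0, n_days + 1))),
            datetime.min.time(),
        ) + timedelta(seconds=int(rng.integers(0, 86400)))
        stroke_class, seq = sample_case(model, rng, onset)

        # --- split the sequence into episodes by care setting -------------
        # each entry keeps its global position in the true sequence so that
        # defect injection can reason about full-sequence adjacency
        segments: list[list[tuple[Activity, datetime, int]]] = []
        for gidx, (act, ts) in enumerate(seq):
            s = _setting_of(act)
            if segments and _setting_of(segments[-1][0][0]) is s:
                segments[-1].append((act, ts, gidx))
            else:
                segments.append([(act, ts, gidx)])

        dx_pool = _DX_CODES[coding_system][stroke_class]
        dx = [dx_pool[int(rng.integers(0, len(dx_pool)))]]
        if rng.random() < 0.4:
            dx.append(_COMORBIDITY[coding_system])

        episode_ids: list[str] = []
        case_events: list[EventRecord] = []
        ev_seq_idx: list[int] = []   # global sequence position of each event row
        case_episodes: list[EpisodeRecord] = []
        for j, segment in enumerate(segments):
            setting = _setting_of(segment[0][0])
            episode_id = f"{case_id}/EP{j}"
            episode_ids.append(episode_id)
            if setting is Setting.ER:
                provider = er_id
            elif setting is Setting.ACUTE_HOSPITAL:
                provider = acute_ids[int(rng.integers(0, len(acute_ids)))]
            else:
                provider = ls_id
            adm_ts = dis_ts = None
            ev_count = 0
            for act, ts, gidx in segment:
                if act in (A.ER_ADMISSION, A.HOSPITAL_ADMISSION, A.LONGSTAY_ADMISSION):
                    adm_ts = ts
                elif act in (A.ER_DISCHARGE, A.HOSPITAL_DISCHARGE, A.LONGSTAY_DISCHARGE):
                    dis_ts = ts
                else:
                    case_events.append(EventRecord(
                        event_id=f"{episode_id}/EV{ev_count}",
                        episode_id=episode_id,
                        source_code=_SOURCE_CODES[act],
                        ts_raw=ts.strftime("%Y-%m-%dT%H:%M:%S"),
                        granularity="datetime",
                    ))
                    ev_seq_idx.append(gidx)
                    ev_count += 1
            is_terminal = j == len(segments) - 1
            if is_terminal:
                discharge_code = "death" if rng.random() < 0.10 else "home"
            else:
                discharge_code = "transfer"
            case_episodes.append(EpisodeRecord(
                episode_id=episode_id,
                patient_id=patient_id,
                provider_id=provider,
                setting=setting,
                admission_ts=adm_ts,
                discharge_ts=dis_ts,
                diagnosis_codes=tuple(dx),
                coding_system=coding_system,
                discharge_code=discharge_code,
            ))

        # --- defect injection ---------------------------------------------
        # timestamp inversion: swap the timestamps of two clinical events
        # that are adjacent in the FULL true sequence (no administrative
        # activity between them) and share an episode — one swap then shows
        # up as exactly one rank descent in the rebuilt case
        if defects.inversion_rate > 0 and rng.random() < defects.inversion_rate:
            for k in range(len(case_events) - 1):
                e1, e2 = case_events[k], case_events[k + 1]
                if (
                    e1.episode_id == e2.episode_id
                    and ev_seq_idx[k + 1] == ev_seq_idx[k] + 1
                    and e1.ts_raw != e2.ts_raw
                ):
                    case_events[k] = dataclasses.replace(e1, ts_raw=e2.ts_raw)
                    case_events[k + 1] = dataclasses.replace(e2, ts_raw=e1.ts_raw)
                    defect_entries.append({
                        "kind": "inversion", "case_id": case_id,
                        "target_id": e1.event_id,
                    })
                    break

        # date-only granularity demotion on clinical events
        if defects.date_only_rate > 0:
            for k, ev in enumerate(case_events):
                if rng.random() < defects.date_only_rate:
                    case_events[k] = dataclasses.replace(
                        ev, ts_raw=ev.ts_raw[:10], granularity="date",
                    )
                    defect_entries.append({
                        "kind": "date_only", "case_id": case_id,
                        "target_id": ev.event_id,
                    })

        # unmappable site-local code
        if defects.unmappable_rate > 0:
            for k, ev in enumerate(case_events):
                if rng.random() < defects.unmappable_rate:
                    unmappable_counter += 1
                    case_events[k] = dataclasses.replace(
                        ev, source_code=f"UNK_{unmappable_counter}",
                    )
                    defect_entries.append({
                        "kind": "unmappable", "case_id": case_id,
                        "target_id": ev.event_id,
                    })

        # missing discharge on the terminal episode
        if defects.missing_discharge_rate > 0 and rng.random() < defects.missing_discharge_rate:
            last = case_episodes[-1]
            if last.discharge_ts is not None:
                case_episodes[-1] = dataclasses.replace(last, discharge_ts=None)
                defect_entries.append({
                    "kind": "missing_discharge", "case_id": case_id,
                    "target_id": last.episode_id,
                })

        episodes.extend(case_episodes)
        events.extend(case_events)
        truth_cases.append(TrueCase(
            case_id=case_id,
            patient_id=patient_id,
            stroke_class=stroke_class,
            events=seq,
            episode_ids=tuple(episode_ids),
        ))

    dataset = CdmDataset(
        patients=patients,
        providers=providers,
        episodes=episodes,
        events=events,
        cdm_version=CDM_VERSION,
        site_id=site_id,
    )
    return dataset, GroundTruth(cases=truth_cases, defects=defect_entries)


def generate_federation(
    n_sites: int,
    n_cases_per_site: int,
    model: PathwayModel | None = None,
    defects: DefectConfig | None = None,
    seed: int = 0,
) -> list[tuple[CdmDataset, GroundTruth]]:
    """Per-site datasets from one shared pathway model.

    Site ids S1..Sn; pseudonym spaces are disjoint by construction (no
    identifier is shared across nodes).  Odd-numbered sites code in ICD-10,
    even-numbered in ICD-9, exercising both code lists.
    """
    model = model or PathwayModel()
    out = []
    for i in range(n_sites):
        out.append(generate_dataset(
            n_cases_per_site,
            model=model,
            defects=defects,
            site_id=f"S{i + 1}",
            seed=(seed + 1000003 * (i + 1)) % (2**31 - 1),
            coding_system="ICD10" if i % 2 == 0 else "ICD9",
        ))
    return out


# ---------------------------------------------------------------------------
# Ledger serialization (same unquoted dialect)
# ---------------------------------------------------------------------------

def write_ground_truth(truth: GroundTruth, data_dir: str | Path) -> None:
    """Write ground_truth.csv (one row per true activity instance) and
    ground_truth_defects.csv next to the CDM tables."""
    data_dir = Path(data_dir)
    lines = ["case_id,patient_id,stroke_class,seq_index,activity,ts"]
    for case in truth.cases:
        for idx, (act, ts) in enumerate(case.events):
            lines.append(
                f"{case.case_id},{case.patient_id},{case.stroke_class.value},"
                f"{idx},{act.value},{ts.strftime('%Y-%m-%dT%H:%M:%S')}"
            )
    (data_dir / "ground_truth.csv").write_text("\n".join(lines) + "\n", encoding="utf-8")

    lines = ["kind,case_id,target_id"]
    for d in truth.defects:
        lines.append(f"{d['kind']},{d['case_id']},{d['target_id']}")
    (data_dir / "ground_truth_defects.csv").write_text(
        "\n".join(lines) + "\n", encoding="utf-8"
    )


def write_site(
    dataset: CdmDataset, truth: GroundTruth, data_dir: str | Path
) -> None:
    """Write the four CDM tables, site metadata and the ground-truth ledger."""
    write_cdm_dir(dataset, data_dir)
    write_ground_truth(truth, data_dir)
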