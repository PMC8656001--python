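"""Cohort selection and stroke classification.

The analysis cohort is every episode that, inside the study period, was
either an emergency-room attendance with symptoms of stroke or a hospital
admission due to stroke.  Membership is decided by matching each
episode's diagnosis codes against configurable ICD-9/ICD-10 prefix sets;
matching is prefix-based and insensitive to dot formatting, so ``I63.4``
and ``I634`` behave identically.

Each care journey is then classified as *ischemic*, *hemorrhagic*,
*suspected* (unconfirmed / TIA) or *unclassified*: confirmed classes take
precedence over suspected, and among confirmed matches the earliest code
position wins (position order approximates diagnostic primacy).
"""

from __future__ import annotations

import enum
from typing import Iterable, Sequence

from .activities import Setting
from .cdm import CdmDataset, EpisodeRecord
from .config import CodeListConfig


class StrokeClass(str, enum.Enum):
    ISCHEMIC = "ischemic"
    HEMORRHAGIC = "hemorrhagic"
    SUSPECTED = "suspected"
    UNCLASSIFIED = "unclassified"


def _normalize(code: str) -> str:
    return code.replace(".", "").upper()


def match_code(code: str, prefix_set: Iterable[str]) -> bool:
    """True iff some configured prefix is a prefix of the dot-stripped code."""
    norm = _normalize(code)
    return any(norm.startswith(_normalize(p)) for p in prefix_set)


def classify_stroke(
    diagnosis_codes: Sequence[str],
    coding_system: str,
    config: CodeListConfig,
) -> StrokeClass:
    """Classify one ordered code list (primary position first).

    Confirmed ischemic/hemorrhagic beat suspected; among confirmed, the
    earliest-position matching code wins.  An empty or non-matching list
    yields ``UNCLASSIFIED``.
    """
    sets = config.prefix_sets(coding_system)
    first_confirmed: StrokeClass | None = None
    saw_suspected = False
    for code in diagnosis_codes:
        if first_confirmed is None:
            if match_code(code, sets["ischemic"]):
                first_confirmed = StrokeClass.ISCHEMIC
            elif match_code(code, sets["hemorrhagic"]):
                first_confirmed = StrokeClass.HEMORRHAGIC
        if match_code(code, sets["suspected"]):
            saw_suspected = True
    if first_confirmed is not None:
        return first_confirmed
    if saw_suspected:
        return StrokeClass.SUSPECTED
    return StrokeClass.UNCLASSIFIED


def episode_matches(episode: EpisodeRecord, config: CodeListConfig) -> bool:
    """True iff any (or the primary, if so configured) diagnosis code of the
    episode falls in any configured stroke code set."""
    sets = config.prefix_sets(episode.coding_system)
    all_prefixes = sets["ischemic"] | sets["hemorrhagic"] | sets["suspected"]
    codes = episode.diagnosis_codes
    if config.primary_position_only:
        codes = codes[:1]
    return any(match_code(c, all_prefixes) for c in codes)


def select_cohort(dataset: CdmDataset, config: CodeListConfig) -> set[str]:
    """Episode ids admitted inside the study period, in the ER or the acute
    hospital, with a matching stroke diagnosis code.

    Deterministic given dataset and configuration; long-stay episodes never
    qualify on their own (they enter the analysis through case linkage).
    """
    start, end = config.study_period
    selected: set[str] = set()
    for ep in dataset.episodes:
        if ep.setting not in (Setting.ER, Setting.ACUTE_HOSPITAL):
            continue
        if not (start <= ep.admission_ts.date() <= end):
            continue
        if episode_matches(ep, config):
            selected.add(ep.episode_id)
    return selected
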