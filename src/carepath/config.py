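"""Analysis configuration: study period, code lists, thresholds, maps.

Comparability across sites in a federated study rests on every node
running the *same* analysis definition.  Everything that can change the
aggregates — stroke code lists, the activity map, the case-linkage gap
threshold, the variant-coverage fraction — lives in one configuration
object whose stable hash (the *fingerprint*) is embedded in every results
bundle so the hub can verify that bundles are comparable.

The default ICD code lists are a documented reconstruction (prefix
matching, dot-insensitive): ischemic ICD-10 {I63} / ICD-9 {433, 434};
hemorrhagic ICD-10 {I60, I61, I62} / ICD-9 {430, 431, 432}; suspected
(including TIA) ICD-10 {I64, G45} / ICD-9 {435, 436}.  They are fully
configurable and recorded in every bundle.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from datetime import date
from pathlib import Path

import yaml

from .activities import Activity, Setting
from .errors import ConfigError


@dataclasses.dataclass(frozen=True)
class CodeListConfig:
    """Study period and ICD-9/ICD-10 prefix sets defining the cohort."""

    study_period: tuple[date, date] = (date(2019, 1, 1), date(2021, 12, 31))
    ischemic_icd9: frozenset[str] = frozenset({"433", "434"})
    ischemic_icd10: frozenset[str] = frozenset({"I63"})
    hemorrhagic_icd9: frozenset[str] = frozenset({"430", "431", "432"})
    hemorrhagic_icd10: frozenset[str] = frozenset({"I60", "I61", "I62"})
    suspected_icd9: frozenset[str] = frozenset({"435", "436"})
    suspected_icd10: frozenset[str] = frozenset({"I64", "G45"})
    primary_position_only: bool = False

    def __post_init__(self):
        start, end = self.study_period
        if start > end:
            raise ConfigError(f"study period start {start} after end {end}")
        for system in ("icd9", "icd10"):
            sets = [
                getattr(self, f"ischemic_{system}"),
                getattr(self, f"hemorrhagic_{system}"),
                getattr(self, f"suspected_{system}"),
            ]
            for i in range(3):
                for j in range(i + 1, 3):
                    overlap = sets[i] & sets[j]
                    if overlap:
                        raise ConfigError(
                            f"{system} prefix sets overlap: {sorted(overlap)}"
                        )

    def prefix_sets(self, coding_system: str) -> dict[str, frozenset[str]]:
        """Class-name -> prefix set for one coding system ('ICD9'/'ICD10')."""
        suffix = "icd9" if coding_system == "ICD9" else "icd10"
        return {
            "ischemic": getattr(self, f"ischemic_{suffix}"),
            "hemorrhagic": getattr(self, f"hemorrhagic_{suffix}"),
            "suspected": getattr(self, f"suspected_{suffix}"),
        }


#: Default map from (setting, site-local event code) to pathway activity.
#: Administrative admissions/discharges are derived from episode timestamps,
#: so only clinical activities appear here.
DEFAULT_ACTIVITY_MAP: dict[tuple[Setting, str], Activity] = {
    (Setting.ER, "FIRST_ATTENTION"): Activity.ER_FIRST_ATTENTION,
    (Setting.ER, "CT_SCAN"): Activity.ER_CT,
    (Setting.ER, "FIBRINOLYSIS"): Activity.ER_FIBRINOLYSIS,
    (Setting.ER, "THROMBECTOMY"): Activity.ER_THROMBECTOMY,
    (Setting.ER, "OBSERVATION_ROOM"): Activity.ER_OBSERVATION_ROOM,
    (Setting.ER, "ER_EXIT"): Activity.ER_EXIT,
    (Setting.ACUTE_HOSPITAL, "FIBRINOLYSIS"): Activity.HOSPITAL_FIBRINOLYSIS,
    (Setting.ACUTE_HOSPITAL, "THROMBECTOMY"): Activity.HOSPITAL_THROMBECTOMY,
}

#: Normalized dictionaries for coded concepts.  Canonical categories map to
#: themselves; site-local synonyms may be added in a config file.
DEFAULT_DICTIONARIES: dict[str, dict[str, str]] = {
    "sex": {
        "male": "male", "female": "female",
        "M": "male", "F": "female", "1": "male", "2": "female",
    },
    "discharge_code": {
        "home": "home", "transfer": "transfer", "death": "death", "other": "other",
        "DOMICILIO": "home", "TRASLADO": "transfer", "EXITUS": "death",
    },
}


@dataclasses.dataclass(frozen=True)
class AnalysisConfig:
    """Everything a node run needs, hashable into a comparability fingerprint."""

    code_lists: CodeListConfig = dataclasses.field(default_factory=CodeListConfig)
    gap_threshold_hours: float = 24.0
    theta: float = 0.95
    min_variant_count: int = 1
    activity_map: dict = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_ACTIVITY_MAP)
    )
    dictionaries: dict = dataclasses.field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_DICTIONARIES.items()}
    )

    def __post_init__(self):
        if not (0.0 < self.theta <= 1.0):
            raise ConfigError(f"theta must be in (0, 1], got {self.theta}")
        if self.gap_threshold_hours <= 0:
            raise ConfigError("gap_threshold_hours must be positive")

    def fingerprint(self) -> str:
        """Stable hash over everything that affects the aggregates."""
        cl = self.code_lists
        payload = {
            "study_period": [d.isoformat() for d in cl.study_period],
            "code_lists": {
                name: sorted(getattr(cl, name))
                for name in (
                    "ischemic_icd9", "ischemic_icd10",
                    "hemorrhagic_icd9", "hemorrhagic_icd10",
                    "suspected_icd9", "suspected_icd10",
                )
            },
            "primary_position_only": cl.primary_position_only,
            "gap_threshold_hours": self.gap_threshold_hours,
            "theta": self.theta,
            "activity_map": sorted(
                [s.value, code, act.value]
                for (s, code), act in self.activity_map.items()
            ),
        }
        blob = json.dumps(payload, sort_keys=True, separators=(",", ":"))
        return hashlib.sha256(blob.encode("utf-8")).hexdigest()[:16]


def _parse_date(text) -> date:
    if isinstance(text, date):
        return text
    try:
        return date.fromisoformat(str(text))
    except ValueError as exc:
        raise ConfigError(f"invalid date {text!r}: {exc}") from exc


def config_from_dict(raw: dict) -> AnalysisConfig:
    """Build an :class:`AnalysisConfig` from a plain (YAML-loaded) mapping."""
    try:
        cl_raw = raw.get("code_lists", {})
        period = cl_raw.get("study_period")
        kwargs = {}
        if period is not None:
            kwargs["study_period"] = (_parse_date(period[0]), _parse_date(period[1]))
        for name in (
            "ischemic_icd9", "ischemic_icd10", "hemorrhagic_icd9",
            "hemorrhagic_icd10", "suspected_icd9", "suspected_icd10",
        ):
            if name in cl_raw:
                kwargs[name] = frozenset(str(c) for c in cl_raw[name])
        if "primary_position_only" in cl_raw:
            kwargs["primary_position_only"] = bool(cl_raw["primary_position_only"])
        code_lists = CodeListConfig(**kwargs)

        activity_map = dict(DEFAULT_ACTIVITY_MAP)
        if "activity_map" in raw:
            activity_map = {}
            for entry in raw["activity_map"]:
                setting, code, act = entry
                activity_map[(Setting(setting), str(code))] = Activity(act)

        dictionaries = {k: dict(v) for k, v in DEFAULT_DICTIONARIES.items()}
        for concept, syns in (raw.get("dictionaries") or {}).items():
            dictionaries.setdefault(concept, {}).update(
                {str(k): str(v) for k, v in syns.items()}
            )

        return AnalysisConfig(
            code_lists=code_lists,
            gap_threshold_hours=float(raw.get("gap_threshold_hours", 24.0)),
            theta=float(raw.get("theta", 0.95)),
            min_variant_count=int(raw.get("min_variant_count", 1)),
            activity_map=activity_map,
            dictionaries=dictionaries,
        )
    except ConfigError:
        raise
    except (KeyError, TypeError, ValueError) as exc:
        raise ConfigError(f"invalid configuration: {exc}") from exc


def load_config(path: str | Path) -> AnalysisConfig:
    """Load an analysis configuration from a YAML file."""
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    return config_from_dict(raw)


def save_config(config: AnalysisConfig, path: str | Path) -> None:
    cl = config.code_lists
    raw = {
        "code_lists": {
            "study_period": [d.isoformat() for d in cl.study_period],
            **{
                name: sorted(getattr(cl, name))
                for name in (
                    "ischemic_icd9", "ischemic_icd10", "hemorrhagic_icd9",
                    "hemorrhagic_icd10", "suspected_icd9", "suspected_icd10",
                )
            },
            "primary_position_only": cl.primary_position_only,
        },
        "gap_threshold_hours": config.gap_threshold_hours,
        "theta": config.theta,
        "min_variant_count": config.min_variant_count,
        "activity_map": sorted(
            [s.value, code, act.value]
            for (s, code), act in config.activity_map.items()
        ),
        "dictionaries": config.dictionaries,
    }
    Path(path).write_text(yaml.safe_dump(raw, sort_keys=True), encoding="utf-8")
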