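"""Common-data-model IO, validation and dictionary normalization."""

from __future__ import annotations

import dataclasses
from datetime import datetime

import pytest
from hypothesis import given, settings, strategies as st

from carepath import (
    CdmDataset,
    EpisodeRecord,
    EventRecord,
    PatientRecord,
    ProviderRecord,
    normalize_code,
    read_cdm_table,
    validate_cdm,
    write_cdm_table,
)
from carepath.activities import Setting
from carepath.cdm import CDM_VERSION, HEADERS, parse_timestamp
from carepath.config import DEFAULT_DICTIONARIES
from carepath.errors import (
    CdmDialectError,
    CdmRowError,
    CdmSchemaError,
    TimestampFormatError,
    UnmappedValueError,
)


def test_events_table_parses_typed_records(tmp_path):
    path = tmp_path / "events.csv"
    path.write_text(
        "event_id,episode_id,source_code,ts_raw,granularity\n"
        "e1,ep1,CT_SCAN,2019-03-05T14:30:00,datetime\n"
        "e2,ep1,FIRST_ATTENTION,2019-03-05,date\n",
        encoding="utf-8",
    )
    records = read_cdm_table(path, "events")
    assert len(records) == 2
    assert records[0] == EventRecord("e1", "ep1", "CT_SCAN",
                                     "2019-03-05T14:30:00", "datetime")
    assert records[1].granularity == "date"


def test_header_with_extra_column_names_the_offender(tmp_path):
    path = tmp_path / "events.csv"
    path.write_text(
        "event_id,episode_id,source_code,ts_raw,granularity,extra\nx,x,x,2019-01-01,date,x\n",
        encoding="utf-8",
    )
    with pytest.raises(CdmSchemaError, match="extra"):
        read_cdm_table(path, "events")


def test_unparseable_row_reports_line_number(tmp_path):
    path = tmp_path / "patients.csv"
    path.write_text(
        ",".join(HEADERS["patients"]) + "\np1,male,notayear,a1\n", encoding="utf-8"
    )
    with pytest.raises(CdmRowError) as err:
        read_cdm_table(path, "patients")
    assert err.value.line_number == 2


def test_value_with_separator_is_a_dialect_error(tmp_path):
    rec = PatientRecord("p1", "male", 1950, "a,b")
    with pytest.raises(CdmDialectError):
        write_cdm_table([rec], tmp_path / "patients.csv", "patients")


def test_empty_collection_writes_header_only(tmp_path):
    path = tmp_path / "providers.csv"
    write_cdm_table([], path, "providers")
    assert path.read_text(encoding="utf-8") == ",".join(HEADERS["providers"]) + "\n"


_id_text = st.text(
    alphabet=st.characters(blacklist_characters=",\n\r",
                           blacklist_categories=("Cs", "Cc")),
    min_size=1, max_size=12,
)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.lists(
    st.tuples(_id_text, st.sampled_from(["male", "female"]),
              st.integers(1900, 2000), _id_text),
    max_size=30,
))
def test_write_then_read_is_identity_on_dialect_legal_patients(tmp_path_factory, rows):
    """Round trip: the strict dialect preserves any comma-free record set."""
    records = [PatientRecord(*r) for r in rows]
    path = tmp_path_factory.mktemp("rt") / "patients.csv"
    write_cdm_table(records, path, "patients")
    assert read_cdm_table(path, "patients") == records


def test_episode_round_trip_preserves_codes_and_missing_discharge(tmp_path):
    ep = EpisodeRecord(
        "ep1", "p1", "pr1", Setting.ER,
        datetime(2019, 3, 5, 10, 0), None,
        ("I63.4", "I10"), "ICD10", "home",
    )
    path = tmp_path / "episodes.csv"
    write_cdm_table([ep], path, "episodes")
    (back,) = read_cdm_table(path, "episodes")
    assert back == ep


@pytest.mark.parametrize("text", ["2019-03-05", "2019-03-05T14:30:00"])
def test_parse_timestamp_accepts_iso(text):
    assert parse_timestamp(text).year == 2019


@pytest.mark.parametrize("text", ["05/03/2019", "2019-3-5", "2019-03-05 14:30:00"])
def test_parse_timestamp_rejects_other_dialects(text):
    with pytest.raises(TimestampFormatError):
        parse_timestamp(text)


def _valid_dataset() -> CdmDataset:
    return CdmDataset(
        patients=[PatientRecord("p1", "male", 1950, "a1")],
        providers=[ProviderRecord("pr1", Setting.ER, "a1")],
        episodes=[EpisodeRecord(
            "ep1", "p1", "pr1", Setting.ER,
            datetime(2019, 3, 5, 10, 0), datetime(2019, 3, 5, 18, 0),
            ("I63.4",), "ICD10", "home",
        )],
        events=[EventRecord("e1", "ep1", "CT_SCAN", "2019-03-05T11:00:00", "datetime")],
        cdm_version=CDM_VERSION, site_id="T",
    )


def test_consistent_dataset_yields_empty_report():
    assert validate_cdm(_valid_dataset()).ok


def test_dangling_event_reference_is_reported():
    ds = _valid_dataset()
    ds.events.append(EventRecord("e2", "missing", "CT_SCAN", "2019-03-05", "date"))
    report = validate_cdm(ds)
    assert [i.kind for i in report.issues] == ["dangling_reference"]
    assert report.issues[0].record_id == "e2"


def test_injected_defects_are_found_exactly():
    """Five injected defects of three kinds -> exactly those five entries."""
    ds = _valid_dataset()
    ds.patients.append(PatientRecord("p1", "female", 1960, "a1"))        # duplicate id
    ds.episodes.append(dataclasses.replace(
        ds.episodes[0], episode_id="ep2", patient_id="ghost",            # dangling
        provider_id="ghost-pr",                                          # dangling
    ))
    ds.episodes.append(dataclasses.replace(
        ds.episodes[0], episode_id="ep3",
        discharge_ts=datetime(2019, 3, 4, 9, 0),                         # before adm
    ))
    ds.patients.append(PatientRecord("p2", "male", 1850, "a1"))          # birth year
    report = validate_cdm(ds)
    assert sorted(report.kinds().items()) == [
        ("birth_year_out_of_range", 1),
        ("dangling_reference", 2),
        ("discharge_before_admission", 1),
        ("duplicate_id", 1),
    ]


def test_normalize_code_maps_synonyms_and_identity():
    assert normalize_code("DOMICILIO", "discharge_code", DEFAULT_DICTIONARIES) == "home"
    assert normalize_code("home", "discharge_code", DEFAULT_DICTIONARIES) == "home"
    with pytest.raises(UnmappedValueError) as err:
        normalize_code("XX9", "discharge_code", DEFAULT_DICTIONARIES)
    assert err.value.value == "XX9"
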