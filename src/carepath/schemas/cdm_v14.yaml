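# Preset headers of the common data model tables, frozen per CDM revision.
# Validation is against this file, never inferred from the data.
cdm_version: "14.0"
headers:
  patients: [patient_id, sex, birth_year, residence_area_id]
  providers: [provider_id, setting, area_id]
  episodes: [episode_id, patient_id, provider_id, setting, admission_ts,
             discharge_ts, diagnosis_codes, coding_system, discharge_code]
  events: [event_id, episode_id, source_code, ts_raw, granularity]
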