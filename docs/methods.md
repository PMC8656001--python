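# Methods

This note documents the models, rules and numerical choices behind
`carepath`, in the order data flows through the package.

## Common data model and exchange dialect

Four linked tables are the interface between a site's local systems and
the analysis: `patients` (pseudonym, sex, birth year, residence area),
`providers` (id, care setting, area), `episodes` (admission/discharge
timestamps, ordered diagnosis codes, coding system, discharge
destination) and `events` (site-local activity code, raw timestamp,
granularity). The residence/healthcare-area entity is folded into
attributes of patients and providers. Headers are frozen in a packaged
schema file versioned as CDM 14.0; validation is always against the
schema, never inferred from data.

The exchange dialect is deliberately rigid so files are bit-comparable
across sites: UTF-8, comma-separated, **no quoting or escaping**. A field
value containing a comma or newline is an error, not something to escape
— cross-site comparability is worth more than dialect generality. Missing
values serialize as the empty string. List-valued diagnosis codes are
pipe-separated (`I63.4|I10`), the only list encoding the unquoted dialect
admits. Timestamps are ISO-8601 text, `YYYY-MM-DD` or
`YYYY-MM-DDTHH:MM:SS`; the event table's explicit granularity column
(`date`/`datetime`) is authoritative over the textual form. Dataset-level
metadata (site id, CDM version) lives in a small `site.yaml` next to the
tables; the reader falls back to the directory name.

Coded concepts (`sex`, `discharge_code`) pass through *normalized
dictionaries*: total, deterministic synonym→canonical maps; a value
outside the declared synonym set is an explicit unmapped-value error.

## Cohort and stroke classification

The cohort is every ER or acute-hospital episode admitted inside the
study period whose diagnosis codes match configurable ICD prefix sets.
Matching is prefix-based after dot-stripping and case-folding, so
`I63.4` ≡ `I634`. The shipped defaults — ischemic ICD-10 {I63} / ICD-9
{433, 434}; hemorrhagic ICD-10 {I60–I62} / ICD-9 {430–432}; suspected
(including TIA) ICD-10 {I64, G45} / ICD-9 {435, 436} — are a documented
reconstruction, pairwise-disjoint by construction and recorded in every
results bundle. Whether only primary-position codes count is a config
flag (default: any position). Classification of a journey scans its
codes in order: a confirmed class (ischemic/hemorrhagic) beats
suspected; among confirmed matches the earliest code position wins,
approximating diagnostic primacy; no match → unclassified. TIA folds
into "suspected" by default.

## Case linkage and the event-log builder

Episodes of one patient chain into one *case* when each next admission
starts within a gap threshold (default 24 h) of the previous discharge
and the settings progress ER → acute hospital → long-stay hospital, with
acute-hospital repeats allowed for transfers. This linkage rule is the
module's central reconstruction — nothing in routine data marks "same
journey" — so it is explicit configuration, hashed into the
comparability fingerprint carried by every bundle. A missing discharge
on a non-terminal episode splits the chain with a warning.

Administrative activities (the three settings' admissions and
discharges) are derived from episode timestamps; clinical activities
come from event rows via the configured (setting, source code) →
activity map. Unmapped events are dropped with a warning and counted in
the build report — the minimum-common-denominator stance — never a
fatal error. Repeated activities stay distinct events so loops remain
visible to discovery. *ER Discharge* (administrative) and *ER Exit*
(physical) are distinct activities; each is emitted only when its
timestamp exists, with no imputation.

Timestamps normalize to date-time granularity: a date-only value becomes
00:00:00 on that date (idempotently). Events order by **(normalized
timestamp, canonical activity rank, source row id)** — a deterministic
total order invariant under input row permutation. The canonical rank is
the activity's position in the expected pathway order (admission before
imaging before treatment before discharge, ER before hospital before
long-stay); it resolves the midnight ties that date-only granularity
creates in favour of the clinically expected sequence.

Consistency checking flags every adjacent pair whose canonical rank
decreases along the built order. This one rule subsumes the concrete
irregularities of interest — a discharge timestamped before its
admission, a hospital admission before the ER admission, an ER exit
before ER admission — and, because the default synthetic pathways are
rank-monotone, makes injected timestamp swaps detectable one-for-one.

## Process discovery

Let a case's trace be its activity-name sequence. The pipeline computes:

- **Variants**: exact-sequence equivalence classes, ordered by
  descending case count then lexicographic sequence; shares sum to 1.
- **Directly-follows process map**: for trace e₁…eₙ the transitions
  START→e₁, eᵢ→eᵢ₊₁, eₙ→END each count once. Node absolute frequency
  counts event instances; case frequency counts distinct cases. Flow
  conservation (inflow = outflow = absolute frequency at every real
  node) holds by construction and is property-tested.
- **Throughput times**: per-edge differences of normalized timestamps in
  hours; median, mean, q1, q3 (linear-interpolation quantiles). Zero
  durations are legal and included — date-only granularity makes them
  common, and excluding them would bias medians upward. START/END edges
  carry no durations.
- **Precedence matrix**: the same counts as a (START + 14 + END)²
  integer matrix; real entries sum to events − cases, START row and END
  column each sum to cases.

The **coverage filter** retains the shortest frequency-ordered variant
prefix whose cumulative case count reaches θ (default 0.95) — minimal by
construction — then recomputes every downstream aggregate on the
retained cases only. Filtering is by *case* coverage over variants, the
standard trace-frequency reading; cumulative *event*-share filtering
would be a one-line change but is not exposed. Arithmetic uses integer
case counts against θ·total with a relative epsilon (1e-9·total) so that
exactly 95 of 100 cases meets θ = 0.95 despite binary rounding. θ = 1
reduces to the identity. START/END never appear as activities; the
exported vocabulary is exactly the 14 pathway activities.

## Federation

A node run executes validate → cohort → build → mine per stratum (all /
ischemic / hemorrhagic / suspected) and writes one JSON bundle per
stratum plus a static HTML dashboard (traces, map, throughput,
precedence matrix). Bundles carry only aggregates: counts, shares,
statistics, warning *kind counts* (never messages, which could quote
record ids), plus the site id, CDM version and the configuration
fingerprint — a SHA-256 over code lists, activity map, gap threshold and
θ — so the hub can verify comparability. The disclosure check is
structural (a fixed allow-list of bundle keys; a smuggled record list
fails) with optional small-cell flagging below a configurable minimum
variant count (default 1 = off, matching a coverage-only regime).

Hub aggregation requires one stratum and distinct site ids, flags
fingerprint mismatches, sums counts element-wise, normalizes shares per
site, and reports per-edge cross-site dispersion (min/max/mean/sd of
shares) — the dispersion summary is a reconstruction of what a
coordinating analyst would inspect, labelled as such. With θ = 1 and
disjoint case sets the pooled map equals mining the concatenated logs
(exact integer identity, tested); with θ < 1 it is labelled "sum of
filtered site models" because per-site filtering breaks the identity in
general. Exchange is by files on disk; there is deliberately no network
layer.

## Synthetic generator

The generator exists so every module is testable with known ground
truth; it claims no epidemiological fidelity. Each synthetic patient
carries exactly one journey (two strokes within the gap threshold would
merge under the linkage rule, making chain recovery ill-posed). A
journey is drawn from a per-class timed Markov chain over the activity
vocabulary, rank-monotone by construction: ER admission → first
attention → CT → {fibrinolysis | thrombectomy | observation | none} →
discharge → exit → possible hospital admission (or direct hospital
entry, 8–10% for confirmed strokes) → possible in-hospital reperfusion →
discharge → possible long-stay episode. Hemorrhagic cases are barred
from fibrinolysis (contraindicated). Class mix defaults to 60% ischemic
/ 20% hemorrhagic / 20% suspected. All probabilities are in one editable
`PathwayModel`.

Delays are log-normal for in-episode hyper-acute steps (e.g. median 15
min admission→first attention, 30 min first-attention→CT, σ ≈ 0.4–0.6 on
the log scale) and exponential for stays and inter-episode gaps (mean
96 h hospital stay, 14 days long-stay). Inter-episode gap delays are
rejection-capped below the 24 h linkage threshold (2 h discharge→exit +
19 h exit→hospital-admission; 21 h to long-stay) so generated chains are
linkable by construction; `Delay.mean()`/`sd()` return the exact
truncated moments (closed forms via the normal CDF / exponential
integrals, verified against simulation), so recovery tests compare
against the true generating values with no slack. Timestamps round to
whole seconds with a one-second floor, keeping written files exactly
reproducible.

Defect injection emulates the data-quality problems of routine records:
date-only granularity demotion (default 10% of clinical events; episode
timestamps keep full granularity), one swapped timestamp pair in 3% of
cases (swapped events are chosen adjacent in the full sequence so each
swap yields exactly one rank-descent flag), unmappable local codes (2%),
missing terminal discharges (2%). Every injection is ledgered, and the
ledger (plus the per-event ground truth) is written in the same CSV
dialect next to the CDM tables.

What passing tests on this generator do **not** show: robustness to real
coding practice (miscoded or evolving ICD use), to episodes missing from
source systems, to multi-journey patients, or to linkage rules other
than the configured one. The generator's defect families are the ones
the builder explicitly handles; real data will contain others.

## Numerical and design choices

- Quantiles: NumPy linear interpolation; medians are the robust headline
  statistic given midnight-normalized timestamps, but means are exported
  too since the field's dashboards vary.
- Determinism: a single seeded `numpy` generator drives all sampling;
  identical inputs give byte-identical CDM files. Sorting keys are total
  orders everywhere (variant ordering, event ordering, bundle
  aggregation after sorting by site id), so outputs are
  permutation-invariant in their inputs.
- Degenerate inputs: an empty cohort yields an empty log and a
  zero-case bundle; an empty log yields empty variant lists and all-zero
  matrices; a single-variant log retains that variant at any θ.
- Problem sizes in tests: oracle-equivalence runs 100 random logs of ≤50
  cases; parameter recovery mines 2,000 generated cases and checks every
  branch probability within 3 binomial standard errors of the true p and
  every well-populated edge's mean throughput within 3·sd/√n of the
  generating mean, using the generating distribution's analytic sd
  (sample-sd standard errors are miscalibrated for right-skewed delays
  at n ≈ 30: samples that land low also have small sd, inflating |z|).
- Exit codes of the CLI: 0 success, 2 validation failure, 3
  configuration error.

## Known limitations

The linkage rule, code lists and activity map are reconstructions that
real federations would have to negotiate; the package makes them
explicit configuration rather than claiming the "right" values. The
pooled model under θ < 1 is not a pooled-mining result and is labelled
accordingly. The precedence matrix is restricted to the closed
14-activity vocabulary; site-local activities outside the map are
dropped, not discovered. There is no conformance checking against a
normative Code Stroke model — comparison with guidelines remains an
inspection task on the exported views.
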