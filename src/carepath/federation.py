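"""Node-side runs and hub-side aggregation of disclosure-safe bundles.

Each data hub (participating site) runs the whole pipeline on its own
premises — validate, select the cohort, build the event log, mine — once
per stratum (all patients, ischemic, hemorrhagic, suspected), and ships
only a *results bundle*: aggregate counts, the filtered variant list,
the process map, the precedence matrix and a run log of warning counts.
No patient-, episode- or event-level record ever leaves the node; the
exchange is files on disk, mirroring the study's manual dashboard
exchange, with no network layer.

The coordination hub merges bundles of one stratum: pooled counts are
element-wise sums, per-site shares are normalized against each site's
own case total, and cross-site dispersion of edge shares and throughput
medians is summarized.  With coverage filtering active (theta < 1) the
pooled model is the sum of *filtered* site models, which is not in
general the model of pooled mining; the hub labels it accordingly.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .activities import END, START
from .cdm import CdmDataset, read_cdm_dir, validate_cdm
from .cohort import StrokeClass, select_cohort
from .config import AnalysisConfig
from .errors import AggregationError, NodeRunError
from .eventlog import BuildReport, build_event_log
from .mining import (
    MATRIX_LABELS,
    MiningResult,
    ThroughputStats,
    mine,
)

BUNDLE_SCHEMA_VERSION = "1.0"

STRATA: tuple[str, ...] = ("all", "ischemic", "hemorrhagic", "suspected")

#: Exactly the keys a serialized bundle may carry; anything else fails the
#: disclosure check structurally.
_ALLOWED_KEYS = {
    "schema_version", "site_id", "cdm_version", "config_fingerprint",
    "stratum", "case_total", "retained_case_total", "theta",
    "variants", "nodes", "edges", "precedence_matrix", "matrix_labels",
    "build_summary", "run_log",
}


@dataclasses.dataclass
class ResultsBundle:
    """Aggregate-only artifact one node ships to the hub for one stratum."""

    site_id: str
    cdm_version: str
    config_fingerprint: str
    stratum: str
    case_total: int
    retained_case_total: int
    theta: float
    variants: list[dict]                    # {sequence, case_count, share}
    nodes: dict[str, dict]                  # activity -> {absolute_frequency, case_frequency}
    edges: list[dict]                       # {source, target, frequency, case_frequency, throughput?}
    precedence_matrix: list[list[int]]
    matrix_labels: list[str]
    build_summary: dict                     # counts only
    run_log: list[dict]                     # [{kind, count}] — never record-level
    schema_version: str = BUNDLE_SCHEMA_VERSION

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    @classmethod
    def from_dict(cls, raw: dict) -> "ResultsBundle":
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in raw.items() if k in known})

    @classmethod
    def from_json(cls, text: str) -> "ResultsBundle":
        return cls.from_dict(json.loads(text))


def _throughput_dict(stats: ThroughputStats | None) -> dict | None:
    if stats is None:
        return None
    return {
        "median_hours": stats.median, "mean_hours": stats.mean,
        "q1_hours": stats.q1, "q3_hours": stats.q3, "n": stats.n,
    }


def bundle_from_result(
    result: MiningResult,
    *,
    site_id: str,
    cdm_version: str,
    fingerprint: str,
    stratum: str,
    build_report: BuildReport | None = None,
) -> ResultsBundle:
    """Serialize one stratum's mining result into a disclosure-safe bundle."""
    report = build_report or BuildReport()
    return ResultsBundle(
        site_id=site_id,
        cdm_version=cdm_version,
        config_fingerprint=fingerprint,
        stratum=stratum,
        case_total=result.case_total,
        retained_case_total=result.retained_case_total,
        theta=result.theta,
        variants=[
            {
                "sequence": list(v.sequence),
                "case_count": v.case_count,
                "share": v.share,
            }
            for v in result.variants
        ],
        nodes={
            name: {
                "absolute_frequency": s.absolute_frequency,
                "case_frequency": s.case_frequency,
            }
            for name, s in result.model.nodes.items()
        },
        edges=[
            {
                "source": a, "target": b,
                "frequency": s.frequency, "case_frequency": s.case_frequency,
                "throughput": _throughput_dict(s.throughput),
            }
            for (a, b), s in result.model.edges.items()
        ],
        precedence_matrix=result.matrix.counts.tolist(),
        matrix_labels=list(result.matrix.labels),
        build_summary={
            "n_cases": report.n_cases,
            "n_events": report.n_events,
            "n_dropped_events": report.n_dropped_events,
        },
        run_log=[
            {"kind": kind, "count": count}
            for kind, count in sorted(report.warning_counts().items())
        ],
    )


# ---------------------------------------------------------------------------
# Node run
# ---------------------------------------------------------------------------

_STRATUM_CLASS = {
    "all": None,
    "ischemic": StrokeClass.ISCHEMIC,
    "hemorrhagic": StrokeClass.HEMORRHAGIC,
    "suspected": StrokeClass.SUSPECTED,
}


def run_node_dataset(
    dataset: CdmDataset, config: AnalysisConfig
) -> tuple[dict[str, ResultsBundle], BuildReport]:
    """Run validate -> cohort -> event log -> mine per stratum, in memory.

    Raises :class:`NodeRunError` (carrying the validation report) when the
    dataset breaks the data-model invariants.
    """
    report = validate_cdm(dataset)
    if not report.ok:
        raise NodeRunError(
            f"data-model validation failed with {len(report.issues)} issue(s)",
            report=report,
        )
    cohort_ids = select_cohort(dataset, config.code_lists)
    log, build_report = build_event_log(dataset, cohort_ids, config)
    fingerprint = config.fingerprint()
    bundles: dict[str, ResultsBundle] = {}
    for stratum in STRATA:
        sub = log.subset(_STRATUM_CLASS[stratum])
        result = mine(sub, theta=config.theta)
        bundles[stratum] = bundle_from_result(
            result,
            site_id=dataset.site_id,
            cdm_version=dataset.cdm_version,
            fingerprint=fingerprint,
            stratum=stratum,
            build_report=build_report,
        )
    return bundles, build_report


def run_node(
    data_dir: str | Path,
    config: AnalysisConfig,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Node-side entry point: read CDM files, run all strata, write bundles
    and a human-readable dashboard.  Returns stratum -> bundle path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    dataset = read_cdm_dir(data_dir)
    bundles, _ = run_node_dataset(dataset, config)
    paths: dict[str, Path] = {}
    for stratum, bundle in bundles.items():
        path = out_dir / f"bundle_{stratum}.json"
        path.write_text(bundle.to_json(), encoding="utf-8")
        paths[stratum] = path
    dashboard = render_dashboard(list(bundles.values()))
    (out_dir / "dashboard.html").write_text(dashboard, encoding="utf-8")
    return paths


# ---------------------------------------------------------------------------
# Disclosure check
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class DisclosureReport:
    ok: bool
    structural_problems: list[str]
    small_count_flags: list[dict]


def disclosure_check(
    bundle_raw: dict | ResultsBundle, min_count: int = 1
) -> DisclosureReport:
    """Verify a bundle is aggregate-only.

    Structural: the serialized object may carry only the known aggregate
    keys (a smuggled event list or identifier field fails).  Optionally
    flags retained variants with fewer than ``min_count`` cases; the
    default 1 disables the flagging, matching a coverage-only disclosure
    regime.
    """
    raw = bundle_raw.to_dict() if isinstance(bundle_raw, ResultsBundle) else bundle_raw
    problems = [f"disallowed key: {k}" for k in sorted(set(raw) - _ALLOWED_KEYS)]
    for key in ("case_total", "retained_case_total"):
        if not isinstance(raw.get(key), int):
            problems.append(f"missing or non-integer {key}")
    for entry in raw.get("run_log", []):
        if not isinstance(entry, dict) or set(entry) != {"kind", "count"}:
            problems.append("run_log entries must be {kind, count} aggregates")
            break
    flags = []
    if min_count > 1:
        for v in raw.get("variants", []):
            if v.get("case_count", 0) < min_count:
                flags.append({
                    "sequence": v.get("sequence"),
                    "case_count": v.get("case_count"),
                    "min_count": min_count,
                })
    return DisclosureReport(
        ok=not problems, structural_problems=problems, small_count_flags=flags
    )


# ---------------------------------------------------------------------------
# Hub aggregation
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class HubComparison:
    """Aligned cross-site tables and the pooled (summed) model."""

    stratum: str
    site_ids: list[str]
    case_totals: dict[str, int]
    variant_shares: pd.DataFrame        # index: trace string, columns: sites
    edge_frequencies: pd.DataFrame      # index: "a -> b", columns: sites (counts)
    edge_shares: pd.DataFrame           # counts / site case_total
    throughput_medians: pd.DataFrame    # hours; NaN where a site lacks the edge
    pooled_nodes: dict[str, dict]
    pooled_edges: dict[tuple[str, str], int]
    pooled_matrix: np.ndarray
    matrix_labels: list[str]
    pooled_case_total: int
    edge_dispersion: pd.DataFrame       # per-edge min/max/mean/sd of shares
    fingerprint_mismatch: bool
    pooled_label: str


def hub_aggregate(bundles: Sequence[ResultsBundle]) -> HubComparison:
    """Merge one stratum's bundles from several sites.

    Pooled counts are element-wise sums; per-site shares are normalized
    against each site's own case total; tables are aligned on the closed
    activity vocabulary with explicit zeros.  Mixed strata or duplicate
    site ids are errors; differing fingerprints are allowed but flagged.
    Permutation-invariant in bundle order.
    """
    if not bundles:
        raise AggregationError("no bundles to aggregate")
    strata = {b.stratum for b in bundles}
    if len(strata) > 1:
        raise AggregationError(f"mixed strata: {sorted(strata)}")
    site_ids = [b.site_id for b in bundles]
    if len(set(site_ids)) != len(site_ids):
        raise AggregationError(f"duplicate site ids: {sorted(site_ids)}")
    order = sorted(range(len(bundles)), key=lambda i: site_ids[i])
    bundles = [bundles[i] for i in order]
    site_ids = [b.site_id for b in bundles]
    fingerprints = {b.config_fingerprint for b in bundles}

    case_totals = {b.site_id: b.case_total for b in bundles}
    retained_totals = {b.site_id: max(b.retained_case_total, 1) for b in bundles}

    # variant share table (share of retained cases, per site)
    variant_rows: dict[str, dict[str, float]] = {}
    for b in bundles:
        for v in b.variants:
            key = " -> ".join(v["sequence"])
            variant_rows.setdefault(key, {})[b.site_id] = (
                v["case_count"] / retained_totals[b.site_id]
            )
    variant_shares = pd.DataFrame.from_dict(
        variant_rows, orient="index", columns=site_ids
    ).fillna(0.0).sort_index()

    # edge tables aligned on the closed vocabulary
    label_pairs = [
        (a, b)
        for a in MATRIX_LABELS for b in MATRIX_LABELS
        if a != END and b != START
    ]
    index = [f"{a} -> {b}" for a, b in label_pairs]
    freq = pd.DataFrame(0, index=index, columns=site_ids, dtype=int)
    medians = pd.DataFrame(np.nan, index=index, columns=site_ids, dtype=float)
    for b in bundles:
        for e in b.edges:
            key = f"{e['source']} -> {e['target']}"
            freq.loc[key, b.site_id] = e["frequency"]
            if e.get("throughput"):
                medians.loc[key, b.site_id] = e["throughput"]["median_hours"]
    shares = freq.astype(float)
    for sid in site_ids:
        shares[sid] = freq[sid] / max(case_totals[sid], 1)

    observed = freq.sum(axis=1) > 0
    freq = freq.loc[observed]
    shares = shares.loc[observed]
    medians = medians.loc[observed]

    dispersion = pd.DataFrame({
        "min": shares.min(axis=1),
        "max": shares.max(axis=1),
        "mean": shares.mean(axis=1),
        "sd": shares.std(axis=1, ddof=0),
    })

    # pooled model: element-wise sums
    pooled_nodes: dict[str, dict] = {}
    for b in bundles:
        for name, s in b.nodes.items():
            agg = pooled_nodes.setdefault(
                name, {"absolute_frequency": 0, "case_frequency": 0}
            )
            agg["absolute_frequency"] += s["absolute_frequency"]
            agg["case_frequency"] += s["case_frequency"]
    pooled_edges: dict[tuple[str, str], int] = {}
    for b in bundles:
        for e in b.edges:
            pair = (e["source"], e["target"])
            pooled_edges[pair] = pooled_edges.get(pair, 0) + e["frequency"]
    labels = list(bundles[0].matrix_labels)
    pooled_matrix = np.zeros((len(labels), len(labels)), dtype=np.int64)
    for b in bundles:
        if list(b.matrix_labels) != labels:
            raise AggregationError("bundles disagree on the activity vocabulary")
        pooled_matrix += np.asarray(b.precedence_matrix, dtype=np.int64)

    theta = bundles[0].theta
    pooled_label = (
        "pooled model (theta = 1: equals mining the concatenated logs)"
        if theta >= 1.0
        else "sum of filtered site models (theta < 1: NOT pooled-mining equivalent)"
    )
    return HubComparison(
        stratum=bundles[0].stratum,
        site_ids=site_ids,
        case_totals=case_totals,
        variant_shares=variant_shares,
        edge_frequencies=freq,
        edge_shares=shares,
        throughput_medians=medians,
        pooled_nodes=pooled_nodes,
        pooled_edges=pooled_edges,
        pooled_matrix=pooled_matrix,
        matrix_labels=labels,
        pooled_case_total=sum(b.retained_case_total for b in bundles),
        edge_dispersion=dispersion,
        fingerprint_mismatch=len(fingerprints) > 1,
        pooled_label=pooled_label,
    )


# ---------------------------------------------------------------------------
# Dashboard rendering
# ---------------------------------------------------------------------------

def _html_table(headers: list[str], rows: list[list]) -> str:
    head = "".join(f"<th>{h}</th>" for h in headers)
    body = "\n".join(
        "<tr>" + "".join(f"<td>{c}</td>" for c in row) + "</tr>" for row in rows
    )
    return f"<table border='1' cellspacing='0'><tr>{head}</tr>\n{body}</table>"


def render_dashboard(bundles: Sequence[ResultsBundle]) -> str:
    """Static HTML with the four per-stratum views: traces, process map
    edges, throughput times, precedence matrix."""
    parts = [
        "<html><head><meta charset='utf-8'><title>Care pathway dashboard</title>",
        "<style>body{font-family:sans-serif} table{margin:1em 0;"
        "border-collapse:collapse} td,th{padding:2px 8px}</style></head><body>",
    ]
    for b in bundles:
        parts.append(
            f"<h1>Site {b.site_id} — stratum: {b.stratum}</h1>"
            f"<p>cases: {b.case_total} (retained after {b.theta:.0%} coverage "
            f"filter: {b.retained_case_total}) — config {b.config_fingerprint}</p>"
        )
        parts.append("<h2>Process traces</h2>")
        parts.append(_html_table(
            ["trace", "cases", "share"],
            [
                [" → ".join(v["sequence"]), v["case_count"], f"{v['share']:.1%}"]
                for v in b.variants
            ],
        ))
        parts.append("<h2>Process map (directly-follows frequencies)</h2>")
        parts.append(_html_table(
            ["from", "to", "transitions", "cases"],
            [
                [e["source"], e["target"], e["frequency"], e["case_frequency"]]
                for e in b.edges
            ],
        ))
        parts.append("<h2>Throughput times (hours)</h2>")
        parts.append(_html_table(
            ["from", "to", "median", "mean", "q1", "q3", "n"],
            [
                [
                    e["source"], e["target"],
                    f"{e['throughput']['median_hours']:.2f}",
                    f"{e['throughput']['mean_hours']:.2f}",
                    f"{e['throughput']['q1_hours']:.2f}",
                    f"{e['throughput']['q3_hours']:.2f}",
                    e["throughput"]["n"],
                ]
                for e in b.edges if e.get("throughput")
            ],
        ))
        parts.append("<h2>Precedence matrix</h2>")
        matrix_rows = [
            [label] + list(row)
            for label, row in zip(b.matrix_labels, b.precedence_matrix)
        ]
        parts.append(_html_table([""] + list(b.matrix_labels), matrix_rows))
    parts.append("</body></html>")
    return "\n".join(parts)
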