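"""Process discovery on the event log.

The pipeline computes four aggregate views of an event log:

* **trace variants** — equivalence classes of cases sharing an identical
  activity sequence, with counts and shares;
* the **process map** — the directly-follows graph: edge a→b counts how
  often activity b immediately follows a within a case, with virtual
  START/END bookkeeping nodes so that flow is conserved at every real
  node;
* **throughput times** — per-edge elapsed-time statistics (median, mean,
  quartiles, in hours) over the normalized timestamps; zero durations
  from date-only granularity are legal and included;
* the **precedence matrix** — the same directly-follows counts as a
  square activity-by-activity integer matrix.

Before publication the variant list is cut to the smallest
frequency-ordered prefix covering at least a fraction ``theta`` of the
cases (default 0.95), and every downstream aggregate is recomputed on
the retained cases only: a lone patient following a singular pathway
never reaches the published aggregates.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .activities import ACTIVITIES, END, START
from .errors import ConfigError
from .eventlog import EventLog


@dataclasses.dataclass(frozen=True)
class Variant:
    sequence: tuple[str, ...]
    case_count: int
    share: float


@dataclasses.dataclass(frozen=True)
class NodeStats:
    absolute_frequency: int     # event instances of the activity
    case_frequency: int         # distinct cases containing it


@dataclasses.dataclass(frozen=True)
class ThroughputStats:
    median: float
    mean: float
    q1: float
    q3: float
    n: int


@dataclasses.dataclass(frozen=True)
class EdgeStats:
    frequency: int              # directly-follows transition count
    case_frequency: int         # distinct cases with the transition
    throughput: ThroughputStats | None = None


@dataclasses.dataclass
class ProcessModel:
    """Directly-follows graph with frequencies and optional throughput."""

    nodes: dict[str, NodeStats]
    edges: dict[tuple[str, str], EdgeStats]
    case_total: int


#: Row/column labels of the precedence matrix: START, the 14 activities in
#: canonical order, END.
MATRIX_LABELS: tuple[str, ...] = (START, *(a.value for a in ACTIVITIES), END)


@dataclasses.dataclass
class PrecedenceMatrix:
    labels: tuple[str, ...]
    counts: np.ndarray          # square int matrix, counts[i, j] = i -> j

    def entry(self, a: str, b: str) -> int:
        return int(self.counts[self.labels.index(a), self.labels.index(b)])


def enumerate_variants(log: EventLog) -> list[Variant]:
    """Group cases by exact activity sequence.

    Ordered by descending case count, then lexicographic sequence; shares
    sum to 1 over a non-empty log.
    """
    counts: dict[tuple[str, ...], int] = {}
    for case in log.cases:
        trace = case.trace
        counts[trace] = counts.get(trace, 0) + 1
    total = len(log.cases)
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return [Variant(seq, n, n / total) for seq, n in ordered]


def _transitions(trace: Sequence[str]):
    yield (START, trace[0])
    for a, b in zip(trace, trace[1:]):
        yield (a, b)
    yield (trace[-1], END)


def build_process_map(log: EventLog) -> ProcessModel:
    """Count the directly-follows graph of the log.

    For a case with activities e1..en the transitions START→e1, ei→ei+1,
    en→END are each counted once; node absolute frequency counts event
    instances, case frequency counts distinct cases.
    """
    node_abs: dict[str, int] = {}
    node_cases: dict[str, int] = {}
    edge_freq: dict[tuple[str, str], int] = {}
    edge_cases: dict[tuple[str, str], int] = {}
    for case in log.cases:
        trace = case.trace
        if not trace:
            continue
        for a in trace:
            node_abs[a] = node_abs.get(a, 0) + 1
        for a in set(trace):
            node_cases[a] = node_cases.get(a, 0) + 1
        pairs = list(_transitions(trace))
        for pair in pairs:
            edge_freq[pair] = edge_freq.get(pair, 0) + 1
        for pair in set(pairs):
            edge_cases[pair] = edge_cases.get(pair, 0) + 1
    nodes = {
        a: NodeStats(node_abs[a], node_cases[a]) for a in sorted(node_abs)
    }
    edges = {
        pair: EdgeStats(edge_freq[pair], edge_cases[pair])
        for pair in sorted(edge_freq)
    }
    return ProcessModel(nodes=nodes, edges=edges, case_total=len(log.cases))


def compute_throughput(log: EventLog) -> dict[tuple[str, str], ThroughputStats]:
    """Per directly-follows pair: duration statistics in hours.

    Durations are differences of normalized timestamps along consecutive
    events of a case (non-negative by the builder's ordering); START/END
    transitions carry no duration.  Quartiles use linear interpolation.
    """
    samples: dict[tuple[str, str], list[float]] = {}
    for case in log.cases:
        for prev, cur in zip(case.events, case.events[1:]):
            pair = (prev.activity.value, cur.activity.value)
            hours = (cur.ts - prev.ts).total_seconds() / 3600.0
            samples.setdefault(pair, []).append(hours)
    out: dict[tuple[str, str], ThroughputStats] = {}
    for pair in sorted(samples):
        arr = np.asarray(samples[pair], dtype=float)
        q1, med, q3 = np.percentile(arr, [25.0, 50.0, 75.0])
        out[pair] = ThroughputStats(
            median=float(med), mean=float(arr.mean()),
            q1=float(q1), q3=float(q3), n=arr.size,
        )
    return out


def precedence_matrix(log: EventLog) -> PrecedenceMatrix:
    """The directly-follows counts as a square activity-by-activity matrix.

    A view of the same count set as :func:`build_process_map`: the sum of
    real-activity entries equals total events minus number of cases, and
    the START row and END column each sum to the number of cases.
    """
    index = {name: i for i, name in enumerate(MATRIX_LABELS)}
    counts = np.zeros((len(MATRIX_LABELS), len(MATRIX_LABELS)), dtype=np.int64)
    for case in log.cases:
        trace = case.trace
        if not trace:
            continue
        for a, b in _transitions(trace):
            counts[index[a], index[b]] += 1
    return PrecedenceMatrix(labels=MATRIX_LABELS, counts=counts)


def filter_coverage(variants: list[Variant], theta: float = 0.95) -> list[Variant]:
    """Shortest frequency-ordered variant prefix whose cumulative share
    reaches ``theta``.

    Minimal by construction: dropping the last retained variant would take
    the cumulative share below ``theta`` (unless a single variant alone
    exceeds it).  ``theta`` = 1.0 retains everything.
    """
    if not (0.0 < theta <= 1.0):
        raise ConfigError(f"theta must be in (0, 1], got {theta}")
    total = sum(v.case_count for v in variants)
    # integer case counts against theta*total, with a relative epsilon so
    # that e.g. 95 of 100 cases meets theta=0.95 despite binary rounding
    target = theta * total - 1e-9 * max(total, 1)
    retained: list[Variant] = []
    cumulative = 0
    for v in variants:
        retained.append(v)
        cumulative += v.case_count
        if cumulative >= target:
            break
    return retained


@dataclasses.dataclass
class MiningResult:
    """All aggregate outputs of one pipeline run on one (sub-)log."""

    variants: list[Variant]                 # retained (post-filter) variants
    all_variants: list[Variant]             # complete pre-filter list
    model: ProcessModel                     # on retained cases, with throughput
    matrix: PrecedenceMatrix                # on retained cases
    throughput: dict[tuple[str, str], ThroughputStats]
    case_total: int                         # pre-filter
    retained_case_total: int
    theta: float


def mine(log: EventLog, theta: float = 0.95) -> MiningResult:
    """Run the whole pipeline: variants, coverage filter, map, matrix, times.

    Filtering selects the cases belonging to retained variants; every
    downstream aggregate is computed on the filtered case set.  With
    ``theta`` = 1.0 the outputs equal the unfiltered pipeline's.
    """
    all_variants = enumerate_variants(log)
    retained = filter_coverage(all_variants, theta)
    retained_seqs = {v.sequence for v in retained}
    filtered = EventLog(
        cases=[c for c in log.cases if c.trace in retained_seqs],
        site_id=log.site_id,
        fingerprint=log.fingerprint,
    )
    model = build_process_map(filtered)
    throughput = compute_throughput(filtered)
    for pair, stats in throughput.items():
        if pair in model.edges:
            e = model.edges[pair]
            model.edges[pair] = EdgeStats(e.frequency, e.case_frequency, stats)
    return MiningResult(
        variants=retained,
        all_variants=all_variants,
        model=model,
        matrix=precedence_matrix(filtered),
        throughput=throughput,
        case_total=len(log.cases),
        retained_case_total=len(filtered.cases),
        theta=theta,
    )


def to_dot(model: ProcessModel) -> str:
    """Render the process map in DOT format (edge labels: frequency and
    median throughput hours where available)."""
    lines = ["digraph process_map {", '  rankdir="TB";']
    for name, stats in model.nodes.items():
        lines.append(
            f'  "{name}" [label="{name}\\n{stats.absolute_frequency}"];'
        )
    lines.append(f'  "{START}" [shape=circle];')
    lines.append(f'  "{END}" [shape=doublecircle];')
    for (a, b), stats in model.edges.items():
        label = str(stats.frequency)
        if stats.throughput is not None:
            label += f"\\n{stats.throughput.median:.1f} h"
        lines.append(f'  "{a}" -> "{b}" [label="{label}"];')
    lines.append("}")
    return "\n".join(lines)
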