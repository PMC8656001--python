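"""Process discovery: variants, map, throughput, matrix, coverage filter."""

from __future__ import annotations

from datetime import datetime

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from carepath import (
    build_process_map,
    compute_throughput,
    enumerate_variants,
    filter_coverage,
    mine,
    precedence_matrix,
)
from carepath.activities import END, START
from carepath.errors import ConfigError
from carepath.eventlog import EventLog
from carepath.mining import MATRIX_LABELS, Variant
from conftest import ABC, make_case, make_log, random_log
from oracles import oracle_edges, oracle_matrix, oracle_nodes, oracle_variants


def test_variants_group_and_order():
    log = make_log([["A", "B"], ["A", "B"], ["A", "C"]])
    variants = enumerate_variants(log)
    assert [(v.sequence, v.case_count) for v in variants] == [
        ((ABC["A"], ABC["B"]), 2),
        ((ABC["A"], ABC["C"]), 1),
    ]
    assert sum(v.share for v in variants) == pytest.approx(1.0)


def test_single_case_is_one_variant_with_share_one():
    (v,) = enumerate_variants(make_log([["A", "B", "C"]]))
    assert v.case_count == 1 and v.share == 1.0


def test_process_map_single_case_chain():
    log = make_log([["A", "B", "C"]])
    model = build_process_map(log)
    a, b, c = ABC["A"], ABC["B"], ABC["C"]
    assert {p: s.frequency for p, s in model.edges.items()} == {
        (START, a): 1, (a, b): 1, (b, c): 1, (c, END): 1,
    }


def test_process_map_branches():
    log = make_log([["A", "B"], ["A", "C"]])
    model = build_process_map(log)
    a, b, c = ABC["A"], ABC["B"], ABC["C"]
    assert model.edges[(START, a)].frequency == 2
    assert model.edges[(a, b)].frequency == 1
    assert model.edges[(a, c)].frequency == 1
    assert model.nodes[a].absolute_frequency == 2
    assert model.nodes[a].case_frequency == 2


def test_throughput_simple_durations():
    log = EventLog([
        make_case("c0", [("ER Admission", datetime(2019, 1, 1, 10, 0)),
                         ("ER CT", datetime(2019, 1, 1, 12, 0))]),
        make_case("c1", [("ER Admission", datetime(2019, 1, 2, 10, 0)),
                         ("ER CT", datetime(2019, 1, 2, 11, 0))]),
        make_case("c2", [("ER Admission", datetime(2019, 1, 3, 10, 0)),
                         ("ER CT", datetime(2019, 1, 3, 13, 0))]),
    ], "T", "f")
    stats = compute_throughput(log)[("ER Admission", "ER CT")]
    assert stats.median == pytest.approx(2.0)
    assert stats.mean == pytest.approx(2.0)
    assert stats.n == 3


def test_zero_durations_are_legal_and_included():
    ts = datetime(2019, 1, 1)
    log = EventLog([make_case("c", [("ER Admission", ts), ("ER CT", ts)])], "T", "f")
    stats = compute_throughput(log)[("ER Admission", "ER CT")]
    assert stats.median == 0.0 and stats.n == 1


def test_matrix_is_a_view_of_the_edge_counts():
    log = make_log([["A", "B"]])
    m = precedence_matrix(log)
    assert m.entry(START, ABC["A"]) == 1
    assert m.entry(ABC["A"], ABC["B"]) == 1
    assert m.entry(ABC["B"], END) == 1
    assert m.counts.sum() == 3


def test_empty_log_gives_empty_outputs():
    empty = EventLog([], "T", "f")
    assert enumerate_variants(empty) == []
    assert precedence_matrix(empty).counts.sum() == 0


def _variants(shares, total=100):
    counts = [round(s * total) for s in shares]
    return [Variant(("x", str(i)), c, c / total) for i, c in enumerate(counts)]


def test_coverage_filter_examples():
    vs = _variants([0.6, 0.3, 0.06, 0.04])
    assert len(filter_coverage(vs, 0.95)) == 3          # cumulative 0.96
    assert len(filter_coverage(vs, 1.0)) == 4
    assert len(filter_coverage(vs[:1], 0.95)) == 1      # single variant retained
    with pytest.raises(ConfigError):
        filter_coverage(vs, 0.0)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.lists(st.integers(1, 50), min_size=1, max_size=20),
       st.floats(0.05, 1.0))
def test_coverage_filter_minimality(counts, theta):
    counts = sorted(counts, reverse=True)
    total = sum(counts)
    vs = [Variant(("t", str(i)), c, c / total) for i, c in enumerate(counts)]
    kept = filter_coverage(vs, theta)
    covered = sum(v.case_count for v in kept)
    assert covered + 1e-9 >= theta * total
    if len(kept) > 1:
        assert covered - kept[-1].case_count < theta * total - 1e-9


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_flow_conservation_on_random_logs(seed):
    """Per real node, inflow (incl. START) equals outflow (incl. END)."""
    log = random_log(np.random.default_rng(seed), max_cases=20, max_len=8)
    model = build_process_map(log)
    for node in model.nodes:
        inflow = sum(s.frequency for (a, b), s in model.edges.items() if b == node)
        outflow = sum(s.frequency for (a, b), s in model.edges.items() if a == node)
        assert inflow == outflow == model.nodes[node].absolute_frequency


def test_small_logs_match_brute_force_oracles():
    rng = np.random.default_rng(1234)
    for _ in range(20):
        log = random_log(rng)
        traces = [c.trace for c in log.cases]
        assert {v.sequence: v.case_count for v in enumerate_variants(log)} \
            == oracle_variants(traces)
        model = build_process_map(log)
        assert {p: s.frequency for p, s in model.edges.items()} == oracle_edges(traces)
        assert {a: (s.absolute_frequency, s.case_frequency)
                for a, s in model.nodes.items()} == oracle_nodes(traces)
        assert precedence_matrix(log).counts.tolist() \
            == oracle_matrix(traces, MATRIX_LABELS)


def test_mine_with_theta_one_is_identity():
    log = make_log([["A", "B"], ["A", "B"], ["A", "C"], ["B"]])
    res = mine(log, theta=1.0)
    assert res.retained_case_total == res.case_total == 4
    unfiltered = build_process_map(log)
    assert {p: s.frequency for p, s in res.model.edges.items()} \
        == {p: s.frequency for p, s in unfiltered.edges.items()}


def test_mine_filters_downstream_aggregates():
    log = make_log([["A", "B"]] * 19 + [["C"]])
    res = mine(log, theta=0.95)
    assert res.case_total == 20 and res.retained_case_total == 19
    assert [v.sequence for v in res.variants] == [(ABC["A"], ABC["B"])]
    assert ABC["C"] not in res.model.nodes
    assert res.matrix.entry(START, ABC["C"]) == 0


def test_stratified_case_totals_partition_the_log(config):
    from carepath import generate_dataset, select_cohort, build_event_log
    from carepath.cohort import StrokeClass
    from carepath.synthdata import NO_DEFECTS

    ds, _ = generate_dataset(120, seed=21, defects=NO_DEFECTS)
    log, _ = build_event_log(ds, select_cohort(ds, config.code_lists), config)
    per_class = [
        mine(log.subset(c), theta=0.95).case_total
        for c in (StrokeClass.ISCHEMIC, StrokeClass.HEMORRHAGIC,
                  StrokeClass.SUSPECTED, StrokeClass.UNCLASSIFIED)
    ]
    assert sum(per_class) == mine(log, theta=0.95).case_total == len(log.cases)
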