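"""Independent brute-force oracles for the mining aggregates.

Deliberately naive — linear scans and explicit pair walks — so they share
no code path with the implementation they check.
"""

from __future__ import annotations

from carepath.activities import END, START


def oracle_variants(traces: list[tuple[str, ...]]) -> dict[tuple[str, ...], int]:
    distinct: list[tuple[str, ...]] = []
    for t in traces:
        if t not in distinct:
            distinct.append(t)
    return {d: sum(1 for t in traces if t == d) for d in distinct}


def oracle_edges(traces: list[tuple[str, ...]]) -> dict[tuple[str, str], int]:
    counts: dict[tuple[str, str], int] = {}
    for t in traces:
        pairs = [(START, t[0])]
        for i in range(len(t) - 1):
            pairs.append((t[i], t[i + 1]))
        pairs.append((t[-1], END))
        for p in pairs:
            counts[p] = counts.get(p, 0) + 1
    return counts


def oracle_nodes(traces: list[tuple[str, ...]]) -> dict[str, tuple[int, int]]:
    """activity -> (absolute event count, distinct-case count)."""
    names: list[str] = []
    for t in traces:
        for a in t:
            if a not in names:
                names.append(a)
    out = {}
    for a in names:
        absolute = sum(1 for t in traces for x in t if x == a)
        cases = sum(1 for t in traces if a in t)
        out[a] = (absolute, cases)
    return out


def oracle_matrix(traces: list[tuple[str, ...]], labels: tuple[str, ...]):
    counts = [[0] * len(labels) for _ in labels]
    for (a, b), n in oracle_edges(traces).items():
        counts[labels.index(a)][labels.index(b)] += n
    return counts
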