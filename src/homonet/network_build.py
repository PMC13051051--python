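"""Turn engagement logs into cumulative weighted undirected graphs.

An engagement log is a flat list of dyadic events (follow/like/dislike/mention
between two agents on a given day).  The graph for a day cutoff collapses all
events up to and including that day — regardless of direction and type — into
a single undirected edge per agent pair whose ``weight`` is the total event
count.  Per-type counts are kept as edge metadata for diagnostics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .errors import ParseError

EVENT_TYPES = ("follow", "like", "dislike", "mention")

__all__ = [
    "EVENT_TYPES",
    "EngagementEvent",
    "build_graph",
    "prune_low_degree",
    "read_events",
    "write_events",
    "read_edgelist_tsv",
    "write_edgelist_tsv",
    "write_graphml",
]


@dataclass(frozen=True, slots=True)
class EngagementEvent:
    """One dyadic action: *source* engaged with *target* on 1-based *day*."""

    source: str
    target: str
    type: str
    day: int

    def __post_init__(self) -> None:
        if self.source == self.target:
            raise ValueError(f"self-engagement not allowed: {self.source!r}")
        if self.type not in EVENT_TYPES:
            raise ValueError(f"unknown engagement type {self.type!r}")
        if self.day < 1:
            raise ValueError(f"day must be >= 1, got {self.day}")


def build_graph(events: Iterable[EngagementEvent], day_cutoff: int) -> nx.Graph:
    """Build the cumulative weighted undirected graph up to ``day_cutoff``.

    Edge weight for pair {a, b} counts events in either direction and of any
    type with ``day <= day_cutoff`` (inclusive).  Agents with no events in the
    window do not appear.  An empty event list yields an empty graph.
    """
    if day_cutoff < 1:
        raise ValueError(f"day_cutoff must be >= 1, got {day_cutoff}")
    graph = nx.Graph(day_cutoff=day_cutoff)
    for ev in events:
        if ev.day > day_cutoff:
            continue
        a, b = ev.source, ev.target
        if graph.has_edge(a, b):
            data = graph.edges[a, b]
            data["weight"] += 1
            data[f"n_{ev.type}"] = data.get(f"n_{ev.type}", 0) + 1
        else:
            graph.add_edge(a, b, weight=1, **{f"n_{ev.type}": 1})
    return graph


def prune_low_degree(
    graph: nx.Graph, min_neighbors: int = 2, iterate: bool = False
) -> nx.Graph:
    """Drop nodes engaged with fewer than ``min_neighbors`` distinct partners.

    The filter is a single pass by default: nodes are tested against their
    degree in the *input* graph, and edges incident to removed nodes are
    dropped without re-testing survivors.  ``iterate=True`` repeats the pass
    until a fixpoint (the ``min_neighbors``-core).
    """
    if min_neighbors < 0:
        raise ValueError(f"min_neighbors must be >= 0, got {min_neighbors}")
    current = graph
    while True:
        keep = [n for n in current.nodes if current.degree(n) >= min_neighbors]
        pruned = current.subgraph(keep).copy()
        pruned.graph.update(graph.graph)
        if not iterate or pruned.number_of_nodes() == current.number_of_nodes():
            return pruned
        current = pruned


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_DEFAULT_COLUMNS = {"day": "day", "source": "source", "target": "target", "type": "type"}


def read_events(
    path: str | Path, column_mapping: Mapping[str, str] | None = None
) -> list[EngagementEvent]:
    """Read events from CSV or JSONL (by extension).

    ``column_mapping`` maps the canonical field names (day/source/target/type)
    to the columns used in a foreign log.  Malformed records raise
    :class:`ParseError` carrying the 1-based data line number.
    """
    path = Path(path)
    cols = dict(_DEFAULT_COLUMNS)
    if column_mapping:
        cols.update(column_mapping)
    if path.suffix.lower() in {".jsonl", ".ndjson"}:
        records = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                try:
                    records.append((lineno, json.loads(line)))
                except json.JSONDecodeError as exc:
                    raise ParseError(f"line {lineno}: invalid JSON ({exc})") from exc
    else:
        frame = pd.read_csv(path, dtype=str)
        records = [(i + 2, row) for i, row in enumerate(frame.to_dict("records"))]
    events = []
    for lineno, rec in records:
        try:
            events.append(
                EngagementEvent(
                    source=str(rec[cols["source"]]),
                    target=str(rec[cols["target"]]),
                    type=str(rec[cols["type"]]),
                    day=int(rec[cols["day"]]),
                )
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ParseError(f"line {lineno}: {exc}") from exc
    return events


def write_events(events: Sequence[EngagementEvent], path: str | Path) -> None:
    """Write events as CSV (columns day, source, target, type) or JSONL."""
    path = Path(path)
    rows = [
        {"day": e.day, "source": e.source, "target": e.target, "type": e.type}
        for e in events
    ]
    if path.suffix.lower() in {".jsonl", ".ndjson"}:
        with open(path, "w") as fh:
            for row in rows:
                fh.write(json.dumps(row) + "\n")
    else:
        pd.DataFrame(rows, columns=["day", "source", "target", "type"]).to_csv(
            path, index=False
        )


def write_edgelist_tsv(graph: nx.Graph, path: str | Path) -> None:
    """Write a weighted edge list as TSV with a header row."""
    with open(path, "w") as fh:
        fh.write("source\ttarget\tweight\n")
        for u, v, w in sorted(graph.edges(data="weight", default=1)):
            fh.write(f"{u}\t{v}\t{w}\n")


def read_edgelist_tsv(path: str | Path) -> nx.Graph:
    frame = pd.read_csv(path, sep="\t", dtype={"source": str, "target": str})
    graph = nx.Graph()
    for row in frame.itertuples(index=False):
        graph.add_edge(row.source, row.target, weight=int(row.weight))
    return graph


def write_graphml(graph: nx.Graph, path: str | Path) -> None:
    nx.write_graphml(graph, str(path))
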