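"""Structural statistics: weighted modularity and categorical assortativity.

Both statistics operate on the weighted mixing matrix, so edge weights
(engagement frequencies) contribute proportionally; pass ``weighted=False``
to fall back to the unweighted forms for sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Mapping

import networkx as nx
import numpy as np

from .errors import DegenerateAttributeError, DomainError

__all__ = [
    "PartitionStats",
    "modularity",
    "attribute_assortativity",
    "pairwise_assortativity",
    "partition_stats",
]


@dataclass(frozen=True)
class PartitionStats:
    """Summary of a partitioned graph: modularity Q and assortativity r."""

    modularity: float
    assortativity: float
    n_nodes: int
    n_edges: int
    total_weight: float


def _assignment(partition) -> Mapping[Hashable, Hashable]:
    """Accept either a Partition object or a plain node -> community map."""
    return getattr(partition, "assignment", partition)


def modularity(graph: nx.Graph, partition, weighted: bool = True) -> float:
    """Weighted Newman modularity of a node partition.

    Q = (1/2m) * sum_ij [w_ij - s_i s_j / (2m)] * delta(c_i, c_j) with s the
    weighted node strength and m the total edge weight.  Nodes missing from
    the partition (e.g. unassigned after small-community filtering) are
    dropped from the graph before computing.
    """
    assignment = _assignment(partition)
    nodes = [n for n in graph.nodes if n in assignment]
    g = graph if len(nodes) == graph.number_of_nodes() else graph.subgraph(nodes)

    w_in: dict[Hashable, float] = {}
    strength: dict[Hashable, float] = {}
    m = 0.0
    for u, v, w in g.edges(data="weight", default=1):
        w = float(w) if weighted else 1.0
        m += w
        cu, cv = assignment[u], assignment[v]
        strength[cu] = strength.get(cu, 0.0) + w
        strength[cv] = strength.get(cv, 0.0) + w
        if cu == cv:
            w_in[cu] = w_in.get(cu, 0.0) + 2.0 * w
    if m <= 0:
        raise DomainError("modularity undefined: graph has zero total edge weight")
    two_m = 2.0 * m
    return sum(
        w_in.get(c, 0.0) / two_m - (s / two_m) ** 2 for c, s in strength.items()
    )


def _mixing_matrix(
    graph: nx.Graph, labels: Mapping[Hashable, Hashable], weighted: bool
) -> np.ndarray:
    missing = [n for n in graph.nodes if n not in labels]
    if missing:
        raise DomainError(f"{len(missing)} nodes unlabeled (e.g. {missing[0]!r})")
    cats = sorted({labels[n] for n in graph.nodes}, key=str)
    idx = {c: i for i, c in enumerate(cats)}
    mat = np.zeros((len(cats), len(cats)))
    for u, v, w in graph.edges(data="weight", default=1):
        w = float(w) if weighted else 1.0
        i, j = idx[labels[u]], idx[labels[v]]
        mat[i, j] += w
        mat[j, i] += w
    total = mat.sum()
    if total <= 0:
        raise DomainError("assortativity undefined: graph has no edge weight")
    return mat / total


def attribute_assortativity(
    graph: nx.Graph, labels: Mapping[Hashable, Hashable], weighted: bool = True
) -> float:
    """Categorical assortativity r on the weighted mixing matrix.

    r = (sum_i e_ii - sum_i a_i^2) / (1 - sum_i a_i^2); 1 means all edge
    weight falls within categories, negative values mean disassortative
    mixing.  Raises :class:`DegenerateAttributeError` when only one category
    is present (denominator 0).
    """
    mix = _mixing_matrix(graph, labels, weighted)
    if mix.shape[0] < 2:
        raise DegenerateAttributeError(
            "assortativity undefined with a single category"
        )
    a = mix.sum(axis=1)
    expected = float(a @ a)
    if np.isclose(expected, 1.0):
        raise DegenerateAttributeError(
            "assortativity undefined: expected within-category weight is 1"
        )
    return float((np.trace(mix) - expected) / (1.0 - expected))


def pairwise_assortativity(
    graph: nx.Graph,
    labels: Mapping[Hashable, Hashable],
    cat_a: Hashable,
    cat_b: Hashable,
    weighted: bool = True,
) -> float:
    """Assortativity on the subgraph induced by two label categories."""
    nodes = [n for n in graph.nodes if labels.get(n) in (cat_a, cat_b)]
    present = {labels[n] for n in nodes}
    if cat_a not in present or cat_b not in present:
        raise DomainError(f"both categories must be present, found {present}")
    sub = graph.subgraph(nodes)
    if sub.number_of_edges() == 0:
        raise DomainError("induced subgraph has no edges")
    return attribute_assortativity(sub, labels, weighted=weighted)


def partition_stats(graph: nx.Graph, partition, weighted: bool = True) -> PartitionStats:
    """Bundle Q and community-label assortativity with graph totals."""
    assignment = _assignment(partition)
    nodes = [n for n in graph.nodes if n in assignment]
    g = graph.subgraph(nodes)
    total = sum(float(w) for _, _, w in g.edges(data="weight", default=1))
    return PartitionStats(
        modularity=modularity(g, assignment, weighted=weighted),
        assortativity=attribute_assortativity(g, assignment, weighted=weighted),
        n_nodes=g.number_of_nodes(),
        n_edges=g.number_of_edges(),
        total_weight=total,
    )
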