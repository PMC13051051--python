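"""Community detection, small-community filtering, and consistency scoring.

Two clustering routes are exposed: asynchronous weighted label propagation
(fast, stochastic — used on full populations) and agglomerative greedy
modularity maximization (deterministic — used on attribute subsets).  Both
are backed by networkx behind this module's Partition contract.

Stability of detected communities is scored with an overlap rate o(A): re-run
the clusterer many times and average, per base community A, the mean of
(largest fraction of A captured by any community in the re-run) and (largest
fraction of any re-run community lying inside A).  Communities whose mean
o(A) clears a threshold are "consistent".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Hashable, Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "Partition",
    "ConsistencyReport",
    "label_propagation",
    "greedy_modularity",
    "filter_small_communities",
    "overlap_rate",
    "consistency_check",
    "read_partition_csv",
    "write_partition_csv",
]


@dataclass
class Partition:
    """A node -> community assignment with its inverse member-set view."""

    assignment: dict[Hashable, int]
    communities: dict[int, frozenset]
    algorithm: str
    seed: int | None = None

    @classmethod
    def from_communities(
        cls,
        communities: Iterable[Iterable[Hashable]],
        algorithm: str,
        seed: int | None = None,
    ) -> "Partition":
        comm_map: dict[int, frozenset] = {}
        assignment: dict[Hashable, int] = {}
        # Deterministic community ids: sort member sets by (-size, repr).
        ordered = sorted(
            (frozenset(c) for c in communities),
            key=lambda c: (-len(c), sorted(map(str, c))),
        )
        for cid, members in enumerate(ordered):
            comm_map[cid] = members
            for node in members:
                if node in assignment:
                    raise ValueError(f"node {node!r} assigned to two communities")
                assignment[node] = cid
        return cls(assignment=assignment, communities=comm_map,
                   algorithm=algorithm, seed=seed)

    @property
    def n_communities(self) -> int:
        return len(self.communities)

    def sizes(self) -> dict[int, int]:
        return {cid: len(m) for cid, m in self.communities.items()}

    def covers(self, nodes: Iterable[Hashable]) -> bool:
        return all(n in self.assignment for n in nodes)


def label_propagation(graph: nx.Graph, seed: int | None = None) -> Partition:
    """Asynchronous weighted label propagation (deterministic given seed).

    Each node iteratively adopts the label with the largest total incident
    edge weight among its neighbours, in a random node order per sweep, with
    uniform random tie-breaking, until every label is locally maximal.
    """
    if graph.number_of_nodes() == 0:
        return Partition({}, {}, algorithm="label_propagation", seed=seed)
    comms = nx.community.asyn_lpa_communities(graph, weight="weight", seed=seed)
    return Partition.from_communities(comms, algorithm="label_propagation", seed=seed)


def greedy_modularity(graph: nx.Graph) -> Partition:
    """Agglomerative weighted modularity maximization (CNM-style).

    Starts from singletons, repeatedly merges the community pair with maximal
    modularity gain, and returns the partition at the dendrogram's maximum Q.
    Deterministic.  A graph with no edges yields the singleton partition.
    """
    if graph.number_of_edges() == 0:
        singletons = [{n} for n in graph.nodes]
        return Partition.from_communities(singletons, algorithm="greedy_modularity")
    comms = nx.community.greedy_modularity_communities(graph, weight="weight")
    return Partition.from_communities(comms, algorithm="greedy_modularity")


def filter_small_communities(
    partition: Partition, graph: nx.Graph, min_frac: float = 0.01
) -> Partition:
    """Drop communities holding strictly less than ``min_frac`` of the nodes.

    Members of dropped communities become unassigned (absent from the
    returned partition) and are excluded from downstream community
    statistics.  The boundary is strict: a community of exactly
    ``min_frac * n`` members is kept.
    """
    if not 0.0 <= min_frac <= 1.0:
        raise ValueError(f"min_frac must be in [0, 1], got {min_frac}")
    threshold = min_frac * graph.number_of_nodes()
    kept = {
        cid: members
        for cid, members in partition.communities.items()
        if len(members) >= threshold
    }
    assignment = {n: cid for cid, members in kept.items() for n in members}
    return Partition(
        assignment=assignment,
        communities=kept,
        algorithm=partition.algorithm,
        seed=partition.seed,
    )


def overlap_rate(reference: Iterable[Hashable], partition: Partition) -> float:
    """Overlap rate o(A) of a reference member set against a partition.

    o = (max_B |A∩B|/|A| + max_B |A∩B|/|B|) / 2, with both maxima taken over
    all communities B of the partition — independently, so the two maxima may
    be achieved by different B.  Equals 1 iff some B equals A exactly.
    """
    ref = frozenset(reference)
    if not ref:
        raise ValueError("reference community must be non-empty")
    if not partition.communities:
        return 0.0
    frac_of_a = 0.0
    frac_of_b = 0.0
    for members in partition.communities.values():
        inter = len(ref & members)
        if inter == 0:
            continue
        frac_of_a = max(frac_of_a, inter / len(ref))
        frac_of_b = max(frac_of_b, inter / len(members))
    return (frac_of_a + frac_of_b) / 2.0


@dataclass
class ConsistencyReport:
    """Mean overlap per base community and the set clearing the threshold."""

    overlap: dict[int, float]
    n_iterations: int
    threshold: float
    kept: frozenset = field(default_factory=frozenset)

    def to_frame(self, partition: Partition) -> pd.DataFrame:
        rows = [
            {
                "community_id": cid,
                "size": len(partition.communities[cid]),
                "mean_overlap": o,
                "kept": cid in self.kept,
            }
            for cid, o in sorted(self.overlap.items())
        ]
        return pd.DataFrame(rows, columns=["community_id", "size", "mean_overlap", "kept"])


_ALGORITHMS: dict[str, Callable] = {
    "label_propagation": lambda g, seed: label_propagation(g, seed=seed),
    "greedy_modularity": lambda g, seed: greedy_modularity(g),
}


def consistency_check(
    graph: nx.Graph,
    base_partition: Partition,
    algorithm: str | Callable[[nx.Graph, int], Partition] = "label_propagation",
    n_iterations: int = 1000,
    threshold: float = 0.80,
    seed: int | None = None,
) -> ConsistencyReport:
    """Score each base community's stability over re-runs of the clusterer.

    Each iteration re-clusters the graph with a fresh seed (unfiltered — small
    communities are not removed before overlap, since o(A) measures identity
    stability, not size) and records o(A) for every base community A; means
    over iterations are compared against ``threshold``.
    """
    if n_iterations < 1:
        raise ValueError(f"n_iterations must be >= 1, got {n_iterations}")
    cluster = _ALGORITHMS[algorithm] if isinstance(algorithm, str) else algorithm
    rng = np.random.default_rng(seed)
    sums = {cid: 0.0 for cid in base_partition.communities}
    for _ in range(n_iterations):
        it_seed = int(rng.integers(0, 2**31 - 1))
        it_partition = cluster(graph, it_seed)
        for cid, members in base_partition.communities.items():
            sums[cid] += overlap_rate(members, it_partition)
    overlap = {cid: s / n_iterations for cid, s in sums.items()}
    # tolerance so an exact-boundary mean is not dropped by float round-off
    kept = frozenset(
        cid for cid, o in overlap.items() if o >= threshold - 1e-12
    )
    return ConsistencyReport(
        overlap=overlap, n_iterations=n_iterations, threshold=threshold, kept=kept
    )


def write_partition_csv(partition: Partition, path: str | Path) -> None:
    rows = sorted(
        ({"agent_id": n, "community_id": c} for n, c in partition.assignment.items()),
        key=lambda r: str(r["agent_id"]),
    )
    pd.DataFrame(rows, columns=["agent_id", "community_id"]).to_csv(path, index=False)


def read_partition_csv(path: str | Path, algorithm: str = "loaded") -> Partition:
    frame = pd.read_csv(path, dtype={"agent_id": str, "community_id": int})
    communities: dict[int, set] = {}
    for row in frame.itertuples(index=False):
        communities.setdefault(int(row.community_id), set()).add(row.agent_id)
    return Partition.from_communities(communities.values(), algorithm=algorithm)
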