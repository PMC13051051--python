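"""Alignment between engagement structure and agent attributes/content.

Covers the categorical route (community x category contingency with Cramér's
V), the semantic route (text cleaning, pluggable embedding, centroid paired
t-test with Cohen's d, pairwise distances binned by engagement count), and
dyadic matrix regression with the quadratic assignment procedure (QAP).
"""

from __future__ import annotations

import hashlib
import re
import warnings
from dataclasses import dataclass, field
from typing import Hashable, Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .community_detect import Partition
from .errors import DomainError

__all__ = [
    "AgentContent",
    "ContingencyResult",
    "CentroidTestResult",
    "QapResult",
    "clean_text",
    "HashedProjectionEncoder",
    "embed_agent",
    "cosine_distance",
    "contingency_alignment",
    "centroid_distance_test",
    "distance_by_engagement_bins",
    "mrqap_correlation",
    "engagement_weight_matrix",
    "cosine_distance_matrix",
]

_NON_ROMAN = re.compile(r"[^A-Za-z0-9\s]+")
_WS = re.compile(r"\s+")


def clean_text(raw: str) -> str:
    """Strip non-roman characters and punctuation; collapse whitespace."""
    return _WS.sub(" ", _NON_ROMAN.sub("", raw)).strip()


@dataclass
class AgentContent:
    """Per-agent text/embedding bundle."""

    agent_id: str
    raw_posts: list[str] = field(default_factory=list)
    cleaned_text: str | None = None
    embedding: np.ndarray | None = None
    language: str | None = None
    excluded: bool = False


class HashedProjectionEncoder:
    """Deterministic offline text encoder: seeded projection of token counts.

    Each token maps to a fixed pseudo-random Gaussian direction (seeded by a
    stable hash of the token and the encoder seed); a text's vector is the
    count-weighted sum, L2-normalized.  Texts sharing no tokens are orthogonal
    in expectation.  Stands in for a pretrained sentence encoder in tests; a
    production adapter can wrap any callable with the same contract.
    """

    def __init__(self, dim: int = 64, seed: int = 0):
        if dim < 2:
            raise ValueError("dim must be >= 2")
        self.dim = dim
        self.seed = seed

    def _token_vector(self, token: str) -> np.ndarray:
        digest = hashlib.blake2b(
            f"{self.seed}:{token}".encode(), digest_size=8
        ).digest()
        rng = np.random.default_rng(int.from_bytes(digest, "little"))
        return rng.standard_normal(self.dim)

    def __call__(self, text: str) -> np.ndarray:
        vec = np.zeros(self.dim)
        for token in text.lower().split():
            vec += self._token_vector(token)
        return vec


def embed_agent(content: AgentContent, encoder) -> AgentContent:
    """Embed an agent's concatenated cleaned posts; unit-norm output.

    Agents whose cleaned text is empty are flagged ``excluded`` (no embedding)
    and must be left out of semantic analyses.
    """
    if content.cleaned_text is None:
        content.cleaned_text = clean_text(" ".join(content.raw_posts))
    if not content.cleaned_text:
        content.excluded = True
        content.embedding = None
        return content
    vec = np.asarray(encoder(content.cleaned_text), dtype=float)
    norm = np.linalg.norm(vec)
    if norm == 0:
        content.excluded = True
        content.embedding = None
        return content
    content.embedding = vec / norm
    return content


def cosine_distance(u: np.ndarray, v: np.ndarray) -> float:
    """1 - cos(u, v); in [0, 2]. Zero vectors are a domain error."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise DomainError("cosine distance undefined for zero vectors")
    return float(1.0 - (u @ v) / (nu * nv))


# ---------------------------------------------------------------------------
# Contingency
# ---------------------------------------------------------------------------

@dataclass
class ContingencyResult:
    chi2: float
    df: int
    p: float
    cramers_v: float
    table: pd.DataFrame
    n: int


def contingency_alignment(
    partition: Partition, labels: Mapping[Hashable, Hashable]
) -> ContingencyResult:
    """Pearson chi-square on the community x category count table.

    Only agents assigned by the partition enter the table; zero-margin rows
    or columns are dropped with a warning before testing.  Cramér's V =
    sqrt(chi2 / (N * (min(R, C) - 1))).
    """
    rows = [
        (cid, labels[a])
        for a, cid in partition.assignment.items()
        if a in labels
    ]
    if not rows:
        raise DomainError("no labeled assigned agents")
    frame = pd.DataFrame(rows, columns=["community", "category"])
    table = pd.crosstab(frame["community"], frame["category"])
    zero_rows = table.index[(table.sum(axis=1) == 0)]
    zero_cols = table.columns[(table.sum(axis=0) == 0)]
    if len(zero_rows) or len(zero_cols):
        warnings.warn("dropping zero-margin rows/columns from contingency table")
        table = table.drop(index=zero_rows, columns=zero_cols)
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise DomainError("contingency test needs >= 2 communities and categories")
    chi2, p, df, _ = stats.chi2_contingency(table.to_numpy(), correction=False)
    n = int(table.to_numpy().sum())
    v = float(np.sqrt(chi2 / (n * (min(table.shape) - 1))))
    return ContingencyResult(
        chi2=float(chi2), df=int(df), p=float(p), cramers_v=v, table=table, n=n
    )


# ---------------------------------------------------------------------------
# Centroid distance test
# ---------------------------------------------------------------------------

@dataclass
class CentroidTestResult:
    t: float
    df: int
    p: float
    cohens_d: float
    ci_d: tuple[float, float]
    n: int
    mean_community_distance: float
    mean_global_distance: float
    degenerate: bool = False


def centroid_distance_test(
    embeddings: Mapping[str, np.ndarray],
    partition: Partition,
    include_self: bool = True,
) -> CentroidTestResult:
    """Paired test: is each agent closer to its community centroid than to
    the global centroid of all agents in scope?

    Per agent, d_comm = cosine distance to its community's mean embedding and
    d_glob = cosine distance to the mean over all embedded agents in
    ``embeddings``; a paired t-test runs on (d_comm - d_glob) with Cohen's
    d = t / sqrt(n).  Communities of size 1 are excluded (degenerate
    centroid) with a warning; ``include_self=False`` gives the leave-one-out
    variant of the community centroid.
    """
    global_centroid = np.mean([np.asarray(v) for v in embeddings.values()], axis=0)
    diffs = []
    d_comm_all = []
    d_glob_all = []
    for cid, members in partition.communities.items():
        embedded = [m for m in members if m in embeddings]
        if len(embedded) < 2:
            if embedded:
                warnings.warn(f"community {cid} has a single embedded member; skipped")
            continue
        mat = np.vstack([embeddings[m] for m in embedded])
        centroid_sum = mat.sum(axis=0)
        for k, m in enumerate(embedded):
            if include_self:
                centroid = centroid_sum / len(embedded)
            else:
                centroid = (centroid_sum - mat[k]) / (len(embedded) - 1)
            d_comm = cosine_distance(mat[k], centroid)
            d_glob = cosine_distance(mat[k], global_centroid)
            d_comm_all.append(d_comm)
            d_glob_all.append(d_glob)
            diffs.append(d_comm - d_glob)
    if not diffs:
        raise DomainError("no testable agents (all communities degenerate)")
    diffs = np.asarray(diffs)
    n = len(diffs)
    if np.allclose(np.std(diffs), 0.0):
        return CentroidTestResult(
            t=float("nan"), df=n - 1, p=float("nan"), cohens_d=0.0,
            ci_d=(0.0, 0.0), n=n,
            mean_community_distance=float(np.mean(d_comm_all)),
            mean_global_distance=float(np.mean(d_glob_all)),
            degenerate=True,
        )
    t, p = stats.ttest_1samp(diffs, 0.0)
    t, p = float(t), float(p)
    d = t / np.sqrt(n)
    # Large-sample normal CI for a paired-design d.
    se_d = np.sqrt(1.0 / n + d * d / (2.0 * n))
    return CentroidTestResult(
        t=t, df=n - 1, p=p, cohens_d=float(d),
        ci_d=(float(d - 1.96 * se_d), float(d + 1.96 * se_d)), n=n,
        mean_community_distance=float(np.mean(d_comm_all)),
        mean_global_distance=float(np.mean(d_glob_all)),
    )


# ---------------------------------------------------------------------------
# Engagement-binned pairwise distances
# ---------------------------------------------------------------------------

BIN_LABELS = ("0", "1", "2", "3", "4", "5+")


def _bin_label(count: float) -> str:
    return "5+" if count >= 5 else str(int(count))


def distance_by_engagement_bins(
    graph: nx.Graph,
    embeddings: Mapping[str, np.ndarray],
    max_zero_pairs: int = 1_000_000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Mean pairwise cosine distance by engagement count bin.

    Engagement count of a pair is the edge weight (absent edge = 0); bins are
    0, 1, 2, 3, 4 and 5+.  Each bin row reports the mean distance with a 95%
    normal CI (±1.96·SE).  The 0-bin is subsampled uniformly (seeded) to
    ``max_zero_pairs`` when the full non-edge pair count exceeds it.
    """
    ids = sorted(embeddings)
    index = {a: i for i, a in enumerate(ids)}
    mat = np.vstack([np.asarray(embeddings[a], dtype=float) for a in ids])
    mat = mat / np.linalg.norm(mat, axis=1, keepdims=True)
    n = len(ids)

    by_bin: dict[str, list[float]] = {b: [] for b in BIN_LABELS}
    edge_keys = set()
    for u, v, w in graph.edges(data="weight", default=1):
        if u not in index or v not in index:
            continue
        i, j = index[u], index[v]
        edge_keys.add((min(i, j), max(i, j)))
        d = 1.0 - float(mat[i] @ mat[j])
        by_bin[_bin_label(w)].append(d)

    total_pairs = n * (n - 1) // 2
    n_zero = total_pairs - len(edge_keys)
    rng = np.random.default_rng(seed)
    if n_zero > 0:
        if n_zero <= max_zero_pairs:
            iu, ju = np.triu_indices(n, k=1)
            for i, j in zip(iu, ju):
                if (int(i), int(j)) not in edge_keys:
                    by_bin["0"].append(1.0 - float(mat[i] @ mat[j]))
        else:
            needed = max_zero_pairs
            seen: set[tuple[int, int]] = set()
            while len(seen) < needed:
                ii = rng.integers(0, n, size=2 * (needed - len(seen)))
                jj = rng.integers(0, n, size=2 * (needed - len(seen)))
                for i, j in zip(ii, jj):
                    if i == j:
                        continue
                    key = (min(int(i), int(j)), max(int(i), int(j)))
                    if key in edge_keys or key in seen:
                        continue
                    seen.add(key)
                    if len(seen) >= needed:
                        break
            for i, j in seen:
                by_bin["0"].append(1.0 - float(mat[i] @ mat[j]))

    rows = []
    for label in BIN_LABELS:
        vals = np.asarray(by_bin[label])
        if len(vals) == 0:
            rows.append({"bin": label, "mean_distance": np.nan,
                         "ci_low": np.nan, "ci_high": np.nan, "n_pairs": 0})
            continue
        mean = float(vals.mean())
        se = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else 0.0
        rows.append({
            "bin": label,
            "mean_distance": mean,
            "ci_low": mean - 1.96 * se,
            "ci_high": mean + 1.96 * se,
            "n_pairs": int(len(vals)),
        })
    return pd.DataFrame(rows, columns=["bin", "mean_distance", "ci_low", "ci_high", "n_pairs"])


# ---------------------------------------------------------------------------
# MRQAP
# ---------------------------------------------------------------------------

@dataclass
class QapResult:
    r: float
    p: float
    ci: tuple[float, float]
    n_permutations: int
    n_nodes: int
    ci_method: str = "dyadic_bootstrap_percentile"


def engagement_weight_matrix(
    graph: nx.Graph, order: Sequence[str]
) -> np.ndarray:
    """Dense symmetric engagement-count matrix in the given node order."""
    index = {a: i for i, a in enumerate(order)}
    mat = np.zeros((len(order), len(order)))
    for u, v, w in graph.edges(data="weight", default=1):
        if u in index and v in index:
            i, j = index[u], index[v]
            mat[i, j] = mat[j, i] = float(w)
    return mat


def cosine_distance_matrix(
    embeddings: Mapping[str, np.ndarray], order: Sequence[str]
) -> np.ndarray:
    mat = np.vstack([np.asarray(embeddings[a], dtype=float) for a in order])
    mat = mat / np.linalg.norm(mat, axis=1, keepdims=True)
    dist = np.clip(1.0 - mat @ mat.T, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    return dist


def mrqap_correlation(
    weight_matrix: np.ndarray,
    distance_matrix: np.ndarray,
    n_permutations: int = 1000,
    seed: int | None = None,
    n_bootstrap: int = 500,
) -> QapResult:
    """QAP correlation between two square symmetric dyadic matrices.

    r is the Pearson correlation over off-diagonal dyads.  The null permutes
    node labels of the distance matrix (rows and columns by the same random
    permutation, preserving dyadic dependence) while holding the weight
    matrix fixed; p is two-sided on |r| with a 1/n_permutations floor.  The
    CI is a dyadic-bootstrap percentile interval (a documented construction
    choice, recorded in the result).
    """
    w = np.asarray(weight_matrix, dtype=float)
    d = np.asarray(distance_matrix, dtype=float)
    if w.shape != d.shape or w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError("matrices must be square and identically shaped")
    n = w.shape[0]
    if n < 4:
        raise ValueError("QAP needs at least 4 nodes")
    if not (np.allclose(w, w.T) and np.allclose(d, d.T)):
        raise ValueError("matrices must be symmetric")
    mask = ~np.eye(n, dtype=bool)
    x = w[mask]
    if np.std(x) == 0 or np.std(d[mask]) == 0:
        raise DomainError("QAP correlation undefined for a constant matrix")
    r = float(np.corrcoef(x, d[mask])[0, 1])

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        dp = d[np.ix_(perm, perm)]
        r_perm = float(np.corrcoef(x, dp[mask])[0, 1])
        if abs(r_perm) >= abs(r) - 1e-12:
            count += 1
    p = max(count, 1) / n_permutations

    iu, ju = np.triu_indices(n, k=1)
    xs = w[iu, ju]
    ys = d[iu, ju]
    boots = np.empty(n_bootstrap)
    for b in range(n_bootstrap):
        pick = rng.integers(0, len(xs), size=len(xs))
        xb, yb = xs[pick], ys[pick]
        if np.std(xb) == 0 or np.std(yb) == 0:
            boots[b] = np.nan
            continue
        boots[b] = np.corrcoef(xb, yb)[0, 1]
    boots = boots[~np.isnan(boots)]
    if len(boots):
        ci = (float(np.percentile(boots, 2.5)), float(np.percentile(boots, 97.5)))
    else:
        ci = (float("nan"), float("nan"))
    return QapResult(r=r, p=float(p), ci=ci, n_permutations=n_permutations, n_nodes=n)
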