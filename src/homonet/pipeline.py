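"""Orchestrate the full multi-day analysis and emit machine-readable tables.

A run walks, for each configured scope (full population, or an attribute
subset such as English-only agents) and each day cutoff: build the cumulative
graph -> prune low-degree nodes -> detect communities -> drop small
communities -> (optionally) consistency-filter them -> structural statistics
with rewiring nulls -> alignment analyses.  Everything is deterministic given
the config seed; provenance (config hash, seeds, library versions) is
recorded in the report.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
import time
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .community_detect import (
    Partition,
    consistency_check,
    filter_small_communities,
    greedy_modularity,
    label_propagation,
)
from .content_alignment import (
    centroid_distance_test,
    contingency_alignment,
    cosine_distance_matrix,
    distance_by_engagement_bins,
    engagement_weight_matrix,
    mrqap_correlation,
)
from .errors import ConfigurationError, DomainError
from .graph_stats import attribute_assortativity, modularity, pairwise_assortativity
from .network_build import EngagementEvent, build_graph, prune_low_degree, read_events
from .null_inference import null_distribution
from .synthetic_society import (
    SocietyConfig,
    generate_society,
    read_embeddings_csv,
)

logger = logging.getLogger("homonet.pipeline")

__all__ = ["ScopeConfig", "RunConfig", "RunReport", "run_pipeline", "emit_tables"]


@dataclass
class ScopeConfig:
    """One analysis scope: a node filter plus its algorithm and analyses."""

    name: str = "full"
    language: str | None = None  # restrict to agents with this language label
    algorithm: str = "label_propagation"
    consistency: bool = False
    contingency: bool = False  # community x language table
    pairwise_language: bool = False
    semantic: bool = False  # centroid test, engagement bins, MRQAP


def default_scopes() -> list[ScopeConfig]:
    return [
        ScopeConfig(
            name="full",
            algorithm="label_propagation",
            contingency=True,
            pairwise_language=True,
        ),
        ScopeConfig(
            name="english",
            language="english",
            algorithm="greedy_modularity",
            consistency=True,
            semantic=True,
        ),
    ]


@dataclass
class RunConfig:
    society: SocietyConfig | None = None
    events_path: str | None = None
    agents_path: str | None = None
    embeddings_path: str | None = None
    day_cutoffs: list[int] = field(default_factory=lambda: [7, 14, 21, 28])
    scopes: list[ScopeConfig] = field(default_factory=default_scopes)
    min_neighbors: int = 2
    min_community_frac: float = 0.01
    consistency_threshold: float = 0.80
    n_consistency: int = 1000
    n_null: int = 1000
    swap_factor: float = 10.0
    qap_permutations: int = 1000
    max_zero_pairs: int = 1_000_000
    seed: int = 0
    out_dir: str | None = None

    def validate(self) -> None:
        if any(b <= a for a, b in zip(self.day_cutoffs, self.day_cutoffs[1:])):
            raise ConfigurationError("day_cutoffs must be strictly increasing")
        if not self.day_cutoffs:
            raise ConfigurationError("day_cutoffs must be non-empty")
        if self.n_null < 1 or self.n_consistency < 1:
            raise ConfigurationError("n_null and n_consistency must be >= 1")
        if self.society is None and self.events_path is None:
            raise ConfigurationError("either society or events_path is required")

    def to_dict(self) -> dict:
        payload = asdict(self)
        return payload

    @classmethod
    def from_dict(cls, data: Mapping) -> "RunConfig":
        data = dict(data)
        if data.get("society") is not None:
            data["society"] = SocietyConfig(**data["society"])
        if data.get("scopes"):
            data["scopes"] = [
                s if isinstance(s, ScopeConfig) else ScopeConfig(**s)
                for s in data["scopes"]
            ]
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    config: dict
    provenance: dict
    results: dict  # "{scope}/day{d}" -> stage outputs (JSON-serializable)

    def to_json(self) -> str:
        return json.dumps(
            {"config": self.config, "provenance": self.provenance, "results": self.results},
            sort_keys=True,
            indent=2,
            default=_jsonable,
        )


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, frozenset):
        return sorted(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")


_CLUSTERERS = {
    "label_propagation": lambda g, seed: label_propagation(g, seed=seed),
    "greedy_modularity": lambda g, seed: greedy_modularity(g),
}


def _load_inputs(config: RunConfig):
    if config.society is not None:
        society = generate_society(config.society)
        events = society.events
        languages = society.languages()
        embeddings = society.embeddings()
    else:
        events = read_events(config.events_path)
        languages, embeddings = {}, {}
        if config.agents_path:
            agents = pd.read_csv(config.agents_path, dtype=str)
            languages = dict(zip(agents["agent_id"], agents["language"]))
        if config.embeddings_path:
            embeddings = read_embeddings_csv(config.embeddings_path)
    return events, languages, embeddings


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the configured analysis; see module docstring for stages."""
    config.validate()
    t_start = time.time()
    events, languages, embeddings = _load_inputs(config)
    logger.info("loaded %d events, %d language labels", len(events), len(languages))

    results: dict[str, dict] = {}
    for s_idx, scope in enumerate(config.scopes):
        if scope.language is not None:
            scoped_ids = {a for a, lang in languages.items() if lang == scope.language}
            scoped_events = [
                e for e in events if e.source in scoped_ids and e.target in scoped_ids
            ]
        else:
            scoped_events = events
        for d_idx, day in enumerate(config.day_cutoffs):
            key = f"{scope.name}/day{day}"
            seed_root = np.random.SeedSequence(
                entropy=config.seed, spawn_key=(s_idx, d_idx)
            )
            seeds = [int(s.generate_state(1)[0]) for s in seed_root.spawn(8)]
            t0 = time.time()
            try:
                results[key] = _run_stage(
                    config, scope, day, scoped_events, languages, embeddings, seeds
                )
            except Exception as exc:
                raise RuntimeError(
                    f"pipeline stage failed at scope={scope.name} day={day}: {exc}"
                ) from exc
            logger.info("%s finished in %.1fs", key, time.time() - t0)

    logger.info("pipeline finished in %.1fs", time.time() - t_start)
    # timings go to the log, not the report: reports are hash-comparable
    provenance = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "homonet_version": __version__,
        "networkx_version": nx.__version__,
        "numpy_version": np.__version__,
    }
    return RunReport(config=config.to_dict(), provenance=provenance, results=results)


def _run_stage(config, scope, day, events, languages, embeddings, seeds):
    out: dict = {"scope": scope.name, "day": day, "algorithm": scope.algorithm}
    graph = build_graph(events, day_cutoff=day)
    graph = prune_low_degree(graph, min_neighbors=config.min_neighbors)
    out["n_nodes"] = graph.number_of_nodes()
    out["n_edges"] = graph.number_of_edges()
    if graph.number_of_edges() == 0:
        out["no_communities"] = True
        return out

    cluster = _CLUSTERERS[scope.algorithm]
    partition = cluster(graph, seeds[0])
    filtered = filter_small_communities(partition, graph, config.min_community_frac)
    out["n_communities_detected"] = partition.n_communities
    out["n_communities_kept"] = filtered.n_communities
    out["community_sizes"] = sorted(filtered.sizes().values(), reverse=True)

    if scope.consistency and filtered.n_communities:
        report = consistency_check(
            graph,
            filtered,
            algorithm=scope.algorithm,
            n_iterations=config.n_consistency,
            threshold=config.consistency_threshold,
            seed=seeds[1],
        )
        filtered = Partition(
            assignment={
                a: c for a, c in filtered.assignment.items() if c in report.kept
            },
            communities={
                c: m for c, m in filtered.communities.items() if c in report.kept
            },
            algorithm=filtered.algorithm,
            seed=filtered.seed,
        )
        out["consistency"] = {
            "mean_overlap": {str(c): o for c, o in report.overlap.items()},
            "n_iterations": report.n_iterations,
            "threshold": report.threshold,
            "n_consistent": len(report.kept),
        }
        out["n_communities_kept"] = filtered.n_communities

    if filtered.n_communities == 0:
        out["no_communities"] = True
    else:
        out["structure"] = _structure_stats(config, scope, graph, filtered, seeds)

    if scope.pairwise_language or scope.contingency:
        out.update(_language_analyses(config, scope, graph, filtered, languages, seeds))
    if scope.semantic and embeddings:
        out.update(
            _semantic_analyses(config, scope, graph, filtered, embeddings, seeds)
        )
    return out


def _structure_stats(config, scope, graph, partition, seeds):
    cluster = _CLUSTERERS[scope.algorithm]
    structure = {}
    q_obs = modularity(graph, partition)
    null_q = null_distribution(
        graph,
        statistic=modularity,
        clustering=cluster,
        n_iterations=config.n_null,
        seed=seeds[2],
        swap_factor=config.swap_factor,
        statistic_name="modularity",
        observed=q_obs,
    )
    structure["modularity"] = {**null_q.to_dict(), "null_mode": "reclustered"}
    try:
        r_obs = attribute_assortativity(graph.subgraph(partition.assignment), partition.assignment)
    except DomainError:
        r_obs = None
    if r_obs is not None:
        def _comm_assort(g, part):
            assign = getattr(part, "assignment", part)
            return attribute_assortativity(g.subgraph(assign), assign)

        null_r = null_distribution(
            graph,
            statistic=_comm_assort,
            clustering=cluster,
            n_iterations=config.n_null,
            seed=seeds[3],
            swap_factor=config.swap_factor,
            statistic_name="assortativity",
            observed=r_obs,
        )
        structure["assortativity"] = {**null_r.to_dict(), "null_mode": "reclustered"}
    return structure


def _language_analyses(config, scope, graph, partition, languages, seeds):
    out: dict = {}
    labeled = {n: languages[n] for n in graph.nodes if n in languages}
    if scope.pairwise_language and labeled:
        langs_present = sorted(set(labeled.values()) - {"other"})
        pairwise = {}
        rng = np.random.default_rng(seeds[4])
        for cat_a, cat_b in itertools.combinations(langs_present, 2):
            nodes = [n for n, l in labeled.items() if l in (cat_a, cat_b)]
            sub = graph.subgraph(nodes).copy()
            sub_labels = {n: labeled[n] for n in nodes}
            try:
                r_obs = attribute_assortativity(sub, sub_labels)
            except DomainError:
                continue
            null = null_distribution(
                sub,
                statistic=attribute_assortativity,
                labels=sub_labels,
                n_iterations=config.n_null,
                seed=int(rng.integers(0, 2**31 - 1)),
                swap_factor=config.swap_factor,
                statistic_name=f"assortativity[{cat_a}|{cat_b}]",
                observed=r_obs,
            )
            pairwise[f"{cat_a}|{cat_b}"] = {**null.to_dict(), "null_mode": "fixed_labels"}
        out["pairwise_language"] = pairwise
        # whole-graph language assortativity with fixed-label null
        try:
            r_lang = attribute_assortativity(graph, labeled) if labeled else None
        except DomainError:
            r_lang = None
        if r_lang is not None and len(labeled) == graph.number_of_nodes():
            null = null_distribution(
                graph,
                statistic=attribute_assortativity,
                labels=labeled,
                n_iterations=config.n_null,
                seed=seeds[5],
                swap_factor=config.swap_factor,
                statistic_name="language_assortativity",
                observed=r_lang,
            )
            out["language_assortativity"] = {**null.to_dict(), "null_mode": "fixed_labels"}
    if scope.contingency and partition.n_communities >= 2 and labeled:
        try:
            cont = contingency_alignment(partition, labeled)
            out["contingency"] = {
                "chi2": cont.chi2,
                "df": cont.df,
                "p": cont.p,
                "cramers_v": cont.cramers_v,
                "n": cont.n,
            }
        except DomainError as exc:
            out["contingency"] = {"error": str(exc)}
    return out


def _semantic_analyses(config, scope, graph, partition, embeddings, seeds):
    out: dict = {}
    in_scope = {a: v for a, v in embeddings.items() if a in graph}
    if not in_scope:
        return out
    if partition.n_communities:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ct = centroid_distance_test(in_scope, partition)
            out["centroid_test"] = {
                "t": ct.t, "df": ct.df, "p": ct.p, "cohens_d": ct.cohens_d,
                "ci_d": list(ct.ci_d), "n": ct.n, "degenerate": ct.degenerate,
            }
        except DomainError as exc:
            out["centroid_test"] = {"error": str(exc)}
    bins = distance_by_engagement_bins(
        graph, in_scope, max_zero_pairs=config.max_zero_pairs, seed=seeds[6]
    )
    out["engagement_bins"] = bins.to_dict("records")
    order = sorted(in_scope)
    if len(order) >= 4:
        try:
            qap = mrqap_correlation(
                engagement_weight_matrix(graph, order),
                cosine_distance_matrix(in_scope, order),
                n_permutations=config.qap_permutations,
                seed=seeds[7],
            )
            out["qap"] = {
                "r": qap.r, "p": qap.p, "ci": list(qap.ci),
                "n_permutations": qap.n_permutations, "n_nodes": qap.n_nodes,
                "ci_method": qap.ci_method,
            }
        except DomainError as exc:
            out["qap"] = {"error": str(exc)}
    return out


# ---------------------------------------------------------------------------
# Table emission
# ---------------------------------------------------------------------------

_SCHEMA = {
    "structure.csv": "scope, day, statistic, observed, ci_low, ci_high, p_boot, p_display, n_iterations, null_mode",
    "pairwise_language.csv": "scope, day, pair, observed, ci_low, ci_high, p_boot, p_display, n_iterations",
    "contingency.csv": "scope, day, chi2, df, p, cramers_v, n",
    "centroid.csv": "scope, day, t, df, p, cohens_d, ci_d_low, ci_d_high, n",
    "bins.csv": "scope, day, bin, mean_distance, ci_low, ci_high, n_pairs",
    "qap.csv": "scope, day, r, p, ci_low, ci_high, n_permutations, n_nodes",
    "report.json": "full machine-readable report with provenance",
}


def emit_tables(report: RunReport, out_dir: str | Path) -> list[Path]:
    """Write the report as CSV tables plus the full JSON; returns paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    structure, pairwise, contingency, centroid, bins, qap = [], [], [], [], [], []
    for key in sorted(report.results):
        res = report.results[key]
        scope, day = res["scope"], res["day"]
        for stat_name, stat in (res.get("structure") or {}).items():
            structure.append({
                "scope": scope, "day": day, "statistic": stat_name,
                "observed": stat["observed"], "ci_low": stat["ci_low"],
                "ci_high": stat["ci_high"], "p_boot": stat["p_boot"],
                "p_display": stat["p_display"],
                "n_iterations": stat["n_iterations"],
                "null_mode": stat.get("null_mode", ""),
            })
        for pair, stat in (res.get("pairwise_language") or {}).items():
            pairwise.append({
                "scope": scope, "day": day, "pair": pair,
                "observed": stat["observed"], "ci_low": stat["ci_low"],
                "ci_high": stat["ci_high"], "p_boot": stat["p_boot"],
                "p_display": stat["p_display"],
                "n_iterations": stat["n_iterations"],
            })
        cont = res.get("contingency")
        if cont and "error" not in cont:
            contingency.append({"scope": scope, "day": day, **cont})
        ct = res.get("centroid_test")
        if ct and "error" not in ct:
            centroid.append({
                "scope": scope, "day": day, "t": ct["t"], "df": ct["df"],
                "p": ct["p"], "cohens_d": ct["cohens_d"],
                "ci_d_low": ct["ci_d"][0], "ci_d_high": ct["ci_d"][1],
                "n": ct["n"],
            })
        for row in res.get("engagement_bins") or []:
            bins.append({"scope": scope, "day": day, **row})
        q = res.get("qap")
        if q and "error" not in q:
            qap.append({
                "scope": scope, "day": day, "r": q["r"], "p": q["p"],
                "ci_low": q["ci"][0], "ci_high": q["ci"][1],
                "n_permutations": q["n_permutations"], "n_nodes": q["n_nodes"],
            })
    written = []
    tables = {
        "structure.csv": structure,
        "pairwise_language.csv": pairwise,
        "contingency.csv": contingency,
        "centroid.csv": centroid,
        "bins.csv": bins,
        "qap.csv": qap,
    }
    for name, rows in tables.items():
        path = out_dir / name
        pd.DataFrame(rows).to_csv(path, index=False)
        written.append(path)
    report_path = out_dir / "report.json"
    report_path.write_text(report.to_json())
    written.append(report_path)
    schema_path = out_dir / "schema.json"
    schema_path.write_text(json.dumps(_SCHEMA, indent=2))
    written.append(schema_path)
    return written
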