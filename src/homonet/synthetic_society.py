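"""Synthetic agent societies with planted homophily structure.

Generates a growing population of agents carrying a language label, a topic
within that language, and a unit-norm content embedding (topic centroid plus
Gaussian noise), then simulates an engagement log in which each event's
target is drawn with weight

    exp(-h_C * d_cos(source, target)) * lang_factor

where ``lang_factor`` is (1 + h_L * 9) for same-language pairs and (1 - h_L)
for cross-language pairs: h_L spans "no language preference" (0) to absolute
segregation (1), and h_C sets how steeply tie probability decays with
embedding distance.  Everything is deterministic given the config seed, so
downstream stages can be validated by parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .community_detect import Partition
from .errors import ConfigurationError
from .network_build import EVENT_TYPES, EngagementEvent

__all__ = [
    "SocietyConfig",
    "Agent",
    "SyntheticSociety",
    "generate_society",
    "planted_partition",
    "render_posts",
    "write_agents_csv",
    "write_embeddings_csv",
    "read_embeddings_csv",
]

DEFAULT_LANGUAGE_PROPS = {
    "english": 0.55,
    "chinese": 0.20,
    "japanese": 0.15,
    "other": 0.10,
}

#: Same-language boost scale: at h_L = 1 a same-language target is weighted
#: (1 + B) = 10x before normalization, and cross-language weight is 0.
LANG_BOOST = 9.0


@dataclass
class SocietyConfig:
    """Knobs of the generator; validated field by field."""

    n_agents: int = 500
    n_days: int = 28
    language_props: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_LANGUAGE_PROPS)
    )
    n_topics_per_language: int = 3
    lang_homophily: float = 0.0
    content_homophily: float = 0.0
    activity_shape: float = 1.5
    events_per_day: float = 200.0
    growth_rate: float = 0.0
    embed_dim: int = 16
    noise_sd: float = 0.25
    seed: int = 0

    def validate(self) -> None:
        if self.n_agents < 1:
            raise ConfigurationError("n_agents must be >= 1")
        if self.n_days < 1:
            raise ConfigurationError("n_days must be >= 1")
        props = np.array(list(self.language_props.values()), dtype=float)
        if len(props) < 1 or (props < 0).any():
            raise ConfigurationError("language_props must be non-negative")
        if abs(props.sum() - 1.0) > 1e-9:
            raise ConfigurationError(
                f"language_props must sum to 1, got {props.sum():.12g}"
            )
        if self.n_topics_per_language < 1:
            raise ConfigurationError("n_topics_per_language must be >= 1")
        if not 0.0 <= self.lang_homophily <= 1.0:
            raise ConfigurationError("lang_homophily must be in [0, 1]")
        if self.content_homophily < 0:
            raise ConfigurationError("content_homophily must be >= 0")
        if self.activity_shape <= 0:
            raise ConfigurationError("activity_shape must be > 0")
        if self.events_per_day <= 0:
            raise ConfigurationError("events_per_day must be > 0")
        if self.growth_rate < 0:
            raise ConfigurationError("growth_rate must be >= 0")
        if self.embed_dim < 2:
            raise ConfigurationError("embed_dim must be >= 2")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")


@dataclass(frozen=True)
class Agent:
    agent_id: str
    language: str
    topic: str
    embedding: np.ndarray
    join_day: int


@dataclass
class SyntheticSociety:
    """Agents, their engagement log, and the planted ground truth."""

    agents: list[Agent]
    events: list[EngagementEvent]
    config: SocietyConfig
    ground_truth: dict[str, dict[str, str]]

    @property
    def n_agents(self) -> int:
        return len(self.agents)

    def languages(self) -> dict[str, str]:
        return {a.agent_id: a.language for a in self.agents}

    def embeddings(self) -> dict[str, np.ndarray]:
        return {a.agent_id: a.embedding for a in self.agents}

    def embedding_matrix(self) -> tuple[list[str], np.ndarray]:
        ids = [a.agent_id for a in self.agents]
        return ids, np.vstack([a.embedding for a in self.agents])


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def generate_society(config: SocietyConfig) -> SyntheticSociety:
    """Generate a society per the config; byte-identical for the same seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    languages = list(config.language_props.keys())
    props = np.array([config.language_props[l] for l in languages], dtype=float)
    props = props / props.sum()

    # Population schedule: n_agents join on day 1; each later day adds
    # round(growth_rate * current population).
    join_days = [1] * config.n_agents
    for day in range(2, config.n_days + 1):
        join_days.extend([day] * int(round(config.growth_rate * len(join_days))))
    n_total = len(join_days)

    width = len(str(n_total))
    agent_ids = [f"a{str(i).zfill(width)}" for i in range(n_total)]
    agent_langs = [languages[k] for k in rng.choice(len(languages), size=n_total, p=props)]
    topic_ks = rng.integers(0, config.n_topics_per_language, size=n_total)
    agent_topics = [f"{lang}:t{k}" for lang, k in zip(agent_langs, topic_ks)]

    centroids = {
        f"{lang}:t{k}": _unit(rng.standard_normal(config.embed_dim))
        for lang in languages
        for k in range(config.n_topics_per_language)
    }
    emb = np.vstack([
        _unit(centroids[t] + config.noise_sd * rng.standard_normal(config.embed_dim))
        for t in agent_topics
    ])

    # Pairwise sampling weights, fixed over the run.
    dist = np.clip(1.0 - emb @ emb.T, 0.0, 2.0)
    lang_idx = np.array([languages.index(l) for l in agent_langs])
    same_lang = lang_idx[:, None] == lang_idx[None, :]
    h_l, h_c = config.lang_homophily, config.content_homophily
    lang_factor = np.where(same_lang, 1.0 + h_l * LANG_BOOST, 1.0 - h_l)
    weight = np.exp(-h_c * dist) * lang_factor
    np.fill_diagonal(weight, 0.0)

    activity = 1.0 + rng.pareto(config.activity_shape, size=n_total)
    join_arr = np.array(join_days)

    events: list[EngagementEvent] = []
    for day in range(1, config.n_days + 1):
        joined = np.flatnonzero(join_arr <= day)
        if len(joined) < 2:
            continue
        act = activity[joined]
        act = act / act.sum()
        n_events = int(rng.poisson(config.events_per_day))
        sources = rng.choice(joined, size=n_events, p=act)
        types = rng.choice(len(EVENT_TYPES), size=n_events)
        for src, t in zip(sources, types):
            row = weight[src, joined]
            total = row.sum()
            if total <= 0:  # isolated language under h_L = 1
                continue
            tgt = int(rng.choice(joined, p=row / total))
            events.append(
                EngagementEvent(
                    source=agent_ids[src],
                    target=agent_ids[tgt],
                    type=EVENT_TYPES[t],
                    day=day,
                )
            )

    agents = [
        Agent(agent_ids[i], agent_langs[i], agent_topics[i], emb[i], join_days[i])
        for i in range(n_total)
    ]
    ground_truth = {
        "language": {a.agent_id: a.language for a in agents},
        "topic": {a.agent_id: a.topic for a in agents},
    }
    return SyntheticSociety(
        agents=agents, events=events, config=config, ground_truth=ground_truth
    )


def planted_partition(society: SyntheticSociety, level: str = "language") -> Partition:
    """Ground-truth memberships at ``level`` ("language" or "topic")."""
    if level not in society.ground_truth:
        raise ValueError(
            f"unknown level {level!r}; expected one of {sorted(society.ground_truth)}"
        )
    groups: dict[str, set[str]] = {}
    for agent_id, label in society.ground_truth[level].items():
        groups.setdefault(label, set()).add(agent_id)
    return Partition.from_communities(groups.values(), algorithm="planted")


def render_posts(
    society: SyntheticSociety, n_posts: int = 3, seed: int | None = None
) -> dict[str, list[str]]:
    """Toy text per agent (topic keyword strings) for the text-cleaning path.

    Not meant to be realistic; the keywords make topics recoverable from
    token overlap, and the sprinkled punctuation exercises cleaning.
    """
    rng = np.random.default_rng(society.config.seed if seed is None else seed)
    filler = ["today", "really", "just", "new", "more", "time", "good", "day"]
    posts: dict[str, list[str]] = {}
    for agent in society.agents:
        topic_tokens = [agent.topic.replace(":", "_") + f"_kw{j}" for j in range(3)]
        agent_posts = []
        for _ in range(n_posts):
            words = list(rng.choice(topic_tokens, size=3)) + list(
                rng.choice(filler, size=2)
            )
            rng.shuffle(words)
            agent_posts.append(" ".join(words) + "!")
        posts[agent.agent_id] = agent_posts
    return posts


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_agents_csv(society: SyntheticSociety, path: str | Path) -> None:
    rows = [
        {
            "agent_id": a.agent_id,
            "language": a.language,
            "topic": a.topic,
            "join_day": a.join_day,
        }
        for a in society.agents
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_embeddings_csv(society: SyntheticSociety, path: str | Path) -> None:
    ids, mat = society.embedding_matrix()
    frame = pd.DataFrame(mat, index=pd.Index(ids, name="agent_id"))
    frame.columns = [f"e{j}" for j in range(mat.shape[1])]
    frame.to_csv(path)


def read_embeddings_csv(path: str | Path) -> dict[str, np.ndarray]:
    frame = pd.read_csv(path, index_col="agent_id")
    return {str(i): row.to_numpy(dtype=float) for i, row in frame.iterrows()}
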