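# homonet

Homophily detection in agent engagement networks.

`homonet` turns dyadic engagement logs (follow / like / dislike / mention
events between agents) into cumulative weighted undirected graphs and asks
whether the network's communities form around similar agents:

- **network_build** — cumulative Day-k graphs from event logs; low-degree
  pruning; CSV/JSONL/TSV/GraphML I/O.
- **community_detect** — weighted asynchronous label propagation and greedy
  modularity clustering; small-community filtering; o(A) overlap-rate
  consistency scoring across repeated clustering runs.
- **graph_stats** — weighted Newman modularity and categorical
  (mixing-matrix) assortativity, including pairwise two-category
  assortativity on induced subgraphs.
- **null_inference** — degree-preserving double-edge-swap rewiring (edge
  weights travel with edges), bootstrapped one-sided p-values and SD-based
  95% confidence intervals for any graph statistic, with re-clustered or
  fixed-label null modes.
- **content_alignment** — community × category contingency tests (Pearson
  χ², Cramér's V), text cleaning, pluggable embedding encoders (a
  deterministic offline hashed-projection encoder is bundled), centroid
  paired t-tests with Cohen's d = t/√n, pairwise cosine distances binned by
  engagement count, and MRQAP dyadic matrix regression.
- **synthetic_society** — a generator of growing agent populations with
  planted language-block and content-similarity homophily (tunable
  `lang_homophily` / `content_homophily`), so every stage is validated by
  parameter recovery.
- **pipeline / cli** — a configured, seeded, logged end-to-end run over
  multiple day cutoffs and scopes, emitting machine-readable CSV tables.

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (oracle
equivalence against brute-force statistics, null calibration, power /
parameter recovery, content-homophily recovery, paired-test arithmetic, and
o(A) unit behavior). The optional dataset tier runs only when
`HOMONET_OSF_DIR` points at a local copy of the deposited dataset.

## CLI

```sh
homonet simulate --n-agents 500 --n-days 28 --lang-homophily 0.9 \
    --seed 1 --out-dir runs/sim
homonet build --events runs/sim/events.csv --day-cutoff 28 --out runs/g28.tsv
homonet cluster --graph runs/g28.tsv --algorithm label_propagation \
    --seed 1 --out runs/partition.csv
homonet stats --graph runs/g28.tsv --partition runs/partition.csv
homonet null --graph runs/g28.tsv --labels runs/sim/agents.csv \
    --iterations 1000 --seed 1
homonet align --partition runs/partition.csv --agents runs/sim/agents.csv
homonet run-all --config config.yaml --out-dir runs/
```

A `run-all` config is YAML mirroring `homonet.RunConfig`; e.g.

```yaml
society:
  n_agents: 500
  n_days: 28
  lang_homophily: 0.9
  seed: 1
day_cutoffs: [7, 14, 21, 28]
n_null: 1000
n_consistency: 1000
seed: 1
```

Outputs land in a directory keyed by the config hash: `structure.csv`,
`pairwise_language.csv`, `contingency.csv`, `centroid.csv`, `bins.csv`,
`qap.csv`, `report.json` and `schema.json`. Reports are deterministic given
seeds (hash-equal JSON across reruns).

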