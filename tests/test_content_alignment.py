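import networkx as nx
import numpy as np
import pytest
from scipy import stats

from homonet import (
    AgentContent,
    DomainError,
    HashedProjectionEncoder,
    Partition,
    centroid_distance_test,
    clean_text,
    contingency_alignment,
    cosine_distance,
    distance_by_engagement_bins,
    embed_agent,
    greedy_modularity,
    mrqap_correlation,
    planted_partition,
)
from homonet.content_alignment import (
    cosine_distance_matrix,
    engagement_weight_matrix,
)


class TestCleanText:
    def test_non_roman_removed(self):
        assert clean_text("Hello, world! 你好") == "Hello world"

    def test_punctuation_removed(self):
        assert clean_text("a.b,c;d") == "abcd"

    def test_whitespace_collapsed(self):
        assert clean_text("  x   y  ") == "x y"

    def test_empty(self):
        assert clean_text("") == ""

    def test_digits_kept(self):
        assert clean_text("agent 42!") == "agent 42"


class TestEncoderAndEmbedding:
    def test_identical_texts_identical_embeddings(self):
        enc = HashedProjectionEncoder(dim=32, seed=0)
        a = embed_agent(AgentContent("a", raw_posts=["hello world"]), enc)
        b = embed_agent(AgentContent("b", raw_posts=["hello world"]), enc)
        np.testing.assert_array_equal(a.embedding, b.embedding)

    def test_unit_norm(self):
        enc = HashedProjectionEncoder(dim=32, seed=1)
        c = embed_agent(AgentContent("a", raw_posts=["some text here"]), enc)
        assert np.linalg.norm(c.embedding) == pytest.approx(1.0, abs=1e-9)

    def test_disjoint_token_sets_near_orthogonal(self):
        sims = []
        for seed in range(50):
            enc = HashedProjectionEncoder(dim=64, seed=seed)
            a = embed_agent(AgentContent("a", raw_posts=["alpha beta gamma"]), enc)
            b = embed_agent(AgentContent("b", raw_posts=["delta epsilon zeta"]), enc)
            sims.append(float(a.embedding @ b.embedding))
        assert abs(np.mean(sims)) < 0.05

    def test_empty_text_excluded(self):
        enc = HashedProjectionEncoder(dim=16, seed=0)
        c = embed_agent(AgentContent("a", raw_posts=["你好。！"]), enc)
        assert c.excluded
        assert c.embedding is None

    def test_cleaning_applied_before_encoding(self):
        enc = HashedProjectionEncoder(dim=32, seed=2)
        a = embed_agent(AgentContent("a", raw_posts=["hello, world!"]), enc)
        b = embed_agent(AgentContent("b", raw_posts=["hello world"]), enc)
        np.testing.assert_allclose(a.embedding, b.embedding)


class TestCosineDistance:
    def test_identical(self):
        v = np.array([1.0, 2.0, 3.0])
        assert cosine_distance(v, v) == pytest.approx(0.0)

    def test_orthogonal(self):
        assert cosine_distance([1, 0], [0, 1]) == pytest.approx(1.0)

    def test_opposite(self):
        assert cosine_distance([1.0, 0.0], [-1.0, 0.0]) == pytest.approx(2.0)

    def test_zero_vector_rejected(self):
        with pytest.raises(DomainError):
            cosine_distance([0.0, 0.0], [1.0, 0.0])


class TestContingency:
    def _partition(self, mapping):
        groups = {}
        for agent, cid in mapping.items():
            groups.setdefault(cid, set()).add(agent)
        return Partition.from_communities(groups.values(), "planted")

    def test_perfect_diagonal_table(self):
        mapping = {f"a{i}": 0 for i in range(10)} | {f"b{i}": 1 for i in range(10)}
        labels = {f"a{i}": "x" for i in range(10)} | {f"b{i}": "y" for i in range(10)}
        res = contingency_alignment(self._partition(mapping), labels)
        assert res.chi2 == pytest.approx(20.0)
        assert res.cramers_v == pytest.approx(1.0)
        assert res.df == 1
        assert res.n == 20

    def test_uniform_table_is_zero(self):
        mapping = {}
        labels = {}
        for cid in range(2):
            for cat in ("x", "y"):
                for k in range(5):
                    agent = f"{cid}{cat}{k}"
                    mapping[agent] = cid
                    labels[agent] = cat
        res = contingency_alignment(self._partition(mapping), labels)
        assert res.chi2 == pytest.approx(0.0)
        assert res.cramers_v == pytest.approx(0.0)

    def test_df_formula(self):
        rng = np.random.default_rng(0)
        mapping, labels = {}, {}
        for i in range(200):
            mapping[f"a{i}"] = int(rng.integers(0, 3))
            labels[f"a{i}"] = str(rng.integers(0, 4))
        res = contingency_alignment(self._partition(mapping), labels)
        assert res.df == (3 - 1) * (4 - 1)
        assert 0.0 <= res.cramers_v <= 1.0

    def test_independence_calibration(self):
        rng = np.random.default_rng(1)
        ps = []
        for _ in range(40):
            mapping, labels = {}, {}
            for i in range(300):
                mapping[f"a{i}"] = int(rng.integers(0, 2))
                labels[f"a{i}"] = int(rng.integers(0, 2))
            res = contingency_alignment(self._partition(mapping), labels)
            ps.append(res.p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_degenerate_table_rejected(self):
        mapping = {"a": 0, "b": 0}
        labels = {"a": "x", "b": "y"}
        with pytest.raises(DomainError):
            contingency_alignment(self._partition(mapping), labels)


class TestCentroidTest:
    def test_identical_embeddings_degenerate(self):
        emb = {f"a{i}": np.array([1.0, 0.0]) for i in range(6)}
        part = Partition.from_communities(
            [{"a0", "a1", "a2"}, {"a3", "a4", "a5"}], "planted"
        )
        res = centroid_distance_test(emb, part)
        assert res.degenerate
        assert res.cohens_d == 0.0

    def test_topic_partition_yields_negative_effect(self, content_society):
        soc = content_society
        emb = soc.embeddings()
        part = planted_partition(soc, "topic")
        res = centroid_distance_test(emb, part)
        assert res.t < 0
        assert res.cohens_d < 0
        assert res.cohens_d == pytest.approx(res.t / np.sqrt(res.n))
        assert res.df == res.n - 1
        assert res.p < 0.05

    def test_singleton_communities_skipped(self):
        rng = np.random.default_rng(0)
        emb = {f"a{i}": rng.standard_normal(4) for i in range(5)}
        emb = {k: v / np.linalg.norm(v) for k, v in emb.items()}
        part = Partition.from_communities([{"a0", "a1", "a2", "a3"}, {"a4"}], "planted")
        with pytest.warns(UserWarning, match="single"):
            res = centroid_distance_test(emb, part)
        assert res.n == 4

    def test_all_degenerate_raises(self):
        emb = {"a": np.array([1.0, 0.0]), "b": np.array([0.0, 1.0])}
        part = Partition.from_communities([{"a"}, {"b"}], "planted")
        with pytest.warns(UserWarning):
            with pytest.raises(DomainError):
                centroid_distance_test(emb, part)

    def test_leave_one_out_flag(self, content_society):
        soc = content_society
        emb = soc.embeddings()
        part = planted_partition(soc, "topic")
        res_in = centroid_distance_test(emb, part, include_self=True)
        res_out = centroid_distance_test(emb, part, include_self=False)
        # excluding the focal agent moves the centroid away from it
        assert res_out.mean_community_distance > res_in.mean_community_distance


class TestEngagementBins:
    def test_weight_seven_lands_in_top_bin(self):
        g = nx.Graph()
        g.add_edge("a", "b", weight=7)
        emb = {"a": np.array([1.0, 0.0]), "b": np.array([0.0, 1.0])}
        table = distance_by_engagement_bins(g, emb, seed=0)
        top = table[table["bin"] == "5+"].iloc[0]
        assert top["n_pairs"] == 1
        assert top["mean_distance"] == pytest.approx(1.0)
        zero = table[table["bin"] == "0"].iloc[0]
        assert zero["n_pairs"] == 0
        assert np.isnan(zero["mean_distance"])

    def test_bins_cover_all_pairs(self):
        rng = np.random.default_rng(2)
        g = nx.Graph()
        ids = [f"a{i}" for i in range(12)]
        for i in range(0, 12, 2):
            g.add_edge(ids[i], ids[i + 1], weight=int(rng.integers(1, 8)))
        emb = {a: rng.standard_normal(5) for a in ids}
        table = distance_by_engagement_bins(g, emb, seed=3)
        assert table["n_pairs"].sum() == 12 * 11 // 2

    def test_zero_bin_subsampled(self):
        rng = np.random.default_rng(4)
        ids = [f"a{i}" for i in range(60)]
        g = nx.Graph()
        g.add_edge(ids[0], ids[1], weight=1)
        emb = {a: rng.standard_normal(4) for a in ids}
        table = distance_by_engagement_bins(g, emb, max_zero_pairs=100, seed=5)
        zero = table[table["bin"] == "0"].iloc[0]
        assert zero["n_pairs"] == 100

    def test_ci_brackets_mean(self):
        rng = np.random.default_rng(6)
        ids = [f"a{i}" for i in range(20)]
        g = nx.Graph()
        for i in range(10):
            g.add_edge(ids[i], ids[i + 10], weight=i % 6 + 1)
        emb = {a: rng.standard_normal(6) for a in ids}
        table = distance_by_engagement_bins(g, emb, seed=7)
        filled = table[table["n_pairs"] > 0]
        assert (filled["ci_low"] <= filled["mean_distance"]).all()
        assert (filled["mean_distance"] <= filled["ci_high"]).all()


class TestMRQAP:
    def _random_symmetric(self, rng, n):
        m = rng.standard_normal((n, n))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0.0)
        return m

    def test_perfect_dependence(self):
        rng = np.random.default_rng(0)
        w = self._random_symmetric(rng, 15)
        d = 2.0 * w + 1.0
        np.fill_diagonal(d, 0.0)
        res = mrqap_correlation(w, d, n_permutations=100, seed=1)
        assert abs(res.r) > 0.999
        assert res.p == pytest.approx(1 / 100)

    def test_independent_matrices_p_uniform(self):
        rng = np.random.default_rng(2)
        ps = []
        for seed in range(60):
            w = self._random_symmetric(rng, 25)
            d = self._random_symmetric(rng, 25)
            res = mrqap_correlation(w, d, n_permutations=100, seed=seed)
            ps.append(res.p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_node_order_invariance(self):
        rng = np.random.default_rng(3)
        w = self._random_symmetric(rng, 12)
        d = self._random_symmetric(rng, 12)
        perm = rng.permutation(12)
        res1 = mrqap_correlation(w, d, n_permutations=200, seed=4)
        res2 = mrqap_correlation(
            w[np.ix_(perm, perm)], d[np.ix_(perm, perm)], n_permutations=200, seed=4
        )
        assert res1.r == pytest.approx(res2.r)
        assert abs(res1.p - res2.p) < 0.1

    def test_constant_matrix_rejected(self):
        rng = np.random.default_rng(5)
        w = np.zeros((6, 6))
        d = self._random_symmetric(rng, 6)
        with pytest.raises(DomainError):
            mrqap_correlation(w, d, n_permutations=10, seed=0)

    def test_too_small_rejected(self):
        m = np.zeros((3, 3))
        with pytest.raises(ValueError):
            mrqap_correlation(m, m, n_permutations=10, seed=0)

    def test_asymmetric_rejected(self):
        rng = np.random.default_rng(6)
        w = self._random_symmetric(rng, 6)
        bad = w.copy()
        bad[0, 1] += 1.0
        with pytest.raises(ValueError):
            mrqap_correlation(w, bad, n_permutations=10, seed=0)

    def test_content_homophily_gives_negative_r(self, content_society):
        soc = content_society
        from homonet import build_graph

        g = build_graph(soc.events, 14)
        order = sorted(a.agent_id for a in soc.agents)
        w = engagement_weight_matrix(g, order)
        d = cosine_distance_matrix(soc.embeddings(), order)
        res = mrqap_correlation(w, d, n_permutations=200, seed=8)
        assert res.r < 0
        assert res.p < 0.05
        assert res.ci[0] <= res.r <= res.ci[1]
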