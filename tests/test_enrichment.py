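import numpy as np
import pandas as pd
import pytest

from topictree import (GeneSetDAG, enrich_all_topics, enrich_topic,
                       ks_term_test, partition_unique_terms, rank_genes,
                       read_gmt, write_gmt)
from topictree.lda import TopicModel


def _model(phi, genes=None, theta=None):
    K, V = phi.shape
    genes = genes or [f"g{i:03d}" for i in range(V)]
    theta = theta if theta is not None else np.full((3, K), 1.0 / K)
    return TopicModel(theta=theta, phi=phi, alpha=np.ones(K),
                      beta=np.ones(V), K=K,
                      cell_ids=[f"c{j}" for j in range(theta.shape[0])],
                      gene_ids=genes, assignments=np.empty(0, dtype=np.int32),
                      loglik_trace=np.empty(0), seed=0)


def _random_model(V=300, K=3, seed=0):
    rng = np.random.default_rng(seed)
    phi = rng.dirichlet(np.full(V, 0.5), size=K)
    return _model(phi)


class TestGmtAndDag:
    def test_gmt_round_trip(self, tmp_path):
        sets = {"T1": {"a", "b", "c"}, "T2": {"c", "d"}}
        write_gmt(sets, tmp_path / "s.gmt")
        back = read_gmt(tmp_path / "s.gmt")
        assert {t: g for t, (_, g) in back.items()} == sets

    def test_cycle_rejected(self):
        with pytest.raises(ValueError, match="cycle"):
            GeneSetDAG({}, {"A": {"x"}, "B": {"y"}},
                       parents={"A": {"B"}, "B": {"A"}})

    def test_annotations_propagate_upward(self):
        dag = GeneSetDAG({}, {"root": set(), "mid": {"m"}, "leaf": {"l"}},
                         parents={"leaf": {"mid"}, "mid": {"root"}})
        assert dag.term_genes["mid"] == {"m", "l"}
        assert dag.term_genes["root"] == {"m", "l"}


class TestRankGenes:
    def test_known_phi_hand_sort(self):
        phi = np.array([[0.5, 0.2, 0.3], [0.1, 0.6, 0.3]])
        m = _model(phi, genes=["gx", "gy", "gz"])
        assert [g for g, _ in rank_genes(m, 1)] == ["gx", "gz", "gy"]
        assert [g for g, _ in rank_genes(m, 2)] == ["gy", "gz", "gx"]

    def test_uniform_row_ties_lexicographic(self):
        phi = np.full((2, 4), 0.25)
        m = _model(phi, genes=["d", "b", "a", "c"])
        ranked = rank_genes(m, 1)
        assert [g for g, _ in ranked] == ["a", "b", "c", "d"]
        assert all(p == pytest.approx(0.25) for _, p in ranked)

    def test_matches_argsort_oracle(self):
        m = _random_model(seed=3)
        ranked = [g for g, _ in rank_genes(m, 2)]
        order = np.argsort(-m.phi[1], kind="stable")
        expected = [m.gene_ids[i] for i in order]
        # identical up to ties (probabilities are continuous: no ties)
        assert ranked == expected

    def test_out_of_range_topic_rejected(self):
        m = _random_model()
        with pytest.raises(ValueError):
            rank_genes(m, 0)
        with pytest.raises(ValueError):
            rank_genes(m, 4)


class TestKsTermTest:
    def test_top_block_is_highly_significant(self):
        m = _random_model(V=1000, seed=1)
        ranked = rank_genes(m, 1)
        term = {g for g, _ in ranked[:10]}
        assert ks_term_test(ranked, term) < 1e-6

    def test_whole_universe_has_no_contrast(self):
        m = _random_model(V=50, seed=2)
        ranked = rank_genes(m, 1)
        assert ks_term_test(ranked, {g for g, _ in ranked},
                            max_term_fraction=1.0) == 1.0

    def test_small_terms_skipped(self):
        m = _random_model(V=50, seed=2)
        ranked = rank_genes(m, 1)
        assert ks_term_test(ranked, {ranked[0][0]}) is None

    def test_null_pvalues_roughly_uniform(self):
        from scipy.stats import kstest
        rng = np.random.default_rng(10)
        m = _random_model(V=500, seed=10)
        ranked = rank_genes(m, 1)
        genes = [g for g, _ in ranked]
        ps = [ks_term_test(ranked, set(rng.choice(genes, 10, replace=False)))
              for _ in range(200)]
        frac = np.mean([p < 0.05 for p in ps])
        se = np.sqrt(0.05 * 0.95 / len(ps))
        assert abs(frac - 0.05) < 3 * se + 1e-9
        assert kstest(ps, "uniform").pvalue > 0.01


def _planted_setup(seed=5):
    """Topic 1's top genes are exactly term A; unrelated terms elsewhere."""
    rng = np.random.default_rng(seed)
    V = 400
    genes = [f"g{i:03d}" for i in range(V)]
    phi = rng.dirichlet(np.full(V, 0.5), size=2)
    top = np.argsort(-phi[0])[:20]
    term_a = {genes[i] for i in top}
    others = {f"R{j}": set(rng.choice(genes, 15, replace=False))
              for j in range(10)}
    dag = GeneSetDAG({}, {"A": term_a, **others})
    return _model(phi, genes=genes), dag, term_a


class TestEnrichTopic:
    def test_edgeless_dag_methods_identical(self):
        m, dag, _ = _planted_setup()
        tables = {meth: enrich_topic(m, 1, dag, method=meth)
                  for meth in ("classic", "elim", "weight")}
        pd.testing.assert_frame_equal(
            tables["classic"].drop(columns="method"),
            tables["elim"].drop(columns="method"))
        pd.testing.assert_frame_equal(
            tables["classic"].drop(columns="method"),
            tables["weight"].drop(columns="method"))

    def test_elim_raises_parent_pvalue_on_chain(self):
        """Child holds all the signal; elim strips it from the parent."""
        rng = np.random.default_rng(6)
        V = 300
        genes = [f"g{i:03d}" for i in range(V)]
        phi = rng.dirichlet(np.full(V, 0.5), size=2)
        top = np.argsort(-phi[0])
        child = {genes[i] for i in top[:12]}
        parent_extra = {genes[i] for i in top[150:160]}
        dag = GeneSetDAG({}, {"child": child, "parent": parent_extra},
                         parents={"child": {"parent"}})
        m = _model(phi, genes=genes)
        classic = enrich_topic(m, 1, dag, method="classic",
                               sig_threshold=0.01).set_index("term_id")
        elim = enrich_topic(m, 1, dag, method="elim",
                            sig_threshold=0.01).set_index("term_id")
        assert elim.loc["parent", "p_raw"] > classic.loc["parent", "p_raw"]
        assert elim.loc["child", "p_raw"] == classic.loc["child", "p_raw"]

    def test_weight_raises_parent_when_child_stronger(self):
        rng = np.random.default_rng(7)
        V = 300
        genes = [f"g{i:03d}" for i in range(V)]
        phi = rng.dirichlet(np.full(V, 0.5), size=2)
        top = np.argsort(-phi[0])
        child = {genes[i] for i in top[:12]}
        parent_extra = {genes[i] for i in top[150:160]}
        dag = GeneSetDAG({}, {"child": child, "parent": parent_extra},
                         parents={"child": {"parent"}})
        m = _model(phi, genes=genes)
        classic = enrich_topic(m, 1, dag, method="classic").set_index("term_id")
        weight = enrich_topic(m, 1, dag, method="weight").set_index("term_id")
        assert weight.loc["parent", "p_raw"] >= classic.loc["parent", "p_raw"]

    def test_planted_term_is_minimum_p_under_all_methods(self):
        m, dag, _ = _planted_setup()
        for meth in ("classic", "elim", "weight"):
            t = enrich_topic(m, 1, dag, method=meth)
            assert t.loc[t["p_raw"].idxmin(), "term_id"] == "A"

    def test_decorrelation_never_adds_significant_terms(self):
        m, dag, _ = _planted_setup(seed=8)
        alpha = 0.05
        counts = {}
        for meth in ("classic", "elim", "weight"):
            t = enrich_topic(m, 1, dag, method=meth)
            counts[meth] = int((t["p_bonferroni"] < alpha).sum())
        assert counts["elim"] <= counts["classic"]
        assert counts["weight"] <= counts["classic"]

    def test_bonferroni_monotone_and_count_correct(self):
        m, dag, _ = _planted_setup()
        t = enrich_topic(m, 1, dag, method="classic")
        assert (t["p_bonferroni"] >= t["p_raw"] - 1e-15).all()
        m_tests = len(t)
        expected = np.minimum(1.0, t["p_raw"] * m_tests)
        np.testing.assert_allclose(t["p_bonferroni"], expected)

    def test_unknown_method_rejected(self):
        m, dag, _ = _planted_setup()
        with pytest.raises(ValueError):
            enrich_topic(m, 1, dag, method="bogus")


class TestPartitionUniqueTerms:
    def _table(self, rows):
        return pd.DataFrame(rows, columns=["topic", "term_id", "name",
                                           "p_raw", "p_bonferroni",
                                           "n_genes_in_term", "method"])

    def test_single_topic_term_is_unique(self):
        rows = [(k, "T", "T", 0.5, 1.0 if k != 1 else 0.001, 5, "classic")
                for k in range(1, 5)]
        out = partition_unique_terms(self._table(rows), alpha=0.05)
        flagged = out[out["unique_to_topic"]]
        assert list(flagged["topic"]) == [1]

    def test_three_of_four_topics_excluded_from_minority(self):
        rows = [(k, "T", "T", 0.001, 0.001 if k <= 3 else 1.0, 5, "classic")
                for k in range(1, 5)]
        out = partition_unique_terms(self._table(rows), alpha=0.05,
                                     n_topics=4)
        sig = out[out["p_bonferroni"] < 0.05]
        assert not sig["unique_to_topic"].any()
        assert not sig["in_minority"].any()  # 3 < 4/2 is false

    def test_exactly_half_is_excluded_boundary(self):
        rows = [(k, "T", "T", 0.001, 0.001 if k <= 2 else 1.0, 5, "classic")
                for k in range(1, 5)]
        out = partition_unique_terms(self._table(rows), alpha=0.05,
                                     n_topics=4)
        assert not out["in_minority"].any()  # 2 < 4/2 is false

    def test_planted_disjoint_signals_are_unique(self):
        rng = np.random.default_rng(9)
        V = 300
        genes = [f"g{i:03d}" for i in range(V)]
        phi = np.zeros((3, V))
        terms = {}
        for k in range(3):
            block = list(range(k * 30, k * 30 + 30))
            row = np.full(V, 0.3 / (V - 30))
            row[block] = 0.7 / 30
            phi[k] = row + rng.uniform(0, 1e-7, V)
            phi[k] /= phi[k].sum()
            terms[f"anchor{k + 1}"] = {genes[i] for i in block}
        m = _model(phi, genes=genes)
        dag = GeneSetDAG({}, terms)
        table = enrich_all_topics(m, dag, method="classic")
        out = partition_unique_terms(table, alpha=0.05)
        for k in range(3):
            row = out[(out["topic"] == k + 1)
                      & (out["term_id"] == f"anchor{k + 1}")]
            assert bool(row["unique_to_topic"].iloc[0])
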