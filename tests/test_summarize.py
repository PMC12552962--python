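"""Enrichment-table contracts, representative terms, broad panel, ranking."""

import numpy as np
import pandas as pd
import pytest

from gosum.clustering import ClusterAssignment
from gosum.errors import InputError, StructuralError
from gosum.similarity import information_content
from gosum.simulate import DagSpec, synth_dag
from gosum.summarize import (
    SIGN_RULE_MESSAGE,
    EnrichmentTable,
    broad_term_panel,
    rank_clusters,
    representative_terms,
)

from conftest import make_graph
from oracles import greedy_representatives


def table(rows, score_type="nes"):
    return EnrichmentTable(
        data=pd.DataFrame(rows, columns=["term_id", "score"]),
        score_type=score_type)


class TestEnrichmentTable:
    def test_duplicate_ids_rejected(self):
        with pytest.raises(InputError, match="duplicated"):
            table([("t1", 2.0), ("t1", 1.5)])

    def test_mixed_sign_nes_rejected_with_documented_error(self):
        with pytest.raises(InputError) as err:
            table([("t1", 2.0), ("t2", -1.5)])
        assert str(err.value) == SIGN_RULE_MESSAGE

    def test_all_negative_nes_accepted(self):
        t = table([("t1", -2.0), ("t2", -1.5)])
        assert t.score_of("t1") == -2.0

    def test_overlap_scores_bounded(self):
        with pytest.raises(InputError, match="overlap"):
            table([("t1", 1.2)], score_type="overlap")

    def test_bad_score_type_rejected(self):
        with pytest.raises(InputError):
            table([("t1", 1.0)], score_type="pvalue")

    def test_tsv_round_trip_with_genes(self):
        text = "term_id\tscore\tpadj\tgenes\nt1\t2.5\t0.01\tg1,g2\nt2\t1.1\t0.03\tg3\n"
        t = EnrichmentTable.read_tsv(text)
        assert t.data.loc[0, "genes"] == ["g1", "g2"]
        t2 = EnrichmentTable.read_tsv(t.to_tsv())
        assert t2.term_ids == ["t1", "t2"]

    def test_padj_outside_unit_interval_rejected(self):
        df = pd.DataFrame({"term_id": ["a"], "score": [1.0], "padj": [1.4]})
        with pytest.raises(InputError, match="p-values"):
            EnrichmentTable(data=df)


class TestRepresentativeTerms:
    def test_singleton_cluster_self_represents(self, diamond):
        rs = representative_terms(diamond, {"d"})
        assert [r.term_id for r in rs.representatives] == ["d"]
        assert rs.representatives[0].covered == frozenset({"d"})

    def test_deepest_shared_ancestor_selected(self):
        g = make_graph([("a1", "root"), ("a2", "a1"), ("a3", "a2"),
                        ("a", "a3"), ("t1", "a"), ("t2", "a")])
        rs = representative_terms(g, {"t1", "t2"}, min_cover=2, min_level=3)
        assert rs.representatives[0].term_id == "a"
        assert rs.representatives[0].covered == frozenset({"t1", "t2"})
        assert not rs.representatives[0].is_member

    def test_root_only_sharing_falls_back_to_self_representation(self):
        g = make_graph([("t1", "root"), ("t2", "root")])
        rs = representative_terms(g, {"t1", "t2"}, min_cover=2, min_level=2)
        assert sorted(r.term_id for r in rs.representatives) == ["t1", "t2"]
        assert all(r.covered == frozenset({r.term_id})
                   for r in rs.representatives)

    def test_covering_partitions_cluster(self):
        for seed in range(20):
            g, _ = synth_dag(DagSpec(n_terms=40, seed=seed))
            rng = np.random.default_rng(seed)
            pool = sorted(g.active_terms)
            members = {pool[i] for i in
                       rng.choice(len(pool), size=12, replace=False)}
            rs = representative_terms(g, members)
            covered = [t for r in rs.representatives for t in r.covered]
            assert sorted(covered) == sorted(members)

    @pytest.mark.parametrize("seed", range(15))
    def test_matches_brute_force_greedy_oracle(self, seed):
        g, _ = synth_dag(DagSpec(n_terms=50, seed=seed))
        rng = np.random.default_rng(seed + 1000)
        pool = sorted(g.active_terms)
        members = {pool[i] for i in
                   rng.choice(len(pool), size=15, replace=False)}
        rs = representative_terms(g, members, min_cover=2, min_level=3,
                                  max_reps=5)
        want = greedy_representatives(g.edges, g.levels, members,
                                      min_cover=2, min_level=3, max_reps=5)
        got = [(r.term_id, r.covered) for r in rs.representatives]
        assert got == want

    def test_min_level_monotonicity(self):
        g, _ = synth_dag(DagSpec(n_terms=60, seed=5))
        pool = sorted(g.active_terms)
        members = set(pool[10:25])
        prev = None
        for min_level in (2, 3, 4, 5):
            rs = representative_terms(g, members, min_level=min_level)
            first_cover = len(rs.representatives[0].covered)
            if prev is not None:
                assert first_cover <= prev
            prev = first_cover

    def test_empty_cluster_rejected(self, diamond):
        with pytest.raises(InputError):
            representative_terms(diamond, set())

    def test_max_reps_budget_respected(self):
        g, _ = synth_dag(DagSpec(n_terms=60, seed=2))
        members = set(sorted(g.active_terms)[5:35])
        rs = representative_terms(g, members, max_reps=2)
        non_self = [r for r in rs.representatives
                    if r.covered != frozenset({r.term_id})
                    or len(r.covered) > 1]
        assert len(non_self) <= 2
        assert rs.covered_union == members


class TestBroadPanel:
    def test_percentage_arithmetic(self):
        edges = [("b", "root"), ("c", "root")]
        edges += [(f"x{i}", "b") for i in range(6)]
        edges += [(f"y{i}", "c") for i in range(4)]
        g = make_graph(edges)
        inputs = [f"x{i}" for i in range(6)] + [f"y{i}" for i in range(4)]
        panel = broad_term_panel(g, inputs, broad_level=2)
        assert dict(panel.entries)["b"] == pytest.approx(60.0)
        assert dict(panel.entries)["c"] == pytest.approx(40.0)

    def test_level_two_input_counts_itself(self):
        g = make_graph([("b", "root"), ("x", "b")])
        panel = broad_term_panel(g, ["b", "x"], broad_level=2)
        assert dict(panel.entries)["b"] == pytest.approx(100.0)

    def test_multi_parent_term_counts_toward_both(self):
        g = make_graph([("b1", "root"), ("b2", "root"),
                        ("t", "b1"), ("t", "b2")])
        panel = broad_term_panel(g, ["t"], broad_level=2)
        assert dict(panel.entries) == {"b1": 100.0, "b2": 100.0}

    def test_missing_level_rejected(self, chain):
        with pytest.raises(StructuralError):
            broad_term_panel(chain, ["b"], broad_level=9)

    def test_order_invariance_and_bounds(self):
        g, _ = synth_dag(DagSpec(n_terms=50, seed=7))
        pool = sorted(g.active_terms)[5:30]
        p1 = broad_term_panel(g, pool, top_k=50)
        p2 = broad_term_panel(g, list(reversed(pool)), top_k=50)
        assert p1.entries == p2.entries
        assert all(0.0 < pct <= 100.0 for _, pct in p1.entries)

    def test_top_k_and_tie_break(self):
        g = make_graph([("b1", "root"), ("b2", "root"), ("b3", "root"),
                        ("t", "b1"), ("t", "b2"), ("u", "b3")])
        panel = broad_term_panel(g, ["t", "u"], broad_level=2, top_k=2)
        assert [e[0] for e in panel.entries] == ["b1", "b2"]


class TestRankClusters:
    def assignment(self, mapping):
        return ClusterAssignment(labels=mapping,
                                 n_clusters=len(set(mapping.values())),
                                 method="binary")

    def test_descending_mean(self):
        t = table([("a", 2.5), ("b", 2.5), ("c", 1.2)])
        asg = self.assignment({"a": 1, "b": 1, "c": 2})
        ranks = rank_clusters(t, asg)
        assert [r.cluster for r in ranks] == [1, 2]
        assert ranks[0].mean_score == pytest.approx(2.5)

    def test_negative_nes_ranked_by_magnitude(self):
        t = table([("a", -2.5), ("b", -1.2)])
        asg = self.assignment({"a": 1, "b": 2})
        ranks = rank_clusters(t, asg)
        assert [r.cluster for r in ranks] == [1, 2]

    def test_tie_prefers_larger_cluster(self):
        rows = [(f"a{i}", 2.0) for i in range(5)] + \
               [(f"b{i}", 2.0) for i in range(3)]
        t = table(rows)
        labels = {f"a{i}": 2 for i in range(5)}
        labels.update({f"b{i}": 1 for i in range(3)})
        ranks = rank_clusters(t, self.assignment(labels))
        assert [r.cluster for r in ranks] == [2, 1]
        assert [r.size for r in ranks] == [5, 3]

    def test_missing_term_named_in_error(self):
        t = table([("a", 2.0)])
        asg = self.assignment({"a": 1, "ghost": 2})
        with pytest.raises(InputError, match="ghost"):
            rank_clusters(t, asg)
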