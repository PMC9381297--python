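"""Shared-gene counting, Jaccard scoring and bipartite network construction."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import _oracles
from diseasome.errors import ValidationError
from diseasome.network import (
    DiseaseGeneSets,
    build_diseasome,
    combine_focal_datasets,
    jaccard_score,
    membership_patterns,
    shared_gene_count,
)

genes = st.sets(st.sampled_from([f"g{i}" for i in range(30)]), max_size=15)


class TestSetScores:
    def test_hand_examples(self):
        assert shared_gene_count({"g1", "g2", "g3"}, {"g2", "g3", "g5"}) == 2
        assert shared_gene_count({"a"}, {"b"}) == 0
        assert jaccard_score({"a", "b", "c"}, {"b", "c", "d"}) == 0.5
        assert jaccard_score({"x", "y"}, {"x", "y"}) == 1.0
        assert jaccard_score({"a"}, {"b"}) == 0.0

    def test_both_empty_is_undefined(self, caplog):
        with caplog.at_level("WARNING"):
            assert math.isnan(jaccard_score(set(), set()))

    def test_matches_brute_force_on_random_pairs(self):
        rng = np.random.default_rng(23)
        pool = [f"g{i}" for i in range(40)]
        for _ in range(1000):
            a = set(rng.choice(pool, size=rng.integers(1, 20), replace=False))
            b = set(rng.choice(pool, size=rng.integers(1, 20), replace=False))
            assert shared_gene_count(a, b) == len(a & b)
            assert jaccard_score(a, b) == pytest.approx(_oracles.jaccard_brute(a, b))

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(genes, genes)
    def test_symmetry_and_bounds(self, a, b):
        if not (a or b):
            return
        assert shared_gene_count(a, b) == shared_gene_count(b, a)
        j = jaccard_score(a, b)
        assert jaccard_score(b, a) == j
        assert 0 <= j <= 1
        if a and b:
            assert j <= min(len(a), len(b)) / max(len(a), len(b))
        if a:
            assert jaccard_score(a, a) == 1.0


class TestDiseaseGeneSets:
    def test_up_down_overlap_rejected(self):
        with pytest.raises(ValidationError):
            DiseaseGeneSets("D", frozenset({"a"}), frozenset({"a"}))

    def test_symbols_uppercased(self):
        s = DiseaseGeneSets("D", frozenset({"tnf"}), frozenset({"il6"}))
        assert s.up_genes == {"TNF"} and s.down_genes == {"IL6"}


class TestCombineFocal:
    def test_per_direction_union(self):
        a = DiseaseGeneSets("A", frozenset({"a"}), frozenset({"c"}))
        b = DiseaseGeneSets("B", frozenset({"b"}), frozenset())
        c = combine_focal_datasets([a, b], "F")
        assert c.up_genes == {"A", "B"} and c.down_genes == {"C"}
        assert c.conflicted == frozenset()

    def test_direction_conflicts_excluded_and_reported(self):
        a = DiseaseGeneSets("A", frozenset({"g"}), frozenset())
        b = DiseaseGeneSets("B", frozenset(), frozenset({"g"}))
        c = combine_focal_datasets([a, b], "F")
        assert "G" not in c.all_genes
        assert c.conflicted == {"G"}

    def test_single_input_identity(self):
        a = DiseaseGeneSets("A", frozenset({"x"}), frozenset({"y"}))
        c = combine_focal_datasets([a], "F")
        assert c.up_genes == a.up_genes and c.down_genes == a.down_genes


class TestBuildDiseasome:
    def focal(self):
        return DiseaseGeneSets("CVD", frozenset({"A", "B"}), frozenset({"D"}))

    def test_shared_gene_links_both_diseases(self):
        rf = DiseaseGeneSets("HTN", frozenset({"B", "C"}), frozenset())
        net = build_diseasome(self.focal(), [rf])
        assert ("CVD", "B", "up") in net.bipartite_edges
        assert ("HTN", "B", "up") in net.bipartite_edges
        assert net.pair_stats[("CVD", "HTN", "up")]["n_shared"] == 1

    def test_disjoint_risk_factor_has_no_pair_entry(self):
        rf = DiseaseGeneSets("HTN", frozenset({"Z"}), frozenset({"Q"}))
        net = build_diseasome(self.focal(), [rf])
        assert not any("HTN" in key[:2] for key in net.pair_stats)

    def test_gene_shared_by_three_diseases_has_degree_three(self):
        rf1 = DiseaseGeneSets("HTN", frozenset({"B"}), frozenset())
        rf2 = DiseaseGeneSets("T2D", frozenset({"B"}), frozenset())
        net = build_diseasome(self.focal(), [rf1, rf2])
        g = net.graph("up")
        assert g.degree("B") == 3

    def test_strictly_bipartite_and_handshake(self):
        rf1 = DiseaseGeneSets("HTN", frozenset({"A", "B"}), frozenset({"D"}))
        rf2 = DiseaseGeneSets("T2D", frozenset({"A"}), frozenset())
        net = build_diseasome(self.focal(), [rf1, rf2])
        g = net.graph()
        for u, v in g.edges:
            assert {g.nodes[u]["type"], g.nodes[v]["type"]} == {"disease", "gene"}
        gene_degree_sum = sum(d for n, d in g.degree if g.nodes[n]["type"] == "gene")
        assert gene_degree_sum == len(net.bipartite_edges)

    def test_pair_stats_symmetric_by_construction(self):
        rf = DiseaseGeneSets("HTN", frozenset({"A", "B", "C"}), frozenset({"D"}))
        net = build_diseasome(self.focal(), [rf])
        for (i, j, _), s in net.pair_stats.items():
            assert i < j  # canonical unordered key
            assert 0 <= s["jaccard"] <= 1 or math.isnan(s["jaccard"])

    def test_duplicate_disease_ids_rejected(self):
        rf = DiseaseGeneSets("CVD", frozenset({"A"}), frozenset())
        with pytest.raises(ValidationError):
            build_diseasome(self.focal(), [rf])


class TestMembershipPatterns:
    def net(self):
        focal = DiseaseGeneSets("CVD", frozenset({"A", "B"}), frozenset())
        rfs = [
            DiseaseGeneSets("HTN", frozenset({"A", "B"}), frozenset()),
            DiseaseGeneSets("OBS", frozenset({"A"}), frozenset()),
            DiseaseGeneSets("AGE", frozenset({"A"}), frozenset()),
        ]
        return build_diseasome(focal, rfs)

    def test_multi_disease_gene_reported_with_disease_list(self):
        rows = membership_patterns(self.net(), min_diseases=3)
        assert rows[0][0] == "A"
        assert rows[0][2] == ["AGE", "CVD", "HTN", "OBS"]

    def test_threshold_above_max_degree_gives_empty(self):
        assert membership_patterns(self.net(), min_diseases=5) == []

    def test_ties_ordered_lexicographically(self):
        focal = DiseaseGeneSets("CVD", frozenset({"B", "A"}), frozenset())
        rf = DiseaseGeneSets("HTN", frozenset({"B", "A"}), frozenset())
        rows = membership_patterns(build_diseasome(focal, [rf]), min_diseases=2)
        assert [r[0] for r in rows] == ["A", "B"]
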