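"""Synthetic-data generators: determinism, planted structure, recoverability."""

import numpy as np
import pytest

from diseasome.deg import DEGConfig, call_degs, deg_sets
from diseasome.errors import ValidationError
from diseasome.network import jaccard_score
from diseasome.ppi import top_hubs
from diseasome.simulate import (
    PLANTED_TERM,
    SimulationDesign,
    gene_universe,
    planted_overlap_design,
    simulate_expression,
    simulate_gmt,
    simulate_ppi,
)


class TestSimulateExpression:
    def null_design(self, seed=0):
        return SimulationDesign(
            n_genes=50,
            diseases=[("A", 4, 4), ("B", 4, 4)],
            planted_membership={},
            seed=seed,
        )

    def test_null_design_has_empty_truth(self):
        _, truth = simulate_expression(self.null_design())
        assert all(not s.all_genes for s in truth.true_sets.values())

    def test_same_seed_is_bit_identical(self):
        d1, _ = simulate_expression(self.null_design(seed=9))
        d2, _ = simulate_expression(self.null_design(seed=9))
        for a, b in zip(d1, d2):
            assert (a.values.to_numpy() == b.values.to_numpy()).all()

    def test_adding_a_disease_leaves_earlier_cohorts_unchanged(self):
        base = self.null_design(seed=4)
        extended = SimulationDesign(
            n_genes=50,
            diseases=[("A", 4, 4), ("B", 4, 4), ("C", 4, 4)],
            planted_membership={},
            seed=4,
        )
        d1, _ = simulate_expression(base)
        d2, _ = simulate_expression(extended)
        assert (d1[0].values.to_numpy() == d2[0].values.to_numpy()).all()
        assert (d1[1].values.to_numpy() == d2[1].values.to_numpy()).all()

    def test_planted_shift_lands_within_sampling_error(self):
        genes = gene_universe(100)
        design = SimulationDesign(
            n_genes=100,
            diseases=[("A", 15, 15)],
            planted_membership={genes[0]: {"A": "up"}, genes[1]: {"A": "down"}},
            effect_size=2.0,
            noise_sd=0.5,
            seed=2,
        )
        (ds,), _ = simulate_expression(design)
        se = 0.5 * np.sqrt(2 / 15)
        up_delta = ds.values.iloc[0, :15].mean() - ds.values.iloc[0, 15:].mean()
        down_delta = ds.values.iloc[1, :15].mean() - ds.values.iloc[1, 15:].mean()
        assert abs(up_delta - 2.0) < 2 * se
        assert abs(down_delta + 2.0) < 2 * se

    def test_out_of_universe_gene_rejected(self):
        with pytest.raises(ValidationError):
            SimulationDesign(
                n_genes=10,
                diseases=[("A", 4, 4)],
                planted_membership={"NOT_A_GENE": {"A": "up"}},
            )

    def test_truth_jaccard_consistent_with_pipeline_scorer(self):
        design = planted_overlap_design(
            n_genes=400, disease_ids=("A", "B", "C"), n_case=4, n_control=4,
            n_core_up=5, n_core_down=5, n_private_up=8, n_private_down=8, seed=3,
        )
        _, truth = simulate_expression(design)
        for (di, dj, direction), s in truth.pair_stats.items():
            gi = truth.true_sets[di].genes(direction)
            gj = truth.true_sets[dj].genes(direction)
            assert s["jaccard"] == jaccard_score(gi, gj)
            assert s["n_shared"] == len(gi & gj)

    def test_planted_core_drives_pairwise_overlap(self):
        design = planted_overlap_design(
            n_genes=400, disease_ids=("A", "B"), n_case=4, n_control=4,
            n_core_up=5, n_core_down=7, n_private_up=8, n_private_down=8, seed=3,
        )
        _, truth = simulate_expression(design)
        assert truth.pair_stats[("A", "B", "up")]["n_shared"] == 5
        assert truth.pair_stats[("A", "B", "down")]["n_shared"] == 7
        assert truth.pair_stats[("A", "B", "combined")]["n_shared"] == 12

    def test_single_seed_recovery_of_planted_calls(self):
        design = planted_overlap_design(
            n_genes=600, disease_ids=("A", "B"), n_case=10, n_control=10, seed=6
        )
        datasets, truth = simulate_expression(design)
        for ds in datasets:
            recovered = deg_sets(call_degs(ds, DEGConfig(p_criterion="adjusted")))
            true = truth.true_sets[ds.disease_id]
            sens = len(recovered.all_genes & true.all_genes) / len(true.all_genes)
            assert sens >= 0.9


class TestSimulatePpi:
    def test_single_hub_spanning_star(self):
        net, truth = simulate_ppi(n_nodes=8, n_edges=7, planted_hubs=[("HUB", 7)], seed=1)
        assert net.degree("HUB") == 7
        assert net.n_edges == 7
        assert truth.hubs == ["HUB"]

    def test_planted_hubs_dominate_ranking(self):
        hubs = [("H1", 20), ("H2", 20), ("H3", 22)]
        net, truth = simulate_ppi(n_nodes=60, n_edges=120, planted_hubs=hubs, seed=5)
        report = top_hubs(net, k=3)
        assert sorted(report.proteins()) == truth.hubs
        non_hub_max = max(d for n, d in net.degree().items() if n not in set(truth.hubs))
        assert min(net.degree(h) for h in ("H1", "H2", "H3")) > non_hub_max

    def test_same_seed_same_edges(self):
        a, _ = simulate_ppi(30, 60, [("H", 10)], seed=8)
        b, _ = simulate_ppi(30, 60, [("H", 10)], seed=8)
        assert a.edges == b.edges

    def test_infeasible_degree_rejected(self):
        with pytest.raises(ValidationError):
            simulate_ppi(n_nodes=10, n_edges=5, planted_hubs=[("H", 12)], seed=0)
        with pytest.raises(ValidationError):
            simulate_ppi(n_nodes=10, n_edges=3, planted_hubs=[("H", 8)], seed=0)


class TestSimulateGmt:
    universe = gene_universe(500)

    def test_full_fraction_contains_query(self):
        query = self.universe[:20]
        lib, truth = simulate_gmt(10, (20, 40), self.universe, 1.0, query, seed=2)
        assert set(query) <= lib.terms[PLANTED_TERM][1]
        assert truth.enriched_terms[lib.library_id] == PLANTED_TERM

    def test_overlap_count_is_ceiling_of_fraction(self):
        query = self.universe[:20]
        lib, _ = simulate_gmt(10, (20, 40), self.universe, 0.8, query, seed=2)
        assert len(lib.terms[PLANTED_TERM][1] & set(query)) == 16

    def test_same_seed_same_library(self):
        q = self.universe[:10]
        a, _ = simulate_gmt(15, (5, 20), self.universe, 0.5, q, seed=3)
        b, _ = simulate_gmt(15, (5, 20), self.universe, 0.5, q, seed=3)
        assert {t: g for t, (_, g) in a.terms.items()} == {t: g for t, (_, g) in b.terms.items()}

    def test_oversized_terms_rejected(self):
        with pytest.raises(ValidationError):
            simulate_gmt(5, (10, 1000), self.universe, 0.5, self.universe[:5], seed=0)
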