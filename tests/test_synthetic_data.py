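import numpy as np
import pytest

from gwsig import (
    ConfigurationError,
    SimulationConfig,
    compute_de_table,
    generate_gene_set_collection,
    generate_interaction_network,
    generate_multistudy_expression,
    gwgs_scores,
    gwrs_matrix,
    intersect_genes,
    rank_by_fold_change,
    select_top_k,
)
from gwsig.enrichment import ContingencyCounts, hypergeometric_tail


def _config(**overrides):
    defaults = dict(
        n_datasets=2,
        genes_per_dataset=[60, 50],
        shared_gene_fraction=0.8,
        n_cases=3,
        n_controls=3,
        n_de=5,
        effect_size=2.0,
        effect_sd=0.0,
        noise_sd=0.5,
        seed=3,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


class TestConfigValidation:
    def test_n_de_exceeding_shared_universe_names_both_counts(self):
        with pytest.raises(ConfigurationError, match="45"):
            _config(n_de=45, shared_gene_fraction=0.8)  # shared = 40

    def test_bad_fraction(self):
        with pytest.raises(ConfigurationError):
            _config(shared_gene_fraction=0.0)
        with pytest.raises(ConfigurationError):
            _config(shared_gene_fraction=1.2)

    def test_negative_noise(self):
        with pytest.raises(ConfigurationError):
            _config(noise_sd=-1.0)

    def test_genes_per_dataset_length_mismatch(self):
        with pytest.raises(ConfigurationError):
            _config(genes_per_dataset=[60, 50, 40])


class TestExpressionGeneration:
    def test_no_planted_signal(self):
        datasets, truth = generate_multistudy_expression(
            _config(n_de=0, noise_sd=0.0)
        )
        assert truth.de_genes == frozenset()
        assert truth.effects == {}
        for ds in datasets:
            case = ds.values[:, ds.case_mask].mean(axis=1)
            control = ds.values[:, ds.control_mask].mean(axis=1)
            np.testing.assert_array_equal(case, control)

    def test_noiseless_effect_is_exact(self):
        datasets, truth = generate_multistudy_expression(
            _config(n_de=1, noise_sd=0.0, effect_size=2.0, effect_sd=0.0)
        )
        (gene,) = truth.de_genes
        assert abs(truth.effects[gene]) == pytest.approx(2.0)
        for ds in datasets:
            i = ds.genes.index(gene)
            diff = (
                ds.values[i, ds.case_mask].mean()
                - ds.values[i, ds.control_mask].mean()
            )
            assert diff == pytest.approx(truth.effects[gene], abs=1e-12)

    def test_dataset_sizes_and_shared_core(self):
        config = _config()
        datasets, _ = generate_multistudy_expression(config)
        assert [len(ds.genes) for ds in datasets] == config.genes_per_dataset
        common = intersect_genes([ds.genes for ds in datasets])
        assert len(common) == config.n_shared

    def test_determinism_bit_identical(self):
        a, truth_a = generate_multistudy_expression(_config())
        b, truth_b = generate_multistudy_expression(_config())
        assert truth_a.de_genes == truth_b.de_genes
        assert truth_a.effects == truth_b.effects
        for x, y in zip(a, b):
            assert x.genes == y.genes
            assert x.samples == y.samples
            assert x.group == y.group
            assert np.array_equal(x.values, y.values)

    def test_different_seeds_differ(self):
        a, _ = generate_multistudy_expression(_config(seed=1))
        b, _ = generate_multistudy_expression(_config(seed=2))
        assert not np.array_equal(a[0].values, b[0].values)

    def test_de_genes_within_shared_universe(self):
        config = _config(n_de=10)
        datasets, truth = generate_multistudy_expression(config)
        common = set(intersect_genes([ds.genes for ds in datasets]))
        assert truth.de_genes <= common

    def test_private_genes_are_disjoint_across_datasets(self):
        datasets, _ = generate_multistudy_expression(_config())
        shared = set(datasets[0].genes) & set(datasets[1].genes)
        private0 = set(datasets[0].genes) - shared
        private1 = set(datasets[1].genes) - shared
        assert private0.isdisjoint(private1)


class TestGeneSetGeneration:
    @pytest.fixture
    def truth(self):
        _, truth = generate_multistudy_expression(_config(n_de=10))
        return truth

    @pytest.fixture
    def universe(self):
        datasets, _ = generate_multistudy_expression(_config(n_de=10))
        return intersect_genes([ds.genes for ds in datasets])

    def test_size_bookkeeping(self, truth, universe):
        coll = generate_gene_set_collection(
            truth, universe, n_sets=1, set_size=10, signal_fraction=0.5, seed=1
        )
        assert len(coll) == 1
        (only,) = list(coll)
        assert len(only.genes) == 10
        assert len(set(only.genes)) == 10

    def test_zero_signal_fraction_has_no_de_genes(self, truth, universe):
        coll = generate_gene_set_collection(
            truth, universe, n_sets=5, set_size=8, signal_fraction=0.0, seed=1
        )
        planted = coll[truth.planted_set_id]
        assert not set(planted.genes) & truth.de_genes

    def test_signal_exceeding_de_pool_is_an_error(self, truth, universe):
        with pytest.raises(ConfigurationError):
            generate_gene_set_collection(
                truth, universe, n_sets=3, set_size=30,
                signal_fraction=1.0, seed=1,
            )

    def test_planted_set_signal_content(self, truth, universe):
        coll = generate_gene_set_collection(
            truth, universe, n_sets=10, set_size=10, signal_fraction=0.8, seed=2
        )
        planted = coll[truth.planted_set_id]
        assert len(set(planted.genes) & truth.de_genes) == 8

    def test_planted_set_has_smallest_hypergeometric_p(self, truth, universe):
        # brute-force comparison across every set, using the true signature
        coll = generate_gene_set_collection(
            truth, universe, n_sets=10, set_size=10, signal_fraction=0.8, seed=2
        )
        sig = truth.de_genes
        n, N = len(sig), len(universe)
        p = {
            s.set_id: hypergeometric_tail(
                ContingencyCounts(
                    N=N, n=n, K=len(s.genes), k=len(set(s.genes) & sig)
                )
            )
            for s in coll
        }
        assert min(p, key=p.get) == truth.planted_set_id

    def test_determinism(self, truth, universe):
        a = generate_gene_set_collection(truth, universe, 5, 8, 0.5, seed=9)
        b = generate_gene_set_collection(truth, universe, 5, 8, 0.5, seed=9)
        assert [(s.set_id, s.genes) for s in a] == [(s.set_id, s.genes) for s in b]


class TestNetworkGeneration:
    def test_star_construction(self):
        sig = [f"S{i}" for i in range(20)]
        edges, hubs = generate_interaction_network(
            sig, [], n_hubs=1, hub_degree=15, background_edge_prob=0.0, seed=4
        )
        assert len(edges) == 15
        (hub,) = hubs
        assert all(hub in (e.gene_a, e.gene_b) for e in edges)

    def test_simple_graph_invariant(self):
        sig = [f"S{i}" for i in range(30)]
        bg = [f"B{i}" for i in range(40)]
        edges, _ = generate_interaction_network(
            sig, bg, n_hubs=3, hub_degree=10, background_edge_prob=0.05, seed=5
        )
        pairs = [(e.gene_a, e.gene_b) for e in edges]
        assert all(a != b for a, b in pairs)
        assert len(set(frozenset(p) for p in pairs)) == len(pairs)

    def test_scores_in_range(self):
        sig = [f"S{i}" for i in range(20)]
        edges, _ = generate_interaction_network(
            sig, [], n_hubs=2, hub_degree=10, background_edge_prob=0.1, seed=6
        )
        assert all(0.4 < e.score <= 1.0 for e in edges)

    def test_impossible_degree_is_an_error(self):
        with pytest.raises(ConfigurationError):
            generate_interaction_network(
                ["A", "B", "C"], [], n_hubs=1, hub_degree=5,
                background_edge_prob=0.0, seed=1,
            )

    def test_too_many_hubs_is_an_error(self):
        with pytest.raises(ConfigurationError):
            generate_interaction_network(
                ["A", "B", "C"], [], n_hubs=4, hub_degree=1,
                background_edge_prob=0.0, seed=1,
            )

    def test_hubs_recorded_in_truth(self):
        _, truth = generate_multistudy_expression(_config(n_de=10))
        sig = sorted(truth.de_genes)
        _, hubs = generate_interaction_network(
            sig, [], n_hubs=2, hub_degree=5, background_edge_prob=0.0,
            seed=7, truth=truth,
        )
        assert truth.planted_hubs == tuple(hubs)
        assert set(hubs) <= truth.de_genes

    def test_planted_hub_degrees_meet_request(self):
        sig = [f"S{i}" for i in range(40)]
        edges, hubs = generate_interaction_network(
            sig, [], n_hubs=3, hub_degree=15, background_edge_prob=0.0, seed=8
        )
        degree: dict[str, int] = {}
        for e in edges:
            degree[e.gene_a] = degree.get(e.gene_a, 0) + 1
            degree[e.gene_b] = degree.get(e.gene_b, 0) + 1
        for hub in hubs:
            assert degree[hub] >= 15

    def test_determinism(self):
        sig = [f"S{i}" for i in range(25)]
        a, ha = generate_interaction_network(sig, [], 2, 10, 0.05, seed=3)
        b, hb = generate_interaction_network(sig, [], 2, 10, 0.05, seed=3)
        assert ha == hb
        assert a.edges == b.edges


def test_null_topk_membership_is_exchangeable():
    """With no planted signal every gene enters the top-K with rate K/m."""
    m, k, n_seeds = 120, 24, 200
    counts = {f"G{i:05d}": 0 for i in range(m)}
    for seed in range(1000, 1000 + n_seeds):
        config = SimulationConfig(
            n_datasets=2,
            genes_per_dataset=[m, m],
            shared_gene_fraction=1.0,
            n_cases=3,
            n_controls=3,
            n_de=0,
            noise_sd=1.0,
            seed=seed,
        )
        datasets, _ = generate_multistudy_expression(config)
        tables = [compute_de_table(ds) for ds in datasets]
        common = intersect_genes([ds.genes for ds in datasets])
        ranked = [rank_by_fold_change(t, restrict_to=common) for t in tables]
        table = gwgs_scores(gwrs_matrix(ranked, genes=common))
        for gene in select_top_k(table, k):
            counts[gene] += 1
    expected = k / m
    se = np.sqrt(expected * (1 - expected) / n_seeds)
    freqs = np.array([c / n_seeds for c in counts.values()])
    assert np.all(np.abs(freqs - expected) <= 3 * se + 1e-12)
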