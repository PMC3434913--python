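"""Synthetic-data generator: Yule tree, coalescent gene trees, sequences."""

import numpy as np
import pytest

import otudelim as od
from otudelim.synthgen import jc_expected_pdist
from otudelim.treepart import is_ultrametric, tree_to_newick


class TestSpeciesTree:
    def test_k_tips_and_reproducibility(self):
        t1 = od.simulate_species_tree(7, seed=5)
        t2 = od.simulate_species_tree(7, seed=5)
        assert sum(1 for _ in t1.leaf_node_iter()) == 7
        assert tree_to_newick(t1) == tree_to_newick(t2)
        assert tree_to_newick(t1) != tree_to_newick(od.simulate_species_tree(7, seed=6))

    def test_ultrametric(self):
        assert is_ultrametric(od.simulate_species_tree(9, seed=1), tol=1e-9)

    @pytest.mark.parametrize("K,lam", [(2, 1.0), (5, 2.0)])
    def test_mean_depth_matches_closed_form(self, K, lam):
        # depth = sum of Exp(k*lam) phases for k = 2..K
        expect = sum(1.0 / (k * lam) for k in range(2, K + 1))
        depths = []
        for seed in range(2000):
            tree = od.simulate_species_tree(K, lambda_sp=lam, seed=seed)
            depths.append(max(nd.age for nd in tree.preorder_node_iter()))
        assert np.mean(depths) == pytest.approx(expect, rel=0.05)

    def test_min_depth_conditioning(self):
        for seed in range(20):
            tree = od.simulate_species_tree(8, seed=seed, min_depth_frac=0.2)
            ages = [nd.age for nd in tree.preorder_node_iter() if not nd.is_leaf()]
            assert min(ages) >= 0.2 * max(ages)


class TestGeneTree:
    def test_tip_count_and_labels(self):
        sp = od.simulate_species_tree(4, seed=3)
        gt, labels = od.simulate_gene_tree(sp, 3, theta=0.05, seed=1)
        assert sum(1 for _ in gt.leaf_node_iter()) == 12
        assert sorted(set(labels.values())) == ["sp1", "sp2", "sp3", "sp4"]
        assert is_ultrametric(gt, tol=1e-6)

    def test_small_theta_tracks_species_tree(self):
        sp = od.simulate_species_tree(5, seed=2, min_depth_frac=0.2)
        gt, labels = od.simulate_gene_tree(sp, 2, theta=1e-6, seed=1)
        pdm = gt.phylogenetic_distance_matrix()
        spd = sp.phylogenetic_distance_matrix()
        for ta in gt.taxon_namespace:
            for tb in gt.taxon_namespace:
                if ta.label >= tb.label:
                    continue
                a, b = labels[ta.label], labels[tb.label]
                got = pdm.patristic_distance(ta, tb)
                if a == b:
                    assert got < 1e-4
                else:
                    want = spd.patristic_distance(
                        *(x for x in sp.taxon_namespace if x.label in (a, b)))
                    assert got == pytest.approx(want, rel=1e-3)

    def test_mean_pairwise_coalescent_time_is_theta(self):
        theta = 0.05
        sp = od.simulate_species_tree(2, seed=8, min_depth_frac=0.5)
        times = []
        for seed in range(400):
            gt, labels = od.simulate_gene_tree(sp, 4, theta=theta, seed=seed)
            pdm = gt.phylogenetic_distance_matrix()
            taxa = list(gt.taxon_namespace)
            for i, ta in enumerate(taxa):
                for tb in taxa[i + 1:]:
                    if labels[ta.label] == labels[tb.label]:
                        times.append(pdm.patristic_distance(ta, tb) / 2.0)
        assert np.mean(times) == pytest.approx(theta, rel=0.05)


class TestSequences:
    def test_zero_rate_gives_identical_sequences(self):
        sp = od.simulate_species_tree(3, seed=1)
        gt, _ = od.simulate_gene_tree(sp, 2, theta=0.05, seed=1)
        aln = od.simulate_sequences(gt, rate=0.0, seq_length=50, seed=1)
        assert len(set(aln.seqs)) == 1

    def test_reproducible(self):
        sp = od.simulate_species_tree(3, seed=1)
        gt, _ = od.simulate_gene_tree(sp, 2, theta=0.05, seed=1)
        a = od.simulate_sequences(gt, rate=0.1, seq_length=100, seed=7)
        b = od.simulate_sequences(gt, rate=0.1, seq_length=100, seed=7)
        assert a.seqs == b.seqs

    @pytest.mark.parametrize("model", ["JC69", "HKY85"])
    def test_two_tip_divergence_matches_jc_expectation(self, model):
        t = 0.1  # each branch; total path 0.2
        tree = od.parse_newick(f"(a:{t},b:{t});")
        ps = []
        L = 400
        for seed in range(150):
            aln = od.simulate_sequences(tree, model=model, seq_length=L, rate=1.0, seed=seed)
            ps.append(od.pdist_matrix(aln).d[0, 1])
        expect = jc_expected_pdist(2 * t)
        se = np.std(ps) / np.sqrt(len(ps))
        tol = 3 * se if model == "JC69" else 0.05  # HKY differs mildly from JC
        assert np.mean(ps) == pytest.approx(expect, abs=max(tol, 1e-3))


class TestMakeDataset:
    def test_duplicate_arithmetic(self):
        cfg = od.SynthConfig.set3_regime(seed=0, duplicate_fraction=0.2)
        aln, truth, _ = od.make_dataset(cfg)
        assert aln.n == 60  # 50 genealogically distinct + 10 duplicates
        assert od.dedup_haplotypes(aln).n_haplotypes <= 50

    def test_no_duplicates_when_fraction_zero(self):
        cfg = od.SynthConfig.set3_regime(seed=0)
        aln, truth, _ = od.make_dataset(cfg)
        assert aln.n == 50
        assert truth.species_partition().n_blocks == cfg.K

    def test_regime_enforced(self):
        for seed in (0, 1, 2):
            cfg = od.SynthConfig.set3_regime(seed=seed)
            _, truth, _ = od.make_dataset(cfg)
            assert truth.summaries["regime_ok"]
            assert truth.summaries["max_within"] <= 0.03
            assert truth.summaries["min_between"] >= 0.06

    def test_chronogram_supports_present(self):
        cfg = od.SynthConfig.set3_regime(seed=4, K=5, samples_per_species=3)
        _, truth, chrono = od.make_dataset(cfg)
        sups = [nd.support for nd in chrono.preorder_node_iter() if not nd.is_leaf()]
        assert all(s is not None for s in sups)
        tree2 = od.parse_newick(truth.gene_tree_newick)
        assert is_ultrametric(tree2, tol=1e-6)

    def test_bit_reproducible(self):
        cfg = od.SynthConfig.set3_regime(seed=9, K=4, samples_per_species=3)
        a1, t1, _ = od.make_dataset(cfg)
        a2, t2, _ = od.make_dataset(cfg)
        assert a1.seqs == a2.seqs and t1.gene_tree_newick == t2.gene_tree_newick


class TestNuclear:
    def test_phased_pairs_and_sharing(self):
        cfg = od.SynthConfig(K=3, samples_per_species=3, seed=5, min_depth_frac=0.2)
        aln, truth = od.make_nuclear_dataset(cfg, shared_pairs=(("sp1", "sp2"),))
        assert aln.n == 18  # 2 phases x 3 samples x 3 species
        haps = od.dedup_haplotypes(aln)
        g1 = [s for s, g in truth.labels.items() if g == "sp1"]
        g2 = [s for s, g in truth.labels.items() if g == "sp2"]
        assert od.min_steps_between(haps, g1, g2) == 0  # forced sharing
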