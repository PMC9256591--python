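import numpy as np
import pytest

from barcodekit.congruence import classify_species
from barcodekit.distances import k2p_distance
from barcodekit.errors import ParameterError
from barcodekit.simulate import (
    SimulationConfig,
    _geometric_counts,
    evolve_sequences,
    gapped_preset,
    simulate_coalescent_tree,
    simulate_dataset,
    simulate_gene_tree,
    simulate_species_tree,
)
from barcodekit.trees import is_ultrametric


class TestSpeciesTree:
    def test_structure_and_clock(self):
        tree = simulate_species_tree(12, seed=0)
        assert tree.n_tips == 12
        ok, _ = is_ultrametric(tree, rel_tol=1e-9)
        assert ok

    def test_seed_reproducibility_byte_identical(self):
        a = simulate_species_tree(8, seed=42).to_newick()
        b = simulate_species_tree(8, seed=42).to_newick()
        assert a == b
        c = simulate_species_tree(8, seed=43).to_newick()
        assert a != c

    def test_height_rescale_with_floor(self):
        tree = simulate_species_tree(10, seed=1, height=0.3, min_divergence=0.12)
        heights = [h for n, h in tree.node_heights().items() if not n.is_leaf()]
        assert max(heights) == pytest.approx(0.3)
        assert min(heights) >= 0.12 - 1e-12

    def test_too_few_species_rejected(self):
        with pytest.raises(ParameterError):
            simulate_species_tree(1, seed=0)


class TestGeneTree:
    def test_one_sample_per_species_mirrors_species_tree(self):
        st = simulate_species_tree(6, seed=2, height=0.2, min_divergence=0.05)
        gt = simulate_gene_tree(st, 1, theta=0.01, seed=3)
        assert sorted(gt.tip_labels) == sorted(f"{sp}_1" for sp in st.tip_labels)
        ok, _ = is_ultrametric(gt, rel_tol=1e-9)
        assert ok
        # species divergences carried over unchanged
        from barcodekit.trees import patristic_matrix

        pm_s = patristic_matrix(st)
        pm_g = patristic_matrix(gt)
        for a in st.tip_labels:
            for b in st.tip_labels:
                if a < b:
                    assert pm_g.get(f"{a}_1", f"{b}_1") == pytest.approx(
                        pm_s.get(a, b), rel=1e-9
                    )

    def test_theta_limit_shallow_within(self):
        st = simulate_species_tree(4, seed=4, height=0.2, min_divergence=0.1)
        gt = simulate_gene_tree(st, 4, theta=1e-8, seed=5)
        from barcodekit.trees import patristic_matrix

        pm = patristic_matrix(gt)
        for sp in st.tip_labels:
            tips = [t for t in gt.tip_labels if t.startswith(sp + "_")]
            for a in tips:
                for b in tips:
                    if a < b:
                        assert pm.get(a, b) < 1e-6

    def test_expected_pairwise_coalescent_depth(self):
        # mean pairwise tree distance between 2 samples of one species ~ theta
        st = simulate_species_tree(2, seed=6, height=5.0, min_divergence=2.0)
        theta = 0.02
        rng_seed = 123
        from barcodekit.trees import patristic_matrix

        dists = []
        for rep in range(200):
            gt = simulate_gene_tree(st, {"sp01": 2, "sp02": 1}, theta, seed=rng_seed + rep)
            pm = patristic_matrix(gt)
            dists.append(pm.get("sp01_1", "sp01_2"))
        mean = np.mean(dists)
        se = np.std(dists) / np.sqrt(len(dists))
        assert abs(mean - theta) < 4 * se + 1e-4


class TestEvolve:
    def test_zero_branch_identical_child(self):
        from barcodekit.trees import PhyloTree

        tree = PhyloTree.from_newick("(a:0.0,b:0.0);", rooted=True)
        aln = evolve_sequences(tree, length=200, seed=0)
        assert aln.sequence("a") == aln.sequence("b")

    def test_k2p_estimator_consistency(self):
        from barcodekit.trees import PhyloTree

        b = 0.15
        tree = PhyloTree.from_newick(f"(a:{b/2},b:{b/2});", rooted=True)
        ds = [
            k2p_distance(*(lambda a: (a.sequence("a"), a.sequence("b")))(
                evolve_sequences(tree, length=641, kappa=4.0, seed=rep)
            ))
            for rep in range(100)
        ]
        mean, se = np.mean(ds), np.std(ds) / 10
        assert abs(mean - b) < 4 * se

    def test_large_kappa_suppresses_transversions(self):
        from barcodekit.distances import encode
        from barcodekit.trees import PhyloTree

        tree = PhyloTree.from_newick("(a:0.1,b:0.1);", rooted=True)
        aln = evolve_sequences(tree, length=5000, kappa=1e6, seed=1)
        a, b = encode(aln.sequence("a")), encode(aln.sequence("b"))
        diff = a != b
        tv = int((diff & ((a & 1) != (b & 1))).sum())
        assert tv == 0


class TestDatasetAndScenarios:
    def test_geometric_counts_match_requested_shape(self):
        cfg = SimulationConfig(n_species=3000)
        counts = _geometric_counts(cfg, np.random.default_rng(0))
        values = np.array(list(counts.values()))
        assert values.min() >= 1 and values.max() <= 24
        # sampling error: sd ~ 4.7, so 3 s.e. over 3000 draws ~ 0.26
        assert abs(values.mean() - 5.0) < 0.3

    def test_full_determinism(self):
        cfg = gapped_preset(6, 3, seed=9, n_mislabels=1)
        d1, d2 = simulate_dataset(cfg), simulate_dataset(cfg)
        assert d1.alignment.seqs == d2.alignment.seqs
        assert d1.metadata.equals(d2.metadata)
        assert d1.gene_tree.to_newick() == d2.gene_tree.to_newick()

    def test_no_scenarios_all_ok(self):
        ds = simulate_dataset(gapped_preset(8, 3, seed=10))
        codes = classify_species(ds.morphospecies(), ds.true_partition)
        assert set(codes.values()) == {"OK"}
        assert ds.expected_codes == codes

    def test_cryptic_split_scenario(self):
        ds = simulate_dataset(gapped_preset(8, 3, seed=11, n_cryptic=1))
        codes = classify_species(ds.morphospecies(), ds.true_partition)
        assert sorted(codes.values()).count("S") == 1
        assert codes == ds.expected_codes
        assert len(set(ds.metadata["morphospecies"])) == 7  # two species, one name

    def test_synonym_lump_scenario(self):
        ds = simulate_dataset(gapped_preset(8, 3, seed=12, n_synonym=1))
        codes = classify_species(ds.morphospecies(), ds.true_partition)
        assert sorted(codes.values()).count("L") == 2
        assert codes == ds.expected_codes

    def test_mislabels_recorded_and_distant(self):
        ds = simulate_dataset(gapped_preset(12, 4, seed=13, n_mislabels=2))
        assert len(ds.true_mislabels) == 2
        meta = ds.metadata.set_index("specimen_id")
        for row in ds.true_mislabels.itertuples():
            assert meta.loc[row.specimen_id, "morphospecies"] == row.planted_label
            assert meta.loc[row.specimen_id, "true_species"] == row.true_species
            assert row.planted_label != row.true_species

    def test_infeasible_scenarios_rejected(self):
        with pytest.raises(ParameterError):
            simulate_dataset(gapped_preset(4, 2, seed=1, n_cryptic=3))

    def test_gap_structure_guarantee(self, gapped_dataset, gapped_k2p):
        from barcodekit.gap import split_intra_inter

        intra, inter = split_intra_inter(gapped_k2p, gapped_dataset.morphospecies())
        assert intra.max() < inter.min()

    def test_write_outputs(self, tmp_path):
        ds = simulate_dataset(gapped_preset(5, 2, seed=3))
        ds.write(tmp_path)
        for name in (
            "sim.fasta", "sim_metadata.tsv", "true_partition.tsv",
            "true_mislabels.tsv", "species_tree.nwk", "gene_tree.nwk", "config.json",
        ):
            assert (tmp_path / name).exists(), name


def test_coalescent_tree_is_clock_like():
    tree = simulate_coalescent_tree(10, theta=0.02, seed=5)
    assert tree.n_tips == 10
    ok, _ = is_ultrametric(tree, rel_tol=1e-9)
    assert ok
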