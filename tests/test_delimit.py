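import numpy as np
import pytest

from barcodekit.delimit import (
    asap_partition,
    gmyc_partition,
    import_partition,
    kot_partition,
    pdt_partition,
    threshold_cluster,
)
from barcodekit.distances import DistanceMatrix, distance_matrix
from barcodekit.errors import (
    DegenerateInputError,
    ParameterError,
    PartitionError,
    TreeError,
)
from barcodekit.io import MotuPartition, write_partition
from barcodekit.simulate import (
    evolve_sequences,
    simulate_gene_tree,
    simulate_species_tree,
)
from barcodekit.trees import PhyloTree
from conftest import make_alignment


def block_matrix(groups: list[int], within: float, between: float) -> DistanceMatrix:
    """Block-structured distances: *within* inside groups, *between* across."""
    ids, labels = [], []
    for g, size in enumerate(groups):
        for k in range(size):
            ids.append(f"g{g}_{k}")
            labels.append(g)
    n = len(ids)
    values = np.full((n, n), between)
    for i in range(n):
        for j in range(n):
            if labels[i] == labels[j]:
                values[i, j] = within
    np.fill_diagonal(values, 0.0)
    return DistanceMatrix(ids, values)


class TestThresholdCluster:
    def test_zero_threshold_all_singletons(self):
        dm = block_matrix([3, 2], 0.01, 0.2)
        assert threshold_cluster(dm, 0.0).n_motus == 5

    def test_threshold_above_max_one_motu(self):
        dm = block_matrix([3, 2], 0.01, 0.2)
        assert threshold_cluster(dm, 0.5).n_motus == 1

    def test_two_groups_at_intermediate_threshold(self):
        dm = block_matrix([3, 2], 0.01, 0.2)
        part = threshold_cluster(dm, 0.07)
        assert part.n_motus == 2
        groups = {frozenset(v) for v in part.motus().values()}
        assert groups == {
            frozenset({"g0_0", "g0_1", "g0_2"}),
            frozenset({"g1_0", "g1_1"}),
        }

    @pytest.mark.parametrize("seed", [0, 1])
    def test_monotone_in_threshold(self, seed):
        rng = np.random.default_rng(seed)
        n = 12
        v = rng.random((n, n)) * 0.3
        v = (v + v.T) / 2
        np.fill_diagonal(v, 0)
        dm = DistanceMatrix([f"s{i}" for i in range(n)], v)
        prev = None
        for t in np.linspace(0, 0.35, 12):
            part = threshold_cluster(dm, t)
            if prev is not None:
                assert part.n_motus <= prev.n_motus
                # refinement: every previous motu is contained in a current one
                cur = {sp: m for sp, m in part.assignments.items()}
                for members in prev.motus().values():
                    assert len({cur[sp] for sp in members}) == 1
            prev = part


class TestAsap:
    def test_two_clear_clusters(self):
        # intra <= 0.02, inter >= 0.20, 10 specimens each
        rng = np.random.default_rng(0)
        st_ = simulate_species_tree(2, seed=1, height=0.12, min_divergence=0.1)
        gt = simulate_gene_tree(st_, 10, theta=0.015, seed=2)
        aln = evolve_sequences(gt, 641, seed=3)
        dm = distance_matrix(aln, "k2p")
        res = asap_partition(dm)
        assert res.best_partition.n_motus == 2
        intra_max = max(
            dm.get(a, b)
            for a in dm.ids
            for b in dm.ids
            if a < b and a.split("_")[0] == b.split("_")[0]
        )
        inter_min = min(
            dm.get(a, b)
            for a in dm.ids
            for b in dm.ids
            if a < b and a.split("_")[0] != b.split("_")[0]
        )
        assert intra_max < res.best_threshold < inter_min

    def test_single_outlier_splits_off(self):
        seqs = {f"x{i}": "A" * 60 for i in range(9)}
        seqs["y"] = "G" * 25 + "A" * 35
        dm = distance_matrix(make_alignment(seqs), "k2p")
        res = asap_partition(dm)
        assert res.best_partition.n_motus == 2

    def test_candidates_form_nested_chain(self, gapped_k2p):
        res = asap_partition(gapped_k2p)
        parts = res.partitions
        assert res.table["n_motus"].is_monotonic_decreasing
        for finer, coarser in zip(parts, parts[1:]):
            coarse_of = coarser.assignments
            for members in finer.motus().values():
                assert len({coarse_of[sp] for sp in members}) == 1

    def test_equal_distances_degenerate(self):
        dm = block_matrix([1, 1, 1], 0.1, 0.1)
        with pytest.raises(DegenerateInputError):
            asap_partition(dm)


def guide_for(dm: DistanceMatrix) -> PhyloTree:
    from barcodekit.trees import neighbor_joining

    return neighbor_joining(dm)


class TestKot:
    def test_two_clean_clades_split(self):
        dm = block_matrix([4, 4], 0.01, 0.20)
        res = kot_partition(dm, guide_for(dm), R=4)
        assert res.partition.n_motus == 2
        top = res.records[res.records.clade_size == 8].iloc[0]
        assert top["K"] == pytest.approx(0.20)
        assert top["ratio"] == pytest.approx(20.0)

    def test_uniform_diversity_one_motu(self):
        # between equal to within: ratio 1 < 4 everywhere
        rng = np.random.default_rng(8)
        n = 8
        v = 0.1 + 0.001 * rng.random((n, n))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 0)
        dm = DistanceMatrix([f"s{i}" for i in range(n)], v)
        res = kot_partition(dm, guide_for(dm), R=4)
        assert res.partition.n_motus == 1

    def test_ratio_between_thresholds(self):
        # K = 0.045 against theta = 0.01: splits at R=4, not at R=5
        dm = block_matrix([3, 3], 0.01, 0.045)
        r4 = kot_partition(dm, guide_for(dm), R=4)
        r5 = kot_partition(dm, guide_for(dm), R=5)
        assert r4.partition.n_motus == 2
        assert r5.partition.n_motus == 1

    def test_r5_never_more_motus_than_r4(self, gapped_k2p):
        guide = guide_for(gapped_k2p)
        n4 = kot_partition(gapped_k2p, guide, R=4).partition.n_motus
        n5 = kot_partition(gapped_k2p, guide, R=5).partition.n_motus
        assert n5 <= n4

    def test_tip_mismatch_rejected(self):
        dm = block_matrix([2, 2], 0.01, 0.2)
        other = PhyloTree.from_newick("((a:1,b:1):1,(c:1,d:1):1);")
        with pytest.raises(PartitionError):
            kot_partition(dm, other, R=4)


class TestPdt:
    def test_star_tree_below_threshold_one_motu(self):
        star = PhyloTree.from_newick("(A:0.05,B:0.05,C:0.05);")
        from barcodekit.trees import patristic_matrix

        part = pdt_partition(patristic_matrix(star), t=0.16)
        assert part.n_motus == 1

    def test_two_far_tips_split(self):
        pair = PhyloTree.from_newick("(A:0.1,B:0.1);")
        from barcodekit.trees import patristic_matrix

        part = pdt_partition(patristic_matrix(pair), t=0.16)
        assert part.n_motus == 2

    def test_two_clades_separated_by_long_stem(self):
        t = PhyloTree.from_newick(
            "(((A:0.02,B:0.02):0.01,C:0.03):0.15,((D:0.02,E:0.02):0.01,F:0.03):0.15);"
        )
        from barcodekit.trees import patristic_matrix

        part = pdt_partition(patristic_matrix(t), t=0.16)
        assert part.n_motus == 2
        assert part.same_clustering(
            MotuPartition({"A": "1", "B": "1", "C": "1", "D": "2", "E": "2", "F": "2"})
        )


class TestGmyc:
    def test_three_tip_entity_bound(self):
        tree = PhyloTree.from_newick("((A:0.1,B:0.1):0.9,C:1.0);")
        fit = gmyc_partition(tree)
        assert 1 <= fit.n_entities <= 3

    def test_structured_tree_recovers_clusters(self):
        st_ = simulate_species_tree(10, seed=5, height=1.0, min_divergence=0.3)
        gt = simulate_gene_tree(st_, 5, theta=0.01, seed=6)
        fit = gmyc_partition(gt)
        assert fit.n_clusters == 10
        assert fit.lr_statistic >= 0
        assert fit.lr_pvalue < 0.05
        part = fit.partition(alpha=0.05)
        assert part.n_motus == 10

    def test_singleton_species_counted_as_entities(self):
        # 4 two-tip species + 2 singleton species, deep splits: the threshold
        # sits above the shallow coalescents and every species is an entity
        st_ = simulate_species_tree(6, seed=1, height=1.0, min_divergence=0.3)
        samples = dict(zip(sorted(st_.tip_labels), [2, 2, 2, 2, 1, 1]))
        gt = simulate_gene_tree(st_, samples, theta=0.01, seed=101)
        fit = gmyc_partition(gt)
        assert fit.n_entities == 6
        assert fit.n_clusters == 4
        assert fit.partition(alpha=0.05).n_motus == 6

    def test_non_ultrametric_rejected(self):
        tree = PhyloTree.from_newick("((A:1,B:2):1,C:2);")
        with pytest.raises(TreeError):
            gmyc_partition(tree)

    def test_deterministic_rerun(self):
        st_ = simulate_species_tree(5, seed=7, height=1.0, min_divergence=0.3)
        gt = simulate_gene_tree(st_, 4, theta=0.01, seed=8)
        f1, f2 = gmyc_partition(gt), gmyc_partition(gt)
        assert f1.best_threshold == f2.best_threshold
        assert f1.partition(None).assignments == f2.partition(None).assignments


class TestImport:
    def test_tagged_with_method(self, tmp_path):
        part = MotuPartition({f"s{i}": f"m{i % 2}" for i in range(5)})
        write_partition(part, tmp_path / "bin.tsv")
        back = import_partition(tmp_path / "bin.tsv", "BIN", specimens=list(part.assignments))
        assert back.method == "BIN"
        assert back.n_motus == 2

    def test_unknown_specimens_rejected(self, tmp_path):
        part = MotuPartition({"s0": "m", "ghost": "m"})
        write_partition(part, tmp_path / "p.tsv")
        with pytest.raises(PartitionError, match="ghost"):
            import_partition(tmp_path / "p.tsv", "PTP", specimens=["s0"])

    def test_import_then_congruence_end_to_end(self, tmp_path):
        from barcodekit.congruence import classify_species

        part = MotuPartition({"a1": "m1", "a2": "m1", "b1": "m2"})
        write_partition(part, tmp_path / "p.tsv")
        imported = import_partition(tmp_path / "p.tsv", "PTP", ["a1", "a2", "b1"])
        codes = classify_species({"a1": "A", "a2": "A", "b1": "B"}, imported)
        assert codes == {"A": "OK", "B": "OK"}
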