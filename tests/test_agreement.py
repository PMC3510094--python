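import numpy as np
import pytest

from upm import (
    ValidationError,
    build_mapped_forest,
    choose_supertree,
    mast_vs_supertree,
    read_newick_tree,
    reduce_and_map,
    rooted_mast,
)
from upm.agreement import MappedForest
from helpers import (
    bf_mast_rooted,
    bf_mast_unrooted,
    rand_gene_tree,
    rand_supertree,
    unrooted_topology_key,
)


class TestRootedMast:
    def test_identical_trees_keep_all_leaves(self):
        a = rand_supertree(9, 4)
        assert rooted_mast(a, a) == a.taxa

    def test_conflicting_quartets(self):
        # the two rooted balanced quartets share no 3-leaf rooted subtree
        a = read_newick_tree("((A:1,B:1):1,(C:1,D:1):1);", rooted=True)
        b = read_newick_tree("((A:1,C:1):1,(B:1,D:1):1);", rooted=True)
        got = rooted_mast(a, b)
        assert len(got) == bf_mast_rooted(a, b) == 2
        assert got == {"A", "B"}  # lexicographic tie-break

    @pytest.mark.parametrize("seed", range(40))
    def test_matches_brute_force_size(self, seed):
        a = rand_supertree(7, seed)
        b = rand_supertree(7, seed + 5000)
        got = rooted_mast(a, b)
        assert len(got) == bf_mast_rooted(a, b)
        # and the returned set must actually agree
        assert a.restrict(got)[0].clades() == b.restrict(got)[0].clades()


class TestMastVsSupertree:
    def test_concordant_gene_tree_keeps_all_leaves(self):
        st = rand_supertree(10, 2)
        gt = read_newick_tree(st.restrict(sorted(st.taxa)[:7])[0].newick(), rooted=False)
        res = mast_vs_supertree(gt, st)
        assert res.size == 7 and res.leaves == gt.taxa

    def test_unrooted_quartet_conflict_gives_three(self):
        st = read_newick_tree("((A:1,B:1):1,(C:1,D:1):1);", rooted=True)
        gt = read_newick_tree("((A:1,C:1):1,(B:1,D:1):1);", rooted=False)
        res = mast_vs_supertree(gt, st)
        assert res.size == 3
        assert res.leaves == {"A", "B", "C"}  # lexicographic tie-break

    def test_foreign_leaf_rejected(self):
        st = read_newick_tree("((A:1,B:1):1,(C:1,D:1):1);", rooted=True)
        gt = read_newick_tree("((A:1,B:1):1,(C:1,X:1):1);", rooted=False)
        with pytest.raises(ValidationError, match="X"):
            mast_vs_supertree(gt, st)

    @pytest.mark.parametrize("seed", range(30))
    def test_max_over_rootings_beats_any_fixed_rooting(self, seed):
        from upm.agreement import _Flat, _gene_rootings, _mast_size

        st = rand_supertree(8, seed)
        gt = rand_gene_tree(st, 6, seed)
        res = mast_vs_supertree(gt, st)
        A = _Flat.from_node(st.restrict(gt.taxa)[0].root)
        sizes = [_mast_size(A, B) for B in _gene_rootings(gt)]
        assert res.size == max(sizes)

    @pytest.mark.parametrize("seed", range(25))
    def test_result_induces_identical_topologies(self, seed):
        st = rand_supertree(9, seed + 100)
        gt = rand_gene_tree(st, 7, seed + 100)
        res = mast_vs_supertree(gt, st)
        if res.size >= 4:
            st_r = st.restrict(res.leaves)[0]
            assert unrooted_topology_key(st_r) == gt.restrict(res.leaves).topology_key()


class TestReduceAndMap:
    def test_concordant_full_gene_gives_singleton_paths(self):
        st = rand_supertree(8, 3)
        gt = read_newick_tree(st.newick(), rooted=False)
        res = mast_vs_supertree(gt, st)
        rows = reduce_and_map(gt, res, st)
        # every path a singleton except the one spanning the root (2 edges)
        sizes = sorted(len(r.st_path) for r in rows)
        assert sizes == [1] * (len(rows) - 1) + [2]

    @pytest.mark.parametrize("seed", range(20))
    def test_paths_partition_restricted_supertree(self, seed):
        st = rand_supertree(12, seed)
        gt = rand_gene_tree(st, 8, seed + 50)
        res = mast_vs_supertree(gt, st)
        if res.size < 4:
            pytest.skip("degenerate MAST")
        rows = reduce_and_map(gt, res, st)
        assert len(rows) == 2 * res.size - 3
        _, comp = st.restrict(res.leaves)
        restricted_edges = set().union(*comp.values())
        seen = [j for r in rows for j in r.st_path]
        assert len(seen) == len(set(seen))  # disjoint
        assert set(seen) == restricted_edges  # covering

    @pytest.mark.parametrize("seed", range(20))
    def test_length_conservation_under_reduction(self, seed):
        st = rand_supertree(12, seed + 500)
        gt = rand_gene_tree(st, 9, seed + 500)
        res = mast_vs_supertree(gt, st)
        if res.size < 4:
            pytest.skip("degenerate MAST")
        rows = reduce_and_map(gt, res, st)
        reduced_total = sum(r.length for r in rows)
        direct_total = sum(gt.restrict(res.leaves).bipartitions().values())
        assert np.isclose(reduced_total, direct_total, rtol=0, atol=1e-9)


class TestBuildMappedForest:
    def test_counts_for_concordant_forest(self):
        st = rand_supertree(12, 9)
        forest = []
        for i in range(5):
            gt = read_newick_tree(st.newick(), rooted=False)
            gt.id = i
            forest.append(gt)
        mf = build_mapped_forest(forest, st, min_mast=10)
        s = mf.summary()
        assert s["n_trees"] == 5
        assert s["n_leaves"] == 60
        assert s["n_edges"] == 5 * 21

    def test_raising_threshold_never_adds_trees(self, upm_case):
        st, T, forest, truth, _ = upm_case
        counts = []
        for tier in (4, 6, 8):
            try:
                mf = build_mapped_forest(forest, st, min_mast=tier)
                counts.append(mf.summary()["n_trees"])
            except ValidationError:
                counts.append(0)
        assert counts == sorted(counts, reverse=True)

    def test_edge_total_matches_mast_sizes(self, upm_case):
        st, T, forest, truth, mf = upm_case
        assert mf.n == sum(2 * m.size - 3 for m in mf.mast_results.values())

    def test_tsv_round_trip(self, tmp_path, upm_case):
        st, T, forest, truth, mf = upm_case
        p = tmp_path / "mf.tsv"
        mf.to_tsv(p)
        again = MappedForest.from_tsv(p, st.n_edges)
        assert again.n == mf.n
        assert again.rows[0].st_path == mf.rows[0].st_path

    def test_empty_surviving_forest_is_error(self, upm_case):
        st, T, forest, truth, _ = upm_case
        with pytest.raises(ValidationError):
            build_mapped_forest(forest, st, min_mast=13)  # larger than m


class TestChooseSupertree:
    def test_single_candidate(self, upm_case):
        st, T, forest, truth, _ = upm_case
        assert choose_supertree([st], forest[:10], min_mast=4) == 0

    def test_generating_topology_beats_shuffled(self):
        from upm import SimConfig, simulate_forest, simulate_supertree

        st, T = simulate_supertree(10, "UPM", 33)
        cfg = SimConfig(
            n_taxa=10, n_genes=15, model="UPM", leaf_keep_prob=0.8,
            noise_sigma=0.2, discordance_moves=0, seed=33,
        )
        forest, _ = simulate_forest((st, T), cfg)
        other = rand_supertree(10, 777)  # same taxa, shuffled topology
        assert choose_supertree([other, st], forest, min_mast=4) == 1
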