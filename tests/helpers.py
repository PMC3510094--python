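"""Shared test utilities: random trees and brute-force MAST oracles."""

from __future__ import annotations

from itertools import combinations

import numpy as np

from upm import GeneTree, SuperTree, read_newick_tree, simulate_supertree
from upm.agreement import _unrooted_key_of_rooted


def rand_supertree(m: int, seed: int, model: str = "UPM") -> SuperTree:
    st, _ = simulate_supertree(m, model, seed)
    return st


def rand_gene_tree(st: SuperTree, n_leaves: int, seed: int) -> GeneTree:
    """Random unrooted topology over a random subset of the supertree taxa."""
    rng = np.random.default_rng(seed)
    subset = rng.choice(sorted(st.taxa), size=n_leaves, replace=False)
    donor = rand_supertree(st.m, seed + 7919)  # independent topology
    sub = donor.restrict(subset)[0]
    return read_newick_tree(sub.newick(), rooted=False)


def unrooted_topology_key(tree):
    if isinstance(tree, SuperTree):
        return _unrooted_key_of_rooted(tree.root, tree.taxa)
    return tree.topology_key()


def bf_mast_unrooted(gt: GeneTree, st: SuperTree) -> int:
    """Exhaustive unrooted MAST size over all leaf subsets (small trees only)."""
    shared = sorted(gt.taxa & st.taxa)
    for size in range(len(shared), 2, -1):
        for sub in combinations(shared, size):
            st_r = st.restrict(sub)[0]
            if unrooted_topology_key(st_r) == gt.restrict(sub).topology_key():
                return size
    return min(len(shared), 3)  # any <=3 shared leaves agree trivially


def bf_mast_rooted(a: SuperTree, b: SuperTree) -> int:
    """Exhaustive rooted MAST size: compare induced clade sets."""
    shared = sorted(a.taxa & b.taxa)
    for size in range(len(shared), 2, -1):
        for sub in combinations(shared, size):
            if a.restrict(sub)[0].clades() == b.restrict(sub)[0].clades():
                return size
    return min(len(shared), 2)  # one or two leaves always agree
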