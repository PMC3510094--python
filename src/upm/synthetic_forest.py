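"""Synthetic gene-tree forests with known ground truth.

The generator emulates the statistical structure the pacemaker analysis
assumes: a rooted binary supertree whose edges carry either equal-depth
time intervals (MC), free lognormal "ticks" (UPM), or one tick vector per
pacemaker (MPM); genes that see random taxon subsets; gene rates drawn
lognormally; and per-edge multiplicative lognormal noise with median 1
(ln eps ~ N(0, sigma^2)).  Optional random subtree-prune-regraft (SPR)
moves emulate topological discordance (horizontal transfer) so the MAST
reduction has something to do.

All randomness flows from one integer seed through counter-keyed
generators (``default_rng([seed, stream, counter])``), so any gene can be
regenerated independently and runs are bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .forest_io import GeneTree, Node, SuperTree

__all__ = [
    "SimConfig",
    "GroundTruth",
    "simulate_supertree",
    "simulate_forest",
    "truth_report",
    "write_simulation",
]

MC = "MC"
UPM = "UPM"
MPM = "MPM"


@dataclass
class SimConfig:
    """Study conditions for one synthetic forest.

    Defaults mirror the archaeal/bacterial forest the method was built
    for: 100 genomes, 6901 gene families, per-gene taxon sampling thin
    enough that a typical reduced tree keeps ~20 leaves, relative rates
    spanning roughly an order of magnitude (lognormal, sigma 0.5) and
    branch-length scatter of ~0.9 ln units.
    """

    n_taxa: int = 100
    n_genes: int = 6901
    model: str = UPM
    k_pacemakers: int = 1
    rate_sigma: float = 0.5
    noise_sigma: float = 0.9
    leaf_keep_prob: float = 0.2
    discordance_moves: int = 1
    tick_sigma: float = 1.0  # ln-scale spread of supertree edge lengths
    seed: int = 0

    def __post_init__(self):
        if self.n_taxa < 4:
            raise ValueError("need at least 4 taxa")
        if not (0 < self.leaf_keep_prob <= 1):
            raise ValueError("leaf_keep_prob must be in (0, 1]")
        if self.model not in (MC, UPM, MPM):
            raise ValueError(f"unknown model {self.model!r}")
        if self.k_pacemakers < 1:
            raise ValueError("k_pacemakers must be >= 1")
        if min(self.rate_sigma, self.noise_sigma, self.tick_sigma) < 0:
            raise ValueError("sigmas must be >= 0")

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        import yaml

        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


@dataclass
class GroundTruth:
    supertree: SuperTree  # topology with pacemaker 0 lengths
    t_pacemakers: np.ndarray  # (k, n_edges) true tick vectors
    r: dict[int, float]  # true gene rates
    pacemaker_of: dict[int, int]
    ln_eps: dict[int, dict[frozenset, float]]  # gene -> edge bipartition -> ln eps
    config: SimConfig


def _label(i: int) -> str:
    return f"T{i:03d}"


def simulate_supertree(
    m: int,
    model: str = UPM,
    seed: int = 0,
    k_pacemakers: int = 1,
    tick_sigma: float = 1.0,
) -> tuple[SuperTree, np.ndarray]:
    """Random rooted binary supertree plus its true edge-length vectors.

    Topology comes from a Yule-like random-join process.  MC trees are
    built ultrametric (node heights strictly increase toward the root);
    UPM/MPM trees get independent lognormal ticks per edge, one vector per
    pacemaker, so they are generically non-ultrametric.

    Returns ``(st, T)`` with ``st`` carrying pacemaker 0's lengths and
    ``T`` of shape (k, 2m-2) holding every pacemaker's vector.
    """
    if m < 4:
        raise ValueError("need at least 4 taxa")
    rng = np.random.default_rng([seed, 0])
    clusters: list[Node] = [Node(_label(i)) for i in range(m)]
    heights = {id(c): 0.0 for c in clusters}
    h = 0.0
    while len(clusters) > 1:
        i, j = sorted(rng.choice(len(clusters), size=2, replace=False))
        h += float(rng.uniform(0.5, 1.5))
        parent = Node()
        a, b = clusters[i], clusters[j]
        parent.children = [a, b]
        if model == MC:
            a.length = h - heights[id(a)]
            b.length = h - heights[id(b)]
        heights[id(parent)] = h
        clusters[j] = parent
        del clusters[i]
    st = SuperTree(clusters[0])
    k = k_pacemakers if model == MPM else 1
    if model == MC:
        # normalise total depth to 1 so scales are comparable across m
        t = st.edge_lengths()
        t = t / h
        T = np.tile(t, (1, 1))
    else:
        T = np.exp(rng.normal(0.0, tick_sigma, size=(k, st.n_edges)))
    return st.with_edge_lengths(T[0]), T


def _spr_move(gt: GeneTree, rng: np.random.Generator) -> GeneTree:
    """One random subtree-prune-regraft move (lengths carried)."""
    root = gt.root.copy()

    def collect(r: Node):
        parent: dict[int, Node] = {}
        nodes: list[Node] = []
        for v in r.postorder():
            nodes.append(v)
            for c in v.children:
                parent[id(c)] = v
        return nodes, parent

    nodes, parent_of = collect(root)
    cand = [v for v in nodes if v is not root]
    if len(cand) < 4:  # too small for a non-trivial move
        return GeneTree(root, gt.id)
    v = cand[int(rng.integers(0, len(cand)))]
    p = parent_of[id(v)]
    p.children.remove(v)
    if p is not root and len(p.children) == 1:
        only = p.children[0]
        gp = parent_of[id(p)]
        only.length += p.length
        gp.children[gp.children.index(p)] = only
    nodes2, parent2 = collect(root)
    targets = [w for w in nodes2 if w is not root]
    if not targets:
        return GeneTree(gt.root.copy(), gt.id)
    w = targets[int(rng.integers(0, len(targets)))]
    gw = parent2[id(w)]
    x = Node(length=w.length / 2.0)
    w.length = w.length / 2.0
    gw.children[gw.children.index(w)] = x
    x.children = [w, v]
    return GeneTree(root, gt.id)


def _unrooted_gene_from_restricted(
    sub: SuperTree, comp: dict[int, frozenset[int]], t_true: np.ndarray
):
    """Unrooted edge list of a restricted supertree: (bipartition, true length)."""
    taxa = sub.taxa
    ref = min(taxa)
    merged: dict[frozenset, float] = {}
    for v in sub.root.postorder():
        if v is sub.root:
            continue
        below = v.leaf_labels()
        side = below if ref not in below else taxa - below
        length = float(sum(t_true[j] for j in comp[v.edge_id]))
        merged[frozenset(side)] = merged.get(frozenset(side), 0.0) + length
    return merged


def _tree_from_bipartitions(taxa: frozenset, lengths: dict[frozenset, float],
                            template: SuperTree) -> GeneTree:
    """Build the unrooted gene tree matching the template's topology."""
    root = template.root.copy()
    ref = min(taxa)
    seen: dict[frozenset, Node] = {}
    for v in root.postorder():
        if v is root:
            continue
        below = v.leaf_labels()
        side = frozenset(below if ref not in below else taxa - below)
        if side in seen:  # second root-child edge: merged unrooted edge
            v.length = lengths[side]
            seen[side].length = 0.0
        else:
            v.length = lengths[side]
            seen[side] = v
    return GeneTree(root)


def simulate_forest(
    st_truth: tuple[SuperTree, np.ndarray] | SuperTree,
    cfg: SimConfig,
) -> tuple[list[GeneTree], GroundTruth]:
    """Draw a forest of gene trees from the configured pacemaker regime.

    Per gene: a rate r_k ~ lognormal(0, rate_sigma^2); a pacemaker chosen
    uniformly (MPM); a Bernoulli(leaf_keep_prob) taxon subset (redrawn
    until >= 4 leaves survive); observed edge lengths path * r_k * eps
    with ln eps ~ N(0, noise_sigma^2) per unrooted edge of the restricted
    supertree; then ``discordance_moves`` SPR moves; finally unrooted.
    """
    if isinstance(st_truth, SuperTree):
        st, T = st_truth, st_truth.edge_lengths()[None, :]
    else:
        st, T = st_truth
    taxa_sorted = sorted(st.taxa)
    k = T.shape[0]
    forest: list[GeneTree] = []
    rates: dict[int, float] = {}
    pm_of: dict[int, int] = {}
    eps_all: dict[int, dict[frozenset, float]] = {}
    for g in range(cfg.n_genes):
        rng = np.random.default_rng([cfg.seed, 1, g])
        r_k = float(np.exp(rng.normal(0.0, cfg.rate_sigma)))
        pm = int(rng.integers(0, k))
        while True:
            keep = [x for x in taxa_sorted if rng.random() < cfg.leaf_keep_prob]
            if len(keep) >= 4:
                break
        sub, comp = st.restrict(keep)
        true_len = _unrooted_gene_from_restricted(sub, comp, T[pm])
        ln_eps = {
            bip: float(rng.normal(0.0, cfg.noise_sigma)) for bip in sorted(
                true_len, key=lambda b: tuple(sorted(b))
            )
        }
        obs = {bip: true_len[bip] * r_k * np.exp(e) for bip, e in ln_eps.items()}
        gt = _tree_from_bipartitions(frozenset(keep), obs, sub)
        for _ in range(cfg.discordance_moves):
            gt = _spr_move(gt, rng)
        gt.id = g
        forest.append(gt)
        rates[g] = r_k
        pm_of[g] = pm
        eps_all[g] = ln_eps
    truth = GroundTruth(
        supertree=st,
        t_pacemakers=T,
        r=rates,
        pacemaker_of=pm_of,
        ln_eps=eps_all,
        config=cfg,
    )
    return forest, truth


def truth_report(truth: GroundTruth, fit) -> dict:
    """Recovery metrics after gauge alignment (matched geometric means).

    Only meaningful for single-pacemaker truths; raises for MPM with k > 1.
    """
    import scipy.stats

    if truth.t_pacemakers.shape[0] != 1:
        raise ValueError("truth_report requires a single-pacemaker ground truth")
    t_true = truth.t_pacemakers[0]
    st = truth.supertree
    # unrooted gene trees never separate the two root-child edges, so only
    # their sum is identifiable; compare it as one quantity
    root_pair = [c.edge_id for c in st.root.children]
    cov = sorted(set(range(t_true.size)) - set(fit.free_edges) - set(root_pair))
    t_fit = np.append(fit.t[cov], fit.t[root_pair].sum())
    t_tru = np.append(t_true[cov], t_true[root_pair].sum())
    c = float(np.exp(np.mean(np.log(t_tru)) - np.mean(np.log(t_fit))))
    t_aligned = t_fit * c
    max_rel_err = float(np.max(np.abs(t_aligned - t_tru) / t_tru))
    genes = sorted(set(truth.r) & set(fit.r))
    ln_r_true = np.log([truth.r[g] for g in genes])
    ln_r_fit = np.log([fit.r[g] / c for g in genes])
    if np.ptp(ln_r_true) > 0 and np.ptp(ln_r_fit) > 0:
        corr = float(scipy.stats.pearsonr(ln_r_true, ln_r_fit)[0])
    else:
        corr = 1.0 if np.allclose(ln_r_true, ln_r_fit) else 0.0
    return {
        "gauge_scale": c,
        "t_max_rel_err": max_rel_err,
        "ln_rate_pearson_r": corr,
        "E2": fit.E2,
    }


def write_simulation(outdir, forest: list[GeneTree], truth: GroundTruth) -> None:
    """forest.nwk (one Newick per line), supertree.nwk and truth.json."""
    import os

    from .forest_io import write_forest

    os.makedirs(outdir, exist_ok=True)
    write_forest(os.path.join(outdir, "forest.nwk"), forest)
    with open(os.path.join(outdir, "supertree.nwk"), "w", encoding="utf-8") as fh:
        fh.write(truth.supertree.newick() + "\n")
    payload = {
        "config": asdict(truth.config),
        "t_pacemakers": truth.t_pacemakers.tolist(),
        "r": {str(g): v for g, v in truth.r.items()},
        "pacemaker_of": {str(g): v for g, v in truth.pacemaker_of.items()},
    }
    with open(os.path.join(outdir, "truth.json"), "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2)
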