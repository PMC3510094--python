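import pytest

from upm import SimConfig, build_mapped_forest, simulate_forest, simulate_supertree


@pytest.fixture(scope="session")
def upm_case():
    """Moderate-noise pacemaker-generated forest with its mapped design."""
    cfg = SimConfig(
        n_taxa=12, n_genes=30, model="UPM", noise_sigma=0.3, rate_sigma=0.5,
        leaf_keep_prob=0.8, discordance_moves=0, seed=7,
    )
    st, T = simulate_supertree(cfg.n_taxa, cfg.model, cfg.seed, tick_sigma=cfg.tick_sigma)
    forest, truth = simulate_forest((st, T), cfg)
    mf = build_mapped_forest(forest, st, min_mast=4)
    return st, T, forest, truth, mf


@pytest.fixture(scope="session")
def mc_case():
    """Clock-generated forest (ultrametric truth)."""
    cfg = SimConfig(
        n_taxa=12, n_genes=30, model="MC", noise_sigma=0.3, rate_sigma=0.5,
        leaf_keep_prob=0.8, discordance_moves=0, seed=19,
    )
    st, T = simulate_supertree(cfg.n_taxa, cfg.model, cfg.seed)
    forest, truth = simulate_forest((st, T), cfg)
    mf = build_mapped_forest(forest, st, min_mast=4)
    return st, T, forest, truth, mf


@pytest.fixture(scope="session")
def upm_fits(upm_case):
    from upm import fit_both

    st, T, forest, truth, mf = upm_case
    return fit_both(mf, st)
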