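"""Per-gene model preference, bootstrap robustness, and covariate analysis.

The joint E^2 decomposes over genes, so each gene's contribution under the
two models measures how strongly that gene prefers the pacemaker over the
clock: ratio = E2_MC,k / E2_UPM,k (> 1 favors the pacemaker), summarised
on a log scale as dfit = log10(ratio) together with the average goodness
of fit afit = -(log10 E2_MC,k + log10 E2_UPM,k)/2.

Because the decomposition is exact, the AIC comparison for any resample of
genes can be recomputed by summation alone; the default bootstrap
therefore resamples per-gene contributions of the full-data fits (refitting
each replicate is available behind a flag but is much slower).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .agreement import MappedForest, MastResult
from .model_selection import delta_aic_from_e2
from .pacemaker_fit import FitResult

__all__ = [
    "GeneDiagnostics",
    "BootstrapResult",
    "per_gene_diagnostics",
    "diagnostics_frame",
    "delta_aic_for_indices",
    "bootstrap_delta_aic",
    "preference_regression",
    "plot_histogram",
]


@dataclass(frozen=True)
class GeneDiagnostics:
    gene_id: int
    e2_mc_k: float
    e2_upm_k: float
    ratio: float  # e2_mc_k / e2_upm_k; nan when either E^2 is zero
    dfit: float  # log10(ratio)
    afit: float  # -(log10 e2_mc_k + log10 e2_upm_k) / 2
    mg: float  # fraction of original leaves retained in the MAST
    leaves_orig: int
    n_edges_k: int
    rate: float  # fitted relative rate under the pacemaker model


def per_gene_diagnostics(
    fit_mc: FitResult,
    fit_upm: FitResult,
    mf: MappedForest,
) -> list[GeneDiagnostics]:
    """One record per gene; genes with a zero E^2 get nan log-scale fields."""
    if set(fit_mc.per_gene_E2) != set(fit_upm.per_gene_E2):
        raise ValueError("fits do not share a gene set")
    edges_per_gene: dict[int, int] = {}
    for row in mf.rows:
        edges_per_gene[row.gene_id] = edges_per_gene.get(row.gene_id, 0) + 1
    out = []
    for g in sorted(fit_mc.per_gene_E2):
        e2m = fit_mc.per_gene_E2[g]
        e2u = fit_upm.per_gene_E2[g]
        if e2m > 0 and e2u > 0:
            ratio = e2m / e2u
            dfit = math.log10(ratio)
            afit = -(math.log10(e2m) + math.log10(e2u)) / 2.0
        else:
            ratio = dfit = afit = float("nan")
        mast = mf.mast_results.get(g)
        out.append(
            GeneDiagnostics(
                gene_id=g,
                e2_mc_k=e2m,
                e2_upm_k=e2u,
                ratio=ratio,
                dfit=dfit,
                afit=afit,
                mg=mast.mg if mast else float("nan"),
                leaves_orig=mast.leaves_orig if mast else -1,
                n_edges_k=edges_per_gene[g],
                rate=fit_upm.r[g],
            )
        )
    return out


def diagnostics_frame(diag: list[GeneDiagnostics]) -> pd.DataFrame:
    return pd.DataFrame([d.__dict__ for d in diag]).set_index("gene_id")


@dataclass
class BootstrapResult:
    n_reps: int
    seed: int
    delta_aic_samples: np.ndarray
    fraction_positive: float
    min: float
    max: float
    point_estimate: float


def delta_aic_for_indices(
    diag: list[GeneDiagnostics], indices: np.ndarray, m: int
) -> float:
    """dAIC recombined from per-gene contributions for one gene resample."""
    e2m = np.array([d.e2_mc_k for d in diag])
    e2u = np.array([d.e2_upm_k for d in diag])
    ne = np.array([d.n_edges_k for d in diag])
    n = int(ne[indices].sum())
    return delta_aic_from_e2(
        float(e2m[indices].sum()), float(e2u[indices].sum()), n, -(m - 1)
    )


def bootstrap_delta_aic(
    diag: list[GeneDiagnostics],
    m: int,
    n_reps: int = 1000,
    seed: int = 0,
    refit: bool = False,
    mf: MappedForest | None = None,
    st=None,
    fit_cfg=None,
) -> BootstrapResult:
    """Gene-level bootstrap of dAIC.

    By default each replicate recombines the per-gene E^2 contributions of
    the full-data fits by summation (the decomposition is exact, so no
    refitting is needed).  With ``refit=True`` — and ``mf``/``st`` supplied
    — every replicate re-estimates both models on the resampled forest;
    this is far slower and matters only if resampling shifts the optimum
    itself.  Replicate r draws its gene sample from a generator keyed
    (seed, r), so runs are reproducible and replicates replayable.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if refit and (mf is None or st is None):
        raise ValueError("refit=True requires mf and st")
    G = len(diag)
    gene_ids = [d.gene_id for d in diag]
    e2m = np.array([d.e2_mc_k for d in diag])
    e2u = np.array([d.e2_upm_k for d in diag])
    ne = np.array([d.n_edges_k for d in diag])
    samples = np.empty(n_reps)
    for rep in range(n_reps):
        rng = np.random.default_rng([seed, rep])
        idx = rng.integers(0, G, size=G)
        if refit:
            samples[rep] = _refit_delta_aic(
                mf, st, [gene_ids[i] for i in idx], m, fit_cfg
            )
        else:
            n = int(ne[idx].sum())
            samples[rep] = delta_aic_from_e2(
                float(e2m[idx].sum()), float(e2u[idx].sum()), n, -(m - 1)
            )
    point = delta_aic_for_indices(diag, np.arange(G), m)
    return BootstrapResult(
        n_reps=n_reps,
        seed=seed,
        delta_aic_samples=samples,
        fraction_positive=float((samples > 0).mean()),
        min=float(samples.min()),
        max=float(samples.max()),
        point_estimate=point,
    )


def _refit_delta_aic(mf, st, genes: list[int], m: int, fit_cfg) -> float:
    """Refit both models on a resampled forest (duplicates renumbered)."""
    from .agreement import MappedRow
    from .pacemaker_fit import fit_both

    by_gene: dict[int, list[MappedRow]] = {}
    for row in mf.rows:
        by_gene.setdefault(row.gene_id, []).append(row)
    rows = []
    for new_id, g in enumerate(genes):
        rows.extend(
            MappedRow(new_id, r.edge_id, r.length, r.st_path) for r in by_gene[g]
        )
    sub = MappedForest(rows, mf.n_st_edges)
    fmc, fupm = fit_both(sub, st, fit_cfg)
    return delta_aic_from_e2(fmc.E2, fupm.E2, fmc.n_edges_used, -(m - 1))


def preference_regression(diag: list[GeneDiagnostics]):
    """OLS of ln(E2_MC,k/E2_UPM,k) on afit, mg and the original leaf count.

    Returns the fitted statsmodels results object (coefficients, p-values
    and R^2 live on it).  Genes with undefined log-ratios are dropped.
    """
    import statsmodels.api as sm

    if len(diag) < 10:
        raise ValueError("need at least 10 genes with defined ratios")
    df = diagnostics_frame(diag)
    df = df.dropna(subset=["ratio", "afit", "mg"])
    if len(df) < 10:
        raise ValueError("need at least 10 genes with defined ratios")
    y = np.log(df["ratio"])
    X = sm.add_constant(df[["afit", "mg", "leaves_orig"]].astype(float))
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("degenerate (collinear) design matrix")
    return sm.OLS(y, X).fit()


def plot_histogram(values, path, xlabel: str, bins: int = 40, log_x: bool = False):
    """Plain histogram (the figures this supports need no kernel smoothing)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    fig, ax = plt.subplots(figsize=(5, 3.5))
    if log_x:
        values = values[values > 0]
        bins_ = np.geomspace(values.min(), values.max(), bins)
        ax.set_xscale("log")
    else:
        bins_ = bins
    ax.hist(values, bins=bins_, color="steelblue", edgecolor="white")
    ax.set_xlabel(xlabel)
    ax.set_ylabel("count")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
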