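"""Information-criterion comparison of the clock and pacemaker fits.

Both models share the plug-in Gaussian likelihood, so for nested fits on
the same n gene-tree edges the criteria reduce to closed forms in the two
residual sums of squares:

    dAIC = 2*dd + n * ln(E2_MC / E2_UPM)
    dBIC = dd * ln(n) + n * ln(E2_MC / E2_UPM)

where dd is the difference in freely optimized parameter counts.  The MC
fit loses one parameter per internal node to the ultrametricity
constraints, so with every supertree edge identifiable dd = -(m-1).
Positive dAIC favors the unconstrained pacemaker; negative favors the
clock.  The same arithmetic, with the appropriate dd, drives the
degenerate multiple-pacemaker (dMPM) bound: one pacemaker per gene fits
perfectly, so its plausibility is assessed against the residual floor a
Poisson substitution process would impose even on perfectly synchronous
genes.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

from .pacemaker_fit import FitResult

__all__ = [
    "ModelComparison",
    "DmpmReport",
    "compare_models",
    "delta_aic_from_e2",
    "delta_bic_from_e2",
    "rmsd",
    "relative_weight",
    "dmpm_analysis",
]


def delta_aic_from_e2(e2_mc: float, e2_upm: float, n: int, delta_d: int) -> float:
    return 2.0 * delta_d + n * math.log(e2_mc / e2_upm)


def delta_bic_from_e2(e2_mc: float, e2_upm: float, n: int, delta_d: int) -> float:
    return delta_d * math.log(n) + n * math.log(e2_mc / e2_upm)


def rmsd(E2: float, n: int) -> tuple[float, float]:
    """Root mean square deviation, in ln units and as a multiplicative factor."""
    if E2 < 0 or n < 1:
        raise ValueError("need E2 >= 0 and n >= 1")
    ln_units = math.sqrt(E2 / n)
    return ln_units, math.exp(ln_units)


def relative_weight(delta_aic: float) -> tuple[float, float]:
    """Likelihood weight exp(-|dAIC|/2) of the suboptimal model.

    Returns the weight (which underflows to 0.0 for large |dAIC|) together
    with its exact base-10 exponent.
    """
    exponent10 = -abs(delta_aic) / (2.0 * math.log(10.0))
    try:
        weight = math.exp(-abs(delta_aic) / 2.0)
    except OverflowError:  # pragma: no cover
        weight = 0.0
    return weight, exponent10


@dataclass
class ModelComparison:
    n: int
    d_mc: int
    d_upm: int
    delta_d: int
    e2_mc: float
    e2_upm: float
    delta_aic: float
    delta_bic: float
    rel_weight: float
    rel_weight_log10: float
    rmsd_ln_mc: float
    rmsd_factor_mc: float
    rmsd_ln_upm: float
    rmsd_factor_upm: float
    n_trees: int | None = None
    n_leaves: int | None = None

    def preferred(self) -> str:
        return "UPM" if self.delta_aic > 0 else "MC"

    def to_json(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}

    def to_markdown(self) -> str:
        """Comparison table: one row per statistic, MC and UPM columns."""
        w = f"10^{self.rel_weight_log10:.1f}" if self.delta_aic > 0 else "1"
        rows = [
            ("Number of trees", str(self.n_trees or "-"), ""),
            ("Number of leaves", str(self.n_leaves or "-"), ""),
            ("Number of edges", str(self.n), ""),
            ("E^2", f"{self.e2_mc:.1f}", f"{self.e2_upm:.1f}"),
            ("r.m.s.d., ln units", f"{self.rmsd_ln_mc:.4f}", f"{self.rmsd_ln_upm:.4f}"),
            ("r.m.s.d., factor", f"{self.rmsd_factor_mc:.4f}", f"{self.rmsd_factor_upm:.4f}"),
            ("dAIC", f"{self.delta_aic:.1f}", "0"),
            ("Relative likelihood weight", w if self.delta_aic > 0 else "1",
             "1" if self.delta_aic > 0 else f"10^{self.rel_weight_log10:.1f}"),
            ("dBIC", f"{self.delta_bic:.1f}", "0"),
        ]
        out = ["| statistic | MC | UPM |", "| --- | --- | --- |"]
        out += [f"| {a} | {b} | {c} |" for a, b, c in rows]
        return "\n".join(out)


def compare_models(
    fit_mc: FitResult, fit_upm: FitResult, m: int,
    n_trees: int | None = None, n_leaves: int | None = None,
) -> ModelComparison:
    """Full AIC/BIC/r.m.s.d. comparison of a clock and a pacemaker fit.

    Both fits must come from the same mapped forest.  The gauge constraint
    cancels in the parameter-count difference, leaving dd = -(m-1) when all
    supertree edges are identifiable.
    """
    if fit_mc.n_edges_used != fit_upm.n_edges_used:
        raise ValueError(
            "fits are not on the same data "
            f"(n={fit_mc.n_edges_used} vs {fit_upm.n_edges_used})"
        )
    n = fit_mc.n_edges_used
    delta_d = fit_mc.n_params - fit_upm.n_params
    if not fit_mc.free_edges and not fit_upm.free_edges:
        assert delta_d == -(m - 1)
    delta_aic = delta_aic_from_e2(fit_mc.E2, fit_upm.E2, n, delta_d)
    delta_bic = delta_bic_from_e2(fit_mc.E2, fit_upm.E2, n, delta_d)
    weight, w10 = relative_weight(delta_aic)
    ln_mc, f_mc = rmsd(fit_mc.E2, n)
    ln_upm, f_upm = rmsd(fit_upm.E2, n)
    return ModelComparison(
        n=n,
        d_mc=fit_mc.n_params,
        d_upm=fit_upm.n_params,
        delta_d=delta_d,
        e2_mc=fit_mc.E2,
        e2_upm=fit_upm.E2,
        delta_aic=delta_aic,
        delta_bic=delta_bic,
        rel_weight=weight,
        rel_weight_log10=w10,
        rmsd_ln_mc=ln_mc,
        rmsd_factor_mc=f_mc,
        rmsd_ln_upm=ln_upm,
        rmsd_factor_upm=f_upm,
        n_trees=n_trees,
        n_leaves=n_leaves,
    )


@dataclass
class DmpmReport:
    total_length: float
    n_edges: int
    protein_len: int
    mean_subs_per_branch: float
    noise_e2_floor: float
    delta_d_upm_vs_dmpm: int
    delta_aic_upm_vs_dmpm: float
    max_pacemakers: int

    def to_json(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def dmpm_analysis(
    total_length: float,
    n_edges: int,
    protein_len: int,
    e2_upm: float,
    n_trees: int,
    n_st_edges: int,
    n_rates: int,
) -> DmpmReport:
    """Degenerate multiple-pacemaker (one pacemaker per gene) bound.

    A pacemaker per gene reproduces every edge exactly, so its E^2 is
    bounded below only by sampling noise.  With branch lengths in
    substitutions per site and proteins of ``protein_len`` sites, a branch
    carries on average s substitutions; a Poisson substitution process then
    implies a typical multiplicative length error of (s + sqrt(s))/s,
    putting a floor of n * ln((s+sqrt(s))/s)^2 on E^2.  The substitution
    count s is rounded to the nearest whole substitution before use.

    The AIC comparison charges the dMPM one full edge-length vector per
    gene and no rates, d = n_trees * n_st_edges, against the single
    pacemaker's n_st_edges + n_rates.  The maximum number of distinct
    pacemakers is the largest c for which c edge-length vectors, each
    fitting its genes perfectly down to the noise floor, still do not beat
    the single pacemaker on AIC.
    """
    if min(n_edges, protein_len, n_trees, n_st_edges, n_rates) <= 0:
        raise ValueError("all counts must be positive")
    mean_subs = total_length / n_edges * protein_len
    s = max(round(mean_subs), 1)
    mean_error = (s + math.sqrt(s)) / s
    floor = n_edges * math.log(mean_error) ** 2
    delta_d = (n_st_edges + n_rates) - n_trees * n_st_edges
    delta_aic = 2.0 * delta_d + n_edges * math.log(e2_upm / floor)
    # largest c with 2*(c*n_st_edges - (n_st_edges + n_rates))
    #               + n_edges*ln(floor/e2_upm) <= 0
    bound = (n_st_edges + n_rates + 0.5 * n_edges * math.log(e2_upm / floor)) / n_st_edges
    max_pm = math.floor(bound + 1e-12)
    return DmpmReport(
        total_length=total_length,
        n_edges=n_edges,
        protein_len=protein_len,
        mean_subs_per_branch=mean_subs,
        noise_e2_floor=floor,
        delta_d_upm_vs_dmpm=delta_d,
        delta_aic_upm_vs_dmpm=delta_aic,
        max_pacemakers=max_pm,
    )


def write_comparison(cmp_: ModelComparison, json_path=None, md_path=None) -> None:
    if json_path is not None:
        with open(json_path, "w", encoding="utf-8") as fh:
            json.dump(cmp_.to_json(), fh, indent=2)
    if md_path is not None:
        with open(md_path, "w", encoding="utf-8") as fh:
            fh.write(cmp_.to_markdown() + "\n")
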