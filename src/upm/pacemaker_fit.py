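"""Maximum-likelihood fit of supertree edge lengths and gene rates.

Model: the observed length of gene-tree edge i of gene k is

    l_ik = t_j * r_k * eps_ik,      ln eps_ik ~ N(0, sigma^2)

where t_j is the total length of the supertree edge path the gene-tree
edge maps to, and r_k is the gene-specific rate.  With lognormal error the
log-likelihood is, after plugging in sigma_hat^2 = E^2/n,

    logL = -(n/2) ln(2 pi E^2 / n) - n/2,

so maximizing the likelihood means minimizing the residual sum of squares

    E^2 = sum_ik ( ln l_ik - ln(sum of t over the path) - ln r_k )^2 .

Two regimes are fitted:

* **UPM** — t unconstrained (positive): supertree edges are arbitrary
  "ticks" of a shared pacemaker.  Optimized in (ln t, ln r) coordinates
  with an analytic gradient (positivity is automatic and, when every path
  is a single edge, the problem is exactly linear).
* **MC** — t additionally satisfies ultrametricity (all root-to-leaf
  depths equal), expressed as m-1 linear equality constraints, one per
  internal node.  Optimized in t coordinates with SLSQP.

The model is invariant under (t, r) -> (c t, r / c); the gauge is fixed
after convergence by rescaling so that the geometric mean of the rates is
1 (rates are therefore relative rates).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.optimize
import scipy.sparse

from .agreement import MappedForest
from .forest_io import Node, SuperTree

__all__ = [
    "FitConfig",
    "FitResult",
    "residual",
    "e2_objective",
    "ultrametric_constraints",
    "initial_values",
    "fit",
    "fit_both",
    "loglik_from_e2",
]

UPM = "UPM"
MC = "MC"


@dataclass
class FitConfig:
    model: str = UPM
    floor: float = 1e-8  # positivity floor for t (MC) and initial values
    max_iter: int = 10_000
    tol: float = 1e-9  # convergence tolerance on the objective
    zero_length_floor: float = 1e-9  # rows with l <= this are dropped
    n_restarts: int = 1
    restart_seed: int = 0
    restart_spread: float = 0.3  # sd of ln-scale start perturbations

    def __post_init__(self):
        if self.model not in (UPM, MC):
            raise ValueError(f"model must be {UPM!r} or {MC!r}")
        if self.floor <= 0 or self.tol <= 0:
            raise ValueError("floor and tol must be positive")


@dataclass
class FitResult:
    model: str
    t: np.ndarray  # full supertree edge-length vector (2m-2)
    r: dict[int, float]  # gene id -> relative rate
    E2: float
    sigma2: float
    loglik: float
    per_gene_E2: dict[int, float]
    n_edges_used: int
    n_params: int
    converged: bool
    iterations: int
    n_dropped_rows: int = 0
    free_edges: frozenset[int] = frozenset()
    restart_seeds: list[int] = field(default_factory=list)
    message: str = ""

    def rates(self) -> np.ndarray:
        return np.array([self.r[g] for g in sorted(self.r)])


def residual(l: float, path_length: float, rate: float) -> float:
    """Log-scale deviation ln l - ln(path length) - ln(rate) of one edge."""
    if l <= 0 or path_length <= 0 or rate <= 0:
        raise ValueError("residual requires strictly positive arguments")
    return math.log(l) - math.log(path_length) - math.log(rate)


def loglik_from_e2(E2: float, n: int) -> float:
    """Plug-in log-likelihood -(n/2) ln(2 pi E^2/n) - n/2.

    A perfect fit (E^2 = 0) makes the plug-in variance collapse, so the
    likelihood diverges; +inf is returned and callers must treat it as the
    degenerate case.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    if E2 <= 0:
        return math.inf
    return -(n / 2.0) * math.log(2.0 * math.pi * E2 / n) - n / 2.0


# ---------------------------------------------------------------------------
# design assembly


class _Design:
    """Arrays extracted from a MappedForest for vectorised objectives."""

    def __init__(self, mf: MappedForest, zero_length_floor: float):
        kept = [r for r in mf.rows if r.length > zero_length_floor]
        self.n_dropped = mf.n - len(kept)
        if not kept:
            raise ValueError("no usable rows (all lengths at or below floor)")
        self.genes = sorted({r.gene_id for r in kept})
        gidx = {g: i for i, g in enumerate(self.genes)}
        self.n_st_edges = mf.n_st_edges
        self.log_l = np.array([math.log(r.length) for r in kept])
        self.gene_of_row = np.array([gidx[r.gene_id] for r in kept], dtype=np.intp)
        rows_idx, cols_idx = [], []
        for i, r in enumerate(kept):
            for j in r.st_path:
                rows_idx.append(i)
                cols_idx.append(j)
        self.P = scipy.sparse.csr_matrix(
            (np.ones(len(rows_idx)), (rows_idx, cols_idx)),
            shape=(len(kept), mf.n_st_edges),
        )
        self.covered = np.asarray((self.P.sum(axis=0) > 0)).ravel()
        self.n = len(kept)
        self.n_genes = len(self.genes)

    def residuals(self, t: np.ndarray, log_r: np.ndarray) -> np.ndarray:
        path = self.P @ t
        return self.log_l - np.log(path) - log_r[self.gene_of_row]

    def per_gene_e2(self, resid: np.ndarray) -> dict[int, float]:
        sums = np.bincount(self.gene_of_row, resid**2, minlength=self.n_genes)
        return {g: float(s) for g, s in zip(self.genes, sums)}


def e2_objective(t, r, mf: MappedForest, zero_length_floor: float = 1e-9) -> float:
    """E^2 at given edge lengths and rates (r maps gene id -> rate)."""
    d = _Design(mf, zero_length_floor)
    t = np.asarray(t, dtype=float)
    if np.any(t[d.covered] <= 0):
        raise ValueError("edge lengths on covered edges must be positive")
    log_r = np.log(np.array([float(r[g]) for g in d.genes]))
    resid = d.residuals(t, log_r)
    return float(resid @ resid)


# ---------------------------------------------------------------------------
# constraints and initial values


def ultrametric_constraints(st: SuperTree) -> np.ndarray:
    """Linear equality constraints A t = 0 enforcing ultrametricity.

    One row per internal node: the depth from the node to a representative
    leaf of its left subtree equals the depth to a representative leaf of
    its right subtree.  By induction over the tree this makes all
    root-to-leaf depths equal.  A rooted binary tree with m leaves yields
    exactly m - 1 rows.
    """
    rows = []

    def leftmost_path(v: Node) -> list[int]:
        path = []
        while v.children:
            c = v.children[0]
            path.append(c.edge_id)
            v = c
        return path

    for v in st.root.postorder():
        if not v.children:
            continue
        a = np.zeros(st.n_edges)
        c1, c2 = v.children
        for e in [c1.edge_id] + leftmost_path(c1):
            a[e] += 1.0
        for e in [c2.edge_id] + leftmost_path(c2):
            a[e] -= 1.0
        rows.append(a)
    A = np.array(rows)
    assert A.shape[0] == st.m - 1
    return A


def initial_values(
    mf: MappedForest, st: SuperTree, zero_length_floor: float = 1e-9
) -> tuple[np.ndarray, dict[int, float]]:
    """Start values: singleton-path means for t, conditional optimum for r.

    For each supertree edge the mean observed length over all gene-tree
    edges that map uniquely to it is taken as t0; edges covered only by
    composite paths (or not at all) fall back to the global mean length.
    Given t0, each gene's rate starts at its conditional ML value
    exp(mean(ln l - ln path)).  On noise-free single-rate data this start
    is already the exact ML solution.
    """
    d = _Design(mf, zero_length_floor)
    sums = np.zeros(st.n_edges)
    counts = np.zeros(st.n_edges)
    for row in mf.rows:
        if row.length <= zero_length_floor:
            continue
        if len(row.st_path) == 1:
            (j,) = row.st_path
            sums[j] += row.length
            counts[j] += 1.0
    global_mean = float(np.exp(d.log_l.mean()))
    t0 = np.where(counts > 0, sums / np.maximum(counts, 1.0), global_mean)
    t0 = np.maximum(t0, 1e-12)
    path = d.P @ t0
    delta = d.log_l - np.log(path)
    means = np.bincount(d.gene_of_row, delta, minlength=d.n_genes) / np.bincount(
        d.gene_of_row, minlength=d.n_genes
    )
    r0 = {g: float(np.exp(mu)) for g, mu in zip(d.genes, means)}
    return t0, r0


def _ultrametric_projection(st: SuperTree, t0: np.ndarray, floor: float) -> np.ndarray:
    """An exactly feasible ultrametric start near t0.

    Node heights are built bottom-up as the maximum over children of
    (child height + child edge length), which keeps every increment at or
    above the floor, so both the equality constraints and the bounds hold
    at the start.
    """
    heights: dict[int, float] = {}

    def rec(v: Node) -> float:
        if not v.children:
            h = 0.0
        else:
            h = max(rec(c) + max(t0[c.edge_id], floor) for c in v.children)
        heights[id(v)] = h
        return h

    rec(st.root)
    t = np.empty(st.n_edges)
    for v in st.root.postorder():
        for c in v.children:
            t[c.edge_id] = max(heights[id(v)] - heights[id(c)], floor)
    return t


# ---------------------------------------------------------------------------
# the fit itself


def _fit_once(
    d: _Design,
    st: SuperTree,
    cfg: FitConfig,
    t0: np.ndarray,
    r0_log: np.ndarray,
):
    E = d.n_st_edges
    G = d.n_genes
    if cfg.model == UPM:
        cov = np.flatnonzero(d.covered)
        Pc = d.P[:, cov].tocsr()
        x0 = np.concatenate([np.log(np.maximum(t0[cov], 1e-12)), r0_log])

        def fun(x):
            tcov = np.exp(x[:cov.size])
            path = Pc @ tcov
            resid = d.log_l - np.log(path) - x[cov.size :][d.gene_of_row]
            w = resid / path
            g_t = -2.0 * (Pc.T @ w) * tcov
            g_r = -2.0 * np.bincount(d.gene_of_row, resid, minlength=G)
            return float(resid @ resid), np.concatenate([g_t, g_r])

        res = scipy.optimize.minimize(
            fun,
            x0,
            jac=True,
            method="L-BFGS-B",
            options={
                "maxiter": cfg.max_iter,
                "ftol": cfg.tol * 1e-3,
                "gtol": 1e-10,
                "maxfun": 10 * cfg.max_iter,
            },
        )
        t = t0.copy()
        t[cov] = np.exp(res.x[: cov.size])
        log_r = res.x[cov.size :]
    else:  # MC
        A = ultrametric_constraints(st)
        t_start = _ultrametric_projection(st, t0, cfg.floor)
        x0 = np.concatenate([t_start, r0_log])

        def fun(x):
            t = x[:E]
            path = d.P @ t
            resid = d.log_l - np.log(path) - x[E:][d.gene_of_row]
            w = resid / path
            g_t = -2.0 * (d.P.T @ w)
            g_r = -2.0 * np.bincount(d.gene_of_row, resid, minlength=G)
            return float(resid @ resid), np.concatenate([g_t, g_r])

        Afull = np.hstack([A, np.zeros((A.shape[0], G))])
        constraints = {
            "type": "eq",
            "fun": lambda x: Afull @ x,
            "jac": lambda x: Afull,
        }
        bounds = [(cfg.floor, None)] * E + [(None, None)] * G
        res = scipy.optimize.minimize(
            fun,
            x0,
            jac=True,
            method="SLSQP",
            bounds=bounds,
            constraints=[constraints],
            options={"maxiter": min(cfg.max_iter, 1000), "ftol": cfg.tol},
        )
        t = np.maximum(res.x[:E], cfg.floor)
        log_r = res.x[E:]
    resid = d.residuals(t, log_r)
    e2 = float(resid @ resid)
    return t, log_r, e2, res


def fit(mf: MappedForest, st: SuperTree, cfg: FitConfig | None = None) -> FitResult:
    """Minimize E^2 for one model and return the full fit record.

    Rows whose observed length is at or below ``cfg.zero_length_floor`` are
    excluded (the lognormal error model gives them zero likelihood) and
    counted in ``n_dropped_rows``.  Supertree edges covered by no retained
    row are unidentifiable; they are reported in ``free_edges`` and excluded
    from the parameter count.
    """
    cfg = cfg or FitConfig()
    if mf.n == 0:
        raise ValueError("empty mapped forest")
    d = _Design(mf, cfg.zero_length_floor)
    t0, r0 = initial_values(mf, st, cfg.zero_length_floor)
    r0_log = np.log(np.array([r0[g] for g in d.genes]))

    starts = [(t0, r0_log)]
    seeds: list[int] = []
    for i in range(1, cfg.n_restarts):
        seed = cfg.restart_seed + i
        seeds.append(seed)
        rng = np.random.default_rng(seed)
        starts.append(
            (
                t0 * np.exp(rng.normal(0, cfg.restart_spread, t0.size)),
                r0_log + rng.normal(0, cfg.restart_spread, r0_log.size),
            )
        )

    best = None
    for t_s, r_s in starts:
        out = _fit_once(d, st, cfg, t_s, r_s)
        if best is None or out[2] < best[2]:
            best = out
    t, log_r, e2, res = best

    # gauge: geometric mean of rates = 1
    shift = float(log_r.mean())
    log_r = log_r - shift
    t = t * math.exp(shift)

    resid = d.residuals(t, log_r)
    e2 = float(resid @ resid)
    n_free_constraints = (st.m - 1) if cfg.model == MC else 0
    n_params = int(d.covered.sum()) + d.n_genes - n_free_constraints - 1
    return FitResult(
        model=cfg.model,
        t=t,
        r={g: float(math.exp(v)) for g, v in zip(d.genes, log_r)},
        E2=e2,
        sigma2=e2 / d.n,
        loglik=loglik_from_e2(e2, d.n),
        per_gene_E2=d.per_gene_e2(resid),
        n_edges_used=d.n,
        n_params=n_params,
        converged=bool(res.success),
        iterations=int(res.nit),
        n_dropped_rows=d.n_dropped,
        free_edges=frozenset(np.flatnonzero(~d.covered).tolist()),
        restart_seeds=seeds,
        message=str(res.message),
    )


def fit_both(
    mf: MappedForest, st: SuperTree, cfg: FitConfig | None = None
) -> tuple[FitResult, FitResult]:
    """Fit MC and UPM on the same mapped forest, enforcing E2_UPM <= E2_MC.

    The MC feasible set is nested in the UPM one, so whenever the UPM
    optimizer lands above the MC optimum it is restarted from the MC
    solution (a feasible UPM point) and the better result kept.
    """
    base = cfg or FitConfig()
    fit_mc = fit(mf, st, _with_model(base, MC))
    fit_upm = fit(mf, st, _with_model(base, UPM))
    if fit_upm.E2 > fit_mc.E2:
        d = _Design(mf, base.zero_length_floor)
        log_r_mc = np.log(np.array([fit_mc.r[g] for g in d.genes]))
        cfg_upm = _with_model(base, UPM)
        t, log_r, e2, res = _fit_once(d, st, cfg_upm, fit_mc.t.copy(), log_r_mc)
        if e2 < fit_upm.E2:
            shift = float(log_r.mean())
            log_r = log_r - shift
            t = t * math.exp(shift)
            resid = d.residuals(t, log_r)
            e2 = float(resid @ resid)
            fit_upm = FitResult(
                model=UPM,
                t=t,
                r={g: float(math.exp(v)) for g, v in zip(d.genes, log_r)},
                E2=e2,
                sigma2=e2 / d.n,
                loglik=loglik_from_e2(e2, d.n),
                per_gene_E2=d.per_gene_e2(resid),
                n_edges_used=d.n,
                n_params=fit_upm.n_params,
                converged=bool(res.success),
                iterations=int(res.nit),
                n_dropped_rows=d.n_dropped,
                free_edges=fit_upm.free_edges,
                message="restarted from MC solution: " + str(res.message),
            )
    return fit_mc, fit_upm


def _with_model(cfg: FitConfig, model: str) -> FitConfig:
    from dataclasses import replace

    return replace(cfg, model=model)


def fit_result_to_json(result: FitResult) -> dict:
    return {
        "model": result.model,
        "t": result.t.tolist(),
        "r": {str(k): v for k, v in result.r.items()},
        "E2": result.E2,
        "sigma2": result.sigma2,
        "loglik": result.loglik,
        "per_gene_E2": {str(k): v for k, v in result.per_gene_E2.items()},
        "n_edges_used": result.n_edges_used,
        "n_params": result.n_params,
        "converged": result.converged,
        "iterations": result.iterations,
        "n_dropped_rows": result.n_dropped_rows,
        "free_edges": sorted(result.free_edges),
    }
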