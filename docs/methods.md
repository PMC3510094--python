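# Methods

## Model and assumptions

The package fits a forest of unrooted gene trees to a fixed rooted binary
supertree topology over *m* taxa.  The supertree contributes 2*m*−2 edge
lengths **t**; each gene *k* contributes one rate *r<sub>k</sub>*.  The
observed length of gene-tree edge *i* (substitutions/site) is modelled as
*l<sub>i,k</sub>* = *t<sub>j</sub>* *r<sub>k</sub>* *ε<sub>i,k</sub>*,
where *t<sub>j</sub>* is the summed length of the supertree edge path the
gene edge maps to and the multiplicative error is lognormal with
ln ε ~ N(0, σ²), independent across edges and genes.  "Lognormal with
mean 1" is read as median 1 (ln ε centred at 0); the mean-1 variant
(centre −σ²/2) would shift every fit by a constant that cancels from all
model comparisons, so nothing downstream depends on the choice.

Two regimes are fitted.  UPM leaves **t** free (positive); MC adds the
ultrametricity requirement that all root-to-leaf depths agree, encoded as
one linear equality per internal node (depth via a representative leaf of
the left subtree = depth via the right subtree; induction over the tree
gives full ultrametricity), *m*−1 equalities in all.

The likelihood is Gaussian in log scale; plugging σ̂² = *E*²/*n* into it
gives log *L* = −(*n*/2) ln(2π*E*²/*n*) − *n*/2, so maximum likelihood is
minimum *E*².  A perfect fit (*E*² = 0) sends the plug-in likelihood to
+∞; the code returns an infinity flag rather than a number, and the
degenerate-pacemaker analysis below is the one place this matters.

## MAST reduction and edge mapping

A gene tree enters the fit only on the leaf set where it agrees with the
supertree.  Rooted MAST is computed by the standard O(|a|·|b|) dynamic
program over node pairs (match the two child pairs both ways, or descend
on either side).  Because gene trees are unrooted, their MAST with the
rooted supertree (restricted first to the gene's taxa) is the maximum
over all edge rootings of the gene tree; rooting at internal nodes is
redundant because the DP's descend moves absorb the resulting degree-2
suppressions.  Ties — between co-optimal leaf sets and between co-optimal
rootings — go to the lexicographically smallest sorted leaf tuple, making
the pipeline deterministic; co-optimal MASTs are genuinely different
reductions and can yield slightly different *E*², so the tie-break is a
convention, not a claim of uniqueness.  A concordance fast path (equal
bipartition sets) skips the DP for topologically identical trees.

Mapping proceeds by bipartition matching: the gene tree reduced to the
MAST leaves and the supertree restricted to them share an unrooted
topology, so each reduced gene edge pairs with exactly one restricted
supertree edge, which in turn records the set of original supertree edges
collapsed into it.  The two root-child edges of the restricted supertree
form a single unrooted edge whose path is the union of both compositions.
A consequence worth stating: no unrooted gene tree can ever separate the
two root-child edges of the supertree, so only their *sum* is
identifiable; both are kept as parameters (preserving the 2*m*−2 count)
and recovery metrics compare the pair through its sum.

Genes whose MAST has fewer than `min_mast` leaves (default 10, with 20
and 30 as conservative tiers) are discarded; mapping needs at least 4.

## Optimization

*Coordinates.*  UPM is optimized in (ln *t*, ln *r*) with an analytic
gradient via L-BFGS-B: positivity is automatic, and when every mapped
path is a single edge the problem is exactly linear in these coordinates
(a unit test checks agreement with the closed-form linear least-squares
solution to 1e−8).  MC is optimized in (*t*, ln *r*) with SLSQP under the
linear equality constraints and bounds *t* ≥ floor (1e−8).

*Initial values.*  t₀ for each supertree edge is the mean observed length
over gene edges mapping uniquely to it; edges seen only inside composite
paths fall back to the global mean length.  Rates start at their
conditional optimum given t₀, exp(mean(ln *l* − ln path)) — on noise-free
single-rate data this start is already the exact solution.  The MC start
additionally projects t₀ to an exactly feasible ultrametric point by
bottom-up height maximization.  Optional random restarts perturb the
start lognormally (sd 0.3); restart seeds are recorded in the result.

*Gauge.*  The model is invariant under (**t**, **r**) → (c**t**, **r**/c).
After convergence the solution is rescaled so the geometric mean of the
rates is 1; rates are therefore relative rates, and one parameter per fit
is deducted from the information-criterion count for the gauge (it
cancels in Δ*d* = −(*m*−1)).

*Degenerate inputs.*  Zero or near-zero branch lengths (≤ 1e−9) have
zero likelihood under a lognormal error, so those rows are excluded and
counted in the result rather than floored, which would inject arbitrary
large residuals.  Supertree edges covered by no surviving row are
unidentifiable: they are reported, frozen at their start value in UPM,
and excluded from the parameter count.

*Convergence.*  Objective tolerance 1e−9, iteration cap 10,000 (1,000
for SLSQP, which uses dense quadratic subproblems); non-convergence is
flagged in the result, never silently accepted.  Because the MC feasible
set is nested in the UPM one, `fit_both` restarts the UPM optimizer from
the MC solution whenever it lands above it, enforcing
*E*²<sub>UPM</sub> ≤ *E*²<sub>MC</sub> by construction.

## Model comparison and the pacemaker-count bound

ΔAIC = 2Δ*d* + *n* ln(*E*²<sub>MC</sub>/*E*²<sub>UPM</sub>) and
ΔBIC = Δ*d* ln *n* + *n* ln(*E*²<sub>MC</sub>/*E*²<sub>UPM</sub>) follow
from the plug-in likelihood; the relative weight of the suboptimal model
is exp(−|ΔAIC|/2), reported with its exact base-10 exponent since the
weight itself underflows.  r.m.s.d. is √(*E*²/*n*) in ln units and its
exponential as a multiplicative factor.

The degenerate multiple-pacemaker (dMPM) analysis asks whether one
pacemaker per gene — which fits every edge exactly — could be taken
seriously.  It cannot fit better than the sampling noise of a Poisson
substitution process: with mean branch length *l̄* and protein length *P*,
a branch carries s = *l̄P* substitutions (rounded to the nearest whole
substitution, since s is a count; the rounding also matches how the
published chain was evaluated), the typical multiplicative error is
(s+√s)/s, and the floor is *n* ln((s+√s)/s)².  The AIC comparison
charges dMPM one edge-length vector per gene and no rates.  The maximum
pacemaker count is the largest c for which c tick vectors, each fitting
its genes perfectly down to the floor, still lose to a single pacemaker
on AIC: c ≤ (E + R + (n/2) ln(E²_UPM/floor))/E with E supertree edges and
R rates.  The floor is a best-case bound — real variation in gene length
and branch length only raises it.

## Per-gene diagnostics and bootstrap

*E*² decomposes exactly over genes, giving each gene a preference ratio
*E*²<sub>MC,k</sub>/*E*²<sub>UPM,k</sub> (dfit = log₁₀ ratio) and an
average goodness of fit afit = −(log₁₀ *E*²<sub>MC,k</sub> +
log₁₀ *E*²<sub>UPM,k</sub>)/2.  The default bootstrap resamples genes
with replacement and recombines these per-gene contributions by summation
— exact for fixed parameter estimates and the reading most consistent
with resampling a completed fit; a refitting mode (each replicate
re-estimated from scratch) is available behind a flag for the case where
parameter re-estimation itself is in question.  An ordinary least-squares
regression of ln ratio on afit, the MAST retention fraction mg and the
original leaf count (statsmodels OLS) quantifies what drives pacemaker
preference; those three covariates are the ones the analysis design
names, and gene-function annotations are out of scope of tree inputs.

## Synthetic forests

The generator emulates the statistical structure the estimator assumes,
with known ground truth.  Defaults describe the kind of forest the method
was built for: 100 taxa, 6,901 genes, leaf retention 0.2 (a typical
reduced tree keeps ~20 leaves), rate spread lognormal σ = 0.5 (fitted
relative rates then span roughly the order of magnitude seen in practice),
edge noise σ = 0.9 ln units (the overdispersion level real fits report),
supertree ticks lognormal σ = 1.0 (edge lengths spanning ~2 orders of
magnitude), and one subtree-prune-regraft (SPR) move per gene so the MAST
reduction is exercised.  MC supertrees are built ultrametric by
construction with total depth normalized to 1; MPM draws one independent
tick vector per pacemaker and assigns genes uniformly.  All randomness
descends from a single seed through counter-keyed generators
(`default_rng([seed, stream, index])`), so each gene is independently
reproducible.

What the generator does *not* emulate: substitution-level sampling error
(branch lengths are exact draws from the edge model, so the Poisson floor
of the dMPM analysis is absent), realistic horizontal-transfer patterns
(SPR moves are topology noise, not a transfer model), correlated rate
variation across branches, and alignment/inference artefacts.  Passing
recovery and power tests therefore validates the estimator and the
decision rule under the model's own assumptions, not robustness to ways
real forests violate them.

## Problem sizes used by the test suite

Simulation-backed tests run at 10–50 taxa and 10–200 genes: noise-free
recovery at 12 taxa × 40 genes; variance consistency at 50 taxa × 104
genes (~10⁴ edges, σ̂² within 10%); rate consistency at 50 taxa × 200
genes (ln-rate r² > 0.95 at σ = 0.2); model-selection power at 10 taxa ×
25 genes × 50 replicates per regime; MAST exactness against exhaustive
search on 200 instances of ≤ 9 leaves; bootstrap behaviour with 1,000
replicates.  These sizes make every property comfortably decidable while
keeping the full suite in the tens of seconds.

## Known limitations

- The supertree topology is taken as given; only its edge lengths are
  estimated.  Supertree *construction* is out of scope (candidates can
  only be ranked by total MAST leaves).
- MAST maximizes over O(m) rootings of each gene tree with an O(n²) DP
  per rooting — fine for ≤ 100 taxa, not tuned for thousands.
- SLSQP's dense subproblems make the MC fit the slow path for very large
  forests (thousands of genes); the UPM path scales much further.
- Co-optimal MASTs are resolved by convention; downstream *E*² can differ
  slightly between equally valid reductions.
- The dMPM bound treats gene assignment to pacemakers as free and its
  noise floor as attainable, so it is an upper bound on pacemaker count,
  not an estimate.
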