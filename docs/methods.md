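# Methods

This note documents the models implemented in `hetphylo`, the
assumptions behind them, the synthetic data the package ships, and the
numerical and design choices a user or reviewer would want stated
explicitly.  Nothing here reports an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Substitution models

Every model couples a symmetric exchangeability matrix `R` with a
composition structure.  The generator at composition π is

    Q_ij = R_ij π_j   (i ≠ j),   rows sum to zero,

scaled so that `−Σ_i π_i Q_ii = 1`.  Branch lengths therefore read as
expected substitutions per site *under that edge's own process*; in
branch-heterogeneous models each edge's generator is normalized at its
own composition, so lengths stay interpretable even though the joint
process is non-stationary.  (No published convention exists for
normalizing per-branch composition models; per-edge scaling is this
package's choice.)

Composition structures:

* **single** — one π; with symmetric `R` the model is reversible and
  the likelihood is invariant to root placement (tested).
* **mixture** — K fixed composition vectors with weights `w` summing
  to 1.  Site likelihoods are `Σ_k w_k Σ_g (1/G) L(site | π_k, r_g)`:
  the profile and gamma-category assignments are fully crossed, so
  "+G" means the same thing for every composition structure.  Only the
  weights are estimated (fixed-profile mixtures of the C-series/UDM
  type); profile estimation itself is out of scope.
* **branch map** — a composition vector per edge plus a root vector,
  drawn from a pool (NDCH: few shared vectors; NDCH2: one per edge).
  The tree is treated as rooted at the map's root and the likelihood
  is intentionally **not** invariant to rerooting (tested as an
  inequality).

Exchangeability presets: JC69 and GTR (DNA), a TIM2-style constrained
GTR (AC = AT, CG = GT), JC2 (binary, for RY-recoded data), Poisson
(uniform amino acid) and LG.  LG ships as a packaged text table of the
published exchangeabilities and frequencies; "LG" here always means
the exchangeabilities only — the composition slot remains whatever the
model specification says.

Compositions are floored at 1e-6 (exactly, by redistributing the
deficit over unfloored entries) before any generator is built.

**ASRV.** Discrete gamma with K equal-probability categories, each
represented by its conditional bin mean computed from the regularized
incomplete gamma function, renormalized to mean exactly 1.  The
default K = 4.  The simulator additionally offers continuous gamma
rates; the default is discrete so that simulation and inference use
the same discretization.

**Ambiguity.** Ambiguity codes (DNA R, Y, N, …; amino-acid B, Z, X)
are treated as missing data for composition counting and divergence
matrices, and as partial state sets in the likelihood (a leaf partial
is the indicator of the denoted states).  An all-missing column
contributes exactly zero log-likelihood.

## Likelihood engine

Felsenstein pruning over unique site patterns with per-component
log-scaling (rescaling applied every other level of the tree — enough
to keep double or single precision in range at the tree depths and
alphabet sizes involved, at half the cost of per-node rescaling).
"Components" are (composition, rate-category) pairs; all per-node
updates are batched over components.  Reversible generators are
eigendecomposed once (symmetrized via the π^{1/2} similarity
transform), so transition matrices and the one-dimensional per-edge
profile likelihoods used in optimization are closed-form in the
eigenvalues.

**Optimization** is block coordinate ascent: Brent on each branch
length (on the log scale, in an ×8 bracket around the current value,
re-centred every sweep), Brent on log α, EM on mixture weights (with
everything else fixed the component site likelihoods are constant, so
EM iterations are essentially free and monotone), and Nelder–Mead on
softmax-reparameterized compositions or GTR rates.  Branch sweeps hold
the directional (outside-subtree) partials fixed within a chunk of
edges and refresh them between chunks; a sweep that fails to improve
the exact likelihood is retried with geometric half-steps and rolled
back if still worse, so the returned lnL never decreases.

**Topology search.** `exhaustive` enumerates all unrooted topologies
(≤ 8 taxa).  `nni` hill-climbs from a neighbor-joining start: all NNI
neighbors are screened cheaply at current branch lengths, the best few
are refined by branch-length re-optimization, and the first refined
improvement is accepted.  `hillclimb` adds a restricted
subtree-prune-regraft stage that rescans every attachment point of
each long-branch subtree (pendant edge ≥ 0.5 by default).  This is the
move a misplaced long stem needs: the likelihood surface between "stem
inside the ingroup" and "stem with the outgroup" has a valley that
single NNI steps cannot cross.  For large alignments the climb runs
coarse-to-fine: the full pipeline on a fixed random 600-column
subsample, then branch-length polish, one SPR re-scan and a parameter
re-tune against all sites.  Screening subsamples and refinement
budgets affect only search effort, never the reported likelihoods,
which are always computed on the full data.

## Distances

With `F̂` the joint state-pair frequency matrix of a taxon pair and
`f`, `g` its marginals:

* paralinear: `d = −(1/c) [ln det F̂ − ½(Σ ln f_x + Σ ln g_y)]`
  (zero for identical sequences of any composition; the default);
* logdet: `d = −(1/c) ln det F̂ − ln c` (the uniform-composition
  variant, kept for cross-checks);
* `jc`: the stationary c-state correction, provided as the
  "homogeneous-model distance" contrast.

Non-positive determinants and empty or zero-marginal pairs yield
flagged-invalid entries with a reason; neighbor joining refuses to run
on a matrix with invalid entries rather than imputing.  Negative NJ
branch lengths are clamped to zero with the deficit moved to the
sibling edge, preserving the joined path length.  Constant-site
removal before distance computation removes `⌊p · #constant⌋` columns
allocated across constant-state classes by largest-remainder rounding
(ties toward the larger quota, then alphabet order; lowest-index
columns within a class) — deterministic under gaps, with a constant
column defined as "all non-missing characters identical, at least one
non-missing".

## Diagnostics

The composition χ² is the standard taxa × states contingency statistic
with expectations from the pooled composition; zero-count states are
dropped with the dof adjusted.  Its asymptotic p-value is reported but
flagged approximate, because alignment columns are correlated through
the tree.  Wherever a fitted (tree, model) is available the package
instead calibrates by parametric bootstrap: simulate under the fitted
pair, recompute the statistic, report the upper-tail fraction (the
tree-and-model composition fit test, and its per-taxon version).  The
null replicates are drawn as one long simulation split into blocks —
sites are independent under every supported model, so this is
statistically identical to separate simulator calls and an order of
magnitude cheaper.  Null-calibrated p-values use at least 100
simulations by contract.

Stuart's marginal-symmetry statistic is `u'V⁻¹u` with `u` the first
c−1 marginal differences and `V` the marginal-homogeneity covariance;
a singular `V` (some states never change) raises an error suggesting
state pooling rather than silently pseudo-inverting.  Note the test
requires every retained state to show some change in the pair — on
sparse recoded data, pool first.

Site rates are posterior-mean category rates,
`Σ_g r_g P(g | site)`, marginalized over mixture components; they feed
fast-site removal (`remove_fastest_n`), which replaces
agreement-score-based site sorting by generic rate ranking.

## Bayesian machinery

Metropolis–Hastings with moves: branch-length multiplier, NNI, α
multiplier, Dirichlet composition proposals (concentration 300 around
the current vector; proposals below the 1e-6 floor are rejected),
NDCH edge-reassignment, and an NDCH2 concentration multiplier.
Priors: branch lengths Exp(10), free compositions flat Dirichlet, α ~
Exp(1), NDCH assignments uniform over the pool, NDCH2 edge
compositions i.i.d. Dirichlet(γ·π̄) with flat-Dirichlet global mean π̄
and log-uniform concentration γ on [1, 1e4].  This hierarchical form
is the minimal faithful reading of "every branch has its own vector,
constrained by a hyperparameter".  All prior densities are normalized,
so stepping-stone estimates are proper marginal likelihoods (the
uniform topology prior is a constant that cancels between models on
the same taxa, and is omitted).

Burn-in is a fixed 25% of iterations; thinning by the sampling
interval; convergence is surfaced by split-frequency agreement between
independent seeds, not auto-stopping.  Prior-only runs
(`likelihood_weight = 0`) are used to validate the sampler against the
analytic prior moments.  The stepping-stone schedule is
`β_k = (k/n)^{1/0.3}` (Beta(0.3, 1) quantile spacing); each power
posterior is sampled with a warm start from the previous stone, and
the estimator sums `ln mean exp[(β_{k+1}−β_k) lnL]` with a max shift.
Stones with effective sample size below 10 raise a warning flag in the
result.  Posterior-predictive simulation reuses the package's own
simulator, so the null is generated by exactly the assumed model.

The NDCH vector-to-branch assignment can be sampled (default) or held
fixed, covering both the fixed-arrangement and free-arrangement styles
of analysis.

## Synthetic data and fixtures

The simulator draws, per site, a profile (for mixtures) and a rate,
samples the root state from the applicable composition, and evolves
states down the tree edge by edge; per-site metadata (profile index,
rate, category) is returned, and a JSON manifest allows exact replay.

**Profile bank.** The packaged composition bank
(`hogenom_like_bank`, 64 amino-acid profiles) is a synthetic stand-in
for database-derived site-composition collections.  It is drawn
hierarchically — 16 sparse Dirichlet(0.2) cluster centers, each with
4 members from a concentrated Dirichlet(60·center) around it — because
real site-composition collections are strongly clustered (that
clustering is exactly why moderate numbers of mixture components
describe them well).  Inference mixtures of size k use k-means
centroids of the bank, mirroring how fixed profile sets are distilled
from larger collections.  The bank seed is fixed; the bank is a
packaged constant.

**Fixture trees.** `two_domain_like` places a 1.8-substitution stem
carrying a two-leaf clade inside a deep, short-branched 7-taxon clade
(internal edges 0.12, attachment edge 0.05), with a three-leaf
outgroup clade at the end of a 2.2-substitution branch.  The depth of
the ingroup matters: reattaching the stem at the base shortens its
path to the outgroup by ~0.5 substitutions, which is what makes the
stem attractable under misspecified models while leaving the true
position identifiable under richer ones.  `three_domain_like` joins
the two long branches.  `thermus_like` is a six-taxon topology with
lengths in [0.05, 0.5].  All lengths are packaged constants (stable
regimes, not per-run draws).  These are declared stand-ins: the
empirical trees whose regime they emulate are not public, and the
experiment functions accept user-supplied newick trees for exact
replication by those who obtain them.

**Case studies.**  `composition_attraction`: five DNA taxa on
`((A,B),(C,D),E)` with 1.0-substitution branches to the non-sister
taxa A and C, which evolve toward GC 0.55 while every other branch and
the root keep GC 0.75; gamma shape 2.0.  The rate heterogeneity is
deliberately moderate: strong enough that the constant-site correction
matters, weak enough that the attraction is driven by the convergent
composition (which paralinear corrects) rather than by rate-driven
distance compression (which it cannot).  `branch_heterogeneous`: six
taxa on the `thermus_like` tree with a second composition vector
(GC 0.45 vs 0.70) on the branches leading to the three "mesophile"
tips; gamma shape 0.935 — stationarity-violating data for the
adequacy-test demonstrations.

What the synthetic data do **not** emulate: indels and alignment
error, among-gene heterogeneity, heterotachy/covarion dynamics,
selection, and the empirical branch-length distributions of real
taxon samples.  Passing tests therefore demonstrate that the methods
behave as designed under controlled compositional and rate
heterogeneity, not that any particular empirical controversy is
settled.

## The experiments

**Tree recovery** (the two-domain/three-domain analog): alignments are
simulated on the fixture trees under the full 64-profile bank with
four-category gamma at shape 0.935, at the package's desk scale —
12 taxa, 2,000 columns, 10 replicates — and re-analysed with
Poisson-exchangeability models of increasing richness: single
composition without ASRV, and 1/4/16-profile mixtures with gamma.
(The full-scale protocol of the study this emulates used 7,000 columns
and up to 256 profiles; it is one configuration change away.)  The
non-ASRV mixture cells are omitted from the default grid — the
single-composition no-ASRV cell already demonstrates the no-ASRV
failure mode, and the profile-count axis is read within the +G series.
Searches use the `hillclimb` strategy from a stationary-distance NJ
start, single precision, with per-cell seeds derived by counter from
the master seed (byte-identical tables given the same seed; per-cell
failures are recorded in-table and the run continues).

The recovery readout is topology-class compatibility, matching how
such experiments are read: the stem is "recovered" when the outgroup
remains a clan, the stem has not joined it, and the stem sits inside
the ingroup (so the ingroup minus the stem is *not* a clan).  Exact
attachment among the short neighboring edges is additionally visible
in the reported RF and branch-score distances but is deliberately not
the recovery criterion: with a ≥ 1.5-substitution stem the
edge-by-edge placement margin is a handful of log units and would make
the readout noise-dominated.

**Case study** (`run_case_study`): on the compositional-attraction
data, stage (a) fits stationary-model ML trees with bootstrap on the
full and reduced taxon sets, (b) re-analyses under RY recoding,
(c) sweeps paralinear-NJ over constant-removal proportions (the
proportion is a required parameter of the sweep — no canonical value
exists), (d) compares homogeneous vs branch-heterogeneous fits on the
fixed generating tree with the composition fit test, and (e) runs the
Bayesian adequacy battery (posterior predictive + stepping stone)
under homogeneous and NDCH2 models.

## Numerical choices and degenerate inputs

* Pattern compression by unique columns; all likelihoods exact to the
  stated tolerances regardless of compression.
* Engine precision is selectable; float64 is the default, float32 is
  used inside the recovery experiment's searches (differences of
  ~1e-4 lnL at the sizes involved; all published comparisons in the
  tests use float64).
* Branch lengths live in [1e-9, 20]; optimizer non-convergence sets a
  flag on the result instead of raising.
* Ties: fastest-site removal breaks rate ties toward lower column
  indices; NJ breaks Q-criterion ties toward the lexicographically
  lowest pair; exhaustive search keeps the first-found optimum.
* Degenerate inputs raise typed errors (`UsageError`, `FormatError`,
  `CharacterError` naming taxon/column/character, `ModelError`), never
  silent coercions.

## Known limitations

* Dirichlet-process mixtures (CAT-style), breakpoint composition
  models, heterotachy/covarion models, and topology tests (AU/KH/SH)
  are out of scope.
* The exhaustive search is capped at 8 taxa; NNI/hillclimb are greedy
  heuristics with restart and SPR mitigation, not global optimizers.
* Stuart's test requires a non-singular covariance; sparse data need
  state pooling first.
* MCMC convergence is the user's responsibility (two-seed split
  agreement is provided as the check); no adaptive proposals.
* The acceptance-scale experiments are desk-scale by design; their
  conclusions are qualitative reproductions of the full-scale
  phenomena, not replications of any empirical dataset.
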