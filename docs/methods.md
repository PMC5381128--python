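# Methods

This note records the models, conventions and numerical choices behind
`fossilclock`, in the order data flows through the package.

## Time-trees

Trees store node ages in Ma before present; branch durations are derived as
`parent.age − child.age`. Storing ages (not branch lengths) keeps fossil
tips exact when attachments move during MCMC. Extant tips sit at age 0
(tolerance 1e−9), fossil tips at positive ages, and sampled ancestors are
degree-2 internal nodes carrying the fossil label; the Newick writer emits
them as zero-length tips for portability with other toolchains. Parsing
(Newick, NEXUS with translate tables) is delegated to dendropy with branch
lengths read as durations and ages assigned so the deepest tip sits at the
present. Taxon matching is exact and case-sensitive; underscores are
preserved at file boundaries.

## Calibration construction

A log-normal calibration with offset *o*, log-s.d. σ and 95th percentile
*q95* has log-scale location `m = ln(q95 − o) − z₀.₉₅ σ` with
z₀.₉₅ = 1.6448536269514722. The NDb margin rule is evaluated continuously,
`margin(a) = 5 · 1.1^(a/5)`: anchoring the 5-Ma age classes at class 0
(margin 5 at a = 0) reproduces the printed 28 Ma margin at a = 90 after
rounding (27.80); anchoring at the youngest fossil's age instead gives 25.3
and was rejected. Off-grid ages use the same smooth expression, which is
monotone and agrees on the grid. The NDn log-s.d. defaults to 1.0 and is
exposed as an argument, since the narrow-density family fixes only the
offset and 95th percentile. σ scaling for NDb interpolates between the
youngest and oldest usable fossil of the *active* set rather than
hard-coding the anchors. Node dating keeps one fossil per clade (the
maximum minimum age); exact age ties are broken lexicographically by fossil
name with a warning, so the selection is deterministic and idempotent.
FBD age ranges follow the same margin rule, truncated by an explicit
root-age ceiling (`cap`) where the raw rule would produce implausibly wide
ranges for the oldest stem fossils.

## Tree priors

Both tree priors use one convention: the process starts from a single
lineage at an origin time carrying an improper uniform prior, and the
density is conditioned on the number of extant samples *n*. Conditioning on
"at least one extant sample" is not integrable against an improper origin
prior for supercritical processes, which is why the exactly-*n* convention
was adopted; because fossil sampling never alters the forward dynamics of
the lineage process, the conditioning constant depends only on (λ, μ, ρ,
n) and is shared by the birth–death and FBD densities — the ψ → 0, no-fossil
degeneracy is therefore exact (the test suite asserts ≤ 1e−8 over random
trees, through two independently coded parameterizations). The conditioning
constant `∫ P(n | origin) d origin` uses the geometric law
`P(n|t) = p₁(t) η(t)^{n−1}` with `η = 1 − p₁/(1 − p₀)` and is evaluated by
adaptive quadrature, cached per parameter vector. For a 2-tip tree the
birth–death density integrates to 1 over the root age, which the tests
verify by numeric quadrature.

Fossil tips at age *y* contribute `ψ p₀(y)/q(y)`, sampled ancestors ψ, and
bifurcations `λ q(x)`, in the standard FBD notation (`c₁ = √((λ−μ−ψ)² +
4λψ)`, `c₂ = −(λ−μ−2λρ−ψ)/c₁`). The density is not conditioned on sampled
descendants on both sides of the root ("root sampling"), so a fossil may
attach above the extant root. A fossil tip whose attachment age approaches
its own age approaches the finite limit `λ ψ p₀(y) ·(rest)`; the
sampled-ancestor state is a lower-dimensional configuration with its own ψ
factor, handled by a reversible-jump toggle move with the uniform
attachment-age proposal supplying the dimension matching.

The critical case λ = μ is rejected at construction; the package targets
supercritical settings.

## Relaxed clock and likelihood

The UCLN clock gives every branch an independent log-normal rate multiplier
with real-scale mean 1 (log-scale location −σ²/2); loci share one clock
unless explicitly split (the default analysis configuration mirrors a
two-clock design in which one fast-evolving locus gets its own clock).
Likelihoods use Felsenstein pruning with per-node rescaling; JC, HKY and
GTR are implemented through the reversible-matrix symmetrization
eigendecomposition, optionally with discrete-gamma rate categories
(category rates are quantile-band means, normalized to mean 1). Gaps and N
are fully ambiguous states. Tree tips without sequences (fossils) carry
all-ones partials; equivalently, the engine computes the likelihood on the
extant backbone, which is exact because attachment points split branches
without changing rate-weighted path lengths under a shared multiplier.

## MCMC engine

One Metropolis–Hastings chain, one proposal per generation, all randomness
from a single seeded generator (same configuration + seed ⇒ bit-identical
trace and tree logs). The extant backbone topology is fixed to the starting
tree; the proposal set is: node-age slide (uniform in the feasible
interval), root-age and whole-tree scale moves, UCLN multiplier log-walks,
clock-rate / clock-s.d. / tree-parameter scale moves, fossil reattachment
(uniform over the feasible branch-length measure of the assigned clade),
fossil-age redraws (range mode) and the sampled-ancestor toggle.
Calibration floors are enforced through the prior (−∞ outside support), so
no sampled calibrated age can cross its floor; infeasible starting states
raise an error, and `calibrated_start_tree` builds a feasible start by
iteratively moving calibrated nodes to their density medians. Tree-prior
hyperpriors (used only when a parameter is listed as sampled) default to
log-normal(−1, 1) on λ, flat Beta(1, 1) on the turnover μ/λ, Exp(1) on ψ,
log-normal(ln 10⁻³, 1.5) on clock rates and Exp(mean 1/3) on the UCLN s.d.;
ρ is always fixed. Attachments above the root require an explicit finite
`stem_cap` so the uniform reattachment proposal has finite measure.

## Summaries

Resampling keeps states at generations {k·f} (N/f + 1 states including
generation 0) and discards the first ⌊b·N/f⌋ — the convention that yields
1401 retained trees for 2×10⁸ generations at frequency 10⁵ with 30%
burn-in. Multiple runs are concatenated after per-run burn-in. ESS uses
Geyer's initial-positive-sequence estimator; constant traces are reported
as ESS = n with a zero-variance flag. The MCC tree maximizes the product of
clade posterior frequencies computed on extant bipartitions after fossil
pruning (fossil placements are draws from the placement prior, not
topological signal) and uses common-ancestor heights: each node's age is
the *mean* over all input trees of the MRCA age of that node's tip set,
with 95% HPD annotations (shortest interval containing ⌈0.95 n⌉ sorted
values, exhaustive over windows).

## Cross-method statistics

Ages are log-transformed (natural log; the base cancels in the z-score) and
standardized per clade over all trees and analyses pooled. Effect sizes come
from a conjugate Gibbs sampler for the random-intercept model
`z = α_analysis + u_tree + ε` with inverse-gamma(10⁻³, 10⁻³) priors on both
variances and a flat prior on the α's (3000 iterations, 500 burn-in,
seeded); a method-of-moments fallback (cluster means with a cluster-robust
normal interval) is provided for speed and is cross-checked against the
Gibbs estimates and against statsmodels' MixedLM in the tests. Effects are
reported as per-analysis means, not contrasts against a baseline. The
Wilcoxon signed-rank test is two-sided, drops zero differences, and is
exact up to 25 non-zero pairs (normal approximation with continuity
correction above), delegated to scipy and verified against full 2ⁿ
enumeration. Prior-sensitivity reports compare specified densities,
effective-prior samples and posterior samples per calibration node; the
1:1-line deviation is the absolute difference of posterior and
effective-prior medians. Leave-one-fossil-out reruns the full analysis per
excluded fossil under a fixed seed, so exclusions that do not change the
analysis specification (a younger duplicate under the oldest-per-clade
rule) give exactly zero deltas; exclusions that empty a calibration set are
recorded as not applicable.

## Synthetic data

Two simulators target the same conditioned process as the tree priors. The
forward simulator runs the birth–death process from a uniformly drawn
origin, ρ-thins the tips and rejects until exactly n are sampled; standing
populations beyond a cap derived from the lineage non-sampling probability
(chosen so the discarded realizations carry < ~10⁻¹⁵ of the acceptance
mass) are aborted early, and the origin window is cut where the per-node
age distribution retains < 10⁻⁶ mass. The direct constructor proposes node
ages iid from the normalized per-lineage density q by closed-form inverse
CDF and accepts with probability Q(max age)/Q(0) — an exact rejection step
for the origin-branch weight — then builds a uniform ranked topology; the
two routes agree in distribution (two-sample KS in the tests) and the
forward route doubles as the independent oracle for the MCMC prior-only
tests. Fossils are Poisson(ψ·duration) events on every branch of the
complete tree including extinct lineages; records report a minimum age
drawn as the true age minus a uniform reporting error (up to 10%,
truncated at zero), the smallest named clade containing the lineage's
sampled descendants, and a stem-branch or within-clade placement mode, with
the true attachment retained for recovery tests. Sequences evolve
site-independently with per-branch transition matrices.

`make_pine_fixture` packages two study bundles. The small scale (15 extant
taxa, 5 fossils of which 3 in the small set, two loci, 800 bp, 5% random
missing data) is the default test vehicle. The paper-shaped scale emulates
the structure of a chloroplast supermatrix study of a conifer genus: 115
extant taxa, 8 concatenated loci totalling 5.9 kb, a per-taxon locus
dropout profile (85 complete taxa, a tail missing 1–7 of 8 loci), and 21
fossils of which 14 form the small set; three records are unusable for node
dating (a stem fossil of the whole in-group plus two without defensible
node assignments) and three are younger duplicates, so node dating retains
12 (small) and 15 (large) calibrations. Fossil ages are set as fixed
fractions of their clade's stem or crown age on the simulated tree, so
every record is feasible by construction while the age span tracks the
tree's depth. Analysis cells fix λ, μ, ρ (and ψ) at the generator's values
and fix clock mean rates at the truth — a calibrated-rate regime chosen so
short chains are informative about ages rather than about rate–time
confounding; all of these can be sampled instead by listing them in
`sample_params`.

What the bundles do *not* emulate: alignment error and indels, model
misspecification (sequences are simulated under the analysis model),
topological uncertainty (the backbone is fixed to the truth), and
morphological data for fossils. Passing tests therefore demonstrate
correctness of the inference machinery under its own assumptions, not
robustness to the violations real data bring.

## Problem sizes and defaults

Default desk-scale runs use 10³–10⁵ generation chains on 12–20 taxon trees
with 0.8–2 kb alignments, sizes chosen so a full analysis matrix runs in
minutes on one CPU while leaving the chain clearly converged relative to
its ESS. The production-scale conventions (10⁸-generation chains, 10⁵
resampling frequency) appear in the subsampling arithmetic and its tests
only; reproducing a full-genus chronology requires the real alignment and
cluster-scale chains and is out of scope for the bundled studies.

## Repository shape

The package is a library: the importable API plus `examples/` scripts are
the interface, and analysis configurations are plain objects/JSON rather
than a shell CLI — the run/simulate entry points the pipeline needs are the
documented functions (`run_analysis_cell`, `make_pine_fixture`,
`StudyBundle.write`).

## Known limitations

* λ = μ (critical) processes are unsupported; heavily subcritical settings
  are untested.
* The FBD conditioning constant treats only the extant sample count;
  analyses that sample λ, μ with informative fossil counts inherit a
  (documented) unconditioned-fossil convention.
* Fixed backbone topology: NNI-style topology moves are not enabled in the
  analysis cells, so topological uncertainty is not propagated.
* The Gibbs mixed model assumes homoscedastic residuals across analyses.
* `subsample_log` requires the log stride to divide the resampling
  frequency; it does not interpolate.
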