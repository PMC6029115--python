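# Methods

## The problem

Relaxed molecular clocks date a phylogeny by combining sequence data, which
constrain only the product rate x time on each branch, with fossil
calibrations, which anchor absolute time at particular nodes.  When several
calibrated clades undergo *parallel* rate decelerations — as large-bodied,
long-lived mammals such as whales and seacows do — an independent-rates
clock cannot tell "slow branch" from "short branch".  Calibrations pin those
clades at their true ages, so the unexplained slowdown is absorbed by the
rate model and re-expressed *stemwards*: rate estimates for neighbouring
branches drop, and the deep, weakly calibrated divergences inflate.  This
package implements the whole demonstration pipeline — synthetic data,
dating engine, factorial experiment — plus the two companion statistics
(fossil diversification rate, GC3 longevity index) used to cross-check
divergence estimates against the fossil record.

## The simulation tree

`build_simulation_tree` constructs the fixed 12-taxon tree: a placental-like
ingroup whose crown originates at 80 Ma, splits into two superorders at
66 Ma (tags V, VI), each splitting into two 2-tip clades at 33 Ma (tags
I–IV); plus a marsupial-like pair (crown 60 Ma) and a monotreme-like pair
(crown 50 Ma) as outgroups, root at 200 Ma.  The marsupial–placental split
(160 Ma) and the outgroup crown ages are not identified by the in-text ages
and are configurable; the defaults are round numbers near accepted values
for those splits.  All ages live in Ma; the dating engine converts to
100-Ma units internally.

## Rate schemes and sequence simulation

Branch rates are iid lognormal with log-location −6.523 and log-s.d. 0.274
(log substitutions/site/Ma), i.e. a median rate of 0.1469 substitutions per
site per 100 Ma.  The location parameter is interpreted so that
100·exp(−6.523) reproduces the printed 0.1469 exactly.  The "mixed" scheme
divides the drawn rate by 5 on the four daughter branches of nodes I and
III.  Sequences evolve site-independently down the tree from model
equilibrium with per-branch expected substitutions = rate x duration;
JC69 is the default for both simulation and inference (the experiment's
logic lives in rates and times, not model richness; HKY85 is available by
configuration).  Alignments default to 20,000 bp and carry site-pattern
compression.

## The dating model

Independent-rates relaxed clock: branch rates iid lognormal with arithmetic
mean mu and log-scale variance sigma2, i.e. log r ~ N(log mu − sigma2/2,
sigma2).  Hyperpriors are gamma in (shape, inverse-scale) form: mu ~
gamma(1, 6.81) for ancestral-rates analyses (prior mean = 1/6.81 = 0.1469
per 100 Ma), gamma(1, 7.51) for mixed-rates analyses (the time-weighted
mean rate of the mixed tree), gamma(1, 5.41) as the empirical default;
sigma2 ~ gamma(1, 2.0) for the simulation experiments (shape 1 is assumed
where only the scale is fixed by the protocol), gamma(1, 4.207) as the
empirical default.

Calibrated nodes carry soft uniform bounds: mass 1 − 2·tail uniform on
[min, max], a power-decay left tail and an exponential right tail each
holding `tail` (default 2.5%) and continuous at the bounds; the density is
proper on (0, ∞).  Uncalibrated node ages take a flat (uniform
order-statistic) density subject to the tree ordering, bounded above by the
calibrated root.  This construction is *unnormalized across calibrated-node
configurations*, so — exactly as in mainstream soft-bound dating software —
the joint prior marginals of nodes adjacent to free nodes are tilted
relative to their specified calibrations (the root's prior-only marginal
sits ~4 Ma above its 200 Ma midpoint on the experiment tree).  Prior-only
runs (`run_mcmc` with no data) are the supported way to inspect these joint
marginals.  A birth–death kernel was deliberately not used: its parameters
are nowhere fixed by the protocol, and the flat kernel is neutral, proper
and testable.

The likelihood is the exact pruning (Felsenstein) likelihood over
compressed site patterns — no Hessian/normal approximation.  Compression is
hierarchical: each internal node stores conditional likelihoods only for
the distinct site patterns restricted to its own subtree, with precomputed
index maps into its children's tables, so proposals touching one branch
recompute partials only along the path to the root.

## The sampler

Metropolis-within-Gibbs sweeps (one "generation" = one sweep):

* sliding-window moves on each internal-node age, reflected at the ordering
  bounds (likelihood recomputed along the path to the root);
* multiplicative moves on each branch rate (each branch proposed on
  alternating sweeps);
* *compensated* age moves: shift a node age and rescale the three adjacent
  branch rates to keep rate x duration fixed — likelihood-free, with the
  exact Jacobian; one tuned narrow version and one untuned wide version
  (window = half the local age bracket) per node per sweep.  These traverse
  the weakly identified directions (deep uncalibrated ages) quickly;
* multiplicative moves on mu and sigma2 (sigma2 floored at 1e-8);
* a global rescale move (ages x c, rates and mu / c) that leaves the
  likelihood exactly invariant and carries the c^(n_ages − n_rates − 1)
  Jacobian.

Step sizes adapt toward 30% acceptance during burn-in only.  Chains start
from calibration-midpoint ages with topological interpolation for free
nodes (the prior's centre), which removes directional burn-in bias on deep
nodes.  Per-node ESS (via `arviz`) and between-chain mean-age gaps are
reported as convergence warnings, never silently acted on; replicates enter
experiment aggregates unless they fail outright, with failures and warnings
recorded in the result object.

Default chain settings follow the study protocol: 200,000 generations,
sampled every 50th, 10,000 burn-in (3,800 retained draws per chain), two
chains.  The "desk" profile used by the test suite and the acceptance
script runs 10 replicates with single 6,000-sweep chains (1,500 burn-in,
thinned by 5) on 20-kb alignments — sized so one scheme-combination cell
runs in a few minutes while matched 15,000-sweep chains reproduce the same
aggregates to well within replicate scatter (equilibration was checked on
matched seeds).

## The factorial experiment

`run_replicates` crosses rate scheme (ancestral | mixed) with calibration
scheme (full: I–VI + root | ancestral-only: II, IV, V, VI + root), drawing
fresh rates and alignments per replicate from seeds derived
deterministically from a master seed.  Calibrations are symmetric soft
bounds equidistant from the true simulated age.  The half-width is the one
genuinely open quantity (it is shown only graphically in the source
figure); the package uses ±10% of the true age for every calibrated node —
the same relative width as the stated 180–220 Ma root bound (so the root
rule and the node rule coincide), and the only width rule we found that
reproduces all three qualitative regimes at once: accurate recovery under
ancestral rates, collapse of uncalibrated low-rate clades to ~8–9 Ma, and
recovery of deep nodes under ancestral-only calibration.  Aggregates are
unweighted means of per-replicate posterior means; CIs are reported per
replicate.  `inflation_report` tabulates bias, CI coverage and the
fractions of replicates whose 95% CI lies fully older/younger than truth.

### What the desk-scale experiment shows (and what it does not)

At desk scale with the ±10% rule the pipeline reproduces, with 10
replicates: the ancestral-rates control (every node's truth inside its 95%
CI in 100% of replicates), the collapse of uncalibrated low-rate clades
(I/III average ≈ 8.8 Ma against the reported ≈ 8.5), the recovery of
superorders under ancestral-only calibration (≈ 66.0), and systematic
upward inflation of the deep nodes under full calibration.  The *magnitude*
of the full-calibration inflation is smaller than reported: superorders
≈ 66.8 Ma versus 80.5, crown ≈ 94.2 versus 107.9.  Profiling shows the
conditional posterior along the compensated direction is nearly flat over
66–84 Ma for a superorder node, so its marginal is controlled by the time
prior's volume terms; with the flat order-statistic kernel the marginal
equilibrates lower than the published MCMCtree values, and widening the
calibration bounds does not close the gap (the posterior is not
bound-limited) while it does break the control and recovery regimes.  We
attribute the residual difference to the unpublished details of the
birth–death time prior used by the original software, and report the
shortfall rather than re-weighting any prior to chase it.

## Fossil diversification statistic

Stages (user-supplied CSV; a synthetic toy table ships for tests and
examples) are merged oldest-first into bins sampling ≥ 80 mammal species,
with named critical stages kept as their own bins; species counts of merged
stages are summed, which treats per-stage richness lists as disjoint — an
approximation the per-bin stage list makes auditable.  The rate is new
eutherian appearances / (bin duration x eutherian standing richness of the
previous bin); the eutherian proportion of new mammal appearances is
averaged over named bin groups as the unweighted mean of per-bin
proportions (the pooled-count alternative is emitted alongside).
Degenerate denominators are flagged NaNs, never silent zeros.

## GC3 longevity index

gamma = −t / ln(tau) with natural log (the published slope/intercept
reproduce sensible longevity magnitudes with ln; the base is
configurable), and maximum longevity = 0.0683·gamma − 10.243 years applied
as given (R² = 0.91 stored as provenance).  `recalibrate` replaces
divergence times at fixed tau, exploiting gamma's linearity in t.

## Numerical choices and limitations

* Transition probabilities come from the symmetrized eigendecomposition of
  the generator; probabilities are clipped at 0 and renormalized only in
  the non-kernel path.
* Partial likelihoods are unscaled doubles — safe for the tree depths and
  branch lengths used here (the worst site likelihood is far above
  underflow); very large trees would need per-node scaling.
* The rescale and compensated moves leave branch lengths fixed up to
  floating rounding (~1e-16 relative); cached P matrices are refreshed the
  next time a likelihood move touches the branch.
* The synthetic-data generator emulates iid lognormal branch rates, no
  among-site rate variation, no indels, a single locus and a correct, fixed
  topology.  Passing tests therefore demonstrate the error-shift mechanism
  under clean conditions; they say nothing about alignment error, model
  misspecification, or topology uncertainty in real data.
* Empirical reanalyses (multi-locus mammal alignments, genome-scale
  datasets, published GC3 coefficient tables) are accepted through the
  standard interfaces (FASTA/PHYLIP + calibrated newick + CSV) but are not
  reproduced at desk scale.
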