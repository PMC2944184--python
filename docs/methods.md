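# Methods

This note records the models implemented in `divtempo`, the conventions and
numerical choices behind them, and what the synthetic-data generator does
and does not emulate.  It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Chronograms and branching times

A chronogram is a rooted tree with branch lengths in time units, validated
ultrametric to a relative tolerance of 1e-6 against the root age (input
trees routinely carry rounding noise from external dating programs).  Ages
are measured backward from the present (tips at 0).  All diversification
math consumes only the vector of internal-node ages t₁ ≥ t₂ ≥ … ≥ t₍ₙ₋₁₎
and the derived internode durations g_k = t₍ₖ₋₁₎ − t_k (with t_n := 0),
the time during which exactly k reconstructed lineages exist.

**Polytomies** are accepted on input and read as bifurcations separated by
zero-length edges: a node with c children contributes c−1 copies of its age
to the branching-time vector.  Zero-length intervals are legitimate limits
of every statistic here (γ included), so they are kept as-is.  Equal ages
are ordered by a stable preorder index, making truncation and sorting
deterministic; rows where this tie-break mattered are flagged.

**Calibration** is linear rescaling only: all ages are multiplied by
(target age)/(current MRCA age).  γ and every other scale-invariant
statistic are unchanged by it (tested to 1e-9).  Rate smoothing and
cross-validated dating are out of scope; trees are expected to arrive
already ultrametric.

## The gamma statistic and the CR test

γ is computed exactly as standardized in the package docstring (README
shows the formula).  Under complete-sampling pure birth with the
final-interval convention below, the partial-sum ratios S_i/T are jointly
distributed as uniform order statistics, so γ has mean 0 and variance 1
*exactly* and is asymptotically normal; at n = 90 the true 5% quantile is
within ~0.01 of the normal value (the acceptance script measures this by
simulation).  The CR test is one-tailed, lower only: early-burst history
makes γ negative, and that is the direction of scientific interest.
Positive γ is reported, never "rejected".  Rejection uses the strict
inequality γ < z_α.

## The simulator

`simulate_yule` grows a tree forward conditioned on n tips: with i
lineages the wait to the next event is Exp(i·λ) and a uniformly chosen
lineage splits (giving the Yule topology distribution without a separate
topology sampler).  **Final-interval convention:** after the n-th lineage
appears, the time separating the last branching from the present is drawn
as the Exp(n·λ) waiting time to the unobserved next event.  This is the
construction under which γ of complete trees is exactly mean-0/variance-1,
i.e. under which the analytic CR test and the simulated null coincide;
cutting the simulation at the n-th birth instead would force g_n = 0 and
bias γ.  λ defaults to 1: γ is scale-invariant, so the rate choice cannot
affect any γ-based null (tested by a KS comparison across rates).

`simulate_birth_death` runs the same forward process with per-lineage rates
(λ, μ), retrying from scratch on extinction until the standing count first
reaches n; the present is then placed one Exp(n·(λ+μ)) waiting time later,
mirroring the pure-birth convention (at μ = 0 the two simulators are
byte-identical).  The reconstructed tree of the n survivors is returned.
This first-passage-plus-retry conditioning is simpler than bridge-style
samplers and adequate at the package's scale (μ/λ < 1 enforced); it is a
convention, and is documented here because conditioning choices shift
birth–death branching-time distributions in the tails.

`sample_incomplete` retains a uniformly random tip subset — the missing-
at-random assumption that underlies the MCCR correction.  Batch null
generation uses a flat-array representation of the same process (an
internal node survives pruning iff both child subtrees retain a kept tip);
the array route and the tree route are tested to agree exactly on shared
draws.

`simulate_mk1_states` evolves the binary character root-to-tip with flip
probability (1 − e^(−2qt))/2 per branch.

What the generator does *not* emulate: non-uniform (clade-biased) species
sampling, diversity-dependence in the generating process, extinction-rate
variation through time, phylogenetic error and calibration uncertainty.
Passing tests therefore validate the statistical machinery under its own
assumptions, not the robustness of those assumptions to real data.

## MCCR testing

The null for n_sampled of n_total species is built by simulating complete
pure-birth trees of n_total tips, pruning each to n_sampled, and computing
γ.  The critical value is the ⌈α·reps⌉-th smallest null value — an exact
order statistic rather than an interpolating quantile, so results are
bit-reproducible given the seed.  The p-value uses the permutation-style
estimator (1 + #{null ≤ γ_obs})/(reps + 1), which cannot be exactly zero.
The richness sweep runs one such test per assumed n_total (default 90–122
inclusive), each row on an independent child stream spawned from the master
seed so rows are independent yet reproducible, and adding rows never
perturbs existing ones.

## Node truncation

"Removing the most recent node" merges the two lineages it separates into
one lineage that still reaches the present — equivalently, the smallest
branching time is deleted and n decremented, and γ is recomputed on what
remains.  The package deliberately does *not* cut the tree at a time
horizon (which would shorten tip branches and change every interval); the
per-node reading keeps each step an honest (n−k)-tip chronogram, and the
two implementations of it (tree surgery vs. vector deletion) are tested to
agree to 1e-9.  Steps run to the 3-tip floor where γ is last defined.  The
profile's summary is the age of the last removed node at the earliest step
from which rejection never recurs.  The per-step threshold defaults to the
analytic −z_α; a per-step MCCR-corrected threshold can be supplied via
`critical_values`.

## Diversification models

For the pure-birth family the process is observed from the root (two
lineages); each of the n−2 interior branching events contributes
ln(i·λ(i)) and every interval contributes survival −i·λ(i)·g_i, the final
interval survival only.  Under this conditioning the pure-birth MLE is the
closed form λ̂ = (n−2)/Σ i·g_i (tested against a 1-D numeric optimizer to
1e-6), and the birth–death likelihood — the classic reconstructed-process
form in (r, a), evaluated stably via ln(e^{rx} − a) = rx + ln(1 − a·e^{−rx})
— reduces to the pure-birth expression term-for-term at a = 0, so nesting
inequalities hold without additive constants.  Users comparing against
other implementations may see a constant lnL offset from conditioning
choices; AIC *differences* are unaffected.  The birth–death ML fit is
cross-checked in the test suite against an independent R implementation
(`ape::birthdeath`) on a frozen fixture tree.

Optimization: birth–death in (log r, logit a) with five deterministic
starts spread over the extinction axis plus an explicit a = 0 boundary
check; DDX by profile likelihood over x ∈ [0, 5] (λ₀ has a closed form at
fixed x); DDL by a 60-point log grid over K − n ∈ [10⁻³·n, 10⁸] with local
refinement (K > n keeps every event rate positive); Yule-2-rate by exact
profile maximization over candidate shift times — the likelihood is
piecewise in t_s, so candidates are the branching times plus midpoints of
consecutive distinct knots, each evaluated in O(1) from prefix sums, with
both regimes required to contain at least one event (degenerate cases
collapse to the one-rate solution, flagged in the fit message).

Model choice: Δ = AIC(best rate-constant) − AIC(best rate-variable).
Because Δ's null distribution under pure birth is not chi-square-like, the
decision threshold is the ⌈(1−α)·reps⌉-th smallest Δ over simulated
pure-birth trees of the observed size (optionally simulated at a larger
richness and pruned, matching the MCCR sampling model).  The rate-constant
family is retained on ties (strict inequality).  AIC is the default; AICc
is available as an option.

## Mk1 ancestral areas

Symmetric two-state likelihood by the pruning recursion with per-node
rescaling (500-tip trees stay in range), root combined under the equal
prior (½, ½) — the stationary distribution of the chain and the only prior
consistent with its symmetry.  Marginals come from the standard
inside/outside two-pass algorithm and are validated against exhaustive
enumeration over all internal-state assignments on trees of ≤ 8 tips
(1e-9).  Reconstruction is marginal, not joint, matching how per-node
pie-diagram probabilities are presented; by default it is performed at the
ML rate q̂ (1-D bounded search on log q over [1e-8, 10] per unit time, with
bracket-end checks), with a fixed-q mode for sensitivity analysis.  The
rate is in the reciprocal units of the input tree's branch lengths.  An
all-tips-identical data set returns the q = 0 boundary with a flag rather
than an error.  The focal-root search returns the oldest internal node
whose marginal for the focal state strictly exceeds the threshold, or an
explicit null carrying the best candidate.

## Pipeline

Stage order: calibration (optional) → Mk1 fit + reconstruction → focal-root
subtree extraction → branching times → γ/CR → MCCR sweep → truncation →
model fits + calibrated comparison.  Per-stage RNG streams are derived as
SeedSequence([master, stage_index]) with a fixed append-only stage table,
so adding stages never changes earlier stages' draws; a report is
bit-reproducible given its configuration.  When no states are supplied the
ancestral stage is skipped and the tree root is used.  By default all
descendants of the focal root are retained (including any lineages that
re-colonized the non-focal area); a tip-prune list supports the sensitivity
variant that removes them.

## Problem sizes in the checked suites

The statistical suites use the study-scale conditions: 90 sampled of up to
122 true species, α = 0.05, and 10,000 replicates for the headline null
constants.  Heavier cross-checks run at sizes chosen to keep the whole
suite desk-scale while leaving Monte-Carlo error well inside each asserted
tolerance: MCCR direction at 5 seeds × 2,000 replicates; pure-birth rate
recovery at 500 trees of 100 tips; model-selection size at 1,000
calibration + 1,000 fresh trees of 90 tips and power at 100 two-rate trees
of 200 tips; Mk1 rate recovery at 100 replicates of 500-tip, root-age-16
trees at q = 0.007 (≈ 10–20 expected changes per tree, hence the
factor-of-two recovery band).

## Known limitations

- The MCCR correction assumes uniformly random missing taxa; clade-biased
  sampling is not modeled.
- Density dependence is indexed by the reconstructed lineage count i, not
  by true standing diversity through time.
- The birth–death simulator's stopping convention (first passage to n) is
  a simple conditioning, adequate for directional and reduction tests but
  not an exact sampler of n-conditioned birth–death branching times.
- Mk1 is the 1-parameter symmetric model only; asymmetric-rate models and
  dispersal–extinction–cladogenesis biogeography are out of scope.
- No NEXUS input, no rate smoothing, no tree inference from sequences.
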