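# Methods

## Model

Observations `y_1..y_n` are modelled as a K-component univariate
Gaussian mixture with latent allocations (one multinomial label per
observation). K is set *above* any plausible true order (default 10);
the prior does the model selection. Priors:

* weights: exchangeable Dirichlet(α, …, α), **truncated** so that no
  weight falls below `weight_floor` (see "Numerical choices");
* variances: σ²_k ~ InvGamma(a, b), shape–scale parameterisation;
* means: μ_k | σ²_k ~ N(l, σ²_k / τ).

Default hyperparameters are data-driven: `l = mean(y)`,
`b = mean((y − l)²)`, `a = 2.5`, `τ = 1`. Centring `l` at the sample
mean keeps the prior inside the data range and speeds convergence; `b`
at the total mean squared deviation makes the variance prior weakly
informative on the data's own scale. The cost of these defaults is a
known one: for a component whose mean sits far from the global mean,
the `τ n_k (ȳ_k − l)² / (2(τ + n_k))` term in the conjugate variance
update inflates the posterior variance, so component variances are
typically over-estimated by a factor around two and, in hard cases,
groups with small separation can be absorbed into a broad neighbour.
Lowering `τ` (e.g. 0.01) relaxes this coupling; it is a plain
`MixturePriors` field.

With d = 2 free parameters per Gaussian component, α < d/2 = 1 is the
regime in which surplus components are emptied of observations rather
than merged; the target chain runs at α = 0.5³⁰.

## Prior parallel tempering

J chains share data, K and the parameter hierarchy and differ only in
α, descending along a fixed ladder (presets: the 18-entry refined
ladder 30, 20, 10, 5, 3, 1, 0.5¹, 0.5², …, 0.5³⁰ and a 22-entry
extension to 0.5⁵⁰; the preset names `ladder25`/`ladder30` are the
nominal chain counts under which these sequences are conventionally
cited). Per iteration each chain does one Gibbs sweep — allocations
from the categorical full conditional computed in log space, weights
from the Dirichlet full conditional, component parameters from the
conjugate normal/inverse-gamma update, empty components refreshed from
the prior (the full conditionals force this; nothing else is defined
for an empty group). Then, with probability `u` (default 1), one
adjacent pair (j, j+1), chosen uniformly, proposes a *complete* state
exchange, accepted with probability min(1, A) where
`log A = (α_j − α_j′)(Σ log π_j′ − Σ log π_j)` — the exact log of the
four-density weight-prior ratio for exchangeable Dirichlets; all other
factors cancel because the chains share likelihood and parameter
priors. Only one pair is proposed per iteration; initial allocations
are uniform on 1..K with parameters then drawn from their full
conditionals.

## Numerical choices

**Log-space weights.** Dirichlet draws use the shape-boost
representation `G(s) = G(s+1) · U^(1/s)` carried in logarithms, so the
log-weight of a component with a near-zero shape parameter is computed
exactly instead of underflowing to −∞. Weights and log-weights are
stored together and every consumer (allocation update, swap ratio, MAP
scoring) works from the logs.

**Truncated weight prior (`weight_floor`, default 0.5³⁰).** The weight
prior is truncated at the smallest concentration in play: after the
log-space draw, log-weights are floored at `log(weight_floor)` and
renormalised on the simplex. Two facts motivate this as a model choice
rather than a numerical convenience. First, a weight at the target
concentration scale (~10⁻⁹) already implies far fewer than one expected
allocation in any realistic sample, so weights below it are
statistically indistinguishable from zero. Second, *untruncated*
near-zero concentrations produce log-weights of order −1/α (−10⁹ at the
target), which makes the exchange ratio between deep-ladder chains
astronomically one-sided: tail swap acceptance collapses to zero, the
target chain decouples from the ladder, and a component emptied by a
fluctuation can never be recovered. With the truncation, every adjacent
pair keeps a workable acceptance rate (the design requirement of the
ladder), the tempered posteriors below α ≈ 10⁻⁸ coincide, and a
strongly outlying observation can still claim a floored component —
which is exactly how a genuinely supported but currently empty group
(e.g. a weight-0.01 component represented by two observations) is
resurrected. The truncation point is deliberately *not* the
floating-point floor: flooring at ~10⁻³⁰⁸ restores tail swaps but
leaves resurrection impossible, and both untruncated variants measurably
degrade order recovery on the built-in designs.

**Vectorised chains, single RNG stream.** The chain axis is vectorised
(all J chains advance in one set of array operations, ~1 ms per
iteration at J = 18, n = 200, K = 10), so a single seeded generator
drives all chains and the swap decisions. Runs are bit-reproducible
given the seed; within-chain sequences are not invariant to J.

**Categorical sampling.** Allocation probabilities are normalised by
log-sum-exp and inverted through per-observation uniforms against the
row cumulative sums; ties have probability zero.

## Relabelling (Zswitch)

Saved target-chain iterations are partitioned by alive count k0. Within
a configuration, the reference is the iteration maximising the
complete-data log posterior restricted to non-empty components (ties →
earliest iteration), with labels compacted so groups 1..k0 are alive.
Every iteration is cross-tabulated against the reference (match table
M); rows whose shared fraction strictly exceeds the threshold `m`
(default 0.5 — a majority-match reading of "most of the component's
members"; the threshold is a tuning parameter) form candidate sets.
If all candidate sets are singletons forming a bijection, that
relabelling is applied (phase 1). Otherwise all bijections in the
product of the candidate sets are enumerated and the one minimising the
summed componentwise relative distance of (π, μ, σ²) between reference
group j and the current group assigned to it wins (phase 2); the sum
runs over all alive groups under the candidate bijection. Safeguards,
each chosen where the procedure is otherwise undefined: an empty
candidate set is widened to its best-matching column; if the
enumeration would exceed 5! = 120 bijections, `m` is raised in steps of
0.1 for that iteration; if no bijection survives at all, the iteration
falls back to a full parameter-distance assignment over all alive
groups and is flagged. Reference parameters of exactly zero would
divide the relative distance by zero; the denominator is floored at
1e-8. Distance ties resolve to the lexicographically smallest
assignment. Empty components are compacted to the label tail. The
relabeller assumes no configuration contains duplicated identical
(merged) components — the near-zero target prior is what justifies
this.

## Post-processing

Per configuration: `p(k0)` is its share of saved iterations; allocation
probabilities are per-observation frequencies of the aligned labels;
reclassification (simulation data only, defined when k0 equals the true
order) assigns each observation to its modal component and matches
estimated to true groups by the agreement-maximising bijection
(computed by linear assignment — identical to exhaustive search over
the k0! bijections). Predictive replicates resample one saved draw per
replicate and simulate n values from its alive mixture. From R
replicates (default 10,000): `P_min = p(min yrep < min y)` and
`P_max = p(max yrep < max y)` (strict inequalities), predictive
concordance = share of observations strictly inside the 2.5%/97.5%
quantiles of the pooled replicate distribution (the replicate margins
are exchangeable, so pooling loses nothing), and the prediction errors
MAPE/MSPE = the absolute (squared) gaps between the sorted observed
sample and each sorted replicate, **summed over the n order statistics**
and averaged over replicates. The sum convention makes these errors
grow with n — they compare configurations on one dataset, never across
sample sizes — and is flagged here because other definitions exist.
MAE/MSE measure posterior parameter means against simulation truth
under the deviation-minimising group matching, averaged over all 3·k0
parameters. Credible intervals are equal-tailed 2.5%/97.5% quantiles.

## Synthetic designs and what the tests show

Four built-in designs span the benchmark space: (1) three
well-separated components (0.5/0.3/0.2, means 15/7/1, unit variances);
(2) two sharp peaks overlapping a broad central component (means
−1/10/4, variances 0.5/0.5/3); (3) two components identical except for
variance (means 1/1, variances 10/1 — a unimodal density); (4) a
weight-0.01 component far from the bulk (0.6/0.39/0.01, means 6/10/20).
Sampling is categorical-then-normal so true labels are exact. These
emulate the cluster structure, overlap and rare-subgroup features of
real univariate data but not heavy tails, skewness or measurement
error; passing tests demonstrate order recovery and calibration under
correctly specified Gaussian mixtures, not robustness to
misspecification (the galaxy-velocity literature is the canonical
cautionary example).

A caveat established during development with exact collapsed-posterior
computations (marginal likelihoods verified against numerical
integration): under the default hierarchy the *exact* posterior at the
target concentration can place most of its mass on a merged
configuration with one fewer, broader component — increasingly so as n
falls. The sampler's finite-run output therefore reflects a
quasi-stable balance between the configurations delivered down the
ladder and the slow within-chain merging dynamics; at n = 200 the true
order dominates, while small samples legitimately favour the sparser
model. Reported `p(k0)` values for ambiguous small samples should be
read as rankings of candidate orders, not as precise posterior masses.

## Problem sizes in the test suite

The suite regenerates everything it tests: full pipeline runs use
n = 100–200 with 20,000 iterations (5,000 burn-in) matching the
replicate-study schedule; replicate consistency uses 10 replicates at
8,000 iterations (2,000 burn-in, proportional to the full schedule);
sampler-correctness checks enumerate a 6-observation, 2-component
problem exactly and compare 200,000 Gibbs sweeps by total variation.

## Known limitations

Univariate Gaussian emissions only; no model averaging across
configurations; no comparison relabellers (k-means/ECR-style); `u`, `m`
and the ladder are fixed design choices rather than adapted online; the
replicate study parallelises trivially but runs serially here.
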