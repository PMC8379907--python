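# Methods

## The model

`statedep` asks whether a binary lifestyle character (0 = nonbuilder,
1 = builder) changes the tempo of continuous-trait evolution on a fixed,
rooted, time-calibrated phylogeny, while guarding against misattributing
unrelated rate heterogeneity to the character (the "straw-man" problem).

The discrete character evolves as a two-state CTMC with gain rate `q01` and
loss rate `q10`.  Conditional on a full character history `h` (a
piecewise-constant state function on every branch), each of `k` traits
diffuses as Brownian motion whose instantaneous variance on branch `l` in
state `s` is

    sigma0^2 * beta_l * zeta_s^delta ,

where

* `sigma0^2` — global trait variance per unit time;
* `beta_l` — branch-specific background rate multiplier, i.i.d.
  lognormal(0, nu) (median 1) given the relaxed-clock spread parameter `nu`;
* `zeta = (zeta0, zeta1)` — state-dependent relative rates constrained to
  mean 1, `(zeta0 + zeta1)/2 = 1`, so that state effects are identified
  separately from `sigma0^2`;
* `delta` — reversible-jump indicator: `delta = 0` is the state-independent
  model (`zeta0 = zeta1 = 1`), `delta = 1` the state-dependent model.

Given `h`, the trait covariance is plain BM on a rescaled tree with effective
branch lengths `v_l = sigma0^2 beta_l (t0_l zeta0^delta + t1_l zeta1^delta)`,
`t0, t1` being dwell times.  The trait likelihood is REML via independent
contrasts: the root state is marginalized and each contrast contributes a
k-variate normal density with covariance `Sigma * V_c`, with `Sigma` a fixed
unit-diagonal trait correlation matrix (identity by default).  REML makes the
likelihood exactly translation-invariant and removes the root nuisance
parameter; it is the standard choice for rate-focused comparative methods.

Three hypotheses are scored from the posterior of `(delta, zeta)`:
H0 `delta = 0`; H1 `delta = 1` and `zeta1 > zeta0` (builders faster);
H2 `delta = 1` and `zeta1 < zeta0` (builders slower).  With a symmetric zeta
prior the prior probabilities are `(1 - p_dep, p_dep/2, p_dep/2)` and the
Bayes factor of a hypothesis is its posterior odds over its prior odds,
estimated from indicator frequencies in the rj trace.  A hypothesis with no
opposing samples reports BF = infinity together with the rule-of-three 95%
lower bound.

## Priors (defaults, all user-swappable for sensitivity reruns)

| parameter | prior | default hyperparameters | why |
|---|---|---|---|
| sigma0^2 | lognormal(m, s) | m = 0, s = 2 | weakly informative on the rate scale |
| nu | Exponential(rate) | mean 0.587 | ~2-fold expected spread of branch rates |
| beta_l given nu | lognormal(0, nu) | median 1 | scale absorbed by sigma0^2 |
| (zeta0, zeta1)/2 | Dirichlet(a, a) | a = 1 (flat simplex) | uninformative on the state effect |
| delta | Bernoulli(p_dep) | p_dep = 0.5 | equal prior odds of the two models |
| q01, q10 | Exponential(rate) | mean 0.1 per unit time | order tens of transitions on trees of total length O(100) |

## The sampler

One generation is a fixed sweep (fixed, non-adaptive tuning constants, so a
chain is a deterministic function of its seed):

1. **Character history** — independence Metropolis-Hastings: a fresh
   stochastic-mapping draw of the full history from the CTMC conditional
   given the tip states (internal node states by Felsenstein pruning plus
   root-down conditioning; per-branch paths by endpoint-conditioned
   uniformization with auxiliary rate `1.1 * max(q01, q10)`), accepted with
   the trait-likelihood ratio.  The CTMC prior and the proposal density
   cancel exactly.
2. Multiplier (log-scale random-walk) moves on `sigma0^2`, `nu`, `q01`,
   `q10`.  The `q` moves see only the history density; the `nu` move only
   the `beta` hyperprior.
3. Per-branch multiplier moves on `beta_l` with incremental likelihood
   updates (only the root path of the changed branch is refolded).  Trees
   with more than 128 branches use a random scan of 128 branches per
   generation instead of a full sweep — a standard random-scan
   Metropolis-within-Gibbs scheme that leaves the posterior invariant while
   keeping the per-generation cost flat in tree size; each branch still
   receives thousands of updates over a default run.
4. A joint `sigma0^2`/`beta` rescale (`sigma0^2 *= m`, all `beta /= m`) that
   walks along the likelihood-invariant ridge, and a `nu`/`beta`
   "shrink-expand" move (`nu' = nu m`, `log beta' = m log beta`) under which
   the lognormal terms cancel; without the latter `nu` mixes poorly because
   it is identified only through the 2n-2 beta values.
5. A reflected random-walk move on the zeta simplex (active when
   `delta = 1`).
6. The reversible-jump toggle: `0 -> 1` draws zeta from its prior
   (independence proposal, so the Hastings ratio reduces to the likelihood
   ratio times the prior odds of delta); `1 -> 0` sets `zeta = (1, 1)`.  The
   toggle is attempted with probability 1/2 each generation: an
   always-accepted toggle (even prior odds, flat likelihood) would otherwise
   alternate `delta` deterministically with period 2 and alias against even
   thinning intervals.

Root-state prior for the discrete character: CTMC stationary distribution by
default, config-overridable to a fixed state.  Two chains with distinct seed
streams are run by default, checked with the classic Gelman-Rubin PSRF (ESS
via arviz), then concatenated post burn-in (25% default), thinned to ~1000
retained samples per chain.

In prior-sampling mode (likelihood held constant) histories are simulated
unconditionally, so every parameter's marginal — including the CTMC rates —
must reproduce its prior exactly; this is the core rj correctness gate in the
test suite.

Initialization draws from the prior, re-drawing up to 100 times while the
joint posterior is non-finite.

## Synthetic data: what it emulates and what it does not

The generator is the exact generative twin of the inference model: Yule
(pure-birth) trees (closed-form height checks; only a time-scaled scaffold is
needed), forward-simulated character histories, lognormal background rates
and state-dependent BM traits, with independent RNG substreams for tree,
history, rates and traits, and a truth manifest for recovery scoring.  The
default recovery regime — 200 tips, one trait, `zeta = (0.25, 1.75)` (ratio
7), `nu = 0.3`, symmetric CTMC rates tuned to ~20 expected transitions —
mirrors a strong-but-realistic effect with the few-dozen gains/losses seen on
real builder/nonbuilder trees, at a tree size that keeps a 50,000-generation
run desk-scale.

Passing recovery tests therefore shows the pipeline is self-consistent under
its own assumptions.  Real morphological data violate several of them:
measurement error and intraspecific variation are absent, traits may follow
non-BM dynamics (OU, early bursts), the empirical tree carries calibration
uncertainty, and real background-rate variation need not be lognormal.  The
tests say nothing about those failure modes.

## Numerical choices

* Effective lengths, dwell times and segment sums are validated to 1e-9;
  contrast folds treat a zero-variance contrast with equal values as a
  degenerate point mass (contribution 0) and return -inf with a warning when
  the values differ.
* The uniformization bridge truncates its Poisson series at the sampled
  quantile (exact sampling); branches with auxiliary mean > 500 fall back to
  forward simulation with endpoint rejection, which is exact and efficient
  in that near-stationary regime.
* An unreachable tip configuration (zero conditional mass in the pruning
  pass) raises immediately — the closed-form two-state pruning detects
  impossibility exactly, so stochastic retries are pointless.
* Trace files print floats at 17 significant digits; write/read is an exact
  bit-level round-trip.
* The "rate variation explained by the state" statistic is, per posterior
  sample, the branch-duration-weighted variance of the per-branch log state
  term over the variance of the log total (state + background) term,
  averaged over samples.  Log scale matches the multiplicative rate model and
  duration weighting matches how variation accrues on the tree; both are
  config-switchable and the choice is echoed in the output.  Zero total
  variance contributes 0.
* H1/H2 are defined on `delta = 1` samples only; a numerically exact tie
  `zeta1 = zeta0` under `delta = 1` (measure zero) counts to neither.

## Problem sizes used by the shipped checks

Likelihood oracles run on 100 random instances of up to 5 tips and 3 traits;
sampler-exactness checks use 10,000-20,000 draws on 1-3 tip trees; prior
recovery uses 400,000 likelihood-off generations thinned to 10,000 draws;
parameter recovery uses 20 state-dependent plus 20 state-independent
200-tip datasets at 50,000 generations each.  The acceptance script runs two
2-chain analyses (one dependent, one independent truth) at the same size.

## Known limitations

* Two discrete states only; no hidden-state or covarion expansions.
* `Sigma` is fixed (default identity), not estimated; per-trait rate scalars
  are not implemented.
* No missing trait data, no measurement-error model, no OU/early-burst
  alternatives.
* Bayes factors come from the rj indicator frequencies, not from marginal
  likelihood estimators; extremely decisive factors are reported as bounds.
* Polytomies are accepted and handled exactly by the pruning algorithms but
  are never resolved.
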