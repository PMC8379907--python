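# statedep

Does a binary lifestyle — living in a constructed web or burrow versus
free hunting — change how fast body morphology evolves?  `statedep` is a
Bayesian pipeline for that question on any clade with a time-calibrated
phylogeny, a binary "builder/nonbuilder" character at the tips, and one or
more continuous (log-scale) morphological traits.  It is written for
comparative biologists who want state-dependent rate tests that do not fall
for the "straw-man" problem of crediting every bit of rate heterogeneity to
the focal character.

## The model

The lifestyle character evolves as a two-state CTMC (gain rate q01, loss
rate q10); full character histories are sampled by stochastic mapping rather
than integrated out.  Given a history, each trait diffuses as Brownian
motion with instantaneous variance on branch *l* in state *s*

    sigma0^2 * beta_l * zeta_s^delta

where sigma0^2 is the global rate, beta_l are branch-specific background
rate multipliers (lognormal, median 1, spread nu — the guard against the
straw man), zeta = (zeta0, zeta1) are state-dependent relative rates with
(zeta0 + zeta1)/2 = 1, and delta is a reversible-jump indicator switching
between the state-independent (delta = 0, zeta0 = zeta1 = 1) and
state-dependent (delta = 1) models within one chain.  The trait likelihood
is REML via phylogenetically independent contrasts.  Three hypotheses are
scored from the posterior:

* **H0** delta = 0 — lifestyle does not change the rate;
* **H1** zeta[builder] > zeta[nonbuilder] — building accelerates evolution;
* **H2** zeta[builder] < zeta[nonbuilder] — building buffers it.

Bayes factors are posterior odds over prior odds of each hypothesis, and a
variance partition reports the share of branch-rate variation attributable
to the state effect.  See `docs/methods.md` for priors, moves and numerics.

## Worked example

Simulate a 200-species dataset in which builders evolve 7x faster
(zeta = (0.25, 1.75)), then infer:

```python
import statedep as sd

ds = sd.generate_dataset(sd.SimConfig(n_tips=200, seed=11))
cfg = sd.RunConfig(n_generations=50_000, n_chains=2, rng_seed=1)
combined, chains, report = sd.run_analysis(ds.tree, ds.tip_states, ds.traits,
                                           sd.Priors(), cfg)
res = sd.hypothesis_posteriors(combined)
frac, note = sd.rate_variation_partition(combined, ds.tree)
dep = combined.df["delta"] == 1
ratio = (combined.df.loc[dep, "zeta1"] / combined.df.loc[dep, "zeta0"]).median()
print("P(H0), P(H1), P(H2):", res.posterior)
print("BF(H1+H2):", res.bayes_factors["H1+H2"], res.notes.get("H1+H2", ""))
print("posterior median zeta1/zeta0:", round(ratio, 2))
print("state-dependent share of rate variation:", round(frac, 3))
```

prints (seeds as above):

```
P(H0), P(H1), P(H2): {'H0': 0.0, 'H1': 1.0, 'H2': 0.0}
BF(H1+H2): inf inf (no opposing samples; 95% lower bound 674)
posterior median zeta1/zeta0: 7.74
state-dependent share of rate variation: 0.932
```

Every retained sample is state-dependent with builders faster (P(H1) = 1, so
the sample-frequency Bayes factor is infinite and is reported with its
rule-of-three lower bound), the posterior rate ratio straddles the
generating value 7, and — as expected for so strong a simulated effect —
the variance partition attributes most branch-rate variation to the
lifestyle state.  On a dataset simulated *without* a state effect the same
pipeline returns BF(H1+H2) well below 1 and a state share under 10% (see
the acceptance script below).

The same analysis runs from the shell on your own files:

```sh
statedep simulate --config sim.yaml --out data/
statedep infer --tree data/tree.nwk --states data/states.tsv \
               --traits data/traits.tsv --config run.yaml --out out/
statedep summarize --trace out/trace_chain0.tsv --tree data/tree.nwk \
                   --states data/states.tsv --out out/
```

`infer --priors alt.yaml` reruns with swapped hyperparameters for prior
sensitivity checks; `summarize` also writes per-branch posterior-mean rate
tables, a rate-annotated newick and an SVG rate map with tips colored by
lifestyle (red = builder, light blue = nonbuilder).

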