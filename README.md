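# treedemog

Size-class demographic transition estimation for tree communities.

Long-term forest plots census every tagged stem into ordered size classes
— seedling, sapling, juvenile, then 10-cm DBH bins — on schedules that
mix 1-, 2- and 4-year revisit intervals.  `treedemog` estimates, per
species *k* and size class *i*, the annual probabilities of stasis
*S*<sub>i,k</sub>, progression *G*<sub>i,k</sub> and retrogression
*R*<sub>i,k</sub> from such censuses, then derives the quantities
ecologists compare across species:

- annual survivorship  *S* + *G* + *R*  and mortality  1 − (*S* + *G* + *R*)
- the growth index  *G* / (*S* + *G* + *R*), the probability that a
  surviving stem advances a class in a year

and tests for growth–survival **trade-offs and synergies** across species
within each class, with and without phylogenetically independent
contrasts (plus Pagel's λ for phylogenetic signal).

The statistical core is a hierarchical Bayesian binomial model: each
class × interval tally contributes three nested binomials on the
conditional decomposition *P*(SV), *P*(ST or PR | SV), *P*(ST | ST or PR);
2- and 4-year observations are linked to annual rates by composing
one-step moves (e.g. *S*<sub>i,2</sub> = *S*² + *G*·*R*₊); species enter
as logit-scale random effects per class with Normal(0, 1000) hyperpriors
on the means and Gamma(100, 100) on the precisions, so species with a
handful of stems borrow strength from the community.  Sampling is an
adaptive Metropolis-within-Gibbs scheme compiled with numba,
deterministic given a seed, with Gelman–Rubin R̂ diagnostics.  See
[docs/methods.md](docs/methods.md) for the full model.

It is intended for forest ecologists and demographic modellers who have
longitudinal census records (or pre-tallied transition counts) and want
stage-structured annual rates with honest uncertainty, and for anyone
studying the evolution of demographic strategies across co-occurring
species.

## Worked example

Every stage is importable; `examples/` has one narrative script per
capability.  A compact end-to-end run:

```python
import treedemog as td

scheme = td.ogawa_scheme()                     # 12 classes, 17 species' maxima
sim = td.make_ogawa_like_config(seed=2, count_scale=0.2, mode="model-exact")
histories = td.simulate_population(sim)        # tagged-stem survey records
tallies = td.tally_transitions(histories, scheme)

draws = td.sample_posterior(tallies, scheme,
                            td.ModelConfig.scaled(10, seed=2),
                            species=sim.true_rates.species)
print(draws.convergence_report()["flagged"].sum())

summary = td.derive_summary(draws)             # mortality / growth per cell
covered, total = td.ci_coverage(draws, sim.true_rates, level=0.9)
print(covered, total)
```

Running `examples/02_fit_transition_model.py` (which does the above)
prints:

```
census: 8899 stems, 320 tally cells
R-hat: median 1.000, max 1.013; 0 of 447 parameters flagged ...
90% credible intervals cover 300/354 planted rates (84.7%)

Fagus_crenata D10: true S=0.750 posterior 0.759 [0.711, 0.804]
```

i.e. the sampler converged (R̂ ≈ 1 everywhere), the 90% credible
intervals caught ~85% of the planted annual rates at this reduced census
scale, and a well-populated cell's stasis probability is recovered to the
third decimal.  The comparative stage (`examples/04_phylo_tradeoffs.py`)
plants an evolutionary correlation of −0.7 between logit survivorship and
logit growth on a 17-species tree and prints

```
raw  Pearson: r = -0.905, p = 0.0000  (n = 17)
PIC  Pearson: r = -0.756, p = 0.0007  (contrasts = 16)
```

— the contrast test recovering the planted trade-off after removing
shared-ancestry resemblance.

A thin CLI chains the same stages
(`treedemog simulate | tally | fit | derive | correlate | report`), each
writing its artifacts plus a checksummed run manifest; identical seeds
give byte-identical outputs.

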