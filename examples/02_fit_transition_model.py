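"""Fit the hierarchical transition model on a small synthetic census.

Samples the joint posterior of every species-level logit probability
(survival; stay-or-advance given survival; stay given stay-or-advance) and
the per-class hyperparameters, then reports convergence and how well the
posterior recovered the planted annual rates.  Chain settings are scaled
well below the reference defaults so this runs in about a minute.
"""

import numpy as np

import treedemog as td

scheme = td.ogawa_scheme()
sim = td.make_ogawa_like_config(seed=2, count_scale=0.2, mode="model-exact")
histories = td.simulate_population(sim)
tallies = td.tally_transitions(histories, scheme)
print(f"census: {len(histories)} stems, {len(tallies)} tally cells")

config = td.ModelConfig.scaled(10, seed=2)  # 30,000 steps, 20,000 burn-in
draws = td.sample_posterior(tallies, scheme, config, species=sim.true_rates.species)

report = draws.convergence_report()
print(f"R-hat: median {np.nanmedian(report['rhat']):.3f}, "
      f"max {np.nanmax(report['rhat']):.3f}; "
      f"{int(report['flagged'].sum())} of {len(report)} parameters flagged "
      f"(data-poor top classes mix slowest; lengthen chains if flagged)")

covered, total = td.ci_coverage(draws, sim.true_rates, level=0.9)
print(f"90% credible intervals cover {covered}/{total} planted rates "
      f"({100 * covered / total:.1f}%)")

k = draws.species.index("Fagus_crenata")
S, G, R = draws.rate_draws()
j = 4  # D10
print(
    f"\nFagus_crenata D10: true S={sim.true_rates.S[k, j]:.3f} "
    f"posterior {S[:, k, j].mean():.3f} "
    f"[{np.quantile(S[:, k, j], 0.05):.3f}, {np.quantile(S[:, k, j], 0.95):.3f}]"
)
print("A well-calibrated fit covers ~90% of planted rates and R-hat ~ 1.")
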