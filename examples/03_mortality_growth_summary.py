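"""Derive annual mortality and the growth index from posterior draws.

Mortality is 1 - (S + G + R) and the growth index G / (S + G + R) -- the
probability that a surviving stem advances a class in a year.  Both are
computed per posterior draw and then averaged, with 95% equal-tailed
intervals.  The table printed here is the exchange format the comparative
stage consumes.
"""

import treedemog as td

scheme = td.ogawa_scheme()
sim = td.make_ogawa_like_config(seed=3, count_scale=0.1, mode="model-exact")
tallies = td.tally_transitions(td.simulate_population(sim), scheme)
draws = td.sample_posterior(
    tallies, scheme, td.ModelConfig.scaled(50, seed=3), species=sim.true_rates.species
)

summary = td.derive_summary(draws)
one = summary[summary["species"] == "Carpinus_cordata"]
cols = ["class_label", "mortality", "mortality_lo", "mortality_hi", "growth_index"]
print(one[cols].to_string(index=False, float_format=lambda v: f"{v:.4f}"))
print(
    "\nMortality is high for new seedlings, falls toward the largest"
    "\nclasses (U-shaped over the full ladder for large-statured species),"
    "\nand the growth index is structurally 1 at the entry class and 0 at"
    "\nthe species' maximum class."
)
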