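"""Sequential-binomial likelihood of transition tallies given annual rates.

Each tally cell contributes three nested binomial masses: survival out of
the starters, stay-or-advance out of the survivors, and stay out of the
stay-or-advancers, with the cell's interval length matched by linking the
annual rates over 1, 2 or 4 years.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
from scipy.stats import binom

from .census import TransitionTally
from .rates import AnnualRates, conditionals_from_rates, link_interval


def _binom_logpmf(k: int, n: int, p: float) -> float:
    if n == 0:
        return 0.0
    # binom.logpmf returns -inf for impossible outcomes (p == 0 with k > 0),
    # which the sampler treats as a rejected state.
    return float(binom.logpmf(k, n, p))


def log_likelihood(
    tallies: Iterable[TransitionTally],
    rates: AnnualRates,
    drop_third_term: bool = True,
) -> float:
    """Joint log-probability of the tallies; additive over cells."""
    linked = {h: link_interval(rates, h, drop_third_term) for h in (1, 2, 4)}
    total = 0.0
    for t in tallies:
        k = rates.index_of(t.species)
        j = t.class_index - 1
        S, G, R = (a[k, j] for a in linked[t.interval_years])
        c = conditionals_from_rates(S, G, R, t.interval_years)
        n_sv = t.n_survivors
        total += _binom_logpmf(n_sv, t.n_all, c.p_sv)
        total += _binom_logpmf(t.n_st + t.n_pr, n_sv, c.p_stpr_sv)
        total += _binom_logpmf(t.n_st, t.n_st + t.n_pr, c.p_st_stpr)
    return total
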