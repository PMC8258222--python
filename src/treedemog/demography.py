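"""Derived demographic quantities: survivorship, mortality, growth index.

From the annual rates the reported quantities are

    survivorship = S + G + R        mortality = 1 - survivorship
    growth index = G / (S + G + R)

the last being the probability that a surviving stem advances a class in a
year -- the stage-classified surrogate for an annual growth rate.  For
posterior draws the quantities are computed per draw and then averaged
(the mean of a ratio is not the ratio of means, and the per-draw order is
the contract here).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .mcmc import PosteriorDraws
from .rates import AnnualRates
from .scheme import SizeClassScheme

SUMMARY_COLUMNS = [
    "species",
    "class",
    "class_label",
    "survivorship",
    "survivorship_lo",
    "survivorship_hi",
    "mortality",
    "mortality_lo",
    "mortality_hi",
    "growth_index",
    "growth_lo",
    "growth_hi",
]


def _derive(S: np.ndarray, G: np.ndarray, R: np.ndarray):
    sv = S + G + R
    with np.errstate(divide="ignore", invalid="ignore"):
        gi = np.where(sv > 0, G / np.where(sv > 0, sv, 1.0), np.nan)
    return sv, 1.0 - sv, gi


def derive_summary(
    draws_or_rates: PosteriorDraws | AnnualRates,
    scheme: SizeClassScheme | None = None,
    interval: float = 0.95,
) -> pd.DataFrame:
    """Summary table of survivorship, mortality and growth index.

    For :class:`PosteriorDraws` input, point values are posterior means of
    the per-draw quantities and the bounds are equal-tailed credible
    intervals at ``interval``.  For plain :class:`AnnualRates` the bounds
    equal the point values.  A cell with zero survivorship reports
    mortality 1 and a missing growth index.  Classes above a species'
    maximum are not reported.
    """
    if isinstance(draws_or_rates, PosteriorDraws):
        pd_draws = draws_or_rates
        scheme = scheme or pd_draws.scheme
        species = pd_draws.species
        S, G, R = pd_draws.rate_draws()  # (n_draws, K, C)
    else:
        rates = draws_or_rates
        scheme = scheme or rates.scheme
        species = rates.species
        S, G, R = (a[None, :, :] for a in (rates.S, rates.G, rates.R))

    sv, mort, gi = _derive(S, G, R)
    alpha = (1.0 - interval) / 2.0
    qs = [alpha, 1.0 - alpha]
    rows = []
    for k, sp in enumerate(species):
        m = scheme.max_class(sp)
        for i in range(1, m + 1):
            j = i - 1
            svd, mtd, gid = sv[:, k, j], mort[:, k, j], gi[:, k, j]
            gi_ok = np.isfinite(gid)
            glo, ghi, gmean = (np.nan,) * 3
            if gi_ok.any():
                gmean = float(np.nanmean(gid))
                glo, ghi = (float(v) for v in np.nanquantile(gid, qs))
            svq = np.quantile(svd, qs)
            mtq = np.quantile(mtd, qs)
            rows.append(
                (
                    sp,
                    i,
                    scheme.label_of(i),
                    float(svd.mean()),
                    float(svq[0]),
                    float(svq[1]),
                    float(mtd.mean()),
                    float(mtq[0]),
                    float(mtq[1]),
                    gmean,
                    glo,
                    ghi,
                )
            )
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS)


def write_summary(summary: pd.DataFrame, path, sep: str = "\t") -> None:
    summary.to_csv(path, sep=sep, index=False)


def read_summary(path, sep: str | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep, engine="python")
    missing = [c for c in SUMMARY_COLUMNS[:4] if c not in df.columns]
    if missing:
        raise ValueError(f"summary table missing columns: {missing}")
    return df
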