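"""Hierarchical Bayesian estimation of annual transition rates.

Model
-----
For every size class the three conditional probabilities (survival;
stay-or-advance given survival; stay given stay-or-advance) get a species
random effect on the logit scale,

    logit(p[class, type, species]) ~ Normal(mu[class, type], sigma2[class, type])

with vague Normal(0, 1000) hyperpriors on each mu and Gamma(100, 100)
hyperpriors on each precision 1/sigma2.  Tallies observed over 2- or
4-year intervals enter the likelihood through the interval-linking
composition of the annual rates, which couples neighbouring classes, so a
single joint posterior over all classes is sampled.

Sampler
-------
Adaptive random-walk Metropolis on every species-level logit (proposal
scales tuned toward 44% acceptance during burn-in only), with Gibbs-exact
conjugate updates for the hyperparameter means and precisions.  The kernel
is compiled with numba; draws are reproducible given the seed, and chains
differ only by derived seeds.

Structural zeros are built in rather than sampled: class 1 permits no
stasis or retrogression (a surviving new seedling ages out), the top class
and each species' maximum class permit no progression, and retrogression
exists only for the retrogression-capable classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .census import TransitionTally
from .rates import AnnualRates
from .scheme import SizeClassScheme
from . import _kernel

TYPE_NAMES = ("sv", "stpr_sv", "st_stpr")
LOGIT_CLAMP = 30.0


@dataclass(frozen=True)
class ModelConfig:
    """Chain settings and priors.

    Defaults reproduce the reference analysis: 300,000 steps with 200,000
    burn-in, thinned every 20 steps, 3 chains (5,000 retained draws per
    chain); Normal(0, 1000) hyperprior on each logit-scale mean and
    Gamma(shape=100, rate=100) on each precision; initial values -11 for
    every species logit, -1 for every mean and 1 for every precision.
    """

    n_steps: int = 300_000
    n_burnin: int = 200_000
    thin: int = 20
    n_chains: int = 3
    prior_mu_mean: float = 0.0
    prior_mu_var: float = 1000.0
    prior_prec_shape: float = 100.0
    prior_prec_rate: float = 100.0
    init_logit_p: float = -11.0
    init_mu: float = -1.0
    init_prec: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.n_burnin < self.n_steps:
            raise ValueError("need 0 < n_burnin < n_steps")
        if self.thin < 1 or self.n_chains < 1:
            raise ValueError("thin and n_chains must be positive")
        if self.prior_mu_var <= 0 or self.prior_prec_shape <= 0 or self.prior_prec_rate <= 0:
            raise ValueError("prior scales must be positive")

    @property
    def n_draws_per_chain(self) -> int:
        return (self.n_steps - self.n_burnin) // self.thin

    @classmethod
    def scaled(cls, factor: int = 10, **overrides) -> "ModelConfig":
        """Defaults with step counts divided by ``factor`` (thin unchanged)."""
        base = cls()
        return replace(
            base,
            n_steps=base.n_steps // factor,
            n_burnin=base.n_burnin // factor,
            **overrides,
        )


def _build_cells(scheme: SizeClassScheme) -> list[tuple[int, int]]:
    """(type, class-index) cells carrying a species-level hierarchy.

    Survival at every class; stay-or-advance-given-survival only where
    retrogression is possible (elsewhere it is structurally 1); stay-given-
    stay-or-advance at interior classes (structurally 0 at class 1, 1 at
    the top class).
    """
    n = scheme.n_classes
    cells: list[tuple[int, int]] = [(0, i) for i in range(1, n + 1)]
    cells += [(1, i) for i in sorted(scheme.retro_classes)]
    cells += [(2, i) for i in range(2, n)]
    return cells


def _validate_structural(
    tallies: Sequence[TransitionTally],
    scheme: SizeClassScheme,
    species: Sequence[str],
    enforce_species_max: bool,
) -> None:
    n = scheme.n_classes
    for t in tallies:
        t.validate_against(scheme, species_max=enforce_species_max)
        if t.class_index == 1 and t.n_st > 0:
            raise ValueError(
                "stasis tallied at class 1, which empties deterministically"
            )
        if t.class_index == n and t.n_pr > 0:
            raise ValueError("progression tallied at the top class")


@dataclass
class PosteriorDraws:
    """MCMC draws of all species logits and hyperparameters.

    ``draws`` is shaped ``(n_chains, n_draws_per_chain, n_params)`` with the
    species-level logits first (cell-major order), then every cell's mu,
    then every cell's precision, in the order of ``param_names``.
    """

    param_names: list[str]
    draws: np.ndarray
    scheme: SizeClassScheme
    species: tuple[str, ...]
    cells: list[tuple[int, int]]
    sp_col: dict[tuple[int, int, int], int]
    config: ModelConfig
    enforce_species_max: bool = True

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    @property
    def n_total_draws(self) -> int:
        return self.draws.shape[0] * self.draws.shape[1]

    def flat(self) -> np.ndarray:
        """Draws pooled over chains, shape (n_total_draws, n_params)."""
        return self.draws.reshape(-1, self.draws.shape[2])

    def rate_draws(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-draw annual rates (S, G, R), each (n_total_draws, K, C).

        Structural zeros and ones are applied, so every draw is a valid
        annual-rate array: class 1 has S = R = 0, each species' maximum
        class (and the ladder top) has G = 0, and R = 0 outside the
        retrogression-capable classes.
        """
        flat = self.flat()
        n_draws = flat.shape[0]
        K, C = len(self.species), self.scheme.n_classes
        P = np.empty((3, n_draws, K, C))
        P[0] = np.nan
        P[1] = 1.0  # structurally no retrogression
        P[2] = 1.0  # structurally no progression (overridden at interior classes)
        for (t, i, k), col in self.sp_col.items():
            P[t, :, k, i - 1] = _expit(flat[:, col])
        P[2, :, :, 0] = 0.0  # class 1: survivors advance
        for k, sp in enumerate(self.species):
            if self.enforce_species_max:
                m = self.scheme.max_class(sp)
                P[2, :, k, m - 1] = 1.0
        S = P[0] * P[1] * P[2]
        G = P[0] * P[1] * (1.0 - P[2])
        R = P[0] * (1.0 - P[1])
        return S, G, R

    def posterior_mean_rates(self) -> AnnualRates:
        S, G, R = self.rate_draws()
        return AnnualRates(
            self.species, self.scheme, S.mean(axis=0), G.mean(axis=0), R.mean(axis=0)
        )

    def gelman_rubin(self) -> pd.Series:
        if self.n_chains < 2 or self.draws.shape[1] < 10:
            raise ValueError(
                "convergence diagnosis needs >= 2 chains and >= 10 retained draws"
            )
        return pd.Series(gelman_rubin(self.draws), index=self.param_names)

    def convergence_report(self, threshold: float = 1.1) -> pd.DataFrame:
        rhat = self.gelman_rubin()
        flagged = rhat[(rhat > threshold) | rhat.isna()]
        return pd.DataFrame({"rhat": rhat, "flagged": rhat.index.isin(flagged.index)})

    def to_frame(self) -> pd.DataFrame:
        """Long-format (parameter, chain, iteration, value) table."""
        m, n, p = self.draws.shape
        return pd.DataFrame(
            {
                "parameter": np.tile(np.repeat(self.param_names, 1), m * n),
                "chain": np.repeat(np.arange(m), n * p),
                "iteration": np.tile(np.repeat(np.arange(n), p), m),
                "value": self.draws.reshape(-1),
            }
        )

    def save(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def _expit(x: np.ndarray) -> np.ndarray:
    x = np.clip(x, -LOGIT_CLAMP, LOGIT_CLAMP)
    return 1.0 / (1.0 + np.exp(-x))


def sample_posterior(
    tallies: Sequence[TransitionTally],
    scheme: SizeClassScheme,
    config: ModelConfig | None = None,
    species: Sequence[str] | None = None,
    enforce_species_max: bool = True,
    fix_mu: float | None = None,
    fix_sigma2: float | None = None,
) -> PosteriorDraws:
    """Sample the joint posterior of all species logits and hyperparameters.

    Parameters
    ----------
    tallies
        Transition tallies (sufficient statistics) over 1/2/4-year
        intervals.
    scheme
        Size-class ladder; its per-species maxima impose structural
        no-progression constraints when ``enforce_species_max``.
    config
        Chain settings; defaults to the full-length reference settings, so
        pass :meth:`ModelConfig.scaled` for quick runs.
    species
        Species to model.  Defaults to the species present in the tallies;
        listing extra species yields prior-shrunk draws for them even
        without data.
    fix_mu, fix_sigma2
        If both given, hyperparameters are held fixed at these values
        instead of being sampled (useful for conjugate checks and
        debugging).

    Returns
    -------
    PosteriorDraws
        Reproducible given ``config.seed``; attach a convergence summary
        via :meth:`PosteriorDraws.convergence_report`.
    """
    config = config or ModelConfig()
    if species is None:
        species = sorted({t.species for t in tallies})
    species = tuple(species)
    unknown = {t.species for t in tallies} - set(species)
    if unknown:
        raise ValueError(f"tallies mention species not modelled: {sorted(unknown)}")
    _validate_structural(tallies, scheme, species, enforce_species_max)

    C, K = scheme.n_classes, len(species)
    cells = _build_cells(scheme)
    n_cells = len(cells)
    sp_of = {sp: k for k, sp in enumerate(species)}

    # per-(cell, species) sampling mask: everything is sampled except the
    # stay-probability at a species' maximum class, which is structurally 1
    smask = np.ones((n_cells, K), dtype=np.uint8)
    if enforce_species_max:
        for c, (t, i) in enumerate(cells):
            if t == 2:
                for k, sp in enumerate(species):
                    if scheme.max_class(sp) == i:
                        smask[c, k] = 0

    # fixed effective-probability entries of the (3, C, K) probability array
    fixed_mask = np.ones((3, C, K), dtype=np.uint8)
    fixed_val = np.empty((3, C, K))
    fixed_val[0] = np.nan
    fixed_val[1] = 1.0
    fixed_val[2] = 1.0
    fixed_val[2, 0, :] = 0.0
    for c, (t, i) in enumerate(cells):
        for k in range(K):
            if smask[c, k]:
                fixed_mask[t, i - 1, k] = 0

    # tallies sorted by (class, horizon) for contiguous affected ranges
    h_code = {1: 0, 2: 1, 4: 2}
    order = sorted(range(len(tallies)), key=lambda q: (tallies[q].class_index, h_code[tallies[q].interval_years]))
    n_t = len(tallies)
    t_sp = np.empty(n_t, dtype=np.int64)
    t_j = np.empty(n_t, dtype=np.int64)
    t_h = np.empty(n_t, dtype=np.int64)
    t_n = np.empty(n_t, dtype=np.int64)
    t_y1 = np.empty(n_t, dtype=np.int64)
    t_y2 = np.empty(n_t, dtype=np.int64)
    t_y3 = np.empty(n_t, dtype=np.int64)
    for pos, q in enumerate(order):
        t = tallies[q]
        t_sp[pos] = sp_of[t.species]
        t_j[pos] = t.class_index - 1
        t_h[pos] = t.interval_years
        t_n[pos] = t.n_all
        t_y1[pos] = t.n_survivors
        t_y2[pos] = t.n_st + t.n_pr
        t_y3[pos] = t.n_st
    class_start = np.searchsorted(t_j, np.arange(C + 1))

    cell_t = np.array([t for t, _ in cells], dtype=np.int64)
    cell_j = np.array([i - 1 for _, i in cells], dtype=np.int64)

    hyper_fixed = fix_mu is not None or fix_sigma2 is not None
    if hyper_fixed and (fix_mu is None or fix_sigma2 is None):
        raise ValueError("fix_mu and fix_sigma2 must be given together")
    mu0 = np.full(n_cells, fix_mu if hyper_fixed else config.init_mu)
    prec0 = np.full(n_cells, 1.0 / fix_sigma2 if hyper_fixed else config.init_prec)

    n_sp_params = int(smask.sum())
    n_params = n_sp_params + 2 * n_cells
    n_draws = config.n_draws_per_chain
    if n_draws < 1:
        raise ValueError("chain settings retain no draws")

    draws = np.empty((config.n_chains, n_draws, n_params))
    base = int(config.seed) % (2**31 - 1)
    for chain in range(config.n_chains):
        chain_seed = (base + 1_000_003 * chain) % (2**31 - 1)
        draws[chain] = _kernel.run_chain(
            chain_seed,
            config.n_steps,
            config.n_burnin,
            config.thin,
            C,
            K,
            cell_t,
            cell_j,
            smask,
            fixed_mask,
            fixed_val,
            float(config.init_logit_p),
            mu0.copy(),
            prec0.copy(),
            hyper_fixed,
            config.prior_mu_mean,
            config.prior_mu_var,
            config.prior_prec_shape,
            config.prior_prec_rate,
            t_sp,
            t_j,
            t_h,
            t_n,
            t_y1,
            t_y2,
            t_y3,
            class_start,
            n_draws,
            n_params,
        )

    names: list[str] = []
    sp_col: dict[tuple[int, int, int], int] = {}
    col = 0
    for c, (t, i) in enumerate(cells):
        lab = scheme.label_of(i)
        for k, sp in enumerate(species):
            if smask[c, k]:
                names.append(f"logit_p_{TYPE_NAMES[t]}[{lab},{sp}]")
                sp_col[(t, i, k)] = col
                col += 1
    for t, i in cells:
        names.append(f"mu_{TYPE_NAMES[t]}[{scheme.label_of(i)}]")
    for t, i in cells:
        names.append(f"prec_{TYPE_NAMES[t]}[{scheme.label_of(i)}]")

    return PosteriorDraws(
        param_names=names,
        draws=draws,
        scheme=scheme,
        species=species,
        cells=cells,
        sp_col=sp_col,
        config=config,
        enforce_species_max=enforce_species_max,
    )


def ci_coverage(
    draws: PosteriorDraws, true_rates: AnnualRates, level: float = 0.9
) -> tuple[int, int]:
    """Count equal-tailed credible intervals covering planted annual rates.

    Returns (covered, total) over every identifiable rate element within
    each species' maximum class: S at classes 2..max, G at 1..max-1 and R
    at the retrogression-capable classes.  Structural zeros are excluded
    (they are not estimated).
    """
    if tuple(true_rates.species) != tuple(draws.species):
        raise ValueError("species mismatch between draws and truth")
    scheme = draws.scheme
    S, G, R = draws.rate_draws()
    alpha = (1.0 - level) / 2.0
    covered = total = 0
    for k, sp in enumerate(draws.species):
        m = scheme.max_class(sp)
        elements: list[tuple[np.ndarray, np.ndarray, int]] = []
        elements += [(S, true_rates.S, i) for i in range(2, m + 1)]
        elements += [(G, true_rates.G, i) for i in range(1, m)]
        elements += [
            (R, true_rates.R, i) for i in sorted(scheme.retro_classes) if i <= m
        ]
        for arr, truth, i in elements:
            lo, hi = np.quantile(arr[:, k, i - 1], [alpha, 1.0 - alpha])
            total += 1
            covered += bool(lo <= truth[k, i - 1] <= hi)
    return covered, total


def gelman_rubin(draws: np.ndarray) -> np.ndarray:
    """Classical potential-scale-reduction factor, per parameter.

    ``draws`` has shape (n_chains, n_iterations, n_params).  Parameters
    with zero within-chain variance are flagged with NaN rather than
    raising; a parameter identical across all chains and iterations is
    returned as exactly 1.
    """
    draws = np.asarray(draws, float)
    if draws.ndim == 2:
        draws = draws[:, :, None]
    if draws.ndim != 3 or draws.shape[0] < 2 or draws.shape[1] < 2:
        raise ValueError("need >= 2 chains and >= 2 draws per chain")
    m, n, _ = draws.shape
    chain_means = draws.mean(axis=1)
    W = draws.var(axis=1, ddof=1).mean(axis=0)
    B = n * chain_means.var(axis=0, ddof=1)
    var_plus = (n - 1) / n * W + B / n
    with np.errstate(divide="ignore", invalid="ignore"):
        rhat = np.sqrt(var_plus / W)
    degenerate = W == 0
    rhat[degenerate] = np.where(B[degenerate] == 0, 1.0, np.nan)
    return rhat
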