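"""Seeded synthetic-data generators for every pipeline stage.

Two generators: an individual-based census simulator producing survey
histories under known annual rates on mixed 1/2/4-year survey schedules
(so tallying, model fitting and the derived summaries can all be tested
against planted truth), and a bivariate Brownian-motion trait simulator on
a phylogeny (so the comparative stage can be tested against planted
evolutionary correlations).

Census simulation runs in one of two modes.  ``mechanistic`` steps every
stem annually through a multinomial over (stasis, progression,
retrogression, death) and records it only at its survey years, so
multi-year observations genuinely aggregate yearly moves -- including the
down-then-up paths the fitted model's linking deliberately drops.
``model-exact`` draws each multi-year outcome directly from the linked
interval probabilities, making the fitted model exactly correctly
specified; parameter-recovery checks use this mode.

Each simulated stem keeps, for life, the survey schedule of the class
group it occupied at recruitment (seedling classes yearly; sapling and
juvenile at the quadrat survey years; DBH classes at the plot survey
years).  This guarantees every consecutive observation interval is 1, 2
or 4 years, which the tally reducer requires.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .census import IndividualHistory, Observation
from .rates import AnnualRates, link_interval
from .scheme import OGAWA_MAX_CLASS, SizeClassScheme, ogawa_scheme

#: quadrat survey years for the sapling/juvenile group
QUADRAT_YEARS = (1987, 1989, 1990, 1992, 1994, 1996, 2000, 2004)
#: plot survey years for the DBH classes
PLOT_YEARS = (1987, 1989, 1991, 1993, 1997, 2001, 2005)
#: yearly seedling surveys
SEEDLING_YEARS = tuple(range(1987, 1998))


@dataclass(frozen=True)
class SimConfig:
    """Inputs of one census simulation.

    ``initial_counts`` maps (species, class index) to the standing count at
    the first survey; ``recruit_rates`` maps (species, class index) to a
    Poisson rate of new recruits per year, tagged at the entry class's next
    survey.  ``schedules`` maps each class index to its survey-year tuple.
    """

    scheme: SizeClassScheme
    true_rates: AnnualRates
    initial_counts: Mapping[tuple[str, int], int]
    schedules: Mapping[int, tuple[int, ...]]
    recruit_rates: Mapping[tuple[str, int], float] = field(default_factory=dict)
    seed: int = 0
    mode: str = "mechanistic"

    def __post_init__(self) -> None:
        if self.mode not in ("mechanistic", "model-exact"):
            raise ValueError("mode must be 'mechanistic' or 'model-exact'")
        for i in range(1, self.scheme.n_classes + 1):
            years = self.schedules.get(i)
            if not years or len(years) < 2:
                raise ValueError(f"class {i} needs at least two survey years")
            gaps = {b - a for a, b in zip(years, years[1:])}
            if not gaps <= {1, 2, 4}:
                raise ValueError(
                    f"class {i} schedule has gaps {sorted(gaps - {1, 2, 4})}; "
                    "only 1-, 2- and 4-year intervals are supported"
                )
        for (sp, i), n in self.initial_counts.items():
            if n < 0:
                raise ValueError("initial counts must be non-negative")
            if i > self.scheme.max_class(sp):
                raise ValueError(
                    f"initial count above the maximum class of {sp}"
                )


def default_schedules(scheme: SizeClassScheme) -> dict[int, tuple[int, ...]]:
    """Survey years per class: seedlings yearly, then quadrat, then plot."""
    out: dict[int, tuple[int, ...]] = {}
    for i in range(1, scheme.n_classes + 1):
        if i <= 2:
            out[i] = SEEDLING_YEARS
        elif i in (3, 4):
            out[i] = QUADRAT_YEARS
        else:
            out[i] = PLOT_YEARS
    return out


def _interval_probs(rates: AnnualRates, mode: str) -> dict[int, tuple[np.ndarray, np.ndarray, np.ndarray]]:
    if mode == "model-exact":
        return {h: link_interval(rates, h) for h in (1, 2, 4)}
    return {1: link_interval(rates, 1)}


def simulate_population(config: SimConfig) -> list[IndividualHistory]:
    """Simulate tagged stems through their survey schedules.

    Returns one history per stem (initial stems plus Poisson recruits),
    each observed at its schedule's survey years until death; the first
    post-death survey records the death and observation stops.
    Reproducible given ``config.seed``.
    """
    rates = config.true_rates
    rates.validate()
    scheme = config.scheme
    rng = np.random.default_rng(config.seed)
    C = scheme.n_classes
    linked = _interval_probs(rates, config.mode)
    histories: list[IndividualHistory] = []

    for k, sp in enumerate(rates.species):
        cohorts: list[tuple[int, int, int]] = []  # (entry year, class, count)
        for i in range(1, C + 1):
            years = config.schedules[i]
            n0 = int(config.initial_counts.get((sp, i), 0))
            if n0:
                cohorts.append((years[0], i, n0))
            rate = float(config.recruit_rates.get((sp, i), 0.0))
            if rate > 0:
                for a, b in zip(years, years[1:]):
                    n = int(rng.poisson(rate * (b - a)))
                    if n:
                        cohorts.append((b, i, n))
        serial = 0
        for entry_year, entry_class, count in cohorts:
            years = [y for y in config.schedules[entry_class] if y >= entry_year]
            if len(years) < 2:
                continue
            state = np.full(count, entry_class, dtype=np.int64)  # 0 == dead
            obs: list[list[Observation]] = [
                [Observation(years[0], True, entry_class)] for _ in range(count)
            ]
            done = np.zeros(count, dtype=bool)
            for y0, y1 in zip(years, years[1:]):
                dt = y1 - y0
                if config.mode == "model-exact":
                    state = _step_linked(rng, state, k, linked[dt], C)
                else:
                    # anchor at the last observation: net displacement within
                    # one observation interval is held to one class, matching
                    # the one-step regime the tally reduction requires
                    anchor = state.copy()
                    for _ in range(dt):
                        state = _step_linked(rng, state, k, linked[1], C)
                        live = state > 0
                        state[live] = np.clip(
                            state[live],
                            np.maximum(anchor[live] - 1, 1),
                            np.minimum(anchor[live] + 1, C),
                        )
                for idx in np.nonzero(~done)[0]:
                    if state[idx] == 0:
                        obs[idx].append(Observation(y1, False, None))
                        done[idx] = True
                    else:
                        obs[idx].append(Observation(y1, True, int(state[idx])))
            for idx in range(count):
                serial += 1
                histories.append(
                    IndividualHistory(f"{sp}:{entry_year}:{serial}", sp, tuple(obs[idx]))
                )
    return histories


def _step_linked(
    rng: np.random.Generator,
    state: np.ndarray,
    k: int,
    linked: tuple[np.ndarray, np.ndarray, np.ndarray],
    C: int,
) -> np.ndarray:
    """One observation-interval move for every live stem of one species."""
    S, G, R = linked
    new = state.copy()
    for c in range(1, C + 1):
        idx = np.nonzero(state == c)[0]
        if idx.size == 0:
            continue
        j = c - 1
        p = np.array([S[k, j], G[k, j], R[k, j]])
        p = np.append(p, max(0.0, 1.0 - p.sum()))
        outcome = rng.choice(4, size=idx.size, p=p / p.sum())
        new[idx[outcome == 0]] = c
        new[idx[outcome == 1]] = min(c + 1, C)
        new[idx[outcome == 2]] = max(c - 1, 1)
        new[idx[outcome == 3]] = 0
    return new


# ---------------------------------------------------------------------------
# the reference-plot-like default configuration

#: Table-magnitude total sample sizes (new seedling, aged seedling, sapling,
#: juvenile, DBH classes pooled) for the 17 focal species
OGAWA_SAMPLE_SIZES: dict[str, tuple[int, int, int, int, int]] = {
    "Betula_grossa": (2847, 175, 3, 0, 227),
    "Carpinus_cordata": (1001, 85, 296, 304, 3088),
    "Carpinus_japonica": (470, 7, 3, 0, 362),
    "Carpinus_tschonoskii": (5319, 21, 30, 16, 565),
    "Carpinus_laxiflora": (7090, 74, 71, 98, 3020),
    "Fagus_crenata": (357, 260, 2213, 569, 693),
    "Fagus_japonica": (2273, 96, 493, 192, 3947),
    "Quercus_crispula": (48, 18, 27, 0, 275),
    "Quercus_serrata": (1896, 348, 15, 0, 1833),
    "Castanea_crenata": (87, 42, 13, 0, 371),
    "Cerasus_leveilleana": (171, 48, 27, 2, 459),
    "Acer_amoenum": (2047, 385, 992, 333, 2896),
    "Acer_rufinerve": (558, 441, 454, 32, 471),
    "Acer_pictum": (6237, 763, 548, 56, 985),
    "Swida_controversa": (2092, 103, 96, 11, 823),
    "Kalopanax_septemlobus": (300, 33, 129, 84, 104),
    "Styrax_obassia": (359, 113, 5, 39, 3191),
}

# logit-scale hyperparameter means of the planted truth: a U-shaped
# survival curve over the ladder, conditional stay probabilities rising
# with size, and high stay-or-advance (little retrogression)
_TEMPLATE_P_SV = (0.45, 0.75, 0.88, 0.94, 0.96, 0.975, 0.985, 0.993, 0.994, 0.992, 0.99, 0.99)
_TEMPLATE_P_ST = (None, 0.80, 0.85, 0.88, 0.90, 0.92, 0.93, 0.94, 0.95, 0.96, 0.96, None)
_TEMPLATE_P_STPR = {3: 0.95, 4: 0.96}
#: logit-scale species scatter around the templates; chosen to match the
#: model's Gamma(100, 100) precision hyperprior (precision concentrated at 1)
_SPECIES_SIGMA = 1.0


def _logit(p: float) -> float:
    return float(np.log(p) - np.log1p(-p))


def _expit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30, 30)))


def make_ogawa_rates(seed: int, scheme: SizeClassScheme | None = None) -> AnnualRates:
    """Planted annual rates for the 17 pseudo-species.

    Species-level logit conditionals scatter around U-shaped-mortality
    templates with standard deviation 1; structural zeros (class 1, species
    maxima, non-retrogression classes) are imposed exactly.
    """
    scheme = scheme or ogawa_scheme()
    rng = np.random.default_rng(seed)
    species = tuple(sorted(OGAWA_SAMPLE_SIZES))
    K, C = len(species), scheme.n_classes
    p_sv = _expit(
        np.array([[_logit(_TEMPLATE_P_SV[j]) for j in range(C)]] * K)
        + _SPECIES_SIGMA * rng.standard_normal((K, C))
    )
    p_st = np.ones((K, C))
    for j in range(C):
        if _TEMPLATE_P_ST[j] is not None:
            p_st[:, j] = _expit(
                _logit(_TEMPLATE_P_ST[j]) + _SPECIES_SIGMA * rng.standard_normal(K)
            )
    p_st[:, 0] = 0.0
    p_stpr = np.ones((K, C))
    for i, tmpl in _TEMPLATE_P_STPR.items():
        if i in scheme.retro_classes:
            p_stpr[:, i - 1] = _expit(
                _logit(tmpl) + _SPECIES_SIGMA * rng.standard_normal(K)
            )
    for k, sp in enumerate(species):
        p_st[k, scheme.max_class(sp) - 1] = 1.0
    S = p_sv * p_stpr * p_st
    G = p_sv * p_stpr * (1.0 - p_st)
    R = p_sv * (1.0 - p_stpr)
    return AnnualRates(species, scheme, S, G, R)


def make_ogawa_like_config(
    seed: int,
    count_scale: float = 1.0,
    mode: str = "model-exact",
) -> SimConfig:
    """A 17-species, 12-class configuration at reference-plot magnitudes.

    Standing counts are the tabulated total sample sizes divided by the
    number of observation pairs in each class group's schedule (totals pool
    survey replicates), with the pooled DBH count spread down the ladder
    geometrically to each species' maximum class.  Seedling recruitment
    keeps the annual new-seedling cohort roughly stationary.  Identical
    seeds give identical configurations.
    """
    scheme = ogawa_scheme()
    rates = make_ogawa_rates(seed, scheme)
    schedules = default_schedules(scheme)
    initial: dict[tuple[str, int], int] = {}
    recruits: dict[tuple[str, int], float] = {}
    n_pairs = {i: len(schedules[i]) - 1 for i in schedules}
    for sp, (ns, asd, sap, juv, d_total) in OGAWA_SAMPLE_SIZES.items():
        m = scheme.max_class(sp)
        per_class = {1: ns / (n_pairs[1] + 1), 2: asd / n_pairs[2], 3: sap / n_pairs[3], 4: juv / n_pairs[4]}
        d_classes = list(range(5, m + 1))
        weights = np.array([0.55**q for q in range(len(d_classes))])
        weights /= weights.sum()
        for i, w in zip(d_classes, weights):
            per_class[i] = d_total * w / n_pairs[i]
        for i, n in per_class.items():
            n_scaled = int(round(n * count_scale))
            if n_scaled > 0:
                initial[(sp, i)] = n_scaled
        r1 = per_class[1] * count_scale
        if r1 > 0:
            recruits[(sp, 1)] = r1
        # the survey protocol also tags new sapling and new large-stem
        # recruits; replace each entry class's annual outflow to keep
        # occupancy roughly stationary
        k = sorted(OGAWA_SAMPLE_SIZES).index(sp)
        for i in (3, 5):
            if i > m or per_class.get(i, 0) <= 0:
                continue
            leave = 1.0 - rates.S[k, i - 1]
            r = per_class[i] * leave * count_scale
            if r > 0:
                recruits[(sp, i)] = r
    return SimConfig(
        scheme=scheme,
        true_rates=rates,
        initial_counts=initial,
        schedules=schedules,
        recruit_rates=recruits,
        seed=seed,
        mode=mode,
    )


def random_tree(n_tips: int, seed: int = 0, prefix: str = "t") -> str:
    """Random bifurcating ultrametric-ish Newick tree with branch lengths.

    Built by repeated random joins with exponential waiting heights, so the
    topology is coalescent-like; deterministic given the seed.  Returns a
    Newick string (parse with :func:`treedemog.read_newick`).
    """
    if n_tips < 3:
        raise ValueError("need at least 3 tips")
    rng = np.random.default_rng(seed)
    nodes = [(f"{prefix}{q}", 0.0) for q in range(n_tips)]
    height = 0.0
    while len(nodes) > 1:
        height += float(rng.exponential(1.0 / len(nodes)))
        a, b = rng.choice(len(nodes), size=2, replace=False)
        (na, ha), (nb, hb) = nodes[a], nodes[b]
        merged = (f"({na}:{height - ha:.10f},{nb}:{height - hb:.10f})", height)
        nodes = [nd for q, nd in enumerate(nodes) if q not in (a, b)] + [merged]
    return nodes[0][0] + ";"


# ---------------------------------------------------------------------------
# correlated trait pairs on a phylogeny


@dataclass(frozen=True)
class TraitSimConfig:
    """Bivariate Brownian-motion trait simulation on a lambda-scaled tree."""

    tree: object  # dendropy.Tree
    lam: float = 1.0
    rate: float = 1.0
    target_corr: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError("lambda must lie in [0, 1]")
        if abs(self.target_corr) > 1.0:
            raise ValueError("|target_corr| must not exceed 1")
        if self.rate <= 0:
            raise ValueError("rate must be positive")


def simulate_traits(config: TraitSimConfig) -> tuple[dict[str, float], dict[str, float]]:
    """Two traits from a bivariate BM with the requested evolutionary correlation.

    Tip values are multivariate normal with covariance
    ``rate * kron([[1, rho], [rho, 1]], C_lambda)`` where ``C_lambda`` is
    the tip covariance with off-diagonals scaled by lambda.  Over
    replicates the PIC correlation of the pair converges to
    ``target_corr`` (exactly, when lambda = 1).
    """
    from .phylo import tip_covariance  # local import to avoid a cycle

    labels, C = tip_covariance(config.tree)
    n = len(labels)
    Clam = config.lam * C
    np.fill_diagonal(Clam, np.diag(C))
    jitter = 1e-10 * np.trace(Clam) / n
    L = np.linalg.cholesky(Clam + jitter * np.eye(n))
    rho = config.target_corr
    cross = np.linalg.cholesky(np.array([[1.0, rho], [rho, 1.0]]) + 1e-15 * np.eye(2))
    rng = np.random.default_rng(config.seed)
    Z = rng.standard_normal((n, 2)) @ cross.T
    X = np.sqrt(config.rate) * (L @ Z)
    return (
        {lab: float(X[q, 0]) for q, lab in enumerate(labels)},
        {lab: float(X[q, 1]) for q, lab in enumerate(labels)},
    )
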