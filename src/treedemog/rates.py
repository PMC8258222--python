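"""Annual stasis/progression/retrogression rates and their conditional form.

The estimands are, per species and size class, the annual probabilities of
stasis ``S`` (alive, same class one year on), progression ``G`` (alive, one
class up) and retrogression ``R`` (alive, one class down).  The model never
works on (S, G, R) directly but on an equivalent triple of sequential
conditional probabilities,

    p_sv      = P(survive the year)            = S + G + R
    p_stpr_sv = P(stay or advance | survive)   = (S + G) / (S + G + R)
    p_st_stpr = P(stay | stay or advance)      = S / (S + G)

each of which is a free probability in [0, 1], so logit-scale sampling keeps
every draw a valid rate triple by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .scheme import SizeClassScheme


@dataclass(frozen=True)
class ConditionalTriple:
    """Survival and the two nested conditionals at a given horizon."""

    p_sv: float
    p_stpr_sv: float
    p_st_stpr: float
    horizon_years: int = 1

    def __post_init__(self) -> None:
        for name in ("p_sv", "p_stpr_sv", "p_st_stpr"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.horizon_years not in (1, 2, 4):
            raise ValueError("horizon must be 1, 2 or 4 years")


def rates_from_conditionals(c: ConditionalTriple) -> tuple[float, float, float]:
    """(S, G, R) implied by a conditional triple."""
    s = c.p_sv * c.p_stpr_sv * c.p_st_stpr
    g = c.p_sv * c.p_stpr_sv * (1.0 - c.p_st_stpr)
    r = c.p_sv * (1.0 - c.p_stpr_sv)
    return s, g, r


def conditionals_from_rates(s: float, g: float, r: float, horizon_years: int = 1) -> ConditionalTriple:
    """Invert (S, G, R) to the conditional triple.

    Zero-probability branches get the harmless conventions p_stpr_sv = 1
    when nothing survives and p_st_stpr = 1 when no survivor stays-or-moves-up,
    so the sampler never meets an undefined conditional.
    """
    if min(s, g, r) < 0 or s + g + r > 1 + 1e-12:
        raise ValueError(f"invalid rate triple ({s}, {g}, {r})")
    p_sv = s + g + r
    p_stpr = (s + g) / p_sv if p_sv > 0 else 1.0
    p_st = s / (s + g) if s + g > 0 else 1.0
    return ConditionalTriple(p_sv, min(p_stpr, 1.0), min(p_st, 1.0), horizon_years)


@dataclass
class AnnualRates:
    """Per-species x per-class annual rates as dense arrays.

    Arrays are shaped ``(n_species, n_classes)``; column ``j`` holds class
    index ``j + 1``.  Cells above a species' maximum class are simply unused
    by the likelihood and the simulator.
    """

    species: tuple[str, ...]
    scheme: SizeClassScheme
    S: np.ndarray
    G: np.ndarray
    R: np.ndarray

    def __post_init__(self) -> None:
        self.species = tuple(self.species)
        shape = (len(self.species), self.scheme.n_classes)
        for name in ("S", "G", "R"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != shape:
                raise ValueError(f"{name} must have shape {shape}, got {arr.shape}")
            setattr(self, name, arr)
        self.validate()

    def validate(self) -> None:
        S, G, R = self.S, self.G, self.R
        if (S < 0).any() or (G < 0).any() or (R < 0).any():
            raise ValueError("rates must be non-negative")
        if (S + G + R > 1 + 1e-9).any():
            raise ValueError("S + G + R must not exceed 1")
        n = self.scheme.n_classes
        non_retro = [j for j in range(n) if (j + 1) not in self.scheme.retro_classes]
        if R[:, non_retro].any():
            raise ValueError("retrogression outside retrogression-capable classes")
        if S[:, 0].any() or R[:, 0].any():
            raise ValueError("class 1 allows progression or death only")
        for k, sp in enumerate(self.species):
            m = self.scheme.max_class(sp)
            if G[k, m - 1] != 0:
                raise ValueError(f"progression from the maximum class of {sp}")

    def index_of(self, species: str) -> int:
        return self.species.index(species)


def link_one_step(
    S: np.ndarray, G: np.ndarray, R: np.ndarray, drop_third_term: bool = True
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Compose per-class one-interval rates into two-interval rates.

    ``S``, ``G``, ``R`` are arrays whose last axis indexes classes 1..C.
    Composition over two intervals, with out-of-ladder neighbours
    contributing structural zeros:

        S2_i = S_i^2 + G_i R_{i+1}  (+ R_i G_{i-1}, dropped by default)
        G2_i = S_i G_i + G_i S_{i+1}
        R2_i = R_i S_{i-1} + S_i R_i

    The dropped third term of S2 mirrors the model's simplification that a
    stem does not leave its class and return within one observation
    interval via the class below; the exact two-step enumeration differs
    from the simplified S2 by exactly ``R_i * G_{i-1}``.
    """
    S = np.asarray(S, float)
    G = np.asarray(G, float)
    R = np.asarray(R, float)
    up = lambda a: np.concatenate([a[..., 1:], np.zeros_like(a[..., :1])], axis=-1)
    dn = lambda a: np.concatenate([np.zeros_like(a[..., :1]), a[..., :-1]], axis=-1)
    S2 = S * S + G * up(R)
    if not drop_third_term:
        S2 = S2 + R * dn(G)
    G2 = S * G + G * up(S)
    R2 = R * dn(S) + S * R
    return S2, G2, R2


def link_interval(
    rates: AnnualRates, horizon_years: int, drop_third_term: bool = True
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Rates over a 1-, 2- or 4-year observation interval.

    The 4-year rates apply the two-interval composition to the 2-year
    rates, exactly as the likelihood links mixed-interval censuses to the
    annual estimands.
    """
    S, G, R = rates.S, rates.G, rates.R
    if horizon_years == 1:
        return S.copy(), G.copy(), R.copy()
    S2, G2, R2 = link_one_step(S, G, R, drop_third_term)
    if horizon_years == 2:
        return S2, G2, R2
    if horizon_years == 4:
        return link_one_step(S2, G2, R2, drop_third_term)
    raise ValueError("horizon must be 1, 2 or 4 years")
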