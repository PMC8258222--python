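"""Phylogenetic comparative analysis of class-specific demographic traits.

Implements the cross-species stage of the pipeline: logit transformation
of per-class survivorship and growth, Felsenstein's phylogenetically
independent contrasts (PIC), Pagel's lambda phylogenetic-signal test, and
Pearson correlation tests with and without phylogenetic information,
including the species filters (minimum per-class sample size; growth
undefined at the entry class and at a species' maximum class).

Trees are handled with dendropy; tip labels are preserved verbatim
(underscores are not rewritten).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy import stats

from .census import TransitionTally
from .scheme import SizeClassScheme

#: probabilities are clamped to [EPS, 1-EPS] before the logit; hierarchical
#: shrinkage makes exact 0/1 essentially impossible in real output, but
#: synthetic edge cases must not produce infinities
LOGIT_EPS = 1e-6

#: zero-length terminal branches get this added before PIC standardization
ZERO_BRANCH_EPS = 1e-8


def logit(p, eps: float = LOGIT_EPS):
    """log(p / (1-p)) with clamping to [eps, 1-eps]."""
    p = np.clip(np.asarray(p, dtype=float), eps, 1.0 - eps)
    out = np.log(p) - np.log1p(-p)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# tree IO


def read_newick(source: str | Path) -> dendropy.Tree:
    """Parse a Newick tree from a string or file path, labels verbatim."""
    text = None
    if isinstance(source, Path):
        text = source.read_text()
    elif isinstance(source, str):
        s = source.strip()
        if s.endswith(";") or "(" in s:
            text = source
        else:
            text = Path(source).read_text()
    try:
        return dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise ValueError(f"Newick parse failure: {exc}") from exc


def write_newick(tree: dendropy.Tree, path: str | Path | None = None) -> str:
    text = tree.as_string(
        schema="newick", suppress_rooting=True, unquoted_underscores=True
    ).strip()
    if path is not None:
        Path(path).write_text(text + "\n")
    return text


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def _pruned_clone(tree: dendropy.Tree, keep: Sequence[str]) -> dendropy.Tree:
    present = set(tip_labels(tree))
    missing = sorted(set(keep) - present)
    if missing:
        raise ValueError(f"species absent from the tree: {missing}")
    clone = tree.clone(depth=1)
    clone.retain_taxa_with_labels(list(keep))
    clone.suppress_unifurcations()
    return clone


def has_polytomy(tree: dendropy.Tree) -> bool:
    return any(len(nd.child_nodes()) > 2 for nd in tree.preorder_node_iter())


def tip_covariance(
    tree: dendropy.Tree, taxa: Sequence[str] | None = None
) -> tuple[list[str], np.ndarray]:
    """Brownian-motion tip covariance (shared root-to-MRCA path lengths)."""
    labels = list(taxa) if taxa is not None else tip_labels(tree)
    work = _pruned_clone(tree, labels)
    depth: dict[int, float] = {}
    leaf_of: dict[str, dendropy.Node] = {}
    for nd in work.preorder_node_iter():
        parent = nd.parent_node
        bl = nd.edge.length or 0.0
        depth[id(nd)] = (depth[id(parent)] if parent is not None else 0.0) + (
            bl if parent is not None else 0.0
        )
        if nd.is_leaf():
            leaf_of[nd.taxon.label] = nd
    pdm = work.phylogenetic_distance_matrix()
    n = len(labels)
    C = np.empty((n, n))
    for a in range(n):
        na = leaf_of[labels[a]]
        C[a, a] = depth[id(na)]
        for b in range(a + 1, n):
            nb = leaf_of[labels[b]]
            d = pdm.patristic_distance(na.taxon, nb.taxon)
            C[a, b] = C[b, a] = 0.5 * (depth[id(na)] + depth[id(nb)] - d)
    return labels, C


# ---------------------------------------------------------------------------
# phylogenetically independent contrasts


@dataclass(frozen=True)
class ContrastVector:
    """Standardized independent contrasts with node bookkeeping."""

    contrasts: np.ndarray
    node_ids: tuple[str, ...]
    n_species: int

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "contrasts", np.asarray(self.contrasts, dtype=float)
        )
        if len(self.contrasts) != self.n_species - 1:
            raise ValueError(
                f"{len(self.contrasts)} contrasts for {self.n_species} species; "
                "expected n - 1"
            )


def pic(
    tree: dendropy.Tree,
    traits: Mapping[str, float],
    resolve_polytomies: bool = False,
) -> ContrastVector:
    """Felsenstein's standardized independent contrasts.

    The tree is pruned to the trait species.  At each internal node with
    child values x1, x2 on (adjusted) branch lengths v1, v2 the contrast is
    (x1 - x2) / sqrt(v1 + v2), the node value is the precision-weighted
    mean and the node's parent branch is lengthened by v1*v2/(v1 + v2).
    Polytomies are rejected unless ``resolve_polytomies`` asks for an
    arbitrary zero-length resolution.
    """
    species = sorted(traits)
    if len(species) < 3:
        raise ValueError("PIC needs traits for at least 3 tree tips")
    bad = [s for s in species if not np.isfinite(traits[s])]
    if bad:
        raise ValueError(f"non-finite trait values for {bad}")
    work = _pruned_clone(tree, species)
    if has_polytomy(work):
        if not resolve_polytomies:
            raise ValueError(
                "tree has polytomies; resolve them explicitly or pass "
                "resolve_polytomies=True for an arbitrary zero-length resolution"
            )
        work.resolve_polytomies(limit=2, update_bipartitions=False)
    for nd in work.preorder_node_iter():
        if nd.parent_node is None:
            continue
        if nd.edge.length is None:
            raise ValueError("PIC requires branch lengths on every edge")
        if nd.is_leaf() and nd.edge.length == 0.0:
            nd.edge.length = ZERO_BRANCH_EPS

    values: dict[int, float] = {}
    lengths: dict[int, float] = {}
    contrasts: list[float] = []
    node_ids: list[str] = []
    for nd in work.postorder_node_iter():
        if nd.is_leaf():
            values[id(nd)] = float(traits[nd.taxon.label])
            lengths[id(nd)] = float(nd.edge.length)
            continue
        kids = nd.child_nodes()
        if len(kids) != 2:
            raise ValueError("internal node is not bifurcating after resolution")
        c1, c2 = kids
        x1, x2 = values[id(c1)], values[id(c2)]
        v1, v2 = lengths[id(c1)], lengths[id(c2)]
        vsum = v1 + v2
        if vsum <= 0:
            vsum = ZERO_BRANCH_EPS
        contrasts.append((x1 - x2) / math.sqrt(vsum))
        node_ids.append(
            nd.label or f"node_{min(c1.leaf_nodes()[0].taxon.label, c2.leaf_nodes()[0].taxon.label)}"
        )
        values[id(nd)] = (x1 / v1 + x2 / v2) / (1.0 / v1 + 1.0 / v2) if v1 > 0 and v2 > 0 else 0.5 * (x1 + x2)
        extra = v1 * v2 / vsum
        lengths[id(nd)] = (nd.edge.length or 0.0) + extra
    return ContrastVector(np.asarray(contrasts), tuple(node_ids), len(species))


# ---------------------------------------------------------------------------
# Pagel's lambda


@dataclass(frozen=True)
class LambdaFit:
    """ML estimate of Pagel's lambda with a likelihood-ratio test vs 0."""

    lambda_hat: float
    log_likelihood: float
    lr_stat: float
    p_value: float
    flat_likelihood: bool = False


def _bm_profile_loglik(x: np.ndarray, C: np.ndarray) -> float:
    """BM log-likelihood profiled over the ancestral mean and the rate."""
    n = len(x)
    sign, logdet = np.linalg.slogdet(C)
    if sign <= 0:
        return -np.inf
    Ci = np.linalg.inv(C)
    one = np.ones(n)
    mu = (one @ Ci @ x) / (one @ Ci @ one)
    dev = x - mu
    sigma2 = (dev @ Ci @ dev) / n
    if sigma2 <= 0:
        sigma2 = np.finfo(float).tiny
    return -0.5 * (n * math.log(2 * math.pi * sigma2) + logdet + n)


def _lambda_cov(C: np.ndarray, lam: float) -> np.ndarray:
    out = lam * C
    np.fill_diagonal(out, np.diag(C))
    return out


def pagel_lambda(
    tree: dendropy.Tree,
    traits: Mapping[str, float],
    tol: float = 1e-4,
) -> LambdaFit:
    """Maximum-likelihood Pagel's lambda on [0, 1] by golden-section search.

    Lambda scales the off-diagonal elements of the Brownian-motion tip
    covariance; the likelihood is profiled analytically over the ancestral
    mean and the rate.  The likelihood-ratio test compares the maximized
    likelihood with the star phylogeny (lambda = 0) on one degree of
    freedom.
    """
    species = sorted(traits)
    if len(species) < 4:
        raise ValueError("Pagel's lambda needs at least 4 species")
    _, C = tip_covariance(tree, species)
    x = np.array([traits[s] for s in species], dtype=float)

    def ll(lam: float) -> float:
        return _bm_profile_loglik(x, _lambda_cov(C, lam))

    # golden-section maximization on [0, 1]
    invphi = (math.sqrt(5.0) - 1.0) / 2.0
    a, b = 0.0, 1.0
    c1 = b - invphi * (b - a)
    c2 = a + invphi * (b - a)
    f1, f2 = ll(c1), ll(c2)
    while b - a > tol:
        if f1 >= f2:
            b, c2, f2 = c2, c1, f1
            c1 = b - invphi * (b - a)
            f1 = ll(c1)
        else:
            a, c1, f1 = c1, c2, f2
            c2 = a + invphi * (b - a)
            f2 = ll(c2)
    lam_hat = 0.5 * (a + b)
    ll_hat = ll(lam_hat)
    # snap to an endpoint when the interior optimum is not better
    for endpoint in (0.0, 1.0):
        if ll(endpoint) >= ll_hat:
            lam_hat, ll_hat = endpoint, ll(endpoint)
    ll0 = ll(0.0)
    lr = max(0.0, 2.0 * (ll_hat - ll0))
    p = float(stats.chi2.sf(lr, df=1))
    flat = abs(ll(1.0) - ll0) < 1e-10 and abs(ll(0.5) - ll0) < 1e-10
    return LambdaFit(float(lam_hat), float(ll_hat), float(lr), p, flat)


# ---------------------------------------------------------------------------
# correlation tests


@dataclass(frozen=True)
class CorrTestResult:
    r: float
    p: float
    n_used: int
    method: str

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.r <= 1.0 + 1e-12:
            raise ValueError(f"correlation {self.r} outside [-1, 1]")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"p-value {self.p} outside [0, 1]")


def _pearson_t_test(x: np.ndarray, y: np.ndarray, df: int) -> tuple[float, float]:
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(-1.0, min(1.0, r))
    if df <= 0:
        raise ValueError("not enough points for a correlation test")
    if abs(r) >= 1.0:
        return r, 0.0
    t = r * math.sqrt(df / (1.0 - r * r))
    return r, float(2.0 * stats.t.sf(abs(t), df))


def correlate(
    x: Mapping[str, float],
    y: Mapping[str, float],
    tree: dendropy.Tree | None = None,
    method: str = "raw",
    through_origin: bool = False,
    resolve_polytomies: bool = False,
) -> CorrTestResult:
    """Pearson correlation between two species traits, raw or on PICs.

    raw: ordinary Pearson r over the shared species, two-sided t-test on
    n - 2 degrees of freedom.  pic: Pearson r over the n - 1 standardized
    contrasts with df = (n - 1) - 2 (a through-origin variant with
    df = (n - 1) - 1 is available but non-default).
    """
    shared = sorted(set(x) & set(y))
    if method == "raw":
        if len(shared) < 3:
            raise ValueError("raw correlation needs at least 3 shared species")
        xv = np.array([x[s] for s in shared])
        yv = np.array([y[s] for s in shared])
        r, p = _pearson_t_test(xv, yv, len(shared) - 2)
        return CorrTestResult(r, p, len(shared), "raw")
    if method != "pic":
        raise ValueError(f"unknown method {method!r}; use 'raw' or 'pic'")
    if tree is None:
        raise ValueError("PIC correlation requires a tree")
    if len(shared) < 4:
        raise ValueError("PIC correlation needs at least 4 shared species")
    cx = pic(tree, {s: x[s] for s in shared}, resolve_polytomies).contrasts
    cy = pic(tree, {s: y[s] for s in shared}, resolve_polytomies).contrasts
    k = len(cx)
    if through_origin:
        denom = math.sqrt(float(cx @ cx) * float(cy @ cy))
        r = float(cx @ cy) / denom if denom > 0 else 0.0
        r = max(-1.0, min(1.0, r))
        df = k - 1
        if abs(r) >= 1.0:
            return CorrTestResult(r, 0.0, len(shared), "pic")
        t = r * math.sqrt(df / (1.0 - r * r))
        return CorrTestResult(r, float(2.0 * stats.t.sf(abs(t), df)), len(shared), "pic")
    r, p = _pearson_t_test(cx, cy, k - 2)
    return CorrTestResult(r, p, len(shared), "pic")


# ---------------------------------------------------------------------------
# species filters and the per-class correlation table


def class_sample_sizes(
    tallies: Iterable[TransitionTally], class_index: int
) -> dict[str, int]:
    """Total starters per species at one class, pooled over intervals."""
    out: dict[str, int] = {}
    for t in tallies:
        if t.class_index == class_index:
            out[t.species] = out.get(t.species, 0) + t.n_all
    return out


def filter_species_for_class(
    summary: pd.DataFrame,
    tallies: Iterable[TransitionTally],
    scheme: SizeClassScheme,
    class_index: int,
    min_n: int = 5,
    trait: str = "survivorship",
) -> list[str]:
    """Species eligible for the cross-species test at one class.

    Keeps species with a pooled sample size of at least ``min_n`` at the
    class.  For the growth trait the entry class and each species' maximum
    class are excluded outright, since growth there is structurally 1 and
    0 respectively.
    """
    if trait not in ("survivorship", "growth"):
        raise ValueError("trait must be 'survivorship' or 'growth'")
    if trait == "growth" and class_index == 1:
        return []
    sizes = class_sample_sizes(tallies, class_index)
    in_summary = set(summary.loc[summary["class"] == class_index, "species"])
    keep = []
    for sp in sorted(in_summary):
        if sizes.get(sp, 0) < min_n:
            continue
        if trait == "growth" and scheme.max_class(sp) == class_index:
            continue
        keep.append(sp)
    return keep


def normality_check(values: Sequence[float]) -> tuple[float, float]:
    """Shapiro-Wilk statistic and p-value; rejects constant input."""
    arr = np.asarray(values, dtype=float)
    if len(arr) < 3:
        raise ValueError("normality check needs at least 3 values")
    if np.ptp(arr) == 0:
        raise ValueError("constant input has no defined normality statistic")
    stat, p = stats.shapiro(arr)
    return float(stat), float(p)


def correlation_table(
    summary: pd.DataFrame,
    tallies: Sequence[TransitionTally],
    tree: dendropy.Tree,
    scheme: SizeClassScheme,
    min_n: int = 5,
    resolve_polytomies: bool = False,
) -> pd.DataFrame:
    """Per-class survivorship-growth correlations, with and without PICs.

    Both traits are logit-transformed.  A class is reported when at least
    4 species pass the filters for both traits and are on the tree.
    Columns mirror the standard presentation: class, PIC r and p, raw r
    and p, and the species count used.
    """
    tips = set(tip_labels(tree))
    rows = []
    for i in range(1, scheme.n_classes + 1):
        sv_sp = filter_species_for_class(summary, tallies, scheme, i, min_n, "survivorship")
        gr_sp = filter_species_for_class(summary, tallies, scheme, i, min_n, "growth")
        species = [s for s in sv_sp if s in gr_sp and s in tips]
        sub = summary[(summary["class"] == i) & summary["species"].isin(species)]
        sub = sub.dropna(subset=["survivorship", "growth_index"])
        species = sorted(sub["species"])
        if len(species) < 4:
            continue
        sv = {r.species: logit(r.survivorship) for r in sub.itertuples()}
        gr = {r.species: logit(r.growth_index) for r in sub.itertuples()}
        res_pic = correlate(sv, gr, tree, "pic", resolve_polytomies=resolve_polytomies)
        res_raw = correlate(sv, gr, method="raw")
        rows.append(
            (
                scheme.label_of(i),
                res_pic.r,
                res_pic.p,
                res_raw.r,
                res_raw.p,
                len(species),
            )
        )
    return pd.DataFrame(
        rows, columns=["class", "r_pic", "p_pic", "r_raw", "p_raw", "n"]
    )
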