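"""Compiled Metropolis-within-Gibbs kernel for the transition model.

One chain runs entirely inside :func:`run_chain`.  Proposals for a given
(class, probability-type) cell are made for all species at once; the
likelihood delta of a proposal only touches tallies within two classes of
the updated class (one class for 2-year tallies, none for 1-year), because
interval linking composes at most two neighbours twice.

Binomial coefficients are omitted throughout -- they are constants that
cancel in every Metropolis ratio.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

LOGIT_CLAMP = 30.0


@njit(cache=True, inline="always")
def _sigmoid(x):
    if x > LOGIT_CLAMP:
        x = LOGIT_CLAMP
    elif x < -LOGIT_CLAMP:
        x = -LOGIT_CLAMP
    return 1.0 / (1.0 + math.exp(-x))


@njit(cache=True, inline="always", fastmath=True)
def _get(A, j, k, C, j0, k0, vn):
    """A[j, k] with an out-of-ladder zero and a single-element override."""
    if j < 0 or j >= C:
        return 0.0
    if j == j0 and k == k0:
        return vn
    return A[j, k]


@njit(cache=True, inline="always", fastmath=True)
def _s2(S, G, R, j, k, C, j0, k0, Sn, Gn, Rn):
    s = _get(S, j, k, C, j0, k0, Sn)
    g = _get(G, j, k, C, j0, k0, Gn)
    ru = _get(R, j + 1, k, C, j0, k0, Rn)
    return s * s + g * ru


@njit(cache=True, inline="always", fastmath=True)
def _g2(S, G, R, j, k, C, j0, k0, Sn, Gn, Rn):
    g = _get(G, j, k, C, j0, k0, Gn)
    s = _get(S, j, k, C, j0, k0, Sn)
    su = _get(S, j + 1, k, C, j0, k0, Sn)
    return g * (s + su)


@njit(cache=True, inline="always", fastmath=True)
def _r2(S, G, R, j, k, C, j0, k0, Sn, Gn, Rn):
    r = _get(R, j, k, C, j0, k0, Rn)
    s = _get(S, j, k, C, j0, k0, Sn)
    sd = _get(S, j - 1, k, C, j0, k0, Sn)
    return r * (sd + s)


@njit(cache=True, inline="always", fastmath=True)
def _tally_ll(S, G, R, j, h, k, n, y1, y2, y3, C, j0, k0, Sn, Gn, Rn):
    """Log-likelihood (no binomial coefficients) of one tally cell.

    (Sn, Gn, Rn) override the annual rates at class row ``j0`` for species
    ``k0``; pass j0 = -1 for no override.  Structural pre-validation
    guarantees every needed probability is strictly positive, so fastmath
    is safe here.
    """
    if h == 1:
        sh = _get(S, j, k, C, j0, k0, Sn)
        gh = _get(G, j, k, C, j0, k0, Gn)
        rh = _get(R, j, k, C, j0, k0, Rn)
    elif h == 2:
        sh = _s2(S, G, R, j, k, C, j0, k0, Sn, Gn, Rn)
        gh = _g2(S, G, R, j, k, C, j0, k0, Sn, Gn, Rn)
        rh = _r2(S, G, R, j, k, C, j0, k0, Sn, Gn, Rn)
    else:
        s2a = _s2(S, G, R, j, k, C, j0, k0, Sn, Gn, Rn)
        g2a = _g2(S, G, R, j, k, C, j0, k0, Sn, Gn, Rn)
        r2a = _r2(S, G, R, j, k, C, j0, k0, Sn, Gn, Rn)
        s2u = _s2(S, G, R, j + 1, k, C, j0, k0, Sn, Gn, Rn)
        r2u = _r2(S, G, R, j + 1, k, C, j0, k0, Sn, Gn, Rn)
        s2d = _s2(S, G, R, j - 1, k, C, j0, k0, Sn, Gn, Rn)
        sh = s2a * s2a + g2a * r2u
        gh = g2a * (s2a + s2u)
        rh = r2a * (s2d + s2a)

    psv = sh + gh + rh
    a = sh + gh
    ll = 0.0
    if y1 > 0 or y2 > 0 or y1 - y2 > 0:
        lpsv = math.log(psv)
        if y1 > 0:
            ll += y1 * lpsv
        if y2 > 0:
            ll += y2 * (math.log(a) - lpsv)
        if y1 - y2 > 0:
            ll += (y1 - y2) * (math.log(rh) - lpsv)
    if n - y1 > 0:
        ll += (n - y1) * math.log1p(-psv)
    if y3 > 0 or y2 - y3 > 0:
        la = math.log(a)
        if y3 > 0:
            ll += y3 * (math.log(sh) - la)
        if y2 - y3 > 0:
            ll += (y2 - y3) * (math.log(gh) - la)
    return ll


@njit(cache=True)
def run_chain(
    seed,
    n_steps,
    n_burnin,
    thin,
    C,
    K,
    cell_t,
    cell_j,
    smask,
    fixed_mask,
    fixed_val,
    init_logit,
    mu,
    prec,
    hyper_fixed,
    prior_mu_mean,
    prior_mu_var,
    prior_prec_shape,
    prior_prec_rate,
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
):
    np.random.seed(seed)
    n_cells = cell_t.shape[0]
    n_tally = t_sp.shape[0]

    # state: logits X, effective probabilities P, annual rates S/G/R
    X = np.full((3, C, K), init_logit)
    P = np.empty((3, C, K))
    for t in range(3):
        for j in range(C):
            for k in range(K):
                if fixed_mask[t, j, k]:
                    P[t, j, k] = fixed_val[t, j, k]
                else:
                    P[t, j, k] = _sigmoid(init_logit)
    S = np.empty((C, K))
    G = np.empty((C, K))
    R = np.empty((C, K))
    for j in range(C):
        for k in range(K):
            S[j, k] = P[0, j, k] * P[1, j, k] * P[2, j, k]
            G[j, k] = P[0, j, k] * P[1, j, k] * (1.0 - P[2, j, k])
            R[j, k] = P[0, j, k] * (1.0 - P[1, j, k])

    llcache = np.empty(n_tally)
    for q in range(n_tally):
        llcache[q] = _tally_ll(
            S, G, R, t_j[q], t_h[q], t_sp[q], t_n[q], t_y1[q], t_y2[q], t_y3[q],
            C, -1, -1, 0.0, 0.0, 0.0,
        )

    ls = np.zeros((n_cells, K))  # log proposal scales, per-species moves
    ls2 = np.zeros(n_cells)  # log proposal scales, joint translation moves
    llnew = np.empty(n_tally)
    prop_x = np.empty(K)
    prop_p = np.empty(K)
    prop_S = np.empty(K)
    prop_G = np.empty(K)
    prop_R = np.empty(K)
    dll = np.empty(K)
    acc = np.zeros(K, dtype=np.uint8)

    out = np.empty((n_draws, n_params))
    draw_i = 0

    for it in range(n_steps):
        adapting = it < n_burnin
        gamma = (it + 1.0) ** (-0.6) if adapting else 0.0

        for c in range(n_cells):
            t = cell_t[c]
            j0 = cell_j[c]
            for k in range(K):
                acc[k] = 0
                dll[k] = 0.0
                if smask[c, k]:
                    xo = X[t, j0, k]
                    xn = xo + math.exp(ls[c, k]) * np.random.normal()
                    prop_x[k] = xn
                    pn = _sigmoid(xn)
                    prop_p[k] = pn
                    p0 = pn if t == 0 else P[0, j0, k]
                    p1 = pn if t == 1 else P[1, j0, k]
                    p2 = pn if t == 2 else P[2, j0, k]
                    prop_S[k] = p0 * p1 * p2
                    prop_G[k] = p0 * p1 * (1.0 - p2)
                    prop_R[k] = p0 * (1.0 - p1)

            jlo = j0 - 2
            if jlo < 0:
                jlo = 0
            jhi = j0 + 3
            if jhi > C:
                jhi = C
            lo = class_start[jlo]
            hi = class_start[jhi]
            for q in range(lo, hi):
                k = t_sp[q]
                if not smask[c, k]:
                    continue
                dj = t_j[q] - j0
                if dj < 0:
                    dj = -dj
                h = t_h[q]
                # 1-year tallies depend only on their own class, 2-year on
                # one neighbour, 4-year on two
                if (h == 1 and dj > 0) or (h == 2 and dj > 1):
                    continue
                v = _tally_ll(
                    S, G, R, t_j[q], h, k, t_n[q], t_y1[q], t_y2[q], t_y3[q],
                    C, j0, k, prop_S[k], prop_G[k], prop_R[k],
                )
                llnew[q] = v
                dll[k] += v - llcache[q]

            for k in range(K):
                if not smask[c, k]:
                    continue
                xo = X[t, j0, k]
                xn = prop_x[k]
                dprior = -0.5 * prec[c] * (
                    (xn - mu[c]) ** 2 - (xo - mu[c]) ** 2
                )
                if math.log(np.random.random()) < dprior + dll[k]:
                    acc[k] = 1
                    X[t, j0, k] = xn
                    P[t, j0, k] = prop_p[k]
                    S[j0, k] = prop_S[k]
                    G[j0, k] = prop_G[k]
                    R[j0, k] = prop_R[k]
                if adapting:
                    a = 1.0 if acc[k] else 0.0
                    ls[c, k] += gamma * (a - 0.44)

            for q in range(lo, hi):
                k = t_sp[q]
                if acc[k]:
                    dj = t_j[q] - j0
                    if dj < 0:
                        dj = -dj
                    h = t_h[q]
                    if (h == 1 and dj > 0) or (h == 2 and dj > 1):
                        continue
                    llcache[q] = llnew[q]

            # joint translation move: shift the cell's mean and every
            # species logit together.  The species-level prior terms are
            # invariant, so this recenters the whole hierarchy in one step
            # and cures the slow random-walk drift of data-poor cells.
            # A stride of 3 keeps its cost small; drift times are far
            # longer than 3 sweeps, so the mixing benefit is unchanged.
            if not hyper_fixed and it % 3 == 0:
                delta = math.exp(ls2[c]) * np.random.normal()
                for k in range(K):
                    if smask[c, k]:
                        xn = X[t, j0, k] + delta
                        prop_x[k] = xn
                        pn = _sigmoid(xn)
                        prop_p[k] = pn
                        p0 = pn if t == 0 else P[0, j0, k]
                        p1 = pn if t == 1 else P[1, j0, k]
                        p2 = pn if t == 2 else P[2, j0, k]
                        prop_S[k] = p0 * p1 * p2
                        prop_G[k] = p0 * p1 * (1.0 - p2)
                        prop_R[k] = p0 * (1.0 - p1)
                dtot = 0.0
                for q in range(lo, hi):
                    k = t_sp[q]
                    if not smask[c, k]:
                        continue
                    dj = t_j[q] - j0
                    if dj < 0:
                        dj = -dj
                    h = t_h[q]
                    if (h == 1 and dj > 0) or (h == 2 and dj > 1):
                        continue
                    v = _tally_ll(
                        S, G, R, t_j[q], h, k, t_n[q], t_y1[q], t_y2[q], t_y3[q],
                        C, j0, k, prop_S[k], prop_G[k], prop_R[k],
                    )
                    llnew[q] = v
                    dtot += v - llcache[q]
                mun = mu[c] + delta
                dtot += -0.5 * (
                    (mun - prior_mu_mean) ** 2 - (mu[c] - prior_mu_mean) ** 2
                ) / prior_mu_var
                shift_acc = math.log(np.random.random()) < dtot
                if shift_acc:
                    mu[c] = mun
                    for k in range(K):
                        if smask[c, k]:
                            X[t, j0, k] = prop_x[k]
                            P[t, j0, k] = prop_p[k]
                            S[j0, k] = prop_S[k]
                            G[j0, k] = prop_G[k]
                            R[j0, k] = prop_R[k]
                    for q in range(lo, hi):
                        k = t_sp[q]
                        if not smask[c, k]:
                            continue
                        dj = t_j[q] - j0
                        if dj < 0:
                            dj = -dj
                        h = t_h[q]
                        if (h == 1 and dj > 0) or (h == 2 and dj > 1):
                            continue
                        llcache[q] = llnew[q]
                if adapting:
                    a2 = 1.0 if shift_acc else 0.0
                    ls2[c] += gamma * (a2 - 0.3)

        if not hyper_fixed:
            for c in range(n_cells):
                t = cell_t[c]
                j0 = cell_j[c]
                kc = 0
                sx = 0.0
                for k in range(K):
                    if smask[c, k]:
                        kc += 1
                        sx += X[t, j0, k]
                vpost = 1.0 / (kc * prec[c] + 1.0 / prior_mu_var)
                mpost = vpost * (prec[c] * sx + prior_mu_mean / prior_mu_var)
                mu[c] = mpost + math.sqrt(vpost) * np.random.normal()
                ss = 0.0
                for k in range(K):
                    if smask[c, k]:
                        d = X[t, j0, k] - mu[c]
                        ss += d * d
                prec[c] = np.random.gamma(
                    prior_prec_shape + 0.5 * kc,
                    1.0 / (prior_prec_rate + 0.5 * ss),
                )

        if it >= n_burnin and (it - n_burnin) % thin == 0 and draw_i < n_draws:
            col = 0
            for c in range(n_cells):
                t = cell_t[c]
                j0 = cell_j[c]
                for k in range(K):
                    if smask[c, k]:
                        out[draw_i, col] = X[t, j0, k]
                        col += 1
            for c in range(n_cells):
                out[draw_i, col] = mu[c]
                col += 1
            for c in range(n_cells):
                out[draw_i, col] = prec[c]
                col += 1
            draw_i += 1

    return out
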