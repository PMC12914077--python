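"""Numba kernel for the Metropolis-within-Gibbs sampler.

One call runs one chain on the collapsed-cell representation.  Updates per
sweep:

* scalar random-walk Metropolis for every fixed effect (intercept, individual
  and area coefficients, temporal terms), with incremental linear-predictor
  updates restricted to the cells where the design column is nonzero;
* single-site random-walk Metropolis for each structured effect ``u_j``
  (ICAR full-conditional prior: neighbor mean, variance ``tau_u2 / n_j``)
  and each unstructured effect ``v_j``, touching only that area's cells;
* sum-to-zero re-centering of ``u`` each sweep (for a connected map the mean
  shift is absorbed exactly by the flat-prior intercept, leaving the
  posterior density unchanged);
* conjugate Gibbs draws for both precisions from their Gamma full
  conditionals.

Proposal scales adapt toward a 0.44 acceptance rate during burn-in
(Robbins-Monro on the log scale) and are frozen afterwards, preserving
detailed balance for the retained draws.  State (linear predictor, cell
risks, aggregate risks) is refreshed from scratch periodically to cancel
incremental round-off.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

_PCLIP = 1e-12


@njit(cache=True, inline="always")
def _softplus(x):
    if x > 30.0:
        return x
    return np.log1p(np.exp(x))


@njit(cache=True, inline="always")
def _expit(x):
    if x >= 0.0:
        p = 1.0 / (1.0 + np.exp(-x))
    else:
        e = np.exp(x)
        p = e / (1.0 + e)
    if p < _PCLIP:
        p = _PCLIP
    elif p > 1.0 - _PCLIP:
        p = 1.0 - _PCLIP
    return p


@njit(cache=True, inline="always")
def _ll_agg_one(y, n, s, family):
    # aggregate log-likelihood kernel for one (j,t); constants dropped
    if n <= 0.0:
        return 0.0
    if family == 0:  # binomial
        return y * np.log(s) + (n - y) * np.log1p(-s)
    return y * np.log(n * s) - n * s  # poisson


@njit(cache=True)
def _refresh(W, theta, u, v, area, cjt, f, eta, sp, p, s, JT):
    ncells = eta.shape[0]
    base = W @ theta
    for c in range(ncells):
        e = base[c] + u[area[c]] + v[area[c]]
        eta[c] = e
        sp[c] = _softplus(e)
        p[c] = _expit(e)
    for j in range(JT):
        s[j] = 0.0
    for c in range(ncells):
        s[cjt[c]] += f[c] * p[c]


@njit(cache=True)
def run_chain(
    W, area, cjt, f, yc, nc,
    yjt, njt, cell_start,
    nbr_idx, nbr_ptr, comp, ncomp, rank,
    coef_prec, zmat, gstart, a_u, b_u, a_v, b_v,
    family, use_agg,
    theta0, u0, v0, prec_u0, prec_v0,
    n_iter, burn, thin, seed, target, adapt_int,
):
    np.random.seed(seed)
    ncells, F = W.shape
    J = u0.shape[0]
    T = 1
    if J > 0:
        T = yjt.shape[0] // J
    JT = yjt.shape[0]

    theta = theta0.copy()
    u = u0.copy()
    v = v0.copy()
    prec_u = prec_u0
    prec_v = prec_v0

    # column-sparse view of the design for incremental updates
    colptr = np.zeros(F + 1, dtype=np.int64)
    for pidx in range(F):
        cnt = 0
        for c in range(ncells):
            if W[c, pidx] != 0.0:
                cnt += 1
        colptr[pidx + 1] = colptr[pidx] + cnt
    colidx = np.zeros(colptr[F], dtype=np.int64)
    colw = np.zeros(colptr[F])
    for pidx in range(F):
        pos = colptr[pidx]
        for c in range(ncells):
            if W[c, pidx] != 0.0:
                colidx[pos] = c
                colw[pos] = W[c, pidx]
                pos += 1

    eta = np.zeros(ncells)
    sp = np.zeros(ncells)
    p = np.zeros(ncells)
    s = np.zeros(max(JT, 1))
    _refresh(W, theta, u, v, area, cjt, f, eta, sp, p, s, JT)

    maxcells = 0
    for pidx in range(F):
        if colptr[pidx + 1] - colptr[pidx] > maxcells:
            maxcells = colptr[pidx + 1] - colptr[pidx]
    for j in range(J):
        if cell_start[j + 1] - cell_start[j] > maxcells:
            maxcells = cell_start[j + 1] - cell_start[j]
    e_new = np.zeros(max(maxcells, 1))
    sp_new = np.zeros(max(maxcells, 1))
    p_new = np.zeros(max(maxcells, 1))

    ds = np.zeros(max(JT, 1))
    stamp = np.full(max(JT, 1), -1, dtype=np.int64)
    touched = np.zeros(max(JT, 1), dtype=np.int64)
    cur = 0

    # approximate per-area likelihood information for site-proposal scaling
    info_area = np.zeros(max(J, 1))
    tot_n = 0.0
    tot_y = 0.0
    for c in range(ncells):
        tot_n += nc[c]
        tot_y += yc[c]
    pbar = tot_y / tot_n if tot_n > 0 else 0.5
    if pbar < 0.01:
        pbar = 0.01
    elif pbar > 0.99:
        pbar = 0.99
    for c in range(ncells):
        info_area[area[c]] += nc[c] * pbar * (1.0 - pbar)
    if use_agg == 1:  # the aggregate level roughly doubles the information
        for j in range(J):
            info_area[j] *= 2.0

    nscalar = F + 2 * J
    ls = np.zeros(nscalar)  # log proposal sd, start at sd=1 -> refine below
    for i in range(nscalar):
        ls[i] = np.log(0.5)
    acc_win = np.zeros(nscalar)
    acc_post = np.zeros(nscalar)
    nwin = 0

    # adapted joint move over the fixed-effect block (Haario-style): the
    # proposal covariance is the running posterior covariance scaled by
    # 2.38^2 / F, estimated during burn-in only and frozen afterwards
    tsum = np.zeros(F)
    tprod = np.zeros((F, F))
    tcount = 0.0
    lmat = np.eye(F) * 0.05
    lbs = 0.0  # log scalar multiplier, adapted toward 0.234 acceptance
    bacc_win = 0.0
    bacc_post = 0.0
    bwin = 0
    eta_b = np.zeros(ncells)
    sp_b = np.zeros(ncells)
    p_b = np.zeros(ncells)
    s_b = np.zeros(max(JT, 1))
    zvec = np.zeros(F)

    # gamma/u translation move: shifting an area coefficient by d while
    # subtracting d * (z - zbar) from u and d * zbar from the intercept
    # leaves the linear predictor untouched, so only the priors vote.
    # Decorrelates the area coefficients from the spatial field.
    Q = zmat.shape[1]
    do_trans = 1 if (Q > 0 and ncomp == 1 and J > 1) else 0
    zbar = np.zeros(max(Q, 1))
    if do_trans == 1:
        for q in range(Q):
            acc0 = 0.0
            for j in range(J):
                acc0 += zmat[j, q]
            zbar[q] = acc0 / J
    lsg = np.zeros(max(Q, 1))
    gacc_win = np.zeros(max(Q, 1))
    gacc_post = np.zeros(max(Q, 1))
    gwin = 0
    u_try = np.zeros(J)
    # second translation route through the unstructured field: gamma_q + d,
    # v_j -= d z_jq -- the i.i.d. field absorbs area-intercept shifts freely
    do_trans_v = 1 if (Q > 0 and J > 0) else 0
    lsv = np.zeros(max(Q, 1))
    vacc_win = np.zeros(max(Q, 1))
    vacc_post = np.zeros(max(Q, 1))

    nkeep = (n_iter - burn + thin - 1) // thin
    theta_draws = np.zeros((nkeep, F))
    u_draws = np.zeros((nkeep, J))
    v_draws = np.zeros((nkeep, J))
    tau_draws = np.zeros((nkeep, 2))
    dev_draws = np.zeros(nkeep)
    keep = 0

    for it in range(n_iter):
        # ---- fixed effects -------------------------------------------------
        for pidx in range(F):
            d = np.exp(ls[pidx]) * np.random.normal()
            dll = 0.0
            if coef_prec[pidx] > 0.0:
                th = theta[pidx]
                dll -= 0.5 * coef_prec[pidx] * ((th + d) ** 2 - th * th)
            nt = 0
            lo = colptr[pidx]
            hi = colptr[pidx + 1]
            for idx in range(lo, hi):
                c = colidx[idx]
                en = eta[c] + d * colw[idx]
                spn = _softplus(en)
                e_new[idx - lo] = en
                sp_new[idx - lo] = spn
                dll += yc[c] * (en - eta[c]) - nc[c] * (spn - sp[c])
                if use_agg == 1:
                    pn = _expit(en)
                    p_new[idx - lo] = pn
                    jt = cjt[c]
                    if stamp[jt] != cur:
                        stamp[jt] = cur
                        ds[jt] = 0.0
                        touched[nt] = jt
                        nt += 1
                    ds[jt] += f[c] * (pn - p[c])
            if use_agg == 1:
                for ti in range(nt):
                    jt = touched[ti]
                    sn = s[jt] + ds[jt]
                    if sn < _PCLIP:
                        sn = _PCLIP
                    elif sn > 1.0 - _PCLIP:
                        sn = 1.0 - _PCLIP
                    dll += _ll_agg_one(yjt[jt], njt[jt], sn, family) - _ll_agg_one(
                        yjt[jt], njt[jt], s[jt], family
                    )
            if np.log(np.random.random()) < dll:
                theta[pidx] += d
                for idx in range(lo, hi):
                    c = colidx[idx]
                    eta[c] = e_new[idx - lo]
                    sp[c] = sp_new[idx - lo]
                    if use_agg == 1:
                        p[c] = p_new[idx - lo]
                if use_agg == 1:
                    for ti in range(nt):
                        jt = touched[ti]
                        s[jt] += ds[jt]
                acc_win[pidx] += 1.0
                if it >= burn:
                    acc_post[pidx] += 1.0
            cur += 1

        # ---- joint fixed-effect block moves --------------------------------
        # repeated a few times per sweep: random-walk exploration of the
        # correlated fixed-effect ridge is the mixing bottleneck
        for _rep in range(5 if F > 0 else 0):
            for i in range(F):
                zvec[i] = np.random.normal()
            dtheta = np.exp(lbs) * (lmat @ zvec)
            dll = 0.0
            for i in range(F):
                if coef_prec[i] > 0.0:
                    th = theta[i]
                    dll -= 0.5 * coef_prec[i] * ((th + dtheta[i]) ** 2 - th * th)
            weta = W @ dtheta
            for jt in range(JT):
                s_b[jt] = 0.0
            for c in range(ncells):
                en = eta[c] + weta[c]
                spn = _softplus(en)
                eta_b[c] = en
                sp_b[c] = spn
                dll += yc[c] * (en - eta[c]) - nc[c] * (spn - sp[c])
                if use_agg == 1:
                    pn = _expit(en)
                    p_b[c] = pn
                    s_b[cjt[c]] += f[c] * pn
            if use_agg == 1:
                for jt in range(JT):
                    if njt[jt] > 0.0:
                        sn = s_b[jt]
                        if sn < _PCLIP:
                            sn = _PCLIP
                        elif sn > 1.0 - _PCLIP:
                            sn = 1.0 - _PCLIP
                        s_b[jt] = sn
                        dll += _ll_agg_one(yjt[jt], njt[jt], sn, family) - _ll_agg_one(
                            yjt[jt], njt[jt], s[jt], family
                        )
            if np.log(np.random.random()) < dll:
                for i in range(F):
                    theta[i] += dtheta[i]
                for c in range(ncells):
                    eta[c] = eta_b[c]
                    sp[c] = sp_b[c]
                    p[c] = p_b[c]
                if use_agg == 1:
                    for jt in range(JT):
                        s[jt] = s_b[jt]
                bacc_win += 1.0
                if it >= burn:
                    bacc_post += 1.0
            if it < burn and _rep == 4:
                tcount += 1.0
                for i in range(F):
                    tsum[i] += theta[i]
                    for k in range(F):
                        tprod[i, k] += theta[i] * theta[k]
                if it >= 400 and (it + 1) % 200 == 0 and tcount > 2.0 * F:
                    cov = np.empty((F, F))
                    for i in range(F):
                        mi = tsum[i] / tcount
                        for k in range(F):
                            cov[i, k] = tprod[i, k] / tcount - mi * tsum[k] / tcount
                    scale = 2.38 * 2.38 / F
                    for i in range(F):
                        for k in range(F):
                            cov[i, k] *= scale
                        cov[i, i] += 1e-8 + 1e-3 * scale
                    lmat = np.linalg.cholesky(cov)
                if _rep == 4 and (it + 1) % adapt_int == 0:
                    bwin += 1
                    delta = 4.0 / np.sqrt(bwin)
                    if delta > 0.5:
                        delta = 0.5
                    elif delta < 0.05:
                        delta = 0.05
                    lbs += delta * (bacc_win / (5.0 * adapt_int) - 0.234)
                    bacc_win = 0.0

        # ---- gamma/u translation moves -------------------------------------
        if do_trans == 1:
          for _t in range(3):
            for q in range(Q):
                d = np.exp(lsg[q]) * np.random.normal()
                g = theta[gstart + q]
                dll = -0.5 * coef_prec[gstart + q] * ((g + d) ** 2 - g * g)
                for j in range(J):
                    u_try[j] = u[j] - d * (zmat[j, q] - zbar[q])
                ss_old = 0.0
                ss_new = 0.0
                for j in range(J):
                    for qq in range(nbr_ptr[j], nbr_ptr[j + 1]):
                        k = nbr_idx[qq]
                        if k > j:
                            ss_old += (u[j] - u[k]) ** 2
                            ss_new += (u_try[j] - u_try[k]) ** 2
                dll -= 0.5 * prec_u * (ss_new - ss_old)
                if np.log(np.random.random()) < dll:
                    for j in range(J):
                        u[j] = u_try[j]
                    theta[gstart + q] += d
                    theta[0] -= d * zbar[q]
                    gacc_win[q] += 1.0
                    if it >= burn:
                        gacc_post[q] += 1.0
            if _t == 2 and it < burn and (it + 1) % adapt_int == 0:
                gwin += 1
                delta = 4.0 / np.sqrt(gwin)
                if delta > 0.5:
                    delta = 0.5
                elif delta < 0.05:
                    delta = 0.05
                for q in range(Q):
                    lsg[q] += delta * (gacc_win[q] / (3.0 * adapt_int) - target)
                    gacc_win[q] = 0.0

        # ---- gamma/v translation moves -------------------------------------
        if do_trans_v == 1:
          for _t in range(3):
            for q in range(Q):
                d = np.exp(lsv[q]) * np.random.normal()
                g = theta[gstart + q]
                dll = -0.5 * coef_prec[gstart + q] * ((g + d) ** 2 - g * g)
                for j in range(J):
                    zj = zmat[j, q]
                    if zj != 0.0:
                        vn = v[j] - d * zj
                        dll -= 0.5 * prec_v * (vn * vn - v[j] * v[j])
                if np.log(np.random.random()) < dll:
                    for j in range(J):
                        if zmat[j, q] != 0.0:
                            v[j] -= d * zmat[j, q]
                    theta[gstart + q] += d
                    vacc_win[q] += 1.0
                    if it >= burn:
                        vacc_post[q] += 1.0
            if _t == 2 and it < burn and (it + 1) % adapt_int == 0:
                for q in range(Q):
                    delta = 4.0 / np.sqrt(max(gwin, 1))
                    if delta > 0.5:
                        delta = 0.5
                    elif delta < 0.05:
                        delta = 0.05
                    lsv[q] += delta * (vacc_win[q] / (3.0 * adapt_int) - target)
                    vacc_win[q] = 0.0

        # ---- spatial effects ----------------------------------------------
        for block in range(2):  # 0: structured u, 1: unstructured v
            for j in range(J):
                nj = nbr_ptr[j + 1] - nbr_ptr[j]
                if block == 0 and nj == 0:
                    continue  # isolated areas keep u_j = 0
                sid = F + block * J + j
                # proposal scaled by the current prior-conditional sd so the
                # adapted ratio stays valid as the precisions move
                if block == 0:
                    csd = 1.0 / np.sqrt(prec_u * nj + info_area[j])
                else:
                    csd = 1.0 / np.sqrt(prec_v + info_area[j])
                d = np.exp(ls[sid]) * csd * np.random.normal()
                if block == 0:
                    ubar = 0.0
                    for q in range(nbr_ptr[j], nbr_ptr[j + 1]):
                        ubar += u[nbr_idx[q]]
                    ubar /= nj
                    old = u[j]
                    dll = -0.5 * prec_u * nj * ((old + d - ubar) ** 2 - (old - ubar) ** 2)
                else:
                    old = v[j]
                    dll = -0.5 * prec_v * ((old + d) ** 2 - old * old)
                nt = 0
                lo = cell_start[j]
                hi = cell_start[j + 1]
                for c in range(lo, hi):
                    en = eta[c] + d
                    spn = _softplus(en)
                    e_new[c - lo] = en
                    sp_new[c - lo] = spn
                    dll += yc[c] * (en - eta[c]) - nc[c] * (spn - sp[c])
                    if use_agg == 1:
                        pn = _expit(en)
                        p_new[c - lo] = pn
                        jt = cjt[c]
                        if stamp[jt] != cur:
                            stamp[jt] = cur
                            ds[jt] = 0.0
                            touched[nt] = jt
                            nt += 1
                        ds[jt] += f[c] * (pn - p[c])
                if use_agg == 1:
                    for ti in range(nt):
                        jt = touched[ti]
                        sn = s[jt] + ds[jt]
                        if sn < _PCLIP:
                            sn = _PCLIP
                        elif sn > 1.0 - _PCLIP:
                            sn = 1.0 - _PCLIP
                        dll += _ll_agg_one(yjt[jt], njt[jt], sn, family) - _ll_agg_one(
                            yjt[jt], njt[jt], s[jt], family
                        )
                if np.log(np.random.random()) < dll:
                    if block == 0:
                        u[j] += d
                    else:
                        v[j] += d
                    for c in range(lo, hi):
                        eta[c] = e_new[c - lo]
                        sp[c] = sp_new[c - lo]
                        if use_agg == 1:
                            p[c] = p_new[c - lo]
                    if use_agg == 1:
                        for ti in range(nt):
                            jt = touched[ti]
                            s[jt] += ds[jt]
                    acc_win[sid] += 1.0
                    if it >= burn:
                        acc_post[sid] += 1.0
                cur += 1

        # ---- re-center u (sum-to-zero per component) -----------------------
        if rank > 0:
            if ncomp == 1:
                m = 0.0
                for j in range(J):
                    m += u[j]
                m /= J
                for j in range(J):
                    u[j] -= m
                theta[0] += m  # flat-prior intercept absorbs the shift
            else:
                for cidx in range(ncomp):
                    m = 0.0
                    cnt = 0
                    for j in range(J):
                        if comp[j] == cidx:
                            m += u[j]
                            cnt += 1
                    if cnt > 1:
                        m /= cnt
                        for j in range(J):
                            if comp[j] == cidx:
                                u[j] -= m
                _refresh(W, theta, u, v, area, cjt, f, eta, sp, p, s, JT)

        # ---- Gibbs for the precisions --------------------------------------
        ss_u = 0.0
        for j in range(J):
            for q in range(nbr_ptr[j], nbr_ptr[j + 1]):
                k = nbr_idx[q]
                if k > j:
                    ss_u += (u[j] - u[k]) ** 2
        prec_u = np.random.gamma(a_u + 0.5 * rank, 1.0 / (b_u + 0.5 * ss_u))
        ss_v = 0.0
        for j in range(J):
            ss_v += v[j] * v[j]
        prec_v = np.random.gamma(a_v + 0.5 * J, 1.0 / (b_v + 0.5 * ss_v))

        # ---- adaptation (burn-in only) -------------------------------------
        if it < burn and (it + 1) % adapt_int == 0:
            nwin += 1
            delta = 4.0 / np.sqrt(nwin)
            if delta > 0.5:
                delta = 0.5
            elif delta < 0.05:
                delta = 0.05  # keep tracking slow hyperparameter drift
            for i in range(nscalar):
                ls[i] += delta * (acc_win[i] / adapt_int - target)
                acc_win[i] = 0.0

        # periodic exact refresh against incremental round-off
        if (it + 1) % 1000 == 0:
            _refresh(W, theta, u, v, area, cjt, f, eta, sp, p, s, JT)

        # ---- retain ---------------------------------------------------------
        if it >= burn and (it - burn) % thin == 0:
            for i in range(F):
                theta_draws[keep, i] = theta[i]
            for j in range(J):
                u_draws[keep, j] = u[j]
                v_draws[keep, j] = v[j]
            tau_draws[keep, 0] = 1.0 / prec_u
            tau_draws[keep, 1] = 1.0 / prec_v
            ll = 0.0
            for c in range(ncells):
                ll += yc[c] * eta[c] - nc[c] * sp[c]
            if use_agg == 1:
                for jt in range(JT):
                    if njt[jt] > 0.0:
                        sv = s[jt]
                        if family == 0:
                            ll += (
                                math.lgamma(njt[jt] + 1.0)
                                - math.lgamma(yjt[jt] + 1.0)
                                - math.lgamma(njt[jt] - yjt[jt] + 1.0)
                                + yjt[jt] * np.log(sv)
                                + (njt[jt] - yjt[jt]) * np.log1p(-sv)
                            )
                        else:
                            ll += yjt[jt] * np.log(njt[jt] * sv) - njt[jt] * sv - math.lgamma(
                                yjt[jt] + 1.0
                            )
            dev_draws[keep] = -2.0 * ll
            keep += 1

    post_n = float(n_iter - burn)
    acc_all = np.zeros(nscalar + 1 + Q)
    for i in range(nscalar):
        acc_all[i] = acc_post[i] / post_n if post_n > 0 else 0.0
    acc_all[nscalar] = bacc_post / (5.0 * post_n) if post_n > 0 else 0.0
    for q in range(Q):
        acc_all[nscalar + 1 + q] = gacc_post[q] / post_n if post_n > 0 else 0.0
    return theta_draws, u_draws, v_draws, tau_draws, dev_draws, acc_all, np.exp(ls)
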