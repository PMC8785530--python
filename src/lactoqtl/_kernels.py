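"""Numba kernels for the single-site Gibbs sampler.

The covariate matrices arrive SNP-major (p, n) and column-centred, with
precomputed weighted sums of squares per SNP.  Residual covariance is
diag(sigma2_e / w_i).  Variance components get scaled inverse chi-squared
full conditionals, sampled via gamma draws.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def _inv_chi2(ss, df):
    # scaled inverse chi-squared draw: ss / chi2(df)
    chi2 = 2.0 * np.random.gamma(df / 2.0, 1.0)
    return ss / chi2


@njit(cache=True, fastmath=True)
def _update_effects(M, xtx, active, w, e, eff, var_eff, var_e):
    # M arrives SNP-major float32; accumulation stays float64
    p, n = M.shape
    for j in range(p):
        if not active[j]:
            continue
        old = eff[j]
        rhs = 0.0
        for i in range(n):
            rhs += w[i] * M[j, i] * e[i]
        rhs += xtx[j] * old
        lhs = xtx[j] + var_e / var_eff
        mean = rhs / lhs
        new = mean + np.random.normal() * np.sqrt(var_e / lhs)
        diff = new - old
        if diff != 0.0:
            for i in range(n):
                e[i] -= M[j, i] * diff
        eff[j] = new


@njit(cache=True)
def gibbs_bayesc0_kernel(
    Ma, Md, w, y, seed,
    n_retained, burn_in, thin,
    nu_a, s2_a, nu_d, s2_d, nu_e, s2_e,
    active_a, active_d, include_dom,
    out_mu, out_alpha, out_delta, out_va, out_vd, out_ve,
):
    np.random.seed(seed)
    p, n = Ma.shape
    sw = 0.0
    for i in range(n):
        sw += w[i]
    xtx_a = np.zeros(p)
    xtx_d = np.zeros(p)
    for j in range(p):
        for i in range(n):
            xtx_a[j] += w[i] * Ma[j, i] * Ma[j, i]
            xtx_d[j] += w[i] * Md[j, i] * Md[j, i]
    # initial state
    mu = 0.0
    for i in range(n):
        mu += w[i] * y[i]
    mu /= sw
    alpha = np.zeros(p)
    delta = np.zeros(p)
    var_a = nu_a * s2_a / (nu_a - 2.0) if nu_a > 2.0 else s2_a
    var_d = nu_d * s2_d / (nu_d - 2.0) if nu_d > 2.0 else s2_d
    var_e = nu_e * s2_e / (nu_e - 2.0) if nu_e > 2.0 else s2_e
    e = np.empty(n)
    for i in range(n):
        e[i] = y[i] - mu
    n_active_a = 0
    n_active_d = 0
    for j in range(p):
        if active_a[j]:
            n_active_a += 1
        if active_d[j]:
            n_active_d += 1

    total = burn_in + n_retained * thin
    t = 0
    for sweep in range(total):
        # overall mean
        num = 0.0
        for i in range(n):
            num += w[i] * (e[i] + mu)
        new_mu = num / sw + np.random.normal() * np.sqrt(var_e / sw)
        dmu = new_mu - mu
        for i in range(n):
            e[i] -= dmu
        mu = new_mu
        # SNP effects
        _update_effects(Ma, xtx_a, active_a, w, e, alpha, var_a, var_e)
        if include_dom:
            _update_effects(Md, xtx_d, active_d, w, e, delta, var_d, var_e)
        # variance components
        ss_a = nu_a * s2_a
        for j in range(p):
            ss_a += alpha[j] * alpha[j]
        var_a = _inv_chi2(ss_a, nu_a + n_active_a)
        if include_dom:
            ss_d = nu_d * s2_d
            for j in range(p):
                ss_d += delta[j] * delta[j]
            var_d = _inv_chi2(ss_d, nu_d + n_active_d)
        ss_e = nu_e * s2_e
        for i in range(n):
            ss_e += w[i] * e[i] * e[i]
        var_e = _inv_chi2(ss_e, nu_e + n)
        # retain
        if sweep >= burn_in and (sweep - burn_in) % thin == 0:
            out_mu[t] = mu
            for j in range(p):
                out_alpha[t, j] = alpha[j]
                out_delta[t, j] = delta[j]
            out_va[t] = var_a
            out_vd[t] = var_d
            out_ve[t] = var_e
            t += 1
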