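"""Numba kernels for the Bayesian-alphabet single-site Gibbs samplers.

One compiled kernel serves all four models (BayesA, BayesB, BayesCpi,
Bayesian Lasso) via an integer model code; the surrounding API lives in
``linmodels``.  The residual vector ``e = y - mu - Z g`` is maintained
incrementally so each marker update is O(n).

State is driven entirely by numba's ``np.random`` bridge seeded inside the
kernel, so chains are bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import numpy as np
from numba import njit

MODEL_A = 0
MODEL_B = 1
MODEL_CPI = 2
MODEL_LASSO = 3


@njit(cache=True)
def _rinvgauss(mu: float, lam: float) -> float:
    """Inverse-Gaussian draw (Michael, Schucany & Haas 1976)."""
    v = np.random.standard_normal()
    v = v * v
    x = mu + mu * mu * v / (2.0 * lam) - (mu / (2.0 * lam)) * np.sqrt(
        4.0 * mu * lam * v + mu * mu * v * v
    )
    if x <= 0.0:
        x = 1e-12
    if np.random.random() <= mu / (mu + x):
        return x
    return mu * mu / x


@njit(cache=True)
def _scaled_inv_chi2(df: float, scale_sum: float) -> float:
    """Draw sigma2 ~ scale_sum / chi2(df)."""
    return scale_sum / np.random.chisquare(df)


@njit(cache=True)
def gibbs_kernel(
    y: np.ndarray,
    Z: np.ndarray,
    model: int,
    pi0: float,          # prior zero-mass (BayesB fixed; Cpi initial value)
    nu: float,
    S: float,
    nu_e: float,
    S_e: float,
    seed: int,
    n_iter: int,
    burn_in: int,
    thin: int,
    fixed_se2: float,    # <= 0 means "sample sigma_e2"
    fixed_sg2: float,    # <= 0 means "sample marker variances"
    lambda2_init: float,
    lambda2_shape: float,
    lambda2_rate: float,
    store_effects: int,  # store thinned effect draws when m <= this
):
    np.random.seed(seed)
    n, m = Z.shape
    zz = np.empty(m)
    for j in range(m):
        s = 0.0
        for i in range(n):
            s += Z[i, j] * Z[i, j]
        zz[j] = s

    g = np.zeros(m)
    delta = np.ones(m)           # inclusion indicators (B / Cpi)
    sg2 = np.empty(m)            # per-marker effect variances
    sg2_common = S * nu / max(nu - 2.0, 0.1)
    for j in range(m):
        sg2[j] = sg2_common
    tau2 = np.ones(m)            # Lasso local scales
    lambda2 = lambda2_init
    pi = pi0
    mu = 0.0
    for i in range(n):
        mu += y[i]
    mu /= n
    se2 = fixed_se2 if fixed_se2 > 0.0 else S_e * nu_e / max(nu_e - 2.0, 0.1)

    e = np.empty(n)
    for i in range(n):
        e[i] = y[i] - mu

    n_saved = 0
    g_sum = np.zeros(m)
    g_sumsq = np.zeros(m)
    mu_sum = 0.0
    pi_sum = 0.0
    se2_sum = 0.0
    do_store = m <= store_effects
    max_saved = (n_iter - burn_in + thin - 1) // thin if thin > 0 else 0
    draws = np.zeros((max_saved if do_store else 1, m if do_store else 1))

    for it in range(n_iter):
        # intercept, flat prior
        ebar = 0.0
        for i in range(n):
            ebar += e[i]
        ebar /= n
        mu_new = mu + ebar + np.random.standard_normal() * np.sqrt(se2 / n)
        shift = mu_new - mu
        for i in range(n):
            e[i] -= shift
        mu = mu_new

        # marker loop
        for j in range(m):
            zzj = zz[j]
            if zzj <= 0.0:
                g[j] = 0.0
                continue
            rhs = zzj * g[j]
            for i in range(n):
                rhs += Z[i, j] * e[i]

            if model == MODEL_A:
                if fixed_sg2 > 0.0:
                    sg2[j] = fixed_sg2
                else:
                    sg2[j] = _scaled_inv_chi2(nu + 1.0, g[j] * g[j] + nu * S)
                c = zzj + se2 / sg2[j]
                gnew = rhs / c + np.random.standard_normal() * np.sqrt(se2 / c)
            elif model == MODEL_B or model == MODEL_CPI:
                if model == MODEL_B:
                    if fixed_sg2 > 0.0:
                        sg2[j] = fixed_sg2
                    elif delta[j] > 0.5:
                        sg2[j] = _scaled_inv_chi2(nu + 1.0, g[j] * g[j] + nu * S)
                    else:
                        sg2[j] = _scaled_inv_chi2(nu, nu * S)
                    sj = sg2[j]
                else:
                    sj = sg2_common
                # log Bayes factor for inclusion, marker effect integrated out
                v1 = zzj * sj + se2
                log_bf = 0.5 * (-np.log(v1 / se2) + rhs * rhs * sj / (se2 * v1))
                if log_bf > 35.0:
                    p_in = 1.0
                else:
                    bf = np.exp(log_bf)
                    p_in = (1.0 - pi) * bf / ((1.0 - pi) * bf + pi)
                if np.random.random() < p_in:
                    delta[j] = 1.0
                    c = zzj + se2 / sj
                    gnew = rhs / c + np.random.standard_normal() * np.sqrt(se2 / c)
                else:
                    delta[j] = 0.0
                    gnew = 0.0
            else:  # MODEL_LASSO (Park & Casella): g_j ~ N(0, se2 * tau2_j)
                gj2 = g[j] * g[j]
                if gj2 < 1e-12:
                    gj2 = 1e-12
                inv_tau2 = _rinvgauss(np.sqrt(lambda2 * se2 / gj2), lambda2)
                tau2[j] = 1.0 / inv_tau2
                c = zzj + inv_tau2
                gnew = rhs / c + np.random.standard_normal() * np.sqrt(se2 / c)

            diff = gnew - g[j]
            if diff != 0.0:
                for i in range(n):
                    e[i] -= Z[i, j] * diff
            g[j] = gnew

        # hyperparameters
        if model == MODEL_CPI:
            m_in = 0.0
            ssg = 0.0
            for j in range(m):
                if delta[j] > 0.5:
                    m_in += 1.0
                    ssg += g[j] * g[j]
            pi = np.random.beta(m - m_in + 1.0, m_in + 1.0)
            if fixed_sg2 > 0.0:
                sg2_common = fixed_sg2
            else:
                sg2_common = _scaled_inv_chi2(nu + m_in, ssg + nu * S)
        elif model == MODEL_LASSO:
            sum_tau2 = 0.0
            for j in range(m):
                sum_tau2 += tau2[j]
            lambda2 = np.random.gamma(
                m + lambda2_shape, 1.0 / (lambda2_rate + 0.5 * sum_tau2)
            )

        if fixed_se2 <= 0.0:
            sse = 0.0
            for i in range(n):
                sse += e[i] * e[i]
            if model == MODEL_LASSO:
                # tau2 scales carry se2, so their quadratic form joins the SSE
                extra = 0.0
                for j in range(m):
                    if tau2[j] > 0.0:
                        extra += g[j] * g[j] / tau2[j]
                se2 = _scaled_inv_chi2(n + m + nu_e, sse + extra + nu_e * S_e)
            else:
                se2 = _scaled_inv_chi2(n + nu_e, sse + nu_e * S_e)

        if not np.isfinite(se2) or not np.isfinite(mu):
            return (g_sum, g_sumsq, mu_sum, pi_sum, se2_sum, n_saved, draws, it + 1)

        if it >= burn_in and (it - burn_in) % thin == 0:
            for j in range(m):
                g_sum[j] += g[j]
                g_sumsq[j] += g[j] * g[j]
            mu_sum += mu
            pi_sum += pi
            se2_sum += se2
            if do_store:
                for j in range(m):
                    draws[n_saved, j] = g[j]
            n_saved += 1

    return (g_sum, g_sumsq, mu_sum, pi_sum, se2_sum, n_saved, draws, 0)
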