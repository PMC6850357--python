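"""Independent brute-force oracles for micro instances (M <= 3, T <= 3).

Everything here deliberately avoids the package's Gauss-Hermite/HMM code
paths: integrals over the standard-normal individual effect use Simpson's
rule on a fine grid, marked-history probabilities enumerate every
three-state path explicitly, and truncated-normal terms go through
``scipy.stats.truncnorm``.
"""

from __future__ import annotations

from itertools import product

import numpy as np
from scipy.integrate import simpson
from scipy.stats import norm, poisson, truncnorm

Z_GRID = np.linspace(-8.0, 8.0, 4001)
_PHI = norm.pdf(Z_GRID)


def z_expect(values_on_grid: np.ndarray) -> float:
    """Simpson integral of ``f(z) * phi(z)`` over the z grid."""
    return float(simpson(values_on_grid * _PHI, x=Z_GRID))


def oracle_pln_pmf(y: int, alpha: float, sigma: float, r: float) -> float:
    lam = np.exp(alpha + sigma * Z_GRID) * r
    return z_expect(poisson.pmf(y, lam))


def oracle_resight_prob(alpha: float, sigma: float, r: float) -> float:
    lam = np.exp(alpha + sigma * Z_GRID) * r
    return 1.0 - z_expect(np.exp(-lam))


def _entry_vector(params, t: int) -> np.ndarray:
    w, g = params.w[t - 1], params.g[t - 1]
    return np.array([1.0 - w, w * (1.0 - g), w * g])


def _trans(params, interval: int) -> np.ndarray:
    i = interval - 1
    phi, gp, gpp = params.phi[i], params.gammaP[i], params.gammaPP[i]
    return np.array([
        [1.0, 0.0, 0.0],
        [1.0 - phi, phi * gp, phi * (1.0 - gp)],
        [1.0 - phi, phi * gpp, phi * (1.0 - gpp)],
    ])


def _path_probability(params, b: int, T: int, path: tuple[int, ...]) -> float:
    """Prior probability of a state path (states 0,1,2 = dead/off/on)."""
    p = _entry_vector(params, b)[path[0]]
    for i, t in enumerate(range(b, T)):
        p *= _trans(params, t)[path[i], path[i + 1]]
    return float(p)


def oracle_marked_loglik_within(data, params) -> float:
    """Exhaustive path sum with per-occasion marginal emissions."""
    total = 0.0
    T = data.T
    for s in range(data.M_T):
        b = int(data.b[s])
        occs = list(range(b, T + 1))
        lik = 0.0
        for path in product((0, 1, 2), repeat=len(occs)):
            pp = _path_probability(params, b, T, path)
            if pp == 0.0:
                continue
            for state, t in zip(path, occs):
                y = int(data.y[s, t - 1])
                if state < 2:
                    pp *= 1.0 if y == 0 else 0.0
                else:
                    pp *= oracle_pln_pmf(y, params.alpha[t - 1],
                                         params.sigma[t - 1], params.r[t - 1])
            lik += pp
        total += np.log(lik)
    return float(total)


def oracle_marked_loglik_across(data, params) -> float:
    """Simpson z-integral of the exhaustive conditional path sum."""
    total = 0.0
    T = data.T
    for s in range(data.M_T):
        b = int(data.b[s])
        occs = list(range(b, T + 1))
        cond = np.zeros_like(Z_GRID)
        for path in product((0, 1, 2), repeat=len(occs)):
            pp = _path_probability(params, b, T, path)
            if pp == 0.0:
                continue
            term = np.full_like(Z_GRID, pp)
            for state, t in zip(path, occs):
                y = int(data.y[s, t - 1])
                if state < 2:
                    term *= 1.0 if y == 0 else 0.0
                else:
                    lam = np.exp(params.alpha[t - 1] + params.sigma[t - 1] * Z_GRID)
                    term *= poisson.pmf(y, lam * params.r[t - 1])
            cond += term
        total += np.log(z_expect(cond))
    return float(total)


def oracle_tn_logpdf(x: float, mean: float, var: float) -> float:
    sd = np.sqrt(var)
    return float(truncnorm.logpdf(x, a=-mean / sd, b=np.inf, loc=mean, scale=sd))


def oracle_composite_loglik(data, params, heterogeneity: str) -> float:
    """Full composite log-likelihood recomputed from scratch."""
    if heterogeneity == "across":
        ll = oracle_marked_loglik_across(data, params)
    else:
        ll = oracle_marked_loglik_within(data, params)
    for t in range(1, data.T + 1):
        a, s_, r = params.alpha[t - 1], params.sigma[t - 1], params.r[t - 1]
        lam_bar = np.exp(a + s_**2 / 2.0)
        spread = np.exp(2 * a) * (np.exp(2 * s_**2) - np.exp(s_**2))
        eta = lam_bar + spread
        kappa = lam_bar * (1 - r) + spread * (1 - r) ** 2
        if data.n_known[t - 1]:
            n_t = float(data.n[t - 1])
        else:
            p_t = oracle_resight_prob(a, s_, r)
            n_t = float(np.sum(data.y[data.b <= t, t - 1] > 0)) / p_t
        if r < 1.0 - 1e-9:
            ll += oracle_tn_logpdf(float(data.e[t - 1]),
                                   n_t * lam_bar * (1 - r), n_t * kappa)
        U_t = params.U[t - 1]
        ll += oracle_tn_logpdf(float(data.u[t - 1]), U_t * lam_bar, U_t * eta)
    return float(ll)
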