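"""Composite log-likelihood of the zero-inflated Poisson log-normal estimator.

The likelihood has three components, treated as independent:

1. Marked-individual resighting histories, modelled as a three-state hidden
   Markov chain (1 = dead or permanent emigrant; 2 = alive off the study
   area; 3 = alive on the study area) whose entry distribution
   ``w_t = [1-w_t, w_t(1-g_t), w_t*g_t]`` zero-inflates histories of marks
   that were released but never available.  On-area individuals emit
   Poisson log-normal identified-resighting counts thinned by the mark
   identification probability ``r_t``; states 1-2 emit only zeros.
2. Per-occasion totals of marked-but-unidentified sightings ``e_t``,
   approximated by a left-truncated normal with moments driven by the
   number of marks on the area (known ``n_t`` or its Horvitz-Thompson
   estimate ``nhat_t``).
3. Per-occasion totals of unmarked sightings ``u_t``, approximated by a
   left-truncated normal with mean ``U_t*lambdabar_t``.

"Within" heterogeneity draws a fresh individual effect every occasion, so
emissions integrate to marginal Poisson log-normal masses occasion by
occasion; "across" heterogeneity shares one effect per individual, so the
whole conditional history is integrated over a single Gauss-Hermite grid.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln, log_ndtr

from zipne.data_model import EncounterData, ModelSpec, ParameterSet
from zipne.quadrature import GHRule, gh_rule

__all__ = [
    "pln_moments",
    "pln_marginal_pmf",
    "state_vectors",
    "transition_matrix",
    "marked_loglik_within",
    "marked_loglik_across",
    "resight_prob",
    "ht_mark_estimate",
    "unmarked_loglik",
    "unidentified_loglik",
    "composite_loglik",
]

_SQRT_PI = np.sqrt(np.pi)
_LOG_FLOOR = 1e-300
_P_FLOOR = 1e-10
_R_ONE = 1.0 - 1e-9


def pln_moments(alpha, sigma, r=None):
    """Marginal moments of a Poisson log-normal count.

    Returns ``(lambdabar, eta)`` — mean ``exp(alpha + sigma^2/2)`` and
    variance ``lambdabar + exp(2*alpha)*(exp(2*sigma^2) - exp(sigma^2))`` —
    or ``(lambdabar, eta, kappa)`` when ``r`` is given, where ``kappa`` is
    the variance term of the unidentified-sighting total per mark:
    ``lambdabar*(1-r) + exp(2*alpha)*(1-r)^2*(exp(2*sigma^2)-exp(sigma^2))``.
    """
    alpha = np.asarray(alpha, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    lam_bar = np.exp(alpha + sigma**2 / 2.0)
    spread = np.exp(2.0 * alpha) * (np.exp(2.0 * sigma**2) - np.exp(sigma**2))
    eta = lam_bar + spread
    if r is None:
        return lam_bar, eta
    r = np.asarray(r, dtype=float)
    kappa = lam_bar * (1.0 - r) + spread * (1.0 - r) ** 2
    return lam_bar, eta, kappa


def _poisson_pmf(y, mu):
    """Poisson pmf via log-gamma, safe at ``mu == 0`` (point mass at 0)."""
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        logp = y * np.log(mu) - mu - gammaln(y + 1.0)
    out = np.exp(logp)
    zero_mu = mu == 0
    if np.any(zero_mu):
        out = np.where(zero_mu, (y == 0).astype(float), out)
    return out


def pln_marginal_pmf(y, alpha: float, sigma: float, r: float, rule: GHRule):
    """Marginal pmf of an identified-resighting count.

    ``(1/sqrt(pi)) * sum_l f_l * Poisson(y; lambda*_l * r)`` with
    ``lambda*_l = exp(alpha + sqrt(2)*sigma*v_l)``.  Exactly Poisson when
    ``sigma == 0``; an indicator of ``y == 0`` when ``r == 0``.
    """
    if not 0.0 <= r <= 1.0:
        raise ValueError(f"r must lie in [0, 1], got {r}")
    y = np.asarray(y)
    lam = rule.transformed_rates(alpha, sigma) * r          # (L,)
    pmf = _poisson_pmf(y[..., None], lam[None, :] if y.ndim else lam)
    res = np.sum(rule.weights * pmf, axis=-1) / _SQRT_PI
    return float(res) if np.isscalar(y) or y.ndim == 0 else res


# ---------------------------------------------------------------------------
# Three-state machinery
# ---------------------------------------------------------------------------

def state_vectors(params: ParameterSet) -> np.ndarray:
    """Entry state distributions, one row per occasion: ``[1-w, w(1-g), wg]``."""
    w, g = params.w, params.g
    return np.stack([1.0 - w, w * (1.0 - g), w * g], axis=1)


def transition_matrix(params: ParameterSet, interval: int) -> np.ndarray:
    """Transition matrix ``G_t`` for interval ``t -> t+1`` (1-based ``t``).

    Rows index the state at ``t``, columns the state at ``t+1``; state 1 is
    absorbing, survivors move off/on the study area according to the
    temporary-emigration probabilities.
    """
    i = interval - 1
    phi = params.phi[i]
    gp = params.gammaP[i]
    gpp = params.gammaPP[i]
    return np.array(
        [
            [1.0, 0.0, 0.0],
            [1.0 - phi, phi * gp, phi * (1.0 - gp)],
            [1.0 - phi, phi * gpp, phi * (1.0 - gpp)],
        ]
    )


def _all_transitions(params: ParameterSet) -> np.ndarray:
    """(T-1, 3, 3) stack of transition matrices."""
    T = params.T
    return np.stack([transition_matrix(params, t) for t in range(1, T)]) if T > 1 else np.zeros((0, 3, 3))


def _forward_marked(y, b, entry, trans, em3, zero_em):
    """HMM forward pass over individuals, vectorised over the leading axes.

    ``em3``: emission probabilities in state 3, shape (..., M, T);
    ``zero_em``: indicator emissions of states 1-2, shape (M, T);
    ``entry``: (T, 3) entry distributions; ``trans``: (T-1, 3, 3).
    Returns total path probability per individual, shape (..., M).
    Rows stay identically zero until their entry occasion, so whole-array
    transitions and emission products are safe.
    """
    M, T = zero_em.shape
    lead = em3.shape[:-2]
    A = np.zeros(lead + (M, 3))
    for t in range(1, T + 1):
        if t > 1:
            A = A @ trans[t - 2]
        entering = b == t
        if entering.any():
            A[..., entering, :] = entry[t - 1]
        A[..., :, 0] *= zero_em[:, t - 1]
        A[..., :, 1] *= zero_em[:, t - 1]
        A[..., :, 2] *= em3[..., :, t - 1]
    return A.sum(axis=-1)


def marked_loglik_within(data: EncounterData, params: ParameterSet, rule: GHRule) -> float:
    """Marked-history log-likelihood under "within" heterogeneity.

    Individual effects are independent across occasions, so the state-3
    emission at each occasion is the marginal Poisson log-normal pmf and the
    history factorises as a plain HMM product
    ``w_{b_s} P_{s,b_s} prod_i G_i P_{s,i+1} 1``.
    """
    em3 = _within_emissions(data.y, params, rule)
    zero_em = (data.y == 0).astype(float)
    probs = _forward_marked(data.y, data.b, state_vectors(params),
                            _all_transitions(params), em3, zero_em)
    if np.any(~np.isfinite(probs)):
        raise FloatingPointError(
            f"non-finite marked likelihood for individual {int(np.flatnonzero(~np.isfinite(probs))[0])}"
        )
    return float(np.sum(np.log(np.maximum(probs, _LOG_FLOOR))))


def _within_emissions(y: np.ndarray, params: ParameterSet, rule: GHRule) -> np.ndarray:
    """(M, T) marginal pmf of each observed count at its occasion."""
    M, T = y.shape
    em = np.empty((M, T))
    for t in range(T):
        # evaluate the weighted Poisson mixture at the distinct counts only
        vals, inv = np.unique(y[:, t], return_inverse=True)
        pm = pln_marginal_pmf(vals, params.alpha[t], params.sigma[t], params.r[t], rule)
        em[:, t] = np.atleast_1d(pm)[inv]
    return em


def marked_loglik_across(data: EncounterData, params: ParameterSet, rule: GHRule) -> float:
    """Marked-history log-likelihood under "across" heterogeneity.

    One individual effect per animal: the conditional HMM product is
    evaluated at every Gauss-Hermite node and mixed with the rule weights,
    ``(1/sqrt(pi)) sum_l f_l * [conditional path probability at node l]``.
    Collapses to the "within" value when all ``sigma_t == 0``.
    """
    M, T = data.y.shape
    # lambda*_{l,t} r_t for each node and occasion
    lam = np.exp(params.alpha[None, :] + np.sqrt(2.0) * params.sigma[None, :] * rule.nodes[:, None])
    mu = lam * params.r[None, :]                              # (L, T)
    em3 = _poisson_pmf(data.y[None, :, :], mu[:, None, :])    # (L, M, T)
    zero_em = (data.y == 0).astype(float)
    cond = _forward_marked(data.y, data.b, state_vectors(params),
                           _all_transitions(params), em3, zero_em)  # (L, M)
    probs = np.einsum("l,lm->m", rule.weights, cond) / _SQRT_PI
    if np.any(~np.isfinite(probs)):
        raise FloatingPointError(
            f"non-finite marked likelihood for individual {int(np.flatnonzero(~np.isfinite(probs))[0])}"
        )
    return float(np.sum(np.log(np.maximum(probs, _LOG_FLOOR))))


# ---------------------------------------------------------------------------
# Detection probability and Horvitz-Thompson mark count
# ---------------------------------------------------------------------------

def resight_prob(t: int, params: ParameterSet, rule: GHRule) -> float:
    """Probability an on-area mark is identified at least once at occasion ``t``.

    ``p_t = 1 - (1/sqrt(pi)) sum_l f_l exp(-lambda*_{l,t} r_t)``.
    """
    lam = rule.transformed_rates(params.alpha[t - 1], params.sigma[t - 1])
    return float(1.0 - np.sum(rule.weights * np.exp(-lam * params.r[t - 1])) / _SQRT_PI)


def ht_mark_estimate(data: EncounterData, t: int, params: ParameterSet, rule: GHRule) -> float:
    """Number of marks on the study area at occasion ``t``.

    Returns the known ``n_t`` where the study design provides it, otherwise
    the Horvitz-Thompson estimate ``sum_{s in M_t} I(y_{s,t} > 0) / p_t``.
    """
    if data.n_known[t - 1]:
        return float(data.n[t - 1])
    p_t = resight_prob(t, params, rule)
    if p_t < _P_FLOOR:
        raise FloatingPointError(f"resighting probability numerically zero at occasion {t}")
    marked = data.b <= t
    return float(np.sum(data.y[marked, t - 1] > 0) / p_t)


# ---------------------------------------------------------------------------
# Truncated-normal components for occasion totals
# ---------------------------------------------------------------------------

def _tn_logpdf(x: float, mean: float, var: float) -> float:
    # normal log-density renormalised to (0, inf): phi((x-m)/sd) / Phi(m/sd)
    var = max(var, 1e-12)
    sd = np.sqrt(var)
    return float(
        -0.5 * np.log(2.0 * np.pi * var)
        - (x - mean) ** 2 / (2.0 * var)
        - log_ndtr(mean / sd)
    )


def unmarked_loglik(u_t: float, U_t: float, alpha: float, sigma: float) -> float:
    """Log-density of the unmarked sighting total ``u_t``.

    ``u_t ~ TN_(0,inf)(U_t * lambdabar_t, U_t * eta_t)``, the sum of ``U_t``
    independent Poisson log-normal counts approximated by a left-truncated
    normal (counts treated as continuous).
    """
    if U_t <= 0:
        raise ValueError("U_t must be positive")
    lam_bar, eta = pln_moments(alpha, sigma)
    if eta <= 0:
        raise ValueError("non-positive Poisson log-normal variance")
    return _tn_logpdf(float(u_t), U_t * float(lam_bar), U_t * float(eta))


def unidentified_loglik(e_t: float, n_t: float, alpha: float, sigma: float, r: float) -> float:
    """Log-density of the unidentified-mark sighting total ``e_t``.

    ``e_t ~ TN_(0,inf)(n_t * lambdabar_t * (1 - r_t), n_t * kappa_t)``.  With
    ``r_t == 1`` every detected mark is identified: the component is dropped
    (contribution 0) and any positive ``e_t`` is an error.
    """
    if n_t < 0:
        raise ValueError("n_t must be non-negative")
    if r >= _R_ONE:
        if e_t > 0:
            raise ValueError("unidentified sightings impossible when r=1")
        return 0.0
    lam_bar, _, kappa = pln_moments(alpha, sigma, r)
    return _tn_logpdf(float(e_t), n_t * float(lam_bar) * (1.0 - r), n_t * float(kappa))


# ---------------------------------------------------------------------------
# Composite likelihood
# ---------------------------------------------------------------------------

def composite_loglik(
    data: EncounterData,
    params: ParameterSet,
    spec: ModelSpec | None = None,
    rule: GHRule | None = None,
) -> float:
    """Composite log-likelihood of the zero-inflated estimator.

    Sum of the marked-history component (within or across heterogeneity per
    ``spec``), the unidentified-mark component at each occasion (using the
    known ``n_t`` where flagged, the Horvitz-Thompson estimate otherwise),
    and the unmarked component at each occasion.
    """
    spec = spec or ModelSpec()
    if spec.estimator != "ziPNE":
        raise ValueError("composite_loglik is the ziPNE likelihood; see ztpne_composite_loglik")
    rule = rule or gh_rule(spec.L)
    if spec.heterogeneity == "across":
        ll = marked_loglik_across(data, params, rule)
    else:
        ll = marked_loglik_within(data, params, rule)
    for t in range(1, data.T + 1):
        n_t = ht_mark_estimate(data, t, params, rule)
        ll += unidentified_loglik(
            data.e[t - 1], n_t, params.alpha[t - 1], params.sigma[t - 1], params.r[t - 1]
        )
        ll += unmarked_loglik(
            data.u[t - 1], params.U[t - 1], params.alpha[t - 1], params.sigma[t - 1]
        )
    return float(ll)
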