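"""Gauss-Hermite quadrature for Poisson log-normal expectations.

The sighting rate of individual ``s`` at occasion ``t`` is
``lambda_{s,t} = exp(alpha_t + sigma_t * z)`` with ``z ~ N(0, 1)``.
Expectations over ``z`` are approximated with physicists' Gauss-Hermite
quadrature (weight function ``exp(-v^2)``)::

    E[ fn(exp(alpha + sigma*z)) ] ~= (1/sqrt(pi)) * sum_l f_l * fn(lambda*_l)

with transformed rates ``lambda*_l = exp(alpha + sqrt(2)*sigma*v_l)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = ["GHRule", "gh_rule", "gh_expect"]

_SQRT_PI = np.sqrt(np.pi)


@dataclass(frozen=True)
class GHRule:
    """A Gauss-Hermite rule: ``L`` nodes ``v_l`` and weights ``f_l``.

    Weights sum to ``sqrt(pi)`` and nodes are symmetric about zero.
    """

    L: int
    nodes: np.ndarray = field(repr=False)
    weights: np.ndarray = field(repr=False)

    def transformed_rates(self, alpha: float, sigma: float) -> np.ndarray:
        """Node rates ``lambda*_l = exp(alpha + sqrt(2)*sigma*v_l)``."""
        return np.exp(np.asarray(alpha) + np.sqrt(2.0) * np.asarray(sigma) * self.nodes)


def gh_rule(L: int) -> GHRule:
    """Build the ``L``-point physicists' Gauss-Hermite rule.

    Parameters
    ----------
    L : int
        Number of quadrature points, at least 1.
    """
    if L < 1:
        raise ValueError(f"number of quadrature points must be >= 1, got {L}")
    nodes, weights = np.polynomial.hermite.hermgauss(int(L))
    return GHRule(L=int(L), nodes=nodes, weights=weights)


def gh_expect(
    fn: Callable[[np.ndarray], np.ndarray],
    alpha: float,
    sigma: float,
    rule: GHRule,
) -> float:
    """Expectation of ``fn(lambda)`` with ``log lambda ~ N(alpha, sigma^2)``.

    Returns ``(1/sqrt(pi)) * sum_l f_l * fn(exp(alpha + sqrt(2)*sigma*v_l))``.
    Exact (a single effective node) when ``sigma == 0``.
    """
    if sigma < 0:
        raise ValueError(f"sigma must be non-negative, got {sigma}")
    lam = rule.transformed_rates(alpha, sigma)
    vals = np.asarray(fn(lam), dtype=float)
    if not np.all(np.isfinite(vals)):
        bad = int(np.flatnonzero(~np.isfinite(np.atleast_1d(vals)))[0])
        raise FloatingPointError(
            f"integrand non-finite at quadrature node {bad} (rate {np.atleast_1d(lam)[bad]})"
        )
    return float(np.sum(rule.weights * vals) / _SQRT_PI)
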