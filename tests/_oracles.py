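"""Independent brute-force oracles used by the test suite.

Everything here is computed by enumeration or closed form, independent of
the sampler code paths it validates.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.special import gammaln

from overmix.core import MixturePriors


def log_marginal_group(y_k: np.ndarray, priors: MixturePriors) -> float:
    """Closed-form marginal likelihood of one group under the
    normal/inverse-gamma hierarchy (integrating out mu and sigma2)."""
    n = y_k.size
    if n == 0:
        return 0.0
    a, b, l, tau = priors.a, priors.b, priors.l, priors.tau
    ybar = y_k.mean()
    ss = np.sum((y_k - ybar) ** 2)
    b_post = b + 0.5 * ss + tau * n * (ybar - l) ** 2 / (2.0 * (tau + n))
    return float(
        -0.5 * n * np.log(2 * np.pi)
        + 0.5 * np.log(tau / (tau + n))
        + gammaln(a + 0.5 * n)
        - gammaln(a)
        + a * np.log(b)
        - (a + 0.5 * n) * np.log(b_post)
    )


def log_dirichlet_multinomial(counts: np.ndarray, alpha: float) -> float:
    """log p(Z) with the weights integrated out."""
    K = counts.size
    n = counts.sum()
    return float(
        gammaln(K * alpha)
        - gammaln(n + K * alpha)
        + np.sum(gammaln(alpha + counts))
        - K * gammaln(alpha)
    )


def exact_allocation_posterior(
    y: np.ndarray, K: int, priors: MixturePriors
) -> dict[tuple[int, ...], float]:
    """Exact posterior over all K**n allocation vectors by enumeration."""
    n = y.size
    logp = {}
    for z in itertools.product(range(K), repeat=n):
        za = np.array(z)
        counts = np.bincount(za, minlength=K)
        lp = log_dirichlet_multinomial(counts, priors.alpha)
        for k in range(K):
            lp += log_marginal_group(y[za == k], priors)
        logp[z] = lp
    vals = np.array(list(logp.values()))
    vals -= vals.max()
    probs = np.exp(vals)
    probs /= probs.sum()
    return dict(zip(logp.keys(), probs))


def exact_count_distribution(
    y: np.ndarray, K: int, priors: MixturePriors
) -> np.ndarray:
    """Exact marginal posterior of n_1 (occupancy of component 1)."""
    post = exact_allocation_posterior(y, K, priors)
    n = y.size
    dist = np.zeros(n + 1)
    for z, p in post.items():
        dist[sum(1 for zi in z if zi == 0)] += p
    return dist
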