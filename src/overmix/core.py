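"""Univariate Gaussian mixture model with conjugate hierarchical priors.

The model is a K-component mixture

    f(y) = sum_k pi_k N(y | mu_k, sigma2_k)

with a latent multinomial allocation z_i for each observation, an
exchangeable Dirichlet(alpha, ..., alpha) prior on the weights, an
inverse-gamma prior on each component variance and a conditionally
Gaussian prior on each mean:

    sigma2_k ~ InvGamma(a, b),   mu_k | sigma2_k ~ N(l, sigma2_k / tau).

All three Gibbs full-conditional updates live here, in a vectorised form
that operates on a batch of independent chains at once (axis 0 is the
chain axis); the public single-state functions are thin wrappers over the
batch kernels so the sampler and the unit-testable operations share one
code path.

A central numerical concern is sampling Dirichlet weights with
concentration parameters as small as 0.5**30 (~9e-10): naive gamma draws
underflow to exact zero long before that.  Weights are therefore sampled
and carried in log space (see :func:`sample_weights`), and every consumer
of the weights works from the log-weight vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

__all__ = [
    "MixturePriors",
    "ComponentParams",
    "MixtureState",
    "sample_allocations",
    "sample_weights",
    "sample_component_params",
    "log_complete_posterior",
    "count_alive",
]

#: free parameters per univariate Gaussian component (mean and variance);
#: the emptying regime of an overfitted mixture requires alpha < D_FREE / 2.
D_FREE = 2

_LOG_2PI = float(np.log(2.0 * np.pi))

#: default truncation point of the weight prior (see MixturePriors.weight_floor)
DEFAULT_WEIGHT_FLOOR = 0.5**30


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MixturePriors:
    """Hyperparameters of the overfitted mixture.

    Parameters
    ----------
    K : int
        Number of components fitted (the deliberate overfit bound, chosen
        larger than the anticipated true order).
    alpha : float
        Shared Dirichlet concentration on the weights.  Values below
        ``D_FREE / 2 = 1`` empty unsupported components; values above it
        merge them.
    a, b : float
        Inverse-gamma shape and scale for the component variances.
    l : float
        Prior mean location for the component means.
    tau : float
        Prior precision scale of the means: ``mu_k | sigma2_k`` has
        variance ``sigma2_k / tau``.
    weight_floor : float
        Truncation point of the Dirichlet weight prior: no component
        weight is allowed below this value (weights are floored and
        renormalised on the simplex).  A weight at or below the smallest
        concentration in play is statistically indistinguishable from an
        exact zero — the component expects far fewer than one allocation
        either way — but untruncated near-zero concentrations produce
        log-weights of order -1/alpha, which (i) freeze the tempering
        exchange moves between deep-ladder chains by making the weight
        prior ratio astronomically one-sided, and (ii) permanently kill
        any component a fluctuation empties, even when the data support
        it.  The default matches the smallest published ladder
        concentration (0.5**30); a strongly outlying observation can
        still claim a floored component, which is what lets the sampler
        resurrect a genuinely supported group.
    """

    K: int
    alpha: float
    a: float = 2.5
    b: float = 1.0
    l: float = 0.0
    tau: float = 1.0
    weight_floor: float = DEFAULT_WEIGHT_FLOOR

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError(f"K must be >= 1, got {self.K}")
        for name in ("alpha", "a", "b", "tau"):
            v = getattr(self, name)
            if not v > 0:
                raise ValueError(f"{name} must be > 0, got {v}")
        if not 0.0 < self.weight_floor < 1.0 / max(self.K, 2):
            raise ValueError(
                f"weight_floor must lie in (0, 1/K), got {self.weight_floor}"
            )

    @classmethod
    def from_data(cls, y: np.ndarray, K: int, alpha: float, tau: float = 1.0,
                  a: float = 2.5) -> "MixturePriors":
        """Data-driven defaults: l = mean(y), b = mean squared deviation.

        Centring the prior mean at the sample mean and scaling b to the
        sample spread keeps the prior inside the range of the data, which
        speeds up Gibbs convergence.
        """
        y = validate_observations(y)
        l = float(np.mean(y))
        b = float(np.mean((y - l) ** 2))
        return cls(K=K, alpha=alpha, a=a, b=b, l=l, tau=tau)


@dataclass
class ComponentParams:
    """Component means and variances, each a length-K vector."""

    mu: np.ndarray
    sigma2: np.ndarray

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma2 = np.asarray(self.sigma2, dtype=float)
        if self.mu.shape != self.sigma2.shape:
            raise ValueError("mu and sigma2 must have the same shape")
        if not np.all(self.sigma2 > 0):
            raise ValueError("all component variances must be > 0")


@dataclass
class MixtureState:
    """One chain's current draw: weights, parameters and allocations.

    Log-weights are carried exactly alongside the weights so that
    downstream consumers (the allocation update and the tempering swap
    ratio) never have to re-take logarithms of underflowed weights.
    Allocation labels are 0-based internally; every external surface
    (files, reports) is 1-based.
    """

    pi: np.ndarray
    theta: ComponentParams
    z: np.ndarray
    log_pi: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        self.z = np.asarray(self.z, dtype=int)
        if self.log_pi is None:
            with np.errstate(divide="ignore"):
                self.log_pi = np.log(self.pi)
        self.log_pi = np.asarray(self.log_pi, dtype=float)
        K = self.pi.shape[0]
        if abs(self.pi.sum() - 1.0) > 1e-10:
            raise ValueError("weights must sum to 1 within 1e-10")
        if self.z.size and (self.z.min() < 0 or self.z.max() >= K):
            raise ValueError("allocation labels must lie in 0..K-1")

    @property
    def K(self) -> int:
        return self.pi.shape[0]


def validate_observations(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y, dtype=float).ravel()
    if y.size < 1:
        raise ValueError("need at least one observation")
    if not np.all(np.isfinite(y)):
        raise ValueError("observations must all be finite")
    return y


# ---------------------------------------------------------------------------
# Batch kernels (axis 0 = chain)
# ---------------------------------------------------------------------------


def batch_sample_allocations(
    y: np.ndarray,
    log_pi: np.ndarray,
    mu: np.ndarray,
    sigma2: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw allocations for J chains at once.

    ``log_pi``, ``mu``, ``sigma2`` have shape (J, K); returns an (J, n)
    integer array.  Each z_i is categorical with mass proportional to
    pi_k * N(y_i | mu_k, sigma2_k), computed entirely in log space and
    normalised per observation.
    """
    # (J, n, K) log joint mass
    logp = (
        log_pi[:, None, :]
        - 0.5 * (_LOG_2PI + np.log(sigma2))[:, None, :]
        - (y[None, :, None] - mu[:, None, :]) ** 2 / (2.0 * sigma2[:, None, :])
    )
    m = logp.max(axis=2, keepdims=True)
    if not np.all(np.isfinite(m)):
        bad = np.argwhere(~np.isfinite(m[..., 0]))
        j, i = bad[0]
        raise FloatingPointError(
            f"all components have zero mass for observation {i} (chain {j})"
        )
    p = np.exp(logp - m)
    cdf = np.cumsum(p, axis=2)
    u = rng.random(size=(logp.shape[0], logp.shape[1], 1))
    u *= cdf[:, :, -1:]
    # number of cdf entries strictly below u = categorical index
    return (cdf < u).sum(axis=2)


def _logsumexp_rows(x: np.ndarray) -> np.ndarray:
    m = x.max(axis=1, keepdims=True)
    return m + np.log(np.exp(x - m).sum(axis=1, keepdims=True))


def batch_sample_weights(
    counts: np.ndarray,
    alphas: np.ndarray,
    rng: np.random.Generator,
    weight_floor: float = DEFAULT_WEIGHT_FLOOR,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw Dirichlet(alpha_j + n_1, ..., alpha_j + n_K) weights per chain.

    Uses the shape-boost representation G(s) = G(s+1) * U**(1/s), carried
    in log space: log G = log G(s+1) + log(U)/s.  For shapes as small as
    1e-10 the log-weight stays finite (of order -1e10) where a direct
    gamma draw would underflow to an exact zero.  Normalisation is by
    log-sum-exp; the result is then floored at ``weight_floor`` (the
    truncated weight prior — see MixturePriors) and renormalised in log
    space.  Returns (pi, log_pi), each of shape (J, K).
    """
    shape = alphas[:, None] + counts
    g1 = rng.gamma(shape + 1.0)
    # g1 is a gamma draw with shape >= 1; exact zeros are essentially
    # impossible but would poison the log, so clamp to the smallest normal.
    np.clip(g1, np.finfo(float).tiny, None, out=g1)
    log_u = np.log1p(-rng.random(size=shape.shape))  # log of U in (0, 1]
    log_g = np.log(g1) + log_u / shape
    log_pi = log_g - _logsumexp_rows(log_g)
    # truncated prior: floor, then renormalise on the simplex
    np.clip(log_pi, np.log(weight_floor), None, out=log_pi)
    log_pi -= _logsumexp_rows(log_pi)
    pi = np.exp(log_pi)
    pi /= pi.sum(axis=1, keepdims=True)
    return pi, log_pi


def batch_sample_component_params(
    counts: np.ndarray,
    sum_y: np.ndarray,
    sum_y2: np.ndarray,
    priors: MixturePriors,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Conjugate draw of (mu, sigma2) for every chain and component.

    Inputs are per-(chain, component) sufficient statistics of shape
    (J, K).  With n_k members, group mean ybar_k and within-group sum of
    squares ss_k, the update is

        sigma2_k ~ InvGamma(a + n_k/2,
                            b + ss_k/2 + tau n_k (ybar_k - l)^2 / (2 (tau + n_k)))
        mu_k | sigma2_k ~ N((tau l + n_k ybar_k) / (tau + n_k),
                            sigma2_k / (tau + n_k))

    Empty components (n_k = 0) reduce exactly to a fresh prior draw.
    """
    a, b, l, tau = priors.a, priors.b, priors.l, priors.tau
    n = counts.astype(float)
    ybar = np.where(n > 0, sum_y / np.maximum(n, 1.0), 0.0)
    ss = np.maximum(sum_y2 - n * ybar**2, 0.0)
    shape = a + 0.5 * n
    scale = b + 0.5 * ss + tau * n * (ybar - l) ** 2 / (2.0 * (tau + n))
    sigma2 = scale / rng.gamma(shape)
    post_mean = (tau * l + n * ybar) / (tau + n)
    mu = post_mean + rng.standard_normal(size=sigma2.shape) * np.sqrt(
        sigma2 / (tau + n)
    )
    return mu, sigma2


def batch_counts(z: np.ndarray, K: int) -> np.ndarray:
    """Occupancy counts n_{jk} for a (J, n) allocation array."""
    J = z.shape[0]
    flat = (np.arange(J)[:, None] * K + z).ravel()
    return np.bincount(flat, minlength=J * K).reshape(J, K)


def batch_suffstats(
    z: np.ndarray, y: np.ndarray, K: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Counts, sums and sums of squares per (chain, component)."""
    J = z.shape[0]
    flat = (np.arange(J)[:, None] * K + z).ravel()
    minl = J * K
    counts = np.bincount(flat, minlength=minl).reshape(J, K)
    y_t = np.broadcast_to(y, z.shape).ravel()
    sum_y = np.bincount(flat, weights=y_t, minlength=minl).reshape(J, K)
    sum_y2 = np.bincount(flat, weights=y_t**2, minlength=minl).reshape(J, K)
    return counts, sum_y, sum_y2


# ---------------------------------------------------------------------------
# Single-state operations
# ---------------------------------------------------------------------------


def sample_allocations(
    y: np.ndarray, state: MixtureState, rng: np.random.Generator
) -> np.ndarray:
    """Gibbs update of the allocation vector for a single state."""
    y = validate_observations(y)
    z = batch_sample_allocations(
        y,
        state.log_pi[None, :],
        state.theta.mu[None, :],
        state.theta.sigma2[None, :],
        rng,
    )
    return z[0]


def sample_weights(
    z: np.ndarray, priors: MixturePriors, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Gibbs update of the weights: Dirichlet(alpha + n_1, ..., alpha + n_K).

    Returns (pi, log_pi); log_pi is finite even when alpha underflows the
    linear scale (tested down to 0.5**30).
    """
    z = np.asarray(z, dtype=int)
    counts = np.bincount(z, minlength=priors.K)[None, :].astype(float)
    pi, log_pi = batch_sample_weights(
        counts, np.array([priors.alpha]), rng, weight_floor=priors.weight_floor
    )
    return pi[0], log_pi[0]


def sample_component_params(
    y: np.ndarray,
    z: np.ndarray,
    priors: MixturePriors,
    rng: np.random.Generator,
) -> ComponentParams:
    """Gibbs update of all component means and variances."""
    y = validate_observations(y)
    counts, sum_y, sum_y2 = batch_suffstats(
        np.asarray(z, dtype=int)[None, :], y, priors.K
    )
    mu, sigma2 = batch_sample_component_params(counts, sum_y, sum_y2, priors, rng)
    return ComponentParams(mu=mu[0], sigma2=sigma2[0])


def count_alive(z: np.ndarray, K: int) -> int:
    """Number of non-empty (alive) components in an allocation vector."""
    return int(np.count_nonzero(np.bincount(np.asarray(z, int), minlength=K)))


def _log_invgamma(x: np.ndarray, a: float, b: float) -> np.ndarray:
    return a * np.log(b) - gammaln(a) - (a + 1.0) * np.log(x) - b / x


def _log_normal(x: np.ndarray, mean: np.ndarray, var: np.ndarray) -> np.ndarray:
    return -0.5 * (_LOG_2PI + np.log(var)) - (x - mean) ** 2 / (2.0 * var)


def log_complete_posterior(
    y: np.ndarray,
    state: MixtureState,
    priors: MixturePriors,
    alive_only: bool = False,
) -> float:
    """Unnormalised log of the complete-data posterior.

    Sum of log p(Y | Z, theta), log p(Z | pi), log p(theta) and log p(pi).
    With ``alive_only`` every product runs over the non-empty components
    only, and the Dirichlet prior is evaluated on the renormalised
    alive-weight vector (of dimension k0).  This restricted score is what
    anchors the MAP reference of the relabelling algorithm; it is exactly
    invariant under simultaneous label permutations of (pi, theta, Z).
    """
    y = validate_observations(y)
    mu, sigma2 = state.theta.mu, state.theta.sigma2
    z = state.z
    K = state.K
    counts = np.bincount(z, minlength=K)
    loglik = float(np.sum(_log_normal(y, mu[z], sigma2[z])))
    log_pz = float(np.sum(state.log_pi[z]))

    if alive_only:
        keep = counts > 0
    else:
        keep = np.ones(K, dtype=bool)
    k_eff = int(keep.sum())

    log_ptheta = float(
        np.sum(_log_invgamma(sigma2[keep], priors.a, priors.b))
        + np.sum(_log_normal(mu[keep], priors.l, sigma2[keep] / priors.tau))
    )

    lp = state.log_pi[keep]
    if alive_only:
        # renormalise the alive weights on their own simplex
        m = lp.max()
        lp = lp - (m + np.log(np.exp(lp - m).sum()))
        # p(Z | pi) must use the same renormalised weights for the
        # alive-only score to be insensitive to empty components
        full_to_alive = -np.ones(K, dtype=int)
        full_to_alive[np.flatnonzero(keep)] = np.arange(k_eff)
        log_pz = float(np.sum(lp[full_to_alive[z]]))
    alpha = priors.alpha
    log_ppi = float(
        gammaln(k_eff * alpha) - k_eff * gammaln(alpha) + (alpha - 1.0) * lp.sum()
    )
    return loglik + log_pz + log_ptheta + log_ppi
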