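"""Prior parallel tempering for overfitted mixtures (the Zmix sampler).

J Gibbs chains are run in parallel on the same data, identical in every
respect except the Dirichlet concentration alpha_j on the mixture
weights.  The ladder starts well above the merge/empty threshold d/2 = 1
(all components merged, an easy surface to traverse) and descends to a
value extremely close to zero, where unsupported components are starved
of observations.  Adjacent chains exchange their complete states through
a Metropolis step whose acceptance ratio reduces to a ratio of Dirichlet
weight-prior densities only — the likelihood and the parameter priors are
common to all chains and cancel:

    A = p_j(pi_j') p_j'(pi_j) / (p_j(pi_j) p_j'(pi_j'))
    log A = (alpha_j - alpha_j') * sum_k (log pi_j'k - log pi_jk)

Inference is read from the *target* chain (the smallest alpha): its
per-iteration number of non-empty components K0(t) is the order
statistic, and the empirical distribution of K0(t) over saved iterations
ranks candidate model orders.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core import (
    D_FREE,
    MixturePriors,
    batch_sample_allocations,
    batch_sample_component_params,
    batch_sample_weights,
    batch_suffstats,
    validate_observations,
)

__all__ = [
    "TemperingLadder",
    "SamplerConfig",
    "ChainSet",
    "SwapRecord",
    "PosteriorDraws",
    "AliveSummary",
    "default_ladder",
    "log_swap_ratio",
    "attempt_swap",
    "run_zmix",
    "alive_summary",
]


# ---------------------------------------------------------------------------
# Ladders
# ---------------------------------------------------------------------------

# Published descending hyperparameter sequences.  The shared head crosses
# the d/2 = 1 threshold; the tail descends geometrically as powers of 1/2.
_HEAD = (30.0, 20.0, 10.0, 5.0, 3.0, 1.0)
_EXP25 = (1, 2, 3, 4, 5, 6, 8, 9, 10, 15, 20, 30)
_EXP30 = _EXP25 + (35, 40, 45, 50)

_PRESETS = {
    "ladder25": _HEAD + tuple(0.5**e for e in _EXP25),
    "ladder30": _HEAD + tuple(0.5**e for e in _EXP30),
}


@dataclass(frozen=True)
class TemperingLadder:
    """Strictly decreasing alpha sequence; the last entry is the target."""

    alphas: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.alphas, dtype=float)
        object.__setattr__(self, "alphas", a)
        if a.ndim != 1 or a.size < 1:
            raise ValueError("ladder must be a non-empty 1-d sequence")
        if not np.all(a > 0):
            raise ValueError("all ladder entries must be > 0")
        if a.size > 1 and not np.all(np.diff(a) < 0):
            raise ValueError("ladder entries must be strictly decreasing")
        # a single chain is a plain Gibbs sampler and may sit anywhere;
        # a true ladder should end below d/2 or the target posterior will
        # merge rather than empty its unsupported components
        if a.size > 1 and not a[-1] < D_FREE / 2:
            warnings.warn(
                f"target alpha {a[-1]} is not below d/2 = {D_FREE / 2}; "
                "unsupported components will merge instead of emptying",
                stacklevel=2,
            )

    @property
    def J(self) -> int:
        return self.alphas.size

    @property
    def target_alpha(self) -> float:
        return float(self.alphas[-1])


def default_ladder(preset: str = "ladder25") -> TemperingLadder:
    """Return a published ladder preset.

    ``"ladder25"`` is the refined ladder used for the replicate studies
    (head 30, 20, 10, 5, 3, 1 followed by 0.5 raised to
    1, 2, 3, 4, 5, 6, 8, 9, 10, 15, 20, 30); ``"ladder30"`` extends the
    tail with 0.5 to the 35, 40, 45 and 50.  The preset names are the
    nominal chain counts under which the sequences were published; the
    sequences themselves contain 18 and 22 distinct values.
    """
    try:
        return TemperingLadder(np.array(_PRESETS[preset]))
    except KeyError:
        raise ValueError(
            f"unknown ladder preset {preset!r}; choose from {sorted(_PRESETS)}"
        ) from None


def resolve_ladder(ladder: str | Sequence[float] | TemperingLadder) -> TemperingLadder:
    if isinstance(ladder, TemperingLadder):
        return ladder
    if isinstance(ladder, str):
        return default_ladder(ladder)
    return TemperingLadder(np.asarray(ladder, dtype=float))


# ---------------------------------------------------------------------------
# Swap ratio
# ---------------------------------------------------------------------------


def log_swap_ratio(
    log_pi_j: np.ndarray,
    log_pi_jp: np.ndarray,
    alpha_j: float,
    alpha_jp: float,
) -> float:
    """Log Metropolis ratio for exchanging the states of chains j and j'.

    For exchangeable Dirichlet priors the four normalising constants
    cancel and the ratio of densities collapses to

        log A = (alpha_j - alpha_j') * sum_k (log pi_j'k - log pi_jk),

    which is evaluated from the exact log-weights so that weights far
    below the linear-scale underflow threshold still contribute.
    """
    return float(
        (alpha_j - alpha_jp) * (np.sum(log_pi_jp) - np.sum(log_pi_j))
    )


# ---------------------------------------------------------------------------
# Chain state and the exchange move
# ---------------------------------------------------------------------------


@dataclass
class ChainSet:
    """The J chains' current states, stacked along axis 0.

    All chains share the data, K and the parameter priors; only the
    weight-prior concentration differs along the ladder.
    """

    pi: np.ndarray        # (J, K)
    log_pi: np.ndarray    # (J, K)
    mu: np.ndarray        # (J, K)
    sigma2: np.ndarray    # (J, K)
    z: np.ndarray         # (J, n)
    alive: np.ndarray     # (J,)

    @property
    def J(self) -> int:
        return self.pi.shape[0]

    def swap(self, j: int, jp: int) -> None:
        """Exchange the FULL states of chains j and j' in place."""
        sel, rev = [j, jp], [jp, j]
        for arr in (self.pi, self.log_pi, self.mu, self.sigma2, self.z, self.alive):
            arr[sel] = arr[rev]


@dataclass(frozen=True)
class SwapRecord:
    """Outcome of one adjacent-pair exchange proposal."""

    iteration: int
    j: int          # lower chain index of the proposed pair, 1-based
    accepted: bool
    log_A: float


def attempt_swap(
    chains: ChainSet,
    ladder: TemperingLadder,
    rng: np.random.Generator,
    iteration: int = 0,
) -> SwapRecord:
    """Propose one exchange between a uniformly chosen adjacent pair.

    The lower index j is uniform on 1..J-1, j' = j + 1; with probability
    min(1, A) the full states (weights with their logs, parameters and
    allocations) of the two chains are exchanged in place.
    """
    if chains.J < 2:
        raise ValueError("swap moves need at least two chains")
    j = int(rng.integers(chains.J - 1))
    log_A = log_swap_ratio(
        chains.log_pi[j], chains.log_pi[j + 1],
        float(ladder.alphas[j]), float(ladder.alphas[j + 1]),
    )
    accepted = bool(np.log1p(-rng.random()) < log_A)
    if accepted:
        chains.swap(j, j + 1)
    return SwapRecord(iteration=iteration, j=j + 1, accepted=accepted, log_A=log_A)


# ---------------------------------------------------------------------------
# Configuration and results
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SamplerConfig:
    """Run configuration for the tempered sampler.

    Defaults follow the replicate-study schedule: K = 10 components,
    20,000 iterations with the first 5,000 discarded, the refined ladder,
    and one adjacent-pair swap attempt per iteration (u = 1).
    """

    K: int = 10
    n_iter: int = 20_000
    burn_in: int = 5_000
    u: float = 1.0
    seed: int | None = None
    ladder: str | Sequence[float] | TemperingLadder = "ladder25"
    store_all_chains: bool = False
    alpha: float | None = None  # single-chain alpha override when J == 1

    def __post_init__(self) -> None:
        if not 0.0 <= self.u <= 1.0:
            raise ValueError(f"u must lie in [0, 1], got {self.u}")
        if not 0 <= self.burn_in < self.n_iter:
            raise ValueError("need 0 <= burn_in < n_iter")
        if self.K < 1:
            raise ValueError("K must be >= 1")


@dataclass
class PosteriorDraws:
    """Saved post-burn-in draws plus tempering diagnostics.

    Target-chain draws are always stored; ``all_*`` arrays are populated
    only when ``store_all_chains`` was set.  ``alive_counts_all`` records
    the per-iteration number of non-empty components in *every* chain,
    which is the raw material for ladder-behaviour diagnostics.
    """

    pi: np.ndarray            # (T, K)
    log_pi: np.ndarray        # (T, K)
    mu: np.ndarray            # (T, K)
    sigma2: np.ndarray        # (T, K)
    z: np.ndarray             # (T, n) int, 0-based
    alive_counts: np.ndarray  # (T,) target-chain K0(t)
    alive_counts_all: np.ndarray  # (T, J)
    swap_iteration: np.ndarray
    swap_pair: np.ndarray     # lower index j of the proposed (j, j+1) pair
    swap_accepted: np.ndarray
    swap_log_A: np.ndarray
    ladder: TemperingLadder
    config: SamplerConfig
    priors: MixturePriors
    y: np.ndarray
    all_chain_draws: dict | None = field(default=None, repr=False)

    @property
    def n_saved(self) -> int:
        return self.pi.shape[0]

    def swap_acceptance_rates(self) -> dict[int, float]:
        """Empirical acceptance rate per adjacent pair (1-based lower index)."""
        rates: dict[int, float] = {}
        for j in range(self.ladder.J - 1):
            mask = self.swap_pair == j
            if mask.any():
                rates[j + 1] = float(self.swap_accepted[mask].mean())
            else:
                rates[j + 1] = float("nan")
        return rates


@dataclass(frozen=True)
class AliveSummary:
    """Empirical distribution of the alive-component count K0(t)."""

    probs: dict[int, float]
    mode: int

    @property
    def configurations(self) -> list[int]:
        return sorted(self.probs)


def alive_summary(draws: PosteriorDraws | np.ndarray) -> AliveSummary:
    """Distribution of K0(t) over saved iterations and its mode.

    Ties in the mode are broken toward the smaller (sparser) order.
    """
    counts = draws.alive_counts if isinstance(draws, PosteriorDraws) else np.asarray(draws)
    if counts.size == 0:
        raise ValueError("no saved iterations")
    values, freq = np.unique(counts, return_counts=True)
    probs = {int(v): float(f) / counts.size for v, f in zip(values, freq)}
    mode = int(values[np.argmax(freq)])  # np.argmax takes first max: smallest k0
    return AliveSummary(probs=probs, mode=mode)


# ---------------------------------------------------------------------------
# The sampler
# ---------------------------------------------------------------------------


def run_zmix(
    y: np.ndarray,
    config: SamplerConfig,
    priors: MixturePriors | None = None,
) -> PosteriorDraws:
    """Run the prior-parallel-tempered Gibbs sampler.

    Per iteration and chain: allocations are refreshed from the
    categorical full conditional, weights from the Dirichlet full
    conditional, and component parameters from the conjugate
    normal/inverse-gamma update (empty components fall back to a fresh
    prior draw).  Then, with probability ``u``, one adjacent pair (j, j+1)
    is chosen uniformly and a full state exchange is proposed, accepted
    with probability min(1, A).

    Fully reproducible given ``config.seed``: a single generator drives
    all chains (the chain axis is vectorised) plus the swap decisions.

    Parameters
    ----------
    y : array-like
        Observations.
    config : SamplerConfig
        Sampler settings; ``config.alpha`` overrides the ladder with a
        single plain Gibbs chain when tempering is not wanted.
    priors : MixturePriors, optional
        Defaults to the data-driven hierarchy (l = mean(y), a = 2.5,
        b = mean squared deviation, tau = 1) with the target-chain alpha.
    """
    y = validate_observations(y)
    n = y.size
    K = config.K

    if config.alpha is not None:
        ladder = TemperingLadder(np.array([config.alpha]))
    else:
        ladder = resolve_ladder(config.ladder)
    alphas = ladder.alphas
    J = ladder.J

    if priors is None:
        priors = MixturePriors.from_data(y, K=K, alpha=ladder.target_alpha)

    rng = np.random.default_rng(config.seed)

    # --- initialisation: uniform random allocations, then parameters and
    # weights from their full conditionals given those allocations.
    z = rng.integers(0, K, size=(J, n))
    counts, sum_y, sum_y2 = batch_suffstats(z, y, K)
    floor = priors.weight_floor
    pi, log_pi = batch_sample_weights(counts.astype(float), alphas, rng,
                                      weight_floor=floor)
    mu, sigma2 = batch_sample_component_params(counts, sum_y, sum_y2, priors, rng)

    n_save = config.n_iter - config.burn_in
    tgt = J - 1
    out_pi = np.empty((n_save, K))
    out_log_pi = np.empty((n_save, K))
    out_mu = np.empty((n_save, K))
    out_sigma2 = np.empty((n_save, K))
    out_z = np.empty((n_save, n), dtype=np.int16)
    out_alive = np.empty(n_save, dtype=np.int16)
    out_alive_all = np.empty((n_save, J), dtype=np.int16)
    swap_it: list[int] = []
    swap_pair: list[int] = []
    swap_acc: list[bool] = []
    swap_la: list[float] = []

    store_all = config.store_all_chains
    if store_all:
        all_draws = {
            "pi": np.empty((n_save, J, K)),
            "mu": np.empty((n_save, J, K)),
            "sigma2": np.empty((n_save, J, K)),
            "z": np.empty((n_save, J, n), dtype=np.int16),
        }
    else:
        all_draws = None

    for t in range(config.n_iter):
        z = batch_sample_allocations(y, log_pi, mu, sigma2, rng)
        counts, sum_y, sum_y2 = batch_suffstats(z, y, K)
        pi, log_pi = batch_sample_weights(counts.astype(float), alphas, rng,
                                          weight_floor=floor)
        mu, sigma2 = batch_sample_component_params(counts, sum_y, sum_y2, priors, rng)
        alive = (counts > 0).sum(axis=1)

        if J > 1 and rng.random() < config.u:
            chains = ChainSet(pi=pi, log_pi=log_pi, mu=mu, sigma2=sigma2,
                              z=z, alive=alive)
            rec = attempt_swap(chains, ladder, rng, iteration=t)
            swap_it.append(rec.iteration)
            swap_pair.append(rec.j - 1)
            swap_acc.append(rec.accepted)
            swap_la.append(rec.log_A)

        if t >= config.burn_in:
            s = t - config.burn_in
            out_pi[s] = pi[tgt]
            out_log_pi[s] = log_pi[tgt]
            out_mu[s] = mu[tgt]
            out_sigma2[s] = sigma2[tgt]
            out_z[s] = z[tgt]
            out_alive[s] = alive[tgt]
            out_alive_all[s] = alive
            if store_all:
                all_draws["pi"][s] = pi
                all_draws["mu"][s] = mu
                all_draws["sigma2"][s] = sigma2
                all_draws["z"][s] = z

    return PosteriorDraws(
        pi=out_pi,
        log_pi=out_log_pi,
        mu=out_mu,
        sigma2=out_sigma2,
        z=out_z,
        alive_counts=out_alive,
        alive_counts_all=out_alive_all,
        swap_iteration=np.asarray(swap_it, dtype=int),
        swap_pair=np.asarray(swap_pair, dtype=int),
        swap_accepted=np.asarray(swap_acc, dtype=bool),
        swap_log_A=np.asarray(swap_la, dtype=float),
        ladder=ladder,
        config=config,
        priors=priors,
        y=y,
        all_chain_draws=all_draws,
    )
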