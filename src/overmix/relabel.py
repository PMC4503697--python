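"""Allocation-based relabelling of overfitted mixture posteriors (Zswitch).

Label switching makes raw marginal summaries of a mixture posterior
meaningless: the posterior is invariant under component-label
permutations, so every component's marginal looks identical.  The
relabeller here works per *configuration*: target-chain iterations are
first partitioned by their alive-component count k0, and each subset is
aligned against a reference drawn from itself — the iteration maximising
the complete-data posterior restricted to non-empty components (the MAP
reference).

Alignment is a two-phase procedure per iteration:

* **Phase one** cross-tabulates the current and reference allocations
  (the match table M) and accepts the labelling outright when every
  current group shares more than a fraction ``m`` of its members with
  exactly one reference group and those targets form a bijection.
* **Phase two** handles the ambiguous iterations by enumerating the
  candidate bijections and picking the one minimising the summed
  componentwise relative distance between current and reference
  parameters (weights, means, variances).

Empty components are compacted to the label tail, so after relabelling
the first k0 labels are always the live, aligned groups.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .core import (
    ComponentParams,
    MixturePriors,
    MixtureState,
    log_complete_posterior,
)
from .tempering import PosteriorDraws

__all__ = [
    "ReferenceLabelling",
    "RelabellingResult",
    "partition_by_k0",
    "select_map_reference",
    "build_match_table",
    "candidate_labels",
    "resolve_iteration",
    "zswitch_run",
]

#: floor for reference parameters in the relative-distance loss, guarding
#: against division by a reference value of exactly zero
_DENOM_FLOOR = 1e-8

#: phase-2 enumeration budget: never evaluate more than 5! candidate
#: bijections; the match threshold m is raised instead
_MAX_CANDIDATES = 120


@dataclass(frozen=True)
class ReferenceLabelling:
    """MAP reference for one configuration, labels compacted to 0..k0-1."""

    z0: np.ndarray       # (n,) reference allocations in 0..k0-1
    pi0: np.ndarray      # (k0,)
    mu0: np.ndarray
    sigma20: np.ndarray
    k0: int
    iteration: int       # index into the saved draws this reference came from


@dataclass
class RelabellingResult:
    """Permutation-corrected draws for one configuration.

    Arrays are indexed by position within ``iterations`` (the subset of
    saved iterations with exactly ``k0`` alive components).  Columns
    0..k0-1 of the parameter arrays are the aligned live groups; the
    remaining columns are the compacted empty components.  ``phases``
    records which phase decided each iteration (1 or 2); ``fallback``
    flags iterations where no candidate bijection survived the match
    table and the alignment fell back to a full parameter match.
    """

    k0: int
    iterations: np.ndarray
    pi: np.ndarray
    mu: np.ndarray
    sigma2: np.ndarray
    z: np.ndarray               # (T, n) in 0..k0-1
    permutations: np.ndarray    # (T, k0) row r of the alive groups -> new label
    phases: np.ndarray          # (T,)
    fallback: np.ndarray        # (T,) bool
    reference: ReferenceLabelling
    m: float

    @property
    def n_iterations(self) -> int:
        return self.iterations.size

    def phase_fractions(self) -> dict[str, float]:
        t = max(self.phases.size, 1)
        return {
            "phase1": float(np.mean(self.phases == 1)) if t else 0.0,
            "phase2": float(np.mean(self.phases == 2)) if t else 0.0,
            "fallback": float(np.mean(self.fallback)) if t else 0.0,
        }


# ---------------------------------------------------------------------------


def partition_by_k0(draws: PosteriorDraws) -> dict[int, np.ndarray]:
    """Disjoint cover of saved iterations by alive-component count."""
    counts = draws.alive_counts
    if counts.size == 0:
        raise ValueError("no saved iterations to partition")
    return {
        int(k0): np.flatnonzero(counts == k0)
        for k0 in np.unique(counts)
    }


def _alive_labels(z: np.ndarray, K: int) -> np.ndarray:
    return np.flatnonzero(np.bincount(z, minlength=K) > 0)


def _compact_reference(
    z: np.ndarray, pi: np.ndarray, mu: np.ndarray, sigma2: np.ndarray, K: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Permute labels so the non-empty groups occupy 0..k0-1 (relative
    order preserved, empties compacted to the tail)."""
    alive = _alive_labels(z, K)
    new_of_old = -np.ones(K, dtype=int)
    new_of_old[alive] = np.arange(alive.size)
    z0 = new_of_old[z]
    return z0, pi[alive], mu[alive], sigma2[alive]


def select_map_reference(
    draws: PosteriorDraws,
    k0: int,
    y: np.ndarray | None = None,
    priors: MixturePriors | None = None,
    iteration_set: np.ndarray | None = None,
) -> ReferenceLabelling:
    """Pick the MAP iteration of a configuration as relabelling anchor.

    The score is the complete-data log posterior restricted to non-empty
    components; ties (e.g. exact label permutations of one another) are
    broken toward the earliest iteration.
    """
    if y is None:
        y = draws.y
    if priors is None:
        priors = draws.priors
    if iteration_set is None:
        iteration_set = partition_by_k0(draws).get(k0)
    if iteration_set is None or len(iteration_set) == 0:
        raise ValueError(f"no saved iterations with k0 = {k0}")

    best_t, best_val = -1, -np.inf
    for t in iteration_set:
        state = MixtureState(
            pi=draws.pi[t],
            log_pi=draws.log_pi[t],
            theta=ComponentParams(mu=draws.mu[t], sigma2=draws.sigma2[t]),
            z=draws.z[t].astype(int),
        )
        val = log_complete_posterior(y, state, priors, alive_only=True)
        if val > best_val:
            best_val, best_t = val, int(t)

    K = draws.pi.shape[1]
    z0, pi0, mu0, s20 = _compact_reference(
        draws.z[best_t].astype(int), draws.pi[best_t], draws.mu[best_t],
        draws.sigma2[best_t], K,
    )
    return ReferenceLabelling(
        z0=z0, pi0=pi0, mu0=mu0, sigma20=s20, k0=k0, iteration=best_t
    )


def build_match_table(
    z_t: np.ndarray, ref: ReferenceLabelling, K: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Cross-tabulate current against reference allocations.

    Returns (M, row_labels): M[r, c] counts observations in the r-th
    alive current group that sit in reference group c; ``row_labels`` are
    the alive current labels in ascending order.  Raises if the current
    iteration does not have exactly k0 alive groups, signalling the
    caller to skip or flag it.
    """
    z_t = np.asarray(z_t, dtype=int)
    if K is None:
        K = max(int(z_t.max()) + 1, ref.k0)
    lam = _alive_labels(z_t, K)
    if lam.size != ref.k0:
        raise ValueError(
            f"alive-count mismatch: iteration has {lam.size} non-empty "
            f"groups, reference has {ref.k0}"
        )
    row_of = -np.ones(K, dtype=int)
    row_of[lam] = np.arange(ref.k0)
    M = np.bincount(
        row_of[z_t] * ref.k0 + ref.z0, minlength=ref.k0 * ref.k0
    ).reshape(ref.k0, ref.k0)
    return M, lam


def candidate_labels(M: np.ndarray, m: float) -> list[np.ndarray]:
    """Candidate reference labels per current group.

    Row r keeps every reference column whose shared fraction strictly
    exceeds the threshold: I_r = {c : M[r, c] / n_r > m}.
    """
    if not 0.0 < m < 1.0:
        raise ValueError(f"m must lie in (0, 1), got {m}")
    n_r = M.sum(axis=1)
    return [np.flatnonzero(M[r] > m * n_r[r]) for r in range(M.shape[0])]


def _count_bijections(sets: list[np.ndarray], cap: int) -> int:
    """Number of row-to-label bijections available, counted with a cap."""
    k0 = len(sets)
    count = 0
    stack = [(0, 0)]  # (row, used-mask)
    while stack:
        r, used = stack.pop()
        if r == k0:
            count += 1
            if count > cap:
                return count
            continue
        for c in sets[r]:
            if not used >> int(c) & 1:
                stack.append((r + 1, used | 1 << int(c)))
    return count


def _relative_cost(
    assign: np.ndarray,
    lam: np.ndarray,
    pi_t: np.ndarray,
    mu_t: np.ndarray,
    sigma2_t: np.ndarray,
    ref: ReferenceLabelling,
) -> float:
    """Summed relative parameter distance of a candidate assignment.

    ``assign[r]`` is the reference label given to the r-th alive current
    group; the loss compares reference group c with the current group it
    receives, summed over all alive groups and the three parameters."""
    cur = lam[np.argsort(assign)]  # current label assigned to ref group c
    cost = 0.0
    for ref_vals, cur_vals in (
        (ref.pi0, pi_t[cur]),
        (ref.mu0, mu_t[cur]),
        (ref.sigma20, sigma2_t[cur]),
    ):
        denom = np.maximum(np.abs(ref_vals), _DENOM_FLOOR)
        cost += float(np.sum(np.abs(ref_vals - cur_vals) / denom))
    return cost


def _cost_matrix(
    lam: np.ndarray,
    pi_t: np.ndarray,
    mu_t: np.ndarray,
    sigma2_t: np.ndarray,
    ref: ReferenceLabelling,
) -> np.ndarray:
    """C[r, c]: relative distance between current group lam[r] and ref c."""
    k0 = ref.k0
    C = np.zeros((k0, k0))
    for ref_vals, cur_vals in (
        (ref.pi0, pi_t[lam]),
        (ref.mu0, mu_t[lam]),
        (ref.sigma20, sigma2_t[lam]),
    ):
        denom = np.maximum(np.abs(ref_vals), _DENOM_FLOOR)
        C += np.abs(cur_vals[:, None] - ref_vals[None, :]) / denom[None, :]
    return C


def resolve_iteration(
    z_t: np.ndarray,
    pi_t: np.ndarray,
    mu_t: np.ndarray,
    sigma2_t: np.ndarray,
    ref: ReferenceLabelling,
    m: float = 0.5,
) -> tuple[np.ndarray, int, bool]:
    """Choose the relabelling of one iteration against the reference.

    Returns ``(assign, phase, fallback)`` where ``assign[r]`` is the new
    (reference) label of the r-th alive current group.

    Phase one applies when the candidate sets are all singletons forming
    a bijection.  Otherwise phase two enumerates the bijections in
    I_1 x ... x I_k0 and minimises the relative parameter distance; ties
    go to the lexicographically smallest assignment.  Safeguards: an
    empty candidate set is widened to its best-matching column; if the
    enumeration would exceed 120 candidates the threshold m is raised in
    steps of 0.1; if no bijection survives at all, the iteration falls
    back to a full parameter-distance assignment over all alive groups
    (flagged via ``fallback``).
    """
    K = pi_t.shape[0]
    M, lam = build_match_table(z_t, ref, K=K)
    k0 = ref.k0
    sets = candidate_labels(M, m)

    sizes = np.array([s.size for s in sets])
    if np.all(sizes == 1):
        targets = np.array([s[0] for s in sets])
        if np.unique(targets).size == k0:
            return targets, 1, False
        # duplicated singleton targets cannot form a bijection: phase 2

    # phase two -------------------------------------------------------
    def widen(sets_: list[np.ndarray]) -> list[np.ndarray]:
        return [
            s if s.size else np.array([int(np.argmax(M[r]))])
            for r, s in enumerate(sets_)
        ]

    sets = widen(sets)
    m_used = m
    while (
        _count_bijections(sets, _MAX_CANDIDATES) > _MAX_CANDIDATES
        and m_used + 0.1 < 1.0
    ):
        m_used += 0.1
        sets = widen(candidate_labels(M, m_used))

    n_bij = _count_bijections(sets, _MAX_CANDIDATES)
    if n_bij == 0:
        # no admissible bijection: match on parameters over all groups
        C = _cost_matrix(lam, pi_t, mu_t, sigma2_t, ref)
        if k0 <= 5:
            best, best_cost = None, np.inf
            for perm in itertools.permutations(range(k0)):
                cost = float(C[np.arange(k0), perm].sum())
                if cost < best_cost - 1e-15:
                    best, best_cost = np.array(perm), cost
            assign = best
        else:
            rows, cols = linear_sum_assignment(C)
            assign = cols[np.argsort(rows)]
        return np.asarray(assign), 2, True

    best_assign, best_cost = None, np.inf
    for combo in itertools.product(*[sorted(map(int, s)) for s in sets]):
        if len(set(combo)) != k0:
            continue
        cost = _relative_cost(np.array(combo), lam, pi_t, mu_t, sigma2_t, ref)
        if cost < best_cost - 1e-15:  # strict improvement keeps lexicographic min
            best_assign, best_cost = np.array(combo), cost
    return best_assign, 2, False


def zswitch_run(
    draws: PosteriorDraws,
    y: np.ndarray | None = None,
    priors: MixturePriors | None = None,
    m: float = 0.5,
) -> dict[int, RelabellingResult]:
    """Resolve label switching for every configuration in the target chain.

    For each alive-component count k0 present in the draws a MAP
    reference is built and every iteration of that configuration is
    aligned against it.  A single problematic iteration never aborts the
    run: it is resolved by the parameter-distance fallback and flagged.
    The relabeller assumes no configuration contains duplicated
    (merged) identical components, which the near-zero weight prior of
    the target chain is designed to prevent.
    """
    if y is None:
        y = draws.y
    if priors is None:
        priors = draws.priors
    K = draws.pi.shape[1]
    n = draws.z.shape[1]
    results: dict[int, RelabellingResult] = {}

    for k0, idx in partition_by_k0(draws).items():
        ref = select_map_reference(draws, k0, y=y, priors=priors, iteration_set=idx)
        T = idx.size
        out_pi = np.empty((T, K))
        out_mu = np.empty((T, K))
        out_s2 = np.empty((T, K))
        out_z = np.empty((T, n), dtype=np.int16)
        perms = np.empty((T, k0), dtype=int)
        phases = np.empty(T, dtype=np.int8)
        fallback = np.zeros(T, dtype=bool)

        for s, t in enumerate(idx):
            z_t = draws.z[t].astype(int)
            pi_t, mu_t, s2_t = draws.pi[t], draws.mu[t], draws.sigma2[t]
            assign, phase, fb = resolve_iteration(z_t, pi_t, mu_t, s2_t, ref, m=m)
            lam = _alive_labels(z_t, K)
            # old label occupying each new position: live groups to their
            # assigned reference label, empties compacted to the tail
            old_of_new = np.empty(K, dtype=int)
            old_of_new[assign] = lam
            empties = np.setdiff1d(np.arange(K), lam, assume_unique=True)
            old_of_new[k0:] = empties
            new_of_old = np.empty(K, dtype=int)
            new_of_old[old_of_new] = np.arange(K)

            out_pi[s] = pi_t[old_of_new]
            out_mu[s] = mu_t[old_of_new]
            out_s2[s] = s2_t[old_of_new]
            out_z[s] = new_of_old[z_t]
            perms[s] = assign
            phases[s] = phase
            fallback[s] = fb

        results[k0] = RelabellingResult(
            k0=k0, iterations=idx, pi=out_pi, mu=out_mu, sigma2=out_s2,
            z=out_z, permutations=perms, phases=phases, fallback=fallback,
            reference=ref, m=m,
        )
    return results
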