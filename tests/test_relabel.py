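"""Tests for the allocation-matching relabeller."""

import itertools

import numpy as np
import pytest

import overmix as om
from overmix.core import ComponentParams, MixturePriors, MixtureState, log_complete_posterior
from overmix.relabel import (
    ReferenceLabelling,
    build_match_table,
    candidate_labels,
    partition_by_k0,
    resolve_iteration,
    select_map_reference,
    zswitch_run,
)
from overmix.tempering import PosteriorDraws, SamplerConfig, TemperingLadder


def make_draws(pi, mu, sigma2, z, y, alpha=0.01):
    """Assemble a PosteriorDraws fixture from plain arrays."""
    pi = np.asarray(pi, float)
    z = np.asarray(z, int)
    T, K = pi.shape
    with np.errstate(divide="ignore"):
        log_pi = np.log(pi)
    alive = np.array(
        [om.count_alive(z[t], K) for t in range(T)], dtype=np.int16
    )
    priors = MixturePriors.from_data(np.asarray(y, float), K=K, alpha=alpha)
    return PosteriorDraws(
        pi=pi, log_pi=log_pi, mu=np.asarray(mu, float),
        sigma2=np.asarray(sigma2, float), z=z.astype(np.int16),
        alive_counts=alive, alive_counts_all=alive[:, None],
        swap_iteration=np.array([], int), swap_pair=np.array([], int),
        swap_accepted=np.array([], bool), swap_log_A=np.array([], float),
        ladder=TemperingLadder(np.array([alpha])),
        config=SamplerConfig(K=K, n_iter=T, burn_in=0, seed=0, alpha=alpha),
        priors=priors, y=np.asarray(y, float),
    )


class TestPartition:
    def test_single_configuration(self):
        y = [0.0, 1.0]
        d = make_draws(
            pi=[[0.5, 0.5]] * 3, mu=[[0, 1]] * 3, sigma2=[[1, 1]] * 3,
            z=[[0, 1]] * 3, y=y,
        )
        parts = partition_by_k0(d)
        assert list(parts) == [2] and parts[2].size == 3

    def test_direct_tally_and_disjoint_cover(self):
        y = [0.0, 1.0, 2.0]
        z = [[0, 0, 0], [0, 1, 2], [1, 1, 0]]
        d = make_draws(
            pi=[[1 / 3] * 3] * 3, mu=[[0, 1, 2]] * 3, sigma2=[[1] * 3] * 3,
            z=z, y=y,
        )
        parts = partition_by_k0(d)
        assert parts[1].tolist() == [0]
        assert parts[3].tolist() == [1]
        assert parts[2].tolist() == [2]
        assert sorted(np.concatenate(list(parts.values()))) == [0, 1, 2]


class TestMatchTable:
    def ref(self, z0, k0):
        return ReferenceLabelling(
            z0=np.asarray(z0, int), pi0=np.ones(k0) / k0,
            mu0=np.arange(k0, dtype=float), sigma20=np.ones(k0),
            k0=k0, iteration=0,
        )

    def test_identity_labelling_is_diagonal(self):
        z = np.array([0, 0, 1, 1, 1])
        M, lam = build_match_table(z, self.ref(z, 2), K=4)
        assert np.array_equal(M, np.diag([2, 3]))
        assert lam.tolist() == [0, 1]

    def test_direct_count_enumeration(self):
        z_t = np.array([0, 0, 1, 1])
        z0 = np.array([0, 1, 1, 1])
        M, _ = build_match_table(z_t, self.ref(z0, 2), K=2)
        assert M.tolist() == [[1, 1], [0, 2]]

    def test_row_sums_equal_group_sizes(self):
        rng = np.random.default_rng(5)
        z_t = rng.integers(0, 3, size=40)
        z0 = rng.integers(0, 3, size=40)
        M, lam = build_match_table(z_t, self.ref(z0, 3), K=5)
        assert np.array_equal(M.sum(axis=1), np.bincount(z_t, minlength=5)[lam])
        assert M.sum() == 40

    def test_alive_count_mismatch_flags(self):
        with pytest.raises(ValueError, match="alive-count mismatch"):
            build_match_table(np.array([0, 0, 0]), self.ref([0, 1, 1], 2), K=2)


class TestCandidateLabels:
    def test_fraction_threshold(self):
        M = np.array([[1, 1], [0, 2]])
        sets = candidate_labels(M, 0.4)
        assert sets[0].tolist() == [0, 1]
        assert sets[1].tolist() == [1]

    def test_strict_inequality_edge(self):
        M = np.array([[1, 1], [0, 2]])
        sets = candidate_labels(M, 0.5)
        assert sets[0].size == 0  # 0.5 is not > 0.5
        assert sets[1].tolist() == [1]

    def test_diagonal_gives_singletons(self):
        M = np.diag([4, 6, 2])
        sets = candidate_labels(M, 0.9)
        assert [s.tolist() for s in sets] == [[0], [1], [2]]

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            candidate_labels(np.eye(2, dtype=int), 1.5)


class TestResolveIteration:
    def ref(self, pi0, mu0, s20, z0):
        k0 = len(pi0)
        return ReferenceLabelling(
            z0=np.asarray(z0, int), pi0=np.asarray(pi0, float),
            mu0=np.asarray(mu0, float), sigma20=np.asarray(s20, float),
            k0=k0, iteration=0,
        )

    def test_identity_phase_one(self):
        z = np.array([0, 0, 1, 1])
        ref = self.ref([0.5, 0.5], [0.0, 5.0], [1.0, 1.0], z)
        assign, phase, fb = resolve_iteration(
            z, np.array([0.5, 0.5]), np.array([0.1, 5.1]), np.array([1.0, 1.0]),
            ref, m=0.5,
        )
        assert assign.tolist() == [0, 1] and phase == 1 and not fb

    def test_swapped_parameters_recovered_in_phase_two(self):
        """Current groups equal the reference with swapped labels and a
        fully ambiguous match table: the distance loss finds the swap."""
        z0 = np.array([0, 1, 0, 1])
        z_t = np.array([0, 1, 1, 0])  # half-half overlap: both columns ambiguous
        ref = self.ref([0.3, 0.7], [0.0, 5.0], [1.0, 2.0], z0)
        assign, phase, fb = resolve_iteration(
            z_t, np.array([0.7, 0.3]), np.array([5.0, 0.0]), np.array([2.0, 1.0]),
            ref, m=0.25,
        )
        assert assign.tolist() == [1, 0]
        assert phase == 2 and not fb

    def test_ambiguous_set_with_forced_bijection(self):
        """I_1 = {1, 2}, I_2 = {2}: the only bijection sends row 1 to
        label 1, row 2 to label 2 (0-based: 0 and 1)."""
        z0 = np.array([0, 1, 1, 1, 0, 0])
        z_t = np.array([0, 1, 1, 1, 0, 1])
        ref = self.ref([0.5, 0.5], [0.0, 4.0], [1.0, 1.0], z0)
        M, _ = build_match_table(z_t, ref, K=2)
        sets = candidate_labels(M, 0.4)
        assert sets[0].tolist() == [0] or sets[1].size > 1 or sets[0].size > 1
        assign, phase, _ = resolve_iteration(
            z_t, np.array([0.4, 0.6]), np.array([0.1, 3.9]), np.array([1.0, 1.0]),
            ref, m=0.3,
        )
        assert assign.tolist() == [0, 1]

    def test_phase_two_matches_exhaustive_enumeration(self):
        """The chosen permutation minimises the summed relative distance
        over all bijections (brute-force oracle)."""
        rng = np.random.default_rng(17)
        k0, n = 3, 60
        z0 = rng.integers(0, k0, n)
        z_t = z0.copy()
        flip = rng.random(n) < 0.45  # heavy switching: ambiguous table
        z_t[flip] = rng.integers(0, k0, flip.sum())
        ref = self.ref([0.3, 0.4, 0.3], [0.0, 3.0, 7.0], [1.0, 1.5, 0.5], z0)
        pi_t = np.array([0.28, 0.42, 0.30])
        mu_t = np.array([0.2, 2.9, 7.2])
        s2_t = np.array([1.1, 1.4, 0.6])
        assign, phase, fb = resolve_iteration(z_t, pi_t, mu_t, s2_t, ref, m=0.2)

        def cost(perm):
            tot = 0.0
            for r, c in enumerate(perm):
                for ref_v, cur_v in (
                    (ref.pi0[c], pi_t[r]), (ref.mu0[c], mu_t[r]),
                    (ref.sigma20[c], s2_t[r]),
                ):
                    tot += abs(ref_v - cur_v) / max(abs(ref_v), 1e-8)
            return tot

        best = min(itertools.permutations(range(k0)), key=cost)
        assert assign.tolist() == list(best)


class TestMapReference:
    def test_singleton_iteration_set(self):
        y = [0.0, 1.0]
        d = make_draws(
            pi=[[0.5, 0.5]], mu=[[0, 1]], sigma2=[[1, 1]], z=[[0, 1]], y=y,
        )
        ref = select_map_reference(d, 2)
        assert ref.iteration == 0 and ref.k0 == 2

    def test_argmax_matches_exhaustive_evaluation(self):
        """Three iterations with hand-evaluable posteriors: the chosen
        reference maximises the alive-only complete-data posterior."""
        y = np.array([-2.0, -1.8, 2.1, 2.3])
        pi = np.array([[0.5, 0.5, 0.0], [0.9, 0.1, 0.0], [0.45, 0.55, 0.0]])
        mu = np.array([[-1.9, 2.2, 0.0], [-1.0, 1.0, 0.0], [-1.95, 2.18, 0.0]])
        s2 = np.array([[0.1, 0.1, 1.0], [4.0, 4.0, 1.0], [0.05, 0.05, 1.0]])
        z = np.array([[0, 0, 1, 1]] * 3)
        d = make_draws(pi, mu, s2, z, y, alpha=0.5)
        ref = select_map_reference(d, 2)
        scores = []
        for t in range(3):
            state = MixtureState(
                pi=pi[t], log_pi=np.log(np.maximum(pi[t], 1e-300)),
                theta=ComponentParams(mu=mu[t], sigma2=s2[t]), z=z[t],
            )
            scores.append(log_complete_posterior(y, state, d.priors, alive_only=True))
        assert ref.iteration == int(np.argmax(scores))

    def test_reference_compaction_puts_alive_first(self):
        y = [0.0, 5.0]
        pi = [[0.0, 0.5, 0.5]]
        mu = [[9.0, 0.1, 5.1]]
        s2 = [[1.0, 1.0, 1.0]]
        z = [[1, 2]]
        d = make_draws(pi, mu, s2, z, y, alpha=0.5)
        ref = select_map_reference(d, 2)
        assert ref.z0.tolist() == [0, 1]
        assert ref.mu0.tolist() == [0.1, 5.1]

    def test_empty_configuration_rejected(self):
        y = [0.0, 1.0]
        d = make_draws(pi=[[0.5, 0.5]], mu=[[0, 1]], sigma2=[[1, 1]],
                       z=[[0, 1]], y=y)
        with pytest.raises(ValueError, match="no saved iterations"):
            select_map_reference(d, 1)


class TestZswitchRun:
    def aligned_fixture(self, T=40, n=80, seed=3):
        """Draws with no label switching: stable well-separated groups."""
        rng = np.random.default_rng(seed)
        means = np.array([0.0, 6.0, 12.0])
        z_base = np.repeat([0, 1, 2], [30, 30, 20])
        y = rng.normal(means[z_base], 0.5)
        K = 5
        pi = np.zeros((T, K))
        mu = np.zeros((T, K))
        s2 = np.ones((T, K))
        z = np.tile(z_base, (T, 1))
        for t in range(T):
            pi[t, :3] = np.array([0.375, 0.375, 0.25]) + rng.normal(0, 0.01, 3)
            pi[t] = np.maximum(pi[t], 0)
            pi[t] /= pi[t].sum()
            mu[t, :3] = means + rng.normal(0, 0.05, 3)
            mu[t, 3:] = rng.normal(5, 3, 2)
            s2[t, :3] = 0.25 + rng.gamma(2, 0.02, 3)
            s2[t, 3:] = rng.gamma(2, 1, 2) + 0.2
        return y, pi, mu, s2, z

    def permute_fixture(self, pi, mu, s2, z, which, perm):
        """Apply a known alive-label permutation at selected iterations."""
        pi, mu, s2, z = pi.copy(), mu.copy(), s2.copy(), z.copy()
        K = pi.shape[1]
        full = np.concatenate([perm, np.arange(len(perm), K)])
        inv = np.argsort(full)
        for t in which:
            pi[t] = pi[t][full]
            mu[t] = mu[t][full]
            s2[t] = s2[t][full]
            z[t] = inv[z[t]]
        return pi, mu, s2, z

    def test_aligned_draws_get_identity_permutations(self):
        y, pi, mu, s2, z = self.aligned_fixture()
        d = make_draws(pi, mu, s2, z, y)
        results = zswitch_run(d)
        assert list(results) == [3]
        res = results[3]
        assert np.all(res.permutations == np.arange(3))
        assert np.all(res.z == z)

    def test_injected_permutations_are_undone(self):
        y, pi, mu, s2, z = self.aligned_fixture()
        odd = np.arange(1, 40, 2)
        pi_p, mu_p, s2_p, z_p = self.permute_fixture(
            pi, mu, s2, z, odd, np.array([2, 0, 1])
        )
        d = make_draws(pi_p, mu_p, s2_p, z_p, y)
        res = zswitch_run(d)[3]
        # alignment restored exactly for the alive groups
        assert np.all(res.z == z)
        assert np.allclose(res.mu[:, :3], mu[:, :3])
        assert np.allclose(res.pi[:, :3], pi[:, :3])
        # the injected shuffle is recovered at exactly the odd iterations
        assert np.all(res.permutations[odd] == np.array([2, 0, 1]))
        even = np.arange(0, 40, 2)
        assert np.all(res.permutations[even] == np.arange(3))

    def test_likelihood_invariant_under_relabelling(self):
        y, pi, mu, s2, z = self.aligned_fixture()
        odd = np.arange(1, 40, 2)
        pi_p, mu_p, s2_p, z_p = self.permute_fixture(
            pi, mu, s2, z, odd, np.array([1, 2, 0])
        )
        d = make_draws(pi_p, mu_p, s2_p, z_p, y)
        res = zswitch_run(d)[3]

        def loglik(mu_row, s2_row, z_row):
            return np.sum(
                -0.5 * np.log(2 * np.pi * s2_row[z_row])
                - (y - mu_row[z_row]) ** 2 / (2 * s2_row[z_row])
            )

        for t in range(40):
            before = loglik(mu_p[t], s2_p[t], z_p[t].astype(int))
            after = loglik(res.mu[t], res.sigma2[t], res.z[t].astype(int))
            assert after == pytest.approx(before, abs=1e-9)

    def test_multiset_of_alive_triples_preserved(self):
        y, pi, mu, s2, z = self.aligned_fixture()
        d = make_draws(pi, mu, s2, z, y)
        res = zswitch_run(d)[3]
        for t in range(0, 40, 7):
            alive_before = {
                (pi[t, k], mu[t, k], s2[t, k]) for k in np.unique(z[t])
            }
            alive_after = {
                (res.pi[t, k], res.mu[t, k], res.sigma2[t, k])
                for k in range(3)
            }
            assert alive_before == alive_after

    def test_idempotence(self):
        y, pi, mu, s2, z = self.aligned_fixture()
        odd = np.arange(1, 40, 2)
        d = make_draws(*self.permute_fixture(pi, mu, s2, z, odd, np.array([2, 0, 1])), y)
        first = zswitch_run(d)[3]
        d2 = make_draws(first.pi, first.mu, first.sigma2, first.z, y)
        second = zswitch_run(d2)[3]
        assert np.all(second.permutations == np.arange(3))
        assert np.all(second.z == first.z)
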