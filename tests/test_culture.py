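"""Interaction network and event-driven cultural dynamics."""

import numpy as np
import pytest

from foragersim import culture as cult


def prog_params(**kw):
    defaults = dict(mode="progressive", c=1, gamma=0.0, lam=0.0,
                    phi1=0.02, phi2=0.002)
    defaults.update(kw)
    return cult.CultureParams(**defaults)


def nonprog_params(**kw):
    defaults = dict(mode="non-progressive", c=1, gamma=0.0, lam=0.0,
                    phi1=0.02, phi2=0.002, Q=2)
    defaults.update(kw)
    return cult.CultureParams(**defaults)


class TestNetwork:
    def test_collinear_bands_with_inclusive_boundaries(self):
        """Distance bands on the published radii and rates, with the
        d = r1 boundary inclusive in the short-range band."""
        X = np.array([[0.0, 0.0], [10.0, 0.0], [30.0, 0.0], [100.0, 0.0]])
        A = cult.build_network(X, r1=20.0, r2=50.0, phi1=0.02, phi2=0.002)
        assert A[0, 1] == 0.02          # d = 10 <= r1
        assert A[0, 2] == 0.002         # r1 < 30 <= r2
        assert A[1, 2] == 0.02          # d = 20, inclusive boundary
        assert A[0, 3] == A[1, 3] == A[2, 3] == 0.0
        np.testing.assert_array_equal(A, A.T)
        np.testing.assert_array_equal(np.diag(A), np.zeros(4))

    def test_single_agent_empty_network(self):
        A = cult.build_network(np.array([[5.0, 5.0]]), 20, 50, 0.02, 0.002)
        np.testing.assert_array_equal(A, [[0.0]])

    def test_permutation_invariance(self):
        rng = np.random.default_rng(0)
        X = rng.uniform(0, 120, (15, 2))
        perm = rng.permutation(15)
        A = cult.build_network(X, 20, 50, 0.02, 0.002)
        Ap = cult.build_network(X[perm], 20, 50, 0.02, 0.002)
        np.testing.assert_array_equal(Ap, A[np.ix_(perm, perm)])

    def test_bad_radii_rejected(self):
        with pytest.raises(ValueError):
            cult.build_network(np.zeros((2, 2)), 50, 20, 0.02, 0.002)

    def test_brute_force_equivalence_random_configs(self):
        """Matches the direct all-pairs banding rule on random layouts."""
        rng = np.random.default_rng(1)
        for _ in range(5):
            n = rng.integers(2, 200)
            X = rng.uniform(0, 300, (n, 2))
            A = cult.build_network(X, 20.0, 50.0, 0.02, 0.002)
            for a in range(n):
                for b in range(n):
                    d = np.hypot(*(X[a] - X[b]))
                    want = 0.0 if a == b else (
                        0.02 if d <= 20.0 else 0.002 if d <= 50.0 else 0.0)
                    assert A[a, b] == want


class TestRateCatalogue:
    def test_isolated_agent_at_floor_only_innovates(self):
        p = prog_params(c=3, gamma=0.001, lam=0.02)
        S = np.zeros((1, 3), dtype=np.int64)
        cat = cult.event_rate_catalogue(S, np.zeros((1, 1)), p)
        assert sum(r for _, r in cat) == pytest.approx(3 * 0.001)
        assert all(kind == "innovation" for (kind, _, _), _ in cat)

    def test_adoption_rate_linear_in_trait_difference(self):
        p = prog_params(phi1=0.02)
        S = np.array([[2], [5]])
        A = np.array([[0.0, 0.02], [0.02, 0.0]])
        cat = dict(cult.event_rate_catalogue(S, A, p))
        assert cat[("adoption", 0, 0)] == pytest.approx(0.02 * 3)
        assert ("adoption", 1, 0) not in cat

    def test_identical_nonprogressive_pair_only_switches(self):
        p = nonprog_params(c=2, gamma=0.001, Q=4)
        S = np.array([[1, 2], [1, 2]])
        A = np.array([[0.0, 0.02], [0.02, 0.0]])
        cat = cult.event_rate_catalogue(S, A, p)
        assert sum(r for _, r in cat) == pytest.approx(2 * 2 * 0.001)
        assert all(kind == "switch" for (kind, _, _), _ in cat)


class TestApplyEvent:
    def test_loss_at_floor_rejected(self):
        p = prog_params(lam=0.02)
        S = np.array([[0]])
        with pytest.raises(ValueError):
            cult.apply_event(S, "loss", 0, 0, p, -1)

    def test_adoption_increments_by_exactly_one(self):
        p = prog_params()
        S = np.array([[1]])
        cult.apply_event(S, "adoption", 0, 0, p, 2)
        assert S[0, 0] == 2
        with pytest.raises(ValueError):
            cult.apply_event(S, "adoption", 0, 0, p, 6)

    def test_nonprogressive_range_enforced(self):
        p = nonprog_params(Q=4)
        S = np.array([[2]])
        with pytest.raises(ValueError):
            cult.apply_event(S, "switch", 0, 0, p, 4)
        cult.apply_event(S, "switch", 0, 0, p, 3)
        assert S[0, 0] == 3


class TestGillespie:
    def test_innovation_counts_poisson_short(self):
        """Event counts of a pure innovation process match Poisson(gamma T)."""
        p = prog_params(gamma=0.001)
        lam_T = 10.0
        counts = []
        rng = np.random.default_rng(123)
        for _ in range(100):
            S = np.zeros((1, 1), dtype=np.int64)
            ev = cult.gillespie_window(S, np.zeros((1, 1)), p, 0.0, 10_000.0,
                                       rng)
            counts.append(len(ev))
        se = np.sqrt(lam_T / len(counts))
        assert np.mean(counts) == pytest.approx(lam_T, abs=3 * se)

    def test_event_timestamps_within_window(self):
        p = prog_params(gamma=0.01)
        rng = np.random.default_rng(5)
        S = np.zeros((2, 1), dtype=np.int64)
        ev = cult.gillespie_window(S, np.zeros((2, 2)), p, 100.0, 50.0, rng)
        assert all(100.0 <= e.t < 150.0 for e in ev)

    def test_adoption_only_converges_to_initial_maximum(self):
        """With gamma = lam = 0 on a connected line, adoption can only move
        agents up to the initial maximum, which itself never increases."""
        p = prog_params(phi1=0.1, phi2=0.01)
        X = np.array([[i * 10.0, 0.0] for i in range(5)])
        A = cult.build_network(X, 20.0, 50.0, p.phi1, p.phi2)
        S = np.array([[0], [3], [1], [0], [2]])
        m0 = S.max()
        rng = np.random.default_rng(7)
        for step in range(400):
            cult.gillespie_window(S, A, p, float(step), 1.0, rng,
                                  collect_events=False)
            assert S.max() <= m0
        np.testing.assert_array_equal(S.ravel(), np.full(5, m0))

    def test_nonprogressive_consensus_is_absorbing(self):
        """Voter-style copying from random starts reaches consensus and
        stays there (gamma = 0)."""
        p = nonprog_params(phi1=0.1, phi2=0.01, Q=3)
        X = np.array([[i * 15.0, 0.0] for i in range(5)])
        A = cult.build_network(X, 20.0, 50.0, p.phi1, p.phi2)
        rng = np.random.default_rng(11)
        S = rng.integers(0, 3, (5, 1))
        for step in range(3_000):
            cult.gillespie_window(S, A, p, float(step), 1.0, rng,
                                  collect_events=False)
            if len(np.unique(S)) == 1:
                break
        assert len(np.unique(S)) == 1
        frozen = S.copy()
        for step in range(50):
            cult.gillespie_window(S, A, p, float(step), 1.0, rng,
                                  collect_events=False)
        np.testing.assert_array_equal(S, frozen)

    def test_event_log_replays_to_final_state(self):
        p = cult.CultureParams(mode="progressive", c=3, gamma=0.01, lam=0.02,
                               phi1=0.1, phi2=0.01)
        rng = np.random.default_rng(17)
        X = rng.uniform(0, 80, (8, 2))
        A = cult.build_network(X, 20.0, 50.0, p.phi1, p.phi2)
        ids = np.arange(100, 108)
        S0 = rng.integers(0, 4, (8, 3))
        S = S0.copy()
        events = []
        for step in range(300):
            events.extend(cult.gillespie_window(S, A, p, float(step), 1.0,
                                                rng, ids=ids))
        replayed = cult.replay_events(S0, events, ids, p)
        np.testing.assert_array_equal(replayed, S)

    def test_progressive_traits_never_negative(self):
        p = prog_params(gamma=0.005, lam=0.5)
        rng = np.random.default_rng(23)
        S = np.zeros((4, 1), dtype=np.int64)
        A = np.full((4, 4), 0.1)
        np.fill_diagonal(A, 0.0)
        for step in range(500):
            cult.gillespie_window(S, A, p, float(step), 1.0, rng,
                                  collect_events=False)
            assert np.all(S >= 0)
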