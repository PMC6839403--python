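import numpy as np
import pytest
from scipy import stats

from cdisim.cells import CellType
from cdisim.geometry import ContactGraph
from cdisim.kinetics import (CdiParams, DuplicateReactionError,
                             PendingReaction, ReactionKind, ReactionQueue,
                             fire, inhibition_propensity,
                             inhibitor_contact_counts, rescale, schedule,
                             sync_reactions)


def graph_from_pairs(pairs, n):
    """Contact graph with zero separation for explicit index pairs."""
    if pairs:
        i, j = map(np.asarray, zip(*pairs))
    else:
        i = j = np.empty(0, dtype=np.int64)
    return ContactGraph(i, j, np.zeros(len(i)), n_cells=n, tol=0.05)


class TestCdiParams:
    def test_defaults_valid(self):
        p = CdiParams()
        assert p.mu == 0.01

    @pytest.mark.parametrize("kwargs", [
        dict(eta=-1), dict(delta=1.5), dict(delta=-0.1), dict(mu=-1),
        dict(beta=1.0), dict(beta=-0.2),
    ])
    def test_invalid(self, kwargs):
        with pytest.raises(ValueError):
            CdiParams(**kwargs)


class TestReactionQueue:
    def test_pop_order(self):
        q = ReactionQueue()
        for cid, tau in [(1, 3.0), (2, 1.0), (3, 2.0)]:
            q.push(PendingReaction(tau=tau, kind=ReactionKind.INHIBITION,
                                   cell_id=cid, rate=1.0))
        assert [q.pop().cell_id for _ in range(3)] == [2, 3, 1]

    def test_duplicate_key(self):
        q = ReactionQueue()
        q.push(PendingReaction(1.0, ReactionKind.INHIBITION, 1, 1.0))
        with pytest.raises(DuplicateReactionError):
            q.push(PendingReaction(2.0, ReactionKind.INHIBITION, 1, 1.0))
        # same cell, different kind is fine
        q.push(PendingReaction(2.0, ReactionKind.RECOVERY, 1, 1.0))
        assert len(q) == 2

    def test_remove_and_contains(self):
        q = ReactionQueue()
        q.push(PendingReaction(1.0, ReactionKind.INHIBITION, 1, 1.0))
        key = (1, ReactionKind.INHIBITION)
        assert key in q
        assert q.remove(key).tau == 1.0
        assert key not in q
        assert q.remove(key) is None

    def test_random_operations_keep_heap_valid(self, rng):
        q = ReactionQueue()
        alive = {}
        for step in range(3000):
            op = rng.integers(0, 4)
            if op == 0 or not alive:
                cid = int(rng.integers(0, 500))
                kind = ReactionKind(int(rng.integers(0, 2)))
                if (cid, kind) not in q:
                    tau = float(rng.uniform(0, 100))
                    q.push(PendingReaction(tau, kind, cid, 1.0))
                    alive[(cid, kind)] = tau
            elif op == 1:
                r = q.pop()
                assert alive.pop(r.key) == min(alive.get(r.key, np.inf),
                                               *alive.values(), r.tau)
            elif op == 2:
                key = list(alive)[int(rng.integers(0, len(alive)))]
                q.remove(key)
                del alive[key]
            else:
                key = list(alive)[int(rng.integers(0, len(alive)))]
                tau = float(rng.uniform(0, 100))
                q.update_time(key, tau, 2.0)
                alive[key] = tau
            q.check()
            assert len(q) == len(alive)
            if alive:
                assert q.peek().tau == min(alive.values())


class TestInhibitionPropensity:
    def test_no_contacts(self):
        types = np.array([CellType.TARGET], dtype=np.int8)
        g = graph_from_pairs([], 1)
        assert inhibition_propensity(0, g, types, 1.0) == 0.0

    def test_two_inhibitors(self):
        # eta = 1/h with two contacting inhibitors -> a = 2/h (mean wait 30 min)
        types = np.array([CellType.TARGET, CellType.INHIBITOR,
                          CellType.INHIBITOR, CellType.TARGET], dtype=np.int8)
        g = graph_from_pairs([(0, 1), (0, 2), (0, 3)], 4)
        assert inhibition_propensity(0, g, types, 1.0) == pytest.approx(2.0)

    def test_slow_rate(self):
        types = np.array([CellType.TARGET, CellType.INHIBITOR], dtype=np.int8)
        g = graph_from_pairs([(0, 1)], 2)
        assert inhibition_propensity(0, g, types, 0.1) == pytest.approx(0.1)

    def test_rejects_non_target(self):
        types = np.array([CellType.INHIBITOR], dtype=np.int8)
        with pytest.raises(ValueError):
            inhibition_propensity(0, graph_from_pairs([], 1), types, 1.0)


class TestSchedule:
    def test_mean_waiting_time(self):
        # a = 2/h: sample mean of tau - now = 0.5 h +/- 0.005 over 1e5 draws
        rng = np.random.default_rng(7)
        waits = np.empty(100_000)
        for k in range(len(waits)):
            q = ReactionQueue()
            r = schedule(ReactionKind.INHIBITION, 0, 2.0, 10.0, rng, q)
            waits[k] = r.tau - 10.0
        assert waits.mean() == pytest.approx(0.5, abs=0.005)

    def test_huge_rate_fires_immediately(self, rng):
        q = ReactionQueue()
        r = schedule(ReactionKind.INHIBITION, 0, 1e12, 5.0, rng, q)
        assert r.tau == pytest.approx(5.0, abs=1e-9)

    def test_replay_deterministic(self):
        taus = []
        for _ in range(2):
            rng = np.random.default_rng(42)
            q = ReactionQueue()
            taus.append(schedule(ReactionKind.RECOVERY, 3, 0.7, 0.0, rng, q).tau)
        assert taus[0] == taus[1]

    def test_zero_rate_rejected(self, rng):
        with pytest.raises(ValueError):
            schedule(ReactionKind.INHIBITION, 0, 0.0, 0.0, rng, ReactionQueue())


class TestRescale:
    def _pending(self, rng, rate=1.0, now=0.0):
        q = ReactionQueue()
        r = schedule(ReactionKind.INHIBITION, 0, rate, now, rng, q)
        return q, r

    def test_doubling_halves_remaining_wait(self):
        q = ReactionQueue()
        q.push(PendingReaction(1.0, ReactionKind.INHIBITION, 0, 1.0))
        out = rescale(q, (0, ReactionKind.INHIBITION), 2.0, 0.2)
        assert out.tau == pytest.approx(0.2 + 0.8 / 2)

    def test_identity(self, rng):
        q, r = self._pending(rng, rate=1.3)
        tau = r.tau
        assert rescale(q, r.key, 1.3, 0.1).tau == tau

    def test_zero_removes(self, rng):
        q, r = self._pending(rng)
        assert rescale(q, r.key, 0.0, 0.1) is None
        assert len(q) == 0

    def test_rate_change_matches_gillespie_oracle(self):
        # rate a1 until t0, then a2: compare the scheduler (schedule + rescale)
        # against inversion sampling of the same piecewise-constant hazard
        a1, a2, t0 = 0.8, 2.5, 0.6
        n = 10_000
        rng = np.random.default_rng(11)
        sched = np.empty(n)
        for k in range(n):
            q = ReactionQueue()
            r = schedule(ReactionKind.INHIBITION, 0, a1, 0.0, rng, q)
            if r.tau > t0:
                r = rescale(q, r.key, a2, t0)
            sched[k] = r.tau
        oracle_rng = np.random.default_rng(99)
        e = oracle_rng.exponential(size=n)
        oracle = np.where(e < a1 * t0, e / a1, t0 + (e - a1 * t0) / a2)
        assert stats.ks_2samp(sched, oracle).pvalue > 0.01

    def test_toggling_contact_matches_oracle(self):
        # contact toggles every 0.1 h (on/off); the reaction is removed when
        # contact is lost and rescheduled on re-contact. Compare against
        # inversion sampling of the piecewise on/off hazard.
        eta, window = 1.7, 0.1
        n = 10_000
        rng = np.random.default_rng(13)
        sched = np.empty(n)
        for k in range(n):
            q = ReactionQueue()
            t = 0.0
            while True:
                r = schedule(ReactionKind.INHIBITION, 0, eta, t, rng, q)
                if r.tau <= t + window:  # fires during the on-window
                    sched[k] = r.tau
                    break
                q.remove(r.key)  # contact lost before firing
                t += 2 * window  # next on-window
        oracle_rng = np.random.default_rng(98)
        on_time = oracle_rng.exponential(scale=1 / eta, size=n)
        k_windows = np.floor(on_time / window)
        oracle = on_time + k_windows * window  # insert the off-windows
        assert stats.ks_2samp(sched, oracle).pvalue > 0.01


class TestSyncReactions:
    def _setup(self, pairs, types, n):
        return graph_from_pairs(pairs, n), np.arange(n, dtype=np.int64), \
            np.asarray(types, dtype=np.int8)

    def test_first_contact_schedules(self, rng):
        g, ids, types = self._setup([(0, 1)], [CellType.TARGET,
                                               CellType.INHIBITOR], 2)
        q = ReactionQueue()
        sync_reactions(g, ids, types, q, CdiParams(eta=1.0), 0.0, rng)
        assert len(q) == 1
        r = q.peek()
        assert r.kind == ReactionKind.INHIBITION and r.cell_id == 0
        assert r.rate == 1.0

    def test_contact_loss_removes(self, rng):
        g, ids, types = self._setup([(0, 1)], [CellType.TARGET,
                                               CellType.INHIBITOR], 2)
        q = ReactionQueue()
        params = CdiParams(eta=1.0)
        sync_reactions(g, ids, types, q, params, 0.0, rng)
        g2 = graph_from_pairs([], 2)
        sync_reactions(g2, ids, types, q, params, 0.1, rng)
        assert len(q) == 0
        assert types[0] == CellType.TARGET  # never inhibited

    def test_contact_count_change_rescales(self, rng):
        types = np.array([CellType.TARGET, CellType.INHIBITOR,
                          CellType.INHIBITOR], dtype=np.int8)
        ids = np.arange(3, dtype=np.int64)
        q = ReactionQueue()
        params = CdiParams(eta=1.0)
        sync_reactions(graph_from_pairs([(0, 1)], 3), ids, types, q,
                       params, 0.0, rng)
        tau1 = q.peek().tau
        sync_reactions(graph_from_pairs([(0, 1), (0, 2)], 3), ids, types, q,
                       params, 0.0, rng)
        assert q.peek().rate == 2.0
        assert q.peek().tau == pytest.approx(tau1 / 2)

    def test_recovery_for_isolated_inhibited(self, rng):
        g, ids, types = self._setup([], [CellType.INHIBITED_TARGET], 1)
        q = ReactionQueue()
        sync_reactions(g, ids, types, q, CdiParams(eta=1.0, mu=0.01), 0.0, rng)
        assert q.peek().kind == ReactionKind.RECOVERY
        assert q.peek().rate == 0.01

    def test_recovery_mean_delay(self):
        # mu = 0.01/h -> mean recovery delay 100 h over 1e4 draws
        rng = np.random.default_rng(5)
        ids = np.array([0], dtype=np.int64)
        types = np.array([CellType.INHIBITED_TARGET], dtype=np.int8)
        g = graph_from_pairs([], 1)
        taus = np.empty(10_000)
        for k in range(len(taus)):
            q = ReactionQueue()
            sync_reactions(g, ids, types, q, CdiParams(mu=0.01), 0.0, rng)
            taus[k] = q.peek().tau
        assert taus.mean() == pytest.approx(100.0, abs=3.0)

    def test_recovery_removed_on_recontact(self, rng):
        types = np.array([CellType.INHIBITED_TARGET, CellType.INHIBITOR],
                         dtype=np.int8)
        ids = np.arange(2, dtype=np.int64)
        q = ReactionQueue()
        params = CdiParams(eta=1.0, mu=0.01)
        sync_reactions(graph_from_pairs([], 2), ids, types, q, params, 0.0, rng)
        assert len(q) == 1
        sync_reactions(graph_from_pairs([(0, 1)], 2), ids, types, q,
                       params, 0.1, rng)
        assert len(q) == 0  # inhibited target in contact: nothing pending

    def test_inhibitors_never_scheduled(self, rng):
        types = np.array([CellType.INHIBITOR, CellType.INHIBITOR],
                         dtype=np.int8)
        q = ReactionQueue()
        sync_reactions(graph_from_pairs([(0, 1)], 2),
                       np.arange(2, dtype=np.int64), types, q,
                       CdiParams(eta=5.0, mu=1.0), 0.0, rng)
        assert len(q) == 0

    def test_stale_entries_dropped(self, rng):
        # a pending reaction for a vanished cell id is removed on sync
        q = ReactionQueue()
        q.push(PendingReaction(1.0, ReactionKind.INHIBITION, 999, 1.0))
        g, ids, types = self._setup([], [CellType.TARGET], 1)
        sync_reactions(g, ids, types, q, CdiParams(eta=1.0), 0.0, rng)
        assert len(q) == 0

    def test_queue_bounded_and_no_orphans(self, rng):
        # randomized contact configurations: queue size <= n, all entries
        # correspond to eligible cells with correct propensities
        params = CdiParams(eta=0.7, mu=0.02)
        for seed in range(30):
            r = np.random.default_rng(seed)
            n = 20
            types = r.integers(0, 3, n).astype(np.int8)
            ids = np.arange(n, dtype=np.int64)
            pairs = {tuple(sorted(p)) for p in
                     r.integers(0, n, size=(15, 2)) if p[0] != p[1]}
            g = graph_from_pairs(sorted(pairs), n)
            q = ReactionQueue()
            sync_reactions(g, ids, types, q, params, 0.0, r)
            assert len(q) <= n
            counts = inhibitor_contact_counts(g, types)
            for key in q.keys():
                cid, kind = key
                if kind == ReactionKind.INHIBITION:
                    assert types[cid] == CellType.TARGET
                    assert q.get(key).rate == pytest.approx(
                        params.eta * counts[cid])
                else:
                    assert types[cid] == CellType.INHIBITED_TARGET
                    assert counts[cid] == 0
            # and every eligible cell is represented
            for cid in range(n):
                if types[cid] == CellType.TARGET and counts[cid] > 0:
                    assert (cid, ReactionKind.INHIBITION) in q
                if types[cid] == CellType.INHIBITED_TARGET and counts[cid] == 0:
                    assert (cid, ReactionKind.RECOVERY) in q


class TestFire:
    def test_inhibition(self):
        types = np.array([CellType.TARGET], dtype=np.int8)
        r = PendingReaction(1.0, ReactionKind.INHIBITION, 0, 1.0)
        assert fire(r, {0: 0}, types) == 0
        assert types[0] == CellType.INHIBITED_TARGET

    def test_recovery(self):
        types = np.array([CellType.INHIBITED_TARGET], dtype=np.int8)
        r = PendingReaction(1.0, ReactionKind.RECOVERY, 0, 1.0)
        fire(r, {0: 0}, types)
        assert types[0] == CellType.TARGET

    def test_stale_cell_dropped(self, caplog):
        types = np.array([CellType.TARGET], dtype=np.int8)
        r = PendingReaction(1.0, ReactionKind.INHIBITION, 42, 1.0)
        assert fire(r, {0: 0}, types) is None
        assert types[0] == CellType.TARGET

    def test_wrong_state_dropped(self):
        types = np.array([CellType.INHIBITOR], dtype=np.int8)
        r = PendingReaction(1.0, ReactionKind.INHIBITION, 0, 1.0)
        assert fire(r, {0: 0}, types) is None
        assert types[0] == CellType.INHIBITOR


class TestDistributionalExactness:
    def test_static_config_exponential(self):
        # static contacts: time to inhibition is exactly Exponential(eta*k)
        eta, k = 0.9, 3
        rng = np.random.default_rng(21)
        types = np.array([CellType.TARGET] + [CellType.INHIBITOR] * k,
                         dtype=np.int8)
        ids = np.arange(k + 1, dtype=np.int64)
        g = graph_from_pairs([(0, j) for j in range(1, k + 1)], k + 1)
        taus = np.empty(10_000)
        for i in range(len(taus)):
            q = ReactionQueue()
            sync_reactions(g, ids, types, q, CdiParams(eta=eta), 0.0, rng)
            taus[i] = q.peek().tau
        res = stats.kstest(taus, stats.expon(scale=1 / (eta * k)).cdf)
        assert res.pvalue > 0.01

    def test_frozen_network_matches_gillespie(self):
        # 10-cell frozen configuration: the scheduler's (first event time,
        # first event identity) distribution matches a direct Gillespie
        # simulation of the same reaction set
        rng = np.random.default_rng(31)
        types = np.array([0, 0, 0, 1, 1, 1, 1, 2, 2, 0], dtype=np.int8)
        ids = np.arange(10, dtype=np.int64)
        pairs = [(0, 3), (0, 4), (1, 5), (2, 3), (2, 4), (2, 6), (7, 8),
                 (1, 0), (9, 2)]
        g = graph_from_pairs([tuple(sorted(p)) for p in pairs], 10)
        params = CdiParams(eta=0.6, mu=0.05)

        counts = inhibitor_contact_counts(g, types)
        # reaction set: inhibition for targets with contacts, recovery for
        # isolated inhibited targets
        rates = {}
        for c in range(10):
            if types[c] == CellType.TARGET and counts[c] > 0:
                rates[c] = params.eta * counts[c]
            elif types[c] == CellType.INHIBITED_TARGET and counts[c] == 0:
                rates[c] = params.mu

        n = 10_000
        first_t = np.empty(n)
        first_who = np.empty(n, dtype=int)
        for i in range(n):
            q = ReactionQueue()
            sync_reactions(g, ids, types.copy(), q, params, 0.0, rng)
            r = q.pop()
            first_t[i] = r.tau
            first_who[i] = r.cell_id

        # direct Gillespie oracle: total-rate exponential + categorical pick
        orng = np.random.default_rng(77)
        cells = np.array(sorted(rates))
        a = np.array([rates[c] for c in cells])
        a0 = a.sum()
        oracle_t = orng.exponential(scale=1 / a0, size=n)
        oracle_who = cells[orng.choice(len(cells), p=a / a0, size=n)]

        assert stats.ks_2samp(first_t, oracle_t).pvalue > 0.01
        # identity distribution: chi-square against expected proportions
        obs = np.array([(first_who == c).sum() for c in cells])
        exp = n * a / a0
        chi = stats.chisquare(obs, exp)
        assert chi.pvalue > 0.01
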