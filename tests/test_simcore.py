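import itertools

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from raidsim import (
    DEVIL,
    LEADER,
    REGULAR,
    SAINT,
    AgentPopulation,
    ConfigurationError,
    ControlAssignment,
    ParameterError,
    SimulationConfig,
    SocialNetwork,
    assign_payoffs,
    expand,
    init_population,
    nucleate,
    play_round,
    run_generation,
    run_simulation,
    update_strategies,
)


def make_pop(strategies, roles):
    return AgentPopulation(np.asarray(strategies, float), np.asarray(roles, np.int8))


class TestConfig:
    def test_defaults_valid(self):
        SimulationConfig().validate(91)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n": 0},
            {"m": 0},
            {"r": 0},
            {"alpha": 0.0},
            {"alpha": 1.5},
            {"reward": 0.0},
            {"cost": -1.0},
            {"placement": "betweenness"},
            {"saints": -1},
            {"stall_window": 0},
        ],
    )
    def test_invalid(self, kwargs):
        with pytest.raises(ConfigurationError):
            SimulationConfig(**kwargs).validate(91)

    def test_role_budget(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(leaders=5, saints=50, devils=40).validate(91)

    def test_leader_count_default(self):
        cfg = SimulationConfig()
        assert cfg.leader_count(91) == 5
        assert cfg.leader_count(500) == 25
        assert cfg.leader_count(5) == 1  # floor of one leader

    def test_round_trip_dict(self):
        cfg = SimulationConfig(n=3, m=7, alpha=0.5)
        assert SimulationConfig.from_dict(cfg.to_dict()) == cfg

    def test_unknown_key(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig.from_dict({"bogus": 1})


class TestInitPopulation:
    def test_strategy_ranges(self, ws91, rng):
        net, leaders = ws91
        pop = init_population(net, SimulationConfig(), leaders, None, rng)
        lead = pop.indices_of(LEADER)
        reg = pop.regular_indices
        assert set(lead) == set(leaders)
        assert np.all((pop.strategy[lead] >= 0.5) & (pop.strategy[lead] <= 1.0))
        assert np.all((pop.strategy[reg] >= 0.0) & (pop.strategy[reg] <= 1.0))
        assert np.all(pop.payoff == 0.0)

    def test_alpha_bounds_regulars(self, ws91, rng):
        net, leaders = ws91
        pop = init_population(net, SimulationConfig(alpha=0.5), leaders, None, rng)
        assert np.all(pop.strategy[pop.regular_indices] <= 0.5)
        # leaders unchanged by alpha
        assert np.all(pop.strategy[pop.indices_of(LEADER)] >= 0.5)

    def test_alpha_zero_rejected(self, ws91, rng):
        net, leaders = ws91
        with pytest.raises(ConfigurationError):
            init_population(net, SimulationConfig(alpha=0.0), leaders, None, rng)

    def test_saint_and_devil_strategies(self, ws91, rng):
        net, leaders = ws91
        free = [v for v in range(net.n) if v not in leaders]
        controls = ControlAssignment(saints=frozenset(free[:3]), devils=frozenset(free[3:6]))
        pop = init_population(net, SimulationConfig(), leaders, controls, rng)
        assert np.all(pop.strategy[list(controls.saints)] == 0.0)
        assert np.all(pop.strategy[list(controls.devils)] == 1.0)
        assert np.all(pop.effective_join_prob(np.array(sorted(controls.saints))) == 0.0)
        assert np.all(pop.effective_join_prob(np.array(sorted(controls.devils))) == 1.0)

    def test_overlapping_roles_rejected(self, ws91, rng):
        net, leaders = ws91
        some_leader = next(iter(leaders))
        controls = ControlAssignment(saints=frozenset({some_leader}))
        with pytest.raises(ConfigurationError):
            init_population(net, SimulationConfig(), leaders, controls, rng)


class TestNucleate:
    def test_all_devils_join(self, ring10, rng):
        roles = [DEVIL] * 10
        roles[0] = LEADER
        pop = make_pop([0.5] * 10, roles)
        invited, nucleus = nucleate(ring10, pop, 0, 3, 1, rng)
        assert invited.size == 3
        assert np.array_equal(nucleus, invited)

    def test_all_saints_refuse(self, ring10, rng):
        roles = [SAINT] * 10
        roles[0] = LEADER
        pop = make_pop([0.9] * 10, roles)
        invited, nucleus = nucleate(ring10, pop, 0, 3, 1, rng)
        assert invited.size == 3
        assert nucleus.size == 0

    def test_invitations_capped_by_neighborhood(self, path4, rng):
        roles = [REGULAR] * 4
        roles[0] = LEADER
        pop = make_pop([1.0] * 4, roles)
        invited, nucleus = nucleate(path4, pop, 0, 5, 2, rng)
        # only nodes 1, 2 are within two hops of node 0
        assert set(invited.tolist()) == {1, 2}

    def test_sampled_from_radius(self, ring10, rng):
        roles = [REGULAR] * 10
        roles[0] = LEADER
        pop = make_pop([1.0] * 10, roles)
        for _ in range(25):
            invited, _ = nucleate(ring10, pop, 0, 2, 1, rng)
            assert set(invited.tolist()) <= {1, 2, 8, 9}

    def test_non_leader_rejected(self, ring10, rng):
        pop = make_pop([0.5] * 10, [REGULAR] * 10)
        with pytest.raises(ParameterError):
            nucleate(ring10, pop, 0, 2, 1, rng)


class TestExpand:
    def test_certain_acceptance(self, path4, rng):
        roles = [LEADER, REGULAR, REGULAR, REGULAR]
        pop = make_pop([0.5, 1.0, 1.0, 1.0], roles)
        invited, joiners = expand(path4, pop, np.array([1]), np.array([1]), 0, rng)
        assert set(invited.tolist()) == {2}
        assert set(joiners.tolist()) == {2}

    def test_exclusions(self, ring10, rng):
        roles = [LEADER] + [REGULAR] * 9
        pop = make_pop([1.0] * 10, roles)
        nucleus = np.array([1, 2])
        already = np.array([1, 2, 3])
        invited, _ = expand(ring10, pop, nucleus, already, 0, rng)
        # friends of {1,2} = {0,1,2,3,4,9} minus nucleus, leader, already asked
        assert set(invited.tolist()) == {4, 9}

    def test_one_draw_regardless_of_adjacency(self, rng):
        # node 4 is adjacent to all three nucleus members 1, 2, 3
        g = nx.Graph([(0, 1), (0, 2), (0, 3), (1, 4), (2, 4), (3, 4)])
        net = SocialNetwork(g)
        roles = [LEADER, REGULAR, REGULAR, REGULAR, REGULAR]
        pop = make_pop([1.0, 1.0, 1.0, 1.0, 0.5], roles)
        nucleus = np.array([1, 2, 3])
        trials = 10_000
        joins = 0
        for _ in range(trials):
            _, joiners = expand(net, pop, nucleus, nucleus, 0, rng)
            joins += 4 in joiners
        # single Bernoulli(0.5) draw: 3-sigma binomial band around 0.5
        sigma = np.sqrt(0.5 * 0.5 / trials)
        assert abs(joins / trials - 0.5) < 3 * sigma

    def test_empty_nucleus_rejected(self, path4, rng):
        pop = make_pop([0.5] * 4, [LEADER, REGULAR, REGULAR, REGULAR])
        with pytest.raises(ParameterError):
            expand(path4, pop, np.array([], dtype=np.int64), np.array([]), 0, rng)


class TestAssignPayoffs:
    @pytest.mark.parametrize(
        "occurred,is_joiner,reward,cost,expected",
        [
            (True, True, 1.0, 1.0, 1.0),    # joined an occurring raid
            (True, False, 1.0, 1.0, -1.0),  # refused an occurring raid
            (False, True, 1.0, 1.0, -1.0),  # joined a failed raid
            (False, False, 1.0, 1.0, 1.0),  # refused a failed raid
            (False, False, 2.0, 1.0, 2.0),  # unequal payoffs: reward twice cost
            (True, False, 2.0, 1.0, -1.0),
        ],
    )
    def test_cases(self, occurred, is_joiner, reward, cost, expected):
        pop = make_pop([0.5] * 5, [REGULAR] * 5)
        asked = np.array([1, 2])
        joined = np.array([1])  # node 1 joined; node 2 was asked and refused
        target = 1 if is_joiner else 2
        assign_payoffs(pop, asked, joined, occurred, reward, cost)
        assert pop.payoff[target] == expected

    def test_unasked_get_zero(self):
        pop = make_pop([0.5] * 5, [LEADER] + [REGULAR] * 4)
        assign_payoffs(pop, np.array([1, 2]), np.array([1]), True, 1.0, 1.0)
        assert pop.payoff[0] == 0.0
        assert pop.payoff[3] == 0.0
        assert pop.payoff[4] == 0.0

    def test_nonzero_exactly_on_asked(self, rng):
        pop = make_pop([0.5] * 10, [REGULAR] * 10)
        asked = np.array([2, 3, 5, 7])
        joined = np.array([3, 5])
        assign_payoffs(pop, asked, joined, True, 1.0, 1.0)
        assert set(np.flatnonzero(pop.payoff != 0).tolist()) == set(asked.tolist())
        # sum = reward * |winners| - cost * |losers|
        assert pop.payoff.sum() == 1.0 * 2 - 1.0 * 2


class TestUpdateStrategies:
    def test_equal_payoffs_no_change(self, rng):
        pop = make_pop([0.1, 0.5, 0.9], [REGULAR] * 3)
        before = pop.strategy.copy()
        update_strategies(pop, rng)
        assert np.array_equal(pop.strategy, before)

    def test_two_agent_exhaustive(self, rng):
        # loser adopts the winner's strategy; winner keeps its own
        pop = make_pop([0.2, 0.8], [REGULAR, REGULAR])
        pop.payoff[:] = [1.0, -1.0]
        update_strategies(pop, rng)
        assert pop.strategy[1] == 0.2
        assert pop.strategy[0] == 0.2  # winner kept its own value

    def test_controls_never_learn_nor_teach(self, rng):
        # saint sits next to the highest payoff; devil likewise
        strategies = [0.0, 1.0, 0.5, 0.5, 0.7]
        roles = [SAINT, DEVIL, REGULAR, REGULAR, LEADER]
        pop = make_pop(strategies, roles)
        pop.payoff[:] = [5.0, 5.0, -1.0, 1.0, 5.0]
        for _ in range(50):
            update_strategies(pop, rng)
        assert pop.strategy[0] == 0.0
        assert pop.strategy[1] == 1.0
        assert pop.strategy[4] == 0.7
        # regulars can only carry another regular's value, never a control's
        assert set(pop.strategy[2:4].tolist()) == {0.5}

    def test_single_regular_noop(self, rng):
        pop = make_pop([0.3, 0.9], [REGULAR, LEADER])
        pop.payoff[:] = [-1.0, 1.0]
        update_strategies(pop, rng)
        assert pop.strategy[0] == 0.3

    def test_synchronous_snapshot(self, rng):
        # all agents see pre-update strategies: with payoffs strictly
        # increasing, everyone who adopts gets a pre-update value
        pop = make_pop([0.1, 0.2, 0.3, 0.4], [REGULAR] * 4)
        pop.payoff[:] = [0.0, 1.0, 2.0, 3.0]
        update_strategies(pop, rng)
        assert set(pop.strategy.tolist()) <= {0.1, 0.2, 0.3, 0.4}
        assert pop.strategy[3] == 0.4  # top payoff never adopts


class TestRunGeneration:
    def test_threshold_met_by_single_devil(self, ring10, rng):
        roles = [LEADER] + [SAINT] * 9
        roles[1] = DEVIL
        pop = make_pop([0.5] * 10, roles)
        cfg = SimulationConfig(n=9, m=1, r=1)
        occurred = [
            run_generation(ring10, pop, cfg, np.array([0]), rng)[0].occurred
            for _ in range(20)
        ]
        # node 1 is always within radius 1 of node 0 and n covers the pool
        assert all(occurred)

    def test_all_saints_never_raid(self, ring10, rng):
        roles = [LEADER] + [SAINT] * 9
        pop = make_pop([0.5] * 10, roles)
        cfg = SimulationConfig(n=4, m=1, r=2)
        for _ in range(20):
            record, _ = run_generation(ring10, pop, cfg, np.array([0]), rng)
            assert not record.occurred
            assert record.nucleus_joined == frozenset()

    def test_record_invariants(self, ws91, rng):
        net, leaders = ws91
        pop = init_population(net, SimulationConfig(), leaders, None, rng)
        cfg = SimulationConfig()
        for _ in range(50):
            record, _ = run_generation(net, pop, cfg, np.array(sorted(leaders)), rng)
            assert record.nucleus_joined <= record.nucleus_invited
            assert record.expansion_joined <= record.expansion_invited
            assert record.joined <= record.asked
            assert record.leader not in record.asked
            assert record.occurred == (len(record.joined) >= cfg.m)

    def test_payoffs_reset_after_generation(self, ws91, rng):
        net, leaders = ws91
        pop = init_population(net, SimulationConfig(), leaders, None, rng)
        run_generation(net, pop, SimulationConfig(), np.array(sorted(leaders)), rng)
        assert np.all(pop.payoff == 0.0)


def exact_raid_probability(net, leader, devils, n, m):
    """Brute-force oracle: exact raid probability with deterministic joiners.

    Enumerates every equally likely nucleation sample; devils join
    surely, everyone else surely refuses, so each sample's outcome is
    deterministic and the occurrence probability is a finite average.
    """
    pool = sorted(int(v) for v in net.neighborhood(leader, 1))
    k = min(n, len(pool))
    total = 0
    hits = 0
    for invited in itertools.combinations(pool, k):
        nucleus = [v for v in invited if v in devils]
        joined = set(nucleus)
        if nucleus:
            friends = set()
            for v in nucleus:
                friends |= set(net.neighbors(v).tolist())
            expansion = friends - set(nucleus) - {leader} - set(invited)
            joined |= {v for v in expansion if v in devils}
        total += 1
        hits += len(joined) >= m
    return hits / total


class TestBruteForceEquivalence:
    def test_six_node_oracle(self):
        g = nx.Graph([(0, 1), (0, 2), (0, 3), (1, 4), (2, 4), (3, 5), (4, 5)])
        net = SocialNetwork(g)
        devils = {1, 4, 5}
        roles = [LEADER] + [DEVIL if v in devils else SAINT for v in range(1, 6)]
        pop = make_pop([0.5] * 6, roles)
        cfg = SimulationConfig(n=2, m=2, r=1)
        exact = exact_raid_probability(net, 0, devils, 2, 2)
        rng = np.random.default_rng(2024)
        trials = 100_000
        hits = 0
        for _ in range(trials):
            record, _ = run_generation(net, pop, cfg, np.array([0]), rng)
            hits += record.occurred
        freq = hits / trials
        sigma = np.sqrt(exact * (1 - exact) / trials)
        assert abs(freq - exact) < 3 * sigma

    def test_oracle_value_is_hand_checkable(self):
        # invited {1,2} and {1,3} both raid via devil 4; {2,3} never nucleates
        g = nx.Graph([(0, 1), (0, 2), (0, 3), (1, 4), (2, 4), (3, 5), (4, 5)])
        net = SocialNetwork(g)
        assert exact_raid_probability(net, 0, {1, 4, 5}, 2, 2) == pytest.approx(2 / 3)


class TestRunSimulation:
    def test_identical_regular_strategies_are_frozen(self, ring10):
        # raids always fail (m > N) and copying identical values changes
        # nothing, so the shared strategy persists and MRR is exactly 1
        pop = make_pop([0.3] * 10, [LEADER] + [REGULAR] * 9)
        initial_mean = pop.mean_strategy()
        rng = np.random.default_rng(0)
        for _ in range(30):
            run_generation(ring10, pop, SimulationConfig(n=3, m=20), np.array([0]), rng)
        assert np.all(pop.strategy[1:] == 0.3)
        assert pop.mean_strategy() / initial_mean == pytest.approx(1.0)

    def test_no_learners_mrr_one(self, ws91):
        net, leaders = ws91
        free = [v for v in range(net.n) if v not in leaders]
        controls = ControlAssignment(saints=frozenset(free))
        cfg = SimulationConfig(saints=len(free))
        res = run_simulation(net, cfg, leaders, controls, seed=3)
        assert res.converged
        assert res.generations == 0
        assert res.mrr == pytest.approx(1.0)

    def test_seeded_determinism(self, ws91):
        net, leaders = ws91
        cfg = SimulationConfig()
        a = run_simulation(net, cfg, leaders, seed=77, record_trajectory=True)
        b = run_simulation(net, cfg, leaders, seed=77, record_trajectory=True)
        assert a.trajectory == b.trajectory
        assert a.mrr == b.mrr and a.generations == b.generations

    def test_mrr_identity(self, ws91):
        net, leaders = ws91
        res = run_simulation(net, SimulationConfig(), leaders, seed=11)
        assert res.mrr == pytest.approx(res.final_mean_strategy / res.initial_mean_strategy)
        assert res.generations <= SimulationConfig().max_generations

    def test_trajectory_and_snapshots(self, ws91):
        net, leaders = ws91
        res = run_simulation(
            net, SimulationConfig(), leaders, seed=11,
            record_trajectory=True, snapshot_generations=[0, 5],
        )
        assert len(res.trajectory) == res.generations + 1
        assert res.trajectory[0] == pytest.approx(res.initial_mean_strategy)
        assert res.trajectory[-1] == pytest.approx(res.final_mean_strategy)
        assert set(res.snapshots) == {0, 5}
        assert res.snapshots[0].shape == (net.n,)


class TestStrategyInvariants:
    @settings(max_examples=10, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_strategies_stay_in_unit_interval(self, ws91, seed):
        net, leaders = ws91
        rng = np.random.default_rng(seed)
        pop = init_population(net, SimulationConfig(), leaders, None, rng)
        initial_values = set(pop.strategy.tolist())
        cfg = SimulationConfig()
        for _ in range(60):
            run_generation(net, pop, cfg, np.array(sorted(leaders)), rng)
            assert np.all((pop.strategy >= 0) & (pop.strategy <= 1))
            # copying cannot create new values
            assert set(pop.strategy.tolist()) <= initial_values

    def test_value_set_shrinks(self, ws91, rng):
        net, leaders = ws91
        pop = init_population(net, SimulationConfig(), leaders, None, rng)
        cfg = SimulationConfig()
        sizes = []
        for _ in range(200):
            run_generation(net, pop, cfg, np.array(sorted(leaders)), rng)
            sizes.append(len(set(pop.strategy[pop.regular_indices].tolist())))
        assert sizes[-1] <= sizes[0]
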