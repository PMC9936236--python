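"""Agent mechanics: actions, reward cases, DDQN targets, prioritized replay."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import stub_plan
from moapn.moapn_agent import (
    ACTION_MULTIPLIERS,
    AgentEnsemble,
    AgentNetworks,
    QNetwork,
    SumTree,
    Transition,
    apply_action,
    ddqn_target,
    reward,
    td_loss,
    train_step,
)


class TestApplyAction:
    @pytest.mark.parametrize(
        "action,expected", [(0, 18.0), (1, 19.4), (2, 20.0), (3, 21.0)]
    )
    def test_multipliers(self, action, expected):
        assert apply_action(20.0, action) == pytest.approx(expected)

    @pytest.mark.parametrize("action", [0, 1, 3])
    def test_inverse_recovers_value(self, action):
        v = apply_action(37.123456789, action, floor_gy=0.0)
        assert v / ACTION_MULTIPLIERS[action] == pytest.approx(
            37.123456789, abs=1e-12
        )

    def test_floor_and_errors(self):
        assert apply_action(0.5, 0, floor_gy=0.5) == 0.5
        with pytest.raises(ValueError, match="action"):
            apply_action(20.0, 4)
        with pytest.raises(ValueError, match="positive"):
            apply_action(0.0, 1)


class TestReward:
    def test_coverage_breach_is_terminal(self):
        prev = stub_plan(d95=51.0, eva=10.0)
        nxt = stub_plan(d95=0.94 * 50.0, eva=50.0)
        assert reward(prev, nxt, 1, "Ring1", dp=50.0) == (-200.0, True)

    def test_increase_on_satisfied_ring(self):
        prev = stub_plan(eva=10.0, ring_geud={"Ring1": 10.0},
                         ring_objectives={"Ring1": 12.0})
        nxt = stub_plan(eva=50.0)
        assert reward(prev, nxt, 3, "Ring1") == (-50.0, False)

    @pytest.mark.parametrize(
        "eva_next,expected", [(-10.0, -20.0), (10.0, 5.0), (40.0, 20.0)]
    )
    def test_eva_comparison_cases(self, eva_next, expected):
        prev = stub_plan(eva=10.0)
        nxt = stub_plan(eva=eva_next)
        assert reward(prev, nxt, 1, "Ring1", eva_tol=1e-6) == (expected, False)

    def test_unscored_state_rejected(self):
        prev = stub_plan()
        prev.eva_score = None
        with pytest.raises(ValueError, match="scored"):
            reward(prev, stub_plan(), 1, "Ring1")

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(
        d95=st.floats(40.0, 55.0),
        geud=st.floats(1.0, 60.0),
        obj=st.floats(1.0, 60.0),
        action=st.integers(0, 3),
        eva_prev=st.floats(-500.0, 900.0),
        eva_next=st.floats(-500.0, 900.0),
    )
    def test_matches_if_chain_oracle(self, d95, geud, obj, action, eva_prev, eva_next):
        """The printed case order is exhaustive and mutually exclusive."""
        prev = stub_plan(eva=eva_prev, ring_geud={"Ring1": geud},
                         ring_objectives={"Ring1": obj})
        nxt = stub_plan(d95=d95, eva=eva_next)
        got = reward(prev, nxt, action, "Ring1", dp=50.0, eva_tol=1e-6)
        if d95 < 47.5:
            expected = (-200.0, True)
        elif action == 3 and geud <= obj:
            expected = (-50.0, False)
        elif eva_next < eva_prev - 1e-6:
            expected = (-20.0, False)
        elif eva_next <= eva_prev + 1e-6:
            expected = (5.0, False)
        else:
            expected = (20.0, False)
        assert got == expected


def constant_net(outputs) -> QNetwork:
    """A QNetwork forced to output a constant Q-vector for any state."""
    net = QNetwork(seed=0)
    for k in ("W1", "W2", "W3"):
        net.params[k] = np.zeros_like(net.params[k])
    net.params["b1"] = np.zeros_like(net.params["b1"])
    net.params["b2"] = np.zeros_like(net.params["b2"])
    net.params["b3"] = np.asarray(outputs, dtype=float)
    return net


def _state(rng=None):
    rng = rng or np.random.default_rng(0)
    return rng.uniform(0, 1, (850, 3))


class TestDDQNTarget:
    def test_hand_example(self):
        nets = AgentNetworks(
            q_eva=constant_net([0.2, 0.8, 0.1, 0.0]),
            q_tar=constant_net([0.9, 0.5, 0.1, 0.2]),
        )
        tr = Transition(_state(), 1, 1.0, _state(), False)
        # argmax Q_eva = action 1; Q_tar(s', 1) = 0.5 -> 1 + 0.9 * 0.5 = 1.45
        assert ddqn_target(tr, nets, gamma=0.9) == pytest.approx(1.45)

    def test_gamma_zero_and_terminal_reduce_to_reward(self):
        nets = AgentNetworks.create(seed=1)
        tr = Transition(_state(), 2, -20.0, _state(), False)
        assert ddqn_target(tr, nets, gamma=0.0) == pytest.approx(-20.0)
        tr_term = Transition(_state(), 2, -200.0, _state(), True)
        assert ddqn_target(tr_term, nets, gamma=0.9) == -200.0

    def test_identical_networks_reduce_to_vanilla_max(self):
        nets = AgentNetworks.create(seed=3)
        s2 = _state()
        tr = Transition(_state(), 0, 2.0, s2, False)
        q = nets.q_tar.forward(s2)[0]
        assert ddqn_target(tr, nets, 0.9) == pytest.approx(2.0 + 0.9 * q.max())

    def test_never_exceeds_max_form(self):
        rng = np.random.default_rng(9)
        for seed in range(5):
            nets = AgentNetworks.create(seed=seed)
            nets.q_eva.adam_step(  # desynchronize the two networks
                {k: rng.normal(size=v.shape) for k, v in nets.q_eva.params.items()},
                lr=0.05,
            )
            s2 = _state(rng)
            tr = Transition(_state(rng), 0, 1.0, s2, False)
            max_form = 1.0 + 0.9 * nets.q_tar.forward(s2)[0].max()
            assert ddqn_target(tr, nets, 0.9) <= max_form + 1e-12


class TestTDLoss:
    def test_zero_when_q_already_equals_targets(self):
        # constant nets, terminal transitions with r equal to the Q output
        nets = AgentNetworks(
            q_eva=constant_net([1.0, 2.0, 3.0, 4.0]),
            q_tar=constant_net([0.0, 0.0, 0.0, 0.0]),
        )
        batch = [Transition(_state(), a, float(a + 1), _state(), True)
                 for a in range(4)]
        loss, td = td_loss(batch, nets, gamma=0.9)
        assert loss == pytest.approx(0.0, abs=1e-18)
        np.testing.assert_allclose(td, 0.0, atol=1e-12)

    def test_single_transition_hand_value(self):
        nets = AgentNetworks(
            q_eva=constant_net([0.2, 0.8, 0.1, 0.0]),
            q_tar=constant_net([0.9, 0.5, 0.1, 0.2]),
        )
        tr = Transition(_state(), 3, 1.0, _state(), False)
        # target 1.45 (above), Q(s, 3) = 0.0 -> loss = 1.45^2
        loss, td = td_loss([tr], nets, 0.9)
        assert loss == pytest.approx(1.45**2)
        assert td[0] == pytest.approx(1.45)

    def test_invariant_to_batch_order(self):
        nets = AgentNetworks.create(seed=5)
        rng = np.random.default_rng(1)
        batch = [
            Transition(_state(rng), int(rng.integers(4)), float(rng.normal()),
                       _state(rng), bool(rng.integers(2)))
            for _ in range(6)
        ]
        l1, _ = td_loss(batch, nets, 0.9)
        l2, _ = td_loss(batch[::-1], nets, 0.9)
        assert l1 == pytest.approx(l2, rel=1e-12)
        with pytest.raises(ValueError, match="empty"):
            td_loss([], nets, 0.9)


def test_training_converges_on_bandit_environment():
    """With fixed rewards (+20 for action 1, -20 otherwise) the greedy
    choice converges to the rewarded action."""
    nets = AgentNetworks.create(seed=0)
    rng = np.random.default_rng(0)
    states = [_state(rng) for _ in range(8)]
    for step in range(300):
        batch = []
        for _ in range(20):
            s = states[rng.integers(len(states))]
            a = int(rng.integers(4))
            r = 20.0 if a == 1 else -20.0
            batch.append(Transition(s, a, r, s, True))
        train_step(batch, nets, gamma=0.0, lr=3e-3)
    q = nets.q_eva.forward(np.stack(states))
    assert (np.argmax(q, axis=1) == 1).all()


class TestSumTree:
    def test_root_is_total_priority(self):
        tree = SumTree(capacity=4)
        for p in (1.0, 2.0, 3.0, 4.0):
            tree.add(p, f"item{p}")
        assert tree.total == pytest.approx(10.0)

    def test_descent_selects_correct_leaf(self):
        tree = SumTree(capacity=4)
        for p in (1.0, 2.0, 3.0, 4.0):
            tree.add(p, p)
        # cumulative 0.5 falls inside the first leaf (priority 1)
        _, priority, data = tree.get(0.5)
        assert (priority, data) == (1.0, 1.0)
        # cumulative 1.5 falls inside the second leaf
        _, priority, data = tree.get(1.5)
        assert (priority, data) == (2.0, 2.0)
        # near-total falls in the last leaf
        _, priority, data = tree.get(9.99)
        assert (priority, data) == (4.0, 4.0)

    def test_root_equals_leaf_sum_under_fuzzing(self):
        rng = np.random.default_rng(11)
        tree = SumTree(capacity=16)
        leaves = []
        for i in range(200):  # overwrites wrap several times
            leaf = tree.add(float(rng.uniform(0.1, 5.0)), i)
            leaves.append(leaf)
            if leaves and rng.uniform() < 0.5:
                tree.update(
                    leaves[rng.integers(len(leaves))], float(rng.uniform(0.1, 5.0))
                )
            assert tree.total == pytest.approx(
                tree.nodes[tree.capacity - 1:].sum(), rel=1e-9
            )
        assert tree.size == 16

    def test_fifo_overwrite(self):
        tree = SumTree(capacity=2)
        tree.add(1.0, "a")
        tree.add(1.0, "b")
        tree.add(1.0, "c")  # overwrites "a"
        assert set(tree.data) == {"b", "c"}

    def test_sampling_errors_and_determinism(self):
        tree = SumTree(capacity=4)
        with pytest.raises(ValueError, match="empty"):
            tree.sample(2, np.random.default_rng(0))
        for p in (1.0, 5.0):
            tree.add(p, p)
        a, _ = tree.sample(10, np.random.default_rng(3))
        b, _ = tree.sample(10, np.random.default_rng(3))
        assert a == b


def test_ensemble_checkpoint_round_trip(tmp_path):
    ens = AgentEnsemble.create(seed=4)
    ens.train_steps = 123
    ens.save(tmp_path)
    loaded = AgentEnsemble.load(tmp_path)
    assert loaded.train_steps == 123
    s = _state()
    for ring, nets in ens.networks.items():
        np.testing.assert_array_equal(
            nets.q_eva.forward(s), loaded.networks[ring].q_eva.forward(s)
        )
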