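"""Multi-agent DDQN machinery: Q-networks, targets, replay, actions, reward.

Five agents — one per dose-gradient ring — each own a small fully-connected
Q-network pair (evaluation and target) and a prioritized replay pool built
on a Sum-Tree.  An agent's input is its 850 x 3 DVH view (PTV, body, own
ring); the output is one Q-value per action.  The four actions rescale the
agent's ring objective by x0.90, x0.97, x1.00 or x1.05.

The double-DQN target decouples action selection (evaluation network) from
valuation (target network):

    y = r + gamma * Q_tar(s', argmax_a Q_eva(s', a))        (non-terminal)
    y = r                                                    (terminal)

The networks are compact numpy multilayer perceptrons trained with Adam on
the mean squared TD error; with five agents and 850 x 3 inputs this trains
comfortably on a single CPU.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dvh_metrics import PlanState

__all__ = [
    "ACTION_MULTIPLIERS",
    "apply_action",
    "reward",
    "QNetwork",
    "AgentNetworks",
    "ddqn_target",
    "td_loss",
    "train_step",
    "Transition",
    "SumTree",
    "AgentEnsemble",
]

#: action id -> multiplicative adjustment of the ring objective:
#: 0 decrease 10%, 1 decrease 3%, 2 keep, 3 increase 5%
ACTION_MULTIPLIERS: tuple[float, ...] = (0.90, 0.97, 1.00, 1.05)


def apply_action(
    objective_gy: float, action_id: int, floor_gy: float = 0.5
) -> float:
    """Rescale an objective dose by the chosen action's multiplier."""
    if objective_gy <= 0:
        raise ValueError("objective dose must be positive")
    if action_id not in range(len(ACTION_MULTIPLIERS)):
        raise ValueError(f"invalid action id {action_id}")
    return max(objective_gy * ACTION_MULTIPLIERS[action_id], floor_gy)


def reward(
    prev: PlanState,
    next_: PlanState,
    agent_action: int,
    agent_ring: str,
    dp: float = 50.0,
    eva_tol: float = 1e-6,
) -> tuple[float, bool]:
    """Per-agent reward for one adjustment step, with its terminal flag.

    Cases, evaluated in order: (1) the adjusted plan's PTV D95 fell below
    95% of prescription -> -200 and the episode terminates; (2) the agent
    increased a ring objective that its ring already satisfied -> -50;
    otherwise the plan-score change decides: decrease -> -20, unchanged
    (within ``eva_tol``) -> +5, increase -> +20.
    """
    if prev.eva_score is None or next_.eva_score is None:
        raise ValueError("both plan states must be scored before reward")
    if next_.metrics["ptv_d95"] < 0.95 * dp:
        return -200.0, True
    if agent_action == 3:
        try:
            actual = prev.ring_geud[agent_ring]
            objective = prev.ring_objectives[agent_ring]
        except KeyError:
            raise ValueError(f"plan state lacks ring data for {agent_ring!r}")
        if actual <= objective:
            return -50.0, False
    delta = next_.eva_score - prev.eva_score
    if delta < -eva_tol:
        return -20.0, False
    if delta <= eva_tol:
        return 5.0, False
    return 20.0, False


# ---------------------------------------------------------------------------
# Q-networks


class QNetwork:
    """Compact MLP Q-network for one agent.

    The 850 x 3 DVH view is average-pooled along the dose axis by a factor
    of 10 (850 -> 85), flattened, and passed through two ReLU layers
    (256, 128) to four linear Q-values.  Adam state lives on the network.
    """

    POOL = 10
    N_BINS = 850
    N_COLS = 3
    N_ACTIONS = 4

    def __init__(self, seed: int = 0, hidden: tuple[int, int] = (256, 128)):
        rng = np.random.default_rng(seed)
        n_in = (self.N_BINS // self.POOL) * self.N_COLS
        dims = [n_in, hidden[0], hidden[1], self.N_ACTIONS]
        self.params: dict[str, np.ndarray] = {}
        for i in range(3):
            fan_in = dims[i]
            self.params[f"W{i + 1}"] = rng.normal(
                0.0, np.sqrt(2.0 / fan_in), size=(dims[i], dims[i + 1])
            )
            self.params[f"b{i + 1}"] = np.zeros(dims[i + 1])
        self._adam_m = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_v = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_t = 0

    # -- forward / backward

    def _pool(self, states: np.ndarray) -> np.ndarray:
        x = np.asarray(states, dtype=float)
        if x.ndim == 2:
            x = x[None]
        if x.shape[1:] != (self.N_BINS, self.N_COLS):
            raise ValueError(
                f"expected ({self.N_BINS}, {self.N_COLS}) agent states, "
                f"got {x.shape[1:]}"
            )
        pooled = x.reshape(x.shape[0], self.N_BINS // self.POOL, self.POOL,
                           self.N_COLS).mean(axis=2)
        return pooled.reshape(x.shape[0], -1)

    def forward(self, states: np.ndarray, with_cache: bool = False):
        """Q-values for a batch of agent states; shape (batch, 4)."""
        x0 = self._pool(states)
        p = self.params
        z1 = x0 @ p["W1"] + p["b1"]
        a1 = np.maximum(z1, 0.0)
        z2 = a1 @ p["W2"] + p["b2"]
        a2 = np.maximum(z2, 0.0)
        q = a2 @ p["W3"] + p["b3"]
        if with_cache:
            return q, (x0, z1, a1, z2, a2)
        return q

    def backward(self, cache, dq: np.ndarray) -> dict[str, np.ndarray]:
        x0, z1, a1, z2, a2 = cache
        p = self.params
        g: dict[str, np.ndarray] = {}
        g["W3"] = a2.T @ dq
        g["b3"] = dq.sum(axis=0)
        da2 = dq @ p["W3"].T
        dz2 = da2 * (z2 > 0)
        g["W2"] = a1.T @ dz2
        g["b2"] = dz2.sum(axis=0)
        da1 = dz2 @ p["W2"].T
        dz1 = da1 * (z1 > 0)
        g["W1"] = x0.T @ dz1
        g["b1"] = dz1.sum(axis=0)
        return g

    def adam_step(
        self,
        grads: dict[str, np.ndarray],
        lr: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ) -> None:
        self._adam_t += 1
        t = self._adam_t
        for k, gk in grads.items():
            self._adam_m[k] = beta1 * self._adam_m[k] + (1 - beta1) * gk
            self._adam_v[k] = beta2 * self._adam_v[k] + (1 - beta2) * gk**2
            m_hat = self._adam_m[k] / (1 - beta1**t)
            v_hat = self._adam_v[k] / (1 - beta2**t)
            self.params[k] -= lr * m_hat / (np.sqrt(v_hat) + eps)

    def get_params(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def set_params(self, params: dict[str, np.ndarray]) -> None:
        for k in self.params:
            self.params[k] = params[k].copy()


@dataclass
class AgentNetworks:
    """Evaluation/target network pair of one agent."""

    q_eva: QNetwork
    q_tar: QNetwork

    @classmethod
    def create(cls, seed: int = 0) -> "AgentNetworks":
        eva = QNetwork(seed=seed)
        tar = QNetwork(seed=seed)
        tar.set_params(eva.get_params())
        return cls(q_eva=eva, q_tar=tar)

    def sync_target(self) -> None:
        self.q_tar.set_params(self.q_eva.get_params())


@dataclass
class Transition:
    """One stored experience (s_t, a_t, r_t, s_{t+1}) with terminal flag."""

    state: np.ndarray
    action: int
    reward: float
    next_state: np.ndarray
    terminal: bool


def ddqn_target(
    transition: Transition, networks: AgentNetworks, gamma: float
) -> float:
    """Double-DQN bootstrap target for one transition."""
    if transition.terminal:
        return float(transition.reward)
    q_eva = networks.q_eva.forward(transition.next_state)[0]
    a_star = int(np.argmax(q_eva))
    q_tar = networks.q_tar.forward(transition.next_state)[0]
    return float(transition.reward + gamma * q_tar[a_star])


def _batch_targets(
    batch: list[Transition], networks: AgentNetworks, gamma: float
) -> np.ndarray:
    next_states = np.stack([t.next_state for t in batch])
    q_eva = networks.q_eva.forward(next_states)
    q_tar = networks.q_tar.forward(next_states)
    a_star = np.argmax(q_eva, axis=1)
    boot = q_tar[np.arange(len(batch)), a_star]
    r = np.array([t.reward for t in batch])
    term = np.array([t.terminal for t in batch])
    return np.where(term, r, r + gamma * boot)


def td_loss(
    batch: list[Transition], networks: AgentNetworks, gamma: float
) -> tuple[float, np.ndarray]:
    """Mean squared TD error of a batch and the per-sample TD errors."""
    if not batch:
        raise ValueError("empty batch")
    targets = _batch_targets(batch, networks, gamma)
    states = np.stack([t.state for t in batch])
    actions = np.array([t.action for t in batch])
    q = networks.q_eva.forward(states)
    td = targets - q[np.arange(len(batch)), actions]
    return float(np.mean(td**2)), td


def train_step(
    batch: list[Transition],
    networks: AgentNetworks,
    gamma: float,
    lr: float = 1e-3,
) -> tuple[float, np.ndarray]:
    """One Adam update of the evaluation network on a replay batch.

    Gradients flow only through the evaluation network; the bootstrap
    targets are held fixed.  Returns (loss, TD errors) for priority updates.
    """
    if not batch:
        raise ValueError("empty batch")
    targets = _batch_targets(batch, networks, gamma)
    states = np.stack([t.state for t in batch])
    actions = np.array([t.action for t in batch])
    q, cache = networks.q_eva.forward(states, with_cache=True)
    idx = np.arange(len(batch))
    td = targets - q[idx, actions]
    dq = np.zeros_like(q)
    dq[idx, actions] = -2.0 * td / len(batch)
    grads = networks.q_eva.backward(cache, dq)
    networks.q_eva.adam_step(grads, lr=lr)
    return float(np.mean(td**2)), td


# ---------------------------------------------------------------------------
# prioritized replay


class SumTree:
    """Binary sum tree over leaf priorities with FIFO overwrite.

    Internal nodes store the sum of their children, so sampling a cumulative
    value descends from the root in O(log capacity).  Stratified sampling
    splits the total priority into equal segments, one uniform draw each.
    """

    def __init__(self, capacity: int = 4096):
        if capacity < 1:
            raise ValueError("capacity must be positive")
        self.capacity = int(capacity)
        self.nodes = np.zeros(2 * self.capacity - 1)
        self.data: list = [None] * self.capacity
        self.write = 0
        self.size = 0
        self.max_priority = 1.0  # priority given to fresh transitions

    @property
    def total(self) -> float:
        return float(self.nodes[0])

    def _propagate(self, leaf: int, change: float) -> None:
        idx = leaf
        while idx != 0:
            idx = (idx - 1) // 2
            self.nodes[idx] += change

    def add(self, priority: float, data) -> int:
        """Insert at the FIFO write position; returns the leaf index."""
        if priority <= 0:
            raise ValueError("priority must be positive")
        leaf = self.write + self.capacity - 1
        self.data[self.write] = data
        self.update(leaf, priority)
        self.write = (self.write + 1) % self.capacity
        self.size = min(self.size + 1, self.capacity)
        return leaf

    def update(self, leaf: int, priority: float) -> None:
        if priority <= 0:
            raise ValueError("priority must be positive")
        change = priority - self.nodes[leaf]
        self.nodes[leaf] = priority
        self._propagate(leaf, change)
        self.max_priority = max(self.max_priority, priority)

    def get(self, cumulative: float) -> tuple[int, float, object]:
        """Descend the tree with a cumulative priority value; returns
        (leaf index, leaf priority, stored data)."""
        idx = 0
        while True:
            left = 2 * idx + 1
            if left >= len(self.nodes):
                break
            if cumulative <= self.nodes[left] or self.nodes[left + 1] <= 0:
                idx = left
            else:
                cumulative -= self.nodes[left]
                idx = left + 1
        return idx, float(self.nodes[idx]), self.data[idx - self.capacity + 1]

    def sample(
        self, batch_size: int, rng: np.random.Generator
    ) -> tuple[list, np.ndarray]:
        """Stratified priority sampling of ``batch_size`` stored items."""
        if self.size == 0 or self.total <= 0:
            raise ValueError("cannot sample from an empty tree")
        seg = self.total / batch_size
        items, leaves = [], []
        for i in range(batch_size):
            v = rng.uniform(i * seg, (i + 1) * seg)
            leaf, _, data = self.get(v)
            items.append(data)
            leaves.append(leaf)
        return items, np.asarray(leaves)


@dataclass
class AgentEnsemble:
    """The five ring agents: network pairs, replay pools, and the shared
    adjustment-step counter that paces target-network synchronisation."""

    networks: dict[str, AgentNetworks]
    pools: dict[str, SumTree]
    train_steps: int = 0

    @classmethod
    def create(cls, seed: int = 0, pool_capacity: int = 4096) -> "AgentEnsemble":
        from .phantom import RING_NAMES

        ss = np.random.SeedSequence(seed)
        children = ss.spawn(len(RING_NAMES))
        networks = {
            ring: AgentNetworks.create(seed=int(child.generate_state(1)[0] % 2**31))
            for ring, child in zip(RING_NAMES, children)
        }
        pools = {ring: SumTree(pool_capacity) for ring in RING_NAMES}
        return cls(networks=networks, pools=pools)

    def sync_targets(self) -> None:
        for nets in self.networks.values():
            nets.sync_target()

    def save(self, directory) -> None:
        """One checkpoint file per agent (network parameters + step counter)."""
        from pathlib import Path

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for ring, nets in self.networks.items():
            np.savez_compressed(
                directory / f"agent_{ring}.npz",
                train_steps=self.train_steps,
                **{f"eva_{k}": v for k, v in nets.q_eva.get_params().items()},
                **{f"tar_{k}": v for k, v in nets.q_tar.get_params().items()},
            )

    @classmethod
    def load(cls, directory, pool_capacity: int = 4096) -> "AgentEnsemble":
        from pathlib import Path

        from .phantom import RING_NAMES

        directory = Path(directory)
        networks = {}
        train_steps = 0
        for ring in RING_NAMES:
            path = directory / f"agent_{ring}.npz"
            if not path.exists():
                raise FileNotFoundError(f"missing agent checkpoint {path}")
            with np.load(path) as d:
                nets = AgentNetworks.create(seed=0)
                nets.q_eva.set_params(
                    {k[4:]: d[k] for k in d.files if k.startswith("eva_")}
                )
                nets.q_tar.set_params(
                    {k[4:]: d[k] for k in d.files if k.startswith("tar_")}
                )
                train_steps = int(d["train_steps"])
            networks[ring] = nets
        pools = {ring: SumTree(pool_capacity) for ring in RING_NAMES}
        return cls(networks=networks, pools=pools, train_steps=train_steps)
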