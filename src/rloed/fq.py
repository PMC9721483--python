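"""Neural fitted Q-learning over a discretised action grid.

The Q-function maps an observation to one value per joint action on a 10x10
grid of input levels.  After every episode the network is re-initialised and
regressed on bootstrapped targets built from every transition seen so far
(fitted Q-iteration); exploration follows an epsilon-greedy schedule that
starts at 1 and decays to 0 an eleventh of the way before the end of training.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .environment import ChemostatOEDEnv, EpisodeRecord, joint_action_grid
from .nets import MLP, GRUStack, Adam, zero_grads, DTYPE

__all__ = [
    "DiscreteActionGrid",
    "ExploreSchedule",
    "FQMemory",
    "QNetwork",
    "TrainingError",
    "epsilon",
    "select_action",
    "q_targets",
    "fq_iteration",
    "fq_learning",
]


class TrainingError(RuntimeError):
    """Raised when a regression diverges (non-finite loss)."""


@dataclass(frozen=True)
class DiscreteActionGrid:
    """Linearly spaced action levels per input; joint actions are the product."""

    n_levels_per_input: int = 10
    bounds: tuple[float, float] = (0.01, 1.0)

    @property
    def levels(self) -> np.ndarray:
        return np.linspace(self.bounds[0], self.bounds[1], self.n_levels_per_input)

    @property
    def joint_actions(self) -> np.ndarray:
        return joint_action_grid(self.n_levels_per_input, self.bounds)

    @property
    def n_actions(self) -> int:
        return self.n_levels_per_input**2

    def action(self, index: int) -> np.ndarray:
        return self.joint_actions[index]


@dataclass(frozen=True)
class ExploreSchedule:
    """Epsilon-greedy schedule: eps(e) = clip(1 - log10(e / A), 0, 1).

    ``A`` defaults to ``total_episodes / 11`` so the explore rate stays at 1
    through the first A episodes, then decays logarithmically and reaches 0 at
    episode 10 A — before the end of training.
    """

    total_episodes: int
    decay_constant: float | None = None

    @property
    def A(self) -> float:
        if self.decay_constant is not None:
            return self.decay_constant
        return self.total_episodes / 11.0


def epsilon(e: int, schedule: ExploreSchedule) -> float:
    """Explore rate at (0-based) episode ``e``."""
    if e < 0:
        raise ValueError("episode index must be >= 0")
    if e == 0:
        return 1.0
    return float(np.clip(1.0 - np.log10(e / schedule.A), 0.0, 1.0))


@dataclass
class FQMemory:
    """Append-only store of all transitions seen during training."""

    obs: list = field(default_factory=list)
    actions: list = field(default_factory=list)  # grid indices
    rewards: list = field(default_factory=list)
    obs_next: list = field(default_factory=list)
    dones: list = field(default_factory=list)

    def add(self, o, a_index: int, r: float, o_next, done: int):
        self.obs.append(o)
        self.actions.append(a_index)
        self.rewards.append(r)
        self.obs_next.append(o_next)
        self.dones.append(done)

    def __len__(self):
        return len(self.obs)


class QNetwork:
    """MLP Q-network (two ReLU hidden layers of 100) with optional recurrent
    front end (two GRU layers of 64) for history-typed observations."""

    def __init__(self, obs_dim: int, n_actions: int, rng,
                 recurrent: bool = False, seq_dim: int = 3,
                 hidden: tuple[int, int] = (100, 100),
                 gru_units: int = 64):
        self.recurrent = recurrent
        self.obs_dim = obs_dim
        self.n_actions = n_actions
        if recurrent:
            self.gru = GRUStack(seq_dim, gru_units, 2, rng)
            head_in = gru_units + obs_dim
        else:
            self.gru = None
            head_in = obs_dim
        self.head = MLP([head_in, *hidden, n_actions], rng)

    def forward(self, obs_batch):
        if self.recurrent:
            cur, seq, mask = obs_batch
            h = self.gru.forward(seq, mask)
            self._h_dim = h.shape[1]
            x = np.concatenate([h, cur], axis=1)
        else:
            x = obs_batch
        return self.head.forward(x)

    def backward(self, dout):
        dx = self.head.backward(dout)
        if self.recurrent:
            self.gru.backward(dx[:, : self._h_dim])

    def params(self):
        ps = list(self.head.params())
        if self.recurrent:
            ps += self.gru.params()
        return ps

    def grads(self):
        gs = list(self.head.grads())
        if self.recurrent:
            gs += self.gru.grads()
        return gs

    def zero_grads(self):
        zero_grads(self.head)
        if self.recurrent:
            zero_grads(self.gru)

    def save(self, path, grid: "DiscreteActionGrid | None" = None,
             scaling=None, schedule_state: dict | None = None):
        """Portable snapshot: weights plus the action grid and scaling the
        network was trained with."""
        meta = {
            "obs_dim": self.obs_dim,
            "n_actions": self.n_actions,
            "recurrent": self.recurrent,
        }
        if grid is not None:
            meta["grid_levels"] = grid.n_levels_per_input
            meta["grid_bounds"] = list(grid.bounds)
        if scaling is not None:
            meta["population_divisor"] = scaling.population_divisor
            meta["time_divisor"] = scaling.time_divisor
            meta["q_target_divisor"] = scaling.q_target_divisor
        if schedule_state:
            meta.update(schedule_state)
        arrays = {f"p{i}": p for i, p in enumerate(self.params())}
        np.savez_compressed(path, __meta__=np.array([str(meta)]), **arrays)

    def load(self, path):
        data = np.load(path, allow_pickle=True)
        for i, p in enumerate(self.params()):
            p[...] = data[f"p{i}"]


def batch_observations(obs_list, recurrent: bool, horizon: int | None = None):
    """Stack observations; for recurrent inputs pad histories and build masks."""
    if not recurrent:
        return np.asarray(obs_list, dtype=DTYPE)
    T = horizon if horizon is not None else max(
        (o["sequence"].shape[0] for o in obs_list), default=0
    )
    B = len(obs_list)
    cur = np.asarray([o["current"] for o in obs_list], dtype=DTYPE)
    seq_dim = obs_list[0]["sequence"].shape[1] if B else 3
    seq = np.zeros((B, max(T, 1), seq_dim), dtype=DTYPE)
    mask = np.zeros((B, max(T, 1)), dtype=DTYPE)
    for i, o in enumerate(obs_list):
        L = o["sequence"].shape[0]
        if L:
            seq[i, :L, :] = o["sequence"]
            mask[i, :L] = 1.0
    return (cur, seq, mask)


def select_action(o, q_net: QNetwork, eps: float, rng: np.random.Generator,
                  n_actions: int | None = None) -> int:
    """Epsilon-greedy action: uniform with probability eps, else argmax
    (ties broken by lowest index)."""
    n = n_actions if n_actions is not None else q_net.n_actions
    if rng.random() < eps:
        return int(rng.integers(n))
    q = q_net.forward(batch_observations([o], q_net.recurrent))[0]
    return int(np.argmax(q))


def q_targets(memory: FQMemory, q_net: QNetwork, gamma: float,
              target_divisor: float = 100.0, horizon: int | None = None
              ) -> np.ndarray:
    """Bootstrapped regression targets r + gamma (1 - d) max_a Q(o', a),
    divided by the target divisor before regression."""
    if len(memory) == 0:
        raise ValueError("memory is empty")
    r = np.asarray(memory.rewards, dtype=float)
    d = np.asarray(memory.dones, dtype=float)
    q_next = q_net.forward(
        batch_observations(memory.obs_next, q_net.recurrent, horizon)
    )
    bootstrap = q_next.max(axis=1).astype(float)
    return (r + gamma * (1.0 - d) * bootstrap) / target_divisor


@dataclass(frozen=True)
class FQTrainConfig:
    gamma: float = 1.0
    learning_rate: float = 1e-3
    batch_size: int = 256
    epochs_per_iteration: int = 1
    target_divisor: float = 100.0
    hidden: tuple[int, int] = (100, 100)
    gru_units: int = 64


def _regress(q_net: QNetwork, obs_batched, actions, targets, cfg: FQTrainConfig,
             rng: np.random.Generator, epochs: int | None = None):
    """Masked regression: only the taken action's output is fitted."""
    n = len(actions)
    opt = Adam(q_net.params(), lr=cfg.learning_rate)
    idx_all = np.arange(n)
    actions = np.asarray(actions)
    targets = np.asarray(targets, dtype=DTYPE)
    for _ in range(epochs or cfg.epochs_per_iteration):
        rng.shuffle(idx_all)
        for start in range(0, n, cfg.batch_size):
            sel = idx_all[start : start + cfg.batch_size]
            if q_net.recurrent:
                cur, seq, mask = obs_batched
                batch = (cur[sel], seq[sel], mask[sel])
            else:
                batch = obs_batched[sel]
            q = q_net.forward(batch)
            rows = np.arange(len(sel))
            err = q[rows, actions[sel]] - targets[sel]
            loss = float(np.mean(err**2))
            if not np.isfinite(loss):
                raise TrainingError("regression loss diverged (non-finite)")
            dq = np.zeros_like(q)
            dq[rows, actions[sel]] = (2.0 / len(sel)) * err
            q_net.zero_grads()
            q_net.backward(dq)
            opt.step(q_net.grads())
    return q_net


def fq_iteration(memory: FQMemory, q_net: QNetwork | None, cfg: FQTrainConfig,
                 obs_dim: int, n_actions: int, seed: int,
                 recurrent: bool = False, horizon: int | None = None
                 ) -> QNetwork:
    """One fitted Q-iteration: compute targets with the previous network,
    re-initialise the network from scratch, regress on the whole memory."""
    if len(memory) == 0:
        raise ValueError("memory is empty")
    rng = np.random.default_rng(seed)
    if q_net is None:
        targets = np.asarray(memory.rewards, dtype=float) / cfg.target_divisor
    else:
        targets = q_targets(memory, q_net, cfg.gamma, cfg.target_divisor, horizon)
    fresh = QNetwork(obs_dim, n_actions, rng, recurrent=recurrent,
                     hidden=cfg.hidden, gru_units=cfg.gru_units)
    obs_b = batch_observations(memory.obs, recurrent, horizon)
    return _regress(fresh, obs_b, memory.actions, targets, cfg, rng)


def fq_learning(
    env: ChemostatOEDEnv,
    n_episodes: int,
    grid: DiscreteActionGrid = DiscreteActionGrid(),
    cfg: FQTrainConfig = FQTrainConfig(),
    schedule: ExploreSchedule | None = None,
    seed: int = 0,
) -> tuple[QNetwork, pd.DataFrame, FQMemory]:
    """Episodic FQ-learning: play an episode epsilon-greedily, store every
    transition, then re-fit the Q-network on the full memory.

    Returns the trained network, the per-episode training curve
    (episode, return, epsilon) and the memory.
    """
    schedule = schedule or ExploreSchedule(n_episodes)
    rng = np.random.default_rng(seed)
    memory = FQMemory()
    obs_dim = env.obs_spec.vector_length()
    recurrent = env.obs_spec.recurrent
    horizon = env.episode_config.n_steps
    q_net: QNetwork | None = None
    curve = []
    for e in range(n_episodes):
        eps = epsilon(e, schedule)
        o = env.reset(seed=int(rng.integers(2**31)))
        done = 0
        ep_return = 0.0
        while not done:
            if q_net is None:
                a_idx = int(rng.integers(grid.n_actions))
            else:
                a_idx = select_action(o, q_net, eps, rng, grid.n_actions)
            r, o_next, done = env.step(grid.action(a_idx))
            memory.add(o, a_idx, r, o_next, done)
            ep_return += r
            o = o_next
        # per-iteration reseed advances deterministically with the episode
        q_net = fq_iteration(
            memory, q_net, cfg, obs_dim, grid.n_actions,
            seed=seed * 100_003 + e, recurrent=recurrent, horizon=horizon,
        )
        curve.append({"episode": e, "return": ep_return, "epsilon": eps})
    return q_net, pd.DataFrame(curve), memory


def greedy_episode(env: ChemostatOEDEnv, q_net: QNetwork,
                   grid: DiscreteActionGrid, seed: int = 0) -> EpisodeRecord:
    """Roll out the greedy (eps = 0) policy of a trained Q-network."""
    rng = np.random.default_rng(seed)
    return env.run_episode(
        lambda o, tau: grid.action(select_action(o, q_net, 0.0, rng)),
        seed=seed,
    )
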