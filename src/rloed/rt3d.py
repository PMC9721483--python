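"""Recurrent twin-delayed deterministic policy gradient (RT3D).

Continuous-action actor-critic for closed-loop experiment design.  Twin
recurrent critics regress on targets built from the minimum of two target
critics at a smoothed target action; the recurrent actor maximises the first
critic and is updated half as often; target networks track the live ones by
Polyak averaging.  Observation histories (scaled measurements and inputs) are
consumed by two GRU layers of 64 units; heads are two ReLU layers of 128.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .environment import (
    ChemostatOEDEnv,
    EpisodeRecord,
    ScalingScheme,
    stability_filter,
)
from .dynamics import IntegrationError
from .fq import ExploreSchedule, TrainingError, epsilon
from .nets import (
    DTYPE,
    MLP,
    Adam,
    GRUStack,
    get_params,
    polyak_update,
    set_params,
    zero_grads,
)

__all__ = [
    "RT3DConfig",
    "Critic",
    "Actor",
    "ReplayBuffer",
    "RT3DAgent",
    "smoothed_target_action",
    "critic_targets",
    "train_rt3d",
]


@dataclass(frozen=True)
class RT3DConfig:
    """Hyperparameters.  Actions inside the networks live in scaled [0, 1]
    units; ``smoothing_sigma`` and ``smoothing_clip`` are in those units."""

    gamma: float = 1.0
    rho: float = 0.995
    smoothing_sigma: float = 0.1
    smoothing_clip: float = 0.25
    a_low: float = 0.01
    a_high: float = 1.0
    batch_size: int = 128
    update_frequency: int = 1  # environment steps per gradient update
    policy_delay: int = 2
    buffer_capacity: int = 1_000_000
    learning_rate: float = 1e-3
    explore_noise: float = 0.2  # std multiplier on eps, scaled action units
    gru_units: int = 64
    head_hidden: tuple[int, int] = (128, 128)

    def __post_init__(self):
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError("rho must be in [0, 1]")
        if self.smoothing_clip <= 0:
            raise ValueError("smoothing_clip must be > 0")
        if not self.a_low < self.a_high:
            raise ValueError("a_low must be < a_high")
        if self.policy_delay < 1:
            raise ValueError("policy_delay must be >= 1")


class Critic:
    """Q(o, a): recurrent encoder over the (measurement, action) history plus
    a feed-forward head on [encoding, current features, candidate action]."""

    def __init__(self, cur_dim: int, rng, cfg: RT3DConfig, seq_dim: int = 3):
        self.gru = GRUStack(seq_dim, cfg.gru_units, 2, rng)
        self.head = MLP([cfg.gru_units + cur_dim + 2, *cfg.head_hidden, 1], rng)
        self._H = cfg.gru_units

    def forward(self, seq, mask, cur, action):
        h = self.gru.forward(seq, mask)
        x = np.concatenate([h, cur, action], axis=1)
        self._cur_dim = cur.shape[1]
        return self.head.forward(x)[:, 0]

    def backward(self, dq):
        """dq: (B,). Returns gradient w.r.t. the action input."""
        dx = self.head.backward(dq[:, None])
        self.gru.backward(dx[:, : self._H])
        return dx[:, self._H + self._cur_dim :]

    def params(self):
        return self.gru.params() + self.head.params()

    def grads(self):
        return self.gru.grads() + self.head.grads()

    def zero_grads(self):
        zero_grads(self.gru)
        zero_grads(self.head)


class Actor:
    """pi(o): recurrent encoder plus head emitting one action per input
    channel, squashed by a sigmoid and mapped affinely onto [a_low, a_high]."""

    def __init__(self, cur_dim: int, rng, cfg: RT3DConfig, seq_dim: int = 3):
        self.gru = GRUStack(seq_dim, cfg.gru_units, 2, rng)
        self.head = MLP([cfg.gru_units + cur_dim, *cfg.head_hidden, 2], rng,
                        out_activation="sigmoid")
        self._H = cfg.gru_units
        self.cfg = cfg

    def forward_scaled(self, seq, mask, cur):
        """Action in scaled [0, 1] units."""
        h = self.gru.forward(seq, mask)
        x = np.concatenate([h, cur], axis=1)
        return self.head.forward(x)

    def forward(self, seq, mask, cur):
        """Action in physical units, inside [a_low, a_high]."""
        s = self.forward_scaled(seq, mask, cur)
        return self.cfg.a_low + (self.cfg.a_high - self.cfg.a_low) * s

    def backward_scaled(self, dout):
        dx = self.head.backward(dout)
        self.gru.backward(dx[:, : self._H])

    def params(self):
        return self.gru.params() + self.head.params()

    def grads(self):
        return self.gru.grads() + self.head.grads()

    def zero_grads(self):
        zero_grads(self.gru)
        zero_grads(self.head)


class ReplayBuffer:
    """Bounded transition store with whole-episode histories recoverable.

    Each stored transition keeps the padded scaled history arrays for o and
    o'; batches are drawn uniformly without replacement within a batch.
    """

    def __init__(self, capacity: int, horizon: int, cur_dim: int,
                 seq_dim: int = 3):
        self.capacity = capacity
        self.horizon = horizon
        self.seq = np.zeros((0, horizon, seq_dim), dtype=DTYPE)
        self._alloc = 0
        self.n = 0
        self._ptr = 0
        shape = lambda *s: np.zeros(s, dtype=DTYPE)  # noqa: E731
        self.o_seq = shape(0, horizon, seq_dim)
        self.o_mask = shape(0, horizon)
        self.o_cur = shape(0, cur_dim)
        self.a = shape(0, 2)
        self.r = shape(0)
        self.o2_seq = shape(0, horizon, seq_dim)
        self.o2_mask = shape(0, horizon)
        self.o2_cur = shape(0, cur_dim)
        self.d = shape(0)

    def _grow(self, extra: int):
        for name in ("o_seq", "o_mask", "o_cur", "a", "r",
                     "o2_seq", "o2_mask", "o2_cur", "d"):
            arr = getattr(self, name)
            new = np.zeros((arr.shape[0] + extra, *arr.shape[1:]), dtype=DTYPE)
            new[: arr.shape[0]] = arr
            setattr(self, name, new)
        self._alloc += extra

    def add(self, o, a, r, o2, d):
        if self.n < self.capacity and self.n == self._alloc:
            self._grow(min(max(1024, self._alloc), self.capacity - self._alloc))
        i = self._ptr
        for name, obs in (("o", o), ("o2", o2)):
            seq = obs["sequence"]
            L = seq.shape[0]
            s = getattr(self, f"{name}_seq")
            m = getattr(self, f"{name}_mask")
            s[i] = 0.0
            m[i] = 0.0
            if L:
                s[i, :L] = seq
                m[i, :L] = 1.0
            getattr(self, f"{name}_cur")[i] = obs["current"]
        self.a[i] = a
        self.r[i] = r
        self.d[i] = d
        self._ptr = (self._ptr + 1) % self.capacity
        self.n = min(self.n + 1, self.capacity)

    def sample(self, batch_size: int, rng: np.random.Generator):
        idx = rng.choice(self.n, size=min(batch_size, self.n), replace=False)
        return {
            "o": (self.o_seq[idx], self.o_mask[idx], self.o_cur[idx]),
            "a": self.a[idx],
            "r": self.r[idx],
            "o2": (self.o2_seq[idx], self.o2_mask[idx], self.o2_cur[idx]),
            "d": self.d[idx],
            "idx": idx,
        }

    def __len__(self):
        return self.n


def smoothed_target_action(actor_targ: Actor, o2, cfg: RT3DConfig,
                           rng: np.random.Generator) -> np.ndarray:
    """clip(pi_targ(o') + clip(xi, -c, c), a_low, a_high), xi ~ N(0, sigma)."""
    seq, mask, cur = o2
    a = actor_targ.forward(seq, mask, cur)
    if cfg.smoothing_sigma > 0:
        xi = rng.normal(0.0, cfg.smoothing_sigma, size=a.shape)
    else:
        xi = np.zeros_like(a)
    span = cfg.a_high - cfg.a_low  # noise is in scaled units
    xi = np.clip(xi, -cfg.smoothing_clip, cfg.smoothing_clip) * span
    return np.clip(a + xi, cfg.a_low, cfg.a_high).astype(DTYPE)


def critic_targets(batch, actor_targ: Actor, critic1_targ: Critic,
                   critic2_targ: Critic, cfg: RT3DConfig,
                   rng: np.random.Generator,
                   reward_divisor: float = 100.0) -> np.ndarray:
    """y = r/divisor + gamma (1 - d) min_i Q_i,targ(o', a') at the smoothed
    target action.  Rewards and Q-values share the same scaling divisor."""
    seq, mask, cur = batch["o2"]
    a2 = smoothed_target_action(actor_targ, batch["o2"], cfg, rng)
    a2s = _scale_action(a2, cfg)
    q1 = critic1_targ.forward(seq, mask, cur, a2s)
    q2 = critic2_targ.forward(seq, mask, cur, a2s)
    return (batch["r"] / reward_divisor
            + cfg.gamma * (1.0 - batch["d"]) * np.minimum(q1, q2)).astype(DTYPE)


def _scale_action(a, cfg: RT3DConfig):
    return ((a - cfg.a_low) / (cfg.a_high - cfg.a_low)).astype(DTYPE)


class RT3DAgent:
    """Twin recurrent critics + recurrent actor with target networks."""

    def __init__(self, cur_dim: int, cfg: RT3DConfig = RT3DConfig(),
                 seed: int = 0, reward_divisor: float = 100.0):
        rng = np.random.default_rng(seed)
        self.cfg = cfg
        self.cur_dim = cur_dim
        self.reward_divisor = reward_divisor
        self.critic1 = Critic(cur_dim, rng, cfg)
        self.critic2 = Critic(cur_dim, rng, cfg)
        self.actor = Actor(cur_dim, rng, cfg)
        self.critic1_targ = Critic(cur_dim, rng, cfg)
        self.critic2_targ = Critic(cur_dim, rng, cfg)
        self.actor_targ = Actor(cur_dim, rng, cfg)
        for net, targ in ((self.critic1, self.critic1_targ),
                          (self.critic2, self.critic2_targ),
                          (self.actor, self.actor_targ)):
            set_params(targ, get_params(net))
        self.opt1 = Adam(self.critic1.params(), lr=cfg.learning_rate)
        self.opt2 = Adam(self.critic2.params(), lr=cfg.learning_rate)
        self.opt_pi = Adam(self.actor.params(), lr=cfg.learning_rate)
        self.update_count = 0

    # -- acting -------------------------------------------------------------
    def act(self, obs: dict, eps: float, rng: np.random.Generator) -> np.ndarray:
        """Epsilon-greedy in continuous space: uniform with probability eps,
        else the actor's action perturbed by N(0, explore_noise * eps)."""
        cfg = self.cfg
        if rng.random() < eps:
            return rng.uniform(cfg.a_low, cfg.a_high, 2)
        seq = obs["sequence"][None, ...].astype(DTYPE)
        mask = np.ones((1, seq.shape[1]), dtype=DTYPE)
        cur = obs["current"][None, ...].astype(DTYPE)
        a = self.actor.forward(seq, mask, cur)[0].astype(float)
        if eps > 0:
            span = cfg.a_high - cfg.a_low
            a = a + rng.normal(0.0, cfg.explore_noise * eps, 2) * span
        return np.clip(a, cfg.a_low, cfg.a_high)

    # -- updates ------------------------------------------------------------
    def update_critics(self, batch, rng) -> tuple[float, float]:
        """One gradient step on each critic's MSE against the shared targets
        (targets treated as constants)."""
        y = critic_targets(batch, self.actor_targ, self.critic1_targ,
                           self.critic2_targ, self.cfg, rng,
                           self.reward_divisor)
        seq, mask, cur = batch["o"]
        a_s = _scale_action(batch["a"], self.cfg)
        losses = []
        for critic, opt in ((self.critic1, self.opt1), (self.critic2, self.opt2)):
            q = critic.forward(seq, mask, cur, a_s)
            err = q - y
            loss = float(np.mean(err**2))
            if not np.isfinite(loss):
                raise TrainingError("critic loss diverged (non-finite)")
            critic.zero_grads()
            critic.backward((2.0 / len(err)) * err)
            opt.step(critic.grads())
            losses.append(loss)
        return tuple(losses)

    def update_actor(self, batch) -> float:
        """One ascent step on mean Q1(o, pi(o)); only actor parameters move."""
        seq, mask, cur = batch["o"]
        a_scaled = self.actor.forward_scaled(seq, mask, cur)
        q = self.critic1.forward(seq, mask, cur, a_scaled)
        loss = -float(np.mean(q))
        if not np.isfinite(loss):
            raise TrainingError("actor loss diverged (non-finite)")
        self.critic1.zero_grads()
        da = self.critic1.backward(np.full(len(q), -1.0 / len(q), dtype=DTYPE))
        self.actor.zero_grads()
        self.actor.backward_scaled(da)
        self.opt_pi.step(self.actor.grads())
        self.critic1.zero_grads()  # critic gradients from this pass are discarded
        return loss

    def update(self, buffer: ReplayBuffer, rng) -> dict:
        batch = buffer.sample(self.cfg.batch_size, rng)
        l1, l2 = self.update_critics(batch, rng)
        out = {"critic1_loss": l1, "critic2_loss": l2}
        self.update_count += 1
        if self.update_count % self.cfg.policy_delay == 0:
            out["actor_loss"] = self.update_actor(batch)
            for net, targ in ((self.critic1, self.critic1_targ),
                              (self.critic2, self.critic2_targ),
                              (self.actor, self.actor_targ)):
                polyak_update(net, targ, self.cfg.rho)
        return out

    # -- persistence --------------------------------------------------------
    def snapshot(self) -> dict:
        """Serializable snapshot: all network parameters plus config."""
        nets = {
            "critic1": self.critic1, "critic2": self.critic2,
            "actor": self.actor, "critic1_targ": self.critic1_targ,
            "critic2_targ": self.critic2_targ, "actor_targ": self.actor_targ,
        }
        return {
            "cfg": self.cfg,
            "cur_dim": self.cur_dim,
            "reward_divisor": self.reward_divisor,
            "params": {k: get_params(v) for k, v in nets.items()},
        }

    @classmethod
    def from_snapshot(cls, snap: dict) -> "RT3DAgent":
        agent = cls(snap["cur_dim"], snap["cfg"],
                    reward_divisor=snap["reward_divisor"])
        for k, values in snap["params"].items():
            set_params(getattr(agent, k), values)
        return agent

    def save(self, path):
        """Write the snapshot as a compressed npz archive."""
        flat = {}
        for k, values in self.snapshot()["params"].items():
            for i, v in enumerate(values):
                flat[f"{k}__{i}"] = v
        np.savez_compressed(
            path, __meta__=np.array(
                [self.cur_dim, self.reward_divisor], dtype=float
            ), **flat,
        )

    def load(self, path):
        data = np.load(path)
        for k in ("critic1", "critic2", "actor",
                  "critic1_targ", "critic2_targ", "actor_targ"):
            net = getattr(self, k)
            values = []
            i = 0
            while f"{k}__{i}" in data:
                values.append(data[f"{k}__{i}"])
                i += 1
            set_params(net, values)


def _greedy_policy(agent: RT3DAgent):
    rng = np.random.default_rng(0)
    return lambda o, tau: agent.act(o, 0.0, rng)


def collect_episodes(env: ChemostatOEDEnv, agent: RT3DAgent, eps: float,
                     seeds, rng: np.random.Generator,
                     scaling: ScalingScheme | None = None,
                     filter_unstable: bool = False):
    """Simulate a batch of episodes under the current policy.

    Episodes run independently (matched seeds give the same transition
    multiset whatever the batch size); unstable or failed episodes are
    flagged discarded so the caller can exclude and resample them.
    """
    records = []
    for seed in seeds:
        ep_rng = np.random.default_rng(seed)
        o = env.reset(seed=seed)
        done = 0
        try:
            while not done:
                a = agent.act(o, eps, ep_rng)
                _, o, done = env.step(a)
        except IntegrationError:
            pass
        record = env.record
        if filter_unstable and not record.discarded:
            if not stability_filter(record, scaling or env.scaling):
                record.discarded = True
        records.append(record)
    return records


def train_rt3d(
    env: ChemostatOEDEnv,
    n_episodes: int,
    cfg: RT3DConfig = RT3DConfig(),
    schedule: ExploreSchedule | None = None,
    seed: int = 0,
    n_parallel: int = 10,
    updates_per_step: float = 1.0,
    filter_unstable: bool = False,
) -> tuple[RT3DAgent, pd.DataFrame]:
    """Train an RT3D agent on the environment.

    Episodes are simulated in batches of ``n_parallel``; after each batch the
    collected transitions enter the replay buffer and gradient updates run in
    proportion to the number of environment steps collected (every
    ``cfg.update_frequency`` steps, times ``updates_per_step``).  Discarded
    episodes (integration failure, or instability under sqrt-mode scaling)
    contribute no transitions and are replaced so the curve length stays
    ``n_episodes``.  Returns the agent and the per-episode training curve.
    """
    if env.obs_spec.family != "III":
        raise ValueError("RT3D requires a history (formulation III) observation")
    schedule = schedule or ExploreSchedule(n_episodes)
    rng = np.random.default_rng(seed)
    cur_dim = env.obs_spec.vector_length()
    agent = RT3DAgent(cur_dim, cfg, seed=seed)
    buffer = ReplayBuffer(cfg.buffer_capacity, env.episode_config.n_steps,
                          cur_dim)
    curve = []
    n_done = 0
    n_discarded = 0
    while n_done < n_episodes:
        k = min(n_parallel, n_episodes - n_done)
        eps = epsilon(n_done, schedule)
        seeds = [int(rng.integers(2**31)) for _ in range(k)]
        records = collect_episodes(env, agent, eps, seeds, rng,
                                   filter_unstable=filter_unstable)
        steps_collected = 0
        for record in records:
            if record.discarded:
                n_discarded += 1
                continue
            for tr in record.transitions:
                buffer.add(tr.o, tr.a, tr.r, tr.o_next, tr.done)
            steps_collected += len(record.transitions)
            curve.append({
                "episode": n_done,
                "return": record.episode_return,
                "epsilon": eps,
            })
            n_done += 1
        if len(buffer) >= cfg.batch_size:
            n_updates = int(steps_collected * updates_per_step
                            / cfg.update_frequency)
            for _ in range(n_updates):
                agent.update(buffer, rng)
    frame = pd.DataFrame(curve)
    frame.attrs["n_discarded"] = n_discarded
    return agent, frame


def greedy_episode(env: ChemostatOEDEnv, agent: RT3DAgent,
                   seed: int = 0) -> EpisodeRecord:
    """Roll out the deterministic (eps = 0) policy."""
    return env.run_episode(_greedy_policy(agent), seed=seed)


def next_input(agent: RT3DAgent, measurements, inputs,
               scaling: ScalingScheme, include_time: bool = True
               ) -> np.ndarray:
    """Deployment entry point: the next input pair for a running experiment.

    ``measurements`` are the population readings at the start of steps
    1..tau (raw units); ``inputs`` the raw input pairs already applied
    (length tau - 1).  Builds the recurrent observation and queries the
    deterministic policy; a single forward pass, so the answer is available
    in well under a second.
    """
    measurements = np.asarray(measurements, dtype=float)
    inputs = np.asarray(inputs, dtype=float).reshape(-1, 2)
    tau = len(measurements)
    if len(inputs) != tau - 1:
        raise ValueError("need exactly one more measurement than inputs")
    seq = np.zeros((tau - 1, 3))
    if tau > 1:
        seq[:, 0] = scaling.scale_population(measurements[:-1])
        seq[:, 1:] = scaling.scale_action(inputs)
    current = [float(scaling.scale_population(measurements[-1]))]
    if include_time:
        current.append(scaling.scale_time(tau))
    obs = {"current": np.array(current), "sequence": seq}
    return agent.act(obs, 0.0, np.random.default_rng(0))
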