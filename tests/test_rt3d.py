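"""Recurrent TD3: target smoothing, twin critics, delayed actor, buffer."""

import numpy as np
import pytest

from rloed.environment import ChemostatOEDEnv, ObservationSpec, ScalingScheme
from rloed.nets import DTYPE, get_params
from rloed.rt3d import (
    Actor,
    Critic,
    ReplayBuffer,
    RT3DAgent,
    RT3DConfig,
    collect_episodes,
    critic_targets,
    smoothed_target_action,
    train_rt3d,
)


@pytest.fixture()
def cfg():
    return RT3DConfig(batch_size=8)


@pytest.fixture()
def agent(cfg):
    return RT3DAgent(cur_dim=2, cfg=cfg, seed=0)


def _batch(agent, n=8, seed=0, horizon=10):
    """Synthetic replay batch with plausible scaled observations."""
    rng = np.random.default_rng(seed)
    mk_seq = lambda: rng.uniform(0, 1, (n, horizon, 3)).astype(DTYPE)  # noqa
    mask = np.zeros((n, horizon), dtype=DTYPE)
    for i in range(n):
        mask[i, : rng.integers(0, horizon)] = 1.0
    return {
        "o": (mk_seq(), mask, rng.uniform(0, 1, (n, 2)).astype(DTYPE)),
        "a": rng.uniform(0.01, 1, (n, 2)).astype(DTYPE),
        "r": rng.normal(0, 1, n).astype(DTYPE),
        "o2": (mk_seq(), mask, rng.uniform(0, 1, (n, 2)).astype(DTYPE)),
        "d": (rng.random(n) < 0.3).astype(DTYPE),
    }


class TestSmoothedTargetAction:
    def test_zero_sigma_is_plain_clipped_policy(self, agent, cfg):
        import dataclasses

        batch = _batch(agent)
        quiet = dataclasses.replace(cfg, smoothing_sigma=0.0)
        rng = np.random.default_rng(0)
        a = smoothed_target_action(agent.actor_targ, batch["o2"], quiet, rng)
        seq, mask, cur = batch["o2"]
        expected = np.clip(
            agent.actor_targ.forward(seq, mask, cur), cfg.a_low, cfg.a_high
        )
        assert a == pytest.approx(expected, abs=1e-7)

    def test_bounds_and_noise_clip(self, agent, cfg):
        batch = _batch(agent)
        rng = np.random.default_rng(1)
        seq, mask, cur = batch["o2"]
        base = agent.actor_targ.forward(seq, mask, cur)
        span = cfg.a_high - cfg.a_low
        for _ in range(200):
            a = smoothed_target_action(agent.actor_targ, batch["o2"], cfg, rng)
            assert np.all(a >= cfg.a_low) and np.all(a <= cfg.a_high)
            assert np.all(np.abs(a - base) <= cfg.smoothing_clip * span + 1e-6)


class TestCriticTargets:
    def test_terminal_targets_are_scaled_rewards(self, agent, cfg):
        batch = _batch(agent)
        batch["d"][:] = 1.0
        y = critic_targets(batch, agent.actor_targ, agent.critic1_targ,
                           agent.critic2_targ, cfg, np.random.default_rng(0))
        assert y == pytest.approx(batch["r"] / 100.0, abs=1e-6)

    def test_twin_minimum_bounds_each_twin(self, agent, cfg):
        import dataclasses

        batch = _batch(agent)
        batch["d"][:] = 0.0
        quiet = dataclasses.replace(cfg, smoothing_sigma=0.0)
        rng = np.random.default_rng(0)
        y = critic_targets(batch, agent.actor_targ, agent.critic1_targ,
                           agent.critic2_targ, quiet, rng)
        seq, mask, cur = batch["o2"]
        a2 = smoothed_target_action(agent.actor_targ, batch["o2"], quiet, rng)
        a2s = ((a2 - cfg.a_low) / (cfg.a_high - cfg.a_low)).astype(DTYPE)
        q1 = agent.critic1_targ.forward(seq, mask, cur, a2s)
        q2 = agent.critic2_targ.forward(seq, mask, cur, a2s)
        resid = y - batch["r"] / 100.0
        assert np.all(resid <= cfg.gamma * q1 + 1e-6)
        assert np.all(resid <= cfg.gamma * q2 + 1e-6)

    def test_identical_twins_reduce_to_single_critic(self, agent, cfg):
        import dataclasses

        from rloed.nets import set_params

        set_params(agent.critic2_targ, get_params(agent.critic1_targ))
        quiet = dataclasses.replace(cfg, smoothing_sigma=0.0)
        batch = _batch(agent)
        rng = np.random.default_rng(0)
        y = critic_targets(batch, agent.actor_targ, agent.critic1_targ,
                           agent.critic2_targ, quiet, rng)
        seq, mask, cur = batch["o2"]
        a2 = smoothed_target_action(agent.actor_targ, batch["o2"], quiet, rng)
        a2s = ((a2 - cfg.a_low) / (cfg.a_high - cfg.a_low)).astype(DTYPE)
        single = batch["r"] / 100.0 + cfg.gamma * (1 - batch["d"]) * \
            agent.critic1_targ.forward(seq, mask, cur, a2s)
        assert y == pytest.approx(single, abs=1e-6)


class TestUpdates:
    def test_critic_losses_decrease_on_repeated_batch(self, agent):
        batch = _batch(agent)
        first = agent.update_critics(batch, np.random.default_rng(0))
        for _ in range(60):
            last = agent.update_critics(batch, np.random.default_rng(0))
        assert last[0] < first[0] and last[1] < first[1]
        assert min(first + last) >= 0.0

    def test_actor_update_improves_q_and_freezes_critic(self, agent):
        batch = _batch(agent)
        seq, mask, cur = batch["o"]

        def mean_q():
            a = agent.actor.forward_scaled(seq, mask, cur)
            return float(np.mean(agent.critic1.forward(seq, mask, cur, a)))

        critic_before = [p.copy() for p in agent.critic1.params()]
        before = mean_q()
        for _ in range(5):
            agent.update_actor(batch)
        assert mean_q() > before
        for p0, p1 in zip(critic_before, agent.critic1.params()):
            assert np.array_equal(p0, p1)

    def test_actor_updates_respect_policy_delay(self, agent, cfg):
        buf = ReplayBuffer(1000, 10, 2)
        batch = _batch(agent, n=32)
        seq, mask, cur = batch["o"]
        for i in range(16):
            buf.add(
                {"sequence": np.asarray(seq[i][mask[i] > 0]), "current": cur[i]},
                batch["a"][i], float(batch["r"][i]),
                {"sequence": np.asarray(seq[i][mask[i] > 0]), "current": cur[i]},
                int(batch["d"][i]),
            )
        rng = np.random.default_rng(0)
        actor_versions = [get_params(agent.actor)]
        for k in range(4):
            agent.update(buf, rng)
            actor_versions.append(get_params(agent.actor))
        changed = [
            not all(np.array_equal(a, b) for a, b in zip(u, v))
            for u, v in zip(actor_versions, actor_versions[1:])
        ]
        # with policy_delay=2: unchanged, changed, unchanged, changed
        assert changed == [False, True, False, True]


class TestAct:
    def test_deterministic_at_zero_eps(self, agent):
        obs = {"sequence": np.random.default_rng(0).uniform(0, 1, (3, 3)),
               "current": np.array([0.4, 0.1])}
        a1 = agent.act(obs, 0.0, np.random.default_rng(1))
        a2 = agent.act(obs, 0.0, np.random.default_rng(2))
        assert np.array_equal(a1, a2)

    def test_full_exploration_is_uniform(self, agent, cfg):
        obs = {"sequence": np.zeros((0, 3)), "current": np.array([0.4, 0.0])}
        rng = np.random.default_rng(3)
        draws = np.array([agent.act(obs, 1.0, rng) for _ in range(5000)])
        from scipy.stats import kstest, uniform

        span = cfg.a_high - cfg.a_low
        for ch in range(2):
            stat = kstest(
                draws[:, ch], uniform(loc=cfg.a_low, scale=span).cdf
            )
            assert stat.pvalue > 1e-3

    def test_actions_always_inside_bounds(self, agent, cfg):
        rng = np.random.default_rng(4)
        obs = {"sequence": rng.uniform(0, 1, (5, 3)),
               "current": np.array([0.9, 0.5])}
        for eps in (0.0, 0.3, 0.7, 1.0):
            for _ in range(200):
                a = agent.act(obs, eps, rng)
                assert np.all(a >= cfg.a_low) and np.all(a <= cfg.a_high)


class TestReplayBuffer:
    def test_uniform_sampling_frequencies(self):
        buf = ReplayBuffer(1000, 4, 1)
        for k in range(50):
            obs = {"sequence": np.zeros((0, 3)), "current": np.array([k])}
            buf.add(obs, np.array([0.5, 0.5]), float(k), obs, 0)
        rng = np.random.default_rng(0)
        counts = np.zeros(50)
        n_draws = 4000
        for _ in range(n_draws):
            counts[buf.sample(5, rng)["idx"]] += 1
        expected = n_draws * 5 / 50
        assert np.all(np.abs(counts - expected) < 6 * np.sqrt(expected))

    def test_no_replacement_within_batch(self):
        buf = ReplayBuffer(100, 4, 1)
        for k in range(10):
            obs = {"sequence": np.zeros((0, 3)), "current": np.array([k])}
            buf.add(obs, np.array([0.5, 0.5]), 0.0, obs, 0)
        rng = np.random.default_rng(1)
        for _ in range(50):
            idx = buf.sample(10, rng)["idx"]
            assert len(set(idx.tolist())) == len(idx)


class TestTraining:
    def _env(self):
        return ChemostatOEDEnv(
            obs_spec=ObservationSpec("IIIa"),
            scaling=ScalingScheme(population_divisor=500e9),
        )

    def test_requires_history_observation(self):
        env = ChemostatOEDEnv(obs_spec=ObservationSpec("Ia"))
        with pytest.raises(ValueError):
            train_rt3d(env, 2)

    def test_curve_length_and_smoke(self):
        env = self._env()
        agent, curve = train_rt3d(
            env, 12, RT3DConfig(batch_size=16), seed=0, n_parallel=4,
            updates_per_step=0.2,
        )
        assert len(curve) == 12

    def test_batched_collection_matches_sequential(self):
        """With a fixed (untrained) policy and matched seeds, batched and
        sequential episode simulation produce the same transition multiset."""
        env = self._env()
        agent = RT3DAgent(2, RT3DConfig(), seed=0)
        rng = np.random.default_rng(0)
        seeds = [11, 22, 33, 44]
        recs_batch = collect_episodes(env, agent, 0.5, seeds, rng)
        recs_seq = [
            collect_episodes(env, agent, 0.5, [s], rng)[0] for s in seeds
        ]
        key = lambda rec: sorted(  # noqa: E731
            (round(float(t.r), 10), tuple(np.round(t.a, 10)))
            for t in rec.transitions
        )
        assert sorted(map(key, recs_batch)) == sorted(map(key, recs_seq))

    def test_snapshot_round_trip(self, tmp_path, agent):
        path = tmp_path / "snap.npz"
        agent.save(path)
        clone = RT3DAgent(2, agent.cfg, seed=99)
        clone.load(path)
        obs = {"sequence": np.random.default_rng(5).uniform(0, 1, (4, 3)),
               "current": np.array([0.3, 0.2])}
        a = agent.act(obs, 0.0, np.random.default_rng(0))
        b = clone.act(obs, 0.0, np.random.default_rng(0))
        assert np.array_equal(a, b)


def test_next_input_deployment(agent):
    import time

    from rloed.rt3d import next_input

    scaling = ScalingScheme(population_divisor=500e9)
    meas = [20e9, 15e9, 30e9]
    inputs = [[0.5, 0.2], [1.0, 0.8]]
    t0 = time.time()
    a = next_input(agent, meas, inputs, scaling)
    assert time.time() - t0 < 1.0
    assert a.shape == (2,) and np.all(a >= 0.01) and np.all(a <= 1.0)
    with pytest.raises(ValueError):
        next_input(agent, meas, inputs[:1], scaling)
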