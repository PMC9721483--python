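"""Episodic RL environment around the chemostat dynamics.

An episode is one simulated experiment: T sample-and-hold intervals (default
ten two-hour intervals) starting from fixed initial conditions.  The reward for
a step is the increase in D-optimality over the interval, with the convention
log|I_0| := 0 at the (information-free) start of the experiment, so that the
episode return telescopes exactly to the final D-optimality score.

The module also implements the six observation formulations used to study
what an agent needs to see in order to learn a value function:

==============  =====================================================
formulation     observation
==============  =====================================================
Ia              scaled N, 9 scaled FIM entries, scaled step index (11)
Ib              scaled N, 9 scaled FIM entries (10)
IIa             scaled N, scaled step index (2)
IIb             scaled N (1)
IIIa            scaled N + step index, plus full history of scaled
                measurements and actions (for recurrent consumption)
IIIb            as IIIa without the step index
==============  =====================================================

Training observations are noiseless model outputs; measurement noise enters
only when simulated data are generated for parameter fitting.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .dynamics import (
    AugmentedState,
    ChemostatParameters,
    ChemostatState,
    InputLevels,
    IntegrationError,
    NoiseModel,
    NOMINAL_PARAMETERS,
    PRIOR_BOUNDS,
    SolverConfig,
    d_optimality,
    integrate_interval,
)

__all__ = [
    "EpisodeConfig",
    "ObservationSpec",
    "ScalingScheme",
    "ParameterPrior",
    "Transition",
    "EpisodeRecord",
    "ChemostatOEDEnv",
    "build_observation",
    "stability_filter",
    "calibrate_fim_divisors",
    "calibrate_sqrt_divisor",
    "OBSERVATION_FORMULATIONS",
]

OBSERVATION_FORMULATIONS = ("Ia", "Ib", "IIa", "IIb", "IIIa", "IIIb")


@dataclass(frozen=True)
class EpisodeConfig:
    """Episode protocol: ten two-hour intervals from fixed initial conditions."""

    n_steps: int = 10
    step_duration: float = 2.0
    initial_state: ChemostatState = field(
        default_factory=lambda: ChemostatState(C0=1.0, C1=0.0, N=20e9)
    )
    input_bounds: tuple[float, float] = (0.01, 1.0)

    def __post_init__(self):
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if self.step_duration <= 0:
            raise ValueError("step_duration must be > 0")
        lo, hi = self.input_bounds
        if not lo < hi:
            raise ValueError("input bounds must satisfy low < high")


@dataclass(frozen=True)
class ObservationSpec:
    """One of the six observation formulations (I/II/III x time flag)."""

    formulation: str = "Ia"

    def __post_init__(self):
        if self.formulation not in OBSERVATION_FORMULATIONS:
            raise ValueError(
                f"formulation must be one of {OBSERVATION_FORMULATIONS}"
            )

    @property
    def family(self) -> str:
        return self.formulation[:-1]

    @property
    def include_time(self) -> bool:
        return self.formulation.endswith("a")

    @property
    def recurrent(self) -> bool:
        return self.family == "III"

    @property
    def uses_fim(self) -> bool:
        return self.family == "I"

    def vector_length(self) -> int:
        base = {"I": 10, "II": 1, "III": 1}[self.family]
        return base + (1 if self.include_time else 0)


@dataclass(frozen=True)
class ScalingScheme:
    """Divisors mapping physical quantities into the network's ~[0, 1] range.

    ``population_divisor`` scales population measurements (50e9 keeps them
    below one for the nominal parametrisation).  ``time_divisor`` scales the
    step index.  ``fim_divisors`` are per-element constants, calibrated as the
    maximum absolute element values seen during a random-action trial run.
    ``sqrt_mode`` switches the population channel to sqrt(N)/sqrt_divisor,
    used when training over a parameter prior whose upper reaches produce far
    larger populations.  ``q_target_divisor`` scales value-regression targets.
    """

    population_divisor: float = 50e9
    time_divisor: float = 10.0
    fim_divisors: np.ndarray = field(default_factory=lambda: np.ones((3, 3)))
    q_target_divisor: float = 100.0
    sqrt_mode: bool = False
    sqrt_divisor: float = 1e5

    def __post_init__(self):
        object.__setattr__(
            self, "fim_divisors", np.asarray(self.fim_divisors, dtype=float)
        )
        if (
            self.population_divisor <= 0
            or self.time_divisor <= 0
            or self.q_target_divisor <= 0
            or self.sqrt_divisor <= 0
            or np.any(self.fim_divisors <= 0)
        ):
            raise ValueError("all divisors must be > 0")

    def scale_population(self, N: float | np.ndarray):
        if self.sqrt_mode:
            return np.sqrt(N) / self.sqrt_divisor
        return N / self.population_divisor

    def scale_time(self, tau: int) -> float:
        # step index tau is 1-based; the first observation maps to 0
        return (tau - 1) / self.time_divisor

    def scale_fim(self, fim: np.ndarray) -> np.ndarray:
        return fim / self.fim_divisors

    def scale_action(self, u, bounds=(0.01, 1.0)) -> np.ndarray:
        lo, hi = bounds
        return (np.asarray(u, dtype=float) - lo) / (hi - lo)

    def unscale_action(self, a, bounds=(0.01, 1.0)) -> np.ndarray:
        lo, hi = bounds
        return lo + np.asarray(a, dtype=float) * (hi - lo)


@dataclass(frozen=True)
class ParameterPrior:
    """Independent uniform box prior over the focal parameters."""

    bounds: dict = field(default_factory=lambda: dict(PRIOR_BOUNDS))

    def __post_init__(self):
        for name, (lo, hi) in self.bounds.items():
            if not lo < hi:
                raise ValueError(f"prior bounds for {name} must satisfy min < max")

    def sample(self, rng: np.random.Generator,
               base: ChemostatParameters) -> ChemostatParameters:
        draws = {
            name: rng.uniform(lo, hi) for name, (lo, hi) in self.bounds.items()
        }
        return replace(base, **draws)

    def center(self, base: ChemostatParameters) -> ChemostatParameters:
        mid = {n: 0.5 * (lo + hi) for n, (lo, hi) in self.bounds.items()}
        return replace(base, **mid)


@dataclass
class Transition:
    """One unit of RL experience."""

    o: object
    a: np.ndarray
    r: float
    o_next: object
    done: int

    def astuple(self):
        return (self.o, self.a, self.r, self.o_next, self.done)


@dataclass
class EpisodeRecord:
    """A completed (or discarded) episode with everything needed downstream."""

    params_used: ChemostatParameters
    transitions: list[Transition] = field(default_factory=list)
    inputs: list[InputLevels] = field(default_factory=list)
    measurements: list[float] = field(default_factory=list)  # N at step starts
    logdets: list[float] = field(default_factory=list)  # after each step
    discarded: bool = False

    @property
    def episode_return(self) -> float:
        return float(sum(t.r for t in self.transitions))

    @property
    def final_logdet(self) -> float:
        return self.logdets[-1] if self.logdets else float("nan")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for k, (tr, u) in enumerate(zip(self.transitions, self.inputs), start=1):
            rows.append(
                {
                    "step": k,
                    "N_measured": self.measurements[k - 1],
                    "C0_in": u.C0_in,
                    "C1_in": u.C1_in,
                    "reward": tr.r,
                    "logdet": self.logdets[k - 1],
                    "done": tr.done,
                }
            )
        return pd.DataFrame(rows)


def build_observation(
    spec: ObservationSpec,
    history: dict,
    scaling: ScalingScheme,
) -> np.ndarray | dict:
    """Render the current observation for a partially completed episode.

    ``history`` holds ``tau`` (1-based index of the upcoming step),
    ``measurements`` (N at the start of steps 1..tau), ``actions`` (raw input
    pairs for steps 1..tau-1) and optionally ``fim`` (the accumulated FIM).

    Formulations I and II return flat vectors.  Formulation III returns a dict
    with the current feature vector and the per-step history of scaled
    measurements and actions for recurrent consumption.
    """
    tau = history["tau"]
    meas = history["measurements"]
    if len(meas) < tau:
        raise ValueError("history must contain the measurement for the current step")
    n_scaled = float(scaling.scale_population(meas[tau - 1]))
    t_scaled = scaling.scale_time(tau)

    if spec.family == "I":
        if "fim" not in history or history["fim"] is None:
            raise ValueError(
                "formulation I requires the FIM in the episode history"
            )
        fim_scaled = scaling.scale_fim(np.asarray(history["fim"])).ravel()
        vec = [n_scaled, *fim_scaled]
        if spec.include_time:
            vec.append(t_scaled)
        return np.array(vec)
    if spec.family == "II":
        vec = [n_scaled]
        if spec.include_time:
            vec.append(t_scaled)
        return np.array(vec)

    # formulation III: current features + full history for the recurrent encoder
    actions = history.get("actions", [])
    if len(actions) != tau - 1:
        raise ValueError("formulation III needs exactly tau-1 past actions")
    current = [n_scaled]
    if spec.include_time:
        current.append(t_scaled)
    seq = np.zeros((tau - 1, 3))
    for i in range(tau - 1):
        seq[i, 0] = scaling.scale_population(meas[i])
        seq[i, 1:3] = scaling.scale_action(np.asarray(actions[i]))
    return {"current": np.array(current), "sequence": seq}


class ChemostatOEDEnv:
    """Episodic environment: reset / step with D-optimality increments.

    With ``mode="sample_prior"`` each reset draws the focal parameters
    uniformly from the prior box; with ``mode="fixed_nominal"`` the supplied
    (default nominal) parameters are used for every episode.
    """

    def __init__(
        self,
        params: ChemostatParameters = NOMINAL_PARAMETERS,
        episode: EpisodeConfig = EpisodeConfig(),
        obs_spec: ObservationSpec = ObservationSpec("Ia"),
        scaling: ScalingScheme = ScalingScheme(),
        noise: NoiseModel = NoiseModel(),
        solver: SolverConfig = SolverConfig(),
        prior: ParameterPrior | None = None,
        mode: str = "fixed_nominal",
        seed: int | None = None,
    ):
        if mode not in ("fixed_nominal", "sample_prior"):
            raise ValueError("mode must be 'fixed_nominal' or 'sample_prior'")
        if mode == "sample_prior" and prior is None:
            prior = ParameterPrior()
        self.base_params = params
        self.episode_config = episode
        self.obs_spec = obs_spec
        self.scaling = scaling
        self.noise = noise
        self.solver = solver
        self.prior = prior
        self.mode = mode
        self.rng = np.random.default_rng(seed)
        self._aug: AugmentedState | None = None
        self.record: EpisodeRecord | None = None
        self._tau = 0
        self._prev_logdet = 0.0

    # -- episode control ----------------------------------------------------
    def reset(self, seed: int | None = None):
        """Start a new episode; returns the first observation."""
        if seed is not None:
            self.rng = np.random.default_rng(seed)
        if self.mode == "sample_prior":
            params = self.prior.sample(self.rng, self.base_params)
        else:
            params = self.base_params
        self._params = params
        self._aug = AugmentedState.initial(self.episode_config.initial_state)
        self._tau = 1
        # baseline convention: log|I_0| := 0, so the first reward is log|I_1|
        self._prev_logdet = 0.0
        self.record = EpisodeRecord(params_used=params)
        self.record.measurements.append(self._aug.state.N)
        return self._observe()

    def _history(self) -> dict:
        return {
            "tau": self._tau,
            "measurements": self.record.measurements,
            "actions": [u.as_array() for u in self.record.inputs],
            "fim": self._aug.fim,
        }

    def _observe(self):
        return build_observation(self.obs_spec, self._history(), self.scaling)

    @property
    def active(self) -> bool:
        return self._aug is not None and 1 <= self._tau <= self.episode_config.n_steps

    def step(self, a: InputLevels | Sequence[float]):
        """Apply one input over a sample-and-hold interval.

        Returns ``(r, o_next, done)``.  Out-of-bounds actions are rejected;
        integration failures mark the episode discarded and re-raise.
        """
        if not self.active:
            raise RuntimeError("episode is not active; call reset()")
        if not isinstance(a, InputLevels):
            a = np.asarray(a, dtype=float)
            lo, hi = self.episode_config.input_bounds
            if np.any(a < lo) or np.any(a > hi):
                raise ValueError(f"action {tuple(a)} outside bounds [{lo}, {hi}]")
            a = InputLevels(float(a[0]), float(a[1]))
        try:
            self._aug = integrate_interval(
                self._aug,
                a,
                self.episode_config.step_duration,
                self._params,
                self.noise,
                self.solver,
            )
        except IntegrationError:
            self.record.discarded = True
            self._tau = 0
            raise
        logdet = d_optimality(self._aug.fim)
        r = logdet - self._prev_logdet
        self._prev_logdet = logdet
        done = int(self._tau == self.episode_config.n_steps)

        o_prev = self._observe()
        self.record.inputs.append(a)
        self.record.measurements.append(self._aug.state.N)
        self.record.logdets.append(logdet)
        self._tau += 1
        o_next = self._observe() if not done else self._terminal_observation()
        self.record.transitions.append(
            Transition(o=o_prev, a=a.as_array(), r=r, o_next=o_next, done=done)
        )
        if done:
            self._tau = 0
        return r, o_next, done

    def _terminal_observation(self):
        # observation "after" the final step; only used as o' of the last
        # transition, where (1 - done) zeroes its contribution
        hist = self._history()
        hist["tau"] = self.episode_config.n_steps + 1
        hist["actions"] = [u.as_array() for u in self.record.inputs]
        return build_observation(self.obs_spec, hist, self.scaling)

    def run_episode(self, policy, seed: int | None = None) -> EpisodeRecord:
        """Roll out one episode with ``policy(observation, tau) -> action``."""
        o = self.reset(seed=seed)
        tau = 1
        done = 0
        while not done:
            a = policy(o, tau)
            _, o, done = self.step(a)
            tau += 1
        return self.record


def stability_filter(record: EpisodeRecord, scaling: ScalingScheme) -> bool:
    """Return True (keep) unless the episode is unstable.

    Under sqrt-mode scaling an episode is unstable when any scaled population
    observation exceeds 1, or when its integration failed.
    """
    if record.discarded:
        return False
    if not scaling.sqrt_mode:
        raise ValueError("stability_filter applies to sqrt-mode scaling")
    scaled = scaling.scale_population(np.asarray(record.measurements))
    return bool(np.all(scaled <= 1.0))


def _random_action_episode(env: ChemostatOEDEnv, rng: np.random.Generator):
    lo, hi = env.episode_config.input_bounds
    env.reset(seed=int(rng.integers(2**31)))
    fims = []
    done = 0
    while not done:
        a = rng.uniform(lo, hi, 2)
        try:
            _, _, done = env.step(a)
        except IntegrationError:
            break
        fims.append(env._aug.fim.copy())
    return fims, env.record


def calibrate_fim_divisors(
    env: ChemostatOEDEnv, n_trial_episodes: int, seed: int = 0
) -> np.ndarray:
    """Per-element FIM divisors: max |element| over random-action episodes.

    Mirrors a trial exploration run; divisors are floored at 1 so constant
    zero elements scale harmlessly.  Deterministic given the seed.
    """
    if n_trial_episodes < 1:
        raise ValueError("n_trial_episodes must be >= 1")
    rng = np.random.default_rng(seed)
    peak = np.zeros((3, 3))
    for _ in range(n_trial_episodes):
        fims, _ = _random_action_episode(env, rng)
        for fim in fims:
            peak = np.maximum(peak, np.abs(fim))
    return np.maximum(peak, 1.0)


def calibrate_sqrt_divisor(
    env: ChemostatOEDEnv, n_trial_episodes: int = 2000, seed: int = 0,
    headroom: float = 1.1,
) -> float:
    """Sqrt-mode population divisor from a random-action pilot at the prior.

    Set to ``headroom`` times the maximum sqrt-population seen, so that only
    the few most extreme episodes of a subsequent training run are discarded
    by the stability filter.
    """
    rng = np.random.default_rng(seed)
    peak = 0.0
    for _ in range(n_trial_episodes):
        _, record = _random_action_episode(env, rng)
        if record.measurements:
            peak = max(peak, float(np.sqrt(np.max(record.measurements))))
    return headroom * peak


def discrete_action_levels(n_levels: int = 10,
                           bounds: tuple[float, float] = (0.01, 1.0)) -> np.ndarray:
    """Linearly spaced per-input action levels including both endpoints."""
    return np.linspace(bounds[0], bounds[1], n_levels)


def joint_action_grid(n_levels: int = 10,
                      bounds: tuple[float, float] = (0.01, 1.0)) -> np.ndarray:
    """Cartesian product of per-input levels: shape (n_levels**2, 2)."""
    lv = discrete_action_levels(n_levels, bounds)
    return np.array(list(itertools.product(lv, lv)))
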