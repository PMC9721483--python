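"""Non-learning experiment designers sharing the dynamics core.

Three baselines produce :class:`ExperimentDesign` objects scored by the same
augmented-FIM integrator the RL environment uses:

* ``rational_design`` wraps a user-supplied input sequence;
* ``osao_design`` is the greedy one-step-ahead optimiser — at each interval it
  maximises that interval's gain in log|I| given the committed trajectory;
* ``mpc_design`` solves one nonlinear program over all 2T inputs maximising
  the final log|I| (a full-horizon open-loop optimisation), with multistart
  restarts because the 20-variable landscape is nonconvex.

Gradients for the NLPs are finite-difference; objective evaluations integrate
the augmented ODE at tight tolerances so the differences are smooth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .dynamics import (
    AugmentedState,
    ChemostatParameters,
    InputLevels,
    NoiseModel,
    SolverConfig,
    d_optimality,
    simulate_design,
)
from .environment import EpisodeConfig

__all__ = [
    "ExperimentDesign",
    "NLPConfig",
    "DesignerError",
    "evaluate_design",
    "osao_design",
    "mpc_design",
    "rational_design",
    "random_design",
]


class DesignerError(RuntimeError):
    """Raised when an optimisation step fails."""


@dataclass(frozen=True)
class ExperimentDesign:
    """A length-T sequence of input pairs plus its provenance."""

    inputs: tuple[InputLevels, ...]
    provenance: str = "rational"

    PROVENANCES = ("rational", "osao", "mpc", "agent", "random")

    def __post_init__(self):
        if self.provenance not in self.PROVENANCES:
            raise ValueError(f"provenance must be one of {self.PROVENANCES}")
        object.__setattr__(self, "inputs", tuple(self.inputs))

    def __len__(self):
        return len(self.inputs)

    def as_array(self) -> np.ndarray:
        return np.array([u.as_array() for u in self.inputs])

    @classmethod
    def from_array(cls, arr, provenance: str) -> "ExperimentDesign":
        arr = np.asarray(arr, dtype=float).reshape(-1, 2)
        return cls(tuple(InputLevels(a, b) for a, b in arr), provenance)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "step": np.arange(1, len(self) + 1),
                "C0_in": [u.C0_in for u in self.inputs],
                "C1_in": [u.C1_in for u in self.inputs],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, provenance: str = "rational") -> "ExperimentDesign":
        frame = pd.read_csv(path)
        return cls.from_array(frame[["C0_in", "C1_in"]].to_numpy(), provenance)


@dataclass(frozen=True)
class NLPConfig:
    """Settings for the scipy-based nonlinear programs."""

    multistart_count: int = 6
    max_iterations: int = 200
    coarse_max_iterations: int = 60  # per-restart budget before the polish
    fd_step: float = 1e-4
    solver_tol: float = 1e-9
    grid_resolution: int = 10  # coarse per-step grid seeding the OSAO polish
    seed: int = 0

    def __post_init__(self):
        if self.multistart_count < 1:
            raise ValueError("multistart_count must be >= 1")


def evaluate_design(
    design: ExperimentDesign,
    params: ChemostatParameters,
    episode: EpisodeConfig = EpisodeConfig(),
    noise: NoiseModel = NoiseModel(),
    solver: SolverConfig = SolverConfig(),
) -> tuple[float, list[AugmentedState]]:
    """Integrate the augmented system over the full design.

    Returns the final D-optimality log|I(T)| and the trajectory at interval
    boundaries.  Pure function of (design, params, tolerances).
    """
    if len(design) != episode.n_steps:
        raise ValueError(
            f"design length {len(design)} != episode n_steps {episode.n_steps}"
        )
    traj = simulate_design(
        design.inputs, params, episode.initial_state, episode.step_duration,
        noise, solver,
    )
    return d_optimality(traj[-1].fim), traj


def _interval_integrator(params, episode, noise, solver):
    def integ(aug: AugmentedState, u) -> AugmentedState:
        return_u = InputLevels(float(u[0]), float(u[1]))
        from .dynamics import integrate_interval

        return integrate_interval(
            aug, return_u, episode.step_duration, params, noise, solver
        )

    return integ


def osao_design(
    params: ChemostatParameters,
    nlp: NLPConfig = NLPConfig(),
    episode: EpisodeConfig = EpisodeConfig(),
    noise: NoiseModel = NoiseModel(),
    solver: SolverConfig = SolverConfig(),
) -> tuple[ExperimentDesign, float]:
    """Greedy one-step-ahead design at known parameters.

    Each step maximises log|I| at the end of that interval: a coarse grid over
    the input box seeds a bounded quasi-Newton polish.  Because log|I_tau| is
    already fixed at the start of the step, maximising the end-of-interval
    log-determinant is identical to maximising the step's information gain.
    """
    lo, hi = episode.input_bounds
    integ = _interval_integrator(params, episode, noise, solver)
    aug = AugmentedState.initial(episode.initial_state)
    inputs = []
    for step in range(episode.n_steps):
        def objective(u, _aug=aug):
            return -d_optimality(integ(_aug, u).fim)

        levels = np.linspace(lo, hi, nlp.grid_resolution)
        scores = {}
        for a in levels:
            for b in levels:
                scores[(a, b)] = objective((a, b))
        seeds = sorted(scores, key=scores.get)[:2]
        best = None
        for x0 in seeds:
            res = minimize(
                objective,
                x0,
                method="L-BFGS-B",
                bounds=[(lo, hi)] * 2,
                options={
                    "maxiter": nlp.max_iterations,
                    "eps": nlp.fd_step,
                    "ftol": nlp.solver_tol,
                },
            )
            cand = (res.fun, tuple(res.x)) if np.isfinite(res.fun) else None
            if cand is not None and (best is None or cand[0] < best[0]):
                best = cand
        if best is None:
            raise DesignerError(f"OSAO optimisation failed at step {step + 1}")
        u = best[1]
        aug = integ(aug, u)
        inputs.append(InputLevels(*u))
    design = ExperimentDesign(tuple(inputs), "osao")
    return design, d_optimality(aug.fim)


def mpc_design(
    params: ChemostatParameters,
    nlp: NLPConfig = NLPConfig(),
    episode: EpisodeConfig = EpisodeConfig(),
    noise: NoiseModel = NoiseModel(),
    solver: SolverConfig = SolverConfig(),
    osao_seed_design: ExperimentDesign | None = None,
) -> tuple[ExperimentDesign, float, list[float]]:
    """Full-horizon open-loop design: one NLP over all 2T input variables.

    Restarts: the OSAO design (computed here if not supplied), the box
    midpoint, and uniform-random interior points.  Each restart runs a
    budgeted quasi-Newton ascent at slightly relaxed integrator tolerances;
    the best restart is then polished at full tolerance.  Seeding with the
    OSAO solution enforces the MPC >= OSAO dominance by construction.
    Returns (design, score, per-restart scores).
    """
    lo, hi = episode.input_bounds
    T = episode.n_steps
    rng = np.random.default_rng(nlp.seed)
    coarse_solver = solver

    def objective(flat, slv):
        design = ExperimentDesign.from_array(np.clip(flat, lo, hi), "mpc")
        score, _ = evaluate_design(design, params, episode, noise, slv)
        return -score

    starts = []
    if osao_seed_design is None and nlp.multistart_count >= 2:
        osao_seed_design, _ = osao_design(params, nlp, episode, noise, solver)
    if osao_seed_design is not None:
        starts.append(osao_seed_design.as_array().ravel())
    starts.append(np.full(2 * T, 0.5 * (lo + hi)))
    while len(starts) < nlp.multistart_count:
        starts.append(rng.uniform(lo, hi, 2 * T))
    starts = starts[: nlp.multistart_count]

    restart_scores = []
    best = None
    for x0 in starts:
        res = minimize(
            objective,
            x0,
            args=(coarse_solver,),
            method="L-BFGS-B",
            bounds=[(lo, hi)] * (2 * T),
            options={
                "maxiter": nlp.coarse_max_iterations,
                "eps": nlp.fd_step,
                "ftol": nlp.solver_tol,
            },
        )
        if not np.isfinite(res.fun):
            restart_scores.append(float("nan"))
            continue
        restart_scores.append(-float(res.fun))
        if best is None or -res.fun > best[0]:
            best = (-float(res.fun), res.x)
    if best is None:
        raise DesignerError("all MPC restarts failed")
    res = minimize(
        objective,
        best[1],
        args=(solver,),
        method="L-BFGS-B",
        bounds=[(lo, hi)] * (2 * T),
        options={
            "maxiter": nlp.max_iterations,
            "eps": nlp.fd_step,
            "ftol": nlp.solver_tol,
        },
    )
    x_best = res.x if np.isfinite(res.fun) and -res.fun >= best[0] else best[1]
    design = ExperimentDesign.from_array(np.clip(x_best, lo, hi), "mpc")
    score, _ = evaluate_design(design, params, episode, noise, solver)
    return design, score, restart_scores


def rational_design(
    sequence, episode: EpisodeConfig = EpisodeConfig()
) -> ExperimentDesign:
    """Validate and wrap a user-supplied (human-chosen) input sequence."""
    arr = np.asarray(sequence, dtype=float)
    if arr.ndim != 2 or arr.shape != (episode.n_steps, 2):
        raise ValueError(
            f"rational design must have shape ({episode.n_steps}, 2); "
            f"got {arr.shape}"
        )
    return ExperimentDesign.from_array(arr, "rational")


def staircase_design(episode: EpisodeConfig = EpisodeConfig()) -> ExperimentDesign:
    """A placeholder human-style staircase design for smoke tests: C0_in steps
    down while C1_in steps up across the experiment."""
    lo, hi = episode.input_bounds
    T = episode.n_steps
    up = np.linspace(lo, hi, T)
    return ExperimentDesign.from_array(
        np.column_stack([up[::-1], up]), "rational"
    )


def random_design(
    rng: np.random.Generator, episode: EpisodeConfig = EpisodeConfig()
) -> ExperimentDesign:
    lo, hi = episode.input_bounds
    return ExperimentDesign.from_array(
        rng.uniform(lo, hi, (episode.n_steps, 2)), "random"
    )
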