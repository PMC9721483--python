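"""Chemostat auxotroph growth model with forward sensitivities and Fisher information.

The model describes an auxotrophic bacterial strain growing in a chemostat at
dilution rate ``q``.  Two nutrient concentrations, ``C0`` and ``C1``, are hidden
state variables replenished through the inflow concentrations ``C0_in`` and
``C1_in`` (the experimental inputs); the population density ``N`` is the only
measured output.  Growth follows a double Monod law

    mu = mu_max * C1 / (K1 + C1) * C0 / (K0 + C0)

and the state equations are

    dC0/dt = q (C0_in - C0) - mu N / gamma0
    dC1/dt = q (C1_in - C1) - mu N / gamma1
    dN/dt  = (mu - q) N

Alongside the state, the module propagates log-scaled parameter sensitivities
``S[i, j] = theta_j * dX_i/dtheta_j`` for the focal parameters
(mu_max, K0, K1) and accumulates the Fisher information matrix (FIM) of the
measured output under a Gaussian noise model.  The D-optimality score of an
experiment is the log-determinant of the accumulated FIM.

Times are in hours throughout; the FIM accumulates per hour.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml
from numba import njit
from scipy.integrate import odeint

__all__ = [
    "ChemostatParameters",
    "ChemostatState",
    "InputLevels",
    "NoiseModel",
    "SolverConfig",
    "AugmentedState",
    "DegenerateNoiseError",
    "IntegrationError",
    "NOMINAL_PARAMETERS",
    "PRIOR_BOUNDS",
    "INPUT_BOUNDS",
    "growth_rate",
    "augmented_derivatives",
    "integrate_interval",
    "d_optimality",
    "simulate_design",
    "trajectory_frame",
    "chemostat_model_spec",
    "load_model_spec",
    "params_from_spec",
]

FOCAL_NAMES = ("mu_max", "K0", "K1")

# upper-triangle index pairs of the 3x3 FIM, packed into y[12:18]
_TRI_I = np.array([0, 0, 0, 1, 1, 2])
_TRI_J = np.array([0, 1, 2, 1, 2, 2])

#: Singular-FIM sentinel: keeps first-interval rewards finite.
LOGDET_SENTINEL = -1.0e6

#: Input bounds for the inflow concentrations, g/L.
INPUT_BOUNDS = (0.01, 1.0)


class DegenerateNoiseError(ValueError):
    """Raised when the measurement-noise covariance would be singular."""


class IntegrationError(RuntimeError):
    """Raised when the ODE solver fails or produces non-finite values."""


@dataclass(frozen=True)
class ChemostatParameters:
    """Model parameter vector.

    Units: ``mu_max`` and ``q`` in 1/h; ``K0``, ``K1`` in g/L; ``gamma0``,
    ``gamma1`` in cells/g.  ``focal_set`` lists the parameters the FIM is
    computed over; the yields are practically unidentifiable and ``q`` is
    experimentally controlled, so neither may be focal.
    """

    mu_max: float = 1.0
    K0: float = 6.8e-5
    K1: float = 4.9e-4
    gamma0: float = 4.8e11
    gamma1: float = 5.2e11
    q: float = 0.5
    focal_set: tuple[str, ...] = FOCAL_NAMES

    def __post_init__(self):
        for name in ("mu_max", "K0", "K1", "gamma0", "gamma1", "q"):
            if getattr(self, name) <= 0:
                raise ValueError(f"parameter {name} must be strictly positive")
        bad = set(self.focal_set) - set(FOCAL_NAMES)
        if bad:
            raise ValueError(
                f"focal_set may only contain {FOCAL_NAMES}; got {sorted(bad)}"
            )
        if len(self.focal_set) != len(set(self.focal_set)):
            raise ValueError("focal_set contains duplicates")

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.mu_max, self.K0, self.K1, self.gamma0, self.gamma1, self.q]
        )

    def focal_values(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in self.focal_set])

    def with_focal(self, values: Sequence[float]) -> "ChemostatParameters":
        """Return a copy with the focal parameters replaced by ``values``."""
        return replace(self, **dict(zip(self.focal_set, values)))


@dataclass(frozen=True)
class ChemostatState:
    """Physical state: nutrient concentrations (g/L) and population (cells/L)."""

    C0: float = 1.0
    C1: float = 0.0
    N: float = 20e9

    def __post_init__(self):
        if self.C0 < 0 or self.C1 < 0 or self.N < 0:
            raise ValueError("concentrations and population must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array([self.C0, self.C1, self.N])


@dataclass(frozen=True)
class InputLevels:
    """Inflow concentrations (g/L) held constant over one interval."""

    C0_in: float
    C1_in: float

    def __post_init__(self):
        lo, hi = INPUT_BOUNDS
        if not (lo <= self.C0_in <= hi and lo <= self.C1_in <= hi):
            raise ValueError(
                f"inputs must lie in [{lo}, {hi}] g/L; got "
                f"({self.C0_in}, {self.C1_in})"
            )

    def as_array(self) -> np.ndarray:
        return np.array([self.C0_in, self.C1_in])


@dataclass(frozen=True)
class NoiseModel:
    """Gaussian measurement noise on the population output.

    The default convention reads "noise of 5% of the measured quantity" as a
    coefficient of variation: the standard deviation of a measurement of ``N``
    is ``cv * N`` (variance ``(cv * N)**2``).  A relative noise model makes
    the FIM — and hence D-optimality — invariant to the unit in which the
    population is expressed, and a 5% coefficient of variation is what the
    reported parameter-inference accuracy of the chemostat study implies.
    ``convention="variance_linear"`` selects the alternative literal reading
    in which the variance itself is ``cv * N`` (unit-dependent).  ``n_floor``
    clamps ``N`` inside the information increment to guard against a singular
    covariance at washout.
    """

    cv: float = 0.05
    convention: str = "cv"
    n_floor: float = 1e3

    def __post_init__(self):
        if self.cv <= 0:
            raise ValueError("cv must be > 0")
        if self.convention not in ("cv", "variance_linear"):
            raise ValueError("convention must be 'cv' or 'variance_linear'")
        if self.n_floor <= 0:
            raise DegenerateNoiseError(
                "n_floor must be > 0: a zero population would make the "
                "measurement covariance singular"
            )

    def variance(self, N: float | np.ndarray) -> float | np.ndarray:
        Nc = np.maximum(N, self.n_floor)
        if self.convention == "cv":
            return (self.cv * Nc) ** 2
        return self.cv * Nc

    def sd(self, N: float | np.ndarray) -> float | np.ndarray:
        return np.sqrt(self.variance(N))


@dataclass(frozen=True)
class SolverConfig:
    """Tolerances for the stiff-capable variable-step integrator (LSODA)."""

    rtol: float = 1e-8
    atol: float = 1e-10
    max_steps: int = 200_000


@dataclass
class AugmentedState:
    """Everything integrated jointly: state, log-scaled sensitivities, FIM.

    ``sens`` has rows indexed by state variable (C0, C1, N) and columns by
    focal parameter; it is all-zero at the start of an experiment because the
    initial conditions are fixed.  ``fim`` is symmetric PSD and zero at t=0.
    """

    state: ChemostatState
    sens: np.ndarray = field(default_factory=lambda: np.zeros((3, 3)))
    fim: np.ndarray = field(default_factory=lambda: np.zeros((3, 3)))
    t: float = 0.0

    def __post_init__(self):
        self.sens = np.asarray(self.sens, dtype=float)
        self.fim = np.asarray(self.fim, dtype=float)
        if self.sens.shape != (3, 3) or self.fim.shape != (3, 3):
            raise ValueError("sens and fim must be 3x3")
        if not np.all(np.isfinite(self.sens)):
            raise ValueError("sensitivities must be finite")
        if self.t < 0:
            raise ValueError("t must be >= 0")

    @classmethod
    def initial(cls, state: ChemostatState) -> "AugmentedState":
        return cls(state=state)

    def pack(self) -> np.ndarray:
        y = np.empty(18)
        y[0:3] = self.state.as_array()
        y[3:12] = self.sens.ravel()
        y[12:18] = self.fim[_TRI_I, _TRI_J]
        return y

    @classmethod
    def unpack(cls, y: np.ndarray, t: float) -> "AugmentedState":
        fim = np.empty((3, 3))
        fim[_TRI_I, _TRI_J] = y[12:18]
        fim[_TRI_J, _TRI_I] = y[12:18]
        state = ChemostatState(C0=max(y[0], 0.0), C1=max(y[1], 0.0), N=max(y[2], 0.0))
        return cls(state=state, sens=y[3:12].reshape(3, 3).copy(), fim=fim, t=t)


#: Nominal parameter values for the auxotroph system.
NOMINAL_PARAMETERS = ChemostatParameters()

#: Uniform prior bounds for the focal parameters (min, max).
PRIOR_BOUNDS = {"mu_max": (0.5, 2.0), "K0": (1e-5, 1e-4), "K1": (1e-4, 1e-3)}


def growth_rate(state: ChemostatState, params: ChemostatParameters) -> float:
    """Specific growth rate mu (1/h) under double Monod kinetics."""
    m0 = state.C0 / (params.K0 + state.C0)
    m1 = state.C1 / (params.K1 + state.C1)
    return params.mu_max * m0 * m1


@njit(cache=True)
def _rhs(y, t, th, u0, u1, cv, nfloor, quadratic):
    """Joint RHS: state (3), log-scaled full-state sensitivities (9), FIM (6).

    Sensitivities are propagated for the full state vector: the growth rate
    depends on the hidden nutrient concentrations, so closing the sensitivity
    system over the measured variable alone would be inconsistent.  Only the
    measured row (N) feeds the information increment.
    """
    mu_max, K0, K1, g0, g1, q = th[0], th[1], th[2], th[3], th[4], th[5]
    C0, C1, N = y[0], y[1], y[2]
    m0 = C0 / (K0 + C0)
    m1 = C1 / (K1 + C1)
    mu = mu_max * m0 * m1
    dmu_dC0 = mu_max * m1 * K0 / (K0 + C0) ** 2
    dmu_dC1 = mu_max * m0 * K1 / (K1 + C1) ** 2

    out = np.empty(18)
    out[0] = q * (u0 - C0) - mu * N / g0
    out[1] = q * (u1 - C1) - mu * N / g1
    out[2] = (mu - q) * N

    # Jacobian dF/dX
    J00 = -q - dmu_dC0 * N / g0
    J01 = -dmu_dC1 * N / g0
    J02 = -mu / g0
    J10 = -dmu_dC0 * N / g1
    J11 = -q - dmu_dC1 * N / g1
    J12 = -mu / g1
    J20 = dmu_dC0 * N
    J21 = dmu_dC1 * N
    J22 = mu - q

    # theta_j * dmu/dtheta_j for the focal parameters (mu_max, K0, K1)
    dmu = np.empty(3)
    dmu[0] = mu
    dmu[1] = -mu_max * m1 * C0 * K0 / (K0 + C0) ** 2
    dmu[2] = -mu_max * m0 * C1 * K1 / (K1 + C1) ** 2

    for j in range(3):
        s0 = y[3 + j]
        s1 = y[6 + j]
        s2 = y[9 + j]
        out[3 + j] = -dmu[j] * N / g0 + J00 * s0 + J01 * s1 + J02 * s2
        out[6 + j] = -dmu[j] * N / g1 + J10 * s0 + J11 * s1 + J12 * s2
        out[9 + j] = dmu[j] * N + J20 * s0 + J21 * s1 + J22 * s2

    Nc = N if N > nfloor else nfloor
    sig = cv * Nc * Nc if quadratic else cv * Nc
    inv = 1.0 / sig
    sN0, sN1, sN2 = y[9], y[10], y[11]
    out[12] = sN0 * sN0 * inv
    out[13] = sN0 * sN1 * inv
    out[14] = sN0 * sN2 * inv
    out[15] = sN1 * sN1 * inv
    out[16] = sN1 * sN2 * inv
    out[17] = sN2 * sN2 * inv
    return out


def _rhs_args(params: ChemostatParameters, u: InputLevels | Sequence[float],
              noise: NoiseModel):
    u = np.asarray(u.as_array() if isinstance(u, InputLevels) else u, dtype=float)
    quadratic = noise.convention == "cv"
    coeff = noise.cv**2 if quadratic else noise.cv
    return (
        params.as_array(),
        float(u[0]),
        float(u[1]),
        coeff,
        noise.n_floor,
        quadratic,
    )


def augmented_derivatives(
    aug: AugmentedState,
    u: InputLevels,
    params: ChemostatParameters,
    noise: NoiseModel = NoiseModel(),
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Right-hand side of the joint system at ``aug``.

    Returns ``(dstate, dsens, dfim)`` with shapes (3,), (3, 3), (3, 3).
    """
    dy = _rhs(aug.pack(), aug.t, *_rhs_args(params, u, noise))
    dfim = np.empty((3, 3))
    dfim[_TRI_I, _TRI_J] = dy[12:18]
    dfim[_TRI_J, _TRI_I] = dy[12:18]
    return dy[0:3], dy[3:12].reshape(3, 3), dfim


def _integrate_packed(
    y: np.ndarray,
    u: Sequence[float],
    duration: float,
    params: ChemostatParameters,
    noise: NoiseModel,
    solver: SolverConfig,
) -> np.ndarray:
    out, info = odeint(
        _rhs,
        y,
        [0.0, duration],
        args=_rhs_args(params, u, noise),
        rtol=solver.rtol,
        atol=solver.atol,
        mxstep=solver.max_steps,
        full_output=True,
    )
    y1 = out[-1]
    if info["message"] != "Integration successful." or not np.all(np.isfinite(y1)):
        raise IntegrationError(
            f"ODE integration failed over {duration} h at u={tuple(u)}: "
            f"{info['message']}"
        )
    return y1


def integrate_interval(
    aug: AugmentedState,
    u: InputLevels,
    duration: float,
    params: ChemostatParameters,
    noise: NoiseModel = NoiseModel(),
    solver: SolverConfig = SolverConfig(),
) -> AugmentedState:
    """Integrate the augmented system over one sample-and-hold interval.

    The input is held constant for ``duration`` hours.  The FIM increment over
    the interval is an integral of weighted outer products and therefore
    symmetric positive semidefinite; integration failures raise
    :class:`IntegrationError` so the caller can discard the episode.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    y1 = _integrate_packed(aug.pack(), u.as_array(), duration, params, noise, solver)
    return AugmentedState.unpack(y1, aug.t + duration)


def d_optimality(fim: np.ndarray, sentinel: float = LOGDET_SENTINEL) -> float:
    """D-optimality score: log-determinant of the FIM.

    Returns ``sentinel`` for a singular or near-singular matrix (smallest
    eigenvalue below 1e-30) so that rewards stay finite at the start of an
    experiment, when the accumulated information is still rank-deficient.
    """
    fim = np.asarray(fim, dtype=float)
    if fim.shape != (fim.shape[0], fim.shape[0]):
        raise ValueError("FIM must be square")
    scale = np.max(np.abs(fim))
    if not np.allclose(fim, fim.T, rtol=1e-8, atol=1e-12 * max(scale, 1.0)):
        raise ValueError("FIM must be symmetric")
    eigs = np.linalg.eigvalsh(fim)
    if eigs[0] < 1e-30:
        return sentinel
    return float(np.sum(np.log(eigs)))


def simulate_design(
    inputs: Iterable[InputLevels],
    params: ChemostatParameters,
    initial_state: ChemostatState = ChemostatState(),
    step_duration: float = 2.0,
    noise: NoiseModel = NoiseModel(),
    solver: SolverConfig = SolverConfig(),
) -> list[AugmentedState]:
    """Integrate a full experiment; returns the augmented state at every
    interval boundary, starting with the initial state (length T+1)."""
    aug = AugmentedState.initial(initial_state)
    out = [aug]
    for u in inputs:
        aug = integrate_interval(aug, u, step_duration, params, noise, solver)
        out.append(aug)
    return out


def trajectory_frame(
    trajectory: Sequence[AugmentedState],
    inputs: Sequence[InputLevels] | None = None,
) -> pd.DataFrame:
    """Tidy trajectory table: t, state, inputs, sensitivities, FIM, logdet.

    ``inputs[k]`` is the input applied over the interval ending at
    ``trajectory[k + 1]``; the first row (t=0) has no inputs.
    """
    rows = []
    for k, aug in enumerate(trajectory):
        row = {"t": aug.t, "C0": aug.state.C0, "C1": aug.state.C1, "N": aug.state.N}
        if inputs is not None and k > 0:
            row["C0_in"] = inputs[k - 1].C0_in
            row["C1_in"] = inputs[k - 1].C1_in
        else:
            row["C0_in"] = np.nan
            row["C1_in"] = np.nan
        for i, sname in enumerate(("C0", "C1", "N")):
            for j, pname in enumerate(FOCAL_NAMES):
                row[f"sens_{sname}_{pname}"] = aug.sens[i, j]
        for i, j in zip(_TRI_I, _TRI_J):
            row[f"fim_{i}{j}"] = aug.fim[i, j]
        row["logdet"] = d_optimality(aug.fim)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Declarative model specification
# ---------------------------------------------------------------------------

def chemostat_model_spec() -> dict:
    """The built-in chemostat auxotroph model as a declarative config block."""
    return {
        "name": "chemostat_auxotroph",
        "parameters": {
            "mu_max": {"value": 1.0, "min": 0.5, "max": 2.0, "unit": "1/h"},
            "K0": {"value": 6.8e-5, "min": 1e-5, "max": 1e-4, "unit": "g/L"},
            "K1": {"value": 4.9e-4, "min": 1e-4, "max": 1e-3, "unit": "g/L"},
            "gamma0": {"value": 4.8e11, "unit": "cells/g"},
            "gamma1": {"value": 5.2e11, "unit": "cells/g"},
            "q": {"value": 0.5, "unit": "1/h"},
        },
        "focal_set": list(FOCAL_NAMES),
        "measured": ["N"],
        "input_bounds": {"C0_in": list(INPUT_BOUNDS), "C1_in": list(INPUT_BOUNDS)},
        "initial_state": {"C0": 1.0, "C1": 0.0, "N": 20e9},
        "noise": {"cv": 0.05, "convention": "cv"},
    }


def load_model_spec(source: str | io.IOBase | dict) -> dict:
    """Load a model spec from YAML/JSON text, a file object, or a dict."""
    if isinstance(source, dict):
        return source
    if hasattr(source, "read"):
        return yaml.safe_load(source)
    return yaml.safe_load(str(source))


def params_from_spec(spec: dict) -> ChemostatParameters:
    p = {k: v["value"] for k, v in spec["parameters"].items()}
    return ChemostatParameters(focal_set=tuple(spec["focal_set"]), **p)


def prior_bounds_from_spec(spec: dict) -> dict[str, tuple[float, float]]:
    out = {}
    for name in spec["focal_set"]:
        entry = spec["parameters"][name]
        out[name] = (entry["min"], entry["max"])
    return out
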