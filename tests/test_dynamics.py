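"""Chemostat model, sensitivity propagation and Fisher-information scoring."""

import numpy as np
import pytest

from rloed.dynamics import (
    AugmentedState,
    ChemostatParameters,
    ChemostatState,
    InputLevels,
    NoiseModel,
    SolverConfig,
    LOGDET_SENTINEL,
    augmented_derivatives,
    chemostat_model_spec,
    d_optimality,
    growth_rate,
    integrate_interval,
    params_from_spec,
    simulate_design,
    trajectory_frame,
)

U11 = InputLevels(1.0, 1.0)


def nominal_trajectory(params, hours=20.0, u=U11, solver=SolverConfig(),
                       step=2.0):
    aug = AugmentedState.initial(ChemostatState())
    for _ in range(int(round(hours / step))):
        aug = integrate_interval(aug, u, step, params, solver=solver)
    return aug


class TestGrowthRate:
    @pytest.mark.parametrize(
        "state, expected",
        [
            (ChemostatState(C0=0.0, C1=0.5, N=1e9), 0.0),  # factor vanishes
            (ChemostatState(C0=6.8e-5, C1=4.9e-4, N=1e9), 0.25),  # half-sat
        ],
    )
    def test_limits(self, nominal, state, expected):
        assert growth_rate(state, nominal) == pytest.approx(
            expected * nominal.mu_max, rel=1e-12
        )

    def test_nominal_matches_direct_evaluation(self, nominal):
        state = ChemostatState(C0=1.0, C1=1.0, N=1e9)
        direct = (
            nominal.mu_max
            * 1.0 / (nominal.K1 + 1.0)
            * 1.0 / (nominal.K0 + 1.0)
        )
        assert growth_rate(state, nominal) == pytest.approx(direct, rel=1e-14)
        assert 0.0 <= growth_rate(state, nominal) <= nominal.mu_max


class TestParameters:
    def test_positivity_enforced(self):
        with pytest.raises(ValueError):
            ChemostatParameters(mu_max=-1.0)

    def test_focal_set_restricted(self):
        with pytest.raises(ValueError):
            ChemostatParameters(focal_set=("mu_max", "gamma0"))

    def test_builtin_spec_round_trip(self, nominal):
        spec = chemostat_model_spec()
        assert params_from_spec(spec) == nominal


class TestAugmentedDerivatives:
    def test_washout_is_absorbing(self, nominal):
        aug = AugmentedState.initial(ChemostatState(C0=0.5, C1=0.5, N=0.0))
        dstate, _, _ = augmented_derivatives(aug, U11, nominal)
        # no growth, no consumption: pure dilution toward the inflow levels
        assert dstate[2] == 0.0
        assert dstate[0] == pytest.approx(nominal.q * (1.0 - 0.5))
        assert dstate[1] == pytest.approx(nominal.q * (1.0 - 0.5))

    def test_zero_sensitivity_reduces_to_explicit_term(self, nominal):
        """With S = 0 the sensitivity RHS is theta_j dF/dtheta_j alone,
        checked against central differences of F in log-parameters."""
        aug = AugmentedState.initial(ChemostatState(C0=0.3, C1=0.2, N=5e10))
        import dataclasses

        _, dsens, _ = augmented_derivatives(aug, U11, nominal)
        h = 1e-6
        for j, name in enumerate(nominal.focal_set):
            th = getattr(nominal, name)
            p_up = dataclasses.replace(nominal, **{name: th * np.exp(h)})
            p_dn = dataclasses.replace(nominal, **{name: th * np.exp(-h)})
            f_up, _, _ = augmented_derivatives(aug, U11, p_up)
            f_dn, _, _ = augmented_derivatives(aug, U11, p_dn)
            fd = (f_up - f_dn) / (2 * h)
            assert dsens[:, j] == pytest.approx(fd, rel=1e-4, abs=1e-3)

    def test_washout_relaxation_closed_form(self, nominal):
        """With N = 0 the concentrations relax exponentially to the inflow
        levels at rate q."""
        aug = AugmentedState.initial(ChemostatState(C0=0.0, C1=0.0, N=0.0))
        u = InputLevels(0.8, 0.4)
        out = integrate_interval(aug, u, 3.0, nominal)
        expected = 1.0 - np.exp(-nominal.q * 3.0)
        assert out.state.C0 == pytest.approx(0.8 * expected, rel=1e-6)
        assert out.state.C1 == pytest.approx(0.4 * expected, rel=1e-6)


class TestSensitivityOracle:
    @pytest.mark.parametrize("hours", [2.0, 20.0])
    def test_matches_finite_differences(self, nominal, hours):
        """Log-scaled sensitivities of N agree with a central-difference
        oracle to better than 1e-3 of the sensitivity scale."""
        import dataclasses

        solver = SolverConfig(rtol=1e-10, atol=1e-12)
        aug = nominal_trajectory(nominal, hours, solver=solver)
        S = aug.sens[2]
        h = 1e-2
        fd = np.empty(3)
        for j, name in enumerate(nominal.focal_set):
            th = getattr(nominal, name)
            p_up = dataclasses.replace(nominal, **{name: th * np.exp(h)})
            p_dn = dataclasses.replace(nominal, **{name: th * np.exp(-h)})
            n_up = nominal_trajectory(p_up, hours, solver=solver).state.N
            n_dn = nominal_trajectory(p_dn, hours, solver=solver).state.N
            fd[j] = (n_up - n_dn) / (2 * h)
        scale = np.linalg.norm(fd)
        assert np.all(np.abs(S - fd) < 1e-3 * scale)


class TestIntegrateInterval:
    def test_chained_intervals_consistent(self, nominal):
        aug0 = AugmentedState.initial(ChemostatState())
        one = integrate_interval(
            integrate_interval(aug0, U11, 1.0, nominal), U11, 1.0, nominal
        )
        two = integrate_interval(aug0, U11, 2.0, nominal)
        for a, b in [
            (one.state.as_array(), two.state.as_array()),
            (one.sens, two.sens),
            (one.fim, two.fim),
        ]:
            scale = np.max(np.abs(b)) + 1e-300
            assert np.all(np.abs(np.asarray(a) - np.asarray(b)) < 1e-6 * scale)

    def test_fim_increment_is_symmetric_psd(self, nominal):
        aug = AugmentedState.initial(ChemostatState())
        rng = np.random.default_rng(0)
        for _ in range(5):
            u = InputLevels(*rng.uniform(0.01, 1, 2))
            nxt = integrate_interval(aug, u, 2.0, nominal)
            inc = nxt.fim - aug.fim
            assert np.allclose(inc, inc.T, rtol=1e-8)
            eigs = np.linalg.eigvalsh(inc)
            assert eigs.min() >= -1e-10 * max(eigs.max(), 1.0)
            aug = nxt

    def test_unit_invariance_of_fim(self, nominal):
        """Expressing the population in a 10x different unit (initial N and
        yields both scaled) leaves the FIM unchanged under relative noise."""
        import dataclasses

        base = nominal_trajectory(nominal, 8.0)
        scaled_params = dataclasses.replace(
            nominal, gamma0=nominal.gamma0 / 10, gamma1=nominal.gamma1 / 10
        )
        aug = AugmentedState.initial(ChemostatState(C0=1.0, C1=0.0, N=2e9))
        for _ in range(4):
            aug = integrate_interval(aug, U11, 2.0, scaled_params)
        assert np.all(
            np.abs(aug.fim - base.fim) < 1e-6 * np.max(np.abs(base.fim))
        )

    def test_monotone_d_optimality_along_episode(self, nominal):
        aug = AugmentedState.initial(ChemostatState())
        rng = np.random.default_rng(3)
        prev = None
        for _ in range(10):
            aug = integrate_interval(
                aug, InputLevels(*rng.uniform(0.01, 1, 2)), 2.0, nominal
            )
            ld = d_optimality(aug.fim)
            if prev is not None and prev > LOGDET_SENTINEL:
                assert ld >= prev - 1e-9
            prev = ld


class TestDOptimality:
    def test_identity_scores(self):
        assert d_optimality(np.eye(3)) == pytest.approx(0.0, abs=1e-12)
        assert d_optimality(2 * np.eye(3)) == pytest.approx(3 * np.log(2))

    def test_matches_eigendecomposition(self):
        rng = np.random.default_rng(7)
        A = rng.normal(size=(3, 3))
        fim = A @ A.T + 0.1 * np.eye(3)
        assert d_optimality(fim) == pytest.approx(
            np.sum(np.log(np.linalg.eigvalsh(fim))), rel=1e-10
        )

    def test_singular_returns_sentinel(self):
        assert d_optimality(np.zeros((3, 3))) == LOGDET_SENTINEL

    def test_rejects_non_symmetric(self):
        with pytest.raises(ValueError):
            d_optimality(np.array([[1.0, 2.0], [0.0, 1.0]]))


class TestNoiseModel:
    def test_conventions(self):
        cv = NoiseModel(cv=0.05)
        assert cv.variance(1e10) == pytest.approx((0.05 * 1e10) ** 2)
        lin = NoiseModel(cv=0.05, convention="variance_linear")
        assert lin.variance(1e10) == pytest.approx(0.05 * 1e10)

    def test_floor_guards_degenerate_covariance(self):
        nm = NoiseModel()
        assert nm.variance(0.0) == pytest.approx((0.05 * nm.n_floor) ** 2)
        with pytest.raises(ValueError):
            NoiseModel(n_floor=0.0)


def test_trajectory_export_schema(nominal):
    inputs = [U11, InputLevels(0.5, 0.2)]
    traj = simulate_design(inputs, nominal)
    frame = trajectory_frame(traj, inputs)
    assert len(frame) == 3
    for col in ("t", "C0", "C1", "N", "C0_in", "C1_in", "logdet"):
        assert col in frame.columns
    assert sum(c.startswith("sens_") for c in frame.columns) == 9
    assert sum(c.startswith("fim_") for c in frame.columns) == 6
    assert frame["t"].tolist() == [0.0, 2.0, 4.0]
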