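"""Value-fitting datasets and the parameter-inference pipeline."""

import numpy as np
import pytest

from rloed.designers import ExperimentDesign, random_design, staircase_design
from rloed.dynamics import NoiseModel
from rloed.environment import EpisodeConfig, ObservationSpec, ScalingScheme
from rloed.evaluation import (
    FitMetrics,
    InferenceReplicate,
    fit_and_score_value,
    fit_parameters,
    generate_value_dataset,
    inference_metrics,
    measurement_times,
    run_inference_study,
    simulate_noisy_dataset,
)


@pytest.fixture(scope="module")
def small_dataset():
    return generate_value_dataset(20, seed=1)


class TestValueDataset:
    def test_record_count(self, small_dataset):
        assert len(small_dataset) == 20
        assert small_dataset.n_records == 200  # n_param x 10 steps

    def test_suffix_sum_identity_exact(self, small_dataset):
        for ep in small_dataset.episodes:
            G, r = ep["returns"], ep["rewards"]
            assert G[-1] == r[-1]  # empty suffix at the final step
            for tau in range(len(r) - 1):
                assert G[tau] == pytest.approx(r[tau] + G[tau + 1], abs=1e-12)

    def test_render_shapes_all_formulations(self, small_dataset):
        scaling = ScalingScheme(
            population_divisor=1.1 * small_dataset.max_population(),
            fim_divisors=small_dataset.fim_divisors(),
        )
        for form, dim in [("Ia", 11), ("Ib", 10), ("IIa", 2), ("IIb", 1)]:
            obs, a, G = small_dataset.render(ObservationSpec(form), scaling)
            assert obs.shape == (200, dim)
            assert a.shape == G.shape == (200,)
        (cur, seq, mask), a, G = small_dataset.render(
            ObservationSpec("IIIa"), scaling
        )
        assert cur.shape == (200, 2) and seq.shape == (200, 10, 3)
        # at step tau the history holds exactly tau - 1 entries
        assert mask.sum(axis=1).tolist() == [t for _ in range(20)
                                             for t in range(10)]

    def test_prior_draws_stay_in_box(self, small_dataset):
        from rloed.dynamics import PRIOR_BOUNDS

        for ep in small_dataset.episodes:
            for name, (lo, hi) in PRIOR_BOUNDS.items():
                assert lo <= getattr(ep["params"], name) <= hi


class TestValueFitting:
    def test_constant_returns_are_trivially_learnable(self, small_dataset):
        import copy

        train = copy.deepcopy(small_dataset)
        for ep in train.episodes:
            ep["returns"] = np.zeros_like(ep["returns"]) + 5.0
        res = fit_and_score_value(
            train, train, ObservationSpec("IIb"), seed=0, n_repeats=1,
            epochs=400,
        )
        assert res["test_mse_mean"] < 1e-2 * 5.0**2


class TestNoisySimulation:
    def test_zero_noise_reproduces_model_output(self, nominal):
        design = staircase_design()
        quiet = NoiseModel(cv=1e-12)
        a = simulate_noisy_dataset(design, nominal, quiet, seed=0, dt=1.0)
        b = simulate_noisy_dataset(design, nominal, quiet, seed=1, dt=1.0)
        assert a == pytest.approx(b, rel=1e-9)

    def test_identical_seeds_identical_series(self, nominal):
        design = staircase_design()
        a = simulate_noisy_dataset(design, nominal, seed=7, dt=1.0)
        b = simulate_noisy_dataset(design, nominal, seed=7, dt=1.0)
        assert np.array_equal(a, b)

    def test_empirical_variance_matches_convention(self, nominal):
        """Across replicates, the sample variance at a fixed time point is
        (cv * N)^2 within Monte-Carlo error."""
        episode = EpisodeConfig(n_steps=1)
        design = ExperimentDesign.from_array([[1.0, 1.0]], "rational")
        noise = NoiseModel(cv=0.05)
        draws = np.array([
            simulate_noisy_dataset(design, nominal, noise, seed=k,
                                   episode=episode, dt=2.0)
            for k in range(3000)
        ])
        n_true = draws[:, 1].mean()
        ratio = draws[:, 1].var() / (0.05 * n_true) ** 2
        assert abs(ratio - 1.0) < 0.08

    def test_grid_length(self, nominal):
        assert len(measurement_times(EpisodeConfig(), dt=0.05)) == 401
        design = staircase_design()
        series = simulate_noisy_dataset(design, nominal, seed=0, dt=0.5)
        assert len(series) == 41


class TestFitParameters:
    def test_noiseless_recovery_and_bounds(self, nominal):
        design = staircase_design()
        obs = simulate_noisy_dataset(
            design, nominal, NoiseModel(cv=1e-12), seed=0, dt=0.5
        )
        fitted, ok, cost = fit_parameters(
            obs, design, nominal, seed=0, n_restarts=2, dt=0.5
        )
        assert ok
        assert fitted.focal_values() == pytest.approx(
            nominal.focal_values(), rel=1e-3
        )
        from rloed.dynamics import PRIOR_BOUNDS

        for name, (lo, hi) in PRIOR_BOUNDS.items():
            assert lo <= getattr(fitted, name) <= hi

    def test_true_init_on_noiseless_data_has_zero_residual(self, nominal):
        design = staircase_design()
        obs = simulate_noisy_dataset(
            design, nominal, NoiseModel(cv=1e-12), seed=0, dt=0.5
        )
        fitted, ok, cost = fit_parameters(
            obs, design, nominal, init_guess=nominal.focal_values(),
            seed=0, n_restarts=1, dt=0.5,
        )
        assert ok and cost < 1e-6


class TestInferenceMetrics:
    def _replicate(self, nominal, values):
        return InferenceReplicate(
            design=staircase_design(), true_params=nominal,
            observations=np.zeros(1), fitted=nominal.with_focal(values),
            converged=True,
        )

    def test_perfect_recovery(self, nominal):
        reps = [self._replicate(nominal, nominal.focal_values())
                for _ in range(3)]
        fm = inference_metrics(reps)
        assert fm.normalised_mse == 0.0
        assert fm.logdet_cov == float("-inf")

    def test_duplication_leaves_mse_unchanged(self, nominal):
        rng = np.random.default_rng(0)
        reps = [
            self._replicate(
                nominal, nominal.focal_values() * rng.uniform(0.8, 1.2, 3)
            )
            for _ in range(5)
        ]
        assert inference_metrics(reps).normalised_mse == pytest.approx(
            inference_metrics(reps + reps).normalised_mse
        )

    def test_requires_two_converged(self, nominal):
        with pytest.raises(ValueError):
            inference_metrics([self._replicate(nominal,
                                               nominal.focal_values())])


class TestDesignQualityRanking:
    def test_better_design_gives_lower_error(self, nominal):
        """The D-optimality ranking of a poor vs a strong design is mirrored
        by their normalised estimation errors (coarse grid, few replicates)."""
        from rloed.designers import evaluate_design

        poor = ExperimentDesign.from_array(
            np.full((10, 2), [1.0, 1.0]), "rational"
        )
        good = ExperimentDesign.from_array(
            np.full((10, 2), [0.01, 0.01]), "rational"
        )
        s_poor, _ = evaluate_design(poor, nominal)
        s_good, _ = evaluate_design(good, nominal)
        assert s_good > s_poor
        kw = dict(n_replicates=6, seed=0, dt=0.5, n_restarts=2)
        m_poor = inference_metrics(run_inference_study(poor, nominal, **kw))
        m_good = inference_metrics(run_inference_study(good, nominal, **kw))
        assert m_good.normalised_mse < m_poor.normalised_mse
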