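"""Run orchestration: config schema, seeding, manifests, design comparison.

A run is a pure function of its :class:`RunConfig`: every source of
randomness derives from the single run seed through a named generator tree,
so adding components (or logging) never perturbs existing random streams.
Artifacts (designs, curves, metrics) are written into the run's output
directory together with a manifest sufficient to re-launch the identical run.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .dynamics import (
    ChemostatParameters,
    ChemostatState,
    NoiseModel,
    SolverConfig,
    chemostat_model_spec,
    params_from_spec,
    prior_bounds_from_spec,
)
from .environment import (
    ChemostatOEDEnv,
    EpisodeConfig,
    ObservationSpec,
    ParameterPrior,
    ScalingScheme,
)
from .designers import (
    ExperimentDesign,
    NLPConfig,
    evaluate_design,
    mpc_design,
    osao_design,
    rational_design,
    staircase_design,
)
from . import evaluation as ev
from .fq import DiscreteActionGrid, FQTrainConfig, fq_learning
from .rt3d import RT3DConfig, train_rt3d

__all__ = [
    "RunConfig",
    "RunManifest",
    "SchemaError",
    "seed_tree",
    "run",
    "compare_designs",
    "JsonLinesLogger",
]

PIPELINES = (
    "design_osao",
    "design_mpc",
    "design_rational",
    "train_fq",
    "train_rt3d",
    "eval_value_fitting",
    "eval_inference",
)


class SchemaError(ValueError):
    """Configuration failed validation; the message names the field path."""


def seed_tree(root_seed: int, *path: str) -> int:
    """Deterministic per-component seed derived from the root seed.

    Stable under addition of unrelated components: the seed depends only on
    the component's own path.  Kept below 2**31.
    """
    h = np.uint64(root_seed)
    for part in path:
        for ch in str(part).encode():
            h = np.uint64((int(h) * 1_000_003 + ch) % (2**61 - 1))
    return int(h % np.uint64(2**31 - 1))


class JsonLinesLogger:
    """Structured event log: one JSON object per line."""

    def __init__(self, path: Path | None):
        self.path = Path(path) if path else None
        if self.path:
            self.path.parent.mkdir(parents=True, exist_ok=True)
            self.path.write_text("")

    def log(self, event: str, **fields):
        if not self.path:
            return
        record = {"t": time.time(), "event": event, **fields}
        with self.path.open("a") as fh:
            fh.write(json.dumps(record, default=float) + "\n")


@dataclass
class RunConfig:
    """Fully serialisable description of one run."""

    pipeline: str
    seed: int = 0
    out_dir: str | None = None
    model: dict = field(default_factory=chemostat_model_spec)
    episode: dict = field(default_factory=dict)
    observation: str = "Ia"
    scaling: dict = field(default_factory=dict)
    noise: dict = field(default_factory=dict)
    solver: dict = field(default_factory=dict)
    nlp: dict = field(default_factory=dict)
    agent: dict = field(default_factory=dict)
    n_episodes: int = 100
    prior_mode: bool = False
    design_file: str | None = None
    rational_inputs: list | None = None
    n_replicates: int = 30
    value_fitting: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, source) -> "RunConfig":
        if hasattr(source, "read"):
            raw = yaml.safe_load(source)
        else:
            text = Path(source).read_text() if Path(str(source)).exists() else str(source)
            raw = yaml.safe_load(text)
        if not isinstance(raw, dict):
            raise SchemaError("run config must be a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise SchemaError(f"unknown config fields: {sorted(unknown)}")
        try:
            cfg = cls(**raw)
        except TypeError as err:
            raise SchemaError(str(err)) from err
        cfg.validate()
        return cfg

    def validate(self):
        if self.pipeline not in PIPELINES:
            raise SchemaError(
                f"pipeline: must be one of {PIPELINES}, got {self.pipeline!r}"
            )
        if "input_bounds" in self.episode:
            lo, hi = self.episode["input_bounds"]
            if not lo < hi:
                raise SchemaError("episode.input_bounds: low must be < high")
        elif self.model is not None and "input_bounds" not in self.model:
            raise SchemaError("model.input_bounds: missing required field")
        for key in ("n_steps", "step_duration"):
            if key in self.episode and self.episode[key] <= 0:
                raise SchemaError(f"episode.{key}: must be positive")

    # -- component builders -------------------------------------------------
    def build_params(self) -> ChemostatParameters:
        return params_from_spec(self.model)

    def build_episode(self) -> EpisodeConfig:
        kw = dict(self.episode)
        init = self.model.get("initial_state")
        if init and "initial_state" not in kw:
            kw["initial_state"] = ChemostatState(**init)
        if "input_bounds" not in kw and "input_bounds" in self.model:
            b = self.model["input_bounds"]["C0_in"]
            kw["input_bounds"] = tuple(b)
        return EpisodeConfig(**kw)

    def build_noise(self) -> NoiseModel:
        kw = dict(self.model.get("noise", {}))
        kw.update(self.noise)
        return NoiseModel(**kw)

    def build_solver(self) -> SolverConfig:
        return SolverConfig(**self.solver)

    def build_env(self, scaling: ScalingScheme | None = None) -> ChemostatOEDEnv:
        prior = None
        if self.prior_mode:
            prior = ParameterPrior(prior_bounds_from_spec(self.model))
        return ChemostatOEDEnv(
            params=self.build_params(),
            episode=self.build_episode(),
            obs_spec=ObservationSpec(self.observation),
            scaling=scaling or ScalingScheme(**self.scaling),
            noise=self.build_noise(),
            solver=self.build_solver(),
            prior=prior,
            mode="sample_prior" if self.prior_mode else "fixed_nominal",
            seed=seed_tree(self.seed, "env"),
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class RunManifest:
    """What a finished run produced; written atomically at run end."""

    config: dict
    seed_record: dict
    metrics: dict
    artifacts: dict
    started: float
    finished: float

    def write(self, path: Path):
        path = Path(path)
        tmp = path.with_suffix(".tmp")
        tmp.write_text(json.dumps(dataclasses.asdict(self), indent=2,
                                  default=float))
        tmp.replace(path)

    @classmethod
    def read(cls, path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))


def _design_pipeline(cfg: RunConfig, log: JsonLinesLogger):
    params = cfg.build_params()
    episode = cfg.build_episode()
    noise = cfg.build_noise()
    solver = cfg.build_solver()
    nlp = NLPConfig(seed=seed_tree(cfg.seed, "nlp"), **cfg.nlp)
    diagnostics = {}
    if cfg.pipeline == "design_osao":
        design, score = osao_design(params, nlp, episode, noise, solver)
    elif cfg.pipeline == "design_mpc":
        design, score, restarts = mpc_design(params, nlp, episode, noise, solver)
        diagnostics["restart_scores"] = restarts
    else:
        if cfg.design_file:
            design = ExperimentDesign.from_csv(cfg.design_file, "rational")
        elif cfg.rational_inputs is not None:
            design = rational_design(cfg.rational_inputs, episode)
        else:
            design = staircase_design(episode)
        score, _ = evaluate_design(design, params, episode, noise, solver)
    log.log("design_done", pipeline=cfg.pipeline, score=score)
    return design, {"d_optimality": score, **diagnostics}


def run(config: RunConfig, out_dir: str | None = None) -> RunManifest:
    """Execute a pipeline; write artifacts and the manifest if out_dir set."""
    started = time.time()
    out = Path(out_dir or config.out_dir) if (out_dir or config.out_dir) else None
    if out:
        out.mkdir(parents=True, exist_ok=True)
    log = JsonLinesLogger(out / "events.jsonl" if out else None)
    metrics: dict = {}
    artifacts: dict = {}

    if config.pipeline.startswith("design_"):
        design, metrics = _design_pipeline(config, log)
        if out:
            design.to_csv(out / "design.csv")
            artifacts["design"] = str(out / "design.csv")
    elif config.pipeline == "train_fq":
        env = config.build_env()
        grid = DiscreteActionGrid(
            n_levels_per_input=config.agent.get("n_levels_per_input", 10),
            bounds=config.build_episode().input_bounds,
        )
        fq_cfg = FQTrainConfig(
            **{k: v for k, v in config.agent.items()
               if k in FQTrainConfig.__dataclass_fields__}
        )
        q_net, curve, _ = fq_learning(
            env, config.n_episodes, grid, fq_cfg,
            seed=seed_tree(config.seed, "fq"),
        )
        metrics = {
            "final_return": float(curve["return"].iloc[-1]),
            "mean_return_last_10pct": float(
                curve["return"].tail(max(1, len(curve) // 10)).mean()
            ),
        }
        if out:
            curve.to_csv(out / "training_curve.csv", index=False)
            artifacts["training_curve"] = str(out / "training_curve.csv")
    elif config.pipeline == "train_rt3d":
        env = config.build_env()
        rt_cfg = RT3DConfig(
            **{k: v for k, v in config.agent.items()
               if k in RT3DConfig.__dataclass_fields__}
        )
        agent, curve = train_rt3d(
            env, config.n_episodes, rt_cfg,
            seed=seed_tree(config.seed, "rt3d"),
            filter_unstable=config.prior_mode,
        )
        metrics = {
            "final_return": float(curve["return"].iloc[-1]),
            "n_discarded": int(curve.attrs.get("n_discarded", 0)),
        }
        if out:
            curve.to_csv(out / "training_curve.csv", index=False)
            agent.save(out / "agent_snapshot.npz")
            artifacts["snapshot"] = str(out / "agent_snapshot.npz")
    elif config.pipeline == "eval_value_fitting":
        vf = config.value_fitting
        prior = ParameterPrior(prior_bounds_from_spec(config.model))
        kw = dict(
            prior=prior, episode=config.build_episode(),
            noise=config.build_noise(), solver=config.build_solver(),
            base_params=config.build_params(),
        )
        n_param = vf.get("n_parametrisations", 1000)
        train = ev.generate_value_dataset(
            n_param, seed=seed_tree(config.seed, "vf", "train"), **kw)
        test = ev.generate_value_dataset(
            n_param, seed=seed_tree(config.seed, "vf", "test"), **kw)
        results = {}
        for form in vf.get("formulations", ["Ia", "IIa", "IIb", "IIIa"]):
            results[form] = ev.fit_and_score_value(
                train, test, ObservationSpec(form),
                seed=seed_tree(config.seed, "vf", form),
                n_repeats=vf.get("n_repeats", 5),
                epochs=vf.get("epochs", 100),
            )
            log.log("value_fitting_done", **results[form])
        metrics = results
    elif config.pipeline == "eval_inference":
        params = config.build_params()
        episode = config.build_episode()
        if not config.design_file:
            raise SchemaError("design_file: required for eval_inference")
        design = ExperimentDesign.from_csv(config.design_file, "rational")
        replicates = ev.run_inference_study(
            design, params, config.n_replicates, config.build_noise(),
            seed=seed_tree(config.seed, "inference"), episode=episode,
            solver=config.build_solver(),
        )
        fm = ev.inference_metrics(replicates)
        metrics = {
            "normalised_mse": fm.normalised_mse,
            "logdet_cov": fm.logdet_cov,
            "n_converged": fm.n_replicates,
        }
        if out:
            ev.replicates_frame(replicates).to_csv(
                out / "replicates.csv", index=False
            )
            artifacts["replicates"] = str(out / "replicates.csv")

    manifest = RunManifest(
        config=config.to_dict(),
        seed_record={"root": config.seed},
        metrics=metrics,
        artifacts=artifacts,
        started=started,
        finished=time.time(),
    )
    if out:
        manifest.write(out / "manifest.json")
    return manifest


def compare_designs(
    designs: dict[str, ExperimentDesign],
    params: ChemostatParameters,
    episode: EpisodeConfig = EpisodeConfig(),
    noise: NoiseModel = NoiseModel(),
    solver: SolverConfig = SolverConfig(),
    n_replicates: int = 0,
    seed: int = 0,
) -> pd.DataFrame:
    """Score designs side by side, sorted by D-optimality (descending).

    With ``n_replicates > 0`` the inference pipeline adds normalised MSE and
    log|cov| columns for each design.
    """
    rows = []
    for name, design in designs.items():
        score, _ = evaluate_design(design, params, episode, noise, solver)
        row = {"design": name, "d_optimality": score}
        if n_replicates > 0:
            reps = ev.run_inference_study(
                design, params, n_replicates, noise,
                seed=seed_tree(seed, "compare", name), episode=episode,
                solver=solver,
            )
            fm = ev.inference_metrics(reps)
            row["normalised_mse"] = fm.normalised_mse
            row["logdet_cov"] = fm.logdet_cov
            row["n_converged"] = fm.n_replicates
        rows.append(row)
    frame = pd.DataFrame(rows).sort_values(
        "d_optimality", ascending=False, ignore_index=True
    )
    return frame
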