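"""Run configuration: a validated YAML schema tying all stages together.

A run config nests the phantom, beam, optimizer and training sub-configs,
an output directory and one global seed; every random stream in a pipeline
run derives from that seed.  Unknown keys are rejected at load time.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field

from .dose_engine import BeamConfig, KernelParams, build_influence
from .phantom import GeometryConfig, GridSpec, generate_case
from .plan_optim import OptimConfig
from .trainer import TrainingConfig, evaluate, train

__all__ = ["RunConfig", "load_config", "run_pipeline"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class PhantomSection(_Strict):
    grid_shape: tuple[int, int, int] = (16, 16, 16)
    spacing_mm: tuple[float, float, float] = (5.0, 5.0, 5.0)
    preset: str = "small"  # "default" | "small"
    n_train_cases: int = 3
    n_eval_cases: int = 20


class BeamSection(_Strict):
    n_beams: int = 9
    angular_interval_deg: float = 40.0
    beamlet_size_mm: tuple[float, float] = (5.0, 5.0)
    mu_per_mm: float = 0.005
    sigma_mm: float = 4.0


class OptimSection(_Strict):
    maxiter: int = 200


class TrainSection(_Strict):
    gamma: float = 0.9
    learning_rate: float = 1e-3
    n_episodes: int = 30
    batch_size: int = 20
    pool_capacity: int = 4096
    target_sync_steps: int = 80
    max_steps_train: int = 20
    max_steps_eval: int = 25


class RunConfig(_Strict):
    """Top-level, schema-validated pipeline configuration."""

    seed: int = 0
    prescription_gy: float = 50.0
    out_dir: str = "moapn_run"
    phantom: PhantomSection = Field(default_factory=PhantomSection)
    beams: BeamSection = Field(default_factory=BeamSection)
    optimizer: OptimSection = Field(default_factory=OptimSection)
    training: TrainSection = Field(default_factory=TrainSection)

    def config_hash(self) -> str:
        blob = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.model_dump()))
        return path


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration; unknown keys fail."""
    payload = yaml.safe_load(Path(path).read_text()) or {}
    return RunConfig.model_validate(payload)


def _build_components(cfg: RunConfig):
    grid = GridSpec(tuple(cfg.phantom.grid_shape), tuple(cfg.phantom.spacing_mm))
    geometry = (
        GeometryConfig.small() if cfg.phantom.preset == "small"
        else GeometryConfig.default()
    )
    beams = BeamConfig(
        n_beams=cfg.beams.n_beams,
        angular_interval_deg=cfg.beams.angular_interval_deg,
        beamlet_size_mm=tuple(cfg.beams.beamlet_size_mm),
    )
    kernel = KernelParams(mu_per_mm=cfg.beams.mu_per_mm, sigma_mm=cfg.beams.sigma_mm)
    training = TrainingConfig(
        gamma=cfg.training.gamma,
        learning_rate=cfg.training.learning_rate,
        n_episodes=cfg.training.n_episodes,
        batch_size=cfg.training.batch_size,
        pool_capacity=cfg.training.pool_capacity,
        target_sync_steps=cfg.training.target_sync_steps,
        max_steps_train=cfg.training.max_steps_train,
        max_steps_eval=cfg.training.max_steps_eval,
        prescription_gy=cfg.prescription_gy,
        optim=OptimConfig(maxiter=cfg.optimizer.maxiter),
    )
    return grid, geometry, beams, kernel, training


def run_pipeline(cfg: RunConfig) -> dict:
    """Full chain: generate cases, initial objectives, train, evaluate.

    Writes the training curve, cohort report and summary under
    ``cfg.out_dir``, each stamped with the config hash and seed; returns
    the artifact paths and the cohort summary.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    grid, geometry, beams, kernel, training = _build_components(cfg)

    ss = np.random.SeedSequence(cfg.seed)
    seeds = ss.generate_state(cfg.phantom.n_train_cases + cfg.phantom.n_eval_cases)
    seeds = [int(s % 2**31) for s in seeds]
    train_seeds = seeds[: cfg.phantom.n_train_cases]
    eval_seeds = seeds[cfg.phantom.n_train_cases:]

    def _make(seed_list):
        cases, infls = [], []
        for s in seed_list:
            case = generate_case(s, grid=grid, geometry=geometry)
            cases.append(case)
            infls.append(build_influence(case, beams, kernel))
        return cases, infls

    train_cases, train_infls = _make(train_seeds)
    eval_cases, eval_infls = _make(eval_seeds)

    ensemble, curve, _ = train(train_cases, train_infls, training, seed=cfg.seed)
    report, summary = evaluate(eval_cases, eval_infls, ensemble, training)

    stamp = {"config_hash": cfg.config_hash(), "seed": cfg.seed}
    curve.to_csv(out / "training_curve.csv", index=False)
    report.to_csv(out / "cohort_report.csv", index=False)
    (out / "summary.json").write_text(
        json.dumps({**stamp, **summary}, indent=2, default=float)
    )
    ensemble.save(out / "agents")
    cfg.to_yaml(out / "run_config.yaml")
    return {
        "summary": summary,
        "curve_path": str(out / "training_curve.csv"),
        "report_path": str(out / "cohort_report.csv"),
        "summary_path": str(out / "summary.json"),
        **stamp,
    }
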