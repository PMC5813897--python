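"""Experiment configuration: a validated YAML schema covering the model,
run, intervention, GA and outcome blocks, with round-trip save/load."""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .ga import GAConfig
from .intervention import InterventionSchedule, InterventionStage
from .mediators import DEFAULT_MEDIATOR_SPECS, MEDIATORS, MediatorSpec
from .params import PROFILES, ModelParams, RuleConstants
from .world import DEFAULT_MAX_STEPS

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Raised with a dotted field path naming the offending key."""


@dataclass
class ExperimentConfig:
    constants: RuleConstants
    specs: tuple[MediatorSpec, ...]
    params: ModelParams
    seed: int = 0
    max_steps: int = DEFAULT_MAX_STEPS
    schedule: InterventionSchedule | None = None
    ga: GAConfig = field(default_factory=lambda: GAConfig())
    n_seeds: int = 100
    n_reseeds: int = 100
    snapshot_step: int = 100

    def to_dict(self) -> dict:
        d: dict = {
            "model": {
                "profile": None,
                "grid": list(self.constants.grid_shape),
                "rules": {
                    k: v
                    for k, v in dataclasses.asdict(self.constants).items()
                    if k != "grid_shape"
                },
                "mediators": {
                    s.name: {"D": s.diffusion_constant, "lam": s.degradation_constant}
                    for s in self.specs
                },
            },
            "run": {
                "params": dataclasses.asdict(self.params),
                "seed": self.seed,
                "max_steps": self.max_steps,
            },
            "outcomes": {
                "n_seeds": self.n_seeds,
                "n_reseeds": self.n_reseeds,
                "snapshot_step": self.snapshot_step,
            },
            "ga": {
                k: v for k, v in dataclasses.asdict(self.ga).items()
            },
        }
        if self.schedule is not None:
            d["intervention"] = {
                "start_step": self.schedule.start_step,
                "spacing_steps": self.schedule.spacing_steps,
                "duration_steps": self.schedule.duration_steps,
                "stages": [list(s.multipliers) for s in self.schedule.stages],
            }
        return d

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def _require_keys(block: dict, allowed: set[str], path: str) -> None:
    unknown = set(block) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} under '{path}'")


def load_config(path) -> ExperimentConfig:
    """Load and validate a YAML experiment config, filling documented
    defaults for everything absent.

    A minimal file may contain just ``run.params``; cross-field constraints
    (injury radius vs grid, stage overlap, allele validity) are enforced
    here so later stages can assume a coherent configuration.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    _require_keys(raw, {"model", "run", "intervention", "ga", "outcomes"}, "<root>")

    model = raw.get("model") or {}
    _require_keys(model, {"profile", "grid", "rules", "mediators"}, "model")
    profile = model.get("profile")
    if profile is not None:
        if profile not in PROFILES:
            raise ConfigError(
                f"model.profile: unknown profile {profile!r} "
                f"(available: {sorted(PROFILES)})"
            )
        constants = PROFILES[profile]
    else:
        constants = RuleConstants()
    if "grid" in model:
        grid = model["grid"]
        if (
            not isinstance(grid, (list, tuple))
            or len(grid) != 2
            or not all(isinstance(g, int) and g >= 3 for g in grid)
        ):
            raise ConfigError("model.grid must be two integers >= 3")
        constants = constants.replace(grid_shape=tuple(grid))
    rules = model.get("rules") or {}
    valid_rule_names = {f.name for f in dataclasses.fields(RuleConstants)}
    for k in rules:
        if k not in valid_rule_names:
            raise ConfigError(f"model.rules.{k}: unknown rule constant")
    if rules:
        constants = constants.replace(
            **{k: v for k, v in rules.items() if k != "grid_shape"}
        )

    specs = list(DEFAULT_MEDIATOR_SPECS)
    med_over = model.get("mediators") or {}
    for name, dd in med_over.items():
        if name not in MEDIATORS:
            raise ConfigError(f"model.mediators.{name}: unknown mediator")
        _require_keys(dd, {"D", "lam"}, f"model.mediators.{name}")
        idx = MEDIATORS.index(name)
        old = specs[idx]
        try:
            specs[idx] = MediatorSpec(
                name,
                float(dd.get("D", old.diffusion_constant)),
                float(dd.get("lam", old.degradation_constant)),
            )
        except ValueError as e:
            raise ConfigError(f"model.mediators.{name}: {e}") from e

    run = raw.get("run") or {}
    _require_keys(run, {"params", "seed", "max_steps"}, "run")
    pdict = run.get("params") or {}
    valid_params = {f.name for f in dataclasses.fields(ModelParams)}
    for k in pdict:
        if k not in valid_params:
            raise ConfigError(f"run.params.{k}: unknown parameter")
    try:
        params = ModelParams(**pdict)
        params.validate_for_grid(constants.grid_shape)
    except ValueError as e:
        raise ConfigError(f"run.params: {e}") from e

    schedule = None
    if "intervention" in raw and raw["intervention"]:
        iv = raw["intervention"]
        _require_keys(
            iv, {"file", "start_step", "spacing_steps", "duration_steps", "stages"},
            "intervention",
        )
        if "file" in iv:
            schedule = InterventionSchedule.load(iv["file"])
        else:
            try:
                stages = tuple(
                    InterventionStage(tuple(float(x) for x in s))
                    for s in iv.get("stages", [])
                )
                schedule = InterventionSchedule(
                    stages,
                    int(iv.get("start_step", 100)),
                    int(iv.get("spacing_steps", 100)),
                    int(iv.get("duration_steps", 99)),
                )
            except ValueError as e:
                raise ConfigError(f"intervention: {e}") from e

    ga_block = raw.get("ga") or {}
    valid_ga = {f.name for f in dataclasses.fields(GAConfig)}
    for k in ga_block:
        if k not in valid_ga:
            raise ConfigError(f"ga.{k}: unknown GA option")
    try:
        ga = GAConfig(**ga_block)
    except ValueError as e:
        raise ConfigError(f"ga: {e}") from e

    out = raw.get("outcomes") or {}
    _require_keys(out, {"n_seeds", "n_reseeds", "snapshot_step"}, "outcomes")

    cfg = ExperimentConfig(
        constants=constants,
        specs=tuple(specs),
        params=params,
        seed=int(run.get("seed", 0)),
        max_steps=int(run.get("max_steps", DEFAULT_MAX_STEPS)),
        schedule=schedule,
        ga=ga,
        n_seeds=int(out.get("n_seeds", 100)),
        n_reseeds=int(out.get("n_reseeds", 100)),
        snapshot_step=int(out.get("snapshot_step", 100)),
    )
    logger.debug("loaded config from %s: %s", path, cfg.to_dict())
    return cfg
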