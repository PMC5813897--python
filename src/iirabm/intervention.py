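"""Multi-stage cytokine intervention schedules and the treated update.

An intervention stage is a 12-vector of multipliers ``T``, one per mediator
in canonical order, drawn from the clinically tractable allele set
{0.05, 0.25, 0.5, 0.75, 1, 2, 5, 10, 20}.  During an active stage the local
cytokine update ``F`` is transformed per location and mediator:
inhibition is multiplicative (``F * T`` for ``T <= 1``) while augmentation
is additive (``F + (T - 1)`` for ``T > 1``), which sustains the
augmentation without the exponential blow-up a multiplicative boost would
cause.  A schedule is an ordered list of stages with a common start step
(default 100 = 12 h post-injury), inter-stage spacing (default 100 steps)
and per-stage duration; outside active stages the multipliers are all
ones, i.e. the untreated dynamics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .mediators import MEDIATORS, N_MEDIATORS

#: The nine permitted augmentation/inhibition values.
ALLELES: tuple[float, ...] = (0.05, 0.25, 0.5, 0.75, 1.0, 2.0, 5.0, 10.0, 20.0)

_ALLELE_ARR = np.array(ALLELES)

IDENTITY = np.ones(N_MEDIATORS)

DEFAULT_START_STEP = 100
DEFAULT_SPACING = 100
#: Stage durations explored in the multi-stage experiments.
STANDARD_DURATIONS = (25, 50, 99)


def _check_allele(value: float, where: str) -> None:
    if not np.any(np.isclose(value, _ALLELE_ARR, rtol=0, atol=1e-12)):
        raise ValueError(f"{where}: multiplier {value} is not in the allele set {ALLELES}")


@dataclass(frozen=True)
class InterventionStage:
    """One simultaneous set of 12 mediator augmentations/inhibitions."""

    multipliers: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.multipliers) != N_MEDIATORS:
            raise ValueError(
                f"stage needs {N_MEDIATORS} multipliers (one per mediator in "
                f"order {MEDIATORS}), got {len(self.multipliers)}"
            )
        for i, t in enumerate(self.multipliers):
            _check_allele(t, f"stage multiplier for {MEDIATORS[i]} (index {i})")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.multipliers, dtype=float)


@dataclass(frozen=True)
class InterventionSchedule:
    """Ordered, non-overlapping intervention stages on the step clock."""

    stages: tuple[InterventionStage, ...]
    start_step: int = DEFAULT_START_STEP
    spacing_steps: int = DEFAULT_SPACING
    duration_steps: int = 99

    def __post_init__(self) -> None:
        if self.start_step < 0:
            raise ValueError("start_step must be >= 0")
        if self.duration_steps < 1:
            raise ValueError("duration_steps must be >= 1")
        if len(self.stages) > 1 and self.duration_steps > self.spacing_steps:
            raise ValueError(
                f"duration_steps ({self.duration_steps}) may not exceed "
                f"spacing_steps ({self.spacing_steps}): stages would overlap"
            )

    @property
    def n_stages(self) -> int:
        return len(self.stages)

    @property
    def final_stage_start(self) -> int:
        return self.start_step + (self.n_stages - 1) * self.spacing_steps

    @property
    def end_step(self) -> int:
        """First step at which no stage will ever be active again."""
        return self.final_stage_start + self.duration_steps

    def to_json(self) -> str:
        return json.dumps(
            {
                "start_step": self.start_step,
                "spacing_steps": self.spacing_steps,
                "duration_steps": self.duration_steps,
                "stages": [list(s.multipliers) for s in self.stages],
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "InterventionSchedule":
        d = json.loads(text)
        return cls(
            stages=tuple(InterventionStage(tuple(s)) for s in d["stages"]),
            start_step=int(d["start_step"]),
            spacing_steps=int(d["spacing_steps"]),
            duration_steps=int(d["duration_steps"]),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path) -> "InterventionSchedule":
        with open(path) as fh:
            return cls.from_json(fh.read())


def stage_transform(base_update: float | np.ndarray, T: float) -> float | np.ndarray:
    """Treated local update: multiplicative inhibition, additive augmentation.

    Returns ``F * T`` when ``T <= 1`` and ``F + (T - 1)`` when ``T > 1``,
    clipped at zero.  The two branches coincide at ``T = 1``.
    """
    _check_allele(T, "stage_transform")
    f = np.asarray(base_update, dtype=float)
    out = f * T if T <= 1.0 else f + (T - 1.0)
    out = np.maximum(out, 0.0)
    return float(out) if np.isscalar(base_update) else out


def apply_multipliers_to_field(conc: np.ndarray, multipliers: np.ndarray) -> np.ndarray:
    """Vectorized treated update of the (12, H, W) concentration field."""
    t = np.asarray(multipliers, dtype=float)
    if t.shape != (N_MEDIATORS,):
        raise ValueError(f"multiplier vector must have shape ({N_MEDIATORS},)")
    t3 = t[:, None, None]
    out = np.where(t3 <= 1.0, conc * t3, conc + (t3 - 1.0))
    np.maximum(out, 0.0, out=out)
    return out


def active_multipliers(schedule: InterventionSchedule, t: int) -> np.ndarray:
    """Multiplier vector in force at step ``t`` (all ones when no stage is).

    Stage ``k`` is active on ``[start + k*spacing, start + k*spacing +
    duration)``; before the first stage, in inter-stage gaps and after the
    final stage the identity vector is returned.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    rel = t - schedule.start_step
    if rel < 0 or schedule.n_stages == 0:
        return IDENTITY.copy()
    if schedule.spacing_steps > 0:
        k = min(rel // schedule.spacing_steps, schedule.n_stages - 1)
    else:
        k = schedule.n_stages - 1
    offset = rel - k * schedule.spacing_steps
    if 0 <= offset < schedule.duration_steps:
        return schedule.stages[k].as_array()
    return IDENTITY.copy()


def schedule_from_chromosome(
    genes: np.ndarray,
    start_step: int = DEFAULT_START_STEP,
    spacing_steps: int = DEFAULT_SPACING,
    duration_steps: int = 99,
) -> InterventionSchedule:
    """Decode a flat 1x12n allele vector into an n-stage schedule.

    Stage ``k`` receives genes ``[12k, 12k + 12)``; the mapping is bijective
    with :func:`flatten_schedule`.
    """
    genes = np.asarray(genes, dtype=float).ravel()
    if genes.size == 0 or genes.size % N_MEDIATORS != 0:
        raise ValueError(
            f"chromosome length {genes.size} is not a positive multiple of "
            f"{N_MEDIATORS} (position {genes.size - (genes.size % N_MEDIATORS)} "
            "onward is an incomplete stage)"
        )
    for i, g in enumerate(genes):
        if not np.any(np.isclose(g, _ALLELE_ARR, rtol=0, atol=1e-12)):
            raise ValueError(f"gene at position {i} has invalid allele {g}")
    stages = tuple(
        InterventionStage(tuple(genes[k * N_MEDIATORS : (k + 1) * N_MEDIATORS]))
        for k in range(genes.size // N_MEDIATORS)
    )
    return InterventionSchedule(stages, start_step, spacing_steps, duration_steps)


def flatten_schedule(schedule: InterventionSchedule) -> np.ndarray:
    """Inverse of :func:`schedule_from_chromosome`."""
    return np.concatenate([s.as_array() for s in schedule.stages])


def identity_schedule(
    n_stages: int,
    start_step: int = DEFAULT_START_STEP,
    spacing_steps: int = DEFAULT_SPACING,
    duration_steps: int = 99,
) -> InterventionSchedule:
    """An n-stage schedule of all-ones stages (no-op treatment)."""
    return schedule_from_chromosome(
        np.ones(n_stages * N_MEDIATORS), start_step, spacing_steps, duration_steps
    )
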