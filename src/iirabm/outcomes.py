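"""Outcome statistics: mortality estimation, responder references,
non-responder detection and adaptive mid-course re-optimization.

Two mortality notions are distinguished.  *General* mortality is the death
fraction over an ensemble of fully independent runs of one parameter set
(distinct RNG seeds from injury onward) — the population-level outcome
distribution.  *Patient-specific* mortality freezes one trajectory at a
time point (typically 12 h post-injury), reseeds its RNG many times and
runs each copy to completion — the outcome distribution of one in-silico
patient at one moment, which evolves as the patient's state evolves.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .ga import GAConfig, optimize_intervention
from .params import DEFAULT_CONSTANTS, ModelParams, RuleConstants
from .mediators import DEFAULT_MEDIATOR_SPECS
from .world import (
    ALIVE,
    DEAD_INFECTION,
    DEAD_SEPSIS,
    DEFAULT_MAX_STEPS,
    HEALED,
    Trajectory,
    init_world,
    run_simulation,
    run_world,
)

logger = logging.getLogger(__name__)


@dataclass
class MortalityEstimate:
    """Death fraction over a seed ensemble with a binomial 95% interval."""

    deaths: int
    n_runs: int
    ci_low: float
    ci_high: float
    by_type: dict[str, int]

    @property
    def death_fraction(self) -> float:
        return self.deaths / self.n_runs

    def __str__(self) -> str:
        return (
            f"{self.deaths}/{self.n_runs} deaths "
            f"({100 * self.death_fraction:.1f}%, 95% CI "
            f"[{100 * self.ci_low:.1f}%, {100 * self.ci_high:.1f}%])"
        )


def _estimate(statuses: list[str]) -> MortalityEstimate:
    deaths = sum(s in (DEAD_INFECTION, DEAD_SEPSIS) for s in statuses)
    n = len(statuses)
    lo, hi = proportion_confint(deaths, n, alpha=0.05, method="wilson")
    by_type = {
        DEAD_INFECTION: statuses.count(DEAD_INFECTION),
        DEAD_SEPSIS: statuses.count(DEAD_SEPSIS),
        HEALED: statuses.count(HEALED),
        ALIVE: statuses.count(ALIVE),
    }
    return MortalityEstimate(deaths, n, float(lo), float(hi), by_type)


def estimate_mortality_general(
    params: ModelParams,
    schedule=None,
    n_seeds: int = 100,
    base_seed: int = 0,
    constants: RuleConstants = DEFAULT_CONSTANTS,
    specs=DEFAULT_MEDIATOR_SPECS,
    max_steps: int = DEFAULT_MAX_STEPS,
) -> MortalityEstimate:
    """General (population) mortality: n_seeds fully independent runs.

    Run ``i`` uses seed ``base_seed + i``.  The estimate is exactly
    ``deaths / n_seeds`` with a Wilson 95% interval; runs still alive at
    the step cap count as survivors.
    """
    if n_seeds < 1:
        raise ValueError("n_seeds must be >= 1")
    statuses = []
    for i in range(n_seeds):
        traj = run_simulation(
            params, base_seed + i, schedule, max_steps, constants, specs,
            record_every=max_steps,
        )
        statuses.append(traj.final_status)
        if (i + 1) % 10 == 0:
            logger.info("general mortality: %d/%d runs done", i + 1, n_seeds)
    return _estimate(statuses)


def estimate_mortality_patient(
    snapshot,
    schedule=None,
    n_reseeds: int = 100,
    base_seed: int = 10_000,
    max_steps: int = DEFAULT_MAX_STEPS,
) -> MortalityEstimate:
    """Patient-specific mortality of a frozen snapshot.

    Each of ``n_reseeds`` copies of the snapshot gets a fresh RNG
    (``base_seed + i``), the schedule (if any) and runs to completion.  An
    already-absorbing snapshot short-circuits to 0 or 1.
    """
    if snapshot.status != ALIVE:
        dead = snapshot.status in (DEAD_INFECTION, DEAD_SEPSIS)
        statuses = [snapshot.status] * n_reseeds
        return _estimate(statuses)
    statuses = []
    for i in range(n_reseeds):
        w = snapshot.copy()
        w.reseed(base_seed + i)
        run_world(w, schedule, max_steps=max_steps, record_every=max_steps)
        statuses.append(w.status)
        if (i + 1) % 10 == 0:
            logger.info("patient mortality: %d/%d reseeds done", i + 1, n_reseeds)
    return _estimate(statuses)


def snapshot_at(
    params: ModelParams,
    seed: int,
    at_step: int = 100,
    constants: RuleConstants = DEFAULT_CONSTANTS,
    specs=DEFAULT_MEDIATOR_SPECS,
):
    """Run one trajectory to ``at_step`` and return the frozen world."""
    world = init_world(params, seed, constants, specs)
    run_world(world, None, max_steps=at_step, record_every=at_step)
    return world


# ------------------------------------------------------ responder analysis

@dataclass
class ResponderReference:
    """Per-step mean and SD of selected observables over responders."""

    observables: tuple[str, ...]
    mean: pd.DataFrame  # indexed by step, one column per observable
    sd: pd.DataFrame

    @property
    def n_steps(self) -> int:
        return len(self.mean)


def build_responder_reference(
    trajectories: list[Trajectory | pd.DataFrame],
    observables: tuple[str, ...] = ("oxygen_deficit", "n_neutrophil", "GCSF"),
) -> ResponderReference:
    """Pointwise mean/SD envelope of an ensemble of responder trajectories.

    The reference is defined on the common support of the inputs, i.e. up
    to the length of the shortest trajectory (at least two trajectories are
    required for an SD to exist).
    """
    if len(trajectories) < 2:
        raise ValueError("need at least 2 responder trajectories")
    frames = [
        t.to_frame() if isinstance(t, Trajectory) else t for t in trajectories
    ]
    n = min(len(f) for f in frames)
    stack = np.stack([f[list(observables)].to_numpy()[:n] for f in frames])
    mean = pd.DataFrame(stack.mean(axis=0), columns=list(observables))
    sd = pd.DataFrame(stack.std(axis=0, ddof=0), columns=list(observables))
    return ResponderReference(tuple(observables), mean, sd)


def detect_non_responder(
    trajectory: Trajectory | pd.DataFrame,
    ref: ResponderReference,
    z_threshold: float = 3.0,
    consecutive_steps: int = 10,
) -> tuple[bool, int | None]:
    """Flag a trajectory that leaves the responder envelope persistently.

    A deviation is declared at the first step at which some monitored
    observable has lain outside ``mean +- z_threshold * sd`` for
    ``consecutive_steps`` consecutive steps; that confirming step index is
    returned.  Steps where the ensemble SD is zero deviate iff the values
    differ.
    """
    frame = trajectory.to_frame() if isinstance(trajectory, Trajectory) else trajectory
    n = min(len(frame), ref.n_steps)
    vals = frame[list(ref.observables)].to_numpy()[:n]
    mean = ref.mean.to_numpy()[:n]
    sd = ref.sd.to_numpy()[:n]
    if np.isinf(z_threshold):
        return False, None
    with np.errstate(invalid="ignore"):
        outside = np.abs(vals - mean) > z_threshold * sd
    outside |= (sd == 0) & (vals != mean)
    any_out = outside.any(axis=1)
    run = 0
    for step_idx, flag in enumerate(any_out):
        run = run + 1 if flag else 0
        if run >= consecutive_steps:
            return True, step_idx
    return False, None


def adaptive_reoptimize(
    snapshot,
    remaining_stage_count: int,
    config: GAConfig,
    spacing_steps: int = 100,
    duration_steps: int = 99,
    max_steps: int = DEFAULT_MAX_STEPS,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Re-train the GA on a deviant patient for the remaining stages only.

    The stages already administered are baked into the snapshot's state;
    the search therefore covers only the tail (``remaining_stage_count``
    stages starting at the snapshot's current step) and returns the
    replacement tail chromosome plus the GA history.
    """
    if remaining_stage_count < 1:
        raise ValueError("remaining_stage_count must be >= 1")
    if snapshot.status != ALIVE:
        raise ValueError(f"snapshot is absorbing (status={snapshot.status})")
    return optimize_intervention(
        snapshot, remaining_stage_count, config, spacing_steps, duration_steps,
        max_steps,
    )


# ------------------------------------------------------------- sweep

def parameter_sweep(
    param_sets: list[ModelParams],
    schedule=None,
    n_seeds: int = 25,
    base_seed: int = 0,
    constants: RuleConstants = DEFAULT_CONSTANTS,
    max_steps: int = DEFAULT_MAX_STEPS,
) -> pd.DataFrame:
    """Desk-scale generalizability sweep: mortality per parameter set.

    Returns one row per parameter set with untreated-or-treated death
    fraction and interval; pair two sweeps (schedule=None vs a schedule)
    to build a before/after mortality histogram.
    """
    rows = []
    for k, p in enumerate(param_sets):
        est = estimate_mortality_general(
            p, schedule, n_seeds, base_seed, constants, max_steps=max_steps
        )
        rows.append(
            {
                "invasiveness": p.invasiveness,
                "toxigenesis": p.toxigenesis,
                "host_resilience": p.host_resilience,
                "environmental_toxicity": p.environmental_toxicity,
                "injury_radius": p.injury_radius,
                "n": est.n_runs,
                "deaths": est.deaths,
                "death_fraction": est.death_fraction,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
                "dead_infection": est.by_type[DEAD_INFECTION],
                "dead_sepsis": est.by_type[DEAD_SEPSIS],
            }
        )
        logger.info("sweep: parameter set %d/%d done", k + 1, len(param_sets))
    return pd.DataFrame(rows)
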