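"""Genetic-algorithm search for multi-stage intervention chromosomes.

A chromosome is a flat 1x12n allele vector (n stages of 12 mediator
multipliers).  Fitness of a candidate is the sum, over stochastic
replicates of a frozen patient snapshot, of the oxygen deficit plus the
infectious load read 12 hours (100 steps) after the final stage begins:

    F = sum_i (OD_i + X_i),   i = 1..n_replicates

lower is better.  Replicates reseed the snapshot's RNG with seeds derived
deterministically from the GA seed, so a fitness evaluation is exactly
reproducible.  Selection is by tournaments of size 2, breeding by uniform
crossover producing two complementary children, plus per-gene mutation;
one elite is carried unchanged per generation, which makes the best-so-far
fitness non-increasing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .intervention import ALLELES, schedule_from_chromosome
from .mediators import N_MEDIATORS
from .world import ALIVE, DEFAULT_MAX_STEPS, observe, run_world


@dataclass
class GAConfig:
    """Knobs of the evolutionary search."""

    population_size: int = 200
    generations: int = 100
    tournament_size: int = 2      # fixed by the selection scheme
    mutation_rate: float | None = None  # default 1/L, set at run time
    replicates: int = 10
    elitism_count: int = 1
    stall_generations: int = 25   # convergence: best F unchanged this long
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 2 or self.population_size % 2:
            raise ValueError("population_size must be an even integer >= 2")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.elitism_count < 0:
            raise ValueError("elitism_count must be >= 0")


@dataclass
class FitnessResult:
    """Replicate-level readouts and their sum F."""

    oxygen_deficits: np.ndarray
    infectious_loads: np.ndarray

    @property
    def F(self) -> float:
        return float(self.oxygen_deficits.sum() + self.infectious_loads.sum())

    @property
    def n_replicates(self) -> int:
        return self.oxygen_deficits.size


def replicate_seeds(rng_seed: int, n: int) -> list[int]:
    """Deterministic per-replicate seeds.

    Seed ``i`` is the first word of ``SeedSequence([rng_seed, i])`` reduced
    below 2**31; the derivation is fixed so independent implementations can
    reproduce a fitness value exactly.
    """
    return [
        int(np.random.SeedSequence([int(rng_seed), i]).generate_state(1)[0] % (2**31))
        for i in range(n)
    ]


def evaluate_fitness(
    genes: np.ndarray,
    snapshot,
    config: GAConfig,
    spacing_steps: int = 100,
    duration_steps: int = 99,
    max_steps: int = DEFAULT_MAX_STEPS,
) -> FitnessResult:
    """Replicate-summed fitness of one chromosome on a frozen snapshot.

    Each replicate copies the snapshot, reseeds its RNG, runs under the
    chromosome's schedule (stages anchored at the snapshot's current step)
    and reads OD and X 100 steps after the final stage starts.  A replicate
    that dies earlier contributes its terminal (maximal) OD and terminal X;
    one that heals earlier contributes zeros.
    """
    if snapshot.status != ALIVE:
        raise ValueError(f"snapshot is absorbing (status={snapshot.status})")
    schedule = schedule_from_chromosome(
        genes, start_step=snapshot.t, spacing_steps=spacing_steps,
        duration_steps=duration_steps,
    )
    eval_step = schedule.final_stage_start + 100
    ods, xs = [], []
    for seed in replicate_seeds(config.rng_seed, config.replicates):
        w = snapshot.copy()
        w.reseed(seed)
        run_world(w, schedule, max_steps=min(eval_step - w.t, max_steps))
        ob = observe(w)
        ods.append(ob.oxygen_deficit)
        xs.append(ob.infectious_load)
    return FitnessResult(np.array(ods), np.array(xs))


# --------------------------------------------------------------------- GA ops

def random_chromosome(n_genes: int, rng: np.random.Generator,
                      alleles: Sequence[float] = ALLELES) -> np.ndarray:
    return rng.choice(np.asarray(alleles, dtype=float), size=n_genes)


def tournament_select(
    population: Sequence[np.ndarray],
    fitnesses: Sequence[float],
    rng: np.random.Generator,
) -> np.ndarray:
    """Size-2 tournament: draw two uniformly with replacement, keep the
    lower-fitness one; ties break uniformly at random."""
    if len(population) == 0:
        raise ValueError("population is empty")
    i, j = rng.integers(0, len(population), size=2)
    fi, fj = fitnesses[i], fitnesses[j]
    if fi < fj:
        return population[i]
    if fj < fi:
        return population[j]
    return population[i if rng.random() < 0.5 else j]


def uniform_crossover(
    p1: np.ndarray, p2: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene coin flip; the two children take complementary alleles."""
    if p1.shape != p2.shape:
        raise ValueError(f"parent length mismatch: {p1.shape} vs {p2.shape}")
    mask = rng.random(p1.size) < 0.5
    c1 = np.where(mask, p1, p2)
    c2 = np.where(mask, p2, p1)
    return c1, c2


def mutate(
    genes: np.ndarray,
    rate: float,
    rng: np.random.Generator,
    alleles: Sequence[float] = ALLELES,
) -> np.ndarray:
    """Each gene is independently redrawn uniformly from the allele set
    with probability ``rate`` (a redraw may return the same allele)."""
    if not 0.0 <= rate <= 1.0:
        raise ValueError("mutation rate must lie in [0, 1]")
    out = genes.copy()
    mask = rng.random(genes.size) < rate
    k = int(mask.sum())
    if k:
        out[mask] = rng.choice(np.asarray(alleles, dtype=float), size=k)
    return out


def allele_diversity(population: Sequence[np.ndarray]) -> float:
    """Mean per-locus fraction of distinct alleles present (1/9 when the
    population is a single point, up to 1 when every allele appears)."""
    arr = np.stack(population)
    counts = [len(np.unique(arr[:, g])) for g in range(arr.shape[1])]
    return float(np.mean(counts)) / len(ALLELES)


def run_ga(
    config: GAConfig,
    fitness_fn: Callable[[np.ndarray], float],
    n_genes: int,
    alleles: Sequence[float] = ALLELES,
    diversity_floor: float = 0.0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Evolve chromosomes to minimize ``fitness_fn``.

    Returns the minimal-fitness chromosome ever evaluated and a
    per-generation history (best/mean fitness, allele diversity).  The
    search stops at the generation cap, after ``stall_generations`` without
    improvement of the best fitness, or when allele diversity falls to
    ``diversity_floor``.
    """
    rng = np.random.default_rng(config.rng_seed)
    mut_rate = config.mutation_rate if config.mutation_rate is not None else 1.0 / n_genes
    alleles = tuple(alleles)
    pop = [random_chromosome(n_genes, rng, alleles) for _ in range(config.population_size)]
    best_genes: np.ndarray | None = None
    best_f = np.inf
    stall = 0
    history = []
    for gen in range(config.generations):
        fits = [fitness_fn(ind) for ind in pop]
        order = np.argsort(fits, kind="stable")
        gen_best = fits[order[0]]
        if gen_best < best_f:
            best_f = gen_best
            best_genes = pop[order[0]].copy()
            stall = 0
        else:
            stall += 1
        div = allele_diversity(pop)
        history.append(
            {"generation": gen, "best_F": best_f, "gen_best_F": gen_best,
             "mean_F": float(np.mean(fits)), "diversity": div}
        )
        if stall >= config.stall_generations or div <= diversity_floor:
            break
        next_pop = [pop[order[k]].copy() for k in range(config.elitism_count)]
        while len(next_pop) < config.population_size:
            p1 = tournament_select(pop, fits, rng)
            p2 = tournament_select(pop, fits, rng)
            c1, c2 = uniform_crossover(p1, p2, rng)
            next_pop.append(mutate(c1, mut_rate, rng, alleles))
            if len(next_pop) < config.population_size:
                next_pop.append(mutate(c2, mut_rate, rng, alleles))
        pop = next_pop
    assert best_genes is not None
    return best_genes, pd.DataFrame(history)


def optimize_intervention(
    snapshot,
    n_stages: int,
    config: GAConfig,
    spacing_steps: int = 100,
    duration_steps: int = 99,
    max_steps: int = DEFAULT_MAX_STEPS,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Convenience wrapper: evolve an n-stage schedule for a frozen patient.

    The snapshot must be non-absorbing; fitness is
    :func:`evaluate_fitness` on copies of it.
    """

    def fitness(genes: np.ndarray) -> float:
        return evaluate_fitness(
            genes, snapshot, config, spacing_steps, duration_steps, max_steps
        ).F

    return run_ga(config, fitness, n_genes=n_stages * N_MEDIATORS)
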