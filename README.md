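# iirabm

An agent-based model of the innate immune response to traumatic injury and
infection, with a genetic-algorithm (GA) search for multi-stage cytokine
control strategies — an in-silico testbed for the question *can a septic
inflammatory trajectory be steered back to health, and how much
intervention does that take?*

The model is aimed at computational/systems biologists studying sepsis
dynamics and control: it reproduces, at desk scale, the qualitative
clinical structure of systemic inflammation — complete healing, death by
infection, death from immune dysregulation, and a *stochastic zone* in
which a patient's fate is genuinely undecided — and provides the machinery
for in-silico trials: population-level and patient-specific mortality
estimation, GA optimization of intervention schedules, and adaptive
re-optimization for treatment non-responders.

## The model in brief

The endothelial–blood interface is a 2-D torus of endothelial locations.
A circular injury seeds damage and microbial infection.  Twelve mediators
(PAF, TNF, sTNFr, IL-1, sIL1r, IL1ra, IFN-γ, IL-4, IL-8, IL-10, IL-12,
G-CSF) evolve per location `n` by

    c_{i,n}(t+1) = f_EC + Σ_A p_{n,A} f_A + D_i (⟨c_i⟩_8 − c_{i,n}) − λ_i c_{i,n}

(endothelial production, summed contributions of mobile immune cells of
type `A` with local census `p_{n,A}`, Moore-neighbourhood diffusion with
constant `D_i`, first-order degradation `λ_i`).  Macrophages, neutrophils
and TH0/TH1/TH2 cells move by chemotaxis-biased random walk, activate,
differentiate and kill microbes; randomness enters through movement,
activation, differentiation and burst recruitment draws from a single
seedable RNG.  One step is 7.2 min (100 steps = 12 h); the system dies
when aggregate endothelial damage exceeds 80%, heals when damage and
infection reach zero.

An intervention stage multiplies (inhibition, `T ≤ 1`) or shifts
(augmentation, `T > 1`, applied as `+ (T − 1)`) the local update of each
mediator, with `T` drawn from {0.05, 0.25, 0.5, 0.75, 1, 2, 5, 10, 20}.
The GA evolves flat `1×12n` chromosomes of such multipliers over `n`
sequential stages, minimizing `F = Σ_replicates (OD + X)` — oxygen deficit
plus infectious load over 10 RNG-reseeded replicates of a frozen patient —
with size-2 tournaments, uniform crossover, per-gene mutation and one
elite.  See `docs/methods.md` for the full rule set, the calibration
procedure and known limitations.

## Worked example

```python
import iirabm as m

# one untreated trajectory of the reference injury on the 25x25 profile
traj = m.run_simulation(m.SMALL_REFERENCE_PARAMS, seed=1,
                        constants=m.SMALL_CONSTANTS, max_steps=4000)
print(traj.final_status)                       # dead_infection
print(traj.observations[-1].t)                 # 416  (~2.1 simulated days)

# population mortality of this parameter set, 100 independent seeds
est = m.estimate_mortality_general(m.SMALL_REFERENCE_PARAMS, n_seeds=100,
                                   constants=m.SMALL_CONSTANTS,
                                   max_steps=4000)
print(est)   # 80/100 deaths (80.0%, 95% CI [71.1%, 86.7%])

# the same patient frozen 12 h post-injury: individual risk via reseeding
snap = m.snapshot_at(m.SMALL_REFERENCE_PARAMS, seed=7, at_step=100,
                     constants=m.SMALL_CONSTANTS)
est = m.estimate_mortality_patient(snap, n_reseeds=100, max_steps=4000)
print(est)   # 68/100 deaths (68.0%, 95% CI [58.3%, 76.3%])
```

The first number is the *general* mortality of the injury type (each seed
is a different patient); the second is the *patient-specific* mortality —
the outcome distribution of one trajectory whose RNG is reseeded at the
12-hour mark, i.e. the risk of this particular patient at this particular
moment.  A GA-optimized single-stage intervention on this patient
(`m.optimize_intervention(snap, 1, m.GAConfig(population_size=20,
generations=6, replicates=10, rng_seed=5))`) drops the held-out reseed
mortality from 64% to 0% in the run shown in the acceptance script.

## Command line

```
iirabm simulate  --config cfg.yml --seed 1 --out traj.csv
iirabm mortality --config cfg.yml --n-seeds 100 --out mort.csv
iirabm mortality --config cfg.yml --patient --out mort.csv
iirabm ga        --config cfg.yml --n-stages 2 --out best.json
iirabm evaluate  --config cfg.yml --intervention best.json --out eval.csv
iirabm adapt     --config cfg.yml --intervention best.json --out tail.json
iirabm sweep     --config cfg.yml --radii 4,6,8 --out sweep.csv
```

A minimal config:

```yaml
model:
  profile: small          # 25x25 calibrated profile (default: 101x101)
run:
  params: {injury_radius: 8}
  seed: 7
```

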