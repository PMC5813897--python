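# Methods

## Overview

`iirabm` is an agent-based model (ABM) of the innate immune response at the
endothelial-blood interface, coupled to a genetic-algorithm (GA) search for
multi-stage cytokine control strategies.  The simulated tissue is the
unwrapped internal vascular surface of an injured region, represented as a
two-dimensional torus of endothelial locations; spatial scale is abstract
and not mapped to anatomy.  A circular traumatic injury seeds endothelial
damage and a microbial infection; the subsequent contest between microbial
expansion, the innate immune response and tissue repair decides whether the
in-silico patient heals completely or dies of accumulated damage.

One time step represents 7.2 minutes of simulated time (100 steps = 12
hours); a run is capped at 18,000 steps (90 days of simulated intensive
care).  The system **dies** when aggregate endothelial damage exceeds 80% of
its maximum — a threshold read as the limit of modern organ-support
technology — and **heals** when damage and infection both reach zero.  Death
is sub-classified at the moment of crossing: if the remaining infectious
load exceeds 25% of the run's historical maximum the death is recorded as
`dead_infection`, otherwise as `dead_sepsis` (death from inflammation after
the infection itself was largely controlled).

## State and observables

Per location `n` the model tracks endothelial damage in [0, 1], microbial
load in [0, `infection_cap`], and the concentrations `c_{i,n}` of twelve
mediators: PAF, TNF, sTNFr, IL-1, sIL1r, IL1ra, IFN-g, IL-4, IL-8, IL-10,
IL-12 and G-CSF (this ordering is canonical throughout; intervention
vectors and GA chromosomes index mediators in it).  Mobile immune agents —
macrophages, neutrophils and TH0/TH1/TH2 lymphocytes with type-specific
lifespans — live on the grid and are backed by finite, slowly replenishing
precursor pools.

The observable state at step `t` is the aggregate mediator vector
`C_i(t) = sum_n c_{i,n}(t)`, the **oxygen deficit** `OD = sum_n damage_n`
(an inverse health measure: each fully damaged location contributes one
unit of oxygen shortfall; the 80% death test is the same field expressed as
a mean), the **infectious load** `X = sum_n load_n`, and per-type immune
cell counts.  The damage aggregate and the oxygen deficit are deliberately
one field viewed on two scales.

## The per-step update

Each step applies, in order:

1. **Mobile agents**, in a freshly shuffled order (the shuffle permutes the
   assignment of random draws to agents, emulating concurrency without
   fixed-order artifacts): sensing, probabilistic activation,
   TH0→TH1/TH2 differentiation with probabilities proportional to local
   IL-12 and IL-4, cytokine secretion, phagocytosis, chemotaxis-biased
   random walk, aging/death, and Poisson recruitment from the pools.
2. **Infection**: logistic local growth scaled by microbial invasiveness,
   with a low-density (Allee) factor that makes sparse colonies fragile;
   stochastic colonization of sterile Moore neighbours by established
   colonies; unassisted decay; stochastic extinction of weak colonies;
   and a systemic-clearance term (below).  Infection damages local tissue
   in proportion to microbial toxigenesis.
3. **Damage and repair**: TNF-mediated cytotoxicity above a threshold of
   effective TNF (TNF discounted by soluble TNF receptor), exogenous
   stress proportional to environmental toxicity at compromised sites, and
   healing at a rate proportional to host resilience, damped by local
   infection and effective TNF.
4. **Transport**: every mediator field is updated as
   `c <- c + D_i (mean8(c) - c) - lam_i c`, where `mean8` is the toroidal
   Moore 8-neighbourhood mean.  `D_i + lam_i <= 1` is enforced at
   configuration time, which guarantees non-negativity; with `lam_i = 0`
   the stencil conserves mass exactly.
5. **Treated update** (only while an intervention stage is active): the
   freshly computed concentration of mediator `i` at every location is
   transformed as `F * T_i` when `T_i <= 1` (multiplicative inhibition) and
   `F + (T_i - 1)` when `T_i > 1` (additive augmentation), clipped at zero.
   Additive augmentation avoids the exponential blow-up a multiplicative
   boost would cause when applied every step.  Because the transform acts
   on the whole local update (production, diffusion and decay combined),
   mass conservation intentionally does not hold during active inhibition
   or augmentation stages.

Randomness enters only through the world's single seedable generator
(numpy PCG64): movement, activation, differentiation, colonization,
extinction and recruitment draws.  Identical (parameters, seed, schedule)
yield bitwise-identical trajectories; `reseed()` replaces the generator in
place, which is the primitive behind stochastic replicates of a frozen
patient.

## Rule constants and calibration

The update rules require numeric coefficients (production rates,
activation thresholds, kill rates, lifespans, recruitment and healing
rates) that are modelling choices of this package; they live in one
documented table (`iirabm.params.RuleConstants`).  Several mechanisms were
introduced specifically to obtain the clinically meaningful outcome
structure — a genuine bistability between healing and death with a
stochastic zone between them — rather than the stable interior equilibria
(chronic smouldering states) that naive parameterizations produce:

- **Allee growth factor and weak-colony extinction**: sparse colonies grow
  slowly and can be wiped out by a phagocyte visit or humoral clearance,
  so near-clearance tips into true clearance instead of low-level
  persistence.
- **Systemic clearance threshold** (`sterilize_threshold`): once total
  burden falls below a small fraction of grid capacity, an additional
  global clearance rate drives the infection to sterility, ending the
  metapopulation dynamics of re-seeding colonies.
- **Burst (batch) neutrophil recruitment**: neutrophils arrive in bursts
  of ~25 cells (emergency granulopoiesis), making the timing of early
  reinforcement a dominant, genuinely random determinant of containment.
- **Pathogen-gated M1 activation**: macrophages fully activate only where
  microbes are present (PAMP signalling plus PAF); sterile damage recruits
  but does not M1-activate.  Likewise the neutrophil oxidative burst fires
  only against microbes.  Both choices let inflammation quench after
  sterilization so survivors heal to zero rather than smouldering.
- **Quadratic alarm signalling**: endothelial PAF/IL-8 release scales with
  damage squared, so heavily injured tissue recruits strongly while
  moderate residual damage resolves.

Calibration followed the documented coarse-search procedure: with all
other constants fixed, the microbial growth rate and colonization
probability were scanned until the reference parameter set — invasiveness
2, toxigenesis 5, host resilience 0.1, environmental toxicity 2, injury
radius 33 on the default grid (radius 8 on the small profile, preserving
the injured-area fraction) — produced approximately 80% mortality over a
100-seed ensemble, and the systemic-clearance threshold was placed at the
corresponding percentile of the per-seed minimum-burden distribution.  The
shipped constants give 80-82 deaths per 100 seeds on the small profile
(the exact count depends on the step cap, since a few slow trajectories
resolve late).  The reference
in-silico patient (`SMALL_REFERENCE_PATIENT_SEED = 7`) was then chosen as
a trajectory whose individual risk at the 12-hour snapshot lies squarely
inside the stochastic zone (68/100 reseeds die untreated).

Under these constants a typical lethal run resolves in 400–1,000 steps and
a healing run in 1,000–1,700, so ensembles of hundreds of runs are
desk-scale; the 18,000-step cap is a safety net, not the typical duration.
Deaths at the reference parameterization are recorded overwhelmingly as
`dead_infection` (damage crosses 80% while the burden is still high);
parameterizations with higher resilience or lower toxigenesis produce
`dead_sepsis` crossings.  The death-type threshold (25% of historical
maximum burden) is a reporting convention, not a dynamical switch.

## Grid profiles

Two constant profiles are shipped.  `default` is the full-scale 101x101
torus (odd extent so the radius-33 injury centres cleanly).  `small` is a
25x25 torus with identical per-site dynamics; only extensive quantities
(precursor pool sizes, per-step recruitment rates and pool replenishment)
are scaled by the grid-area ratio.  The small profile is the calibrated,
tested configuration used by the test-suite and the acceptance script;
experiments on the default grid should re-verify mortality before relying
on exact rates, since containment geometry does not scale perfectly with
area.

## Interventions and the GA

An intervention stage is a 12-vector of multipliers from the allele set
{0.05, 0.25, 0.5, 0.75, 1, 2, 5, 10, 20}; a schedule is an ordered list of
stages with a start step (default 100 = 12 h post-injury), an inter-stage
spacing (default 100 steps) and a per-stage duration (25, 50 or 99 steps
in the standard experiments).  Outside active stages — before the start,
in gaps, and after the final stage (no wash-out; pharmacokinetics are out
of scope) — the multipliers are identically 1, and a schedule of all-ones
stages reproduces the untreated trajectory exactly at every seed.  A
duration-99 stage with spacing 100 leaves a literal 1-step gap between
stages; this is preserved as specified rather than smoothed over.

The GA evolves flat `1 x 12n` chromosomes (n = number of stages).
Fitness of a chromosome on a frozen patient snapshot is
`F = sum_i (OD_i + X_i)` over 10 stochastic replicates, each produced by
copying the snapshot, reseeding its RNG with a seed derived
deterministically from the GA seed (`SeedSequence([ga_seed, i])`, reduced
below 2^31), and reading OD and X 100 steps (12 h) after the final stage
begins.  A replicate that dies earlier contributes its terminal (maximal)
OD and terminal X — death is penalized through the readouts, without a
separate term; one that heals earlier contributes zeros.  The evaluation
anchor "100 steps after the final stage starts" coincides to within one
step with "12 h after the application" for the longest (99-step) stages.

Selection is by tournaments of size 2 (ties uniform), breeding by uniform
crossover producing two complementary children, mutation by per-gene
uniform redraw at rate 1/L (L = chromosome length), plus one elite carried
unchanged per generation — elitism makes the best-so-far fitness
non-increasing and is the only departure from a textbook generational GA;
it can be disabled.  Convergence is declared when the best fitness has not
improved for `stall_generations` (default 25) or when the population's
allele diversity collapses.  No claim of global optimality is made or
needed: the search space is astronomically large (9^12 per stage) and the
product is a good-enough local optimum.

## Outcome estimation

- **General mortality** of a parameter set: the death fraction over an
  ensemble of fully independent runs with seeds `base, base+1, ...`; the
  exact ratio `deaths/n` with a Wilson 95% interval (Wilson is used
  because its coverage stays near nominal across the p range, which the
  test-suite checks empirically).
- **Patient-specific mortality**: the death fraction over RNG reseedings
  of one frozen trajectory at one time point.  It is a time-indexed
  quantity — the same patient's risk evolves as their state evolves — and
  is the GA's training signal denominator.
- **Responder reference**: pointwise mean/SD envelope of selected
  observables (default: oxygen deficit, neutrophil count, total G-CSF)
  over trajectories that healed under a given intervention, defined on the
  common support (the shortest trajectory).
- **Non-responder detection**: a trajectory is flagged at the first step
  at which any monitored observable has been outside mean ± z·SD (default
  z = 3) for a persistence window (default 10 consecutive steps).  The
  observables, z and window are parameters, not canonical values.
- **Adaptive re-optimization**: at the flagged step the simulation is
  frozen and the GA is re-trained on the deviant snapshot over only the
  remaining stages (the administered head is baked into the state),
  yielding a replacement tail.

## Numerical and degenerate-input choices

- Concentrations are clipped at zero after the treated transform and after
  transport (round-off guard; the untreated update is non-negative by
  construction).
- Microbial loads below 10^-3 per site are set to zero.
- A world whose stored status is absorbing refuses to step (warning,
  no-op).  Stored status is evaluated at the end of each step; a freshly
  initialized world is `alive` until first stepped, so a radius-0 injury
  heals at step 1, not step 0.
- An injury radius exceeding half the smaller grid dimension is rejected
  at construction with an explicit message.
- Tournament ties break uniformly; argsort ties in elitism are stable.

## Limitations

- The rule constants are calibrated on the small profile at the reference
  parameter set only; the 8291-parameter-set generalizability census of
  cluster-scale work is replaced by a coarse desk-scale sweep
  (`parameter_sweep`, configurable grid).
- Mediator identities shape which interventions help (e.g. TNF/PAF/IL-1
  inhibition improves survival by releasing the healing brake; TNF
  augmentation is reliably harmful), but no pharmacological realism is
  claimed: multipliers are abstract synthesis modifiers, not drugs.
- The synthetic dynamics reproduce the qualitative clinical structure
  (three outcomes, a stochastic zone, non-responders under a fixed
  protocol) — passing tests demonstrate control of this surrogate, not of
  clinical sepsis.
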