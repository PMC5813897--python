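"""Injury/host parameterization and the rule-constant table.

A simulated patient is characterized by five parameters: the initial
injury radius (grid cells), microbial invasiveness (spread/growth rate of
the infecting organism), microbial toxigenesis (tissue damage per unit
microbial load), environmental toxicity (exogenous stress on compromised
tissue) and host resilience (healing propensity).  The reference
parameterization used throughout the package is invasiveness 2,
toxigenesis 5, host resilience 0.1, environmental toxicity 2 and an
injury radius of 33 cells on the default 101x101 torus.

The behavioural rules (production, activation, killing, recruitment,
healing) carry coefficients that are not fixed by the model's published
description; they are collected here in :class:`RuleConstants` as a single
documented default set, calibrated so that the reference parameterization
produces roughly 80% mortality (see docs/methods.md).  A ``small`` profile
provides the same dynamics on a 25x25 torus for desk-scale experiments.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass


@dataclass(frozen=True)
class ModelParams:
    """The five-parameter injury/host configuration."""

    invasiveness: float = 2.0
    toxigenesis: float = 5.0
    host_resilience: float = 0.1
    environmental_toxicity: float = 2.0
    injury_radius: int = 33

    def __post_init__(self) -> None:
        for name in ("invasiveness", "toxigenesis", "environmental_toxicity"):
            v = getattr(self, name)
            if v < 0:
                raise ValueError(f"{name} must be non-negative, got {v}")
        if not 0.0 <= self.host_resilience <= 1.0:
            raise ValueError(
                f"host_resilience must lie in [0, 1], got {self.host_resilience}"
            )
        if int(self.injury_radius) != self.injury_radius or self.injury_radius < 0:
            raise ValueError(
                f"injury_radius must be a non-negative integer, got {self.injury_radius}"
            )

    def validate_for_grid(self, grid_shape: tuple[int, int]) -> None:
        """Reject injury radii that do not fit on the torus."""
        limit = min(grid_shape) // 2
        if self.injury_radius > limit:
            raise ValueError(
                f"injury_radius {self.injury_radius} exceeds half the smaller grid "
                f"dimension ({limit}) for grid {grid_shape}"
            )


# Reference parameter set: a severe, stochastically lethal contaminated injury.
REFERENCE_PARAMS = ModelParams(
    invasiveness=2.0,
    toxigenesis=5.0,
    host_resilience=0.1,
    environmental_toxicity=2.0,
    injury_radius=33,
)


@dataclass(frozen=True)
class RuleConstants:
    """Coefficients of the behavioural rule set.

    All rates are per 7.2-minute time step.  Damage is tracked per
    endothelial location on a [0, 1] scale; microbial load per location is
    capped at ``infection_cap``.
    """

    grid_shape: tuple[int, int] = (101, 101)

    # --- initial condition -------------------------------------------------
    init_damage: float = 0.75          # damage of each location inside the injury
    init_infection: float = 50.0       # microbial load seeded inside the injury
    init_macrophages_per_1k: float = 30.0   # resting macrophages per 1000 locations
    init_neutrophils_per_1k: float = 10.0
    init_th0_per_1k: float = 10.0

    # --- infection ---------------------------------------------------------
    infection_growth: float = 0.254    # logistic growth rate, scaled by invasiveness
    infection_spread: float = 0.02     # per-neighbour colonization prob, x invasiveness
    colonize_threshold: float = 20.0   # load needed before a colony can seed neighbours
    colonize_seed: float = 1.0         # load planted in a newly colonized location
    infection_cap: float = 100.0       # per-location carrying capacity
    infection_decay: float = 0.005     # unassisted clearance fraction per step
    growth_allee: float = 2.0          # load at which growth reaches half speed
    extinction_threshold: float = 5.0  # colonies below this load may die out
    extinction_prob: float = 0.05      # per-step extinction chance of weak colonies
    sterilize_threshold: float = 0.0137  # X below this fraction of grid capacity
    sterilize_rate: float = 0.30       # extra global clearance below the threshold
    toxin_damage: float = 6.0e-4       # damage per step per (load/cap), x toxigenesis

    # --- inflammation-mediated damage (the sepsis loop) --------------------
    cyto_damage: float = 4.0e-3        # damage per unit of excess effective TNF
    tnf_damage_threshold: float = 0.5  # local effective TNF below this is harmless
    neut_damage: float = 4.0e-3        # collateral damage per activated neutrophil
    il10_protection: float = 0.5       # IL-10 damping of neutrophil collateral damage
    stnfr_neutralization: float = 0.4  # sTNFr damping of effective TNF
    sil1r_neutralization: float = 0.3  # sIL1r + IL1ra damping of effective IL-1

    # --- healing and exogenous stress ---------------------------------------
    heal_rate: float = 0.07            # x host_resilience, damped by local threat
    heal_block_infection: float = 0.25 # infection load weight in the healing damper
    heal_block_tnf: float = 1.0        # effective-TNF weight in the healing damper
    env_stress: float = 2.0e-3         # x environmental_toxicity at compromised sites

    # --- endothelial cytokine release ---------------------------------------
    ec_paf_release: float = 0.30       # PAF per unit local damage
    ec_il8_release: float = 0.22       # IL-8 per unit local damage
    ec_il8_infection: float = 0.5      # IL-8 per unit local (load/cap): tracks the front
    ec_stnfr_shed: float = 0.030       # sTNFr shed per unit local TNF
    ec_sil1r_shed: float = 0.025       # sIL1r shed per unit local IL-1
    ec_il1ra_shed: float = 0.020       # IL1ra shed per unit local IL-1

    # --- immune-cell activation ---------------------------------------------
    mac_activation_threshold: float = 0.8   # PAF + pathogen-signal trigger
    pamp_signal: float = 1.2                # microbial-presence activation signal
    neut_activation_threshold: float = 0.4  # IL-8 + PAF trigger
    activation_steepness: float = 1.2       # probability ramp above threshold
    deactivation_prob: float = 0.05         # chance per step to return to rest
    il10_activation_damping: float = 1.0    # IL-10 raises activation thresholds

    # --- per-cell cytokine production (active cells) -------------------------
    mac_tnf: float = 0.55
    mac_il1: float = 0.45
    mac_il8: float = 0.30
    mac_il12: float = 0.12
    mac_il10: float = 0.10
    mac_gcsf: float = 0.20
    neut_tnf: float = 0.08
    th1_ifng: float = 0.30
    th2_il4: float = 0.25
    th2_il10: float = 0.30
    il10_production_damping: float = 0.8  # IL-10 autoinhibition of M1 output

    # --- killing ------------------------------------------------------------
    mac_kill: float = 10.0              # microbial load removed per active macrophage
    neut_kill: float = 30.0             # per active neutrophil
    kill_spillover: float = 0.5        # killing capacity spent on the Moore ring
    resting_kill_fraction: float = 0.30  # constitutive macrophage phagocytosis
    ifng_kill_boost: float = 0.4       # IFN-gamma multiplier on phagocytosis

    # --- differentiation ----------------------------------------------------
    th1_diff: float = 0.03             # x local IL-12, per TH0 per step
    th2_diff: float = 0.03             # x local IL-4

    # --- movement -----------------------------------------------------------
    chemotaxis_prob: float = 0.8       # chance of following the gradient when present
    chemokine_sense_threshold: float = 0.05

    # --- lifespans (steps) ---------------------------------------------------
    mac_lifespan: int = 1200
    neut_lifespan: int = 160
    th_lifespan: int = 600
    gcsf_life_extension: float = 0.05  # fractional neutrophil lifespan gain per GCSF

    # --- recruitment ---------------------------------------------------------
    neut_recruit: float = 40.0         # baseline Poisson rate x inflammation signal
    mac_recruit: float = 9.8
    th0_recruit: float = 3.3
    gcsf_recruit_boost: float = 0.5    # GCSF amplification of neutrophil recruitment
    recruit_batch: float = 25.0        # neutrophils arriving per recruitment burst
    recruit_signal_scale: float = 1.0  # converts mean TNF+IL8 into recruitment drive
    pool_neut: int = 8150              # marrow/circulating precursor pools
    pool_mac: int = 2040
    pool_th0: int = 1470
    pool_replenish: float = 4.9        # precursors regenerated per step per pool

    # --- outcome classification ----------------------------------------------
    death_threshold: float = 0.8       # mean damage fraction at which the system dies
    infection_death_fraction: float = 0.25  # X/X_max above this at death => infection

    def replace(self, **kw) -> "RuleConstants":
        return dataclasses.replace(self, **kw)


#: Constants for the full-scale 101x101 torus (radius-33 reference injury).
DEFAULT_CONSTANTS = RuleConstants()

#: Desk-scale profile: identical dynamics on a 25x25 torus.  The reference
#: injury scales to radius 8 (same injured-area fraction as 33/101); precursor
#: pools scale with grid area.
SMALL_CONSTANTS = RuleConstants(
    grid_shape=(25, 25),
    pool_neut=250,
    pool_mac=125,
    pool_th0=90,
    pool_replenish=0.3,
)

#: Reference injury radius for the small profile, preserving the injured-area
#: fraction of the full-scale radius-33 injury.
SMALL_REFERENCE_PARAMS = dataclasses.replace(REFERENCE_PARAMS, injury_radius=8)

#: The reference in-silico patient of the small profile: the trajectory begun
#: with this seed sits squarely in the stochastic zone 12 h post-injury
#: (individual risk of death well away from both 0 and 1), and is the
#: default subject for patient-specific mortality and GA training.
SMALL_REFERENCE_PATIENT_SEED = 7

PROFILES: dict[str, RuleConstants] = {
    "default": DEFAULT_CONSTANTS,
    "small": SMALL_CONSTANTS,
}
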