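"""Core agent-based model of the innate immune response at the
endothelial-blood interface.

The simulated tissue is a toroidal grid of endothelial locations.  A
circular traumatic injury seeds tissue damage and a microbial infection at
the centre of the grid.  Mobile immune agents (macrophages, neutrophils and
TH0/TH1/TH2 lymphocytes, backed by finite precursor pools) move over the
grid, sense local cytokine concentrations, activate, differentiate, kill
microbes and secrete mediators.  Twelve cytokine/mediator fields diffuse
over the Moore 8-neighbourhood and decay first-order each step.

One time step represents 7.2 minutes (100 steps = 12 hours); a full run is
capped at 18,000 steps (90 simulated days).  The system dies when aggregate
endothelial damage exceeds 80% of its maximum, heals when damage and
infection both reach zero, and otherwise keeps evolving.  Randomness enters
through immune-cell movement (a chemotaxis-biased random walk),
probabilistic activation and differentiation, and Poisson recruitment from
the precursor pools; agent order is freshly shuffled every step so that
random-draw assignment carries no fixed-order artifact.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mediators import (
    DEFAULT_MEDIATOR_SPECS,
    GCSF,
    IFNG,
    IL1,
    IL1RA,
    IL4,
    IL8,
    IL10,
    IL12,
    MEDIATORS,
    MediatorSpec,
    N_MEDIATORS,
    PAF,
    SIL1R,
    STNFR,
    TNF,
    spec_arrays,
)
from .params import DEFAULT_CONSTANTS, ModelParams, RuleConstants

STEP_MINUTES = 7.2
STEPS_PER_12H = 100
DEFAULT_MAX_STEPS = 18_000  # 90 days

# agent type codes
MACROPHAGE, NEUTROPHIL, TH0, TH1, TH2 = range(5)
CELL_TYPE_NAMES = ("macrophage", "neutrophil", "TH0", "TH1", "TH2")

ALIVE = "alive"
HEALED = "healed"
DEAD_INFECTION = "dead_infection"
DEAD_SEPSIS = "dead_sepsis"
ABSORBING = (HEALED, DEAD_INFECTION, DEAD_SEPSIS)

# Moore 8-neighbourhood offsets (row, col)
_MOORE = tuple(
    (dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)
)


def moore_mean(a: np.ndarray) -> np.ndarray:
    """Toroidal mean over the Moore 8-neighbourhood of the last two axes."""
    out = np.zeros_like(a)
    for dr, dc in _MOORE:
        out += np.roll(np.roll(a, dr, axis=-2), dc, axis=-1)
    out /= 8.0
    return out


def diffuse_and_decay(
    concentrations: np.ndarray,
    specs: list[MediatorSpec] | tuple[MediatorSpec, ...] = DEFAULT_MEDIATOR_SPECS,
) -> np.ndarray:
    """One diffusion + degradation update of the mediator fields.

    For each mediator ``i`` with diffusion constant ``D_i`` and degradation
    constant ``lam_i`` the update is::

        c_new = c + D_i * (moore_mean(c) - c) - lam_i * c

    on the torus.  With ``D_i + lam_i <= 1`` (enforced at spec construction)
    non-negativity is preserved, and with ``lam_i = 0`` total mass is
    conserved exactly, since the Moore mean redistributes without loss.

    Parameters
    ----------
    concentrations
        Array of shape ``(12, H, W)`` (or ``(H, W)`` for a single field with
        a single spec in ``specs``).
    specs
        Mediator transport constants, one per field.
    """
    c = np.asarray(concentrations, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentration field contains negative values")
    if c.ndim == 2:
        if len(specs) != 1:
            raise ValueError("2-D field requires exactly one MediatorSpec")
        d = np.array([specs[0].diffusion_constant])
        lam = np.array([specs[0].degradation_constant])
        c = c[None]
        squeeze = True
    else:
        d, lam = spec_arrays(list(specs))
        squeeze = False
    new = c + d[:, None, None] * (moore_mean(c) - c) - lam[:, None, None] * c
    np.maximum(new, 0.0, out=new)  # guard round-off only; the update is stable
    return new[0] if squeeze else new


@dataclass
class Observation:
    """Aggregate view of one world state at one step."""

    t: int
    C: np.ndarray               # total of each mediator over the grid, order MEDIATORS
    oxygen_deficit: float       # sum of per-location oxygen shortfall (== damage)
    infectious_load: float      # total microbial burden X
    cell_counts: dict[str, int]
    status: str


class WorldState:
    """Full mutable simulation state.

    Attributes
    ----------
    conc : ndarray (12, H, W)
        Per-location mediator concentrations.
    damage : ndarray (H, W)
        Endothelial damage per location in [0, 1]; the oxygen deficit is the
        sum of this field and death occurs when its mean exceeds the 80%
        threshold.
    infection : ndarray (H, W)
        Microbial load per location, capped at ``constants.infection_cap``.
    cell_type, row, col, age, active : ndarrays (n_agents,)
        Struct-of-arrays representation of the mobile immune agents.
    pools : dict
        Remaining precursor counts per recruitable lineage.
    rng : numpy.random.Generator
        The single seedable source of randomness; :meth:`reseed` replaces it
        in place (used by the patient-specific replicate protocol).
    """

    def __init__(
        self,
        params: ModelParams,
        constants: RuleConstants,
        specs: tuple[MediatorSpec, ...],
        seed: int,
    ):
        params.validate_for_grid(constants.grid_shape)
        self.params = params
        self.constants = constants
        self.specs = tuple(specs)
        self._d, self._lam = spec_arrays(list(specs))
        h, w = constants.grid_shape
        self.conc = np.zeros((N_MEDIATORS, h, w))
        self.damage = np.zeros((h, w))
        self.infection = np.zeros((h, w))
        self.t = 0
        self.status = ALIVE
        self.max_infection_seen = 0.0
        self.rng = np.random.default_rng(seed)
        self.seed = seed

        # injury: circular damaged + infected patch at the grid centre
        r0 = params.injury_radius
        cy, cx = h // 2, w // 2
        yy, xx = np.ogrid[:h, :w]
        disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= r0**2
        if r0 > 0:
            self.damage[disk] = constants.init_damage
            self.infection[disk] = constants.init_infection
            self.max_infection_seen = float(self.infection.sum())

        # resting tissue-resident immune cells, uniformly placed
        n_sites = h * w
        counts = {
            MACROPHAGE: int(round(constants.init_macrophages_per_1k * n_sites / 1000)),
            NEUTROPHIL: int(round(constants.init_neutrophils_per_1k * n_sites / 1000)),
            TH0: int(round(constants.init_th0_per_1k * n_sites / 1000)),
        }
        types, rows, cols = [], [], []
        for ct, n in counts.items():
            types.append(np.full(n, ct, dtype=np.int8))
            rows.append(self.rng.integers(0, h, n))
            cols.append(self.rng.integers(0, w, n))
        self.cell_type = np.concatenate(types).astype(np.int8)
        self.row = np.concatenate(rows).astype(np.int64)
        self.col = np.concatenate(cols).astype(np.int64)
        n_agents = self.cell_type.size
        self.age = np.zeros(n_agents, dtype=np.int64)
        self.active = np.zeros(n_agents, dtype=bool)

        self.pools = {
            "neutrophil": float(constants.pool_neut),
            "macrophage": float(constants.pool_mac),
            "th0": float(constants.pool_th0),
        }

    # ------------------------------------------------------------------ util
    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.constants.grid_shape

    @property
    def n_locations(self) -> int:
        h, w = self.grid_shape
        return h * w

    def copy(self) -> "WorldState":
        """Deep, replay-exact copy (including the RNG state)."""
        return copy.deepcopy(self)

    def reseed(self, seed: int) -> None:
        """Replace the RNG state in place with a fresh generator.

        This is the primitive behind stochastic replicates of a frozen
        patient: the world state is untouched, only its future random draws
        change.
        """
        self.rng = np.random.default_rng(seed)

    def damage_fraction(self) -> float:
        return float(self.damage.mean())

    def cell_counts(self) -> dict[str, int]:
        out = {}
        for code, name in enumerate(CELL_TYPE_NAMES):
            out[name] = int(np.count_nonzero(self.cell_type == code))
        return out

    # ------------------------------------------------------------- dynamics
    def _local(self, mediator: int) -> np.ndarray:
        """Per-agent local concentration of one mediator."""
        return self.conc[mediator, self.row, self.col]

    def _deposit(self, mediator: int, mask: np.ndarray, amount) -> None:
        if not np.any(mask):
            return
        np.add.at(self.conc[mediator], (self.row[mask], self.col[mask]), amount)

    def _effective_tnf(self) -> np.ndarray:
        k = self.constants.stnfr_neutralization
        return self.conc[TNF] / (1.0 + k * self.conc[STNFR])


def init_world(
    params: ModelParams,
    seed: int,
    constants: RuleConstants = DEFAULT_CONSTANTS,
    specs: tuple[MediatorSpec, ...] = DEFAULT_MEDIATOR_SPECS,
) -> WorldState:
    """Create a fresh world: healthy torus plus the configured injury.

    Identical ``(params, constants, specs, seed)`` always produce
    bitwise-identical worlds.
    """
    return WorldState(params, constants, specs, seed)


def observe(world: WorldState) -> Observation:
    """Aggregate the world into the observable state vector.

    ``C_i`` is the exact sum of mediator ``i`` over all locations; the
    oxygen deficit is the summed per-location damage (each fully damaged
    location contributes a shortfall of 1); ``status`` is derived from the
    death/heal criteria on the current fields.
    """
    C = world.conc.sum(axis=(1, 2))
    od = float(world.damage.sum())
    x = float(world.infection.sum())
    status = world.status
    if status == ALIVE:
        status = _classify(world)
    return Observation(
        t=world.t,
        C=C,
        oxygen_deficit=od,
        infectious_load=x,
        cell_counts=world.cell_counts(),
        status=status,
    )


def _classify(world: WorldState) -> str:
    c = world.constants
    if world.damage.mean() > c.death_threshold:
        x = world.infection.sum()
        if world.max_infection_seen > 0 and (
            x > c.infection_death_fraction * world.max_infection_seen
        ):
            return DEAD_INFECTION
        return DEAD_SEPSIS
    if world.damage.sum() <= 0.0 and world.infection.sum() <= 0.0:
        return HEALED
    return ALIVE


def step(world: WorldState, multipliers: np.ndarray | None = None) -> WorldState:
    """Advance the world by one 7.2-minute step (in place).

    The update order is: mobile agents act in a freshly shuffled order
    (sense, activate, differentiate, secrete, kill, move), then aging/death
    and recruitment; infection grows, spreads and poisons tissue; healing
    and environmental stress are applied; mediator fields diffuse and
    decay; finally, if an intervention multiplier vector is supplied, the
    treated update transform is applied to the new fields.

    Stepping an absorbing (healed/dead) world warns and is a no-op.
    """
    if world.status in ABSORBING:
        warnings.warn(
            f"step() called on absorbing world (status={world.status}); ignored",
            stacklevel=2,
        )
        return world

    c = world.constants
    p = world.params
    rng = world.rng
    h, w = world.grid_shape

    # ---- (1) mobile agents, freshly shuffled -----------------------------
    n = world.cell_type.size
    if n:
        perm = rng.permutation(n)
        world.cell_type = world.cell_type[perm]
        world.row = world.row[perm]
        world.col = world.col[perm]
        world.age = world.age[perm]
        world.active = world.active[perm]

        loc_paf = world._local(PAF)
        loc_il8 = world._local(IL8)
        loc_il10 = world._local(IL10)
        loc_il12 = world._local(IL12)
        loc_il4 = world._local(IL4)
        loc_ifng = world._local(IFNG)
        loc_gcsf = world._local(GCSF)

        is_mac = world.cell_type == MACROPHAGE
        is_neut = world.cell_type == NEUTROPHIL
        is_th0 = world.cell_type == TH0

        # activation: probability ramps with signal above an IL-10-raised
        # threshold; resting is re-entered slowly at random.  Full (M1)
        # macrophage activation needs a pathogen-associated signal at the
        # site -- sterile damage recruits but does not M1-activate, so
        # inflammation quenches once the tissue is sterile
        damp = 1.0 + c.il10_activation_damping * loc_il10
        loc_pamp = (world.infection[world.row, world.col] > 0).astype(float)
        mac_sig = (loc_paf + c.pamp_signal * loc_pamp) / damp
        neut_sig = (loc_il8 + loc_paf) / damp
        u = rng.random(n)
        p_act = np.zeros(n)
        over = np.where(is_mac, mac_sig - c.mac_activation_threshold,
                        np.where(is_neut, neut_sig - c.neut_activation_threshold, -1.0))
        ramp = over > 0
        p_act[ramp] = 1.0 - np.exp(-c.activation_steepness * over[ramp])
        world.active = world.active | (u < p_act)
        world.active &= ~(rng.random(n) < c.deactivation_prob)
        world.active &= is_mac | is_neut  # lymphocytes use differentiation instead

        # TH0 differentiation, cytokine-parameterized
        if np.any(is_th0):
            p1 = np.clip(c.th1_diff * loc_il12, 0.0, 0.5)
            p2 = np.clip(c.th2_diff * loc_il4, 0.0, 0.5)
            v = rng.random(n)
            to_th1 = is_th0 & (v < p1)
            to_th2 = is_th0 & ~to_th1 & (v < p1 + p2)
            world.cell_type[to_th1] = TH1
            world.cell_type[to_th2] = TH2

        is_th1 = world.cell_type == TH1
        is_th2 = world.cell_type == TH2
        act_mac = is_mac & world.active
        act_neut = is_neut & world.active

        # secretion
        m1_damp = 1.0 / (1.0 + c.il10_production_damping * loc_il10)
        world._deposit(TNF, act_mac, c.mac_tnf * m1_damp[act_mac])
        world._deposit(IL1, act_mac, c.mac_il1 * m1_damp[act_mac])
        world._deposit(IL8, act_mac, c.mac_il8 * m1_damp[act_mac])
        world._deposit(IL12, act_mac, c.mac_il12 * m1_damp[act_mac])
        world._deposit(GCSF, act_mac, c.mac_gcsf * m1_damp[act_mac])
        world._deposit(IL10, act_mac, c.mac_il10)
        world._deposit(TNF, act_neut, c.neut_tnf * m1_damp[act_neut])
        world._deposit(IFNG, is_th1, c.th1_ifng)
        world._deposit(IL4, is_th2, c.th2_il4)
        world._deposit(IL10, is_th2, c.th2_il10)

        # phagocytosis / microbial killing, boosted by IFN-gamma
        kill = np.zeros((h, w))
        boost = 1.0 + c.ifng_kill_boost * loc_ifng
        if np.any(act_mac):
            np.add.at(kill, (world.row[act_mac], world.col[act_mac]),
                      c.mac_kill * boost[act_mac])
        rest_mac = is_mac & ~world.active
        if np.any(rest_mac):  # constitutive phagocytosis mops up residual colonies
            np.add.at(kill, (world.row[rest_mac], world.col[rest_mac]),
                      c.mac_kill * c.resting_kill_fraction * boost[rest_mac])
        if np.any(act_neut):
            np.add.at(kill, (world.row[act_neut], world.col[act_neut]),
                      c.neut_kill * boost[act_neut])
        # phagocytes patrol their immediate surroundings: part of the killing
        # capacity is spent on the Moore neighbourhood (capacity-conserving)
        spill = c.kill_spillover
        world.infection -= (1.0 - spill) * kill + spill * moore_mean(kill)
        np.maximum(world.infection, 0.0, out=world.infection)

        # neutrophil collateral damage (oxidative burst), damped by IL-10;
        # the burst fires only against microbes, so sterile tissue is spared
        burst_mask = act_neut & (world.infection[world.row, world.col] > 0)
        if np.any(burst_mask):
            burst = c.neut_damage / (1.0 + c.il10_protection * loc_il10[burst_mask])
            np.add.at(world.damage, (world.row[burst_mask], world.col[burst_mask]), burst)

        # movement: chemotaxis up the type-specific chemokine gradient,
        # otherwise an unbiased random walk on the Moore neighbourhood
        neigh = np.empty((n, 8))
        combined = world.conc[IL8] + world.conc[PAF]
        for k, (dr, dc) in enumerate(_MOORE):
            rr = (world.row + dr) % h
            cc = (world.col + dc) % w
            neigh[:, k] = np.where(
                is_neut, world.conc[IL8][rr, cc], combined[rr, cc]
            )
        here = np.where(is_neut, world.conc[IL8][world.row, world.col],
                        combined[world.row, world.col])
        best = np.argmax(neigh, axis=1)
        best_val = neigh[np.arange(n), best]
        follow = (
            (best_val > here)
            & (best_val > c.chemokine_sense_threshold)
            & (rng.random(n) < c.chemotaxis_prob)
        )
        rand_dir = rng.integers(0, 8, n)
        chosen = np.where(follow, best, rand_dir)
        moore = np.array(_MOORE)
        world.row = (world.row + moore[chosen, 0]) % h
        world.col = (world.col + moore[chosen, 1]) % w

        # aging and death; GCSF extends neutrophil life
        world.age += 1
        life = np.full(n, c.mac_lifespan, dtype=float)
        life[is_neut] = c.neut_lifespan * (
            1.0 + c.gcsf_life_extension * loc_gcsf[is_neut]
        )
        life[is_th1 | is_th2 | (world.cell_type == TH0)] = c.th_lifespan
        keep = world.age < life
        if not keep.all():
            world.cell_type = world.cell_type[keep]
            world.row = world.row[keep]
            world.col = world.col[keep]
            world.age = world.age[keep]
            world.active = world.active[keep]

    # recruitment from precursor pools, driven by systemic inflammation
    signal = c.recruit_signal_scale * float(
        (world.conc[TNF].mean() + world.conc[IL8].mean())
    )
    gcsf_mean = float(world.conc[GCSF].mean())
    rates = {
        "neutrophil": c.neut_recruit * signal * (1.0 + c.gcsf_recruit_boost * gcsf_mean),
        "macrophage": c.mac_recruit * signal,
        "th0": c.th0_recruit * signal,
    }
    codes = {"neutrophil": NEUTROPHIL, "macrophage": MACROPHAGE, "th0": TH0}
    for lineage, rate in rates.items():
        avail = world.pools[lineage]
        # neutrophils arrive in bursts (emergency granulopoiesis); burst
        # timing is a major source of outcome variance
        batch = c.recruit_batch if lineage == "neutrophil" else 1.0
        n_new = int(min(batch * rng.poisson(max(rate, 0.0) / batch), int(avail)))
        if n_new > 0:
            world.pools[lineage] = avail - n_new
            world.cell_type = np.concatenate(
                [world.cell_type, np.full(n_new, codes[lineage], dtype=np.int8)]
            )
            world.row = np.concatenate([world.row, rng.integers(0, h, n_new)])
            world.col = np.concatenate([world.col, rng.integers(0, w, n_new)])
            world.age = np.concatenate([world.age, np.zeros(n_new, dtype=np.int64)])
            world.active = np.concatenate([world.active, np.zeros(n_new, dtype=bool)])
        world.pools[lineage] = min(
            world.pools[lineage] + c.pool_replenish,
            float({"neutrophil": c.pool_neut, "macrophage": c.pool_mac,
                   "th0": c.pool_th0}[lineage]),
        )

    # ---- (2) infection: logistic growth, stochastic colonization front,
    # toxin damage ----------------------------------------------------------
    inf = world.infection
    if inf.any():
        growth = c.infection_growth * p.invasiveness
        # low-density (Allee) factor: sparse colonies grow slowly, so a
        # phagocyte visit or unassisted decay can extinguish them
        density = inf / (inf + c.growth_allee)
        inf += growth * inf * density * (1.0 - inf / c.infection_cap)
        # established colonies (load above the colonization threshold) seed
        # each sterile Moore neighbour with a small per-step probability
        established = inf > c.colonize_threshold
        if established.any():
            pressure = moore_mean(established.astype(float)) * 8.0  # neighbour count
            p_col = np.clip(c.infection_spread * p.invasiveness * pressure, 0.0, 1.0)
            newly = (inf == 0) & (rng.random((h, w)) < p_col)
            inf[newly] = c.colonize_seed
        inf *= 1.0 - c.infection_decay
        # once the total burden is small, systemic (humoral) clearance
        # dominates and drives the residual infection to sterility
        if inf.sum() < c.sterilize_threshold * c.infection_cap * inf.size:
            inf *= 1.0 - c.sterilize_rate
        # weak colonies (below the establishment threshold) are cleared
        # stochastically by humoral defences; most new seeds never establish
        weak = (inf > 0) & (inf < c.extinction_threshold)
        if weak.any():
            extinct = weak & (rng.random((h, w)) < c.extinction_prob)
            inf[extinct] = 0.0
        inf[inf < 1e-3] = 0.0
        np.clip(inf, 0.0, c.infection_cap, out=inf)
        world.damage += c.toxin_damage * p.toxigenesis * inf / c.infection_cap
        world.max_infection_seen = max(world.max_infection_seen, float(inf.sum()))

    # ---- (3) inflammation damage, environmental stress, healing ----------
    eff_tnf_field = world._effective_tnf()
    excess = np.maximum(eff_tnf_field - c.tnf_damage_threshold, 0.0)
    world.damage += c.cyto_damage * excess
    compromised = world.damage > 0
    world.damage[compromised] += c.env_stress * p.environmental_toxicity
    heal = c.heal_rate * p.host_resilience / (
        1.0
        + c.heal_block_infection * world.infection
        + c.heal_block_tnf * eff_tnf_field
    )
    world.damage -= heal
    np.clip(world.damage, 0.0, 1.0, out=world.damage)

    # endothelial alarm signalling rises superlinearly with local damage, so
    # badly injured tissue recruits strongly while moderate residual damage
    # quenches and can heal; soluble receptors are shed in proportion to the
    # agonist they neutralize
    dmg_signal = world.damage**2
    world.conc[PAF] += c.ec_paf_release * dmg_signal
    world.conc[IL8] += c.ec_il8_release * dmg_signal
    world.conc[IL8] += c.ec_il8_infection * world.infection / c.infection_cap
    world.conc[STNFR] += c.ec_stnfr_shed * world.conc[TNF]
    world.conc[SIL1R] += c.ec_sil1r_shed * world.conc[IL1]
    world.conc[IL1RA] += c.ec_il1ra_shed * world.conc[IL1]

    # ---- (4) mediator transport ------------------------------------------
    world.conc = diffuse_and_decay(world.conc, world.specs)

    # ---- (5) treated update transform ------------------------------------
    if multipliers is not None:
        from .intervention import apply_multipliers_to_field

        world.conc = apply_multipliers_to_field(world.conc, multipliers)

    world.t += 1
    world.status = _classify(world)
    return world


@dataclass
class Trajectory:
    """Ordered observation sequence of one run."""

    params: ModelParams
    seed: int
    observations: list[Observation]
    final_status: str

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for ob in self.observations:
            row = {"step": ob.t, "hours": ob.t * STEP_MINUTES / 60.0}
            for i, m in enumerate(MEDIATORS):
                row[m] = ob.C[i]
            row["oxygen_deficit"] = ob.oxygen_deficit
            row["infectious_load"] = ob.infectious_load
            for k, v in ob.cell_counts.items():
                row[f"n_{k}"] = v
            row["status"] = ob.status
            rows.append(row)
        return pd.DataFrame(rows)


def run_world(
    world: WorldState,
    schedule=None,
    max_steps: int = DEFAULT_MAX_STEPS,
    record_every: int = 1,
) -> Trajectory:
    """Step an existing world until an absorbing state or the step cap.

    ``schedule`` (an :class:`~iirabm.intervention.InterventionSchedule` or
    ``None``) supplies per-step multiplier vectors via its
    ``active_multipliers`` contract; absolute step indices are used, so a
    snapshot resumed mid-schedule sees the correct stage.
    """
    obs = [observe(world)] if world.t == 0 else []
    end = world.t + max_steps if world.t > 0 else max_steps
    while world.status == ALIVE and world.t < end:
        mult = None
        if schedule is not None:
            from .intervention import active_multipliers

            mult = active_multipliers(schedule, world.t)
        step(world, mult)
        if world.t % record_every == 0 or world.status != ALIVE:
            obs.append(observe(world))
    return Trajectory(world.params, world.seed, obs, world.status)


def run_simulation(
    params: ModelParams,
    seed: int,
    schedule=None,
    max_steps: int = DEFAULT_MAX_STEPS,
    constants: RuleConstants = DEFAULT_CONSTANTS,
    specs: tuple[MediatorSpec, ...] = DEFAULT_MEDIATOR_SPECS,
    record_every: int = 1,
) -> Trajectory:
    """Run one full patient trajectory from injury to outcome.

    Deterministic in ``(params, seed, schedule, constants)``: repeated calls
    return identical trajectories.
    """
    if max_steps < 1:
        raise ValueError("max_steps must be >= 1")
    world = init_world(params, seed, constants, specs)
    return run_world(world, schedule, max_steps, record_every)
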