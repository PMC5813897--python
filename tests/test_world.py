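"""Core-model unit and property tests: initialization, transport,
stepping, observation and full runs."""

import copy
import warnings

import numpy as np
import pytest

import iirabm as m
from iirabm.mediators import MediatorSpec, N_MEDIATORS
from iirabm.world import ALIVE, HEALED, moore_mean, step


def brute_force_disk_count(radius: int, shape: tuple[int, int]) -> int:
    """Independent lattice-point count: enumerate every grid point."""
    h, w = shape
    cy, cx = h // 2, w // 2
    count = 0
    for r in range(h):
        for c in range(w):
            if (r - cy) ** 2 + (c - cx) ** 2 <= radius**2:
                count += 1
    return count


def stencil_oracle(field: np.ndarray, d: float, lam: float) -> np.ndarray:
    """Explicit per-cell Moore-stencil reference (no vectorization)."""
    h, w = field.shape
    out = np.empty_like(field)
    for r in range(h):
        for c in range(w):
            s = 0.0
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    if dr == 0 and dc == 0:
                        continue
                    s += field[(r + dr) % h, (c + dc) % w]
            out[r, c] = field[r, c] + d * (s / 8.0 - field[r, c]) - lam * field[r, c]
    return out


class TestInitWorld:
    def test_no_injury_is_pristine(self, tiny_constants):
        w = m.init_world(m.ModelParams(injury_radius=0), 1, tiny_constants)
        ob = m.observe(w)
        assert ob.oxygen_deficit == 0.0
        assert ob.infectious_load == 0.0
        assert w.t == 0

    def test_same_seed_bitwise_identical(self, tiny_params, tiny_constants):
        w1 = m.init_world(tiny_params, 5, tiny_constants)
        w2 = m.init_world(tiny_params, 5, tiny_constants)
        assert np.array_equal(w1.damage, w2.damage)
        assert np.array_equal(w1.conc, w2.conc)
        assert np.array_equal(w1.row, w2.row)
        assert np.array_equal(w1.col, w2.col)
        assert np.array_equal(w1.cell_type, w2.cell_type)

    @pytest.mark.parametrize("radius,shape", [(4, (15, 15)), (8, (25, 25)), (33, (101, 101))])
    def test_injured_patch_matches_lattice_count(self, radius, shape):
        const = m.DEFAULT_CONSTANTS.replace(grid_shape=shape)
        w = m.init_world(m.ModelParams(injury_radius=radius), 1, const)
        expected = brute_force_disk_count(radius, shape)
        assert int(np.count_nonzero(w.damage)) == expected
        assert int(np.count_nonzero(w.infection)) == expected

    def test_oversized_radius_rejected(self, tiny_constants):
        with pytest.raises(ValueError, match="injury_radius"):
            m.init_world(m.ModelParams(injury_radius=12), 1, tiny_constants)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            m.ModelParams(host_resilience=1.5)
        with pytest.raises(ValueError):
            m.ModelParams(invasiveness=-1)


class TestDiffuseAndDecay:
    def test_uniform_field_invariant(self):
        spec = [MediatorSpec("TNF", 0.7, 0.0)]
        field = np.full((9, 9), 3.25)
        out = m.diffuse_and_decay(field, spec)
        np.testing.assert_allclose(out, field)

    def test_zero_constants_identity(self, rng):
        spec = [MediatorSpec("TNF", 0.0, 0.0)]
        field = rng.random((8, 8))
        np.testing.assert_array_equal(m.diffuse_and_decay(field, spec), field)

    def test_matches_explicit_stencil_oracle(self, rng):
        field = rng.random((8, 8)) * 10
        out = m.diffuse_and_decay(field, [MediatorSpec("IL8", 0.4, 0.0)])
        expected = stencil_oracle(field, 0.4, 0.0)
        np.testing.assert_allclose(out, expected, rtol=1e-12)

    def test_mass_conserved_without_decay(self, rng):
        field = rng.random((12, 16)) * 5
        out = m.diffuse_and_decay(field, [MediatorSpec("GCSF", 0.6, 0.0)])
        assert out.sum() == pytest.approx(field.sum(), rel=1e-9)

    def test_decay_removes_exact_fraction(self, rng):
        field = rng.random((10, 10))
        out = m.diffuse_and_decay(field, [MediatorSpec("PAF", 0.0, 0.25)])
        np.testing.assert_allclose(out, 0.75 * field)

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            m.diffuse_and_decay(np.full((4, 4), -1.0), [MediatorSpec("TNF", 0.1, 0.1)])

    def test_unstable_constants_rejected_at_spec(self):
        with pytest.raises(ValueError, match="negative concentrations"):
            MediatorSpec("TNF", 0.8, 0.5)


class TestStep:
    def test_empty_world_only_clock_advances(self, tiny_constants):
        w = m.init_world(m.ModelParams(injury_radius=0), 1, tiny_constants)
        # strip resident cells to make the world fully inert
        for name in ("cell_type", "row", "col", "age", "active"):
            setattr(w, name, getattr(w, name)[:0])
        step(w)
        assert w.t == 1
        assert w.damage.sum() == 0
        assert w.infection.sum() == 0
        assert w.conc.sum() == 0

    def test_replay_from_copy_identical(self, small_world):
        for _ in range(20):
            step(small_world)
        w2 = small_world.copy()
        step(small_world)
        step(w2)
        assert np.array_equal(small_world.conc, w2.conc)
        assert np.array_equal(small_world.damage, w2.damage)
        assert np.array_equal(small_world.infection, w2.infection)
        assert np.array_equal(small_world.row, w2.row)

    def test_point_mass_conserved_without_decay_or_producers(self, tiny_constants):
        specs = list(m.DEFAULT_MEDIATOR_SPECS)
        specs[4] = MediatorSpec("sIL1r", 0.4, 0.0)  # no decay, no producer rule
        w = m.init_world(m.ModelParams(injury_radius=0), 1, tiny_constants, tuple(specs))
        for name in ("cell_type", "row", "col", "age", "active"):
            setattr(w, name, getattr(w, name)[:0])
        w.damage[0, 0] = 0.9  # keep the world out of the healed state
        w.conc[4, 7, 7] = 100.0
        total_before = w.conc[4].sum()
        for _ in range(10):
            step(w)
        assert w.conc[4].sum() == pytest.approx(total_before, rel=1e-9)

    def test_absorbing_state_is_noop_with_warning(self, small_world):
        small_world.damage[:] = 1.0
        step(small_world)  # crosses the death threshold
        assert small_world.status.startswith("dead")
        t_dead = small_world.t
        snap = copy.deepcopy(small_world.damage)
        with pytest.warns(UserWarning, match="absorbing"):
            step(small_world)
        assert small_world.t == t_dead
        assert np.array_equal(small_world.damage, snap)

    def test_fields_stay_non_negative(self, small_world):
        for _ in range(100):
            step(small_world)
        assert (small_world.conc >= 0).all()
        assert (small_world.infection >= 0).all()
        assert (small_world.damage >= 0).all()


class TestObserve:
    def test_healthy_sterile_world_is_healed(self, tiny_constants):
        w = m.init_world(m.ModelParams(injury_radius=0), 1, tiny_constants)
        ob = m.observe(w)
        assert ob.oxygen_deficit == 0
        assert ob.infectious_load == 0
        assert ob.status == HEALED

    def test_damage_above_threshold_is_dead(self, tiny_world):
        tiny_world.damage[:] = 0.85
        ob = m.observe(tiny_world)
        assert ob.status in ("dead_infection", "dead_sepsis")

    def test_damage_below_threshold_alive(self, tiny_world):
        tiny_world.damage[:] = 0.5
        assert m.observe(tiny_world).status == ALIVE

    def test_aggregates_match_brute_force_sum(self, rng):
        # 100 random worlds: C_i must equal an independent summation
        const = m.SMALL_CONSTANTS.replace(grid_shape=(9, 9))
        for k in range(100):
            w = m.init_world(m.ModelParams(injury_radius=2), k, const)
            w.conc = rng.random((N_MEDIATORS, 9, 9))
            ob = m.observe(w)
            for i in range(N_MEDIATORS):
                expected = sum(
                    w.conc[i, r, c] for r in range(9) for c in range(9)
                )
                assert ob.C[i] == pytest.approx(expected, rel=1e-12)


class TestRunSimulation:
    def test_terminates_by_step_cap(self, tiny_params, tiny_constants):
        traj = m.run_simulation(tiny_params, 1, max_steps=50, constants=tiny_constants)
        assert traj.observations[-1].t <= 50

    def test_identity_schedule_matches_untreated(self, tiny_params, tiny_constants):
        sched = m.identity_schedule(2, start_step=5, spacing_steps=10, duration_steps=8)
        t1 = m.run_simulation(tiny_params, 9, None, 40, tiny_constants)
        t2 = m.run_simulation(tiny_params, 9, sched, 40, tiny_constants)
        f1, f2 = t1.to_frame(), t2.to_frame()
        assert f1.equals(f2)

    def test_full_determinism(self, tiny_params, tiny_constants):
        t1 = m.run_simulation(tiny_params, 4, None, 60, tiny_constants)
        t2 = m.run_simulation(tiny_params, 4, None, 60, tiny_constants)
        assert t1.final_status == t2.final_status
        assert t1.to_frame().equals(t2.to_frame())

    def test_trajectory_frame_columns(self, tiny_params, tiny_constants):
        traj = m.run_simulation(tiny_params, 1, max_steps=10, constants=tiny_constants)
        frame = traj.to_frame()
        for col in ("step", "hours", "TNF", "GCSF", "oxygen_deficit",
                    "infectious_load", "n_neutrophil", "status"):
            assert col in frame.columns
        # 100 steps = 12 h
        np.testing.assert_allclose(frame["hours"], frame["step"] * 0.12)
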