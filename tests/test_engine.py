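"""Engine: initial conditions, loop invariants, determinism, replicates."""

import numpy as np
import pytest

import spheroidsim as s
from spheroidsim import mechanics as mech
from spheroidsim.cycle import radius_from_volume
from spheroidsim.engine import (ConfigurationError, calibrate_spacing,
                                hex_disc_points, init_spheroid, run,
                                run_replicates, _mechanics_step,
                                _position_voxel_density)

NULL_DYNAMICS = dict(rdiv=0.0, S0=0.0, rdeg0=0.0, ccca=0.0, cccr=0.0)


class TestInitSpheroid:
    def test_200um_spheroid_has_139_cells(self):
        state = init_spheroid(s.ModelParams(), seed=0)
        assert state.n_cells == 139

    def test_calibrated_spacing_within_scan_bounds(self):
        p = s.ModelParams()
        a = calibrate_spacing(p.cell_radius)
        assert 1.8 * p.cell_radius <= a <= 2.0 * p.cell_radius

    def test_degenerate_disc_seeds_one_cell_at_origin(self):
        state = init_spheroid(s.ModelParams(), seed=0, diameter=10.0)
        assert state.n_cells == 1
        np.testing.assert_array_equal(state.pos, [[0.0, 0.0]])

    def test_pairwise_distances_at_least_the_spacing(self):
        state = init_spheroid(s.ModelParams(), seed=0)
        d = np.linalg.norm(state.pos[:, None] - state.pos[None, :], axis=2)
        d[np.diag_indices_from(d)] = np.inf
        assert d.min() >= state.packing_spacing - 1e-9

    def test_ecm_cleared_under_the_spheroid_only(self):
        state = init_spheroid(s.ModelParams(), seed=0)
        grid = state.grid
        xc, yc = grid.voxel_centres()
        dist = np.hypot(xc[None, :], yc[:, None])
        assert np.all(grid.density[dist <= 100.0] == 0.0)
        assert np.all(grid.density[dist > 100.0] == 1.0)

    def test_cells_start_at_full_volume_with_zero_direction(self):
        state = init_spheroid(s.ModelParams(), seed=0)
        assert np.all(state.vol == state.params.cell_volume_max)
        assert np.all(state.dirs == 0.0)

    def test_unreachable_calibration_is_a_configuration_error(self):
        with pytest.raises(ConfigurationError):
            calibrate_spacing(cell_radius=2.0)  # tiny cells: 139 unreachable

    def test_spheroid_must_fit_in_domain(self):
        with pytest.raises(Exception):
            init_spheroid(s.ModelParams(domain_half_width=80.0), seed=0)


def test_hex_disc_monotone_in_radius():
    counts = [len(hex_disc_points(16.0, r)) for r in (0, 20, 50, 100)]
    assert counts[0] == 1
    assert counts == sorted(counts)


class TestRun:
    def test_t_end_zero_returns_initial_state(self, fast_params):
        state = init_spheroid(fast_params, seed=3)
        pos0 = state.pos.copy()
        res = run(state, 0.0)
        np.testing.assert_array_equal(state.pos, pos0)
        assert list(res.metrics["time_min"]) == [0.0]
        assert res.metrics["relative_growth"].iloc[0] == 1.0

    def test_null_dynamics_is_a_fixed_point(self, fast_params):
        params = fast_params.replace(**NULL_DYNAMICS)
        state = init_spheroid(params, seed=3)
        pos0 = state.pos.copy()
        rho0 = state.grid.density.copy()
        run(state, 120.0, compute_metrics=False)
        np.testing.assert_array_equal(state.pos, pos0)
        np.testing.assert_array_equal(state.grid.density, rho0)
        assert state.n_cells == 139

    def test_same_seed_is_bit_identical(self, fast_params):
        results = []
        for _ in range(2):
            state = init_spheroid(fast_params, seed=11)
            results.append(run(state, 180.0).metrics)
        assert results[0].equals(results[1])

    def test_different_seeds_differ(self, fast_params):
        finals = []
        for seed in (1, 2):
            state = init_spheroid(fast_params, seed=seed)
            run(state, 360.0, compute_metrics=False)
            finals.append(state.pos.copy())
        assert finals[0].shape != finals[1].shape or \
            not np.allclose(finals[0], finals[1])

    def test_density_in_bounds_and_nonincreasing_cell_count_nondecreasing(
            self, fast_params):
        state = init_spheroid(fast_params, seed=5)
        prev_rho = state.grid.density.copy()
        prev_n = state.n_cells
        for _ in range(6):  # six 1 h legs of one continuous run
            run(state, 60.0, compute_metrics=False)
            rho = state.grid.density
            assert rho.min() >= 0.0 and rho.max() <= 1.0
            assert np.all(rho <= prev_rho + 1e-15)
            assert state.n_cells >= prev_n
            prev_rho = rho.copy()
            prev_n = state.n_cells

    def test_division_halves_volume_and_places_daughters_inside_parent(
            self, fast_params):
        # rdiv*dt_cell = 1 with f_IP = 1 makes both cells divide in the
        # first phenotype step, deterministically
        params = fast_params.replace(rdiv=1.0 / 6.0, S0=0.0, rdeg0=0.0,
                                     growth_rate_k=0.0)
        state = init_spheroid(params, seed=7, diameter=10.0)
        v = params.cell_volume_max
        state.pos = np.array([[0.0, 0.0], [18.0, 0.0]])  # touching pair
        state.vol = np.full(2, v)
        state.dirs = np.zeros((2, 2))
        state.ids = np.arange(2)
        state.next_id = 2
        state.grid.density[:] = 0.0  # no matrix confinement anywhere
        run(state, 6.0, compute_metrics=False, snapshot_interval_min=6.0)
        assert state.n_cells == 4
        np.testing.assert_allclose(state.vol, v / 2)  # volume conserved
        r_parent = radius_from_volume(v)
        for parent, daughter in ((0, 2), (1, 3)):
            gap = np.linalg.norm(state.pos[parent] - state.pos[daughter])
            assert gap == pytest.approx(r_parent, rel=1e-12)

    def test_detached_cell_does_not_divide(self, fast_params):
        params = fast_params.replace(rdiv=1.0 / 6.0, S0=0.0, rdeg0=0.0)
        state = init_spheroid(params, seed=7, diameter=10.0)  # one cell
        state.grid.density[:] = 0.0
        run(state, 60.0, compute_metrics=False)
        assert state.n_cells == 1

    def test_isolated_cell_at_full_density_does_not_move(self, fast_params):
        # no degradation, so the wall persists for the whole run
        state = init_spheroid(fast_params.replace(rdeg0=0.0), seed=9,
                              diameter=10.0)
        state.grid.density[:] = 1.0  # wall everywhere, even under the cell
        state.dirs[0] = [1.0, 0.0]
        pos0 = state.pos.copy()
        run(state, 60.0, compute_metrics=False)
        np.testing.assert_array_equal(state.pos, pos0)

    def test_invalid_t_end_rejected(self, fast_params):
        state = init_spheroid(fast_params, seed=0)
        with pytest.raises(ValueError):
            run(state, 90.0)  # not a multiple of the 60 min snapshot cadence


class TestKernelAgreesWithReference:
    """The numba hot path must match the numpy reference step for step."""

    def _reference_step(self, state):
        p = state.params
        rad = state.radii
        rad_a = p.adhesion_radius_multiple * rad
        vox = [state.grid.select_interaction_voxel(state.pos[i],
                                                   state.dirs[i], rad[i])
               for i in range(state.n_cells)]
        for v in dict.fromkeys(vox):  # each selected voxel decays once
            state.grid.degrade(v, p.rdeg_rib, p.dt_mech)
        state.dirs = mech.direction_update(state.dirs, p.Tper, p.dt_mech,
                                           state.rng)
        rho = np.array([state.grid.density[v] for v in vox])
        v_cc = mech.cell_cell_velocity(state.pos, rad, rad_a, p.ccca, p.cccr)
        v_cma = mech.cell_ecm_adhesion_velocity(state.dirs, rho, p.S_rib)
        v_total = (v_cc + v_cma) + mech.cell_ecm_repulsion_velocity(
            v_cc, v_cma, rho)
        state.pos = mech.step_positions(state.pos, v_total, p.dt_mech)

    def test_one_hour_of_steps(self, fast_params):
        a = init_spheroid(fast_params, seed=21)
        b = init_spheroid(fast_params, seed=21)
        # randomise directions and densities so every term is exercised
        setup = np.random.Generator(np.random.PCG64(99))
        theta = setup.random(a.n_cells) * 2 * np.pi
        dirs = np.column_stack([np.cos(theta), np.sin(theta)])
        dirs[::7] = 0.0
        noise = 0.2 + 0.8 * setup.random(a.grid.density.shape)
        density = np.where(a.grid.density > 0, noise, 0.0)
        for st in (a, b):
            st.dirs = dirs.copy()
            st.grid.density = density.copy()
        for _ in range(600):
            _mechanics_step(a)
            self._reference_step(b)
        np.testing.assert_allclose(b.pos, a.pos, rtol=1e-10, atol=1e-12)
        np.testing.assert_allclose(b.grid.density, a.grid.density, rtol=1e-12)
        np.testing.assert_array_equal(b.dirs, a.dirs)


class TestRunReplicates:
    def test_single_replicate_equals_run(self, fast_params):
        df = run_replicates(fast_params, 1, base_seed=4, t_end_min=120.0)
        state = init_spheroid(fast_params, seed=4)
        res = run(state, 120.0)
        np.testing.assert_allclose(
            df["relative_growth"], res.metrics["relative_growth"])

    def test_replicate_seeds_are_offset(self, fast_params):
        df = run_replicates(fast_params, 2, base_seed=10, t_end_min=60.0)
        assert sorted(df["seed"].unique()) == [10, 11]

    def test_position_voxel_density_matches_grid_lookup(self, fast_params):
        state = init_spheroid(fast_params, seed=2)
        rho = _position_voxel_density(state)
        expected = [state.grid.density[state.grid.voxel_of_point(tuple(p))]
                    for p in state.pos]
        np.testing.assert_array_equal(rho, expected)
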