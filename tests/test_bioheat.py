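"""Conjugate bioheat solver: schedule, single steps, oracles, conservation."""

import numpy as np
import pytest

import cryovessel as cv
from cryovessel.bioheat import (BioheatSolver, BoundarySpec, StepError,
                                advance, run_simulation, time_step)
from cryovessel.materials import enthalpy
from cryovessel.verification import make_fixture, semi_infinite_conduction


class TestTimeStepSchedule:
    @pytest.mark.parametrize("t, scale, expected", [
        (0.5, 1.0, 0.005),
        (1.0, 1.0, 0.01),
        (5.0, 1.0, 0.01),
        (50.0, 1.0, 0.05),
        (100.0, 1.0, 0.05),
        (200.0, 10.0, 1.0),
    ])
    def test_schedule(self, t, scale, expected):
        assert time_step(t, scale) == pytest.approx(expected)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            time_step(-1.0)
        with pytest.raises(ValueError):
            time_step(1.0, scale=0.5)


class TestSingleCell:
    def test_uniform_body_temperature_is_steady(self):
        # perfusion vanishes at T = Tcb; only Qm drifts, bounded by Qm dt/C
        grid, cfg = make_fixture("single_cell")
        solver = BioheatSolver(grid, cfg["props"], BoundarySpec())
        solver.step(0.1)
        drift = solver.T[0] - 37.0
        bound = cfg["props"].Qm * 0.1 / cfg["props"].Ct
        assert 0 <= drift <= bound * 1.001

    def test_perfusion_relaxes_toward_blood_temperature(self):
        grid, cfg = make_fixture("single_cell")
        solver = BioheatSolver(grid, cfg["props"], BoundarySpec(), T_init=30.0)
        T0 = solver.T[0]
        solver.step(10.0)
        assert T0 < solver.T[0] < 37.1  # warmed toward Tcb, not beyond


class TestSlabConduction:
    def test_frozen_slab_matches_erf_solution(self):
        # fully frozen slab (no band crossing): pure conduction at alpha_f
        props = cv.MaterialProperties()
        grid, _ = make_fixture("slab_1d", n=81, h=1.0)
        bounds = BoundarySpec(T_probe=-196.0)
        solver = BioheatSolver(grid, props, bounds, T_init=-50.0)
        t_end, dt = 30.0, 0.05
        while solver.t < t_end - 1e-9:
            solver.step(dt)
        alpha = props.kappa_f / props.Cf
        x = (np.arange(len(solver.T)) + 0.5) * 1e-3
        exact = semi_infinite_conduction(x, t_end, -50.0, -196.0, alpha)
        core = x < 0.05  # away from the far end
        err = np.abs(solver.T[core] - exact[core]).max()
        assert err < 2.0  # degC, first-order in h and dt

    def test_maximum_principle(self):
        # no temperature outside [T_probe, max(T_init, Tcb) + Qm bound]
        grid, cfg = make_fixture("slab_1d", n=41, h=1.0)
        solver = BioheatSolver(grid, cv.MaterialProperties(), BoundarySpec())
        for _ in range(50):
            solver.step(0.1)
            assert solver.T.min() >= -196.0 - 1e-9
            assert solver.T.max() <= 37.0 + 1e-3

    def test_energy_conservation(self):
        # enthalpy change equals time-integrated boundary + source power
        grid, cfg = make_fixture("slab_1d", n=41, h=1.0)
        props = cfg["props"]
        solver = BioheatSolver(grid, props, BoundarySpec(), picard_tol=1e-6)
        H0 = solver.total_enthalpy()
        work = 0.0
        for _ in range(100):
            solver.step(0.1)
            work += 0.1 * solver.boundary_power()
        dH = solver.total_enthalpy() - H0
        assert dH == pytest.approx(work, rel=5e-3)

    def test_picard_failure_raises(self):
        grid, cfg = make_fixture("slab_1d", n=41, h=1.0)
        solver = BioheatSolver(grid, cfg["props"], BoundarySpec(),
                               picard_max=1)
        with pytest.raises(StepError):
            for _ in range(200):
                solver.step(5.0)


class TestConjugateAdvection:
    def test_uniform_body_temperature_steady_under_flow(self, default_geometry):
        # advective in/out fluxes balance cell-by-cell: flowing 37 degC
        # blood through 37 degC tissue changes nothing (up to Qm drift)
        grid = cv.voxelize(default_geometry, 2.5)
        flow = cv.analytic_flow(default_geometry, grid, 0.2)
        solver = BioheatSolver(grid, cv.MaterialProperties(), BoundarySpec(),
                               flow)
        for _ in range(4):
            solver.step(0.5)
        assert solver.T.min() >= 37.0 - 1e-6
        assert solver.T.max() <= 37.0 + 1e-3


class TestAdvanceFunctional:
    def test_matches_persistent_solver(self):
        grid, cfg = make_fixture("slab_1d", n=21, h=2.0)
        props = cv.MaterialProperties()
        solver = BioheatSolver(grid, props, BoundarySpec())
        field0 = solver.to_field()
        stepped = advance(field0, None, grid, props, BoundarySpec(), 0.1)
        solver.step(0.1)
        ref = solver.to_field()
        assert np.allclose(stepped.data[~np.isnan(ref.data)],
                           ref.data[~np.isnan(ref.data)], atol=1e-9)
        assert stepped.time == pytest.approx(0.1)


class TestRunSimulation:
    def test_zero_end_time_gives_initial_metrics(self):
        grid, cfg = make_fixture("mini_bifurcation")
        props = cv.MaterialProperties()
        series, cps = run_simulation(grid, props, BoundarySpec(), None,
                                     t_end=0.0)
        assert series.time == [0.0]
        assert series.iceball_volume[0] == 0.0
        assert series.min_wall_temperature[0] == pytest.approx(37.0)

    def test_iceball_growth_monotone_and_checkpoints(self):
        grid, cfg = make_fixture("mini_bifurcation")
        geo = cfg["geometry"]
        flow = cv.analytic_flow(geo, grid, 0.2)
        series, cps = run_simulation(grid, cv.MaterialProperties(),
                                     BoundarySpec(), flow, t_end=60.0,
                                     dt_scale=10.0, cadence=5.0,
                                     checkpoint_times=(30.0, 60.0))
        vols = np.array(series.iceball_volume)
        # growth is monotone up to sub-cell interpolation noise; at this
        # very coarse fixture resolution (h = 4 mm, tens of frozen voxels)
        # the estimate can dip by a few tens of percent transiently
        running_max = np.maximum.accumulate(vols)
        assert np.all(vols >= 0.65 * running_max)
        assert vols[-1] > 0.0
        assert set(cps) == {30.0, 60.0}
        assert cps[60.0].time == pytest.approx(60.0)
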