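"""One-dimensional slab drivers: the bridge between the voxel solver and
the analytic Stefan / conduction oracles.

A slab fixture is an N x 1 x 1 tissue column whose first cell is a probe
tip, so the face at ``x = h`` is a Dirichlet cold wall; lateral faces are
adiabatic, making the march exactly one-dimensional.  These drivers run
the full conjugate solver on that column and report the freezing-front
position for comparison with the Neumann similarity solution.
"""

from __future__ import annotations

import numpy as np

from .bioheat import BioheatSolver, BoundarySpec
from .verification import StefanParams, make_fixture, stefan_front

__all__ = ["run_stefan_slab", "front_position_mm", "stefan_slab_front_error"]


def front_position_mm(solver: BioheatSolver, T_m: float, wall_x0: float) -> float:
    """Location (mm, measured from the cold wall) where the temperature
    profile crosses ``T_m``, linearly interpolated between cell centers."""
    T = solver.T  # active cells in C-order = tissue cells 1..N-1 of the column
    n = len(T)
    h = solver.grid.h
    x = (np.arange(n) + 0.5) * h  # cell centers measured from the wall face
    below = T <= T_m
    if not below.any():
        # front between the wall itself and the first cell center
        Tw = solver.bounds.T_probe
        if Tw > T_m:
            return 0.0
        return float(0.5 * h * (Tw - T_m) / (Tw - T[0]))
    i = int(np.nonzero(below)[0][-1])
    if i + 1 >= n:
        raise RuntimeError("freezing front reached the end of the slab")
    frac = (T[i] - T_m) / (T[i] - T[i + 1])
    return float(x[i] + frac * (x[i + 1] - x[i]))


def run_stefan_slab(h: float = 1.0, t_end: float = 240.0,
                    dt: float | None = None, n: int | None = None,
                    band: float = 7.0):
    """March the effective-capacity solver on the 1D slab and return
    ``(solver, config, front_mm)`` at ``t_end`` seconds."""
    n = n or int(round(60.0 / h)) + 1
    grid, cfg = make_fixture("slab_1d", n=n, h=h, band=band)
    stefan: StefanParams = cfg["stefan"]
    props = cfg["props"]
    bounds = BoundarySpec(T_inlet=stefan.T_init, T_probe=stefan.T_wall)
    solver = BioheatSolver(grid, props, bounds, flow=None, T_init=stefan.T_init)
    dt = dt if dt is not None else 0.1 * h
    while solver.t < t_end - 1e-9:
        solver.step(min(dt, t_end - solver.t))
    # wall sits at the face between the tip cell and the first tissue cell
    front = front_position_mm(solver, stefan.T_m, wall_x0=h)
    return solver, cfg, front


def stefan_slab_front_error(h: float = 1.0, t_end: float = 240.0,
                            dt: float | None = None) -> float:
    """Relative error of the numerical freezing-front position against the
    Neumann two-phase solution at ``t_end``."""
    _, cfg, front = run_stefan_slab(h=h, t_end=t_end, dt=dt)
    exact = stefan_front(t_end, cfg["stefan"]) * 1e3  # m -> mm
    return abs(front - exact) / exact
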