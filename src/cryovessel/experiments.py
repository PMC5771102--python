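"""Parameter studies: probe-distance and inlet-velocity sweeps, the
treatment-time matrix, and the three-probe layout.

Every study is a thin orchestration over ``run_case``: build geometry,
voxelize, obtain the steady flow, march the freezing simulation, extract
metrics.  Results are deterministic functions of the config.
"""

from __future__ import annotations

import json
import time as _time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import bioheat, hemodynamics, metrics
from .config import CaseConfig
from .geometry import LabeledGrid, build_geometry, voxelize
from .hemodynamics import FlowParams

__all__ = ["CaseResult", "SweepSpec", "run_case", "run_sweep",
           "run_table1", "run_table2", "run_table3", "run_three_probe"]


@dataclass
class CaseResult:
    config: CaseConfig
    series: metrics.MetricSeries
    checkpoints: dict
    grid: LabeledGrid
    geometry: object
    flow: object
    summary: dict = field(default_factory=dict)

    def save(self, outdir) -> None:
        import pathlib
        out = pathlib.Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.series.to_csv(out / "metrics.csv")
        with open(out / "summary.json", "w") as f:
            json.dump(self.summary, f, indent=2, default=float)
        for t, fld in self.checkpoints.items():
            fld.save_vtk(out / f"temperature_{int(t)}s.vtk")


def _make_flow(cfg: CaseConfig, geometry, grid):
    params = FlowParams(V=cfg.V, mu=cfg.mu, rho=cfg.rho)
    if cfg.flow_mode == "none" or cfg.V == 0.0:
        return hemodynamics.analytic_flow(geometry, grid, 0.0), params
    if cfg.flow_mode == "analytic":
        return hemodynamics.analytic_flow(geometry, grid, cfg.V), params
    if cfg.flow_mode == "solved":
        return hemodynamics.solve_steady_flow(grid, params, geometry), params
    raise ValueError(f"unknown flow_mode {cfg.flow_mode!r}")


def run_case(cfg: CaseConfig, dt_scale_schedule=None) -> CaseResult:
    """Run one case end to end: geometry -> flow -> freezing -> metrics.

    ``dt_scale_schedule`` optionally maps simulated time to a time-step
    scale as a list of ``(t_until, scale)`` pairs; the default applies
    ``cfg.dt_scale`` throughout.
    """
    t0 = _time.perf_counter()
    geometry = build_geometry(cfg.bifurcation_params(), cfg.probe_specs())
    grid = voxelize(geometry, cfg.h)
    flow, fparams = _make_flow(cfg, geometry, grid)
    props = cfg.material_properties()
    bounds = bioheat.BoundarySpec(T_inlet=cfg.T_inlet, T_probe=cfg.T_probe)

    sample_points = {k: tuple(v) for k, v in cfg.sample_points.items()}
    schedule = dt_scale_schedule or [(float("inf"), cfg.dt_scale)]
    from .geometry import probe_surface_scale
    solver = bioheat.BioheatSolver(
        grid, props, bounds, flow,
        probe_area_scale=probe_surface_scale(grid, cfg.probe_specs()))
    series = None
    checkpoints = {}
    for t_until, scale in schedule:
        upto = min(t_until, cfg.t_end)
        if solver.t >= upto - 1e-12:
            continue
        series, cps = bioheat.run_simulation(
            grid, props, bounds, flow, t_end=upto, dt_scale=scale,
            cadence=cfg.cadence, sample_points=sample_points,
            checkpoint_times=tuple(t for t in cfg.checkpoint_times
                                   if solver.t < t <= upto),
            stop_when_wall_below=cfg.stop_when_wall_below,
            solver=solver, series=series)
        checkpoints.update(cps)
        if (cfg.stop_when_wall_below is not None
                and series.min_wall_temperature[-1] < cfg.stop_when_wall_below):
            break

    summary = {
        "config": cfg.to_dict(),
        "n_cells": int(np.prod(grid.shape)),
        "n_active": int(solver.n),
        "reynolds": hemodynamics.reynolds_number(fparams, cfg.D0 * 1e-3),
        "wall_time_s": _time.perf_counter() - t0,
        **series.summary(),
    }
    return CaseResult(config=cfg, series=series, checkpoints=checkpoints,
                      grid=grid, geometry=geometry, flow=flow, summary=summary)


@dataclass
class SweepSpec:
    """One-parameter sweep: ``parameter`` in {"Ld", "V"} applied on top of a
    base single-probe config."""

    parameter: str
    values: list[float]
    base: CaseConfig
    Ld: float = 30.0          # fixed Ld for V sweeps
    V: float = 0.20           # fixed V for Ld sweeps

    def __post_init__(self) -> None:
        if not self.values:
            raise ValueError("sweep value list is empty")
        if self.parameter not in ("Ld", "V"):
            raise ValueError(f"unknown sweep parameter {self.parameter!r}")


def run_sweep(spec: SweepSpec) -> dict[float, CaseResult]:
    out = {}
    base = _strip_probe_keys(spec.base.to_dict())
    for v in spec.values:
        if spec.parameter == "Ld":
            cfg = CaseConfig.single_probe(Ld=v, V=spec.V, **base)
        else:
            cfg = CaseConfig.single_probe(Ld=spec.Ld, V=v, **base)
        out[v] = run_case(cfg)
    return out


def _strip_probe_keys(d: dict) -> dict:
    d = dict(d)
    d.pop("probes", None)
    d.pop("V", None)
    return d


def run_table1(Ld_values=(20.0, 30.0, 40.0), V: float = 0.20,
               **cfg_kw) -> pd.DataFrame:
    """Iceball and lethal volumes at fixed freezing duration for different
    probe-bifurcation distances."""
    rows = []
    for Ld in Ld_values:
        res = run_case(CaseConfig.single_probe(Ld=Ld, V=V, **cfg_kw))
        rows.append({"Ld_mm": Ld,
                     "iceball_volume_cm3": res.series.iceball_volume[-1],
                     "lethal_volume_cm3": res.series.lethal_volume[-1]})
    return pd.DataFrame(rows)


def run_table2(V_values=(0.01, 0.05, 0.10, 0.20, 0.30), Ld: float = 30.0,
               **cfg_kw) -> pd.DataFrame:
    """Iceball and lethal volumes for different root inlet velocities."""
    rows = []
    for V in V_values:
        res = run_case(CaseConfig.single_probe(Ld=Ld, V=V, **cfg_kw))
        rows.append({"V_m_per_s": V,
                     "iceball_volume_cm3": res.series.iceball_volume[-1],
                     "lethal_volume_cm3": res.series.lethal_volume[-1]})
    return pd.DataFrame(rows)


def treatment_time_case(Ld: float, V: float, horizon: float = 1200.0,
                        fine_until: float = 120.0, **cfg_kw) -> float:
    """Treatment time (s) for one probe position / inlet velocity: first
    crossing of 0 degC by the minimum artery-surface temperature, or inf
    if the wall never freezes within the horizon.

    The march runs at unscaled time steps while t < ``fine_until`` (short
    treatment times need the fine schedule; probes far from the vessel can
    skip it), then at the configured desk scale.
    """
    cfg_kw.setdefault("cadence", 0.5)
    cfg = CaseConfig.single_probe(Ld=Ld, V=V, t_end=horizon,
                                  stop_when_wall_below=-1.0, **cfg_kw)
    schedule = [(fine_until, 1.0), (float("inf"), cfg.dt_scale)]
    res = run_case(cfg, dt_scale_schedule=schedule)
    return metrics.treatment_time(res.series.time,
                                  res.series.min_wall_temperature,
                                  horizon=horizon)


def run_table3(Ld_values=(10.0, 15.0, 20.0, 30.0, 40.0),
               V_values=(0.01, 0.05, 0.10, 0.20, 0.30),
               horizon: float = 1200.0, **cfg_kw) -> pd.DataFrame:
    """Treatment-time matrix (rows: V, columns: Ld); inf marks cases where
    the artery surface never reaches 0 degC within the horizon."""
    data = {}
    for Ld in Ld_values:
        col = []
        for V in V_values:
            col.append(treatment_time_case(Ld, V, horizon=horizon, **cfg_kw))
        data[f"Ld={Ld:g}mm"] = col
    return pd.DataFrame(data, index=[f"V={v:g}m/s" for v in V_values])


def run_three_probe(V: float = 0.20, Ld: float = 30.0, t_end: float = 1500.0,
                    checkpoint_times=(300.0, 900.0, 1500.0),
                    **cfg_kw) -> CaseResult:
    """Three thin probes on a 20 mm ring around the cylinder axis: separate
    iceballs form and merge into one."""
    cfg_kw.setdefault("h", 2.0)
    cfg = CaseConfig.three_probe(Ld=Ld, V=V, t_end=t_end,
                                 checkpoint_times=list(checkpoint_times),
                                 **cfg_kw)
    res = run_case(cfg)
    counts = {t: metrics.frozen_component_count(f, res.grid)
              for t, f in res.checkpoints.items()}
    res.summary["frozen_components"] = counts
    return res
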