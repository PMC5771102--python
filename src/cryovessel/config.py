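"""Case configuration: one freezing scenario as a plain, serializable record.

All geometric lengths are mm, velocities m/s, times s.  A config fully
determines a run — there is no randomness anywhere in the pipeline — so
re-running the same config reproduces the metric series bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

from .geometry import BifurcationParams, ProbeSpec, three_probe_layout
from .materials import MaterialProperties

__all__ = ["CaseConfig", "load_config", "save_config"]


@dataclass
class CaseConfig:
    """Everything needed to reproduce one simulation case."""

    # geometry (mm / degrees)
    L1: float = 20.0
    L2: float = 80.0
    D0: float = 10.0
    phi: float = 60.0
    Dt: float = 120.0
    Lt: float = 100.0
    takeoff_angle: float | None = 60.0
    lateral_extent: float = 45.0
    arc_radius: float = 5.0
    # probes: list of dicts with Dp, Lp, tip_center, axis (see ProbeSpec)
    probes: list[dict] = field(default_factory=list)
    # flow
    V: float = 0.20
    flow_mode: str = "analytic"      # analytic | solved | none
    mu: float = 2.5e-3
    rho: float = 1050.0
    # discretization
    h: float = 2.5                   # voxel spacing, mm
    dt_scale: float = 10.0           # multiplier on the time-step schedule
    # run control
    t_end: float = 1200.0
    cadence: float = 1.0
    stop_when_wall_below: float | None = None
    checkpoint_times: list[float] = field(default_factory=list)
    sample_points: dict[str, list[float]] = field(default_factory=dict)
    # boundary temperatures (degC)
    T_inlet: float = 37.0
    T_probe: float = -196.0
    # material overrides (SI), e.g. {"omega_cb": 0.0}
    materials: dict[str, float] = field(default_factory=dict)

    # -- derived objects ----------------------------------------------------

    def bifurcation_params(self) -> BifurcationParams:
        return BifurcationParams(L1=self.L1, L2=self.L2, D0=self.D0,
                                 phi=self.phi, Dt=self.Dt, Lt=self.Lt,
                                 takeoff_angle=self.takeoff_angle,
                                 lateral_extent=self.lateral_extent,
                                 arc_radius=self.arc_radius)

    def probe_specs(self) -> list[ProbeSpec]:
        return [ProbeSpec(Dp=p["Dp"], Lp=p["Lp"],
                          tip_center=tuple(p["tip_center"]),
                          axis=tuple(p.get("axis", (0.0, 1.0, 0.0))),
                          Ld=p.get("Ld"))
                for p in self.probes]

    def material_properties(self) -> MaterialProperties:
        return MaterialProperties(**self.materials)

    # -- convenience constructors ------------------------------------------

    @classmethod
    def single_probe(cls, Ld: float, V: float = 0.20, Dp: float = 4.0,
                     Lp: float = 22.0, **kw) -> "CaseConfig":
        """Standard single-probe case: probe along y, tip midpoint on the
        cylinder axis at depth L1 + Ld."""
        cfg = cls(V=V, **kw)
        spec = ProbeSpec.horizontal(Ld=Ld, L1=cfg.L1, Dp=Dp, Lp=Lp)
        cfg.probes = [_probe_dict(spec)]
        return cfg

    @classmethod
    def three_probe(cls, Ld: float = 30.0, V: float = 0.20,
                    ring_radius: float = 20.0, Dp: float = 2.0,
                    Lp: float = 20.0, **kw) -> "CaseConfig":
        cfg = cls(V=V, **kw)
        cfg.probes = [_probe_dict(s) for s in three_probe_layout(
            cfg.bifurcation_params(), Ld=Ld, ring_radius=ring_radius,
            Dp=Dp, Lp=Lp)]
        return cfg

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CaseConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


def _probe_dict(spec: ProbeSpec) -> dict:
    return {"Dp": spec.Dp, "Lp": spec.Lp,
            "tip_center": list(spec.tip_center), "axis": list(spec.axis),
            "Ld": spec.Ld}


def load_config(path) -> CaseConfig:
    with open(path) as f:
        return CaseConfig.from_dict(json.load(f))


def save_config(cfg: CaseConfig, path) -> None:
    with open(path, "w") as f:
        json.dump(cfg.to_dict(), f, indent=2)
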