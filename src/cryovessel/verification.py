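"""Analytic oracles and deterministic fixtures for solver verification.

The phase-change machinery is verified against the classical two-phase
Neumann solution of the planar Stefan problem (sharp freezing front at
``T_m``), and the diffusion operator against the semi-infinite erf
solution.  The fixtures build small labelled grids wired to the boundary
conditions each unit test needs; everything is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.special import erf, erfc

from .geometry import (BifurcationParams, Geometry, Label, LabeledGrid,
                       ProbeSpec, build_geometry, voxelize)
from .materials import MaterialProperties

__all__ = [
    "StefanParams",
    "neumann_stefan_lambda",
    "stefan_front",
    "stefan_temperature",
    "semi_infinite_conduction",
    "make_fixture",
]


@dataclass(frozen=True)
class StefanParams:
    """Planar two-phase freezing: half-space initially liquid at ``T_init``,
    wall at ``x = 0`` held at ``T_wall`` < ``T_m``; a sharp front at the
    melting temperature ``T_m`` advances as ``X(t) = 2 lambda sqrt(alpha_s t)``.

    Capacities are volumetric [J/(m^3 K)] and the latent heat ``Q`` is
    volumetric [J/m^3], matching the effective-capacity tissue model.
    """

    T_init: float = 37.0
    T_wall: float = -196.0
    T_m: float = -4.5
    k_s: float = 2.0        # frozen (solid) conductivity [W/m K]
    k_l: float = 0.5        # unfrozen (liquid) conductivity [W/m K]
    C_s: float = 1.8e6      # frozen volumetric heat capacity [J/m^3 K]
    C_l: float = 3.6e6      # unfrozen volumetric heat capacity [J/m^3 K]
    Q: float = 250.0e6      # volumetric latent heat [J/m^3]

    def __post_init__(self) -> None:
        if not self.T_wall < self.T_m < self.T_init:
            raise ValueError("require T_wall < T_m < T_init")
        for name in ("k_s", "k_l", "C_s", "C_l"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.Q < 0:
            raise ValueError("latent heat must be non-negative")

    @property
    def alpha_s(self) -> float:
        return self.k_s / self.C_s

    @property
    def alpha_l(self) -> float:
        return self.k_l / self.C_l


def stefan_residual(lam: float, p: StefanParams) -> float:
    """Residual of the Neumann transcendental equation at trial ``lam``.

    Derived from the interface energy balance
    ``k_s dT_s/dx - k_l dT_l/dx = Q dX/dt`` at ``x = X(t)`` with the erf
    similarity profiles in each phase; time cancels.
    """
    nu = np.sqrt(p.alpha_s / p.alpha_l)
    solid = (p.k_s * (p.T_m - p.T_wall) * np.exp(-lam**2)
             / (erf(lam) * np.sqrt(np.pi * p.alpha_s)))
    liquid = (p.k_l * (p.T_init - p.T_m) * np.exp(-(lam * nu) ** 2)
              / (erfc(lam * nu) * np.sqrt(np.pi * p.alpha_l)))
    return solid - liquid - p.Q * lam * np.sqrt(p.alpha_s)


def neumann_stefan_lambda(p: StefanParams, tol: float = 1e-12) -> float:
    """Dimensionless front coefficient: the root of the Neumann equation.

    Bracketing root find on (0, 5); the residual is +inf as ``lam -> 0+``
    and negative for large ``lam``, so a sign change always exists for
    valid parameters.
    """
    lo, hi = 1e-8, 5.0
    if stefan_residual(lo, p) <= 0 or stefan_residual(hi, p) >= 0:
        raise ValueError("no sign change in bracket; check Stefan parameters")
    return float(brentq(stefan_residual, lo, hi, args=(p,), xtol=tol,
                        rtol=8.9e-16))


def stefan_front(t, p: StefanParams, lam: float | None = None):
    """Front position ``X(t) = 2 lam sqrt(alpha_s t)`` in metres."""
    if lam is None:
        lam = neumann_stefan_lambda(p)
    return 2.0 * lam * np.sqrt(p.alpha_s * np.asarray(t, dtype=float))


def stefan_temperature(x, t: float, p: StefanParams, lam: float | None = None):
    """Exact Neumann temperature profile at time ``t`` (x in metres, degC)."""
    if t <= 0:
        raise ValueError("t must be positive")
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("x must be non-negative")
    if lam is None:
        lam = neumann_stefan_lambda(p)
    nu = np.sqrt(p.alpha_s / p.alpha_l)
    eta_s = x / (2.0 * np.sqrt(p.alpha_s * t))
    eta_l = x / (2.0 * np.sqrt(p.alpha_l * t))
    T_solid = p.T_wall + (p.T_m - p.T_wall) * erf(eta_s) / erf(lam)
    T_liquid = p.T_init - (p.T_init - p.T_m) * erfc(eta_l) / erfc(lam * nu)
    out = np.where(x <= stefan_front(t, p, lam), T_solid, T_liquid)
    return out if out.ndim else float(out)


def semi_infinite_conduction(x, t: float, T0: float, Ts: float, alpha: float):
    """Single-phase erf solution: half-space at ``T0``, surface held at ``Ts``."""
    if t <= 0:
        raise ValueError("t must be positive")
    x = np.asarray(x, dtype=float)
    out = Ts + (T0 - Ts) * erf(x / (2.0 * np.sqrt(alpha * t)))
    return out if out.ndim else float(out)


def stefan_material_properties(p: StefanParams, band: float = 7.0) -> MaterialProperties:
    """Tissue properties whose effective-capacity model matches ``p`` with a
    transition band of width ``band`` degC centred on ``T_m`` (perfusion and
    metabolism off, as the Stefan problem has no volumetric sources)."""
    return MaterialProperties(
        Ct=p.C_l, Cf=p.C_s, Cb=p.C_l, Qf=p.Q,
        kappa_t=p.k_l, kappa_f=p.k_s, kappa_b=p.k_l,
        omega_cb=0.0, Qm=0.0,
        Tu=p.T_m + band / 2.0, Tl=p.T_m - band / 2.0,
    )


def straight_tube_geometry(D: float, L: float, margin: float = 4.0) -> Geometry:
    """Analytic geometry of a single straight tube along z (no branching):
    lets the flow and conjugate solvers run on the tube fixture."""
    from .geometry import _Branch, _polyline_tangents

    params = BifurcationParams(L1=L / 2.0, L2=L / 2.0, D0=D, phi=60.0,
                               Dt=D + 2.0 * margin, Lt=L,
                               takeoff_angle=0.0, lateral_extent=0.0,
                               arc_radius=min(D, L / 4.0))
    zs = -np.linspace(0.0, L, int(L * 4) + 2)
    pts = np.stack([np.zeros_like(zs), np.zeros_like(zs), zs], axis=1)
    branch = _Branch(pts, _polyline_tangents(pts), D / 2.0, 1.0)
    return Geometry(params=params, probes=[], branches=[branch])


def _grid_from_labels(labels: np.ndarray, h: float) -> LabeledGrid:
    return LabeledGrid(labels=labels, h=float(h),
                       origin=np.array([0.0, 0.0, -labels.shape[2] * h]))


def make_fixture(name: str, **kw):
    """Small deterministic geometries for unit tests.

    Returns ``(grid, config)`` where ``config`` is a dict of objects the
    test needs (geometry, suggested properties, boundary values).

    - ``single_cell``: one adiabatic TISSUE cell (lumped ODE comparisons).
    - ``slab_1d``: N x 1 x 1 tissue slab, first cell a PROBE_TIP so its far
      face is a Dirichlet cold wall at x = h (1D conduction / Stefan runs).
    - ``straight_tube``: cylindrical lumen along z inside a tissue box
      (Poiseuille and conjugate-transfer tests).
    - ``mini_bifurcation``: reduced-size full geometry with one probe,
      < 1e4 cells, for fast end-to-end smoke runs.
    """
    if name == "single_cell":
        labels = np.full((1, 1, 1), Label.TISSUE, dtype=np.uint8)
        grid = _grid_from_labels(labels, kw.get("h", 1.0))
        return grid, {"props": MaterialProperties()}

    if name == "slab_1d":
        n = int(kw.get("n", 100))
        h = float(kw.get("h", 1.0))
        labels = np.full((n, 1, 1), Label.TISSUE, dtype=np.uint8)
        labels[0, 0, 0] = Label.PROBE_TIP
        grid = _grid_from_labels(labels, h)
        stefan = StefanParams()
        return grid, {
            "stefan": stefan,
            "props": stefan_material_properties(stefan, band=kw.get("band", 7.0)),
            "wall_x0": h,  # mm position of the Dirichlet face
        }

    if name == "straight_tube":
        # Tube of diameter D along z, tissue margin around it.
        D = float(kw.get("D", 10.0))
        L = float(kw.get("L", 40.0))
        margin = float(kw.get("margin", 4.0))
        h = float(kw.get("h", 1.0))
        geo = straight_tube_geometry(D, L, margin)
        nxy = 2 * int(round((D / 2.0 + margin) / h)) + 1
        nz = int(round(L / h))
        labels = np.zeros((nxy, nxy, nz), dtype=np.uint8)
        x = (np.arange(nxy) - (nxy - 1) / 2.0) * h
        X, Y = np.meshgrid(x, x, indexing="ij")
        lum = X**2 + Y**2 <= (D / 2.0) ** 2
        labels[:] = Label.TISSUE
        labels[lum, :] = Label.LUMEN
        grid = LabeledGrid(labels=labels, h=h,
                           origin=np.array([-nxy * h / 2.0, -nxy * h / 2.0, -nz * h]))
        return grid, {"D": D, "L": L, "geometry": geo}

    if name == "mini_bifurcation":
        h = float(kw.get("h", 4.0))
        params = BifurcationParams(L1=15.0, L2=45.0, D0=8.0, phi=60.0,
                                   Dt=80.0, Lt=60.0, lateral_extent=25.0,
                                   arc_radius=8.0)
        probe = ProbeSpec.horizontal(Ld=kw.get("Ld", 10.0), L1=params.L1,
                                     Dp=4.0, Lp=16.0)
        geo = build_geometry(params, [probe])
        grid = voxelize(geo, h)
        if grid.labels.size >= 10_000:
            raise AssertionError("mini_bifurcation fixture grew beyond 1e4 cells")
        return grid, {"geometry": geo, "params": params, "probe": probe}

    raise ValueError(f"unknown fixture {name!r}")
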