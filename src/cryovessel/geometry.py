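"""Parametric bifurcated-artery geometry and its voxelization.

A symmetric arterial bifurcation (one straight root tube splitting into two
equal curved daughter tubes, Murray-type cube-law diameters) is embedded in
a cylindrical block of tissue; one or more cylindrical cryoprobes are
inserted perpendicular to the bifurcation plane.  The analytic geometry is
rasterized onto a uniform Cartesian voxel grid by cell-center membership
tests; the resulting labelled grid is the computational domain for the flow
and bioheat solvers.

Coordinate convention: the tissue-cylinder axis is the z-axis, the root
inlet disc lies in the plane z = 0 and depth increases toward negative z;
the bifurcation point is at (0, 0, -L1) and the bifurcation plane is the
x-z plane.  All geometric lengths are millimetres.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "Label",
    "BifurcationParams",
    "ProbeSpec",
    "Geometry",
    "LabeledGrid",
    "InterfaceFaces",
    "GeometryError",
    "PlacementError",
    "ResolutionError",
    "daughter_diameter",
    "build_geometry",
    "voxelize",
    "interface_faces",
]


class GeometryError(ValueError):
    """Invalid geometric parameter."""


class PlacementError(GeometryError):
    """A probe is placed outside the tissue or inside the vessel lumen."""


class ResolutionError(GeometryError):
    """Grid spacing too coarse to resolve a geometric feature."""


class Label(IntEnum):
    EXTERIOR = 0
    TISSUE = 1
    LUMEN = 2
    PROBE_SHAFT = 3
    PROBE_TIP = 4


def daughter_diameter(D0: float) -> float:
    """Diameter of each daughter vessel from the root diameter ``D0`` (mm).

    Symmetric cube-law (Murray-type) branching: ``2 D1^3 = D0^3`` so
    ``D1 = 2**(-1/3) * D0``.
    """
    if D0 <= 0:
        raise GeometryError(f"root diameter must be positive, got {D0}")
    return float(D0) * 2.0 ** (-1.0 / 3.0)


@dataclass(frozen=True)
class BifurcationParams:
    """Dimensions (mm / degrees) of the bifurcation and tissue cylinder.

    ``phi`` is the nominal full angle between the two daughter branches.

    Two daughter-centerline models are available:

    - wide-apex (default, ``takeoff_angle`` set): each daughter leaves the
      bifurcation point at ``takeoff_angle`` degrees from the root axis and
      relaxes exponentially toward vertical,
      ``x(d) = x_e [1 - exp(-tan(theta0) d / x_e)]`` with ``d`` the depth
      below the apex and ``x_e`` = ``lateral_extent``.  The default
      ``takeoff_angle = 60`` reads the bifurcation angle as each daughter's
      take-off from the root axis; the branches then straighten so their
      vertical extent L2 fits inside the tissue cylinder.  Only this kind
      of widely-opening apex leaves tissue between the daughters for a
      probe at the smallest studied probe-bifurcation distances.
    - tangent-arc (``takeoff_angle=None``): circular arcs of radius
      ``arc_radius`` tangent to the root axis at the apex, turning onto a
      straight run at ``phi/2`` from the axis (the full-angle reading).
    """

    L1: float = 20.0
    L2: float = 80.0
    D0: float = 10.0
    phi: float = 60.0
    Dt: float = 120.0
    Lt: float = 100.0
    takeoff_angle: float | None = 60.0
    lateral_extent: float = 45.0
    arc_radius: float = 5.0

    def __post_init__(self) -> None:
        for name in ("L1", "L2", "D0", "Dt", "Lt", "arc_radius"):
            if getattr(self, name) <= 0:
                raise GeometryError(f"{name} must be positive")
        if not 0 < self.phi < 180:
            raise GeometryError(f"phi must lie in (0, 180) degrees, got {self.phi}")
        if abs(self.L1 + self.L2 - self.Lt) > 1e-9 * self.Lt:
            raise GeometryError(
                f"require L1 + L2 == Lt, got {self.L1} + {self.L2} != {self.Lt}"
            )
        if self.D0 >= self.Dt:
            raise GeometryError("root diameter must be smaller than tissue cylinder")
        half = np.radians(self.phi / 2.0)
        if self.arc_radius * np.sin(half) >= self.L2:
            raise GeometryError("arc_radius too large: turn does not fit in L2")
        if self.takeoff_angle is not None:
            if not 0 <= self.takeoff_angle < 90:
                raise GeometryError("takeoff_angle must lie in [0, 90) degrees")
            if self.lateral_extent + self.D1 / 2.0 >= self.Dt / 2.0:
                raise GeometryError(
                    "lateral_extent puts the daughters outside the tissue "
                    "cylinder")

    @property
    def D1(self) -> float:
        return daughter_diameter(self.D0)


@dataclass(frozen=True)
class ProbeSpec:
    """A cylindrical cryoprobe: cryogenic active tip plus adiabatic shaft.

    ``tip_center`` is the midpoint of the active tip (mm); ``axis`` is the
    unit insertion direction, the shaft extending from the tip toward the
    entry point (``+axis`` side).
    """

    Dp: float
    Lp: float
    tip_center: tuple[float, float, float]
    axis: tuple[float, float, float]
    Ld: float | None = None  # distance (mm) probe centerline to bifurcation point

    def __post_init__(self) -> None:
        if self.Dp <= 0 or self.Lp <= 0:
            raise GeometryError("probe diameter and tip length must be positive")
        if self.Ld is not None and self.Ld < 0:
            raise GeometryError("Ld must be non-negative")
        a = np.asarray(self.axis, dtype=float)
        n = np.linalg.norm(a)
        if not np.isfinite(n) or abs(n - 1.0) > 1e-6:
            raise GeometryError("probe axis must be a unit vector")

    @staticmethod
    def horizontal(Ld: float, L1: float = 20.0, Dp: float = 4.0, Lp: float = 22.0) -> "ProbeSpec":
        """Standard single-probe placement: axis along +y (normal to the
        bifurcation plane), active-tip midpoint on the cylinder axis at depth
        ``L1 + Ld`` so the probe centerline passes ``Ld`` below the
        bifurcation point."""
        return ProbeSpec(Dp=Dp, Lp=Lp, tip_center=(0.0, 0.0, -(L1 + Ld)),
                         axis=(0.0, 1.0, 0.0), Ld=Ld)


def three_probe_layout(params: "BifurcationParams", Ld: float = 30.0,
                       ring_radius: float = 20.0, Dp: float = 2.0,
                       Lp: float = 20.0) -> list[ProbeSpec]:
    """Three probes parallel to y, tip midpoints distributed uniformly on a
    circle of ``ring_radius`` mm in the bifurcation (x-z) plane centred on
    the cylinder axis at depth ``L1 + Ld``, polar angles 90/210/330 deg."""
    zc = -(params.L1 + Ld)
    probes = []
    for ang in (90.0, 210.0, 330.0):
        a = np.radians(ang)
        x = ring_radius * np.cos(a)
        z = zc + ring_radius * np.sin(a)
        probes.append(ProbeSpec(Dp=Dp, Lp=Lp, tip_center=(x, 0.0, z),
                                axis=(0.0, 1.0, 0.0), Ld=Ld))
    return probes


@dataclass
class _Branch:
    points: np.ndarray      # (n, 3) polyline samples, mm
    tangents: np.ndarray    # (n, 3) unit downstream tangents
    radius: float           # lumen radius, mm
    mean_speed_factor: float  # branch mean speed / root mean speed


@dataclass
class Geometry:
    """Analytic geometry: branch centerlines, tissue cylinder and probes."""

    params: BifurcationParams
    probes: list[ProbeSpec] = field(default_factory=list)
    branches: list[_Branch] = field(default_factory=list)

    def lumen_radius_bound(self) -> float:
        return max(b.radius for b in self.branches)


def _daughter_centerline(p: BifurcationParams, sign: float, ds: float) -> np.ndarray:
    """Polyline of one daughter centerline down to the bottom plane z = -Lt."""
    if p.phi < 1e-3:  # degenerate: daughters continue straight down the axis
        d = np.arange(0.0, p.L2 + ds, ds)
        d = d[d <= p.L2 + 1e-9]
        return np.stack([np.zeros_like(d), np.zeros_like(d), -p.L1 - d], axis=1)
    if p.takeoff_angle is not None:
        a = np.tan(np.radians(p.takeoff_angle))
        d = np.arange(0.0, p.L2 + ds, ds)
        d = d[d <= p.L2 + 1e-9]
        if p.lateral_extent <= 0 or a <= 0:
            x = np.zeros_like(d)
        else:
            x = sign * p.lateral_extent * (-np.expm1(-a * d / p.lateral_extent))
        return np.stack([x, np.zeros_like(d), -p.L1 - d], axis=1)
    half = np.radians(p.phi / 2.0)
    R = p.arc_radius
    # Arc: center (sign*R, 0, -L1), from angle 0 (pointing -z) to angle `half`.
    thetas = np.arange(0.0, half, ds / max(R, ds))
    arc = np.stack([
        sign * R * (1.0 - np.cos(thetas)),
        np.zeros_like(thetas),
        -p.L1 - R * np.sin(thetas),
    ], axis=1)
    # Straight continuation until the bottom plane.
    d = np.array([sign * np.sin(half), 0.0, -np.cos(half)])
    start = np.array([sign * R * (1.0 - np.cos(half)), 0.0, -p.L1 - R * np.sin(half)])
    run = (-p.Lt - start[2]) / d[2]
    ss = np.arange(0.0, run + ds, ds)
    ss = ss[start[2] + ss * d[2] >= -p.Lt - 1e-9]
    straight = start[None, :] + ss[:, None] * d[None, :]
    return np.vstack([arc, straight])


def _polyline_tangents(points: np.ndarray) -> np.ndarray:
    t = np.gradient(points, axis=0)
    n = np.linalg.norm(t, axis=1, keepdims=True)
    return t / np.maximum(n, 1e-30)


def _segment_point_distance(p0: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Distances from points ``p0`` (n,3) to segment a-b."""
    ab = b - a
    tt = np.clip((p0 - a) @ ab / (ab @ ab), 0.0, 1.0)
    proj = a + tt[:, None] * ab
    return np.linalg.norm(p0 - proj, axis=1)


def build_geometry(params: BifurcationParams, probes: list[ProbeSpec] | None = None,
                   ds: float = 0.25) -> Geometry:
    """Construct the analytic bifurcation + tissue + probe geometry.

    Validates probe placement: a probe whose tip lies outside the tissue
    cylinder, or whose centerline penetrates the vessel lumen, is rejected.
    Surface-to-surface contact between a probe and the lumen (which occurs
    for the smallest probe-bifurcation distances) is tolerated with a
    warning; the voxel label priority resolves the contact cells.
    """
    probes = list(probes or [])
    p = params
    root_pts = np.stack([
        np.zeros(int(p.L1 / ds) + 2),
        np.zeros(int(p.L1 / ds) + 2),
        -np.linspace(0.0, p.L1, int(p.L1 / ds) + 2),
    ], axis=1)
    branches = [_Branch(root_pts, _polyline_tangents(root_pts), p.D0 / 2.0, 1.0)]
    # Mean daughter speed = (Q/2) / (pi R1^2) = V * 2**(-1/3).
    for sign in (+1.0, -1.0):
        pts = _daughter_centerline(p, sign, ds)
        branches.append(_Branch(pts, _polyline_tangents(pts), p.D1 / 2.0,
                                2.0 ** (-1.0 / 3.0)))
    geo = Geometry(params=p, probes=probes, branches=branches)

    for probe in probes:
        c = np.asarray(probe.tip_center)
        if np.hypot(c[0], c[1]) > p.Dt / 2.0 or not (-p.Lt <= c[2] <= 0.0):
            raise PlacementError(f"probe tip center {tuple(c)} outside tissue cylinder")
        axis = np.asarray(probe.axis)
        a = c - 0.5 * probe.Lp * axis
        b = c + 0.5 * probe.Lp * axis
        for br in geo.branches:
            d = np.minimum(_segment_point_distance(br.points, a, b),
                           np.linalg.norm(br.points - c, axis=1))
            dmin = float(d.min())
            if dmin < br.radius:
                raise PlacementError(
                    f"probe centerline penetrates the lumen (clearance "
                    f"{dmin - br.radius:.2f} mm)")
            overlap = (br.radius + probe.Dp / 2.0) - dmin
            if overlap > 1e-9:
                warnings.warn(
                    f"probe surface overlaps lumen surface by {overlap:.2f} mm; "
                    "contact resolved by voxel label priority", stacklevel=2)
    return geo


@dataclass
class LabeledGrid:
    """Uniform Cartesian voxel grid with per-cell region labels.

    ``labels`` has shape (nx, ny, nz); cell centers are at
    ``origin + (ijk + 0.5) * h`` (mm).  k increases with z: k = 0 is the
    bottom (outlet) layer, k = nz-1 touches the inlet plane z = 0.
    """

    labels: np.ndarray
    h: float                  # spacing, mm
    origin: np.ndarray        # lower corner, mm

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.labels.shape)

    def axis_centers(self, axis: int) -> np.ndarray:
        n = self.labels.shape[axis]
        return self.origin[axis] + (np.arange(n) + 0.5) * self.h

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return np.meshgrid(*(self.axis_centers(a) for a in range(3)), indexing="ij")

    def counts(self) -> dict[str, int]:
        return {lab.name: int(np.count_nonzero(self.labels == lab)) for lab in Label}

    def volumes_cm3(self) -> dict[str, float]:
        cell = (self.h * 0.1) ** 3  # mm^3 -> cm^3
        return {k: v * cell for k, v in self.counts().items()}

    def cell_volume_m3(self) -> float:
        return (self.h * 1e-3) ** 3

    def save_vtk(self, path, cell_data: dict[str, np.ndarray] | None = None) -> None:
        from .vtkio import write_structured_points
        data = {"label": self.labels.astype(np.int32)}
        if cell_data:
            data.update(cell_data)
        write_structured_points(path, self, data)


def voxelize(geometry: Geometry, h: float) -> LabeledGrid:
    """Rasterize the analytic geometry to a labelled voxel grid.

    Each cell is labelled by a membership test of its center, with priority
    PROBE_TIP > PROBE_SHAFT > LUMEN > TISSUE > EXTERIOR.  The x and y axes
    carry an odd number of cells so that a cell-center column lies exactly
    on the cylinder axis, which keeps a probe of diameter >= h resolvable.
    """
    p = geometry.params
    if h <= 0:
        raise ResolutionError("spacing h must be positive")
    for probe in geometry.probes:
        if h > probe.Dp + 1e-12:
            raise ResolutionError(
                f"h = {h} mm too coarse to resolve probe diameter {probe.Dp} mm")
    nxy = 2 * int(round(p.Dt / (2.0 * h))) + 1
    nz = max(int(round(p.Lt / h)), 1)
    if nxy < 3 or nz < 2:
        raise ResolutionError(f"h = {h} mm produces a degenerate {nxy}x{nxy}x{nz} grid")
    origin = np.array([-nxy * h / 2.0, -nxy * h / 2.0, -nz * h])
    labels = np.zeros((nxy, nxy, nz), dtype=np.uint8)

    xs = origin[0] + (np.arange(nxy) + 0.5) * h
    zs = origin[2] + (np.arange(nz) + 0.5) * h
    X, Y, Z = np.meshgrid(xs, xs, zs, indexing="ij")
    inside = (X**2 + Y**2 <= (p.Dt / 2.0) ** 2) & (Z >= -p.Lt) & (Z <= 0.0)
    labels[inside] = Label.TISSUE

    centers = np.stack([X[inside], Y[inside], Z[inside]], axis=1)
    lumen = np.zeros(len(centers), dtype=bool)
    for br in geometry.branches:
        tree = cKDTree(br.points)
        d, _ = tree.query(centers, k=1, workers=-1)
        lumen |= d <= br.radius
    li = np.where(inside)
    lab_flat = labels[li]
    lab_flat[lumen] = Label.LUMEN
    labels[li] = lab_flat

    for probe in geometry.probes:
        c = np.asarray(probe.tip_center)
        axis = np.asarray(probe.axis)
        s = (X - c[0]) * axis[0] + (Y - c[1]) * axis[1] + (Z - c[2]) * axis[2]
        perp2 = ((X - c[0]) ** 2 + (Y - c[1]) ** 2 + (Z - c[2]) ** 2) - s**2
        # a probe thinner than the cell diagonal still must rasterize to a
        # connected one-cell-wide run; the bioheat solver normalizes the
        # resulting Dirichlet surface back to the analytic tip area
        r_eff = max(probe.Dp / 2.0, np.sqrt(0.5) * h * 1.0001)
        inrad = perp2 <= r_eff**2 + 1e-12
        tip = inrad & (np.abs(s) <= probe.Lp / 2.0) & (labels != Label.EXTERIOR)
        shaft = inrad & (s > probe.Lp / 2.0) & (labels != Label.EXTERIOR)
        if not tip.any():
            raise ResolutionError(
                f"h = {h} mm produced no PROBE_TIP cell for probe at "
                f"{probe.tip_center}")
        labels[shaft] = Label.PROBE_SHAFT
        labels[tip] = Label.PROBE_TIP
    return LabeledGrid(labels=labels, h=float(h), origin=origin)


@dataclass
class InterfaceFaces:
    """Faces separating LUMEN cells from TISSUE cells (the artery surface).

    ``lumen``/``tissue`` hold the flat (C-order) cell indices on each side
    of every face; ``axis`` the face-normal axis (0, 1, 2); ``area`` the
    face area in m^2.  Each face is listed once.
    """

    lumen: np.ndarray
    tissue: np.ndarray
    axis: np.ndarray
    area: float

    def __len__(self) -> int:
        return len(self.lumen)


def probe_surface_scale(grid: LabeledGrid, probes: list[ProbeSpec]) -> float:
    """Ratio of the analytic probe active-tip surface area to its voxel
    (stair-step) face area.

    Stair-stepping inflates curved surface areas (up to 4/pi for a
    cylinder), so without correction a voxelized probe extracts more heat
    than the cylinder it represents.  The bioheat solver multiplies the
    probe-face Dirichlet conductance by this factor — the standard
    embedded-boundary area weighting.
    """
    if not probes:
        return 1.0
    lab = grid.labels
    active = (lab == Label.TISSUE) | (lab == Label.LUMEN)
    tip = lab == Label.PROBE_TIP
    nfaces = 0
    for ax in range(3):
        a = [slice(None)] * 3
        b = [slice(None)] * 3
        a[ax] = slice(None, -1)
        b[ax] = slice(1, None)
        nfaces += int((active[tuple(a)] & tip[tuple(b)]).sum())
        nfaces += int((tip[tuple(a)] & active[tuple(b)]).sum())
    if nfaces == 0:
        return 1.0
    # lateral area + one exposed end cap (the other end meets the shaft)
    analytic = sum(np.pi * p.Dp * (p.Lp + p.Dp / 4.0) for p in probes)  # mm^2
    return float(analytic / (nfaces * grid.h**2))


def interface_faces(grid: LabeledGrid) -> InterfaceFaces:
    lab = grid.labels
    flat = np.arange(lab.size).reshape(lab.shape)
    lum, tis, axes = [], [], []
    for ax in range(3):
        sl_a = [slice(None)] * 3
        sl_b = [slice(None)] * 3
        sl_a[ax] = slice(None, -1)
        sl_b[ax] = slice(1, None)
        a, b = lab[tuple(sl_a)], lab[tuple(sl_b)]
        fa, fb = flat[tuple(sl_a)], flat[tuple(sl_b)]
        m1 = (a == Label.LUMEN) & (b == Label.TISSUE)
        m2 = (a == Label.TISSUE) & (b == Label.LUMEN)
        lum.extend([fa[m1], fb[m2]])
        tis.extend([fb[m1], fa[m2]])
        axes.extend([np.full(m1.sum(), ax), np.full(m2.sum(), ax)])
    return InterfaceFaces(
        lumen=np.concatenate(lum) if lum else np.empty(0, dtype=int),
        tissue=np.concatenate(tis) if tis else np.empty(0, dtype=int),
        axis=np.concatenate(axes) if axes else np.empty(0, dtype=int),
        area=(grid.h * 1e-3) ** 2,
    )
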