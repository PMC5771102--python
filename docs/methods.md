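# Methods

`cryovessel` simulates the freezing of perfused tissue around a large
bifurcated artery during cryosurgery: a three-dimensional transient
conjugate heat-transfer problem in which one or more cryoprobes held at
liquid-nitrogen temperature grow an iceball that interacts with the warm
arterial blood stream. This note records the model, its numerical
treatment, the parameters that matter, and the choices made where the
problem statement was genuinely open.

## Physical model

**Tissue.** The Pennes bioheat equation with the effective (apparent)
heat-capacity treatment of freezing:

    Ĉ(T) ∂T/∂t = ∇·(κ̂(T) ∇T) + ω̂(T) C_b (T_cb − T) + Q̂_m(T)

The phase change is smeared over a transition band [T_l, T_u] = [−8, −1] °C:
inside the band the apparent capacity carries the latent-heat spike
Q_f/(T_u−T_l) on top of a linear blend between the frozen (C_f) and
unfrozen (C_t) capacities, and the conductivity blends linearly between
κ_t and κ_f. Capillary perfusion (ω_cb C_b (T_cb − T)) and metabolic heat
(Q_m) switch off as soon as the tissue enters the band — capillary flow
stops as ice forms.

**Blood.** The lumen of the bifurcated artery carries steady, laminar,
temperature-independent Newtonian flow; its energy balance is

    C_b (∂T/∂t + V·∇T) = ∇·(κ_b ∇T)

with no phase change (the flowing blood stays well above the band in all
studied cases). The two fields couple through flux continuity at the
lumen–tissue interface (conjugate heat transfer).

**Default constants** (SI; temperatures °C), standard liver-tissue values:
C_t = C_b = 3.6 MJ/(m³ K), C_f = 1.8 MJ/(m³ K), Q_f = 250 MJ/m³,
κ_t = κ_b = 0.5 W/(m K), κ_f = 2 W/(m K), ω_cb = 5·10⁻⁴ s⁻¹,
Q_m = 420 W/m³ (treated as a volumetric heat-generation *rate*; at
cryogenic gradients its influence is negligible either way),
T_cb = 37 °C, T_u = −1 °C, T_l = −8 °C, μ = 2.5·10⁻³ Pa·s.
Blood density is required by the momentum equation but is not part of the
thermal parameter set; ρ = 1050 kg/m³.

**Boundary conditions.** Root inlet: parabolic profile
u(r) = 2V[1 − (2r/D₀)²] at T₀ = 37 °C; daughter outlets: zero reference
pressure, zero-gradient (advective) thermal outflow; outer tissue shell
and probe shafts: adiabatic; probe active tips: fixed T_p = −196 °C.
Initial condition: 37 °C everywhere.

## Geometry

A symmetric bifurcation — straight root tube (D₀ = 10 mm, length
L₁ = 20 mm) splitting into two equal daughters (cube law 2D₁³ = D₀³,
D₁ = 7.94 mm, vertical extent L₂ = 80 mm) — embedded in a tissue cylinder
(D_t = 120 mm, L_t = 100 mm). The vessel wall has zero thickness.
Coordinates: the cylinder axis is z, the inlet disc is z = 0, depth is
−z, the bifurcation point sits at (0, 0, −L₁), and the bifurcation plane
is x–z.

**Daughter centerline shape.** The upstream parametric vessel model this
geometry abstracts is not fully specified by its printed dimensions, and
the phrase "the angle of bifurcation" is ambiguous between the full
inter-daughter angle and each daughter's angle from the root axis. The
two readings differ qualitatively: with the full-angle reading (30° per
side, implemented as circular arcs tangent to the root axis —
`takeoff_angle=None`) the daughters separate so slowly that a standard
4 mm probe midway between them at the closest studied distance
(L_d = 10 mm) geometrically overlaps the lumen, which contradicts the
finite freezing margins of exactly those cases. The default model
therefore reads the bifurcation angle as the per-daughter take-off from
the axis: each centerline leaves the apex at 60° and relaxes
exponentially toward vertical, x(d) = x_e[1 − exp(−tan 60°·d/x_e)] with
lateral extent x_e = 45 mm, which keeps the daughters inside the tissue
cylinder over their full 80 mm vertical extent. With this shape the
probe-to-artery clearances at L_d = 10/15/20 mm match, through the
Neumann front-position relation X(t) = 2λ√(α_s t), the conduction-limited
freezing margins those cases exhibit at the slowest inlet velocity; no
other quantity was used to fix the shape.

**Probes.** A probe is a cylinder of diameter D_p with a cryogenic active
tip of length L_p and an adiabatic shaft; the standard single probe lies
along y (normal to the bifurcation plane) with its tip midpoint on the
cylinder axis at depth L₁ + L_d. The three-probe layout places tip
midpoints at polar angles 90°/210°/330° on a 20 mm-radius circle in the
bifurcation plane centred on the axis at depth L₁ + L_d, all axes
parallel to y. A probe whose centerline would pass through the lumen is
rejected; mere surface contact (which the closest arc-model cases force)
warns and is resolved by voxel label priority.

## Discretization

**Grid.** Uniform Cartesian voxels of spacing h; each cell is labelled
(tissue / lumen / probe tip / probe shaft / exterior) by a cell-center
membership test with priority tip > shaft > lumen > tissue. The x and y
axes carry an odd cell count so a cell-center column lies exactly on the
cylinder axis, keeping a probe of diameter ≥ h resolvable. Voxelized
volumes converge first order in h; the stair-step representation of
curved interfaces carries two known systematic biases documented by the
test suite: the lateral surface area of a cylinder converges to 4/π times
the true area, and the no-slip boundary is positioned only to ±h/2.

**Flow.** Two interchangeable routes produce the divergence-free face
velocities on the staggered (MAC) grid:
*analytic* (default for desk runs): Poiseuille profiles oriented along
the local centerline tangent, branch mean speeds from the cube-law flux
split (daughters carry half the flux each at mean speed 2^(−1/3) V),
blended near the junction and projected to exact discrete mass
conservation (sparse-LU pressure solve; inlet flux held at V·π(D₀/2)²);
*solved*: incompressible Navier–Stokes marched to steady state by Chorin
pseudo-time projection — explicit first-order-upwind convection, central
diffusion, tangential ghost reflection for stair-step no-slip, exact
pressure projection each step, convergence when the max velocity change
over 100 steps falls below 10⁻⁴ V. The solved route reproduces the
qualitative junction hemodynamics (apex stagnation, recirculation at the
outer daughter walls, profiles skewed toward the inner walls) and a 50/50
outlet split to machine precision on the symmetric geometry; Re = ρVD₀/μ
(840 at V = 0.2 m/s) is reported per run and asserted laminar. The flow
is solved once and frozen for the whole freezing transient.

**Bioheat.** Finite volumes, backward Euler, one linear system over
tissue + lumen cells per step (no domain partitioning): per-face
harmonic-mean conductivity (tissue κ̂ at the current iterate), first-order
upwind advection on the precomputed face velocities, Dirichlet probe and
inlet values applied at half-cell distance. The phase-change nonlinearity
is iterated with a Newton-type enthalpy linearization: the apparent
capacity is the local slope and the right-hand side carries the enthalpy
residual H(T_it) − H(T_old) from the closed-form enthalpy integral, so
the latent heat released over a step is exact at convergence no matter
how many band temperatures the step jumps; updates entering the band from
outside are clamped at the near edge so the next iterate sees the
latent-heat branch. Tolerance 10⁻³ °C max change, cap 50 iterations
(typically 3–4). A plain Picard iteration with capacity under-relaxation
flip-flops across the band at the freezing front and was discarded.
Linear systems: BiCGStab with a block preconditioner — Jacobi on tissue
plus an exact LU of the small lumen block, which removes the stiffness of
the advection chain along the vessel (a handful of Krylov iterations per
solve); direct sparse solve below 4000 unknowns.

**Time stepping.** The nonuniform schedule Δt = 0.005 s (t < 1 s),
0.01 s (1–5 s), 0.05 s (5–100 s), 0.1 s (t > 100 s) resolves the violent
early transient near the probe; a scale factor multiplies the schedule
(desk runs use 10). Treatment-time studies always run the first 120 s
unscaled so crossings of ~10 s are resolved.

**Fidelity modes.** Desk: h = 2.5 mm, schedule scale 10, analytic flow —
a 20-minute freeze in under a minute of CPU. Convergence: h = 1 mm,
scale 1, solved flow. Freezing volumes and their parameter trends are
stable at desk resolution, but wall-freezing (treatment-time) studies are
not: the artery-surface temperature estimate converges from above as the
near-wall layer refines, so those studies run at h = 1.25 mm. The
three-probe layout runs at h = 2 mm; its 2 mm probes rasterize to a
one-cell-wide run whose Dirichlet coupling is normalized to the analytic
tip area (the same embedded-boundary area weighting applied to every
probe, which removes the stair-step surface-area bias of the voxelized
tip).

## Observables

- **Iceball / lethal volume**: tissue at or below 0 °C / −40 °C.
  Sub-cell estimate: along every tissue–tissue face whose endpoint
  temperatures straddle the threshold the iso-surface position is
  interpolated linearly; per-cell frozen fractions are clamped to [0, 1]
  (a pure face-additive correction can go negative for barely-frozen
  cells with several warm neighbors at coarse h). Converges ~O(h²) on
  smooth fields vs ~O(h) for plain counting, which remains available for
  sensitivity checks. At very coarse resolution the estimate can wiggle
  transiently by a few voxels while the count is monotone.
- **Artery-surface heat flux**: Σ over lumen–tissue faces of
  κ_harm (T_lumen − T_tissue)/h · h², positive from blood into tissue.
- **Minimum artery-surface temperature**: the wall has zero thickness, so
  the surface temperature at each interface face is reconstructed from
  flux continuity, T_face = (κ_b T_lumen + κ̂_t T_tissue)/(κ_b + κ̂_t),
  and the minimum is taken over faces. This estimator is the solver's own
  implicit face value and converges to the surface temperature; the
  lumen-cell-center alternative carries a warm half-cell bias that at
  h = 2.5 mm is large enough to miss wall-freezing events entirely.
- **Treatment time**: first crossing of 0 °C by the minimum artery-surface
  temperature, linearly interpolated between samples (default cadence
  1 s; 0.5 s for treatment-time studies); "exceeds horizon" (inf) if no
  crossing within the study horizon (20 min).
- **Point temperatures**: trilinear interpolation of cell-centered values,
  exact on linear fields; NaN (probe/exterior) corners are dropped with
  weight renormalization.
- **Iceball connectivity** (three-probe study): connected components of
  the frozen tissue mask, 26-connectivity.

## Verification

Self-contained analytic oracles, no external data:

- **Neumann–Stefan**: the classical two-phase planar freezing solution.
  The transcendental front coefficient λ is bracketed and solved to
  10⁻¹² and independently checked by a residual sign scan; the solver,
  run on a 1D slab fixture with material properties matched to the sharp
  front (band centred on T_m = −4.5 °C, sources off), reproduces the
  front position within 7.4 %, 1.9 %, 1.0 % at h = 2, 1, 0.5 mm
  (observed order ≥ 1; the plateau reflects the deliberately smeared
  7 °C transition band vs the sharp-front oracle).
- **erf conduction**: the fully-frozen slab (no band crossing) against
  the semi-infinite single-phase solution.
- **Energy**: the domain enthalpy change equals the time-integrated
  boundary + source power to well under 0.5 % (exact at Picard
  convergence by construction of the chord scheme).
- **Poiseuille**: the steady solver's developed tube profile matches the
  analytic parabola to 1.3 % (L2) away from the stair-step boundary ring;
  cells whose centers lie within h/2 of the nominal wall are excluded
  from the comparison because the voxel wall position is only defined to
  that tolerance.
- **Mass and symmetry**: inlet/outlet flux balance to machine precision
  (exact projection); mirror-symmetric fields on the symmetric geometry.

## Known limitations

- Stair-step walls: no body-fitted or cut-cell treatment; surface areas
  carry the 4/π bias (the reported artery-surface flux inherits it) and
  near-wall velocity/temperature boundary layers are first-order.
- The blood-side thermal boundary layer (~0.3 mm) is unresolved at desk
  resolution; artery-surface temperatures are bracketed by the face and
  cell-center estimators, which still differ noticeably at h ≥ 1.25 mm.
  In consequence the model under-delivers convective heat at the vessel
  wall: freezing volumes near the artery run high and the wall freezes in
  configurations where a boundary-layer-resolving model keeps it a few
  degrees above zero.
- Advection is first-order upwind (numerically diffusive); the
  deferred-correction second-order option was not implemented.
- Single freeze only: no thaw/refreeze cycles, no cryoprobe refrigerant
  model, no Arrhenius damage integral beyond the −40 °C lethal threshold,
  no nanoparticle or external-field wall protection.
- The daughter-centerline shape beyond its take-off angle and lateral
  extent is a modelling choice; freezing volumes are weakly, and
  treatment times strongly, sensitive to it.
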