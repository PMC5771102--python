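# cryovessel

Three-dimensional simulation of cryosurgical freezing next to a large
bifurcated artery.

During cryoablation, one or more cryoprobes held at liquid-nitrogen
temperature (−196 °C) grow an "iceball" of frozen tissue. A thermally
significant artery running through the target region continuously
delivers heat at body temperature, deforming the iceball, limiting the
destroyed volume, and protecting (or failing to protect) its own wall
from freezing. `cryovessel` models this interaction for a symmetric
arterial bifurcation embedded in a tissue cylinder, for researchers in
bioheat transfer and thermal-therapy planning who need a scriptable,
fully testable alternative to a commercial CFD setup.

## Model

Tissue follows the Pennes bioheat equation with the effective
heat-capacity treatment of freezing,

    Ĉ(T) ∂T_t/∂t = ∇·(κ̂(T) ∇T_t) + ω̂ C_b (T_cb − T_t) + Q̂_m ,

where the apparent capacity Ĉ carries the latent heat Q_f across the
transition band [T_l, T_u] = [−8, −1] °C and perfusion/metabolism switch
off below T_u. The arterial lumen carries steady laminar blood
(parabolic inlet u(r) = 2V[1 − (2r/D₀)²], cube-law daughters
D₁ = 2^(−1/3) D₀) with energy balance

    C_b (∂T_b/∂t + V·∇T_b) = ∇·(κ_b ∇T_b) ,

coupled to the tissue through the vessel surface (conjugate heat
transfer). Everything is discretized by finite volumes on a uniform
Cartesian voxel grid, backward Euler in time with the nonuniform
schedule Δt = 0.005…0.1 s, and a Newton-type enthalpy iteration for the
latent-heat nonlinearity. See `docs/methods.md` for the full model,
numerics and limitations.

## Worked example

Freeze for 20 minutes with a single 4 mm probe 20 mm below the
bifurcation point, root inlet velocity 0.20 m/s, desk resolution:

```python
from cryovessel.config import CaseConfig
from cryovessel.experiments import run_case

cfg = CaseConfig.single_probe(Ld=20.0, V=0.20, t_end=1200.0)
res = run_case(cfg)
s = res.series
print(f"iceball  {s.iceball_volume[-1]:.1f} cm^3")
print(f"lethal   {s.lethal_volume[-1]:.1f} cm^3")
print(f"min artery-surface temperature {min(s.min_wall_temperature):.1f} C")
```

which prints (desk fidelity: h = 2.5 mm voxels, 10× time-step scale,
analytic flow; about a minute of CPU):

```
iceball  43.2 cm^3
lethal   7.8 cm^3
min artery-surface temperature -9.9 C
```

The iceball is the tissue at or below 0 °C; the lethal volume is the
part at or below −40 °C, the threshold for certain cell destruction.
The minimum artery-surface temperature dropping below 0 °C signals
freezing injury to the vessel wall — at this probe-vessel distance the
wall is not safe, and the treatment-time studies
(`cryovessel.experiments.run_table3`) report how long freezing may
proceed before the wall reaches 0 °C for each probe distance and inlet
velocity.

The same machinery runs the parameter studies: `run_table1` /
`run_table2` (iceball and lethal volumes vs probe distance and inlet
velocity), `run_table3` (treatment-time matrix) and `run_three_probe`
(three thin probes on a ring, separate iceballs merging into one). The
`cryovessel` command line exposes them (`cryovessel table1 --fidelity
desk --out out/`), and `cryovessel verify` runs the analytic-oracle
convergence report (freezing-front position against the exact
Neumann–Stefan solution).

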