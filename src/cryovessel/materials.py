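"""Thermophysical properties of perfused tissue and blood with phase change.

The freezing of tissue is modelled with the effective (apparent) heat
capacity method: instead of tracking a sharp front, the volumetric heat
capacity is inflated over a transition band ``[T_l, T_u]`` so that its
integral across the band carries the volumetric latent heat ``Q_f``.
Conductivity is blended linearly across the band, and the Pennes perfusion
and metabolic source terms switch off once the tissue has entered the
transition band (capillary flow stops as ice forms).

All quantities are SI: volumetric heat capacities in J/(m^3 K),
conductivities in W/(m K), latent heat in J/m^3, perfusion rate in 1/s,
metabolic heat in W/m^3, temperatures in degrees Celsius.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "MaterialProperties",
    "effective_heat_capacity",
    "effective_conductivity",
    "effective_sources",
    "enthalpy",
]


@dataclass(frozen=True)
class MaterialProperties:
    """Tissue/blood constants for the bioheat model.

    Defaults are standard liver-tissue values used throughout the
    cryosurgery literature.
    """

    Ct: float = 3.6e6       # unfrozen tissue volumetric heat capacity [J/m^3 K]
    Cf: float = 1.8e6       # frozen tissue volumetric heat capacity [J/m^3 K]
    Cb: float = 3.6e6       # blood volumetric heat capacity [J/m^3 K]
    Qf: float = 250.0e6     # volumetric latent heat of freezing [J/m^3]
    kappa_t: float = 0.5    # unfrozen tissue conductivity [W/m K]
    kappa_f: float = 2.0    # frozen tissue conductivity [W/m K]
    kappa_b: float = 0.5    # blood conductivity [W/m K]
    omega_cb: float = 5.0e-4  # capillary blood perfusion rate [1/s]
    Qm: float = 420.0       # metabolic volumetric heat generation [W/m^3]
    Tu: float = -1.0        # upper phase-transition temperature [degC]
    Tl: float = -8.0        # lower phase-transition temperature [degC]
    Tcb: float = 37.0       # perfusing (capillary) blood temperature [degC]

    def __post_init__(self) -> None:
        if not self.Tl < self.Tu:
            raise ValueError(f"require Tl < Tu, got Tl={self.Tl}, Tu={self.Tu}")
        for name in ("Ct", "Cf", "Cb", "Qf", "kappa_t", "kappa_f", "kappa_b"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.omega_cb < 0:
            raise ValueError("omega_cb must be non-negative")


def _band_fraction(T, props: MaterialProperties):
    return (np.asarray(T, dtype=float) - props.Tl) / (props.Tu - props.Tl)


def effective_heat_capacity(T, props: MaterialProperties):
    """Apparent volumetric heat capacity [J/(m^3 K)] at temperature ``T``.

    Piecewise: ``Cf`` below the band, ``Ct`` above, and inside the band the
    latent-heat spike ``Qf/(Tu-Tl)`` plus the linear sensible blend between
    ``Cf`` and ``Ct``.  Accepts scalars or arrays.
    """
    T = np.asarray(T, dtype=float)
    f = _band_fraction(T, props)
    dT = props.Tu - props.Tl
    band = props.Qf / dT + props.Cf + (props.Ct - props.Cf) * f
    out = np.where(T < props.Tl, props.Cf, np.where(T > props.Tu, props.Ct, band))
    return out if out.ndim else float(out)


def effective_conductivity(T, props: MaterialProperties):
    """Apparent tissue conductivity [W/(m K)]: linear blend across the band."""
    T = np.asarray(T, dtype=float)
    f = np.clip(_band_fraction(T, props), 0.0, 1.0)
    out = props.kappa_f + (props.kappa_t - props.kappa_f) * f
    return out if out.ndim else float(out)


def effective_sources(T, props: MaterialProperties):
    """Pennes source terms ``(perfusion heat, metabolic heat)`` in W/m^3.

    Both vanish for ``T <= Tu`` (capillary perfusion and metabolism stop as
    soon as the tissue enters the transition band).
    """
    T = np.asarray(T, dtype=float)
    alive = T > props.Tu
    perf = np.where(alive, props.omega_cb * props.Cb * (props.Tcb - T), 0.0)
    met = np.where(alive, props.Qm, 0.0)
    if perf.ndim:
        return perf, met
    return float(perf), float(met)


def enthalpy(T, props: MaterialProperties):
    """Volumetric enthalpy ``H(T) = \\int_{Tl}^{T} C_hat dT'`` in J/m^3.

    Reference ``H(Tl) = 0``.  Closed-form integral of the apparent heat
    capacity; used for the energy-conserving chord (secant) capacity in the
    implicit solver and for verification of the latent-heat content.
    """
    T = np.asarray(T, dtype=float)
    dT = props.Tu - props.Tl
    x = T - props.Tl
    below = props.Cf * x
    band = props.Qf * x / dT + props.Cf * x + 0.5 * (props.Ct - props.Cf) * x**2 / dT
    H_Tu = props.Qf + props.Cf * dT + 0.5 * (props.Ct - props.Cf) * dT
    above = H_Tu + props.Ct * (T - props.Tu)
    out = np.where(T < props.Tl, below, np.where(T > props.Tu, above, band))
    return out if out.ndim else float(out)
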