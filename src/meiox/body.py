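"""Steady-state oxygen inside a cylindrical meiofaunal body.

A worm-shaped organism (the canonical case is a nematode) is modelled as an
infinite cylinder of radius R that takes up oxygen by molecular diffusion
through its body wall and consumes it at a constant volumetric rate Q
throughout its tissue.  At steady state the radial oxygen profile is the
classical parabola

    C(r) = AW - (Q / 4D) * (R**2 - r**2)

with AW the ambient pore-water concentration at the wall and D the effective
tissue diffusivity.  From this follow three quantities of ecological
interest:

* the **critical thickness** 2*R_crit = 4*sqrt(D*AW/Q), the widest body whose
  centre is still oxygenated;
* the critical thickness as a function of sediment depth, obtained by
  composing the above with a pore-water O2(z) profile; and
* the **oxygen residence time** tau = Cbar/Q, the turnover time of the body
  oxygen inventory (Cbar is the cross-sectional mean concentration).

Bodies wider than the critical thickness develop an anoxic core; those
geometries raise :class:`AnoxicCoreError` rather than solving the
moving-boundary problem, because the steady-state balance above only holds
while the whole cross-section respires.

Field units (µmol l⁻¹, µm, mm, mol l⁻¹ d⁻¹) at the interface; SI internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Literal

import numpy as np

from .units import (
    m_to_um,
    mol_l_d_to_mol_m3_s,
    mol_m3_to_umol_l,
    um_to_m,
    umol_l_to_mol_m3,
)

__all__ = [
    "AnoxicCoreError",
    "BodyModelParams",
    "BodyGeometry",
    "RadialProfile",
    "SedimentProfile",
    "radial_o2_profile",
    "critical_thickness",
    "critical_thickness_vs_depth",
    "residence_time",
    "make_sediment_profile",
]


class AnoxicCoreError(ValueError):
    """Body is wider than the critical thickness: its centre would be anoxic."""


@dataclass(frozen=True)
class BodyModelParams:
    """Physiology and environment of the body-oxygen model.

    Parameters
    ----------
    aw : ambient pore-water O2 concentration [µmol l⁻¹].
    q : volumetric tissue respiration [mol O2 l⁻¹ d⁻¹]; 0.5 is the
        literature value for active meiofaunal tissue.
    d : effective O2 diffusivity of body tissue [m² s⁻¹]; default is the
        order of O2 diffusivity in water/tissue at 20 °C.
    """

    aw: float
    q: float = 0.5
    d: float = 1.0e-9

    def __post_init__(self) -> None:
        if self.aw < 0:
            raise ValueError(f"ambient O2 must be >= 0, got {self.aw}")
        if self.q <= 0:
            raise ValueError(f"respiration rate must be > 0, got {self.q}")
        if self.d <= 0:
            raise ValueError(f"diffusivity must be > 0, got {self.d}")

    @property
    def aw_si(self) -> float:
        """AW in mol m⁻³."""
        return umol_l_to_mol_m3(self.aw)

    @property
    def q_si(self) -> float:
        """Q in mol m⁻³ s⁻¹."""
        return mol_l_d_to_mol_m3_s(self.q)


@dataclass(frozen=True)
class BodyGeometry:
    """Cylinder radius in µm; thickness (body width) is the diameter."""

    radius_um: float

    def __post_init__(self) -> None:
        if self.radius_um <= 0:
            raise ValueError(f"radius must be > 0, got {self.radius_um}")

    @property
    def thickness_um(self) -> float:
        return 2.0 * self.radius_um


@dataclass(frozen=True)
class RadialProfile:
    """O2 concentration on an evenly spaced radial grid from axis to wall."""

    r_um: np.ndarray
    o2_umol_l: np.ndarray


@dataclass(frozen=True)
class SedimentProfile:
    """Pore-water O2 as a function of sediment depth.

    O2(0) equals the surface concentration ``aw0`` and O2(z) is 0 at and
    below the oxygen penetration depth ``opd_mm``; in between the profile is
    monotonically non-increasing with the chosen shape.
    """

    aw0: float
    opd_mm: float
    shape: Literal["parabolic", "exponential", "linear"]
    _func: Callable[[np.ndarray], np.ndarray] = field(repr=False)

    def o2(self, z_mm):
        """Concentration [µmol l⁻¹] at depth z [mm]; scalar or array."""
        z = np.asarray(z_mm, dtype=float)
        out = np.where(z >= self.opd_mm, 0.0, np.clip(self._func(z), 0.0, None))
        return float(out) if np.isscalar(z_mm) else out


def make_sediment_profile(
    aw0: float, opd_mm: float, shape: str = "parabolic"
) -> SedimentProfile:
    """Construct a parametric pore-water O2(z) profile.

    ``parabolic`` is the steady-state profile of a sediment with constant
    volumetric oxygen consumption and diffusive uptake, AW0·(1−z/OPD)²;
    ``exponential`` decays to 1% of AW0 at the OPD; ``linear`` is the
    straight ramp. All shapes are clipped to 0 at and below the OPD.
    """
    if aw0 <= 0:
        raise ValueError(f"surface O2 must be > 0, got {aw0}")
    if opd_mm <= 0:
        raise ValueError(f"oxygen penetration depth must be > 0, got {opd_mm}")

    if shape == "parabolic":
        func = lambda z: aw0 * (1.0 - z / opd_mm) ** 2
    elif shape == "exponential":
        k = -math.log(0.01) / opd_mm
        func = lambda z: aw0 * np.exp(-k * z)
    elif shape == "linear":
        func = lambda z: aw0 * (1.0 - z / opd_mm)
    else:
        raise ValueError(
            f"unknown profile shape {shape!r}; "
            "expected 'parabolic', 'exponential' or 'linear'"
        )
    return SedimentProfile(aw0=aw0, opd_mm=opd_mm, shape=shape, _func=func)


def critical_thickness(params: BodyModelParams) -> float:
    """Maximum body width [µm] whose centre is still oxygenated.

    Setting C(0) = 0 in the parabolic profile gives R_crit = sqrt(4·D·AW/Q),
    hence thickness 2·R_crit = 4·sqrt(D·AW/Q). Scales as sqrt(AW): a body in
    four times more oxygen may be twice as wide.
    """
    return m_to_um(4.0 * math.sqrt(params.d * params.aw_si / params.q_si))


def _check_subcritical(params: BodyModelParams, geom: BodyGeometry) -> None:
    crit = critical_thickness(params)
    if geom.thickness_um > crit * (1.0 + 1e-12):
        raise AnoxicCoreError(
            f"body thickness {geom.thickness_um:.1f} µm exceeds the critical "
            f"thickness {crit:.1f} µm at AW={params.aw} µmol l⁻¹: "
            "the body centre would be anoxic"
        )


def radial_o2_profile(
    params: BodyModelParams, geom: BodyGeometry, n_points: int = 101
) -> RadialProfile:
    """Steady-state radial O2 profile C(r) = AW − (Q/4D)·(R²−r²).

    Raises :class:`AnoxicCoreError` for supercritical bodies. C is
    non-decreasing in r and equals AW exactly at the wall.
    """
    if n_points <= 0:
        raise ValueError(f"n_points must be positive, got {n_points}")
    _check_subcritical(params, geom)
    radius_m = um_to_m(geom.radius_um)
    r = np.linspace(0.0, radius_m, n_points)
    c_si = params.aw_si - params.q_si / (4.0 * params.d) * (radius_m**2 - r**2)
    return RadialProfile(
        r_um=m_to_um(r), o2_umol_l=np.clip(mol_m3_to_umol_l(c_si), 0.0, None)
    )


def residence_time(params: BodyModelParams, geom: BodyGeometry) -> float:
    """Turnover time [s] of the body oxygen inventory.

    tau = Cbar/Q with Cbar = AW − Q·R²/(8D), the cross-sectional mean of the
    parabolic profile. Strictly below the thin-body limit AW/Q; at the
    critical radius Cbar = AW/2 and tau is half that limit.
    """
    _check_subcritical(params, geom)
    radius_m = um_to_m(geom.radius_um)
    c_mean = params.aw_si - params.q_si * radius_m**2 / (8.0 * params.d)
    return c_mean / params.q_si


def critical_thickness_vs_depth(
    params: BodyModelParams, profile: SedimentProfile, z_grid_mm
) -> "pd.DataFrame":
    """Critical thickness [µm] along a sediment O2(z) profile.

    Evaluates :func:`critical_thickness` pointwise with AW = O2(z); the curve
    is non-increasing in depth and exactly 0 at and below the OPD. Returns a
    DataFrame with columns ``z_mm``, ``o2_umol_l``, ``critical_thickness_um``.
    """
    import pandas as pd

    z = np.asarray(z_grid_mm, dtype=float)
    if np.any(z < 0):
        raise ValueError("depths must be >= 0")
    o2 = profile.o2(z)
    thick = np.array(
        [
            critical_thickness(BodyModelParams(aw=c, q=params.q, d=params.d))
            for c in o2
        ]
    )
    return pd.DataFrame(
        {"z_mm": z, "o2_umol_l": o2, "critical_thickness_um": thick}
    )
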