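"""Unit converters between field units and SI.

Field conventions: concentrations in µmol O2 l⁻¹, body sizes in µm, sediment
depths in mm, volumetric respiration in mol O2 l⁻¹ d⁻¹ (body tissue) or
µmol O2 l⁻¹ h⁻¹ (chamber water). Internal diffusion math runs in SI
(mol m⁻³, m, s). All converters are pure and round-trip exactly.
"""

SECONDS_PER_DAY = 86400.0
SECONDS_PER_HOUR = 3600.0
UG_C_PER_UMOL_C = 12.0  # atomic mass of carbon


def umol_l_to_mol_m3(c: float) -> float:
    """µmol O2 l⁻¹ → mol m⁻³ (1 µmol/l = 1e-6 mol / 1e-3 m³)."""
    return c * 1e-3


def mol_m3_to_umol_l(c: float) -> float:
    return c * 1e3


def um_to_m(x: float) -> float:
    return x * 1e-6


def m_to_um(x: float) -> float:
    return x * 1e6


def mm_to_m(x: float) -> float:
    return x * 1e-3


def mol_l_d_to_mol_m3_s(q: float) -> float:
    """mol l⁻¹ d⁻¹ → mol m⁻³ s⁻¹."""
    return q * 1e3 / SECONDS_PER_DAY
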