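"""Unit conversions and physical constants shared across the package.

All rates are carried as mmol m⁻² d⁻¹ and all current densities as mA m⁻²;
every conversion between the two lives here so that electron-balance
arithmetic is consistent package-wide.
"""

from __future__ import annotations

#: Faraday constant, C per mol of electrons.
FARADAY = 96485.33212

#: Seconds per day.
SECONDS_PER_DAY = 86400.0

#: Reciprocal Faraday conversion sometimes quoted in the sediment
#: electrochemistry literature: 1 A corresponds to 1.036e-5 mol e⁻ s⁻¹.
MOL_E_PER_AMP_SECOND = 1.036e-5


def electron_flux_to_current_density(electron_flux_mmol_m2_d: float) -> float:
    """Convert an areal electron flux (mmol e⁻ m⁻² d⁻¹) to mA m⁻².

    I = F · n_e / t with n_e in mol m⁻² and t one day in seconds,
    expressed in milliamperes.
    """
    mol_per_m2_s = electron_flux_mmol_m2_d * 1e-3 / SECONDS_PER_DAY
    return mol_per_m2_s * FARADAY * 1e3


def current_density_to_electron_flux(current_ma_m2: float) -> float:
    """Inverse of :func:`electron_flux_to_current_density`."""
    mol_per_m2_s = current_ma_m2 * 1e-3 / FARADAY
    return mol_per_m2_s * SECONDS_PER_DAY * 1e3


def tortuosity_factor(porosity: float) -> float:
    """Tortuosity correction 1 − 2·ln(φ) for sediment of porosity φ.

    Equals 1 in free solution (φ = 1) and grows as the sediment becomes
    less porous.
    """
    if not 0.0 < porosity <= 1.0:
        raise ValueError(f"porosity must be in (0, 1], got {porosity}")
    import math

    return 1.0 - 2.0 * math.log(porosity)
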