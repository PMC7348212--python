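"""Electron balance of electrogenic sulfur oxidation (e-SOx).

Cable bacteria spatially separate two half-reactions and couple them by a
current running along the filament:

    cathodic:  O₂ + 4 H⁺ + 4 e⁻  →  2 H₂O          (4 e⁻ per O₂)
    anodic:    H₂S + 4 H₂O       →  SO₄²⁻ + 10 H⁺ + 8 e⁻   (8 e⁻ per sulfide)

Either half-reaction rate, expressed as an areal electron flux, yields an
estimate of the electric current density through the filament network; in a
closed balance the two estimates agree.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional

from .units import electron_flux_to_current_density

__all__ = [
    "ELECTRONS_PER_O2",
    "ELECTRONS_PER_SULFIDE",
    "RateWithSD",
    "SulfideBudget",
    "CurrentDensity",
    "cathodic_rate",
    "esox_fraction",
    "current_from_o2",
    "sulfide_budget",
    "current_from_sulfide",
]

ELECTRONS_PER_O2 = 4
ELECTRONS_PER_SULFIDE = 8


class CurrentSource(str, Enum):
    cathodic_O2 = "cathodic_O2"
    anodic_S = "anodic_S"


@dataclass
class RateWithSD:
    """An areal rate (mmol m⁻² d⁻¹) with its standard deviation."""

    value: float
    sd: float = 0.0

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be non-negative")


@dataclass
class CathodicRate:
    """Cathodic O₂ reduction rate attributed to cable bacteria.

    Difference between total O₂ uptake with and without an active cable
    bacteria population; ``fraction_percent`` is the share of total uptake
    attributable to e-SOx. ``negative_difference`` flags the (physically
    meaningless) case where the unamended uptake exceeds the stimulated one.
    """

    value: float
    sd: float
    fraction_percent: float
    sd_mode: str
    negative_difference: bool = False


@dataclass
class SulfideBudget:
    """Anodic sulfide sources feeding e-SOx, all in mmol H₂S m⁻² d⁻¹.

    The upward sulfide flux from the sulfidic zone is produced by sulfate
    reduction over a zone of width ``w_sulfidic``; assuming the same
    volumetric rate in the suboxic zone (width ``w_suboxic``) gives the
    in-zone production ``sr_suboxic``. Net FeS dissolution supplies sulfide
    1:1 with the upward Fe²⁺ flux. The total is what anodic oxidation must
    consume at steady state.
    """

    J_up_sulfide: float
    w_suboxic: float
    w_sulfidic: float
    J_feS: float
    sr_suboxic: float
    total_anodic: float


@dataclass
class CurrentDensity:
    """Electric current density (mA m⁻²) implied by an areal electron flux."""

    value: float
    source: CurrentSource
    electron_flux: float
    sd: Optional[float] = None


def cathodic_rate(
    J_total_with_cb: RateWithSD | tuple,
    J_total_without_cb: RateWithSD | tuple,
    sd_mode: str = "additive",
) -> CathodicRate:
    """Cathodic O₂ reduction rate as the with/without-cable-bacteria difference.

    ``sd_mode='additive'`` sums the two standard deviations (the convention
    used when reporting sediment incubation contrasts); ``'quadrature'``
    combines them as sqrt(sd₁² + sd₂²). A negative difference is returned
    with a warning flag rather than raised: it means no detectable
    cable-bacteria oxygen signal.
    """
    a = RateWithSD(*J_total_with_cb) if not isinstance(J_total_with_cb, RateWithSD) else J_total_with_cb
    b = (
        RateWithSD(*J_total_without_cb)
        if not isinstance(J_total_without_cb, RateWithSD)
        else J_total_without_cb
    )
    if a.value < 0 or b.value < 0:
        raise ValueError("O2 uptake rates must be non-negative")
    diff = a.value - b.value
    if sd_mode == "additive":
        sd = a.sd + b.sd
    elif sd_mode == "quadrature":
        sd = (a.sd**2 + b.sd**2) ** 0.5
    else:
        raise ValueError(f"unknown sd_mode {sd_mode!r}")
    fraction = 100.0 * diff / a.value if a.value > 0 else 0.0
    return CathodicRate(
        value=diff,
        sd=sd,
        fraction_percent=fraction,
        sd_mode=sd_mode,
        negative_difference=diff < 0,
    )


def esox_fraction(cathodic_o2: float, total_o2_uptake: float) -> float:
    """Share of total O₂ uptake attributable to e-SOx, percent."""
    if total_o2_uptake <= 0:
        raise ValueError("total O2 uptake must be positive")
    return 100.0 * cathodic_o2 / total_o2_uptake


def current_from_o2(cathodic_o2: float, sd: Optional[float] = None) -> CurrentDensity:
    """Current density from a cathodic O₂ reduction rate (4 e⁻ per O₂)."""
    if cathodic_o2 < 0:
        raise ValueError("cathodic O2 rate must be non-negative")
    eflux = ELECTRONS_PER_O2 * cathodic_o2
    return CurrentDensity(
        value=electron_flux_to_current_density(eflux),
        source=CurrentSource.cathodic_O2,
        electron_flux=eflux,
        sd=None if sd is None else electron_flux_to_current_density(ELECTRONS_PER_O2 * sd),
    )


def sulfide_budget(
    J_up_sulfide: float,
    w_suboxic: float,
    w_sulfidic: float,
    J_feS: float = 0.0,
) -> SulfideBudget:
    """Assemble the anodic sulfide budget.

    sr_suboxic = (w_suboxic / w_sulfidic) · J_up_sulfide (same volumetric
    sulfate-reduction rate assumed in both zones);
    total = J_up_sulfide + sr_suboxic + J_feS.
    """
    if w_sulfidic <= 0 or w_suboxic <= 0:
        raise ValueError("zone widths must be positive")
    if J_up_sulfide < 0 or J_feS < 0:
        raise ValueError("sulfide fluxes must be non-negative")
    sr = (w_suboxic / w_sulfidic) * J_up_sulfide
    return SulfideBudget(
        J_up_sulfide=J_up_sulfide,
        w_suboxic=w_suboxic,
        w_sulfidic=w_sulfidic,
        J_feS=J_feS,
        sr_suboxic=sr,
        total_anodic=J_up_sulfide + sr + J_feS,
    )


def current_from_sulfide(budget: SulfideBudget, sd: Optional[float] = None) -> CurrentDensity:
    """Current density from the anodic sulfide budget (8 e⁻ per sulfide → sulfate)."""
    eflux = ELECTRONS_PER_SULFIDE * budget.total_anodic
    return CurrentDensity(
        value=electron_flux_to_current_density(eflux),
        source=CurrentSource.anodic_S,
        electron_flux=eflux,
        sd=None if sd is None else electron_flux_to_current_density(ELECTRONS_PER_SULFIDE * sd),
    )
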