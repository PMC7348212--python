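"""Microsensor pore-water depth profiles: speciation, zonation, diffusive flux.

Depth convention: millimetres, 0 at the sediment–water interface, positive
downward (negative depths are overlying water). Concentrations are μmol L⁻¹
for dissolved gases; pH is on the total scale.

The diffusive flux across the interface follows Fick's first law with the
tortuosity correction 1 − 2·ln(φ):

    J = −φ · D / (1 − 2 ln φ) · dC/dx

so that a concentration decreasing downward (e.g. O₂ consumed in the
sediment) yields a positive, downward-directed flux.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .units import tortuosity_factor

__all__ = [
    "Analyte",
    "DepthProfile",
    "FluxEstimate",
    "Zonation",
    "sum_h2s",
    "fick_flux",
    "detect_zonation",
    "read_profile_table",
    "DEFAULT_DIFFUSION_COEFFICIENTS",
]


class Analyte(str, Enum):
    O2 = "O2"
    H2S = "H2S"
    SumH2S = "SumH2S"
    pH = "pH"
    Fe2 = "Fe2"


#: Molecular diffusion coefficients in m² d⁻¹ at 16 °C, salinity 30,
#: from standard seawater diffusivity tables. Explicit config inputs:
#: operations never reach for these silently.
DEFAULT_DIFFUSION_COEFFICIENTS = {
    Analyte.O2: 1.36e-4,
    Analyte.H2S: 1.28e-4,
    Analyte.Fe2: 5.2e-5,
}


class AlignmentError(ValueError):
    """Raised when two profiles do not share an overlapping depth range."""


@dataclass
class DepthProfile:
    """One analyte's concentration (or pH) versus depth.

    Parameters
    ----------
    analyte : Analyte
        What was measured.
    depth_mm : array-like
        Strictly increasing depths in mm, 0 at the sediment–water interface.
    value : array-like
        μmol L⁻¹ for gases, total-scale units for pH.
    temperature : float
        Incubation temperature, °C.
    salinity : float
        Practical salinity (unitless).
    porosity : float
        Sediment porosity φ, in (0, 1].
    """

    analyte: Analyte
    depth_mm: np.ndarray
    value: np.ndarray
    temperature: float = 16.0
    salinity: float = 30.0
    porosity: float = 0.88

    def __post_init__(self) -> None:
        self.analyte = Analyte(self.analyte)
        self.depth_mm = np.asarray(self.depth_mm, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        if self.depth_mm.shape != self.value.shape:
            raise ValueError("depth and value must have equal length")
        if self.depth_mm.size < 3:
            raise ValueError("a profile needs at least 3 points")
        if not np.all(np.diff(self.depth_mm) > 0):
            raise ValueError("depth must be strictly increasing")
        if self.analyte is Analyte.pH:
            if np.any((self.value <= 0) | (self.value >= 14)):
                raise ValueError("pH values must lie in (0, 14)")
        elif np.any(self.value < 0):
            raise ValueError("concentrations must be non-negative")
        if not 0.0 < self.porosity <= 1.0:
            raise ValueError("porosity must be in (0, 1]")

    def interp(self, depths: np.ndarray) -> np.ndarray:
        """Linear interpolation of the profile onto new depths (no extrapolation)."""
        depths = np.asarray(depths, dtype=float)
        if depths.min() < self.depth_mm[0] or depths.max() > self.depth_mm[-1]:
            raise AlignmentError(
                "requested depths extend outside the measured range "
                f"[{self.depth_mm[0]}, {self.depth_mm[-1]}] mm"
            )
        return np.interp(depths, self.depth_mm, self.value)


@dataclass
class FluxEstimate:
    """Diffusive flux from a linear fit of a concentration profile.

    J is in mmol m⁻² d⁻¹, signed positive downward; slope is the fitted
    concentration gradient in μmol L⁻¹ mm⁻¹ (= mmol m⁻³ mm⁻¹).
    """

    J: float
    slope: float
    D: float
    tortuosity_factor: float
    fit_window: Tuple[float, float]
    fit_r2: float
    n_points: int


@dataclass
class Zonation:
    """Redox zonation derived from O₂, ΣH₂S and pH profiles.

    ``opd`` (oxygen penetration depth) and ``sulfide_appearance`` are in mm;
    both may be None when the corresponding crossing never occurs, in which
    case ``suboxic_width`` is None as well (undefined, not zero).
    """

    opd: Optional[float]
    sulfide_appearance: Optional[float]
    suboxic_width: Optional[float]
    ph_max: Tuple[float, float]
    ph_min: Tuple[float, float]


def sum_h2s(
    h2s_profile: DepthProfile,
    ph_profile: DepthProfile,
    pK1: float,
) -> DepthProfile:
    """Total dissolved sulfide ΣH₂S = H₂S + HS⁻ from measured H₂S and pH.

    Uses the first dissociation equilibrium of H₂S:

        ΣH₂S(z) = [H₂S](z) · (1 + 10^(pH(z) − pK1))

    pH is interpolated linearly onto the H₂S depth grid; the result keeps
    the H₂S grid. At pH = pK1 the two species are equimolar and ΣH₂S is
    exactly twice the measured H₂S.
    """
    if pK1 is None:
        raise ValueError("pK1 is required configuration for sulfide speciation")
    if h2s_profile.analyte is not Analyte.H2S:
        raise ValueError("first argument must be an H2S profile")
    if ph_profile.analyte is not Analyte.pH:
        raise ValueError("second argument must be a pH profile")
    ph_on_grid = ph_profile.interp(h2s_profile.depth_mm)
    total = h2s_profile.value * (1.0 + np.power(10.0, ph_on_grid - pK1))
    return DepthProfile(
        analyte=Analyte.SumH2S,
        depth_mm=h2s_profile.depth_mm.copy(),
        value=total,
        temperature=h2s_profile.temperature,
        salinity=h2s_profile.salinity,
        porosity=h2s_profile.porosity,
    )


def fick_flux(
    profile: DepthProfile,
    D: float,
    window: Optional[Tuple[float, float]] = None,
) -> FluxEstimate:
    """Diffusive flux across the sediment–water interface by Fick's first law.

    The concentration gradient is estimated by ordinary least squares over
    the points falling in ``window`` (mm, half-open [top, bottom); defaults
    to the whole profile), then

        J = −φ · D / (1 − 2 ln φ) · slope

    with units reconciled so J is in mmol m⁻² d⁻¹: the profile's
    μmol L⁻¹ mm⁻¹ gradient equals 10³ mmol m⁻⁴ and D is in m² d⁻¹.

    Parameters
    ----------
    D : float
        Molecular diffusion coefficient, m² d⁻¹ (must be supplied; see
        ``DEFAULT_DIFFUSION_COEFFICIENTS`` for packaged 16 °C / S=30 values).
    """
    if D <= 0:
        raise ValueError("diffusion coefficient must be positive")
    phi = profile.porosity
    theta2 = tortuosity_factor(phi)

    if window is None:
        mask = np.ones_like(profile.depth_mm, dtype=bool)
        window = (float(profile.depth_mm[0]), float(profile.depth_mm[-1]) + np.finfo(float).eps)
    else:
        top, bottom = window
        mask = (profile.depth_mm >= top) & (profile.depth_mm < bottom)
    x = profile.depth_mm[mask]
    y = profile.value[mask]
    if x.size < 2:
        raise ValueError("need at least 2 points inside the fit window")

    if x.size == 2:
        slope = (y[1] - y[0]) / (x[1] - x[0])
        r2 = 1.0
    else:
        slope, intercept = np.polyfit(x, y, 1)
        yhat = slope * x + intercept
        ss_res = float(np.sum((y - yhat) ** 2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot

    # μmol L⁻¹ mm⁻¹ → mmol m⁻³ per 1e-3 m = 1e3 mmol m⁻⁴
    slope_si = slope * 1e3
    J = -phi * D / theta2 * slope_si
    return FluxEstimate(
        J=float(J),
        slope=float(slope),
        D=D,
        tortuosity_factor=theta2,
        fit_window=(float(window[0]), float(window[1])),
        fit_r2=float(r2),
        n_points=int(x.size),
    )


def _first_downcross(depth: np.ndarray, value: np.ndarray, threshold: float) -> Optional[float]:
    """Shallowest depth ≥ 0 where value first falls below threshold (linear interp)."""
    sed = depth >= 0
    d, v = depth[sed], value[sed]
    below = v < threshold
    if not below.any():
        return None
    i = int(np.argmax(below))
    if i == 0:
        return float(d[0])
    # interpolate between bracketing samples
    d0, d1, v0, v1 = d[i - 1], d[i], v[i - 1], v[i]
    if v0 == v1:
        return float(d1)
    return float(d0 + (v0 - threshold) / (v0 - v1) * (d1 - d0))


def _first_upcross(depth: np.ndarray, value: np.ndarray, threshold: float) -> Optional[float]:
    """Shallowest depth ≥ 0 where value first exceeds threshold (linear interp)."""
    sed = depth >= 0
    d, v = depth[sed], value[sed]
    above = v > threshold
    if not above.any():
        return None
    i = int(np.argmax(above))
    if i == 0:
        return float(d[0])
    d0, d1, v0, v1 = d[i - 1], d[i], v[i - 1], v[i]
    if v0 == v1:
        return float(d1)
    return float(d0 + (threshold - v0) / (v1 - v0) * (d1 - d0))


def detect_zonation(
    o2: DepthProfile,
    sumh2s: DepthProfile,
    ph: DepthProfile,
    threshold: float = 1.0,
) -> Zonation:
    """Locate the oxic / suboxic / sulfidic zonation of a sediment profile.

    The oxygen penetration depth (opd) is the shallowest sediment depth at
    which O₂ first falls below ``threshold`` (μmol L⁻¹, default 1); sulfide
    appearance is where ΣH₂S first exceeds it. The suboxic zone — where both
    are below detection — is their difference, floored at 0. Its width is a
    geochemical fingerprint of electrogenic sulfur oxidation, along with the
    subsurface pH maximum (cathodic proton consumption) and the deeper pH
    minimum (anodic proton production), which are located on the measured
    grid.
    """
    if threshold <= 0:
        raise ValueError("detection threshold must be positive")
    opd = _first_downcross(o2.depth_mm, o2.value, threshold)
    sulf = _first_upcross(sumh2s.depth_mm, sumh2s.value, threshold)

    if opd is None or sulf is None:
        width = None
    else:
        width = max(sulf - opd, 0.0)

    sed = ph.depth_mm >= 0
    d, v = ph.depth_mm[sed], ph.value[sed]
    imax, imin = int(np.argmax(v)), int(np.argmin(v))
    return Zonation(
        opd=opd,
        sulfide_appearance=sulf,
        suboxic_width=width,
        ph_max=(float(d[imax]), float(v[imax])),
        ph_min=(float(d[imin]), float(v[imin])),
    )


def read_profile_table(
    path: str | Path,
    analyte: Optional[str] = None,
    **metadata,
) -> DepthProfile | dict:
    """Read depth profiles from a delimited table.

    Accepts either a two-column table (``depth_mm``, ``value``) for a single
    analyte, or a long-format table with an additional ``analyte`` column.
    Lines beginning with '#' are header comments and may carry metadata as
    ``# key = value`` pairs (temperature, salinity, porosity, pK1).

    Returns a single :class:`DepthProfile` (two-column input, or long format
    with ``analyte`` given) or a dict mapping analyte name to profile.
    """
    path = Path(path)
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if "=" in line:
                key, _, val = line.lstrip("# ").partition("=")
                try:
                    meta[key.strip()] = float(val)
                except ValueError:
                    meta[key.strip()] = val.strip()
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    df = pd.read_csv(path, sep=sep, comment="#")
    meta.update(metadata)
    pk1 = meta.pop("pK1", None)
    fields = {k: meta[k] for k in ("temperature", "salinity", "porosity") if k in meta}

    def _build(name: str, sub: pd.DataFrame) -> DepthProfile:
        return DepthProfile(
            analyte=Analyte(name),
            depth_mm=sub["depth_mm"].to_numpy(),
            value=sub["value"].to_numpy(),
            **fields,
        )

    if "analyte" in df.columns:
        out = {name: _build(name, sub) for name, sub in df.groupby("analyte", sort=False)}
        if analyte is not None:
            return out[analyte]
        if pk1 is not None:
            out["pK1"] = pk1
        return out
    if analyte is None:
        raise ValueError("two-column profile tables require the analyte argument")
    return _build(analyte, df)
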