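"""qPCR standard curves and absolute quantification of 16S gene copies.

The calibration relation is log-linear: Cq = intercept + slope·log10(copies),
with slope < 0 for a working assay. Amplification efficiency follows from the
slope as E = 10^(−1/slope) − 1; a perfect per-cycle doubling gives
slope = −1/log10(2) ≈ −3.3219 and E = 100%.

Copy densities are expressed per gram of wet sediment:

    copies g⁻¹ = copies μl⁻¹ template × dilution factor × elution volume / wet mass
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import stats

__all__ = [
    "Target",
    "StandardCurve",
    "SampleQuant",
    "fit_standard_curve",
    "quantify",
    "detection_limit",
    "PERFECT_SLOPE",
]

#: Slope of a perfectly doubling assay: −1/log10(2).
PERFECT_SLOPE = -1.0 / math.log10(2.0)


class Target(str, Enum):
    """qPCR targets: total bacteria, Desulfobulbaceae, cable bacteria."""

    TB = "TB"
    DSB = "DSB"
    CB = "CB"


class InvalidCurveError(ValueError):
    """Standard-curve fit is unusable (non-negative slope, too few levels)."""


@dataclass
class StandardCurve:
    """A fitted log-linear Cq-vs-copies calibration.

    Attributes
    ----------
    slope : float
        Cq per log10(copies μl⁻¹); negative for a valid assay.
    intercept : float
        Cq at 1 copy μl⁻¹.
    efficiency : float
        Per-cycle amplification gain, 1.0 = 100% (perfect doubling).
    r2 : float
    n_standards : int
    target : Target | None
    """

    slope: float
    intercept: float
    efficiency: float
    r2: float
    n_standards: int
    target: Optional[Target] = None

    @classmethod
    def fit(
        cls,
        copies_per_ul: Sequence[float],
        cq: Sequence[float],
        target: Optional[Target] = None,
    ) -> "StandardCurve":
        """Least-squares fit of Cq against log10(copies μl⁻¹).

        Requires at least 3 distinct concentration levels and strictly
        positive copy numbers; a non-negative slope raises
        :class:`InvalidCurveError`.
        """
        copies = np.asarray(copies_per_ul, dtype=float)
        cqv = np.asarray(cq, dtype=float)
        if copies.shape != cqv.shape:
            raise ValueError("copies and Cq must have equal length")
        if np.any(copies <= 0):
            raise ValueError("standard copy numbers must be positive")
        if np.unique(copies).size < 3:
            raise InvalidCurveError("need at least 3 distinct standard concentrations")
        x = np.log10(copies)
        res = stats.linregress(x, cqv)
        if res.slope >= 0:
            raise InvalidCurveError(f"standard curve slope is non-negative ({res.slope:.3g})")
        return cls(
            slope=float(res.slope),
            intercept=float(res.intercept),
            efficiency=efficiency_from_slope(float(res.slope)),
            r2=float(res.rvalue**2),
            n_standards=int(copies.size),
            target=target,
        )

    def copies_from_cq(self, cq: float) -> float:
        """Invert the calibration: copies μl⁻¹ template at a given Cq."""
        return 10.0 ** ((cq - self.intercept) / self.slope)


def efficiency_from_slope(slope: float) -> float:
    """Amplification efficiency E = 10^(−1/slope) − 1 (1.0 = 100%)."""
    return 10.0 ** (-1.0 / slope) - 1.0


def fit_standard_curve(
    standards: Sequence[Tuple[float, float]],
    target: Optional[Target] = None,
) -> StandardCurve:
    """Fit a standard curve from (copies μl⁻¹, Cq) pairs."""
    copies, cq = zip(*standards)
    return StandardCurve.fit(copies, cq, target=target)


@dataclass
class SampleQuant:
    """Absolute quantification of one sample against a standard curve."""

    cq: Tuple[float, ...]
    dilution_factor: float
    elution_volume_ul: float
    wet_mass_g: float
    copies_per_ul_template: float
    copy_density: float
    replicate_cv: float
    below_detection: bool
    target: Optional[Target] = None


def quantify(
    cq_replicates: Sequence[float],
    curve: StandardCurve,
    dilution_factor: float,
    elution_volume_ul: float,
    wet_mass_g: float,
    cq_cutoff: float = 38.0,
) -> SampleQuant:
    """Convert replicate Cq values into 16S copies per gram wet sediment.

    Replicates are averaged on the Cq scale (the noise model is log-domain);
    the coefficient of variation of the per-replicate copy numbers is
    reported. Mean Cq at or above ``cq_cutoff`` flags the sample as below
    detection (copy density still computed, but it must not enter profile
    means).

    Elution volume and wet mass have no defaults: absolute densities depend
    on them directly, so they are required metadata.
    """
    if wet_mass_g <= 0:
        raise ValueError("wet mass must be positive")
    if dilution_factor <= 0 or elution_volume_ul <= 0:
        raise ValueError("dilution factor and elution volume must be positive")
    cqs = np.asarray(list(cq_replicates), dtype=float)
    if cqs.size == 0:
        raise ValueError("at least one Cq replicate required")
    mean_cq = float(cqs.mean())
    copies_mean = curve.copies_from_cq(mean_cq)
    per_rep = np.array([curve.copies_from_cq(c) for c in cqs])
    cv = float(per_rep.std(ddof=1) / per_rep.mean()) if cqs.size > 1 else 0.0
    density = copies_mean * dilution_factor * elution_volume_ul / wet_mass_g
    return SampleQuant(
        cq=tuple(float(c) for c in cqs),
        dilution_factor=dilution_factor,
        elution_volume_ul=elution_volume_ul,
        wet_mass_g=wet_mass_g,
        copies_per_ul_template=float(copies_mean),
        copy_density=float(density),
        replicate_cv=cv,
        below_detection=mean_cq >= cq_cutoff,
        target=curve.target,
    )


def detection_limit(
    min_detectable_copies_per_rxn: float,
    dilution_factor: float,
    elution_volume_ul: float,
    wet_mass_g: float,
) -> float:
    """Assay detection limit in copies per gram wet sediment.

    limit = minimum detectable copies μl⁻¹ × dilution × elution volume / wet
    mass, with every factor explicit — the limit scales linearly with each.
    """
    if min(min_detectable_copies_per_rxn, dilution_factor, elution_volume_ul, wet_mass_g) <= 0:
        raise ValueError("all detection-limit factors must be positive")
    return min_detectable_copies_per_rxn * dilution_factor * elution_volume_ul / wet_mass_g
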