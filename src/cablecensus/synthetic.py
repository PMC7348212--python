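"""Synthetic input generator with planted ground truth.

Every analysis stage in the package has a generator here that is its right
inverse in the noiseless limit: pore-water profiles whose planted fluxes and
zonation are recovered exactly, Cq tables whose planted copy densities are
recovered exactly, reference databases whose planted specificity counts the
screen reproduces, and count tables whose planted relative abundances are
recovered to sampling error. All randomness flows from the single scenario
seed.

The electrogenic scenario emulates the geochemical fingerprint of an active
cable-bacteria population: a centimetre-scale suboxic zone where both O₂ and
free sulfide are below detection, a subsurface pH maximum at the oxygen
penetration depth (cathodic proton consumption) and a pH minimum at depth
(anodic proton production). The non-electrogenic scenario has sulfide meeting
oxygen and no pH excursions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .primers import DegeneratePrimer, IUPAC_SETS, expand_degenerate, revcomp
from .profiles import Analyte, DepthProfile, DEFAULT_DIFFUSION_COEFFICIENTS
from .units import tortuosity_factor

__all__ = [
    "ScenarioSpec",
    "gen_porewater",
    "gen_qpcr",
    "gen_reference_db",
    "gen_community_reads",
    "DEFAULT_COPY_PROFILES",
]

#: Layered copy densities (copies per g wet sediment) typical of a stimulated
#: incubation: cable bacteria at 3e8 in the colonised top 1.5 cm falling to a
#: background of ~9e4 at depth; total bacteria ~1.3e10 at the surface over
#: 5.4e9 below; Desulfobulbaceae enriched to 4.6e8 where cable bacteria grow.
DEFAULT_COPY_PROFILES: Dict[str, List[Tuple[float, float, float]]] = {
    "TB": [(0.0, 0.5, 1.3e10), (0.5, 1.5, 5.4e9), (1.5, 3.0, 5.4e9)],
    "DSB": [(0.0, 0.5, 4.6e8), (0.5, 1.5, 4.6e8), (1.5, 3.0, 1.5e8)],
    "CB": [(0.0, 0.5, 3.0e8), (0.5, 1.5, 3.0e8), (1.5, 3.0, 9.1e4)],
}

DEFAULT_CURVE_PARAMS: Dict[str, Tuple[float, float]] = {
    "TB": (-3.321928094887362, 36.0),
    "DSB": (-3.4, 35.0),
    "CB": (-3.3, 34.5),
}


@dataclass
class ScenarioSpec:
    """A complete synthetic study scenario.

    Pore-water geometry (oxygen penetration depth ``opd_mm``, suboxic zone
    width), planted fluxes (``o2_uptake``, ``sulfide_flux``, both positive
    magnitudes in mmol m⁻² d⁻¹), pH excursion parameters, per-target copy
    densities by depth layer, standard-curve parameters, noise levels and the
    master seed.
    """

    regime: str = "electrogenic"
    opd_mm: float = 1.0
    suboxic_width_mm: float = 10.0
    o2_uptake: float = 35.1
    sulfide_flux: float = 4.8
    ph_overlying: float = 7.8
    ph_peak_amplitude: float = 0.25
    ph_min: float = 6.2
    ph_min_depth_mm: float = 12.0
    porosity: float = 0.88
    temperature: float = 16.0
    salinity: float = 30.0
    pK1: float = 6.6
    D_O2: float = DEFAULT_DIFFUSION_COEFFICIENTS[Analyte.O2]
    D_H2S: float = DEFAULT_DIFFUSION_COEFFICIENTS[Analyte.H2S]
    grid_step_mm: float = 0.05
    max_depth_mm: float = 30.0
    profile_noise_sd: float = 0.0
    copy_profiles: Dict[str, List[Tuple[float, float, float]]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_COPY_PROFILES.items()}
    )
    curve_params: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_CURVE_PARAMS)
    )
    cq_noise_sd: float = 0.0
    dilution_factors: Dict[str, float] = field(
        default_factory=lambda: {"TB": 1e4, "DSB": 1e2, "CB": 1e2}
    )
    elution_volume_ul: float = 100.0
    wet_mass_g: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.regime not in ("electrogenic", "non_electrogenic"):
            raise ValueError("regime must be electrogenic or non_electrogenic")
        if self.regime == "electrogenic":
            if self.suboxic_width_mm <= 0 or self.ph_peak_amplitude <= 0:
                raise ValueError(
                    "electrogenic scenarios require a positive suboxic width "
                    "and pH peak amplitude"
                )
        elif self.suboxic_width_mm != 0:
            raise ValueError("non-electrogenic scenarios have suboxic width 0")
        if self.opd_mm <= 0 or self.o2_uptake < 0 or self.sulfide_flux < 0:
            raise ValueError("inconsistent scenario geometry")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def gen_porewater(spec: ScenarioSpec) -> Dict[str, DepthProfile]:
    """Pore-water O₂, H₂S, ΣH₂S and pH profiles with planted ground truth.

    O₂ falls linearly from the interface to zero at the oxygen penetration
    depth, with the gradient chosen so the tortuosity-corrected Fick flux
    equals ``spec.o2_uptake`` exactly. ΣH₂S is zero through the suboxic zone
    and rises below it with a gradient planting ``spec.sulfide_flux`` (an
    upward flux). H₂S is back-computed from ΣH₂S and pH through the
    speciation relation, so the speciation operation round-trips. Gaussian
    noise (``profile_noise_sd``, μmol L⁻¹) is optional and seeded.
    """
    rng = spec.rng()
    z = np.arange(-2.0, spec.max_depth_mm + spec.grid_step_mm / 2, spec.grid_step_mm)
    theta2 = tortuosity_factor(spec.porosity)

    # O2: flux J = phi*D/theta2 * slope_si; slope in μM/mm = slope_si/1e3
    o2_grad = spec.o2_uptake * theta2 / (spec.porosity * spec.D_O2) / 1e3  # μM per mm
    o2 = np.where(z < 0, o2_grad * spec.opd_mm, o2_grad * (spec.opd_mm - z))
    o2 = np.clip(o2, 0.0, None)

    sulf_app = spec.opd_mm + spec.suboxic_width_mm
    h2s_grad = spec.sulfide_flux * theta2 / (spec.porosity * spec.D_H2S) / 1e3
    sumh2s = np.clip(h2s_grad * (z - sulf_app), 0.0, None)

    if spec.regime == "electrogenic":
        pts_z = [-2.0, 0.0, spec.opd_mm, spec.ph_min_depth_mm, spec.max_depth_mm]
        pts_v = [
            spec.ph_overlying,
            spec.ph_overlying,
            spec.ph_overlying + spec.ph_peak_amplitude,
            spec.ph_min,
            spec.ph_min + 0.3,
        ]
    else:
        pts_z = [-2.0, 0.0, spec.max_depth_mm]
        pts_v = [spec.ph_overlying, spec.ph_overlying, spec.ph_overlying - 0.5]
    ph = np.interp(z, pts_z, pts_v)

    if spec.profile_noise_sd > 0:
        o2 = np.clip(o2 + rng.normal(0, spec.profile_noise_sd, z.size), 0.0, None)
        sumh2s = np.clip(sumh2s + rng.normal(0, spec.profile_noise_sd, z.size), 0.0, None)
        ph = ph + rng.normal(0, spec.profile_noise_sd * 0.01, z.size)

    h2s = sumh2s / (1.0 + np.power(10.0, ph - spec.pK1))

    meta = dict(
        temperature=spec.temperature, salinity=spec.salinity, porosity=spec.porosity
    )
    return {
        "O2": DepthProfile(Analyte.O2, z, o2, **meta),
        "H2S": DepthProfile(Analyte.H2S, z, h2s, **meta),
        "SumH2S": DepthProfile(Analyte.SumH2S, z, sumh2s, **meta),
        "pH": DepthProfile(Analyte.pH, z, ph, **meta),
    }


def gen_qpcr(
    spec: ScenarioSpec,
    standard_decades: Sequence[int] = (2, 3, 4, 5, 6, 7),
    n_replicates: int = 2,
) -> pd.DataFrame:
    """A Cq table (standards plus samples) from planted copy densities.

    Standards run a 10-fold dilution series across ``standard_decades``
    (copies μl⁻¹ = 10^k); sample Cq values are computed from the planted
    per-layer copy densities through the target's log-linear curve, the
    dilution factor, elution volume and wet mass. Gaussian Cq noise with
    ``spec.cq_noise_sd`` is applied to every Cq; seeded by the scenario.

    Columns match the qPCR input contract: target, sample_id, depth_top_cm,
    depth_bottom_cm, cq, dilution_factor, elution_volume_ul, wet_mass_g,
    role, copies_per_ul.
    """
    rng = spec.rng()
    rows = []
    for target, (slope, intercept) in spec.curve_params.items():
        if slope >= 0:
            raise ValueError("standard-curve slopes must be negative")
        for k in standard_decades:
            copies = 10.0**k
            for rep in range(n_replicates):
                cq = intercept + slope * math.log10(copies)
                if spec.cq_noise_sd > 0:
                    cq += rng.normal(0, spec.cq_noise_sd)
                rows.append(
                    dict(
                        target=target,
                        sample_id=f"std_{target}_1e{k}_r{rep + 1}",
                        depth_top_cm=np.nan,
                        depth_bottom_cm=np.nan,
                        cq=cq,
                        dilution_factor=np.nan,
                        elution_volume_ul=np.nan,
                        wet_mass_g=np.nan,
                        role="standard",
                        copies_per_ul=copies,
                    )
                )
        dil = spec.dilution_factors.get(target, 1e2)
        for top, bottom, density in spec.copy_profiles.get(target, []):
            copies_per_ul = density * spec.wet_mass_g / (dil * spec.elution_volume_ul)
            for rep in range(n_replicates):
                cq = intercept + slope * math.log10(copies_per_ul)
                if spec.cq_noise_sd > 0:
                    cq += rng.normal(0, spec.cq_noise_sd)
                rows.append(
                    dict(
                        target=target,
                        sample_id=f"{target}_{top:g}-{bottom:g}cm_r{rep + 1}",
                        depth_top_cm=top,
                        depth_bottom_cm=bottom,
                        cq=cq,
                        dilution_factor=dil,
                        elution_volume_ul=spec.elution_volume_ul,
                        wet_mass_g=spec.wet_mass_g,
                        role="sample",
                        copies_per_ul=np.nan,
                    )
                )
    return pd.DataFrame(rows)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def _mutate_primer_positions(
    site: str, primer: DegeneratePrimer, positions: Sequence[int], rng: np.random.Generator
) -> str:
    """Introduce guaranteed mismatches at 1-based primer positions.

    ``site`` is the concrete sequence the primer is compared against (already
    in primer orientation); each listed position is replaced by a base outside
    the primer's IUPAC set there.
    """
    chars = list(site)
    for p in positions:
        if not 1 <= p <= len(primer):
            raise ValueError(f"mismatch position {p} exceeds primer length {len(primer)}")
        allowed = IUPAC_SETS[primer.sequence[p - 1]]
        options = sorted(set("ACGT") - allowed)
        if not options:
            raise ValueError(f"primer position {p} is fully degenerate; cannot mismatch")
        chars[p - 1] = options[int(rng.integers(len(options)))]
    return "".join(chars)


def gen_reference_db(
    n_in_target: int,
    n_off_target: int,
    fwd: DegeneratePrimer,
    rev: DegeneratePrimer,
    mismatch_spec: Optional[Dict[str, Sequence[int]]] = None,
    seed: int = 0,
    seq_length: int = 900,
    max_amplicon: int = 200,
    in_target_taxon: str = "Bacteria;Desulfobulbaceae;Ca_Electrothrix",
    off_target_taxon: str = "Bacteria;Desulfobulbaceae;Desulfobulbus",
) -> Tuple[Dict[str, str], Dict[str, str], Dict[str, int]]:
    """A local 16S reference set with planted primer sites.

    In-target records carry exact sites for both primers in productive
    orientation with an amplicon length drawn ≤ ``max_amplicon``; off-target
    records carry the same sites but with mismatches at the 1-based primer
    positions given in ``mismatch_spec`` ({'fwd': [...], 'rev': [...]}).

    Returns (records, taxonomy, planted amplicon length per record id).
    """
    rng = np.random.default_rng(seed)
    mismatch_spec = mismatch_spec or {}
    records: Dict[str, str] = {}
    taxonomy: Dict[str, str] = {}
    lengths: Dict[str, int] = {}
    min_len = len(fwd) + len(rev) + 10

    def plant(rid: str, taxon: str, fwd_mm: Sequence[int], rev_mm: Sequence[int]) -> None:
        seq = list(_random_seq(rng, seq_length))
        amp_len = int(rng.integers(min_len, max_amplicon + 1))
        start = int(rng.integers(50, seq_length - amp_len - 50))
        fsite = sorted(expand_degenerate(fwd))[0]
        fsite = _mutate_primer_positions(fsite, fwd, fwd_mm, rng)
        rsite = sorted(expand_degenerate(rev))[0]
        rsite = _mutate_primer_positions(rsite, rev, rev_mm, rng)
        seq[start : start + len(fwd)] = fsite
        # reverse primer anneals to the + strand; its site is revcomp(primer)
        rplus = revcomp(rsite)
        seq[start + amp_len - len(rev) : start + amp_len] = rplus
        records[rid] = "".join(seq)
        taxonomy[rid] = taxon
        lengths[rid] = amp_len

    for i in range(n_in_target):
        plant(f"in_{i:03d}", in_target_taxon, (), ())
    for i in range(n_off_target):
        plant(
            f"off_{i:03d}",
            off_target_taxon,
            tuple(mismatch_spec.get("fwd", ())),
            tuple(mismatch_spec.get("rev", ())),
        )
    return records, taxonomy, lengths


def gen_community_reads(
    rel_abundances: Dict[str, Dict[str, float]],
    total_reads: int = 52000,
    seed: int = 0,
    filler_taxon: str = "Bacteria;Other;Other",
) -> pd.DataFrame:
    """Multinomial ASV count table from planted per-layer relative abundances.

    ``rel_abundances`` maps layer id → {taxonomy lineage: fraction}; fractions
    in each layer must sum to ≤ 1 and the remainder is assigned to a filler
    bacterial taxon. Returns a count matrix with a ``taxonomy`` column and one
    column per layer. Identical seeds yield identical tables.
    """
    rng = np.random.default_rng(seed)
    taxa = sorted({t for layer in rel_abundances.values() for t in layer})
    if filler_taxon not in taxa:
        taxa.append(filler_taxon)
    data = {"taxonomy": taxa}
    for layer, fractions in rel_abundances.items():
        total_frac = sum(fractions.values())
        if total_frac > 1.0 + 1e-12:
            raise ValueError(f"abundances in layer {layer} sum to {total_frac} > 1")
        probs = [fractions.get(t, 0.0) for t in taxa]
        probs[taxa.index(filler_taxon)] += 1.0 - total_frac
        data[layer] = rng.multinomial(total_reads, probs)
    return pd.DataFrame(data)
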