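# Methods

`cablecensus` implements the quantitative chain from raw marine-sediment
measurements to a census of electrogenic cable bacteria (filamentous
*Desulfobulbaceae*, genus *Ca.* Electrothrix in marine settings): diffusive
fluxes from microsensor pore-water profiles, an electron balance converting
those fluxes into electric current densities, qPCR-based absolute abundance,
per-filament and per-cell metabolic rates, degenerate-primer evaluation for
assay design, and amplicon cross-validation. Everything runs offline against
a synthetic-data generator with planted ground truth.

## Pore-water profiles and diffusive fluxes

A `DepthProfile` carries one analyte (O₂, H₂S, ΣH₂S or pH) versus depth in
mm, 0 at the sediment–water interface, positive downward, with environment
metadata (temperature, salinity, porosity φ). Intervals are half-open
[top, bottom), matching microsensor and core-slicing practice.

Total dissolved sulfide is computed from measured free sulfide and pH via the
first dissociation equilibrium, ΣH₂S = [H₂S]·(1 + 10^(pH−pK1)), with pH
linearly interpolated onto the H₂S grid. The pK1 is a config scalar
(default 6.6, a typical seawater value near 16 °C and salinity 30); no
single authoritative value exists for incubation conditions, so it is never
hard-coded into the operation.

Diffusive fluxes use Fick's first law with the tortuosity correction
1 − 2·ln(φ):

    J = −φ · D / (1 − 2 ln φ) · dC/dx

The gradient is fitted by ordinary least squares over a depth window
(two-point fallback when only two points fall inside); OLS reduces to the
exact derivative for linear data and is more robust to sensor noise than a
two-point difference. The minus sign makes a downward-decreasing O₂ profile
yield a positive (downward, into-sediment) flux, the convention in which
sediment O₂ uptake is reported as a positive number; an upward sulfide flux
out of the sulfidic zone is correspondingly negative and callers take the
magnitude where a source strength is meant. Fit windows default to
interface-to-OPD for O₂ and a short window at the base of the suboxic zone
for ΣH₂S, both overridable — window sizes are an analyst's choice, not a
physical constant.

Molecular diffusion coefficients are explicit inputs. Packaged defaults for
O₂ (1.36 × 10⁻⁴ m² d⁻¹), H₂S (1.28 × 10⁻⁴) and Fe²⁺ (5.2 × 10⁻⁵) at 16 °C,
salinity 30 come from standard seawater diffusivity tables; none of the
headline quantities depend on them, because the electron balance consumes
measured fluxes directly.

Zonation detection locates the oxygen penetration depth (shallowest sediment
depth where O₂ falls below a detection threshold, default 1 μmol L⁻¹,
linearly interpolated between bracketing samples) and the sulfide appearance
depth (first exceedance of the same threshold). Their difference, floored at
zero, is the suboxic zone width — together with a subsurface pH maximum in
the oxic zone and a pH minimum at depth, the geochemical fingerprint of
electrogenic sulfur oxidation (e-SOx). When O₂ never drops below the
threshold, the OPD and suboxic width are undefined (None), not zero.

## Electron balance and current densities

e-SOx couples two spatially separated half-reactions through currents along
the filaments: cathodic O₂ reduction near the interface (4 e⁻ per O₂) and
anodic sulfide oxidation to sulfate at depth (8 e⁻ per sulfide). Two
independent current-density estimates follow:

- **Cathodic route.** The cable-bacteria O₂ consumption is the difference in
  total diffusive O₂ uptake between an incubation with an active population
  and one without. Standard deviations combine additively by default — the
  conservative convention for treatment contrasts of this kind — with
  quadrature available as the statistically standard alternative. A negative
  difference is flagged, not raised: it simply means no detectable signal.
- **Anodic route.** The sulfide supply to the anodic reaction sums the
  upward flux from the sulfidic zone, the in-zone production by sulfate
  reduction in the suboxic zone — scaled from the deep flux by the ratio of
  zone widths, assuming equal volumetric sulfate-reduction rates — and the
  sulfide released by net FeS dissolution, taken 1:1 with the upward Fe²⁺
  flux (the downward Fe²⁺ flux is assumed to re-precipitate as FeS and is
  ignored). The FeS term enters the total additively; bookkeeping
  conventions that print dissolution as a negative number are a sign-only
  artifact.

Electron fluxes convert to current densities through the Faraday constant
(96 485 C mol⁻¹; the literature shorthand 1 A = 1.036 × 10⁻⁵ mol e⁻ s⁻¹
agrees to 0.04%). All rates are carried in mmol m⁻² d⁻¹ and currents in
mA m⁻², with the conversion centralized in one module.

## qPCR quantification

Standard curves are least-squares fits of Cq against log₁₀(copies μl⁻¹)
over a 10-fold dilution series (≥3 distinct levels enforced); amplification
efficiency is E = 10^(−1/slope) − 1, exactly 100% at slope −1/log₁₀2 ≈
−3.3219. Sample Cq replicates are averaged on the Cq scale (the noise model
is log-domain); the CV of per-replicate copy numbers is reported, and to
first order the CV of recovered copies grows as ln(10)/|slope| · σ_Cq.

Copy densities are copies per gram wet sediment:
copies μl⁻¹ template × dilution factor × elution volume / wet mass. Elution
volume and wet mass are required metadata, never defaulted: absolute
densities scale linearly with both. Samples with mean Cq at or beyond a
no-template cutoff (default 38 cycles) are flagged below detection and must
be excluded from profile means, never imputed as zero.

The detection-limit helper exposes the same four factors explicitly. Note a
known bookkeeping gap in assay write-ups of this kind: a limit quoted from
"10² dilution and 10 copies μl⁻¹ detected" cannot be reconstructed without
also stating elution volume and wet mass (10 × 100 × 50 μl / 0.5 g is 10⁵
copies g⁻¹, not 10²); the operation therefore takes all factors and no
canonical value is asserted.

## Filament and cell census

With C_qPCR in copies per g wet sediment, per-cell 16S copy number n_copy,
mean cell length L_cell and wet bulk density ρ_w:

- cells cm⁻³ = C_qPCR · ρ_w / n_copy
- N_F,volume (m of filament per cm³) = cells cm⁻³ × L_cell
- N_F,area (m per cm²) = N_F,volume × L_CB, the colonisation depth
- filaments cm⁻² = N_F,area / L_CB expressed per-filament-length in metres
  (straight, vertically oriented filaments of length L_CB)

Defaults (3 μm cells, 2 copies per cell as in the *Ca.* E. aarhusiensis
genome, ρ_w = 1.32 g cm⁻³, L_CB = 1.5 cm) describe a laboratory enrichment
of marine cable bacteria. The census is linear in C_qPCR and inversely
linear in n_copy. The depth-integration default is the uniform-density
shortcut (one C_qPCR over L_CB); integrating layered copy profiles is
available through the qPCR table but the shortcut is the documented,
headline-reproducing default.

Mean horizontal filament spacing places the areal count on a regular
lattice: square d = n^(−1/2) or hexagonal d = (2/(√3 n))^(1/2), default
hexagonal. For 6 × 10⁴ filaments cm⁻² these give 40.8 and 43.9 μm; field
reports of ~45 μm fall nearest the hexagonal model but neither formula
reproduces such values exactly, so spacing is a descriptive output only.

Per-filament current divides an areal current density by the filament count
per m² (reported in pA); the cell-specific O₂ consumption rate divides the
cathodic O₂ rate by the cell inventory of the oxic layer (volumetric cell
density × oxygen penetration depth), in fmol O₂ cell⁻¹ d⁻¹ — only cells in
the oxic zone participate in cathodic reduction. Growth timing converts a
fold increase in copy density to doublings (log₂, reported raw and rounded)
and elapsed days at a given doubling time. Report-style rounding to one
significant figure is a separate helper; all operations return full
precision.

## Degenerate-primer evaluation

Primers are 5′→3′ IUPAC strings (reverse primers 5′→3′ on the reverse
strand, as in primer tables). Expansion enumerates all concrete sequences
(count = the per-position cardinality product). Matching is asymmetric:
primer codes are base sets, the template must be concrete, a template N is
always a mismatch. Binding-site search scans every window (the reverse
complement of the window for reverse primers) and reports 0-based half-open
template coordinates with 1-based primer-position mismatches; an optional
"0-mismatch zone" can forbid mismatches near the 3′ end, off by default.
In-silico PCR pairs forward and reverse sites in productive orientation and
reports products up to a length cap (default 200 bp, the usual qPCR
amplicon limit), with length counted from forward 5′ through reverse 5′ on
the + strand.

Design-rule QC covers GC content (40–60% band), a G/C 5′ start, a GC-rich
3′ end (≥4 G/C in the last five bases), hairpins (internal
reverse-complementary seed ≥4 nt separated by ≥3 nt) and self-/hetero-dimers
(longest antiparallel complementary run ≥5 nt, with 3′-anchored runs noted).
These are run-length heuristics, not free-energy minimisation — the design
rules themselves are qualitative, and thresholds are configurable. Melting
temperatures use nearest-neighbor thermodynamics (Biopython's `Tm_NN`) with
salt correction; published primer-table Tm values computed by unstated
methods are treated as descriptive, not as test targets.

The specificity screen emulates a TestProbe/TestPrime-style query against a
local reference set (FASTA plus a record→lineage taxonomy table): per-taxon
counts of templates hit at each mismatch allowance, where a pair hit
requires both primers bound in productive orientation within the amplicon
cap, the allowance applying to each primer separately. Records without
taxonomy are excluded from denominators with a warning. No live database is
queried; reference sets are local inputs or synthetic stand-ins.

## Amplicon cross-validation

Per depth layer, the qPCR relative abundance (target copies / total-bacteria
copies, %) is paired with the amplicon relative abundance (target reads /
reads classified as Bacteria, %; unclassified reads excluded by default,
toggleable). The regression of qPCR on amplicon percentage defaults to
through-origin — the object of interest is a proportionality constant — with
the intercept variant available, since published analyses rarely state
which was used. The ASV detection limit is the copy density worth one read:
total-bacteria copy density / total reads.

## Synthetic data

The generator is, by construction, a right inverse of each analysis stage in
the noiseless limit — the pipeline's core correctness surface:

- **Pore water** (50-μm grid to 30 mm, configurable): O₂ linear from the
  interface to zero at the planted OPD with the gradient chosen so the
  tortuosity-corrected Fick flux over the oxic window equals the planted
  uptake exactly; ΣH₂S zero through the suboxic zone, rising below it with a
  gradient planting the sulfide flux; pH piecewise-linear through the
  electrogenic fingerprint (subsurface maximum at the OPD, minimum at
  depth). Free H₂S is back-computed from ΣH₂S and pH so speciation
  round-trips. Defaults are the electrogenic study conditions: OPD 1 mm,
  suboxic width 10 mm, O₂ uptake 35.1 and sulfide flux 4.8 mmol m⁻² d⁻¹, pH
  peak +0.25, pH minimum 6.2 near 12 mm. Because the O₂ gradient is set by
  the planted flux, the interface concentration is a derived quantity and
  may exceed air saturation; round trips depend on the gradient, not the
  absolute level.
- **Cq tables**: standards over decades 10²–10⁷ plus samples whose Cq
  values are computed from planted layer densities through the target's
  log-linear curve, dilution (10⁴ for total bacteria, 10² otherwise),
  elution volume (100 μl) and wet mass (0.5 g), with optional Gaussian Cq
  noise. Default planted profiles emulate a stimulated incubation: cable
  bacteria at 3 × 10⁸ copies g⁻¹ in the top 1.5 cm over a 9.1 × 10⁴
  background, total bacteria 1.3 × 10¹⁰ at the surface over 5.4 × 10⁹.
- **Reference sets**: random templates with exact primer sites planted in
  in-target records (amplicon length drawn ≤200 bp) and guaranteed
  mismatches (bases chosen outside the primer's IUPAC set) at specified
  primer positions in off-target records.
- **Count tables**: multinomial read draws from planted per-layer relative
  abundances at a default depth of 52 000 reads per sample.

All randomness flows from a single scenario seed (NumPy `default_rng`);
identical specs give identical outputs. What the generator does **not**
emulate: sensor drift and calibration error, non-steady-state diagenesis,
PCR inhibition and amplification bias, chimeras and sequencing error,
phylogenetically realistic reference sequences. Passing round trips
therefore demonstrate the correctness of the computational chain, not the
field accuracy of microsensor or qPCR measurements.

## Problem sizes and numerical choices

The test suite and the acceptance script run desk-scale problems: profiles
of ~600 points, 1000-draw efficiency simulations, 200 random primer/template
draws for the search-equivalence check, reference sets of ~15 templates of
~900 nt. These sizes already exercise every code path and give sub-percent
Monte-Carlo error on the simulated proportions. Noisy-curve efficiency
simulations use σ_Cq = 0.15 over a 5-decade series, which places ≥95% of
fitted efficiencies inside the 92–104% band expected of a well-behaved
assay. Crossing depths are interpolated linearly between bracketing samples;
ties in pH extrema resolve to the shallowest grid point (NumPy argmax/argmin
semantics); degenerate inputs (zero copy density, empty reference sets,
never-depleted O₂) return explicit zeros, empty reports or None flags rather
than raising.

## Known limitations

- Steady-state, one-dimensional diffusion only; no reactive-transport or
  bioirrigation corrections.
- Dimer/hairpin heuristics do not rank thermodynamic stability.
- The census assumes straight, vertical filaments and a uniform copy
  density over the colonised depth; tortuous filaments make the length
  density a lower bound.
- Amplicon comparisons take taxonomy labels as given; classification error
  propagates directly into relative abundances.
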