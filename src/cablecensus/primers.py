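"""IUPAC-degenerate primer evaluation: expansion, mismatch-tolerant binding
site search, in-silico PCR, design-rule QC and specificity screening.

Matching semantics are asymmetric, reflecting annealing: each primer position
is an IUPAC *set* of bases, while the template must be concrete — a template
position matches iff its base is a member of the primer code's set, and an
ambiguous template base (N etc.) counts as a mismatch. For a degenerate
primer this per-position rule equals the minimum mismatch count over all
concrete expansions ("best variant" semantics).

Coordinates are 0-based half-open internally; primer positions in reports are
1-based from the primer's 5′ end.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import pandas as pd
from Bio import SeqIO
from Bio.Data.IUPACData import ambiguous_dna_values
from Bio.Seq import Seq
from Bio.SeqUtils import MeltingTemp, gc_fraction

__all__ = [
    "DegeneratePrimer",
    "BindingSite",
    "Amplicon",
    "PrimerQCReport",
    "SpecificityReport",
    "expand_degenerate",
    "count_mismatches",
    "find_binding_sites",
    "in_silico_pcr",
    "primer_qc",
    "specificity_screen",
    "load_qpcr_primers",
    "read_reference_db",
]

#: Base sets for each IUPAC nucleotide code.
IUPAC_SETS: Dict[str, frozenset] = {
    code: frozenset(bases) for code, bases in ambiguous_dna_values.items()
}
VALID_CODES = frozenset("ACGTRYSWKMBDHVN")
CONCRETE = frozenset("ACGT")

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def revcomp(seq: str) -> str:
    """Reverse complement preserving IUPAC degeneracy codes."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class DegeneratePrimer:
    """An oligonucleotide primer written 5′→3′ with IUPAC degeneracy codes.

    A reverse primer's sequence is given 5′→3′ on the reverse strand, the
    convention of primer tables; its binding site on the + strand of a
    template is the reverse complement of the primer sequence.
    """

    name: str
    sequence: str
    orientation: str = "forward"

    def __post_init__(self) -> None:
        seq = self.sequence.upper().replace(" ", "")
        object.__setattr__(self, "sequence", seq)
        bad = set(seq) - VALID_CODES
        if bad:
            raise ValueError(f"invalid IUPAC code(s) {sorted(bad)} in primer {self.name}")
        if len(seq) < 10:
            raise ValueError(f"primer {self.name} shorter than 10 nt")
        if self.orientation not in ("forward", "reverse"):
            raise ValueError("orientation must be 'forward' or 'reverse'")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def degeneracy(self) -> int:
        """Number of concrete sequences the primer represents."""
        n = 1
        for c in self.sequence:
            n *= len(IUPAC_SETS[c])
        return n


@dataclass(frozen=True)
class BindingSite:
    """A located primer match on a template.

    ``start``/``end`` are 0-based half-open + strand coordinates;
    ``mismatch_positions`` are 1-based within the primer, 5′→3′.
    """

    template_id: str
    start: int
    end: int
    strand: str
    mismatches: int
    mismatch_positions: Tuple[int, ...]


@dataclass(frozen=True)
class Amplicon:
    """A predicted PCR product on the + strand (0-based half-open)."""

    template_id: str
    start: int
    end: int
    length: int
    mismatches_fwd: int
    mismatches_rev: int

    @property
    def total_mismatches(self) -> int:
        return self.mismatches_fwd + self.mismatches_rev


def expand_degenerate(primer: Union[DegeneratePrimer, str]) -> set:
    """All concrete sequences of a degenerate primer; |result| = degeneracy."""
    seq = primer.sequence if isinstance(primer, DegeneratePrimer) else primer.upper()
    bad = set(seq) - VALID_CODES
    if bad:
        raise ValueError(f"invalid IUPAC code(s): {sorted(bad)}")
    return {"".join(p) for p in itertools.product(*(sorted(IUPAC_SETS[c]) for c in seq))}


def count_mismatches(
    primer: Union[DegeneratePrimer, str], site: str
) -> Tuple[int, Tuple[int, ...]]:
    """Mismatches between a primer and an equal-length concrete site.

    Position i (1-based from the primer 5′ end) matches iff the site base is
    in the primer code's IUPAC set; ambiguous site bases never match.
    Returns (count, sorted 1-based mismatch positions).
    """
    pseq = primer.sequence if isinstance(primer, DegeneratePrimer) else primer.upper()
    site = site.upper()
    if len(pseq) != len(site):
        raise ValueError("primer and site must have equal length")
    positions = tuple(
        i + 1
        for i, (pc, sb) in enumerate(zip(pseq, site))
        if sb not in CONCRETE or sb not in IUPAC_SETS[pc]
    )
    return len(positions), positions


def find_binding_sites(
    primer: DegeneratePrimer,
    template: str,
    max_mismatches: int = 0,
    template_id: str = "",
    three_prime_exact: int = 0,
) -> List[BindingSite]:
    """All binding sites of a primer on a template, up to ``max_mismatches``.

    Forward primers are scanned directly along the + strand; reverse primers
    are compared against the reverse complement of each window (the site they
    anneal to). ``three_prime_exact`` forbids any mismatch within that many
    bases of the primer's 3′ end. Sites are sorted by position, then by
    mismatch count.
    """
    template = template.upper()
    L = len(primer)
    if len(template) < L:
        return []
    sites: List[BindingSite] = []
    strand = "+" if primer.orientation == "forward" else "-"
    for start in range(len(template) - L + 1):
        window = template[start : start + L]
        probe = window if strand == "+" else revcomp(window)
        n, pos = count_mismatches(primer, probe)
        if n > max_mismatches:
            continue
        if three_prime_exact and any(p > L - three_prime_exact for p in pos):
            continue
        sites.append(
            BindingSite(
                template_id=template_id,
                start=start,
                end=start + L,
                strand=strand,
                mismatches=n,
                mismatch_positions=pos,
            )
        )
    sites.sort(key=lambda s: (s.start, s.mismatches))
    return sites


def in_silico_pcr(
    fwd: DegeneratePrimer,
    rev: DegeneratePrimer,
    template: str,
    max_mismatches: int = 0,
    max_amplicon: int = 200,
    template_id: str = "",
    three_prime_exact: int = 0,
) -> List[Amplicon]:
    """Predict PCR products of a primer pair on one template.

    Enumerates all forward/reverse binding-site pairs in productive
    orientation (the reverse site downstream of, and not overlapping, the
    forward site) with product length — forward 5′ through reverse 5′ on the
    + strand, inclusive — at most ``max_amplicon``. ``max_mismatches``
    applies to each primer separately.
    """
    if fwd.orientation != "forward" or rev.orientation != "reverse":
        raise ValueError("expected a (forward, reverse) primer pair")
    fsites = find_binding_sites(fwd, template, max_mismatches, template_id, three_prime_exact)
    rsites = find_binding_sites(rev, template, max_mismatches, template_id, three_prime_exact)
    out = []
    for fs in fsites:
        for rs in rsites:
            if rs.start < fs.end:
                continue
            length = rs.end - fs.start
            if length <= max_amplicon:
                out.append(
                    Amplicon(
                        template_id=template_id,
                        start=fs.start,
                        end=rs.end,
                        length=length,
                        mismatches_fwd=fs.mismatches,
                        mismatches_rev=rs.mismatches,
                    )
                )
    out.sort(key=lambda a: (a.start, a.length))
    return out


# --- primer QC -------------------------------------------------------------


@dataclass
class PrimerQCReport:
    """Design-rule check of a primer (GC band, ends, secondary structure, Tm)."""

    name: str
    gc_percent_range: Tuple[float, float]
    gc_in_band: bool
    starts_with_gc: bool
    three_prime_gc_count: int
    gc_rich_end: bool
    hairpin: bool
    self_dimer: bool
    hetero_dimer: Optional[bool]
    tm_range_c: Tuple[float, float]


def _longest_complementary_run(a: str, b: str) -> Tuple[int, bool]:
    """Longest antiparallel complementary run between two concrete sequences.

    Equals the longest common substring of ``a`` and revcomp(``b``). Returns
    (run length, whether the run reaches the 3′ end of either sequence).
    """
    rb = revcomp(b)
    n, m = len(a), len(rb)
    best, anchored = 0, False
    # O(n·m) dynamic program; primers are short.
    prev = [0] * (m + 1)
    for i in range(1, n + 1):
        cur = [0] * (m + 1)
        for j in range(1, m + 1):
            if a[i - 1] == rb[j - 1]:
                cur[j] = prev[j - 1] + 1
                if cur[j] > best or (cur[j] == best and not anchored):
                    at_a3 = i == n
                    # rb index j-1 corresponds to b position m-j; b's 3' end is b[-1] = rb[0]
                    at_b3 = (j - cur[j]) == 0
                    if cur[j] > best:
                        best, anchored = cur[j], at_a3 or at_b3
                    elif at_a3 or at_b3:
                        anchored = True
        prev = cur
    return best, anchored


def _has_hairpin(seq: str, seed: int = 4, min_loop: int = 3) -> bool:
    """Internal reverse-complementary seed of length ≥ seed, loop ≥ min_loop."""
    n = len(seq)
    for i in range(n - 2 * seed - min_loop + 1):
        stem = seq[i : i + seed]
        target = revcomp(stem)
        rest = seq[i + seed + min_loop :]
        if target in rest:
            return True
    return False


def primer_qc(
    primer: DegeneratePrimer,
    partner: Optional[DegeneratePrimer] = None,
    thermo: Optional[dict] = None,
    gc_band: Tuple[float, float] = (40.0, 60.0),
    clamp_threshold: int = 4,
    hairpin_seed: int = 4,
    dimer_run: int = 5,
) -> PrimerQCReport:
    """Check a primer against standard qPCR design rules.

    Rules: GC content within ``gc_band`` percent; 5′ base preferably G/C; no
    GC-rich 3′ end (≥ ``clamp_threshold`` G/C among the last five bases); no
    hairpin (internal reverse-complementary seed ≥ ``hairpin_seed`` separated
    by ≥3 bases); no self- or hetero-dimer (longest antiparallel
    complementary run ≥ ``dimer_run``). Tm by nearest-neighbor thermodynamics
    with salt correction; ranges are over all concrete expansions of a
    degenerate primer.

    ``thermo`` passes keyword arguments through to
    ``Bio.SeqUtils.MeltingTemp.Tm_NN`` (e.g. Na, Mg, dnac1, saltcorr).
    """
    thermo = dict(thermo or {})
    thermo.setdefault("Na", 50.0)
    thermo.setdefault("Mg", 3.0)
    variants = sorted(expand_degenerate(primer))
    gcs = [100.0 * gc_fraction(v) for v in variants]
    tms = [float(MeltingTemp.Tm_NN(Seq(v), **thermo)) for v in variants]
    clamp = sum(1 for b in primer.sequence[-5:] if IUPAC_SETS[b] <= {"G", "C"})
    self_run = max(_longest_complementary_run(v, v)[0] for v in variants)
    hetero = None
    if partner is not None:
        hetero = any(
            _longest_complementary_run(v, w)[0] >= dimer_run
            for v in variants
            for w in expand_degenerate(partner)
        )
    return PrimerQCReport(
        name=primer.name,
        gc_percent_range=(min(gcs), max(gcs)),
        gc_in_band=all(gc_band[0] <= g <= gc_band[1] for g in gcs),
        starts_with_gc=IUPAC_SETS[primer.sequence[0]] <= {"G", "C"},
        three_prime_gc_count=clamp,
        gc_rich_end=clamp >= clamp_threshold,
        hairpin=any(_has_hairpin(v, hairpin_seed) for v in variants),
        self_dimer=self_run >= dimer_run,
        hetero_dimer=hetero,
        tm_range_c=(min(tms), max(tms)),
    )


# --- specificity screening --------------------------------------------------


@dataclass
class SpecificityReport:
    """Per-taxon hit counts at each mismatch level.

    ``counts`` is a tidy DataFrame with columns taxon, max_mismatches, hits,
    n_templates; ``mode`` is 'single' or 'pair'. For pairs a template counts
    only when both primers bind in productive orientation within the amplicon
    limit, the mismatch allowance applying to each primer separately.
    """

    counts: pd.DataFrame
    mode: str
    skipped: Tuple[str, ...] = ()

    def hits(self, taxon: str, level: int) -> int:
        sub = self.counts[
            (self.counts["taxon"] == taxon) & (self.counts["max_mismatches"] == level)
        ]
        return int(sub["hits"].iloc[0]) if len(sub) else 0


def read_reference_db(fasta_path: str | Path, taxonomy_path: str | Path):
    """Load a reference set: FASTA sequences plus a 2-column taxonomy TSV
    (record_id, semicolon-delimited lineage)."""
    records = {r.id: str(r.seq).upper() for r in SeqIO.parse(str(fasta_path), "fasta")}
    tax = pd.read_csv(taxonomy_path, sep="\t", header=None, names=["record_id", "lineage"])
    taxonomy = dict(zip(tax["record_id"], tax["lineage"]))
    return records, taxonomy


def specificity_screen(
    primer_or_pair: Union[DegeneratePrimer, Tuple[DegeneratePrimer, DegeneratePrimer]],
    references: Dict[str, str],
    taxonomy: Dict[str, str],
    mismatch_levels: Sequence[int] = (0, 1),
    max_amplicon: int = 200,
    rank: Optional[int] = None,
    three_prime_exact: int = 0,
) -> SpecificityReport:
    """Count reference templates hit per taxon at each mismatch allowance.

    ``references`` maps record id to sequence, ``taxonomy`` maps record id to
    a semicolon-delimited lineage string. ``rank`` selects one lineage field
    for grouping (default: the full lineage string). Records without a
    taxonomy row are excluded with a warning entry in ``skipped``.
    """
    if isinstance(primer_or_pair, tuple):
        mode = "pair"
        fwd, rev = primer_or_pair
    else:
        mode = "single"

    skipped = tuple(rid for rid in references if rid not in taxonomy)

    def taxon_of(rid: str) -> str:
        lin = taxonomy[rid]
        return lin.split(";")[rank].strip() if rank is not None else lin

    rows = []
    usable = [rid for rid in references if rid in taxonomy]
    taxa = sorted({taxon_of(rid) for rid in usable})
    per_taxon_n = {t: sum(1 for rid in usable if taxon_of(rid) == t) for t in taxa}
    for level in mismatch_levels:
        hit_counts = {t: 0 for t in taxa}
        for rid in usable:
            seq = references[rid]
            if mode == "pair":
                hit = bool(
                    in_silico_pcr(
                        fwd, rev, seq, level, max_amplicon, rid, three_prime_exact
                    )
                )
            else:
                hit = bool(
                    find_binding_sites(
                        primer_or_pair, seq, level, rid, three_prime_exact
                    )
                )
            if hit:
                hit_counts[taxon_of(rid)] += 1
        for t in taxa:
            rows.append(
                {
                    "taxon": t,
                    "max_mismatches": level,
                    "hits": hit_counts[t],
                    "n_templates": per_taxon_n[t],
                }
            )
    return SpecificityReport(counts=pd.DataFrame(rows), mode=mode, skipped=skipped)


def load_qpcr_primers() -> Dict[str, DegeneratePrimer]:
    """Packaged qPCR primer table (total bacteria, Desulfobulbaceae and
    Ca. Electrothrix assays), keyed by primer name."""
    with resources.files("cablecensus.data").joinpath("primers_qpcr.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    return {
        row["name"]: DegeneratePrimer(row["name"], row["sequence"], row["orientation"])
        for _, row in df.iterrows()
    }
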