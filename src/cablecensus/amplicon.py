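"""Cross-validation of qPCR copy densities against 16S amplicon abundances.

Per depth layer, the qPCR relative abundance (target copies / total-bacteria
copies, %) is paired with the amplicon relative abundance (target reads /
bacterial reads, %); a regression of one on the other tests whether the two
enumeration routes agree, and the sequencing depth sets a copy-density
detection floor for an amplicon sequence variant (ASV).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "AbundanceComparison",
    "relative_abundances",
    "ratio_regression",
    "asv_detection_limit",
]


@dataclass
class AbundanceComparison:
    """Paired qPCR / amplicon relative abundances for one depth layer (%)."""

    layer: str
    qpcr_rel: float
    amplicon_rel: float
    group: Optional[str] = None

    def __post_init__(self) -> None:
        for v in (self.qpcr_rel, self.amplicon_rel):
            if not 0.0 <= v <= 100.0:
                raise ValueError("relative abundances must lie in [0, 100]")


def relative_abundances(
    copy_table: pd.DataFrame,
    counts: pd.DataFrame,
    target_taxon: str,
    target: str = "CB",
    total: str = "TB",
    include_unclassified: bool = False,
    group: Optional[str] = None,
) -> List[AbundanceComparison]:
    """Pair per-layer qPCR and amplicon relative abundances.

    Parameters
    ----------
    copy_table : DataFrame
        Columns ``layer``, ``target``, ``copy_density`` — copy densities per
        depth layer for at least the target and the total-bacteria assay.
    counts : DataFrame
        ASV count matrix: a ``taxonomy`` column (semicolon-delimited lineage)
        plus one column per layer id.
    target_taxon : str
        Substring of the lineage identifying target reads.
    include_unclassified : bool
        If False (default) the read denominator is reads classified as
        Bacteria (lineage starting with 'Bacteria'); if True, all reads.

    Layers lacking either measurement are dropped with a log entry; a layer
    with zero denominator reads raises.
    """
    pivot = copy_table.pivot_table(
        index="layer", columns="target", values="copy_density", aggfunc="mean"
    )
    layer_cols = [c for c in counts.columns if c != "taxonomy"]
    out: List[AbundanceComparison] = []
    for layer in pivot.index:
        if layer not in layer_cols:
            logger.info("layer %s missing from the count table; dropped", layer)
            continue
        row = pivot.loc[layer]
        if target not in row or total not in row or pd.isna(row[target]) or pd.isna(row[total]):
            logger.info("layer %s lacks a qPCR measurement; dropped", layer)
            continue
        col = counts[layer]
        if include_unclassified:
            denom = int(col.sum())
        else:
            bacterial = counts["taxonomy"].str.startswith("Bacteria")
            denom = int(col[bacterial].sum())
        if denom == 0:
            raise ValueError(f"layer {layer} has zero denominator reads")
        target_reads = int(col[counts["taxonomy"].str.contains(target_taxon, regex=False)].sum())
        out.append(
            AbundanceComparison(
                layer=str(layer),
                qpcr_rel=100.0 * row[target] / row[total],
                amplicon_rel=100.0 * target_reads / denom,
                group=group,
            )
        )
    return out


def ratio_regression(
    pairs: Sequence[AbundanceComparison],
    through_origin: bool = True,
) -> Tuple[float, float]:
    """Least-squares slope (and r²) of qPCR on amplicon relative abundance.

    ``through_origin=True`` (default) regresses y = b·x, the natural model
    when the object of interest is the ratio of two abundance measures; the
    intercept variant is available for comparison. Returns (slope, r²), with
    r² computed against the fitted model.
    """
    if len(pairs) < 2:
        raise ValueError("need at least 2 pairs")
    x = np.array([p.amplicon_rel for p in pairs], dtype=float)
    y = np.array([p.qpcr_rel for p in pairs], dtype=float)
    if np.allclose(x.var(), 0.0) and not through_origin:
        raise ValueError("degenerate x variance")
    if through_origin:
        sxx = float(np.sum(x * x))
        if sxx == 0:
            raise ValueError("degenerate x values")
        slope = float(np.sum(x * y) / sxx)
        yhat = slope * x
    else:
        slope, intercept = np.polyfit(x, y, 1)
        yhat = slope * x + intercept
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return float(slope), float(r2)


def asv_detection_limit(tb_copy_density: float, total_reads: int) -> float:
    """Copy density corresponding to a single read at the observed depth.

    One read out of ``total_reads`` represents tb_copy_density / total_reads
    copies per gram wet sediment — the floor below which an ASV is invisible
    to amplicon sequencing.
    """
    if total_reads < 1:
        raise ValueError("total_reads must be at least 1")
    if tb_copy_density < 0:
        raise ValueError("copy density must be non-negative")
    return tb_copy_density / total_reads
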