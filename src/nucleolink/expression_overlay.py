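"""Differential-expression thresholding and its bridge to enrichment tests.

The DE statistics themselves (fold changes and q-values) are consumed, not
computed: records carry a gene id, a log2 fold change (mutant over
wild-type) and an FDR-adjusted q-value.  Classification applies a q cutoff
(default 0.01) with a linear fold cutoff of 1.41 (~sqrt(2), i.e. |log2FC|
>= 0.5); "strong" subsets use a strict > 2-fold change.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .enrichment_stats import EnrichmentResult, hypergeometric_overlap
from .genome_model import GenomicInterval, overlaps

__all__ = [
    "DESets",
    "classify_de",
    "misregulated_summary",
    "genes_with_promoter_overlap",
    "genes_with_up_nucleosome_promoters",
    "promoter_alteration_overlap",
]


@dataclass
class DESets:
    up: set[str] = field(default_factory=set)
    down: set[str] = field(default_factory=set)
    strong_up: set[str] = field(default_factory=set)
    strong_down: set[str] = field(default_factory=set)
    n_skipped: int = 0


def classify_de(
    records: pd.DataFrame,
    q_cut: float = 0.01,
    fold_cut: float = 1.41,
    strong_cut: float = 2.0,
) -> DESets:
    """Split genes into up/down(/strong) sets by q-value and fold thresholds.

    The fold cut is inclusive on the linear scale (fold >= 1.41, so log2FC =
    0.5 qualifies); the strong cut is strict (> 2-fold).  Records with a
    missing fold change or q-value are skipped and counted.
    """
    if fold_cut <= 1 or strong_cut <= 1:
        raise ValueError("fold cuts must exceed 1")
    sets = DESets()
    for row in records.itertuples(index=False):
        lfc, q = row.log2fc, row.qvalue
        if pd.isna(lfc) or pd.isna(q):
            sets.n_skipped += 1
            continue
        if q >= q_cut:
            continue
        fold_up = 2.0**lfc
        fold_down = 2.0**-lfc
        if fold_up >= fold_cut:
            sets.up.add(row.gene)
            if fold_up > strong_cut:
                sets.strong_up.add(row.gene)
        elif fold_down >= fold_cut:
            sets.down.add(row.gene)
            if fold_down > strong_cut:
                sets.strong_down.add(row.gene)
    return sets


def misregulated_summary(up: set[str], down: set[str], universe_size: int) -> dict:
    """Counts of misregulated genes and their percentage of the gene universe."""
    if universe_size <= 0:
        raise ValueError("universe_size must be positive")
    if up & down:
        raise ValueError("up and down sets overlap")
    total = len(up) + len(down)
    return {
        "up": len(up),
        "down": len(down),
        "misregulated": total,
        "universe": universe_size,
        "percent": 100.0 * total / universe_size,
    }


def genes_with_promoter_overlap(
    intervals: list[GenomicInterval],
    promoters: dict[str, GenomicInterval],
) -> set[str]:
    """Genes whose promoter window overlaps any given interval by >= 1 bp."""
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    out = set()
    for gid, prom in promoters.items():
        if prom is None:
            continue
        for iv in by_chrom.get(prom.chrom, []):
            if overlaps(prom, iv) >= 1:
                out.add(gid)
                break
    return out


def genes_with_up_nucleosome_promoters(
    up_nucleosomes: list[GenomicInterval],
    promoters: dict[str, GenomicInterval],
) -> set[str]:
    """Genes whose promoter holds at least one occupancy-increase nucleosome."""
    return genes_with_promoter_overlap(up_nucleosomes, promoters)


def promoter_alteration_overlap(
    de_genes: set[str],
    up_nucleosome_genes: set[str],
    universe: list[str],
) -> EnrichmentResult:
    """Overlap between a DE gene set and genes with up-nucleosome promoters."""
    uni = set(universe)
    k = len(de_genes & up_nucleosome_genes & uni)
    return hypergeometric_overlap(
        len(uni), len(up_nucleosome_genes & uni), len(de_genes & uni), k
    )


def volcano_frame(records: pd.DataFrame) -> pd.DataFrame:
    """log2FC vs -log10 q table, the standard volcano-plot coordinates."""
    out = records.copy()
    out["neg_log10_q"] = out["qvalue"].map(
        lambda q: -math.log10(q) if q and q > 0 else float("inf")
    )
    return out
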