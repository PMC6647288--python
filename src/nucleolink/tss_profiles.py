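"""TSS-aligned occupancy matrices, metaprofiles and per-nucleosome tests.

Rows are genes, columns are strand-oriented positions relative to the TSS
(upstream negative, so the +1 nucleosome is downstream for every row).  The
mean over rows is the metaprofile; its local maxima around the promoter NFR
are labelled -2, -1 (upstream) and +1..+5 (downstream), and occupancy "at"
a labelled nucleosome is the mean signal in a small window around the
labelled peak position.  Genotypes are compared per label with a paired
two-tailed t-test across genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genome_model import GenomeAnnotation

__all__ = [
    "TSSMatrix",
    "build_tss_matrix",
    "locate_canonical_nucleosomes",
    "paired_occupancy_test",
    "select_control_genes",
]

CANONICAL_LABELS = (-2, -1, 1, 2, 3, 4, 5)


@dataclass
class TSSMatrix:
    values: np.ndarray  # genes x positions
    genes: list[str]
    offsets: np.ndarray  # positions relative to TSS, upstream negative

    def metaprofile(self) -> np.ndarray:
        return self.values.mean(axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.offsets)


def build_tss_matrix(
    track: dict[str, np.ndarray],
    annotation: GenomeAnnotation,
    window: int = 1000,
    gene_ids: list[str] | None = None,
) -> TSSMatrix:
    """Strand-oriented occupancy matrix around each gene's TSS.

    Minus-strand rows are mirrored so downstream is always positive.  Rows
    are normalised by the genome-wide mean track level (library size), so
    matrices from libraries of different depth are comparable.  Genes whose
    window leaves the chromosome are skipped with a warning.
    """
    ids = gene_ids if gene_ids is not None else sorted(annotation.genes)
    offsets = np.arange(-window, window + 1)
    total = sum(float(t.sum()) for t in track.values())
    length = sum(len(t) for t in track.values())
    norm = (total / length) if length and total > 0 else 1.0
    rows, kept = [], []
    skipped = 0
    for gid in ids:
        gene = annotation.genes[gid]
        chrom = gene.interval.chrom
        arr = track.get(chrom)
        if arr is None:
            skipped += 1
            continue
        tss = gene.tss
        if tss - window < 0 or tss + window + 1 > len(arr):
            skipped += 1
            continue
        row = arr[tss - window : tss + window + 1]
        if gene.strand == "-":
            row = row[::-1]
        rows.append(row / norm)
        kept.append(gid)
    if skipped:
        warnings.warn(f"{skipped} genes skipped (window outside chromosome)")
    values = np.vstack(rows) if rows else np.empty((0, len(offsets)))
    return TSSMatrix(values=values, genes=kept, offsets=offsets)


def locate_canonical_nucleosomes(
    metaprofile: np.ndarray,
    offsets: np.ndarray,
    min_separation: int = 120,
    nfr_search: tuple[int, int] = (-250, 60),
) -> dict[int, int]:
    """Label the -2..+5 nucleosome peaks of a TSS metaprofile.

    The promoter NFR is located as the profile minimum in ``nfr_search``;
    peaks are then scanned outward from it, the first ones downstream
    becoming +1..+5 and the first two upstream -1 and -2.  Fewer peaks than
    labels yields a partial set with a warning.
    """
    from scipy.signal import find_peaks

    lo = int(np.searchsorted(offsets, nfr_search[0]))
    hi = int(np.searchsorted(offsets, nfr_search[1]))
    if hi <= lo:
        raise ValueError("NFR search window outside the profile")
    nfr_pos = offsets[lo + int(np.argmin(metaprofile[lo:hi]))]
    peaks, _ = find_peaks(metaprofile, distance=min_separation)
    peak_offsets = offsets[peaks]
    down = peak_offsets[peak_offsets > nfr_pos]
    up = peak_offsets[peak_offsets < nfr_pos][::-1]  # closest to NFR first
    out: dict[int, int] = {}
    for i, off in enumerate(down[:5], start=1):
        out[i] = int(off)
    for i, off in enumerate(up[:2], start=1):
        out[-i] = int(off)
    if len(out) < len(CANONICAL_LABELS):
        warnings.warn(
            f"only {len(out)} of {len(CANONICAL_LABELS)} canonical nucleosomes located"
        )
    return out


def _label_values(matrix: TSSMatrix, position: int, halfwin: int) -> np.ndarray:
    lo = int(np.searchsorted(matrix.offsets, position - halfwin))
    hi = int(np.searchsorted(matrix.offsets, position + halfwin + 1))
    return matrix.values[:, lo:hi].mean(axis=1)


def paired_occupancy_test(
    matrix_a: TSSMatrix,
    matrix_b: TSSMatrix,
    canonical_positions: dict[int, int],
    halfwin: int = 20,
) -> pd.DataFrame:
    """Paired two-tailed t-test per canonical nucleosome across shared genes.

    Occupancy "at" a label is the mean signal within +/- ``halfwin`` bp of
    the labelled peak.  Rows must describe the same genes in the same
    order.  Zero variance of the paired differences is reported as p = 0
    with a degenerate flag.
    """
    if matrix_a.genes != matrix_b.genes:
        raise ValueError("matrices must cover the same genes in the same order")
    n = len(matrix_a.genes)
    if n < 2:
        raise ValueError("need at least 2 genes for a paired test")
    rows = []
    for label, pos in sorted(canonical_positions.items()):
        a = _label_values(matrix_a, pos, halfwin)
        b = _label_values(matrix_b, pos, halfwin)
        diff = b - a
        degenerate = bool(np.allclose(diff.std(ddof=1), 0.0))
        if degenerate:
            t, p = (0.0, 1.0) if np.allclose(diff, 0.0) else (np.inf, 0.0)
        else:
            res = stats.ttest_rel(b, a)
            t, p = float(res.statistic), float(res.pvalue)
        rows.append(
            {
                "label": label,
                "position": pos,
                "mean_a": float(a.mean()),
                "mean_b": float(b.mean()),
                "t": t,
                "df": n - 1,
                "pvalue": p,
                "degenerate": degenerate,
            }
        )
    return pd.DataFrame(rows)


def select_control_genes(
    annotation: GenomeAnnotation,
    excluded_gene_sets: list[set[str]],
    chromosomes: list[str],
) -> list[str]:
    """Genes on the named chromosomes minus any excluded (misregulated) gene."""
    unknown = [c for c in chromosomes if c not in annotation.chromosomes]
    if unknown:
        raise ValueError(f"unknown chromosomes: {unknown}")
    excluded: set[str] = set().union(*excluded_gene_sets) if excluded_gene_sets else set()
    out = [
        gid
        for gid, gene in sorted(annotation.genes.items())
        if gene.interval.chrom in chromosomes and gid not in excluded
    ]
    if not out:
        raise ValueError("no control genes left after exclusions")
    return out
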