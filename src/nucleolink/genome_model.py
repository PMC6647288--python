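"""Genome coordinate types, annotation I/O and interval algebra.

All coordinates are 0-based, half-open internally; GFF3 I/O converts
from/to the 1-based closed convention of that format.  The module derives
intergenic regions (IGRs) with orientation labels from the flanking gene
strands, builds strand-aware promoter windows, and assigns arbitrary
intervals to genomic region classes (rDNA, telomere, pericentromeric,
tDNA, ARS, IGR, ORF) with a fixed precedence, which is how nucleosomes
and cohesin peaks are later tabulated per region.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "GenomicInterval",
    "Gene",
    "GenomeAnnotation",
    "IGR",
    "IGRCatalog",
    "GeneCategoryMap",
    "overlaps",
    "derive_igrs",
    "promoter_interval",
    "assign_to_region_classes",
    "read_gff3",
    "write_gff3",
    "read_bed6",
    "write_bed6",
    "read_category_map",
    "write_category_map",
    "REGION_CLASS_PRECEDENCE",
]

#: Feature classes tracked in annotations, in their region-class precedence
#: order (earlier wins when an interval hits several classes).
REGION_CLASS_PRECEDENCE = (
    "rDNA",
    "telomere",
    "pericentromeric",
    "tDNA",
    "ARS",
    "IGR",
    "ORF",
)

FEATURE_CLASSES = ("tDNA", "ARS", "telomere", "centromere", "rDNA")

# GFF3 feature types used on disk for each feature class.
_GFF_TYPE = {
    "tDNA": "tRNA_gene",
    "ARS": "ARS",
    "telomere": "telomere",
    "centromere": "centromere",
    "rDNA": "rRNA_gene",
}
_GFF_TYPE_INV = {v: k for k, v in _GFF_TYPE.items()}


class AnnotationError(ValueError):
    """Raised when an annotation or interval refers to unknown coordinates."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open interval on a named chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"empty/inverted interval {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


def overlaps(a: GenomicInterval, b: GenomicInterval) -> int:
    """Overlap length in bp between two intervals (0 if different chromosomes).

    Two features "overlap" in the downstream counting operations when this
    returns >= 1; abutting half-open intervals return 0.
    """
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


@dataclass(frozen=True)
class Gene:
    gene_id: str
    interval: GenomicInterval
    strand: str  # '+' or '-'

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r} for {self.gene_id}")

    @property
    def tss(self) -> int:
        """TSS position: interval start on '+', interval end - 1 on '-'."""
        return self.interval.start if self.strand == "+" else self.interval.end - 1


@dataclass
class GenomeAnnotation:
    """Chromosome sizes, genes and non-genic feature catalogs."""

    chromosomes: dict[str, int]
    genes: dict[str, Gene] = field(default_factory=dict)
    features: dict[str, list[GenomicInterval]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cls in FEATURE_CLASSES:
            self.features.setdefault(cls, [])
        self.validate()

    def validate(self) -> None:
        for gene in self.genes.values():
            self._check(gene.interval, f"gene {gene.gene_id}")
        for cls, ivs in self.features.items():
            if cls not in FEATURE_CLASSES:
                raise AnnotationError(f"unknown feature class {cls!r}")
            for iv in ivs:
                self._check(iv, cls)

    def _check(self, iv: GenomicInterval, what: str) -> None:
        if iv.chrom not in self.chromosomes:
            raise AnnotationError(f"{what}: unknown chromosome {iv.chrom!r}")
        if iv.end > self.chromosomes[iv.chrom]:
            raise AnnotationError(
                f"{what}: {iv.chrom}:{iv.start}-{iv.end} exceeds chromosome "
                f"length {self.chromosomes[iv.chrom]}"
            )

    def genes_on(self, chrom: str) -> list[Gene]:
        return sorted(
            (g for g in self.genes.values() if g.interval.chrom == chrom),
            key=lambda g: (g.interval.start, g.interval.end),
        )


@dataclass(frozen=True)
class IGR:
    interval: GenomicInterval
    orientation: str  # convergent / divergent / tandem / end
    left_gene: str | None
    right_gene: str | None


@dataclass
class IGRCatalog:
    igrs: list[IGR]

    def by_orientation(self) -> dict[str, list[IGR]]:
        out: dict[str, list[IGR]] = {}
        for igr in self.igrs:
            out.setdefault(igr.orientation, []).append(igr)
        return out

    def intervals(self) -> list[GenomicInterval]:
        return [igr.interval for igr in self.igrs]


def _orientation(left: Gene | None, right: Gene | None) -> str:
    if left is None or right is None:
        return "end"
    if left.strand == "+" and right.strand == "-":
        return "convergent"
    if left.strand == "-" and right.strand == "+":
        return "divergent"
    return "tandem"


def derive_igrs(annotation: GenomeAnnotation) -> IGRCatalog:
    """Maximal inter-gene-body intervals labelled by flanking gene orientation.

    Overlapping/abutting gene bodies are merged first, so a 0 bp gap yields
    no IGR.  Gaps between a chromosome end and the first/last gene are
    labelled ``end``.
    """
    igrs: list[IGR] = []
    for chrom, length in annotation.chromosomes.items():
        genes = annotation.genes_on(chrom)
        if not genes:
            continue
        # merge gene bodies into blocks, remembering boundary genes
        blocks: list[tuple[int, int, Gene, Gene]] = []  # start, end, first, last
        for g in genes:
            s, e = g.interval.start, g.interval.end
            if blocks and s <= blocks[-1][1]:
                bs, be, bf, bl = blocks[-1]
                if e > be:
                    blocks[-1] = (bs, e, bf, g)
            else:
                blocks.append((s, e, g, g))
        if blocks[0][0] > 0:
            igrs.append(
                IGR(
                    GenomicInterval(chrom, 0, blocks[0][0]),
                    "end",
                    None,
                    blocks[0][2].gene_id,
                )
            )
        for (s1, e1, f1, l1), (s2, e2, f2, l2) in zip(blocks, blocks[1:]):
            if s2 > e1:
                igrs.append(
                    IGR(
                        GenomicInterval(chrom, e1, s2),
                        _orientation(l1, f2),
                        l1.gene_id,
                        f2.gene_id,
                    )
                )
        if blocks[-1][1] < length:
            igrs.append(
                IGR(
                    GenomicInterval(chrom, blocks[-1][1], length),
                    "end",
                    blocks[-1][3].gene_id,
                    None,
                )
            )
    return IGRCatalog(igrs)


def promoter_interval(
    gene: Gene, upstream_len: int = 500, chrom_length: int | None = None
) -> GenomicInterval | None:
    """Strand-aware promoter window of ``upstream_len`` bp upstream of the TSS.

    '+' strand genes get [TSS - len, TSS); '-' strand genes the mirrored
    window [TSS, TSS + len).  Windows are clipped to chromosome bounds; a
    window clipped to nothing returns None with a warning.
    """
    if upstream_len <= 0:
        raise ValueError("upstream_len must be positive")
    tss = gene.tss
    chrom = gene.interval.chrom
    if gene.strand == "+":
        start, end = tss - upstream_len, tss
    else:
        start, end = tss, tss + upstream_len
    start = max(0, start)
    if chrom_length is not None:
        end = min(end, chrom_length)
    if start >= end:
        warnings.warn(
            f"promoter of {gene.gene_id} clipped to nothing at chromosome edge"
        )
        return None
    return GenomicInterval(chrom, start, end)


def _class_intervals(
    annotation: GenomeAnnotation,
    igrs: IGRCatalog,
    pericentromeric_halfwidth: int,
) -> dict[str, list[GenomicInterval]]:
    peri = []
    for cen in annotation.features.get("centromere", []):
        length = annotation.chromosomes[cen.chrom]
        peri.append(
            GenomicInterval(
                cen.chrom,
                max(0, cen.start - pericentromeric_halfwidth),
                min(length, cen.end + pericentromeric_halfwidth),
            )
        )
    return {
        "rDNA": annotation.features.get("rDNA", []),
        "telomere": annotation.features.get("telomere", []),
        "pericentromeric": peri,
        "tDNA": annotation.features.get("tDNA", []),
        "ARS": annotation.features.get("ARS", []),
        "IGR": igrs.intervals(),
        "ORF": [g.interval for g in annotation.genes.values()],
    }


def assign_to_region_classes(
    intervals: list[GenomicInterval],
    annotation: GenomeAnnotation,
    igrs: IGRCatalog,
    pericentromeric_halfwidth: int = 10_000,
) -> list[str]:
    """Assign each interval exactly one region class.

    Classes are tested in ``REGION_CLASS_PRECEDENCE`` order; the first class
    the interval overlaps by >= 1 bp wins (so a nucleosome inside an IGR
    within the pericentromeric span is counted as pericentromeric, and
    anything in the rDNA span is rDNA regardless of internal annotation).
    Intervals hitting nothing are classed ``other``.
    """
    by_class = _class_intervals(annotation, igrs, pericentromeric_halfwidth)
    # index class intervals per chromosome, sorted, for binary-search lookup
    import bisect

    index: dict[str, dict[str, tuple[list[int], list[int]]]] = {}
    for cls, ivs in by_class.items():
        per: dict[str, list[tuple[int, int]]] = {}
        for iv in ivs:
            per.setdefault(iv.chrom, []).append((iv.start, iv.end))
        index[cls] = {
            chrom: ([s for s, _ in sorted(v)], [e for _, e in sorted(v)])
            for chrom, v in per.items()
        }

    def hits(cls: str, iv: GenomicInterval) -> bool:
        got = index[cls].get(iv.chrom)
        if not got:
            return False
        starts, ends = got
        i = bisect.bisect_right(starts, iv.end - 1)
        # any member among the first i with end > iv.start overlaps
        lo = max(0, i - 64)  # class intervals are near-disjoint; bounded scan
        return any(e > iv.start for e in ends[lo:i])

    out = []
    for iv in intervals:
        if iv.chrom not in annotation.chromosomes:
            raise AnnotationError(f"interval on unknown chromosome {iv.chrom!r}")
        for cls in REGION_CLASS_PRECEDENCE:
            if hits(cls, iv):
                out.append(cls)
                break
        else:
            out.append("other")
    return out


@dataclass
class GeneCategoryMap:
    """Named gene categories over an explicit, ordered gene universe.

    The universe size N is the denominator of every enrichment test
    downstream and is therefore never inferred from a category.
    """

    universe: list[str]
    categories: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        uni = set(self.universe)
        if len(uni) != len(self.universe):
            raise ValueError("universe contains duplicate gene ids")
        for name, members in self.categories.items():
            extra = members - uni
            if extra:
                raise ValueError(
                    f"category {name!r} has members outside the universe: "
                    f"{sorted(extra)[:5]}"
                )

    @property
    def n(self) -> int:
        return len(self.universe)

    def size(self, category: str) -> int:
        return len(self.categories[category])

    def add(self, name: str, members: set[str]) -> None:
        extra = members - set(self.universe)
        if extra:
            raise ValueError(f"members outside universe: {sorted(extra)[:5]}")
        self.categories[name] = set(members)


# ---------------------------------------------------------------------------
# I/O


def write_gff3(annotation: GenomeAnnotation, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom, length in annotation.chromosomes.items():
            fh.write(f"##sequence-region {chrom} 1 {length}\n")
        for gene in sorted(
            annotation.genes.values(), key=lambda g: (g.interval.chrom, g.interval.start)
        ):
            iv = gene.interval
            fh.write(
                f"{iv.chrom}\tnucleolink\tgene\t{iv.start + 1}\t{iv.end}\t.\t"
                f"{gene.strand}\t.\tID={gene.gene_id}\n"
            )
        for cls in FEATURE_CLASSES:
            for i, iv in enumerate(annotation.features.get(cls, [])):
                fh.write(
                    f"{iv.chrom}\tnucleolink\t{_GFF_TYPE[cls]}\t{iv.start + 1}\t"
                    f"{iv.end}\t.\t.\t.\tID={cls}_{i + 1}\n"
                )


def read_gff3(path) -> GenomeAnnotation:
    """Read an annotation written by :func:`write_gff3` (or compatible GFF3)."""
    import gffutils

    chromosomes: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("##sequence-region"):
                _, chrom, _start, end = line.split()
                chromosomes[chrom] = int(end)
            elif not line.startswith("#"):
                break
    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    genes: dict[str, Gene] = {}
    features: dict[str, list[GenomicInterval]] = {c: [] for c in FEATURE_CLASSES}
    for feat in db.all_features():
        chromosomes.setdefault(feat.seqid, 0)
        iv = GenomicInterval(feat.seqid, feat.start - 1, feat.end)
        if feat.featuretype == "gene":
            gid = feat.attributes.get("ID", [feat.id])[0]
            genes[gid] = Gene(gid, iv, feat.strand if feat.strand in "+-" else "+")
        elif feat.featuretype in _GFF_TYPE_INV:
            features[_GFF_TYPE_INV[feat.featuretype]].append(iv)
    for chrom in list(chromosomes):
        if chromosomes[chrom] == 0:  # no pragma: fall back to max coordinate
            chromosomes[chrom] = max(
                [g.interval.end for g in genes.values() if g.interval.chrom == chrom]
                + [iv.end for ivs in features.values() for iv in ivs if iv.chrom == chrom]
            )
    return GenomeAnnotation(chromosomes, genes, features)


def write_bed6(intervals, path, names=None, scores=None, strands=None) -> None:
    rows = []
    for i, iv in enumerate(intervals):
        rows.append(
            (
                iv.chrom,
                iv.start,
                iv.end,
                names[i] if names is not None else f"region_{i + 1}",
                scores[i] if scores is not None else 0,
                strands[i] if strands is not None else ".",
            )
        )
    pd.DataFrame(
        rows, columns=["chrom", "start", "end", "name", "score", "strand"]
    ).to_csv(path, sep="\t", header=False, index=False)


def read_bed6(path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
        usecols=range(6),
    )
    return df


def write_category_map(catmap: GeneCategoryMap, path) -> None:
    """Long-format TSV; the full universe is recorded under 'universe'."""
    rows = [(g, "universe") for g in catmap.universe]
    for name in sorted(catmap.categories):
        rows.extend((g, name) for g in sorted(catmap.categories[name]))
    pd.DataFrame(rows, columns=["gene_id", "category"]).to_csv(
        path, sep="\t", index=False
    )


def read_category_map(path) -> GeneCategoryMap:
    df = pd.read_csv(path, sep="\t")
    universe = df.loc[df["category"] == "universe", "gene_id"].tolist()
    cats = {
        name: set(sub["gene_id"])
        for name, sub in df[df["category"] != "universe"].groupby("category")
    }
    return GeneCategoryMap(universe=universe, categories=cats)
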