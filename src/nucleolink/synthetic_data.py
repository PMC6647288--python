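"""Synthetic yeast-like data with planted ground truth.

The generator emulates the data properties the downstream analyses depend
on, so the whole pipeline runs and can be validated without any download:

* a compact annotation (a few chromosomes with telomeres, one centromere
  each, tDNAs, ARS elements and a single-copy rDNA span) carrying genes
  with strand, TSS and correlated promoter-architecture categories
  (open/closed, OPN/DPN, FN/SN, TATA, SAGA/TFIID, Mediator, NuA4, SWR1,
  RSC- and Scc2-binding);
* MNase-seq read-midpoint maps for two conditions: nucleosomes phased off
  each TSS (+1 at TSS+80, then one per spacing), promoter NFRs whose
  length depends on the open/closed class, Poisson read counts and
  Gaussian positional jitter, with planted occupancy (fold), position
  (50-90 bp) and fuzziness (sd multiplier) alterations in the mutant;
* tiling-array probe tables (tagged wild type, tagged mutant, untagged)
  on a 5 bp grid with Gaussian background and plateau peaks planted at
  convergent IGRs, the pericentromere, tDNAs, the rDNA and telomeres;
  per-probe p-values are one-sided upper tails under the known background
  null.  Mutant peak amplitudes in selected classes are scaled to emulate
  a redistribution between conditions;
* a per-gene expression table with Benjamini-Hochberg q-values, planted
  down-regulation biased toward OPN/FN/TATA promoters and planted
  up-regulation biased toward cohesin-peak-bearing promoters.

Every draw comes from one seeded generator with named substreams per
stage, so each stage is individually reproducible.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd

from .genome_model import (
    Gene,
    GeneCategoryMap,
    GenomeAnnotation,
    GenomicInterval,
    IGRCatalog,
    derive_igrs,
    promoter_interval,
    write_category_map,
    write_gff3,
)

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "generate_genome",
    "generate_nucleosome_maps",
    "generate_tiling_signal",
    "generate_expression_table",
    "simulate_all",
    "write_simulation",
]

_ROMAN = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X", "XI", "XII"]


def substream(seed: int, label: str) -> np.random.Generator:
    """Named, reproducible random substream derived from the master seed."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF, zlib.crc32(label.encode())])
    )


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic genome and its data sets."""

    seed: int = 0
    # genome
    n_chromosomes: int = 3
    chrom_length: int = 150_000
    n_genes: int = 180
    mean_gene_length: int = 1400
    gene_length_sd: int = 350
    min_gene_length: int = 400
    min_igr: int = 250
    max_igr: int = 700
    telomere_length: int = 3000
    centromere_size: int = 120
    rdna_length: int = 15_000
    n_tdna_per_chrom: int = 6
    n_ars_per_chrom: int = 5
    # promoter classes
    p_open: float = 0.65
    nfr_open: int = 170  # bp, open/DPN promoters (>= 150)
    nfr_closed: int = 100  # bp, closed/OPN promoters (< 150)
    # nucleosome maps
    nucleosome_spacing: int = 165
    reads_per_nucleosome: float = 30.0
    read_jitter_sd: float = 15.0
    occupancy_heterogeneity_sd: float = 0.0  # lognormal sd of shared baseline
    alteration_fractions: dict = field(
        default_factory=lambda: {
            "occ_up": 0.03,
            "occ_down": 0.05,
            "shift": 0.006,
            "fuzzy": 0.03,
        }
    )
    occupancy_fold: float = 2.0
    shift_min: int = 50
    shift_max: int = 90
    fuzziness_factor: float = 1.8
    # tiling array
    probe_step: int = 5
    probe_length: int = 25
    probe_noise_sd: float = 0.5
    peak_amplitude: float = 1.5
    peak_width: int = 500
    peak_density: dict = field(
        default_factory=lambda: {
            "convergent_igr": 0.30,
            "pericentromeric": 1.0,
            "tDNA": 0.8,
            "rDNA": 1.0,
            "telomere": 0.5,
        }
    )
    mutant_region_gain: dict = field(
        default_factory=lambda: {"rDNA": 1.5, "tDNA": 1.5, "telomere": 1.5}
    )
    # expression
    de_frac_down: float = 0.066
    de_frac_up: float = 0.085
    de_effect_min: float = 0.7
    de_effect_max: float = 2.0
    de_null_sd: float = 0.15
    de_enrichment_odds: float = 3.0
    promoter_len: int = 500

    def __post_init__(self) -> None:
        for name, frac in self.alteration_fractions.items():
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"alteration fraction {name}={frac} outside [0,1]")
        if self.nucleosome_spacing <= 147:
            raise ValueError("nucleosome spacing must exceed the 147 bp footprint")
        if self.probe_step < 1:
            raise ValueError("probe step must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


@dataclass
class SyntheticTruth:
    """Planted ground truth referencing the simulated objects by id/coordinate."""

    nucleosome_alterations: pd.DataFrame | None = None  # chrom,dyad,category,magnitude
    peaks: pd.DataFrame | None = None  # chrom,start,end,region_class,amplitude_*
    de_genes: pd.DataFrame | None = None  # gene,direction,log2fc

    def to_json(self, path) -> None:
        payload = {}
        for name in ("nucleosome_alterations", "peaks", "de_genes"):
            df = getattr(self, name)
            payload[name] = df.to_dict(orient="list") if df is not None else None
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            payload = json.load(fh)
        kwargs = {
            name: (pd.DataFrame(val) if val is not None else None)
            for name, val in payload.items()
        }
        return cls(**kwargs)


# ---------------------------------------------------------------------------
# genome


def _chrom_names(n: int) -> list[str]:
    if n > len(_ROMAN):
        return [f"chr{i + 1}" for i in range(n)]
    return [f"chr{_ROMAN[i]}" for i in range(n)]


def generate_genome(config: SimulationConfig) -> tuple[GenomeAnnotation, GeneCategoryMap]:
    """Simulate the annotation and correlated promoter/regulator categories.

    Genes are packed left to right between the telomeres, skipping the
    centromere and the rDNA span; intergenic gaps are uniform draws wide
    enough to hold either promoter's NFR.  Raises if the configured gene
    count cannot be packed.
    """
    rng = substream(config.seed, "genome")
    names = _chrom_names(config.n_chromosomes)
    L = config.chrom_length
    if config.n_genes * (config.mean_gene_length + config.min_igr) > (
        config.n_chromosomes * L
    ):
        raise ValueError("infeasible packing: too many genes for the genome size")
    chromosomes = {name: L for name in names}
    features: dict[str, list[GenomicInterval]] = {
        "tDNA": [],
        "ARS": [],
        "telomere": [],
        "centromere": [],
        "rDNA": [],
    }
    rdna_chrom = names[-1]
    rdna_start = int(0.65 * L)
    for name in names:
        features["telomere"].append(GenomicInterval(name, 0, config.telomere_length))
        features["telomere"].append(
            GenomicInterval(name, L - config.telomere_length, L)
        )
        cen_start = L // 2
        features["centromere"].append(
            GenomicInterval(name, cen_start, cen_start + config.centromere_size)
        )
    features["rDNA"].append(
        GenomicInterval(rdna_chrom, rdna_start, rdna_start + config.rdna_length)
    )

    # blocked spans where no gene may be placed
    blocked: dict[str, list[tuple[int, int]]] = {name: [] for name in names}
    for cen in features["centromere"]:
        blocked[cen.chrom].append((cen.start - 500, cen.end + 500))
    blocked[rdna_chrom].append((rdna_start, rdna_start + config.rdna_length))

    per_chrom = int(np.ceil(config.n_genes / config.n_chromosomes))
    genes: dict[str, Gene] = {}
    gene_no = 0
    for name in names:
        cursor = config.telomere_length
        placed = 0
        while placed < per_chrom and gene_no < config.n_genes:
            gap = int(rng.integers(config.min_igr, config.max_igr + 1))
            glen = int(
                np.clip(
                    rng.normal(config.mean_gene_length, config.gene_length_sd),
                    config.min_gene_length,
                    None,
                )
            )
            start = cursor + gap
            end = start + glen
            moved = True
            while moved:
                moved = False
                for bs, be in blocked[name]:
                    if start < be and end > bs:
                        start = be + gap
                        end = start + glen
                        moved = True
            if end > L - config.telomere_length:
                break
            gene_no += 1
            gid = f"GEN{gene_no:04d}"
            strand = "+" if rng.random() < 0.5 else "-"
            genes[gid] = Gene(gid, GenomicInterval(name, start, end), strand)
            cursor = end
            placed += 1
    if gene_no < config.n_genes:
        raise ValueError(
            f"infeasible packing: placed only {gene_no} of {config.n_genes} genes"
        )

    # tDNA / ARS dropped into distinct intergenic gaps
    for name in names:
        chrom_genes = sorted(
            (g for g in genes.values() if g.interval.chrom == name),
            key=lambda g: g.interval.start,
        )
        gaps = [
            (a.interval.end, b.interval.start)
            for a, b in zip(chrom_genes, chrom_genes[1:])
            if b.interval.start - a.interval.end >= 220
        ]
        rng.shuffle(gaps)
        want = config.n_tdna_per_chrom + config.n_ars_per_chrom
        for i, (gs, ge) in enumerate(gaps[:want]):
            mid = (gs + ge) // 2
            if i < config.n_tdna_per_chrom:
                features["tDNA"].append(GenomicInterval(name, mid - 40, mid + 40))
            else:
                features["ARS"].append(GenomicInterval(name, mid - 100, mid + 100))

    annotation = GenomeAnnotation(chromosomes, genes, features)

    # correlated promoter / regulator categories
    ids = sorted(genes)
    n = len(ids)
    is_open = rng.random(n) < config.p_open
    p_opn = np.where(is_open, 0.08, 0.55)
    is_opn = rng.random(n) < p_opn
    p_dpn = np.where(is_open, 0.45, 0.05)
    is_dpn = (rng.random(n) < p_dpn) & ~is_opn
    p_fn = np.where(is_open, 0.42, 0.10)
    is_fn = rng.random(n) < p_fn
    is_sn = ~is_fn
    p_tata = np.where(is_opn, 0.55, np.where(~is_open, 0.30, 0.10))
    is_tata = rng.random(n) < p_tata
    p_saga = np.where(is_tata, 0.45, 0.03)
    is_saga = rng.random(n) < p_saga
    p_tfiid = np.where(is_saga, 0.10, 0.85)
    is_tfiid = rng.random(n) < p_tfiid
    p_med = np.where(is_saga, 0.45, 0.02)
    is_med = rng.random(n) < p_med
    p_nua4 = np.where(is_tfiid, 0.09, 0.02)
    is_nua4 = rng.random(n) < p_nua4
    is_swr1 = rng.random(n) < 0.07
    p_rsc = np.where(is_fn, 0.09, 0.015)
    is_rsc = rng.random(n) < p_rsc
    is_scc2 = rng.random(n) < 0.03

    def _set(mask: np.ndarray) -> set[str]:
        return {ids[i] for i in np.flatnonzero(mask)}

    categories = {
        "Open": _set(is_open),
        "Closed": _set(~is_open),
        "OPN": _set(is_opn),
        "DPN": _set(is_dpn),
        "FN": _set(is_fn),
        "SN": _set(is_sn),
        "TATA": _set(is_tata),
        "SAGA": _set(is_saga),
        "TFIID": _set(is_tfiid),
        "Mediator": _set(is_med),
        "NuA4": _set(is_nua4),
        "SWR1": _set(is_swr1),
        "RSC": _set(is_rsc),
        "Scc2": _set(is_scc2),
    }
    return annotation, GeneCategoryMap(universe=ids, categories=categories)


def nfr_length(config: SimulationConfig, categories: GeneCategoryMap, gene_id: str) -> int:
    return (
        config.nfr_open
        if gene_id in categories.categories["Open"]
        else config.nfr_closed
    )


# ---------------------------------------------------------------------------
# nucleosome maps


def _plan_dyads(
    config: SimulationConfig,
    annotation: GenomeAnnotation,
    categories: GeneCategoryMap,
) -> pd.DataFrame:
    """Deterministic dyad layout: TSS-phased arrays plus gap filling.

    The +1 dyad sits at TSS+80 (strand-aware), subsequent dyads one spacing
    apart through the gene body; the -1 dyad sits one half-footprint plus
    half a linker beyond the promoter NFR.  Remaining gaps longer than two
    spacings are tiled, and the centromere core stays nucleosome-free.
    """
    spacing = config.nucleosome_spacing
    rows = []
    nfr_spans: dict[str, list[tuple[int, int]]] = {
        c: [] for c in annotation.chromosomes
    }
    for gid in sorted(annotation.genes):
        gene = annotation.genes[gid]
        chrom = gene.interval.chrom
        d = 1 if gene.strand == "+" else -1
        tss = gene.tss
        nfr = nfr_length(config, categories, gid)
        if gene.strand == "+":
            nfr_spans[chrom].append((tss - nfr, tss))
        else:
            nfr_spans[chrom].append((tss + 1, tss + 1 + nfr))
        # genic array: +1, +2, ...
        pos = tss + d * 80
        while gene.interval.start <= pos < gene.interval.end:
            rows.append((chrom, pos))
            pos += d * spacing
        # upstream array: -1, -2, -3 beyond the NFR
        pos = tss - d * (nfr + 80)
        for _ in range(3):
            if 0 <= pos < annotation.chromosomes[chrom]:
                rows.append((chrom, pos))
            pos -= d * spacing

    df = pd.DataFrame(rows, columns=["chrom", "dyad"]).drop_duplicates()
    out_rows = []
    for chrom, length in annotation.chromosomes.items():
        dyads = np.sort(df.loc[df["chrom"] == chrom, "dyad"].to_numpy())
        filled = []
        prev = None
        for dyad in dyads:
            if prev is not None and dyad - prev > 2 * spacing:
                n_extra = (dyad - prev) // spacing - 1
                step = (dyad - prev) / (n_extra + 1)
                filled.extend(int(prev + step * (i + 1)) for i in range(n_extra))
            filled.append(int(dyad))
            prev = dyad
        # minimum separation: greedy thinning
        kept = []
        for dyad in filled:
            if not kept or dyad - kept[-1] >= 150:
                kept.append(dyad)
        # strip centromere core and NFRs
        cen = [
            (iv.start - 100, iv.end + 100)
            for iv in annotation.features["centromere"]
            if iv.chrom == chrom
        ]
        bad = cen + nfr_spans[chrom]
        for dyad in kept:
            if any(s <= dyad < e for s, e in bad):
                continue
            if 74 <= dyad < length - 74:
                out_rows.append((chrom, dyad))
    out = pd.DataFrame(out_rows, columns=["chrom", "dyad"])
    return out.sort_values(["chrom", "dyad"], ignore_index=True)


def generate_nucleosome_maps(
    config: SimulationConfig,
    annotation: GenomeAnnotation,
    categories: GeneCategoryMap,
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Simulate wild-type and mutant read-midpoint maps with planted changes.

    Per nucleosome and condition the read count is Poisson with mean
    ``reads_per_nucleosome`` times the condition's occupancy factor, and
    midpoints are normal around the condition's dyad with sd
    ``read_jitter_sd`` times the fuzziness factor.  Alteration categories
    are disjoint; wild-type maps are never altered.
    """
    dyads = _plan_dyads(config, annotation, categories)
    n = len(dyads)
    rng_alt = substream(config.seed, "alterations")
    order = rng_alt.permutation(n)
    fracs = config.alteration_fractions
    counts = {k: int(round(fracs.get(k, 0.0) * n)) for k in ("occ_up", "occ_down", "shift", "fuzzy")}
    sel: dict[str, np.ndarray] = {}
    lo = 0
    for cat in ("occ_up", "occ_down", "shift", "fuzzy"):
        sel[cat] = order[lo : lo + counts[cat]]
        lo += counts[cat]

    occ_factor = np.ones(n)
    occ_factor[sel["occ_up"]] = config.occupancy_fold
    occ_factor[sel["occ_down"]] = 1.0 / config.occupancy_fold
    fuzz_factor = np.ones(n)
    fuzz_factor[sel["fuzzy"]] = config.fuzziness_factor
    shift = np.zeros(n, dtype=int)
    if len(sel["shift"]):
        mag = rng_alt.integers(config.shift_min, config.shift_max + 1, len(sel["shift"]))
        sign = rng_alt.choice([-1, 1], len(sel["shift"]))
        shift[sel["shift"]] = mag * sign

    if config.occupancy_heterogeneity_sd > 0:
        base = np.exp(
            substream(config.seed, "baseline").normal(
                0.0, config.occupancy_heterogeneity_sd, n
            )
        )
    else:
        base = np.ones(n)

    truth_rows = []
    for cat, idx in sel.items():
        for i in idx:
            mag = {
                "occ_up": config.occupancy_fold,
                "occ_down": 1.0 / config.occupancy_fold,
                "shift": float(shift[i]),
                "fuzzy": config.fuzziness_factor,
            }[cat]
            truth_rows.append(
                (dyads.loc[i, "chrom"], int(dyads.loc[i, "dyad"]), cat, mag)
            )
    truth = SyntheticTruth(
        nucleosome_alterations=pd.DataFrame(
            truth_rows, columns=["chrom", "dyad", "category", "magnitude"]
        ).sort_values(["chrom", "dyad"], ignore_index=True)
    )

    lengths = annotation.chromosomes

    def _draw(label: str, dyad_pos: np.ndarray, occ: np.ndarray, fuzz: np.ndarray):
        rng = substream(config.seed, label)
        k = rng.poisson(config.reads_per_nucleosome * base * occ)
        chroms = np.repeat(dyads["chrom"].to_numpy(), k)
        centers = np.repeat(dyad_pos, k)
        sds = np.repeat(config.read_jitter_sd * fuzz, k)
        pos = np.rint(rng.normal(centers.astype(float), sds)).astype(np.int64)
        limit = np.array([lengths[c] for c in chroms])
        pos = np.clip(pos, 0, limit - 1)
        return (
            pd.DataFrame({"chrom": chroms, "pos": pos})
            .sort_values(["chrom", "pos"], ignore_index=True)
        )

    wt = _draw("reads_wt", dyads["dyad"].to_numpy(), np.ones(n), np.ones(n))
    mut = _draw(
        "reads_mut", dyads["dyad"].to_numpy() + shift, occ_factor, fuzz_factor
    )
    truth.nucleosome_alterations.attrs["n_nucleosomes"] = n
    wt.attrs["n_nucleosomes"] = n
    mut.attrs["n_nucleosomes"] = n
    return wt, mut, truth


# ---------------------------------------------------------------------------
# tiling signal


def _peak_candidates(
    config: SimulationConfig, annotation: GenomeAnnotation, igrs: IGRCatalog
) -> list[tuple[str, GenomicInterval]]:
    cands: list[tuple[str, GenomicInterval]] = []
    for igr in igrs.igrs:
        if igr.orientation == "convergent" and igr.interval.length >= 100:
            cands.append(("convergent_igr", igr.interval))
    for cen in annotation.features["centromere"]:
        length = annotation.chromosomes[cen.chrom]
        cands.append(
            (
                "pericentromeric",
                GenomicInterval(
                    cen.chrom, max(0, cen.start - 2000), min(length, cen.end + 2000)
                ),
            )
        )
    for iv in annotation.features["tDNA"]:
        length = annotation.chromosomes[iv.chrom]
        cands.append(
            (
                "tDNA",
                GenomicInterval(
                    iv.chrom, max(0, iv.start - 150), min(length, iv.end + 150)
                ),
            )
        )
    for iv in annotation.features["rDNA"]:
        for s in range(iv.start, iv.end, 3000):
            cands.append(("rDNA", GenomicInterval(iv.chrom, s, min(s + 2000, iv.end))))
    for iv in annotation.features["telomere"]:
        cands.append(("telomere", iv))
    return cands


def generate_tiling_signal(
    config: SimulationConfig,
    annotation: GenomeAnnotation,
    igrs: IGRCatalog,
) -> tuple[dict[str, pd.DataFrame], SyntheticTruth]:
    """Simulate probe tables for tagged WT, tagged mutant and untagged strains.

    Background is iid Normal(0, sigma) per probe and strain; planted peaks
    add a plateau of the configured amplitude (the mutant's amplitude is
    scaled per region class by ``mutant_region_gain``).  p-values are
    one-sided upper tails of the strain's own signal under the known
    background null, which is the untagged-strain-independent part of the
    filtering; the subtraction happens in the caller.
    """
    rng = substream(config.seed, "tiling")
    grids = {
        chrom: np.arange(
            config.probe_step, length - config.probe_step, config.probe_step
        )
        for chrom, length in annotation.chromosomes.items()
    }
    amp_wt = {c: np.zeros(len(g)) for c, g in grids.items()}
    amp_mut = {c: np.zeros(len(g)) for c, g in grids.items()}
    truth_rows = []
    for cls, iv in _peak_candidates(config, annotation, igrs):
        if rng.random() >= config.peak_density.get(cls, 0.0):
            continue
        width = min(config.peak_width, iv.length)
        mid = (iv.start + iv.end) // 2
        s, e = mid - width // 2, mid - width // 2 + width
        amp = config.peak_amplitude * float(rng.uniform(0.9, 1.1))
        gain = config.mutant_region_gain.get(cls, 1.0)
        grid = grids[iv.chrom]
        mask = (grid >= s) & (grid < e)
        amp_wt[iv.chrom][mask] += amp
        amp_mut[iv.chrom][mask] += amp * gain
        truth_rows.append(
            (iv.chrom, s, e, cls, amp, amp * gain, amp * mask.sum(), amp * gain * mask.sum())
        )
    truth = SyntheticTruth(
        peaks=pd.DataFrame(
            truth_rows,
            columns=[
                "chrom",
                "start",
                "end",
                "region_class",
                "amplitude_wt",
                "amplitude_mut",
                "signal_sum_wt",
                "signal_sum_mut",
            ],
        ).sort_values(["chrom", "start"], ignore_index=True)
    )

    from scipy.stats import norm

    sigma = config.probe_noise_sd
    tables: dict[str, pd.DataFrame] = {}
    for strain, amp in (
        ("tagged_wt", amp_wt),
        ("tagged_mut", amp_mut),
        ("untagged", None),
    ):
        frames = []
        srng = substream(config.seed, f"tiling_{strain}")
        for chrom, grid in grids.items():
            signal = srng.normal(0.0, sigma, len(grid))
            if amp is not None:
                signal = signal + amp[chrom]
            pval = norm.sf(signal / sigma) if sigma > 0 else np.where(signal > 0, 0.0, 1.0)
            pval = np.clip(pval, np.finfo(float).tiny, 1.0)
            frames.append(
                pd.DataFrame(
                    {"chrom": chrom, "pos": grid, "signal": signal, "pvalue": pval}
                )
            )
        tables[strain] = pd.concat(frames, ignore_index=True)
    return tables, truth


# ---------------------------------------------------------------------------
# expression


def generate_expression_table(
    config: SimulationConfig,
    annotation: GenomeAnnotation,
    categories: GeneCategoryMap,
    truth_peaks: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Simulate the per-gene DE table (log2FC, p, BH q) with planted DE genes.

    Null genes draw log2FC ~ Normal(0, sd); planted genes add an effect of
    at least ``de_effect_min`` in log2.  Down-regulated genes are sampled
    with ``de_enrichment_odds``-fold weight from OPN/FN/TATA promoters;
    up-regulated genes with the same odds from genes whose promoter
    overlaps a planted cohesin peak.
    """
    from statsmodels.stats.multitest import multipletests

    rng = substream(config.seed, "expression")
    ids = list(categories.universe)
    n = len(ids)
    down_bias_set = (
        categories.categories["OPN"]
        | categories.categories["FN"]
        | categories.categories["TATA"]
    )
    bound = set()
    if truth_peaks is not None and len(truth_peaks):
        peak_ivs = [
            GenomicInterval(r.chrom, int(r.start), int(r.end))
            for r in truth_peaks.itertuples(index=False)
        ]
        from .genome_model import overlaps as _ov

        for gid in ids:
            gene = annotation.genes[gid]
            prom = promoter_interval(
                gene, config.promoter_len, annotation.chromosomes[gene.interval.chrom]
            )
            if prom is not None and any(_ov(prom, piv) for piv in peak_ivs):
                bound.add(gid)

    odds = config.de_enrichment_odds
    w_down = np.array([odds if g in down_bias_set else 1.0 for g in ids])
    n_down = int(round(config.de_frac_down * n))
    down_idx = rng.choice(n, size=n_down, replace=False, p=w_down / w_down.sum())
    remaining = np.setdiff1d(np.arange(n), down_idx)
    w_up = np.array([odds if ids[i] in bound else 1.0 for i in remaining])
    n_up = int(round(config.de_frac_up * n))
    up_idx = remaining[
        rng.choice(len(remaining), size=n_up, replace=False, p=w_up / w_up.sum())
    ]

    lfc = rng.normal(0.0, config.de_null_sd, n)
    eff_down = rng.uniform(config.de_effect_min, config.de_effect_max, n_down)
    eff_up = rng.uniform(config.de_effect_min, config.de_effect_max, n_up)
    lfc[down_idx] -= eff_down
    lfc[up_idx] += eff_up

    from scipy.stats import norm

    pvals = 2.0 * norm.sf(np.abs(lfc) / config.de_null_sd)
    pvals = np.clip(pvals, np.finfo(float).tiny, 1.0)
    qvals = multipletests(pvals, method="fdr_bh")[1]
    table = pd.DataFrame(
        {"gene": ids, "log2fc": lfc, "pvalue": pvals, "qvalue": qvals}
    )
    de_rows = [(ids[i], "down", float(lfc[i])) for i in down_idx] + [
        (ids[i], "up", float(lfc[i])) for i in up_idx
    ]
    truth = SyntheticTruth(
        de_genes=pd.DataFrame(de_rows, columns=["gene", "direction", "log2fc"])
        .sort_values("gene", ignore_index=True)
    )
    return table, truth


# ---------------------------------------------------------------------------
# orchestration / file output


def simulate_all(config: SimulationConfig) -> dict:
    """Run every generator stage; returns a dict of in-memory objects."""
    annotation, categories = generate_genome(config)
    igrs = derive_igrs(annotation)
    wt, mut, nuc_truth = generate_nucleosome_maps(config, annotation, categories)
    probes, peak_truth = generate_tiling_signal(config, annotation, igrs)
    expr, de_truth = generate_expression_table(
        config, annotation, categories, peak_truth.peaks
    )
    truth = SyntheticTruth(
        nucleosome_alterations=nuc_truth.nucleosome_alterations,
        peaks=peak_truth.peaks,
        de_genes=de_truth.de_genes,
    )
    return {
        "config": config,
        "annotation": annotation,
        "categories": categories,
        "igrs": igrs,
        "wt_reads": wt,
        "mut_reads": mut,
        "probes": probes,
        "expression": expr,
        "truth": truth,
        "n_nucleosomes": wt.attrs.get("n_nucleosomes"),
    }


def _write_bedgraph(track: dict[str, np.ndarray], path) -> None:
    """Run-length-encoded bedGraph of a per-bp track (zeros skipped)."""
    with open(path, "w") as fh:
        for chrom in sorted(track):
            arr = np.asarray(track[chrom])
            if len(arr) == 0:
                continue
            change = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [len(arr)]])
            for s, e in zip(starts, ends):
                v = arr[s]
                if v != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")


def write_simulation(sim: dict, outdir) -> dict[str, str]:
    """Write every simulated object to plain-text files under ``outdir``."""
    import os

    os.makedirs(outdir, exist_ok=True)
    paths = {}

    def _p(name):
        paths[name] = os.path.join(outdir, name)
        return paths[name]

    write_gff3(sim["annotation"], _p("annotation.gff3"))
    write_category_map(sim["categories"], _p("categories.tsv"))
    for cond, df in (("wt", sim["wt_reads"]), ("mut", sim["mut_reads"])):
        out = df.copy()
        out["condition"] = cond
        out.to_csv(_p(f"reads_{cond}.tsv"), sep="\t", index=False)
    from .nucleosome_dynamics import occupancy_track

    for cond, df in (("wt", sim["wt_reads"]), ("mut", sim["mut_reads"])):
        track = occupancy_track(df, sim["annotation"].chromosomes, smoothing_sigma=0)
        _write_bedgraph(track, _p(f"occupancy_{cond}.bedgraph"))
    for strain, df in sim["probes"].items():
        out = df.copy()
        out["strain"] = strain
        out.to_csv(_p(f"probes_{strain}.tsv"), sep="\t", index=False)
    sim["expression"].to_csv(_p("expression.tsv"), sep="\t", index=False)
    sim["truth"].to_json(_p("truth.json"))
    sim["config"].to_yaml(_p("config.yaml"))
    return paths


def scaled_config(config: SimulationConfig, **overrides) -> SimulationConfig:
    """Convenience copy-with-overrides (dataclasses.replace wrapper)."""
    return replace(config, **overrides)
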