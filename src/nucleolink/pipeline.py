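"""End-to-end orchestration: simulate (or load), analyse, report.

``run_pipeline`` executes the stages in dependency order — simulation,
nucleosome calling/classification, TSS profiles, cohesin peak calling and
region quantitation, DE thresholding and the gene-set enrichment matrix —
writes each stage's table under the output directory and returns a
machine-readable manifest (also written as JSON) whose scalar results and
file hashes are stable for a fixed seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os

import numpy as np
import pandas as pd

from . import (
    cohesin_peaks as cp,
    enrichment_stats as es,
    expression_overlay as eo,
    genome_model as gm,
    nucleosome_dynamics as nd,
    synthetic_data as sd,
    tss_profiles as tp,
)

__all__ = ["PipelineConfig", "run_pipeline", "validate_against_printed"]

log = logging.getLogger("nucleolink")


@dataclasses.dataclass
class PipelineConfig:
    """Seed, output directory and per-stage thresholds for one run."""

    outdir: str = "nucleolink_out"
    seed: int = 0
    simulate: bool = True
    simulation: sd.SimulationConfig | None = None
    # nucleosome dynamics
    log10p_cutoff: float = -15.0
    shift_range: tuple[float, float] = (50.0, 90.0)
    # peaks
    alpha: float = 0.05
    max_gap: int = 250
    min_run: int = 30
    # DE
    q_cut: float = 0.01
    fold_cut: float = 1.41
    strong_cut: float = 2.0
    # geometry
    promoter_len: int = 500
    pericentromeric_halfwidth: int = 10_000
    tss_window: int = 1000
    enrichment_alpha: float = 1e-3

    def __post_init__(self) -> None:
        if self.simulation is None:
            self.simulation = sd.SimulationConfig(seed=self.seed)
        else:
            self.simulation = dataclasses.replace(self.simulation, seed=self.seed)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        sim = data.pop("simulation", None)
        cfg = cls(**data)
        if sim:
            cfg.simulation = sd.SimulationConfig(seed=cfg.seed, **sim)
        return cfg


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns (and writes) the results manifest."""
    os.makedirs(config.outdir, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    manifest: dict = {
        "seed": config.seed,
        "parameters": {
            "log10p_cutoff": config.log10p_cutoff,
            "shift_range": list(config.shift_range),
            "alpha": config.alpha,
            "max_gap": config.max_gap,
            "min_run": config.min_run,
            "q_cut": config.q_cut,
            "fold_cut": config.fold_cut,
            "strong_cut": config.strong_cut,
            "promoter_len": config.promoter_len,
        },
        "outputs": {},
        "results": {},
    }

    def _write(name: str, df: pd.DataFrame) -> str:
        path = os.path.join(config.outdir, name)
        df.to_csv(path, sep="\t", index=False, float_format="%.6g")
        manifest["outputs"][name] = {"path": path}
        return path

    # --- stage 1: data
    log.info("simulating input data (seed=%d)", config.seed)
    if not config.simulate:
        raise NotImplementedError(
            "loading externally supplied data directories is done through the "
            "per-stage CLI subcommands; run_pipeline drives the simulator"
        )
    sim = sd.simulate_all(config.simulation)
    sim_paths = sd.write_simulation(sim, os.path.join(config.outdir, "simulated"))
    annotation: gm.GenomeAnnotation = sim["annotation"]
    categories: gm.GeneCategoryMap = sim["categories"]
    igrs = sim["igrs"]

    # --- stage 2: nucleosome dynamics
    log.info("calling and comparing nucleosomes")
    exclude = {
        iv.chrom: [(iv.start - 100, iv.end + 100)]
        for iv in annotation.features["centromere"]
    }
    params = nd.NucleosomeParams(
        log10p_cutoff=config.log10p_cutoff, shift_range=tuple(config.shift_range)
    )
    comparisons = nd.compare_maps(
        sim["wt_reads"], sim["mut_reads"], annotation.chromosomes, params, exclude
    )
    classified = nd.classify_dynamic(
        comparisons, config.log10p_cutoff, tuple(config.shift_range)
    )
    total_nucs = len(classified)
    table1 = nd.summarize_alterations(classified, total_nucs)
    _write("comparisons.tsv", classified)
    _write("alteration_summary.tsv", pd.DataFrame([table1]))
    manifest["results"]["alteration_summary"] = table1

    # region breakdown of altered nucleosomes
    altered = classified[classified["altered"]]
    ref = np.where(altered["wt_summit"] >= 0, altered["wt_summit"], altered["mut_summit"])
    altered_ivs = [
        gm.GenomicInterval(c, max(0, int(s) - 73), int(s) + 74)
        for c, s in zip(altered["chrom"], ref)
    ]
    all_ref = np.where(
        classified["wt_summit"] >= 0, classified["wt_summit"], classified["mut_summit"]
    )
    all_ivs = [
        gm.GenomicInterval(c, max(0, int(s) - 73), int(s) + 74)
        for c, s in zip(classified["chrom"], all_ref)
    ]
    all_classes = gm.assign_to_region_classes(
        all_ivs, annotation, igrs, config.pericentromeric_halfwidth
    )
    alt_classes = gm.assign_to_region_classes(
        altered_ivs, annotation, igrs, config.pericentromeric_halfwidth
    )
    totals_by_class = pd.Series(all_classes).value_counts().to_dict()
    altered_by_class = pd.Series(alt_classes).value_counts().to_dict()
    region_table = es.region_alteration_enrichment(altered_by_class, totals_by_class)
    _write("region_alterations.tsv", region_table)

    # --- stage 3: TSS profiles
    log.info("building TSS profiles")
    wt_track = nd.occupancy_track(sim["wt_reads"], annotation.chromosomes)
    mut_track = nd.occupancy_track(sim["mut_reads"], annotation.chromosomes)
    gene_ids = sorted(annotation.genes)
    m_wt = tp.build_tss_matrix(wt_track, annotation, config.tss_window, gene_ids)
    m_mut = tp.build_tss_matrix(
        mut_track, annotation, config.tss_window, list(m_wt.genes)
    )
    canon = tp.locate_canonical_nucleosomes(m_wt.metaprofile(), m_wt.offsets)
    tss_tests = tp.paired_occupancy_test(m_wt, m_mut, canon)
    _write("tss_paired_tests.tsv", tss_tests)
    pd.DataFrame(
        {"offset": m_wt.offsets, "wt": m_wt.metaprofile(), "mut": m_mut.metaprofile()}
    ).to_csv(os.path.join(config.outdir, "metaprofile.tsv"), sep="\t", index=False)
    manifest["outputs"]["metaprofile.tsv"] = {
        "path": os.path.join(config.outdir, "metaprofile.tsv")
    }
    manifest["results"]["canonical_nucleosomes"] = {str(k): v for k, v in canon.items()}

    # --- stage 4: cohesin peaks
    log.info("calling cohesin peaks")
    peaks_by_cond: dict[str, list[cp.CohesinPeak]] = {}
    qualifying = {}
    for cond, strain in (("wt", "tagged_wt"), ("mut", "tagged_mut")):
        corrected = cp.correct_signal(sim["probes"][strain], sim["probes"]["untagged"])
        qual = cp.select_probes(corrected, config.alpha)
        qualifying[cond] = qual
        peaks = cp.assemble_peaks(qual, config.max_gap, config.min_run)
        peaks_by_cond[cond] = peaks
        frame = cp.peaks_to_frame(peaks)
        _write(f"peaks_{cond}.tsv", frame)
    regions = gm._class_intervals(annotation, igrs, config.pericentromeric_halfwidth)
    amounts = {
        cond: cp.region_cohesin_amount(qual, regions)
        for cond, qual in qualifying.items()
    }
    ratios = cp.normalized_condition_ratio(amounts["mut"], amounts["wt"])
    manifest["results"]["region_cohesin_ratio"] = {
        k: (None if np.isnan(v) else round(v, 6)) for k, v in ratios.items()
    }
    overlap_counts = cp.feature_overlap_counts(
        peaks_by_cond["wt"],
        {c: regions[c] for c in ("tDNA", "ARS", "telomere", "ORF", "IGR")},
        igrs,
    )
    manifest["results"]["feature_overlap_counts"] = overlap_counts

    # --- stage 5: differential expression
    log.info("thresholding differential expression")
    de = eo.classify_de(
        sim["expression"], config.q_cut, config.fold_cut, config.strong_cut
    )
    summary = eo.misregulated_summary(de.up, de.down, categories.n)
    manifest["results"]["de_summary"] = summary
    for name, s in (("up", de.up), ("down", de.down)):
        with open(os.path.join(config.outdir, f"de_{name}.txt"), "w") as fh:
            fh.write("\n".join(sorted(s)) + ("\n" if s else ""))
        manifest["outputs"][f"de_{name}.txt"] = {
            "path": os.path.join(config.outdir, f"de_{name}.txt")
        }

    # Fig-2b-style overlay: down genes vs promoters holding up-nucleosomes
    promoters = {
        gid: gm.promoter_interval(
            g, config.promoter_len, annotation.chromosomes[g.interval.chrom]
        )
        for gid, g in annotation.genes.items()
    }
    up_nuc_ivs = [
        iv
        for iv, cls_row in zip(all_ivs, classified.itertuples(index=False))
        if cls_row.occupancy_subtype == "increase"
    ]
    up_prom_genes = eo.genes_with_up_nucleosome_promoters(up_nuc_ivs, promoters)
    overlay = eo.promoter_alteration_overlap(de.down, up_prom_genes, categories.universe)
    manifest["results"]["down_vs_up_nucleosome_promoters"] = {
        "N": overlay.N,
        "K": overlay.K,
        "n": overlay.n,
        "k": overlay.k,
        "obs_exp": None if np.isnan(overlay.obs_exp) else round(overlay.obs_exp, 6),
        "pvalue": overlay.pvalue,
    }

    # --- stage 6: enrichment matrix (with Scc1-binding from called WT peaks)
    log.info("building enrichment matrix")
    scc1_genes = eo.genes_with_promoter_overlap(
        [p.interval for p in peaks_by_cond["wt"]], promoters
    )
    catmap = gm.GeneCategoryMap(
        universe=list(categories.universe),
        categories={**categories.categories, "Scc1": scc1_genes},
    )
    matrix = es.enrichment_matrix(
        {"up": de.up, "down": de.down}, catmap, config.enrichment_alpha
    )
    _write("enrichment_matrix.tsv", matrix)

    # --- manifest
    for name, info in manifest["outputs"].items():
        info["sha256"] = _sha256(info["path"])
    for name, path in sim_paths.items():
        manifest["outputs"][f"simulated/{name}"] = {
            "path": path,
            "sha256": _sha256(path),
        }
    manifest["n_nucleosomes"] = total_nucs
    path = os.path.join(config.outdir, "manifest.json")
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True, default=float)
    log.info("manifest written to %s", path)
    return manifest


def validate_against_printed(manifest: dict, expectations: list[dict]) -> pd.DataFrame:
    """Check manifest scalars against (id, key, expected, tolerance) entries.

    ``key`` is a dotted path into the manifest (e.g.
    ``results.alteration_summary.percent_altered``).  Unknown keys produce a
    failed 'unknown' row rather than an exception.
    """
    rows = []
    for exp in expectations:
        node = manifest
        status = "pass"
        value = None
        try:
            for part in exp["key"].split("."):
                node = node[part]
            value = float(node)
            if abs(value - float(exp["expected"])) > float(exp.get("tolerance", 0.0)):
                status = "fail"
        except (KeyError, TypeError, ValueError):
            status = "unknown"
        rows.append(
            {
                "id": exp.get("id", exp["key"]),
                "key": exp["key"],
                "expected": exp.get("expected"),
                "value": value,
                "tolerance": exp.get("tolerance", 0.0),
                "status": status,
            }
        )
    return pd.DataFrame(rows)
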