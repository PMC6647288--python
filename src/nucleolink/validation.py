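"""Benchmark harness: recover planted ground truth and score the pipeline.

Every routine here generates synthetic data with known truth, runs the
relevant analysis stage through its public interface and returns scores
(sensitivity, false-discovery rate, boundary error, calibration fractions,
determinism).  They are used both by the test suite and by the standalone
acceptance script, so the numbers reported in either place come from one
implementation.
"""

from __future__ import annotations

import json
import math
import os
import tempfile
import warnings

import numpy as np
import pandas as pd

from . import (
    cohesin_peaks as cp,
    nucleosome_dynamics as nd,
    synthetic_data as sd,
    tss_profiles as tp,
)
from .enrichment_stats import hypergeometric_overlap
from .genome_model import derive_igrs
from .pipeline import PipelineConfig, run_pipeline

__all__ = [
    "hypergeometric_enumeration_error",
    "evaluate_peak_recovery",
    "evaluate_null_peaks",
    "evaluate_dynamics_recovery",
    "evaluate_null_maps",
    "evaluate_tss_detection",
    "evaluate_determinism",
]

_MASK = 0x7FFFFFFF


def hypergeometric_enumeration_error(max_n: int = 60) -> dict:
    """Worst |scipy tail - exact big-integer tail| over all instances N <= max_n.

    The exact reference enumerates P(X >= k) as suffix sums of
    C(K, i) C(N-K, n-i) / C(N, n) in arbitrary-precision integers.
    """
    worst = 0.0
    n_instances = 0
    for N in range(1, max_n + 1):
        for K in range(0, N + 1):
            for n in range(0, N + 1):
                denom = math.comb(N, n)
                kmin = max(0, n - (N - K))
                kmax = min(K, n)
                pmf = [
                    math.comb(K, i) * math.comb(N - K, n - i)
                    for i in range(kmin, kmax + 1)
                ]
                exact = np.cumsum(pmf[::-1])[::-1] / denom
                for j, k in enumerate(range(kmin, kmax + 1)):
                    got = hypergeometric_overlap(N, K, n, k).pvalue
                    worst = max(worst, abs(got - float(exact[j])))
                n_instances += len(pmf)
    return {"max_abs_error": worst, "n_instances": n_instances}


def evaluate_peak_recovery(seed: int) -> dict:
    """Noise-free planted peaks: boundary and signal-sum recovery accuracy.

    Only truth peaks isolated from all others by more than the merge gap are
    scored, since merged composites have no single planted boundary.
    """
    cfg = sd.SimulationConfig(seed=seed & _MASK, probe_noise_sd=0.0)
    annotation, _ = sd.generate_genome(cfg)
    igrs = derive_igrs(annotation)
    tables, truth = sd.generate_tiling_signal(cfg, annotation, igrs)
    corrected = cp.correct_signal(tables["tagged_wt"], tables["untagged"])
    qualifying = cp.select_probes(corrected, 0.05)
    called = cp.assemble_peaks(qualifying, 250, 30, mode="centers")
    tf = truth.peaks
    isolated = []
    for i, r in tf.iterrows():
        same = tf[(tf["chrom"] == r.chrom) & (tf.index != i)]
        gaps = np.maximum(same["start"] - r.end, r.start - same["end"])
        if len(same) == 0 or gaps.min() > 260:
            isolated.append(r)
    boundary_err = 0
    signal_err = 0.0
    missed = 0
    for r in isolated:
        hit = [
            p
            for p in called
            if p.interval.chrom == r.chrom
            and min(p.interval.end, r.end) - max(p.interval.start, r.start) > 0
        ]
        if not hit:
            missed += 1
            continue
        p = hit[0]
        boundary_err = max(
            boundary_err, abs(p.interval.start - r.start), abs(p.interval.end - r.end)
        )
        signal_err = max(signal_err, abs(p.peak_signal - r.signal_sum_wt))
    return {
        "n_isolated": len(isolated),
        "n_missed": missed,
        "max_boundary_error_bp": boundary_err,
        "max_signal_abs_error": signal_err,
    }


def evaluate_null_peaks(seed: int, n_permutations: int = 20) -> dict:
    """Calibration on a peak-free track: qualifying fraction and chance-rate peaks.

    Under the iid null the qualifying-probe positions are exchangeable, so
    permuting the per-probe (signal, p) rows gives the chance distribution of
    assembled-peak counts for the same caller settings.
    """
    cfg = sd.SimulationConfig(seed=seed & _MASK, peak_density={})
    annotation, _ = sd.generate_genome(cfg)
    igrs = derive_igrs(annotation)
    tables, _ = sd.generate_tiling_signal(cfg, annotation, igrs)
    corrected = cp.correct_signal(tables["tagged_wt"], tables["untagged"])
    qualifying = cp.select_probes(corrected, 0.05)
    observed = len(cp.assemble_peaks(qualifying, 250, 30))
    rng = np.random.default_rng(seed & _MASK)
    permuted = []
    for _ in range(n_permutations):
        perm = corrected.copy()
        idx = rng.permutation(len(perm))
        perm["signal"] = perm["signal"].to_numpy()[idx]
        perm["pvalue"] = perm["pvalue"].to_numpy()[idx]
        permuted.append(len(cp.assemble_peaks(cp.select_probes(perm, 0.05), 250, 30)))
    return {
        "qualifying_fraction": len(qualifying) / len(corrected),
        "observed_peaks": observed,
        "permuted_mean_peaks": float(np.mean(permuted)),
        "n_probes": len(corrected),
    }


def _centromere_exclusion(annotation) -> dict:
    return {
        iv.chrom: [(iv.start - 100, iv.end + 100)]
        for iv in annotation.features["centromere"]
    }


def evaluate_dynamics_recovery(
    seeds, log10p_cutoff: float = -3.0, match_window: int = 75
) -> dict:
    """Sensitivity/FDR for planted occupancy changes and position shifts.

    A planted occupancy alteration counts as recovered when a classified row
    within ``match_window`` bp carries the occupancy flag with the planted
    direction; a planted shift when a row there carries the position-shift
    flag.  A false positive is a row flagged for occupancy or shift whose
    reference summit is not within the window of any planted alteration.
    The returned sensitivity pools occupancy and shift plants; fuzziness is
    reported separately (its flag is variance-based and scored on its own).
    """
    per_seed = []
    detail: dict[str, list] = {k: [] for k in ("occ_up", "occ_down", "shift", "fuzzy")}
    for seed in seeds:
        cfg = sd.SimulationConfig(seed=int(seed) & _MASK)
        annotation, categories = sd.generate_genome(cfg)
        wt, mut, truth = sd.generate_nucleosome_maps(cfg, annotation, categories)
        comp = nd.compare_maps(
            wt, mut, annotation.chromosomes, exclude=_centromere_exclusion(annotation)
        )
        cl = nd.classify_dynamic(comp, log10p_cutoff)
        ref = np.where(cl["wt_summit"] >= 0, cl["wt_summit"], cl["mut_summit"])
        ta = truth.nucleosome_alterations

        def rows_near(chrom, dyad):
            return cl[(cl["chrom"] == chrom) & (np.abs(ref - dyad) <= match_window)]

        hits = {k: 0 for k in detail}
        totals = {k: 0 for k in detail}
        for r in ta.itertuples(index=False):
            near = rows_near(r.chrom, r.dyad)
            if r.category == "occ_up":
                ok = (near["occupancy_subtype"] == "increase").any()
            elif r.category == "occ_down":
                ok = (near["occupancy_subtype"] == "decrease").any()
            elif r.category == "shift":
                ok = near["position_shift"].any()
            else:
                ok = near["fuzziness_change"].any()
            totals[r.category] += 1
            hits[r.category] += bool(ok)
        for k in detail:
            if totals[k]:
                detail[k].append(hits[k] / totals[k])
        planted_pos = {c: g["dyad"].to_numpy() for c, g in ta.groupby("chrom")}
        flagged = cl[(cl["occupancy_change"]) | (cl["position_shift"])]
        flagged_ref = np.where(
            flagged["wt_summit"] >= 0, flagged["wt_summit"], flagged["mut_summit"]
        )
        fp = 0
        for chrom, pos in zip(flagged["chrom"], flagged_ref):
            near = planted_pos.get(chrom, np.empty(0))
            if not (len(near) and np.min(np.abs(near - pos)) <= match_window):
                fp += 1
        scored = ("occ_up", "occ_down", "shift")
        sens = sum(hits[k] for k in scored) / max(sum(totals[k] for k in scored), 1)
        fdr = fp / max(len(flagged), 1)
        per_seed.append((sens, fdr))
    return {
        "sensitivity": float(np.mean([s for s, _ in per_seed])),
        "fdr": float(np.mean([f for _, f in per_seed])),
        "n_seeds": len(per_seed),
        "per_category_sensitivity": {
            k: float(np.mean(v)) if v else float("nan") for k, v in detail.items()
        },
    }


def evaluate_null_maps(seeds, log10p_cutoff: float = -15.0) -> dict:
    """Percent of nucleosomes flagged altered on maps with no planted effects."""
    altered = 0
    total = 0
    for seed in seeds:
        cfg = sd.SimulationConfig(seed=int(seed) & _MASK, alteration_fractions={})
        annotation, categories = sd.generate_genome(cfg)
        wt, _, _ = sd.generate_nucleosome_maps(cfg, annotation, categories)
        cfg2 = sd.scaled_config(cfg, seed=(int(seed) + 7_000_001) & _MASK)
        mut, _, _ = sd.generate_nucleosome_maps(cfg2, annotation, categories)
        comp = nd.compare_maps(
            wt, mut, annotation.chromosomes, exclude=_centromere_exclusion(annotation)
        )
        cl = nd.classify_dynamic(comp, log10p_cutoff)
        altered += int(cl["altered"].sum())
        total += len(cl)
    return {"percent_altered": 100.0 * altered / total, "n_nucleosomes": total}


def evaluate_tss_detection(
    seeds, n_target: int = 400, effect: float = 0.2
) -> dict:
    """Planted fractional occupancy gain at the -1 nucleosome of target genes.

    Targets live on four chromosomes; the remaining two supply untouched
    control genes.  The comparison condition is an independent draw of the
    same layout plus the planted extra reads, so the control paired test is
    an honest null.  Returns the fraction of seeds with target p < 0.001 at
    the -1 label and the fraction with control p >= 0.05 there.
    """
    target_hits = 0
    control_ok = 0
    for seed in seeds:
        seed = int(seed) & _MASK
        cfg = sd.SimulationConfig(
            seed=seed, n_chromosomes=6, chrom_length=250_000, n_genes=600
        )
        annotation, categories = sd.generate_genome(cfg)
        chroms = list(annotation.chromosomes)
        target_chroms, control_chroms = chroms[:4], chroms[4:]
        target = [
            gid
            for gid, gene in sorted(annotation.genes.items())
            if gene.interval.chrom in target_chroms
        ][:n_target]
        rng = sd.substream(seed, "tss_planted")
        extra = []
        for gid in target:
            gene = annotation.genes[gid]
            nfr = sd.nfr_length(cfg, categories, gid)
            d = 1 if gene.strand == "+" else -1
            minus1 = gene.tss - d * (nfr + 80)
            k = rng.poisson(effect * cfg.reads_per_nucleosome)
            if k:
                extra.append(
                    pd.DataFrame(
                        {
                            "chrom": gene.interval.chrom,
                            "pos": np.rint(
                                rng.normal(minus1, cfg.read_jitter_sd, k)
                            ).astype(np.int64),
                        }
                    )
                )
        null_cfg = sd.scaled_config(cfg, alteration_fractions={})
        wt, _, _ = sd.generate_nucleosome_maps(null_cfg, annotation, categories)
        other = sd.scaled_config(null_cfg, seed=(seed + 1_000_003) & _MASK)
        mut, _, _ = sd.generate_nucleosome_maps(other, annotation, categories)
        mut = pd.concat([mut] + extra, ignore_index=True).sort_values(
            ["chrom", "pos"], ignore_index=True
        )
        wt_track = nd.occupancy_track(wt, annotation.chromosomes)
        mut_track = nd.occupancy_track(mut, annotation.chromosomes)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m_wt = tp.build_tss_matrix(wt_track, annotation, 1000, target)
            m_mut = tp.build_tss_matrix(mut_track, annotation, 1000, list(m_wt.genes))
            canon = tp.locate_canonical_nucleosomes(m_wt.metaprofile(), m_wt.offsets)
            res_t = tp.paired_occupancy_test(m_wt, m_mut, canon)
            controls = tp.select_control_genes(annotation, [set(target)], control_chroms)
            c_wt = tp.build_tss_matrix(wt_track, annotation, 1000, controls)
            c_mut = tp.build_tss_matrix(mut_track, annotation, 1000, list(c_wt.genes))
            res_c = tp.paired_occupancy_test(c_wt, c_mut, canon)
        p_target = float(res_t.loc[res_t["label"] == -1, "pvalue"].iloc[0])
        p_control = float(res_c.loc[res_c["label"] == -1, "pvalue"].iloc[0])
        target_hits += p_target < 0.001
        control_ok += p_control >= 0.05
    n = len(list(seeds))
    return {
        "target_detection_rate": target_hits / n,
        "control_nonsig_rate": control_ok / n,
        "n_seeds": n,
    }


def evaluate_determinism(seed: int) -> dict:
    """Run the full pipeline twice with one seed; compare results and hashes."""
    manifests = []
    for _ in range(2):
        with tempfile.TemporaryDirectory() as outdir:
            cfg = PipelineConfig(outdir=os.path.join(outdir, "run"), seed=int(seed) & _MASK)
            manifests.append(run_pipeline(cfg))
    a, b = manifests
    results_equal = json.dumps(a["results"], sort_keys=True, default=float) == json.dumps(
        b["results"], sort_keys=True, default=float
    )
    hashes_a = {name: info["sha256"] for name, info in a["outputs"].items()}
    hashes_b = {name: info["sha256"] for name, info in b["outputs"].items()}
    return {
        "results_identical": bool(results_equal),
        "hashes_identical": hashes_a == hashes_b,
        "n_outputs": len(hashes_a),
    }
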