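import numpy as np
import pandas as pd
import pytest

from nucleolink import synthetic_data as sd
from nucleolink.genome_model import derive_igrs, read_gff3
from nucleolink.nucleosome_dynamics import call_nucleosomes, map_statistics


class TestSimulationConfig:
    def test_validation(self):
        with pytest.raises(ValueError):
            sd.SimulationConfig(alteration_fractions={"occ_up": 1.5})
        with pytest.raises(ValueError):
            sd.SimulationConfig(nucleosome_spacing=140)
        with pytest.raises(ValueError):
            sd.SimulationConfig(probe_step=0)

    def test_yaml_round_trip(self, tmp_path):
        cfg = sd.SimulationConfig(seed=9, n_genes=50, p_open=0.4)
        path = tmp_path / "cfg.yaml"
        cfg.to_yaml(path)
        assert sd.SimulationConfig.from_yaml(path) == cfg


class TestGenerateGenome:
    def test_deterministic(self):
        cfg = sd.SimulationConfig(seed=1)
        a1, c1 = sd.generate_genome(cfg)
        a2, c2 = sd.generate_genome(cfg)
        assert a1.chromosomes == a2.chromosomes
        assert {g: (v.interval, v.strand) for g, v in a1.genes.items()} == {
            g: (v.interval, v.strand) for g, v in a2.genes.items()
        }
        assert c1.categories == c2.categories

    def test_seed_changes_layout(self):
        a1, _ = sd.generate_genome(sd.SimulationConfig(seed=1))
        a2, _ = sd.generate_genome(sd.SimulationConfig(seed=2))
        tss1 = sorted(g.tss for g in a1.genes.values())
        tss2 = sorted(g.tss for g in a2.genes.values())
        assert tss1 != tss2

    def test_category_partitions(self, categories):
        uni = set(categories.universe)
        cats = categories.categories
        assert cats["Open"] | cats["Closed"] == uni
        assert not cats["Open"] & cats["Closed"]
        assert cats["FN"] | cats["SN"] == uni
        assert not cats["FN"] & cats["SN"]
        assert not cats["OPN"] & cats["DPN"]

    def test_requested_gene_count(self, annotation):
        assert len(annotation.genes) == sd.SimulationConfig().n_genes

    def test_infeasible_packing_rejected(self):
        with pytest.raises(ValueError, match="packing"):
            sd.generate_genome(
                sd.SimulationConfig(n_genes=2000, n_chromosomes=1, chrom_length=100_000)
            )

    def test_feature_catalog_shapes(self, annotation):
        cfg = sd.SimulationConfig()
        assert len(annotation.features["telomere"]) == 2 * cfg.n_chromosomes
        assert len(annotation.features["centromere"]) == cfg.n_chromosomes
        assert len(annotation.features["rDNA"]) == 1


class TestNucleosomeMaps:
    def test_no_alterations_null(self):
        cfg = sd.SimulationConfig(seed=3, alteration_fractions={})
        ann, cats = sd.generate_genome(cfg)
        wt, mut, truth = sd.generate_nucleosome_maps(cfg, ann, cats)
        assert len(truth.nucleosome_alterations) == 0
        # same layout, different sampling noise only
        assert abs(len(wt) - len(mut)) < 0.05 * len(wt)

    def test_truth_counts_match_fractions(self, sim):
        truth = sim["truth"].nucleosome_alterations
        n = sim["n_nucleosomes"]
        fracs = sim["config"].alteration_fractions
        counts = truth["category"].value_counts().to_dict()
        for cat, frac in fracs.items():
            assert counts.get(cat, 0) == round(frac * n)

    def test_alteration_categories_disjoint(self, sim):
        truth = sim["truth"].nucleosome_alterations
        assert not truth.duplicated(subset=["chrom", "dyad"]).any()

    def test_planted_occupancy_fold_recoverable(self, sim):
        truth = sim["truth"].nucleosome_alterations
        wt = sim["wt_reads"]
        mut = sim["mut_reads"]
        wt_by = {c: g["pos"].to_numpy() for c, g in wt.groupby("chrom")}
        mut_by = {c: g["pos"].to_numpy() for c, g in mut.groupby("chrom")}
        ratios = []
        for r in truth[truth["category"] == "occ_up"].itertuples(index=False):
            w = np.sum(np.abs(wt_by[r.chrom] - r.dyad) <= 73)
            m = np.sum(np.abs(mut_by[r.chrom] - r.dyad) <= 73)
            if w:
                ratios.append(m / w)
        assert np.mean(ratios) == pytest.approx(sim["config"].occupancy_fold, abs=0.3)

    def test_planted_shift_recovered_at_high_coverage(self):
        cfg = sd.SimulationConfig(
            seed=5,
            reads_per_nucleosome=300.0,
            read_jitter_sd=8.0,
            alteration_fractions={"shift": 0.01},
        )
        ann, cats = sd.generate_genome(cfg)
        wt, mut, truth = sd.generate_nucleosome_maps(cfg, ann, cats)
        wt_calls = call_nucleosomes(wt, ann.chromosomes)
        mut_calls = call_nucleosomes(mut, ann.chromosomes)
        wt_by = {c: g["summit"].to_numpy() for c, g in wt_calls.groupby("chrom")}
        mut_by = {c: g["summit"].to_numpy() for c, g in mut_calls.groupby("chrom")}
        errs = []
        for r in truth.nucleosome_alterations.itertuples(index=False):
            ws = wt_by[r.chrom][np.argmin(np.abs(wt_by[r.chrom] - r.dyad))]
            ms = mut_by[r.chrom][np.argmin(np.abs(mut_by[r.chrom] - (r.dyad + r.magnitude)))]
            errs.append(abs((ms - ws) - r.magnitude))
        # most planted shifts are recovered to caller resolution; shifts that
        # land a mutant dyad within the summit-separation limit of a
        # neighbour merge and are excluded from the accuracy median
        assert np.median(errs) <= 10

    def test_mean_fuzziness_matches_jitter(self, sim):
        calls = call_nucleosomes(sim["wt_reads"], sim["annotation"].chromosomes)
        stats_out = map_statistics(calls)
        assert stats_out["fuzziness_summary"]["median"] == pytest.approx(
            sim["config"].read_jitter_sd, abs=2.0
        )

    def test_spacing_matches_config(self, sim):
        calls = call_nucleosomes(sim["wt_reads"], sim["annotation"].chromosomes)
        stats_out = map_statistics(calls)
        assert stats_out["distance_summary"]["median"] == pytest.approx(
            sim["config"].nucleosome_spacing, abs=10
        )

    def test_deterministic(self):
        cfg = sd.SimulationConfig(seed=11)
        ann, cats = sd.generate_genome(cfg)
        wt1, mut1, _ = sd.generate_nucleosome_maps(cfg, ann, cats)
        wt2, mut2, _ = sd.generate_nucleosome_maps(cfg, ann, cats)
        pd.testing.assert_frame_equal(wt1, wt2)
        pd.testing.assert_frame_equal(mut1, mut2)


class TestTilingSignal:
    def test_null_pvalue_calibration(self):
        cfg = sd.SimulationConfig(seed=6, peak_density={})
        ann, _ = sd.generate_genome(cfg)
        tables, truth = sd.generate_tiling_signal(cfg, ann, derive_igrs(ann))
        assert len(truth.peaks) == 0
        frac = (tables["tagged_wt"]["pvalue"] < 0.05).mean()
        assert 0.04 < frac < 0.06

    def test_mutant_gain_applied(self, sim):
        peaks = sim["truth"].peaks
        gain = sim["config"].mutant_region_gain
        for r in peaks.itertuples(index=False):
            expected = gain.get(r.region_class, 1.0)
            assert r.amplitude_mut == pytest.approx(r.amplitude_wt * expected)

    def test_byte_identical_output(self, tmp_path):
        cfg = sd.SimulationConfig(seed=8)
        for sub in ("a", "b"):
            sim = sd.simulate_all(cfg)
            sd.write_simulation(sim, tmp_path / sub)
        for name in ("probes_tagged_wt.tsv", "reads_wt.tsv", "expression.tsv"):
            assert (tmp_path / "a" / name).read_bytes() == (
                tmp_path / "b" / name
            ).read_bytes()


class TestExpressionTable:
    def test_no_planted_de_bh_control(self):
        cfg = sd.SimulationConfig(seed=4, de_frac_down=0.0, de_frac_up=0.0)
        ann, cats = sd.generate_genome(cfg)
        table, truth = sd.generate_expression_table(cfg, ann, cats)
        assert len(truth.de_genes) == 0
        called = ((table["qvalue"] < 0.01) & (table["log2fc"].abs() >= 0.5)).sum()
        assert called <= 2  # BH false-discovery control at the null

    def test_planted_counts(self, sim):
        truth = sim["truth"].de_genes
        cfg = sim["config"]
        n = len(sim["categories"].universe)
        assert (truth["direction"] == "down").sum() == round(cfg.de_frac_down * n)
        assert (truth["direction"] == "up").sum() == round(cfg.de_frac_up * n)

    def test_down_bias_enriched_over_seeds(self):
        """Planted down genes hit the biased promoter classes above chance."""
        obs, exp = 0.0, 0.0
        for seed in range(10):
            cfg = sd.SimulationConfig(seed=seed)
            ann, cats = sd.generate_genome(cfg)
            _, truth = sd.generate_expression_table(cfg, ann, cats)
            bias = (
                cats.categories["OPN"]
                | cats.categories["FN"]
                | cats.categories["TATA"]
            )
            down = set(truth.de_genes.loc[truth.de_genes["direction"] == "down", "gene"])
            obs += len(down & bias)
            exp += len(down) * len(bias) / len(cats.universe)
        assert obs > 1.2 * exp

    def test_qvalues_valid(self, sim):
        q = sim["expression"]["qvalue"]
        assert ((q > 0) & (q <= 1)).all()


class TestTruthSerialization:
    def test_json_round_trip(self, sim, tmp_path):
        path = tmp_path / "truth.json"
        sim["truth"].to_json(path)
        back = sd.SyntheticTruth.from_json(path)
        for name in ("nucleosome_alterations", "peaks", "de_genes"):
            a = getattr(sim["truth"], name).reset_index(drop=True)
            b = getattr(back, name)[a.columns].reset_index(drop=True)
            pd.testing.assert_frame_equal(a, b, check_dtype=False)


class TestWriteSimulation:
    def test_annotation_survives_disk(self, sim, tmp_path):
        paths = sd.write_simulation(sim, tmp_path)
        back = read_gff3(paths["annotation.gff3"])
        assert back.chromosomes == sim["annotation"].chromosomes
        assert set(back.genes) == set(sim["annotation"].genes)
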