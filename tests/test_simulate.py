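"""Generator determinism, marginal statistics and planted structure."""

import filecmp

import numpy as np
import pytest

from silencescan.chipchip import compute_ratio_track
from silencescan.simulate import (
    TruthConfig,
    generate_annotation,
    generate_truth,
    plant_motifs,
    promoter_sequences,
    simulate_all,
    simulate_peak_replicates,
    simulate_probe_table,
    simulate_reads,
)

TINY = dict(n_genes=30, genome_length=1_500_000, depth=20_000,
            noise_peaks_per_replicate=20)


class TestConfig:
    def test_fraction_validation(self):
        with pytest.raises(ValueError):
            TruthConfig(exon_fraction=1.5)
        with pytest.raises(ValueError):
            TruthConfig(class_fractions={"silenced": 0.5, "induced": 0.5, "unchanged": 0.5})

    def test_yaml_round_trip(self, tmp_path):
        cfg = TruthConfig(**TINY, seed=5)
        p = tmp_path / "cfg.yaml"
        cfg.to_yaml(p)
        assert TruthConfig.from_yaml(p) == cfg


class TestAnnotationGen:
    def test_genes_non_overlapping_both_strands(self):
        cfg = TruthConfig(**TINY, seed=2)
        genes, genome = generate_annotation(cfg)
        assert len(genome) == cfg.genome_length
        prev_end = -1
        for g in sorted(genes, key=lambda g: g.start):
            assert g.start >= prev_end
            prev_end = g.end
        assert {g.strand for g in genes} == {"+", "-"}

    def test_exon_fraction_one_single_block(self):
        cfg = TruthConfig(**TINY, exon_fraction=1.0, seed=3)
        genes, _ = generate_annotation(cfg)
        assert all(len(g.exons) == 1 and g.exonic_length == g.length for g in genes)

    def test_zero_genes_valid(self, tmp_path):
        cfg = TruthConfig(n_genes=0, genome_length=10_000, depth=100,
                          n_rrna_genes=0, n_mirna_genes=0, seed=1)
        paths = simulate_all(cfg, tmp_path)
        from silencescan.annotation import read_gene_models

        assert read_gene_models(paths["genes_gff3"]) == []
        assert read_gene_models(paths["genes_bed12"], "bed12") == []

    def test_placement_failure_suggests_larger_genome(self):
        with pytest.raises(ValueError, match="genome_length"):
            generate_annotation(TruthConfig(n_genes=50, genome_length=100_000, seed=1))


class TestProbes:
    def test_probe_count_per_promoter(self):
        # window 4250 bp, 50 bp probes stepping 10 bp: floor((4250-50)/10)+1
        cfg = TruthConfig(**TINY, seed=4)
        genes, _ = generate_annotation(cfg)
        truth = generate_truth(cfg, genes)
        probes = simulate_probe_table(cfg, truth, genes)
        per_gene = probes.groupby(probes["probe_id"].str.split("_p").str[0]).size()
        assert (per_gene == 421).all()

    def test_noiseless_delta_exact(self):
        cfg = TruthConfig(**TINY, probe_log2_sd=0.0,
                          deacetylation_given_silenced=1.0, seed=6)
        genes, _ = generate_annotation(cfg)
        truth = generate_truth(cfg, genes)
        track = compute_ratio_track(simulate_probe_table(cfg, truth, genes))
        vals = set(np.round(track["deacetylation"], 9))
        assert vals <= {0.0, cfg.deacetylation_delta}
        deacet = set(truth.loc[truth["deacetylated"], "gene_id"])
        if deacet:
            sub = track[track["probe_id"].str.split("_p").str[0].isin(deacet)]
            assert np.isclose(sub["deacetylation"], cfg.deacetylation_delta).any()

    def test_no_deacetylation_when_probability_zero(self):
        cfg = TruthConfig(**TINY, probe_log2_sd=0.0,
                          deacetylation_given_silenced=0.0, seed=6)
        genes, _ = generate_annotation(cfg)
        truth = generate_truth(cfg, genes)
        track = compute_ratio_track(simulate_probe_table(cfg, truth, genes))
        assert (track["deacetylation"] == 0.0).all()


class TestReads:
    def test_mrna_reads_never_intronic(self):
        cfg = TruthConfig(n_genes=60, genome_length=3_000_000, depth=60_000, seed=7)
        genes, genome = generate_annotation(cfg)
        truth = generate_truth(cfg, genes)
        reads = simulate_reads(cfg, truth, genes, genome, "mRNA", "untreated")
        genic = reads[reads["name"].str.contains(":G")]
        exon_lookup = {g.gene_id: g.exons for g in genes}
        for _, r in genic.iterrows():
            gid = r["name"].split(":")[1]
            assert any(
                s <= r["start"] and r["end"] <= e for s, e in exon_lookup[gid]
            ), "mRNA read crosses an exon boundary"

    def test_spiked_fractions_within_binomial_bounds(self):
        cfg = TruthConfig(n_genes=40, genome_length=2_000_000, depth=100_000,
                          lowcomplexity_fraction=0.1, seed=8)
        genes, genome = generate_annotation(cfg)
        truth = generate_truth(cfg, genes)
        reads = simulate_reads(cfg, truth, genes, genome, "nascent", "untreated")
        n_low = reads["name"].str.contains("lowcomplexity").sum()
        expect = cfg.depth * 0.1
        sd = np.sqrt(cfg.depth * 0.1 * 0.9)
        assert abs(n_low - expect) < 4 * sd

    def test_class_fractions_within_multinomial_bounds(self):
        cfg = TruthConfig(n_genes=2000, genome_length=60_000_000, seed=9)
        genes, _ = generate_annotation(cfg)
        truth = generate_truth(cfg, genes)
        eligible = truth[truth["class_label"] != "rrna"]
        n = len(eligible)
        for cls, frac in cfg.class_fractions.items():
            k = (eligible["class_label"] == cls).sum()
            assert abs(k - n * frac) < 3 * np.sqrt(n * frac * (1 - frac))

    def test_poisson_limit_count_ratio_matches_fold(self):
        """With dispersion -> 0 and high depth, the LPS/untreated count
        ratio of a silenced gene converges to 1/fold."""
        cfg = TruthConfig(n_genes=30, genome_length=1_500_000, depth=1_000_000,
                          nb_dispersion=0.0, rrna_fraction=0.0,
                          lowcomplexity_fraction=0.0, multihit_fraction=0.0, seed=10)
        genes, genome = generate_annotation(cfg)
        truth = generate_truth(cfg, genes)
        untr = simulate_reads(cfg, truth, genes, genome, "nascent", "untreated")
        lps = simulate_reads(cfg, truth, genes, genome, "nascent", "LPS1h")
        sil = truth[(truth["class_label"] == "silenced") & (truth["true_fold"] < 20)]
        assert len(sil) > 0
        for _, t in sil.iterrows():
            cu = untr["name"].str.contains(f":{t['gene_id']}:").sum()
            cl = lps["name"].str.contains(f":{t['gene_id']}:").sum()
            if cu > 2000:
                assert cl / cu == pytest.approx(1.0 / t["true_fold"], rel=0.15)


class TestPeaksAndMotifs:
    def test_zero_jitter_no_noise_replicates_identical(self, tmp_path):
        cfg = TruthConfig(**{**TINY, "noise_peaks_per_replicate": 0},
                          peak_jitter_sd=0.0, seed=12)
        genes, _ = generate_annotation(cfg)
        truth = generate_truth(cfg, genes)
        r1, r2 = simulate_peak_replicates(cfg, truth, genes)
        assert r1[["chrom", "start", "end", "summit"]].equals(
            r2[["chrom", "start", "end", "summit"]]
        )

    def test_plant_probability_extremes(self):
        from silencescan.data import packaged_motifs

        cfg0 = TruthConfig(**TINY, seed=13,
                           motif_insert_probability={"silenced": 0, "induced": 0, "unchanged": 0})
        genes, genome = generate_annotation(cfg0)
        proms = promoter_sequences(genes, genome, 450, 50)
        assert all(len(s) == 500 for s in proms.values())
        motif = packaged_motifs()[0]
        out0, placed0 = plant_motifs(cfg0, generate_truth(cfg0, genes), proms, motif)
        assert out0 == proms and len(placed0) == 0
        cfg1 = TruthConfig(**TINY, seed=13,
                           motif_insert_probability={"silenced": 1, "induced": 1, "unchanged": 1})
        truth1 = generate_truth(cfg1, genes)
        out1, placed1 = plant_motifs(cfg1, truth1, proms, motif)
        assert len(placed1) == (truth1["class_label"] != "rrna").sum()


class TestDeterminism:
    def test_byte_identical_outputs(self, tmp_path):
        cfg = TruthConfig(**TINY, seed=21)
        p1 = simulate_all(cfg, tmp_path / "a")
        p2 = simulate_all(cfg, tmp_path / "b")
        for key in p1:
            assert filecmp.cmp(p1[key], p2[key], shallow=False), key

    def test_seed_changes_outputs(self, tmp_path):
        a = simulate_all(TruthConfig(**TINY, seed=1), tmp_path / "a")
        b = simulate_all(TruthConfig(**TINY, seed=2), tmp_path / "b")
        assert not filecmp.cmp(a["probes"], b["probes"], shallow=False)
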