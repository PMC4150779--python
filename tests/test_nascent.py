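"""Read filtering, containment assignment, RPKM and fold classification."""

import numpy as np
import pandas as pd
import pytest

from silencescan.annotation import GeneModel
from silencescan.nascent import (
    assign_reads,
    classify_change,
    compute_rpkm,
    expression_table,
    filter_reads,
    nascent_qc,
)


def read_frame(rows):
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "name", "n_genome_hits", "strand", "seq"]
    )


def random_read(rng, i, L=50):
    seq = "".join(rng.choice(list("ACGT"), size=L))
    return ("chr1", 1000 + i, 1000 + i + L, f"r{i}", 1, "+", seq)


class TestFilter:
    @pytest.mark.parametrize(
        "seq,reason",
        [
            ("A" * 50, "mono_repeat"),
            ("AC" * 25, "di_repeat"),
            ("ACGTN" * 10, "invalid_alphabet"),
        ],
    )
    def test_rejection_reasons(self, seq, reason):
        df = read_frame([("chr1", 0, 50, "r", 1, "+", seq)])
        kept, log = filter_reads(df)
        assert len(kept) == 0
        assert log[reason] == 1

    def test_ninety_percent_repeat_boundary(self):
        # 45 of 50 bases in a dinucleotide run: exactly at the 90% cutoff
        seq = "GATCG" + "TA" * 22 + "T"
        df = read_frame([("chr1", 0, 50, "r", 1, "+", seq)])
        kept, log = filter_reads(df)
        assert log["di_repeat"] == 1

    def test_random_reads_pass(self):
        rng = np.random.default_rng(0)
        df = read_frame([random_read(rng, i) for i in range(10_000)])
        kept, log = filter_reads(df)
        assert len(kept) == 10_000
        assert log["mono_repeat"] == log["di_repeat"] == 0

    def test_multi_hit_and_rrna(self):
        rrna = GeneModel("rn", "chr1", "+", 100, 600, biotype="rRNA")
        rng = np.random.default_rng(1)
        rows = [
            random_read(rng, 0),
            ("chr1", 550, 600, "in_rrna", 1, "+", "ACGT" * 12 + "AG"),
            ("chr1", 2000, 2050, "multi", 7, "+", "ACGT" * 12 + "AG"),
        ]
        kept, log = filter_reads(read_frame(rows), [rrna])
        assert log["rrna"] == 1 and log["multi_hit"] == 1
        assert kept["name"].tolist() == ["r0"]

    def test_precounted_mode_warns(self):
        df = pd.DataFrame(
            {"chrom": ["chr1"], "start": [0], "end": [50], "name": ["r"],
             "n_genome_hits": [1], "strand": ["+"]}
        )
        with pytest.warns(UserWarning, match="sequence"):
            kept, _ = filter_reads(df)
        assert len(kept) == 1


GENES = [
    GeneModel("gx", "chr1", "+", 1000, 3000, exons=((1000, 1500), (2500, 3000))),
    GeneModel("gy", "chr1", "+", 5000, 6000),
]


def mini_reads(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


class TestAssign:
    def test_intronic_read_counts_only_for_nascent(self):
        reads = mini_reads([("chr1", 1800, 1850, "r1")])
        nas, _ = assign_reads(reads, GENES, "nascent")
        mrna, _ = assign_reads(reads, GENES, "mRNA")
        assert nas.loc["gx", "count"] == 1 and nas.loc["gx", "intronic"] == 1
        assert mrna.loc["gx", "count"] == 0

    def test_exon_boundary_spanning_read_not_mrna(self):
        reads = mini_reads([("chr1", 1480, 1530, "r1")])
        mrna, _ = assign_reads(reads, GENES, "mRNA")
        nas, _ = assign_reads(reads, GENES, "nascent")
        assert mrna.loc["gx", "count"] == 0
        assert nas.loc["gx", "count"] == 1

    def test_nested_genes_ambiguous(self):
        nested = [
            GeneModel("outer", "chr1", "+", 0, 10_000),
            GeneModel("inner", "chr1", "-", 4000, 6000),
        ]
        reads = mini_reads([("chr1", 4500, 4550, "r1")])
        counts, info = assign_reads(reads, nested, "nascent")
        assert info["n_ambiguous"] == 1
        assert counts["count"].sum() == 0

    def test_matches_quadratic_oracle(self):
        rng = np.random.default_rng(3)
        genes = []
        pos = 0
        for i in range(60):
            pos += rng.integers(100, 400)
            length = int(rng.integers(200, 2000))
            genes.append(GeneModel(f"g{i}", "chr1", "+", pos, pos + length))
            pos += length
        starts = rng.integers(0, pos, size=2000)
        reads = mini_reads(
            [("chr1", int(s), int(s) + 50, f"r{j}") for j, s in enumerate(starts)]
        )
        counts, _ = assign_reads(reads, genes, "nascent")
        # oracle: all-pairs containment
        expected = {g.gene_id: 0 for g in genes}
        for s in starts:
            for g in genes:
                if g.start <= s and s + 50 <= g.end:
                    expected[g.gene_id] += 1
        assert counts["count"].to_dict() == expected


class TestRpkm:
    @pytest.mark.parametrize(
        "count,length,lib,expected",
        [(100, 1000, 10**6, 100.0), (50, 2000, 500_000, 50.0)],
    )
    def test_hand_formula(self, count, length, lib, expected):
        assert compute_rpkm([count], [length], lib)[0] == pytest.approx(expected)

    def test_scale_invariance(self):
        a = compute_rpkm([7], [1234], 10_000)[0]
        b = compute_rpkm([14], [1234], 20_000)[0]
        assert a == pytest.approx(b)

    def test_zero_library_errors(self):
        with pytest.raises(ValueError):
            compute_rpkm([1], [1000], 0)


class TestClassify:
    def test_strict_tier_boundary(self):
        # 10 -> 2 RPKM with no pseudocount: exactly 5-fold down, which
        # is NOT ">5-fold" under the strict inequality
        cls = classify_change([10.0], [2.0], epsilon=0.0)
        assert cls[2.0][0] == "silenced"
        assert cls[3.0][0] == "silenced"
        assert cls[5.0][0] == "unchanged"

    def test_below_baseline_not_expressed(self):
        cls = classify_change([0.5], [0.8])
        assert all(cls[k][0] == "not_expressed" for k in (2.0, 3.0, 5.0))

    def test_identity_ratio_unchanged(self):
        cls = classify_change([4.0], [4.0])
        assert all(cls[k][0] == "unchanged" for k in (2.0, 3.0, 5.0))

    def test_partition_nesting_antisymmetry(self):
        rng = np.random.default_rng(9)
        ru = rng.lognormal(1.0, 2.0, size=10_000)
        rl = rng.lognormal(1.0, 2.0, size=10_000)
        fwd = classify_change(ru, rl)
        rev = classify_change(rl, ru)
        for k in (2.0, 3.0, 5.0):
            labels = set(np.unique(fwd[k]))
            assert labels <= {"induced", "silenced", "unchanged", "not_expressed"}
            # swapping the libraries swaps induced and silenced exactly
            swap = {"induced": "silenced", "silenced": "induced"}
            assert all(
                rev[k][i] == swap.get(fwd[k][i], fwd[k][i]) for i in range(len(ru))
            )
        # tier nesting
        s2, s3, s5 = (fwd[k] == "silenced" for k in (2.0, 3.0, 5.0))
        assert (s5 <= s3).all() and (s3 <= s2).all()

    def test_epsilon_gives_finite_fold_for_zero(self):
        cls = classify_change([10.0], [0.0])
        assert np.isfinite(cls["fold"][0])
        assert cls[2.0][0] == "silenced"


class TestQc:
    def test_generator_fractions(self, small_analysis, small_cfg):
        """The nascent library's intronic fraction tracks intron length
        share; the mRNA library is intron-free; rRNA spike is reported."""
        from silencescan.nascent import assign_reads, filter_reads
        from silencescan.simulate import simulate_reads

        genes = small_analysis["genes"]
        truth = small_analysis["truth"]
        import silencescan.simulate as sim

        _, genome = sim.generate_annotation(small_cfg)
        nr = simulate_reads(small_cfg, truth, genes, genome, "nascent", "untreated")
        mr = simulate_reads(small_cfg, truth, genes, genome, "mRNA", "untreated")
        nk, nlog = filter_reads(nr, genes)
        mk, _ = filter_reads(mr, genes)
        nc, _ = assign_reads(nk, genes, "nascent")
        mc, _ = assign_reads(mk, genes, "mRNA")
        qc = nascent_qc(nc, mc, nlog)
        # expected intronic share: count-weighted intron length fraction
        t = truth[truth["class_label"] != "rrna"]
        w = t["nascent_rpkm"] * t["length"]
        expected = float((w * (1 - t["exonic_length"] / t["length"])).sum() / w.sum())
        assert qc["intronic_fraction_nascent"] == pytest.approx(expected, abs=0.05)
        assert qc["intronic_fraction_mRNA"] == 0.0
        assert qc["rrna_fraction"] == pytest.approx(small_cfg.rrna_fraction, abs=0.01)
        assert qc["rrna_depletion_pass"]
        assert qc["fraction_separation"] == "PASS"


def test_expression_table_self_consistent(small_analysis):
    expr = small_analysis["expression"]["nascent"]
    lengths = {g.gene_id: g.length for g in small_analysis["genes"]}
    lib = expr["count_untreated"].sum()
    row = expr.iloc[int(expr["count_untreated"].idxmax())]
    manual = row["count_untreated"] / (lengths[row["gene_id"]] / 1000 * lib / 1e6)
    assert row["rpkm_untreated"] == pytest.approx(manual, rel=1e-9)
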