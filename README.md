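# silencescan

Tools for studying **rapid stimulus-induced gene silencing** in
maturing dendritic cells — the mirror image of the classical
induction response. Within one hour of a microbial stimulus (LPS),
hundreds of promoters lose histone H4 acetylation and the
transcription rate of the affected genes collapses, long before
steady-state mRNA levels move. `silencescan` re-implements the full
computational path of that analysis as a tested, reusable pipeline:

1. **Promoter deacetylation calling** (`silencescan.chipchip`) —
   two-channel tiling-array signals over promoter windows
   (−3500..+750 bp of the TSS; ~50 bp probes, 5′ ends ~10 bp apart)
   are reduced to per-probe log₂ ratios; `deacetylation =
   log₂(iDC/LPS1h)` is positive where acetylation is lost on
   stimulation. A promoter is called *decreased* when a sliding window
   of 5 consecutive probes contains ≥ 4 probes at ≥ 1.0 log₂ units
   (*increased* by the mirrored rule).
2. **Transcription-rate classification** (`silencescan.nascent`) —
   chromatin-bound (nascent) and mRNA reads are filtered
   (mono/di-nucleotide repeats, multi-mappers, rRNA loci), assigned to
   genes by full containment (nascent: gene span; mRNA: single exon),
   and quantified as RPKM = count / (length_kb × library_millions).
   Genes ≥ 1 RPKM are classified *induced*/*silenced*/*unchanged* at
   strict >2, >3 and >5-fold tiers from the ratio
   r = (RPKM_LPS + ε)/(RPKM_untreated + ε), ε = 0.1.
3. **Integration** (`silencescan.integrate`) — the deacetylated ∩
   expressed ∩ silenced intersection yields the *deacetylated-silenced*
   gene sets per tier, plus the headline fractions (% of deacetylated
   promoters expressed; % of those silenced >2-fold).
4. **TSS peak occupancy** (`silencescan.peaks`) — narrowPeak calls are
   kept when significant (p < 10⁻⁵, strict) and reproducible
   (overlapping a second-replicate peak by ≥ 1 nt), then profiled as
   the percent of genes with ≥ 1 peak within windows centered on the
   TSS, against the all-genes baseline.
5. **Promoter motif enrichment** (`silencescan.motifs`) — each
   −450..+50 promoter window is scored per JASPAR-style PWM by the
   min–max-normalized best log-odds hit over both strands, and gene
   sets are tested with z = (mean_set − mean_bg)/(sd_bg/√n_set),
   significant at p < 10⁻³.

Because the original raw data require external downloads, the package
ships a first-class **synthetic-data generator**
(`silencescan.simulate`) that emulates the statistical structure of
the study and plants a known ground truth — silenced/induced/unchanged
classes with log-uniform fold changes (2–100×), promoter
deacetylation, TSS-proximal binding sites and promoter motifs — so the
whole pipeline is exercised and validated end to end, offline.

## Worked example

```python
from silencescan.simulate import TruthConfig
from silencescan.evaluate import run_synthetic_analysis, recovery_metrics

cfg = TruthConfig(n_genes=500, genome_length=16_000_000,
                  depth=500_000, seed=7)
analysis = run_synthetic_analysis(cfg, with_reads=True)
print(analysis["summary"]["pct_deacetylated_expressed"])
print(analysis["summary"]["pct_expressed_deacetylated_silenced_2"])
print(recovery_metrics(analysis))
```

prints (seed 7):

```
100.0
100.0
{'silenced_sensitivity': 1.0, 'n_silenced_min_fold': 41,
 'unchanged_mislabel_rate': 0.009852216748768473, 'n_unchanged': 406,
 'jaccard_deacetylated_silenced': 1.0, 'n_planted_deacetylated': 44,
 'caller_sensitivity': 1.0, 'caller_fpr': 0.0}
```

i.e. at this problem size every promoter called deacetylated belongs
to a gene expressed ≥ 1 RPKM in untreated cells, all of those drop
more than 2-fold in nascent transcription after stimulation, every
planted ≥ 4-fold silenced gene is recovered as silenced@2, 1.0% of
truly unchanged genes are mislabeled, and the recovered
deacetylated-silenced set coincides with the planted one
(Jaccard 1.0).

The same stages are available from the shell:

```bash
silencescan simulate --outdir sim/            # all inputs + truth
silencescan run --config pipeline.yaml        # full pipeline
silencescan chipchip --probes sim/probes.tsv --genes sim/genes.gff3 --out calls.tsv
```

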