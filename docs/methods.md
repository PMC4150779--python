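# Methods

## Scope and model

`silencescan` analyses the first hour of dendritic-cell maturation,
when a set of genes is actively shut down: their promoters lose
histone H4 acetylation and their transcription rate (measured on
chromatin-bound nascent transcripts) drops 2- to ~100-fold while
steady-state mRNA has barely moved. The pipeline intersects three
measurements anchored on the transcription start site (TSS):
two-channel tiling-array chromatin signals over promoters,
nascent/mRNA sequencing read counts, and ChIP-seq peak calls; promoter
sequence is scanned with position weight matrices (PWMs) for
enrichment of transcription-factor binding sites.

All genomic intervals are 0-based half-open internally; GFF3/GTF
1-based closed coordinates are converted only at the file boundary.
Multi-transcript genes collapse to one model (union of exons, 5′-most
start); the analysis is gene-level throughout, matching the
one-promoter-per-gene design of the arrays.

## Promoter deacetylation calling

Per probe: `acetylation = log₂(iDC/input)`,
`deacetylation = log₂(iDC/LPS1h)` (positive = acetylation lost on
LPS). Intensities below 1.0 are floored at 1.0 before ratios so
background-subtracted channels cannot produce infinities; non-positive
or missing intensities are an input error.

The vendor software used on the original arrays does not document its
peak rule, so the caller here is fully specified: probes whose
midpoints fall in the promoter window (default −3500..+750 bp,
strand-aware) are sorted by position and scanned with a sliding window
of `win_probes = 5` consecutive probes; the promoter is *decreased* if
any window holds `min_probes_above = 4` probes with deacetylation
≥ `threshold = 1.0` log₂ units, *increased* by the mirrored rule on
the negated signal, *unchanged* otherwise. This is an ACME-style
run-of-probes rule; all three constants are parameters. If both
directions qualify somewhere in a window the stronger extremal window
mean wins (a tie-break that essentially never fires on real-shaped
signal). The call's score is the extremal window mean and its
`peak_offset` the signed strand-aware distance of that window's
midpoint from the TSS. Fewer than `win_probes` probes yield an
*unchanged* call flagged `insufficient_probes`.

Because the published percentages (~4% decreased, ~1% increased)
depend on unpublished vendor parameters and raw data, they are not
reproduction targets; the caller is instead validated by planted-truth
recovery (sensitivity ≥ 0.9, FPR ≤ 0.05 at Δ = 1.5, per-channel noise
sd 0.3) and by exact agreement with a brute-force enumeration of all
probe windows.

## Read filtering, assignment and classification

Reads are dropped when (first matching reason) they contain non-ACGT
characters; when ≥ 90% of the read is a tandem repeat of a 1- or 2-mer
(the repeat filter is named but not quantified in the original
description; 90% coverage is this package's definition, computed from
the shifted-self-equality runs of the sequence); when they map to more
than one genomic location; or when they overlap an annotated rRNA
gene (emulating rRNA depletion). A read counts for a gene when fully
contained in the gene span (nascent fraction) or in a single exon
(mRNA fraction); reads contained in more than one gene are ambiguous
and count for none. Containment of fixed-length reads removes
junction ambiguity without a spliced aligner.

RPKM uses the gene span (nascent) or exonic length (mRNA) and, by
default, the total *assigned* reads of the library as its size — the
original analysis does not state which convention it used, so the
choice is explicit and overridable (`library_sizes=`). Genes below
1 RPKM in both conditions are *not_expressed*. Otherwise
r = (RPKM_LPS + ε)/(RPKM_untr + ε) with ε = 0.1 pseudo-RPKM (genes
falling to zero reads need a finite fold; ε is a parameter and all
validation pins it), and labels are assigned with strict inequalities
(">2-fold" read literally): induced@k if r > k, silenced@k if
r < 1/k, else unchanged@k, for k ∈ {2, 3, 5}. Strictness makes
boundary genes deterministic; labels nest by construction. Read
strand is ignored for assignment (library strandedness is not part of
the model).

## Integration

*Expressed* is anchored to the untreated nascent RPKM (the study
frames expression in immature cells). The deacetylated-silenced set at
tier k is `decreased-call ∧ expressed ∧ silenced@k` on the nascent
fraction; mRNA evidence is reported alongside but not required for
membership, matching how the transcription-level analysis is framed.
The mRNA fold of each perturbed gene is attenuated toward 1 in the
generator (see below), so synthetic data reproduce the qualitative
observation that more genes are down at the nascent than at the mRNA
level after 1 h.

## Peak occupancy

Peaks below p = 10⁻⁵ (strict) are kept if some peak of the second
biological replicate overlaps them by ≥ `min_overlap_nt` bases.
"Overlapping by >1 nt" is ambiguous in the source (literally ≥ 2);
the default here is ≥ 1 nt, the standard reproducibility semantics,
and the knob is exposed. Retained peaks take the union interval of
the supporting pair(s). A peak's position is its summit when present,
else the interval midpoint (summits are not guaranteed across
narrowPeak dialects). Occupancy profiles report, per gene set and
window size w, the percent of genes with ≥ 1 peak position within
w/2 bp of the TSS (inclusive); distance bins are signed and
strand-aware (upstream negative); the all-genes baseline is always
computed alongside. The accompanying two-proportion z-test is
descriptive plumbing, not a statistic of the original study.

## Motif enrichment

PWMs are JASPAR-style count matrices. Column probabilities get a
pseudocount of 1% of the column sum, split by the background base
frequencies (uniform by default); scores are log₂ odds. A promoter's
score for a motif is the best hit over all positions and both strands
of its −450..+50 window, min–max normalized by the motif's attainable
extremes so scores are comparable across motifs; N bases (contig-edge
padding) contribute the background-expected column score. Set
enrichment follows the promoter-scanning convention:
z = (mean_set − mean_bg)/(sd_bg/√n_set) against the all-promoters
background (population sd), one-sided upper-tail normal p,
significant at p < 10⁻³ with no multiple-testing correction (the
reported semantics of the original analysis). The packaged PWM set is
synthetic: an ETS-like matrix (consensus AGAGGAAGTG, the planted
motif), a REL-like matrix and an unrelated decoy.

## Synthetic data generator

The generator defines the study conditions; defaults are fixed, not
tuned. 2000 non-overlapping genes (two rRNA, five microRNA among
them) are placed on a 60-Mb uniform-random chromosome with 5–15 kb
intergenic gaps, log-uniform lengths 2–50 kb, 40% exonic. Classes:
10% silenced, 10% induced, 80% unchanged; true folds log-uniform on
2–100 (the observed range of transcription reductions); 90% of
silenced genes are deacetylated over a 1-kb region whose center sits
near the TSS (Gaussian, sd 250 bp), with a log₂ drop of 1.5 against
per-channel log-normal probe noise of sd 0.3. Binding sites are
planted near the TSS with probability 0.9 (silenced) vs 0.3 (other
classes); promoter motifs with probability 0.8 vs 0.2.

Expression levels are log-uniform: 2–256 nominal RPKM for silenced
and unchanged genes, 0.25–4 for induced genes. The asymmetry is
biological and compositional at once: strongly inducible
primary-response genes start near-off, and were they to start high,
100-fold inductions at 10% of genes would inflate total library
output ~3-fold and make every unchanged gene look silenced under
per-million normalization. Levels are rescaled once so that
Σ(RPKM × length_kb) = 10⁶ in the untreated nascent library, making
nominal RPKM equal expected measured RPKM at the configured depth
(2×10⁶ reads/library). The per-gene expression-level distribution is
not constrained by the source study and remains configurable.

Counts are Gamma-Poisson: each gene draws one Gamma rate multiplier
(mean 1, variance = `nb_dispersion` = 0.1) per fraction, shared
between the untreated and stimulated libraries of that fraction, and
per-library counts are Poisson around rate × multiplier. Marginal
counts are therefore negative binomial with the configured
dispersion, and the model reduces to pure Poisson as dispersion → 0.
Sharing the multiplier across the two conditions of one biological
sample models gene-level rate heterogeneity rather than
condition-independent noise; this matters because the two conditions
here are the same cells before/after treatment, and it is what makes
a 2-fold cutoff on a single library pair a meaningful classifier —
with independent per-library dispersion 0.1 the log₂ ratio of an
unchanged gene would have sd ≈ 0.65 and >10% of unchanged genes
would cross 2-fold at any depth. mRNA folds are attenuated:
fold_mRNA = fold^`mrna_attenuation` (default 0.3), emulating the lag
of steady-state pools at 1 h; attenuation 1 means mRNA tracks
transcription exactly.

Nascent reads are uniform over gene spans, mRNA reads uniform over
(and fully inside) single exons; spiked reads contribute rRNA-locus
reads (4%), mono/di-nucleotide tandem repeats (1%) and multi-mappers
(0.5%). Replicate ChIP peaks share per-site width and significance
(drawn once) and differ by Gaussian positional jitter (sd 50 bp) plus
replicate-private noise peaks of mixed significance, so zero jitter
and zero noise yield byte-identical replicates. Every artifact has
its own RNG stream derived from the master seed by label hashing:
adding an output never perturbs existing ones, and a config (with its
seed) determines every output byte.

What the generator does **not** model — and hence what passing tests
do not establish about real data: sequencing errors and quality
scores, paired-end geometry, mappability and GC structure of a real
genome, splice-junction reads, inter-array normalization across
biological replicates, correlated probe noise, and real motif
co-occurrence structure. Recovery results validate the pipeline's
logic, not the original study's numbers, which depend on raw data
and unpublished tool parameters.

## Numerical and design choices

- Strict inequalities at every published threshold (p < 10⁻⁵,
  p < 10⁻³, >k-fold), so boundary cases are deterministic and
  documented.
- The minus-strand promoter window is the exact mirror image of the
  plus-strand window under coordinate reflection (length always
  upstream + downstream; the TSS base is included).
- A promoter window clipped at coordinate 0 is shortened, not
  shifted.
- `classify_change` computes the ratio after adding ε to both
  conditions; with ε = 0 a 5-fold drop is exactly not ">5-fold".
- Deacetylation calls with both directions qualifying resolve to the
  larger absolute window mean.
- The TSS-offset histogram of an empty decreased set is all-zero
  rather than an error, so downstream tabulation is total.
- Problem sizes in the test-suite recovery runs (200–2000 genes,
  10⁵–2×10⁶ reads) are the package's chosen desk-scale conditions;
  the full default configuration is exercised in the end-to-end
  recovery tests and by `scripts/acceptance.py`.

## Known limitations

- No inter-array or between-library normalization is implemented;
  the deacetylation caller assumes channels are already comparable
  (the original analysis relied on vendor processing and biological
  replicates; replicate-consistent calling is exposed as a parameter
  but synthetic data model a single array).
- Gene-level collapse ignores alternative TSSs; genes whose dominant
  promoter differs between conditions are outside the model.
- The motif statistic ignores the overlap between a gene set and its
  background (the convention of the method it follows); for sets that
  are a large fraction of the background the z is conservative.
- best-hit scoring reports one site per promoter; multi-site
  promoters are not scored higher.
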