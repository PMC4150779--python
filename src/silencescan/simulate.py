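"""Synthetic-data generation with planted ground truth.

Generates every input the pipeline consumes -- genome, annotation,
two-channel promoter tiling-array probe signals, positioned nascent and
mRNA reads for two conditions, replicate ChIP-seq peak calls, and
motif-planted promoter sequences -- from a single seeded configuration,
so every downstream stage can be tested against a known truth without
downloading anything.

The generative model mirrors the statistical structure the analysis
assumes: ~10% of genes are rapidly silenced on stimulation (true folds
log-uniform on 2-100), ~10% induced, the rest unchanged; 90% of
silenced genes additionally lose promoter H4 acetylation over a ~1 kb
region near the TSS (log2 drop of 1.5 on the treated channel); silenced
genes are enriched for TSS-proximal transcription-factor peaks and for
a planted promoter motif. Read counts are Gamma-Poisson: a per-gene
Gamma rate multiplier (variance = ``nb_dispersion``) shared across the
libraries of a fraction models gene-level biological heterogeneity, and
per-library Poisson sampling models counting noise, so marginal counts
are negative binomial with the configured dispersion and the model
reduces to pure Poisson as the dispersion goes to zero.

Every output derives from one RNG stream per artifact, keyed by a label
hashed together with the master seed, so adding an output never
perturbs existing ones and identical configs are byte-reproducible.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import peaks as peaks_mod
from .annotation import GeneModel, GenomicWindow, write_bed12, write_gff3
from .motifs import MotifMatrix, reverse_complement

__all__ = [
    "TruthConfig",
    "generate_annotation",
    "generate_truth",
    "simulate_probe_table",
    "simulate_reads",
    "simulate_peak_replicates",
    "plant_motifs",
    "promoter_sequences",
    "simulate_all",
    "write_genome_fasta",
]

GENE_CLASSES = ("silenced", "induced", "unchanged")
_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP_TABLE = np.zeros(256, dtype=np.uint8)
for a, b in zip(b"ACGTN", b"TGCAN"):
    _COMP_TABLE[a] = b


def _rng(seed: int, label: str) -> np.random.Generator:
    """Independent, platform-stable stream per (seed, artifact label)."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(label.encode())])
    )


@dataclass
class TruthConfig:
    """All knobs of the generator; the seed fully determines every byte.

    Distances are bp, rates are fractions in [0, 1], expression levels
    nominal RPKM (rescaled so library output matches ``depth``).
    """

    n_genes: int = 2000
    genome_length: int = 60_000_000
    chrom: str = "chr1"
    gene_length_range: tuple = (2000, 50_000)
    intergenic_gap_range: tuple = (5000, 15_000)
    exon_fraction: float = 0.4
    class_fractions: dict = field(
        default_factory=lambda: {"silenced": 0.10, "induced": 0.10, "unchanged": 0.80}
    )
    fold_range: tuple = (2.0, 100.0)
    expression_rpkm_range: tuple = (2.0, 256.0)
    induced_rpkm_range: tuple = (0.25, 4.0)
    mrna_attenuation: float = 0.3
    deacetylation_given_silenced: float = 0.9
    deacetylation_delta: float = 1.5
    deacetylation_width: int = 1000
    deacetylation_center_sd: float = 250.0
    pu1_site_probability: dict = field(
        default_factory=lambda: {"silenced": 0.9, "induced": 0.3, "unchanged": 0.3}
    )
    motif_insert_probability: dict = field(
        default_factory=lambda: {"silenced": 0.8, "induced": 0.2, "unchanged": 0.2}
    )
    nb_dispersion: float = 0.1
    probe_log2_sd: float = 0.3
    peak_jitter_sd: float = 50.0
    peak_width_range: tuple = (150, 400)
    noise_peaks_per_replicate: int = 500
    depth: int = 2_000_000
    rrna_fraction: float = 0.04
    lowcomplexity_fraction: float = 0.01
    multihit_fraction: float = 0.005
    read_length: int = 50
    probe_length: int = 50
    probe_step: int = 10
    promoter_upstream: int = 3500
    promoter_downstream: int = 750
    motif_window_upstream: int = 450
    motif_window_downstream: int = 50
    n_rrna_genes: int = 2
    n_mirna_genes: int = 5
    seed: int = 42

    def __post_init__(self):
        for name in (
            "exon_fraction", "deacetylation_given_silenced", "rrna_fraction",
            "lowcomplexity_fraction", "multihit_fraction", "mrna_attenuation",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for d in (self.pu1_site_probability, self.motif_insert_probability):
            for k, v in d.items():
                if not 0.0 <= v <= 1.0:
                    raise ValueError(f"probability for class {k!r} out of [0, 1]")
        if abs(sum(self.class_fractions.values()) - 1.0) > 1e-9:
            raise ValueError("class_fractions must sum to 1")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be non-negative")

    def to_yaml(self, path: str) -> None:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str) -> "TruthConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        for k, v in d.items():
            if isinstance(v, list):
                d[k] = tuple(v)
        return cls(**d)


# ---------------------------------------------------------------------------
# annotation + genome


def _split_lengths(rng, total, n, min_size):
    """Split ``total`` into n positive parts >= min_size (best effort)."""
    if n <= 1 or total < 2 * min_size:
        return [total]
    n = min(n, max(1, total // min_size))
    props = rng.dirichlet(np.full(n, 5.0))
    sizes = np.maximum(np.round(props * total).astype(int), min_size)
    # fix rounding drift on the largest part
    sizes[int(np.argmax(sizes))] += total - int(sizes.sum())
    if sizes.min() < 1:
        return [total]
    return sizes.tolist()


def _make_exons(rng, start, length, exon_fraction, min_block=100):
    if exon_fraction >= 1.0:
        return ((start, start + length),)
    exonic = max(min_block, int(round(exon_fraction * length)))
    exonic = min(exonic, length)
    intronic = length - exonic
    if intronic < min_block:
        return ((start, start + length),)
    n_exons = int(np.clip(round(length / 6000) + 1, 2, 15))
    n_exons = min(n_exons, exonic // min_block, intronic // min_block + 1)
    if n_exons < 2:
        return ((start, start + exonic),)
    ex_sizes = _split_lengths(rng, exonic, n_exons, min_block)
    in_sizes = _split_lengths(rng, intronic, len(ex_sizes) - 1, min_block)
    if len(in_sizes) != len(ex_sizes) - 1:
        return ((start, start + exonic),)
    exons = []
    pos = start
    for i, es in enumerate(ex_sizes):
        exons.append((pos, pos + es))
        pos += es
        if i < len(in_sizes):
            pos += in_sizes[i]
    # absorb any residue into the final exon so the span ends exonic
    last_s, last_e = exons[-1]
    exons[-1] = (last_s, start + length)
    return tuple(exons)


def generate_annotation(cfg: TruthConfig) -> tuple:
    """Place non-overlapping genes on a uniform-random genome.

    Returns ``(genes, genome)`` where genome is a uint8 array of ASCII
    bases for the single synthetic chromosome. Both strands are used;
    rRNA and microRNA genes are single-exon.
    """
    rng = _rng(cfg.seed, "annotation")
    n = cfg.n_genes
    lo, hi = cfg.gene_length_range
    lengths = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n)).astype(int)
    biotype = np.array(["protein_coding"] * n, dtype=object)
    if n > 0:
        special = rng.permutation(n)
        n_rrna = min(cfg.n_rrna_genes, n)
        n_mirna = min(cfg.n_mirna_genes, max(0, n - n_rrna))
        biotype[special[:n_rrna]] = "rRNA"
        biotype[special[n_rrna : n_rrna + n_mirna]] = "microRNA"
        lengths[special[:n_rrna]] = 5000
        lengths[special[n_rrna : n_rrna + n_mirna]] = rng.integers(
            1000, 3000, size=n_mirna
        )
    gaps = rng.integers(*cfg.intergenic_gap_range, size=n + 1) if n else np.empty(0, int)
    strands = rng.choice(np.array(["+", "-"], dtype=object), size=n)
    genes = []
    pos = int(gaps[0]) if n else 0
    for i in range(n):
        start = pos
        end = start + int(lengths[i])
        if end + int(gaps[i + 1]) > cfg.genome_length:
            raise ValueError(
                f"could not place {n} genes in genome_length={cfg.genome_length}; "
                "increase genome_length"
            )
        ef = 1.0 if biotype[i] in ("rRNA", "microRNA") else cfg.exon_fraction
        exons = _make_exons(rng, start, int(lengths[i]), ef)
        genes.append(
            GeneModel(
                gene_id=f"G{i:05d}",
                chrom=cfg.chrom,
                strand=strands[i],
                start=start,
                end=end,
                exons=exons,
                biotype=biotype[i],
            )
        )
        pos = end + int(gaps[i + 1])
    genome = _BASE_BYTES[_rng(cfg.seed, "genome").integers(0, 4, cfg.genome_length)]
    return genes, genome


def write_genome_fasta(genome: np.ndarray, path: str, chrom: str = "chr1") -> None:
    raw = genome.tobytes()
    with open(path, "wb") as fh:
        fh.write(f">{chrom}\n".encode())
        for i in range(0, len(raw), 80):
            fh.write(raw[i : i + 80] + b"\n")


# ---------------------------------------------------------------------------
# ground truth


def generate_truth(cfg: TruthConfig, genes: list) -> pd.DataFrame:
    """Per-gene planted truth: class, fold, expression, marks and sites.

    Expression levels are drawn log-uniform (low for induced genes,
    which start near-off) and rescaled so that sum(rpkm x length_kb)
    equals 1e6 in the untreated nascent library -- i.e. the nominal RPKM
    is also the expected measured RPKM at the configured depth.
    """
    rng = _rng(cfg.seed, "truth")
    rows = []
    classes = list(cfg.class_fractions)
    probs = np.array([cfg.class_fractions[c] for c in classes])
    for g in genes:
        if g.biotype == "rRNA":
            cls, fold = "rrna", 1.0
        else:
            cls = classes[rng.choice(len(classes), p=probs)]
            if cls in ("silenced", "induced"):
                fold = float(
                    np.exp(rng.uniform(*np.log(np.array(cfg.fold_range))))
                )
            else:
                fold = 1.0
        if cls == "induced":
            base = float(np.exp(rng.uniform(*np.log(np.array(cfg.induced_rpkm_range)))))
        elif cls == "rrna":
            base = 0.0
        else:
            base = float(
                np.exp(rng.uniform(*np.log(np.array(cfg.expression_rpkm_range))))
            )
        deacet = cls == "silenced" and rng.random() < cfg.deacetylation_given_silenced
        center = -1
        if deacet:
            off = int(np.round(rng.normal(0.0, cfg.deacetylation_center_sd)))
            off = int(
                np.clip(
                    off,
                    -(cfg.promoter_upstream - cfg.deacetylation_width // 2),
                    cfg.promoter_downstream - cfg.deacetylation_width // 2,
                )
            )
            center = g.tss + off if g.strand == "+" else g.tss - off
        p_site = cfg.pu1_site_probability.get(cls, 0.0)
        has_site = rng.random() < p_site
        site_pos = (
            int(g.tss + rng.integers(-250, 251)) if has_site else -1
        )
        p_motif = cfg.motif_insert_probability.get(cls, 0.0)
        has_motif = rng.random() < p_motif
        if cfg.nb_dispersion > 0:
            gamma_n = rng.gamma(1.0 / cfg.nb_dispersion, cfg.nb_dispersion)
            gamma_m = rng.gamma(1.0 / cfg.nb_dispersion, cfg.nb_dispersion)
        else:
            gamma_n = gamma_m = 1.0
        rows.append(
            {
                "gene_id": g.gene_id,
                "biotype": g.biotype,
                "strand": g.strand,
                "tss": g.tss,
                "length": g.length,
                "exonic_length": g.exonic_length,
                "class_label": cls,
                "true_fold": fold,
                "base_rpkm": base,
                "deacetylated": deacet,
                "deacet_center": center,
                "pu1_site": has_site,
                "pu1_pos": site_pos,
                "motif_planted": has_motif,
                "gamma_nascent": gamma_n,
                "gamma_mrna": gamma_m,
            }
        )
    truth = pd.DataFrame(rows)
    if len(truth):
        for col, length in (
            ("nascent_rpkm", truth["length"]),
            ("mrna_rpkm", truth["exonic_length"]),
        ):
            weight = float((truth["base_rpkm"] * length / 1000.0).sum())
            scale = 1e6 / weight if weight > 0 else 0.0
            truth[col] = truth["base_rpkm"] * scale
    return truth


# ---------------------------------------------------------------------------
# probe table


def simulate_probe_table(cfg: TruthConfig, truth: pd.DataFrame, genes: list) -> pd.DataFrame:
    """Two-channel tiling probes over every promoter window.

    Probes are ``probe_length`` bp with 5' ends ``probe_step`` bp apart.
    Non-deacetylated promoters have E[log2(iDC/LPS1h)] = 0; deacetylated
    promoters drop by ``deacetylation_delta`` over a ``deacetylation_width``
    region around the planted center. Channels carry independent
    log-normal noise (log2 sd = ``probe_log2_sd``); the input channel is
    flat.
    """
    rng = _rng(cfg.seed, "probes")
    tmap = truth.set_index("gene_id") if len(truth) else None
    baseline = 500.0
    acetyl_log2 = 2.0
    frames = []
    for g in genes:
        w = GenomicWindow(
            g.chrom, g.tss, g.strand, cfg.promoter_upstream, cfg.promoter_downstream
        )
        starts = np.arange(w.start, w.end - cfg.probe_length + 1, cfg.probe_step)
        if len(starts) == 0:
            continue
        mids = starts + cfg.probe_length / 2.0
        delta = np.zeros(len(starts))
        if tmap is not None and g.gene_id in tmap.index:
            t = tmap.loc[g.gene_id]
            if bool(t["deacetylated"]):
                half = cfg.deacetylation_width / 2.0
                delta[np.abs(mids - t["deacet_center"]) <= half] = cfg.deacetylation_delta
        noise = rng.normal(0.0, cfg.probe_log2_sd, size=(3, len(starts)))
        frames.append(
            pd.DataFrame(
                {
                    "probe_id": [f"{g.gene_id}_p{i:04d}" for i in range(len(starts))],
                    "chrom": g.chrom,
                    "start": starts,
                    "end": starts + cfg.probe_length,
                    "iDC": baseline * 2 ** (acetyl_log2 + noise[0]),
                    "LPS1h": baseline * 2 ** (acetyl_log2 - delta + noise[1]),
                    "input": baseline * 2 ** noise[2],
                }
            )
        )
    if not frames:
        return pd.DataFrame(
            columns=["probe_id", "chrom", "start", "end", "iDC", "LPS1h", "input"]
        )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# reads


def _extract_seqs(genome: np.ndarray, starts: np.ndarray, length: int) -> np.ndarray:
    mat = np.empty((len(starts), length), dtype=np.uint8)
    offsets = np.arange(length, dtype=np.int64)
    chunk = 200_000  # bound the temporary index array
    for i in range(0, len(starts), chunk):
        mat[i : i + chunk] = genome[starts[i : i + chunk, None] + offsets]
    return mat


def _mat_to_strings(mat: np.ndarray) -> list:
    raw = mat.tobytes()
    L = mat.shape[1]
    return [raw[i * L : (i + 1) * L].decode() for i in range(mat.shape[0])]


def _condition_factor(cls: str, fold: float, condition: str, attenuation: float) -> float:
    if condition != "LPS1h" or cls in ("unchanged", "rrna"):
        return 1.0
    f = fold ** attenuation
    return 1.0 / f if cls == "silenced" else f


def simulate_reads(
    cfg: TruthConfig,
    truth: pd.DataFrame,
    genes: list,
    genome: np.ndarray,
    fraction: str = "nascent",
    condition: str = "untreated",
) -> pd.DataFrame:
    """Positioned fixed-length reads for one library.

    Genic counts are Poisson around the per-gene rate (base RPKM x
    condition factor x shared Gamma multiplier x feature length x
    depth); nascent reads are uniform over the gene span, mRNA reads
    uniform over (and fully inside) single exons. Spiked-in reads:
    rRNA-locus reads at ``rrna_fraction``, mono-/di-nucleotide repeat
    reads at ``lowcomplexity_fraction`` and multi-mapping reads at
    ``multihit_fraction``.
    """
    if fraction not in ("nascent", "mRNA"):
        raise ValueError(f"unknown fraction {fraction!r}")
    if condition not in ("untreated", "LPS1h"):
        raise ValueError(f"unknown condition {condition!r}")
    if cfg.depth < 1:
        raise ValueError("depth must be >= 1")
    rng = _rng(cfg.seed, f"reads:{fraction}:{condition}")
    rl = cfg.read_length
    att = 1.0 if fraction == "nascent" else cfg.mrna_attenuation
    gene_by_id = {g.gene_id: g for g in genes}

    all_starts, all_names, all_hits, seq_chunks = [], [], [], []
    for _, t in truth.iterrows():
        g = gene_by_id[t["gene_id"]]
        rpkm = t["nascent_rpkm"] if fraction == "nascent" else t["mrna_rpkm"]
        gamma = t["gamma_nascent"] if fraction == "nascent" else t["gamma_mrna"]
        feat_len = g.length if fraction == "nascent" else g.exonic_length
        factor = _condition_factor(t["class_label"], t["true_fold"], condition, att)
        mu = rpkm * gamma * factor * (feat_len / 1000.0) * (cfg.depth / 1e6)
        c = int(rng.poisson(mu)) if mu > 0 else 0
        if c == 0:
            continue
        if fraction == "nascent":
            starts = rng.integers(g.start, g.end - rl + 1, size=c)
        else:
            sizes = np.array([max(0, e - s - rl + 1) for s, e in g.exons])
            if sizes.sum() == 0:
                continue
            which = rng.choice(len(g.exons), size=c, p=sizes / sizes.sum())
            offs = rng.integers(0, sizes[np.clip(which, 0, None)])
            starts = np.array([g.exons[w][0] for w in which]) + offs
        all_starts.append(starts)
        all_names.append((t["gene_id"], c))
        all_hits.append(np.ones(c, dtype=int))

    # spike-ins
    rrna_genes = [g for g in genes if g.biotype == "rRNA"]
    n_rrna = rng.binomial(cfg.depth, cfg.rrna_fraction) if rrna_genes else 0
    if n_rrna:
        which = rng.integers(0, len(rrna_genes), size=n_rrna)
        starts = np.array(
            [
                rng.integers(rrna_genes[w].start, rrna_genes[w].end - rl + 1)
                for w in which
            ]
        )
        all_starts.append(starts)
        all_names.append(("rRNA_spike", n_rrna))
        all_hits.append(np.ones(n_rrna, dtype=int))
    n_low = rng.binomial(cfg.depth, cfg.lowcomplexity_fraction)
    n_multi = rng.binomial(cfg.depth, cfg.multihit_fraction)
    for label, c in (("lowcomplexity", n_low), ("multihit", n_multi)):
        if c == 0:
            continue
        starts = rng.integers(0, max(1, len(genome) - rl), size=c)
        all_starts.append(starts)
        all_names.append((label, c))
        hits = (
            rng.integers(2, 20, size=c) if label == "multihit" else np.ones(c, dtype=int)
        )
        all_hits.append(hits)

    if not all_starts:
        return pd.DataFrame(columns=["chrom", "start", "end", "name", "n_genome_hits", "strand", "seq"])
    starts = np.concatenate(all_starts)
    hits = np.concatenate(all_hits)
    names = np.empty(len(starts), dtype=object)
    pos = 0
    prefix = f"{fraction[0]}{condition[0]}"
    for label, c in all_names:
        for j in range(c):
            names[pos + j] = f"{prefix}:{label}:{j}"
        pos += c
    strands = rng.choice(np.array(["+", "-"], dtype=object), size=len(starts))

    mat = _extract_seqs(genome, starts, rl)
    minus = strands == "-"
    if minus.any():
        mat[minus] = _COMP_TABLE[mat[minus]][:, ::-1]
    # overwrite spiked low-complexity reads with tandem repeats
    lc_offset = 0
    for label, c in all_names:
        if label == "lowcomplexity":
            units = rng.integers(0, 4, size=(c, 2))
            k = rng.integers(1, 3, size=c)  # 1- or 2-mer unit
            for j in range(c):
                unit = _BASE_BYTES[units[j, : k[j]]]
                mat[lc_offset + j] = np.resize(unit, rl)
        lc_offset += c

    df = pd.DataFrame(
        {
            "chrom": cfg.chrom,
            "start": starts,
            "end": starts + rl,
            "name": names,
            "n_genome_hits": hits,
            "strand": strands,
            "seq": _mat_to_strings(mat),
        }
    )
    df = df.sort_values(["start", "name"], kind="stable").reset_index(drop=True)
    return df


# ---------------------------------------------------------------------------
# peaks


def simulate_peak_replicates(cfg: TruthConfig, truth: pd.DataFrame, genes: list) -> tuple:
    """Two narrowPeak replicates: jittered true peaks plus private noise.

    True (planted) peaks appear in both replicates with Gaussian
    positional jitter and -log10 p drawn above the significance cutoff;
    noise peaks are replicate-specific with mixed significance.
    """
    planted = truth[truth["pu1_site"]] if len(truth) else truth
    # per-site width/strength come from a stream shared by both
    # replicates, so with zero jitter the replicate files coincide
    shared = _rng(cfg.seed, "peaks:shared")
    site_width = shared.integers(*cfg.peak_width_range, size=len(planted))
    site_signal = shared.uniform(5, 50, size=len(planted))
    site_nlp = shared.uniform(6, 30, size=len(planted))
    out = []
    for rep in ("rep1", "rep2"):
        rng = _rng(cfg.seed, f"peaks:{rep}")
        rows = []
        for j, (_, t) in enumerate(planted.iterrows()):
            center = int(t["pu1_pos"] + round(rng.normal(0.0, cfg.peak_jitter_sd)))
            width = int(site_width[j])
            start = max(0, center - width // 2)
            rows.append(
                {
                    "chrom": cfg.chrom,
                    "start": start,
                    "end": start + width,
                    "name": f"{rep}_{t['gene_id']}",
                    "score": 1000,
                    "strand": ".",
                    "signal": float(site_signal[j]),
                    "neg_log10_p": float(site_nlp[j]),
                    "neg_log10_q": -1.0,
                    "summit": center - start,
                }
            )
        n_noise = cfg.noise_peaks_per_replicate
        for j in range(n_noise):
            width = int(rng.integers(*cfg.peak_width_range))
            start = int(rng.integers(0, max(1, cfg.genome_length - width)))
            rows.append(
                {
                    "chrom": cfg.chrom,
                    "start": start,
                    "end": start + width,
                    "name": f"{rep}_noise{j}",
                    "score": 200,
                    "strand": ".",
                    "signal": float(rng.uniform(1, 10)),
                    "neg_log10_p": float(rng.uniform(2, 12)),
                    "neg_log10_q": -1.0,
                    "summit": width // 2,
                }
            )
        df = pd.DataFrame(
            rows,
            columns=peaks_mod.NARROWPEAK_COLUMNS,
        )
        df["p_value"] = np.power(10.0, -df["neg_log10_p"])
        df = df.sort_values(["start", "name"], kind="stable").reset_index(drop=True)
        out.append(df)
    return tuple(out)


# ---------------------------------------------------------------------------
# promoter sequences + motifs


def promoter_sequences(
    genes: list,
    genome: np.ndarray,
    upstream: int = 450,
    downstream: int = 50,
    chrom: str | None = None,
) -> dict:
    """Promoter-sense window sequences (default -450..+50 of the TSS).

    Windows extending past a contig edge are padded with N so every
    sequence has length upstream + downstream.
    """
    out = {}
    total = upstream + downstream
    for g in genes:
        if chrom is not None and g.chrom != chrom:
            continue
        if g.strand == "+":
            lo, hi = g.tss - upstream, g.tss + downstream
        else:
            lo, hi = g.tss - downstream + 1, g.tss + upstream + 1
        pad_left = max(0, -lo)
        pad_right = max(0, hi - len(genome))
        seq = genome[max(0, lo) : min(len(genome), hi)].tobytes().decode()
        seq = "N" * pad_left + seq + "N" * pad_right
        if g.strand == "-":
            seq = reverse_complement(seq)
        assert len(seq) == total
        out[g.gene_id] = seq
    return out


def plant_motifs(
    cfg: TruthConfig,
    truth: pd.DataFrame,
    promoters: dict,
    motif: MotifMatrix,
) -> tuple:
    """Insert sampled motif instances into promoters flagged in the truth.

    For each gene with ``motif_planted``, one instance sampled from the
    PWM replaces the sequence at a uniform position, on a random strand.
    Returns ``(new_promoters, placements)``.
    """
    rng = _rng(cfg.seed, f"motifs:{motif.motif_id}")
    L = motif.length
    new = dict(promoters)
    placements = []
    flagged = set(truth.loc[truth["motif_planted"], "gene_id"]) if len(truth) else set()
    for gid, seq in promoters.items():
        if gid not in flagged:
            continue
        if L >= len(seq):
            raise ValueError("motif longer than promoter sequence")
        site = motif.sample_site(rng)
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            site = reverse_complement(site)
        pos = int(rng.integers(0, len(seq) - L + 1))
        new[gid] = seq[:pos] + site + seq[pos + L :]
        placements.append(
            {"gene_id": gid, "offset": pos, "strand": strand, "site": site}
        )
    return new, pd.DataFrame(placements, columns=["gene_id", "offset", "strand", "site"])


# ---------------------------------------------------------------------------
# one-shot generation


def write_promoter_fasta(promoters: dict, path: str) -> None:
    with open(path, "w") as fh:
        for gid, seq in promoters.items():
            fh.write(f">{gid}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


def simulate_all(cfg: TruthConfig, outdir: str, motif: MotifMatrix | None = None) -> dict:
    """Generate and write every pipeline input plus the ground truth.

    Returns a dict of output paths. The planted motif defaults to the
    first matrix of the packaged synthetic motif set.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if motif is None:
        from .data import packaged_motifs

        motif = packaged_motifs()[0]
    genes, genome = generate_annotation(cfg)
    truth = generate_truth(cfg, genes)
    paths = {}

    paths["config"] = outdir / "config.yaml"
    cfg.to_yaml(paths["config"])
    paths["genome"] = outdir / "genome.fa"
    write_genome_fasta(genome, paths["genome"], cfg.chrom)
    paths["genes_gff3"] = outdir / "genes.gff3"
    write_gff3(genes, paths["genes_gff3"])
    paths["genes_bed12"] = outdir / "genes.bed"
    write_bed12(genes, paths["genes_bed12"])
    paths["truth"] = outdir / "truth.tsv"
    truth.to_csv(paths["truth"], sep="\t", index=False, float_format="%.8g")

    probes = simulate_probe_table(cfg, truth, genes)
    paths["probes"] = outdir / "probes.tsv"
    probes.to_csv(paths["probes"], sep="\t", index=False, float_format="%.6f")

    from .nascent import write_read_table

    for fraction in ("nascent", "mRNA"):
        for condition in ("untreated", "LPS1h"):
            reads = simulate_reads(cfg, truth, genes, genome, fraction, condition)
            key = f"reads_{fraction.lower()}_{condition.lower()}"
            paths[key] = outdir / f"{key}.bed"
            write_read_table(reads, paths[key])

    rep1, rep2 = simulate_peak_replicates(cfg, truth, genes)
    for rep, df in (("rep1", rep1), ("rep2", rep2)):
        paths[f"peaks_{rep}"] = outdir / f"peaks_{rep}.narrowPeak"
        peaks_mod.write_narrowpeak(df, paths[f"peaks_{rep}"])

    promoters = promoter_sequences(
        genes, genome, cfg.motif_window_upstream, cfg.motif_window_downstream
    )
    promoters, placements = plant_motifs(cfg, truth, promoters, motif)
    paths["promoters"] = outdir / "promoters.fa"
    write_promoter_fasta(promoters, paths["promoters"])
    paths["motif_placements"] = outdir / "motif_placements.tsv"
    placements.to_csv(paths["motif_placements"], sep="\t", index=False)
    return {k: str(v) for k, v in paths.items()}
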