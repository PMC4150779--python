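"""Read filtering, gene assignment, RPKM and fold-change classification.

Two sequencing fractions are quantified per condition (untreated immature
cells vs 1 h LPS):

* ``nascent`` -- chromatin-bound primary transcripts; reads map across
  introns and exons, so a read counts for a gene when fully contained in
  the gene span. Abundance tracks instantaneous transcription rate.
* ``mRNA`` -- steady-state messenger RNA; reads must be fully contained
  in a single exon.

Expression is reported as RPKM (reads per kb of feature length per
million assigned reads; feature length = span for nascent, exonic length
for mRNA). Genes below 1 RPKM in both conditions are ``not_expressed``;
otherwise the (pseudocount-stabilized) RPKM ratio classifies them as
induced / silenced / unchanged at strict >2, >3 and >5-fold tiers.
"""

from __future__ import annotations

import warnings
from typing import Iterable

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .annotation import GeneModel

__all__ = [
    "filter_reads",
    "assign_reads",
    "compute_rpkm",
    "classify_change",
    "expression_table",
    "nascent_qc",
    "read_read_table",
    "write_read_table",
]

READ_COLUMNS = ["chrom", "start", "end", "name", "n_genome_hits", "strand", "seq"]
DEFAULT_BASELINE_RPKM = 1.0
DEFAULT_EPSILON = 0.1
DEFAULT_TIERS = (2.0, 3.0, 5.0)
REPEAT_FRACTION = 0.9

_ACGT = frozenset(b"ACGT")


def read_read_table(path: str) -> pd.DataFrame:
    """Read a BED6-like read table (name=read id, score=n_genome_hits).

    A 7th column, when present, carries the read sequence.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    ncol = df.shape[1]
    df.columns = READ_COLUMNS[:ncol]
    return df


def write_read_table(reads: pd.DataFrame, path: str) -> None:
    cols = [c for c in READ_COLUMNS if c in reads.columns]
    reads[cols].to_csv(path, sep="\t", header=False, index=False)


def _longest_true_run(mask: np.ndarray) -> np.ndarray:
    if mask.shape[1] == 0:
        return np.zeros(mask.shape[0], dtype=np.int32)
    c = np.cumsum(mask, axis=1, dtype=np.int32)
    anchored = np.where(mask, 0, c)
    run = c - np.maximum.accumulate(anchored, axis=1)
    return run.max(axis=1)


def _longest_repeat_run(seq_mat: np.ndarray, period: int) -> np.ndarray:
    """Longest tandem-repeat run of any ``period``-mer unit per row.

    A substring is a tandem repeat of a k-mer iff every base equals the
    base k positions earlier; run lengths come from that shifted-equality
    mask (a mononucleotide run therefore also counts at period 2).
    """
    if seq_mat.shape[1] <= period:
        return np.full(seq_mat.shape[0], seq_mat.shape[1], dtype=np.int32)
    return _longest_true_run(seq_mat[:, period:] == seq_mat[:, :-period]) + period


def _to_matrix(seqs: np.ndarray, L: int) -> np.ndarray:
    """Uppercase byte matrix from equal-length sequence strings."""
    if L == 0:
        return np.zeros((len(seqs), 0), dtype=np.uint8)
    mat = seqs.astype(f"S{L}").view(np.uint8).reshape(len(seqs), L).copy()
    lower = (mat >= 97) & (mat <= 122)
    if lower.any():
        mat[lower] -= 32
    return mat


def filter_reads(
    reads: pd.DataFrame,
    genes: Iterable[GeneModel] = (),
    repeat_fraction: float = REPEAT_FRACTION,
) -> tuple:
    """Drop low-complexity, multi-hit, invalid and rRNA-locus reads.

    Rejection reasons (first that applies, per read):

    * ``invalid_alphabet`` -- sequence contains non-ACGT characters
    * ``mono_repeat`` / ``di_repeat`` -- >= ``repeat_fraction`` of the
      read is a tandem repeat of a 1- or 2-mer
    * ``multi_hit`` -- n_genome_hits > 1 (not an exact unique match)
    * ``rrna`` -- overlaps an annotated rRNA gene by >= 1 bp

    Returns ``(kept, log)`` where ``log`` counts rejections per reason.
    Sequence-based checks are skipped with a warning when the table has
    no ``seq`` column (pre-counted / position-only mode).
    """
    n = len(reads)
    reason = np.full(n, "", dtype=object)

    if "seq" in reads.columns and n > 0:
        seqs = reads["seq"].to_numpy()
        lengths = np.fromiter((len(s) for s in seqs), dtype=int, count=n)
        for L in np.unique(lengths):
            idx = np.flatnonzero(lengths == L)
            mat = _to_matrix(seqs[idx], int(L))
            valid = np.isin(mat, np.frombuffer(b"ACGT", dtype=np.uint8)).all(axis=1)
            cut = repeat_fraction * L
            # a mononucleotide run is also period-2, so the di-run flags
            # both; the mono-run is computed only on flagged reads to
            # pick the reason
            is_rep = _longest_repeat_run(mat, 2) >= cut
            flagged = np.flatnonzero(valid & is_rep)
            if len(flagged):
                is_mono = _longest_repeat_run(mat[flagged], 1) >= cut
                reason[idx[flagged[is_mono]]] = "mono_repeat"
                reason[idx[flagged[~is_mono]]] = "di_repeat"
            reason[idx[~valid]] = "invalid_alphabet"
    elif "seq" not in reads.columns:
        warnings.warn(
            "read table has no sequence column; low-complexity filter skipped",
            stacklevel=2,
        )

    free = reason == ""
    if "n_genome_hits" in reads.columns:
        multi = reads["n_genome_hits"].to_numpy() > 1
        reason[free & multi] = "multi_hit"
        free = reason == ""

    rrna = [g for g in genes if g.biotype == "rRNA"]
    if rrna and n > 0:
        starts = reads["start"].to_numpy()
        ends = reads["end"].to_numpy()
        chroms = reads["chrom"].to_numpy()
        hit = np.zeros(n, dtype=bool)
        for g in rrna:
            hit |= (chroms == g.chrom) & (starts < g.end) & (ends > g.start)
        reason[free & hit] = "rrna"

    kept = reads[reason == ""].reset_index(drop=True)
    log = {"input": n, "kept": len(kept)}
    for r in ("invalid_alphabet", "mono_repeat", "di_repeat", "multi_hit", "rrna"):
        log[r] = int((reason == r).sum())
    return kept, log


def _genes_overlap(genes_sorted) -> bool:
    prev_end = -1
    for g in genes_sorted:
        if g.start < prev_end:
            return True
        prev_end = max(prev_end, g.end)
    return False


def assign_reads(
    reads: pd.DataFrame, genes: list, fraction: str = "nascent"
) -> tuple:
    """Count reads per gene by full containment.

    ``nascent`` mode counts a read when fully contained in the gene span
    (introns + exons); ``mRNA`` mode requires full containment in a
    single exon. A read contained in more than one gene is ambiguous and
    counts for none. Returns ``(counts, info)``: counts is a DataFrame
    indexed by gene_id with ``count``, ``exonic`` and ``intronic``
    columns (intronic = contained in span but not in a single exon).
    """
    if fraction not in ("nascent", "mRNA"):
        raise ValueError(f"unknown fraction {fraction!r}")
    n = len(reads)
    gene_idx = np.full(n, -1, dtype=int)
    ambiguous = np.zeros(n, dtype=bool)
    starts = reads["start"].to_numpy() if n else np.empty(0, dtype=int)
    ends = reads["end"].to_numpy() if n else np.empty(0, dtype=int)
    chroms = reads["chrom"].to_numpy() if n else np.empty(0, dtype=object)

    global_pos = {g.gene_id: k for k, g in enumerate(genes)}
    for chrom in pd.unique(chroms):
        ridx = np.flatnonzero(chroms == chrom)
        gs = sorted(
            (g for g in genes if g.chrom == chrom), key=lambda g: (g.start, g.end)
        )
        if not gs:
            continue
        to_global = np.array([global_pos[g.gene_id] for g in gs])
        if not _genes_overlap(gs):
            g_start = np.array([g.start for g in gs])
            g_end = np.array([g.end for g in gs])
            pos = np.searchsorted(g_start, starts[ridx], side="right") - 1
            ok = (pos >= 0) & (ends[ridx] <= g_end[np.clip(pos, 0, None)])
            gene_idx[ridx[ok]] = to_global[pos[ok]]
        else:
            tree = IntervalTree()
            for i, g in enumerate(gs):
                tree[g.start : g.end] = i
            for r in ridx:
                hits = [
                    iv.data
                    for iv in tree[starts[r]]
                    if starts[r] >= iv.begin and ends[r] <= iv.end
                ]
                if len(hits) == 1:
                    gene_idx[r] = to_global[hits[0]]
                elif len(hits) > 1:
                    ambiguous[r] = True

    counts = pd.DataFrame(
        0,
        index=pd.Index([g.gene_id for g in genes], name="gene_id"),
        columns=["count", "exonic", "intronic"],
        dtype=int,
    )
    assigned = np.flatnonzero(gene_idx >= 0)
    for gi in np.unique(gene_idx[assigned]):
        g = genes[gi]
        rsel = assigned[gene_idx[assigned] == gi]
        ex_start = np.array([s for s, _ in g.exons])
        ex_end = np.array([e for _, e in g.exons])
        j = np.searchsorted(ex_start, starts[rsel], side="right") - 1
        in_exon = (j >= 0) & (ends[rsel] <= ex_end[np.clip(j, 0, None)])
        n_ex = int(in_exon.sum())
        if fraction == "mRNA":
            counts.loc[g.gene_id] = [n_ex, n_ex, 0]
        else:
            counts.loc[g.gene_id] = [len(rsel), n_ex, len(rsel) - n_ex]
    info = {
        "n_reads": n,
        "n_assigned": int(counts["count"].sum()),
        "n_ambiguous": int(ambiguous.sum()),
        "n_unassigned": int(n - (gene_idx >= 0).sum() - ambiguous.sum()),
    }
    return counts, info


def compute_rpkm(
    counts: np.ndarray, lengths_bp: np.ndarray, library_size: int
) -> np.ndarray:
    """RPKM = count / (length_kb * library_size_millions)."""
    if library_size <= 0:
        raise ValueError("library size must be positive")
    counts = np.asarray(counts, dtype=float)
    lengths_kb = np.asarray(lengths_bp, dtype=float) / 1000.0
    return counts / (lengths_kb * (library_size / 1e6))


def classify_change(
    rpkm_untreated: np.ndarray,
    rpkm_lps: np.ndarray,
    baseline: float = DEFAULT_BASELINE_RPKM,
    tiers: tuple = DEFAULT_TIERS,
    epsilon: float = DEFAULT_EPSILON,
) -> dict:
    """Label genes per fold tier with strict inequalities.

    ``not_expressed`` when both conditions are below ``baseline`` RPKM;
    otherwise r = (rpkm_lps + eps) / (rpkm_untreated + eps) and a gene is
    induced@k if r > k, silenced@k if r < 1/k, else unchanged@k. Labels
    nest: silenced@5 implies silenced@3 implies silenced@2. Returns
    {"ratio": r, "fold": signed fold, k: label array per tier}.
    """
    ru = np.asarray(rpkm_untreated, dtype=float)
    rl = np.asarray(rpkm_lps, dtype=float)
    not_expr = (ru < baseline) & (rl < baseline)
    r = (rl + epsilon) / (ru + epsilon)
    with np.errstate(divide="ignore"):
        fold = np.where(r >= 1, r, -1.0 / r)
    out = {"ratio": r, "fold": fold, "not_expressed": not_expr}
    for k in tiers:
        lab = np.full(len(r), "unchanged", dtype=object)
        lab[r > k] = "induced"
        lab[r < 1.0 / k] = "silenced"
        lab[not_expr] = "not_expressed"
        out[k] = lab
    return out


def expression_table(
    counts_untreated: pd.DataFrame,
    counts_lps: pd.DataFrame,
    genes: list,
    fraction: str,
    baseline: float = DEFAULT_BASELINE_RPKM,
    tiers: tuple = DEFAULT_TIERS,
    epsilon: float = DEFAULT_EPSILON,
    library_sizes: tuple | None = None,
) -> pd.DataFrame:
    """Per-gene expression records for one fraction across both conditions.

    Library size defaults to the total assigned (genic) reads of each
    library; pass ``library_sizes=(n_untreated, n_lps)`` to use totals
    from all mapped reads instead.
    """
    gene_ids = [g.gene_id for g in genes]
    lengths = np.array(
        [g.length if fraction == "nascent" else g.exonic_length for g in genes]
    )
    cu = counts_untreated["count"].reindex(gene_ids).fillna(0).to_numpy()
    cl = counts_lps["count"].reindex(gene_ids).fillna(0).to_numpy()
    if library_sizes is None:
        library_sizes = (int(cu.sum()), int(cl.sum()))
    ru = compute_rpkm(cu, lengths, library_sizes[0])
    rl = compute_rpkm(cl, lengths, library_sizes[1])
    cls = classify_change(ru, rl, baseline=baseline, tiers=tiers, epsilon=epsilon)
    df = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "fraction": fraction,
            "count_untreated": cu.astype(int),
            "count_LPS1h": cl.astype(int),
            "rpkm_untreated": ru,
            "rpkm_LPS1h": rl,
            "fold": cls["fold"],
            "not_expressed": cls["not_expressed"],
        }
    )
    for k in tiers:
        df[f"label_{k:g}"] = cls[k]
    return df


def nascent_qc(
    nascent_counts: pd.DataFrame,
    mrna_counts: pd.DataFrame,
    nascent_log: dict | None = None,
    rrna_depletion_target: float = 0.95,
) -> dict:
    """Library-level sanity checks for the fraction separation.

    Reports the intronic fraction of genic reads per fraction (the
    nascent library should contain intronic signal, the mRNA library by
    construction none), the pre-filter rRNA read fraction, and FAILs
    when the mRNA library looks more intronic than the nascent one.
    """
    out = {}
    for label, c in (("nascent", nascent_counts), ("mRNA", mrna_counts)):
        tot = c["count"].sum()
        out[f"intronic_fraction_{label}"] = (
            float(c["intronic"].sum() / tot) if tot else float("nan")
        )
    if nascent_log is not None and nascent_log.get("input"):
        frac = nascent_log.get("rrna", 0) / nascent_log["input"]
        out["rrna_fraction"] = float(frac)
        out["rrna_depletion_pass"] = bool(1.0 - frac >= rrna_depletion_target)
    ok = not (
        out["intronic_fraction_mRNA"] > out["intronic_fraction_nascent"]
    )
    out["fraction_separation"] = "PASS" if ok else "FAIL"
    return out
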