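"""ChIP-seq peak filtering and TSS-centered occupancy profiles.

Peak calls arrive as ENCODE narrowPeak. Peaks are kept when significant
(p < 1e-5, strict) and reproducible (overlapping a peak from the second
biological replicate by at least ``min_overlap_nt`` bases). Occupancy
profiles report, per gene set, the percent of genes with at least one
peak within windows of increasing size centered on the TSS, signed
strand-aware distance bins, and a per-gene binary heatmap over +/-2 kb;
the full gene universe is always profiled alongside as the baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from statsmodels.stats.proportion import proportions_ztest

from .annotation import GeneModel, GenomicWindow

__all__ = [
    "read_narrowpeak",
    "write_narrowpeak",
    "filter_significant",
    "reproducible_peaks",
    "occupancy_profile",
    "profile_gene_sets",
    "compare_profiles",
    "OccupancyProfile",
]

NARROWPEAK_COLUMNS = [
    "chrom", "start", "end", "name", "score", "strand",
    "signal", "neg_log10_p", "neg_log10_q", "summit",
]
DEFAULT_ALPHA = 1e-5
DEFAULT_WINDOW_SIZES = (500, 1000, 2000, 4000)
HEATMAP_HALF_WINDOW = 2000


def read_narrowpeak(path: str, replicate_id: str | None = None) -> pd.DataFrame:
    """Read a 10-column narrowPeak file; adds a linear ``p_value`` column.

    narrowPeak stores -log10(p); a sentinel of -1 (not computed) maps to
    NaN and will be rejected by :func:`filter_significant`.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    if df.shape[1] < 10:
        raise ValueError(f"{path}: narrowPeak requires 10 columns, got {df.shape[1]}")
    df = df.iloc[:, :10]
    df.columns = NARROWPEAK_COLUMNS
    neg = df["neg_log10_p"].to_numpy(dtype=float)
    df["p_value"] = np.where(neg < 0, np.nan, np.power(10.0, -neg))
    if replicate_id is not None:
        df["replicate"] = replicate_id
    return df


def write_narrowpeak(peaks: pd.DataFrame, path: str) -> None:
    out = peaks.copy()
    if "neg_log10_p" not in out.columns and "p_value" in out.columns:
        out["neg_log10_p"] = -np.log10(out["p_value"])
    for col, default in (
        ("name", "."), ("score", 0), ("strand", "."), ("signal", 0.0),
        ("neg_log10_q", -1.0), ("summit", -1),
    ):
        if col not in out.columns:
            out[col] = default
    out[NARROWPEAK_COLUMNS].to_csv(
        path, sep="\t", header=False, index=False, float_format="%.6g"
    )


def filter_significant(peaks: pd.DataFrame, alpha: float = DEFAULT_ALPHA) -> pd.DataFrame:
    """Retain peaks with p_value strictly below ``alpha``."""
    if "p_value" not in peaks.columns:
        raise ValueError("peaks lack a p_value column")
    p = peaks["p_value"].to_numpy(dtype=float)
    if np.isnan(p).any():
        raise ValueError("missing p-values in peak table")
    return peaks[p < alpha].reset_index(drop=True)


def reproducible_peaks(
    rep_a: pd.DataFrame, rep_b: pd.DataFrame, min_overlap_nt: int = 1
) -> pd.DataFrame:
    """Peaks of replicate A supported by replicate B.

    A peak is retained iff some replicate-B peak overlaps it by at least
    ``min_overlap_nt`` bases; retained peaks carry the union interval of
    the A peak with all of its overlapping B peaks (summit kept from A).
    """
    trees = {}
    for chrom, sub in rep_b.groupby("chrom", sort=False):
        t = IntervalTree()
        for s, e in zip(sub["start"], sub["end"]):
            t[s:e] = None
        trees[chrom] = t
    rows = []
    for _, pk in rep_a.iterrows():
        t = trees.get(pk["chrom"])
        if t is None:
            continue
        mates = [
            iv
            for iv in t.overlap(pk["start"], pk["end"])
            if min(iv.end, pk["end"]) - max(iv.begin, pk["start"]) >= min_overlap_nt
        ]
        if not mates:
            continue
        row = pk.copy()
        new_start = min([pk["start"]] + [iv.begin for iv in mates])
        if pk["summit"] >= 0:
            row["summit"] = int(pk["summit"] + (pk["start"] - new_start))
        row["start"] = new_start
        row["end"] = max([pk["end"]] + [iv.end for iv in mates])
        rows.append(row)
    if not rows:
        return rep_a.iloc[0:0].copy()
    return pd.DataFrame(rows).reset_index(drop=True)


def peak_positions(peaks: pd.DataFrame) -> pd.DataFrame:
    """Reference position per peak: summit when present, else midpoint."""
    start = peaks["start"].to_numpy()
    end = peaks["end"].to_numpy()
    if "summit" in peaks.columns:
        summit = peaks["summit"].to_numpy()
        pos = np.where(summit >= 0, start + summit, (start + end) // 2)
    else:
        pos = (start + end) // 2
    return pd.DataFrame({"chrom": peaks["chrom"].to_numpy(), "pos": pos})


@dataclass
class OccupancyProfile:
    """TSS-centered peak occupancy for one gene set."""

    label: str
    n_genes: int
    window_sizes: tuple
    n_with_peak: np.ndarray  # per window size
    bin_edges: np.ndarray  # signed bp, strand-aware
    n_per_bin: np.ndarray  # genes with >=1 peak in each distance bin
    heatmap: pd.DataFrame = field(repr=False, default=None)

    @property
    def percent_with_peak(self) -> np.ndarray:
        return 100.0 * self.n_with_peak / self.n_genes

    @property
    def percent_per_bin(self) -> np.ndarray:
        return 100.0 * self.n_per_bin / self.n_genes


def occupancy_profile(
    peaks: pd.DataFrame,
    genes: list,
    gene_set: list | None = None,
    label: str = "set",
    window_sizes: tuple = DEFAULT_WINDOW_SIZES,
    bin_bp: int = 200,
    half_window: int = HEATMAP_HALF_WINDOW,
) -> OccupancyProfile:
    """Profile peak occupancy around the TSSs of a gene set.

    For window size w, a gene counts as occupied when at least one peak
    position lies within w/2 bp of its TSS (inclusive). Distances are
    signed strand-aware (upstream negative). ``gene_set`` is a list of
    gene ids and must be a subset of ``genes``; None means all genes.
    """
    by_id = {g.gene_id: g for g in genes}
    if gene_set is None:
        members = list(genes)
    else:
        if len(gene_set) == 0:
            raise ValueError("empty gene set")
        missing = [gid for gid in gene_set if gid not in by_id]
        if missing:
            raise ValueError(f"gene set not a subset of annotation: {missing[:3]}")
        members = [by_id[gid] for gid in gene_set]

    pos_df = peak_positions(peaks)
    by_chrom = {
        chrom: np.sort(sub["pos"].to_numpy())
        for chrom, sub in pos_df.groupby("chrom", sort=False)
    }
    window_sizes = tuple(sorted(window_sizes))
    n_with = np.zeros(len(window_sizes), dtype=int)
    edges = np.arange(-half_window, half_window + bin_bp, bin_bp)
    n_per_bin = np.zeros(len(edges) - 1, dtype=int)
    heat = np.zeros((len(members), len(edges) - 1), dtype=np.int8)
    empty = np.empty(0, dtype=int)
    for i, g in enumerate(members):
        pos = by_chrom.get(g.chrom, empty)
        for j, w in enumerate(window_sizes):
            half = w // 2
            lo = np.searchsorted(pos, g.tss - half, side="left")
            hi = np.searchsorted(pos, g.tss + half, side="right")
            if hi > lo:
                n_with[j] += 1
        near_lo = np.searchsorted(pos, g.tss - half_window, side="left")
        near_hi = np.searchsorted(pos, g.tss + half_window, side="right")
        near = pos[near_lo:near_hi]
        if len(near):
            d = near - g.tss if g.strand == "+" else g.tss - near
            binned = np.clip(np.searchsorted(edges, d, side="right") - 1, 0, len(edges) - 2)
            heat[i, np.unique(binned)] = 1
    n_per_bin = heat.sum(axis=0)
    hm = pd.DataFrame(
        heat, index=[g.gene_id for g in members], columns=edges[:-1].astype(int)
    )
    prof = OccupancyProfile(
        label=label,
        n_genes=len(members),
        window_sizes=window_sizes,
        n_with_peak=n_with,
        bin_edges=edges,
        n_per_bin=n_per_bin,
        heatmap=hm,
    )
    pct = prof.percent_with_peak
    assert np.all(np.diff(pct) >= 0), "occupancy must be monotone in window size"
    return prof


def profile_gene_sets(
    peaks: pd.DataFrame,
    genes: list,
    gene_sets: dict,
    baseline_label: str = "all_genes",
    **kwargs,
) -> dict:
    """Profile each gene set plus the all-genes baseline."""
    out = {
        baseline_label: occupancy_profile(
            peaks, genes, None, label=baseline_label, **kwargs
        )
    }
    for label, ids in gene_sets.items():
        out[label] = occupancy_profile(peaks, genes, list(ids), label=label, **kwargs)
    return out


def compare_profiles(
    profiles: dict, baseline_label: str = "all_genes"
) -> pd.DataFrame:
    """Set-vs-baseline occupancy ratios per window size.

    The two-proportion z-test p-value is descriptive plumbing, not a
    statistic from the underlying study.
    """
    base = profiles[baseline_label]
    rows = []
    for label, prof in profiles.items():
        if label == baseline_label:
            continue
        for j, w in enumerate(prof.window_sizes):
            k_set, k_base = int(prof.n_with_peak[j]), int(base.n_with_peak[j])
            pct_set = 100.0 * k_set / prof.n_genes
            pct_base = 100.0 * k_base / base.n_genes
            if pct_base == 0:
                ratio, p = float("nan"), float("nan")
                note = "baseline occupancy is 0; ratio undefined"
            else:
                ratio = pct_set / pct_base
                note = ""
                if k_set in (0, prof.n_genes) and k_base in (0, base.n_genes):
                    p = 1.0
                else:
                    _, p = proportions_ztest(
                        [k_set, k_base], [prof.n_genes, base.n_genes]
                    )
            rows.append(
                {
                    "gene_set": label,
                    "window_bp": w,
                    "percent_set": pct_set,
                    "percent_baseline": pct_base,
                    "ratio": ratio,
                    "p_value": p,
                    "note": note,
                }
            )
    return pd.DataFrame(rows)
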