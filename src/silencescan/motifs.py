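"""PWM promoter scanning and gene-set enrichment z-statistics.

Each promoter window (-450..+50 around the TSS, promoter-sense strand)
is scored with each position weight matrix by the best log-odds hit over
all positions and both strands, min-max normalized to [0, 1] using the
motif's attainable extremes:

    score = (s_best - s_min) / (s_max - s_min)

Gene-set enrichment against the all-promoters background uses

    z = (mean_set - mean_bg) / (sd_bg / sqrt(n_set)),  p = upper tail

with motifs called significantly over-represented at p < 1e-3, the
convention of Pscan-style promoter analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import motifs as bio_motifs
from numpy.lib.stride_tricks import sliding_window_view
from scipy.stats import norm

__all__ = [
    "MotifMatrix",
    "read_jaspar",
    "best_hit_score",
    "score_promoters",
    "set_enrichment",
    "enrichment_heatmap",
]

BASES = "ACGT"
_BASE_INDEX = {ord(b): i for i, b in enumerate(BASES)}
SIGNIFICANCE_ALPHA = 1e-3


@dataclass
class MotifMatrix:
    """A JASPAR-style count matrix with scoring machinery.

    ``counts`` has rows A, C, G, T. The pseudocount added to each cell is
    ``pseudocount_fraction`` x column sum, split by the background base
    frequencies (uniform by default).
    """

    motif_id: str
    counts: np.ndarray
    name: str = ""
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    pseudocount_fraction: float = 0.01

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape[0] != 4 or self.counts.shape[1] < 4:
            raise ValueError(
                f"motif {self.motif_id}: counts must be 4 x L with L >= 4"
            )
        if (self.counts.sum(axis=0) <= 0).any():
            raise ValueError(f"motif {self.motif_id}: zero column sum")
        self.background = np.asarray(self.background, dtype=float)
        self.background = self.background / self.background.sum()

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    def log_odds(self) -> np.ndarray:
        """4 x L log2 odds matrix after background-weighted pseudocounts."""
        colsum = self.counts.sum(axis=0)
        pc = self.pseudocount_fraction * colsum
        p = (self.counts + pc * self.background[:, None]) / (colsum + pc)
        return np.log2(p / self.background[:, None])

    def score_range(self) -> tuple:
        lo = self.log_odds()
        return float(lo.min(axis=0).sum()), float(lo.max(axis=0).sum())

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.counts.argmax(axis=0))

    def sample_site(self, rng: np.random.Generator) -> str:
        """Draw one site with per-column base probabilities ~ counts."""
        p = self.counts / self.counts.sum(axis=0)
        return "".join(
            BASES[rng.choice(4, p=p[:, j])] for j in range(self.length)
        )


def read_jaspar(path: str) -> list:
    """Read JASPAR-format count matrices (via Biopython)."""
    with open(path) as fh:
        parsed = bio_motifs.parse(fh, "jaspar")
    out = []
    for m in parsed:
        counts = np.array([m.counts[b] for b in BASES], dtype=float)
        out.append(
            MotifMatrix(
                motif_id=m.matrix_id or m.name, counts=counts, name=m.name or ""
            )
        )
    return out


_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def reverse_complement(seq: str) -> str:
    return "".join(_COMP.get(b, "N") for b in reversed(seq.upper()))


def _encode(seq: str) -> np.ndarray:
    """ACGT -> 0..3, anything else -> 4 (scored at background expectation)."""
    raw = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    enc = np.full(len(raw), 4, dtype=np.int8)
    for byte, i in _BASE_INDEX.items():
        enc[raw == byte] = i
    return enc


def best_hit_score(motif: MotifMatrix, seq: str) -> float:
    """Normalized best-hit score of a motif over both strands of a sequence.

    Ambiguous bases (N) contribute the background-expected log-odds of
    their column. Raises when the sequence is shorter than the motif.
    """
    L = motif.length
    if len(seq) < L:
        raise ValueError(
            f"sequence of length {len(seq)} shorter than motif {motif.motif_id} ({L})"
        )
    lo = motif.log_odds()
    n_row = (motif.background[:, None] * lo).sum(axis=0)  # expectation row for N
    lo_ext = np.vstack([lo, n_row])
    # reverse strand: scan with the reverse-complemented matrix
    lo_rc = lo[::-1, ::-1]
    lo_rc_ext = np.vstack([lo_rc, n_row[::-1]])
    enc = _encode(seq)
    wins = sliding_window_view(enc, L)
    cols = np.arange(L)
    fwd = lo_ext[wins, cols].sum(axis=1)
    rev = lo_rc_ext[wins, cols].sum(axis=1)
    best = float(max(fwd.max(), rev.max()))
    s_min, s_max = motif.score_range()
    return (best - s_min) / (s_max - s_min)


def score_promoters(motifs: list, promoters: dict) -> pd.DataFrame:
    """Dense genes x motifs matrix of normalized best-hit scores.

    ``promoters`` maps gene id to its window sequence; duplicate gene
    ids (already impossible in a dict, but checked for sequence lists of
    ``(gene_id, seq)`` pairs) raise.
    """
    if not isinstance(promoters, dict):
        ids = [gid for gid, _ in promoters]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate gene id in promoter sequences")
        promoters = dict(promoters)
    data = {
        m.motif_id: [best_hit_score(m, seq) for seq in promoters.values()]
        for m in motifs
    }
    return pd.DataFrame(data, index=pd.Index(promoters.keys(), name="gene_id"))


def set_enrichment(
    scores: pd.DataFrame,
    gene_set: list,
    label: str = "set",
    alpha: float = SIGNIFICANCE_ALPHA,
) -> pd.DataFrame:
    """Per-motif z and one-sided p of a gene set vs the full background.

    The background is the full score matrix (the set included), matching
    the all-promoters reference of the underlying analysis. ``sd_bg`` is
    the population standard deviation.
    """
    gene_set = list(gene_set)
    if len(gene_set) < 2:
        raise ValueError("gene set must contain at least 2 genes")
    missing = set(gene_set) - set(scores.index)
    if missing:
        raise ValueError(f"gene set ids missing from score matrix: {sorted(missing)[:3]}")
    sub = scores.loc[gene_set]
    rows = []
    for motif_id in scores.columns:
        bg = scores[motif_id].to_numpy(dtype=float)
        mean_bg, sd_bg = float(bg.mean()), float(bg.std(ddof=0))
        mean_set = float(sub[motif_id].mean())
        if sd_bg == 0:
            z, p, flagged = float("nan"), float("nan"), "sd_bg_zero"
        else:
            z = (mean_set - mean_bg) / (sd_bg / np.sqrt(len(gene_set)))
            p = float(norm.sf(z))
            flagged = ""
        rows.append(
            {
                "motif_id": motif_id,
                "gene_set": label,
                "n_set": len(gene_set),
                "mean_set": mean_set,
                "mean_bg": mean_bg,
                "sd_bg": sd_bg,
                "z": z,
                "p": p,
                "significant": bool(p < alpha) if np.isfinite(p) else False,
                "status": flagged,
            }
        )
    return pd.DataFrame(rows)


def enrichment_heatmap(
    results: dict, alpha: float = SIGNIFICANCE_ALPHA
) -> pd.DataFrame:
    """z matrix (motifs x gene sets) for motifs significant in >=1 set."""
    frames = []
    for label, df in results.items():
        frames.append(df.set_index("motif_id")[["z", "p"]].rename(
            columns={"z": f"z:{label}", "p": f"p:{label}"}
        ))
    wide = pd.concat(frames, axis=1)
    p_cols = [c for c in wide.columns if c.startswith("p:")]
    keep = (wide[p_cols] < alpha).any(axis=1)
    z_cols = [c for c in wide.columns if c.startswith("z:")]
    out = wide.loc[keep, z_cols]
    out.columns = [c[2:] for c in out.columns]
    return out
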