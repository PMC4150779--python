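"""Two-channel tiling-array log2 ratios and promoter deacetylation calling.

The arrays tile promoter windows (default -3500..+750 bp around each TSS)
with ~50 bp probes whose 5' ends are ~10 bp apart. Per probe we derive

* ``acetylation``    = log2(iDC / input)   -- H4Ac level in immature cells
* ``deacetylation``  = log2(iDC / LPS1h)   -- positive when acetylation is
  LOST upon 1 h of LPS stimulation.

A promoter is called ``decreased`` (deacetylated) when any sliding window
of ``win_probes`` consecutive probes contains at least ``min_probes_above``
probes with deacetylation >= ``threshold`` log2 units; ``increased`` by the
mirrored rule on the negated signal. The vendor software used for the
original arrays does not publish its rule, so this ACME-like run rule is
fully specified here and every constant is a parameter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation import GeneModel, GenomicWindow

__all__ = [
    "DeacetylationCall",
    "compute_ratio_track",
    "call_promoter",
    "call_promoters",
    "classify_array",
    "tss_offset_histogram",
]

CHANNELS = ("iDC", "LPS1h", "input")
INTENSITY_FLOOR = 1.0


@dataclass
class DeacetylationCall:
    """Per-promoter deacetylation call.

    ``score`` is the extremal sliding-window mean log2(iDC/LPS1h);
    ``peak_offset`` is the signed, strand-aware bp offset of the extremal
    window midpoint from the TSS (negative = upstream).
    """

    gene_id: str
    chrom: str
    interval: tuple
    direction: str  # decreased | increased | unchanged
    score: float
    peak_offset: float
    n_probes: int
    status: str = "ok"


def compute_ratio_track(
    probes: pd.DataFrame,
    channels: tuple = CHANNELS,
    floor: float = INTENSITY_FLOOR,
) -> pd.DataFrame:
    """Add ``acetylation`` and ``deacetylation`` log2-ratio columns.

    Intensities in (0, floor) are clipped up to ``floor`` before taking
    ratios, preventing infinities from background-subtracted channels;
    non-positive or missing intensities are an error naming the probe.
    """
    idc, lps, inp = channels
    for ch in channels:
        if ch not in probes.columns:
            raise ValueError(f"probe table lacks channel column {ch!r}")
        vals = probes[ch].to_numpy(dtype=float)
        bad = ~(vals > 0) | ~np.isfinite(vals)
        if bad.any():
            pid = probes["probe_id"].to_numpy()[bad][0]
            raise ValueError(
                f"non-positive intensity in channel {ch!r} at probe {pid!r}"
            )
    out = probes.copy()
    v = {ch: np.maximum(probes[ch].to_numpy(dtype=float), floor) for ch in channels}
    out["acetylation"] = np.log2(v[idc] / v[inp])
    out["deacetylation"] = np.log2(v[idc] / v[lps])
    return out


def _windowed_calls(deac, mids, win_probes, min_above, t):
    """Sliding-window qualification; returns (qualifies, means, wmids)."""
    from numpy.lib.stride_tricks import sliding_window_view

    w = sliding_window_view(deac, win_probes)
    means = w.mean(axis=1)
    above = (w >= t).sum(axis=1)
    below = (w <= -t).sum(axis=1)
    wmids = (mids[: len(means)] + mids[win_probes - 1 :]) / 2.0
    return above >= min_above, below >= min_above, means, wmids


def call_promoter(
    track: pd.DataFrame,
    window: GenomicWindow,
    gene_id: str = "",
    win_probes: int = 5,
    min_probes_above: int = 4,
    threshold: float = 1.0,
) -> DeacetylationCall:
    """Call one promoter from its ratio track.

    Probes whose midpoints fall inside the window are sorted by position
    and scanned with a ``win_probes``-probe sliding window (see module
    docstring for the rule). With fewer than ``win_probes`` probes the
    call is ``unchanged`` with status ``insufficient_probes``.
    """
    mids = ((track["start"].to_numpy() + track["end"].to_numpy()) / 2.0).astype(float)
    deac = track["deacetylation"].to_numpy(dtype=float)
    inside = (
        (track["chrom"].to_numpy() == window.chrom)
        & (mids >= window.start)
        & (mids < window.end)
    )
    mids, deac = mids[inside], deac[inside]
    order = np.argsort(mids, kind="stable")
    mids, deac = mids[order], deac[order]
    return _call_sorted(deac, mids, window, gene_id, win_probes, min_probes_above, threshold)


def _call_sorted(deac, mids, window, gene_id, win_probes, min_above, t):
    interval = window.interval
    n = len(deac)
    if n < win_probes:
        return DeacetylationCall(
            gene_id, window.chrom, interval, "unchanged", float("nan"),
            float("nan"), n, status="insufficient_probes",
        )
    dec_q, inc_q, means, wmids = _windowed_calls(deac, mids, win_probes, min_above, t)
    has_dec, has_inc = bool(dec_q.any()), bool(inc_q.any())
    if has_dec:
        i_dec = int(np.flatnonzero(dec_q)[np.argmax(means[dec_q])])
    if has_inc:
        i_inc = int(np.flatnonzero(inc_q)[np.argmin(means[inc_q])])
    if has_dec and has_inc:
        # both directions qualify somewhere: keep the stronger extremum
        if means[i_dec] >= -means[i_inc]:
            has_inc = False
        else:
            has_dec = False
    if has_dec:
        direction, score, mid = "decreased", float(means[i_dec]), wmids[i_dec]
    elif has_inc:
        direction, score, mid = "increased", float(means[i_inc]), wmids[i_inc]
    else:
        i = int(np.argmax(np.abs(means)))
        direction, score, mid = "unchanged", float(means[i]), wmids[i]
    return DeacetylationCall(
        gene_id, window.chrom, interval, direction, score,
        float(window.signed_offset(mid)), n,
    )


def call_promoters(
    track: pd.DataFrame,
    genes: list,
    upstream_bp: int = 3500,
    downstream_bp: int = 750,
    win_probes: int = 5,
    min_probes_above: int = 4,
    threshold: float = 1.0,
) -> pd.DataFrame:
    """Call every gene's promoter; returns one row per gene."""
    mids_all = ((track["start"].to_numpy() + track["end"].to_numpy()) / 2.0).astype(float)
    deac_all = track["deacetylation"].to_numpy(dtype=float)
    chrom_all = track["chrom"].to_numpy()
    by_chrom = {}
    for chrom in pd.unique(chrom_all):
        sel = chrom_all == chrom
        m = mids_all[sel]
        d = deac_all[sel]
        order = np.argsort(m, kind="stable")
        by_chrom[chrom] = (m[order], d[order])
    rows = []
    for g in genes:
        w = GenomicWindow(g.chrom, g.tss, g.strand, upstream_bp, downstream_bp)
        if g.chrom in by_chrom:
            m, d = by_chrom[g.chrom]
            lo, hi = np.searchsorted(m, [w.start, w.end])
            call = _call_sorted(
                d[lo:hi], m[lo:hi], w, g.gene_id, win_probes, min_probes_above, threshold
            )
        else:
            call = _call_sorted(
                np.empty(0), np.empty(0), w, g.gene_id, win_probes,
                min_probes_above, threshold,
            )
        rows.append(
            {
                "gene_id": call.gene_id,
                "chrom": call.chrom,
                "window_start": call.interval[0],
                "window_end": call.interval[1],
                "direction": call.direction,
                "score": call.score,
                "peak_offset": call.peak_offset,
                "n_probes": call.n_probes,
                "status": call.status,
            }
        )
    return pd.DataFrame(rows)


def classify_array(calls: pd.DataFrame) -> dict:
    """Percent of promoters with decreased / increased / unchanged H4Ac."""
    if calls["gene_id"].duplicated().any():
        dup = calls.loc[calls["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValueError(f"duplicate gene in calls: {dup!r}")
    n = len(calls)
    if n == 0:
        raise ValueError("no calls to classify")
    out = {"n": n}
    for d in ("decreased", "increased", "unchanged"):
        ids = calls.loc[calls["direction"] == d, "gene_id"].tolist()
        out[f"percent_{d}"] = 100.0 * len(ids) / n
        out[f"genes_{d}"] = ids
    return out


def tss_offset_histogram(
    calls: pd.DataFrame,
    bin_bp: int = 500,
    upstream_bp: int = 3500,
    downstream_bp: int = 750,
) -> pd.DataFrame:
    """Histogram of decreased-call peak offsets relative to the TSS.

    Bins are signed multiples of ``bin_bp`` spanning [-upstream,
    +downstream]; total count equals the number of decreased calls.
    """
    dec = calls[calls["direction"] == "decreased"]
    lo = -int(np.ceil(upstream_bp / bin_bp)) * bin_bp
    hi = int(np.ceil(downstream_bp / bin_bp)) * bin_bp
    edges = np.arange(lo, hi + bin_bp, bin_bp)
    counts, _ = np.histogram(dec["peak_offset"].to_numpy(dtype=float), bins=edges)
    return pd.DataFrame(
        {"bin_start": edges[:-1], "bin_end": edges[1:], "count": counts}
    )
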