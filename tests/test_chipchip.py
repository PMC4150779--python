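"""Log2 ratio computation and the sliding-window deacetylation caller."""

import numpy as np
import pandas as pd
import pytest

from silencescan.annotation import GenomicWindow
from silencescan.chipchip import (
    call_promoter,
    classify_array,
    compute_ratio_track,
    tss_offset_histogram,
)


def probe_frame(values, start=0, step=10, length=50, chrom="chr1"):
    starts = start + step * np.arange(len(values))
    return pd.DataFrame(
        {
            "probe_id": [f"p{i}" for i in range(len(values))],
            "chrom": chrom,
            "start": starts,
            "end": starts + length,
            "deacetylation": np.asarray(values, dtype=float),
        }
    )


def window_for(track, strand="+"):
    lo = track["start"].min()
    hi = track["end"].max()
    tss = int(hi) if strand == "+" else int(lo)
    up = int(hi - lo + 100)
    return GenomicWindow("chr1", tss, strand, up, 100)


class TestRatioTrack:
    def test_log2_ratios(self):
        df = pd.DataFrame(
            {
                "probe_id": ["a", "b"],
                "chrom": "chr1",
                "start": [0, 10],
                "end": [50, 60],
                "iDC": [200.0, 100.0],
                "LPS1h": [50.0, 400.0],
                "input": [200.0, 100.0],
            }
        )
        out = compute_ratio_track(df)
        assert out["deacetylation"].tolist() == [2.0, -2.0]
        assert out["acetylation"].tolist() == [0.0, 0.0]

    def test_identical_channels_zero(self):
        df = pd.DataFrame(
            {
                "probe_id": ["a"], "chrom": "c", "start": [0], "end": [50],
                "iDC": [123.0], "LPS1h": [123.0], "input": [123.0],
            }
        )
        out = compute_ratio_track(df)
        assert out["deacetylation"].iloc[0] == 0.0

    def test_non_positive_intensity_names_probe(self):
        df = pd.DataFrame(
            {
                "probe_id": ["bad1"], "chrom": "c", "start": [0], "end": [50],
                "iDC": [0.0], "LPS1h": [10.0], "input": [10.0],
            }
        )
        with pytest.raises(ValueError, match="bad1"):
            compute_ratio_track(df)

    def test_small_intensities_floored_not_infinite(self):
        df = pd.DataFrame(
            {
                "probe_id": ["a"], "chrom": "c", "start": [0], "end": [50],
                "iDC": [0.25], "LPS1h": [1024.0], "input": [1.0],
            }
        )
        out = compute_ratio_track(df)
        assert np.isfinite(out["deacetylation"]).all()
        assert out["deacetylation"].iloc[0] == -10.0  # floor at 1.0


def brute_force_call(values, win=5, min_above=4, t=1.0):
    """Independent oracle: enumerate every window of consecutive probes."""
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n < win:
        return "unchanged"
    dec = inc = None
    for i in range(n - win + 1):
        w = values[i : i + win]
        if (w >= t).sum() >= min_above:
            dec = max(dec, w.mean()) if dec is not None else w.mean()
        if (w <= -t).sum() >= min_above:
            inc = min(inc, w.mean()) if inc is not None else w.mean()
    if dec is not None and inc is not None:
        return "decreased" if dec >= -inc else "increased"
    if dec is not None:
        return "decreased"
    if inc is not None:
        return "increased"
    return "unchanged"


class TestCallPromoter:
    def test_uniform_signal_decreased(self):
        track = probe_frame([1.5] * 20)
        call = call_promoter(track, window_for(track), "g")
        assert call.direction == "decreased"
        assert call.score == pytest.approx(1.5)

    def test_flat_zero_unchanged(self):
        track = probe_frame([0.0] * 20)
        call = call_promoter(track, window_for(track), "g")
        assert call.direction == "unchanged"
        assert call.score == 0.0

    def test_alternating_signal_never_qualifies(self):
        # {1.5, 0, 1.5, 0, ...}: at most 3 of any 5 consecutive probes
        # reach the threshold, below the >=4 rule
        track = probe_frame([1.5, 0.0] * 10)
        call = call_promoter(track, window_for(track), "g")
        assert call.direction == "unchanged"

    def test_too_few_probes_flagged(self):
        track = probe_frame([2.0] * 3)
        call = call_promoter(track, window_for(track), "g")
        assert call.direction == "unchanged"
        assert call.status == "insufficient_probes"

    def test_negation_swaps_direction(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            vals = rng.normal(0, 1.2, size=40)
            track = probe_frame(vals)
            neg = probe_frame(-vals)
            a = call_promoter(track, window_for(track), "g")
            b = call_promoter(neg, window_for(neg), "g")
            swap = {"decreased": "increased", "increased": "decreased", "unchanged": "unchanged"}
            assert b.direction == swap[a.direction]

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(17)
        for _ in range(200):
            n = rng.integers(5, 60)
            vals = rng.normal(0.3, 1.0, size=n)
            track = probe_frame(vals)
            call = call_promoter(track, window_for(track), "g")
            assert call.direction == brute_force_call(vals)

    def test_raising_threshold_shrinks_decreased_set(self):
        rng = np.random.default_rng(23)
        tracks = [probe_frame(rng.normal(0.8, 0.8, size=30)) for _ in range(50)]
        previous = None
        for t in (0.5, 1.0, 1.5, 2.0):
            dec = {
                i
                for i, tr in enumerate(tracks)
                if call_promoter(tr, window_for(tr), "g", threshold=t).direction
                == "decreased"
            }
            if previous is not None:
                assert dec <= previous
            previous = dec

    def test_minus_strand_offset_sign(self):
        # signal at larger coordinates than a minus-strand TSS is upstream
        vals = [0.0] * 30 + [2.0] * 10
        track = probe_frame(vals)
        w = GenomicWindow("chr1", int(track["start"].min()), "-", 600, 100)
        call = call_promoter(track, w, "g")
        assert call.direction == "decreased"
        assert call.peak_offset < 0


class TestSummaries:
    def test_percentages(self):
        calls = pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(100)],
                "direction": ["decreased"] * 4 + ["increased"] * 1 + ["unchanged"] * 95,
            }
        )
        s = classify_array(calls)
        assert (s["percent_decreased"], s["percent_increased"], s["percent_unchanged"]) == (
            4.0, 1.0, 95.0,
        )
        assert len(s["genes_decreased"]) == 4

    def test_all_unchanged(self):
        calls = pd.DataFrame({"gene_id": ["a", "b"], "direction": "unchanged"})
        s = classify_array(calls)
        assert s["percent_unchanged"] == 100.0

    def test_duplicate_gene_raises(self):
        calls = pd.DataFrame({"gene_id": ["a", "a"], "direction": "unchanged"})
        with pytest.raises(ValueError, match="duplicate"):
            classify_array(calls)

    def test_histogram_single_call(self):
        calls = pd.DataFrame(
            {"gene_id": ["g"], "direction": ["decreased"], "peak_offset": [-120.0]}
        )
        h = tss_offset_histogram(calls, bin_bp=500)
        row = h[(h["bin_start"] == -500) & (h["bin_end"] == 0)]
        assert row["count"].iloc[0] == 1
        assert h["count"].sum() == 1

    def test_histogram_empty_decreased_all_zero(self):
        calls = pd.DataFrame(
            {"gene_id": ["g"], "direction": ["unchanged"], "peak_offset": [0.0]}
        )
        h = tss_offset_histogram(calls, bin_bp=500)
        assert (h["count"] == 0).all()


def test_planted_deacetylation_centers_near_tss(small_analysis):
    """The planted deacetylated region prefers the TSS, and the recovered
    offset distribution has its mode in the TSS-containing bin."""
    calls = small_analysis["calls"]
    h = tss_offset_histogram(calls, bin_bp=500)
    top = h.loc[h["count"].idxmax()]
    assert top["bin_start"] <= 0 <= top["bin_end"]
    assert h["count"].sum() == (calls["direction"] == "decreased").sum()
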