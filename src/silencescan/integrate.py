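"""Intersection of deacetylation calls with transcription-rate classes,
and the end-to-end pipeline driver.

The headline quantities are (a) the percent of deacetylated promoters
whose gene is expressed (>= 1 RPKM, untreated nascent fraction) and
(b) the percent of those expressed deacetylated genes whose nascent
transcription drops more than 2-fold within 1 h of stimulation -- the
"deacetylated-silenced" set, resolved further at the >3 and >5-fold
tiers.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import chipchip, motifs as motifs_mod, nascent, peaks as peaks_mod
from .annotation import read_gene_models

logger = logging.getLogger(__name__)

__all__ = ["integrate", "compare_transcription_vs_mrna", "run_pipeline"]

DEFAULT_TIERS = (2.0, 3.0, 5.0)


def integrate(
    calls: pd.DataFrame,
    nascent_expr: pd.DataFrame,
    mrna_expr: pd.DataFrame | None = None,
    baseline: float = nascent.DEFAULT_BASELINE_RPKM,
    tiers: tuple = DEFAULT_TIERS,
) -> tuple:
    """Join promoter calls with expression classes.

    Returns ``(table, summary)``. The table has one row per gene present
    in both the calls and the nascent expression records (genes missing
    from the expression table are excluded with a warning count in the
    summary); membership sets follow
    deacetylated_silenced@k = deacetylated AND expressed AND silenced@k.
    """
    ncols = {"gene_id", "rpkm_untreated"}
    if not ncols <= set(nascent_expr.columns):
        raise ValueError("nascent expression table lacks required columns")
    merged = calls.merge(
        nascent_expr.add_prefix("nascent_"),
        left_on="gene_id",
        right_on="nascent_gene_id",
        how="left",
    )
    missing = merged["nascent_gene_id"].isna()
    n_missing = int(missing.sum())
    if n_missing:
        logger.warning(
            "%d genes with promoter calls lack expression records; excluded",
            n_missing,
        )
    merged = merged[~missing].drop(columns=["nascent_gene_id"])
    if mrna_expr is not None:
        merged = merged.merge(
            mrna_expr.add_prefix("mrna_"),
            left_on="gene_id",
            right_on="mrna_gene_id",
            how="left",
        ).drop(columns=["mrna_gene_id"])

    merged["deacetylated"] = merged["direction"] == "decreased"
    merged["expressed"] = merged["nascent_rpkm_untreated"] >= baseline
    for k in tiers:
        lab = merged[f"nascent_label_{k:g}"]
        merged[f"deacetylated_silenced_{k:g}"] = (
            merged["deacetylated"] & merged["expressed"] & (lab == "silenced")
        )
        merged[f"induced_{k:g}"] = lab == "induced"
    merged["no_change"] = merged[f"nascent_label_{tiers[0]:g}"] == "unchanged"

    n_deacet = int(merged["deacetylated"].sum())
    n_deacet_expr = int((merged["deacetylated"] & merged["expressed"]).sum())
    summary = {
        "n_genes": int(len(merged)),
        "n_missing_expression": n_missing,
        "n_deacetylated": n_deacet,
        "n_deacetylated_expressed": n_deacet_expr,
    }
    if n_deacet == 0:
        logger.warning("no deacetylated promoters; headline fractions undefined")
        summary["pct_deacetylated_expressed"] = float("nan")
    else:
        summary["pct_deacetylated_expressed"] = 100.0 * n_deacet_expr / n_deacet
    for k in tiers:
        summary[f"n_deacetylated_silenced_{k:g}"] = int(
            merged[f"deacetylated_silenced_{k:g}"].sum()
        )
        summary[f"n_induced_{k:g}"] = int(merged[f"induced_{k:g}"].sum())
    summary["n_no_change"] = int(merged["no_change"].sum())
    k0 = tiers[0]
    if n_deacet_expr == 0:
        summary[f"pct_expressed_deacetylated_silenced_{k0:g}"] = float("nan")
    else:
        summary[f"pct_expressed_deacetylated_silenced_{k0:g}"] = (
            100.0 * summary[f"n_deacetylated_silenced_{k0:g}"] / n_deacet_expr
        )
    # dot-plot ordering: genes ranked by their change in nascent expression
    merged = merged.sort_values("nascent_fold", kind="stable").reset_index(drop=True)
    return merged, summary


def gene_sets_from_table(table: pd.DataFrame, tiers: tuple = DEFAULT_TIERS) -> dict:
    """Named gene-id sets for downstream profiling/enrichment."""
    sets = {}
    for k in tiers:
        sets[f"deacetylated_silenced_{k:g}"] = table.loc[
            table[f"deacetylated_silenced_{k:g}"], "gene_id"
        ].tolist()
        sets[f"induced_{k:g}"] = table.loc[table[f"induced_{k:g}"], "gene_id"].tolist()
    sets["no_change"] = table.loc[table["no_change"], "gene_id"].tolist()
    return sets


def compare_transcription_vs_mrna(
    nascent_expr: pd.DataFrame, mrna_expr: pd.DataFrame, tier: float = 2.0
) -> tuple:
    """Paired (nascent fold, mRNA fold) per gene, with silenced counts.

    At 1 h, steady-state mRNA pools lag transcription, so more genes are
    expected down at the nascent level than at the mRNA level.
    """
    lab = f"label_{tier:g}"
    merged = nascent_expr[["gene_id", "fold", lab]].merge(
        mrna_expr[["gene_id", "fold", lab]],
        on="gene_id",
        suffixes=("_nascent", "_mrna"),
    )
    counts = {
        "silenced_nascent": int((merged[f"{lab}_nascent"] == "silenced").sum()),
        "silenced_mrna": int((merged[f"{lab}_mrna"] == "silenced").sum()),
    }
    return merged, counts


# ---------------------------------------------------------------------------
# pipeline driver


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[stage {stage}] {message}")
        self.stage = stage


def _fmt(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def run_pipeline(config, outdir: str | None = None) -> dict:
    """Run every stage from a YAML config (or dict) of input paths.

    Required inputs: ``genes``, ``probes`` and the four read tables
    (``nascent_untreated``, ``nascent_lps``, ``mrna_untreated``,
    ``mrna_lps``). Optional: ``peaks_rep1``/``peaks_rep2``, ``promoters``
    (FASTA) and ``motifs`` (JASPAR text; defaults to the packaged set).
    Outputs are deterministic given the config and inputs.
    """
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    inputs = config.get("inputs", {})
    params = config.get("params", {})
    outdir = Path(outdir or config.get("outdir", "silencescan_out"))
    outdir.mkdir(parents=True, exist_ok=True)
    tiers = tuple(params.get("tiers", DEFAULT_TIERS))
    baseline = float(params.get("baseline_rpkm", 1.0))
    epsilon = float(params.get("epsilon_rpkm", 0.1))

    def need(key):
        if key not in inputs:
            raise PipelineError("inputs", f"missing required input {key!r}")
        p = Path(inputs[key])
        if not p.exists():
            raise PipelineError("inputs", f"input file not found: {p}")
        return p

    # --- annotation
    try:
        genes = read_gene_models(need("genes"))
    except PipelineError:
        raise
    except Exception as e:
        raise PipelineError("annotation", str(e)) from e

    results = {"outdir": str(outdir)}
    log_lines = [f"genes: {len(genes)}"]

    # --- chipchip
    try:
        probes = pd.read_csv(need("probes"), sep="\t")
        track = chipchip.compute_ratio_track(probes)
        calls = chipchip.call_promoters(
            track,
            genes,
            upstream_bp=int(params.get("promoter_upstream", 3500)),
            downstream_bp=int(params.get("promoter_downstream", 750)),
            win_probes=int(params.get("win_probes", 5)),
            min_probes_above=int(params.get("min_probes_above", 4)),
            threshold=float(params.get("threshold_log2", 1.0)),
        )
        array_summary = chipchip.classify_array(calls)
        hist = chipchip.tss_offset_histogram(
            calls,
            bin_bp=int(params.get("offset_bin_bp", 500)),
            upstream_bp=int(params.get("promoter_upstream", 3500)),
            downstream_bp=int(params.get("promoter_downstream", 750)),
        )
        _fmt(calls, outdir / "deacetylation_calls.tsv")
        _fmt(hist, outdir / "tss_offset_histogram.tsv")
    except PipelineError:
        raise
    except Exception as e:
        raise PipelineError("chipchip", str(e)) from e

    # --- quantification
    try:
        expr = {}
        libs = {}
        for fraction, keys in (
            ("nascent", ("nascent_untreated", "nascent_lps")),
            ("mRNA", ("mrna_untreated", "mrna_lps")),
        ):
            counts = []
            for key in keys:
                reads = nascent.read_read_table(need(key))
                kept, flog = nascent.filter_reads(reads, genes)
                c, info = nascent.assign_reads(kept, genes, fraction)
                counts.append(c)
                libs[key] = {"filter": flog, "assign": info}
                log_lines.append(f"{key}: {flog} {info}")
            expr[fraction] = nascent.expression_table(
                counts[0], counts[1], genes, fraction,
                baseline=baseline, tiers=tiers, epsilon=epsilon,
            )
            _fmt(expr[fraction], outdir / f"expression_{fraction.lower()}.tsv")
            libs[f"counts_{fraction}"] = counts
        qc = nascent.nascent_qc(
            libs["counts_nascent"][0],
            libs["counts_mRNA"][0],
            libs["nascent_untreated"]["filter"],
        )
        log_lines.append(f"qc: {qc}")
    except PipelineError:
        raise
    except Exception as e:
        raise PipelineError("quantify", str(e)) from e

    # --- integration
    try:
        table, summary = integrate(
            calls, expr["nascent"], expr["mRNA"], baseline=baseline, tiers=tiers
        )
        sets = gene_sets_from_table(table, tiers)
        _fmt(table, outdir / "integrated.tsv")
        for label, ids in sets.items():
            (outdir / f"genes_{label}.txt").write_text(
                "".join(f"{g}\n" for g in ids)
            )
        paired, mrna_counts = compare_transcription_vs_mrna(
            expr["nascent"], expr["mRNA"], tier=tiers[0]
        )
        _fmt(paired, outdir / "fold_nascent_vs_mrna.tsv")
        dot = table[
            table["deacetylated"]
            & table["expressed"]
        ][["gene_id", "nascent_fold"] + (["mrna_fold"] if "mrna_fold" in table else [])]
        _fmt(dot, outdir / "dotplot_deacetylated.tsv")
    except PipelineError:
        raise
    except Exception as e:
        raise PipelineError("integrate", str(e)) from e

    # --- peaks (optional)
    profile_rows = None
    if "peaks_rep1" in inputs or "peaks_rep2" in inputs:
        try:
            rep1 = peaks_mod.read_narrowpeak(need("peaks_rep1"), "rep1")
            rep2 = peaks_mod.read_narrowpeak(need("peaks_rep2"), "rep2")
            alpha = float(params.get("peak_alpha", 1e-5))
            rep1 = peaks_mod.filter_significant(rep1, alpha)
            rep2 = peaks_mod.filter_significant(rep2, alpha)
            merged_peaks = peaks_mod.reproducible_peaks(
                rep1, rep2, int(params.get("min_overlap_nt", 1))
            )
            peaks_mod.write_narrowpeak(merged_peaks, outdir / "peaks_reproducible.narrowPeak")
            profile_sets = {
                k: v
                for k, v in sets.items()
                if v and k in set(params.get(
                    "profile_sets",
                    ["deacetylated_silenced_5", "induced_5", "no_change"],
                ))
            }
            profiles = peaks_mod.profile_gene_sets(
                merged_peaks, genes, profile_sets,
                window_sizes=tuple(params.get("window_sizes", (500, 1000, 2000, 4000))),
                bin_bp=int(params.get("peak_bin_bp", 200)),
            )
            profile_rows = peaks_mod.compare_profiles(profiles)
            _fmt(profile_rows, outdir / "occupancy_profiles.tsv")
            for label, prof in profiles.items():
                prof.heatmap.to_csv(
                    outdir / f"heatmap_{label}.tsv", sep="\t"
                )
        except PipelineError:
            raise
        except Exception as e:
            raise PipelineError("peaks", str(e)) from e

    # --- motifs (optional)
    enrichment = None
    if "promoters" in inputs:
        try:
            from Bio import SeqIO

            motif_path = inputs.get("motifs")
            if motif_path is None:
                from .data import packaged_motif_path

                motif_path = str(packaged_motif_path())
            motif_list = motifs_mod.read_jaspar(motif_path)
            records = list(SeqIO.parse(str(need("promoters")), "fasta"))
            ids = [r.id for r in records]
            if len(set(ids)) != len(ids):
                raise ValueError("duplicate gene in promoter FASTA")
            proms = {r.id: str(r.seq) for r in records}
            scores = motifs_mod.score_promoters(motif_list, proms)
            _fmt(scores.reset_index(), outdir / "motif_scores.tsv")
            results_by_set = {}
            for label, idset in sets.items():
                idset = [g for g in idset if g in scores.index]
                if len(idset) >= 2:
                    results_by_set[label] = motifs_mod.set_enrichment(
                        scores, idset, label,
                        alpha=float(params.get("motif_alpha", 1e-3)),
                    )
            if results_by_set:
                enrichment = pd.concat(results_by_set.values(), ignore_index=True)
                _fmt(enrichment, outdir / "motif_enrichment.tsv")
                heat = motifs_mod.enrichment_heatmap(
                    results_by_set, alpha=float(params.get("motif_alpha", 1e-3))
                )
                heat.to_csv(outdir / "motif_enrichment_heatmap.tsv", sep="\t",
                            float_format="%.6g")
        except PipelineError:
            raise
        except Exception as e:
            raise PipelineError("motifs", str(e)) from e

    # --- summary + report
    summary_df = pd.DataFrame(
        sorted(
            {
                **{k: v for k, v in summary.items()},
                "percent_promoters_decreased": array_summary["percent_decreased"],
                "percent_promoters_increased": array_summary["percent_increased"],
                "percent_promoters_unchanged": array_summary["percent_unchanged"],
                "silenced_nascent_2x": mrna_counts["silenced_nascent"],
                "silenced_mrna_2x": mrna_counts["silenced_mrna"],
            }.items()
        ),
        columns=["metric", "value"],
    )
    _fmt(summary_df, outdir / "summary.tsv")
    report = [
        "# silencescan pipeline report",
        "",
        f"Genes: {len(genes)}",
        "",
        "## Promoter H4-deacetylation",
        f"- decreased: {array_summary['percent_decreased']:.2f}%",
        f"- increased: {array_summary['percent_increased']:.2f}%",
        "",
        "## Integration",
        *[f"- {k}: {v}" for k, v in sorted(summary.items())],
        "",
        "## Transcription vs mRNA (silenced >2x)",
        f"- nascent: {mrna_counts['silenced_nascent']}",
        f"- mRNA: {mrna_counts['silenced_mrna']}",
        "",
        "## Log",
        *[f"- {line}" for line in log_lines],
        "",
    ]
    (outdir / "report.md").write_text("\n".join(report))
    results.update(
        {
            "genes": genes,
            "calls": calls,
            "array_summary": array_summary,
            "expression": expr,
            "integrated": table,
            "summary": summary,
            "gene_sets": sets,
            "profiles": profile_rows,
            "enrichment": enrichment,
            "qc": qc,
        }
    )
    return results
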