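"""End-to-end assembly of per-gene records and the headline associations.

A GeneRecord row collects, for every analysis gene, the quantities the
population-frequency analyses condition on: exon-weighted H3K9me3 density
per stage, nearest-TE attributes (distance, length, family, population
frequency, piRNA densities), TE counts per distance bin, local gene density
and recombination rate, and the stage-enrichment count.
"""
from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import chromatin, expression, genome, pirna, popfreq


def build_gene_records(
    ann: genome.GenomeAnnotation,
    tracks: Sequence[chromatin.DensityTrack],
    weighted_reads: pd.DataFrame | None,
    te_frequency: pd.DataFrame | None,
    recomb_map: pd.DataFrame | None,
    exclude_ids: Sequence[str] = (),
    enrichment_q: float = 0.10,
) -> pd.DataFrame:
    """Per-gene table of every derived quantity, indexed by gene id.

    ``tracks`` must already be clamped.  ``te_frequency`` is indexed by te_id
    with columns ``frequency`` and ``observed``; passing None leaves those
    columns NaN (likewise for piRNA and recombination inputs).
    """
    analysis_genes = genome.select_analysis_genes(ann, exclude_ids=exclude_ids)
    tes = ann.tes
    te_by_id = {t.te_id: t for t in tes}
    rows = []
    pirna_te = (
        pirna.pirna_density_table(weighted_reads, tes)
        if weighted_reads is not None
        else None
    )
    pirna_gene = (
        pirna.pirna_density_table(weighted_reads, analysis_genes)
        if weighted_reads is not None
        else None
    )
    for g in analysis_genes:
        near, dist, tie = genome.nearest_te(g, tes)
        counts = genome.te_counts_by_bin(g, tes)
        rec: dict = {
            "gene_id": g.gene_id,
            "distance_category": genome.distance_category(g, tes),
            "nearest_te_tie": tie,
            "nearest_te_id": near.te_id if near else None,
            "nearest_te_distance": float(dist) if dist is not None else np.nan,
            "nearest_te_length": float(near.length) if near else np.nan,
            "nearest_te_family": near.family if near else None,
        }
        for bin_name, c in counts.items():
            rec[f"n_te_{bin_name}"] = c
        if near is not None and te_frequency is not None and near.te_id in te_frequency.index:
            rec["nearest_te_frequency"] = float(te_frequency.loc[near.te_id, "frequency"])
            rec["nearest_te_observed"] = bool(te_frequency.loc[near.te_id, "observed"])
        else:
            rec["nearest_te_frequency"] = np.nan
            rec["nearest_te_observed"] = None
        if near is not None and pirna_te is not None:
            rec["nearest_te_pirna_sense"] = float(pirna_te.loc[near.te_id, "sense"])
            rec["nearest_te_pirna_antisense"] = float(pirna_te.loc[near.te_id, "antisense"])
        else:
            rec["nearest_te_pirna_sense"] = np.nan
            rec["nearest_te_pirna_antisense"] = np.nan
        if pirna_gene is not None:
            rec["gene_pirna_sense"] = float(pirna_gene.loc[g.gene_id, "sense"])
            rec["gene_pirna_antisense"] = float(pirna_gene.loc[g.gene_id, "antisense"])
        if recomb_map is not None:
            density, rate = genome.local_context(g, ann.genes, recomb_map)
            rec["gene_density"] = density
            rec["recomb_rate"] = rate
        for track in tracks:
            rec[f"h3k9_{track.stage}"] = chromatin.gene_h3k9_density(track, g)
        rows.append(rec)
    records = pd.DataFrame(rows).set_index("gene_id")
    stage_cols = [f"h3k9_{t.stage}" for t in tracks]
    if stage_cols:
        records["stage_enrichment_count"] = chromatin.stage_enrichment_count(
            records[stage_cols].rename(columns=lambda c: c[len("h3k9_") :]),
            q=enrichment_q,
        )
    return records


def panel_expression_tests(
    ann: genome.GenomeAnnotation,
    panel: expression.StrainPanel,
    windows: Sequence[str] = ("in_gene", "1kb", "2kb", "5kb", "10kb"),
    alpha: float = 0.05,
    enumeration_cap: int = expression.DEFAULT_ENUMERATION_CAP,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """With-TE vs without-TE permutation tests over every gene, window, sex.

    Returns (per-test results, per-window/sex excess-significance summary).
    Only genes with at least one TE site in the window enter; untestable
    configurations (groups < 2 or <= 20 label assignments) are kept in the
    results table but excluded from the summary, mirroring how the real
    analysis restricts to genes whose p-value could reach significance.
    """
    ranked = {
        sex: expression.rank_expression_panel(expr)
        for sex, expr in panel.expression.items()
    }
    gene_spans = {
        g.gene_id: (g.span.chrom, g.span.start, g.span.end) for g in ann.genes
    }
    rows = []
    sites_idx = panel.sites.set_index("site_id")
    for g in ann.genes:
        span = gene_spans[g.gene_id]
        # intronic sites: TE sites overlapping the gene span itself
        overlap = (
            (sites_idx["chrom"] == span[0])
            & (sites_idx["start"] < span[2])
            & (sites_idx["end"] > span[1])
        )
        intronic = list(sites_idx.index[overlap])
        for w in windows:
            sids = expression.sites_near_gene(panel, span, w, intronic)
            grouping = expression.allele_state(panel, g.gene_id, sids, w)
            if grouping.n_sites == 0:
                continue
            for sex, rk in ranked.items():
                res = expression.gene_permutation_test(
                    rk, grouping, g.gene_id, sex, enumeration_cap=enumeration_cap
                )
                rows.append(res)
    results = pd.DataFrame([vars(r) for r in rows])
    summaries = []
    if not results.empty:
        testable = results[results["testable"]]
        for (w, sex), sub in testable.groupby(["window", "sex"]):
            s = expression.excess_significance(
                sub["p_one_tail"].to_list(), alpha=alpha, window=w, sex=sex
            )
            summaries.append(vars(s))
    return results, pd.DataFrame(summaries)


def headline_associations(records: pd.DataFrame, stage: str) -> dict:
    """The qualitative associations the spreading model predicts, at one stage.

    Uses genes with a unique nearest TE.  Returns Spearman rho/p for
    density~distance (expected negative), density~nearest-TE frequency
    (negative), density~nearest-TE antisense piRNA (positive), plus the
    piRNA association within each distance tertile (expected strongest for
    the shortest distances).
    """
    col = f"h3k9_{stage}"
    pairs = records[~records["nearest_te_tie"] & records["nearest_te_id"].notna()].copy()
    out: dict = {"n_pairs": len(pairs)}
    d = pairs[[col, "nearest_te_distance"]].dropna()
    out["rho_distance"], out["p_distance"] = popfreq.spearman_suite(
        d[col], d["nearest_te_distance"]
    )
    f = pairs[[col, "nearest_te_frequency"]].dropna()
    out["rho_frequency"], out["p_frequency"] = popfreq.spearman_suite(
        f[col], f["nearest_te_frequency"]
    )
    p = pairs[[col, "nearest_te_pirna_antisense", "nearest_te_distance"]].dropna()
    out["rho_pirna"], out["p_pirna"] = popfreq.spearman_suite(
        p[col], p["nearest_te_pirna_antisense"]
    )
    tert = genome.distance_tertiles(p["nearest_te_distance"].to_numpy())
    for label, t in (("short", 0), ("intermediate", 1), ("long", 2)):
        sub = p.iloc[tert == t]
        try:
            rho, pv = popfreq.spearman_suite(sub[col], sub["nearest_te_pirna_antisense"])
        except ValueError:
            rho, pv = np.nan, np.nan
        out[f"rho_pirna_{label}"] = rho
        out[f"p_pirna_{label}"] = pv
    return out
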