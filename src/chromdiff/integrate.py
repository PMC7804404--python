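"""Cross-assay integration: differential accessibility, the gene-regulatory
interaction network, gained/lost-to-up/down coupling tests, and eRNA
analysis.

A gene-regulatory chromatin interaction is a tested Hi-C bin pair with a
differentially accessible peak in one anchor and the promoter of an
expressed gene in the other.  Interaction classes (gained / lost /
unchanged) come from the differential interaction test; gene classes
(up / down / unchanged) from the expression test; the coupling between them
is assessed with Fisher exact tests at the interaction-gene link level.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import BinTable, overlap_query
from .stats import (
    CountMatrix,
    cpm_filter,
    fisher_exact_2x2,
    ql_test,
    tmm_factors,
    voom_weighted_lm,
    wilcoxon_rank_sum,
)

__all__ = [
    "define_promoters",
    "test_differential_accessibility",
    "build_regulatory_network",
    "coupling_tests",
    "accessibility_by_interaction_class",
    "erna_analysis",
]


def define_promoters(
    genes: pd.DataFrame,
    upstream: int = 1000,
    downstream: int = 100,
    chrom_sizes: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Strand-aware promoter windows around the TSS (-1 kb to +100 bp).

    On the plus strand the promoter is [TSS - upstream, TSS + downstream);
    mirrored on the minus strand; clipped at chromosome ends.
    """
    missing = genes["strand"].isna() | ~genes["strand"].isin(["+", "-"])
    if missing.any():
        bad = genes.loc[missing, "gene_id"].iloc[0]
        raise ValueError(f"gene {bad} has no usable strand")
    tss = genes["tss"].to_numpy(np.int64)
    plus = (genes["strand"] == "+").to_numpy()
    start = np.where(plus, tss - upstream, tss - downstream)
    end = np.where(plus, tss + downstream, tss + upstream)
    start = np.maximum(start, 0)
    if chrom_sizes is not None:
        lim = genes["chrom"].map(chrom_sizes).to_numpy(np.int64)
        end = np.minimum(end, lim)
    return pd.DataFrame(
        {
            "chrom": genes["chrom"].to_numpy(),
            "start": start,
            "end": end,
            "gene_id": genes["gene_id"].to_numpy(),
        }
    )


def test_differential_accessibility(
    peak_counts: CountMatrix,
    design,
    contrast,
    fdr_threshold: float = 0.05,
    normalize: bool = True,
) -> pd.DataFrame:
    """TMM-normalized QL F-test per peak; DA = FDR below threshold, signed."""
    cm = peak_counts
    if normalize:
        cm = CountMatrix(
            counts=cm.counts,
            samples=list(cm.samples),
            feature_ids=cm.feature_ids,
            lib_sizes=cm.lib_sizes.copy(),
            norm_factors=tmm_factors(cm),
        )
    tab = ql_test(cm, design, contrast)
    tab["status"] = np.where(
        tab["fdr"] < fdr_threshold,
        np.where(tab["logFC"] > 0, "up", "down"),
        "unchanged",
    )
    return tab


def _features_to_bins(features: pd.DataFrame, bins: BinTable) -> dict[int, list]:
    """Map each feature to every bin it overlaps; returns bin -> feature ids.

    Expects columns (chrom, start, end, id) in that order; features spanning
    a bin edge are assigned to every bin they overlap.
    """
    out: dict[int, list] = {}
    for row in features.itertuples(index=False):
        chrom, start, end = row[0], int(row[1]), int(row[2])
        if chrom not in bins.chroms:
            continue
        lo, hi = bins.index_range(chrom)
        first = lo + start // bins.width
        last = lo + (end - 1) // bins.width
        for b in range(first, min(last, hi - 1) + 1):
            out.setdefault(b, []).append(row[-1])
    return out


def build_regulatory_network(
    di: pd.DataFrame,
    da: pd.DataFrame,
    peaks: pd.DataFrame,
    promoters: pd.DataFrame,
    bins: BinTable,
    expressed_genes: set | None = None,
    da_only: bool = True,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Link-level gene-regulatory interaction network.

    For every tested bin pair, peaks overlapping one anchor are linked with
    promoters overlapping the other anchor (both orientations; anchors must
    be distinct bins).  Interaction class comes from the DI result: gained
    (FDR < threshold, logFC > 0), lost (FDR < threshold, logFC < 0), else
    unchanged.  With ``da_only``, only differentially accessible peaks enter
    the network; DA status is annotated either way.
    """
    da = da.rename(columns={"feature": "peak"})
    peak_status = dict(zip(da["peak"], da["status"]))
    peak_logfc = dict(zip(da["peak"], da["logFC"]))
    use_peaks = peaks.rename(columns={"name": "peak"})[["chrom", "start", "end", "peak"]]
    if da_only:
        keep = use_peaks["peak"].map(peak_status).isin(["up", "down"])
        use_peaks = use_peaks[keep]
    prom = promoters[["chrom", "start", "end", "gene_id"]]
    if expressed_genes is not None:
        prom = prom[prom["gene_id"].isin(expressed_genes)]
    peak_bins = _features_to_bins(use_peaks, bins)
    prom_bins = _features_to_bins(prom, bins)
    rows = []
    for row in di.itertuples(index=False):
        a1, a2 = int(row.anchor1), int(row.anchor2)
        if a1 == a2:
            continue
        if row.fdr < fdr_threshold:
            iclass = "gained" if row.logFC > 0 else "lost"
        else:
            iclass = "unchanged"
        for pa, ga in ((a1, a2), (a2, a1)):
            for pk in peak_bins.get(pa, ()):  # peaks in one anchor
                for gene in prom_bins.get(ga, ()):  # promoters in the other
                    rows.append(
                        {
                            "anchor1": a1,
                            "anchor2": a2,
                            "peak": pk,
                            "gene_id": gene,
                            "interaction_class": iclass,
                            "di_logFC": row.logFC,
                            "peak_status": peak_status.get(pk, "unchanged"),
                            "peak_logFC": peak_logfc.get(pk, np.nan),
                        }
                    )
    net = pd.DataFrame(
        rows,
        columns=[
            "anchor1", "anchor2", "peak", "gene_id", "interaction_class",
            "di_logFC", "peak_status", "peak_logFC",
        ],
    ).drop_duplicates(subset=["anchor1", "anchor2", "peak", "gene_id"])
    return net.reset_index(drop=True)


def coupling_tests(net: pd.DataFrame, de: pd.DataFrame, unit: str = "link") -> dict:
    """Fisher tests coupling interaction classes with gene regulation.

    Builds gained-vs-rest x up-vs-rest and lost-vs-rest x down-vs-rest 2x2
    tables, plus the class composition (fraction up/down/unchanged genes per
    interaction class).  ``unit='link'`` counts one unit per interaction-gene
    link; ``unit='gene'`` collapses to unique genes (linked-to-class vs not),
    which makes units exchangeable under gene-label permutation.
    """
    de = de.rename(columns={"feature": "gene_id"})
    gene_status = dict(zip(de["gene_id"], de["status"]))
    links = net.drop_duplicates(subset=["anchor1", "anchor2", "gene_id"]).copy()
    links["gene_status"] = links["gene_id"].map(gene_status).fillna("unchanged")
    comp = {}
    for icl, grp in links.groupby("interaction_class"):
        frac = grp["gene_status"].value_counts(normalize=True).to_dict()
        comp[icl] = {k: float(frac.get(k, 0.0)) for k in ("up", "down", "unchanged")}
    if unit == "gene":
        by_gene = links.groupby("gene_id")["interaction_class"].agg(set)
        links = pd.DataFrame(
            {
                "gene_id": by_gene.index,
                "classes": by_gene.values,
            }
        )
        links["gene_status"] = links["gene_id"].map(gene_status).fillna("unchanged")
    elif unit != "link":
        raise ValueError("unit must be 'link' or 'gene'")
    out: dict = {"n_links": len(links), "unit": unit}
    out["composition"] = comp
    for icl, gcl in (("gained", "up"), ("lost", "down")):
        if unit == "gene":
            in_class = links["classes"].apply(lambda s: icl in s)
        else:
            in_class = links["interaction_class"] == icl
        a = (in_class & (links["gene_status"] == gcl)).sum()
        b = (in_class & (links["gene_status"] != gcl)).sum()
        c = (~in_class & (links["gene_status"] == gcl)).sum()
        d = (~in_class & (links["gene_status"] != gcl)).sum()
        table = np.array([[a, b], [c, d]])
        entry = {"table": table}
        if table.sum() and min(table.sum(axis=0).min(), table.sum(axis=1).min()) > 0:
            odds, p = fisher_exact_2x2(table)
            entry["odds_ratio"] = odds
            entry["p"] = p
        else:
            entry["degenerate"] = True
        out[f"{icl}_x_{gcl}"] = entry
    return out


def accessibility_by_interaction_class(net: pd.DataFrame) -> dict:
    """Distributions of member-peak accessibility logFC per interaction
    class, with pairwise Wilcoxon comparisons."""
    out: dict = {"distributions": {}, "wilcoxon": {}}
    per_class = {}
    for icl, grp in net.drop_duplicates(subset=["anchor1", "anchor2", "peak"]).groupby(
        "interaction_class"
    ):
        vals = grp["peak_logFC"].to_numpy(float)
        vals = vals[~np.isnan(vals)]
        if len(vals):
            per_class[icl] = vals
    out["distributions"] = per_class
    for a, b in (("gained", "lost"), ("gained", "unchanged")):
        if a in per_class and b in per_class:
            _, p = wilcoxon_rank_sum(per_class[a], per_class[b])
            out["wilcoxon"][f"{a} vs {b}"] = p
    return out


def erna_analysis(
    erna_counts: CountMatrix,
    peaks: pd.DataFrame,
    exons: pd.DataFrame,
    genome_totals: np.ndarray,
    design,
    contrast,
    da: pd.DataFrame,
    cpm_threshold: float = 0.5,
    min_samples: int = 2,
) -> dict:
    """Differential eRNA expression over non-exonic peaks.

    Library sizes are fixed to total genome-aligned reads; regions below the
    CPM filter are dropped; TMM factors normalize composition; differential
    expression uses the precision-weighted moderated t pipeline.  eRNA logFC
    is compared between peaks gaining and losing accessibility.
    """
    use = peaks.rename(columns={"name": "peak"})
    hits = overlap_query(
        use[["chrom", "start", "end"]],
        exons.rename(columns={"exon_start": "start", "exon_end": "end"})[
            ["chrom", "start", "end"]
        ],
    )
    exonic = np.array([len(h) > 0 for h in hits])
    if exonic.any():
        raise ValueError(
            f"{int(exonic.sum())} peaks overlap annotated exons; "
            "eRNA analysis requires non-exonic peaks"
        )
    genome_totals = np.asarray(genome_totals, float)
    keep = cpm_filter(erna_counts, cpm_threshold, min_samples, lib_sizes=genome_totals)
    sub = erna_counts.subset(keep)
    factors = tmm_factors(
        CountMatrix(sub.counts, list(sub.samples), lib_sizes=genome_totals)
    )
    tab = voom_weighted_lm(
        sub, design, contrast, lib_sizes=genome_totals * factors
    )
    tab = tab.rename(columns={"feature": "peak"})
    da = da.rename(columns={"feature": "peak"})
    status = dict(zip(da["peak"], da["status"]))
    tab["da_status"] = tab["peak"].map(status).fillna("unchanged")
    gained = tab.loc[tab["da_status"] == "up", "logFC"].to_numpy()
    lost = tab.loc[tab["da_status"] == "down", "logFC"].to_numpy()
    out = {"table": tab, "n_expressed": int(keep.sum())}
    if len(gained) and len(lost):
        _, p = wilcoxon_rank_sum(gained, lost)
        out["gained_vs_lost_p"] = p
        out["median_logfc_gained"] = float(np.median(gained))
        out["median_logfc_lost"] = float(np.median(lost))
    return out
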