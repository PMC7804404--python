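"""High-level pipeline runners tying the analysis stages together.

Each runner takes simulated (or fixture-loaded) inputs plus a sample sheet
and returns the stage's result tables.  The command-line interface and the
acceptance machinery are thin wrappers around these functions.
"""
from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from . import compartments as comp
from . import hic, integrate, tads
from .genome import BinTable, make_bins, read_bed, read_gene_table
from .stats import (
    CountMatrix,
    cpm_filter,
    make_design,
    tmm_factors,
    voom_weighted_lm,
)

__all__ = [
    "run_di_pipeline",
    "run_tad_pipeline",
    "run_dtb_pipeline",
    "run_compartment_pipeline",
    "run_expression",
    "run_accessibility",
    "load_fixtures",
    "FixtureData",
]


def _design(samples: pd.DataFrame, factors=("condition", "lineage", "donor")):
    return make_design(samples, factors=factors, contrast="condition")


def run_di_pipeline(
    reads: dict[str, pd.DataFrame],
    chrom_sizes: dict[str, int],
    samples: pd.DataFrame,
    bin_width: int = 25_000,
    fold: float = 6.0,
    near_cutoff: float | None = None,
    max_cluster_size: float | None = None,
    blacklist: pd.DataFrame | None = None,
    exclude_chroms: tuple[str, ...] = (),
    factors=("condition", "lineage", "donor"),
) -> dict:
    """Read pairs -> filtered bin pairs -> DI table -> clusters -> span stats."""
    if near_cutoff is None:
        near_cutoff = 100_000 if bin_width <= 25_000 else 150_000
    if max_cluster_size is None:
        max_cluster_size = 500_000 if bin_width <= 25_000 else 1_000_000
    bins = make_bins(chrom_sizes, bin_width)
    bp, inter = hic.count_bin_pairs(reads, bins)
    background = hic.background_ligation_frequency(reads, chrom_sizes)
    fbp = hic.filter_bin_pairs(
        bp, background, fold=fold, blacklist=blacklist, exclude_chroms=exclude_chroms
    )
    fbp.offsets = hic.loess_offsets(fbp, near_cutoff=near_cutoff)
    X, cvec = _design(samples, factors)
    order = [list(reads).index(s) for s in samples["sample"]]
    fbp_ordered = hic.BinPairCounts(
        bins=fbp.bins,
        anchor1=fbp.anchor1,
        anchor2=fbp.anchor2,
        counts=fbp.counts[:, order],
        samples=[fbp.samples[i] for i in order],
        lib_sizes=fbp.lib_sizes[order],
        offsets=fbp.offsets[:, order],
    )
    di = hic.test_differential_interactions(fbp_ordered, X, cvec)
    clusters = hic.cluster_differential_interactions(di, bins, max_size=max_cluster_size)
    span = hic.interaction_span_contrast(di)
    return {
        "bins": bins,
        "bin_pairs": bp,
        "filtered": fbp_ordered,
        "background": background,
        "di": di,
        "clusters": clusters,
        "span": span,
    }


def run_tad_pipeline(
    reads: dict[str, pd.DataFrame],
    chrom_sizes: dict[str, int],
    samples: pd.DataFrame,
    bin_width: int = 50_000,
    window: int = 10,
    prominence: float = 0.5,
    frac: float = 0.75,
) -> dict:
    """Per-condition TAD calls from summed replicate matrices + intersections."""
    bins = make_bins(chrom_sizes, bin_width)
    bp, _ = hic.count_bin_pairs(reads, bins)
    conditions = list(dict.fromkeys(samples["condition"]))
    tadsets = {}
    profiles = {}
    for cond in conditions:
        ss = list(samples[samples["condition"] == cond]["sample"])
        profs = {
            c: tads.insulation_profile(hic.contact_matrix(bp, c, ss), window)
            for c in bins.chroms
        }
        profiles[cond] = profs
        tadsets[cond] = tads.call_tads(profs, bins, min_depth=prominence, condition=cond)
    out = {"bins": bins, "bin_pairs": bp, "tadsets": tadsets, "profiles": profiles}
    if len(conditions) == 2:
        out["intersection"] = tads.tad_intersection_stats(
            tadsets[conditions[0]], tadsets[conditions[1]], frac=frac
        )
    return out


def run_dtb_pipeline(
    reads: dict[str, pd.DataFrame],
    samples: pd.DataFrame,
    tadsets: dict,
    bin_width: int = 50_000,
    flank: int = 1_000_000,
    min_logcpm: float = 0.8,
    factors=("donor", "lineage"),
) -> dict:
    """Differential boundary strength over the union of called boundaries."""
    rows = set()
    for ts in tadsets.values():
        for _, r in ts.boundaries.iterrows():
            rows.add((r["chrom"], int(r["pos"]), int(r["pos"]) + bin_width))
    regions = pd.DataFrame(sorted(rows), columns=["chrom", "start", "end"])
    bct = tads.boundary_updown_counts(reads, regions, flank=flank, bin_width=bin_width)
    dtb = tads.test_boundary_strength(
        bct, samples, min_logcpm=min_logcpm, factors=factors
    )
    return {"regions": regions, "counts": bct, "dtb": dtb}


def run_compartment_pipeline(
    reads: dict[str, pd.DataFrame],
    chrom_sizes: dict[str, int],
    samples: pd.DataFrame,
    orientation: dict,
    bin_width: int = 50_000,
) -> dict:
    """Per-condition compartment tracks and the between-condition flip table."""
    bins = make_bins(chrom_sizes, bin_width)
    bp, _ = hic.count_bin_pairs(reads, bins)
    conditions = list(dict.fromkeys(samples["condition"]))
    tracks, mats = {}, {}
    for cond in conditions:
        ss = list(samples[samples["condition"] == cond]["sample"])
        mats[cond] = {c: hic.contact_matrix(bp, c, ss) for c in bins.chroms}
        tracks[cond] = comp.call_compartments(
            mats[cond], orientation[cond], bins, condition=cond
        )
    out = {"bins": bins, "tracks": tracks, "matrices": mats}
    if len(conditions) == 2:
        a, b = conditions
        flips = {}
        for c in bins.chroms:
            flips[c] = comp.classify_flips(
                tracks[a][c], tracks[b][c], mats[a][c], mats[b][c]
            )
        out["flips"] = flips
    return out


def run_expression(
    cm: CountMatrix,
    samples: pd.DataFrame,
    cpm_threshold: float = 1.5,
    min_samples: int = 2,
    factors=("condition", "lineage", "donor"),
    fdr_threshold: float = 0.05,
) -> dict:
    """Filter, TMM, voom + moderated t differential expression."""
    keep = cpm_filter(cm, cpm_threshold, min_samples)
    sub = cm.subset(keep)
    sub.norm_factors = tmm_factors(sub)
    X, cvec = _design(samples, factors)
    tab = voom_weighted_lm(sub, X, cvec)
    tab["status"] = np.where(
        tab["fdr"] < fdr_threshold,
        np.where(tab["logFC"] > 0, "up", "down"),
        "unchanged",
    )
    return {"expressed_mask": keep, "table": tab}


def run_accessibility(
    cm: CountMatrix,
    samples: pd.DataFrame,
    factors=("condition", "lineage", "donor"),
    fdr_threshold: float = 0.05,
) -> dict:
    """TMM + QL F-test differential accessibility."""
    X, cvec = _design(samples, factors)
    tab = integrate.test_differential_accessibility(
        cm, X, cvec, fdr_threshold=fdr_threshold
    )
    return {"table": tab}


# ---------------------------------------------------------------------------
# fixture loading
# ---------------------------------------------------------------------------


@dataclass
class FixtureData:
    manifest: dict
    samples: pd.DataFrame
    chrom_sizes: dict[str, int]
    reads: dict[str, pd.DataFrame]
    rna_counts: CountMatrix
    atac_counts: CountMatrix
    genes: pd.DataFrame
    peaks: pd.DataFrame
    occupancy: pd.DataFrame | None


def _read_counts(path: str, lib_sizes=None) -> CountMatrix:
    df = pd.read_csv(path, sep="\t")
    feats = df["feature"].to_numpy()
    counts = df.drop(columns=["feature"]).to_numpy()
    return CountMatrix(
        counts=counts,
        samples=list(df.columns[1:]),
        feature_ids=feats,
        lib_sizes=lib_sizes,
    )


def load_fixtures(fixture_dir: str) -> FixtureData:
    """Load a fixture tree written by ``write_fixture_set``."""
    with open(os.path.join(fixture_dir, "manifest.yaml")) as fh:
        manifest = yaml.safe_load(fh)
    samples = pd.DataFrame(manifest["samples"])
    reads = {
        s: pd.read_csv(os.path.join(fixture_dir, f"hic_{s}.tsv"), sep="\t")
        for s in samples["sample"]
    }
    occ_path = os.path.join(fixture_dir, "occupancy.bedgraph")
    occupancy = None
    if os.path.exists(occ_path):
        occupancy = pd.read_csv(
            occ_path, sep="\t", names=["chrom", "start", "end", "score"]
        )
    return FixtureData(
        manifest=manifest,
        samples=samples,
        chrom_sizes=manifest["chrom_sizes"],
        reads=reads,
        rna_counts=_read_counts(os.path.join(fixture_dir, "rna_counts.tsv")),
        atac_counts=_read_counts(os.path.join(fixture_dir, "atac_counts.tsv")),
        genes=read_gene_table(os.path.join(fixture_dir, "genes.tsv")),
        peaks=read_bed(os.path.join(fixture_dir, "peaks.bed")),
        occupancy=occupancy,
    )
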