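"""From Hi-C read pairs to clustered differential interactions.

Read pairs are counted into fixed-width intra-chromosomal bin pairs; a
background ligation frequency estimated from inter-chromosomal 2 Mb bin
pairs sets the retention floor; bin pairs are filtered, normalized with
distance-stratified LOESS offsets, tested for differential intensity with
the NB quasi-likelihood framework, and significant bin pairs are aggregated
into interaction-space clusters with Simes combined p-values and
cluster-level FDR control.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

from .genome import BinTable
from .stats import (
    CountMatrix,
    DispersionFit,
    bh_adjust,
    estimate_dispersion_trend,
    ql_test,
    simes_p,
)

__all__ = [
    "BinPairCounts",
    "BackgroundEstimate",
    "count_bin_pairs",
    "background_ligation_frequency",
    "filter_bin_pairs",
    "loess_offsets",
    "test_differential_interactions",
    "cluster_differential_interactions",
    "interaction_span_contrast",
    "contact_matrix",
]


@dataclass
class BinPairCounts:
    """Sparse intra-chromosomal bin-pair x sample count table.

    ``anchor1 <= anchor2`` are global bin indices on the same chromosome.
    ``lib_sizes`` are total input read pairs per sample (intra + inter), so
    abundances are comparable with the inter-chromosomal background.
    """

    bins: BinTable
    anchor1: np.ndarray
    anchor2: np.ndarray
    counts: np.ndarray  # pairs x samples
    samples: list[str]
    lib_sizes: np.ndarray
    offsets: np.ndarray | None = None

    def __post_init__(self):
        if (self.anchor1 > self.anchor2).any():
            raise ValueError("anchor1 must be <= anchor2")
        chrom1 = self.bins.chrom_of(self.anchor1)
        chrom2 = self.bins.chrom_of(self.anchor2)
        if (chrom1 != chrom2).any():
            raise ValueError("bin pairs must be intra-chromosomal")

    @property
    def n_pairs(self) -> int:
        return len(self.anchor1)

    @property
    def gap(self) -> np.ndarray:
        return np.abs(self.bins.mids(self.anchor2) - self.bins.mids(self.anchor1))

    def ave_log_cpm(self) -> np.ndarray:
        tot = self.counts.sum(axis=1)
        return np.log2((tot + 0.5) / self.lib_sizes.sum() * 1e6)

    def to_count_matrix(self) -> CountMatrix:
        ids = np.array(
            [f"{a1}:{a2}" for a1, a2 in zip(self.anchor1, self.anchor2)]
        )
        return CountMatrix(
            counts=self.counts,
            samples=list(self.samples),
            feature_ids=ids,
            lib_sizes=self.lib_sizes.copy(),
            offsets=None if self.offsets is None else self.offsets.copy(),
        )

    def subset(self, mask: np.ndarray) -> "BinPairCounts":
        return BinPairCounts(
            bins=self.bins,
            anchor1=self.anchor1[mask],
            anchor2=self.anchor2[mask],
            counts=self.counts[mask],
            samples=list(self.samples),
            lib_sizes=self.lib_sizes.copy(),
            offsets=None if self.offsets is None else self.offsets[mask],
        )


def count_bin_pairs(
    read_pairs: dict[str, pd.DataFrame],
    bins: BinTable,
) -> tuple[BinPairCounts, dict[str, pd.DataFrame]]:
    """Count read pairs into intra-chromosomal bin pairs per sample.

    Returns the bin-pair count table (anchors ordered, union of non-zero
    pairs across samples) and the inter-chromosomal read pairs per sample,
    which feed the background ligation estimator rather than the table.
    """
    samples = list(read_pairs)
    keys_per_sample = []
    inter: dict[str, pd.DataFrame] = {}
    nb = bins.n_bins
    for s in samples:
        df = read_pairs[s]
        intra_mask = (df["chrom1"] == df["chrom2"]).to_numpy()
        intra = df[intra_mask]
        inter[s] = df[~intra_mask].reset_index(drop=True)
        b1 = bins.assign(intra["chrom1"].to_numpy(), intra["pos1"].to_numpy())
        b2 = bins.assign(intra["chrom2"].to_numpy(), intra["pos2"].to_numpy())
        a1 = np.minimum(b1, b2)
        a2 = np.maximum(b1, b2)
        keys_per_sample.append(a1.astype(np.int64) * nb + a2)
    allkeys = np.unique(np.concatenate(keys_per_sample)) if keys_per_sample else np.array([], np.int64)
    counts = np.zeros((len(allkeys), len(samples)), dtype=np.int64)
    for si, keys in enumerate(keys_per_sample):
        uk, cnt = np.unique(keys, return_counts=True)
        counts[np.searchsorted(allkeys, uk), si] = cnt
    lib = np.array([len(read_pairs[s]) for s in samples], dtype=float)
    return (
        BinPairCounts(
            bins=bins,
            anchor1=(allkeys // nb).astype(np.int64),
            anchor2=(allkeys % nb).astype(np.int64),
            counts=counts,
            samples=samples,
            lib_sizes=lib,
        ),
        inter,
    )


@dataclass
class BackgroundEstimate:
    """Average abundance (logCPM) of inter-chromosomal 2 Mb bin pairs."""

    log_cpm_2mb: float
    bin_width: int
    total_lib: float

    def scaled_to(self, width: int) -> float:
        """Background abundance rescaled to a smaller bin-pair area."""
        return self.log_cpm_2mb - 2.0 * np.log2(self.bin_width / width)


def background_ligation_frequency(
    read_pairs: dict[str, pd.DataFrame],
    chrom_sizes: dict[str, int],
    bin_width: int = 2_000_000,
) -> BackgroundEstimate:
    """Estimate background ligation frequency from inter-chromosomal pairs.

    The mean count per inter-chromosomal ``bin_width`` bin pair (over all
    possible such pairs, summed across samples) is expressed as log2 CPM of
    the total library size.
    """
    if len(chrom_sizes) < 2:
        raise ValueError("cannot estimate background: need >= 2 chromosomes")
    nb = {c: -(-L // bin_width) for c, L in chrom_sizes.items()}
    chroms = list(chrom_sizes)
    n_inter_pairs = 0
    for a in range(len(chroms)):
        for b in range(a + 1, len(chroms)):
            n_inter_pairs += nb[chroms[a]] * nb[chroms[b]]
    total_inter = 0
    total_lib = 0
    for s, df in read_pairs.items():
        total_lib += len(df)
        total_inter += int((df["chrom1"] != df["chrom2"]).sum())
    if total_inter == 0:
        raise ValueError("cannot estimate background: no inter-chromosomal pairs")
    mean_count = total_inter / n_inter_pairs
    return BackgroundEstimate(
        log_cpm_2mb=float(np.log2((mean_count + 0.5) / total_lib * 1e6)),
        bin_width=bin_width,
        total_lib=float(total_lib),
    )


def filter_bin_pairs(
    bp: BinPairCounts,
    background: BackgroundEstimate,
    fold: float = 6.0,
    blacklist: pd.DataFrame | None = None,
    exclude_chroms: tuple[str, ...] = (),
    min_bin_count: int = 5,
    diag_width: int = 1,
) -> BinPairCounts:
    """Retain bin pairs clear of the diagonal, blacklist and background.

    Filters, in order: anchors on excluded chromosomes; anchors in bins
    touched by blacklist regions; anchors in bins whose marginal count
    (summed over samples) is below ``min_bin_count``; first-diagonal pairs
    (|anchor1 - anchor2| <= ``diag_width``); and abundance not more than
    ``fold``-fold above the background ligation frequency (strict).
    """
    keep = np.ones(bp.n_pairs, dtype=bool)
    chrom1 = bp.bins.chrom_of(bp.anchor1)
    if exclude_chroms:
        keep &= ~np.isin(chrom1, list(exclude_chroms))
    if blacklist is not None and len(blacklist):
        bad_bins = set()
        for row in blacklist.itertuples(index=False):
            if row.chrom not in bp.bins.chroms:
                continue
            lo, hi = bp.bins.index_range(row.chrom)
            first = lo + int(row.start) // bp.bins.width
            last = lo + (int(row.end) - 1) // bp.bins.width
            bad_bins.update(range(first, min(last, hi - 1) + 1))
        if bad_bins:
            bad = np.array(sorted(bad_bins))
            keep &= ~np.isin(bp.anchor1, bad) & ~np.isin(bp.anchor2, bad)
    if min_bin_count > 0:
        marginal = np.zeros(bp.bins.n_bins, dtype=np.int64)
        tot = bp.counts.sum(axis=1)
        np.add.at(marginal, bp.anchor1, tot)
        diag = bp.anchor1 == bp.anchor2
        np.add.at(marginal, bp.anchor2[~diag], tot[~diag])
        low = marginal < min_bin_count
        keep &= ~low[bp.anchor1] & ~low[bp.anchor2]
    keep &= (bp.anchor2 - bp.anchor1) > diag_width
    threshold = background.scaled_to(bp.bins.width) + np.log2(fold)
    keep &= bp.ave_log_cpm() > threshold
    return bp.subset(keep)


def loess_offsets(
    bp: BinPairCounts,
    near_cutoff: float = 100_000,
    span: float = 0.3,
    iterations: int = 3,
    min_stratum: int = 50,
) -> np.ndarray:
    """Abundance-dependent normalization offsets (natural-log scale).

    Within each distance stratum (gap below/above ``near_cutoff``), each
    sample's deviation of log2 counts from the bin-pair mean is regressed on
    average abundance by robust LOESS; fitted curves are row-centred and
    shifted so the mean offset per bin pair equals the mean log library size.
    """
    if len(bp.samples) < 2:
        raise ValueError("need >= 2 samples to normalize")
    lc = np.log2(bp.counts + 0.5)
    mean_lc = lc.mean(axis=1, keepdims=True)
    dev = lc - mean_lc
    abund = bp.ave_log_cpm()
    fitted = np.zeros_like(dev)
    gap = bp.gap
    for stratum_mask in (gap < near_cutoff, gap >= near_cutoff):
        m = int(stratum_mask.sum())
        if m == 0:
            continue
        if m < min_stratum:
            warnings.warn(
                f"stratum with {m} bin pairs: falling back to median offsets"
            )
            fitted[stratum_mask] = np.median(dev[stratum_mask], axis=0, keepdims=True)
            continue
        x = abund[stratum_mask]
        if np.ptp(x) < 1e-8:
            fitted[stratum_mask] = dev[stratum_mask].mean(axis=0, keepdims=True)
            continue
        for si in range(dev.shape[1]):
            fitted[stratum_mask, si] = _sm_lowess(
                dev[stratum_mask, si], x, frac=span, it=iterations,
                return_sorted=False,
            )
    fitted = fitted - fitted.mean(axis=1, keepdims=True)
    offsets = fitted * np.log(2.0) + np.mean(np.log(bp.lib_sizes))
    return offsets


def test_differential_interactions(
    bp: BinPairCounts,
    design,
    contrast,
    dispfit: DispersionFit | None = None,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """QL F-test per bin pair; DI = FDR below threshold, signed by logFC."""
    cm = bp.to_count_matrix()
    if dispfit is None:
        from .stats import _resolve_contrast

        X, _ = _resolve_contrast(design, contrast)
        dispfit = estimate_dispersion_trend(cm, X)
    tab = ql_test(cm, design, contrast, dispfit=dispfit)
    tab = tab.drop(columns=["feature"])
    tab.insert(0, "anchor1", bp.anchor1)
    tab.insert(1, "anchor2", bp.anchor2)
    tab.insert(2, "chrom", bp.bins.chrom_of(bp.anchor1))
    tab["span"] = bp.gap
    tab["significant"] = tab["fdr"] < fdr_threshold
    tab["direction"] = np.where(tab["logFC"] > 0, "gained", "lost")
    return tab


def _connected_components(a1, a2, tol=1):
    """Union-find over bin pairs adjacent within Chebyshev distance tol."""
    n = len(a1)
    parent = np.arange(n)

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    index = {}
    for k in range(n):
        index.setdefault((a1[k], a2[k]), []).append(k)
    for k in range(n):
        for da in range(-tol, tol + 1):
            for db in range(-tol, tol + 1):
                for other in index.get((a1[k] + da, a2[k] + db), []):
                    union(k, other)
    roots = np.array([find(k) for k in range(n)])
    _, labels = np.unique(roots, return_inverse=True)
    return labels


def _split_oversized(members, a1, a2, max_bins):
    """Recursively bisect clusters whose bounding box exceeds max_bins."""
    out = []
    stack = [members]
    while stack:
        mem = stack.pop()
        s1 = a1[mem].max() - a1[mem].min() + 1
        s2 = a2[mem].max() - a2[mem].min() + 1
        if (s1 <= max_bins and s2 <= max_bins) or len(mem) == 1:
            out.append(mem)
            continue
        if s1 >= s2:
            coord = a1[mem]
        else:
            coord = a2[mem]
        mid = (coord.max() + coord.min() + 1) / 2.0
        left = mem[coord < mid]
        right = mem[coord >= mid]
        if len(left) == 0 or len(right) == 0:  # degenerate; accept as-is
            out.append(mem)
            continue
        stack.extend([left, right])
    return out


def cluster_differential_interactions(
    di: pd.DataFrame,
    bins: BinTable,
    max_size: float = 500_000,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Aggregate significant bin pairs into interaction-space clusters.

    Membership threshold is the BH threshold at ``fdr`` on the bin-pair
    p-values; members adjacent in interaction space (Chebyshev distance <= 1
    bin) join a cluster, clusters are bisected until no bounding-box side
    exceeds ``max_size``; the combined p per cluster is Simes' over members
    and the cluster-level FDR is BH over combined p-values.
    """
    sig = di[di["fdr"] < fdr]
    if len(sig) == 0:
        return pd.DataFrame(
            columns=[
                "cluster", "chrom", "start1", "end1", "start2", "end2",
                "n_members", "combined_p", "cluster_fdr", "best_anchor1",
                "best_anchor2", "best_p", "direction", "members",
            ]
        )
    max_bins = max(1, int(max_size // bins.width))
    rows = []
    cid = 0
    for chrom, grp in sig.groupby("chrom", sort=False):
        a1 = grp["anchor1"].to_numpy()
        a2 = grp["anchor2"].to_numpy()
        labels = _connected_components(a1, a2)
        for lab in np.unique(labels):
            mem = np.flatnonzero(labels == lab)
            for cluster_members in _split_oversized(mem, a1, a2, max_bins):
                sub = grp.iloc[cluster_members]
                p = sub["p"].to_numpy()
                best = int(np.argmin(p))
                lo, _ = bins.index_range(chrom)
                rows.append(
                    {
                        "cluster": cid,
                        "chrom": chrom,
                        "start1": int((sub["anchor1"].min() - lo) * bins.width),
                        "end1": int((sub["anchor1"].max() - lo + 1) * bins.width),
                        "start2": int((sub["anchor2"].min() - lo) * bins.width),
                        "end2": int((sub["anchor2"].max() - lo + 1) * bins.width),
                        "n_members": len(sub),
                        "combined_p": simes_p(p),
                        "best_anchor1": int(sub["anchor1"].iloc[best]),
                        "best_anchor2": int(sub["anchor2"].iloc[best]),
                        "best_p": float(p[best]),
                        "direction": "gained"
                        if (sub["logFC"] > 0).mean() >= 0.5
                        else "lost",
                        "members": sub.index.to_numpy(),
                    }
                )
                cid += 1
    out = pd.DataFrame(rows)
    out["cluster_fdr"] = bh_adjust(out["combined_p"].to_numpy())
    return out


def interaction_span_contrast(di: pd.DataFrame) -> dict:
    """Welch t contrast of interaction spans, gained vs lost DIs."""
    sig = di[di["significant"]]
    gained = sig.loc[sig["direction"] == "gained", "span"].to_numpy()
    lost = sig.loc[sig["direction"] == "lost", "span"].to_numpy()
    out = {
        "n_gained": len(gained),
        "n_lost": len(lost),
        "mean_span_gained": float(gained.mean()) if len(gained) else np.nan,
        "mean_span_lost": float(lost.mean()) if len(lost) else np.nan,
    }
    if len(gained) >= 2 and len(lost) >= 2:
        t, p = sps.ttest_ind(gained, lost, equal_var=False)
        out["t"] = float(t)
        out["p"] = float(p)
    else:
        out["t"] = np.nan
        out["p"] = np.nan
        out["undefined"] = True
    return out


def contact_matrix(
    bp: BinPairCounts,
    chrom: str,
    samples: list[str] | None = None,
) -> np.ndarray:
    """Inflate bin-pair counts into a dense symmetric per-chromosome matrix,
    summed over the requested samples."""
    lo, hi = bp.bins.index_range(chrom)
    n = hi - lo
    cols = (
        np.arange(len(bp.samples))
        if samples is None
        else np.array([bp.samples.index(s) for s in samples])
    )
    m = np.zeros((n, n))
    sel = (bp.anchor1 >= lo) & (bp.anchor1 < hi)
    i = bp.anchor1[sel] - lo
    j = bp.anchor2[sel] - lo
    v = bp.counts[np.ix_(sel, cols)].sum(axis=1)
    m[i, j] = v
    m[j, i] = v
    return m
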