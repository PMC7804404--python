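"""Synthetic multi-omic data with planted chromatin architecture.

Generates Hi-C read pairs, ATAC peak counts, RNA gene counts and auxiliary
tracks for a two-donor, resting/activated, CD4/CD8 T-cell style design, with
exported truth tables so that every downstream statistic can be scored
against planted ground truth.

The contact model is multiplicative on a uniform bin grid: a power-law decay
with distance, an enrichment factor for bin pairs inside the same TAD, an
attenuation across TAD boundaries proportional to the strongest boundary
crossed, a same-compartment enrichment for checkerboard A/B labels, and
per-loop intensity multipliers.  Counts are negative-binomially distributed
around library-size-scaled expectations with a per-donor random effect, and
a configurable fraction of read pairs is inter-chromosomal background
ligation noise.

Defaults are desk-scale: a few tens of Mb of genome and a few million read
pairs per sample, chosen so that each planted effect is recoverable by the
corresponding pipeline stage at that depth.
"""
from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .genome import BinTable, make_bins
from .stats import CountMatrix

__all__ = [
    "ArchitectureSpec",
    "OmicsSpec",
    "TruthTables",
    "Scenario",
    "simulate_contact_reads",
    "simulate_feature_counts",
    "build_activation_scenario",
    "build_null_scenario",
    "simulate_hic_samples",
    "write_fixture_set",
]


# ---------------------------------------------------------------------------
# specifications
# ---------------------------------------------------------------------------


@dataclass
class ArchitectureSpec:
    """Generative description of one condition's chromatin architecture."""

    chrom_sizes: dict[str, int]
    bin_width: int = 25_000
    decay_exponent: float = 1.0
    tad_factor: float = 3.0
    comp_factor: float = 1.5
    background_rate: float = 0.15  # fraction of pairs that are trans ligation noise
    insulation_range: int = 2_000_000  # boundary attenuation is local to the diagonal
    tad_breakpoints: dict[str, np.ndarray] = field(default_factory=dict)
    boundary_strengths: dict[str, np.ndarray] = field(default_factory=dict)
    compartment_labels: dict[str, np.ndarray] = field(default_factory=dict)
    loops: pd.DataFrame | None = None  # chrom, bin1, bin2, mult

    def __post_init__(self):
        for c, bp in self.tad_breakpoints.items():
            bp = np.asarray(bp)
            if (np.diff(bp) <= 0).any():
                raise ValueError(f"breakpoints not sorted on {c}")
            n = -(-self.chrom_sizes[c] // self.bin_width)
            if len(bp) and (bp[0] <= 0 or bp[-1] >= n):
                raise ValueError(f"breakpoint outside chromosome {c}")
            st = np.asarray(self.boundary_strengths.get(c, np.ones(len(bp))), float)
            if (st < 1.0).any():
                raise ValueError("boundary strengths must be >= 1")
            self.tad_breakpoints[c] = bp
            self.boundary_strengths[c] = st
        if self.loops is not None and len(self.loops):
            if (self.loops["mult"] <= 0).any():
                raise ValueError("loop multipliers must be positive")

    @property
    def bins(self) -> BinTable:
        return make_bins(self.chrom_sizes, self.bin_width)


@dataclass
class OmicsSpec:
    """Feature-count generative parameters for one assay.

    ``features`` carries per-feature annotation including the planted
    ``true_logfc`` (log2, activated vs resting) and baseline proportions.
    """

    features: pd.DataFrame  # feature, chrom, pos(, strand), baseline, true_logfc
    samples: pd.DataFrame  # sample, condition, lineage, donor
    lib_sizes: np.ndarray
    dispersion: float = 0.05
    donor_effect_sd: float = 0.1  # log2 scale

    def __post_init__(self):
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        counts = self.samples.groupby("condition").size()
        if (counts < 2).any():
            raise ValueError("need >= 2 samples per condition")


@dataclass
class TruthTables:
    loops: pd.DataFrame         # chrom, bin1, bin2, class, peak, gene
    boundaries: pd.DataFrame    # chrom, bin, class (strengthened/weakened/stable/new)
    compartments: pd.DataFrame  # chrom, bin50, label_resting, label_activated, flipped
    genes: pd.DataFrame         # gene, status, true_logfc
    peaks: pd.DataFrame         # peak, status, true_logfc


@dataclass
class Scenario:
    name: str
    base_seed: int
    specs: dict[str, ArchitectureSpec]  # per condition
    samples: pd.DataFrame               # sample, condition, lineage, donor, depth
    genes: pd.DataFrame                 # gene_id, chrom, tss, strand, exon_start, exon_end, baseline, true_logfc
    peaks: pd.DataFrame                 # name, chrom, start, end, baseline, true_logfc
    truth: TruthTables
    rna_lib_sizes: np.ndarray
    atac_lib_sizes: np.ndarray
    dispersion: float
    donor_effect_sd: float
    occupancy: pd.DataFrame | None = None      # chrom, start, end, score (50 kb bins)
    # per condition, per chromosome: ATAC-coverage-like orientation covariate
    # on the 50 kb grid (elevated in A compartment)
    orientation: dict | None = None
    erna_coupling: float = 0.8

    def omics_spec(self, assay: str) -> OmicsSpec:
        if assay == "rna":
            feats = self.genes.rename(columns={"gene_id": "feature", "tss": "pos"})
            libs = self.rna_lib_sizes
        elif assay == "atac":
            feats = self.peaks.rename(columns={"name": "feature", "start": "pos"})
            libs = self.atac_lib_sizes
        elif assay == "erna":
            # RNA reads over peaks: low baseline, logFC coupled to accessibility
            feats = self.peaks.rename(columns={"name": "feature", "start": "pos"})
            feats = feats.assign(
                baseline=feats["erna_baseline"], true_logfc=feats["erna_logfc"]
            )
            libs = self.rna_lib_sizes
        else:
            raise ValueError(f"unknown assay {assay!r}")
        return OmicsSpec(
            features=feats,
            samples=self.samples,
            lib_sizes=libs,
            dispersion=self.dispersion,
            donor_effect_sd=self.donor_effect_sd,
        )


# ---------------------------------------------------------------------------
# contact-map simulation
# ---------------------------------------------------------------------------


def _tad_ids(spec: ArchitectureSpec, chrom: str, n: int) -> np.ndarray:
    bp = spec.tad_breakpoints.get(chrom, np.array([], dtype=int))
    return np.searchsorted(bp, np.arange(n), side="right")


def _boundary_max_strength(spec: ArchitectureSpec, chrom: str) -> np.ndarray:
    """T x T table of the max boundary strength between TAD t1 and t2 (t1<t2)."""
    st = spec.boundary_strengths.get(chrom, np.array([]))
    t = len(st) + 1
    out = np.ones((t, t))
    for a in range(t):
        if a < len(st):
            out[a, a + 1 :] = np.maximum.accumulate(st[a:])
    return np.maximum(out, out.T)


def intensity_table(spec: ArchitectureSpec, chrom: str):
    """Upper-triangle (i, j, relative intensity) for one chromosome."""
    n = spec.bins.nbins(chrom)
    i, j = np.triu_indices(n)
    d = (j - i).astype(float)
    inten = (d + 1.0) ** (-spec.decay_exponent)
    tid = _tad_ids(spec, chrom, n)
    same_tad = tid[i] == tid[j]
    smax = _boundary_max_strength(spec, chrom)
    cross = smax[tid[i], tid[j]]
    # insulation attenuates contacts only near the diagonal; far-field
    # intensity is decay x compartment structure, as in real contact maps
    local = d * spec.bin_width < spec.insulation_range
    inten *= np.where(same_tad, spec.tad_factor,
                      np.where(local, 1.0 / cross, 1.0))
    labels = spec.compartment_labels.get(chrom)
    if labels is not None:
        labels = np.asarray(labels)
        inten *= np.where(labels[i] == labels[j], spec.comp_factor, 1.0)
    if spec.loops is not None and len(spec.loops):
        sel = spec.loops[spec.loops["chrom"] == chrom]
        if len(sel):
            key = i.astype(np.int64) * n + j
            lkey = sel["bin1"].to_numpy(np.int64) * n + sel["bin2"].to_numpy(np.int64)
            pos = np.searchsorted(key, lkey)
            ok = (pos < len(key)) & (key[np.minimum(pos, len(key) - 1)] == lkey)
            inten[pos[ok]] *= sel["mult"].to_numpy(float)[ok]
    return i, j, inten


def _draw_counts(rng, mean, dispersion):
    mean = np.maximum(mean, 1e-12)
    if dispersion <= 0:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    return rng.negative_binomial(r, r / (r + mean))


def simulate_contact_reads(
    spec: ArchitectureSpec,
    depth: float,
    seed: int,
    dispersion: float = 0.05,
    log2_bias: dict[str, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Simulate one Hi-C library as a read-pair table (chrom1,pos1,chrom2,pos2).

    Intra-chromosomal expectations follow the spec's multiplicative contact
    model scaled to ``depth * (1 - background_rate)``; inter-chromosomal
    background ligation pairs are Poisson and uniform over chromosome pairs.
    ``log2_bias`` optionally supplies a per-bin-pair multiplicative bias
    (upper-triangle order) per chromosome, e.g. a donor batch effect.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = np.random.default_rng(seed)
    bins = spec.bins
    chroms = list(spec.chrom_sizes)
    tabs = {}
    total_inten = 0.0
    for c in chroms:
        i, j, inten = intensity_table(spec, c)
        if log2_bias is not None and c in log2_bias:
            inten = inten * 2.0 ** np.asarray(log2_bias[c], float)
        tabs[c] = (i, j, inten)
        total_inten += inten.sum()
    intra_depth = depth * (1.0 - spec.background_rate)
    frames = []
    width = spec.bin_width
    for c in chroms:
        i, j, inten = tabs[c]
        mean = inten * (intra_depth / total_inten)
        cnt = _draw_counts(rng, mean, dispersion)
        nz = cnt > 0
        if not nz.any():
            continue
        ii = np.repeat(i[nz], cnt[nz])
        jj = np.repeat(j[nz], cnt[nz])
        L = spec.chrom_sizes[c]
        w1 = np.minimum((ii + 1) * width, L) - ii * width
        w2 = np.minimum((jj + 1) * width, L) - jj * width
        pos1 = ii * width + rng.integers(0, w1)
        pos2 = jj * width + rng.integers(0, w2)
        frames.append(
            pd.DataFrame(
                {"chrom1": c, "pos1": pos1, "chrom2": c, "pos2": pos2}
            )
        )
    # inter-chromosomal background ligation
    if len(chroms) > 1 and spec.background_rate > 0:
        sizes = np.array([spec.chrom_sizes[c] for c in chroms], dtype=float)
        pair_w = []
        pair_idx = []
        for a in range(len(chroms)):
            for b in range(a + 1, len(chroms)):
                pair_idx.append((a, b))
                pair_w.append(sizes[a] * sizes[b])
        pair_w = np.array(pair_w)
        n_inter = rng.poisson(depth * spec.background_rate)
        alloc = rng.multinomial(n_inter, pair_w / pair_w.sum())
        for (a, b), k in zip(pair_idx, alloc):
            if k == 0:
                continue
            frames.append(
                pd.DataFrame(
                    {
                        "chrom1": chroms[a],
                        "pos1": rng.integers(0, spec.chrom_sizes[chroms[a]], k),
                        "chrom2": chroms[b],
                        "pos2": rng.integers(0, spec.chrom_sizes[chroms[b]], k),
                    }
                )
            )
    if not frames:
        import warnings

        warnings.warn("depth too small: no read pairs generated")
        return pd.DataFrame(columns=["chrom1", "pos1", "chrom2", "pos2"])
    out = pd.concat(frames, ignore_index=True)
    out["pos1"] = out["pos1"].astype(np.int64)
    out["pos2"] = out["pos2"].astype(np.int64)
    return out


def _sample_seed(base_seed: int, tag: str) -> int:
    h = hashlib.sha256(f"{base_seed}:{tag}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31)


def simulate_hic_samples(scenario: Scenario, seed: int | None = None) -> dict[str, pd.DataFrame]:
    """Simulate all Hi-C libraries of a scenario, with shared donor biases."""
    base = scenario.base_seed if seed is None else seed
    donors = list(dict.fromkeys(scenario.samples["donor"]))
    any_spec = next(iter(scenario.specs.values()))
    donor_bias: dict[str, dict[str, np.ndarray]] = {}
    sd = scenario.donor_effect_sd
    for d in donors:
        rng = np.random.default_rng(_sample_seed(base, f"hic-donor-{d}"))
        donor_bias[d] = {}
        for c in any_spec.chrom_sizes:
            n = any_spec.bins.nbins(c)
            npair = n * (n + 1) // 2
            donor_bias[d][c] = rng.normal(0.0, sd, npair) if sd > 0 else np.zeros(npair)
    out = {}
    for row in scenario.samples.itertuples(index=False):
        spec = scenario.specs[row.condition]
        out[row.sample] = simulate_contact_reads(
            spec,
            depth=row.depth,
            seed=_sample_seed(base, f"hic-{row.sample}"),
            dispersion=scenario.dispersion,
            log2_bias=donor_bias[row.donor],
        )
    return out


# ---------------------------------------------------------------------------
# feature-count simulation
# ---------------------------------------------------------------------------


def simulate_feature_counts(spec: OmicsSpec, seed: int) -> tuple[CountMatrix, pd.DataFrame]:
    """NB feature counts for a design, with truth columns.

    mean = lib_size * baseline * 2^(condition_logfc + donor_effect); the donor
    effect is an additive log2 random intercept per (donor, feature).
    """
    rng = np.random.default_rng(seed)
    feats = spec.features
    g = len(feats)
    samples = spec.samples
    n = len(samples)
    base = feats["baseline"].to_numpy(float)
    base = base / base.sum()
    logfc = feats["true_logfc"].to_numpy(float)
    donors = list(dict.fromkeys(samples["donor"]))
    donor_eff = {
        d: (rng.normal(0.0, spec.donor_effect_sd, g) if spec.donor_effect_sd > 0 else np.zeros(g))
        for d in donors
    }
    counts = np.empty((g, n), dtype=np.int64)
    for s in range(n):
        cond = samples["condition"].iloc[s]
        x = 1.0 if cond == "activated" else 0.0
        eff = logfc * x + donor_eff[samples["donor"].iloc[s]]
        mean = spec.lib_sizes[s] * base * 2.0**eff
        counts[:, s] = _draw_counts(rng, mean, spec.dispersion)
    cm = CountMatrix(
        counts=counts,
        samples=list(samples["sample"]),
        feature_ids=feats["feature"].to_numpy(),
        lib_sizes=np.asarray(spec.lib_sizes, float),
    )
    truth = pd.DataFrame(
        {
            "feature": feats["feature"],
            "true_logfc": logfc,
            "status": np.where(logfc > 0, "up", np.where(logfc < 0, "down", "unchanged")),
        }
    )
    return cm, truth


# ---------------------------------------------------------------------------
# scenario builders
# ---------------------------------------------------------------------------


def _make_tads(rng, n_bins, min_bins, max_bins, align=2):
    """Random TAD breakpoints (bin indices) aligned to a sub-grid."""
    bps = []
    pos = 0
    while True:
        size = int(rng.integers(min_bins // align, max_bins // align + 1)) * align
        pos += max(size, align)
        if pos >= n_bins - min_bins // 2:
            break
        bps.append(pos)
    return np.array(bps, dtype=int)


def _checkerboard(rng, n_bins, block=20):
    phase = int(rng.integers(0, 2))
    lab = ((np.arange(n_bins) // block + phase) % 2) * 2 - 1
    return lab.astype(int)  # +1 = A, -1 = B


def _sample_sheet(depth, n_donors=2, lineages=("CD4", "CD8")) -> pd.DataFrame:
    rows = []
    for lin in lineages:
        for d in range(1, n_donors + 1):
            for cond in ("resting", "activated"):
                rows.append(
                    {
                        "sample": f"{lin}_{cond}_d{d}",
                        "condition": cond,
                        "lineage": lin,
                        "donor": f"d{d}",
                        "depth": float(depth),
                    }
                )
    return pd.DataFrame(rows)


def build_activation_scenario(
    base_seed: int,
    chrom_sizes: dict[str, int] | None = None,
    bin_width: int = 25_000,
    depth: float = 5e6,
    lineages=("CD4", "CD8"),
    split_fraction: float = 0.5,
    strengthen_fraction: float = 0.2,
    weaken_fraction: float = 0.2,
    flip_fraction: float = 0.015,
    n_loops: int = 200,
    loop_mult: float = 4.0,
    loop_gap_gained=(6, 20),
    loop_gap_lost=(20, 48),
    n_genes: int = 2000,
    n_peaks: int = 3000,
    fraction_de: float = 0.2,
    fraction_da: float = 0.2,
    effect_logfc: float = 2.0,
    dispersion: float = 0.05,
    donor_effect_sd: float = 0.1,
    boundary_strength: float = 3.0,
    compartment_block_50kb: int = 40,
) -> Scenario:
    """Resting/activated scenario with planted TAD splits, boundary changes,
    compartment flips, and gained/lost loops wired to DA peaks and DE genes.

    Activation (a) splits ``split_fraction`` of resting TADs at an internal
    boundary, (b) strengthens/weakens boundary subsets by ``boundary_strength``,
    (c) flips ``flip_fraction`` of compartment bins, and (d) adds gained loops
    whose anchors hold an up DA peak and an up DE gene's promoter (lost loops
    are wired to down-regulated features).  All couplings land in the truth
    tables.
    """
    for frac in (split_fraction, strengthen_fraction, weaken_fraction, flip_fraction,
                 fraction_de, fraction_da):
        if not 0.0 <= frac <= 1.0:
            raise ValueError("fractions must lie in [0, 1]")
    if chrom_sizes is None:
        chrom_sizes = {"chrA": 20_000_000, "chrB": 15_000_000}
    rng = np.random.default_rng(_sample_seed(base_seed, "architecture"))
    bins = make_bins(chrom_sizes, bin_width)
    per50 = max(1, 50_000 // bin_width)  # bins per 50 kb unit
    # --- TADs (mean ~1 Mb) with 50 kb aligned breakpoints
    tad_bp, strengths_rest, strengths_act = {}, {}, {}
    boundary_rows = []
    split_rows = []
    for c in chrom_sizes:
        n = bins.nbins(c)
        bp = _make_tads(rng, n, min_bins=600_000 // bin_width,
                        max_bins=1_400_000 // bin_width, align=per50)
        st_rest = np.ones(len(bp))
        role = np.array(["stable"] * len(bp), dtype=object)
        k = len(bp)
        n_str = int(round(strengthen_fraction * k))
        n_wk = int(round(weaken_fraction * k))
        pick = rng.permutation(k)
        role[pick[:n_str]] = "strengthened"
        role[pick[n_str : n_str + n_wk]] = "weakened"
        st_rest[role == "weakened"] = boundary_strength
        st_act = st_rest.copy()
        st_act[role == "strengthened"] = boundary_strength
        st_act[role == "weakened"] = 1.0
        tad_bp[c] = bp
        strengths_rest[c] = st_rest
        strengths_act[c] = st_act
        for b, r in zip(bp, role):
            boundary_rows.append({"chrom": c, "bin": int(b), "class": r})
        # TAD splits: new internal boundaries in the activated condition
        edges = np.concatenate([[0], bp, [n]])
        tad_list = list(zip(edges[:-1], edges[1:]))
        n_split = int(round(split_fraction * len(tad_list)))
        # keep new boundaries clear of chromosome ends, where insulation
        # profiles are undefined for any window-based caller
        margin = 600_000 // bin_width
        for t in rng.permutation(len(tad_list))[:n_split]:
            lo, hi = tad_list[t]
            if hi - lo < 4 * per50:
                continue
            units = np.arange(lo // per50 + 1, hi // per50)
            units = units[(units * per50 >= margin) & (units * per50 <= n - margin)]
            if not len(units):
                continue
            newbp = int(units[len(units) // 2]) * per50
            split_rows.append({"chrom": c, "bin": newbp, "class": "new"})
    # merge split boundaries into the activated breakpoint lists
    act_bp, act_st = {}, {}
    for c in chrom_sizes:
        extra = sorted(r["bin"] for r in split_rows if r["chrom"] == c)
        allbp = np.sort(np.concatenate([tad_bp[c], np.array(extra, dtype=int)]))
        stmap = dict(zip(tad_bp[c], strengths_act[c]))
        act_bp[c] = allbp
        act_st[c] = np.array([stmap.get(b, boundary_strength) for b in allbp])
    boundary_rows.extend(split_rows)
    boundaries = pd.DataFrame(boundary_rows, columns=["chrom", "bin", "class"])
    # --- compartments: checkerboard; flip a fraction of 50 kb units
    comp_rest, comp_act = {}, {}
    comp_rows = []
    for c in chrom_sizes:
        n = bins.nbins(c)
        n50 = n // per50
        lab50 = _checkerboard(rng, n50, block=compartment_block_50kb)
        lab_rest = np.repeat(lab50, per50)[:n]
        if len(lab_rest) < n:
            lab_rest = np.concatenate([lab_rest, [lab50[-1]] * (n - len(lab_rest))])
        lab_act50 = lab50.copy()
        n_flip = int(round(flip_fraction * n50))
        flip_units = rng.permutation(n50)[:n_flip]
        lab_act50[flip_units] *= -1
        lab_act = np.repeat(lab_act50, per50)[:n]
        if len(lab_act) < n:
            lab_act = np.concatenate([lab_act, [lab_act50[-1]] * (n - len(lab_act))])
        comp_rest[c] = lab_rest
        comp_act[c] = lab_act
        for u in range(n50):
            comp_rows.append(
                {
                    "chrom": c,
                    "bin50": u,
                    "label_resting": "A" if lab50[u] > 0 else "B",
                    "label_activated": "A" if lab_act50[u] > 0 else "B",
                    "flipped": bool(u in set(flip_units)),
                }
            )
    compartments = pd.DataFrame(comp_rows)
    # --- loops, coupled genes and peaks
    half = n_loops // 2
    loop_rows = []
    used_bins: set[tuple[str, int]] = set()
    chrom_names = list(chrom_sizes)
    chrom_weights = np.array([bins.nbins(c) for c in chrom_names], float)
    chrom_weights /= chrom_weights.sum()
    tad_edges = {}
    for c in chrom_sizes:
        e = np.concatenate([[0], tad_bp[c], [bins.nbins(c)]])
        tad_edges[c] = list(zip(e[:-1], e[1:]))
    attempt = 0
    while len(loop_rows) < n_loops and attempt < n_loops * 50:
        attempt += 1
        kind = "gained" if len(loop_rows) < half else "lost"
        gap_rng = loop_gap_gained if kind == "gained" else loop_gap_lost
        c = chrom_names[rng.choice(len(chrom_names), p=chrom_weights)]
        n = bins.nbins(c)
        gap = int(rng.integers(gap_rng[0], gap_rng[1] + 1))
        if gap >= n - 2:
            continue
        # prefer intra-TAD anchors (higher baseline, CTCF-loop-like spans)
        fitting = [t for t in tad_edges[c] if t[1] - t[0] > gap + 2]
        if fitting:
            lo, hi = fitting[int(rng.integers(0, len(fitting)))]
            b1 = int(rng.integers(lo + 1, hi - gap - 1))
        else:
            b1 = int(rng.integers(1, n - gap - 1))
        b2 = b1 + gap
        if (c, b1) in used_bins or (c, b2) in used_bins:
            continue
        used_bins.update({(c, b1), (c, b2)})
        loop_rows.append({"chrom": c, "bin1": b1, "bin2": b2, "class": kind})
    loops_truth = pd.DataFrame(
        loop_rows, columns=["chrom", "bin1", "bin2", "class"]
    )
    loops_rest = loops_truth.assign(
        mult=np.where(loops_truth["class"] == "lost", loop_mult, 1.0)
    )[["chrom", "bin1", "bin2", "mult"]]
    loops_act = loops_truth.assign(
        mult=np.where(loops_truth["class"] == "gained", loop_mult, 1.0)
    )[["chrom", "bin1", "bin2", "mult"]]
    loops_rest = loops_rest[loops_rest["mult"] != 1.0].reset_index(drop=True)
    loops_act = loops_act[loops_act["mult"] != 1.0].reset_index(drop=True)
    # genes: coupled ones at loop anchors (bin2), the rest uniform
    gene_rows = []
    for k, row in loops_truth.iterrows():
        tss = int(row["bin2"]) * bin_width + bin_width // 2
        strand = "+" if rng.random() < 0.5 else "-"
        fc = effect_logfc if row["class"] == "gained" else -effect_logfc
        gene_rows.append(
            {"gene_id": f"g{k:05d}", "chrom": row["chrom"], "tss": tss,
             "strand": strand, "true_logfc": fc, "coupled_loop": int(k)}
        )
    k0 = len(gene_rows)
    for k in range(k0, n_genes):
        c = chrom_names[rng.choice(len(chrom_names), p=chrom_weights)]
        tss = int(rng.integers(2_000, chrom_sizes[c] - 2_000))
        de = rng.random() < fraction_de
        sign = 1.0 if rng.random() < 0.5 else -1.0
        gene_rows.append(
            {"gene_id": f"g{k:05d}", "chrom": c, "tss": tss,
             "strand": "+" if rng.random() < 0.5 else "-",
             "true_logfc": sign * effect_logfc if de else 0.0, "coupled_loop": -1}
        )
    genes = pd.DataFrame(gene_rows)
    genes["exon_start"] = np.where(
        genes["strand"] == "+", genes["tss"], genes["tss"] - 1500
    ).clip(min=0)
    genes["exon_end"] = genes["exon_start"] + 1500
    genes["baseline"] = rng.lognormal(0.0, 1.2, len(genes))
    # peaks: coupled ones at loop anchors (bin1), the rest uniform & non-exonic
    peak_rows = []
    for k, row in loops_truth.iterrows():
        start = int(row["bin1"]) * bin_width + bin_width // 2 - 250
        fc = effect_logfc if row["class"] == "gained" else -effect_logfc
        peak_rows.append(
            {"name": f"p{k:05d}", "chrom": row["chrom"], "start": start,
             "end": start + 500, "true_logfc": fc, "coupled_loop": int(k)}
        )
    k0 = len(peak_rows)
    exon_iv = {
        c: grp[["exon_start", "exon_end"]].to_numpy()
        for c, grp in genes.groupby("chrom")
    }
    k = k0
    while k < n_peaks:
        c = chrom_names[rng.choice(len(chrom_names), p=chrom_weights)]
        start = int(rng.integers(0, chrom_sizes[c] - 500))
        iv = exon_iv.get(c)
        if iv is not None and ((start < iv[:, 1]) & (start + 500 > iv[:, 0])).any():
            continue
        da = rng.random() < fraction_da
        sign = 1.0 if rng.random() < 0.5 else -1.0
        peak_rows.append(
            {"name": f"p{k:05d}", "chrom": c, "start": start, "end": start + 500,
             "true_logfc": sign * effect_logfc if da else 0.0, "coupled_loop": -1}
        )
        k += 1
    peaks = pd.DataFrame(peak_rows)
    peaks["baseline"] = rng.lognormal(0.0, 1.0, len(peaks))
    # compartment-flip coupling: features in flipped 50 kb units follow the flip
    for c in chrom_sizes:
        sub = compartments[(compartments["chrom"] == c) & compartments["flipped"]]
        for u, to_label in zip(sub["bin50"], sub["label_activated"]):
            lo, hi = u * 50_000, (u + 1) * 50_000
            fc = effect_logfc if to_label == "A" else -effect_logfc
            gm = (genes["chrom"] == c) & (genes["tss"] >= lo) & (genes["tss"] < hi) & (genes["coupled_loop"] < 0)
            genes.loc[gm, "true_logfc"] = fc
            pm = (peaks["chrom"] == c) & (peaks["start"] >= lo) & (peaks["start"] < hi) & (peaks["coupled_loop"] < 0)
            peaks.loc[pm, "true_logfc"] = fc
    # boundary-proximal coupling: weakened boundaries sit in regions that gain
    # accessibility and expression on activation; strengthened and newly
    # formed boundaries in regions that lose both
    bnd_window = 100_000
    for _, row in boundaries.iterrows():
        pos = int(row["bin"]) * bin_width
        lo, hi = pos - bnd_window, pos + bnd_window
        if row["class"] == "weakened":
            fc = effect_logfc
        elif row["class"] in ("strengthened", "new"):
            fc = -effect_logfc
        else:
            continue
        gm = (genes["chrom"] == row["chrom"]) & (genes["tss"] >= lo) & (genes["tss"] < hi) & (genes["coupled_loop"] < 0)
        genes.loc[gm, "true_logfc"] = fc
        pm = (peaks["chrom"] == row["chrom"]) & (peaks["start"] >= lo) & (peaks["start"] < hi) & (peaks["coupled_loop"] < 0)
        peaks.loc[pm, "true_logfc"] = fc
    # eRNA transcription over peaks: weak baseline, logFC coupled to DA
    erna_coupling = 0.8
    peaks["erna_baseline"] = rng.lognormal(-1.0, 1.0, len(peaks))
    peaks["erna_logfc"] = erna_coupling * peaks["true_logfc"] + rng.normal(
        0.0, 0.3, len(peaks)
    )
    # occupancy track on the 50 kb grid: elevated at strengthened boundaries
    occ_rows = []
    for c in chrom_sizes:
        n50 = bins.nbins(c) // per50
        score = rng.normal(0.5, 0.03, n50)
        # newly formed and strengthened boundaries carry elevated occupancy
        sub = boundaries[
            (boundaries["chrom"] == c)
            & boundaries["class"].isin(["strengthened", "new"])
        ]
        for b in sub["bin"]:
            u = int(b) // per50
            if u < n50:
                score[u] += 0.2
        for u in range(n50):
            occ_rows.append(
                {"chrom": c, "start": u * 50_000, "end": (u + 1) * 50_000,
                 "score": float(score[u])}
            )
    occupancy = pd.DataFrame(occ_rows)
    # orientation covariate: ATAC-like coverage per 50 kb bin, open in A
    rng_ori = np.random.default_rng(_sample_seed(base_seed, "orientation"))
    orientation: dict[str, dict[str, np.ndarray]] = {}
    for cond, labs in (("resting", comp_rest), ("activated", comp_act)):
        orientation[cond] = {}
        for c in chrom_sizes:
            n50 = bins.nbins(c) // per50
            lab50 = labs[c][::per50][:n50]
            orientation[cond][c] = (
                2.0 + (lab50 > 0) * 1.0 + rng_ori.normal(0.0, 0.2, n50)
            )
    truth = TruthTables(
        loops=loops_truth.assign(
            peak=[f"p{k:05d}" for k in range(len(loops_truth))],
            gene=[f"g{k:05d}" for k in range(len(loops_truth))],
        ),
        boundaries=boundaries,
        compartments=compartments,
        genes=genes[["gene_id", "true_logfc"]].assign(
            status=np.where(genes["true_logfc"] > 0, "up",
                            np.where(genes["true_logfc"] < 0, "down", "unchanged"))
        ),
        peaks=peaks[["name", "true_logfc"]].assign(
            status=np.where(peaks["true_logfc"] > 0, "up",
                            np.where(peaks["true_logfc"] < 0, "down", "unchanged"))
        ),
    )
    spec_rest = ArchitectureSpec(
        chrom_sizes=chrom_sizes, bin_width=bin_width,
        tad_breakpoints={c: tad_bp[c].copy() for c in chrom_sizes},
        boundary_strengths=strengths_rest,
        compartment_labels=comp_rest, loops=loops_rest,
    )
    spec_act = ArchitectureSpec(
        chrom_sizes=chrom_sizes, bin_width=bin_width,
        tad_breakpoints=act_bp, boundary_strengths=act_st,
        compartment_labels=comp_act, loops=loops_act,
    )
    samples = _sample_sheet(depth, lineages=lineages)
    rng2 = np.random.default_rng(_sample_seed(base_seed, "libsizes"))
    nsamp = len(samples)
    return Scenario(
        name="activation",
        base_seed=base_seed,
        specs={"resting": spec_rest, "activated": spec_act},
        samples=samples,
        genes=genes,
        peaks=peaks,
        truth=truth,
        rna_lib_sizes=rng2.uniform(8e6, 12e6, nsamp),
        atac_lib_sizes=rng2.uniform(12e6, 18e6, nsamp),
        dispersion=dispersion,
        donor_effect_sd=donor_effect_sd,
        occupancy=occupancy,
        orientation=orientation,
    )


def build_null_scenario(
    base_seed: int,
    chrom_sizes: dict[str, int] | None = None,
    bin_width: int = 25_000,
    depth: float = 5e6,
    lineages=("CD4",),
    n_genes: int = 5000,
    n_peaks: int = 5000,
    dispersion: float = 0.05,
    donor_effect_sd: float = 0.1,
    background_rate: float = 0.25,
) -> Scenario:
    """Scenario with no planted differences: identical architecture and zero
    true log-fold-changes in both conditions.  Drives type-I-error checks."""
    scen = build_activation_scenario(
        base_seed,
        chrom_sizes=chrom_sizes or {"chrA": 7_000_000, "chrB": 7_000_000},
        bin_width=bin_width,
        depth=depth,
        lineages=lineages,
        split_fraction=0.0,
        strengthen_fraction=0.0,
        weaken_fraction=0.0,
        flip_fraction=0.0,
        n_loops=0,
        n_genes=n_genes,
        n_peaks=n_peaks,
        fraction_de=0.0,
        fraction_da=0.0,
        dispersion=dispersion,
        donor_effect_sd=donor_effect_sd,
    )
    for spec in scen.specs.values():
        spec.background_rate = background_rate
    scen.name = "null"
    return scen


# ---------------------------------------------------------------------------
# fixture writing
# ---------------------------------------------------------------------------


def write_fixture_set(scenario: Scenario, out_dir, force: bool = False) -> dict:
    """Write read-pair tables, count matrices, annotations, tracks, truth
    tables and a manifest to ``out_dir``; returns the path map."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    if os.listdir(out_dir) and not force:
        raise FileExistsError(f"{out_dir} is not empty (use force=True)")
    paths = {}
    reads = simulate_hic_samples(scenario)
    for s, df in reads.items():
        p = os.path.join(out_dir, f"hic_{s}.tsv")
        df.to_csv(p, sep="\t", index=False)
        paths[f"hic_{s}"] = p
    for assay in ("rna", "atac"):
        cm, truth = simulate_feature_counts(
            scenario.omics_spec(assay), _sample_seed(scenario.base_seed, assay)
        )
        tab = pd.DataFrame(cm.counts, columns=cm.samples)
        tab.insert(0, "feature", cm.feature_ids)
        p = os.path.join(out_dir, f"{assay}_counts.tsv")
        tab.to_csv(p, sep="\t", index=False)
        paths[f"{assay}_counts"] = p
    gcols = ["gene_id", "chrom", "tss", "strand", "exon_start", "exon_end"]
    scenario.genes[gcols].to_csv(os.path.join(out_dir, "genes.tsv"), sep="\t", index=False)
    paths["genes"] = os.path.join(out_dir, "genes.tsv")
    with open(os.path.join(out_dir, "peaks.bed"), "w") as fh:
        for r in scenario.peaks.itertuples(index=False):
            fh.write(f"{r.chrom}\t{int(r.start)}\t{int(r.end)}\t{r.name}\n")
    paths["peaks"] = os.path.join(out_dir, "peaks.bed")
    if scenario.occupancy is not None:
        with open(os.path.join(out_dir, "occupancy.bedgraph"), "w") as fh:
            for r in scenario.occupancy.itertuples(index=False):
                fh.write(f"{r.chrom}\t{int(r.start)}\t{int(r.end)}\t{r.score:.6f}\n")
        paths["occupancy"] = os.path.join(out_dir, "occupancy.bedgraph")
    truthdir = os.path.join(out_dir, "truth")
    os.makedirs(truthdir, exist_ok=True)
    for name in ("loops", "boundaries", "compartments", "genes", "peaks"):
        tdf = getattr(scenario.truth, name)
        p = os.path.join(truthdir, f"{name}.tsv")
        tdf.to_csv(p, sep="\t", index=False)
        paths[f"truth_{name}"] = p
    any_spec = next(iter(scenario.specs.values()))
    manifest = {
        "name": scenario.name,
        "base_seed": int(scenario.base_seed),
        "bin_width": int(any_spec.bin_width),
        "chrom_sizes": {c: int(v) for c, v in any_spec.chrom_sizes.items()},
        "dispersion": float(scenario.dispersion),
        "donor_effect_sd": float(scenario.donor_effect_sd),
        "background_rate": float(any_spec.background_rate),
        "decay_exponent": float(any_spec.decay_exponent),
        "tad_factor": float(any_spec.tad_factor),
        "comp_factor": float(any_spec.comp_factor),
        "samples": scenario.samples.to_dict(orient="records"),
    }
    with open(os.path.join(out_dir, "manifest.yaml"), "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    paths["manifest"] = os.path.join(out_dir, "manifest.yaml")
    return paths
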