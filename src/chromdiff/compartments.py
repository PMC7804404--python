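"""A/B compartment scores and flip classification.

Per chromosome, the observed/expected contact matrix (expected = mean count
per diagonal) is turned into a Pearson correlation matrix; the leading
eigenvector of that matrix is the compartment score, oriented so that it
correlates positively with an open-chromatin covariate (A = positive).
Between conditions, a bin flips compartment when its A/B label changes AND
the correlation between its observed/expected interaction profiles in the
two conditions is negative.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg

from .genome import BinTable
from .stats import wilcoxon_rank_sum

__all__ = [
    "CompartmentTrack",
    "observed_expected",
    "observed_expected_correlation",
    "compartment_scores",
    "classify_flips",
    "flip_feature_stats",
    "call_compartments",
]


@dataclass
class CompartmentTrack:
    """Per-bin PC1 score and A/B label for one chromosome and condition."""

    chrom: str
    condition: str
    score: np.ndarray   # NaN for masked bins
    label: np.ndarray   # 'A' / 'B' / '' for masked
    weak_structure: bool = False


def observed_expected(contacts: np.ndarray, min_informative: int = 10):
    """O/E matrix and valid-bin mask.

    Expected is the mean count per diagonal; entries on empty diagonals are
    NaN; bins with fewer than ``min_informative`` nonzero contacts are masked.
    """
    m = np.asarray(contacts, dtype=float)
    n = m.shape[0]
    if m.sum() <= 0:
        raise ValueError("all-zero contact matrix")
    exp = np.zeros((n, n))
    for d in range(n):
        mu = np.mean(np.diagonal(m, d))
        idx = np.arange(n - d)
        exp[idx, idx + d] = mu
        exp[idx + d, idx] = mu
    with np.errstate(divide="ignore", invalid="ignore"):
        oe = np.where(exp > 0, m / exp, np.nan)
    valid = (m > 0).sum(axis=1) >= min_informative
    oe[~valid, :] = np.nan
    oe[:, ~valid] = np.nan
    return oe, valid


def observed_expected_correlation(
    contacts: np.ndarray, min_informative: int = 10
):
    """Pearson correlation matrix of O/E columns over non-missing entries.

    Returns (corr, valid); corr rows/cols of masked bins are NaN.  A matrix
    whose O/E is constant (already equal to its expectation) is flagged
    degenerate by returning an all-NaN correlation.
    """
    oe, valid = observed_expected(contacts, min_informative)
    n = oe.shape[0]
    corr = np.full((n, n), np.nan)
    idx = np.flatnonzero(valid)
    if len(idx) < 3:
        return corr, valid
    sub = oe[np.ix_(idx, idx)]
    sub = np.where(np.isnan(sub), np.nanmean(sub, axis=0, keepdims=True), sub)
    sd = sub.std(axis=0)
    if np.all(sd < 1e-12):
        return corr, valid
    with np.errstate(invalid="ignore"):
        c = np.corrcoef(sub, rowvar=False)
    corr[np.ix_(idx, idx)] = c
    return corr, valid


def compartment_scores(
    corr: np.ndarray,
    orientation: np.ndarray,
    valid: np.ndarray | None = None,
    chrom: str = "",
    condition: str = "",
    weak_tol: float = 0.05,
) -> CompartmentTrack:
    """PC1 of the correlation matrix, sign-oriented by an open-chromatin
    covariate; label A where the score is positive.

    A warning flag is set when the leading eigenvalue barely dominates the
    second (no clear compartment structure).
    """
    n = corr.shape[0]
    if valid is None:
        valid = ~np.isnan(corr).all(axis=1)
    idx = np.flatnonzero(valid)
    score = np.full(n, np.nan)
    label = np.array([""] * n, dtype=object)
    weak = False
    if len(idx) >= 3:
        sub = corr[np.ix_(idx, idx)]
        sub = np.nan_to_num(sub, nan=0.0)
        sub = 0.5 * (sub + sub.T)
        w, v = linalg.eigh(sub, subset_by_index=(len(idx) - 2, len(idx) - 1))
        pc1 = v[:, -1]
        weak = bool((w[-1] - w[-2]) < weak_tol * max(abs(w[-1]), 1e-12))
        ori = np.asarray(orientation, dtype=float)[idx]
        ok = ~np.isnan(ori)
        if ok.sum() >= 2 and np.ptp(ori[ok]) > 0:
            r = np.corrcoef(pc1[ok], ori[ok])[0, 1]
            if r < 0:
                pc1 = -pc1
        score[idx] = pc1
        label[idx] = np.where(pc1 > 0, "A", "B")
    return CompartmentTrack(
        chrom=chrom, condition=condition, score=score, label=label,
        weak_structure=weak,
    )


def _profile_correlations(
    oe_a: np.ndarray, oe_b: np.ndarray, exclude_bins: int = 40
) -> np.ndarray:
    """Per-bin Pearson correlation between O/E profiles of two conditions.

    Entries within ``exclude_bins`` of the profile's own bin are excluded:
    domain-scale structure near the diagonal is shared between conditions and
    carries no compartment information.
    """
    n = oe_a.shape[0]
    out = np.full(n, np.nan)
    pos = np.arange(n)
    for i in range(n):
        a, b = oe_a[i], oe_b[i]
        ok = ~np.isnan(a) & ~np.isnan(b) & (np.abs(pos - i) >= exclude_bins)
        if ok.sum() >= 3 and a[ok].std() > 0 and b[ok].std() > 0:
            out[i] = np.corrcoef(a[ok], b[ok])[0, 1]
    return out


def classify_flips(
    track_rest: CompartmentTrack,
    track_act: CompartmentTrack,
    contacts_rest: np.ndarray,
    contacts_act: np.ndarray,
    min_informative: int = 10,
    require_label_change: bool = True,
    exclude_bins: int = 40,
) -> pd.DataFrame:
    """Per-bin flip classification between two conditions.

    class is the label pair (e.g. 'A->B'); ``profile_corr`` is the Pearson
    correlation of the bin's O/E interaction profile between conditions; the
    flip flag requires a label change AND a negative profile correlation
    (set ``require_label_change=False`` for the correlation-only criterion).
    """
    oe_r, _ = observed_expected(contacts_rest, min_informative)
    oe_a, _ = observed_expected(contacts_act, min_informative)
    pcorr = _profile_correlations(oe_r, oe_a, exclude_bins)
    lab_r = track_rest.label
    lab_a = track_act.label
    n = len(lab_r)
    cls = np.array([""] * n, dtype=object)
    for i in range(n):
        if lab_r[i] and lab_a[i]:
            cls[i] = f"{lab_r[i]}->{lab_a[i]}"
    changed = np.array([c in ("A->B", "B->A") for c in cls])
    neg = np.nan_to_num(pcorr, nan=1.0) < 0
    flip = (changed & neg) if require_label_change else neg & (cls != "")
    return pd.DataFrame(
        {
            "bin": np.arange(n),
            "class": cls,
            "profile_corr": pcorr,
            "flip": flip,
        }
    )


def flip_feature_stats(
    flips: pd.DataFrame,
    accessibility_logfc: np.ndarray | None = None,
    expression_logfc: np.ndarray | None = None,
) -> dict:
    """Per-class distributions of accessibility/expression log fold changes
    with pairwise Wilcoxon tests (classes without members are skipped)."""
    out: dict = {}
    classes = ("A->A", "B->B", "A->B", "B->A")
    for name, vals in (
        ("accessibility", accessibility_logfc),
        ("expression", expression_logfc),
    ):
        if vals is None:
            continue
        vals = np.asarray(vals, dtype=float)
        dists = {}
        for c in classes:
            m = (flips["class"] == c).to_numpy() & ~np.isnan(vals)
            if m.any():
                dists[c] = vals[m]
        tests = {}
        pairs = [("B->A", "A->B"), ("B->A", "A->A"), ("A->B", "B->B")]
        for a, b in pairs:
            if a in dists and b in dists:
                _, p = wilcoxon_rank_sum(dists[a], dists[b])
                tests[f"{a} vs {b}"] = p
        out[name] = {"distributions": dists, "wilcoxon": tests}
    return out


def call_compartments(
    matrices: dict[str, np.ndarray],
    orientation: dict[str, np.ndarray],
    bins: BinTable,
    condition: str = "",
    min_informative: int = 10,
) -> dict[str, CompartmentTrack]:
    """Compartment tracks for all chromosomes of one condition.

    ``matrices`` maps chromosome to its (summed-replicate) contact matrix and
    ``orientation`` to the per-bin open-chromatin covariate.
    """
    out = {}
    for chrom, m in matrices.items():
        corr, valid = observed_expected_correlation(m, min_informative)
        out[chrom] = compartment_scores(
            corr, orientation[chrom], valid, chrom=chrom, condition=condition
        )
    return out
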