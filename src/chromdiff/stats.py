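"""Count-based statistical engine.

Implements the shared machinery used by every differential analysis in the
package: TMM normalization, CPM filtering, negative-binomial GLMs with
quasi-likelihood (QL) dispersion moderation and F-tests, voom-style
precision-weighted linear models with moderated t-statistics, BH multiple
testing, Simes combination, and small-sample utility tests.

The QL framework follows its published description: per-feature NB GLMs are
fitted with a trended dispersion, the QL dispersion is the residual deviance
divided by its degrees of freedom, and the QL dispersions are squeezed toward
a second abundance trend by empirical Bayes, estimating the prior degrees of
freedom from winsorized moments of the log residual variances.  Exact
numerical agreement with any particular implementation of this framework is
not a goal; the distributional properties (null uniformity, moderation
limits) are the contract.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, special
from scipy import stats as sps
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CountMatrix",
    "DispersionFit",
    "tmm_factors",
    "cpm_filter",
    "fit_nb_glm",
    "nb_deviance",
    "estimate_dispersion_trend",
    "ql_test",
    "bh_adjust",
    "simes_p",
    "voom_weighted_lm",
    "leading_logfc_distance",
    "fisher_exact_2x2",
    "wilcoxon_rank_sum",
    "make_design",
    "squeeze_variances",
]

_LN2 = np.log(2.0)


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class CountMatrix:
    """Feature x sample integer counts with library sizes and offsets.

    ``offsets``, when present, are natural-log scale and override the default
    log effective library size in GLM fits.
    """

    counts: np.ndarray
    samples: list[str]
    feature_ids: np.ndarray | None = None
    lib_sizes: np.ndarray | None = None
    norm_factors: np.ndarray | None = None
    offsets: np.ndarray | None = None

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2-D (features x samples)")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        g, n = self.counts.shape
        if len(self.samples) != n:
            raise ValueError("sample names do not match count columns")
        if self.feature_ids is None:
            self.feature_ids = np.arange(g)
        self.feature_ids = np.asarray(self.feature_ids)
        if self.lib_sizes is None:
            self.lib_sizes = self.counts.sum(axis=0).astype(float)
        self.lib_sizes = np.asarray(self.lib_sizes, dtype=float)
        if self.norm_factors is None:
            self.norm_factors = np.ones(n)
        self.norm_factors = np.asarray(self.norm_factors, dtype=float)
        if (self.norm_factors <= 0).any():
            raise ValueError("norm factors must be positive")
        if self.offsets is not None:
            self.offsets = np.asarray(self.offsets, dtype=float)
            if self.offsets.shape != self.counts.shape:
                raise ValueError("offset matrix shape must match counts")

    @property
    def n_features(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    @property
    def effective_lib_sizes(self) -> np.ndarray:
        return self.lib_sizes * self.norm_factors

    def offset_matrix(self) -> np.ndarray:
        if self.offsets is not None:
            return self.offsets
        return np.broadcast_to(
            np.log(self.effective_lib_sizes), self.counts.shape
        ).copy()

    def cpm(self, lib_sizes: np.ndarray | None = None, prior: float = 0.0) -> np.ndarray:
        lib = self.effective_lib_sizes if lib_sizes is None else np.asarray(lib_sizes, float)
        return (self.counts + prior) / lib * 1e6

    def ave_log_cpm(self) -> np.ndarray:
        """log2 CPM of the per-feature total over the total library size."""
        tot = self.counts.sum(axis=1)
        return np.log2((tot + 0.5) / self.effective_lib_sizes.sum() * 1e6)

    def subset(self, mask: np.ndarray) -> "CountMatrix":
        return CountMatrix(
            counts=self.counts[mask],
            samples=list(self.samples),
            feature_ids=self.feature_ids[mask],
            lib_sizes=self.lib_sizes.copy(),
            norm_factors=self.norm_factors.copy(),
            offsets=None if self.offsets is None else self.offsets[mask],
        )


# ---------------------------------------------------------------------------
# normalization and filtering
# ---------------------------------------------------------------------------


def _tmm_pair(obs, ref, lib_obs, lib_ref, trim_m, trim_a):
    pos = (obs > 0) & (ref > 0)
    if not pos.any():
        return 1.0
    o = obs[pos] / lib_obs
    r = ref[pos] / lib_ref
    m = np.log2(o / r)
    a = 0.5 * np.log2(o * r)
    if np.max(np.abs(m)) < 1e-6:
        return 1.0
    # delta-method precision of each M-value
    w = (lib_obs - obs[pos]) / (lib_obs * obs[pos]) + (lib_ref - ref[pos]) / (
        lib_ref * ref[pos]
    )
    n = len(m)
    lo_m = np.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rank_m = sps.rankdata(m)
    rank_a = sps.rankdata(a)
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        return 1.0
    f = np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])
    if not np.isfinite(f):
        return 1.0
    return float(2.0**f)


def tmm_factors(
    cm: CountMatrix,
    ref: int | None = None,
    trim_m: float = 0.3,
    trim_a: float = 0.05,
) -> np.ndarray:
    """Trimmed mean of M-values normalization factors (geometric mean 1).

    The reference sample defaults to the column whose upper quartile of CPM is
    closest to the mean upper quartile.
    """
    counts = cm.counts.astype(float)
    lib = cm.lib_sizes
    if cm.n_samples < 2:
        raise ValueError("TMM needs at least 2 samples")
    if (counts.sum(axis=0) == 0).any():
        raise ValueError("sample with all-zero counts")
    if ref is None:
        uq = np.array([np.quantile(counts[:, s] / lib[s], 0.75) for s in range(cm.n_samples)])
        ref = int(np.argmin(np.abs(uq - uq.mean())))
    factors = np.array(
        [
            _tmm_pair(counts[:, s], counts[:, ref], lib[s], lib[ref], trim_m, trim_a)
            for s in range(cm.n_samples)
        ]
    )
    factors = factors / np.exp(np.mean(np.log(factors)))
    return factors


def cpm_filter(
    cm: CountMatrix,
    threshold: float,
    min_samples: int,
    lib_sizes: np.ndarray | None = None,
) -> np.ndarray:
    """Keep features with CPM strictly above ``threshold`` in >= ``min_samples``.

    CPM uses effective library sizes unless a fixed ``lib_sizes`` vector is
    supplied (e.g. total genome-aligned reads for eRNA quantification).
    """
    lib = cm.effective_lib_sizes if lib_sizes is None else np.asarray(lib_sizes, float)
    if (lib <= 0).any():
        raise ValueError("library sizes must be positive")
    cpm = cm.counts / lib * 1e6
    return (cpm > threshold).sum(axis=1) >= min_samples


# ---------------------------------------------------------------------------
# NB GLM
# ---------------------------------------------------------------------------


@dataclass
class NBGLMFit:
    coef: np.ndarray          # features x coefficients (natural-log scale)
    mu: np.ndarray            # fitted means, features x samples
    deviance: np.ndarray      # per-feature residual deviance
    converged: np.ndarray     # per-feature flag
    design: np.ndarray
    dispersion: np.ndarray
    offset: np.ndarray


def nb_deviance(y: np.ndarray, mu: np.ndarray, dispersion) -> np.ndarray:
    """Residual deviance of an NB (or Poisson at dispersion 0) fit, per feature."""
    y = np.asarray(y, dtype=float)
    mu = np.maximum(np.asarray(mu, dtype=float), 1e-10)
    phi = np.asarray(dispersion, dtype=float)
    if phi.ndim == 1:
        phi = phi[:, None]
    phi = np.broadcast_to(phi, y.shape)
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(y > 0, y * np.log(np.maximum(y, 1e-300) / mu), 0.0)
    phi_safe = np.maximum(phi, 1e-12)
    nb_t2 = (y + 1.0 / phi_safe) * np.log((1.0 + phi_safe * y) / (1.0 + phi_safe * mu))
    pois_t2 = y - mu
    t2 = np.where(phi > 1e-12, nb_t2, pois_t2)
    return 2.0 * (t1 - t2).sum(axis=-1)


def fit_nb_glm(
    counts: np.ndarray,
    design: np.ndarray,
    dispersion,
    offsets: np.ndarray | None = None,
    max_iter: int = 50,
    tol: float = 1e-8,
) -> NBGLMFit:
    """Fit per-feature NB log-link GLMs by IRLS with a shared design.

    Fisher scoring runs to convergence (relative deviance change below ``tol``)
    or ``max_iter`` iterations; non-converging features are flagged, not fatal.
    """
    y = np.asarray(counts, dtype=float)
    X = np.asarray(design, dtype=float)
    g, n = y.shape
    p = X.shape[1]
    if X.shape[0] != n:
        raise ValueError("design rows must match samples")
    if n - p < 1:
        raise ValueError("need at least one residual degree of freedom")
    phi = np.broadcast_to(np.asarray(dispersion, dtype=float), (g,)).copy()
    off = np.zeros((g, n)) if offsets is None else np.broadcast_to(
        np.asarray(offsets, float), (g, n)
    )

    # start from a least-squares fit on shifted log counts
    z0 = np.log(y + 0.5) - off
    beta = np.linalg.lstsq(X, z0.T, rcond=None)[0].T  # g x p

    eye = np.eye(p)[None, :, :]
    eta = np.clip(off + beta @ X.T, -30.0, 45.0)
    mu = np.exp(eta)
    dev = nb_deviance(y, mu, phi)
    converged = np.zeros(g, dtype=bool)
    phi_col = phi[:, None]
    for _ in range(max_iter):
        act = ~converged
        if not act.any():
            break
        w = mu[act] / (1.0 + phi_col[act] * mu[act])
        z = (eta[act] - off[act]) + (y[act] - mu[act]) / mu[act]
        A = np.einsum("np,gn,nq->gpq", X, w, X)
        A = A + 1e-10 * eye
        b = np.einsum("np,gn->gp", X, w * z)
        try:
            beta_new = np.linalg.solve(A, b[..., None])[..., 0]
        except np.linalg.LinAlgError:
            beta_new = np.linalg.lstsq(
                A.reshape(-1, p), b.reshape(-1, 1), rcond=None
            )[0]  # pragma: no cover
        delta = beta_new - beta[act]
        # step-halving keeps the deviance non-increasing
        step = np.ones((act.sum(), 1))
        best_beta = beta[act].copy()
        best_dev = dev[act].copy()
        for _half in range(6):
            cand = beta[act] + step * delta
            eta_c = np.clip(off[act] + cand @ X.T, -30.0, 45.0)
            dev_c = nb_deviance(y[act], np.exp(eta_c), phi[act])
            better = np.isfinite(dev_c) & (dev_c <= best_dev + 1e-12)
            best_beta[better] = cand[better]
            best_dev[better] = dev_c[better]
            if better.all():
                break
            step[~better] *= 0.5
        old_dev = dev[act]
        beta[act] = best_beta
        eta[act] = np.clip(off[act] + best_beta @ X.T, -30.0, 45.0)
        mu[act] = np.exp(eta[act])
        dev_act = best_dev
        done = np.abs(old_dev - dev_act) < tol * (np.abs(dev_act) + 1.0)
        dev[act] = dev_act
        idx = np.flatnonzero(act)
        converged[idx[done]] = True
    return NBGLMFit(
        coef=beta,
        mu=mu,
        deviance=dev,
        converged=converged,
        design=X,
        dispersion=phi,
        offset=np.asarray(off),
    )


# ---------------------------------------------------------------------------
# dispersion estimation
# ---------------------------------------------------------------------------


@dataclass
class DispersionFit:
    """Trended NB dispersion plus (after QL testing) the QL moderation state."""

    abundance_grid: np.ndarray
    dispersion_grid: np.ndarray
    raw: np.ndarray | None = None
    ql_dispersions: np.ndarray | None = None
    squeezed_ql: np.ndarray | None = None
    prior_df: float | None = None

    def __call__(self, abundance: np.ndarray) -> np.ndarray:
        return np.interp(
            np.asarray(abundance, float),
            self.abundance_grid,
            self.dispersion_grid,
        )


def _nb_loglik(y, mu, phi) -> np.ndarray:
    """Per-feature NB log-likelihood at fixed dispersion phi > 0."""
    r = 1.0 / phi
    mu = np.maximum(mu, 1e-10)
    ll = (
        special.gammaln(y + r)
        - special.gammaln(r)
        - special.gammaln(y + 1.0)
        + r * np.log(r / (r + mu))
        + y * np.log(mu / (r + mu))
    )
    return ll.sum(axis=1)


def _cox_reid_apl(y, X, phi, offs) -> np.ndarray:
    """Cox-Reid adjusted profile log-likelihood of phi, per feature."""
    fit = fit_nb_glm(y, X, phi, offs)
    w = fit.mu / (1.0 + phi * fit.mu)
    info = np.einsum("np,gn,nq->gpq", X, w, X)
    sign, logdet = np.linalg.slogdet(info + 1e-10 * np.eye(X.shape[1]))
    return _nb_loglik(y, fit.mu, phi) - 0.5 * logdet


def estimate_dispersion_trend(
    cm: CountMatrix,
    design: np.ndarray,
    nbins: int = 10,
    grid: np.ndarray | None = None,
    max_features: int = 4000,
) -> DispersionFit:
    """Fit a mean-dependent NB dispersion trend.

    The Cox-Reid adjusted profile likelihood is evaluated on a dispersion grid
    for an abundance-stratified subset of features; within each abundance bin
    the summed profile likelihood is maximized (with quadratic interpolation
    on the log-dispersion grid), giving a trend point at the bin's mean
    abundance.  The trend is evaluated anywhere by linear interpolation with
    flat extrapolation.
    """
    X = np.asarray(design, float)
    y = cm.counts.astype(float)
    n, p = X.shape[0], X.shape[1]
    if n - p < 1:
        raise ValueError("need at least one residual degree of freedom")
    if grid is None:
        grid = np.logspace(-4, np.log10(5.0), 21)
    abund = cm.ave_log_cpm()
    g = len(abund)
    order = np.argsort(abund)
    if g > max_features:
        sub = order[np.linspace(0, g - 1, max_features).astype(int)]
    else:
        sub = order
    ysub = y[sub]
    osub = cm.offset_matrix()[sub]
    apl = np.empty((len(sub), len(grid)))
    for k, phi in enumerate(grid):
        apl[:, k] = _cox_reid_apl(ysub, X, phi, osub)
    # per-feature argmax for diagnostics
    raw = np.full(g, np.nan)
    raw[sub] = grid[np.argmax(apl, axis=1)]
    # abundance bins: maximize the summed APL per bin
    if np.ptp(abund[sub]) > 1e-8 and len(sub) >= 2 * nbins:
        chunks = np.array_split(np.arange(len(sub)), nbins)
    else:
        chunks = [np.arange(len(sub))]
    logphi = np.log(grid)
    bx, by = [], []
    for ch in chunks:
        tot = apl[ch].sum(axis=0)
        k = int(np.argmax(tot))
        if 0 < k < len(grid) - 1:
            # quadratic interpolation around the grid maximum
            y0, y1, y2 = tot[k - 1], tot[k], tot[k + 1]
            denom = y0 - 2.0 * y1 + y2
            shift = 0.0 if denom >= 0 else 0.5 * (y0 - y2) / denom
            shift = float(np.clip(shift, -1.0, 1.0))
            lp = logphi[k] + shift * (logphi[min(k + 1, len(grid) - 1)] - logphi[k])
        else:
            lp = logphi[k]
        bx.append(abund[sub][ch].mean())
        by.append(np.exp(lp))
    bx, by = np.array(bx), np.maximum(np.array(by), 1e-8)
    srt = np.argsort(bx)
    return DispersionFit(abundance_grid=bx[srt], dispersion_grid=by[srt], raw=raw)


# ---------------------------------------------------------------------------
# empirical Bayes variance squeezing
# ---------------------------------------------------------------------------


def _trigamma_inverse(yv: float) -> float:
    if yv <= 0:
        return np.inf
    if yv > 1e7:
        return 1.0 / np.sqrt(yv)
    if yv < 1e-6:
        return 1.0 / yv
    x = 0.5 + 1.0 / yv
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / yv) / special.polygamma(2, x)
        x = x + dif
        if abs(dif) < 1e-8 * x:
            break
    return float(x)


def _winsorized_var(v: np.ndarray, qlo: float, qhi: float) -> float:
    lo, hi = np.quantile(v, [qlo, qhi])
    w = np.clip(v, lo, hi)
    return float(np.var(w))


def _fit_prior_df_winsorized(resid: np.ndarray, df1: float, qlo=0.05, qhi=0.95) -> float:
    """Match winsorized variance of log residual variances to a log-F model."""
    emp = _winsorized_var(resid - resid.mean(), qlo, qhi)
    u = (np.arange(4001) + 0.5) / 4001.0

    def theo(d0: float) -> float:
        # underflowed quantiles are clipped; they land in the winsorized tail
        x = np.log(np.maximum(sps.f.ppf(u, df1, d0), 1e-300))
        return _winsorized_var(x - x.mean(), qlo, qhi)

    if emp <= theo(1e8):
        return np.inf
    lo, hi = -2.0, 8.0  # log10 d0
    if emp >= theo(10**lo):
        return 10**lo
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        if theo(10**mid) > emp:
            lo = mid
        else:
            hi = mid
    return float(10 ** (0.5 * (lo + hi)))


@dataclass
class SqueezeResult:
    var_post: np.ndarray
    var_prior: np.ndarray
    df_prior: float


def squeeze_variances(
    s2: np.ndarray,
    df: float,
    covariate: np.ndarray | None = None,
    robust: bool = True,
    span: float = 0.4,
) -> SqueezeResult:
    """Empirical-Bayes squeeze of sample variances toward an abundance trend.

    The prior degrees of freedom come from matching (winsorized, if robust)
    moments of log(s2/trend) to the log-F distribution they follow under the
    hierarchical model.
    """
    s2 = np.asarray(s2, dtype=float)
    g = len(s2)
    ok = s2 > 1e-300
    bias1 = special.digamma(df / 2.0) - np.log(df / 2.0)
    if g <= 2 or ok.sum() <= 2:
        warnings.warn("too few features to estimate prior df; using full squeeze")
        s20 = np.full(g, np.median(s2[ok]) if ok.any() else 1.0)
        return SqueezeResult(var_post=s20, var_prior=s20, df_prior=np.inf)
    z = np.full(g, np.nan)
    z[ok] = np.log(s2[ok])
    # plain (non-robust) lowess estimates the conditional mean of z, matching
    # the mean-bias correction below; robust iterations would shift the centre
    # toward the median of the very skewed log-chi-square residuals.
    if covariate is not None and np.ptp(covariate[ok]) > 1e-8:
        fitted = _sm_lowess(
            z[ok], covariate[ok], frac=span, it=0, return_sorted=False
        )
        ztr = np.empty(g)
        ztr[ok] = fitted
        if (~ok).any():
            order = np.argsort(covariate[ok])
            ztr[~ok] = np.interp(
                covariate[~ok], covariate[ok][order], fitted[order]
            )
    else:
        ztr = np.full(g, np.mean(z[ok]))
    s20 = np.exp(ztr - bias1)
    resid = z[ok] - ztr[ok]
    if robust:
        d0 = _fit_prior_df_winsorized(resid, df)
    else:
        evar = float(np.var(resid)) - special.polygamma(1, df / 2.0)
        d0 = 2.0 * _trigamma_inverse(evar) if evar > 0 else np.inf
    if np.isinf(d0):
        var_post = s20
    else:
        var_post = (d0 * s20 + df * np.where(ok, s2, 0.0)) / (d0 + df)
    return SqueezeResult(var_post=var_post, var_prior=s20, df_prior=d0)


# ---------------------------------------------------------------------------
# QL test
# ---------------------------------------------------------------------------


def _resolve_contrast(design, contrast):
    if isinstance(design, pd.DataFrame):
        X = design.to_numpy(dtype=float)
        cols = list(design.columns)
    else:
        X = np.asarray(design, dtype=float)
        cols = None
    if isinstance(contrast, str):
        if cols is None:
            raise ValueError("string contrast requires a DataFrame design")
        cvec = np.zeros(X.shape[1])
        cvec[cols.index(contrast)] = 1.0
    else:
        cvec = np.asarray(contrast, dtype=float)
        if cvec.shape != (X.shape[1],):
            raise ValueError("contrast length must match design columns")
    return X, cvec


def ql_test(
    cm: CountMatrix,
    design,
    contrast,
    dispfit: DispersionFit | None = None,
    robust: bool = True,
    prior_df: float | None = None,
) -> pd.DataFrame:
    """NB quasi-likelihood F-test of a single contrast per feature.

    Returns a table with log2 fold change, average logCPM, F statistic,
    p-value and BH FDR, in input feature order.  ``prior_df=0`` disables
    moderation and reduces to the plain deviance F-test.
    """
    X, cvec = _resolve_contrast(design, contrast)
    n, p = X.shape
    df_resid = n - p
    if df_resid < 1:
        raise ValueError("no residual degrees of freedom")
    if dispfit is None:
        dispfit = estimate_dispersion_trend(cm, X)
    abund = cm.ave_log_cpm()
    phi = np.maximum(dispfit(abund), 1e-8)
    offs = cm.offset_matrix()
    y = cm.counts.astype(float)
    full = fit_nb_glm(y, X, phi, offs)
    nullspace = linalg.null_space(cvec[None, :])
    Xnull = X @ nullspace
    nullfit = fit_nb_glm(y, Xnull, phi, offs)
    dev_drop = np.maximum(nullfit.deviance - full.deviance, 0.0)
    s2 = full.deviance / df_resid
    if prior_df is None:
        sq = squeeze_variances(s2, df_resid, covariate=abund, robust=robust)
        s2_post, d0 = sq.var_post, sq.df_prior
    elif prior_df == 0:
        s2_post, d0 = s2, 0.0
    elif np.isinf(prior_df):
        sq = squeeze_variances(s2, df_resid, covariate=abund, robust=robust)
        s2_post, d0 = sq.var_prior, np.inf
    else:
        sq = squeeze_variances(s2, df_resid, covariate=abund, robust=robust)
        d0 = float(prior_df)
        s2_post = (d0 * sq.var_prior + df_resid * s2) / (d0 + df_resid)
    s2_post = np.maximum(s2_post, 1e-10)
    fstat = dev_drop / s2_post
    if np.isinf(d0):
        pvals = sps.chi2.sf(fstat, 1)
    else:
        pvals = sps.f.sf(fstat, 1, df_resid + d0)
    dispfit.ql_dispersions = s2
    dispfit.squeezed_ql = s2_post
    dispfit.prior_df = d0
    logfc = (full.coef @ cvec) / _LN2
    return pd.DataFrame(
        {
            "feature": cm.feature_ids,
            "logFC": logfc,
            "ave_logCPM": abund,
            "F": fstat,
            "p": pvals,
            "fdr": bh_adjust(pvals),
        }
    )


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def simes_p(p: np.ndarray) -> float:
    """Simes combined p-value over a set of member p-values."""
    p = np.sort(np.asarray(p, dtype=float))
    m = len(p)
    if m == 0:
        raise ValueError("empty p-value set")
    return float(min(1.0, np.min(m * p / np.arange(1, m + 1))))


# ---------------------------------------------------------------------------
# voom-style weighted linear modelling
# ---------------------------------------------------------------------------


def voom_weighted_lm(
    cm: CountMatrix,
    design,
    contrast,
    span: float = 0.5,
    robust: bool = True,
    prior_df: float | None = None,
    lib_sizes: np.ndarray | None = None,
) -> pd.DataFrame:
    """log2-CPM precision-weighted linear models with moderated t-statistics.

    Counts are transformed to log2-CPM with prior count 0.5; the mean-variance
    trend (sqrt residual SD against average log2 count) is fitted by local
    regression and inverted into per-observation weights; residual variances
    are squeezed by empirical Bayes and the contrast is tested with a
    moderated t on augmented degrees of freedom.  ``prior_df=0`` gives the
    ordinary weighted least-squares t-test.
    """
    X, cvec = _resolve_contrast(design, contrast)
    n, p = X.shape
    df_resid = n - p
    if df_resid < 1:
        raise ValueError("no residual degrees of freedom")
    lib = cm.effective_lib_sizes if lib_sizes is None else np.asarray(lib_sizes, float)
    y = np.log2((cm.counts + 0.5) / (lib + 1.0) * 1e6)
    # first pass: unweighted fit for the mean-variance trend
    pinv = np.linalg.pinv(X)
    beta = y @ pinv.T
    resid = y - beta @ X.T
    sigma = np.sqrt((resid**2).sum(axis=1) / df_resid)
    amean = y.mean(axis=1)
    sx = amean + np.mean(np.log2(lib + 1.0)) - np.log2(1e6)
    sy = np.sqrt(sigma)
    if np.ptp(sx) > 1e-8 and len(sx) >= 10:
        lo = _sm_lowess(sy, sx, frac=span, it=3)
        lx, ly = lo[:, 0], lo[:, 1]
    else:
        lx = np.array([sx.min() - 1.0, sx.max() + 1.0])
        ly = np.array([sy.mean(), sy.mean()])
    fitted_logcount = beta @ X.T + (np.log2(lib + 1.0) - np.log2(1e6))[None, :]
    sqrt_sd = np.interp(fitted_logcount, lx, ly)
    w = np.maximum(sqrt_sd, 1e-6) ** -4
    # weighted least squares per feature
    A = np.einsum("np,gn,nq->gpq", X, w, X)
    b = np.einsum("np,gn->gp", X, w * y)
    beta = np.linalg.solve(A, b[..., None])[..., 0]
    resid = y - beta @ X.T
    s2 = (w * resid**2).sum(axis=1) / df_resid
    Ainv_c = np.linalg.solve(A, np.broadcast_to(cvec, (len(s2), p))[..., None])[..., 0]
    var_unscaled = Ainv_c @ cvec
    if prior_df == 0:
        s2_post, d0 = s2, 0.0
    else:
        sq = squeeze_variances(s2, df_resid, covariate=amean, robust=robust)
        if prior_df is None:
            s2_post, d0 = sq.var_post, sq.df_prior
        elif np.isinf(prior_df):
            s2_post, d0 = sq.var_prior, np.inf
        else:
            d0 = float(prior_df)
            s2_post = (d0 * sq.var_prior + df_resid * s2) / (d0 + df_resid)
    logfc = beta @ cvec
    tstat = logfc / np.sqrt(np.maximum(var_unscaled * s2_post, 1e-300))
    if np.isinf(d0):
        pvals = 2.0 * sps.norm.sf(np.abs(tstat))
    else:
        pvals = 2.0 * sps.t.sf(np.abs(tstat), df_resid + d0)
    return pd.DataFrame(
        {
            "feature": cm.feature_ids,
            "logFC": logfc,
            "ave_logCPM": amean,
            "t": tstat,
            "p": pvals,
            "fdr": bh_adjust(pvals),
        }
    )


# ---------------------------------------------------------------------------
# distances and utility tests
# ---------------------------------------------------------------------------


def leading_logfc_distance(
    logcpm: np.ndarray,
    top_n: int,
    covariates: np.ndarray | None = None,
) -> np.ndarray:
    """Sample-pair RMS of the top-N largest absolute log differences.

    ``covariates`` (samples x k), when given, are regressed out of each
    feature first (batch correction, e.g. a donor indicator).
    """
    y = np.asarray(logcpm, dtype=float)
    g, n = y.shape
    if top_n > g:
        raise ValueError("top_n exceeds number of features")
    if covariates is not None:
        Z = np.asarray(covariates, dtype=float)
        if Z.ndim == 1:
            Z = Z[:, None]
        Zc = Z - Z.mean(axis=0, keepdims=True)
        coef = np.linalg.lstsq(Zc, y.T, rcond=None)[0]
        y = y - (Zc @ coef).T
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            diff2 = (y[:, i] - y[:, j]) ** 2
            top = np.partition(diff2, g - top_n)[g - top_n :]
            d[i, j] = d[j, i] = np.sqrt(top.mean())
    return d


def fisher_exact_2x2(table) -> tuple[float, float]:
    """Two-sided Fisher exact test of a 2x2 contingency table."""
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (t < 0).any():
        raise ValueError("negative entries")
    odds, p = sps.fisher_exact(t, alternative="two-sided")
    return float(odds), float(p)


def wilcoxon_rank_sum(x, y) -> tuple[float, float]:
    """Two-sided rank-sum test; exact for small tie-free samples."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("empty group")
    pooled = np.concatenate([x, y])
    ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(pooled) <= 20 and not ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# design helper
# ---------------------------------------------------------------------------


def make_design(
    samples: pd.DataFrame,
    factors=("condition", "lineage", "donor"),
    contrast: str = "condition",
) -> tuple[pd.DataFrame, np.ndarray]:
    """Intercept + treatment-coded factor design from a sample sheet.

    Factor levels are ordered by first appearance; single-level factors are
    dropped.  The returned contrast vector selects the (single) non-reference
    level of the ``contrast`` factor.
    """
    cols = {"intercept": np.ones(len(samples))}
    contrast_col = None
    for f in factors:
        if f not in samples.columns:
            continue
        levels = list(dict.fromkeys(samples[f]))
        for lev in levels[1:]:
            name = f"{f}[{lev}]"
            cols[name] = (samples[f] == lev).astype(float).to_numpy()
            if f == contrast and contrast_col is None:
                contrast_col = name
    X = pd.DataFrame(cols, index=samples.index)
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("design matrix is not full column rank")
    if contrast_col is None:
        raise ValueError(f"contrast factor {contrast!r} has fewer than 2 levels")
    cvec = np.zeros(X.shape[1])
    cvec[list(X.columns).index(contrast_col)] = 1.0
    return X, cvec
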