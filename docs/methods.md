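# Methods

## Statistical model

All count-based tests share one engine. Counts for feature *g* (a gene, an
ATAC peak, a Hi-C bin pair, or an up/down boundary observation) in sample
*s* are modelled as negative binomial,

    y_gs ~ NB(mu_gs, phi_g),     log mu_gs = x_s' beta_g + o_gs,

where `x_s` encodes condition, lineage and donor (treatment coding, levels
ordered by first appearance) and `o_gs` is a natural-log offset — the log
effective library size, or the LOESS offset matrix for Hi-C bin pairs.
Because the GLM is fitted per feature, a donor column in the design absorbs
arbitrary per-feature donor effects, which is exactly how the generator
plants its donor batch effect (a per-donor, per-feature log-normal
intercept).

**Dispersion trend.** The NB dispersion is estimated as a function of
average log-CPM: the Cox–Reid adjusted profile likelihood (log-likelihood at
the fitted means minus half the log-determinant of the Fisher information)
is evaluated on a 21-point log-spaced dispersion grid for an
abundance-stratified subset of up to 4 000 features; within each of ~10
equal-count abundance bins the *summed* profile likelihood is maximised
(with quadratic interpolation on the log grid), and the trend is linearly
interpolated between bin centres with flat extrapolation. Aggregating the
likelihood within bins is what makes the estimate usable at one residual
degree of freedom, where individual per-feature estimates are hopeless; a
per-feature Pearson-moment variant was tried first and was biased low by
more than a factor of two in that regime.

**Quasi-likelihood F-test.** The QL dispersion of a feature is its GLM
residual deviance divided by the residual degrees of freedom d₁. The log QL
dispersions are regressed on abundance by (non-robust) lowess; subtracting
the analytic mean bias `digamma(d1/2) - log(d1/2)` of log chi-square noise
turns the fitted curve into the prior trend s₀²(A). The non-robust local
*mean* is deliberate: the bias correction is only valid for a conditional
mean, and a robustified (median-like) fit inflates the prior and makes every
test conservative. The prior degrees of freedom d₀ are estimated by
matching the winsorized (5%/95%) variance of `log(s²/s₀²)` to the winsorized
variance of a log-F(d₁, d₀) sample computed on a quantile grid — a
winsorized-moment version of robust empirical Bayes. The moderated
dispersion is `(d0*s0² + d1*s²)/(d0+d1)` and the test statistic
`F = deviance drop / moderated dispersion` is referred to F(1, d1+d0)
(chi-square when d₀ is infinite). `prior_df=0` disables moderation and
reduces exactly to the plain deviance F-test, which the tests verify against
independent linear-algebra and likelihood oracles.

**voom path.** For RNA and eRNA the counts are transformed to log2-CPM with
prior count 0.5, the sqrt residual SD from an unweighted fit is regressed on
average log2 count by lowess (span 0.5), inverse-fourth-power weights are
interpolated at the fitted log-counts, and weighted least squares with the
same empirical-Bayes variance squeeze yields moderated t statistics.

**Multiplicity.** BH step-up everywhere; FDR < 5% defines DI / DA / DE /
differential boundaries. DI clusters combine member p-values with Simes'
method; cluster FDR is BH over combined p-values, with cluster membership at
the bin-pair BH 5% threshold and bounding boxes bisected until no side
exceeds the maximum cluster size (500 kb at 25 kb resolution).

## Hi-C specifics

Read pairs are counted into fixed-width bin pairs (anchors ordered, intra-
chromosomal only); inter-chromosomal pairs feed the background ligation
frequency: the mean count per inter-chromosomal 2 Mb bin pair expressed as
log2 CPM of the total library, rescaled to the analysis bin size by
`-2*log2(2Mb/width)`. Bin pairs are retained when their average abundance
exceeds background + log2(6) (strict), after dropping excluded chromosomes,
blacklist-touching bins, bins with marginal count below 5, and the first
diagonal (|i-j| <= 1). LOESS offsets are fitted per sample within two
distance strata (gap below/above 100 kb at 25 kb resolution, 150 kb at
100 kb), row-centred, and anchored at the mean log library size.

**Boundary strength.** Upstream/downstream counts at a 50 kb boundary region
(one anchor inside, the other within (0, 1 Mb] up- or downstream; both-in
pairs count for neither) form a paired design with per-sample intercepts, a
direction indicator, direction x nuisance interactions and the tested
direction x condition interaction. A significant region is *strengthened*
when the magnitude of its up/down asymmetry increases between conditions.
The magnitude rule matters: a direction-relative rule is undefined for
newly formed boundaries (baseline asymmetry ~0) and a fixed-sign rule flips
with which side of the breakpoint the called region falls on.

**Compartments.** Per chromosome, expected counts are per-diagonal means;
O/E columns (bins with fewer than 10 informative contacts masked) give a
Pearson correlation matrix whose leading eigenvector is the compartment
score, sign-oriented by an open-chromatin covariate (the generator exports
an ATAC-coverage-like track; the CLI derives one from peak CPM). Profile
correlations between conditions exclude entries within 40 bins (2 Mb) of
the bin itself — domain-scale structure is shared between conditions and
carries no compartment information; without the exclusion, true flips sit
near zero correlation and are missed.

## The synthetic generator

Expected intra-chromosomal intensity for bins i < j is

    (d+1)^-alpha  *  T_ij  *  C_ij  *  L_ij,      d = j - i,

with alpha = 1, `T_ij` = 3 inside a TAD and `1/max(boundary strengths
crossed)` across TADs *within 2 Mb of the diagonal only* (insulation is a
local phenomenon; making it global creates chromosome-scale meta-domains
that drown the compartment plaid), `C_ij` = 1.5 for same-compartment bins,
and `L_ij` the per-condition loop multiplier. Counts are NB (dispersion
0.05) around library-scaled expectations with a per-donor log-normal bias
(sd 0.1 log2); a configurable fraction of pairs (15% by default, 25% in the
null scenario) is uniform inter-chromosomal ligation noise; read positions
are uniform within bins. Everything is a pure function of (spec, seed).

The activation scenario (2 donors x {resting, activated} x {CD4, CD8},
5 M pairs/sample, 20 + 15 Mb genome at 25 kb generator resolution) plants:
TAD splits in half of the resting TADs (new internal boundary, kept >=600 kb
from chromosome ends where insulation is undefined); strengthening/weakening
(x3 attenuation) of 20%/20% of boundaries; compartment flips in 1.5% of
50 kb bins on a 2 Mb checkerboard; 200 loops (100 gained x4, 100 lost x4 in
resting), gained short-range (150–500 kb) and lost long-range (0.5–1.2 Mb),
each wired to a planted DA peak in one anchor and a planted DE gene promoter
in the other; occupancy elevated at strengthened *and newly formed*
boundaries; and accessibility/expression changes for features near weakened
(up) versus strengthened/new (down) boundaries and inside flipped
compartment bins (B->A up, A->B down). eRNA log fold changes are 0.8x the
peak accessibility change plus noise. Feature counts use log-normal
baselines, |logFC| = 2 effects and NB dispersion 0.05.

Desk-scale depth is a deliberate reduction from the hundreds of millions of
valid pairs a real library yields. Two consequences are handled explicitly:
the null calibration genome is small (2 x 7 Mb) so that ~5 000 bin pairs
survive the sixfold background filter at 5 M pairs/sample, and the
boundary-test null calibration uses a wide genome (2 x 60 Mb, ~2 300 50-kb
regions) because a uniformity statistic on a few hundred regions is
dominated by its own sampling noise.

### What the generator does not emulate

Restriction-fragment structure and enzyme-specific bin boundaries, sequence
content and mappability bias, CTCF motif orientation, loop extrusion
dynamics, nested/hierarchical TADs, sub-compartments, and distance-dependent
dispersion. Passing the recovery tests therefore shows the statistical
machinery is correct and calibrated on data matching its model assumptions,
not that the pipeline is robust to every artefact of real Hi-C libraries.

## Numerical choices

IRLS with step halving, convergence at relative deviance change < 1e-8 or
50 iterations (non-convergence flags the feature, never fails the run);
linear predictors clipped to [-30, 45]; dispersions floored at 1e-8;
degenerate strata (fewer than 50 bin pairs) fall back to median offsets with
a warning; fewer than 3 features falls back to infinite prior (full
squeeze); O/E entries with zero expectation are missing; compartment tracks
flag chromosomes whose leading eigenvalue barely dominates the second.
TMM uses 30%/5% trims and the upper-quartile-closest-to-mean reference;
factors multiply library sizes (so a compositionally inflated sample gets a
factor below one) and are normalised to geometric mean 1.

## Known limitations

- At one residual degree of freedom the QL F-test is slightly conservative
  (observed null rejection ~4% at nominal 5%); power claims at 2 v 2 should
  be read accordingly.
- The insulation caller reports no boundaries within one window (500 kb) of
  chromosome ends, and its prominence knob is not comparable to the
  confidence scores of model-based TAD callers.
- Compartment calls at 50 kb need high per-bin coverage; at desk-scale depth
  the analyses use genomes a few tens of Mb long to emulate the per-bin
  coverage of a full-depth experiment.
- Trans (inter-chromosomal) interactions are never tested; they are used
  only to estimate background ligation.
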