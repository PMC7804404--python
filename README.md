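# chromdiff

Multi-level differential chromatin architecture analysis for a two-condition,
replicated design — the kind of experiment where resting and activated
primary T cells (CD4⁺ and CD8⁺, two donors) are profiled in parallel by in
situ Hi-C, ATAC-seq and RNA-seq.  The package asks, at every level of
chromatin organisation, *what changed on activation and is the change
statistically solid relative to donor-to-donor variability*:

- **Differential interactions (DI).** Hi-C read pairs are counted into
  fixed-width intra-chromosomal bin pairs; pairs are kept only if their mean
  intensity is more than sixfold above the background ligation frequency
  estimated from inter-chromosomal 2 Mb bin pairs; LOESS offsets remove
  abundance-dependent biases; each bin pair is tested with a negative-binomial
  quasi-likelihood (QL) F-test, `y_gs ~ NB(μ_gs, φ_g)`,
  `log μ_gs = x_sᵀβ_g + o_gs`, with the QL dispersions squeezed toward an
  abundance trend by empirical Bayes.  Significant pairs (FDR < 5%) are
  aggregated into interaction-space clusters with Simes combined p-values and
  cluster-level FDR control.
- **TADs and differential boundaries (DTB).** Insulation scores (log₂ of
  window contact density over its distance-matched expectation) segment each
  condition's summed contact map into TADs; boundary strength is the ratio of
  upstream to downstream read pairs anchored at each 50 kb boundary region,
  and its change between conditions is tested with the same QL machinery via
  a condition × direction interaction.
- **A/B compartments.** Per chromosome, PC1 of the Pearson correlation matrix
  of the observed/expected contact map gives the compartment score (oriented
  so A correlates with open chromatin); a bin flips compartment when its
  label changes *and* the correlation of its interaction profile between
  conditions is negative.
- **DA / DE / eRNA.** Differential accessibility uses TMM normalisation and
  the QL F-test; differential expression uses log₂-CPM with voom-style
  precision weights and robust empirical-Bayes moderated t-statistics; eRNA
  expression is quantified over non-exonic peaks with library sizes fixed to
  total genome-aligned reads.
- **Integration.** Tested bin pairs that connect a DA peak with the promoter
  (−1 kb to +100 bp of the TSS) of an expressed gene form the gene-regulatory
  interaction network; Fisher exact tests quantify the coupling of gained /
  lost interactions to up- / down-regulated genes.

A synthetic-data module generates the whole multi-omic design — NB counts,
power-law contact decay, planted TADs that partition on activation, planted
gained/lost loops wired to DA peaks and DE genes, checkerboard compartments
with rare flips, donor batch effects and inter-chromosomal ligation noise —
with exported truth tables, so every stage is testable without downloads.

## Worked example

```python
from chromdiff.simulate import build_activation_scenario, simulate_hic_samples
from chromdiff.pipeline import run_di_pipeline, run_tad_pipeline

scen = build_activation_scenario(31)          # 2 donors x 2 conditions x 2 lineages
reads = simulate_hic_samples(scen)            # ~5M read pairs per sample
sizes = scen.specs["resting"].chrom_sizes

di = run_di_pipeline(reads, sizes, scen.samples)
print(di["di"]["significant"].sum(), "DIs of", len(di["di"]), "tested bin pairs")

tad = run_tad_pipeline(reads, sizes, scen.samples)
for cond, ts in tad["tadsets"].items():
    print(cond, ts.n_tads, "TADs, mean size %.2f Mb" % (ts.mean_size() / 1e6))
print("intersect fraction %.2f" % tad["intersection"]["intersect_fraction"])
```

On the default activation scenario this prints

```
14919 DIs of 35238 tested bin pairs
resting 34 TADs, mean size 1.03 Mb
activated 51 TADs, mean size 0.69 Mb
intersect fraction 0.53
```

i.e. activation partitions TADs into smaller, more numerous domains (34 → 51,
1.03 → 0.69 Mb), only half of which intersect reciprocally (>75%) across
conditions, and thousands of bin pairs change interaction intensity — the
planted loop gains/losses carry positive/negative log fold changes and the
boundary and compartment changes are recovered by the corresponding stages
(see the test suite for the full recovery checks).

The same stages are available from the shell:

```bash
chromdiff simulate --seed 31 --scenario activation --out fixtures/
chromdiff di --fixtures fixtures/ --out results/di
chromdiff tads --fixtures fixtures/ --out results/tads
```

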