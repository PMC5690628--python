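# ovoquant

Label-free, spectral-count proteomics of egg quality. `ovoquant`
implements the quantitative pipeline that links a fish egg proteome to
embryo developmental competence: normalized spectral-count (N-SC)
quantification, differential-regulation classification, functional
category and annotation-term over-representation tests, spawn-survival
phenotyping with Tukey's quick test, and a marker-panel summed-score
classifier — plus a seeded synthetic-data generator with ground truth
for validating every stage.

It is written for reproductive-biology and aquaculture proteomics
groups who have protein (or peptide) spectral-count tables from a
two-group comparison — for example good versus poor quality zebrafish
egg batches — and want the full downstream analysis as tested,
scriptable code instead of a spreadsheet.

## The model

Egg quality is operationalized on the spawn phenotype: the percentage
of incubated eggs yielding *normal* embryos 24 hours post spawning
(hps). Spawns above 90% are good quality, below 30% poor quality.

Raw MS/MS spectral counts SC(i, s) for protein *i* in sample *s* are
converted to N-SC in three sequential steps:

1. **Shared-peptide apportionment.** A peptide shared by protein groups
   {1..m} contributes its count times U_i / Σ_j U_j to protein *i*,
   where U_i is the group's unique-peptide count (equal split when all
   U_j = 0). Per-sample totals are conserved.
2. **Total scaling.** Each sample column is multiplied by
   (mean sample total) / (its total), computed within each
   (experiment, gel-fraction) stratum, so library depth cancels.
3. **Length scaling.** Each row is divided by the protein's length in
   amino-acid residues, so long proteins do not dominate.

A protein is *differentially regulated* when its mean N-SC differs
≥ 2-fold between groups or it is unique to one group; ≥ 5-fold (pooled
design) or ≥ 4-fold (replicated design) marks the *highly up-regulated*
tier. In the replicated design, per-protein Student t-tests
(Benjamini–Hochberg within fraction: raw p < 0.05 and q < 0.1) and a
one-sample t-test against zero (for uniqueness) are applied. Category
distributions are compared with an uncorrected χ² on the 2 × C table
plus BH-corrected 2 × 2 post-hoc tests; term over-representation uses
the upper-tail binomial test with Bonferroni control, fold enrichment
= observed / expected. A marker panel scores each sample by
Σ N-SC over panel proteins (isoforms summed) and classifies by a
midpoint threshold.

## Worked example

```python
import ovoquant as oq

# spawn phenotype: the packaged 16-female spawning-performance table
records = oq.packaged_survival_table()
pooled = [r for r in records if r.experiment == "pooled"]
print(oq.group_survival_stats(pooled, 24).round(2))
good = [r.normal_survival(24) for r in pooled if oq.classify_spawn(r) == "good"]
poor = [r.normal_survival(24) for r in pooled if oq.classify_spawn(r) == "poor"]
print(oq.tukey_duckworth_test(good, poor))
```

prints

```
       n   mean   sem   min    max
group
good   4  99.58  0.43  98.3  100.0
poor   4   7.22  3.34   0.0   14.3
{'statistic': 8.0, 'significant_at': {0.05}}
```

— good-quality spawns average 99.6 ± 0.4% survival at 24 hps against
7.2 ± 3.3% for poor-quality spawns, and the quick-test statistic of 8
(all four good values above the poor maximum, all four poor values
below the good minimum) exceeds the 0.05-level critical value 7 but
not the 0.01-level value 10.

Running the full pipeline on synthetic data with known truth:

```python
from ovoquant import (SimulationConfig, simulate_counts_dataset,
                      nsc_pipeline, classify_regulation, evaluate_against_truth)

ds, truth = simulate_counts_dataset(SimulationConfig(seed=1, fold_range=(8, 8)))
nsc, report = nsc_pipeline(ds)               # apportion -> totals -> length
records = classify_regulation(nsc, ds.design)
print(evaluate_against_truth(records, truth))
```

```
{'sensitivity': 0.964, 'specificity': 0.8333, 'fdr': 0.3415}
```

— 96% of the planted 8-fold effects are recovered in the up-regulated
or unique tiers. The same stages are available from the shell via the
`ovoquant` executable (`simulate`, `normalize`, `diff`, `enrich`,
`score`, `survival`, `all` subcommands).

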