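# Methods

## Quantification model

Spectral counting treats the number of MS/MS spectra assigned to a
protein's peptides as a proxy for its abundance. Three biases are
corrected sequentially, and the order matters because the steps do not
commute:

1. **Shared-peptide apportionment** (peptide-level input only). A
   peptide mapping to several protein groups has its count split in
   proportion to each group's unique-peptide count U. The weighting
   basis is the standard one for count apportionment; the tie rule —
   equal split when every sharing group has U = 0 — is our choice, made
   because such peptides carry no evidence favouring either group.
   Apportionment conserves per-sample totals to 1e-9 relative
   tolerance (tested).
2. **Total scaling.** Column c is multiplied by T̄/T_c where T_c is the
   sample total and T̄ the arithmetic mean of totals in the sample's
   stratum. Mean (rather than median or max) keeps the stratum's grand
   total invariant; since any strictly positive reference yields the
   same normalized *profiles* and hence identical downstream fold
   changes, the choice is cosmetic. A corollary worth stating: scaling
   one raw column by a constant leaves every normalized profile
   unchanged but shifts the common reference, so the absolute
   normalized values all move by one shared factor — the tested
   invariant is profile equality, not bitwise column equality.
   Scaling is computed within each (experiment, gel-fraction) stratum
   because separately excised gel fractions are independent MS runs.
3. **Length scaling.** Division by the protein's residue count. Plain
   division is the default; the NSAF convention (additionally
   re-normalizing each column to sum to 1) is available behind
   `nsaf=True` but off by default, since downstream thresholds are
   calibrated on plain length-scaled values.

Counts must be integers at the raw stage (spectra are events);
apportioned and later stages are fractional.

## Phenotype

Normal-embryo survival at 24 hps is the quality criterion: survival ×
(1 − abnormal/100) when an abnormal percentage is recorded. Cuts are
strict (> 90 good, < 30 poor); the 30–90 band is labelled intermediate
and excluded from contrasts. Group summaries use the sample standard
deviation (n − 1) over √n for the SEM.

Tukey's quick (Tukey–Duckworth) test counts values in the
higher-maximum sample above the other sample's maximum plus values in
the lower-minimum sample below the other's minimum; critical values
7 / 10 / 13 give the 0.05 / 0.01 / 0.001 levels. Boundary ties count
one half (Tukey's convention). Two degenerate inputs return statistic
0: one sample spanning the other (no two-tail pattern exists) and both
extremes tied across samples (neither sample owns an extreme). The
statistic depends only on ranks, hence is invariant under strictly
increasing transforms (tested by property).

## Differential regulation

Fold change is computed on group means of N-SC, oriented so it is
always ≥ 1 with a recorded direction. Tier precedence: uniqueness,
then the high cut (5-fold pooled, 4-fold replicated — descriptively
the top ~2.3% of common-protein fold differences), then the 2-fold
cut. In the replicated design, "unique" means the opposite group's
values do not significantly differ from zero by a one-sample t-test
at α = 0.05; without replication the strict all-zero rule applies.
Proteins undetected in both groups are dropped.

Per-protein significance uses Student's pooled-variance t (Welch
behind a flag), two-sided, with BH correction within each fraction's
protein set (a pooling flag exists); "significant" requires raw
p < 0.05 *and* q < 0.1. Zero-variance ties with equal means return
p = 1 rather than NaN. Marker candidacy = (common protein at the high
cut, or unique protein with mean N-SC ≥ 0.5 in its group), gated on
test significance where tests apply.

For category analyses the HMW/LMW fractions are combined and
deduplicated by protein, keeping the larger fold (unique records,
fold = ∞, dominate); statistics stay per-fraction. The overall test is
an uncorrected χ² on the 2 × C table; per-category post-hoc 2 × 2 χ²
p-values are BH-adjusted across the C categories, "other" included.
The category vocabulary is closed (13 curated labels + "other");
unknown labels are a validation error because χ² needs a fixed table.

## Enrichment

The over-representation p-value is the upper-tail binomial probability
P(X ≥ k) with X ~ Binomial(n_list, K_ref/N_ref), matching the classic
gene-list tools; the hypergeometric tail is available for users who
prefer sampling without replacement. Bonferroni multiplies by the
number of terms actually tested (K_ref ≥ 1), not the vocabulary size.
The default reference is the set of proteins detected in the
experiment; a whole-proteome reference table can be supplied instead.
Annotation-database content (GO hierarchies, pathway memberships) is
deliberately out of scope: the package ingests flat protein→term
tables.

## Marker panel

The score is the plain sum of N-SC over panel members, isoform values
summed within a member; absent isoforms contribute zero with a log
warning. Confidence intervals are mean ± t(0.975, n−1) × SEM. The n=4
Student-t interval reproduces the published poor-group bounds
(−2.73, 7.39) exactly from the printed mean 2.33 and SEM 1.59; for the
good group it yields (10.30, 27.04) against printed (10.32, 27.03),
consistent with the source rounding mean and SEM before printing —
we document the difference rather than adjust anything.

The classification threshold is the midpoint between the lower group's
maximum and the upper group's minimum (the published analysis asserts
perfect sorting without stating a rule; the midpoint is the natural
maximum-margin choice for a 1-D separable problem). A leave-one-out
variant re-estimates the threshold without the held-out sample.
Accuracy is invariant under affine transforms of the scores, and under
any strictly increasing transform when the groups are separable; with
overlapping groups the midpoint is not rank-based, so general monotone
invariance cannot hold and is not claimed.

## Synthetic data

The generator emulates the replicated study layout: two groups × 4
spawns, log-normal baseline abundances (log-mean 3 ≈ 20 spectra,
log-sd 1), negative-binomial counts with variance m + φm² (φ = 0.1 by
default; φ = 0 gives Poisson), 20% of proteins with planted uniform
2–8× fold changes split evenly between directions, 20/30 group-unique
proteins as structural zeros, peptides per protein 2–12 with 10%
shared two ways, lengths uniform on 100–2000 residues, 14 functional
categories, ~30 annotation terms at 8% reference frequency with one
planted term over-sampling differentially regulated proteins 10-fold,
and survival records drawn above/below the quality cuts with survival
flat after 24 hps. All draws come from one seeded generator;
identical configs give byte-identical outputs.

What it does *not* emulate: spectra, retention times, identification
FDR, gel migration, correlated proteins (values are independent across
proteins given the design), batch effects, or missingness beyond
sampling zeros and structural zeros. Passing recovery tests therefore
demonstrates correctness of the statistical machinery under the stated
noise model, not robustness to real-data pathologies.

## Problem sizes and numerical choices

The validation suite and the reproduction script use 1000 proteins,
4 vs 4 samples and three seeds per condition — large enough that the
binomial 99% band around a 5% type-I rate is ±1.8 points, small
enough to run comfortably on a laptop. Measured under these
conditions: null t-test type-I ≈ 0.049–0.060, sensitivity to planted
8-fold effects ≈ 0.96–0.98.

Tolerances: conservation and idempotence at 1e-9/1e-12 relative;
table round-trips at 12 significant digits (text TSV interchange).
BH is verified against a brute-force enumeration of the step-up
definition, binomial tails against explicit pmf summation for n ≤ 12,
and χ² against the closed form Σ(O−E)²/E.

## Known limitations

- The upstream identification pipeline (database search, FDR
  filtering, protein grouping) is out of scope; the package starts
  from count tables and trusts their protein groups.
- Proprietary apportionment and total-normalization references in
  commercial tools are unpublished; the implementations here follow
  the published verbal description and are flagged as such.
- Spectral counts are a coarse abundance proxy at low counts; no
  count-model (negative-binomial regression) testing is offered
  because the analysis being reimplemented uses plain t and χ² tests.
- The 2015-era annotation databases behind the original enrichment
  bars are unrecoverable, so enrichment correctness rests on
  closed-form and synthetic planted-term checks.
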