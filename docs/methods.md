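# Methods

## Scope and model

`top3quant` implements the downstream half of a label-free DIA proteomics
comparison: it starts from a long peptide × run intensity table (the kind
of export produced by feature-detection software) and ends at differential
protein classes, clustered expression profiles and pathway
over-representation. Raw spectra, peptide identification and ion-mobility
processing are out of scope; the peptide table is taken as given.

Protein abundance is the Top3 (Hi-3) estimator: the arithmetic mean of the
three most intense peptides of a protein in one injection. When only one or
two peptides are measured, their mean is used and the count is recorded per
cell (`used_peptide_count`); dropping such cells outright would contradict
the downstream ≥2-peptides filter. Intensity ties are broken
lexicographically by peptide sequence so rollup is deterministic. Shared
peptides contribute their full intensity to every protein that lists them —
no apportionment is attempted; the unique-peptide filter protects the
inference instead.

## Normalization

Runs are normalized at the peptide level before rollup. The reference run
is the one whose total log-intensity is the median across runs (ties to the
first in design order); every other run is multiplied by
exp(−median log-ratio to the reference) over peptides observed in both
runs, which drives each run's median log-ratio to the reference to zero. If
a run shares no peptide with the reference (possible only under extreme
missingness) it falls back to total-intensity scaling. Normalizing an
exactly rescaled table is idempotent.

## Filter cascade

Filters apply in a fixed trail: decoy → replication → peptide count →
unique peptide → CV → ANOVA → fold change. Defaults: decoy prefix `REV_`;
full replication in **both** conditions required for testing, with the
all-vs-none presence pattern routed to the exclusive classes; ≥2 peptides,
≥1 unique; CV = SD/mean on linear-scale Top3, computed per condition with
both conditions required ≤ 0.30 (the conservative two-sided reading); then
one-way fixed-effects ANOVA on log2 abundances (variance-stabilized scale)
and the volcano rule: up in tumor iff log2(tumor/control) ≥ +1.2 and
p ≤ 0.05, up in control iff ≤ −1.2 and p ≤ 0.05, boundaries inclusive.
Proteins passing the quality filters but failing ANOVA or the fold-change
cutoff are classed `unchanged` (they survive the cascade; only quality
failures produce `filtered_out`). No multiple-testing correction is applied
to the cascade ANOVA p-values — the classification thresholds raw p ≤ 0.05
by design; BH correction is available in `enrich` where set-level FDR
control is the point.

Degenerate ANOVA cases are deterministic: zero within-group variance with
unequal means gives p = 0, equal constant groups give p = 1. With two
groups the F statistic equals the squared pooled-variance t statistic, a
property the tests exploit against an independent implementation.

## Profiles and clustering

z-scores standardize each protein across all injections (both conditions
pooled). The SD uses the sample convention (n−1) by default; the population
convention can be toggled (`ddof=0`) and the choice is recorded on the
profile object. Constant rows are emitted all-zero and flagged rather than
erroring. Clustering is agglomerative complete linkage on Pearson distance
d = 1 − r; with missing cells the correlation is pairwise-complete with at
least 3 shared positions. Items with undefined distances (e.g. two proteins
exclusive to opposite conditions share no runs) are excluded greedily —
repeatedly dropping the item with the most undefined pairs — and reported.
Dendrograms serialize to Newick with branch lengths equal to merge-height
differences, so every leaf's root distance is the root merge height.

## Enrichment

Over-representation uses the one-sided hypergeometric tail
P(X ≥ k | N, K, n) with log-gamma-stable evaluation, BH step-up FDR across
sets, retention at FDR ≤ 0.05 and −log10(FDR) for plotting. The default
universe is the quantified-protein list rather than a whole annotation: a
membrane-enriched input against a genome-wide universe would be
anticonservative. Identifier matching is exact-string and case-sensitive.

## Synthetic data generator

The generator emulates the structure of the motivating two-cell-line
experiment, and its defaults are the study conditions used throughout the
tests:

| parameter | default | rationale |
|---|---|---|
| n_proteins | 1300 | shared quantifiable proteins in the reference dataset |
| mean_peptides_per_protein | 9 | observed average; counts are 1 + Poisson(mean−1), so ≥1 |
| abundance_span_orders | 6.5 | reported dynamic range (log10) |
| replicate_cv | 0.15 | mid-range replicate variability for DIA label-free data |
| ppm_error_sd | 6.6 | makes the expected within-±10-ppm fraction 2·Φ(10/6.6)−1 ≈ 0.870, matching the ~87% regime reported |
| frac_exclusive_per_condition | 0.025 | ≈ 32/33 exclusive proteins at n = 1300 |
| frac_decoy | 0.05 | enough reversed entries to exercise the decoy filter |
| frac_diff | 0.15 | not stated by the reference analysis; a generator choice |
| log2 effects | Normal(0, 2) | spans sub-cutoff to >4-fold effects in both directions |
| dropout | logistic in log10 intensity, midpoint 0.5, steepness 3 | intensity-dependent missingness without modeling acquisition |

Base abundances are log-uniform over the configured span. Peptide
ionization factors are lognormal(0, 1) rescaled per protein so that the
mean of the top-min(3, k) factors is exactly 1: a protein's noise-free Top3
then equals its base abundance, which makes the noise-free limit exactly
identifiable and keeps the simulated matrix's dynamic range equal to the
sampled abundance span under null effects. Replicate noise is mean-one
lognormal with the configured CV. Peptide sequences are synthetic
tryptic-like strings (K/R-terminated, length 7–20) with theoretical
monoisotopic masses from pyteomics; 5% of peptides are shared with a
second protein and flagged non-unique. Decoy proteins carry the `REV_`
prefix in the ledger and are simulated like ordinary null proteins so they
survive to the post-quantification stage where the cascade discards them.

What the generator does **not** emulate: correlated peptide noise within a
protein, retention-time or batch drift, interference/chimeric signals,
identification errors, and non-lognormal heavy-tailed noise. Passing tests
therefore demonstrate correctness of the analysis logic and calibration
under the stated noise model, not robustness to every artifact of real
acquisitions.

## Verification strategy and problem sizes

Every statistical routine is checked against an independent oracle: the
cascade against a literal single-pass reimplementation on random ≤20-protein
tables; complete linkage against a naive O(n³) agglomerator via cophenetic
distances (invariant to tie order); the ANOVA against scipy's `f_oneway`
and the t² identity; BH against a hand-coded step-up on all permutations of
five p-values; the hypergeometric tail against exhaustive `math.comb`
enumeration for all universes N ≤ 12. Calibration checks use 20 null
simulations of 2,000 proteins (type-I error in [0.03, 0.07]), a ≥10⁵-row
table for the ppm fraction (±0.01 of the closed form), and 500-protein
noise-free runs for exact recovery; these sizes give stable Monte-Carlo
estimates while keeping the default suite in the minutes range.
`scripts/acceptance.py` reruns the default 1,300-protein conditions plus a
reduced 5×1,000-protein null calibration for its reported type-I rate.

## Known limitations

- The CV filter is applied per condition (both must pass); whether the
  original analysis pooled all six runs is not determinable, so the choice
  is recorded in every record's filter trail for auditability.
- Exclusive-protein calls use the strict all-vs-none rule; under dropout a
  planted exclusive can be missed (a replicate dropped) or a low-abundance
  null protein can masquerade as exclusive, which is visible in the
  recovery report's confusion table.
- `normalize_runs` assumes shared peptides dominate; with systematic
  condition-specific proteomes the median log-ratio can absorb real
  biology.
- Enrichment treats sets as flat lists; no topology or redundancy
  handling.
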