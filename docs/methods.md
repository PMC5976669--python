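# Methods

This note documents the models, estimators, numerical choices and known
limitations behind each module, and what the synthetic-data generator does
and does not emulate.

## Count model and the exact NB test

Counts for gene *g* in sample *s* are modeled NB(μ_gs, φ) with
Var = μ + φμ², φ shared across genes (φ = 0 is the Poisson limit). The
two-group test follows the exact-test construction of the empirical-DGE
family:

1. **Scale factors.** Per-sample factors are the trimmed mean (30%
   symmetric trim) of log2 ratios to a per-gene geometric-mean
   pseudo-reference, restricted to genes observed in every sample, and
   renormalized to geometric mean 1. These factors absorb both sequencing
   depth and composition bias; a column that is exactly 2× another gets a
   factor 2× larger. Effective library sizes anchor the factors to the
   geometric mean of the column sums.
2. **Quantile adjustment.** Counts are mapped to a common library size by
   an NB quantile–quantile transform, approximated as the average of a
   moment-matched normal map and a moment-matched gamma map. The transform
   is the identity when library sizes are equal, so small-sample oracle
   comparisons are exact.
3. **Common dispersion.** φ maximizes the conditional log-likelihood of the
   within-group counts given their totals (exchangeable replicates after
   equalization), optimized over log10 φ ∈ [−6, 1] by bounded scalar
   minimization; estimates below 2×10⁻⁶ are reported as 0. On data
   simulated at known φ the estimator is unbiased to within simulation
   error (checked at φ = 0 and φ = 0.4 with 5,000 genes).
4. **Exact test.** Conditional on a gene's total *s* (group sums rounded to
   integers after adjustment), the split probabilities are
   P(a) ∝ f_NB(a; n_A μ, φ/n_A) · f_NB(s−a; n_B μ, φ/n_B) with μ = s/(n_A+n_B);
   the two-sided p-value sums all splits no more likely than the observed
   one (likelihood-ordering double tail, with a 1e−12 relative slack so
   exact ties are included). At φ = 0 this is the exact binomial split
   test. The per-gene cost is O(s), acceptable for bulk depths.

Fold changes are computed on depth-normalized group means with a
configurable pseudocount (default 0; a zero-vs-positive comparison yields a
±∞ sentinel that clears any finite threshold). Calls use strict
inequalities — |FC| > 3 and FDR < 0.01 — so values exactly at a threshold
are not called. FDR is Benjamini–Hochberg. The study's per-transcript fold
magnitudes from the original tool are not reproducible since its
normalization and pseudocount are unpublished; the thresholds and test
family are what this package commits to.

The ΔΔCt utility returns 2^−ΔΔCt; group comparison uses the two-sided
Mann–Whitney U test, exact for ≤ 8 replicates per arm.

## Specificity

z-scores standardize one gene's expression across conditions; the sample
(n−1) standard deviation is the default (configurable `ddof`). A constant
row maps to all-zero z and is unclassifiable rather than an error. The
specificity rule requires z > 1.5 in exactly one condition. Note an
algebraic constraint: with the sample sd, the largest attainable z over n
conditions is (n−1)/√n, which equals exactly 1.5 at n = 4 — so a 4-month
panel can never satisfy the rule with ddof = 1. The pipeline therefore
classifies month specificity with the population sd (ddof = 0, maximum
√3 ≈ 1.73); tissue panels (n = 13, maximum ≈ 3.33) use the default.

Enrichment folds are proportion ratios rounded to one decimal (raw value
available via `ndigits=None`); a zero-specific background returns an
infinite-fold sentinel with a warning. Temporal trajectories are per-month
case/control ratios with a 0.01 TPM pseudocount, aggregated over a gene
list by the unweighted mean of per-gene ratios.

## Co-localization

Intervals are 0-based half-open in memory (GFF3 written 1-based inclusive,
BED 0-based half-open). The gap is the number of bases strictly between
the nearest ends of the two loci, strand-agnostic; "< 50 kb" is strict.
Intersecting loci are `overlap` with gap 0; abutting loci (zero intervening
bases) are also treated as overlap, since no base separates them.
Orientation is sense iff strands match. The chi-square tests use Pearson's
statistic without continuity correction so small printed tables match the
hand formula; the enrichment denominator for "all pairs" is the full DE
lncRNA × DE mRNA cross. The correlation-sign classes for the orientation
association are R > 0 vs R < 0 (threshold-free), with NaN correlations
dropped.

## miRNA sites, consensus, sponges, precursors

The built-in scanner is a deterministic canonical-seed stand-in for
external predictors, not a thermodynamic model: a site is a
reverse-complement match on the target (5'→3') to miRNA positions 2–7,
upgraded to 7mer-m8/7mer-A1/8mer by the flanking position-8 match and/or an
A opposite position 1. U and T are interchangeable on input; the internal
alphabet is DNA. mRNAs are scanned only in the annotated 3'UTR, lncRNAs
full-length. Each 6mer core match is reported once at its most specific
class.

Consensus across predictor tables requires sites for the same (miRNA,
transcript) from ≥ k sources (default: all) with coordinate overlap ≥ 1 nt;
the consensus interval is the intersection, and an `exact=True` switch
demands identical coordinates, since tools differ in coordinate
conventions. Lowering k never shrinks the supported regions. Score gates
follow the published per-tool semantics: energy ≤ −20 kcal/mol for every
source, miRanda score ≥ 150, TargetSpy ≥ 0.99; sources without a score
threshold are gated by energy alone.

Sponge triples pair every miRNA that has a (high-confidence) site on both a
lncRNA and an mRNA, annotated with the lncRNA–mRNA Pearson correlation and
ranked by it. Pre-miRNA harboring is exact substring matching (no
mismatch, no gap) on both strands of the host; a query longer than its
host is simply no hit.

## Interaction filtering

RNA–RNA and RNA–protein predictors are imported-table inputs. Thresholds
keep their published strict/inclusive semantics: energy < −100 kcal/mol
(exactly −100 dropped), strength and power ≥ 96% (exactly 96 kept); both
filters are idempotent. The toy complementarity-run scorer (−2 kcal/mol per
base of the longest exact reverse-complement run, found by binary search
over shared k-mers) exists only so the synthetic pipeline can exercise the
filtering stage; it is explicitly non-physical.

## Co-expression network

Columns are scaled to equal totals (mean library), then pairwise Pearson
correlations are computed on the scaled values without log transform (a
log2(x+1) option exists). The edge rule is strict: R > 0.97 or R < −0.97;
R = 0.97 exactly is no edge. Constant rows are excluded with a warning.
Components are ordinary undirected connected components over non-isolated
nodes (an edgeless graph has zero components), tallied per biotype; hubs
are ranked by degree with ties broken by id (betweenness available as an
alternative "centrality" reading). Exports: SIF (`coexp` relation) and
GraphML with biotype/direction node attributes; both round-trip. The null
edge probability at threshold r with n samples is the exact t-tail
2·P(t_{n−2} > r√((n−2)/(1−r²))) — at r = 0.97, n = 30 it is ~10⁻¹⁸, so any
observed null edge indicates a bug, and planted-module recovery is
essentially deterministic.

## Synthetic-data generator

The generator emulates the *structure* of the study design: a toy genome
(default 5 × 10 Mb chromosomes) with 60 mRNA and 80 lncRNA loci placed in
blocks ≥ 200 kb apart so that a configurable fraction of lncRNAs is within
50 kb of (or overlapping) a partner mRNA and all others are ≥ 200 kb from
every mRNA; every mRNA carries a 300-bp 3'UTR; 10 miRNAs (22 nt) with
64-nt precursors, two of which are inserted verbatim into host lncRNAs.
Planted 8mer site strings are made unique by scrubbing chance occurrences
(iterated point mutation outside protected regions), so scanning at the
8mer class recovers planted sites with precision and recall 1. Counts are
NB with shared φ (default 0.1), 4 replicates per group at mean depth 10⁶
and a 2× log-uniform library-size spread; planted signed folds (default
4–12×) set the case/control mean ratio exactly, up to the per-library depth
renormalization. Panels: 13 tissues with 20× elevation for
tissue-restricted genes over lognormal noise; 4 months with one library per
month (as in pooled time-course designs) and a 6× December peak in the case
series; 30 samples in which module members share a latent factor (loading
0.999, noise sd 0.01 → within-module |R| ≈ 0.9999). Planted modules are
sign-pure: a shared per-sample scaling constant adds common-mode variation
that caps attainable anti-correlation, so planted anti-members could not
hold |R| > 0.99 after normalization; negative edges are exercised by
dedicated fixtures instead.

What it does **not** emulate — and hence what passing tests do not show
about real data: introns and isoforms (transcript = locus), GC/length
biases, mapping ambiguity, overdispersion heterogeneity across genes
(tagwise dispersion), correlated baseline programs outside planted modules,
real seed-pairing thermodynamics, and real genome composition (background
is uniform A/C/G/T). Problem sizes in the test-suite and acceptance runs
(150-transcript genomes, 400–2,000-gene count matrices) were chosen as the
smallest at which the calibration quantities are statistically
well-resolved.

## Pipeline

One declarative config (YAML-loadable; validation collects all errors and
names offending keys) drives the stage graph; each stage writes its table
before dependents run, the resolved config is written next to the outputs,
and the JSON report holds only quantities re-derivable from the stage
files. File-based (non-simulated) inputs run through the per-stage CLI
subcommands; `degradome all` currently orchestrates the synthetic design
end to end.

## Known limitations

- Common dispersion only; no tagwise/trended dispersion or GLM designs.
- The exact test's O(s) enumeration is slow for extremely deep single
  genes (s ≫ 10⁶).
- The consensus rule enumerates site combinations per (miRNA, transcript);
  pathological inputs with hundreds of stacked sites per pair would be
  slow.
- Month specificity at n = 4 is sensitive to the sd convention (see
  above); reported month-specific counts should be read with that in mind.
- The toy interaction scorer is not a physical energy model.
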