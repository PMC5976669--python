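# degradome

Toolkit for analysing the coding/noncoding transcriptome of atrophying
skeletal muscle: which mRNAs, long noncoding RNAs (lncRNAs) and microRNAs
change together, where their genes sit relative to each other, and how they
might interact — as miRNA targets, miRNA "sponges" (competing endogenous
RNAs), miRNA precursors, or direct RNA–RNA/RNA–protein binding partners.
The motivating system is gonadogenesis-associated muscle atrophy in rainbow
trout (gravid diploid females vs sterile triploids, 4 fish per group), but
every operation is generic bulk-RNA-seq methodology.

It is written for computational biologists who have count/TPM matrices and
annotation in hand and want the full interaction analysis — or who want to
validate such a pipeline end to end against planted ground truth, which the
built-in synthetic-data generator provides.

## What it computes

**Differential expression.** Two-group exact negative-binomial test in the
Robinson–Smyth family: counts are quantile-adjusted to a common library
size (trimmed-mean-of-log-ratio scale factors), a common dispersion φ
(Var = μ + φμ²) is estimated by conditional maximum likelihood, and each
gene's group sums are compared by conditional exact enumeration. Fold
changes are signed (B/A up, −A/B down, so |FC| ≥ 1) and calls use the
strict thresholds FDR < 0.01 (Benjamini–Hochberg) and |FC| > 3.

**Specificity.** A gene is *specific* to a tissue (13-tissue TPM panel) or
month (4-month panel) when its z-score exceeds 1.5 in exactly that
condition; enrichment of specificity among DE genes is a simple proportion
ratio, e.g. (348/852)/(4,583/61,412) = 5.5-fold for muscle-specific mRNAs.

**Genomic co-localization.** lncRNA–mRNA pairs that overlap or sit < 50 kb
apart (strict; gap measured between nearest interval ends), sense/antisense
orientation, Pearson correlation of expression, a 2×2 chi-square for
enrichment of strong correlation (R > 0.85) among co-localized pairs, and
the distance–correlation trend.

**miRNA interactions.** Canonical seed-site scanning (6mer/7mer-A1/7mer-m8/
8mer reverse-complement matches to miRNA positions 2–8), a consensus rule
over external predictor tables ("same site from all k tools", coordinate
overlap ≥ 1 nt), the published score gates (energy ≤ −20 kcal/mol, miRanda
≥ 150, TargetSpy ≥ 0.99), sponge triples (miRNA with sites on both a lncRNA
and an mRNA, ranked by lncRNA–mRNA correlation), reciprocal-DE filtering,
and exact-substring detection of ~64-nt pre-miRNAs harbored inside lncRNAs.

**Interaction filtering.** Imported RNA–RNA tables kept at energy
< −100 kcal/mol (strict) and RNA–protein tables at strength ≥ 96% and
discriminative power ≥ 96% (inclusive), plus the pass/fail × strong/weak
correlation chi-square.

**Co-expression network.** Pearson correlations over a 30-sample panel on
scale-normalized values; an edge requires R > 0.97 or R < −0.97 (strict).
Connected components are the coordinated programs — in atrophying muscle
the large upregulated component is the proteolytic "degradome" — with
degree-ranked hubs and SIF/GraphML export for Cytoscape.

## Worked example

Run the whole pipeline on a synthetic dataset (150 transcripts on a toy
5-chromosome genome, 4 vs 4 counts, 13-tissue/4-month/30-sample panels):

```sh
degradome all --outdir demo_run --seed 7
```

which prints the run report (abridged):

```json
{
 "de":        {"de_total": 44, "up": 19, "down": 25,
               "de_by_biotype": {"mRNA": 13, "lncRNA": 30, "miRNA": 1}},
 "specificity": {"tissue_specific": 116, "tissue_specific_in_de": 33,
               "peak_month": "December"},
 "targets":   {"sites": 15},
 "sponges":   {"triples": 10, "mirnas_shared": 5},
 "premirna":  {"harbored": 2},
 "network":   {"edges": 132, "component_sizes": [12, 12]}
}
```

Reading it: of 45 transcripts planted as differentially expressed, 44 are
called (19 up, 25 down) and none of the null transcripts are; the temporal
profile of planted December-peaking genes indeed peaks in December; all 15
planted 8mer seed sites are found, giving the 10 planted sponge triples;
both pre-miRNA inserts are recovered at their exact offsets; and the
co-expression network resolves exactly the two planted 12-member
correlation modules. Stage tables (`de_table.tsv`, `coloc_pairs.tsv`,
`sponge_triples.tsv`, `network.sif`, ...) and `ground_truth.json` are left
in `demo_run/`.

Individual stages are exposed as subcommands (`degradome de`,
`degradome coloc`, `degradome targets`, `degradome network`, ...) and as
plain library functions (`degradome.diffexpr.de_analysis`, etc.).

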