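# dosereg

Allelic-series dosage-response transcriptomics with ChIP-seq target
integration.

`dosereg` is for researchers dissecting *gene dosage*: when a pair of
redundant paralogous transcription factors (the motivating case is the
Pax1/Pax9 pair in sclerotome and intervertebral-disc development) is knocked
out copy by copy, which downstream genes give way at which rung of the allele
ladder? The package takes bead-array–style expression data over the four
genotypes (2,2) → (0,2) → (0,1) → (0,0) functional copies, plus binding peaks,
gene models, a genome and a motif, and produces:

1. **Preprocessing** — quantile normalization, detection-flag filtering
   (present: detection p > 0.8 in ≥ 1 sample), 20–100th percentile filtering,
   probe→gene collapse.
2. **Differential expression** — signed fold changes on linear group means,
   Welch one-way ANOVA (or t-tests), Benjamini–Hochberg FDR, SNK post hoc;
   significant ⟺ q < 0.05 and |FC| ≥ 1.5.
3. **Dosage classification** — with S_i = (|step FC_i| ≥ 1.5) over the three
   consecutive ladder contrasts: group 1 = (¬S₁∧¬S₂∧¬S₃) (gradual, all
   alleles contribute), group 2 = (¬S₁∧S₂∧¬S₃) (two copies of the second
   paralog required), group 3 = (¬S₁∧¬S₂∧S₃) (a single copy suffices);
   applied to all genes with |overall FC| ≥ 1.5.
4. **Peak annotation** — six-way distance taxonomy around the TSS
   (TSS / promoter / intragenic / proximal / distal / others).
5. **Motif scanning** — PWM log-odds scores with *exact* dynamic-programming
   p-values, two-strand scanning at p ≤ 0.001, and a binomial
   central-enrichment statistic over peak centers.
6. **Target integration** — direct (DE ∧ bound) vs indirect (DE ∧ ¬bound)
   calls, bound fractions, hypergeometric overlap, Venn-region counts.

A synthetic-data generator plants all of this with recorded ground truth —
dosage classes, peak categories, motif instances — so the entire pipeline is
testable without any external download. See `docs/methods.md` for the model,
conventions and caveats.

## Worked example

Run the full pipeline on the default synthetic dataset (2,000 genes, 100 per
planted dosage class, 3 replicates per genotype, σ = 0.15 log2 noise; 600
peaks over a 26 Mb toy chromosome with the consensus CGCGTGACCG planted at
every summit):

```sh
dosereg run-all --seed 1 --outdir run1
```

The manifest (`run1/manifest.json`) records, per stage:

```
preprocess: 2000 probes in, 1800 after the flag filter, 1547 after the
            percentile filter
de:         354 of 1547 genes significant (WT vs double-null, q<0.05, |FC|>=1.5)
dosage:     universe 490; group1 252, group2 89, group3 149, unclassified 0
annotate:   600 peaks categorized
scan:       762 motif hits; 600/600 peaks with a passing site, all central
integrate:  1571 target calls; 5.4% of DE genes bound
```

Reading these numbers: the universe (490) holds every gene whose overall
fold change crosses 1.5; group 2 is visibly under-recovered (89 observed vs
200 planted) because its defining step, 2^0.6 ≈ 1.52-fold, sits only 0.015
log2 above the 1.5-fold threshold — about half of the group 2 genes fail
their defining predicate at this noise level and are re-labelled group 1
(that is a property of thresholded step classification, quantified in
`docs/methods.md`). The bound fraction is low here simply because the toy
genome carries peaks for 100 of the 2,000 simulated genes. Each stage's
table (`dosage_assignments.tsv`, `peak_annotations.tsv`, `target_calls.tsv`,
…) is tab-delimited with a `#`-prefixed header.

Individual stages are available as subcommands (`simulate`, `preprocess`,
`de`, `dosage`, `annotate-peaks`, `scan-motifs`, `integrate`) on files you
provide; `dosereg --help` lists the options.

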