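# hexatac

Integrative chromatin-accessibility / expression analysis for hexaploid
genomes: ACR refinement and annotation, tissue-specificity clustering of
differential accessibility and expression, homeolog-triad bias
classification, subgenome motif-density profiling, and stage-resolved
TF→target network construction — exercised end-to-end on a synthetic
three-subgenome genome with full ground truth, so no external data is
required.

## Modules

| module | what it does |
| --- | --- |
| `hexatac.genomic_core` | interval/gene/genome types, BED/GFF3/FASTA/TSV I/O, TPM, promoter windows, nearest-gene lookup |
| `hexatac.synthetic_hexaploid` | simulator: three labelled subgenomes, syntenic triads, planted tissue-specific ACRs with Tn5 integration pileups, accessibility-coupled expression, planted bias categories, motif occurrences per cluster/subgenome cell, variant depletion at distal ACR centers — all recorded in a `GroundTruth` bundle |
| `hexatac.acr_refinement` | raw-peak refinement (150 bp bins / 50 bp step → Poisson-calibrated integration-density filter → 150 bp-gap merge → blacklist/organelle masking), genic/proximal/distal classification, replicate QC, variation metaprofiles |
| `hexatac.differential_accessibility` | CPM-in-peaks scoring, moderated-t pairwise calling with BH adjustment, eight-way specificity clustering, median-of-ratios DE calling (padj < 0.01, \|log2FC\| > 1), ACR–gene association, permutation overlap enrichment |
| `hexatac.triad_bias` | seven-centroid ternary classification (Balanced / A-B-D Dominant / A-B-D Suppressed), stage-transition tables, expression-vs-accessibility concordance |
| `hexatac.motif_regnet` | IUPAC/PWM motif scanning (both strands, palindromes deduplicated), per-cluster × subgenome density tables with the density > 1/kb flag, TFBS∩ACR intersection, four-gate TF→target network |
| `hexatac.cli_pipeline` | configuration, the `run_all` orchestrator and the `hexatac` CLI |

## CLI

```sh
# synthetic fixture with ground truth
hexatac simulate --seed 7 --outdir fixture/

# everything at once (simulates into OUTDIR/fixture when --simulate is set)
hexatac run-all --simulate --seed 7 --outdir out/

# individual stages
hexatac refine-peaks --peaks peaks.bed --tis tis_r1.bed --tis tis_r2.bed \
    --genome genome.fa --blacklist blacklist.bed --out acrs.bed
hexatac classify-acrs --acrs acrs.bed --gff3 genes.gff3 --out classes.tsv
hexatac diff-genes --counts counts.tsv --out degs.tsv
hexatac triad-bias --triads triads.tsv --matrix tpm.tsv --out bias.tsv
hexatac enrich-overlap --set-a a.txt --set-b b.txt --universe u.txt
hexatac build-network --indir fixture/ --out edges.tsv
```

Every threshold lives in a YAML config (`--config cfg.yaml`); defaults are
bins 150/50, merge gap 150, promoter −2000/+100 bp, class cutoff 2 kb with
a {2,4,5,6,8,10} kb scan, DEG padj < 0.01 and |log2FC| > 1. Each output
table embeds the fully resolved parameter set in its `#` header, and
`run-all` writes a manifest of output SHA-256 hashes — two runs with the
same seed are hash-identical.

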