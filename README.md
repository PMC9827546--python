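# mitoburst

Analysis pipeline for **post-mitotic transcriptional reactivation** and its
modulation by **mitotic bookmarking** transcription factors, built around the
kind of experiment where mitotically arrested cells (nocodazole block) are
released and sampled densely — asynchronous (A) and mitotic (M) reference
pools plus release timepoints at 20, 30, 40, 50, 60, 90 and 120 minutes —
with transcription read out as **pre-mRNA (intronic) TPM**, optionally in two
arms (untreated vs. acute CTCF depletion through an auxin-inducible degron,
+IAA).

It is written for computational biologists who want to re-run this style of
analysis end-to-end, on their own data or on the bundled synthetic generator
that plants known ground truth under every stage.

## What it computes

**Trajectories.** For each gene, per-replicate log2 fold changes to the
paired mitotic sample, then averaged:
lfc_g(t) = mean_r log2((TPM_{g,t,r} + pc) / (TPM_{g,M,r} + pc)), with the
asynchronous anchor computed identically and a pseudocount pc = 1 TPM.
Genes are kept when mean asynchronous TPM > 0.5 or TPM > 0.5 in at least two
release samples (curated genes only), and ranked by the mean fold change
over 20–90 min.

**Reactivation timing.** A gene's class is the earliest release minute at
which lfc_g(t) reaches its asynchronous level: t40 (reached by 40 min), t50,
t60, t90, or late (120 min or never). Genes *below* their mitotic level in
asynchronous cells form the separate G1_high class (preferential early-G1
transcription). Cumulative curves report the percentage of genes past their
trajectory maximum and at asynchronous levels per timepoint; PCA on
per-sample fold changes yields the PC1t/PC1b/PC2t/PC2b loading groups.

**Enrichment.** One-sided Fisher (hypergeometric upper tail, log-space)
with Benjamini–Hochberg correction, applied per gene set to windows slid
along the ranking and to fixed groups.

**Bookmarking proximity.** Interphase binding sites overlapping a mitotic
site are *Book*, the rest *Lost*. Per gene class the pipeline reports the
fraction with a site within a 25-kb TSS window, site-count and
binding-level (RPM) distributions, distance-stratified Fisher tracks
(group membership vs. nearest Book/Lost site within d, over a 1 kb–1 Mb
grid), and strand-oriented metagene coverage profiles over 8 kb around
TSSs.

**Depletion response.** Per contrast (asynchronous, each release minute),
+IAA vs. untreated on log2(TPM+1) with an empirical-Bayes moderated t
(gene-wise variances shrunk toward a fitted prior; a plain Welch variant
and an import path for externally computed DE tables are provided). A gene
responds if FDR < 0.1 and |log2FC| > 0.2 in asynchronous or in ≥ 2 release
contrasts; responders are classed asy/late/early × up/down.

## Worked example

```bash
mitoburst simulate --seed 1 --n-genes 2000 --outdir results/synthetic
mitoburst run --indir results/synthetic --outdir results/pipeline_run
mitoburst report --run-dir results/pipeline_run
```

or, step by step with commentary, `python analysis/01_simulate.py` …
`06_report.py`. On seed 1 the run prints:

```
expression filter: 1600/2000 genes kept
reactivation classes: {'t40': 793, 'late': 311, 't50': 173, 'G1_high': 160, 't60': 154, 't90': 9}
maximum-reached plateau: 83.9% (the rest peak in asynchronous cells)
949/3004 interphase peaks retained in mitosis (Book)
173 depletion-responsive genes: {'early_down': 56, 'late_down': 33, 'early_up': 30, ...}
early_down vs Book/Lost (-log10 p) at <=25 kb:
label         Book  Lost
1.0          12.02  0.77
2.5          16.96  0.42
5.0          21.75  0.45
```

Reading: the 400 planted silent genes fall below the expression filter; the
planted fast-burst genes dominate t40; genes maximal in asynchronous
populations (the S-phase-like program) cap the maximum curve at ~84%; and
genes that lose expression early after mitosis upon CTCF depletion
(early_down) are strongly and specifically enriched near *bookmarked* —
not lost — binding sites, the planted bookmarking signature.

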