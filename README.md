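# regulonseq

Reconstruction of a bacterial transcription-factor regulon from paired
ChIP-seq and RNA-seq data, built around the analysis of a CRP-family
regulator (CgrA-like, cGMP-responsive) on a dense high-GC replicon.

Given per-base IP and input coverage, a gene-by-sample count matrix for
wild-type and TF-deletion strains, the genome sequence and its annotation,
the pipeline answers: *which genes does the TF regulate, and which of those
does it regulate directly, by binding their promoters?*

## Method in brief

1. **Peaks** — two independent background models over 300 bp windows:
   an upper-tail Poisson test against a local lambda
   (max of genome-wide and 1/5/10 kb input means, input scaled to IP depth,
   p ≤ 1e-5) and a GC-stratified negative-binomial test with per-GC-bin
   robust depth scaling. Only peaks called by both are retained.
2. **DEGs** — median-of-ratios normalization, moderated NB Wald test,
   Benjamini–Hochberg FDR; a gene is differentially expressed when
   |log₂FC| ≥ 1.32 (fold change ≥ 2.5) at q < 0.05. Negative log₂FC
   (lower in the deletion strain) means TF-activated.
3. **Motifs** — the CRP palindrome TGTGA-N₆-TCACA (16 bp) and relaxed
   GTG-N₈-CAC / GTG-N₁₀-CAC cores, scanned as exact spaced dyads and as a
   PWM with exact per-position p-values (column-convolution null).
4. **Integration** — summit context classification (intergenic upstream /
   divergent pair / intragenic-upstream / intragenic / rRNA-tRNA locus),
   operon inference (same strand, gap < 50 bp, co-expression within
   1 log₂ unit), and assignment of each DEG as **direct** (summit within
   −1000..+50 bp of its start codon), **direct via operon**, or
   **indirect**, with intergenic-enrichment and peak-height statistics.

A synthetic-data module generates complete datasets with planted sites,
operons and fold changes plus ground-truth tables, so every stage can be
scored for recall and false positives; a transcription of the published
direct-regulon table is packaged for replay.

## Worked example

```python
from regulonseq import PipelineConfig, run_pipeline

summary = run_pipeline(PipelineConfig(outdir="demo", seed=1))
print({k: summary[k] for k in
       ("n_direct", "n_direct_via_operon", "n_indirect",
        "intergenic_peak_fraction", "intergenic_enrichment_p")})
```

prints

```
{'n_direct': 16, 'n_direct_via_operon': 13, 'n_indirect': 10,
 'intergenic_peak_fraction': 1.0,
 'intergenic_enrichment_p': 9.980018988604835e-21}
```

On the default 200 kb simulation (20 planted sites, 8× enrichment, three
replicates per condition) the consensus caller finds all 20 sites with no
false positives; of the 39 genes with planted expression changes, 16 are
recovered as directly bound, 13 as members of directly bound operons and
10 as indirect — exactly the planted structure. All 20 summits are
intergenic against a 10 % intergenic genome, and the binomial enrichment
p-value (~1e-20) mirrors the strong intergenic bias reported for
CRP-family binding. Stage outputs (narrowPeak, DEG and regulon TSVs,
summary JSON, run manifest) land under `demo/`.

The same stages are exposed on the command line:

```sh
regulonseq simulate --seed 1 --outdir demo/data
regulonseq callpeaks --ip demo/data/ip.bedgraph --input demo/data/input.bedgraph \
    --genome demo/data/genome.fasta --annotation demo/data/annotation.gff3
regulonseq deg --counts demo/data/counts.tsv
regulonseq replay-table1
```

`replay-table1` recomputes the published direct-regulon bookkeeping from
the packaged table:

```json
{"unique_loci": 45, "direct_genes": 30, "singular_genes": 25,
 "first_in_operon_genes": 5, "activated": 22, "repressed": 8,
 "divergent_pairs": 2, "distinct_peaks": 27, "dyad_consensus_peaks": 1}
```

i.e. 30 genes sit directly downstream of a binding peak (25 singular,
5 operon-first; 22 activated, 8 repressed; two divergent pairs share one
peak each), expanding to 45 loci once operon members are counted.

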