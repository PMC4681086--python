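# Methods

`regulonseq` reconstructs a bacterial transcription-factor (TF) regulon by
integrating two genome-wide measurements: ChIP-seq binding-site calls for
the TF and RNA-seq differential expression between a wild-type and a
TF-deletion strain. The design target is a CRP-family regulator (CgrA-like)
on a single dense, high-GC replicon, but every threshold is configurable.

## Peak calling

Coverage tracks are per-base fragment pile-ups for the immunoprecipitated
(IP) and input (sheared whole-genome) samples. Both callers slide a 300 bp
window in 75 bp steps and convert the window coverage mass to approximate
fragment counts by dividing by the fragment size; testing raw per-base sums
against a count distribution would be overdispersed by a factor of the
fragment size. Fragment-count mass (sum of fractional window overlaps of
independent Poisson fragments) has variance at most its mean, so the tail
tests below are mildly conservative.

* **Local-lambda Poisson caller.** The input is scaled to the IP depth; the
  expected window count is the maximum of the genome-wide mean and the
  1 kb / 5 kb / 10 kb local input means around the window. A window is
  significant when the upper Poisson tail of its IP count is at or below
  the cutoff (default 1e-5). This mirrors the classic model-based caller's
  band-width-300 local background; fragment-model estimation is not
  reproduced — the fragment size is a configuration input.
* **GC-aware NB caller.** Windows are stratified into GC-fraction bins
  (default 10 equal-width bins; bins with fewer than 20 windows merge into
  their nearest populated neighbour). Per bin, a negative-binomial
  background is fitted to the input window counts by method of moments,
  after scaling by a robust per-bin depth ratio, median(IP)/median(input).
  The per-bin ratio is what makes the caller GC-aware in practice: a
  GC-tracking amplification bias present only in the IP inflates the naive
  global scaling of the Poisson caller but is absorbed here. When the input
  shows no overdispersion the NB fit degenerates to Poisson.
* **Consensus.** Peaks from the Poisson caller overlapping (>= 1 bp) any NB
  peak are retained, keeping the Poisson caller's interval and summit
  (leftmost maximal base on ties) — the geometry convention the reference
  analysis reports.

## Differential expression

Counts are normalized by median-of-ratios size factors (geometric mean 1).
Genes with mean normalized count below 10 in both conditions are not
tested. For the rest, a per-gene NB dispersion (var = mu + alpha mu^2) is
estimated by pooled method of moments and shrunk toward the median
dispersion of the well-expressed genes with a prior weight of 4 pseudo-df —
the usual moderation remedy for 3-vs-3 designs, where raw per-gene
dispersions carry only 4 df. The Wald statistic log2FC / SE uses a
delta-method SE and a two-sided t reference at residual-plus-prior df
(8 at 3-vs-3); at larger replication this converges to the normal
reference. A plain plug-in normal Wald was measurably anti-conservative
(~11 % of null genes at p < 0.05 with 3 replicates); the moderated t
variant sits near nominal while keeping full power on 4-fold planted
effects at the default depth. Zero condition means get a 0.5
normalized-unit pseudocount, preserving ordering while avoiding infinite
fold changes.

A gene is a DEG when |log2FC| >= 1.32 (fold change >= 2.5) and the BH
q-value is below 0.05, computed over tested genes. Sign convention:
fold change is mutant over wild type, so TF-*activated* genes have
negative log2FC (lower in the deletion strain), repressed genes positive.

## Motif analysis

The binding site is the CRP-type palindrome TGTGA-N6-TCACA (16 bp), with
relaxed cores GTG-N8-CAC and GTG-N10-CAC. Two scanners are provided:

* **Spaced dyad**: exact matching of half-sites around each allowed spacer
  on both strands, overlapping hits included. The strict dyad is its own
  reverse complement in shape, so every forward hit pairs with a reverse
  hit over the same interval.
* **PWM**: log-odds bits against the genome mononucleotide background
  (uniform backgrounds mislead at 70.5 % GC). Per-position p-values are
  exact: the null score distribution is built by column-wise convolution
  of the score distribution discretised at 0.001 bits, and scanning uses
  the same discretisation, so scan results match exhaustive enumeration on
  small widths.

Motif alignment/EM discovery is out of scope: sites enter pre-aligned
(fixed-width windows around dyad hits), and consensus construction is
majority-per-column with IUPAC codes when the top two base frequencies are
within 10 %, with information content 2 + sum(f log2 f) bits per column.

## Operons and regulation assignment

Operons are maximal runs of adjacent same-strand genes separated by fewer
than 50 bp whose neighbouring mean expression levels (wild-type RPKM)
differ by at most 1.0 log2 unit. The 2-fold co-expression bound is a
documented choice: "similar expression" has no published numeric
definition, and 1.0 log2 unit keeps genuinely co-transcribed neighbours
together under NB sampling noise while splitting units with independent
promoters. Singletons are discarded; minus-strand operons are listed in
transcription order.

Each consensus summit is classified into one of five exclusive contexts —
rRNA/tRNA locus; intergenic between a divergent pair with both starts in
the promoter window; intergenic upstream; intragenic but within the window
of a start codon; purely intragenic. The promoter window is −1000..+50 bp
of the start codon, measured along the gene's strand with negative
distances upstream (a summit just past a start codon, e.g. +36, is still
"directly upstream" under the +50 bound). When a summit is within the
window of two same-strand starts the nearer start wins; a divergent peak
can make both flanking genes direct.

DEGs are then partitioned: **direct** (a summit in the promoter window),
**direct via operon** (inside an operon whose first gene is direct), or
**indirect**. Direct records carry the best motif hit inside the peak,
preferring exact dyad hits, then lowest PWM p-value. Summaries include the
intergenic-enrichment exact binomial test (observed intergenic summit
fraction against the genome's intergenic base fraction) and a
Mann-Whitney U comparison (normal approximation) of peak heights between
intergenic and intragenic sites.

## Synthetic data

The generator emulates the statistical structure the analysis assumes, at
desk scale: a 200 kb replicon (default) at 70.5 % GC, 120 genes covering
90 % of the sequence, transcription units (singletons and 2–4-gene
operons, operon fraction 0.5) separated by >= 200 bp intergenic gaps with
<50 bp gaps inside operons. Twenty dyad sites are written into promoter
regions 60–190 bp upstream of unit-first genes (a flag plants a fraction
mid-gene to exercise context classification). IP/input tracks are Poisson
fragment-start processes (0.25 fragments/bp, 150 bp fragments) with extra
IP fragments at each site such that expected summit height is 8x
background. Counts are NB (dispersion 0.05) with means proportional to
gene length times a shared per-unit lognormal expression level, planted
|log2FC| of 2 on 80 % of promoter-site genes (25 % repressed), their
operon followers, and 10 site-free indirect genes; library sizes vary
±30 %. Indirect targets are drawn only from genes with *no* site anywhere
in their promoter window, so the truth table is consistent with the
method's own definition of direct. Everything is deterministic under one
seed.

What the generator does **not** model: read-level errors and mapping bias,
duplicate fragments, fragment-length variation, transcription-unit
read-through, strand-specific coverage asymmetry around summits, and
between-replicate biological variation beyond the NB dispersion. Passing
recovery tests therefore demonstrates correctness of the inference logic
under its assumed model, not robustness to the artefacts of real
sequencing libraries.

## Reference table replay

A 46-row transcription of the published direct-regulon table ships with
the package (one row per peak-gene pair, including the duplicate printing
of one locus under two functional categories). `replay_table1` recomputes
the bookkeeping from the rows — unique loci, genes with an upstream peak
(rows bearing a summit distance), singular vs operon-first roles, the
activated/repressed split, divergent pairs (peaks shared by opposite-strand
distance-bearing loci), and strict-dyad matches among the predicted site
sequences — rather than storing any total.

## Numerical choices and degenerate inputs

* Peak p-values are floored at 1e-300 to stay in (0, 1].
* Summit ties break to the leftmost base.
* PWM p-value discretisation: 0.001 bits (configurable).
* Dispersion floor 0.01; BH runs over tested genes only; untested genes
  keep p = q = 1 and mode "none".
* Gene packing raises a clear error when the requested gene content plus
  minimum gaps exceeds the genome; zero-expression genes yield all-zero
  counts; empty peak or DEG sets flow through every stage as empty outputs.

## Limitations

Single replicon; no multi-contig support beyond independent runs. The NB
Wald test is deliberately simple — no trended dispersion fits or
empirical-Bayes shrinkage of fold changes. The GC-aware caller stratifies
by window GC only; it does not regress counts on GC within bins. Operon
inference uses expression similarity at one condition (wild-type mean),
not temporal profiles.
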