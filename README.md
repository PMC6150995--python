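# zingdiv

Transcriptome-based divergence analysis for incipient plant species, built
around the case of two sympatric wild gingers (*Zingiber*) endemic to
Taiwan. Given a pseudo-reference transcriptome, a two-species SNP table and
per-transcript read counts — plus chloroplast-DNA population alignments —
the package answers two questions: **when** did the species diverge, and
**how** (adaptively, through positive selection on coding sequence, or
plastically, through expression divergence alone)?

It is aimed at researchers analysing two-species RNA-seq comparisons
without replicates or a reference genome, and at anyone wanting a tested,
simulation-backed implementation of the underlying estimators.

## What it computes

* **cpDNA layer** — nucleotide diversity π, between-population divergence
  d_XY, net divergence (corrected π_XY = d_XY − (π_X + π_Y)/2), and
  Hudson-style pairwise F_ST = (d_XY − π̄_within)/d_XY with a
  random-allelic permutation test.
* **Divergence times** — from the mutation clock μ = K/2T, so
  T = K/(2μ) generations: the *onset* of divergence uses the variant rate
  (all SNPs per site of polymorphic transcripts), the *completion* uses
  the fixation rate (fixed differences per site).
* **Variant annotation** — a transcript-space effect classifier (exon /
  5′UTR / 3′UTR / intergenic / splice site; synonymous / missense /
  stop-gained / stop-lost / start-lost / stop-retained).
* **Count-based Ka/Ks** — per transcript, missense count m and synonymous
  count s over exonic SNPs, with Ka/Ks = m/(2s) under the approximation
  that coding sequence carries twice as many nonsynonymous as synonymous
  sites; Ka/Ks > 1 flags positive selection, > 2 "highly adaptive".
* **Differential expression** — FPKM, log2 fold change with a pseudocount,
  and a two-sided Fisher exact test on raw counts (the study design has one
  pooled library per species, so no replicate-based dispersion exists);
  DEG ⇔ |log2FC| > 1 and P < 0.05.
* **Adaptive-vs-plastic classification** — every transcript lands in
  exactly one category by intersecting DEG status, CDS polymorphism and
  Ka/Ks class; plastic divergence = differential expression with no
  positive-selection signal, adaptive divergence = both.
* **Synthetic data** — a two-lineage simulator with known divergence time,
  per-gene dN/dS class, DEG effects and cpDNA structure, used as ground
  truth by the test suite and the `analysis/` drivers.

## Worked example

The numbered scripts under `analysis/` run the full pipeline on a
simulated study (2000 transcripts) and write their tables under
`results/`:

```sh
python analysis/01_simulate.py 1        # seed 1
python analysis/02_cpdna_popgen.py 1
python analysis/03_annotate_variants.py
python analysis/04_divergence_times.py
python analysis/05_expression_degs.py
python analysis/06_classify_divergence.py
```

Output of steps 2–4 (seed 1):

```
species ZA: pi = 3.7e-05 per site (90 sequences)
species ZB: pi = 0 per site (30 sequences)
interspecific F_ST (last vs first population): 0.995*

4086 SNPs in 1609 polymorphic transcripts (1165466 nt)
variant rate  0.00351 per site
fixation rate 0.0006 per site

onset      K=0.00351 mu=6.5e-09 -> T = 2.7e+05 generations
completion K=0.0006 mu=6.5e-09 -> T = 4.61e+04 generations
```

Reading this: within-species cpDNA diversity is near zero while the two
species are fully differentiated (F_ST ≈ 1, starred = permutation
P < 0.05) — the pattern of recently separated, internally homogeneous
lineages. On the transcriptome side, the total variant rate dates the
onset of divergence to ≈ 2.7 × 10⁵ generations ago, while fixed
differences alone date its completion to ≈ 4.6 × 10⁴ generations — the
gap is the lineage-sorting period during which shared polymorphism
persisted. The simulator's true completion time here is 4.75 × 10⁴
generations.

The same functions are exposed as a CLI (`zingdiv simulate | popgen |
annotate | divergence | kaks | expression | classify | run-all`) for use
on real inputs (FASTA + ORF TSV + two-sample VCF + count TSV).

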