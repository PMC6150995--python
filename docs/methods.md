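# Methods

## The divergence model

Two lineages separate from a panmictic ancestor T generations ago and
accumulate substitutions independently at a constant rate μ per site per
generation. A site that substituted in either lineage is a *fixed
difference*; the expected per-site fixed divergence is K = 2μT, giving the
mutation-clock estimator T = K/(2μ). Two readings of K produce two times:

* **onset** — the variant rate (fixed + polymorphic SNPs per site), an
  upper bound on separation because shared and post-split polymorphism
  inflate it;
* **completion** — the fixation rate (fixed differences only), dating the
  point at which lineage sorting finished.

Because fixation ≤ variant rate, completion ≤ onset always; both are
reported at the two *Arabidopsis*-calibrated mutation rates 6.5 × 10⁻⁹
and 7.1 × 10⁻⁹ substitutions/site/generation.

The per-site denominators follow the transcriptome convention of the
analysis: the summed length of *polymorphic* transcripts (those carrying
at least one SNP), not the full reference. This is the only denominator
consistent with the printed per-site rates the estimator is designed
around, but it is upward-biased as an estimate of 2μT, because
zero-SNP transcripts are excluded from the denominator while contributing
no SNPs. Conversely, purifying selection (ω < 1) suppresses coding
substitutions below the neutral clock. The parameter-recovery tests
therefore measure the realized rate over the full simulated length in a
non-coding configuration, where the rate is exactly Poisson(2μT·L); on
coding-rich data both biases apply, in opposite directions, and the same
caveats hold for real-data estimates.

## Count-based Ka/Ks

Per transcript, m = missense and s = synonymous exonic SNP counts, and
Ka/Ks = m/(2s), under the fixed approximation that coding sequence offers
twice as many nonsynonymous as synonymous sites. This site ratio is
deliberately hard-coded (not codon-model-derived): it is the defining
approximation of the screen, and the simulator draws its counts under the
same 2:1 assumption so that the estimator is unbiased under its own model
and any discrepancy isolates an implementation error. Classes are strict:
ratio < 1 constrained, = 1 neutral, > 1 positive, > 2 highly adaptive;
s = 0 leaves the ratio undefined and the transcript is reported in its own
class rather than as infinite. Both fixed and polymorphic exonic variants
count by default (`fixed_only` restricts to fixed differences).

Note that the *mean* of per-transcript ratios is a ratio of Poisson
variables, so E[m/(2s) | s > 0] exceeds ω by roughly ω/E[s] (Jensen). The
class-recovery test uses CDS ≥ 900 nt and a per-site divergence of 0.08
so that E[s] ≈ 40 and this bias stays near 2–3%, well inside the 10%
recovery band; at low divergence the bias grows and pooled
Σm/(2Σs) is the better summary.

## Variant annotation

Models are transcript-space: one contig, at most one CDS interval
(ATG…stop, in frame), UTRs on either side, no multi-exon coordinates.
Region assignment: splice site (±2 nt of a user-supplied junction, taking
precedence) > exon ([cds_start, cds_end)) > 5′/3′ UTR > intergenic (no
CDS). Codon effects use the standard nuclear code with a fixed precedence
for determinism: start_lost > stop_retained > stop_lost > stop_gained >
synonymous > missense. An "initiator codon variant" class exists for
parity with genome annotators but cannot arise from a SNP in this model
(any first-codon SNP destroys ATG and is start_lost); it is never emitted.
Effects are computed against the pseudo-reference allele; polarity does
not affect m/(2s).

## Differential expression without replicates

FPKM = count·10⁹/(length·library); log2FC = log2((FPKM_B + c)/(FPKM_A + c))
with pseudocount c = 0.25 so zero-expression transcripts stay computable;
DEG ⇔ |log2FC| > 1 and P < 0.05 (raw, no multiple-testing correction —
matching the screen's design). The test is a two-sided Fisher exact test
on [[count_A, lib_A − count_A], [count_B, lib_B − count_B]]: with a single
pooled library per species, replicate-based dispersion estimation is
undefined, and the Fisher test is the deterministic exact choice. Its
null is binomial sampling; it is exactly calibrated under Poisson counts
(verified ≤ 6% rejection at α = 0.05) but anti-conservative under
biological overdispersion — at the generator's default dispersion of 0.1
the called DEG fraction exceeds the true effect fraction. This is a
property of any replicate-free design, not of the implementation, and is
the reason the classification layer treats DEG status as a screen, not an
inference. The FPKM-significance check used by the highly-adaptive class
is the same Fisher p-value.

## cpDNA diversity and differentiation

π is the mean pairwise difference over all unordered pairs, per pair and
per site; gaps are handled by pairwise deletion (a column counts for a
pair only when both bases are A/C/G/T), so an indel-only population has
π = 0. Per-site π averages the per-pair diff/valid-columns ratios; for
gap-free alignments this equals π_per_pair divided by the column count.
d_XY is the mean over all between-population pairs; net π_XY =
d_XY − (π_X + π_Y)/2, floored at 0. F_ST is the Hudson-style
(d_XY − π̄_within)/d_XY, clamped to [0, 1], with F_ST := 0 when d_XY = 0
(the sensible value for identical monomorphic populations, where the
index is otherwise 0/0). Significance is by random allelic permutation of
individuals across the two population labels (default 1023 permutations;
p = (1 + #{F_ST* ≥ F_ST})/(1 + N), never 0, deterministic under seed).

## The synthetic-data generator

The generator emulates the study conditions end to end; the pipeline
never reads its ground-truth table.

* **Reference**: gamma-distributed transcript lengths (shape 4) around a
  mean of 671 nt with a 150 nt floor; a configurable fraction (default
  0.6) carries an in-frame ORF (ATG + non-stop codons + stop) with short
  UTRs.
* **Divergence**: per transcript, synonymous fixed differences
  s ~ Poisson(2Tμ·L_cds/3) and missense m ~ Poisson(ω·2Tμ·2L_cds/3) under
  the same 2:1 site assumption as the estimator, placed at compatible
  codon positions in interior codons (so the annotator recovers the
  intended labels exactly — asserted in the tests); non-coding fixed
  differences ~ Poisson(2Tμ·L_nc); polymorphic variants ~
  Poisson(θ_poly·L) at frequency 0.5 in exactly one species. Placement is
  infinite-sites with bounded retries; a transcript whose CDS cannot host
  its drawn placements is skipped with a warning.
* **Defaults**: μ = 6.5 × 10⁻⁹, T_div = 4.75 × 10⁴ (the completion-time
  regime) and θ_poly = 2.482 × 10⁻³ per site, chosen so the realized
  fixation rate is ≈ 6.2 × 10⁻⁴ and the total variant rate ≈ 3.1 × 10⁻³
  per site — the regime the estimators are designed for. ω classes default
  to 0.2 (90%), 1.0 (6%), 2.5 (4%), an L-shaped, constraint-dominated
  spectrum. θ_poly is a free knob of the generator, not an empirical
  estimate of within-species transcriptome polymorphism.
* **Counts**: shared log-normal baseline (σ = 1) per transcript; a
  deg_fraction subset (default 7.02%) gets the species-B mean multiplied
  by 2^(±deg_log2fc) (sign random, default effect 2.0); fragments are
  Gamma-Poisson (negative binomial, default dispersion 0.1) proportional
  to length and library size (default 2 × 10⁶ per species, a scale chosen
  to keep the default analysis run in seconds). Library sizes recorded as
  the realized column sums.
* **cpDNA**: one ancestral haplotype per species separated by
  cp_fixed_diffs (default 22) substitutions over 3000 bp; species-A
  sequences carry private singletons at cp_theta = 10⁻⁵ per site (π ≈
  2 × 10⁻⁵); species B carries only indel columns — the indel-only,
  substitution-free pattern. 9 + 3 populations of 10 samples.

What the generator does **not** emulate: read-level noise (counts are
drawn directly, no FASTQ/mapping), recombination and gene flow after the
split, demographic change, selection on expression itself, multi-allelic
transcripts beyond VCF decomposition, and sequencing/assembly artefacts.
Passing tests therefore demonstrate correctness of the estimators under
their own model assumptions, not robustness to real-data violations of
them. In particular, polymorphic exonic variants are placed uniformly, so
synthetic exonic composition is richer in missense than real
constraint-filtered polymorphism.

## Problem sizes and numerical choices

The default analysis run simulates 2000 transcripts (~1.3 Mb); the
parameter-recovery check uses 7500 transcripts (~5 Mb, ~15k fixed
differences); Ka/Ks recovery uses 900 CDS-only transcripts (≥ 200 per ω
class at CDS ≥ 900 nt); calibration uses 400 permutation-test replicates
and 2500 Fisher tests. All randomness flows through numpy Generators
seeded from a single integer; per-stage streams are derived as
(seed, stage) so stage outputs are independent of call order. Floats in
reports are serialized at 6 significant digits; Venn proportions are exact
rationals. Determinism (same seed → byte-identical outputs) is asserted
for every generator stage and for the report writer.

## Known limitations

* The clock assumes constant μ and complete lineage sorting for the
  completion estimate; post-split shared polymorphism biases the onset
  estimate upward, and the polymorphic-transcript denominator adds the
  conditioning bias discussed above.
* Count-based Ka/Ks with the fixed 2:1 site ratio ignores codon
  composition, transition/transversion bias and multiple hits; it is a
  screen, not a substitution-model estimate.
* The Fisher DE test is anti-conservative under overdispersion and the
  pipeline applies no multiple-testing correction, by design of the
  original screen.
* F_ST is the Hudson difference form; no AMOVA variance components,
  no distance-model correction for the cpDNA distances.
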