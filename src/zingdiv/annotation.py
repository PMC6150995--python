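"""Variant-effect annotation on transcript-space models.

Each SNP is assigned a *region* (exon, 5'/3' UTR, intergenic, splice site)
from the transcript's CDS interval and, for exonic SNPs, a *codon effect*
under the standard nuclear genetic code. Genome-wide variant and fixation
rates use the summed length of polymorphic transcripts (those carrying at
least one SNP) as the denominator — the per-site rate that feeds the
mutation-clock divergence-time estimate.

Classification precedence for codon effects is fixed so ties are
deterministic: start_lost > stop_retained > stop_lost > stop_gained >
synonymous > missense. An "initiator codon variant" class exists in the
enum for snpEff parity but cannot arise from a single-nucleotide change in
a transcript-space model, so it is never emitted.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

from Bio.Data.CodonTable import standard_dna_table

from .io_formats import SnpRecord, TranscriptModel

# codon -> amino acid, with '*' for stops
CODON_AA: dict[str, str] = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    CODON_AA[_stop] = "*"

STOP_CODONS = frozenset(standard_dna_table.stop_codons)


class Region(str, Enum):
    EXON = "exon"
    FIVE_PRIME_UTR = "five_prime_utr"
    THREE_PRIME_UTR = "three_prime_utr"
    INTERGENIC = "intergenic"
    SPLICE_SITE = "splice_site"


class CodonEffect(str, Enum):
    SYNONYMOUS = "synonymous"
    MISSENSE = "missense"
    STOP_GAINED = "stop_gained"
    STOP_LOST = "stop_lost"
    START_LOST = "start_lost"
    INITIATOR_CODON = "initiator_codon"  # unreachable for SNPs; kept for parity
    STOP_RETAINED = "stop_retained"
    NOT_APPLICABLE = "not_applicable"


@dataclass
class VariantEffect:
    snp: SnpRecord
    region: Region
    codon_effect: CodonEffect

    @property
    def transcript_id(self) -> str:
        return self.snp.transcript_id


@dataclass
class RateSummary:
    """Variant/fixation rates over the polymorphic-transcript denominator."""

    n_snps: int
    n_fixed: int
    denominator_nt: int
    n_polymorphic_transcripts: int = 0

    @property
    def variant_rate(self) -> float:
        return self.n_snps / self.denominator_nt if self.denominator_nt else 0.0

    @property
    def fixation_rate(self) -> float:
        return self.n_fixed / self.denominator_nt if self.denominator_nt else 0.0

    @property
    def degenerate(self) -> bool:
        return self.denominator_nt == 0

    @classmethod
    def from_counts(cls, n_snps: int, n_fixed: int, denominator_nt: int) -> "RateSummary":
        if n_fixed > n_snps:
            raise ValueError("n_fixed exceeds n_snps")
        return cls(n_snps=n_snps, n_fixed=n_fixed, denominator_nt=denominator_nt)


def classify_region(
    snp: SnpRecord,
    model: TranscriptModel,
    junctions: Sequence[int] | None = None,
) -> Region:
    """Region of a SNP; splice-site (±2 nt of a junction) takes precedence."""
    if snp.pos >= model.length:
        raise ValueError(f"{snp.transcript_id}:{snp.pos} beyond transcript end")
    if junctions:
        for j in junctions:
            if abs(snp.pos - j) <= 2:
                return Region.SPLICE_SITE
    if not model.has_cds:
        return Region.INTERGENIC
    if snp.pos < model.cds_start:
        return Region.FIVE_PRIME_UTR
    if snp.pos >= model.cds_end:
        return Region.THREE_PRIME_UTR
    return Region.EXON


def classify_codon_effect(snp: SnpRecord, model: TranscriptModel) -> CodonEffect:
    """Codon effect of an exonic SNP under the standard nuclear code."""
    offset = snp.pos - model.cds_start
    if offset < 0 or snp.pos >= model.cds_end:
        raise ValueError(f"{snp.transcript_id}:{snp.pos} not inside the CDS")
    codon_idx, within = divmod(offset, 3)
    start = model.cds_start + 3 * codon_idx
    ref_codon = model.sequence[start : start + 3]
    if ref_codon[within] != snp.ref:
        raise ValueError(
            f"{snp.transcript_id}:{snp.pos}: REF {snp.ref} inconsistent with"
            f" codon {ref_codon}"
        )
    alt_codon = ref_codon[:within] + snp.alt + ref_codon[within + 1 :]
    ref_is_stop = ref_codon in STOP_CODONS
    alt_is_stop = alt_codon in STOP_CODONS
    if codon_idx == 0 and ref_codon == "ATG" and alt_codon != "ATG":
        return CodonEffect.START_LOST
    if ref_is_stop and alt_is_stop:
        return CodonEffect.STOP_RETAINED
    if ref_is_stop and not alt_is_stop:
        return CodonEffect.STOP_LOST
    if alt_is_stop and not ref_is_stop:
        return CodonEffect.STOP_GAINED
    if CODON_AA[ref_codon] == CODON_AA[alt_codon]:
        return CodonEffect.SYNONYMOUS
    return CodonEffect.MISSENSE


def annotate_variants(
    snps: Iterable[SnpRecord],
    models: Sequence[TranscriptModel],
    junctions: Mapping[str, Sequence[int]] | None = None,
) -> list[VariantEffect]:
    """Classify every SNP; total — each receives exactly one region."""
    by_id = {m.transcript_id: m for m in models}
    effects: list[VariantEffect] = []
    for snp in snps:
        model = by_id[snp.transcript_id]
        junc = junctions.get(snp.transcript_id) if junctions else None
        region = classify_region(snp, model, junc)
        if region is Region.EXON:
            effect = classify_codon_effect(snp, model)
        else:
            effect = CodonEffect.NOT_APPLICABLE
        effects.append(VariantEffect(snp, region, effect))
    return effects


def summarize_rates(
    effects: Sequence[VariantEffect],
    models: Sequence[TranscriptModel],
) -> tuple[RateSummary, dict]:
    """Rates over polymorphic transcripts plus region/effect composition.

    The denominator is the summed length of transcripts carrying >=1 SNP
    (not the full reference), matching the per-site rates used for the
    divergence clock.
    """
    by_id = {m.transcript_id: m for m in models}
    poly_ids = {e.transcript_id for e in effects}
    denominator = sum(by_id[t].length for t in poly_ids)
    n_snps = len(effects)
    n_fixed = sum(e.snp.fixed_difference for e in effects)
    summary = RateSummary(n_snps, n_fixed, denominator, len(poly_ids))

    region_counts = {r.value: 0 for r in Region}
    effect_counts = {c.value: 0 for c in CodonEffect if c is not CodonEffect.NOT_APPLICABLE}
    for e in effects:
        region_counts[e.region.value] += 1
        if e.region is Region.EXON:
            effect_counts[e.codon_effect.value] += 1
    n_exonic = region_counts[Region.EXON.value]
    composition = {
        "region_counts": region_counts,
        "region_percent": {
            k: (100.0 * v / n_snps if n_snps else 0.0)
            for k, v in region_counts.items()
        },
        "exonic_effect_counts": effect_counts,
        "exonic_effect_percent": {
            k: (100.0 * v / n_exonic if n_exonic else 0.0)
            for k, v in effect_counts.items()
        },
    }
    return summary, composition
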