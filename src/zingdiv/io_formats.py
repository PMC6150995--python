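"""Readers and writers for every external format the pipeline touches.

All downstream modules consume the in-memory types defined here:

* :class:`TranscriptModel` — a pseudo-reference transcript with an optional
  single-interval ORF (transcript-space CDS), giving the UTR/exon geometry
  used by the variant annotator.
* :class:`SnpRecord` — one biallelic SNP with per-species alternate-allele
  frequencies derived from the two pooled-library genotypes.
* :class:`CountTable` — per-transcript read counts for the two species.
* :class:`PopAlignment` — aligned haplotypes with population labels, the
  input of the cpDNA diversity/differentiation layer.

Conventions: FASTA headers for population alignments encode the population
as ``>sampleID|population``; the ORF table is 1-based inclusive on disk
(GFF-like) and 0-based half-open in memory; VCF sites are decomposed into
one record per ALT allele.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger("zingdiv")

DNA = frozenset("ACGT")
GAP = "-"


class FormatError(ValueError):
    """Malformed or inconsistent input file."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class TranscriptModel:
    """A pseudo-reference contig, optionally carrying a CDS interval.

    ``cds_start``/``cds_end`` are 0-based half-open nucleotide offsets; both
    are ``None`` for transcripts without an ORF model (treated as intergenic
    by the annotator). A CDS span must be a positive multiple of 3.
    """

    transcript_id: str
    sequence: str
    cds_start: int | None = None
    cds_end: int | None = None

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def has_cds(self) -> bool:
        return self.cds_start is not None

    @property
    def cds_sequence(self) -> str | None:
        if not self.has_cds:
            return None
        return self.sequence[self.cds_start : self.cds_end]

    def validate(self, strict_orf: bool = False) -> None:
        if not self.sequence:
            raise FormatError(f"{self.transcript_id}: empty sequence")
        bad = set(self.sequence) - DNA
        if bad:
            raise FormatError(
                f"{self.transcript_id}: non-DNA characters {sorted(bad)!r}"
            )
        if self.has_cds:
            if not (0 <= self.cds_start < self.cds_end <= self.length):
                raise FormatError(
                    f"{self.transcript_id}: CDS [{self.cds_start},{self.cds_end})"
                    f" out of bounds for length {self.length}"
                )
            if (self.cds_end - self.cds_start) % 3 != 0:
                raise FormatError(
                    f"{self.transcript_id}: CDS span not a multiple of 3"
                )
            cds = self.cds_sequence
            starts_atg = cds[:3] == "ATG"
            ends_stop = cds[-3:] in ("TAA", "TAG", "TGA")
            if not (starts_atg and ends_stop):
                msg = (
                    f"{self.transcript_id}: ORF does not begin with ATG and end"
                    " with a stop codon"
                )
                if strict_orf:
                    raise FormatError(msg)
                log.warning(msg)


@dataclass
class SnpRecord:
    """One biallelic variant with per-species alternate-allele frequencies.

    ``freq_a``/``freq_b`` are the ALT dosages of the single pooled sample per
    species (0, 0.5 or 1 for a diploid call). A *fixed difference* is a site
    where one species is fixed for REF and the other for ALT.
    """

    transcript_id: str
    pos: int  # 0-based offset on the transcript
    ref: str
    alt: str
    freq_a: float
    freq_b: float
    qual: float = 60.0

    @property
    def fixed_difference(self) -> bool:
        return {self.freq_a, self.freq_b} == {0.0, 1.0}

    def validate(self, model: TranscriptModel | None = None) -> None:
        if self.ref == self.alt or self.ref not in DNA or self.alt not in DNA:
            raise FormatError(
                f"{self.transcript_id}:{self.pos}: bad alleles {self.ref}>{self.alt}"
            )
        if not (0.0 <= self.freq_a <= 1.0 and 0.0 <= self.freq_b <= 1.0):
            raise FormatError(f"{self.transcript_id}:{self.pos}: frequency outside [0,1]")
        if model is not None:
            if self.pos >= model.length:
                raise FormatError(
                    f"{self.transcript_id}:{self.pos}: beyond transcript end"
                )
            if model.sequence[self.pos] != self.ref:
                raise FormatError(
                    f"{self.transcript_id}:{self.pos}: REF {self.ref} does not"
                    f" match reference base {model.sequence[self.pos]}"
                )


@dataclass
class CountTable:
    """Per-transcript fragment counts for species A and B.

    Library sizes default to the column sums (every mapped read counted);
    they may be set larger but never smaller.
    """

    counts: dict[str, tuple[int, int]]
    library_size_a: int = 0
    library_size_b: int = 0

    def __post_init__(self) -> None:
        sum_a = sum(a for a, _ in self.counts.values())
        sum_b = sum(b for _, b in self.counts.values())
        if self.library_size_a == 0:
            self.library_size_a = sum_a
        if self.library_size_b == 0:
            self.library_size_b = sum_b
        if self.library_size_a < sum_a or self.library_size_b < sum_b:
            raise FormatError("library size smaller than column sum")
        if any(a < 0 or b < 0 for a, b in self.counts.values()):
            raise FormatError("negative read count")


@dataclass
class PopAlignment:
    """Aligned haplotypes with population labels.

    ``records`` holds ``(sample_id, population, sequence)`` triples; all
    sequences share one alignment length and use ``-`` for gaps.
    """

    records: list[tuple[str, str, str]]

    @property
    def n_columns(self) -> int:
        return len(self.records[0][2]) if self.records else 0

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for _, pop, _ in self.records:
            seen.setdefault(pop, None)
        return list(seen)

    def population(self, label: str) -> list[str]:
        return [seq for _, pop, seq in self.records if pop == label]

    def validate(self) -> None:
        if not self.records:
            raise FormatError("empty alignment")
        ncol = self.n_columns
        allowed = DNA | {GAP}
        for sid, _, seq in self.records:
            if len(seq) != ncol:
                raise FormatError(f"{sid}: ragged alignment")
            bad = set(seq) - allowed
            if bad:
                raise FormatError(f"{sid}: illegal characters {sorted(bad)!r}")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> list[TranscriptModel]:
    """Read reference transcripts; uppercase, U→T, ambiguity codes rejected."""
    path = Path(path)
    models: list[TranscriptModel] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        tid = rec.id
        if tid in seen:
            raise FormatError(f"{path}: duplicate transcript id {tid!r}")
        seen.add(tid)
        seq = str(rec.seq).upper().replace("U", "T")
        model = TranscriptModel(tid, seq)
        model.validate()
        models.append(model)
    if not models:
        raise FormatError(f"{path}: no FASTA records")
    return models


def write_fasta(models: Iterable[TranscriptModel], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(m.sequence), id=m.transcript_id, description="")
        for m in models
    ]
    SeqIO.write(records, str(path), "fasta")


def read_pop_alignment(path: str | Path) -> PopAlignment:
    """Read a population-labelled alignment (``>sampleID|population``)."""
    path = Path(path)
    records: list[tuple[str, str, str]] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if "|" not in rec.id:
            raise FormatError(f"{path}: header {rec.id!r} lacks '|population'")
        sid, pop = rec.id.split("|", 1)
        records.append((sid, pop, str(rec.seq).upper().replace("U", "T")))
    aln = PopAlignment(records)
    aln.validate()
    return aln


def write_pop_alignment(aln: PopAlignment, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=f"{sid}|{pop}", description="")
        for sid, pop, seq in aln.records
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# ORF table (1-based inclusive on disk, 0-based half-open in memory)
# ---------------------------------------------------------------------------

ORF_COLUMNS = ["transcript_id", "cds_start", "cds_end"]


def read_orf_table(path: str | Path, models: Sequence[TranscriptModel]) -> list[TranscriptModel]:
    """Attach CDS intervals to ``models``; transcripts absent from the table
    keep ``cds=None`` and will annotate as intergenic."""
    df = pd.read_csv(path, sep="\t", dtype={"transcript_id": str})
    missing = [c for c in ORF_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    by_id = {m.transcript_id: m for m in models}
    bad_rows: list[str] = []
    for row in df.itertuples(index=False):
        model = by_id.get(row.transcript_id)
        if model is None:
            bad_rows.append(f"{row.transcript_id}: unknown transcript")
            continue
        start0 = int(row.cds_start) - 1
        end0 = int(row.cds_end)  # inclusive -> half-open
        span = end0 - start0
        if not (0 <= start0 < end0 <= model.length) or span % 3 != 0:
            bad_rows.append(
                f"{row.transcript_id}: CDS {row.cds_start}-{row.cds_end}"
                f" (span {span}) invalid for length {model.length}"
            )
            continue
        model.cds_start, model.cds_end = start0, end0
        model.validate()
    if bad_rows:
        raise FormatError("invalid ORF rows:\n  " + "\n  ".join(bad_rows))
    return list(models)


def write_orf_table(models: Iterable[TranscriptModel], path: str | Path) -> None:
    rows = [
        {
            "transcript_id": m.transcript_id,
            "cds_start": m.cds_start + 1,
            "cds_end": m.cds_end,
        }
        for m in models
        if m.has_cds
    ]
    pd.DataFrame(rows, columns=ORF_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# VCF (two samples: species A, species B)
# ---------------------------------------------------------------------------

QUAL_THRESHOLD = 30.0  # sites with QUAL <= 30 are dropped


def read_vcf(path: str | Path, models: Sequence[TranscriptModel]) -> list[SnpRecord]:
    """Read a two-sample VCF into decomposed biallelic :class:`SnpRecord`.

    Sites with QUAL <= 30 are dropped (the count is logged), multi-allelic
    sites are decomposed into one record per ALT, indels are skipped, and a
    missing genotype in either species excludes the site. Per-species ALT
    frequency is the genotype's allele dosage.
    """
    from cyvcf2 import VCF

    by_id = {m.transcript_id: m for m in models}
    vcf = VCF(str(path))
    if len(vcf.samples) != 2:
        raise FormatError(
            f"{path}: expected 2 samples (species A, B), found {len(vcf.samples)}"
        )
    records: list[SnpRecord] = []
    n_qual = n_missing = n_indel = 0
    for v in vcf:
        if v.QUAL is not None and v.QUAL <= QUAL_THRESHOLD:
            n_qual += 1
            continue
        model = by_id.get(v.CHROM)
        if model is None:
            raise FormatError(f"{path}: unknown transcript {v.CHROM}")
        pos = v.POS - 1
        if model.sequence[pos : pos + len(v.REF)] != v.REF:
            raise FormatError(
                f"{path}: REF mismatch at {v.CHROM}:{v.POS}"
                f" ({v.REF} vs {model.sequence[pos:pos + len(v.REF)]})"
            )
        genos = v.genotypes  # [[a0, a1, phased], ...]
        alleles_a = [a for a in genos[0][:-1]]
        alleles_b = [a for a in genos[1][:-1]]
        if -1 in alleles_a or -1 in alleles_b:
            n_missing += 1
            continue
        for alt_index, alt in enumerate(v.ALT, start=1):
            if len(v.REF) != 1 or len(alt) != 1:
                n_indel += 1
                continue
            freq_a = sum(a == alt_index for a in alleles_a) / len(alleles_a)
            freq_b = sum(a == alt_index for a in alleles_b) / len(alleles_b)
            rec = SnpRecord(v.CHROM, pos, v.REF, alt, freq_a, freq_b,
                            qual=float(v.QUAL) if v.QUAL is not None else 60.0)
            rec.validate(model)
            records.append(rec)
    log.info(
        "read_vcf: %d SNP records kept; %d sites below QUAL %g, %d with"
        " missing genotype, %d indel alleles skipped",
        len(records), n_qual, QUAL_THRESHOLD, n_missing, n_indel,
    )
    return records


def _gt_from_freq(freq: float) -> str:
    if freq == 0.0:
        return "0/0"
    if freq == 1.0:
        return "1/1"
    return "0/1"


def write_vcf(
    records: Iterable[SnpRecord],
    models: Sequence[TranscriptModel],
    path: str | Path,
    sample_a: str = "SPECIES_A",
    sample_b: str = "SPECIES_B",
) -> None:
    """Write biallelic SnpRecords as an uncompressed two-sample VCF 4.2."""
    lines = ["##fileformat=VCFv4.2", "##source=zingdiv"]
    for m in models:
        lines.append(f"##contig=<ID={m.transcript_id},length={m.length}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        f"{sample_a}\t{sample_b}"
    )
    ordered = sorted(records, key=lambda r: (r.transcript_id, r.pos, r.alt))
    for r in ordered:
        lines.append(
            f"{r.transcript_id}\t{r.pos + 1}\t.\t{r.ref}\t{r.alt}\t{r.qual:g}"
            f"\t.\t.\tGT\t{_gt_from_freq(r.freq_a)}\t{_gt_from_freq(r.freq_b)}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# counts & generic reports
# ---------------------------------------------------------------------------


def read_counts(path: str | Path) -> CountTable:
    df = pd.read_csv(path, sep="\t", dtype={"transcript_id": str})
    needed = ["transcript_id", "count_a", "count_b"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    counts = {
        str(r.transcript_id): (int(r.count_a), int(r.count_b))
        for r in df.itertuples(index=False)
    }
    return CountTable(counts)


def write_counts(table: CountTable, path: str | Path) -> None:
    rows = [
        {"transcript_id": t, "count_a": a, "count_b": b}
        for t, (a, b) in sorted(table.counts.items())
    ]
    pd.DataFrame(rows, columns=["transcript_id", "count_a", "count_b"]).to_csv(
        path, sep="\t", index=False
    )


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Deterministic TSV: fixed column order, floats at 6 significant digits."""
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_json(obj: Mapping, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def write_results(records: Sequence[Mapping], path: str | Path, kind: str) -> None:
    """Write a record list as TSV plus a mirroring JSON summary (``.json``)."""
    df = pd.DataFrame(list(records))
    if df.empty:
        Path(path).write_text("\t".join(df.columns) + "\n" if len(df.columns) else "")
        write_json({"kind": kind, "n_records": 0}, Path(path).with_suffix(".json"))
        return
    write_table(df, path)
    summary = {"kind": kind, "n_records": len(df)}
    write_json(summary, Path(path).with_suffix(".json"))
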