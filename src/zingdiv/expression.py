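"""FPKM, fold change, and a replicate-free differential-expression test.

The study design has a single pooled library per species, so dispersion
cannot be estimated from replicates; differential expression is tested
with a two-sided Fisher exact test on the 2×2 table of a transcript's
fragments against the rest of each library. A transcript is a DEG when
|log2FC| > 1 and P < 0.05 (raw, no multiple-testing correction).

log2FC is computed on FPKM with a fixed pseudocount (default 0.25) so
transcripts expressed in only one species remain computable. DEGs are
split into the three expression clusters: unique to species A (FPKM 0 in
B), unique to species B, and shared-but-differential.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from scipy.stats import fisher_exact

from .io_formats import CountTable, TranscriptModel

DEFAULT_PSEUDOCOUNT = 0.25
DEFAULT_ALPHA = 0.05
DEFAULT_LFC = 1.0


@dataclass
class ExpressionRecord:
    transcript_id: str
    count_a: int
    count_b: int
    fpkm_a: float
    fpkm_b: float
    log2fc: float  # log2((fpkm_b + c) / (fpkm_a + c))
    p_value: float
    is_deg: bool

    @property
    def cluster(self) -> str:
        """unique_a / unique_b / shared (DEGs only; 'none' otherwise)."""
        if not self.is_deg:
            return "none"
        if self.fpkm_b == 0.0 and self.fpkm_a > 0.0:
            return "unique_a"
        if self.fpkm_a == 0.0 and self.fpkm_b > 0.0:
            return "unique_b"
        return "shared"


def fpkm(count: int, length_nt: int, library_size: int) -> float:
    """Fragments per kilobase of transcript per million mapped reads."""
    if length_nt <= 0 or library_size <= 0:
        raise ValueError("length and library size must be positive")
    return count * 1e9 / (length_nt * library_size)


def log2_fold_change(fpkm_a: float, fpkm_b: float, pseudocount: float = DEFAULT_PSEUDOCOUNT) -> float:
    """log2((fpkm_b + c)/(fpkm_a + c)); antisymmetric under a/b swap."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    return math.log2((fpkm_b + pseudocount) / (fpkm_a + pseudocount))


def de_test(count_a: int, count_b: int, lib_a: int, lib_b: int) -> float:
    """Two-sided Fisher exact p on [[count_a, rest_a], [count_b, rest_b]]."""
    if min(count_a, count_b) < 0 or count_a > lib_a or count_b > lib_b:
        raise ValueError("counts must lie in [0, library size]")
    table = [[count_a, lib_a - count_a], [count_b, lib_b - count_b]]
    return float(fisher_exact(table, alternative="two-sided").pvalue)


def call_degs(
    counts: CountTable,
    models: Sequence[TranscriptModel],
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    alpha: float = DEFAULT_ALPHA,
    lfc: float = DEFAULT_LFC,
) -> tuple[list[ExpressionRecord], dict]:
    by_id = {m.transcript_id: m for m in models}
    missing = [t for t in counts.counts if t not in by_id]
    if missing:
        raise ValueError(f"transcripts in counts but not in models: {missing[:5]}")
    records: list[ExpressionRecord] = []
    for tid in sorted(counts.counts):
        ca, cb = counts.counts[tid]
        length = by_id[tid].length
        fa = fpkm(ca, length, counts.library_size_a)
        fb = fpkm(cb, length, counts.library_size_b)
        l2 = log2_fold_change(fa, fb, pseudocount)
        p = de_test(ca, cb, counts.library_size_a, counts.library_size_b)
        records.append(
            ExpressionRecord(tid, ca, cb, fa, fb, l2, p,
                             is_deg=abs(l2) > lfc and p < alpha)
        )
    n = len(records)
    degs = [r for r in records if r.is_deg]
    clusters = {"unique_a": 0, "unique_b": 0, "shared": 0}
    for r in degs:
        clusters[r.cluster] += 1
    summary = {
        "n_transcripts": n,
        "n_deg": len(degs),
        "deg_fraction": len(degs) / n if n else 0.0,
        "clusters": clusters,
    }
    return records, summary
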