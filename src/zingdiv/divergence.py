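"""Divergence-time estimation and the count-based Ka/Ks selection screen.

The mutation clock: with per-site divergence K accumulating on both
lineages at rate μ per generation, μ = K/2T, so T = K/(2μ). Two readings
of K give two times — the *onset* of divergence uses all variants per site
(fixed + polymorphic), the *completion* uses fixed differences only, so
the completion estimate can never exceed the onset estimate.

The selection screen is a count-based Ka/Ks: per transcript, missense
variant count m and synonymous count s over exonic SNPs, with the ratio
m/(2s) under the approximation that coding sequence offers twice as many
nonsynonymous as synonymous sites. s = 0 leaves the ratio undefined
(reported as its own class rather than as infinity).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

from .annotation import CodonEffect, Region, VariantEffect

# nonsynonymous:synonymous site ratio of the count-based estimator
SITE_RATIO = 2.0


class Mode(str, Enum):
    ONSET = "onset"  # all variants per site
    COMPLETION = "completion"  # fixed differences per site


class SelectionClass(str, Enum):
    CONSTRAINED = "constrained"  # ratio < 1
    NEUTRAL = "neutral"  # ratio == 1
    POSITIVE = "positive"  # ratio > 1
    HIGHLY_ADAPTIVE = "highly_adaptive"  # ratio > 2 (subset of positive)
    UNDEFINED = "undefined"  # s == 0


@dataclass
class DivergenceEstimate:
    K: float
    mu: float
    mode: Mode

    @property
    def T(self) -> float:
        return self.K / (2.0 * self.mu)


@dataclass
class KaKsRecord:
    transcript_id: str
    m: int  # missense exonic variants
    s: int  # synonymous exonic variants

    @property
    def ratio(self) -> float | None:
        return None if self.s == 0 else self.m / (SITE_RATIO * self.s)

    @property
    def selection_class(self) -> SelectionClass:
        r = self.ratio
        if r is None:
            return SelectionClass.UNDEFINED
        if r < 1.0:
            return SelectionClass.CONSTRAINED
        if r == 1.0:
            return SelectionClass.NEUTRAL
        if r > 2.0:
            return SelectionClass.HIGHLY_ADAPTIVE
        return SelectionClass.POSITIVE

    @property
    def positively_selected(self) -> bool:
        r = self.ratio
        return r is not None and r > 1.0


def estimate_T(K: float, mu: float, mode: Mode | str = Mode.ONSET) -> DivergenceEstimate:
    """T = K/(2μ) generations since divergence (onset or completion)."""
    if mu <= 0:
        raise ValueError("mutation rate must be positive")
    if K < 0:
        raise ValueError("per-site rate K must be non-negative")
    return DivergenceEstimate(K=K, mu=mu, mode=Mode(mode))


def kaks_ratio(m: int, s: int) -> float | None:
    """Count-based Ka/Ks = m/(2s); None when s == 0."""
    if m < 0 or s < 0:
        raise ValueError("negative variant counts")
    return None if s == 0 else m / (SITE_RATIO * s)


def selection_screen(
    effects: Sequence[VariantEffect],
    fixed_only: bool = False,
) -> tuple[list[KaKsRecord], dict]:
    """Per-transcript m/s tallies over exonic SNPs plus a class spectrum.

    Transcripts with no exonic SNP emit no record (they are not polymorphic
    in CDS). ``fixed_only`` restricts the tallies to fixed differences, for
    sensitivity analysis; by default both fixed and polymorphic exonic
    variants count.
    """
    tallies: dict[str, list[int]] = {}
    for e in effects:
        if e.region is not Region.EXON:
            continue
        if fixed_only and not e.snp.fixed_difference:
            continue
        t = tallies.setdefault(e.transcript_id, [0, 0])
        if e.codon_effect is CodonEffect.MISSENSE:
            t[0] += 1
        elif e.codon_effect is CodonEffect.SYNONYMOUS:
            t[1] += 1
    records = [
        KaKsRecord(tid, m, s)
        for tid, (m, s) in sorted(tallies.items())
        if m + s > 0
    ]
    class_counts = {c.value: 0 for c in SelectionClass}
    ratios = []
    for r in records:
        class_counts[r.selection_class.value] += 1
        if r.ratio is not None:
            ratios.append(r.ratio)
    defined = len(ratios)
    n_conserved = class_counts[SelectionClass.CONSTRAINED.value]
    summary = {
        "n_records": len(records),
        "class_counts": class_counts,
        "fraction_conserved": n_conserved / defined if defined else 0.0,
        "mean_ratio": sum(ratios) / defined if defined else math.nan,
    }
    return records, summary
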