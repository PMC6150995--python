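"""Adaptive-vs-plastic divergence classification.

Every transcript is assigned exactly one category by intersecting its DEG
status, CDS polymorphism and count-based Ka/Ks class:

* *plastic* divergence — differential expression with no signature of
  positive selection on the coding sequence (no exonic SNPs, Ka/Ks < 1, or
  Ka/Ks == 1);
* *adaptive* divergence — differential expression together with Ka/Ks > 1,
  with a terminal *highly adaptive* class for Ka/Ks > 2 plus a significant
  FPKM difference (P < 0.05);
* transcripts under positive selection but not differentially expressed
  are exposed as their own class, as are DEGs whose Ka/Ks is undefined
  (s = 0, excluded from the positive/non-positive proportions).

Venn proportions use exact rational arithmetic with the DEG ∩ polymorphic
set as denominator, so counts at full study scale reproduce without float
drift.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from fractions import Fraction
from typing import Mapping, Sequence

from .annotation import RateSummary
from .divergence import DivergenceEstimate, KaKsRecord, SelectionClass
from .expression import ExpressionRecord

SCHEMA_VERSION = 1


class Category(str, Enum):
    NON_DEG = "non_deg"
    PLASTIC_NONPOLYMORPHIC = "plastic_nonpolymorphic"  # DEG, no exonic SNPs
    PLASTIC_CONSTRAINED = "plastic_constrained"  # DEG, ratio < 1
    PLASTIC_NEUTRAL = "plastic_neutral"  # DEG, ratio == 1
    ADAPTIVE = "adaptive"  # DEG, ratio > 1
    HIGHLY_ADAPTIVE = "highly_adaptive"  # DEG, ratio > 2, FPKM p < 0.05
    SELECTED_NON_DEG = "selected_non_deg"  # ratio > 1, not DEG
    UNDEFINED_KAKS = "undefined_kaks"  # DEG, s == 0


@dataclass
class DivergenceClass:
    transcript_id: str
    category: Category


@dataclass
class VennSummary:
    n_deg: int
    n_polymorphic_cds: int
    n_deg_and_polymorphic: int
    n_deg_positive: int  # ratio > 1
    n_deg_nonpositive: int  # defined ratio <= 1
    n_deg_undefined: int  # s == 0
    n_highly_adaptive: int
    proportions: dict[str, Fraction] = field(default_factory=dict)

    def __post_init__(self) -> None:
        assert (
            self.n_deg_positive + self.n_deg_nonpositive + self.n_deg_undefined
            == self.n_deg_and_polymorphic
        )
        denom = self.n_deg_and_polymorphic
        if denom and not self.proportions:
            self.proportions = {
                "deg_positive": Fraction(self.n_deg_positive, denom),
                "deg_nonpositive": Fraction(self.n_deg_nonpositive, denom),
                "deg_constrained": Fraction(self._n_constrained, denom),
                "deg_undefined": Fraction(self.n_deg_undefined, denom),
            }

    _n_constrained: int = 0  # defined ratio < 1, set by venn_summary


def classify_transcripts(
    expression_records: Sequence[ExpressionRecord],
    kaks_records: Sequence[KaKsRecord],
) -> list[DivergenceClass]:
    """Assign every expressed transcript to exactly one category."""
    kaks_by_id: dict[str, KaKsRecord] = {}
    for k in kaks_records:
        if k.transcript_id in kaks_by_id:
            raise ValueError(f"duplicate Ka/Ks record for {k.transcript_id}")
        kaks_by_id[k.transcript_id] = k
    seen: set[str] = set()
    out: list[DivergenceClass] = []
    for e in expression_records:
        if e.transcript_id in seen:
            raise ValueError(f"duplicate expression record for {e.transcript_id}")
        seen.add(e.transcript_id)
        k = kaks_by_id.get(e.transcript_id)
        if not e.is_deg:
            if k is not None and k.positively_selected:
                cat = Category.SELECTED_NON_DEG
            else:
                cat = Category.NON_DEG
        elif k is None:
            cat = Category.PLASTIC_NONPOLYMORPHIC
        else:
            r = k.ratio
            if r is None:
                cat = Category.UNDEFINED_KAKS
            elif r < 1.0:
                cat = Category.PLASTIC_CONSTRAINED
            elif r == 1.0:
                cat = Category.PLASTIC_NEUTRAL
            elif r > 2.0 and e.p_value < 0.05:
                cat = Category.HIGHLY_ADAPTIVE
            else:
                cat = Category.ADAPTIVE
        out.append(DivergenceClass(e.transcript_id, cat))
    return out


def venn_summary(
    classes: Sequence[DivergenceClass],
    kaks_records: Sequence[KaKsRecord],
) -> VennSummary:
    """Counts and exact proportions of the DEG × selection intersection."""
    deg_cats = {
        Category.PLASTIC_NONPOLYMORPHIC,
        Category.PLASTIC_CONSTRAINED,
        Category.PLASTIC_NEUTRAL,
        Category.ADAPTIVE,
        Category.HIGHLY_ADAPTIVE,
        Category.UNDEFINED_KAKS,
    }
    by_cat: dict[Category, int] = {c: 0 for c in Category}
    for c in classes:
        by_cat[c.category] += 1
    n_deg = sum(by_cat[c] for c in deg_cats)
    n_positive = by_cat[Category.ADAPTIVE] + by_cat[Category.HIGHLY_ADAPTIVE]
    n_constrained = by_cat[Category.PLASTIC_CONSTRAINED]
    n_nonpositive = n_constrained + by_cat[Category.PLASTIC_NEUTRAL]
    n_undefined = by_cat[Category.UNDEFINED_KAKS]
    summary = VennSummary(
        n_deg=n_deg,
        n_polymorphic_cds=len(kaks_records),
        n_deg_and_polymorphic=n_positive + n_nonpositive + n_undefined,
        n_deg_positive=n_positive,
        n_deg_nonpositive=n_nonpositive,
        n_deg_undefined=n_undefined,
        n_highly_adaptive=by_cat[Category.HIGHLY_ADAPTIVE],
        _n_constrained=n_constrained,
    )
    return summary


def build_report(
    classes: Sequence[DivergenceClass] | None = None,
    venn: VennSummary | None = None,
    estimates: Sequence[DivergenceEstimate] | None = None,
    rates: RateSummary | None = None,
) -> dict:
    """Consolidated machine-readable run report; missing stages are null."""
    report: dict = {"schema_version": SCHEMA_VERSION}
    if classes is not None:
        counts: dict[str, int] = {c.value: 0 for c in Category}
        for c in classes:
            counts[c.category.value] += 1
        report["classification"] = {
            "n_transcripts": len(classes),
            "category_counts": counts,
        }
    else:
        report["classification"] = None
    if venn is not None:
        report["venn"] = {
            "n_deg": venn.n_deg,
            "n_polymorphic_cds": venn.n_polymorphic_cds,
            "n_deg_and_polymorphic": venn.n_deg_and_polymorphic,
            "n_deg_positive": venn.n_deg_positive,
            "n_deg_nonpositive": venn.n_deg_nonpositive,
            "n_deg_undefined": venn.n_deg_undefined,
            "n_highly_adaptive": venn.n_highly_adaptive,
            "proportions_percent": {
                k: float(100 * v) for k, v in venn.proportions.items()
            },
        }
    else:
        report["venn"] = None
    if estimates is not None:
        report["divergence_times"] = [
            {"mode": e.mode.value, "K": e.K, "mu": e.mu,
             "T_generations": float(f"{e.T:.3g}")}
            for e in estimates
        ]
    else:
        report["divergence_times"] = None
    if rates is not None:
        report["rates"] = {
            "n_snps": rates.n_snps,
            "n_fixed": rates.n_fixed,
            "denominator_nt": rates.denominator_nt,
            "variant_rate": rates.variant_rate,
            "fixation_rate": rates.fixation_rate,
        }
    else:
        report["rates"] = None
    return report
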