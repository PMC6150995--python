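"""Adaptive-vs-plastic classification and the consolidated run report.

Intersects DEG status with the per-transcript Ka/Ks class: plastic
divergence is differential expression without positive selection on the
coding sequence (non-polymorphic, constrained, or neutral); adaptive
divergence is differential expression with Ka/Ks > 1, with a highly
adaptive terminal class at Ka/Ks > 2 and FPKM-test P < 0.05. Writes the
per-transcript categories, the Venn proportions over the DEG ∩ polymorphic
set, and the consolidated report joining every stage's summary.
"""

import json
import sys
from pathlib import Path

import pandas as pd

from zingdiv import (
    KaKsRecord,
    Mode,
    build_report,
    classify_transcripts,
    estimate_T,
    venn_summary,
    write_json,
    write_table,
)
from zingdiv.annotation import RateSummary
from zingdiv.expression import ExpressionRecord

ROOT = Path(__file__).resolve().parents[1]


def main(_seed: int = 0) -> None:
    res = ROOT / "results"
    edf = pd.read_csv(res / "expression.tsv", sep="\t")
    expr = [
        ExpressionRecord(str(r.transcript_id), int(r.count_a), int(r.count_b),
                         float(r.fpkm_a), float(r.fpkm_b), float(r.log2fc),
                         float(r.p_value), bool(r.is_deg))
        for r in edf.itertuples(index=False)
    ]
    kdf = pd.read_csv(res / "kaks.tsv", sep="\t")
    kaks = [KaKsRecord(str(r.transcript_id), int(r.missense), int(r.synonymous))
            for r in kdf.itertuples(index=False)]
    classes = classify_transcripts(expr, kaks)
    venn = venn_summary(classes, kaks)

    rates_json = json.loads((res / "rates.json").read_text())
    rates = RateSummary.from_counts(rates_json["n_snps"], rates_json["n_fixed"],
                                    rates_json["denominator_nt"])
    estimates = [
        estimate_T(k, mu, mode)
        for mu in (6.5e-9, 7.1e-9)
        for mode, k in ((Mode.ONSET, rates.variant_rate),
                        (Mode.COMPLETION, rates.fixation_rate))
    ]
    report = build_report(classes, venn, estimates, rates)
    write_table(
        pd.DataFrame([{"transcript_id": c.transcript_id,
                       "category": c.category.value} for c in classes]),
        res / "divergence_classes.tsv",
    )
    write_json(report, res / "report.json")
    print(f"{venn.n_deg} DEGs; {venn.n_deg_and_polymorphic} also polymorphic in CDS")
    if venn.n_deg_and_polymorphic:
        for name, frac in venn.proportions.items():
            print(f"  {name}: {float(100 * frac):.2f}%")
    print(f"highly adaptive transcripts: {venn.n_highly_adaptive}")
    print(f"report written to {res / 'report.json'}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 0)
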