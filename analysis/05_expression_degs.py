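"""Differential expression: FPKM, log2 fold change, and DEG calls.

A transcript is a DEG when |log2FC| > 1 and the two-sided Fisher exact
test on raw counts gives P < 0.05. DEGs split into three clusters:
expressed in one species only (either direction) or shared but
differential. Compares the called DEG fraction against the simulator's
truth table.
"""

import sys
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from zingdiv import call_degs, read_counts, read_fasta, write_json, write_table

ROOT = Path(__file__).resolve().parents[1]


def main(_seed: int = 0) -> None:
    sim = ROOT / "results" / "simulated"
    models = read_fasta(sim / "reference.fasta")
    counts = read_counts(sim / "counts.tsv")
    records, summary = call_degs(counts, models)
    write_table(
        pd.DataFrame([asdict(r) | {"cluster": r.cluster} for r in records]),
        ROOT / "results" / "expression.tsv",
    )
    write_json(summary, ROOT / "results" / "expression_summary.json")
    print(f"{summary['n_deg']} of {summary['n_transcripts']} transcripts are DEGs "
          f"({100 * summary['deg_fraction']:.2f}%)")
    print(f"clusters: {summary['clusters']}")

    truth = pd.read_csv(sim / "truth.tsv", sep="\t")
    true_deg = set(truth.loc[truth.is_deg, "transcript_id"])
    called = {r.transcript_id for r in records if r.is_deg}
    recall = len(true_deg & called) / len(true_deg) if true_deg else float("nan")
    print(f"truth check: {len(true_deg)} true DEGs, recall {recall:.2f}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 0)
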