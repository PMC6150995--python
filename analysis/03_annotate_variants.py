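"""Annotate every SNP by region and codon effect; summarize variant and
fixation rates over the polymorphic transcripts.

Reads the simulated reference, ORF table and VCF; writes effects.tsv and
a rates/composition summary JSON. The denominator of both per-site rates
is the summed length of transcripts carrying at least one SNP.
"""

import sys
from pathlib import Path

import pandas as pd

from zingdiv import (
    annotate_variants,
    read_fasta,
    read_orf_table,
    read_vcf,
    summarize_rates,
    write_json,
    write_table,
)

ROOT = Path(__file__).resolve().parents[1]


def effects_frame(effects) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"transcript_id": e.transcript_id, "pos": e.snp.pos,
             "ref": e.snp.ref, "alt": e.snp.alt,
             "freq_a": e.snp.freq_a, "freq_b": e.snp.freq_b,
             "fixed": e.snp.fixed_difference,
             "region": e.region.value, "codon_effect": e.codon_effect.value}
            for e in effects
        ]
    )


def main(_seed: int = 0) -> None:
    sim = ROOT / "results" / "simulated"
    models = read_orf_table(sim / "orfs.tsv", read_fasta(sim / "reference.fasta"))
    snps = read_vcf(sim / "variants.vcf", models)
    effects = annotate_variants(snps, models)
    rates, composition = summarize_rates(effects, models)
    write_table(effects_frame(effects), ROOT / "results" / "effects.tsv")
    write_json(
        {"n_snps": rates.n_snps, "n_fixed": rates.n_fixed,
         "denominator_nt": rates.denominator_nt,
         "variant_rate": rates.variant_rate,
         "fixation_rate": rates.fixation_rate, **composition},
        ROOT / "results" / "rates.json",
    )
    print(f"{rates.n_snps} SNPs in {rates.n_polymorphic_transcripts} polymorphic "
          f"transcripts ({rates.denominator_nt} nt)")
    print(f"variant rate  {rates.variant_rate:.3g} per site")
    print(f"fixation rate {rates.fixation_rate:.3g} per site")
    pct = composition["region_percent"]
    print("region composition: " + ", ".join(
        f"{k} {v:.1f}%" for k, v in pct.items() if v > 0))
    epct = composition["exonic_effect_percent"]
    print("exonic effects: " + ", ".join(
        f"{k} {v:.1f}%" for k, v in epct.items() if v > 0))


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 0)
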