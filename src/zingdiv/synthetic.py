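"""Synthetic two-species study generator with known ground truth.

Generates every input the pipeline consumes — pseudo-reference
transcripts with ORFs, a two-species SNP table with known divergence time
and per-gene dN/dS class, expression counts with known DEG effects, and
cpDNA population alignments — so each downstream stage can be checked
against truth without any external data.

Model. Two lineages split T_div generations ago and accumulate fixed
differences independently at mutation rate μ per site per generation, so
the expected per-site fixed divergence is K = 2μT. Within coding
sequence the fixed differences are drawn class-conditionally under the
2:1 nonsynonymous:synonymous site approximation: per transcript,
synonymous count s ~ Poisson(2Tμ·L_cds/3) and missense count
m ~ Poisson(ω·2Tμ·2·L_cds/3), where ω is the transcript's dN/dS class;
placements are codon-compatible (synonymous changes at degenerate
positions, missense changes that alter the amino acid without touching
start/stop codons), so the annotator's labels agree exactly with the
intended ones. Non-coding fixed differences are Poisson(2Tμ·L_noncoding).
Polymorphic variants (frequency 0.5 in exactly one species) arrive at
theta_poly per site. Placement is infinite-sites: one variant per site,
collisions retried.

Counts. Baseline expression is log-normal; DEG transcripts have the
species-B mean multiplied by 2^(±deg_log2fc); fragments are
negative-binomial (Gamma-Poisson) with the given dispersion, proportional
to transcript length and library size.

cpDNA. One ancestral haplotype per species separated by cp_fixed_diffs
substitutions; species-A sequences carry private singletons at cp_theta
per site (giving π ≈ 2·cp_theta per site); species B carries only indel
columns, emulating an indel-only, substitution-free species.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .annotation import CODON_AA, STOP_CODONS
from .io_formats import (
    CountTable,
    PopAlignment,
    SnpRecord,
    TranscriptModel,
    write_counts,
    write_fasta,
    write_json,
    write_orf_table,
    write_pop_alignment,
    write_table,
    write_vcf,
)

log = logging.getLogger("zingdiv")

BASES = "ACGT"
MIN_TRANSCRIPT_LENGTH = 150  # assembly floor for contig length

# per-codon substitution options, excluding anything involving a stop codon
_SYN_OPTIONS: dict[str, list[tuple[int, str]]] = {}
_MIS_OPTIONS: dict[str, list[tuple[int, str]]] = {}
for _codon, _aa in CODON_AA.items():
    syn: list[tuple[int, str]] = []
    mis: list[tuple[int, str]] = []
    if _aa != "*":
        for _i in range(3):
            for _b in BASES:
                if _b == _codon[_i]:
                    continue
                _alt = _codon[:_i] + _b + _codon[_i + 1 :]
                if _alt in STOP_CODONS:
                    continue
                (syn if CODON_AA[_alt] == _aa else mis).append((_i, _b))
    _SYN_OPTIONS[_codon] = syn
    _MIS_OPTIONS[_codon] = mis

_NON_STOP_CODONS = sorted(c for c, a in CODON_AA.items() if a != "*")
_STOP_LIST = sorted(STOP_CODONS)


@dataclass
class OmegaClass:
    name: str
    omega: float
    proportion: float


# default ω classes: heavy constraint with small neutral and adaptive tails,
# echoing an L-shaped Ka/Ks spectrum dominated by conserved genes
DEFAULT_OMEGA_CLASSES = (
    OmegaClass("constrained", 0.2, 0.90),
    OmegaClass("neutral", 1.0, 0.06),
    OmegaClass("adaptive", 2.5, 0.04),
)


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic two-species dataset.

    Defaults emulate the study's realized regime: completion-time
    divergence T_div = 4.75e4 generations at μ = 6.5e-9 (per-site fixed
    divergence 2μT ≈ 6.18e-4), with theta_poly chosen so the total
    variant rate is ≈ 3.10e-3 per site; a 7% DEG fraction; and a cpDNA
    layer with 22 fixed interspecific differences, near-zero diversity in
    species A and an indel-only species B (9 + 3 populations).
    """

    n_transcripts: int = 2000
    mean_length: int = 671
    cds_fraction: float = 0.6
    mu: float = 6.5e-9
    T_div: float = 4.75e4
    theta_poly: float = 2.482e-3
    omega_classes: tuple[OmegaClass, ...] = DEFAULT_OMEGA_CLASSES
    deg_fraction: float = 0.0702
    deg_log2fc: float = 2.0
    library_size: int = 2_000_000
    dispersion: float = 0.1
    cp_length: int = 3000
    cp_n_pops_a: int = 9
    cp_n_pops_b: int = 3
    cp_n_per_pop: int = 10
    cp_fixed_diffs: int = 22
    cp_theta: float = 1e-5
    cp_indels: int = 2
    seed: int = 0

    def validate(self) -> None:
        if self.n_transcripts < 0 or self.mean_length < MIN_TRANSCRIPT_LENGTH:
            raise ValueError("bad transcript counts/lengths")
        for frac in (self.cds_fraction, self.deg_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0,1]")
        for rate in (self.mu, self.T_div, self.theta_poly, self.cp_theta,
                     self.dispersion):
            if rate < 0:
                raise ValueError("rates must be non-negative")
        total = sum(c.proportion for c in self.omega_classes)
        if abs(total - 1.0) > 1e-9:
            raise ValueError("omega class proportions must sum to 1")


@dataclass
class TranscriptTruth:
    transcript_id: str
    omega_class: str
    omega: float
    n_syn_fixed: int = 0
    n_mis_fixed: int = 0
    n_noncoding_fixed: int = 0
    n_polymorphic: int = 0
    is_deg: bool = False
    log2fc: float = 0.0


@dataclass
class GroundTruth:
    """Written alongside the dataset; never read by the pipeline."""

    per_transcript: dict[str, TranscriptTruth] = field(default_factory=dict)
    T_div: float = 0.0
    mu: float = 0.0
    realized_variant_rate: float = 0.0
    realized_fixation_rate: float = 0.0

    def to_frame(self) -> pd.DataFrame:
        rows = [dataclasses.asdict(t) for t in self.per_transcript.values()]
        return pd.DataFrame(rows)


def _rng(config: SimulationConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stage])


# ---------------------------------------------------------------------------
# reference
# ---------------------------------------------------------------------------


def simulate_reference(config: SimulationConfig) -> list[TranscriptModel]:
    """Random transcripts; a ``cds_fraction`` subset gets an in-frame ORF."""
    config.validate()
    rng = _rng(config, 1)
    models: list[TranscriptModel] = []
    width = max(1, int(config.n_transcripts)).bit_length() // 4 + 5
    for i in range(config.n_transcripts):
        length = max(
            MIN_TRANSCRIPT_LENGTH,
            int(rng.gamma(shape=4.0, scale=config.mean_length / 4.0)),
        )
        tid = f"TR{i:0{width}d}"
        if rng.random() < config.cds_fraction:
            # geometry: 5'UTR + ATG + non-stop codons + stop + 3'UTR
            utr5 = int(rng.integers(0, max(1, length // 6)))
            max_codons = (length - utr5 - 6) // 3
            n_internal = max(3, int(max_codons * rng.uniform(0.5, 0.95)))
            codons = ["ATG"]
            codons += list(rng.choice(_NON_STOP_CODONS, size=n_internal))
            codons.append(str(rng.choice(_STOP_LIST)))
            cds = "".join(codons)
            utr3 = length - utr5 - len(cds)
            if utr3 < 0:
                utr3 = 0
                length = utr5 + len(cds)
            seq = (
                "".join(rng.choice(list(BASES), size=utr5))
                + cds
                + "".join(rng.choice(list(BASES), size=utr3))
            )
            model = TranscriptModel(tid, seq, utr5, utr5 + len(cds))
        else:
            seq = "".join(rng.choice(list(BASES), size=length))
            model = TranscriptModel(tid, seq)
        model.validate(strict_orf=True)
        models.append(model)
    return models


# ---------------------------------------------------------------------------
# divergence
# ---------------------------------------------------------------------------


def _place_coding(
    rng: np.random.Generator,
    model: TranscriptModel,
    n_needed: int,
    options: dict[str, list[tuple[int, str]]],
    used: set[int],
) -> list[tuple[int, str]] | None:
    """Pick ``n_needed`` distinct codon-compatible sites by rejection.

    Interior codons only (first and last excluded) so placements never
    touch start/stop codons. Returns None on placement failure.
    """
    n_codons = (model.cds_end - model.cds_start) // 3
    if n_codons <= 2:
        return None if n_needed else []
    placements: list[tuple[int, str]] = []
    attempts = 0
    max_attempts = 200 * max(1, n_needed)
    while len(placements) < n_needed:
        attempts += 1
        if attempts > max_attempts:
            return None
        ci = int(rng.integers(1, n_codons - 1))
        start = model.cds_start + 3 * ci
        codon = model.sequence[start : start + 3]
        opts = options[codon]
        if not opts:
            continue
        within, alt = opts[int(rng.integers(len(opts)))]
        pos = start + within
        if pos in used:
            continue
        used.add(pos)
        placements.append((pos, alt))
    return placements


def _assign_omega(rng: np.random.Generator, config: SimulationConfig) -> OmegaClass:
    p = np.array([c.proportion for c in config.omega_classes])
    return config.omega_classes[int(rng.choice(len(p), p=p / p.sum()))]


def simulate_divergence(
    models: Sequence[TranscriptModel],
    config: SimulationConfig,
) -> tuple[list[SnpRecord], GroundTruth]:
    """Draw fixed differences and polymorphisms with known ground truth."""
    config.validate()
    rng = _rng(config, 2)
    d = 2.0 * config.mu * config.T_div  # expected fixed diffs per site
    truth = GroundTruth(T_div=config.T_div, mu=config.mu)
    records: list[SnpRecord] = []
    for model in models:
        t = TranscriptTruth(model.transcript_id, "noncoding", float("nan"))
        if model.has_cds:
            oc = _assign_omega(rng, config)
            t.omega_class, t.omega = oc.name, oc.omega
        t.is_deg = bool(rng.random() < config.deg_fraction)
        if t.is_deg:
            t.log2fc = float(config.deg_log2fc * rng.choice([-1.0, 1.0]))
        used: set[int] = set()
        placements: list[tuple[int, str, bool]] = []  # pos, alt, fixed
        if model.has_cds:
            l_cds = model.cds_end - model.cds_start
            n_syn = int(rng.poisson(d * l_cds / 3.0))
            n_mis = int(rng.poisson(t.omega * d * 2.0 * l_cds / 3.0))
            syn = _place_coding(rng, model, n_syn, _SYN_OPTIONS, used)
            mis = _place_coding(rng, model, n_mis, _MIS_OPTIONS, used)
            if syn is None or mis is None:
                log.warning(
                    "simulate_divergence: placement failure on %s; skipped",
                    model.transcript_id,
                )
                continue
            t.n_syn_fixed, t.n_mis_fixed = len(syn), len(mis)
            placements += [(p, a, True) for p, a in syn + mis]
            noncoding_positions = list(range(0, model.cds_start)) + list(
                range(model.cds_end, model.length)
            )
        else:
            noncoding_positions = list(range(model.length))
        n_nc = int(rng.poisson(d * len(noncoding_positions)))
        n_nc = min(n_nc, len(noncoding_positions))
        if n_nc:
            for pos in rng.choice(noncoding_positions, size=n_nc, replace=False):
                pos = int(pos)
                if pos in used:
                    continue
                used.add(pos)
                ref = model.sequence[pos]
                alt = BASES[(BASES.index(ref) + int(rng.integers(1, 4))) % 4]
                placements.append((pos, alt, True))
                t.n_noncoding_fixed += 1
        n_poly = int(rng.poisson(config.theta_poly * model.length))
        for _ in range(n_poly):
            for _try in range(50):
                pos = int(rng.integers(model.length))
                if pos not in used:
                    break
            else:
                continue
            used.add(pos)
            ref = model.sequence[pos]
            alt = BASES[(BASES.index(ref) + int(rng.integers(1, 4))) % 4]
            placements.append((pos, alt, False))
            t.n_polymorphic += 1
        for pos, alt, fixed in placements:
            if fixed:
                in_b = bool(rng.random() < 0.5)
                freq_a, freq_b = (0.0, 1.0) if in_b else (1.0, 0.0)
            else:
                in_b = bool(rng.random() < 0.5)
                freq_a, freq_b = (0.0, 0.5) if in_b else (0.5, 0.0)
            rec = SnpRecord(
                model.transcript_id, pos, model.sequence[pos], alt,
                freq_a, freq_b,
                qual=float(np.round(31.0 + 60.0 * rng.random(), 1)),
            )
            rec.validate(model)
            records.append(rec)
        truth.per_transcript[model.transcript_id] = t
    poly_ids = {r.transcript_id for r in records}
    denom = sum(m.length for m in models if m.transcript_id in poly_ids)
    if denom:
        truth.realized_variant_rate = len(records) / denom
        truth.realized_fixation_rate = (
            sum(r.fixed_difference for r in records) / denom
        )
    return records, truth


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------


def simulate_expression(
    models: Sequence[TranscriptModel],
    truth: GroundTruth,
    config: SimulationConfig,
) -> CountTable:
    """Length- and depth-scaled negative-binomial counts with DEG effects."""
    config.validate()
    rng = _rng(config, 3)
    n = len(models)
    if n == 0:
        return CountTable({})
    base = rng.lognormal(mean=0.0, sigma=1.0, size=n)
    lengths = np.array([m.length for m in models], dtype=float)
    l2fc = np.array(
        [truth.per_transcript.get(m.transcript_id, TranscriptTruth("", "", 0)).log2fc
         for m in models]
    )
    w_a = base * lengths
    w_b = base * lengths * np.power(2.0, l2fc)
    mean_a = w_a / w_a.sum() * config.library_size
    mean_b = w_b / w_b.sum() * config.library_size
    counts_a = _nb_draw(rng, mean_a, config.dispersion)
    counts_b = _nb_draw(rng, mean_b, config.dispersion)
    counts = {
        m.transcript_id: (int(a), int(b))
        for m, a, b in zip(models, counts_a, counts_b)
    }
    return CountTable(counts)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Gamma-Poisson mixture: var = m + dispersion·m²; Poisson at 0."""
    if dispersion <= 0:
        return rng.poisson(mean)
    lam = rng.gamma(shape=1.0 / dispersion, scale=mean * dispersion)
    return rng.poisson(lam)


# ---------------------------------------------------------------------------
# cpDNA
# ---------------------------------------------------------------------------


def simulate_cpdna(config: SimulationConfig) -> PopAlignment:
    """Two species of populations around two divergent cpDNA haplotypes."""
    config.validate()
    rng = _rng(config, 4)
    anc = rng.choice(list(BASES), size=config.cp_length)
    hap_a = anc.copy()
    hap_b = anc.copy()
    diff_sites = rng.choice(config.cp_length, size=config.cp_fixed_diffs, replace=False)
    for pos in diff_sites:
        ref = hap_b[pos]
        hap_b[pos] = BASES[(BASES.index(ref) + int(rng.integers(1, 4))) % 4]
    records: list[tuple[str, str, str]] = []
    for p in range(config.cp_n_pops_a):
        pop = f"ZA_P{p + 1:02d}"
        for s in range(config.cp_n_per_pop):
            seq = hap_a.copy()
            for _ in range(int(rng.poisson(config.cp_theta * config.cp_length))):
                pos = int(rng.integers(config.cp_length))
                seq[pos] = BASES[(BASES.index(seq[pos]) + int(rng.integers(1, 4))) % 4]
            records.append((f"{pop}_S{s + 1:02d}", pop, "".join(seq)))
    indel_cols = (
        rng.choice(config.cp_length, size=config.cp_indels, replace=False)
        if config.cp_indels
        else np.array([], dtype=int)
    )
    for p in range(config.cp_n_pops_b):
        pop = f"ZB_P{p + 1:02d}"
        for s in range(config.cp_n_per_pop):
            seq = hap_b.copy().astype(object)
            if config.cp_indels and rng.random() < 0.5:
                for col in indel_cols:
                    seq[col] = "-"
            records.append((f"{pop}_S{s + 1:02d}", pop, "".join(seq)))
    aln = PopAlignment(records)
    aln.validate()
    return aln


# ---------------------------------------------------------------------------
# full study
# ---------------------------------------------------------------------------


def simulate_study(config: SimulationConfig, outdir: str | Path) -> dict:
    """Generate and write the complete synthetic study; returns the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    models = simulate_reference(config)
    snps, truth = simulate_divergence(models, config)
    counts = simulate_expression(models, truth, config)
    cpdna = simulate_cpdna(config)
    write_fasta(models, outdir / "reference.fasta")
    write_orf_table(models, outdir / "orfs.tsv")
    write_vcf(snps, models, outdir / "variants.vcf")
    write_counts(counts, outdir / "counts.tsv")
    write_pop_alignment(cpdna, outdir / "cpdna.fasta")
    write_table(truth.to_frame(), outdir / "truth.tsv")
    manifest = {
        "config": {
            **{k: v for k, v in dataclasses.asdict(config).items()
               if k != "omega_classes"},
            "omega_classes": [dataclasses.asdict(c) for c in config.omega_classes],
        },
        "n_transcripts": len(models),
        "n_snps": len(snps),
        "n_fixed": sum(r.fixed_difference for r in snps),
        "realized_variant_rate": truth.realized_variant_rate,
        "realized_fixation_rate": truth.realized_fixation_rate,
        "files": [
            "reference.fasta", "orfs.tsv", "variants.vcf",
            "counts.tsv", "cpdna.fasta", "truth.tsv",
        ],
    }
    write_json(manifest, outdir / "manifest.json")
    return manifest
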