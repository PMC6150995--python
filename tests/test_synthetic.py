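"""Simulator determinism, invariants, and ground-truth consistency."""

import numpy as np
import pytest

from zingdiv import (
    SimulationConfig,
    nucleotide_diversity,
    simulate_cpdna,
    simulate_divergence,
    simulate_expression,
    simulate_reference,
)


class TestReference:
    def test_zero_transcripts_gives_empty_list(self):
        cfg = SimulationConfig(n_transcripts=0, seed=1)
        assert simulate_reference(cfg) == []

    def test_same_seed_gives_identical_fasta_bytes(self, tmp_path):
        from zingdiv import write_fasta

        cfg = SimulationConfig(n_transcripts=30, seed=3)
        p1, p2 = tmp_path / "a.fasta", tmp_path / "b.fasta"
        write_fasta(simulate_reference(cfg), p1)
        write_fasta(simulate_reference(cfg), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_full_cds_fraction_satisfies_orf_invariants(self):
        cfg = SimulationConfig(n_transcripts=40, cds_fraction=1.0, seed=4)
        for m in simulate_reference(cfg):
            assert m.has_cds
            m.validate(strict_orf=True)  # ATG start, stop end, in-frame
            assert m.length >= 150

    def test_bad_config_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(cds_fraction=1.5).validate()
        with pytest.raises(ValueError):
            SimulationConfig(mu=-1e-9).validate()


class TestDivergence:
    def test_no_time_no_polymorphism_means_no_snps(self):
        cfg = SimulationConfig(n_transcripts=25, T_div=0.0, theta_poly=0.0, seed=5)
        models = simulate_reference(cfg)
        snps, truth = simulate_divergence(models, cfg)
        assert snps == []

    def test_snp_records_satisfy_invariants_against_reference(self, divergence_sim):
        models, snps, _, _ = divergence_sim
        by_id = {m.transcript_id: m for m in models}
        for r in snps:
            r.validate(by_id[r.transcript_id])  # ref matches, pos in bounds
        # infinite sites: one variant per site
        sites = [(r.transcript_id, r.pos) for r in snps]
        assert len(sites) == len(set(sites))

    def test_neutral_omega_ratio_concentrates_near_one(self):
        """Realized pooled m/(2s) for omega=1 within 3 CV of 1 across seeds."""
        from zingdiv import OmegaClass

        ratios = []
        for seed in range(20):
            cfg = SimulationConfig(
                n_transcripts=40, mean_length=1200, cds_fraction=1.0,
                mu=6.5e-9, T_div=3e6, theta_poly=0.0,
                omega_classes=(OmegaClass("neutral", 1.0, 1.0),), seed=100 + seed,
            )
            models = simulate_reference(cfg)
            _, truth = simulate_divergence(models, cfg)
            m = sum(t.n_mis_fixed for t in truth.per_transcript.values())
            s = sum(t.n_syn_fixed for t in truth.per_transcript.values())
            ratios.append(m / (2 * s))
        mean = np.mean(ratios)
        cv = np.std(ratios) / mean
        assert abs(mean - 1.0) <= 3 * cv

    def test_realized_per_site_rate_matches_2muT(self):
        """theta=0: realized fixed differences per site near K = 2 mu T."""
        # non-coding regime: every site is neutral, so the expected per-site
        # rate is exactly 2 mu T (coding sequence is omega-suppressed)
        cfg = SimulationConfig(
            n_transcripts=3000, mean_length=800, cds_fraction=0.0,
            mu=6.5e-9, T_div=238_462, theta_poly=0.0, seed=8,
        )
        models = simulate_reference(cfg)
        snps, truth = simulate_divergence(models, cfg)
        total_nt = sum(m.length for m in models)
        realized = len(snps) / total_nt  # over ALL transcripts
        expected = 2 * cfg.mu * cfg.T_div  # = 3.10e-3
        sd = np.sqrt(expected / total_nt)
        assert realized == pytest.approx(expected, abs=3 * sd)

    def test_polymorphic_variants_have_half_frequency_in_one_species(self):
        cfg = SimulationConfig(n_transcripts=30, T_div=0.0, theta_poly=5e-3, seed=9)
        models = simulate_reference(cfg)
        snps, _ = simulate_divergence(models, cfg)
        assert snps
        for r in snps:
            assert sorted((r.freq_a, r.freq_b)) == [0.0, 0.5]
            assert not r.fixed_difference


class TestExpression:
    def test_same_seed_identical_counts(self):
        cfg = SimulationConfig(n_transcripts=50, seed=10)
        models = simulate_reference(cfg)
        _, truth = simulate_divergence(models, cfg)
        c1 = simulate_expression(models, truth, cfg)
        c2 = simulate_expression(models, truth, cfg)
        assert c1.counts == c2.counts

    def test_null_config_counts_equal_in_expectation(self):
        cfg = SimulationConfig(
            n_transcripts=500, deg_fraction=0.0, dispersion=0.0,
            library_size=500_000, seed=11,
        )
        models = simulate_reference(cfg)
        _, truth = simulate_divergence(models, cfg)
        counts = simulate_expression(models, truth, cfg)
        a = np.array([v[0] for v in counts.counts.values()], dtype=float)
        b = np.array([v[1] for v in counts.counts.values()], dtype=float)
        # paired Poisson symmetry: mean difference is 0 within 4 SE
        diff = a - b
        se = np.sqrt((a + b).sum()) / len(diff)
        assert abs(diff.mean()) <= 4 * se


class TestCpdna:
    def test_zero_theta_means_identical_within_species(self):
        cfg = SimulationConfig(cp_theta=0.0, cp_indels=0, seed=12)
        aln = simulate_cpdna(cfg)
        for species in ("ZA", "ZB"):
            seqs = [s for _, p, s in aln.records if p.startswith(species)]
            assert len(set(seqs)) == 1
            assert nucleotide_diversity(seqs).pi_per_seq == 0.0

    def test_fixed_diffs_propagate_to_net_divergence(self):
        from zingdiv import net_divergence

        cfg = SimulationConfig(cp_theta=0.0, cp_indels=0, cp_fixed_diffs=22, seed=13)
        aln = simulate_cpdna(cfg)
        x = [s for _, p, s in aln.records if p.startswith("ZA")]
        y = [s for _, p, s in aln.records if p.startswith("ZB")]
        assert net_divergence(x, y).net_pixy_per_seq == 22.0

    def test_same_seed_identical_alignment(self):
        cfg = SimulationConfig(seed=14)
        assert simulate_cpdna(cfg).records == simulate_cpdna(cfg).records

    def test_indel_only_species_still_has_zero_pi(self):
        cfg = SimulationConfig(cp_indels=3, seed=15)
        aln = simulate_cpdna(cfg)
        seqs = [s for _, p, s in aln.records if p.startswith("ZB")]
        assert any("-" in s for s in seqs)
        assert nucleotide_diversity(seqs).pi_per_seq == 0.0


class TestRoundTrip:
    def test_written_study_rereads_to_identical_objects(self, small_study, small_config):
        from zingdiv import (
            read_counts,
            read_fasta,
            read_orf_table,
            read_pop_alignment,
            read_vcf,
            simulate_cpdna,
            simulate_divergence,
            simulate_expression,
            simulate_reference,
        )

        outdir, _ = small_study
        models_mem = simulate_reference(small_config)
        snps_mem, truth = simulate_divergence(models_mem, small_config)
        counts_mem = simulate_expression(models_mem, truth, small_config)
        cpdna_mem = simulate_cpdna(small_config)

        models = read_orf_table(outdir / "orfs.tsv", read_fasta(outdir / "reference.fasta"))
        assert [(m.transcript_id, m.sequence, m.cds_start, m.cds_end) for m in models] == [
            (m.transcript_id, m.sequence, m.cds_start, m.cds_end) for m in models_mem
        ]
        snps = read_vcf(outdir / "variants.vcf", models)
        as_tuple = lambda rs: sorted(
            (r.transcript_id, r.pos, r.ref, r.alt, r.freq_a, r.freq_b) for r in rs
        )
        assert as_tuple(snps) == as_tuple(snps_mem)
        assert read_counts(outdir / "counts.tsv").counts == counts_mem.counts
        assert read_pop_alignment(outdir / "cpdna.fasta").records == cpdna_mem.records
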