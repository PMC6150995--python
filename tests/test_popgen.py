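"""Diversity/differentiation statistics against exhaustive-pair oracles."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from zingdiv import (
    fst_permutation_test,
    net_divergence,
    nucleotide_diversity,
    pairwise_fst,
)
from .conftest import random_alignment

DNA = set("ACGT")


# -- independent exhaustive-pair oracle --------------------------------------

def pair_diff(s1: str, s2: str) -> tuple[int, int]:
    d = v = 0
    for a, b in zip(s1, s2):
        if a in DNA and b in DNA:
            v += 1
            if a != b:
                d += 1
    return d, v


def brute_pi(seqs) -> tuple[float, float]:
    pairs = list(itertools.combinations(seqs, 2))
    diffs = [pair_diff(a, b) for a, b in pairs]
    per_seq = sum(d for d, _ in diffs) / len(pairs)
    per_site = sum((d / v if v else 0.0) for d, v in diffs) / len(pairs)
    return per_seq, per_site


def brute_dxy(pop_x, pop_y) -> float:
    diffs = [pair_diff(a, b)[0] for a in pop_x for b in pop_y]
    return sum(diffs) / len(diffs)


def brute_fst(pop_x, pop_y) -> float:
    dxy = brute_dxy(pop_x, pop_y)
    if dxy == 0:
        return 0.0
    pi_x = brute_pi(pop_x)[0] if len(pop_x) > 1 else 0.0
    pi_y = brute_pi(pop_y)[0] if len(pop_y) > 1 else 0.0
    return min(1.0, max(0.0, (dxy - 0.5 * (pi_x + pi_y)) / dxy))


# -- nucleotide diversity -----------------------------------------------------

class TestDiversity:
    def test_identical_sequences_have_zero_pi(self):
        d = nucleotide_diversity(["ACGTACGT"] * 4)
        assert d.pi_per_seq == 0.0 and d.pi_per_site == 0.0

    def test_single_pair_single_mismatch(self):
        d = nucleotide_diversity(["A" * 100, "A" * 99 + "T"])
        assert d.pi_per_seq == 1.0
        assert d.pi_per_site == pytest.approx(0.01)

    def test_four_sequence_example_matches_enumeration(self):
        # 6 pairs with differences 0,1,2,1,2,1 -> mean 7/6
        seqs = ["AAAAAAAAAA", "AAAAAAAAAA", "AAAAAAAAAT", "AAAAAAAATT"]
        d = nucleotide_diversity(seqs)
        assert d.pi_per_seq == pytest.approx(7 / 6)
        assert d.pi_per_site == pytest.approx(7 / 60)

    def test_gapless_invariant_per_site_times_columns(self):
        rng = np.random.default_rng(0)
        seqs = random_alignment(rng, 6, 40, gap_prob=0.0)
        d = nucleotide_diversity(seqs)
        assert d.pi_per_site == pytest.approx(d.pi_per_seq / d.n_sites_used)

    def test_requires_two_sequences(self):
        with pytest.raises(ValueError):
            nucleotide_diversity(["ACGT"])


# -- net divergence and F_ST --------------------------------------------------

class TestNetDivergence:
    def test_fixed_haplotypes_net_equals_site_count(self):
        x = ["A" * 50] * 4
        y = [("A" * 28) + ("T" * 22)] * 3
        res = net_divergence(x, y)
        assert res.dxy_per_seq == 22.0
        assert res.net_pixy_per_seq == 22.0

    def test_identical_populations_have_zero_net(self):
        rng = np.random.default_rng(1)
        pop = random_alignment(rng, 4, 30, gap_prob=0.0)
        res = net_divergence(pop, pop)
        assert res.net_pixy_per_seq == 0.0

    def test_mixed_case_matches_enumeration(self):
        x = ["AAAA", "AAAT"]
        y = ["TTAA", "TTAT"]
        res = net_divergence(x, y)
        assert res.dxy_per_seq == pytest.approx(brute_dxy(x, y))
        assert res.net_pixy_per_seq == pytest.approx(
            brute_dxy(x, y) - 0.5 * (brute_pi(x)[0] + brute_pi(y)[0])
        )

    def test_empty_population_is_error(self):
        with pytest.raises(ValueError):
            net_divergence([], ["ACGT"])


class TestFst:
    def test_fixed_difference_populations_give_one(self):
        x = ["ACGTACGT"] * 12
        y = ["ACGTACGA"] * 8
        assert pairwise_fst(x, y) == 1.0

    def test_zero_divergence_defined_as_zero(self):
        assert pairwise_fst(["AAAA"] * 3, ["AAAA"] * 3) == 0.0

    def test_three_plus_three_toy_matches_hand_arithmetic(self):
        x = ["AAAAAAAAAA", "AAAAAAAAAT", "AAAAAAAAAA"]
        y = ["TTTTTAAAAA", "TTTTTAAAAT", "TTTTTAAAAA"]
        fst = pairwise_fst(x, y)
        assert 0.0 < fst < 1.0
        assert fst == pytest.approx(brute_fst(x, y))

    def test_symmetry_under_population_relabeling(self):
        rng = np.random.default_rng(2)
        x = random_alignment(rng, 5, 30)
        y = random_alignment(rng, 4, 30)
        assert pairwise_fst(x, y) == pytest.approx(pairwise_fst(y, x))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_invariant_under_column_permutation(self, seed):
        rng = np.random.default_rng(seed)
        x = random_alignment(rng, 4, 25)
        y = random_alignment(rng, 4, 25)
        perm = rng.permutation(25)
        xp = ["".join(s[i] for i in perm) for s in x]
        yp = ["".join(s[i] for i in perm) for s in y]
        assert pairwise_fst(x, y) == pytest.approx(pairwise_fst(xp, yp))

    def test_monotone_in_added_fixed_differences(self):
        rng = np.random.default_rng(3)
        x = random_alignment(rng, 5, 60, gap_prob=0.0)
        y = random_alignment(rng, 5, 60, gap_prob=0.0)
        last = -1.0
        for k in range(0, 40, 8):
            # append k columns fixed for A in x and T in y
            xk = [s + "A" * k for s in x]
            yk = [s + "T" * k for s in y]
            fst = pairwise_fst(xk, yk)
            assert fst >= last - 1e-12
            last = fst

    def test_oracle_agreement_on_random_alignments(self):
        rng = np.random.default_rng(4)
        for _ in range(60):
            nx, ny = rng.integers(2, 9, size=2)
            ncol = int(rng.integers(5, 51))
            x = random_alignment(rng, int(nx), ncol)
            y = random_alignment(rng, int(ny), ncol)
            res = net_divergence(x, y)
            assert res.dxy_per_seq == pytest.approx(brute_dxy(x, y))
            assert res.fst == pytest.approx(brute_fst(x, y))
            ps, psite = brute_pi(x)
            d = nucleotide_diversity(x)
            assert d.pi_per_seq == pytest.approx(ps)
            assert d.pi_per_site == pytest.approx(psite)


class TestPermutationTest:
    def test_fixed_difference_populations_are_significant(self):
        x = ["ACGTACGT" * 4] * 6
        y = [("ACGTACGA" * 4)] * 6
        res = fst_permutation_test(x, y, n_perm=999, seed=0)
        assert res.p_perm <= 0.05

    def test_identical_monomorphic_populations_give_p_one(self):
        res = fst_permutation_test(["AAAA"] * 5, ["AAAA"] * 5, n_perm=199, seed=0)
        assert res.p_perm == 1.0

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(5)
        x = random_alignment(rng, 5, 40)
        y = random_alignment(rng, 5, 40)
        p1 = fst_permutation_test(x, y, n_perm=199, seed=7).p_perm
        p2 = fst_permutation_test(x, y, n_perm=199, seed=7).p_perm
        assert p1 == p2

    def test_rejects_too_few_permutations(self):
        with pytest.raises(ValueError):
            fst_permutation_test(["AAAA"] * 3, ["AAAT"] * 3, n_perm=10)
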