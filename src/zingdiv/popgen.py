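"""Diversity and differentiation statistics on population alignments.

Implements the intraspecific/interspecific cpDNA layer: nucleotide
diversity π (per pair and per site), between-population divergence d_XY,
net divergence (corrected π_XY = d_XY − (π_X + π_Y)/2), a Hudson-style
pairwise F_ST = (d_XY − π̄_within) / d_XY, and a random-allelic permutation
test of F_ST.

Gap handling is pairwise deletion: a column counts for a pair only when
both bases are A/C/G/T. Per-site π averages the per-pair diff/valid-column
ratios; a population fixed for one haplotype therefore has π = 0 even when
it segregates indels. With d_XY = 0 the F_ST is defined as 0 rather than
left undefined, matching the boundary behaviour of within-species
comparisons between identical monomorphic populations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import PopAlignment

_DNA_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)

DEFAULT_N_PERMUTATIONS = 1023


@dataclass
class DiversityResult:
    pi_per_site: float
    pi_per_seq: float
    n_sequences: int
    n_sites_used: int


@dataclass
class PairwiseDivergenceResult:
    dxy_per_seq: float
    net_pixy_per_seq: float
    fst: float
    p_perm: float | None = None
    n_permutations: int = 0


def _encode(seqs: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    """Byte matrix plus validity mask (True where base is A/C/G/T)."""
    arr = np.frombuffer("".join(seqs).encode(), dtype=np.uint8).reshape(
        len(seqs), -1
    )
    valid = np.isin(arr, _DNA_BYTES)
    return arr, valid


def diff_matrix(seqs: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise difference counts and valid-column counts (n×n, symmetric)."""
    arr, valid = _encode(seqs)
    n = len(seqs)
    diffs = np.zeros((n, n), dtype=np.int64)
    valids = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        both = valid[i] & valid[i + 1 :]
        d = (arr[i] != arr[i + 1 :]) & both
        diffs[i, i + 1 :] = d.sum(axis=1)
        valids[i, i + 1 :] = both.sum(axis=1)
    diffs += diffs.T
    valids += valids.T
    return diffs, valids


def nucleotide_diversity(seqs: Sequence[str]) -> DiversityResult:
    """π over all unordered pairs, with pairwise gap deletion."""
    n = len(seqs)
    if n < 2:
        raise ValueError("nucleotide diversity needs >= 2 sequences")
    diffs, valids = diff_matrix(seqs)
    iu = np.triu_indices(n, 1)
    pair_diffs = diffs[iu]
    pair_valid = valids[iu]
    pi_seq = float(pair_diffs.mean())
    with np.errstate(invalid="ignore", divide="ignore"):
        ratios = np.where(pair_valid > 0, pair_diffs / pair_valid, 0.0)
    pi_site = float(ratios.mean())
    arr, valid = _encode(seqs)
    n_sites_used = int(valid.all(axis=0).sum())
    return DiversityResult(pi_site, pi_seq, n, n_sites_used)


def _within_pi(diffs: np.ndarray, idx: np.ndarray) -> float:
    """Mean pairwise differences within a group; 0 for singleton groups."""
    if len(idx) < 2:
        return 0.0
    sub = diffs[np.ix_(idx, idx)]
    iu = np.triu_indices(len(idx), 1)
    return float(sub[iu].mean())


def _fst_from_matrix(diffs: np.ndarray, idx_x: np.ndarray, idx_y: np.ndarray) -> tuple[float, float, float, float]:
    """(dxy, pi_x, pi_y, fst) from a precomputed difference matrix."""
    dxy = float(diffs[np.ix_(idx_x, idx_y)].mean())
    pi_x = _within_pi(diffs, idx_x)
    pi_y = _within_pi(diffs, idx_y)
    if dxy == 0.0:
        return dxy, pi_x, pi_y, 0.0
    fst = (dxy - 0.5 * (pi_x + pi_y)) / dxy
    return dxy, pi_x, pi_y, min(1.0, max(0.0, fst))


def net_divergence(pop_x: Sequence[str], pop_y: Sequence[str]) -> PairwiseDivergenceResult:
    """d_XY and net π_XY (floored at 0) between two populations."""
    if not pop_x or not pop_y:
        raise ValueError("empty population")
    diffs, _ = diff_matrix(list(pop_x) + list(pop_y))
    idx_x = np.arange(len(pop_x))
    idx_y = np.arange(len(pop_x), len(pop_x) + len(pop_y))
    dxy, pi_x, pi_y, fst = _fst_from_matrix(diffs, idx_x, idx_y)
    net = max(0.0, dxy - 0.5 * (pi_x + pi_y))
    return PairwiseDivergenceResult(dxy, net, fst)


def pairwise_fst(pop_x: Sequence[str], pop_y: Sequence[str]) -> float:
    """Hudson-style F_ST = (d_XY − mean within-π) / d_XY, clamped to [0,1]."""
    return net_divergence(pop_x, pop_y).fst


def fst_permutation_test(
    pop_x: Sequence[str],
    pop_y: Sequence[str],
    n_perm: int = DEFAULT_N_PERMUTATIONS,
    seed: int | None = None,
) -> PairwiseDivergenceResult:
    """Permute individuals across the two labels; p with +1 correction."""
    if n_perm < 99:
        raise ValueError("use at least 99 permutations")
    res = net_divergence(pop_x, pop_y)
    diffs, _ = diff_matrix(list(pop_x) + list(pop_y))
    n_x, n_total = len(pop_x), len(pop_x) + len(pop_y)
    rng = np.random.default_rng(seed)
    n_ge = 0
    for _ in range(n_perm):
        perm = rng.permutation(n_total)
        _, _, _, f = _fst_from_matrix(diffs, perm[:n_x], perm[n_x:])
        if f >= res.fst:
            n_ge += 1
    res.p_perm = (1 + n_ge) / (1 + n_perm)
    res.n_permutations = n_perm
    return res


def population_matrix(
    aln: PopAlignment,
    n_perm: int = DEFAULT_N_PERMUTATIONS,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-population diversity table and the two-triangle matrix.

    Returns ``(diversity, matrix)``: the matrix carries net π_XY above the
    diagonal and F_ST below, with ``*`` marking permutation P < 0.05 —
    mirroring the layout used for between-population cpDNA comparisons.
    """
    pops = aln.populations
    div_rows = []
    for pop in pops:
        seqs = aln.population(pop)
        if len(seqs) >= 2:
            d = nucleotide_diversity(seqs)
            div_rows.append(
                {"population": pop, "n": d.n_sequences,
                 "pi_per_site": d.pi_per_site, "pi_per_seq": d.pi_per_seq}
            )
        else:
            div_rows.append(
                {"population": pop, "n": len(seqs),
                 "pi_per_site": 0.0, "pi_per_seq": 0.0}
            )
    matrix = pd.DataFrame("–", index=pops, columns=pops, dtype=object)
    for i, px in enumerate(pops):
        for j, py in enumerate(pops):
            if i >= j:
                continue
            res = fst_permutation_test(
                aln.population(px), aln.population(py), n_perm=n_perm,
                seed=None if seed is None else seed + 131 * i + j,
            )
            star = "*" if res.p_perm < 0.05 else ""
            matrix.iloc[i, j] = f"{res.net_pixy_per_seq:.3f}{star}"
            matrix.iloc[j, i] = f"{res.fst:.3f}{star}"
    return pd.DataFrame(div_rows), matrix
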