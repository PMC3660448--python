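"""Pairwise LD from unphased genotypes and greedy tag-SNP selection.

Two-locus haplotype frequencies are estimated by the standard EM over the
double-heterozygote phase ambiguity (the computation behind Haploview-style
LD displays); D, D' and r-squared follow from the four haplotype
frequencies.  Tags are chosen by a greedy set cover at a strict r-squared
threshold: every variant must exceed the threshold with its covering tag
(a tag covers itself with r-squared 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from extremevar.variant_io import GenotypeMatrix

EM_TOL = 1e-8
EM_MAX_ITER = 1000

# Unambiguous haplotype contributions of each two-locus genotype cell
# (dosage_a, dosage_b) -> counts of (AB, Ab, aB, ab); the (1,1) double
# heterozygote is ambiguous (AB/ab vs Ab/aB) and is resolved by EM.
_CELL_HAPLOTYPES = {
    (0, 0): (0, 0, 0, 2),
    (0, 1): (0, 0, 1, 1),
    (0, 2): (0, 0, 2, 0),
    (1, 0): (0, 1, 0, 1),
    (1, 2): (1, 0, 1, 0),
    (2, 0): (0, 2, 0, 0),
    (2, 1): (1, 1, 0, 0),
    (2, 2): (2, 0, 0, 0),
}


@dataclass(frozen=True)
class LDPair:
    """Two-locus haplotype frequencies and LD summaries.

    ``hap_freqs`` is (pAB, pAb, paB, pab) where A and B are the coded
    alleles at the two loci.  ``defined`` is False when either locus is
    monomorphic; D' and r-squared are then NaN.
    """

    hap_freqs: tuple
    d: float
    d_prime: float
    r2: float
    defined: bool


@dataclass
class TagSet:
    """Greedy tag selection result: chosen tags and, for every variant,
    the tag that covers it."""

    tags: list
    coverage_map: dict
    r2_threshold: float


def em_haplotype_freqs(dosage_a, dosage_b, missing_a=None, missing_b=None
                       ) -> tuple[np.ndarray, bool]:
    """ML two-locus haplotype frequencies (pAB, pAb, paB, pab) via EM.

    Dosages are coded-allele counts (0,1,2); subjects with a missing call
    at either locus are dropped (pairwise complete-case).  Convergence when
    the largest frequency change falls below 1e-8, capped at 1000
    iterations.  Returns the frequency vector and a flag that is False when
    either locus is monomorphic (frequencies then degenerate to products of
    allele frequencies).
    """
    a = np.asarray(dosage_a, dtype=np.int64)
    b = np.asarray(dosage_b, dtype=np.int64)
    keep = np.ones(a.shape, dtype=bool)
    if missing_a is not None:
        keep &= ~np.asarray(missing_a, dtype=bool)
    if missing_b is not None:
        keep &= ~np.asarray(missing_b, dtype=bool)
    a, b = a[keep], b[keep]
    n = a.size
    if n < 2:
        raise ValueError("need >=2 subjects non-missing at both loci")
    table = np.zeros((3, 3), dtype=np.int64)
    np.add.at(table, (a, b), 1)
    pA = a.sum() / (2 * n)
    pB = b.sum() / (2 * n)
    if pA in (0.0, 1.0) or pB in (0.0, 1.0):
        freqs = np.array([pA * pB, pA * (1 - pB), (1 - pA) * pB, (1 - pA) * (1 - pB)])
        return freqs, False

    n_dh = int(table[1, 1])
    base = np.zeros(4)
    for cell, haps in _CELL_HAPLOTYPES.items():
        base += table[cell] * np.array(haps, dtype=float)

    freqs = np.full(4, 0.25)
    for _ in range(EM_MAX_ITER):
        denom = freqs[0] * freqs[3] + freqs[1] * freqs[2]
        frac_cis = freqs[0] * freqs[3] / denom if (n_dh and denom > 0) else 0.5
        counts = base.copy()
        counts[[0, 3]] += n_dh * frac_cis
        counts[[1, 2]] += n_dh * (1 - frac_cis)
        new = counts / (2 * n)
        done = np.abs(new - freqs).max() < EM_TOL
        freqs = new
        if done:
            break
    return freqs, True


def ld_stats(hap_freqs, defined: bool = True) -> LDPair:
    """D, D' and r-squared from haplotype frequencies (pAB, pAb, paB, pab).

    D = pAB - pA pB; D' = |D| / Dmax with Dmax = min(pA pb, pa pB) for
    D > 0 and min(pA pB, pa pb) otherwise; r2 = D^2 / (pA pa pB pb).
    """
    freqs = np.asarray(hap_freqs, dtype=float)
    if freqs.min() < -1e-9 or abs(freqs.sum() - 1.0) > 1e-6:
        raise ValueError("haplotype frequencies must be non-negative and sum to 1")
    p_AB, p_Ab, p_aB, p_ab = freqs
    pA = p_AB + p_Ab
    pB = p_AB + p_aB
    pa, pb = 1 - pA, 1 - pB
    d = p_AB - pA * pB
    if not defined or min(pA, pa, pB, pb) <= 0:
        return LDPair(tuple(freqs), d, math.nan, math.nan, False)
    d_max = min(pA * pb, pa * pB) if d > 0 else min(pA * pB, pa * pb)
    d_prime = abs(d) / d_max if d_max > 0 else 0.0
    r2 = d * d / (pA * pa * pB * pb)
    return LDPair(tuple(freqs), d, d_prime, r2, True)


def pair_ld(dosage_a, dosage_b, missing_a=None, missing_b=None) -> LDPair:
    freqs, defined = em_haplotype_freqs(dosage_a, dosage_b, missing_a, missing_b)
    return ld_stats(freqs, defined)


def ld_matrix(gm: GenotypeMatrix) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All-pairs r-squared and D' matrices (unit diagonal; NaN where a
    locus is monomorphic)."""
    m = gm.n_variants
    r2 = np.eye(m)
    dp = np.eye(m)
    for i in range(m):
        for j in range(i + 1, m):
            pair = pair_ld(gm.dosage[:, i], gm.dosage[:, j],
                           gm.missing[:, i], gm.missing[:, j])
            r2[i, j] = r2[j, i] = pair.r2
            dp[i, j] = dp[j, i] = pair.d_prime
    ids = list(gm.variant_ids)
    return (pd.DataFrame(r2, index=ids, columns=ids),
            pd.DataFrame(dp, index=ids, columns=ids))


def greedy_tags(r2: pd.DataFrame, r2_threshold: float = 0.7,
                maf=None, pos=None) -> TagSet:
    """Greedy set cover: repeatedly pick the variant covering the most
    still-uncovered variants at r2 > threshold (strict).

    Ties break toward higher MAF, then smaller position, then first in
    input order.  Coverage is total: every variant is assigned a covering
    tag (itself if nothing else covers it).
    """
    ids = list(r2.index)
    m = len(ids)
    mat = r2.to_numpy(dtype=float)
    if mat.shape != (m, m):
        raise ValueError("r2 matrix must be square")
    covers = np.nan_to_num(mat) > r2_threshold
    np.fill_diagonal(covers, True)
    maf = np.zeros(m) if maf is None else np.asarray(maf, dtype=float)
    pos = np.arange(m) if pos is None else np.asarray(pos, dtype=float)
    uncovered = np.ones(m, dtype=bool)
    tags: list = []
    coverage: dict = {}
    while uncovered.any():
        gains = (covers & uncovered[None, :]).sum(axis=1)
        cand = np.flatnonzero(gains == gains.max())
        cand = cand[np.lexsort((cand, pos[cand], -maf[cand]))]
        pick = int(cand[0])
        tags.append(ids[pick])
        for j in np.flatnonzero(covers[pick] & uncovered):
            coverage[ids[j]] = ids[pick]
        uncovered &= ~covers[pick]
    return TagSet(tags=tags, coverage_map=coverage, r2_threshold=r2_threshold)
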