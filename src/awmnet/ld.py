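"""Two-locus linkage disequilibrium (D, D', r^2) from unphased genotypes.

Haplotype frequencies are estimated by EM over the double-heterozygote
phase ambiguity (all other two-locus genotype classes contribute
unambiguous haplotype counts), initialized at linkage equilibrium.
D' = |D| / D_max is 1 under complete LD — the situation reported for the
PPARG/NR2C2 SNP pair that motivates this module.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .qc import GenotypeMatrix, MISSING

__all__ = ["LdResult", "em_haplotype_freqs", "d_prime", "ld_pair", "ld_window"]


@dataclass
class LdResult:
    snp_a: str
    snp_b: str
    freqs: np.ndarray  # (p_AB, p_Ab, p_aB, p_ab); "A"/"B" = counted alleles
    D: float
    D_prime: float
    r2: float
    n: int  # individuals with both calls


def em_haplotype_freqs(geno_a: np.ndarray, geno_b: np.ndarray,
                       tol: float = 1e-8, max_iter: int = 1000) -> tuple[np.ndarray, int]:
    """EM haplotype frequency estimate for two biallelic loci.

    ``geno_a``/``geno_b`` are dosage vectors (0/1/2, -1 or NaN missing) over
    the same individuals; pairs with a missing call are dropped.  Returns
    (freqs, n_used) with freqs = (p_AB, p_Ab, p_aB, p_ab).
    """
    a = np.asarray(geno_a, dtype=float)
    b = np.asarray(geno_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("genotype vectors differ in length")
    ok = ~(np.isnan(a) | np.isnan(b) | (a == MISSING) | (b == MISSING))
    a, b = a[ok].astype(int), b[ok].astype(int)
    n = len(a)
    if n == 0:
        raise ValueError("no complete genotype pairs")
    pa, pb = a.mean() / 2.0, b.mean() / 2.0
    if pa in (0.0, 1.0) or pb in (0.0, 1.0):
        raise ValueError("monomorphic locus: LD undefined")

    # unambiguous haplotype counts; z = number of double heterozygotes
    counts = np.zeros((3, 3))
    for i in range(3):
        for j in range(3):
            counts[i, j] = np.sum((a == i) & (b == j))
    nAB = 2 * counts[2, 2] + counts[2, 1] + counts[1, 2]
    nAb = 2 * counts[2, 0] + counts[2, 1] + counts[1, 0]
    naB = 2 * counts[0, 2] + counts[0, 1] + counts[1, 2]
    nab = 2 * counts[0, 0] + counts[0, 1] + counts[1, 0]
    z = counts[1, 1]

    # start at linkage equilibrium
    f = np.array([pa * pb, pa * (1 - pb), (1 - pa) * pb, (1 - pa) * (1 - pb)])
    total = 2.0 * n
    for _ in range(max_iter):
        cis = f[0] * f[3]
        trans = f[1] * f[2]
        pc = cis / (cis + trans) if (cis + trans) > 0 else 0.5
        new = np.array([
            nAB + z * pc,
            nAb + z * (1 - pc),
            naB + z * (1 - pc),
            nab + z * pc,
        ]) / total
        if np.max(np.abs(new - f)) < tol:
            f = new
            break
        f = new
    return f, n


def d_prime(freqs: np.ndarray) -> tuple[float, float, float]:
    """(D, D', r^2) from haplotype frequencies (p_AB, p_Ab, p_aB, p_ab)."""
    f = np.asarray(freqs, dtype=float)
    if f.shape != (4,) or np.any(f < -1e-12) or abs(f.sum() - 1.0) > 1e-6:
        raise ValueError("haplotype frequencies must be 4 non-negative values summing to 1")
    f = np.clip(f, 0.0, 1.0)
    pA = f[0] + f[1]
    pB = f[0] + f[2]
    qA, qB = 1.0 - pA, 1.0 - pB
    if min(pA, qA, pB, qB) <= 0:
        raise ValueError("fixed allele: D' and r^2 undefined")
    D = f[0] - pA * pB
    if D > 0:
        dmax = min(pA * qB, qA * pB)
    else:
        dmax = min(pA * pB, qA * qB)
    dp = abs(D) / dmax if dmax > 0 else 0.0
    r2 = D * D / (pA * qA * pB * qB)
    return float(D), float(dp), float(r2)


def ld_pair(geno: GenotypeMatrix, snp_a: str, snp_b: str) -> LdResult:
    pos = {s: i for i, s in enumerate(geno.snp_ids)}
    for s in (snp_a, snp_b):
        if s not in pos:
            raise KeyError(f"SNP {s!r} not in genotype matrix")
    f, n = em_haplotype_freqs(geno.dosages[pos[snp_a]], geno.dosages[pos[snp_b]])
    D, dp, r2 = d_prime(f)
    return LdResult(snp_a, snp_b, f, D, dp, r2, n)


def ld_window(geno: GenotypeMatrix, snp_map: pd.DataFrame, center_snp: str,
              window_kb: float = 2000.0) -> pd.DataFrame:
    """Pairwise D'/r^2 among all SNPs within +/- window_kb of a focal SNP.

    Returns a Haploview-style triangle listing (one row per pair).
    Monomorphic SNPs in the window are skipped.
    """
    m = snp_map.drop_duplicates("snp_id").set_index("snp_id")
    if center_snp not in m.index:
        raise KeyError(f"SNP {center_snp!r} not in map")
    chrom, bp = m.loc[center_snp, "chrom"], m.loc[center_snp, "bp"]
    win = m[(m["chrom"] == chrom) & ((m["bp"] - bp).abs() <= window_kb * 1e3)]
    ids = [s for s in geno.snp_ids if s in set(win.index)]
    rows = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            try:
                res = ld_pair(geno, ids[i], ids[j])
            except ValueError:
                continue
            rows.append((ids[i], ids[j], int(m.loc[ids[i], "bp"]), int(m.loc[ids[j], "bp"]),
                         res.D, res.D_prime, res.r2, res.n))
    return pd.DataFrame(rows, columns=["snp_a", "snp_b", "bp_a", "bp_b", "D", "D_prime", "r2", "n"])
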