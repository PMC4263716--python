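"""Genotype quality control: MAF / missingness filters and Mendelian checks.

Mirrors the standard pre-association cleaning of a 60K-chip dataset:
animals with >5% missing calls are dropped first, then SNPs with minor
allele frequency <5% (computed on the remaining cohort), unmapped markers
are excluded, and offspring calls impossible under biallelic inheritance
from the genotyped parents are flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["GenotypeMatrix", "QcReport", "filter_maf_missingness", "filter_unmapped", "check_mendelian"]

MISSING = -1  # sentinel in the int8 dosage matrix


@dataclass
class GenotypeMatrix:
    """SNP x individual biallelic dosages; entries in {0,1,2} or -1 (missing).

    Dosage counts copies of the allele written as "2" in the PED file; the
    association model's -1/0/+1 genotype indicator is ``dosage - 1``, so the
    choice of counted allele only flips effect signs.
    """

    snp_ids: np.ndarray
    individual_ids: np.ndarray
    dosages: np.ndarray  # int8, shape (n_snps, n_individuals)

    def __post_init__(self):
        self.snp_ids = np.asarray(self.snp_ids)
        self.individual_ids = np.asarray(self.individual_ids)
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.shape != (len(self.snp_ids), len(self.individual_ids)):
            raise ValueError("dosage matrix shape inconsistent with id vectors")
        bad = ~np.isin(self.dosages, [-1, 0, 1, 2])
        if bad.any():
            raise ValueError("dosages must be 0/1/2 or -1 (missing)")
        if len(np.unique(self.individual_ids)) != len(self.individual_ids):
            raise ValueError("duplicated individual ids in genotype matrix")
        if len(np.unique(self.snp_ids)) != len(self.snp_ids):
            raise ValueError("duplicated snp ids in genotype matrix")

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    def maf(self) -> np.ndarray:
        """Folded allele frequency per SNP over non-missing calls (NaN if all missing)."""
        d = self.dosages
        obs = d != MISSING
        n_called = obs.sum(axis=1)
        alt = np.where(obs, d, 0).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = alt / (2.0 * n_called)
        p = np.where(n_called > 0, p, np.nan)
        return np.minimum(p, 1.0 - p)

    def subset(self, snp_mask=None, ind_mask=None) -> "GenotypeMatrix":
        sm = np.ones(self.n_snps, bool) if snp_mask is None else np.asarray(snp_mask)
        im = np.ones(self.n_individuals, bool) if ind_mask is None else np.asarray(ind_mask)
        return GenotypeMatrix(self.snp_ids[sm], self.individual_ids[im],
                              self.dosages[np.ix_(sm, im)])


@dataclass
class QcReport:
    snps_input: int
    individuals_input: int
    snps_removed_maf: int = 0
    snps_removed_unmapped: int = 0
    individuals_removed_missingness: int = 0
    mendelian_errors: list = field(default_factory=list)
    snps_retained: int = 0
    individuals_retained: int = 0

    def to_frame(self) -> pd.DataFrame:
        d = {k: getattr(self, k) for k in (
            "snps_input", "individuals_input", "snps_removed_maf",
            "snps_removed_unmapped", "individuals_removed_missingness",
            "snps_retained", "individuals_retained")}
        d["mendelian_error_count"] = len(self.mendelian_errors)
        return pd.DataFrame([d])

    def log_lines(self) -> list:
        return [
            f"input: {self.snps_input} SNPs x {self.individuals_input} individuals",
            f"individuals removed for missingness: {self.individuals_removed_missingness}",
            f"SNPs removed for MAF: {self.snps_removed_maf}",
            f"SNPs removed as unmapped: {self.snps_removed_unmapped}",
            f"Mendelian errors flagged: {len(self.mendelian_errors)}",
            f"retained: {self.snps_retained} SNPs x {self.individuals_retained} individuals",
        ]


def filter_maf_missingness(geno: GenotypeMatrix, maf_min: float = 0.05,
                           ind_miss_max: float = 0.05) -> tuple[GenotypeMatrix, QcReport]:
    """Drop high-missingness individuals, then low-MAF SNPs.

    The individual filter runs first so that MAF reflects the cohort that
    actually enters the association analysis.  SNPs with every call missing
    are removed with the MAF filter.
    """
    if not (0.0 <= maf_min <= 0.5):
        raise ValueError("maf_min must lie in [0, 0.5]")
    if not (0.0 <= ind_miss_max <= 1.0):
        raise ValueError("ind_miss_max must lie in [0, 1]")
    if geno.n_snps == 0 or geno.n_individuals == 0:
        raise ValueError("empty genotype matrix")

    miss_frac = (geno.dosages == MISSING).mean(axis=0)
    ind_keep = miss_frac <= ind_miss_max
    if not ind_keep.any():
        raise ValueError("all individuals removed by the missingness filter")
    g1 = geno.subset(ind_mask=ind_keep)

    maf = g1.maf()
    snp_keep = np.nan_to_num(maf, nan=-1.0) >= maf_min
    g2 = g1.subset(snp_mask=snp_keep)

    report = QcReport(
        snps_input=geno.n_snps,
        individuals_input=geno.n_individuals,
        snps_removed_maf=int((~snp_keep).sum()),
        individuals_removed_missingness=int((~ind_keep).sum()),
        snps_retained=g2.n_snps,
        individuals_retained=g2.n_individuals,
    )
    return g2, report


def filter_unmapped(geno: GenotypeMatrix, snp_map: pd.DataFrame) -> GenotypeMatrix:
    """Remove SNPs absent from the map or lacking chromosome/position."""
    m = snp_map.drop_duplicates("snp_id").set_index("snp_id")
    aligned = m.reindex(geno.snp_ids)
    keep = (aligned["chrom"].notna() & aligned["bp"].notna()).to_numpy()
    return geno.subset(snp_mask=keep)


def check_mendelian(geno: GenotypeMatrix, pedigree: pd.DataFrame) -> list:
    """Flag offspring calls impossible under biallelic inheritance.

    Only trios with both parents genotyped and no missing call at the SNP
    are checked.  Returns tuples (snp_id, offspring_id, sire_id, dam_id).
    """
    pos = {iid: i for i, iid in enumerate(geno.individual_ids)}
    if len(pos) != geno.n_individuals:
        raise ValueError("duplicated individuals in genotype matrix")
    errors = []
    d = geno.dosages
    for _, row in pedigree.iterrows():
        o, s, dm = row["individual_id"], row["sire_id"], row["dam_id"]
        if o not in pos or s is None or dm is None or pd.isna(s) or pd.isna(dm):
            continue
        if s not in pos or dm not in pos:
            continue
        go, gs, gd = d[:, pos[o]], d[:, pos[s]], d[:, pos[dm]]
        ok = (go != MISSING) & (gs != MISSING) & (gd != MISSING)
        # impossible transmissions from either single parent or the pair
        bad = ((gs == 0) & (go == 2)) | ((gs == 2) & (go == 0)) \
            | ((gd == 0) & (go == 2)) | ((gd == 2) & (go == 0)) \
            | ((gs == 0) & (gd == 0) & (go != 0)) \
            | ((gs == 2) & (gd == 2) & (go != 2)) \
            | ((gs == 0) & (gd == 2) & (go != 1)) \
            | ((gs == 2) & (gd == 0) & (go != 1))
        for i in np.flatnonzero(bad & ok):
            errors.append((geno.snp_ids[i], o, s, dm))
    return errors


def zero_mendelian(geno: GenotypeMatrix, errors: list) -> GenotypeMatrix:
    """Set flagged offspring calls to missing (opt-in; errors are reported, not auto-zeroed)."""
    d = geno.dosages.copy()
    spos = {sid: i for i, sid in enumerate(geno.snp_ids)}
    ipos = {iid: i for i, iid in enumerate(geno.individual_ids)}
    for snp_id, off, _s, _d in errors:
        d[spos[snp_id], ipos[off]] = MISSING
    return GenotypeMatrix(geno.snp_ids, geno.individual_ids, d)
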