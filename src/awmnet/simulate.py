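"""Synthetic Iberian x Landrace backcross generator.

Produces a statistically faithful stand-in for a three-generation pig
resource population: a pedigree mixing two divergent founder breeds
(A = Iberian-like, B = Landrace-like), SNP genotypes dropped through the
pedigree with Haldane-model recombination (so admixture + linkage create
realistic LD), a BED-like gene/miRNA annotation engineered to exercise every
branch of the AWM SNP-to-gene assignment rule, and 12 correlated phenotypes
(growth/conformation vs fatness) with a known genetic architecture:

* two antagonistic trait blocks — QTLs that increase the growth traits
  decrease the fatness traits and vice versa;
* a polygenic term with covariance proportional to the pedigree numerator
  relationship matrix, simulated by mating-path accumulation (offspring
  breeding value = parent average + Mendelian-sampling deviate with the
  exact inbreeding correction);
* sex and slaughter-batch fixed effects plus an age trend, so the
  covariate scheme of the association model is applicable.

Everything is a deterministic function of ``SimConfig.seed``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kinship import tabular_A

__all__ = [
    "TRAITS",
    "GROWTH_TRAITS",
    "FAT_TRAITS",
    "TRAIT_MEANS",
    "TRAIT_SDS",
    "SimConfig",
    "TrueArchitecture",
    "GenomeAnnotation",
    "SimulatedStudy",
    "simulate_cross",
    "simulate_annotation",
    "random_pedigree",
    "polygenic_values",
]

# Trait panel: body weights, carcass measures, primal-cut weights and fat
# depositions, with reference means/SDs for a Landrace-type backcross.
GROWTH_TRAITS = ["BW125", "BW155", "BW180", "CW", "CL", "HW", "SW", "BLW"]
FAT_TRAITS = ["BFT155", "BFT180", "BFTS", "IMF"]
TRAITS = ["BW125", "BW155", "BW180", "CW", "CL", "BFT155", "BFT180", "BFTS", "IMF", "HW", "SW", "BLW"]

TRAIT_MEANS = {
    "BW125": 58.11, "BW155": 80.74, "BW180": 100.10, "CW": 74.46, "CL": 81.86,
    "BFT155": 13.34, "BFT180": 15.60, "BFTS": 23.26, "IMF": 1.52,
    "HW": 21.62, "SW": 10.04, "BLW": 7.33,
}
TRAIT_SDS = {
    "BW125": 8.71, "BW155": 13.61, "BW180": 14.91, "CW": 11.07, "CL": 6.23,
    "BFT155": 3.08, "BFT180": 3.21, "BFTS": 6.13, "IMF": 0.78,
    "HW": 3.39, "SW": 1.72, "BLW": 1.14,
}

PHENOTYPED_GENERATIONS = ("BC1", "BC", "F3")


@dataclass
class SimConfig:
    """Parameters of the simulated cross.

    Distances in bp, recombination in cM/Mb, effect scales in units of the
    corresponding trait SD.  ``seed`` fully determines every output.
    """

    n_founders_breedA: int = 3
    n_founders_breedB: int = 79
    generation_sizes: dict = field(
        default_factory=lambda: {"f1": 30, "f2": 60, "bc1": 159, "bc": 79, "f3": 54}
    )
    n_chromosomes: int = 10
    snps_per_chromosome: int = 200
    chromosome_length_bp: int = 100_000_000
    recomb_rate: float = 1.0  # cM per Mb
    founder_freq_divergence: float = 0.5
    n_qtl_per_block: int = 8
    qtl_effect_sd: float = 0.30  # per-allele effect, trait-SD units
    shared_pleiotropy: float = 0.5  # P(QTL also hits the opposite block, sign flipped)
    polygenic_frac: float = 0.20  # polygenic variance as fraction of trait variance
    heritability_per_trait: float | dict = 0.35
    trait_means: dict = field(default_factory=lambda: dict(TRAIT_MEANS))
    trait_sds: dict = field(default_factory=lambda: dict(TRAIT_SDS))
    sex_effect: float = 0.3  # male-female difference, trait-SD units
    batch_effect_sd: float = 0.15  # SD of batch offsets, trait-SD units
    age_slope: float = 0.3  # trait-SD per age-SD
    age_mean: float = 180.0
    age_sd: float = 2.8
    n_batches: int = 9
    missing_rate: float = 0.02
    # annotation construction
    near_gene_frac: float = 0.6
    mirna_frac: float = 0.8
    regulator_frac: float = 0.10
    n_go_regulators: int = 22
    seed: int = 42

    def heritabilities(self) -> dict:
        h = self.heritability_per_trait
        if isinstance(h, dict):
            return {t: float(h[t]) for t in TRAITS}
        return {t: float(h) for t in TRAITS}

    def validate(self) -> None:
        if self.n_founders_breedA < 1 or self.n_founders_breedB < 1:
            raise ValueError("both founder breeds need at least one individual")
        for k, v in self.generation_sizes.items():
            if v < 0:
                raise ValueError(f"negative generation size for {k!r}")
        if sum(self.generation_sizes.get(g, 0) for g in ("f1",)) < 1:
            raise ValueError("at least one F1 individual is required")
        for t, h in self.heritabilities().items():
            if not (0.0 < h < 1.0):
                raise ValueError(f"heritability for {t} must lie in (0,1), got {h}")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must lie in [0,1)")
        if not (0.0 <= self.founder_freq_divergence <= 1.0):
            raise ValueError("founder_freq_divergence must lie in [0,1]")
        if self.chromosome_length_bp < 50 * self.snps_per_chromosome:
            raise ValueError("chromosome shorter than the requested SNP spacing")


@dataclass
class TrueArchitecture:
    """Ground truth planted by the simulator (realized, post-calibration units)."""

    qtl_snp_ids: list
    effects: pd.DataFrame  # index qtl snp_id, columns TRAITS, trait units/allele
    block: dict  # qtl snp_id -> "growth" | "fat"
    qtl_gene_ids: dict  # qtl snp_id -> overlapping gene id
    planted_regulator_gene_ids: list


@dataclass
class GenomeAnnotation:
    features: pd.DataFrame  # chrom, start, end, id, kind in {gene, miRNA}; 0-based half-open
    tf_ids: list
    go_ids: list
    mirna_ids: list
    planted_regulator_ids: list


@dataclass
class SimulatedStudy:
    config: SimConfig
    pedigree: pd.DataFrame
    geno: "GenotypeMatrix"
    snp_map: pd.DataFrame
    phenotypes: pd.DataFrame  # all individuals; `phenotyped` column marks the cohort
    architecture: TrueArchitecture
    annotation: GenomeAnnotation
    haplotypes: np.ndarray  # (n_ind, 2, n_snp) alleles in {0,1}, pre-masking
    breed_origin: np.ndarray  # (n_ind, 2, n_snp), 0 = breed A, 1 = breed B


def _rng(config: SimConfig, key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=config.seed, spawn_key=(key,)))


# stable child-stream keys
_K_MAP, _K_FOUNDERS, _K_DROP, _K_PHENO, _K_ANNOT, _K_MISS, _K_PED = range(7)


def _snp_map_and_strata(config: SimConfig):
    """Deterministic SNP map with construction strata.

    Each chromosome is laid out as: a gene-bearing region (first 92%), a
    1-Mb miRNA band, and a terminal gene desert (> 1 Mb from any gene), so
    the near-gene / near-miRNA / desert branches of the assignment rule are
    all populated for any seed.
    """
    rng = _rng(config, _K_MAP)
    L = config.chromosome_length_bp
    n = config.snps_per_chromosome
    gene_end = int(0.92 * L)
    rows = []
    for c in range(1, config.n_chromosomes + 1):
        n_desert = max(3, round(0.05 * n))
        n_band = max(2, round(0.02 * n))
        n_gene = n - n_desert - n_band
        pos_gene = rng.integers(10_000, gene_end - 30_000, size=n_gene)
        pos_band = rng.integers(gene_end + 5_000, gene_end + 985_000, size=n_band)
        pos_desert = rng.integers(gene_end + 1_030_000, L - 10_000, size=n_desert)
        stratum = (["generegion"] * n_gene) + (["band"] * n_band) + (["desert"] * n_desert)
        order = np.argsort(np.concatenate([pos_gene, pos_band, pos_desert]), kind="stable")
        pos = np.concatenate([pos_gene, pos_band, pos_desert])[order]
        strat = np.array(stratum, dtype=object)[order]
        # refine gene-region SNPs into near-gene vs intermediate
        near = rng.random(len(pos)) < config.near_gene_frac
        mirna = rng.random(len(pos)) < config.mirna_frac
        for i, (p, s) in enumerate(zip(pos, strat)):
            if s == "generegion":
                s = "near" if near[i] else "mid"
            elif s == "band":
                s = "mirna" if mirna[i] else "mid"
            rows.append((c, f"SNP{c:02d}_{i:04d}", p / 1e6 * config.recomb_rate, int(p), s))
        # guarantee at least one near-gene and one miRNA SNP per chromosome
        chrom_rows = [r for r in rows if r[0] == c]
        if not any(r[4] == "near" for r in chrom_rows):
            idx = next(i for i, r in enumerate(rows) if r[0] == c)
            rows[idx] = rows[idx][:4] + ("near",)
        if not any(r[4] == "mirna" for r in chrom_rows):
            idx = next(i for i, r in enumerate(rows) if r[0] == c and
                       gene_end < r[3] < gene_end + 1_000_000)
            rows[idx] = rows[idx][:4] + ("mirna",)
    snp_map = pd.DataFrame(rows, columns=["chrom", "snp_id", "cm", "bp", "stratum"])
    return snp_map, gene_end


def _select_qtls(config: SimConfig, snp_map: pd.DataFrame):
    rng = _rng(config, _K_MAP + 100)
    near = snp_map.index[snp_map["stratum"] == "near"].to_numpy()
    n_qtl = 2 * config.n_qtl_per_block
    if len(near) < n_qtl:
        raise ValueError("not enough near-gene SNPs to place the requested QTLs")
    picked = np.sort(rng.choice(near, size=n_qtl, replace=False))
    qtl_ids = snp_map.loc[picked, "snp_id"].tolist()
    blocks = {s: ("growth" if i < config.n_qtl_per_block else "fat") for i, s in enumerate(qtl_ids)}
    return qtl_ids, blocks


def _build_annotation(config: SimConfig, snp_map: pd.DataFrame, gene_end: int,
                      qtl_ids: list) -> GenomeAnnotation:
    rng = _rng(config, _K_ANNOT)
    feats = []
    qtl_gene = {}
    gene_ids = []
    for c, sub in snp_map.groupby("chrom"):
        k = 0
        # anchor gene pinning the gene-region boundary (keeps band SNPs <1 Mb from a gene)
        feats.append((c, gene_end - 21_000, gene_end - 1_000, f"GANC{c:02d}", "gene"))
        for _, row in sub.iterrows():
            if row["stratum"] == "near" or row["snp_id"] in qtl_ids:
                offs = int(rng.integers(200, 2_000))
                length = int(rng.integers(5_000, 30_000))
                gid = f"G{c:02d}{k:03d}"
                feats.append((c, int(row["bp"]) - offs, int(row["bp"]) - offs + length, gid, "gene"))
                gene_ids.append(gid)
                if row["snp_id"] in qtl_ids:
                    qtl_gene[row["snp_id"]] = gid
                k += 1
            elif row["stratum"] == "mirna":
                offs = int(rng.integers(2_600, 9_000))
                mid = f"MIR{c:02d}{k:03d}"
                feats.append((c, int(row["bp"]) + offs, int(row["bp"]) + offs + 80, mid, "miRNA"))
                k += 1
    features = pd.DataFrame(feats, columns=["chrom", "start", "end", "id", "kind"])
    features = features.sort_values(["chrom", "start", "id"]).reset_index(drop=True)
    mirna_ids = features.loc[features["kind"] == "miRNA", "id"].tolist()
    planted = sorted(set(qtl_gene.values()))
    other = [g for g in gene_ids if g not in planted]
    n_extra = int(round(config.regulator_frac * len(gene_ids)))
    extra = sorted(rng.choice(other, size=min(n_extra, len(other)), replace=False).tolist())
    tf_ids = sorted(set(planted) | set(extra))
    go_pool = sorted(gene_ids)
    go_ids = sorted(rng.choice(go_pool, size=min(config.n_go_regulators, len(go_pool)),
                               replace=False).tolist())
    return GenomeAnnotation(features, tf_ids, go_ids, mirna_ids, planted), qtl_gene


def simulate_annotation(config: SimConfig) -> GenomeAnnotation:
    """Gene/miRNA annotation matched to the SNP map implied by ``config``."""
    config.validate()
    snp_map, gene_end = _snp_map_and_strata(config)
    qtl_ids, _ = _select_qtls(config, snp_map)
    ann, _ = _build_annotation(config, snp_map, gene_end, qtl_ids)
    return ann


def _build_pedigree(config: SimConfig) -> pd.DataFrame:
    rng = _rng(config, _K_PED)
    rows = []  # individual_id, sire, dam, sex, generation

    def add(n, gen, sire_pool, dam_pool, prefix):
        ids = []
        for i in range(n):
            iid = f"{prefix}{i + 1:04d}"
            sire = sire_pool[int(rng.integers(len(sire_pool)))] if sire_pool else None
            dam = dam_pool[int(rng.integers(len(dam_pool)))] if dam_pool else None
            sex = 1 if i % 2 == 0 else 2  # 1 = male, 2 = female
            rows.append((iid, sire, dam, sex, gen))
            ids.append(iid)
        return ids

    a_ids = []
    for i in range(config.n_founders_breedA):
        iid = f"A{i + 1:03d}"
        rows.append((iid, None, None, 1, "FOUNDER_A"))
        a_ids.append(iid)
    b_ids = []
    for i in range(config.n_founders_breedB):
        iid = f"B{i + 1:03d}"
        rows.append((iid, None, None, 2, "FOUNDER_B"))
        b_ids.append(iid)

    gs = config.generation_sizes
    f1 = add(gs.get("f1", 0), "F1", a_ids, b_ids, "F1_")
    f1_males = [i for i, r in zip(f1, rows[-len(f1):]) if r[3] == 1] if f1 else []
    f1_females = [i for i, r in zip(f1, rows[-len(f1):]) if r[3] == 2] if f1 else []
    f2 = add(gs.get("f2", 0), "F2", f1_males or f1, f1_females or f1, "F2_")
    f2_rows = rows[-len(f2):] if f2 else []
    f2_males = [i for i, r in zip(f2, f2_rows) if r[3] == 1]
    f2_females = [i for i, r in zip(f2, f2_rows) if r[3] == 2]
    add(gs.get("bc1", 0), "BC1", f1_males[:5] or f1_males or f1, b_ids, "BC1_")
    add(gs.get("bc", 0), "BC", f2_males[:4] or f2_males or f2, b_ids, "BC2_")
    if gs.get("f3", 0):
        add(gs["f3"], "F3", f2_males or f2, f2_females or f2, "F3_")

    ped = pd.DataFrame(rows, columns=["individual_id", "sire_id", "dam_id", "sex", "generation"])
    ped["phenotyped"] = ped["generation"].isin(PHENOTYPED_GENERATIONS)
    # slaughter batches: round-robin within the phenotyped cohort, 1..n_batches
    batch = np.ones(len(ped), dtype=int)
    ph_idx = np.flatnonzero(ped["phenotyped"].to_numpy())
    batch[ph_idx] = (np.arange(len(ph_idx)) % config.n_batches) + 1
    ped["batch"] = batch
    return ped


def _meiosis(rng, haps, origins, cm, chrom_slices):
    """One gamete from a parent's two haplotypes, Haldane crossovers."""
    n_snp = haps.shape[1]
    gam = np.empty(n_snp, dtype=np.int8)
    org = np.empty(n_snp, dtype=np.int8)
    for sl in chrom_slices:
        cm_c = cm[sl]
        span = cm_c[-1] - cm_c[0] if len(cm_c) > 1 else 0.0
        ncx = rng.poisson(span / 100.0)
        start = int(rng.integers(2))
        if ncx:
            cx = np.sort(rng.uniform(cm_c[0], cm_c[-1], size=ncx))
            choice = (start + np.searchsorted(cx, cm_c, side="right")) % 2
        else:
            choice = np.full(len(cm_c), start)
        idx = np.arange(sl.start, sl.stop)
        gam[sl] = haps[choice, idx]
        org[sl] = origins[choice, idx]
    return gam, org


def polygenic_values(pedigree: pd.DataFrame, sigma2: float,
                     rng: np.random.Generator, n_traits: int = 1,
                     inbreeding: np.ndarray | None = None) -> np.ndarray:
    """Breeding values by mating-path accumulation (exact under the pedigree model).

    Offspring value = parent average + Mendelian deviate with variance
    0.5 * sigma2 * (1 - (F_sire + F_dam)/2).  Requires the pedigree rows to
    be topologically ordered (parents first), as produced by the simulator.
    Returns an (n_individuals, n_traits) array.
    """
    ids = list(pedigree["individual_id"])
    pos = {v: k for k, v in enumerate(ids)}
    n = len(ids)
    sd = np.sqrt(sigma2)
    u = np.zeros((n, n_traits))
    F = np.zeros(n) if inbreeding is None else np.asarray(inbreeding, dtype=float)
    for i, (_, row) in enumerate(pedigree.iterrows()):
        s, d = row["sire_id"], row["dam_id"]
        si = pos.get(s) if s not in (None, "0") and not pd.isna(s) else None
        di = pos.get(d) if d not in (None, "0") and not pd.isna(d) else None
        if si is None and di is None:
            u[i] = rng.normal(0.0, sd, size=n_traits)
        else:
            pa = np.zeros(n_traits)
            fbar = 0.0
            if si is not None:
                pa += 0.5 * u[si]
                fbar += 0.5 * F[si]
            if di is not None:
                pa += 0.5 * u[di]
                fbar += 0.5 * F[di]
            msv = 0.5 * sigma2 * (1.0 - fbar)
            u[i] = pa + rng.normal(0.0, np.sqrt(msv), size=n_traits)
    return u


def random_pedigree(n_founders: int, n_per_generation: int, n_generations: int,
                    seed: int) -> pd.DataFrame:
    """Deep random-mating pedigree used by the variance-component tests."""
    rng = np.random.default_rng(seed)
    rows = [(f"P0_{i:04d}", None, None, 1 if i % 2 == 0 else 2, "G0") for i in range(n_founders)]
    prev = [r[0] for r in rows]
    prev_sex = {r[0]: r[3] for r in rows}
    for g in range(1, n_generations + 1):
        males = [i for i in prev if prev_sex[i] == 1]
        females = [i for i in prev if prev_sex[i] == 2]
        cur = []
        for i in range(n_per_generation):
            iid = f"P{g}_{i:04d}"
            sex = 1 if i % 2 == 0 else 2
            rows.append((iid, males[int(rng.integers(len(males)))],
                         females[int(rng.integers(len(females)))], sex, f"G{g}"))
            cur.append(iid)
            prev_sex[iid] = sex
        prev = cur
    return pd.DataFrame(rows, columns=["individual_id", "sire_id", "dam_id", "sex", "generation"])


def simulate_cross(config: SimConfig) -> SimulatedStudy:
    """Run the full generative model; see module docstring."""
    from .qc import GenotypeMatrix  # local import to avoid a cycle

    config.validate()
    snp_map, gene_end = _snp_map_and_strata(config)
    qtl_ids, blocks = _select_qtls(config, snp_map)
    annotation, qtl_gene = _build_annotation(config, snp_map, gene_end, qtl_ids)
    ped = _build_pedigree(config)
    n_ind = len(ped)
    n_snp = len(snp_map)
    cm = snp_map["cm"].to_numpy()
    chrom_slices = []
    chroms = snp_map["chrom"].to_numpy()
    for c in np.unique(chroms):
        w = np.flatnonzero(chroms == c)
        chrom_slices.append(slice(int(w[0]), int(w[-1]) + 1))

    # founder allele frequencies, divergent between breeds
    rng_f = _rng(config, _K_FOUNDERS)
    p0 = rng_f.uniform(0.2, 0.8, n_snp)
    sign = rng_f.choice([-1.0, 1.0], n_snp)
    delta = 0.5 * config.founder_freq_divergence * sign
    p_a = np.clip(p0 + delta, 0.02, 0.98)
    p_b = np.clip(p0 - delta, 0.02, 0.98)

    haps = np.zeros((n_ind, 2, n_snp), dtype=np.int8)
    origins = np.zeros((n_ind, 2, n_snp), dtype=np.int8)
    rng_d = _rng(config, _K_DROP)
    pos = {v: k for k, v in enumerate(ped["individual_id"])}
    gen = ped["generation"].to_numpy()
    sires = ped["sire_id"].to_numpy()
    dams = ped["dam_id"].to_numpy()
    for i in range(n_ind):
        if gen[i] == "FOUNDER_A":
            haps[i] = (rng_d.random((2, n_snp)) < p_a).astype(np.int8)
            origins[i] = 0
        elif gen[i] == "FOUNDER_B":
            haps[i] = (rng_d.random((2, n_snp)) < p_b).astype(np.int8)
            origins[i] = 1
        else:
            si, di = pos[sires[i]], pos[dams[i]]
            haps[i, 0], origins[i, 0] = _meiosis(rng_d, haps[si], origins[si], cm, chrom_slices)
            haps[i, 1], origins[i, 1] = _meiosis(rng_d, haps[di], origins[di], cm, chrom_slices)

    dosage = haps.sum(axis=1).T.astype(np.int8)  # (n_snp, n_ind), counts of allele "2"

    # ---- phenotypes -------------------------------------------------------
    rng_p = _rng(config, _K_PHENO)
    h2 = config.heritabilities()
    sds = np.array([config.trait_sds[t] for t in TRAITS])
    means = np.array([config.trait_means[t] for t in TRAITS])
    gidx = {t: j for j, t in enumerate(TRAITS)}

    qtl_rows = snp_map.set_index("snp_id").index.get_indexer(qtl_ids)
    D = dosage[qtl_rows].T.astype(float)  # (n_ind, n_qtl)
    E = np.zeros((len(qtl_ids), len(TRAITS)))
    for q, sid in enumerate(qtl_ids):
        own = GROWTH_TRAITS if blocks[sid] == "growth" else FAT_TRAITS
        other = FAT_TRAITS if blocks[sid] == "growth" else GROWTH_TRAITS
        mags = np.abs(rng_p.normal(0.0, config.qtl_effect_sd, len(TRAITS))) + 0.1 * config.qtl_effect_sd
        shared = rng_p.random() < config.shared_pleiotropy
        for t in own:
            E[q, gidx[t]] = mags[gidx[t]] * sds[gidx[t]]
        if shared:
            for t in other:
                E[q, gidx[t]] = -mags[gidx[t]] * sds[gidx[t]]

    # polygenic term, exact Mendelian-sampling variances via pedigree F
    s_idx = np.array([pos[s] if s is not None else -1 for s in sires])
    d_idx = np.array([pos[d] if d is not None else -1 for d in dams])
    A = tabular_A(s_idx, d_idx)  # pedigree is built parents-first
    F = np.diag(A) - 1.0
    U_unit = polygenic_values(ped, 1.0, rng_p, n_traits=len(TRAITS), inbreeding=F)
    U = U_unit * (np.sqrt(config.polygenic_frac) * sds)[None, :]

    G = D @ E + U
    scale = np.ones(len(TRAITS))
    for j, t in enumerate(TRAITS):
        vg = G[:, j].var()
        if vg > 0:
            scale[j] = np.sqrt(h2[t] * sds[j] ** 2 / vg)
    G = G * scale
    E_realized = E * scale  # QTL effects actually expressed, trait units/allele

    sex = ped["sex"].to_numpy()
    batch = ped["batch"].to_numpy()
    age = rng_p.normal(config.age_mean, config.age_sd, n_ind)
    sex_term = np.where(sex == 1, 0.5, -0.5)[:, None] * (config.sex_effect * sds)[None, :]
    batch_eff = rng_p.normal(0.0, config.batch_effect_sd, (config.n_batches + 1, len(TRAITS))) * sds[None, :]
    batch_term = batch_eff[batch]
    age_term = ((age - config.age_mean) / config.age_sd)[:, None] * (config.age_slope * sds)[None, :]
    resid = rng_p.normal(0.0, 1.0, (n_ind, len(TRAITS))) * (np.sqrt(1.0 - np.array([h2[t] for t in TRAITS])) * sds)[None, :]
    Y = means[None, :] + sex_term + batch_term + age_term + G + resid

    pheno = pd.DataFrame(Y, columns=TRAITS)
    pheno.insert(0, "individual_id", ped["individual_id"].to_numpy())
    pheno.insert(1, "sex", sex)
    pheno.insert(2, "batch", batch)
    pheno.insert(3, "generation", ped["generation"].to_numpy())
    pheno.insert(4, "phenotyped", ped["phenotyped"].to_numpy())
    pheno.insert(5, "age", age)

    # genotype missingness
    rng_m = _rng(config, _K_MISS)
    dosage_obs = dosage.copy()
    if config.missing_rate > 0:
        mask = rng_m.random(dosage.shape) < config.missing_rate
        dosage_obs[mask] = -1

    geno = GenotypeMatrix(
        snp_ids=snp_map["snp_id"].to_numpy(),
        individual_ids=ped["individual_id"].to_numpy(),
        dosages=dosage_obs,
    )
    arch = TrueArchitecture(
        qtl_snp_ids=list(qtl_ids),
        effects=pd.DataFrame(E_realized, index=qtl_ids, columns=TRAITS),
        block=dict(blocks),
        qtl_gene_ids=dict(qtl_gene),
        planted_regulator_gene_ids=list(annotation.planted_regulator_ids),
    )
    return SimulatedStudy(
        config=config, pedigree=ped, geno=geno,
        snp_map=snp_map.drop(columns=["stratum"]).assign(stratum=snp_map["stratum"]),
        phenotypes=pheno, architecture=arch, annotation=annotation,
        haplotypes=haps, breed_origin=origins,
    )
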