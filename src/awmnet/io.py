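"""Plain-text readers/writers for the pipeline's interchange formats.

Genotypes travel as plink-style PED/MAP text (alleles coded 1/2, missing 0),
phenotypes/pedigree as TSV with header, annotation as a BED-like TSV
(0-based half-open intervals), regulator lists as one id per line.  All
writers are deterministic (fixed float formatting, stable ordering) so a
rerun under the same seed is byte-identical.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .qc import GenotypeMatrix
from .simulate import GenomeAnnotation, SimulatedStudy, TRAITS

FLOAT_FMT = "%.10g"


def write_map(snp_map: pd.DataFrame, path) -> None:
    cols = snp_map[["chrom", "snp_id", "cm", "bp"]].copy()
    cols["cm"] = cols["cm"].map(lambda v: FLOAT_FMT % v)
    cols.to_csv(path, sep="\t", header=False, index=False)


def read_map(path) -> pd.DataFrame:
    m = pd.read_csv(path, sep=r"\s+", header=None,
                    names=["chrom", "snp_id", "cm", "bp"])
    return m


def write_ped(geno: GenotypeMatrix, pedigree: pd.DataFrame, path,
              family_id: str = "SIM") -> None:
    """PED rows: fam, id, sire, dam, sex, phenotype(-9), then 2 alleles/SNP.

    Dosage d (count of allele "2") is expanded as d copies of allele 2 and
    2-d of allele 1; missing dosage becomes "0 0".
    """
    ped = pedigree.set_index("individual_id")
    d = geno.dosages  # (n_snp, n_ind)
    a1 = np.where(d == -1, 0, np.where(d >= 1, 2, 1))
    a2 = np.where(d == -1, 0, np.where(d == 2, 2, 1))
    with open(path, "w") as fh:
        for j, iid in enumerate(geno.individual_ids):
            row = ped.loc[iid]
            sire = row["sire_id"] if pd.notna(row["sire_id"]) and row["sire_id"] is not None else "0"
            dam = row["dam_id"] if pd.notna(row["dam_id"]) and row["dam_id"] is not None else "0"
            lead = [family_id, str(iid), str(sire), str(dam), str(int(row["sex"])), "-9"]
            alleles = np.empty(2 * geno.n_snps, dtype=np.int64)
            alleles[0::2] = a1[:, j]
            alleles[1::2] = a2[:, j]
            fh.write(" ".join(lead) + " " + " ".join(map(str, alleles)) + "\n")


def read_ped(path, snp_ids) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Read a PED file back into dosages + a minimal pedigree frame."""
    ids, sires, dams, sexes = [], [], [], []
    dosage_cols = []
    n_snp = len(snp_ids)
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            _fam, iid, sire, dam, sex, _ph = parts[:6]
            alleles = np.array(parts[6:], dtype=np.int64)
            if len(alleles) != 2 * n_snp:
                raise ValueError(f"PED row for {iid} has {len(alleles)//2} SNPs, expected {n_snp}")
            a1, a2 = alleles[0::2], alleles[1::2]
            miss = (a1 == 0) | (a2 == 0)
            dos = (a1 == 2).astype(np.int8) + (a2 == 2).astype(np.int8)
            dos[miss] = -1
            ids.append(iid)
            sires.append(None if sire == "0" else sire)
            dams.append(None if dam == "0" else dam)
            sexes.append(int(sex))
            dosage_cols.append(dos)
    geno = GenotypeMatrix(np.asarray(snp_ids), np.array(ids),
                          np.column_stack(dosage_cols))
    ped = pd.DataFrame({"individual_id": ids, "sire_id": sires,
                        "dam_id": dams, "sex": sexes})
    return geno, ped


def write_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FMT)


def read_tsv(path, **kw) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kw)


def write_annotation(ann: GenomeAnnotation, outdir) -> None:
    outdir = Path(outdir)
    write_tsv(ann.features, outdir / "annotation.tsv")
    for name, ids in (("tf_ids.txt", ann.tf_ids), ("go_ids.txt", ann.go_ids),
                      ("mirna_ids.txt", ann.mirna_ids),
                      ("planted_regulators.txt", ann.planted_regulator_ids)):
        (outdir / name).write_text("".join(f"{i}\n" for i in ids))


def read_annotation(outdir) -> GenomeAnnotation:
    outdir = Path(outdir)
    feats = read_tsv(outdir / "annotation.tsv")

    def ids(name):
        p = outdir / name
        return [l for l in p.read_text().splitlines() if l] if p.exists() else []

    return GenomeAnnotation(feats, ids("tf_ids.txt"), ids("go_ids.txt"),
                            ids("mirna_ids.txt"), ids("planted_regulators.txt"))


def read_id_list(path) -> list:
    return [l.strip() for l in Path(path).read_text().splitlines() if l.strip()]


def write_study(study: SimulatedStudy, outdir) -> None:
    """Write every simulator output as text (PED/MAP, TSVs, id lists)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_map(study.snp_map, outdir / "genotypes.map")
    write_ped(study.geno, study.pedigree, outdir / "genotypes.ped")
    write_tsv(study.pedigree, outdir / "pedigree.tsv")
    write_tsv(study.phenotypes, outdir / "phenotypes.tsv")
    write_annotation(study.annotation, outdir)
    arch = study.architecture
    eff = arch.effects.copy()
    eff.insert(0, "block", [arch.block[s] for s in eff.index])
    eff.insert(1, "gene_id", [arch.qtl_gene_ids.get(s, "") for s in eff.index])
    eff.index.name = "snp_id"
    write_tsv(eff, outdir / "true_architecture.tsv", index=True)
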