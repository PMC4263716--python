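"""End-to-end pipeline: simulate -> qc -> gwas -> awm -> network -> trio -> ld.

Every stage exchanges plain-text tables (PED/MAP, TSV, id lists) under the
run directory and appends its bookkeeping (row/edge counts, parameters,
seeds, output checksums) to a deterministic ``manifest.json`` — mirroring
the counts a study of this design reports: SNPs retained after QC, AWM
rows, edges before/after the |r| threshold, trio coverage.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .simulate import SimConfig, simulate_cross, TRAITS
from .qc import filter_maf_missingness, filter_unmapped, check_mendelian, zero_mendelian
from .kinship import numerator_relationship_matrix
from .gwas import default_scheme, snp_association_scan
from .awm import SelectionRule, zscore_effects, build_awm, cluster_traits
from .network import gene_correlation_matrix, pcit_filter, threshold_edges, topology
from .regulators import mark_regulators, find_top_trio
from .ld import ld_window
from . import io

log = logging.getLogger("awmnet")

STAGES = ("simulate", "qc", "gwas", "awm", "network", "trio", "ld")


@dataclass
class PipelineConfig:
    out_dir: str = "awmnet_run"
    seed: int = 42
    stages: tuple = STAGES
    sim: dict = field(default_factory=dict)  # SimConfig field overrides
    maf_min: float = 0.05
    ind_miss_max: float = 0.05
    zero_mendelian_calls: bool = False
    key_trait: str = "HW"
    alpha: float = 0.05
    min_traits: int = 3
    near_gene_kb: float = 2.5
    far_gene_kb: float = 1000.0
    mirna_kb: float = 10.0
    dedupe_window_kb: float = 1000.0
    drop_intermediate: bool = True
    edge_threshold: float = 0.86
    trio_on_thresholded: bool = True
    ld_window_kb: float = 2000.0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)

    def selection_rule(self) -> SelectionRule:
        return SelectionRule(key_trait=self.key_trait, alpha=self.alpha,
                             min_traits=self.min_traits, near_gene_kb=self.near_gene_kb,
                             far_gene_kb=self.far_gene_kb, mirna_kb=self.mirna_kb,
                             dedupe_window_kb=self.dedupe_window_kb,
                             drop_intermediate=self.drop_intermediate)

    def sim_config(self) -> SimConfig:
        return SimConfig(seed=self.seed, **self.sim)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages; returns the manifest dictionary."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = set(config.stages)
    manifest: dict = {
        "package": "awmnet",
        "version": __version__,
        "seed": config.seed,
        "parameters": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in dataclasses.asdict(config).items()},
        "stages": {},
        "files": {},
    }

    def record(stage: str, counts: dict, files: list):
        manifest["stages"][stage] = counts
        for f in files:
            manifest["files"][str(f.relative_to(out))] = _sha256(f)
        log.info("stage %s: %s", stage, counts)

    # ---- simulate ---------------------------------------------------------
    if "simulate" not in stages:
        raise ValueError("this pipeline runs on simulated input; enable the simulate stage")
    sim_dir = out / "sim"
    study = simulate_cross(config.sim_config())
    io.write_study(study, sim_dir)
    record("simulate", {
        "individuals": int(len(study.pedigree)),
        "phenotyped": int(study.pedigree["phenotyped"].sum()),
        "snps": int(study.geno.n_snps),
        "genes": int((study.annotation.features["kind"] == "gene").sum()),
        "mirnas": int((study.annotation.features["kind"] == "miRNA").sum()),
        "qtls": len(study.architecture.qtl_snp_ids),
    }, sorted(sim_dir.iterdir()))

    geno, snp_map = study.geno, study.snp_map
    pedigree, pheno = study.pedigree, study.phenotypes

    # ---- qc ---------------------------------------------------------------
    if "qc" in stages:
        qc_dir = out / "qc"
        qc_dir.mkdir(exist_ok=True)
        n0 = geno.n_snps
        geno = filter_unmapped(geno, snp_map)
        n_unmapped = n0 - geno.n_snps
        geno, report = filter_maf_missingness(geno, config.maf_min, config.ind_miss_max)
        report.snps_removed_unmapped = n_unmapped
        report.snps_input = n0
        errors = check_mendelian(geno, pedigree)
        report.mendelian_errors = errors
        if config.zero_mendelian_calls and errors:
            geno = zero_mendelian(geno, errors)
        io.write_tsv(report.to_frame(), qc_dir / "qc_report.tsv")
        (qc_dir / "qc.log").write_text("".join(l + "\n" for l in report.log_lines()))
        io.write_tsv(pd.DataFrame(errors, columns=["snp_id", "offspring_id", "sire_id", "dam_id"]),
                     qc_dir / "mendelian_errors.tsv")
        record("qc", {
            "snps_input": n0,
            "snps_removed_unmapped": n_unmapped,
            "snps_removed_maf": report.snps_removed_maf,
            "individuals_removed_missingness": report.individuals_removed_missingness,
            "mendelian_errors": len(errors),
            "snps_retained": geno.n_snps,
            "individuals_retained": geno.n_individuals,
        }, sorted(qc_dir.iterdir()))
    if not (stages & {"gwas", "awm", "network", "trio", "ld"}):
        _write_manifest(manifest, out)
        return manifest
    if "qc" not in stages and (geno.dosages == -1).any():
        raise ValueError("qc stage disabled but genotypes contain missing calls")

    # ---- gwas -------------------------------------------------------------
    gwas_dir = out / "gwas"
    gwas_dir.mkdir(exist_ok=True)
    cohort = pheno[pheno["phenotyped"]].copy()
    geno_ph = geno.subset(ind_mask=np.isin(geno.individual_ids, cohort["individual_id"]))
    A = numerator_relationship_matrix(pedigree)
    scheme = default_scheme()
    result = snp_association_scan(geno_ph, cohort, scheme, A)
    io.write_tsv(result.effects, gwas_dir / "effects.tsv", index=True)
    io.write_tsv(result.pvalues, gwas_dir / "pvalues.tsv", index=True)
    for trait in scheme.traits:
        io.write_tsv(result.trait_frame(trait, snp_map), gwas_dir / f"gwas_{trait}.tsv")
    vc_frame = pd.DataFrame([
        {"trait": t, "sigma_u2": v.sigma_u2, "sigma_e2": v.sigma_e2}
        for t, v in result.varcomps.items()])
    io.write_tsv(vc_frame, gwas_dir / "variance_components.tsv")
    record("gwas", {
        "snps_tested": int(geno_ph.n_snps),
        "individuals": int(geno_ph.n_individuals),
        "traits": len(scheme.traits),
        "monomorphic": int((result.status == "monomorphic").any(axis=1).sum()),
    }, sorted(gwas_dir.iterdir()))
    if "awm" not in stages:
        _write_manifest(manifest, out)
        return manifest

    # ---- awm --------------------------------------------------------------
    awm_dir = out / "awm"
    awm_dir.mkdir(exist_ok=True)
    ok_rows = result.effects.notna().all(axis=1)
    z = zscore_effects(result.effects.loc[ok_rows])
    rule = config.selection_rule()
    awm = build_awm(z, result.pvalues.loc[ok_rows], snp_map,
                    study.annotation.features, rule)
    awm_out = awm.provenance.set_index("feature_id").join(awm.values)
    io.write_tsv(awm_out, awm_dir / "awm.tsv", index=True)
    clust = cluster_traits(awm)
    labels = pd.DataFrame({"trait": clust.traits,
                           "cluster": [clust.labels[t] for t in clust.traits]})
    io.write_tsv(labels, awm_dir / "trait_clusters.tsv")
    record("awm", {
        "snps_selected": int(len(awm.provenance)),
        "awm_rows": int(len(awm.values)),
        "gene_rows": int((awm.provenance["kind"] == "gene").sum()),
        "mirna_rows": int((awm.provenance["kind"] == "miRNA").sum()),
        "desert_rows": int((awm.provenance["kind"] == "desert").sum()),
        "trait_cluster_sizes": sorted(labels["cluster"].value_counts().tolist()),
    }, sorted(awm_dir.iterdir()))
    if "network" not in stages:
        _write_manifest(manifest, out)
        return manifest

    # ---- network ----------------------------------------------------------
    net_dir = out / "network"
    net_dir.mkdir(exist_ok=True)
    R, dropped = gene_correlation_matrix(awm)
    net, decisions = pcit_filter(R)
    net.write_edge_list(net_dir / "edges_pcit.tsv")
    thr = threshold_edges(net, config.edge_threshold)
    thr.write_edge_list(net_dir / "edges_thresholded.tsv")
    thr.write_sif(net_dir / "network.sif")
    topo = topology(thr)
    io.write_tsv(topo.to_frame(), net_dir / "topology.tsv")
    io.write_tsv(topo.degrees.rename_axis("node").reset_index(), net_dir / "degrees.tsv")
    record("network", {
        "awm_rows_used": int(R.shape[0]),
        "constant_rows_dropped": len(dropped),
        "edges_pcit": int(net.n_edges),
        "edge_threshold": config.edge_threshold,
        "edges_thresholded": int(thr.n_edges),
        "nodes_thresholded": int(thr.n_nodes),
        "mean_degree": round(topo.mean_degree, 4),
        "mean_distance": round(topo.mean_distance, 4) if np.isfinite(topo.mean_distance) else None,
    }, sorted(net_dir.iterdir()))
    if "trio" not in stages:
        _write_manifest(manifest, out)
        return manifest

    # ---- trio -------------------------------------------------------------
    trio_dir = out / "trio"
    trio_dir.mkdir(exist_ok=True)
    target_net = thr if config.trio_on_thresholded else net
    ann = study.annotation
    regs = mark_regulators(target_net, ann.tf_ids, ann.go_ids, ann.mirna_ids)
    used_full_network = False
    if len(regs) < 3 and target_net is thr:
        # too few regulators survive the strong-edge cut: search the full PCIT graph
        target_net = net
        regs = mark_regulators(target_net, ann.tf_ids, ann.go_ids, ann.mirna_ids)
        used_full_network = True
    trio = find_top_trio(target_net, regs)
    trio.subnetwork.write_edge_list(trio_dir / "trio_subnetwork.tsv")
    trio.subnetwork.write_sif(trio_dir / "trio_subnetwork.sif")
    trio_report = {
        "members": list(trio.members),
        "coverage": trio.coverage,
        "redundancy": trio.redundancy,
        "member_degrees": trio.member_degrees,
        "subnetwork_nodes": trio.subnetwork.n_nodes,
        "subnetwork_edges": trio.subnetwork.n_edges,
        "n_regulators_in_network": len(regs),
        "searched_full_pcit_network": used_full_network,
    }
    (trio_dir / "trio.json").write_text(json.dumps(trio_report, indent=2, sort_keys=True) + "\n")
    record("trio", trio_report, sorted(trio_dir.iterdir()))
    if "ld" not in stages:
        _write_manifest(manifest, out)
        return manifest

    # ---- ld ---------------------------------------------------------------
    ld_dir = out / "ld"
    ld_dir.mkdir(exist_ok=True)
    # LD landscape around the representative SNP of the best-connected trio member
    top_member = max(trio.member_degrees, key=lambda m: (trio.member_degrees[m], m))
    prov = awm.provenance.set_index("feature_id")
    center = prov.loc[top_member, "snp_id"] if top_member in prov.index else geno.snp_ids[0]
    table = ld_window(geno, snp_map, center, config.ld_window_kb)
    io.write_tsv(table, ld_dir / f"ld_window_{center}.tsv")
    counts = {"center_snp": str(center), "pairs": int(len(table))}
    if len(table):
        counts["max_d_prime"] = round(float(table["D_prime"].max()), 6)
        counts["median_d_prime"] = round(float(table["D_prime"].median()), 6)
    record("ld", counts, sorted(ld_dir.iterdir()))

    _write_manifest(manifest, out)
    return manifest


def _write_manifest(manifest: dict, out: Path) -> None:
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
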