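"""Association Weight Matrix construction.

The AWM condenses a multi-trait GWAS into a gene x trait matrix of
standardized additive effects: SNP effects are z-scored per trait, SNPs are
admitted if nominally associated (p < 0.05) with the key phenotype (ham
weight) or with at least three traits, each admitted SNP is mapped to a
genomic feature (nearest gene within 2.5 kb; else nearest miRNA within
10 kb; SNPs more than 1,000 kb from any gene are kept as standalone
regulatory-region nodes; anything in between is discarded), and SNPs
clustering within 1 Mb are collapsed to the one associated with the most
traits.  Rows of the resulting matrix feed the co-association network.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

__all__ = [
    "SelectionRule", "Awm", "zscore_effects", "select_snps", "assign_genes",
    "dedupe_by_window", "build_awm", "cluster_traits", "TraitClustering",
]


@dataclass
class SelectionRule:
    key_trait: str = "HW"
    alpha: float = 0.05
    min_traits: int = 3
    near_gene_kb: float = 2.5
    far_gene_kb: float = 1000.0
    mirna_kb: float = 10.0
    dedupe_window_kb: float = 1000.0
    # when False, intermediate-distance SNPs (between near and far bounds)
    # are assigned to the nearest gene instead of being discarded
    drop_intermediate: bool = True

    def __post_init__(self):
        if not (0.0 < self.alpha <= 1.0):
            raise ValueError("alpha must lie in (0, 1]")
        for f in ("near_gene_kb", "far_gene_kb", "mirna_kb", "dedupe_window_kb"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be positive")


@dataclass
class Awm:
    """Gene x trait matrix of z-scored additive effects with SNP provenance."""

    values: pd.DataFrame  # index feature_id, columns traits
    provenance: pd.DataFrame  # feature_id, snp_id, kind, chrom, bp, distance, n_traits_associated, key_p

    @property
    def feature_ids(self) -> list:
        return list(self.values.index)


def zscore_effects(effects: pd.DataFrame) -> pd.DataFrame:
    """Per-trait standardization (x - mean) / sample SD (ddof=1)."""
    if len(effects) < 2:
        raise ValueError("need at least two SNPs per column to z-score")
    sd = effects.std(axis=0, ddof=1)
    if (sd <= 0).any() or sd.isna().any():
        bad = list(sd.index[(sd <= 0) | sd.isna()])
        raise ValueError(f"zero-variance effect column(s): {bad}")
    return (effects - effects.mean(axis=0)) / sd


def select_snps(pvalues: pd.DataFrame, rule: SelectionRule) -> pd.DataFrame:
    """Key-phenotype / >=3-trait admission rule.

    Returns a frame indexed by the selected snp_ids with columns
    ``n_traits_associated`` (count of traits with p < alpha, over all
    traits) and ``key_p``.
    """
    if rule.key_trait not in pvalues.columns:
        raise ValueError(f"key trait {rule.key_trait!r} absent from p-value columns")
    sig = pvalues < rule.alpha
    n_assoc = sig.sum(axis=1)
    keep = sig[rule.key_trait] | (n_assoc >= rule.min_traits)
    out = pd.DataFrame({
        "n_traits_associated": n_assoc[keep],
        "key_p": pvalues.loc[keep, rule.key_trait],
    })
    out.index.name = "snp_id"
    return out


def _nearest_feature(bp: int, feats: pd.DataFrame) -> tuple[str, float]:
    """(feature_id, distance) of the nearest interval; 0 if the SNP lies inside.

    Intervals are 0-based half-open; SNP positions are 1-based.  Ties on
    distance break lexicographically on feature id.
    """
    start = feats["start"].to_numpy()
    end = feats["end"].to_numpy()
    dist = np.maximum.reduce([start - (bp - 1), bp - end, np.zeros(len(feats), dtype=np.int64)])
    best = dist.min()
    cand = feats["id"].to_numpy()[dist == best]
    return sorted(cand)[0], float(best)


def assign_genes(snp_ids, snp_map: pd.DataFrame, annotation: pd.DataFrame,
                 rule: SelectionRule) -> pd.DataFrame:
    """Map each SNP to a feature per the distance rules.

    Returns a frame (snp_id, feature_id, kind, chrom, bp, distance) with
    kind in {gene, miRNA, desert}; SNPs falling in the discarded
    intermediate zone are absent from the output.
    """
    m = snp_map.drop_duplicates("snp_id").set_index("snp_id")
    rows = []
    genes = annotation[annotation["kind"] == "gene"]
    mirnas = annotation[annotation["kind"] == "miRNA"]
    for sid in snp_ids:
        if sid not in m.index:
            continue
        chrom, bp = m.loc[sid, "chrom"], int(m.loc[sid, "bp"])
        g = genes[genes["chrom"] == chrom]
        mi = mirnas[mirnas["chrom"] == chrom]
        g_id, g_d = _nearest_feature(bp, g) if len(g) else (None, np.inf)
        if g_d < rule.near_gene_kb * 1e3:
            rows.append((sid, g_id, "gene", chrom, bp, g_d))
            continue
        mi_id, mi_d = _nearest_feature(bp, mi) if len(mi) else (None, np.inf)
        if mi_d < rule.mirna_kb * 1e3:
            rows.append((sid, mi_id, "miRNA", chrom, bp, mi_d))
        elif g_d > rule.far_gene_kb * 1e3:
            if np.isinf(g_d) and rule.drop_intermediate is False:
                raise ValueError(f"SNP {sid} on chromosome {chrom} with no annotated features")
            rows.append((sid, sid, "desert", chrom, bp, g_d))
        elif not rule.drop_intermediate:
            rows.append((sid, g_id, "gene", chrom, bp, g_d))
    return pd.DataFrame(rows, columns=["snp_id", "feature_id", "kind", "chrom", "bp", "distance"])


def dedupe_by_window(assigned: pd.DataFrame, selection: pd.DataFrame,
                     rule: SelectionRule) -> pd.DataFrame:
    """One representative SNP per 1-Mb single-linkage positional cluster.

    Within a cluster the SNP associated with the most traits wins; ties go
    to the smaller key-trait p, then the smaller position.
    """
    df = assigned.merge(selection, left_on="snp_id", right_index=True, how="left")
    df = df.sort_values(["chrom", "bp", "snp_id"], kind="stable").reset_index(drop=True)
    win = rule.dedupe_window_kb * 1e3
    keep_rows = []
    for _, sub in df.groupby("chrom", sort=True):
        bp = sub["bp"].to_numpy()
        new_cluster = np.ones(len(sub), bool)
        new_cluster[1:] = np.diff(bp) >= win
        cluster = np.cumsum(new_cluster)
        for _, cl in sub.groupby(cluster):
            best = cl.sort_values(["n_traits_associated", "key_p", "bp"],
                                  ascending=[False, True, True], kind="stable").iloc[0]
            keep_rows.append(best)
    out = pd.DataFrame(keep_rows).reset_index(drop=True)
    return out


def build_awm(zscores: pd.DataFrame, pvalues: pd.DataFrame, snp_map: pd.DataFrame,
              annotation: pd.DataFrame, rule: SelectionRule | None = None) -> Awm:
    """Compose z-score -> select -> assign -> dedupe into the AWM.

    ``zscores``/``pvalues`` are SNP x trait frames over all QC-passing SNPs
    (z-scoring over the full panel precedes selection).  If several
    representative SNPs map to the same feature, the one associated with
    more traits (same tie-breaks as the window dedup) provides the row.
    """
    rule = rule or SelectionRule()
    sel = select_snps(pvalues, rule)
    if sel.empty:
        raise ValueError("no SNP passed the selection rule")
    assigned = assign_genes(sel.index, snp_map, annotation, rule)
    reps = dedupe_by_window(assigned, sel, rule)
    reps = reps.sort_values(["n_traits_associated", "key_p", "bp"],
                            ascending=[False, True, True], kind="stable")
    reps = reps.drop_duplicates("feature_id", keep="first")
    reps = reps.sort_values(["chrom", "bp", "snp_id"], kind="stable").reset_index(drop=True)
    values = zscores.loc[reps["snp_id"]].copy()
    values.index = pd.Index(reps["feature_id"], name="feature_id")
    prov = reps[["feature_id", "snp_id", "kind", "chrom", "bp", "distance",
                 "n_traits_associated", "key_p"]].reset_index(drop=True)
    return Awm(values=values, provenance=prov)


@dataclass
class TraitClustering:
    linkage: np.ndarray  # scipy linkage matrix over trait columns
    labels: dict  # trait -> cluster id at k=2
    traits: list

    def partition(self) -> tuple[frozenset, frozenset]:
        a = frozenset(t for t, l in self.labels.items() if l == 1)
        b = frozenset(t for t, l in self.labels.items() if l == 2)
        return a, b


def cluster_traits(awm: Awm, method: str = "average", metric: str = "euclidean",
                   k: int = 2) -> TraitClustering:
    """Agglomerative clustering of trait columns (defaults: Euclidean/average)."""
    traits = list(awm.values.columns)
    if len(traits) < 2:
        raise ValueError("need at least two trait columns to cluster")
    X = awm.values.to_numpy().T
    Z = hierarchy.linkage(pdist(X, metric=metric), method=method)
    flat = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    return TraitClustering(linkage=Z, labels=dict(zip(traits, flat)), traits=traits)
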