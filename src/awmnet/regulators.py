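"""Putative regulators and the best-covering regulator trio.

Regulators are the union of a transcription-factor catalogue, a GO-derived
regulator list and the annotated miRNAs, intersected with the network
nodes.  The top trio maximizes *coverage* (distinct non-trio nodes adjacent
to at least one member); ties break on minimum *redundancy* (summed
pairwise shared-neighbor counts), then lexicographically on the sorted id
triple, so the search is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .network import CoassocNetwork

__all__ = ["RegulatorSet", "TrioResult", "mark_regulators", "find_top_trio", "trio_subnetwork"]


@dataclass
class RegulatorSet:
    ids: list  # sorted regulator ids present in the network
    sources: dict  # id -> sorted list of labels from {TF-list, GO-regulator, miRNA}

    def __len__(self) -> int:
        return len(self.ids)


@dataclass
class TrioResult:
    members: tuple  # three regulator ids, sorted
    coverage: int
    redundancy: int
    member_degrees: dict
    subnetwork: CoassocNetwork


def mark_regulators(net: CoassocNetwork, tf_ids, go_ids, mirna_ids) -> RegulatorSet:
    """Union of the three regulator sources restricted to network nodes."""
    nodes = set(net.nodes)
    sources: dict = {}
    for label, ids in (("TF-list", tf_ids), ("GO-regulator", go_ids), ("miRNA", mirna_ids)):
        for i in ids:
            if i in nodes:
                sources.setdefault(i, set()).add(label)
    if not sources:
        raise ValueError("no regulator id intersects the network nodes")
    return RegulatorSet(ids=sorted(sources),
                        sources={k: sorted(v) for k, v in sorted(sources.items())})


def _neighbor_matrix(net: CoassocNetwork, regs: list) -> tuple[np.ndarray, dict]:
    pos = {n: i for i, n in enumerate(net.nodes)}
    N = np.zeros((len(regs), len(net.nodes)), dtype=bool)
    rpos = {r: i for i, r in enumerate(regs)}
    for a, b in net.edges[["node_a", "node_b"]].itertuples(index=False, name=None):
        if a in rpos:
            N[rpos[a], pos[b]] = True
        if b in rpos:
            N[rpos[b], pos[a]] = True
    return N, pos


def find_top_trio(net: CoassocNetwork, regs: RegulatorSet) -> TrioResult:
    """Exhaustive search over all C(|regs|, 3) trios.

    Coverage is computed with vectorized boolean neighbor unions (one pass
    per regulator pair); redundancy is only evaluated for the trios tied on
    maximal coverage.
    """
    ids = list(regs.ids)
    if len(ids) < 3:
        raise ValueError("need at least three regulators in the network")
    N, pos = _neighbor_matrix(net, ids)
    R = len(ids)
    member_col = np.zeros((R, len(net.nodes)), dtype=bool)
    for i, r in enumerate(ids):
        member_col[i, pos[r]] = True

    best_cov = -1
    candidates: list = []
    for i in range(R - 2):
        for j in range(i + 1, R - 1):
            pair = N[i] | N[j]
            ks = np.arange(j + 1, R)
            union = pair[None, :] | N[j + 1:]
            # exclude the trio members themselves from the covered set
            trio_mask = member_col[i] | member_col[j]
            cov = (union & ~trio_mask[None, :] & ~member_col[j + 1:]).sum(axis=1)
            m = int(cov.max()) if len(cov) else -1
            if m > best_cov:
                best_cov = m
                candidates = []
            if m == best_cov:
                for k in ks[cov == best_cov]:
                    candidates.append((i, j, int(k)))

    def redundancy(t):
        i, j, k = t
        return int((N[i] & N[j]).sum() + (N[i] & N[k]).sum() + (N[j] & N[k]).sum())

    scored = sorted(((redundancy(t), tuple(sorted(ids[x] for x in t)), t) for t in candidates))
    red, members, _ = scored[0]
    g_deg = {}
    nbrs = net.neighbor_sets()
    for m in members:
        g_deg[m] = len(nbrs[m])
    sub = trio_subnetwork(net, members)
    return TrioResult(members=members, coverage=best_cov, redundancy=red,
                      member_degrees=g_deg, subnetwork=sub)


def trio_subnetwork(net: CoassocNetwork, trio) -> CoassocNetwork:
    """All edges with at least one endpoint in the trio, plus their endpoints."""
    trio = list(trio)
    missing = [t for t in trio if t not in set(net.nodes)]
    if missing:
        raise ValueError(f"trio member(s) absent from network: {missing}")
    e = net.edges
    mask = e["node_a"].isin(trio) | e["node_b"].isin(trio)
    edges = e.loc[mask].reset_index(drop=True)
    nodes = sorted(set(trio) | set(edges["node_a"]) | set(edges["node_b"]))
    return CoassocNetwork(nodes=nodes, edges=edges)
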