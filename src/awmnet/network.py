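"""Gene co-association network: row correlations, PCIT filter, topology.

PCIT (partial correlation + information theory) visits every triad
(x, y, z), computes the three first-order partial correlations, forms a
local tolerance epsilon as the mean of the ratios |partial/direct| (terms
with a zero direct correlation are skipped), and eliminates the edge (x,y)
if for some z both |r_xy| <= eps*|r_xz| and |r_xy| <= eps*|r_yz|.
Surviving pairs keep the *direct* correlation as edge weight.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import pandas as pd
import networkx as nx

__all__ = [
    "CoassocNetwork", "TopologyReport", "gene_correlation_matrix",
    "first_order_partial", "pcit_filter", "threshold_edges", "topology",
]

_EPS = 1e-12


@dataclass
class CoassocNetwork:
    """Undirected weighted gene graph; edges stored symmetric-unique (a < b)."""

    nodes: list
    edges: pd.DataFrame  # columns node_a, node_b, r
    threshold_applied: float | None = None
    n_edges_pre_threshold: int | None = None

    def __post_init__(self):
        e = self.edges
        if len(e):
            if (e["node_a"] == e["node_b"]).any():
                raise ValueError("self-edges are not allowed")
            if (e["r"].abs() > 1 + 1e-9).any():
                raise ValueError("|r| must not exceed 1")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_weighted_edges_from(
            self.edges[["node_a", "node_b", "r"]].itertuples(index=False, name=None))
        return g

    def neighbor_sets(self) -> dict:
        nbrs = {n: set() for n in self.nodes}
        for a, b in self.edges[["node_a", "node_b"]].itertuples(index=False, name=None):
            nbrs[a].add(b)
            nbrs[b].add(a)
        return nbrs

    def write_edge_list(self, path) -> None:
        out = self.edges.copy()
        out["r"] = out["r"].map(lambda v: "%.10g" % v)
        out.to_csv(path, sep="\t", index=False)

    def write_sif(self, path) -> None:
        with open(path, "w") as fh:
            for a, b in self.edges[["node_a", "node_b"]].itertuples(index=False, name=None):
                fh.write(f"{a}\tcoassoc\t{b}\n")


def gene_correlation_matrix(awm) -> tuple[pd.DataFrame, list]:
    """Pearson correlations between AWM gene rows across the trait columns.

    Zero-variance rows are excluded with a warning.  Returns (R, dropped_ids).
    """
    V = awm.values
    if V.shape[1] < 3:
        raise ValueError("need at least three trait columns")
    sd = V.std(axis=1, ddof=1)
    dropped = list(V.index[(sd <= 0) | sd.isna()])
    if dropped:
        warnings.warn(f"excluding {len(dropped)} constant AWM row(s): {dropped[:5]}...")
        V = V.drop(index=dropped)
    R = np.corrcoef(V.to_numpy())
    np.fill_diagonal(R, 1.0)
    return pd.DataFrame(R, index=V.index, columns=V.index), dropped


def first_order_partial(r_xy: float, r_xz: float, r_yz: float) -> float:
    """r_xy.z = (r_xy - r_xz*r_yz) / sqrt((1 - r_xz^2)(1 - r_yz^2))."""
    for r in (r_xy, r_xz, r_yz):
        if abs(r) > 1 + 1e-12:
            raise ValueError("correlations must lie in [-1, 1]")
    den = (1.0 - r_xz ** 2) * (1.0 - r_yz ** 2)
    if den <= _EPS:
        raise ValueError("degenerate conditioning: |r_xz| or |r_yz| is 1")
    return (r_xy - r_xz * r_yz) / np.sqrt(den)


def pcit_filter(R: pd.DataFrame | np.ndarray, node_ids=None):
    """Apply PCIT to a symmetric correlation matrix.

    Returns (CoassocNetwork, decisions) where decisions is a DataFrame with
    one row per unordered pair: node_a, node_b, r, kept, eliminating_node
    (the smallest-index z that removed the pair, empty if kept).
    """
    if isinstance(R, pd.DataFrame):
        ids = list(R.index)
        M = R.to_numpy(dtype=float)
    else:
        M = np.asarray(R, dtype=float)
        ids = list(node_ids) if node_ids is not None else list(range(M.shape[0]))
    n = M.shape[0]
    if M.shape != (n, n) or not np.allclose(M, M.T, atol=1e-8):
        raise ValueError("correlation matrix must be square and symmetric")
    if np.isnan(M).any():
        raise ValueError("correlation matrix contains NaN")
    M = 0.5 * (M + M.T)

    absM = np.abs(M)
    one_minus_sq = np.clip(1.0 - M ** 2, _EPS, None)
    eliminated = np.zeros((n, n), bool)
    eliminator = np.full((n, n), -1, dtype=np.int64)
    offdiag = ~np.eye(n, dtype=bool)

    for z in range(n):
        Rz = M[:, z]
        # partials conditioned on z, all pairs at once
        den_z = np.sqrt(np.outer(one_minus_sq[:, z], one_minus_sq[:, z]))
        P_z = (M - np.outer(Rz, Rz)) / den_z
        with np.errstate(divide="ignore", invalid="ignore"):
            T1 = np.abs(P_z) / absM            # |r_xy.z / r_xy|
        V1 = offdiag & (absM > 0)
        # U[c, i] = |r_iz.c / r_iz|
        num = Rz[None, :] - M * Rz[:, None]
        den = np.sqrt(one_minus_sq) * np.sqrt(one_minus_sq[:, z])[:, None]
        with np.errstate(divide="ignore", invalid="ignore"):
            U = np.abs(num / den) / np.abs(Rz)[None, :]
        VU = (np.abs(Rz) > 0)[None, :] & offdiag  # valid where r_iz != 0, c != i
        T2, V2 = U.T, VU.T                      # term for pair (x,z) conditioned on y
        T3, V3 = U, VU                          # term for pair (y,z) conditioned on x

        tsum = np.where(V1, T1, 0.0) + np.where(V2, T2, 0.0) + np.where(V3, T3, 0.0)
        cnt = V1.astype(int) + V2.astype(int) + V3.astype(int)
        with np.errstate(divide="ignore", invalid="ignore"):
            eps = tsum / cnt
        valid = cnt > 0
        lim_x = eps * np.abs(Rz)[:, None]  # eps * |r_xz| over (x, y)
        lim_y = eps * np.abs(Rz)[None, :]  # eps * |r_yz|
        cond = valid & (absM <= lim_x) & (absM <= lim_y)
        cond &= offdiag
        cond[z, :] = False
        cond[:, z] = False
        newly = cond & ~eliminated
        eliminator[newly] = z
        eliminated |= cond

    iu, ju = np.triu_indices(n, k=1)
    kept = ~(eliminated[iu, ju] | eliminated[ju, iu])
    elim_z = np.where(eliminated[iu, ju], eliminator[iu, ju], eliminator[ju, iu])
    decisions = pd.DataFrame({
        "node_a": [ids[i] for i in iu],
        "node_b": [ids[j] for j in ju],
        "r": M[iu, ju],
        "kept": kept,
        "eliminating_node": ["" if k else ids[e] for k, e in zip(kept, elim_z)],
    })
    edge_mask = kept & (M[iu, ju] != 0.0)
    edges = decisions.loc[edge_mask, ["node_a", "node_b", "r"]].reset_index(drop=True)
    net = CoassocNetwork(nodes=ids, edges=edges)
    return net, decisions


def threshold_edges(net: CoassocNetwork, min_abs_r: float = 0.86) -> CoassocNetwork:
    """Keep edges with |r| strictly greater than the cut; drop isolated nodes."""
    keep = net.edges["r"].abs() > min_abs_r
    edges = net.edges.loc[keep].reset_index(drop=True)
    connected = sorted(set(edges["node_a"]) | set(edges["node_b"]))
    return CoassocNetwork(nodes=connected, edges=edges,
                          threshold_applied=min_abs_r,
                          n_edges_pre_threshold=net.n_edges)


@dataclass
class TopologyReport:
    n_nodes: int
    n_edges: int
    mean_degree: float
    mean_distance: float  # over connected ordered pairs
    n_unreachable_pairs: int
    degrees: pd.Series

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "n_nodes": self.n_nodes, "n_edges": self.n_edges,
            "mean_degree": self.mean_degree, "mean_distance": self.mean_distance,
            "n_unreachable_pairs": self.n_unreachable_pairs,
        }])


def topology(net: CoassocNetwork) -> TopologyReport:
    """Degrees, mean degree and BFS mean shortest-path over connected pairs."""
    if net.n_nodes < 1:
        raise ValueError("empty network")
    g = net.to_networkx()
    deg = pd.Series(dict(g.degree()), name="degree").sort_index()
    total, count = 0, 0
    for _src, dists in nx.all_pairs_shortest_path_length(g):
        for _dst, d in dists.items():
            if d > 0:
                total += d
                count += 1
    n_ordered = net.n_nodes * (net.n_nodes - 1)
    return TopologyReport(
        n_nodes=net.n_nodes,
        n_edges=net.n_edges,
        mean_degree=2.0 * net.n_edges / net.n_nodes,
        mean_distance=total / count if count else float("nan"),
        n_unreachable_pairs=n_ordered - count,
        degrees=deg,
    )
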