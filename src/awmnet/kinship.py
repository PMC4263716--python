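"""Pedigree-based numerator relationship matrix (Henderson's tabular method).

The numerator relationship matrix **A** holds the expected additive genetic
covariance between individuals under the infinitesimal model, scaled so a
non-inbred individual has a self-relationship of 1.  It is the covariance
structure of the polygenic term in the mixed-model association scan.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["numerator_relationship_matrix", "topological_order", "inbreeding_coefficients"]


def topological_order(ids: list, sire: dict, dam: dict) -> list:
    """Return ids ordered so every parent precedes its offspring.

    Raises ValueError on a pedigree cycle (an individual being its own
    ancestor) or on a parent id that is not itself in ``ids``.
    """
    idset = set(ids)
    for i in ids:
        for p in (sire.get(i), dam.get(i)):
            if p is not None and p not in idset:
                raise ValueError(f"parent {p!r} of {i!r} missing from pedigree")
    order: list = []
    state: dict = {}  # 0 = in progress, 1 = done

    for root in ids:
        if state.get(root) == 1:
            continue
        stack = [(root, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded:
                state[node] = 1
                order.append(node)
                continue
            if state.get(node) == 1:
                continue
            if state.get(node) == 0:
                raise ValueError(f"pedigree cycle involving {node!r}")
            state[node] = 0
            stack.append((node, True))
            for p in (sire.get(node), dam.get(node)):
                if p is not None and state.get(p) != 1:
                    if state.get(p) == 0:
                        raise ValueError(f"pedigree cycle involving {p!r}")
                    stack.append((p, False))
    return order


def _parent_indices(pedigree: pd.DataFrame) -> tuple[list, np.ndarray, np.ndarray]:
    ids = list(pedigree["individual_id"])
    sire = dict(zip(ids, pedigree["sire_id"]))
    dam = dict(zip(ids, pedigree["dam_id"]))

    def norm(p):
        if p is None or (isinstance(p, float) and np.isnan(p)) or p in ("", "0", 0):
            return None
        return p

    sire = {k: norm(v) for k, v in sire.items()}
    dam = {k: norm(v) for k, v in dam.items()}
    order = topological_order(ids, sire, dam)
    pos = {v: k for k, v in enumerate(order)}
    s_idx = np.array([pos[sire[i]] if sire[i] is not None else -1 for i in order], dtype=np.int64)
    d_idx = np.array([pos[dam[i]] if dam[i] is not None else -1 for i in order], dtype=np.int64)
    return order, s_idx, d_idx


def tabular_A(s_idx: np.ndarray, d_idx: np.ndarray) -> np.ndarray:
    """Henderson's tabular method on parent index arrays (-1 = unknown).

    Requires parents to precede offspring (index of parent < index of child).
    """
    n = len(s_idx)
    if np.any(s_idx >= np.arange(n)) or np.any(d_idx >= np.arange(n)):
        raise ValueError("parents must precede offspring in the index order")
    A = np.zeros((n, n))
    for i in range(n):
        s, d = s_idx[i], d_idx[i]
        if i > 0:
            row = np.zeros(i)
            if s >= 0:
                row += 0.5 * A[:i, s]
            if d >= 0:
                row += 0.5 * A[:i, d]
            A[i, :i] = row
            A[:i, i] = row
        A[i, i] = 1.0 + (0.5 * A[s, d] if (s >= 0 and d >= 0) else 0.0)
    return A


def numerator_relationship_matrix(pedigree: pd.DataFrame) -> pd.DataFrame:
    """Numerator relationship matrix A over all pedigree members.

    Parameters
    ----------
    pedigree
        DataFrame with columns ``individual_id``, ``sire_id``, ``dam_id``;
        unknown parents encoded as None/NaN/"0".  Any ordering is accepted;
        a topological sort is applied internally and the result is returned
        indexed in the *input* id order.
    """
    if pedigree["individual_id"].duplicated().any():
        raise ValueError("duplicated individual ids in pedigree")
    order, s_idx, d_idx = _parent_indices(pedigree)
    A = tabular_A(s_idx, d_idx)
    out = pd.DataFrame(A, index=order, columns=order)
    ids = list(pedigree["individual_id"])
    return out.loc[ids, ids]


def inbreeding_coefficients(pedigree: pd.DataFrame) -> pd.Series:
    """F = diag(A) - 1 per individual."""
    A = numerator_relationship_matrix(pedigree)
    return pd.Series(np.diag(A.to_numpy()) - 1.0, index=A.index, name="F")
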