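"""Independent, deliberately naive triple-loop PCIT used as the test oracle.

Written directly from the algorithm's definition, sharing no code with the
vectorized implementation under test.
"""

import math

import numpy as np


def naive_pcit_edges(R: np.ndarray) -> set:
    """Return the set of kept pairs (i, j), i < j, with nonzero correlation."""
    R = np.asarray(R, dtype=float)
    n = R.shape[0]
    eliminated = set()
    for x in range(n):
        for y in range(n):
            if y == x:
                continue
            for z in range(n):
                if z == x or z == y:
                    continue
                terms = []
                for (a, b, c) in ((x, y, z), (x, z, y), (y, z, x)):
                    r_ab, r_ac, r_bc = R[a, b], R[a, c], R[b, c]
                    if r_ab == 0:
                        continue
                    den = (1 - r_ac ** 2) * (1 - r_bc ** 2)
                    den = max(den, 1e-12)
                    partial = (r_ab - r_ac * r_bc) / math.sqrt(den)
                    terms.append(abs(partial / r_ab))
                if not terms:
                    continue
                eps = sum(terms) / len(terms)
                if abs(R[x, y]) <= eps * abs(R[x, z]) and abs(R[x, y]) <= eps * abs(R[y, z]):
                    eliminated.add((min(x, y), max(x, y)))
                    break
    kept = set()
    for i in range(n):
        for j in range(i + 1, n):
            if (i, j) not in eliminated and R[i, j] != 0:
                kept.add((i, j))
    return kept


def random_correlation(rng: np.random.Generator, n: int, n_obs: int = 12,
                       block: bool = False) -> np.ndarray:
    """Correlation matrix of simulated AWM-like rows (n rows, n_obs traits)."""
    if block:
        sign = rng.choice([-1.0, 1.0], size=n)
        base = rng.normal(size=n_obs)
        X = sign[:, None] * base[None, :] + rng.normal(0, 0.6, size=(n, n_obs))
    else:
        X = rng.normal(size=(n, n_obs))
    R = np.corrcoef(X)
    np.fill_diagonal(R, 1.0)
    return R
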