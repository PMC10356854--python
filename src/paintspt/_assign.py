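"""Gated one-to-one assignment shared by the tracker and the colocalizer.

The matching convention used throughout the package: among candidate pairs
that satisfy the distance gate, take the maximum-cardinality one-to-one
matching and, among those, the one with minimum total cost. This is solved
exactly with the Hungarian algorithm by pricing infeasible pairs above the
sum of all feasible costs.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linear_sum_assignment

__all__ = ["gated_pairs"]


def gated_pairs(cost: np.ndarray, feasible: np.ndarray) -> np.ndarray:
    """Max-cardinality, then min-total-cost matching restricted to `feasible`.

    Parameters
    ----------
    cost : (n, m) array of pairwise costs (must be finite where feasible).
    feasible : (n, m) boolean gate.

    Returns
    -------
    (k, 2) integer array of (row, col) matched indices, sorted by row.
    Deterministic for a given input (ties resolved by the Hungarian solver's
    fixed scan order, i.e. by lower row/column index).
    """
    cost = np.asarray(cost, dtype=float)
    feasible = np.asarray(feasible, dtype=bool)
    if cost.size == 0 or not feasible.any():
        return np.empty((0, 2), dtype=int)
    # Price infeasible pairs so that (a) any matching using fewer infeasible
    # pairs is strictly cheaper and (b) among equal-cardinality matchings the
    # feasible-cost total decides.
    big = float(cost[feasible].sum()) + 1.0
    priced = np.where(feasible, cost, big)
    rows, cols = linear_sum_assignment(priced)
    keep = feasible[rows, cols]
    out = np.stack([rows[keep], cols[keep]], axis=1)
    return out[np.argsort(out[:, 0])]
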