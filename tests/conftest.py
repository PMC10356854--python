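"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

from itertools import permutations

import numpy as np
import pandas as pd
import pytest

from paintspt.linking import TrackSet


def brute_force_matching(cost: np.ndarray, feasible: np.ndarray):
    """Exhaustive max-cardinality, min-total-cost one-to-one matching.

    Independent oracle for the Hungarian-based matcher; only usable for tiny
    matrices. Enumerates all injective row->column maps (including partial
    ones via a 'skip' symbol) and returns the set of matched (row, col) pairs.
    """
    n, m = cost.shape
    best = None  # (n_matched, total_cost, pairs)
    cols = list(range(m)) + [None] * n  # None = unmatched
    for perm in set(permutations(cols, n)):
        pairs = []
        ok = True
        for i, j in enumerate(perm):
            if j is None:
                continue
            if not feasible[i, j]:
                ok = False
                break
            pairs.append((i, j))
        if not ok:
            continue
        key = (-len(pairs), sum(cost[i, j] for i, j in pairs))
        if best is None or key < best[0]:
            best = (key, pairs)
    return set(best[1]) if best else set()


def make_trackset(track_frames: dict, dt: float = 1.0,
                  channel: int = 1) -> TrackSet:
    """Build a TrackSet from {track_id: [(frame, x, y), ...]}."""
    rows = []
    lid = 0
    for tid, pts in track_frames.items():
        for f, x, y in pts:
            rows.append((tid, channel, int(f), float(x), float(y), lid))
            lid += 1
    table = pd.DataFrame(rows, columns=["track_id", "channel", "frame",
                                        "x", "y", "loc_id"])
    return TrackSet(table=table, dt=dt)


def brownian_trackset(n_tracks: int, n_frames: int, D: float, dt: float,
                      sigma_loc: float, seed: int = 0,
                      spacing: float = 50.0) -> TrackSet:
    """Ideal Brownian tracks (no linking step) on a widely spaced grid."""
    rng = np.random.default_rng(seed)
    rows = []
    lid = 0
    for tid in range(n_tracks):
        x0 = np.array([spacing * tid, 0.0])
        steps = rng.normal(0.0, np.sqrt(2 * D * dt), size=(n_frames - 1, 2))
        pos = x0 + np.concatenate([np.zeros((1, 2)), np.cumsum(steps, axis=0)])
        obs = pos + rng.normal(0.0, sigma_loc, size=pos.shape) if sigma_loc > 0 else pos
        for f in range(n_frames):
            rows.append((tid, 1, f, obs[f, 0], obs[f, 1], lid))
            lid += 1
    table = pd.DataFrame(rows, columns=["track_id", "channel", "frame",
                                        "x", "y", "loc_id"])
    return TrackSet(table=table, dt=dt)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
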