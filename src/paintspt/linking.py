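"""Trajectory reconstruction from per-frame localizations.

Frame-to-frame linking uses an optimal (Hungarian) one-to-one assignment
between active track heads and new localizations, gated at a maximum step
`r_max` and minimizing total squared displacement; unmatched heads survive a
configurable number of `memory` frames (gap closing) before the track is
terminated. Track filtering applies the standard rejection rules for
single-particle tracking on membranes: minimum number of localizations and a
minimum short-time diffusion coefficient to remove immobile molecules.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._assign import gated_pairs

__all__ = [
    "TrackSet",
    "SurvivalCurve",
    "ensure_loc_ids",
    "default_r_max",
    "link_frames",
    "track_D_lag1",
    "filter_tracks",
    "track_survival",
]

TRACK_COLUMNS = ["track_id", "channel", "frame", "x", "y", "loc_id"]


def default_r_max(dt: float, D_max: float = 1.0) -> float:
    """Linking gate: 3x the RMS frame displacement at the fastest plausible
    mobility (D_max, default 1 um^2/s)."""
    return 3.0 * math.sqrt(4.0 * D_max * dt)


def ensure_loc_ids(locs: pd.DataFrame) -> pd.DataFrame:
    """Normalize a localization table: sort by frame (stable) and attach a
    persistent integer ``loc_id``. Idempotent; the same ids are used by the
    tracker and the colocalizer so that pairs can be mapped onto tracks."""
    if "frame" not in locs.columns:
        raise ValueError("localization table lacks required column 'frame'")
    frames = locs["frame"].to_numpy()
    if len(frames) and (np.any(frames < 0) or np.any(frames != frames.astype(int))):
        raise ValueError("frames must be non-negative integers")
    if len(locs) and not np.all(np.isfinite(locs[["x", "y"]].to_numpy(dtype=float))):
        raise ValueError("coordinates must be finite")
    if "loc_id" in locs.columns:
        return locs
    out = locs.sort_values("frame", kind="stable").reset_index(drop=True)
    out["loc_id"] = np.arange(len(out))
    out.attrs = dict(locs.attrs)
    return out


@dataclass
class TrackSet:
    """Linked trajectories of one or both channels.

    table : DataFrame (track_id, channel, frame, x, y, loc_id), frames
            strictly increasing within a track (gaps allowed).
    dt    : frame interval in seconds.
    """

    table: pd.DataFrame
    dt: float
    metadata: dict = field(default_factory=dict)

    @property
    def n_tracks(self) -> int:
        return self.table["track_id"].nunique()

    def track_ids(self) -> np.ndarray:
        return self.table["track_id"].unique()

    def track(self, track_id) -> pd.DataFrame:
        return self.table[self.table["track_id"] == track_id]

    def durations_frames(self) -> pd.Series:
        """Track duration in frames: last - first + 1 (gaps included)."""
        g = self.table.groupby("track_id")["frame"]
        return g.max() - g.min() + 1

    def n_localizations(self) -> pd.Series:
        return self.table.groupby("track_id")["frame"].size()

    def __len__(self) -> int:
        return self.n_tracks


def _link_one_channel(df: pd.DataFrame, r_max: float, memory: int,
                      next_tid: int) -> tuple[list, int]:
    rows_out = []
    frames = df["frame"].to_numpy()
    xs = df["x"].to_numpy()
    ys = df["y"].to_numpy()
    lids = df["loc_id"].to_numpy()
    ch = int(df["channel"].iloc[0]) if "channel" in df.columns and len(df) else 0

    # heads: tid -> (last_frame, x, y)
    heads: dict[int, tuple[int, float, float]] = {}
    order = np.argsort(frames, kind="stable")
    f_sorted = frames[order]
    start = 0
    r2 = r_max * r_max
    for f in np.unique(f_sorted):
        stop = int(np.searchsorted(f_sorted, f, side="right"))
        idx = order[start:stop]
        start = stop
        # retire stale heads
        for tid in [t for t, (lf, _, _) in heads.items() if f - lf > memory + 1]:
            del heads[tid]
        head_ids = sorted(heads)
        if head_ids and idx.size:
            hx = np.array([[heads[t][1], heads[t][2]] for t in head_ids])
            px = np.stack([xs[idx], ys[idx]], axis=1)
            d2 = ((hx[:, None, :] - px[None, :, :]) ** 2).sum(axis=2)
            pairs = gated_pairs(d2, d2 <= r2)
        else:
            pairs = np.empty((0, 2), dtype=int)
        matched_pts = set()
        for hi, pi in pairs:
            tid = head_ids[hi]
            j = idx[pi]
            heads[tid] = (int(f), xs[j], ys[j])
            rows_out.append((tid, ch, int(f), xs[j], ys[j], lids[j]))
            matched_pts.add(pi)
        for pi in range(idx.size):
            if pi not in matched_pts:
                j = idx[pi]
                tid = next_tid
                next_tid += 1
                heads[tid] = (int(f), xs[j], ys[j])
                rows_out.append((tid, ch, int(f), xs[j], ys[j], lids[j]))
    return rows_out, next_tid


def link_frames(locs: pd.DataFrame, r_max: float = None, memory: int = 6,
                dt: float = None) -> TrackSet:
    """Reconstruct trajectories from a localization table.

    Per frame, active track heads are assigned one-to-one to localizations by
    minimum total squared displacement among candidates within `r_max`;
    unmatched heads stay active for `memory` frames (gap closing), unmatched
    localizations open new tracks. Channels are linked independently.
    """
    if dt is None:
        dt = locs.attrs.get("metadata", {}).get("dt")
        if dt is None:
            raise ValueError("dt must be given or present in table metadata")
    if r_max is None:
        r_max = default_r_max(dt)
    if r_max <= 0:
        raise ValueError("r_max must be > 0")
    if memory < 0:
        raise ValueError("memory must be >= 0")
    locs = ensure_loc_ids(locs)
    if locs["loc_id"].duplicated().any():
        raise ValueError("duplicated loc_id in input")
    if "channel" not in locs.columns:
        locs = locs.assign(channel=1)
    rows = []
    next_tid = 0
    for _, sub in locs.groupby("channel", sort=True):
        r, next_tid = _link_one_channel(sub, r_max, memory, next_tid)
        rows.extend(r)
    table = pd.DataFrame(rows, columns=TRACK_COLUMNS)
    table = table.sort_values(["track_id", "frame"], kind="stable").reset_index(drop=True)
    meta = dict(locs.attrs.get("metadata", {}))
    meta.update({"r_max": r_max, "memory": memory, "dt": dt, "linker": "hungarian"})
    return TrackSet(table=table, dt=dt, metadata=meta)


def track_D_lag1(track: pd.DataFrame, dt: float) -> float:
    """Lag-1 MSD diffusion estimate D1 = <step^2> / (4 dt), no intercept.

    Used for the immobile-track filter. Biased upward by sigma_loc^2/dt, which
    only makes the immobility threshold more permissive. If a gappy track has
    no adjacent-frame pairs, the smallest available lag n is used with
    MSD(n)/(4 n dt).
    """
    f = track["frame"].to_numpy()
    xy = track[["x", "y"]].to_numpy()
    order = np.argsort(f)
    f, xy = f[order], xy[order]
    if len(f) < 2:
        return 0.0
    df_ = np.diff(f)
    d2 = (np.diff(xy, axis=0) ** 2).sum(axis=1)
    adj = df_ == 1
    if adj.any():
        return float(d2[adj].mean() / (4.0 * dt))
    n = int(df_.min())
    sel = df_ == n
    return float(d2[sel].mean() / (4.0 * n * dt))


def filter_tracks(ts: TrackSet, min_frames: int = 10,
                  min_D: float = 0.01) -> TrackSet:
    """Reject tracks with fewer than `min_frames` localizations or a lag-1
    diffusion coefficient below `min_D` (immobile molecules).

    Defaults (10 frames, 0.01 um^2/s) follow standard membrane-SPT practice.
    Removal counts per criterion are recorded in the output metadata.
    """
    tab = ts.table
    if len(tab) == 0:
        meta = dict(ts.metadata)
        meta.update({"min_frames": min_frames, "min_D": min_D,
                     "n_removed_short": 0, "n_removed_slow": 0})
        return TrackSet(table=tab.copy(), dt=ts.dt, metadata=meta)
    g = tab.groupby("track_id")
    n_locs = g["frame"].size()
    d1 = g[["frame", "x", "y"]].apply(lambda t: track_D_lag1(t, ts.dt))
    short = n_locs < min_frames
    slow = d1 < min_D
    keep = ~(short | slow)
    kept_ids = n_locs.index[keep]
    out = tab[tab["track_id"].isin(set(kept_ids))].reset_index(drop=True)
    meta = dict(ts.metadata)
    meta.update({
        "min_frames": min_frames,
        "min_D": min_D,
        "n_removed_short": int(short.sum()),
        "n_removed_slow": int((slow & ~short).sum()),
    })
    return TrackSet(table=out, dt=ts.dt, metadata=meta)


@dataclass
class SurvivalCurve:
    """Track survival statistics.

    thresholds_s / survival : fraction of tracks with duration >= T
                              (non-increasing, starts at 1).
    frames / alive / alive_normalized : per-frame number of concurrently
                              alive tracks, normalized to the first frame.
    tau_half : duration at which the survival fraction crosses 0.5, by linear
               interpolation of the mid-jump empirical survival function.
    censored : True when the crossing sits at the maximum (movie-limited)
               duration.
    """

    thresholds_s: np.ndarray
    survival: np.ndarray
    frames: np.ndarray
    alive: np.ndarray
    alive_normalized: np.ndarray
    tau_half: float
    censored: bool
    n_tracks: int


def track_survival(ts: TrackSet, normalize: bool = True) -> SurvivalCurve:
    """Duration-threshold survival curve and per-frame alive counts."""
    if ts.n_tracks == 0:
        raise ValueError("track_survival requires at least one track")
    dur = ts.durations_frames().to_numpy() * ts.dt
    n = len(dur)
    thresholds = np.unique(dur)
    ge = np.array([(dur >= t).sum() for t in thresholds], dtype=float)
    gt = np.array([(dur > t).sum() for t in thresholds], dtype=float)
    survival = ge / n
    s_mid = (ge + gt) / (2.0 * n)  # mid-jump convention for the 0.5 crossing
    if s_mid[-1] >= 0.5:
        tau_half = float(thresholds[-1])
        censored = True
    else:
        tau_half = float(np.interp(0.5, s_mid[::-1], thresholds[::-1]))
        censored = tau_half >= thresholds[-1]
    g = ts.table.groupby("track_id")["frame"]
    first = g.min().to_numpy()
    last = g.max().to_numpy()
    fmin, fmax = int(first.min()), int(last.max())
    frames = np.arange(fmin, fmax + 1)
    alive = np.array([((first <= f) & (last >= f)).sum() for f in frames],
                     dtype=float)
    alive_norm = alive / alive[0] if normalize and alive[0] > 0 else alive.copy()
    return SurvivalCurve(thresholds_s=thresholds, survival=survival,
                         frames=frames, alive=alive,
                         alive_normalized=alive_norm, tau_half=tau_half,
                         censored=censored, n_tracks=n)
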