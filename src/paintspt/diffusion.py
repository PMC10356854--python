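"""Mean-squared-displacement analysis and diffusion-coefficient estimation.

The time-averaged MSD of a 2D Brownian track with static localization noise is

    MSD(tau) = 4 D tau + 4 sigma_loc^2,

so the ensemble estimator fits a weighted line over the first few lags with a
free intercept (the noise offset), while the quick per-track estimator used
for immobility filtering is the lag-1 value without intercept (biased upward
by sigma_loc^2 / dt; see linking.track_D_lag1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .linking import TrackSet

__all__ = [
    "MsdCurve",
    "DiffusionEstimate",
    "PopulationComparison",
    "msd",
    "ensemble_msd",
    "estimate_D",
    "per_track_diffusion",
    "compare_populations",
]


@dataclass
class MsdCurve:
    lags_s: np.ndarray    # lag times (s), starting at dt
    values: np.ndarray    # time-averaged MSD (um^2)
    counts: np.ndarray    # displacement pairs per lag


@dataclass
class DiffusionEstimate:
    D: float                 # um^2/s
    intercept: float         # um^2, approx 4 sigma_loc^2
    D_se: Optional[float]
    lags: tuple
    n_tracks: int
    negative_intercept: bool

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"DiffusionEstimate(D={self.D:.4g} um^2/s, "
                f"intercept={self.intercept:.4g} um^2, n={self.n_tracks})")


def _msd_arrays(frames: np.ndarray, xy: np.ndarray, max_lag: int):
    """Per-lag (sum of squared displacements, count), skipping gap frames."""
    order = np.argsort(frames)
    frames = frames[order]
    xy = xy[order]
    sums = np.zeros(max_lag)
    counts = np.zeros(max_lag, dtype=int)
    pos = {int(f): i for i, f in enumerate(frames)}
    for lag in range(1, max_lag + 1):
        i_from, i_to = [], []
        for f, i in pos.items():
            j = pos.get(f + lag)
            if j is not None:
                i_from.append(i)
                i_to.append(j)
        if i_from:
            d = xy[np.array(i_to)] - xy[np.array(i_from)]
            sums[lag - 1] = (d ** 2).sum()
            counts[lag - 1] = len(i_from)
    return sums, counts


def msd(track: pd.DataFrame, max_lag: int, dt: float) -> MsdCurve:
    """Time-averaged MSD of one track over lags 1..max_lag frames.

    `track` needs columns (frame, x, y); gap frames are skipped (pairs are
    formed only between frames that are both present).
    """
    if max_lag < 1:
        raise ValueError("max_lag must be >= 1")
    if len(track) < max_lag + 1:
        raise ValueError(
            f"track has {len(track)} localizations; max_lag={max_lag} "
            f"requires at least {max_lag + 1}")
    frames = track["frame"].to_numpy()
    xy = track[["x", "y"]].to_numpy(dtype=float)
    sums, counts = _msd_arrays(frames, xy, max_lag)
    values = np.divide(sums, counts, out=np.zeros(max_lag), where=counts > 0)
    return MsdCurve(lags_s=np.arange(1, max_lag + 1) * dt, values=values,
                    counts=counts)


def ensemble_msd(ts: TrackSet, max_lag: int) -> MsdCurve:
    """Ensemble (count-weighted) time-averaged MSD over all tracks."""
    sums = np.zeros(max_lag)
    counts = np.zeros(max_lag, dtype=int)
    for _, t in ts.table.groupby("track_id"):
        s, c = _msd_arrays(t["frame"].to_numpy(),
                           t[["x", "y"]].to_numpy(dtype=float), max_lag)
        sums += s
        counts += c
    values = np.divide(sums, counts, out=np.zeros(max_lag), where=counts > 0)
    return MsdCurve(lags_s=np.arange(1, max_lag + 1) * ts.dt, values=values,
                    counts=counts)


def _fit_line(tau: np.ndarray, y: np.ndarray, w: np.ndarray,
              with_intercept: bool):
    """Weighted LS fit y = 4 D tau (+ b); returns (D, b, D_se)."""
    sw = np.sqrt(w)
    if with_intercept:
        A = np.stack([4.0 * tau, np.ones_like(tau)], axis=1)
    else:
        A = (4.0 * tau)[:, None]
    Aw = A * sw[:, None]
    yw = y * sw
    coef, res, _, _ = np.linalg.lstsq(Aw, yw, rcond=None)
    D = float(coef[0])
    b = float(coef[1]) if with_intercept else 0.0
    D_se = None
    dof = len(tau) - A.shape[1]
    if dof > 0:
        resid = yw - Aw @ coef
        s2 = float(resid @ resid) / dof
        cov = s2 * np.linalg.inv(Aw.T @ Aw)
        D_se = float(np.sqrt(cov[0, 0]))
    return D, b, D_se


def estimate_D(ts: TrackSet, lags: Sequence[int] = (1, 2, 3, 4),
               with_intercept: bool = True) -> DiffusionEstimate:
    """Ensemble diffusion coefficient from a weighted linear fit of the
    ensemble MSD over the given lags, MSD(tau) = 4 D tau + b.

    Weights are the number of displacement pairs per lag. The intercept b
    absorbs the localization-noise offset (approx 4 sigma_loc^2); a negative
    intercept is possible within noise and is flagged.
    """
    lags = tuple(sorted(set(int(l) for l in lags)))
    if len(lags) < 2 and with_intercept:
        raise ValueError("need at least 2 lags to fit slope and intercept")
    curve = ensemble_msd(ts, max_lag=max(lags))
    sel = np.array(lags) - 1
    usable = curve.counts[sel] > 0
    if usable.sum() < (2 if with_intercept else 1):
        raise ValueError("fewer than 2 usable lags in the ensemble MSD")
    tau = curve.lags_s[sel][usable]
    y = curve.values[sel][usable]
    w = curve.counts[sel][usable].astype(float)
    D, b, D_se = _fit_line(tau, y, w, with_intercept)
    return DiffusionEstimate(D=D, intercept=b, D_se=D_se, lags=lags,
                             n_tracks=ts.n_tracks,
                             negative_intercept=b < 0)


def per_track_diffusion(ts: TrackSet, lags: Sequence[int] = (1, 2, 3, 4),
                        with_intercept: bool = True) -> pd.DataFrame:
    """Per-track D from a weighted MSD line fit (free intercept by default).

    Tracks too short for the requested lags fall back to the largest feasible
    lag range; tracks with fewer than 2 usable lags get the lag-1 estimate
    without intercept (column `method` records which was used).
    Returns a DataFrame (track_id, D, n_locs, n_frames, method).
    """
    lags = tuple(sorted(set(int(l) for l in lags)))
    rows = []
    for tid, t in ts.table.groupby("track_id"):
        frames = t["frame"].to_numpy()
        xy = t[["x", "y"]].to_numpy(dtype=float)
        max_lag = max(lags)
        sums, counts = _msd_arrays(frames, xy, max_lag)
        sel = np.array(lags) - 1
        usable = counts[sel] > 1
        n_frames = int(frames.max() - frames.min() + 1)
        if usable.sum() >= 2 and with_intercept:
            tau = (np.array(lags) * ts.dt)[usable]
            y = (sums[sel] / counts[sel])[usable]
            w = counts[sel][usable].astype(float)
            D, _, _ = _fit_line(tau, y, w, True)
            method = "msd_fit"
        elif counts[0] > 0:
            D = float(sums[0] / counts[0] / (4.0 * ts.dt))
            method = "lag1"
        else:
            continue
        rows.append((tid, D, len(t), n_frames, method))
    return pd.DataFrame(rows, columns=["track_id", "D", "n_locs", "n_frames",
                                       "method"])


@dataclass
class PopulationComparison:
    slowdown_pct: float
    ci_low: float
    ci_high: float
    median_reference: float
    median_other: float
    n_reference: int
    n_other: int


def compare_populations(D_monomers, D_dimers, n_boot: int = 2000,
                        seed: int = 0, ci: float = 0.95) -> PopulationComparison:
    """Mobility slowdown of one population relative to another.

    slowdown = 100 * (1 - median(D_dimers) / median(D_monomers)), with a
    bootstrap percentile confidence interval (seeded). Medians are used for
    robustness, matching the usual box-plot presentation of per-track D.
    """
    dm = np.asarray(D_monomers, dtype=float)
    dd = np.asarray(D_dimers, dtype=float)
    if dm.size == 0 or dd.size == 0:
        raise ValueError("both populations must be non-empty")
    m_ref = float(np.median(dm))
    if m_ref <= 0:
        raise ValueError("median monomer D must be > 0")
    m_oth = float(np.median(dd))
    slow = 100.0 * (1.0 - m_oth / m_ref)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        bm = np.median(rng.choice(dm, size=dm.size, replace=True))
        bd = np.median(rng.choice(dd, size=dd.size, replace=True))
        boots[i] = 100.0 * (1.0 - bd / bm) if bm > 0 else np.nan
    alpha = (1.0 - ci) / 2.0
    lo, hi = np.nanpercentile(boots, [100 * alpha, 100 * (1 - alpha)])
    return PopulationComparison(slowdown_pct=slow, ci_low=float(lo),
                                ci_high=float(hi), median_reference=m_ref,
                                median_other=m_oth, n_reference=dm.size,
                                n_other=dd.size)
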