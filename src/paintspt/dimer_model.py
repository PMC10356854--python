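"""Ligand-induced homodimerization equilibrium and titration fitting.

Membrane-anchored monomers M bind a bivalent ligand B from solution
(dissociation constant K_B, molar units) and a ligand-bound monomer MB
crosslinks a free monomer into a dimer D (2D dissociation constant K_X,
um^-2):

    M + B <-> MB        K_B = m * L / mb      (L: bulk ligand, undepleted)
    MB + M <-> D        K_X = mb * m / d

With total labeled density rho_tot (um^-2) and mass conservation
m + mb + 2 d = rho_tot, the free-monomer density m solves

    a m^2 + (1 + L/K_B) m - rho_tot = 0,      a = 2 (L/K_B) / K_X,

and the fraction of monomer units in dimers is f = 2 d / rho_tot with
d = m^2 (L/K_B) / K_X. The titration curve f(L) is bell-shaped ("hook"
effect): at high L every monomer carries its own ligand and crosslinking
partners vanish. In the weak-crosslinking limit (rho_tot / K_X << 1) the
peak sits at L = K_B and f is symmetric in log L about it.

With equimolar two-color labeling only hetero-color dimers are observable,
so the detected fraction is beta * f with beta = 0.5 by default.

K_X is defined exactly as above (crosslinking of MB with M); no statistical
symmetry factor is inserted, so fitted constants are convention-explicit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares, minimize_scalar

__all__ = [
    "DimerModelParams",
    "equilibrium_fraction",
    "detected_fraction",
    "mass_balance_residual",
    "peak_ligand",
    "DimerTitrationModel",
    "TitrationFitResults",
]


@dataclass
class DimerModelParams:
    """Equilibrium parameters: K_B (M), K_X (um^-2), total labeled monomer
    density rho_tot (um^-2) and the dual-color detection factor beta."""

    K_B: float
    K_X: float
    rho_tot: float = 0.1
    beta: float = 0.5

    def validate(self) -> None:
        if not (np.isfinite(self.K_B) and self.K_B > 0):
            raise ValueError("K_B must be finite and > 0")
        if not (np.isfinite(self.K_X) and self.K_X > 0):
            raise ValueError("K_X must be finite and > 0")
        if not (np.isfinite(self.rho_tot) and self.rho_tot > 0):
            raise ValueError("rho_tot must be finite and > 0")
        if not (0.0 < self.beta <= 1.0):
            raise ValueError("beta must be in (0, 1]")


def _free_monomer(L: np.ndarray, p: DimerModelParams) -> np.ndarray:
    """Positive root of a m^2 + (1 + L/K_B) m - rho_tot = 0, numerically
    stable for a -> 0 (L -> 0)."""
    # clip the saturation ratio so extreme optimizer trials stay finite;
    # f(L) is already ~0 far before the clip bites
    lk = np.minimum(L / p.K_B, 1e100)
    a = 2.0 * lk / p.K_X
    c1 = 1.0 + lk
    # m = 2 rho / (c1 + sqrt(c1^2 + 4 a rho)) avoids cancellation at small a
    return 2.0 * p.rho_tot / (c1 + np.sqrt(c1 * c1 + 4.0 * a * p.rho_tot))


def equilibrium_fraction(L, p: DimerModelParams):
    """Fraction of monomer units in dimers at bulk ligand concentration L (M).

    Vectorized over L. Mass conservation m + m L/K_B + 2 d = rho_tot holds to
    ~1e-15 relative by construction (see `mass_balance_residual`).
    """
    p.validate()
    L_arr = np.asarray(L, dtype=float)
    if np.any(L_arr < 0) or not np.all(np.isfinite(L_arr)):
        raise ValueError("L must be finite and >= 0")
    m = _free_monomer(L_arr, p)
    d = m * m * np.minimum(L_arr / p.K_B, 1e100) / p.K_X
    f = 2.0 * d / p.rho_tot
    return float(f) if np.isscalar(L) else f


def mass_balance_residual(L, p: DimerModelParams):
    """Relative mass-balance residual |m + mb + 2d - rho_tot| / rho_tot."""
    L_arr = np.asarray(L, dtype=float)
    m = _free_monomer(L_arr, p)
    d = m * m * (L_arr / p.K_B) / p.K_X
    res = np.abs(m + m * L_arr / p.K_B + 2.0 * d - p.rho_tot) / p.rho_tot
    return float(res) if np.isscalar(L) else res


def detected_fraction(L, p: DimerModelParams):
    """Observable (hetero-color) dimer fraction: beta * equilibrium_fraction."""
    return p.beta * equilibrium_fraction(L, p)


def peak_ligand(p: DimerModelParams, n_grid: int = 601,
                half_decades: float = 6.0) -> float:
    """Ligand concentration maximizing the dimer fraction.

    Coarse search on a log grid centered on K_B, refined by bounded scalar
    minimization in log10 L. In the weak-crosslinking limit
    (rho_tot / K_X << 1) the maximum approaches L = K_B exactly.
    """
    p.validate()
    logs = np.log10(p.K_B) + np.linspace(-half_decades, half_decades, n_grid)
    f = equilibrium_fraction(10.0 ** logs, p)
    i = int(np.argmax(f))
    lo = logs[max(i - 1, 0)]
    hi = logs[min(i + 1, n_grid - 1)]
    res = minimize_scalar(lambda x: -equilibrium_fraction(10.0 ** x, p),
                          bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-10})
    return float(10.0 ** res.x)


# --------------------------------------------------------------------------
# titration fitting (Model / Results)
# --------------------------------------------------------------------------

class DimerTitrationModel:
    """Titration-curve model of detected dimer fraction vs ligand concentration.

    Parameters
    ----------
    ligand_M : ligand concentrations (M), length >= 4, spanning the peak.
    fraction : detected dimer fraction at each concentration.
    sd       : optional per-point standard deviations (weights 1/sd; points
               with sd == 0 or missing sd get unit weight).
    rho_tot  : total labeled density (um^-2), fixed from the measured track
               density rather than fitted (it trades off against K_X).
    beta     : dual-color detection factor, fixed at 0.5 for equimolar
               labeling (free amplitude available via beta=None is *not*
               supported in the fit; vary it externally for sensitivity).

    Examples
    --------
    >>> model = DimerTitrationModel(ligand, fraction, sd, rho_tot=0.1)
    >>> res = model.fit(seed=1)
    >>> res.params["K_B"], res.params["K_X"], res.rsquared
    """

    def __init__(self, ligand_M, fraction, sd=None, *, rho_tot: float = 0.1,
                 beta: float = 0.5):
        self.ligand = np.asarray(ligand_M, dtype=float)
        self.fraction = np.asarray(fraction, dtype=float)
        if self.ligand.shape != self.fraction.shape:
            raise ValueError("ligand and fraction must have the same length")
        if len(self.ligand) < 4:
            raise ValueError("need at least 4 titration points")
        if np.any(self.ligand < 0):
            raise ValueError("ligand concentrations must be >= 0")
        if np.any((self.fraction < 0) | (self.fraction > 1)):
            raise ValueError("fractions must lie in [0, 1]")
        self.sd = None if sd is None else np.asarray(sd, dtype=float)
        self.rho_tot = float(rho_tot)
        self.beta = float(beta)
        if self.sd is not None and np.all(self.sd > 0):
            self.weights = 1.0 / self.sd
        else:
            self.weights = np.ones_like(self.fraction)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, ligand_col: str = "ligand_M",
                       fraction_col: str = "fraction", sd_col: str = "sd",
                       **kwargs) -> "DimerTitrationModel":
        sd = df[sd_col].to_numpy() if sd_col in df.columns else None
        return cls(df[ligand_col].to_numpy(), df[fraction_col].to_numpy(),
                   sd, **kwargs)

    def _params(self, theta) -> DimerModelParams:
        return DimerModelParams(K_B=10.0 ** theta[0], K_X=10.0 ** theta[1],
                                rho_tot=self.rho_tot, beta=self.beta)

    def predict(self, theta=None, params: DimerModelParams = None,
                ligand=None) -> np.ndarray:
        if params is None:
            params = self._params(theta)
        L = self.ligand if ligand is None else np.asarray(ligand, dtype=float)
        return detected_fraction(L, params)

    def _residuals(self, theta) -> np.ndarray:
        return self.weights * (self.predict(theta) - self.fraction)

    def fit(self, n_starts: int = 10, seed: int = 0,
            kb_range=(1e-13, 1e-6), kx_range=(1e-5, 1e2)) -> "TitrationFitResults":
        """Weighted least squares in (log10 K_B, log10 K_X) with multistart.

        Starts are drawn log-uniformly from the given ranges (seeded), plus a
        heuristic start at the ligand concentration of the observed peak; the
        best converged fit is reported. Standard errors come from the local
        curvature (Gauss-Newton covariance), transformed to the linear scale.
        """
        if np.max(self.fraction) <= 0:
            raise ValueError("titration data are all zero: model is "
                             "non-identifiable (flagged)")
        rng = np.random.default_rng(seed)
        starts = [np.array([
            math.log10(max(self.ligand[int(np.argmax(self.fraction))], 1e-13)),
            math.log10(self.rho_tot),
        ])]
        lo = np.log10([kb_range[0], kx_range[0]])
        hi = np.log10([kb_range[1], kx_range[1]])
        for _ in range(max(n_starts - 1, 0)):
            starts.append(lo + rng.uniform(size=2) * (hi - lo))
        best = None
        n_converged = 0
        for x0 in starts:
            try:
                sol = least_squares(self._residuals, x0, method="lm",
                                    xtol=1e-15, ftol=1e-15, gtol=1e-15,
                                    max_nfev=5000)
            except Exception:
                continue
            if not np.all(np.isfinite(sol.x)):
                continue
            n_converged += 1
            if best is None or sol.cost < best.cost:
                best = sol
        if best is None:
            raise RuntimeError(
                f"no start converged out of {len(starts)} (data may not span "
                "the titration peak)")
        theta = best.x
        params = self._params(theta)
        fitted = self.predict(theta)
        resid = self.fraction - fitted
        # curvature-based SEs in log10 space, delta method to linear scale
        J = best.jac
        dof = max(len(self.fraction) - 2, 1)
        s2 = 2.0 * best.cost / dof
        try:
            cov_log = s2 * np.linalg.inv(J.T @ J)
            se_log = np.sqrt(np.diag(cov_log))
        except np.linalg.LinAlgError:
            se_log = np.full(2, np.nan)
        ln10 = math.log(10.0)
        bse = pd.Series({"K_B": params.K_B * ln10 * se_log[0],
                         "K_X": params.K_X * ln10 * se_log[1]})
        w2 = self.weights ** 2
        ybar = np.average(self.fraction, weights=w2)
        ss_tot = float(np.sum(w2 * (self.fraction - ybar) ** 2))
        ss_res = float(np.sum(w2 * resid ** 2))
        rsq = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
        return TitrationFitResults(
            model=self, params=pd.Series({"K_B": params.K_B, "K_X": params.K_X}),
            bse=bse, rsquared=rsq, residuals=resid, fittedvalues=fitted,
            n_starts=len(starts), n_converged=n_converged,
            cost=float(best.cost), theta=theta)


@dataclass
class TitrationFitResults:
    """Fit results: parameter estimates, their standard errors, R^2 and the
    multistart convergence record. `summary()` renders a text table."""

    model: DimerTitrationModel
    params: pd.Series
    bse: pd.Series
    rsquared: float
    residuals: np.ndarray
    fittedvalues: np.ndarray
    n_starts: int
    n_converged: int
    cost: float
    theta: np.ndarray

    def predict(self, ligand) -> np.ndarray:
        return self.model.predict(self.theta, ligand=ligand)

    @property
    def model_params(self) -> DimerModelParams:
        return self.model._params(self.theta)

    def summary(self) -> str:
        lines = [
            "Dimerization titration fit (weighted least squares, multistart)",
            "=" * 64,
            f"  observations: {len(self.model.ligand)}",
            f"  rho_tot (fixed): {self.model.rho_tot:g} um^-2"
            f"    beta (fixed): {self.model.beta:g}",
            f"  converged starts: {self.n_converged}/{self.n_starts}"
            f"    R^2 = {self.rsquared:.4f}",
            "-" * 64,
            f"  K_B = {self.params['K_B']:.4g} M"
            f"  (+/- {self.bse['K_B']:.2g})",
            f"  K_X = {self.params['K_X']:.4g} um^-2"
            f"  (+/- {self.bse['K_X']:.2g})",
            "=" * 64,
        ]
        return "\n".join(lines)
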