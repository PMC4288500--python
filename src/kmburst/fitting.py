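"""Concentration-response (Hill), voltage-activation (Boltzmann) and linear
conductance fits for whole-cell and single-channel K+ current data.

The three fits quantify drug action on M-type (Kv7) and BK channels:

* Hill: percentage increase of current vs drug concentration -> EC50, n_H.
* Boltzmann: relative conductance G/G_max vs step potential -> V_1/2 and the
  apparent gating charge q (steepness in units of elementary charge, using
  q*F/(R*T) as the exponential slope).
* Ordinary least squares on I-V points -> whole-cell chord conductance (nS)
  or single-channel conductance (pS).

`HillCurve` and `BoltzmannCurve` are scikit-learn style estimators; the
module-level `fit_*` functions are thin wrappers that return frozen result
records.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "FARADAY",
    "GAS_CONSTANT",
    "DEFAULT_TEMPERATURE",
    "HillFit",
    "BoltzmannFit",
    "LinearConductanceFit",
    "hill",
    "boltzmann",
    "eval_hill",
    "eval_boltzmann",
    "HillCurve",
    "BoltzmannCurve",
    "fit_hill",
    "fit_boltzmann",
    "conductance_slope",
    "single_channel_conductance",
]

FARADAY = 96485.33212  # C / mol
GAS_CONSTANT = 8.314462618  # J / (mol K)
#: recordings were made at room temperature; 295 K ~= 22 degC
DEFAULT_TEMPERATURE = 295.0


# ---------------------------------------------------------------------------
# result records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HillFit:
    """Hill concentration-response parameters.

    e_max : maximal response (% of the top-concentration effect)
    ec50  : half-maximal concentration (uM), > 0
    n_h   : Hill coefficient, > 0
    """

    e_max: float
    ec50: float
    n_h: float
    se: dict = field(default_factory=dict)
    converged: bool = True
    message: str = ""

    def __post_init__(self):
        if self.converged and not (self.ec50 > 0 and self.e_max > 0 and self.n_h > 0):
            raise ValueError("HillFit requires e_max, ec50, n_h > 0")


@dataclass(frozen=True)
class BoltzmannFit:
    """Boltzmann activation parameters: G/G_max = 1/(1+exp(-(V-V_1/2) q F / RT)).

    g_max in nS (or the unit of the fitted conductance data), v_half in mV,
    q in elementary charges, temperature in K.
    """

    g_max: float
    v_half: float
    q: float
    temperature: float = DEFAULT_TEMPERATURE
    se: dict = field(default_factory=dict)
    converged: bool = True
    message: str = ""

    def __post_init__(self):
        if self.converged and not (self.g_max > 0 and self.q > 0 and self.temperature > 0):
            raise ValueError("BoltzmannFit requires g_max, q, temperature > 0")


@dataclass(frozen=True)
class LinearConductanceFit:
    """OLS line through I-V points inside a voltage window; slope in nS."""

    slope_nS: float
    intercept_pA: float
    window: tuple
    se: dict = field(default_factory=dict)
    n_points: int = 0

    def __post_init__(self):
        lo, hi = self.window
        if not lo < hi:
            raise ValueError("voltage window must satisfy lower < upper")


# ---------------------------------------------------------------------------
# closed forms
# ---------------------------------------------------------------------------


def hill(conc, e_max: float, ec50: float, n_h: float, denominator: str = "standard"):
    """Hill response at concentration ``conc`` (same unit as ec50).

    ``denominator="standard"`` uses EC50**n_H + C**n_H (dimensionally
    consistent for any n_H).  ``"as_printed"`` reproduces the variant with a
    bare EC50 in the denominator, kept only for comparison.
    """
    c = np.asarray(conc, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentrations must be non-negative")
    if denominator == "standard":
        den = ec50 ** n_h + c ** n_h
    elif denominator == "as_printed":
        den = ec50 + c ** n_h
    else:
        raise ValueError(f"unknown denominator form {denominator!r}")
    with np.errstate(invalid="ignore"):
        out = e_max * c ** n_h / den
    return out if out.ndim else float(out)


def boltzmann(v_mV, v_half: float, q: float, temperature: float = DEFAULT_TEMPERATURE):
    """Open fraction 1/(1+exp(-(V-V_1/2) q F/(R T))); strictly increasing in V."""
    v = np.asarray(v_mV, dtype=float)
    kT_mV = 1e3 * GAS_CONSTANT * temperature / FARADAY  # RT/F in mV (~25.4 at 295 K)
    out = 1.0 / (1.0 + np.exp(-(v - v_half) * q / kT_mV))
    return out if out.ndim else float(out)


def eval_hill(fit: HillFit, conc, denominator: str = "standard"):
    return hill(conc, fit.e_max, fit.ec50, fit.n_h, denominator=denominator)


def eval_boltzmann(fit: BoltzmannFit, v_mV):
    """Relative conductance in (0, 1) at potential ``v_mV``."""
    return boltzmann(v_mV, fit.v_half, fit.q, fit.temperature)


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------


def _as_1d(X):
    X = np.asarray(X, dtype=float)
    if X.ndim == 2 and X.shape[1] == 1:
        X = X[:, 0]
    if X.ndim != 1:
        raise ValueError("expected a 1-d stimulus array (or an (n, 1) column)")
    return X


class HillCurve(RegressorMixin, BaseEstimator):
    """Least-squares Hill fit of response vs concentration.

    Parameters
    ----------
    denominator : "standard" or "as_printed" Hill denominator form.
    temperature-free; concentration unit is whatever the data carry (uM here).

    Fitted attributes: ``e_max_``, ``ec50_``, ``n_h_``, ``se_`` (dict of
    curvature-based standard errors), ``converged_``, ``message_``.
    Non-convergence and degenerate inputs are flagged, never silent.
    """

    def __init__(self, denominator: str = "standard", maxfev: int = 20000):
        self.denominator = denominator
        self.maxfev = maxfev

    def fit(self, X, y, init: Optional[HillFit] = None):
        c = _as_1d(X)
        y = np.asarray(y, dtype=float)
        if c.shape != y.shape:
            raise ValueError("X and y must have the same length")
        if np.any(c < 0):
            raise ValueError("concentrations must be non-negative")
        if np.unique(c[c > 0]).size < 4:
            raise ValueError("need >= 4 distinct positive concentrations")

        if init is not None:
            p0 = [init.e_max, init.ec50, init.n_h]
        else:
            e0 = float(np.nanmax(y))
            e0 = e0 if e0 > 0 else 1.0
            # start EC50 at the concentration whose mean response is nearest
            # half-maximal
            half = e0 / 2.0
            cs = np.unique(c[c > 0])
            means = np.array([y[c == ci].mean() for ci in cs])
            ec0 = float(cs[np.argmin(np.abs(means - half))])
            p0 = [e0, ec0, 1.0]

        self.n_features_in_ = 1
        if np.allclose(y, y[0]):
            self._flag("degenerate input: responses are constant", p0)
            return self
        f = lambda cc, e, ec, nh: hill(cc, e, ec, nh, denominator=self.denominator)
        try:
            popt, pcov = curve_fit(
                f, c, y, p0=p0,
                bounds=([1e-12, 1e-12, 1e-3], [np.inf, np.inf, 20.0]),
                maxfev=self.maxfev,
            )
        except (RuntimeError, ValueError) as err:
            self._flag(f"optimizer failed: {err}", p0)
            return self
        perr = np.sqrt(np.diag(pcov))
        self.e_max_, self.ec50_, self.n_h_ = map(float, popt)
        self.se_ = {"e_max": float(perr[0]), "ec50": float(perr[1]), "n_h": float(perr[2])}
        self.converged_ = bool(np.all(np.isfinite(popt)))
        self.message_ = "" if self.converged_ else "non-finite parameter estimate"
        return self

    def _flag(self, msg, p0):
        self.e_max_, self.ec50_, self.n_h_ = map(float, p0)
        self.se_ = {"e_max": np.inf, "ec50": np.inf, "n_h": np.inf}
        self.converged_ = False
        self.message_ = msg

    def predict(self, X):
        return hill(_as_1d(X), self.e_max_, self.ec50_, self.n_h_, denominator=self.denominator)

    def result_(self) -> HillFit:
        return HillFit(self.e_max_, self.ec50_, self.n_h_, se=self.se_,
                       converged=self.converged_, message=self.message_)


class BoltzmannCurve(RegressorMixin, BaseEstimator):
    """Least-squares fit of G(V) = G_max / (1 + exp(-(V-V_1/2) q F/(R T))).

    Fitted attributes: ``g_max_``, ``v_half_``, ``q_``, ``se_``,
    ``converged_``, ``message_``.
    """

    def __init__(self, temperature: float = DEFAULT_TEMPERATURE, maxfev: int = 20000):
        self.temperature = temperature
        self.maxfev = maxfev

    def fit(self, X, y):
        v = _as_1d(X)
        g = np.asarray(y, dtype=float)
        if v.shape != g.shape:
            raise ValueError("X and y must have the same length")
        if np.unique(v).size < 4:
            raise ValueError("need >= 4 distinct potentials spanning the inflection")

        g_hi = float(np.max(g))
        self.n_features_in_ = 1
        if np.allclose(g, g[0]):
            self._flag("degenerate input: conductances are constant", [max(g_hi, 1.0), float(np.median(v)), 2.0])
            return self
        # V_half starts at the voltage of half-range conductance; q starts at 2
        half = float(np.min(g)) + 0.5 * (g_hi - float(np.min(g)))
        order = np.argsort(v)
        v_half0 = float(np.interp(half, g[order], v[order]))
        p0 = [g_hi if g_hi > 0 else 1.0, v_half0, 2.0]

        f = lambda vv, gm, vh, qq: gm * boltzmann(vv, vh, qq, self.temperature)
        try:
            popt, pcov = curve_fit(
                f, v, g, p0=p0,
                bounds=([1e-12, -500.0, 1e-3], [np.inf, 500.0, 50.0]),
                maxfev=self.maxfev,
            )
        except (RuntimeError, ValueError) as err:
            self._flag(f"optimizer failed: {err}", p0)
            return self
        perr = np.sqrt(np.diag(pcov))
        self.g_max_, self.v_half_, self.q_ = map(float, popt)
        self.se_ = {"g_max": float(perr[0]), "v_half": float(perr[1]), "q": float(perr[2])}
        self.converged_ = bool(np.all(np.isfinite(popt)))
        self.message_ = "" if self.converged_ else "non-finite parameter estimate"
        return self

    def _flag(self, msg, p0):
        self.g_max_, self.v_half_, self.q_ = map(float, p0)
        self.se_ = {"g_max": np.inf, "v_half": np.inf, "q": np.inf}
        self.converged_ = False
        self.message_ = msg

    def predict(self, X):
        return self.g_max_ * boltzmann(_as_1d(X), self.v_half_, self.q_, self.temperature)

    def result_(self) -> BoltzmannFit:
        return BoltzmannFit(self.g_max_, self.v_half_, self.q_, temperature=self.temperature,
                            se=self.se_, converged=self.converged_, message=self.message_)


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------


def fit_hill(table, init: Optional[HillFit] = None, denominator: str = "standard") -> HillFit:
    """Fit a Hill curve to a dose-response table.

    ``table`` is a DataFrame with columns ``conc_uM`` and ``response_pct``
    (one row per cell and concentration), or a (conc, response) pair of
    arrays.
    """
    if isinstance(table, pd.DataFrame):
        c, y = table["conc_uM"].to_numpy(float), table["response_pct"].to_numpy(float)
    else:
        c, y = map(np.asarray, table)
    est = HillCurve(denominator=denominator).fit(c, y, init=init)
    return est.result_()


def activation_curve(sweepset, v_k: float = -91.0, tail_fraction: float = 0.1):
    """Chord-conductance activation data from voltage-step sweeps.

    End-of-pulse currents are converted to conductance G = I_end/(V - V_K)
    and averaged over cells; returns an (n_steps, 2) array of
    (step_mV, mean conductance nS) ready for :func:`fit_boltzmann`.
    """
    end = sweepset.end_of_pulse(tail_fraction)
    end = end[end["step_mV"] != v_k].copy()
    end["g_nS"] = end["i_end_pA"] / (end["step_mV"] - v_k)
    mean = end.groupby("step_mV", as_index=False)["g_nS"].mean()
    return mean.to_numpy(float)


def fit_boltzmann(gv_points, temperature: float = DEFAULT_TEMPERATURE) -> BoltzmannFit:
    """Fit a Boltzmann activation curve to (V_mV, conductance) points."""
    pts = np.asarray(gv_points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("gv_points must be an (n, 2) array of (mV, conductance)")
    est = BoltzmannCurve(temperature=temperature).fit(pts[:, 0], pts[:, 1])
    return est.result_()


def conductance_slope(iv_points, window: Sequence[float] = (-30.0, -10.0)) -> LinearConductanceFit:
    """Whole-cell chord conductance: OLS slope of I (pA) vs V (mV) inside
    the closed ``window``; pA/mV == nS."""
    pts = np.asarray(iv_points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("iv_points must be an (n, 2) array of (mV, pA)")
    lo, hi = float(window[0]), float(window[1])
    if not lo < hi:
        raise ValueError("voltage window must satisfy lower < upper")
    mask = (pts[:, 0] >= lo) & (pts[:, 0] <= hi)
    v, i = pts[mask, 0], pts[mask, 1]
    if np.unique(v).size < 2:
        raise ValueError("need >= 2 distinct potentials inside the window")
    coef = np.polyfit(v, i, 1)
    slope, intercept = float(coef[0]), float(coef[1])
    se = {}
    if v.size > 2:
        resid = i - (slope * v + intercept)
        s2 = float(resid @ resid) / (v.size - 2)
        sxx = float(np.sum((v - v.mean()) ** 2))
        se = {"slope": float(np.sqrt(s2 / sxx))}
    return LinearConductanceFit(slope, intercept, (lo, hi), se=se, n_points=int(v.size))


def single_channel_conductance(amp_table, reversal: Optional[float] = None) -> float:
    """Single-channel conductance (pS) by linear regression of mean unitary
    current amplitudes (pA) on holding potential (mV).

    If ``reversal`` is given the line is constrained through (reversal, 0);
    otherwise both slope and intercept are fitted.
    """
    pts = np.asarray(amp_table, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("amp_table must be an (n, 2) array of (mV, pA)")
    v, i = pts[:, 0], pts[:, 1]
    if np.unique(v).size < 2:
        raise ValueError("need >= 2 distinct potentials")
    if reversal is None:
        slope = float(np.polyfit(v, i, 1)[0])
    else:
        dv = v - float(reversal)
        slope = float((dv @ i) / (dv @ dv))
    return slope * 1e3  # pA/mV = nS -> pS
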