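"""Fast-slow decomposition of the burst model.

The burst cycle is governed by two slow gates: ``n`` (T-type Ca2+
activation, depolarizing, autocatalytic) and ``o`` (K_Ca activation,
hyperpolarizing feedback).  Treating (n, o) as frozen parameters leaves a
fast spiking subsystem (V with the Na+/K+ spike gates); its resting
equilibrium disappears through a saddle-node bifurcation as n grows or o
shrinks.  The locus of that fold in the (n, o) plane is the "voltage
nullcline" boundary: frozen points with n above the fold value spike
repetitively, points below sit at a stable rest.  Raising g_M or g_KCa
moves the boundary toward larger n (upward), shrinking the spiking region,
while the projected burst trajectory loops across the boundary once per
burst.

Conventions: the fold is computed as n(o) on an ``o`` grid (single-valued
in n per o); the Ca2+ pool and the AHP gate are frozen at the burst-cycle
average when evaluating the fast subsystem; the M gate is slaved to its
voltage steady state.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from .model import ModelParams, Modulation, SimTrace
from .model import engine
from .model.kinetics import KINETICS

__all__ = [
    "NullclineCurve",
    "TrajectoryLoop",
    "fast_subsystem_equilibria",
    "fast_subsystem_spiking",
    "compute_nullcline",
    "project_trajectory",
    "nullcline_shift",
    "cycle_average_ca",
]

logger = logging.getLogger(__name__)

#: equilibria below this potential count as the resting (silent) state
V_REST_CUT = -50.0
DEFAULT_CA_UM = 0.3


@dataclass
class NullclineCurve:
    """Saddle-node boundary samples (n, o) with n single-valued per o."""

    n: np.ndarray
    o: np.ndarray
    params_id: str = ""
    ca_um: float = DEFAULT_CA_UM

    def __post_init__(self):
        self.n = np.asarray(self.n, dtype=float)
        self.o = np.asarray(self.o, dtype=float)
        if self.n.shape != self.o.shape:
            raise ValueError("n and o must have the same shape")
        if self.n.size and (self.n.min() < 0 or self.n.max() > 1
                            or self.o.min() < 0 or self.o.max() > 1):
            raise ValueError("nullcline samples must lie in [0, 1]^2")


@dataclass
class TrajectoryLoop:
    """One steady burst cycle projected onto the (n, o) plane."""

    n: np.ndarray
    o: np.ndarray
    enclosed_area: float
    degenerate: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.enclosed_area < 0:
            raise ValueError("area must be >= 0")


def _pk(params: ModelParams, modulation: Optional[Modulation]):
    return params.to_vector(modulation or Modulation()), KINETICS


def fast_subsystem_equilibria(params: ModelParams, n: float, o: float,
                              ca_um: float = DEFAULT_CA_UM,
                              modulation: Optional[Modulation] = None,
                              v_range: Tuple[float, float] = (-120.0, 60.0),
                              scan_step_mv: float = 0.25,
                              tol_mv: float = 1e-6) -> List[Tuple[float, bool]]:
    """Equilibria of the fast subsystem at frozen (n, o).

    Roots of the quasi-steady current balance F(V; n, o) are located by
    sign-change bracketing on a ``scan_step_mv`` grid followed by bisection
    to ``tol_mv``; stability is the sign of dF/dV (F > 0 depolarizes, so
    dF/dV < 0 is stable).  An empty list is a valid return.
    """
    if not (0.0 <= n <= 1.0 and 0.0 <= o <= 1.0):
        raise ValueError("n and o must lie in [0, 1]")
    p, kin = _pk(params, modulation)
    vs = np.arange(v_range[0], v_range[1] + scan_step_mv / 2, scan_step_mv)
    fv = np.array([engine.f_steady(v, n, o, ca_um, p, kin) for v in vs])
    out: List[Tuple[float, bool]] = []
    exact = np.flatnonzero(fv == 0.0)
    for i in exact:
        v_star = float(vs[i])
        eps = 1e-3
        dfdv = (engine.f_steady(v_star + eps, n, o, ca_um, p, kin)
                - engine.f_steady(v_star - eps, n, o, ca_um, p, kin)) / (2 * eps)
        out.append((v_star, bool(dfdv < 0)))
    for i in np.flatnonzero(np.sign(fv[:-1]) * np.sign(fv[1:]) < 0):
        lo, hi = vs[i], vs[i + 1]
        flo = fv[i]
        while hi - lo > tol_mv:
            mid = 0.5 * (lo + hi)
            fmid = engine.f_steady(mid, n, o, ca_um, p, kin)
            if flo * fmid <= 0:
                hi = mid
            else:
                lo, flo = mid, fmid
        v_star = 0.5 * (lo + hi)
        eps = 1e-3
        dfdv = (engine.f_steady(v_star + eps, n, o, ca_um, p, kin)
                - engine.f_steady(v_star - eps, n, o, ca_um, p, kin)) / (2 * eps)
        out.append((float(v_star), bool(dfdv < 0)))
    return out


def _has_rest(params_vec, kin, n, o, ca_um) -> bool:
    vs = np.arange(-120.0, V_REST_CUT + 0.125, 0.25)
    fv = np.array([engine.f_steady(v, n, o, ca_um, params_vec, kin) for v in vs])
    # a stable sub-threshold root has F passing + -> -
    return bool(np.any((fv[:-1] > 0) & (fv[1:] < 0)))


def fast_subsystem_spiking(params: ModelParams, n: float, o: float,
                           ca_um: float = DEFAULT_CA_UM,
                           modulation: Optional[Modulation] = None,
                           duration_ms: float = 1000.0, dt_ms: float = 0.002,
                           v0: float = -70.0) -> bool:
    """Simulate the fast subsystem at frozen (n, o); True if it fires
    repetitively (>= 3 upward 0 mV crossings in the second half)."""
    p, kin = _pk(params, modulation)
    n_steps = int(round(duration_ms / dt_ms))
    _, v_rec, _ = engine.integrate_fast(v0, n, o, ca_um, p, kin, dt_ms,
                                        n_steps, max(int(0.05 / dt_ms), 1))
    half = v_rec[v_rec.size // 2:]
    crossings = np.count_nonzero((half[:-1] < 0.0) & (half[1:] >= 0.0))
    return crossings >= 3


def compute_nullcline(params: ModelParams,
                      o_grid: Optional[np.ndarray] = None,
                      ca_um: float = DEFAULT_CA_UM,
                      modulation: Optional[Modulation] = None,
                      n_max: float = 1.0,
                      tol: float = 1e-6) -> NullclineCurve:
    """Saddle-node boundary n(o): for each o, the n at which the resting
    equilibrium of the fast subsystem disappears.

    Found by bisection on n with the (stable sub-threshold) equilibria
    count as the indicator; grid points where no fold exists within
    [0, n_max] are omitted and logged.
    """
    if o_grid is None:
        o_grid = np.linspace(0.0, 1.0, 41)
    o_grid = np.asarray(o_grid, dtype=float)
    if o_grid.size < 2:
        raise ValueError("o_grid needs >= 2 points")
    p, kin = _pk(params, modulation)

    ns, os_ = [], []
    for o in o_grid:
        lo, hi = 0.0, float(n_max)
        if not _has_rest(p, kin, lo, o, ca_um):
            logger.info("no resting state even at n = 0 for o = %.3f; point omitted", o)
            continue
        if _has_rest(p, kin, hi, o, ca_um):
            logger.info("rest persists up to n = %g for o = %.3f; no fold found", n_max, o)
            continue
        while hi - lo > tol:
            mid = 0.5 * (lo + hi)
            if _has_rest(p, kin, mid, o, ca_um):
                lo = mid
            else:
                hi = mid
        ns.append(0.5 * (lo + hi))
        os_.append(float(o))
    return NullclineCurve(np.array(ns), np.array(os_),
                          params_id=f"gM={p[7]:g},gKCa={p[8]:g}", ca_um=ca_um)


def cycle_average_ca(trace: SimTrace, transient_ms: float = 1000.0) -> float:
    """Mean Ca_i over the post-transient part of a simulated trace (uM)."""
    mask = trace.t_ms >= transient_ms
    if not mask.any():
        raise ValueError("transient longer than the trace")
    return float(trace.ca[mask].mean())


def project_trajectory(trace: SimTrace, transient_ms: float = 1000.0,
                       min_cycle_ms: float = 200.0) -> TrajectoryLoop:
    """Extract one steady burst cycle as a closed loop in the (n, o) plane.

    The cycle is delimited by successive minima of the slow feedback gate
    ``o``; the enclosed area is computed with the shoelace formula.  A
    trace that has settled to a fixed point degenerates to a single point
    with area 0 (flagged).
    """
    mask = trace.t_ms >= transient_ms
    if not mask.any():
        raise ValueError("transient longer than the trace")
    n_t = trace.gates["n"][mask]
    o_t = trace.gates["o"][mask]
    dt = trace.dt_record_ms

    if np.ptp(o_t) < 1e-5:
        return TrajectoryLoop(np.array([n_t[-1]]), np.array([o_t[-1]]), 0.0,
                              degenerate=True, meta={"reason": "fixed point"})

    from scipy.signal import find_peaks
    dist = max(int(min_cycle_ms / dt), 1)
    minima, _ = find_peaks(-o_t, distance=dist, prominence=0.1 * np.ptp(o_t))
    if minima.size < 2:
        return TrajectoryLoop(np.array([n_t[-1]]), np.array([o_t[-1]]), 0.0,
                              degenerate=True,
                              meta={"reason": "no periodic cycle detected"})
    i0, i1 = minima[-2], minima[-1]
    n_loop = n_t[i0:i1 + 1]
    o_loop = o_t[i0:i1 + 1]
    area = _shoelace(n_loop, o_loop)
    return TrajectoryLoop(n_loop, o_loop, area,
                          meta={"cycle_ms": (i1 - i0) * dt})


def _shoelace(x: np.ndarray, y: np.ndarray) -> float:
    x1, y1 = np.roll(x, -1), np.roll(y, -1)
    return float(0.5 * abs(np.sum(x * y1 - x1 * y)))


def nullcline_shift(a: NullclineCurve, b: NullclineCurve) -> float:
    """Mean shift of the fold curve from ``a`` to ``b`` along n, over the
    shared o range (positive = upward = toward the spiking side)."""
    lo = max(a.o.min(), b.o.min())
    hi = min(a.o.max(), b.o.max())
    if lo > hi:
        raise ValueError("nullclines have disjoint o ranges")
    grid = a.o[(a.o >= lo) & (a.o <= hi)]
    na = np.interp(grid, a.o, a.n)
    nb = np.interp(grid, b.o, b.n)
    return float(np.mean(nb - na))
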