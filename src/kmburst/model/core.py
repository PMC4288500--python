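"""Public API of the burst model: parameters, simulation, current read-out.

Units form one coherent per-area system: Cm = 1 uF/cm2, conductances in
mS/cm2 (the default magnitudes follow the modeled neuron's published
parameter table read in this unit), currents in uA/cm2, voltages in mV,
time in ms, intracellular Ca2+ in uM.  The applied current default is
0.004 uA/cm2 — at the sub-threshold conductance scale of this parameter
set (~0.02-0.06 mS/cm2) a milliampere-scale current density could not be
balanced by any of the K+ currents, so the printed magnitude is read in
uA/cm2 (see docs/methods.md).

The M-current is included in the summed K+ currents: the model
parameterizes g_M and reports its time course, so the voltage equation
sums I_Na, I_CaT, I_CaL, I_CaN, I_KDR, I_A, I_KCa, I_AHP, I_M and I_Leak
against I_app.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, Optional, Sequence, Union

import numpy as np

from . import engine
from .kinetics import KINETICS

__all__ = [
    "CURRENT_NAMES",
    "ModelParams",
    "Modulation",
    "SimConfig",
    "StateVector",
    "SimTrace",
    "RestingState",
    "simulate",
    "resting_state",
    "current_time_course",
]

CURRENT_NAMES = ("I_Na", "I_CaT", "I_CaL", "I_CaN", "I_KDR", "I_A",
                 "I_KCa", "I_AHP", "I_M", "I_Leak")
GATE_NAMES = ("h", "a", "d", "w", "n", "o", "q")


@dataclass(frozen=True)
class ModelParams:
    """Maximal conductances (mS/cm2), reversals (mV) and Ca2+ pool.

    Defaults are the modeled CA3 pyramidal neuron's published table values
    (g_Na 2, g_CaT 0.45, g_CaL 0.0025, g_CaN 0.0025, g_KDR 0.08, g_A 0.1,
    g_M 0.02, g_KCa 0.05, g_Kahp 0.0018, g_leak 0.0167; V_Na +50,
    V_K -91, V_Leak -65; I_app 0.004).
    """

    cm: float = 1.0
    g_Na: float = 2.0
    g_CaT: float = 0.45
    g_CaL: float = 0.0025
    g_CaN: float = 0.0025
    g_KDR: float = 0.08
    g_A: float = 0.1
    g_M: float = 0.02
    g_KCa: float = 0.05
    g_Kahp: float = 0.0018
    g_leak: float = 0.0167
    i_app: float = 0.004
    v_Na: float = 50.0
    v_K: float = -91.0
    v_Leak: float = -65.0
    ca_ext_mM: float = 2.0
    #: single well-mixed Ca2+ pool: dCa/dt = -influx_factor * I_Ca - Ca/tau
    ca_pool: dict = field(default_factory=lambda: {
        "influx_factor": 0.004, "removal_time_constant": 150.0})

    def __post_init__(self):
        for name in ("g_Na", "g_CaT", "g_CaL", "g_CaN", "g_KDR", "g_A",
                     "g_M", "g_KCa", "g_Kahp", "g_leak"):
            val = getattr(self, name)
            if not (math.isfinite(val) and val >= 0):
                raise ValueError(f"{name} must be finite and >= 0")
        if not self.cm > 0:
            raise ValueError("cm must be > 0")

    def to_vector(self, modulation: Optional["Modulation"] = None) -> np.ndarray:
        g_m = self.g_M
        g_kca = self.g_KCa
        if modulation is not None:
            g_m *= modulation.g_M_scale
            g_kca *= modulation.g_KCa_scale
        return np.array([
            self.cm, self.g_Na, self.g_CaT, self.g_CaL, self.g_CaN,
            self.g_KDR, self.g_A, g_m, g_kca, self.g_Kahp, self.g_leak,
            self.i_app, self.v_Na, self.v_K, self.v_Leak,
            self.ca_ext_mM * 1e3,
            self.ca_pool["influx_factor"], self.ca_pool["removal_time_constant"],
        ], dtype=np.float64)


@dataclass(frozen=True)
class Modulation:
    """Multiplicative scaling of g_M and g_KCa (drug-effect surrogate)."""

    g_M_scale: float = 1.0
    g_KCa_scale: float = 1.0

    def __post_init__(self):
        if self.g_M_scale < 0 or self.g_KCa_scale < 0:
            raise ValueError("modulation scales must be >= 0")


@dataclass
class StateVector:
    """Membrane potential, gate variables and Ca2+ concentration."""

    v: float
    gates: Dict[str, float]
    ca: float

    def __post_init__(self):
        for name, val in self.gates.items():
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"gate {name} = {val} outside [0, 1]")
        if self.ca < 0:
            raise ValueError("Ca_i must be >= 0")

    def to_array(self) -> np.ndarray:
        return np.array([self.v] + [self.gates[g] for g in GATE_NAMES] + [self.ca])

    @classmethod
    def from_array(cls, y: np.ndarray) -> "StateVector":
        return cls(float(y[0]), {g: float(y[1 + i]) for i, g in enumerate(GATE_NAMES)},
                   float(y[8]))

    @classmethod
    def steady(cls, v: float, ca: float = 0.05) -> "StateVector":
        y = np.empty(engine.N_STATE)
        engine.steady_gates(v, ca, KINETICS, y)
        return cls.from_array(y)


@dataclass(frozen=True)
class SimConfig:
    """Integration settings: explicit Euler, dt = 0.001 ms by default."""

    dt_ms: float = 0.001
    duration_ms: float = 3000.0
    record_interval_ms: float = 0.01
    method: str = "euler"  # or "rk4"
    initial_state: Union[str, StateVector] = "resting"
    equilibration_ms: float = 2000.0

    def __post_init__(self):
        if self.dt_ms <= 0:
            raise ValueError("dt_ms must be > 0")
        if self.duration_ms < self.dt_ms:
            raise ValueError("duration_ms must be >= dt_ms")
        if self.method not in ("euler", "rk4"):
            raise ValueError("method must be 'euler' or 'rk4'")


@dataclass
class SimTrace:
    """Recorded trajectory: V(t), gates, Ca_i and per-current time courses."""

    t_ms: np.ndarray
    v: np.ndarray
    ca: np.ndarray
    gates: Dict[str, np.ndarray]
    currents: Dict[str, np.ndarray]
    dvdt: np.ndarray
    params: ModelParams
    config: SimConfig
    modulation: Modulation

    @property
    def dt_record_ms(self) -> float:
        return float(self.t_ms[1] - self.t_ms[0]) if self.t_ms.size > 1 else self.config.dt_ms

    def states(self) -> np.ndarray:
        cols = [self.v] + [self.gates[g] for g in GATE_NAMES] + [self.ca]
        return np.column_stack(cols)

    def membrane_residual(self) -> np.ndarray:
        """Cm dV/dt + sum(I) - I_app at every recorded step (== 0 up to
        rounding, by construction of the recording)."""
        total = np.sum([self.currents[n] for n in CURRENT_NAMES], axis=0)
        p = self.params.to_vector(self.modulation)
        return p[0] * self.dvdt + total - p[11]


@dataclass
class RestingState:
    state: StateVector
    oscillatory: bool
    max_abs_deriv: float


def _initial_array(params: ModelParams, config: SimConfig,
                   modulation: Modulation) -> np.ndarray:
    init = config.initial_state
    if isinstance(init, StateVector):
        return init.to_array()
    if init == "resting":
        rest = resting_state(params, modulation=modulation,
                             equilibration_ms=config.equilibration_ms,
                             dt_ms=max(config.dt_ms, 0.001))
        return rest.state.to_array()
    raise ValueError(f"unknown initial_state {init!r}")


def simulate(params: ModelParams = ModelParams(),
             config: SimConfig = SimConfig(),
             modulation: Optional[Modulation] = None) -> SimTrace:
    """Integrate the model and return the recorded trajectory.

    ``modulation`` scales g_M / g_KCa multiplicatively (e.g. both x2 to
    mimic pharmacological channel activation).  Raises RuntimeError with
    diagnostics on numerical blow-up (|V| > 200 mV).
    """
    modulation = modulation or Modulation()
    p = params.to_vector(modulation)
    if not np.all(np.isfinite(p)):
        raise ValueError("model parameters must be finite")
    y0 = _initial_array(params, config, modulation)
    n_steps = int(round(config.duration_ms / config.dt_ms))
    stride = max(int(round(config.record_interval_ms / config.dt_ms)), 1)
    t, states, currents, dvdt, _, status = engine.integrate(
        y0, p, KINETICS, config.dt_ms, n_steps, stride, config.method == "rk4")
    if status >= 0:
        raise RuntimeError(
            f"numerical blow-up at t = {status * config.dt_ms:.3f} ms "
            f"(last recorded V = {states[-1, 0]:.1f} mV); reduce dt or check parameters")
    gates = {g: states[:, 1 + i] for i, g in enumerate(GATE_NAMES)}
    cur = {name: currents[:, i] for i, name in enumerate(CURRENT_NAMES)}
    return SimTrace(t, states[:, 0], states[:, 8], gates, cur, dvdt,
                    params, config, modulation)


def resting_state(params: ModelParams = ModelParams(),
                  modulation: Optional[Modulation] = None,
                  equilibration_ms: float = 2000.0,
                  dt_ms: float = 0.001) -> RestingState:
    """Equilibrate for ``equilibration_ms`` with I_app = 0.

    Returns the final state plus an ``oscillatory`` flag: the state is a
    genuine rest point only if all derivatives fall below 1e-6 per ms;
    with the default parameters the model is an endogenous burster and is
    flagged oscillatory.
    """
    modulation = modulation or Modulation()
    quiet = replace(params, i_app=0.0)
    p = quiet.to_vector(modulation)
    y0 = StateVector.steady(-70.0).to_array()
    n_steps = int(round(equilibration_ms / dt_ms))
    _, states, _, _, y_end, status = engine.integrate(
        y0, p, KINETICS, dt_ms, n_steps, max(n_steps // 200, 1), False)
    if status >= 0:
        raise RuntimeError("blow-up during equilibration")
    dy = np.empty(engine.N_STATE)
    cur = np.empty(engine.N_CURRENT)
    engine.deriv(y_end, p, KINETICS, dy, cur)
    max_deriv = float(np.max(np.abs(dy)))
    tail_v = states[states.shape[0] // 2:, 0]
    oscillatory = max_deriv >= 1e-6 or float(np.ptp(tail_v)) > 1.0
    y_end = y_end.copy()
    y_end[1:8] = np.clip(y_end[1:8], 0.0, 1.0)
    return RestingState(StateVector.from_array(y_end), oscillatory, max_deriv)


def current_time_course(trace: SimTrace, name: str) -> np.ndarray:
    """Reconstruct a current's time course from the recorded states
    (g * gates * driving force, GHK form for the Ca2+ currents)."""
    if name not in CURRENT_NAMES:
        raise KeyError(f"unknown current {name!r}; known: {CURRENT_NAMES}")
    p = trace.params.to_vector(trace.modulation)
    states = trace.states()
    out = np.empty(states.shape[0])
    cur = np.empty(engine.N_CURRENT)
    idx = CURRENT_NAMES.index(name)
    for i in range(states.shape[0]):
        engine.eval_currents(states[i], p, KINETICS, cur)
        out[i] = cur[idx]
    return out
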