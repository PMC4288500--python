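"""Seeded synthetic electrophysiology data.

These generators emulate the statistical structure of the recordings the
downstream analyses expect, so every stage of the pipeline can be exercised
and validated without raw data:

* whole-cell M-current voltage-step sweeps (Boltzmann-activated conductance
  relaxing mono-exponentially, Gaussian trace noise, lognormal cell-to-cell
  G_max spread),
* per-cell Hill-shaped concentration-response tables,
* N-channel two-state telegraph single-channel traces with exponential dwell
  times and a fixed unitary amplitude,
* Poisson trains of brief biphasic action-current waveforms,
* unitary current-voltage tables for single-channel conductance regression.

All randomness flows from ``NoiseSpec.seed`` through one named stream per
generator (see :mod:`kmburst._rng`); identical specs and seeds reproduce
outputs bit for bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._rng import stream
from .fitting import BoltzmannFit, HillFit, eval_boltzmann, eval_hill

__all__ = [
    "NoiseSpec",
    "StepProtocol",
    "ChannelSimSpec",
    "Trace",
    "SweepSet",
    "gen_ikm_sweeps",
    "gen_dose_response",
    "gen_single_channel_trace",
    "gen_action_current_train",
    "gen_single_channel_iv",
    "default_action_current_waveform",
]

#: default single-channel noise, as a fraction of the unitary amplitude;
#: at 0.15 the half-amplitude idealization is reliable.
CHANNEL_NOISE_FRACTION = 0.15


@dataclass(frozen=True)
class NoiseSpec:
    """Noise and variability settings shared by the generators.

    trace_noise_sd : Gaussian sample noise sd in pA (None -> per-generator
        default); cell_cv : lognormal coefficient of variation applied to
        per-cell amplitude parameters (G_max, E_max); seed : master seed.
    """

    trace_noise_sd: Optional[float] = None
    cell_cv: float = 0.15
    seed: int = 0

    def __post_init__(self):
        if self.trace_noise_sd is not None and self.trace_noise_sd < 0:
            raise ValueError("trace_noise_sd must be >= 0")
        if self.cell_cv < 0:
            raise ValueError("cell_cv must be >= 0")

    def sd(self, default: float) -> float:
        return default if self.trace_noise_sd is None else float(self.trace_noise_sd)


@dataclass(frozen=True)
class StepProtocol:
    """Voltage-step protocol: holding level, step levels, timing (all mV/ms)."""

    holding_mV: float = -20.0
    step_levels_mV: tuple = (-50.0, -40.0, -30.0, -20.0, -10.0, 0.0, 10.0)
    step_duration_ms: float = 1000.0
    sample_interval_ms: float = 1.0

    def __post_init__(self):
        if len(self.step_levels_mV) == 0:
            raise ValueError("step_levels_mV must be non-empty")
        if self.step_duration_ms <= 0 or self.sample_interval_ms <= 0:
            raise ValueError("durations and sample interval must be > 0")


@dataclass(frozen=True)
class ChannelSimSpec:
    """Two-state N-channel gating spec.

    Either ``open_probability`` or ``mean_closed_time_ms`` may be omitted;
    the missing one is derived from Po = open/(open+closed).  If both are
    given they must be consistent.
    """

    n_channels: int = 1
    open_probability: Optional[float] = None
    unitary_amplitude_pA: float = 10.8
    mean_open_time_ms: float = 2.0
    mean_closed_time_ms: Optional[float] = None
    duration_ms: float = 60000.0

    def __post_init__(self):
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")
        if self.unitary_amplitude_pA == 0:
            raise ValueError("unitary_amplitude_pA must be non-zero")
        if self.mean_open_time_ms <= 0:
            raise ValueError("dwell means must be > 0")
        if self.open_probability is None and self.mean_closed_time_ms is None:
            raise ValueError("give open_probability or mean_closed_time_ms")
        po, mc = self.open_probability, self.mean_closed_time_ms
        if po is not None and not 0.0 <= po <= 1.0:
            raise ValueError("open_probability must lie in [0, 1]")
        if po is not None and mc is not None:
            implied = self.mean_open_time_ms / (self.mean_open_time_ms + mc)
            if abs(implied - po) > 1e-6 * max(po, 1e-12):
                raise ValueError("open_probability inconsistent with dwell means")

    @property
    def po(self) -> float:
        if self.open_probability is not None:
            return float(self.open_probability)
        mo, mc = self.mean_open_time_ms, self.mean_closed_time_ms
        return mo / (mo + mc)

    @property
    def closed_time_ms(self) -> float:
        if self.mean_closed_time_ms is not None:
            return float(self.mean_closed_time_ms)
        po = self.po
        if po >= 1.0:
            return 0.0
        if po <= 0.0:
            return math.inf
        return self.mean_open_time_ms * (1.0 - po) / po


@dataclass
class Trace:
    """Uniformly sampled current trace with generator ground truth in meta."""

    values_pA: np.ndarray
    sample_interval_ms: float
    meta: dict = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return int(self.values_pA.size)

    @property
    def duration_ms(self) -> float:
        return self.n_samples * self.sample_interval_ms

    def time_ms(self) -> np.ndarray:
        return np.arange(self.n_samples) * self.sample_interval_ms


@dataclass
class SweepSet:
    """Tidy collection of voltage-step sweeps plus protocol metadata."""

    data: pd.DataFrame  # cell_id, sweep_id, step_mV, time_ms, value_pA
    protocol: StepProtocol
    meta: dict = field(default_factory=dict)

    def end_of_pulse(self, tail_fraction: float = 0.1) -> pd.DataFrame:
        """Mean current over the last ``tail_fraction`` of each step."""
        t_cut = self.protocol.step_duration_ms * (1.0 - tail_fraction)
        tail = self.data[self.data["time_ms"] >= t_cut]
        out = (tail.groupby(["cell_id", "step_mV"], as_index=False)["value_pA"]
               .mean().rename(columns={"value_pA": "i_end_pA"}))
        return out


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------


def gen_ikm_sweeps(
    protocol: StepProtocol,
    boltz: BoltzmannFit,
    tau_relax_ms: float = 150.0,
    reversal_mV: float = -91.0,
    noise: NoiseSpec = NoiseSpec(),
    n_cells: int = 1,
    v_half_jitter_sd: float = 2.1,
) -> SweepSet:
    """Whole-cell M-current sweeps.

    Each sweep steps the conductance target from the holding level to the
    step level; the current relaxes mono-exponentially with ``tau_relax_ms``
    from the instantaneous value G(V_hold)*(V_step - V_K) to the steady value
    G(V_step)*(V_step - V_K), plus Gaussian noise.  G_max is jittered
    lognormally per cell (cv = ``noise.cell_cv``) and V_1/2 normally
    (sd = ``v_half_jitter_sd`` mV, back-calculated from the reported SEM).
    """
    for name, val in [("g_max", boltz.g_max), ("v_half", boltz.v_half), ("q", boltz.q),
                      ("tau_relax_ms", tau_relax_ms), ("reversal_mV", reversal_mV)]:
        if not math.isfinite(val):
            raise ValueError(f"non-finite parameter {name}")
    if tau_relax_ms < 0:
        raise ValueError("tau_relax_ms must be >= 0")
    rng = stream(noise.seed, "ikm_sweeps")
    sd = noise.sd(1.0)
    t = np.arange(0.0, protocol.step_duration_ms, protocol.sample_interval_ms)
    decay = np.exp(-t / tau_relax_ms) if tau_relax_ms > 0 else np.zeros_like(t)

    sigma = math.sqrt(math.log(1.0 + noise.cell_cv ** 2))
    frames = []
    truth = []
    for cell in range(n_cells):
        g_max_i = boltz.g_max * rng.lognormal(-0.5 * sigma ** 2, sigma)
        v_half_i = boltz.v_half + rng.normal(0.0, v_half_jitter_sd)
        cell_fit = BoltzmannFit(g_max_i, v_half_i, boltz.q, boltz.temperature)
        g_hold = g_max_i * eval_boltzmann(cell_fit, protocol.holding_mV)
        truth.append({"cell_id": cell, "g_max_nS": g_max_i, "v_half_mV": v_half_i})
        for sweep, v_step in enumerate(protocol.step_levels_mV):
            drive = v_step - reversal_mV
            i_ss = g_max_i * eval_boltzmann(cell_fit, v_step) * drive
            i_0 = g_hold * drive
            i_t = i_ss + (i_0 - i_ss) * decay + rng.normal(0.0, sd, t.size)
            frames.append(pd.DataFrame({
                "cell_id": cell, "sweep_id": sweep, "step_mV": v_step,
                "time_ms": t, "value_pA": i_t,
            }))
    data = pd.concat(frames, ignore_index=True)
    meta = {
        "generator": "gen_ikm_sweeps",
        "boltzmann": {"g_max": boltz.g_max, "v_half": boltz.v_half, "q": boltz.q,
                      "temperature": boltz.temperature},
        "tau_relax_ms": tau_relax_ms, "reversal_mV": reversal_mV,
        "noise_sd_pA": sd, "cell_cv": noise.cell_cv, "seed": noise.seed,
        "cells": truth,
    }
    return SweepSet(data, protocol, meta)


def gen_dose_response(
    hill: HillFit,
    concentrations: Sequence[float],
    noise: NoiseSpec = NoiseSpec(),
    n_cells: int = 10,
    ec50_cell_sd: Optional[float] = None,
    response_sd: float = 5.0,
) -> pd.DataFrame:
    """Per-cell normalized concentration-response table.

    Each cell gets a lognormally jittered E_max and a normally jittered
    EC50.  The EC50 jitter defaults to 0.85 * cell_cv * ec50 (~1.25 uM at
    the default cv of 0.15 and EC50 9.8 uM), back-calculated so that the
    fitted-EC50 standard error at n ~ 10 cells matches the reported
    +/-0.4 uM; per-point noise is Gaussian with sd ``response_sd``
    (percent).  Responses are renormalized so the mean at the top
    concentration is 100%.

    Returns a DataFrame with columns cell_id, conc_uM, response_pct.
    """
    conc = np.asarray(list(concentrations), dtype=float)
    if conc.size == 0:
        raise ValueError("concentration list must not be empty")
    if np.any(conc <= 0):
        raise ValueError("concentrations must be > 0")
    rng = stream(noise.seed, "dose_response")
    sd_pt = noise.sd(response_sd)
    if ec50_cell_sd is None:
        ec50_cell_sd = 0.85 * noise.cell_cv * hill.ec50
    top = conc.max()
    sigma = math.sqrt(math.log(1.0 + noise.cell_cv ** 2))

    rows = []
    for cell in range(n_cells):
        e_max_i = hill.e_max * rng.lognormal(-0.5 * sigma ** 2, sigma)
        ec50_i = max(hill.ec50 + rng.normal(0.0, ec50_cell_sd), 0.05 * hill.ec50)
        cell_fit = HillFit(e_max_i, ec50_i, hill.n_h)
        resp = eval_hill(cell_fit, conc) + rng.normal(0.0, sd_pt, conc.size)
        rows.append(pd.DataFrame({"cell_id": cell, "conc_uM": conc, "response_pct": resp}))
    table = pd.concat(rows, ignore_index=True)
    top_mean = table.loc[table["conc_uM"] == top, "response_pct"].mean()
    if top_mean != 0:
        table["response_pct"] *= 100.0 / top_mean
    table.attrs["meta"] = {
        "generator": "gen_dose_response", "seed": noise.seed,
        "hill": {"e_max": hill.e_max, "ec50": hill.ec50, "n_h": hill.n_h},
        "ec50_cell_sd": ec50_cell_sd, "response_sd": sd_pt, "cell_cv": noise.cell_cv,
    }
    return table


def _telegraph_occupancy(spec: ChannelSimSpec, n_samples: int, dt: float,
                         rng: np.random.Generator) -> np.ndarray:
    """Number of simultaneously open channels at each sample (exact
    event-driven two-state simulation per channel)."""
    occ = np.zeros(n_samples, dtype=np.int16)
    mo, mc, po = spec.mean_open_time_ms, spec.closed_time_ms, spec.po
    duration = n_samples * dt
    for _ in range(spec.n_channels):
        t = 0.0
        state = bool(rng.random() < po)  # stationary initial condition
        while t < duration:
            dwell = rng.exponential(mo if state else mc)
            if state:
                i0 = int(math.ceil(t / dt))
                i1 = min(int(math.ceil((t + dwell) / dt)), n_samples)
                if i1 > i0:
                    occ[i0:i1] += 1
            t += dwell
            state = not state
    return occ


def gen_single_channel_trace(
    spec: ChannelSimSpec,
    noise: NoiseSpec = NoiseSpec(),
    sample_interval_ms: float = 0.1,
    baseline_pA: float = 0.0,
) -> Trace:
    """N-channel telegraph trace at ``unitary_amplitude_pA`` per open channel.

    Dwell times are exponential; channels are independent; Gaussian noise of
    sd 0.15 x |unitary| is added unless ``noise.trace_noise_sd`` overrides.
    The exact open-channel count per sample is kept in ``meta['occupancy']``
    as the idealization oracle.
    """
    if sample_interval_ms <= 0:
        raise ValueError("sample_interval_ms must be > 0")
    mo, mc = spec.mean_open_time_ms, spec.closed_time_ms
    if 0.0 < spec.po < 1.0 and min(mo, mc) < 5.0 * sample_interval_ms:
        raise ValueError(
            f"unresolvable dwell times: mean open {mo} ms / closed {mc} ms "
            f"must both be >= 5 x sample interval ({sample_interval_ms} ms)")
    rng = stream(noise.seed, "single_channel")
    n = int(round(spec.duration_ms / sample_interval_ms))
    if spec.po == 0.0:
        occ = np.zeros(n, dtype=np.int16)
    elif spec.po == 1.0:
        occ = np.full(n, spec.n_channels, dtype=np.int16)
    else:
        occ = _telegraph_occupancy(spec, n, sample_interval_ms, rng)
    sd = noise.sd(CHANNEL_NOISE_FRACTION * abs(spec.unitary_amplitude_pA))
    values = baseline_pA + occ * spec.unitary_amplitude_pA
    if sd > 0:
        values = values + rng.normal(0.0, sd, n)
    return Trace(values.astype(float), sample_interval_ms, meta={
        "generator": "gen_single_channel_trace", "seed": noise.seed,
        "occupancy": occ, "baseline_pA": baseline_pA, "noise_sd_pA": sd,
        "spec": spec,
    })


def default_action_current_waveform(sample_interval_ms: float, amplitude_pA: float,
                                    width_ms: float = 1.0) -> np.ndarray:
    """Biphasic (downward-then-upward) capacitive spike waveform: the first
    derivative of a Gaussian, scaled so the downward peak is -amplitude."""
    half = 4.0 * width_ms
    t = np.arange(-half, half + sample_interval_ms / 2, sample_interval_ms)
    w = t * np.exp(-t ** 2 / (2.0 * width_ms ** 2))  # negative lobe first
    return w * (abs(amplitude_pA) / abs(w.min()))  # min(w) == -|amplitude|


def gen_action_current_train(
    rate_hz: float,
    duration_s: float,
    waveform: Optional[np.ndarray] = None,
    noise: NoiseSpec = NoiseSpec(),
    sample_interval_ms: float = 0.2,
    snr: float = 10.0,
) -> Trace:
    """Homogeneous Poisson train of action-current waveforms on a noisy
    baseline.  Expected event count is rate * duration.

    ``meta['event_times_s']`` holds the true peak (downward extremum) times.
    """
    if rate_hz < 0:
        raise ValueError("rate must be >= 0")
    if duration_s <= 0:
        raise ValueError("duration must be > 0")
    rng = stream(noise.seed, "action_currents")
    sd = noise.sd(1.0)
    if waveform is None:
        waveform = default_action_current_waveform(sample_interval_ms, amplitude_pA=snr * max(sd, 1e-12))
    waveform = np.asarray(waveform, dtype=float)
    if rate_hz > 0 and waveform.size * sample_interval_ms > 1000.0 / rate_hz:
        raise ValueError("waveform must be shorter than the mean inter-event interval")

    n = int(round(duration_s * 1000.0 / sample_interval_ms))
    values = rng.normal(0.0, sd, n) if sd > 0 else np.zeros(n)
    n_events = rng.poisson(rate_hz * duration_s)
    onsets = np.sort(rng.uniform(0.0, duration_s, n_events))  # Poisson order statistics
    peak_offset = int(np.argmin(waveform))
    event_times = []
    for t0 in onsets:
        i0 = int(round(t0 * 1000.0 / sample_interval_ms))
        i1 = min(i0 + waveform.size, n)
        if i1 <= i0:
            continue
        values[i0:i1] += waveform[: i1 - i0]
        event_times.append((i0 + peak_offset) * sample_interval_ms / 1000.0)
    return Trace(values, sample_interval_ms, meta={
        "generator": "gen_action_current_train", "seed": noise.seed,
        "rate_hz": rate_hz, "duration_s": duration_s, "noise_sd_pA": sd,
        "event_times_s": np.asarray(event_times), "waveform": waveform,
    })


def gen_single_channel_iv(
    conductance_pS: float,
    reversal_mV: float,
    potentials_mV: Sequence[float],
    noise: NoiseSpec = NoiseSpec(),
) -> pd.DataFrame:
    """Unitary current amplitude table: amp = g * (V - V_rev) (+ noise).

    Returns a DataFrame with columns step_mV, amp_pA.  Noise defaults to 0
    (the table emulates *mean* amplitudes over many openings).
    """
    pots = np.asarray(list(potentials_mV), dtype=float)
    if np.unique(pots).size < 2:
        raise ValueError("need >= 2 distinct potentials")
    rng = stream(noise.seed, "single_channel_iv")
    sd = noise.sd(0.0)
    amp = conductance_pS * (pots - reversal_mV) / 1e3
    if sd > 0:
        amp = amp + rng.normal(0.0, sd, pots.size)
    df = pd.DataFrame({"step_mV": pots, "amp_pA": amp})
    df.attrs["meta"] = {"generator": "gen_single_channel_iv", "seed": noise.seed,
                        "conductance_pS": conductance_pS, "reversal_mV": reversal_mV}
    return df
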