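"""Spike and burst metrics for voltage traces.

Spikes are upward threshold crossings (default 0 mV, 2 ms lockout); bursts
are maximal runs of spikes whose inter-spike intervals stay below a gap
(default 100 ms, well between the intra-burst ISIs of tens of ms and the
interburst intervals of hundreds of ms produced by the model).  The
after-hyperpolarization (AHP) is the voltage minimum over the windows
*between* bursts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import numpy as np

__all__ = [
    "BurstMetrics",
    "detect_spikes",
    "segment_bursts",
    "intraburst_rate",
    "interburst_interval",
    "ahp_depth",
    "fold_change",
    "burst_metrics",
]

DEFAULT_SPIKE_THRESHOLD_MV = 0.0
DEFAULT_SPIKE_LOCKOUT_MS = 2.0
DEFAULT_BURST_GAP_MS = 100.0


@dataclass
class BurstMetrics:
    """Summary of a spiking trace.

    bursts: list of (start_ms, end_ms, spike_count); intraburst_rate_hz is
    the mean over multi-spike bursts of (spikes-1)/duration; ahp_min_mV is
    nan when fewer than two bursts exist (no interburst window).
    """

    spike_times_ms: np.ndarray
    bursts: List[Tuple[float, float, int]]
    intraburst_rate_hz: float
    interburst_interval_ms: float
    ahp_min_mV: float
    mean_spikes_per_burst: float
    peak_currents: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_spikes": int(self.spike_times_ms.size),
            "n_bursts": len(self.bursts),
            "mean_spikes_per_burst": self.mean_spikes_per_burst,
            "intraburst_rate_hz": self.intraburst_rate_hz,
            "interburst_interval_ms": self.interburst_interval_ms,
            "ahp_min_mV": self.ahp_min_mV,
            "peak_currents": self.peak_currents,
        }


def detect_spikes(v_mV: Sequence[float], dt_ms: float,
                  threshold_mV: float = DEFAULT_SPIKE_THRESHOLD_MV,
                  lockout_ms: float = DEFAULT_SPIKE_LOCKOUT_MS) -> np.ndarray:
    """Times (ms) of upward crossings of ``threshold_mV``."""
    v = np.asarray(v_mV, dtype=float)
    if dt_ms <= 0:
        raise ValueError("dt_ms must be > 0")
    up = np.flatnonzero((v[:-1] < threshold_mV) & (v[1:] >= threshold_mV)) + 1
    if up.size == 0:
        return np.array([])
    lock = lockout_ms / dt_ms
    out = [up[0]]
    for i in up[1:]:
        if i - out[-1] >= lock:
            out.append(i)
    return np.asarray(out) * dt_ms


def segment_bursts(spike_times_ms: Sequence[float],
                   gap_ms: float = DEFAULT_BURST_GAP_MS) -> List[Tuple[float, float, int]]:
    """Maximal runs of spikes with consecutive ISIs < ``gap_ms``.

    Singleton spikes count as one-spike bursts.  Returns (start, end, count)
    tuples ordered in time.
    """
    if gap_ms <= 0:
        raise ValueError("gap_ms must be > 0")
    t = np.asarray(spike_times_ms, dtype=float)
    if t.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(t) >= gap_ms)
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [t.size - 1]])
    return [(float(t[i]), float(t[j]), int(j - i + 1)) for i, j in zip(starts, ends)]


def intraburst_rate(bursts: List[Tuple[float, float, int]]) -> float:
    """Mean of (spikes-1)/duration over bursts with >= 2 spikes, in Hz."""
    rates = [1000.0 * (n - 1) / (e - s) for s, e, n in bursts if n >= 2 and e > s]
    return float(np.mean(rates)) if rates else math.nan


def interburst_interval(bursts: List[Tuple[float, float, int]]) -> float:
    """Mean interval (ms) from one burst's end to the next burst's start."""
    if len(bursts) < 2:
        return math.nan
    gaps = [bursts[i + 1][0] - bursts[i][1] for i in range(len(bursts) - 1)]
    return float(np.mean(gaps))


def ahp_depth(v_mV: Sequence[float], t_ms: Sequence[float],
              bursts: List[Tuple[float, float, int]]) -> float:
    """Minimum membrane potential over all interburst windows (mV).

    Requires >= 2 bursts so that at least one interburst window exists;
    returns nan (flagged undefined) otherwise.
    """
    if len(bursts) < 2:
        return math.nan
    v = np.asarray(v_mV, dtype=float)
    t = np.asarray(t_ms, dtype=float)
    lows = []
    for (s0, e0, _), (s1, _, _) in zip(bursts[:-1], bursts[1:]):
        mask = (t > e0) & (t < s1)
        if mask.any():
            lows.append(float(v[mask].min()))
    return min(lows) if lows else math.nan


def fold_change(trace_a, trace_b, current: str, transient_ms: float = 500.0) -> float:
    """Ratio of peak |I_current| in ``trace_b`` over ``trace_a`` after
    discarding ``transient_ms`` from each trace."""
    peaks = []
    for tr in (trace_a, trace_b):
        if current not in tr.currents:
            raise KeyError(f"current {current!r} was not recorded")
        mask = tr.t_ms >= transient_ms
        peaks.append(float(np.max(np.abs(tr.currents[current][mask]))))
    if peaks[0] == 0:
        raise ZeroDivisionError("zero peak current in the denominator trace")
    return peaks[1] / peaks[0]


def burst_metrics(v_mV: Sequence[float], dt_ms: float,
                  threshold_mV: float = DEFAULT_SPIKE_THRESHOLD_MV,
                  gap_ms: float = DEFAULT_BURST_GAP_MS,
                  transient_ms: float = 0.0) -> BurstMetrics:
    """Full burst summary of a uniformly sampled voltage trace."""
    v = np.asarray(v_mV, dtype=float)
    t = np.arange(v.size) * dt_ms
    mask = t >= transient_ms
    spikes = detect_spikes(v[mask], dt_ms, threshold_mV) + t[mask][0] if mask.any() else np.array([])
    bursts = segment_bursts(spikes, gap_ms)
    counts = [n for _, _, n in bursts]
    return BurstMetrics(
        spike_times_ms=spikes,
        bursts=bursts,
        intraburst_rate_hz=intraburst_rate(bursts),
        interburst_interval_ms=interburst_interval(bursts),
        ahp_min_mV=ahp_depth(v, t, bursts),
        mean_spikes_per_burst=float(np.mean(counts)) if counts else 0.0,
    )
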