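"""Single-channel idealization, open-probability estimation and
action-current detection.

Idealization follows the field-standard half-amplitude threshold scheme:
an all-points amplitude histogram is fitted with a mixture of Gaussians to
locate the baseline and the unitary current; each sample is then assigned
the nearest integer level (number of simultaneously open channels).  NPo is
the duration-weighted mean level; for a single channel it equals Po.

Action currents (capacitive spikes reporting APs in cell-attached clamp)
are detected as downward excursions beyond k x robust baseline SD (median
absolute deviation based) with a 20 ms refractory lockout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import find_peaks

from .synth import Trace

__all__ = [
    "IdealizedTrace",
    "EventTrain",
    "LevelFit",
    "amplitude_histogram_fit",
    "idealize_trace",
    "estimate_npo",
    "detect_action_currents",
    "firing_frequency",
]

#: runs shorter than this many samples are merged into their neighbours
#: (the idealization dead time)
MIN_DWELL_SAMPLES = 2
#: refractory lockout for action-current detection, ms (~1 Hz firing)
DEFAULT_LOCKOUT_MS = 20.0


@dataclass
class IdealizedTrace:
    """Piecewise-constant level sequence covering the whole trace.

    ``segments`` is an (n, 3) array of (start_ms, duration_ms, level) with
    contiguous, non-overlapping rows; levels count simultaneously open
    channels (>= 0).
    """

    segments: np.ndarray
    unitary_amplitude_pA: float
    baseline_pA: float
    sample_interval_ms: float

    def __post_init__(self):
        seg = np.asarray(self.segments, dtype=float)
        if seg.size and np.any(seg[:, 1] <= 0):
            raise ValueError("segment durations must be > 0")
        if seg.size > 3:
            starts, durs = seg[:-1, 0], seg[:-1, 1]
            if not np.allclose(starts + durs, seg[1:, 0]):
                raise ValueError("segments must be contiguous")
        self.segments = seg

    @property
    def total_duration_ms(self) -> float:
        return float(self.segments[:, 1].sum()) if self.segments.size else 0.0

    def levels_per_sample(self) -> np.ndarray:
        reps = np.round(self.segments[:, 1] / self.sample_interval_ms).astype(int)
        return np.repeat(self.segments[:, 2].astype(int), reps)


@dataclass
class EventTrain:
    """Detected event times (s), strictly increasing, within [0, duration]."""

    event_times_s: np.ndarray
    duration_s: float

    def __post_init__(self):
        t = np.asarray(self.event_times_s, dtype=float)
        if t.size and (np.any(np.diff(t) <= 0) or t[0] < 0 or t[-1] > self.duration_s):
            raise ValueError("event times must be strictly increasing within [0, duration]")
        self.event_times_s = t

    @property
    def n_events(self) -> int:
        return int(self.event_times_s.size)


@dataclass
class LevelFit:
    """Gaussian-mixture fit of the all-points amplitude histogram."""

    means_pA: np.ndarray
    sds_pA: np.ndarray
    weights: np.ndarray
    unitary_amplitude_pA: float
    converged: bool = True
    message: str = ""
    flags: list = field(default_factory=list)


def _values(trace: Union[Trace, np.ndarray]) -> np.ndarray:
    return trace.values_pA if isinstance(trace, Trace) else np.asarray(trace, dtype=float)


def amplitude_histogram_fit(trace: Union[Trace, np.ndarray], n_levels: int,
                            bins: int = 256) -> LevelFit:
    """Fit ``n_levels`` Gaussians to the binned all-points histogram.

    Level means are constrained only by initialization (histogram peaks);
    the unitary amplitude is the mean spacing of adjacent level means and
    weights are normalized to sum to 1.  Fewer apparent modes than
    ``n_levels`` raises a flag on the returned fit rather than an error.
    """
    x = _values(trace)
    if x.size < 1000:
        raise ValueError("trace must have >= 1000 samples")
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")

    counts, edges = np.histogram(x, bins=bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    bin_w = edges[1] - edges[0]

    # initial means from histogram peaks (tallest first), padded by even
    # spacing if fewer modes are apparent
    flags = []
    order = np.argsort(counts)[::-1]
    smooth = np.convolve(counts, np.ones(5) / 5.0, mode="same")
    peaks, _ = find_peaks(smooth, height=0.02 * smooth.max(),
                          prominence=0.08 * smooth.max(),
                          distance=max(2, bins // 40))
    peak_centers = centers[peaks[np.argsort(smooth[peaks])[::-1]]]
    if peak_centers.size < n_levels:
        flags.append(f"only {peak_centers.size} apparent modes for {n_levels} requested levels")
        start = centers[order[0]]
        span = (x.max() - x.min()) / max(n_levels - 1, 1)
        extra = start + np.sign(np.mean(x) - start + 1e-12) * span * np.arange(1, n_levels)
        peak_centers = np.concatenate([peak_centers, extra])[:n_levels]
    means0 = np.sort(peak_centers[:n_levels])
    sd0 = max(np.std(x) / n_levels, bin_w)

    def mixture(c, *p):
        mus, sds, amps = (np.array(p[:n_levels]), np.array(p[n_levels:2 * n_levels]),
                          np.array(p[2 * n_levels:]))
        return np.sum(amps[:, None] * np.exp(-(c[None, :] - mus[:, None]) ** 2
                                             / (2 * sds[:, None] ** 2)), axis=0)

    p0 = np.concatenate([means0, np.full(n_levels, sd0), np.full(n_levels, counts.max() / 2)])
    lo = np.concatenate([np.full(n_levels, x.min() - 1), np.full(n_levels, bin_w / 10),
                         np.zeros(n_levels)])
    hi = np.concatenate([np.full(n_levels, x.max() + 1), np.full(n_levels, np.ptp(x)),
                         np.full(n_levels, 10.0 * counts.max())])
    try:
        popt, _ = curve_fit(mixture, centers, counts.astype(float), p0=p0,
                            bounds=(lo, hi), maxfev=20000)
        converged, message = True, ""
    except (RuntimeError, ValueError) as err:
        popt, converged, message = p0, False, f"mixture fit failed: {err}"

    mus = np.array(popt[:n_levels])
    sds = np.array(popt[n_levels:2 * n_levels])
    amps = np.array(popt[2 * n_levels:])
    idx = np.argsort(mus)
    mus, sds, amps = mus[idx], sds[idx], amps[idx]
    mass = amps * sds  # proportional to area under each Gaussian
    weights = mass / mass.sum() if mass.sum() > 0 else np.full(n_levels, 1.0 / n_levels)
    unitary = float(np.mean(np.diff(mus))) if n_levels > 1 else 0.0
    return LevelFit(mus, np.abs(sds), weights, unitary, converged=converged,
                    message=message, flags=flags)


def idealize_trace(trace: Union[Trace, np.ndarray], baseline_pA: float,
                   unitary_pA: float,
                   sample_interval_ms: Optional[float] = None) -> IdealizedTrace:
    """Half-amplitude threshold idealization.

    Each sample is assigned level round((x - baseline)/unitary), clamped at
    >= 0 (so ``unitary_pA`` carries the deflection sign: negative for
    cell-attached K_M openings, positive for inside-out BK openings).
    Runs shorter than MIN_DWELL_SAMPLES are merged into the preceding run.
    """
    if unitary_pA == 0:
        raise ValueError("unitary amplitude must be non-zero")
    x = _values(trace)
    if sample_interval_ms is None:
        if not isinstance(trace, Trace):
            raise ValueError("sample_interval_ms required for bare arrays")
        sample_interval_ms = trace.sample_interval_ms

    rel = (x - baseline_pA) / unitary_pA  # sign-normalized open-channel count
    frac_opposite = float(np.mean(rel < -0.5))
    frac_open = float(np.mean(rel > 0.5))
    if frac_opposite > 0.05 and frac_opposite > 2.0 * frac_open:
        raise ValueError("unitary amplitude sign is inconsistent with the "
                         "deflection direction of the trace")
    levels = np.clip(np.round(rel), 0, None).astype(int)

    # run-length encode, then censor dwells below the dead time
    change = np.flatnonzero(np.diff(levels)) + 1
    starts = np.concatenate([[0], change])
    lengths = np.diff(np.concatenate([starts, [levels.size]]))
    vals = levels[starts]
    if vals.size > 1:
        keep_vals, keep_lens = [vals[0]], [lengths[0]]
        for v, ln in zip(vals[1:], lengths[1:]):
            if ln < MIN_DWELL_SAMPLES:
                keep_lens[-1] += ln  # absorbed by the preceding dwell
            elif v == keep_vals[-1]:
                keep_lens[-1] += ln
            else:
                keep_vals.append(v)
                keep_lens.append(ln)
        vals = np.array(keep_vals)
        lengths = np.array(keep_lens)
        starts = np.concatenate([[0], np.cumsum(lengths)[:-1]])

    seg = np.column_stack([starts * sample_interval_ms,
                           lengths * sample_interval_ms,
                           vals.astype(float)])
    return IdealizedTrace(seg, unitary_pA, baseline_pA, sample_interval_ms)


def estimate_npo(ideal: IdealizedTrace) -> float:
    """NPo = sum(level_i * duration_i) / total duration.

    For a single channel this is Po in [0, 1]; for an unknown number of
    channels it is the time-averaged count of simultaneously open channels.
    """
    if ideal.segments.size == 0:
        raise ValueError("empty idealization")
    dur = ideal.segments[:, 1]
    return float((ideal.segments[:, 2] * dur).sum() / dur.sum())


def detect_action_currents(trace: Trace, k_sd: float = 6.0,
                           lockout_ms: float = DEFAULT_LOCKOUT_MS) -> EventTrain:
    """Detect downward action-current deflections.

    Threshold = baseline median - k_sd x (1.4826 x MAD); events are local
    minima below threshold separated by at least ``lockout_ms``; the event
    time is the peak (most negative) time.
    """
    if k_sd <= 0:
        raise ValueError("k_sd must be > 0")
    x = trace.values_pA
    dt = trace.sample_interval_ms
    if x.size * dt < 10_000.0:
        raise ValueError("trace must be >= 10 s for stable baseline statistics")
    med = float(np.median(x))
    sd = 1.4826 * float(np.median(np.abs(x - med)))
    thr = med - k_sd * sd

    below = x < thr
    if not below.any():
        return EventTrain(np.array([]), x.size * dt / 1000.0)
    # contiguous sub-threshold regions -> deepest sample each
    idx = np.flatnonzero(below)
    splits = np.flatnonzero(np.diff(idx) > 1) + 1
    groups = np.split(idx, splits)
    cand = np.array([g[np.argmin(x[g])] for g in groups])

    lock = lockout_ms / dt
    accepted = []
    last = -np.inf
    for i in cand:
        if i - last >= lock:
            accepted.append(i)
            last = i
    times_s = np.array(accepted) * dt / 1000.0
    return EventTrain(times_s, x.size * dt / 1000.0)


def firing_frequency(train: EventTrain) -> float:
    """Mean event rate in Hz (count / duration)."""
    if train.duration_s <= 0:
        raise ValueError("duration must be > 0")
    return train.n_events / train.duration_s
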