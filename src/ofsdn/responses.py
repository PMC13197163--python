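"""Spike-train quantification: rate estimation, windowed means, direction
tuning, velocity response functions and response-onset detection.

Spike times are in seconds from trial start.  Rates are estimated with a
centred square-wave (boxcar) filter, 100 ms wide by default, on a uniform
grid whose default step of 25 microseconds matches the 40 kHz acquisition
rate of the extracellular recordings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .circstats import CosineFit, fit_cosine
from .stimuli import VelocitySchedule

__all__ = [
    "RateSeries",
    "OnsetResult",
    "VelocityResponseFunction",
    "SPONTANEOUS_WINDOWS",
    "spike_rate",
    "mean_rate_window",
    "spontaneous_rate",
    "direction_tuning",
    "velocity_response_function",
    "response_onset_neural",
]

#: Pre-onset spontaneous-rate windows (s) used by the three protocols:
#: receptive-field mapping, optic-flow presentations, velocity trials.
SPONTANEOUS_WINDOWS = {"rf_mapping": 0.8, "optic_flow": 0.48, "velocity": 2.0}


@dataclass(frozen=True)
class RateSeries:
    """Spike rate (spikes/s) on a uniform time grid (s)."""

    t: np.ndarray
    rate: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.t, dtype=float)
        r = np.asarray(self.rate, dtype=float)
        if t.shape != r.shape:
            raise ValueError("t and rate must have equal shape")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "rate", r)

    @property
    def step(self) -> float:
        return float(self.t[1] - self.t[0]) if self.t.size > 1 else float("nan")


@dataclass(frozen=True)
class OnsetResult:
    """Response onset by the 80 %-of-mean rule.

    ``onset_time`` is seconds from stimulus onset, NaN when the signal
    never reaches threshold (or the window mean is degenerate, in which
    case ``degenerate`` is set).
    """

    onset_time: float
    threshold: float
    window: tuple[float, float]
    degenerate: bool = False

    @property
    def defined(self) -> bool:
        return np.isfinite(self.onset_time)


@dataclass(frozen=True)
class VelocityResponseFunction:
    """Per-velocity median response after stationary subtraction.

    ``repetition_values`` maps each velocity to the raw per-repetition
    responses (before subtraction); ``stationary`` is the mean response at
    velocity 0 that was subtracted from the medians.
    """

    velocities: np.ndarray
    medians: np.ndarray
    repetition_values: dict
    stationary: float
    missing_velocities: tuple = ()

    @property
    def n_reps(self) -> dict:
        return {v: len(r) for v, r in self.repetition_values.items()}


def _check_sorted(times: np.ndarray) -> np.ndarray:
    t = np.asarray(times, dtype=float).ravel()
    if t.size and np.any(np.diff(t) < 0):
        raise ValueError("spike times must be non-decreasing")
    return t


def spike_rate(
    times,
    t_start: float,
    t_stop: float,
    filter_width: float = 0.1,
    resolution: float = 2.5e-5,
) -> RateSeries:
    """Boxcar spike-rate estimate on a uniform grid over [t_start, t_stop].

    rate(t) = count in [t - w/2, t + w/2] / w.  Near the series boundary
    the window is truncated to the recorded interval and renormalised by
    its overlap, so a stationary train keeps an unbiased rate at the edges.
    An empty train gives an all-zero series.
    """
    if filter_width <= 0 or resolution <= 0:
        raise ValueError("filter_width and resolution must be positive")
    if t_stop <= t_start:
        raise ValueError("t_stop must exceed t_start")
    t = _check_sorted(times)
    n = int(np.floor((t_stop - t_start) / resolution + 1e-9)) + 1
    grid = t_start + resolution * np.arange(n)
    lo = np.maximum(grid - filter_width / 2.0, t_start)
    hi = np.minimum(grid + filter_width / 2.0, t_stop)
    counts = np.searchsorted(t, hi, side="right") - np.searchsorted(t, lo, side="left")
    width = hi - lo
    rate = counts / width
    return RateSeries(t=grid, rate=rate)


def mean_rate_window(times, t0: float, t1: float, skip: float = 0.0) -> float:
    """Mean spike frequency over [t0 + skip, t1] (spikes/s).

    The direction-tuning protocol uses a 1-s window skipping the first
    100 ms to avoid onset transients.
    """
    if t1 <= t0 + skip:
        raise ValueError("window must have positive duration after skip")
    t = _check_sorted(times)
    a, b = t0 + skip, t1
    count = np.searchsorted(t, b, side="right") - np.searchsorted(t, a, side="left")
    return float(count / (b - a))


def spontaneous_rate(
    times,
    stim_onset: float,
    mode: str = "rf_mapping",
    trial_start: float = 0.0,
) -> tuple[float, bool]:
    """Firing rate in the protocol's pre-onset window (spikes/s).

    ``mode`` selects the window length: 0.8 s (receptive-field mapping),
    0.48 s (optic-flow presentations) or 2.0 s (velocity trials).  When
    less pre-onset data exist than the window asks for, the available
    span is used and the returned flag is True.
    """
    if mode not in SPONTANEOUS_WINDOWS:
        raise ValueError(f"mode must be one of {sorted(SPONTANEOUS_WINDOWS)}")
    window = SPONTANEOUS_WINDOWS[mode]
    avail = stim_onset - trial_start
    if avail <= 0:
        raise ValueError("no pre-onset data available")
    truncated = avail < window
    w = min(window, avail)
    t = _check_sorted(times)
    count = np.searchsorted(t, stim_onset, side="left") - np.searchsorted(
        t, stim_onset - w, side="left"
    )
    return float(count / w), truncated


def direction_tuning(
    directions,
    rates,
    ventral_up: bool = False,
    mirror: bool = False,
) -> CosineFit:
    """Cosine fit to per-direction mean rates with display corrections.

    ``ventral_up`` rotates the fitted preferred direction by 180° (the
    animal is recorded ventral side up); ``mirror`` then reflects it
    across the vertical midline, theta -> (180 - theta) mod 360, to
    display left-side neurons as right-side ones.
    """
    fit = fit_cosine(directions, rates)
    phase = fit.preferred_phase
    if np.isfinite(phase):
        if ventral_up:
            phase = (phase + 180.0) % 360.0
        if mirror:
            phase = (180.0 - phase) % 360.0
    return CosineFit(
        baseline=fit.baseline,
        amplitude=fit.amplitude,
        preferred_phase=phase,
        rms_residual=fit.rms_residual,
    )


def velocity_response_function(
    trains,
    schedules,
    window: float = 1.0,
) -> VelocityResponseFunction:
    """Velocity response function from one or more velocity-step trials.

    For every step the mean spike frequency is taken over the final
    ``window`` seconds of the step; repetitions of each velocity are
    pooled across trials and summarised by their median; the across-
    repetition *mean* response at velocity 0 (the stationary stimulus) is
    subtracted from every median.  Velocities configured in a schedule
    but with no repetitions are reported in ``missing_velocities``.
    """
    if isinstance(schedules, VelocitySchedule):
        schedules = [schedules]
        trains = [trains]
    if len(trains) != len(schedules):
        raise ValueError("one spike train per schedule required")
    per_velocity: dict[float, list[float]] = {}
    for times, sched in zip(trains, schedules):
        t = _check_sorted(times)
        for _, v, onset, dur in sched.steps():
            w = min(window, dur)
            r = mean_rate_window(t, onset + dur - w, onset + dur)
            per_velocity.setdefault(float(v), []).append(r)
    if not per_velocity:
        raise ValueError("schedules contain no steps")
    missing = tuple(v for v, reps in per_velocity.items() if len(reps) == 0)
    per_velocity = {v: r for v, r in per_velocity.items() if r}
    stationary = float(np.mean(per_velocity[0.0])) if 0.0 in per_velocity else 0.0
    velocities = np.array(sorted(per_velocity))
    medians = np.array([np.median(per_velocity[v]) - stationary for v in velocities])
    return VelocityResponseFunction(
        velocities=velocities,
        medians=medians,
        repetition_values={v: tuple(per_velocity[v]) for v in velocities},
        stationary=stationary,
        missing_velocities=missing,
    )


def response_onset_neural(
    rate: RateSeries,
    stim_onset: float,
    duration: float = 0.97,
    skip: float = 0.1,
) -> OnsetResult:
    """Neural response onset: first grid point after ``skip`` where the
    rate reaches 80 % of its mean over [onset + skip, onset + duration].

    Returns onset in seconds from stimulus onset; NaN (flagged degenerate)
    when the window mean is zero, NaN (not degenerate) when the rate never
    reaches threshold.
    """
    if duration <= skip:
        raise ValueError("duration must exceed skip")
    sel = (rate.t >= stim_onset + skip - 1e-12) & (rate.t <= stim_onset + duration + 1e-12)
    if not np.any(sel):
        raise ValueError("rate series does not cover the analysis window")
    window_rate = rate.rate[sel]
    window_t = rate.t[sel]
    m = float(np.mean(window_rate))
    thresh = 0.8 * m
    win = (skip, duration)
    if m <= 0:
        return OnsetResult(float("nan"), thresh, win, degenerate=True)
    # >= with a whisker of numerical slack so exact crossings are not
    # missed to floating-point rounding
    hits = np.nonzero(window_rate >= thresh - 1e-9 * max(1.0, abs(thresh)))[0]
    if hits.size == 0:
        return OnsetResult(float("nan"), thresh, win)
    return OnsetResult(float(window_t[hits[0]] - stim_onset), thresh, win)
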