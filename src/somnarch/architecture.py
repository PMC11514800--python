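"""Hypnogram-derived sleep-architecture measures.

Time in state (% of total recording time of an analysis window), hourly
state traces, bout number and duration, post-SD NREM sleep-onset latency,
and sleep-deprivation efficiency.  Conventions:

* a bout is a maximal run of >= 2 consecutive same-state epochs (8 s at
  4-s epochs); shorter runs are excluded from bout lists but their epochs
  still count toward time in state;
* bouts spanning a window boundary are clipped, and the clipped segment
  must itself satisfy the minimum length to be counted in that window;
* the latency-qualifying NREM bout is >= 28 s (exactly 7 epochs at 4 s),
  enforced as an epoch count; sub-threshold NREM runs before it are
  ignored but their time elapses;
* artifact flags do not affect any measure here (they gate spectral
  analyses only).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import NREM, STATE_LABELS, WAKE, Hypnogram, Recording

MIN_BOUT_EPOCHS = 2
LATENCY_MIN_BOUT_S = 28.0


@dataclass(frozen=True)
class Bout:
    """Maximal same-state run: state code, start epoch, length."""

    state: int
    start_epoch: int
    n_epochs: int
    epoch_s: float = 4.0

    @property
    def duration_s(self) -> float:
        return self.n_epochs * self.epoch_s


def _runs(states: np.ndarray):
    """(starts, lengths, values) run-length encoding."""
    if states.size == 0:
        return np.array([], int), np.array([], int), np.array([], np.int8)
    change = np.flatnonzero(np.diff(states))
    starts = np.concatenate(([0], change + 1))
    ends = np.concatenate((change + 1, [states.size]))
    return starts, ends - starts, states[starts]


def detect_bouts(
    hypnogram: Hypnogram,
    min_epochs: int = MIN_BOUT_EPOCHS,
    window_h: tuple[float, float] | None = None,
) -> list[Bout]:
    """Qualifying bouts, optionally clipped to an analysis window.

    Runs are maximal over the full sequence; with ``window_h`` each run is
    intersected with the window and the clipped segment must itself reach
    ``min_epochs``.
    """
    if window_h is None:
        lo, hi = 0, hypnogram.n_epochs
    else:
        sl = hypnogram.window_index(*window_h)
        lo, hi = sl.start, sl.stop
    starts, lengths, values = _runs(hypnogram.states)
    bouts = []
    for st, m, v in zip(starts, lengths, values):
        a, b = max(st, lo), min(st + m, hi)
        if b - a >= min_epochs:
            bouts.append(Bout(int(v), int(a), int(b - a), hypnogram.epoch_s))
    return bouts


def phase_period_window(recording: Recording, phase: str, period: str) -> tuple[float, float]:
    """Analysis window in hours from recording start.

    Baseline light/dark are ZT [0, 12) / [12, 24).  The recovery "light
    period" is the light remaining after SD release ([SD end, lights-off)
    of day 2); recovery dark is the full dark period of day 2.
    """
    proto = recording.protocol
    sched = recording.hypnogram.schedule
    if phase == "baseline":
        b0, _ = proto.baseline
        if period == "light":
            return (b0 + sched.lights_on_h, b0 + sched.lights_off_h)
        if period == "dark":
            return (b0 + sched.lights_off_h, b0 + sched.period_h)
    elif phase == "recovery":
        day2 = proto.sd[0]
        if period == "light":
            return (proto.sd[1], day2 + sched.lights_off_h)
        if period == "dark":
            return (day2 + sched.lights_off_h, day2 + sched.period_h)
    raise ValueError(f"unknown phase/period {phase!r}/{period!r}")


def time_in_state(recording: Recording, phase: str, period: str) -> pd.DataFrame:
    """Percent of total recording time per state in a phase/period window.

    Artifact-flagged epochs retain their scored state; the three state
    percentages sum to 100 exactly (up to floating point).
    """
    window = phase_period_window(recording, phase, period)
    sl = recording.hypnogram.window_index(*window)
    states = recording.hypnogram.states[sl]
    if states.size == 0:
        raise ValueError(f"empty analysis window {window}")
    counts = np.bincount(states, minlength=3)
    pct = 100.0 * counts / states.size
    return pd.DataFrame(
        {
            "animal_id": recording.animal_id,
            "phase": phase,
            "period": period,
            "state": STATE_LABELS,
            "pct_trt": pct,
        }
    )


def hourly_time_in_state(recording: Recording) -> pd.DataFrame:
    """Per-hour state percentages over the whole recording.

    Each epoch is assigned to the hour containing its start time.  Hours
    are reported as hours from recording start (ZT = hour mod 24).
    """
    hyp = recording.hypnogram
    hour = (hyp.epoch_start_h()).astype(int)
    n_hours = int(np.ceil(hyp.duration_h - 1e-9))
    rows = []
    for h in range(n_hours):
        states = hyp.states[hour == h]
        counts = np.bincount(states, minlength=3)
        pct = 100.0 * counts / states.size
        for s, lab in enumerate(STATE_LABELS):
            rows.append((recording.animal_id, h, h % 24, lab, pct[s]))
    return pd.DataFrame(rows, columns=["animal_id", "hour", "zt_hour", "state", "pct_trt"])


def hourly_state_fraction(
    hypnogram: Hypnogram, state: int, start_h: float, end_h: float
) -> np.ndarray:
    """Fast per-hour occupancy of one state over ``[start_h, end_h)``."""
    sl = hypnogram.window_index(start_h, end_h)
    per_h = int(round(3600.0 / hypnogram.epoch_s))
    seg = hypnogram.states[sl]
    n_hours = seg.size // per_h
    seg = seg[: n_hours * per_h].reshape(n_hours, per_h)
    return (seg == state).mean(axis=1)


def nrem_latency_after_sd(
    recording: Recording, min_bout_s: float = LATENCY_MIN_BOUT_S
) -> float | None:
    """Minutes from SD release to the first qualifying NREM bout.

    The qualifying bout is the first maximal NREM run of at least
    ``min_bout_s`` (an exact epoch count; 28 s = 7 epochs at 4 s).
    Sub-threshold NREM runs before it are ignored but their time counts.
    Returns ``None`` (with a warning) if no qualifying bout exists.
    """
    hyp = recording.hypnogram
    min_epochs = int(np.ceil(min_bout_s / hyp.epoch_s - 1e-9))
    sd_end = hyp.window_index(*recording.protocol.sd).stop
    tail = hyp.states[sd_end:]
    starts, lengths, values = _runs(tail)
    for st, m, v in zip(starts, lengths, values):
        if v == NREM and m >= min_epochs:
            return st * hyp.epoch_s / 60.0
    warnings.warn(
        f"{recording.animal_id}: no NREM bout >= {min_bout_s:g} s in recovery; "
        "latency reported as missing",
        stacklevel=2,
    )
    return None


def sd_efficiency(recording: Recording) -> float:
    """Percent of epochs scored wake within the SD window."""
    sl = recording.hypnogram.window_index(*recording.protocol.sd)
    states = recording.hypnogram.states[sl]
    if states.size == 0:
        raise ValueError("SD window contains no epochs")
    return 100.0 * float(np.mean(states == WAKE))


def bout_statistics(recording: Recording, phase: str, period: str) -> pd.DataFrame:
    """Count and mean duration (s) of qualifying bouts per state.

    Zero bouts of a state give count 0 and missing duration.
    """
    window = phase_period_window(recording, phase, period)
    bouts = detect_bouts(recording.hypnogram, window_h=window)
    rows = []
    for s, lab in enumerate(STATE_LABELS):
        durs = [b.duration_s for b in bouts if b.state == s]
        rows.append(
            (
                recording.animal_id,
                phase,
                period,
                lab,
                len(durs),
                float(np.mean(durs)) if durs else np.nan,
            )
        )
    return pd.DataFrame(
        rows,
        columns=["animal_id", "phase", "period", "state", "bout_count", "mean_duration_s"],
    )


__all__ = [
    "Bout",
    "MIN_BOUT_EPOCHS",
    "LATENCY_MIN_BOUT_S",
    "detect_bouts",
    "phase_period_window",
    "time_in_state",
    "hourly_time_in_state",
    "hourly_state_fraction",
    "nrem_latency_after_sd",
    "sd_efficiency",
    "bout_statistics",
]
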