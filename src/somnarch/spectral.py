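"""Relative EEG power spectra, CI-overlap difference criterion, and the
normalized homeostatic NREM delta-power time course.

Normalization convention: per animal and phase, the *total power* is the
mean per-epoch power over all artifact-free epochs of that phase (pooling
all vigilance states), summed over the 0.05-50 Hz grid.  Each state's mean
spectrum divided by this scalar (x100) gives relative power in percent;
the occupancy-weighted sum over states and bins is then exactly 100%,
which makes state spectra comparable within an animal and is the
conservation law the tests check.

Sleep pressure is the recovery-period hourly NREM delta power (0.5-4 Hz)
divided by the animal's mean NREM delta power over the last four hours of
the baseline light period (ZT 8-12), computed epoch-weighted.  Any global
gain of an animal's spectra cancels in the ratio.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import DELTA_BAND, NREM, STATE_LABELS, Recording

#: baseline reference window for sleep-pressure normalization, ZT hours
PRESSURE_REFERENCE_ZT = (8.0, 12.0)


def _phase_window(recording: Recording, phase: str) -> tuple[float, float]:
    if phase == "baseline":
        return recording.protocol.baseline
    if phase == "recovery":
        return recording.protocol.recovery
    raise ValueError(f"unknown phase {phase!r}")


def relative_spectra(recording: Recording, phase: str) -> pd.DataFrame:
    """Per-state relative power spectra (% of total power) for one phase.

    Artifact epochs are excluded.  States with zero artifact-free epochs
    are reported missing with a warning; if every epoch is flagged the
    result is empty.
    """
    if recording.spectra is None:
        raise ValueError("recording has no spectra")
    hyp, spec = recording.hypnogram, recording.spectra
    sl = hyp.window_index(*_phase_window(recording, phase))
    states = hyp.states[sl]
    good = ~hyp.artifact[sl]
    power = spec.power[sl]
    if not good.any():
        warnings.warn(
            f"{recording.animal_id}/{phase}: all epochs artifact-flagged; "
            "no spectra available",
            stacklevel=2,
        )
        return pd.DataFrame(
            columns=["animal_id", "phase", "state", "freq_hz", "rel_power"]
        )
    total = power[good].mean(axis=0).sum()
    frames = []
    for s, lab in enumerate(STATE_LABELS):
        rows = good & (states == s)
        if not rows.any():
            warnings.warn(
                f"{recording.animal_id}/{phase}: no artifact-free {lab} epochs",
                stacklevel=2,
            )
            continue
        rel = 100.0 * power[rows].mean(axis=0) / total
        frames.append(
            pd.DataFrame(
                {
                    "animal_id": recording.animal_id,
                    "phase": phase,
                    "state": lab,
                    "freq_hz": spec.freqs,
                    "rel_power": rel,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def state_occupancy_weights(recording: Recording, phase: str) -> np.ndarray:
    """Artifact-free epoch fraction per state within a phase (sums to 1)."""
    hyp = recording.hypnogram
    sl = hyp.window_index(*_phase_window(recording, phase))
    states = hyp.states[sl][~hyp.artifact[sl]]
    counts = np.bincount(states, minlength=3)
    return counts / counts.sum()


def group_spectrum_ci(spectra: list[np.ndarray], level: float = 0.95):
    """Across-animal mean and two-sided t confidence interval per bin.

    ``spectra`` is a list of per-animal relative-power arrays on a common
    grid; the CI reflects biological replication (animals), never epochs.
    Returns ``(mean, lo, hi)``; with fewer than 2 animals the CI is NaN.
    """
    X = np.vstack(spectra)
    n = X.shape[0]
    mean = X.mean(axis=0)
    if n < 2:
        nan = np.full_like(mean, np.nan)
        return mean, nan, nan
    half = sps.t.ppf(0.5 + level / 2.0, n - 1) * X.std(axis=0, ddof=1) / np.sqrt(n)
    return mean, mean - half, mean + half


def spectral_difference_bins(ci_a, ci_b) -> np.ndarray:
    """Bins where two group 95% CIs fail to overlap.

    ``ci_a``/``ci_b`` are ``(mean, lo, hi)`` triples on the same grid.
    Touching endpoints count as overlap (not different); the criterion is
    symmetric in its arguments.
    """
    _, lo_a, hi_a = ci_a
    _, lo_b, hi_b = ci_b
    if lo_a.shape != lo_b.shape:
        raise ValueError("frequency grids of the two groups differ")
    return (hi_a < lo_b) | (hi_b < lo_a)


def _delta_sum(power: np.ndarray, freqs: np.ndarray) -> np.ndarray:
    lo, hi = DELTA_BAND
    mask = (freqs >= lo - 1e-9) & (freqs <= hi + 1e-9)
    return power[:, mask].sum(axis=1)


def nrem_delta_power(
    recording: Recording, window_h: tuple[float, float] | None = None
) -> pd.Series:
    """Hourly NREM delta power (0.5-4 Hz, bins by center) in a window.

    Per hour: mean over artifact-free NREM epochs of the summed delta-bin
    power.  Hours with no qualifying epoch are missing (NaN), never 0.
    """
    if recording.spectra is None:
        raise ValueError("recording has no spectra")
    hyp, spec = recording.hypnogram, recording.spectra
    if window_h is None:
        window_h = recording.protocol.recovery
    sl = hyp.window_index(*window_h)
    t_h = hyp.epoch_start_h()[sl]
    good = (hyp.states[sl] == NREM) & ~hyp.artifact[sl]
    delta = _delta_sum(spec.power[sl], spec.freqs)
    hours = np.arange(int(np.floor(window_h[0])), int(np.ceil(window_h[1] - 1e-9)))
    out = pd.Series(np.nan, index=pd.Index(hours, name="hour"), name="delta_power")
    hour_of = t_h.astype(int)
    for h in hours:
        rows = good & (hour_of == h)
        if rows.any():
            out.loc[h] = float(delta[rows].mean())
    return out


def pressure_reference(recording: Recording) -> float | None:
    """Epoch-weighted mean NREM delta power over baseline ZT 8-12.

    Returns ``None`` (with a warning) when the reference window has no
    artifact-free NREM epoch; such animals are excluded from the pressure
    analysis.
    """
    hyp, spec = recording.hypnogram, recording.spectra
    sl = hyp.window_index(*PRESSURE_REFERENCE_ZT)
    good = (hyp.states[sl] == NREM) & ~hyp.artifact[sl]
    if not good.any():
        warnings.warn(
            f"{recording.animal_id}: empty baseline reference window for "
            "sleep pressure; animal excluded",
            stacklevel=2,
        )
        return None
    return float(_delta_sum(spec.power[sl], spec.freqs)[good].mean())


def normalized_sleep_pressure(recording: Recording) -> pd.DataFrame:
    """Recovery hourly NREM delta normalized to the baseline reference.

    One row per recovery hour with at least one artifact-free NREM epoch;
    ``norm_delta`` = hourly delta / baseline ZT 8-12 reference.  Global
    rescaling of an animal's spectra leaves the series unchanged.
    """
    if recording.spectra is None:
        raise ValueError("recording has no spectra")
    ref = pressure_reference(recording)
    if ref is None:
        return pd.DataFrame(columns=["animal_id", "hour", "zt_hour", "norm_delta"])
    hourly = nrem_delta_power(recording, recording.protocol.recovery)
    out = (hourly / ref).rename("norm_delta").reset_index()
    out.insert(0, "animal_id", recording.animal_id)
    out["zt_hour"] = out["hour"] % 24
    return out[["animal_id", "hour", "zt_hour", "norm_delta"]]


__all__ = [
    "PRESSURE_REFERENCE_ZT",
    "relative_spectra",
    "state_occupancy_weights",
    "group_spectrum_ci",
    "spectral_difference_bins",
    "nrem_delta_power",
    "pressure_reference",
    "normalized_sleep_pressure",
]
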