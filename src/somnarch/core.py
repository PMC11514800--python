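"""Core data containers for polysomnography analysis.

The package works on epoch-scored recordings: a hypnogram (one vigilance
state per fixed-duration scoring epoch), optional per-epoch EEG power
spectra on a fixed frequency grid, and protocol/animal metadata.  Time is
expressed in hours from recording start; recordings start at lights-on, so
hour ``h`` of day 1 is Zeitgeber time ``ZT h`` and hour ``24 + h`` is
``ZT h`` of day 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

#: integer state codes used throughout (order matters for transition matrices)
WAKE, NREM, REM = 0, 1, 2
STATE_LABELS = ("WAKE", "NREM", "REM")
STATE_CODES = {lab: i for i, lab in enumerate(STATE_LABELS)}

SEXES = ("M", "F")
GENOTYPES = ("WT", "MUT")

#: frequency bands in Hz: homeostatic delta and the full analysed range
DELTA_BAND = (0.5, 4.0)
TOTAL_BAND = (0.05, 50.0)


@dataclass(frozen=True)
class LightSchedule:
    """12:12 light:dark schedule anchored at lights-on (ZT 0)."""

    lights_on_h: float = 0.0
    lights_off_h: float = 12.0
    period_h: float = 24.0

    def is_light(self, zt_h):
        """True where the given recording-time hours fall in the light period."""
        z = np.asarray(zt_h, dtype=float) % self.period_h
        return (z >= self.lights_on_h) & (z < self.lights_off_h)


@dataclass(frozen=True)
class Protocol:
    """Protocol windows in hours from recording start.

    Baseline day, enforced-wake sleep deprivation (SD) from lights-on of
    day 2, then undisturbed recovery to the end of the recording.
    """

    baseline: tuple[float, float] = (0.0, 24.0)
    sd: tuple[float, float] = (24.0, 29.0)
    recovery: tuple[float, float] = (29.0, 48.0)

    def __post_init__(self):
        b, s, r = self.baseline, self.sd, self.recovery
        for lo, hi in (b, s, r):
            if not hi > lo:
                raise ValueError(f"empty protocol window ({lo}, {hi})")
        if not (b[1] <= s[0] and s[1] <= r[0]):
            raise ValueError("protocol windows must be disjoint and ordered")
        if s[0] % 24.0 != 0.0:
            raise ValueError("SD window must begin at lights-on of day 2")

    @property
    def span_h(self) -> float:
        return self.recovery[1]

    @property
    def sd_hours(self) -> float:
        return self.sd[1] - self.sd[0]


@dataclass
class Hypnogram:
    """Epoch-by-epoch vigilance-state sequence of one animal.

    Parameters
    ----------
    animal_id : str
    states : array of int8
        One of WAKE/NREM/REM per epoch.
    artifact : bool array
        Epochs whose EEG contains artifacts.  Artifact epochs keep their
        scored state for time-in-state/bout analyses and are excluded from
        spectral analyses only.
    epoch_s : float
        Scoring epoch length in seconds (4 s by convention).
    start_zt_h : float
        ZT of the first epoch (0 = lights-on).
    """

    animal_id: str
    states: np.ndarray
    artifact: np.ndarray = None
    epoch_s: float = 4.0
    start_zt_h: float = 0.0
    schedule: LightSchedule = field(default_factory=LightSchedule)

    def __post_init__(self):
        self.states = np.asarray(self.states, dtype=np.int8)
        if self.states.ndim != 1:
            raise ValueError("states must be a 1-d sequence")
        if self.artifact is None:
            self.artifact = np.zeros(self.states.size, dtype=bool)
        self.artifact = np.asarray(self.artifact, dtype=bool)
        if self.artifact.shape != self.states.shape:
            raise ValueError("states and artifact must have the same length")
        if not self.epoch_s > 0:
            raise ValueError("epoch_s must be positive")
        if self.states.size and (self.states.min() < 0 or self.states.max() > 2):
            raise ValueError("states must be coded WAKE=0, NREM=1, REM=2")

    @property
    def n_epochs(self) -> int:
        return self.states.size

    @property
    def duration_h(self) -> float:
        return self.n_epochs * self.epoch_s / 3600.0

    def epoch_start_h(self) -> np.ndarray:
        """Start time of every epoch in hours from recording start."""
        return self.start_zt_h + np.arange(self.n_epochs) * (self.epoch_s / 3600.0)

    def window_index(self, start_h: float, end_h: float) -> slice:
        """Epoch slice whose start times fall in ``[start_h, end_h)``.

        Window edges are multiples of ``epoch_s`` in every protocol used
        here, so the slice is exact.
        """
        per_h = 3600.0 / self.epoch_s
        i0 = int(np.ceil((start_h - self.start_zt_h) * per_h - 1e-9))
        i1 = int(np.ceil((end_h - self.start_zt_h) * per_h - 1e-9))
        i0 = max(i0, 0)
        i1 = min(max(i1, i0), self.n_epochs)
        return slice(i0, i1)


@dataclass
class EpochSpectra:
    """Per-epoch EEG power on a fixed ascending frequency grid (Hz)."""

    freqs: np.ndarray
    power: np.ndarray
    band_edges: dict = field(
        default_factory=lambda: {"delta": DELTA_BAND, "total": TOTAL_BAND}
    )

    def __post_init__(self):
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.freqs.ndim != 1 or np.any(np.diff(self.freqs) <= 0):
            raise ValueError("frequency grid must be 1-d and strictly increasing")
        if self.power.ndim != 2 or self.power.shape[1] != self.freqs.size:
            raise ValueError("power must be (n_epochs, n_bins)")
        if np.any(self.power < 0):
            raise ValueError("power must be non-negative")

    @property
    def n_epochs(self) -> int:
        return self.power.shape[0]

    def band_mask(self, band: str | tuple[float, float]) -> np.ndarray:
        """Boolean mask of bins whose centers lie in the closed band."""
        lo, hi = self.band_edges[band] if isinstance(band, str) else band
        return (self.freqs >= lo - 1e-9) & (self.freqs <= hi + 1e-9)


@dataclass(frozen=True)
class AnimalMeta:
    """Animal identity, design cell, and exclusion scope."""

    animal_id: str
    sex: str
    genotype: str
    excluded: str = "none"  # none | recovery | all

    def __post_init__(self):
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.genotype not in GENOTYPES:
            raise ValueError(f"genotype must be one of {GENOTYPES}, got {self.genotype!r}")
        if self.excluded not in ("none", "recovery", "all"):
            raise ValueError("excluded must be 'none', 'recovery' or 'all'")


@dataclass
class Recording:
    """One animal's 48-h recording: hypnogram, optional spectra, metadata."""

    hypnogram: Hypnogram
    meta: AnimalMeta
    spectra: Optional[EpochSpectra] = None
    protocol: Protocol = field(default_factory=Protocol)
    acquisition: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.spectra is not None and self.spectra.n_epochs != self.hypnogram.n_epochs:
            raise ValueError("spectra row count must equal hypnogram epoch count")
        if self.hypnogram.duration_h + 1e-9 < self.protocol.span_h:
            raise ValueError(
                f"hypnogram covers {self.hypnogram.duration_h:.3f} h, "
                f"protocol requires {self.protocol.span_h:.3f} h"
            )

    @property
    def animal_id(self) -> str:
        return self.meta.animal_id


def recordings_for_phase(recordings, phase: str):
    """Filter a cohort by exclusion scope.

    Animals flagged ``excluded='all'`` never appear; ``excluded='recovery'``
    animals are dropped from recovery-phase analyses only (the study design:
    one animal lost to artifacts after sleep deprivation).
    """
    out = []
    for rec in recordings:
        if rec.meta.excluded == "all":
            continue
        if rec.meta.excluded == "recovery" and phase == "recovery":
            continue
        out.append(rec)
    return out


__all__ = [
    "WAKE",
    "NREM",
    "REM",
    "STATE_LABELS",
    "STATE_CODES",
    "SEXES",
    "GENOTYPES",
    "DELTA_BAND",
    "TOTAL_BAND",
    "LightSchedule",
    "Protocol",
    "Hypnogram",
    "EpochSpectra",
    "AnimalMeta",
    "Recording",
    "recordings_for_phase",
]
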