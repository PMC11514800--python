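"""Shared fixtures: tiny hand-built recordings and small simulated cohorts.

All inputs are generated programmatically; session-scoped cohorts are
shared across test modules to keep the suite fast.
"""

from __future__ import annotations

import numpy as np
import pytest

from somnarch.core import (
    NREM,
    REM,
    WAKE,
    AnimalMeta,
    EpochSpectra,
    Hypnogram,
    Protocol,
    Recording,
)
from somnarch.simulate import SimulationConfig, simulate_cohort


def states_from_string(text: str) -> np.ndarray:
    """'W W N N R' -> int8 state codes."""
    lut = {"W": WAKE, "N": NREM, "R": REM}
    return np.array([lut[c] for c in text.split()], dtype=np.int8)


@pytest.fixture
def make_hypnogram():
    def _make(text_or_states, epoch_s=4.0, artifact=None, animal_id="a0"):
        states = (
            states_from_string(text_or_states)
            if isinstance(text_or_states, str)
            else np.asarray(text_or_states, dtype=np.int8)
        )
        return Hypnogram(animal_id, states, artifact=artifact, epoch_s=epoch_s)

    return _make


@pytest.fixture
def make_recording(make_hypnogram):
    """Recording with an arbitrary (short) protocol matched to the data."""

    def _make(text_or_states, epoch_s=4.0, protocol=None, spectra=None,
              artifact=None, sex="M", genotype="WT", animal_id="a0"):
        hyp = make_hypnogram(text_or_states, epoch_s=epoch_s, artifact=artifact,
                             animal_id=animal_id)
        if protocol is None:
            span = hyp.duration_h
            protocol = Protocol(
                baseline=(0.0, span * 0.5),
                sd=(span * 0.5, span * 0.75),
                recovery=(span * 0.75, span),
            ) if span >= 48 else None
        if protocol is None:
            raise ValueError("pass an explicit protocol for short recordings")
        return Recording(
            hypnogram=hyp,
            meta=AnimalMeta(animal_id, sex, genotype),
            spectra=spectra,
            protocol=protocol,
        )

    return _make


@pytest.fixture(scope="session")
def small_config():
    """2 animals per cell, full 48-h protocol, default study conditions."""
    return SimulationConfig(seed=42, n_per_group=2)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    """8 simulated recordings with spectra, plus generator ground truth."""
    return simulate_cohort(small_config, with_spectra=True)


@pytest.fixture(scope="session")
def hypnogram_cohort():
    """Full-size (28-animal) cohort without spectra; fast to simulate."""
    cfg = SimulationConfig(seed=7)
    recs, gt = simulate_cohort(cfg, with_spectra=False)
    return cfg, recs, gt
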