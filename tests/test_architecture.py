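"""Bout detection, time in state, latency, SD efficiency — including the
brute-force run-length and first-qualifying-run oracles."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from somnarch.architecture import (
    bout_statistics,
    detect_bouts,
    hourly_state_fraction,
    nrem_latency_after_sd,
    sd_efficiency,
    time_in_state,
)
from somnarch.core import NREM, REM, WAKE, Protocol

from conftest import states_from_string


# independent brute-force oracles -------------------------------------------


def rle_oracle(states):
    """Element-by-element run-length encoding."""
    runs = []
    for i, s in enumerate(states):
        if runs and runs[-1][0] == s:
            runs[-1][2] += 1
        else:
            runs.append([s, i, 1])
    return [(s, i, n) for s, i, n in runs]


def latency_oracle(tail, min_epochs, epoch_s):
    """First NREM run of >= min_epochs, by scanning every start index."""
    for i in range(len(tail)):
        if tail[i] == NREM and (i == 0 or tail[i - 1] != NREM):
            n = 0
            while i + n < len(tail) and tail[i + n] == NREM:
                n += 1
            if n >= min_epochs:
                return i * epoch_s / 60.0
    return None


# bouts ----------------------------------------------------------------------


def test_bout_examples(make_hypnogram):
    bouts = detect_bouts(make_hypnogram("W W N N N W"))
    assert [(b.state, b.start_epoch, b.n_epochs) for b in bouts] == [
        (WAKE, 0, 2),
        (NREM, 2, 3),
    ]
    assert detect_bouts(make_hypnogram("W N W N W")) == []


def test_bout_clipping_reapplies_min_length(make_hypnogram):
    # NREM run spans the boundary at epoch 4: left clip 3 epochs counts,
    # right clip 1 epoch does not
    hyp = make_hypnogram("W N N N N W W W")
    left = detect_bouts(hyp, window_h=(0, 4 * hyp.epoch_s / 3600))
    right = detect_bouts(hyp, window_h=(4 * hyp.epoch_s / 3600, 8 * hyp.epoch_s / 3600))
    assert [(b.state, b.n_epochs) for b in left] == [(NREM, 3)]
    assert [(b.state, b.n_epochs) for b in right] == [(WAKE, 3)]


def test_bouts_match_rle_oracle_randomized(make_hypnogram):
    rng = np.random.default_rng(0)
    for _ in range(300):
        states = rng.integers(0, 3, size=rng.integers(1, 500)).astype(np.int8)
        hyp = make_hypnogram(states)
        expected = [
            (s, i, n) for s, i, n in rle_oracle(states.tolist()) if n >= 2
        ]
        got = [(b.state, b.start_epoch, b.n_epochs) for b in detect_bouts(hyp)]
        assert got == expected


@settings(deadline=None, max_examples=60, derandomize=True)
@given(st.lists(st.integers(0, 2), min_size=1, max_size=200))
def test_bout_epochs_never_exceed_state_epochs(states):
    from somnarch.core import Hypnogram

    hyp = Hypnogram("h", np.array(states, np.int8))
    for s in (WAKE, NREM, REM):
        in_bouts = sum(b.n_epochs for b in detect_bouts(hyp) if b.state == s)
        assert in_bouts <= int(np.sum(hyp.states == s))


# time in state --------------------------------------------------------------


def _proto_48():
    return Protocol()


def test_time_in_state_counts(make_recording):
    # 48 h of repeating W,W,N,N,N,R,R,N,W,W -> 40% W, 40% N, 20% R
    pattern = states_from_string("W W N N N R R N W W")
    states = np.tile(pattern, 4320)
    rec = make_recording(states, protocol=_proto_48())
    tis = time_in_state(rec, "baseline", "light").set_index("state")["pct_trt"]
    assert tis["WAKE"] == pytest.approx(40.0)
    assert tis["NREM"] == pytest.approx(40.0)
    assert tis["REM"] == pytest.approx(20.0)
    assert tis.sum() == pytest.approx(100.0, abs=1e-9)


def test_recovery_light_window_starts_at_sd_end(make_recording):
    states = np.zeros(43200, np.int8)
    # only NREM between 29 h and 36 h
    states[26100:32400] = NREM
    rec = make_recording(states, protocol=_proto_48())
    tis = time_in_state(rec, "recovery", "light").set_index("state")["pct_trt"]
    assert tis["NREM"] == pytest.approx(100.0)
    dark = time_in_state(rec, "recovery", "dark").set_index("state")["pct_trt"]
    assert dark["WAKE"] == pytest.approx(100.0)


def test_time_in_state_ignores_artifact_flags(make_recording):
    states = np.tile(states_from_string("W N"), 21600)
    art = np.zeros(43200, bool)
    art[::3] = True
    rec_a = make_recording(states, artifact=art, protocol=_proto_48())
    rec_b = make_recording(states, protocol=_proto_48())
    a = time_in_state(rec_a, "baseline", "dark")["pct_trt"].to_numpy()
    b = time_in_state(rec_b, "baseline", "dark")["pct_trt"].to_numpy()
    assert np.array_equal(a, b)


def test_group_difference_recovers_injected_effect():
    from somnarch.simulate import GroupEffect, SimulationConfig, simulate_cohort

    eff = {("M", "MUT"): GroupEffect(occupancy_delta={"dark": (0.10, -0.085, -0.015)})}
    cfg = SimulationConfig(seed=44, n_per_group=5, effects=eff)
    recs, _ = simulate_cohort(cfg, with_spectra=False)
    means = {}
    for g in ("WT", "MUT"):
        vals = [
            time_in_state(r, "baseline", "dark").set_index("state")["pct_trt"]["WAKE"]
            for r in recs
            if r.meta.sex == "M" and r.meta.genotype == g
        ]
        means[g] = np.mean(vals)
    assert means["MUT"] - means["WT"] == pytest.approx(10.0, abs=4.0)


# latency ---------------------------------------------------------------------


def test_latency_zero_when_recovery_starts_with_qualifying_bout(make_recording):
    states = np.zeros(43200, np.int8)
    states[26100:26110] = NREM
    rec = make_recording(states, protocol=_proto_48())
    assert nrem_latency_after_sd(rec) == 0.0


def test_latency_ignores_subthreshold_runs(make_recording):
    states = np.zeros(43200, np.int8)
    i = 26100
    states[i + 15 : i + 21] = NREM  # 6 epochs: sub-threshold
    states[i + 25 : i + 40] = NREM  # qualifying
    rec = make_recording(states, protocol=_proto_48())
    assert nrem_latency_after_sd(rec) == pytest.approx((15 + 6 + 4) * 4 / 60.0)


def test_latency_missing_is_none_with_warning(make_recording):
    states = np.zeros(43200, np.int8)
    rec = make_recording(states, protocol=_proto_48())
    with pytest.warns(UserWarning, match="missing"):
        assert nrem_latency_after_sd(rec) is None


def test_latency_monotone_in_threshold(make_recording):
    rng = np.random.default_rng(1)
    states = rng.integers(0, 3, 43200).astype(np.int8)
    rec = make_recording(states, protocol=_proto_48())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        lats = [nrem_latency_after_sd(rec, min_bout_s=s) for s in (4, 8, 16, 28)]
    lats = [l for l in lats if l is not None]
    assert lats == sorted(lats)


def test_latency_matches_scan_oracle(make_recording):
    rng = np.random.default_rng(2)
    for _ in range(200):
        states = np.zeros(43200, np.int8)
        tail = rng.integers(0, 3, size=900).astype(np.int8)
        states[26100 : 26100 + 900] = tail
        rec = make_recording(states, protocol=_proto_48())
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            got = nrem_latency_after_sd(rec)
        assert got == latency_oracle(tail.tolist(), 7, 4.0)


# SD efficiency ---------------------------------------------------------------


def test_sd_efficiency_arithmetic(make_recording):
    states = np.zeros(43200, np.int8)
    sd = slice(21600, 26100)
    states[sd] = WAKE
    states[21600 : 21600 + 90] = NREM  # 90 sleep epochs of 4500
    rec = make_recording(states, protocol=_proto_48())
    assert sd_efficiency(rec) == pytest.approx(100.0 * 4410 / 4500)


def test_simulated_cohort_efficiency_near_target(hypnogram_cohort):
    _, recs, _ = hypnogram_cohort
    mean_eff = np.mean([sd_efficiency(r) for r in recs])
    assert 95.0 <= mean_eff <= 99.0


# bout statistics -------------------------------------------------------------


def test_bout_statistics_example(make_recording):
    states = np.tile(states_from_string("N N N W W N N W W W"), 4320)
    rec = make_recording(states, protocol=_proto_48())
    stats = bout_statistics(rec, "baseline", "light").set_index("state")
    # per repeat: NREM 3+2 epochs in 2 bouts, WAKE 2+3 in 2 bouts
    assert stats.loc["NREM", "bout_count"] == 2 * 10800 // 10
    assert stats.loc["NREM", "mean_duration_s"] == pytest.approx(10.0)
    assert stats.loc["WAKE", "mean_duration_s"] == pytest.approx(10.0)
    assert stats.loc["REM", "bout_count"] == 0
    assert np.isnan(stats.loc["REM", "mean_duration_s"])


def test_hourly_state_fraction_reshape(make_hypnogram):
    states = np.tile(states_from_string("W N N N"), 10800)
    hyp = make_hypnogram(states)
    frac = hourly_state_fraction(hyp, NREM, 0, 48)
    assert frac.shape == (48,)
    assert np.allclose(frac, 0.75)
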