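"""Synthetic polysomnography generator.

Produces cohorts of 48-h recordings with the statistical structure the
analysis pipeline assumes:

* circadian vigilance-state dynamics as a discrete-time Markov chain with
  separate transition matrices for the light and dark period,
* a two-process (Process S) homeostat: sleep pressure rises exponentially
  toward an upper asymptote during wake/REM and discharges toward a lower
  asymptote during NREM sleep,
* state-specific EEG spectral templates (NREM delta peak, REM theta peak)
  with animal-level gain/shape variability and epoch-level noise; NREM
  delta bins are scaled by the instantaneous sleep pressure,
* a 5-h enforced-wake sleep-deprivation (SD) window from lights-on of
  day 2, calibrated to a configurable wake efficiency with brief sleep
  intrusions preserved,
* configurable sex x genotype effects on state occupancy, NREM delta
  power, and post-SD sleep-onset latency.

Transition matrices are built from target stationary occupancies via
``P = (1 - r) I + r 1 pi^T``: each epoch the state is redrawn from ``pi``
with probability ``r``, so the stationary distribution is exactly ``pi``
and mean run length of state ``i`` is ``1 / (r (1 - pi_i))`` epochs.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

from .core import (
    WAKE,
    NREM,
    REM,
    SEXES,
    GENOTYPES,
    AnimalMeta,
    EpochSpectra,
    Hypnogram,
    LightSchedule,
    Protocol,
    Recording,
)

# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class ProcessSParams:
    """Two-process homeostat parameters (time constants in hours).

    ``tau_i`` governs the saturating rise of sleep pressure S toward
    ``upper`` during wake/REM; ``tau_d`` the exponential discharge toward
    ``lower`` during NREM sleep.  Defaults are canonical murine values.
    """

    tau_i: float = 8.0
    tau_d: float = 2.0
    s0: float = 0.6
    lower: float = 0.2
    upper: float = 1.1

    def __post_init__(self):
        if self.tau_i <= 0 or self.tau_d <= 0:
            raise ValueError("time constants must be positive")
        if not self.lower < self.upper:
            raise ValueError("lower asymptote must be below upper asymptote")
        if not (self.lower <= self.s0 <= self.upper):
            raise ValueError("s0 must lie between the asymptotes")


@dataclass(frozen=True)
class SpectralParams:
    """State spectral templates and noise structure.

    The grid is 0.25-Hz bins spanning (0, 50] Hz — the FFT resolution of a
    4-s epoch.  Templates are smooth positive curves: 1/f background plus a
    delta peak (NREM), a theta peak (REM), and a weak theta bump (wake).
    Animal-level variability is a log-normal scalar gain (cancels under
    relative normalization) plus a smooth log-amplitude shape perturbation
    (does not cancel; sets the width of between-animal CIs).  Epoch-level
    noise is i.i.d. log-normal per bin.
    """

    f_step: float = 0.25
    f_max: float = 50.0
    animal_gain_sd: float = 0.2
    animal_shape_sd: float = 0.08
    n_shape_modes: int = 4
    epoch_noise_sd: float = 0.15

    def freq_grid(self) -> np.ndarray:
        n = int(round(self.f_max / self.f_step))
        return np.arange(1, n + 1) * self.f_step

    def templates(self) -> np.ndarray:
        """(3, n_bins) noiseless state templates in arbitrary power units."""
        f = self.freq_grid()
        wake = 1.0 / (f + 1.0) + 0.25 * np.exp(-((f - 8.0) ** 2) / (2 * 2.0**2)) + 0.02
        nrem = 2.2 * np.exp(-((f - 1.5) ** 2) / (2 * 1.3**2)) + 0.8 / (f + 1.0) + 0.02
        rem = 1.6 * np.exp(-((f - 7.0) ** 2) / (2 * 1.2**2)) + 0.35 / (f + 1.0) + 0.02
        return np.vstack([wake, nrem, rem])


@dataclass(frozen=True)
class GroupEffect:
    """Per-group (sex, genotype) modifiers injected by the generator.

    ``occupancy_delta`` maps 'light'/'dark' to additive shifts of the
    stationary (wake, NREM, REM) occupancy, summing to ~0.
    ``nrem_delta_factor`` multiplies the NREM template in the delta band.
    ``latency_extra_min`` is the mean of an exponential extra enforced-wake
    interval appended after SD release (post-SD sleep-onset latency shift).
    """

    occupancy_delta: dict = field(default_factory=dict)
    nrem_delta_factor: float = 1.0
    latency_extra_min: float = 0.0

    def __post_init__(self):
        for block, d in self.occupancy_delta.items():
            if block not in ("light", "dark"):
                raise ValueError(f"unknown circadian block {block!r}")
            if abs(sum(d)) > 1e-9:
                raise ValueError("occupancy deltas must sum to 0")
        if self.nrem_delta_factor <= 0:
            raise ValueError("nrem_delta_factor must be positive")
        if self.latency_extra_min < 0:
            raise ValueError("latency_extra_min must be non-negative")


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters of the synthetic cohort.

    Defaults reproduce the study conditions: 4-s epochs, 48-h protocol
    (24-h baseline, 5-h SD from lights-on of day 2, 19-h recovery),
    7 animals per sex x genotype cell, 12:12 light:dark, SD wake
    efficiency 97%.  Occupancies are set to wild-type printed group means
    (light: 36/56/8% wake/NREM/REM; dark: 69/28.5/2.5%).
    """

    epoch_s: float = 4.0
    n_per_group: int = 7
    occupancy: dict = field(
        default_factory=lambda: {
            "light": (0.36, 0.56, 0.08),
            "dark": (0.69, 0.285, 0.025),
        }
    )
    switch_rate: float = 0.06
    transition_matrices: dict | None = None
    process_s: ProcessSParams = field(default_factory=ProcessSParams)
    spectral: SpectralParams = field(default_factory=SpectralParams)
    effects: dict = field(default_factory=dict)
    artifact_fraction: float = 0.02
    sd_window: tuple[float, float] = (0.0, 5.0)
    sd_efficiency_target: float = 0.97
    protocol: Protocol = None
    seed: int = 0

    def __post_init__(self):
        if self.protocol is None:
            sd0, sd1 = self.sd_window
            object.__setattr__(
                self, "protocol", Protocol(sd=(24.0 + sd0, 24.0 + sd1), recovery=(24.0 + sd1, 48.0))
            )
        if not 0.5 < self.sd_efficiency_target <= 1.0:
            raise ValueError("sd_efficiency_target must be in (0.5, 1]")
        if not 0 < self.switch_rate <= 1:
            raise ValueError("switch_rate must be in (0, 1]")
        if not 0 <= self.artifact_fraction < 1:
            raise ValueError("artifact_fraction must be in [0, 1)")
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        for block in ("light", "dark"):
            pi = np.asarray(self.occupancy[block], float)
            if pi.shape != (3,) or np.any(pi <= 0) or abs(pi.sum() - 1) > 1e-9:
                raise ValueError(f"{block} occupancy must be 3 positive values summing to 1")
        if self.transition_matrices is not None:
            for block in ("light", "dark"):
                _validate_matrix(np.asarray(self.transition_matrices[block], float), block)

    # -- derived quantities -------------------------------------------------

    @property
    def n_epochs(self) -> int:
        return int(round(self.protocol.span_h * 3600.0 / self.epoch_s))

    def effect_for(self, meta: AnimalMeta) -> GroupEffect:
        return self.effects.get((meta.sex, meta.genotype), GroupEffect())

    def group_occupancy(self, block: str, effect: GroupEffect) -> np.ndarray:
        pi = np.asarray(self.occupancy[block], float)
        if block in effect.occupancy_delta:
            pi = pi + np.asarray(effect.occupancy_delta[block], float)
        if np.any(pi <= 0) or np.any(pi >= 1):
            raise ValueError("occupancy effect pushes a state probability out of (0, 1)")
        return pi / pi.sum()

    def transition_matrix(self, block: str, effect: GroupEffect | None = None) -> np.ndarray:
        """3x3 transition matrix for a circadian block, effects applied."""
        if self.transition_matrices is not None:
            return np.asarray(self.transition_matrices[block], float)
        pi = self.group_occupancy(block, effect or GroupEffect())
        return build_transition_matrix(pi, self.switch_rate)


def _validate_matrix(P: np.ndarray, name: str) -> None:
    if P.shape != (3, 3) or np.any(P < 0):
        raise ValueError(f"{name} transition matrix must be 3x3 non-negative")
    if np.any(np.abs(P.sum(axis=1) - 1.0) > 1e-12):
        raise ValueError(f"rows of the {name} transition matrix must sum to 1")
    if np.any(np.diag(P) >= 1.0 - 1e-12):
        raise ValueError(
            f"{name} transition matrix has an absorbing state (diagonal entry 1); "
            "this would yield a single infinite bout"
        )


def build_transition_matrix(pi, switch_rate: float) -> np.ndarray:
    """Matrix with stationary distribution ``pi`` via per-epoch redraw."""
    pi = np.asarray(pi, float)
    P = (1.0 - switch_rate) * np.eye(3) + switch_rate * np.tile(pi, (3, 1))
    _validate_matrix(P, "constructed")
    return P


def stationary_distribution(P: np.ndarray) -> np.ndarray:
    """Stationary distribution by eigen-analysis of ``P^T``."""
    w, v = np.linalg.eig(P.T)
    i = int(np.argmin(np.abs(w - 1.0)))
    pi = np.real(v[:, i])
    return pi / pi.sum()


# ---------------------------------------------------------------------------
# hypnogram simulation

_LIGHT, _DARK, _SD, _FORCED = 0, 1, 2, 3


@njit(cache=True)
def _markov_path(cum, block, s0, u):  # pragma: no cover - exercised via wrapper
    n = u.shape[0]
    out = np.empty(n, np.int8)
    s = s0
    for i in range(n):
        c = cum[block[i], s]
        r = u[i]
        if r < c[0]:
            s = 0
        elif r < c[1]:
            s = 1
        else:
            s = 2
        out[i] = s
    return out


_SD_MATRIX_CACHE: dict = {}


def _sd_matrix(P_light: np.ndarray, target: float) -> np.ndarray:
    """Enforced-wake chain: sleep draws are diverted to wake with
    probability ``q`` calibrated (by bisection on the stationary wake
    occupancy) so the expected wake fraction over the SD window equals
    ``target``, while brief sleep intrusions persist."""

    def modified(q):
        P = P_light.copy()
        sleep = P[:, [NREM, REM]]
        P[:, WAKE] += q * sleep.sum(axis=1)
        P[:, [NREM, REM]] = (1.0 - q) * sleep
        return P

    def wake_occ(q):
        return stationary_distribution(modified(q))[WAKE]

    key = (P_light.tobytes(), target)
    if key in _SD_MATRIX_CACHE:
        return _SD_MATRIX_CACHE[key]
    if wake_occ(0.0) >= target:
        out = P_light.copy()
    else:
        lo, hi = 0.0, 1.0
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if wake_occ(mid) < target:
                lo = mid
            else:
                hi = mid
        out = modified(0.5 * (lo + hi))
    _SD_MATRIX_CACHE[key] = out
    return out


def _block_index(config: SimulationConfig) -> np.ndarray:
    """Per-epoch circadian/protocol block (light, dark, SD)."""
    t_h = np.arange(config.n_epochs) * (config.epoch_s / 3600.0)
    sched = LightSchedule()
    block = np.where(sched.is_light(t_h), _LIGHT, _DARK).astype(np.int8)
    sd0, sd1 = config.protocol.sd
    block[(t_h >= sd0) & (t_h < sd1)] = _SD
    return block


def _animal_rng(config: SimulationConfig, meta: AnimalMeta) -> np.random.Generator:
    """Deterministic per-animal stream derived from the master seed."""
    return np.random.default_rng(
        np.random.SeedSequence([config.seed, zlib.crc32(meta.animal_id.encode())])
    )


def simulate_hypnogram(
    config: SimulationConfig,
    meta: AnimalMeta,
    rng: np.random.Generator | None = None,
    block: np.ndarray | None = None,
) -> Hypnogram:
    """Simulate one animal's 48-h hypnogram.

    States are drawn from the light/dark Markov chain of the animal's
    group; the SD window uses the efficiency-calibrated enforced-wake
    chain; an optional group latency effect appends forced wake after SD
    release.  Artifact epochs are flagged independently at
    ``config.artifact_fraction``.
    """
    rng = rng if rng is not None else _animal_rng(config, meta)
    effect = config.effect_for(meta)
    P_light = config.transition_matrix("light", effect)
    P_dark = config.transition_matrix("dark", effect)
    P_sd = _sd_matrix(P_light, config.sd_efficiency_target)
    forced = np.zeros((3, 3))
    forced[:, WAKE] = 1.0
    cum = np.cumsum(np.stack([P_light, P_dark, P_sd, forced]), axis=2)

    block = (block if block is not None else _block_index(config)).copy()
    per_h = 3600.0 / config.epoch_s
    if effect.latency_extra_min > 0:
        extra = int(round(rng.exponential(effect.latency_extra_min) * 60.0 / config.epoch_s))
        i0 = int(round(config.protocol.sd[1] * per_h))
        block[i0 : i0 + extra] = _FORCED

    pi0 = stationary_distribution(P_light)
    s0 = int(rng.choice(3, p=pi0))
    u = rng.random(config.n_epochs)
    states = _markov_path(cum, block, s0, u)
    artifact = rng.random(config.n_epochs) < config.artifact_fraction
    return Hypnogram(
        animal_id=meta.animal_id,
        states=states,
        artifact=artifact,
        epoch_s=config.epoch_s,
    )


# ---------------------------------------------------------------------------
# Process S

def _branch_runs(states: np.ndarray):
    """Run-length encoding of the discharge branch (NREM) vs build branch.

    Returns (starts, lengths, is_nrem) of maximal constant-branch runs.
    """
    nrem = states == NREM
    change = np.flatnonzero(np.diff(nrem.astype(np.int8)))
    starts = np.concatenate(([0], change + 1))
    ends = np.concatenate((change + 1, [states.size]))
    return starts, ends - starts, nrem[starts]


def process_s_trajectory(
    states: np.ndarray, params: ProcessSParams, epoch_s: float
) -> np.ndarray:
    """Per-epoch Process-S values (value at each epoch's end).

    Within a run of ``m`` same-branch epochs the per-epoch exponential
    update composes exactly:  S_end = A + (S_start - A) exp(-m dt / tau),
    with A/tau the branch asymptote and time constant.
    """
    dt = epoch_s / 3600.0
    starts, lengths, is_nrem = _branch_runs(states)
    s = np.empty(states.size)
    cur = params.s0
    for st, m, dn in zip(starts, lengths, is_nrem):
        if dn:
            asym, tau = params.lower, params.tau_d
        else:
            asym, tau = params.upper, params.tau_i
        seg = asym + (cur - asym) * np.exp(-np.arange(1, m + 1) * dt / tau)
        s[st : st + m] = seg
        cur = seg[-1]
    return s


def simulate_process_s(hypnogram: Hypnogram, config: SimulationConfig) -> np.ndarray:
    """Ground-truth sleep-pressure trajectory for a simulated hypnogram."""
    return process_s_trajectory(hypnogram.states, config.process_s, hypnogram.epoch_s)


# ---------------------------------------------------------------------------
# spectra

def _shape_perturbation(rng, sp: SpectralParams) -> np.ndarray:
    """Smooth animal-level log-amplitude perturbation across the grid."""
    f = sp.freq_grid()
    x = np.log(f / f[0]) / np.log(f[-1] / f[0])
    log_amp = np.zeros(f.size)
    for k in range(1, sp.n_shape_modes + 1):
        log_amp += rng.normal(0.0, sp.animal_shape_sd) * np.cos(k * np.pi * x)
    return np.exp(log_amp)


def noiseless_templates(config: SimulationConfig, effect: GroupEffect) -> np.ndarray:
    """(3, n_bins) group-level templates with the delta effect applied."""
    sp = config.spectral
    T = sp.templates().copy()
    delta = (sp.freq_grid() >= 0.5) & (sp.freq_grid() <= 4.0)
    T[NREM, delta] *= effect.nrem_delta_factor
    return T


def simulate_spectra(
    hypnogram: Hypnogram,
    s_traj: np.ndarray,
    config: SimulationConfig,
    meta: AnimalMeta | None = None,
    rng: np.random.Generator | None = None,
) -> EpochSpectra:
    """Per-epoch power spectra coupled to state and sleep pressure.

    power(epoch, bin) = template[state] x animal gain x animal shape
    x epoch noise, with NREM delta bins additionally scaled by S(t)
    (the template represents delta power at S = 1).
    """
    if s_traj.shape != hypnogram.states.shape:
        raise ValueError("S trajectory must align with the hypnogram")
    rng = rng if rng is not None else np.random.default_rng(0)
    sp = config.spectral
    effect = config.effect_for(meta) if meta is not None else GroupEffect()
    T = noiseless_templates(config, effect)
    f = sp.freq_grid()
    delta = (f >= 0.5) & (f <= 4.0)

    gain = rng.lognormal(0.0, sp.animal_gain_sd) if sp.animal_gain_sd > 0 else 1.0
    shape = _shape_perturbation(rng, sp) if sp.animal_shape_sd > 0 else np.ones(f.size)
    power = T[hypnogram.states] * (gain * shape)
    nrem_rows = hypnogram.states == NREM
    power[np.ix_(nrem_rows, delta)] *= s_traj[nrem_rows, None]
    if sp.epoch_noise_sd > 0:
        power *= rng.lognormal(0.0, sp.epoch_noise_sd, size=power.shape)
    return EpochSpectra(freqs=f, power=power)


# ---------------------------------------------------------------------------
# cohorts


@dataclass
class GroundTruth:
    """What the generator actually injected, for parameter-recovery tests."""

    s_traj: dict = field(default_factory=dict)
    effects: dict = field(default_factory=dict)
    occupancy: dict = field(default_factory=dict)
    template_means: dict = field(default_factory=dict)


def cohort_metadata(config: SimulationConfig) -> list[AnimalMeta]:
    """Design cells in deterministic order: M/F x WT/MUT x n_per_group."""
    metas = []
    for sex in SEXES:
        for genotype in GENOTYPES:
            for i in range(config.n_per_group):
                metas.append(AnimalMeta(f"{sex}_{genotype}_{i:02d}", sex, genotype))
    return metas


def iter_cohort(config: SimulationConfig, with_spectra: bool = True):
    """Yield ``(Recording, per-animal ground truth dict)`` one at a time.

    Streaming keeps memory flat: a full cohort of per-epoch spectra is
    ~2 GB, one animal is ~70 MB.
    """
    block = _block_index(config)
    for meta in cohort_metadata(config):
        rng = _animal_rng(config, meta)
        hyp = simulate_hypnogram(config, meta, rng=rng, block=block)
        spectra = None
        s = None
        if with_spectra:
            s = simulate_process_s(hyp, config)
            spectra = simulate_spectra(hyp, s, config, meta=meta, rng=rng)
        rec = Recording(
            hypnogram=hyp,
            meta=meta,
            spectra=spectra,
            protocol=config.protocol,
            acquisition={"sample_rate_hz": 250, "bandpass_hz": [0.05, 50.0], "notch_hz": 60},
        )
        effect = config.effect_for(meta)
        truth = {
            "s_traj": s,
            "effect": effect,
            "occupancy": {b: config.group_occupancy(b, effect) for b in ("light", "dark")},
            "template_means": noiseless_templates(config, effect),
        }
        yield rec, truth


def simulate_cohort(config: SimulationConfig, with_spectra: bool = True):
    """Simulate the full cohort; returns ``(recordings, GroundTruth)``.

    Deterministic under a fixed ``config.seed``: per-animal streams are
    derived from the master seed and the animal id, so each animal's data
    is independent of cohort order and of whether spectra are generated
    (state draws precede spectral draws in the per-animal stream).
    """
    recordings, gt = [], GroundTruth()
    for rec, truth in iter_cohort(config, with_spectra=with_spectra):
        recordings.append(rec)
        gt.s_traj[rec.animal_id] = truth["s_traj"]
        gt.effects[rec.animal_id] = truth["effect"]
        gt.occupancy[rec.animal_id] = truth["occupancy"]
        gt.template_means[rec.animal_id] = truth["template_means"]
    return recordings, gt


def shank3_like_effects() -> dict:
    """Effect preset qualitatively mirroring the mutant phenotype.

    Mutant males: more dark-period wake / less NREM, longer post-SD
    latency.  Mutant females: less light-period sleep, more dark-period
    sleep, longest latencies.  Both sexes: reduced NREM delta power.
    """
    return {
        ("M", "MUT"): GroupEffect(
            occupancy_delta={"dark": (0.096, -0.089, -0.007)},
            nrem_delta_factor=0.8,
            latency_extra_min=14.0,
        ),
        ("F", "MUT"): GroupEffect(
            occupancy_delta={
                "light": (0.076, -0.068, -0.008),
                "dark": (-0.087, 0.072, 0.015),
            },
            nrem_delta_factor=0.8,
            latency_extra_min=31.0,
        ),
    }


__all__ = [
    "ProcessSParams",
    "SpectralParams",
    "GroupEffect",
    "SimulationConfig",
    "GroundTruth",
    "build_transition_matrix",
    "stationary_distribution",
    "simulate_hypnogram",
    "simulate_process_s",
    "process_s_trajectory",
    "simulate_spectra",
    "simulate_cohort",
    "iter_cohort",
    "cohort_metadata",
    "noiseless_templates",
    "shank3_like_effects",
]
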