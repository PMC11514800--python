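# somnarch

Sleep-architecture and sleep-homeostasis analysis for rodent
polysomnography, built around the standard mouse sleep-deprivation
protocol: 24 h of undisturbed baseline from lights-on (ZT 0), 5 h of
enforced wakefulness from lights-on of day 2, then undisturbed recovery
sleep. Input is epoch-scored data — a hypnogram (wake / NREM / REM per
4-s epoch) and, optionally, per-epoch EEG power spectra on a fixed
0.05–50 Hz grid — for cohorts crossed by sex and genotype.

The package is aimed at sleep/chronobiology labs that score recordings in
commercial software and want a reproducible, fully tested downstream
pipeline: state occupancy and bout structure, spectral phenotypes,
homeostatic sleep pressure, and the repeated-measures statistics that go
with a sex × genotype design. A synthetic-cohort generator with known
ground truth makes every stage verifiable without recorded data.

## What it computes

**Architecture** — time in state as % of total recording time (%TRT) per
light (ZT 0–12) and dark (ZT 12–24) period and per hour; bout number and
mean duration per state (a bout is a maximal run of ≥ 2 epochs, i.e. 8 s);
NREM sleep-onset latency after sleep deprivation (time from release to
the first NREM bout ≥ 28 s = 7 epochs); SD efficiency (% wake epochs
during the SD window).

**Spectra** — relative power per vigilance state: each state's mean
artifact-free spectrum as a percent of the animal's total power pooled
across states (0.05–50 Hz), so that the occupancy-weighted sum over
states and bins is exactly 100 %. Group comparison uses across-animal
95 % t-intervals per frequency bin; two groups *differ* in a bin iff
their intervals fail to overlap.

**Homeostasis** — hourly NREM delta power (0.5–4 Hz) during recovery,
normalized per animal to its mean NREM delta power over the last four
hours of the baseline light period (ZT 8–12). This is the operational
sleep-pressure measure: > 1 right after SD, discharging toward 1 as sleep
pressure dissipates. A two-process model can be fitted to the hourly
series (`ProcessSModel`): pressure *S* rises as
S ← U + (S − U)·e^(−Δt/τᵢ) during wake/REM and falls as
S ← L + (S − L)·e^(−Δt/τ_d) during NREM, with the build and discharge
time constants τᵢ, τ_d estimated by least squares.

**Statistics** — the study design's mixed (split-plot) repeated-measures
ANOVA: time as the within-subject factor, sex and genotype between.
Between terms are tested against the subjects-within-cells mean square,
within terms against the time × subjects mean square (classical
univariate partition; Greenhouse–Geisser available behind a flag). Post
hoc tests run only when a main effect of sex or genotype, or a
sex × time / genotype × time interaction, is significant; they are
unpaired Student t-tests (within sex across genotype and within genotype
across sex), except for sleep pressure, which uses per-comparison
two-group RM-ANOVAs to preserve the time course. All post hoc families
are Benjamini–Hochberg corrected.

**Simulation** — `SimulationConfig` / `simulate_cohort` generate cohorts
with circadian Markov-chain hypnograms (separate light/dark transition
matrices with prescribed stationary occupancies), Process-S-coupled NREM
delta power, state-specific spectral templates with animal- and
epoch-level noise, an SD window calibrated to a target wake efficiency
(default 97 %), and configurable group effects on occupancy, delta power,
and post-SD latency.

## Worked example

```python
from somnarch import (SimulationConfig, simulate_cohort, shank3_like_effects,
                      time_in_state, sd_efficiency, rm_anova)
from somnarch.architecture import hourly_state_fraction
import numpy as np, pandas as pd

cfg = SimulationConfig(seed=1, effects=shank3_like_effects())
recordings, truth = simulate_cohort(cfg, with_spectra=False)
print(len(recordings), "animals")

male_wt = [r for r in recordings if r.meta.sex == "M" and r.meta.genotype == "WT"]
male_mut = [r for r in recordings if r.meta.sex == "M" and r.meta.genotype == "MUT"]
dark_wake = lambda rs: np.mean(
    [time_in_state(r, "baseline", "dark").set_index("state").pct_trt["WAKE"] for r in rs])
print(f"dark wake %TRT  WT {dark_wake(male_wt):.1f}  MUT {dark_wake(male_mut):.1f}")
print(f"SD efficiency   {np.mean([sd_efficiency(r) for r in recordings]):.1f}%")

rows = [(r.animal_id, r.meta.sex, r.meta.genotype, h, 100 * f)
        for r in recordings
        for h, f in enumerate(hourly_state_fraction(r.hypnogram, 0, 13, 24))]
res = rm_anova(pd.DataFrame(rows, columns=["animal_id", "sex", "genotype", "hour", "pct"]),
               dv="pct")
print(res.summary())
```

prints

```
28 animals
dark wake %TRT  WT 70.1  MUT 78.9
SD efficiency   96.9%

Mixed-design repeated-measures ANOVA
  subjects: 28; time levels: 11; between: sex x genotype

  term                           F          df           p
  sex                     137.8154     (1, 24)   1.966e-11
  genotype                  0.0231     (1, 24)      0.8805
  sex:genotype             83.4369     (1, 24)   2.794e-09
  time                      1.4654   (10, 240)      0.1531
  sex:time                  0.6434   (10, 240)      0.7758
  genotype:time             0.6836   (10, 240)      0.7393
  sex:genotype:time         0.2561   (10, 240)      0.9895
```

— the injected phenotype: mutant males gain ~9 points of dark-period
wake while mutant females lose it, so the opposing shifts cancel in the
genotype main effect and surface as a strong sex × genotype interaction
(plus a sex main effect); the gated post hoc t-tests then localize the
genotype difference within each sex.

The same pipeline runs end to end from the shell:

```bash
somnarch simulate --seed 1 --out-dir cohort/          # stage/spectra files + manifest
somnarch run-all --manifest cohort/cohort.yaml --out-dir run/
somnarch report run/                                  # Markdown summary
```

## Layout

- `somnarch.core` — containers: `Hypnogram`, `EpochSpectra`, `Recording`,
  protocol/schedule types.
- `somnarch.simulate` — the synthetic-cohort generator and ground truth.
- `somnarch.io` — stage files (native CSV + tolerant scoring-export
  dialect), spectra matrices, YAML cohort manifests, metric tables.
- `somnarch.architecture` — bouts, %TRT, hourly traces, latency, SD
  efficiency.
- `somnarch.spectral` — relative spectra, group CIs, CI-overlap
  differences, delta power, normalized sleep pressure.
- `somnarch.homeostasis` — `ProcessSModel` / `ProcessSResults`.
- `somnarch.stats` — `MixedAnova` / `MixedAnovaResults`, within-group
  baseline-vs-recovery RM-ANOVA, post hoc gate/tests, Benjamini–Hochberg.
- `somnarch.pipeline`, `somnarch.cli` — orchestration, reports, CLI.

Methodological details and design decisions are documented in
`docs/methods.md`.
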