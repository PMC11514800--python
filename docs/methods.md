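# Methods

This note documents the models, conventions, and numerical choices behind
somnarch, and what the synthetic-data generator does and does not emulate.

## Conventions

- **Epochs and time.** Scoring epochs are 4 s; a 48-h recording has
  43,200 epochs. Time is counted in hours from recording start, which
  coincides with lights-on, so hour *h* mod 24 is Zeitgeber time.
  Each epoch belongs to the hour containing its start time. All protocol
  windows are multiples of the epoch length, so no epoch straddles a
  window boundary.
- **Periods.** Light = ZT [0, 12), dark = ZT [12, 24). The recovery
  "light period" is the light remaining after SD release, ZT [5, 12) of
  day 2; recovery dark is ZT [12, 24) of day 2. Published hour labels of
  the form "6–12" and "13–24" are 1-based labels of these same bins; the
  half-open ZT convention is used throughout.
- **Bouts.** A bout is a maximal same-state run of at least 2 epochs
  (8 s). Shorter runs never enter bout counts or durations but their
  epochs still count toward time in state. When bout statistics are
  computed per period, a run spanning the period boundary is clipped and
  the clipped segment must itself reach the 2-epoch minimum; boundary
  handling is not standardized in the field, so it is stated here and
  tested.
- **Latency.** NREM sleep-onset latency after SD is the time from SD
  release to the *start* of the first NREM run of ≥ 28 s. The threshold
  is enforced as an exact epoch count (7 epochs) to avoid floating-point
  comparisons. Sub-threshold NREM runs before the qualifying bout are
  ignored but their time elapses — the scan does not restart after them.
  An animal with no qualifying bout gets a missing latency (with a
  warning), never 0 or infinity.
- **Artifacts.** Artifact-flagged epochs keep their scored state for all
  hypnogram-derived measures and are excluded from all spectral
  computations only.

## Relative power spectra

Per animal and phase (baseline = hours [0, 24), recovery = hours after SD
release), the *total power* is the mean per-epoch power over all
artifact-free epochs of the phase, pooled across states and summed over
the 0.05–50 Hz grid. Each state's mean artifact-free spectrum divided by
this scalar, ×100, is its relative power. The published convention
("percent of total power across vigilance states") does not pin down the
denominator; pooling per animal-phase was chosen because it makes state
spectra comparable within an animal and yields an exact conservation law
(occupancy-weighted relative power sums to 100 %), which the tests
enforce. A per-state normalization would be a different, also defensible,
reading.

The default grid is 0.25-Hz bins spanning (0, 50] — the FFT resolution of
a 4-s epoch; file-backed grids override it. Band membership is by bin
center: delta = centers in [0.5, 4] Hz (15 bins on the default grid).

Group spectra are summarized by the across-animal mean and two-sided 95 %
t-interval per bin — biological replication only, never epochs as the
unit. Two groups differ in a bin iff their intervals are disjoint;
touching endpoints count as overlap. With 7 animals per group this
criterion is conservative relative to a per-bin test and is symmetric in
the groups.

## Normalized sleep pressure

Sleep pressure is recovery hourly NREM delta power divided by the
animal's reference: the epoch-weighted mean NREM delta power over
baseline ZT [8, 12) (the last four light hours, when pressure is lowest).
Epoch weighting (not a mean of hourly means) is stated because the
convention is otherwise ambiguous. The ratio cancels any per-animal gain,
so it is invariant to amplifier scaling. Recovery hours without an
artifact-free NREM epoch are missing and propagate as missing into group
means (no imputation); animals with an empty reference window are
excluded from the pressure analysis with a warning.

## The two-process homeostat

The generator and the `ProcessSModel` fitter share one model: sleep
pressure S follows a per-epoch exponential update with branch-specific
asymptote and time constant — toward the upper asymptote U with time
constant τᵢ during wake and REM, toward the lower asymptote L with τ_d
during NREM. The update composes exactly over runs of constant branch,
so trajectories are computed by run-length encoding with closed-form
segments (no ODE discretization error).

Defaults: τᵢ = 8 h, τ_d = 2 h, L = 0.2, U = 1.1, S₀ = 0.6 — canonical
murine magnitudes for delta-power homeostasis. NREM delta power is
proportional to S (the spectral template represents delta power at
S = 1), so normalized pressure ≈ S(t)/S(baseline ZT 8–12).

Under the default occupancies this yields a quasi-equilibrium S ≈ 0.37
in the light period and ≈ 0.57 in the dark; 5 h of enforced wake raises
S to ≈ 0.8, giving a first-recovery-hour normalized pressure near 2 that
discharges toward ~1.1 across the remaining light period. The dark
period then *rebuilds* pressure (wake-dominant active phase), so the
normalized series rises again after ZT 12 of the recovery day — the
discharge-shape checks therefore evaluate the post-SD light period,
which is the physiological discharge window.

Fitting estimates τᵢ and τ_d (log-parameterized, bounded to
[0.2, 100] h) by least squares on the hourly NREM delta series, with a
proportionality gain solved in closed form at each step; L, U, and S₀
are held at generator values. With both a baseline day and an SD
perturbation in the data the two time constants are well identified:
single-animal fits at default noise recover both within a few percent.

## The synthetic cohort generator

- **Hypnograms.** Discrete-time Markov chain over (wake, NREM, REM), one
  transition matrix per circadian block. Matrices are built from target
  stationary occupancies π via P = (1 − r)·I + r·**1**πᵀ (redraw from π
  with probability r each epoch), which makes the stationary distribution
  exactly π and gives geometric state runs with mean 1/(r(1 − π_state))
  epochs. Default r = 0.06 yields mean bouts of roughly 2 min (wake,
  light), 2.5 min (NREM), and 1.2 min (REM) — realistic murine scales.
  Default occupancies (light 36/56/8 %, dark 69/28.5/2.5 % for
  wake/NREM/REM) are wild-type group means of the study design this
  package targets. The construction permits rare direct wake→REM
  transitions (probability r·π_REM ≈ 0.0015 per epoch); tolerated for
  analytic transparency.
- **Circadian structure** is two matrices, not a continuous oscillator —
  matching the light/dark granularity of the analyses. The light→dark
  hand-off creates a genuine ~1-min occupancy transient at ZT 12 (the
  chain relaxes to the new stationary distribution); statistical
  calibration analyses therefore use ZT 13–24 as the steady-state dark
  window.
- **Sleep deprivation.** During the SD window the chain's sleep-bound
  transitions are diverted to wake with a probability q calibrated by
  bisection so the modified chain's stationary wake occupancy equals the
  efficiency target (default 0.97). Brief sleep intrusions persist, as
  in gentle-handling SD; realized cohort efficiencies land at ~97 ± 1 %.
- **Spectra.** Smooth positive state templates (1/f background; delta
  peak in NREM at 1.5 Hz; theta peak in REM at 7 Hz; weak theta bump in
  wake). Per animal: a log-normal scalar gain (σ = 0.2; cancels under
  relative normalization) and a smooth log-amplitude shape perturbation
  (4 cosine modes on log-frequency, σ = 0.08 each; does *not* cancel and
  sets between-animal CI width). Per epoch: i.i.d. log-normal noise per
  bin (σ = 0.15), small enough that per-epoch NREM delta tracks S with
  Spearman ρ ≈ 0.95. Artifacts are flagged independently per epoch
  (default 2 %).
- **Group effects** are additive occupancy shifts per block (summing to
  zero), a multiplicative NREM delta-band factor, and an exponential
  extra enforced-wake interval after SD release (mean in minutes) for
  latency phenotypes. `shank3_like_effects()` is a preset qualitatively
  matching the mutant phenotype the package was built around.
- **Determinism.** Every animal's random stream is derived from the
  master seed and the animal id (CRC-32), so cohorts are bit-reproducible
  and per-animal data do not depend on cohort order or on whether spectra
  are generated.

**What the generator does not emulate** — and hence what passing tests do
not show about recorded data: raw waveforms (only per-epoch spectra);
realistic single-epoch FFT variability (true per-epoch power is
χ²-distributed with CV near 1; the default epoch noise is far smaller so
that the S-coupling is visible per epoch); heavy-tailed and
stage-fragmentation bout structure (runs are geometric; published
bout-length distributions were not available to calibrate against); REM
homeostasis; a circadian (Process C) modulation of delta power;
scorer disagreement or state-dependent artifact rates.

## Statistics

- **Mixed-design RM-ANOVA.** Classical univariate split-plot partition;
  between terms (sex, genotype, sex × genotype) tested against
  subjects-within-cells, within terms (time and its interactions) against
  time × subjects-within-cells. Implementation is by Type-III model
  comparison with sum-to-zero coding, which reproduces the textbook
  marginal-means decomposition exactly on balanced designs (verified to
  1e-8 against an independent explicit sums-of-squares oracle, and
  against pingouin for single-between designs) and handles the
  near-balanced case (e.g. one excluded animal) conventionally.
- **Sphericity.** No correction by default — matching the uncorrected-df
  reporting convention of the target design; Greenhouse–Geisser is
  available via `fit(gg_correction=True)`. Under the generator's
  defaults, hourly occupancies are nearly exchangeable across hours and
  all seven terms' empirical type-I rates sit at 4–6.5 % at α = 0.05.
- **Degenerate inputs.** A constant dependent variable (zero error SS)
  reports F and p as missing rather than 0/0; subjects with incomplete
  time courses are dropped listwise with a warning; cells with fewer than
  2 subjects are an error.
- **Post hoc gate.** Comparisons run iff sex, genotype, sex × time, or
  genotype × time is significant at α = 0.05 (per-term, not
  family-adjusted — the gating convention of the target design). The
  four comparisons (each sex across genotype, each genotype across sex)
  form one BH family per measure.
- **t-tests** are two-sided Student (pooled variance) by default — the
  plain reading of "unpaired t-tests" — with Welch behind a flag.
- **Sleep-pressure post hocs** are per-comparison two-group RM-ANOVAs
  (group + group × time reported) to preserve the discharge time course;
  each term's four p-values form a BH family.
- **Baseline vs recovery** within a group is a fully within-subject
  two-factor RM-ANOVA (phase × hour) over matched ZT hours, each effect
  tested against its own effect × subject interaction; light
  (ZT [5, 12)) and dark (ZT [12, 24)) windows are analyzed separately.
- **Benjamini–Hochberg** adjustment delegates to statsmodels'
  `multipletests(method="fdr_bh")` and is tested against the hand-written
  step-up closed form; printed denominator dfs of any particular
  published table are not treated as a contract, since they depend on
  complete-case counts not recoverable from summaries.

## Problem sizes used by the test suite

Calibration checks simulate at the design's native size (28 animals,
43,200 epochs): 1,000 null cohorts for type-I rates, 200 cohorts for
power/effect recovery at a +10-point dark-wake effect, 100 single-animal
replicates for Process-S recovery, and single cohorts for spectral and
homeostatic shape checks. The Markov simulation is numba-accelerated and
cohorts stream one animal at a time, which keeps the full suite within a
few minutes and memory flat (~70 MB per animal with spectra).

## Known limitations

- The relative-power denominator choice (pooled per animal-phase) may
  differ from other labs' per-state normalization; conclusions about
  *relative* group differences are unaffected, absolute percentages are
  not comparable across conventions.
- The CI-overlap difference criterion has no formal error-rate control;
  it is reported because it is the field's convention, with its empirical
  behavior (localization and false-flag rate) characterized in tests.
- The Process-S fit conditions on known asymptotes; with free asymptotes
  the gain is only jointly identified and recovery would need longer
  recordings or multiple SD challenges.
- Bout-length realism is qualitative only (geometric runs); analyses that
  depend on bout-length *distributions* beyond count and mean should not
  be validated against this generator.
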