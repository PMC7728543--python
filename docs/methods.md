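# Methods

## Signal model

A game session is modelled as a phone resting on the palm for
`session_duration_s` (default 10 s), sampling at a nominal
`nominal_rate_hz` (default 50 Hz). The simulated acceleration is

    a(t) = g·n + m·A·sin(φ(t))·n + ε(t),

with gravity g = 9.81 m/s² along the unit axis `n`, tremor amplitude
`A` (m/s²), medication multiplier `m ∈ [0, 1]`, and i.i.d. Gaussian
noise `ε` of standard deviation `noise_sd` per axis. The tremor is
applied **along the gravity axis**: the analysis pipeline reduces the
triaxial signal to its Euclidean magnitude, and for an oscillation
orthogonal to a dominant gravity component the magnitude is
`√(g² + a²) ≈ g + a²/2g`, which doubles the apparent frequency and
suppresses the amplitude. The vertical bobbing of a palm-held phone is
also the physically dominant component. Simulations therefore exercise
the raw-accelerometer path (gravity present, removed later as the
session mean) rather than a gravity-free linear-acceleration stream.

The instantaneous frequency wanders as a slow Gaussian random walk
(step s.d. `freq_jitter_hz·√Δt`, i.e. a drift of roughly
`freq_jitter_hz` per second) clipped to ±3·`freq_jitter_hz` around the
centre frequency — real tremor is not a pure tone, but F0 must stay
well-defined. The phase starts at a uniformly random angle.

Sampling-time irregularity has three regimes: `none` (exact grid, for
oracles), `gaussian` (each inter-sample interval perturbed with s.d.
`timing_jitter_frac`·nominal interval, default 0.1 ≙ 2 ms at 50 Hz —
the scale of smartphone sensor-timestamp scheduling jitter), and
`dropout-burst` (one or two windows of 0.5–1.5 s during which only
every fifth sample survives, mimicking devices whose effective rate
collapses intermittently). Timestamps are strictly increasing and span
≈ the session duration in all regimes.

### Default study conditions

The generator defaults define the simulated study: 10 s sessions at
nominal 50 Hz with Gaussian timing jitter; tremor at 5 Hz with 0.1 Hz
frequency wander; amplitude 0.5 m/s²; noise s.d. 0.1 m/s² (signal power
A²/2 = 0.125 vs noise power 0.01 per axis ⇒ SNR ≈ 11 dB). The bundled
cohort template mirrors the study composition: 11 participants — 3
without tremor, 4 with tremor in an unspecified location, 2 with hand
tremor playing with the unaffected hand, 2 playing with the affected
hand — with tremor amplitude mapped from the self-reported UPDRS II
tremor item (0→0.02, 1→0.2, 2→0.45, 3→0.9 m/s²) and a ×2.2 boost when
the affected hand holds the phone, tremor frequencies spread over the
rest (3–6 Hz) and postural (6–9 Hz) bands, and regimens of 2–4 intakes
per day. Session times are scattered uniformly over the waking day
(07:30–22:30) with non-overlapping starts; the real distribution of
play times relative to intakes is unknown, so uniform scatter is a
modelling choice, not an observed property.

### Medication effect

A piecewise-linear amplitude multiplier of minutes-since-intake: 1
before `onset_min` (default 15 min, the minimum time oral PD medication
needs to act), falling linearly to `1 − attenuation` at `peak_min`
(default 60 min), and returning linearly to 1 at `wearoff_min` (default
240 min, a typical levodopa duration). Default `attenuation` 0.5.
Sessions with no prior intake get multiplier 1.

## Preprocessing

Each axis is linearly interpolated onto the grid `0, 1/r, 2/r, …` (r =
target rate, default 50 Hz) anchored at the first sample and truncated
at the last — interpolation only, never extrapolation. Grid points
coinciding with input timestamps reproduce the input exactly. The
scalar series is the per-sample Euclidean magnitude minus its session
mean; single-axis reductions are available for sensitivity analyses.
Sessions spanning under 5 s after resampling are rejected as malformed
(degenerate recordings — e.g. single-sample sessions — carry too few
Welch segments to be comparable).

**Known bias.** Linear interpolation of misaligned samples attenuates a
tone's power by ≈ (2πf/fs)²/6 — about 1.5% at 3 Hz, 6.5% at 5 Hz, and
growing quadratically toward the top of the band at fs = 50 Hz. The
effect depends on f/fs, not on the jitter magnitude; it biases
absolute band powers low at higher tremor frequencies but leaves peak
locations (F0, F50) and cross-session comparisons at a common frequency
intact. The test suite pins this attenuation to its analytic value.

## Spectral estimation and features

Welch PSD with Hann window, 2.56 s segments (128 samples at 50 Hz, ⇒
bin width 50/128 ≈ 0.39 Hz), 50% overlap, constant detrend, density
scaling — about 7 averaged segments per 10 s session, a deliberate
balance of resolution against variance; all parameters configurable.
Density scaling makes ∫PSD df ≈ signal variance (Parseval, up to
windowing bias; verified within 10%).

Features are computed inside the 1–12 Hz analysis band (sub-1 Hz
posture drift excluded; all interpretation bands lie within):

- **PV, F0**: in-band PSD maximum and its frequency; ties broken toward
  the lowest frequency for determinism.
- **F50**: smallest grid frequency at which the cumulative in-band
  power (discrete sum over bins) reaches 50% of the in-band total. No
  sub-bin interpolation — F50 always lies on the grid.
- **SF50**: `f(84%) − f(16%)` of the same cumulative curve — the
  power-central band holding 68% of the in-band power. The alternative
  frequency-symmetric reading (a band centred on F50) is not used; the
  quantile reading keeps the band central *in power*, which is what a
  dispersion measure should track. SF50 is floored at one bin width so
  TIP = PV/SF50 stays finite when all power concentrates in one bin.
- **AUC**: trapezoidal integral of the PSD. Band edges falling between
  grid points are linearly interpolated, so the four symptom-band AUCs
  tile the 1–12 Hz AUC exactly. Whether "total power" means the full
  spectrum or the analysis band is ambiguous in the field; both the
  per-band AUCs and the 1–12 Hz total (`auc_band`) are exported.
- **Category**: F0 mapped through the contiguous scheme dyskinesia
  [1, 3), rest [3, 6), postural [6, 9), kinetic [9, 12] — half-open
  intervals, last one closed.

Zero in-band power raises a dedicated error and the session is excluded
with a logged reason.

## Medication labeling

Nearest intake first (minimizing |session start − intake|, exact ties
to the earlier intake), window rule second — a session is never
re-attributed to a farther intake whose window it would satisfy. For
≤ 2 intakes/day: before ⇔ −300 ≤ δ ≤ +15 min, after ⇔ +30 ≤ δ ≤ +180;
for > 2 intakes/day: before ⇔ −60 ≤ δ ≤ +15, after ⇔ +30 ≤ δ ≤ +90;
everything else excluded. Endpoints are inclusive ("between X and Y"
read inclusively). δ is measured from the session start (sessions last
10 s, so the midpoint distinction is immaterial). No cap by the
previous intake's window is applied; under the stated regimens' spacing
the windows cannot overlap.

## Statistics

- **Kendall tau-b** (tie-corrected) between per-session TIP and the
  participant's UPDRS II tremor item, with z = S/√var(S) using the
  classical tie-corrected null variance and a two-sided normal p. The
  UPDRS scores are heavily tied across sessions, which is why tau-b is
  required. Both aggregation units are computed: per-session pairing
  (many pairs, high power) and per-participant median TIP (conservative,
  n = participants); the per-session unit is the headline number.
- **Wilcoxon rank-sum** (Mann–Whitney): exact enumeration when both
  samples have ≤ 10 observations and no ties, otherwise the normal
  approximation with tie and continuity corrections. The reported W is
  the U statistic of the first sample.
- **Pairwise group tests** pool sessions across each group's members —
  six pairs × ten features. **Before/after tests** run per participant
  per feature with ≥ 2 sessions required in each condition. **Percent
  change** is 100·(mean_after − mean_before)/mean_before (negative =
  lower after intake; undefined when the before-mean is 0).
- No multiplicity correction by default, matching the analysis design
  being reproduced; Benjamini–Hochberg is available via `adjust="bh"`.
- Repeated sessions within a participant are pooled, not modelled
  (no mixed effects) — a deliberate fidelity-preserving limitation.

## Validation studies and problem sizes

`tremorkit.studies` packages the Monte-Carlo experiments; the test
suite and `scripts/acceptance.py` run them at these sizes, chosen to
keep each verdict stable (binomial s.e. ≤ ~1.5 points) at desk-scale
runtimes:

- frequency recovery: 200 seeds, default conditions; hit = F0 within
  one bin of the true 5 Hz.
- TIP monotonicity: amplitudes {0, 0.1, 0.3, 1.0} m/s² at fixed noise,
  median TIP over 100 seeds each.
- medication-effect power: attenuation 0.5, 30 sessions per condition,
  200 seeds; type-I calibration: attenuation 0, 1000 seeds, α = .05.
- oracle equivalence: 1000 random periodograms for the spectral
  features; exhaustive permutation enumeration for all rank-sum sample
  sizes ≤ 8 plus 1000 random larger cases for both rank statistics.
- full pipeline: 11-participant cohort × 7 days × 4 sessions/day.

## What the synthetic data does and does not show

The generator reproduces the features of real recordings that drive
this pipeline — oscillation in the tremor bands, amplitude ∝ severity,
timing irregularity, medication-locked attenuation — so passing tests
demonstrate that the pipeline recovers known ground truth through
realistic measurement artifacts. It does **not** emulate voluntary
corrective hand movements, game-strategy effects (bracing the elbow,
playing seated), device heterogeneity beyond timing jitter, dyskinetic
movement distinct from tremor, or multi-peaked spectra; real-data
effect sizes and p-values will differ, and conclusions about clinical
validity require real recordings.

## Other limitations

- TIP has units (PSD/Hz) and depends on the Welch configuration; it is
  comparable only across sessions analysed with identical settings.
- The magnitude reduction is orientation-invariant but nonlinear; very
  large tremor orthogonal to gravity would partially frequency-double.
- The medication-effect model is a single-compartment caricature: no
  dose, drug class, or inter-intake accumulation.
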