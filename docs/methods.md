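# Methods

## The scoring rule and its free choices

The RWA rule itself is short: phasic chin-EMG activity is a burst of
0.1–5 s with amplitude at least four times the background; a 3-s
mini-epoch is active when more than half of it is covered by such
activity; a 30-s REM epoch with active mini-epochs is an RWA epoch; RWA %
is the share of REM epochs so flagged. Around that rule, several
quantities are not fixed by the rule's statement, and this package makes
the following choices:

* **Amplitude** is the magnitude of the analytic (Hilbert) signal after
  band-passing the chin/EOG channel (4th-order Butterworth, 10 Hz to 90 %
  of Nyquist), smoothed with a 50-ms moving average. The analytic
  magnitude equals the amplitude of a pure tone exactly, which makes the
  envelope's scale interpretable; full-wave rectification (which
  converges to 2/π of the tone amplitude instead) is available as
  `method="rectify"`. Since every threshold is expressed relative to the
  background estimated from the *same* envelope, the choice affects run
  geometry, not calibration.
* **Background** is the median of the envelope over all REM epochs of the
  night after discarding the top decile of samples (so that the bursts
  being detected do not inflate their own reference level). Scope is
  configurable (`whole_night`); per-night REM scope is the default
  because the 4× rule is applied within REM.
* **Boundary semantics**: a sample exactly at 4× background belongs to a
  run (≥); a mini-epoch at exactly 50 % occupancy is *not* active
  (strict >). Both boundaries are tested.
* **Runs longer than 5 s** are discarded entirely, not truncated: the
  0.1–5 s window describes phasic activity, and a longer run is tonic
  elevation, a different phenomenon. A sustained elevation therefore
  contributes nothing to occupancy.
* **Mini-epoch grid**: non-overlapping 3-s windows anchored at recording
  start, ten per 30-s epoch.
* **Epoch rule**: ≥ 1 active mini-epoch flags the epoch (configurable
  k-of-10 via `min_active`).
* **Patient level**: RWA % of multiple nights is averaged (max as
  option); a patient is RWA-positive when the aggregate strictly exceeds
  0 %. The 0 % cutoff follows from the smallest positive per-patient
  value observed in practice (1.2 %) — any flagged epoch counts.
* A night without REM sleep has *undefined* RWA % (an explicit no-REM
  result), never 0 %.

## Sleep metrics

Metrics are computed on the 30-s grid within the lights-off→lights-on
window (for a home device, the recording span by default). Sleep onset is
the first epoch of any sleep stage; SOL the wake time before it; WASO the
wake time between onset and the last sleep epoch (terminal wake
excluded); TST the sleep-stage minutes; efficiency 100·TST/TIB. These
definitions make `TST + SOL + WASO + terminal wake = TIB` an exact
identity, which the suite asserts on random hypnograms. REM duration is
analysed on the natural-log scale; a zero-REM night has no log-REM and is
excluded from log-scale analyses with a warning rather than imputed.

## Statistics

* Mann–Whitney U: the exact null distribution when the combined sample is
  tie-free with n ≤ 30, the tie-corrected normal approximation otherwise.
  The effect size r = |z|/√N always uses the normal deviate (without
  continuity correction) so it is defined in both regimes. An independent
  full-enumeration oracle (all C(n, n₁) group assignments) backs the
  exact path in tests.
* 2×2 tables: φ = |ad − bc|/√(product of margins). The default p-value is
  Fisher's exact two-sided test — the published tables this analysis
  emulates print values (0.332 for the sex table, > 0.999 for several
  near-null tables) that reproduce under Fisher and not under Pearson —
  with plain Pearson χ² as an option. A zero margin leaves φ undefined
  and raises.
* Covariate cutoffs are applied with the printed boundary semantics
  (≥ 400 inclusive, > 109 strict, etc.). The fatigue cutoff (≥ 3.3) only
  makes sense on the fatigue scale's mean-per-item scoring (range 1–5),
  so the cohort simulator draws the scale on that metric; note the
  emulated study's own tables print the ~16-item total in one place and
  item-level values in another.
* ANCOVA: OLS of log-REM on the RWA indicator plus the ladder's
  covariates (model 1: age, sex, BMI; model 2: + LEED ≥ 400, duration
  > 109; model 3: + Hoehn–Yahr, log-UPDRS-3, UPDRS-4; full: + depression,
  fatigue, anxiety, psychosis, RBDSQ ≥ 5 and the three sleep-scale
  subdomains). The adjusted mean difference is the group coefficient,
  with a t-based 95 % CI and exp back-transform to a fold-change ratio.
  The ladder's effect size is partial η² = t²/(t² + df_resid) for the
  group term — the published table does not define its effect-size
  column, and partial η² is the conventional ANCOVA choice; it is
  documented here as an assumption. Complete-case analysis with a logged
  exclusion count; rank-deficient designs raise an error naming the most
  collinear column pairs. No multiplicity correction by default (the
  emulated analysis applies none); Holm is available as a flag.

## The synthetic-data generator

The generator exists to give the pipeline inputs with known ground
truth; it makes no claim to device-accurate physiology.

* **Hypnogram**: first-order Markov chain over {W, N1, N2, N3, REM} per
  30-s epoch, with a REM-cycling bias — the weight of entering REM from
  N2 ramps linearly with time since the last REM period (full weight
  after 40 min), emulating ultradian cycling. The default transition
  weights put mean REM at ≈ 20 % of total sleep time (asserted band
  15–25 % over many nights) and sleep efficiency in the mid-80s, with
  REM-period dwell ≈ 7 min. Nights ≥ 90 min are guaranteed at least one
  REM epoch: the chain is redrawn up to 8 times, then (never observed in
  practice) a late sleep block is relabelled.
* **Chin signal**: stationary band-limited (10–55 Hz) Gaussian noise
  scaled so the median analytic amplitude equals the configured
  background scale. Planted bursts multiply the noise by their amplitude
  ratio with 20-ms cosine edge ramps — raised-envelope noise, so envelope
  extraction is non-trivial rather than a delta detection. The EEG
  channel is cosmetic slow-band noise.
* **Burst planting**: exactly ⌈target/100 × #REM⌉ evenly spaced REM
  epochs receive bursts. Defaults: two mini-epochs per target epoch, each
  with a centred burst covering 80 % of its window, at 6× background.
  The margin matters: a realised burst's stochastic envelope dips below
  the 4× threshold now and then, fragmenting it into shorter runs and
  eroding measured occupancy; 0.8 coverage on two mini-epochs keeps the
  epoch scoreable with high probability, which is what makes planted
  recovery exact to one epoch quantum in ≥ 95 % of nights at ratio ≥ 6.
  Ground-truth mini-epoch flags are derived from plan geometry by
  interval arithmetic, independent of the scorer.
* **Cohort**: covariate marginals (age 72.4 ± 6.6 y, 61 % male, BMI
  21.6 ± 3.3, log-normal disease duration with median 109 months,
  log-normal LEED, instrument scores on their scales) emulate a
  Parkinson's disease sleep-study population. log-REM minutes =
  2.97 + effect·RWA + small age/sex/BMI terms + N(0, σ); defaults:
  n = 41, RWA prevalence 27/41, effect 0.93 (the emulated cohort's
  unadjusted group contrast on mean log-REM), σ = 1.0 (between the two
  groups' printed SDs of 0.73 and 1.29). The generator does **not**
  reproduce inter-covariate correlations, skewed instrument floors, or
  any coupling between RWA status and the clinical covariates; passing
  tests therefore validate the *pipeline* (estimator bias, CI coverage,
  type-I error under the model), not claims about the real cohort's
  covariate structure.
* Determinism: each generator draws all randomness from one
  `numpy.random.Generator` seeded per call; identical seed + config is
  bit-identical.

## Validation sizes and numerical notes

The suite validates the chain at these problem sizes, chosen so each
suite completes quickly while leaving Monte-Carlo error small relative to
its tolerance: burst-oracle instances ≤ 1000 samples; exact Mann–Whitney
enumeration to combined n = 8; ANCOVA recovery/type-I with 500 cohorts of
n = 200 (bias tolerance ±0.05; coverage and rejection rate within 3
binomial SEs of 0.95 / 0.05); planted-recovery nights of 2 h at 128 Hz
across 20 seeds. The analysis drivers use similar sizes and print what
they find.

Numerical edge cases: envelope filtering uses zero-phase `sosfiltfilt`
(no group delay to bias burst onsets); occupancy is clipped to [0, 1]
against float accumulation; burst/mini-epoch boundary comparisons carry
1e-9-second guards; EDF round-trips are exact to the 16-bit quantization
of each channel's physical span.

## Known limitations

* The background estimator assumes phasic activity is sparse within REM
  (≲ 40 % of samples); a night of near-continuous activity would inflate
  the background and undercount bursts — on such data, use
  `scope="whole_night"` or a fixed reference.
* Tonic RWA (sustained elevation) is deliberately not quantified; only
  the phasic 0.1–5 s rule is implemented.
* Periodic limb movements and any video-based behaviour analysis are out
  of scope for a two-channel device.
* The automatic sleep stager of the recording device is not reimplemented;
  hypnograms are an input.
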