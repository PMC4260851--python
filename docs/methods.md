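# Methods

`gaitsync` simulates, in a closed loop, an adaptive music player that tries
to align its beat schedule with a walking or running person, and provides
the circular statistics used to evaluate the resulting footfall-beat
relative-phase distributions. This note records the model, the parameter
choices, and the numerical decisions behind the implementation.

## Relative phase

The quantity everything revolves around is the relative phase of a footfall
within its bracketing beat interval,

    φ = 360° · (t_footfall − t_prev_beat) / (t_next_beat − t_prev_beat),

reported on the display scale (−180°, +180°]: 0° means the step landed on
the beat, ±180° exactly between beats, a negative angle that the step
preceded the upcoming beat. Two conventions are fixed here because the
definition alone does not decide them: a footfall exactly on a beat belongs
to the interval that starts at that beat (so φ = 0 is representable), and
the anti-phase boundary maps to +180° (one canonical value). Left and right
steps are treated identically — the phase is per step, not per gait cycle.
Phases are only computed between two consecutive beats of the same
playback; steps falling inside a song change are dropped.

## The player: four alignment strategies

The player is an event-driven state machine acting once per detected
footfall. All strategies share:

- a cadence estimator averaging the last up-to-5 accepted inter-step
  intervals (steps per minute, SPM). An interval is accepted only if it
  matches the current average or its ×0.5 / ×2 harmonics within a 20%
  relative margin; rejected steps ("erroneous gait frequency") leave both
  the estimate and the controller untouched. The window length is 5 *steps*
  (one source describes 5 *seconds* for one variant; at typical cadences
  the two are close, and the window is configurable);
- a tempo modifier clamped to [0.9, 1.1] — the stretch range a time
  stretcher can apply without objectionable audio artefacts. Playback is a
  pure timing contract: remaining nominal inter-beat gaps are scaled by
  1/modifier, emitted beats are never rescheduled, and a mid-song modifier
  change takes effect at the next unemitted beat;
- a song-change debounce: when the *unclamped* tempo request stays outside
  the stretch range for more than 5 s, a new song with BPM nearest the
  current SPM is selected (ties break to the smallest song id, and songs
  already played are excluded until the library is exhausted).

The strategies differ in what they control:

1. **period-adaptive, phase-random** — modifier := SPM/BPM on every
   accepted step; songs start at a uniformly random offset within one beat
   period; debounced song changes are immediate.
2. **period-fixed, phase-random** — the modifier is set once when a song
   starts (optionally quantised to whole-percent steps in ±3%, emulating
   pre-rendered song versions on a mobile build) and never touched until
   the song ends; random start phase.
3. **period-adaptive, phase-starting** — adaptation as in 1, but song
   changes are queued, and the queued song — skipped to its first annotated
   beat — starts at the wall time where the walker's predicted phase equals
   the configured start phase: last footfall + T_step for 0°, half a beat
   period earlier for 180°. T_step is the last *accepted raw* interval,
   not the 5-step average: the prediction concerns the very next step.
4. **period- and phase-adaptive** — strategy 3 with 0° starts plus a
   per-step nudge: when the step's phase leaves the ±30° band, the modifier
   is moved by 0.03 (once per step, applied after the base ratio and before
   the clamp). The sign is the corrective one: a step lagging the beat
   (φ > +30°) *slows* the music so the next beats wait for the walker; a
   leading step speeds it up. (Speeding up on a lagging step — a reading
   some textual descriptions suggest — is dynamically unstable: since
   earlier beats increase φ, it drives the phase away from 0° and creates
   an attracting oscillation around ±180°; the closed loop then never
   aligns. The corrective sign reproduces the intended behaviour of the
   tempo "pushing the relative phase back to 0°".)

Strict inequalities are used for the band and stretch-range comparisons;
the debounce clock resets whenever the request re-enters range.

## The walker: a discrete HKB-style phase-correction map

Footfalls are the only actionable instants, so the walker is a per-step map
rather than a continuous oscillator. At footfall n with relative phase φ_n
(radians) to the heard beats,

    I_{n+1} = T_pref/detuning + ε_n − (a·sin φ_n + b·sin 2φ_n) · T_beat/2π,

with T_pref = 60/base_spm, step noise ε_n, and beat period T_beat. This is
the discrete analogue of the HKB potential −a·cos φ − (b/2)·cos 2φ: for
a > 0 the in-phase fixed point is stable and anti-phase unstable; for
2b > a a *locally* stable anti-phase fixed point appears with basin
half-width arccos(a/2b) — always smaller than the in-phase basin, which is
why offbeat synchronisation is fragile and in-beat synchronisation robust.
(A sign variant with −b·sin 2φ makes anti-phase unstable for every b and
cannot produce a weak anti-phase attractor at all; the + sign is the HKB
form.) With a = b = 0 the walker ignores the music entirely — the model of
people who do not entrain.

Defaults (free parameters; no published human values exist for this loop):
`base_spm` 115 (natural walking band 110–120 SPM), `noise_sd` 15 ms
(step-time CV ≈ 3%), `coupling_a` 0.12 and `coupling_b` 0.08. The gains
give a per-step in-phase contraction of a + 2b ≈ 0.28 — the magnitude of
per-tap phase-correction gains reported in sensorimotor-synchronisation
research — and satisfy 2b > a so the anti-phase attractor exists but is
weak (linear contraction only 1 − (2b − a) = 0.96 per step, basin ±41°):
under 15 ms step noise a walker parked at 180° escapes to 0° within
minutes, while the 0° lock is tight. Cohorts draw uniformly from ranges
around these defaults and include 30% non-entrainers (zero coupling),
assigned by deterministic striding so that extending a cohort never
changes earlier participants.

Step noise is white Gaussian by default. A 1/f-like long-memory mode
(spectral synthesis, amplitude ∝ f^(−1/2)) is available to emulate the
spectral character of real gait; both modes were simulated and the
closed-loop findings below do not depend on the choice.

The sensor model rounds event times *up* to the next tick of a 100 Hz
sampling grid (a sensor cannot report an event before it happens): mean
absolute error half a sample (5 ms), maximum below one sample (10 ms),
never reordering events. The player sees quantised footfalls; the walker
hears the true beat times with zero latency (audio latency is out of
scope).

## What the closed loop shows — and one mechanism worth naming

With the default cohort (20 walkers, 10-minute trials) the pooled resultant
length orders strategy 4 > strategy 3 (0°) > strategy 2 > strategy 1, the
0° start condition beats the 180° condition under strategy 3 (higher R,
distributions separated by Watson's U²), and strategy 4 keeps |φ| ≤ 30° for
well over 90% of steps even for zero-coupling walkers — machine-side
entrainment needs no cooperation.

One emergent mechanism deserves explicit mention because it shapes what
the simulation can and cannot reproduce: under the period-adaptive
strategies the tempo tracker *cancels* the walker's phase motion. The beat
period equals a lagged moving average of the very intervals that drive the
phase, so the phase increment is a high-pass-filtered copy of the step
noise, whose running sum is bounded: each song freezes near its (random)
starting phase instead of diffusing toward uniformity. A 10-minute
strategy-1 trial therefore pools a handful of frozen random phases
(per-trial R ≈ 0.4 in expectation) rather than a uniform sample; only the
phases pooled across trials and songs are near-uniform. For entraining
walkers the same cancellation works against the walker's own corrections —
the "wobble" that makes the period-adaptive strategy the weakest of the
four.

## Circular statistics

Summaries follow the second-trigonometric-moment conventions of the
CircStat/Berens toolbox. With mean direction θ̄ and mean resultant length
R: circular variance V = 1 − R, angular deviation s = √(2(1−R)) in radians,
skewness b = mean sin 2(α−θ̄), kurtosis k = mean cos 2(α−θ̄); the
standardised (Fisher) variants are exposed separately. V = 1 − R and
s = √(2(1−R)) hold exactly for every summary emitted. Degrees at all
interfaces, radians internally.

- **Rayleigh test** (unimodal alternative): Z = nR², p from the standard
  four-term series in Z and n; checked against pingouin and a 10⁴-replicate
  simulated null. Requires n ≥ 3.
- **Hodges–Ajne / omnibus test** (asymmetric multimodal alternatives):
  m = the minimum number of points in any closed half-circle. The statistic
  is discrete, so the reported p is the mid-p, ½[P(M≤m) + P(M≤m−1)], from
  the combinatorial tail formula (n−2m)·C(n,m)/2^(n−1) — computed exactly
  for n ≤ 64 and in log-space beyond. The plain tail p is conservative
  (achievable sizes at n = 100 jump from 0.028 to 0.052 around α = 0.05);
  the mid-p restores calibration while staying within Monte-Carlo error of
  the tail probability. The formula is guarded (p = 1) near m ≈ n/2 where
  it turns non-monotone. Known limitation: a perfectly balanced antipodal
  mixture fills every half-circle (m ≈ n/2), so this test — like the
  Rayleigh test — has no power against it; it detects *asymmetric*
  multimodality. Requires n ≥ 9.
- **Watson's two-sample U²** from the pooled circular ranks, ties by
  averaging the cumulative-difference statistic over tied blocks; p from
  the asymptotic alternating series (p = 1 at the degenerate minimum),
  checked against a 10⁴-shuffle permutation oracle.
- **Mean-direction CI**: the standard large-sample χ²₁-based circular CI
  (CircStat's form, with the separate high-concentration branch at
  R ≥ 0.9), degenerate at zero width for identical angles and refused for
  samples too dispersed for a meaningful mean. Cross-checked against a
  bootstrap percentile CI on continuous concentrated samples; on discrete
  atom samples the bootstrap distribution is lumpy and no meaningful
  comparison exists.
- **Per-participant classification**: a participant counts as synchronised
  when their own Rayleigh test rejects at α (default 0.05); no multiplicity
  correction is applied, α is configurable.

## Experiments, determinism, problem sizes

An experiment is a pure function of (config, master seed): walker
parameters derive from per-participant children of the master seed, and
each (participant, condition) player receives a counter-derived sub-seed,
so cohorts extend without perturbing earlier participants and logs are
byte-identical across reruns. Every trial writes footfall, beat, phase and
controller-trace CSVs; phases are recomputed from the logs alone, so any
reported number can be re-derived from the files.

Simulation-based checks in the test suite use 10-minute trials, cohorts of
20 walkers, and 10⁴-replicate Monte-Carlo nulls — sizes at which every
asserted gap exceeds twice its standard error while the whole suite stays
fast.

## What the synthetic walker does and does not capture

The walker reproduces: stable spontaneous in-phase locking, the weaker
anti-phase attractor, step-to-step timing variability, non-entrainers, and
sensor quantisation. It does not capture: biomechanics (step length,
treadmill constraints), attention/motivation effects of music, tempo
preference drift over minutes, higher-order metrical levels (only the main
beat exists), or audio/actuation latency. Passing closed-loop tests
therefore demonstrates the *controller-side* claims — which alignment
strategy makes synchronisation easy for a given coupling law — not
quantitative agreement with any human cohort, whose empirical phase
distributions are far broader than the model's.
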