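# Methods

## Onset detection and timestamp fusion

The detector operates on the per-sample magnitude of the 3-axis acceleration
vector. The magnitude series is differenced, rectified and smoothed with an
exponentially weighted moving average,
`y[n] = |x[n−1] − x[n]|(1 − α) + α y[n−1]`, initialized at `y[0] = 0` (the
envelope of an unseen past difference is taken to be zero). A tap onset is
reported at the *first* sample where the envelope crosses the threshold from
below — the onset, not the envelope apex, is the proxy for physical contact —
and further crossings are suppressed for a refractory period.

The envelope is applied to the magnitude (one scalar series, one threshold)
rather than per axis. A per-axis variant followed by a norm of envelopes
would respond similarly to sharp taps but requires three coupled thresholds;
the single-envelope design keeps calibration one-dimensional.

Fusion: once a touchscreen event is logged at time `L`, the most recent
accelerometer onset in `[L − w, L]` supersedes it, where the window `w`
defaults to one touchscreen frame period (8.33 ms at 120 Hz). With no onset
in the window the logged time is used unchanged, so fusion can only improve
on touchscreen resolution, and the fused RT never exceeds the
touchscreen-only RT.

Parameters and defaults:

| parameter | default | units | rationale |
|---|---|---|---|
| α (EWMA weight) | 0.5 | — | balances noise suppression against onset sharpness; at 0.5 a tap's first difference already lifts the envelope to a quarter of the pulse amplitude |
| threshold | max(amplitude/8, 12·noise SD) via `default_fusion_params`, or `calibrate_threshold` (k·SD of a tap-free envelope segment, k = 8) | envelope units | must sit below the onset-sample envelope (~amplitude/4) and above the noise floor |
| refractory | 50 | ms | debounces the ringing of one physical tap; well below any plausible inter-tap interval |
| window | one touch frame period | ms | a genuine tap's impulse precedes its logged frame by at most one frame plus pipeline delay |

## Synthetic sensor streams

The accelerometer model is a constant gravity vector (9.81 on the z axis)
plus independent Gaussian noise per axis, with each tap adding a 3-sample
triangular transient (peak amplitude 20 m/s², i.e. ~2 g — a sharp intentional
tap) starting at the first sample at-or-after the contact time. The
triangular pulse is the minimal shape producing one sharp
successive-difference peak; real tap waveforms ring and vary with grip and
case, which this model does not emulate. Touch events are delayed by a
zero-truncated Gaussian pipeline latency and then rounded **up** to the next
scan-grid boundary — a physical digitizer reports a contact at the following
scan, never before it.

The virtual bench randomizes the audio→vibration interval uniformly in
0.5–1.5 s and the vibration→tap delay uniformly in 1–2 s (both configurable),
draws device latencies from the profile's (mean, SD) pairs, and obtains the
internal tap timestamp from the fused detector running on the simulated
streams. All draws come from one `numpy` generator seeded per call, so every
simulator output is a pure function of (inputs, seed).

Bundled device profiles declare sensor rates, one-way audio latency (half the
published round-trip figure) and feature flags per handset; the latency SDs
and the vibration/touch-pipeline latencies are nominal synthetic values —
real devices must be measured, and profile YAMLs are meant to be edited with
bench results.

## Timing statistics and suitability

Deltas are summarized with mean/min/max and the sample (n−1) SD. Suitability
uses the SD of the sync (AA′) and RT (BB′) delta series with an inclusive
10 ms bound on both: an order of magnitude below human audio-tactile
asynchrony detection thresholds (~50–100 ms). The bound and its inclusive
boundary are documented conventions, pinned by tests and configurable. The
measurement-chain noise floor is recorded as a constant: 3 ms round-trip
loopback variability, halved to 1.5 ms one-way; simulated benches do not add
this term, so their precision figures are attributable to the modeled device
alone.

## Paradigm schedule

Delays T1–T6 are 105, 1625, 2385, 2765, 2955, 3050 ms from sound onset (all
within the 3250 ms sound); looming distances at touch time are 640, 320, 160,
80, 40, 20 cm, and the fixed source stays at 640 cm. Each block holds 4
repetitions of each of the 12 movement × delay cells plus 24 catch trials
split evenly between fixed and looming sounds — the even split avoids
confounding sound movement with tactile expectancy. Per-block cell balance is
a design choice (only per-session counts are externally constrained) and both
the per-block repetitions and the catch count are configurable. Trials carry
a 300 ms pre-sound silence and a uniform 1000–1400 ms post-sound silence.
Block duration is informational; trial counts govern the design.

## Synthetic cohorts

Within-cell RTs are lognormal: `RT = median · exp(σ·Z)` with σ = 0.15,
which yields realistically right-skewed single-trial RTs (~15% coefficient of
variation). The median is assembled additively in milliseconds —
`base[delay] + participant offset − effect[delay]·[looming]` — so the
injected facilitation equals the headline ms quantity the pipeline should
recover. Defaults: base medians 420, 400, 380, 360, 345, 330 ms across T1–T6
(a monotone expectancy profile; the absolute values are package choices, only
the decrease is meaningful), facilitation 0 at T1–T2 and 22.5 ms at T3–T6
(the middle of the 20–25 ms band expected once a looming source has entered
peripersonal space), participant SD 30 ms, miss probability 1.4% per
experimental trial, false alarms off. The generator does not model
anticipation dynamics, sequential effects, fatigue, or RT-miss dependence;
passing recovery tests therefore demonstrate pipeline correctness under the
assumed generative model, not robustness to violations of it.

## RT analysis

Exclusion: a participant is dropped when their miss rate exceeds the full
sample's mean + 3·SD, computed once (no iterative re-screening); the rule is
pluggable. Filtering keeps RTs in [100, 1000] ms inclusive — readings outside
are treated as anticipations or lapses — and reports the removed percentage
of RT-bearing trials (defined as 0, with a warning, when there are none).

Cell summaries are geometric means (exponentiated mean ln RT) per participant
and cell; group cell means are arithmetic means of the participant geometric
means (not a grand geometric mean), with SEM across participants.
Facilitation per delay = fixed − looming group mean; positive when looming is
faster.

The ANOVA is the classical two-way fully-within-subject decomposition: each
effect is tested against its effect × subject interaction, df (1, n−1) for
movement and (5, 5(n−1)) for delay and the interaction at six delay levels,
with ηp² = SS_effect/(SS_effect + SS_error). No sphericity correction by
default; a Greenhouse–Geisser option shrinks the df by an epsilon estimated
from the double-centered covariance of the relevant subject × level matrix
(for the interaction, the per-delay fixed−looming differences). Per-delay
contrasts are paired t tests on the ln-scale cell means, unadjusted by
default with Holm available; with effects at four of six delays, unadjusted
tests match the conventional reporting style while Holm guards the family.

Degenerate inputs: a flat design yields F = 0 (not NaN); unbalanced or
incomplete designs raise immediately with the offending participant/cell
named; all tabular outputs are deterministic functions of their input frames.

## Problem sizes used in the test suite

The fusion-resolution check uses 1000 jittered noiseless taps; jitter
recovery uses 1000 bench trials; parameter recovery averages 20 cohorts of 18
participants × 432 trials; the null-calibration check pools 1200 paired tests
from 200 reduced (one-block) cohorts. These sizes give sampling error
comfortably below the asserted tolerances (e.g. the 3-sigma binomial band
±1.9 percentage points around the 5% nominal rejection rate).

## Known limitations

- Latency distributions are Gaussian (zero-truncated); real pipelines show
  heavy right tails and occasional frame drops.
- The tap transient is stereotyped; threshold calibration on real traces
  should use the provided noise-floor helper on a verified tap-free segment.
- Device profiles mix declared and nominal values; suitability verdicts on
  bundled profiles characterize the profile, not the physical handset.
- No modeling of battery state, thermal throttling or background-app
  interference.
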