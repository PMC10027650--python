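# Methods

`mirrorkit` models the computational core of a *virtual mirror*: a system in
which an avatar imitates a viewer's facial behaviour in real time, used in
enfacement research to manipulate the sense of agency (SoA) over a virtual
face. This note documents the models, the defaults and why they were chosen,
what the synthetic data does and does not emulate, and the numerical
decisions a maintainer would want written down.

## The pipeline model

A mirror is a linear chain of modules (source → tracker → manipulators →
renderer → sink) exchanging *messages*: a frame id, a capture timestamp on a
monotonic millisecond clock, an optional raster, and a namespaced key-value
map (`pose.*`, `au.*`, `camera.*`, `timing.*`, `avatar.*`). Modules run
concurrently (one worker thread each) but individually preserve message
order, so delivered frame ids are strictly increasing. Two back-pressure
policies exist per edge:

* **latest-wins** (default): only the most recent pending message is kept;
  older pending messages are counted as dropped. A mirror must show the
  freshest frame, so shedding stale frames is correct behaviour, not loss.
* **queue-all**: unbounded FIFO, for offline processing where every frame
  matters.

In both cases `emitted = delivered + dropped` holds exactly; drops are
counted at the point of discard, not inferred from the balance, so the
conservation tests are meaningful.

A second execution mode (`run_stepped`) pushes frames through the chain
synchronously under a simulated clock. It is bit-reproducible and is what
the latency harness and the stepped experiment session use. One consequence:
per-module `timing.*` durations are 0 in stepped mode, because the simulated
clock only advances between frames; duration statistics are informative in
threaded mode only.

Pipelines are described in plain text, one module per line
(`type key=value ...`, `#` comments). The first module must be a source, the
last a sink; unknown module types are reported with their line number.

## Face state and synthetic motion

A face state is a 6-DoF head pose (translations in mm; pitch/yaw/roll in
degrees, intrinsic pitch–yaw–roll order; positive yaw = subject's left) plus
17 continuous FACS action-unit intensities (AU01…AU45) clamped to [0, 5],
with a validity flag and confidence. The 17-AU set and [0, 5] range follow
the common continuous-intensity tracker convention; neutral is all zeros.

Synthetic motion is generated from piecewise scripts (hold or linear
segments, optionally looped):

* **Calibration stimulus**: frontal hold 1.5 s, then an abrupt (no ramp)
  25° left turn held 0.5 s, looped — period 2.0 s. The recommended analysis
  sub-sequence is 1.5× the period, i.e. 3 s.
* **Rest sequence**: near-neutral face with subtle breathing, modelled as a
  sinusoid traced by 32 linear knots per cycle (default amplitude 2 mm on
  `tz`, period 4 s; AU25 covaries at one tenth of the amplitude in AU
  units). Amplitude 0 degenerates to a strictly constant neutral script.
  This is the sequence replayed to the avatar in the baseline condition, so
  the avatar looks alive while being fully decoupled from the viewer.

`sample_states` turns a script into a timestamped stream at a given frame
rate (frame *t* at `t·1000/fps` ms) with optional independent Gaussian
jitter per channel (separate SDs for pose and AU channels; AUs re-clamped
after jitter), seeded and exactly reproducible. Tracks round-trip through a
CSV schema (`frame,capture_time_ms,tx…rz,AU01…AU45,valid,confidence`,
written at 10 significant digits, read by header name) to within 1e-6.

What the generator does **not** emulate: tracker dropouts and occlusions,
identity-dependent AU cross-talk, non-Gaussian heavy-tailed tracking error,
rolling-shutter/exposure artefacts, or any dependence of noise on head pose.
Tests passing on this synthetic stream therefore validate the *machinery*
(delays, gating, scaling, shift estimation, scoring), not tracker quality on
real video.

## Condition manipulators

* **Delay** (asynchrony): a timestamp buffer emitting the newest state
  captured at or before `now − d`. No interpolation, so every output equals
  some past input exactly; the emitted age is in `[d, d + one frame)` in
  steady state. Before the buffer covers `d`, a flagged neutral state is
  emitted (the choice of what to show during warm-up is ours; flagging lets
  an experiment blank the screen instead). Entries that can never be
  selected again are evicted immediately, which bounds memory without a
  retention tunable. Default asynchronous delay: 2000 ms, configurable.
* **AU scaling**: `min(5, s·AU)` per unit, pose untouched; multiplicative
  below the clamp. Default factor 1.5.
* **Condition gate** (the four study conditions): B replaces the state with
  the replay source's state at the current time (live input ignored
  entirely); P passes pose and forces a neutral expression; E passes
  expression and holds the pose at rest; PE is the identity. B without a
  configured replay source is a configuration error, not a silent neutral.
* **Replay**: loops a recorded track with duration = last timestamp + one
  median frame interval, so querying exactly at the duration wraps to the
  first state; un-looped replay holds the final state.

Invalid (tracking-lost) states pass through every manipulator unchanged and
are flagged via `manipulator.skipped`.

## Schematic renderer

The renderer is a pure function (avatar, state, size) → uint8 raster:
flat-shaded 2D face with ellipse features on a fixed background, no
randomness, no external renderer. Yaw/pitch become horizontal/vertical
shifts (0.9 px per degree per layout unit), roll rotates the feature layout,
`tz` scales the head. Mapped AUs deform features monotonically: AU01/02/04
move brows, AU05/07/45 open/close eyes, AU12/14/15/17/20/25/26 shape the
mouth; unmapped AUs (06, 09, 10, 23) have no visual effect. This affine
stand-in is deliberately not a 3D projection: it is sufficient for the
calibration analysis (the yaw signal is recoverable from the head-pixel
centroid) and for region-wise deformation tests, while staying byte-
deterministic across platforms. A photorealistic engine can be plugged in as
any callable `(state, avatar_id, size) → raster`.

## Latency calibration

Tracks are z-transformed, then smoothed with a centred moving average
(default width 5 frames at 120 fps; the width is exposed because the
appropriate kernel depends on the recording). The frame shift between
stimulus and mimic is estimated by sampling `n_sub = 50` sub-sequence starts
uniformly without replacement (seeded) from the admissible range, and for
each start taking the integer lag in `[0, period·fps)` that maximises the
Pearson correlation between the reference sub-sequence (length
`1.5 × period`) and the lag-shifted mimic window. Ties break toward the
smallest lag. Because the stimulus is periodic, only the shift modulo one
period (240 frames at 120 fps) is identifiable; the estimator returns the
minimal non-negative representative. `latency = mean(shifts) × 1000 / fps`.

Numerical notes: correlations are computed on mean-centred windows with a
vectorised sliding-window product; windows with zero variance score −inf and
can never win; for noiseless periodic input the estimator is exact for every
integer shift (verified against an independent FFT circular-correlation
argmax). Detrending beyond the z-transform is not applied; for the step-like
calibration stimulus there is no trend to remove, and the smoothing window
is config-exposed for recordings where there is.

The end-to-end harness drives the stimulus through a pipeline frame by frame
under a simulated clock and records stimulus and output yaw with a virtual
second camera at the recording fps. A pipeline containing a `delay` module
is thus a self-test with known ground truth: an injected 200 ms delay must
be recovered within one frame interval (8.33 ms at 120 fps). The harness
measures *software* delay only; camera exposure and display response are
properties of physical devices and are explicitly outside what a simulation
can measure, so the report labels its estimate accordingly. Problem sizes
used throughout (30 s at 120 fps = 3600 frames, 50 sub-sequences) match the
measurement procedure the stimulus was designed for.

## Experiment session and schedule

`MirrorSession` wraps a pipeline for a host experiment: non-blocking
retrieval of the most recent rendered frame (`None` before the first frame;
identical frame between deliveries), and live adjustment of delay,
condition, avatar, and amplification, each taking effect on the next frame.
Stepped mode is deterministic; live mode paces a background thread at the
source frame rate. Every command and frame delivery is appended to an event
log exportable as CSV.

`build_schedule` emits the induction plan: baseline B first for every
participant, then the three synchronous conditions in one of the six
permutations of (P, E, PE), assigned in balanced fashion (exact with a
multiple of six participants, counts differing by at most one otherwise,
with a warning). Full permutation balancing was chosen over a Latin square
because with three free blocks all six orders are feasible at typical sample
sizes. Each block is instruction 30 s / mirror 180 s / free 30 s (240 s);
the three synchronous blocks use three distinct avatars per participant, and
the baseline avatar also differs when the pool has at least four identities.
Five-minute breaks between blocks are schedule metadata, not enforced.

## SoA scoring

Responses are 0–100 visual-analogue ratings per (participant, item,
condition). The score is a weighted item sum, `Σ_j λ_j·x_j` on the raw
responses, with weights λ from the first principal component of the item
correlation matrix — a proxy for the latent SoA variable. Correlation
rather than covariance PCA: items share a scale but not necessarily a
variance. Loadings are sign-fixed so they sum positive; a zero-variance item
is an error naming the item.

The *condition-general* loadings are estimated from pooled rows that are
centred within condition first. The between-condition mean differences are
the experimental effect, not measurement structure; left in, they act as an
artificial equal-loading common factor that flattens the general loadings —
and congruence against a near-flat vector is almost permutation-invariant,
which would blind the invariance check to genuine loading-pattern changes.
Condition-specific loadings come from each condition's own rows (centring is
then immaterial to a correlation PCA).

Measurement invariance is assessed with Tucker's congruence coefficient
`φ(x, y) = Σx_i y_i / √(Σx_i² Σy_i²)` between general and condition-specific
loadings. The check is report-only by default; the conventional markers .85
(fair) and .95 (good) can be applied via a configurable benchmark. The
response generator draws from a one-factor model,
`x = clamp(μ_c + λ_j η_ic + ε_ijc, 0, 100)`, with default condition means
ordered B < P < E ≤ PE (40, 62, 74, 78) — the qualitative pattern expected
of a working mirror — default loadings (18, 22, 20, 15) VAS units per latent
SD, latent SD 1, and noise SD 10. These defaults describe a 4-item VAS
questionnaire answered by a default of 24 participants; recovery tests use
n = 200 so that sampling error does not dominate the property under test.

## Known limitations

* The renderer is schematic; nothing here speaks to photorealism, uncanny-
  valley effects, or the appearance of any particular avatar stock.
* The latency harness cannot see hardware lag; numbers from it are lower
  bounds on a physical installation's end-to-end latency.
* The scheduler balances condition order only; it does not counterbalance
  avatar-to-condition assignment beyond the distinctness constraint.
* The scoring generator is a one-factor Gaussian model with clamping; it is
  a recovery test bed, not a model of real questionnaire response styles
  (no acquiescence, anchoring, or floor/ceiling clustering beyond the
  clamp).
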