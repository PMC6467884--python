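# Methods

This note documents the models inside `triadbci`, the defaults and why
they were chosen, the numerical choices, and what the simulations can and
cannot say about real recordings.

## Synthetic EEG

A recording is a target sinusoid plus Gaussian 1/f^α background noise
(α = 1 by default, the typical broadband slope of resting EEG; α = 0 gives
white noise). Noise is synthesized by spectrally shaping white Gaussian
noise in the frequency domain with |H(f)| = f^(−α/2) and zeroed DC.

**SNR definition.** `snr` is the ratio of sinusoid power to noise power
*within the 0–30 Hz analysis band* — the band the decoder sees — so
accuracy-versus-SNR curves are directly interpretable. The noise
realization is rescaled so the realized band-power ratio equals the
request exactly; determinism is per (seed, parameters).

Amplitudes are nominally µV but only power *ratios* matter downstream.
Senders are sampled at 250 Hz; the Receiver's amplifier at 5000 Hz, then
decimated to 500 Hz with an anti-aliasing FIR low-pass
(`scipy.signal.decimate`, zero-phase) before decoding — aliasing onto the
15/17 Hz bins would otherwise corrupt the vote.

A small physical caveat: with a 1/f background the expected PSD at 15 Hz
exceeds that at 17 Hz by a factor 17/15, so idle (no-stimulus) EEG carries
a slight "do-not-rotate" bias. This is a property of pink noise, not a
decoder defect, and disappears for α = 0.

**Defaults.** The real recordings' SNR is unknown; the default
`snr = 2.0` was chosen, together with the channel and agent defaults
below, so that the simulated triads operate at the performance level the
human study reports (accuracy ≈ 0.81, triad AUC ≈ 0.83). At snr = 2 the
10-second decoder is near-perfect; errors in the loop come mostly from the
channel and the Receiver's behavior.

## Decoder

- 4th-order Butterworth, implemented as mean removal plus a causal 30 Hz
  low-pass (`sosfilt`). A true 0 Hz high-pass corner is degenerate; mean
  removal is its limit. A causal filter is used so the attenuation of
  out-of-band tones matches the designed magnitude response, as in an
  online system.
- Welch settings inside a 1-s epoch are a free choice; we use a single
  full-length Hann segment (periodogram-style), giving exactly 1 Hz bin
  spacing at 250 and 500 Hz so 15 and 17 Hz fall on exact bins. The
  estimate is evaluated directly via rfft and is numerically identical to
  `scipy.signal.welch(x, fs, nperseg=len(x))` (asserted in tests).
- Epoch vote: yes iff P(17) > P(15); an exact tie abstains (it carries no
  evidence). Cursor step 0.2 per epoch — five consistent epochs reach a
  side; the original system's gain is unpublished.
- Tally: a cursor hit decides with basis `hit` (all epochs are still
  voted, matching the 10-second window); otherwise majority; a tied
  majority falls back to the side closest to the cursor's last position,
  with dead center resolving to "do not rotate" (the conservative action).

## Game protocol and channel

Blocks are abstract two-orientation objects (0°/180°); a trial clears iff
the final orientation matches the gap. Sessions are 16 trials, 8 requiring
rotation, 4 per half, order randomized per seed.

**Forced errors.** The unreliable Sender's *transmitted* decision is
replaced by the complement of the currently correct action on 10 randomly
chosen trials, in both rounds. "Incorrect" is recomputed against the live
game state: after a wrong round-1 rotation the correct action flips, and
the forced error flips with it. In a noise-free pipeline this makes the
bad Sender's transmitted accuracy exactly 6/16 per round.

**Channel.** Yes → above-threshold pulse → phosphene; No → below-threshold
pulse → none. The default intensities (52/62/72% of maximum output)
follow the 5%-step calibration convention around a typical occipital
threshold. `perception_noise = 0.05` flips the reported percept: the
calibrated levels are reliable, but phosphene perception is not error-free.
The 8-second inter-pulse delay is logical time recorded in the log, not a
wall-clock sleep.

**Threshold calibration.** `pest_calibrate` is an adaptive staircase with
the classic sequential-testing step rules — halve on reversal, same size
for the second same-direction step, double from the third (capped) — and a
minimum-step stopping criterion; one simulated pulse per level, final
level as the estimate. Parameter recovery on a logistic psychometric
centered at 62% intensity is within 2 intensity-percent on average (200
runs). `staircase_levels` then finds the lowest level with 10/10 simulated
phosphenes above threshold and 10/10 misses below.

## Agents

Senders intend the correct action with probability `competence`
(default 1.0: in the original design all errors on the unreliable side are
injected by the forced-error manipulation, not by the Sender).

The Receiver combines two percept-implied actions:

1. **Trust.** Each Sender's reliability is a Beta-Bernoulli posterior over
   "percept agreed with the revealed correct action", updated from
   end-of-trial feedback only (both rounds of the finished trial); weight
   = posterior mean, uniform prior, both Senders starting at 0.5.
2. **Vote.** Agreement is followed; disagreement goes to the higher-weight
   Sender, with a seeded coin flip at exactly equal weights.
3. **Familiarization.** On trial t the Receiver instead answers uniformly
   at random with probability 0.8 · max(0, 1 − t/12).

The familiarization term deserves explanation, because the bare weighted
vote (items 1–2) is *not* sufficient to reproduce gradual reliability
learning: a hard argmax switches to the reliable Sender as soon as the
agreement counts differ — typically after a single trial — so the
Receiver/good-Sender coupling is already at its ceiling in block 1 and no
ascending block-wise trend exists to detect. (Probability matching,
Thompson sampling and posterior-confidence-gated variants were evaluated
and also fail to produce a robust trend; they only blur the same fast
switch.) Human receivers, by contrast, must first learn to read their own
phosphene percepts at all, and their coupling to the reliable Sender rises
near-linearly across all four blocks. The decaying-exploration term models
that practice effect in the simplest way and spans the transition across
the session. `explore_start = 0` recovers the pure weighted-vote policy.
The learning signal itself (MI separation between good and bad Senders)
does not depend on this term; only the *time course* does.

## Study conditions and what the simulations show

The default conditions — EEG snr 2.0, perception noise 0.05, competence
1.0, familiarization 0.8 over 12 trials — were fixed once, before the
replication runs, to place the simulated triads at the human study's
reported operating point. Realized values over replicates: mean accuracy
≈ 0.80 (reported: 0.8125), MI(good)/MI(bad) ≈ 0.28/0.03 (reported:
0.336/0.051), triad AUC ≈ 0.80 (reported: 0.83).

Under these conditions, across 100 replications of the five-triad design,
MI(good) > MI(bad) and both learning-trend Z statistics are positive in
well over 90% of replicates (asserted in the test suite at the ≥ 90%
level).

What this does *not* show: the synthetic EEG has no artifacts, eye
movements, electrode drift, alpha bursts or inter-subject variability; the
channel noise is i.i.d. rather than attention-dependent; and the Receiver
model is a deliberately minimal stand-in for human learning. Passing
these tests validates the pipeline's logic and statistics, not any claim
about real neural data.

## Numerical choices and degenerate inputs

- Epoching truncates a trailing partial epoch; recordings shorter than one
  epoch are rejected.
- MI uses 0·log 0 = 0; the result is clamped by construction to
  [0, 1] bits for binary pairs. The bias b = −N_R/(2 N_S ln 2) is reported
  alongside but not subtracted (estimates are deliberately uncorrected).
- `block_beta` rejects an all-zero Sender vector; `block_correlation`
  rejects constant vectors; `trend_z` rejects series of fewer than three
  blocks and flags zero-variance series (a perfectly linear 4-point series
  has zero residual and hence an undefined Z — only equal-slope series
  return Z = 0).
- One-sample transformed tests default to the directional ("greater")
  alternative — the natural above-chance hypothesis — making the
  signed-rank statistic the sum of positive ranks (R's V, e.g. V = 15 when
  all five values exceed the reference); two-group tests default to
  two-sided.
- All session randomness derives from one seed via `SeedSequence` spawning
  (separate streams for intents, channel, tie-breaks, and EEG noise), so
  logs are bit-reproducible.
- EDF output is plain 16-bit EDF; the writer quantizes with the exact
  inverse of the reader's affine rescaling, and round-trips are verified
  against MNE's independent EDF reader.

## Known limitations

- Single-channel EEG only; no artifact model or rejection.
- The 20-sample-per-block learning curves are intrinsically noisy; Z
  values of individual replicates vary widely even when their sign is
  stable.
- The pooled binomial test is exposed as generic `(successes, n, p0)`
  because the group-level convention used for the original p = 0.002 is
  not recoverable from the published numbers (13/16 gives p ≈ 0.0106
  one-sided).
- PEST is implemented in its classic step-rule form; other variants (e.g.
  Wald-rule run lengths) would give slightly different trial counts.
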