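"""Two-round collaborative game protocol and the simulated phosphene channel.

A session is 16 independent trials of a simplified Tetris-like game: a
block must either be rotated by 180 degrees or left alone so that it fills
a gap in the bottom line, which only the two Senders can see.  Each trial
runs two rounds — the block drops halfway after the Receiver's first
action, giving the Senders a chance to send corrective advice — so a wrong
first-round action can still be rectified.

One randomly chosen Sender is made unreliable: in 10 of the 16 trials the
decision actually sent to the Receiver is forced to be incorrect in both
rounds ("incorrect" is recomputed against the current game state, which in
round 2 depends on the round-1 action).

The stimulation channel is simulated: a "rotate" decision is delivered as
an above-threshold pulse that elicits a phosphene percept, "do not rotate"
as a below-threshold pulse eliciting none, with an optional perception-flip
probability and an 8-second logical delay between the two Senders' pulses.
Threshold calibration (PEST staircase plus the 5%-step consecutive-pulse
procedure for the two stimulation levels) is simulated against a
user-supplied psychometric function.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Literal

import numpy as np

from .agents import ReceiverModel, SenderModel, sender_intent
from .decoder import Decision, DecoderConfig, decode
from .synth_eeg import SSVEPSpec, downsample, generate_ssvep

__all__ = [
    "TrialState",
    "SessionPlan",
    "ChannelModel",
    "RoundRecord",
    "SessionLog",
    "EEGParams",
    "make_session_plan",
    "apply_forced_error",
    "transmit",
    "advance",
    "pest_calibrate",
    "staircase_levels",
    "run_session",
]

N_TRIALS = 16
N_FORCED = 10
Percept = Literal["phosphene", "none"]


@dataclass(frozen=True)
class TrialState:
    """State of one block: orientation and which orientation clears the line."""

    orientation: int = 0  # degrees, 0 or 180
    gap_fit: int = 0      # orientation that fills the gap
    round: int = 1
    phase: Literal["start", "midway", "resolved"] = "start"
    outcome: Literal["pending", "cleared", "failed"] = "pending"

    def __post_init__(self) -> None:
        if self.orientation not in (0, 180) or self.gap_fit not in (0, 180):
            raise ValueError("orientations are restricted to 0 or 180 degrees")

    @property
    def correct_action(self) -> int:
        """The currently correct decision: rotate (1) iff orientation mismatches the gap."""
        return int(self.orientation != self.gap_fit)


@dataclass(frozen=True)
class SessionPlan:
    """Randomized plan of one 16-trial session.

    ``trials[i]`` is the ground-truth required action of trial i (1 =
    rotate).  Eight trials require rotation and eight do not, four of each
    per half.  One Sender (``bad_sender``, 0-based index) transmits a
    forced-incorrect decision on the 10 ``forced_error_trials``.
    """

    trials: tuple[int, ...]
    bad_sender: int
    forced_error_trials: frozenset[int]
    seed: int

    def __post_init__(self) -> None:
        if len(self.trials) != N_TRIALS or sum(self.trials) != N_TRIALS // 2:
            raise ValueError(f"plan needs {N_TRIALS} trials, half of them rotations")
        half = N_TRIALS // 2
        if sum(self.trials[:half]) != half // 2 or sum(self.trials[half:]) != half // 2:
            raise ValueError("each half of the session must contain 4 rotation trials")
        if len(self.forced_error_trials) != N_FORCED:
            raise ValueError(f"exactly {N_FORCED} forced-error trials required")
        if self.bad_sender not in (0, 1):
            raise ValueError("bad_sender must be 0 or 1")


@dataclass(frozen=True)
class ChannelModel:
    """Parameters of the simulated occipital stimulation channel.

    Intensities are percent of maximum stimulator output.  ``yes_intensity``
    sits above the absolute phosphene threshold and ``no_intensity`` below
    it; ``perception_noise`` is the probability that the Receiver's report
    of the percept flips.  ``inter_pulse_delay`` (seconds) separates the two
    Senders' pulses in simulated logical time.
    """

    absolute_threshold: float = 62.0
    yes_intensity: float = 72.0
    no_intensity: float = 52.0
    perception_noise: float = 0.05
    inter_pulse_delay: float = 8.0

    def __post_init__(self) -> None:
        if not (self.no_intensity < self.absolute_threshold < self.yes_intensity):
            raise ValueError(
                "need no_intensity < absolute_threshold < yes_intensity, got "
                f"{self.no_intensity} / {self.absolute_threshold} / {self.yes_intensity}"
            )
        if not (0.0 <= self.perception_noise <= 0.5):
            raise ValueError("perception_noise must be in [0, 0.5]")


@dataclass(frozen=True)
class EEGParams:
    """Synthetic-EEG operating point used inside a simulated session.

    ``snr`` applies to every subject's SSVEP recording; ``math.inf`` gives a
    noise-free pipeline.  Senders are sampled at ``sender_fs``; the
    Receiver is acquired at ``receiver_fs`` and decimated to
    ``receiver_decode_fs`` before decoding.
    """

    snr: float = 2.0
    amplitude: float = 1.0
    noise_exponent: float = 1.0
    sender_fs: float = 250.0
    receiver_fs: float = 5000.0
    receiver_decode_fs: float = 500.0


@dataclass(frozen=True)
class RoundRecord:
    """Everything that happened in one round of one trial."""

    trial: int
    round: int
    truth: int                 # correct action at the start of this round
    s1_intent: int
    s1_sent: int
    s2_intent: int
    s2_sent: int
    percept1: Percept
    percept2: Percept
    receiver_intent: int
    receiver_decision: int
    forced_flag: bool
    pulse_times: tuple[float, float] = (0.0, 8.0)
    trust_weights: tuple[float, float] = (0.5, 0.5)


@dataclass
class SessionLog:
    """Complete record of one simulated session; input to all statistics."""

    plan: SessionPlan
    rows: list[RoundRecord] = field(default_factory=list)
    outcomes: list[str] = field(default_factory=list)  # per trial: cleared/failed
    exclusion_mask: frozenset[int] = frozenset()
    seed: int = 0

    @property
    def included_trials(self) -> list[int]:
        return [t for t in range(len(self.outcomes)) if t not in self.exclusion_mask]

    def decisions(
        self, who: Literal["receiver", "sender-1", "sender-2"], transmitted: bool = True
    ) -> list[int]:
        """Ordered decision sequence over included trials x rounds.

        For Senders, ``transmitted`` selects the post-forced-error decision
        actually delivered to the Receiver rather than the decoded intent.
        """
        out = []
        for row in self.rows:
            if row.trial in self.exclusion_mask:
                continue
            if who == "receiver":
                out.append(row.receiver_decision)
            elif who == "sender-1":
                out.append(row.s1_sent if transmitted else row.s1_intent)
            else:
                out.append(row.s2_sent if transmitted else row.s2_intent)
        return out

    def truths(self) -> list[int]:
        """Correct action per included trial x round, aligned with decisions()."""
        return [r.truth for r in self.rows if r.trial not in self.exclusion_mask]


def make_session_plan(seed: int) -> SessionPlan:
    """Draw a randomized, reproducible session plan.

    Rotation/non-rotation order is randomized under the constraint of four
    rotations per 8-trial half; the unreliable Sender and its 10
    forced-error trials are drawn uniformly.
    """
    rng = np.random.default_rng(seed)
    half = [1] * 4 + [0] * 4
    trials = tuple(rng.permutation(half).tolist() + rng.permutation(half).tolist())
    bad_sender = int(rng.integers(0, 2))
    forced = frozenset(int(i) for i in rng.choice(N_TRIALS, size=N_FORCED, replace=False))
    return SessionPlan(trials=trials, bad_sender=bad_sender, forced_error_trials=forced, seed=seed)


def apply_forced_error(
    decision: Decision,
    plan: SessionPlan,
    trial: int,
    correct_action: int,
    sender_index: int,
) -> Decision:
    """Force the unreliable Sender's transmitted decision to be incorrect.

    On a forced trial the output is the complement of the currently correct
    action — recomputed against the live game state, so a round-2 forced
    error is wrong with respect to the (possibly already rotated) block —
    regardless of what the Sender actually decided.  Non-forced trials pass
    through.  Calling this for the reliable Sender is an error.
    """
    if sender_index != plan.bad_sender:
        raise ValueError("forced errors apply only to the designated unreliable Sender")
    if trial in plan.forced_error_trials:
        return replace(decision, value=1 - correct_action)
    return decision


def transmit(
    decision: Decision | int, channel: ChannelModel, rng: np.random.Generator
) -> Percept:
    """Deliver one decision as a stimulation pulse and return the percept.

    Rotate (1) maps to an above-threshold pulse (phosphene), do-not-rotate
    (0) to a below-threshold pulse (no phosphene); the reported percept
    flips with probability ``channel.perception_noise``.
    """
    value = decision.value if isinstance(decision, Decision) else decision
    percept: Percept = "phosphene" if value == 1 else "none"
    if channel.perception_noise > 0 and rng.random() < channel.perception_noise:
        percept = "none" if percept == "phosphene" else "phosphene"
    return percept


def advance(state: TrialState, receiver_decision: Decision | int) -> TrialState:
    """Apply the Receiver's action and move the trial forward one round.

    Round 1 rotates (or not) and drops the block halfway; round 2 resolves
    the trial, which clears iff the final orientation matches the gap.
    """
    if state.phase == "resolved":
        raise ValueError("cannot advance a resolved trial")
    value = receiver_decision.value if isinstance(receiver_decision, Decision) else receiver_decision
    orientation = (state.orientation + 180) % 360 if value == 1 else state.orientation
    if state.round == 1:
        return replace(state, orientation=orientation, round=2, phase="midway")
    outcome = "cleared" if orientation == state.gap_fit else "failed"
    return replace(state, orientation=orientation, phase="resolved", outcome=outcome)


def _check_monotone(psychometric: Callable[[float], float], lo: float, hi: float) -> None:
    grid = np.linspace(lo, hi, 41)
    probs = np.array([psychometric(x) for x in grid])
    if np.any(np.diff(probs) < -1e-9):
        raise ValueError("simulated psychometric function must be non-decreasing in intensity")


def pest_calibrate(
    psychometric_sim: Callable[[float], float],
    start_intensity: float,
    *,
    initial_step: float = 8.0,
    min_step: float = 1.0,
    max_step: float = 16.0,
    max_trials: int = 200,
    bounds: tuple[float, float] = (0.0, 100.0),
    rng: np.random.Generator | None = None,
    seed: int = 0,
) -> float:
    """Estimate the 50% phosphene threshold with an adaptive PEST staircase.

    One simulated pulse is presented per level; a perceived phosphene steps
    the intensity down, a miss steps it up.  Step sizes follow the classic
    sequential-testing rules: halve on every reversal, keep the size on the
    second step in the same direction, double from the third consecutive
    same-direction step (capped at ``max_step``).  The staircase terminates
    when the next step would fall below ``min_step``; the final tested
    intensity is the threshold estimate.

    ``psychometric_sim`` maps intensity (percent of maximum output) to
    probability of perceiving a phosphene and must be non-decreasing.
    """
    _check_monotone(psychometric_sim, *bounds)
    if rng is None:
        rng = np.random.default_rng(seed)
    level = float(start_intensity)
    step = float(initial_step)
    direction = 0  # +1 up, -1 down
    run_length = 0
    for _ in range(max_trials):
        perceived = rng.random() < psychometric_sim(level)
        new_direction = -1 if perceived else +1
        if direction == 0:
            run_length = 1
        elif new_direction == direction:
            run_length += 1
            if run_length >= 3:
                step = min(step * 2.0, max_step)
        else:  # reversal
            step = step / 2.0
            run_length = 1
            if step < min_step:
                break
        direction = new_direction
        level = float(np.clip(level + direction * step, *bounds))
    return level


def staircase_levels(
    absolute_threshold: float,
    psychometric_sim: Callable[[float], float],
    rng: np.random.Generator,
    *,
    step: float = 5.0,
    n_consecutive: int = 10,
    bounds: tuple[float, float] = (0.0, 100.0),
) -> tuple[float, float]:
    """Find the two stimulation levels used for yes and no decisions.

    From the absolute threshold, intensity is raised in 5% increments until
    phosphenes are elicited on 10 consecutive simulated pulses (the "yes"
    level), then lowered in 5% decrements until no phosphene occurs on 10
    consecutive pulses (the "no" level).
    """
    _check_monotone(psychometric_sim, *bounds)

    def qualifies(level: float, want_phosphene: bool) -> bool:
        for _ in range(n_consecutive):
            perceived = rng.random() < psychometric_sim(level)
            if perceived != want_phosphene:
                return False
        return True

    yes_intensity = None
    level = absolute_threshold
    while level + step <= bounds[1]:
        level += step
        if qualifies(level, want_phosphene=True):
            yes_intensity = level
            break
    if yes_intensity is None:
        raise ValueError(
            "no intensity within bounds elicited phosphenes on "
            f"{n_consecutive} consecutive pulses; psychometric may be too shallow"
        )
    no_intensity = None
    level = absolute_threshold
    while level - step >= bounds[0]:
        level -= step
        if qualifies(level, want_phosphene=False):
            no_intensity = level
            break
    if no_intensity is None:
        raise ValueError(
            "no intensity within bounds suppressed phosphenes on "
            f"{n_consecutive} consecutive pulses; psychometric may be too shallow"
        )
    return yes_intensity, no_intensity


def _decode_intent(
    intent: int,
    cfg: DecoderConfig,
    eeg: EEGParams,
    fs: float,
    eeg_seed: int,
    decode_fs: float | None = None,
    **decision_kwargs,
) -> Decision:
    """Render an intent as synthetic SSVEP EEG and run it through the decoder."""
    freq = cfg.f_yes if intent == 1 else cfg.f_no
    spec = SSVEPSpec(
        target_freq=freq,
        amplitude=eeg.amplitude,
        noise_exponent=eeg.noise_exponent,
        snr=eeg.snr,
        seed=eeg_seed,
    )
    rec = generate_ssvep(spec, duration=cfg.window_len, fs=fs)
    if decode_fs is not None and decode_fs != fs:
        rec = downsample(rec, decode_fs)
    decision, _ = decode(rec, cfg, **decision_kwargs)
    return decision


def run_session(
    plan: SessionPlan,
    senders: tuple[SenderModel, SenderModel] = (SenderModel(), SenderModel()),
    receiver: ReceiverModel | None = None,
    decoder_cfg: DecoderConfig = DecoderConfig(),
    channel: ChannelModel = ChannelModel(),
    seed: int = 0,
    eeg: EEGParams = EEGParams(),
) -> SessionLog:
    """Simulate one full 16-trial, two-round session end to end.

    Per round: each Sender forms an intent, conveys it as synthetic SSVEP
    EEG which is decoded; the unreliable Sender's decision is replaced by a
    forced error on designated trials; both decisions cross the phosphene
    channel with an 8-second logical inter-pulse delay; the Receiver
    integrates the two percepts via its trust policy, conveys its own
    decision through the same SSVEP interface (acquired at 5000 Hz,
    decimated to 500 Hz), and the game state advances.  Trust updates on
    end-of-trial feedback.  Fully seeded and reproducible.
    """
    if receiver is None:
        receiver = ReceiverModel()
    ss = np.random.SeedSequence(seed)
    rng_intent, rng_channel, rng_tie = (
        np.random.default_rng(s) for s in ss.spawn(3)
    )
    eeg_seeds = iter(ss.spawn(1).pop().generate_state(N_TRIALS * 2 * 3 * 4))

    log = SessionLog(plan=plan, exclusion_mask=frozenset(), seed=seed)
    clock = 0.0
    for trial_idx, truth in enumerate(plan.trials):
        state = TrialState(orientation=0, gap_fit=180 if truth == 1 else 0)
        trial_records: list[RoundRecord] = []
        while state.phase != "resolved":
            round_no = state.round
            correct = state.correct_action
            intents, decoded = [], []
            for k, model in enumerate(senders):
                intent = sender_intent(correct, model, rng_intent)
                d = _decode_intent(
                    intent,
                    decoder_cfg,
                    eeg,
                    fs=eeg.sender_fs,
                    eeg_seed=int(next(eeg_seeds)) % (2**31),
                    role=f"sender-{k + 1}",
                    trial=trial_idx,
                    round=round_no,
                )
                intents.append(intent)
                decoded.append(d)
            sent = list(decoded)
            forced = trial_idx in plan.forced_error_trials
            sent[plan.bad_sender] = apply_forced_error(
                decoded[plan.bad_sender], plan, trial_idx, correct, plan.bad_sender
            )
            percept1 = transmit(sent[0], channel, rng_channel)
            pulse_times = (clock, clock + channel.inter_pulse_delay)
            clock += 2 * channel.inter_pulse_delay
            percept2 = transmit(sent[1], channel, rng_channel)
            percept_actions = (
                1 if percept1 == "phosphene" else 0,
                1 if percept2 == "phosphene" else 0,
            )
            receiver_intent = receiver.decide(percept_actions, rng_tie, trial=trial_idx)
            receiver_decision = _decode_intent(
                receiver_intent,
                decoder_cfg,
                eeg,
                fs=eeg.receiver_fs,
                eeg_seed=int(next(eeg_seeds)) % (2**31),
                decode_fs=eeg.receiver_decode_fs,
                role="receiver",
                trial=trial_idx,
                round=round_no,
            )
            trial_records.append(
                RoundRecord(
                    trial=trial_idx,
                    round=round_no,
                    truth=correct,
                    s1_intent=intents[0],
                    s1_sent=sent[0].value,
                    s2_intent=intents[1],
                    s2_sent=sent[1].value,
                    percept1=percept1,
                    percept2=percept2,
                    receiver_intent=receiver_intent,
                    receiver_decision=receiver_decision.value,
                    forced_flag=forced,
                    pulse_times=pulse_times,
                    trust_weights=receiver.trust.weights,
                )
            )
            state = advance(state, receiver_decision)
        # end-of-trial feedback: correct per-round actions become known
        for rec_row in trial_records:
            percept_actions = (
                1 if rec_row.percept1 == "phosphene" else 0,
                1 if rec_row.percept2 == "phosphene" else 0,
            )
            receiver.learn(percept_actions, rec_row.truth)
        log.rows.extend(trial_records)
        log.outcomes.append(state.outcome)
    return log
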