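"""SSVEP decision pipeline: filter, epoch, Welch, vote, cursor, tally.

The pipeline mirrors an online SSVEP cursor interface.  Incoming EEG is
band-limited with a 4th-order Butterworth filter (0-30 Hz, realized as mean
removal plus a causal 30 Hz low-pass, since a true 0 Hz high-pass corner is
degenerate), cut into consecutive 1-second epochs, and each epoch is
transformed with Welch's method.  An epoch votes "yes" (rotate) when power
at 17 Hz exceeds power at 15 Hz and "no" for the converse; an exact tie
abstains.  Votes drive a cursor from the center (0) toward the Yes side
(-1) or the No side (+1).  Hitting a side decides immediately; otherwise
the majority of epoch votes over the 10-second window decides, and a
residual tie falls back to the side closest to the cursor's last position.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import signal

from .synth_eeg import EEGRecording

__all__ = [
    "DecoderConfig",
    "PSDEstimate",
    "CursorTrace",
    "Decision",
    "Vote",
    "bandlimit",
    "epochs",
    "welch_power",
    "epoch_vote",
    "cursor_update",
    "tally_decision",
    "decode",
]

Vote = Literal["yes", "no", "abstain"]


@dataclass(frozen=True)
class DecoderConfig:
    """Settings of the SSVEP decision pipeline.

    Defaults follow the two-choice LED design: yes/rotate at 17 Hz,
    no/do-not-rotate at 15 Hz, a 0-30 Hz 4th-order Butterworth band limit,
    1-second epochs tallied over a 10-second window.  ``cursor_step`` is the
    fraction of the half-screen the cursor moves per epoch vote (0.2 means
    five consistent epochs reach a side).
    """

    filter_order: int = 4
    band: tuple[float, float] = (0.0, 30.0)
    epoch_len: float = 1.0
    window_len: float = 10.0
    f_yes: float = 17.0
    f_no: float = 15.0
    cursor_step: float = 0.2

    def __post_init__(self) -> None:
        if self.f_yes == self.f_no:
            raise ValueError("f_yes and f_no must differ")
        lo, hi = self.band
        for f in (self.f_yes, self.f_no):
            if not (lo <= f <= hi):
                raise ValueError(f"target frequency {f} Hz outside band {self.band}")
        if self.epoch_len <= 0 or self.window_len < self.epoch_len:
            raise ValueError("need 0 < epoch_len <= window_len")
        if not (0 < self.cursor_step <= 2):
            raise ValueError("cursor_step must be in (0, 2]")

    @property
    def max_epochs(self) -> int:
        return int(self.window_len / self.epoch_len)


@dataclass(frozen=True)
class PSDEstimate:
    """Welch power spectral density of one epoch (power in uV^2/Hz)."""

    freqs: np.ndarray
    power: np.ndarray
    epoch_index: int = 0

    def power_at(self, freq: float) -> float:
        """Power at the grid bin nearest ``freq``."""
        idx = int(np.argmin(np.abs(self.freqs - freq)))
        return float(self.power[idx])


@dataclass
class CursorTrace:
    """Cursor positions after each epoch; -1 is the Yes side, +1 the No side."""

    positions: list[float] = field(default_factory=list)
    hit: Literal["none", "yes-side", "no-side"] = "none"

    @property
    def last_position(self) -> float:
        return self.positions[-1] if self.positions else 0.0


@dataclass(frozen=True)
class Decision:
    """A binary rotate (1) / do-not-rotate (0) decision."""

    value: int
    role: str = "sender-1"
    trial: int = 0
    round: int = 1
    basis: Literal["hit", "majority", "closest-side"] = "majority"

    def __post_init__(self) -> None:
        if self.value not in (0, 1):
            raise ValueError(f"decision value must be 0 or 1, got {self.value}")


def bandlimit(rec: EEGRecording, cfg: DecoderConfig = DecoderConfig()) -> EEGRecording:
    """Mean-remove and low-pass the recording at the upper band edge.

    Uses a causal Butterworth of ``cfg.filter_order`` so out-of-band tones
    (e.g. 60 Hz line noise) are attenuated per the designed magnitude
    response; in-band SSVEP content passes within filter ripple.
    """
    hi = cfg.band[1]
    if hi >= rec.fs / 2:
        raise ValueError(
            f"band edge {hi} Hz must be below Nyquist ({rec.fs / 2} Hz)"
        )
    x = rec.samples - np.mean(rec.samples)
    sos = signal.butter(cfg.filter_order, hi, btype="low", fs=rec.fs, output="sos")
    y = signal.sosfilt(sos, x)
    return EEGRecording(samples=y, fs=rec.fs, label=rec.label, start_time=rec.start_time)


def epochs(rec: EEGRecording, cfg: DecoderConfig = DecoderConfig()) -> list[EEGRecording]:
    """Cut into consecutive non-overlapping epochs; a trailing partial epoch is dropped."""
    samples_per_epoch = round(cfg.epoch_len * rec.fs)
    if len(rec.samples) < samples_per_epoch:
        raise ValueError(
            f"recording of {len(rec.samples)} samples is shorter than one "
            f"epoch ({samples_per_epoch} samples)"
        )
    n_epochs = len(rec.samples) // samples_per_epoch
    return [
        EEGRecording(
            samples=rec.samples[i * samples_per_epoch : (i + 1) * samples_per_epoch],
            fs=rec.fs,
            label=rec.label,
            start_time=rec.start_time + i * cfg.epoch_len,
        )
        for i in range(n_epochs)
    ]


def welch_power(
    epoch: EEGRecording, cfg: DecoderConfig = DecoderConfig(), epoch_index: int = 0
) -> PSDEstimate:
    """Welch PSD of one epoch.

    A single full-length Hann segment per 1-s epoch gives 1 Hz bin spacing,
    so 15 and 17 Hz fall on exact grid bins at both 250 and 500 Hz.  The
    one-segment estimate is evaluated directly (mean removal, Hann taper,
    one-sided periodogram scaling), numerically identical to
    ``scipy.signal.welch(x, fs, nperseg=len(x))``.
    """
    x = epoch.samples
    n = len(x)
    window = signal.get_window("hann", n)
    tapered = (x - np.mean(x)) * window
    spectrum = np.fft.rfft(tapered)
    power = (np.abs(spectrum) ** 2) / (epoch.fs * np.sum(window**2))
    power[1:] *= 2.0
    if n % 2 == 0:
        power[-1] /= 2.0
    freqs = np.fft.rfftfreq(n, d=1.0 / epoch.fs)
    return PSDEstimate(freqs=freqs, power=power, epoch_index=epoch_index)


def epoch_vote(psd: PSDEstimate, cfg: DecoderConfig = DecoderConfig()) -> Vote:
    """Vote yes iff power at f_yes exceeds power at f_no; exact tie abstains."""
    p_yes = psd.power_at(cfg.f_yes)
    p_no = psd.power_at(cfg.f_no)
    if p_yes > p_no:
        return "yes"
    if p_no > p_yes:
        return "no"
    return "abstain"


def cursor_update(position: float, vote: Vote, cfg: DecoderConfig = DecoderConfig()) -> float:
    """Move the cursor one step toward the voted side, clamped to [-1, 1]."""
    if abs(position) > 1:
        raise ValueError(f"cursor position {position} outside [-1, 1]")
    if vote == "yes":
        position -= cfg.cursor_step
    elif vote == "no":
        position += cfg.cursor_step
    return float(min(1.0, max(-1.0, position)))


def tally_decision(
    votes: Sequence[Vote],
    trace: CursorTrace,
    cfg: DecoderConfig = DecoderConfig(),
    **decision_kwargs,
) -> Decision:
    """Resolve a window of epoch votes into one binary decision.

    A cursor hit decides immediately for that side.  Otherwise the majority
    of yes/no votes decides; an exact tie (including all-abstain) falls back
    to the side nearest the cursor's last position, the do-not-rotate side
    winning from dead center.
    """
    if len(votes) == 0:
        raise ValueError("cannot tally an empty vote sequence")
    if len(votes) > cfg.max_epochs:
        raise ValueError(f"{len(votes)} votes exceed the {cfg.max_epochs}-epoch window")
    if trace.hit == "yes-side":
        return Decision(value=1, basis="hit", **decision_kwargs)
    if trace.hit == "no-side":
        return Decision(value=0, basis="hit", **decision_kwargs)
    n_yes = sum(v == "yes" for v in votes)
    n_no = sum(v == "no" for v in votes)
    if n_yes > n_no:
        return Decision(value=1, basis="majority", **decision_kwargs)
    if n_no > n_yes:
        return Decision(value=0, basis="majority", **decision_kwargs)
    value = 1 if trace.last_position < 0 else 0
    return Decision(value=value, basis="closest-side", **decision_kwargs)


def decode(
    rec: EEGRecording, cfg: DecoderConfig = DecoderConfig(), **decision_kwargs
) -> tuple[Decision, CursorTrace]:
    """Run the full pipeline on one recording window.

    Composition of bandlimit -> epoching -> per-epoch Welch -> power vote ->
    cursor update -> tally.  All epochs in the window are voted on; the
    first boundary contact is recorded as the hit and takes precedence at
    tally time.  Deterministic for fixed input.
    """
    filtered = bandlimit(rec, cfg)
    votes: list[Vote] = []
    trace = CursorTrace()
    position = 0.0
    for i, ep in enumerate(epochs(filtered, cfg)[: cfg.max_epochs]):
        vote = epoch_vote(welch_power(ep, cfg, epoch_index=i), cfg)
        votes.append(vote)
        position = cursor_update(position, vote, cfg)
        trace.positions.append(position)
        if trace.hit == "none":
            if position <= -1.0:
                trace.hit = "yes-side"
            elif position >= 1.0:
                trace.hit = "no-side"
    decision = tally_decision(votes, trace, cfg, **decision_kwargs)
    return decision, trace
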