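"""Behavioral models for the two Senders and the trust-learning Receiver.

The human Receiver in the original design integrates two phosphene bits and
demonstrably learns which Sender is reliable.  The learning rule itself is
unobserved, so the Receiver here uses a minimal-assumption model: each
Sender's reliability is tracked as a Beta-Bernoulli posterior over
"percept agreed with the revealed correct action", and on disagreement the
Receiver follows the Sender with the higher posterior-mean weight (seeded
coin flip on exact ties).  Alternative policies can be plugged in by
subclassing :class:`ReceiverModel`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SenderModel", "TrustState", "ReceiverModel", "sender_intent", "receiver_decide", "trust_update"]


@dataclass(frozen=True)
class SenderModel:
    """A Sender who intends the correct action with probability ``competence``."""

    competence: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.competence <= 1.0):
            raise ValueError(f"competence must be in [0, 1], got {self.competence}")


@dataclass(frozen=True)
class TrustState:
    """Beta-Bernoulli evidence about each Sender's reliability.

    ``agreements[i]`` / ``disagreements[i]`` count how often Sender i's
    percept-implied action matched / contradicted the correct action revealed
    by end-of-trial feedback.  The weight of Sender i is the posterior mean
    of a Beta(1 + agreements, 1 + disagreements) reliability estimate; both
    Senders start at weight 0.5.
    """

    agreements: tuple[int, int] = (0, 0)
    disagreements: tuple[int, int] = (0, 0)

    @property
    def weights(self) -> tuple[float, float]:
        return tuple(
            (1 + a) / (2 + a + d)
            for a, d in zip(self.agreements, self.disagreements)
        )


def sender_intent(true_action: int, model: SenderModel, rng: np.random.Generator) -> int:
    """The action the Sender tries to convey: correct w.p. ``competence``."""
    if rng.random() < model.competence:
        return true_action
    return 1 - true_action


def receiver_decide(
    percepts: tuple[int, int], trust: TrustState, rng: np.random.Generator
) -> int:
    """Integrate the two percept-implied actions into one decision.

    Agreement is followed unconditionally; on disagreement the
    higher-weight Sender wins, with a seeded coin flip at exactly equal
    weights.
    """
    p1, p2 = percepts
    if p1 == p2:
        return p1
    w1, w2 = trust.weights
    if w1 > w2:
        return p1
    if w2 > w1:
        return p2
    return p1 if rng.random() < 0.5 else p2


def trust_update(trust: TrustState, percepts: tuple[int, int], correct_action: int) -> TrustState:
    """Update reliability evidence after feedback reveals the correct action.

    Each Sender whose percept-implied action equals ``correct_action`` gains
    an agreement, the others a disagreement.
    """
    if correct_action not in (0, 1):
        raise ValueError("trust can only be updated once the correct action is resolved")
    agreements = list(trust.agreements)
    disagreements = list(trust.disagreements)
    for i, p in enumerate(percepts):
        if p == correct_action:
            agreements[i] += 1
        else:
            disagreements[i] += 1
    return TrustState(agreements=tuple(agreements), disagreements=tuple(disagreements))


@dataclass
class ReceiverModel:
    """Weighted-vote Receiver with Beta-Bernoulli trust learning and a
    decaying familiarization (practice) phase.

    The weighted vote alone converges within a trial or two, which is far
    faster than human receivers — who must first learn to interpret their
    phosphene percepts at all — and leaves no gradual block-by-block trend.
    The practice phase models that early perceptual uncertainty: on trial
    ``t`` (0-based) the Receiver answers uniformly at random with
    probability ``explore_start * max(0, 1 - t / explore_decay_trials)``
    and otherwise applies the trust-weighted vote.  With the defaults the
    random fraction decays linearly from 0.8 to 0 over the first 12 of the
    16 trials, producing the near-linear rise in Receiver/good-Sender
    coupling seen in gradual reliability learning.  Setting
    ``explore_start=0`` recovers the pure weighted-vote policy.

    Percepts are taken at face value (no awareness of perception errors);
    trust updates only on end-of-trial feedback, not mid-trial.
    """

    trust: TrustState = field(default_factory=TrustState)
    explore_start: float = 0.8
    explore_decay_trials: int = 12

    def exploration_rate(self, trial: int) -> float:
        if self.explore_decay_trials <= 0:
            return 0.0
        return self.explore_start * max(0.0, 1.0 - trial / self.explore_decay_trials)

    def decide(
        self, percepts: tuple[int, int], rng: np.random.Generator, trial: int = 0
    ) -> int:
        if self.explore_start > 0 and rng.random() < self.exploration_rate(trial):
            return int(rng.random() < 0.5)
        return receiver_decide(percepts, self.trust, rng)

    def learn(self, percepts: tuple[int, int], correct_action: int) -> None:
        self.trust = trust_update(self.trust, percepts, correct_action)
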