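"""Evaluation statistics for simulated brain-to-brain sessions.

Implements the complete analysis suite: accuracy with an exact binomial
test, per-epoch SSVEP power comparison, single-operating-point ROC/AUC with
arcsine-square-root (angular) transformed t-tests and Wilcoxon tests,
plug-in mutual information between decision sequences with the first-order
small-sample bias approximation, and the block-wise reliability-learning
analysis (no-intercept regression weights, Pearson correlations, and the
slope-difference Z test for linear trends).

Conventions
-----------
* Decisions are binary: 0 = do-not-rotate, 1 = rotate.
* A single binary classifier has one ROC operating point; its AUC is the
  area of the trapezoid through (0,0) -> (FPR,TPR) -> (1,1), i.e.
  ``(1 + TPR - FPR) / 2``.
* MI is reported in bits, so a perfectly informative balanced binary
  channel gives 1.0 and independence gives 0.0.  The plug-in estimator on
  ``N_S`` samples with ``N_R`` possible responses carries an approximate
  bias ``b = -N_R / (2 N_S ln 2)`` bits.
* Learning curves concatenate, per 4-trial block, the round-1 decisions of
  same-role participants across triads (20-long vectors for 5 triads).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .game import SessionLog

__all__ = [
    "MIResult",
    "ROCResult",
    "TrendResult",
    "TriadResult",
    "accuracy",
    "binomial_test",
    "power_comparison",
    "roc_single_point",
    "angular_transform",
    "transformed_tests",
    "mutual_information",
    "mi_bias",
    "block_beta",
    "block_correlation",
    "trend_z",
    "evaluate",
]


@dataclass(frozen=True)
class MIResult:
    """Plug-in mutual information of a binary decision pair, in bits."""

    mi: float
    joint_counts: np.ndarray
    n_samples: int
    bias: float


@dataclass(frozen=True)
class ROCResult:
    """Single-operating-point ROC summary of a binary decision sequence."""

    tpr: float
    fpr: float
    auc: float


@dataclass(frozen=True)
class TrendResult:
    """Linear-trend slopes for the good and bad Sender and their difference Z."""

    slope_good: float
    slope_bad: float
    se_good: float
    se_bad: float
    z: float


def accuracy(log: SessionLog) -> float:
    """Proportion of cleared trials among those not excluded from analysis."""
    included = log.included_trials
    if not included:
        raise ValueError("no included trials after applying the exclusion mask")
    cleared = sum(log.outcomes[t] == "cleared" for t in included)
    return cleared / len(included)


def binomial_test(successes: int, n: int, p0: float = 0.5) -> float:
    """One-sided upper-tail exact binomial p-value, P(X >= successes)."""
    if not (0 <= successes <= n):
        raise ValueError(f"need 0 <= successes <= n, got {successes}/{n}")
    return float(sps.binomtest(successes, n, p0, alternative="greater").pvalue)


def power_comparison(
    epoch_powers_correct: np.ndarray, epoch_powers_incorrect: np.ndarray
) -> tuple[float, float]:
    """Two-sample t-test of per-epoch band power, correct vs incorrect frequency.

    Returns ``(t, p)``; a positive t means more power at the frequency
    corresponding to the correct answer.  Degenerate (zero-variance-in-both)
    input is flagged.
    """
    a = np.asarray(epoch_powers_correct, dtype=float)
    b = np.asarray(epoch_powers_incorrect, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least two epochs per group")
    if np.var(a) == 0 and np.var(b) == 0:
        if np.mean(a) == np.mean(b):
            return 0.0, 1.0
        raise ValueError("degenerate zero-variance groups with unequal means")
    t, p = sps.ttest_ind(a, b)
    return float(t), float(p)


def roc_single_point(decisions, truth) -> ROCResult:
    """ROC operating point and trapezoid AUC of a binary decision sequence.

    TPR is the probability of deciding 1 when the truth is 1, FPR of
    deciding 1 when the truth is 0; AUC is ``(1 + TPR - FPR) / 2``.
    """
    d = np.asarray(decisions, dtype=int)
    t = np.asarray(truth, dtype=int)
    if d.shape != t.shape:
        raise ValueError("decisions and truth must have equal length")
    if t.min() == t.max():
        raise ValueError("truth must contain both classes for ROC analysis")
    tpr = float(np.mean(d[t == 1]))
    fpr = float(np.mean(d[t == 0]))
    return ROCResult(tpr=tpr, fpr=fpr, auc=(1.0 + tpr - fpr) / 2.0)


def angular_transform(x: float) -> float:
    """Arcsine-square-root (variance-stabilizing) transform of a proportion."""
    arr = np.asarray(x, dtype=float)
    if np.any(arr < 0) or np.any(arr > 1):
        raise ValueError("angular transform is defined on [0, 1]")
    return np.arcsin(np.sqrt(arr)) if arr.ndim else float(np.arcsin(math.sqrt(float(arr))))


def transformed_tests(
    values,
    reference: float | None = None,
    second_group=None,
    paired: bool = True,
    alternative: str | None = None,
) -> dict[str, float]:
    """Parametric and non-parametric tests on proportion-valued data.

    The t-test runs on angular-transformed values (one-sample against
    ``reference``, or two-sample against ``second_group``, paired across
    triads by default); the Wilcoxon test runs on the untransformed values
    with a continuity correction (signed-rank in the one-sample/paired
    case, rank-sum otherwise).  The one-sample case defaults to the
    directional ``greater`` alternative — testing above-chance performance
    — so the signed-rank statistic is the sum of positive ranks (R's
    ``V``); the two-group case defaults to two-sided.  Returns
    ``{"t", "t_p", "w", "w_p"}``.
    """
    vals = np.asarray(values, dtype=float)
    if len(vals) < 2:
        raise ValueError("need at least two values")
    if (reference is None) == (second_group is None):
        raise ValueError("provide exactly one of reference or second_group")
    tv = angular_transform(vals)
    if reference is not None:
        alternative = alternative or "greater"
        if np.all(vals == reference):
            return {"t": 0.0, "t_p": 1.0, "w": 0.0, "w_p": 1.0}
        t, t_p = sps.ttest_1samp(tv, angular_transform(reference), alternative=alternative)
        w, w_p = sps.wilcoxon(vals - reference, correction=True, alternative=alternative)
    else:
        alternative = alternative or "two-sided"
        other = np.asarray(second_group, dtype=float)
        to = angular_transform(other)
        if paired:
            if np.all(vals == other):
                return {"t": 0.0, "t_p": 1.0, "w": 0.0, "w_p": 1.0}
            t, t_p = sps.ttest_rel(tv, to)
            w, w_p = sps.wilcoxon(vals - other, correction=True)
        else:
            t, t_p = sps.ttest_ind(tv, to)
            w, w_p = sps.mannwhitneyu(vals, other, use_continuity=True)
    return {"t": float(t), "t_p": float(t_p), "w": float(w), "w_p": float(w_p)}


def mutual_information(r, s) -> MIResult:
    """Plug-in mutual information (bits) of two equal-length binary sequences.

    Computed from the empirical 2x2 joint; 0*log(0) terms contribute zero.
    Includes the analytic first-order bias of the estimate for reference
    (the reported ``mi`` is uncorrected).
    """
    rv = np.asarray(r, dtype=int)
    sv = np.asarray(s, dtype=int)
    if rv.shape != sv.shape or rv.ndim != 1 or len(rv) < 1:
        raise ValueError("r and s must be equal-length 1-D sequences")
    counts = np.zeros((2, 2))
    for ri, si in zip(rv, sv):
        counts[ri, si] += 1
    n = len(rv)
    joint = counts / n
    pr = joint.sum(axis=1)
    ps = joint.sum(axis=0)
    mi = 0.0
    for i in (0, 1):
        for j in (0, 1):
            if joint[i, j] > 0:
                mi += joint[i, j] * math.log2(joint[i, j] / (pr[i] * ps[j]))
    return MIResult(mi=mi, joint_counts=counts, n_samples=n, bias=mi_bias(2, n))


def mi_bias(n_responses: int, n_samples: int) -> float:
    """First-order small-sample bias of plug-in MI: -N_R / (2 N_S ln 2) bits."""
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    return -n_responses / (2.0 * n_samples * math.log(2.0))


def block_beta(r, s) -> float:
    """No-intercept least-squares weight of Receiver on Sender decisions.

    For binary vectors this is ``beta = (S^T S)^-1 S^T R = sum(s*r)/sum(s^2)``.
    """
    rv = np.asarray(r, dtype=float)
    sv = np.asarray(s, dtype=float)
    if rv.shape != sv.shape:
        raise ValueError("vectors must have equal length")
    denom = float(sv @ sv)
    if denom == 0:
        raise ValueError("Sender vector is all-zero; regression weight undefined")
    return float(sv @ rv) / denom


def block_correlation(r, s) -> float:
    """Pearson correlation of two binary decision vectors."""
    rv = np.asarray(r, dtype=float)
    sv = np.asarray(s, dtype=float)
    if np.var(rv) == 0 or np.var(sv) == 0:
        raise ValueError("Pearson correlation undefined for a constant vector")
    return float(sps.pearsonr(rv, sv).statistic)


def _ols_trend(y: np.ndarray) -> tuple[float, float]:
    """Slope and slope standard error of y against block index 1..len(y)."""
    y = np.asarray(y, dtype=float)
    x = np.arange(1, len(y) + 1, dtype=float)
    if len(y) < 3:
        raise ValueError("need at least three blocks for a trend")
    res = sps.linregress(x, y)
    return float(res.slope), float(res.stderr)


def trend_z(metric_by_block_good, metric_by_block_bad) -> TrendResult:
    """Slope-difference Z between good- and bad-Sender learning trends.

    Each series is fit with ordinary least squares against block number;
    ``Z = (beta_g - beta_b) / sqrt(SE_g^2 + SE_b^2)``.  Z is antisymmetric
    under swapping the two series.  If both slope standard errors are zero
    (noiseless series) the statistic is undefined and flagged.
    """
    bg, seg = _ols_trend(metric_by_block_good)
    bb, seb = _ols_trend(metric_by_block_bad)
    denom = math.sqrt(seg**2 + seb**2)
    if denom == 0:
        if bg == bb:
            return TrendResult(bg, bb, seg, seb, 0.0)
        raise ValueError("zero-variance trend series; Z undefined")
    return TrendResult(slope_good=bg, slope_bad=bb, se_good=seg, se_bad=seb, z=(bg - bb) / denom)


@dataclass
class TriadResult:
    """All computed metrics of a multi-triad evaluation."""

    accuracy_per_triad: list[float]
    accuracy_mean: float
    roc_triad: list[ROCResult]
    roc_good: list[ROCResult]
    roc_bad: list[ROCResult]
    mi_good: list[MIResult]
    mi_bad: list[MIResult]
    beta_curve_good: list[float] = field(default_factory=list)
    beta_curve_bad: list[float] = field(default_factory=list)
    corr_curve_good: list[float] = field(default_factory=list)
    corr_curve_bad: list[float] = field(default_factory=list)
    trend_beta: TrendResult | None = None
    trend_corr: TrendResult | None = None

    @property
    def mean_auc(self) -> float:
        return float(np.mean([r.auc for r in self.roc_triad]))

    @property
    def mean_mi_good(self) -> float:
        return float(np.mean([m.mi for m in self.mi_good]))

    @property
    def mean_mi_bad(self) -> float:
        return float(np.mean([m.mi for m in self.mi_bad]))


def _role_names(log: SessionLog) -> tuple[str, str]:
    """(good, bad) sender column names for one session."""
    bad = f"sender-{log.plan.bad_sender + 1}"
    good = f"sender-{2 - log.plan.bad_sender}"
    return good, bad


def _block_vectors(logs, who: str, n_blocks: int = 4, block_size: int = 4):
    """Concatenated round-1 decision vectors per block across all sessions.

    ``who`` is "receiver", "good" or "bad".  Excluded trials are dropped,
    so block vectors may be shorter than (block_size x n_sessions).
    """
    vectors = [[] for _ in range(n_blocks)]
    for log in logs:
        good, bad = _role_names(log)
        col = {"receiver": "receiver", "good": good, "bad": bad}[who]
        for row in log.rows:
            if row.round != 1 or row.trial in log.exclusion_mask:
                continue
            block = min(row.trial // block_size, n_blocks - 1)
            if col == "receiver":
                vectors[block].append(row.receiver_decision)
            elif col == "sender-1":
                vectors[block].append(row.s1_sent)
            else:
                vectors[block].append(row.s2_sent)
    return vectors


def evaluate(logs: list[SessionLog]) -> TriadResult:
    """Run the full evaluation suite over one or more session logs.

    Per session: accuracy, single-point ROC/AUC of the triad (Receiver
    decisions vs correct actions over all included rounds) and of each
    Sender type, and MI between the Receiver and each Sender's transmitted
    decisions (up to 32 samples: 16 trials x 2 rounds).  Across sessions:
    block-wise learning curves on concatenated decision vectors and the
    slope-difference trend Z for both measures.  Exclusion masks are
    honored throughout.
    """
    if not logs:
        raise ValueError("need at least one session log")
    acc = [accuracy(log) for log in logs]
    roc_triad, roc_good, roc_bad, mi_good, mi_bad = [], [], [], [], []
    for log in logs:
        truths = log.truths()
        rdec = log.decisions("receiver")
        good, bad = _role_names(log)
        gdec = log.decisions(good)
        bdec = log.decisions(bad)
        roc_triad.append(roc_single_point(rdec, truths))
        roc_good.append(roc_single_point(gdec, truths))
        roc_bad.append(roc_single_point(bdec, truths))
        mi_good.append(mutual_information(rdec, gdec))
        mi_bad.append(mutual_information(rdec, bdec))

    result = TriadResult(
        accuracy_per_triad=acc,
        accuracy_mean=float(np.mean(acc)),
        roc_triad=roc_triad,
        roc_good=roc_good,
        roc_bad=roc_bad,
        mi_good=mi_good,
        mi_bad=mi_bad,
    )

    rec_blocks = _block_vectors(logs, "receiver")
    good_blocks = _block_vectors(logs, "good")
    bad_blocks = _block_vectors(logs, "bad")
    try:
        result.beta_curve_good = [block_beta(r, s) for r, s in zip(rec_blocks, good_blocks)]
        result.beta_curve_bad = [block_beta(r, s) for r, s in zip(rec_blocks, bad_blocks)]
        result.trend_beta = trend_z(result.beta_curve_good, result.beta_curve_bad)
    except ValueError:
        pass  # degenerate blocks (e.g. an all-zero sender vector): curves omitted
    try:
        result.corr_curve_good = [
            block_correlation(r, s) for r, s in zip(rec_blocks, good_blocks)
        ]
        result.corr_curve_bad = [
            block_correlation(r, s) for r, s in zip(rec_blocks, bad_blocks)
        ]
        result.trend_corr = trend_z(result.corr_curve_good, result.corr_curve_bad)
    except ValueError:
        pass
    return result
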