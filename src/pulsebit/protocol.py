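"""Renewal-process pulse protocols on a 1-minute grid.

A stimulation protocol is fully described by the probability law of the
interval between consecutive light pulses.  Treating the pulse train as a
discrete-time renewal process, this module derives the per-minute pulse
hazard, the input entropy rate, and the joint law of (interval, time since
last pulse) that the decoder's training sampler needs, and builds concrete
pulse sequences — either i.i.d. draws or orderings in which each interval
length is preceded by intervals representative of the reference law.

All entropies are computed in nats internally; conversion to bits happens
once, at the reporting boundary.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

#: Hazard probabilities are clipped into this open interval before logit
#: transforms; the forced pulse at the maximum interval (hazard 1) would
#: otherwise produce an infinite prior logit.
HAZARD_CLIP = 1e-4

#: Occurrence counts of each interval length (minutes) in the experimental
#: light-pulse sequence: 57 intervals totalling 1010 min (~17 h).
EXPERIMENTAL_INTERVAL_COUNTS: dict[int, int] = {
    **{i: 2 for i in range(5, 13)},
    **{i: 3 for i in range(13, 18)},
    **{i: 2 for i in range(18, 26)},
    **{i: 1 for i in range(26, 36)},
}


@dataclass(frozen=True)
class IntervalDistribution:
    """Probability law of pulse-to-pulse intervals on the 1-min grid.

    Parameters
    ----------
    support : array of int
        Distinct interval lengths in minutes, ascending, all >= 1.
    probs : array of float
        Probability of each support element; non-negative, sums to 1.
    """

    support: np.ndarray
    probs: np.ndarray

    def __post_init__(self):
        support = np.asarray(self.support, dtype=np.int64)
        probs = np.asarray(self.probs, dtype=np.float64)
        if support.ndim != 1 or probs.shape != support.shape:
            raise ValueError("support and probs must be 1-d arrays of equal length")
        if support.size == 0:
            raise ValueError("empty support")
        if np.any(support < 1):
            raise ValueError("interval lengths must be >= 1 minute")
        if np.any(np.diff(support) <= 0):
            raise ValueError("support must be strictly ascending distinct integers")
        if np.any(probs < 0):
            raise ValueError("probabilities must be non-negative")
        if abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError(f"probabilities sum to {probs.sum()!r}, not 1")
        object.__setattr__(self, "support", support)
        object.__setattr__(self, "probs", probs)

    def mean(self) -> float:
        """Expected interval length in minutes."""
        return float(self.support @ self.probs)

    def entropy_nat(self) -> float:
        p = self.probs[self.probs > 0]
        return float(-(p @ np.log(p)))

    def entropy_bits(self) -> float:
        """Shannon entropy per interval ('letter'), in bits."""
        return self.entropy_nat() / math.log(2)

    def quantile(self, q: float) -> int:
        """Smallest support value with CDF >= q."""
        cdf = np.cumsum(self.probs)
        idx = int(np.searchsorted(cdf, q - 1e-12, side="left"))
        return int(self.support[min(idx, self.support.size - 1)])

    def prob_of(self, interval: int) -> float:
        idx = np.searchsorted(self.support, interval)
        if idx < self.support.size and self.support[idx] == interval:
            return float(self.probs[idx])
        return 0.0


@dataclass(frozen=True)
class Hazard:
    """Per-minute pulse probability given the time since the last pulse.

    ``probs_by_last[L-1]`` is P(pulse now | last pulse L minutes ago), for
    L = 1 .. max supported interval.  At the maximum interval the hazard
    is 1: a pulse is certain once only the longest interval remains.
    """

    probs_by_last: np.ndarray

    def __post_init__(self):
        h = np.asarray(self.probs_by_last, dtype=np.float64)
        if h.ndim != 1 or h.size == 0:
            raise ValueError("hazard must be a non-empty 1-d array")
        if np.any((h < 0) | (h > 1)):
            raise ValueError("hazard values must lie in [0, 1]")
        object.__setattr__(self, "probs_by_last", h)

    @property
    def max_last(self) -> int:
        return int(self.probs_by_last.size)

    def at(self, last) -> np.ndarray:
        """Hazard at integer ``last`` (scalar or array), 1-based."""
        last = np.asarray(last, dtype=np.int64)
        if np.any((last < 1) | (last > self.max_last)):
            raise ValueError(f"last outside hazard domain 1..{self.max_last}")
        return self.probs_by_last[last - 1]

    def logit_at(self, last) -> np.ndarray:
        """Natural-log prior logit of the clipped hazard."""
        h = np.clip(self.at(last), HAZARD_CLIP, 1.0 - HAZARD_CLIP)
        return np.log(h) - np.log1p(-h)


@dataclass(frozen=True)
class PulseSequence:
    """Ordered light-pulse times (integer minutes) within a recording.

    ``origin`` is the time of the first recorded frame; all pulse times lie
    in ``[origin, origin + n_timepoints)``.
    """

    pulse_times: np.ndarray
    n_timepoints: int
    origin: int = 0

    def __post_init__(self):
        t = np.asarray(self.pulse_times, dtype=np.int64)
        if t.ndim != 1:
            raise ValueError("pulse_times must be 1-d")
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError("pulse times must be strictly increasing")
        if t.size and (t[0] < self.origin or t[-1] >= self.origin + self.n_timepoints):
            raise ValueError("pulse times outside [origin, origin + n_timepoints)")
        object.__setattr__(self, "pulse_times", t)

    @property
    def intervals(self) -> np.ndarray:
        """Differences between consecutive pulse times (minutes)."""
        return np.diff(self.pulse_times)


def empirical_distribution_from_counts(counts: dict[int, int]) -> IntervalDistribution:
    """Normalize occurrence counts of interval lengths into a distribution."""
    if not counts:
        raise ValueError("counts must be non-empty")
    for interval, c in counts.items():
        if int(c) != c or c <= 0:
            raise ValueError(f"count for interval {interval} must be a positive integer, got {c!r}")
    support = np.array(sorted(counts), dtype=np.int64)
    n = np.array([counts[int(i)] for i in support], dtype=np.float64)
    return IntervalDistribution(support, n / n.sum())


def experimental_distribution() -> IntervalDistribution:
    """The interval law of the experimental stimulation sequence."""
    return empirical_distribution_from_counts(EXPERIMENTAL_INTERVAL_COUNTS)


def gamma_interval_distribution(shape: float = 4.0, scale_min: float = 5.0,
                                support_min: int = 1, support_max: int = 90) -> IntervalDistribution:
    """Gamma(shape, scale) design law discretized onto integer minutes.

    The experimental protocol was designed to approximate Gamma(4, 5 min).
    """
    from scipy import stats

    support = np.arange(support_min, support_max + 1)
    # probability mass of each 1-min bin centred on the grid point
    cdf = stats.gamma.cdf(np.concatenate([[support_min - 0.5], support + 0.5]),
                          shape, scale=scale_min)
    probs = np.diff(cdf)
    if probs.sum() <= 0:
        raise ValueError("gamma law has no mass on the requested support")
    return IntervalDistribution(support, probs / probs.sum())


def geometric_distribution(p: float = 0.5, max_support: int = 64) -> IntervalDistribution:
    """Memoryless protocol: an independent pulse each minute with probability p.

    Intervals are geometric; the truncation tail mass is folded into the
    last support point, which preserves the constant hazard p exactly on
    1..max_support-1.  For p = 1/2 the entropy rate is 60 bit/h.
    """
    if not 0 < p < 1:
        raise ValueError("p must lie in (0, 1)")
    support = np.arange(1, max_support + 1)
    probs = p * (1 - p) ** (support - 1.0)
    probs[-1] = (1 - p) ** (max_support - 1.0)
    return IntervalDistribution(support, probs / probs.sum())


def hazard_from_distribution(dist: IntervalDistribution) -> Hazard:
    """Renewal hazard: h(L) = P(I = L) / P(I >= L), for L = 1..max(support)."""
    max_l = int(dist.support[-1])
    pmf = np.zeros(max_l + 1)
    pmf[dist.support] = dist.probs
    survival = np.cumsum(pmf[::-1])[::-1]  # survival[L] = P(I >= L)
    with np.errstate(invalid="ignore", divide="ignore"):
        h = np.where(survival[1:] > 0, pmf[1:] / survival[1:], 0.0)
    h[-1] = 1.0 if pmf[max_l] > 0 else h[-1]
    return Hazard(np.clip(h, 0.0, 1.0))


def distribution_from_hazard(hazard: Hazard) -> IntervalDistribution:
    """Invert :func:`hazard_from_distribution` (round-trip inverse)."""
    h = hazard.probs_by_last
    survival = np.concatenate([[1.0], np.cumprod(1.0 - h)])[: h.size]
    pmf = survival * h
    keep = pmf > 1e-15
    support = np.arange(1, h.size + 1)[keep]
    probs = pmf[keep]
    return IntervalDistribution(support, probs / probs.sum())


def entropy_rate(dist: IntervalDistribution) -> float:
    """Input entropy rate of the renewal pulse train, in bit/hour.

    Each interval carries H(I) bits and occupies E[I] minutes on average,
    so the rate is 60 * H(I) / E[I].  For the memoryless per-minute-1/2
    protocol this equals 60 bit/h; a deterministic interval carries 0.
    """
    return 60.0 * dist.entropy_bits() / dist.mean()


def joint_interval_last(dist: IntervalDistribution) -> dict[tuple[int, int], float]:
    """Joint law of (interval containing a timepoint, minutes since last pulse).

    A uniformly chosen timepoint falls in an interval of length I with
    length-biased probability I * p(I) / E[I] and is uniform over the I
    positions L = 1..I within it, hence P(I, L) = p(I) / E[I].
    """
    mean = dist.mean()
    out: dict[tuple[int, int], float] = {}
    for interval, p in zip(dist.support, dist.probs):
        if p <= 0:
            continue
        cell = float(p / mean)
        for last in range(1, int(interval) + 1):
            out[(int(interval), last)] = cell
    return out


def sample_pulse_sequence(dist: IntervalDistribution, duration: int, seed: int,
                          origin: int = 0) -> PulseSequence:
    """Draw i.i.d. intervals from ``dist`` until ``duration`` is exhausted.

    The first pulse occurs one interval after ``origin``; pulses beyond
    ``origin + duration`` are discarded.
    """
    if duration < int(dist.support[0]):
        raise ValueError(f"duration {duration} shorter than the minimum interval "
                         f"{int(dist.support[0])}")
    rng = np.random.default_rng(seed)
    times = []
    t = origin
    while True:
        t += int(rng.choice(dist.support, p=dist.probs))
        if t >= origin + duration:
            break
        times.append(t)
    return PulseSequence(np.array(times, dtype=np.int64), n_timepoints=duration, origin=origin)


def sequence_from_intervals(intervals, origin: int = 0, pad: int = 10) -> PulseSequence:
    """Build a PulseSequence whose consecutive pulse gaps are ``intervals``."""
    intervals = np.asarray(intervals, dtype=np.int64)
    times = origin + np.cumsum(intervals)
    return PulseSequence(times, n_timepoints=int(intervals.sum()) + pad, origin=origin)


def order_intervals(counts: dict[int, int], reference: IntervalDistribution,
                    seed: int = 0) -> PulseSequence:
    """Order an interval multiset so predecessors represent the reference law.

    For each length with m occurrences the desired predecessors are the
    reference quantiles at levels j/(m+1), j = 1..m; a greedy pass then
    chains the occurrences, always emitting next the pending occurrence
    whose predecessor target is closest to the interval just emitted.  The
    first interval (which has no predecessor) is the occurrence with the
    largest target.  If targets cannot be matched exactly the greedy
    assignment is best-effort and a warning is logged.
    """
    if not counts:
        raise ValueError("counts must be non-empty")
    rng = np.random.default_rng(seed)
    items: list[tuple[int, float]] = []  # (length, target predecessor)
    for length in sorted(counts):
        m = counts[length]
        if int(m) != m or m <= 0:
            raise ValueError(f"count for interval {length} must be a positive integer")
        for j in range(1, int(m) + 1):
            items.append((int(length), float(reference.quantile(j / (m + 1)))))

    if len(items) == 1:
        return sequence_from_intervals([items[0][0]])

    # occurrence with the largest target goes first (its target is unused)
    first_idx = max(range(len(items)), key=lambda i: (items[i][1], items[i][0]))
    order = [items[first_idx]]
    pending = [it for i, it in enumerate(items) if i != first_idx]
    worst = 0.0
    while pending:
        current = order[-1][0]
        costs = np.array([abs(current - target) for _, target in pending])
        best = float(costs.min())
        worst = max(worst, best)
        tied = np.flatnonzero(costs == best)
        pick = int(tied[rng.integers(tied.size)]) if tied.size > 1 else int(tied[0])
        order.append(pending.pop(pick))
    if worst > max(1.0, reference.mean() / 2):
        logger.warning("order_intervals: best-effort ordering; worst predecessor "
                       "mismatch %.1f min", worst)
    return sequence_from_intervals([length for length, _ in order])
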