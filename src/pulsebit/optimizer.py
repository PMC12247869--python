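"""In-silico optimization of the input interval distribution.

With the decoder frozen, the bitrate becomes a function of the input
protocol alone: the protocol sets both the prior hazard and the law from
which (interval, last) pairs are drawn.  Parametrizing the interval law
as a softmax over unnormalized log-probabilities phi on a 5-90 min
support, the expected pointwise information is maximized by gradient
ascent.  Because the sampling law itself depends on phi, each step
samples from a frozen copy phi' and re-weights with importance weights
p_phi / p_phi' — the weights equal 1 at phi = phi' but carry a non-zero
gradient (the score-function trick).  Intervals longer than the longest
measured one (35 min) are served by imputing trajectory slices from the
35-min interval, preserving the time since the last pulse when it is
short and the time to the next pulse when that is short; the decoder is
always given the *true* time since the last pulse.  A second-difference
penalty on the interval log-probabilities (alpha = 0.003) keeps the
optimized protocol smooth.  The maximum attainable value is the channel
capacity of the pathway under renewal encodings on this support.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._mlp import sigmoid
from .estimator import GroupedDataset, POSTERIOR_CLIP, feature_columns
from .protocol import HAZARD_CLIP, IntervalDistribution

logger = logging.getLogger(__name__)

LN2 = math.log(2)

#: Longest interval present in the experimental data; longer sampled
#: intervals are imputed from it.
MAX_DATA_INTERVAL = 35
#: Below this elapsed/remaining time the response is kept as measured.
IMPUTE_KEEP_MIN = 10


def impute_reference_key(interval: int, last: int,
                         max_interval: int = MAX_DATA_INTERVAL,
                         keep: int = IMPUTE_KEEP_MIN) -> tuple[int, int]:
    """Map an out-of-data (interval, last) onto the longest measured interval.

    For interval <= 35 min the key is unchanged.  Otherwise interval* = 35
    and last* keeps the elapsed time if it is under 10 min, keeps the time
    remaining to the next pulse if that is under 10 min, and linearly
    rescales the middle stretch in between (rounded to the minute grid).
    """
    if last > interval:
        raise ValueError(f"last ({last}) exceeds interval ({interval})")
    if last < 1:
        raise ValueError("last must be >= 1")
    if interval <= max_interval:
        return int(interval), int(last)
    if last < keep:
        last_star = float(last)
    elif interval - last < keep:
        last_star = float(max_interval - (interval - last))
    else:
        last_star = keep + (last - keep) * (max_interval - 2 * keep) / (interval - 2 * keep)
    return int(max_interval), int(round(last_star))


def log_softmax(phi: np.ndarray) -> np.ndarray:
    m = phi.max()
    return phi - m - np.log(np.exp(phi - m).sum())


def smoothness_penalty(phi: np.ndarray, alpha: float) -> tuple[float, np.ndarray]:
    """alpha * mean of squared second differences of interval log-probabilities.

    Returns (value, gradient w.r.t. phi).  Vanishes for log-probabilities
    affine in the interval length.  Supports of size < 3 get penalty 0.
    """
    m = phi.size
    if m < 3:
        logger.warning("smoothness_penalty: support smaller than 3, penalty 0")
        return 0.0, np.zeros(m)
    ell = log_softmax(phi)
    d2 = ell[2:] - 2 * ell[1:-1] + ell[:-2]
    value = alpha * float(np.mean(d2 ** 2))
    g_ell = np.zeros(m)
    coef = 2 * alpha / (m - 2)
    np.add.at(g_ell, np.arange(m - 2), coef * d2)
    np.add.at(g_ell, np.arange(1, m - 1), -2 * coef * d2)
    np.add.at(g_ell, np.arange(2, m), coef * d2)
    p = np.exp(ell)
    g_phi = g_ell - p * g_ell.sum()
    return value, g_phi


@dataclass
class ProtocolParams:
    """Optimization variable: unnormalized log-probs over the support."""

    support: np.ndarray
    phi: np.ndarray
    alpha: float = 0.003

    def distribution(self) -> IntervalDistribution:
        return IntervalDistribution(self.support, np.exp(log_softmax(self.phi)))


@dataclass
class CapacityReport:
    """Result of protocol optimization against a frozen decoder."""

    optimized: IntervalDistribution
    capacity: float                  # bit/h under the optimized protocol
    initial_bitrate: float           # bit/h under the initial protocol
    trace: list = field(default_factory=list)
    n_steps: int = 0

    @property
    def gain_fraction(self) -> float:
        if self.initial_bitrate == 0:
            return float("nan")
        return (self.capacity - self.initial_bitrate) / abs(self.initial_bitrate)


class ProtocolOptimizer:
    """Importance-weighted gradient ascent over interval distributions.

    Parameters
    ----------
    update_fn : callable
        Maps a raw feature matrix (columns as in the training dataset) to
        the decoder's logit update u_Bayes; the decoder weights stay
        frozen throughout.
    dataset : DataFrame
        Datapoints of the transmitting subpopulation under the
        experimental protocol (rows as from ``build_dataset``).
    support : (lo, hi)
        Interval range of admissible protocols, minutes.
    """

    def __init__(self, update_fn, dataset: pd.DataFrame,
                 support: tuple[int, int] = (5, 90), r: int = 6,
                 max_data_interval: int = MAX_DATA_INTERVAL,
                 posterior_clip: float = POSTERIOR_CLIP):
        self.update_fn = update_fn
        self.r = r
        self.posterior_clip = posterior_clip
        self.support = np.arange(support[0], support[1] + 1, dtype=np.int64)
        self.max_data_interval = max_data_interval
        grouped = GroupedDataset(dataset, r=r)
        self.features = grouped.features
        self.log_last_col = 0  # feature layout starts with log(last)

        # enumerate all (interval, last) pairs of the support and resolve
        # each to a contiguous block of dataset rows (imputing I > 35)
        pair_I, pair_L = [], []
        for interval in self.support:
            pair_I.append(np.full(interval, interval))
            pair_L.append(np.arange(1, interval + 1))
        self.pair_I = np.concatenate(pair_I)
        self.pair_L = np.concatenate(pair_L)
        self.n_pairs = self.pair_I.size
        self.sup_idx_of_I = np.searchsorted(self.support, self.pair_I)

        rows_concat, start, length = [], np.zeros(self.n_pairs, np.int64), \
            np.zeros(self.n_pairs, np.int64)
        off = 0
        for i in range(self.n_pairs):
            key = impute_reference_key(int(self.pair_I[i]), int(self.pair_L[i]),
                                       max_interval=max_data_interval)
            if key not in grouped.groups:
                raise KeyError(f"no datapoints for pair {key} "
                               f"(requested ({self.pair_I[i]}, {self.pair_L[i]}))")
            g = grouped.groups[key]
            rows_concat.append(g)
            start[i], length[i] = off, g.size
            off += g.size
        self.rows_concat = np.concatenate(rows_concat)
        self.group_start = start
        self.group_len = length

    # -- protocol-dependent quantities --------------------------------------
    def pair_probs(self, phi: np.ndarray) -> np.ndarray:
        """q(I, L) = p(I) / E[I] for every enumerated pair (sums to 1)."""
        p = np.exp(log_softmax(phi))
        mean = float(p @ self.support)
        return p[self.sup_idx_of_I] / mean

    def hazard_probs(self, phi: np.ndarray) -> np.ndarray:
        """Hazard over last = 1..max(support) for the softmax(phi) law."""
        p = np.exp(log_softmax(phi))
        max_l = int(self.support[-1])
        pmf = np.zeros(max_l + 1)
        pmf[self.support] = p
        survival = np.cumsum(pmf[::-1])[::-1]
        with np.errstate(invalid="ignore", divide="ignore"):
            h = np.where(survival[1:] > 0, pmf[1:] / survival[1:], 0.0)
        return np.clip(h, 0.0, 1.0)

    def sample_batch(self, phi_frozen: np.ndarray, size: int,
                     rng: np.random.Generator):
        """Draw (rows, pair_ids) with pair frequencies q(phi_frozen)."""
        q = self.pair_probs(phi_frozen)
        cdf = np.cumsum(q)
        cdf[-1] = 1.0
        pair_ids = np.searchsorted(cdf, rng.random(size), side="right")
        offsets = (rng.random(size) * self.group_len[pair_ids]).astype(np.int64)
        rows = self.rows_concat[self.group_start[pair_ids] + offsets]
        return rows, pair_ids

    def objective_and_grad(self, phi: np.ndarray, phi_frozen: np.ndarray,
                           rows: np.ndarray, pair_ids: np.ndarray,
                           with_grad: bool = True):
        """Importance-weighted bitrate estimate (bit/h) and its phi-gradient.

        The batch was sampled under phi_frozen; weights q_phi/q_phi'
        equal 1 when phi == phi_frozen but contribute to the gradient.
        The decoder sees the true time since the last pulse both in its
        log-last feature and in the prior.
        """
        I = self.pair_I[pair_ids].astype(np.float64)
        L = self.pair_L[pair_ids]
        x = (self.pair_I[pair_ids] == L).astype(np.float64)

        X = self.features[rows].copy()
        X[:, self.log_last_col] = np.log(L.astype(np.float64))
        u = self.update_fn(X)

        p = np.exp(log_softmax(phi))
        mean = float(p @ self.support)
        h_all = self.hazard_probs(phi)
        h = h_all[L - 1]
        h_clipped = (h <= HAZARD_CLIP) | (h >= 1 - HAZARD_CLIP)
        hc = np.clip(h, HAZARD_CLIP, 1 - HAZARD_CLIP)
        a = np.log(hc) - np.log1p(-hc)
        z = u + a
        sign = 2 * x - 1
        p_post_raw = sigmoid(sign * z)
        post_clipped = (p_post_raw <= self.posterior_clip) | \
            (p_post_raw >= 1 - self.posterior_clip)
        p_post = np.clip(p_post_raw, self.posterior_clip, 1 - self.posterior_clip)
        p_prior = sigmoid(sign * a)
        f = (np.log(p_post) - np.log(p_prior)) * (60.0 / LN2)

        q_now = self.pair_probs(phi)
        q_frozen = self.pair_probs(phi_frozen)
        w = q_now[pair_ids] / q_frozen[pair_ids]
        B = rows.size
        value = float(np.mean(f * w))
        if not with_grad:
            return value, None

        # d(value)/da through both posterior and prior surprisal terms
        df_da = (60.0 / LN2) * sign * (
            np.where(post_clipped, 0.0, 1.0 - p_post_raw) - (1.0 - p_prior))
        # da/dphi_j = (delta_{j,idx(L)} - p_j 1[v_j >= L] / S(L)) / (1 - h)
        max_l = int(self.support[-1])
        pmf = np.zeros(max_l + 1)
        pmf[self.support] = p
        survival = np.cumsum(pmf[::-1])[::-1]
        S_L = survival[L]  # P(I >= L)
        grad = np.zeros(phi.size)

        active = (~h_clipped) & (L >= int(self.support[0]))
        if np.any(active):
            c = (df_da[active] * w[active]) / (1.0 - h[active])
            idx_L = np.searchsorted(self.support, L[active])
            np.add.at(grad, idx_L, c / B)
            # minus p_j * cumulative sum of c/S over datapoints with L <= v_j
            ratio = c / S_L[active]
            hist = np.zeros(max_l + 2)
            np.add.at(hist, L[active], ratio)
            cum = np.cumsum(hist)[self.support]  # sum over L <= v_j
            grad -= p * cum / B
        # score-function term: f * dlog q/dphi_j = f * (delta_{j,I} - p_j v_j / E)
        fw = f * w
        np.add.at(grad, self.sup_idx_of_I[pair_ids], fw / B)
        grad -= p * self.support * (fw.sum() / B) / mean
        return value, grad

    # -- the ascent loop ----------------------------------------------------
    def optimize(self, init: IntervalDistribution, alpha: float = 0.003,
                 steps: int = 500, step_size: float = 0.05,
                 batch_size: int = 10_000, seed: int = 0,
                 eval_batch: int = 100_000, init_floor: float = 1e-4) -> CapacityReport:
        """Gradient-ascend the regularized bitrate from ``init``.

        Each step freezes phi, samples a batch under it, takes one
        ascent step on the importance-weighted objective minus the
        smoothness penalty, and refreshes the frozen copy.  The reported
        capacity comes from a large fresh evaluation batch under the
        better of the final and initial distributions (the initial
        protocol is inside the feasible set, so optimization can never
        return something worse).
        """
        rng = np.random.default_rng(seed)
        init_probs = np.array([init.prob_of(int(v)) for v in self.support])
        if init_probs.sum() <= 0:
            raise ValueError("initial distribution has no mass on the support")
        p0 = init_probs + init_floor
        phi = np.log(p0 / p0.sum())

        # reference bitrate under the exact initial protocol
        phi_init_exact = np.log(np.maximum(init_probs / init_probs.sum(), 1e-300))
        rows, pids = self.sample_batch(phi_init_exact, eval_batch, rng)
        initial_bitrate, _ = self.objective_and_grad(
            phi_init_exact, phi_init_exact, rows, pids, with_grad=False)

        trace = []
        for step in range(steps):
            phi_frozen = phi.copy()
            rows, pids = self.sample_batch(phi_frozen, batch_size, rng)
            value, grad = self.objective_and_grad(phi, phi_frozen, rows, pids)
            pen, pen_grad = smoothness_penalty(phi, alpha)
            if not np.isfinite(value):
                raise FloatingPointError(f"non-finite objective at step {step}; "
                                         f"trace tail {trace[-5:]}")
            trace.append(value - pen)
            phi = phi + step_size * (grad - pen_grad)

        rows, pids = self.sample_batch(phi, eval_batch, rng)
        capacity, _ = self.objective_and_grad(phi, phi, rows, pids, with_grad=False)
        if capacity >= initial_bitrate:
            final_dist = ProtocolParams(self.support, phi, alpha).distribution()
        else:  # keep the best-found protocol: the start point itself
            logger.warning("optimization did not improve on the initial protocol "
                           "(%.3f vs %.3f bit/h); returning the initial law",
                           capacity, initial_bitrate)
            final_dist, capacity = init, initial_bitrate
        return CapacityReport(optimized=final_dist, capacity=float(capacity),
                              initial_bitrate=float(initial_bitrate),
                              trace=trace, n_steps=steps)


def decoder_update_fn(decoder):
    """Adapter: frozen PulseDecoder -> raw-feature update function."""
    def fn(X: np.ndarray) -> np.ndarray:
        return decoder.model_.forward(decoder.standardizer_.transform(X))
    return fn
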