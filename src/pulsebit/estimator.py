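"""Classifier-based lower bound on the information transmission rate.

The pulse train X (one bit per minute) and a cell's reporter trajectory Y
determine a mutual-information rate b(X;Y).  Writing the input as a
renewal process, the prior pulse probability at a timepoint depends only
on the time since the previous pulse (``last``); a classifier that
predicts the pulse indicator from a short trajectory slice then yields
the bound

    b >= -E[ log p(x | last) - log p_theta(x | last, slice, s, covariates) ]

in bits per timepoint (x 60 = bit/h).  The classifier is an MLP that
outputs a logit *update* u_Bayes added to the prior logit, trained by
cross-entropy on minibatches whose (interval, last) frequencies follow
the assumed protocol.  The same pointwise surprisal reduction averaged
within one track gives single-cell bitrates, which decompose the
population rate exactly as a track-length-weighted mean and define the
transmitting / non-transmitting split.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from ._mlp import OffsetMLP, bce_with_logits, sigmoid
from .preprocessing import PreprocessResult
from .protocol import (Hazard, IntervalDistribution, PulseSequence,
                       hazard_from_distribution, joint_interval_last)

logger = logging.getLogger(__name__)

LN2 = math.log(2)
R_DEFAULT = 6
POSTERIOR_CLIP = 1e-6

CELL_LINE_CODES = {"STE-1": 0.0, "BEAS-2B": 1.0}

FEATURE_COLUMNS = ["log_last"] + [f"dy_{i}" for i in range(1, R_DEFAULT + 1)] + \
    ["s", "cell_line_code", "alki_um", "meki_um", "calci_um"]


def feature_columns(r: int = R_DEFAULT) -> list[str]:
    return ["log_last"] + [f"dy_{i}" for i in range(1, r + 1)] + \
        ["s", "cell_line_code", "alki_um", "meki_um", "calci_um"]


# ---------------------------------------------------------------------------
# dataset construction
# ---------------------------------------------------------------------------

def build_dataset(pre: PreprocessResult, seq: PulseSequence, lead_in: int = 0,
                  r: int = R_DEFAULT) -> pd.DataFrame:
    """One row per (track, timepoint) with label, timing and features.

    Eligible timepoints k lie strictly after the first pulse and at or
    before the last pulse (so that ``last`` and the containing interval
    are defined) and require y(k..k+r) fully observed; the trajectory
    slice enters as the r consecutive differences dy_(k+1..k+r), which
    abstracts from each cell's reporter expression level.
    """
    pulses = np.sort(seq.pulse_times - seq.origin + lead_in).astype(np.int64)
    if pulses.size < 2:
        raise ValueError("need at least two pulses to define intervals")
    rows = []
    for tid, grp in pre.tracks.groupby("track_id", sort=True):
        grp = grp.sort_values("time_min")
        times = grp["time_min"].to_numpy(dtype=np.int64)
        yv = grp["y"].to_numpy(dtype=np.float64)
        t0, t1 = int(times[0]), int(times[-1])
        if times.size != t1 - t0 + 1 or not np.all(np.diff(times) == 1):
            # re-grid with NaN gaps; incomplete windows are dropped below
            full = np.full(t1 - t0 + 1, np.nan)
            full[times - t0] = yv
            yv = full
            times = np.arange(t0, t1 + 1)
        k_lo = max(t0, int(pulses[0]) + 1)
        k_hi = min(t1 - r, int(pulses[-1]))
        if k_hi < k_lo:
            continue
        k = np.arange(k_lo, k_hi + 1)
        idx = np.searchsorted(pulses, k, side="left")
        last = k - pulses[idx - 1]
        interval = pulses[idx] - pulses[idx - 1]
        x = (last == interval).astype(np.int8)
        dy = np.diff(yv)
        # dy window for timepoint k: differences at positions k+1..k+r
        win = np.lib.stride_tricks.sliding_window_view(dy, r)[k - t0 + 1 - 1]
        y_k_ok = np.isfinite(yv[k - t0])
        ok = np.all(np.isfinite(win), axis=1) & y_k_ok
        if not np.any(ok):
            continue
        meta = grp.iloc[0]
        cl = meta["cell_line"]
        if cl not in CELL_LINE_CODES:
            raise ValueError(f"unknown cell line {cl!r}")
        df = pd.DataFrame({
            "track_id": tid,
            "replicate_id": meta["replicate_id"],
            "k": k[ok],
            "x": x[ok],
            "last": last[ok],
            "interval": interval[ok],
            "log_last": np.log(last[ok].astype(float)),
            "s": float(pre.responsiveness[tid]),
            "cell_line_code": CELL_LINE_CODES[cl],
            "alki_um": float(meta["alki_um"]),
            "meki_um": float(meta["meki_um"]),
            "calci_um": float(meta["calci_um"]),
        })
        for i in range(r):
            df[f"dy_{i + 1}"] = win[ok, i]
        rows.append(df)
    if not rows:
        raise ValueError("no eligible datapoints (tracks misaligned with sequence?)")
    out = pd.concat(rows, ignore_index=True)
    return out[["track_id", "replicate_id", "k", "x", "last", "interval"]
               + feature_columns(r)]


@dataclass(frozen=True)
class FeatureStandardizer:
    """Column-wise zero-mean unit-sd scaler; zero-variance columns pass through."""

    mean_: np.ndarray
    scale_: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "FeatureStandardizer":
        mean = X.mean(axis=0)
        scale = X.std(axis=0)
        scale = np.where(scale > 0, scale, 1.0)
        return cls(mean, scale)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean_) / self.scale_

    def inverse_transform(self, Z: np.ndarray) -> np.ndarray:
        return Z * self.scale_ + self.mean_


def prior_logit(hazard: Hazard, last) -> np.ndarray:
    """Natural-log logit of the (clipped) hazard at ``last``."""
    return hazard.logit_at(last)


class GroupedDataset:
    """Dataset rows grouped by (interval, last) for protocol-driven sampling."""

    def __init__(self, dataset: pd.DataFrame, r: int = R_DEFAULT):
        dataset = dataset.reset_index(drop=True)
        self.r = r
        self.features = dataset[feature_columns(r)].to_numpy(dtype=np.float64)
        self.x = dataset["x"].to_numpy(dtype=np.float64)
        self.last = dataset["last"].to_numpy(dtype=np.int64)
        self.interval = dataset["interval"].to_numpy(dtype=np.int64)
        self.groups: dict[tuple[int, int], np.ndarray] = {
            (int(i), int(l)): idx.to_numpy()
            for (i, l), idx in dataset.groupby(["interval", "last"]).groups.items()
        }

    def sample(self, joint: dict[tuple[int, int], float], size: int,
               rng: np.random.Generator,
               impute: "callable | None" = None) -> np.ndarray:
        """Row indices whose (interval, last) frequencies follow ``joint``.

        Pairs absent from the data are redirected through ``impute``
        (pair -> pair); without an imputation rule a missing pair is an
        error naming the pair.
        """
        if size == 0:
            return np.empty(0, dtype=np.int64)
        pairs = list(joint.keys())
        probs = np.array([joint[p] for p in pairs])
        probs = probs / probs.sum()
        counts = rng.multinomial(size, probs)
        out = []
        for pair, c in zip(pairs, counts):
            if c == 0:
                continue
            key = pair
            if key not in self.groups:
                if impute is None:
                    raise KeyError(f"no datapoints for (interval, last) = {pair} "
                                   "and no imputation rule")
                key = impute(*pair)
                key = (int(key[0]), int(round(key[1])))
                if key not in self.groups:
                    raise KeyError(f"imputed pair {key} for {pair} missing from data")
            grp = self.groups[key]
            out.append(grp[rng.integers(grp.size, size=c)])
        return np.concatenate(out)


# ---------------------------------------------------------------------------
# the decoder
# ---------------------------------------------------------------------------

class PulseDecoder(BaseEstimator):
    """MLP pulse-probability decoder with a renewal-prior logit offset.

    Parameters
    ----------
    protocol : IntervalDistribution
        Assumed input protocol; fixes the prior hazard and the
        (interval, last) minibatch sampling law.
    r : int
        Number of trajectory differences in the feature slice.
    hidden_layer_sizes : tuple of int
        MLP hidden sizes (paper architecture: (40, 20), leaky ReLU).
    batch_size, n_batches, learning_rate : training schedule (Adam).
    val_fraction, eval_every, patience : early stopping on a held-out
        fraction of tracks; best weights are restored.
    random_state : int
        Seeds minibatch sampling, the train/validation split and weight
        initialization.

    Attributes (after fit)
    ----------------------
    model_ : OffsetMLP ; standardizer_ : FeatureStandardizer ;
    hazard_ : Hazard ; loss_curve_, val_curve_ : lists ;
    n_batches_run_ : int.
    """

    def __init__(self, protocol: IntervalDistribution | None = None,
                 r: int = R_DEFAULT, hidden_layer_sizes: tuple = (40, 20),
                 leak: float = 0.01, learning_rate: float = 1e-3,
                 batch_size: int = 10_000, n_batches: int = 3000,
                 val_fraction: float = 0.1, eval_every: int = 25,
                 patience: int = 300, posterior_clip: float = POSTERIOR_CLIP,
                 random_state: int = 0, verbose: int = 0):
        self.protocol = protocol
        self.r = r
        self.hidden_layer_sizes = hidden_layer_sizes
        self.leak = leak
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.n_batches = n_batches
        self.val_fraction = val_fraction
        self.eval_every = eval_every
        self.patience = patience
        self.posterior_clip = posterior_clip
        self.random_state = random_state
        self.verbose = verbose

    # -- helpers ------------------------------------------------------------
    def _loss(self, u: np.ndarray, prior: np.ndarray, x: np.ndarray,
              weights: np.ndarray | None = None) -> float:
        z = u + prior
        p = np.clip(sigmoid(z), self.posterior_clip, 1 - self.posterior_clip)
        nll = -(x * np.log(p) + (1 - x) * np.log1p(-p))
        return float(np.mean(nll) if weights is None else weights @ nll)

    def fit(self, dataset: pd.DataFrame, y=None):
        """Train on a dataset from :func:`build_dataset`."""
        if self.protocol is None:
            raise ValueError("protocol must be set before fitting")
        if dataset.empty:
            raise ValueError("empty dataset")
        x_all = dataset["x"].to_numpy()
        if x_all.min() == x_all.max():
            logger.warning("single-class dataset (all x = %d)", int(x_all[0]))
        root = np.random.default_rng(self.random_state)
        init_seed = int(root.integers(2**31))
        split_rng = np.random.default_rng(int(root.integers(2**31)))
        batch_rng = np.random.default_rng(int(root.integers(2**31)))
        val_rng = np.random.default_rng(int(root.integers(2**31)))

        self.hazard_ = hazard_from_distribution(self.protocol)
        joint = joint_interval_last(self.protocol)
        feats = feature_columns(self.r)
        self.standardizer_ = FeatureStandardizer.fit(dataset[feats].to_numpy(np.float64))

        tracks = np.array(sorted(dataset["track_id"].unique()))
        n_val = int(round(self.val_fraction * tracks.size))
        val_tracks = set(split_rng.choice(tracks, size=n_val, replace=False).tolist()) \
            if n_val > 0 else set()
        is_val = dataset["track_id"].isin(val_tracks).to_numpy()
        train_ds = dataset.loc[~is_val].reset_index(drop=True)
        val_ds = dataset.loc[is_val].reset_index(drop=True)
        if train_ds.empty:
            raise ValueError("validation split left no training data")
        grouped = GroupedDataset(train_ds, self.r)
        Z_train = self.standardizer_.transform(grouped.features)
        # minibatches can only draw pairs the training tracks cover; dropped
        # protocol mass (missing frames, short tracks) is renormalized away
        covered = {p: q for p, q in joint.items() if p in grouped.groups}
        dropped = 1.0 - sum(covered.values()) / sum(joint.values())
        if dropped > 1e-6:
            logger.warning("training data misses (interval, last) pairs carrying "
                           "%.2f%% of the protocol mass; renormalizing", 100 * dropped)
        joint = covered

        has_val = not val_ds.empty
        if has_val:
            val_grouped = GroupedDataset(val_ds, self.r)
            # deterministic protocol-weighted validation loss: weight each
            # datapoint by q(pair) / (val count of pair), renormalized
            wv = np.zeros(len(val_ds))
            for pair, idx in val_grouped.groups.items():
                q = joint.get(pair)
                if q:
                    wv[idx] = q / idx.size
            if wv.sum() == 0:
                has_val = False
            else:
                wv /= wv.sum()
                Zv = self.standardizer_.transform(val_grouped.features)
                xv = val_grouped.x
                pv = self.hazard_.logit_at(val_grouped.last)

        mlp = OffsetMLP(len(feats), tuple(self.hidden_layer_sizes), self.leak,
                        seed=init_seed)
        best = mlp.get_weights()
        best_val = np.inf
        best_batch = 0
        self.loss_curve_ = []
        self.val_curve_ = []
        n_run = 0
        for step in range(self.n_batches):
            idx = grouped.sample(joint, self.batch_size, batch_rng)
            Z = Z_train[idx]
            xb = grouped.x[idx]
            prior = self.hazard_.logit_at(grouped.last[idx])
            u, acts = mlp.forward(Z, cache=True)
            z = u + prior
            loss = float(np.mean(bce_with_logits(z, xb)))
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at batch {step}; "
                    f"u range [{u.min():.3g}, {u.max():.3g}]")
            d_u = (sigmoid(z) - xb) / xb.size
            gW, gb = mlp.backward(acts, d_u)
            mlp.adam_step(gW, gb, self.learning_rate)
            self.loss_curve_.append(loss)
            n_run = step + 1
            if has_val and (step + 1) % self.eval_every == 0:
                vloss = self._loss(mlp.forward(Zv), pv, xv, weights=wv)
                self.val_curve_.append(vloss)
                if vloss < best_val - 1e-5:
                    best_val = vloss
                    best = mlp.get_weights()
                    best_batch = step + 1
                elif step + 1 - best_batch >= self.patience:
                    if self.verbose:
                        logger.info("early stop at batch %d (best %d)", step + 1, best_batch)
                    break
        if has_val and np.isfinite(best_val):
            mlp.set_weights(*best)
        self.model_ = mlp
        self.n_batches_run_ = n_run
        self.best_val_loss_ = best_val if has_val else None
        self.n_features_in_ = len(feats)
        return self

    def predict_update(self, dataset: pd.DataFrame) -> np.ndarray:
        """Logit Bayesian update u_Bayes per datapoint."""
        Z = self.standardizer_.transform(
            dataset[feature_columns(self.r)].to_numpy(np.float64))
        return self.model_.forward(Z)

    def predict_posterior_logit(self, dataset: pd.DataFrame) -> np.ndarray:
        return self.predict_update(dataset) + \
            self.hazard_.logit_at(dataset["last"].to_numpy())

    def predict_proba_pulse(self, dataset: pd.DataFrame) -> np.ndarray:
        return sigmoid(self.predict_posterior_logit(dataset))


class PriorOnlyDecoder:
    """Stub decoder with u_Bayes = 0: the posterior equals the prior."""

    def __init__(self, protocol: IntervalDistribution, r: int = R_DEFAULT):
        self.protocol = protocol
        self.r = r
        self.hazard_ = hazard_from_distribution(protocol)

    def predict_update(self, dataset: pd.DataFrame) -> np.ndarray:
        return np.zeros(len(dataset))

    def predict_posterior_logit(self, dataset: pd.DataFrame) -> np.ndarray:
        return self.hazard_.logit_at(dataset["last"].to_numpy())


# ---------------------------------------------------------------------------
# bitrate accounting
# ---------------------------------------------------------------------------

def pointwise_information(u: np.ndarray, prior_logit_: np.ndarray, x: np.ndarray,
                          clip: float = POSTERIOR_CLIP) -> np.ndarray:
    """Surprisal reduction log2 p_post(x) - log2 p_prior(x), bits/timepoint.

    Negative values mean the trajectory misled the decoder below the
    prior at that timepoint.
    """
    x = np.asarray(x, dtype=np.float64)
    sign = 2 * x - 1
    p_post = np.clip(sigmoid(sign * (u + prior_logit_)), clip, 1 - clip)
    p_prior = sigmoid(sign * prior_logit_)
    return (np.log(p_post) - np.log(p_prior)) / LN2


def _info_for(model, dataset: pd.DataFrame) -> np.ndarray:
    u = model.predict_update(dataset)
    prior = model.hazard_.logit_at(dataset["last"].to_numpy())
    return pointwise_information(u, prior, dataset["x"].to_numpy())


def population_bitrate(model, dataset: pd.DataFrame) -> float:
    """Mean pointwise information over the dataset, in bit/h."""
    return float(_info_for(model, dataset).mean() * 60.0)


def single_cell_bitrates(model, dataset: pd.DataFrame) -> pd.DataFrame:
    """Per-track bitrate b_j (bit/h) and weight w_j (datapoint count).

    The w_j-weighted mean of b_j equals the population bitrate exactly.
    """
    info = _info_for(model, dataset)
    df = pd.DataFrame({"track_id": dataset["track_id"].to_numpy(), "info": info})
    agg = df.groupby("track_id")["info"].agg(["mean", "size"])
    return pd.DataFrame({"track_id": agg.index,
                         "bitrate": agg["mean"].to_numpy() * 60.0,
                         "weight": agg["size"].to_numpy()}).reset_index(drop=True)


@dataclass
class TransmittingSplit:
    transmitting: pd.Series          # bool per track_id
    fraction_weighted: float         # weighted by datapoint counts
    fraction_unweighted: float
    mean_bitrate_transmitting: float
    mean_bitrate_nontransmitting: float


def split_transmitting(bitrates: pd.DataFrame, strict: bool = True) -> TransmittingSplit:
    """Longest ascending-bitrate prefix with negative weighted mean.

    Cells in that prefix are non-transmitting; the rest transmit.  With
    ``strict=False`` the prefix may close at a non-positive (rather than
    strictly negative) weighted mean.  Ties sort by (bitrate, track_id).
    """
    if bitrates.empty:
        raise ValueError("no cells to split")
    df = bitrates.sort_values(["bitrate", "track_id"]).reset_index(drop=True)
    b = df["bitrate"].to_numpy()
    w = df["weight"].to_numpy(dtype=np.float64)
    csum = np.cumsum(w * b)
    neg = csum < 0 if strict else csum <= 0
    n_non = int(np.flatnonzero(neg)[-1] + 1) if np.any(neg) else 0
    flags = np.ones(len(df), dtype=bool)
    flags[:n_non] = False
    transmitting = pd.Series(flags, index=df["track_id"]).sort_index()
    W = w.sum()
    wt = w[n_non:].sum()
    mean_t = float(csum[-1] - (csum[n_non - 1] if n_non else 0.0)) / wt if wt else float("nan")
    mean_n = float(csum[n_non - 1] / w[:n_non].sum()) if n_non else float("nan")
    return TransmittingSplit(
        transmitting=transmitting,
        fraction_weighted=float(wt / W),
        fraction_unweighted=float(flags.sum() / len(df)),
        mean_bitrate_transmitting=mean_t,
        mean_bitrate_nontransmitting=mean_n,
    )


def mean_update_table(model, dataset: pd.DataFrame) -> pd.DataFrame:
    """Mean logit update u_Bayes grouped by (interval, last) (diagnostic)."""
    u = model.predict_update(dataset)
    df = pd.DataFrame({"interval": dataset["interval"].to_numpy(),
                       "last": dataset["last"].to_numpy(), "u": u})
    return df.groupby(["interval", "last"])["u"].agg(["mean", "size"]).reset_index()


@dataclass
class BitrateReport:
    """Population bitrate, its per-cell decomposition and diagnostics."""

    bitrate: float
    per_cell: pd.DataFrame
    split: TransmittingSplit
    n_datapoints: int
    update_table: pd.DataFrame
    input_entropy_rate: float

    def decomposition_error(self) -> float:
        w = self.per_cell["weight"].to_numpy(dtype=float)
        b = self.per_cell["bitrate"].to_numpy()
        return abs(float((w * b).sum() / w.sum()) - self.bitrate)


def estimate_bitrate(model, dataset: pd.DataFrame, strict_split: bool = True) -> BitrateReport:
    from .protocol import entropy_rate
    per_cell = single_cell_bitrates(model, dataset)
    return BitrateReport(
        bitrate=population_bitrate(model, dataset),
        per_cell=per_cell,
        split=split_transmitting(per_cell, strict=strict_split),
        n_datapoints=len(dataset),
        update_table=mean_update_table(model, dataset),
        input_entropy_rate=entropy_rate(model.protocol)
        if getattr(model, "protocol", None) is not None else float("nan"),
    )


def crossvalidate_by_replicate(dataset: pd.DataFrame, protocol: IntervalDistribution,
                               seed: int = 0, **decoder_kwargs) -> pd.DataFrame:
    """Leave-one-replicate-out check that the decoder does not overfit.

    For each replicate, retrain on the others and compare the held-out
    bitrate against the all-data model's bitrate on the same records.
    """
    reps = sorted(dataset["replicate_id"].unique())
    if len(reps) < 2:
        raise ValueError("cross-validation needs at least two replicates")
    full = PulseDecoder(protocol=protocol, random_state=seed, **decoder_kwargs)
    full.fit(dataset)
    rows = []
    for i, rep in enumerate(reps):
        held = dataset["replicate_id"] == rep
        model = PulseDecoder(protocol=protocol, random_state=seed + 1 + i,
                             **decoder_kwargs)
        model.fit(dataset.loc[~held])
        b_fold = population_bitrate(model, dataset.loc[held])
        b_full = population_bitrate(full, dataset.loc[held])
        rows.append({"replicate_id": rep, "bitrate_heldout": b_fold,
                     "bitrate_fullmodel": b_full, "delta": b_fold - b_full})
    return pd.DataFrame(rows)
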