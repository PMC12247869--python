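"""From raw per-frame quantifications to analysis-ready trajectories.

Implements the post-segmentation steps: negative-log normalization of
nuclear reporter intensity by the frame mean, the 3-hour minimum track
length filter, gating on optoFGFR expression within cell-line-specific
windows around length-weighted population moments, per-pulse response
amplitudes with interval-matched baseline correction, and the per-cell
responsiveness statistic fed to the decoder.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .protocol import PulseSequence

logger = logging.getLogger(__name__)

RAW_COLUMNS = [
    "track_id", "time_min", "nuclear_intensity", "frame_mean_intensity",
    "optofgfr_intensity", "cell_line", "alki_um", "meki_um", "calci_um",
    "replicate_id",
]

#: Gating windows per cell line, as multiples of the length-weighted
#: standard deviation around the length-weighted mean optoFGFR level.
GATING_WINDOWS: dict[str, tuple[float, float]] = {
    "BEAS-2B": (0.0, 3.0),
    "STE-1": (-0.5, 2.0),
}

MIN_TRACK_MIN = 180
RESPONSE_LAG = 7  # minutes between pulse and amplitude readout


def normalize_trajectory(records: pd.DataFrame) -> pd.DataFrame:
    """Negative-log normalized trajectory y = -log(nuclear / frame mean).

    Rows with non-positive intensities are dropped (count logged).  The
    result is scale-invariant: a per-frame illumination factor common to
    nucleus and frame mean cancels.
    """
    ok = (records["nuclear_intensity"] > 0) & (records["frame_mean_intensity"] > 0)
    n_bad = int((~ok).sum())
    if n_bad:
        logger.info("normalize_trajectory: dropped %d records with non-positive intensity", n_bad)
    records = records.loc[ok].copy()
    records["y"] = -np.log(records["nuclear_intensity"] / records["frame_mean_intensity"])
    return records


def filter_tracks_by_length(tracks: pd.DataFrame, min_minutes: int = MIN_TRACK_MIN) -> pd.DataFrame:
    """Keep tracks whose observed time span is at least ``min_minutes``."""
    if tracks.empty:
        return tracks
    span = tracks.groupby("track_id")["time_min"].agg(lambda t: t.max() - t.min() + 1)
    keep = span.index[span >= min_minutes]
    return tracks[tracks["track_id"].isin(keep)].copy()


def optofgfr_track_means(tracks: pd.DataFrame, seq: PulseSequence,
                         lead_in: int = 0) -> pd.Series:
    """Mean optoFGFR intensity per track over stimulation timepoints only."""
    pulse_times = set((seq.pulse_times - seq.origin + lead_in).tolist())
    stim = tracks[tracks["time_min"].isin(pulse_times)]
    if stim.empty:  # no stimulated frames observed: fall back to all frames
        stim = tracks
    return stim.groupby("track_id")["optofgfr_intensity"].mean()


def gate_by_optofgfr(tracks: pd.DataFrame, cell_line: str,
                     optofgfr_mean: pd.Series | None = None,
                     seq: PulseSequence | None = None,
                     lead_in: int = 0,
                     windows: dict[str, tuple[float, float]] | None = None) -> pd.DataFrame:
    """Discard tracks with outlying optoFGFR expression.

    mu and sigma are the track-length-weighted mean and (population)
    standard deviation of per-track mean optoFGFR intensity; tracks are
    retained iff their level lies in [mu + lo*sigma, mu + hi*sigma] with
    (lo, hi) specific to the cell line: (0, 3) for BEAS-2B, (-0.5, 2)
    for STE-1.
    """
    windows = {**GATING_WINDOWS, **(windows or {})}
    if cell_line not in windows:
        raise ValueError(f"unknown cell line {cell_line!r}; known: {sorted(windows)}")
    lo, hi = windows[cell_line]
    if tracks.empty:
        return tracks
    if optofgfr_mean is None:
        if seq is None:
            optofgfr_mean = tracks.groupby("track_id")["optofgfr_intensity"].mean()
        else:
            optofgfr_mean = optofgfr_track_means(tracks, seq, lead_in)
    lengths = tracks.groupby("track_id")["time_min"].size().reindex(optofgfr_mean.index)
    w = lengths.to_numpy(dtype=float)
    x = optofgfr_mean.to_numpy(dtype=float)
    mu = float(np.average(x, weights=w))
    sigma = float(np.sqrt(np.average((x - mu) ** 2, weights=w)))
    keep = optofgfr_mean.index[(x >= mu + lo * sigma) & (x <= mu + hi * sigma)]
    return tracks[tracks["track_id"].isin(keep)].copy()


def _pivot_y(tracks: pd.DataFrame) -> pd.DataFrame:
    """(time x track) matrix of y, NaN where unobserved."""
    return tracks.pivot_table(index="time_min", columns="track_id", values="y",
                              aggfunc="first")


def amplitude_baseline(tracks: pd.DataFrame, seq: PulseSequence, lead_in: int = 0,
                       lag: int = RESPONSE_LAG) -> pd.Series:
    """Cohort-average residual drift c(L) used to correct response amplitudes.

    c(L) is the average, over all tracks and all pulses followed by a gap
    of at least L + lag minutes, of y(pulse + L + lag) - y(pulse + L):
    what the trajectory does L minutes after a pulse when NO new pulse
    intervened, i.e. the ongoing relaxation from the previous response.
    """
    mat = _pivot_y(tracks)
    times = mat.index.to_numpy()
    pulses = np.sort(seq.pulse_times - seq.origin + lead_in)
    gaps = np.diff(np.concatenate([pulses, [times.max() + 1]]))
    intervals = sorted(set(np.diff(pulses).tolist()))
    out = {}
    for L in intervals:
        num, den = 0.0, 0
        for p, gap in zip(pulses, gaps):
            if gap < L + lag:
                continue
            t0, t1 = p + L, p + L + lag
            if t0 not in mat.index or t1 not in mat.index:
                continue
            d = mat.loc[t1] - mat.loc[t0]
            num += np.nansum(d)
            den += int(d.notna().sum())
        out[L] = num / den if den else 0.0
    return pd.Series(out, name="c")


def compute_response_amplitude(tracks: pd.DataFrame, seq: PulseSequence,
                               lead_in: int = 0, lag: int = RESPONSE_LAG,
                               baseline: pd.Series | None = None) -> pd.DataFrame:
    """Per-(track, pulse) response amplitudes with baseline correction.

    raw = y(pulse + lag) - y(pulse); corrected = raw - c(L) where L is the
    interval from the previous pulse and c is :func:`amplitude_baseline`.
    Pulses whose readout frames are unobserved are skipped.  The first
    pulse of the sequence (undefined L) is excluded.
    """
    if baseline is None:
        baseline = amplitude_baseline(tracks, seq, lead_in, lag)
    mat = _pivot_y(tracks)
    pulses = np.sort(seq.pulse_times - seq.origin + lead_in)
    rows = []
    for i in range(1, len(pulses)):
        p = int(pulses[i])
        L = int(pulses[i] - pulses[i - 1])
        if p not in mat.index or p + lag not in mat.index:
            continue
        raw = mat.loc[p + lag] - mat.loc[p]
        c = float(baseline.get(L, 0.0))
        for track_id, val in raw.dropna().items():
            rows.append((track_id, p, L, float(val), float(val) - c))
    return pd.DataFrame(rows, columns=["track_id", "pulse_time", "interval",
                                       "raw_amplitude", "amplitude"])


def compute_responsiveness(y: np.ndarray, times: np.ndarray | None = None,
                           lag: int = RESPONSE_LAG) -> float:
    """Responsiveness s = Std over k of (y(k) - y(k + lag)).

    A pulse-timing-independent measure of trajectory activity.  Requires
    at least lag + 1 frames; population (ddof=0) standard deviation.
    """
    y = np.asarray(y, dtype=np.float64)
    if times is None:
        times = np.arange(y.size)
    times = np.asarray(times)
    if y.size < lag + 1:
        raise ValueError(f"track too short for responsiveness (needs > {lag} frames)")
    if times.size == y.size and np.all(np.diff(times) == 1):  # contiguous fast path
        return float(np.std(y[:-lag] - y[lag:]))
    pos = {int(t): i for i, t in enumerate(times)}
    diffs = [y[i] - y[pos[int(t) + lag]]
             for t, i in ((t, i) for i, t in enumerate(times)) if int(t) + lag in pos]
    if not diffs:
        raise ValueError("no complete 7-min windows in track")
    return float(np.std(diffs))


@dataclass
class PreprocessResult:
    tracks: pd.DataFrame           # long format with y
    responsiveness: pd.Series      # per track_id
    optofgfr_mean: pd.Series       # per track_id
    n_raw_tracks: int
    n_after_length: int
    n_after_gating: int


def preprocess(raw: pd.DataFrame, seq: PulseSequence, lead_in: int = 0,
               min_minutes: int = MIN_TRACK_MIN, gate: bool = True,
               windows: dict[str, tuple[float, float]] | None = None) -> PreprocessResult:
    """Full preprocessing chain: normalize, length-filter, gate, annotate.

    Gating is applied per (cell_line, replicate) cohort, as the gating
    moments are defined within a replicate.
    """
    tracks = normalize_trajectory(raw)
    n_raw = tracks["track_id"].nunique()
    tracks = filter_tracks_by_length(tracks, min_minutes)
    n_len = tracks["track_id"].nunique()
    if gate and not tracks.empty:
        parts = []
        for (cl, _rep), grp in tracks.groupby(["cell_line", "replicate_id"], sort=True):
            parts.append(gate_by_optofgfr(grp, cl, seq=seq, lead_in=lead_in,
                                          windows=windows))
        tracks = pd.concat(parts, ignore_index=True)
    n_gate = tracks["track_id"].nunique() if not tracks.empty else 0

    resp = {}
    for tid, grp in tracks.groupby("track_id"):
        grp = grp.sort_values("time_min")
        resp[tid] = compute_responsiveness(grp["y"].to_numpy(), grp["time_min"].to_numpy())
    responsiveness = pd.Series(resp, name="s")
    opto = (optofgfr_track_means(tracks, seq, lead_in)
            if not tracks.empty else pd.Series(dtype=float))
    return PreprocessResult(tracks=tracks, responsiveness=responsiveness,
                            optofgfr_mean=opto, n_raw_tracks=n_raw,
                            n_after_length=n_len, n_after_gating=n_gate)
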