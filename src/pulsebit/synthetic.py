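"""Synthetic single-cell reporter trajectories under pulsed stimulation.

Generates track tables with the statistical structure the estimator
assumes in real kinase-translocation-reporter (KTR) data: each light pulse
evokes, in responding cells, a small nuclear-import 'dip' about 2 min
after the pulse followed by a cytoplasmic-export peak about 7 min after
it, with an amplitude that recovers with the preceding interval
(refractoriness saturating near 20 min), on top of per-cell amplitude
heterogeneity, a mixture of responding and non-responding cells, and
additive per-frame noise.  Output is the raw track CSV schema consumed by
:mod:`pulsebit.preprocessing`, including frame-mean intensities so the
negative-log normalization is exercised end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .protocol import PulseSequence

#: Minutes of unstimulated imaging preceding the first possible pulse.
LEAD_IN_MIN = 90

PEAK_TIME = 7.0   # minutes after pulse, ERK-driven cytoplasmic translocation
DIP_TIME = 2.0    # minutes after pulse, calcineurin-driven nuclear dip


@dataclass(frozen=True)
class CellPhenotype:
    """Per-cell response parameters.

    Non-responders must have zero peak and dip amplitude.  A
    ``refractory_halftime`` of ``None`` disables refractoriness (full
    response at any interval), emulating the fast-recovering
    RTK/calcineurin channel.
    """

    responder: bool
    peak_amplitude: float
    dip_amplitude: float
    refractory_halftime: float | None
    noise_sd: float
    optofgfr_level: float
    baseline: float = 0.5

    def __post_init__(self):
        if not self.responder and (self.peak_amplitude != 0 or self.dip_amplitude != 0):
            raise ValueError("non-responders must have zero amplitudes")
        if self.dip_amplitude < 0:
            raise ValueError("dip_amplitude must be >= 0")
        if self.refractory_halftime is not None and self.refractory_halftime <= 0:
            raise ValueError("refractory_halftime must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class PopulationConfig:
    """Parameters of a simulated cell population (one condition)."""

    n_cells: int = 300
    responder_fraction: float = 1.0
    #: (log-mean, log-sd) of the log-normal law of responder peak amplitude.
    amplitude_log_mean: float = np.log(0.4)
    amplitude_log_sd: float = 0.3
    dip_fraction_of_peak: float = 0.25
    refractory_halftime: float | None = 9.0
    noise_sd: float = 0.04
    cell_line: str = "BEAS-2B"
    alki_um: float = 0.0
    meki_um: float = 0.0
    calci_um: float = 0.0
    replicate: str = "R1"
    #: Per-frame probability that a track ends (varying track lengths).
    track_dropout: float = 0.0
    optofgfr_log_mean: float = np.log(100.0)
    optofgfr_log_sd: float = 0.25

    def __post_init__(self):
        if not 0.0 <= self.responder_fraction <= 1.0:
            raise ValueError("responder_fraction must lie in [0, 1]")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")


def _cosine_bump(t: np.ndarray, t_max: float, rise: float, fall: float) -> np.ndarray:
    """Unit raised-cosine bump: 0 before t_max-rise, 1 at t_max, 0 after t_max+fall."""
    out = np.zeros_like(t, dtype=np.float64)
    up = (t > t_max - rise) & (t <= t_max)
    out[up] = 0.5 * (1.0 - np.cos(np.pi * (t[up] - (t_max - rise)) / rise))
    down = (t > t_max) & (t < t_max + fall)
    out[down] = 0.5 * (1.0 + np.cos(np.pi * (t[down] - t_max) / fall))
    return out


def g_peak(t) -> np.ndarray:
    """Unit pulse-response peak, maximal 7 min post-pulse, <5% by 20 min."""
    return _cosine_bump(np.asarray(t, dtype=np.float64), PEAK_TIME, rise=5.0, fall=12.0)


def g_dip(t) -> np.ndarray:
    """Unit nuclear-import dip, maximal 2 min post-pulse, gone by 6 min."""
    return _cosine_bump(np.asarray(t, dtype=np.float64), DIP_TIME, rise=2.0, fall=4.0)


def recovery(prev_interval, halftime: float | None) -> np.ndarray:
    """Refractory recovery factor 1 - 2^(-L/halftime); 1 when refractory-free.

    Monotone increasing in the preceding interval L and saturating toward 1,
    emulating the ~8-10 min effective refractory time of the RTK/ERK channel.
    """
    prev_interval = np.asarray(prev_interval, dtype=np.float64)
    if halftime is None:
        return np.ones_like(prev_interval)
    return 1.0 - np.power(2.0, -prev_interval / halftime)


def response_kernel(t_since_pulse, prev_interval, phenotype: CellPhenotype) -> np.ndarray:
    """Deterministic trajectory increment evoked by one pulse.

    ``prev_interval`` is the interval preceding that pulse (np.inf for the
    first pulse); it scales the whole response through :func:`recovery`.
    """
    t = np.asarray(t_since_pulse, dtype=np.float64)
    if np.any(t < 0):
        raise ValueError("t_since_pulse must be >= 0")
    if not phenotype.responder:
        return np.zeros_like(t)
    rec = recovery(prev_interval, phenotype.refractory_halftime)
    return rec * (phenotype.peak_amplitude * g_peak(t) - phenotype.dip_amplitude * g_dip(t))


def simulate_track(seq: PulseSequence, phenotype: CellPhenotype, seed: int,
                   lead_in: int = LEAD_IN_MIN) -> pd.DataFrame:
    """Simulate one cell's per-minute trajectory (columns time_min, y).

    The trajectory is baseline + the additive superposition of pulse
    kernels + i.i.d. Gaussian per-frame noise, preceded by ``lead_in``
    minutes of unstimulated imaging.  Pulse times of ``seq`` are shifted
    by ``lead_in``.
    """
    rng = np.random.default_rng(seed)
    n = lead_in + seq.n_timepoints
    times = np.arange(n, dtype=np.int64)
    y = np.full(n, phenotype.baseline, dtype=np.float64)
    pulses = seq.pulse_times - seq.origin + lead_in
    prev_intervals = np.concatenate([[np.inf], np.diff(pulses)]) if pulses.size else pulses
    for p, prev in zip(pulses, prev_intervals):
        tail = times[times >= p] - p
        y[times >= p] += response_kernel(tail, prev, phenotype)
    if phenotype.noise_sd > 0:
        y += rng.normal(0.0, phenotype.noise_sd, size=n)
    return pd.DataFrame({"time_min": times, "y": y})


def simulate_population(config: PopulationConfig, seq: PulseSequence, seed: int) -> pd.DataFrame:
    """Simulate a population and emit the raw track CSV schema.

    Phenotypes: responder flag ~ Bernoulli(responder_fraction); responder
    peak amplitudes log-normal; optoFGFR expression log-normal.  Intensities
    are reconstructed from y as nuclear = frame_mean * exp(-y), with a
    shared per-frame illumination factor so that normalization by the
    frame mean is exercised (and is exactly scale-invariant).
    """
    root = np.random.default_rng(seed)
    pheno_rng = np.random.default_rng(root.integers(2**31))
    frame_rng = np.random.default_rng(root.integers(2**31))
    n_frames = LEAD_IN_MIN + seq.n_timepoints
    # per-frame illumination drift common to all cells in the replicate
    frame_factor = 1.0 + 0.05 * frame_rng.standard_normal(n_frames)
    frame_factor = np.clip(frame_factor, 0.5, None)

    responders = pheno_rng.random(config.n_cells) < config.responder_fraction
    peak_amps = np.where(
        responders,
        np.exp(pheno_rng.normal(config.amplitude_log_mean, config.amplitude_log_sd,
                                config.n_cells)),
        0.0,
    )
    opto = np.exp(pheno_rng.normal(config.optofgfr_log_mean, config.optofgfr_log_sd,
                                   config.n_cells))
    track_seeds = root.integers(2**31, size=config.n_cells)
    frames_mean_nuc = 120.0  # a.u., typical background-subtracted nuclear level

    parts = []
    for j in range(config.n_cells):
        phenotype = CellPhenotype(
            responder=bool(responders[j]),
            peak_amplitude=float(peak_amps[j]),
            dip_amplitude=float(config.dip_fraction_of_peak * peak_amps[j]),
            refractory_halftime=config.refractory_halftime,
            noise_sd=config.noise_sd,
            optofgfr_level=float(opto[j]),
        )
        track = simulate_track(seq, phenotype, int(track_seeds[j]))
        if config.track_dropout > 0:
            rng = np.random.default_rng(int(track_seeds[j]) ^ 0x5EED)
            n_keep = 1 + int(rng.geometric(config.track_dropout))
            track = track.iloc[:n_keep]
        frames = track["time_min"].to_numpy()
        fm = frames_mean_nuc * frame_factor[frames]
        part = pd.DataFrame({
            "track_id": f"{config.replicate}_c{j:04d}",
            "time_min": frames,
            "nuclear_intensity": fm * np.exp(-track["y"].to_numpy()),
            "frame_mean_intensity": fm,
            "optofgfr_intensity": phenotype.optofgfr_level
            * (1.0 + 0.02 * np.random.default_rng(int(track_seeds[j]) ^ 0xF0F0)
               .standard_normal(frames.size)),
            "cell_line": config.cell_line,
            "alki_um": config.alki_um,
            "meki_um": config.meki_um,
            "calci_um": config.calci_um,
            "replicate_id": config.replicate,
        })
        parts.append(part)
    return pd.concat(parts, ignore_index=True)
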