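"""End-to-end orchestration: simulate/load -> preprocess -> train -> report.

A run is described by a YAML config and a seed; its outputs land in one
directory (processed tracks, trained model, bitrate report with per-cell
decomposition, optional capacity report, and figure-level summary
tables) so that every reported number can be traced to a config hash and
seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import estimator as est
from . import optimizer as opt
from . import preprocessing as prep
from . import protocol as proto
from . import synthetic as synth

logger = logging.getLogger(__name__)

MODEL_FORMAT_VERSION = 1


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Pipeline configuration; blocks mirror the pipeline stages."""

    tracks_csv: str | None = None
    pulses_csv: str | None = None
    out_dir: str = "run"
    simulate: dict | None = None          # PopulationConfig kwargs (or list)
    protocol: dict = field(default_factory=dict)
    preprocessing: dict = field(default_factory=dict)
    estimator: dict = field(default_factory=dict)
    optimizer: dict | None = None
    lead_in: int = synth.LEAD_IN_MIN

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:12]


def resolve_protocol(block: dict) -> proto.IntervalDistribution:
    """Protocol block -> interval law (default: the experimental counts)."""
    kind = block.get("kind", "experimental")
    if kind == "experimental":
        return proto.experimental_distribution()
    if kind == "gamma":
        return proto.gamma_interval_distribution(
            shape=block.get("gamma_shape", 4.0),
            scale_min=block.get("gamma_scale_min", 5.0),
            support_min=block.get("support_min", 1),
            support_max=block.get("support_max", 90))
    if kind == "counts":
        return proto.empirical_distribution_from_counts(
            {int(k): int(v) for k, v in block["counts"].items()})
    raise ValueError(f"unknown protocol kind {kind!r}")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def load_tracks_csv(path) -> pd.DataFrame:
    """Read and validate a raw track table.

    Raises with row numbers for missing columns, non-numeric fields and
    duplicate (track_id, time_min) pairs.
    """
    df = pd.read_csv(path)
    missing = [c for c in prep.RAW_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"raw track CSV is missing column(s): {', '.join(missing)}")
    numeric = ["time_min", "nuclear_intensity", "frame_mean_intensity",
               "optofgfr_intensity", "alki_um", "meki_um", "calci_um"]
    for col in numeric:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.isna() & df[col].notna()]
        if len(bad):
            raise ValueError(f"non-numeric values in column {col!r} at rows "
                             f"{list(bad[:10])}")
        df[col] = vals
    dup = df.duplicated(subset=["track_id", "time_min"], keep=False)
    if dup.any():
        rows = df.index[dup][:10].tolist()
        raise ValueError(f"duplicate (track_id, time_min) pairs at rows {rows}")
    return df


def load_pulses_csv(path, duration: int | None = None) -> proto.PulseSequence:
    df = pd.read_csv(path)
    times = np.sort(df["pulse_time_min"].to_numpy(dtype=np.int64))
    n = int(duration if duration is not None else times[-1] + 1)
    return proto.PulseSequence(times, n_timepoints=n)


def save_pulses_csv(seq: proto.PulseSequence, path) -> None:
    pd.DataFrame({"pulse_time_min": seq.pulse_times}).to_csv(path, index=False)


def save_distribution_csv(dist: proto.IntervalDistribution, path) -> None:
    pd.DataFrame({"interval_min": dist.support,
                  "probability": dist.probs}).to_csv(path, index=False)


def load_distribution_csv(path) -> proto.IntervalDistribution:
    df = pd.read_csv(path)
    order = np.argsort(df["interval_min"].to_numpy())
    return proto.IntervalDistribution(df["interval_min"].to_numpy()[order],
                                      df["probability"].to_numpy()[order])


def save_model(decoder: est.PulseDecoder, path) -> None:
    """Serialize a fitted decoder (architecture, weights, standardizer)."""
    W, b = decoder.model_.get_weights()
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "r": decoder.r,
        "hidden_layer_sizes": list(decoder.hidden_layer_sizes),
        "leak": decoder.leak,
        "weights": [w.tolist() for w in W],
        "biases": [x.tolist() for x in b],
        "standardizer_mean": decoder.standardizer_.mean_.tolist(),
        "standardizer_scale": decoder.standardizer_.scale_.tolist(),
        "protocol_support": decoder.protocol.support.tolist(),
        "protocol_probs": decoder.protocol.probs.tolist(),
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path) -> est.PulseDecoder:
    data = json.loads(Path(path).read_text())
    if data.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model format {data.get('format_version')!r}")
    dist = proto.IntervalDistribution(np.array(data["protocol_support"]),
                                      np.array(data["protocol_probs"]))
    dec = est.PulseDecoder(protocol=dist, r=data["r"],
                           hidden_layer_sizes=tuple(data["hidden_layer_sizes"]),
                           leak=data["leak"])
    from ._mlp import OffsetMLP
    mlp = OffsetMLP(1 + data["r"] + 5, tuple(data["hidden_layer_sizes"]), data["leak"])
    mlp.set_weights(data["weights"], data["biases"])
    dec.model_ = mlp
    dec.standardizer_ = est.FeatureStandardizer(
        np.array(data["standardizer_mean"]), np.array(data["standardizer_scale"]))
    dec.hazard_ = proto.hazard_from_distribution(dist)
    dec.n_features_in_ = 1 + data["r"] + 5
    return dec


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def amplitude_by_interval(amplitudes: pd.DataFrame) -> pd.DataFrame:
    """Mean corrected response amplitude per preceding interval."""
    g = amplitudes.groupby("interval")["amplitude"].agg(["mean", "sem", "size"])
    return g.reset_index()


def update_by_interval(update_table: pd.DataFrame) -> pd.DataFrame:
    """Mean diagonal logit update (interval == last): detection certainty."""
    diag = update_table[update_table["interval"] == update_table["last"]]
    return diag[["interval", "mean", "size"]].rename(columns={"mean": "mean_update"})


def bitrate_histogram(per_cell: pd.DataFrame, n_bins: int = 30) -> pd.DataFrame:
    counts, edges = np.histogram(per_cell["bitrate"], bins=n_bins)
    return pd.DataFrame({"bin_left": edges[:-1], "bin_right": edges[1:],
                         "count": counts})


# ---------------------------------------------------------------------------
# the run
# ---------------------------------------------------------------------------

def _simulate_inputs(config: RunConfig, seed: int):
    dist = resolve_protocol(config.protocol)
    ref = proto.gamma_interval_distribution(support_max=int(dist.support[-1]))
    counts_block = (config.protocol.get("counts")
                    or proto.EXPERIMENTAL_INTERVAL_COUNTS)
    seq = proto.order_intervals({int(k): int(v) for k, v in counts_block.items()},
                                ref, seed=seed)
    blocks = config.simulate if isinstance(config.simulate, list) else [config.simulate]
    parts = []
    for i, block in enumerate(blocks):
        pc = synth.PopulationConfig(**{**block, "replicate": block.get(
            "replicate", f"R{i + 1}")})
        parts.append(synth.simulate_population(pc, seq, seed=seed + 1000 + i))
    # re-express pulse times on the absolute frame grid (lead-in included) so
    # the emitted schedule aligns with the track tables without further shifts
    seq_abs = proto.PulseSequence(seq.pulse_times - seq.origin + config.lead_in,
                                  n_timepoints=config.lead_in + seq.n_timepoints)
    return pd.concat(parts, ignore_index=True), seq_abs, dist


def run_pipeline(config: RunConfig, seed: int) -> dict:
    """Execute all stages and write the output bundle; returns the summary."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "summaries").mkdir(exist_ok=True)
    log_lines = [f"{time.strftime('%Y-%m-%dT%H:%M:%S')} start "
                 f"config={config.config_hash()} seed={seed}"]

    def stage(name):
        log_lines.append(f"{time.strftime('%Y-%m-%dT%H:%M:%S')} stage {name}")

    try:
        stage("inputs")
        if config.simulate is not None:
            raw, seq, dist = _simulate_inputs(config, seed)
            lead_in = 0  # sequence already on the absolute frame grid
        else:
            if not config.tracks_csv or not config.pulses_csv:
                raise ValueError("either simulate block or tracks_csv+pulses_csv required")
            raw = load_tracks_csv(config.tracks_csv)
            seq = load_pulses_csv(config.pulses_csv)
            dist = resolve_protocol(config.protocol)
            lead_in = 0  # pulse times in the CSV are absolute frame times
        save_pulses_csv(seq, out / "pulses.csv")

        stage("preprocess")
        pre = prep.preprocess(raw, seq, lead_in=lead_in, **config.preprocessing)
        proc = (pre.tracks
                .merge(pre.responsiveness.rename("s"), left_on="track_id",
                       right_index=True)
                .merge(pre.optofgfr_mean.rename("optofgfr_mean"),
                       left_on="track_id", right_index=True))
        proc[["track_id", "time_min", "y", "s", "optofgfr_mean", "cell_line",
              "alki_um", "meki_um", "calci_um", "replicate_id"]] \
            .to_csv(out / "processed_tracks.csv", index=False)

        stage("dataset")
        r = int(config.estimator.get("r", est.R_DEFAULT))
        dataset = est.build_dataset(pre, seq, lead_in=lead_in, r=r)

        stage("train")
        dec_kwargs = {k: v for k, v in config.estimator.items()}
        dec = est.PulseDecoder(protocol=dist, random_state=seed, **dec_kwargs)
        dec.fit(dataset)
        save_model(dec, out / "model.json")

        stage("estimate")
        report = est.estimate_bitrate(dec, dataset)
        decomp_err = report.decomposition_error()
        report.per_cell.assign(
            transmitting=report.split.transmitting.reindex(
                report.per_cell["track_id"]).to_numpy()
        ).to_csv(out / "per_cell_bitrates.csv", index=False)
        amps = prep.compute_response_amplitude(pre.tracks, seq, lead_in=lead_in)
        amplitude_by_interval(amps).to_csv(out / "summaries" / "amplitude_by_interval.csv",
                                           index=False)
        update_by_interval(report.update_table).to_csv(
            out / "summaries" / "update_by_interval.csv", index=False)
        report.update_table.to_csv(out / "summaries" / "update_by_interval_last.csv",
                                   index=False)
        bitrate_histogram(report.per_cell).to_csv(
            out / "summaries" / "bitrate_histogram.csv", index=False)

        summary = {
            "config_hash": config.config_hash(),
            "seed": seed,
            "n_tracks_raw": pre.n_raw_tracks,
            "n_tracks_after_length": pre.n_after_length,
            "n_tracks_after_gating": pre.n_after_gating,
            "n_datapoints": report.n_datapoints,
            "input_entropy_rate_bit_per_h": report.input_entropy_rate,
            "population_bitrate_bit_per_h": report.bitrate,
            "decomposition_error": decomp_err,
            "transmitting_fraction_weighted": report.split.fraction_weighted,
            "transmitting_fraction_unweighted": report.split.fraction_unweighted,
            "mean_bitrate_transmitting": report.split.mean_bitrate_transmitting,
            "mean_bitrate_nontransmitting": report.split.mean_bitrate_nontransmitting,
        }

        if config.optimizer is not None:
            stage("optimize")
            ob = dict(config.optimizer)
            keep = report.split.transmitting
            trans_ids = keep.index[keep.to_numpy()]
            sub = dataset[dataset["track_id"].isin(trans_ids)]
            popt = opt.ProtocolOptimizer(
                opt.decoder_update_fn(dec), sub,
                support=tuple(ob.pop("support", (5, 90))), r=r)
            cap = popt.optimize(dist, seed=seed + 7, **ob)
            save_distribution_csv(cap.optimized, out / "optimized_protocol.csv")
            cap_payload = {
                "capacity_bit_per_h": cap.capacity,
                "initial_bitrate_bit_per_h": cap.initial_bitrate,
                "gain_fraction": cap.gain_fraction,
                "n_steps": cap.n_steps,
                "trace": [float(v) for v in cap.trace],
            }
            (out / "capacity_report.json").write_text(
                json.dumps(cap_payload, sort_keys=True, indent=1))
            summary["capacity_bit_per_h"] = cap.capacity
            summary["capacity_gain_fraction"] = cap.gain_fraction

        (out / "config.yaml").write_text(config.to_yaml())
        summary = {k: (None if isinstance(v, float) and not np.isfinite(v) else v)
                   for k, v in summary.items()}
        (out / "bitrate_report.json").write_text(
            json.dumps(summary, sort_keys=True, indent=1))
        stage("done")
        return summary
    except Exception as exc:
        log_lines.append(f"{time.strftime('%Y-%m-%dT%H:%M:%S')} FAILED: {exc}")
        raise
    finally:
        (out / "log.txt").write_text("\n".join(log_lines) + "\n")
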