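import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from pulsebit import protocol as proto
from pulsebit import synthetic as synth

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def table1_dist():
    return proto.experimental_distribution()


@pytest.fixture(scope="session")
def table1_sequence():
    return proto.order_intervals(
        proto.EXPERIMENTAL_INTERVAL_COUNTS,
        proto.gamma_interval_distribution(support_max=35), seed=1)


@pytest.fixture(scope="session")
def toy_sequence():
    """Short pulse train on a 3-5 min interval alphabet."""
    toy = proto.IntervalDistribution([3, 4, 5], [0.3, 0.4, 0.3])
    return proto.sample_pulse_sequence(toy, 400, seed=1), toy


@pytest.fixture(scope="session")
def toy_dataset(toy_sequence):
    """Small clean dataset covering every (interval, last) pair of the toy law."""
    from pulsebit import estimator as est
    from pulsebit import preprocessing as prep
    seq, toy = toy_sequence
    cfg = synth.PopulationConfig(n_cells=6, responder_fraction=1.0, noise_sd=0.05,
                                 refractory_halftime=None)
    raw = synth.simulate_population(cfg, seq, seed=2)
    pre = prep.preprocess(raw, seq, lead_in=synth.LEAD_IN_MIN, gate=False)
    return est.build_dataset(pre, seq, lead_in=synth.LEAD_IN_MIN), toy


def make_raw_track(track_id="t0", times=None, nuclear=None, frame_mean=None,
                   opto=10.0, cell_line="BEAS-2B", replicate="R1"):
    times = np.arange(200) if times is None else np.asarray(times)
    nuclear = np.full(times.size, 100.0) if nuclear is None else np.asarray(nuclear, float)
    frame_mean = np.full(times.size, 100.0) if frame_mean is None else np.asarray(frame_mean, float)
    return pd.DataFrame({
        "track_id": track_id, "time_min": times, "nuclear_intensity": nuclear,
        "frame_mean_intensity": frame_mean,
        "optofgfr_intensity": np.full(times.size, float(opto)),
        "cell_line": cell_line, "alki_um": 0.0, "meki_um": 0.0, "calci_um": 0.0,
        "replicate_id": replicate,
    })
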