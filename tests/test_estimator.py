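import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import make_raw_track
from pulsebit import estimator as est
from pulsebit import preprocessing as prep
from pulsebit import protocol as proto
from pulsebit import synthetic as synth
from pulsebit.estimator import (FeatureStandardizer, GroupedDataset, PriorOnlyDecoder,
                                PulseDecoder, build_dataset, pointwise_information,
                                population_bitrate, single_cell_bitrates,
                                split_transmitting)


def _single_interval_dataset(L=10, r=6):
    """One track covering exactly one interval of length L plus r trailing frames."""
    seq = proto.PulseSequence(np.array([5, 5 + L]), n_timepoints=5 + L + r + 1)
    n = seq.n_timepoints
    raw = make_raw_track(times=np.arange(n))
    pre = prep.PreprocessResult(
        tracks=prep.normalize_trajectory(raw),
        responsiveness=pd.Series({"t0": 0.1}),
        optofgfr_mean=pd.Series({"t0": 10.0}),
        n_raw_tracks=1, n_after_length=1, n_after_gating=1)
    return build_dataset(pre, seq, r=r), seq


class TestBuildDataset:
    def test_single_interval_enumeration(self):
        ds, _ = _single_interval_dataset(L=10)
        assert len(ds) == 10
        assert ds["x"].sum() == 1
        row = ds[ds["x"] == 1].iloc[0]
        assert row["last"] == row["interval"] == 10
        assert np.array_equal(ds["last"].to_numpy(), np.arange(1, 11))

    def test_trailing_window_requirement(self):
        # track ending r-1 frames after the last pulse: pulse timepoint dropped
        L, r = 10, 6
        seq = proto.PulseSequence(np.array([5, 15]), n_timepoints=15 + r)
        raw = make_raw_track(times=np.arange(15 + r))  # last frame 15 + r - 1
        pre = prep.PreprocessResult(
            tracks=prep.normalize_trajectory(raw),
            responsiveness=pd.Series({"t0": 0.1}),
            optofgfr_mean=pd.Series({"t0": 10.0}),
            n_raw_tracks=1, n_after_length=1, n_after_gating=1)
        ds = build_dataset(pre, seq, r=r)
        assert ds["k"].max() == 14
        assert ds["x"].sum() == 0

    def test_label_conservation(self, toy_dataset):
        ds, _ = toy_dataset
        n_tracks = ds["track_id"].nunique()
        pulses_per_track = ds.groupby("track_id")["x"].sum().unique()
        # full-length identical tracks cover the same pulse count
        assert len(pulses_per_track) == 1
        assert ds["x"].sum() == int(pulses_per_track[0]) * n_tracks

    def test_x_iff_last_equals_interval(self, toy_dataset):
        ds, _ = toy_dataset
        assert np.array_equal(ds["x"] == 1, ds["last"] == ds["interval"])
        assert (ds["last"] >= 1).all() and (ds["last"] <= ds["interval"]).all()


class TestFeatureStandardizer:
    @given(st.integers(0, 2**31 - 1))
    def test_roundtrip(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(3, 5, size=(40, 4))
        X[:, 2] = 7.0  # zero-variance column
        std = FeatureStandardizer.fit(X)
        Z = std.transform(X)
        assert np.allclose(std.inverse_transform(Z), X, atol=1e-9)
        assert np.allclose(Z[:, 2], 0.0)
        assert std.scale_[2] == 1.0


class TestMinibatchSampling:
    def test_point_mass_protocol_pairs(self, toy_dataset):
        ds, _ = toy_dataset
        grouped = GroupedDataset(ds)
        joint = proto.joint_interval_last(proto.IntervalDistribution([3], [1.0]))
        rng = np.random.default_rng(0)
        idx = grouped.sample(joint, 30_000, rng)
        pairs = list(zip(grouped.interval[idx], grouped.last[idx]))
        counts = pd.Series(pairs).value_counts(normalize=True)
        assert set(counts.index) == {(3, 1), (3, 2), (3, 3)}
        assert np.allclose(counts.to_numpy(), 1 / 3, atol=0.02)

    def test_empty_and_deterministic(self, toy_dataset):
        ds, toy = toy_dataset
        grouped = GroupedDataset(ds)
        joint = proto.joint_interval_last(toy)
        assert grouped.sample(joint, 0, np.random.default_rng(1)).size == 0
        a = grouped.sample(joint, 500, np.random.default_rng(7))
        b = grouped.sample(joint, 500, np.random.default_rng(7))
        assert np.array_equal(a, b)

    def test_missing_pair_named_in_error(self, toy_dataset):
        ds, _ = toy_dataset
        grouped = GroupedDataset(ds)
        joint = proto.joint_interval_last(proto.IntervalDistribution([9], [1.0]))
        with pytest.raises(KeyError, match=r"\(9, "):
            grouped.sample(joint, 10, np.random.default_rng(0))


class TestPointwiseInformation:
    def test_zero_update_zero_information(self):
        prior = np.array([0.3, -2.0, 5.0])
        info = pointwise_information(np.zeros(3), prior, np.array([1, 0, 1]))
        assert np.allclose(info, 0.0)

    def test_confident_correct_prediction(self):
        # prior 0.2, posterior ~1 (clipped), x=1 -> ~log2(1/0.2) bits
        prior = np.log(0.2 / 0.8)
        info = pointwise_information(np.array([50.0]), np.array([prior]),
                                     np.array([1]))
        assert info[0] == pytest.approx(np.log2(1 / 0.2), abs=0.01)

    def test_misleading_response_negative(self):
        prior = np.log(0.2 / 0.8)
        post = np.log(0.9 / 0.1)
        info = pointwise_information(np.array([post - prior]), np.array([prior]),
                                     np.array([0]))
        assert info[0] == pytest.approx(np.log2(0.1 / 0.8))
        assert info[0] < 0


class TestBitrates:
    def test_prior_only_model_zero_bitrate(self, toy_dataset):
        ds, toy = toy_dataset
        model = PriorOnlyDecoder(toy)
        assert population_bitrate(model, ds) == 0.0
        bj = single_cell_bitrates(model, ds)
        assert np.allclose(bj["bitrate"], 0.0)

    def test_perfect_classifier_attains_empirical_entropy(self, toy_dataset):
        """Posterior == label indicator: bitrate equals the empirical prior
        surprisal rate (oracle: direct substitution into the bound)."""
        ds, toy = toy_dataset
        hazard = proto.hazard_from_distribution(toy)

        class Oracle:
            hazard_ = hazard

            def predict_update(self, d):
                # huge logit towards the true label
                return (2 * d["x"].to_numpy() - 1) * 60.0 - hazard.logit_at(
                    d["last"].to_numpy())

        b = population_bitrate(Oracle(), ds)
        prior = hazard.at(ds["last"].to_numpy())
        x = ds["x"].to_numpy()
        surprisal = -np.where(x == 1, np.log2(np.clip(prior, 1e-4, 1 - 1e-4)),
                              np.log2(1 - np.clip(prior, 1e-4, 1 - 1e-4)))
        clip_adjust = np.log2(1 - est.POSTERIOR_CLIP)
        assert b == pytest.approx(60 * (surprisal.mean() + clip_adjust), abs=0.02)

    def test_decomposition_identity(self, toy_dataset):
        ds, toy = toy_dataset
        model = PriorOnlyDecoder(toy)
        rng = np.random.default_rng(0)

        class Jitter(PriorOnlyDecoder):
            def predict_update(self, d):
                return rng.normal(0, 1, len(d))

        m = Jitter(toy)
        u = m.predict_update(ds)  # fixed realization

        class Fixed(PriorOnlyDecoder):
            def predict_update(self, d):
                return u[:len(d)] if len(d) == len(ds) else np.zeros(len(d))

        f = Fixed(toy)
        b = population_bitrate(f, ds)
        bj = single_cell_bitrates(f, ds)
        w = bj["weight"].to_numpy(float)
        assert (w * bj["bitrate"]).sum() / w.sum() == pytest.approx(b, abs=1e-9)


class TestTransmittingSplit:
    def test_documented_example(self):
        df = pd.DataFrame({"track_id": list("abcd"), "bitrate": [-2.0, -1.0, 1.0, 4.0],
                           "weight": [1, 1, 1, 1]})
        split = split_transmitting(df)
        assert split.fraction_unweighted == pytest.approx(0.25)
        assert split.transmitting.tolist() == [False, False, False, True]

    def test_all_positive_and_all_negative(self):
        pos = pd.DataFrame({"track_id": ["a", "b"], "bitrate": [1.0, 2.0],
                            "weight": [1, 1]})
        neg = pd.DataFrame({"track_id": ["a", "b"], "bitrate": [-1.0, -2.0],
                            "weight": [1, 1]})
        assert split_transmitting(pos).fraction_weighted == 1.0
        assert split_transmitting(neg).fraction_weighted == 0.0
        with pytest.raises(ValueError):
            split_transmitting(pd.DataFrame(columns=["track_id", "bitrate", "weight"]))

    @given(st.integers(0, 10_000))
    def test_matches_bruteforce_prefix_search(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(1, 12)
        df = pd.DataFrame({"track_id": [f"t{i}" for i in range(n)],
                           "bitrate": rng.normal(0, 2, n).round(3),
                           "weight": rng.integers(1, 50, n)})
        split = split_transmitting(df)
        srt = df.sort_values(["bitrate", "track_id"]).reset_index(drop=True)
        best = 0
        for k in range(1, n + 1):
            w = srt["weight"][:k].to_numpy(float)
            if (w * srt["bitrate"][:k]).sum() / w.sum() < 0:
                best = k
        expected = 1 - srt["weight"][best:].sum() / srt["weight"].sum()
        assert 1 - split.fraction_weighted == pytest.approx(expected)


class TestTraining:
    def test_noise_only_converges_to_prior(self, table1_sequence):
        """Pure-noise tracks: validation cross-entropy stays at the prior
        entropy and the bitrate stays near zero."""
        cfg = synth.PopulationConfig(n_cells=20, responder_fraction=0.0,
                                     noise_sd=0.05)
        raw = synth.simulate_population(cfg, table1_sequence, seed=5)
        pre = prep.preprocess(raw, table1_sequence, lead_in=synth.LEAD_IN_MIN,
                              gate=False)
        ds = build_dataset(pre, table1_sequence)
        dist = proto.experimental_distribution()
        dec = PulseDecoder(protocol=dist, random_state=0, n_batches=400,
                           patience=150)
        dec.fit(ds)
        assert abs(population_bitrate(dec, ds)) < 0.5

    def test_same_seed_identical_training(self, toy_dataset):
        ds, toy = toy_dataset
        kw = dict(protocol=toy, random_state=3, n_batches=60,
                  hidden_layer_sizes=(8, 4), batch_size=500, val_fraction=0.2)
        a = PulseDecoder(**kw).fit(ds)
        b = PulseDecoder(**kw).fit(ds)
        assert a.loss_curve_ == b.loss_curve_
        assert population_bitrate(a, ds) == population_bitrate(b, ds)

    def test_sklearn_params_roundtrip(self):
        dec = PulseDecoder(n_batches=10)
        params = dec.get_params()
        assert params["n_batches"] == 10
        dec.set_params(learning_rate=0.01)
        assert dec.learning_rate == 0.01


class TestCrossValidation:
    def test_single_replicate_rejected(self, toy_dataset):
        ds, toy = toy_dataset
        with pytest.raises(ValueError):
            est.crossvalidate_by_replicate(ds, toy)

    def test_identical_replicates_small_deltas(self, toy_sequence):
        seq, toy = toy_sequence
        parts = []
        for rep in ["R1", "R2"]:
            cfg = synth.PopulationConfig(n_cells=6, responder_fraction=1.0,
                                         noise_sd=0.05, refractory_halftime=None,
                                         replicate=rep)
            parts.append(synth.simulate_population(cfg, seq, seed=11))
        raw = pd.concat(parts, ignore_index=True)
        pre = prep.preprocess(raw, seq, lead_in=synth.LEAD_IN_MIN, gate=False)
        ds = build_dataset(pre, seq)
        folds = est.crossvalidate_by_replicate(
            ds, toy, seed=1, n_batches=250, hidden_layer_sizes=(16, 8),
            batch_size=2000, patience=100)
        assert len(folds) == 2
        assert np.all(np.abs(folds["delta"]) < 1.5)
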