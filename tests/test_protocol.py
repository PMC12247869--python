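import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pulsebit import protocol as proto
from pulsebit.protocol import (EXPERIMENTAL_INTERVAL_COUNTS, IntervalDistribution,
                               distribution_from_hazard,
                               empirical_distribution_from_counts, entropy_rate,
                               geometric_distribution, hazard_from_distribution,
                               joint_interval_last, order_intervals,
                               sample_pulse_sequence)


@st.composite
def interval_distributions(draw):
    n = draw(st.integers(2, 12))
    support = draw(st.lists(st.integers(1, 60), min_size=n, max_size=n, unique=True))
    weights = draw(st.lists(st.floats(0.01, 10.0), min_size=n, max_size=n))
    w = np.array(weights)
    return IntervalDistribution(np.sort(support), w / w.sum())


class TestIntervalDistribution:
    def test_experimental_counts_normalize(self):
        d = proto.experimental_distribution()
        assert d.probs.size == 31
        assert d.probs.sum() == pytest.approx(1.0, abs=1e-12)
        assert d.mean() == pytest.approx(1010 / 57)

    @pytest.mark.parametrize("counts,expected", [
        ({20: 7}, {20: 1.0}),
        ({2: 1, 3: 1}, {2: 0.5, 3: 0.5}),
    ])
    def test_from_counts(self, counts, expected):
        d = empirical_distribution_from_counts(counts)
        for iv, p in expected.items():
            assert d.prob_of(iv) == pytest.approx(p)

    @pytest.mark.parametrize("bad", [{}, {5: 0}, {5: -1}, {5: 1.5}])
    def test_invalid_counts_rejected(self, bad):
        with pytest.raises(ValueError):
            empirical_distribution_from_counts(bad)

    def test_invalid_distributions_rejected(self):
        with pytest.raises(ValueError):
            IntervalDistribution([2, 2], [0.5, 0.5])   # duplicate support
        with pytest.raises(ValueError):
            IntervalDistribution([0, 2], [0.5, 0.5])   # below 1 min
        with pytest.raises(ValueError):
            IntervalDistribution([2, 3], [0.6, 0.6])   # mass != 1


class TestHazard:
    def test_point_mass(self):
        h = hazard_from_distribution(IntervalDistribution([20], [1.0]))
        assert np.all(h.at(np.arange(1, 20)) == 0.0)
        assert h.at(20) == 1.0

    def test_uniform_two_point(self):
        h = hazard_from_distribution(IntervalDistribution([2, 3], [0.5, 0.5]))
        assert h.at(2) == pytest.approx(0.5)
        assert h.at(3) == pytest.approx(1.0)

    def test_memoryless_constant_hazard(self):
        h = hazard_from_distribution(geometric_distribution(0.5, 30))
        assert np.allclose(h.at(np.arange(1, 30)), 0.5)

    @given(interval_distributions())
    def test_roundtrip_recovers_distribution(self, dist):
        back = distribution_from_hazard(hazard_from_distribution(dist))
        assert np.array_equal(back.support, dist.support)
        assert np.allclose(back.probs, dist.probs, atol=1e-9)

    def test_prior_logit_clipping(self):
        h = hazard_from_distribution(IntervalDistribution([5, 20], [0.2, 0.8]))
        # forced pulse at max support: logit of 1 - 1e-4
        assert h.logit_at(20) == pytest.approx(np.log((1 - 1e-4) / 1e-4))
        # below min support: hazard 0 -> logit of 1e-4
        assert h.logit_at(3) == pytest.approx(np.log(1e-4 / (1 - 1e-4)))


class TestEntropyRate:
    def test_experimental_value(self):
        assert entropy_rate(proto.experimental_distribution()) == pytest.approx(16.4, abs=0.05)

    def test_memoryless_ceiling(self):
        assert entropy_rate(geometric_distribution(0.5)) == pytest.approx(60.0, abs=1e-9)

    @pytest.mark.parametrize("L", [1, 7, 35])
    def test_deterministic_interval_zero(self, L):
        assert entropy_rate(IntervalDistribution([L], [1.0])) == 0.0

    @given(interval_distributions())
    def test_bounds(self, dist):
        r = entropy_rate(dist)
        assert r >= 0.0
        assert r <= 60 * np.log2(dist.support.size) / dist.support[0] + 1e-9


class TestJointIntervalLast:
    def test_uniform_two_point(self):
        j = joint_interval_last(IntervalDistribution([2, 3], [0.5, 0.5]))
        assert len(j) == 5
        for v in j.values():
            assert v == pytest.approx(0.2)

    def test_point_mass(self):
        j = joint_interval_last(IntervalDistribution([3], [1.0]))
        assert j == {(3, 1): pytest.approx(1 / 3), (3, 2): pytest.approx(1 / 3),
                     (3, 3): pytest.approx(1 / 3)}

    @given(interval_distributions())
    def test_marginals(self, dist):
        j = joint_interval_last(dist)
        assert sum(j.values()) == pytest.approx(1.0, abs=1e-9)
        mean = dist.mean()
        # marginal over L is the length-biased law I * p(I) / E[I]
        for iv, p in zip(dist.support, dist.probs):
            mass = sum(v for (i, _), v in j.items() if i == iv)
            assert mass == pytest.approx(iv * p / mean, abs=1e-9)
        # diagonal cells (a pulse per interval) sum to the pulse rate 1/E[I]
        diag = sum(v for (i, l), v in j.items() if i == l)
        assert diag == pytest.approx(1 / mean, abs=1e-9)


class TestPulseSequences:
    def test_deterministic_draw(self):
        seq = sample_pulse_sequence(IntervalDistribution([10], [1.0]), 35, seed=0)
        assert seq.pulse_times.tolist() == [10, 20, 30]

    def test_same_seed_identical(self, table1_dist):
        a = sample_pulse_sequence(table1_dist, 1010, seed=42)
        b = sample_pulse_sequence(table1_dist, 1010, seed=42)
        assert np.array_equal(a.pulse_times, b.pulse_times)

    def test_too_short_duration_rejected(self, table1_dist):
        with pytest.raises(ValueError):
            sample_pulse_sequence(table1_dist, 3, seed=0)

    def test_long_draw_matches_distribution(self, table1_dist):
        from scipy import stats
        seq = sample_pulse_sequence(table1_dist, 60_000, seed=7)
        iv = seq.intervals
        obs = np.array([(iv == s).sum() for s in table1_dist.support])
        expected = table1_dist.probs * obs.sum()
        chi2 = ((obs - expected) ** 2 / expected).sum()
        p = stats.chi2.sf(chi2, df=table1_dist.support.size - 1)
        assert p > 1e-4  # sanity, not exactness

    def test_nonmonotone_pulse_times_rejected(self):
        with pytest.raises(ValueError):
            proto.PulseSequence(np.array([5, 5, 9]), n_timepoints=20)


class TestOrderIntervals:
    def test_multiset_preserved(self, table1_sequence):
        iv = np.concatenate([[table1_sequence.pulse_times[0]],
                             table1_sequence.intervals])
        counts = {int(v): int(c) for v, c in zip(*np.unique(iv, return_counts=True))}
        assert counts == EXPERIMENTAL_INTERVAL_COUNTS
        assert int(iv.sum()) == 1010

    def test_single_interval(self):
        seq = order_intervals({9: 1}, IntervalDistribution([9], [1.0]))
        assert seq.pulse_times.tolist() == [9]

    def test_predecessors_track_reference_quantiles(self, table1_sequence):
        """Repeated interval lengths should be preceded by a spread of
        intervals tracking the reference quantiles, not all-short ones."""
        ref = proto.gamma_interval_distribution(support_max=35)
        iv = np.concatenate([[table1_sequence.pulse_times[0]],
                             table1_sequence.intervals])
        preds = {}
        for prev, cur in zip(iv[:-1], iv[1:]):
            preds.setdefault(int(cur), []).append(int(prev))
        spreads = []
        for length, pp in preds.items():
            m = len(pp)
            if m < 3:
                continue
            targets = sorted(ref.quantile(j / (m + 1)) for j in range(1, m + 1))
            spreads.append(np.corrcoef(sorted(pp), targets)[0, 1])
        assert np.mean(spreads) > 0.7

    def test_deterministic_under_seed(self, table1_dist):
        a = order_intervals(EXPERIMENTAL_INTERVAL_COUNTS, table1_dist, seed=3)
        b = order_intervals(EXPERIMENTAL_INTERVAL_COUNTS, table1_dist, seed=3)
        assert np.array_equal(a.pulse_times, b.pulse_times)
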