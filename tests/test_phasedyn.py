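import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from smrdyn.datatypes import ANALYSIS_CHANNELS, wrap_phase
from smrdyn.phasedyn import (
    GPSEpisode,
    cluster_patterns,
    embed_patterns,
    gps_patterns,
    gps_segment,
    gps_threshold,
    instability_index,
    relative_phase,
)
from test_plv import make_phases


class TestWrapPhase:
    def test_range_is_half_open(self):
        assert wrap_phase(np.pi) == pytest.approx(np.pi)
        assert wrap_phase(-np.pi) == pytest.approx(np.pi)
        assert wrap_phase(0.0) == 0.0
        x = np.linspace(-10, 10, 1001)
        w = wrap_phase(x)
        assert np.all(w > -np.pi) and np.all(w <= np.pi)

    def test_preserves_angle(self):
        x = np.linspace(-10, 10, 101)
        assert np.allclose(np.exp(1j * wrap_phase(x)), np.exp(1j * x), atol=1e-12)


class TestRelativePhase:
    def test_equal_phases_give_zero(self, rng):
        base = rng.uniform(-np.pi, np.pi, size=(2, 1, 20))
        phases = make_phases(np.repeat(base, 9, axis=1))
        rel = relative_phase(phases)
        assert np.allclose(rel, 0.0, atol=1e-12)

    def test_zero_references_pass_through(self):
        phases = np.zeros((1, 9, 5))
        i = ANALYSIS_CHANNELS.index("Cz")
        phases[0, i, :] = np.pi / 3
        rel = relative_phase(make_phases(phases))
        assert np.allclose(rel[0, i, :], np.pi / 3)
        refs = [ANALYSIS_CHANNELS.index(c) for c in ("FC3", "FC4", "CP3", "CP4")]
        assert np.allclose(rel[0, refs, :], 0.0)

    def test_circular_mean_reference(self):
        # two references at 0 and pi/2: circular mean pi/4 (atan2 oracle)
        phases = np.zeros((1, 9, 3))
        phases[0, ANALYSIS_CHANNELS.index("FC3"), :] = 0.0
        phases[0, ANALYSIS_CHANNELS.index("FC4"), :] = np.pi / 2
        rel = relative_phase(
            make_phases(phases), references=("FC3", "FC4")
        )
        theta_r = np.arctan2(np.sin(0) + np.sin(np.pi / 2), np.cos(0) + np.cos(np.pi / 2))
        assert theta_r == pytest.approx(np.pi / 4)
        i = ANALYSIS_CHANNELS.index("Cz")
        assert np.allclose(rel[0, i, :], -np.pi / 4, atol=1e-12)

    def test_missing_reference_rejected(self, rng):
        phases = make_phases(rng.uniform(size=(1, 2, 5)), labels=("C3", "C4"))
        with pytest.raises(KeyError):
            relative_phase(phases)

    def test_wrap_point_safety(self):
        # references straddling the wrap point: arithmetic mean would be ~0,
        # the circular mean stays near pi
        phases = np.zeros((1, 9, 1))
        for c in ("FC3", "FC4", "CP3", "CP4"):
            phases[0, ANALYSIS_CHANNELS.index(c), 0] = np.pi - 0.1
        phases[0, ANALYSIS_CHANNELS.index("FC4"), 0] = -np.pi + 0.1
        phases[0, ANALYSIS_CHANNELS.index("CP4"), 0] = -np.pi + 0.1
        rel = relative_phase(make_phases(phases))
        i = ANALYSIS_CHANNELS.index("Cz")  # at phase 0, reference ~ pi
        assert abs(abs(rel[0, i, 0]) - np.pi) < 1e-6


class TestInstabilityIndex:
    def test_identical_phases_zero(self):
        rel = np.full((9, 10), 0.4)
        i, d = instability_index(rel)
        assert np.allclose(i, 0.0, atol=1e-12)
        assert np.allclose(d, 0.0, atol=1e-12)

    def test_two_channel_antiphase(self):
        # Phi difference pi: d_1 = d_2 = 1, I = 2
        rel = np.array([[0.0], [np.pi]])
        i, d = instability_index(rel)
        assert np.allclose(d, 1.0)
        assert np.allclose(i, 2.0)

    def test_matches_bruteforce_double_loop(self, rng):
        rel = rng.uniform(-np.pi, np.pi, size=(9, 30))
        i, d = instability_index(rel)
        n = rel.shape[0]
        d_expected = np.zeros_like(rel)
        for c in range(n):
            for h in range(n):
                d_expected[c] += 1.0 - np.cos(rel[c] - rel[h])
        d_expected /= n
        assert np.allclose(d, d_expected, atol=1e-10)
        assert np.allclose(i, (d_expected**2).sum(axis=0), atol=1e-10)

    def test_common_offset_invariance(self, rng):
        rel = rng.uniform(-np.pi, np.pi, size=(9, 20))
        i1, _ = instability_index(rel)
        i2, _ = instability_index(wrap_phase(rel + 1.234))
        assert np.allclose(i1, i2, atol=1e-10)

    def test_d_range(self, rng):
        _, d = instability_index(rng.uniform(-np.pi, np.pi, size=(9, 200)))
        assert d.min() >= 0.0 and d.max() <= 2.0

    def test_single_channel_rejected(self):
        with pytest.raises(ValueError):
            instability_index(np.zeros((1, 5)))


class TestGPSSegmentation:
    def test_worked_example(self):
        eps = gps_segment(np.array([1.0, 2.0, 3.0, 4.0]))
        assert eps == [GPSEpisode(0, 2)]  # median 2.5, strict below

    def test_increasing_series_splits_in_half(self, rng):
        for n in (4, 10, 100):
            i_series = np.sort(rng.uniform(size=2 * n))
            eps = gps_segment(i_series)
            assert eps == [GPSEpisode(0, n)]

    def test_constant_series_yields_nothing(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING):
            eps = gps_segment(np.full(100, 3.3))
        assert eps == []
        assert "zero episodes" in caplog.text

    def test_coverage_of_continuous_series(self, rng):
        i_series = rng.gamma(2.0, 1.0, size=5000)
        eps = gps_segment(i_series)
        covered = sum(e.length for e in eps)
        assert 0.40 <= covered / len(i_series) <= 0.55

    def test_episodes_disjoint_and_ordered(self, rng):
        eps = gps_segment(rng.normal(size=1000))
        for a, b in zip(eps, eps[1:]):
            assert a.end <= b.start

    def test_external_threshold(self):
        i_series = np.array([5.0, 1.0, 1.0, 5.0, 1.0])
        eps = gps_segment(i_series, threshold=2.0)
        assert eps == [GPSEpisode(1, 3), GPSEpisode(4, 5)]

    def test_percentile_linear_interpolation(self):
        assert gps_threshold(np.array([1.0, 2.0, 3.0, 4.0])) == 2.5

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            gps_segment(np.array([]))


class TestGPSPatterns:
    def test_constant_phase(self):
        rel = np.full((9, 10), 0.8)
        patterns, degenerate = gps_patterns(rel, [GPSEpisode(2, 8)])
        assert np.allclose(patterns, 0.8, atol=1e-12)
        assert not degenerate.any()

    def test_two_sample_circular_mean(self):
        rel = np.array([[0.0, np.pi / 2]])
        rel = np.repeat(rel, 2, axis=0)
        patterns, _ = gps_patterns(rel, [GPSEpisode(0, 2)])
        assert np.allclose(patterns, np.pi / 4, atol=1e-10)

    def test_antipodal_degenerate_flagged(self):
        rel = np.array([[-np.pi / 2, np.pi / 2], [0.3, 0.3]])
        patterns, degenerate = gps_patterns(rel, [GPSEpisode(0, 2)])
        assert patterns[0, 0] == 0.0  # convention for vanishing resultant
        assert patterns[0, 1] == pytest.approx(0.3)
        assert degenerate[0]

    def test_empty_episode_rejected(self):
        with pytest.raises(ValueError):
            gps_patterns(np.zeros((2, 10)), [GPSEpisode(3, 3)])


class TestClusterPatterns:
    def test_planted_templates_recovered(self, rng):
        k = 6
        # pairwise angular separation >= pi/2 via spread layout
        centers = np.array(
            [wrap_phase(np.full(9, a)) + rng.uniform(-0.05, 0.05, 9) for a in np.linspace(-np.pi * 0.9, np.pi * 0.75, k)]
        )
        truth = rng.integers(k, size=600)
        patterns = wrap_phase(centers[truth] + rng.uniform(-0.1, 0.1, size=(600, 9)))
        _, labels = cluster_patterns(patterns, k=k, seed=0)
        assert adjusted_rand_score(truth, labels) >= 0.99

    def test_identical_patterns_single_cluster(self):
        patterns = np.tile(np.linspace(-1, 1, 9), (20, 1))
        model, labels = cluster_patterns(patterns, k=6, seed=0)
        assert len(np.unique(labels)) == 1

    def test_too_few_patterns_rejected(self, rng):
        with pytest.raises(ValueError, match="at least 6"):
            cluster_patterns(rng.uniform(size=(5, 9)), k=6)

    def test_embedding_shape(self, rng):
        patterns = rng.uniform(-np.pi, np.pi, size=(10, 9))
        emb = embed_patterns(patterns)
        assert emb.shape == (10, 18)
        assert np.allclose((emb[:, :9] ** 2 + emb[:, 9:] ** 2), 1.0)
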