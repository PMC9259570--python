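"""Spatial maps: binning, pixelwise normalization, patterns, clustering."""

from pathlib import Path

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from calyximg import spatial_patterns as sp
from calyximg import synthetic_data as sd

DATA = Path(__file__).parent / "data"

MOTIF_CENTERS = ((8.0, 24.0), (24.0, 8.0), (24.0, 40.0))


def motif_recovery_config(seed_unused=None):
    """High-SNR movie conditions under which motifs are recoverable:
    temporally isolated events (low rate, short decay), no bleaching,
    centers >= 16 px apart (>= 10 blob sigmas)."""
    return sd.SimulationConfig(
        segment_durations_s={"pre": 180.0},
        segments=("pre",),
        spont_rate_hz=0.06,
        noise_sd_pct=0.05,
        n_motifs=3,
        frame_shape=(48, 48),
        motif_sigma_px=1.5,
        bleach_tau_s=np.inf,
        kernel=sd.TransientKernel(amplitude_pct=3.0, decay_tau_s=0.5),
        motif_centers=MOTIF_CENTERS,
    )


def extract_event_patterns(movie, roi, truth, cfg):
    binned = sp.bin2x2(movie)
    roi_b = sp.bin2x2(roi.mask[None].astype(float))[0] >= 0.5
    norm = sp.pixelwise_dff(binned, 400)
    pats, ids = [], []
    for t0, m in zip(truth.event_times_s, truth.event_motif_ids):
        peak = int(np.floor(t0 * 20)) + cfg.kernel.rise_frames
        if 1 <= peak <= norm.shape[0] - 2:
            pats.append(sp.extract_pattern(norm, peak, roi_b))
            ids.append(int(m))
    return pats, ids, roi_b


class TestBin2x2:
    def test_constant_movie_unchanged(self):
        out = sp.bin2x2(np.full((3, 4, 4), 7.0))
        np.testing.assert_array_equal(out, np.full((3, 2, 2), 7.0))

    def test_block_mean_example(self):
        frame = np.array([[[0.0, 100.0], [50.0, 50.0]]])
        assert sp.bin2x2(frame)[0, 0, 0] == 50.0

    def test_matches_brute_force_blocks(self, rng):
        data = rng.uniform(0, 1, size=(2, 8, 8))
        out = sp.bin2x2(data)
        for t in range(2):
            for r in range(4):
                for c in range(4):
                    expected = data[t, 2 * r : 2 * r + 2, 2 * c : 2 * c + 2].mean()
                    assert out[t, r, c] == pytest.approx(expected, rel=1e-12)

    def test_odd_dimensions_cropped_with_warning(self):
        with pytest.warns(UserWarning, match="odd"):
            out = sp.bin2x2(np.zeros((2, 5, 7)))
        assert out.shape == (2, 2, 3)


class TestPixelwiseDff:
    def test_constant_movie_gives_zero(self):
        out = sp.pixelwise_dff(np.full((450, 3, 3), 10.0), 400)
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_impulse_matches_brute_force_rolling_mean(self):
        t_len, window = 420, 400
        data = np.full((t_len, 2, 2), 100.0)
        data[210, 0, 0] = 300.0
        out = sp.pixelwise_dff(data, window)
        # brute-force shrinking-window centered rolling mean, every pixel
        half_lo = (window - 1) // 2
        half_hi = window - half_lo
        full = np.empty_like(data, dtype=float)
        for r in range(2):
            for c in range(2):
                s = data[:, r, c]
                for t in range(t_len):
                    w = s[max(0, t - half_lo) : min(t_len, t + half_hi)]
                    full[t, r, c] = (s[t] - w.mean()) / w.mean() * 100.0
        full -= full.min()
        np.testing.assert_allclose(out, full, atol=1e-9)

    def test_global_minimum_exactly_zero(self, rng):
        data = rng.uniform(50, 150, size=(430, 3, 3))
        out = sp.pixelwise_dff(data, 400)
        assert out.min() == 0.0

    def test_movie_shorter_than_window_raises(self):
        with pytest.raises(ValueError, match="rolling window"):
            sp.pixelwise_dff(np.ones((100, 2, 2)), 400)

    def test_nonpositive_baseline_raises(self):
        data = np.zeros((450, 2, 2))
        with pytest.raises(ValueError, match="non-positive"):
            sp.pixelwise_dff(data, 400)


class TestExtractPattern:
    def test_uniform_roi_activity_all_survive_at_one(self):
        movie = np.zeros((5, 8, 8))
        mask = np.zeros((8, 8), bool)
        mask[2:6, 2:6] = True
        movie[:, mask] = 4.0
        pat = sp.extract_pattern(movie, 2, mask, gaussian_on=False)
        assert np.all(pat.map[mask] == 1.0)
        assert np.all(pat.map[~mask] == 0.0)

    def test_single_blob_peak_at_center(self):
        rows, cols = np.mgrid[0:16, 0:16]
        blob = np.exp(-(((rows - 8) ** 2 + (cols - 8) ** 2) / 4.0))
        movie = np.stack([blob, 2 * blob, blob])
        mask = np.ones((16, 16), bool)
        pat = sp.extract_pattern(movie, 1, mask)
        assert pat.map[8, 8] == 1.0
        assert np.unravel_index(pat.map.argmax(), pat.map.shape) == (8, 8)

    def test_two_blob_fixture_matches_committed_golden(self):
        H = W = 12
        rows, cols = np.mgrid[0:H, 0:W]
        blob_a = np.exp(-(((rows - 3.0) ** 2 + (cols - 4.0) ** 2) / (2 * 1.0**2)))
        blob_b = np.exp(-(((rows - 8.0) ** 2 + (cols - 8.0) ** 2) / (2 * 1.2**2)))
        movie = np.stack(
            [0.05 + w * (blob_a + 0.6 * blob_b) for w in (0.5, 1.0, 0.8)]
        )
        mask = np.zeros((H, W), bool)
        mask[1:-1, 1:-1] = True
        pat = sp.extract_pattern(movie, 1, mask)
        golden = np.loadtxt(DATA / "two_blob_pattern.csv", delimiter=",")
        np.testing.assert_allclose(pat.map, golden, atol=1e-9)

    def test_values_in_unit_interval_and_threshold_idempotent(self, rng):
        movie = rng.uniform(0, 5, size=(5, 10, 10))
        mask = np.ones((10, 10), bool)
        pat = sp.extract_pattern(movie, 2, mask)
        assert pat.map.min() >= 0.0 and pat.map.max() <= 1.0
        again = np.where(pat.map >= 0.5, pat.map, 0.0)
        np.testing.assert_array_equal(again, pat.map)

    def test_zero_roi_activity_warns_and_returns_empty(self):
        movie = np.zeros((5, 6, 6))
        mask = np.ones((6, 6), bool)
        with pytest.warns(UserWarning, match="empty pattern"):
            pat = sp.extract_pattern(movie, 2, mask)
        assert np.all(pat.map == 0.0)

    def test_peak_frame_needs_both_neighbours(self):
        movie = np.ones((5, 4, 4))
        with pytest.raises(ValueError, match="neighbours"):
            sp.extract_pattern(movie, 0, np.ones((4, 4), bool))


class TestClusterPatterns:
    def _blob_patterns(self, rng, centers, n_each, shape=(16, 16), noise=0.02):
        rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]]
        mask = np.ones(shape, bool)
        pats, ids = [], []
        for i, (r0, c0) in enumerate(centers):
            for _ in range(n_each):
                m = np.exp(-(((rows - r0) ** 2 + (cols - c0) ** 2) / 3.0))
                m = m + rng.normal(0, noise, shape)
                m = np.clip(m / m.max(), 0, 1)
                m = np.where(m >= 0.5, m, 0.0)
                pats.append(sp.SpatialPattern(m, 0))
                ids.append(i)
        return pats, ids, mask

    def test_identical_patterns_k1_zero_inertia(self):
        mask = np.ones((8, 8), bool)
        pats = [sp.SpatialPattern(np.full((8, 8), 0.7), 0) for _ in range(5)]
        cl = sp.cluster_patterns(pats, mask, k=1)
        assert cl.inertia == pytest.approx(0.0, abs=1e-12)

    def test_planted_motifs_recovered(self, rng):
        pats, ids, mask = self._blob_patterns(rng, [(4, 4), (4, 12), (12, 8)], 6)
        cl = sp.cluster_patterns(pats, mask, k=3, seed=0)
        assert adjusted_rand_score(ids, cl.labels) == 1.0

    def test_inertia_nonincreasing_in_k(self, rng):
        pats, _, mask = self._blob_patterns(rng, [(4, 4), (4, 12), (12, 8)], 5)
        inertias = [
            sp.cluster_patterns(pats, mask, k=k, seed=0).inertia for k in (1, 2, 3, 4)
        ]
        assert all(a >= b - 1e-9 for a, b in zip(inertias, inertias[1:]))

    def test_silhouette_k_selection_finds_planted_k(self, rng):
        pats, _, mask = self._blob_patterns(rng, [(4, 4), (4, 12), (12, 8)], 6)
        cl = sp.cluster_patterns(pats, mask, k_range=range(2, 7), seed=0)
        assert cl.k == 3

    def test_fixed_seed_reproducible(self, rng):
        pats, _, mask = self._blob_patterns(rng, [(4, 4), (12, 12)], 5)
        a = sp.cluster_patterns(pats, mask, k=2, seed=7)
        b = sp.cluster_patterns(pats, mask, k=2, seed=7)
        np.testing.assert_array_equal(a.labels, b.labels)
        np.testing.assert_array_equal(a.centroids, b.centroids)

    def test_fewer_patterns_than_k_raises(self):
        mask = np.ones((4, 4), bool)
        pats = [sp.SpatialPattern(np.zeros((4, 4)), 0)]
        with pytest.raises(ValueError, match="cannot support"):
            sp.cluster_patterns(pats, mask, k=3)

    def test_centroid_is_mean_of_members(self, rng):
        pats, _, mask = self._blob_patterns(rng, [(4, 4), (12, 12)], 6)
        cl = sp.cluster_patterns(pats, mask, k=2, seed=0)
        X = np.array([p.map[mask] for p in pats])
        for j in range(2):
            np.testing.assert_allclose(
                cl.centroids[j], X[cl.labels == j].mean(axis=0), atol=1e-8
            )


class TestAssignStimulusPatterns:
    def _clustering(self, rng):
        rows, cols = np.mgrid[0:16, 0:16]
        mask = np.ones((16, 16), bool)
        pats = []
        for r0, c0 in [(4, 4), (4, 12), (12, 8)] * 5:
            m = np.exp(-(((rows - r0) ** 2 + (cols - c0) ** 2) / 3.0))
            m += rng.normal(0, 0.02, (16, 16))
            pats.append(sp.SpatialPattern(np.clip(m / m.max(), 0, 1), 0))
        return sp.cluster_patterns(pats, mask, k=3, seed=0), mask

    def test_centroid_assigned_to_itself_with_match(self, rng):
        cl, mask = self._clustering(rng)
        cmap = np.zeros(mask.shape)
        cmap[mask] = cl.centroids[1]
        labels, flags = sp.assign_stimulus_patterns([sp.SpatialPattern(cmap, 0)], cl)
        assert labels[0] == 1 and flags[0]

    def test_far_pattern_assigned_without_match(self, rng):
        cl, mask = self._clustering(rng)
        far = sp.SpatialPattern(np.ones(mask.shape) * 50.0, 0)
        _, flags = sp.assign_stimulus_patterns([far], cl)
        assert not flags[0]

    def test_matches_exhaustive_nearest_centroid(self, rng):
        cl, mask = self._clustering(rng)
        stim = [
            sp.SpatialPattern(rng.uniform(0, 1, mask.shape), 0) for _ in range(8)
        ]
        labels, _ = sp.assign_stimulus_patterns(stim, cl)
        X = np.array([p.map[mask] for p in stim])
        for i in range(len(stim)):
            dists = [np.linalg.norm(X[i] - c) for c in cl.centroids]
            assert labels[i] == int(np.argmin(dists))

    def test_empty_inputs_raise(self, rng):
        cl, _ = self._clustering(rng)
        with pytest.raises(ValueError):
            sp.assign_stimulus_patterns([], cl)


class TestEndToEndMotifRecovery:
    def test_planted_motifs_recovered_from_movie(self):
        cfg = motif_recovery_config()
        movie, roi, truth = sd.simulate_movie(cfg, 0)
        pats, ids, roi_b = extract_event_patterns(movie, roi, truth, cfg)
        assert len(set(ids)) == 3
        cl = sp.cluster_patterns(pats, roi_b, k=3, seed=0)
        assert adjusted_rand_score(ids, cl.labels) == 1.0
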