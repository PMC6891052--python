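import numpy as np
import pandas as pd
import pytest

from rhythmgain import decoding, stimgen
from rhythmgain.preprocess import EpochSet


def _component_epochs(data, t0=0):
    return EpochSet(
        data=data, times_ms=np.arange(t0, t0 + data.shape[-1]),
        labels=pd.DataFrame(index=range(data.shape[0])),
    )


class TestShrinkageCovariance:
    def test_matches_sklearn_ledoit_wolf(self):
        """Independent oracle: sklearn's analytic Ledoit-Wolf estimator."""
        from sklearn.covariance import LedoitWolf

        rng = np.random.default_rng(0)
        for _ in range(100):
            n = rng.integers(5, 60)
            p = rng.integers(2, 12)
            X = rng.normal(size=(n, p)) @ rng.normal(size=(p, p))
            cov, s = decoding.shrinkage_covariance(X)
            ref = LedoitWolf(assume_centered=False).fit(X)
            assert np.allclose(cov, ref.covariance_, atol=1e-10)
            assert s == pytest.approx(ref.shrinkage_, abs=1e-10)

    def test_rank_deficient_data_still_invertible(self):
        rng = np.random.default_rng(1)
        direction = rng.normal(size=6)
        X = np.outer(rng.normal(size=20), direction)  # rank 1
        cov, s = decoding.shrinkage_covariance(X)
        assert s > 0
        np.linalg.cholesky(cov)  # PD or raises

    def test_isotropic_data_fully_shrunk(self):
        """When the sample covariance is already a scaled identity the
        dispersion d^2 is ~0 and the estimate collapses onto mu*I."""
        X = np.array([[1.0, 0.0], [-1.0, 0.0], [0.0, 1.0], [0.0, -1.0]])
        cov, s = decoding.shrinkage_covariance(X)
        assert np.allclose(cov, 0.5 * np.eye(2))

    def test_too_few_trials_rejected(self):
        with pytest.raises(ValueError):
            decoding.shrinkage_covariance(np.zeros((1, 4)))


class TestMahalanobis:
    def test_identity_covariance_is_euclidean(self):
        assert decoding.mahalanobis([1.0, 0.0], [0.0, 0.0], np.eye(2)) == pytest.approx(1.0)

    def test_scaling_by_standard_deviation(self):
        cov = np.diag([4.0, 1.0])
        assert decoding.mahalanobis([2.0, 0.0], [0.0, 0.0], cov) == pytest.approx(1.0)

    def test_zero_iff_at_mean(self):
        rng = np.random.default_rng(2)
        A = rng.normal(size=(5, 5))
        cov = A @ A.T + np.eye(5)
        mu = rng.normal(size=5)
        assert decoding.mahalanobis(mu, mu, cov) == 0.0
        assert decoding.mahalanobis(mu + 0.1, mu, cov) > 0.0

    def test_matches_explicit_inverse(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            A = rng.normal(size=(5, 5))
            cov = A @ A.T + 0.5 * np.eye(5)
            x, mu = rng.normal(size=5), rng.normal(size=5)
            ref = np.sqrt((x - mu) @ np.linalg.inv(cov) @ (x - mu))
            assert decoding.mahalanobis(x, mu, cov) == pytest.approx(ref, rel=1e-10)


class TestLooInternals:
    def test_loo_covariances_match_per_fold_estimates(self):
        """The vectorised leave-one-out shrinkage covariances equal the
        direct estimator applied to each fold."""
        rng = np.random.default_rng(4)
        X = rng.normal(size=(15, 6)) @ rng.normal(size=(6, 6))
        covs = decoding._loo_shrunk_covariances(X)
        for i in range(15):
            ref, _ = decoding.shrinkage_covariance(np.delete(X, i, axis=0))
            assert np.allclose(covs[i], ref, atol=1e-10)

    def test_loo_distances_match_bruteforce(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(24, 4))
        y = rng.integers(0, 3, size=24)
        d = decoding._loo_class_distances(X, y, 3)
        for i in range(24):
            rest = np.delete(np.arange(24), i)
            cov, _ = decoding.shrinkage_covariance(X[rest])
            for k in range(3):
                members = rest[y[rest] == k]
                ref = decoding.mahalanobis(X[i], X[members].mean(axis=0), cov)
                assert d[i, k] == pytest.approx(ref, rel=1e-8)


class TestIdealMatrix:
    def test_structure(self, grid):
        ideal = decoding.ideal_matrix(grid)
        assert np.allclose(np.diag(ideal), 0.0)
        assert np.allclose(ideal, ideal.T)
        # entries increase away from the diagonal within each row
        for i in range(15):
            row = ideal[i]
            assert np.all(np.diff(row[i:]) > 0)
            assert np.all(np.diff(row[: i + 1]) < 0) if i else True


class TestScoring:
    def test_perfect_and_inverted(self, grid):
        ideal = decoding.ideal_matrix(grid)
        assert decoding.score_decoding(ideal, ideal) == pytest.approx(1.0)
        assert decoding.score_decoding(-ideal, ideal) == pytest.approx(-1.0)

    def test_constant_matrix_scores_zero(self, grid):
        ideal = decoding.ideal_matrix(grid)
        assert decoding.score_decoding(np.ones_like(ideal), ideal) == 0.0

    def test_missing_cells_pairwise_deleted(self, grid):
        ideal = decoding.ideal_matrix(grid)
        obs = ideal.copy()
        obs[3, :] = np.nan
        assert decoding.score_decoding(obs, ideal) == pytest.approx(1.0)

    def test_too_few_pairs_rejected(self, grid):
        ideal = decoding.ideal_matrix(grid)
        obs = np.full_like(ideal, np.nan)
        obs[0, 0] = 1.0
        with pytest.raises(ValueError):
            decoding.score_decoding(obs, ideal)


def _make_tone_trials(rng, n_trials, n_comp, slope, noise, t_len=200):
    """Synthetic component epochs with a linear frequency code at a fixed
    response latency (offset 50 in the epoch)."""
    bands = rng.integers(0, 15, size=n_trials)
    pattern = rng.normal(size=n_comp)
    data = rng.normal(scale=noise, size=(n_trials, n_comp, t_len))
    for i, b in enumerate(bands):
        data[i, :, 40:60] += slope * (b - 7.0) * pattern[:, None]
    return _component_epochs(data), bands


class TestToneDecoding:
    def test_default_lag_grid_size(self):
        assert len(decoding.default_lags()) == 101
        assert len(decoding.default_response_window()) == 21

    def test_distinct_patterns_decode_diagonally(self):
        """With clear band-specific patterns, each row of the distance
        matrix is minimised on the diagonal."""
        rng = np.random.default_rng(6)
        n = 90
        bands = np.repeat(np.arange(15), 6)
        patterns = rng.normal(size=(15, 5))
        data = rng.normal(scale=0.05, size=(n, 5, 120))
        for i, b in enumerate(bands):
            data[i, :, 30:70] += patterns[b][:, None]
        ep = _component_epochs(data)
        bal = np.tile(bands[:, None], (1, 1))
        dms = decoding.decode_tone_frequency(
            ep, bal, lags_ms=[0], response_window_ms=[36, 46, 56]
        )
        mat = dms.matrices[0]
        assert np.all(np.isfinite(mat))
        assert np.array_equal(np.argmin(mat, axis=1), np.arange(15))

    def test_score_increases_with_coding_strength(self, grid):
        """Monotone relation between the simulated frequency-code slope and
        the decoding score (fixed noise and seeds)."""
        ideal = decoding.ideal_matrix(grid)
        scores = []
        for slope in (0.0, 0.4, 1.5):
            vals = []
            for seed in range(3):
                rng = np.random.default_rng(100 + seed)
                ep, bands = _make_tone_trials(rng, 75, 5, slope, 1.0)
                dms = decoding.decode_tone_frequency(
                    ep, bands[:, None], lags_ms=[0], response_window_ms=[45, 50, 55]
                )
                vals.append(decoding.score_decoding(dms.matrices[0], ideal))
            scores.append(np.mean(vals))
        assert scores[0] < scores[1] < scores[2]

    def test_shuffled_labels_score_zero_on_average(self, grid):
        ideal = decoding.ideal_matrix(grid)
        rng = np.random.default_rng(7)
        ep, bands = _make_tone_trials(rng, 75, 5, 1.0, 0.5)
        scores = []
        for _ in range(60):
            shuffled = rng.permutation(bands)
            dms = decoding.decode_tone_frequency(
                ep, shuffled[:, None], lags_ms=[0], response_window_ms=[50]
            )
            scores.append(decoding.score_decoding(dms.matrices[0], ideal))
        assert np.mean(scores) == pytest.approx(0.0, abs=0.05)

    def test_lags_without_tones_flagged_missing(self):
        rng = np.random.default_rng(8)
        ep, bands = _make_tone_trials(rng, 40, 4, 1.0, 0.5)
        bal = np.column_stack([bands, np.full(40, -1)])
        dms = decoding.decode_tone_frequency(
            ep, bal, lags_ms=[0, 10], response_window_ms=[50]
        )
        assert np.all(np.isnan(dms.matrices[1]))
        assert np.isfinite(dms.matrices[0]).any()

    def test_epoch_window_validated(self):
        rng = np.random.default_rng(9)
        ep, bands = _make_tone_trials(rng, 30, 4, 1.0, 0.5, t_len=60)
        with pytest.raises(ValueError):
            decoding.decode_tone_frequency(
                ep, bands[:, None], lags_ms=[0], response_window_ms=[100]
            )


class TestChordDecoding:
    def _chord_epochs(self, rng, separation, n=40, t_len=300):
        ids = np.array(["A", "B"])[rng.integers(0, 2, size=n)]
        pattern = rng.normal(size=4)
        data = rng.normal(scale=1.0, size=(n, 4, t_len))
        for i, ident in enumerate(ids):
            sign = 1.0 if ident == "A" else -1.0
            # epoch times start at -100 ms: indices 240:280 = 140..180 ms
            data[i, :, 240:280] += sign * separation * pattern[:, None]
        return _component_epochs(data, t0=-100), ids

    def test_no_signal_means_zero_relative_distance(self):
        rng = np.random.default_rng(10)
        ep, ids = self._chord_epochs(rng, separation=0.0)
        series = decoding.decode_chord(
            ep, ids, times_ms=[0, 100], response_window_ms=[30, 50]
        )
        assert np.all(np.abs(series.relative_distance) < 0.5)

    def test_identity_signal_detected_at_response_latency(self):
        rng = np.random.default_rng(11)
        ep, ids = self._chord_epochs(rng, separation=2.0)
        series = decoding.decode_chord(
            ep, ids, times_ms=[-50, 100], response_window_ms=[26, 46, 66]
        )
        # signal at 140..180 in epoch time: reachable from t=100 (126..166)
        assert series.relative_distance[1] > series.relative_distance[0] + 0.5
        assert series.relative_distance[1] > 0.5

    def test_default_time_axis_span(self):
        times = np.arange(-100, 401, 10)
        rng = np.random.default_rng(12)
        ep, ids = self._chord_epochs(rng, 1.0, t_len=640)
        ep.times_ms = np.arange(-110, 530)
        series = decoding.decode_chord(ep, ids, times_ms=times, response_window_ms=[26])
        assert series.times_ms[0] == -100 and series.times_ms[-1] == 400

    def test_single_identity_rejected(self):
        rng = np.random.default_rng(13)
        ep, _ = self._chord_epochs(rng, 1.0)
        with pytest.raises(ValueError):
            decoding.decode_chord(ep, np.array(["A"] * ep.n_epochs), times_ms=[0],
                                  response_window_ms=[30])


class TestToneTimeline:
    def test_band_at_lag_matches_events(self, small_recording):
        ev = small_recording.events
        chords = ev[(ev.event_kind == "chord") & (ev.preceding_isi_ms == 1000.0)]
        onsets = chords["onset_ms"].to_numpy(int)
        lags = np.array([-200, -50, 0, 150])
        bal = decoding.tone_bands_at_lags(small_recording, onsets, lags)
        tones = ev[ev.event_kind == "tone"]
        for i, onset in enumerate(onsets[:10]):
            for j, lag in enumerate(lags):
                t = onset + lag
                hit = tones[(tones.onset_ms <= t) & (tones.onset_ms + tones.duration_ms > t)]
                chord_hit = ev[
                    (ev.event_kind == "chord") & (ev.onset_ms <= t)
                    & (ev.onset_ms + ev.duration_ms > t)
                ]
                if len(chord_hit):
                    assert bal[i, j] == -1
                elif len(hit):
                    assert bal[i, j] == hit.iloc[0]["band"]
                else:
                    assert bal[i, j] == -1
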