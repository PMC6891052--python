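import numpy as np
import pandas as pd
import pytest
from scipy import signal as sps

from rhythmgain import preprocess, synthmeeg


def _recording_from_array(data, sensors, sfreq=1000.0):
    events = pd.DataFrame(
        {"event_kind": [], "onset_ms": [], "duration_ms": [], "band": []}
    )
    return synthmeeg.Recording(
        data=data, sfreq=sfreq, sensors=sensors, events=events, condition="rhythmic"
    )


@pytest.fixture(scope="module")
def flat_sensors():
    return synthmeeg.make_sensor_array(4, 2, 2, seed=0)


class TestFilterContinuous:
    def test_dc_removed_by_highpass(self, flat_sensors):
        rec = _recording_from_array(np.full((8, 20000), 3.7), flat_sensors)
        out = preprocess.filter_continuous(rec)
        assert np.abs(out.data[:, 5000:15000]).max() < 0.05

    def test_line_frequency_attenuated(self, flat_sensors):
        t = np.arange(30000) / 1000.0
        rec = _recording_from_array(
            np.tile(np.sin(2 * np.pi * 50.0 * t), (8, 1)), flat_sensors
        )
        out = preprocess.filter_continuous(rec)
        inner = slice(5000, 25000)
        atten = np.sqrt(
            np.mean(out.data[:, inner] ** 2) / np.mean(rec.data[:, inner] ** 2)
        )
        assert 20 * np.log10(atten) < -20.0

    def test_passband_preserved(self, flat_sensors):
        t = np.arange(30000) / 1000.0
        rec = _recording_from_array(
            np.tile(np.sin(2 * np.pi * 10.0 * t), (8, 1)), flat_sensors
        )
        out = preprocess.filter_continuous(rec)
        inner = slice(5000, 25000)
        ratio = np.sqrt(
            np.mean(out.data[:, inner] ** 2) / np.mean(rec.data[:, inner] ** 2)
        )
        assert ratio == pytest.approx(1.0, abs=0.05)

    def test_zero_phase_no_group_delay(self, flat_sensors):
        """Forward-backward filtering leaves a bandlimited input unshifted:
        the input/output cross-correlation peaks at lag zero."""
        rng = np.random.default_rng(0)
        x = rng.normal(size=20000)
        sos = sps.butter(4, 30.0, fs=1000.0, output="sos")
        x = sps.sosfiltfilt(sos, x)
        rec = _recording_from_array(np.tile(x, (8, 1)), flat_sensors)
        out = preprocess.filter_continuous(rec)
        a, b = rec.data[0, 5000:15000], out.data[0, 5000:15000]
        lags = np.arange(-50, 51)
        xc = [np.dot(a, np.roll(b, k)) for k in lags]
        assert lags[np.argmax(xc)] == 0

    def test_output_length_matches_input(self, flat_sensors):
        rec = _recording_from_array(np.random.default_rng(1).normal(size=(8, 12345)), flat_sensors)
        assert preprocess.filter_continuous(rec).n_samples == 12345

    def test_cutoff_above_nyquist_rejected(self, flat_sensors):
        rec = _recording_from_array(np.zeros((8, 1000)), flat_sensors)
        with pytest.raises(ValueError):
            preprocess.filter_continuous(rec, lp_hz=600.0)


class TestRereference:
    def test_eeg_mean_zero_and_meg_untouched(self, flat_sensors):
        rng = np.random.default_rng(2)
        rec = _recording_from_array(rng.normal(size=(8, 500)), flat_sensors)
        out = preprocess.rereference_eeg(rec)
        eeg = flat_sensors.family_indices("eeg")
        meg = np.setdiff1d(np.arange(8), eeg)
        assert np.abs(out.data[eeg].mean(axis=0)).max() < 1e-12
        assert np.array_equal(out.data[meg], rec.data[meg])

    def test_identical_eeg_becomes_zero(self, flat_sensors):
        data = np.zeros((8, 100))
        data[:4] = 1.5
        rec = _recording_from_array(data, flat_sensors)
        out = preprocess.rereference_eeg(rec)
        assert np.allclose(out.data[:4], 0.0)

    def test_too_few_eeg_channels_rejected(self):
        sens = synthmeeg.make_sensor_array(1, 3, 3, seed=0)
        rec = _recording_from_array(np.zeros((7, 100)), sens)
        with pytest.raises(ValueError):
            preprocess.rereference_eeg(rec)


class TestEpoching:
    def test_window_sample_count(self, flat_sensors):
        rec = _recording_from_array(np.zeros((8, 2000)), flat_sensors)
        ep = preprocess.epoch_events(rec, [500], (-200, 400))
        assert ep.data.shape == (1, 8, 601)
        assert ep.times_ms[0] == -200 and ep.times_ms[-1] == 400

    def test_out_of_bounds_event_dropped(self, flat_sensors):
        rec = _recording_from_array(np.zeros((8, 2000)), flat_sensors)
        ep = preprocess.epoch_events(rec, [10, 500], (-200, 400))
        assert ep.n_epochs == 1 and ep.n_dropped == 1

    def test_impulse_localised_at_time_zero(self, flat_sensors):
        data = np.zeros((8, 2000))
        data[:, 700] = 1.0
        rec = _recording_from_array(data, flat_sensors)
        ep = preprocess.epoch_events(rec, [700], (-200, 400))
        t0 = np.searchsorted(ep.times_ms, 0)
        assert np.all(ep.data[0, :, t0] == 1.0)
        assert ep.data.sum() == 8.0

    def test_all_dropped_raises(self, flat_sensors):
        rec = _recording_from_array(np.zeros((8, 300)), flat_sensors)
        with pytest.raises(ValueError):
            preprocess.epoch_events(rec, [10], (-200, 400))


class TestSmoothing:
    def _epochs(self, data):
        return preprocess.EpochSet(
            data=data, times_ms=np.arange(data.shape[-1]),
            labels=pd.DataFrame(index=range(data.shape[0])),
        )

    def test_constant_unchanged(self):
        ep = self._epochs(np.full((2, 3, 100), 4.2))
        out = preprocess.smooth_epochs(ep, 20)
        assert np.allclose(out.data, 4.2)

    def test_impulse_becomes_boxcar(self):
        data = np.zeros((1, 1, 100))
        data[0, 0, 50] = 1.0
        out = preprocess.smooth_epochs(self._epochs(data), 20)
        interior = out.data[0, 0, 45:55]
        assert np.allclose(interior, 1.0 / 20.0)
        assert out.data.shape == data.shape

    def test_noise_variance_reduced_by_window_length(self):
        rng = np.random.default_rng(3)
        data = rng.normal(size=(200, 1, 200))
        out = preprocess.smooth_epochs(self._epochs(data), 20)
        ratio = out.data[:, :, 50:150].var() / data[:, :, 50:150].var()
        assert ratio == pytest.approx(1.0 / 20.0, rel=0.15)

    def test_window_longer_than_epoch_rejected(self):
        with pytest.raises(ValueError):
            preprocess.smooth_epochs(self._epochs(np.zeros((1, 1, 10))), 20)


class TestComponentBasis:
    def test_rank_one_map_needs_one_mode(self):
        u = np.random.default_rng(0).normal(size=10)
        v = np.random.default_rng(1).normal(size=50)
        basis = preprocess.compute_component_basis({"eeg": np.outer(u, v)})
        assert basis.n_modes["eeg"] == 1
        assert basis.retained_variance["eeg"] == pytest.approx(1.0)

    def test_variance_target_met_minimally(self):
        rng = np.random.default_rng(4)
        mat = rng.normal(size=(12, 80))
        basis = preprocess.compute_component_basis({"eeg": mat}, var_target=0.95)
        k = basis.n_modes["eeg"]
        assert basis.retained_variance["eeg"] >= 0.95
        # one fewer mode would not reach the target
        s = np.linalg.svd(mat, compute_uv=False)
        frac = np.cumsum(s**2) / np.sum(s**2)
        if k > 1:
            assert frac[k - 2] < 0.95

    def test_weights_orthonormal(self):
        rng = np.random.default_rng(5)
        basis = preprocess.compute_component_basis({"mag": rng.normal(size=(9, 40))})
        w = basis.weights["mag"]
        assert np.allclose(w.T @ w, np.eye(w.shape[1]), atol=1e-10)

    def test_rank_zero_rejected(self):
        with pytest.raises(ValueError):
            preprocess.compute_component_basis({"eeg": np.zeros((5, 20))})

    def test_apply_identity_basis_is_noop(self):
        rng = np.random.default_rng(6)
        data = rng.normal(size=(4, 3, 60))
        ep = preprocess.EpochSet(
            data=data, times_ms=np.arange(60),
            labels=pd.DataFrame(index=range(4)),
            feature_families=np.array(["eeg"] * 3),
        )
        basis = preprocess.ComponentBasis(
            weights={"eeg": np.eye(3)}, retained_variance={"eeg": 1.0},
            channel_indices={"eeg": np.arange(3)},
        )
        out = preprocess.apply_basis(ep, basis)
        assert np.allclose(out.data, data)

    def test_full_basis_preserves_variance(self):
        """With every mode kept, projection is an isometry per family."""
        rng = np.random.default_rng(7)
        data = rng.normal(size=(6, 5, 40))
        summary = data.mean(axis=0)
        ep = preprocess.EpochSet(
            data=data, times_ms=np.arange(40),
            labels=pd.DataFrame(index=range(6)),
            feature_families=np.array(["grad"] * 5),
        )
        basis = preprocess.compute_component_basis(
            {"grad": summary}, var_target=1.0, channel_indices={"grad": np.arange(5)}
        )
        out = preprocess.apply_basis(ep, basis)
        assert out.data.shape[1] == 5
        assert np.sum(out.data**2) == pytest.approx(np.sum(data**2), rel=1e-10)

    def test_reconstruction_explains_target_variance(self):
        """Projecting epochs whose summary map defined the basis and
        reconstructing through the pseudo-inverse retains >= var_target of
        the summary variance."""
        rng = np.random.default_rng(8)
        mat = rng.normal(size=(8, 100)) + 5 * np.outer(rng.normal(size=8), rng.normal(size=100))
        basis = preprocess.compute_component_basis({"eeg": mat}, var_target=0.95)
        w = basis.weights["eeg"]
        recon = w @ (w.T @ mat)
        explained = 1.0 - np.sum((mat - recon) ** 2) / np.sum(mat**2)
        assert explained >= 0.95

    def test_channel_mismatch_rejected(self):
        ep = preprocess.EpochSet(
            data=np.zeros((2, 4, 10)), times_ms=np.arange(10),
            labels=pd.DataFrame(index=range(2)),
            feature_families=np.array(["eeg"] * 4),
        )
        basis = preprocess.ComponentBasis(
            weights={"eeg": np.eye(3)}, retained_variance={"eeg": 1.0},
            channel_indices={"eeg": np.arange(3)},
        )
        with pytest.raises(ValueError):
            preprocess.apply_basis(
                preprocess.EpochSet(
                    data=np.zeros((2, 2, 10)), times_ms=np.arange(10),
                    labels=pd.DataFrame(index=range(2)),
                    feature_families=np.array(["eeg"] * 2),
                ),
                basis,
            )
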