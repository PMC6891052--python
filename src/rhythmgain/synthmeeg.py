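"""Synthetic sensor-level M/EEG generator with known ground truth.

The generator produces multichannel recordings at 1 kHz that carry the
statistical structure the analysis pipeline assumes:

* tone-evoked responses whose amplitude varies linearly with the tone's
  frequency rank on the log-spaced grid (a monotonic frequency code),
  peaking ~76 ms after tone onset;
* chord-evoked responses with identity-specific topographies;
* a 1 Hz component that is phase-locked to chord onsets in rhythmic blocks
  but has a random phase per trial in jittered blocks (equal power in both
  conditions, so condition differences appear in phase locking only);
* an optional multiplicative gain applied to tone-evoked responses in a
  configurable window of lags before the next chord, in one condition only
  (the "rhythmic gain boost" that decoding should recover);
* spatially mixed Gaussian sensor noise.

No head modelling or artifact simulation is attempted: the purpose is
parameter-recovery testing of the analysis chain, not biophysical realism.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stimgen import StimulusBlock

__all__ = [
    "SensorArray",
    "GroundTruth",
    "Recording",
    "make_sensor_array",
    "simulate_recording",
    "simulate_behavior",
]

FAMILIES = ("eeg", "mag", "grad")


@dataclass
class SensorArray:
    """Channel ids, families and 3-D positions (arbitrary units)."""

    ids: tuple[str, ...]
    families: np.ndarray  # str array, one of FAMILIES
    positions: np.ndarray  # (n_channels, 3)

    @property
    def n_channels(self) -> int:
        return len(self.ids)

    def family_indices(self, family: str) -> np.ndarray:
        return np.flatnonzero(self.families == family)


def make_sensor_array(
    n_eeg: int = 20, n_mag: int = 20, n_grad: int = 40, seed: int = 0
) -> SensorArray:
    """Quasi-regular sensor layout on a spherical cap (z > 0.4, unit radius).

    Channels sit on a jittered Fibonacci spiral, emulating the near-uniform
    spacing of real sensor helmets/caps, and are assigned to families in a
    seeded random order so every family spans the whole cap.
    """
    counts = dict(eeg=n_eeg, mag=n_mag, grad=n_grad)
    if any(c < 0 for c in counts.values()):
        raise ValueError("channel counts must be non-negative")
    total = sum(counts.values())
    if total == 0:
        raise ValueError("at least one channel family must be non-empty")
    rng = np.random.default_rng(seed)
    i = np.arange(total)
    z = 0.4 + 0.6 * (i + 0.5) / total
    golden = np.pi * (3.0 - np.sqrt(5.0))
    spacing = np.sqrt(2.0 * np.pi * 0.6 / total)  # cap area / channel
    theta = i * golden + rng.uniform(-0.1, 0.1, total) * spacing
    z = np.clip(z + rng.uniform(-0.05, 0.05, total) * spacing, 0.35, 0.999)
    r = np.sqrt(1.0 - z**2)
    positions = np.column_stack([r * np.cos(theta), r * np.sin(theta), z])
    positions = positions[rng.permutation(total)]
    ids, families = [], []
    for fam in FAMILIES:
        for k in range(counts[fam]):
            ids.append(f"{fam.upper()}{k + 1:03d}")
            families.append(fam)
    return SensorArray(ids=tuple(ids), families=np.asarray(families), positions=positions)


@dataclass
class GroundTruth:
    """Forward-model parameters; everything is in arbitrary sensor units.

    ``tone_topography_slope`` is the amplitude change per frequency rank of
    the rank-dependent part of the tone-evoked topography.  ``gain_boost``
    multiplies tone-evoked responses by (1 + boost) when the tone onset falls
    inside ``gain_window_ms`` (lag relative to the next chord onset) in the
    ``gain_condition`` only.
    """

    tone_amp: float = 1.0
    tone_topography_slope: float = 0.25
    evoked_latency_ms: float = 76.0
    evoked_width_ms: float = 12.0
    chord_amp: float = 1.5
    chord_identity_amp: float = 0.6
    chord_latency_ms: float = 125.0
    chord_width_ms: float = 15.0
    entrain_strength: dict = field(default_factory=lambda: {"rhythmic": 0.8, "jittered": 0.8})
    entrain_freq_hz: float = 1.0
    gain_boost: float = 5.0
    gain_window_ms: tuple[float, float] = (-100.0, -80.0)
    gain_condition: str = "rhythmic"
    noise_sd: float = 1.0
    spatial_mixing: float = 0.5
    pink_noise: bool = False
    behavior_accuracy: dict = field(default_factory=lambda: {"rhythmic": 0.72, "jittered": 0.69})
    rt_median_ms: float = 715.0
    rt_sigma: float = 0.2
    pattern_seed: int = 0

    def gain_envelope(self, lag_to_next_chord_ms: float, condition: str) -> float:
        """Multiplicative gain on a tone-evoked response (always > 0)."""
        if condition != self.gain_condition or not np.isfinite(lag_to_next_chord_ms):
            return 1.0
        lo, hi = self.gain_window_ms
        if lo <= lag_to_next_chord_ms <= hi:
            return 1.0 + self.gain_boost
        return 1.0

    def validate(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if any(v < 0 for v in self.entrain_strength.values()):
            raise ValueError("entrain_strength must be >= 0")
        if self.gain_boost <= -1.0:
            raise ValueError("gain envelope must stay positive")


@dataclass
class Recording:
    """Continuous multichannel recording plus its aligned event table.

    ``events`` uses recording time (``onset_ms`` includes the pre-roll).
    """

    data: np.ndarray  # (n_channels, n_samples)
    sfreq: float
    sensors: SensorArray
    events: pd.DataFrame
    condition: str

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_ms(self) -> float:
        return 1000.0 * self.n_samples / self.sfreq

    def copy(self) -> "Recording":
        return Recording(
            data=self.data.copy(), sfreq=self.sfreq, sensors=self.sensors,
            events=self.events.copy(), condition=self.condition,
        )

    def to_mne_raw(self):
        """Export as an :class:`mne.io.RawArray` (unit-scaled, convenience only)."""
        import mne

        type_map = {"eeg": "eeg", "mag": "mag", "grad": "grad"}
        info = mne.create_info(
            list(self.sensors.ids), self.sfreq,
            ch_types=[type_map[f] for f in self.sensors.families],
        )
        return mne.io.RawArray(self.data, info, verbose="error")


def _patterns(sensors: SensorArray, truth: GroundTruth) -> dict[str, np.ndarray]:
    """Fixed unit-norm topographies, deterministic in ``truth.pattern_seed``."""
    rng = np.random.default_rng(truth.pattern_seed)
    names = ["tone_base", "tone_mod", "chord_common", "chord_A", "chord_B", "entrain"]
    out = {}
    for name in names:
        v = rng.normal(size=sensors.n_channels)
        out[name] = v / np.linalg.norm(v) * np.sqrt(sensors.n_channels)
    return out


def _gauss_kernel(latency_ms: float, width_ms: float) -> np.ndarray:
    """Unit-peak Gaussian evoked kernel sampled at 1 kHz from t=0."""
    n = int(np.ceil(latency_ms + 4.0 * width_ms))
    t = np.arange(n, dtype=float)
    return np.exp(-0.5 * ((t - latency_ms) / width_ms) ** 2)


def simulate_recording(
    block: StimulusBlock,
    sensors: SensorArray,
    truth: GroundTruth,
    seed: int = 0,
    pre_roll_ms: int = 1500,
    post_roll_ms: int = 1500,
    n_bands: int = 15,
    sfreq: float = 1000.0,
) -> Recording:
    """Render one stimulus block into a continuous sensor-level recording."""
    truth.validate()
    if sfreq != 1000.0:
        raise ValueError("only 1 kHz simulation is supported")
    rng = np.random.default_rng(seed)
    pat = _patterns(sensors, truth)
    n_ch = sensors.n_channels
    n_samp = int(block.duration_ms) + pre_roll_ms + post_roll_ms + 1
    mid_rank = (n_bands - 1) / 2.0

    if truth.noise_sd > 0:
        noise = rng.normal(scale=truth.noise_sd, size=(n_ch, n_samp))
        if truth.pink_noise:
            noise = _pinkify(noise, rng)
        if truth.spatial_mixing > 0:
            mix = np.eye(n_ch) + truth.spatial_mixing * rng.normal(size=(n_ch, n_ch)) / np.sqrt(n_ch)
            mix /= np.linalg.norm(mix, axis=1, keepdims=True)
            data = mix @ noise
        else:
            data = noise
    else:
        data = np.zeros((n_ch, n_samp))

    tone_kernel = _gauss_kernel(truth.evoked_latency_ms, truth.evoked_width_ms)
    chord_kernel = _gauss_kernel(truth.chord_latency_ms, truth.chord_width_ms)

    for trial in block.trials:
        chord_onsets = np.array([c.onset_ms for c in trial.chords], dtype=float)
        # tone-evoked responses with pre-chord gain
        for tone in trial.tones:
            later = chord_onsets[chord_onsets > tone.onset_ms]
            # gain profile evaluated at the tone's temporal midpoint
            mid = tone.onset_ms + tone.duration_ms / 2.0
            lag = mid - later[0] if later.size else np.nan
            gain = truth.gain_envelope(lag, block.condition)
            topo = truth.tone_amp * pat["tone_base"] + (
                truth.tone_topography_slope * (tone.band - mid_rank) * pat["tone_mod"]
            )
            _add_response(data, topo * gain, tone_kernel, tone.onset_ms + pre_roll_ms)
        # chord-evoked responses
        for chord in trial.chords:
            topo = truth.chord_amp * pat["chord_common"] + truth.chord_identity_amp * (
                pat["chord_A"] if chord.identity == "A" else pat["chord_B"]
            )
            _add_response(data, topo, chord_kernel, chord.onset_ms + pre_roll_ms)
        # 1 Hz component spanning the trial: phase-locked to chord onsets in
        # rhythmic blocks, random phase per trial in jittered blocks
        strength = truth.entrain_strength.get(block.condition, 0.0)
        if strength > 0:
            t0 = int(trial.tones[0].onset_ms) + pre_roll_ms
            t1 = int(trial.target.onset_ms + trial.target.duration_ms) + pre_roll_ms
            t = np.arange(t0, min(t1, n_samp), dtype=float)
            phase0 = (
                0.0 if block.condition == "rhythmic" else rng.uniform(0.0, 2.0 * np.pi)
            )
            osc = np.cos(
                2.0 * np.pi * truth.entrain_freq_hz * (t - chord_onsets[0] - pre_roll_ms) / 1000.0
                + phase0
            )
            data[:, t0 : t0 + len(t)] += strength * np.outer(pat["entrain"], osc)

    events = block.events_frame()
    events["onset_ms"] = events["onset_ms"] + pre_roll_ms
    events["condition"] = block.condition
    return Recording(data=data, sfreq=sfreq, sensors=sensors, events=events, condition=block.condition)


def _add_response(data: np.ndarray, topo: np.ndarray, kernel: np.ndarray, onset_sample: int) -> None:
    stop = min(onset_sample + len(kernel), data.shape[1])
    if stop <= onset_sample:
        return
    data[:, onset_sample:stop] += np.outer(topo, kernel[: stop - onset_sample])


def _pinkify(noise: np.ndarray, rng) -> np.ndarray:
    """Shape white noise to a 1/f amplitude spectrum (variance preserved)."""
    spec = np.fft.rfft(noise, axis=1)
    freqs = np.fft.rfftfreq(noise.shape[1], d=1e-3)
    scale = np.ones_like(freqs)
    scale[1:] = 1.0 / np.sqrt(freqs[1:] / freqs[1])
    shaped = np.fft.irfft(spec * scale, n=noise.shape[1], axis=1)
    shaped *= noise.std() / shaped.std()
    return shaped


def simulate_behavior(block: StimulusBlock, truth: GroundTruth, seed: int = 0) -> pd.DataFrame:
    """Simulate button responses to the target chords of one block.

    Responses are correct with the condition's accuracy; reaction times are
    drawn from a lognormal law around ``rt_median_ms``.
    """
    acc = truth.behavior_accuracy[block.condition]
    if not (0.0 < acc <= 1.0):
        raise ValueError("behavioral accuracy must be in (0, 1]")
    rng = np.random.default_rng(seed)
    rows = []
    for trial in block.trials:
        target = trial.target
        correct = bool(rng.random() < acc)
        chosen = target.identity if correct else ("B" if target.identity == "A" else "A")
        rt = float(np.exp(rng.normal(np.log(truth.rt_median_ms), truth.rt_sigma)))
        rows.append(
            dict(
                trial=trial.index, condition=block.condition,
                true_identity=target.identity, chosen_identity=chosen,
                correct=correct, rt_ms=rt,
                preceding_isi_ms=target.preceding_isi_ms,
            )
        )
    return pd.DataFrame(rows)
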