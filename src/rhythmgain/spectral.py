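"""Time-frequency decomposition and phase locking around chord onsets.

Instantaneous phase and power of low-frequency activity (default
0.5-5 Hz) are estimated with a fixed-duration windowed complex sinusoid
(2000 ms taper per estimate, frequency-independent time resolution).  The
phase-locking value (PLV) is the magnitude of the across-trial mean unit
phasor: 1 for perfect phase alignment across trials, 0 for uniformly
distributed phases.  Only chords preceded AND followed by the canonical
1 s interval enter the phase analysis, so the stimulation immediately
around the analysed chords is physically identical across conditions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import EpochSet
from .stimgen import StimulusBlock

__all__ = [
    "TimeFrequencyMap",
    "morlet_transform",
    "compute_plv",
    "plv_map",
    "power_map",
    "select_plv_chords",
    "default_freqs",
    "default_times",
]


def default_freqs() -> np.ndarray:
    """0.5-5 Hz in 0.1 Hz steps (46 frequencies)."""
    return np.round(np.arange(0.5, 5.0 + 1e-9, 0.1), 10)


def default_times() -> np.ndarray:
    """-500..500 ms in 50 ms steps relative to chord onset."""
    return np.arange(-500, 501, 50)


@dataclass
class TimeFrequencyMap:
    coeffs: np.ndarray  # complex (n_trials, n_features, n_freqs, n_times)
    freqs_hz: np.ndarray
    times_ms: np.ndarray

    @property
    def phase(self) -> np.ndarray:
        return np.angle(self.coeffs)

    @property
    def power(self) -> np.ndarray:
        return np.abs(self.coeffs) ** 2


def _window_taper(n: int, kind: str) -> np.ndarray:
    if kind == "hann":
        return np.hanning(n)
    if kind == "gaussian":
        tau = np.arange(n) - (n - 1) / 2.0
        return np.exp(-0.5 * (tau / (n / 6.0)) ** 2)
    raise ValueError(f"unknown taper {kind!r}")


def morlet_transform(
    ep: EpochSet,
    freqs_hz=None,
    times_ms=None,
    window_ms: float = 2000.0,
    taper: str = "hann",
) -> TimeFrequencyMap:
    """Complex time-frequency coefficients with a fixed analysis window.

    Each estimate multiplies a ``window_ms``-long tapered complex sinusoid
    with the epoch segment centred on the requested time point, giving the
    same temporal resolution at every frequency.  Epochs must span every
    requested time point +/- half the window.
    """
    freqs = np.asarray(default_freqs() if freqs_hz is None else freqs_hz, dtype=float)
    times = np.asarray(default_times() if times_ms is None else times_ms, dtype=int)
    half = int(round(window_ms / 2.0))
    n_w = 2 * half + 1
    t_min, t_max = ep.times_ms[0], ep.times_ms[-1]
    if times.min() - half < t_min or times.max() + half > t_max:
        raise ValueError(
            "epochs do not span every requested time +/- half the analysis window"
        )
    tau = (np.arange(n_w) - half) / 1000.0  # seconds
    win = _window_taper(n_w, taper)
    bank = win[:, None] * np.exp(-2j * np.pi * freqs[None, :] * tau[:, None])
    norm = 2.0 / win.sum()
    n_ep, n_feat, _ = ep.data.shape
    coeffs = np.empty((n_ep, n_feat, len(freqs), len(times)), dtype=complex)
    for k, t in enumerate(times):
        i0 = int(np.searchsorted(ep.times_ms, t - half))
        seg = ep.data[:, :, i0 : i0 + n_w].reshape(n_ep * n_feat, n_w)
        coeffs[:, :, :, k] = (norm * (seg @ bank)).reshape(n_ep, n_feat, len(freqs))
    return TimeFrequencyMap(coeffs=coeffs, freqs_hz=freqs, times_ms=times)


def compute_plv(phases) -> float:
    """PLV of a set of single-trial phases: ``|mean(exp(i*phi))|``."""
    phases = np.asarray(phases, dtype=float)
    if phases.size < 2:
        raise ValueError("PLV needs at least 2 trials")
    if not np.all(np.isfinite(phases)):
        raise ValueError("phases must be finite")
    return float(np.abs(np.mean(np.exp(1j * phases))))


def plv_map(tfm: TimeFrequencyMap) -> np.ndarray:
    """Across-trial PLV per feature, frequency and time point."""
    if tfm.coeffs.shape[0] < 2:
        raise ValueError("PLV needs at least 2 trials")
    mag = np.abs(tfm.coeffs)
    phasors = np.divide(
        tfm.coeffs, mag, out=np.zeros_like(tfm.coeffs), where=mag > 0
    )
    return np.abs(phasors.mean(axis=0))


def power_map(tfm: TimeFrequencyMap) -> np.ndarray:
    """Across-trial mean power per feature, frequency and time point."""
    return tfm.power.mean(axis=0)


def select_plv_chords(events, isi_ms: float = 1000.0) -> pd.DataFrame:
    """Chord events preceded and followed by the canonical ISI.

    Accepts a :class:`~rhythmgain.stimgen.StimulusBlock` or an event table.
    The first chord of each trial (no preceding within-trial interval) and
    the trial-final target (no following interval) are excluded by
    construction of the event table.
    """
    if isinstance(events, StimulusBlock):
        events = events.events_frame()
    chords = events[events["event_kind"] == "chord"]
    sel = chords[
        (chords["preceding_isi_ms"] == isi_ms) & (chords["following_isi_ms"] == isi_ms)
    ]
    if len(sel) == 0:
        import warnings

        warnings.warn("no chords satisfy the PLV selection criteria", RuntimeWarning)
    return sel.reset_index(drop=True)
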