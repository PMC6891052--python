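"""Continuous-data conditioning, epoching, smoothing and SVD reduction.

The conditioning chain mirrors standard M/EEG practice: zero-phase
Butterworth filtering (high-pass 0.1 Hz, notch at the line frequency and
harmonics, low-pass 200 Hz), average-reference for the EEG family, epoching
around events, and a 20 ms moving-average smoother.  Dimensionality
reduction uses a per-channel-family singular value decomposition of a
summary channels-by-time matrix, retaining the smallest number of modes
that explains the requested variance fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .synthmeeg import Recording

__all__ = [
    "EpochSet",
    "ComponentBasis",
    "filter_continuous",
    "rereference_eeg",
    "epoch_events",
    "smooth_epochs",
    "compute_component_basis",
    "apply_basis",
]


@dataclass
class EpochSet:
    """Epochs x features x samples array with a per-epoch label table.

    ``features`` are channels for sensor-space epochs or components after
    :func:`apply_basis`.  The time axis is uniform at 1 ms resolution.
    """

    data: np.ndarray  # (n_epochs, n_features, n_times)
    times_ms: np.ndarray
    labels: pd.DataFrame
    feature_families: np.ndarray | None = None
    n_dropped: int = 0

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    def time_index(self, t_ms) -> np.ndarray:
        """Sample index (or indices) of time point(s) ``t_ms``."""
        idx = np.searchsorted(self.times_ms, np.atleast_1d(t_ms))
        if np.any(idx >= len(self.times_ms)) or np.any(self.times_ms[idx] != np.atleast_1d(t_ms)):
            raise ValueError("requested time not on the epoch time axis")
        return idx if np.ndim(t_ms) else int(idx[0])


def filter_continuous(
    rec: Recording,
    hp_hz: float = 0.1,
    notch_hz: float = 50.0,
    lp_hz: float = 200.0,
    notch_width_hz: float = 2.0,
    order: int = 5,
) -> Recording:
    """High-pass, notch (line frequency and harmonics) and low-pass filter.

    All filters are Butterworth designs of the given order applied
    forward-backward (zero phase); the output has the same length as the
    input.
    """
    nyq = rec.sfreq / 2.0
    if lp_hz >= nyq or hp_hz >= nyq:
        raise ValueError("filter cutoffs must be below the Nyquist frequency")
    out = rec.copy()
    # single precision avoids denormal slow paths in the near-DC high-pass;
    # filter precision is far below the simulated noise floor either way
    x = out.data.astype(np.float32)
    if hp_hz > 0:
        sos = signal.butter(order, hp_hz, btype="highpass", fs=rec.sfreq, output="sos")
        x = signal.sosfiltfilt(sos, x, axis=1)
    if notch_hz:
        f = notch_hz
        while f < min(lp_hz + notch_hz / 2.0, nyq - notch_width_hz):
            band = (f - notch_width_hz, f + notch_width_hz)
            sos = signal.butter(order, band, btype="bandstop", fs=rec.sfreq, output="sos")
            x = signal.sosfiltfilt(sos, x, axis=1)
            f += notch_hz
    if lp_hz:
        sos = signal.butter(order, lp_hz, btype="lowpass", fs=rec.sfreq, output="sos")
        x = signal.sosfiltfilt(sos, x, axis=1)
    out.data = np.ascontiguousarray(x, dtype=np.float64)
    return out


def rereference_eeg(rec: Recording) -> Recording:
    """Re-reference the EEG family to its instantaneous average.

    Magnetometer and gradiometer channels are left untouched.
    """
    eeg = rec.sensors.family_indices("eeg")
    if len(eeg) < 2:
        raise ValueError("average reference needs at least 2 EEG channels")
    out = rec.copy()
    out.data[eeg] -= out.data[eeg].mean(axis=0, keepdims=True)
    return out


def epoch_events(
    rec: Recording,
    onsets_ms,
    window_ms: tuple[float, float] = (-200.0, 400.0),
    labels: pd.DataFrame | None = None,
) -> EpochSet:
    """Cut epochs around event onsets; out-of-bounds events are dropped."""
    onsets = np.asarray(onsets_ms, dtype=int)
    t0, t1 = int(window_ms[0]), int(window_ms[1])
    times = np.arange(t0, t1 + 1)
    ok = (onsets + t0 >= 0) & (onsets + t1 < rec.n_samples)
    n_dropped = int((~ok).sum())
    kept = onsets[ok]
    if kept.size == 0:
        raise ValueError("no events remain inside the recording bounds")
    idx = kept[:, None] + times[None, :]
    data = rec.data[:, idx]  # (n_ch, n_epochs, n_times)
    data = np.ascontiguousarray(np.moveaxis(data, 0, 1))
    if labels is None:
        lab = pd.DataFrame({"onset_ms": kept})
    else:
        lab = labels.loc[np.asarray(ok)].reset_index(drop=True)
    return EpochSet(
        data=data, times_ms=times, labels=lab,
        feature_families=np.asarray(rec.sensors.families), n_dropped=n_dropped,
    )


def smooth_epochs(ep: EpochSet, window_ms: int = 20) -> EpochSet:
    """Centered moving average with a truncated (shrinking) window at edges."""
    w = int(window_ms)
    n_t = ep.data.shape[-1]
    if w < 1:
        raise ValueError("window must be at least 1 sample")
    if w > n_t:
        raise ValueError("smoothing window longer than the epoch")
    half_lo = w // 2
    half_hi = w - half_lo  # window covers [i - half_lo, i + half_hi)
    cs = np.concatenate(
        [np.zeros(ep.data.shape[:-1] + (1,)), np.cumsum(ep.data, axis=-1)], axis=-1
    )
    i = np.arange(n_t)
    lo = np.clip(i - half_lo, 0, n_t)
    hi = np.clip(i + half_hi, 0, n_t)
    smoothed = (cs[..., hi] - cs[..., lo]) / (hi - lo)
    return EpochSet(
        data=smoothed, times_ms=ep.times_ms.copy(), labels=ep.labels.copy(),
        feature_families=ep.feature_families, n_dropped=ep.n_dropped,
    )


@dataclass
class ComponentBasis:
    """Per-family orthonormal channel weights from an SVD of a summary map."""

    weights: dict[str, np.ndarray]  # family -> (n_channels_in_family, n_modes)
    retained_variance: dict[str, float]
    channel_indices: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def n_modes(self) -> dict[str, int]:
        return {fam: w.shape[1] for fam, w in self.weights.items()}

    @property
    def total_modes(self) -> int:
        return sum(w.shape[1] for w in self.weights.values())


def compute_component_basis(
    family_maps: dict[str, np.ndarray],
    var_target: float = 0.95,
    max_modes: int | None = None,
    channel_indices: dict[str, np.ndarray] | None = None,
    exact_modes: int | None = None,
) -> ComponentBasis:
    """SVD each family's channels-by-time summary map into principal modes.

    Retains the smallest mode count whose cumulative squared singular values
    reach ``var_target`` (optionally capped at ``max_modes``; the retained
    variance fraction is recorded either way).  ``exact_modes`` forces a
    fixed mode count per family, which keeps component spaces the same size
    across datasets (useful when stacking subjects).  Mode signs follow a
    fixed convention: the largest-magnitude weight of each mode is positive.
    """
    weights, retained = {}, {}
    for fam, mat in family_maps.items():
        mat = np.asarray(mat, dtype=float)
        if mat.ndim != 2 or mat.shape[1] < 2:
            raise ValueError(f"family {fam!r}: need a channels x time matrix")
        if not np.all(np.isfinite(mat)):
            raise ValueError(f"family {fam!r}: summary map contains non-finite values")
        u, s, _ = np.linalg.svd(mat, full_matrices=False)
        total = float(np.sum(s**2))
        if total == 0:
            raise ValueError(f"family {fam!r}: summary map has rank 0")
        frac = np.cumsum(s**2) / total
        if exact_modes is not None:
            k = min(exact_modes, len(s))
        else:
            k = int(np.searchsorted(frac, var_target) + 1)
            k = min(k, len(s))
            if max_modes is not None:
                k = min(k, max_modes)
        w = u[:, :k]
        # deterministic sign convention
        flip = np.sign(w[np.argmax(np.abs(w), axis=0), np.arange(k)])
        flip[flip == 0] = 1.0
        weights[fam] = w * flip
        retained[fam] = float(frac[k - 1])
    return ComponentBasis(
        weights=weights, retained_variance=retained,
        channel_indices=dict(channel_indices or {}),
    )


def apply_basis(ep: EpochSet, basis: ComponentBasis) -> EpochSet:
    """Project sensor-space epochs into the component space.

    Each family's channels are projected through its weight matrix; the
    component axes of all families are concatenated.
    """
    comps, fams = [], []
    for fam, w in basis.weights.items():
        idx = basis.channel_indices.get(fam)
        if idx is None:
            if ep.feature_families is None:
                raise ValueError("basis lacks channel indices and epochs lack families")
            idx = np.flatnonzero(ep.feature_families == fam)
        if len(idx) != w.shape[0] or (len(idx) and np.max(idx) >= ep.data.shape[1]):
            raise ValueError(
                f"family {fam!r}: basis channel set does not match the epochs"
            )
        comps.append(np.einsum("ck,ect->ekt", w, ep.data[:, idx, :]))
        fams += [fam] * w.shape[1]
    return EpochSet(
        data=np.concatenate(comps, axis=1),
        times_ms=ep.times_ms.copy(),
        labels=ep.labels.copy(),
        feature_families=np.asarray(fams),
        n_dropped=ep.n_dropped,
    )
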