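"""Mass-univariate encoding of tone frequency in sensor amplitude.

For every channel (or component) and time point, Spearman rank correlation
is computed between the per-band mean evoked amplitude and a contrast
vector over the 15-band frequency axis: a monotonic contrast (rank order of
frequency) or a quadratic one (extreme frequencies high, middle frequency
low).  The resulting maps are the basis-rationale analysis for the
multivariate decoding and provide the summary matrices from which the SVD
component basis is derived.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .preprocess import EpochSet

__all__ = ["EncodingMap", "contrast_vector", "band_average", "correlate_amplitude_frequency"]


@dataclass
class EncodingMap:
    rho: np.ndarray  # (n_features, n_times)
    contrast_kind: str
    degenerate: np.ndarray  # bool mask where amplitude had zero variance


def contrast_vector(kind: str, n_bands: int = 15) -> np.ndarray:
    """Frequency-axis contrast: 'monotonic' (increasing ranks) or
    'quadratic' (V-shape: extremes highest, middle band lowest)."""
    if kind == "monotonic":
        return np.arange(1, n_bands + 1, dtype=float)
    if kind == "quadratic":
        return np.abs(np.arange(n_bands, dtype=float) - (n_bands - 1) / 2.0)
    raise ValueError(f"unknown contrast kind {kind!r}")


def band_average(ep: EpochSet, n_bands: int = 15, band_column: str = "band") -> np.ndarray:
    """Per-band mean epoch: (n_bands, n_features, n_times); NaN if unseen."""
    bands = ep.labels[band_column].to_numpy()
    out = np.full((n_bands,) + ep.data.shape[1:], np.nan)
    for b in range(n_bands):
        mask = bands == b
        if mask.any():
            out[b] = ep.data[mask].mean(axis=0)
    return out


def correlate_amplitude_frequency(per_band_means: np.ndarray, contrast: np.ndarray) -> EncodingMap:
    """Spearman correlation of amplitude with the frequency contrast,
    independently per feature and time point.

    Zero-variance amplitude profiles get a coefficient of 0 and are flagged
    in ``degenerate``.
    """
    a = np.asarray(per_band_means, dtype=float)
    n_bands = a.shape[0]
    if len(contrast) != n_bands:
        raise ValueError("contrast length must match the number of bands")
    if np.isnan(a).any():
        raise ValueError("per-band means contain NaN (band missing from the data)")
    ar = rankdata(a, axis=0)
    cr = rankdata(np.asarray(contrast, dtype=float))
    ar_c = ar - ar.mean(axis=0)
    cr_c = (cr - cr.mean())[:, None, None]
    num = np.sum(ar_c * cr_c, axis=0)
    denom = np.sqrt(np.sum(ar_c**2, axis=0) * np.sum(cr_c**2))
    degenerate = denom == 0
    rho = np.zeros_like(num)
    np.divide(num, denom, out=rho, where=~degenerate)
    kind = "monotonic" if np.all(np.diff(contrast) > 0) else "quadratic"
    return EncodingMap(rho=rho, contrast_kind=kind, degenerate=degenerate)
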