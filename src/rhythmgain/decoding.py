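"""Mahalanobis-distance decoding of tone frequency and chord identity.

Tone decoding quantifies how well the 15 carrier frequencies can be told
apart from multi-component M/EEG amplitudes, separately for every lag
relative to chord onset: for each held-out trial, Mahalanobis distances to
the per-band mean patterns (means and shrinkage covariance estimated from
all other trials) are computed at a grid of response-latency offsets
(default 26-126 ms after the tone, in 5 ms steps) and the per-band minimum
across offsets is retained, accommodating frequency-dependent response
latencies.  Averaging the held-out distances by presented band yields a
15 x 15 distance matrix per lag, which is scored by Spearman correlation
against the ideal matrix of absolute carrier-frequency differences.

Chord decoding applies the identical scheme to the two chord identities
and reports the relative distance (other-identity minus same-identity),
positive when the evoked patterns discriminate the chords.

The covariance estimator is the analytic Ledoit-Wolf shrinkage toward a
scaled identity, recomputed exactly for every leave-one-out fold (the
whole fold family is evaluated in closed form, vectorised over held-out
trials).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .preprocess import EpochSet
from .stimgen import FrequencyGrid
from .synthmeeg import Recording

__all__ = [
    "DistanceMatrices",
    "ChordDecodingSeries",
    "shrinkage_covariance",
    "mahalanobis",
    "ideal_matrix",
    "tone_bands_at_lags",
    "decode_tone_frequency",
    "score_decoding",
    "score_series",
    "decode_chord",
    "default_lags",
    "default_response_window",
]


def default_lags() -> np.ndarray:
    """-500..500 ms relative to chord onset in 10 ms steps (101 lags)."""
    return np.arange(-500, 501, 10)


def default_response_window() -> np.ndarray:
    """Response-latency offsets 26..126 ms after tone onset in 5 ms steps."""
    return np.arange(26, 127, 5)


# ---------------------------------------------------------------------------
# shrinkage covariance and Mahalanobis distance
# ---------------------------------------------------------------------------


def shrinkage_covariance(training: np.ndarray) -> tuple[np.ndarray, float]:
    """Ledoit-Wolf shrinkage covariance toward a scaled identity.

    Returns ``(cov, shrinkage)`` where ``cov = (1 - s) * S + s * mu * I``,
    ``S`` the (biased, 1/n) sample covariance, ``mu = trace(S)/p`` and the
    shrinkage intensity ``s`` chosen by the analytic Ledoit-Wolf formula.
    The estimate is symmetric positive-definite whenever the data are not
    all identical.
    """
    X = np.asarray(training, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need at least 2 training trials")
    n, p = X.shape
    Y = X - X.mean(axis=0)
    S = Y.T @ Y / n
    mu = np.trace(S) / p
    d2 = np.sum((S - mu * np.eye(p)) ** 2) / p
    if d2 <= 0:
        return mu * np.eye(p) if mu > 0 else np.eye(p) * np.finfo(float).tiny, 1.0
    sq = np.sum(Y**2, axis=1)
    b_bar2 = (np.sum(sq**2) - n * np.sum(S**2)) / (n**2 * p)
    b2 = min(b_bar2, d2)
    s = b2 / d2
    return (1.0 - s) * S + s * mu * np.eye(p), float(s)


def mahalanobis(x: np.ndarray, mu: np.ndarray, cov: np.ndarray) -> float:
    """Covariance-whitened distance ``sqrt((x-mu)' C^-1 (x-mu))``."""
    d = np.asarray(x, dtype=float) - np.asarray(mu, dtype=float)
    from scipy.linalg import cho_factor, cho_solve

    try:
        c = cho_factor(cov)
    except np.linalg.LinAlgError as exc:  # pragma: no cover
        raise np.linalg.LinAlgError("covariance is not positive-definite") from exc
    return float(np.sqrt(max(d @ cho_solve(c, d), 0.0)))


def _loo_shrunk_covariances(X: np.ndarray) -> np.ndarray:
    """Exact Ledoit-Wolf shrinkage covariance of every leave-one-out fold.

    Returns an (n, p, p) array whose i-th slice is the shrunk covariance of
    ``X`` with row i removed; algebraically identical to calling
    :func:`shrinkage_covariance` on each fold, but vectorised.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n < 3:
        raise ValueError("need at least 3 trials for leave-one-out folds")
    m = n - 1
    s = X.sum(axis=0)
    G = X.T @ X
    means = (s[None, :] - X) / m  # (n, p)
    S = (G[None, :, :] - np.einsum("ip,iq->ipq", X, X)) / m - np.einsum(
        "ip,iq->ipq", means, means
    )
    mu = np.trace(S, axis1=1, axis2=2) / p
    normS2 = np.einsum("ipq,ipq->i", S, S)
    d2 = normS2 / p - mu**2
    # sum over retained trials j of ((x_j - mean_i) . (x_j - mean_i))^2
    r = np.sum(X**2, axis=1)
    cross = X @ means.T  # (j, i)
    D = r[:, None] - 2.0 * cross + np.sum(means**2, axis=1)[None, :]
    q = np.sum(D**2, axis=0) - np.diag(D) ** 2
    b_bar2 = (q - m * normS2) / (m**2 * p)
    with np.errstate(invalid="ignore", divide="ignore"):
        lam = np.where(d2 > 0, np.minimum(b_bar2, d2) / np.where(d2 > 0, d2, 1.0), 1.0)
    lam = np.clip(lam, 0.0, 1.0)
    eye = np.eye(p)
    covs = (1.0 - lam)[:, None, None] * S + (lam * mu)[:, None, None] * eye
    # guard against fully degenerate folds
    degen = mu <= 0
    if degen.any():
        covs[degen] += np.finfo(float).tiny * eye
    return covs


def _loo_class_distances(X: np.ndarray, y: np.ndarray, n_classes: int) -> np.ndarray:
    """Leave-one-out Mahalanobis distances of each trial to every class mean.

    For held-out trial i, class means exclude trial i and the covariance is
    the shrunk estimate from all trials but i.  Classes with no remaining
    training trial for a fold yield NaN.
    """
    n, p = X.shape
    sums = np.zeros((n_classes, p))
    counts = np.zeros(n_classes)
    np.add.at(sums, y, X)
    np.add.at(counts, y, 1.0)
    cnt = np.broadcast_to(counts, (n, n_classes)).copy()
    csums = np.broadcast_to(sums, (n, n_classes, p)).copy()
    rows = np.arange(n)
    cnt[rows, y] -= 1.0
    csums[rows, y] -= X
    with np.errstate(invalid="ignore", divide="ignore"):
        mus = csums / cnt[:, :, None]
    diffs = X[:, None, :] - mus  # (n, K, p); NaN where class missing
    covs = _loo_shrunk_covariances(X)
    finite = np.isfinite(diffs)
    solved = np.linalg.solve(covs, np.where(finite, diffs, 0.0).transpose(0, 2, 1))
    d2 = np.einsum("nkp,npk->nk", np.where(finite, diffs, 0.0), solved)
    d = np.sqrt(np.clip(d2, 0.0, None))
    d[~finite.all(axis=2)] = np.nan
    return d


# ---------------------------------------------------------------------------
# tone-frequency decoding
# ---------------------------------------------------------------------------


def ideal_matrix(grid: FrequencyGrid) -> np.ndarray:
    """Absolute carrier-frequency differences (Hz) between band pairs."""
    f = grid.carriers_hz
    return np.abs(f[:, None] - f[None, :])


def tone_bands_at_lags(rec: Recording, chord_onsets_ms, lags_ms) -> np.ndarray:
    """Band index of the tone active at each lag relative to each chord.

    Tones are gapless, so at most one tone spans any time point; samples
    inside chords (or outside the tone sequence) return -1.
    """
    timeline = np.full(rec.n_samples, -1, dtype=int)
    ev = rec.events
    tones = ev[ev["event_kind"] == "tone"]
    for onset, dur, band in zip(
        tones["onset_ms"].astype(int), tones["duration_ms"].astype(int), tones["band"].astype(int)
    ):
        timeline[onset : onset + dur] = band
    chords = ev[ev["event_kind"] == "chord"]
    for onset, dur in zip(chords["onset_ms"].astype(int), chords["duration_ms"].astype(int)):
        timeline[onset : onset + dur] = -1
    onsets = np.asarray(chord_onsets_ms, dtype=int)
    lags = np.asarray(lags_ms, dtype=int)
    idx = np.clip(onsets[:, None] + lags[None, :], 0, rec.n_samples - 1)
    return timeline[idx]


@dataclass
class DistanceMatrices:
    """Stack of per-lag mean distance matrices for one condition.

    ``matrices[l, i, j]`` is the mean distance of held-out trials whose
    presented band was ``i`` to the mean pattern of band ``j`` at lag
    ``lags_ms[l]``; NaN rows/columns mark bands absent at that lag.
    """

    lags_ms: np.ndarray
    matrices: np.ndarray  # (n_lags, n_bands, n_bands)
    n_trials: np.ndarray  # (n_lags, n_bands) held-out trial counts per row
    condition: str = ""

    def averaged(self, lag_window_ms: tuple[float, float]) -> np.ndarray:
        """Mean matrix over lags inside the (inclusive) window."""
        lo, hi = lag_window_ms
        sel = (self.lags_ms >= lo) & (self.lags_ms <= hi)
        if not sel.any():
            raise ValueError("no lags inside the requested window")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(self.matrices[sel], axis=0)


def decode_tone_frequency(
    ep: EpochSet,
    bands_at_lags: np.ndarray,
    lags_ms=None,
    response_window_ms=None,
    n_bands: int = 15,
    min_trials: int = 6,
    condition: str = "",
) -> DistanceMatrices:
    """Leave-one-out tone-frequency decoding per lag relative to chord onset.

    ``ep`` holds component-space epochs around the selected chords (those
    preceded by the canonical 1 s interval); ``bands_at_lags`` gives, per
    epoch and lag, the band of the tone active at that lag (-1 for none).
    """
    lags = np.asarray(default_lags() if lags_ms is None else lags_ms, dtype=int)
    offsets = np.asarray(
        default_response_window() if response_window_ms is None else response_window_ms, dtype=int
    )
    if bands_at_lags.shape != (ep.n_epochs, len(lags)):
        raise ValueError("bands_at_lags must be (n_epochs, n_lags)")
    needed = np.concatenate([lags + offsets[0], lags + offsets[-1]])
    if needed.min() < ep.times_ms[0] or needed.max() > ep.times_ms[-1]:
        raise ValueError("epoch window too short for the lag/offset grid")
    n_lags = len(lags)
    matrices = np.full((n_lags, n_bands, n_bands), np.nan)
    n_trials = np.zeros((n_lags, n_bands), dtype=int)
    for li, lag in enumerate(lags):
        y = bands_at_lags[:, li]
        valid = y >= 0
        if valid.sum() < max(min_trials, 3) or len(np.unique(y[valid])) < 2:
            continue
        yv = y[valid].astype(int)
        dists = np.full((len(offsets), valid.sum(), n_bands), np.nan)
        for oi, off in enumerate(offsets):
            t = int(np.searchsorted(ep.times_ms, lag + off))
            X = ep.data[valid, :, t]
            dists[oi] = _loo_class_distances(X, yv, n_bands)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            min_d = np.nanmin(dists, axis=0)  # (n_valid, n_bands)
            for b in range(n_bands):
                rows = yv == b
                if rows.any():
                    matrices[li, b] = np.nanmean(min_d[rows], axis=0)
                    n_trials[li, b] = int(rows.sum())
    return DistanceMatrices(lags_ms=lags, matrices=matrices, n_trials=n_trials, condition=condition)


def score_decoding(obs: np.ndarray, ideal: np.ndarray) -> float:
    """Spearman rho between an observed distance matrix and the ideal one.

    Missing (NaN) cells are pairwise-deleted; a constant observed matrix
    scores 0 by convention (degenerate input).
    """
    obs = np.asarray(obs, dtype=float).ravel()
    ide = np.asarray(ideal, dtype=float).ravel()
    if obs.shape != ide.shape:
        raise ValueError("matrices must have the same shape")
    mask = np.isfinite(obs) & np.isfinite(ide)
    if mask.sum() < 3:
        raise ValueError("fewer than 3 retained cell pairs; score undefined")
    if np.ptp(obs[mask]) == 0 or np.ptp(ide[mask]) == 0:
        return 0.0
    rho, _ = stats.spearmanr(obs[mask], ide[mask])
    return float(rho)


def score_series(dms: DistanceMatrices, ideal: np.ndarray) -> np.ndarray:
    """Decoding score per lag; NaN for lags without a distance matrix."""
    out = np.full(len(dms.lags_ms), np.nan)
    for li in range(len(dms.lags_ms)):
        mat = dms.matrices[li]
        if np.isfinite(mat).sum() >= 3:
            out[li] = score_decoding(mat, ideal)
    return out


# ---------------------------------------------------------------------------
# chord decoding
# ---------------------------------------------------------------------------


@dataclass
class ChordDecodingSeries:
    """Relative distance (other-identity minus same-identity) over time."""

    times_ms: np.ndarray
    relative_distance: np.ndarray
    condition: str = ""

    def averaged(self, window_ms: tuple[float, float]) -> float:
        lo, hi = window_ms
        sel = (self.times_ms >= lo) & (self.times_ms <= hi)
        return float(np.nanmean(self.relative_distance[sel]))


def decode_chord(
    ep: EpochSet,
    identities,
    times_ms=None,
    response_window_ms=None,
    condition: str = "",
) -> ChordDecodingSeries:
    """Leave-one-out chord-identity decoding over peri-chord time points.

    Uses the same windowed-minimum Mahalanobis scheme as tone decoding but
    with two classes (chord A vs B): for each held-out trial the minimum
    distance across response offsets to the same-identity and to the
    other-identity mean are subtracted and averaged across trials.
    """
    times = np.asarray(np.arange(-100, 401, 10) if times_ms is None else times_ms, dtype=int)
    offsets = np.asarray(
        default_response_window() if response_window_ms is None else response_window_ms, dtype=int
    )
    ids = np.asarray(identities)
    if ep.n_epochs != len(ids):
        raise ValueError("one identity label per epoch required")
    classes = np.unique(ids)
    if len(classes) < 2:
        raise ValueError("need trials of both chord identities")
    y = np.searchsorted(classes, ids)
    rel = np.full(len(times), np.nan)
    for ti, t in enumerate(times):
        dists = np.full((len(offsets), ep.n_epochs, 2), np.nan)
        for oi, off in enumerate(offsets):
            tp = t + off
            if tp < ep.times_ms[0] or tp > ep.times_ms[-1]:
                raise ValueError("epoch window too short for the time/offset grid")
            X = ep.data[:, :, int(np.searchsorted(ep.times_ms, tp))]
            dists[oi] = _loo_class_distances(X, y, 2)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            min_d = np.nanmin(dists, axis=0)  # (n_trials, 2)
        d_same = min_d[np.arange(ep.n_epochs), y]
        d_other = min_d[np.arange(ep.n_epochs), 1 - y]
        rel[ti] = float(np.nanmean(d_other - d_same))
    return ChordDecodingSeries(times_ms=times, relative_distance=rel, condition=condition)
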