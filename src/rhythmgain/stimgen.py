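"""Stimulus design for the auditory rhythmic-expectation paradigm.

The paradigm presents gapless sequences of brief pure tones (carriers drawn
from a log-spaced grid) interleaved with six-tone chords.  Chords come in two
identities (A/B) that share their member frequencies but differ in the
amplitudes of four "discriminant" tones.  Chords are either isochronous
(rhythmic condition, 1 s inter-stimulus interval) or temporally jittered.
A subset of chords is markedly longer and serves as the discrimination target.

This module generates the frequency grid, the per-listener chord assignment,
complete timed event sequences for whole blocks, the adaptive staircase used
to titrate chord discriminability, and (optionally) rendered audio.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FrequencyGrid",
    "ChordSpec",
    "BandClassMap",
    "ChordEvent",
    "ToneEvent",
    "Trial",
    "StimulusBlock",
    "BlockParams",
    "LogisticObserver",
    "build_frequency_grid",
    "assign_chord_frequencies",
    "generate_block",
    "staircase_calibrate",
    "render_audio",
    "write_wav",
]

#: durations (ms) used for pure tones and short chords
SHORT_DURATIONS_MS = (23, 28, 33, 38, 43)
#: duration (ms) of long target chords
TARGET_DURATION_MS = 165
#: rise/fall taper applied to every rendered stimulus (ms)
TAPER_MS = 5.0


@dataclass
class FrequencyGrid:
    """Logarithmically spaced carrier-frequency grid."""

    carriers_hz: np.ndarray
    f_min_hz: float
    span_octaves: float

    @property
    def n_bands(self) -> int:
        return len(self.carriers_hz)

    def __post_init__(self) -> None:
        self.carriers_hz = np.asarray(self.carriers_hz, dtype=float)


def build_frequency_grid(
    f_min_hz: float = 460.0, span_octaves: float = 2.0, n_bands: int = 15
) -> FrequencyGrid:
    """Build ``n_bands`` log-spaced carriers spanning ``span_octaves`` octaves.

    With the defaults this reproduces the 15-band, two-octave grid from
    460 to 1840 Hz used for both tones and chord members.
    """
    if not (np.isfinite(f_min_hz) and f_min_hz > 0):
        raise ValueError(f"f_min_hz must be positive and finite, got {f_min_hz}")
    if not (np.isfinite(span_octaves) and span_octaves > 0):
        raise ValueError(f"span_octaves must be positive, got {span_octaves}")
    if n_bands < 2:
        raise ValueError(f"n_bands must be >= 2, got {n_bands}")
    exponents = np.linspace(0.0, span_octaves, n_bands)
    carriers = f_min_hz * 2.0 ** exponents
    return FrequencyGrid(carriers_hz=carriers, f_min_hz=f_min_hz, span_octaves=span_octaves)


@dataclass
class ChordSpec:
    """Six-tone chord pair sharing members but differing in amplitude profile.

    Two member bands are "common" (identical amplitude in A and B); the four
    "discriminant" bands split into a pair louder in chord A and a pair louder
    in chord B.  The high-for-A pair is never entirely above or entirely below
    the high-for-B pair on the frequency axis, so the chords cannot be told
    apart by overall pitch.
    """

    member_band_indices: tuple[int, ...]
    common: tuple[int, int]
    high_for_a: tuple[int, int]
    high_for_b: tuple[int, int]
    amplitude_delta: float = 0.5
    #: amplitude of the common tones; ``None`` -> mean of the two
    #: discriminant amplitude levels
    common_amplitude: float | None = None

    @property
    def discriminant(self) -> tuple[int, ...]:
        return tuple(sorted(self.high_for_a + self.high_for_b))

    def amplitudes(self, identity: str) -> dict[int, float]:
        """Per-band amplitude profile for chord ``identity`` ('A' or 'B')."""
        if identity not in ("A", "B"):
            raise ValueError(f"identity must be 'A' or 'B', got {identity!r}")
        hi, lo = 1.0, 1.0 - self.amplitude_delta
        common_amp = self.common_amplitude
        if common_amp is None:
            common_amp = 0.5 * (hi + lo)
        high_pair = self.high_for_a if identity == "A" else self.high_for_b
        low_pair = self.high_for_b if identity == "A" else self.high_for_a
        amps = {b: common_amp for b in self.common}
        amps.update({b: hi for b in high_pair})
        amps.update({b: lo for b in low_pair})
        return amps


@dataclass
class BandClassMap:
    """Per-band functional class on the frequency grid.

    ``discriminant`` and ``common`` are chord members; non-member bands
    immediately neighbouring a discriminant band are ``adjacent``; all
    remaining non-members are ``distant``.
    """

    labels: tuple[str, ...]

    def indices(self, klass: str) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.labels) == klass)

    @property
    def classes(self) -> tuple[str, ...]:
        return ("discriminant", "adjacent", "distant", "common")


def assign_chord_frequencies(
    grid: FrequencyGrid, seed: int, amplitude_delta: float = 0.5
) -> tuple[ChordSpec, BandClassMap]:
    """Pseudorandomly assign chord member bands for one listener.

    Six of the grid bands become chord members (two common + four
    discriminant).  The discriminant bands are partitioned so that the pair
    louder in chord A interleaves with the pair louder in chord B.
    """
    if grid.n_bands < 8:
        raise ValueError("need at least 8 bands to assign chord frequencies")
    rng = np.random.default_rng(seed)
    for _ in range(1000):
        members = np.sort(rng.choice(grid.n_bands, size=6, replace=False))
        common = rng.choice(members, size=2, replace=False)
        disc = np.sort(np.setdiff1d(members, common))
        d1, d2, d3, d4 = (int(d) for d in disc)
        # interleaving partitions of the four discriminant bands
        pairings = [((d1, d3), (d2, d4)), ((d1, d4), (d2, d3))]
        pair_a, pair_b = pairings[rng.integers(2)]
        if rng.integers(2):
            pair_a, pair_b = pair_b, pair_a
        if _interleaved(pair_a, pair_b):
            break
    else:  # pragma: no cover - unreachable for sane grids
        raise RuntimeError("could not find a valid chord assignment")
    spec = ChordSpec(
        member_band_indices=tuple(int(m) for m in members),
        common=tuple(int(c) for c in np.sort(common)),
        high_for_a=pair_a,
        high_for_b=pair_b,
        amplitude_delta=amplitude_delta,
    )
    labels = ["distant"] * grid.n_bands
    for b in spec.discriminant:
        labels[b] = "discriminant"
    for b in spec.common:
        labels[b] = "common"
    member_set = set(spec.member_band_indices)
    for b in spec.discriminant:
        for nb in (b - 1, b + 1):
            if 0 <= nb < grid.n_bands and nb not in member_set:
                labels[nb] = "adjacent"
    return spec, BandClassMap(labels=tuple(labels))


def _interleaved(pair_a: tuple[int, int], pair_b: tuple[int, int]) -> bool:
    """True when neither pair lies entirely above or below the other."""
    a_lo, a_hi = min(pair_a), max(pair_a)
    b_lo, b_hi = min(pair_b), max(pair_b)
    both_higher = a_lo > b_hi
    both_lower = a_hi < b_lo
    return not (both_higher or both_lower)


# ---------------------------------------------------------------------------
# block generation
# ---------------------------------------------------------------------------


@dataclass
class ChordEvent:
    onset_ms: int
    duration_ms: int
    identity: str  # 'A' or 'B'
    kind: str  # 'short' or 'target'
    preceding_isi_ms: float  # NaN for the first chord of a trial
    following_isi_ms: float  # NaN for the target (trial-final) chord


@dataclass
class ToneEvent:
    onset_ms: int
    duration_ms: int
    band: int


@dataclass
class Trial:
    index: int
    chords: list[ChordEvent]
    tones: list[ToneEvent]

    @property
    def target(self) -> ChordEvent:
        return self.chords[-1]


@dataclass
class BlockParams:
    """Design constants of one block.

    The defaults match the full paradigm (60 targets and, in expectation,
    240 short chords per block); tests and desk-scale simulations override
    ``n_trials``.
    """

    n_trials: int = 60
    isi_ms: int = 1000
    jitter_low_ms: tuple[int, int] = (570, 908)
    jitter_high_ms: tuple[int, int] = (1092, 1430)
    short_durations_ms: tuple[int, ...] = SHORT_DURATIONS_MS
    target_duration_ms: int = TARGET_DURATION_MS
    n_short_range: tuple[int, int] = (3, 5)
    lead_in_ms: int = 1000
    tail_ms: int = 700
    intertrial_gap_ms: int = 600


@dataclass
class StimulusBlock:
    """One block of trials: timed chord events plus gapless tone fill."""

    condition: str
    trials: list[Trial]
    params: BlockParams
    seed: int

    def all_chords(self) -> list[ChordEvent]:
        return [c for t in self.trials for c in t.chords]

    def all_tones(self) -> list[ToneEvent]:
        return [t for tr in self.trials for t in tr.tones]

    @property
    def duration_ms(self) -> int:
        last = self.trials[-1]
        ends = [c.onset_ms + c.duration_ms for c in last.chords]
        ends += [t.onset_ms + t.duration_ms for t in last.tones]
        return max(ends)

    def events_frame(self) -> pd.DataFrame:
        """Long-format event table (chords and tones) for export/alignment."""
        rows = []
        for tr in self.trials:
            for c in tr.chords:
                rows.append(
                    dict(
                        trial=tr.index, event_kind="chord", onset_ms=c.onset_ms,
                        duration_ms=c.duration_ms, band=-1, identity=c.identity,
                        chord_kind=c.kind, preceding_isi_ms=c.preceding_isi_ms,
                        following_isi_ms=c.following_isi_ms,
                    )
                )
            for t in tr.tones:
                rows.append(
                    dict(
                        trial=tr.index, event_kind="tone", onset_ms=t.onset_ms,
                        duration_ms=t.duration_ms, band=t.band, identity="",
                        chord_kind="", preceding_isi_ms=np.nan,
                        following_isi_ms=np.nan,
                    )
                )
        return pd.DataFrame(rows).sort_values("onset_ms", ignore_index=True)

    def to_tsv(self, path) -> None:
        self.events_frame().to_csv(path, sep="\t", index=False)


def _draw_isis(condition: str, n_isis: int, params: BlockParams, rng) -> np.ndarray:
    """ISI pool for a whole block.

    Rhythmic blocks use the constant ISI.  Jittered blocks enforce the design
    proportions exactly per block (half constant, one quarter early, one
    quarter late) by shuffled assignment rather than independent coin flips.
    """
    if condition == "rhythmic":
        return np.full(n_isis, params.isi_ms, dtype=int)
    n_low = n_isis // 4
    n_high = n_isis // 4
    n_iso = n_isis - n_low - n_high
    isis = np.concatenate(
        [
            np.full(n_iso, params.isi_ms, dtype=int),
            rng.integers(params.jitter_low_ms[0], params.jitter_low_ms[1] + 1, n_low),
            rng.integers(params.jitter_high_ms[0], params.jitter_high_ms[1] + 1, n_high),
        ]
    )
    rng.shuffle(isis)
    return isis


def _fill_tones(start_ms: int, end_ms: int, params: BlockParams, rng, n_bands: int) -> list[ToneEvent]:
    """Tile [start, end) with gapless tones; the last tone is truncated."""
    tones: list[ToneEvent] = []
    t = start_ms
    durations = np.asarray(params.short_durations_ms)
    while t < end_ms:
        dur = int(rng.choice(durations))
        dur = min(dur, end_ms - t)
        tones.append(ToneEvent(onset_ms=t, duration_ms=dur, band=int(rng.integers(n_bands))))
        t += dur
    return tones


def generate_block(
    condition: str,
    chord_spec: ChordSpec,
    params: BlockParams | None = None,
    seed: int = 0,
    n_bands: int = 15,
) -> StimulusBlock:
    """Generate one block of timed trials for the given condition.

    Each trial is a lead-in of tones, three to five short chords, a long
    target chord, and a tone tail; tones tile every inter-chord interval
    without gaps or overlaps.
    """
    if condition not in ("rhythmic", "jittered"):
        raise ValueError(f"condition must be 'rhythmic' or 'jittered', got {condition!r}")
    params = params or BlockParams()
    max_chord = max(max(params.short_durations_ms), params.target_duration_ms)
    min_isi = params.isi_ms if condition == "rhythmic" else params.jitter_low_ms[0]
    if min_isi <= max(params.short_durations_ms):
        raise ValueError("ISI must exceed the longest short-chord duration")
    if params.n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)

    lo, hi = params.n_short_range
    n_short = rng.integers(lo, hi + 1, size=params.n_trials)
    isi_pool = _draw_isis(condition, int(n_short.sum()), params, rng)

    trials: list[Trial] = []
    t = 0
    isi_idx = 0
    for k in range(params.n_trials):
        n_chords = int(n_short[k]) + 1  # shorts + target
        isis = isi_pool[isi_idx : isi_idx + n_chords - 1]
        isi_idx += n_chords - 1
        onset = t + params.lead_in_ms
        chords: list[ChordEvent] = []
        for j in range(n_chords):
            is_target = j == n_chords - 1
            dur = params.target_duration_ms if is_target else int(rng.choice(params.short_durations_ms))
            chords.append(
                ChordEvent(
                    onset_ms=onset,
                    duration_ms=dur,
                    identity="A" if rng.integers(2) else "B",
                    kind="target" if is_target else "short",
                    preceding_isi_ms=float(isis[j - 1]) if j > 0 else np.nan,
                    following_isi_ms=float(isis[j]) if j < n_chords - 1 else np.nan,
                )
            )
            if j < n_chords - 1:
                onset += int(isis[j])
        tones: list[ToneEvent] = []
        tones += _fill_tones(t, chords[0].onset_ms, params, rng, n_bands)
        for j in range(n_chords - 1):
            gap_start = chords[j].onset_ms + chords[j].duration_ms
            tones += _fill_tones(gap_start, chords[j + 1].onset_ms, params, rng, n_bands)
        target_end = chords[-1].onset_ms + chords[-1].duration_ms
        tones += _fill_tones(target_end, target_end + params.tail_ms, params, rng, n_bands)
        trials.append(Trial(index=k, chords=chords, tones=tones))
        t = target_end + params.tail_ms + params.intertrial_gap_ms
    return StimulusBlock(condition=condition, trials=trials, params=params, seed=seed)


# ---------------------------------------------------------------------------
# staircase
# ---------------------------------------------------------------------------


@dataclass
class LogisticObserver:
    """Simulated observer: P(correct) as a logistic function of the
    discriminant-amplitude difference, with a 50% guess floor."""

    threshold: float = 0.3
    slope: float = 0.1
    guess_rate: float = 0.5
    lapse_rate: float = 0.0

    def __call__(self, amplitude_delta: float) -> float:
        from scipy.special import expit

        upper = 1.0 - self.guess_rate - self.lapse_rate
        return self.guess_rate + upper * expit((amplitude_delta - self.threshold) / self.slope)


def staircase_calibrate(
    observer,
    n_trials: int = 400,
    seed: int = 0,
    initial_delta: float = 0.6,
    initial_step: float = 0.1,
    step_floor: float = 0.01,
    delta_bounds: tuple[float, float] = (0.01, 1.0),
    n_avg_reversals: int = 60,
) -> float:
    """One-up-two-down adaptive staircase with a halving step size.

    The stimulus level (discriminant amplitude difference) is lowered after
    two consecutive correct responses and raised after each error, so the
    procedure converges on the level where p(correct)**2 = 0.5, i.e.
    ~70.7% accuracy.  The step size is halved at every reversal down to a
    floor of 1% amplitude.  Returns the mean of the final reversal levels
    (at most ``n_avg_reversals``, trimmed to an even count so peaks and
    troughs of the staircase oscillation balance).
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)
    delta = float(initial_delta)
    step = float(initial_step)
    lo, hi = delta_bounds
    n_correct_streak = 0
    last_direction = 0  # -1 going down, +1 going up
    reversals: list[float] = []
    for _ in range(n_trials):
        p = float(observer(delta))
        correct = rng.random() < p
        direction = 0
        if correct:
            n_correct_streak += 1
            if n_correct_streak >= 2:
                direction = -1
                n_correct_streak = 0
        else:
            n_correct_streak = 0
            direction = +1
        if direction != 0:
            if last_direction != 0 and direction != last_direction:
                reversals.append(delta)
                step = max(step / 2.0, step_floor)
            last_direction = direction
            delta = float(np.clip(delta + direction * step, lo, hi))
    if len(reversals) < 4:
        warnings.warn(
            f"staircase did not converge ({len(reversals)} reversals); "
            "returning last level",
            RuntimeWarning,
        )
        return delta
    tail = reversals[-n_avg_reversals:]
    if len(tail) % 2:
        tail = tail[1:]
    return float(np.mean(tail))


# ---------------------------------------------------------------------------
# audio rendering
# ---------------------------------------------------------------------------


def _taper(n_samples: int, ramp_samples: int) -> np.ndarray:
    """Hanning-flank onset/offset taper of total length ``n_samples``."""
    env = np.ones(n_samples)
    ramp = min(ramp_samples, n_samples // 2)
    if ramp > 0:
        flank = 0.5 * (1.0 - np.cos(np.pi * np.arange(ramp) / ramp))
        env[:ramp] = flank
        env[-ramp:] = flank[::-1]
    return env


def _render_stimulus(freqs_hz, amps, duration_ms: float, sr: float) -> np.ndarray:
    n = int(round(duration_ms * sr / 1000.0))
    t = np.arange(n) / sr
    y = np.zeros(n)
    for f, a in zip(np.atleast_1d(freqs_hz), np.atleast_1d(amps)):
        y += a * np.sin(2.0 * np.pi * f * t)
    y *= _taper(n, int(round(TAPER_MS * sr / 1000.0)))
    rms = np.sqrt(np.mean(y**2))
    if rms > 0:
        y /= rms
    return y


def render_audio(
    block: StimulusBlock,
    grid: FrequencyGrid,
    chord_spec: ChordSpec | None = None,
    sample_rate: float = 48000.0,
    level: float = 0.05,
) -> np.ndarray:
    """Render a block to a mono waveform.

    Every tone and chord is Hanning-tapered over 5 ms rise/fall and scaled
    by a loudness normalizer (equal RMS over its duration), keeping the
    perceived level constant across the sequence.
    """
    if sample_rate < 2.0 * float(np.max(grid.carriers_hz)):
        raise ValueError("sample_rate too low for the carrier grid (aliasing)")
    if not block.trials:
        return np.zeros(0)
    n_total = int(np.ceil(block.duration_ms * sample_rate / 1000.0)) + 1
    wave = np.zeros(n_total)
    for tone in block.all_tones():
        if tone.duration_ms <= 0:
            continue
        y = _render_stimulus(grid.carriers_hz[tone.band], 1.0, tone.duration_ms, sample_rate)
        i0 = int(round(tone.onset_ms * sample_rate / 1000.0))
        wave[i0 : i0 + len(y)] += y
    for chord in block.all_chords():
        if chord_spec is None:
            continue
        amps = chord_spec.amplitudes(chord.identity)
        bands = sorted(amps)
        y = _render_stimulus(
            grid.carriers_hz[bands], [amps[b] for b in bands], chord.duration_ms, sample_rate
        )
        i0 = int(round(chord.onset_ms * sample_rate / 1000.0))
        wave[i0 : i0 + len(y)] += y
    return level * wave


def write_wav(path, waveform: np.ndarray, sample_rate: int = 48000) -> None:
    """Write a waveform as 16-bit PCM."""
    from scipy.io import wavfile

    peak = np.max(np.abs(waveform)) if waveform.size else 0.0
    scaled = waveform / peak * 0.95 if peak > 0 else waveform
    wavfile.write(path, int(sample_rate), (scaled * 32767).astype(np.int16))
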