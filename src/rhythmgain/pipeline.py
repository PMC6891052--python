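"""End-to-end orchestration: simulate, preprocess, analyse, assemble.

A :class:`RunConfig` fixes every design constant and every seed of a
virtual experiment.  :func:`run_subject` produces one virtual
participant's complete single-subject results (behavior, encoding maps,
PLV/power maps, tone and chord decoding, tuning-model fits);
:func:`run_experiment` loops over participants and runs the group-level
inference (cluster permutation tests of condition contrasts, Bayesian
model selection over the gain/tuning model space, the 2 x 4 frequency-class
ANOVA, and cross-measure correlations).

All randomness derives from the master seed through named seed streams,
so a finished run is bit-reproducible.
"""

from __future__ import annotations

import hashlib
import json
import warnings
import zlib
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd

from . import behavior, decoding, encoding, preprocess, spectral, statkit, stimgen, synthmeeg, tuningmodel
from .preprocess import EpochSet

__all__ = ["RunConfig", "SubjectResult", "ExperimentResult", "run_subject", "run_experiment", "equalize_samples"]

FAMILIES = ("eeg", "mag", "grad")
CLASS_ORDER = ("discriminant", "adjacent", "distant", "common")


@dataclass
class RunConfig:
    """All design constants, ground-truth parameters and analysis settings.

    The default configuration is desk-scale: it preserves the structure of
    the full design (three channel families, a 2:1 jittered:rhythmic block
    ratio so both conditions contribute similar numbers of 1 s-preceded
    chords, the full lag range) at a fraction of the computational cost.
    ``paper_scale`` restores the full trial counts and grids.
    """

    master_seed: int = 0
    n_subjects: int = 8
    n_rhythmic_blocks: int = 1
    n_jittered_blocks: int = 2
    trials_per_block: int = 12
    n_eeg: int = 14
    n_mag: int = 14
    n_grad: int = 20
    amplitude_delta: float = 0.5
    truth: synthmeeg.GroundTruth = field(default_factory=synthmeeg.GroundTruth)
    # analysis settings
    lag_step_ms: int = 20
    lag_range_ms: tuple[int, int] = (-500, 500)
    response_window_ms: tuple[int, int, int] = (26, 126, 20)
    fit_window_ms: tuple[int, int] = (-100, -80)
    chord_times_ms: tuple[int, int, int] = (-100, 400, 20)
    chord_window_ms: tuple[int, int] = (115, 136)
    plv_freqs_hz: tuple[float, float, float] = (0.5, 3.0, 0.5)
    plv_times_ms: tuple[int, int, int] = (-200, 200, 100)
    encoding_window_ms: tuple[int, int] = (-200, 400)
    smoothing_ms: int = 20
    var_target: float = 0.95
    max_modes: int | None = 6
    decode_smoothing_ms: int = 20
    n_perm: int = 1000
    alpha: float = 0.05

    @classmethod
    def paper_scale(cls, **overrides) -> "RunConfig":
        """Full-size design: 22 subjects, 60-trial blocks, 3/6 blocks,
        10 ms lag grid, 5 ms response offsets, full PLV grids."""
        base = dict(
            n_subjects=22, n_rhythmic_blocks=3, n_jittered_blocks=6,
            trials_per_block=60, n_eeg=60, n_mag=102, n_grad=204,
            lag_step_ms=10, response_window_ms=(26, 126, 5),
            chord_times_ms=(-100, 400, 10),
            plv_freqs_hz=(0.5, 5.0, 0.1), plv_times_ms=(-500, 500, 50),
            max_modes=None,
        )
        base.update(overrides)
        return cls(**base)

    def lags(self) -> np.ndarray:
        lo, hi = self.lag_range_ms
        return np.arange(lo, hi + 1, self.lag_step_ms)

    def response_offsets(self) -> np.ndarray:
        lo, hi, step = self.response_window_ms
        return np.arange(lo, hi + 1, step)

    def chord_times(self) -> np.ndarray:
        lo, hi, step = self.chord_times_ms
        return np.arange(lo, hi + 1, step)

    def plv_freqs(self) -> np.ndarray:
        lo, hi, step = self.plv_freqs_hz
        return np.round(np.arange(lo, hi + 1e-9, step), 10)

    def plv_times(self) -> np.ndarray:
        lo, hi, step = self.plv_times_ms
        return np.arange(lo, hi + 1, step)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def stage_seed(master_seed: int, subject: int, stage: str, extra: int = 0) -> int:
    """Deterministic per-stage seed derived from the master seed."""
    ss = np.random.SeedSequence(
        [master_seed % 2**32, subject % 2**32, zlib.crc32(stage.encode()), extra % 2**32]
    )
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


# ---------------------------------------------------------------------------
# single-subject pipeline
# ---------------------------------------------------------------------------


@dataclass
class SubjectResult:
    subject: int
    chord_spec: stimgen.ChordSpec
    band_classes: stimgen.BandClassMap
    lags_ms: np.ndarray
    score_series: dict  # condition -> per-lag decoding score
    distance_matrices: dict  # condition -> decoding.DistanceMatrices
    chord_series: dict  # condition -> decoding.ChordDecodingSeries
    plv: dict  # condition -> (features, freqs, times)
    power: dict
    plv_freqs_hz: np.ndarray
    plv_times_ms: np.ndarray
    encoding_summary: dict  # (contrast, family) -> time series
    encoding_times_ms: np.ndarray
    behavior_summaries: dict  # condition -> BehavioralSummary
    tuning_fits: dict  # condition -> TuningModelFit (full model)
    avg_matrix: np.ndarray  # condition-averaged distance matrix in fit window
    class_fits: dict  # condition -> {class -> TuningModelFit}
    basis_modes: dict


def _concat_epochs(sets: list[EpochSet]) -> EpochSet:
    if len(sets) == 1:
        return sets[0]
    return EpochSet(
        data=np.concatenate([s.data for s in sets], axis=0),
        times_ms=sets[0].times_ms,
        labels=pd.concat([s.labels for s in sets], ignore_index=True),
        feature_families=sets[0].feature_families,
        n_dropped=sum(s.n_dropped for s in sets),
    )


def _band_evoked_means(recs, window_ms, n_bands: int = 15) -> np.ndarray:
    """Per-band mean tone-evoked epoch pooled over recordings."""
    t0, t1 = int(window_ms[0]), int(window_ms[1])
    times = np.arange(t0, t1 + 1)
    n_ch = recs[0].data.shape[0]
    sums = np.zeros((n_bands, n_ch, len(times)))
    counts = np.zeros(n_bands)
    for rec in recs:
        ev = rec.events
        tones = ev[ev["event_kind"] == "tone"]
        onsets_all = tones["onset_ms"].to_numpy(dtype=int)
        bands_all = tones["band"].to_numpy(dtype=int)
        ok = (onsets_all + t0 >= 0) & (onsets_all + t1 < rec.n_samples)
        onsets_all, bands_all = onsets_all[ok], bands_all[ok]
        for b in range(n_bands):
            onsets = onsets_all[bands_all == b]
            if onsets.size == 0:
                continue
            idx = onsets[:, None] + times[None, :]
            sums[b] += rec.data[:, idx].sum(axis=1)
            counts[b] += onsets.size
    if np.any(counts == 0):
        raise ValueError("some frequency bands were never presented")
    return sums / counts[:, None, None]


def run_subject(config: RunConfig, subject: int) -> SubjectResult:
    """Simulate and analyse one virtual participant."""
    seed = lambda stage, extra=0: stage_seed(config.master_seed, subject, stage, extra)
    grid = stimgen.build_frequency_grid()
    chord_spec, classes = stimgen.assign_chord_frequencies(
        grid, seed("chords"), amplitude_delta=config.amplitude_delta
    )
    sensors = synthmeeg.make_sensor_array(
        config.n_eeg, config.n_mag, config.n_grad, seed=seed("sensors")
    )
    truth = replace(config.truth, pattern_seed=seed("patterns"))
    params = stimgen.BlockParams(n_trials=config.trials_per_block)

    recs, behav_frames = [], []
    block_specs = [("rhythmic", i) for i in range(config.n_rhythmic_blocks)] + [
        ("jittered", i) for i in range(config.n_jittered_blocks)
    ]
    for cond, i in block_specs:
        block = stimgen.generate_block(
            cond, chord_spec, params=params, seed=seed(f"block_{cond}", i)
        )
        rec = synthmeeg.simulate_recording(
            block, sensors, truth, seed=seed(f"recording_{cond}", i)
        )
        rec = preprocess.rereference_eeg(preprocess.filter_continuous(rec))
        recs.append(rec)
        behav_frames.append(synthmeeg.simulate_behavior(block, truth, seed=seed(f"behavior_{cond}", i)))

    # --- encoding maps and component basis -------------------------------
    band_means = _band_evoked_means(recs, config.encoding_window_ms)
    enc_times = np.arange(config.encoding_window_ms[0], config.encoding_window_ms[1] + 1)
    band_ep = EpochSet(
        data=band_means, times_ms=enc_times,
        labels=pd.DataFrame({"band": np.arange(band_means.shape[0])}),
    )
    band_means_sm = preprocess.smooth_epochs(band_ep, config.smoothing_ms).data
    family_maps, channel_indices = {}, {}
    enc_summary = {}
    for contrast_kind in ("monotonic", "quadratic"):
        contrast = encoding.contrast_vector(contrast_kind, band_means.shape[0])
        enc_map = encoding.correlate_amplitude_frequency(band_means_sm, contrast)
        for fam in FAMILIES:
            idx = sensors.family_indices(fam)
            if idx.size == 0:
                continue
            if contrast_kind == "monotonic":
                family_maps[fam] = enc_map.rho[idx]
                channel_indices[fam] = idx
    # a fixed mode count per family keeps component spaces comparable
    # across virtual subjects (group maps stack components positionally)
    basis = preprocess.compute_component_basis(
        family_maps, var_target=config.var_target,
        channel_indices=channel_indices, exact_modes=config.max_modes,
    )
    # component-summarised encoding series (per contrast and family)
    for contrast_kind in ("monotonic", "quadratic"):
        contrast = encoding.contrast_vector(contrast_kind, band_means.shape[0])
        enc_map = encoding.correlate_amplitude_frequency(band_means_sm, contrast)
        for fam in FAMILIES:
            idx = channel_indices.get(fam)
            if idx is None:
                continue
            proj = basis.weights[fam].T @ enc_map.rho[idx]
            enc_summary[(contrast_kind, fam)] = proj.mean(axis=0)

    # --- epoch selected chords in component space ------------------------
    lags = config.lags()
    offsets = config.response_offsets()
    decode_window = (int(lags[0]), int(lags[-1] + offsets[-1] + 4))
    tone_sets = {c: [] for c in ("rhythmic", "jittered")}
    band_maps = {c: [] for c in ("rhythmic", "jittered")}
    plv_sets = {c: [] for c in ("rhythmic", "jittered")}
    plv_times = config.plv_times()
    plv_halfwin = 1000
    plv_window = (int(plv_times[0] - plv_halfwin), int(plv_times[-1] + plv_halfwin))
    for rec in recs:
        ev = rec.events
        chords = ev[
            (ev["event_kind"] == "chord")
            & (ev["chord_kind"] == "short")
            & (ev["preceding_isi_ms"] == 1000.0)
        ]
        onsets = chords["onset_ms"].to_numpy(dtype=int)
        ep = preprocess.epoch_events(rec, onsets, decode_window, labels=chords.reset_index(drop=True))
        ep = preprocess.apply_basis(ep, basis)
        if config.decode_smoothing_ms:
            # light temporal smoothing of the single-trial component series
            # stabilises the windowed-minimum distance estimates
            ep = preprocess.smooth_epochs(ep, config.decode_smoothing_ms)
        tone_sets[rec.condition].append(ep)
        band_maps[rec.condition].append(decoding.tone_bands_at_lags(rec, onsets, lags))
        plv_chords = spectral.select_plv_chords(ev)
        ep_plv = preprocess.epoch_events(
            rec, plv_chords["onset_ms"].to_numpy(dtype=int), plv_window, labels=plv_chords
        )
        plv_sets[rec.condition].append(preprocess.apply_basis(ep_plv, basis))

    ideal = decoding.ideal_matrix(grid)
    score_series, dist_mats, chord_series = {}, {}, {}
    plv_maps, power_maps = {}, {}
    tuning_fits, class_fits = {}, {}
    cond_mats, tfms = [], {}
    for cond in ("rhythmic", "jittered"):
        ep = _concat_epochs(tone_sets[cond])
        bands_at = np.concatenate(band_maps[cond], axis=0)
        dms = decoding.decode_tone_frequency(
            ep, bands_at, lags_ms=lags, response_window_ms=offsets, condition=cond
        )
        dist_mats[cond] = dms
        score_series[cond] = decoding.score_series(dms, ideal)
        chord_series[cond] = decoding.decode_chord(
            ep, ep.labels["identity"].to_numpy(), times_ms=config.chord_times(),
            response_window_ms=offsets, condition=cond,
        )
        ep_plv = _concat_epochs(plv_sets[cond])
        tfms[cond] = spectral.morlet_transform(
            ep_plv, freqs_hz=config.plv_freqs(), times_ms=plv_times, window_ms=2 * plv_halfwin
        )
        cond_mats.append(dms.averaged(config.fit_window_ms))

    # PLV is positively biased by ~1/sqrt(N trials): equalise trial counts
    # across conditions (seeded random subsample) so that the condition
    # difference of PLV maps is unbiased under a null ground truth
    n_common = min(t.coeffs.shape[0] for t in tfms.values())
    sub_rng = np.random.default_rng(seed("plv_subsample"))
    for cond, tfm in tfms.items():
        if tfm.coeffs.shape[0] > n_common:
            keep = np.sort(sub_rng.choice(tfm.coeffs.shape[0], n_common, replace=False))
            tfm = spectral.TimeFrequencyMap(
                coeffs=tfm.coeffs[keep], freqs_hz=tfm.freqs_hz, times_ms=tfm.times_ms
            )
        plv_maps[cond] = spectral.plv_map(tfm)
        power_maps[cond] = spectral.power_map(tfm)

    # common starting point from the condition-averaged matrix, so the two
    # condition fits are directly comparable
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        subject_avg = np.nanmean(np.stack(cond_mats), axis=0)
    start = tuningmodel.fit_model(subject_avg).params
    for cond, avg in zip(("rhythmic", "jittered"), cond_mats):
        tuning_fits[cond] = tuningmodel.fit_model(avg, start=start)
        class_fits[cond] = tuningmodel.fit_by_frequency_class(avg, classes, start=start)

    behav = pd.concat(behav_frames, ignore_index=True)
    behavior_summaries = {
        cond: behavior.summarize_condition(behav, cond) for cond in ("rhythmic", "jittered")
    }
    return SubjectResult(
        subject=subject, chord_spec=chord_spec, band_classes=classes, lags_ms=lags,
        score_series=score_series, distance_matrices=dist_mats, chord_series=chord_series,
        plv=plv_maps, power=power_maps, plv_freqs_hz=config.plv_freqs(),
        plv_times_ms=plv_times, encoding_summary=enc_summary, encoding_times_ms=enc_times,
        behavior_summaries=behavior_summaries, tuning_fits=tuning_fits,
        avg_matrix=subject_avg, class_fits=class_fits,
        basis_modes=basis.n_modes,
    )


# ---------------------------------------------------------------------------
# group-level assembly
# ---------------------------------------------------------------------------


@dataclass
class ExperimentResult:
    config: RunConfig
    subjects: list
    behavior_table: pd.DataFrame
    behavior_contrast: pd.DataFrame
    encoding_tests: dict  # (contrast, family) -> ClusterResult
    decoding_contrast: statkit.ClusterResult
    decoding_valid_lags: np.ndarray
    chord_contrast: statkit.ClusterResult
    plv_contrast: statkit.ClusterResult
    power_contrast: statkit.ClusterResult
    bms: tuningmodel.BmsResult
    model_names: list
    parameter_tests: pd.DataFrame
    class_anova: statkit.AnovaResult
    correlations: pd.DataFrame
    manifest: dict

    def save(self, out_dir) -> None:
        """Write the tabular results and the manifest as plain text."""
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.behavior_table.to_csv(out / "behavior.tsv", sep="\t", index=False)
        self.behavior_contrast.to_csv(out / "behavior_contrast.tsv", sep="\t", index=False)
        self.parameter_tests.to_csv(out / "parameter_tests.tsv", sep="\t", index=False)
        self.correlations.to_csv(out / "correlations.tsv", sep="\t", index=False)
        rows = []
        for s in self.subjects:
            for cond, series in s.score_series.items():
                for lag, rho in zip(s.lags_ms, series):
                    rows.append(dict(subject=s.subject, condition=cond, lag_ms=int(lag), rho=rho))
        pd.DataFrame(rows).to_csv(out / "decoding_scores.tsv", sep="\t", index=False)
        with open(out / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=2, default=str)


def equalize_samples(blocks_by_condition: dict, isi_ms: float = 1000.0) -> dict:
    """Retain only the chords preceded by the canonical ISI per condition.

    With the 2:1 jittered:rhythmic block ratio (where only half of the
    jittered intervals equal 1 s) the retained counts are approximately
    equal across conditions by design.
    """
    out = {}
    for cond, blocks in blocks_by_condition.items():
        if not blocks:
            raise ValueError(f"no blocks for condition {cond!r}")
        frames = []
        for b in blocks:
            ev = b.events_frame() if isinstance(b, stimgen.StimulusBlock) else b
            chords = ev[(ev["event_kind"] == "chord") & (ev["preceding_isi_ms"] == isi_ms)]
            frames.append(chords)
        sel = pd.concat(frames, ignore_index=True)
        if len(sel) == 0:
            raise ValueError(f"no chords preceded by {isi_ms} ms in condition {cond!r}")
        out[cond] = sel
    if not out:
        raise ValueError("no conditions supplied")
    return out


def run_experiment(config: RunConfig) -> ExperimentResult:
    """Run the full virtual experiment and group-level inference."""
    subjects = [run_subject(config, i) for i in range(config.n_subjects)]
    n = len(subjects)
    gseed = lambda stage: stage_seed(config.master_seed, -1, stage)

    # behavior
    brows = []
    for s in subjects:
        for cond, summ in s.behavior_summaries.items():
            brows.append(
                dict(subject=s.subject, condition=cond, accuracy=summ.accuracy,
                     dprime=summ.dprime, criterion=summ.criterion,
                     mean_rt_ms=summ.mean_rt_ms, n_included=summ.n_included,
                     n_excluded=summ.n_excluded)
            )
    behavior_table = pd.DataFrame(brows)
    behavior_contrast = behavior.condition_contrast(behavior_table)

    # encoding: one-sample cluster tests on component-summarised series
    encoding_tests = {}
    for key in subjects[0].encoding_summary:
        stack = np.stack([s.encoding_summary[key] for s in subjects])
        encoding_tests[key] = statkit.cluster_test_1d(
            stack, kind="one-sample", alpha_cluster=config.alpha,
            n_perm=config.n_perm, seed=gseed(f"enc_{key}"),
        )

    # tone-decoding condition contrast
    scores = {
        cond: np.stack([s.score_series[cond] for s in subjects])
        for cond in ("rhythmic", "jittered")
    }
    valid = np.all(np.isfinite(scores["rhythmic"]), axis=0) & np.all(
        np.isfinite(scores["jittered"]), axis=0
    )
    diffs = (scores["rhythmic"] - scores["jittered"])[:, valid]
    decoding_contrast = statkit.cluster_test_1d(
        diffs, kind="paired", alpha_cluster=config.alpha, n_perm=config.n_perm,
        seed=gseed("decoding"),
    )

    # chord-decoding condition contrast
    chord_diffs = np.stack(
        [
            s.chord_series["rhythmic"].relative_distance
            - s.chord_series["jittered"].relative_distance
            for s in subjects
        ]
    )
    chord_contrast = statkit.cluster_test_1d(
        chord_diffs, kind="paired", alpha_cluster=config.alpha, n_perm=config.n_perm,
        seed=gseed("chord"),
    )

    # PLV and power contrasts over components x freq x time
    plv_diffs = np.stack([s.plv["rhythmic"] - s.plv["jittered"] for s in subjects])
    n_feat = plv_diffs.shape[1]
    no_adjacency = np.zeros((n_feat, n_feat), dtype=bool)
    plv_contrast = statkit.cluster_test_chan_tf(
        plv_diffs, no_adjacency, alpha_cluster=config.alpha, n_perm=config.n_perm,
        seed=gseed("plv"),
    )
    power_diffs = np.stack([s.power["rhythmic"] - s.power["jittered"] for s in subjects])
    power_contrast = statkit.cluster_test_chan_tf(
        power_diffs, no_adjacency, alpha_cluster=config.alpha, n_perm=config.n_perm,
        seed=gseed("power"),
    )

    # gain/tuning model space, AIC, BMS
    with np.errstate(invalid="ignore"):
        grand = np.nanmean(np.stack([s.avg_matrix for s in subjects]), axis=0)
    anchor_fit = tuningmodel.fit_model(grand)
    anchors = anchor_fit.params
    models = tuningmodel.model_space()
    aic_matrix = np.zeros((n, len(models)))
    for si, s in enumerate(subjects):
        for mi, model in enumerate(models):
            fit = tuningmodel.fit_model(
                s.avg_matrix, fixed=model.fixed_from(anchors), start=anchors
            )
            aic_matrix[si, mi] = fit.aic
    bms = tuningmodel.bayesian_model_selection(-aic_matrix / 2.0, seed=gseed("bms"))

    # per-condition parameter tests (Bonferroni over the three parameters)
    prow = []
    alpha_corr = statkit.bonferroni_alpha(config.alpha, 3)
    for pname in tuningmodel.PARAM_NAMES:
        a = np.array([s.tuning_fits["rhythmic"].params[pname] for s in subjects])
        b = np.array([s.tuning_fits["jittered"].params[pname] for s in subjects])
        t, df, p = statkit.paired_t(a, b)
        prow.append(
            dict(parameter=pname, mean_rhythmic=float(a.mean()), mean_jittered=float(b.mean()),
                 t=t, df=df, p=p, significant=p < alpha_corr)
        )
    parameter_tests = pd.DataFrame(prow)

    # frequency-class ANOVA on the gain parameter
    gvals = np.full((n, 2, 4), np.nan)
    for si, s in enumerate(subjects):
        for ci, cond in enumerate(("rhythmic", "jittered")):
            for ki, klass in enumerate(CLASS_ORDER):
                fit = s.class_fits[cond].get(klass)
                if fit is not None:
                    gvals[si, ci, ki] = fit.g
    class_anova = statkit.rm_anova_2x4(np.nan_to_num(gvals, nan=np.nanmean(gvals)))

    # cross-measure correlations of condition differences
    fit_w = config.fit_window_ms
    lag_sel = (subjects[0].lags_ms >= fit_w[0]) & (subjects[0].lags_ms <= fit_w[1])
    measures = {
        "tone_decoding": np.array(
            [
                np.nanmean(s.score_series["rhythmic"][lag_sel])
                - np.nanmean(s.score_series["jittered"][lag_sel])
                for s in subjects
            ]
        ),
        "gain": np.array(
            [s.tuning_fits["rhythmic"].g - s.tuning_fits["jittered"].g for s in subjects]
        ),
        "chord_decoding": np.array(
            [
                s.chord_series["rhythmic"].averaged(config.chord_window_ms)
                - s.chord_series["jittered"].averaged(config.chord_window_ms)
                for s in subjects
            ]
        ),
        "accuracy": np.array(
            [
                s.behavior_summaries["rhythmic"].accuracy
                - s.behavior_summaries["jittered"].accuracy
                for s in subjects
            ]
        ),
    }
    names = list(measures)
    pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1 :]]
    alpha_corr_r = statkit.bonferroni_alpha(config.alpha, len(pairs))
    crows = []
    for a, b in pairs:
        try:
            res = statkit.correlate_with_influence(measures[a], measures[b])
            crows.append(
                dict(x=a, y=b, r=res.r, p=res.p, r_excluded=res.r_excluded,
                     p_excluded=res.p_excluded, n_excluded=len(res.excluded),
                     significant=res.p < alpha_corr_r)
            )
        except ValueError:
            crows.append(dict(x=a, y=b, r=np.nan, p=np.nan, r_excluded=np.nan,
                              p_excluded=np.nan, n_excluded=0, significant=False))
    correlations = pd.DataFrame(crows)

    import rhythmgain

    manifest = dict(
        config_hash=config.config_hash(), master_seed=config.master_seed,
        n_subjects=n, package_version=rhythmgain.__version__,
        numpy_version=np.__version__,
        basis_modes=[s.basis_modes for s in subjects],
    )
    return ExperimentResult(
        config=config, subjects=subjects, behavior_table=behavior_table,
        behavior_contrast=behavior_contrast, encoding_tests=encoding_tests,
        decoding_contrast=decoding_contrast,
        decoding_valid_lags=subjects[0].lags_ms[valid],
        chord_contrast=chord_contrast, plv_contrast=plv_contrast,
        power_contrast=power_contrast, bms=bms,
        model_names=[m.name for m in models], parameter_tests=parameter_tests,
        class_anova=class_anova, correlations=correlations, manifest=manifest,
    )
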