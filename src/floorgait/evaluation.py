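"""Evaluation metrics and end-to-end synthetic recovery experiments.

Metrics: per-class and macro F-1, mean absolute error, and Fig.-style
confusion matrices (counts plus precision-normalized percentages per
predicted class). The experiment harness wires simulator output through
detection, feature extraction, rebalancing and the hierarchical model,
scoring everything against the simulator's ground-truth annotations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import pipeline, sigfeat, symptoms
from .hierarchy import (
    FeatureDataset,
    ModelConfig,
    assemble_step_features,
    encode_biometrics,
    train_hierarchical,
)
from .records import FootstepImpulse, SensorRecording, SubjectData, WalkTrace
from .symptoms import ContactModel
from .synthetic import (
    CONTACT_TYPES,
    FloorModel,
    SensorLayout,
    gait_profile_for_stage,
    generate_cohort,
    generate_footstep_pulse,
    generate_walk_trace,
    inject_distractors,
)

__all__ = [
    "f1_scores",
    "mae",
    "confusion_matrix",
    "make_contact_training_set",
    "extract_trace_sample",
    "extract_features",
    "match_events",
    "run_detection_experiment",
    "run_mae_experiment",
    "run_trend_experiment",
    "RecoveryConfig",
    "run_recovery_experiment",
]


# --------------------------------------------------------------------------
# metrics
# --------------------------------------------------------------------------

def f1_scores(predictions, truths) -> dict:
    """Per-class precision/recall/F-1 and the unweighted (macro) mean F-1.

    Degenerate 0/0 ratios are 0 by convention (flagged per class).
    """
    predictions, truths = list(predictions), list(truths)
    if len(predictions) != len(truths):
        raise ValueError("prediction and truth lists must have equal length")
    if not predictions:
        raise ValueError("empty input")
    classes = sorted(set(predictions) | set(truths))
    per_class = {}
    for c in classes:
        tp = sum(1 for p, t in zip(predictions, truths) if p == c and t == c)
        fp = sum(1 for p, t in zip(predictions, truths) if p == c and t != c)
        fn = sum(1 for p, t in zip(predictions, truths) if p != c and t == c)
        precision = tp / (tp + fp) if (tp + fp) else 0.0
        recall = tp / (tp + fn) if (tp + fn) else 0.0
        f1 = 2 * precision * recall / (precision + recall) if (precision + recall) else 0.0
        per_class[c] = {
            "precision": precision,
            "recall": recall,
            "f1": f1,
            "degenerate": (tp + fp + fn) == 0,
        }
    macro = float(np.mean([v["f1"] for v in per_class.values()]))
    return {"per_class": per_class, "macro_f1": macro}


def mae(predictions, truths) -> float:
    """Mean absolute error between two equal-length numeric lists."""
    p = np.asarray(predictions, dtype=float)
    t = np.asarray(truths, dtype=float)
    if p.shape != t.shape or p.size == 0:
        raise ValueError("inputs must be equal-length and non-empty")
    return float(np.mean(np.abs(p - t)))


def confusion_matrix(predictions, truths, class_set) -> dict:
    """Counts (rows = truth, columns = prediction) and per-predicted-class
    precision percentages (columns normalized to 100%)."""
    classes = list(class_set)
    index = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=int)
    for p, t in zip(predictions, truths):
        if p not in index or t not in index:
            raise ValueError(f"label {p!r}/{t!r} outside the class set")
        counts[index[t], index[p]] += 1
    col = counts.sum(axis=0, keepdims=True).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        precision_pct = np.where(col > 0, counts / col * 100.0, 0.0)
    return {"classes": classes, "counts": counts, "precision_percent": precision_pct}


# --------------------------------------------------------------------------
# contact-classifier training data
# --------------------------------------------------------------------------

def make_contact_training_set(
    n_per_class: int = 60,
    sampling_rate: float = 500.0,
    floor: FloorModel | None = None,
    noise_sd: float = 0.02,
    rng_seed: int | np.random.Generator | None = None,
    n_bins: int = 25,
) -> tuple[np.ndarray, list[str]]:
    """Labeled footstep spectra for the three initial-contact classes."""
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    floor = floor or FloorModel()
    spectra, labels = [], []
    for contact in CONTACT_TYPES:
        for _ in range(n_per_class):
            pulse = generate_footstep_pulse(contact, 1.0, floor, sampling_rate, rng)
            if noise_sd > 0:
                pulse = pulse + rng.normal(0.0, noise_sd, pulse.size)
            imp = FootstepImpulse(
                onset_time=0.0,
                offset_time=pulse.size / sampling_rate,
                samples=pulse,
                sampling_rate=sampling_rate,
            )
            spectra.append(symptoms.footstep_spectrum(imp, n_bins=n_bins))
            labels.append(contact)
    return np.asarray(spectra), labels


# --------------------------------------------------------------------------
# per-recording feature extraction
# --------------------------------------------------------------------------

def process_recording(
    recording: SensorRecording,
) -> tuple[list[FootstepImpulse], symptoms.StrikeSequence]:
    """Full detection path for one recording.

    Lowpass -> noise stats -> windowed detection -> footstep filters ->
    Wiener denoising -> segmentation, plus the Morse-band strike sequence.
    """
    rec = pipeline.lowpass_filter(recording)
    noise = pipeline.estimate_noise_stats(rec)
    candidates = pipeline.detect_impulses(rec, noise)
    accepted = pipeline.filter_footstep_impulses(candidates)
    denoised = pipeline.wiener_denoise(rec, noise)
    impulses = pipeline.segment_footsteps(denoised, accepted)
    strikes = symptoms.strikes_from_recording(denoised)
    return impulses, strikes


def extract_trace_sample(
    recording: SensorRecording,
    contact_model: ContactModel,
) -> tuple[np.ndarray, np.ndarray] | None:
    """Step feature rows (n, 12) and the 14-dim trace feature vector.

    Returns None when the recording yields too few footsteps for the
    trace-level symptoms (fewer than 3 impulses or 2 strikes).
    """
    impulses, strikes = process_recording(recording)
    if len(impulses) < 3 or strikes.n < 2:
        return None

    onsets = np.array([imp.onset_time for imp in impulses])
    dts = np.diff(onsets)
    step_time_per_imp = np.append(dts, dts[-1])

    spectra = np.array(
        [symptoms.footstep_spectrum(imp, n_bins=contact_model.n_bins) for imp in impulses]
    )
    toe_idx = contact_model.classes.index("toe")
    toe_probs = contact_model.predict_proba(spectra)[:, toe_idx]

    rows = []
    for k, imp in enumerate(impulses):
        rows.append(
            assemble_step_features(
                step_time=float(step_time_per_imp[k]),
                toe_probability=float(toe_probs[k]),
                sensor_id=recording.sensor_id,
                basic=sigfeat.basic_stats(imp),
                dominant_freq_strike=sigfeat.dominant_frequency(imp, "strike"),
                dominant_freq_off=sigfeat.dominant_frequency(imp, "off"),
                psd_bands=sigfeat.psd_band_powers(imp, n_bands=3),
            )
        )

    x90 = np.array([symptoms.x90_amplitude(imp) for imp in impulses])
    if np.any(x90 <= 0):
        return None
    sym = symptoms.symmetry_score(x90)
    st = symptoms.step_times(strikes)
    cad = symptoms.cadence(strikes)
    stv = symptoms.step_time_variability(st) if st.size >= 2 else 0.0
    energies = np.array([sigfeat.footstep_energy(imp) for imp in impulses])
    ev = sigfeat.energy_variability(energies)
    rep = sigfeat.representative_footstep(impulses)
    rep_psd = symptoms.footstep_spectrum(rep, n_bins=10)
    trace_feat = np.concatenate([[sym, stv, cad, ev], rep_psd])
    return np.asarray(rows), trace_feat


def extract_features(
    cohort: list[SubjectData],
    contact_model: ContactModel,
    rebalance: bool = True,
    rng_seed: int | np.random.Generator | None = None,
) -> FeatureDataset:
    """Cohort -> multi-level feature tables.

    Every (trace, sensor) pair is one trace sample, as each recording of
    a walking pass by one sensor stands alone. Per-subject trace-sample
    counts are optionally rebalanced to the cohort median.
    """
    per_subject: list[list[tuple[np.ndarray, np.ndarray]]] = []
    for subject in cohort:
        samples = []
        for trace in subject.traces:
            for rec in trace.recordings:
                out = extract_trace_sample(rec, contact_model)
                if out is not None:
                    samples.append(out)
        per_subject.append(samples)
    if any(len(s) == 0 for s in per_subject):
        bad = [i for i, s in enumerate(per_subject) if not s]
        raise ValueError(f"subjects {bad} yielded no usable trace samples")
    if rebalance:
        per_subject = pipeline.rebalance_subjects(per_subject, rng_seed)

    step_rows, step_trace, trace_rows, trace_person = [], [], [], []
    person_bio, person_label = [], []
    t_idx = 0
    for p_idx, (subject, samples) in enumerate(zip(cohort, per_subject)):
        person_bio.append(encode_biometrics(subject.biometrics))
        person_label.append(subject.stage)
        for rows, trace_feat in samples:
            trace_rows.append(trace_feat)
            trace_person.append(p_idx)
            for row in rows:
                step_rows.append(row)
                step_trace.append(t_idx)
            t_idx += 1
    return FeatureDataset(
        step_X=np.asarray(step_rows),
        step_trace=np.asarray(step_trace, dtype=int),
        trace_X=np.asarray(trace_rows),
        trace_person=np.asarray(trace_person, dtype=int),
        person_bio=np.asarray(person_bio),
        person_label=np.asarray(person_label, dtype=int),
    )


# --------------------------------------------------------------------------
# detection scoring
# --------------------------------------------------------------------------

def match_events(
    detected: np.ndarray, truth: np.ndarray, tolerance: float
) -> tuple[int, int, int]:
    """Greedy one-to-one matching of onset times; returns (TP, FP, FN)."""
    detected = np.sort(np.asarray(detected, dtype=float))
    truth = np.sort(np.asarray(truth, dtype=float))
    used = np.zeros(truth.size, dtype=bool)
    tp = 0
    for d in detected:
        if truth.size == 0:
            break
        j = int(np.argmin(np.where(used, np.inf, np.abs(truth - d))))
        if not used[j] and abs(truth[j] - d) <= tolerance:
            used[j] = True
            tp += 1
    return tp, detected.size - tp, truth.size - tp


def _trace_noise_sd_for_snr(trace: WalkTrace, snr: float) -> float:
    """Noise sd so that the weakest footstep's best-sensor peak has the
    requested amplitude SNR."""
    fs = trace.recordings[0].sampling_rate
    strike_idx = np.round(trace.annotations.strike_times * fs).astype(int)
    best_peaks = []
    for k, t0 in enumerate(strike_idx):
        window = slice(t0, t0 + int(0.6 * fs))
        best_peaks.append(
            max(float(np.max(np.abs(r.samples[window]))) for r in trace.recordings)
        )
    return min(best_peaks) / snr


def _add_noise(rec: SensorRecording, noise_sd: float, rng: np.random.Generator) -> SensorRecording:
    return SensorRecording(
        samples=rec.samples + rng.normal(0.0, noise_sd, rec.samples.size),
        sampling_rate=rec.sampling_rate,
        sensor_id=rec.sensor_id,
        noise_reference=rec.noise_reference,
        position=rec.position,
        distractor_intervals=list(rec.distractor_intervals),
    )


def run_detection_experiment(
    n_traces: int = 50,
    rng_seed: int = 0,
    snr: float = 20.0,
    with_distractors: bool = True,
    layout: SensorLayout | None = None,
    floor: FloorModel | None = None,
) -> dict:
    """Score footstep detection + filtering against simulator annotations.

    Each trace is generated noise-free, the noise level is set so the
    weakest footstep keeps the requested amplitude SNR at its best
    sensor, and all three distractor kinds are superimposed. A footstep
    counts as detected when any sensor accepts an impulse whose onset
    lies within 0.15 s of the annotated strike; accepted impulses
    matching a logged distractor interval count as false positives.
    """
    rng = np.random.default_rng(rng_seed)
    layout = layout or SensorLayout()
    floor = floor or FloorModel()
    tp = fp = fn = 0
    distractors_injected = distractors_accepted = 0
    for _ in range(n_traces):
        stage = int(rng.integers(0, 6))
        profile = gait_profile_for_stage(stage, rng)
        trace = generate_walk_trace(
            profile, int(rng.integers(8, 13)), layout, floor, 0.0, rng, stage_label=stage
        )
        noise_sd = _trace_noise_sd_for_snr(trace, snr)
        onsets_all = []
        for rec in trace.recordings:
            noisy = _add_noise(rec, noise_sd, rng)
            if with_distractors:
                noisy = inject_distractors(
                    noisy, ["isolated_impulse", "long_transient", "short_blip"], rng
                )
            impulses, _ = process_recording(noisy)
            onsets = [imp.onset_time for imp in impulses]
            distractors_injected += len(noisy.distractor_intervals)
            for a, b, _kind in noisy.distractor_intervals:
                if any(a - 0.15 <= o <= b + 0.15 for o in onsets):
                    distractors_accepted += 1
            onsets_all.extend(onsets)
        # union across sensors: cluster onsets within the matching tolerance
        onsets_all = np.sort(onsets_all)
        fused = []
        for o in onsets_all:
            if not fused or o - fused[-1] > 0.15:
                fused.append(o)
        t, f, m = match_events(np.asarray(fused), trace.annotations.strike_times, 0.15)
        tp, fp, fn = tp + t, fp + f, fn + m
    precision = tp / (tp + fp) if (tp + fp) else 0.0
    recall = tp / (tp + fn) if (tp + fn) else 0.0
    return {
        "n_traces": n_traces,
        "precision": precision,
        "recall": recall,
        "distractors_injected": distractors_injected,
        "distractors_accepted": distractors_accepted,
    }


def run_mae_experiment(
    n_traces: int = 100,
    rng_seed: int = 0,
    snr_db: float = 10.0,
    layout: SensorLayout | None = None,
    floor: FloorModel | None = None,
) -> dict:
    """Step-time and cadence recovery accuracy at a given SNR (dB).

    SNR is the usual power ratio: per trace, the noise variance is set to
    the mean clean signal power over the active walking span (averaged
    across sensors) divided by ``10^(snr_db/10)``. Strike sequences from
    all sensors are fused (0.15 s clustering, mean time per cluster);
    step-time MAE is computed over matched strike pairs and cadence MAE
    per trace against the annotated values.
    """
    rng = np.random.default_rng(rng_seed)
    layout = layout or SensorLayout()
    floor = floor or FloorModel()
    step_errors: list[float] = []
    cadence_pred, cadence_true = [], []
    for _ in range(n_traces):
        stage = int(rng.integers(0, 6))
        profile = gait_profile_for_stage(stage, rng)
        trace = generate_walk_trace(
            profile, int(rng.integers(8, 13)), layout, floor, 0.0, rng, stage_label=stage
        )
        fs = layout.sampling_rate
        t_ann = trace.annotations.strike_times
        a = int(t_ann[0] * fs)
        b = min(int((t_ann[-1] + 0.6) * fs), trace.recordings[0].samples.size)
        signal_power = float(
            np.mean([np.mean(r.samples[a:b] ** 2) for r in trace.recordings])
        )
        noise_sd = float(np.sqrt(signal_power / 10.0 ** (snr_db / 10.0)))
        all_times = []
        for rec in trace.recordings:
            noisy = _add_noise(rec, noise_sd, rng)
            strikes = symptoms.strikes_from_recording(noisy)
            all_times.extend(strikes.strike_times.tolist())
        fused = _fuse_strike_times(np.asarray(all_times), 0.15)
        truth = trace.annotations.strike_times
        # matched strike pairs -> matched step-time pairs
        matched_det, matched_tru = _paired_times(fused, truth, 0.2)
        if matched_det.size >= 2:
            step_errors.extend(
                np.abs(np.diff(matched_det) - np.diff(matched_tru)).tolist()
            )
        if fused.size >= 2:
            cadence_pred.append(
                symptoms.cadence(symptoms.StrikeSequence(fused))
            )
            cadence_true.append(
                symptoms.cadence(symptoms.StrikeSequence(truth))
            )
    return {
        "n_traces": n_traces,
        "snr_db": snr_db,
        "step_time_mae_s": float(np.mean(step_errors)) if step_errors else float("nan"),
        "cadence_mae_spm": mae(cadence_pred, cadence_true),
        "n_step_pairs": len(step_errors),
    }


def _fuse_strike_times(times: np.ndarray, tol: float) -> np.ndarray:
    """Cluster per-sensor strike times within tol; one mean time per cluster."""
    times = np.sort(np.asarray(times, dtype=float))
    if times.size == 0:
        return times
    clusters = [[times[0]]]
    for t in times[1:]:
        if t - clusters[-1][-1] <= tol:
            clusters[-1].append(t)
        else:
            clusters.append([t])
    return np.array([float(np.mean(c)) for c in clusters])


def _paired_times(
    detected: np.ndarray, truth: np.ndarray, tol: float
) -> tuple[np.ndarray, np.ndarray]:
    """Consecutively matched (detected, truth) time pairs for step-time MAE."""
    d_out, t_out = [], []
    used = np.zeros(truth.size, dtype=bool)
    for d in np.sort(detected):
        if truth.size == 0:
            break
        j = int(np.argmin(np.where(used, np.inf, np.abs(truth - d))))
        if not used[j] and abs(truth[j] - d) <= tol:
            used[j] = True
            d_out.append(d)
            t_out.append(truth[j])
    order = np.argsort(t_out)
    return np.asarray(d_out)[order], np.asarray(t_out)[order]


def run_trend_experiment(
    traces_per_stage: int = 10,
    rng_seed: int = 0,
    noise_sd: float = 0.02,
    layout: SensorLayout | None = None,
    floor: FloorModel | None = None,
    contact_model: ContactModel | None = None,
) -> dict:
    """Mean extracted symmetry score and toe-contact probability per stage.

    Everything is measured through the detection + feature pipeline, so
    the experiment checks that the generator's stage trends survive
    sensing: symmetry should fall and toe probability rise with stage.
    """
    rng = np.random.default_rng(rng_seed)
    layout = layout or SensorLayout()
    floor = floor or FloorModel()
    if contact_model is None:
        spectra, labels = make_contact_training_set(rng_seed=rng)
        contact_model = symptoms.train_contact_classifier(spectra, labels)
    toe_idx = contact_model.classes.index("toe")
    sym_means, toe_means = [], []
    for stage in range(6):
        syms, toes = [], []
        for _ in range(traces_per_stage):
            profile = gait_profile_for_stage(stage, rng)
            trace = generate_walk_trace(
                profile, int(rng.integers(8, 13)), layout, floor, noise_sd, rng,
                stage_label=stage,
            )
            for rec in trace.recordings:
                impulses, _ = process_recording(rec)
                if len(impulses) < 3:
                    continue
                x90 = np.array([symptoms.x90_amplitude(i) for i in impulses])
                if np.all(x90 > 0):
                    syms.append(symptoms.symmetry_score(x90))
                spec = np.array(
                    [symptoms.footstep_spectrum(i, n_bins=contact_model.n_bins)
                     for i in impulses]
                )
                toes.extend(contact_model.predict_proba(spec)[:, toe_idx].tolist())
        sym_means.append(float(np.mean(syms)))
        toe_means.append(float(np.mean(toes)))
    return {
        "stages": list(range(6)),
        "mean_symmetry_score": sym_means,
        "mean_toe_probability": toe_means,
    }


# --------------------------------------------------------------------------
# full recovery experiment
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class RecoveryConfig:
    """Study conditions for the synthetic stage-recovery experiment."""

    n_subjects: int = 12
    stage_distribution: tuple[float, ...] = (1 / 6,) * 6
    traces_per_subject: tuple[int, int] = (5, 10)
    n_steps_range: tuple[int, int] = (8, 12)
    noise_sd: float = 0.02
    contact_examples_per_class: int = 60
    layout: SensorLayout = field(default_factory=SensorLayout)
    floor: FloorModel = field(default_factory=FloorModel)
    model: ModelConfig = field(default_factory=ModelConfig)


def run_recovery_experiment(
    config: RecoveryConfig | None = None, rng_seed: int = 0
) -> dict:
    """Generate a cohort, run the full pipeline, train and score the model.

    Returns step-, trace- and person-level test accuracies, macro F-1 and
    the person-level confusion matrix; fully reproducible under the seed.
    """
    config = config or RecoveryConfig()
    rng = np.random.default_rng(rng_seed)
    cohort = generate_cohort(
        config.n_subjects,
        np.asarray(config.stage_distribution),
        config.traces_per_subject,
        rng,
        layout=config.layout,
        floor=config.floor,
        noise_sd=config.noise_sd,
        n_steps_range=config.n_steps_range,
    )
    spectra, labels = make_contact_training_set(
        config.contact_examples_per_class,
        config.layout.sampling_rate,
        config.floor,
        config.noise_sd,
        rng,
    )
    contact_model = symptoms.train_contact_classifier(
        spectra, labels, rng_seed=int(rng.integers(2**31))
    )
    data = extract_features(cohort, contact_model, rebalance=True, rng_seed=rng)
    model = train_hierarchical(data, config.model, seed=int(rng.integers(2**31)))
    predictions = model.predict_stage(data)
    pred_stages = [p.stage for p in predictions]
    true_stages = data.person_label.tolist()
    cm = confusion_matrix(pred_stages, true_stages, list(range(6)))
    return {
        "n_subjects": config.n_subjects,
        "n_trace_samples": int(data.trace_X.shape[0]),
        "n_step_samples": int(data.step_X.shape[0]),
        "step_accuracy": model.metrics["step_accuracy"],
        "trace_accuracy": model.metrics["trace_accuracy"],
        "person_accuracy": model.metrics["person_accuracy"],
        "person_macro_f1": f1_scores(pred_stages, true_stages)["macro_f1"],
        "person_confusion_counts": cm["counts"].tolist(),
        "predicted_stages": pred_stages,
        "true_stages": true_stages,
    }
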