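"""End-to-end helpers chaining the analysis stages on one session.

These are the pieces the CLI and the evaluation report are built from:
EMG onset labeling, per-subject band selection on the bipolar motor
channel, onset-detector training/scoring, and decoder-input assembly.
"""

from __future__ import annotations

import numpy as np

from . import onset as onset_mod
from .decoding import FeatureSeries, build_features
from .evaluate import DecodingData, make_trial_ids, movement_gate
from .preprocess import EmgOnsetResult, bandpass_emg, bipolar_derivation, detect_emg_onsets
from .session import Direction, MarkerKind, SessionRecording
from .tf import BandSpec, ErdErsMap, erders, ks_significance, select_band, spectrogram

DEFAULT_BASELINE_INTERVAL = (0.5, 4.5)  # session lead-in, guaranteed rest


def emg_onsets_for(
    rec: SessionRecording,
    channel: int = 0,
    baseline_interval: tuple[float, float] | None = None,
    k: float = 3.0,
) -> EmgOnsetResult:
    """Band-pass the designated EMG channel and run burst detection.

    The baseline defaults to the movement-free lead-in: from 0.5 s after
    session start to 0.5 s before the first GO cue (or the first 4 s when
    no GO markers exist).
    """
    if baseline_interval is None:
        gos = rec.markers_of(MarkerKind.GO)
        if gos:
            baseline_interval = (0.5, max(gos[0].time - 0.5, 2.0))
        else:
            baseline_interval = DEFAULT_BASELINE_INTERVAL
    emg = bandpass_emg(rec.emg[channel], rec.rate_ecog)
    return detect_emg_onsets(emg, rec.rate_ecog, baseline_interval, k=k)


def trial_directions(rec: SessionRecording, onsets: np.ndarray) -> list[Direction]:
    """Direction of the GO marker immediately preceding each onset."""
    gos = rec.markers_of(MarkerKind.GO)
    go_times = np.array([m.time for m in gos])
    dirs = []
    for onset in onsets:
        before = np.flatnonzero(go_times <= onset + 1e-9)
        if before.size == 0:
            dirs.append(Direction.NONE)
        else:
            dirs.append(gos[before[-1]].direction)
    return dirs


def erders_map(
    rec: SessionRecording,
    onsets: np.ndarray,
    signal: np.ndarray | None = None,
    pre: float = 4.0,
    post: float = 8.0,
    fmax: float = 300.0,
    with_pvalues: bool = False,
    ks_time_step: int = 10,
    max_trials: int | None = None,
) -> ErdErsMap:
    """Trial-averaged ERD/ERS map of the bipolar motor channel.

    Trials are cut at [-pre, +post] around each onset and transformed
    individually; only onsets whose window fits the recording are used.
    """
    if signal is None:
        signal = bipolar_derivation(rec, "ECOG1", "ECOG0")
    rate = rec.rate_ecog
    maps = []
    used = 0
    for onset in onsets:
        if max_trials is not None and used >= max_trials:
            break
        i0 = int(round((onset - pre) * rate))
        i1 = i0 + int(round((pre + post) * rate))
        if i0 < 0 or i1 > signal.size:
            continue
        maps.append(
            spectrogram(signal[i0:i1], rate, fmax=fmax, t_offset=-pre)
        )
        used += 1
    emap = erders(maps)
    if with_pvalues:
        emap.p_values = ks_significance(maps, time_step=ks_time_step)
    return emap


def select_subject_bands(
    emap: ErdErsMap,
    gamma_search: tuple[float, float] = (30.0, 200.0),
    ab_search: tuple[float, float] = (8.0, 30.0),
) -> tuple[BandSpec, BandSpec]:
    """(gamma ERS band, alpha-beta ERD band) from an ERD/ERS map."""
    gamma = select_band(emap, gamma_search, mode="ers")
    alphabeta = select_band(emap, ab_search, mode="erd")
    return gamma, alphabeta


def train_split_time(emg: EmgOnsetResult, n_train_trials: int = 10) -> float:
    """Boundary between the training trials and the held-out remainder:
    midway between the end of trial ``n-1`` and the next onset."""
    if len(emg.onsets) <= n_train_trials:
        raise ValueError(
            f"need more than {n_train_trials} trials to split"
        )
    return 0.5 * (emg.offsets[n_train_trials - 1] + emg.onsets[n_train_trials])


def detection_report(
    rec: SessionRecording,
    gamma_band: BandSpec,
    emg: EmgOnsetResult,
    n_train_trials: int = 10,
    signal: np.ndarray | None = None,
    extra_bands: list[BandSpec] | None = None,
):
    """Train the onset LDA on the first trials, score on the remainder.

    Returns ``(report, model, onset_times, gate, features)`` where the
    report counts only detections and EMG onsets after the train/test
    split.
    """
    if signal is None:
        signal = bipolar_derivation(rec, "ECOG1", "ECOG0")
    bands = [gamma_band] + (extra_bands or [])
    feats = onset_mod.band_power_windows(signal, rec.rate_ecog, bands)
    feats = onset_mod.label_windows(feats, emg)
    split = train_split_time(emg, n_train_trials)
    model = onset_mod.train_onset_lda(feats, bands=bands, train_until_s=split)

    onset_times, gate, _ = onset_mod.detect_onsets(model, feats)
    held = onset_times >= split
    truth_held = EmgOnsetResult(
        onsets=emg.onsets[emg.onsets >= split],
        offsets=emg.offsets[emg.onsets >= split],
        baseline_mean=emg.baseline_mean,
        baseline_sd=emg.baseline_sd,
        threshold_used=emg.threshold_used,
    )
    _, _, report = onset_mod.detect_onsets(model, feats, emg_truth=None)
    # score only the held-out detections against held-out truth
    report = _score_events(onset_times[held], truth_held)
    return report, model, onset_times, gate, feats


def _score_events(
    detected: np.ndarray, truth: EmgOnsetResult, tol: float = 0.5
) -> onset_mod.ClassificationReport:
    true_onsets = np.asarray(truth.onsets, dtype=float)
    claimed = np.zeros(true_onsets.size, dtype=bool)
    tp, fp = 0, 0
    lats = []
    for det in detected:
        if true_onsets.size:
            dist = np.abs(true_onsets - det)
            dist[claimed] = np.inf
            j = int(np.argmin(dist))
            if dist[j] <= tol:
                claimed[j] = True
                tp += 1
                lats.append(det - true_onsets[j])
                continue
        fp += 1
    return onset_mod.ClassificationReport(
        tp=tp, fp=fp, fn=int(np.count_nonzero(~claimed)),
        latencies_s=np.asarray(lats),
    )


def prepare_decoding(
    rec: SessionRecording,
    onsets: np.ndarray,
    offsets: np.ndarray,
    directions: list[Direction],
    alphabeta: BandSpec,
    gamma: BandSpec,
    gate: np.ndarray | None = None,
    features: FeatureSeries | None = None,
) -> DecodingData:
    """Bundle features, kinematics, gate and trial assignment on the
    kinematics clock. The default gate opens during EMG bursts."""
    if features is None:
        features = build_features(rec, alphabeta, gamma)
    n_out = rec.kinematics.shape[1]
    if gate is None:
        gate = movement_gate(n_out, rec.rate_kin, onsets, offsets)
    ids = make_trial_ids(n_out, rec.rate_kin, onsets, offsets)
    return DecodingData(
        E=features,
        K=rec.kinematics,
        gate=np.asarray(gate),
        trial_ids=ids,
        directions=list(directions),
        output_rate=rec.rate_kin,
    )
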