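"""Movement-onset detection from windowed band power.

Band power is computed in 200-ms windows stepped every 50 ms, windows are
labeled movement/rest from EMG bursts, a Fisher linear discriminant is
trained on the log powers of the first trials, and the classifier is then
run over the continuous recording to produce onset events and a binary
gate signal. Detection quality is scored with the F1 measure and the
detection latency relative to the EMG-defined onsets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy import signal as sps

from .preprocess import EmgOnsetResult
from .tf import BandSpec

MOVE, REST = 1, 0


@dataclass
class WindowFeatures:
    times: np.ndarray  # window centers, seconds
    power: np.ndarray  # [n_bands x n_windows], uV^2
    window_s: float = 0.2
    step_s: float = 0.05
    labels: np.ndarray | None = None  # 1 = MOVE, 0 = REST

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.power = np.atleast_2d(np.asarray(self.power, dtype=float))
        if np.any(self.power < 0):
            raise ValueError("window powers must be non-negative")


@dataclass
class ClassificationReport:
    tp: int
    fp: int
    fn: int
    tn: int = 0
    latencies_s: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def f1(self) -> float:
        if self.tp == 0 and (self.fp + self.fn) > 0:
            return 0.0
        return f1(self.tp, self.fp, self.fn)

    @property
    def latency_mean_ms(self) -> float:
        return float(np.mean(self.latencies_s) * 1e3) if self.latencies_s.size else float("nan")

    @property
    def latency_sd_ms(self) -> float:
        return float(np.std(self.latencies_s, ddof=1) * 1e3) if self.latencies_s.size > 1 else float("nan")

    def as_dict(self) -> dict:
        return {
            "f1": self.f1,
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "latency_ms": {
                "mean": self.latency_mean_ms,
                "sd": self.latency_sd_ms,
            },
        }


def f1(tp: int, fp: int, fn: int) -> float:
    """F1 = 2TP / (2TP + FP + FN), evaluated in exact rational arithmetic."""
    if tp < 0 or fp < 0 or fn < 0:
        raise ValueError("counts must be non-negative")
    if tp == 0 and fp == 0 and fn == 0:
        raise ValueError("F1 undefined for TP = FP = FN = 0")
    return float(Fraction(2 * tp, 2 * tp + fp + fn))


def chance_f1(move_prevalence: float) -> float:
    """F1 of an always-MOVE (or prevalence-matched random) window
    classifier: 2p / (1 + p) for MOVE prevalence p."""
    p = float(move_prevalence)
    return 2.0 * p / (1.0 + p)


def band_power_windows(
    signal: np.ndarray,
    rate: float,
    bands: list[BandSpec],
    window_s: float = 0.2,
    step_s: float = 0.05,
    filter_order: int = 3,
) -> WindowFeatures:
    """Mean-square band amplitude in sliding windows.

    Each band is isolated with a zero-phase Butterworth band-pass before
    squaring and window-averaging.
    """
    x = np.asarray(signal, dtype=float)
    nyq = rate / 2.0
    nwin = int(round(window_s * rate))
    step = int(round(step_s * rate))
    n_frames = (x.size - nwin) // step + 1
    if n_frames < 1:
        raise ValueError("signal shorter than one window")

    powers = np.empty((len(bands), n_frames))
    idx = np.arange(nwin)[None, :] + step * np.arange(n_frames)[:, None]
    for bi, band in enumerate(bands):
        lo, hi = band.edges
        if hi >= nyq or lo <= 0:
            raise ValueError(f"band {lo:.1f}-{hi:.1f} Hz outside (0, Nyquist)")
        sos = sps.butter(filter_order, [lo, hi], btype="bandpass", fs=rate,
                         output="sos")
        filt = sps.sosfiltfilt(sos, x)
        powers[bi] = np.mean(filt[idx] ** 2, axis=1)

    times = (np.arange(n_frames) * step + nwin / 2.0) / rate
    return WindowFeatures(times=times, power=powers, window_s=window_s,
                          step_s=step_s)


def label_windows(features: WindowFeatures, emg: EmgOnsetResult) -> WindowFeatures:
    """MOVE iff the window center lies inside any EMG burst [onset, offset]."""
    labels = np.zeros(features.times.size, dtype=int)
    for onset, offset in zip(emg.onsets, emg.offsets):
        labels[(features.times >= onset) & (features.times <= offset)] = MOVE
    features.labels = labels
    return features


@dataclass
class OnsetModel:
    """Fisher linear discriminant on log10 band powers with a midpoint
    threshold; emits a binary gate over continuous recordings."""

    bands: list[BandSpec] = field(default_factory=list)
    weights: np.ndarray | None = None
    threshold: float = 0.0
    n_train_trials: int = 10
    debounce: int = 2
    trained: bool = False
    log_floor: float = 1e-12

    def _scores(self, features: WindowFeatures) -> np.ndarray:
        logp = np.log10(np.maximum(features.power, self.log_floor))
        return self.weights @ logp

    def fit(self, features: WindowFeatures) -> "OnsetModel":
        if features.labels is None:
            raise ValueError("features must be labeled before training")
        y = features.labels
        if len(np.unique(y)) < 2:
            raise ValueError("training windows contain a single class")
        logp = np.log10(np.maximum(features.power, self.log_floor))
        x_move = logp[:, y == MOVE]
        x_rest = logp[:, y == REST]
        mu1 = x_move.mean(axis=1)
        mu0 = x_rest.mean(axis=1)
        n1, n0 = x_move.shape[1], x_rest.shape[1]
        cov = (
            np.cov(x_move) * (n1 - 1) + np.cov(x_rest) * (n0 - 1)
        ) / max(n1 + n0 - 2, 1)
        cov = np.atleast_2d(cov)
        cov += 1e-9 * np.trace(cov) / cov.shape[0] * np.eye(cov.shape[0])
        self.weights = np.linalg.solve(cov, mu1 - mu0)
        proj1 = self.weights @ mu1
        proj0 = self.weights @ mu0
        self.threshold = 0.5 * (proj1 + proj0)
        self.trained = True
        return self

    def decide(self, features: WindowFeatures) -> np.ndarray:
        if not self.trained:
            raise ValueError("model is not trained")
        return (self._scores(features) > self.threshold).astype(int)


def train_onset_lda(
    features: WindowFeatures,
    bands: list[BandSpec] | None = None,
    train_until_s: float | None = None,
    n_train_trials: int = 10,
) -> OnsetModel:
    """Train the discriminant on labeled windows.

    ``train_until_s`` restricts training to windows centered before that
    time (e.g. the end of the first 10 trials); the caller computes it from
    the trial schedule.
    """
    model = OnsetModel(bands=bands or [], n_train_trials=n_train_trials)
    if train_until_s is not None:
        keep = features.times < train_until_s
        sub = WindowFeatures(
            times=features.times[keep],
            power=features.power[:, keep],
            window_s=features.window_s,
            step_s=features.step_s,
            labels=None if features.labels is None else features.labels[keep],
        )
        return model.fit(sub)
    return model.fit(features)


def _debounced_states(decisions: np.ndarray, debounce: int) -> np.ndarray:
    """State machine: a flip requires ``debounce`` consecutive agreeing
    windows; the state change is stamped at the first window of the run."""
    states = np.empty_like(decisions)
    state = decisions[0]
    run = 0
    for i, d in enumerate(decisions):
        if d != state:
            run += 1
            if run >= debounce:
                state = d
                # back-date the flip to the start of the agreeing run
                states[i - run + 1 : i] = state
                run = 0
        else:
            run = 0
        states[i] = state
    return states


def detect_onsets(
    model: OnsetModel,
    features: WindowFeatures,
    emg_truth: EmgOnsetResult | None = None,
    match_tol_s: float = 0.5,
) -> tuple[np.ndarray, np.ndarray, ClassificationReport | None]:
    """Run the trained classifier over continuous windows.

    Returns ``(onset_times, gate, report)``: REST->MOVE transition times,
    the per-window binary gate after debouncing, and — when EMG truth is
    given — a report counting a detection as TP if it falls within
    ``match_tol_s`` of an unclaimed EMG onset (greedy one-to-one match),
    FP otherwise; unmatched EMG onsets are FN. Latency = detected - true.
    """
    decisions = model.decide(features)
    gate = _debounced_states(decisions, model.debounce)
    trans = np.flatnonzero(np.diff(gate) == 1) + 1
    onset_times = features.times[trans]

    report = None
    if emg_truth is not None:
        true_onsets = np.asarray(emg_truth.onsets, dtype=float)
        claimed = np.zeros(true_onsets.size, dtype=bool)
        tp, fp = 0, 0
        latencies = []
        for det in onset_times:
            if true_onsets.size:
                dist = np.abs(true_onsets - det)
                dist[claimed] = np.inf
                j = int(np.argmin(dist))
                if dist[j] <= match_tol_s:
                    claimed[j] = True
                    tp += 1
                    latencies.append(det - true_onsets[j])
                    continue
            fp += 1
        fn = int(np.count_nonzero(~claimed))
        report = ClassificationReport(
            tp=tp, fp=fp, fn=fn, latencies_s=np.asarray(latencies)
        )
    return onset_times, gate, report


def gate_signal(
    features_times: np.ndarray, gate: np.ndarray, query_times: np.ndarray
) -> np.ndarray:
    """Sample the per-window gate at arbitrary times (previous-window
    hold, right-continuous)."""
    idx = np.searchsorted(features_times, query_times, side="right") - 1
    idx = np.clip(idx, 0, len(gate) - 1)
    return gate[idx]
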