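"""EMG conditioning, EMG burst/onset labeling, and bipolar ECoG derivation."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .session import SessionRecording


@dataclass
class EmgOnsetResult:
    onsets: np.ndarray  # seconds, strictly increasing
    offsets: np.ndarray  # seconds, offsets[i] > onsets[i]
    baseline_mean: float
    baseline_sd: float
    threshold_used: float

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=float)
        self.offsets = np.asarray(self.offsets, dtype=float)
        if np.any(np.diff(self.onsets) <= 0):
            raise ValueError("onsets must be strictly increasing")
        if len(self.onsets) != len(self.offsets) or np.any(
            self.offsets <= self.onsets
        ):
            raise ValueError("each offset must follow its onset")


def bandpass_emg(signal: np.ndarray, rate: float, lo: float = 20.0,
                 hi: float = 500.0, order: int = 4) -> np.ndarray:
    """Zero-phase 20–500 Hz band-pass (Butterworth, forward-backward)."""
    if rate <= 2 * hi:
        raise ValueError(f"rate {rate} Hz too low for a {hi} Hz band edge")
    sos = sps.butter(order, [lo, hi], btype="bandpass", fs=rate, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(signal, dtype=float))


def _moving_average(x: np.ndarray, n: int) -> np.ndarray:
    """Centered moving average with edge shrinkage (zero group delay)."""
    kernel = np.ones(n) / n
    num = np.convolve(x, kernel, mode="same")
    norm = np.convolve(np.ones_like(x), kernel, mode="same")
    return num / norm


def detect_emg_onsets(
    emg: np.ndarray,
    rate: float,
    baseline_interval: tuple[float, float],
    k: float = 3.0,
    smooth_s: float = 0.100,
    merge_gap_s: float = 0.250,
    min_burst_s: float = 0.5,
) -> EmgOnsetResult:
    """Threshold-based EMG burst detection.

    The signal is rectified and smoothed with a centered 100-ms moving
    average; a burst starts when the result exceeds
    ``baseline_mean + k * baseline_sd`` (statistics taken over
    ``baseline_interval``) and ends when it falls back below.
    Supra-threshold excursions shorter than ``min_burst_s`` are discarded
    as noise blips (before merging, so they cannot drag a real onset
    early); remaining bursts separated by less than ``merge_gap_s`` are
    merged.
    """
    x = np.abs(np.asarray(emg, dtype=float))
    n_smooth = max(int(round(smooth_s * rate)), 1)
    env = _moving_average(x, n_smooth)

    b0, b1 = baseline_interval
    i0, i1 = int(round(b0 * rate)), int(round(b1 * rate))
    base = env[i0:i1]
    if base.size < 2:
        raise ValueError("baseline interval too short")
    mu, sd = float(np.mean(base)), float(np.std(base))
    if sd == 0:
        raise ValueError("zero-variance baseline")
    thresh = mu + k * sd

    above = env > thresh
    edges = np.diff(above.astype(int))
    starts = np.flatnonzero(edges == 1) + 1
    stops = np.flatnonzero(edges == -1) + 1
    if above[0]:
        starts = np.r_[0, starts]
    if above[-1]:
        stops = np.r_[stops, len(above)]

    # drop noise blips first, then merge bursts separated by short gaps
    min_len = int(round(min_burst_s * rate))
    kept = [(s, e) for s, e in zip(starts, stops) if e - s >= min_len]
    merged: list[list[int]] = []
    gap = int(round(merge_gap_s * rate))
    for s, e in kept:
        if merged and s - merged[-1][1] < gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])

    onsets = np.array([s / rate for s, _ in merged])
    offsets = np.array([e / rate for _, e in merged])
    return EmgOnsetResult(
        onsets=onsets,
        offsets=offsets,
        baseline_mean=mu,
        baseline_sd=sd,
        threshold_used=thresh,
    )


def bipolar_derivation(
    rec: SessionRecording, signal_ch: str, reference_ch: str
) -> np.ndarray:
    """Sample-wise difference ``signal - reference`` of two channels."""
    return rec.channel(signal_ch) - rec.channel(reference_ch)
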