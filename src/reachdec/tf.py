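"""Time-frequency analysis: spectrograms, baseline-normalized ERD/ERS maps,
significance testing, per-subject band selection, and bandwidth curves.

Spectrogram convention: 0.5-s Hamming window, 10-ms hop, zero-padded to
the sample rate so bins fall on a 1-Hz grid, one-sided PSD scaling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy import signal as sps
from scipy import stats as spstats


class BandRole(str, Enum):
    GAMMA_ERS = "GAMMA_ERS"
    ALPHABETA_ERD = "ALPHABETA_ERD"
    SLOW = "SLOW"


@dataclass(frozen=True)
class BandSpec:
    """Per-subject frequency band.

    ``center`` +/- ``width``/2 is the selection band used for filtering;
    ``halfmax_band`` is the measured extent where the spectral response
    stays above 50% of its peak.
    """

    center: float
    width: float = 4.0
    halfmax_band: tuple[float, float] | None = None
    role: BandRole = BandRole.GAMMA_ERS
    peak_pct: float = 0.0

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("width must be > 0")
        if self.halfmax_band is not None:
            lo, hi = self.halfmax_band
            if not (lo < self.center < hi):
                raise ValueError("halfmax_band must bracket the center")

    @property
    def edges(self) -> tuple[float, float]:
        return (self.center - self.width / 2.0, self.center + self.width / 2.0)


@dataclass
class TFMap:
    power: np.ndarray  # [n_freqs x n_times], uV^2/Hz
    freqs: np.ndarray  # Hz, 1-Hz spacing
    times: np.ndarray  # seconds, window centers on a 10-ms grid
    window: float = 0.5

    def __post_init__(self) -> None:
        if np.any(self.power < 0):
            raise ValueError("power must be non-negative")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be strictly increasing")


@dataclass
class ErdErsMap:
    pct_change: np.ndarray  # [n_freqs x n_times], percent vs baseline
    freqs: np.ndarray
    times: np.ndarray  # seconds relative to alignment point
    baseline_interval: tuple[float, float] = (-2.0, -1.5)
    p_values: np.ndarray | None = None


def spectrogram(
    signal: np.ndarray,
    rate: float,
    window_s: float = 0.5,
    hop_s: float = 0.010,
    fmax: float | None = None,
    t_offset: float = 0.0,
) -> TFMap:
    """Short-time Fourier power of a 1-D signal.

    The window is zero-padded to ``rate`` samples so bins land at integer
    frequencies. ``t_offset`` shifts the reported times (e.g. to align
    trial windows to movement onset). ``fmax`` truncates the frequency
    axis to bound memory.
    """
    x = np.asarray(signal, dtype=float)
    nperseg = int(round(window_s * rate))
    if x.size < nperseg:
        raise ValueError(
            f"signal ({x.size} samples) shorter than the {window_s}-s window"
        )
    hop = int(round(hop_s * rate))
    nfft = int(round(rate))  # zero-pad to 1-Hz bins
    win = sps.get_window("hamming", nperseg)

    n_frames = (x.size - nperseg) // hop + 1
    idx = np.arange(nperseg)[None, :] + hop * np.arange(n_frames)[:, None]
    frames = x[idx] * win
    spec = np.fft.rfft(frames, n=nfft, axis=1)
    power = (np.abs(spec) ** 2).T  # [freq x time]
    # one-sided PSD scaling with Hamming window correction
    scale = 1.0 / (rate * np.sum(win**2))
    power *= scale
    power[1:-1] *= 2.0

    freqs = np.fft.rfftfreq(nfft, 1.0 / rate)
    times = (np.arange(n_frames) * hop + nperseg / 2.0) / rate + t_offset
    if fmax is not None:
        keep = freqs <= fmax
        freqs, power = freqs[keep], power[keep]
    return TFMap(power=power, freqs=freqs, times=times, window=window_s)


def _check_aligned(trials: list[TFMap]) -> tuple[np.ndarray, np.ndarray]:
    if len(trials) < 2:
        raise ValueError("need at least 2 trials")
    f0, t0 = trials[0].freqs, trials[0].times
    for tf in trials[1:]:
        if tf.power.shape != trials[0].power.shape:
            raise ValueError("trial TF maps must share shape")
    return f0, t0


def erders(
    trials: list[TFMap],
    baseline: tuple[float, float] = (-2.0, -1.5),
    per_trial_baseline: bool = False,
) -> ErdErsMap:
    """Trial-averaged percent power change relative to the pre-movement
    baseline: ``100 * (P(f,t) - Pb(f)) / Pb(f)``.

    With ``per_trial_baseline`` each trial is normalized by its own
    baseline before averaging; the default normalizes the trial-averaged
    power by the trial-averaged baseline.
    """
    freqs, times = _check_aligned(trials)
    b0, b1 = baseline
    bcols = (times >= b0) & (times < b1)
    if not np.any(bcols):
        raise ValueError("baseline interval outside the trial window")

    if per_trial_baseline:
        maps = []
        for tf in trials:
            pb = tf.power[:, bcols].mean(axis=1, keepdims=True)
            _raise_on_zero_baseline(pb[:, 0], freqs)
            maps.append(100.0 * (tf.power - pb) / pb)
        pct = np.mean(maps, axis=0)
    else:
        pbar = np.mean([tf.power for tf in trials], axis=0)
        pb = pbar[:, bcols].mean(axis=1, keepdims=True)
        _raise_on_zero_baseline(pb[:, 0], freqs)
        pct = 100.0 * (pbar - pb) / pb
    return ErdErsMap(
        pct_change=pct, freqs=freqs, times=times, baseline_interval=baseline
    )


def _raise_on_zero_baseline(pb: np.ndarray, freqs: np.ndarray) -> None:
    bad = np.flatnonzero(pb <= 0)
    if bad.size:
        raise ValueError(f"zero baseline power at {freqs[bad[0]]:.0f} Hz")


def ks_significance(
    trials: list[TFMap],
    baseline: tuple[float, float] = (-2.0, -1.5),
    time_step: int = 1,
) -> np.ndarray:
    """Two-sample Kolmogorov-Smirnov p-values per (frequency, time).

    At each (f, t) the across-trial sample of power values is compared
    with the across-trial sample of baseline power at the same frequency
    (one mid-baseline window per trial, so both samples are single-window
    estimates and exchangeable under the null). P-values are unadjusted.
    ``time_step`` subsamples the time axis (columns in between get the
    nearest computed value).
    """
    if len(trials) < 2:
        raise ValueError("need at least 2 trials")
    if len(trials) < 8:
        warnings.warn("fewer than 8 trials: KS p-values will be coarse")
    freqs, times = _check_aligned(trials)
    b0, b1 = baseline
    bcols = np.flatnonzero((times >= b0) & (times < b1))
    # one column per trial (the window centered mid-baseline), so both
    # samples are single-window estimates and exchangeable under the null
    mid = bcols[len(bcols) // 2]
    stack = np.stack([tf.power for tf in trials])  # [trial x f x t]
    base = stack[:, :, mid].T  # [f x trial]

    n_f, n_t = len(freqs), len(times)
    pvals = np.ones((n_f, n_t))
    cols = range(0, n_t, time_step)
    for fi in range(n_f):
        bsample = base[fi]
        for ti in cols:
            pvals[fi, ti] = spstats.ks_2samp(
                stack[:, fi, ti], bsample, method="asymp"
            ).pvalue
    if time_step > 1:
        for ti in range(n_t):
            src = min(round(ti / time_step) * time_step, n_t - 1)
            pvals[:, ti] = pvals[:, src]
    return pvals


def select_band(
    emap: ErdErsMap,
    search: tuple[float, float],
    mode: str = "ers",
    movement_interval: tuple[float, float] = (0.0, 1.0),
    selection_width: float = 4.0,
    alpha: float = 0.01,
) -> BandSpec:
    """Pick the frequency with maximal movement-interval ERD/ERS.

    The response per frequency is the mean percent change over the
    movement interval; ``mode`` selects the sign ("ers" for increases,
    "erd" for decreases). The selection band is center +/- 2 Hz; the
    half-max band is the contiguous run of bins around the center whose
    response exceeds 50% of the peak. Ties break toward lower frequency.

    If ``emap.p_values`` is present, the selection band must contain an
    above-chance fraction of significant movement cells (more than
    10 * ``alpha``, i.e. ten times the false-positive rate of the
    uncorrected per-cell tests); otherwise a "no movement-responsive
    band" error is raised. Any single cell reaching ``alpha`` is expected
    by chance alone across thousands of cells.
    """
    lo, hi = search
    fmask = (emap.freqs >= lo) & (emap.freqs <= hi)
    if not np.any(fmask):
        raise ValueError("search range outside the map frequencies")
    m0, m1 = movement_interval
    tmask = (emap.times >= m0) & (emap.times < m1)
    if not np.any(tmask):
        raise ValueError("movement interval outside the map times")

    resp_full = emap.pct_change[:, tmask].mean(axis=1)
    signed = resp_full if mode.lower() == "ers" else -resp_full
    sub = signed[fmask]
    sub_freqs = emap.freqs[fmask]
    ci = int(np.argmax(sub))  # argmax takes the first (lowest-f) maximum
    center = float(sub_freqs[ci])
    peak = float(sub[ci])

    if emap.p_values is not None:
        pv = emap.p_values[fmask][:, tmask]
        band_rows = np.abs(sub_freqs - center) <= selection_width / 2.0
        frac_sig = float(np.mean(pv[band_rows] < alpha))
        if frac_sig <= 10.0 * alpha:
            raise ValueError(
                "no movement-responsive band (significant-cell fraction "
                f"{frac_sig:.3f} not above chance at alpha={alpha})"
            )
    if peak <= 0:
        raise ValueError("no movement-responsive band (peak response <= 0)")

    # contiguous half-max run around the peak, in the full frequency axis
    full_idx = int(np.flatnonzero(fmask)[ci])
    above = signed >= 0.5 * peak
    i_lo = full_idx
    while i_lo > 0 and above[i_lo - 1]:
        i_lo -= 1
    i_hi = full_idx
    while i_hi < len(above) - 1 and above[i_hi + 1]:
        i_hi += 1
    # a single-bin run cannot bracket the center; widen to the neighbors
    i_lo = min(i_lo, max(full_idx - 1, 0))
    i_hi = max(i_hi, min(full_idx + 1, len(above) - 1))
    halfmax = (float(emap.freqs[i_lo]), float(emap.freqs[i_hi]))

    role = BandRole.GAMMA_ERS if mode.lower() == "ers" else BandRole.ALPHABETA_ERD
    signed_peak = peak if mode.lower() == "ers" else -peak
    return BandSpec(
        center=center,
        width=selection_width,
        halfmax_band=halfmax,
        role=role,
        peak_pct=signed_peak,
    )


def bandwidth_ratio_curve(
    trial_signals: list[np.ndarray],
    rate: float,
    center: float,
    widths: list[float],
    onset_index: int,
    move_interval: tuple[float, float] = (0.0, 1.0),
    rest_interval: tuple[float, float] = (-1.0, 0.0),
) -> list[tuple[float, float, float]]:
    """Movement/pre-movement band-power ratio (dB) vs filter bandwidth.

    For each width, trials are zero-phase band-pass filtered with a
    3rd-order Butterworth at center +/- width/2 and the ratio of mean power
    in ``move_interval`` to mean power in ``rest_interval`` (seconds
    relative to ``onset_index``) is averaged across trials. Returns
    ``(width, mean ratio in dB, standard error in dB)`` per width.
    """
    nyq = rate / 2.0
    out = []
    for width in widths:
        lo = max(center - width / 2.0, 0.1)
        hi = center + width / 2.0
        if hi >= nyq:
            raise ValueError(f"band {lo:.1f}-{hi:.1f} Hz exceeds Nyquist")
        sos = sps.butter(3, [lo, hi], btype="bandpass", fs=rate, output="sos")
        ratios_db = []
        for sig in trial_signals:
            filt = sps.sosfiltfilt(sos, np.asarray(sig, dtype=float))
            mi = slice(
                onset_index + int(round(move_interval[0] * rate)),
                onset_index + int(round(move_interval[1] * rate)),
            )
            ri = slice(
                onset_index + int(round(rest_interval[0] * rate)),
                onset_index + int(round(rest_interval[1] * rate)),
            )
            p_move = np.mean(filt[mi] ** 2)
            p_rest = np.mean(filt[ri] ** 2)
            ratios_db.append(10.0 * np.log10(p_move / p_rest))
        ratios_db = np.asarray(ratios_db)
        sem = float(np.std(ratios_db, ddof=1) / np.sqrt(len(ratios_db)))
        out.append((float(width), float(np.mean(ratios_db)), sem))
    return out
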