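"""Seeded synthetic-session generator with known ground truth.

The signal model per ECoG channel is additive:

* 1/f background noise (spectral exponent 1),
* an oscillatory comb: sinusoids at 2-Hz spacing with channel-specific
  random phases and equal baseline amplitude, whose per-component power is
  modulated during movement by sharp-peaked profiles centered on the
  alpha-beta (power drop, ERD) and gamma (power rise, ERS) bands,
* a slow (<2 Hz) component equal to the lag-advanced projection of the 3-D
  minimum-jerk reach velocity through an encoding matrix.

The modulation profile equals 1 at the band center and 0.5 at
center +/- width/2, so the measured percent power change peaks at the
configured center with the configured half-maximum width — matching the
convention that a band's "width" is where the response is above 50% of its
peak. Using a deterministic comb (rather than filtered noise) keeps the
trial-to-trial variance of spectral estimates near zero, so configured
effect sizes are recovered tightly; the comb grid is parity-aligned to the
band centers and cross-line beats cancel over the analysis windows.

EMG is baseline noise plus an amplitude burst spanning each movement;
kinematics are the minimum-jerk speed times a per-trial reach vector,
sampled at the kinematics rate, with optional observation noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import signal as sps

from .session import (
    Direction,
    EventMarker,
    MarkerKind,
    SessionRecording,
    save_session,
)

N_ECOG = 8

#: Reach directions: unit vectors with all three components non-zero so
#: every kinematic axis carries signal (lateral, forward, upward).
DIRECTION_VECTORS = {
    Direction.RTL: np.array([-0.62, 0.54, 0.57]),
    Direction.RTM: np.array([0.30, 0.77, 0.56]),
    Direction.RTR: np.array([0.62, 0.54, 0.57]),
}


@dataclass(frozen=True)
class SimBand:
    """Narrowband spectral effect: center/width in Hz, effect in percent
    power change during movement (positive = ERS, negative = ERD). The
    width is the half-maximum extent of the effect's spectral profile."""

    center: float
    width: float
    effect_pct: float

    def profile(self, freqs: np.ndarray) -> np.ndarray:
        """Sharp-peaked modulation shape 2^(-|2 df / width|): 1 at the
        center, 0.5 at +/- width/2, falling steeply around the peak."""
        df = np.abs(np.asarray(freqs) - self.center)
        return np.exp2(-2.0 * df / self.width)


@dataclass
class SimConfig:
    n_trials_per_direction: int = 40
    directions: tuple[Direction, ...] = (
        Direction.RTL,
        Direction.RTM,
        Direction.RTR,
    )
    rest_range: tuple[float, float] = (6.0, 8.0)
    move_duration_range: tuple[float, float] = (1.0, 3.0)
    reach_distance_range: tuple[float, float] = (30.0, 40.0)
    reaction_time_range: tuple[float, float] = (0.2, 0.5)
    gamma_band: SimBand = field(
        default_factory=lambda: SimBand(155.0, 19.0, 281.0)
    )
    alphabeta_band: SimBand = field(
        default_factory=lambda: SimBand(22.0, 10.0, -87.0)
    )
    comb_amp: float = 6.0  # baseline amplitude per comb component, microvolts
    comb_range: tuple[float, float] = (8.0, 316.0)  # Hz, 2-Hz spacing
    slow_gain: float = 0.6  # microvolts per cm/s, scales the encoding matrix
    lag_true: float = 0.100  # seconds; ECoG leads kinematics by this much
    noise_1f_scale: float = 6.0  # background RMS, microvolts
    emg_snr: float = 10.0
    kin_noise_frac: float = 0.10  # kinematic observation noise / RMS speed
    tremor_frac: float = 0.0  # 2-4.5 Hz submovement RMS / per-trial peak speed
    direction_jitter: float = 0.2  # per-trial scatter of the reach vector
    blink_trials: tuple[int, ...] = ()
    blink_amplitude: float = 150.0
    n_eeg: int = 2
    shared_encoding: bool = True
    rate_ecog: float = 1200.0
    rate_kin: float = 40.0
    edge_ramp: float = 0.05  # seconds, raised-cosine envelope edges
    band_overhang: float = 0.04  # band modulation extends past the movement
    # interval so its half-max duration matches the EMG-detector duration
    # (the 100-ms smoother widens detected bursts by ~30 ms per side)
    band_duration_jitter: float = 0.25  # s, per-edge scatter of the band
    # modulation relative to the movement (cortical and muscle activity
    # durations correlate but do not match exactly)
    seed: int = 0

    def validate(self) -> None:
        nyq = self.rate_ecog / 2.0
        for band in (self.gamma_band, self.alphabeta_band):
            lo = band.center - band.width / 2.0
            hi = band.center + band.width / 2.0
            if not (0.0 < lo < hi < nyq):
                raise ValueError(
                    f"band {band.center}±{band.width / 2} Hz outside (0, {nyq})"
                )
        if self.lag_true < 0:
            raise ValueError("lag_true must be >= 0")
        for name in ("noise_1f_scale", "emg_snr"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class GroundTruth:
    onset_times: np.ndarray
    offset_times: np.ndarray
    go_times: np.ndarray
    directions: list[Direction]
    durations: np.ndarray
    distances: np.ndarray
    beta_true: np.ndarray  # [n_ecog x 3] velocity -> channel loading
    lag_true: float
    blink_trials: tuple[int, ...]
    velocity: np.ndarray  # [3 x n_kin] noiseless velocity at rate_kin


# Table-style presets: (alpha-beta peak Hz, ERD %, ab width Hz,
#                       gamma peak Hz, ERS %, gamma width Hz)
_PRESETS = {
    1: (22.0, 87.0, 10.0, 155.0, 281.0, 19.0),
    2: (24.0, 54.0, 20.0, 64.0, 247.0, 8.0),
    3: (22.0, 52.0, 22.0, 77.0, 114.0, 14.0),
}


def preset(participant: int, **overrides) -> SimConfig:
    """Per-subject simulation presets with published spectral effect sizes."""
    if participant not in _PRESETS:
        raise ValueError(f"unknown preset {participant!r}; choose 1, 2 or 3")
    ab_peak, erd, ab_w, g_peak, ers, g_w = _PRESETS[participant]
    cfg = SimConfig(
        gamma_band=SimBand(g_peak, g_w, ers),
        alphabeta_band=SimBand(ab_peak, ab_w, -erd),
    )
    return replace(cfg, **overrides) if overrides else cfg


def min_jerk_velocity(distance: float, duration: float, rate: float) -> np.ndarray:
    """Speed profile of a straight minimum-jerk reach.

    v(t) = (D/T) * (30 tau^2 - 60 tau^3 + 30 tau^4), tau = t/T, sampled at
    ``rate`` on [0, T]; endpoint speeds are zero and the profile integrates
    to ``distance``. Peak speed is 1.875 * D/T at tau = 0.5.
    """
    if distance <= 0 or duration <= 0 or rate <= 0:
        raise ValueError("distance, duration and rate must be > 0")
    t = np.arange(0.0, duration + 0.5 / rate, 1.0 / rate)
    tau = np.clip(t / duration, 0.0, 1.0)
    return (distance / duration) * (30 * tau**2 - 60 * tau**3 + 30 * tau**4)


def _min_jerk_at(t: np.ndarray, distance: float, duration: float) -> np.ndarray:
    """Minimum-jerk speed evaluated at arbitrary times (0 outside [0, T])."""
    tau = t / duration
    inside = (tau >= 0.0) & (tau <= 1.0)
    tau = np.where(inside, tau, 0.0)
    prof = (distance / duration) * (30 * tau**2 - 60 * tau**3 + 30 * tau**4)
    return np.where(inside, prof, 0.0)


def _one_over_f(rng: np.random.Generator, n: int, rate: float, rms: float) -> np.ndarray:
    """Gaussian noise with a 1/f amplitude spectrum, unit exponent."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, 1.0 / rate)
    shaping = np.ones_like(freqs)
    nz = freqs > 0
    shaping[nz] = 1.0 / np.sqrt(freqs[nz])
    shaping[0] = 0.0
    x = np.fft.irfft(spec * shaping, n)
    return x * (rms / np.std(x))


def _static_comb(
    n: int, rate: float, freqs: np.ndarray, amps: np.ndarray,
    phases: np.ndarray,
) -> np.ndarray:
    """Sum of sinusoids a_f * sin(2*pi*f*t + phi_f) synthesized via an
    inverse FFT (frequencies must sit on the n-sample FFT grid)."""
    spec = np.zeros(n // 2 + 1, dtype=complex)
    bins = np.round(freqs * n / rate).astype(int)
    spec[bins] = (n / 2.0) * amps * np.exp(1j * (phases - np.pi / 2.0))
    return np.fft.irfft(spec, n)


def _box_envelope(
    t: np.ndarray, start: float, stop: float, ramp: float
) -> np.ndarray:
    """Raised-cosine-edged boxcar supported exactly on [start, stop]
    (the ramps lie inside the interval)."""
    env = np.zeros_like(t)
    core = (t >= start + ramp) & (t <= stop - ramp)
    env[core] = 1.0
    if ramp > 0:
        up = (t >= start) & (t < start + ramp)
        env[up] = 0.5 * (1 - np.cos(np.pi * (t[up] - start) / ramp))
        down = (t > stop - ramp) & (t <= stop)
        env[down] = 0.5 * (1 - np.cos(np.pi * (stop - t[down]) / ramp))
    return env


def simulate_session(cfg: SimConfig) -> tuple[SessionRecording, GroundTruth]:
    """Generate one session; deterministic given ``cfg.seed``."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    # ---- trial schedule ------------------------------------------------
    n_trials = cfg.n_trials_per_direction * len(cfg.directions)
    dirs = [d for d in cfg.directions for _ in range(cfg.n_trials_per_direction)]
    rng.shuffle(dirs)

    durations = rng.uniform(*cfg.move_duration_range, size=n_trials)
    distances = rng.uniform(*cfg.reach_distance_range, size=n_trials)
    reaction = rng.uniform(*cfg.reaction_time_range, size=n_trials)
    rests = rng.uniform(*cfg.rest_range, size=n_trials)

    onsets = np.empty(n_trials)
    t_cursor = 5.0  # lead-in so the first pre-window fits
    for i in range(n_trials):
        t_cursor += rests[i]
        onsets[i] = t_cursor
        t_cursor += durations[i]
    total_dur = float(np.ceil(t_cursor + 9.0))  # post-window tail

    offsets = onsets + durations
    go_times = onsets - reaction

    n_hi = int(round(total_dur * cfg.rate_ecog))
    n_kin = int(round(total_dur * cfg.rate_kin))
    t_hi = np.arange(n_hi) / cfg.rate_ecog
    t_kin = np.arange(n_kin) / cfg.rate_kin

    # ---- kinematics ----------------------------------------------------
    # optional tremor: per-trial random sinusoids (2-4.5 Hz), a continuous-
    # time waveform so the kinematics and the lag-advanced cortical drive
    # sample the identical trajectory
    n_trem = 6
    trem_freqs = rng.uniform(2.0, 4.5, size=(n_trials, n_trem))
    trem_phases = rng.uniform(0.0, 2.0 * np.pi, size=(n_trials, n_trem))
    trem_amps = rng.uniform(0.5, 1.0, size=(n_trials, n_trem))
    trem_amps /= np.sqrt(np.sum(trem_amps**2, axis=1, keepdims=True) / 2.0)

    # per-trial reach vectors: nominal target direction plus scatter
    trial_vecs = []
    for d in dirs:
        u = DIRECTION_VECTORS[d] + cfg.direction_jitter * rng.standard_normal(3)
        trial_vecs.append(u / np.linalg.norm(u))
    trial_vecs = np.asarray(trial_vecs)

    def trial_speed(i: int, t: np.ndarray) -> np.ndarray:
        """Speed profile of trial i at session times ``t``."""
        onset, dur, dist = onsets[i], durations[i], distances[i]
        speed = _min_jerk_at(t - onset, dist, dur)
        if cfg.tremor_frac > 0:
            peak = 1.875 * dist / dur
            wig = np.zeros_like(t)
            for k in range(n_trem):
                wig += trem_amps[i, k] * np.sin(
                    2.0 * np.pi * trem_freqs[i, k] * (t - onset)
                    + trem_phases[i, k]
                )
            taper = _box_envelope(t - onset, 0.0, dur, min(0.2, dur / 4))
            speed = speed + cfg.tremor_frac * peak * wig * taper
        return speed

    def velocity_at(t: np.ndarray) -> np.ndarray:
        v = np.zeros((3, len(t)))
        for i in range(n_trials):
            speed = trial_speed(i, t)
            nzmask = speed != 0
            if np.any(nzmask):
                v[:, nzmask] += np.outer(trial_vecs[i], speed[nzmask])
        return v

    v_kin_clean = velocity_at(t_kin)
    speed = np.linalg.norm(v_kin_clean, axis=0)
    moving = speed > 0
    # noise scale: fraction of the RMS speed during movement
    rms_speed = float(np.sqrt(np.mean(speed[moving] ** 2))) if np.any(moving) else 1.0
    kin_noise = cfg.kin_noise_frac * rms_speed * rng.standard_normal(v_kin_clean.shape)
    kinematics = v_kin_clean + kin_noise

    # ---- ECoG ----------------------------------------------------------
    g = cfg.gamma_band
    ab = cfg.alphabeta_band
    nyq = cfg.rate_ecog / 2.0
    comb_lo, comb_hi = cfg.comb_range
    comb_lo = max(int(np.ceil(comb_lo)), 1)
    comb_hi = int(min(comb_hi, nyq - 50.0))
    # 2-Hz spacing, parity-aligned to each band's center so a comb line
    # sits exactly on the peak; cross-line beats are then all at even
    # frequencies and integrate to zero over 0.5-s and 1-s analysis means.
    split = 0.5 * (ab.center + g.center)
    all_f = np.arange(comb_lo, comb_hi + 1, dtype=float)
    lo_par = int(round(ab.center)) % 2
    hi_par = int(round(g.center)) % 2
    comb_freqs = np.concatenate([
        all_f[(all_f < split) & (all_f.astype(int) % 2 == lo_par)],
        all_f[(all_f >= split) & (all_f.astype(int) % 2 == hi_par)],
    ])
    # leave a spectral gap at center +/- 2 Hz of each band so the 4-Hz
    # detection band holds a single line: its windowed power is then free
    # of intra-band beating and stays steady at rest (the skipped bins of
    # the ERD/ERS curve are filled in by window leakage from the center)
    for band in (g, ab):
        comb_freqs = comb_freqs[np.abs(np.abs(comb_freqs - band.center) - 2.0) > 0.5]
    # per-component power modulation during movement:
    #   P(f, move) / P(f, rest) = 1 + sum of signed band effects.
    # The injected effects are pre-compensated for the one systematic
    # attenuation of the downstream ERD/ERS estimate: edge coverage
    # (0.5-s analysis windows straddling the movement onset dilute the
    # [0, 1]-s movement mean), so that the *measured* percent change
    # matches the configured one.
    coverage = 0.90  # empirical, for the [0, 1]-s movement interval
    boost = 1.0 / coverage
    effect = (
        g.effect_pct / 100.0 * boost * g.profile(comb_freqs)
        + ab.effect_pct / 100.0 * boost * ab.profile(comb_freqs)
    )
    effect = np.clip(effect, -0.97, None)
    # components whose amplitude actually changes need time-domain synthesis
    dyn = np.abs(effect) > 0.02
    phases = rng.uniform(0.0, 2.0 * np.pi, size=(N_ECOG, comb_freqs.size))
    # the two motor-strip contacts see the source in anti-phase, so the
    # bipolar derivation (contact 1 - contact 0) doubles the oscillatory
    # components instead of possibly cancelling them
    phases[1] = phases[0] + np.pi

    # Encoding matrix: velocity (3) -> slow component per channel (8).
    beta_true = cfg.slow_gain * rng.uniform(0.5, 1.5, size=(N_ECOG, 3)) * rng.choice(
        [-1.0, 1.0], size=(N_ECOG, 3)
    )
    if cfg.shared_encoding:
        slow_hi = beta_true @ velocity_at(t_hi + cfg.lag_true)
    else:
        # Direction-specific (near-orthogonal) encodings: each direction's
        # velocity is projected through its own loading matrix.
        slow_hi = np.zeros((N_ECOG, n_hi))
        per_dir = {
            d: cfg.slow_gain
            * rng.uniform(0.5, 1.5, size=(N_ECOG, 3))
            * rng.choice([-1.0, 1.0], size=(N_ECOG, 3))
            for d in cfg.directions
        }
        for i, d in enumerate(dirs):
            speed = trial_speed(i, t_hi + cfg.lag_true)
            slow_hi += per_dir[d] @ np.outer(trial_vecs[i], speed)
        beta_true = per_dir[cfg.directions[0]]

    amps = np.full(comb_freqs.size, cfg.comb_amp)
    ecog = np.empty((N_ECOG, n_hi))
    for ch in range(N_ECOG):
        bg = _one_over_f(rng, n_hi, cfg.rate_ecog, cfg.noise_1f_scale)
        comb = _static_comb(n_hi, cfg.rate_ecog, comb_freqs, amps, phases[ch])
        ecog[ch] = bg + comb + slow_hi[ch]

    # movement-locked amplitude correction for the dynamic comb components:
    # delta_f(t) = a_f * (sqrt(1 + effect_f * env(t)) - 1) * sin(2 pi f t + phi)
    dfreqs = comb_freqs[dyn]
    deff = effect[dyn]
    damp = amps[dyn]
    # cortical band modulation leads the EMG-defined movement by the
    # corticokinematic lag, like the slow component; its envelope's
    # half-maximum points overhang the movement interval symmetrically
    ramp = 2.0 * cfg.edge_ramp
    pad = cfg.band_overhang + cfg.edge_ramp
    # onset-edge timing is tight (it drives detection); persistence varies
    edge_jit = rng.normal(0.0, 1.0, size=(n_trials, 2))
    edge_jit[:, 0] *= cfg.band_duration_jitter / 3.0
    edge_jit[:, 1] *= cfg.band_duration_jitter * 4.0 / 3.0
    for i, (onset, offset) in enumerate(
        zip(onsets - cfg.lag_true, offsets - cfg.lag_true)
    ):
        start = onset - pad - edge_jit[i, 0]
        stop = offset + pad + edge_jit[i, 1]
        stop = max(stop, start + 2 * ramp + 0.1)
        i0 = max(int(round(start * cfg.rate_ecog)), 0)
        i1 = min(int(round(stop * cfg.rate_ecog)) + 1, n_hi)
        tseg = t_hi[i0:i1]
        env_seg = _box_envelope(tseg, start, stop, ramp)
        gain = np.sqrt(1.0 + deff[:, None] * env_seg[None, :]) - 1.0  # [f x t]
        arg = 2.0 * np.pi * dfreqs[:, None] * tseg[None, :]
        u = gain * np.sin(arg)  # modulated in-phase part
        w = gain * np.cos(arg)  # modulated quadrature part
        for ch in range(N_ECOG):
            cph = np.cos(phases[ch, dyn]) * damp
            sph = np.sin(phases[ch, dyn]) * damp
            ecog[ch, i0:i1] += cph @ u + sph @ w

    # ---- EMG -----------------------------------------------------------
    emg_base_sd = 4.0
    emg_noise = rng.standard_normal(n_hi)
    burst_env = np.zeros(n_hi)
    for onset, offset in zip(onsets, offsets):
        burst_env = np.maximum(
            burst_env, _box_envelope(t_hi, onset, offset, cfg.edge_ramp)
        )
    emg = emg_base_sd * emg_noise * (1.0 + cfg.emg_snr * burst_env)
    # band-limit to the recorded EMG range so baseline statistics are tame
    sos = sps.butter(4, [20.0, 500.0], btype="bandpass", fs=cfg.rate_ecog,
                     output="sos")
    emg = sps.sosfiltfilt(sos, emg)
    emg = np.atleast_2d(emg)

    # ---- EEG (for blink rejection) ------------------------------------
    eeg = None
    if cfg.n_eeg > 0:
        eeg = np.vstack(
            [_one_over_f(rng, n_hi, cfg.rate_ecog, 5.0) for _ in range(cfg.n_eeg)]
        )
        for ti in cfg.blink_trials:
            if ti < 0 or ti >= n_trials:
                raise ValueError(f"blink trial index {ti} out of range")
            center = onsets[ti] + 1.0
            pulse = cfg.blink_amplitude * np.exp(
                -0.5 * ((t_hi - center) / 0.08) ** 2
            )
            eeg += pulse

    # ---- markers -------------------------------------------------------
    markers = []
    for go, onset, offset, d in zip(go_times, onsets, offsets, dirs):
        markers.append(EventMarker(time=float(go), kind=MarkerKind.GO, direction=d))
        markers.append(
            EventMarker(time=float(onset), kind=MarkerKind.EMG_ONSET, direction=d)
        )
        markers.append(
            EventMarker(time=float(offset), kind=MarkerKind.EMG_OFFSET, direction=d)
        )
    markers.sort(key=lambda m: m.time)

    rec = SessionRecording(
        ecog=ecog,
        emg=emg,
        eeg=eeg,
        kinematics=kinematics,
        rate_ecog=cfg.rate_ecog,
        rate_kin=cfg.rate_kin,
        markers=markers,
        eeg_labels=["EEG_FP1", "EEG_FZ"][: cfg.n_eeg]
        if cfg.n_eeg <= 2
        else [f"EEG_{i}" for i in range(cfg.n_eeg)],
    )
    truth = GroundTruth(
        onset_times=onsets,
        offset_times=offsets,
        go_times=go_times,
        directions=list(dirs),
        durations=durations,
        distances=distances,
        beta_true=beta_true,
        lag_true=cfg.lag_true,
        blink_trials=cfg.blink_trials,
        velocity=v_kin_clean,
    )
    return rec, truth


def save_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    payload = {
        "onset_times": truth.onset_times.tolist(),
        "offset_times": truth.offset_times.tolist(),
        "go_times": truth.go_times.tolist(),
        "directions": [d.value for d in truth.directions],
        "durations": truth.durations.tolist(),
        "distances": truth.distances.tolist(),
        "beta_true": truth.beta_true.tolist(),
        "lag_true": truth.lag_true,
        "blink_trials": list(truth.blink_trials),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
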