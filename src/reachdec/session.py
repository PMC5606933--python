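"""Session data model and I/O.

A session bundles multichannel ECoG/EMG/EEG signals sampled at a common
high rate with 3-D kinematics sampled at a lower rate and a list of timed
event markers. Signals are stored in an EDF file; kinematics and markers
live in delimited-text sidecar files next to it.

Conventions: times in seconds from session start, intervals half-open
``[start, end)``, sample indices 0-based. Kinematics and high-rate signals
are kept at their native rates; alignment happens downstream.
"""

from __future__ import annotations

import csv
import logging
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np

from .edf import EdfFile, EdfSignalHeader, read_edf, write_edf

log = logging.getLogger(__name__)

EDF_NAME = "session.edf"
KIN_NAME = "kinematics.tsv"
MARKER_NAME = "markers.tsv"


class MarkerKind(str, Enum):
    GO = "GO"
    EMG_ONSET = "EMG_ONSET"
    EMG_OFFSET = "EMG_OFFSET"
    TRIAL_REJECT = "TRIAL_REJECT"


class Direction(str, Enum):
    RTL = "RTL"
    RTM = "RTM"
    RTR = "RTR"
    NONE = "NONE"


@dataclass(frozen=True)
class EventMarker:
    time: float
    kind: MarkerKind
    direction: Direction = Direction.NONE

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError(f"marker time must be >= 0, got {self.time}")
        if self.kind == MarkerKind.GO and self.direction == Direction.NONE:
            raise ValueError("GO markers require a direction")


@dataclass
class SessionRecording:
    """Multirate recording container.

    ``ecog``/``emg``/``eeg`` are [n_channels x n_samples] arrays in
    microvolts at ``rate_ecog``; ``kinematics`` is [3 x n_kin] in cm/s at
    ``rate_kin``.
    """

    ecog: np.ndarray
    emg: np.ndarray
    kinematics: np.ndarray
    rate_ecog: float = 1200.0
    rate_kin: float = 40.0
    eeg: np.ndarray | None = None
    markers: list[EventMarker] = field(default_factory=list)
    ecog_labels: list[str] = field(default_factory=list)
    emg_labels: list[str] = field(default_factory=list)
    eeg_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.ecog = np.atleast_2d(np.asarray(self.ecog, dtype=float))
        self.emg = np.atleast_2d(np.asarray(self.emg, dtype=float))
        self.kinematics = np.atleast_2d(np.asarray(self.kinematics, dtype=float))
        if self.eeg is not None:
            self.eeg = np.atleast_2d(np.asarray(self.eeg, dtype=float))
        if not self.ecog_labels:
            self.ecog_labels = [f"ECOG{i}" for i in range(self.ecog.shape[0])]
        if not self.emg_labels:
            self.emg_labels = [f"EMG_{i}" for i in range(self.emg.shape[0])]
        if self.eeg is not None and not self.eeg_labels:
            self.eeg_labels = [f"EEG_{i}" for i in range(self.eeg.shape[0])]
        self.validate()

    # -- validation ------------------------------------------------------

    def validate(self) -> None:
        n = self.ecog.shape[1]
        if self.emg.shape[1] != n:
            raise ValueError("ECoG and EMG sample counts differ")
        if self.eeg is not None and self.eeg.shape[1] != n:
            raise ValueError("ECoG and EEG sample counts differ")
        if self.kinematics.shape[0] != 3:
            raise ValueError("kinematics must have 3 rows (vx, vy, vz)")
        dur = self.duration
        kin_dur = self.kinematics.shape[1] / self.rate_kin
        if abs(kin_dur - dur) > 1.0 / self.rate_kin + 1e-9:
            raise ValueError(
                f"kinematics duration {kin_dur:.3f}s does not match signal "
                f"duration {dur:.3f}s within one kinematics sample"
            )
        for m in self.markers:
            if not (0 <= m.time <= dur):
                raise ValueError(
                    f"marker at t={m.time}s lies outside session [0, {dur:.3f}]"
                )

    @property
    def duration(self) -> float:
        """Session length in seconds at the high rate."""
        return self.ecog.shape[1] / self.rate_ecog

    @property
    def n_samples(self) -> int:
        return self.ecog.shape[1]

    # -- channel access --------------------------------------------------

    def channel(self, label: str) -> np.ndarray:
        for labels, block in (
            (self.ecog_labels, self.ecog),
            (self.emg_labels, self.emg),
            (self.eeg_labels, self.eeg if self.eeg is not None else None),
        ):
            if block is None:
                continue
            if label in labels:
                return block[labels.index(label)]
        raise KeyError(f"unknown channel label {label!r}")

    def markers_of(self, kind: MarkerKind) -> list[EventMarker]:
        return [m for m in self.markers if m.kind == kind]


@dataclass
class Trial:
    """A window around one movement onset, as views into the session."""

    onset_time: float
    direction: Direction
    pre: float
    post: float
    ecog: np.ndarray
    emg: np.ndarray
    kinematics: np.ndarray
    eeg: np.ndarray | None
    rate_ecog: float
    rate_kin: float
    index: int = 0
    rejected: bool = False
    reject_reason: str = ""

    @property
    def window(self) -> tuple[float, float]:
        return (self.onset_time - self.pre, self.onset_time + self.post)

    @property
    def duration(self) -> float:
        return self.pre + self.post

    def times_ecog(self) -> np.ndarray:
        """Sample times relative to onset for the high-rate channels."""
        n = self.ecog.shape[1]
        return np.arange(n) / self.rate_ecog - self.pre


# -- epoching ------------------------------------------------------------


def extract_trials(
    rec: SessionRecording,
    onsets: list[float],
    pre: float = 4.0,
    post: float = 8.0,
    directions: list[Direction] | None = None,
) -> list[Trial]:
    """Cut one trial per onset time: ``[onset-pre, onset+post)``.

    Trials whose window does not fit inside the recording are dropped with
    a warning. Sample index 0 of each trial maps to session sample
    ``round((onset - pre) * rate)`` for every channel group at its rate.
    """
    trials: list[Trial] = []
    order = np.argsort(onsets)
    len_hi = int(round((pre + post) * rec.rate_ecog))
    len_kin = int(round((pre + post) * rec.rate_kin))
    for idx, oi in enumerate(order):
        onset = float(onsets[oi])
        start = onset - pre
        stop = onset + post
        if start < 0 or stop > rec.duration + 1e-9:
            log.warning(
                "dropping trial at onset %.3fs: window [%.3f, %.3f) outside "
                "recording [0, %.3f)", onset, start, stop, rec.duration,
            )
            continue
        i0 = int(round(start * rec.rate_ecog))
        k0 = int(round(start * rec.rate_kin))
        i1 = min(i0 + len_hi, rec.n_samples)
        k1 = min(k0 + len_kin, rec.kinematics.shape[1])
        direction = Direction.NONE
        if directions is not None:
            direction = directions[oi]
        trials.append(
            Trial(
                onset_time=onset,
                direction=direction,
                pre=pre,
                post=post,
                ecog=rec.ecog[:, i0:i1],
                emg=rec.emg[:, i0:i1],
                kinematics=rec.kinematics[:, k0:k1],
                eeg=rec.eeg[:, i0:i1] if rec.eeg is not None else None,
                rate_ecog=rec.rate_ecog,
                rate_kin=rec.rate_kin,
                index=len(trials),
            )
        )
    return trials


def reject_blink_trials(
    trials: list[Trial],
    eeg_frontal: np.ndarray | None,
    z_thresh: float = 5.0,
) -> list[Trial]:
    """Flag trials whose frontal-EEG amplitude is an outlier.

    A trial is rejected when the absolute deviation of any frontal-EEG
    sample inside its window exceeds ``z_thresh`` robust standard
    deviations (1.4826 * MAD about the median) of the session-wide frontal
    signal. Returns the same list; rejected trials get ``rejected=True``.
    """
    if z_thresh <= 0:
        raise ValueError("z_thresh must be > 0")
    if eeg_frontal is None or np.size(eeg_frontal) == 0:
        warnings.warn("no EEG channels available; blink rejection skipped")
        return trials
    frontal = np.atleast_2d(np.asarray(eeg_frontal, dtype=float))
    med = np.median(frontal, axis=1, keepdims=True)
    mad = np.median(np.abs(frontal - med), axis=1, keepdims=True)
    robust_sd = 1.4826 * mad
    robust_sd[robust_sd == 0] = np.inf
    for trial in trials:
        if trial.eeg is None:
            continue
        dev = np.abs(trial.eeg - med) / robust_sd
        if np.max(dev) > z_thresh:
            trial.rejected = True
            trial.reject_reason = "blink"
    return trials


# -- disk layout ---------------------------------------------------------


def save_session(rec: SessionRecording, path: str | Path) -> Path:
    """Write a session directory: EDF signals + TSV kinematics/markers.

    EDF quantizes to 16 bits over a symmetric physical range per channel;
    signals already on that grid round-trip bit-exactly.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    signals, headers = [], []
    spr = int(round(rec.rate_ecog))
    blocks = [(rec.ecog_labels, rec.ecog), (rec.emg_labels, rec.emg)]
    if rec.eeg is not None:
        blocks.append((rec.eeg_labels, rec.eeg))
    for labels, block in blocks:
        for lab, sig in zip(labels, block):
            amax = float(np.max(np.abs(sig))) if sig.size else 1.0
            # power-of-two range: re-saving loaded data reuses the same
            # quantization grid, making save->load idempotent
            amax = float(2.0 ** np.ceil(np.log2(max(amax, 1e-6))))
            headers.append(
                EdfSignalHeader(
                    label=lab,
                    physical_min=-amax,
                    physical_max=amax,
                    samples_per_record=spr,
                )
            )
            signals.append(np.asarray(sig, dtype=float))
    write_edf(path / EDF_NAME, EdfFile(signals=signals, headers=headers))

    with open(path / KIN_NAME, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["time_s", "vx", "vy", "vz"])
        times = np.arange(rec.kinematics.shape[1]) / rec.rate_kin
        for t, (vx, vy, vz) in zip(times, rec.kinematics.T):
            writer.writerow(
                [f"{t:.6f}"] + [f"{float(v):.17g}" for v in (vx, vy, vz)]
            )

    with open(path / MARKER_NAME, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["time_s", "kind", "direction"])
        for m in rec.markers:
            writer.writerow(
                [f"{float(m.time):.17g}", m.kind.value, m.direction.value]
            )

    return path


def load_session(path: str | Path) -> SessionRecording:
    """Load a session directory written by :func:`save_session`.

    Sample rates come from the EDF header (samples per 1-s record).
    Channel roles are inferred from label prefixes (ECOG/EMG/EEG).
    """
    path = Path(path)
    edf_path = path / EDF_NAME
    if not edf_path.exists():
        raise FileNotFoundError(f"missing signal file: {edf_path}")
    for sidecar in (KIN_NAME, MARKER_NAME):
        if not (path / sidecar).exists():
            raise FileNotFoundError(f"missing sidecar file: {path / sidecar}")

    edf = read_edf(edf_path)
    rates = {h.samples_per_record / edf.record_duration for h in edf.headers}
    if len(rates) != 1:
        raise ValueError(f"mixed sample rates in EDF: {sorted(rates)}")
    rate_ecog = rates.pop()

    groups: dict[str, tuple[list[str], list[np.ndarray]]] = {
        "ECOG": ([], []),
        "EMG": ([], []),
        "EEG": ([], []),
    }
    for hdr, sig in zip(edf.headers, edf.signals):
        for prefix in groups:
            if hdr.label.upper().startswith(prefix):
                groups[prefix][0].append(hdr.label)
                groups[prefix][1].append(sig)
                break
        else:
            raise ValueError(f"unrecognized channel label {hdr.label!r}")
    if not groups["ECOG"][0]:
        raise ValueError("no ECOG channels found")

    kin_rows = []
    with open(path / KIN_NAME, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or "time_s" not in reader.fieldnames:
            raise ValueError(f"{KIN_NAME} requires a header row with time_s")
        for row in reader:
            kin_rows.append(
                (float(row["time_s"]), float(row["vx"]), float(row["vy"]),
                 float(row["vz"]))
            )
    kin = np.array([[r[1], r[2], r[3]] for r in kin_rows]).T
    if len(kin_rows) >= 2:
        dt = np.diff([r[0] for r in kin_rows])
        rate_kin = 1.0 / float(np.median(dt))
    else:
        rate_kin = 40.0

    markers = []
    with open(path / MARKER_NAME, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            markers.append(
                EventMarker(
                    time=float(row["time_s"]),
                    kind=MarkerKind(row["kind"]),
                    direction=Direction(row.get("direction", "NONE")),
                )
            )

    n_true = kin.shape[1] and int(round(kin.shape[1] / rate_kin * rate_ecog))
    ecog = np.array(groups["ECOG"][1])
    emg = np.array(groups["EMG"][1]) if groups["EMG"][0] else np.empty((0, ecog.shape[1]))
    eeg = np.array(groups["EEG"][1]) if groups["EEG"][0] else None
    # EDF pads to whole records; trim back using the kinematics duration.
    if n_true and ecog.shape[1] >= n_true:
        ecog = ecog[:, :n_true]
        emg = emg[:, :n_true] if emg.size else emg
        if eeg is not None:
            eeg = eeg[:, :n_true]
    if emg.shape[0] == 0:
        emg = np.empty((0, ecog.shape[1]))

    return SessionRecording(
        ecog=ecog,
        emg=emg,
        eeg=eeg,
        kinematics=kin,
        rate_ecog=rate_ecog,
        rate_kin=round(rate_kin, 6),
        markers=markers,
        ecog_labels=groups["ECOG"][0],
        emg_labels=groups["EMG"][0],
        eeg_labels=groups["EEG"][0],
    )
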