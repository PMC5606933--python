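# reachdec

Movement-onset detection and 3-D arm-velocity reconstruction from
few-channel ECoG, with a seeded synthetic-session simulator for end-to-end
validation against known ground truth.

The toolkit covers the full analysis chain for reach experiments recorded
with 8 ECoG contacts (1200 Hz), surface EMG, optional frontal EEG, and
3-D kinematics (40 Hz):

- **Session model & I/O** (`reachdec.session`) — multirate recording
  container, EDF signal storage with delimited-text sidecars for
  kinematics and event markers, trial epoching, and automated blink-trial
  rejection from frontal EEG.
- **Simulator** (`reachdec.simulate`) — seeded sessions with configurable
  per-subject spectral effects (alpha-beta ERD, gamma ERS as percent power
  change with a given peak frequency and half-max bandwidth), a slow
  cortical component encoding the minimum-jerk reach velocity at a
  configurable corticokinematic lag, EMG bursts, and eye-blink artifacts.
  Presets 1–3 reproduce published per-subject effect sizes.
- **Preprocessing** (`reachdec.preprocess`) — zero-phase 20–500 Hz EMG
  band-pass, 3-SD EMG burst/onset detection, bipolar ECoG derivation.
- **Time–frequency analysis** (`reachdec.tf`) — 0.5-s Hamming / 10-ms hop
  spectrograms on a 1-Hz grid, baseline-normalized ERD/ERS maps,
  two-sample Kolmogorov–Smirnov significance maps, per-subject band
  selection (4-Hz band at the ERD/ERS peak, half-max bandwidth), and
  movement/rest band-power ratio vs bandwidth curves.
- **Onset detection** (`reachdec.onset`) — 200-ms/50-ms-step band-power
  windows, Fisher linear discriminant on log powers, continuous detection
  with a debounced binary gate, F1 and latency scoring against
  EMG-defined onsets.
- **Velocity decoding** (`reachdec.decoding`) — 24-row feature series
  (8 raw channels + 8 alpha-beta + 8 gamma envelopes), gated lagged
  multiple linear regression (default order 6, one-sample lag spacing at
  the ECoG rate), and a leave-one-trial-out corticokinematic delay search
  (50–200 ms in 5-ms steps).
- **Evaluation** (`reachdec.evaluate`) — leave-one-trial-out scoring,
  cross-direction transfer, pooled-direction models, and EMG-vs-band
  activity duration regressions (free and through-origin, 95% CIs).

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (onset F1,
reconstruction accuracy, delay recovery, band selection, duration slope,
numerical oracles, null models, bandwidth curve) on full-size simulated
sessions; the remaining files are unit/property tests per module.

## CLI

```sh
reachdec simulate --preset 1 --seed 7 --out sess/    # write a session
reachdec inspect sess/                               # channels, markers
reachdec emg-onsets sess/ --k 3 --out markers.tsv    # EMG burst labels
reachdec select-band sess/ --mode ers --range 30 200 # subject band
reachdec detect sess/ --train-trials 10              # onset F1 report
reachdec decode sess/ --direction RTR --delay auto   # LOO accuracy
reachdec evaluate sess/ --out report.json            # full report
```

A session directory contains `session.edf` (all high-rate channels,
labels `ECOG0..7`, `EMG_*`, `EEG_*`), `kinematics.tsv`
(`time_s vx vy vz`, cm/s), and `markers.tsv` (`time_s kind direction`).

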