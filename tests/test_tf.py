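import numpy as np
import pytest
from scipy import signal as sps

from reachdec import pipeline
from reachdec.simulate import SimBand, preset, simulate_session
from reachdec.tf import (
    BandSpec,
    ErdErsMap,
    TFMap,
    bandwidth_ratio_curve,
    erders,
    ks_significance,
    select_band,
    spectrogram,
)

RATE = 1200.0


def _sine(freq, duration=5.0, amp=1.0):
    t = np.arange(int(duration * RATE)) / RATE
    return amp * np.sin(2 * np.pi * freq * t)


class TestSpectrogram:
    def test_pure_tone_row_argmax(self):
        tf = spectrogram(_sine(20.0), RATE, fmax=100)
        assert np.all(np.argmax(tf.power, axis=0) == 20)

    def test_quadratic_power_scaling(self):
        p1 = spectrogram(_sine(20.0, amp=1.0), RATE).power
        p2 = spectrogram(_sine(20.0, amp=2.0), RATE).power
        ratio = p2[20] / p1[20]
        np.testing.assert_allclose(ratio, 4.0, rtol=1e-9)

    def test_axes_contract(self):
        tf = spectrogram(_sine(20.0), RATE)
        assert np.all(np.diff(tf.freqs) == 1.0)
        np.testing.assert_allclose(np.diff(tf.times), 0.01)
        assert np.all(tf.power >= 0)

    def test_parseval_energy(self, rng):
        x = rng.standard_normal(int(2 * RATE))
        tf = spectrogram(x, RATE)
        win = sps.get_window("hamming", 600)
        # column 0 covers samples [0, 600)
        seg_energy = np.sum((x[:600] * win) ** 2)
        # integrate the one-sided PSD: sum * df * (rate * sum(w^2)) = energy
        col_energy = np.sum(tf.power[:, 0]) * 1.0 * (RATE * np.sum(win**2)) / RATE
        assert abs(col_energy - seg_energy) / seg_energy < 0.05

    def test_brute_force_oracle(self, rng):
        x = rng.standard_normal(int(1.0 * RATE))
        tf = spectrogram(x, RATE)
        win = sps.get_window("hamming", 600)
        scale = 1.0 / (RATE * np.sum(win**2))
        for ci in (0, 17, tf.power.shape[1] - 1):
            seg = x[ci * 12 : ci * 12 + 600] * win
            ref = np.abs(np.fft.rfft(seg, n=1200)) ** 2 * scale
            ref[1:-1] *= 2.0
            np.testing.assert_allclose(tf.power[:, ci], ref, rtol=1e-10)

    def test_too_short_signal(self):
        with pytest.raises(ValueError):
            spectrogram(np.zeros(100), RATE)


def _flat_trials(n_trials=6, base=2.0, move_factor=1.0, seed=0):
    """Synthetic aligned TF maps: constant baseline power, scaled during
    t >= 0."""
    rng = np.random.default_rng(seed)
    freqs = np.arange(0, 50.0)
    times = np.arange(-3.0, 2.0, 0.01)
    trials = []
    for _ in range(n_trials):
        p = np.full((freqs.size, times.size), base)
        p *= 1.0 + 0.01 * rng.standard_normal(p.shape)
        p[:, times >= 0] *= move_factor
        trials.append(TFMap(power=p, freqs=freqs, times=times))
    return trials


class TestErders:
    def test_no_change_gives_zero_map(self):
        emap = erders(_flat_trials(move_factor=1.0))
        assert np.max(np.abs(emap.pct_change)) < 5.0

    def test_doubling_gives_plus_100(self):
        emap = erders(_flat_trials(move_factor=2.0))
        move_cols = emap.times >= 0.05
        med = np.median(emap.pct_change[:, move_cols])
        assert abs(med - 100.0) < 5.0

    def test_baseline_columns_near_zero(self):
        emap = erders(_flat_trials(move_factor=2.0))
        bcols = (emap.times >= -2.0) & (emap.times < -1.5)
        assert np.max(np.abs(emap.pct_change[:, bcols].mean(axis=1))) < 2.0

    def test_preset1_gamma_within_25pct(self, emap1):
        tmask = (emap1.times >= 0) & (emap1.times < 1)
        resp = emap1.pct_change[:, tmask].mean(axis=1)
        gmask = (emap1.freqs >= 30) & (emap1.freqs <= 300)
        peak = np.max(resp[gmask])
        assert abs(peak - 281.0) / 281.0 < 0.25

    def test_requires_two_trials(self):
        with pytest.raises(ValueError):
            erders(_flat_trials(n_trials=1))

    def test_zero_baseline_error_names_bin(self):
        trials = _flat_trials()
        for tf in trials:
            tf.power[7, :] = 0.0
        with pytest.raises(ValueError, match="7"):
            erders(trials)

    def test_per_trial_baseline_option(self):
        a = erders(_flat_trials(move_factor=2.0), per_trial_baseline=True)
        b = erders(_flat_trials(move_factor=2.0), per_trial_baseline=False)
        move_cols = a.times >= 0.05
        assert abs(
            np.median(a.pct_change[:, move_cols])
            - np.median(b.pct_change[:, move_cols])
        ) < 5.0


class TestKsSignificance:
    def test_null_false_positive_rate(self, rng):
        # identical generated distributions: p < 0.01 in ~1% of cells
        freqs = np.arange(0, 30.0)
        times = np.arange(-3.0, 2.0, 0.05)
        trials = [
            TFMap(
                power=rng.chisquare(4, size=(freqs.size, times.size)),
                freqs=freqs,
                times=times,
            )
            for _ in range(20)
        ]
        pv = ks_significance(trials)
        frac = float(np.mean(pv < 0.01))
        assert frac < 0.05
        assert np.median(pv) > 0.1

    def test_effect_bin_significant(self, preset1_small, emg1):
        rec, _ = preset1_small
        emap = pipeline.erders_map(
            rec, emg1.onsets, with_pvalues=True, max_trials=12
        )
        gamma_row = int(155)
        mv = (emap.times >= 0.2) & (emap.times < 0.8)
        rest = (emap.times >= -3.5) & (emap.times < -2.5)
        assert np.median(emap.p_values[gamma_row, mv]) < 0.01
        # at rest p-values are uniform-ish; nearby columns share windows,
        # so pool neighboring gamma rows for a stable median
        rows = slice(145, 166)
        assert np.median(emap.p_values[rows, rest]) > 0.1

    def test_too_few_trials(self):
        with pytest.raises(ValueError):
            ks_significance(_flat_trials(n_trials=1))


class TestSelectBand:
    def test_preset_recovery(self, emap1):
        band = select_band(emap1, (30.0, 200.0), mode="ers")
        assert abs(band.center - 155.0) <= 1.0
        assert band.width == 4.0
        lo, hi = band.halfmax_band
        assert lo < band.center < hi

    def test_scale_invariance(self, emap1):
        band = select_band(emap1, (30.0, 200.0), mode="ers")
        # percent change is scale-free: same selection from a scaled map
        scaled = ErdErsMap(
            pct_change=emap1.pct_change.copy(),
            freqs=emap1.freqs,
            times=emap1.times,
        )
        band2 = select_band(scaled, (30.0, 200.0), mode="ers")
        assert band2.center == band.center

    def test_erd_mode(self, emap1):
        band = select_band(emap1, (8.0, 30.0), mode="erd")
        assert abs(band.center - 22.0) <= 2.0
        assert band.peak_pct < 0

    def test_flat_null_raises(self, rng):
        freqs = np.arange(0, 200.0)
        times = np.arange(-3.0, 2.0, 0.05)
        pct = 2.0 * rng.standard_normal((freqs.size, times.size))
        pvals = rng.uniform(size=pct.shape)
        emap = ErdErsMap(pct_change=pct, freqs=freqs, times=times, p_values=pvals)
        with pytest.raises(ValueError, match="movement-responsive"):
            select_band(emap, (30.0, 200.0), mode="ers")

    def test_halfmax_width_of_constructed_peak(self):
        # deterministic profile with known 14-Hz half-max width
        freqs = np.arange(0, 200.0)
        times = np.arange(-3.0, 2.0, 0.05)
        prof = 200.0 * np.exp2(-2.0 * np.abs(freqs - 90.0) / 14.0)
        pct = np.zeros((freqs.size, times.size))
        pct[:, times >= 0] = prof[:, None]
        emap = ErdErsMap(pct_change=pct, freqs=freqs, times=times)
        band = select_band(emap, (30.0, 200.0), mode="ers")
        assert band.center == 90.0
        lo, hi = band.halfmax_band
        assert abs((hi - lo) - 14.0) <= 2.0

    def test_simulated_halfmax_width(self, emap1):
        band = select_band(emap1, (30.0, 200.0), mode="ers")
        lo, hi = band.halfmax_band
        assert abs((hi - lo) - 19.0) <= 3.0

    def test_search_range_validation(self, emap1):
        with pytest.raises(ValueError):
            select_band(emap1, (500.0, 600.0), mode="ers")


class TestBandwidthRatioCurve:
    def _trial_signals(self, preset_id=3, seed=2, n=10):
        cfg = preset(preset_id, seed=seed, n_trials_per_direction=4)
        rec, truth = simulate_session(cfg)
        x = rec.ecog[1] - rec.ecog[0]
        out = []
        for onset in truth.onset_times[:n]:
            i0 = int(round((onset - 2.0) * rec.rate_ecog))
            out.append(x[i0 : i0 + int(4.0 * rec.rate_ecog)])
        return out, int(2.0 * rec.rate_ecog), cfg

    def test_narrow_beats_wide(self):
        signals, onset_idx, cfg = self._trial_signals()
        widths = [2.0, 8.0, 20.0, 40.0]
        curve = bandwidth_ratio_curve(
            signals, 1200.0, cfg.gamma_band.center, widths, onset_idx
        )
        assert curve[0][1] > curve[-1][1]

    def test_monotone_within_sem(self):
        signals, onset_idx, cfg = self._trial_signals()
        widths = list(np.arange(2.0, 41.0, 4.0))
        curve = bandwidth_ratio_curve(
            signals, 1200.0, cfg.gamma_band.center, widths, onset_idx
        )
        for (w1, m1, s1), (w2, m2, s2) in zip(curve[:-1], curve[1:]):
            assert m2 <= m1 + (s1 + s2)

    def test_null_ratio_near_zero_db(self, rng):
        signals = [rng.standard_normal(int(4 * 1200)) for _ in range(8)]
        curve = bandwidth_ratio_curve(
            signals, 1200.0, 80.0, [60.0], int(2 * 1200)
        )
        assert abs(curve[0][1]) < 1.0

    def test_nyquist_guard(self):
        signals = [np.zeros(int(4 * 1200))]
        with pytest.raises(ValueError):
            bandwidth_ratio_curve(signals, 1200.0, 500.0, [300.0], 2400)


class TestBandSpec:
    def test_invariants(self):
        with pytest.raises(ValueError):
            BandSpec(center=50.0, width=-1.0)
        with pytest.raises(ValueError):
            BandSpec(center=50.0, width=4.0, halfmax_band=(60.0, 70.0))
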