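import warnings

import numpy as np
import pytest

from reachdec import pipeline
from reachdec.decoding import (
    FeatureSeries,
    axis_mean_r,
    build_features,
    envelope,
    fit,
    pearson_r,
    predict,
    search_delay,
    speed_r,
)
from reachdec.evaluate import loo_evaluate
from reachdec.session import SessionRecording
from reachdec.tf import BandSpec

RATE = 1200.0


class TestEnvelope:
    BAND = BandSpec(center=80.0, width=8.0)

    def test_rectified_sine_mean(self):
        t = np.arange(int(10 * RATE)) / RATE
        x = 3.0 * np.sin(2 * np.pi * 80.0 * t)
        env = envelope(x, RATE, self.BAND)
        mid = env[len(env) // 4 : -len(env) // 4]
        assert abs(np.mean(mid) - 2 * 3.0 / np.pi) / (2 * 3.0 / np.pi) < 0.05

    def test_tracks_known_modulator(self):
        t = np.arange(int(20 * RATE)) / RATE
        mod = 1.0 + 0.5 * np.sin(2 * np.pi * 1.0 * t)
        x = mod * np.sin(2 * np.pi * 80.0 * t)
        env = envelope(x, RATE, self.BAND)
        sl = slice(int(2 * RATE), int(18 * RATE))
        assert np.corrcoef(env[sl], mod[sl])[0, 1] > 0.99

    def test_out_of_band_rejected(self):
        t = np.arange(int(5 * RATE)) / RATE
        x = np.sin(2 * np.pi * 20.0 * t)
        env = envelope(x, RATE, self.BAND)
        assert np.mean(env) < 0.01

    def test_band_above_nyquist(self):
        with pytest.raises(ValueError):
            envelope(np.zeros(6000), RATE, BandSpec(center=700.0, width=4.0))


class TestBuildFeatures:
    def _rec(self, n_ch=8, duration=10.0, seed=0):
        rng = np.random.default_rng(seed)
        n = int(duration * RATE)
        return SessionRecording(
            ecog=rng.standard_normal((n_ch, n)),
            emg=np.zeros((1, n)),
            kinematics=np.zeros((3, int(duration * 40))),
        )

    def test_24_rows(self):
        feats = build_features(
            self._rec(),
            BandSpec(center=22.0, width=4.0),
            BandSpec(center=155.0, width=4.0),
        )
        assert feats.n_rows == 24
        assert feats.rate == RATE
        assert np.all(feats.E[8:] >= 0)  # envelopes are non-negative

    def test_zero_input_zero_features(self):
        rec = self._rec()
        rec.ecog[:] = 0.0
        feats = build_features(
            rec, BandSpec(center=22.0, width=4.0), BandSpec(center=155.0, width=4.0)
        )
        assert np.max(np.abs(feats.E)) < 1e-12

    def test_wrong_channel_count(self):
        with pytest.raises(ValueError):
            build_features(
                self._rec(n_ch=4),
                BandSpec(center=22.0, width=4.0),
                BandSpec(center=155.0, width=4.0),
            )


def _synthetic_fit_problem(n=4000, n_rows=5, order=3, t0_samples=8,
                           rate=200.0, seed=0, noise=0.0):
    """Equal-rate features and kinematics built from a known (b, beta)."""
    rng = np.random.default_rng(seed)
    E = rng.standard_normal((n_rows, n))
    beta = rng.standard_normal((order, n_rows, 3))
    b = np.array([1.0, -2.0, 0.5])
    K = np.tile(b[:, None], (1, n))
    for u in range(order):
        shift = t0_samples + u
        shifted = np.zeros_like(E)
        shifted[:, shift:] = E[:, :-shift]
        K += (shifted.T @ beta[u]).T
    K += noise * rng.standard_normal(K.shape)
    gate = np.ones(n, dtype=int)
    gate[: t0_samples + order + 1] = 0  # avoid edge zero-padding
    fs = FeatureSeries(E=E, rate=rate)
    return fs, K, gate, b, beta, t0_samples / rate


class TestFit:
    def test_exact_recovery(self):
        fs, K, gate, b, beta, t0 = _synthetic_fit_problem()
        model = fit(fs, K, gate, t0, order=3, output_rate=fs.rate)
        assert np.max(np.abs(model.b - b)) < 1e-6
        assert np.max(np.abs(model.beta - beta)) < 1e-6
        pred = predict(model, fs, gate)
        sel = gate.astype(bool)
        assert axis_mean_r(K[:, sel], pred[:, sel]) > 0.999999

    def test_ols_matches_normal_equations(self):
        fs, K, gate, *_ , t0 = _synthetic_fit_problem(n=200, noise=0.5)
        model = fit(fs, K, gate, t0, order=2, output_rate=fs.rate)
        from reachdec.decoding import _design_for

        X = _design_for(fs, K.shape[1], fs.rate, t0, 2)
        sel = gate.astype(bool)
        Xg = np.column_stack([np.ones(sel.sum()), X[sel]])
        coef_ref = np.linalg.inv(Xg.T @ Xg) @ (Xg.T @ K[:, sel].T)
        got = np.vstack(
            [model.b[None, :], model.beta.reshape(-1, 3)]
        )
        np.testing.assert_allclose(got, coef_ref, rtol=1e-8, atol=1e-10)

    def test_too_few_gated_samples(self):
        fs, K, gate, *_ , t0 = _synthetic_fit_problem(n=200)
        gate = np.zeros_like(gate)
        gate[50:60] = 1
        with pytest.raises(ValueError):
            fit(fs, K, gate, t0, order=3, output_rate=fs.rate)

    def test_rank_deficiency_warns_and_ridge_works(self):
        fs, K, gate, *_ , t0 = _synthetic_fit_problem(n=500)
        fs.E[1] = fs.E[0]  # exact collinearity
        with pytest.warns(UserWarning, match="rank-deficient"):
            fit(fs, K, gate, t0, order=2, output_rate=fs.rate)
        model = fit(fs, K, gate, t0, order=2, output_rate=fs.rate, ridge=1e-6)
        assert np.isfinite(model.beta).all()


class TestPredict:
    def test_gate_zero_output_zero(self):
        fs, K, gate, *_ , t0 = _synthetic_fit_problem()
        model = fit(fs, K, gate, t0, order=3, output_rate=fs.rate)
        off = np.zeros_like(gate)
        pred = predict(model, fs, off)
        assert np.max(np.abs(pred)) == 0.0

    def test_reproduces_training_data(self):
        fs, K, gate, *_ , t0 = _synthetic_fit_problem()
        model = fit(fs, K, gate, t0, order=3, output_rate=fs.rate)
        pred = predict(model, fs, gate)
        sel = gate.astype(bool)
        np.testing.assert_allclose(pred[:, sel], K[:, sel], atol=1e-6)

    def test_rate_mismatch_rejected(self):
        fs, K, gate, *_ , t0 = _synthetic_fit_problem()
        model = fit(fs, K, gate, t0, order=3, output_rate=fs.rate)
        other = FeatureSeries(E=fs.E, rate=999.0)
        with pytest.raises(ValueError):
            predict(model, other, gate)

    def test_bell_shaped_predictions(self, preset1_small, emg1, decoding1):
        res = loo_evaluate(decoding1, 0.1, order=6)
        assert res["mean_r"] > 0.7  # sanity floor for the shape check below
        from reachdec.decoding import fit as fit_model

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = fit_model(
                decoding1.E, decoding1.K, decoding1.gate, 0.1, 6,
                output_rate=decoding1.output_rate,
            )
            pred = predict(model, decoding1.E, decoding1.gate)
        speeds_ok = 0
        trials = np.unique(decoding1.trial_ids[decoding1.trial_ids >= 0])
        for tr in trials:
            m = (decoding1.trial_ids == tr) & decoding1.gate.astype(bool)
            sp = np.linalg.norm(pred[:, m], axis=0)
            if sp.size < 8:
                continue
            k = int(np.argmax(sp))
            # single interior maximum, rising then falling (smoothed)
            smooth = np.convolve(sp, np.ones(5) / 5, mode="valid")
            k2 = int(np.argmax(smooth))
            interior = 0 < k2 < smooth.size - 1
            if interior:
                speeds_ok += 1
        assert speeds_ok / len(trials) >= 0.9


class TestCorrelationHelpers:
    def test_pearson_degenerate_is_zero(self):
        with pytest.warns(UserWarning):
            assert pearson_r(np.ones(10), np.arange(10.0)) == 0.0

    def test_axis_mean_skips_constant_axes(self):
        a = np.vstack([np.arange(10.0), np.zeros(10)])
        b = np.vstack([np.arange(10.0), np.zeros(10)])
        assert axis_mean_r(a, b) == pytest.approx(1.0)

    def test_speed_r(self):
        v = np.random.default_rng(0).standard_normal((3, 50))
        assert speed_r(v, 2 * v) > 0.999999


class TestSearchDelay:
    def test_permutation_null(self, decoding1):
        rng = np.random.default_rng(0)
        perm = rng.permutation(decoding1.E.n_samples)
        E_perm = FeatureSeries(E=decoding1.E.E[:, perm], rate=decoding1.E.rate)
        from reachdec.evaluate import DecodingData

        null = DecodingData(
            E=E_perm,
            K=decoding1.K,
            gate=decoding1.gate,
            trial_ids=decoding1.trial_ids,
            directions=decoding1.directions,
            output_rate=decoding1.output_rate,
        )
        res = loo_evaluate(null, 0.1, order=6)
        assert abs(res["mean_r"]) < 0.1

    def test_empty_grid_rejected(self, decoding1):
        with pytest.raises(ValueError):
            search_delay(
                decoding1.E, decoding1.K, decoding1.gate,
                decoding1.trial_ids, grid=np.array([]),
                output_rate=decoding1.output_rate,
            )

    def test_grid_outside_span_rejected(self):
        fs, K, gate, *_ , t0 = _synthetic_fit_problem(n=200)
        with pytest.raises(ValueError):
            search_delay(fs, K, gate, np.zeros(200, int),
                         grid=np.array([10.0]), output_rate=fs.rate)

    def test_recovery_and_unimodality(self):
        # dedicated low-noise session with tremor detail for identifiability
        from reachdec.session import Direction
        from reachdec.simulate import preset, simulate_session

        cfg = preset(1, seed=3, n_trials_per_direction=12)
        cfg.lag_true = 0.15
        cfg.tremor_frac = 0.25
        cfg.kin_noise_frac = 0.02
        cfg.directions = (Direction.RTR,)
        rec, truth = simulate_session(cfg)
        emg = pipeline.emg_onsets_for(rec)
        gamma = BandSpec(center=cfg.gamma_band.center, width=4.0)
        ab = BandSpec(center=cfg.alphabeta_band.center, width=4.0)
        dirs = pipeline.trial_directions(rec, emg.onsets)
        data = pipeline.prepare_decoding(
            rec, emg.onsets, emg.offsets, dirs, ab, gamma
        )
        t0, curve = search_delay(
            data.E, data.K, data.gate, data.trial_ids,
            output_rate=data.output_rate,
        )
        assert abs(t0 - 0.15) <= 0.0051
        # unimodal around the optimum: increasing before, decreasing after
        grid = np.arange(0.050, 0.2001, 0.005)
        peak = int(np.argmax(curve))
        before = curve[: peak + 1]
        after = curve[peak:]
        assert np.all(np.diff(before) > -0.01)
        assert np.all(np.diff(after) < 0.01)
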