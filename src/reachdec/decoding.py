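"""Gated, lagged multiple linear regression of 3-D arm velocity.

Features are the 8 raw ECoG channels plus the 8 alpha-beta and 8 gamma
band envelopes (24 rows). Lags are taken at the ECoG rate (one-sample
spacing, so 6 taps span ~5 ms at 1200 Hz); the lagged feature block is
anti-alias filtered and decimated onto the kinematics clock for the
regression. Fitting is ordinary least squares restricted to gated samples,
and predictions are forced to zero wherever the gate is off.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .session import SessionRecording
from .tf import BandSpec

N_FEATURES = 24


@dataclass
class FeatureSeries:
    """[n_rows x n_samples] feature matrix at ``rate`` Hz.

    For sessions this holds the full-rate (ECoG clock) matrix; use
    :meth:`lowpassed` + index decimation to move to the kinematics clock.
    """

    E: np.ndarray
    rate: float
    band_specs: dict = field(default_factory=dict)
    _lowpassed: np.ndarray | None = None
    lp_cutoff: float = 5.0

    def __post_init__(self) -> None:
        self.E = np.atleast_2d(np.asarray(self.E, dtype=float))

    @property
    def n_rows(self) -> int:
        return self.E.shape[0]

    @property
    def n_samples(self) -> int:
        return self.E.shape[1]

    def lowpassed(self) -> np.ndarray:
        """Zero-phase anti-alias low-pass of every row (cached)."""
        if self._lowpassed is None:
            sos = sps.butter(4, self.lp_cutoff, btype="lowpass", fs=self.rate,
                             output="sos")
            self._lowpassed = sps.sosfiltfilt(sos, self.E, axis=1)
        return self._lowpassed


@dataclass
class DecoderModel:
    b: np.ndarray  # 3-vector intercept, cm/s
    beta: np.ndarray  # [order x n_rows x 3]
    t0: float  # delay, seconds
    order: int
    feature_rate: float
    output_rate: float
    residual_var: np.ndarray  # per-axis variance of the residuals
    n_fit_samples: int = 0

    @property
    def n_params(self) -> int:
        return self.order * self.beta.shape[1] + 1


def envelope(signal: np.ndarray, rate: float, band: BandSpec,
             lp_cutoff: float = 5.0, order: int = 4) -> np.ndarray:
    """Band amplitude: zero-phase band-pass, full-wave rectification, then
    a zero-phase low-pass at ``lp_cutoff`` Hz."""
    lo, hi = band.edges
    if hi >= rate / 2.0 or lo <= 0:
        raise ValueError(f"band {lo:.1f}-{hi:.1f} Hz outside (0, Nyquist)")
    sos_bp = sps.butter(order, [lo, hi], btype="bandpass", fs=rate, output="sos")
    rect = np.abs(sps.sosfiltfilt(sos_bp, np.asarray(signal, dtype=float)))
    sos_lp = sps.butter(order, lp_cutoff, btype="lowpass", fs=rate, output="sos")
    # the low-pass can ring slightly negative on rectified input
    return np.clip(sps.sosfiltfilt(sos_lp, rect), 0.0, None)


def build_features(
    rec: SessionRecording, alphabeta: BandSpec, gamma: BandSpec
) -> FeatureSeries:
    """24-row feature series: raw channels 0-7, then the alpha-beta and
    gamma envelopes of each channel, at the ECoG rate."""
    n_ch = rec.ecog.shape[0]
    if n_ch != 8:
        raise ValueError(f"expected 8 ECoG channels, got {n_ch}")
    rows = [rec.ecog[i] for i in range(n_ch)]
    rows += [envelope(rec.ecog[i], rec.rate_ecog, alphabeta) for i in range(n_ch)]
    rows += [envelope(rec.ecog[i], rec.rate_ecog, gamma) for i in range(n_ch)]
    return FeatureSeries(
        E=np.vstack(rows),
        rate=rec.rate_ecog,
        band_specs={"alphabeta": alphabeta, "gamma": gamma},
    )


def _lagged_design(
    E: FeatureSeries,
    out_times: np.ndarray,
    t0: float,
    order: int,
    antialias: bool,
) -> np.ndarray:
    """Design matrix [n_out x (order * n_rows)] of lagged features.

    Row k holds E(t_k - t0 - u/rate) for u = 0..order-1, taken from the
    (optionally anti-alias filtered) full-rate matrix by index shifts.
    Out-of-range samples are zero.
    """
    mat = E.lowpassed() if antialias else E.E
    n = mat.shape[1]
    base_idx = np.round(out_times * E.rate).astype(int)
    s0 = int(round(t0 * E.rate))
    cols = []
    for u in range(order):
        idx = base_idx - s0 - u
        valid = (idx >= 0) & (idx < n)
        block = np.zeros((len(out_times), mat.shape[0]))
        block[valid] = mat[:, idx[valid]].T
        cols.append(block)
    return np.concatenate(cols, axis=1)


def _design_for(
    E: FeatureSeries,
    n_out: int,
    output_rate: float,
    t0: float,
    order: int,
) -> np.ndarray:
    """Lagged design on the output clock; skips the anti-alias filter when
    feature and output rates already match."""
    out_times = np.arange(n_out) / output_rate
    antialias = abs(E.rate - output_rate) > 1e-9
    return _lagged_design(E, out_times, t0, order, antialias)


def fit(
    E: FeatureSeries,
    K: np.ndarray,
    gate: np.ndarray,
    t0: float,
    order: int = 6,
    output_rate: float | None = None,
    ridge: float = 0.0,
) -> DecoderModel:
    """Least-squares fit of gated, lagged features to 3-D velocity.

    ``K`` is [3 x n] on the output clock, ``gate`` a binary array of the
    same length. Only samples with gate = 1 enter the fit. ``ridge`` adds
    an L2 penalty for rank-deficient designs (default off: plain OLS).
    """
    K = np.atleast_2d(np.asarray(K, dtype=float))
    gate = np.asarray(gate)
    n_out = K.shape[1]
    if gate.shape[0] != n_out:
        raise ValueError("gate and kinematics lengths differ")
    rate_out = output_rate if output_rate is not None else (
        E.rate if E.n_samples == n_out else n_out / (E.n_samples / E.rate)
    )

    X = _design_for(E, n_out, rate_out, t0, order)
    sel = gate.astype(bool)
    n_params = X.shape[1] + 1
    if np.count_nonzero(sel) < n_params:
        raise ValueError(
            f"only {np.count_nonzero(sel)} gated samples for {n_params} parameters"
        )
    Xg = np.column_stack([np.ones(np.count_nonzero(sel)), X[sel]])
    Yg = K[:, sel].T

    if ridge > 0:
        A = Xg.T @ Xg + ridge * np.eye(Xg.shape[1])
        A[0, 0] -= ridge  # do not penalize the intercept
        coef = np.linalg.solve(A, Xg.T @ Yg)
    else:
        coef, _, rank, _ = np.linalg.lstsq(Xg, Yg, rcond=None)
        if rank < Xg.shape[1]:
            warnings.warn(
                f"rank-deficient design (rank {rank} < {Xg.shape[1]}); "
                "coefficients are the minimum-norm solution — consider ridge"
            )

    resid = Yg - Xg @ coef
    return DecoderModel(
        b=coef[0],
        beta=coef[1:].reshape(order, E.n_rows, 3),
        t0=t0,
        order=order,
        feature_rate=E.rate,
        output_rate=rate_out,
        residual_var=np.var(resid, axis=0),
        n_fit_samples=int(np.count_nonzero(sel)),
    )


def predict(
    model: DecoderModel, E: FeatureSeries, gate: np.ndarray
) -> np.ndarray:
    """Predicted [3 x n] velocity; exactly zero wherever the gate is off."""
    if abs(model.feature_rate - E.rate) > 1e-9:
        raise ValueError(
            f"feature rate {E.rate} differs from training rate {model.feature_rate}"
        )
    gate = np.asarray(gate)
    n_out = gate.shape[0]
    X = _design_for(E, n_out, model.output_rate, model.t0, model.order)
    coef = model.beta.reshape(model.order * E.n_rows, 3)
    K_hat = (X @ coef + model.b).T
    K_hat[:, ~gate.astype(bool)] = 0.0
    return K_hat


def pearson_r(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation; 0 (with a warning) if either input is constant."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size < 2 or np.std(a) == 0 or np.std(b) == 0:
        warnings.warn("degenerate (constant) series: correlation set to 0")
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def axis_mean_r(K_true: np.ndarray, K_pred: np.ndarray,
                mask: np.ndarray | None = None) -> float:
    """Mean per-axis Pearson correlation over (optionally masked) samples.
    Axes where the actual velocity is constant are skipped."""
    if mask is not None:
        K_true = K_true[:, mask]
        K_pred = K_pred[:, mask]
    rs = []
    for ax in range(K_true.shape[0]):
        if np.std(K_true[ax]) == 0:
            continue
        rs.append(pearson_r(K_true[ax], K_pred[ax]))
    return float(np.mean(rs)) if rs else 0.0


def speed_r(K_true: np.ndarray, K_pred: np.ndarray,
            mask: np.ndarray | None = None) -> float:
    """Pearson correlation of speeds |K| over (optionally masked) samples."""
    if mask is not None:
        K_true = K_true[:, mask]
        K_pred = K_pred[:, mask]
    return pearson_r(
        np.linalg.norm(K_true, axis=0), np.linalg.norm(K_pred, axis=0)
    )


def search_delay(
    E: FeatureSeries,
    K: np.ndarray,
    gate: np.ndarray,
    trial_ids: np.ndarray,
    grid: np.ndarray | None = None,
    order: int = 1,
    output_rate: float | None = None,
) -> tuple[float, np.ndarray]:
    """Leave-one-trial-out delay search.

    For each candidate ``t0`` the mean LOO per-trial correlation is
    computed (Gram-matrix downdating, so each left-out trial costs one
    linear solve); returns the argmax (ties toward the smallest ``t0``)
    and the full correlation curve.

    The search defaults to a single-lag design (``order=1``): with several
    closely spaced taps, least squares can emulate arbitrary time shifts
    of smooth band-limited features through derivative-like tap
    combinations, which flattens the correlation-vs-delay objective and
    leaves the delay unidentified. The full multi-tap model is then fitted
    at the returned delay.

    ``trial_ids`` assigns every output sample to a trial (-1 = no trial);
    only gated samples inside trials participate.
    """
    if grid is None:
        grid = np.arange(0.050, 0.2001, 0.005)
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty delay grid")

    K = np.atleast_2d(np.asarray(K, dtype=float))
    n_out = K.shape[1]
    rate_out = output_rate if output_rate is not None else (
        E.rate if E.n_samples == n_out else n_out / (E.n_samples / E.rate)
    )
    span = E.n_samples / E.rate
    if np.max(grid) > span:
        raise ValueError("delay grid exceeds the data span")

    gate = np.asarray(gate).astype(bool)
    trial_ids = np.asarray(trial_ids)
    sel = gate & (trial_ids >= 0)
    trials = np.unique(trial_ids[sel])

    curve = np.empty(grid.size)
    for gi, t0 in enumerate(grid):
        X = _design_for(E, n_out, rate_out, t0, order)
        Xg = np.column_stack([np.ones(np.count_nonzero(sel)), X[sel]])
        Yg = K[:, sel].T
        ids = trial_ids[sel]
        G = Xg.T @ Xg
        C = Xg.T @ Yg
        jitter = 1e-10 * np.trace(G) / G.shape[0]
        rs = []
        for tr in trials:
            hold = ids == tr
            Xi, Yi = Xg[hold], Yg[hold]
            Gi = G - Xi.T @ Xi
            Ci = C - Xi.T @ Yi
            try:
                coef = np.linalg.solve(
                    Gi + jitter * np.eye(Gi.shape[0]), Ci
                )
            except np.linalg.LinAlgError:
                coef = np.linalg.lstsq(Gi, Ci, rcond=None)[0]
            pred = Xi @ coef
            rs.append(axis_mean_r(Yi.T, pred.T))
        curve[gi] = float(np.mean(rs))
    best = int(np.argmax(curve))  # first (smallest t0) maximum on ties
    return float(grid[best]), curve
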