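"""Cross-validated decoder scoring, cross-direction transfer, pooled
models, and duration-regression analyses."""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as spstats

from .decoding import (
    FeatureSeries,
    _design_for,
    axis_mean_r,
    fit,
    predict,
    pearson_r,
    speed_r,
)
from .session import Direction


@dataclass
class DecodingData:
    """Everything the decoder needs on a common output clock."""

    E: FeatureSeries  # full-rate features
    K: np.ndarray  # [3 x n_out] velocity at output_rate
    gate: np.ndarray  # binary, length n_out
    trial_ids: np.ndarray  # int, -1 outside trials
    directions: list[Direction]  # per trial
    output_rate: float


def make_trial_ids(
    n_out: int,
    output_rate: float,
    onsets: np.ndarray,
    offsets: np.ndarray,
    margin: float = 0.25,
) -> np.ndarray:
    """Assign output samples to trials by movement interval (+/- margin)."""
    ids = np.full(n_out, -1, dtype=int)
    t = np.arange(n_out) / output_rate
    for i, (a, b) in enumerate(zip(onsets, offsets)):
        ids[(t >= a - margin) & (t <= b + margin)] = i
    return ids


def movement_gate(
    n_out: int, output_rate: float, onsets: np.ndarray, offsets: np.ndarray
) -> np.ndarray:
    """Binary gate that is on during [onset, offset] intervals."""
    gate = np.zeros(n_out, dtype=int)
    t = np.arange(n_out) / output_rate
    for a, b in zip(onsets, offsets):
        gate[(t >= a) & (t <= b)] = 1
    return gate


def _loo_gram(
    data: DecodingData,
    t0: float,
    order: int,
    trials: np.ndarray,
    metric: str = "axes",
) -> list[float]:
    """Per-trial leave-one-out correlations via Gram downdating."""
    sel = data.gate.astype(bool) & (data.trial_ids >= 0)
    X = _design_for(data.E, data.K.shape[1], data.output_rate, t0, order)
    Xg = np.column_stack([np.ones(np.count_nonzero(sel)), X[sel]])
    Yg = data.K[:, sel].T
    ids = data.trial_ids[sel]
    G = Xg.T @ Xg
    C = Xg.T @ Yg
    jitter = 1e-10 * np.trace(G) / G.shape[0]
    rs = []
    for tr in trials:
        hold = ids == tr
        if not np.any(hold):
            continue
        Xi, Yi = Xg[hold], Yg[hold]
        Gi = G - Xi.T @ Xi + jitter * np.eye(G.shape[0])
        Ci = C - Xi.T @ Yi
        coef = np.linalg.solve(Gi, Ci)
        pred = (Xi @ coef).T
        if metric == "speed":
            rs.append(speed_r(Yi.T, pred))
        else:
            rs.append(axis_mean_r(Yi.T, pred))
    return rs


def loo_evaluate(
    data: DecodingData,
    t0: float,
    order: int = 6,
    direction: Direction | None = None,
    metric: str = "axes",
) -> dict:
    """Leave-one-trial-out evaluation.

    Fits on all-but-one trial's gated samples, predicts the held-out
    trial, and reports per-trial Pearson correlations plus mean +/- sd.
    ``direction`` restricts both fitting and scoring to that direction's
    trials.
    """
    all_trials = np.unique(data.trial_ids[data.trial_ids >= 0])
    if direction is not None:
        keep = [t for t in all_trials if data.directions[t] == direction]
    else:
        keep = list(all_trials)
    if len(keep) < 3:
        raise ValueError("need at least 3 trials for leave-one-out")

    if direction is not None:
        sub = _restrict_to_trials(data, keep)
        rs = _loo_gram(sub, t0, order, np.asarray(keep), metric)
    else:
        rs = _loo_gram(data, t0, order, np.asarray(keep), metric)
    rs = np.asarray(rs)
    return {
        "per_trial_r": rs,
        "mean_r": float(np.mean(rs)),
        "sd_r": float(np.std(rs, ddof=1)) if rs.size > 1 else 0.0,
        "n_trials": int(rs.size),
    }


def _restrict_to_trials(data: DecodingData, keep: list[int]) -> DecodingData:
    mask = np.isin(data.trial_ids, keep)
    ids = data.trial_ids.copy()
    ids[~mask] = -1
    gate = data.gate.copy()
    gate[~mask] = 0
    return DecodingData(
        E=data.E, K=data.K, gate=gate, trial_ids=ids,
        directions=data.directions, output_rate=data.output_rate,
    )


def transfer_evaluate(
    data: DecodingData,
    train_dir: Direction,
    test_dir: Direction,
    t0: float,
    order: int = 6,
) -> float:
    """Train on one direction's trials, score speed correlation on another.

    ``train_dir == test_dir`` reduces to in-sample evaluation.
    """
    trials = np.unique(data.trial_ids[data.trial_ids >= 0])
    train_trials = [t for t in trials if data.directions[t] == train_dir]
    test_trials = [t for t in trials if data.directions[t] == test_dir]
    if not train_trials or not test_trials:
        raise ValueError(
            f"missing trials for {train_dir.value}->{test_dir.value} transfer"
        )
    train = _restrict_to_trials(data, train_trials)
    model = fit(train.E, train.K, train.gate, t0, order,
                output_rate=train.output_rate)
    test = _restrict_to_trials(data, test_trials)
    K_hat = predict(model, test.E, test.gate)
    mask = test.gate.astype(bool)
    return speed_r(test.K, K_hat, mask)


def pooled_evaluate(data: DecodingData, t0: float, order: int = 6) -> dict:
    """Leave-one-out over all trials pooled across directions."""
    return loo_evaluate(data, t0, order, direction=None)


@dataclass
class RegressionFit:
    slope: float
    intercept: float
    r_squared: float
    slope_ci: tuple[float, float]
    intercept_ci: tuple[float, float]
    n: int
    zero_intercept: bool


def duration_regression(
    durations_x: np.ndarray,
    durations_y: np.ndarray,
    zero_intercept: bool = False,
    conf: float = 0.95,
) -> RegressionFit:
    """OLS of band-activity duration on EMG-burst duration.

    Free-intercept mode is standard simple regression. With
    ``zero_intercept`` the line is constrained through the origin and the
    R-squared is computed about the origin (uncentered:
    ``1 - SS_res / sum(y^2)``). Confidence bounds use normal-theory
    t intervals.
    """
    x = np.asarray(durations_x, dtype=float)
    y = np.asarray(durations_y, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 paired durations")
    if np.var(x) == 0:
        raise ValueError("zero-variance x")

    if zero_intercept:
        sxx = float(np.sum(x * x))
        slope = float(np.sum(x * y) / sxx)
        resid = y - slope * x
        dof = n - 1
        s2 = float(np.sum(resid**2) / dof)
        se_slope = np.sqrt(s2 / sxx)
        tcrit = spstats.t.ppf(0.5 + conf / 2.0, dof)
        ss_tot = float(np.sum(y**2))
        r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 0.0
        return RegressionFit(
            slope=slope,
            intercept=0.0,
            r_squared=r2,
            slope_ci=(slope - tcrit * se_slope, slope + tcrit * se_slope),
            intercept_ci=(0.0, 0.0),
            n=n,
            zero_intercept=True,
        )

    res = spstats.linregress(x, y)
    dof = n - 2
    tcrit = spstats.t.ppf(0.5 + conf / 2.0, dof)
    return RegressionFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        slope_ci=(
            float(res.slope - tcrit * res.stderr),
            float(res.slope + tcrit * res.stderr),
        ),
        intercept_ci=(
            float(res.intercept - tcrit * res.intercept_stderr),
            float(res.intercept + tcrit * res.intercept_stderr),
        ),
        n=n,
        zero_intercept=False,
    )


def band_activity_durations(
    env: np.ndarray,
    rate: float,
    onsets: np.ndarray,
    offsets: np.ndarray,
    pre: float = 1.0,
    post: float = 1.0,
    rel_thresh: float = 0.5,
) -> np.ndarray:
    """Per-trial duration for which a band envelope stays above
    ``rel_thresh`` of its in-trial peak (after subtracting the trial's
    pre-movement floor)."""
    durations = np.empty(len(onsets))
    for i, (a, b) in enumerate(zip(onsets, offsets)):
        i0 = max(int(round((a - pre) * rate)), 0)
        i1 = min(int(round((b + post) * rate)), env.size)
        seg = env[i0:i1]
        floor = np.percentile(seg, 10)
        rel = seg - floor
        peak = np.max(rel)
        durations[i] = np.count_nonzero(rel >= rel_thresh * peak) / rate
    return durations


def make_report(
    detection: dict | None,
    per_direction: dict[str, dict] | None,
    transfer: dict[str, float] | None,
    pooled: dict | None,
    duration_fits: list[dict] | None,
) -> dict:
    """Assemble the evaluation JSON document from stage outputs."""
    report: dict = {}
    if detection is not None:
        report["detection"] = detection
    if per_direction is not None:
        report["reconstruction"] = {
            d: {
                "mean_r": v["mean_r"],
                "sd_r": v["sd_r"],
                "n_trials": v["n_trials"],
            }
            for d, v in per_direction.items()
        }
        report["reconstruction"]["average_r"] = float(
            np.mean([v["mean_r"] for v in per_direction.values()])
        )
    if transfer is not None:
        report["transfer"] = transfer
    if pooled is not None:
        report["pooled"] = {
            "mean_r": pooled["mean_r"],
            "sd_r": pooled["sd_r"],
            "n_trials": pooled["n_trials"],
        }
    if duration_fits is not None:
        report["duration_regressions"] = duration_fits
    return report


def regression_fit_as_dict(band_role: str, fit_: RegressionFit) -> dict:
    return {
        "band": band_role,
        "slope": fit_.slope,
        "intercept": fit_.intercept,
        "r_squared": fit_.r_squared,
        "slope_ci": list(fit_.slope_ci),
        "zero_intercept": fit_.zero_intercept,
        "n": fit_.n,
    }
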