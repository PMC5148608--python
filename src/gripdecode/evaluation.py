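"""Cross-validation, decoding metrics and BIC model comparison.

Metric definitions: WithinTrialR is the Pearson correlation between the
predicted and measured force within a trial; nRMSE is the RMSE as a percent
of the maximal measured value; StableFrcR is the across-trial correlation
of holding-phase (1-2 s post cue) means; DifRT the predicted-minus-measured
force onset latency.  Models are compared with
``BIC = n * ln(sigma_e^2) + k * ln(n)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.optimize import least_squares

from gripdecode.exceptions import DegenerateDataError, InputError
from gripdecode.features import Trial, detect_onset, force_yank
from gripdecode.models import FitResult, fit_model, get_model, simulate_forward

logger = logging.getLogger(__name__)

__all__ = [
    "TrialPrediction",
    "MetricSet",
    "within_trial_r",
    "nrmse",
    "stable_force",
    "stable_force_r",
    "dif_rt",
    "bic",
    "fisher_z",
    "effort_split_cv",
    "kfold_cv",
    "summarize_predictions",
    "average_trials",
    "sre_scaling",
    "performance_vs_modulation",
    "EFFORT_SPLIT_THRESHOLD",
]

#: SRE threshold for the low/high effort split; 5 belongs to the LOW half.
EFFORT_SPLIT_THRESHOLD = 5

HOLDING_WINDOW = (1.0, 2.0)  # seconds re cue, inclusive start / exclusive end


@dataclass
class TrialPrediction:
    """Predicted vs measured force for one tested trial."""

    measured: np.ndarray
    predicted: np.ndarray  # clamped at >= 0
    times: np.ndarray  # seconds re cue
    sre: int
    fold: int = -1
    trial_index: int = -1

    def __post_init__(self):
        if len(self.measured) != len(self.predicted):
            raise InputError("measured and predicted lengths differ")


@dataclass
class MetricSet:
    """Aggregate decoding metrics for a set of trial predictions."""

    within_r: list[float]
    nrmse_pct: list[float]
    stable_r: float | None
    stable_slope: float | None
    stable_intercept: float | None
    dif_rt_s: list[float]
    bic: float | None
    sigma_e2: float
    n: int
    k: int
    n_excluded_r: int = 0
    n_excluded_rt: int = 0

    @property
    def median_within_r(self) -> float:
        return float(np.median(self.within_r)) if self.within_r else np.nan

    @property
    def median_nrmse(self) -> float:
        return float(np.median(self.nrmse_pct)) if self.nrmse_pct else np.nan


# ---------------------------------------------------------------------------
# elementary metrics


def within_trial_r(pred: np.ndarray, meas: np.ndarray) -> float | None:
    """Pearson r between predicted and measured force over the decode window.

    Returns None (excluded) when either sequence has zero variance.
    """
    pred = np.asarray(pred, dtype=float)
    meas = np.asarray(meas, dtype=float)
    if pred.size < 3:
        raise InputError("need at least 3 samples for a correlation")
    if np.ptp(pred) == 0 or np.ptp(meas) == 0:  # exact constant check
        return None
    return float(np.corrcoef(pred, meas)[0, 1])


def nrmse(pred: np.ndarray, meas: np.ndarray) -> float:
    """RMSE as a percent of the maximal measured value."""
    pred = np.asarray(pred, dtype=float)
    meas = np.asarray(meas, dtype=float)
    m = float(np.max(meas))
    if m <= 0:
        raise DegenerateDataError("maximal measured value is zero")
    return float(100.0 * np.sqrt(np.mean((pred - meas) ** 2)) / m)


def stable_force(
    trace: np.ndarray, times: np.ndarray, window: tuple[float, float] = HOLDING_WINDOW
) -> float:
    """Mean force over the holding phase (1-2 s post cue)."""
    times = np.asarray(times)
    sel = (times >= window[0]) & (times < window[1])
    if not np.any(sel):
        raise InputError(f"holding window {window} outside the trace")
    return float(np.asarray(trace)[sel].mean())


def stable_force_r(
    predictions: list[TrialPrediction],
) -> tuple[float, float, float]:
    """Across-trial r, OLS slope and intercept of predicted vs measured stable force."""
    if len(predictions) < 3:
        raise InputError("need at least 3 trials")
    meas = np.array([stable_force(p.measured, p.times) for p in predictions])
    pred = np.array([stable_force(p.predicted, p.times) for p in predictions])
    if np.ptp(meas) == 0 or np.ptp(pred) == 0:
        raise DegenerateDataError("zero variance in stable force across trials")
    r = float(np.corrcoef(pred, meas)[0, 1])
    slope, intercept = np.polyfit(meas, pred, 1)
    return r, float(slope), float(intercept)


def dif_rt(pred: np.ndarray, meas: np.ndarray, times: np.ndarray) -> float | None:
    """Predicted minus measured force-onset time; None when either is undefined."""
    onset_p = detect_onset(pred, times)
    onset_m = detect_onset(meas, times)
    if onset_p is None or onset_m is None:
        return None
    return float(onset_p - onset_m)


def bic(residual_ss: float, n: int, k: int) -> float:
    """Bayesian information criterion ``n * ln(sigma_e^2) + k * ln(n)``.

    ``sigma_e^2 = residual_ss / n`` is the error variance over the n tested
    time points; k is the model's free-parameter count.
    """
    if n <= 0:
        raise InputError("n must be positive")
    sigma2 = residual_ss / n
    if sigma2 <= 0:
        raise DegenerateDataError("perfect fit: zero error variance, BIC undefined")
    return float(n * np.log(sigma2) + k * np.log(n))


def fisher_z(r: float) -> float:
    """Fisher z-transform, atanh(r); defined for |r| < 1."""
    r = float(r)
    if abs(r) >= 1.0:
        raise InputError(f"|r|={abs(r)} >= 1: Fisher z undefined")
    return float(np.arctanh(r))


# ---------------------------------------------------------------------------
# aggregation


def summarize_predictions(
    predictions: list[TrialPrediction], k: int
) -> MetricSet:
    """All decoding metrics plus BIC for a set of tested trials."""
    if not predictions:
        raise InputError("no predictions to summarise")
    rs, nr, drt = [], [], []
    n_ex_r = n_ex_rt = 0
    ss = 0.0
    n = 0
    for p in predictions:
        r = within_trial_r(p.predicted, p.measured)
        if r is None:
            n_ex_r += 1
            logger.info("trial %d excluded from WithinR (zero variance)", p.trial_index)
        else:
            rs.append(r)
        if np.max(p.measured) > 0:
            nr.append(nrmse(p.predicted, p.measured))
        d = dif_rt(p.predicted, p.measured, p.times)
        if d is None:
            n_ex_rt += 1
        else:
            drt.append(d)
        ss += float(np.sum((p.measured - p.predicted) ** 2))
        n += len(p.measured)
    try:
        sr, slope, intercept = stable_force_r(predictions)
    except (InputError, DegenerateDataError):
        sr = slope = intercept = None
    sigma2 = ss / n
    b = bic(ss, n, k) if sigma2 > 0 else None
    return MetricSet(
        within_r=rs,
        nrmse_pct=nr,
        stable_r=sr,
        stable_slope=slope,
        stable_intercept=intercept,
        dif_rt_s=drt,
        bic=b,
        sigma_e2=sigma2,
        n=n,
        k=k,
        n_excluded_r=n_ex_r,
        n_excluded_rt=n_ex_rt,
    )


# ---------------------------------------------------------------------------
# cross-validation schemes


def average_trials(trials: list[Trial]) -> tuple[dict[str, np.ndarray], np.ndarray, np.ndarray]:
    bands = {
        b: np.mean([getattr(t.band_trace, b) for t in trials], axis=0)
        for b in ("alpha", "beta", "gamma")
    }
    force = np.mean([t.force for t in trials], axis=0)
    times = trials[0].band_trace.times
    return bands, force, times


def effort_split_cv(
    trials: list[Trial],
    model_ids: list[int],
    fs_feature: float = 100.0,
) -> dict[int, dict]:
    """Fit on one effort half's trial average, predict the other's.

    Trials are split at SRE <= 5 (low) vs > 5 (high); band traces and force
    are averaged within each half; each model is fitted on one average and
    tested on the other, in both directions.  The per-model BIC combines the
    test residuals of both directions.
    """
    sres = np.array([t.sre for t in trials])
    low = [t for t in trials if t.sre <= EFFORT_SPLIT_THRESHOLD]
    high = [t for t in trials if t.sre > EFFORT_SPLIT_THRESHOLD]
    if not low or not high:
        raise InputError(
            f"effort split needs both halves non-empty; SRE distribution: "
            f"{np.bincount(sres, minlength=11).tolist()}"
        )
    halves = {"low": average_trials(low), "high": average_trials(high)}
    results: dict[int, dict] = {}
    for mid in model_ids:
        spec = get_model(mid)
        directions = {}
        ss = 0.0
        n = 0
        for train, test in (("low", "high"), ("high", "low")):
            tb, tf, _ = halves[train]
            vb, vf, vt = halves[test]
            fit = fit_model(spec, tb, tf, fs_feature)
            pred = simulate_forward(spec, fit.params, vb, fs_feature, clamp=True)
            sre_rep = 10 if test == "high" else 0
            tp = TrialPrediction(
                measured=vf, predicted=pred, times=vt, sre=sre_rep
            )
            directions[f"{train}_to_{test}"] = {
                "fit": fit,
                "prediction": tp,
                "within_r": within_trial_r(pred, vf),
                "nrmse_pct": nrmse(pred, vf) if np.max(vf) > 0 else None,
            }
            ss += float(np.sum((vf - pred) ** 2))
            n += len(vf)
        results[mid] = {
            "directions": directions,
            "bic": bic(ss, n, spec.k),
            "sigma_e2": ss / n,
            "n": n,
            "k": spec.k,
        }
    return results


def kfold_assignment(
    n_trials: int, n_folds: int, seed: int | None = None
) -> np.ndarray:
    """Seeded random partition into folds whose sizes differ by at most one."""
    if n_trials < n_folds:
        raise InputError(f"cannot make {n_folds} folds from {n_trials} trials")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_trials)
    assignment = np.empty(n_trials, dtype=int)
    for fold, chunk in enumerate(np.array_split(perm, n_folds)):
        assignment[chunk] = fold
    return assignment


def kfold_cv(
    trials: list[Trial],
    model_id: int,
    n_folds: int = 5,
    seed: int | None = None,
    fs_feature: float = 100.0,
) -> tuple[list[TrialPrediction], list[FitResult]]:
    """K-fold cross-validation on individual trials.

    Each fold is held out once; the model is fitted on the concatenated
    remaining trials and used to predict the held-out trials, so every trial
    is tested exactly once.
    """
    spec = get_model(model_id)
    assignment = kfold_assignment(len(trials), n_folds, seed)
    predictions: list[TrialPrediction] = []
    fits: list[FitResult] = []
    for fold in range(n_folds):
        train = [t for t, a in zip(trials, assignment) if a != fold]
        fit = fit_model(spec, [t.band_trace for t in train],
                        [t.force for t in train], fs_feature)
        fits.append(fit)
        for i, (t, a) in enumerate(zip(trials, assignment)):
            if a != fold:
                continue
            pred = simulate_forward(
                spec, fit.params, t.band_trace, fs_feature, clamp=True
            )
            predictions.append(
                TrialPrediction(
                    measured=t.force,
                    predicted=pred,
                    times=t.band_trace.times,
                    sre=t.sre,
                    fold=fold,
                    trial_index=i,
                )
            )
    predictions.sort(key=lambda p: p.trial_index)
    return predictions, fits


# ---------------------------------------------------------------------------
# effort-scaling and performance-vs-modulation analyses


def sre_scaling(trials: list[Trial], fs_feature: float = 100.0) -> dict[str, float]:
    """Spearman correlations of stable force and peak yank against SRE."""
    if len(trials) < 3:
        raise InputError("need at least 3 trials")
    sre = np.array([t.sre for t in trials])
    if np.unique(sre).size < 2:
        raise DegenerateDataError("all trials share the same SRE")
    stable = np.array(
        [stable_force(t.force, t.band_trace.times) for t in trials]
    )
    peaks = np.array(
        [force_yank(t.force, fs_feature, t.band_trace.times)[1] for t in trials]
    )
    def _spearman(x):
        if np.ptp(x) == 0:  # constant -> correlation undefined
            return float("nan")
        return float(stats.spearmanr(x, sre).statistic)

    return {
        "stable_force_vs_sre": _spearman(stable),
        "peak_yank_vs_sre": _spearman(peaks),
    }


def performance_vs_modulation(
    modulation: np.ndarray, performance: np.ndarray
) -> dict[str, float]:
    """Fit ``y = a * exp(-b * x) + k`` of decoding performance vs modulation.

    Bounded least squares with a deterministic multi-start over the decay
    rate; returns the parameters and the variance explained (R^2).  A fit
    with near-zero decay is flagged as degenerate.
    """
    x = np.asarray(modulation, dtype=float)
    y = np.asarray(performance, dtype=float)
    if x.size != y.size or x.size < 4:
        raise InputError("need at least 4 (x, y) points for a 3-parameter fit")

    def resid(theta):
        a, b, k = theta
        return a * np.exp(-b * x) + k - y

    scale = max(np.ptp(np.abs(x)), 1e-9)
    best = None
    for b0 in (0.1 / scale, 1.0 / scale, 10.0 / scale, 100.0 / scale):
        res = least_squares(
            resid,
            [y[np.argmin(x)] - y[np.argmax(x)], b0, y[np.argmax(x)]],
            bounds=([-np.inf, 0.0, -np.inf], [np.inf, np.inf, np.inf]),
        )
        if best is None or res.cost < best.cost:
            best = res
    a, b, k = best.x
    ss_res = float(2 * best.cost)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    return {
        "a": float(a),
        "b": float(b),
        "k": float(k),
        "r_squared": float(r2),
        "degenerate": bool(b < 1e-8 or ss_tot == 0),
    }
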