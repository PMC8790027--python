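"""Window-level physio-cognitive measurements and per-phase features.

Seven window measurements summarize the preprocessed streams: cognitive
load (mean baseline-normalized pupil diameter), the information
processing index (global-to-local gaze processing ratio), saccade
velocity, mean heart rate, skin-conductance peak count, and tonic and
phasic electrodermal level.  Two cycle-level gaze measurements — time to
the first fixation on the question and the shares of transitions
between the question, the right option and the wrong options — are
computed once per cycle.

Feature vectors per (participant, question, phase) describe the window
series of each measurement with histogram statistics (mean, median, SD,
skewness, kurtosis), the first two coefficients of an order-2
autoregressive fit, and the GARCH(1,1) alpha/beta of the conditional
variance.  Features that cannot be estimated at the available series
length are marked missing, never silently zeroed.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.signal import find_peaks
from scipy.stats import kurtosis, skew

from .config import MEASUREMENTS

__all__ = [
    "count_eda_peaks", "compute_ipi", "aoi_transition_shares",
    "time_to_first_fixation", "minmax_normalize", "extract_features",
    "compute_window_measurements", "fit_garch11",
]

FEATURE_STATS = ("mean", "median", "sd", "skewness", "kurtosis",
                 "ar1", "ar2", "garch_alpha", "garch_beta")


def count_eda_peaks(phasic: np.ndarray, prominence: float = 0.01) -> int:
    """Number of phasic local maxima with at least the given prominence."""
    if prominence <= 0:
        raise ValueError("prominence must be positive")
    x = np.asarray(phasic, float)
    if x.size < 3:
        return 0
    peaks, _ = find_peaks(x, prominence=prominence)
    return int(peaks.size)


def compute_ipi(events: pd.DataFrame, fix_dur_threshold: float,
                amp_threshold: float) -> float:
    """Information processing index of a fixation/saccade sequence.

    Each (fixation, following saccade) pair is classified *global*
    (short fixation and long saccade), *local* (long fixation and short
    saccade) or neither; the index is ``(n_global + 1) / (n_local + 1)``.
    NaN when the window holds no such pair.
    """
    if fix_dur_threshold <= 0 or amp_threshold <= 0:
        raise ValueError("thresholds must be positive")
    kinds = events["kind"].to_numpy()
    n_global = n_local = n_pairs = 0
    for i in range(len(events) - 1):
        if kinds[i] != "fixation" or kinds[i + 1] != "saccade":
            continue
        n_pairs += 1
        fd = events["t_end"].iat[i] - events["t_start"].iat[i]
        amp = events["amplitude"].iat[i + 1]
        if fd < fix_dur_threshold and amp > amp_threshold:
            n_global += 1
        elif fd > fix_dur_threshold and amp < amp_threshold:
            n_local += 1
    if n_pairs == 0:
        return float("nan")
    return (n_global + 1) / (n_local + 1)


def _fixation_aoi(x: float, y: float, layout: dict) -> str | None:
    q = layout["question"]
    if q["x0"] <= x < q["x1"] and q["y0"] <= y < q["y1"]:
        return "question"
    for opt in layout["options"]:
        if opt["x0"] <= x < opt["x1"] and opt["y0"] <= y < opt["y1"]:
            return "right" if opt["correct"] else "wrong"
    return None


def aoi_transition_shares(fixations: pd.DataFrame, layout: dict
                          ) -> dict[str, float]:
    """Percentage shares of the three inter-AOI transition types.

    Categories: question<->right option, question<->wrong options, and
    right<->wrong options.  Fixations outside every AOI break the chain;
    wrong<->wrong pairs are uncategorized and excluded from the
    denominator.  All NaN when no categorized transition occurs.
    """
    labels: list[str | None] = [
        _fixation_aoi(float(r.x), float(r.y), layout)
        for r in fixations.itertuples()
    ]
    counts = {"q_right": 0, "q_wrong": 0, "right_wrong": 0}
    for a, b in zip(labels[:-1], labels[1:]):
        if a is None or b is None or a == b:
            continue
        pair = frozenset((a, b))
        if pair == frozenset(("question", "right")):
            counts["q_right"] += 1
        elif pair == frozenset(("question", "wrong")):
            counts["q_wrong"] += 1
        elif pair == frozenset(("right", "wrong")):
            counts["right_wrong"] += 1
    total = sum(counts.values())
    if total == 0:
        return {k: float("nan") for k in counts}
    return {k: 100.0 * v / total for k, v in counts.items()}


def time_to_first_fixation(onset: float, fixations: pd.DataFrame,
                           layout: dict) -> float:
    """Seconds from question onset to the first fixation on the question."""
    q = layout["question"]
    for r in fixations.itertuples():
        if r.t_end <= onset:
            continue
        if q["x0"] <= r.x < q["x1"] and q["y0"] <= r.y < q["y1"]:
            return max(float(r.t_start) - onset, 0.0)
    return float("nan")


def minmax_normalize(values: pd.Series | np.ndarray
                     ) -> tuple[np.ndarray, bool]:
    """Scale one measurement's values into [0, 1].

    Missing values stay missing; a constant group maps to 0 and raises
    the returned flag.  Raises on an all-missing group.
    """
    x = np.asarray(values, float)
    finite = np.isfinite(x)
    if not finite.any():
        raise ValueError("cannot minmax-normalize an empty group")
    lo, hi = np.min(x[finite]), np.max(x[finite])
    out = x.copy()
    if hi == lo:
        out[finite] = 0.0
        return out, True
    out[finite] = (x[finite] - lo) / (hi - lo)
    return out, False


def compute_window_measurements(
    events: pd.DataFrame,
    pupil_norm: pd.Series,
    hr_t: np.ndarray, hr: np.ndarray,
    eda_t: np.ndarray, tonic: np.ndarray, phasic: np.ndarray,
    phasic_raw: np.ndarray,
    window: tuple[float, float],
    peak_prominence: float = 0.01,
    ipi_fix_threshold: float = 0.3,
    ipi_amp_threshold: float = 0.2,
) -> dict[str, float]:
    """All seven window measurements for one analysis window.

    ``phasic``/``tonic`` are in participant-normalized units while
    ``phasic_raw`` keeps the µS scale required by the peak-prominence
    threshold.  Windows with no saccades (or no fixation-saccade pairs)
    yield NaN for saccade velocity (or the processing index).
    """
    t0, t1 = window
    out: dict[str, float] = {}

    pt = pupil_norm.index.to_numpy()
    pv = pupil_norm.to_numpy()
    sel = (pt >= t0) & (pt < t1) & np.isfinite(pv)
    out["cognitive_load"] = float(np.mean(pv[sel])) if sel.any() else float("nan")

    ev = events[(events["t_start"] >= t0) & (events["t_start"] < t1)]
    sac = ev[ev["kind"] == "saccade"]
    out["saccade_velocity"] = (float(sac["peak_velocity"].mean())
                               if len(sac) else float("nan"))
    out["ipi"] = compute_ipi(ev, ipi_fix_threshold, ipi_amp_threshold)

    hsel = (hr_t >= t0) & (hr_t < t1)
    out["mean_hr"] = float(np.mean(hr[hsel])) if hsel.any() else float("nan")

    esel = (eda_t >= t0) & (eda_t < t1)
    if esel.any():
        out["tonic_eda"] = float(np.mean(tonic[esel]))
        out["phasic_eda"] = float(np.mean(phasic[esel]))
        out["eda_peaks"] = float(count_eda_peaks(phasic_raw[esel], peak_prominence))
    else:
        out["tonic_eda"] = out["phasic_eda"] = out["eda_peaks"] = float("nan")
    return out


def fit_garch11(x: np.ndarray) -> tuple[float, float, float]:
    """Gaussian MLE of a GARCH(1,1): sigma2_t = omega + alpha*x2_{t-1} + beta*sigma2_{t-1}.

    Returns (omega, alpha, beta); input is demeaned first.
    """
    x = np.asarray(x, float)
    x = x - x.mean()
    v = float(np.var(x))
    if v == 0:
        return 0.0, 0.0, 0.0

    def nll(params: np.ndarray) -> float:
        omega, alpha, beta = params
        if alpha + beta >= 0.999:
            return 1e9
        sig2 = np.empty(x.size)
        sig2[0] = v
        for i in range(1, x.size):
            sig2[i] = omega + alpha * x[i - 1] ** 2 + beta * sig2[i - 1]
        if np.any(sig2 <= 0):
            return 1e9
        return float(0.5 * np.sum(np.log(sig2) + x**2 / sig2))

    best = None
    for a0, b0 in ((0.1, 0.8), (0.05, 0.5), (0.2, 0.2)):
        res = minimize(nll, x0=np.array([v * (1 - a0 - b0), a0, b0]),
                       method="L-BFGS-B",
                       bounds=[(1e-10 * max(v, 1e-12), 10 * v),
                               (0.0, 0.998), (0.0, 0.998)])
        if best is None or res.fun < best.fun:
            best = res
    omega, alpha, beta = best.x
    return float(omega), float(alpha), float(beta)


def _ar_coeffs(x: np.ndarray) -> tuple[float, float]:
    from statsmodels.tsa.ar_model import AutoReg
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = AutoReg(x, lags=2, old_names=False).fit()
    return float(res.params[1]), float(res.params[2])


def extract_features(series: np.ndarray,
                     min_ar: int = 6, min_garch: int = 10) -> dict[str, float]:
    """Feature dict for one measurement's window series.

    Histogram statistics are always attempted (SD needs n >= 2,
    skewness/kurtosis n >= 3); AR coefficients need ``min_ar`` points
    and GARCH parameters ``min_garch``.  Unavailable entries are NaN.
    """
    x = np.asarray(series, float)
    x = x[np.isfinite(x)]
    nan = float("nan")
    out = {k: nan for k in FEATURE_STATS}
    if x.size == 0:
        return out
    out["mean"] = float(np.mean(x))
    out["median"] = float(np.median(x))
    if x.size >= 2:
        out["sd"] = float(np.std(x, ddof=1))
    if x.size >= 3 and out["sd"] and out["sd"] > 0:
        out["skewness"] = float(skew(x))
        out["kurtosis"] = float(kurtosis(x))
    if x.size >= min_ar and np.std(x) > 0:
        try:
            out["ar1"], out["ar2"] = _ar_coeffs(x)
        except Exception:
            pass
    if x.size >= min_garch and np.std(x) > 0:
        try:
            _, out["garch_alpha"], out["garch_beta"] = fit_garch11(x)
        except Exception:
            pass
    return out
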