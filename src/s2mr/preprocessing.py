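"""Signal preprocessing: gaze event detection, normalization, EDA
decomposition and analysis windowing.

Gaze events are classified with a velocity-threshold (I-VT) scheme:
point-to-point velocity above the threshold marks a saccade sample,
below marks a fixation sample, and runs of invalid samples (lost pupil)
become blinks.  The velocity threshold is expressed in normalized screen
units per second, so the classifier is resolution-free and invariant
under screen-coordinate translation.

Electrodermal activity is split into a slow tonic component (centered
moving median) and the residual phasic component; the two reconstruct
the smoothed input exactly, which the test suite asserts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter, uniform_filter1d

__all__ = [
    "GazeEvent",
    "Window",
    "detect_gaze_events",
    "normalize_pupil",
    "smooth_series",
    "decompose_eda",
    "baseline_normalize",
    "make_windows",
    "phase_windows",
]


@dataclass(frozen=True)
class GazeEvent:
    kind: str  # fixation | saccade | blink
    t_start: float
    t_end: float
    x: float = np.nan
    y: float = np.nan
    amplitude: float = np.nan
    peak_velocity: float = np.nan


@dataclass(frozen=True)
class Window:
    index: int
    t_start: float
    t_end: float
    phase: str | None = None


EVENT_COLUMNS = ["kind", "t_start", "t_end", "x", "y", "amplitude", "peak_velocity"]


def _runs(labels: np.ndarray) -> list[tuple[int, int, int]]:
    """Run-length encode an int array into (label, start, stop) triples."""
    if labels.size == 0:
        return []
    change = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate(([0], change))
    stops = np.concatenate((change, [labels.size]))
    return [(int(labels[a]), int(a), int(b)) for a, b in zip(starts, stops)]


def detect_gaze_events(
    gaze: pd.DataFrame,
    velocity_threshold: float,
    min_fixation_s: float = 0.06,
) -> pd.DataFrame:
    """Classify raw gaze samples into fixation/saccade/blink events.

    Parameters
    ----------
    gaze:
        Frame with columns ``t, x, y, pupil_l, pupil_r, valid``.
    velocity_threshold:
        Saccade threshold in screen units / s.
    min_fixation_s:
        Fixations shorter than this are dropped and their flanking
        saccades merged; pass 0 to disable (useful for oracle tests).

    Returns
    -------
    DataFrame with one row per event and columns ``kind, t_start, t_end,
    x, y, amplitude, peak_velocity``; empty (with a ``flagged`` attr) if
    no valid samples exist.
    """
    t = gaze["t"].to_numpy(float)
    x = gaze["x"].to_numpy(float)
    y = gaze["y"].to_numpy(float)
    valid = (
        (gaze["valid"].to_numpy() > 0)
        & np.isfinite(x)
        & np.isfinite(y)
        & np.isfinite(gaze["pupil_l"].to_numpy(float))
        & np.isfinite(gaze["pupil_r"].to_numpy(float))
    )
    out = pd.DataFrame(columns=EVENT_COLUMNS)
    if valid.sum() < 2:
        out.attrs["flagged"] = True
        return out

    # 0 = fixation, 1 = saccade, 2 = blink
    labels = np.full(t.size, 2, dtype=int)
    iv = np.flatnonzero(valid)
    tv, xv, yv = t[iv], x[iv], y[iv]
    dt = np.diff(tv)
    vel = np.hypot(np.diff(xv), np.diff(yv)) / np.maximum(dt, 1e-9)
    samp = np.where(vel > velocity_threshold, 1, 0)
    # a valid sample takes the label of the velocity into it; the first
    # valid sample takes the label of the velocity out of it
    lab_valid = np.concatenate(([samp[0]], samp))
    labels[iv] = lab_valid

    dt_med = float(np.median(np.diff(t))) if t.size > 1 else 0.0
    events: list[dict] = []
    for lab, a, b in _runs(labels):
        idx = np.arange(a, b)
        t0 = float(t[a])
        t1 = float(t[b]) if b < t.size else float(t[b - 1] + dt_med)
        if lab == 2:
            events.append(dict(kind="blink", t_start=t0, t_end=t1, x=np.nan, y=np.nan,
                               amplitude=np.nan, peak_velocity=np.nan))
        elif lab == 0:
            events.append(dict(kind="fixation", t_start=t0, t_end=t1,
                               x=float(np.mean(x[idx])), y=float(np.mean(y[idx])),
                               amplitude=np.nan, peak_velocity=np.nan))
        else:
            # amplitude spans from the last pre-saccade to the first
            # post-saccade position so single-sample saccades keep theirs
            lo = max(a - 1, 0)
            hi = min(b, t.size - 1)
            amp = float(np.hypot(x[hi] - x[lo], y[hi] - y[lo]))
            seg_v = np.hypot(np.diff(x[lo:b]), np.diff(y[lo:b])) / np.maximum(np.diff(t[lo:b]), 1e-9)
            pv = float(np.max(seg_v)) if seg_v.size else 0.0
            events.append(dict(kind="saccade", t_start=t0, t_end=t1, x=np.nan, y=np.nan,
                               amplitude=amp, peak_velocity=pv))

    if min_fixation_s > 0:
        events = _drop_short_fixations(events, min_fixation_s)
    df = pd.DataFrame(events, columns=EVENT_COLUMNS)
    df.attrs["flagged"] = False
    return df


def _drop_short_fixations(events: list[dict], min_fixation_s: float) -> list[dict]:
    kept: list[dict] = []
    for ev in events:
        if ev["kind"] == "fixation" and (ev["t_end"] - ev["t_start"]) < min_fixation_s:
            continue
        if kept and kept[-1]["kind"] == ev["kind"] == "saccade":
            prev = kept[-1]
            prev["t_end"] = ev["t_end"]
            prev["amplitude"] = prev["amplitude"] + ev["amplitude"]
            prev["peak_velocity"] = max(prev["peak_velocity"], ev["peak_velocity"])
            continue
        kept.append(dict(ev))
    return kept


def normalize_pupil(gaze: pd.DataFrame, baseline: tuple[float, float],
                    participant: str = "?") -> pd.Series:
    """Z-score pupil diameter against a participant baseline interval.

    Both eyes are averaged where valid; blink samples come back NaN.
    Raises ``ValueError`` if the baseline holds under 1 s of valid data.
    """
    t = gaze["t"].to_numpy(float)
    pl = gaze["pupil_l"].to_numpy(float)
    pr = gaze["pupil_r"].to_numpy(float)
    valid = gaze["valid"].to_numpy() > 0
    import warnings as _w
    with np.errstate(invalid="ignore"), _w.catch_warnings():
        _w.simplefilter("ignore", RuntimeWarning)
        pup = np.nanmean(np.column_stack([pl, pr]), axis=1)
    pup[~valid] = np.nan
    mask = (t >= baseline[0]) & (t < baseline[1]) & np.isfinite(pup)
    if mask.sum() < 2:
        raise ValueError(f"participant {participant}: empty pupil baseline")
    span = t[mask][-1] - t[mask][0]
    if span < 1.0:
        raise ValueError(f"participant {participant}: under 1 s of valid pupil baseline")
    mu = float(np.mean(pup[mask]))
    sd = float(np.std(pup[mask], ddof=1))
    if sd == 0:
        sd = 1.0
    return pd.Series((pup - mu) / sd, index=t, name="pupil_norm")


def smooth_series(x: np.ndarray, fs: float, width_s: float = 0.5) -> np.ndarray:
    """Moving-average smoother used on EDA and HR before analysis."""
    size = max(int(round(width_s * fs)), 1)
    return uniform_filter1d(np.asarray(x, float), size=size, mode="nearest")


def decompose_eda(x: np.ndarray, fs: float, tonic_window_s: float = 4.0
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Split a (smoothed) EDA series into tonic and phasic components.

    Tonic is a centered moving median; phasic is the residual, so
    ``tonic + phasic`` reconstructs the input exactly.
    """
    x = np.asarray(x, float)
    size = max(int(round(tonic_window_s * fs)) | 1, 3)  # odd, >= 3
    tonic = median_filter(x, size=size, mode="nearest")
    return tonic, x - tonic


def baseline_normalize(x: np.ndarray, fs: float, baseline_s: float = 30.0
                       ) -> tuple[np.ndarray, bool]:
    """Z-score a stream against its first ``baseline_s`` seconds.

    Returns the normalized stream and a flag that is True when the
    baseline SD was zero (division by 1 was used instead).
    """
    x = np.asarray(x, float)
    n = int(round(baseline_s * fs))
    if x.size < n:
        raise ValueError(f"stream shorter than {baseline_s} s baseline")
    mu = float(np.mean(x[:n]))
    sd = float(np.std(x[:n], ddof=1))
    flagged = sd == 0
    return (x - mu) / (1.0 if flagged else sd), flagged


def make_windows(t_start: float, t_end: float, window: float, hop: float,
                 phase: str | None = None) -> list[Window]:
    """Tile ``[t_start, t_end)`` with overlapping analysis windows.

    Full windows start every ``hop`` seconds; when no full window fits,
    a single partial window spanning the interval is kept provided it is
    at least half a window long.
    """
    length = t_end - t_start
    if length <= 0:
        return []
    out: list[Window] = []
    k = 0
    while t_start + k * hop + window <= t_end + 1e-9:
        s = t_start + k * hop
        out.append(Window(index=k, t_start=s, t_end=s + window, phase=phase))
        k += 1
    if not out and length >= window / 2:
        out.append(Window(index=0, t_start=t_start, t_end=t_end, phase=phase))
    return out


def phase_windows(t_start: float, t_end: float, window: float, hop: float,
                  phase: str) -> list[Window]:
    """Windows for a single phase segment.

    Same tiling as :func:`make_windows`, but a segment too short for
    even a half-window still yields one window spanning the whole
    segment, so every phase of every cycle contributes data.
    """
    out = make_windows(t_start, t_end, window, hop, phase=phase)
    if not out and t_end - t_start > 0:
        out = [Window(index=0, t_start=t_start, t_end=t_end, phase=phase)]
    return out


def assign_phase(win: Window, segments: list[tuple[str, float, float]]) -> Window:
    """Label a window by the phase containing its midpoint (global mode)."""
    mid = 0.5 * (win.t_start + win.t_end)
    for phase, a, b in segments:
        if a <= mid < b:
            return Window(win.index, win.t_start, win.t_end, phase)
    return Window(win.index, win.t_start, win.t_end, None)
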