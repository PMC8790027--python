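"""Phase segmentation of question cycles.

Each cycle is split into three contiguous half-open segments:

* *see-solve* starts at the first fixation whose centroid lies inside
  the question area of interest at or after question onset;
* *move* starts at the first skeletal frame after that whose total
  joint displacement exceeds an individual movement threshold;
* *respond* runs from the logged selection to the logged response.

Boundaries are clamped so the three segments always partition
``[see_solve_start, response)`` in order.  A cycle in which no fixation
ever lands on the question is flagged unusable and excluded downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import PHASES, RunConfig
from .synthetic import SessionBundle

log = logging.getLogger(__name__)

__all__ = ["PhaseSegment", "joint_displacement", "movement_threshold",
           "segment_cycle", "segment_session"]


@dataclass(frozen=True)
class PhaseSegment:
    participant_id: str
    question_key: tuple[int, int, int]  # (domain, game, question)
    phase: str
    t_start: float
    t_end: float


class SegmentationError(ValueError):
    pass


def joint_displacement(skel: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame total joint displacement.

    Sum over the 25 joints of the Euclidean distance travelled between
    consecutive frames; value ``i`` belongs to the frame at ``t[i+1]``.
    """
    t = skel["t"].to_numpy(float)
    coords = skel.drop(columns="t").to_numpy(float).reshape(len(skel), -1, 3)
    d = np.linalg.norm(np.diff(coords, axis=0), axis=2).sum(axis=1)
    return t[1:], d


def movement_threshold(displacements: np.ndarray, k: float = 2.0) -> float:
    """Individual threshold: mean + k·SD of baseline displacements."""
    d = np.asarray(displacements, float)
    if d.size < 2:
        raise SegmentationError("need at least 3 baseline frames")
    sd = float(np.std(d, ddof=1))
    return max(float(np.mean(d)) + k * sd, 0.0)


def _in_rect(x: float, y: float, r: dict) -> bool:
    return r["x0"] <= x < r["x1"] and r["y0"] <= y < r["y1"]


def segment_cycle(events: pd.DataFrame, disp_t: np.ndarray, disp: np.ndarray,
                  log_entry: dict, k: float = 2.0,
                  fallback_threshold: float | None = None,
                  ) -> list[PhaseSegment] | None:
    """Segment one question cycle; ``None`` if the cycle is unusable.

    ``disp_t``/``disp`` are the per-frame displacement series of the
    whole session (see :func:`joint_displacement`).
    """
    onset = log_entry["onset"]
    selection = log_entry["selection"]
    response = log_entry["response"]
    qrect = log_entry["aoi"]["question"]

    fix = events[(events["kind"] == "fixation") & (events["t_end"] > onset)
                 & (events["t_start"] < response)]
    fx = fix["x"].to_numpy(float)
    fy = fix["y"].to_numpy(float)
    hit = ((fx >= qrect["x0"]) & (fx < qrect["x1"])
           & (fy >= qrect["y0"]) & (fy < qrect["y1"]))
    if not hit.any():
        return None
    ss_start = max(float(fix["t_start"].to_numpy(float)[hit][0]), onset)
    if ss_start >= selection:
        return None

    # threshold from the first half of the candidate see-solve interval,
    # which is the stretch most plausibly free of answer movement; short
    # intervals give unstable SD estimates, so fall back to the
    # participant-level baseline when fewer than 6 frames are available
    half = ss_start + 0.5 * (selection - ss_start)
    base = disp[(disp_t > ss_start) & (disp_t <= half)]
    if base.size >= 6:
        thr = movement_threshold(base, k)
    elif fallback_threshold is not None:
        thr = fallback_threshold
    elif base.size >= 2:
        thr = movement_threshold(base, k)
    else:
        raise SegmentationError("too few skeletal frames and no fallback threshold")

    win = (disp_t > ss_start) & (disp_t <= selection)
    wt = disp_t[win]
    above = disp[win] > thr
    # the answer movement is a sustained super-threshold excursion that
    # lasts until the selection, so prefer the run of consecutive
    # super-threshold frames reaching the end of the interval; isolated
    # jitter spikes earlier in the cycle then cannot trigger
    move_start = None
    runs = []
    start = None
    for i in range(above.size):
        if above[i] and start is None:
            start = i
        elif not above[i] and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, above.size))
    if runs:
        if runs[-1][1] == above.size:
            move_start = float(wt[runs[-1][0]])
        else:
            long_runs = [r for r in runs if r[1] - r[0] >= 3]
            pick = long_runs[0] if long_runs else runs[0]
            move_start = float(wt[pick[0]])
    if move_start is None:
        move_start = selection
        log.warning("move onset not detected before selection; collapsing move "
                    "segment at t=%.2f", selection)
    move_start = float(np.clip(move_start, ss_start, selection))

    pid = log_entry.get("participant", "?")
    key = (log_entry["domain"], log_entry["game"], log_entry["question"])
    return [
        PhaseSegment(pid, key, "see_solve", ss_start, move_start),
        PhaseSegment(pid, key, "move", move_start, selection),
        PhaseSegment(pid, key, "respond", selection, response),
    ]


def segment_session(bundle: SessionBundle, config: RunConfig | None = None
                    ) -> tuple[pd.DataFrame, int]:
    """Segment every cycle of a session.

    Returns a segment table (one row per phase per usable cycle) and the
    number of unusable cycles.  The participant-level fallback movement
    threshold is computed from the idle lead-in before the first question.
    """
    cfg = config or RunConfig()
    events = _session_events(bundle, cfg)
    disp_t, disp = joint_displacement(bundle.skeleton)

    first_onset = min(e["onset"] for e in bundle.log)
    lead = disp[(disp_t < first_onset)]
    fallback = movement_threshold(lead, cfg.movement_k) if lead.size >= 2 else None

    rows = []
    unusable = 0
    for entry in bundle.log:
        entry = dict(entry, participant=bundle.participant_id)
        segs = segment_cycle(events, disp_t, disp, entry, cfg.movement_k, fallback)
        if segs is None:
            unusable += 1
            continue
        for s in segs:
            rows.append(dict(participant=s.participant_id, domain=s.question_key[0],
                             game=s.question_key[1], question=s.question_key[2],
                             phase=s.phase, t_start=s.t_start, t_end=s.t_end))
    cols = ["participant", "domain", "game", "question", "phase", "t_start", "t_end"]
    return pd.DataFrame(rows, columns=cols), unusable


def _session_events(bundle: SessionBundle, cfg: RunConfig) -> pd.DataFrame:
    from .preprocessing import detect_gaze_events
    return detect_gaze_events(bundle.gaze, cfg.velocity_threshold, cfg.min_fixation_s)
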