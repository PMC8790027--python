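"""Synthetic multimodal game-play sessions with known ground truth.

Each generated participant "plays" a sequence of multiple-choice
questions across two content domains.  Every question cycle passes
through three phases — reading/solving the question (*see-solve*),
moving the body toward the chosen answer (*move*) and dragging it to
the response slot (*respond*) — and emits five raw streams:

* gaze samples (50 Hz): screen position, per-eye pupil diameter, validity;
* wrist electrodermal activity (64 Hz, µS): tonic drift plus
  gamma-shaped skin-conductance responses at a Poisson rate;
* heart rate (1 Hz, bpm): participant baseline plus AR(1) noise;
* 25-joint skeletal frames (1 Hz, metres): idle jitter plus a sustained
  whole-body excursion that starts exactly at the move boundary;
* a game log with question onset, selection and response events,
  the chosen option, correctness and the screen layout of the
  question/option areas of interest.

Group differences between right- and wrong-labelled cycles can be
planted per measurement and per phase on the *latent channel* each
measurement summarizes (pupil level for cognitive load, saccade
geometry for the information-processing index and saccade velocity,
skin-conductance response rate for peak counts, response amplitude for
phasic level, heart-rate level for mean HR).  A planted effect of size
``d`` shifts the channel of the affine-labelled cycles by ``d`` pooled
channel SDs, where the pool combines between-participant and
between-cycle variability; the per-cycle channel values are recorded in
the bundle's ground truth so recovery is directly checkable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .config import MEASUREMENTS, PHASES

__all__ = [
    "CohortConfig",
    "EffectSpec",
    "SessionBundle",
    "CHANNEL_MODELS",
    "generate_cohort",
    "generate_question_cycle",
    "make_layout",
]


class GeneratorConfigError(ValueError):
    """Invalid cohort or effect specification."""


@dataclass
class CohortConfig:
    """Study-shaped cohort: 40 children, 2 domains x 3 games x 5 questions,
    five-to-one right:wrong answer imbalance."""

    n_participants: int = 40
    n_domains: int = 2
    n_games_per_domain: int = 3
    n_questions_per_game: int = 5
    p_correct: float = 5.0 / 6.0
    gaze_hz: float = 50.0
    eda_hz: float = 64.0
    hr_hz: float = 1.0
    skeleton_hz: float = 1.0
    #: lognormal medians (s) for see-solve / move / respond durations
    phase_median_s: tuple[float, float, float] = (6.0, 2.0, 2.0)
    phase_log_sd: tuple[float, float, float] = (0.35, 0.30, 0.30)
    gap_s: tuple[float, float] = (2.0, 4.0)
    lead_in_s: float = 35.0
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (self.n_participants, self.n_domains,
                  self.n_games_per_domain, self.n_questions_per_game)
        if any(c < 1 for c in counts):
            raise GeneratorConfigError("all counts must be >= 1")
        if not 0 < self.p_correct < 1:
            raise GeneratorConfigError("p_correct must lie in (0, 1)")
        if min(self.gaze_hz, self.eda_hz, self.hr_hz, self.skeleton_hz) <= 0:
            raise GeneratorConfigError("sampling rates must be positive")
        if any(m <= 0 for m in self.phase_median_s):
            raise GeneratorConfigError("phase medians must be positive")


@dataclass
class EffectSpec:
    """A planted standardized group difference for one measurement.

    ``affinity`` names the label ("right" or "wrong") whose cycles carry
    the *higher* channel value; ``d_*`` are Cohen's-d scale shifts per
    phase in pooled channel SD units.
    """

    measurement: str
    affinity: str
    d_see_solve: float = 0.0
    d_move: float = 0.0
    d_respond: float = 0.0

    def __post_init__(self) -> None:
        if self.measurement not in MEASUREMENTS:
            raise GeneratorConfigError(
                f"unknown measurement {self.measurement!r}; "
                f"supported: {MEASUREMENTS}")
        ds = (self.d_see_solve, self.d_move, self.d_respond)
        if any(d < 0 for d in ds):
            raise GeneratorConfigError("effect sizes must be >= 0")
        if any(d > 0 for d in ds) and self.affinity not in ("right", "wrong"):
            raise GeneratorConfigError("affinity must be 'right' or 'wrong'")

    def d(self, phase: str) -> float:
        return {"see_solve": self.d_see_solve, "move": self.d_move,
                "respond": self.d_respond}[phase]


@dataclass
class SessionBundle:
    """One participant's five raw streams plus game log and ground truth."""

    participant_id: str
    gaze: pd.DataFrame | None
    eda: pd.DataFrame | None
    hr: pd.DataFrame | None
    skeleton: pd.DataFrame | None
    log: list[dict]
    rates: dict[str, float] = field(default_factory=dict)
    ground_truth: dict | None = None


# Latent channel models: base level, between-participant SD, between-cycle SD,
# optional physical floor. Units: pupil mm, HR bpm, saccade velocity screen
# units/s, SCR rate 1/s, amplitudes µS, IPI drive on a logit scale.
CHANNEL_MODELS: dict[str, dict[str, float]] = {
    "cognitive_load":    dict(base=3.60, p_sd=0.30, c_sd=0.20),
    "mean_hr":           dict(base=85.0, p_sd=6.00, c_sd=2.00),
    "saccade_velocity":  dict(base=2.50, p_sd=0.35, c_sd=0.25, floor=1.3),
    "ipi":               dict(base=0.00, p_sd=0.60, c_sd=0.40),
    "eda_peaks":         dict(base=0.08, p_sd=0.020, c_sd=0.015, floor=0.005),
    "phasic_eda":        dict(base=0.15, p_sd=0.040, c_sd=0.030, floor=0.01),
    "tonic_eda":         dict(base=0.00, p_sd=0.25, c_sd=0.15),
}

_Q_RECT = (0.15, 0.85, 0.75, 0.95)  # question strip along the bottom
_OPT_Y = (0.05, 0.30)


def make_layout(correct_index: int) -> dict:
    """Screen layout: one question rect, three option rects (one correct).

    Coordinates normalized to [0, 1], origin top-left, rects half-open.
    """
    options = []
    for i in range(3):
        x0 = 0.03 + i * 0.33
        options.append(dict(x0=x0, x1=x0 + 0.28, y0=_OPT_Y[0], y1=_OPT_Y[1],
                            correct=(i == correct_index)))
    q = dict(x0=_Q_RECT[0], x1=_Q_RECT[1], y0=_Q_RECT[2], y1=_Q_RECT[3])
    return {"question": q, "options": options}


def _rect_center(r: dict) -> tuple[float, float]:
    return (0.5 * (r["x0"] + r["x1"]), 0.5 * (r["y0"] + r["y1"]))


@dataclass
class _Profile:
    """Per-participant latent state shared by all of their cycles."""

    participant_id: str
    channel_base: dict[str, float]   # base + participant offset, per channel
    pupil_asym: float
    eda_level: float
    eda_drift: float
    hr_phi: float = 0.6
    hr_sd: float = 1.2


def _spawn_profile(pid: str, rng: np.random.Generator) -> _Profile:
    bases = {}
    for m, mdl in CHANNEL_MODELS.items():
        v = mdl["base"] + rng.normal(0.0, mdl["p_sd"])
        if "floor" in mdl:
            v = max(v, mdl["floor"])
        bases[m] = v
    return _Profile(
        participant_id=pid,
        channel_base=bases,
        pupil_asym=rng.normal(0.0, 0.06),
        eda_level=max(0.5, 2.0 + rng.normal(0.0, 0.4)),
        eda_drift=rng.normal(0.0, 0.0008),
    )


def _cycle_channels(profile: _Profile, label: str, effects: list[EffectSpec],
                    rng: np.random.Generator) -> dict[str, dict[str, float]]:
    """Draw per-(cycle, phase) channel values with planted shifts."""
    by_meas = {e.measurement: e for e in effects}
    out: dict[str, dict[str, float]] = {}
    for m, mdl in CHANNEL_MODELS.items():
        c_off = rng.normal(0.0, mdl["c_sd"])
        pool = math.hypot(mdl["p_sd"], mdl["c_sd"])
        per_phase = {}
        for ph in PHASES:
            v = profile.channel_base[m] + c_off
            eff = by_meas.get(m)
            if eff is not None and eff.d(ph) > 0 and label == eff.affinity:
                v += eff.d(ph) * pool
            if "floor" in mdl:
                v = max(v, mdl["floor"])
            per_phase[ph] = v
        out[m] = per_phase
    return out


def generate_question_cycle(profile: _Profile, correctness: str,
                            effects: list[EffectSpec],
                            rng: np.random.Generator,
                            config: CohortConfig | None = None,
                            onset: float = 0.0,
                            domain: int = 0, game: int = 0, question: int = 0,
                            ) -> dict:
    """Generate the latent plan of a single question cycle.

    Returns a dict with the log entry, the ground-truth boundaries and
    channel values, and the gaze event plan (fixation/saccade schedule)
    that the stream rasterizer turns into samples.  Total for all valid
    inputs: never raises.
    """
    cfg = config or CohortConfig()
    medians, sds = cfg.phase_median_s, cfg.phase_log_sd
    durs = [m * math.exp(rng.normal(0.0, s)) for m, s in zip(medians, sds)]
    ttff = rng.uniform(0.2, 0.8)
    t_ss = onset + ttff
    t_move = t_ss + durs[0]
    t_sel = t_move + durs[1]
    t_resp = t_sel + durs[2]

    correct_index = int(rng.integers(0, 3))
    layout = make_layout(correct_index)
    if correctness == "right":
        chosen = correct_index
    else:
        chosen = int(rng.choice([i for i in range(3) if i != correct_index]))

    channels = _cycle_channels(profile, correctness, effects, rng)
    plan = _plan_gaze(layout, chosen, channels, (t_ss, t_move, t_sel, t_resp), rng)

    log_entry = dict(domain=int(domain), game=int(game), question=int(question),
                     onset=float(onset), selection=float(t_sel),
                     response=float(t_resp), chosen=int(chosen),
                     correctness=correctness, aoi=layout)
    truth = dict(domain=int(domain), game=int(game), question=int(question),
                 label=correctness, onset=float(onset), t_see_solve=float(t_ss),
                 t_move=float(t_move), t_respond=float(t_sel),
                 t_end=float(t_resp), channels=channels)
    return dict(log=log_entry, truth=truth, gaze_plan=plan,
                chosen=chosen, layout=layout)


def _plan_gaze(layout: dict, chosen: int, channels: dict,
               times: tuple[float, float, float, float],
               rng: np.random.Generator) -> list[dict]:
    """Fixation/saccade schedule covering [t_ss, t_resp).

    The balance between "global" pairs (short fixation then a jump to a
    different area of interest) and "local" pairs (long fixation then a
    small within-area shift) follows the cycle's IPI drive channel, and
    every saccade moves at the cycle's planted peak velocity.
    """
    t_ss, t_move, t_sel, t_resp = times
    q_c = _rect_center(layout["question"])
    opt_c = [_rect_center(o) for o in layout["options"]]
    aois = [("question", q_c)] + [(f"option{i}", c) for i, c in enumerate(opt_c)]

    events: list[dict] = []
    pos = q_c
    cur_aoi = "question"

    def other_target(phase: str) -> tuple[str, tuple[float, float]]:
        if phase == "see_solve":
            if cur_aoi == "question":
                i = int(rng.integers(0, 3))
                return f"option{i}", opt_c[i]
            if rng.random() < 0.55:
                return "question", q_c
            i = int(rng.integers(0, 3))
            return f"option{i}", opt_c[i]
        main = (f"option{chosen}", opt_c[chosen])
        alt = ("question", q_c)
        pick_main = rng.random() < 0.6
        cand = main if pick_main else alt
        if cand[0] == cur_aoi:
            cand = alt if pick_main else main
        return cand

    for phase, a, b in zip(PHASES, (t_ss, t_move, t_sel), (t_move, t_sel, t_resp)):
        drive = channels["ipi"][phase]
        p_global = 1.0 / (1.0 + math.exp(-drive))
        sv = channels["saccade_velocity"][phase]
        t = a
        first = phase == "see_solve"
        while t < b - 1e-9:
            if first:
                fd = max(0.4, rng.normal(0.7, 0.15))
                pos, cur_aoi = q_c, "question"
                first = False
                is_global = True
            elif rng.random() < p_global:
                fd = float(np.clip(rng.normal(0.15, 0.03), 0.08, None))
                is_global = True
            else:
                fd = float(np.clip(rng.normal(0.45, 0.08), 0.25, None))
                is_global = False
            fe = min(t + fd, b)
            events.append(dict(kind="fixation", t_start=t, t_end=fe,
                               x=pos[0], y=pos[1]))
            t = fe
            if t >= b - 1e-9:
                break
            if is_global:
                cur_aoi, target = other_target(phase)
                jitter = rng.normal(0.0, 0.02, size=2)
                target = (float(np.clip(target[0] + jitter[0], 0.02, 0.98)),
                          float(np.clip(target[1] + jitter[1], 0.02, 0.98)))
            else:
                r = float(np.clip(rng.normal(0.10, 0.02), 0.05, None))
                th = rng.uniform(0.0, 2 * math.pi)
                target = (float(np.clip(pos[0] + r * math.cos(th), 0.02, 0.98)),
                          float(np.clip(pos[1] + r * math.sin(th), 0.02, 0.98)))
            dist = math.hypot(target[0] - pos[0], target[1] - pos[1])
            v = max(1.3, sv + rng.normal(0.0, 0.2))
            sd_dur = max(dist / v, 0.02)
            se = min(t + sd_dur, b)
            events.append(dict(kind="saccade", t_start=t, t_end=se,
                               x=pos[0], y=pos[1], x2=target[0], y2=target[1]))
            pos = target
            t = se
    return events


_SCR_RISE, _SCR_DECAY = 0.7, 3.0


def _scr_kernel(fs: float) -> np.ndarray:
    tk = np.arange(0.0, 10.0, 1.0 / fs)
    k = (1.0 - np.exp(-tk / _SCR_RISE)) * np.exp(-tk / _SCR_DECAY)
    return k / k.max()


# 25-joint resting template (m), body-centered: head, shoulder-center,
# spine, hip-center, then L/R hand, wrist, elbow, shoulder, foot, ankle,
# knee, hip.
def _template() -> np.ndarray:
    left = np.array([
        [-0.45, 1.05, 0.05], [-0.42, 1.10, 0.03], [-0.35, 1.25, 0.0],
        [-0.20, 1.45, 0.0], [-0.10, 0.05, 0.02], [-0.10, 0.10, 0.0],
        [-0.12, 0.50, 0.0], [-0.10, 0.95, 0.0],
    ])
    right = left * np.array([-1.0, 1.0, 1.0])
    center = np.array([[0.0, 1.70, 0.0], [0.0, 1.45, 0.0],
                       [0.0, 1.20, 0.0], [0.0, 0.95, 0.0]])
    return np.vstack([center, left, right])  # 20 of the 25 joints


_TEMPLATE = None


def _joint_template() -> np.ndarray:
    global _TEMPLATE
    if _TEMPLATE is None:
        base = _template()
        extra = np.array([[0.0, 1.60, 0.05], [0.05, 1.35, 0.02],
                          [-0.05, 1.35, 0.02], [0.15, 1.10, 0.0],
                          [-0.15, 1.10, 0.0]])
        _TEMPLATE = np.vstack([base, extra])  # 25 joints
    return _TEMPLATE


def _generate_session(pid: str, cfg: CohortConfig, effects: list[EffectSpec],
                      rng: np.random.Generator, streams: bool) -> SessionBundle:
    profile = _spawn_profile(pid, rng)

    cycles: list[dict] = []
    t = cfg.lead_in_s
    for d in range(cfg.n_domains):
        for g in range(cfg.n_games_per_domain):
            for q in range(cfg.n_questions_per_game):
                label = "right" if rng.random() < cfg.p_correct else "wrong"
                cyc = generate_question_cycle(
                    profile, label, effects, rng, cfg, onset=t,
                    domain=d, game=g, question=q)
                cycles.append(cyc)
                t = cyc["truth"]["t_end"] + rng.uniform(*cfg.gap_s)
    total = t + 5.0

    log = [c["log"] for c in cycles]
    truth = dict(participant=pid,
                 cycles=[c["truth"] for c in cycles],
                 effects=[asdict(e) for e in effects])
    rates = dict(gaze=cfg.gaze_hz, eda=cfg.eda_hz, hr=cfg.hr_hz,
                 skeleton=cfg.skeleton_hz)

    if not streams:
        return SessionBundle(pid, None, None, None, None, log, rates, truth)

    gaze = _raster_gaze(profile, cfg, cycles, total, rng)
    eda = _raster_eda(profile, cfg, cycles, total, rng)
    hr = _raster_hr(profile, cfg, cycles, total, rng)
    skel = _raster_skeleton(profile, cfg, cycles, total, rng)
    return SessionBundle(pid, gaze, eda, hr, skel, log, rates, truth)


def _ar1_fast(n: int, phi: float, proc_sd: float,
              rng: np.random.Generator) -> np.ndarray:
    """AR(1) via lfilter (vectorized)."""
    from scipy.signal import lfilter
    e = rng.normal(0.0, proc_sd * math.sqrt(1 - phi * phi), size=n)
    e[0] = rng.normal(0.0, proc_sd)
    return lfilter([1.0], [1.0, -phi], e)


def _raster_gaze(profile: _Profile, cfg: CohortConfig, cycles: list[dict],
                 total: float, rng: np.random.Generator) -> pd.DataFrame:
    fs = cfg.gaze_hz
    n = int(total * fs)
    t = np.arange(n) / fs

    # idle: slow wandering inside a central box that avoids all AOIs
    x = 0.5 + np.clip(np.cumsum(rng.normal(0, 0.008, n)), -0.18, 0.18)
    y = 0.5 + np.clip(np.cumsum(rng.normal(0, 0.008, n)), -0.12, 0.12)

    slow = _ar1_fast(n, 0.995, 0.06, rng)
    pup = np.full(n, profile.channel_base["cognitive_load"]) + slow

    for cyc in cycles:
        tr = cyc["truth"]
        for ev in cyc["gaze_plan"]:
            i0 = int(np.ceil(ev["t_start"] * fs))
            i1 = max(int(np.ceil(ev["t_end"] * fs)), i0 + 1)
            i0, i1 = min(i0, n), min(i1, n)
            if i1 <= i0:
                continue
            m = i1 - i0
            if ev["kind"] == "fixation":
                x[i0:i1] = ev["x"] + rng.normal(0, 0.002, m)
                y[i0:i1] = ev["y"] + rng.normal(0, 0.002, m)
            else:
                frac = (t[i0:i1] - ev["t_start"]) / max(ev["t_end"] - ev["t_start"], 1e-9)
                x[i0:i1] = ev["x"] + frac * (ev["x2"] - ev["x"])
                y[i0:i1] = ev["y"] + frac * (ev["y2"] - ev["y"])
        # pupil follows the phase's cognitive-load channel
        bounds = (tr["t_see_solve"], tr["t_move"], tr["t_respond"], tr["t_end"])
        for ph, a, b in zip(PHASES, bounds[:-1], bounds[1:]):
            i0, i1 = int(np.ceil(a * fs)), min(int(np.ceil(b * fs)), n)
            if i1 > i0:
                pup[i0:i1] = cyc["truth"]["channels"]["cognitive_load"][ph] + slow[i0:i1]

    valid = np.ones(n, dtype=int)
    # blinks: background Poisson plus roughly one per third of cycles
    blink_times = list(rng.uniform(0, total, size=rng.poisson(0.04 * total)))
    for cyc in cycles:
        tr = cyc["truth"]
        if rng.random() < 0.3:
            blink_times.append(rng.uniform(tr["onset"], tr["t_end"]))
    for bt in blink_times:
        i0 = int(bt * fs)
        i1 = min(i0 + int(rng.uniform(0.1, 0.2) * fs), n)
        valid[i0:i1] = 0

    pl = pup + profile.pupil_asym / 2 + rng.normal(0, 0.02, n)
    pr = pup - profile.pupil_asym / 2 + rng.normal(0, 0.02, n)
    xb, yb = x.copy(), y.copy()
    bad = valid == 0
    xb[bad] = np.nan
    yb[bad] = np.nan
    pl[bad] = np.nan
    pr[bad] = np.nan
    return pd.DataFrame(dict(t=t, x=xb, y=yb, pupil_l=pl, pupil_r=pr, valid=valid))


def _raster_eda(profile: _Profile, cfg: CohortConfig, cycles: list[dict],
                total: float, rng: np.random.Generator) -> pd.DataFrame:
    fs = cfg.eda_hz
    n = int(total * fs)
    t = np.arange(n) / fs
    tonic = (profile.eda_level + profile.eda_drift * t
             + 0.12 * np.sin(2 * math.pi * t / 300.0 + rng.uniform(0, 2 * math.pi)))
    sig = tonic.copy()

    kernel = _scr_kernel(fs)
    kl = kernel.size

    def add_scrs(a: float, b: float, rate: float, amp: float) -> None:
        dur = b - a
        for _ in range(rng.poisson(max(rate, 0.0) * dur)):
            i0 = int(rng.uniform(a, b) * fs)
            if i0 >= n:
                continue
            seg = min(kl, n - i0)
            sig[i0:i0 + seg] += amp * math.exp(rng.normal(0, 0.3) - 0.045) * kernel[:seg]

    # background arousal outside of question cycles
    add_scrs(0.0, total, 0.03, profile.channel_base["phasic_eda"])
    for cyc in cycles:
        tr = cyc["truth"]
        ch = tr["channels"]
        bounds = (tr["t_see_solve"], tr["t_move"], tr["t_respond"], tr["t_end"])
        for ph, a, b in zip(PHASES, bounds[:-1], bounds[1:]):
            add_scrs(a, b, ch["eda_peaks"][ph], ch["phasic_eda"][ph])
            i0, i1 = int(np.ceil(a * fs)), min(int(np.ceil(b * fs)), n)
            if i1 > i0:
                sig[i0:i1] += ch["tonic_eda"][ph] - CHANNEL_MODELS["tonic_eda"]["base"]

    sig += rng.normal(0, 0.005, n)
    # occasional single-sample artifacts the pre-smoother must absorb
    for _ in range(rng.poisson(0.02 * total)):
        i = int(rng.uniform(0, n))
        sig[i] += rng.choice([-1.0, 1.0]) * rng.uniform(0.1, 0.3)
    return pd.DataFrame(dict(t=t, eda=np.maximum(sig, 0.0)))


def _raster_hr(profile: _Profile, cfg: CohortConfig, cycles: list[dict],
               total: float, rng: np.random.Generator) -> pd.DataFrame:
    fs = cfg.hr_hz
    n = int(total * fs)
    t = np.arange(n) / fs
    hr = profile.channel_base["mean_hr"] + _ar1_fast(n, profile.hr_phi,
                                                     profile.hr_sd, rng)
    base = profile.channel_base["mean_hr"]
    for cyc in cycles:
        tr = cyc["truth"]
        bounds = (tr["t_see_solve"], tr["t_move"], tr["t_respond"], tr["t_end"])
        for ph, a, b in zip(PHASES, bounds[:-1], bounds[1:]):
            i0 = int(np.ceil(a * fs))
            i1 = min(max(int(np.ceil(b * fs)), i0 + 1), n)
            if i1 > i0:
                hr[i0:i1] += cyc["truth"]["channels"]["mean_hr"][ph] - base
    return pd.DataFrame(dict(t=t, hr=hr))


def _raster_skeleton(profile: _Profile, cfg: CohortConfig, cycles: list[dict],
                     total: float, rng: np.random.Generator) -> pd.DataFrame:
    fs = cfg.skeleton_hz
    n = int(total * fs)
    t = np.arange(n) / fs
    center = np.zeros((n, 3))

    for cyc in cycles:
        tr = cyc["truth"]
        opt = cyc["layout"]["options"][cyc["chosen"]]
        target_x = (0.5 * (opt["x0"] + opt["x1"]) - 0.5) * 2.0
        t_move, t_sel, t_end = tr["t_move"], tr["t_respond"], tr["t_end"]
        # move: step toward the screen; respond: slide to the option column
        m = (t >= t_move) & (t < t_sel)
        frac = (t[m] - t_move) / max(t_sel - t_move, 1e-9)
        center[m, 2] = 0.4 * frac
        r = (t >= t_sel) & (t < t_end)
        frac = (t[r] - t_sel) / max(t_end - t_sel, 1e-9)
        center[r, 0] = target_x * frac
        center[r, 2] = 0.4 * (1 - frac)
        # drift back to the start mark during the following gap
        back = (t >= t_end) & (t < t_end + 1.5)
        frac = 1.0 - (t[back] - t_end) / 1.5
        center[back, 0] = target_x * frac

    joints = _joint_template()[None, :, :] + center[:, None, :]
    joints = joints + rng.normal(0, 0.004, size=joints.shape)
    cols = {}
    for j in range(25):
        for k, ax in enumerate("xyz"):
            cols[f"j{j:02d}_{ax}"] = joints[:, j, k]
    return pd.DataFrame(dict(t=t, **cols))


def generate_cohort(config: CohortConfig, effects: list[EffectSpec] | None = None,
                    streams: bool = True) -> list[SessionBundle]:
    """Generate a full cohort of session bundles.

    Deterministic for a fixed ``config.seed``; each participant draws
    from an independent child stream of the cohort seed.  With
    ``streams=False`` only logs, ground truth and latent channel values
    are produced (fast path for generator-level checks).
    """
    effects = list(effects or [])
    for e in effects:
        if not isinstance(e, EffectSpec):
            raise GeneratorConfigError("effects must be EffectSpec instances")
    ss = np.random.SeedSequence(config.seed)
    bundles = []
    for i, child in enumerate(ss.spawn(config.n_participants)):
        rng = np.random.default_rng(child)
        bundles.append(_generate_session(f"P{i:03d}", config, effects, rng, streams))
    return bundles
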