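"""End-to-end orchestration: preprocess streams, window them by phase,
extract measurements and features, and run both carry-forward analyses.

The analysis unit is one game domain: measurements are minmax-normalized
and tested within a domain, the Bonferroni family is all
(measurement x phase) tests of that domain, and predictive models are
fitted per (domain, phase).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import CYCLE_MEASUREMENTS, MEASUREMENTS, PHASES, RunConfig
from .inferential import analyze_game
from .measurements import (FEATURE_STATS, aoi_transition_shares,
                           count_eda_peaks, extract_features,
                           minmax_normalize, time_to_first_fixation)
from .preprocessing import (assign_phase, baseline_normalize,
                            decompose_eda, detect_gaze_events, make_windows,
                            normalize_pupil, phase_windows, smooth_series)
from .predictive import (classify_cfe_predictive, fit_ensemble, lopo_folds,
                         predict_and_evaluate, rank_feature_importance)
from .segmentation import segment_session
from .synthetic import SessionBundle

__all__ = ["preprocess_session", "session_measurements", "cohort_tables",
           "cycle_values", "run_inferential", "feature_table",
           "run_predictive", "run_all"]

FEATURE_COLUMNS = [f"{m}:{s}" for m in MEASUREMENTS for s in FEATURE_STATS]


@dataclass
class ProcessedSession:
    events: pd.DataFrame
    pupil_norm: pd.Series
    hr_t: np.ndarray
    hr_norm: np.ndarray
    eda_t: np.ndarray
    tonic_norm: np.ndarray
    phasic_norm: np.ndarray
    phasic_raw: np.ndarray
    ipi_fix_threshold: float
    ipi_amp_threshold: float
    flags: dict


def preprocess_session(bundle: SessionBundle, cfg: RunConfig) -> ProcessedSession:
    """Clean and normalize one session's raw streams."""
    events = detect_gaze_events(bundle.gaze, cfg.velocity_threshold,
                                cfg.min_fixation_s)
    pupil = normalize_pupil(bundle.gaze, (0.0, cfg.baseline_s),
                            bundle.participant_id)

    hr_hz = bundle.rates["hr"]
    hr_s = smooth_series(bundle.hr["hr"].to_numpy(float), hr_hz, cfg.eda_smooth_s)
    hr_norm, hr_flag = baseline_normalize(hr_s, hr_hz, cfg.baseline_s)

    eda_hz = bundle.rates["eda"]
    eda_s = smooth_series(bundle.eda["eda"].to_numpy(float), eda_hz,
                          cfg.eda_smooth_s)
    tonic_raw, phasic_raw = decompose_eda(eda_s, eda_hz, cfg.tonic_window_s)
    nb = int(round(cfg.baseline_s * eda_hz))
    if eda_s.size < nb:
        raise ValueError(f"participant {bundle.participant_id}: EDA stream "
                         f"shorter than {cfg.baseline_s} s baseline")
    mu = float(np.mean(eda_s[:nb]))
    sd = float(np.std(eda_s[:nb], ddof=1))
    eda_flag = sd == 0
    sd = sd if sd > 0 else 1.0

    fix = events[events["kind"] == "fixation"]
    sac = events[events["kind"] == "saccade"]
    fix_thr = float((fix["t_end"] - fix["t_start"]).median()) if len(fix) else 0.3
    amp_thr = float(sac["amplitude"].median()) if len(sac) else 0.2

    return ProcessedSession(
        events=events, pupil_norm=pupil,
        hr_t=bundle.hr["t"].to_numpy(float), hr_norm=hr_norm,
        eda_t=bundle.eda["t"].to_numpy(float),
        tonic_norm=(tonic_raw - mu) / sd, phasic_norm=phasic_raw / sd,
        phasic_raw=phasic_raw,
        ipi_fix_threshold=max(fix_thr, 1e-3),
        ipi_amp_threshold=max(amp_thr, 1e-3),
        flags=dict(hr_baseline_sd_zero=hr_flag, eda_baseline_sd_zero=eda_flag,
                   gaze_empty=bool(events.attrs.get("flagged", False))))


class _FastStreams:
    """Per-session numpy views used by the windowed extraction loop."""

    def __init__(self, proc: ProcessedSession, peak_prominence: float):
        ev = proc.events
        kinds = ev["kind"].to_numpy()
        self.sac_t = ev["t_start"].to_numpy(float)[kinds == "saccade"]
        self.sac_pv = ev["peak_velocity"].to_numpy(float)[kinds == "saccade"]
        # classify every (fixation, following saccade) pair once
        t_start = ev["t_start"].to_numpy(float)
        t_end = ev["t_end"].to_numpy(float)
        amp = ev["amplitude"].to_numpy(float)
        pair = (kinds[:-1] == "fixation") & (kinds[1:] == "saccade")
        idx = np.nonzero(pair)[0]
        fd = t_end[idx] - t_start[idx]
        pamp = amp[idx + 1]
        # a pair counts for a window when both the fixation and its
        # saccade start inside it
        self.pair_t = t_start[idx]
        self.pair_sac_t = t_start[idx + 1]
        self.pair_global = ((fd < proc.ipi_fix_threshold)
                            & (pamp > proc.ipi_amp_threshold)).astype(int)
        self.pair_local = ((fd > proc.ipi_fix_threshold)
                           & (pamp < proc.ipi_amp_threshold)).astype(int)
        self.cum_global = np.concatenate(([0], np.cumsum(self.pair_global)))
        self.cum_local = np.concatenate(([0], np.cumsum(self.pair_local)))

        pt = proc.pupil_norm.index.to_numpy(float)
        pv = proc.pupil_norm.to_numpy(float)
        ok = np.isfinite(pv)
        self.pup_t, self.pup_v = pt[ok], pv[ok]
        self.cum_pup = np.concatenate(([0.0], np.cumsum(self.pup_v)))
        self.hr_t, self.hr_v = proc.hr_t, proc.hr_norm
        self.cum_hr = np.concatenate(([0.0], np.cumsum(self.hr_v)))
        self.eda_t = proc.eda_t
        self.cum_tonic = np.concatenate(([0.0], np.cumsum(proc.tonic_norm)))
        self.cum_phasic = np.concatenate(([0.0], np.cumsum(proc.phasic_norm)))
        self.phasic_raw = proc.phasic_raw
        self.prominence = peak_prominence

    def window_values(self, t0: float, t1: float) -> dict[str, float]:
        nan = float("nan")
        out = {}
        a, b = np.searchsorted(self.pup_t, (t0, t1))
        out["cognitive_load"] = ((self.cum_pup[b] - self.cum_pup[a]) / (b - a)
                                 if b > a else nan)
        a, b = np.searchsorted(self.sac_t, (t0, t1))
        out["saccade_velocity"] = (float(np.mean(self.sac_pv[a:b]))
                                   if b > a else nan)
        a = np.searchsorted(self.pair_t, t0)
        b = np.searchsorted(self.pair_sac_t, t1)
        if b > a:
            ng = self.cum_global[b] - self.cum_global[a]
            nl = self.cum_local[b] - self.cum_local[a]
            out["ipi"] = (ng + 1) / (nl + 1)
        else:
            out["ipi"] = nan
        a, b = np.searchsorted(self.hr_t, (t0, t1))
        out["mean_hr"] = (self.cum_hr[b] - self.cum_hr[a]) / (b - a) if b > a else nan
        a, b = np.searchsorted(self.eda_t, (t0, t1))
        if b > a:
            n = b - a
            out["tonic_eda"] = (self.cum_tonic[b] - self.cum_tonic[a]) / n
            out["phasic_eda"] = (self.cum_phasic[b] - self.cum_phasic[a]) / n
            out["eda_peaks"] = float(count_eda_peaks(self.phasic_raw[a:b],
                                                     self.prominence))
        else:
            out["tonic_eda"] = out["phasic_eda"] = out["eda_peaks"] = nan
        return out


def session_measurements(bundle: SessionBundle, cfg: RunConfig
                         ) -> tuple[pd.DataFrame, pd.DataFrame, int]:
    """Window- and cycle-level measurements for one session.

    Returns the tidy window table (participant, domain, game, question,
    phase, window, measurement, value, label), the cycle-level gaze
    table, and the count of unusable cycles.
    """
    proc = preprocess_session(bundle, cfg)
    segments, unusable = segment_session(bundle, cfg)

    labels = {(e["domain"], e["game"], e["question"]): e["correctness"]
              for e in bundle.log}
    layouts = {(e["domain"], e["game"], e["question"]): e["aoi"]
               for e in bundle.log}
    onsets = {(e["domain"], e["game"], e["question"]): e["onset"]
              for e in bundle.log}

    fast = _FastStreams(proc, cfg.peak_prominence)
    rows = []
    seg_arr = segments.to_records(index=False)
    by_key: dict[tuple, list] = {}
    for r in seg_arr:
        by_key.setdefault((r.domain, r.game, r.question), []).append(
            (r.phase, r.t_start, r.t_end))
    for key in sorted(by_key):
        segs = sorted(by_key[key], key=lambda s: s[1])
        if cfg.windowing == "per_phase":
            wins = [w for ph, a, b in segs
                    for w in phase_windows(a, b, cfg.window_s, cfg.hop_s, ph)]
        else:
            t0 = min(a for _, a, _ in segs)
            t1 = max(b for _, _, b in segs)
            wins = [assign_phase(w, segs)
                    for w in make_windows(t0, t1, cfg.window_s, cfg.hop_s)]
            wins = [w for w in wins if w.phase is not None]
        for wi, w in enumerate(wins):
            vals = fast.window_values(w.t_start, w.t_end)
            for meas, v in vals.items():
                rows.append((bundle.participant_id, *key, w.phase, wi,
                             w.t_start, meas, v, labels[key]))
    win_df = pd.DataFrame(rows, columns=[
        "participant", "domain", "game", "question", "phase", "window",
        "w_start", "measurement", "value", "label"])

    crows = []
    fix = proc.events[proc.events["kind"] == "fixation"]
    for key, layout in layouts.items():
        if key not in by_key:
            continue
        onset = onsets[key]
        end = max(b for _, _, b in by_key[key])
        cyc_fix = fix[(fix["t_end"] > onset) & (fix["t_start"] < end)]
        ttff = time_to_first_fixation(onset, cyc_fix, layout)
        shares = aoi_transition_shares(cyc_fix, layout)
        crows.append((bundle.participant_id, *key, labels[key], ttff,
                      shares["q_right"], shares["q_wrong"],
                      shares["right_wrong"]))
    cyc_df = pd.DataFrame(crows, columns=[
        "participant", "domain", "game", "question", "label",
        *CYCLE_MEASUREMENTS])
    return win_df, cyc_df, unusable


def cohort_tables(bundles: list[SessionBundle], cfg: RunConfig
                  ) -> tuple[pd.DataFrame, pd.DataFrame, int]:
    """Concatenated measurement tables for a whole cohort."""
    wins, cycs, bad = [], [], 0
    for b in bundles:
        w, c, u = session_measurements(b, cfg)
        wins.append(w)
        cycs.append(c)
        bad += u
    return pd.concat(wins, ignore_index=True), \
        pd.concat(cycs, ignore_index=True), bad


def cycle_values(win_df: pd.DataFrame, cfg: RunConfig,
                 normalize: bool = True) -> pd.DataFrame:
    """Per-(cycle, phase) measurement values.

    Window values are averaged within each phase of each question, then
    minmax-normalized per measurement within each domain (the analysis
    family).
    """
    agg = (win_df.groupby(["participant", "domain", "game", "question",
                           "phase", "measurement", "label"], as_index=False)
           ["value"].mean())
    if normalize:
        parts = []
        for (_, _), grp in agg.groupby(["domain", "measurement"]):
            grp = grp.copy()
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                grp["value"], _ = minmax_normalize(grp["value"].to_numpy())
            parts.append(grp)
        agg = pd.concat(parts, ignore_index=True)
    return agg


def run_inferential(bundles: list[SessionBundle], cfg: RunConfig,
                    win_df: pd.DataFrame | None = None) -> dict[int, dict]:
    """Inferential carry-forward analysis per domain."""
    if win_df is None:
        win_df, _, _ = cohort_tables(bundles, cfg)
    vals = cycle_values(win_df, cfg)
    out = {}
    for dom, sub in vals.groupby("domain"):
        table, cfe, results = analyze_game(sub, cfg)
        out[int(dom)] = dict(effects=table, cfe=cfe, results=results)
    return out


def feature_table(win_df: pd.DataFrame, cfg: RunConfig) -> pd.DataFrame:
    """Wide per-(participant, question, phase) feature vectors.

    With ``feature_scope="game"`` the window series of one measurement
    concatenates across all questions of a game (labels then refer to
    the questions the windows came from and the last label wins); the
    default keeps one series per question.
    """
    keys = ["participant", "domain", "game", "question", "phase"]
    if cfg.feature_scope == "game":
        keys = ["participant", "domain", "game", "phase"]
    rows = []
    for key, grp in win_df.groupby(keys, sort=True):
        row = dict(zip(keys, key))
        row["label"] = grp["label"].iloc[-1]
        for meas, sub in grp.groupby("measurement"):
            series = sub.sort_values(["question", "w_start"])["value"].to_numpy() \
                if "question" not in keys else sub.sort_values("w_start")["value"].to_numpy()
            feats = extract_features(series)
            for stat, v in feats.items():
                row[f"{meas}:{stat}"] = v
        rows.append(row)
    df = pd.DataFrame(rows)
    for col in FEATURE_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    return df


def run_predictive(features: pd.DataFrame, cfg: RunConfig,
                   rng: np.random.Generator) -> dict[int, dict]:
    """Predictive modeling and rank-based carry-forward analysis.

    Per (domain, phase): leave-one-participant-out fitting of the
    weighted ensemble, evaluation on the participant holdout, and
    permutation-importance ranks; per domain the per-phase ranks are
    combined into a carry-forward class per feature.
    """
    out: dict[int, dict] = {}
    for dom, dsub in features.groupby("domain"):
        metrics_rows = []
        imp_by_phase: dict[str, pd.DataFrame] = {}
        for ph in PHASES:
            sub = dsub[dsub["phase"] == ph]
            X = sub[FEATURE_COLUMNS].to_numpy(float)
            y = sub["label"].to_numpy()
            pids = sub["participant"].to_numpy()
            holdout, folds = lopo_folds(pids, rng, cfg.holdout_fraction)
            hold_mask = np.isin(pids, holdout)

            fitted = []
            weight_sum = None
            for train_ids, val_ids in folds:
                tr = np.isin(pids, train_ids)
                va = np.isin(pids, val_ids)
                if np.unique(y[tr]).size < 2 or va.sum() == 0:
                    continue
                model = fit_ensemble(X[tr], y[tr], X[va], y[va], rng,
                                     per_point=cfg.smote_per_point)
                fitted.append((model, X[va], y[va]))
                weight_sum = (model.weights if weight_sum is None
                              else weight_sum + model.weights)
            if not fitted:
                continue
            imp = rank_feature_importance(fitted, FEATURE_COLUMNS, rng,
                                          cfg.top_fraction)
            imp_by_phase[ph] = imp

            rest = ~hold_mask
            final = fit_ensemble(X[rest], y[rest], X[rest], y[rest], rng,
                                 per_point=cfg.smote_per_point)
            final.weights = weight_sum / weight_sum.sum()
            ev = predict_and_evaluate(final, X[hold_mask], y[hold_mask])
            metrics_rows.append(dict(phase=ph, precision=ev.precision,
                                     recall=ev.recall, f1=ev.f1,
                                     tp=ev.tp, fp=ev.fp, tn=ev.tn, fn=ev.fn))

        cfe_rows = []
        for feat in FEATURE_COLUMNS:
            ranks, top = {}, {}
            for ph, imp in imp_by_phase.items():
                row = imp[imp["feature"] == feat].iloc[0]
                ranks[ph] = float(row["rank"])
                top[ph] = bool(row["top"])
            if len(ranks) == len(PHASES):
                cls = classify_cfe_predictive(ranks, top)
                cfe_rows.append(dict(
                    feature=feat,
                    rank_see_solve=ranks["see_solve"] if top["see_solve"] else np.nan,
                    rank_move=ranks["move"] if top["move"] else np.nan,
                    rank_respond=ranks["respond"] if top["respond"] else np.nan,
                    in_top_any=any(top.values()), cfe=cls))
        rank_df = pd.DataFrame(cfe_rows)
        if len(rank_df):
            rank_df = rank_df[rank_df["in_top_any"]].drop(columns="in_top_any")
        out[int(dom)] = dict(metrics=pd.DataFrame(metrics_rows),
                             ranks=rank_df,
                             importance=imp_by_phase)
    return out


def run_all(cohort_config, effects, cfg: RunConfig,
            with_predictive: bool = True) -> dict:
    """Simulate a cohort and run the complete analysis.

    Returns a dict with the window/cycle tables, per-domain inferential
    and predictive results, and per-domain feedback plans.
    """
    from .feedback import prioritize
    from .synthetic import generate_cohort

    bundles = generate_cohort(cohort_config, effects)
    win_df, cyc_df, unusable = cohort_tables(bundles, cfg)
    inf = run_inferential(bundles, cfg, win_df=win_df)

    pred = {}
    if with_predictive:
        feats = feature_table(win_df, cfg)
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 7]))
        pred = run_predictive(feats, cfg, rng)

    plans = {}
    for dom, res in inf.items():
        cfe_classes = {m: c.cfe_class for m, c in res["cfe"].items()}
        evidence = {}
        for m in cfe_classes:
            r = res["results"][m]
            evidence[m] = dict(
                es_see_solve=r["see_solve"].effect_size,
                affinity=r["see_solve"].affinity,
                sig={ph: bool(r[ph].testable and np.isfinite(r[ph].p_adj)
                              and r[ph].p_adj < cfg.alpha) for ph in PHASES})
        plans[dom] = prioritize(cfe_classes, evidence)

    return dict(bundles=bundles, windows=win_df, cycles=cyc_df,
                unusable=unusable, inferential=inf, predictive=pred,
                plans=plans)
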