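"""On-disk formats for session bundles and result reports.

A session directory holds five files:

* ``gaze.csv`` — columns ``t,x,y,pupil_l,pupil_r,valid``;
* ``eda.csv`` / ``hr.csv`` — wristband dialect: row 1 is the UTC start
  epoch, row 2 the sampling rate in Hz, then one value per row;
* ``skeleton.csv`` — ``t`` plus 75 joint-coordinate columns
  (``j00_x`` … ``j24_z``);
* ``log.json`` — one object per question (onset/selection/response
  times, chosen option, correctness, AOI layout).

Timestamps are seconds as decimal text and every stream is re-based to
a shared t = 0 on read.  Readers validate required columns, strict
timestamp monotonicity and that each stream covers the logged session
span, so silently truncated files are rejected rather than returned as
partial streams.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import SessionBundle

__all__ = ["FormatError", "write_session", "read_session", "write_cohort",
           "read_cohort", "write_reports"]

_EPOCH = 1600000000.0

GAZE_COLUMNS = ["t", "x", "y", "pupil_l", "pupil_r", "valid"]


class FormatError(ValueError):
    """A session file failed validation; the message names file and line."""


def write_session(bundle: SessionBundle, path: str | Path) -> None:
    """Write one session bundle to a directory."""
    d = Path(path)
    d.mkdir(parents=True, exist_ok=True)
    bundle.gaze.to_csv(d / "gaze.csv", index=False, float_format="%.6f")

    for name, df, col in (("eda", bundle.eda, "eda"), ("hr", bundle.hr, "hr")):
        rate = bundle.rates[name]
        lines = [f"{_EPOCH:.6f}", f"{rate:.6f}"]
        lines += [f"{v:.6f}" for v in df[col].to_numpy(float)]
        (d / f"{name}.csv").write_text("\n".join(lines) + "\n")

    bundle.skeleton.to_csv(d / "skeleton.csv", index=False, float_format="%.6f")
    meta = dict(participant=bundle.participant_id, rates=bundle.rates,
                questions=bundle.log)
    (d / "log.json").write_text(json.dumps(meta, indent=1, sort_keys=True))
    if bundle.ground_truth is not None:
        (d / "ground_truth.json").write_text(
            json.dumps(bundle.ground_truth, sort_keys=True))


def _read_e4(path: Path, expected_span: float
             ) -> tuple[pd.DataFrame, np.ndarray, float]:
    lines = path.read_text().strip().splitlines()
    if len(lines) < 3:
        raise FormatError(f"{path}: line 1: need start epoch, rate and data rows")
    try:
        float(lines[0])
        rate = float(lines[1])
    except ValueError as exc:
        raise FormatError(f"{path}: line 1-2: bad header ({exc})") from exc
    if rate <= 0:
        raise FormatError(f"{path}: line 2: rate must be positive")
    try:
        vals = np.array([float(v) for v in lines[2:]])
    except ValueError as exc:
        raise FormatError(f"{path}: data row: {exc}") from exc
    span = len(vals) / rate
    if span + 1.0 / rate < expected_span:
        raise FormatError(
            f"{path}: line {len(lines)}: stream covers {span:.1f} s but the "
            f"log spans {expected_span:.1f} s (truncated file?)")
    t = np.arange(len(vals)) / rate
    return pd.DataFrame({"t": t}), vals, rate


def _check_monotone(t: np.ndarray, path: Path) -> None:
    bad = np.nonzero(np.diff(t) <= 0)[0]
    if bad.size:
        raise FormatError(f"{path}: line {bad[0] + 3}: timestamps not "
                          "strictly increasing")


def _check_columns(df: pd.DataFrame, cols: list[str], path: Path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: line 1: missing columns {missing}")


def read_session(path: str | Path) -> SessionBundle:
    """Read a session directory back into a :class:`SessionBundle`."""
    d = Path(path)
    log_path = d / "log.json"
    if not log_path.exists():
        raise FormatError(f"{log_path}: missing")
    meta = json.loads(log_path.read_text())
    questions = meta["questions"]
    span = max((q["response"] for q in questions), default=0.0)

    gaze = pd.read_csv(d / "gaze.csv")
    _check_columns(gaze, GAZE_COLUMNS, d / "gaze.csv")
    _check_monotone(gaze["t"].to_numpy(float), d / "gaze.csv")
    if len(gaze) and gaze["t"].iloc[-1] < span:
        raise FormatError(f"{d / 'gaze.csv'}: line {len(gaze) + 1}: stream ends "
                          f"at {gaze['t'].iloc[-1]:.1f} s before the logged "
                          f"session end {span:.1f} s (truncated file?)")

    eda_df, eda_vals, eda_rate = _read_e4(d / "eda.csv", span)
    hr_df, hr_vals, hr_rate = _read_e4(d / "hr.csv", span)
    eda = pd.DataFrame({"t": eda_df["t"], "eda": eda_vals})
    hr = pd.DataFrame({"t": hr_df["t"], "hr": hr_vals})

    skel = pd.read_csv(d / "skeleton.csv")
    joint_cols = [f"j{j:02d}_{ax}" for j in range(25) for ax in "xyz"]
    _check_columns(skel, ["t"] + joint_cols, d / "skeleton.csv")
    _check_monotone(skel["t"].to_numpy(float), d / "skeleton.csv")

    # re-base all streams to a shared t = 0
    t0 = min(gaze["t"].iloc[0] if len(gaze) else 0.0,
             eda["t"].iloc[0], hr["t"].iloc[0],
             skel["t"].iloc[0] if len(skel) else 0.0)
    for df in (gaze, eda, hr, skel):
        df["t"] = df["t"] - t0

    truth = None
    gt_path = d / "ground_truth.json"
    if gt_path.exists():
        truth = json.loads(gt_path.read_text())
    rates = meta.get("rates", dict(gaze=50.0, eda=eda_rate, hr=hr_rate,
                                   skeleton=1.0))
    return SessionBundle(meta["participant"], gaze, eda, hr, skel,
                         questions, rates, truth)


def write_cohort(bundles: list[SessionBundle], path: str | Path) -> None:
    d = Path(path)
    d.mkdir(parents=True, exist_ok=True)
    for b in bundles:
        write_session(b, d / b.participant_id)
    (d / "cohort.json").write_text(json.dumps(
        dict(participants=[b.participant_id for b in bundles]), sort_keys=True))


def read_cohort(path: str | Path) -> list[SessionBundle]:
    d = Path(path)
    meta = json.loads((d / "cohort.json").read_text())
    return [read_session(d / pid) for pid in meta["participants"]]


def _fmt(v) -> str:
    if v is None or (isinstance(v, float) and not np.isfinite(v)):
        return "-"
    if isinstance(v, (bool, np.bool_)):
        return str(bool(v))
    if isinstance(v, (float, np.floating)):
        return f"{v:.4f}"
    return str(v)


def _write_tsv(path: Path, columns: list[str], rows: list[dict]) -> None:
    lines = ["\t".join(columns)]
    for r in rows:
        lines.append("\t".join(_fmt(r.get(c)) for c in columns))
    path.write_text("\n".join(lines) + "\n")


def write_reports(out_dir: str | Path, inferential: dict | None = None,
                  predictive: dict | None = None,
                  plans: dict | None = None) -> list[Path]:
    """Write the effect, rank, metric and feedback-plan reports.

    One file set per domain: ``effects_<d>.tsv`` (measurement, per-phase
    effect size and significance, carry-forward class),
    ``metrics_<d>.tsv`` (per-phase precision/recall/F1),
    ``ranks_<d>.tsv`` (feature, per-phase importance rank,
    carry-forward class) and ``feedback_plan_<d>.json``.  Empty result
    sets yield headers-only files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    for dom, res in sorted((inferential or {}).items()):
        p = out / f"effects_{dom}.tsv"
        cols = ["measurement", "es_see_solve", "es_move", "es_respond",
                "sig_see_solve", "sig_move", "sig_respond", "cfe"]
        _write_tsv(p, cols, res["effects"].to_dict("records")
                   if len(res["effects"]) else [])
        written.append(p)

    for dom, res in sorted((predictive or {}).items()):
        p = out / f"metrics_{dom}.tsv"
        cols = ["phase", "precision", "recall", "f1"]
        _write_tsv(p, cols, res["metrics"].to_dict("records")
                   if len(res["metrics"]) else [])
        written.append(p)
        p = out / f"ranks_{dom}.tsv"
        cols = ["feature", "rank_see_solve", "rank_move", "rank_respond", "cfe"]
        _write_tsv(p, cols, res["ranks"].to_dict("records")
                   if len(res["ranks"]) else [])
        written.append(p)

    for dom, plan in sorted((plans or {}).items()):
        p = out / f"feedback_plan_{dom}.json"
        p.write_text(json.dumps(plan.to_json_obj(), indent=1, sort_keys=True,
                                default=_json_default))
        written.append(p)
    return written


def _json_default(v):
    if isinstance(v, (np.floating, np.integer)):
        v = v.item()
    if isinstance(v, float) and not np.isfinite(v):
        return None
    return v
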