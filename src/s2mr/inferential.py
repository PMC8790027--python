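"""Inferential carry-forward-effect analysis.

For every (measurement, phase) cell the per-cycle values are compared
between right and wrong responses with a repeated-measures ANOVA using
the participant as grouping variable.  Normality of the residuals is
screened with a Shapiro-Wilk test (failure triggers a rank-based
z-transform) and homoscedasticity with a Breusch-Pagan test (failure
switches to a Welch one-way ANOVA on participant-level means, since
Welch's correction has no repeated-measures form).  Effect size is
partial eta-squared; raw p-values are Bonferroni-adjusted within the
family of all (measurement x phase) tests of one game.

A measurement carries forward when four conditions hold: (1) the group
difference is significant in every phase, (2) the effect size peaks in
see-solve, (3) the move effect exceeds the respond effect, and (4) the
affinity (label of the larger group mean) is the same in every phase.
All four give a *perfect* effect; by default failing only condition (3)
gives a *pseudo* effect (the variant where condition (4) is the
pseudo-breaking one is selectable); anything else is *none*.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import MEASUREMENTS, PHASES, RunConfig

__all__ = ["EffectResult", "CFEResult", "run_phase_test", "bonferroni_adjust",
           "classify_cfe_inferential", "analyze_game"]


@dataclass
class EffectResult:
    measurement: str
    phase: str
    F: float = float("nan")
    df1: float = float("nan")
    df2: float = float("nan")
    p: float = float("nan")
    p_adj: float = float("nan")
    effect_size: float = float("nan")
    affinity: str | None = None
    welch_used: bool = False
    ztransformed: bool = False
    testable: bool = True
    reason: str = ""

    @property
    def significant(self) -> bool:
        return self.testable and np.isfinite(self.p_adj) and self.p_adj < self._alpha

    _alpha: float = 0.05


@dataclass
class CFEResult:
    measurement: str
    cfe_class: str  # perfect | pseudo | none
    sig_all: bool = False
    max_in_see_solve: bool = False
    move_gt_respond: bool = False
    affinity_consistent: bool = False
    reason: str = ""


def _rank_z(x: np.ndarray) -> np.ndarray:
    """Rank-based inverse-normal (van der Waerden) transform."""
    r = stats.rankdata(x)
    return stats.norm.ppf((r - 0.375) / (x.size + 0.25))


def run_phase_test(values: np.ndarray, labels: np.ndarray,
                   participants: np.ndarray, alpha: float = 0.05,
                   measurement: str = "?", phase: str = "?",
                   force_z: bool | None = None,
                   force_welch: bool | None = None) -> EffectResult:
    """One (measurement, phase) group comparison.

    ``values`` are per-cycle measurement values, ``labels`` the
    right/wrong outcome of each cycle and ``participants`` the
    participant identifier used as the repeated-measures grouping
    variable.  ``force_z``/``force_welch`` override the Shapiro-Wilk and
    Breusch-Pagan screening decisions; the per-game driver uses them to
    apply one decision to all three phases of a measurement so the
    effect sizes it compares share a scale.
    """
    import pingouin as pg

    res = EffectResult(measurement=measurement, phase=phase)
    res._alpha = alpha
    mask = np.isfinite(values)
    x = np.asarray(values, float)[mask]
    lab = np.asarray(labels)[mask]
    pid = np.asarray(participants)[mask]

    for g in ("right", "wrong"):
        if (lab == g).sum() < 2:
            res.testable = False
            res.reason = f"label {g!r} has fewer than 2 observations"
            return res
    if np.unique(pid).size < 2:
        res.testable = False
        res.reason = "fewer than 2 participants"
        return res

    means = {g: float(np.mean(x[lab == g])) for g in ("right", "wrong")}
    res.affinity = max(means, key=means.get)

    # residuals around group means -> normality screen
    if force_z is None:
        resid = x - np.where(lab == "right", means["right"], means["wrong"])
        sub = resid if resid.size <= 4000 else \
            np.random.default_rng(0).choice(resid, 4000, replace=False)
        do_z = np.std(sub) > 0 and stats.shapiro(sub).pvalue < 0.05
    else:
        do_z = force_z
    if do_z:
        x = _rank_z(x)
        res.ztransformed = True

    if force_welch is None:
        # Breusch-Pagan: residual variance explained by the group indicator
        d = (lab == "wrong").astype(float)
        from statsmodels.stats.diagnostic import het_breuschpagan
        import statsmodels.api as sm
        exog = sm.add_constant(d)
        r2 = x - sm.OLS(x, exog).fit().fittedvalues
        try:
            bp_p = het_breuschpagan(r2, exog)[3]
        except Exception:
            bp_p = 1.0
        welch = bp_p < 0.05
    else:
        welch = force_welch

    df = pd.DataFrame({"y": x, "label": lab, "pid": pid})
    agg = df.groupby(["pid", "label"], as_index=False)["y"].mean()

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if not welch:
            counts = agg.groupby("pid")["label"].nunique()
            complete = counts[counts == 2].index
            if complete.size >= 2:
                sub2 = agg[agg["pid"].isin(complete)]
                aov = pg.rm_anova(data=sub2, dv="y", within="label",
                                  subject="pid", detailed=False, effsize="np2")
                res.F = float(aov["F"].iloc[0])
                res.df1 = float(aov["ddof1"].iloc[0])
                res.df2 = float(aov["ddof2"].iloc[0])
                res.p = float(aov["p_unc"].iloc[0])
                res.effect_size = float(aov["np2"].iloc[0])
                return res
            welch = True  # too few complete participants for pairing
        res.welch_used = True
        aov = pg.welch_anova(data=agg, dv="y", between="label")
        res.F = float(aov["F"].iloc[0])
        res.df1 = float(aov["ddof1"].iloc[0])
        res.df2 = float(aov["ddof2"].iloc[0])
        res.p = float(aov["p_unc"].iloc[0])
        res.effect_size = float(aov["np2"].iloc[0])
    return res


def bonferroni_adjust(p_values: list[float]) -> list[float]:
    """p_adj = min(1, p*m) over a nonempty family of m tests."""
    m = len(p_values)
    if m == 0:
        raise ValueError("empty test family")
    return [min(1.0, p * m) if np.isfinite(p) else p for p in p_values]


def classify_cfe_inferential(results: dict[str, EffectResult],
                             alpha: float = 0.05,
                             pseudo_rule: str = "move_respond") -> CFEResult:
    """Classify one measurement's three per-phase results.

    ``pseudo_rule`` selects which single failed condition downgrades to
    pseudo: ``"move_respond"`` (condition 3, following the worked
    classification of measurements whose effect rebounds in respond) or
    ``"affinity"`` (condition 4).  Ties fail the strict comparisons.
    """
    meas = next(iter(results.values())).measurement
    missing = [ph for ph in PHASES if ph not in results]
    if missing:
        return CFEResult(meas, "none", reason=f"missing phases {missing}")
    rs = [results[ph] for ph in PHASES]
    if not all(r.testable for r in rs):
        why = "; ".join(r.reason for r in rs if not r.testable)
        return CFEResult(meas, "none", reason=f"untestable: {why}")

    es = [r.effect_size for r in rs]
    sig_all = all(r.p_adj < alpha for r in rs)
    max_ss = es[0] > es[1] and es[0] > es[2]
    move_gt = es[1] > es[2]
    aff = len({r.affinity for r in rs}) == 1

    out = CFEResult(meas, "none", sig_all=sig_all, max_in_see_solve=max_ss,
                    move_gt_respond=move_gt, affinity_consistent=aff)
    if sig_all and max_ss and move_gt and aff:
        out.cfe_class = "perfect"
    elif pseudo_rule == "move_respond" and sig_all and max_ss and aff and not move_gt:
        out.cfe_class = "pseudo"
    elif pseudo_rule == "affinity" and sig_all and max_ss and move_gt and not aff:
        out.cfe_class = "pseudo"
    return out


def analyze_game(table: pd.DataFrame, config: RunConfig | None = None
                 ) -> tuple[pd.DataFrame, dict[str, CFEResult],
                            dict[str, dict[str, EffectResult]]]:
    """Full inferential analysis of one game's measurement table.

    ``table`` holds one row per (participant, question, phase,
    measurement) with columns ``participant, question, phase,
    measurement, label, value`` (values already minmax-normalized).
    Returns the effect table (one row per measurement x phase), the
    carry-forward classification per measurement, and the raw results.
    """
    cfg = config or RunConfig()
    results: dict[str, dict[str, EffectResult]] = {}
    order: list[EffectResult] = []
    for meas in MEASUREMENTS:
        # screen each phase, then apply one decision per measurement:
        # mixing Welch and repeated-measures phases would put the three
        # effect sizes on different scales, which the carry-forward
        # ordering conditions cannot tolerate
        per_phase = {}
        for ph in PHASES:
            sub = table[(table["measurement"] == meas) & (table["phase"] == ph)]
            per_phase[ph] = (sub["value"].to_numpy(float),
                             sub["label"].to_numpy(),
                             sub["participant"].to_numpy())
        first = {ph: run_phase_test(*per_phase[ph], alpha=cfg.alpha,
                                    measurement=meas, phase=ph)
                 for ph in PHASES}
        testable = [r for r in first.values() if r.testable]
        any_welch = any(r.welch_used for r in testable)
        any_z = any(r.ztransformed for r in testable)
        results[meas] = {}
        for ph in PHASES:
            r = first[ph]
            if r.testable and (r.welch_used != any_welch
                               or r.ztransformed != any_z):
                r = run_phase_test(*per_phase[ph], alpha=cfg.alpha,
                                   measurement=meas, phase=ph,
                                   force_z=any_z, force_welch=any_welch)
            results[meas][ph] = r
            order.append(r)

    ps = [r.p for r in order]
    for r, p_adj in zip(order, bonferroni_adjust(ps)):
        r.p_adj = p_adj

    cfe = {m: classify_cfe_inferential(results[m], cfg.alpha, cfg.pseudo_rule)
           for m in MEASUREMENTS}

    rows = []
    for m in MEASUREMENTS:
        row: dict = {"measurement": m}
        for ph in PHASES:
            r = results[m][ph]
            row[f"es_{ph}"] = r.effect_size
            row[f"p_adj_{ph}"] = r.p_adj
            row[f"sig_{ph}"] = bool(r.testable and np.isfinite(r.p_adj)
                                    and r.p_adj < cfg.alpha)
            row[f"affinity_{ph}"] = r.affinity
        row["cfe"] = cfe[m].cfe_class
        rows.append(row)
    return pd.DataFrame(rows), cfe, results
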