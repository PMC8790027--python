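"""Window measurements, cycle-level gaze measures, normalization and
feature extraction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from s2mr.measurements import (aoi_transition_shares, compute_ipi,
                               count_eda_peaks, extract_features,
                               minmax_normalize, time_to_first_fixation)
from s2mr.synthetic import make_layout


def _events(pairs):
    """Build an event table from (fix_dur, sacc_amp) pairs."""
    rows, t = [], 0.0
    for fd, amp in pairs:
        rows.append(dict(kind="fixation", t_start=t, t_end=t + fd,
                         x=0.5, y=0.5, amplitude=np.nan, peak_velocity=np.nan))
        t += fd
        rows.append(dict(kind="saccade", t_start=t, t_end=t + 0.05,
                         x=np.nan, y=np.nan, amplitude=amp, peak_velocity=amp / 0.05))
        t += 0.05
    return pd.DataFrame(rows)


class TestEdaPeaks:
    def test_flat_signal_has_no_peaks(self):
        assert count_eda_peaks(np.zeros(500), 0.01) == 0

    def test_three_bumps_counted(self):
        t = np.arange(0, 30, 1 / 64)
        x = np.zeros_like(t)
        for c in (5, 15, 25):
            x += 0.05 * np.exp(-((t - c) ** 2) / 0.5)
        assert count_eda_peaks(x, 0.01) == 3

    def test_count_monotone_in_prominence(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            x = np.cumsum(rng.normal(0, 0.01, 500))
            counts = [count_eda_peaks(x, p) for p in (0.005, 0.01, 0.02, 0.05, 0.1)]
            assert counts == sorted(counts, reverse=True)

    def test_rejects_nonpositive_prominence(self):
        with pytest.raises(ValueError):
            count_eda_peaks(np.zeros(10), 0.0)


class TestIPI:
    FIX_THR, AMP_THR = 0.3, 0.2

    def test_all_local_pairs(self):
        ev = _events([(0.5, 0.05)] * 4)  # long fixation, short saccade
        assert compute_ipi(ev, self.FIX_THR, self.AMP_THR) == pytest.approx(0.2)

    def test_balanced_pairs_give_one(self):
        ev = _events([(0.5, 0.05), (0.1, 0.5)] * 3)
        assert compute_ipi(ev, self.FIX_THR, self.AMP_THR) == pytest.approx(1.0)

    def test_no_pairs_is_missing(self):
        ev = _events([]).reindex(columns=["kind", "t_start", "t_end", "x", "y",
                                          "amplitude", "peak_velocity"])
        assert np.isnan(compute_ipi(ev, self.FIX_THR, self.AMP_THR))

    def test_matches_pair_enumeration_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            pairs = [(rng.uniform(0.05, 0.8), rng.uniform(0.01, 0.6))
                     for _ in range(rng.integers(1, 12))]
            for thr_f, thr_a in ((0.3, 0.2), (0.4, 0.1)):
                ng = sum(1 for fd, a in pairs if fd < thr_f and a > thr_a)
                nl = sum(1 for fd, a in pairs if fd > thr_f and a < thr_a)
                expect = (ng + 1) / (nl + 1)
                assert compute_ipi(_events(pairs), thr_f, thr_a) == \
                    pytest.approx(expect)


def _fix_seq(layout, names):
    """Fixation table visiting named AOIs ('Q', 'R', 'W0', 'W1', 'out')."""
    opts = layout["options"]
    right = next(o for o in opts if o["correct"])
    wrongs = [o for o in opts if not o["correct"]]
    centers = {"Q": (0.5, 0.85), "out": (0.01, 0.5),
               "R": (0.5 * (right["x0"] + right["x1"]),
                     0.5 * (right["y0"] + right["y1"]))}
    for i, w in enumerate(wrongs):
        centers[f"W{i}"] = (0.5 * (w["x0"] + w["x1"]), 0.5 * (w["y0"] + w["y1"]))
    rows = []
    for i, name in enumerate(names):
        x, y = centers[name]
        rows.append(dict(kind="fixation", t_start=float(i), t_end=i + 0.5,
                         x=x, y=y))
    return pd.DataFrame(rows)


class TestAoiTransitions:
    layout = make_layout(correct_index=1)

    def test_question_right_question(self):
        s = aoi_transition_shares(_fix_seq(self.layout, ["Q", "R", "Q"]),
                                  self.layout)
        assert s["q_right"] == 100.0
        assert s["q_wrong"] == 0.0 and s["right_wrong"] == 0.0

    def test_wrong_wrong_pairs_are_uncategorized(self):
        # Q->W0 and W1->R count; W0->W1 belongs to no category
        s = aoi_transition_shares(_fix_seq(self.layout, ["Q", "W0", "W1", "R"]),
                                  self.layout)
        assert s["q_wrong"] == pytest.approx(50.0)
        assert s["right_wrong"] == pytest.approx(50.0)

    def test_outside_fixations_break_chains(self):
        s = aoi_transition_shares(_fix_seq(self.layout, ["Q", "out", "R"]),
                                  self.layout)
        assert all(np.isnan(v) for v in s.values())

    def test_matches_transition_matrix_oracle(self):
        rng = np.random.default_rng(11)
        names = ["Q", "R", "W0", "W1", "out"]
        cats = {frozenset(("Q", "R")): "q_right",
                frozenset(("Q", "W")): "q_wrong",
                frozenset(("R", "W")): "right_wrong"}
        for _ in range(30):
            seq = [names[i] for i in rng.integers(0, 5, size=rng.integers(2, 15))]
            counts = {"q_right": 0, "q_wrong": 0, "right_wrong": 0}
            for a, b in zip(seq[:-1], seq[1:]):
                a2 = "W" if a.startswith("W") else a
                b2 = "W" if b.startswith("W") else b
                if "out" in (a, b) or a2 == b2 and not (a2 == "W" and a != b):
                    continue
                key = cats.get(frozenset((a2, b2)))
                if key:
                    counts[key] += 1
            total = sum(counts.values())
            got = aoi_transition_shares(_fix_seq(self.layout, seq), self.layout)
            if total == 0:
                assert all(np.isnan(v) for v in got.values())
            else:
                for k in counts:
                    assert got[k] == pytest.approx(100.0 * counts[k] / total)

    def test_shares_sum_to_100_when_defined(self):
        rng = np.random.default_rng(4)
        names = ["Q", "R", "W0", "W1"]
        for _ in range(10):
            seq = [names[i] for i in rng.integers(0, 4, size=10)]
            s = aoi_transition_shares(_fix_seq(self.layout, seq), self.layout)
            vals = list(s.values())
            if not np.isnan(vals[0]):
                assert sum(vals) == pytest.approx(100.0)


class TestTimeToFirstFixation:
    layout = make_layout(0)

    def test_fixation_at_onset(self):
        fx = _fix_seq(self.layout, ["Q"])
        assert time_to_first_fixation(0.0, fx, self.layout) == 0.0

    def test_delay_measured_from_onset(self):
        fx = _fix_seq(self.layout, ["out", "Q"])
        fx.loc[1, "t_start"] = 1.4
        assert time_to_first_fixation(0.0, fx, self.layout) == \
            pytest.approx(1.4)

    def test_equals_brute_force_scan(self):
        rng = np.random.default_rng(6)
        for _ in range(10):
            seq = [["Q", "R", "out"][i] for i in rng.integers(0, 3, 8)]
            fx = _fix_seq(self.layout, seq)
            onset = 0.5
            q = self.layout["question"]
            cands = [max(r.t_start - onset, 0.0) for r in fx.itertuples()
                     if r.t_end > onset
                     and q["x0"] <= r.x < q["x1"] and q["y0"] <= r.y < q["y1"]]
            got = time_to_first_fixation(onset, fx, self.layout)
            if cands:
                assert got == pytest.approx(min(cands))
            else:
                assert np.isnan(got)


class TestMinMax:
    def test_basic(self):
        out, flag = minmax_normalize(np.array([1.0, 3.0, 5.0]))
        np.testing.assert_allclose(out, [0.0, 0.5, 1.0])
        assert not flag

    def test_constant_maps_to_zero_with_flag(self):
        out, flag = minmax_normalize(np.array([2.0, 2.0]))
        np.testing.assert_allclose(out, [0.0, 0.0])
        assert flag

    def test_missing_stay_missing_and_empty_errors(self):
        out, _ = minmax_normalize(np.array([1.0, np.nan, 3.0]))
        assert np.isnan(out[1])
        with pytest.raises(ValueError):
            minmax_normalize(np.array([np.nan]))

    @settings(derandomize=True, max_examples=30)
    @given(st.lists(st.floats(-1e3, 1e3), min_size=2, max_size=30))
    def test_idempotent(self, vals):
        once, _ = minmax_normalize(np.asarray(vals))
        twice, _ = minmax_normalize(once)
        np.testing.assert_allclose(twice, once, atol=1e-12)
        assert np.all((once >= 0) & (once <= 1))


class TestFeatures:
    def test_constant_series(self):
        f = extract_features(np.full(20, 3.0))
        assert f["mean"] == 3.0 and f["median"] == 3.0 and f["sd"] == 0.0
        for k in ("skewness", "kurtosis", "ar1", "ar2",
                  "garch_alpha", "garch_beta"):
            assert np.isnan(f[k])

    def test_short_series_missing_markers(self):
        f = extract_features(np.array([1.0]))
        assert f["mean"] == 1.0
        assert np.isnan(f["sd"]) and np.isnan(f["skewness"])
        f = extract_features(np.array([1.0, 2.0, 3.0, 4.0, 5.0]))
        assert np.isfinite(f["sd"]) and np.isfinite(f["skewness"])
        assert np.isnan(f["ar1"])  # needs n >= 6

    def test_ar1_recovery(self):
        rng = np.random.default_rng(0)
        x = np.empty(200)
        acc = 0.0
        for i in range(200):
            acc = 0.6 * acc + rng.normal()
            x[i] = acc
        f = extract_features(x)
        assert f["ar1"] == pytest.approx(0.6, abs=0.1)

    def test_garch_recovery(self):
        rng = np.random.default_rng(100)
        om, al, be = 0.2, 0.1, 0.8
        n = 500
        x = np.empty(n)
        s2 = om / (1 - al - be)
        for i in range(n):
            x[i] = rng.normal(0, np.sqrt(s2))
            s2 = om + al * x[i] ** 2 + be * s2
        f = extract_features(x)
        assert f["garch_alpha"] == pytest.approx(al, abs=0.15)
        assert f["garch_beta"] == pytest.approx(be, abs=0.15)

    def test_deterministic(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0, 1, 50)
        assert extract_features(x) == extract_features(x)


class TestWindowMeasurements:
    def _inputs(self):
        ev = _events([(0.5, 0.05), (0.1, 0.5)])
        pupil = pd.Series(np.zeros(50), index=np.arange(50) / 50.0)
        hr_t = np.array([0.0, 0.4, 0.8])
        hr = np.array([60.0, 62.0, 64.0])
        eda_t = np.arange(0, 1.2, 1 / 64)
        flat = np.zeros_like(eda_t)
        return ev, pupil, hr_t, hr, eda_t, flat

    def test_baseline_pupil_and_mean_hr(self):
        from s2mr.measurements import compute_window_measurements
        ev, pupil, hr_t, hr, eda_t, flat = self._inputs()
        out = compute_window_measurements(ev, pupil, hr_t, hr, eda_t, flat,
                                          flat, flat, (0.0, 1.2))
        assert out["cognitive_load"] == 0.0
        assert out["mean_hr"] == pytest.approx(62.0)
        assert out["eda_peaks"] == 0.0

    def test_windows_without_saccades_marked_missing(self):
        from s2mr.measurements import compute_window_measurements
        ev, pupil, hr_t, hr, eda_t, flat = self._inputs()
        ev = ev[ev["kind"] == "fixation"]
        out = compute_window_measurements(ev, pupil, hr_t, hr, eda_t, flat,
                                          flat, flat, (0.0, 1.2))
        assert np.isnan(out["saccade_velocity"]) and np.isnan(out["ipi"])
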