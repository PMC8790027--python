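"""Run-time configuration for the analysis pipeline.

A flat key/value document (YAML) maps one-to-one onto :class:`RunConfig`;
unknown keys are rejected so typos in config files fail loudly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict
from pathlib import Path

import yaml

PHASES = ("see_solve", "move", "respond")

#: Window-level measurements entering the per-phase statistical family.
MEASUREMENTS = (
    "cognitive_load",
    "ipi",
    "saccade_velocity",
    "mean_hr",
    "eda_peaks",
    "tonic_eda",
    "phasic_eda",
)

#: Cycle-level gaze measurements reported alongside the family above.
CYCLE_MEASUREMENTS = (
    "time_to_first_fixation",
    "aoi_transition_q_right",
    "aoi_transition_q_wrong",
    "aoi_transition_right_wrong",
)


class ConfigError(ValueError):
    """Invalid configuration value."""


@dataclass
class RunConfig:
    """Tunable parameters of the analysis pipeline.

    Attributes
    ----------
    window_s, hop_s:
        Analysis window length and hop in seconds. Successive windows
        overlap by ``window_s - hop_s``.
    baseline_s:
        Length of the stream-initial interval used to normalize EDA, HR
        and pupil diameter per participant.
    velocity_threshold:
        I-VT saccade threshold in normalized screen units per second.
    min_fixation_s:
        Fixations shorter than this are discarded and flanking saccades
        merged.
    peak_prominence:
        Minimum prominence (µS) of a phasic skin-conductance peak.
    movement_k:
        Movement threshold is mean + ``movement_k``·SD of baseline
        skeletal displacement.
    tonic_window_s:
        Width of the centered moving median that estimates tonic EDA.
    eda_smooth_s:
        Width of the moving-average pre-smoother applied to EDA and HR.
    alpha:
        Family-wise significance level (applied after Bonferroni).
    top_fraction:
        Fraction of features counted as "most important" when reading
        carry-forward effects off importance ranks.
    pseudo_rule:
        Which failed condition downgrades a perfect carry-forward effect
        to pseudo in the inferential classifier: ``"move_respond"``
        (effect size not larger in move than respond; default, follows
        the worked examples) or ``"affinity"`` (inconsistent affinity).
    feature_scope:
        Whether feature series span one question ("question") or are
        concatenated across a game ("game").
    windowing:
        "per_phase" tiles windows inside each phase segment;
        "global" tiles the whole cycle and labels windows by midpoint.
    """

    window_s: float = 10.0
    hop_s: float = 5.0
    baseline_s: float = 30.0
    velocity_threshold: float = 1.0
    min_fixation_s: float = 0.06
    peak_prominence: float = 0.01
    movement_k: float = 2.0
    tonic_window_s: float = 4.0
    eda_smooth_s: float = 0.5
    alpha: float = 0.05
    top_fraction: float = 0.10
    pseudo_rule: str = "move_respond"
    feature_scope: str = "question"
    windowing: str = "per_phase"
    smote_neighbors: int = 5
    smote_per_point: int = 4
    holdout_fraction: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hop_s > self.window_s:
            raise ConfigError("hop_s must be <= window_s")
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must lie in (0, 1)")
        if not 0 < self.top_fraction <= 1:
            raise ConfigError("top_fraction must lie in (0, 1]")
        if self.window_s <= 0 or self.hop_s <= 0 or self.baseline_s <= 0:
            raise ConfigError("window_s, hop_s and baseline_s must be positive")
        if self.pseudo_rule not in ("move_respond", "affinity"):
            raise ConfigError("pseudo_rule must be 'move_respond' or 'affinity'")
        if self.feature_scope not in ("question", "game"):
            raise ConfigError("feature_scope must be 'question' or 'game'")
        if self.windowing not in ("per_phase", "global"):
            raise ConfigError("windowing must be 'per_phase' or 'global'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(doc, dict):
            raise ConfigError(f"{path}: config must be a flat mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**doc)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))
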