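"""Feedback selection and prioritization from carry-forward evidence.

Each measurement maps to the remediation the literature attaches to it
(worked examples for high cognitive load, small content hints for high
saccade velocity, gaze-contingent expert overlays for a high
information-processing index, pause suggestions for elevated heart
rate, emotion-regulation support for electrodermal arousal).  A
measurement whose affinity already lies with the desired outcome gets
positive reinforcement instead of remediation.

The plan orders measurements by carry-forward class (perfect before
pseudo before none); within perfect/pseudo by descending see-solve
effect size; within none by the lexicographic significance pattern
(see-solve, then move, then respond) and then effect size; final ties
put undesired-outcome affinity first.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .config import PHASES

__all__ = ["FeedbackEntry", "FeedbackPlan", "feedback_for", "prioritize"]

FEEDBACK_TYPES = (
    "worked_example_or_hint", "easier_problem", "content_hint",
    "gaze_contingent_overlay", "pause_suggestion", "emotion_regulation",
    "encouragement",
)

_MAPPING = {
    "cognitive_load": "worked_example_or_hint",
    "saccade_velocity": "content_hint",
    "ipi": "gaze_contingent_overlay",
    "mean_hr": "pause_suggestion",
    "eda_peaks": "emotion_regulation",
    "phasic_eda": "emotion_regulation",
    "tonic_eda": "emotion_regulation",
}


@dataclass(frozen=True)
class FeedbackEntry:
    priority: int
    measurement: str
    cfe_class: str
    affinity: str | None
    feedback: str
    rationale: str


@dataclass
class FeedbackPlan:
    entries: list[FeedbackEntry] = field(default_factory=list)

    def to_json_obj(self) -> list[dict]:
        out = []
        for e in self.entries:
            d = dict(vars(e))
            for k, v in list(d.items()):
                if isinstance(v, float) and v != v:
                    d[k] = None
            out.append(d)
        return out


def feedback_for(measurement: str, affinity: str | None,
                 desired: str = "right") -> str:
    """Feedback type for a measurement given its outcome affinity.

    Affinity with the desired outcome needs no remediation — the entry
    becomes positive reinforcement.
    """
    if measurement not in _MAPPING:
        raise KeyError(f"unknown measurement {measurement!r}")
    if affinity == desired:
        return "encouragement"
    return _MAPPING[measurement]


def _sort_key(item: dict, desired: str):
    cls_order = {"perfect": 0, "pseudo": 1, "none": 2}[item["cfe_class"]]
    if item["cfe_class"] == "none":
        pattern = tuple(0 if item["sig"].get(ph, False) else 1 for ph in PHASES)
    else:
        pattern = (0, 0, 0)
    es = item.get("es_see_solve")
    es = es if es == es and es is not None else -1.0  # NaN-safe
    undesired_first = 0 if item.get("affinity") not in (None, desired) else 1
    return (cls_order, pattern, -es, undesired_first, item["measurement"])


def prioritize(cfe_by_measurement: dict[str, str],
               evidence: dict[str, dict],
               desired: str = "right") -> FeedbackPlan:
    """Build the ordered feedback plan for one game's analysis.

    ``evidence[measurement]`` carries ``es_see_solve`` (effect size),
    ``affinity`` and ``sig`` (dict phase -> bool).  Empty input yields
    an empty plan.
    """
    items = []
    for meas, cls in cfe_by_measurement.items():
        ev = evidence.get(meas, {})
        items.append(dict(measurement=meas, cfe_class=cls,
                          es_see_solve=ev.get("es_see_solve"),
                          affinity=ev.get("affinity"),
                          sig=ev.get("sig", {})))
    items.sort(key=lambda it: _sort_key(it, desired))
    entries = []
    for i, it in enumerate(items, start=1):
        fb = feedback_for(it["measurement"], it["affinity"], desired)
        why = (f"{it['cfe_class']} carry-forward effect; "
               f"affinity={it['affinity']}; "
               f"see-solve effect size={it['es_see_solve']}")
        entries.append(FeedbackEntry(priority=i, measurement=it["measurement"],
                                     cfe_class=it["cfe_class"],
                                     affinity=it["affinity"], feedback=fb,
                                     rationale=why))
    return FeedbackPlan(entries)
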