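"""Canonical behavioral feature table.

The behavior space has 34 features: 32 GRID questionnaire items describing an
emotional event (rated 1-7) plus two peripheral physiology measures (heart
rate and respiration rate) aggregated per event.  Each feature belongs to one
component of the Component Process Model (CPM): appraisal, motivation,
expression, physiology, or feelings.

``REFERENCE_LOADINGS`` holds the published six-factor varimax loading pattern
for these features (factors D1..D6: valence, arousal, expression, novelty,
action tendency, social norms).  It is used as ground truth by the synthetic
factor-model generator and by EFA recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Feature",
    "FEATURES",
    "FEATURE_IDS",
    "GRID_FEATURE_IDS",
    "PHYSIO_FEATURE_IDS",
    "FEELINGS_FEATURE_IDS",
    "COMPONENTS",
    "component_members",
    "feelings_indices",
    "REFERENCE_LOADINGS",
    "EMOTION_CATEGORIES",
    "N_FEATURES",
]

COMPONENTS = ("appraisal", "motivation", "expression", "physiology", "feelings")

#: the ten discrete emotion categories used for video labeling
EMOTION_CATEGORIES = (
    "fear",
    "anxiety",
    "anger",
    "joy",
    "sadness",
    "satisfaction",
    "surprise",
    "love",
    "disgust",
    "calm",
)


@dataclass(frozen=True)
class Feature:
    """One behavioral feature: id, question text, CPM component, reference loadings."""

    id: str
    question: str
    component: str
    loadings: tuple[float, ...]  # D1..D6


# 32 GRID items in canonical (published-table) order, then the two
# event-aggregated physiology measures.
FEATURES: tuple[Feature, ...] = (
    Feature("feel_good", "Feel good?", "feelings",
            (-0.85, -0.12, -0.17, -0.06, -0.13, -0.03)),
    Feature("unpleasant_for_you", "Feel situation was unpleasant for you?", "appraisal",
            (0.81, 0.20, 0.29, 0.01, 0.10, 0.11)),
    Feature("feel_bad", "Feel bad?", "feelings",
            (0.81, 0.27, 0.25, 0.01, 0.09, 0.06)),
    Feature("want_to_undo", "Want to undo what was happening?", "motivation",
            (0.81, 0.21, 0.15, 0.01, 0.15, 0.17)),
    Feature("want_situation_continue", "Want the situation to continue?", "motivation",
            (-0.81, 0.12, -0.05, -0.07, -0.11, -0.02)),
    Feature("urge_to_stop", "Feel the urge to stop what was happening?", "motivation",
            (0.81, 0.19, 0.17, 0.00, 0.16, 0.16)),
    Feature("unpleasant_for_other", "Feel it was unpleasant for someone else?", "appraisal",
            (0.71, 0.13, 0.07, 0.18, 0.16, 0.18)),
    Feature("feel_calm", "Feel calm?", "feelings",
            (-0.69, -0.19, -0.26, -0.11, -0.18, -0.08)),
    Feature("feel_strong", "Feel strong?", "feelings",
            (-0.54, 0.04, -0.08, -0.08, -0.01, 0.03)),
    Feature("want_to_tackle", "Want to tackle the situation and do s.th.?", "motivation",
            (0.51, 0.35, 0.00, -0.05, 0.38, 0.14)),
    Feature("intense_emotional_state", "Feel an intense emotional state?", "feelings",
            (0.19, 0.82, 0.28, -0.07, 0.06, 0.06)),
    Feature("long_lasting_emotion", "Experience an emotional state for a long time?", "feelings",
            (0.17, 0.79, 0.24, -0.06, 0.06, 0.04)),
    Feature("motivated_attention", "Feel motivated to pay attention to the scene?", "motivation",
            (-0.15, 0.42, -0.08, 0.06, 0.08, 0.05)),
    Feature("lump_in_throat", "Have a feeling of lump in the throat?", "physiology",
            (0.42, 0.40, 0.29, -0.09, 0.14, -0.02)),
    Feature("show_tears", "Show tears?", "expression",
            (0.15, 0.39, 0.01, -0.12, 0.08, -0.13)),
    Feature("important_for_other_goal", "Think it was important for somebody's goal need?", "appraisal",
            (0.06, 0.18, 0.06, 0.01, 0.00, 0.03)),
    Feature("muscles_tensing", "Experience muscles tensing?", "physiology",
            (0.45, 0.21, 0.49, 0.01, 0.22, 0.04)),
    Feature("abrupt_body_movement", "Produce abrupt body movement?", "physiology",
            (0.19, 0.10, 0.48, 0.10, 0.19, 0.09)),
    Feature("close_eyes", "Close your eyes?", "expression",
            (0.23, 0.05, 0.45, 0.00, 0.05, 0.01)),
    Feature("stomach_trouble", "Have stomach trouble?", "expression",
            (0.35, 0.37, 0.45, -0.01, 0.10, -0.04)),
    Feature("feel_warm", "Feel warm?", "physiology",
            (0.02, 0.15, 0.39, -0.02, 0.10, -0.05)),
    Feature("eyebrows_up", "Have eyebrow go up?", "expression",
            (0.15, 0.04, 0.30, 0.27, 0.07, 0.20)),
    Feature("press_lips", "Press lips together?", "expression",
            (0.26, 0.24, 0.28, 0.01, 0.05, 0.05)),
    Feature("jaw_drop", "Have the jaw drop?", "expression",
            (0.06, 0.09, 0.23, 0.26, 0.10, 0.12)),
    Feature("event_unpredictable", "Feel that the event was unpredictable?", "appraisal",
            (0.08, -0.02, 0.09, 0.77, 0.01, 0.06)),
    Feature("occurred_suddenly", "Feel the event occurred suddenly?", "appraisal",
            (0.21, 0.03, 0.13, 0.68, 0.05, 0.06)),
    Feature("consequence_predictable", "Think that the consequence was predictable?", "appraisal",
            (0.06, 0.07, 0.02, -0.42, 0.09, 0.05)),
    Feature("caused_by_chance", "Think the event was caused by chance?", "appraisal",
            (0.01, -0.04, -0.01, 0.42, -0.04, -0.01)),
    Feature("want_to_destroy", "Want to destroy s.th.?", "motivation",
            (0.30, 0.15, 0.20, -0.06, 0.73, 0.05)),
    Feature("want_to_damage", "Want to damage, hit or say s.th. that hurts?", "motivation",
            (0.35, 0.18, 0.18, -0.06, 0.70, 0.12)),
    Feature("violated_norms", "Think it violated laws/social norms?", "appraisal",
            (0.59, 0.07, 0.16, 0.09, 0.18, 0.64)),
    Feature("incongruent_standards", "Think it was incongruent with your standards?", "appraisal",
            (0.61, 0.06, 0.20, 0.06, 0.16, 0.62)),
    Feature("heart_rate", "Heart rate (bpm, event mean)", "physiology",
            (-0.01, 0.02, 0.20, 0.03, -0.06, 0.02)),
    Feature("respiration_rate", "Respiration rate (breaths/min, event mean)", "physiology",
            (0.09, -0.04, 0.15, 0.05, 0.05, 0.06)),
)

N_FEATURES = len(FEATURES)
assert N_FEATURES == 34

FEATURE_IDS: tuple[str, ...] = tuple(f.id for f in FEATURES)
PHYSIO_FEATURE_IDS: tuple[str, ...] = ("heart_rate", "respiration_rate")
GRID_FEATURE_IDS: tuple[str, ...] = tuple(
    f.id for f in FEATURES if f.id not in PHYSIO_FEATURE_IDS
)
FEELINGS_FEATURE_IDS: tuple[str, ...] = tuple(
    f.id for f in FEATURES if f.component == "feelings"
)

#: 34 x 6 published varimax loading pattern, canonical feature order.
REFERENCE_LOADINGS: np.ndarray = np.array([f.loadings for f in FEATURES])


def component_members(component: str) -> tuple[str, ...]:
    """Feature ids belonging to one CPM component."""
    if component not in COMPONENTS:
        raise ValueError(f"unknown component {component!r}; expected one of {COMPONENTS}")
    return tuple(f.id for f in FEATURES if f.component == component)


def feelings_indices() -> np.ndarray:
    """Column indices of the six feelings items in the canonical ordering."""
    return np.array([FEATURE_IDS.index(fid) for fid in FEELINGS_FEATURE_IDS])
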